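"""Solve the sigma-potential of pure DHA.

mu_s(sigma) is the chemical potential a unit surface segment of polarity
sigma would have inside the liquid: negative values mean the liquid offers
attractive partners for that polarity, positive values mean insertion is
penalised. For a nonpolar liquid like DHA, near-zero sigma is cheap while
strongly polar segments are expensive (nothing complements them).
"""

from ilscreen import InteractionParams, make_dha_like, sigma_potential

params = InteractionParams()
dha = make_dha_like()
potential = sigma_potential(dha, params)

print(f"converged: {potential.converged} after {potential.iterations} iterations "
      f"(residual {potential.residual:.2e} RT)")
print(f"{'sigma':>8}  {'mu_s [kcal/mol]':>15}")
for sigma, mu in zip(potential.grid.centers()[::5], potential.mu[::5]):
    print(f"{sigma:+8.3f}  {mu:15.4f}")
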