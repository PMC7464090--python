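"""Independent brute-force oracles used by the test suite.

Deliberately written as plain-Python loops, separate from the package's
vectorised implementations, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math


def energy_scalar(sigma, sigma_prime, aeff, alpha_prime, c_hb, sigma_hb, hb=True):
    """Segment contact energy assembled from scalar arithmetic only."""
    e = aeff * alpha_prime / 2.0 * (sigma + sigma_prime) ** 2
    if hb:
        donor = min(sigma, sigma_prime)
        acceptor = max(sigma, sigma_prime)
        e += aeff * c_hb * min(0.0, donor + sigma_hb) * max(0.0, acceptor - sigma_hb)
    return e


def _self_consistency_rhs(mu, p, E, RT):
    n = len(p)
    out = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if p[j] > 0:
                acc += p[j] * math.exp((mu[j] - E[i][j]) / RT)
        out.append(-RT * math.log(acc))
    return out


def brute_force_segment_potentials(p, E, RT, tol=1e-12):
    """Solve the segment self-consistency equation by an independent
    algorithm: Newton-type root finding on the plain-Python residual
    rhs(mu) - mu (the plain undamped substitution is not a contraction at
    realistic interaction strengths — it settles into a two-cycle)."""
    from scipy.optimize import root

    n = len(p)

    def residual(mu):
        rhs = _self_consistency_rhs(list(mu), p, E, RT)
        return [rhs[i] - mu[i] for i in range(n)]

    solution = root(residual, [0.0] * n, method="hybr", tol=tol)
    if not solution.success:
        raise RuntimeError(f"oracle root solve failed: {solution.message}")
    mu = list(solution.x)
    assert max(abs(r) for r in residual(mu)) <= 1e-9 * RT
    return mu


def brute_force_ln_gamma(solute_areas, solvent_areas, sigmas, aeff, alpha_prime,
                         c_hb, sigma_hb, RT, hb=True):
    """Literal reimplementation of the residual activity-coefficient chain:
    energies, both ensemble solves and the segment-count contraction."""
    n = len(sigmas)
    E = [
        [energy_scalar(sigmas[i], sigmas[j], aeff, alpha_prime, c_hb, sigma_hb, hb)
         for j in range(n)]
        for i in range(n)
    ]
    p_solvent = [a / sum(solvent_areas) for a in solvent_areas]
    p_solute = [a / sum(solute_areas) for a in solute_areas]
    mu_solvent = brute_force_segment_potentials(p_solvent, E, RT)
    mu_reference = brute_force_segment_potentials(p_solute, E, RT)
    total_in_solvent = sum(
        solute_areas[i] / aeff * mu_solvent[i] for i in range(n)
    )
    total_reference = sum(
        solute_areas[i] / aeff * mu_reference[i] for i in range(n)
    )
    return (total_in_solvent - total_reference) / RT


def kendall_tau_pairs(x_ranks, y_ranks):
    """Kendall tau by exhaustive pair concordance counting."""
    n = len(x_ranks)
    concordant = discordant = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x_ranks[i] - x_ranks[j]) * (y_ranks[i] - y_ranks[j])
            if s > 0:
                concordant += 1
            elif s < 0:
                discordant += 1
    return (concordant - discordant) / (n * (n - 1) / 2)
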