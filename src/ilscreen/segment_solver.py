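"""Self-consistent segment chemical potentials (the sigma-potential).

The chemical potential mu_s(sigma) of a unit surface segment of polarity
sigma immersed in a solvent ensemble P_S(sigma') satisfies the nonlinear
self-consistency relation

    mu_s(sigma) = -RT * ln  sum_{sigma'} P_S(sigma') *
                  exp[ (mu_s(sigma') - E(sigma, sigma')) / RT ]

where E is the pairwise segment contact energy (misfit + hydrogen bond).
mu here is stored per *segment* (kcal/mol); dividing by the effective
segment area a_eff recovers the per-area sigma-potential curve plotted in
sigma-potential diagrams.  The continuous integral over sigma' is discretised
as the probability-weighted sum over grid bins (P_S already normalised).

The equation is solved by damped successive substitution from mu = 0:
    mu <- damping * rhs(mu) + (1 - damping) * mu
which is robust for this contraction-like map.  Convergence is declared on
max |rhs(mu) - mu| / RT <= tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .exceptions import ConvergenceError, ValidationError
from .interaction_model import InteractionParams, energy_matrix
from .sigma_profiles import MixtureProfile, SigmaGrid, SigmaProfile, mix_profiles

__all__ = [
    "SolverSettings",
    "SegmentPotential",
    "solve_segment_potentials",
    "sigma_potential",
]


@dataclass(frozen=True)
class SolverSettings:
    """Fixed-point iteration controls (tolerance is on mu/RT, dimensionless)."""

    tolerance: float = 1e-10
    max_iterations: int = 10_000
    damping: float = 0.5

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")
        if not (0.0 < self.damping <= 1.0):
            raise ValidationError("damping must be in (0, 1]")


@dataclass
class SegmentPotential:
    """mu_s(sigma) per segment (kcal/mol) over the grid, with solver diagnostics."""

    grid: SigmaGrid
    mu: np.ndarray
    converged: bool
    iterations: int
    residual: float


DEFAULT_SETTINGS = SolverSettings()


def _fixed_point_rhs(mu: np.ndarray, log_p: np.ndarray, E: np.ndarray,
                     RT: float) -> np.ndarray:
    # rhs_i = -RT * logsumexp_j [ log p_j + (mu_j - E_ij)/RT ]
    return -RT * logsumexp(log_p[None, :] + (mu[None, :] - E) / RT, axis=1)


def solve_segment_potentials(
    mixture: MixtureProfile,
    params: InteractionParams,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> SegmentPotential:
    """Solve the segment self-consistency equation for a solvent ensemble.

    Raises :class:`ConvergenceError` (carrying the last residual) if the
    damped iteration does not reach tolerance within ``max_iterations``.
    """
    p = np.asarray(mixture.p_s, dtype=float)
    if p.sum() <= 0:
        raise ValidationError("mixture distribution sums to zero")
    E = energy_matrix(mixture.grid, params).values
    RT = params.RT
    with np.errstate(divide="ignore"):
        log_p = np.log(p)
    mu = np.zeros(mixture.grid.n_bins)
    residual = np.inf
    for iteration in range(1, settings.max_iterations + 1):
        rhs = _fixed_point_rhs(mu, log_p, E, RT)
        residual = float(np.max(np.abs(rhs - mu)) / RT)
        if residual <= settings.tolerance:
            return SegmentPotential(
                grid=mixture.grid, mu=rhs, converged=True,
                iterations=iteration, residual=residual,
            )
        mu = settings.damping * rhs + (1.0 - settings.damping) * mu
    raise ConvergenceError(
        f"segment solver did not converge in {settings.max_iterations} iterations "
        f"(residual {residual:.3e})",
        residual=residual,
        iterations=settings.max_iterations,
    )


def sigma_potential(
    profile: SigmaProfile,
    params: InteractionParams,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> SegmentPotential:
    """Sigma-potential of a pure compound (its own single-component ensemble)."""
    return solve_segment_potentials(mix_profiles([(profile, 1.0)]), params, settings)
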