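"""Compound chemical potentials, activity coefficients and extraction capacity.

The residual chemical potential of a solute X in a solvent ensemble S is the
area-weighted sum of the solvent's segment potentials over the solute's
profile,

    mu_X^S = sum_sigma n_X(sigma) * mu_S(sigma),   n_X(sigma) = A_X(sigma)/a_eff,

and the activity coefficient follows from the symmetric (pure-liquid
reference) convention

    ln gamma = (mu_X^S - mu_X^X) / RT  [+ Staverman-Guggenheim combinatorial],

so gamma = 1 for a solute in itself by construction.  Infinite dilution is
realised *exactly* by evaluating mu_X in the unperturbed solvent ensemble
(solute mole fraction identically zero) — no numerical limit is taken.  The
screening metric is the capacity C_inf = 1/gamma_inf: large capacity means
strong solute-solvent affinity and hence extraction power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .exceptions import GridMismatchError, ValidationError
from .interaction_model import InteractionParams
from .segment_solver import (
    DEFAULT_SETTINGS,
    SegmentPotential,
    SolverSettings,
    solve_segment_potentials,
)
from .sigma_profiles import MixtureProfile, SigmaProfile, mix_profiles

__all__ = [
    "ActivityResult",
    "CapacityResult",
    "compound_chemical_potential",
    "ln_gamma",
    "gamma_infinite_dilution",
    "capacity",
]

logger = logging.getLogger(__name__)

# Staverman-Guggenheim normalisers: standard segment volume (A^3) and area
# (A^2) of the open segment-model parametrization, coordination number z = 10.
SG_R_NORM = 66.69
SG_Q_NORM = 79.53
SG_Z = 10.0


@dataclass
class ActivityResult:
    solute_id: str
    solvent_id: str
    ln_gamma: float
    combinatorial_included: bool
    temperature: float

    @property
    def gamma(self) -> float:
        return math.exp(self.ln_gamma)


@dataclass
class CapacityResult:
    """Capacity C_inf = 1/gamma_inf and its base-10 logarithm."""

    c_inf: float
    log10_c_inf: float


def compound_chemical_potential(
    solute: SigmaProfile,
    solvent_mu: SegmentPotential,
    params: InteractionParams,
) -> float:
    """Residual chemical potential (kcal/mol) of ``solute`` in the solvent
    ensemble whose segment potentials are ``solvent_mu``."""
    if solute.grid != solvent_mu.grid:
        raise GridMismatchError("solute profile and segment potential grids differ")
    n_segments = solute.areas / params.aeff
    return float(np.dot(n_segments, solvent_mu.mu))


def _sg_combinatorial_inf(
    solute_area: float,
    solute_volume: float,
    solvent_area: float,
    solvent_volume: float,
) -> float:
    """Staverman-Guggenheim ln gamma_comb at infinite dilution.

    Uses normalised volume (r) and area (q) parameters; at x -> 0 the
    volume-fraction/mole-fraction ratio tends to r_i/r_S and the
    area-fraction ratio to q_i/q_S.
    """
    r_i = solute_volume / SG_R_NORM
    q_i = solute_area / SG_Q_NORM
    r_s = solvent_volume / SG_R_NORM
    q_s = solvent_area / SG_Q_NORM
    phi = r_i / r_s          # phi_i / x_i in the dilute limit
    phi_over_theta = (r_i * q_s) / (r_s * q_i)
    return (
        math.log(phi) + 1.0 - phi
        - (SG_Z / 2.0) * q_i * (math.log(phi_over_theta) + 1.0 - phi_over_theta)
    )


def ln_gamma(
    solute: SigmaProfile,
    solvent: MixtureProfile,
    params: InteractionParams,
    settings: SolverSettings = DEFAULT_SETTINGS,
    combinatorial: bool | None = None,
    _solute_reference_mu: float | None = None,
) -> ActivityResult:
    """Activity coefficient of ``solute`` in the ``solvent`` ensemble.

    ``combinatorial=None`` enables the Staverman-Guggenheim term when cavity
    volumes are available on both sides and disables it (with a logged
    warning) otherwise; ``True`` without volumes is an error.
    ``_solute_reference_mu`` lets callers reuse a precomputed pure-solute
    reference potential across many solvents (screening loop).
    """
    if solute.grid != solvent.grid:
        raise GridMismatchError("solute and solvent grids differ")
    volumes_present = (
        solute.cavity_volume is not None and solvent.cavity_volume is not None
    )
    if combinatorial is None:
        combinatorial = volumes_present
        if not volumes_present:
            logger.warning(
                "cavity volumes missing; combinatorial term disabled for %s in %s",
                solute.compound_id, solvent.label,
            )
    elif combinatorial and not volumes_present:
        raise ValidationError(
            "combinatorial term requested but cavity volumes are missing"
        )

    solvent_potential = solve_segment_potentials(solvent, params, settings)
    mu_in_solvent = compound_chemical_potential(solute, solvent_potential, params)
    if _solute_reference_mu is None:
        reference_potential = solve_segment_potentials(
            mix_profiles([(solute, 1.0)]), params, settings
        )
        _solute_reference_mu = compound_chemical_potential(
            solute, reference_potential, params
        )
    value = (mu_in_solvent - _solute_reference_mu) / params.RT
    if combinatorial:
        value += _sg_combinatorial_inf(
            solute.total_area,
            solute.cavity_volume,  # type: ignore[arg-type]
            solvent.total_area,
            solvent.cavity_volume,  # type: ignore[arg-type]
        )
    return ActivityResult(
        solute_id=solute.compound_id,
        solvent_id=solvent.label,
        ln_gamma=value,
        combinatorial_included=combinatorial,
        temperature=params.T,
    )


def gamma_infinite_dilution(
    solute: SigmaProfile,
    solvent: MixtureProfile,
    params: InteractionParams,
    settings: SolverSettings = DEFAULT_SETTINGS,
    combinatorial: bool | None = None,
    _solute_reference_mu: float | None = None,
) -> ActivityResult:
    """gamma_inf of ``solute`` in ``solvent``: the solvent ensemble contains no
    solute, so the infinite-dilution limit is exact by construction."""
    return ln_gamma(
        solute, solvent, params, settings,
        combinatorial=combinatorial,
        _solute_reference_mu=_solute_reference_mu,
    )


def capacity(activity: ActivityResult | float) -> CapacityResult:
    """Extraction capacity C_inf = 1/gamma_inf (and log10 thereof)."""
    gamma = activity.gamma if isinstance(activity, ActivityResult) else float(activity)
    if not (gamma > 0):
        raise ValidationError(f"gamma must be > 0, got {gamma}")
    c = 1.0 / gamma
    return CapacityResult(c_inf=c, log10_c_inf=math.log10(c))
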