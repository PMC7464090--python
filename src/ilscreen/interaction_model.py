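"""Segment pair interaction energies: misfit, hydrogen bonding, van der Waals.

Two surface segments of charge densities sigma and sigma' brought into contact
pay an electrostatic *misfit* penalty when their screening charges do not
cancel,

    E_misfit(sigma, sigma') = a_eff * (alpha'/2) * (sigma + sigma')^2 >= 0,

and gain a *hydrogen-bond* energy when a strongly negative (donor, H-bearing)
segment meets a strongly positive (acceptor) segment beyond the threshold
sigma_hb,

    E_hb = a_eff * c_hb * min(0, sigma_d + sigma_hb) * max(0, sigma_a - sigma_hb) <= 0,

with donor = min(sigma, sigma'), acceptor = max(sigma, sigma') (H atoms screen
negatively, so the more negative segment is the donor).  A compound-additive
van der Waals term a_eff*(tau + tau') exists behind ``vdw_mode``; it cancels
between mixture and pure reference states and is off by default.

Default constants are the open published segment-model parametrization
(a_eff = 7.5 A^2, sigma_hb = 0.0084 e/A^2, a_eff*alpha' = 16466.72 and
a_eff*c_hb = 85580 kcal A^4 mol^-1 e^-2); energies are kcal/mol per segment
contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError
from .sigma_profiles import SigmaGrid

__all__ = [
    "InteractionParams",
    "EnergyMatrix",
    "misfit_energy",
    "hb_energy",
    "vdw_energy",
    "energy_matrix",
]

#: kcal mol^-1 K^-1
GAS_CONSTANT_KCAL = 1.9872e-3


@dataclass(frozen=True)
class InteractionParams:
    """All model constants; energies in kcal/mol, areas in A^2, sigma in e/A^2."""

    aeff: float = 7.5
    alpha_prime: float = 16466.72 / 7.5
    c_hb: float = 85580.0 / 7.5
    sigma_hb: float = 0.0084
    tau_vdw: dict[str, float] = field(default_factory=dict)
    R: float = GAS_CONSTANT_KCAL
    T: float = 298.15
    hb_enabled: bool = True
    vdw_mode: str = "off"  # off | compound_additive

    def __post_init__(self) -> None:
        if self.aeff <= 0:
            raise ValidationError("aeff must be > 0")
        if self.sigma_hb < 0:
            raise ValidationError("sigma_hb must be >= 0")
        if self.c_hb < 0:
            raise ValidationError("c_hb must be >= 0")
        if self.T <= 0:
            raise ValidationError("temperature must be > 0")
        if self.vdw_mode not in ("off", "compound_additive"):
            raise ValidationError(f"unknown vdw_mode {self.vdw_mode!r}")

    @property
    def RT(self) -> float:
        return self.R * self.T

    @classmethod
    def from_dict(cls, d: dict) -> "InteractionParams":
        """Build from the YAML config keys (missing keys keep defaults)."""
        mapping = {
            "aeff": "aeff",
            "alpha_prime": "alpha_prime",
            "c_hb": "c_hb",
            "sigma_hb": "sigma_hb",
            "temperature_K": "T",
            "hb_enabled": "hb_enabled",
            "vdw_mode": "vdw_mode",
        }
        kwargs = {attr: d[key] for key, attr in mapping.items() if key in d}
        return cls(**kwargs)


@dataclass
class EnergyMatrix:
    """Pairwise segment contact energies E(sigma_i, sigma_j) on a grid (symmetric)."""

    grid: SigmaGrid
    values: np.ndarray


def misfit_energy(
    sigma: float, sigma_prime: float, params: InteractionParams
) -> float:
    """Electrostatic misfit penalty per segment contact (>= 0, kcal/mol)."""
    return params.aeff * (params.alpha_prime / 2.0) * (sigma + sigma_prime) ** 2


def hb_energy(sigma: float, sigma_prime: float, params: InteractionParams) -> float:
    """Hydrogen-bond energy per segment contact (<= 0, kcal/mol).

    Zero unless the donor (more negative) segment is below -sigma_hb and the
    acceptor (more positive) segment is above +sigma_hb.
    """
    donor = min(sigma, sigma_prime)
    acceptor = max(sigma, sigma_prime)
    return (
        params.aeff
        * params.c_hb
        * min(0.0, donor + params.sigma_hb)
        * max(0.0, acceptor - params.sigma_hb)
    )


def vdw_energy(tau: float, tau_prime: float, params: InteractionParams) -> float:
    """Compound-additive van der Waals term a_eff*(tau + tau')."""
    return params.aeff * (tau + tau_prime)


def energy_matrix(grid: SigmaGrid, params: InteractionParams) -> EnergyMatrix:
    """Misfit (+ hydrogen-bond, if enabled) energies for every bin pair."""
    s = grid.centers()
    si, sj = np.meshgrid(s, s, indexing="ij")
    values = params.aeff * (params.alpha_prime / 2.0) * (si + sj) ** 2
    if params.hb_enabled:
        donor = np.minimum(si, sj)
        acceptor = np.maximum(si, sj)
        values += (
            params.aeff
            * params.c_hb
            * np.minimum(0.0, donor + params.sigma_hb)
            * np.maximum(0.0, acceptor - params.sigma_hb)
        )
    return EnergyMatrix(grid=grid, values=values)
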