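"""Synthetic sigma-profile generator.

Real sigma profiles come from quantum-chemistry cavity calculations that are
not part of this package.  This module generates profiles with the *stated
statistical structure* of those inputs so that every downstream stage
(solver, activity coefficients, screening, trend reports) is exercisable and
testable without any quantum-chemistry dependency:

* the DHA-like solute is nonpolar-dominated (>= 80% of its surface inside
  |sigma| <= 0.01 e/A^2) with a small hydrogen-*donor* peak at -0.018 (the
  carboxylic H) and a small *acceptor* peak at +0.012 (carboxylate oxygens);
* cations screen negatively; lengthening the N-alkyl chain adds nonpolar
  surface and dilutes the charge (larger total area, smaller mean |sigma|);
* small inorganic anions screen as sharp strongly-positive acceptor peaks,
  large organic anions as broader, less positive ones.

Only these qualitative, monotone features are emulated — no claim of
chemical accuracy is made.  Generation is deterministic (optional seeded
multiplicative noise for robustness studies; default off).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy.special import erf

from .exceptions import ValidationError
from .ion_library import CATION_FAMILIES, Ion
from .sigma_profiles import DEFAULT_GRID, SigmaGrid, SigmaProfile

__all__ = [
    "PeakSpec",
    "ProfileSpec",
    "generate_profile",
    "make_dha_like",
    "make_ion_like",
    "anion_size_score",
]

#: cavity volume heuristic: V = k * A, the near-linear area-volume relation of
#: chain-like molecules, tuned to plausible molecular volumes
_VOLUME_COEFF = 0.85


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian contribution: center (e/A^2), s.d. width (e/A^2), area (A^2)."""

    center: float
    width: float
    area: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValidationError("peak width must be > 0")
        if self.area < 0:
            raise ValidationError("peak area must be >= 0")


@dataclass(frozen=True)
class ProfileSpec:
    compound_id: str
    peaks: tuple[PeakSpec, ...]
    cavity_volume: float | None = None
    noise_sd: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if sum(p.area for p in self.peaks) <= 0:
            raise ValidationError("total requested area must be > 0")


def _binned_gaussian(center: float, width: float, grid: SigmaGrid) -> np.ndarray:
    """Gaussian mass integrated over each bin (edges at center +/- spacing/2)."""
    edges = np.concatenate(
        [grid.centers() - grid.spacing / 2.0, [grid.sigma_max + grid.spacing / 2.0]]
    )
    z = (edges - center) / (width * math.sqrt(2.0))
    cdf = 0.5 * (1.0 + erf(z))
    return np.diff(cdf)


def generate_profile(spec: ProfileSpec, grid: SigmaGrid = DEFAULT_GRID) -> SigmaProfile:
    """Sum of bin-integrated Gaussian peaks, renormalised so the profile total
    equals the sum of requested peak areas exactly."""
    areas = np.zeros(grid.n_bins)
    for peak in spec.peaks:
        if not (grid.sigma_min <= peak.center <= grid.sigma_max):
            raise ValidationError(
                f"peak center {peak.center} outside grid "
                f"[{grid.sigma_min}, {grid.sigma_max}]"
            )
        shape = _binned_gaussian(peak.center, peak.width, grid)
        mass = shape.sum()
        if mass <= 0:
            raise ValidationError("peak has no mass on the grid")
        areas += peak.area * shape / mass
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        factors = np.clip(1.0 + spec.noise_sd * rng.standard_normal(grid.n_bins), 0.0, None)
        areas = areas * factors
    total = sum(p.area for p in spec.peaks)
    areas = areas * (total / areas.sum())
    volume = spec.cavity_volume
    if volume is None:
        volume = _VOLUME_COEFF * total
    return SigmaProfile(
        compound_id=spec.compound_id, grid=grid, areas=areas, cavity_volume=volume
    )


#: DHA-like solute: long polyunsaturated hydrocarbon surface (nonpolar bulk)
#: plus the carboxylic acid's donor (-0.018) and acceptor (+0.012) shoulders.
DHA_SPEC = ProfileSpec(
    compound_id="DHA",
    peaks=(
        PeakSpec(center=-0.004, width=0.003, area=190.0),
        PeakSpec(center=+0.004, width=0.003, area=190.0),
        PeakSpec(center=-0.018, width=0.0015, area=14.0),
        PeakSpec(center=+0.012, width=0.0015, area=22.0),
    ),
)


def make_dha_like(grid: SigmaGrid = DEFAULT_GRID) -> SigmaProfile:
    """Fixed DHA-like solute profile (deterministic packaged spec)."""
    return generate_profile(DHA_SPEC, grid)


def anion_size_score(ion: Ion) -> int:
    """Deterministic size proxy for an anion: count of element symbols and
    digit-implied atoms parsed from the formula-like abbreviation.

    Small monatomic anions score lowest; bulky organic anions score highest.
    Only the monotone qualitative effect of this score is relied upon.
    """
    formula = ion.abbreviation.strip("[]+-")
    tokens = re.findall(r"[A-Z][a-z]?|\d+", formula)
    score = 0
    for tok in tokens:
        score += int(tok) if tok.isdigit() else 1
    return score


def _cation_spec(ion: Ion) -> ProfileSpec:
    """Polar head of fixed charge density plus a neutral tail whose area grows
    with chain length: charge dilution by added nonpolar surface.

    The head sits at -0.007 e/A^2 — inside the hydrogen-bond threshold band,
    since quaternary/ring cation surfaces are weak hydrogen-bond donors.
    """
    n = ion.alkyl_chain_length or 1
    head_area = {
        "ammonium": 40.0,
        "imidazolium": 45.0,
        "pyrrolidinium": 48.0,
        "pyridinium": 50.0,
        "piperidinium": 52.0,
    }[ion.family]
    tail_area = 40.0 + 18.0 * n  # ~ one CH2 worth of COSMO surface per carbon
    return ProfileSpec(
        compound_id=ion.abbreviation,
        peaks=(
            PeakSpec(center=-0.007, width=0.003, area=head_area),
            PeakSpec(center=0.0, width=0.0035, area=tail_area),
        ),
    )


def _anion_spec(ion: Ion) -> ProfileSpec:
    """Acceptor peak whose position/sharpness follow the size proxy: small
    inorganic anions are sharp, strongly positive acceptors; bulky organic
    anions are broader, less positive, with an extra nonpolar skeleton peak."""
    s = anion_size_score(ion)
    center = 0.021 - 0.0006 * min(s, 12)
    width = 0.0015 + 0.0003 * min(s, 10)
    organic = ion.anion_class == "organic"
    peaks = [
        PeakSpec(
            center=max(center - (0.002 if organic else 0.0), 0.012),
            width=width + (0.0008 if organic else 0.0),
            area=25.0 + 6.0 * min(s, 15),
        )
    ]
    if organic:
        peaks.append(PeakSpec(center=0.002, width=0.003, area=10.0 + 6.0 * min(s, 15)))
    return ProfileSpec(compound_id=ion.abbreviation, peaks=tuple(peaks))


def make_ion_like(ion: Ion, grid: SigmaGrid = DEFAULT_GRID) -> SigmaProfile:
    """Deterministic heuristic sigma profile for one library ion."""
    if ion.is_cation:
        if ion.family not in CATION_FAMILIES:
            raise ValidationError(f"unknown cation family {ion.family!r}")
        spec = _cation_spec(ion)
    else:
        spec = _anion_spec(ion)
    return generate_profile(spec, grid)
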