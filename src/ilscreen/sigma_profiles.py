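"""Sigma-profile data model, file I/O and mole-fraction mixing.

A sigma profile p_X(sigma) is the histogram of a molecule's screening-surface
area as a function of surface charge density sigma (e/A^2).  It is the sole
molecular descriptor of the segment interaction model: every downstream
quantity (segment potentials, activity coefficients, capacities) is a
functional of these histograms.

Profiles store *areas* per bin (A^2); probability distributions appear only in
:class:`MixtureProfile`, where the ensemble distribution of a solvent is

    P_S(sigma) = sum_i x_i * p_i(sigma) / sum_i x_i * A_i

i.e. mole-fraction-weighted areas normalised by the weighted total cavity area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, GridMismatchError, ValidationError

__all__ = [
    "SigmaGrid",
    "SigmaProfile",
    "MixtureProfile",
    "DEFAULT_GRID",
    "read_sigma_profile",
    "write_sigma_profile",
    "mix_profiles",
]


@dataclass(frozen=True)
class SigmaGrid:
    """Uniform discretisation of the charge-density axis, symmetric about 0.

    The default [-0.025, +0.025] e/A^2 with 0.001 spacing (51 bins) is the
    convention of the open sigma-profile databases.
    """

    sigma_min: float = -0.025
    sigma_max: float = 0.025
    spacing: float = 0.001

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValidationError("grid spacing must be > 0")
        if not np.isclose(self.sigma_min, -self.sigma_max):
            raise ValidationError("grid must be symmetric about 0")
        n = (self.sigma_max - self.sigma_min) / self.spacing
        if not np.isclose(n, round(n)):
            raise ValidationError("grid span must be an integer number of bins")

    @property
    def n_bins(self) -> int:
        return int(round((self.sigma_max - self.sigma_min) / self.spacing)) + 1

    def centers(self) -> np.ndarray:
        """Bin centre sigma values, length ``n_bins``."""
        return self.sigma_min + self.spacing * np.arange(self.n_bins)

    def nearest_bin(self, sigma: float) -> int:
        """Index of the bin whose centre is closest to ``sigma``.

        Raises :class:`ValidationError` if sigma falls outside the grid by
        more than half a spacing.
        """
        idx = int(round((sigma - self.sigma_min) / self.spacing))
        if idx < 0 or idx >= self.n_bins:
            raise ValidationError(
                f"sigma={sigma} outside grid [{self.sigma_min}, {self.sigma_max}]"
            )
        return idx


DEFAULT_GRID = SigmaGrid()


@dataclass
class SigmaProfile:
    """Discretised sigma profile of one species: surface area (A^2) per bin."""

    compound_id: str
    grid: SigmaGrid
    areas: np.ndarray
    total_area: float = None  # type: ignore[assignment]
    cavity_volume: float | None = None

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (self.grid.n_bins,):
            raise ValidationError(
                f"areas length {self.areas.shape} != grid bins {self.grid.n_bins}"
            )
        if np.any(self.areas < 0):
            raise ValidationError("profile areas must be non-negative")
        s = float(self.areas.sum())
        if self.total_area is None:
            self.total_area = s
        elif abs(s - self.total_area) > 1e-9 * max(1.0, abs(self.total_area)):
            raise ValidationError(
                f"sum(areas)={s} inconsistent with total_area={self.total_area}"
            )
        if self.total_area == 0.0:
            warnings.warn(
                f"profile '{self.compound_id}' has zero total area (degenerate)",
                stacklevel=2,
            )

    def probabilities(self) -> np.ndarray:
        """Normalised area distribution p(sigma); requires total_area > 0."""
        if self.total_area <= 0:
            raise ValidationError("cannot normalise a zero-area profile")
        return self.areas / self.total_area


@dataclass
class MixtureProfile:
    """Ensemble sigma distribution P_S(sigma) of a (possibly multi-component) solvent."""

    grid: SigmaGrid
    p_s: np.ndarray
    total_area: float
    components: list[tuple[str, float]] = field(default_factory=list)
    cavity_volume: float | None = None

    def __post_init__(self) -> None:
        self.p_s = np.asarray(self.p_s, dtype=float)
        if self.p_s.shape != (self.grid.n_bins,):
            raise ValidationError("p_s length does not match grid")
        if np.any(self.p_s < 0):
            raise ValidationError("p_s must be non-negative")
        if abs(self.p_s.sum() - 1.0) > 1e-12 * self.grid.n_bins:
            raise ValidationError(f"p_s must sum to 1, got {self.p_s.sum()!r}")
        xs = sum(x for _, x in self.components)
        if self.components and abs(xs - 1.0) > 1e-9:
            raise ValidationError(f"mole fractions must sum to 1, got {xs!r}")

    @property
    def label(self) -> str:
        return "+".join(cid for cid, _ in self.components) or "<mixture>"


def read_sigma_profile(path: str | Path, grid: SigmaGrid = DEFAULT_GRID) -> SigmaProfile:
    """Read a two-column text sigma profile and bin it onto ``grid``.

    Dialect: optional ``#`` header/comment lines (recognised keys ``area``,
    ``volume``, ``compound``), then whitespace-separated rows of
    ``sigma  area`` with sigma in e/A^2 and area in A^2.  Values are assigned
    to the nearest grid bin; the profile total is the column sum.
    """
    path = Path(path)
    areas = np.zeros(grid.n_bins)
    volume: float | None = None
    compound_id = path.stem
    n_rows = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            for token in line.lstrip("#").split():
                if "=" in token:
                    key, _, val = token.partition("=")
                    if key == "volume":
                        volume = float(val)
                    elif key == "compound":
                        compound_id = val
            continue
        parts = line.split()
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected two columns, got {line!r}")
        sigma, area = float(parts[0]), float(parts[1])
        if area < 0:
            raise ValidationError(f"{path}:{lineno}: negative area {area}")
        areas[grid.nearest_bin(sigma)] += area
        n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: no data rows")
    return SigmaProfile(compound_id=compound_id, grid=grid, areas=areas,
                        cavity_volume=volume)


def write_sigma_profile(profile: SigmaProfile, path: str | Path) -> None:
    """Write ``profile`` in the two-column text dialect (round-trip exact)."""
    path = Path(path)
    lines = [f"# compound={profile.compound_id}", f"# area={profile.total_area:.10g}"]
    if profile.cavity_volume is not None:
        lines.append(f"# volume={profile.cavity_volume:.10g}")
    centers = profile.grid.centers()
    for sigma, area in zip(centers, profile.areas):
        lines.append(f"{sigma:+.6f} {area:.12e}")
    path.write_text("\n".join(lines) + "\n")


def mix_profiles(
    components: list[tuple[SigmaProfile, float]],
) -> MixtureProfile:
    """Mole-fraction mixing of sigma profiles into an ensemble distribution.

    Areas are weighted by mole fraction and the result normalised by the
    weighted total area, so ``p_s`` is the probability that a randomly chosen
    surface patch of the solvent ensemble has charge density sigma.
    """
    if not components:
        raise ValidationError("mix_profiles requires at least one component")
    grid = components[0][0].grid
    fractions = np.array([x for _, x in components], dtype=float)
    if np.any(fractions < 0):
        raise ValidationError("mole fractions must be non-negative")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValidationError(f"mole fractions must sum to 1, got {fractions.sum()}")
    weighted = np.zeros(grid.n_bins)
    total_area = 0.0
    volume = 0.0
    have_volumes = True
    for prof, x in components:
        if prof.grid != grid:
            raise GridMismatchError(
                f"profile '{prof.compound_id}' is on a different grid"
            )
        weighted += x * prof.areas
        total_area += x * prof.total_area
        if prof.cavity_volume is None:
            have_volumes = False
        else:
            volume += x * prof.cavity_volume
    if total_area <= 0:
        raise ValidationError("mixture has zero total area")
    return MixtureProfile(
        grid=grid,
        p_s=weighted / total_area,
        total_area=total_area,
        components=[(p.compound_id, x) for p, x in components],
        cavity_volume=volume if have_volumes else None,
    )
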