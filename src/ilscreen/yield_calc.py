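"""Experimental-validation arithmetic: DHA yield from GC-FID peak areas.

After extraction and transesterification the fatty acid methyl esters
(FAMEs) are quantified by gas chromatography.  The DHA fraction is

    DHA %wt = 100 * (DHA peak area) / (total FAME peak area)
    DHA content (mg/g) = total FAMEs (mg/g) * DHA% / 100

and the screening model is judged by the *rank* concordance between the
predicted capacities and the measured DHA yields across the validated
ionic liquids (Spearman correlation).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
from scipy import stats

from .exceptions import ValidationError

__all__ = [
    "GCPeakTable",
    "YieldRecord",
    "dha_percent",
    "dha_content",
    "capacity_yield_concordance",
    "load_validation_table",
]

#: peak names with this prefix are internal standards, excluded from the total
INTERNAL_STANDARD_PREFIX = "IS"

_DHA_NAMES = {"DHA", "C22:6", "C22:6N-3", "C22:6N3"}


@dataclass
class GCPeakTable:
    """FAME peak areas (detector units) plus total FAMEs per g biomass."""

    peak_areas: dict[str, float]
    total_fames: float

    def __post_init__(self) -> None:
        for name, area in self.peak_areas.items():
            if area < 0:
                raise ValidationError(f"negative peak area for {name!r}")
        if self.total_fames < 0:
            raise ValidationError("total_fames must be >= 0")

    @classmethod
    def from_csv(cls, path: str | Path, total_fames: float) -> "GCPeakTable":
        df = pd.read_csv(path)
        if not {"fame", "area"}.issubset(df.columns):
            raise ValidationError(f"{path}: expected columns 'fame,area'")
        return cls(
            peak_areas=dict(zip(df["fame"].astype(str), df["area"].astype(float))),
            total_fames=total_fames,
        )


@dataclass
class YieldRecord:
    il_label: str
    dha_percent: float
    dha_content: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.dha_percent <= 100.0):
            raise ValidationError("dha_percent must be in [0, 100]")
        if self.dha_content < 0:
            raise ValidationError("dha_content must be >= 0")


def _find_dha_peak(table: GCPeakTable) -> str:
    for name in table.peak_areas:
        if name.strip().upper() in _DHA_NAMES:
            return name
    raise ValidationError("no DHA peak (expected a name like 'DHA' or 'C22:6')")


def dha_percent(table: GCPeakTable) -> float:
    """DHA weight percentage: 100 * DHA area / total FAME area.

    Internal-standard peaks (name prefix ``IS``) are excluded from the total.
    """
    dha_key = _find_dha_peak(table)
    total = sum(
        area for name, area in table.peak_areas.items()
        if not name.strip().upper().startswith(INTERNAL_STANDARD_PREFIX)
    )
    if total <= 0:
        raise ValidationError("total FAME peak area must be > 0")
    return 100.0 * table.peak_areas[dha_key] / total


def dha_content(total_fames: float, dha_pct: float) -> float:
    """DHA amount in mg per g biomass: total FAMEs * DHA% / 100."""
    if total_fames < 0 or dha_pct < 0:
        raise ValidationError("inputs must be >= 0")
    return total_fames * dha_pct / 100.0


def capacity_yield_concordance(
    capacities: Mapping[str, float], yields: Mapping[str, float]
) -> float:
    """Spearman rank correlation between predicted capacities and measured
    yields over their common ionic liquids (requires at least 3)."""
    common = sorted(set(capacities) & set(yields))
    if len(common) < 3:
        raise ValidationError("need at least 3 common ionic liquids")
    rho = stats.spearmanr(
        [capacities[k] for k in common], [yields[k] for k in common]
    ).statistic
    return float(rho)


def load_validation_table() -> pd.DataFrame:
    """Packaged table of the five experimentally validated ionic liquids:
    reported log-capacity and measured DHA yield (mg/g)."""
    path = resources.files("ilscreen").joinpath("data/validation_capacity_yield.csv")
    return pd.read_csv(path)  # type: ignore[arg-type]
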