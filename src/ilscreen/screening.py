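"""Ionic-liquid screening pipeline and trend analyses.

For every candidate cation-anion pair the pipeline builds an electroneutral
ion-pair pseudo-compound (areas and cavity volumes summed), computes the
infinite-dilution activity coefficient of the solute in that solvent and the
capacity C_inf = 1/gamma_inf, and ranks all pairs by capacity.  Trend reports
summarise how capacity varies with cation alkyl-chain length (per family and
anion, by rank correlation) and how the anion ordering compares with the
Hofmeister series reference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import stats

from .activity import capacity, gamma_infinite_dilution
from .exceptions import ConvergenceError, ValidationError
from .interaction_model import InteractionParams
from .ion_library import ILPair, IonLibrary, enumerate_pairs
from .segment_solver import (
    DEFAULT_SETTINGS,
    SolverSettings,
    solve_segment_potentials,
)
from .activity import compound_chemical_potential
from .sigma_profiles import MixtureProfile, SigmaProfile, mix_profiles

__all__ = [
    "ScreeningResult",
    "TrendReport",
    "HOFMEISTER_ANION_ORDER",
    "build_il_profile",
    "screen",
    "rank_from_capacities",
    "chain_length_trend",
    "anion_concordance",
]

logger = logging.getLogger(__name__)

#: Hofmeister series reference ordering of anions (strongest salting-out first).
HOFMEISTER_ANION_ORDER: tuple[str, ...] = (
    "[SO4]-", "[Cl]-", "[NO3]-", "[Br]-", "[I]-", "[ClO4]-", "[SCN]-",
)


@dataclass
class ScreeningResult:
    il_label: str
    cation_abbrev: str
    anion_abbrev: str
    gamma_inf: float
    capacity: float
    log10_capacity: float
    rank: int | None
    converged: bool = True


@dataclass
class TrendReport:
    """Per-cation-family summary of capacity trends."""

    family: str
    per_anion_direction: dict[str, str] = field(default_factory=dict)
    anion_order: dict[str, list[str]] = field(default_factory=dict)
    concordance_with_reference: float | None = None


def build_il_profile(
    pair: ILPair,
    profiles: Mapping[str, SigmaProfile],
    dissociated: bool = False,
) -> MixtureProfile:
    """Solvent ensemble for one ionic liquid.

    Default: single electroneutral ion-pair pseudo-compound (areas and
    volumes summed) at mole fraction 1.  ``dissociated=True`` instead mixes
    the two ions as an equimolar two-component solvent; the resulting
    ensemble distribution is identical (area-weighted sum either way).
    """
    try:
        cation = profiles[pair.cation.abbreviation]
        anion = profiles[pair.anion.abbreviation]
    except KeyError as exc:
        raise KeyError(f"no sigma profile for ion {exc.args[0]!r}") from exc
    if dissociated:
        return mix_profiles([(cation, 0.5), (anion, 0.5)])
    volume = None
    if cation.cavity_volume is not None and anion.cavity_volume is not None:
        volume = cation.cavity_volume + anion.cavity_volume
    pseudo = SigmaProfile(
        compound_id=pair.label,
        grid=cation.grid,
        areas=cation.areas + anion.areas,
        cavity_volume=volume,
    )
    return mix_profiles([(pseudo, 1.0)])


def screen(
    solute: SigmaProfile,
    library: IonLibrary,
    profiles: Mapping[str, SigmaProfile],
    params: InteractionParams,
    settings: SolverSettings = DEFAULT_SETTINGS,
    combinatorial: bool | None = None,
    dissociated: bool = False,
) -> list[ScreeningResult]:
    """Capacity of ``solute`` against every enumerated cation-anion pair.

    Returns one row per pair sorted by capacity descending (ties broken by
    label); non-converged pairs are kept, flagged and excluded from ranking.
    The pure-solute reference potential is solved once and reused.
    """
    reference_potential = solve_segment_potentials(
        mix_profiles([(solute, 1.0)]), params, settings
    )
    reference_mu = compound_chemical_potential(solute, reference_potential, params)

    results: list[ScreeningResult] = []
    for pair in enumerate_pairs(library):
        solvent = build_il_profile(pair, profiles, dissociated=dissociated)
        try:
            activity = gamma_infinite_dilution(
                solute, solvent, params, settings,
                combinatorial=combinatorial,
                _solute_reference_mu=reference_mu,
            )
        except ConvergenceError as exc:
            logger.warning("pair %s did not converge: %s", pair.label, exc)
            results.append(
                ScreeningResult(
                    il_label=pair.label,
                    cation_abbrev=pair.cation.abbreviation,
                    anion_abbrev=pair.anion.abbreviation,
                    gamma_inf=math.nan,
                    capacity=math.nan,
                    log10_capacity=math.nan,
                    rank=None,
                    converged=False,
                )
            )
            continue
        cap = capacity(activity)
        results.append(
            ScreeningResult(
                il_label=pair.label,
                cation_abbrev=pair.cation.abbreviation,
                anion_abbrev=pair.anion.abbreviation,
                gamma_inf=activity.gamma,
                capacity=cap.c_inf,
                log10_capacity=cap.log10_c_inf,
                rank=None,
            )
        )
    converged = [r for r in results if r.converged]
    converged.sort(key=lambda r: (-r.capacity, r.il_label))
    for i, r in enumerate(converged, start=1):
        r.rank = i
    failed = [r for r in results if not r.converged]
    failed.sort(key=lambda r: r.il_label)
    return converged + failed


def rank_from_capacities(
    records: Mapping[str, float] | list[tuple[str, float]],
) -> list[str]:
    """Labels ordered by capacity-like value descending, ties lexicographic."""
    items = list(records.items()) if isinstance(records, Mapping) else list(records)
    for label, value in items:
        if not np.isfinite(value):
            raise ValidationError(f"non-finite value for {label!r}")
    return [label for label, _ in sorted(items, key=lambda kv: (-kv[1], kv[0]))]


def _direction(chain_lengths: list[int], capacities: list[float]) -> str:
    if len(set(chain_lengths)) < 2:
        return "undetermined"
    if len(set(capacities)) < 2:
        return "non-monotone"  # constant capacities: rho undefined, treated as 0
    rho = stats.spearmanr(chain_lengths, capacities).statistic
    if np.isclose(rho, -1.0):
        return "decreasing"
    if np.isclose(rho, 1.0):
        return "increasing"
    return "non-monotone"


def chain_length_trend(
    results: list[ScreeningResult], library: IonLibrary
) -> dict[str, TrendReport]:
    """Capacity-vs-chain-length direction per (cation family, anion).

    Direction is the sign of the Spearman rank correlation of capacity with
    chain length: perfectly falling series are 'decreasing', perfectly rising
    ones 'increasing', anything else 'non-monotone' ('undetermined' when the
    family has fewer than two chain lengths for that anion).  Also reports,
    per cation, the anion ordering by capacity and the family's Kendall-tau
    concordance with the Hofmeister reference (over shared anions, by mean
    capacity across the family).
    """
    by_abbrev = {ion.abbreviation: ion for ion in library.ions()}
    reports: dict[str, TrendReport] = {}
    families = sorted({ion.family for ion in library.cations})
    for family in families:
        report = TrendReport(family=family)
        rows = [
            r for r in results
            if r.converged and by_abbrev[r.cation_abbrev].family == family
        ]
        anions = sorted({r.anion_abbrev for r in rows})
        for anion in anions:
            sub = [r for r in rows if r.anion_abbrev == anion]
            chains = [by_abbrev[r.cation_abbrev].alkyl_chain_length for r in sub]
            caps = [r.capacity for r in sub]
            report.per_anion_direction[anion] = _direction(chains, caps)
        for cation in sorted({r.cation_abbrev for r in rows}):
            sub = {r.anion_abbrev: r.capacity for r in rows if r.cation_abbrev == cation}
            report.anion_order[cation] = rank_from_capacities(sub)
        mean_caps: dict[str, float] = {}
        for anion in anions:
            vals = [r.capacity for r in rows if r.anion_abbrev == anion]
            mean_caps[anion] = float(np.mean(vals))
        family_order = rank_from_capacities(mean_caps)
        common = [a for a in family_order if a in HOFMEISTER_ANION_ORDER]
        if len(common) >= 2:
            report.concordance_with_reference = anion_concordance(
                family_order, list(HOFMEISTER_ANION_ORDER)
            )
        reports[family] = report
    return reports


def anion_concordance(
    anion_order: list[str], reference: list[str] | None = None
) -> float:
    """Kendall-tau between an observed anion ordering and a reference ordering
    (Hofmeister series by default), over their common elements."""
    if reference is None:
        reference = list(HOFMEISTER_ANION_ORDER)
    common = [a for a in anion_order if a in reference]
    if len(common) < 2:
        raise ValidationError("orders share fewer than 2 elements")
    observed_ranks = [anion_order.index(a) for a in common]
    reference_ranks = [reference.index(a) for a in common]
    tau = stats.kendalltau(observed_ranks, reference_ranks).statistic
    return float(tau)
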