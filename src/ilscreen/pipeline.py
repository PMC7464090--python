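"""End-to-end screening pipeline: load ions, build profiles, screen, report.

The pipeline is deterministic for a fixed configuration; every output bundle
carries machine-readable metadata (parameter values, seed, library size,
package version, config hash) sufficient to reproduce it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .exceptions import IlscreenError, ValidationError
from .interaction_model import InteractionParams
from .ion_library import IonLibrary, load_ion_library
from .screening import ScreeningResult, TrendReport, chain_length_trend, screen
from .segment_solver import SolverSettings
from .sigma_profiles import DEFAULT_GRID, SigmaGrid, SigmaProfile, read_sigma_profile
from .synthetic_profiles import make_dha_like, make_ion_like

__all__ = ["RunConfig", "PipelineOutput", "run_screening_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a screening run depends on.

    ``library_path=None`` uses the packaged ion inventory; ``solute_path`` /
    ``profile_dir=None`` fall back to the synthetic generator, so the default
    configuration runs with no external inputs at all.
    """

    output_dir: Path = Path("ilscreen-out")
    library_path: Path | None = None
    solute_path: Path | None = None
    profile_dir: Path | None = None
    params: InteractionParams = field(default_factory=InteractionParams)
    settings: SolverSettings = field(default_factory=SolverSettings)
    combinatorial: bool | None = None
    dissociated: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("output_dir", "library_path", "solute_path", "profile_dir"):
            if raw.get(key) is not None:
                kwargs[key] = Path(raw[key])
        if "params" in raw:
            kwargs["params"] = InteractionParams.from_dict(raw["params"])
        if "solver" in raw:
            kwargs["settings"] = SolverSettings(**raw["solver"])
        for key in ("combinatorial", "dissociated", "seed"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key in ("output_dir", "library_path", "solute_path", "profile_dir"):
            if d[key] is not None:
                d[key] = str(d[key])
        return d


@dataclass
class PipelineOutput:
    results_csv: Path
    trends_tsv: Path
    metadata_json: Path
    results: list[ScreeningResult]
    trends: dict[str, TrendReport]


def _stage(name: str):
    """Decorator-free context: re-raise stage errors with the stage name."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, IlscreenError):
                raise IlscreenError(f"stage '{name}' failed: {exc}") from exc
            if isinstance(exc, IlscreenError):
                exc.args = (f"stage '{name}': {exc.args[0]}",) + exc.args[1:]
            return False
    return _Ctx()


def _load_profiles(
    config: RunConfig, library: IonLibrary, grid: SigmaGrid
) -> dict[str, SigmaProfile]:
    profiles: dict[str, SigmaProfile] = {}
    for ion in library.ions():
        if config.profile_dir is not None:
            candidate = config.profile_dir / f"{ion.abbreviation}.sigma"
            if not config.profile_dir.is_dir():
                raise FileNotFoundError(f"profile dir {config.profile_dir} missing")
            if candidate.exists():
                profiles[ion.abbreviation] = read_sigma_profile(candidate, grid)
                continue
        profiles[ion.abbreviation] = make_ion_like(ion, grid)
    return profiles


def run_screening_pipeline(config: RunConfig, grid: SigmaGrid = DEFAULT_GRID) -> PipelineOutput:
    """Execute load -> profiles -> screen -> trends -> reports and write the
    output bundle (results CSV, trends TSV, metadata JSON)."""
    with _stage("load-library"):
        library = load_ion_library(config.library_path)
    with _stage("profiles"):
        profiles = _load_profiles(config, library, grid)
        if config.solute_path is not None:
            solute = read_sigma_profile(config.solute_path, grid)
        else:
            solute = make_dha_like(grid)
    with _stage("screen"):
        results = screen(
            solute, library, profiles,
            config.params, config.settings,
            combinatorial=config.combinatorial,
            dissociated=config.dissociated,
        )
    with _stage("trends"):
        trends = chain_length_trend(results, library)
    with _stage("report"):
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        results_csv = out / "results.csv"
        df = pd.DataFrame(
            [
                {
                    "rank": r.rank if r.rank is not None else "",
                    "il_label": r.il_label,
                    "cation": r.cation_abbrev,
                    "anion": r.anion_abbrev,
                    "gamma_inf": r.gamma_inf,
                    "capacity": r.capacity,
                    "log10_capacity": r.log10_capacity,
                    "converged": r.converged,
                }
                for r in results
            ]
        )
        df.to_csv(results_csv, index=False, float_format="%.10g")

        trends_tsv = out / "trends.tsv"
        rows = []
        for family, report in trends.items():
            for anion, direction in report.per_anion_direction.items():
                rows.append(
                    {
                        "family": family,
                        "anion": anion,
                        "direction": direction,
                        "hofmeister_kendall_tau": report.concordance_with_reference,
                    }
                )
        pd.DataFrame(rows).to_csv(trends_tsv, sep="\t", index=False)

        config_dict = config.to_dict()
        config_hash = hashlib.sha256(
            json.dumps(config_dict, sort_keys=True).encode()
        ).hexdigest()
        metadata_json = out / "run_metadata.json"
        metadata_json.write_text(
            json.dumps(
                {
                    "package_version": __version__,
                    "config": config_dict,
                    "config_sha256": config_hash,
                    "seed": config.seed,
                    "library": {
                        "n_cations": len(library.cations),
                        "n_anions": len(library.anions),
                        "notes": library.notes,
                    },
                    "n_results": len(results),
                    "n_converged": sum(r.converged for r in results),
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )
    return PipelineOutput(
        results_csv=results_csv,
        trends_tsv=trends_tsv,
        metadata_json=metadata_json,
        results=results,
        trends=trends,
    )
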