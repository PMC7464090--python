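"""Sigma-profile / sigma-potential figures.

Two-panel layout: the area histogram p(sigma) on top, the sigma-potential
curve mu_s(sigma) below, with dashed separators at +/-0.01 e/A^2 marking the
hydrogen-donor (< -0.01), nonpolar (|sigma| <= 0.01) and hydrogen-acceptor
(> +0.01) regions.  Output is vector (SVG) and deterministic for fixed
inputs (hash salt and no embedded date).
"""

from __future__ import annotations

import logging
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .exceptions import ConvergenceError, ValidationError
from .interaction_model import InteractionParams
from .segment_solver import DEFAULT_SETTINGS, SolverSettings, sigma_potential
from .sigma_profiles import SigmaProfile

__all__ = ["plot_profile_and_potential", "POLAR_CUTOFF"]

logger = logging.getLogger(__name__)

#: |sigma| boundary between the nonpolar region and the donor/acceptor regions
POLAR_CUTOFF = 0.01


def plot_profile_and_potential(
    profile: SigmaProfile,
    params: InteractionParams,
    settings: SolverSettings = DEFAULT_SETTINGS,
    out_dir: str | Path = ".",
    region_cutoff: float = POLAR_CUTOFF,
) -> Path:
    """Write ``<compound_id>_sigma.svg`` with profile and potential panels.

    If the solver fails, the profile panel is still produced (with a logged
    warning and an annotation in place of the potential curve).
    """
    if profile.total_area <= 0:
        raise ValidationError("cannot plot a zero-area profile")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sigma = profile.grid.centers()

    with plt.rc_context({"svg.hashsalt": profile.compound_id}):
        fig, (ax_p, ax_mu) = plt.subplots(2, 1, figsize=(6, 7), sharex=True)
        ax_p.bar(sigma, profile.areas, width=profile.grid.spacing * 0.9,
                 color="#4878a8")
        ax_p.set_ylabel(r"$p(\sigma)$ / $\AA^2$ per bin")
        ax_p.set_title(profile.compound_id)

        try:
            potential = sigma_potential(profile, params, settings)
            ax_mu.plot(sigma, potential.mu, color="#a84848")
            ax_mu.set_ylabel(r"$\mu_s(\sigma)$ / kcal mol$^{-1}$")
        except ConvergenceError as exc:
            logger.warning("sigma-potential solve failed for %s: %s",
                           profile.compound_id, exc)
            ax_mu.annotate("solver did not converge", xy=(0.5, 0.5),
                           xycoords="axes fraction", ha="center")
        ax_mu.set_xlabel(r"$\sigma$ / e $\AA^{-2}$")

        for ax in (ax_p, ax_mu):
            for x in (-region_cutoff, +region_cutoff):
                ax.axvline(x, linestyle="--", color="grey", linewidth=1)

        path = out_dir / f"{profile.compound_id}_sigma.svg"
        fig.savefig(path, format="svg", metadata={"Date": None})
        plt.close(fig)
    return path
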