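"""End-to-end orchestration of the screen → fit → synergy → rank pipeline."""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .doseresponse import fit_median_effect, normalize_viability
from .errors import ComboScreenError, StageError
from .growthstats import GrowthStudy, bonferroni, randomization_test
from .io import ScreenConfig
from .ranking import build_screen_matrix, rank_treatments
from .synergy import CombinationDesign, ci_profile


@dataclass
class ReportBundle:
    """Deterministic result bundle of one pipeline run."""

    fits: dict = field(default_factory=dict)  # (model, treatment) -> MedianEffectFit
    ci_profiles: dict = field(default_factory=dict)  # (model, pair_id) -> CIProfile
    matrices: dict = field(default_factory=dict)  # level -> ScreenMatrix
    ranking: object = None  # RankingResult at config.rank_level
    growth_results: dict = field(default_factory=dict)  # "a_vs_b" -> PermutationResult
    growth_adjusted: dict = field(default_factory=dict)  # "a_vs_b" -> Bonferroni p
    run_log: dict = field(default_factory=dict)


def _config_hash(config: ScreenConfig) -> str:
    payload = json.dumps(
        {
            "cmax": {k: float(v) for k, v in sorted(config.cmax.items())},
            "pairs": [list(p) for p in config.pairs],
            "levels": list(config.levels),
            "ladder_points": config.ladder_points,
            "dilution_factor": config.dilution_factor,
            "clip_eps": config.clip_eps,
            "auc_axis": config.auc_axis,
            "rank_level": config.rank_level,
            "rank_metric": config.rank_metric,
            "bootstrap_resamples": config.bootstrap_resamples,
            "seed": config.seed,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(
    config: ScreenConfig,
    plates,
    measurements: GrowthStudy | None = None,
    growth_comparisons=None,
) -> ReportBundle:
    """Run the full analysis on plate records (and optional growth data).

    Stages: viability normalization → single-agent median-effect fits →
    Fa–CI profiles for every configured pair with a measured combination
    curve → screen matrices at each fixed-ratio level → cross-model ranking
    at ``config.rank_level`` → optional growth-curve randomization tests with
    Bonferroni correction.  All randomness flows from ``config.seed``; the
    bundle is identical across runs with the same inputs.
    """
    bundle = ReportBundle()
    plates = list(plates)
    seeds = np.random.SeedSequence(config.seed).spawn(2)
    perm_seed = int(seeds[1].generate_state(1)[0] % (2**31 - 1))

    def stage(name, fn):
        try:
            return fn()
        except ComboScreenError as exc:
            raise StageError(name, exc) from exc

    curves = stage("normalize", lambda: normalize_viability(plates))
    pair_ids = {f"{a}+{b}": (a, b) for a, b in config.pairs}
    single_curves = [c for c in curves if c.treatment_id not in pair_ids]
    combo_curves = [c for c in curves if c.treatment_id in pair_ids]

    def do_fits():
        fits = {}
        for c in single_curves:
            fits[(c.model_id, c.treatment_id)] = fit_median_effect(c, clip_eps=config.clip_eps)
        return fits

    bundle.fits = stage("fit", do_fits)

    def do_synergy():
        profiles = {}
        for c in combo_curves:
            a, b = pair_ids[c.treatment_id]
            fit_a = bundle.fits.get((c.model_id, a))
            fit_b = bundle.fits.get((c.model_id, b))
            if fit_a is None or fit_b is None:
                continue  # CI needs both single-agent curves in the same model
            design = CombinationDesign(a, b, config.cmax[a], config.cmax[b],
                                       levels=tuple(config.levels))
            profiles[(c.model_id, c.treatment_id)] = ci_profile(
                c, fit_a, fit_b, design, clip_eps=config.clip_eps
            )
        return profiles

    bundle.ci_profiles = stage("synergy", do_synergy)

    ranked_curves = combo_curves if combo_curves else single_curves

    def do_matrices():
        return {
            level: build_screen_matrix(ranked_curves, level=level, metric="viability")
            for level in config.levels
        }

    bundle.matrices = stage("matrix", do_matrices)
    rank_matrix = bundle.matrices.get(config.rank_level)
    if rank_matrix is None:
        rank_matrix = stage(
            "matrix",
            lambda: build_screen_matrix(ranked_curves, level=config.rank_level,
                                        metric=config.rank_metric),
        )
    bundle.ranking = stage("rank", lambda: rank_treatments(rank_matrix))

    if measurements is not None:
        comparisons = growth_comparisons
        if comparisons is None:
            groups = measurements.groups
            comparisons = [(groups[0], g) for g in groups[1:]]

        def do_growth():
            results = {}
            for a, b in comparisons:
                results[f"{a}_vs_{b}"] = randomization_test(
                    measurements, a, b, seed=perm_seed
                )
            return results

        bundle.growth_results = stage("growthtest", do_growth)
        labels = sorted(bundle.growth_results)
        adjusted = bonferroni([bundle.growth_results[k].p_value for k in labels])
        bundle.growth_adjusted = dict(zip(labels, adjusted))

    bundle.run_log = {
        "comboscreen_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": config.seed,
        "permutation_seed": perm_seed,
        "config_hash": _config_hash(config),
        "n_plate_records": len(plates),
        "n_curves": len(curves),
        "n_fits": len(bundle.fits),
        "n_ci_profiles": len(bundle.ci_profiles),
    }
    return bundle
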