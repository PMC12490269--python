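"""Screen matrices and AUC-based cross-model ranking of treatments.

A screen is summarized as a treatments x model-lines matrix of either percent
viability at one fixed-ratio level or area under the viability-vs-dose curve
(AUC).  Treatments are ranked by their mean score across all models — lower
viability/AUC means a more effective treatment, so rank 1 is the smallest
mean.  AUC is the trapezoid sum ``ΔX·(Y1 + Y2)/2`` over adjacent dose pairs,
by default on a log10 dose axis (standard for sigmoidal screening curves;
linear optional).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .doseresponse import ConcentrationResponse
from .errors import CompletenessError, ParameterError

#: Relative tolerance used to match a requested level dose to a ladder dose.
_LEVEL_RTOL = 1e-6


def auc_trapezoid(xs, ys) -> float:
    """Trapezoid area under ``ys`` over ``xs``: sum of (x2−x1)·(y1+y2)/2.

    ``xs`` must be strictly increasing and of the same length as ``ys``
    (>= 2 points).
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.ndim != 1 or xs.shape != ys.shape:
        raise ParameterError(
            f"xs and ys must be 1-D of equal length, got {xs.shape} and {ys.shape}"
        )
    if xs.size < 2:
        raise ParameterError("AUC needs at least 2 points")
    dx = np.diff(xs)
    if np.any(dx <= 0):
        raise ParameterError("xs must be strictly increasing")
    return float(np.sum(dx * (ys[:-1] + ys[1:]) / 2.0))


def curve_auc(curve: ConcentrationResponse, axis: str = "log10") -> float:
    """AUC of a curve's replicate-mean viability over its dose ladder."""
    if axis == "log10":
        xs = np.log10(curve.doses)
    elif axis == "linear":
        xs = curve.doses
    else:
        raise ParameterError(f"unknown AUC axis {axis!r} (log10 or linear)")
    return auc_trapezoid(xs, curve.mean_viability)


def bootstrap_curve_auc(
    curve: ConcentrationResponse,
    n_boot: int = 1000,
    seed: int | None = None,
    axis: str = "log10",
    ci_level: float = 0.95,
) -> tuple[float, float, float]:
    """Nonparametric bootstrap confidence limits for a curve's AUC.

    Replicates are resampled with replacement within each dose, the AUC of the
    resampled means recomputed, and percentile limits returned as
    ``(auc, lo, hi)``.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    xs = np.log10(curve.doses) if axis == "log10" else curve.doses
    boots = np.empty(n_boot)
    for b in range(n_boot):
        means = np.array(
            [v[rng.integers(0, v.size, size=v.size)].mean() for v in curve.viability]
        )
        boots[b] = auc_trapezoid(xs, means)
    alpha = (1.0 - ci_level) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return curve_auc(curve, axis=axis), float(lo), float(hi)


@dataclass
class ScreenMatrix:
    """Treatments x model-lines matrix of percent viability or AUC.

    ``level`` records which fixed-ratio level the matrix summarizes (None for
    AUC over the full ladder); ``provenance`` maps each cell to the dose and
    replicate count it came from.
    """

    values: pd.DataFrame  # rows: treatments, cols: models
    metric: str  # "viability" or "auc"
    level: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.values.isna().any().any():
            missing = [
                (t, m)
                for t in self.values.index
                for m in self.values.columns
                if pd.isna(self.values.loc[t, m])
            ]
            raise CompletenessError(missing)


def build_screen_matrix(
    curves,
    level: float | None = 0.1,
    metric: str = "viability",
    axis: str = "log10",
) -> ScreenMatrix:
    """Assemble the screen matrix from measured curves.

    For ``metric="viability"`` each cell is the replicate-mean percent
    viability at the dose ``level x`` the curve's top dose (the fixed-ratio
    level dose); the ladder must contain that dose.  For ``metric="auc"`` each
    cell is the trapezoid AUC over the whole ladder.  Values are never
    clamped; cells above 100% remain as measured.  Missing (treatment, model)
    combinations raise a completeness error — they are never silently zero.
    """
    curves = list(curves)
    if not curves:
        raise ParameterError("no treatment curves supplied (control-only input?)")
    if metric not in ("viability", "auc"):
        raise ParameterError(f"unknown metric {metric!r}")
    if metric == "viability" and not (level and 0 < level <= 1):
        raise ParameterError(f"viability matrix needs a level in (0, 1], got {level}")

    treatments = sorted({c.treatment_id for c in curves})
    models = sorted({c.model_id for c in curves})
    values = pd.DataFrame(np.nan, index=treatments, columns=models)
    provenance: dict = {}
    for c in curves:
        if metric == "auc":
            cell = curve_auc(c, axis=axis)
            prov = {"metric": "auc", "axis": axis, "n_doses": int(c.doses.size)}
        else:
            target = level * c.doses.max()
            idx = int(np.argmin(np.abs(c.doses - target)))
            if not np.isclose(c.doses[idx], target, rtol=_LEVEL_RTOL):
                raise CompletenessError([(c.treatment_id, c.model_id)])
            cell = float(c.viability[idx].mean())
            prov = {
                "metric": "viability",
                "dose_uM": float(c.doses[idx]),
                "n_replicates": int(c.viability[idx].size),
            }
        values.loc[c.treatment_id, c.model_id] = cell
        provenance[(c.treatment_id, c.model_id)] = prov
    return ScreenMatrix(values=values, metric=metric, level=level if metric == "viability" else None,
                        provenance=provenance)


@dataclass
class RankingResult:
    """Cross-model ranking of treatments (rank 1 = most effective)."""

    order: list  # treatment ids, ascending mean score
    means: pd.Series  # per-treatment cross-model mean, in ranked order
    per_model: pd.DataFrame  # ranked treatments x models
    ties: list = field(default_factory=list)  # groups of treatments with equal means


def rank_treatments(matrix: ScreenMatrix) -> RankingResult:
    """Rank treatments by ascending cross-model mean score.

    Lower viability or AUC means greater effect, so the most effective
    treatment ranks first.  Exact ties are broken lexicographically by
    treatment id and reported.
    """
    df = matrix.values
    if df.empty:
        raise ParameterError("cannot rank an empty screen matrix")
    means = df.mean(axis=1)
    order = sorted(df.index, key=lambda t: (means[t], t))
    ties = [
        sorted(group.index)
        for _, group in means.groupby(means)
        if len(group) > 1
    ]
    return RankingResult(
        order=order,
        means=means.loc[order],
        per_model=df.loc[order],
        ties=ties,
    )


def write_matrix_csv(matrix: ScreenMatrix, path) -> None:
    """Write the matrix as CSV, treatments as rows and models as columns."""
    matrix.values.to_csv(path, index_label="treatment")


def plot_screen_heatmap(matrix: ScreenMatrix, path, title: str | None = None) -> None:
    """Render the screen matrix as a heatmap PNG/PDF.

    Color semantics follow the screening convention: 0% viability is darkest
    red, 100% is white.  Cells above 100% are rendered white (they carry no
    inhibition signal) and remain flagged in the matrix itself.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = matrix.values
    shown = df.clip(upper=100.0)
    fig, ax = plt.subplots(
        figsize=(1.0 + 0.6 * df.shape[1], 1.0 + 0.45 * df.shape[0])
    )
    im = ax.imshow(shown.to_numpy(), cmap="Reds_r", vmin=0.0, vmax=100.0, aspect="auto")
    ax.set_xticks(range(df.shape[1]), df.columns, rotation=45, ha="right")
    ax.set_yticks(range(df.shape[0]), df.index)
    label = "% viability" if matrix.metric == "viability" else "AUC"
    fig.colorbar(im, ax=ax, label=label)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def write_ranking_json(ranking: RankingResult, path, bootstrap: dict | None = None) -> None:
    """Write ranking, means, ties (and optional bootstrap intervals) as JSON."""
    payload = {
        "ranking": list(ranking.order),
        "means": {t: float(v) for t, v in ranking.means.items()},
        "per_model": {
            t: {m: float(v) for m, v in row.items()}
            for t, row in ranking.per_model.iterrows()
        },
        "ties": [list(g) for g in ranking.ties],
    }
    if bootstrap is not None:
        payload["bootstrap_intervals"] = bootstrap
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
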