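"""Viability normalization and median-effect concentration-response fitting.

Raw plate absorbances are normalized to percent viability against the
vehicle-control wells of the same model line
(``viability = treated / mean(control) x 100``).  Single-agent and
fixed-ratio-combination curves are then summarized with the median-effect
model

    fa / fu = (D / Dm) ** m,

where ``fa`` is the fraction of cells affected (killed), ``fu = 1 - fa``,
``Dm`` is the dose producing a 50% effect and ``m`` the sigmoidicity of the
curve.  The model is linear in log-log coordinates, so the fit is an ordinary
least-squares line of ``log10(fa/fu)`` on ``log10(D)`` — the classical
median-effect plot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import FitError, NormalizationError, ParameterError

#: Default clipping bound for fraction-affected values before log-linearization.
DEFAULT_CLIP_EPS = 0.005

#: Default dilution factor of a dose ladder: half-log steps spanning ~2.5
#: orders of magnitude over 6 points from the C_max anchor.
HALF_LOG = math.sqrt(10.0)


@dataclass(frozen=True)
class PlateRecord:
    """One well of a viability plate.

    ``concentration`` is in µM; vehicle-control wells carry
    ``concentration == 0`` and ``is_control=True``.
    """

    model_id: str
    treatment_id: str
    concentration: float
    replicate: int
    absorbance: float
    is_control: bool = False

    def __post_init__(self):
        if self.absorbance < 0:
            raise ParameterError(
                f"negative absorbance {self.absorbance} in well "
                f"({self.model_id}, {self.treatment_id}, rep {self.replicate})"
            )
        if self.concentration < 0:
            raise ParameterError(f"negative concentration {self.concentration} µM")
        if self.replicate < 1:
            raise ParameterError(f"replicate index must be >= 1, got {self.replicate}")


@dataclass
class ConcentrationResponse:
    """Replicate percent-viability measurements of one treatment in one model.

    ``doses`` is strictly increasing (µM); ``viability[i]`` holds the replicate
    percentages at ``doses[i]`` (values above 100 are retained, see
    ``over_control``).
    """

    model_id: str
    treatment_id: str
    doses: np.ndarray
    viability: list  # list of 1-D arrays, one per dose
    over_control: list = field(default_factory=list)  # parallel bool arrays

    def __post_init__(self):
        self.doses = np.asarray(self.doses, dtype=float)
        if self.doses.size < 1:
            raise ParameterError("a concentration-response curve needs >= 1 dose")
        if np.any(np.diff(self.doses) <= 0):
            raise ParameterError("doses must be strictly increasing")
        if len(self.viability) != self.doses.size:
            raise ParameterError("viability list must parallel doses")
        self.viability = [np.atleast_1d(np.asarray(v, dtype=float)) for v in self.viability]
        for d, v in zip(self.doses, self.viability):
            if v.size < 1:
                raise ParameterError(f"dose {d} µM has no replicates")
        if not self.over_control:
            self.over_control = [v > 100.0 for v in self.viability]

    @property
    def mean_viability(self) -> np.ndarray:
        """Replicate-mean percent viability per dose."""
        return np.array([v.mean() for v in self.viability])

    @property
    def sd_viability(self) -> np.ndarray:
        """Replicate standard deviation (ddof=1; 0 for singletons) per dose."""
        return np.array([v.std(ddof=1) if v.size > 1 else 0.0 for v in self.viability])

    @property
    def mean_fa(self) -> np.ndarray:
        """Fraction affected per dose, ``fa = 1 - viability/100`` of the mean."""
        return 1.0 - self.mean_viability / 100.0


@dataclass(frozen=True)
class DoseLadder:
    """Serial-dilution design anchored at the clinical C_max.

    ``top`` is the highest concentration (µM, the C_max anchor); each of the
    ``n_points`` doses is the previous divided by ``dilution_factor``.
    """

    top: float
    n_points: int = 6
    dilution_factor: float = HALF_LOG

    def __post_init__(self):
        if self.top <= 0:
            raise ParameterError(f"ladder top must be positive, got {self.top}")
        if self.n_points < 2:
            raise ParameterError(f"ladder needs >= 2 points, got {self.n_points}")
        if self.dilution_factor <= 1:
            raise ParameterError(
                f"dilution factor must exceed 1, got {self.dilution_factor}"
            )


def make_ladder(ladder: DoseLadder) -> np.ndarray:
    """Return the ladder's doses in µM, strictly decreasing from ``top``."""
    return ladder.top / ladder.dilution_factor ** np.arange(ladder.n_points)


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted median-effect parameters with linear-regression diagnostics.

    ``dm`` (µM) is the dose for 50% effect; ``m`` the sigmoidicity; ``r2`` the
    coefficient of determination of the log-log line; ``n_points_used`` the
    doses entering the regression and ``n_clipped`` those excluded because the
    observed fraction affected fell outside the open unit interval.
    """

    model_id: str
    treatment_id: str
    dm: float
    m: float
    r2: float
    n_points_used: int
    n_clipped: int = 0

    def __post_init__(self):
        if not (self.dm > 0 and np.isfinite(self.dm)):
            raise FitError(f"Dm must be positive and finite, got {self.dm}")
        if not (self.m > 0 and np.isfinite(self.m)):
            raise FitError(f"m must be positive and finite, got {self.m}")
        if self.n_points_used < 2:
            raise FitError("a median-effect fit needs >= 2 points")


def normalize_viability(records) -> list[ConcentrationResponse]:
    """Normalize raw plate absorbances to percent viability per model line.

    The control mean is taken over all ``is_control`` wells of a model;
    each treated well maps to ``absorbance / control_mean x 100``.  Control
    wells therefore average exactly 100% and are not emitted as treatment
    curves.  Values above 100% are retained and flagged (``over_control``).

    Raises
    ------
    NormalizationError
        If a model has no control wells or a nonpositive control mean.
    """
    records = list(records)
    if not records:
        raise NormalizationError("no plate records supplied")

    control_mean: dict[str, float] = {}
    models = sorted({r.model_id for r in records})
    for model in models:
        ctrl = [r.absorbance for r in records if r.model_id == model and r.is_control]
        if not ctrl:
            raise NormalizationError(f"model {model!r} has no control wells")
        mean = float(np.mean(ctrl))
        if mean <= 0:
            raise NormalizationError(
                f"model {model!r} has nonpositive control mean absorbance {mean}"
            )
        control_mean[model] = mean

    curves: list[ConcentrationResponse] = []
    treated = [r for r in records if not r.is_control]
    groups = sorted({(r.model_id, r.treatment_id) for r in treated})
    for model, treatment in groups:
        sub = [r for r in treated if r.model_id == model and r.treatment_id == treatment]
        doses = sorted({r.concentration for r in sub})
        if any(d <= 0 for d in doses):
            raise NormalizationError(
                f"treated well at zero concentration in ({model!r}, {treatment!r}); "
                "zero-dose wells must be flagged is_control"
            )
        viab = [
            np.array(
                [
                    r.absorbance / control_mean[model] * 100.0
                    for r in sub
                    if r.concentration == d
                ]
            )
            for d in doses
        ]
        curves.append(
            ConcentrationResponse(
                model_id=model, treatment_id=treatment, doses=np.array(doses), viability=viab
            )
        )
    return curves


def fit_median_effect(
    curve: ConcentrationResponse,
    clip_eps: float = DEFAULT_CLIP_EPS,
    include_clipped: bool = False,
) -> MedianEffectFit:
    """Fit ``(Dm, m)`` to a curve by the median-effect log-log regression.

    Replicates are averaged to one fraction affected per dose before the
    regression (per-dose scatter is available on the curve itself).  Doses
    whose mean ``fa`` falls outside ``(clip_eps, 1 - clip_eps)`` are clipped
    to that band and, by default, excluded from the regression; pass
    ``include_clipped=True`` to keep them at the clipped value.

    Raises
    ------
    FitError
        Fewer than two usable doses, a nonpositive fitted slope, or
        nonpositive doses among the fitted points.
    """
    if not 0 < clip_eps < 0.5:
        raise ParameterError(f"clip_eps must lie in (0, 0.5), got {clip_eps}")
    fa = curve.mean_fa
    doses = curve.doses
    if np.any(doses <= 0):
        raise FitError(
            f"curve ({curve.model_id!r}, {curve.treatment_id!r}) contains "
            "nonpositive doses; controls must not enter the fit"
        )
    interior = (fa > clip_eps) & (fa < 1.0 - clip_eps)
    n_clipped = int((~interior).sum())
    if include_clipped:
        fa_used = np.clip(fa, clip_eps, 1.0 - clip_eps)
        d_used = doses
        n_used = doses.size
    else:
        fa_used = fa[interior]
        d_used = doses[interior]
        n_used = int(interior.sum())
    if n_used < 2:
        raise FitError(
            f"curve ({curve.model_id!r}, {curve.treatment_id!r}) has {n_used} "
            f"usable points after clipping at {clip_eps} (need >= 2)"
        )
    y = np.log10(fa_used / (1.0 - fa_used))
    x = np.log10(d_used)
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise FitError(
            f"curve ({curve.model_id!r}, {curve.treatment_id!r}) yields "
            f"nonpositive median-effect slope m={m:.4g}"
        )
    dm = float(10.0 ** (-res.intercept / m))
    r2 = float(res.rvalue**2) if np.isfinite(res.rvalue) else 1.0
    return MedianEffectFit(
        model_id=curve.model_id,
        treatment_id=curve.treatment_id,
        dm=dm,
        m=m,
        r2=r2,
        n_points_used=n_used,
        n_clipped=n_clipped,
    )


def predict_fa(fit: MedianEffectFit, dose) -> np.ndarray | float:
    """Forward median-effect equation: fraction affected at ``dose`` µM.

    ``fa = (D/Dm)^m / (1 + (D/Dm)^m)``; zero dose maps to zero effect and the
    response is strictly increasing in dose.
    """
    d = np.asarray(dose, dtype=float)
    if np.any(d < 0):
        raise ParameterError("dose must be nonnegative")
    # 1 / (1 + (Dm/D)^m) is stable for large D where (D/Dm)^m would overflow
    with np.errstate(divide="ignore", over="ignore"):
        inv = np.power(fit.dm / np.where(d > 0, d, np.nan), fit.m)
    fa = np.where(d > 0, 1.0 / (1.0 + inv), 0.0)
    return float(fa) if fa.ndim == 0 else fa
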