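"""Fixed-ratio combination designs and Chou–Talalay combination indices.

A two-drug combination is screened at a *fixed molar ratio* set by the drugs'
clinical peak plasma concentrations: at scale level ``s`` the mixture delivers
``(s * cmax_a, s * cmax_b)``, so the ratio ``cmax_a : cmax_b`` is constant
while total dose varies.  The screen uses two levels, full C_max (``s = 1``)
and 10% C_max (``s = 0.1``).

For a combination producing fraction affected ``fa`` at component doses
``(D1, D2)``, the combination index in the mutually exclusive form is

    CI = D1 / Dx1(fa) + D2 / Dx2(fa),

with ``Dx_i(fa) = Dm_i * (fa / (1 - fa)) ** (1 / m_i)`` the single-agent dose
producing the same effect.  CI < 1 indicates synergism, CI = 1 additivity
(Loewe), CI > 1 antagonism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np

from .doseresponse import (
    DEFAULT_CLIP_EPS,
    ConcentrationResponse,
    MedianEffectFit,
)
from .errors import EmptyProfileError, FitError, ParameterError

#: Half-width of the band around CI = 1 reported as "additive"; the strict
#: CI = 1 definition is unusable on noisy data.
ADDITIVE_TOL = 0.05

#: The two fixed-ratio levels of the screening design: C_max and 10% C_max.
DEFAULT_LEVELS = (1.0, 0.1)


@dataclass(frozen=True)
class CombinationDesign:
    """An ordered drug pair mixed at the fixed ratio of their C_max values."""

    drug_a: str
    drug_b: str
    cmax_a: float
    cmax_b: float
    levels: tuple = DEFAULT_LEVELS

    def __post_init__(self):
        if self.cmax_a <= 0 or self.cmax_b <= 0:
            raise ParameterError(
                f"C_max values must be positive, got ({self.cmax_a}, {self.cmax_b})"
            )
        for s in self.levels:
            if not 0 < s <= 1:
                raise ParameterError(f"fixed-ratio level {s} outside (0, 1]")

    @property
    def pair_id(self) -> str:
        return f"{self.drug_a}+{self.drug_b}"

    @property
    def weight_a(self) -> float:
        """Fraction of the total dose contributed by drug A (constant across levels)."""
        return self.cmax_a / (self.cmax_a + self.cmax_b)

    @property
    def weight_b(self) -> float:
        return 1.0 - self.weight_a

    @property
    def total_cmax(self) -> float:
        """Total dose at the full-C_max level (µM)."""
        return self.cmax_a + self.cmax_b

    def component_doses(self, total_dose: float) -> tuple[float, float]:
        """Split a total dose into per-drug doses at the fixed ratio."""
        return self.weight_a * total_dose, self.weight_b * total_dose

    def doses_at_level(self, level: float) -> tuple[float, float]:
        """Per-drug doses delivered at scale level ``s``: (s·cmax_a, s·cmax_b)."""
        return level * self.cmax_a, level * self.cmax_b


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Invert the median-effect model: dose producing fraction affected ``fa``.

    ``Dx = Dm * (fa / (1 - fa)) ** (1 / m)``; round trip with the forward
    equation holds by construction.
    """
    if not 0.0 < fa < 1.0:
        raise ParameterError(f"fa must lie strictly in (0, 1), got {fa}")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    design: CombinationDesign,
    total_dose: float,
    fa: float,
) -> float:
    """Mutually exclusive combination index at one (total dose, effect) point.

    The total dose is split at the design's fixed ratio into ``(D1, D2)`` and
    referenced against the single-agent doses producing the same effect.
    """
    if total_dose <= 0:
        raise ParameterError(f"total dose must be positive, got {total_dose}")
    if fit_a.m <= 0 or fit_b.m <= 0:
        raise FitError("degenerate median-effect fit (m <= 0)")
    d1, d2 = design.component_doses(total_dose)
    return d1 / dose_for_effect(fit_a, fa) + d2 / dose_for_effect(fit_b, fa)


def interpret_ci(ci: float, tol: float = ADDITIVE_TOL) -> str:
    """Label a combination index: synergism (CI<1), additive (|CI−1|<=tol), antagonism."""
    if ci <= 0:
        raise ParameterError(f"combination index must be positive, got {ci}")
    if abs(ci - 1.0) <= tol:
        return "additive"
    return "synergism" if ci < 1.0 else "antagonism"


@dataclass(frozen=True)
class CIPoint:
    """One point of a combination-index profile."""

    fa: float
    total_dose: float
    ci: float
    label: str


@dataclass
class CIProfile:
    """Combination-index values along a measured fixed-ratio combination curve."""

    design: CombinationDesign
    model_id: str
    points: list = field(default_factory=list)
    n_excluded: int = 0  # combo doses whose fa fell outside the clip band


def ci_profile(
    curve_combo: ConcentrationResponse,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    design: CombinationDesign,
    clip_eps: float = DEFAULT_CLIP_EPS,
    additive_tol: float = ADDITIVE_TOL,
) -> CIProfile:
    """Compute the Fa–CI profile of a fixed-ratio combination curve.

    The fraction affected at each combination dose comes from the *measured*
    combination viability (replicate mean), while the iso-effective
    single-agent doses come from the single-agent fits.  Points whose fa falls
    outside ``(clip_eps, 1 - clip_eps)`` are excluded and counted.

    Raises
    ------
    EmptyProfileError
        If no combination dose yields an interior fraction affected.
    """
    fa_all = curve_combo.mean_fa
    doses = curve_combo.doses
    profile = CIProfile(design=design, model_id=curve_combo.model_id)
    for total_dose, fa in zip(doses, fa_all):
        if not clip_eps < fa < 1.0 - clip_eps:
            profile.n_excluded += 1
            continue
        ci = combination_index(fit_a, fit_b, design, float(total_dose), float(fa))
        profile.points.append(
            CIPoint(fa=float(fa), total_dose=float(total_dose), ci=ci,
                    label=interpret_ci(ci, additive_tol))
        )
    if not profile.points:
        raise EmptyProfileError(
            f"combination ({curve_combo.model_id!r}, {curve_combo.treatment_id!r}): "
            f"all {profile.n_excluded} doses have fraction affected outside "
            f"({clip_eps}, {1 - clip_eps})"
        )
    return profile


def write_ci_profiles_csv(profiles, path) -> None:
    """Write Fa–CI profiles as CSV: pair, model_id, fa, total_dose_uM, CI, label."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pair", "model_id", "fa", "total_dose_uM", "CI", "label"])
        for prof in profiles:
            for p in prof.points:
                writer.writerow(
                    [prof.design.pair_id, prof.model_id,
                     f"{p.fa:.6g}", f"{p.total_dose:.6g}", f"{p.ci:.6g}", p.label]
                )
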