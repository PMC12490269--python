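"""Tumor-volume computation and the randomization test for in vivo studies.

Caliper measurements are converted with the standard ellipsoid approximation
``volume = length x width^2 / 2`` (mm³).  Treatment arms are compared with a
permutation (randomization) test on a per-animal growth summary — by default
the trapezoidal area under the volume-vs-day curve — with Bonferroni
correction across a family of comparisons.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np

from .errors import ParameterError
from .ranking import auc_trapezoid

#: Above this many distinct relabelings the test switches to Monte Carlo.
EXACT_ENUMERATION_LIMIT = 20_000

#: Relative slack when comparing permuted statistics to the observed one;
#: relabelings exactly as extreme as the observed one must count as hits
#: despite float round-off, whatever the scale of the summaries.
_TIE_RTOL = 1e-9


def tumor_volume(length, width):
    """Tumor volume in mm³ from caliper length and width (mm): L·W²/2."""
    length = np.asarray(length, dtype=float)
    width = np.asarray(width, dtype=float)
    if np.any(length < 0) or np.any(width < 0):
        raise ParameterError("caliper measurements must be nonnegative")
    vol = length * width**2 / 2.0
    return float(vol) if vol.ndim == 0 else vol


@dataclass
class Animal:
    """One animal's measurement series; length >= width by convention.

    Measurements violating the convention are swapped and flagged rather than
    rejected (caliper axes are easily transposed at the bench).
    """

    animal_id: str
    group: str
    days: np.ndarray
    lengths: np.ndarray
    widths: np.ndarray
    swapped: np.ndarray = field(default=None)

    def __post_init__(self):
        self.days = np.asarray(self.days, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if not (self.days.size == self.lengths.size == self.widths.size):
            raise ParameterError(f"animal {self.animal_id!r}: ragged measurement arrays")
        if self.days.size == 0:
            raise ParameterError(f"animal {self.animal_id!r} has no measurements")
        if np.any(np.diff(self.days) < 0):
            raise ParameterError(f"animal {self.animal_id!r}: days must be nondecreasing")
        swap = self.widths > self.lengths
        if np.any(swap):
            L = np.where(swap, self.widths, self.lengths)
            W = np.where(swap, self.lengths, self.widths)
            self.lengths, self.widths = L, W
        self.swapped = swap

    @property
    def volumes(self) -> np.ndarray:
        return tumor_volume(self.lengths, self.widths)


@dataclass
class GrowthStudy:
    """Per-animal tumor volume time series grouped into treatment arms."""

    animals: list

    def __post_init__(self):
        if not self.animals:
            raise ParameterError("a growth study needs at least one animal")
        ids = [a.animal_id for a in self.animals]
        if len(set(ids)) != len(ids):
            raise ParameterError("duplicate animal ids in growth study")

    @property
    def groups(self) -> list[str]:
        return sorted({a.group for a in self.animals})

    def arm(self, group: str) -> list[Animal]:
        return [a for a in self.animals if a.group == group]


def animal_summary(animal: Animal, stat: str = "auc") -> float:
    """Per-animal growth summary: volume-vs-day trapezoid AUC or endpoint volume."""
    vols = animal.volumes
    if stat == "auc":
        if animal.days.size < 2:
            raise ParameterError(
                f"animal {animal.animal_id!r}: AUC summary needs >= 2 time points"
            )
        return auc_trapezoid(animal.days, vols)
    if stat == "endpoint":
        return float(vols[-1])
    raise ParameterError(f"unknown summary statistic {stat!r} (auc or endpoint)")


@lru_cache(maxsize=8)
def _relabeling_masks(n: int, na: int) -> np.ndarray:
    """All C(n, na) group-A membership indicators as a (N, n) 0/1 matrix."""
    masks = np.zeros((math.comb(n, na), n))
    for row, idx in enumerate(combinations(range(n), na)):
        masks[row, list(idx)] = 1.0
    return masks


@dataclass(frozen=True)
class PermutationResult:
    """Outcome of a two-sided randomization test."""

    p_value: float
    observed_diff: float  # mean(group_a) - mean(group_b) of the summary
    statistic: str
    method: str  # "exact" or "montecarlo"
    n_permutations: int  # relabelings enumerated or drawn
    seed: int | None = None


def randomization_test(
    study: GrowthStudy,
    group_a: str,
    group_b: str,
    stat: str = "auc",
    n_perm: int = 10_000,
    seed: int | None = None,
    method: str = "auto",
) -> PermutationResult:
    """Two-sided permutation test of the group-mean difference in a summary.

    Animals are relabeled between the two arms; the p-value is the fraction
    of relabelings whose absolute mean difference is at least the observed
    one.  When the number of distinct relabelings is at most
    ``EXACT_ENUMERATION_LIMIT`` the null distribution is enumerated exactly
    (the identity relabeling counts, so p >= 1/N); otherwise ``n_perm`` Monte
    Carlo draws are used with the add-one correction ``p = (b + 1)/(n + 1)``.
    """
    arm_a = study.arm(group_a)
    arm_b = study.arm(group_b)
    if not arm_a or not arm_b:
        empty = group_a if not arm_a else group_b
        raise ParameterError(f"group {empty!r} is empty or unknown")
    if method not in ("auto", "exact", "montecarlo"):
        raise ParameterError(f"unknown method {method!r}")
    if method != "exact" and n_perm < 100:
        raise ParameterError(f"n_perm must be >= 100 for a usable p-value, got {n_perm}")

    xa = np.array([animal_summary(a, stat) for a in arm_a])
    xb = np.array([animal_summary(a, stat) for a in arm_b])
    observed = float(xa.mean() - xb.mean())
    pooled = np.concatenate([xa, xb])
    n, na = pooled.size, xa.size
    threshold = abs(observed) - _TIE_RTOL * (np.max(np.abs(pooled)) + 1.0)

    n_exact = math.comb(n, na)
    if method == "exact" and n_exact > 50 * EXACT_ENUMERATION_LIMIT:
        raise ParameterError(
            f"{n_exact} relabelings is too many to enumerate; use method='montecarlo'"
        )
    use_exact = method == "exact" or (method == "auto" and n_exact <= EXACT_ENUMERATION_LIMIT)
    if use_exact:
        masks = _relabeling_masks(n, na)
        sums_a = masks @ pooled
        diffs = sums_a / na - (pooled.sum() - sums_a) / (n - na)
        hits = int(np.count_nonzero(np.abs(diffs) >= threshold))
        return PermutationResult(
            p_value=hits / n_exact,
            observed_diff=observed,
            statistic=stat,
            method="exact",
            n_permutations=n_exact,
            seed=None,
        )

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(pooled, (n_perm, 1)), axis=1)
    diffs = perms[:, :na].mean(axis=1) - perms[:, na:].mean(axis=1)
    hits = int(np.count_nonzero(np.abs(diffs) >= threshold))
    return PermutationResult(
        p_value=(hits + 1) / (n_perm + 1),
        observed_diff=observed,
        statistic=stat,
        method="montecarlo",
        n_permutations=n_perm,
        seed=seed,
    )


def bonferroni(p_values, family_size: int | None = None) -> list[float]:
    """Bonferroni-adjusted p-values: each multiplied by the family size, capped at 1."""
    ps = list(p_values)
    for p in ps:
        if not 0.0 <= p <= 1.0:
            raise ParameterError(f"p-value {p} outside [0, 1]")
    k = family_size if family_size is not None else len(ps)
    if k < 1:
        raise ParameterError(f"family size must be >= 1, got {k}")
    return [min(1.0, p * k) for p in ps]


def write_growth_results_json(results: dict, path, family_size: int | None = None) -> None:
    """Write raw and Bonferroni-adjusted randomization-test results as JSON.

    ``results`` maps comparison labels to :class:`PermutationResult`.
    """
    labels = sorted(results)
    raw = [results[k].p_value for k in labels]
    adj = bonferroni(raw, family_size=family_size or len(labels))
    payload = {
        label: {
            "p_value": results[label].p_value,
            "p_value_bonferroni": adj[i],
            "observed_diff": results[label].observed_diff,
            "statistic": results[label].statistic,
            "method": results[label].method,
            "n_permutations": results[label].n_permutations,
            "seed": results[label].seed,
        }
        for i, label in enumerate(labels)
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
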