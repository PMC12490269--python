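"""Ground-truth synthetic data generators for every pipeline input.

The generators emulate the screening study's designs with known truth so the
analysis can be validated end to end:

* single-agent plates — median-effect response ``fa = (D/Dm)^m / (1+(D/Dm)^m)``
  on a 6-point serial dilution anchored at the drug's C_max, converted to
  absorbance with multiplicative plate noise;
* fixed-ratio combination plates — the combined fraction affected solves the
  Loewe additivity equation with a potency-boost interaction ``ψ``:

      ψ·d_a / Dx_a(fa) + ψ·d_b / Dx_b(fa) = 1,

  so ``ψ = 1`` is exact Loewe additivity (downstream CI = 1), ``ψ > 1``
  synergy (CI = 1/ψ) and ``ψ < 1`` antagonism — a closed-form oracle for the
  combination-index pipeline;
* multi-model screens with one planted dominating combination;
* per-animal exponential tumor growth with lognormal measurement noise.

All generators are deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .doseresponse import DoseLadder, PlateRecord, make_ladder
from .errors import ParameterError, SimulationError
from .growthstats import Animal, GrowthStudy
from .synergy import CombinationDesign

#: Default number of replicate wells per dose (and of control wells).
DEFAULT_REPLICATES = 3

#: Default relative (multiplicative Gaussian) absorbance noise of the plates.
DEFAULT_NOISE_SD = 0.02


@dataclass(frozen=True)
class DrugTruth:
    """Ground-truth single-agent parameters: median-effect (Dm, m) and C_max."""

    drug: str
    dm: float
    m: float
    cmax: float

    def __post_init__(self):
        if min(self.dm, self.m, self.cmax) <= 0:
            raise ParameterError(
                f"DrugTruth({self.drug!r}) parameters must all be positive"
            )

    def fa(self, dose: float) -> float:
        """True fraction affected at a dose (µM)."""
        if dose < 0:
            raise ParameterError("dose must be nonnegative")
        if dose == 0:
            return 0.0
        return 1.0 / (1.0 + (self.dm / dose) ** self.m)

    def dose_for(self, fa: float) -> float:
        """True dose producing fraction affected ``fa``."""
        if not 0.0 < fa < 1.0:
            raise ParameterError(f"fa must lie in (0, 1), got {fa}")
        return self.dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass(frozen=True)
class InteractionTruth:
    """Pairwise interaction ground truth as a potency-boost factor ψ.

    ψ = 1 is Loewe-additive, ψ > 1 synergistic (the combination behaves as if
    both doses were multiplied by ψ), ψ < 1 antagonistic.
    """

    drug_a: str
    drug_b: str
    psi: float = 1.0

    def __post_init__(self):
        if self.psi <= 0:
            raise ParameterError(f"psi must be positive, got {self.psi}")


@dataclass(frozen=True)
class GrowthTruth:
    """Ground truth for one treatment arm's tumor growth.

    Volumes follow ``V(t) = V0 · exp(rate · effect · t)`` with per-measurement
    lognormal noise; ``effect < 1`` slows growth, ``effect < 0`` would shrink.
    The default V0 of 70 mm³ matches randomization at enrollment.
    """

    group: str
    initial_volume: float = 70.0
    rate: float = 0.25  # per day
    effect: float = 1.0  # treatment multiplier on the rate
    noise_sd: float = 0.15  # sd of log-volume measurement noise

    def __post_init__(self):
        if self.initial_volume <= 0:
            raise ParameterError("initial volume must be positive")
        if self.noise_sd < 0:
            raise ParameterError("noise sd must be nonnegative")


def _noisy_absorbance(base: np.ndarray, rng, noise_sd: float) -> np.ndarray:
    """Multiplicative Gaussian plate noise, truncated at zero."""
    return np.maximum(base * (1.0 + rng.normal(0.0, noise_sd, size=base.shape)), 0.0)


def _control_records(model_id: str, n: int, rng, noise_sd: float) -> list[PlateRecord]:
    values = _noisy_absorbance(np.ones(n), rng, noise_sd)
    return [
        PlateRecord(model_id, "control", 0.0, rep + 1, float(values[rep]), True)
        for rep in range(n)
    ]


def simulate_single_agent_plate(
    truth: DrugTruth,
    ladder: DoseLadder | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    model_id: str = "model-1",
) -> list[PlateRecord]:
    """Simulate one single-agent plate with control wells.

    Control absorbance has mean 1.0; a treated well's expected absorbance is
    ``(1 - fa(D))`` times the control level.  The ladder defaults to a 6-point
    half-log dilution anchored at the drug's C_max.
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be nonnegative, got {noise_sd}")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    if ladder is None:
        ladder = DoseLadder(top=truth.cmax)
    rng = np.random.default_rng(seed)
    records = _control_records(model_id, replicates, rng, noise_sd)
    for dose in make_ladder(ladder):
        base = np.full(replicates, 1.0 - truth.fa(float(dose)))
        values = _noisy_absorbance(base, rng, noise_sd)
        records.extend(
            PlateRecord(model_id, truth.drug, float(dose), rep + 1, float(values[rep]))
            for rep in range(replicates)
        )
    return records


def loewe_fraction_affected(
    dose_a: float,
    dose_b: float,
    truth_a: DrugTruth,
    truth_b: DrugTruth,
    psi: float = 1.0,
) -> float:
    """Fraction affected of a dose pair under Loewe additivity with boost ψ.

    Solves ``ψ·d_a/Dx_a(fa) + ψ·d_b/Dx_b(fa) = 1`` for ``fa`` by bracketed
    root-finding; single-agent boundaries (one dose zero) reduce exactly to
    the other drug's response.
    """
    if dose_a < 0 or dose_b < 0:
        raise ParameterError("doses must be nonnegative")
    if psi <= 0:
        raise ParameterError(f"psi must be positive, got {psi}")
    if dose_a == 0 and dose_b == 0:
        return 0.0
    if dose_b == 0:
        return truth_a.fa(psi * dose_a)
    if dose_a == 0:
        return truth_b.fa(psi * dose_b)

    def excess(fa: float) -> float:
        return psi * dose_a / truth_a.dose_for(fa) + psi * dose_b / truth_b.dose_for(fa) - 1.0

    lo, hi = 1e-12, 1.0 - 1e-12
    try:
        return float(brentq(excess, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200))
    except ValueError as exc:  # pragma: no cover - bracket failure is pathological
        raise SimulationError(
            f"Loewe bisection failed for doses ({dose_a}, {dose_b}) µM, psi={psi}: "
            f"excess({lo})={excess(lo):.3g}, excess({hi})={excess(hi):.3g}"
        ) from exc


def simulate_combination_plate(
    truth_a: DrugTruth,
    truth_b: DrugTruth,
    interaction: InteractionTruth,
    design: CombinationDesign | None = None,
    ladder: DoseLadder | None = None,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    seed: int | None = None,
    model_id: str = "model-1",
    include_controls: bool = True,
) -> list[PlateRecord]:
    """Simulate a fixed-ratio combination plate.

    Each well's concentration is the *total* dose of the mixture along the
    ladder (default: 6-point half-log ladder anchored at
    ``cmax_a + cmax_b``, so the ladder contains the full-C_max and 10%-C_max
    levels); it is split at the design's fixed ratio, the combined fraction
    affected solved from the Loewe equation with the interaction's ψ, and
    converted to absorbance like the single-agent generator.
    """
    if noise_sd < 0:
        raise ParameterError(f"noise_sd must be nonnegative, got {noise_sd}")
    if design is None:
        design = CombinationDesign(truth_a.drug, truth_b.drug, truth_a.cmax, truth_b.cmax)
    if ladder is None:
        ladder = DoseLadder(top=design.total_cmax)
    rng = np.random.default_rng(seed)
    records = (
        _control_records(model_id, replicates, rng, noise_sd) if include_controls else []
    )
    for total in make_ladder(ladder):
        d_a, d_b = design.component_doses(float(total))
        fa = loewe_fraction_affected(d_a, d_b, truth_a, truth_b, interaction.psi)
        base = np.full(replicates, 1.0 - fa)
        values = _noisy_absorbance(base, rng, noise_sd)
        records.extend(
            PlateRecord(model_id, design.pair_id, float(total), rep + 1, float(values[rep]))
            for rep in range(replicates)
        )
    return records


@dataclass
class ScreenTruth:
    """Ground truth of a simulated multi-model combination screen."""

    designs: list  # CombinationDesign per combination
    drug_truths: dict  # (model_id, drug) -> DrugTruth
    interactions: dict  # pair_id -> InteractionTruth
    planted_winner: str  # pair_id of the dominating combination
    model_ids: list = field(default_factory=list)


def _expected_screen_viability(
    design: CombinationDesign,
    pot_a: float,
    pot_b: float,
    m_a: float,
    m_b: float,
    psi: float,
    sensitivity: np.ndarray,
    level: float,
) -> float:
    """Noiseless cross-model mean percent viability of a combo at a ladder level."""
    d_a, d_b = design.doses_at_level(level)
    fas = [
        loewe_fraction_affected(
            d_a,
            d_b,
            DrugTruth(design.drug_a, dm=design.cmax_a * pot_a * s, m=m_a, cmax=design.cmax_a),
            DrugTruth(design.drug_b, dm=design.cmax_b * pot_b * s, m=m_b, cmax=design.cmax_b),
            psi,
        )
        for s in sensitivity
    ]
    return float(100.0 * (1.0 - np.mean(fas)))


def simulate_screen(
    n_combos: int = 5,
    n_models: int = 7,
    replicates: int = DEFAULT_REPLICATES,
    noise_sd: float = DEFAULT_NOISE_SD,
    planted_psi: float = 3.0,
    background_psi: float = 1.0,
    rank_level: float = 0.1,
    dominance_margin: float = 3.0,
    seed: int | None = None,
) -> tuple[list[PlateRecord], ScreenTruth]:
    """Simulate a combination screen with one planted dominating combination.

    Each combination is an independent drug pair; drug potency is drawn
    narrowly around Dm = 2 x C_max (0.15 log10-sd) and sigmoidicity from
    U(1, 2), so single agents are modest, and per-model sensitivity factors
    are shared across combinations (they shift every cell of a model's column
    alike).  The first combination receives potency boost ``planted_psi``
    while the rest are Loewe-additive (``background_psi``).  Dominance is part
    of the generator's contract: a competitor whose expected noiseless
    cross-model viability at ``rank_level`` comes within ``dominance_margin``
    percentage points of the planted combination's is redrawn, so the planted
    winner leads the true ranking by at least the margin.  Returns the plate
    records of every (combination, model) pair plus the ground truth.
    """
    if n_combos < 2 or n_models < 1:
        raise ParameterError("need >= 2 combinations and >= 1 model")
    if planted_psi <= background_psi:
        raise ParameterError("planted_psi must exceed background_psi for a planted winner")
    rng = np.random.default_rng(seed)
    model_ids = [f"MM-{i + 1:03d}" for i in range(n_models)]
    # model-level sensitivity multiplies every drug's Dm in that model
    sensitivity = 10.0 ** rng.normal(0.0, 0.1, size=n_models)

    designs, interactions = [], {}
    drug_truths: dict = {}
    records: list[PlateRecord] = []
    planted_viability = None
    for k in range(n_combos):
        name_a, name_b = f"drug{2 * k + 1:02d}", f"drug{2 * k + 2:02d}"
        cmax_a, cmax_b = float(10.0 ** rng.uniform(-0.5, 1.0)), float(10.0 ** rng.uniform(-0.5, 1.0))
        design = CombinationDesign(name_a, name_b, cmax_a, cmax_b)
        designs.append(design)
        psi = planted_psi if k == 0 else background_psi
        interactions[design.pair_id] = InteractionTruth(name_a, name_b, psi)
        for attempt in range(200):
            # per-combo potency: Dm ≈ 2 x C_max with narrow spread
            pot_a = 2.0 * 10.0 ** rng.normal(0.0, 0.15)
            pot_b = 2.0 * 10.0 ** rng.normal(0.0, 0.15)
            m_a, m_b = float(rng.uniform(1.0, 2.0)), float(rng.uniform(1.0, 2.0))
            expected = _expected_screen_viability(
                design, pot_a, pot_b, m_a, m_b, psi, sensitivity, rank_level
            )
            if k == 0:
                planted_viability = expected
                break
            if expected >= planted_viability + dominance_margin:
                break
        else:
            raise SimulationError(
                f"could not draw a competitor {design.pair_id} dominated by the "
                f"planted combination (margin {dominance_margin} points)"
            )
        for j, model in enumerate(model_ids):
            ta = DrugTruth(name_a, dm=cmax_a * pot_a * sensitivity[j], m=m_a, cmax=cmax_a)
            tb = DrugTruth(name_b, dm=cmax_b * pot_b * sensitivity[j], m=m_b, cmax=cmax_b)
            drug_truths[(model, name_a)] = ta
            drug_truths[(model, name_b)] = tb
            records.extend(
                simulate_combination_plate(
                    ta,
                    tb,
                    interactions[design.pair_id],
                    design=design,
                    replicates=replicates,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                    model_id=model,
                    include_controls=(k == 0),
                )
            )
    truth = ScreenTruth(
        designs=designs,
        drug_truths=drug_truths,
        interactions=interactions,
        planted_winner=designs[0].pair_id,
        model_ids=model_ids,
    )
    return records, truth


def simulate_growth_study(
    truths,
    n_per_group: int = 8,
    days=None,
    seed: int | None = None,
) -> GrowthStudy:
    """Simulate a tumor growth study with one arm per :class:`GrowthTruth`.

    Per-animal volumes follow the arm's exponential trajectory with lognormal
    measurement noise; volumes are converted to caliper (length, width) pairs
    with length = width, so the volume formula round-trips exactly.
    """
    truths = list(truths)
    if not truths:
        raise ParameterError("need at least one treatment arm")
    if n_per_group < 3:
        raise ParameterError(f"need >= 3 animals per arm, got {n_per_group}")
    days = np.asarray([0, 3, 6, 9, 12, 15, 18, 21] if days is None else days, dtype=float)
    if days.size == 0:
        raise ParameterError("days must be nonempty")
    rng = np.random.default_rng(seed)
    animals = []
    for truth in truths:
        for i in range(n_per_group):
            log_noise = rng.normal(0.0, truth.noise_sd, size=days.size)
            volumes = truth.initial_volume * np.exp(truth.rate * truth.effect * days + log_noise)
            # L = W = (2V)^(1/3) makes tumor_volume(L, W) return V exactly
            side = np.cbrt(2.0 * volumes)
            animals.append(
                Animal(
                    animal_id=f"{truth.group}-{i + 1:02d}",
                    group=truth.group,
                    days=days.copy(),
                    lengths=side,
                    widths=side.copy(),
                )
            )
    return GrowthStudy(animals=animals)
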