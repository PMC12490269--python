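"""CSV readers/writers and the screen configuration.

All readers validate strictly: a file with any malformed row is rejected as a
whole, with every problem reported by line number.  Silent row-dropping would
corrupt downstream ranking matrices.

Dialects (all UTF-8, comma-separated, headered):

* plate CSV: ``model_id,treatment_id,concentration_uM,replicate,absorbance,is_control``
* drug metadata CSV: ``drug,cmax_uM`` (clinical peak plasma concentrations)
* measurements CSV: ``animal_id,group,day,length_mm,width_mm``
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import numpy as np
import yaml

from .doseresponse import DEFAULT_CLIP_EPS, HALF_LOG, PlateRecord
from .errors import ConfigError, CSVFormatError, ParameterError
from .growthstats import Animal, GrowthStudy

PLATE_COLUMNS = ["model_id", "treatment_id", "concentration_uM", "replicate", "absorbance", "is_control"]
CMAX_COLUMNS = ["drug", "cmax_uM"]
MEASUREMENT_COLUMNS = ["animal_id", "group", "day", "length_mm", "width_mm"]

_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _read_rows(path, required_columns):
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in required_columns if c not in header]
        if missing:
            raise CSVFormatError(path, [f"missing column(s): {', '.join(missing)}"])
        return list(reader)


def _parse_bool(text: str) -> bool:
    low = text.strip().lower()
    if low in _TRUE:
        return True
    if low in _FALSE:
        return False
    raise ValueError(f"not a boolean: {text!r}")


def read_plate_csv(path) -> list[PlateRecord]:
    """Read and validate a long-format plate CSV into plate records.

    Strict mode: any malformed row fails the whole file, and every model must
    contain at least one control well.
    """
    rows = _read_rows(path, PLATE_COLUMNS)
    problems: list[str] = []
    records: list[PlateRecord] = []
    for lineno, row in enumerate(rows, start=2):  # header is line 1
        try:
            records.append(
                PlateRecord(
                    model_id=row["model_id"].strip(),
                    treatment_id=row["treatment_id"].strip(),
                    concentration=float(row["concentration_uM"]),
                    replicate=int(row["replicate"]),
                    absorbance=float(row["absorbance"]),
                    is_control=_parse_bool(row["is_control"]),
                )
            )
        except (TypeError, ValueError, ParameterError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise CSVFormatError(path, problems)
    if not records:
        raise CSVFormatError(path, ["file contains no data rows"])
    models_with_controls = {r.model_id for r in records if r.is_control}
    orphans = sorted({r.model_id for r in records} - models_with_controls)
    if orphans:
        raise CSVFormatError(
            path, [f"model {m!r} has no control wells" for m in orphans]
        )
    return records


def write_plate_csv(records, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PLATE_COLUMNS)
        for r in records:
            writer.writerow(
                [r.model_id, r.treatment_id, repr(r.concentration),
                 r.replicate, repr(r.absorbance), str(r.is_control).lower()]
            )


def read_cmax_csv(path) -> dict[str, float]:
    """Read the drug metadata table mapping drug name to clinical C_max (µM)."""
    rows = _read_rows(path, CMAX_COLUMNS)
    problems, cmax = [], {}
    for lineno, row in enumerate(rows, start=2):
        drug = row["drug"].strip()
        try:
            value = float(row["cmax_uM"])
            if value <= 0:
                raise ValueError(f"C_max must be positive, got {value}")
            if drug in cmax:
                raise ValueError(f"duplicate drug {drug!r}")
            cmax[drug] = value
        except (TypeError, ValueError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise CSVFormatError(path, problems)
    if not cmax:
        raise CSVFormatError(path, ["file contains no drugs"])
    return cmax


def write_cmax_csv(cmax: dict, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CMAX_COLUMNS)
        for drug in sorted(cmax):
            writer.writerow([drug, repr(float(cmax[drug]))])


def read_measurements_csv(path) -> GrowthStudy:
    """Read a caliper-measurement CSV into a growth study."""
    rows = _read_rows(path, MEASUREMENT_COLUMNS)
    problems = []
    series: dict[str, dict] = {}
    for lineno, row in enumerate(rows, start=2):
        try:
            aid = row["animal_id"].strip()
            group = row["group"].strip()
            day = float(row["day"])
            length = float(row["length_mm"])
            width = float(row["width_mm"])
            if length < 0 or width < 0:
                raise ValueError("caliper measurements must be nonnegative")
            entry = series.setdefault(aid, {"group": group, "points": []})
            if entry["group"] != group:
                raise ValueError(f"animal {aid!r} appears in two groups")
            entry["points"].append((day, length, width))
        except (TypeError, ValueError) as exc:
            problems.append(f"line {lineno}: {exc}")
    if problems:
        raise CSVFormatError(path, problems)
    if not series:
        raise CSVFormatError(path, ["file contains no measurements"])
    animals = []
    for aid in sorted(series):
        pts = sorted(series[aid]["points"])
        days, lengths, widths = (np.array(col) for col in zip(*pts))
        animals.append(
            Animal(animal_id=aid, group=series[aid]["group"],
                   days=days, lengths=lengths, widths=widths)
        )
    return GrowthStudy(animals=animals)


def write_measurements_csv(study: GrowthStudy, path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(MEASUREMENT_COLUMNS)
        for animal in study.animals:
            for day, length, width in zip(animal.days, animal.lengths, animal.widths):
                writer.writerow(
                    [animal.animal_id, animal.group, repr(float(day)),
                     repr(float(length)), repr(float(width))]
                )


@dataclass
class ScreenConfig:
    """Configuration of a screen→rank→synergy run.

    ``cmax`` maps drug names to clinical C_max (µM); ``pairs`` lists the
    ordered drug combinations to analyze.  All randomness (bootstrap,
    permutations) flows from the single top-level ``seed``.
    """

    cmax: dict
    pairs: list = field(default_factory=list)  # list of (drug_a, drug_b)
    levels: tuple = (1.0, 0.1)
    ladder_points: int = 6
    dilution_factor: float = HALF_LOG
    clip_eps: float = DEFAULT_CLIP_EPS
    auc_axis: str = "log10"
    rank_level: float = 0.1
    rank_metric: str = "viability"
    bootstrap_resamples: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not self.cmax:
            raise ConfigError("cmax table is empty")
        for drug, value in self.cmax.items():
            if value <= 0:
                raise ConfigError(f"C_max for {drug!r} must be positive, got {value}")
        self.pairs = [tuple(p) for p in self.pairs]
        for a, b in self.pairs:
            for drug in (a, b):
                if drug not in self.cmax:
                    raise ConfigError(f"pair drug {drug!r} missing from the C_max table")
        for s in self.levels:
            if not 0 < s <= 1:
                raise ConfigError(f"fixed-ratio level {s} outside (0, 1]")
        if self.auc_axis not in ("log10", "linear"):
            raise ConfigError(f"unknown AUC axis {self.auc_axis!r}")
        if self.rank_metric not in ("viability", "auc"):
            raise ConfigError(f"unknown rank metric {self.rank_metric!r}")

    @classmethod
    def from_yaml(cls, path) -> "ScreenConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            cfg = cls(**data)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc
        if "levels" in data:
            cfg.levels = tuple(data["levels"])
        return cfg

    def to_yaml(self, path) -> None:
        payload = {
            "cmax": {k: float(v) for k, v in self.cmax.items()},
            "pairs": [list(p) for p in self.pairs],
            "levels": list(self.levels),
            "ladder_points": self.ladder_points,
            "dilution_factor": self.dilution_factor,
            "clip_eps": self.clip_eps,
            "auc_axis": self.auc_axis,
            "rank_level": self.rank_level,
            "rank_metric": self.rank_metric,
            "bootstrap_resamples": self.bootstrap_resamples,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)
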