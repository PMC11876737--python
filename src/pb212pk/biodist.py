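"""Destructive-sampling biodistribution quantification.

Each mouse is sampled once (one nominal timepoint); every organ yields
γ-counter net counts which are turned into percent injected dose per
gram (%ID/g) against a per-animal standard. Two decay-correction
conventions are supported:

``to_injection``
    counts referenced back to the injection time — physical decay is
    removed entirely, isolating the biology (uptake/washout).
``to_collection``
    counts referenced to the organ-collection time — physical ²¹²Pb
    decay up to collection is retained, approximating the activity that
    was actually present in the tissue (the absorbed-dose surrogate
    convention).

Under both modes the standard is referenced to injection time, so the
counting delay cancels and the two conventions differ exactly by
e^{λ(collection − injection)}.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PB212_HALF_LIFE_H

LAMBDA_PB212 = math.log(2.0) / PB212_HALF_LIFE_H  # 1/h

#: organ label normalisation (lower-case singular keys)
ORGAN_ALIASES = {
    "kidneys": "kidney",
    "lungs": "lung",
    "tumour": "tumor",
}


class CorrectionMode(enum.Enum):
    """Decay-correction convention for %ID/g."""

    TO_INJECTION = "injection"
    TO_COLLECTION = "collection"


def normalize_organ(label: str) -> str:
    key = label.strip().lower()
    return ORGAN_ALIASES.get(key, key)


def subtract_background(gross_counts: float, background_counts: float) -> tuple[float, bool]:
    """Net counts = max(gross − background, 0); flag when clamped.

    Clamping (rather than dropping) keeps cohort n intact.
    """
    if gross_counts < 0 or background_counts < 0:
        raise ValueError("counts must be non-negative")
    net = gross_counts - background_counts
    if net < 0:
        return 0.0, True
    return net, False


@dataclass(frozen=True)
class OrganSample:
    """One organ from one animal: mass and background-subtracted counts."""

    organ: str
    mass_g: float
    net_counts: float
    count_time_h: float
    collection_time_h: float
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError(f"{self.organ}: mass must be positive")
        if self.net_counts < 0:
            raise ValueError(f"{self.organ}: net counts must be non-negative")
        if self.count_time_h < self.collection_time_h:
            raise ValueError(f"{self.organ}: counted before collection")
        object.__setattr__(self, "organ", normalize_organ(self.organ))


@dataclass(frozen=True)
class AnimalRecord:
    """One animal: injection, per-animal standard, and organ samples.

    The standard is an aliquot representing ``standard_fraction`` of the
    injected dose, counted at ``standard_count_time_h``; it anchors the
    injected-dose-equivalent counts every %ID/g is normalised by.
    """

    animal_id: str
    compound: str
    injection_time_h: float
    injected_standard_counts: float
    standard_fraction: float
    standard_count_time_h: float
    samples: tuple[OrganSample, ...]
    nominal_timepoint_h: float

    def __post_init__(self) -> None:
        if not 0 < self.standard_fraction <= 1:
            raise ValueError("standard_fraction must be in (0, 1]")
        if self.injected_standard_counts <= 0:
            raise ValueError("standard counts must be positive")

    def sample(self, organ: str) -> OrganSample:
        organ = normalize_organ(organ)
        for s in self.samples:
            if s.organ == organ:
                return s
        raise KeyError(f"animal {self.animal_id}: no sample for organ {organ!r}")

    def injected_dose_counts(self) -> float:
        """Standard counts referenced to injection time, scaled to the full dose."""
        back = math.exp(
            LAMBDA_PB212 * (self.standard_count_time_h - self.injection_time_h)
        )
        return self.injected_standard_counts * back / self.standard_fraction


@dataclass
class CohortTable:
    """A destructive-sampling study: animals grouped by (compound, timepoint)."""

    study_id: str
    records: list[AnimalRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.compound, rec.animal_id)
            if key in seen:
                raise ValueError(
                    f"animal {rec.animal_id} appears more than once (destructive sampling)"
                )
            seen.add(key)

    def compounds(self) -> list[str]:
        return sorted({r.compound for r in self.records})

    def timepoints(self, compound: str) -> list[float]:
        return sorted({r.nominal_timepoint_h for r in self.records if r.compound == compound})

    def group(self, compound: str, timepoint_h: float) -> list[AnimalRecord]:
        return [
            r
            for r in self.records
            if r.compound == compound and r.nominal_timepoint_h == timepoint_h
        ]


def percent_id_per_gram(
    sample: OrganSample, animal: AnimalRecord, mode: CorrectionMode
) -> float:
    """%ID/g of one organ sample under the chosen correction convention."""
    s0 = animal.injected_dose_counts()
    if mode is CorrectionMode.TO_INJECTION:
        ref = animal.injection_time_h
    elif mode is CorrectionMode.TO_COLLECTION:
        ref = sample.collection_time_h
    else:  # pragma: no cover - exhaustive enum
        raise ValueError(f"unknown mode {mode!r}")
    corrected = sample.net_counts * math.exp(LAMBDA_PB212 * (sample.count_time_h - ref))
    return 100.0 * corrected / (s0 * sample.mass_g)


def animal_pidg(animal: AnimalRecord, organ: str, mode: CorrectionMode) -> float:
    """Convenience: %ID/g for one organ of one animal."""
    return percent_id_per_gram(animal.sample(organ), animal, mode)


def cohort_summary(
    table: CohortTable, organ: str, mode: CorrectionMode, compound: str | None = None
) -> pd.DataFrame:
    """Per-(compound, timepoint) mean %ID/g, sample SD (n−1) and n.

    SD is reported as NaN (not 0) for n = 1 groups. A requested organ
    missing from an entire group raises, naming the gap.
    """
    organ = normalize_organ(organ)
    compounds = [compound] if compound is not None else table.compounds()
    rows = []
    for cmp_ in compounds:
        tps = table.timepoints(cmp_)
        if not tps:
            raise ValueError(f"no animals for compound {cmp_!r}")
        for tp in tps:
            vals = []
            for rec in table.group(cmp_, tp):
                try:
                    vals.append(animal_pidg(rec, organ, mode))
                except KeyError:
                    continue
            if not vals:
                raise ValueError(
                    f"organ {organ!r} missing from every animal of "
                    f"({cmp_!r}, {tp} h)"
                )
            arr = np.asarray(vals)
            rows.append(
                {
                    "compound": cmp_,
                    "timepoint_h": tp,
                    "organ": organ,
                    "mode": mode.value,
                    "mean_pidg": arr.mean(),
                    "sd_pidg": arr.std(ddof=1) if len(arr) > 1 else np.nan,
                    "n": len(arr),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV schema (one row per organ sample); times ISO-8601 or hours

_SCHEMA = [
    "study_id",
    "compound",
    "animal_id",
    "nominal_timepoint_h",
    "organ",
    "mass_g",
    "gross_counts",
    "background_counts",
    "count_time",
    "collection_time",
    "injection_time",
    "standard_counts",
    "standard_count_time",
    "standard_fraction",
]

_TIME_COLS = ["count_time", "collection_time", "injection_time", "standard_count_time"]


def _times_to_hours(df: pd.DataFrame) -> pd.DataFrame:
    """Convert the schema's time columns to hours from the study epoch.

    Accepts either ISO-8601 strings (epoch = earliest injection) or
    numeric hours (used as-is).
    """
    df = df.copy()
    if all(pd.api.types.is_numeric_dtype(df[c]) for c in _TIME_COLS):
        return df
    parsed = {c: pd.to_datetime(df[c]) for c in _TIME_COLS}
    epoch = parsed["injection_time"].min()
    for c in _TIME_COLS:
        df[c] = (parsed[c] - epoch).dt.total_seconds() / 3600.0
    return df


def read_cohort_csv(path) -> CohortTable:
    """Load a biodistribution CSV into a :class:`CohortTable`.

    Schema violations are reported with the offending row index.
    """
    df = pd.read_csv(path)
    missing = set(_SCHEMA) - set(df.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    df = _times_to_hours(df)
    study_ids = df["study_id"].unique()
    if len(study_ids) != 1:
        raise ValueError(f"expected one study_id per file, found {list(study_ids)}")
    records = []
    for (cmp_, animal), grp in df.groupby(["compound", "animal_id"], sort=True):
        head = grp.iloc[0]
        samples = []
        for idx, row in grp.iterrows():
            net, clamped = subtract_background(
                row["gross_counts"], row["background_counts"]
            )
            try:
                samples.append(
                    OrganSample(
                        organ=row["organ"],
                        mass_g=row["mass_g"],
                        net_counts=net,
                        count_time_h=row["count_time"],
                        collection_time_h=row["collection_time"],
                        clamped=clamped,
                    )
                )
            except ValueError as exc:
                raise ValueError(f"row {idx}: {exc}") from None
        records.append(
            AnimalRecord(
                animal_id=str(animal),
                compound=str(cmp_),
                injection_time_h=head["injection_time"],
                injected_standard_counts=head["standard_counts"],
                standard_fraction=head["standard_fraction"],
                standard_count_time_h=head["standard_count_time"],
                samples=tuple(samples),
                nominal_timepoint_h=head["nominal_timepoint_h"],
            )
        )
    return CohortTable(study_id=str(study_ids[0]), records=records)


def write_cohort_csv(table: CohortTable, path) -> None:
    """Write a cohort in the canonical input schema (numeric hours).

    Net counts are emitted as gross with zero background (background was
    already subtracted upstream), so the file round-trips through
    :func:`read_cohort_csv`.
    """
    df = cohort_to_frame(table).rename(
        columns={
            "net_counts": "gross_counts",
            "count_time_h": "count_time",
            "collection_time_h": "collection_time",
            "injection_time_h": "injection_time",
            "standard_count_time_h": "standard_count_time",
        }
    )
    df["background_counts"] = 0.0
    df[_SCHEMA].to_csv(path, index=False)


def cohort_to_frame(table: CohortTable) -> pd.DataFrame:
    """Flatten a cohort to one row per organ sample (hours, net counts)."""
    rows = []
    for rec in table.records:
        for s in rec.samples:
            rows.append(
                {
                    "study_id": table.study_id,
                    "compound": rec.compound,
                    "animal_id": rec.animal_id,
                    "nominal_timepoint_h": rec.nominal_timepoint_h,
                    "organ": s.organ,
                    "mass_g": s.mass_g,
                    "net_counts": s.net_counts,
                    "count_time_h": s.count_time_h,
                    "collection_time_h": s.collection_time_h,
                    "injection_time_h": rec.injection_time_h,
                    "standard_counts": rec.injected_standard_counts,
                    "standard_count_time_h": rec.standard_count_time_h,
                    "standard_fraction": rec.standard_fraction,
                }
            )
    return pd.DataFrame(rows)
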