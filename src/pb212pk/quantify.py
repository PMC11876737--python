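"""Instrument readings → true ²¹²Pb activity.

A dose calibrator converts ionisation current to an activity readout
through an opaque "dial value" (Capintec: calibration number); a wrong
dial scales every reading multiplicatively. Readings here are anchored
to an HPGe measurement extrapolated for total activity, dial settings
are compared empirically, and historically misreported doses are
rescaled by the measured overestimation ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .constants import GAMMA_YIELD_238KEV, PB212_HALF_LIFE_H
from .decay import decay_factor

#: Same-source readings must agree in time to this tolerance (hours).
TIMESTAMP_TOLERANCE_H = 5.0 / 60.0


@dataclass(frozen=True)
class CalibratorReading:
    """One dose-calibrator measurement at a given dial setting."""

    instrument: str
    dial_value: float
    reading_mbq: float
    read_time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.reading_mbq < 0:
            raise ValueError("reading must be non-negative")
        if self.dial_value <= 0:
            raise ValueError("dial value must be positive")


@dataclass(frozen=True)
class CalibrationAnchor:
    """Trusted activity at a reference time (e.g. HPGe extrapolation)."""

    reference_activity_mbq: float
    reference_time_h: float = 0.0
    method: str = "HPGe extrapolation"

    def __post_init__(self) -> None:
        if self.reference_activity_mbq <= 0:
            raise ValueError("reference activity must be positive")


def dial_overestimation_ratio(
    suspect: CalibratorReading, trusted: CalibratorReading
) -> float:
    """Suspect reading as a percent OF the trusted reading.

    The percent-of convention (100 × suspect/trusted) is used: a reading
    3.2× too high reports as 320%, the factor by which doses quantified
    at the suspect dial were overestimated.
    """
    if trusted.reading_mbq <= 0:
        raise ValueError("trusted reading must be positive")
    if abs(suspect.read_time_h - trusted.read_time_h) > TIMESTAMP_TOLERANCE_H:
        raise ValueError(
            "readings are not of the same source at the same time "
            f"(Δt = {abs(suspect.read_time_h - trusted.read_time_h):.3f} h)"
        )
    return 100.0 * suspect.reading_mbq / trusted.reading_mbq


def round_ratio_for_report(ratio_pct: float) -> float:
    """Human-facing rounding of a dial ratio to the nearest 10%."""
    return round(ratio_pct / 10.0) * 10.0


def rescale_reported_dose(reported: float, ratio_pct: float) -> float:
    """Correct a dose that was read at an overestimating dial setting.

    Units of ``reported`` are preserved.
    """
    if ratio_pct <= 0:
        raise ValueError("ratio must be positive")
    return reported * 100.0 / ratio_pct


def predict_reading(anchor: CalibrationAnchor, elapsed_h: float) -> float:
    """Expected ²¹²Pb activity (MBq) after physical decay from the anchor."""
    return anchor.reference_activity_mbq * decay_factor(elapsed_h, PB212_HALF_LIFE_H)


def counts_to_activity(
    net_counts: float,
    live_time_s: float,
    efficiency: float,
    gamma_yield: float = GAMMA_YIELD_238KEV,
) -> float:
    """γ-counter net counts in the 238 keV window → activity in Bq."""
    if live_time_s <= 0:
        raise ValueError("live time must be positive")
    if not 0 < efficiency <= 1:
        raise ValueError("efficiency must be in (0, 1]")
    if net_counts < 0:
        raise ValueError("net counts must be non-negative")
    return net_counts / (live_time_s * efficiency * gamma_yield)


def expected_counts(
    activity_bq: float,
    live_time_s: float,
    efficiency: float,
    gamma_yield: float = GAMMA_YIELD_238KEV,
) -> float:
    """Algebraic inverse of :func:`counts_to_activity`."""
    return activity_bq * live_time_s * efficiency * gamma_yield


def read_instrument_log(path) -> pd.DataFrame:
    """Read an instrument-log CSV.

    Columns: instrument, dial_value, reading_value, reading_unit,
    read_time (ISO-8601). Times are converted to hours from the earliest
    entry and stored in ``read_time_h``.
    """
    df = pd.read_csv(path)
    required = {"instrument", "dial_value", "reading_value", "reading_unit", "read_time"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"instrument log missing columns: {sorted(missing)}")
    ts = pd.to_datetime(df["read_time"])
    df["read_time_h"] = (ts - ts.min()).dt.total_seconds() / 3600.0
    return df
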