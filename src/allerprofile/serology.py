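"""Immunoassay statistics: ELISA positivity, sensitization rates, inhibition.

The positivity cutoff for a serum IgE ELISA is three times the mean OD450 of
nonallergic control sera; a serum is called positive when its (replicate-
averaged) OD lies strictly above the cutoff.  The sensitization rate is the
percent of positive calls among tested sera, reported to one decimal.

Competition assays (inhibition ELISA / inhibition immunoblot) are summarised
with percent inhibition

    100 x (S_no - S_inh) / S_no

where ``S_no`` is the signal without inhibitor.  Negative values (signal
enhancement) are kept, not clamped.  A dilution series is dose-dependent when
percent inhibition never drops more than 2 percentage points below its
running maximum as concentration increases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ODPlate",
    "InhibitionSeries",
    "SensitizationResult",
    "InhibitionSummary",
    "read_plate",
    "read_inhibition",
    "elisa_cutoff",
    "call_positives",
    "sensitization_rate",
    "percent_inhibition",
    "inhibition_summary",
]

STATUSES = ("allergic", "nonallergic")


@dataclass
class ODPlate:
    """Long-format OD450 readings: one row per (serum, antigen, replicate)."""

    data: pd.DataFrame  # columns: serum_id, status, antigen, od

    def __post_init__(self) -> None:
        required = {"serum_id", "status", "antigen", "od"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"plate table missing columns {sorted(missing)}")
        if (self.data["od"] < 0).any():
            raise ValueError("OD readings must be non-negative")
        bad = set(self.data["status"]) - set(STATUSES)
        if bad:
            raise ValueError(f"unknown serum status values: {sorted(bad)}")

    def mean_od(self, antigen: str | None = None) -> pd.DataFrame:
        """Replicate-averaged OD per serum (mean and SD), optionally one antigen."""
        df = self.data
        if antigen is not None:
            df = df[df["antigen"] == antigen]
            if df.empty:
                raise ValueError(f"no readings for antigen {antigen!r}")
        out = (
            df.groupby(["serum_id", "status"], sort=False)["od"]
            .agg(od_mean="mean", od_sd="std", n_replicates="count")
            .reset_index()
        )
        out["od_sd"] = out["od_sd"].fillna(0.0)
        return out

    def negative_ods(self, antigen: str | None = None) -> np.ndarray:
        means = self.mean_od(antigen)
        neg = means[means["status"] == "nonallergic"]["od_mean"]
        return neg.to_numpy()


def read_plate(path, sep: str = "\t") -> ODPlate:
    """Read a plate TSV with columns serum_id, status, antigen, od[, replicate]."""
    return ODPlate(pd.read_csv(path, sep=sep))


@dataclass
class InhibitionSeries:
    """Signals along an inhibitor dilution series plus the no-inhibitor signal."""

    inhibitor: str
    concentrations: np.ndarray  # ug/mL, strictly increasing
    signals: np.ndarray  # OD or band intensity at each concentration
    signal_no_inhibitor: float

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.concentrations.shape != self.signals.shape:
            raise ValueError("concentrations and signals must be parallel")
        if not (np.diff(self.concentrations) > 0).all():
            raise ValueError("concentrations must be strictly increasing")
        if self.signal_no_inhibitor <= 0:
            raise ValueError("no-inhibitor signal must be positive")
        if (self.signals < 0).any():
            raise ValueError("signals must be non-negative")

    @property
    def percent_inhibition(self) -> np.ndarray:
        return np.array(
            [percent_inhibition(self.signal_no_inhibitor, s) for s in self.signals]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "inhibitor": self.inhibitor,
                "concentration_ug_ml": self.concentrations,
                "signal": self.signals,
                "percent_inhibition": np.round(self.percent_inhibition, 1),
            }
        )


def read_inhibition(path, sep: str = "\t") -> list[InhibitionSeries]:
    """Read an inhibition TSV (inhibitor, concentration_ug_ml, signal).

    The row with concentration 0 is the no-inhibitor reference for its
    inhibitor and is required once per series.
    """
    df = pd.read_csv(path, sep=sep)
    required = {"inhibitor", "concentration_ug_ml", "signal"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    series = []
    for inhibitor, grp in df.groupby("inhibitor", sort=False):
        ref = grp[grp["concentration_ug_ml"] == 0]
        if len(ref) != 1:
            raise ValueError(
                f"{path}: inhibitor {inhibitor!r} needs exactly one "
                "concentration-0 (no-inhibitor) row"
            )
        rest = grp[grp["concentration_ug_ml"] > 0].sort_values("concentration_ug_ml")
        series.append(
            InhibitionSeries(
                inhibitor=str(inhibitor),
                concentrations=rest["concentration_ug_ml"].to_numpy(),
                signals=rest["signal"].to_numpy(),
                signal_no_inhibitor=float(ref["signal"].iloc[0]),
            )
        )
    return series


@dataclass
class SensitizationResult:
    antigen: str
    n_tested: int
    n_positive: int
    rate: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0 <= self.n_positive <= self.n_tested):
            raise ValueError("need 0 <= n_positive <= n_tested")
        self.rate = round(100.0 * self.n_positive / self.n_tested, 1)


def elisa_cutoff(negative_ods: Sequence[float], multiplier: float = 3.0) -> float:
    """Positivity cutoff: ``multiplier`` x mean OD of nonallergic sera."""
    ods = np.asarray(list(negative_ods), dtype=float)
    if ods.size == 0:
        raise ValueError("need at least one nonallergic (negative) OD")
    if (ods < 0).any():
        raise ValueError("OD readings must be non-negative")
    if multiplier <= 0:
        raise ValueError("multiplier must be positive")
    return float(multiplier * ods.mean())


def call_positives(
    plate: ODPlate, cutoff: float, antigen: str | None = None
) -> pd.Series:
    """Per-serum positivity calls: replicate-mean OD strictly above the cutoff.

    Ties at the cutoff are called negative (conservative boundary rule).
    """
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    means = plate.mean_od(antigen)
    return pd.Series(
        (means["od_mean"] > cutoff).to_numpy(),
        index=means["serum_id"],
        name="positive",
    )


def sensitization_rate(
    calls: Sequence[bool], antigen: str = ""
) -> SensitizationResult:
    """Percent of positive calls (1 decimal), with counts carried alongside."""
    calls = np.asarray(list(calls), dtype=bool)
    if calls.size == 0:
        raise ValueError("cannot compute a rate from zero tested sera")
    return SensitizationResult(antigen, int(calls.size), int(calls.sum()))


def percent_inhibition(
    signal_no_inhibitor: float, signal_with_inhibitor: float
) -> float:
    """100 x (S_no - S_inh)/S_no; negative when the inhibitor enhances signal."""
    if signal_no_inhibitor <= 0:
        raise ValueError("no-inhibitor signal must be positive")
    if signal_with_inhibitor < 0:
        raise ValueError("inhibited signal must be non-negative")
    return 100.0 * (signal_no_inhibitor - signal_with_inhibitor) / signal_no_inhibitor


@dataclass
class InhibitionSummary:
    inhibitor: str
    max_inhibition: float
    concentration_at_max: float
    dose_dependent: bool
    any_negative: bool  # flags enhancement artifacts somewhere in the series


def inhibition_summary(
    series: InhibitionSeries, tolerance: float = 2.0
) -> InhibitionSummary:
    """Maximum percent inhibition and a dose-dependence flag.

    The series is dose-dependent when inhibition never falls more than
    ``tolerance`` percentage points below its running maximum as the
    inhibitor concentration increases.
    """
    if series.concentrations.size < 3:
        raise ValueError("need at least three concentrations to summarise a series")
    inh = series.percent_inhibition
    running_max = np.maximum.accumulate(inh)
    dose_dependent = bool((running_max - inh <= tolerance).all())
    i_max = int(np.argmax(inh))
    return InhibitionSummary(
        inhibitor=series.inhibitor,
        max_inhibition=float(inh[i_max]),
        concentration_at_max=float(series.concentrations[i_max]),
        dose_dependent=dose_dependent,
        any_negative=bool((inh < 0).any()),
    )
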