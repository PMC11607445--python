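"""SOFA scoring, suspicion of infection, and Sepsis-3 onset labeling.

The Sequential Organ Failure Assessment (SOFA) score grades six organ
systems -- respiration, coagulation, liver, cardiovascular, central nervous
system and renal -- on integer levels 0--4 and sums them (range 0--24).  The
aggregate used here is the trailing-window worst value per subscore: at any
time t each subscore is the maximum level observed in the window (t - w, t]
(w = 24 h by default), carrying the last known level forward when the window
is empty and 0 before the first observation.

A suspicion of infection (SOI) is the co-occurrence of an antibiotic
administration and a microbiological culture sampling: antibiotic first with
the culture within 24 h, or culture first with the antibiotic within 72 h
(boundaries inclusive).  The SOI time is the earlier event of the qualifying
pair.  A patient is labeled septic (Sepsis-3) when a SOFA value >= 2 occurs
within 48 h before or 24 h after some SOI; the onset returned is the SOI time
of the earliest qualifying SOI.

Subscore breakpoint tables are configuration data, not code, so they can be
adapted to site conventions (vasopressor tiers in particular vary between
implementations).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "SubscoreTable",
    "SofaConfig",
    "DEFAULT_SOFA_CONFIG",
    "SoiEvent",
    "sofa_subscores",
    "rolling_worst",
    "detect_soi",
    "label_sepsis_onset",
]


# --------------------------------------------------------------------- config
@dataclass(frozen=True)
class SubscoreTable:
    """Breakpoints mapping a raw measurement to integer levels 0-4.

    `thresholds` are the four boundaries for levels 1..4.  For
    ``direction="high_bad"`` a value v scores level k when
    v >= thresholds[k-1]; for ``direction="low_bad"`` when v < thresholds[k-1]
    (the conventional strict readings: e.g. platelets < 150 k/uL scores 1,
    bilirubin >= 1.2 mg/dl scores 1).
    """

    variable: str
    direction: str  # "high_bad" | "low_bad"
    thresholds: Sequence[float]

    def __post_init__(self):
        t = list(self.thresholds)
        if len(t) != 4:
            raise ValueError("need exactly 4 thresholds (levels 1-4)")
        inc = all(a < b for a, b in zip(t, t[1:]))
        dec = all(a > b for a, b in zip(t, t[1:]))
        if not (inc or dec):
            raise ValueError(f"thresholds for {self.variable} not strictly monotone")
        if self.direction not in ("high_bad", "low_bad"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def level(self, value: float) -> int:
        lev = 0
        for k, thr in enumerate(self.thresholds, start=1):
            hit = value >= thr if self.direction == "high_bad" else value < thr
            if hit:
                lev = max(lev, k)
        return lev


@dataclass(frozen=True)
class SofaConfig:
    """Per-subscore breakpoint tables plus the rolling-worst window (hours)."""

    tables: Mapping[str, SubscoreTable] = field(default_factory=dict)
    window: float = 24.0

    def __post_init__(self):
        if self.window <= 0:
            raise ValueError("window must be positive")


# Standard Sepsis-3 subscore breakpoints.  Respiration ignores the
# ventilation qualifier for levels 3-4 and cardiovascular uses a pre-derived
# tier variable (0 = MAP >= 70, 1 = MAP < 70, 2-4 = vasopressor dose tiers),
# since vasopressor-dose conventions differ between sites.
DEFAULT_SOFA_CONFIG = SofaConfig(
    tables={
        "respiration": SubscoreTable("pao2_fio2", "low_bad", (400.0, 300.0, 200.0, 100.0)),
        "coagulation": SubscoreTable("platelets", "low_bad", (150.0, 100.0, 50.0, 20.0)),
        "liver": SubscoreTable("bilirubin_total", "high_bad", (1.2, 2.0, 6.0, 12.0)),
        "cardiovascular": SubscoreTable("cardio_tier", "high_bad", (1.0, 2.0, 3.0, 4.0)),
        "cns": SubscoreTable("gcs", "low_bad", (15.0, 13.0, 10.0, 6.0)),
        "renal": SubscoreTable("creatinine", "high_bad", (1.2, 2.0, 3.5, 5.0)),
    }
)


# ------------------------------------------------------------------ subscores
def sofa_subscores(
    measurements: Mapping[str, tuple],
    config: SofaConfig = DEFAULT_SOFA_CONFIG,
) -> dict:
    """Map raw measurement series to six integer subscore series.

    Parameters
    ----------
    measurements
        Mapping variable name -> (times, values) arrays.  Every variable must
        be referenced by some subscore table.

    Returns
    -------
    dict subscore name -> (times, integer levels in {0..4})
    """
    by_var = {tab.variable: name for name, tab in config.tables.items()}
    for var in measurements:
        if var not in by_var:
            raise KeyError(f"no SOFA subscore table consumes variable {var!r}")
    out = {}
    for name, tab in config.tables.items():
        if tab.variable not in measurements:
            continue
        times, values = measurements[tab.variable]
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        levels = np.array([tab.level(v) for v in values], dtype=int)
        order = np.argsort(times, kind="stable")
        out[name] = (times[order], levels[order])
    return out


def _worst_in_window(times, levels, t, window):
    """Max level in (t-window, t]; carry-forward last level if window empty."""
    in_win = (times > t - window) & (times <= t)
    if in_win.any():
        return int(levels[in_win].max())
    past = times <= t
    if past.any():
        return int(levels[past][-1])
    return 0


def rolling_worst(
    subscores: Mapping[str, tuple],
    window: float = 24.0,
    at: Optional[np.ndarray] = None,
) -> tuple:
    """Aggregate subscore series into the SOFA series.

    SOFA(t) = sum over subscores of the worst (max) level observed in
    (t - window, t].  An empty window carries the last known level forward;
    before the first observation a subscore contributes 0.

    Parameters
    ----------
    subscores
        Mapping name -> (times, levels), e.g. from :func:`sofa_subscores`.
    at
        Evaluation times; defaults to the sorted union of observation times.

    Returns
    -------
    (times, sofa) arrays; empty input gives empty output.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    series = [(np.asarray(t, float), np.asarray(v, int)) for t, v in subscores.values()]
    if at is None:
        all_t = np.concatenate([t for t, _ in series]) if series else np.array([])
        at = np.unique(all_t)
    at = np.asarray(at, dtype=float)
    if at.size == 0:
        return at, np.zeros(0, dtype=int)
    sofa = np.zeros(at.size, dtype=int)
    for times, levels in series:
        if times.size == 0:
            continue
        sofa += np.array([_worst_in_window(times, levels, t, window) for t in at])
    return at, sofa


# ------------------------------------------------------------------------ SOI
@dataclass(frozen=True)
class SoiEvent:
    """A qualifying antibiotic/culture pair; soi_time is the earlier event."""

    soi_time: float
    antibiotic_time: float
    culture_time: float

    def __post_init__(self):
        if self.soi_time != min(self.antibiotic_time, self.culture_time):
            raise ValueError("soi_time must be the earlier component event")


def detect_soi(
    antibiotic_times: Iterable[float],
    culture_times: Iterable[float],
    abx_then_culture: float = 24.0,
    culture_then_abx: float = 72.0,
) -> list:
    """Find all suspicion-of-infection events.

    A pair (antibiotic at a, culture at c) qualifies iff c - a in [0, 24] h
    or a - c in [0, 72] h, boundaries inclusive.  Returns events sorted by
    soi_time (duplicate soi_times collapsed to the first qualifying pair).
    """
    abx = np.sort(np.asarray(list(antibiotic_times), dtype=float))
    cul = np.sort(np.asarray(list(culture_times), dtype=float))
    if not (np.isfinite(abx).all() and np.isfinite(cul).all()):
        raise ValueError("event times must be finite")
    events = []
    for a in abx:
        for c in cul:
            if (0.0 <= c - a <= abx_then_culture) or (0.0 <= a - c <= culture_then_abx):
                events.append(SoiEvent(min(a, c), a, c))
    events.sort(key=lambda e: (e.soi_time, e.antibiotic_time, e.culture_time))
    seen, out = set(), []
    for e in events:
        if e.soi_time not in seen:
            seen.add(e.soi_time)
            out.append(e)
    return out


def label_sepsis_onset(
    sofa_times: np.ndarray,
    sofa_values: np.ndarray,
    soi_events: Sequence[SoiEvent],
    before: float = 48.0,
    after: float = 24.0,
    threshold: float = 2.0,
) -> Optional[float]:
    """Sepsis-3 label: earliest SOI with a SOFA >= threshold in its window.

    A SOI qualifies when some SOFA value >= `threshold` has a timestamp in
    [soi - before, soi + after] (boundaries inclusive).  Returns the
    soi_time of the earliest qualifying SOI, or None if the patient is not
    septic.
    """
    t = np.asarray(sofa_times, dtype=float)
    v = np.asarray(sofa_values, dtype=float)
    high = t[v >= threshold]
    for e in sorted(soi_events, key=lambda e: e.soi_time):
        if np.any((high >= e.soi_time - before) & (high <= e.soi_time + after)):
            return e.soi_time
    return None
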