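"""Patient-level data containers and long-format table I/O.

A :class:`PatientRecord` holds one patient's raw clinical data in the shape
it arrives from an EHR export: an irregular long-format observation table
(time, variable, value), antibiotic administration intervals, microbiology
events and static demographics.  Model-ready tensors (hourly grids, masks,
control paths) are produced from these records by :mod:`optab.preprocess`.

Cohorts are stored on disk as four delimited text files per directory:
``observations.csv`` (patient_id, time_h, variable, value),
``treatments.csv`` (patient_id, start_h, end_h, antibiotic),
``micro.csv`` (patient_id, sample_time_h, result_time_h, organism_class,
resistant_to) and ``statics.csv`` (patient_id + one column per static).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

__all__ = ["PatientRecord", "write_cohort", "read_cohort"]

OBS_COLUMNS = ["patient_id", "time_h", "variable", "value"]
TREAT_COLUMNS = ["patient_id", "start_h", "end_h", "antibiotic"]
MICRO_COLUMNS = ["patient_id", "sample_time_h", "result_time_h", "organism_class", "resistant_to"]


@dataclass
class PatientRecord:
    """Raw irregular data for one patient.

    observations: columns (time_h, variable, value), times in hours from
    admission/onset reference; treatments: (start_h, end_h, antibiotic)
    intervals during which the antibiotic is ongoing; micro: culture events
    with the organism class and a ';'-separated list of antibiotics the
    organism is resistant to; statics: e.g. sex, age, height, weight.
    """

    patient_id: int
    observations: pd.DataFrame
    treatments: pd.DataFrame
    micro: pd.DataFrame
    statics: Dict[str, float]
    t0: float = 0.0
    sepsis_onset: Optional[float] = None

    def variable(self, name: str):
        """(times, values) arrays for one variable, sorted by time."""
        sub = self.observations[self.observations["variable"] == name]
        sub = sub.sort_values("time_h", kind="stable")
        return sub["time_h"].to_numpy(float), sub["value"].to_numpy(float)

    def treatment_indicator(self, antibiotic: str, times: np.ndarray) -> np.ndarray:
        """Binary ongoing-treatment indicator evaluated at `times`.

        A patient counts as treated at t when some interval satisfies
        start_h <= t < end_h (end exclusive so back-to-back intervals do not
        double-count the switch hour).
        """
        times = np.asarray(times, dtype=float)
        ind = np.zeros(times.size, dtype=float)
        sub = self.treatments[self.treatments["antibiotic"] == antibiotic]
        for _, row in sub.iterrows():
            ind[(times >= row["start_h"]) & (times < row["end_h"])] = 1.0
        return ind


def write_cohort(cohort: List[PatientRecord], out_dir) -> None:
    """Write a cohort to a directory of delimited text tables."""
    if not cohort:
        raise ValueError("cohort is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    obs = pd.concat(
        [p.observations.assign(patient_id=p.patient_id) for p in cohort],
        ignore_index=True,
    )[OBS_COLUMNS]
    tre = pd.concat(
        [p.treatments.assign(patient_id=p.patient_id) for p in cohort],
        ignore_index=True,
    )
    tre = tre[TREAT_COLUMNS] if len(tre) else pd.DataFrame(columns=TREAT_COLUMNS)
    mic = pd.concat(
        [p.micro.assign(patient_id=p.patient_id) for p in cohort], ignore_index=True
    )
    mic = mic[MICRO_COLUMNS] if len(mic) else pd.DataFrame(columns=MICRO_COLUMNS)
    sta = pd.DataFrame(
        [{"patient_id": p.patient_id, "t0": p.t0, **p.statics} for p in cohort]
    )
    obs.to_csv(out / "observations.csv", index=False)
    tre.to_csv(out / "treatments.csv", index=False)
    mic.to_csv(out / "micro.csv", index=False)
    sta.to_csv(out / "statics.csv", index=False)


def read_cohort(in_dir) -> List[PatientRecord]:
    """Read a cohort written by :func:`write_cohort` (exact round trip)."""
    src = Path(in_dir)
    obs = pd.read_csv(src / "observations.csv")
    tre = pd.read_csv(src / "treatments.csv")
    mic = pd.read_csv(src / "micro.csv", keep_default_na=False, na_values=[])
    sta = pd.read_csv(src / "statics.csv")
    cohort = []
    for _, srow in sta.iterrows():
        pid = int(srow["patient_id"])
        statics = {k: srow[k] for k in sta.columns if k not in ("patient_id", "t0")}
        cohort.append(
            PatientRecord(
                patient_id=pid,
                observations=obs[obs["patient_id"] == pid]
                .drop(columns="patient_id")
                .reset_index(drop=True),
                treatments=tre[tre["patient_id"] == pid]
                .drop(columns="patient_id")
                .reset_index(drop=True),
                micro=mic[mic["patient_id"] == pid]
                .drop(columns="patient_id")
                .reset_index(drop=True),
                statics=statics,
                t0=float(srow.get("t0", 0.0)),
            )
        )
    return cohort
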