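"""From labeled cohorts to model-ready tensors.

Pipeline (in the order it runs):

1. coverage filter -- drop variables measured in less than half the cohort;
2. correlation selection -- keep variables whose absolute Spearman
   correlation with SOFA exceeds 0.3 in at least one 12 h interval
   (per-patient within-bin means pooled across patients by default);
3. hourly rounding with a keep-latest collision rule;
4. z-normalization with statistics fitted on the training split only;
5. KNN imputation of the initial (t0) values;
6. cumulative missing-count masks as extra channels;
7. rectilinear control path construction.

The rectilinear (time-then-value) interpolation makes the control path at
time t depend only on data observed up to t, which is what makes the
encoder causal and online-updateable: appending later observations extends
the knot sequence without touching existing knots.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import warnings

import numpy as np
import pandas as pd
from scipy.stats import ConstantInputWarning, spearmanr
from sklearn.impute import KNNImputer

from .records import PatientRecord


def _spearman(a, b) -> float:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantInputWarning)
        return spearmanr(a, b).statistic

__all__ = [
    "PreprocessConfig",
    "GridRecord",
    "ControlPath",
    "PreprocessResult",
    "filter_by_coverage",
    "select_by_spearman",
    "fit_apply_normalization",
    "knn_impute_initial",
    "round_to_hours",
    "cumulative_masks",
    "build_rectilinear_path",
    "preprocess_cohort",
]

#: outcome rows Y: disease state plus side-effect indicating labs
OUTCOMES = ("sofa", "creatinine", "bilirubin_total", "alt")


@dataclass
class PreprocessConfig:
    coverage_min: float = 0.5
    spearman_min: float = 0.3
    bin_width: float = 12.0            # hours
    knn_k: int = 5
    hour_collision: str = "latest"     # "latest" | "mean"
    spearman_mode: str = "binned"      # "binned" | "raw"
    time_scale: float = 1.0 / 24.0     # control-path time channel units
    mask_scale: float = 0.1            # cumulative-count channel units
    grid_hours: Optional[int] = None   # common grid length; default = cohort max

    def __post_init__(self):
        if not 0.0 < self.coverage_min <= 1.0:
            raise ValueError("coverage_min must be in (0, 1]")
        if not 0.0 <= self.spearman_min <= 1.0:
            raise ValueError("spearman_min must be in [0, 1]")


# ------------------------------------------------------------------ selection
def filter_by_coverage(
    cohort: Sequence[PatientRecord], coverage_min: float = 0.5
) -> List[str]:
    """Variables observed at least once in >= coverage_min of the patients.

    The boundary is kept: a variable covering exactly the threshold fraction
    survives ("less than 50%" is what gets excluded).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    counts: Dict[str, int] = {}
    for p in cohort:
        for var in p.observations["variable"].unique():
            counts[var] = counts.get(var, 0) + 1
    n = len(cohort)
    return sorted(v for v, c in counts.items() if c / n >= coverage_min)


def select_by_spearman(
    cohort: Sequence[PatientRecord],
    candidates: Optional[Sequence[str]] = None,
    spearman_min: float = 0.3,
    bin_width: float = 12.0,
    mode: str = "binned",
    sofa_variable: str = "sofa",
) -> Tuple[List[str], pd.DataFrame]:
    """Keep variables correlated with SOFA in at least one time interval.

    For each `bin_width`-hour interval the per-patient mean of the variable
    and of SOFA are pooled across patients and the Spearman rank correlation
    is computed (``mode="raw"`` pools raw observation pairs matched to the
    nearest SOFA value in the bin instead).  A variable is selected when
    max over bins of \\|rho\\| strictly exceeds `spearman_min`.  Bins with
    fewer than 3 pairs are skipped.  SOFA itself and the outcome labs are
    always retained.

    Returns (selected variables, report) where the report has one row per
    (variable, bin) with the correlation.
    """
    all_obs = pd.concat(
        [p.observations.assign(patient_id=p.patient_id) for p in cohort],
        ignore_index=True,
    )
    if sofa_variable not in set(all_obs["variable"]):
        raise ValueError("SOFA series required for correlation selection")
    if candidates is None:
        candidates = sorted(all_obs["variable"].unique())
    all_obs["bin"] = (all_obs["time_h"] // bin_width).astype(int)

    if mode not in ("binned", "raw"):
        raise ValueError(f"unknown spearman mode {mode!r}")
    agg = (
        all_obs.groupby(["patient_id", "bin", "variable"])["value"]
        .mean()
        .unstack("variable")
    )
    raw_sofa = (
        all_obs[all_obs["variable"] == sofa_variable]
        .set_index(["patient_id", "bin"])["value"]
        .groupby(level=[0, 1])
        .mean()
    )

    rows, selected = [], set()
    for var in candidates:
        if var == sofa_variable:
            continue
        best = 0.0
        if mode == "binned":
            if var not in agg.columns:
                continue
            grouped = agg.groupby(level="bin")
            for b, sub in grouped:
                pair = sub[[var, sofa_variable]].dropna()
                if len(pair) < 3:
                    continue
                rho = _spearman(pair[var], pair[sofa_variable])
                if np.isnan(rho):
                    continue
                rows.append({"variable": var, "bin": int(b), "spearman": rho})
                best = max(best, abs(rho))
        else:
            # raw observations paired with the patient's within-bin mean SOFA
            sub = all_obs[all_obs["variable"] == var].copy()
            sub["sofa_ref"] = raw_sofa.reindex(
                pd.MultiIndex.from_frame(sub[["patient_id", "bin"]])
            ).to_numpy()
            for b, grp in sub.groupby("bin"):
                pair = grp[["value", "sofa_ref"]].dropna()
                if len(pair) < 3:
                    continue
                rho = _spearman(pair["value"], pair["sofa_ref"])
                if np.isnan(rho):
                    continue
                rows.append({"variable": var, "bin": int(b), "spearman": rho})
                best = max(best, abs(rho))
        if best > spearman_min:
            selected.add(var)
    selected.update(v for v in OUTCOMES if v in set(all_obs["variable"]))
    selected.add(sofa_variable)
    keep = sorted(selected & (set(candidates) | {sofa_variable}))
    return keep, pd.DataFrame(rows, columns=["variable", "bin", "spearman"])


# -------------------------------------------------------------- normalization
def fit_apply_normalization(
    cohort: Sequence[PatientRecord],
    stats: Optional[Dict[str, Tuple[float, float]]] = None,
    variables: Optional[Sequence[str]] = None,
) -> Tuple[List[PatientRecord], Dict[str, Tuple[float, float]]]:
    """z-normalize observations: z~ = (z - mean) / sd.

    Statistics are pooled over all patients and times of `cohort` when
    `stats` is None (the fitting split); pass fitted `stats` to apply the
    same affine map unchanged to another split.
    """
    all_obs = pd.concat([p.observations for p in cohort], ignore_index=True)
    if stats is None:
        stats = {}
        for var, sub in all_obs.groupby("variable"):
            if variables is not None and var not in variables:
                continue
            mean = float(sub["value"].mean())
            sd = float(sub["value"].std(ddof=0))
            if sd == 0.0:
                raise ValueError(f"variable {var!r} is degenerate (zero variance)")
            stats[var] = (mean, sd)
    out = []
    for p in cohort:
        obs = p.observations.copy()
        for var, (mean, sd) in stats.items():
            sel = obs["variable"] == var
            obs.loc[sel, "value"] = (obs.loc[sel, "value"] - mean) / sd
        out.append(replace(p, observations=obs))
    return out, stats


def knn_impute_initial(
    initial: np.ndarray, k: int, reference: Optional[np.ndarray] = None
) -> np.ndarray:
    """Complete missing entries of per-patient initial vectors by KNN.

    Each missing entry is replaced by the mean of that entry over the k
    nearest reference vectors (Euclidean distance on commonly observed
    entries; distances rescaled for missingness as in the standard
    nan-Euclidean metric).  `reference` defaults to `initial` itself
    (fit on the training split, then impute other splits against it).
    """
    initial = np.asarray(initial, dtype=float)
    if np.isnan(initial).all(axis=1).any():
        raise ValueError("a patient has every initial value missing")
    ref = initial if reference is None else np.asarray(reference, dtype=float)
    if ref.shape[0] < k:
        raise ValueError(f"need at least k={k} reference vectors")
    imputer = KNNImputer(n_neighbors=k, weights="uniform")
    imputer.fit(ref)
    return imputer.transform(initial)


# -------------------------------------------------------------------- gridding
def round_to_hours(record: PatientRecord, collision: str = "latest") -> PatientRecord:
    """Round observation timestamps to the nearest integer hour.

    Two observations of one variable landing in the same hour collapse to
    the later raw observation (``collision="latest"``, preserving online
    causality) or to their mean (``collision="mean"``).
    """
    obs = record.observations.copy()
    obs["_raw_time"] = obs["time_h"]
    obs["time_h"] = np.rint(obs["time_h"].to_numpy(float))
    if collision == "latest":
        obs = (
            obs.sort_values(["variable", "time_h", "_raw_time"], kind="stable")
            .groupby(["variable", "time_h"], as_index=False)
            .last()
        )
    elif collision == "mean":
        obs = (
            obs.groupby(["variable", "time_h"], as_index=False)
            .agg({"value": "mean", "_raw_time": "max"})
        )
    else:
        raise ValueError(f"unknown collision rule {collision!r}")
    obs = (
        obs.drop(columns="_raw_time")
        .sort_values(["time_h", "variable"], kind="stable")
        .reset_index(drop=True)[["time_h", "variable", "value"]]
    )
    return replace(record, observations=obs)


@dataclass
class GridRecord:
    """One patient on the common hourly grid, normalized.

    Z has NaN where a variable was not observed in that hour; masks hold
    cumulative observation counts (unscaled); A is the binary ongoing-
    treatment indicator; d the normalized statics.  Y (the outcome subset)
    is addressed through `outcome_idx` into the rows of Z.
    """

    patient_id: int
    times: np.ndarray            # integer hours 0..K
    variables: List[str]
    Z: np.ndarray                # (V, K+1), normalized, NaN = unobserved
    masks: np.ndarray            # (V, K+1) cumulative counts
    A: np.ndarray                # (M, K+1) binary
    antibiotics: List[str]
    d: np.ndarray                # (D,) normalized statics
    outcome_idx: np.ndarray      # indices of OUTCOMES present, in order
    z0: Optional[np.ndarray] = None   # imputed initial values (V,)
    path_time_scale: float = 1.0 / 24.0
    path_mask_scale: float = 0.1

    @property
    def y(self) -> np.ndarray:
        return self.Z[self.outcome_idx]

    @property
    def y_mask(self) -> np.ndarray:
        return ~np.isnan(self.Z[self.outcome_idx])


def cumulative_masks(Z: np.ndarray) -> np.ndarray:
    """Cumulative count of observations per variable up to and incl. each hour."""
    return np.cumsum(~np.isnan(Z), axis=1).astype(float)


# ----------------------------------------------------------------- control path
@dataclass
class ControlPath:
    """Rectilinear interpolation of (time, values, masks, treatments).

    Knots alternate time-advance segments (only the time channel moves, at
    held values) and value-update segments (time frozen, value channels jump
    to the new observations).  The path is parameterized by the knot index
    s in [0, n_knots - 1]; each segment's derivative is constant, so the
    driven CDE restricted to a segment is an autonomous ODE.
    """

    knots: np.ndarray            # (S, C)
    channels: List[str]
    knot_times: np.ndarray       # (S,) clock time of each knot, hours
    time_scale: float = 1.0 / 24.0
    mask_scale: float = 0.1
    n_vars: int = 0
    n_treatments: int = 0

    @property
    def n_segments(self) -> int:
        return self.knots.shape[0] - 1

    def evaluate(self, s: float) -> np.ndarray:
        s = float(np.clip(s, 0, self.n_segments))
        k = int(np.floor(s))
        if k == self.n_segments:
            return self.knots[-1].copy()
        frac = s - k
        return (1 - frac) * self.knots[k] + frac * self.knots[k + 1]

    def derivative(self, segment: int) -> np.ndarray:
        return self.knots[segment + 1] - self.knots[segment]

    def segments_up_to(self, t_hours: float) -> int:
        """Number of leading segments whose data lie at clock time <= t."""
        ok = self.knot_times <= t_hours + 1e-9
        return int(np.sum(ok)) - 1


def build_rectilinear_path(
    gr: GridRecord,
    time_scale: Optional[float] = None,
    mask_scale: Optional[float] = None,
    up_to_hour: Optional[int] = None,
) -> ControlPath:
    """Build the causal control path for one grid record.

    Channel order: time, then the variables (forward-filled from the
    imputed initial values), then their cumulative masks, then the M
    treatment channels.  Knot ordering within each hour is time-then-value:
    first the time channel advances at held values, then the value channels
    update at frozen time.  Requires complete initial values (`gr.z0`).
    """
    if gr.z0 is None or np.isnan(gr.z0).any():
        raise ValueError("initial values must be imputed before path construction")
    if time_scale is None:
        time_scale = gr.path_time_scale
    if mask_scale is None:
        mask_scale = gr.path_mask_scale
    K = gr.times.size - 1 if up_to_hour is None else int(up_to_hour)
    V, M = len(gr.variables), len(gr.antibiotics)
    channels = (
        ["time"]
        + list(gr.variables)
        + [f"mask_{v}" for v in gr.variables]
        + list(gr.antibiotics)
    )
    vals = gr.z0.copy()
    n_knots = 2 * K + 1
    knots = np.zeros((n_knots, 1 + 2 * V + M))
    ktimes = np.zeros(n_knots)

    def fill(row, t_idx):
        knots[row, 0] = gr.times[t_idx] * time_scale
        knots[row, 1 : 1 + V] = vals
        knots[row, 1 + V : 1 + 2 * V] = gr.masks[:, t_idx] * mask_scale
        knots[row, 1 + 2 * V :] = gr.A[:, t_idx]
        ktimes[row] = gr.times[t_idx]

    # hour 0: observed-or-imputed initial state
    fill(0, 0)
    row = 1
    for j in range(1, K + 1):
        # time advance at held values (masks/treatments held too)
        knots[row] = knots[row - 1]
        knots[row, 0] = gr.times[j] * time_scale
        ktimes[row] = gr.times[j]
        row += 1
        # value update at frozen time
        obs = gr.Z[:, j]
        vals = np.where(np.isnan(obs), vals, obs)
        fill(row, j)
        row += 1
    return ControlPath(
        knots=knots,
        channels=channels,
        knot_times=ktimes,
        time_scale=time_scale,
        mask_scale=mask_scale,
        n_vars=V,
        n_treatments=M,
    )


# ------------------------------------------------------------------- pipeline
@dataclass
class PreprocessResult:
    grids: List[GridRecord]
    variables: List[str]
    stats: Dict[str, Tuple[float, float]]
    static_stats: Dict[str, Tuple[float, float]]
    report: pd.DataFrame
    config: PreprocessConfig
    initial_reference: np.ndarray


def _static_matrix(cohort, names, stats=None):
    X = np.array([[p.statics[n] for n in names] for p in cohort], dtype=float)
    if stats is None:
        stats = {}
        for i, n in enumerate(names):
            sd = X[:, i].std()
            stats[n] = (float(X[:, i].mean()), float(sd if sd > 0 else 1.0))
    for i, n in enumerate(names):
        mean, sd = stats[n]
        X[:, i] = (X[:, i] - mean) / sd
    return X, stats


def preprocess_cohort(
    cohort: Sequence[PatientRecord],
    config: PreprocessConfig = PreprocessConfig(),
    fitted: Optional[PreprocessResult] = None,
    antibiotics: Sequence[str] = ("Ceftriaxone", "Piperacillin/Tazobactam", "Vancomycin"),
) -> PreprocessResult:
    """Run the full preprocessing pipeline on a cohort.

    With ``fitted=None`` this is the fitting split: variables are selected
    and normalization / imputation statistics estimated here.  Passing a
    fitted result reapplies every fitted statistic unchanged (validation and
    test splits see only the affine map and the training donors).
    """
    cohort = list(cohort)
    if fitted is None:
        covered = filter_by_coverage(cohort, config.coverage_min)
        variables, report = select_by_spearman(
            cohort,
            candidates=covered,
            spearman_min=config.spearman_min,
            bin_width=config.bin_width,
            mode=config.spearman_mode,
        )
        stats = None
        static_stats = None
    else:
        variables = fitted.variables
        report = fitted.report
        stats = fitted.stats
        static_stats = fitted.static_stats

    normalized, stats = fit_apply_normalization(cohort, stats=stats, variables=variables)
    rounded = [round_to_hours(p, config.hour_collision) for p in normalized]

    if config.grid_hours is not None:
        K = int(config.grid_hours)
    elif fitted is not None and fitted.grids:
        K = fitted.grids[0].times.size - 1
    else:
        K = int(max(p.observations["time_h"].max() for p in rounded))
    times = np.arange(K + 1, dtype=float)

    static_names = sorted(cohort[0].statics)
    D, static_stats = _static_matrix(cohort, static_names, static_stats)

    grids = []
    for p, praw, d in zip(rounded, cohort, D):
        V = len(variables)
        Z = np.full((V, K + 1), np.nan)
        for vi, var in enumerate(variables):
            t, v = p.variable(var)
            sel = (t >= 0) & (t <= K)
            Z[vi, t[sel].astype(int)] = v[sel]
        masks = cumulative_masks(Z)
        A = np.stack([praw.treatment_indicator(a, times) for a in antibiotics])
        out_idx = np.array([variables.index(v) for v in OUTCOMES if v in variables])
        grids.append(
            GridRecord(
                patient_id=p.patient_id,
                times=times,
                variables=list(variables),
                Z=Z,
                masks=masks,
                A=A,
                antibiotics=list(antibiotics),
                d=d,
                outcome_idx=out_idx,
                path_time_scale=config.time_scale,
                path_mask_scale=config.mask_scale,
            )
        )

    # KNN-impute initial values against the fitting split's donors (a fitted
    # result with no stored donors falls back to this cohort's own initials)
    initial = np.stack([g.Z[:, 0] for g in grids])
    if fitted is None or fitted.initial_reference.size == 0:
        reference = initial
    else:
        reference = fitted.initial_reference
    k = min(config.knn_k, reference.shape[0])
    completed = knn_impute_initial(initial, k, reference=reference)
    for g, z0 in zip(grids, completed):
        g.z0 = z0

    return PreprocessResult(
        grids=grids,
        variables=list(variables),
        stats=stats,
        static_stats=static_stats,
        report=report,
        config=config,
        initial_reference=reference,
    )
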