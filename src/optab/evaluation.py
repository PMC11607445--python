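"""Evaluation procedures: forecast-error grids, counterfactual side-effect
contrasts, counterfactual/factual matching, and average treatment improvement.

All procedures run on held-out cohorts (synthetic or user data) through a
trained :class:`optab.selector.ModelBundle`.  Forecast errors are reported
in units of the variable's variance so that a predict-the-global-mean
baseline scores 1.0 -- the same normalization used for forecast-accuracy
heatmaps over (observation time x forecast horizon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .preprocess import GridRecord, build_rectilinear_path
from .records import PatientRecord
from .selector import (
    ContraindicationRuleSet,
    ModelBundle,
    TreatmentOption,
    _canon,
    forecast_under_option,
    select_optimal,
)
from .tecde import Tensor, _predictive_index

__all__ = [
    "MSEGrid",
    "mse_grid",
    "ContrastResult",
    "side_effect_contrast",
    "counterfactual_matching",
    "ImprovementResult",
    "average_treatment_improvement",
]


# ------------------------------------------------------------------- MSE grid
@dataclass
class MSEGrid:
    """Forecast MSE per (observation time, horizon), in variance units."""

    variable: str
    obs_times: np.ndarray
    horizons: np.ndarray
    values: np.ndarray          # (len(obs_times), len(horizons)); NaN = no data
    counts: np.ndarray
    variance: float

    def weighted_mean(self) -> float:
        """Count-weighted mean over non-empty cells."""
        ok = self.counts > 0
        return float((self.values[ok] * self.counts[ok]).sum() / self.counts[ok].sum())


def _denorm(bundle: ModelBundle, variable: str, x):
    mean, sd = bundle.stats[variable]
    return x * sd + mean


def mse_grid(
    bundle: ModelBundle,
    grids: Sequence[GridRecord],
    variable: str,
    obs_times: Optional[Sequence[int]] = None,
    horizons: Optional[Sequence[int]] = None,
    predictor: str = "model",
    lab_smoothing: bool = False,
    normalizer: str = "observations",
) -> MSEGrid:
    """Forecast-error grid for one variable on a held-out cohort.

    For each observation time o the encoder assimilates each patient's data
    up to o; the decoder extrapolates to o + h and the squared error against
    the observations at o + h is accumulated, divided by the variable's
    variance over all observations (``normalizer="observations"``) or over
    the multiset of grid contributions (``normalizer="contributions"``,
    under which the mean-predictor baseline grid averages to exactly 1).
    ``predictor="mean"`` scores the predict-the-global-mean baseline on the
    same cells.  ``lab_smoothing`` averages each cell over 5 consecutive
    observation-time cells (centered), as appropriate for sparsely measured
    laboratory values.
    """
    model = bundle.model
    vi_out = bundle.outcome_variables.index(variable)
    vi = grids[0].variables.index(variable)
    K = grids[0].times.size - 1
    if obs_times is None:
        obs_times = np.arange(0, K - 1)
    if horizons is None:
        horizons = np.arange(1, 49)
    obs_times = np.asarray(list(obs_times), dtype=int)
    horizons = np.asarray(list(horizons), dtype=int)

    obs_matrix = np.stack([_denorm(bundle, variable, g.Z[vi]) for g in grids])  # (N, K+1)
    observed = np.stack([~np.isnan(g.Z[vi]) for g in grids])

    # encoder states for the whole cohort, computed once
    knots = np.stack([build_rectilinear_path(g).knots for g in grids])
    d = np.stack([g.d for g in grids])
    states = model.encode_knot_states(knots, d)

    max_h = int(horizons.max())
    sq = np.full((obs_times.size, horizons.size), np.nan)
    counts = np.zeros_like(sq)
    contributions = []
    for oi, o in enumerate(obs_times):
        if predictor == "model":
            anchor = Tensor(states[_predictive_index(o + 1)].data)
            dec = model.decode_states(anchor, d, max_h - 1)
            xs = np.stack([s.data for s in dec])             # (max_h, N, P)
            y = model.h_alpha_dec(Tensor(xs.reshape(-1, model.P))).data
            y = y.reshape(max_h, len(grids), model.R)[:, :, vi_out]
            y = _denorm(bundle, variable, y)                 # forecast at o+1..o+max_h
        for hi, h in enumerate(horizons):
            t_target = o + h
            if t_target > K:
                continue
            m = observed[:, t_target]
            if not m.any():
                continue
            target = obs_matrix[m, t_target]
            if predictor == "model":
                pred = y[h - 1, m]
            elif predictor == "mean":
                pred = np.full(target.shape, np.nan)  # filled below
            else:
                raise ValueError(f"unknown predictor {predictor!r}")
            counts[oi, hi] = m.sum()
            if predictor == "mean":
                contributions.append((oi, hi, target))
            else:
                sq[oi, hi] = float(((pred - target) ** 2).mean())
                contributions.append((oi, hi, target))

    all_contrib = (
        np.concatenate([c[2] for c in contributions])
        if contributions
        else np.zeros(0)
    )
    all_obs = obs_matrix[observed]
    pool = all_contrib if normalizer == "contributions" else all_obs
    if pool.size == 0 or pool.var() == 0:
        raise ValueError(f"variance normalizer for {variable!r} is degenerate")
    variance = float(pool.var())
    if predictor == "mean":
        ybar = float(pool.mean())
        for oi, hi, target in contributions:
            sq[oi, hi] = float(((ybar - target) ** 2).mean())
    sq = sq / variance
    if lab_smoothing:
        sq = (
            pd.DataFrame(sq)
            .rolling(5, center=True, min_periods=1)
            .mean()
            .to_numpy()
        )
    return MSEGrid(
        variable=variable,
        obs_times=obs_times,
        horizons=horizons,
        values=sq,
        counts=counts,
        variance=variance,
    )


# --------------------------------------------------------- side-effect contrast
@dataclass
class ContrastResult:
    """Per-time distributions of the paired treatment difference Delta."""

    pair: Tuple[TreatmentOption, TreatmentOption]
    times: np.ndarray                       # hours since treatment start
    delta: Dict[str, pd.DataFrame]          # lab -> (patients x times)
    sampled_patients: List[int]
    group_counts: Dict[str, int]

    def mean(self, lab: str) -> np.ndarray:
        return self.delta[lab].mean(axis=0).to_numpy()

    def kde(self, lab: str, time_index: int) -> gaussian_kde:
        """Gaussian kernel density of Delta at one time (reference bandwidth)."""
        return gaussian_kde(self.delta[lab].iloc[:, time_index].to_numpy())


def _single_treatment_group(record: PatientRecord) -> Optional[str]:
    abx = set(record.treatments["antibiotic"])
    return abx.pop() if len(abx) == 1 else None


def side_effect_contrast(
    bundle: ModelBundle,
    records: Sequence[PatientRecord],
    grids: Sequence[GridRecord],
    pair: Tuple[Sequence[str], Sequence[str]] = (("Vancomycin",), ("Ceftriaxone",)),
    horizon: float = 72.0,
    labs: Sequence[str] = ("creatinine", "bilirubin_total", "alt"),
    seed: int = 0,
) -> ContrastResult:
    """Counterfactual side-effect contrast between two antibiotic options.

    Excludes patients factually treated with multiple antibiotics, then
    draws a balanced sample (equal counts, without replacement) from each
    remaining factual single-treatment group.  For every sampled patient
    both options of `pair` are simulated from the factual first treatment
    time over `horizon` hours and the per-lab difference
    Delta = first option minus second option is collected per time point.
    """
    opt_a, opt_b = _canon(pair[0]), _canon(pair[1])
    groups: Dict[str, List[int]] = {}
    for i, r in enumerate(records):
        g = _single_treatment_group(r)
        if g is not None:
            groups.setdefault(g, []).append(i)
    if not groups:
        raise ValueError("no single-treatment patients to sample from")
    for abx in bundle.antibiotics:
        if abx not in groups or not groups[abx]:
            raise ValueError(f"factual treatment group {abx!r} is empty")
    n_per = min(len(v) for v in groups.values())
    rng = np.random.default_rng(np.random.SeedSequence((seed, 303)))
    sampled = []
    for abx in sorted(groups):
        sampled.extend(sorted(rng.choice(groups[abx], size=n_per, replace=False)))

    horizon = float(horizon)
    eps = bundle.model.config.epsilon
    rel_times = eps + np.arange(int(round(horizon - eps)) + 1, dtype=float)
    delta = {lab: [] for lab in labs}
    K = grids[0].times.size - 1
    used = []
    for i in sampled:
        r, g = records[i], grids[i]
        t1 = int(round(r.treatments["start_h"].min())) if len(r.treatments) else 0
        h_eff = min(horizon, K - t1)
        if h_eff < 2:
            continue
        cache: dict = {"path": build_rectilinear_path(g)}
        fa = forecast_under_option(bundle, g, opt_a, t1, h_eff, _cache=cache)
        fb = forecast_under_option(bundle, g, opt_b, t1, h_eff, _cache=cache)
        used.append(r.patient_id)
        for lab in labs:
            dd = (fa[lab] - fb[lab]).to_numpy()
            row = np.full(rel_times.size, np.nan)
            row[: dd.size] = dd
            delta[lab].append(row)
    frames = {
        lab: pd.DataFrame(np.stack(rows), index=used, columns=rel_times)
        for lab, rows in delta.items()
    }
    return ContrastResult(
        pair=(opt_a, opt_b),
        times=rel_times,
        delta=frames,
        sampled_patients=used,
        group_counts={k: len(v) for k, v in groups.items()},
    )


# ------------------------------------------------------------------- matching
def _first_option(record: PatientRecord) -> Optional[TreatmentOption]:
    if not len(record.treatments):
        return None
    t1 = record.treatments["start_h"].min()
    abx = record.treatments[np.isclose(record.treatments["start_h"], t1)]["antibiotic"]
    return tuple(sorted(set(abx)))


def _sofa_locf(record: PatientRecord, times: np.ndarray) -> np.ndarray:
    t, v = record.variable("sofa")
    out = np.full(times.size, np.nan)
    for j, tt in enumerate(times):
        past = t <= tt
        if past.any():
            out[j] = v[past][-1]
    return out


def counterfactual_matching(
    bundle: ModelBundle,
    records: Sequence[PatientRecord],
    grids: Sequence[GridRecord],
    selected: Dict[int, TreatmentOption],
    onset_window: float = 3.0,
    horizon: float = 48.0,
    ci: str = "normal",
    n_boot: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Counterfactual vs. factual matching of SOFA trajectories.

    Counterfactual arm: for each patient whose factual first treatment
    differs from the selected optimum, find the most similar patient
    (Euclidean distance on the normalized covariates at onset, ties broken
    by patient id) who factually received that optimum; average
    \\|predicted SOFA under the optimum - matched factual SOFA\\| per time.
    Factual arm: nearest same-treatment neighbour, \\|factual - factual\\|.
    Only patients first treated within `onset_window` hours of onset enter.
    95% confidence intervals per time point via the normal approximation
    over pairs (``ci="bootstrap"`` resamples pairs instead).
    """
    eps = bundle.model.config.epsilon
    rel_times = eps + np.arange(int(round(horizon - eps)) + 1, dtype=float)
    feats, factual, eligible = {}, {}, []
    for i, (r, g) in enumerate(zip(records, grids)):
        opt = _first_option(r)
        if opt is None:
            continue
        t1 = r.treatments["start_h"].min()
        if t1 - (r.sepsis_onset or 0.0) > onset_window:
            continue
        factual[i] = opt
        feats[i] = np.concatenate([g.z0, g.d])
        eligible.append(i)
    if not eligible:
        raise ValueError("no eligible patients for matching")

    def nearest(i, pool):
        cand = [
            (float(np.linalg.norm(feats[i] - feats[j])), records[j].patient_id, j)
            for j in pool
            if j != i
        ]
        if not cand:
            return None
        return min(cand)[2]

    cf_rows, f_rows = [], []
    for i in eligible:
        opt = selected.get(records[i].patient_id)
        # factual arm: nearest neighbour with the same factual treatment
        jf = nearest(i, [j for j in eligible if factual[j] == factual[i]])
        if jf is not None:
            a = _sofa_locf(records[i], rel_times)
            b = _sofa_locf(records[jf], rel_times)
            f_rows.append(np.abs(a - b))
        # counterfactual arm
        if opt is None or opt == factual[i]:
            continue
        jc = nearest(i, [j for j in eligible if factual[j] == opt])
        if jc is None:
            continue
        t1 = int(round(records[i].treatments["start_h"].min()))
        fc = forecast_under_option(bundle, grids[i], opt, t1, horizon)
        pred = fc["sofa"].to_numpy()
        matched = _sofa_locf(records[jc], t1 + rel_times)
        row = np.full(rel_times.size, np.nan)
        row[: pred.size] = np.abs(pred - matched[: pred.size])
        cf_rows.append(row)
    if not cf_rows:
        raise ValueError("no counterfactually matched pairs")

    def summarize(rows, prefix):
        X = np.stack(rows)
        mean = np.nanmean(X, axis=0)
        n = np.sum(~np.isnan(X), axis=0)
        if ci == "normal":
            se = np.nanstd(X, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
            lo, hi = mean - 1.96 * se, mean + 1.96 * se
        elif ci == "bootstrap":
            rng = np.random.default_rng(np.random.SeedSequence((seed, 404)))
            boots = np.stack(
                [
                    np.nanmean(X[rng.integers(0, X.shape[0], X.shape[0])], axis=0)
                    for _ in range(n_boot)
                ]
            )
            lo, hi = np.percentile(boots, [2.5, 97.5], axis=0)
        else:
            raise ValueError(f"unknown ci mode {ci!r}")
        return {
            f"{prefix}_mean": mean,
            f"{prefix}_lo": lo,
            f"{prefix}_hi": hi,
            f"{prefix}_n": n,
        }

    out = {"time": rel_times}
    out.update(summarize(cf_rows, "counterfactual"))
    out.update(summarize(f_rows, "factual"))
    return pd.DataFrame(out)


# ------------------------------------------------- average treatment improvement
@dataclass
class ImprovementResult:
    times: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    area: float                 # trapezoid integral of the mean curve
    per_patient: np.ndarray     # (N, T)
    mode: str


def average_treatment_improvement(
    bundle: ModelBundle,
    records: Sequence[PatientRecord],
    grids: Sequence[GridRecord],
    mode: str = "constrained",
    horizon: float = 48.0,
    rules: ContraindicationRuleSet = ContraindicationRuleSet(),
) -> ImprovementResult:
    """Mean forecast SOFA difference, selected optimum minus factual option.

    Decisions are taken at each patient's first treatment time; Delta(t) is
    the difference of the forecast SOFA trajectories under the selected and
    the factual option over the next `horizon` hours, averaged over
    patients with a 95% normal-approximation CI, plus the trapezoid area
    under the mean curve.  In unconstrained mode Delta at the horizon is
    <= 0 for every patient by construction of the argmin.
    """
    eps = bundle.model.config.epsilon
    rel_times = eps + np.arange(int(round(horizon - eps)) + 1, dtype=float)
    rows = []
    for r, g in zip(records, grids):
        factual = _first_option(r)
        if factual is None:
            continue
        t1 = int(round(r.treatments["start_h"].min()))
        dec = select_optimal(bundle, r, g, t1, horizon, rules, mode)
        fc_opt = dec.forecasts[dec.selected]["sofa"].to_numpy()
        factual = _canon(factual)
        if factual in dec.forecasts:
            fc_fac = dec.forecasts[factual]["sofa"].to_numpy()
        else:
            cache = {"path": build_rectilinear_path(g)}
            fc_fac = forecast_under_option(
                bundle, g, factual, t1, horizon, _cache=cache
            )["sofa"].to_numpy()
        row = np.full(rel_times.size, np.nan)
        n = min(fc_opt.size, rel_times.size)
        row[:n] = fc_opt[:n] - fc_fac[:n]
        rows.append(row)
    X = np.stack(rows)
    mean = np.nanmean(X, axis=0)
    n = np.sum(~np.isnan(X), axis=0)
    se = np.nanstd(X, axis=0, ddof=1) / np.sqrt(np.maximum(n, 1))
    area = float(np.trapezoid(mean, rel_times))
    return ImprovementResult(
        times=rel_times,
        mean=mean,
        lo=mean - 1.96 * se,
        hi=mean + 1.96 * se,
        area=area,
        per_patient=X,
        mode=mode,
    )
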