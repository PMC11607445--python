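"""Confounded synthetic EHR cohorts with known counterfactual ground truth.

Real sepsis EHR data (irregular measurements, heavy missingness,
treatment assignment driven by the patient's current state) are
credentialed-access, and counterfactual outcomes are unobservable in any
real dataset.  This simulator emulates the *structure* of such data while
retaining a full oracle: for every patient it stores the latent severity
path and the outcome paths that would have been realized under each of the
six candidate antibiotic options from every decision time, all sharing one
Brownian noise draw so option contrasts are noise-free.

Model
-----
Latent severity u(t) (continuous, roughly on the 0-24 SOFA scale) follows a
mean-reverting diffusion with an additive treatment drift:

    du = kappa * (u_eq - u) dt + delta(option, pathogen) dt + sigma dW,

integrated by Euler--Maruyama at 0.25 h steps.  u_eq sits above the onset
severity, so untreated disease worsens; an effective option's drift
``delta`` (sum of its antibiotics' per-pathogen-class efficacies, <= 0 for
effective pairs) pulls severity down.  Continuous SOFA is u clipped to
[0, 24].  Laboratory and vital variables are affine in u plus per-patient
baselines; nephro-/hepatotoxicity enter as constant positive drifts on
creatinine (Vancomycin) and on bilirubin total / alanine transaminase
(Ceftriaxone) proportional to exposure time.  Fungal and viral pathogen
classes receive zero antibiotic efficacy.

Treatment assignment is a softmax policy over the six options whose score
depends on current SOFA (sicker patients prefer two-antibiotic options) and
current creatinine (high creatinine discourages Vancomycin) -- this induces
the time-dependent confounding the forecaster must handle.  Decision times
are 0 h, 48 h, then every 24 h.  Observations are drawn by per-variable
Poisson processes and thinned by ``missing_frac``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .records import PatientRecord, read_cohort, write_cohort

__all__ = [
    "ANTIBIOTICS",
    "TREATMENT_OPTIONS",
    "OUTCOME_VARIABLES",
    "SimConfig",
    "SimGroundTruth",
    "simulate_cohort",
    "counterfactual_outcomes",
    "true_best_option",
    "export_long_format",
    "import_long_format",
]

ANTIBIOTICS: Tuple[str, ...] = ("Ceftriaxone", "Piperacillin/Tazobactam", "Vancomycin")

#: All candidate options: singletons then pairs, lexicographic within size.
TREATMENT_OPTIONS: Tuple[Tuple[str, ...], ...] = tuple(
    [(a,) for a in ANTIBIOTICS]
    + [tuple(sorted(p)) for p in itertools.combinations(ANTIBIOTICS, 2)]
)

PATHOGEN_CLASSES = ("gram_pos", "gram_neg", "mixed", "fungal", "viral")

OUTCOME_VARIABLES = ("sofa", "creatinine", "bilirubin_total", "alt")

# Per-variable generative model: per-patient baseline ~ N(mean, sd),
# value(t) = baseline + coupling * u(t) (+ class offset + toxicity drift),
# observed at Poisson(rate/h) times with N(0, noise) measurement error.
# "glucose" is deliberately uncoupled to severity: it exercises the
# correlation-based variable exclusion downstream.
VARIABLE_MODEL = {
    "sofa": dict(base=(0.0, 0.0), coupling=1.0, noise=0.25, rate=1.0),
    "creatinine": dict(base=(1.0, 0.15), coupling=0.05, noise=0.05, rate=0.10),
    "bilirubin_total": dict(base=(0.8, 0.20), coupling=0.06, noise=0.05, rate=0.08),
    "alt": dict(base=(40.0, 10.0), coupling=3.0, noise=8.0, rate=0.06),
    "anion_gap": dict(base=(12.0, 1.0), coupling=0.30, noise=0.5, rate=0.30),
    "bicarbonate": dict(base=(26.0, 1.5), coupling=-0.40, noise=0.5, rate=0.30),
    "bun": dict(base=(18.0, 4.0), coupling=1.2, noise=1.5, rate=0.10),
    "dbp": dict(base=(72.0, 6.0), coupling=-1.0, noise=3.0, rate=0.80),
    "sbp": dict(base=(122.0, 8.0), coupling=-1.8, noise=4.0, rate=0.80),
    "platelets": dict(
        base=(250.0, 30.0), coupling=-12.0, noise=10.0, rate=0.12,
        class_offset={"gram_neg": -70.0, "mixed": -35.0},
    ),
    "rdw": dict(
        base=(13.5, 0.4), coupling=0.30, noise=0.15, rate=0.12,
        class_offset={"gram_pos": 2.0, "mixed": 1.0},
    ),
    "glucose": dict(base=(120.0, 20.0), coupling=0.0, noise=10.0, rate=0.30),
}

# Softmax-policy score weights (see module docstring).
POLICY_W_SOFA = 5.0       # pair preference scales with SOFA/24
POLICY_W_CREAT = 0.6      # per mg/dl creatinine against Vancomycin options
POLICY_PAIR_COST = 1.2    # base reluctance to combine two antibiotics
POLICY_PERSISTENCE = 2.5  # clinical inertia: bonus for keeping the current option
POLICY_INTERCEPT = {"Ceftriaxone": 0.3, "Piperacillin/Tazobactam": 0.0, "Vancomycin": 0.9}


def _default_efficacy() -> Dict[str, Dict[str, float]]:
    # severity-units/h drift per (antibiotic, pathogen class); <= 0 = effective
    return {
        "Vancomycin": {"gram_pos": -0.24, "gram_neg": -0.02, "mixed": -0.06,
                       "fungal": 0.0, "viral": 0.0},
        "Ceftriaxone": {"gram_pos": -0.04, "gram_neg": -0.20, "mixed": -0.02,
                        "fungal": 0.0, "viral": 0.0},
        "Piperacillin/Tazobactam": {"gram_pos": -0.10, "gram_neg": -0.12,
                                    "mixed": -0.24, "fungal": 0.0, "viral": 0.0},
    }


def _default_toxicity() -> Dict[str, List[Tuple[str, float]]]:
    # lab-units/h drift while the antibiotic is ongoing
    return {
        "Vancomycin": [("creatinine", 0.012)],
        "Ceftriaxone": [("bilirubin_total", 0.010), ("alt", 1.2)],
        "Piperacillin/Tazobactam": [],
    }


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort generator."""

    n_patients: int = 500
    horizon: float = 96.0              # hours
    dt: float = 0.25                   # Euler-Maruyama step, hours
    latent_noise_sd: float = 0.15      # severity units per sqrt(hour)
    pathogen_class_probs: Dict[str, float] = field(
        default_factory=lambda: {
            "gram_pos": 0.40, "gram_neg": 0.35, "mixed": 0.10,
            "fungal": 0.10, "viral": 0.05,
        }
    )
    efficacy_matrix: Dict[str, Dict[str, float]] = field(default_factory=_default_efficacy)
    toxicity: Dict[str, List[Tuple[str, float]]] = field(default_factory=_default_toxicity)
    policy_temperature: float = 1.0
    obs_rates: Dict[str, float] = field(
        default_factory=lambda: {k: v["rate"] for k, v in VARIABLE_MODEL.items()}
    )
    missing_frac: float = 0.2
    obs_noise_scale: float = 1.0       # multiplies per-variable noise sd
    init_obs_prob: float = 0.8         # P(variable observed at t = 0)
    resistance_prob: float = 0.0       # per antibiotic, bacterial classes only
    mean_reversion: float = 0.02       # kappa, 1/h
    disease_pull: float = 4.0          # u_eq = u0 + disease_pull
    onset_severity: Tuple[float, float] = (9.0, 2.5)   # mean, sd of u0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients <= 0 or self.horizon <= 0:
            raise ValueError("n_patients and horizon must be positive")
        p = np.array([self.pathogen_class_probs[c] for c in PATHOGEN_CLASSES])
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("pathogen_class_probs must sum to 1")
        if any(r <= 0 for r in self.obs_rates.values()):
            raise ValueError("obs_rates must be positive")

    def decision_times(self) -> List[float]:
        """0 h, 48 h, then every 24 h, strictly inside the horizon."""
        times, t = [0.0], 48.0
        while t < self.horizon:
            times.append(t)
            t += 24.0
        return times


@dataclass
class PatientTruth:
    """Oracle data for one simulated patient."""

    pathogen_class: str
    resistant_to: Tuple[str, ...]
    u0: float
    baselines: Dict[str, float]
    u_factual: np.ndarray                       # severity on the sim grid
    factual_options: List[Tuple[float, Tuple[str, ...]]]  # (t_dec, option)
    policy_logprobs: Dict[float, Dict[Tuple[str, ...], float]]
    counterfactual_u: Dict[Tuple[float, Tuple[str, ...]], np.ndarray]
    exposure_factual: Dict[str, np.ndarray]     # cumulative hours on each abx

    def option_at(self, t: float) -> Tuple[str, ...]:
        opt = self.factual_options[0][1]
        for td, o in self.factual_options:
            if td <= t:
                opt = o
        return opt


@dataclass
class SimGroundTruth:
    """Latent severity and full counterfactual paths for a simulated cohort."""

    config: SimConfig
    grid: np.ndarray                     # sim time grid, hours
    patients: Dict[int, PatientTruth]


# ----------------------------------------------------------------- simulation
def _option_drift(config, pathogen, option, resistant) -> float:
    drift = 0.0
    for abx in option:
        if abx in resistant:
            continue
        drift += config.efficacy_matrix[abx][pathogen]
    return drift


def _policy_logits(config, option_list, sofa_now, creat_now, excluded, current=()):
    logits = []
    for opt in option_list:
        if any(a in excluded for a in opt):
            logits.append(-np.inf)
            continue
        s = sum(POLICY_INTERCEPT[a] for a in opt)
        s += (POLICY_W_SOFA * (sofa_now / 24.0) - POLICY_PAIR_COST) * (len(opt) - 1)
        if "Vancomycin" in opt:
            s -= POLICY_W_CREAT * creat_now
        if current and opt == current:
            s += POLICY_PERSISTENCE
        logits.append(s)
    logits = np.array(logits) / config.policy_temperature
    logits -= np.max(logits[np.isfinite(logits)])
    p = np.exp(logits)
    p[~np.isfinite(logits)] = 0.0
    return p / p.sum(), logits - np.log(np.exp(logits).sum())


def _lab_value(var, baselines, u, exposure, config):
    m = VARIABLE_MODEL[var]
    v = baselines[var] + m["coupling"] * u
    for abx, entries in config.toxicity.items():
        for lab, drift in entries:
            if lab == var:
                v = v + drift * exposure[abx]
    return v


def simulate_cohort(config: SimConfig):
    """Simulate a confounded cohort with counterfactual ground truth.

    Returns
    -------
    (cohort, truth)
        cohort: list of :class:`optab.records.PatientRecord`;
        truth: :class:`SimGroundTruth` with per-patient latent severity,
        policy log-probabilities and the counterfactual severity path for
        every (decision time, option) pair under shared noise.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n_steps = int(round(config.horizon / config.dt))
    grid = np.arange(n_steps + 1) * config.dt
    dec_times = config.decision_times()
    dec_idx = {t: int(round(t / config.dt)) for t in dec_times}

    cohort, patients = [], {}
    class_p = np.array([config.pathogen_class_probs[c] for c in PATHOGEN_CLASSES])

    for pid in range(config.n_patients):
        prng = np.random.default_rng(np.random.SeedSequence((config.seed, pid)))
        pathogen = PATHOGEN_CLASSES[prng.choice(len(PATHOGEN_CLASSES), p=class_p)]
        resistant = tuple(
            a
            for a in ANTIBIOTICS
            if pathogen in ("gram_pos", "gram_neg", "mixed")
            and prng.random() < config.resistance_prob
        )
        sex = int(prng.random() < 0.5)
        statics = {
            "sex": float(sex),
            "age": float(np.round(prng.normal(65.0, 12.0), 1)),
            "height": float(np.round(prng.normal(176.0 if sex else 163.0, 7.0), 1)),
            "weight": float(np.round(prng.normal(82.0 if sex else 70.0, 12.0), 1)),
        }
        u0 = max(2.0, prng.normal(*config.onset_severity))
        u_eq = u0 + config.disease_pull
        baselines = {
            var: prng.normal(*m["base"]) for var, m in VARIABLE_MODEL.items()
        }
        for var, m in VARIABLE_MODEL.items():
            off = m.get("class_offset", {}).get(pathogen, 0.0)
            baselines[var] += off
        baselines["sofa"] = 0.0

        # one Brownian draw shared by the factual and all counterfactual paths
        dW = prng.normal(0.0, config.latent_noise_sd * np.sqrt(config.dt), size=n_steps)

        # ---- factual path with the softmax policy at decision times
        u = np.empty(n_steps + 1)
        u[0] = u0
        exposure = {a: np.zeros(n_steps + 1) for a in ANTIBIOTICS}
        options_log: List[Tuple[float, Tuple[str, ...]]] = []
        logprobs: Dict[float, Dict[Tuple[str, ...], float]] = {}
        current: Tuple[str, ...] = ()
        micro_result_time = prng.uniform(48.0, 72.0)
        for k in range(n_steps):
            t = grid[k]
            if t in dec_idx and dec_idx[t] == k:
                excluded = set(resistant) if t >= micro_result_time else set()
                creat_now = _lab_value("creatinine", baselines, u[k],
                                       {a: exposure[a][k] for a in ANTIBIOTICS}, config)
                sofa_now = float(np.clip(u[k], 0.0, 24.0))
                probs, lp = _policy_logits(config, TREATMENT_OPTIONS, sofa_now,
                                           creat_now, excluded, current)
                choice = prng.choice(len(TREATMENT_OPTIONS), p=probs)
                current = TREATMENT_OPTIONS[choice]
                options_log.append((t, current))
                logprobs[t] = dict(zip(TREATMENT_OPTIONS, lp))
            drift = _option_drift(config, pathogen, current, resistant)
            u[k + 1] = (
                u[k]
                + config.mean_reversion * (u_eq - u[k]) * config.dt
                + drift * config.dt
                + dW[k]
            )
            for a in ANTIBIOTICS:
                exposure[a][k + 1] = exposure[a][k] + (config.dt if a in current else 0.0)

        # ---- counterfactual severity paths (shared noise, option held fixed)
        cf: Dict[Tuple[float, Tuple[str, ...]], np.ndarray] = {}
        for td in dec_times:
            k0 = dec_idx[td]
            for opt in TREATMENT_OPTIONS:
                ucf = u.copy()
                drift = _option_drift(config, pathogen, opt, resistant)
                for k in range(k0, n_steps):
                    ucf[k + 1] = (
                        ucf[k]
                        + config.mean_reversion * (u_eq - ucf[k]) * config.dt
                        + drift * config.dt
                        + dW[k]
                    )
                cf[(td, opt)] = ucf

        # ---- observation process
        rows = []
        for var, m in VARIABLE_MODEL.items():
            rate = config.obs_rates.get(var, m["rate"])
            n_obs = prng.poisson(rate * config.horizon)
            times = np.sort(prng.uniform(0.0, config.horizon, size=n_obs))
            keep = prng.random(n_obs) >= config.missing_frac
            times = times[keep]
            if var == "sofa" or prng.random() < config.init_obs_prob:
                times = np.concatenate([[0.0], times])
            idx = np.clip(np.round(times / config.dt).astype(int), 0, n_steps)
            for t_obs, k in zip(times, idx):
                expo = {a: exposure[a][k] for a in ANTIBIOTICS}
                if var == "sofa":
                    val = float(np.clip(u[k], 0.0, 24.0))
                else:
                    val = _lab_value(var, baselines, u[k], expo, config)
                val += prng.normal(0.0, m["noise"] * config.obs_noise_scale)
                if var == "sofa":
                    val = float(np.clip(val, 0.0, 24.0))
                rows.append((float(t_obs), var, float(val)))
        obs = pd.DataFrame(rows, columns=["time_h", "variable", "value"])
        obs = obs.sort_values(["time_h", "variable"], kind="stable").reset_index(drop=True)

        # ---- treatment intervals from the factual option sequence
        treat_rows = []
        bounds = [t for t, _ in options_log] + [config.horizon]
        for (td, opt), t_next in zip(options_log, bounds[1:]):
            for abx in opt:
                treat_rows.append((td, t_next, abx))
        treatments = pd.DataFrame(treat_rows, columns=["start_h", "end_h", "antibiotic"])

        micro = pd.DataFrame(
            [
                {
                    "sample_time_h": 0.0,
                    "result_time_h": float(np.round(micro_result_time, 2)),
                    "organism_class": pathogen,
                    "resistant_to": ";".join(resistant),
                }
            ]
        )

        cohort.append(
            PatientRecord(
                patient_id=pid,
                observations=obs,
                treatments=treatments,
                micro=micro,
                statics=statics,
                t0=0.0,
                sepsis_onset=0.0,
            )
        )
        patients[pid] = PatientTruth(
            pathogen_class=pathogen,
            resistant_to=resistant,
            u0=u0,
            baselines=baselines,
            u_factual=u,
            factual_options=options_log,
            policy_logprobs=logprobs,
            counterfactual_u=cf,
            exposure_factual=exposure,
        )

    return cohort, SimGroundTruth(config=config, grid=grid, patients=patients)


# --------------------------------------------------------------------- oracle
def counterfactual_outcomes(
    truth: SimGroundTruth,
    patient_id: int,
    option: Tuple[str, ...],
    t_start: float,
    horizon: float,
    at: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Noise-shared counterfactual outcome paths for one patient and option.

    The option is held fixed from `t_start` to `t_start + horizon`; before
    `t_start` the path is factual.  Returns a DataFrame indexed by time with
    one column per outcome variable (sofa, creatinine, bilirubin total, ALT),
    evaluated on the simulation grid restricted to the query window (or at
    `at` if given).
    """
    option = tuple(sorted(option))
    if option not in TREATMENT_OPTIONS:
        raise KeyError(f"unknown treatment option {option!r}")
    pt = truth.patients[patient_id]
    cfg = truth.config
    if t_start + horizon > cfg.horizon + 1e-9:
        raise ValueError("query window exceeds the simulated horizon")
    key = (t_start, option)
    if key not in pt.counterfactual_u:
        raise KeyError(f"no stored counterfactual at t_start={t_start}")
    u = pt.counterfactual_u[key]
    grid = truth.grid
    k0 = int(round(t_start / cfg.dt))
    # counterfactual exposure: factual before t_start, option held after
    expo = {a: pt.exposure_factual[a].copy() for a in ANTIBIOTICS}
    for a in ANTIBIOTICS:
        inc = cfg.dt if a in option else 0.0
        for k in range(k0, len(grid) - 1):
            expo[a][k + 1] = expo[a][k] + inc
    if at is None:
        sel = (grid >= t_start - 1e-9) & (grid <= t_start + horizon + 1e-9)
        idx = np.where(sel)[0]
    else:
        idx = np.clip(np.round(np.asarray(at, float) / cfg.dt).astype(int), 0, len(grid) - 1)
    out = {"sofa": np.clip(u[idx], 0.0, 24.0)}
    for var in ("creatinine", "bilirubin_total", "alt"):
        out[var] = np.array(
            [
                _lab_value(var, pt.baselines, u[k], {a: expo[a][k] for a in ANTIBIOTICS}, cfg)
                for k in idx
            ]
        )
    return pd.DataFrame(out, index=grid[idx])


def true_best_option(
    truth: SimGroundTruth, patient_id: int, t_start: float = 0.0, horizon: float = 48.0
) -> Tuple[str, ...]:
    """Ground-truth best option: argmin counterfactual SOFA at t_start+horizon.

    Ties (e.g. fungal/viral patients, for whom all options coincide) break
    toward fewer antibiotics, then lexicographic -- the same de-escalation
    preference the selector uses.
    """
    scores = []
    for opt in TREATMENT_OPTIONS:
        path = counterfactual_outcomes(truth, patient_id, opt, t_start, horizon)
        scores.append((path["sofa"].iloc[-1], len(opt), opt))
    scores.sort(key=lambda s: (s[0], s[1], s[2]))
    return scores[0][2]


# ------------------------------------------------------------------------ I/O
def export_long_format(cohort: List[PatientRecord], out_dir) -> None:
    """Write the cohort as long-format delimited text tables (round-trip safe)."""
    write_cohort(cohort, out_dir)


def import_long_format(in_dir) -> List[PatientRecord]:
    return read_cohort(in_dir)
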