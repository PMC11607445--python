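"""Encoder--decoder neural differential equation model (TE-CDE).

The encoder is a neural controlled differential equation driven by the
rectilinear control path X(s) of times, covariates, cumulative masks and
treatment indicators:

    x(t0) = g_eta(z_t0, a_t0, d),    dx = F_theta(x) dX(s)

Because the rectilinear path has a piecewise-constant derivative, the CDE
restricted to one knot segment is an autonomous ODE; it is integrated with
fixed-step classical Runge--Kutta (RK4) on each segment, subdivided
``substeps`` times.  Fixed stepping keeps every forecast bit-reproducible
and exactly causal: appending data after time t adds knot segments without
touching the computation on [t0, t].

The decoder is an uncontrolled neural ODE for long-term extrapolation,
initialized from the encoder's latent disease state at t + eps (eps = 1 h):

    x(t+eps) = g_phi(x_enc(t+eps), d),    dx/ds = f_phi(x)

Outcome heads map latent states to the R outcome channels (normalized
units); the treatment head maps them to per-antibiotic probabilities
through an element-wise logistic link (softmax optional), which is what the
adversarial balancing penalty in :mod:`optab.training` attacks.  All maps
are two-hidden-layer tanh perceptrons.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._autodiff import MLP, Adam, Tensor, concat, fused_mlp_bmv
from .preprocess import ControlPath, GridRecord

__all__ = [
    "ModelConfig",
    "TECDEModel",
    "LatentTrajectory",
    "encode",
    "decode",
    "apply_heads",
    "rolling_one_hour_forecast",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass
class ModelConfig:
    latent_dim: int = 8
    hidden: Tuple[int, int] = (32, 32)
    substeps: int = 1            # RK4 subdivisions per knot segment / hour
    epsilon: float = 1.0         # short-term forecast horizon, hours
    treatment_link: str = "sigmoid"   # "sigmoid" | "softmax"
    field_scale: float = 0.1     # initial scale of the vector-field output layer

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be >= 1")


@dataclass
class LatentTrajectory:
    """Latent states along a time grid, tagged with their provenance."""

    times: np.ndarray
    states: np.ndarray           # (T, P)
    provenance: str              # "encoder" | "decoder"

    def __post_init__(self):
        if not np.isfinite(self.states).all():
            raise FloatingPointError("non-finite latent state (integration error)")


class TECDEModel:
    """Parameters and integrators of the TE-CDE.

    Dimensions: P latent, V covariates, M treatments, D statics, R outcomes;
    the control path has C = 1 + 2V + M channels (time, covariates,
    cumulative masks, treatments).
    """

    def __init__(
        self,
        n_vars: int,
        n_treatments: int,
        n_statics: int,
        n_outcomes: int,
        config: ModelConfig = ModelConfig(),
        seed: int = 0,
    ):
        self.config = config
        self.V, self.M, self.D, self.R = n_vars, n_treatments, n_statics, n_outcomes
        self.P = config.latent_dim
        self.C = 1 + 2 * n_vars + n_treatments
        rng = np.random.default_rng(np.random.SeedSequence((seed, 17)))
        h = tuple(config.hidden)
        self.g_eta = MLP(n_vars + n_treatments + n_statics, self.P, h, rng)
        self.F_theta = MLP(self.P, self.P * self.C, h, rng, final_scale=config.field_scale)
        # decoder maps start at the persistence solution: g_phi is residual
        # with a zero-initialized correction and f_phi a zero-initialized
        # field, so initial long-horizon forecasts carry the anchor state
        # unchanged instead of collapsing toward an attractor
        self.g_phi = MLP(self.P + n_statics, self.P, h, rng, final_scale=0.0)
        self.f_phi = MLP(self.P, self.P, h, rng, final_scale=0.0)
        self.h_alpha = MLP(self.P, n_outcomes, h, rng)
        self.h_alpha_dec = MLP(self.P, n_outcomes, h, rng)
        self.h_beta = MLP(self.P, n_treatments, h, rng)

    # ------------------------------------------------------------- parameters
    @property
    def encoder_params(self):
        return [*self.g_eta.params, *self.F_theta.params, *self.h_alpha.params]

    @property
    def decoder_params(self):
        return [*self.g_phi.params, *self.f_phi.params, *self.h_alpha_dec.params]

    @property
    def adversary_params(self):
        return list(self.h_beta.params)

    @property
    def all_params(self):
        return [*self.encoder_params, *self.decoder_params, *self.adversary_params]

    def set_requires_grad(self, flag: bool):
        for p in self.all_params:
            p.requires_grad = flag

    # ------------------------------------------------------------ integrators
    def _vf(self, x: Tensor, dX) -> Tensor:
        dX = dX.data if isinstance(dX, Tensor) else dX
        return fused_mlp_bmv(x, self.F_theta.weights, self.F_theta.biases, dX, self.P, self.C)

    def cde_segment(self, x: Tensor, dX) -> Tensor:
        """RK4 over one knot segment (s in [0,1]) with constant control slope."""
        h = 1.0 / self.config.substeps
        for _ in range(self.config.substeps):
            k1 = self._vf(x, dX)
            k2 = self._vf(x + (h / 2) * k1, dX)
            k3 = self._vf(x + (h / 2) * k2, dX)
            k4 = self._vf(x + h * k3, dX)
            x = x + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        return x

    def ode_hour(self, x: Tensor) -> Tensor:
        """RK4 over one hour of the uncontrolled decoder field."""
        h = 1.0 / self.config.substeps
        for _ in range(self.config.substeps):
            k1 = self.f_phi(x)
            k2 = self.f_phi(x + (h / 2) * k1)
            k3 = self.f_phi(x + (h / 2) * k2)
            k4 = self.f_phi(x + h * k3)
            x = x + (h / 6) * (k1 + 2 * k2 + 2 * k3 + k4)
        return x

    # --------------------------------------------------------------- encoding
    def initial_state(self, knots0: np.ndarray, d: np.ndarray) -> Tensor:
        """x_t0 = g_eta(z_t0, a_t0, d) from the first knot of each path."""
        z0 = knots0[:, 1 : 1 + self.V]
        a0 = knots0[:, 1 + 2 * self.V :]
        inp = np.concatenate([z0, a0, np.atleast_2d(d)], axis=1)
        return self.g_eta(Tensor(inp))

    def encode_knot_states(
        self,
        knots: np.ndarray,
        d: np.ndarray,
        n_segments: Optional[int] = None,
        x0: Optional[Tensor] = None,
        start_segment: int = 0,
    ) -> List[Tensor]:
        """Integrate the CDE along batched knot arrays (B, S, C).

        Returns the latent state at every knot from `start_segment` on.
        Supplying `x0` resumes integration from a cached state (used for
        per-option branching in the selector).
        """
        S = knots.shape[1]
        n_seg = S - 1 if n_segments is None else int(n_segments)
        x = self.initial_state(knots[:, 0], d) if x0 is None else x0
        states = [x]
        for seg in range(start_segment, n_seg):
            dX = knots[:, seg + 1] - knots[:, seg]
            x = self.cde_segment(x, dX)
            states.append(x)
        return states

    def decode_states(self, x_anchor: Tensor, d: np.ndarray, n_hours: int) -> List[Tensor]:
        """Decoder latent states at the anchor and each of the next n_hours.

        The initial map is residual: x(t+eps) = x_anchor + g_phi(x_anchor, d).
        """
        inp = concat([x_anchor, Tensor(np.atleast_2d(d))], axis=1)
        x = x_anchor + self.g_phi(inp)
        states = [x]
        for _ in range(int(n_hours)):
            x = self.ode_hour(x)
            states.append(x)
        return states

    # ------------------------------------------------------------------ heads
    def outcome_head(self, states: List[Tensor], provenance: str = "encoder"):
        head = self.h_alpha if provenance == "encoder" else self.h_alpha_dec
        return [head(x) for x in states]

    def treatment_head(self, states: List[Tensor], logits: bool = False):
        outs = []
        for x in states:
            z = self.h_beta(x)
            if logits:
                outs.append(z)
            elif self.config.treatment_link == "sigmoid":
                outs.append(z.sigmoid())
            elif self.config.treatment_link == "softmax":
                e = (z - Tensor(z.data.max(axis=1, keepdims=True))).exp()
                outs.append(e / e.sum(axis=1).reshape(-1, 1))
            else:
                raise ValueError(f"unknown link {self.config.treatment_link!r}")
        return outs

    # ------------------------------------------------------------ persistence
    def state_dict(self) -> dict:
        nets = {}
        for name in ("g_eta", "F_theta", "g_phi", "f_phi", "h_alpha", "h_alpha_dec", "h_beta"):
            net = getattr(self, name)
            nets[name] = {
                "weights": [w.data.tolist() for w in net.weights],
                "biases": [b.data.tolist() for b in net.biases],
            }
        return {
            "dims": {"V": self.V, "M": self.M, "D": self.D, "R": self.R},
            "config": asdict(self.config),
            "nets": nets,
        }

    def load_state_dict(self, sd: dict) -> None:
        for name, payload in sd["nets"].items():
            net = getattr(self, name)
            for w, data in zip(net.weights, payload["weights"]):
                w.data = np.asarray(data, dtype=float)
            for b, data in zip(net.biases, payload["biases"]):
                b.data = np.asarray(data, dtype=float)

    @classmethod
    def from_state_dict(cls, sd: dict) -> "TECDEModel":
        dims, cfg = sd["dims"], sd["config"]
        cfg = dict(cfg)
        cfg["hidden"] = tuple(cfg["hidden"])
        model = cls(dims["V"], dims["M"], dims["D"], dims["R"], ModelConfig(**cfg))
        model.load_state_dict(sd)
        return model


# ----------------------------------------------------- single-record wrappers
def _predictive_index(hour: int) -> int:
    """Knot index of the state informed by data < hour (after the advance)."""
    return 2 * hour - 1 if hour >= 1 else 0


def _filtered_index(hour: int) -> int:
    """Knot index of the state after assimilating the hour's observations."""
    return 2 * hour


def encode(
    model: TECDEModel, path: ControlPath, d: np.ndarray, t_end: float
) -> LatentTrajectory:
    """Assimilate one patient's control path up to clock time t_end.

    Returns the latent trajectory at every knot with time <= t_end.
    Deterministic given parameters and path; raises on non-finite states.
    """
    n_seg = path.segments_up_to(t_end)
    if n_seg < 0:
        raise ValueError("t_end precedes the first knot")
    states = model.encode_knot_states(path.knots[None], d[None], n_segments=n_seg)
    arr = np.stack([s.data[0] for s in states])
    return LatentTrajectory(
        times=path.knot_times[: n_seg + 1], states=arr, provenance="encoder"
    )


def decode(
    model: TECDEModel,
    x_anchor: np.ndarray,
    d: np.ndarray,
    t_anchor: float,
    t_horizon: float,
) -> LatentTrajectory:
    """Extrapolate from a latent anchor with the uncontrolled decoder ODE."""
    if t_horizon <= t_anchor:
        raise ValueError("t_horizon must exceed t_anchor")
    n_hours = int(round(t_horizon - t_anchor))
    states = model.decode_states(Tensor(np.atleast_2d(x_anchor)), d[None], n_hours)
    arr = np.stack([s.data[0] for s in states])
    return LatentTrajectory(
        times=t_anchor + np.arange(n_hours + 1, dtype=float),
        states=arr,
        provenance="decoder",
    )


def apply_heads(model: TECDEModel, traj: LatentTrajectory):
    """Outcome forecasts (normalized units) and treatment probabilities."""
    if traj.states.size == 0:
        raise ValueError("empty trajectory")
    states = [Tensor(traj.states)]
    y = model.outcome_head(states, traj.provenance)[0].data
    p = model.treatment_head(states)[0].data
    return y, p


def rolling_one_hour_forecast(
    model: TECDEModel, path: ControlPath, d: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """One-hour-ahead outcome forecasts at every grid hour.

    For each hour t >= 1 the encoder state informed by data up to t - 1
    (plus the time advance into t) is mapped through the outcome head;
    element t of the returned series is the forecast of y_t.
    """
    states = model.encode_knot_states(path.knots[None], d[None])
    K = (path.knots.shape[0] - 1) // 2
    hours = np.arange(1, K + 1, dtype=float)
    xs = np.stack([states[_predictive_index(h)].data[0] for h in range(1, K + 1)])
    y = model.outcome_head([Tensor(xs)])[0].data
    return hours, y


# ------------------------------------------------------------------ checkpoint
def save_checkpoint(
    path,
    model: TECDEModel,
    variables: Sequence[str],
    antibiotics: Sequence[str],
    stats: Dict[str, Tuple[float, float]],
    static_stats: Dict[str, Tuple[float, float]],
    extra: Optional[dict] = None,
) -> None:
    """Serialize model parameters plus preprocessing statistics to JSON."""
    payload = {
        "version": CHECKPOINT_VERSION,
        "model": model.state_dict(),
        "variables": list(variables),
        "antibiotics": list(antibiotics),
        "stats": {k: list(v) for k, v in stats.items()},
        "static_stats": {k: list(v) for k, v in static_stats.items()},
        "extra": extra or {},
    }
    Path(path).write_text(json.dumps(payload))


def load_checkpoint(path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("version") != CHECKPOINT_VERSION:
        raise ValueError(f"unsupported checkpoint version {payload.get('version')!r}")
    payload["model"] = TECDEModel.from_state_dict(payload["model"])
    payload["stats"] = {k: tuple(v) for k, v in payload["stats"].items()}
    payload["static_stats"] = {k: tuple(v) for k, v in payload["static_stats"].items()}
    return payload
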