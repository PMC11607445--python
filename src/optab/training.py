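"""Losses, confounding balancing, and two-stage optimization.

The objective combines the masked outcome MSE L_y with the treatment
binary cross-entropy L_a, weighted by the balancing parameter mu.  The
treatment term is *maximized* with respect to the encoder so that the
latent disease state carries no information about the upcoming treatment
assignment (mitigating time-dependent confounding), while the treatment
head itself is trained to predict as well as it can -- an adversarial
pair.  Two equivalent mechanisms are provided: a gradient-reversal node
between the latent state and the treatment head (default), or an explicit
negated term with separate adversary updates; both yield identical encoder
gradients.

Training is two-stage: first the encoder (with the outcome head and the
balancing adversary) on one-hour-ahead targets with t_start = 1, then --
with the encoder frozen -- the decoder (initial map, vector field and its
own outcome head) on long-horizon targets from anchor hours sampled per
batch.  Early stopping monitors the validation outcome loss in both
stages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from ._autodiff import Adam, Tensor, concat
from .preprocess import GridRecord, build_rectilinear_path
from .tecde import TECDEModel, _predictive_index

__all__ = [
    "TrainConfig",
    "outcome_loss",
    "treatment_loss",
    "combined_loss",
    "split_cohort",
    "train_two_stage",
    "treatment_predictability_auc",
]

_CLIP = 1e-7


@dataclass
class TrainConfig:
    mu: float = 0.5                       # balancing weight
    split_fractions: Tuple[float, float, float] = (0.8, 0.1, 0.1)
    encoder_t_start: int = 1
    decoder_anchor_range: Optional[Tuple[int, int]] = None  # default (1, K-2)
    decoder_horizon: int = 48             # hours
    anchors_per_batch: int = 6
    lr: float = 1e-2
    adversary_lr: float = 1e-2
    batch_size: int = 100
    max_epochs_encoder: int = 40
    max_epochs_decoder: int = 25
    patience: int = 6
    balancing: str = "gradient_reversal"  # | "negated_term"
    adversary_steps: int = 1              # extra head updates per batch (negated_term)
    balance_decoder: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if not np.isclose(sum(self.split_fractions), 1.0):
            raise ValueError("split fractions must sum to 1")
        if self.balancing not in ("gradient_reversal", "negated_term"):
            raise ValueError(f"unknown balancing mechanism {self.balancing!r}")


# ---------------------------------------------------------------------- losses
def outcome_loss(y_hat, y, mask, t_start: int = 1):
    """Masked outcome MSE.

    Mean of squared error over observed outcome entries with time index
    >= t_start.  `y_hat` may be a Tensor or array of shape (..., T, R);
    `y` the targets with NaN allowed at unobserved entries; `mask` boolean
    of the same shape.
    """
    y = np.nan_to_num(np.asarray(y, dtype=float))
    m = np.asarray(mask, dtype=bool).copy()
    m[..., :t_start, :] = False
    count = int(m.sum())
    if count == 0:
        raise ValueError("no observed outcome entries at or after t_start")
    if isinstance(y_hat, Tensor):
        diff = (y_hat - Tensor(y)) * Tensor(m.astype(float))
        return diff.square().sum() * (1.0 / count)
    diff = (np.asarray(y_hat, dtype=float) - y) * m
    return float((diff**2).sum() / count)


def treatment_loss(p_hat, a, t_start: int = 1):
    """Treatment binary cross-entropy (conventional non-negative form).

    Mean over time points >= t_start and the M treatment channels of
    -[a log p + (1-a) log(1-p)].  Probabilities at exactly 0 or 1 are
    clipped to 1e-7 with a warning.
    """
    a = np.asarray(a, dtype=float)
    T = a.shape[-2]
    sel = np.zeros_like(a)
    sel[..., t_start:, :] = 1.0
    count = int(sel.sum())
    if count == 0:
        raise ValueError("no treatment entries at or after t_start")
    if isinstance(p_hat, Tensor):
        if np.any((p_hat.data <= 0) | (p_hat.data >= 1)):
            warnings.warn("treatment probabilities clipped to (1e-7, 1-1e-7)")
        p = p_hat.clip(_CLIP, 1.0 - _CLIP)
        ll = Tensor(a) * p.log() + Tensor(1.0 - a) * (1.0 - p).log()
        return -(ll * Tensor(sel)).sum() * (1.0 / count)
    p = np.asarray(p_hat, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn("treatment probabilities clipped to (1e-7, 1-1e-7)")
    p = np.clip(p, _CLIP, 1.0 - _CLIP)
    ll = a * np.log(p) + (1.0 - a) * np.log(1.0 - p)
    return float(-(ll * sel).sum() / count)


def combined_loss(L_y, L_a, mu: float, mechanism: str = "negated_term"):
    """Encoder objective combining outcome fit and confounding balancing.

    With ``negated_term`` the encoder minimizes L_y - mu * L_a (the
    treatment head is trained separately to minimize L_a).  With
    ``gradient_reversal`` the sign flip lives inside the graph (the
    reversal node between latent state and treatment head), so the
    optimized scalar is L_y + mu * L_a; both mechanisms produce identical
    encoder gradients.
    """
    if mu < 0:
        raise ValueError("mu must be non-negative")
    if mechanism == "negated_term":
        return L_y - mu * L_a
    if mechanism == "gradient_reversal":
        return L_y + mu * L_a
    raise ValueError(f"unknown balancing mechanism {mechanism!r}")


# ---------------------------------------------------------------------- splits
def split_cohort(cohort: Sequence, fractions=(0.8, 0.1, 0.1), seed: int = 0):
    """Reproducible disjoint patient-level train/val/test partition."""
    n = len(cohort)
    if n < 3:
        raise ValueError("need at least 3 patients to split")
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 101)))
    order = rng.permutation(n)
    n_tr = int(round(fractions[0] * n))
    n_va = int(round(fractions[1] * n))
    n_tr = min(n_tr, n - 2)
    n_va = max(1, min(n_va, n - n_tr - 1))
    idx_tr, idx_va, idx_te = (
        order[:n_tr],
        order[n_tr : n_tr + n_va],
        order[n_tr + n_va :],
    )
    take = lambda idx: [cohort[i] for i in sorted(idx)]
    return take(idx_tr), take(idx_va), take(idx_te)


# ------------------------------------------------------------------ internals
@dataclass
class _SplitArrays:
    knots: np.ndarray    # (N, S, C)
    d: np.ndarray        # (N, D)
    y: np.ndarray        # (N, K+1, R)
    y_mask: np.ndarray   # (N, K+1, R)
    a: np.ndarray        # (N, K+1, M)
    K: int


def _prepare(grids: Sequence[GridRecord]) -> _SplitArrays:
    paths = [build_rectilinear_path(g) for g in grids]
    knots = np.stack([p.knots for p in paths])
    d = np.stack([g.d for g in grids])
    y = np.stack([g.y.T for g in grids])
    y_mask = np.stack([g.y_mask.T for g in grids])
    a = np.stack([g.A.T for g in grids])
    return _SplitArrays(knots, d, y, y_mask, a, grids[0].times.size - 1)


def _predictive_stack(model, states, K):
    """Stack predictive latent states for hours 0..K into one (B,(K+1)*P)."""
    xs = [states[_predictive_index(h)].reshape(-1, 1, model.P) for h in range(K + 1)]
    return concat(xs, axis=1)  # (B, K+1, P)


def _head_over_time(head, x_bt: Tensor, n_out: int):
    B, T, P = x_bt.shape
    flat = head(x_bt.reshape(B * T, P))
    return flat.reshape(B, T, n_out)


def _treatment_probs(model, logits: Tensor) -> Tensor:
    if model.config.treatment_link == "sigmoid":
        return logits.sigmoid()
    if model.config.treatment_link == "softmax":
        shifted = logits - Tensor(logits.data.max(axis=-1, keepdims=True))
        e = shifted.exp()
        B, T, M = e.shape
        return e / e.sum(axis=-1).reshape(B, T, 1)
    raise ValueError(f"unknown treatment link {model.config.treatment_link!r}")


def _encoder_forward(model, arr, idx, mu, mechanism, t_start):
    knots, d = arr.knots[idx], arr.d[idx]
    states = model.encode_knot_states(knots, d)
    x_bt = _predictive_stack(model, states, arr.K)
    y_hat = _head_over_time(model.h_alpha, x_bt, model.R)
    L_y = outcome_loss(y_hat, arr.y[idx], arr.y_mask[idx], t_start)
    if mu == 0:
        return L_y, L_y, None
    x_for_adv = x_bt.grad_reverse() if mechanism == "gradient_reversal" else x_bt
    logits = _head_over_time(model.h_beta, x_for_adv, model.M)
    p_hat = _treatment_probs(model, logits)
    L_a = treatment_loss(p_hat, arr.a[idx], t_start)
    return combined_loss(L_y, L_a, mu, mechanism), L_y, L_a


def _copy_params(params):
    return [p.data.copy() for p in params]


def _restore_params(params, saved):
    for p, s in zip(params, saved):
        p.data = s.copy()


def _check_finite(value, stage, epoch):
    if not np.isfinite(value):
        raise FloatingPointError(
            f"non-finite loss in {stage} at epoch {epoch}: {value!r}"
        )


# ------------------------------------------------------------------- training
def train_two_stage(
    model: TECDEModel,
    train: Sequence[GridRecord],
    val: Sequence[GridRecord],
    config: TrainConfig = TrainConfig(),
) -> Tuple[TECDEModel, List[dict]]:
    """Two-stage optimization: encoder (+balancing), then frozen-encoder decoder.

    Stage 1 fits the encoder CDE, the encoder outcome head and (for mu > 0)
    the adversarial treatment head on one-hour-ahead targets (t_start = 1).
    Stage 2 freezes the encoder, copies the outcome head into the decoder
    head, and fits the decoder maps on outcomes over (t+eps, t+horizon]
    from anchor hours drawn per batch.  Early stopping restores the best
    validation parameters in each stage.  Fully seeded and CPU-deterministic.
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, 202)))
    arr_tr, arr_va = _prepare(train), _prepare(val)
    history: List[dict] = []
    t_start = config.encoder_t_start

    # ---------------- stage 1: encoder + heads
    enc_params = model.encoder_params
    opt = Adam(enc_params + (model.adversary_params if config.mu > 0 else []),
               lr=config.lr)
    adv_opt = Adam(model.adversary_params, lr=config.adversary_lr)
    best, best_params, wait = np.inf, None, 0
    n_tr = arr_tr.knots.shape[0]
    for epoch in range(config.max_epochs_encoder):
        order = rng.permutation(n_tr)
        ep_loss = []
        for lo in range(0, n_tr, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            obj, L_y, L_a = _encoder_forward(
                model, arr_tr, idx, config.mu, config.balancing, t_start
            )
            opt.zero_grad()
            obj.backward()
            opt.step()
            if config.mu > 0 and config.balancing == "negated_term":
                # adversary updates: minimize L_a with the latent detached
                states = model.encode_knot_states(arr_tr.knots[idx], arr_tr.d[idx])
                x_bt = Tensor(_predictive_stack(model, states, arr_tr.K).data)
                for _ in range(config.adversary_steps):
                    logits_adv = _head_over_time(model.h_beta, x_bt, model.M)
                    La_adv = treatment_loss(_treatment_probs(model, logits_adv),
                                            arr_tr.a[idx], t_start)
                    adv_opt.zero_grad()
                    La_adv.backward()
                    adv_opt.step()
            ep_loss.append(float(L_y.data))
        # validation outcome loss (no update)
        _, L_y_va, _ = _encoder_forward(model, arr_va, np.arange(arr_va.knots.shape[0]),
                                        0.0, config.balancing, t_start)
        val_loss = float(L_y_va.data)
        _check_finite(val_loss, "encoder", epoch)
        history.append(
            {"stage": "encoder", "epoch": epoch,
             "train_outcome_loss": float(np.mean(ep_loss)),
             "val_outcome_loss": val_loss}
        )
        if val_loss < best - 1e-6:
            best, best_params, wait = val_loss, _copy_params(model.all_params), 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_params is not None:
        _restore_params(model.all_params, best_params)

    # ---------------- stage 2: decoder with frozen encoder
    # decoder outcome head starts from the trained encoder head
    for w_src, w_dst in zip(model.h_alpha.params, model.h_alpha_dec.params):
        w_dst.data = w_src.data.copy()
    for p in model.encoder_params + model.adversary_params:
        p.requires_grad = False
    K = arr_tr.K
    a_lo, a_hi = config.decoder_anchor_range or (1, max(2, K - 2))
    horizon = config.decoder_horizon
    dec_opt = Adam(model.decoder_params, lr=config.lr)
    val_anchors = np.unique(np.linspace(a_lo, a_hi, 5).astype(int))
    best, best_params, wait = np.inf, None, 0
    for epoch in range(config.max_epochs_decoder):
        if epoch == config.max_epochs_decoder // 2:
            dec_opt.lr = config.lr * 0.3  # finer steps in the second half
        order = rng.permutation(n_tr)
        ep_loss = []
        for lo in range(0, n_tr, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            states = model.encode_knot_states(arr_tr.knots[idx], arr_tr.d[idx])
            # the earliest anchor is always included: decisions are taken at
            # onset, where the decoder must work from minimal assimilation
            anchors = np.concatenate(
                [[a_lo], rng.integers(a_lo, a_hi + 1, size=config.anchors_per_batch - 1)]
            )
            bal_mu = config.mu if config.balance_decoder else 0.0
            loss = _decoder_loss(model, states, arr_tr, idx, anchors, horizon,
                                 balance_mu=bal_mu, mechanism=config.balancing)
            dec_opt.zero_grad()
            loss.backward()
            dec_opt.step()
            ep_loss.append(float(loss.data))
        states_va = model.encode_knot_states(arr_va.knots, arr_va.d)
        val_loss = float(
            _decoder_loss(model, states_va, arr_va,
                          np.arange(arr_va.knots.shape[0]), val_anchors, horizon).data
        )
        _check_finite(val_loss, "decoder", epoch)
        history.append(
            {"stage": "decoder", "epoch": epoch,
             "train_outcome_loss": float(np.mean(ep_loss)),
             "val_outcome_loss": val_loss}
        )
        if val_loss < best - 1e-6:
            best, best_params, wait = val_loss, _copy_params(model.all_params), 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    if best_params is not None:
        _restore_params(model.all_params, best_params)
    for p in model.all_params:
        p.requires_grad = True
    return model, history


def _decoder_loss(model, enc_states, arr, idx, anchors, horizon,
                  balance_mu=0.0, mechanism="gradient_reversal"):
    """Masked MSE of decoder forecasts over the given anchor hours.

    All anchors are decoded as one stacked batch (B * n_anchors rows);
    targets beyond the end of the grid are masked out.  With
    ``balance_mu > 0`` the adversarial treatment term is added over the
    decoder states as well (off by default: the decoder sees no future
    treatments, so there is normally nothing to balance in stage 2).
    """
    K = arr.K
    H = int(horizon)
    B = len(idx)
    anchors = [int(t) for t in anchors if K - int(t) >= 1]
    if not anchors:
        raise ValueError("no decoder targets available for the sampled anchors")
    x_list, y_list, m_list = [], [], []
    for tau in anchors:
        x_list.append(enc_states[_predictive_index(tau)].data)
        y = np.full((B, H, arr.y.shape[-1]), np.nan)
        n_h = min(H, K - tau)
        y[:, :n_h] = arr.y[idx][:, tau + 1 : tau + 1 + n_h]
        y_list.append(y)
        m = np.zeros((B, H, arr.y.shape[-1]), dtype=bool)
        m[:, :n_h] = arr.y_mask[idx][:, tau + 1 : tau + 1 + n_h]
        m_list.append(m)
    x_anchor = Tensor(np.concatenate(x_list, axis=0))  # frozen encoder
    d_tiled = np.tile(arr.d[idx], (len(anchors), 1))
    y = np.nan_to_num(np.concatenate(y_list, axis=0))
    m = np.concatenate(m_list, axis=0)
    count = int(m.sum())
    if count == 0:
        raise ValueError("no decoder targets available for the sampled anchors")
    dec = model.decode_states(x_anchor, d_tiled, H)
    xs = concat([s.reshape(-1, 1, model.P) for s in dec[1:]], axis=1)
    y_hat = _head_over_time(model.h_alpha_dec, xs, model.R)
    diff = (y_hat - Tensor(y)) * Tensor(m.astype(float))
    loss = diff.square().sum() * (1.0 / count)
    if balance_mu > 0:
        a_win = np.concatenate(
            [
                np.pad(arr.a[idx][:, tau + 1 : tau + 1 + min(H, arr.K - tau)],
                       ((0, 0), (0, H - min(H, arr.K - tau)), (0, 0)))
                for tau in anchors
            ],
            axis=0,
        )
        x_adv = xs.grad_reverse() if mechanism == "gradient_reversal" else xs
        logits = _head_over_time(model.h_beta, x_adv, model.M)
        L_a = treatment_loss(_treatment_probs(model, logits), a_win, t_start=0)
        loss = combined_loss(loss, L_a, balance_mu, mechanism)
    return loss


# -------------------------------------------------------------------- probing
def treatment_predictability_auc(
    model: TECDEModel,
    train_grids: Sequence[GridRecord],
    test_grids: Sequence[GridRecord],
    hour=(24, 48, 72),
    label: str = "pair",
) -> float:
    """AUC of a logistic probe predicting treatment from frozen latents.

    The probe is fitted on the training cohort's predictive latent states
    (pooled over the given hours -- pooling several hours gives a much
    stabler estimate than a single time point) and evaluated on the
    held-out cohort.  ``label="pair"`` predicts whether a two-antibiotic
    option is ongoing at the state's hour; ``label="vancomycin"`` the
    Vancomycin channel.  Used to quantify how much confounding information
    the balancing penalty removed.
    """
    hours = [int(hour)] if np.isscalar(hour) else [int(h) for h in hour]

    def latents_labels(grids):
        arr = _prepare(grids)
        states = model.encode_knot_states(arr.knots, arr.d)
        Xs, ys = [], []
        for h in hours:
            Xs.append(states[_predictive_index(h)].data)
            a_now = arr.a[:, h]
            if label == "pair":
                ys.append((a_now.sum(axis=1) >= 2).astype(int))
            elif label == "vancomycin":
                vi = grids[0].antibiotics.index("Vancomycin")
                ys.append((a_now[:, vi] > 0).astype(int))
            else:
                raise ValueError(f"unknown label {label!r}")
        return np.concatenate(Xs, axis=0), np.concatenate(ys)

    X_tr, y_tr = latents_labels(train_grids)
    X_te, y_te = latents_labels(test_grids)
    if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
        raise ValueError("treatment label is constant; cannot compute AUC")
    clf = LogisticRegression(max_iter=2000).fit(X_tr, y_tr)
    return float(roc_auc_score(y_te, clf.predict_proba(X_te)[:, 1]))
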