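"""Recurrent path-integration network with dual population-code decoders.

A single LSTM cell (default 128 hidden units) consumes per-step self-motion
triples (v_t, sin(phi_t), cos(phi_t)).  Its cell and hidden states are
initialised from the ground-truth population codes of the starting pose via
four bias-free linear maps,

    c_0 = W_c^pc pcact_0 + W_c^hd hdcact_0
    h_0 = W_h^pc pcact_0 + W_h^hd hdcact_0,

all four matrices learned jointly with the rest of the network.  Each hidden
state is projected through a linear layer to 256 activations (the layer whose
spatial tuning the analysis module later scores), with dropout applied to
those activations during training only, and two softmax heads decode the
linear activations into predicted place-cell and head-direction-cell
probability vectors.  Training minimises the soft-target cross-entropy of
both heads, equally weighted, by Adam with global-norm gradient clipping.

Everything — forward unroll, backpropagation through time, optimiser — is
implemented directly on NumPy arrays; the analytic gradients are validated
against finite differences in the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import TrajectoryRecord
from .population import (
    HeadDirectionEnsemble,
    PlaceCellEnsemble,
    decode_position,
    hd_activations,
    place_activations,
)

__all__ = [
    "NetworkConfig",
    "NetworkParams",
    "ForwardOutputs",
    "NumericalFailureError",
    "init_states",
    "forward",
    "loss",
    "loss_and_grads",
    "train",
    "collect_activations",
    "records_to_batch",
    "median_position_error",
    "uniform_baseline_error",
]


class NumericalFailureError(FloatingPointError):
    """Non-finite activations appeared during the forward unroll."""

    def __init__(self, step: int):
        super().__init__(f"non-finite activations at step {step}")
        self.step = step


@dataclass(frozen=True)
class NetworkConfig:
    hidden_units: int = 128
    linear_units: int = 256
    dropout_prob: float = 0.5
    n_place: int = 256
    n_hd: int = 12
    learning_rate: float = 1e-4
    batch_size: int = 32
    epochs: int = 10
    grad_clip: float = 1.0
    seed: int = 0
    dtype: str = "float32"
    eval_every: int = 5

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_prob < 1.0:
            raise ValueError("dropout_prob must lie in [0, 1)")
        for name in ("hidden_units", "linear_units", "n_place", "n_hd",
                     "batch_size", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _glorot(rng: np.random.Generator, shape: tuple[int, int], dtype) -> np.ndarray:
    limit = np.sqrt(6.0 / (shape[0] + shape[1]))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


@dataclass
class NetworkParams:
    """All learnable arrays; see module docstring for roles."""

    init_cell_from_pc: np.ndarray  # (H, N)
    init_cell_from_hd: np.ndarray  # (H, M)
    init_hidden_from_pc: np.ndarray  # (H, N)
    init_hidden_from_hd: np.ndarray  # (H, M)
    w_x: np.ndarray  # (3, 4H) input-to-gates
    w_h: np.ndarray  # (H, 4H) hidden-to-gates
    b_gates: np.ndarray  # (4H,)
    w_linear: np.ndarray  # (H, L)
    b_linear: np.ndarray  # (L,)
    w_pc: np.ndarray  # (L, N)
    b_pc: np.ndarray  # (N,)
    w_hd: np.ndarray  # (L, M)
    b_hd: np.ndarray  # (M,)

    @classmethod
    def init(cls, cfg: NetworkConfig, rng: np.random.Generator) -> "NetworkParams":
        """Variance-scaled uniform init; forget-gate bias set to 1."""
        h, l = cfg.hidden_units, cfg.linear_units
        n, m = cfg.n_place, cfg.n_hd
        dt = np.dtype(cfg.dtype)
        b_gates = np.zeros(4 * h, dtype=dt)
        b_gates[h : 2 * h] = 1.0  # open forget gates at start of training
        return cls(
            init_cell_from_pc=_glorot(rng, (h, n), dt),
            init_cell_from_hd=_glorot(rng, (h, m), dt),
            init_hidden_from_pc=_glorot(rng, (h, n), dt),
            init_hidden_from_hd=_glorot(rng, (h, m), dt),
            w_x=_glorot(rng, (3, 4 * h), dt),
            w_h=_glorot(rng, (h, 4 * h), dt),
            b_gates=b_gates,
            w_linear=_glorot(rng, (h, l), dt),
            b_linear=np.zeros(l, dtype=dt),
            w_pc=_glorot(rng, (l, n), dt),
            b_pc=np.zeros(n, dtype=dt),
            w_hd=_glorot(rng, (l, m), dt),
            b_hd=np.zeros(m, dtype=dt),
        )

    def arrays(self) -> dict[str, np.ndarray]:
        return dict(vars(self))

    def copy(self) -> "NetworkParams":
        return NetworkParams(**{k: v.copy() for k, v in self.arrays().items()})

    def save(self, path: str | Path, cfg: NetworkConfig | None = None) -> None:
        path = Path(path)
        np.savez(path, **self.arrays())
        if cfg is not None:
            path.with_suffix(".json").write_text(json.dumps(cfg.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkParams":
        with np.load(Path(path)) as data:
            return cls(**{k: data[k] for k in data.files})


@dataclass
class ForwardOutputs:
    linear_activations: np.ndarray  # (B, T, L), pre-dropout
    pc_pred: np.ndarray  # (B, T, N), rows sum to 1
    hd_pred: np.ndarray  # (B, T, M), rows sum to 1


def init_states(
    pc0: np.ndarray, hd0: np.ndarray, params: NetworkParams
) -> tuple[np.ndarray, np.ndarray]:
    """Initial (cell, hidden) states from the time-0 population codes."""
    cell = pc0 @ params.init_cell_from_pc.T + hd0 @ params.init_cell_from_hd.T
    hidden = pc0 @ params.init_hidden_from_pc.T + hd0 @ params.init_hidden_from_hd.T
    return cell, hidden


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def _forward_cache(params, inputs, pc0, hd0):
    """Unrolled forward pass; returns pre-dropout activations plus everything BPTT needs."""
    x = np.asarray(inputs, dtype=params.w_x.dtype)
    if x.ndim == 2:
        x = x[None]
    B, T, _ = x.shape
    H = params.w_h.shape[0]
    c, h = init_states(
        np.asarray(pc0, dtype=x.dtype), np.asarray(hd0, dtype=x.dtype), params
    )
    c = np.atleast_2d(c)
    h = np.atleast_2d(h)

    gates_i = np.empty((B, T, H), dtype=x.dtype)
    gates_f = np.empty_like(gates_i)
    gates_g = np.empty_like(gates_i)
    gates_o = np.empty_like(gates_i)
    tanh_c = np.empty_like(gates_i)
    c_all = np.empty((B, T + 1, H), dtype=x.dtype)
    h_all = np.empty((B, T + 1, H), dtype=x.dtype)
    c_all[:, 0] = c
    h_all[:, 0] = h

    for t in range(T):
        z = x[:, t] @ params.w_x + h_all[:, t] @ params.w_h + params.b_gates
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H : 2 * H])
        g = np.tanh(z[:, 2 * H : 3 * H])
        o = _sigmoid(z[:, 3 * H :])
        c = f * c_all[:, t] + i * g
        tc = np.tanh(c)
        h = o * tc
        if not np.all(np.isfinite(h)):
            raise NumericalFailureError(t)
        gates_i[:, t], gates_f[:, t], gates_g[:, t], gates_o[:, t] = i, f, g, o
        c_all[:, t + 1], tanh_c[:, t], h_all[:, t + 1] = c, tc, h

    lin = h_all[:, 1:] @ params.w_linear + params.b_linear
    cache = {
        "x": x, "pc0": np.atleast_2d(np.asarray(pc0, dtype=x.dtype)),
        "hd0": np.atleast_2d(np.asarray(hd0, dtype=x.dtype)),
        "i": gates_i, "f": gates_f, "g": gates_g, "o": gates_o,
        "tanh_c": tanh_c, "c_all": c_all, "h_all": h_all, "lin": lin,
    }
    return cache


def _heads(params, lin_dropped):
    log_pc = _log_softmax(lin_dropped @ params.w_pc + params.b_pc)
    log_hd = _log_softmax(lin_dropped @ params.w_hd + params.b_hd)
    return log_pc, log_hd


def forward(
    params: NetworkParams,
    inputs: np.ndarray,
    pc0: np.ndarray,
    hd0: np.ndarray,
    mode: str = "eval",
    rng: np.random.Generator | None = None,
    dropout_prob: float = 0.5,
) -> ForwardOutputs:
    """Run the network over a batch of input sequences.

    ``inputs`` is (B, T, 3) (a single (T, 3) sequence is promoted), ``pc0``
    and ``hd0`` the time-0 activation vectors.  In train mode an ``rng`` must
    be supplied for the dropout masks; in eval mode the pass is deterministic.
    """
    cache = _forward_cache(params, inputs, pc0, hd0)
    lin = cache["lin"]
    if mode == "train":
        if rng is None:
            raise ValueError("train mode requires an rng for dropout")
        keep = 1.0 - dropout_prob
        mask = (rng.random(lin.shape) < keep).astype(lin.dtype) / keep
        lin_dropped = lin * mask
    elif mode == "eval":
        lin_dropped = lin
    else:
        raise ValueError("mode must be 'train' or 'eval'")
    log_pc, log_hd = _heads(params, lin_dropped)
    return ForwardOutputs(lin, np.exp(log_pc), np.exp(log_hd))


def loss(out: ForwardOutputs, pc_target: np.ndarray, hd_target: np.ndarray) -> float:
    """Soft-target cross-entropy of both heads, averaged over batch and time."""
    log_pc = np.log(np.clip(out.pc_pred, 1e-30, None))
    log_hd = np.log(np.clip(out.hd_pred, 1e-30, None))
    ce_pc = -(pc_target * log_pc).sum(axis=-1)
    ce_hd = -(hd_target * log_hd).sum(axis=-1)
    return float((ce_pc + ce_hd).mean())


def loss_and_grads(
    params: NetworkParams,
    inputs: np.ndarray,
    pc0: np.ndarray,
    hd0: np.ndarray,
    pc_target: np.ndarray,
    hd_target: np.ndarray,
    mode: str = "train",
    dropout_prob: float = 0.5,
    dropout_seed: int | None = None,
    want_grads: bool = True,
) -> tuple[float, dict[str, np.ndarray] | None]:
    """Loss and (optionally) analytic gradients for one batch.

    The dropout mask is drawn from ``dropout_seed`` so that repeated calls
    with identical arguments — e.g. the two sides of a finite-difference
    check — see the same mask.
    """
    cache = _forward_cache(params, inputs, pc0, hd0)
    lin = cache["lin"]
    if mode == "train" and dropout_prob > 0.0:
        rng = np.random.default_rng(dropout_seed)
        keep = 1.0 - dropout_prob
        mask = (rng.random(lin.shape) < keep).astype(lin.dtype) / keep
    else:
        mask = None
    lin_dropped = lin if mask is None else lin * mask
    log_pc, log_hd = _heads(params, lin_dropped)

    pc_target = np.asarray(pc_target, dtype=lin.dtype)
    hd_target = np.asarray(hd_target, dtype=lin.dtype)
    if pc_target.ndim == 2:
        pc_target = pc_target[None]
    if hd_target.ndim == 2:
        hd_target = hd_target[None]
    B, T, _ = log_pc.shape
    total = float(-((pc_target * log_pc).sum(-1) + (hd_target * log_hd).sum(-1)).mean())
    if not want_grads:
        return total, None

    scale = 1.0 / (B * T)
    d_pc = (np.exp(log_pc) - pc_target) * scale
    d_hd = (np.exp(log_hd) - hd_target) * scale

    ld_flat = lin_dropped.reshape(-1, lin.shape[-1])
    grads: dict[str, np.ndarray] = {}
    grads["w_pc"] = ld_flat.T @ d_pc.reshape(-1, d_pc.shape[-1])
    grads["b_pc"] = d_pc.sum(axis=(0, 1))
    grads["w_hd"] = ld_flat.T @ d_hd.reshape(-1, d_hd.shape[-1])
    grads["b_hd"] = d_hd.sum(axis=(0, 1))

    d_lind = d_pc @ params.w_pc.T + d_hd @ params.w_hd.T
    d_lin = d_lind if mask is None else d_lind * mask
    h_seq = cache["h_all"][:, 1:]
    grads["w_linear"] = h_seq.reshape(-1, h_seq.shape[-1]).T @ d_lin.reshape(
        -1, d_lin.shape[-1]
    )
    grads["b_linear"] = d_lin.sum(axis=(0, 1))
    dh_seq = d_lin @ params.w_linear.T

    # backpropagation through time
    H = params.w_h.shape[0]
    gw_x = np.zeros_like(params.w_x)
    gw_h = np.zeros_like(params.w_h)
    gb = np.zeros_like(params.b_gates)
    dh_carry = np.zeros((B, H), dtype=lin.dtype)
    dc_carry = np.zeros((B, H), dtype=lin.dtype)
    i_, f_, g_, o_ = cache["i"], cache["f"], cache["g"], cache["o"]
    tc, c_all, h_all, x = cache["tanh_c"], cache["c_all"], cache["h_all"], cache["x"]
    for t in range(T - 1, -1, -1):
        dh = dh_seq[:, t] + dh_carry
        do = dh * tc[:, t]
        dc = dc_carry + dh * o_[:, t] * (1.0 - tc[:, t] ** 2)
        di = dc * g_[:, t]
        dg = dc * i_[:, t]
        df = dc * c_all[:, t]
        dz = np.concatenate(
            [
                di * i_[:, t] * (1.0 - i_[:, t]),
                df * f_[:, t] * (1.0 - f_[:, t]),
                dg * (1.0 - g_[:, t] ** 2),
                do * o_[:, t] * (1.0 - o_[:, t]),
            ],
            axis=1,
        )
        gw_x += x[:, t].T @ dz
        gw_h += h_all[:, t].T @ dz
        gb += dz.sum(axis=0)
        dh_carry = dz @ params.w_h.T
        dc_carry = dc * f_[:, t]
    grads["w_x"], grads["w_h"], grads["b_gates"] = gw_x, gw_h, gb

    pc0_b, hd0_b = cache["pc0"], cache["hd0"]
    grads["init_cell_from_pc"] = dc_carry.T @ pc0_b
    grads["init_cell_from_hd"] = dc_carry.T @ hd0_b
    grads["init_hidden_from_pc"] = dh_carry.T @ pc0_b
    grads["init_hidden_from_hd"] = dh_carry.T @ hd0_b
    return total, grads


class _Adam:
    def __init__(self, params: NetworkParams, lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.arrays().items()}
        self.v = {k: np.zeros_like(v) for k, v in params.arrays().items()}

    def step(self, params: NetworkParams, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
            arr = getattr(params, k)
            arr -= (self.lr * update).astype(arr.dtype)


def _clip_grads(grads: dict[str, np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads.values():
            g *= scale


def records_to_batch(
    records: Sequence[TrajectoryRecord],
    pc: PlaceCellEnsemble,
    hd: HeadDirectionEnsemble,
) -> dict[str, np.ndarray]:
    """Stack records into dense arrays with materialised activation targets."""
    inputs = np.stack([r.inputs for r in records])
    tpos = np.stack([r.target_positions for r in records])
    thead = np.stack([r.target_headings for r in records])
    init_pos = np.stack([r.init_position for r in records])
    init_head = np.array([r.init_heading for r in records])
    return {
        "inputs": inputs,
        "target_positions": tpos,
        "pc_target": place_activations(tpos, pc),
        "hd_target": hd_activations(thead, hd),
        "pc0": place_activations(init_pos, pc),
        "hd0": hd_activations(init_head, hd),
    }


def median_position_error(
    out: ForwardOutputs, target_positions: np.ndarray, pc: PlaceCellEnsemble
) -> float:
    """Median Euclidean error (m) of positions decoded from pc predictions."""
    decoded = decode_position(out.pc_pred, pc)
    err = np.linalg.norm(decoded - target_positions, axis=-1)
    return float(np.median(err))


def uniform_baseline_error(
    target_positions: np.ndarray, pc: PlaceCellEnsemble
) -> float:
    """Median error of the uninformed predictor (uniform place activations).

    A uniform activation vector decodes to the centroid of the cell centres,
    so this is the median distance of the targets from that fixed point.
    """
    centroid = pc.centers.mean(axis=0)
    err = np.linalg.norm(np.asarray(target_positions) - centroid, axis=-1)
    return float(np.median(err))


def train(
    train_records: Sequence[TrajectoryRecord],
    eval_records: Sequence[TrajectoryRecord],
    pc: PlaceCellEnsemble,
    hd: HeadDirectionEnsemble,
    cfg: NetworkConfig,
    checkpoint_dir: str | Path | None = None,
) -> tuple[NetworkParams, list[dict]]:
    """Gradient training loop; returns final parameters and the metric log.

    Logs train loss every epoch and evaluation loss / median decoding error
    every ``cfg.eval_every`` epochs (plus epoch 0 and the final epoch).  On a
    non-finite loss the last finite-loss parameters are restored and training
    stops early.
    """
    if not train_records:
        raise ValueError("training split is empty")
    rng = np.random.default_rng(cfg.seed)
    params = NetworkParams.init(cfg, rng)
    opt = _Adam(params, cfg.learning_rate)
    tb = records_to_batch(train_records, pc, hd)
    eb = records_to_batch(eval_records, pc, hd) if eval_records else None
    n = tb["inputs"].shape[0]
    log: list[dict] = []
    last_good = params.copy()

    def eval_metrics() -> dict:
        if eb is None:
            return {}
        out = forward(params, eb["inputs"], eb["pc0"], eb["hd0"], mode="eval")
        return {
            "eval_loss": loss(out, eb["pc_target"], eb["hd_target"]),
            "eval_pos_error": median_position_error(out, eb["target_positions"], pc),
        }

    entry = {"epoch": 0, "train_loss": None, **eval_metrics()}
    log.append(entry)
    diverged = False
    for epoch in range(1, cfg.epochs + 1):
        perm = rng.permutation(n)
        epoch_losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start : start + cfg.batch_size]
            seed = int(rng.integers(2**31))
            batch_loss, grads = loss_and_grads(
                params,
                tb["inputs"][idx],
                tb["pc0"][idx],
                tb["hd0"][idx],
                tb["pc_target"][idx],
                tb["hd_target"][idx],
                mode="train",
                dropout_prob=cfg.dropout_prob,
                dropout_seed=seed,
            )
            if not np.isfinite(batch_loss):
                diverged = True
                break
            _clip_grads(grads, cfg.grad_clip)
            opt.step(params, grads)
            epoch_losses.append(batch_loss)
        if diverged:
            params = last_good
            log.append({"epoch": epoch, "train_loss": float("nan"), "diverged": True})
            break
        last_good = params.copy()
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if epoch % cfg.eval_every == 0 or epoch == cfg.epochs:
            entry.update(eval_metrics())
        log.append(entry)
        if checkpoint_dir is not None:
            params.save(Path(checkpoint_dir) / "checkpoint.npz", cfg)
    return params, log


def collect_activations(
    records: Sequence[TrajectoryRecord],
    params: NetworkParams,
    pc: PlaceCellEnsemble,
    hd: HeadDirectionEnsemble,
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eval-mode linear-layer activations paired with ground-truth pose.

    Returns (positions (n, 2), headings (n,), activations (n, L)) with one
    row per step of every record; dropout is off, so the activations are the
    deterministic quantities whose spatial tuning the analysis module scores.
    """
    positions, headings, acts = [], [], []
    records = list(records)
    for start in range(0, len(records), batch_size):
        chunk = records[start : start + batch_size]
        b = records_to_batch(chunk, pc, hd)
        out = forward(params, b["inputs"], b["pc0"], b["hd0"], mode="eval")
        L = out.linear_activations.shape[-1]
        acts.append(out.linear_activations.reshape(-1, L))
        positions.append(b["target_positions"].reshape(-1, 2))
        headings.append(np.stack([r.target_headings for r in chunk]).reshape(-1))
    return (
        np.concatenate(positions),
        np.concatenate(headings),
        np.concatenate(acts),
    )
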