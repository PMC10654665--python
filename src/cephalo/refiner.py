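"""Stage-2 coordinate refinement.

Two independent three-layer perceptrons (23 -> 500 -> 23), one for the x-axis
and one for the y-axis, map the 23 stage-1 coordinate estimates of one image
to 23 refined coordinates, exploiting inter-landmark structure.  Coordinates
are normalized into [0, 1] by the image side before entering the network.

The two axis networks share no parameters, use independent random streams,
and keep their optimizer and shuffling state across calls so that training
may resume cycle after cycle without re-initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tape, Var
from .core import N_LANDMARKS, ContractError, LandmarkSet
from .nn import Adam, Linear, Module


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class RefinerConfig:
    n_landmarks: int = N_LANDMARKS
    hidden: int = 500
    lr: float = 1e-5
    weight_decay: float = 1e-4
    epochs_per_cycle: int = 100
    batch_size: int = 16
    norm_side: float = 1200.0
    residual: bool = False  # regress corrections instead of absolute coords
    init: str = "near_identity"  # or "random"; warm start speeds convergence
    init_scale: float = 0.01  # perturbation scale for the near-identity init


class AxisNet(Module):
    """One 23 -> hidden -> 23 perceptron with a rectifier hidden layer."""

    def __init__(self, cfg: RefinerConfig, rng: np.random.Generator) -> None:
        self.fc1 = Linear(cfg.n_landmarks, cfg.hidden, rng)
        self.fc2 = Linear(cfg.hidden, cfg.n_landmarks, rng)

    def __call__(self, tape: Tape, x: Var) -> Var:
        return self.fc2(tape, ad.relu(tape, self.fc1(tape, x)))

    @property
    def in_features(self) -> int:
        return self.fc1.w.data.shape[1]

    @property
    def out_features(self) -> int:
        return self.fc2.w.data.shape[0]

    @property
    def hidden_features(self) -> int:
        return self.fc1.w.data.shape[0]


class RefinerModel:
    def __init__(self, cfg: RefinerConfig = RefinerConfig(), seed: int = 0) -> None:
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        init_x, init_y, shuf_x, shuf_y = ss.spawn(4)
        self.x_net = AxisNet(cfg, np.random.default_rng(init_x))
        self.y_net = AxisNet(cfg, np.random.default_rng(init_y))
        if cfg.init == "near_identity":
            self._init_near_identity(self.x_net, np.random.default_rng(init_x))
            self._init_near_identity(self.y_net, np.random.default_rng(init_y))
        elif cfg.init != "random":
            raise ContractError(f"unknown init {cfg.init!r}")
        self._rng_x = np.random.default_rng(shuf_x)
        self._rng_y = np.random.default_rng(shuf_y)
        self.opt_x = Adam(self.x_net.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
        self.opt_y = Adam(self.y_net.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)

    def _init_near_identity(self, net: AxisNet, rng: np.random.Generator) -> None:
        """Warm start: output ~= input via the rectifier split x = relu(x) - relu(-x),
        with a small random perturbation on the hidden layer."""
        cfg = self.cfg
        n = cfg.n_landmarks
        if cfg.hidden < 2 * n:
            return  # fall back to the random init already applied
        w1 = rng.standard_normal(net.fc1.w.data.shape) * cfg.init_scale
        w1[:n, :] += np.eye(n)
        w1[n : 2 * n, :] -= np.eye(n)
        net.fc1.w.data = w1
        net.fc1.b.data = np.zeros_like(net.fc1.b.data)
        w2 = np.zeros_like(net.fc2.w.data)
        w2[:, :n] = np.eye(n)
        w2[:, n : 2 * n] = -np.eye(n)
        net.fc2.w.data = w2
        net.fc2.b.data = np.zeros_like(net.fc2.b.data)

    def set_lr(self, lr: float) -> None:
        self.opt_x.lr = lr
        self.opt_y.lr = lr

    # -- inference ---------------------------------------------------------

    def _forward_axis(self, net: AxisNet, values: np.ndarray) -> np.ndarray:
        tape = Tape()
        out = net(tape, Var(values / self.cfg.norm_side))
        refined = out.data * self.cfg.norm_side
        if self.cfg.residual:
            refined = values + refined
        return refined

    def refine_coords(self, coords: np.ndarray) -> np.ndarray:
        """Refine a batch of coordinate arrays of shape (n, 23, 2) or (23, 2)."""
        arr = np.asarray(coords, dtype=float)
        single = arr.ndim == 2
        if single:
            arr = arr[None]
        if arr.shape[1:] != (self.cfg.n_landmarks, 2):
            raise ContractError(
                f"expected (n, {self.cfg.n_landmarks}, 2) coordinates, got {arr.shape}"
            )
        x = self._forward_axis(self.x_net, arr[:, :, 0])
        y = self._forward_axis(self.y_net, arr[:, :, 1])
        out = np.stack([x, y], axis=-1)
        return out[0] if single else out

    def refine(self, ls: LandmarkSet) -> LandmarkSet:
        """Refine one stage-1 landmark set; returns a set with role 'refined'."""
        refined = self.refine_coords(ls.coords)
        return LandmarkSet(ls.scheme, ls.space, refined, role="refined")

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        import json

        state = {}
        for tag, net, opt in (("x", self.x_net, self.opt_x), ("y", self.y_net, self.opt_y)):
            for k, v in net.state_dict().items():
                state[f"{tag}.{k}"] = v
            for k, v in opt.state_dict().items():
                state[f"opt_{tag}.{k}"] = v
        meta = asdict(self.cfg)
        state["__config__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path) -> "RefinerModel":
        import json

        with np.load(path) as data:
            meta = json.loads(bytes(data["__config__"].tobytes()).decode())
            model = cls(RefinerConfig(**meta), seed=0)
            for tag, net, opt in (("x", model.x_net, model.opt_x), ("y", model.y_net, model.opt_y)):
                net.load_state_dict(
                    {k[len(tag) + 1 :]: data[k] for k in data.files if k.startswith(f"{tag}.")}
                )
                opt.load_state_dict(
                    {k[len(tag) + 5 :]: data[k] for k in data.files if k.startswith(f"opt_{tag}.")}
                )
        return model


def make_identity_refiner(cfg: RefinerConfig = RefinerConfig()) -> RefinerModel:
    """A refiner whose networks implement the exact identity map (test utility).

    Uses the rectifier decomposition x = relu(x) - relu(-x); requires
    ``hidden >= 2 * n_landmarks``.
    """
    if cfg.hidden < 2 * cfg.n_landmarks:
        raise ContractError("identity construction needs hidden >= 2 * n_landmarks")
    model = RefinerModel(cfg, seed=0)
    n = cfg.n_landmarks
    for net in (model.x_net, model.y_net):
        w1 = np.zeros_like(net.fc1.w.data)
        w1[:n, :] = np.eye(n)
        w1[n : 2 * n, :] = -np.eye(n)
        net.fc1.w.data = w1
        net.fc1.b.data = np.zeros_like(net.fc1.b.data)
        w2 = np.zeros_like(net.fc2.w.data)
        w2[:, :n] = np.eye(n)
        w2[:, n : 2 * n] = -np.eye(n)
        net.fc2.w.data = w2
        net.fc2.b.data = np.zeros_like(net.fc2.b.data)
    return model


def refiner_loss(pred: np.ndarray, gt: np.ndarray) -> float:
    """Per-axis L2 loss: sum over the 23 landmarks of squared differences."""
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gt, dtype=float)
    if p.shape != (N_LANDMARKS,) or g.shape != (N_LANDMARKS,):
        raise ContractError(f"expected two length-{N_LANDMARKS} vectors")
    d = p - g
    return float(np.sum(d * d))


def _coords_array(sets_or_array, n_landmarks: int) -> np.ndarray:
    if isinstance(sets_or_array, np.ndarray):
        arr = np.asarray(sets_or_array, dtype=float)
    else:
        arr = np.stack([s.coords if isinstance(s, LandmarkSet) else np.asarray(s) for s in sets_or_array])
    if arr.ndim != 3 or arr.shape[1:] != (n_landmarks, 2):
        raise ContractError(f"expected (n, {n_landmarks}, 2) coordinates, got {arr.shape}")
    return arr


def _train_axis(
    net: AxisNet,
    opt: Adam,
    rng: np.random.Generator,
    inputs: np.ndarray,
    targets: np.ndarray,
    epochs: int,
    batch_size: int,
    norm_side: float,
    residual: bool,
) -> List[float]:
    n = inputs.shape[0]
    xin = inputs / norm_side
    tgt = (targets - inputs) / norm_side if residual else targets / norm_side
    trace = []
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            tape = Tape()
            pred = net(tape, Var(xin[idx]))
            loss = ad.sse_loss(tape, pred, tgt[idx], scale=1.0 / len(idx))
            opt.zero_grad()
            tape.backward(loss)
            opt.step()
            total += float(loss.data) * len(idx)
        trace.append(total / n)
    return trace


def train_refiner(
    model: RefinerModel,
    stage1,
    ground_truth,
    epochs: Optional[int] = None,
) -> Tuple[RefinerModel, List[float]]:
    """Train both axis networks independently on (stage-1, ground-truth) pairs.

    Parameters persist across calls: optimizer moments, step counters and the
    shuffling streams continue where the previous call left off, so two calls
    of e epochs equal one call of 2e epochs on the same data.

    Returns the model and a per-epoch loss trace (mean of the two axis
    losses, per image).
    """
    cfg = model.cfg
    s1 = _coords_array(stage1, cfg.n_landmarks)
    gt = _coords_array(ground_truth, cfg.n_landmarks)
    if s1.shape != gt.shape:
        raise ContractError("stage-1 and ground-truth pair counts differ")
    if s1.shape[0] == 0:
        raise DataError("empty training pair set")
    n_epochs = cfg.epochs_per_cycle if epochs is None else epochs
    trace_x = _train_axis(model.x_net, model.opt_x, model._rng_x, s1[:, :, 0], gt[:, :, 0],
                          n_epochs, cfg.batch_size, cfg.norm_side, cfg.residual)
    trace_y = _train_axis(model.y_net, model.opt_y, model._rng_y, s1[:, :, 1], gt[:, :, 1],
                          n_epochs, cfg.batch_size, cfg.norm_side, cfg.residual)
    trace = [0.5 * (a + b) for a, b in zip(trace_x, trace_y)]
    return model, trace
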