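"""Layer modules and the Adam optimizer on top of the autodiff tape."""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np

from . import autodiff as ad
from .autodiff import Tape, Var


class Module:
    """Base class: children are discovered from instance attributes."""

    def named_params(self, prefix: str = "") -> List[Tuple[str, Var]]:
        out: List[Tuple[str, Var]] = []
        for key, value in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(value, Var):
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend(value.named_params(prefix=f"{name}."))
            elif isinstance(value, (list, tuple)):
                for k, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_params(prefix=f"{name}.{k}."))
        return out

    def params(self) -> List[Var]:
        return [p for _, p in self.named_params()]

    def named_buffers(self, prefix: str = "") -> List[Tuple[str, np.ndarray]]:
        out: List[Tuple[str, np.ndarray]] = []
        for key, value in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(value, np.ndarray):
                out.append((name, value))
            elif isinstance(value, Module):
                out.extend(value.named_buffers(prefix=f"{name}."))
            elif isinstance(value, (list, tuple)):
                for k, item in enumerate(value):
                    if isinstance(item, Module):
                        out.extend(item.named_buffers(prefix=f"{name}.{k}."))
        return out

    def state_dict(self) -> Dict[str, np.ndarray]:
        state = {f"param.{n}": p.data for n, p in self.named_params()}
        state.update({f"buffer.{n}": b for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        for n, p in self.named_params():
            p.data = np.array(state[f"param.{n}"], dtype=float)
        for n, b in self.named_buffers():
            b[...] = state[f"buffer.{n}"]


class Conv2d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, pad: Optional[int] = None, bias: bool = True) -> None:
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        std = np.sqrt(2.0 / (cin * k * k))
        self.w = Var(rng.standard_normal((cout, cin, k, k)) * std)
        self.b = Var(np.zeros(cout)) if bias else None

    def __call__(self, tape: Tape, x: Var) -> Var:
        return ad.conv2d(tape, x, self.w, self.b, stride=self.stride, pad=self.pad)


class BatchNorm2d(Module):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Var(np.ones(c))
        self.beta = Var(np.zeros(c))
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, tape: Tape, x: Var, train: bool) -> Var:
        return ad.batchnorm2d(
            tape, x, self.gamma, self.beta, self.running_mean, self.running_var,
            train=train, momentum=self.momentum, eps=self.eps,
        )


class Linear(Module):
    def __init__(self, fin: int, fout: int, rng: np.random.Generator) -> None:
        bound = np.sqrt(1.0 / fin)
        self.w = Var(rng.uniform(-bound, bound, size=(fout, fin)))
        self.b = Var(rng.uniform(-bound, bound, size=fout))

    def __call__(self, tape: Tape, x: Var) -> Var:
        return ad.linear(tape, x, self.w, self.b)


class ConvBNReLU(Module):
    """3x3 (or 1x1) convolution + batch norm + optional ReLU."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 stride: int = 1, act: bool = True) -> None:
        self.conv = Conv2d(cin, cout, k, rng, stride=stride, bias=False)
        self.bn = BatchNorm2d(cout)
        self.act = act

    def __call__(self, tape: Tape, x: Var, train: bool) -> Var:
        y = self.bn(tape, self.conv(tape, x), train)
        return ad.relu(tape, y) if self.act else y


class Adam:
    """Adam with optional decoupled-from-nothing classic L2 weight decay."""

    def __init__(self, params: Iterable[Var], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0) -> None:
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad if p.grad is not None else np.zeros_like(p.data)
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def state_dict(self) -> Dict[str, np.ndarray]:
        state: Dict[str, np.ndarray] = {"t": np.array(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            state[f"m.{i}"] = m
            state[f"v.{i}"] = v
        return state

    def load_state_dict(self, state: Dict[str, np.ndarray]) -> None:
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i] = np.array(state[f"m.{i}"], dtype=float)
            self.v[i] = np.array(state[f"v.{i}"], dtype=float)
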