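"""AdamW and a cosine learning-rate schedule with linear warmup."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = ["AdamW", "cosine_lr"]


class AdamW:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr: float | None = None):
        lr = self.lr if lr is None else lr
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / bc1
            vh = self.v[i] / bc2
            p.data -= lr * (mh / (np.sqrt(vh) + self.eps)
                            + self.weight_decay * p.data)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state(self) -> dict:
        return dict(t=self.t, m=[m.copy() for m in self.m],
                    v=[v.copy() for v in self.v])

    def load_state(self, state: dict):
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]


def cosine_lr(step: int, total_steps: int, base_lr: float,
              warmup: int = 0, final_frac: float = 0.0) -> float:
    """Linear warmup to ``base_lr`` then cosine decay to
    ``final_frac * base_lr``."""
    if warmup and step < warmup:
        return base_lr * (step + 1) / warmup
    denom = max(total_steps - warmup, 1)
    t = min(max(step - warmup, 0) / denom, 1.0)
    lo = final_frac * base_lr
    return lo + (base_lr - lo) * 0.5 * (1.0 + np.cos(np.pi * t))
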