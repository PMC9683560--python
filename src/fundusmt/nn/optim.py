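"""Adam optimizer over named parameter groups."""

from __future__ import annotations

import numpy as np

from .modules import Parameter


class Adam:
    """Adam with framework-default moments (beta1=0.9, beta2=0.999, eps=1e-8).

    ``params`` is a mapping from parameter name to :class:`Parameter`; the
    learning rate may be reassigned between steps (cosine annealing drives
    it from outside).  Parameters whose gradient is ``None`` are skipped.
    """

    def __init__(self, params: dict[str, Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = dict(params)
        self.lr = float(lr)
        self.beta1, self.beta2 = betas
        self.eps = eps
        self._m = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._v = {k: np.zeros_like(p.data) for k, p in self.params.items()}
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self._t += 1
        b1t = 1.0 - self.beta1 ** self._t
        b2t = 1.0 - self.beta2 ** self._t
        for k, p in self.params.items():
            g = p.grad
            if g is None:
                continue
            m = self._m[k]
            v = self._v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * np.square(g)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
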