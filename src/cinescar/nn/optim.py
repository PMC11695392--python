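"""Plain stochastic gradient descent."""

from __future__ import annotations

from .layers import Parameter


class SGD:
    def __init__(self, parameters: list[Parameter], lr: float) -> None:
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.parameters = parameters
        self.lr = lr

    def zero_grad(self) -> None:
        for p in self.parameters:
            p.grad[...] = 0

    def step(self) -> None:
        for p in self.parameters:
            p.value -= (self.lr * p.grad).astype(p.value.dtype, copy=False)
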