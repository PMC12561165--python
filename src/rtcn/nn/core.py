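"""Minimal layer-based neural-network engine on numpy.

Each :class:`Module` implements ``forward`` (caching what backward needs) and
``backward`` (returning the gradient w.r.t. its input while accumulating
parameter gradients).  This explicit reverse-mode scheme is all the pipeline
needs: supervised training of the cascade, diffusion-model training, and
Grad-CAM (which reads activations and their gradients at a chosen layer).

Determinism: every random choice (initialization, dropout) is driven by a
`numpy.random.Generator` supplied at construction time.
"""
from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)

    @property
    def shape(self):
        return self.value.shape

    def zero_grad(self):
        self.grad[...] = 0.0


class Module:
    """Base class: parameter discovery, train/eval mode, activation capture."""

    def __init__(self):
        self.training = True
        self._out = None        # last forward output (for explainability)
        self._out_grad = None   # gradient of the loss w.r.t. that output

    # -- parameter / submodule discovery ------------------------------------
    def named_parameters(self, prefix=""):
        for name, attr in vars(self).items():
            if isinstance(attr, Parameter):
                yield f"{prefix}{name}", attr
            elif isinstance(attr, Module):
                yield from attr.named_parameters(f"{prefix}{name}.")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{prefix}{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{prefix}{name}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for attr in vars(self).values():
            if isinstance(attr, Module):
                yield from attr.modules()
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- forward / backward --------------------------------------------------
    def forward(self, x):
        raise NotImplementedError

    def backward(self, grad_out):
        raise NotImplementedError

    def __call__(self, x):
        out = self.forward(x)
        self._out = out
        return out

    # -- state (save/load) ---------------------------------------------------
    def state_dict(self):
        return {name: p.value.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state):
        for name, p in self.named_parameters():
            p.value[...] = state[name]


class Sequential(Module):
    """Chain of modules; backward replays the chain in reverse and records the
    gradient of each layer's output (used by Grad-CAM)."""

    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            layer._out_grad = grad_out
            grad_out = layer.backward(grad_out)
        return grad_out

    def __iter__(self):
        return iter(self.layers)

    def __getitem__(self, i):
        return self.layers[i]


class Identity(Module):
    def forward(self, x):
        return x

    def backward(self, g):
        return g
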