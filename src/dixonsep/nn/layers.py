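"""Layers and the module container for the volumetric GAN networks."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor

__all__ = [
    "Module",
    "Conv3d",
    "ConvTranspose3d",
    "Norm3d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Sequential",
]


class Module:
    """Base class: named parameters, recursive collection, state dicts."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def add(self, name: str, module: "Module") -> None:
        self._children[name] = module
        object.__setattr__(self, name, module)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + name: p for name, p in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        missing = set(params) - set(state)
        extra = set(state) - set(params)
        if missing or extra:
            raise ValueError(f"state dict mismatch: missing {sorted(missing)}, unexpected {sorted(extra)}")
        for k, p in params.items():
            if p.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}: {p.data.shape} vs {state[k].shape}")
            p.data = np.asarray(state[k], dtype=np.float32).copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


def _gaussian_init(rng: np.random.Generator, shape, std: float = 0.02) -> Tensor:
    return Tensor(rng.normal(0.0, std, size=shape).astype(np.float32), requires_grad=True)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.weight = _gaussian_init(rng, (out_ch, in_ch, kernel, kernel, kernel))
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return x.conv3d(self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int = 4, stride: int = 2,
                 padding: int = 1, bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = padding
        self.weight = _gaussian_init(rng, (in_ch, out_ch, kernel, kernel, kernel))
        self.bias = (
            Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None
        )

    def forward(self, x: Tensor) -> Tensor:
        return x.conv_transpose3d(self.weight, self.bias, self.stride, self.padding)


class Norm3d(Module):
    """Feature normalization with per-channel affine parameters.

    ``kind='instance'`` normalizes each (sample, channel) over its spatial
    extent; ``kind='batch'`` pools the batch as well. Statistics always come
    from the current batch (the pix2pix convention of keeping normalization
    in training mode at inference time).
    """

    def __init__(self, channels: int, kind: str = "instance"):
        super().__init__()
        if kind not in ("instance", "batch"):
            raise ValueError(f"norm kind must be 'instance' or 'batch', got {kind!r}")
        self.kind = kind
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        axes = (2, 3, 4) if self.kind == "instance" else (0, 2, 3, 4)
        return x.normalize(axes, self.gamma, self.beta)


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        super().__init__()
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self.modules = list(modules)
        for i, m in enumerate(modules):
            self.add(f"m{i}", m)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.modules:
            x = m(x)
        return x
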