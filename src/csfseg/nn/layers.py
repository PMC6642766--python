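"""Network building blocks on top of the autodiff core."""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, concat, conv2d, max_pool2d, pixel_shuffle

__all__ = [
    "Module",
    "Sequential",
    "Identity",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "PixelShuffle",
    "SelfAttention2d",
]


class Module:
    """Base class with recursive parameter/buffer discovery and train/eval mode."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, *args, **kwargs) -> Tensor:
        return self.forward(*args, **kwargs)

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for _, child in self._children():
            yield from child.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Conv2d(Module):
    """2D convolution, He-normal initialized."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int | None = None,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        self.stride = stride
        self.padding = k // 2 if padding is None else padding
        std = np.sqrt(2.0 / (in_channels * k * k))
        self.weight = Parameter(rng.normal(0.0, std, size=(out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        gamma, beta = self.gamma, self.beta
        if self.training:
            mu = x.data.mean(axis=(0, 2, 3))
            var = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (mu.astype(np.float32) - self.running_mean)
            self.running_var += self.momentum * (var.astype(np.float32) - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat_data = (x.data - mu[:, None, None]) * inv[:, None, None]
        out = Tensor(xhat_data * gamma.data[:, None, None] + beta.data[:, None, None])
        training = self.training

        def backward(g):
            if gamma.requires_grad:
                gamma._accumulate(np.sum(g * xhat_data, axis=(0, 2, 3)).astype(np.float32))
            if beta.requires_grad:
                beta._accumulate(np.sum(g, axis=(0, 2, 3)).astype(np.float32))
            if x.requires_grad or x._prev:
                gxh = g * gamma.data[:, None, None]
                if training:
                    mean_g = gxh.mean(axis=(0, 2, 3), keepdims=True)
                    mean_gx = (gxh * xhat_data).mean(axis=(0, 2, 3), keepdims=True)
                    gx = inv[:, None, None] * (gxh - mean_g - xhat_data * mean_gx)
                else:
                    gx = gxh * inv[:, None, None]
                x._accumulate(gx.astype(x.data.dtype, copy=False))

        return Tensor._track(out, (x, gamma, beta), backward)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int | None = None, padding: int = 0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel_size, self.stride, self.padding)


class PixelShuffle(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        return pixel_shuffle(x, self.scale)


class SelfAttention2d(Module):
    """Self-attention over spatial positions with a learned residual gate.

    Three 1×1 projections produce queries/keys (``channels // 8``) and values
    (full width). The attention map is row-softmaxed (each output position's
    weights over input positions sum to 1) and the aggregated values are added
    back through a scalar gain ``gamma`` initialized to 0, so at initialization
    the block is an exact identity.
    """

    def __init__(self, channels: int, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        inner = max(channels // 8, 1)
        self.query = Conv2d(channels, inner, 1, bias=False, rng=rng)
        self.key = Conv2d(channels, inner, 1, bias=False, rng=rng)
        self.value = Conv2d(channels, channels, 1, bias=False, rng=rng)
        self.gamma = Parameter(np.zeros(1))

    def attention_map(self, x: Tensor) -> Tensor:
        """(B, N, N) row-stochastic attention weights for a (B, C, H, W) input."""
        B, C, H, W = x.shape
        n = H * W
        q = self.query(x).reshape(B, -1, n)
        k = self.key(x).reshape(B, -1, n)
        scores = q.swapaxes(1, 2).matmul(k)  # (B, N_out, N_in)
        return scores.softmax(axis=-1)

    def forward(self, x: Tensor) -> Tensor:
        B, C, H, W = x.shape
        n = H * W
        attn = self.attention_map(x)
        v = self.value(x).reshape(B, C, n)
        out = v.matmul(attn.swapaxes(1, 2))  # (B, C, N_out)
        return x + self.gamma * out.reshape(B, C, H, W)


def concat_channels(tensors) -> Tensor:
    return concat(tensors, axis=1)
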