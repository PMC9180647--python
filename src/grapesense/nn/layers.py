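"""Layers with explicit forward/backward passes.

Conventions: spectral feature maps are float32 arrays of shape
(batch, channels, length); fully connected activations are (batch, features).
``forward(x, training, rng)`` caches whatever ``backward(grad)`` needs;
``backward`` returns the gradient with respect to the layer input and
accumulates parameter gradients in ``.grads``.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


class ArchitectureError(ValueError):
    """A layer's output length underflowed to zero."""


def xavier_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int,
                   rng: np.random.Generator) -> np.ndarray:
    """Glorot uniform initialization: U(-a, a) with a = sqrt(6 / (fan_in + fan_out))."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(DTYPE)


class Layer:
    params: dict
    grads: dict

    def __init__(self) -> None:
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray, training: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.params.values())

    def out_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        """Output shape (excluding batch) for a given input shape, by arithmetic."""
        return in_shape


class Conv1d(Layer):
    """1-D convolution, stride 1, symmetric zero padding.

    Output length follows L_out = L_in + 2*padding - kernel + 1. The forward
    and backward passes are written as a short sum over kernel offsets, each
    a single tensor contraction, which keeps memory flat for kernels of
    length 3-5.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.padding = padding
        fan_in, fan_out = in_channels * kernel, out_channels * kernel
        self.params["W"] = xavier_uniform((out_channels, in_channels, kernel),
                                          fan_in, fan_out, rng)
        self.params["b"] = np.zeros(out_channels, dtype=DTYPE)

    def _l_out(self, l_in: int) -> int:
        l_out = l_in + 2 * self.padding - self.kernel + 1
        if l_out < 1:
            raise ArchitectureError(
                f"conv(k={self.kernel}, p={self.padding}) underflows: "
                f"input length {l_in} gives output length {l_out}"
            )
        return l_out

    def out_shape(self, in_shape):
        c, l = in_shape
        if c != self.in_channels:
            raise ArchitectureError(
                f"expected {self.in_channels} input channels, got {c}")
        return (self.out_channels, self._l_out(l))

    def forward(self, x, training, rng):
        n, c, l = x.shape
        l_out = self._l_out(l)
        p = self.padding
        x_pad = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        self._x_pad = x_pad
        W, b = self.params["W"], self.params["b"]
        out = np.zeros((n, self.out_channels, l_out),
                       dtype=np.result_type(W.dtype, x.dtype))
        for t in range(self.kernel):
            # out[n,o,l] += sum_c W[o,c,t] * x_pad[n,c,l+t]
            out += np.einsum("oc,ncl->nol", W[:, :, t], x_pad[:, :, t:t + l_out],
                             optimize=True)
        return out + b[None, :, None]

    def backward(self, grad):
        x_pad = self._x_pad
        l_out = grad.shape[2]
        W = self.params["W"]
        dW = np.empty_like(W)
        dx_pad = np.zeros_like(x_pad)
        for t in range(self.kernel):
            seg = x_pad[:, :, t:t + l_out]
            dW[:, :, t] = np.einsum("nol,ncl->oc", grad, seg, optimize=True)
            dx_pad[:, :, t:t + l_out] += np.einsum("oc,nol->ncl", W[:, :, t], grad,
                                                   optimize=True)
        self.grads["W"] = dW
        self.grads["b"] = grad.sum(axis=(0, 2))
        p = self.padding
        return dx_pad[:, :, p:x_pad.shape[2] - p] if p else dx_pad


class BatchNorm(Layer):
    """Batch normalization over (batch, length) per channel, or batch per feature.

    The axis set is inferred from input rank: 3-D conv maps normalize each
    channel over batch and length; 2-D fully connected activations normalize
    each feature over the batch. Running statistics (momentum 0.1) are used
    in evaluation mode, making inference deterministic.
    """

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(num_features, dtype=DTYPE)
        self.params["beta"] = np.zeros(num_features, dtype=DTYPE)
        self.running_mean = np.zeros(num_features, dtype=DTYPE)
        self.running_var = np.ones(num_features, dtype=DTYPE)

    def _expand(self, v, ndim):
        return v[None, :, None] if ndim == 3 else v[None, :]

    def forward(self, x, training, rng):
        axes = (0, 2) if x.ndim == 3 else (0,)
        self._axes, self._ndim = axes, x.ndim
        gamma = self._expand(self.params["gamma"], x.ndim)
        beta = self._expand(self.params["beta"], x.ndim)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean).astype(DTYPE)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_sd = 1.0 / np.sqrt(np.asarray(var, dtype=x.dtype) + self.eps)
        x_hat = (x - self._expand(np.asarray(mean, dtype=x.dtype), x.ndim)) \
            * self._expand(inv_sd, x.ndim)
        self._x_hat, self._inv_sd, self._training = x_hat, inv_sd, training
        return gamma * x_hat + beta

    def backward(self, grad):
        gamma = self._expand(self.params["gamma"], self._ndim)
        x_hat, inv_sd = self._x_hat, self._inv_sd
        axes = self._axes
        self.grads["gamma"] = (grad * x_hat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * gamma
        if not self._training:
            # eval mode: running stats are constants, BN is an affine map
            return g * self._expand(inv_sd, self._ndim)
        m = np.prod([grad.shape[a] for a in axes])
        dxhat_sum = g.sum(axis=axes, keepdims=True)
        dxhat_xhat_sum = (g * x_hat).sum(axis=axes, keepdims=True)
        return (g - dxhat_sum / m - x_hat * dxhat_xhat_sum / m) * self._expand(
            inv_sd, self._ndim
        )


class ReLU(Layer):
    def forward(self, x, training, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class AvgPool1d(Layer):
    """Non-overlapping average pooling (stride = kernel); trailing remainder dropped."""

    def __init__(self, kernel: int = 2) -> None:
        super().__init__()
        self.kernel = kernel

    def out_shape(self, in_shape):
        c, l = in_shape
        l_out = l // self.kernel
        if l_out < 1:
            raise ArchitectureError(f"avgpool(k={self.kernel}) underflows at length {l}")
        return (c, l_out)

    def forward(self, x, training, rng):
        n, c, l = x.shape
        l_out = l // self.kernel
        if l_out < 1:
            raise ArchitectureError(f"avgpool(k={self.kernel}) underflows at length {l}")
        self._in_len = l
        return x[:, :, : l_out * self.kernel].reshape(n, c, l_out, self.kernel).mean(axis=3)

    def backward(self, grad):
        n, c, l_out = grad.shape
        dx = np.zeros((n, c, self._in_len), dtype=grad.dtype)
        expanded = np.repeat(grad / self.kernel, self.kernel, axis=2)
        dx[:, :, : l_out * self.kernel] = expanded
        return dx


class GlobalAvgPool1d(Layer):
    """Mean over the length axis: (n, c, l) -> (n, c), band-count independent."""

    def out_shape(self, in_shape):
        return (in_shape[0],)

    def forward(self, x, training, rng):
        self._in_len = x.shape[2]
        return x.mean(axis=2)

    def backward(self, grad):
        return np.repeat(grad[:, :, None], self._in_len, axis=2) / self._in_len


class Flatten(Layer):
    def out_shape(self, in_shape):
        return (int(np.prod(in_shape)),)

    def forward(self, x, training, rng):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.params["W"] = xavier_uniform((out_features, in_features),
                                          in_features, out_features, rng)
        self.params["b"] = np.zeros(out_features, dtype=DTYPE)

    def out_shape(self, in_shape):
        if in_shape != (self.in_features,):
            raise ArchitectureError(
                f"linear expected {self.in_features} features, got {in_shape}")
        return (self.out_features,)

    def forward(self, x, training, rng):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = grad.T @ self._x
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"]


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training, rng):
        if not training or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.p).astype(x.dtype) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Sequential(Layer):
    """A chain of layers; also the container used for whole networks."""

    def __init__(self, layers: list[Layer]) -> None:
        super().__init__()
        self.layers = layers

    def out_shape(self, in_shape):
        for layer in self.layers:
            in_shape = layer.out_shape(in_shape)
        return in_shape

    def forward(self, x, training, rng):
        for layer in self.layers:
            x = layer.forward(x, training, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def parameters(self):
        """Yield (layer, name) pairs for every trainable tensor."""
        for layer in self.layers:
            if isinstance(layer, (Sequential, ResidualBlock)):
                yield from layer.parameters()
            else:
                for name in layer.params:
                    yield layer, name

    def modules(self):
        """Yield every leaf layer, descending into blocks."""
        for layer in self.layers:
            if isinstance(layer, Sequential):
                yield from layer.modules()
            elif isinstance(layer, ResidualBlock):
                yield from layer._sublayers()
            else:
                yield layer

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self.layers)


class ResidualBlock(Layer):
    """Basic two-convolution residual block with an identity or projected skip.

    Main path: conv(k)+BN+ReLU -> conv(k)+BN; the skip carries the input
    directly when channel counts match, otherwise through a kernel-1
    convolution plus BN. The sum passes a final ReLU.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 padding: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv1d(in_channels, out_channels, kernel, padding, rng)
        self.bn1 = BatchNorm(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, kernel, padding, rng)
        self.bn2 = BatchNorm(out_channels)
        self.relu_out = ReLU()
        if in_channels != out_channels:
            self.skip_conv = Conv1d(in_channels, out_channels, 1, 0, rng)
            self.skip_bn = BatchNorm(out_channels)
        else:
            self.skip_conv = None
            self.skip_bn = None

    def _sublayers(self):
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2, self.relu_out]
        if self.skip_conv is not None:
            subs += [self.skip_conv, self.skip_bn]
        return subs

    def out_shape(self, in_shape):
        shape = self.conv1.out_shape(in_shape)
        shape = self.conv2.out_shape(shape)
        if self.skip_conv is not None:
            skip_shape = self.skip_conv.out_shape(in_shape)
        else:
            skip_shape = in_shape
        if shape != skip_shape:
            raise ArchitectureError(
                f"residual shapes disagree: main {shape} vs skip {skip_shape}")
        return shape

    def forward(self, x, training, rng):
        main = self.conv1.forward(x, training, rng)
        main = self.bn1.forward(main, training, rng)
        main = self.relu1.forward(main, training, rng)
        main = self.conv2.forward(main, training, rng)
        main = self.bn2.forward(main, training, rng)
        if self.skip_conv is not None:
            skip = self.skip_conv.forward(x, training, rng)
            skip = self.skip_bn.forward(skip, training, rng)
        else:
            skip = x
        return self.relu_out.forward(main + skip, training, rng)

    def backward(self, grad):
        grad = self.relu_out.backward(grad)
        g_main = self.bn2.backward(grad)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.bn1.backward(g_main)
        g_main = self.conv1.backward(g_main)
        if self.skip_conv is not None:
            g_skip = self.skip_bn.backward(grad)
            g_skip = self.skip_conv.backward(g_skip)
        else:
            g_skip = grad
        return g_main + g_skip

    def parameters(self):
        for layer in self._sublayers():
            for name in layer.params:
                yield layer, name

    def param_count(self) -> int:
        return sum(layer.param_count() for layer in self._sublayers())
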