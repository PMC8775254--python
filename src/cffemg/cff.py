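"""Analytical core of the concatenate-feature-fusion (CFF) strategy.

Dimensionality reduction in a CNN front end is usually done either by
max-pooling or by a strided convolution, and each discards information in its
own way:

* max-pooling is a parameter-free, featurewise amplitude detector — it is
  invariant to any reordering of the samples inside a pooling window, so
  temporal order within the window is lost;
* a strided convolution mixes features through a learned weighted sum — it
  retains context, but distinct inputs can produce identical outputs (a
  collision), e.g. the kernel ``(-1, 1, 2)`` maps both ``(1, 1, 1)`` and
  ``(3, 1, 2)`` to 2.

The CFF block runs both reducers in parallel on the same map and concatenates
them channelwise, so two inputs that collide under one branch are still told
apart by the other.  This module implements the operators in plain numpy so
every claim (invariance, collisions, receptive field, discrimination) can be
checked directly; the trainable counterparts live in :mod:`cffemg.models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ShapeError(ValueError):
    pass


@dataclass
class PoolConfig:
    """Max-pooling geometry: window ``size`` and step ``stride`` (usually equal)."""

    size: int = 2
    stride: int = 2

    def __post_init__(self):
        if self.size < 1 or self.stride < 1:
            raise ValueError("pool size and stride must be >= 1")


@dataclass
class ConvConfig:
    """A 1-D convolution: ``kernel`` of length k (or (F, k) for F filters),
    ``stride``, ``padding`` ('valid' or 'same'), optional ``bias``."""

    kernel: np.ndarray
    stride: int = 1
    padding: str = "valid"
    bias: float | None = None

    def __post_init__(self):
        self.kernel = np.atleast_1d(np.asarray(self.kernel, dtype=float))
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError("padding must be 'valid' or 'same'")

    @property
    def k(self) -> int:
        return self.kernel.shape[-1]


def max_pool(x: np.ndarray, cfg: PoolConfig = PoolConfig()) -> np.ndarray:
    """Featurewise max-pooling along the first axis.

    ``z_t = max(y_t, ..., y_{t+size-1})`` stepping by ``stride``; the output
    length is ``floor((L - size)/stride) + 1``.  No trainable parameters.
    Accepts ``(L,)`` or ``(L, C)`` input.
    """
    x = np.asarray(x, dtype=float)
    L = x.shape[0]
    if L < cfg.size:
        raise ShapeError(f"input length {L} shorter than pool window {cfg.size}")
    n_out = (L - cfg.size) // cfg.stride + 1
    return np.stack(
        [x[t * cfg.stride : t * cfg.stride + cfg.size].max(axis=0) for t in range(n_out)]
    )


def _pad_same(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    L = x.shape[0]
    n_out = -(-L // stride)  # ceil
    total = max((n_out - 1) * stride + k - L, 0)
    before = total // 2
    pad = [(before, total - before)] + [(0, 0)] * (x.ndim - 1)
    return np.pad(x, pad)


def strided_conv(x: np.ndarray, cfg: ConvConfig) -> np.ndarray:
    """Single-channel strided convolution ``y_t = sum_j c_j x_{s(t-1)+j}``.

    Pre-activation and biasless by default, matching the analytical setting.
    Output length: ``floor((L - k)/s) + 1`` (valid) or ``ceil(L/s)`` (same,
    zero-padded).  A ``(F, k)`` kernel applies F filters, giving ``(n_out, F)``.
    """
    x = np.asarray(x, dtype=float)
    kernels = np.atleast_2d(cfg.kernel)  # (F, k)
    k, s = cfg.k, cfg.stride
    if cfg.padding == "same":
        x = _pad_same(x, k, s)
    L = x.shape[0]
    if L < k:
        raise ShapeError(f"input length {L} shorter than kernel {k}")
    n_out = (L - k) // s + 1
    windows = np.stack([x[t * s : t * s + k] for t in range(n_out)])  # (n_out, k)
    y = windows @ kernels.T
    if cfg.bias is not None:
        y = y + cfg.bias
    return y[:, 0] if cfg.kernel.ndim == 1 else y


def find_collision(cfg: ConvConfig, x: np.ndarray, delta: float = 2.0):
    """Construct ``x' != x`` with the same single-step convolution output.

    Distinct inputs map to equal outputs whenever the kernel has a nontrivial
    null space: with two nonzero weights ``c_i, c_j`` mass is transferred
    between coordinates (``x'_i = x_i + delta``, ``x'_j = x_j - delta*c_i/c_j``);
    a zero-weight coordinate can be perturbed freely.  Returns ``x'`` or
    ``None`` when the kernel is injective (k == 1 with a nonzero weight).

    Raises ``ValueError`` for the all-zero kernel, where every input collides
    trivially.
    """
    c = np.atleast_1d(np.asarray(cfg.kernel, dtype=float))
    if c.ndim != 1:
        raise ValueError("collision construction expects a single (k,) kernel")
    x = np.asarray(x, dtype=float)
    if x.shape != c.shape:
        raise ShapeError(f"input shape {x.shape} does not match kernel shape {c.shape}")
    nz = np.flatnonzero(c)
    if nz.size == 0:
        raise ValueError("degenerate all-zero kernel: every input collides")
    if c.size == 1:
        return None  # scalar multiplication is injective
    x2 = x.copy()
    zero = np.flatnonzero(c == 0)
    if zero.size:
        x2[zero[0]] += delta
        return x2
    i, j = nz[0], nz[-1]
    x2[i] += delta
    x2[j] -= delta * c[i] / c[j]
    return x2


def receptive_field(n: int, k: int) -> int:
    """Input positions seen by one output of ``n`` stacked 1-stride, valid,
    kernel-``k`` convolutions: ``n*(k-1) + 1``."""
    if n < 1 or k < 1:
        raise ValueError("need n >= 1 and k >= 1")
    return n * (k - 1) + 1


def receptive_field_bruteforce(n: int, k: int, rng=None) -> int:
    """Count by direct sensitivity analysis: perturb each input position of a
    random ``n``-layer 1-stride valid conv stack and count positions that move
    the first output element.  Independent check of :func:`receptive_field`.
    """
    rng = np.random.default_rng(rng)
    L = n * (k - 1) + k + 3  # long enough for every layer plus slack
    kernels = [rng.uniform(0.5, 1.5, size=k) for _ in range(n)]

    def stack(x):
        for ker in kernels:
            x = strided_conv(x, ConvConfig(kernel=ker, stride=1, padding="valid"))
        return x[0]

    x0 = rng.normal(size=L)
    y0 = stack(x0)
    sensitive = 0
    for i in range(L):
        x1 = x0.copy()
        x1[i] += 1.0
        if not np.isclose(stack(x1), y0):
            sensitive += 1
    return sensitive


@dataclass
class CffBlockConfig:
    """The fusion block: a parameter-free pool branch in parallel with a
    learned stride-2 convolution branch, channel-concatenated (pool first)."""

    pool: PoolConfig = field(default_factory=PoolConfig)
    conv: ConvConfig | None = None  # kernel (F, k) or (k,); stride must equal pool stride


def _ceil_pool(x: np.ndarray, size: int, stride: int) -> np.ndarray:
    """Max-pool emitting ceil(L/stride) outputs: the final window is truncated
    at the edge rather than dropped, so pool and same-padded conv branches of a
    fusion block always agree in spatial extent."""
    L = x.shape[0]
    n_out = -(-L // stride)
    return np.stack(
        [x[t * stride : min(t * stride + size, L)].max(axis=0) for t in range(n_out)]
    )


def cff_block(x: np.ndarray, cfg: CffBlockConfig) -> np.ndarray:
    """Apply pool and stride-2 conv branches in parallel and concatenate.

    ``x`` is ``(L,)`` or ``(L, C)``; output is ``(ceil(L/2), C + F)`` with the
    pool-branch channels first.  The two branch outputs must agree in spatial
    extent (asserted; the conv branch uses same padding to guarantee it).
    """
    x = np.asarray(x, dtype=float)
    if cfg.conv is None:
        raise ValueError("CffBlockConfig.conv must be provided")
    x2 = x[:, None] if x.ndim == 1 else x
    pooled = _ceil_pool(x2, cfg.pool.size, cfg.pool.stride)
    kernel = np.asarray(cfg.conv.kernel, dtype=float)
    C = x2.shape[1]
    if kernel.ndim == 1:  # (k,) -> one filter per channel, depthwise
        kernel = np.broadcast_to(kernel, (C, 1, kernel.size)).transpose(1, 2, 0)
    elif kernel.ndim == 2:  # (F, k) -> filters applied to a 1-channel input
        if C != 1:
            raise ShapeError("(F, k) kernel needs single-channel input")
        kernel = kernel[:, :, None]
    # kernel is now (F, k, C): standard channel-mixing filters
    F, k, Ck = kernel.shape
    if Ck != C:
        raise ShapeError(f"kernel expects {Ck} channels, input has {C}")
    s = cfg.conv.stride
    xp = _pad_same(x2, k, s)
    n_out = -(-x2.shape[0] // s)
    windows = np.stack([xp[t * s : t * s + k] for t in range(n_out)])  # (n_out, k, C)
    conved = np.einsum("tkc,fkc->tf", windows, kernel)
    if cfg.conv.bias is not None:
        conved = conved + cfg.conv.bias
    if pooled.shape[0] != conved.shape[0]:
        raise ShapeError(
            f"branch shape mismatch: pool {pooled.shape} vs conv {conved.shape}"
        )
    return np.concatenate([pooled, conved], axis=1)
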