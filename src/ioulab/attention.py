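"""Multi-Dimensional Attention (MDA): a parameter-light attention operator.

MDA refines a C×H×W feature map in two stages:

1. **Channel stage** — global average pooling over the spatial axes gives a
   length-C descriptor; a same-length 1-D convolution (zero padding, no bias)
   mixes neighbouring channels; a sigmoid turns the result into per-channel
   weights in (0, 1) that rescale the input. The kernel size adapts to the
   channel count through the standard efficient-channel-attention rule
   ``k = nearest_odd(log2(C)/γ + b/γ)`` with γ = 2, b = 1.
2. **Directional stage** — the refined map is average-pooled over (channel,
   height) to a length-W width descriptor and over (channel, width) to a
   length-H height descriptor; both pass through a sigmoid and multiply the
   refined map broadcast along their axis. This stage has zero parameters.

The whole operator therefore learns exactly ``k`` scalars (the convolution
kernel), versus the ``2C²/r`` of a squeeze-excitation block. With the kernel
initialized to zeros the untrained operator is a benign contraction (the
channel stage halves the map; the directional weights lie in (0, 1)).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import correlate1d

__all__ = [
    "MDAParams",
    "MDA",
    "adaptive_kernel_size",
    "channel_attention_stage",
    "directional_attention_stage",
    "mda_forward",
    "parameter_count",
    "selftest",
]


def adaptive_kernel_size(C: int, gamma: float = 2.0, b: float = 1.0) -> int:
    """Odd 1-D kernel size adapted to the channel count.

    Nearest odd integer to ``log2(C)/gamma + b/gamma``, at least 1; exact
    ties between adjacent odd integers resolve downward.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    t = math.log2(C) / gamma + b / gamma
    lower = max(1, 2 * math.floor((t - 1) / 2) + 1)  # greatest odd <= t (floor to odd)
    upper = lower + 2
    k = lower if (t - lower) <= (upper - t) else upper
    return max(1, k)


@dataclass
class MDAParams:
    """The operator's learned state: one odd-length kernel, no bias."""

    kernel: np.ndarray
    gamma: float = 2.0
    b: float = 1.0

    def __post_init__(self):
        self.kernel = np.asarray(self.kernel, dtype=float).ravel()
        if self.kernel.size % 2 == 0:
            raise ValueError("kernel size must be odd")

    @property
    def k(self) -> int:
        return self.kernel.size

    @classmethod
    def for_channels(cls, C: int, gamma: float = 2.0, b: float = 1.0,
                     init: str = "zeros", seed: int | None = None) -> "MDAParams":
        k = adaptive_kernel_size(C, gamma, b)
        if init == "zeros":
            kernel = np.zeros(k)
        elif init == "random":
            kernel = np.random.default_rng(seed).normal(0.0, 1.0 / math.sqrt(k), k)
        else:
            raise ValueError("init must be 'zeros' or 'random'")
        return cls(kernel, gamma, b)

    def to_json(self) -> str:
        return json.dumps(
            {"kernel": self.kernel.tolist(), "gamma": self.gamma, "b": self.b}
        )

    @classmethod
    def from_json(cls, text: str) -> "MDAParams":
        d = json.loads(text)
        return cls(np.asarray(d["kernel"]), float(d["gamma"]), float(d["b"]))


def parameter_count(params: MDAParams) -> int:
    """Number of learned scalars: the kernel length k, nothing else."""
    return params.k


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _check_input(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 3:
        raise ValueError(f"expected a C×H×W array, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValueError("feature map contains non-finite entries")
    return x


def channel_attention_stage(x, params: MDAParams) -> np.ndarray:
    """Per-channel reweighting via spatial pooling + 1-D convolution.

    Spatial mean → (C,) vector; same-length zero-padded convolution across
    the channel axis; sigmoid; input scaled per channel. Shape-preserving.
    """
    x = _check_input(x)
    pooled = x.mean(axis=(1, 2))
    mixed = correlate1d(pooled, params.kernel, mode="constant", cval=0.0)
    weights = _sigmoid(mixed)
    return x * weights[:, None, None]


def directional_attention_stage(refined) -> np.ndarray:
    """Width- and height-direction reweighting of the refined map.

    The length-W and length-H directional means are sigmoid-squashed and both
    applied multiplicatively (in parallel) to the refined map. Zero
    parameters.
    """
    refined = _check_input(refined)
    w_vec = refined.mean(axis=(0, 1))  # (W,)
    h_vec = refined.mean(axis=(0, 2))  # (H,)
    return refined * _sigmoid(w_vec)[None, None, :] * _sigmoid(h_vec)[None, :, None]


def mda_forward(x, params: MDAParams) -> np.ndarray:
    """Full operator: channel stage followed by the directional stage."""
    return directional_attention_stage(channel_attention_stage(x, params))


class MDA:
    """Callable MDA operator bound to a channel count.

    >>> op = MDA(channels=64)
    >>> y = op(np.random.default_rng(0).normal(size=(64, 8, 8)))
    """

    def __init__(self, channels: int | None = None, params: MDAParams | None = None,
                 gamma: float = 2.0, b: float = 1.0, init: str = "zeros",
                 seed: int | None = None):
        if params is None:
            if channels is None:
                raise ValueError("provide either channels or params")
            params = MDAParams.for_channels(channels, gamma, b, init=init, seed=seed)
        self.params = params

    @property
    def n_parameters(self) -> int:
        return parameter_count(self.params)

    def __call__(self, x) -> np.ndarray:
        return mda_forward(x, self.params)


def selftest(shape=(64, 80, 80), seed: int = 0, init: str = "random") -> dict:
    """Run the operator's invariants on a random map; returns a report dict."""
    C, H, W = shape
    rng = np.random.default_rng(seed)
    x = rng.normal(size=(C, H, W))
    params = MDAParams.for_channels(C, init=init, seed=seed)
    refined = channel_attention_stage(x, params)
    y = directional_attention_stage(refined)
    report = {
        "shape": list(shape),
        "kernel_size": params.k,
        "parameter_count": parameter_count(params),
        "shape_preserved": y.shape == x.shape,
        "finite": bool(np.all(np.isfinite(y))),
        "contractive_vs_input": bool(np.all(np.abs(y) <= np.abs(x) + 1e-12)),
        "contractive_vs_refined": bool(np.all(np.abs(y) <= np.abs(refined) + 1e-12)),
        "sign_preserved": bool(np.all(np.sign(y) == np.sign(x))),
        "max_abs_output": float(np.abs(y).max()),
    }
    report["ok"] = all(
        report[k] for k in
        ("shape_preserved", "finite", "contractive_vs_input",
         "contractive_vs_refined", "sign_preserved")
    )
    return report
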