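"""The IoU metric family for bounding-box regression, including S-MPDIoU.

Eight metrics are implemented — IoU, GIoU, DIoU, CIoU, EIoU, SIoU, MPDIoU and
S-MPDIoU — each as a similarity ``m ∈ (-inf, 1]`` (1 iff the boxes coincide)
and as a loss ``1 - m`` with a differentiable contract against the four
predicted-box parameters ``(x_c, y_c, w, h)``.

S-MPDIoU refines MPDIoU in two ways. MPDIoU penalizes the squared distances
``d1², d2²`` between matching top-left / bottom-right corners, normalized by
the squared feature-map diagonal ``W² + H²``. S-MPDIoU instead normalizes by
an angle-dependent baseline ``C``: with ``α = atan2(C_h, C_w)`` the angle of
the center-to-center segment, the baseline is the chord of the map crossed at
that angle (``C² = W²(1 + tan²α)`` for ``α < π/4``, ``C² = H²(1 + cot²α)``
otherwise), so a nearer ground truth is measured against a shorter baseline
and keeps contributing gradient. Second, the penalty is multiplied by a scale
factor ``log2(input_ref / W)`` — a constant per detection head that
counteracts the sharp gradient shrink-off when the boxes are close but not
yet overlapping. The scale factor is a plain constant: no gradient flows
through it, nor through the α-branch selection.

All metric *values* are symmetric in the two boxes; gradients are taken with
respect to the *predicted* box only. Gradients are computed with the
forward-mode autodiff in :mod:`ioulab._dual` and are exact almost everywhere;
at an exactly identical pair (the kinked minimum of every loss) the zero
subgradient is returned.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from . import _dual as D
from .boxes import Box, FeatureMapGeometry, iou

__all__ = [
    "LOSS_NAMES",
    "LossSpec",
    "giou",
    "diou",
    "ciou",
    "eiou",
    "siou",
    "mpdiou",
    "smpdiou",
    "smpdiou_alpha",
    "smpdiou_baseline",
    "scale_factor",
    "metric",
    "metric_values",
    "loss_and_gradient",
    "loss_and_gradient_batch",
]

LOSS_NAMES = ("iou", "giou", "diou", "ciou", "eiou", "siou", "mpdiou", "smpdiou")

#: losses whose definition involves the feature-map frame
_NEEDS_GEOMETRY = ("mpdiou", "smpdiou")

_SIOU_THETA = 4.0  # shape-cost exponent of the SIoU reference formulation


@dataclass(frozen=True)
class LossSpec:
    """A named loss plus the feature-map geometry it may require.

    ``scale_in_gradient`` is fixed False: the S-MPDIoU scale factor is a
    constant multiplier excluded from gradient computation (which is also the
    only self-consistent reading, since it does not depend on the boxes).
    """

    name: str
    geometry: Optional[FeatureMapGeometry] = None
    scale_in_gradient: bool = field(default=False)

    def __post_init__(self):
        if self.name not in LOSS_NAMES:
            raise ValueError(f"unknown loss {self.name!r}; expected one of {LOSS_NAMES}")
        if self.scale_in_gradient:
            raise ValueError("scale_in_gradient is fixed False")
        if self.name in _NEEDS_GEOMETRY and self.geometry is None:
            raise ValueError(f"{self.name} requires a FeatureMapGeometry")

    def to_dict(self) -> dict:
        d = {"name": self.name, "scale_in_gradient": self.scale_in_gradient}
        if self.geometry is not None:
            d["geometry"] = self.geometry.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "LossSpec":
        geom = d.get("geometry")
        return cls(
            name=d["name"],
            geometry=FeatureMapGeometry.from_dict(geom) if geom else None,
            scale_in_gradient=bool(d.get("scale_in_gradient", False)),
        )

    @classmethod
    def from_config(cls, path) -> "LossSpec":
        """Load from a YAML or JSON config file mirroring the LossSpec fields."""
        with open(path) as fh:
            text = fh.read()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        return cls.from_dict(data)


def scale_factor(geometry: FeatureMapGeometry) -> float:
    """``log2(downsample)`` with ``downsample = input_ref / W``.

    E.g. a 640-pixel input on an 80×80 map gives downsample 8 and scale 3.
    """
    ds = geometry.downsample
    if ds < 1:
        raise ValueError(
            f"downsample {ds} < 1: feature map wider than the reference input"
        )
    return math.log2(ds)


def smpdiou_alpha(a: Box, b: Box) -> float:
    """Angle of the center-to-center segment, in ``[0, π/2]``.

    Computed as ``atan2(C_h, C_w)`` so a vertical alignment gives exactly
    π/2. Coincident centers are the degenerate case and return ``nan`` as a
    flag; :func:`smpdiou_baseline` maps it to the full map diagonal.
    """
    c_w = abs(a.x_c - b.x_c)
    c_h = abs(a.y_c - b.y_c)
    if c_w == 0 and c_h == 0:
        return math.nan
    return math.atan2(c_h, c_w)


def smpdiou_baseline(alpha: float, geometry: FeatureMapGeometry) -> float:
    """Angle-dependent baseline length ``C``.

    ``α < π/4``: the segment exits through the vertical map edge, so
    ``w1 = W, h1 = W·tanα``. ``α ≥ π/4`` (the boundary is assigned to this
    branch): ``w1 = H/tanα, h1 = H``. The degenerate coincident-center flag
    (nan) falls back to the full diagonal ``sqrt(W² + H²)``, the continuous
    limit along α = π/4 on square maps.
    """
    W, H = geometry.W, geometry.H
    if math.isnan(alpha):
        return math.sqrt(W * W + H * H)
    if not 0 <= alpha <= math.pi / 2:
        raise ValueError(f"alpha must lie in [0, pi/2], got {alpha}")
    if alpha < math.pi / 4:
        w1, h1 = W, W * math.tan(alpha)
    else:
        t = math.tan(alpha)
        w1 = 0.0 if math.isinf(t) or alpha == math.pi / 2 else H / t
        h1 = H
    return math.hypot(w1, h1)


# -------------------------------------------------------------------------
# vectorized metric core (works on plain arrays or dual numbers for pred)
# -------------------------------------------------------------------------

def _core(name, px, py, pw, ph, gx, gy, gw, gh, geom, baseline, scale,
          ciou_alpha=None):
    px1, py1 = px - pw * 0.5, py - ph * 0.5
    px2, py2 = px + pw * 0.5, py + ph * 0.5
    gx1, gy1 = gx - gw * 0.5, gy - gh * 0.5
    gx2, gy2 = gx + gw * 0.5, gy + gh * 0.5

    iw = D.maximum(D.minimum(px2, gx2) - D.maximum(px1, gx1), 0.0)
    ih = D.maximum(D.minimum(py2, gy2) - D.maximum(py1, gy1), 0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    iou_ = inter / union
    if name == "iou":
        return iou_

    # enclosing box
    cw = D.maximum(px2, gx2) - D.minimum(px1, gx1)
    ch = D.maximum(py2, gy2) - D.minimum(py1, gy1)

    if name == "giou":
        ac = cw * ch
        return iou_ - (ac - union) / ac

    if name in ("diou", "ciou", "eiou"):
        rho2 = (px - gx) ** 2 + (py - gy) ** 2
        c2 = cw ** 2 + ch ** 2
        diou_ = iou_ - rho2 / c2
        if name == "diou":
            return diou_
        if name == "eiou":
            return diou_ - (pw - gw) ** 2 / cw ** 2 - (ph - gh) ** 2 / ch ** 2
        # CIoU aspect-consistency term; its trade-off weight is evaluated
        # with the current IoU and treated as constant during differentiation
        v_ = (4.0 / math.pi ** 2) * (D.arctan(gw / gh) - D.arctan(pw / ph)) ** 2
        if ciou_alpha is None:
            v_val, iou_val = D.value(v_), D.value(iou_)
            denom = 1.0 - iou_val + v_val
            alpha_t = np.where(denom > 0, v_val / np.where(denom > 0, denom, 1.0), 0.0)
        else:
            alpha_t = np.asarray(ciou_alpha, dtype=float)
        return diou_ - alpha_t * v_

    if name == "siou":
        # angle, distance and shape costs per the SIoU reference formulation
        s_cw, s_ch = px - gx, py - gy
        sigma = D.sqrt(s_cw ** 2 + s_ch ** 2)
        degen = D.value(sigma) == 0
        sig_safe = D.where(degen, 1.0, sigma)
        sa1 = D.absolute(s_cw) / sig_safe
        sa2 = D.absolute(s_ch) / sig_safe
        sin_a = D.where(D.value(sa1) > math.sqrt(2) / 2, sa2, sa1)
        angle_cost = 2.0 * sin_a * D.sqrt(D.maximum(1.0 - sin_a ** 2, 0.0))
        gamma = angle_cost - 2.0
        rho_x = (s_cw / cw) ** 2
        rho_y = (s_ch / ch) ** 2
        distance_cost = 2.0 - D.exp(gamma * rho_x) - D.exp(gamma * rho_y)
        om_w = D.absolute(pw - gw) / D.maximum(pw, gw)
        om_h = D.absolute(ph - gh) / D.maximum(ph, gh)
        shape_cost = (1.0 - D.exp(-om_w)) ** _SIOU_THETA + (1.0 - D.exp(-om_h)) ** _SIOU_THETA
        return iou_ - (distance_cost + shape_cost) * 0.5

    if name in ("mpdiou", "smpdiou"):
        if geom is None:
            raise ValueError(f"{name} requires a FeatureMapGeometry")
        d1sq = (px1 - gx1) ** 2 + (py1 - gy1) ** 2
        d2sq = (px2 - gx2) ** 2 + (py2 - gy2) ** 2
        if name == "mpdiou":
            return iou_ - (d1sq + d2sq) * (1.0 / geom.diagonal_sq)
        # S-MPDIoU
        s = scale_factor(geom) if scale is None else float(scale)
        W2, H2, diag2 = geom.W ** 2, geom.H ** 2, geom.diagonal_sq
        if baseline == "diagonal":
            c2 = diag2
            return iou_ - s * ((d1sq + d2sq) / c2)
        elif baseline != "angle":
            raise ValueError("baseline must be 'angle' or 'diagonal'")
        c_w = D.absolute(px - gx)
        c_h = D.absolute(py - gy)
        v_cw, v_ch = D.value(c_w), D.value(c_h)
        degen = (v_cw == 0) & (v_ch == 0)
        b1 = v_ch < v_cw  # alpha < pi/4; boundary goes to the other branch
        r1 = c_h / D.where(b1, c_w, 1.0)  # tan(alpha) on branch 1
        c2_low = W2 * (1.0 + r1 ** 2)
        b2 = (~b1) & (~degen)
        r2 = c_w / D.where(b2, c_h, 1.0)  # cot(alpha) on branch 2
        c2_high = H2 * (1.0 + r2 ** 2)
        c2 = D.where(b1, c2_low, D.where(degen, diag2, c2_high))
        return iou_ - s * ((d1sq + d2sq) / c2)

    raise ValueError(f"unknown loss {name!r}")


def _split(arr):
    arr = np.asarray(arr, dtype=float)
    return arr[..., 0], arr[..., 1], arr[..., 2], arr[..., 3]


def metric_values(name, pred, gt, geometry=None, *, baseline="angle", scale=None,
                  ciou_alpha=None):
    """Vectorized metric over ``(..., 4)`` center/size arrays.

    ``ciou_alpha`` optionally pins CIoU's trade-off weight to a fixed value;
    finite-difference checks of the (alpha-frozen) CIoU gradient use it.
    """
    gx, gy, gw, gh = _split(gt)
    px, py, pw, ph = _split(pred)
    return _core(name, px, py, pw, ph, gx, gy, gw, gh, geometry, baseline, scale,
                 ciou_alpha)


def metric(name, a: Box, b: Box, geometry=None, *, baseline="angle", scale=None) -> float:
    """Scalar metric for a pair of boxes (symmetric in its arguments)."""
    return float(
        metric_values(name, a.as_array(), b.as_array(), geometry,
                      baseline=baseline, scale=scale)
    )


def giou(a: Box, b: Box) -> float:
    """IoU minus the enclosing-box slack ratio; range (-1, 1]."""
    return metric("giou", a, b)


def diou(a: Box, b: Box) -> float:
    """IoU minus squared center distance over squared enclosing diagonal."""
    return metric("diou", a, b)


def ciou(a: Box, b: Box) -> float:
    """DIoU minus the weighted aspect-ratio consistency penalty."""
    return metric("ciou", a, b)


def eiou(a: Box, b: Box) -> float:
    """DIoU minus normalized squared width and height gaps."""
    return metric("eiou", a, b)


def siou(a: Box, b: Box) -> float:
    """IoU minus half the sum of the angle-modulated distance and shape costs."""
    return metric("siou", a, b)


def mpdiou(a: Box, b: Box, geometry: FeatureMapGeometry) -> float:
    """IoU minus both squared corner distances over the squared map diagonal."""
    return metric("mpdiou", a, b, geometry)


def smpdiou(a: Box, b: Box, geometry: FeatureMapGeometry, *,
            baseline="angle", scale=None) -> float:
    """IoU minus scale × both squared corner distances over the baseline C².

    ``baseline='diagonal'`` together with ``scale=1`` reduces exactly to
    MPDIoU (a testing hook for the equivalence contract).
    """
    return metric("smpdiou", a, b, geometry, baseline=baseline, scale=scale)


# -------------------------------------------------------------------------
# differentiable contract
# -------------------------------------------------------------------------

def loss_and_gradient_batch(spec: LossSpec, gt, pred, *, baseline="angle", scale=None):
    """Loss ``1 - m`` and its gradient w.r.t. the predicted parameters.

    ``gt`` and ``pred`` are ``(..., 4)`` center/size arrays; returns
    ``(loss, grad)`` with ``grad`` of shape ``(..., 4)``. At exactly identical
    pairs the zero subgradient of the kinked minimum is returned. A non-finite
    gradient at finite inputs signals an implementation fault and aborts.
    """
    gt = np.asarray(gt, dtype=float)
    pred = np.asarray(pred, dtype=float)
    gx, gy, gw, gh = _split(gt)
    px, py, pw, ph = D.Dual.seed(pred)
    with np.errstate(all="ignore"):  # finiteness is checked on the result
        m = _core(spec.name, px, py, pw, ph, gx, gy, gw, gh,
                  spec.geometry, baseline, scale)
    loss = 1.0 - m.v
    grad = -m.g
    identical = np.all(pred == np.broadcast_to(gt, pred.shape), axis=-1)
    if np.any(identical):
        loss = np.where(identical, 0.0, loss)
        grad = np.where(identical[..., None], 0.0, grad)
    if not (np.all(np.isfinite(loss)) and np.all(np.isfinite(grad))):
        raise FloatingPointError(
            f"non-finite loss/gradient in {spec.name} at finite inputs"
        )
    return loss, grad


def loss_and_gradient(spec: LossSpec, gt: Box, pred: Box):
    """Scalar convenience wrapper of :func:`loss_and_gradient_batch`."""
    loss, grad = loss_and_gradient_batch(spec, gt.as_array(), pred.as_array())
    return float(loss), grad


# re-export the plain IoU under the family's namespace for symmetry
iou = iou  # noqa: PLW0127 - intentional alias from boxes
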