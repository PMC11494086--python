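"""Gradient-descent box-regression simulator.

A population of (ground-truth box, initial predicted box) pairs is optimized
by plain gradient descent on the predicted box's four parameters
``(x_c, y_c, w, h)`` under a chosen IoU-family loss ``1 - m``. Convergence is
declared on the L1 parameter gap

    gap = |x_gt - x| + |y_gt - y| + |w_gt - w| + |h_gt - h|

(not on the training loss itself), at a fixed learning rate. Two canned
experiments are provided:

* :func:`experiment1` — three fixed configurations (horizontal / diagonal /
  vertical initial displacement) run to a tight threshold (0.01) with a
  100,000-epoch budget, reporting epochs-to-convergence per loss.
* :func:`experiment2` — a randomized population of cases on a 20×20 or 40×40
  feature map (centers uniform in the inscribed circle; 7 aspect ratios for
  both boxes, 7 area scales for the predicted box; unit-area ground truths),
  run to a loose threshold (0.5) for 10,000 epochs, reporting the per-epoch
  total gap curve per loss.

The update rule is plain per-case gradient descent (no momentum, no weight
decay): the minimal reading of a fixed learning rate. After each step, width
and height are clamped to a floor of 1e-4 so iterates remain valid boxes.
Converged cases are frozen by default — their parameters stop updating but
their residual gap still accumulates in the aggregate curve — which prevents
oscillation artifacts around the kinked loss minimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .boxes import Box, FeatureMapGeometry, boxes_to_array
from .losses import LOSS_NAMES, LossSpec, loss_and_gradient_batch, scale_factor

__all__ = [
    "SimConfig",
    "RegressionCase",
    "SimResult",
    "BoxRegression",
    "BoxRegressionResults",
    "l1_gap",
    "gd_step",
    "run_case",
    "experiment1",
    "experiment1_speedups",
    "generate_experiment2_cases",
    "experiment2",
    "EXP1_GEOMETRY",
    "EXP1_GT",
    "EXP1_PRED",
    "EXP2_ASPECT_RATIOS",
    "EXP2_AREA_SCALES",
]

_SIZE_FLOOR = 1e-4  # w/h clamp after each step; keeps Box invariants

# -- experiment 1 constants -------------------------------------------------
# The three-case setup: ground truth centered at [1, 1] with w = h = 0.5;
# predicted boxes of w = 1, h = 2 centered at [7, 1], [7, 7] and [1, 7].
# The canvas/scale convention for this experiment is a documented default
# (nothing pins it): a 10x10 map at reference input 640, hence scale
# log2(64) = 6; both are overridable.
EXP1_GT = Box(1.0, 1.0, 0.5, 0.5)
EXP1_PRED = {
    "horizontal": Box(7.0, 1.0, 1.0, 2.0),
    "diagonal": Box(7.0, 7.0, 1.0, 2.0),
    "vertical": Box(1.0, 7.0, 1.0, 2.0),
}
EXP1_GEOMETRY = FeatureMapGeometry(10.0, 10.0, 640.0)

# -- experiment 2 constants -------------------------------------------------
EXP2_ASPECT_RATIOS = (7.0, 4.0, 2.0, 1.0, 1 / 2, 1 / 4, 1 / 7)
EXP2_AREA_SCALES = (0.5, 0.67, 0.75, 1.0, 1.33, 1.5, 2.0)
EXP2_N_PRED_CENTERS = 50
EXP2_N_GT_CENTERS = 5


@dataclass(frozen=True)
class SimConfig:
    """Optimizer settings for one simulator run."""

    loss: LossSpec
    learning_rate: float = 0.02
    max_epochs: int = 10_000
    convergence_threshold: float = 0.5
    freeze_converged: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")
        if self.convergence_threshold <= 0:
            raise ValueError("convergence_threshold must be positive")

    def to_dict(self) -> dict:
        return {
            "loss": self.loss.to_dict(),
            "learning_rate": self.learning_rate,
            "max_epochs": self.max_epochs,
            "convergence_threshold": self.convergence_threshold,
            "freeze_converged": self.freeze_converged,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class RegressionCase:
    """One (ground truth, initial prediction) pair within a map frame."""

    gt: Box
    pred0: Box
    geometry: FeatureMapGeometry


def l1_gap(gt, pred):
    """Sum of absolute differences of the four box parameters.

    Accepts a pair of Boxes (returns a float) or ``(..., 4)`` arrays.
    """
    if isinstance(gt, Box):
        gt = gt.as_array()
    if isinstance(pred, Box):
        pred = pred.as_array()
    return np.abs(np.asarray(gt, float) - np.asarray(pred, float)).sum(axis=-1)


def gd_step(gt, pred, config: SimConfig):
    """One plain gradient-descent step on the predicted box parameters.

    ``θ ← θ - lr · ∇(1 - m)``, followed by clamping w and h to 1e-4.
    Accepts Boxes (returns a Box) or ``(..., 4)`` arrays.
    """
    as_box = isinstance(pred, Box)
    gt_arr = gt.as_array() if isinstance(gt, Box) else np.asarray(gt, float)
    pred_arr = pred.as_array() if as_box else np.asarray(pred, float)
    _, grad = loss_and_gradient_batch(config.loss, gt_arr, pred_arr)
    new = pred_arr - config.learning_rate * grad
    new[..., 2:] = np.maximum(new[..., 2:], _SIZE_FLOOR)
    if not np.all(np.isfinite(new)):
        raise FloatingPointError("gradient-descent step produced non-finite parameters")
    return Box(*new) if as_box else new


class BoxRegressionResults:
    """Results of a simulator run: convergence accounting plus loss curves.

    Attributes
    ----------
    converged_epoch : (n,) int array, -1 where a case never converged
    final_gap : (n,) array of final L1 parameter gaps
    final_params : (n, 4) array of final predicted parameters
    curve : (max_epochs + 1,) per-epoch total L1 gap over all cases
        (``curve[0]`` is the initial population gap)
    diverged : (n,) bool array of cases aborted on non-finite parameters
    trajectory : optional (epochs + 1, n, 4) parameter history
    """

    def __init__(self, config, converged_epoch, final_gap, final_params,
                 curve, diverged, trajectory=None):
        self.config = config
        self.converged_epoch = converged_epoch
        self.final_gap = final_gap
        self.final_params = final_params
        self.curve = curve
        self.diverged = diverged
        self.trajectory = trajectory

    @property
    def n_cases(self) -> int:
        return len(self.converged_epoch)

    @property
    def n_converged(self) -> int:
        return int(np.sum(self.converged_epoch >= 0))

    @property
    def fraction_converged(self) -> float:
        return self.n_converged / self.n_cases

    @property
    def final_total_gap(self) -> float:
        return float(self.final_gap.sum())

    def summary(self) -> str:
        conv = self.converged_epoch[self.converged_epoch >= 0]
        lines = [
            "Box regression (plain gradient descent)",
            "=" * 46,
            f"loss:                  {self.config.loss.name}",
            f"learning rate:         {self.config.learning_rate}",
            f"convergence threshold: {self.config.convergence_threshold} (L1 gap)",
            f"epoch budget:          {self.config.max_epochs}",
            f"cases:                 {self.n_cases}",
            f"converged:             {self.n_converged} "
            f"({100 * self.fraction_converged:.1f}%)",
            f"diverged:              {int(self.diverged.sum())}",
            f"final total L1 gap:    {self.final_total_gap:.6g}",
        ]
        if conv.size:
            lines.append(
                f"epochs to convergence: median {int(np.median(conv))}, "
                f"max {int(conv.max())}"
            )
        return "\n".join(lines)

    def plot_curve(self, ax=None, label=None, **kwargs):
        """Plot the per-epoch total L1 gap curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.curve, label=label or self.config.loss.name, **kwargs)
        ax.set_xlabel("epoch")
        ax.set_ylabel("total L1 gap")
        if label is not False:
            ax.legend()
        return ax


#: the simulator result type of the public API
SimResult = BoxRegressionResults


class BoxRegression:
    """Gradient-descent regression of predicted boxes onto ground truths.

    Parameters
    ----------
    gt, pred0 : ``(n, 4)`` center/size arrays (or lists of Boxes)
    config : SimConfig with the loss and optimizer settings
    """

    def __init__(self, gt, pred0, config: SimConfig):
        self.gt = self._coerce(gt)
        self.pred0 = self._coerce(pred0)
        if self.gt.shape != self.pred0.shape:
            raise ValueError("gt and pred0 must have matching shapes")
        self.config = config

    @staticmethod
    def _coerce(x):
        if isinstance(x, Box):
            x = [x]
        if len(x) and isinstance(x[0], Box):
            return boxes_to_array(x)
        return np.asarray(x, dtype=float).reshape(-1, 4)

    @classmethod
    def from_cases(cls, cases: Sequence[RegressionCase], config: SimConfig):
        gt = boxes_to_array([c.gt for c in cases])
        pred0 = boxes_to_array([c.pred0 for c in cases])
        return cls(gt, pred0, config)

    def fit(self, record_trajectory: bool = False) -> BoxRegressionResults:
        cfg = self.config
        params = self.pred0.copy()
        n = params.shape[0]
        conv = np.full(n, -1, dtype=np.int64)
        diverged = np.zeros(n, dtype=bool)
        curve = np.empty(cfg.max_epochs + 1)

        gap = l1_gap(self.gt, params)
        curve[0] = gap.sum()
        conv[gap < cfg.convergence_threshold] = 0
        traj = [params.copy()] if record_trajectory else None

        lr = cfg.learning_rate
        for epoch in range(1, cfg.max_epochs + 1):
            if cfg.freeze_converged:
                active = (conv < 0) & ~diverged
            else:
                active = ~diverged
            if not active.any():
                # population fully frozen: the curve is constant from here on
                curve[epoch:] = curve[epoch - 1]
                if record_trajectory:
                    traj.extend(traj[-1] for _ in range(cfg.max_epochs + 1 - epoch))
                break
            if active.all():
                _, grad = loss_and_gradient_batch(cfg.loss, self.gt, params)
                stepped = params - lr * grad
            else:
                _, grad = loss_and_gradient_batch(
                    cfg.loss, self.gt[active], params[active]
                )
                stepped = params.copy()
                stepped[active] = params[active] - lr * grad
            stepped[:, 2:] = np.maximum(stepped[:, 2:], _SIZE_FLOOR)
            bad = ~np.isfinite(stepped).all(axis=1)
            if bad.any():
                # abort the offending cases, keep their last finite state
                stepped[bad] = params[bad]
                diverged |= bad
            params = stepped
            gap = l1_gap(self.gt, params)
            curve[epoch] = gap.sum()
            newly = (conv < 0) & (gap < cfg.convergence_threshold) & ~diverged
            conv[newly] = epoch
            if record_trajectory:
                traj.append(params.copy())

        return BoxRegressionResults(
            config=cfg,
            converged_epoch=conv,
            final_gap=gap,
            final_params=params,
            curve=curve,
            diverged=diverged,
            trajectory=np.array(traj) if record_trajectory else None,
        )


def run_case(case: RegressionCase, config: SimConfig,
             record_trajectory: bool = False) -> BoxRegressionResults:
    """Run one RegressionCase to convergence (or budget exhaustion)."""
    return BoxRegression.from_cases([case], config).fit(record_trajectory)


# -------------------------------------------------------------------------
# experiment 1: three fixed configurations
# -------------------------------------------------------------------------

def _spec_for(name: str, geometry: FeatureMapGeometry) -> LossSpec:
    return LossSpec(name, geometry if name in ("mpdiou", "smpdiou") else None)


def experiment1(losses=LOSS_NAMES, *, learning_rate: float = 0.02,
                convergence_threshold: float = 0.01, max_epochs: int = 100_000,
                geometry: FeatureMapGeometry = EXP1_GEOMETRY) -> pd.DataFrame:
    """Epochs-to-convergence per loss for the three fixed configurations.

    Returns a DataFrame indexed by loss name with columns ``horizontal``,
    ``diagonal`` and ``vertical``; NaN marks a case that did not reach the
    threshold within the budget.
    """
    names = list(EXP1_PRED)
    gt = boxes_to_array([EXP1_GT] * len(names))
    pred0 = boxes_to_array([EXP1_PRED[k] for k in names])
    rows = {}
    for loss in losses:
        cfg = SimConfig(
            loss=_spec_for(loss, geometry),
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            convergence_threshold=convergence_threshold,
        )
        res = BoxRegression(gt, pred0, cfg).fit()
        rows[loss] = {
            k: (float(e) if e >= 0 else math.nan)
            for k, e in zip(names, res.converged_epoch)
        }
    return pd.DataFrame.from_dict(rows, orient="index")[names]


def experiment1_speedups(table: pd.DataFrame, reference: str = "mpdiou") -> pd.DataFrame:
    """Per-case epoch ratios ``epochs(reference) / epochs(loss)``.

    Values above 1 mean the row's loss converges faster than the reference.
    """
    if reference not in table.index:
        raise ValueError(f"reference loss {reference!r} not in the table")
    return table.loc[reference] / table


# -------------------------------------------------------------------------
# experiment 2: randomized case population
# -------------------------------------------------------------------------

def _aspect_box(cx, cy, area, ratio):
    w = math.sqrt(area * ratio)
    return Box(cx, cy, w, math.sqrt(area / ratio))


def _experiment2_arrays(map_size: float, seed: int):
    """Vectorized case population: returns (gt, pred0) ``(n, 4)`` arrays.

    Case order is the nested cross-product (pred center, pred aspect,
    pred area scale, gt center, gt aspect), reproducible from the seed.
    """
    rng = np.random.default_rng(seed)
    radius = map_size / 2.0
    center = np.array([radius, radius])

    def disk(n):
        r = radius * np.sqrt(rng.uniform(0, 1, n))
        theta = rng.uniform(0, 2 * np.pi, n)
        return center + np.c_[r * np.cos(theta), r * np.sin(theta)]

    pred_centers = disk(EXP2_N_PRED_CENTERS)
    gt_centers = disk(EXP2_N_GT_CENTERS)

    ratios = np.asarray(EXP2_ASPECT_RATIOS)
    scales = np.asarray(EXP2_AREA_SCALES)

    # broadcast the five factors to the full cross product
    pc, pr, ps, gc, gr = np.meshgrid(
        np.arange(EXP2_N_PRED_CENTERS), np.arange(len(ratios)),
        np.arange(len(scales)), np.arange(EXP2_N_GT_CENTERS),
        np.arange(len(ratios)), indexing="ij",
    )
    pc, pr, ps, gc, gr = (a.ravel() for a in (pc, pr, ps, gc, gr))

    gt_area = 1.0
    gt = np.empty((pc.size, 4))
    gt[:, 0:2] = gt_centers[gc]
    gt[:, 2] = np.sqrt(gt_area * ratios[gr])
    gt[:, 3] = np.sqrt(gt_area / ratios[gr])

    pred = np.empty((pc.size, 4))
    pred[:, 0:2] = pred_centers[pc]
    pred_area = scales[ps]
    pred[:, 2] = np.sqrt(pred_area * ratios[pr])
    pred[:, 3] = np.sqrt(pred_area / ratios[pr])

    return gt, pred


def generate_experiment2_cases(map_size: float, seed: int) -> list[RegressionCase]:
    """The full randomized case population as RegressionCase objects.

    Following the stated recipe — 50 predicted centers and 5 ground-truth
    centers uniform in the inscribed circle, 7 aspect ratios each, 7 predicted
    area scales — the cross product yields 50·7·7·5·7 = 85,750 cases.
    """
    if map_size not in (20, 40):
        raise ValueError("map_size must be 20 or 40")
    gt, pred = _experiment2_arrays(map_size, seed)
    geom = FeatureMapGeometry(float(map_size), float(map_size), 640.0)
    return [
        RegressionCase(Box(*g), Box(*p), geom) for g, p in zip(gt, pred)
    ]


def experiment2(losses=LOSS_NAMES, map_size: float = 40, *, seed: int = 0,
                learning_rate: float = 0.02, convergence_threshold: float = 0.5,
                max_epochs: int = 10_000,
                n_cases_override: Optional[int] = None) -> dict[str, BoxRegressionResults]:
    """Run the randomized population under each loss; results per loss.

    ``n_cases_override`` deterministically subsamples the population (first k
    after a seeded shuffle) for desk-scale runs.
    """
    if map_size not in (20, 40):
        raise ValueError("map_size must be 20 or 40")
    gt, pred = _experiment2_arrays(map_size, seed)
    if n_cases_override is not None:
        perm = np.random.default_rng(seed).permutation(gt.shape[0])
        keep = perm[:n_cases_override]
        gt, pred = gt[keep], pred[keep]
    geom = FeatureMapGeometry(float(map_size), float(map_size), 640.0)
    out = {}
    for loss in losses:
        cfg = SimConfig(
            loss=_spec_for(loss, geom),
            learning_rate=learning_rate,
            max_epochs=max_epochs,
            convergence_threshold=convergence_threshold,
            seed=seed,
        )
        out[loss] = BoxRegression(gt, pred, cfg).fit()
    return out


def experiment2_curves(results: dict[str, BoxRegressionResults]) -> pd.DataFrame:
    """Stack per-loss total-gap curves into one DataFrame (index = epoch)."""
    df = pd.DataFrame({name: r.curve for name, r in results.items()})
    df.index.name = "epoch"
    return df
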