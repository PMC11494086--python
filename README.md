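# ioulab

Bounding-box regression losses for small-object detection — the IoU family
(IoU, GIoU, DIoU, CIoU, EIoU, SIoU, MPDIoU) plus **S-MPDIoU**, an
angle-adaptive, scale-amplified corner-distance loss — together with a
gradient-descent box-regression simulator that measures how fast each loss
actually pulls a predicted box onto a ground truth, a parameter-light
**multi-dimensional attention (MDA)** operator for detection backbones, and a
desk-scale **patch-triage pipeline** for flagging lymphocyte-dense regions in
stained-tissue slides.

The intended audience is detection researchers who want to study loss-function
convergence behaviour in isolation (no network, no dataset — just boxes and
gradients) and pathology-imaging practitioners prototyping a count-and-flag
triage flow, e.g. for lymphocytic infiltration in labial-gland biopsies.

## The loss at the core

Every metric in the family has the form `m = IoU − penalty`, used for training
as the loss `1 − m`. MPDIoU penalizes the squared distances between matching
top-left and bottom-right corners of the predicted and ground-truth boxes,
normalized by the squared diagonal of the `W × H` detection feature map:

    MPDIoU = IoU − d₁²/(W² + H²) − d₂²/(W² + H²)

S-MPDIoU changes the normalization and amplifies the penalty:

    α = atan2(C_h, C_w)                         (center-to-center angle)
    C² = W²(1 + tan²α)      if α < π/4          (angle-dependent baseline)
    C² = H²(1 + cot²α)      if α ≥ π/4
    scale = log₂(input_ref / W)                 (e.g. 3 for an 80×80 map at 640 px)

    S-MPDIoU = IoU − scale · (d₁²/C² + d₂²/C²)

A nearby ground truth is measured against a shorter baseline, and the constant
`scale` factor keeps the penalty gradient substantial when the boxes are close
but not yet overlapping — the regime where plain MPDIoU stalls. Gradients with
respect to the predicted `(x_c, y_c, w, h)` are exact (forward-mode autodiff),
with `scale` and the branch selection treated as constants.

## Worked example

```python
from ioulab import Box, FeatureMapGeometry, LossSpec, smpdiou, loss_and_gradient
from ioulab.simulator import experiment1, experiment1_speedups

geom = FeatureMapGeometry(20, 20, input_ref=640)
gt, pred = Box(5, 5, 2, 2), Box(9, 5, 2, 2)
print(smpdiou(gt, pred, geom))                       # -0.4
print(loss_and_gradient(LossSpec("smpdiou", geom), gt, pred))
# (1.4, array([ 0.2, -0. , -0. , -0. ]))

table = experiment1(["mpdiou", "smpdiou"])
print(table)
#          horizontal  diagonal  vertical
# mpdiou       5733.0    5901.0    4802.0
# smpdiou       598.0    1352.0     596.0
print(experiment1_speedups(table, "mpdiou").loc["smpdiou"])
# horizontal    9.586957
# diagonal      4.364645
# vertical      8.057047
```

The metric for the disjoint pair is −0.4 (zero overlap, both corner gaps 4
cells against a baseline of 20 cells, amplified by scale 5), and its loss
gradient pushes the predicted center left, toward the ground truth. The
experiment table lists epochs of plain gradient descent (learning rate 0.02)
until the summed parameter gap drops below 0.01: S-MPDIoU converges several
times faster than MPDIoU in every arrangement.

The same surfaces are scriptable from a shell:

```bash
ioulab loss eval --loss smpdiou --gt 5,5,2,2 --pred 9,5,2,2 --map-size 20
ioulab sim1 --losses all --out results/sim1
ioulab sim2 --map-size 40 --n-cases 2000 --max-epochs 2000 --out results/sim2
ioulab mda selftest --shape 64,80,80
ioulab fixtures make --seed 7 --out fx && \
  ioulab triage run --slide fx/slide.png --ledger fx/ledger.csv --out report
```

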