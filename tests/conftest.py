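import numpy as np
import pytest

from ioulab.boxes import FeatureMapGeometry


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def geom20():
    return FeatureMapGeometry(20.0, 20.0, 640.0)


@pytest.fixture(scope="session")
def geom40():
    return FeatureMapGeometry(40.0, 40.0, 640.0)


def sample_boxes(rng, n, frame=20.0, size_lo=0.5, size_hi=6.0):
    """Random (n, 4) center/size boxes inside a square frame."""
    out = np.empty((n, 4))
    out[:, 0:2] = rng.uniform(0.15 * frame, 0.85 * frame, (n, 2))
    out[:, 2:4] = rng.uniform(size_lo, size_hi, (n, 2))
    return out


def sample_pairs_off_boundary(rng, n, frame=20.0, margin=1e-3):
    """Box pairs kept away from the piecewise branch boundaries.

    Rejects pairs whose corner orderings, overlap widths, center offsets or
    baseline-branch comparison sit within ``margin`` of a tie, so central
    finite differences of the piecewise-smooth losses are well defined.
    """
    gts, preds = [], []
    while len(gts) < n:
        gt = sample_boxes(rng, 1, frame)[0]
        pred = sample_boxes(rng, 1, frame)[0]
        deltas = []
        for i, sign in ((0, 1), (1, 1)):
            dc = pred[i] - gt[i]
            deltas.append(abs(dc))  # center offsets (abs kinks, alpha branch)
        # corner orderings and overlap widths on both axes
        for i in (0, 1):
            p1, p2 = pred[i] - pred[i + 2] / 2, pred[i] + pred[i + 2] / 2
            g1, g2 = gt[i] - gt[i + 2] / 2, gt[i] + gt[i + 2] / 2
            deltas += [abs(p1 - g1), abs(p2 - g2), abs(min(p2, g2) - max(p1, g1))]
        deltas.append(abs(abs(pred[0] - gt[0]) - abs(pred[1] - gt[1])))  # pi/4
        deltas.append(abs(pred[2] - gt[2]))  # shape-cost abs kinks
        deltas.append(abs(pred[3] - gt[3]))
        if min(deltas) > margin:
            gts.append(gt)
            preds.append(pred)
    return np.array(gts), np.array(preds)


@pytest.fixture
def pair_sampler():
    return sample_pairs_off_boundary
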