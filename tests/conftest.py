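import numpy as np
import pytest

from gazedict import FixationDataset, KernelConfig


def make_dataset(pos_pts, neg_pts, subject_pos="sA", subject_neg="sB"):
    """Assemble a FixationDataset from raw per-class point arrays."""
    pos_pts = np.asarray(pos_pts, dtype=float).reshape(-1, 2)
    neg_pts = np.asarray(neg_pts, dtype=float).reshape(-1, 2)
    pts = np.vstack([pos_pts, neg_pts]) if len(neg_pts) else pos_pts
    labels = np.r_[np.ones(len(pos_pts)), -np.ones(len(neg_pts))]
    sids = np.array([subject_pos] * len(pos_pts) + [subject_neg] * len(neg_pts), dtype=object)
    iids = np.array(["img"] * len(pts), dtype=object)
    return FixationDataset(pts, labels, sids, iids)


def random_dataset(seed, n_pos=20, n_neg=20, spread=30.0):
    """Two overlapping Gaussian clouds with labels, seeded."""
    rng = np.random.default_rng(seed)
    pos = rng.normal((300.0, 250.0), spread, (n_pos, 2))
    neg = rng.normal((330.0, 270.0), spread, (n_neg, 2))
    return make_dataset(pos, neg)


@pytest.fixture
def two_cluster_data():
    """Tight positive cluster at (100,100), tight negative at (500,400)."""
    rng = np.random.default_rng(0)
    pos = rng.normal((100.0, 100.0), 10.0, (200, 2))
    neg = rng.normal((500.0, 400.0), 10.0, (200, 2))
    return make_dataset(pos, neg)


@pytest.fixture
def cfg30():
    return KernelConfig(h=30.0)
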