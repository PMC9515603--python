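import numpy as np
import pytest

from antmimic import phylo_gls, synthetic_data


@pytest.fixture(scope="session")
def tree70():
    """A 70-tip pure-birth tree, depth-normalized to 1."""
    return synthetic_data.gen_tree(70, seed=1)


@pytest.fixture(scope="session")
def vcv70(tree70):
    return phylo_gls.tree_to_vcv(tree70)


@pytest.fixture(scope="session")
def small_bundle():
    """A small full study bundle shared by pipeline-level tests."""
    sc = synthetic_data.StudyScenario(n_triplets=8, n_specimens=2, theta=0.8, seed=11)
    return synthetic_data.gen_study(sc)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def rasterize_rotated_rectangle(width=260, height=40, angle_deg=30.0, pad=40):
    """Analytic point-in-polygon rasterization of a rotated rectangle."""
    th = np.deg2rad(angle_deg)
    H = int(width * abs(np.sin(th)) + height * abs(np.cos(th))) + 2 * pad
    W = int(width * abs(np.cos(th)) + height * abs(np.sin(th))) + 2 * pad
    yy, xx = np.mgrid[0:H, 0:W]
    cx, cy = W / 2, H / 2
    xr = (xx - cx) * np.cos(-th) - (yy - cy) * np.sin(-th)
    yr = (xx - cx) * np.sin(-th) + (yy - cy) * np.cos(-th)
    return (np.abs(xr) <= width / 2) & (np.abs(yr) <= height / 2)


def best_shift_iou(a, b, max_shift=3):
    """IoU of two binary shapes after bbox cropping and best integer shift."""
    def bbox(x):
        r, c = np.nonzero(x)
        return x[r.min() : r.max() + 1, c.min() : c.max() + 1]

    a, b = bbox(a), bbox(b)
    H = max(a.shape[0], b.shape[0]) + 2 * max_shift
    W = max(a.shape[1], b.shape[1]) + 2 * max_shift
    A = np.zeros((H, W), bool)
    A[max_shift : max_shift + a.shape[0], max_shift : max_shift + a.shape[1]] = a
    best = 0.0
    for dr in range(-max_shift, max_shift + 1):
        for dc in range(-max_shift, max_shift + 1):
            B = np.zeros((H, W), bool)
            r0 = max_shift + dr + (a.shape[0] - b.shape[0]) // 2
            c0 = max_shift + dc + (a.shape[1] - b.shape[1]) // 2
            if r0 < 0 or c0 < 0 or r0 + b.shape[0] > H or c0 + b.shape[1] > W:
                continue
            B[r0 : r0 + b.shape[0], c0 : c0 + b.shape[1]] = b
            best = max(best, (A & B).sum() / (A | B).sum())
    return best
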