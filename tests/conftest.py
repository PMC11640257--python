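import numpy as np
import pytest

from mipsa import ExpressionDataset, GeneSubset, SyntheticSpec, simulate

TOY_MATRIX = """sample_id,G1,G2,G3,G4
a,0.1,1.2,3.0,4.5
b,0.2,1.1,2.9,4.4
c,5.0,6.0,7.0,8.0
"""

TOY_LABELS = "sample_id,label\na,0\nb,1\nc,1\n"


@pytest.fixture
def toy_files(tmp_path):
    matrix = tmp_path / "matrix.csv"
    labels = tmp_path / "labels.csv"
    matrix.write_text(TOY_MATRIX)
    labels.write_text(TOY_LABELS)
    return matrix, labels


@pytest.fixture(scope="session")
def calibrated_sim():
    """The default planted-signal dataset: 60 x 200, 10 informative, d=2."""
    return simulate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def separable_dataset():
    """Two well-separated Gaussian classes over 5 genes."""
    rng = np.random.default_rng(7)
    n = 40
    labels = np.array([0] * (n // 2) + [1] * (n // 2))
    values = rng.normal(0.0, 1.0, size=(n, 5))
    values[labels == 1] += 6.0
    return ExpressionDataset(
        [f"S{i}" for i in range(n)], [f"G{i}" for i in range(5)], values, labels
    )


def brute_force_mi(x_bins: np.ndarray, y: np.ndarray) -> float:
    """Direct joint-distribution plug-in MI (bits): independent oracle."""
    x_bins = np.asarray(x_bins)
    y = np.asarray(y)
    n = len(y)
    mi = 0.0
    for xv in np.unique(x_bins):
        px = np.mean(x_bins == xv)
        for yv in np.unique(y):
            py = np.mean(y == yv)
            pxy = np.mean((x_bins == xv) & (y == yv))
            if pxy > 0:
                mi += pxy * np.log2(pxy / (px * py))
    return mi


def concordance_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney concordance probability by brute-force pairwise count."""
    labels = np.asarray(labels)
    scores = np.asarray(scores)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    c = 0.0
    for p in pos:
        for q in neg:
            c += 1.0 if p > q else (0.5 if p == q else 0.0)
    return c / (len(pos) * len(neg))
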