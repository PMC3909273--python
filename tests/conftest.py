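import numpy as np
import pytest

from shapespace.preprocess import PCEmbedding


def make_embedding(coords, tc_ids=None) -> PCEmbedding:
    """Wrap bare coordinates in a minimal PCEmbedding for clustering tests."""
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    frac = np.full(d, 1.0 / d)
    return PCEmbedding(
        coords=coords,
        loadings=np.eye(d),
        variance_fractions=frac,
        full_variance_fractions=frac,
        mean=np.zeros(d),
        cell_ids=np.array([f"c{i}" for i in range(n)], dtype=object),
        tc_ids=np.array(
            tc_ids if tc_ids is not None else ["TC0"] * n, dtype=object
        ),
    )


def gaussian_blobs(rng, centers, n_per, sd=0.1):
    """Sample labelled isotropic Gaussian blobs around the given centers."""
    centers = np.asarray(centers, dtype=float)
    coords, labels = [], []
    for i, c in enumerate(centers):
        coords.append(rng.normal(c, sd, size=(n_per, len(c))))
        labels.extend([i + 1] * n_per)
    return np.vstack(coords), np.asarray(labels)


def brute_force_silhouette(coords, labels):
    """O(n^2) double-loop silhouette oracle (singletons and duplicates -> 0)."""
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            continue
        a = np.mean(
            [np.linalg.norm(coords[i] - coords[j]) for j in range(n) if own[j] and j != i]
        )
        b = np.inf
        for c in np.unique(labels):
            if c == labels[i]:
                continue
            mask = labels == c
            b = min(
                b,
                np.mean(
                    [np.linalg.norm(coords[i] - coords[j]) for j in np.where(mask)[0]]
                ),
            )
        denom = max(a, b)
        out[i] = 0.0 if denom == 0 else (b - a) / denom
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
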