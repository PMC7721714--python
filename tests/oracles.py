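"""Brute-force reference implementations used to validate the fast paths.

Each oracle recomputes a quantity by the most direct possible method
(explicit loops over voxels, exhaustive search over assignments or
thresholds) so that agreement with the library is evidence of
correctness, not of shared code. The suite runners draw many small random
instances and compare library output against the oracle on each.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_edt(mask: np.ndarray) -> np.ndarray:
    """Distance from every voxel to the nearest True voxel, by explicit
    pairwise distances."""
    mask = np.asarray(mask).astype(bool)
    targets = np.argwhere(mask).astype(float)
    out = np.zeros(mask.shape)
    for idx in np.ndindex(mask.shape):
        d = np.sqrt(((targets - np.asarray(idx, dtype=float)) ** 2).sum(axis=1))
        out[idx] = d.min()
    return out


def brute_hausdorff(a: np.ndarray, b: np.ndarray, spacing: float) -> float:
    """Bidirectional Hausdorff distance by explicit max-min over voxel pairs."""
    pa = np.argwhere(np.asarray(a).astype(bool)).astype(float)
    pb = np.argwhere(np.asarray(b).astype(bool)).astype(float)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2)
    return float(max(d.min(axis=1).max(), d.min(axis=0).max()) * spacing)


def brute_line_sum(field: np.ndarray, a, b, step: float = 0.5) -> float:
    """Line sum by a plain Python loop over the same 0.5-voxel sampling:
    round each sample to a voxel, keep each visited voxel once, sum."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    length = float(np.linalg.norm(b - a))
    n = max(1, int(np.ceil(length / step)))
    visited = set()
    for i in range(n + 1):
        t = i / n
        p = a + t * (b - a)
        visited.add(tuple(int(v) for v in np.round(p)))
    return float(sum(field[v] for v in visited))


def brute_best_assignment(M: np.ndarray) -> int:
    """Maximum total overlap of any one-to-one label assignment, by
    exhaustive enumeration (small matrices only)."""
    M = np.asarray(M)
    r, c = M.shape
    if r > c:
        return brute_best_assignment(M.T)
    best = 0
    for cols in itertools.permutations(range(c), r):
        best = max(best, int(sum(M[i, j] for i, j in enumerate(cols))))
    return best


def brute_otsu_variance(values):
    """Between-class variance per 256-bin histogram split, by explicit sums.

    Returns (bin centers, variance array). The Otsu threshold is any bin
    center attaining the maximum; empty-gap bins between well-separated
    modes form an exact plateau of maxima (they all induce the same data
    split), so oracle equivalence is checked on the attained variance, not
    on the tie-broken bin choice.
    """
    values = np.asarray(values, dtype=float).ravel()
    counts, edges = np.histogram(values, bins=256)
    centers = (edges[:-1] + edges[1:]) / 2
    total = counts.sum()
    sigma = np.full(256, -np.inf)
    for k in range(256):
        n0 = counts[: k + 1].sum()
        n1 = total - n0
        if n0 == 0 or n1 == 0:
            continue
        mu0 = (counts[: k + 1] * centers[: k + 1]).sum() / n0
        mu1 = (counts[k + 1:] * centers[k + 1:]).sum() / n1
        sigma[k] = (n0 / total) * (n1 / total) * (mu0 - mu1) ** 2
    return centers, sigma


# ---------------------------------------------------------------------------
# random-instance suite runners (>= 50 instances each in the acceptance run)
# ---------------------------------------------------------------------------

def run_edt_suite(n_instances: int, seed: int = 0) -> None:
    from morphoseg.distance import membrane_distance
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        shape = tuple(rng.integers(3, 8, size=3))
        mask = rng.random(shape) < rng.uniform(0.05, 0.5)
        if not mask.any():
            mask[tuple(rng.integers(0, s) for s in shape)] = True
        np.testing.assert_allclose(membrane_distance(mask), brute_edt(mask),
                                   atol=1e-9)


def run_hausdorff_suite(n_instances: int, seed: int = 0) -> None:
    from morphoseg.metrics import hausdorff
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        shape = tuple(rng.integers(3, 8, size=3))
        a = rng.random(shape) < rng.uniform(0.1, 0.6)
        b = rng.random(shape) < rng.uniform(0.1, 0.6)
        if not a.any():
            a[tuple(rng.integers(0, s) for s in shape)] = True
        if not b.any():
            b[tuple(rng.integers(0, s) for s in shape)] = True
        spacing = float(rng.uniform(0.1, 1.0))
        np.testing.assert_allclose(hausdorff(a, b, spacing),
                                   brute_hausdorff(a, b, spacing), atol=1e-9)


def run_line_sum_suite(n_instances: int, seed: int = 0) -> None:
    from morphoseg.watershed import line_sum
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        shape = tuple(rng.integers(5, 15, size=3))
        field = rng.random(shape)
        a = rng.uniform(0, np.asarray(shape) - 1)
        b = rng.uniform(0, np.asarray(shape) - 1)
        np.testing.assert_allclose(line_sum(field, a, b),
                                   brute_line_sum(field, a, b), atol=1e-9)


def run_assignment_suite(n_instances: int, seed: int = 0) -> None:
    from morphoseg.metrics import unify_labels
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        shape = tuple(rng.integers(3, 7, size=3))
        n_pred = int(rng.integers(1, 5))
        n_truth = int(rng.integers(1, 5))
        pred = rng.integers(0, n_pred + 1, size=shape)
        truth = rng.integers(0, n_truth + 1, size=shape)
        matched = unify_labels(pred, truth)
        total = int((matched.relabeled[matched.relabeled == truth] > 0).sum())
        assert total == brute_best_assignment(matched.overlap) \
            if matched.overlap.size else total == 0


def run_otsu_suite(n_instances: int, seed: int = 0) -> None:
    from morphoseg.watershed import otsu_threshold
    rng = np.random.default_rng(seed)
    for _ in range(n_instances):
        n0, n1 = rng.integers(5, 40, size=2)
        lo = rng.normal(rng.uniform(0, 2), rng.uniform(0.05, 0.5), size=n0)
        hi = rng.normal(rng.uniform(4, 10), rng.uniform(0.05, 0.5), size=n1)
        values = np.concatenate([lo, hi])
        thr = otsu_threshold(values)
        centers, sigma = brute_otsu_variance(values)
        k = int(np.argmin(np.abs(centers - thr)))
        assert abs(centers[k] - thr) < 1e-9, "threshold is not a bin center"
        assert sigma[k] >= sigma.max() - 1e-9 * max(1.0, abs(sigma.max())), \
            "chosen threshold does not attain the maximum between-class variance"
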