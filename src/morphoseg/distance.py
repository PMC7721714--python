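"""Distance-constrained learning targets.

A binary membrane mask is turned into the network's learning target in three
steps: (1) the Euclidean distance from every voxel to the nearest membrane
voxel, (2) reversal and truncation so the map takes its maximum ``d`` on the
membrane and decays to 0 at distance >= d, and (3) nonlinear discretization
into ordinal classes {0..K} with bins that shrink toward the membrane, so
the top class K is exactly the membrane center mask.

All distances are in voxel units on an isotropic grid.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage


def membrane_distance(mask: np.ndarray) -> np.ndarray:
    """Euclidean distance (voxels) from each voxel to the nearest membrane voxel.

    ``mask`` is binary with 1 on the membrane. Returns 0 on membrane voxels.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("membrane mask is empty")
    # EDT measures distance to the nearest zero of its input, so feed the
    # complement of the membrane.
    return ndimage.distance_transform_edt(~mask)


def reverse_truncate(dist: np.ndarray, d: float, *, literal_eq4: bool = False) -> np.ndarray:
    """Reverse and truncate a distance field: M = d - min(dist, d).

    The result equals ``d`` on the membrane (dist = 0) and decays linearly to
    0 at distance >= d, i.e. it is monotonically decreasing from the membrane
    into the background.

    With ``literal_eq4=True`` the alternative reading "reverse against the
    global maximum, then truncate at d" is applied instead; it saturates at d
    everywhere within ``max(dist) - d`` of the membrane and is kept only for
    comparison.
    """
    dist = np.asarray(dist, dtype=float)
    if d <= 0:
        raise ValueError("truncation distance d must be positive")
    if dist.min() < 0:
        raise ValueError("distances must be non-negative")
    if literal_eq4:
        return np.minimum(dist.max() - dist, d)
    return d - np.minimum(dist, d)


def bin_edges(d: float, K: int, gamma: float) -> np.ndarray:
    """Class-boundary positions in M-space: edge_k = d * (k/K)**(1/gamma).

    With gamma > 1 successive bin widths strictly shrink toward class K
    (the membrane), concentrating resolution where shape detail matters.
    """
    if K < 2:
        raise ValueError("need at least 2 classes")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    k = np.arange(K + 1, dtype=float)
    return d * (k / K) ** (1.0 / gamma)


def discretize(M: np.ndarray, d: float, K: int, gamma: float = 2.0) -> np.ndarray:
    """Quantize a truncated-reversed distance map into ordinal classes {0..K}.

    class(v) = floor(K * (M(v)/d)**gamma), clipped to K. Membrane voxels
    (M = d) map to class K, pure background (M = 0) to class 0, and for
    gamma > 1 the class boundaries crowd toward the membrane.
    """
    if K < 2:
        raise ValueError("need at least 2 classes")
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if d <= 0:
        raise ValueError("d must be positive")
    M = np.asarray(M, dtype=float)
    frac = np.clip(M / d, 0.0, 1.0)
    cls = np.floor(K * frac**gamma).astype(np.int32)
    return np.minimum(cls, K)


def target_from_mask(mask: np.ndarray, d: float = 16.0, K: int = 16,
                     gamma: float = 2.0) -> np.ndarray:
    """Full mask -> discrete distance map pipeline (classes {0..K})."""
    return discretize(reverse_truncate(membrane_distance(mask), d), d, K, gamma)


def class_weights(K: int, schedule: str = "linear") -> np.ndarray:
    """Per-class weights xi_k, length K+1, positive, non-decreasing in k,
    normalized to mean 1.

    ``linear`` (default): xi_k proportional to 1 + k/K, biasing the loss
    toward classes near the membrane. ``uniform``: all ones.
    """
    if K < 2:
        raise ValueError("need at least 2 classes")
    k = np.arange(K + 1, dtype=float)
    if schedule == "uniform":
        w = np.ones(K + 1)
    elif schedule == "linear":
        w = 1.0 + k / K
    else:
        raise ValueError(f"unknown class-weight schedule: {schedule!r}")
    return w / w.mean()
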