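"""Per-cell morphology, cell-cell contacts, and temporal-consistency metrics.

Quantities follow the conventions used throughout early-embryo morphometry:

* volume V (um^3) from voxel counts, surface area S (um^2) from a
  marching-cubes isosurface of the cell's binary mask;
* the dimensionless shape-irregularity score eta = sqrt(S) / cbrt(V),
  which depends only on shape and is minimized by a sphere at
  2^(1/3) * 3^(1/3) * pi^(1/6) ~= 2.1991;
* cell-cell contact areas from shared voxel faces, filtered into
  "effective" contacts by area fraction, duration and cross-embryo
  reproducibility;
* the volume-inconsistency coefficient rho_c = sd(V)/mean(V) over a cell's
  lifespan, and an ordinary log-log least-squares fit of cell-cycle
  duration against cell volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil, pi

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

#: Analytic minimum of eta, attained by a perfect sphere.
SPHERE_ETA = 2.0 ** (1 / 3) * 3.0 ** (1 / 3) * pi ** (1 / 6)


# ---------------------------------------------------------------------------
# shape measurement
# ---------------------------------------------------------------------------

def irregularity(S: float, V: float) -> float:
    """Shape irregularity eta = sqrt(S) / V^(1/3).

    Scale-free: eta(lambda^2 S, lambda^3 V) = eta(S, V) for any lambda > 0.
    """
    if S <= 0 or V <= 0:
        raise ValueError("surface area and volume must be positive")
    return np.sqrt(S) / V ** (1.0 / 3.0)


def surface_area(mask: np.ndarray, spacing: float, *, smooth_sigma: float = 1.0) -> float:
    """Isosurface area (um^2) of a binary region mask.

    The mask is lightly Gaussian-smoothed (in voxel units) before running
    marching cubes at level 0.5; the smoothing removes the voxelization
    staircase that would otherwise inflate the area of curved surfaces.
    """
    mask = np.asarray(mask, dtype=float)
    padded = np.pad(mask, 2)
    if smooth_sigma > 0:
        padded = ndimage.gaussian_filter(padded, smooth_sigma)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5,
                                                spacing=(spacing,) * 3)
    return float(measure.mesh_surface_area(verts, faces))


def measure_cell(labels: np.ndarray, label: int, spacing: float):
    """Volume (um^3), surface area (um^2) and centroid (um, x/y/z) of one cell.

    Volume is voxel count times spacing^3; surface area comes from a
    triangulated isosurface of the region's binary mask; the centroid is the
    mean voxel coordinate scaled to um (x along axis 2, y axis 1, z axis 0).
    """
    region = np.asarray(labels) == label
    n = int(region.sum())
    if n == 0:
        raise ValueError(f"label {label} not present")
    V = n * spacing**3
    S = surface_area(region, spacing)
    zz, yy, xx = np.nonzero(region)
    centroid = np.array([xx.mean(), yy.mean(), zz.mean()]) * spacing
    return V, S, centroid


def morphology_table(labels: np.ndarray, spacing: float,
                     names: dict[int, str] | None = None,
                     cavity_labels: set[int] | frozenset[int] = frozenset(),
                     embryo: str = "", time: int = 1) -> pd.DataFrame:
    """Per-cell morphology records for every nonzero label in a label field."""
    rows = []
    for lab in np.unique(labels):
        if lab == 0:
            continue
        V, S, c = measure_cell(labels, int(lab), spacing)
        rows.append({
            "embryo": embryo, "time": time, "label": int(lab),
            "cell": (names or {}).get(int(lab), f"L{int(lab)}"),
            "volume_um3": V, "surface_um2": S, "eta": irregularity(S, V),
            "cx": c[0], "cy": c[1], "cz": c[2],
            "is_cavity": int(lab) in cavity_labels,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def contact_areas(labels: np.ndarray, spacing: float,
                  names: dict[int, str] | None = None,
                  exclude: set[int] | frozenset[int] = frozenset(),
                  bridge_ridge: bool = False) -> pd.DataFrame:
    """Pairwise contact areas (um^2) from 6-neighbor voxel-face adjacencies.

    ``labels`` is expected to be a full partition (each voxel one region).
    With ``bridge_ridge`` a face across a single zero-label (membrane dam)
    voxel is attributed to the two flanking regions instead. Background
    (label 0) and any label in ``exclude`` never form contacts; zero-area
    pairs are omitted.
    """
    labels = np.asarray(labels)
    counts: dict[tuple[int, int], int] = {}

    def _add(a: np.ndarray, b: np.ndarray) -> None:
        sel = (a != b) & (a > 0) & (b > 0)
        if not sel.any():
            return
        lo = np.minimum(a[sel], b[sel])
        hi = np.maximum(a[sel], b[sel])
        pairs, n = np.unique(np.stack([lo, hi], axis=1), axis=0, return_counts=True)
        for (pa, pb), c in zip(pairs, n):
            counts[(int(pa), int(pb))] = counts.get((int(pa), int(pb)), 0) + int(c)

    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        _add(labels[tuple(sl_a)], labels[tuple(sl_b)])
        if bridge_ridge and labels.shape[ax] >= 3:
            sl_m = [slice(None)] * 3
            sl_a2 = [slice(None)] * 3
            sl_b2 = [slice(None)] * 3
            sl_a2[ax] = slice(None, -2)
            sl_m[ax] = slice(1, -1)
            sl_b2[ax] = slice(2, None)
            mid = labels[tuple(sl_m)]
            a2, b2 = labels[tuple(sl_a2)].copy(), labels[tuple(sl_b2)].copy()
            ridge = mid == 0
            a2[~ridge] = 0
            b2[~ridge] = 0
            _add(a2, b2)

    rows = []
    for (a, b), c in sorted(counts.items()):
        if a in exclude or b in exclude:
            continue
        na = (names or {}).get(a, f"L{a}")
        nb = (names or {}).get(b, f"L{b}")
        rows.append({"cell_a": na, "cell_b": nb, "label_a": a, "label_b": b,
                     "area_um2": c * spacing**2})
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "label_a", "label_b",
                                       "area_um2"])


def close_packing_contact_fraction(radius_ratio: Fraction = Fraction(1, 3),
                                   replacement_count: int = 4) -> Fraction:
    """Derive the default effective-contact area fraction from close packing.

    In a hexagonal close packing of equal spheres each sphere touches a
    number of neighbors given by the lattice kissing number (counted here
    from the lattice itself, = 12), so one neighbor claims 1/12 of the
    surface budget. Since a neighbor of relative radius ``radius_ratio``
    (up to 1/3 between neighboring embryonic cells) can replace a unit
    neighbor in groups of at most ``replacement_count`` (= 4), the smallest
    biologically meaningful contact is 1/12 * 1/4 = 1/48 of a cell's
    surface area.
    """
    kissing = _hcp_kissing_number()
    if replacement_count < 1:
        raise ValueError("replacement_count must be >= 1")
    return Fraction(1, kissing) * Fraction(1, replacement_count)


def _hcp_kissing_number() -> int:
    """Count nearest neighbors of a sphere in the hexagonal close packing."""
    a = 1.0  # sphere diameter = lattice spacing
    pts = []
    # two-layer ABAB stacking, enough shells to cover nearest neighbors
    for i in range(-2, 3):
        for j in range(-2, 3):
            for k in range(-2, 3):
                x = a * (i + 0.5 * (j % 2) + 0.5 * (k % 2))
                y = a * (np.sqrt(3) / 2 * j + np.sqrt(3) / 6 * (k % 2))
                z = a * np.sqrt(6) / 3 * k
                pts.append((x, y, z))
    pts = np.array(pts)
    d = np.linalg.norm(pts, axis=1)
    return int(np.sum(np.abs(d - a) < 1e-9))


@dataclass
class EffectiveContactCriteria:
    """Filters defining an effective cell-cell contact."""
    area_fraction_min: float = 1.0 / 48.0
    min_consecutive_frames: int = 2
    min_duration_min: float = 3.0
    reproducibility_fraction: float = 1.0

    def __post_init__(self):
        if (self.area_fraction_min <= 0 or self.min_consecutive_frames < 1
                or self.min_duration_min <= 0
                or not (0 < self.reproducibility_fraction <= 1)):
            raise ValueError("invalid effective-contact criteria")


def effective_contacts(records: pd.DataFrame, morph: pd.DataFrame,
                       criteria: EffectiveContactCriteria | None = None,
                       frame_interval_min: float = 1.5) -> pd.DataFrame:
    """Filter raw contact records into effective contacts.

    ``records`` needs columns embryo,time,cell_a,cell_b,area_um2; ``morph``
    needs embryo,cell,time,surface_um2. A pair passes in one embryo iff the
    relative area s_contact / S_surface reaches ``area_fraction_min`` for at
    least one member of the pair over enough consecutive frames to cover
    both ``min_consecutive_frames`` and ``min_duration_min``; a pair is
    effective iff it passes in at least ``reproducibility_fraction`` of the
    embryos. Returns one row per effective pair with per-embryo qualifying
    intervals.
    """
    criteria = criteria or EffectiveContactCriteria()
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be positive")
    need = max(criteria.min_consecutive_frames,
               ceil(criteria.min_duration_min / frame_interval_min))
    surf = morph.set_index(["embryo", "cell", "time"])["surface_um2"]
    embryos = sorted(records["embryo"].unique())
    n_embryos = len(embryos)
    out = []
    key = records.assign(
        pair=[tuple(sorted(p)) for p in zip(records["cell_a"], records["cell_b"])])
    for pair, grp in key.groupby("pair"):
        passing = {}
        for emb, g in grp.groupby("embryo"):
            g = g.sort_values("time")
            ok_times = []
            for _, r in g.iterrows():
                rel = 0.0
                for cell in pair:
                    s = surf.get((emb, cell, r["time"]), np.nan)
                    if np.isfinite(s) and s > 0:
                        rel = max(rel, r["area_um2"] / s)
                if rel >= criteria.area_fraction_min:
                    ok_times.append(int(r["time"]))
            run = _longest_consecutive_run(ok_times)
            if run is not None and run[1] - run[0] + 1 >= need:
                passing[emb] = run
        if n_embryos and len(passing) / n_embryos >= criteria.reproducibility_fraction:
            out.append({"cell_a": pair[0], "cell_b": pair[1],
                        "n_embryos_passing": len(passing),
                        "intervals": {e: list(v) for e, v in passing.items()}})
    return pd.DataFrame(out, columns=["cell_a", "cell_b", "n_embryos_passing",
                                      "intervals"])


def _longest_consecutive_run(times: list[int]):
    if not times:
        return None
    best = cur = (times[0], times[0])
    for t in times[1:]:
        cur = (cur[0], t) if t == cur[1] + 1 else (t, t)
        if cur[1] - cur[0] > best[1] - best[0]:
            best = cur
    return best


# ---------------------------------------------------------------------------
# temporal consistency and scaling laws
# ---------------------------------------------------------------------------

def volume_inconsistency(volumes, lifespan_mid: float | None = None,
                         total_time: float | None = None):
    """rho_c = population sd / mean of a cell's volume over its lifespan.

    Returns (rho_c, t_c) where t_c is the lifespan midpoint mapped to [0, 1]
    when ``lifespan_mid`` and ``total_time`` are supplied (None otherwise).
    NaNs (missing frames) are skipped.
    """
    v = np.asarray(volumes, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least 2 volume observations")
    rho = float(v.std() / v.mean())
    t_c = None
    if lifespan_mid is not None and total_time is not None:
        t_c = float(lifespan_mid / total_time)
    return rho, t_c


def sister_ratio_stats(morph: pd.DataFrame, lineage: pd.DataFrame) -> pd.DataFrame:
    """Sister-cell size ratios and their cross-embryo variability.

    For every pair of cells sharing a parent, the per-embryo ratio is
    smaller/larger of the lifespan-averaged volumes (and surfaces); the
    variation coefficient is sd/mean of that ratio across embryos. Also
    reports the cross-embryo variation coefficient of each sister's own
    mean volume for comparison.
    """
    kids = lineage[lineage["parent"] != ""].drop_duplicates("cell")
    pairs = []
    for parent, grp in kids.groupby("parent"):
        cells = sorted(grp["cell"].unique())
        if len(cells) == 2:
            pairs.append((parent, cells[0], cells[1]))
    per_cell = (morph.groupby(["embryo", "cell"])
                .agg(volume=("volume_um3", "mean"), surface=("surface_um2", "mean")))
    rows = []
    for parent, a, b in pairs:
        embryos = sorted(set(per_cell.index.get_level_values(0)))
        vr, sr, va, vb = [], [], [], []
        for emb in embryos:
            try:
                ra = per_cell.loc[(emb, a)]
                rb = per_cell.loc[(emb, b)]
            except KeyError:
                continue
            vr.append(min(ra["volume"], rb["volume"]) / max(ra["volume"], rb["volume"]))
            sr.append(min(ra["surface"], rb["surface"]) / max(ra["surface"], rb["surface"]))
            va.append(ra["volume"])
            vb.append(rb["volume"])
        if len(vr) < 2:
            continue
        vr, sr, va, vb = map(np.asarray, (vr, sr, va, vb))
        cv = lambda x: float(x.std() / x.mean()) if x.mean() > 0 else np.nan
        rows.append({
            "parent": parent, "cell_a": a, "cell_b": b, "n_embryos": len(vr),
            "volume_ratio_mean": float(vr.mean()), "volume_ratio_cv": cv(vr),
            "surface_ratio_mean": float(sr.mean()), "surface_ratio_cv": cv(sr),
            "volume_cv_a": cv(va), "volume_cv_b": cv(vb),
            "volume_ratio_min": float(vr.min()), "volume_ratio_max": float(vr.max()),
            "volume_ratio_p99": float(np.percentile(vr, 99)),
        })
    return pd.DataFrame(rows)


def fit_powerlaw(cycle_minutes, volumes):
    """Least-squares power-law fit T = exp(intercept) * V**slope.

    Ordinary least squares of log T on log V; returns (slope, intercept).
    """
    T = np.asarray(cycle_minutes, dtype=float)
    V = np.asarray(volumes, dtype=float)
    if T.size < 3:
        raise ValueError("need at least 3 cells")
    if (T <= 0).any() or (V <= 0).any():
        raise ValueError("cycle durations and volumes must be positive")
    slope, intercept = np.polyfit(np.log(V), np.log(T), 1)
    return float(slope), float(intercept)
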