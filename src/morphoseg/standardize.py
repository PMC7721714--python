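"""Spatial standardization of multiple embryos into a common frame.

Embryos are imaged in arbitrary poses; comparing per-cell positions
across samples requires bringing them into one coordinate system. The
procedure: (1) make the slice stack symmetric about the xz plane
(translation in yz, rotation about x); (2) center the xz projection and
align its minimum-area enclosing ellipse's major axis with x (translation
in xz, rotation about y); (3) rescale every embryo to the across-embryo
mean extent per axis; (4) refine against a reference by interleaved
closed-form rounds of rotation, translation and per-axis scaling
minimizing the sum of squared same-cell distances. The per-cell
positional spread across embryos is summarized by the RMSD
Delta_r = sqrt(mean ||r_i - r_mean||^2).

Positions are (x, y, z) in um throughout: x anterior-posterior,
y left-right, z dorsal-ventral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class EmbryoAlignment:
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: np.ndarray = field(default_factory=lambda: np.ones(3))

    def apply(self, positions: np.ndarray) -> np.ndarray:
        p = np.asarray(positions, dtype=float)
        return (self.rotation @ (self.scale[:, None] * p.T)).T + self.translation


def _rot_x(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)


def _rot_y(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]], dtype=float)


def symmetrize_z(positions: np.ndarray,
                 plane_normal=(0.0, 1.0, 0.0)) -> EmbryoAlignment:
    """Make the slice stack symmetric about the xz plane.

    ``plane_normal`` is the normal of the imaging planes (the stacking
    direction, nominally +y). Returns the rigid transform that rotates the
    normal onto +y (rotation about x) and translates along y so the first
    and last planes sit symmetrically on both sides of the xz plane.
    """
    p = np.asarray(positions, dtype=float)
    if p.ndim != 2 or p.shape[1] != 3 or len(p) == 0:
        raise ValueError("positions must be a nonempty (n, 3) array")
    n = np.asarray(plane_normal, dtype=float)
    if np.linalg.norm(n) == 0:
        raise ValueError("degenerate plane normal")
    n = n / np.linalg.norm(n)
    angle = np.arctan2(n[2], n[1])          # rotate about x: (0, ny, nz) -> +y
    R = _rot_x(-angle)
    rotated = (R @ p.T).T
    ymin, ymax = rotated[:, 1].min(), rotated[:, 1].max()
    if ymax - ymin == 0 and len(p) > 1:
        pass  # flat stack is fine; a single plane is centered directly
    t = np.array([0.0, -(ymin + ymax) / 2.0, 0.0])
    return EmbryoAlignment(rotation=R, translation=t)


def min_area_enclosing_ellipse(points2d: np.ndarray, tol: float = 1e-7,
                               max_iter: int = 10000):
    """Minimum-area enclosing ellipse (Khachiyan's algorithm).

    Returns (center, A) with the ellipse {u : (u-c)^T A (u-c) <= 1}.
    """
    P = np.asarray(points2d, dtype=float)
    n, d = P.shape
    if n < 3 or np.linalg.matrix_rank(P - P.mean(axis=0)) < 2:
        raise ValueError("need >= 3 non-collinear points")
    Q = np.column_stack([P, np.ones(n)]).T          # (3, n)
    u = np.full(n, 1.0 / n)
    for _ in range(max_iter):
        X = Q @ np.diag(u) @ Q.T
        M = np.einsum("in,ij,jn->n", Q, np.linalg.inv(X), Q)
        j = int(np.argmax(M))
        step = (M[j] - d - 1.0) / ((d + 1.0) * (M[j] - 1.0))
        new_u = (1 - step) * u
        new_u[j] += step
        if np.linalg.norm(new_u - u) < tol:
            u = new_u
            break
        u = new_u
    center = P.T @ u
    cov = (P.T * u) @ P - np.outer(center, center)
    A = np.linalg.inv(cov) / d
    return center, A


def fit_min_ellipse_xz(positions: np.ndarray) -> EmbryoAlignment:
    """Center the xz projection and align its enclosing ellipse with x.

    Computes the minimum-area enclosing ellipse of the (x, z) projection,
    translates its center to the origin and rotates about y so the major
    axis lies along x.
    """
    p = np.asarray(positions, dtype=float)
    proj = p[:, [0, 2]]
    center, A = min_area_enclosing_ellipse(proj)
    evals, evecs = np.linalg.eigh(A)
    major = evecs[:, 0]                     # smallest eigenvalue = longest axis
    angle = np.arctan2(major[1], major[0])  # angle of major axis in the xz plane
    if angle > np.pi / 2:
        angle -= np.pi
    if angle < -np.pi / 2:
        angle += np.pi
    # rotation about y by +angle maps (x, z) = (cos a, sin a) onto (1, 0)
    R = _rot_y(angle)
    c3 = np.array([center[0], 0.0, center[1]])
    t = -(R @ c3)
    return EmbryoAlignment(rotation=R, translation=t)


def rescale_to_average(position_sets: list[np.ndarray]):
    """Rescale every embryo's per-axis extent to the across-embryo mean.

    Returns (scaled position sets, per-embryo scale triples); the
    geometric structure within each embryo is preserved axis-wise and the
    mean of the scale factors per axis is ~1.
    """
    if len(position_sets) < 2:
        raise ValueError("need at least 2 embryos")
    extents = np.array([[p[:, a].max() - p[:, a].min() for a in range(3)]
                        for p in position_sets])
    if (extents <= 0).any():
        raise ValueError("zero extent on some axis")
    target = extents.mean(axis=0)
    scales = target[None, :] / extents
    scaled = [p * s[None, :] for p, s in zip(position_sets, scales)]
    return scaled, scales


def normalize_positions(positions: dict[str, np.ndarray],
                        reference: dict[str, np.ndarray],
                        rotation_cycles: int = 60,
                        translation_cycles: int = 60,
                        scaling_cycles: int = 30):
    """Refine one embryo onto a reference by interleaved closed-form steps.

    ``positions`` and ``reference`` map cell names to (x, y, z) um. The
    model is p' = R diag(s) p + t; each cycle applies the exact minimizer
    of the summed squared distance for one transform family with the
    others fixed, so the objective is monotonically non-increasing.
    Returns (EmbryoAlignment, final objective).
    """
    shared = sorted(set(positions) & set(reference))
    if len(shared) < 4:
        raise ValueError("need at least 4 shared cells")
    P = np.array([positions[c] for c in shared])    # (n, 3)
    Rf = np.array([reference[c] for c in shared])
    R = np.eye(3)
    t = np.zeros(3)
    s = np.ones(3)

    def objective():
        return float(((((R @ (s[:, None] * P.T)).T + t) - Rf) ** 2).sum())

    total = max(rotation_cycles, translation_cycles, scaling_cycles)
    for cycle in range(total):
        if cycle < rotation_cycles:
            Q = s[None, :] * P
            qc = Q - Q.mean(axis=0)
            rc = Rf - Rf.mean(axis=0)
            H = qc.T @ rc
            U, _, Vt = np.linalg.svd(H)
            D = np.diag([1.0, 1.0, np.sign(np.linalg.det(Vt.T @ U.T))])
            R = Vt.T @ D @ U.T
            t = Rf.mean(axis=0) - R @ Q.mean(axis=0)
        if cycle < translation_cycles:
            t = (Rf - (R @ (s[:, None] * P.T)).T).mean(axis=0)
        if cycle < scaling_cycles:
            U2 = (R.T @ (Rf - t).T).T            # rotate target back
            denom = (P**2).sum(axis=0)
            num = (P * U2).sum(axis=0)
            cand = np.where(denom > 0, num / denom, 1.0)
            # scales must stay positive; keeping the current value when the
            # unconstrained minimizer is not preserves monotonicity
            s = np.where(cand > 0, cand, s)
    return EmbryoAlignment(rotation=R, translation=t, scale=s), objective()


def spatial_deviation(positions_by_embryo: np.ndarray,
                      literal_formula: bool = False) -> float:
    """Per-cell positional deviation Delta_r across embryos (um).

    Delta_r = sqrt(sum_i ||r_i - r_mean||^2 / N) (true RMSD). The
    ``literal_formula`` variant omits the square on the deviation norm.
    """
    p = np.asarray(positions_by_embryo, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need positions from at least 2 embryos")
    dev = np.linalg.norm(p - p.mean(axis=0), axis=1)
    if literal_formula:
        return float(np.sqrt(dev.sum() / len(p)))
    return float(np.sqrt((dev**2).mean()))


def atlas_deviation_table(positions: pd.DataFrame) -> pd.DataFrame:
    """Delta_r per cell from a long table embryo,cell,x_um,y_um,z_um."""
    rows = []
    for cell, grp in positions.groupby("cell"):
        if len(grp) < 2:
            continue
        rows.append({"cell": cell, "n_embryos": len(grp),
                     "delta_r_um": spatial_deviation(
                         grp[["x_um", "y_um", "z_um"]].to_numpy())})
    return pd.DataFrame(rows)
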