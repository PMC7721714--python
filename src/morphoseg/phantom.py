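"""Ground-truth-complete synthetic embryo phantoms.

A phantom is a Voronoi partition of an ellipsoidal embryo into densely
packed cells, a thin membrane shell along every inter-cell and
cell-exterior boundary, per-cell nucleus blobs with a lineage table, and
fluorescence renderings of both channels with the degradations the real
imaging shows: anisotropic blur from the elongated confocal light volume,
exponential laser attenuation with depth, extra dimming of membrane
patches lying parallel to the focal plane, and detector noise.

Axes follow the embryo convention: x = anterior-posterior (array axis 2),
y = left-right (axis 1), z = dorsal-ventral / imaging axis (axis 0).
Voxels are isotropic; all physical parameters are in um.

Two ground-truth views are kept. ``truth_labels`` carves the membrane
shell out of the cells (labels 0 on membrane and exterior), which is the
natural target for learning the membrane. ``full_partition`` is the
compartment partition: every voxel, membrane included, belongs to the
compartment (cell or exterior background) whose interior is nearest, so
each membrane wall is split down its middle between the two compartments
it separates. This is the convention a ridge-flooding watershed realizes,
which makes it the right reference for scoring a full segmentation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from . import atlas


@dataclass(frozen=True)
class PhantomConfig:
    grid_shape: tuple[int, int, int] = (48, 64, 80)       # (z, y, x) voxels
    spacing_um: float = 0.5
    n_cells: int = 8
    embryo_semiaxes_um: tuple[float, float, float] = (18.0, 14.0, 10.0)  # (x, y, z)
    membrane_thickness_um: float = 1.0
    psf_sigma_um: tuple[float, float] = (0.2, 0.5)        # (lateral, axial)
    attenuation_coeff: float = 0.02                       # per um along z
    noise_sd: float = 0.05                                # fraction of base signal
    orientation_alpha: float = 0.5                        # membrane dimming strength
    background_level: float = 0.0                         # detector offset, fraction of base
    base_intensity: float = 1000.0
    nucleus_sigma_um: float = 1.5
    rng_seed: int = 0

    def __post_init__(self):
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")
        if self.spacing_um <= 0:
            raise ValueError("spacing_um must be positive")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.membrane_thickness_um <= 0:
            raise ValueError("membrane_thickness_um must be positive")
        if self.psf_sigma_um[1] < self.psf_sigma_um[0]:
            raise ValueError("axial psf sigma must be >= lateral (elongated light volume)")
        ext = self._extent_check()
        if not ext:
            raise ValueError("embryo ellipsoid does not fit inside the grid")

    def _extent_check(self) -> bool:
        nz, ny, nx = self.grid_shape
        ax, ay, az = (s / self.spacing_um for s in self.embryo_semiaxes_um)
        return 2 * ax + 2 <= nx and 2 * ay + 2 <= ny and 2 * az + 2 <= nz

    @property
    def center_vox(self) -> np.ndarray:
        return (np.asarray(self.grid_shape, dtype=float) - 1) / 2  # (z, y, x)

    @property
    def semiaxes_vox(self) -> np.ndarray:
        ax, ay, az = (s / self.spacing_um for s in self.embryo_semiaxes_um)
        return np.array([az, ay, ax])  # (z, y, x) order


@dataclass
class EmbryoPhantom:
    config: PhantomConfig
    truth_labels: np.ndarray            # cells >= 1, membrane/exterior 0
    membrane_mask: np.ndarray           # bool
    voronoi: np.ndarray                 # raw nearest-seed partition of the ellipsoid
    full_partition: np.ndarray          # compartment partition (membrane split mid-wall)
    membrane_image: np.ndarray
    nucleus_image: np.ndarray
    lineage: pd.DataFrame               # time,cell,parent,x_um,y_um,z_um
    truth_morphology: pd.DataFrame
    names: dict[int, str]
    cavity_labels: set[int] = field(default_factory=set)
    anaphase: dict[int, str] = field(default_factory=dict)  # label -> expected (mother) name
    time: int = 1

    def copy(self) -> "EmbryoPhantom":
        return EmbryoPhantom(
            config=self.config,
            truth_labels=self.truth_labels.copy(),
            membrane_mask=self.membrane_mask.copy(),
            voronoi=self.voronoi.copy(),
            full_partition=self.full_partition.copy(),
            membrane_image=self.membrane_image.copy(),
            nucleus_image=self.nucleus_image.copy(),
            lineage=self.lineage.copy(),
            truth_morphology=self.truth_morphology.copy(),
            names=dict(self.names),
            cavity_labels=set(self.cavity_labels),
            anaphase=dict(self.anaphase),
            time=self.time,
        )


def interior_mask(config: PhantomConfig) -> np.ndarray:
    """Boolean mask of voxels strictly inside the embryo ellipsoid."""
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in config.grid_shape),
                             indexing="ij")
    c = config.center_vox
    a = config.semiaxes_vox
    q = (((zz - c[0]) / a[0]) ** 2 + ((yy - c[1]) / a[1]) ** 2
         + ((xx - c[2]) / a[2]) ** 2)
    return q <= 1.0


def _boundary_voxels(labels_full: np.ndarray) -> np.ndarray:
    """Voxels with a 6-neighbor of different value.

    Both sides of every interface are marked, including the exterior side
    of the embryo surface, so each wall straddles its interface
    symmetrically and membrane attribution/flooding has no systematic
    ties.
    """
    b = np.zeros(labels_full.shape, dtype=bool)
    for ax in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[ax] = slice(None, -1)
        sl_b[ax] = slice(1, None)
        diff = labels_full[tuple(sl_a)] != labels_full[tuple(sl_b)]
        b[tuple(sl_a)] |= diff
        b[tuple(sl_b)] |= diff
    return b


def _membrane_from_partition(labels_full: np.ndarray, config: PhantomConfig) -> np.ndarray:
    """Membrane shell: interior voxels within half a thickness of a boundary.

    The shell is at least one voxel thick on each side of every boundary and
    is sealed against diagonal leaks: no two non-membrane voxels of
    different compartments (exterior included) are 26-adjacent, so any
    straight path from one compartment interior to another passes through
    at least one membrane voxel.
    """
    b = _boundary_voxels(labels_full)
    layers = max(1.0, config.membrane_thickness_um / (2 * config.spacing_um))
    dist = ndimage.distance_transform_edt(~b)
    memb = dist <= layers - 1 + 1e-6
    return _seal_diagonal_leaks(memb, labels_full)


def _seal_diagonal_leaks(memb: np.ndarray, labels_full: np.ndarray) -> np.ndarray:
    """Add membrane voxels until no 26-adjacent pair of non-membrane voxels
    carries two different compartment labels (staircase corners of the
    voxelized interface leak otherwise)."""
    memb = memb.copy()
    for _ in range(8):  # fixed point is reached in one or two passes
        lab = np.where(memb, -1, labels_full)
        leak = np.zeros(memb.shape, dtype=bool)
        for dz in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    if dz == dy == dx == 0:
                        continue
                    sl_a = tuple(slice(max(d, 0), s + min(d, 0))
                                 for d, s in zip((dz, dy, dx), memb.shape))
                    sl_b = tuple(slice(max(-d, 0), s + min(-d, 0))
                                 for d, s in zip((dz, dy, dx), memb.shape))
                    a, bb = lab[sl_a], lab[sl_b]
                    bad = (a != bb) & (a >= 0) & (bb >= 0)
                    leak[sl_a] |= bad
                    leak[sl_b] |= bad
        # the exterior background keeps its voxels; seal on the cell side
        leak &= labels_full > 0
        if not leak.any():
            return memb
        memb |= leak
    return memb


def _default_name(i: int) -> str:
    return f"C{i:02d}"


def generate_phantom(config: PhantomConfig) -> EmbryoPhantom:
    """Build a phantom: Voronoi cells, membrane shell, images, lineage."""
    rng = np.random.default_rng(config.rng_seed)
    inside = interior_mask(config)
    c = config.center_vox
    a = config.semiaxes_vox

    # deterministic seed points, uniform in a slightly shrunk ellipsoid so no
    # seed sits inside the outer membrane rim
    seeds = []
    while len(seeds) < config.n_cells:
        p = rng.uniform(-1, 1, size=3)
        if (p**2).sum() <= 0.9**2:
            seeds.append(c + p * a)
    seeds = np.asarray(seeds)  # (n, 3) voxel coords (z, y, x)

    # nearest-seed (Voronoi) partition of the interior
    vz, vy, vx = np.nonzero(inside)
    coords = np.stack([vz, vy, vx], axis=1).astype(float)
    best = np.full(len(coords), np.inf)
    lab = np.zeros(len(coords), dtype=np.int32)
    for i, s in enumerate(seeds):
        d2 = ((coords - s) ** 2).sum(axis=1)
        take = d2 < best
        best[take] = d2[take]
        lab[take] = i + 1
    full = np.zeros(config.grid_shape, dtype=np.int32)
    full[vz, vy, vx] = lab

    membrane = _membrane_from_partition(full, config)
    truth = full.copy()
    truth[membrane] = 0
    compartments = _compartment_partition(full, membrane)

    names = {i + 1: _default_name(i + 1) for i in range(config.n_cells)}
    for lab_id, name in names.items():
        if not (truth == lab_id).any():
            raise ValueError(f"cell {name} has zero interior voxels after "
                             "membrane carving; reduce n_cells or thickness")

    # lineage: one nucleus per cell at its compartment centroid
    rows = []
    for lab_id, name in names.items():
        zz2, yy2, xx2 = np.nonzero(compartments == lab_id)
        pos = np.array([xx2.mean(), yy2.mean(), zz2.mean()]) * config.spacing_um
        rows.append({"time": 1, "cell": name, "parent": "",
                     "x_um": pos[0], "y_um": pos[1], "z_um": pos[2]})
    lineage = pd.DataFrame(rows)

    membrane_image, nucleus_image = render_imaging(truth, config, lineage=lineage,
                                                   membrane=membrane)
    morph = atlas.morphology_table(compartments, config.spacing_um, names=names)
    return EmbryoPhantom(config=config, truth_labels=truth, membrane_mask=membrane,
                         voronoi=full, full_partition=compartments,
                         membrane_image=membrane_image,
                         nucleus_image=nucleus_image, lineage=lineage,
                         truth_morphology=morph, names=names)


def _compartment_partition(labels_full: np.ndarray, membrane: np.ndarray) -> np.ndarray:
    """Assign every voxel to the compartment whose interior is nearest.

    Compartment interiors are the non-membrane voxels (cells keep their
    label, exterior background is 0); each membrane voxel takes the label
    of the nearest interior voxel, which splits every membrane wall down
    its middle between the two compartments it separates.
    """
    interiors = np.where(membrane, 0, labels_full)
    _, (iz, iy, ix) = ndimage.distance_transform_edt(membrane, return_indices=True)
    return interiors[iz, iy, ix].astype(np.int32)


# ---------------------------------------------------------------------------
# imaging model
# ---------------------------------------------------------------------------

def _run_lengths(mask: np.ndarray, axis: int) -> np.ndarray:
    """Per-voxel length of the run of consecutive True voxels along ``axis``."""
    m = np.moveaxis(mask, axis, 0)
    fwd = np.zeros(m.shape, dtype=np.int32)
    acc = np.zeros(m.shape[1:], dtype=np.int32)
    for i in range(m.shape[0]):
        acc = (acc + 1) * m[i]
        fwd[i] = acc
    bwd = np.zeros(m.shape, dtype=np.int32)
    acc[:] = 0
    for i in range(m.shape[0] - 1, -1, -1):
        acc = (acc + 1) * m[i]
        bwd[i] = acc
    run = fwd + bwd - 1
    run[~m] = 0
    return np.moveaxis(run, 0, axis)


def _membrane_normal_z(membrane: np.ndarray) -> np.ndarray:
    """|n_z| of the local membrane sheet normal, estimated from chord lengths.

    A thin sheet is short across its normal and long along it, so the
    direction cosines are taken proportional to the inverse chord length of
    the membrane along each axis through the voxel.
    """
    inv = np.zeros((3,) + membrane.shape)
    for ax in range(3):
        run = _run_lengths(membrane, ax).astype(float)
        with np.errstate(divide="ignore"):
            inv[ax] = np.where(run > 0, 1.0 / run, 0.0)
    norm = np.sqrt((inv**2).sum(axis=0))
    nz = np.zeros(membrane.shape)
    ok = norm > 0
    nz[ok] = inv[0][ok] / norm[ok]
    return nz


def render_imaging(truth_labels: np.ndarray, config: PhantomConfig,
                   lineage: pd.DataFrame | None = None,
                   membrane: np.ndarray | None = None):
    """Render membrane and nucleus fluorescence channels from ground truth.

    Membrane intensity starts as the base signal on membrane voxels, is
    scaled by exp(-attenuation_coeff * depth_um) and by an orientation
    factor 1 - alpha * |n_z| (sheets parallel to the focal plane are
    dimmest), blurred with the anisotropic psf, offset by the detector
    background, degraded by additive Gaussian noise of sd
    noise_sd * base, and clipped to [0, 2 * base].

    ``truth_labels`` uses the membrane-carved convention; when the shell
    mask is not passed explicitly it is recovered as the zero-label voxels
    within one voxel of the embryo ellipsoid (the shell straddles the
    surface, so its outermost layer sits just outside).
    """
    if membrane is None:
        inside = interior_mask(config)
        near = ndimage.binary_dilation(inside, structure=np.ones((3, 3, 3), bool))
        membrane = (np.asarray(truth_labels) == 0) & near
    base = config.base_intensity
    s = config.spacing_um

    img = np.zeros(config.grid_shape, dtype=float)
    img[membrane] = base
    if config.attenuation_coeff > 0:
        depth_um = np.arange(config.grid_shape[0])[:, None, None] * s
        img *= np.exp(-config.attenuation_coeff * depth_um)
    if config.orientation_alpha > 0:
        img *= 1.0 - config.orientation_alpha * _membrane_normal_z(membrane)
    lat, axi = config.psf_sigma_um
    if lat > 0 or axi > 0:
        img = ndimage.gaussian_filter(img, sigma=(axi / s, lat / s, lat / s))
    img += config.background_level * base
    if config.noise_sd > 0:
        rng = np.random.default_rng(config.rng_seed + 1)
        img = img + rng.normal(0.0, config.noise_sd * base, size=img.shape)
    img = np.clip(img, 0.0, 2 * base)

    nucleus = np.zeros(config.grid_shape, dtype=float)
    if lineage is not None:
        nucleus = _render_nuclei(lineage, config)
    return img, nucleus


def _render_nuclei(lineage: pd.DataFrame, config: PhantomConfig) -> np.ndarray:
    base = config.base_intensity
    s = config.spacing_um
    sig = config.nucleus_sigma_um / s
    img = np.zeros(config.grid_shape, dtype=float)
    half = int(np.ceil(4 * sig))
    for _, r in lineage.iterrows():
        czyx = np.array([r["z_um"], r["y_um"], r["x_um"]]) / s
        lo = np.maximum(np.floor(czyx).astype(int) - half, 0)
        hi = np.minimum(np.floor(czyx).astype(int) + half + 1, config.grid_shape)
        grids = np.meshgrid(*(np.arange(lo[i], hi[i], dtype=float) for i in range(3)),
                            indexing="ij")
        d2 = sum((g - czyx[i]) ** 2 for i, g in enumerate(grids))
        img[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += base * np.exp(-d2 / (2 * sig**2))
    return np.clip(img, 0, 2 * base)


# ---------------------------------------------------------------------------
# perturbations: anaphase frames and cavities
# ---------------------------------------------------------------------------

def inject_division_frame(phantom: EmbryoPhantom, cell: str,
                          offset_um: float = 1.5) -> EmbryoPhantom:
    """Replace a cell's nucleus with two sister nuclei inside the same region.

    The region itself is untouched (the membrane is still shared during
    anaphase); the lineage gains daughter records "<cell>a" / "<cell>p" with
    the cell as parent at this frame, and the region's expected assigned
    name is recorded as the mother's.
    """
    inv = {v: k for k, v in phantom.names.items()}
    if cell not in inv:
        raise ValueError(f"unknown cell {cell!r}")
    label = inv[cell]
    if label in phantom.anaphase:
        raise ValueError(f"cell {cell!r} already carries an anaphase frame")
    row = phantom.lineage[(phantom.lineage["cell"] == cell)
                          & (phantom.lineage["time"] == phantom.time)]
    if row.empty:
        raise ValueError(f"cell {cell!r} has no nucleus record at t={phantom.time}")
    pos = row.iloc[0][["x_um", "y_um", "z_um"]].to_numpy(dtype=float)

    s = phantom.config.spacing_um
    region = phantom.truth_labels == label
    rng = np.random.default_rng(phantom.config.rng_seed + 1000 + label)
    axes = rng.permutation(3)  # axis indices in (x, y, z) order
    placed = None
    for ax in axes:
        delta = np.zeros(3)
        delta[ax] = offset_um
        pa, pb = pos + delta, pos - delta
        ok = True
        for p in (pa, pb):
            vox = np.round(np.array([p[2], p[1], p[0]]) / s).astype(int)
            if (vox < 0).any() or (vox >= np.array(region.shape)).any() \
                    or not region[tuple(vox)]:
                ok = False
        if ok:
            placed = (pa, pb)
            break
    if placed is None:
        raise ValueError(f"sister nuclei at offset {offset_um} um fall outside "
                         f"the region of cell {cell!r}")

    out = phantom.copy()
    keep = ~((out.lineage["cell"] == cell) & (out.lineage["time"] == out.time))
    new = pd.DataFrame([
        {"time": out.time, "cell": cell + "a", "parent": cell,
         "x_um": placed[0][0], "y_um": placed[0][1], "z_um": placed[0][2]},
        {"time": out.time, "cell": cell + "p", "parent": cell,
         "x_um": placed[1][0], "y_um": placed[1][1], "z_um": placed[1][2]},
    ])
    out.lineage = pd.concat([out.lineage[keep], new], ignore_index=True)
    out.nucleus_image = _render_nuclei(out.lineage, out.config)
    out.anaphase[label] = cell
    return out


def carve_cavity(phantom: EmbryoPhantom, location_um, radius_um: float) -> EmbryoPhantom:
    """Carve a spherical nucleus-free cavity (blastocoel-like) into the phantom.

    Voxels inside the sphere become a new compartment flagged as cavity; the
    membrane is recomputed so a shell straddles the sphere surface like
    every other boundary, and the compartment partition then hands the
    shell's inner half back to the cavity — its compartment volume stays
    the analytic sphere volume up to voxelization. No lineage record is
    added. Errors if the (dilated) sphere touches exterior background.
    """
    cfg = phantom.config
    s = cfg.spacing_um
    loc = np.asarray(location_um, dtype=float)  # (x, y, z) um
    center_vox = np.array([loc[2], loc[1], loc[0]]) / s
    zz, yy, xx = np.meshgrid(*(np.arange(n, dtype=float) for n in cfg.grid_shape),
                             indexing="ij")
    d2 = (zz - center_vox[0]) ** 2 + (yy - center_vox[1]) ** 2 + (xx - center_vox[2]) ** 2
    sphere = d2 <= (radius_um / s) ** 2
    if not sphere.any():
        raise ValueError("cavity radius below voxel resolution")
    dilated = ndimage.binary_dilation(sphere, structure=np.ones((3, 3, 3), bool))
    if (phantom.voronoi[dilated] == 0).any():
        raise ValueError("cavity touches exterior background")

    out = phantom.copy()
    new_label = int(out.voronoi.max()) + 1
    out.voronoi[sphere] = new_label
    out.membrane_mask = _membrane_from_partition(out.voronoi, cfg)
    out.truth_labels = out.voronoi.copy()
    out.truth_labels[out.membrane_mask] = 0
    out.full_partition = _compartment_partition(out.voronoi, out.membrane_mask)

    out.cavity_labels.add(new_label)
    out.names[new_label] = f"CAV{new_label:02d}"
    out.truth_morphology = atlas.morphology_table(
        out.full_partition, s, names=out.names, cavity_labels=out.cavity_labels)
    out.membrane_image, _ = render_imaging(out.truth_labels, cfg, lineage=None,
                                           membrane=out.membrane_mask)
    out.nucleus_image = _render_nuclei(out.lineage, cfg)
    return out


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def write_phantom(phantom: EmbryoPhantom, directory) -> None:
    """Write a phantom as TIFF volumes + lineage CSV + config JSON."""
    from pathlib import Path
    from . import io as msio
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    msio.write_volume(d / "membrane.tif", phantom.membrane_image)
    msio.write_volume(d / "nucleus.tif", phantom.nucleus_image)
    msio.write_labels(d / "truth_labels.tif", phantom.truth_labels)
    msio.write_labels(d / "membrane_mask.tif", phantom.membrane_mask.astype(np.uint8))
    msio.write_labels(d / "full_partition.tif", phantom.full_partition)
    msio.write_lineage(d / "lineage.csv", phantom.lineage)
    msio.write_json(d / "config.json", dataclasses.asdict(phantom.config))
    phantom.truth_morphology.to_csv(d / "morphology.csv", index=False)
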