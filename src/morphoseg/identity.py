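"""Naming segmented regions from nucleus lineage records.

Automated lineaging tools report, per time point, each nucleus's name,
parent and position. Those records name the membrane-derived partitions:
a region holding exactly one nucleus takes that nucleus's name; a region
holding two sister nuclei (anaphase, membrane still shared) takes the
mother's name; a nucleus-free region is a cavity if it is enclosed in the
embryo and background if it reaches the volume faces; nuclei that cannot
be paired one-to-one with a region are reported lost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

CAVITY = "CAVITY"
BACKGROUND = "BACKGROUND"


@dataclass
class NamedSegmentation:
    time: int
    status: dict[int, str]                     # label -> "cell" | CAVITY | BACKGROUND
    names: dict[int, str]                      # label -> assigned cell name
    lost: list[tuple[str, str]] = field(default_factory=list)   # (name, reason)
    resolved_daughters: dict[str, tuple[str, str]] = field(default_factory=dict)
    multiplicity: dict[int, int] = field(default_factory=dict)  # label -> nucleus count


def _region_of_nucleus(labels: np.ndarray, vox: np.ndarray) -> int:
    """Region containing a nucleus voxel; membrane/ridge voxels (label 0)
    fall back to the majority nonzero label in the 3x3x3 neighborhood."""
    z, y, x = vox
    lab = int(labels[z, y, x])
    if lab != 0:
        return lab
    sl = tuple(slice(max(c - 1, 0), min(c + 2, s))
               for c, s in zip(vox, labels.shape))
    neigh = labels[sl].ravel()
    neigh = neigh[neigh > 0]
    if neigh.size == 0:
        return 0
    vals, counts = np.unique(neigh, return_counts=True)
    return int(vals[np.argmax(counts)])


def _face_connected(labels: np.ndarray, label: int) -> bool:
    """True if the region touches a volume face or is 26-connected to
    face-reaching zero-label (exterior) background."""
    region = labels == label
    shape = np.array(labels.shape)
    vox = np.argwhere(region)
    if ((vox == 0) | (vox == shape - 1)).any():
        return True
    mask = region | (labels == 0)
    comp, _ = ndimage.label(mask, structure=np.ones((3, 3, 3), int))
    region_comps = set(np.unique(comp[region]))
    faces = np.zeros(labels.shape, dtype=bool)
    for ax in range(3):
        sl0 = [slice(None)] * 3
        sl1 = [slice(None)] * 3
        sl0[ax] = 0
        sl1[ax] = -1
        faces[tuple(sl0)] = True
        faces[tuple(sl1)] = True
    face_comps = set(np.unique(comp[faces & mask]))
    return bool(region_comps & face_comps)


def assign_names(labels: np.ndarray, lineage: pd.DataFrame, t: int,
                 spacing: float) -> NamedSegmentation:
    """Pair nuclei with regions at time point ``t`` and name every region."""
    recs = lineage[lineage["time"] == t]
    if recs.empty:
        raise ValueError(f"time point {t} absent from lineage")
    labels = np.asarray(labels)
    parent = dict(zip(recs["cell"], recs["parent"]))

    by_region: dict[int, list[tuple[str, np.ndarray]]] = {}
    out = NamedSegmentation(time=t, status={}, names={})
    for _, r in recs.iterrows():
        pos = np.array([r["z_um"], r["y_um"], r["x_um"]]) / spacing
        vox = np.round(pos).astype(int)
        if (vox < 0).any() or (vox >= np.array(labels.shape)).any():
            raise ValueError(f"nucleus {r['cell']!r} outside the volume")
        lab = _region_of_nucleus(labels, vox)
        if lab == 0:
            out.lost.append((r["cell"], "nucleus on background/membrane"))
            continue
        by_region.setdefault(lab, []).append((r["cell"], pos))

    all_labels = [int(v) for v in np.unique(labels) if v != 0]
    for lab in all_labels:
        nuclei = by_region.get(lab, [])
        out.multiplicity[lab] = len(nuclei)
        if len(nuclei) == 0:
            if _face_connected(labels, lab):
                out.status[lab] = BACKGROUND
            else:
                out.status[lab] = CAVITY
            continue
        out.status[lab] = "cell"
        if len(nuclei) == 1:
            out.names[lab] = nuclei[0][0]
        elif len(nuclei) == 2 and parent.get(nuclei[0][0]) \
                and parent.get(nuclei[0][0]) == parent.get(nuclei[1][0]):
            mother = parent[nuclei[0][0]]
            out.names[lab] = mother
            out.resolved_daughters[mother] = (nuclei[0][0], nuclei[1][0])
        else:
            # non-sister cohabitation: a segmentation merge error
            region_vox = np.argwhere(labels == lab)
            centroid = region_vox.mean(axis=0)
            d = [np.linalg.norm(p - centroid) for _, p in nuclei]
            keep = int(np.argmin(d))
            out.names[lab] = nuclei[keep][0]
            for i, (name, _) in enumerate(nuclei):
                if i != keep:
                    out.lost.append((name, "merged region (non-sister cohabitation)"))
    return out


def lost_cell_ratio(named_by_time: dict[int, NamedSegmentation],
                    lineage: pd.DataFrame) -> pd.DataFrame:
    """Per-time-point lost-cell counts and ratios.

    The expected count at t treats an anaphase sister pair as its mother
    (one membrane compartment), consistent with the naming rule.
    """
    rows = []
    for t, named in sorted(named_by_time.items()):
        recs = lineage[lineage["time"] == t]
        n_records = len(recs)
        # each sister pair resolved into its mother occupies one compartment
        n_total = n_records - len(named.resolved_daughters)
        n_lost = len(named.lost)
        rows.append({"time": t, "n_total": n_total, "n_lost": n_lost,
                     "ratio": (n_lost / n_total) if n_total else 0.0})
    return pd.DataFrame(rows)


def cell_lifespans(lineage: pd.DataFrame) -> pd.DataFrame:
    """Per-cell (first, last) frames with anaphase frames assigned to the mother.

    A daughter whose records begin while its mother's membrane compartment
    is still shared (its first frame coincides with sister records carrying
    the same parent while the mother still exists up to that frame) starts
    its own lifespan at the first frame after the shared ones.
    """
    spans = (lineage.groupby("cell")["time"].agg(["min", "max"])
             .rename(columns={"min": "first", "max": "last"}))
    parent_of = dict(lineage.drop_duplicates("cell")[["cell", "parent"]].values)
    rows = []
    for cell, r in spans.iterrows():
        first, last = int(r["first"]), int(r["last"])
        times = sorted(lineage.loc[lineage["cell"] == cell, "time"].unique())
        if times != list(range(first, last + 1)):
            raise ValueError(f"lifespan of {cell!r} is not contiguous: {times}")
        p = parent_of.get(cell, "")
        if p and p in spans.index:
            p_last = int(spans.loc[p, "last"])
            if first <= p_last:
                # frames shared with the mother's compartment belong to the mother
                first = p_last + 1
            elif first != p_last + 1:
                raise ValueError(
                    f"daughter {cell!r} first frame {first} does not follow "
                    f"mother {p!r} last frame {p_last}")
        rows.append({"cell": cell, "first": first, "last": last})
    out = pd.DataFrame(rows).set_index("cell")
    return out[out["first"] <= out["last"]]
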