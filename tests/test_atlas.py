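from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from morphoseg.atlas import (SPHERE_ETA, EffectiveContactCriteria,
                             _hcp_kissing_number, close_packing_contact_fraction,
                             contact_areas, effective_contacts, fit_powerlaw,
                             irregularity, measure_cell, morphology_table,
                             sister_ratio_stats, surface_area,
                             volume_inconsistency)


# ---------------------------------------------------------------------------
# irregularity and surface measurement
# ---------------------------------------------------------------------------

def test_irregularity_scale_free_and_sphere_minimum():
    S, V = 4 * np.pi * 3.0**2, 4 / 3 * np.pi * 3.0**3
    np.testing.assert_allclose(irregularity(S, V), SPHERE_ETA)
    lam = 2.7
    np.testing.assert_allclose(irregularity(lam**2 * S, lam**3 * V),
                               irregularity(S, V))
    with pytest.raises(ValueError):
        irregularity(0.0, 1.0)
    with pytest.raises(ValueError):
        irregularity(1.0, -1.0)


def _ball(radius, pad=4):
    n = 2 * radius + 2 * pad
    zz, yy, xx = np.meshgrid(*([np.arange(n)] * 3), indexing="ij")
    c = (n - 1) / 2
    return (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def test_surface_area_of_ball():
    r = 12
    S = surface_area(_ball(r), spacing=0.5)
    exact = 4 * np.pi * (r * 0.5) ** 2
    assert abs(S - exact) / exact < 0.02


def test_measure_cell_box():
    labels = np.zeros((8, 8, 8), dtype=int)
    labels[2:6, 2:6, 2:6] = 3
    V, S, c = measure_cell(labels, 3, spacing=0.5)
    np.testing.assert_allclose(V, 64 * 0.5**3)
    np.testing.assert_allclose(c, [3.5 * 0.5] * 3)
    with pytest.raises(ValueError):
        measure_cell(labels, 9, spacing=0.5)


def test_morphology_table_columns_and_cavity_flag():
    labels = np.zeros((10, 10, 10), dtype=int)
    labels[1:5, 1:5, 1:5] = 1
    labels[5:9, 5:9, 5:9] = 2
    table = morphology_table(labels, 0.5, names={1: "A"}, cavity_labels={2},
                             embryo="e1", time=4)
    assert list(table["cell"]) == ["A", "L2"]
    assert list(table["is_cavity"]) == [False, True]
    assert set(table.columns) >= {"embryo", "time", "label", "cell",
                                  "volume_um3", "surface_um2", "eta",
                                  "cx", "cy", "cz"}
    # note: eta >= SPHERE_ETA only holds for well-resolved regions; tiny
    # 4-voxel cubes undershoot because pre-mesh smoothing shrinks the
    # measured surface relative to the voxel-count volume
    assert (table["eta"] > 0).all()


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------

def test_contact_areas_plane_interface():
    labels = np.ones((4, 6, 6), dtype=int)
    labels[2:] = 2
    df = contact_areas(labels, spacing=0.5)
    assert len(df) == 1
    np.testing.assert_allclose(df["area_um2"].iloc[0], 36 * 0.25)
    assert df.iloc[0]["cell_a"] == "L1" and df.iloc[0]["cell_b"] == "L2"


def test_contact_areas_bridge_ridge_and_exclude():
    labels = np.ones((5, 4, 4), dtype=int)
    labels[2] = 0                 # one-voxel membrane dam
    labels[3:] = 2
    assert contact_areas(labels, 0.5).empty
    bridged = contact_areas(labels, 0.5, bridge_ridge=True)
    np.testing.assert_allclose(bridged["area_um2"].iloc[0], 16 * 0.25)
    assert contact_areas(labels, 0.5, bridge_ridge=True, exclude={2}).empty


def test_close_packing_constants():
    assert _hcp_kissing_number() == 12
    assert close_packing_contact_fraction() == Fraction(1, 48)
    with pytest.raises(ValueError):
        close_packing_contact_fraction(replacement_count=0)


def test_effective_contact_criteria_validation():
    with pytest.raises(ValueError):
        EffectiveContactCriteria(area_fraction_min=0.0)
    with pytest.raises(ValueError):
        EffectiveContactCriteria(reproducibility_fraction=1.5)


def test_effective_contacts_duration_and_reproducibility():
    # pair (A, B) is large enough in both embryos but persists long enough
    # only in e1+e2; pair (A, C) is always below the area fraction.
    rows = []
    for emb in ("e1", "e2"):
        for t in (1, 2, 3):
            rows.append({"embryo": emb, "time": t, "cell_a": "A",
                         "cell_b": "B", "area_um2": 30.0})
            rows.append({"embryo": emb, "time": t, "cell_a": "A",
                         "cell_b": "C", "area_um2": 0.1})
    records = pd.DataFrame(rows)
    morph = pd.DataFrame([
        {"embryo": emb, "cell": c, "time": t, "surface_um2": 400.0}
        for emb in ("e1", "e2") for c in ("A", "B", "C") for t in (1, 2, 3)])
    crit = EffectiveContactCriteria(min_consecutive_frames=2,
                                    min_duration_min=3.0)
    out = effective_contacts(records, morph, crit, frame_interval_min=1.5)
    assert len(out) == 1
    assert (out.iloc[0]["cell_a"], out.iloc[0]["cell_b"]) == ("A", "B")
    assert out.iloc[0]["n_embryos_passing"] == 2
    # a single-frame contact fails the duration requirement
    single = records[records["time"] == 1]
    assert effective_contacts(single, morph, crit).empty


# ---------------------------------------------------------------------------
# temporal consistency and scaling laws
# ---------------------------------------------------------------------------

def test_volume_inconsistency():
    rho, t_c = volume_inconsistency([10.0, 10.0, 10.0])
    assert rho == 0.0 and t_c is None
    v = np.array([8.0, 10.0, 12.0])
    rho, t_c = volume_inconsistency(v, lifespan_mid=30.0, total_time=60.0)
    np.testing.assert_allclose(rho, v.std() / v.mean())
    np.testing.assert_allclose(t_c, 0.5)
    with pytest.raises(ValueError):
        volume_inconsistency([5.0])


def test_fit_powerlaw_exact():
    V = np.array([10.0, 20.0, 50.0, 100.0])
    T = 3.0 * V**-0.293
    slope, intercept = fit_powerlaw(T, V)
    np.testing.assert_allclose(slope, -0.293, atol=1e-12)
    np.testing.assert_allclose(np.exp(intercept), 3.0)
    with pytest.raises(ValueError):
        fit_powerlaw([1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        fit_powerlaw([1.0, -2.0, 3.0], [1.0, 2.0, 3.0])


def test_sister_ratio_stats():
    lineage = pd.DataFrame([
        {"time": 1, "cell": "Ma", "parent": "M", "x_um": 0, "y_um": 0, "z_um": 0},
        {"time": 1, "cell": "Mp", "parent": "M", "x_um": 0, "y_um": 0, "z_um": 0},
    ])
    morph = pd.DataFrame([
        {"embryo": e, "cell": c, "time": 1, "volume_um3": v, "surface_um2": s}
        for e, c, v, s in [("e1", "Ma", 100.0, 110.0), ("e1", "Mp", 50.0, 60.0),
                           ("e2", "Ma", 90.0, 100.0), ("e2", "Mp", 45.0, 55.0)]])
    out = sister_ratio_stats(morph, lineage)
    assert len(out) == 1
    np.testing.assert_allclose(out.iloc[0]["volume_ratio_mean"], 0.5)
    assert out.iloc[0]["n_embryos"] == 2
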