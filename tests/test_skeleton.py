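"""Bundle morphometrics: snake I/O, orientational correlation and the
persistence-length pipeline."""
import xml.etree.ElementTree as ET

import numpy as np
import pytest

import asterforge as af
from asterforge.skeleton import (Polyline, CorrelationProfile,
                                 read_soax_snakes, write_soax_snakes,
                                 read_polylines, write_polylines,
                                 write_cmm_markers,
                                 orientational_correlation,
                                 fit_persistence_length, bundle_geometry,
                                 cohort_persistence_length)

SOAX_FIXTURE = """\
# synthetic snake file in the SOAX result dialect (not real image data)
intensity-scaling 0.0
gaussian-std 0.0
ridge-threshold 0.01
s p x y z fg_int bg_int
0 0 1.0 0.0 0.0 210.0 30.0
0 1 2.0 0.1 0.0 208.0 30.0
0 2 3.0 0.1 0.1 207.0 30.0
0 3 4.0 0.2 0.1 206.0 30.0
0 4 5.0 0.2 0.2 207.0 30.0
0 5 6.0 0.3 0.2 208.0 30.0
0 6 7.0 0.3 0.3 209.0 30.0
0 7 8.0 0.4 0.3 210.0 30.0
0 8 9.0 0.4 0.4 211.0 30.0
0 9 10.0 0.5 0.4 210.0 30.0
1 0 0.0 5.0 1.0 190.0 28.0
1 1 0.5 5.5 1.0 191.0 28.0
1 2 1.0 6.0 1.1 192.0 28.0
1 3 1.5 6.5 1.1 191.0 28.0
1 4 2.0 7.0 1.2 190.0 28.0
1 5 2.5 7.5 1.2 191.0 28.0
1 6 3.0 8.0 1.3 192.0 28.0
1 7 3.5 8.5 1.3 191.0 28.0
1 8 4.0 9.0 1.4 190.0 28.0
1 9 4.5 9.5 1.4 191.0 28.0
[junctions]
1.0 6.0 1.1
"""


# ------------------------------------------------------------------- I/O
def test_read_soax_fixture(tmp_path):
    p = tmp_path / "snakes.txt"
    p.write_text(SOAX_FIXTURE)
    polys = read_soax_snakes(p)
    assert len(polys) == 2
    assert all(len(q.points) == 10 for q in polys)
    assert polys[0].points[0] == pytest.approx([1.0, 0.0, 0.0])
    assert polys[1].points[-1] == pytest.approx([4.5, 9.5, 1.4])
    assert polys[0].junctions is not None


def test_read_soax_empty_file(tmp_path):
    p = tmp_path / "empty.txt"
    p.write_text("")
    assert read_soax_snakes(p) == []


def test_soax_round_trip(tmp_path):
    p = tmp_path / "snakes.txt"
    p.write_text(SOAX_FIXTURE)
    polys = read_soax_snakes(p)
    q = tmp_path / "rt.txt"
    write_soax_snakes(polys, q)
    back = read_soax_snakes(q)
    for a, b in zip(polys, back):
        assert np.allclose(a.points, b.points, atol=1e-6)


def test_read_soax_malformed_row_reports_line(tmp_path):
    p = tmp_path / "bad.txt"
    p.write_text("s p x y z fg bg\n0 0 1.0 2.0 0.0 1 1\n0 1 3.0\n")
    with pytest.raises(ValueError, match="line 3"):
        read_soax_snakes(p)


def test_plain_polyline_round_trip(tmp_path):
    pts = np.column_stack([np.linspace(0, 5, 8),
                           np.sin(np.linspace(0, 2, 8)),
                           np.linspace(0, 1, 8)])
    polys = [Polyline(3, pts)]
    f = tmp_path / "p.txt"
    write_polylines(polys, f)
    back = read_polylines(f)
    assert len(back) == 1 and back[0].id == 3
    assert np.allclose(back[0].points, pts, atol=1e-6)


def test_cmm_markers_structure_and_colors(tmp_path):
    pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 5.0], [2.0, 0.0, 10.0]])
    f = tmp_path / "m.cmm"
    write_cmm_markers([Polyline(0, pts)], f, z_colormap="viridis")
    root = ET.parse(f).getroot()
    assert root.tag == "marker_set"
    markers = root.findall("marker")
    links = root.findall("link")
    assert len(markers) == 3 and len(links) == 2
    for m in markers:
        for attr in ("x", "y", "z", "r", "g", "b"):
            assert attr in m.attrib
    # z extremes get colormap extremes
    import matplotlib
    cmap = matplotlib.colormaps["viridis"]
    lo = tuple(float(markers[0].get(c)) for c in "rgb")
    hi = tuple(float(markers[2].get(c)) for c in "rgb")
    assert lo == pytest.approx(cmap(0.0)[:3], abs=1e-3)
    assert hi == pytest.approx(cmap(1.0)[:3], abs=1e-3)


def test_cmm_constant_z_single_color(tmp_path):
    pts = np.column_stack([np.arange(4.0), np.zeros(4), np.full(4, 2.0)])
    f = tmp_path / "m.cmm"
    write_cmm_markers([Polyline(0, pts)], f)
    root = ET.parse(f).getroot()
    colors = {tuple(m.get(c) for c in "rgb")
              for m in root.findall("marker")}
    assert len(colors) == 1


# ------------------------------------------- correlation and geometry
def test_correlation_straight_line_is_one():
    pts = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    prof = orientational_correlation(Polyline(0, pts))
    assert prof.C[0] == pytest.approx(1.0)
    assert np.allclose(prof.C, 1.0, atol=1e-12)


def test_correlation_of_circular_arc_matches_cos_s_over_R():
    """Chord directions on a circle of radius R rotate uniformly:
    C(s) = cos(s/R) with s the arc separation between chords."""
    R = 5.0
    n = 60
    dphi = 0.05                      # radians per step
    phi = np.arange(n) * dphi
    pts = np.column_stack([R * np.cos(phi), R * np.sin(phi), np.zeros(n)])
    prof = orientational_correlation(Polyline(0, pts))
    # chord length per step = 2R sin(dphi/2); the profile bins by chord
    # arc, but successive chord DIRECTIONS rotate by exactly dphi
    chord = 2 * R * np.sin(dphi / 2)
    k = np.rint(prof.s / chord).astype(int)
    expected = np.cos(k * dphi)
    assert np.allclose(prof.C, expected, atol=1e-10)


def test_correlation_mirrored_polyline_identical(rng):
    pts = rng.normal(0, 1, (20, 3)).cumsum(axis=0)
    a = orientational_correlation(Polyline(0, pts))
    m = pts * np.array([1.0, -1.0, 1.0])      # mirror in y
    b = orientational_correlation(Polyline(0, m))
    assert np.allclose(a.C, b.C, atol=1e-12)
    assert np.allclose(a.s, b.s)


def test_wlc_cohort_correlation_matches_exponential():
    spec = af.WLCSpec(lp=20.0, bond_length=0.2, contour_range=(10.0, 10.0),
                      n_chains=200, seed=6)
    chains = af.generate_wlc(spec)
    profs = [orientational_correlation(c) for c in chains]
    s = profs[0].s
    C = np.mean([p.C[:len(s)] for p in profs], axis=0)
    sel = s <= 5.0
    assert np.allclose(C[sel], np.exp(-s[sel] / 20.0), atol=0.03)


def test_fit_exact_exponential_profile():
    s = np.arange(0.0, 5.01, 0.5)
    prof = CorrelationProfile(s, np.exp(-s / 10.0), np.ones_like(s))
    fit = fit_persistence_length(prof, L=10.0)
    assert fit.lp == pytest.approx(10.0, rel=1e-9)
    assert fit.r_squared == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.accepted


def test_fit_straight_polyline_rejected():
    s = np.arange(0.0, 5.01, 0.5)
    prof = CorrelationProfile(s, np.ones_like(s), np.ones_like(s))
    fit = fit_persistence_length(prof, L=10.0)
    assert not fit.accepted
    assert np.isinf(fit.lp)


def test_fit_filters_reject_noise_and_length(rng):
    s = np.arange(0.0, 5.01, 0.5)
    noisy = np.abs(rng.normal(0.5, 0.3, len(s)))
    noisy[0] = 1.0
    fit = fit_persistence_length(
        CorrelationProfile(s, noisy, np.ones_like(s)), L=10.0,
        max_bond_separations=None)
    assert fit.r_squared <= 0.8 and not fit.accepted
    # perfect profile but bundle too long → rejected by the length window
    good = np.exp(-s / 10.0)
    fit = fit_persistence_length(
        CorrelationProfile(s, good, np.ones_like(s)), L=25.0)
    assert not fit.accepted


def test_fit_requires_three_positive_points():
    s = np.array([0.0, 0.5, 1.0])
    C = np.array([1.0, -0.1, -0.2])
    with pytest.raises(ValueError, match="3 usable"):
        fit_persistence_length(CorrelationProfile(s, C, np.ones(3)), L=10.0)


def test_bundle_geometry_regular_polygon():
    phi = np.linspace(0, 2 * np.pi, 101)   # closed: last point = first
    pts = np.column_stack([5 * np.cos(phi), 5 * np.sin(phi),
                           np.zeros(101)])
    geo = bundle_geometry(Polyline(0, pts))
    assert geo["mean_radius_of_curvature"] == pytest.approx(5.0, rel=1e-9)
    assert geo["center_of_mass"] == pytest.approx([0.0, 0.0, 0.0],
                                                  abs=1e-9)
    side = 2 * 5 * np.sin(np.pi / 100)
    assert geo["contour_length"] == pytest.approx(100 * side, rel=1e-9)


def test_bundle_geometry_straight_line_infinite_radius():
    pts = np.column_stack([np.arange(6.0), np.zeros(6), np.zeros(6)])
    geo = bundle_geometry(Polyline(0, pts))
    assert geo["contour_length"] == pytest.approx(5.0)
    assert np.isinf(geo["mean_radius_of_curvature"])
    assert geo["n_collinear_triplets"] == 4


def test_bundle_geometry_noisy_circle_radius_recovery(rng):
    # sampling coarse enough that the triplet sagitta (~0.37 µm for an
    # octagon of circumradius 5) dominates the 0.05 µm point noise
    vals = []
    for _ in range(100):
        phi = np.linspace(0, 2 * np.pi, 9)[:-1]
        pts = np.column_stack([5 * np.cos(phi), 5 * np.sin(phi),
                               np.zeros(8)]) + rng.normal(0, 0.05, (8, 3))
        geo = bundle_geometry(Polyline(0, pts))
        vals.append(geo["mean_radius_of_curvature"])
    assert np.mean(vals) == pytest.approx(5.0, rel=0.05)


# ------------------------------------------------------------- cohorts
def test_cohort_recovers_wlc_ground_truth():
    spec = af.WLCSpec(lp=33.3, bond_length=0.2, contour_range=(8, 20),
                      n_chains=100, seed=42)
    res = cohort_persistence_length(af.generate_wlc(spec))
    assert res["mean_lp"] == pytest.approx(33.3, rel=0.10)
    assert res["n_accepted"] > 50


def test_cohort_identical_profiles_sem_zero():
    pts = np.column_stack([np.arange(0, 12.2, 0.2)]
                          + [np.zeros(61), np.zeros(61)])
    pts[:, 1] = 0.3 * np.sin(pts[:, 0] / 2.0)   # gentle bend, L in window
    cohort = [Polyline(i, pts) for i in range(5)]
    res = cohort_persistence_length(cohort)
    assert res["n_accepted"] == 5
    assert res["sem_lp"] == pytest.approx(0.0, abs=1e-12)
    assert res["sd_lp"] == pytest.approx(0.0, abs=1e-12)


def test_cohort_length_filter_excludes_out_of_window():
    inside = af.generate_wlc(af.WLCSpec(lp=30.0, contour_range=(10, 10),
                                        n_chains=5, seed=1))
    outside = af.generate_wlc(af.WLCSpec(lp=30.0, contour_range=(25, 25),
                                         n_chains=5, seed=2))
    res = cohort_persistence_length(inside + outside)
    assert res["n_accepted"] <= 5
    assert res["n_total"] == 10
    for f in res["fits"]:
        if f.contour_length > 20:
            assert not f.accepted


def test_cohort_all_rejected_raises():
    chains = af.generate_wlc(af.WLCSpec(lp=30.0, contour_range=(30, 30),
                                        n_chains=3, seed=3))
    with pytest.raises(ValueError, match="no bundle"):
        cohort_persistence_length(chains)


def test_lp_uncorrelated_with_length():
    """|Pearson r| between accepted L_p′ and bundle length < 0.2."""
    chains = af.generate_wlc(af.WLCSpec(lp=50.0, bond_length=0.2,
                                        contour_range=(8, 20),
                                        n_chains=200, seed=8))
    res = cohort_persistence_length(chains)
    acc = [f for f in res["fits"] if f.accepted and np.isfinite(f.lp)]
    lp = np.array([f.lp for f in acc])
    L = np.array([f.contour_length for f in acc])
    r = np.corrcoef(lp, L)[0, 1]
    assert abs(r) < 0.2
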