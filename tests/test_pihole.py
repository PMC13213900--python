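"""Axial candidate search, sector profiles, validation, whole-complex runs."""

import numpy as np
import pytest

from piholescan.chemio import ScalarGrid
from piholescan.espfield import CoverageError, FieldSpec, GridRequest, \
    point_charge_field
from piholescan.fixtures import make_grids, mirror_bump_fixture
from piholescan.frame import Frame, fit_plane
from piholescan.pihole import (
    DetectionParams,
    PiHoleCandidate,
    SectorProfile,
    analyze_complex,
    scan_axis,
    sector_profile,
    validate,
)

from conftest import dense_axial_local_maxima

IDENTITY_FRAME = Frame(np.zeros(3), np.eye(3))


def symmetric_grid_spec(charges=(), gaussians=(), half=6.0, n=91):
    req = GridRequest(origin=-half * np.ones(3), shape=(n, n, n),
                      spacing=2 * half / (n - 1))
    return FieldSpec(charges=list(charges), gaussians=list(gaussians),
                     grid=req)


# ---------------------------------------------------------------------------
# scan_axis
# ---------------------------------------------------------------------------


def test_monopole_has_no_axial_candidate():
    spec = symmetric_grid_spec(charges=[(2.0, np.zeros(3))])
    esp = point_charge_field(spec)
    params = DetectionParams(zmin=0.5)
    for hemisphere in ("+z", "-z"):
        assert scan_axis(esp, IDENTITY_FRAME, hemisphere, params) == []


def test_bump_candidate_matches_dense_oracle(bump_fixture, bump_grids):
    esp, _ = bump_grids
    fr = fit_plane(bump_fixture.molecule.coords[:4])
    cands = scan_axis(esp, fr, "+z")
    assert len(cands) == 1
    c = cands[0]
    assert abs(c.z - 2.0) <= 0.05
    assert c.curvature < 0
    oracle = dense_axial_local_maxima(bump_fixture.spec)
    assert len(oracle) == 1
    assert abs(c.z - oracle[0]) <= 0.05  # within one scan step


def test_mirror_symmetric_bumps_give_symmetric_candidates():
    fx = mirror_bump_fixture()
    spec = symmetric_grid_spec(charges=fx.spec.charges,
                               gaussians=fx.spec.gaussians)
    esp = point_charge_field(spec)
    up = scan_axis(esp, IDENTITY_FRAME, "+z")
    dn = scan_axis(esp, IDENTITY_FRAME, "-z")
    assert len(up) == 1 and len(dn) == 1
    assert abs(up[0].z) == pytest.approx(abs(dn[0].z), abs=1e-6)
    assert up[0].V == pytest.approx(dn[0].V, abs=1e-6)


def test_scan_axis_coverage_error_on_small_grid():
    req = GridRequest(origin=-np.ones(3), shape=(9, 9, 9), spacing=0.25)
    esp = point_charge_field(FieldSpec(charges=[(1.0, np.zeros(3))],
                                       grid=req))
    with pytest.raises(CoverageError):
        scan_axis(esp, IDENTITY_FRAME, "+z")


def test_lateral_confirmation_rejects_off_axis_maximum():
    """A ridge that is higher off-axis at the same z fails the probe check."""
    gauss = [(60.0, np.array([1.0, 0.0, 2.0]), 0.45)]
    spec = symmetric_grid_spec(charges=[(0.05, np.zeros(3))], gaussians=gauss)
    esp = point_charge_field(spec)
    with_probe = scan_axis(esp, IDENTITY_FRAME, "+z", DetectionParams())
    without = scan_axis(esp, IDENTITY_FRAME, "+z",
                        DetectionParams(lateral_check=False))
    assert with_probe == []
    assert len(without) >= 1


# ---------------------------------------------------------------------------
# sector_profile
# ---------------------------------------------------------------------------


def _candidate(z=2.0, V=0.0):
    return PiHoleCandidate(z=z, position=np.array([0, 0, z]), V=V,
                           curvature=-1.0, hemisphere="+z")


def test_sector_profile_constant_field_exact():
    grid = ScalarGrid(-6 * np.ones(3), np.eye(3) * 0.2,
                      np.full((61, 61, 61), 3.5), "esp_kcalmol")
    prof = sector_profile(grid, _candidate(), IDENTITY_FRAME)
    assert prof.sector_means == pytest.approx([3.5] * 8, abs=1e-12)
    assert prof.samples_per_sector == 1000


def test_sector_profile_linear_field_antisymmetry():
    req = GridRequest(origin=-6 * np.ones(3), shape=(61, 61, 61), spacing=0.2)
    nodes = req.node_coordinates()
    grid = ScalarGrid(req.origin, req.axes(), 4.0 * nodes[..., 0],
                      "esp_kcalmol")
    prof = sector_profile(grid, _candidate(), IDENTITY_FRAME)
    m = prof.sector_means
    # opposing sectors are exactly antisymmetric for V = a*x
    for i in range(4):
        assert m[i] == pytest.approx(-m[i + 4], abs=1e-6)
    assert m[2] == pytest.approx(0.0, abs=1e-6)  # sector centred on +y


def test_sector_profile_against_monte_carlo_oracle(depletion_fixture,
                                                   depletion_grids):
    """Stratified sector means agree with a dense seeded MC estimate."""
    esp, _ = depletion_grids
    fr = fit_plane(depletion_fixture.molecule.coords[:4])
    cand = scan_axis(esp, fr, "+z")[0]
    prof = sector_profile(esp, cand, fr)

    from piholescan.espfield import sample as grid_sample
    from piholescan.frame import unalign

    rng = np.random.default_rng(2024)
    n = 1_000_000
    params = DetectionParams()
    width = 2 * np.pi / 8
    for i in range(8):
        r = np.sqrt(rng.random(n)) * params.sector_radius
        theta = i * width + (rng.random(n) - 0.5) * width
        z = cand.z + (rng.random(n) - 0.5) * 2 * params.sector_halfheight
        pts = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
        mc = grid_sample(esp, unalign(pts, fr)).mean()
        assert prof.sector_means[i] == pytest.approx(mc, rel=0.005)


def test_sector_profile_random_sampler_close_to_stratified(depletion_fixture,
                                                           depletion_grids):
    esp, _ = depletion_grids
    fr = fit_plane(depletion_fixture.molecule.coords[:4])
    cand = scan_axis(esp, fr, "+z")[0]
    strat = sector_profile(esp, cand, fr)
    rand = sector_profile(esp, cand, fr,
                          DetectionParams(sampler="random", seed=11))
    # 1000 uniform draws carry ~2% Monte-Carlo noise on these fields
    assert np.allclose(rand.sector_means, strat.sector_means, rtol=0.05)
    rand2 = sector_profile(esp, cand, fr,
                           DetectionParams(sampler="random", seed=11))
    assert np.array_equal(rand.sector_means, rand2.sector_means)


# ---------------------------------------------------------------------------
# validate
# ---------------------------------------------------------------------------


def _profile(means):
    means = np.asarray(means, dtype=float)
    return SectorProfile(means, 45.0 * np.arange(8), 1000)


def test_validate_flat_background_invalid():
    res = validate(_candidate(V=10.0), _profile([10.0] * 8))
    assert res.v_hole_mean == 0.0 and res.dv_hole == 0.0
    assert not res.valid and res.status == "failed_validation"


def test_validate_descriptor_identities_on_printed_values():
    """Constructed sector means reproducing a published Zn complex row:
    V_hole,mean 30.30, V_hole,max 41.83, V_hole,min 19.76."""
    V = 100.0
    means = np.full(8, V - 30.135)
    means[2] = V - 41.83  # lowest-mean sector -> V_hole,max
    means[6] = V - 19.76  # highest-mean sector -> V_hole,min
    res = validate(_candidate(V=V), _profile(means))
    assert res.v_hole_mean == pytest.approx(30.30, abs=1e-9)
    assert res.v_hole_max == pytest.approx(41.83, abs=1e-12)
    assert res.v_hole_min == pytest.approx(19.76, abs=1e-12)
    assert res.dv_hole == pytest.approx(22.07, abs=1e-9)
    assert res.v_hole_min <= res.v_hole_mean <= res.v_hole_max
    assert res.valid
    assert res.dv_angle_deg == 180.0


def test_validate_negative_mean_fails_threshold():
    # a candidate sitting 0.90 below the sector mean is not a pi-hole
    means = np.full(8, 10.9)
    res = validate(_candidate(V=10.0), _profile(means))
    assert res.v_hole_mean == pytest.approx(-0.90)
    assert not res.valid


@pytest.mark.parametrize("i_max, i_min, expect", [
    (0, 4, 180.0), (0, 1, 45.0), (1, 0, 45.0), (0, 7, 45.0),
    (2, 7, 135.0), (0, 2, 90.0),
])
def test_dv_angle_circular_separation(i_max, i_min, expect):
    means = np.zeros(8)
    means[i_max] = 1.0
    means[i_min] = -1.0
    res = validate(_candidate(V=5.0), _profile(means))
    assert res.dv_angle_deg == expect


def test_dv_hole_identity_always_holds(suite_with_grids):
    for fx, esp, dens in suite_with_grids:
        for res in analyze_complex(fx.molecule, esp, dens):
            if res.profile is None:
                continue
            spread = res.profile.sector_means.max() - res.profile.sector_means.min()
            assert res.dv_hole == pytest.approx(spread, abs=1e-12)
            assert res.v_hole_min <= res.v_hole_mean <= res.v_hole_max


# ---------------------------------------------------------------------------
# analyze_complex
# ---------------------------------------------------------------------------


def test_axial_depletion_detected_in_band(depletion_fixture, depletion_grids):
    esp, dens = depletion_grids
    results = analyze_complex(depletion_fixture.molecule, esp, dens)
    up = next(r for r in results if r.hemisphere == "+z")
    dn = next(r for r in results if r.hemisphere == "-z")
    assert up.status == "validated" and up.valid
    assert 1.8 <= up.candidate.z <= 2.4
    assert dn.status == "no_candidate"
    assert up.vs_max is not None and dn.vs_max == up.vs_max


def test_blocked_axis_yields_no_candidate(blocked_fixture, blocked_grids):
    esp, dens = blocked_grids
    results = analyze_complex(blocked_fixture.molecule, esp, dens)
    assert all(r.status == "no_candidate" for r in results)
    assert all(not r.valid for r in results)


def test_constant_shift_leaves_relative_descriptors(depletion_fixture,
                                                    depletion_grids):
    """Adding a constant to the ESP must not move any relative
    descriptor, while the absolute surface maximum shifts exactly."""
    esp, dens = depletion_grids
    shift = 37.5
    shifted = ScalarGrid(esp.origin, esp.axes, esp.values + shift,
                         esp.kind)
    base = analyze_complex(depletion_fixture.molecule, esp, dens)
    moved = analyze_complex(depletion_fixture.molecule, shifted, dens)
    for a, b in zip(base, moved):
        assert b.vs_max == pytest.approx(a.vs_max + shift, abs=1e-9)
        if a.candidate is None:
            assert b.candidate is None
            continue
        assert b.v_hole_mean == pytest.approx(a.v_hole_mean, abs=1e-9)
        assert b.v_hole_max == pytest.approx(a.v_hole_max, abs=1e-9)
        assert b.v_hole_min == pytest.approx(a.v_hole_min, abs=1e-9)
        assert b.dv_hole == pytest.approx(a.dv_hole, abs=1e-9)
        assert b.dv_angle_deg == a.dv_angle_deg
        assert b.candidate.z == a.candidate.z


def test_rigid_motion_equivariance_right_angle(depletion_fixture):
    """90° rotation + generic translation with regenerated grids."""
    from piholescan.fixtures import Fixture

    fx = depletion_fixture
    R = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
    t = np.array([1.37, -0.82, 2.05])
    mol2 = fx.molecule.copy()
    mol2.coords = fx.molecule.coords @ R.T + t
    fx2 = Fixture("moved", mol2, fx.spec.rotated(R, t), fx.expected_z)

    base = analyze_complex(fx.molecule, *make_grids(fx))
    moved = analyze_complex(fx2.molecule, *make_grids(fx2))
    for a, b in zip(base, moved):
        assert a.status == b.status
        if a.candidate is None:
            continue
        assert b.candidate.V == pytest.approx(a.candidate.V, abs=1e-3)
        assert abs(b.candidate.z) == pytest.approx(abs(a.candidate.z),
                                                   abs=1e-6)
        assert b.v_hole_mean == pytest.approx(a.v_hole_mean, abs=1e-3)
        assert b.dv_hole == pytest.approx(a.dv_hole, abs=1e-3)
        assert b.vs_max == pytest.approx(a.vs_max, abs=1e-3)


def test_generic_rotation_equivariance_within_interpolation_error(
        depletion_fixture):
    """A generic-angle rigid motion agrees to interpolation accuracy."""
    from scipy.spatial.transform import Rotation
    from piholescan.fixtures import Fixture

    fx = depletion_fixture
    R = Rotation.from_euler("zyx", [33.0, 14.0, -27.0], degrees=True
                            ).as_matrix()
    t = np.array([0.6, 1.1, -0.4])
    mol2 = fx.molecule.copy()
    mol2.coords = fx.molecule.coords @ R.T + t
    fx2 = Fixture("moved", mol2, fx.spec.rotated(R, t), fx.expected_z)
    base = analyze_complex(fx.molecule, *make_grids(fx))
    moved = analyze_complex(fx2.molecule, *make_grids(fx2))
    up_a = next(r for r in base if r.candidate is not None)
    up_b = next(r for r in moved if r.candidate is not None)
    # tolerance is the trilinear interpolation scale h²·V''/8 ≈ 3 kcal/mol
    # for the sharp axial feature on a 0.13 Å grid
    assert up_b.v_hole_mean == pytest.approx(up_a.v_hole_mean, abs=4.0)
    assert abs(up_b.candidate.z) == pytest.approx(abs(up_a.candidate.z),
                                                  abs=0.1)
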