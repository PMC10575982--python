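"""Tests for oxDNA parsing, RMSD/RMSF, guide points, and helix fitting."""

import numpy as np
import pytest

from nanospring.exceptions import DegenerateGeometryError, DomainError, ParseError
from nanospring.synthetic import gen_helix_points, gen_trajectory
from nanospring.trajectory import (
    OXDNA_LENGTH_NM,
    OXDNA_TIME_PS,
    Trajectory,
    average_guide_points,
    compare_backbone_pier,
    fit_helix,
    read_oxdna,
    rmsd_trace,
    rmsf,
    select_time_window,
    write_oxdna,
)

from conftest import RADIUS_ANTI


def rmsd_bruteforce(traj):
    """Double-loop oracle for the no-superposition RMSD."""
    out = []
    for f in range(traj.n_frames):
        acc = 0.0
        for i in range(traj.n_entities):
            d = traj.positions_nm[f, i] - traj.positions_nm[0, i]
            acc += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
        out.append(np.sqrt(acc / traj.n_entities))
    return np.array(out)


def rmsf_bruteforce(traj, idx):
    out = []
    for i in range(traj.n_entities):
        ref = np.zeros(3)
        for f in idx:
            ref += traj.positions_nm[f, i]
        ref /= len(idx)
        acc = 0.0
        for f in idx:
            d = traj.positions_nm[f, i] - ref
            acc += d[0] ** 2 + d[1] ** 2 + d[2] ** 2
        out.append(np.sqrt(acc / len(idx)))
    return np.array(out)


# ---------------------------------------------------------------- oxDNA I/O

FIXTURE_TOP = "3 1\n1 T -1 1\n1 T 0 2\n1 T 1 -1\n"


def write_fixture(tmp_path, conf_text, top_text=FIXTURE_TOP):
    top = tmp_path / "f.top"
    conf = tmp_path / "f.conf"
    top.write_text(top_text)
    conf.write_text(conf_text)
    return top, conf


def frame_text(t, rows):
    lines = [f"t = {t}", "b = 100 100 100", "E = 0 0 0"]
    for r in rows:
        lines.append(" ".join(str(v) for v in r) + " 1 0 0 0 1 0 0 0 0 0 0 0")
    return "\n".join(lines) + "\n"


class TestReadOxdna:
    def test_hand_written_fixture(self, tmp_path):
        rows1 = [(1.0, 2.0, 3.0), (4.0, 5.0, 6.0), (7.0, 8.0, 9.0)]
        rows2 = [(1.5, 2.5, 3.5), (4.5, 5.5, 6.5), (7.5, 8.5, 9.5)]
        top, conf = write_fixture(tmp_path, frame_text(0, rows1) + frame_text(500, rows2))
        traj = read_oxdna(top, conf)
        assert traj.positions_nm.shape == (2, 3, 3)
        assert traj.positions_nm[0] == pytest.approx(np.array(rows1) * OXDNA_LENGTH_NM)
        assert traj.positions_nm[1] == pytest.approx(np.array(rows2) * OXDNA_LENGTH_NM)

    def test_time_conversion(self, tmp_path):
        rows = [(0, 0, 0), (1, 1, 1), (2, 2, 2)]
        top, conf = write_fixture(tmp_path, frame_text(1000, rows))
        traj = read_oxdna(top, conf)
        assert traj.times_ps[0] == pytest.approx(1000 * OXDNA_TIME_PS)  # 3030 ps

    def test_truncated_frame_error(self, tmp_path):
        rows = [(0, 0, 0), (1, 1, 1), (2, 2, 2)]
        text = frame_text(0, rows) + "t = 100\nb = 100 100 100\nE = 0 0 0\n0 0 0 1 0 0 0 1 0 0 0 0 0 0 0\n"
        top, conf = write_fixture(tmp_path, text)
        with pytest.raises(ParseError, match="frame 2"):
            read_oxdna(top, conf)

    def test_wrong_column_count(self, tmp_path):
        text = "t = 0\nb = 100 100 100\nE = 0 0 0\n" + "1 2 3\n" * 3
        top, conf = write_fixture(tmp_path, text)
        with pytest.raises(ParseError, match="15 columns"):
            read_oxdna(top, conf)

    def test_malformed_header(self, tmp_path):
        top, conf = write_fixture(tmp_path, "x = 0\n")
        with pytest.raises(ParseError, match="t ="):
            read_oxdna(top, conf)

    def test_topology_count_mismatch(self, tmp_path):
        top, conf = write_fixture(
            tmp_path, frame_text(0, [(0, 0, 0)] * 3), top_text="5 1\n1 T -1 1\n1 T 0 -1\n")
        with pytest.raises(ParseError):
            read_oxdna(top, conf)

    def test_write_read_round_trip(self, tmp_path):
        base = gen_helix_points(20.0, 40.0, 2.0, 26)
        traj = gen_trajectory(base, 1.0, 5, seed=4)
        top = tmp_path / "w.top"
        conf = tmp_path / "w.conf"
        write_oxdna(top, conf, traj)
        back = read_oxdna(top, conf)
        assert back.positions_nm == pytest.approx(traj.positions_nm, abs=1e-7)
        assert back.times_ps == pytest.approx(traj.times_ps, abs=1e-3)


class TestRmsd:
    def test_first_frame_zero(self):
        traj = gen_trajectory(gen_helix_points(20, 40, 2, 13), 1.0, 5, seed=0)
        _, rmsd = rmsd_trace(traj)
        assert rmsd[0] == 0.0

    def test_rigid_translation_exact(self):
        base = gen_helix_points(20, 40, 2, 13)
        pos = np.stack([base, base + np.array([3.0, 4.0, 0.0])])
        traj = Trajectory(times_ps=[0.0, 1.0], positions_nm=pos)
        _, rmsd = rmsd_trace(traj)
        assert rmsd[1] == pytest.approx(5.0, rel=1e-12)

    def test_gaussian_displacement_sqrt3_sigma(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 50, (1000, 3))
        pos = np.stack([base, base + rng.normal(0, 2.0, base.shape)])
        traj = Trajectory(times_ps=[0.0, 1.0], positions_nm=pos)
        _, rmsd = rmsd_trace(traj)
        assert rmsd[1] == pytest.approx(2.0 * np.sqrt(3), rel=0.02)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(1)
        traj = Trajectory(times_ps=np.arange(5.0), positions_nm=rng.normal(0, 3, (5, 7, 3)))
        _, rmsd = rmsd_trace(traj)
        assert rmsd == pytest.approx(rmsd_bruteforce(traj), abs=1e-12)


class TestRmsf:
    def test_static_trajectory_zero(self):
        base = gen_helix_points(20, 40, 2, 13)
        traj = gen_trajectory(base, 0.0, 5, seed=0)
        assert np.allclose(rmsf(traj), 0.0)

    def test_gaussian_fluctuation_sqrt3_sigma(self):
        base = gen_helix_points(20, 40, 2, 50)
        traj = gen_trajectory(base, 1.0, 100, seed=2)
        values = rmsf(traj)
        assert np.mean(values) == pytest.approx(np.sqrt(3.0), rel=0.05)
        assert np.all(np.abs(values - np.sqrt(3.0)) < 0.1 * np.sqrt(3) * 4)

    def test_window_2000_3000ns_selects_100_frames(self):
        base = gen_helix_points(20, 40, 2, 13)
        traj = gen_trajectory(base, 1.0, 400, frame_spacing_ns=10.0, seed=0)
        idx = select_time_window(traj, 2000.0, 3000.0)
        assert len(idx) == 100

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        traj = Trajectory(times_ps=np.arange(5.0), positions_nm=rng.normal(0, 3, (5, 7, 3)))
        idx = np.arange(5)
        assert rmsf(traj, idx) == pytest.approx(rmsf_bruteforce(traj, idx), abs=1e-12)

    def test_empty_window_error(self):
        base = gen_helix_points(20, 40, 2, 13)
        traj = gen_trajectory(base, 1.0, 5, seed=0)
        with pytest.raises(DomainError):
            rmsf(traj, [0])


class TestGuidePoints:
    def test_26_entities_to_13_points(self):
        pos = np.arange(26 * 3, dtype=float).reshape(26, 3)
        pairs = [(i, i + 13) for i in range(13)]
        pts = average_guide_points(pos, pairs)
        assert pts.shape == (13, 3)
        assert pts[0] == pytest.approx(0.5 * (pos[0] + pos[13]))

    def test_identical_pair(self):
        pos = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert average_guide_points(pos, [(0, 1)])[0] == pytest.approx([1.0, 2.0, 3.0])

    def test_symmetric_pairs_at_origin(self):
        p = np.array([[1.0, -2.0, 3.0]])
        pos = np.vstack([p, -p])
        assert average_guide_points(pos, [(0, 1)])[0] == pytest.approx([0, 0, 0])

    def test_out_of_range(self):
        with pytest.raises(DomainError):
            average_guide_points(np.zeros((4, 3)), [(0, 7)])


class TestFitHelix:
    def test_noiseless_round_trip(self):
        pts = gen_helix_points(20.0, 40.0, 2.0, 13, "right")
        fit = fit_helix(pts)
        assert fit.radius_nm == pytest.approx(20.0, abs=1e-6)
        assert fit.pitch_nm == pytest.approx(40.0, abs=1e-6)
        assert fit.turns == pytest.approx(2.0, abs=1e-6)
        assert fit.handedness == "right"
        assert fit.rms_nm < 1e-6

    def test_mirror_flips_handedness(self):
        pts = gen_helix_points(20.0, 40.0, 2.0, 13, "right")
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        fit = fit_helix(mirrored)
        assert fit.radius_nm == pytest.approx(20.0, abs=1e-6)
        assert fit.pitch_nm == pytest.approx(40.0, abs=1e-6)
        assert fit.handedness == "left"

    def test_anti_gqns_radius(self):
        pts = gen_helix_points(RADIUS_ANTI, 39.0, 3.5, 200, "right")
        assert fit_helix(pts).radius_nm == pytest.approx(RADIUS_ANTI, abs=1e-6)

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation

        pts = gen_helix_points(20.0, 40.0, 2.0, 13, "right")
        R = Rotation.from_euler("zyx", [0.4, -1.0, 2.2]).as_matrix()
        moved = pts @ R.T + np.array([10.0, -20.0, 5.0])
        fit = fit_helix(moved)
        assert fit.radius_nm == pytest.approx(20.0, abs=1e-6)
        assert fit.pitch_nm == pytest.approx(40.0, abs=1e-6)
        assert fit.handedness == "right"
        # the axis transforms covariantly
        assert abs(fit.axis_direction @ (R @ np.array([0, 0, 1.0]))) == pytest.approx(1.0, abs=1e-6)

    def test_left_handed_generator(self):
        pts = gen_helix_points(20.0, 40.0, 2.0, 13, "left")
        assert fit_helix(pts).handedness == "left"

    def test_collinear_error(self):
        pts = np.column_stack([np.arange(10.0), np.arange(10.0), np.arange(10.0)])
        with pytest.raises(DegenerateGeometryError):
            fit_helix(pts)

    def test_noise_recovery(self):
        for sigma in (0.0, 0.5, 1.0):
            errs = []
            for seed in range(20):
                pts = gen_helix_points(20.0, 40.0, 2.0, 13, "right", sigma, seed)
                errs.append(abs(fit_helix(pts).radius_nm - 20.0))
            assert np.median(errs) <= max(sigma, 1e-9)


class TestCompareBackbonePier:
    def _fit(self, radius, pitch=40.0):
        return fit_helix(gen_helix_points(radius, pitch, 2.0, 20))

    def test_backbone_inside(self):
        res = compare_backbone_pier(self._fit(20.0), self._fit(26.0))
        assert res.call == "backbone-inside"
        assert res.difference_nm == pytest.approx(6.0, abs=1e-6)

    def test_equal_radii_indeterminate(self):
        res = compare_backbone_pier(self._fit(20.0), self._fit(20.0))
        assert res.call == "indeterminate"

    def test_swap_negates(self):
        a = compare_backbone_pier(self._fit(20.0), self._fit(26.0))
        b = compare_backbone_pier(self._fit(26.0), self._fit(20.0))
        assert a.difference_nm == pytest.approx(-b.difference_nm, abs=1e-9)

    def test_incompatible_axes(self):
        pts = gen_helix_points(20.0, 40.0, 2.0, 20)
        rotated = pts @ np.array([[0.0, 0.0, 1.0], [0.0, 1.0, 0.0], [-1.0, 0.0, 0.0]])
        with pytest.raises(DomainError):
            compare_backbone_pier(fit_helix(pts), fit_helix(rotated))
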