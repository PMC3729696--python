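"""Geometric observables: twist dihedral, adjacent angles, RMSD, windows."""

import numpy as np
import pytest

from crossbeta import (
    ValidationError,
    build_protofilament,
    rmsd,
    summarize_angles,
    total_twist_angle,
    twist_series,
)
from crossbeta.geometry import (
    AngleSeries,
    NotDefinedError,
    adjacent_monomer_angle,
    mean_adjacent_angle,
    signed_dihedral,
)
from tests.conftest import (
    oracle_dihedral,
    oracle_total_twist,
    rodrigues_matrix,
    twisted_ensemble,
)


class TestTwistAngle:
    def test_untwisted_build_measures_zero(self, proto6):
        assert total_twist_angle(proto6) == pytest.approx(0.0, abs=1e-6)

    def test_fewer_than_four_chains_undefined(self, template_chain):
        small = build_protofilament(template_chain, n=3)
        with pytest.raises(NotDefinedError):
            total_twist_angle(small)

    @pytest.mark.parametrize("n,twist", [(12, 2.0), (8, 5.0), (24, 3.0)])
    def test_imposed_twist_matches_rotation_oracle(self, template_chain,
                                                   n, twist):
        asm = build_protofilament(template_chain, n=n)
        ens = twisted_ensemble(asm, twist, n_frames=7)
        measured = twist_series(ens).per_frame
        expected = oracle_total_twist(asm, twist, np.linspace(0, 1, 7))
        np.testing.assert_allclose(measured, expected, atol=1e-3)

    def test_unwrapping_tracks_past_180_degrees(self, template_chain):
        """A 48-mer at 7 deg/monomer accumulates > 300 degrees, which only
        an unwrapped series can report."""
        asm = build_protofilament(template_chain, n=48)
        ens = twisted_ensemble(asm, 7.0, n_frames=15)
        measured = twist_series(ens).per_frame
        expected = oracle_total_twist(asm, 7.0, np.linspace(0, 1, 15))
        assert measured[-1] > 300.0
        np.testing.assert_allclose(measured, expected, atol=1e-3)

    def test_sum_of_adjacent_rotations_matches_total(self, template_chain):
        asm = build_protofilament(template_chain, n=10)
        ens = twisted_ensemble(asm, 10.0, n_frames=9)
        final = ens.frame(ens.n_frames - 1)
        total = twist_series(ens).per_frame[-1]
        adj_sum = sum(adjacent_monomer_angle(final, 0, i)
                      for i in range(1, 8))  # chains 2..9, 7 steps
        assert abs(total - adj_sum) < 2.0


class TestAdjacentAngle:
    def test_untwisted_any_index_is_zero(self, proto6):
        for i in range(5):
            assert adjacent_monomer_angle(proto6, 0, i) == pytest.approx(
                0.0, abs=1e-9)

    def test_perpendicular_marker_vector_reads_the_rotation(self,
                                                            template_chain):
        """The V18->V24 vector is perpendicular to the growth axis, so a
        twist of delta reads back exactly delta."""
        asm = build_protofilament(template_chain, n=6)
        v = (asm.layers[0][0].residue(24).atom("CA").coord
             - asm.layers[0][0].residue(18).atom("CA").coord)
        assert abs(v @ asm.growth_axis) < 1e-9
        ens = twisted_ensemble(asm, 6.5, n_frames=3)
        final = ens.frame(2)
        for i in range(5):
            assert adjacent_monomer_angle(final, 0, i) == pytest.approx(
                6.5, abs=1e-9)

    def test_axis_parallel_vector_is_rotation_blind(self):
        """Rotation about the axis fixes axis-parallel vectors: the angle
        between them stays 0 whatever the twist."""
        v = np.array([0.0, 0.0, 1.0])
        for twist in (5.0, 60.0, 170.0):
            rot = rodrigues_matrix([0, 0, 1.0], twist)
            w = rot @ v
            cosang = v @ w
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == \
                pytest.approx(0.0, abs=1e-9)

    def test_out_of_range_index_rejected(self, proto4):
        with pytest.raises(IndexError):
            adjacent_monomer_angle(proto4, 0, 3)


class TestSignedDihedral:
    def test_agrees_with_independent_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            pts = rng.normal(0, 5, (4, 3))
            assert signed_dihedral(*pts) == pytest.approx(
                oracle_dihedral(*pts), abs=1e-9)


class TestRmsd:
    def test_self_rmsd_is_zero(self, proto4):
        assert rmsd(proto4, proto4) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_is_removed(self, proto4):
        import copy
        moved = copy.deepcopy(proto4)
        rot = rodrigues_matrix([1.0, 2.0, 0.5], 37.0)
        coords = moved.coords() @ rot.T + np.array([5.0, -3.0, 9.0])
        moved.set_coords(coords)
        assert rmsd(moved, proto4) == pytest.approx(0.0, abs=1e-5)

    def test_single_displaced_atom_closed_form(self, proto4):
        import copy
        moved = copy.deepcopy(proto4)
        coords = moved.coords()
        # displace the first backbone atom by 1 A; superposition disabled
        moved.set_coords(coords)
        moved.layers[0][0].residues[1].atom("N").coord += np.array(
            [1.0, 0.0, 0.0])
        m = sum(1 for _l, _c, _r, a in proto4.iter_atoms()
                if a.name in ("N", "CA", "C", "O"))
        expected = np.sqrt(1.0 / m)
        assert rmsd(moved, proto4, superpose=False) == pytest.approx(
            expected, rel=1e-9)

    def test_symmetry(self, proto4):
        import copy
        other = copy.deepcopy(proto4)
        rng = np.random.default_rng(0)
        other.set_coords(other.coords() + rng.normal(0, 0.4,
                                                     other.coords().shape))
        assert rmsd(proto4, other) == pytest.approx(rmsd(other, proto4),
                                                    abs=1e-9)

    def test_selection_mismatch_rejected(self, proto4, proto6):
        with pytest.raises(ValidationError):
            rmsd(proto4, proto6)


class TestAngleWindows:
    def test_constant_series_mean_is_the_constant(self):
        s = AngleSeries(per_frame=np.full(10, 42.0),
                        times=np.arange(10.0), window_ps=3.0)
        assert s.mean_last_window == pytest.approx(42.0)

    def test_linear_ramp_trailing_mean_matches_direct_computation(self):
        vals = np.linspace(0.0, 100.0, 100)
        times = np.arange(100.0)
        s = AngleSeries(per_frame=vals, times=times, window_ps=10.0)
        direct = vals[-10:].mean()
        assert s.mean_last_window == pytest.approx(direct)

    def test_full_duration_window_is_global_mean(self):
        vals = np.array([1.0, 2.0, 6.0, 11.0])
        s = AngleSeries(per_frame=vals, times=np.arange(4.0) * 5,
                        window_ps=15.0)
        assert summarize_angles(s, 15.0) == pytest.approx(vals.mean())

    def test_invalid_window_rejected(self):
        s = AngleSeries(per_frame=np.ones(3), times=np.arange(3.0),
                        window_ps=1.0)
        with pytest.raises(ValidationError):
            summarize_angles(s, -2.0)


class TestScaleContrast:
    def test_per_monomer_angle_size_independent_total_grows(self,
                                                            template_chain):
        """On noise-free imposed-twist ensembles the adjacent-monomer angle
        does not depend on oligomer size while the total twist grows --
        the hallmark contrast between the two angle observables."""
        twist = 4.0
        totals, adjacents = [], []
        for n in (6, 10, 16):
            asm = build_protofilament(template_chain, n=n)
            ens = twisted_ensemble(asm, twist, n_frames=5)
            final = ens.frame(4)
            totals.append(twist_series(ens).per_frame[-1])
            adjacents.append(mean_adjacent_angle(final))
        np.testing.assert_allclose(adjacents, twist, atol=1e-6)
        assert totals[0] < totals[1] < totals[2]
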