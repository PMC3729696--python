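"""Salt bridges and Kabsch-Sander beta-sheet content."""

import numpy as np
import pytest

from crossbeta import (
    Ensemble,
    PerturbationParams,
    build_protofilament,
    detect_salt_bridges,
    kabsch_sander_energy,
    make_synthetic_ensemble,
    parallel_beta_content,
    salt_bridge_occupancy,
)
from crossbeta.contacts import (
    KS_CLAMP,
    KS_COUPLING,
    KS_THRESHOLD,
    interchain_hbonds,
)
from crossbeta.model import AtomRecord, ResidueRecord
from tests.conftest import static_ensemble


def _residue_with(name_coords, aa="A", seq=20):
    atoms = [AtomRecord(n, n[0], np.asarray(c, float))
             for n, c in name_coords.items()]
    return ResidueRecord(aa_code=aa, seq_index=seq, atoms=atoms)


class TestKabschSanderEnergy:
    def test_near_ideal_geometry_matches_formula_oracle(self):
        """Atoms placed so the four pair distances are exactly the
        near-ideal hydrogen-bond values; the energy must equal a direct
        hand evaluation of the 0.084 * 332 * (1/r_ON + 1/r_CH - 1/r_OH -
        1/r_CN) formula and count as a bond."""
        r_on, r_ch, r_oh, r_cn = 2.9, 3.9, 1.9, 3.9
        donor = _residue_with({
            "N": (0.0, 0.0, 0.0),
            "H": (0.0, 0.0, -1.0),
            "CA": (1.4, 0.0, 0.0),
        })
        # O on the N-H axis gives r_OH = r_ON - 1; C placed off-axis so
        # that |C-N| = |C-H| = 3.9 exactly
        acceptor = _residue_with({
            "O": (0.0, 0.0, -2.9),
            "C": (np.sqrt(r_cn ** 2 - 0.25), 0.0, -0.5),
        }, seq=30)
        n, h = np.zeros(3), np.array([0.0, 0.0, -1.0])
        o, c = acceptor.atom("O").coord, acceptor.atom("C").coord
        assert np.isclose(np.linalg.norm(o - n), r_on)
        assert np.isclose(np.linalg.norm(o - h), r_oh)
        assert np.isclose(np.linalg.norm(c - n), r_cn)
        assert np.isclose(np.linalg.norm(c - h), r_ch)
        e = kabsch_sander_energy(donor, acceptor)
        oracle = 0.084 * 332.0 * (1 / r_on + 1 / r_ch - 1 / r_oh - 1 / r_cn)
        assert e == pytest.approx(oracle, abs=1e-12)
        assert e < KS_THRESHOLD  # this geometry is a bond

    def test_infinite_separation_is_no_bond(self):
        donor = _residue_with({"N": (0, 0, 0), "H": (0, 0, -1),
                               "CA": (1.4, 0, 0)})
        acceptor = _residue_with({"O": (0, 0, -1e6), "C": (0, 0, -1e6 - 1)},
                                 seq=30)
        e = kabsch_sander_energy(donor, acceptor)
        assert abs(e) < 1e-4
        assert not e < KS_THRESHOLD

    def test_criterion_is_directional(self):
        donor = _residue_with({"N": (0, 0, 0), "H": (0, 0, -1),
                               "CA": (1.4, 0, 0), "C": (2.0, 1.0, 0),
                               "O": (2.0, 2.0, 0)})
        acceptor = _residue_with({"N": (0.5, 0, -4.4), "H": (0.5, 0, -3.6),
                                  "CA": (1.9, 0, -4.4),
                                  "O": (0, 0, -2.9), "C": (0, 0, -3.9)},
                                 seq=30)
        e_fwd = kabsch_sander_energy(donor, acceptor)
        e_rev = kabsch_sander_energy(acceptor, donor)
        assert e_fwd != pytest.approx(e_rev, abs=1e-3)

    def test_overlapping_atoms_clamp(self):
        donor = _residue_with({"N": (0, 0, 0), "H": (0, 0, -0.3),
                               "CA": (1.4, 0, 0)})
        acceptor = _residue_with({"O": (0, 0, -0.4), "C": (0, 0, -1.6)},
                                 seq=30)
        assert kabsch_sander_energy(donor, acceptor) == KS_CLAMP

    def test_coupling_constant_value(self):
        assert KS_COUPLING == pytest.approx(27.888)


class TestSaltBridges:
    def test_template_intra_bridge_present_by_construction(self, proto6):
        recs = detect_salt_bridges(proto6)
        intra = [r for r in recs if r.kind == "intra"]
        assert len(intra) == 6
        assert all(r.present for r in intra)

    def test_classification_exhaustive_and_exclusive(self, proto6):
        recs = detect_salt_bridges(proto6)
        assert len(recs) == 6 + 5  # per chain + per adjacent pair
        for r in recs:
            assert (r.kind == "intra") == (r.donor_chain == r.acceptor_chain)

    def test_no_records_across_layers(self, pair4):
        recs = detect_salt_bridges(pair4)
        layer_of = {c.chain_id: li for li, layer in enumerate(pair4.layers)
                    for c in layer}
        for r in recs:
            assert layer_of[r.donor_chain] == layer_of[r.acceptor_chain]

    def test_closed_cutoff_boundary(self, template_chain):
        """4.20 A is present, 4.21 A is absent (closed <= cutoff)."""
        import copy
        chain = copy.deepcopy(template_chain)
        d23 = chain.residue(23)
        nz = chain.residue(28).atom("NZ")
        for target, expect in ((4.20, True), (4.21, False)):
            od1 = d23.atom("OD1")
            direction = od1.coord - nz.coord
            direction /= np.linalg.norm(direction)
            od1.coord = nz.coord + target * direction
            # push the other oxygen out of the way
            d23.atom("OD2").coord = nz.coord + 10.0 * direction
            from crossbeta.model import Assembly
            asm = Assembly(layers=[[chain]])
            rec = [r for r in detect_salt_bridges(asm) if r.kind == "intra"][0]
            assert rec.min_distance == pytest.approx(target, abs=1e-9)
            assert rec.present is expect


class TestOccupancy:
    def test_intact_ensemble_has_full_occupancy(self, proto4):
        ens = static_ensemble(proto4, n_frames=3)
        df = salt_bridge_occupancy(ens)
        intra = df[df["kind"] == "intra"]
        assert (intra["occupancy"] == 1.0).all()

    def test_half_broken_bridge_reads_half(self, proto4):
        """Break every intra bridge in exactly half the frames by moving
        the NZ atoms away."""
        frames = []
        for k in range(4):
            asm = proto4.copy()
            if k % 2:
                for chain in asm.all_chains():
                    chain.residue(28).atom("NZ").coord += np.array(
                        [0.0, 50.0, 0.0])
            frames.append(asm)
        ens = Ensemble.from_frames(frames, times=np.arange(4.0))
        df = salt_bridge_occupancy(ens)
        intra = df[df["kind"] == "intra"]
        assert (intra["occupancy"] == 0.5).all()

    def test_occupancies_bounded(self, proto4):
        ens = make_synthetic_ensemble(
            proto4, PerturbationParams(seed=3, noise_sigma=0.4, n_frames=5))
        df = salt_bridge_occupancy(ens)
        assert df["occupancy"].between(0.0, 1.0).all()


class TestParallelBetaContent:
    def test_two_chain_ideal_build_flags_interior_strands(self,
                                                          template_chain):
        asm = build_protofilament(template_chain, n=2)
        ens = static_ensemble(asm, n_frames=1)
        bc = parallel_beta_content(ens)
        # interior residues of both sheets are bridged; the turn cap is not
        for i in (12, 15, 18, 35, 38):
            assert bc.per_residue[i] == 1.0, f"residue {i} not bridged"
        for i in (25, 26, 27):
            assert bc.per_residue[i] == 0.0

    def test_single_chain_content_is_zero_with_warning(self, template_chain):
        asm = build_protofilament(template_chain, n=1)
        ens = static_ensemble(asm, n_frames=1)
        with pytest.warns(UserWarning, match="single chain"):
            bc = parallel_beta_content(ens)
        assert bc.window_means["whole"] == 0.0

    def test_interior_hbond_count_uniform_across_chain_pairs(self, proto6):
        """Translational symmetry: every adjacent chain pair shares the
        same number of hydrogen bonds."""
        bonds = interchain_hbonds(proto6)
        ids = [c.chain_id for c in proto6.layers[0]]
        per_pair = {}
        for b in bonds:
            key = tuple(sorted((b.donor[0], b.acceptor[0])))
            per_pair[key] = per_pair.get(key, 0) + 1
        adjacent = [tuple(sorted((a, b))) for a, b in zip(ids, ids[1:])]
        counts = {per_pair[p] for p in adjacent}
        assert len(counts) == 1 and counts.pop() > 0

    def test_noise_degrades_content_monotonically(self, proto4):
        """Mean content decreases with noise sigma, averaged over seeds."""
        means = []
        for sigma in (0.0, 0.4, 0.9):
            vals = []
            for seed in range(20):
                ens = make_synthetic_ensemble(
                    proto4, PerturbationParams(
                        seed=seed, twist_per_monomer=0.0, hinge_bend=0.0,
                        noise_sigma=sigma, n_frames=2))
                vals.append(
                    parallel_beta_content(ens).window_means["whole"])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
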