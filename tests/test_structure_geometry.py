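import math

import numpy as np
import pandas as pd
import pytest

from funsav import structure_features as strf
from funsav.io_formats import Atom, Chain, Residue, Structure, VariantRecord
from funsav.synthetic import SyntheticSpec, make_structure
from conftest import point_structure


def rigid_transform(structure, rng):
    """Random rotation + translation applied in place (returns a copy)."""
    from scipy.spatial.transform import Rotation
    rot = Rotation.random(random_state=rng).as_matrix()
    shift = rng.uniform(-50, 50, 3)
    import copy
    moved = copy.deepcopy(structure)
    for chain in moved.chains:
        for res in chain.residues:
            for atom in res.atoms:
                atom.coord = rot @ atom.coord + shift
    return moved


class TestSasa:
    def test_isolated_atom_closed_form(self):
        s = point_structure([(0, 0, 0)])
        b = strf.sasa(s, "A", relative=False)
        exact = 4 * math.pi * (1.70 + 1.4) ** 2
        assert b.table.iloc[0]["NAC_all_abs"] == pytest.approx(exact, rel=0.01)

    def test_two_overlapping_atoms_match_high_density_oracle(self):
        """Two spheres at partial overlap: each atom keeps its unburied cap.
        Compared against the same geometry sampled at 10⁴ points."""
        coords = [(0, 0, 0), (2.0, 0, 0)]
        s = point_structure(coords)
        coarse = strf.sasa(s, "A", n_points=960, relative=False)
        fine = strf.sasa(s, "A", n_points=10000, relative=False)
        for pos in (1, 2):
            assert coarse.table.loc[pos, "NAC_all_abs"] == pytest.approx(
                fine.table.loc[pos, "NAC_all_abs"], rel=0.02)
        # and each is strictly between half and full isolated area
        full = 4 * math.pi * 3.1 ** 2
        assert full / 2 < fine.table.loc[1, "NAC_all_abs"] < full

    def test_gly_x_gly_reference_is_100_percent(self):
        tri = strf._tripeptide("ALA")
        b = strf.sasa(tri, "A")
        assert b.table.loc[2, "NAC_all"] == pytest.approx(100.0, abs=1e-6)
        assert b.table.loc[2, "NAC_npa"] == pytest.approx(100.0, abs=1e-6)

    def test_rotation_invariance(self, helix20):
        rng = np.random.default_rng(5)
        base = strf.sasa(helix20, "A", relative=False).table["NAC_all_abs"].sum()
        moved = rigid_transform(helix20, rng)
        after = strf.sasa(moved, "A", relative=False).table["NAC_all_abs"].sum()
        assert after == pytest.approx(base, rel=0.005)

    def test_unknown_element_raises(self):
        s = point_structure([(0, 0, 0)], element="ZZ")
        with pytest.raises(strf.RadiusTableError, match="ZZ"):
            strf.sasa(s, "A")

    def test_category_subset_bound(self, helix20):
        t = strf.sasa(helix20, "A", relative=False).table
        for cat in ("sc", "mc", "npa", "pa"):
            assert (t["NAC_all_abs"] >= t[f"NAC_{cat}_abs"] - 1e-9).all()


class TestHalfSphereExposure:
    def test_single_residue_no_neighbors(self):
        s = make_structure(SyntheticSpec(seed=0, n_residues=1))
        h = strf.half_sphere_exposure(s, "A")
        assert h.loc[1, "CN"] == 0 and h.loc[1, "HSEAU"] == 0 and h.loc[1, "HSEAD"] == 0

    def test_cn_partition_identity(self, helix20):
        h = strf.half_sphere_exposure(helix20, "A")
        assert (h["CN"] == h["HSEAU"] + h["HSEAD"]).all()

    def test_cn_matches_brute_force_distance_count(self, helix20):
        h = strf.half_sphere_exposure(helix20, "A", radius=13.0)
        ca = np.array([r.get_atom("CA").coord for r in helix20.chain("A").residues])
        d = np.linalg.norm(ca[:, None] - ca[None, :], axis=2)
        brute = ((d <= 13.0).sum(axis=1) - 1)
        np.testing.assert_array_equal(h["CN"].to_numpy(), brute)

    def test_rigid_motion_invariance(self, helix20):
        rng = np.random.default_rng(6)
        base = strf.half_sphere_exposure(helix20, "A")
        moved = rigid_transform(helix20, rng)
        after = strf.half_sphere_exposure(moved, "A")
        for col in ("CN", "HSEAU", "HSEBU", "HSEAD", "HSEBD"):
            np.testing.assert_array_equal(after[col].to_numpy(), base[col].to_numpy())

    def test_depths_nonnegative(self, helix20):
        h = strf.half_sphere_exposure(helix20, "A")
        assert (h["RD"] >= 0).all() and (h["RDa"] >= 0).all()


class TestBackboneGeometry:
    def test_collinear_kappa_180(self):
        s = point_structure([(i * 3.8, 0, 0) for i in range(6)])
        g = strf.backbone_geometry(s, "A")
        assert g.loc[3, "KAPPA"] == pytest.approx(180.0)
        assert g.loc[4, "KAPPA"] == pytest.approx(180.0)
        assert np.isnan(g.loc[1, "KAPPA"])  # no i-2 neighbor

    def test_planar_zigzag_alpha_180(self):
        pts = [(i * 2.0, i % 2, 0.0) for i in range(6)]
        g = strf.backbone_geometry(point_structure(pts), "A")
        assert abs(g.loc[3, "ALPHA"]) == pytest.approx(180.0)

    def test_parallel_co_gives_tco_1(self):
        def res(i, origin):
            o = np.array(origin)
            return Residue(seqnum=i, icode=" ", name="GLY", atoms=[
                Atom("C", "C", o), Atom("O", "O", o + [0, 0, 1.23])])
        s = Structure("t", [Chain("A", [res(1, (0, 0, 0)), res(2, (3.8, 0, 0))])])
        g = strf.backbone_geometry(s, "A")
        assert g.loc[2, "TCO"] == pytest.approx(1.0)

    def test_helix_angles_match_vector_oracle(self, helix20):
        from funsav import geometry as geo
        g = strf.backbone_geometry(helix20, "A")
        ca = [r.get_atom("CA").coord for r in helix20.chain("A").residues]
        i = 9  # 0-based interior residue
        expect_kappa = geo.bond_angle(ca[i - 2], ca[i], ca[i + 2])
        expect_alpha = geo.dihedral(ca[i - 1], ca[i], ca[i + 1], ca[i + 2])
        assert g.loc[i + 1, "KAPPA"] == pytest.approx(expect_kappa, abs=1e-9)
        assert g.loc[i + 1, "ALPHA"] == pytest.approx(expect_alpha, abs=1e-9)
        assert -1 <= g["TCO"].dropna().min() and g["TCO"].dropna().max() <= 1


class TestHydrogenBonds:
    def test_distant_residues_no_bond(self):
        a = make_structure(SyntheticSpec(seed=0, n_residues=2))
        for res in a.chains[0].residues:
            pass
        # move second residue 50 Å away
        for atom in a.chains[0].residues[1].atoms:
            atom.coord = atom.coord + np.array([50.0, 0, 0])
        assert strf.hydrogen_bonds(a, "A").sum() == 0

    def test_helix_i_to_i_plus_4_pattern(self, helix20):
        counts = strf.hydrogen_bonds(helix20, "A")
        # interior residues participate in the helical ladder
        assert (counts.iloc[4:16] >= 1).all()

    def test_extended_chain_has_no_bonds(self, extended20):
        assert strf.hydrogen_bonds(extended20, "A").sum() == 0

    def test_degenerate_cutoff(self, helix20):
        assert strf.hydrogen_bonds(helix20, "A", energy_cutoff=-1e9).sum() == 0


class TestDisulfideAndSites:
    def _cys_pair(self, sg_gap):
        def cys(i, x):
            return Residue(seqnum=i, icode=" ", name="CYS", atoms=[
                Atom("CA", "C", [x, 0, 0]), Atom("SG", "S", [x, sg_gap / 2 if i == 1 else -sg_gap / 2, 0])])
        res1 = Residue(seqnum=1, icode=" ", name="CYS",
                       atoms=[Atom("CA", "C", [0, 0, 0]), Atom("SG", "S", [0, 0, 0])])
        res2 = Residue(seqnum=2, icode=" ", name="CYS",
                       atoms=[Atom("CA", "C", [4, 0, 0]), Atom("SG", "S", [sg_gap, 0, 0])])
        return Structure("p1", [Chain("A", [res1, res2])])

    def test_disulfide_flag_at_2_05(self):
        s = self._cys_pair(2.05)
        var = VariantRecord("p1", "A", 1, "C", "Y", "disease")
        ann = pd.DataFrame({"protein_id": ["p1"], "ft_key": ["ACT_SITE"],
                            "start": [2], "end": [2]})
        out = strf.disulfide_and_site_distances(s, [var], ann)
        assert out.iloc[0]["Disulfide"] == 1.0

    def test_no_disulfide_beyond_cutoff(self):
        s = self._cys_pair(3.5)
        var = VariantRecord("p1", "A", 1, "C", "Y", "disease")
        ann = pd.DataFrame({"protein_id": ["p1"], "ft_key": ["ACT_SITE"],
                            "start": [2], "end": [2]})
        out = strf.disulfide_and_site_distances(s, [var], ann)
        assert out.iloc[0]["Disulfide"] == 0.0

    def test_variant_at_annotated_site_zero_distance(self):
        s = self._cys_pair(3.5)
        var = VariantRecord("p1", "A", 2, "C", "Y", "neutral")
        ann = pd.DataFrame({"protein_id": ["p1"], "ft_key": ["ACT_SITE"],
                            "start": [2], "end": [2]})
        out = strf.disulfide_and_site_distances(s, [var], ann)
        assert out.iloc[0]["SeqDist_site"] == 0.0
        assert out.iloc[0]["D3_site"] == pytest.approx(0.0)

    def test_metal_flag(self):
        s = self._cys_pair(3.5)
        var = VariantRecord("p1", "A", 1, "C", "Y", "disease")
        ann = pd.DataFrame({"protein_id": ["p1"], "ft_key": ["METAL"],
                            "start": [1], "end": [1]})
        out = strf.disulfide_and_site_distances(s, [var], ann)
        assert out.iloc[0]["Metal"] == 1.0

    def test_no_annotations_all_missing(self):
        s = self._cys_pair(2.05)
        var = VariantRecord("p1", "A", 1, "C", "Y", "disease")
        out = strf.disulfide_and_site_distances(s, [var], None)
        assert out.iloc[0].isna().all()
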