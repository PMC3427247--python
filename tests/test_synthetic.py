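import hashlib
import math
import warnings
from pathlib import Path

import numpy as np
import pytest

from funsav import io_formats as io
from funsav import synthetic as syn
from funsav.coevolution import column_entropy, pairwise_coevolution
from funsav.model import cross_validate
from funsav.structure_features import hydrogen_bonds


def dir_digest(path: Path) -> dict:
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(path.iterdir()) if p.is_file()}


class TestMakeStructure:
    def test_helix_ca_distances(self):
        s = syn.make_structure(syn.SyntheticSpec(seed=0, n_residues=20))
        ca = [r.get_atom("CA").coord for r in s.chains[0].residues]
        d = [np.linalg.norm(b - a) for a, b in zip(ca, ca[1:])]
        assert all(abs(x - 3.8) < 0.05 for x in d)

    def test_extended_mode_no_hydrogen_bonds(self):
        s = syn.make_structure(syn.SyntheticSpec(seed=0, n_residues=15,
                                                 geometry="extended"))
        assert hydrogen_bonds(s, "A").sum() == 0

    def test_single_residue_pdb_round_trip(self, tmp_path):
        s = syn.make_structure(syn.SyntheticSpec(seed=0, n_residues=1))
        p = tmp_path / "one.pdb"
        io.write_structure(s, p)
        back = io.read_structure(p)
        assert len(back.chain("A").residues) == 1

    def test_unknown_geometry(self):
        with pytest.raises(ValueError):
            syn.make_structure(syn.SyntheticSpec(seed=0, geometry="noodle"))

    def test_random_coil_reproducible(self):
        a = syn.make_structure(syn.SyntheticSpec(seed=5, geometry="random-coil"))
        b = syn.make_structure(syn.SyntheticSpec(seed=5, geometry="random-coil"))
        for ra, rb in zip(a.chains[0].residues, b.chains[0].residues):
            np.testing.assert_array_equal(ra.get_atom("CA").coord,
                                          rb.get_atom("CA").coord)


class TestMakeMsa:
    def test_planted_pair_mi_equals_entropy_at_eps0(self):
        spec = syn.SyntheticSpec(seed=1, msa_rows=150, msa_cols=12,
                                 covarying_pairs=[(3, 9, 0.0)])
        msa = syn.make_msa(spec)
        m = pairwise_coevolution(msa)
        assert m.mi[2, 8] == pytest.approx(column_entropy(msa, 3), abs=1e-12)

    def test_eps_half_pair_blends_into_background(self):
        """At ε=0.5 the planted pair's MI is within the spread of the
        independent-column MI distribution."""
        spec = syn.SyntheticSpec(seed=1, msa_rows=150, msa_cols=12,
                                 covarying_pairs=[(3, 9, 0.5)])
        m = pairwise_coevolution(syn.make_msa(spec))
        background = [m.mi[i, j] for i in range(12) for j in range(i + 1, 12)
                      if (i, j) != (2, 8)]
        assert m.mi[2, 8] < np.mean(background) + 4 * np.std(background)

    def test_out_of_range_pair_rejected(self):
        spec = syn.SyntheticSpec(seed=1, msa_cols=5, covarying_pairs=[(1, 99, 0.0)])
        with pytest.raises(ValueError):
            syn.make_msa(spec)

    def test_seed_reproducibility(self):
        spec = syn.SyntheticSpec(seed=8, msa_rows=30, msa_cols=10)
        assert syn.make_msa(spec).sequences == syn.make_msa(spec).sequences


class TestLabeledDataset:
    def test_zero_effect_cv_mcc_near_zero(self):
        spec = syn.SyntheticSpec(seed=2, n_samples=200, n_informative=2,
                                 n_noise=10, effect_sizes=[0.0, 0.0])
        df, _ = syn.make_labeled_dataset(spec)
        res = cross_validate(df, ["informative_0", "informative_1"], k=5, repeats=2,
                             seed=0, params={"n_estimators": 50})
        assert abs(res.metrics.mcc) < 0.25

    def test_missingness_expectation(self):
        spec = syn.SyntheticSpec(seed=3, n_samples=1000,
                                 tool_missingness={"panther": 0.3})
        _, tools = syn.make_labeled_dataset(spec)
        assert tools["panther"].isna().mean() == pytest.approx(0.3, abs=0.05)
        assert tools["sift"].notna().all()

    def test_categorical_tools_encoded(self):
        _, tools = syn.make_labeled_dataset(syn.SyntheticSpec(seed=4, n_samples=50))
        assert set(tools["phdsnp"].unique()) <= {1.0, -1.0}

    def test_balance(self):
        df, _ = syn.make_labeled_dataset(syn.SyntheticSpec(seed=5, n_samples=100,
                                                           class_balance=0.3))
        assert (df["label"] == 1).sum() == 30


class TestFixtureDir:
    def test_bytewise_reproducibility(self, tmp_path):
        spec = syn.SyntheticSpec(seed=9, n_residues=15, n_variants=6)
        syn.make_fixture_dir(tmp_path / "a", spec)
        syn.make_fixture_dir(tmp_path / "b", spec)
        assert dir_digest(tmp_path / "a") == dir_digest(tmp_path / "b")

    def test_files_reread_without_warnings(self, tmp_path):
        spec = syn.SyntheticSpec(seed=9, n_residues=15, n_variants=6)
        syn.make_fixture_dir(tmp_path / "fx", spec)
        fx = tmp_path / "fx"
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            s = io.read_structure(fx / "synth.pdb")
            pssm = io.read_pssm(fx / "synth.pssm")
            msa = io.read_msa(fx / "synth.msa.fasta")
            variants = io.read_variant_table(fx / "variants.tsv")
            tools = io.read_tool_scores(fx / "tool_scores.tsv")
            ann = io.read_annotations(fx / "annotations.tsv")
        assert len(s.chain("A").residues) == 15
        assert len(pssm) == 15 and msa.n_cols == 15
        assert len(variants) == 6 and len(tools) == 6 and len(ann) == 3
        assert not pssm.fallback_rows
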