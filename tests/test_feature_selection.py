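import numpy as np
import pandas as pd
import pytest

from funsav import feature_selection as fsel
from funsav.synthetic import SyntheticSpec, make_labeled_dataset

FAST_FOREST = {"n_estimators": 50}


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(seed=10, n_samples=300, n_informative=3, n_noise=30,
                         effect_sizes=[2.0, 2.0, 2.0])
    df, _ = make_labeled_dataset(spec)
    return df


class TestMdgiZscores:
    def test_planted_features_rank_top(self, planted):
        report = fsel.compute_mdgi_zscores(planted, repeats=10,
                                           forest_params=FAST_FOREST, seed=0)
        top3 = report.table["zscore"].nlargest(3).index
        assert set(top3) == {"informative_0", "informative_1", "informative_2"}

    def test_zscores_standardized(self, planted):
        report = fsel.compute_mdgi_zscores(planted, repeats=5,
                                           forest_params=FAST_FOREST, seed=1)
        z = report.table["zscore"]
        assert z.mean() == pytest.approx(0.0, abs=1e-9)
        assert z.std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_deterministic_given_seed(self, planted):
        a = fsel.compute_mdgi_zscores(planted, repeats=3, forest_params=FAST_FOREST, seed=5)
        b = fsel.compute_mdgi_zscores(planted, repeats=3, forest_params=FAST_FOREST, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_single_class_rejected(self, planted):
        df = planted.copy()
        df["label"] = 1
        with pytest.raises(Exception):
            fsel.compute_mdgi_zscores(df, repeats=2, forest_params=FAST_FOREST)

    def test_all_noise_flags_at_null_rate(self):
        """With exchangeable noise-only features, the Z>1 flag rate stays
        near the standardization-implied rate (no feature is special)."""
        spec = SyntheticSpec(seed=20, n_samples=120, n_informative=0, n_noise=40,
                             effect_sizes=[])
        df, _ = make_labeled_dataset(spec)
        report = fsel.compute_mdgi_zscores(df, repeats=10, forest_params=FAST_FOREST,
                                           seed=3)
        rate = report.table["candidate"].mean()
        assert rate < 0.35  # ~16% expected under normality; generous MC bound


class TestSelectCandidates:
    def _report(self, z):
        table = pd.DataFrame({"mean_mdgi": np.abs(z), "zscore": z,
                              "candidate": np.array(z) > 1.0},
                             index=[f"f{i}" for i in range(len(z))])
        return fsel.ZScoreReport(table=table, mean=0, sd=1, threshold=1.0,
                                 repeats=1, seed=0)

    def test_strict_inequality_at_boundary(self):
        assert fsel.select_candidates(self._report([2.0, 1.0, 0.5])) == ["f0"]

    def test_minus_inf_threshold_selects_all(self):
        got = fsel.select_candidates(self._report([2.0, 1.0, 0.5]), threshold=-np.inf)
        assert got == ["f0", "f1", "f2"]

    def test_empty_selection_raises(self):
        with pytest.raises(fsel.EmptySelectionError):
            fsel.select_candidates(self._report([0.5, 0.2, -0.1]))


class TestStepwise:
    def test_noise_feature_removed_and_mcc_non_decreasing(self, planted):
        feats = ["informative_0", "informative_1", "informative_2",
                 "noise_000", "noise_001"]
        trace = fsel.stepwise_select(planted, feats, cv_k=5, cv_repeats=2, seed=0,
                                     forest_params=FAST_FOREST)
        mccs = [trace.initial_mcc] + [r.mcc_after for r in trace.rounds]
        assert all(b > a for a, b in zip(mccs, mccs[1:]))
        assert len(trace.rounds) <= len(feats)
        assert set(trace.final_features) >= {"informative_0", "informative_1",
                                             "informative_2"}

    def test_duplicated_informative_column_pruned(self, planted):
        df = planted.copy()
        df["informative_dup"] = df["informative_0"]
        feats = ["informative_0", "informative_dup", "informative_1", "informative_2"]
        trace = fsel.stepwise_select(df, feats, cv_k=5, cv_repeats=2, seed=1,
                                     forest_params=FAST_FOREST)
        final = trace.final_features
        assert ("informative_0" in final) != ("informative_dup" in final) or \
            len(trace.rounds) == 0  # duplicates carry identical signal; if any
        # removal was accepted, exactly one of the duplicates must have survived

    def test_single_candidate_terminates_immediately(self, planted):
        trace = fsel.stepwise_select(planted, ["informative_0"], cv_k=5, cv_repeats=1,
                                     seed=0, forest_params=FAST_FOREST)
        assert trace.rounds == [] and trace.final_features == ["informative_0"]

    def test_full_determinism(self, planted):
        feats = ["informative_0", "informative_1", "noise_000"]
        kwargs = dict(cv_k=5, cv_repeats=2, seed=7, forest_params=FAST_FOREST)
        t1 = fsel.stepwise_select(planted, feats, **kwargs)
        t2 = fsel.stepwise_select(planted, feats, **kwargs)
        assert t1.initial_mcc == t2.initial_mcc
        assert [(r.removed, r.mcc_after) for r in t1.rounds] == \
               [(r.removed, r.mcc_after) for r in t2.rounds]

    def test_trace_serialization(self, planted, tmp_path):
        trace = fsel.stepwise_select(planted, ["informative_0", "noise_000"],
                                     cv_k=5, cv_repeats=1, seed=0,
                                     forest_params=FAST_FOREST)
        trace.to_json(tmp_path / "t.json")
        trace.to_tsv(tmp_path / "t.tsv")
        assert (tmp_path / "t.json").exists()
        assert (tmp_path / "t.tsv").read_text().startswith("round\t")
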