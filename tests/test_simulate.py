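import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metabias import (
    DegenerateCorpusError,
    GeneratorConfig,
    apply_selection,
    fit_multilevel,
    generate_corpus,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"between_study_sd": -0.1},
            {"selection_strength": -1.0},
            {"group_size_range": (2, 10)},
            {"year_range": (2020, 2000)},
            {"metric": "OR"},
            {"n_meta": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)


class TestDeterminism:
    def test_same_seed_same_corpus(self):
        cfg = GeneratorConfig(n_meta=4, seed=42, metric="mixed")
        a_corpus, a_truth = generate_corpus(cfg)
        b_corpus, b_truth = generate_corpus(cfg)
        pd.testing.assert_frame_equal(a_corpus, b_corpus)
        pd.testing.assert_frame_equal(a_truth, b_truth)

    def test_different_seed_different_corpus(self):
        a, _ = generate_corpus(GeneratorConfig(n_meta=2, seed=1))
        b, _ = generate_corpus(GeneratorConfig(n_meta=2, seed=2))
        assert not a["es"].equals(b["es"])


class TestStructure:
    def test_truth_has_one_row_per_meta(self):
        corpus, truth = generate_corpus(GeneratorConfig(n_meta=5, seed=3))
        assert len(truth) == 5
        assert set(truth["meta_id"]) == set(corpus["meta_id"].unique())

    def test_sampling_variances_match_metric_formulas(self):
        """Generated variances must obey the closed-form metric variance
        formulas exactly (recomputable from the stored es and group sizes)."""
        corpus, _ = generate_corpus(
            GeneratorConfig(n_meta=6, metric="mixed", seed=4)
        )
        smd = corpus[corpus["metric"] == "SMD"]
        expected = (smd["n_e"] + smd["n_c"]) / (smd["n_e"] * smd["n_c"]) + smd[
            "es"
        ] ** 2 / (2 * (smd["n_e"] + smd["n_c"]))
        np.testing.assert_allclose(smd["var"], expected, rtol=1e-12)
        zr = corpus[corpus["metric"] == "Zr"]
        np.testing.assert_allclose(zr["var"], 1.0 / (zr["n_total"] - 3), rtol=1e-12)

    def test_years_within_range(self):
        cfg = GeneratorConfig(n_meta=3, year_range=(2005, 2010), seed=5)
        corpus, _ = generate_corpus(cfg)
        assert corpus["year"].between(2005, 2010).all()


class TestNoiseFreeLimit:
    def test_huge_samples_no_heterogeneity_recover_truth(self):
        cfg = GeneratorConfig(
            n_meta=1,
            studies_per_meta=10,
            effects_per_study=1,
            metric="SMD",
            true_effect=0.3,
            between_study_sd=0.0,
            within_study_sd=0.0,
            group_size_range=(20000, 20000),
            seed=6,
        )
        corpus, _ = generate_corpus(cfg)
        assert corpus["es"].to_numpy() == pytest.approx(0.3, abs=0.05)
        fit = fit_multilevel(
            corpus["es"], v=corpus["var"], groups=corpus["study_id"]
        )
        assert fit.coef_[0] == pytest.approx(0.3, abs=0.02)


class TestSelection:
    def _biased_corpus(self, seed=7):
        cfg = GeneratorConfig(
            n_meta=1, studies_per_meta=30, effects_per_study=2,
            true_effect=0.2, seed=seed,
        )
        corpus, _ = generate_corpus(cfg)
        return corpus

    def test_zero_strength_is_identity(self):
        df = self._biased_corpus()
        out = apply_selection(df, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, df)

    def test_infinite_strength_keeps_only_significant(self):
        df = self._biased_corpus()
        out = apply_selection(df, 1e9, seed=1)
        p = 2 * stats.norm.sf(np.abs(out["es"] / out["se"]))
        assert (p < 0.05).all()

    def test_significant_records_never_removed_and_counts_shrink(self):
        df = self._biased_corpus()
        p = 2 * stats.norm.sf(np.abs(df["es"] / df["se"]))
        sig_ids = set(df.loc[p < 0.05, "obs_id"])
        out = apply_selection(df, 1.5, seed=2)
        assert sig_ids <= set(out["obs_id"])
        assert len(out) <= len(df)

    def test_decline_mode_retains_more_recent_nonsignificant_records(self):
        rng_checks = []
        for seed in range(5):
            df = self._biased_corpus(seed=seed)
            p = 2 * stats.norm.sf(np.abs(df["es"] / df["se"]))
            nonsig = df[p >= 0.05]
            out = apply_selection(df, 3.0, decline_mode=True, seed=seed)
            kept = nonsig[nonsig["obs_id"].isin(out["obs_id"])]
            if len(kept) and len(nonsig):
                rng_checks.append(kept["year"].mean() - nonsig["year"].mean())
        assert np.mean(rng_checks) > 0  # surviving non-significant records skew late

    def test_degenerate_corpus_raises(self):
        cfg = GeneratorConfig(
            n_meta=1, studies_per_meta=3, effects_per_study=1,
            true_effect=0.0, seed=9,
        )
        corpus, _ = generate_corpus(cfg)
        with pytest.raises(DegenerateCorpusError):
            apply_selection(corpus, 1e9, seed=1)

    def test_selection_inside_generate_corpus(self):
        cfg_sel = GeneratorConfig(n_meta=3, selection_strength=2.0, seed=10)
        cfg_none = GeneratorConfig(n_meta=3, selection_strength=0.0, seed=10)
        with_sel, truth = generate_corpus(cfg_sel)
        without, _ = generate_corpus(cfg_none)
        assert len(with_sel) < len(without)
        assert (truth["selection_strength"] == 2.0).all()
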