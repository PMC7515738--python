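"""Translation-efficiency arithmetic, classification rule, concordance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from leaderscan.te import (
    classify_gene,
    cross_study_concordance,
    rpkm,
    simple_te_test,
    translation_efficiency,
)
from leaderscan.simulate import SimulationConfig, simulate_counts, simulate_transcriptome


class TestRpkm:
    def test_unit_definition(self):
        assert rpkm(10, 1000, 10**6) == 10.0

    def test_zero_counts(self):
        assert rpkm(0, 500, 10**6) == 0.0

    def test_hand_arithmetic(self):
        # 7 / 0.35 kb / 2.4 M reads
        assert rpkm(7, 350, 2_400_000) == pytest.approx(7 / 0.35 / 2.4)

    def test_zero_library_rejected(self):
        with pytest.raises(ValueError):
            rpkm(1, 100, 0)

    @given(
        counts=st.integers(0, 10**6),
        length=st.integers(1, 10**5),
        lib=st.integers(1, 10**9),
        k=st.integers(1, 50),
    )
    @settings(max_examples=50, deadline=None)
    def test_linear_in_counts_and_scale_invariant(self, counts, length, lib, k):
        base = rpkm(counts, length, lib)
        assert rpkm(k * counts, length, lib) == pytest.approx(k * base)
        assert rpkm(k * counts, length, k * lib) == pytest.approx(base)


class TestTranslationEfficiency:
    def test_ratio(self):
        assert translation_efficiency(20, 10) == 2.0

    def test_identity(self):
        for x in (0.1, 1.0, 57.3):
            assert translation_efficiency(x, x) == 1.0

    def test_zero_rna_undefined(self):
        with pytest.raises(ValueError):
            translation_efficiency(5, 0)

    def test_planted_twofold_drop_recovered(self):
        """NB simulation: TE ratio treated/vehicle near 0.5 for a -1 shift."""
        rng = np.random.default_rng(6)
        n_rep, mu_r, mu_n = 6, 5000.0, 2000.0
        ribo_v = rng.poisson(mu_r, n_rep)
        rna_v = rng.poisson(mu_n, n_rep)
        ribo_t = rng.poisson(mu_r * 0.5, n_rep)
        rna_t = rng.poisson(mu_n, n_rep)
        te_v = np.mean(ribo_v / rna_v)
        te_t = np.mean(ribo_t / rna_t)
        assert te_t / te_v == pytest.approx(0.5, rel=0.1)


class TestClassifyGene:
    @pytest.mark.parametrize(
        "padj,log2fc,expected",
        [
            (0.20, -1.0, "NS"),
            (0.01, -0.5, "DOWN"),
            (0.04, +2.0, "UP"),
            (0.05, -3.0, "NS"),  # boundary goes to NS
            (0.049999, 0.5, "UP"),
            (1.0, 0.0, "NS"),
        ],
    )
    def test_rule(self, padj, log2fc, expected):
        label, _ = classify_gene(padj, log2fc)
        assert label == expected

    def test_missing_padj_untested(self):
        label, flags = classify_gene(float("nan"), -2.0)
        assert label == "NS" and "UNTESTED" in flags

    def test_zero_fc_significant_stays_ns(self):
        label, flags = classify_gene(0.001, 0.0)
        assert label == "NS" and "ZERO_FC" in flags

    def test_partition_is_exhaustive_and_disjoint(self):
        rng = np.random.default_rng(0)
        for padj, fc in zip(rng.uniform(0, 1, 200), rng.normal(0, 2, 200)):
            label, _ = classify_gene(float(padj), float(fc))
            assert label in {"NS", "UP", "DOWN"}


class TestConcordance:
    def test_identical_vectors_rho_one(self):
        fc = pd.Series([0.5, -1, 2, 0, 3], index=list("abcde"))
        rho, n = cross_study_concordance(fc, fc)
        assert rho == pytest.approx(1.0) and n == 5

    def test_reversed_ranking_rho_minus_one(self):
        fc = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        rho, _ = cross_study_concordance(fc, -fc)
        assert rho == pytest.approx(-1.0)

    def test_matches_rank_and_pearson_oracle(self):
        rng = np.random.default_rng(3)
        a = pd.Series(rng.normal(size=10), index=[f"t{i}" for i in range(10)])
        b = pd.Series(rng.normal(size=10), index=a.index)
        # first-principles oracle: average ranks then Pearson
        ra = sps.rankdata(a.values)
        rb = sps.rankdata(b.values)
        expected = np.corrcoef(ra, rb)[0, 1]
        rho, _ = cross_study_concordance(a, b)
        assert rho == pytest.approx(expected)

    def test_zero_read_transcripts_discarded(self):
        ids = [f"t{i}" for i in range(6)]
        fc = pd.Series(np.arange(6.0), index=ids)
        reads = pd.DataFrame(
            {"c1": [5, 0, 4, 2, 9, 1], "c2": [3, 7, 0, 6, 2, 8]}, index=ids
        )
        rho, n = cross_study_concordance(fc, fc, reads_a=reads)
        assert n == 4 and rho == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        a = pd.Series(rng.normal(size=20), index=[f"t{i}" for i in range(20)])
        b = pd.Series(rng.normal(size=20), index=a.index)
        rho1, _ = cross_study_concordance(a, b)
        rho2, _ = cross_study_concordance(np.exp(a), b**3 + 5 * b)
        assert rho1 == pytest.approx(rho2)

    def test_tiny_intersection_rejected(self):
        a = pd.Series([1.0, 2.0], index=["x", "y"])
        with pytest.raises(ValueError):
            cross_study_concordance(a, a)


class TestSimpleTeTest:
    def test_bh_adjustment_monotone_and_above_raw(self):
        from statsmodels.stats.multitest import multipletests

        raw = np.array([0.01, 0.02, 0.03, 0.04])
        _, padj, _, _ = multipletests(raw, method="fdr_bh")
        assert np.all(np.diff(padj) >= -1e-12)
        assert np.all(padj >= raw)

    def test_single_replicate_rejected(self):
        counts = pd.DataFrame(
            {
                "gene_id": ["g1"] * 2,
                "condition": ["vehicle", "treated"],
                "replicate": [1, 1],
                "ribo": [10, 10],
                "rna": [10, 10],
            }
        )
        with pytest.raises(ValueError, match="external"):
            simple_te_test(counts)

    def test_null_type_one_error_controlled(self):
        """No planted effect: BH keeps the significant fraction <= 5%."""
        fractions = []
        for seed in range(10):
            cfg = SimulationConfig(n_genes=200, seed=seed, te_effect_log2=0.0)
            study = simulate_transcriptome(cfg)
            res = simple_te_test(simulate_counts(study))
            fractions.append((res["padj"] < 0.05).mean())
        assert np.mean(fractions) <= 0.05

    def test_planted_down_effect_detected(self):
        """Planted -1 log2 TE shift: most responsive genes called DOWN."""
        cfg = SimulationConfig(n_genes=400, seed=5)
        study = simulate_transcriptome(cfg)
        res = simple_te_test(simulate_counts(study))
        merged = res.merge(study.truth, on="gene_id")
        down_frac = (
            merged.loc[merged.regime == "responsive", "class_label"] == "DOWN"
        ).mean()
        assert down_frac > 0.5
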