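"""Leader feature panel: composition, positional GC, MFE layers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from leaderscan.features import (
    composition,
    fit_background_mfe,
    mfe_corrected,
    mfe_global,
    mfe_per_nt,
    mfe_windows,
    positional_gc_profile,
)

# Frozen before implementation from the RNAfold command-line tool
# (ViennaRNA 2.7.2, default Turner parameters at 37 C).
RNAFOLD_ORACLE = {
    "GGGGAAAACCCC": -5.40,
    "GCGCGCAAAGCGCGC": -9.60,
    "CCCCGGGGAAAACCCCGGGG": -17.70,
    "AUGGCUAGCGUAGCUAGCUAGGCGCGAUCGC": -11.00,
    "AAAAAAAAAAAAAAAAAAAA": 0.00,
    "GGGUUAGGGUUAGGGUUAGGG": 0.00,
}

SEQ_ALPHABET = st.text(alphabet="ACGU", min_size=1, max_size=120)


class TestComposition:
    def test_gcgc_exhaustive(self):
        pct = composition("GCGC")
        assert pct["pct_gc"] == 100.0 and pct["pct_c"] == 50.0

    def test_ccaauu(self):
        pct = composition("CCAAUU")
        assert pct["pct_c"] == pytest.approx(100 / 3)
        assert pct["pct_pyrimidine"] == pytest.approx(200 / 3)

    def test_t_u_equivalent(self):
        assert composition("ACGT") == composition("ACGU")

    def test_n_excluded_from_denominator(self):
        pct = composition("GCNN")
        assert pct["pct_gc"] == 100.0

    def test_empty_and_all_n_rejected(self):
        for bad in ("", "NNN"):
            with pytest.raises(ValueError):
                composition(bad)

    @given(seq=SEQ_ALPHABET)
    @settings(max_examples=60, deadline=None)
    def test_percentages_sum_and_reversal_invariance(self, seq):
        pct = composition(seq)
        total = pct["pct_a"] + pct["pct_c"] + pct["pct_g"] + pct["pct_u"]
        assert total == pytest.approx(100.0, abs=1e-6)
        assert composition(seq[::-1]) == pct

    @given(seq=SEQ_ALPHABET)
    @settings(max_examples=60, deadline=None)
    def test_gc_invariant_under_complementation(self, seq):
        comp = seq.translate(str.maketrans("ACGU", "UGCA"))
        assert composition(comp)["pct_gc"] == pytest.approx(
            composition(seq)["pct_gc"]
        )


class TestPositionalGc:
    def test_two_bins_constructed(self):
        assert positional_gc_profile("GGGGAAAA", 2) == [100.0, 0.0]

    def test_bins_average_to_whole_leader_gc(self):
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGU"), 103))
        bins = positional_gc_profile(seq, 10)
        sizes = [11, 11, 11, 10, 10, 10, 10, 10, 10, 10]
        weighted = sum(b * s for b, s in zip(bins, sizes)) / sum(sizes)
        assert weighted == pytest.approx(composition(seq)["pct_gc"])

    def test_uniform_sequence_flat_profile(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGU"), 1000))
        bins = positional_gc_profile(seq, 10)
        # binomial sampling noise: sd ~ sqrt(.25/100)*100 = 5 pp per bin
        assert all(abs(b - 50) < 20 for b in bins)

    def test_short_leader_single_bin(self):
        assert positional_gc_profile("GC", 10) == [100.0]


class TestMfe:
    def test_unstructurable_poly_a_is_zero(self):
        assert mfe_global("A" * 20) == 0.0

    @pytest.mark.parametrize("seq,expected", sorted(RNAFOLD_ORACLE.items()))
    def test_matches_folding_oracle(self, seq, expected):
        assert mfe_global(seq) == pytest.approx(expected, abs=0.01)

    def test_t_read_as_u(self):
        assert mfe_global("GGGGTTTTCCCC") == mfe_global("GGGGUUUUCCCC")

    def test_non_nucleotide_rejected(self):
        with pytest.raises(ValueError):
            mfe_global("ACGX")

    @given(seq=st.text(alphabet="ACGU", min_size=5, max_size=60))
    @settings(max_examples=30, deadline=None)
    def test_mfe_never_positive(self, seq):
        assert mfe_global(seq) <= 0.0

    def test_per_nt(self):
        assert mfe_per_nt(-50, 100) == -0.5
        assert mfe_per_nt(0, 40) == 0.0
        # arithmetic on the printed leader descriptors
        assert mfe_per_nt(-165.4, 297) == pytest.approx(-0.5569, abs=1e-4)

    def test_per_nt_zero_length_rejected(self):
        with pytest.raises(ValueError):
            mfe_per_nt(-5, 0)


class TestMfeWindows:
    def test_boundary_single_window(self):
        assert len(mfe_windows("A" * 20)) == 1

    def test_count_formula(self):
        assert len(mfe_windows("A" * 24)) == 3  # floor((24-20)/2)+1

    def test_short_sequence_empty_profile(self):
        assert mfe_windows("ACGU") == []

    def test_poly_a_windows_all_zero(self):
        assert mfe_windows("A" * 60) == [0.0] * 21
        assert all(v <= 0 for v in mfe_windows("GCGC" * 15))


class TestBackgroundCorrection:
    def _background(self, rng, n=80):
        lengths = rng.integers(50, 500, n).astype(float)
        gc = rng.uniform(30, 70, n)
        return lengths, gc

    def test_perfect_linear_background_residuals_zero(self):
        rng = np.random.default_rng(1)
        lengths, gc = self._background(rng)
        mfes = -0.3 * lengths
        model = fit_background_mfe(lengths, gc, mfes)
        for l, g, m in zip(lengths, gc, mfes):
            assert mfe_corrected(m, l, g, model) == pytest.approx(0.0, abs=1e-8)

    def test_planted_outlier_recovered(self):
        rng = np.random.default_rng(2)
        lengths, gc = self._background(rng)
        mfes = -0.3 * lengths - 0.5 * gc
        model = fit_background_mfe(lengths, gc, mfes)
        outlier = (-0.3 * 200 - 0.5 * 50) - 50.0
        corrected = mfe_corrected(outlier, 200, 50, model)
        assert corrected == pytest.approx(-50.0, abs=1e-6)

    def test_residuals_sum_to_zero(self):
        rng = np.random.default_rng(3)
        lengths, gc = self._background(rng)
        mfes = -0.3 * lengths - 0.5 * gc + rng.normal(0, 5, len(lengths))
        model = fit_background_mfe(lengths, gc, mfes)
        resid = [
            mfe_corrected(m, l, g, model) for m, l, g in zip(mfes, lengths, gc)
        ]
        assert sum(resid) == pytest.approx(0.0, abs=1e-6)

    def test_too_small_background_rejected(self):
        with pytest.raises(ValueError, match=">= 50"):
            fit_background_mfe([100.0] * 10, [50.0] * 10, [-30.0] * 10)

    def test_degenerate_design_names_column(self):
        with pytest.raises(ValueError, match="length"):
            fit_background_mfe(
                [100.0] * 60, list(np.linspace(30, 70, 60)), [-30.0] * 60
            )
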