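"""Additive scan, permutation significance, peak calling and trait utilities."""

import numpy as np
import pandas as pd
import pytest

from rilqtl.core import AncestryMatrix, NullDistribution
from rilqtl.scan import (
    call_qtl_peaks,
    correlate_traits,
    genomewide_p,
    map_residuals,
    permutation_null,
    qtl_h2,
    scan_additive,
)
from rilqtl.simulate import AdditiveSimConfig, simulate_additive_phenotype


def _single_window(g):
    g = np.asarray(g, dtype=float)
    return AncestryMatrix(
        np.array([f"r{i}" for i in range(g.size)], dtype=object),
        np.array(["w"], dtype=object),
        g[:, None],
    )


def _oracle_lod(g, y):
    """Brute-force LOD via explicit design-matrix least squares."""
    ok = ~np.isnan(g) & ~np.isnan(y)
    g, y = g[ok], y[ok]
    X = np.column_stack([np.ones(g.size), g])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    rss1 = np.sum((y - X @ beta) ** 2)
    rss0 = np.sum((y - y.mean()) ** 2)
    return (g.size / 2.0) * np.log10(rss0 / rss1)


class TestScanAdditive:
    def test_worked_example(self):
        """g=[0,0,2,2], y=[.1,-.1,.9,1.1]: b=0.5, LOD=2*log10(1.04/0.04)."""
        m = _single_window([0, 0, 2, 2])
        scan = scan_additive(m, np.array([0.1, -0.1, 0.9, 1.1]))
        assert scan["b"][0] == pytest.approx(0.5, abs=1e-12)
        assert scan["lod"][0] == pytest.approx(2 * np.log10(1.04 / 0.04), abs=1e-9)

    def test_constant_phenotype_gives_zero_lod(self, small_panel):
        matrix, _ = small_panel
        scan = scan_additive(matrix, np.full(matrix.n_rils, 3.0))
        assert (scan["lod"] == 0).all()

    def test_affine_invariance(self, small_panel):
        matrix, _ = small_panel
        rng = np.random.default_rng(0)
        y = rng.normal(size=matrix.n_rils)
        lod1 = scan_additive(matrix, y)["lod"]
        lod2 = scan_additive(matrix, -2.5 * y + 7.0)["lod"]
        np.testing.assert_allclose(lod1, lod2, atol=1e-8)

    def test_negation_flips_b_keeps_lod(self, small_panel):
        matrix, _ = small_panel
        rng = np.random.default_rng(1)
        y = rng.normal(size=matrix.n_rils) + 0.4 * matrix.dosage[:, 10]
        s1 = scan_additive(matrix, y)
        s2 = scan_additive(matrix, -y)
        np.testing.assert_allclose(s1["b"], -s2["b"], atol=1e-9)
        np.testing.assert_allclose(s1["lod"], s2["lod"], atol=1e-9)

    def test_zero_genotype_variance_flagged(self):
        m = _single_window([2, 2, 2, 2])
        scan = scan_additive(m, np.array([1.0, 2.0, 3.0, 4.0]))
        assert scan["lod"][0] == 0.0
        assert bool(scan["degenerate"][0])

    def test_perfect_fit_sentinel(self):
        m = _single_window([0, 0, 2, 2])
        scan = scan_additive(m, np.array([1.0, 1.0, 2.0, 2.0]))
        assert np.isinf(scan["lod"][0])
        assert bool(scan["perfect_fit"][0])

    def test_missing_genotypes_complete_case(self):
        g = np.array([0, 0, 2, 2, np.nan])
        y = np.array([0.1, -0.1, 0.9, 1.1, 99.0])
        scan = scan_additive(_single_window(g), y)
        assert scan["n"][0] == 4
        assert scan["lod"][0] == pytest.approx(2 * np.log10(1.04 / 0.04), abs=1e-9)

    def test_matches_oracle_with_missing_data(self, small_panel):
        matrix, _ = small_panel
        rng = np.random.default_rng(3)
        d = matrix.dosage.copy()
        d[rng.random(d.shape) < 0.1] = np.nan
        noisy = AncestryMatrix(matrix.rils, matrix.windows, d)
        y = rng.normal(size=matrix.n_rils)
        scan = scan_additive(noisy, y)
        for j in rng.choice(noisy.n_windows, 10, replace=False):
            expected = _oracle_lod(d[:, j], y)
            assert scan["lod"][j] == pytest.approx(expected, abs=1e-9)


class TestPermutationNull:
    def test_deterministic(self, small_panel, small_summary):
        matrix, _ = small_panel
        y = np.random.default_rng(5).normal(size=matrix.n_rils)
        n1 = permutation_null(matrix, y, small_summary, n_perm=50, seed=9)
        n2 = permutation_null(matrix, y, small_summary, n_perm=50, seed=9)
        np.testing.assert_array_equal(n1.values, n2.values)

    def test_zero_permutations_rejected(self, small_panel, small_summary):
        matrix, _ = small_panel
        with pytest.raises(ValueError):
            permutation_null(matrix, np.zeros(matrix.n_rils), small_summary, n_perm=0)

    def test_sorted_and_sized(self, small_panel, small_summary):
        matrix, _ = small_panel
        y = np.random.default_rng(6).normal(size=matrix.n_rils)
        null = permutation_null(matrix, y, small_summary, n_perm=64, seed=1)
        assert null.values.size == 64
        assert (np.diff(null.values) >= 0).all()


class TestGenomewideP:
    def _null(self):
        return NullDistribution(np.linspace(1.0, 2.0, 100), n_perm=100, seed=0)

    def test_boundaries_and_median(self):
        null = self._null()
        assert null.p_value(5.0) == 0.0  # more extreme than any permutation
        assert null.p_value(1.0) == 1.0  # every null value >= it
        assert null.p_value(float(np.median(null.values))) == pytest.approx(0.5, abs=0.02)

    def test_plus_one_estimator(self):
        null = self._null()
        assert null.p_value(5.0, plus_one=True) == pytest.approx(1 / 101)

    def test_attaches_p_column(self, small_panel, small_summary):
        matrix, _ = small_panel
        y = np.random.default_rng(7).normal(size=matrix.n_rils)
        scan = scan_additive(matrix, y, small_summary)
        out = genomewide_p(scan, self._null())
        assert out["p"].notna().sum() == (~scan["excluded"]).sum()


def _scan_frame(lods, p, cm=None, arm="2L"):
    n = len(lods)
    cm = cm if cm is not None else [float(i) for i in range(n)]
    scan = pd.DataFrame(
        {
            "window_id": [f"{arm}_w{i}" for i in range(n)],
            "n": 100,
            "b": 0.1,
            "lod": lods,
            "p": p,
            "excluded": False,
            "degenerate": False,
            "perfect_fit": False,
        }
    )
    wmap = pd.DataFrame(
        {
            "window_id": scan["window_id"],
            "arm": arm,
            "start": [i * 1000 for i in range(n)],
            "end": [(i + 1) * 1000 for i in range(n)],
            "cM": cm,
            "n_snps": 10,
        }
    )
    return scan, wmap


class TestCallQtlPeaks:
    def test_shallow_valley_removes_minor_peak(self):
        """Intervening LOD 2.5 >= 3.4 - 1.5, so the minor peak is dropped."""
        lods = [1.0, 3.6, 2.5, 3.4, 1.0]
        p = [0.5, 0.01, 0.2, 0.02, 0.5]
        scan, wmap = _scan_frame(lods, p, cm=[0, 15, 30, 45, 60])
        calls = call_qtl_peaks(scan, wmap)
        assert len(calls) == 1
        assert calls[0].peak_window == "2L_w1"

    def test_deep_valley_keeps_both_peaks(self):
        """Intervening LOD 1.8 < 3.5 - 1.5 and peaks > 10 cM apart."""
        lods = [1.0, 3.6, 1.8, 3.5, 1.0]
        p = [0.5, 0.01, 0.2, 0.02, 0.5]
        scan, wmap = _scan_frame(lods, p, cm=[0, 15, 30, 45, 60])
        calls = call_qtl_peaks(scan, wmap)
        assert {c.peak_window for c in calls} == {"2L_w1", "2L_w3"}

    def test_close_peaks_pruned_by_cM(self):
        lods = [1.0, 3.6, 1.8, 3.5, 1.0]
        p = [0.5, 0.01, 0.2, 0.02, 0.5]
        scan, wmap = _scan_frame(lods, p, cm=[0, 2, 4, 6, 8])  # 4 cM apart
        calls = call_qtl_peaks(scan, wmap)
        assert len(calls) == 1
        assert calls[0].peak_window == "2L_w1"

    def test_lod_drop_confidence_interval(self):
        """CI = contiguous windows with LOD > 3.6 - 1.5 = 2.1."""
        lods = [2.0, 2.2, 3.6, 2.2, 1.9]
        p = [0.5, 0.2, 0.01, 0.2, 0.5]
        scan, wmap = _scan_frame(lods, p)
        calls = call_qtl_peaks(scan, wmap)
        assert calls[0].ci_windows == ("2L_w1", "2L_w2", "2L_w3")

    def test_no_significant_windows_gives_empty_list(self):
        scan, wmap = _scan_frame([1.0, 2.0, 1.0], [0.5, 0.4, 0.5])
        assert call_qtl_peaks(scan, wmap) == []

    def test_boundary_p_excluded(self):
        """P exactly at alpha does not qualify (strict inequality)."""
        scan, wmap = _scan_frame([1.0, 3.0, 1.0], [0.5, 0.10, 0.5])
        assert call_qtl_peaks(scan, wmap, alpha=0.10) == []

    def test_invariant_to_appended_zero_windows(self):
        lods = [1.0, 3.6, 2.5, 3.4, 1.0]
        p = [0.5, 0.01, 0.2, 0.02, 0.5]
        scan1, wmap1 = _scan_frame(lods, p, cm=[0, 15, 30, 45, 60])
        scan2, wmap2 = _scan_frame(lods + [0.0, 0.0], p + [1.0, 1.0], cm=[0, 15, 30, 45, 60, 75, 90])
        c1 = call_qtl_peaks(scan1, wmap1)
        c2 = call_qtl_peaks(scan2, wmap2)
        assert [c.peak_window for c in c1] == [c.peak_window for c in c2]

    def test_requires_p_values(self):
        scan, wmap = _scan_frame([1.0, 2.0], [np.nan, np.nan])
        with pytest.raises(ValueError):
            call_qtl_peaks(scan, wmap)


class TestQtlH2:
    def test_zero_lod_gives_zero(self):
        assert qtl_h2(0.0, 100) == 0.0

    def test_matches_regression_r2(self):
        g = np.array([0.0, 0, 2, 2])
        y = np.array([0.1, -0.1, 0.9, 1.1])
        scan = scan_additive(_single_window(g), y)
        r2 = 1.0 - 0.04 / 1.04
        assert qtl_h2(float(scan["lod"][0]), 4) == pytest.approx(r2, abs=1e-12)

    def test_limit_is_one(self):
        assert qtl_h2(1e9, 100) == pytest.approx(1.0)

    def test_negative_lod_rejected(self):
        with pytest.raises(ValueError):
            qtl_h2(-0.1, 100)


class TestTraitUtilities:
    def test_self_and_negation_correlation(self):
        rng = np.random.default_rng(2)
        t = rng.normal(size=50)
        df = pd.DataFrame({"a": t, "b": -t})
        r, p, n = correlate_traits(df)
        assert r.loc["a", "a"] == pytest.approx(1.0)
        assert r.loc["a", "b"] == pytest.approx(-1.0)

    def test_shared_qtl_induces_correlation(self, small_panel):
        matrix, _ = small_panel
        g = matrix.dosage[:, 5]
        rng = np.random.default_rng(3)
        a = g + rng.normal(0, 0.5, g.size)
        b = g + rng.normal(0, 0.5, g.size)
        var_g = np.var(g)
        expected = var_g / (var_g + 0.25)
        r, _, _ = correlate_traits(pd.DataFrame({"a": a, "b": b}))
        assert r.loc["a", "b"] == pytest.approx(expected, abs=0.2)

    def test_too_few_pairs_left_missing(self):
        df = pd.DataFrame({"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, np.nan, 1.0, 2.0]})
        r, _, n = correlate_traits(df)
        assert np.isnan(r.loc["a", "b"])
        assert n.loc["a", "b"] == 0

    def test_residual_scan_of_identical_traits_is_null(self, small_panel, small_summary):
        matrix, _ = small_panel
        y = np.random.default_rng(4).normal(size=matrix.n_rils)
        scan = map_residuals(y, y, matrix, small_summary)
        assert (scan["lod"].fillna(0.0) == 0.0).all()

    def test_residual_scan_recovers_extra_qtl(self, small_panel, small_summary):
        matrix, _ = small_panel
        rng = np.random.default_rng(5)
        w = 30
        base = rng.normal(size=matrix.n_rils)
        extra = base + 1.0 * matrix.dosage[:, w] + rng.normal(0, 0.2, matrix.n_rils)
        scan = map_residuals(extra, base, matrix, small_summary)
        assert int(np.nanargmax(scan["lod"].to_numpy())) == w

    def test_constant_covariate_trait_rejected(self, small_panel):
        matrix, _ = small_panel
        y = np.random.default_rng(6).normal(size=matrix.n_rils)
        with pytest.raises(ValueError):
            map_residuals(y, np.ones(matrix.n_rils), matrix)
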