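"""Hudson F_ST components, window statistics and outlier flagging."""

import numpy as np
import pandas as pd
import pytest

from rilqtl.fst import (
    DEFAULT_HIGH_RECOMB,
    flag_outliers,
    snp_fst,
    window_fst_from_arrays,
    window_fst_from_genotypes,
    window_fst_vcf,
)
from rilqtl.simulate import simulate_snp_matrix


def _wmap(n, arm="2L", size=1000, start0=1_000_000):
    return pd.DataFrame(
        {
            "window_id": [f"{arm}_f{i}" for i in range(n)],
            "arm": arm,
            "start": [start0 + i * size for i in range(n)],
            "end": [start0 + (i + 1) * size for i in range(n)],
            "cM": [float(i) for i in range(n)],
            "n_snps": 10,
        }
    )


class TestSnpFst:
    def test_equal_frequencies_near_zero(self):
        # slightly negative in expectation: the numerator is unbiased
        num, den = snp_fst(500, 1000, 500, 1000)
        assert num / den == pytest.approx(0.0, abs=2e-3)

    def test_fixed_difference_is_one(self):
        num, den = snp_fst(10, 10, 0, 10)
        assert num / den == pytest.approx(1.0)

    def test_closed_form_example(self):
        """p1=0.8, p2=0.2 with n=9 alleles each: num 0.32, den 0.68."""
        num, den = snp_fst(7.2, 9, 1.8, 9)
        assert num == pytest.approx(0.32, abs=1e-12)
        assert den == pytest.approx(0.68, abs=1e-12)
        assert num / den == pytest.approx(0.4706, abs=1e-4)

    def test_monomorphic_both_gives_zero_components(self):
        num, den = snp_fst(0, 10, 0, 10)
        assert num == 0.0 and den == 0.0

    def test_small_samples_rejected(self):
        with pytest.raises(ValueError):
            snp_fst(1, 1, 5, 10)

    def test_mean_fst_matches_estimator_expectation(self):
        """Hudson estimator on simulated SNPs at p1=0.8, p2=0.2 averages to
        the plug-in value of the closed form."""
        g, labels = simulate_snp_matrix(50, 50, 2000, (0.8, 0.2), seed=3)
        ac1 = g[labels == "pop1"].sum(axis=0)
        ac2 = g[labels == "pop2"].sum(axis=0)
        num, den = snp_fst(ac1, 100, ac2, 100)
        ratio = num.sum() / den.sum()
        expected = (0.6**2) / (0.8 * 0.8 + 0.2 * 0.2)  # unbiased numerator / den
        assert ratio == pytest.approx(expected, abs=0.02)


class TestWindowFst:
    def test_single_snp_window_fullwin_equals_maxsnp(self):
        wmap = _wmap(1)
        res = window_fst_from_arrays(
            ["2L"], [1_000_500], [8], [10], [2], [10], wmap
        )
        assert res["fst_fullwin_raw"][0] == res["fst_maxsnp_raw"][0]

    def test_three_snp_ratio_of_sums_vs_mean_of_ratios(self):
        """Hand computation on three SNP frequency pairs: the window uses
        ratio-of-sums, which differs from the mean of per-SNP ratios."""
        wmap = _wmap(1)
        acs = [(10, 0), (8, 2), (6, 4)]  # derived counts of 10 alleles each
        nums, dens = [], []
        for a1, a2 in acs:
            n, d = snp_fst(a1, 10, a2, 10)
            nums.append(float(n))
            dens.append(float(d))
        res = window_fst_from_arrays(
            ["2L"] * 3,
            [1_000_100, 1_000_200, 1_000_300],
            [a for a, _ in acs], [10] * 3,
            [b for _, b in acs], [10] * 3,
            wmap,
        )
        ratio_of_sums = sum(nums) / sum(dens)
        mean_of_ratios = np.mean([n / d for n, d in zip(nums, dens)])
        assert res["fst_fullwin_raw"][0] == pytest.approx(ratio_of_sums, abs=1e-12)
        assert res["fst_maxsnp_raw"][0] == pytest.approx(max(n / d for n, d in zip(nums, dens)))
        assert abs(ratio_of_sums - mean_of_ratios) > 1e-6

    def test_identical_frequencies_near_zero(self):
        g, labels = simulate_snp_matrix(30, 30, 200, (0.5, 0.5), seed=4)
        wmap = _wmap(1, size=10_000)
        pos = np.linspace(1_000_010, 1_009_990, 200).astype(int)
        res = window_fst_from_genotypes(g, labels, ["2L"] * 200, pos, wmap)
        assert abs(res["fst_fullwin_raw"][0]) < 0.05

    def test_window_without_snps_missing(self):
        wmap = _wmap(2)
        res = window_fst_from_arrays(["2L"], [1_000_100], [8], [10], [2], [10], wmap)
        assert np.isnan(res["fst_fullwin_raw"][1])
        assert res["n_snps_used"][1] == 0

    def test_label_permutation_centers_near_zero(self):
        g, labels = simulate_snp_matrix(30, 30, 500, (0.9, 0.1), seed=5)
        rng = np.random.default_rng(6)
        perm = rng.permutation(labels)
        wmap = _wmap(1, size=50_000)
        pos = np.linspace(1_000_010, 1_049_990, 500).astype(int)
        res = window_fst_from_genotypes(g, perm, ["2L"] * 500, pos, wmap)
        assert abs(res["fst_fullwin_raw"][0]) < 0.05


class TestVcfReader:
    def test_vcf_matches_array_route(self, tmp_path):
        rng = np.random.default_rng(7)
        n1 = n2 = 6
        n_snps = 40
        g, labels = simulate_snp_matrix(n1, n2, n_snps, (0.8, 0.2), seed=8)
        samples = [f"s{i}" for i in range(n1 + n2)]
        pos = np.arange(1_000_100, 1_000_100 + n_snps * 10, 10)
        lines = [
            "##fileformat=VCFv4.2",
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            "##contig=<ID=2L>",
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples),
        ]
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j in range(n_snps):
            gts = "\t".join(gt_map[int(g[i, j])] for i in range(n1 + n2))
            lines.append(f"2L\t{pos[j] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}")
        vcf_path = tmp_path / "synthetic.vcf"
        vcf_path.write_text("\n".join(lines) + "\n")

        wmap = _wmap(1, size=1_000)
        pops = pd.DataFrame({"sample": samples, "population": labels})
        res_vcf = window_fst_vcf(vcf_path, wmap, pops)
        ac1 = g[labels == "pop1"].sum(axis=0)
        ac2 = g[labels == "pop2"].sum(axis=0)
        res_arr = window_fst_from_arrays(
            ["2L"] * n_snps, pos, ac1, [2 * n1] * n_snps, ac2, [2 * n2] * n_snps, wmap
        )
        assert res_vcf["fst_fullwin_raw"][0] == pytest.approx(
            res_arr["fst_fullwin_raw"][0], abs=1e-12
        )
        assert res_vcf["n_snps_used"][0] == res_arr["n_snps_used"][0]


class TestFlagOutliers:
    def _results(self, values, arm="2L", start0=1_000_000):
        n = len(values)
        return pd.DataFrame(
            {
                "window_id": [f"{arm}_f{i}" for i in range(n)],
                "arm": arm,
                "start": [start0 + i * 1000 for i in range(n)],
                "end": [start0 + (i + 1) * 1000 for i in range(n)],
                "fst_fullwin": values,
                "fst_maxsnp": values,
                "fst_fullwin_raw": values,
                "fst_maxsnp_raw": values,
                "n_snps_used": 5,
            }
        )

    def test_exactly_two_of_200_flagged(self):
        vals = list(np.linspace(0.0, 0.5, 200))
        out = flag_outliers(self._results(vals))
        assert int(out["outlier_fst_fullwin"].sum()) == 2

    def test_window_outside_recomb_interval_never_flagged(self):
        vals = [0.1] * 50 + [0.99]
        res = self._results(vals)
        res.loc[50, ["start", "end"]] = [40_000_000, 40_001_000]  # beyond 2L interval
        out = flag_outliers(res)
        assert not bool(out.loc[50, "outlier"])
        assert not bool(out.loc[50, "eligible"])

    def test_ties_at_threshold_all_flagged(self):
        vals = [0.2] * 150
        with pytest.warns(UserWarning):
            out = flag_outliers(self._results(vals[:50]))
        assert out["outlier"].all()  # all tied at the (k=1) threshold

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        vals = list(rng.uniform(0, 1, 120))
        res = self._results(vals)
        out1 = flag_outliers(res)
        shuffled = res.sample(frac=1.0, random_state=1)
        out2 = flag_outliers(shuffled).sort_index()
        pd.testing.assert_series_equal(out1["outlier"], out2["outlier"])

    def test_extra_statistic_joins_union(self):
        res = self._results([0.1] * 200)
        res["chi_md"] = 0.0
        res.loc[7, "chi_md"] = 5.0
        out = flag_outliers(res, extra_statistics=["chi_md"])
        assert bool(out.loc[7, "outlier"])

    def test_default_intervals_cover_expected_arms(self):
        assert set(DEFAULT_HIGH_RECOMB) == {"X", "2L", "2R", "3L", "3R"}
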