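"""Normalization factors, offsets, count-model inference and enrichment
scores."""

import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata, spearmanr

from mavekit import (
    adjust_fdr,
    filter_by_min_count,
    fit_nb_ql,
    fit_voom,
    ppi_scores,
    simulate_counts,
    tmm_factors,
    wt_offsets,
)


def design_two_group(cols, split):
    g = [0] * split + [1] * (len(cols) - split)
    return pd.DataFrame({"intercept": 1.0, "group": g}, index=cols)


def tmm_oracle(y, ref, log_ratio_trim=0.3, sum_trim=0.05):
    """Independently coded trimmed weighted mean of M-values (explicit
    loops over features)."""
    lib = y.sum(axis=0)
    factors = []
    for j in range(y.shape[1]):
        ms, aas, ws = [], [], []
        for g in range(y.shape[0]):
            o, r = y[g, j], y[g, ref]
            if o == 0 or r == 0:
                continue
            po, pr = o / lib[j], r / lib[ref]
            ms.append(np.log2(po / pr))
            aas.append(0.5 * np.log2(po * pr))
            ws.append((lib[j] - o) / (lib[j] * o) + (lib[ref] - r) / (lib[ref] * r))
        ms, aas, ws = map(np.asarray, (ms, aas, ws))
        if ms.size == 0 or np.max(np.abs(ms)) < 1e-6:
            factors.append(1.0)
            continue
        n = ms.size
        rm, ra = rankdata(ms), rankdata(aas)
        lo_m, hi_m = np.floor(n * log_ratio_trim) + 1, n - np.floor(n * log_ratio_trim)
        lo_a, hi_a = np.floor(n * sum_trim) + 1, n - np.floor(n * sum_trim)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        f = np.sum(ms[keep] / ws[keep]) / np.sum(1.0 / ws[keep])
        factors.append(2.0 ** f)
    factors = np.asarray(factors)
    return factors / np.exp(np.mean(np.log(factors)))


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        y = pd.DataFrame(np.tile([[10], [200], [3000], [50]], (1, 4)))
        assert (tmm_factors(y) == 1.0).all()

    def test_pure_depth_scaling_gives_unit_factors(self, rng):
        base = rng.poisson(100, size=200)
        y = pd.DataFrame({"a": base, "b": 2 * base})
        f = tmm_factors(y)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_scale_invariance(self, rng):
        """Depth-only rescaling of one sample leaves factors unchanged up
        to the (library-size dependent) precision weighting."""
        y = rng.poisson(100.0, size=(300, 4)).astype(float)
        y[:30, 2] *= 5
        f1 = tmm_factors(pd.DataFrame(y), ref_sample=0)
        y2 = y.copy()
        y2[:, 1] *= 7.0
        f2 = tmm_factors(pd.DataFrame(y2), ref_sample=0)
        assert np.allclose(f1, f2, atol=5e-3)

    def test_composition_shift_matches_independent_oracle(self, rng):
        y = rng.negative_binomial(5, 5 / 205, size=(200, 6)).astype(float)
        y[:20, 3] *= 8
        got = tmm_factors(pd.DataFrame(y), ref_sample=0)
        want = tmm_oracle(y, ref=0)
        assert np.allclose(got, want, atol=1e-10)

    def test_matches_edger_reference_implementation(self, rng, tmp_path):
        y = rng.negative_binomial(5, 5 / 205, size=(150, 5))
        y[:15, 2] *= 6
        df = pd.DataFrame(y, columns=[f"s{i}" for i in range(5)])
        path = tmp_path / "counts.tsv"
        df.to_csv(path, sep="\t", index=False)
        script = (
            'suppressMessages(library(edgeR));'
            f'y <- as.matrix(read.delim("{path}"));'
            'cat(sprintf("%.8f", calcNormFactors(y, method="TMM")), sep=" ")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        ref = np.array([float(v) for v in out.stdout.split()])
        assert np.allclose(tmm_factors(df).to_numpy(), ref, atol=1e-6)

    def test_all_zero_column_is_hard_error(self):
        y = pd.DataFrame({"a": [1, 2], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(y)


class TestWtOffsets:
    def test_single_wildtype_row_sum(self):
        y = pd.DataFrame({"a": [10, 5], "b": [20, 6]}, index=["WT", "v"])
        assert np.allclose(wt_offsets(y, ["WT"]), np.log([10, 20]))

    def test_two_rows_geometric_mean(self):
        y = pd.DataFrame({"a": [10, 1000]}, index=["w1", "w2"])
        assert np.allclose(wt_offsets(y, ["w1", "w2"], "geomean"), np.log(100))

    def test_sum_and_geomean_agree_on_equal_rows(self):
        y = pd.DataFrame({"a": [50, 50]}, index=["w1", "w2"])
        s = wt_offsets(y, ["w1", "w2"], "sum")
        g = wt_offsets(y, ["w1", "w2"], "geomean")
        assert np.allclose(np.exp(s), 2 * np.exp(g))

    def test_zero_aggregate_is_hard_error(self):
        y = pd.DataFrame({"a": [0], "b": [5]}, index=["WT"])
        with pytest.raises(ValueError):
            wt_offsets(y, ["WT"])


class TestInference:
    def test_constant_feature_has_zero_logfc(self):
        counts, _ = simulate_counts(60, (3, 3), 200, 0.1, seed=4)
        counts.loc["flat"] = 500
        design = design_two_group(counts.columns, 3)
        res = fit_nb_ql(counts, design, "group", normalization="libsize")
        # offsets equal across samples (equal nominal depth) -> exact fit
        assert abs(res.loc["flat", "logFC"]) < 0.2

    def test_wildtype_offset_logfc_of_wildtype_is_zero(self):
        counts, _ = simulate_counts(100, (3, 3), 300, 0.1, seed=5)
        counts.loc["WT"] = [4000, 4500, 5000, 5200, 4800, 4700]
        design = design_two_group(counts.columns, 3)
        res = fit_nb_ql(counts, design, "group", normalization="wtsum",
                        wt_rows=["WT"])
        assert abs(res.loc["WT", "logFC"]) < 1e-8

    def test_large_effects_rank_above_nulls_in_spike_simulation(self):
        lfc = np.zeros(500)
        lfc[:10] = 4.0
        counts, _ = simulate_counts(500, (3, 3), 2000, 0.02, logfc=lfc,
                                    seed=8, mean_spread_log2=0.3)
        design = design_two_group(counts.columns, 3)
        res = fit_voom(counts, design, "group")
        top10 = set(res.nsmallest(10, "pvalue").index)
        assert top10 == {f"v{i+1}" for i in range(10)}

    def test_nbql_and_voom_agree_in_sign_for_strong_effects(self, rng):
        lfc = np.zeros(300)
        lfc[:50] = rng.choice([-1.5, 1.5], size=50)
        counts, _ = simulate_counts(300, (3, 3), 800, 0.05, logfc=lfc, seed=13)
        design = design_two_group(counts.columns, 3)
        a = fit_nb_ql(counts, design, "group")
        b = fit_voom(counts, design, "group")
        strong = [f"v{i+1}" for i in range(50)]
        agree = np.sign(a.loc[strong, "logFC"]) == np.sign(b.loc[strong, "logFC"])
        assert agree.mean() >= 0.95

    def test_nbql_matches_edger_qlf_reference(self, tmp_path):
        lfc = np.zeros(300)
        lfc[:30] = np.linspace(-2, 2, 30)
        counts, _ = simulate_counts(300, (3, 3), 400, 0.1, logfc=lfc, seed=21)
        path = tmp_path / "m.tsv"
        counts.to_csv(path, sep="\t")
        design = design_two_group(counts.columns, 3)
        res = fit_nb_ql(counts, design, "group", normalization="tmm")
        script = f'''
suppressMessages(library(edgeR))
x <- read.delim("{path}", row.names=1)
y <- DGEList(as.matrix(x)); y <- calcNormFactors(y)
design <- model.matrix(~factor(c(0,0,0,1,1,1)))
y <- estimateDisp(y, design)
q <- glmQLFTest(glmQLFit(y, design), coef=2)
tt <- topTags(q, n=Inf, sort.by="none")$table
write.table(tt, "{tmp_path}/edger.tsv", sep="\\t", quote=FALSE)
'''
        subprocess.run(["Rscript", "-e", script], capture_output=True,
                       text=True, check=True)
        ref = pd.read_csv(tmp_path / "edger.tsv", sep="\t")
        ref.index = counts.index
        assert np.max(np.abs(res["logFC"] - ref["logFC"])) < 0.05
        assert spearmanr(res["pvalue"], ref["PValue"]).statistic > 0.95

    def test_rank_deficient_design_rejected(self):
        counts, _ = simulate_counts(20, (2, 2), 100, 0.1, seed=1)
        bad = pd.DataFrame({"a": [1.0] * 4, "b": [2.0] * 4},
                           index=counts.columns)
        with pytest.raises(ValueError, match="full column rank"):
            fit_nb_ql(counts, bad, "b")

    def test_min_count_filter_applies_to_selected_samples(self):
        counts = pd.DataFrame(
            {"in1": [100, 10], "in2": [60, 80], "out1": [5, 200]},
            index=["keep", "drop"],
        )
        kept = filter_by_min_count(counts, 50, ["in1", "in2"])
        assert list(kept.index) == ["keep"]


class TestPpiScores:
    def test_wildtype_scores_zero_in_every_replicate(self):
        counts = pd.DataFrame(
            {"i1": [10, 40], "i2": [20, 10], "o1": [30, 120], "o2": [10, 5]},
            index=["WT", "v"],
        )
        s = ppi_scores(counts, ["i1", "i2"], ["o1", "o2"], "WT")
        assert (s.loc["WT"] == 0).all()

    def test_variant_matching_wildtype_ratio_scores_zero(self):
        counts = pd.DataFrame({"i1": [10, 100], "o1": [30, 300]},
                              index=["WT", "v"])
        s = ppi_scores(counts, ["i1"], ["o1"], "WT")
        assert s.loc["v", "rep1"] == pytest.approx(0.0)

    def test_fourfold_enrichment_over_wildtype_scores_two(self):
        counts = pd.DataFrame({"i1": [10, 10], "o1": [20, 80]},
                              index=["WT", "v"])
        s = ppi_scores(counts, ["i1"], ["o1"], "WT")
        assert s.loc["v", "rep1"] == pytest.approx(2.0)

    def test_unpaired_samples_rejected(self):
        counts = pd.DataFrame({"i1": [1], "o1": [2]}, index=["WT"])
        with pytest.raises(ValueError):
            ppi_scores(counts, ["i1"], [], "WT")


class TestAdjustFdr:
    def test_single_pvalue_unchanged(self):
        assert adjust_fdr([0.05]) == pytest.approx([0.05])

    def test_equal_pvalues_unchanged(self):
        assert adjust_fdr([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    def test_stepup_hand_computed_example(self):
        # p_(i) * m / i, cummin from the right: all become 0.04
        assert adjust_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_out_of_range_pvalues_rejected(self):
        with pytest.raises(ValueError):
            adjust_fdr([0.5, 1.5])
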