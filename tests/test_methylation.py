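"""Tests for methylation-context annotation, differential labeling,
enrichment nulls, cis correlation and the survival screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epireg import methylation as meth
from epireg import synth
from epireg.io import GenomicIntervalSet


def intervals(rows):
    return GenomicIntervalSet(pd.DataFrame(
        rows, columns=GenomicIntervalSet.COLUMNS))


class TestCpGContext:
    @pytest.mark.parametrize("pos,expected", [
        (10250, "island"),   # inside [10000, 10500)
        (9000, "shore"),     # 1000 bp upstream of the island start
        (7000, "shelf"),     # 3000 bp upstream
        (5000, "open_sea"),  # 5000 bp upstream
        (10499, "island"),   # last island base (half-open)
        (10500, "shore"),    # first base past the island
        (9999, "shore"),     # one left of the island start
    ])
    def test_single_island_distances(self, pos, expected):
        cpgi = intervals([("chr1", 10000, 10500, "i1", 0, ".")])
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [pos]}, index=["s"])
        assert meth.cpg_context(sites, cpgi)["s"] == expected

    def test_gap_between_close_islands_is_all_shore(self):
        cpgi = intervals([("chr1", 10000, 10500, "i1", 0, "."),
                          ("chr1", 11500, 12000, "i2", 0, ".")])
        gap = np.arange(10500, 11500, 97)
        sites = pd.DataFrame({"chrom": "chr1", "pos": gap},
                             index=[f"s{i}" for i in range(len(gap))])
        ctx = meth.cpg_context(sites, cpgi)
        assert (ctx == "shore").all()

    def test_every_site_gets_exactly_one_context(self, small_genome):
        coords = small_genome.site_coords
        ctx = meth.cpg_context(coords, small_genome.cpg_islands)
        assert ctx.isin(meth.CPG_CONTEXTS).all()


class TestGeneContext:
    def _genes(self):
        return pd.DataFrame({
            "chrom": ["chr1", "chr1"],
            "start": [50000, 49000],
            "end": [60000, 49500],
            "strand": ["+", "-"],
            "tss": [50000, 49499],
        }, index=["geneA", "geneB"])

    def test_promoter_assignment_strand_aware(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [48500]}, index=["s"])
        out = meth.gene_context(sites, self._genes())
        assert out.loc["s", "gene_context"] == "promoter"

    def test_promoter_precedence_over_gene_body(self):
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [10000, 21000],
            "end": [30000, 25000], "strand": ["+", "+"],
            "tss": [10000, 21000]}, index=["host", "inner"])
        # inside host's body but within 2 kb of inner's TSS
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [20500]}, index=["s"])
        out = meth.gene_context(sites, genes)
        assert out.loc["s", "gene_context"] == "promoter"
        assert out.loc["s", "gene"] == "inner"

    def test_equidistant_tss_tie_breaks_lexicographically(self):
        genes = pd.DataFrame({
            "chrom": ["chr1", "chr1"], "start": [10000, 30000],
            "end": [11000, 31000], "strand": ["+", "+"],
            "tss": [10000, 30000]}, index=["zgene", "agene"])
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [20000]}, index=["s"])
        out = meth.gene_context(sites, genes)
        assert out.loc["s", "gene_context"] == "intergenic"
        assert out.loc["s", "gene"] == "agene"

    def test_gene_body_pairs_with_host(self):
        sites = pd.DataFrame({"chrom": ["chr1"], "pos": [55000]}, index=["s"])
        out = meth.gene_context(sites, self._genes())
        assert out.loc["s", "gene_context"] == "gene_body"
        assert out.loc["s", "gene"] == "geneA"


class TestLog2FC:
    def _beta(self, cancer_mean, normal_mean, n=60):
        rng = np.random.default_rng(0)
        idx = [f"c{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
        groups = pd.Series(["cancer"] * n + ["normal"] * n, index=idx)
        vals = np.concatenate([
            np.clip(cancer_mean + 0.01 * rng.standard_normal(n), 1e-4, 1),
            np.clip(normal_mean + 0.01 * rng.standard_normal(n), 1e-4, 1)])
        return pd.DataFrame({"s1": vals}, index=idx), groups

    def test_hyper_label_for_high_cancer_methylation(self):
        beta, groups = self._beta(0.8, 0.2)
        out = meth.methylation_log2fc(beta, groups)
        assert out.loc["s1", "log2fc"] == pytest.approx(-2.0, abs=0.1)
        assert out.loc["s1", "label"] == "hyper"

    def test_hypo_label_for_low_cancer_methylation(self):
        beta, groups = self._beta(0.2, 0.8)
        out = meth.methylation_log2fc(beta, groups)
        assert out.loc["s1", "log2fc"] == pytest.approx(2.0, abs=0.1)
        assert out.loc["s1", "label"] == "hypo"

    def test_equal_means_are_medium(self):
        beta, groups = self._beta(0.5, 0.5)
        out = meth.methylation_log2fc(beta, groups)
        assert abs(out.loc["s1", "log2fc"]) < 0.2
        assert out.loc["s1", "label"] == "medium"

    def test_antisymmetric_under_group_swap(self):
        beta, groups = self._beta(0.7, 0.3)
        a = meth.methylation_log2fc(beta, groups)
        swapped = groups.map({"cancer": "normal", "normal": "cancer"})
        b = meth.methylation_log2fc(beta, swapped)
        assert a.loc["s1", "log2fc"] == pytest.approx(
            -b.loc["s1", "log2fc"], abs=1e-9)
        assert {a.loc["s1", "label"], b.loc["s1", "label"]} == \
            {"hyper", "hypo"}

    def test_planted_labels_agree_with_convention(self, small_cohort):
        mats, meta_df, truth = small_cohort
        beta = mats["meth"].data
        out = meth.methylation_log2fc(beta, meta_df["group"])
        planted = truth.informative["meth"]
        # direction (sign of log2FC) must match the planted label for all
        for site in planted:
            lfc = out.loc[site, "log2fc"]
            if truth.dms_label[site] == "hyper":
                assert lfc < 0
            else:
                assert lfc > 0


class TestDifferentialTest:
    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(1)
        n, p = 60, 400
        idx = [f"s{i}" for i in range(n)]
        groups = pd.Series(["cancer"] * 30 + ["normal"] * 30, index=idx)
        values = pd.DataFrame(rng.normal(size=(n, p)), index=idx,
                              columns=[f"f{i}" for i in range(p)])
        out = meth.differential_test(values, groups)
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_shift_detected_after_fdr(self):
        rng = np.random.default_rng(2)
        idx = [f"s{i}" for i in range(120)]
        groups = pd.Series(["cancer"] * 100 + ["normal"] * 20, index=idx)
        base = rng.normal(size=(120, 50))
        base[:100, 0] += 2.0                      # 2 pooled SDs
        values = pd.DataFrame(base, index=idx,
                              columns=[f"f{i}" for i in range(50)])
        out = meth.differential_test(values, groups)
        assert out.loc["f0", "q"] < 0.05

    def test_tiny_group_skipped_with_warning(self):
        idx = ["a", "b", "c", "d"]
        groups = pd.Series(["cancer", "cancer", "cancer", "normal"],
                           index=idx)
        values = pd.DataFrame({"f": [1.0, 2.0, 3.0, 4.0]}, index=idx)
        with pytest.warns(UserWarning):
            out = meth.differential_test(values, groups)
        assert np.isnan(out.loc["f", "p"])


class TestRegionEnrichment:
    def test_matched_proportions_give_no_calls(self):
        bg = ["island"] * 100 + ["shore"] * 100 + ["shelf"] * 100 + \
            ["open_sea"] * 100
        obs = ["island"] * 25 + ["shore"] * 25 + ["shelf"] * 25 + \
            ["open_sea"] * 25
        out = meth.region_enrichment(obs, bg)
        assert (out["p_bonferroni"] > 0.9).all()

    def test_overrepresented_region_called_enriched(self):
        rng = np.random.default_rng(3)
        regions = np.array(meth.CPG_CONTEXTS)
        bg = list(rng.choice(regions, size=4000, p=[0.25] * 4))
        obs = list(rng.choice(regions, size=2000,
                              p=[0.5, 1 / 6, 1 / 6, 1 / 6]))
        out = meth.region_enrichment(obs, bg).set_index("region")
        assert out.loc["island", "p_bonferroni"] < 0.05
        assert out.loc["island", "direction"] == "enriched"

    def test_absent_region_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            out = meth.region_enrichment(["island"] * 10, ["island"] * 10)
        assert set(out["region"]) == {"island"}


class TestChromatinStateEnrichment:
    def _tracks(self):
        rows = []
        for i, s in enumerate(synth.CHROMATIN_STATES):
            rows.append(("chr1", i * 1000, (i + 1) * 1000, s, 0, "."))
        return intervals(rows)

    def _sites(self, positions):
        return pd.DataFrame({"chrom": "chr1", "pos": positions},
                            index=[f"s{i}" for i in range(len(positions))])

    def test_uniform_subset_not_significant(self):
        states = self._tracks()
        rng = np.random.default_rng(4)
        panel = self._sites(rng.integers(0, 8000, 600))
        sub_idx = rng.choice(600, 80, replace=False)
        dms = panel.iloc[sub_idx]
        out = meth.chromatin_state_enrichment(dms, states, panel,
                                              n_draws=400, seed=5)
        assert (out["p_two_sided"] > 0.01).all()

    def test_fully_planted_state_attains_minimum_p(self):
        states = self._tracks()
        rng = np.random.default_rng(6)
        panel = self._sites(np.concatenate([
            rng.integers(0, 8000, 900),
            rng.integers(6000, 7000, 100)]))   # heterochromatin is state 7
        dms = panel.iloc[-60:]                 # all inside heterochromatin
        out = meth.chromatin_state_enrichment(dms, states, panel,
                                              n_draws=1000, seed=7)
        row = out.set_index("state").loc["heterochromatin"]
        assert row["p_enrich"] == pytest.approx(1 / 1001)

    def test_zero_draws_rejected(self):
        states = self._tracks()
        sites = self._sites([100])
        with pytest.raises(ValueError):
            meth.chromatin_state_enrichment(sites, states, sites, n_draws=0)

    def test_empirical_p_bounds_and_tail_identity(self, rng):
        null = rng.normal(size=200)
        for obs in (-10, 0.0, 10):
            hi, lo, two = meth.empirical_p(null, obs)
            assert 0 < hi <= 1 and 0 < lo <= 1 and 0 < two <= 1
            assert hi + lo >= 1.0


class TestCisCorrelation:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        idx = [f"s{i}" for i in range(80)]
        expr = pd.DataFrame({"geneA": rng.lognormal(3, 1, 80)}, index=idx)
        gene_table = pd.DataFrame({"chrom": ["chr1"], "tss": [500_000],
                                   "start": [500_000], "end": [520_000],
                                   "strand": ["+"]}, index=["geneA"])
        x = np.log(expr["geneA"].to_numpy())
        z = (x - x.mean()) / x.std()
        near = np.clip(1 / (1 + np.exp(1.5 * z)) +
                       0.03 * rng.standard_normal(80), 1e-6, 1 - 1e-6)
        beta = pd.DataFrame({
            "cg_near": near,
            "cg_far": rng.uniform(0.2, 0.8, 80),
        }, index=idx)
        coords = pd.DataFrame({"chrom": ["chr1", "chr1"],
                               "pos": [600_000, 2_500_000]},
                              index=["cg_near", "cg_far"])
        return expr, beta, gene_table, coords

    def test_planted_negative_pair_detected(self):
        expr, beta, genes, coords = self._setup()
        out = meth.cis_correlation(expr, beta, genes, coords)
        hit = out[(out["gene"] == "geneA") & (out["site"] == "cg_near")]
        assert len(hit) == 1 and bool(hit.iloc[0]["significant"])
        assert hit.iloc[0]["rho"] <= -0.6

    def test_site_outside_window_never_tested(self):
        expr, beta, genes, coords = self._setup()
        out = meth.cis_correlation(expr, beta, genes, coords)
        assert "cg_far" not in set(out["site"])   # 2 Mbp away

    def test_constant_beta_skipped(self):
        expr, beta, genes, coords = self._setup()
        beta["cg_near"] = 0.5
        out = meth.cis_correlation(expr, beta, genes, coords)
        assert out.empty


class TestSurvival:
    def test_constant_beta_site_skipped(self):
        idx = [f"s{i}" for i in range(20)]
        beta = pd.DataFrame({"flat": np.full(20, 0.4)}, index=idx)
        surv = pd.DataFrame({"time": np.arange(1, 21, dtype=float),
                             "event": np.ones(20, dtype=int)}, index=idx)
        out = meth.survival_screen(beta, surv)
        assert out.empty

    def test_planted_hazard_site_significant(self, rng):
        n = 200
        idx = [f"s{i}" for i in range(n)]
        beta = pd.DataFrame({"site": rng.uniform(0, 1, n)}, index=idx)
        high = (beta["site"] > beta["site"].median()).to_numpy()
        lam = np.where(high, 0.3, 0.1)
        time = rng.exponential(1 / lam)
        surv = pd.DataFrame({"time": time, "event": np.ones(n, dtype=int)},
                            index=idx)
        out = meth.survival_screen(beta, surv)
        assert out.loc["site", "p"] < 0.01

    def test_bootstrap_null_counts_cover_uniform_subset(self, rng):
        n = 120
        idx = [f"s{i}" for i in range(n)]
        beta = pd.DataFrame(rng.uniform(0, 1, size=(n, 60)), index=idx,
                            columns=[f"cg{i}" for i in range(60)])
        surv = pd.DataFrame({"time": rng.exponential(10, n),
                             "event": rng.integers(0, 2, n)}, index=idx)
        counts = meth.survival_bootstrap_null(beta, surv, set_size=30,
                                              n_rounds=50, seed=1)
        screen = meth.survival_screen(beta.iloc[:, :30], surv)
        observed = int(screen["significant"].sum())
        lo, hi = np.percentile(counts, [2.5, 97.5])
        assert lo - 2 <= observed <= hi + 2
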