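"""Genomic-context annotation and statistics for DNA methylation sites.

Covers CpG-island context (island / shore / shelf / open sea, with shores and
shelves as successive 2 kb flanks), gene context (promoter = TSS +/- 2 kb,
strand-aware; precedence promoter > gene body > intergenic; intergenic sites
pair with the nearest TSS), hyper/medium/hypo labeling from the beta-value
log2 fold change, rank-based differential tests with FDR, chi-squared region
enrichment against the array background, chromatin-state enrichment with a
constructed resampling null, a +/- 1 Mbp cis-correlation screen, and a
median-split log-rank survival screen with a bootstrap null.

Fold-change conventions (logged prominently because the two omics differ):
methylation log2FC = log2(mean beta normal / mean beta cancer), so sites more
methylated in cancer get log2FC <= -1 and the label "hyper"; expression
log2FC (see :mod:`epireg.regnet`) is log2(cancer / normal), so genes silenced
in cancer get negative values.
"""

from __future__ import annotations

import logging
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenomicIntervalSet

log = logging.getLogger("epireg")

EPS = 1e-6   # pseudocount guarding log of zero group means

CPG_CONTEXTS = ("island", "shore", "shelf", "open_sea")
GENE_CONTEXTS = ("promoter", "gene_body", "intergenic")


# ---------------------------------------------------------------------------
# Context annotation
# ---------------------------------------------------------------------------

def cpg_context(sites: pd.DataFrame, cpgi: GenomicIntervalSet,
                flank: int = 2000) -> pd.Series:
    """CpG context per site with precedence island > shore > shelf > open sea.

    ``sites`` needs columns ``chrom`` and ``pos``.  A site inside an island is
    ``island``; within ``flank`` bp of an island edge, ``shore``; within a
    further ``flank`` bp, ``shelf``; otherwise ``open_sea``.  Overlapping
    flanks of neighboring islands resolve by that precedence; flanks are
    implicitly clipped at chromosome bounds (positions are never negative).
    """
    out = pd.Series("open_sea", index=sites.index, dtype=object)
    islands = cpgi.by_chrom()
    for chrom, grp in sites.groupby("chrom"):
        isl = islands.get(chrom)
        if isl is None:
            continue
        starts = isl["start"].to_numpy()
        ends = isl["end"].to_numpy()
        pos = grp["pos"].to_numpy()
        # distance to the nearest island: 0 if inside (half-open intervals)
        dist = np.full(len(pos), np.inf)
        for s, e in zip(starts, ends):
            d = np.maximum.reduce([s - pos, pos - (e - 1), np.zeros(len(pos))])
            dist = np.minimum(dist, d)
        ctx = np.where(dist == 0, "island",
                       np.where(dist <= flank, "shore",
                                np.where(dist <= 2 * flank, "shelf",
                                         "open_sea")))
        out.loc[grp.index] = ctx
    return out


def gene_context(sites: pd.DataFrame, genes: pd.DataFrame,
                 promoter_flank: int = 2000) -> pd.DataFrame:
    """Gene context and paired target gene per site.

    ``genes`` is the table from :meth:`GenomeFixture.gene_table` (columns
    ``chrom``, ``start``, ``end``, ``strand``, ``tss`` indexed by gene name).
    Promoter = within ``promoter_flank`` bp of the strand-aware TSS;
    precedence promoter > gene body > intergenic.  Promoter and intergenic
    sites pair with the nearest-TSS gene (ties by lexicographic gene ID);
    gene-body sites pair with their host gene.
    """
    ctx = pd.Series("intergenic", index=sites.index, dtype=object)
    paired = pd.Series("", index=sites.index, dtype=object)
    for chrom, grp in sites.groupby("chrom"):
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        pos = grp["pos"].to_numpy()[:, None]
        tss = g["tss"].to_numpy()[None, :]
        names = np.array(g.index, dtype=object)
        dist = np.abs(pos - tss)                       # n_sites x n_genes
        # nearest TSS with lexicographic tie-break: sort genes by name first
        order = np.argsort(names)
        dist_o = dist[:, order]
        nearest = order[np.argmin(dist_o, axis=1)]     # argmin takes first=lex
        min_dist = dist[np.arange(len(pos)), nearest]
        in_promoter = min_dist <= promoter_flank
        in_body = ((pos >= g["start"].to_numpy()[None, :]) &
                   (pos < g["end"].to_numpy()[None, :]))
        body_any = in_body.any(axis=1)
        # host gene for body sites: nearest TSS among hosts, ties lexicographic
        body_gene = np.full(len(pos), "", dtype=object)
        for i in np.nonzero(body_any)[0]:
            hosts = np.nonzero(in_body[i])[0]
            hd = dist[i, hosts]
            best = hosts[np.lexsort((names[hosts], hd))][0]
            body_gene[i] = names[best]
        chrom_ctx = np.where(in_promoter, "promoter",
                             np.where(body_any, "gene_body", "intergenic"))
        chrom_gene = np.where(in_promoter, names[nearest],
                              np.where(body_any, body_gene, names[nearest]))
        ctx.loc[grp.index] = chrom_ctx
        paired.loc[grp.index] = chrom_gene
    return pd.DataFrame({"gene_context": ctx, "gene": paired})


# ---------------------------------------------------------------------------
# Differential methylation
# ---------------------------------------------------------------------------

def methylation_log2fc(beta: pd.DataFrame, groups: pd.Series,
                       threshold: float = 1.0) -> pd.DataFrame:
    """Per-site log2FC = log2(mean beta normal / mean beta cancer) and the
    hyper/medium/hypo label (hyper iff log2FC <= -threshold)."""
    is_cancer = (groups.loc[beta.index] == "cancer").to_numpy()
    mean_c = beta.loc[is_cancer].mean(axis=0)
    mean_n = beta.loc[~is_cancer].mean(axis=0)
    lfc = np.log2((mean_n + EPS) / (mean_c + EPS))
    label = pd.Series("medium", index=beta.columns, dtype=object)
    label[lfc <= -threshold] = "hyper"
    label[lfc >= threshold] = "hypo"
    return pd.DataFrame({"mean_cancer": mean_c, "mean_normal": mean_n,
                         "log2fc": lfc, "label": label})


def differential_test(values: pd.DataFrame, groups: pd.Series,
                      shapiro_alpha: float = 0.05) -> pd.DataFrame:
    """Two-sided rank-sum test per feature with Benjamini-Hochberg FDR.

    A Shapiro-Wilk normality check is run per feature and logged (the
    nonparametric test is used regardless, as the conservative choice for
    bounded beta-values); features with fewer than 3 samples in a group are
    skipped with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    is_cancer = (groups.loc[values.index] == "cancer").to_numpy()
    a = values.loc[is_cancer]
    b = values.loc[~is_cancer]
    ps, shapiro_ps = {}, {}
    if len(a) < 3 or len(b) < 3:
        warnings.warn("a group has fewer than 3 samples; all features skipped")
        return pd.DataFrame({"p": np.nan, "q": np.nan, "shapiro_p": np.nan,
                             "normal_ok": False}, index=values.columns)
    for col in values.columns:
        x, y = a[col].to_numpy(), b[col].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                sp = min(stats.shapiro(x).pvalue, stats.shapiro(y).pvalue)
            except ValueError:
                sp = np.nan
        shapiro_ps[col] = sp
        ps[col] = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
    out = pd.DataFrame({"p": pd.Series(ps), "shapiro_p": pd.Series(shapiro_ps)})
    out["normal_ok"] = out["shapiro_p"] > shapiro_alpha
    n_nonnormal = int((~out["normal_ok"]).sum())
    log.info("Shapiro-Wilk gate: %d / %d features non-normal; "
             "rank-sum test applied", n_nonnormal, len(out))
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out.loc[values.columns]


# ---------------------------------------------------------------------------
# Enrichment against backgrounds
# ---------------------------------------------------------------------------

def region_enrichment(observed: Sequence[str], background: Sequence[str],
                      regions: Sequence[str] = CPG_CONTEXTS) -> pd.DataFrame:
    """Per-region 2x2 chi-squared test (tested set vs background panel,
    in-region vs out-of-region) with Bonferroni correction over regions."""
    obs = pd.Series(observed).value_counts()
    bg = pd.Series(background).value_counts()
    n_obs, n_bg = obs.sum(), bg.sum()
    rows = []
    tested = [r for r in regions if (obs.get(r, 0) + bg.get(r, 0)) > 0]
    skipped = [r for r in regions if r not in tested]
    if skipped:
        warnings.warn(f"regions absent from both sets skipped: {skipped}")
    for region in tested:
        a, b = obs.get(region, 0), n_obs - obs.get(region, 0)
        c, d = bg.get(region, 0), n_bg - bg.get(region, 0)
        table = np.array([[a, b], [c, d]])
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            p = 1.0
        else:
            p = stats.chi2_contingency(table, correction=False).pvalue
        odds = ((a + 0.5) / (b + 0.5)) / ((c + 0.5) / (d + 0.5))
        rows.append({"region": region,
                     "observed_frac": a / n_obs,
                     "background_frac": c / n_bg,
                     "odds_ratio": odds, "p": p,
                     "direction": "enriched" if odds > 1 else "depleted"})
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(tested), 1.0)
    return out


def assign_states(sites: pd.DataFrame,
                  states: GenomicIntervalSet) -> pd.Series:
    """Chromatin state per site (the state track tiles each chromosome)."""
    out = pd.Series("", index=sites.index, dtype=object)
    by_chrom = states.by_chrom()
    for chrom, grp in sites.groupby("chrom"):
        seg = by_chrom.get(chrom)
        if seg is None:
            raise KeyError(f"no chromatin states for chromosome {chrom!r}")
        idx = np.searchsorted(seg["start"].to_numpy(), grp["pos"].to_numpy(),
                              side="right") - 1
        idx = np.clip(idx, 0, len(seg) - 1)
        out.loc[grp.index] = seg["name"].to_numpy()[idx]
    return out


def empirical_p(null: np.ndarray, observed: float) -> tuple[float, float, float]:
    """(enrichment p, depletion p, two-sided p); never 0, never above 1."""
    r = len(null)
    p_hi = (1 + int((null >= observed).sum())) / (1 + r)
    p_lo = (1 + int((null <= observed).sum())) / (1 + r)
    return p_hi, p_lo, min(1.0, 2 * min(p_hi, p_lo))


def chromatin_state_enrichment(dms_sites: pd.DataFrame,
                               states: GenomicIntervalSet,
                               panel_sites: pd.DataFrame,
                               n_draws: int = 1000,
                               seed: int = 0) -> pd.DataFrame:
    """Per-state log2 fold change of the tested sites against a resampling
    null of size-matched draws from the array panel.

    Each of ``n_draws`` rounds draws ``len(dms_sites)`` loci without
    replacement from the panel and records the percentage falling in each
    state; logFC = log2(observed % / mean random %); empirical p-values are
    (1 + exceedances) / (1 + draws) per tail, two-sided = twice the smaller
    tail capped at 1.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    panel_states = assign_states(panel_sites, states)
    dms_states = assign_states(dms_sites, states)
    names = sorted(set(states.df["name"]))
    k = len(dms_sites)
    obs_pct = (dms_states.value_counts(normalize=True) * 100.0)
    panel_arr = panel_states.to_numpy()
    null_pct = np.zeros((n_draws, len(names)))
    name_idx = {s: i for i, s in enumerate(names)}
    coded = np.array([name_idx[s] for s in panel_arr])
    for r in range(n_draws):
        draw = rng.choice(len(coded), size=k, replace=False)
        counts = np.bincount(coded[draw], minlength=len(names))
        null_pct[r] = counts / k * 100.0
    rows = []
    for s in names:
        j = name_idx[s]
        o = float(obs_pct.get(s, 0.0))
        mean_null = null_pct[:, j].mean()
        lfc = np.log2((o + EPS) / (mean_null + EPS))
        p_hi, p_lo, p2 = empirical_p(null_pct[:, j], o)
        rows.append({"state": s, "observed_pct": o, "null_mean_pct": mean_null,
                     "log2fc": lfc, "p_enrich": p_hi, "p_deplete": p_lo,
                     "p_two_sided": p2})
    out = pd.DataFrame(rows)
    # Bonferroni over the tested states, matching the correction discipline
    # applied to the other genomic-region tests
    out["p_corrected"] = np.minimum(out["p_two_sided"] * len(out), 1.0)
    out["significant"] = out["p_corrected"] < 0.05
    return out


# ---------------------------------------------------------------------------
# Cis correlation screen
# ---------------------------------------------------------------------------

def cis_correlation(expression: pd.DataFrame, beta: pd.DataFrame,
                    gene_table: pd.DataFrame, site_coords: pd.DataFrame,
                    window: int = 1_000_000, rho_threshold: float = 0.6,
                    q_threshold: float = 0.05) -> pd.DataFrame:
    """Spearman screen between gene expression and beta-values of sites
    within ``window`` bp of the gene's TSS on the same chromosome.

    Returns the tested pairs with rho, FDR q, TSS distance and a
    ``significant`` flag (|rho| >= ``rho_threshold`` and q <= ``q_threshold``).
    Constant beta columns are skipped (rho undefined).
    """
    from statsmodels.stats.multitest import multipletests

    common = expression.index.intersection(beta.index)
    rows = []
    for gene in expression.columns:
        if gene not in gene_table.index:
            continue
        chrom = gene_table.loc[gene, "chrom"]
        tss = int(gene_table.loc[gene, "tss"])
        sites = site_coords[(site_coords["chrom"] == chrom) &
                            (abs(site_coords["pos"] - tss) <= window)]
        x = expression.loc[common, gene].to_numpy()
        for site in sites.index:
            y = beta.loc[common, site].to_numpy()
            if np.ptp(y) == 0 or np.ptp(x) == 0:
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"gene": gene, "site": site, "rho": rho, "p": p,
                         "tss_distance": int(site_coords.loc[site, "pos"]) - tss})
    out = pd.DataFrame(rows, columns=["gene", "site", "rho", "p",
                                      "tss_distance"])
    if out.empty:
        out["q"] = out["significant"] = []
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["rho"].abs() >= rho_threshold) & \
        (out["q"] <= q_threshold)
    return out


# ---------------------------------------------------------------------------
# Survival screen
# ---------------------------------------------------------------------------

def survival_screen(beta: pd.DataFrame, survival: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Two-group log-rank test per site on the median beta split.

    Samples with beta equal to the median go to the low group; sites whose
    split leaves a group empty (constant beta) are skipped.
    """
    from lifelines.statistics import logrank_test

    common = beta.index.intersection(survival.index)
    t = survival.loc[common, "time"].to_numpy(dtype=float)
    e = survival.loc[common, "event"].to_numpy(dtype=int)
    rows = []
    for site in beta.columns:
        v = beta.loc[common, site].to_numpy()
        high = v > np.median(v)
        if high.all() or not high.any():
            continue
        res = logrank_test(t[high], t[~high], e[high], e[~high])
        rows.append({"site": site, "p": res.p_value,
                     "significant": res.p_value < alpha})
    return pd.DataFrame(rows, columns=["site", "p", "significant"]
                        ).set_index("site")


def survival_bootstrap_null(panel_beta: pd.DataFrame, survival: pd.DataFrame,
                            set_size: int, n_rounds: int = 100,
                            alpha: float = 0.05, seed: int = 0) -> np.ndarray:
    """Null distribution of significant-site counts: each round draws
    ``set_size`` sites from the panel (without replacement) and counts
    log-rank p < alpha among them.  Per-site p-values depend only on the
    site, so they are computed once and re-used across rounds."""
    rng = np.random.default_rng(seed)
    screen = survival_screen(panel_beta, survival, alpha=alpha)
    sig = screen["significant"].reindex(panel_beta.columns).fillna(False)
    sig = sig.to_numpy()
    counts = np.empty(n_rounds, dtype=int)
    for r in range(n_rounds):
        draw = rng.choice(len(sig), size=min(set_size, len(sig)),
                          replace=False)
        counts[r] = int(sig[draw].sum())
    return counts
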