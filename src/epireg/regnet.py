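"""Regulatory-model layer: miRNA filters, miRNA-mRNA correlation screening,
the TF + methylation feature-selection run, and per-target linear models
with tissue-type ablation.

Expression fold change uses log2(mean cancer / mean normal) with a
pseudocount, so genes silenced in cancer read negative; a miRNA is
"down-expressed" when log2FC <= -0.5.  Screened miRNA-mRNA pairs must be
negatively correlated (Spearman rho <= -0.2) and survive BH-FDR at 0.05.
Per-target ordinary-least-squares models use the selected TF expressions and
methylation beta-values plus a 0/1 tissue indicator; a model is
"best-fitted" when its BH-adjusted F-test p is <= 0.05 and R-squared exceeds
0.5, and the ablation refits without the tissue column to report how much of
the fit tissue type carries.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import OmicsMatrix
from .mcfs import MCFSParams, MCFSResult, run_mcfs_with_cutoff

log = logging.getLogger("epireg")

EPS = 1e-6


# ---------------------------------------------------------------------------
# miRNA filters and screen
# ---------------------------------------------------------------------------

def expression_log2fc(values: pd.DataFrame, groups: pd.Series) -> pd.Series:
    """log2(mean cancer / mean normal) per feature, with pseudocount."""
    is_cancer = (groups.loc[values.index] == "cancer").to_numpy()
    mean_c = values.loc[is_cancer].mean(axis=0)
    mean_n = values.loc[~is_cancer].mean(axis=0)
    if (mean_n <= 0).any() or (mean_c <= 0).any():
        log.info("zero group mean encountered; pseudocount %.0e applied", EPS)
    return np.log2((mean_c + EPS) / (mean_n + EPS))


def select_down_mirnas(mirna: OmicsMatrix, groups: pd.Series,
                       cutoff: float = -0.5) -> list[str]:
    """miRNAs down-expressed in cancer: expression log2FC <= ``cutoff``."""
    lfc = expression_log2fc(mirna.data, groups)
    return sorted(lfc.index[lfc <= cutoff])


def mirna_mrna_screen(mirna: OmicsMatrix, mrna: OmicsMatrix,
                      target_map: Mapping[str, Sequence[str]],
                      rho_cutoff: float = -0.2,
                      q_cutoff: float = 0.05) -> pd.DataFrame:
    """Spearman screen over the mapped miRNA->mRNA pairs; keeps negative
    correlations (rho <= ``rho_cutoff``) with BH-FDR q <= ``q_cutoff``."""
    from statsmodels.stats.multitest import multipletests

    common = mirna.data.index.intersection(mrna.data.index)
    rows = []
    for mir, targets in target_map.items():
        if mir not in mirna.data.columns:
            continue
        x = mirna.data.loc[common, mir].to_numpy()
        for gene in targets:
            if gene not in mrna.data.columns:
                continue
            y = mrna.data.loc[common, gene].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append({"mirna": mir, "gene": gene, "rho": rho, "p": p})
    out = pd.DataFrame(rows, columns=["mirna", "gene", "rho", "p"])
    if out.empty:
        out["q"] = out["significant"] = []
        return out
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = (out["rho"] <= rho_cutoff) & (out["q"] <= q_cutoff)
    return out


# ---------------------------------------------------------------------------
# TF + DMS feature selection
# ---------------------------------------------------------------------------

def tf_dms_mcfs(tf_expression: pd.DataFrame, dms_beta: pd.DataFrame,
                groups: pd.Series, params: MCFSParams) -> MCFSResult:
    """Classification-mode MCFS-ID on the concatenated TF-expression and
    methylation features, restricted to samples carrying both omics."""
    common = tf_expression.index.intersection(dms_beta.index)
    if len(common) == 0:
        raise ValueError("the two omics share no samples")
    X = pd.concat([tf_expression.loc[common], dms_beta.loc[common]], axis=1)
    return run_mcfs_with_cutoff(X, groups.loc[common], params)


# ---------------------------------------------------------------------------
# Per-target linear models
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LinearModelReport:
    target: str
    predictors: list[str]          # includes "tissue"
    coefficients: pd.Series        # by predictor, plus const
    std_errors: pd.Series
    r_squared: float
    f_pvalue: float
    q_value: float = np.nan
    best_fitted: bool = False
    pearson_with_tissue: float = np.nan
    pearson_without_tissue: float = np.nan
    dropped: list[str] = dataclasses.field(default_factory=list)


def _drop_collinear(X: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Drop columns collinear to machine precision (QR-based)."""
    cols = list(X.columns)
    keep: list[str] = []
    dropped: list[str] = []
    M = np.column_stack([np.ones(len(X))])
    for c in cols:
        v = X[c].to_numpy(dtype=float)[:, None]
        trial = np.hstack([M, v])
        if np.linalg.matrix_rank(trial, tol=1e-10) > np.linalg.matrix_rank(
                M, tol=1e-10):
            keep.append(c)
            M = trial
        else:
            dropped.append(c)
    if dropped:
        warnings.warn(f"collinear predictors dropped: {dropped}")
    return X[keep], dropped


def fit_target_models(targets: Mapping[str, pd.Series],
                      predictor_sets: Mapping[str, pd.DataFrame],
                      tissue: pd.Series,
                      q_cutoff: float = 0.05, r2_cutoff: float = 0.5
                      ) -> list[LinearModelReport]:
    """OLS per target on its predictor set plus the tissue indicator.

    ``targets`` maps target gene -> expression series; ``predictor_sets``
    maps target gene -> DataFrame of predictor columns (TF expressions, DMS
    beta-values) on the same samples.  Model F-test p-values are BH-adjusted
    across targets; "best-fitted" requires adjusted p <= ``q_cutoff`` and
    R-squared > ``r2_cutoff``.  Each model is refit without the tissue column
    and both full-fit Pearson correlations are reported.
    """
    import statsmodels.api as sm
    from statsmodels.stats.multitest import multipletests

    reports: list[LinearModelReport] = []
    for target, y in targets.items():
        X = predictor_sets[target].copy()
        common = y.index.intersection(X.index).intersection(tissue.index)
        y_ = y.loc[common].astype(float)
        X = X.loc[common].astype(float)
        X["tissue"] = (tissue.loc[common] == "cancer").astype(float)
        X, dropped = _drop_collinear(X)
        model = sm.OLS(y_, sm.add_constant(X)).fit()
        pred_full = model.fittedvalues
        r_full = _pearson(pred_full, y_)
        if "tissue" in X.columns and X.shape[1] > 1:
            X_abl = X.drop(columns="tissue")
            m_abl = sm.OLS(y_, sm.add_constant(X_abl)).fit()
            r_abl = _pearson(m_abl.fittedvalues, y_)
        else:
            r_abl = np.nan
        reports.append(LinearModelReport(
            target=target, predictors=list(X.columns),
            coefficients=model.params, std_errors=model.bse,
            r_squared=float(model.rsquared),
            f_pvalue=float(model.f_pvalue),
            pearson_with_tissue=r_full, pearson_without_tissue=r_abl,
            dropped=dropped))
    if reports:
        q = multipletests([r.f_pvalue for r in reports], method="fdr_bh")[1]
        for r, qv in zip(reports, q):
            r.q_value = float(qv)
            r.best_fitted = (qv <= q_cutoff) and (r.r_squared > r2_cutoff)
    return reports


def _pearson(a: pd.Series, b: pd.Series) -> float:
    av, bv = np.asarray(a, float), np.asarray(b, float)
    if np.ptp(av) == 0 or np.ptp(bv) == 0:
        return np.nan
    return float(np.corrcoef(av, bv)[0, 1])


def reports_table(reports: Sequence[LinearModelReport]) -> pd.DataFrame:
    return pd.DataFrame([{
        "target": r.target, "n_predictors": len(r.predictors),
        "r_squared": r.r_squared, "f_pvalue": r.f_pvalue, "q": r.q_value,
        "best_fitted": r.best_fitted,
        "pearson_with_tissue": r.pearson_with_tissue,
        "pearson_without_tissue": r.pearson_without_tissue,
    } for r in reports])


# ---------------------------------------------------------------------------
# Regulatory edge table
# ---------------------------------------------------------------------------

def model_edges(reports: Sequence[LinearModelReport],
                predictor_kinds: Mapping[str, str],
                mirna_hits: pd.DataFrame | None = None) -> pd.DataFrame:
    """Edge table of the regulatory graph: for each best-fitted model every
    TF connects to every DMS and every DMS to the target; miRNA edges come
    from the correlation screen where they touch model targets.  Duplicate
    edges collapse with weight = count."""
    edges: dict[tuple[str, str, str], int] = {}

    def add(src: str, dst: str, kind: str) -> None:
        key = (src, dst, kind)
        edges[key] = edges.get(key, 0) + 1

    model_targets = set()
    for r in reports:
        if not r.best_fitted:
            continue
        model_targets.add(r.target)
        tfs = [p for p in r.predictors
               if predictor_kinds.get(p) == "tf"]
        dmss = [p for p in r.predictors
                if predictor_kinds.get(p) == "dms"]
        for d in dmss:
            for t in tfs:
                add(t, d, "tf_dms")
            add(d, r.target, "dms_target")
    if mirna_hits is not None and not mirna_hits.empty:
        sig = mirna_hits[mirna_hits["significant"]]
        for _, row in sig.iterrows():
            if row["gene"] in model_targets:
                add(row["mirna"], row["gene"], "mirna_target")
    rows = [{"source": s, "target": t, "kind": k, "weight": w}
            for (s, t, k), w in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["source", "target", "kind", "weight"])
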