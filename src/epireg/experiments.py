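"""The study's experiment designs over the MCFS-ID core.

The main experiment runs feature selection four times: once on the joined
multi-omics table restricted to complete samples (capturing cross-omic
interactions) and once per omic on all samples carrying that omic (capturing
features that would fall below the relevance threshold inside the wider
table).  Per omic it reports the joined-set, individual-set, intersection and
union ("sum") significant sets, and validates the selection by training RF
and SVM classifiers on the complete samples and scoring weighted accuracy on
held-out samples never seen during selection.

The mass experiments treat each significant mRNA as a regression target with
miRNA expression or (chromosome-restricted) methylation as predictors, gate
targets on cross-validated Pearson correlation of a regression-tree fit on
the significant set, and aggregate the per-target rankings into frequency /
summed-RI / mean-RI tables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .io import OmicsMatrix
from .mcfs import (MCFSParams, MCFSResult, build_tree, predict_tree,
                   random_forest_predict, run_mcfs_with_cutoff,
                   weighted_accuracy)

log = logging.getLogger("epireg")


# ---------------------------------------------------------------------------
# Main four-run experiment
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class OmicSelection:
    joined_set: set[str]
    individual_set: set[str]

    @property
    def intersection(self) -> set[str]:
        return self.joined_set & self.individual_set

    @property
    def union(self) -> set[str]:
        return self.joined_set | self.individual_set


@dataclasses.dataclass
class MainExperimentResult:
    per_omic: dict[str, OmicSelection]
    wacc: pd.DataFrame                 # omic x classifier held-out wAcc
    joined_result: MCFSResult | None
    individual_results: dict[str, MCFSResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        for om, sel in self.per_omic.items():
            rows.append({
                "omic": om,
                "joined_set": len(sel.joined_set),
                "individual_set": len(sel.individual_set),
                "intersection": len(sel.intersection),
                "sum": len(sel.union),
                "rf_wacc": self.wacc.loc[om, "RF"]
                if om in self.wacc.index else np.nan,
                "svm_wacc": self.wacc.loc[om, "SVM"]
                if om in self.wacc.index else np.nan,
            })
        return pd.DataFrame(rows)


def main_experiment(matrices: dict[str, OmicsMatrix], meta: pd.DataFrame,
                    params: MCFSParams, run_joined: bool = True,
                    validate: bool = True) -> MainExperimentResult:
    """Four MCFS-ID runs plus held-out classification validation.

    ``matrices`` maps omic name to its matrix (each restricted to the samples
    carrying that omic); ``meta`` holds ``group`` and ``complete`` columns.
    """
    complete = meta.index[meta["complete"]]
    if len(complete) == 0:
        raise ValueError("no complete samples across the three omics")

    joined_sig: dict[str, set[str]] = {om: set() for om in matrices}
    joined_result = None
    if run_joined:
        parts, owners = [], {}
        for om, mat in matrices.items():
            sub = mat.data.loc[mat.data.index.intersection(complete)]
            parts.append(sub)
            owners.update({f: om for f in sub.columns})
        joined = pd.concat(parts, axis=1).loc[complete]
        y = meta.loc[complete, "group"]
        if y.nunique() < 2:
            warnings.warn("joined run skipped: fewer than 2 classes")
        else:
            joined_result = run_mcfs_with_cutoff(joined, y, params)
            for f in joined_result.significant:
                joined_sig[owners[f]].add(f)

    individual: dict[str, MCFSResult] = {}
    per_omic: dict[str, OmicSelection] = {}
    wacc_rows = {}
    for om, mat in matrices.items():
        y_all = meta.loc[mat.data.index, "group"]
        if y_all.nunique() < 2:
            warnings.warn(f"omic {om!r} skipped: fewer than 2 classes")
            continue
        res = run_mcfs_with_cutoff(mat.data, y_all, params)
        individual[om] = res
        sel = OmicSelection(joined_set=joined_sig[om],
                            individual_set=set(res.significant))
        per_omic[om] = sel
        if validate and sel.union:
            train_ids = mat.data.index.intersection(complete)
            test_ids = mat.data.index.difference(complete)
            if len(test_ids) and len(train_ids):
                wacc_rows[om] = {
                    clf: validate_selection(mat, meta["group"],
                                            sorted(sel.union), train_ids,
                                            test_ids, classifier=clf,
                                            seed=params.seed)
                    for clf in ("RF", "SVM")}
    wacc = pd.DataFrame(wacc_rows).T if wacc_rows else pd.DataFrame(
        columns=["RF", "SVM"])
    return MainExperimentResult(per_omic=per_omic, wacc=wacc,
                                joined_result=joined_result,
                                individual_results=individual)


def validate_selection(matrix: OmicsMatrix, groups: pd.Series,
                       selected: Sequence[str], train_ids: Sequence[str],
                       test_ids: Sequence[str],
                       classifier: Literal["RF", "SVM"] = "RF",
                       seed: int = 0, n_trees: int = 100) -> float:
    """Held-out weighted accuracy of a classifier trained on the selected
    features over the complete samples and tested on unseen samples.

    RF is a bagged forest of this package's own trees; SVM delegates to a
    standard RBF support vector machine with feature standardization.
    """
    selected = list(selected)
    if not selected:
        raise ValueError("at least one selected feature is required")
    Xtr = matrix.data.loc[train_ids, selected]
    Xte = matrix.data.loc[test_ids, selected]
    ytr = groups.loc[train_ids].to_numpy()
    yte = groups.loc[test_ids].to_numpy()
    if classifier == "RF":
        pred = random_forest_predict(Xtr, ytr, Xte, n_trees=n_trees, seed=seed)
    else:
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import SVC
        model = make_pipeline(StandardScaler(), SVC(random_state=seed))
        model.fit(Xtr.to_numpy(), ytr)
        pred = model.predict(Xte.to_numpy())
    return weighted_accuracy(yte, pred)


# ---------------------------------------------------------------------------
# Mass per-target regression experiments
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TargetResult:
    target: str
    result: MCFSResult
    cv_pearson: float
    well_predicted: bool

    @property
    def significant(self) -> list[str]:
        return self.result.significant


def _cv_pearson(X: pd.DataFrame, y: np.ndarray, k: int, seed: int,
                min_samples_split: int = 5, n_trees: int = 30) -> float:
    """Mean held-out Pearson correlation over k folds of a bagged
    regression-tree ensemble fit on the given predictor set.

    A single piecewise-constant tree attenuates the correlation of a
    multi-driver continuous target substantially at moderate sample sizes;
    bagging this package's own trees (mirroring the bagged forest used for
    classification validation) removes that variance without changing the
    tree model class.
    """
    rng = np.random.default_rng(seed)
    n = len(y)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    ids = [str(c) for c in X.columns]
    fidx = {f: j for j, f in enumerate(ids)}
    Xv = X.to_numpy(dtype=float)
    cors = []
    for f in folds:
        te = np.zeros(n, dtype=bool)
        te[f] = True
        Xtr, ytr = Xv[~te], y[~te]
        preds = []
        for _ in range(n_trees):
            rows = rng.integers(0, len(ytr), size=len(ytr))
            root = build_tree(Xtr[rows], ytr[rows], ids, task="regression",
                              min_samples_split=min_samples_split)
            preds.append(predict_tree(root, Xv[te], fidx).astype(float))
        pred = np.mean(preds, axis=0)
        if np.ptp(pred) == 0 or np.ptp(y[te]) == 0:
            cors.append(0.0)
        else:
            cors.append(float(np.corrcoef(pred, y[te])[0, 1]))
    return float(np.mean(cors))


def mass_experiments(mrna: OmicsMatrix, predictors: OmicsMatrix,
                     targets: Sequence[str], params: MCFSParams,
                     gene_table: pd.DataFrame | None = None,
                     site_coords: pd.DataFrame | None = None,
                     pearson_gate: float = 0.8, cv_folds: int = 5,
                     log_target: bool = True) -> list[TargetResult]:
    """One regression-mode MCFS-ID run per target mRNA.

    Predictors are the full miRNA panel, or — when ``gene_table`` and
    ``site_coords`` are given — only the methylation sites on the target
    gene's chromosome.  Expression targets are log-transformed by default
    (multiplicative noise).  A target is "well-predicted" when the mean
    held-out Pearson correlation of a regression tree fit on its significant
    set reaches ``pearson_gate``.
    """
    common = mrna.data.index.intersection(predictors.data.index)
    results: list[TargetResult] = []
    reg_params = dataclasses.replace(params, task="regression")
    for i, target in enumerate(targets):
        y = mrna.data.loc[common, target].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            warnings.warn(f"target {target!r} has zero variance; skipped")
            continue
        if log_target:
            y = np.log(np.maximum(y, 1e-12))
        X = predictors.data.loc[common]
        if site_coords is not None and gene_table is not None:
            chrom = gene_table.loc[target, "chrom"]
            keep = site_coords.index[site_coords["chrom"] == chrom]
            X = X.loc[:, X.columns.intersection(keep)]
        p = dataclasses.replace(reg_params, seed=params.seed + 101 * (i + 1))
        res = run_mcfs_with_cutoff(X, pd.Series(y, index=common), p)
        sig = res.significant
        if sig:
            cv = _cv_pearson(X[sig], y, k=cv_folds, seed=p.seed)
        else:
            cv = 0.0
        results.append(TargetResult(target=target, result=res, cv_pearson=cv,
                                    well_predicted=cv >= pearson_gate))
        log.info("mass target %s: %d significant, cv Pearson %.3f",
                 target, len(sig), cv)
    return results


def aggregate_mass(results: Sequence[TargetResult],
                   main_ranking: pd.DataFrame | None = None) -> pd.DataFrame:
    """Aggregate significant sets of well-predicted targets into the
    Freq / Sum RI / Mean RI table, sorted by Sum RI descending.

    ``Freq`` counts the well-predicted targets whose significant set contains
    the feature; ``Mean RI`` is exactly ``Sum RI / Freq``.  Optionally joins
    each feature's rank in the main experiment.
    """
    freq: dict[str, int] = {}
    sum_ri: dict[str, float] = {}
    for tr in results:
        if not tr.well_predicted:
            continue
        ri = tr.result.ranking.set_index("feature")["RI"]
        for f in tr.significant:
            freq[f] = freq.get(f, 0) + 1
            sum_ri[f] = sum_ri.get(f, 0.0) + float(ri[f])
    rows = [{"feature": f, "freq": freq[f], "sum_ri": sum_ri[f],
             "mean_ri": sum_ri[f] / freq[f]} for f in freq]
    out = pd.DataFrame(rows, columns=["feature", "freq", "sum_ri", "mean_ri"])
    out = out.sort_values(["sum_ri", "feature"],
                          ascending=[False, True]).reset_index(drop=True)
    if main_ranking is not None and not out.empty:
        ranks = main_ranking.set_index("feature")["rank"]
        out["main_rank"] = out["feature"].map(ranks)
    return out
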