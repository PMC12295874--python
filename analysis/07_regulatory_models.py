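"""Regulatory-model layer: the down-expressed miRNA filter, the
miRNA-mRNA negative-correlation screen against the planted regulator map,
per-target linear models with a tissue indicator and its ablation, and the
regulatory edge table.  Reads results/cohort/, writes results/regnet/."""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from epireg import io, regnet, synth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/regnet"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    mirna = io.read_matrix(args.cohort / "mirna.tsv", kind="mirna")
    mrna = io.read_matrix(args.cohort / "mrna.tsv", kind="mrna")
    meth = io.read_matrix(args.cohort / "meth.tsv", kind="meth")
    meta = pd.read_csv(args.cohort / "samples.tsv", sep="\t", index_col=0)
    truth = synth.GroundTruth.from_json(args.cohort / "ground_truth.json")

    down = regnet.select_down_mirnas(mirna, meta["group"])
    print(f"{len(down)} miRNAs down-expressed in cancer (log2FC <= -0.5)")

    target_map: dict[str, list[str]] = {}
    for target, drivers in truth.regulator_map.items():
        for mir, _ in drivers:
            target_map.setdefault(mir, []).append(target)
    screen = regnet.mirna_mrna_screen(mirna, mrna, target_map)
    screen.to_csv(args.out / "mirna_screen.tsv", sep="\t", index=False)
    print(f"miRNA-mRNA screen: {int(screen['significant'].sum())} "
          f"significant negative pairs of {len(screen)} mapped pairs")

    # per-target linear models: each planted target explained by its
    # drivers' expression, one methylation site, and the tissue indicator
    common = mrna.data.index.intersection(mirna.data.index).intersection(
        meth.data.index)
    targets, preds, kinds = {}, {}, {}
    sites = list(meth.data.columns)
    for i, (target, drivers) in enumerate(truth.regulator_map.items()):
        y = np.log(mrna.data.loc[common, target])
        X = np.log(mirna.data.loc[common, [d for d, _ in drivers]])
        site = sites[i % len(sites)]
        X[site] = meth.data.loc[common, site]
        targets[target] = y
        preds[target] = X
        kinds.update({d: "tf" for d, _ in drivers})
        kinds[site] = "dms"
    reports = regnet.fit_target_models(targets, preds, meta["group"])
    table = regnet.reports_table(reports)
    table.to_csv(args.out / "linear_models.tsv", sep="\t", index=False)
    best = table[table["best_fitted"]]
    print(f"{len(best)}/{len(table)} best-fitted models "
          f"(adjusted p <= 0.05, R^2 > 0.5); Pearson with tissue "
          f"{best['pearson_with_tissue'].mean():.2f} vs without "
          f"{best['pearson_without_tissue'].mean():.2f}")

    edges = regnet.model_edges(reports, kinds, screen)
    edges.to_csv(args.out / "regulatory_edges.tsv", sep="\t", index=False)
    print(f"regulatory edge table: {len(edges)} edges")


if __name__ == "__main__":
    main()
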