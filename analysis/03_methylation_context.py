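"""Genomic context of the methylation sites: CpG-island/shore/shelf/open-sea
and promoter/gene-body/intergenic annotation, hyper/medium/hypo labeling
with rank-sum tests, region and chromatin-state enrichment with resampling
nulls, the cis-correlation screen, and the median-split survival screen.
Reads results/cohort/ (+ significant sites from results/selection/ if
present), writes tables under results/methylation/."""

import argparse
from pathlib import Path

import pandas as pd

from epireg import io, methylation as meth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--selection", type=Path,
                    default=Path("results/selection"))
    ap.add_argument("--out", type=Path, default=Path("results/methylation"))
    ap.add_argument("--n-draws", type=int, default=1000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    beta = io.read_matrix(args.cohort / "meth.tsv", kind="meth").data
    meta = pd.read_csv(args.cohort / "samples.tsv", sep="\t", index_col=0)
    coords = pd.read_csv(args.cohort / "site_coords.tsv", sep="\t",
                         index_col=0)
    cpgi = io.read_bed(args.cohort / "cpgi.bed")
    states = io.read_bed(args.cohort / "chromatin_states.bed")
    genes_bed = io.read_bed(args.cohort / "genes.bed")
    genes = genes_bed.df.set_index("name")
    genes["tss"] = genes.apply(
        lambda r: r["start"] if r["strand"] == "+" else r["end"] - 1, axis=1)

    stats_df = meth.methylation_log2fc(beta, meta["group"])
    stats_df = stats_df.join(meth.differential_test(beta, meta["group"]))
    stats_df["cpg_context"] = meth.cpg_context(coords, cpgi)
    gc = meth.gene_context(coords, genes)
    stats_df = stats_df.join(gc)
    stats_df.index.name = "site"
    stats_df.to_csv(args.out / "site_stats.tsv", sep="\t")
    print("labels:", stats_df["label"].value_counts().to_dict())
    print("CpG contexts:", stats_df["cpg_context"].value_counts().to_dict())

    sig_file = args.selection / "significant_meth.tsv"
    if sig_file.exists():
        dms_ids = list(pd.read_csv(sig_file, sep="\t")["feature"])
    else:
        dms_ids = list(stats_df.index[stats_df["q"] < 0.05])
    dms_ids = [s for s in dms_ids if s in coords.index]
    if dms_ids:
        enr = meth.region_enrichment(stats_df.loc[dms_ids, "cpg_context"],
                                     stats_df["cpg_context"])
        enr.to_csv(args.out / "region_enrichment.tsv", sep="\t", index=False)
        print(enr.to_string(index=False))
        chrom_enr = meth.chromatin_state_enrichment(
            coords.loc[dms_ids], states, coords, n_draws=args.n_draws,
            seed=args.seed)
        chrom_enr.to_csv(args.out / "chromatin_enrichment.tsv", sep="\t",
                         index=False)
        called = chrom_enr[chrom_enr["significant"]]
        print(f"chromatin states called at corrected p < 0.05: "
              f"{list(called['state']) or 'none'}")

    expr = io.read_matrix(args.cohort / "mrna.tsv", kind="mrna").data
    expr_genes = [g for g in genes.index if g in expr.columns]
    if expr_genes:
        pairs = meth.cis_correlation(expr[expr_genes], beta, genes, coords)
        pairs.to_csv(args.out / "cis_pairs.tsv", sep="\t", index=False)
        print(f"cis screen: {int(pairs['significant'].sum())} significant "
              f"pairs of {len(pairs)} tested")

    if {"time", "event"} <= set(meta.columns):
        surv = meta.dropna(subset=["time"])
        screen = meth.survival_screen(beta.loc[beta.index.isin(surv.index),
                                               dms_ids or beta.columns[:200]],
                                      surv)
        screen.to_csv(args.out / "survival_screen.tsv", sep="\t")
        observed = int(screen["significant"].sum())
        null_counts = meth.survival_bootstrap_null(
            beta.loc[beta.index.isin(surv.index)], surv,
            set_size=len(screen), n_rounds=100, seed=args.seed)
        print(f"survival: {observed} significant sites; null count range "
              f"[{null_counts.min()}, {null_counts.max()}] over 100 draws")
        pd.Series(null_counts).to_csv(args.out / "survival_null_counts.tsv",
                                      sep="\t", index=False,
                                      header=["significant_count"])


if __name__ == "__main__":
    main()
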