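"""Methylation-aware motif analysis: 41-bp windows around differentially
methylated sites, motif enrichment against background windows, exact
p-value scanning, intersection of binding sites with the methylation
positions, and PWM-similarity clustering with UPGMA.  Reads
results/cohort/, writes results/motifs/."""

import argparse
from pathlib import Path

import pandas as pd

from epireg import io, motifs, synth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--out", type=Path, default=Path("results/motifs"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    genome = io.read_fasta(args.cohort / "genome.fa")
    coords = pd.read_csv(args.cohort / "site_coords.tsv", sep="\t",
                         index_col=0)
    pwms = io.read_meme(args.cohort / "motifs.meme")
    truth = synth.GroundTruth.from_json(args.cohort / "ground_truth.json")

    planted_sites = truth.informative["meth"][:10]    # motif-planted sites
    background_sites = coords.index.difference(planted_sites)[:60]
    fg = motifs.extract_windows(coords.loc[planted_sites], genome)
    bg = motifs.extract_windows(coords.loc[background_sites], genome)
    enr = motifs.motif_enrichment({k: w.seq for k, w in fg.items()},
                                  {k: w.seq for k, w in bg.items()},
                                  pwms, p_cutoff=1e-3, seed=args.seed)
    enr.to_csv(args.out / "enrichment.tsv", sep="\t", index=False)
    print("enriched motifs:",
          list(enr.loc[enr["enriched"], "motif"]) or "none")

    hits = []
    origin, widths = {}, {p.name: p.width for p in pwms}
    for pwm in pwms:
        dist = motifs.score_distribution(pwm)
        for sid, win in fg.items():
            origin[sid] = (win.chrom, win.start)
            hits += motifs.scan(win.seq, pwm, p_threshold=1e-4, seq_id=sid,
                                dist=dist)
    dms_pos = {s: (coords.loc[s, "chrom"], int(coords.loc[s, "pos"]))
               for s in planted_sites}
    kept = motifs.intersect_hits_with_dms(hits, origin, dms_pos, widths)
    motifs.hits_to_frame(hits).to_csv(args.out / "hits.tsv", sep="\t",
                                      index=False)
    motifs.hits_to_frame(kept).to_csv(args.out / "hits_on_dms.tsv", sep="\t",
                                      index=False)
    print(f"{len(hits)} motif hits in {len(fg)} windows; "
          f"{len(kept)} overlap a methylation site")

    dist_matrix = motifs.pwm_distance_matrix(pwms)
    dist_matrix.to_csv(args.out / "pwm_distances.tsv", sep="\t")
    tree = motifs.upgma(dist_matrix)
    (args.out / "pwm_tree.nwk").write_text(tree.newick() + "\n")
    print("UPGMA tree:", tree.newick())


if __name__ == "__main__":
    main()
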