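"""Generate the synthetic multi-omics study: three omics matrices with
planted cancer/normal effects, a toy genome with gene/CpG-island/chromatin
tracks, planted motif instances, survival times, and the ground-truth
answer key.  Writes everything under results/cohort/."""

import argparse
from pathlib import Path

from epireg import io, synth


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cohort"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = synth.CohortSpec(seed=args.seed)
    matrices, meta, truth = synth.generate_cohort(spec)
    genome = synth.generate_genome_fixture(
        seed=args.seed, meth_ids=matrices["meth"].features)
    pwms = synth.demo_pwms(seed=args.seed)
    planted_sites = truth.informative["meth"][:10]
    insertions = synth.plant_motifs(genome, pwms, planted_sites,
                                    seed=args.seed)
    meta = synth.generate_survival(meta, matrices["meth"].data,
                                   truth.survival_dms or planted_sites[:1],
                                   hazard_ratio=3.0, seed=args.seed)

    for om, mat in matrices.items():
        io.write_matrix(mat, args.out / f"{om}.tsv")
    meta.to_csv(args.out / "samples.tsv", sep="\t")
    io.write_fasta(genome.fasta(), args.out / "genome.fa")
    io.write_bed(genome.genes, args.out / "genes.bed")
    io.write_bed(genome.cpg_islands, args.out / "cpgi.bed")
    io.write_bed(genome.chromatin_states, args.out / "chromatin_states.bed")
    genome.site_coords.to_csv(args.out / "site_coords.tsv", sep="\t")
    io.write_meme(pwms, args.out / "motifs.meme")
    truth.to_json(args.out / "ground_truth.json")

    n = len(meta)
    print(f"cohort: {n} samples "
          f"({(meta['group'] == 'cancer').sum()} cancer / "
          f"{(meta['group'] == 'normal').sum()} normal), "
          f"{int(meta['complete'].sum())} complete across all three omics")
    for om, mat in matrices.items():
        print(f"  {om}: {len(mat.samples)} samples x "
              f"{len(mat.features)} features "
              f"({len(truth.informative[om])} planted)")
    print(f"  genome: {len(genome.sequences)} chromosomes, "
          f"{len(genome.genes)} genes, {len(genome.cpg_islands)} CpG "
          f"islands, {len(insertions)} planted motif instances")


if __name__ == "__main__":
    main()
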