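#!/usr/bin/env python
"""Generate the synthetic study data set.

Writes the chromosome-6-like annotation (genes, exons, L1 repeats at ~13%
background with a ~29% L1 focal domain), the nuclear RNA-seq coverage track
over the six-domain cluster (one expressed ~185 kb domain), allele-count and
hybrid-genotype tables, and a manifest recording seeds and parameters.
"""

import argparse
from pathlib import Path

import pandas as pd

from asarscan.io import write_bed, write_bedgraph
from asarscan.simulate import (
    SimulationConfig,
    simulate_allele_counts,
    simulate_annotation,
    simulate_coverage,
    write_manifest,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out-dir", type=Path, default=Path("results/simdata"))
    args = ap.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    cfg = SimulationConfig(master_seed=args.seed)
    ann = simulate_annotation(cfg, args.seed)
    write_bed(ann, args.out_dir / "annotation.bed")
    n_rep = sum(f.kind == "repeat" for f in ann)
    n_gene = sum(f.kind == "gene" for f in ann)
    print(f"annotation: {n_gene} genes, {n_rep} L1 copies on {list(cfg.genome)}")

    track = simulate_coverage(cfg.domains, cfg.genome, "poisson",
                              cfg.background_rate, args.seed)
    write_bedgraph(track, args.out_dir / "coverage.bedgraph")
    expressed = [d for d in cfg.domains if d.depth > 0]
    print(f"coverage: {len(cfg.domains)} planted domains, {len(expressed)} expressed "
          f"({expressed[0].interval.length // 1000} kb at depth {expressed[0].depth})")

    records, hybrids, truth = simulate_allele_counts(
        "monoallelic", cfg.n_snps, cfg.snp_depth, cfg.snp_error_rate, args.seed
    )
    pd.DataFrame(
        [{"snp_id": r.snp_id, "chrom": r.position.chrom, "pos": r.position.start,
          "ref": r.ref_base, "alt": r.alt_base, "dna_gt": r.dna_genotype,
          "rna_ref": r.rna_ref_count, "rna_alt": r.rna_alt_count}
         for r in records]
    ).to_csv(args.out_dir / "allele_counts.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"snp_id": k, "homolog_a_allele": a, "homolog_b_allele": b}
         for k, (a, b) in hybrids.items()]
    ).to_csv(args.out_dir / "hybrid_genotypes.tsv", sep="\t", index=False)
    print(f"allele counts: {len(records)} heterozygous SNPs, "
          f"true expressed homolog {truth['expressed_homolog']}")

    write_manifest(args.out_dir / "manifest.json", cfg)
    print(f"data set written to {args.out_dir}")


if __name__ == "__main__":
    main()
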