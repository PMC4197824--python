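#!/usr/bin/env python
"""Simulate the synthetic promoter cohort and write its raw data files.

Generates the default cohort — bimodal promoter PolII fragments, a
uniform gene-body background, head-to-head bidirectional pairs, and
first-exon RNA-seq coverage — and writes annotation/truth tables, tag
and fragment BED files, and a pooled RNA bedGraph under results/.
"""

import argparse
from collections import Counter
from pathlib import Path

from polpause import io
from polpause import workflows as wf
from polpause.promoter_catalog import expression_strata
from polpause.synthetic_cohort import CohortConfig, truth_table


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--n-genes", type=int, default=150)
    ap.add_argument("--seed", type=int, default=11)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    cfg = CohortConfig(n_genes=args.n_genes, seed=args.seed)
    cohort = wf.simulate_cohort(cfg)

    io.write_annotation_tsv(cohort.annotation, args.outdir / "annotation.tsv")
    io.write_truth_tsv(truth_table(cohort.truths), args.outdir / "truth.tsv")
    io.write_tags_bed(cohort.track, args.outdir / "tags.bed")
    io.write_fragments_bed(cohort.fragments, cfg.chrom,
                           args.outdir / "fragments.bed")

    rna_map = Counter()
    for gid, prof in cohort.rna.items():
        strand = cohort.annotation.set_index("gene_id").loc[gid, "strand"]
        sign = 1 if strand == "+" else -1
        for rel, val in zip(prof.rel_coords(), prof.values):
            if val:
                rna_map[prof.anchor + sign * int(rel)] += val
    io.write_bedgraph(rna_map, cfg.chrom, args.outdir / "rna.bedgraph")

    strata = expression_strata(cohort.annotation.expression).value_counts()
    n_bidir = sum(g.opposite_tss is not None for g in cohort.truths)
    print(f"cohort: {len(cohort.truths)} genes on {cfg.chrom}, "
          f"{n_bidir} in bidirectional pairs")
    print(f"expression strata: {strata.to_dict()}")
    print(f"PolII fragments: {len(cohort.fragments)}, "
          f"tags: {cohort.track.total()}")
    print(f"wrote annotation/truth/tags/fragments/rna under {args.outdir}/")


if __name__ == "__main__":
    main()
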