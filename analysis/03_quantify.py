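#!/usr/bin/env python
"""Normalise the RNA counts and integrate both omics at family level.

Median-of-ratios size factors, family-level abundance aggregation for RNA
and protein, per-sample toxin fractions, and transcriptome-to-proteome
recruitment of the annotated toxin clusters.
"""

from pathlib import Path

from cnidotox import abundance as ab
from cnidotox.pipeline import quantify
from cnidotox.rules import read_assignments

DATA = Path("results/synthetic/data")
OUT = Path("results/synthetic")


def main() -> None:
    counts = ab.AbundanceMatrix.read_tsv(DATA / "counts.tsv", kind="raw_rna")
    proteome = ab.AbundanceMatrix.read_tsv(DATA / "proteome.tsv", kind="protein")
    assignments = read_assignments(OUT / "assignments.tsv")

    result = quantify(counts, proteome, assignments)
    ab.write_size_factors(result.size_factors, OUT / "size_factors.tsv")
    result.rna_families.to_tsv(OUT / "family_abundance_rna.tsv")
    result.protein_families.to_tsv(OUT / "family_abundance_protein.tsv")

    sf = result.size_factors.factors
    print(f"size factors: min {sf.min():.3f}, max {sf.max():.3f}")
    print(f"RNA toxin share : {result.rna_toxin_fraction.mean_pct:.1f}% "
          f"(per-sample {min(result.rna_toxin_fraction.per_sample_pct.values()):.1f}"
          f"-{max(result.rna_toxin_fraction.per_sample_pct.values()):.1f}%)")
    if result.protein_toxin_fraction:
        print(f"protein toxin share: "
              f"{result.protein_toxin_fraction.mean_pct:.1f}%")
    print(f"recruitment: {result.detection.n_detected} of "
          f"{result.detection.n_toxin} toxin clusters "
          f"({result.detection.recruitment_pct:.1f}%) detected in venom")


if __name__ == "__main__":
    main()
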