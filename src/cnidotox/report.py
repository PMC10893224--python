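"""Quantitative venom-profile outputs.

Builds the cross-omics summaries a venom-profiling study reports: the
transcriptome/proteome summary count table, the per-category recruitment
table (how many toxin gene clusters expressed in tentacle RNA are actually
detected in milked venom), venom composition shares by category and family,
top-N family rankings compared between RNA and protein abundance, and the
dominant-venom-phenotype test — whether a single toxin family accounts for
strictly more than 50% of total toxin expression on a chosen basis,
including the restricted eight-family panel (actinoporins, NEP3, NEP6, NaTx
and the potassium-channel toxin families KTx1/ShK-like, KTx2, KTx3, KTx5)
used in comparative work on sea anemone venom phenotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .abundance import FamilyAbundance, ProteomeDetection
from .rules import ToxinAssignment, VENOM_CATEGORIES
from .seqio import BestHit, GeneCluster
from .util import round_half_up

DOMINANCE_THRESHOLD = 0.5  # strict: a dominant family needs share > 50%

# KTx1 is the ShK-like family under its potassium-toxin panel name.
SMITH_PANEL = ("Actinoporins", "NEP3", "NEP6", "NaTx",
               "ShK-like", "KTx2", "KTx3", "KTx5")

NOT_PRESENT = "Not present"


# --------------------------------------------------------------------------
# Recruitment (transcriptome -> proteome)
# --------------------------------------------------------------------------

@dataclass
class RecruitmentRow:
    category: str
    rna_clusters: int
    rna_families: int
    protein_clusters: int
    protein_families: int

    @property
    def percentage(self) -> float:
        if self.rna_clusters == 0:
            return 0.0
        return round_half_up(100.0 * self.protein_clusters / self.rna_clusters, 1)


def recruitment_rows_from_counts(
        counts: Mapping[str, tuple[int, int, int, int]]) -> list[RecruitmentRow]:
    """Build rows from per-category (rna_clusters, rna_families,
    protein_clusters, protein_families) tuples."""
    rows = []
    for cat in sorted(counts, key=lambda c: VENOM_CATEGORIES.index(c)
                      if c in VENOM_CATEGORIES else len(VENOM_CATEGORIES)):
        rc, rf, pc, pf = counts[cat]
        if pc > rc:
            raise ValueError(f"{cat}: more proteome than transcriptome clusters")
        rows.append(RecruitmentRow(cat, rc, rf, pc, pf))
    return rows


def recruitment_table(assignments: Iterable[ToxinAssignment],
                      detection: ProteomeDetection,
                      ) -> tuple[list[RecruitmentRow], RecruitmentRow]:
    """Per-category recruitment rows plus a totals row."""
    counts: dict[str, list] = {}
    fams_rna: dict[str, set] = {}
    fams_prot: dict[str, set] = {}
    for a in assignments:
        entry = counts.setdefault(a.category, [0, 0, 0, 0])
        entry[0] += 1
        fams_rna.setdefault(a.category, set()).add(a.family)
        if detection.detected.get(a.cluster_id, False):
            entry[2] += 1
            fams_prot.setdefault(a.category, set()).add(a.family)
    final = {cat: (entry[0], len(fams_rna.get(cat, ())),
                   entry[2], len(fams_prot.get(cat, ())))
             for cat, entry in counts.items()}
    rows = recruitment_rows_from_counts(final)
    total = RecruitmentRow(
        "Total",
        sum(r.rna_clusters for r in rows),
        sum(r.rna_families for r in rows),
        sum(r.protein_clusters for r in rows),
        sum(r.protein_families for r in rows))
    return rows, total


# --------------------------------------------------------------------------
# Composition shares and dominance
# --------------------------------------------------------------------------

@dataclass
class CompositionShares:
    basis: str                       # cluster_count | rna_abundance | protein_abundance
    include_unknown: bool
    category_shares: dict[str, float]   # proportions summing to 1
    family_shares: dict[str, float]
    family_values: dict[str, float]
    family_categories: dict[str, str]

    def category_pct(self) -> dict[str, float]:
        return {c: round_half_up(100.0 * s, 1)
                for c, s in self.category_shares.items()}

    def family_pct(self) -> dict[str, float]:
        return {f: round_half_up(100.0 * s, 1)
                for f, s in self.family_shares.items()}


def _family_mapping(source) -> dict[str, tuple[str, float]]:
    if isinstance(source, FamilyAbundance):
        return source.as_mapping()
    return dict(source)


def composition_shares(source, basis: str = "cluster_count",
                       include_unknown: bool = True) -> CompositionShares:
    """Category and family shares of the venom profile.

    ``source`` is a FamilyAbundance or a mapping family -> (category, value);
    with ``include_unknown=False`` the Unknown category is removed before
    re-normalising, mirroring the known-function-only view.
    """
    mapping = _family_mapping(source)
    if not include_unknown:
        mapping = {f: (c, v) for f, (c, v) in mapping.items() if c != "Unknown"}
    if not mapping:
        raise ValueError("no families to aggregate")
    grand = sum(v for _, v in mapping.values())
    if grand == 0:
        raise ValueError("grand total is zero")
    fam_shares = {f: v / grand for f, (_, v) in mapping.items()}
    cat_values: dict[str, float] = {}
    for f, (c, v) in mapping.items():
        cat_values[c] = cat_values.get(c, 0.0) + v
    cat_shares = {c: v / grand for c, v in cat_values.items()}
    return CompositionShares(
        basis=basis, include_unknown=include_unknown,
        category_shares=cat_shares, family_shares=fam_shares,
        family_values={f: v for f, (_, v) in mapping.items()},
        family_categories={f: c for f, (c, _) in mapping.items()})


@dataclass
class PhenotypeVerdict:
    basis: str
    include_unknown: bool
    shares: dict[str, float]
    dominant_family: Optional[str]
    threshold: float = DOMINANCE_THRESHOLD


def dominant_phenotype(shares: CompositionShares | Mapping[str, float],
                       basis: str = "", include_unknown: bool = True,
                       ) -> PhenotypeVerdict:
    """A family is dominant iff its share strictly exceeds 50%."""
    if isinstance(shares, CompositionShares):
        basis = shares.basis
        include_unknown = shares.include_unknown
        fam = shares.family_shares
    else:
        fam = dict(shares)
    dominant = None
    if fam:
        best = min(sorted(fam), key=lambda f: (-fam[f], f))
        if fam[best] > DOMINANCE_THRESHOLD:
            dominant = best
    return PhenotypeVerdict(basis=basis, include_unknown=include_unknown,
                            shares=fam, dominant_family=dominant)


# --------------------------------------------------------------------------
# Cross-omics ranking
# --------------------------------------------------------------------------

@dataclass
class CrossRankRow:
    family: str
    category: str
    value: float
    rank: int
    other_rank: object  # int or "Not present"


def _rank_families(mapping: Mapping[str, tuple[str, float]]) -> dict[str, int]:
    ordered = sorted(mapping, key=lambda f: (-mapping[f][1], f))
    return {f: i + 1 for i, f in enumerate(ordered)}


def top_n_crossrank(primary, other, n: int = 10) -> list[CrossRankRow]:
    """Top-n families of ``primary`` annotated with their rank in ``other``.

    Families sort descending by abundance, ties broken lexicographically;
    families absent from the other dataset get the "Not present" token.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    pm = _family_mapping(primary)
    om = _family_mapping(other)
    p_ranks = _rank_families(pm)
    o_ranks = _rank_families(om)
    rows = []
    for fam in sorted(pm, key=lambda f: p_ranks[f])[:n]:
        cat, val = pm[fam]
        rows.append(CrossRankRow(
            family=fam, category=cat, value=val, rank=p_ranks[fam],
            other_rank=o_ranks.get(fam, NOT_PRESENT)))
    return rows


# --------------------------------------------------------------------------
# Restricted family panel
# --------------------------------------------------------------------------

@dataclass
class PanelReport:
    panel: tuple[str, ...]
    cluster_counts: dict[str, int]
    shares: dict[str, float]        # re-normalised over the panel
    verdict: PhenotypeVerdict


def panel_analysis(assignments: Iterable[ToxinAssignment],
                   rna_families: FamilyAbundance | Mapping,
                   panel: Sequence[str] = SMITH_PANEL) -> PanelReport:
    """Dominance analysis restricted to a fixed family panel.

    Panel families without clusters are reported with count 0 and share 0;
    shares are re-normalised over the panel members present.
    """
    if not panel:
        raise ValueError("empty family panel")
    mapping = _family_mapping(rna_families)
    counts = {f: 0 for f in panel}
    for a in assignments:
        if a.family in counts:
            counts[a.family] += 1
    values = {f: mapping.get(f, ("", 0.0))[1] for f in panel}
    total = sum(values.values())
    if total == 0:
        shares = {f: 0.0 for f in panel}
    else:
        shares = {f: v / total for f, v in values.items()}
    verdict = dominant_phenotype(shares, basis="rna_abundance_panel")
    return PanelReport(panel=tuple(panel), cluster_counts=counts,
                       shares=shares, verdict=verdict)


# --------------------------------------------------------------------------
# Summary count table
# --------------------------------------------------------------------------

@dataclass
class Table1Summary:
    rna: dict[str, int]
    protein: dict[str, int]
    signal_data_available: bool


def table1_summary(clusters: Sequence[GeneCluster],
                   assignments: Sequence[ToxinAssignment],
                   signal_map: Optional[Mapping[str, bool]],
                   best_hits: Mapping[str, BestHit],
                   proteome_ids: Iterable[str]) -> Table1Summary:
    """Summary counts for the RNA universe and the venom-protein universe.

    ``proteome_ids`` is the full set of clusters detected in milked venom
    (toxin and non-toxin alike); it must be a subset of the RNA universe.
    """
    toxin_ids = {a.cluster_id for a in assignments}
    proteome_ids = set(proteome_ids)
    has_signal = signal_map or {}

    def tally(ids: set[str]) -> dict[str, int]:
        ann = {cid for cid in ids if cid in best_hits}
        toxins = ids & toxin_ids
        return {
            "orf_sequences": len(ids),
            "annotated_orfs": len(ann),
            "unique_best_hit_subjects": len({best_hits[c].subject for c in ann}),
            "orfs_with_signal": sum(1 for c in ids if has_signal.get(c) is True),
            "putative_toxin_orfs": len(toxins),
            "toxin_orfs_with_signal": sum(1 for c in toxins
                                          if has_signal.get(c) is True),
            "toxin_unique_best_hit_subjects": len(
                {best_hits[c].subject for c in toxins if c in best_hits}),
        }

    all_ids = {c.id for c in clusters}
    if not proteome_ids <= all_ids:
        raise ValueError("proteome universe is not a subset of the RNA universe")
    return Table1Summary(rna=tally(all_ids), protein=tally(proteome_ids),
                         signal_data_available=signal_map is not None)


# --------------------------------------------------------------------------
# Export
# --------------------------------------------------------------------------

def _write_recruitment_tsv(rows: list[RecruitmentRow], total: RecruitmentRow,
                           path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("category\trna_clusters\trna_families\tprotein_clusters\t"
                 "protein_families\tpercentage\n")
        for r in list(rows) + [total]:
            fh.write(f"{r.category}\t{r.rna_clusters}\t{r.rna_families}\t"
                     f"{r.protein_clusters}\t{r.protein_families}\t"
                     f"{r.percentage:.1f}\n")


def read_recruitment_tsv(path: str | Path) -> list[RecruitmentRow]:
    rows = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            cat, rc, rf, pc, pf, _ = line.rstrip("\n").split("\t")
            rows.append(RecruitmentRow(cat, int(rc), int(rf), int(pc), int(pf)))
    return rows


def _shares_tsv(shares: CompositionShares, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("family\tcategory\tvalue\tshare_pct\n")
        for fam in sorted(shares.family_shares,
                          key=lambda f: (-shares.family_shares[f], f)):
            fh.write(f"{fam}\t{shares.family_categories[fam]}\t"
                     f"{shares.family_values[fam]:.6g}\t"
                     f"{round_half_up(100 * shares.family_shares[fam], 1):.1f}\n")


def _crossrank_tsv(rows: list[CrossRankRow], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("rank\tfamily\tcategory\tvalue\trank_in_other\n")
        for r in rows:
            fh.write(f"{r.rank}\t{r.family}\t{r.category}\t{r.value:.6g}\t"
                     f"{r.other_rank}\n")


def export_report(outdir: str | Path, *,
                  recruitment: Optional[tuple[list[RecruitmentRow], RecruitmentRow]] = None,
                  compositions: Mapping[str, CompositionShares] = (),
                  crossranks: Mapping[str, list[CrossRankRow]] = (),
                  verdicts: Mapping[str, PhenotypeVerdict] = (),
                  panel: Optional[PanelReport] = None,
                  table1: Optional[Table1Summary] = None,
                  extras: Optional[Mapping[str, object]] = None) -> Path:
    """Write every computed table as TSV plus one structured JSON summary.

    Deterministic: identical inputs produce byte-identical files.
    Returns the path of the JSON summary.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}
    if recruitment is not None:
        rows, total = recruitment
        _write_recruitment_tsv(rows, total, outdir / "recruitment.tsv")
        summary["recruitment"] = {
            r.category: {"rna_clusters": r.rna_clusters,
                         "rna_families": r.rna_families,
                         "protein_clusters": r.protein_clusters,
                         "protein_families": r.protein_families,
                         "percentage": r.percentage}
            for r in rows + [total]}
    comp_summary = {}
    for name, shares in dict(compositions).items():
        _shares_tsv(shares, outdir / f"composition_{name}.tsv")
        comp_summary[name] = {
            "basis": shares.basis,
            "include_unknown": shares.include_unknown,
            "category_pct": shares.category_pct(),
            "family_pct": shares.family_pct(),
        }
    if comp_summary:
        summary["composition"] = comp_summary
    for name, rows in dict(crossranks).items():
        _crossrank_tsv(rows, outdir / f"crossrank_{name}.tsv")
    if crossranks:
        summary["crossrank"] = {
            name: [{"rank": r.rank, "family": r.family,
                    "value": r.value, "other_rank": r.other_rank}
                   for r in rows]
            for name, rows in dict(crossranks).items()}
    if verdicts:
        summary["dominance"] = {
            name: {"basis": v.basis, "include_unknown": v.include_unknown,
                   "dominant_family": v.dominant_family,
                   "max_share_pct": round_half_up(
                       100 * max(v.shares.values()), 1) if v.shares else 0.0}
            for name, v in dict(verdicts).items()}
    if panel is not None:
        with open(outdir / "panel.tsv", "w") as fh:
            fh.write("family\tclusters\tshare_pct\n")
            for fam in panel.panel:
                fh.write(f"{fam}\t{panel.cluster_counts[fam]}\t"
                         f"{round_half_up(100 * panel.shares[fam], 1):.1f}\n")
        summary["panel"] = {
            "families": list(panel.panel),
            "cluster_counts": panel.cluster_counts,
            "share_pct": {f: round_half_up(100 * s, 1)
                          for f, s in panel.shares.items()},
            "dominant_family": panel.verdict.dominant_family,
        }
    if table1 is not None:
        with open(outdir / "table1.tsv", "w") as fh:
            fh.write("metric\trna\tprotein\n")
            for key in table1.rna:
                fh.write(f"{key}\t{table1.rna[key]}\t{table1.protein[key]}\n")
        summary["summary_counts"] = {"rna": table1.rna, "protein": table1.protein,
                                     "signal_data_available": table1.signal_data_available}
    if extras:
        summary["extras"] = dict(extras)
    out = outdir / "summary.json"
    with open(out, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
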