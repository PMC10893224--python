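"""Published Entacmaea quadricolor summary counts and the worked example.

The full study dataset (hundreds of thousands of gene clusters, raw reads,
DIA mass spectra) is not reproducible at desk scale, but every percentage in
its category-level summaries is plain arithmetic on the printed counts.
This module ships those counts as package data and recomputes the derived
quantities through the same report functions the synthetic pipeline uses,
so the reporting layer is exercised against real published numbers.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .report import (CompositionShares, CrossRankRow, RecruitmentRow,
                     composition_shares, recruitment_rows_from_counts,
                     top_n_crossrank)
from .util import round_half_up


def _data_path(name: str) -> Path:
    return resources.files("cnidotox").joinpath("data", name)


def load_category_counts() -> dict[str, tuple[int, int, int, int]]:
    """category -> (rna_clusters, rna_families, protein_clusters, protein_families)."""
    out = {}
    with open(_data_path("eq_category_counts.tsv")) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("category\t") or not line.strip():
                continue
            cat, rc, rf, pc, pf = line.rstrip("\n").split("\t")
            out[cat] = (int(rc), int(rf), int(pc), int(pf))
    return out


def load_summary_counts() -> dict[str, tuple[int, int]]:
    """metric -> (rna universe count, protein universe count)."""
    out = {}
    with open(_data_path("eq_summary_counts.tsv")) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("metric\t") or not line.strip():
                continue
            metric, rna, protein = line.rstrip("\n").split("\t")
            out[metric] = (int(rna), int(protein))
    return out


def load_family_abundance() -> dict[str, dict[str, tuple[str, float]]]:
    """dataset ('rna'|'protein') -> {family: (category, abundance)}."""
    out: dict[str, dict[str, tuple[str, float]]] = {"rna": {}, "protein": {}}
    with open(_data_path("eq_family_abundance.tsv")) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("dataset\t") or not line.strip():
                continue
            dataset, family, category, abundance = line.rstrip("\n").split("\t")
            out[dataset][family] = (category, float(abundance))
    return out


def worked_example() -> dict:
    """Recompute every category-level percentage from the printed counts.

    Returns a flat dict of named quantities (percentages on the 0-100 scale,
    rounded half-up to 1 decimal) plus the recruitment rows and rankings.
    """
    cat_counts = load_category_counts()
    totals = load_summary_counts()
    fam_ab = load_family_abundance()

    rows: list[RecruitmentRow] = recruitment_rows_from_counts(cat_counts)
    n_toxin_rna = sum(r.rna_clusters for r in rows)
    n_toxin_prot = sum(r.protein_clusters for r in rows)

    rna_shares: CompositionShares = composition_shares(
        {cat: (cat, float(v[0])) for cat, v in cat_counts.items()},
        basis="cluster_count")
    prot_shares: CompositionShares = composition_shares(
        {cat: (cat, float(v[2])) for cat, v in cat_counts.items()},
        basis="cluster_count")

    rank_rna: list[CrossRankRow] = top_n_crossrank(
        fam_ab["rna"], fam_ab["protein"], n=10)
    rank_prot: list[CrossRankRow] = top_n_crossrank(
        fam_ab["protein"], fam_ab["rna"], n=10)

    n_clusters, n_proteome = totals["orf_sequences"]

    quantities = {
        "toxin_recruitment_pct": round_half_up(
            100.0 * n_toxin_prot / n_toxin_rna, 1),
        "unknown_cluster_share_pct": rna_shares.category_pct()["Unknown"],
        "haemostatic_cluster_share_pct":
            rna_shares.category_pct()["Haemostatic and haemorrhagic"],
        "proteome_unknown_cluster_share_pct": prot_shares.category_pct()["Unknown"],
        "proteome_haemostatic_cluster_share_pct":
            prot_shares.category_pct()["Haemostatic and haemorrhagic"],
        "venom_clusters_pct_of_transcriptome": round_half_up(
            100.0 * n_proteome / n_clusters, 1),
        "toxin_pct_of_venom_proteome": round_half_up(
            100.0 * n_toxin_prot / n_proteome, 1),
    }
    for r in rows:
        key = ("recruitment_" +
               r.category.lower().replace(" and ", "_").replace(" ", "_") +
               "_pct")
        quantities[key] = r.percentage
    return {
        "quantities": quantities,
        "recruitment_rows": rows,
        "rna_cluster_shares": rna_shares,
        "protein_cluster_shares": prot_shares,
        "crossrank_rna": rank_rna,
        "crossrank_protein": rank_prot,
        "n_toxin_rna": n_toxin_rna,
        "n_toxin_protein": n_toxin_prot,
    }
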