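"""Recruitment, composition shares, rankings, dominance, panel, export."""

import json

import pytest

from cnidotox.refdata import (load_category_counts, load_family_abundance,
                              worked_example)
from cnidotox.report import (NOT_PRESENT, composition_shares,
                             dominant_phenotype, export_report,
                             panel_analysis, read_recruitment_tsv,
                             recruitment_rows_from_counts, table1_summary,
                             top_n_crossrank, SMITH_PANEL)
from cnidotox.rules import ToxinAssignment
from cnidotox.seqio import BestHit, GeneCluster


def _assign(cid, family, category="Unknown"):
    return ToxinAssignment(cluster_id=cid, family=family, category=category,
                           evidence=[], architecture="")


class TestRecruitment:
    def test_published_rows(self):
        rows = recruitment_rows_from_counts(load_category_counts())
        by_cat = {r.category: r for r in rows}
        assert by_cat["Allergen and innate immunity"].percentage == 44.4
        assert by_cat["Mixed function enzymes"].percentage == 4.2
        assert by_cat["Unknown"].percentage == 20.3

    def test_zero_detected(self):
        rows = recruitment_rows_from_counts({"Neurotoxins": (10, 3, 0, 0)})
        assert rows[0].percentage == 0.0

    def test_internal_consistency(self):
        for r in recruitment_rows_from_counts(load_category_counts()):
            recomputed = round(100.0 * r.protein_clusters / r.rna_clusters, 1)
            assert abs(recomputed - r.percentage) <= 0.05


class TestCompositionShares:
    def test_cluster_basis_published_shares(self):
        counts = load_category_counts()
        shares = composition_shares(
            {c: (c, float(v[0])) for c, v in counts.items()})
        assert shares.category_pct()["Haemostatic and haemorrhagic"] == 32.7
        assert shares.category_pct()["Unknown"] == 42.9

    def test_proteome_cluster_basis(self):
        counts = load_category_counts()
        shares = composition_shares(
            {c: (c, float(v[2])) for c, v in counts.items()})
        assert shares.category_pct()["Unknown"] == 47.4

    def test_single_family_is_total(self):
        shares = composition_shares({"Z3": ("Unknown", 42.0)})
        assert shares.family_shares["Z3"] == 1.0

    def test_exclude_unknown_identity(self):
        mapping = {"A": ("Neurotoxins", 30.0), "B": ("Unknown", 50.0),
                   "C": ("Pore forming", 20.0)}
        full = composition_shares(mapping)
        known = composition_shares(mapping, include_unknown=False)
        manual = {f: v / 50.0 for f, (c, v) in mapping.items()
                  if c != "Unknown"}
        assert known.family_shares == pytest.approx(manual)
        # removing Unknown from the full shares and re-normalising agrees
        renorm = {f: s / (1 - full.category_shares["Unknown"])
                  for f, s in full.family_shares.items() if f != "B"}
        assert known.family_shares == pytest.approx(renorm)

    def test_zero_total_errors(self):
        with pytest.raises(ValueError):
            composition_shares({"A": ("Unknown", 0.0)})


class TestCrossRank:
    def test_published_top_ranks(self):
        fam = load_family_abundance()
        rows = top_n_crossrank(fam["rna"], fam["protein"], 10)
        assert (rows[0].family, rows[0].rank, rows[0].other_rank) == ("Z3", 1, 1)
        sa8 = next(r for r in rows if r.family == "Sea Anemone 8")
        assert sa8.other_rank == NOT_PRESENT

    def test_tie_broken_lexicographically(self):
        a = {"Beta": ("Unknown", 5.0), "Alpha": ("Unknown", 5.0)}
        rows = top_n_crossrank(a, a, 2)
        assert [r.family for r in rows] == ["Alpha", "Beta"]

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            top_n_crossrank({}, {}, 0)


class TestDominance:
    def test_clear_majority(self):
        v = dominant_phenotype({"ShK-like": 0.77, "Actinoporins": 0.23})
        assert v.dominant_family == "ShK-like"

    def test_no_majority(self):
        v = dominant_phenotype({"A": 0.40, "B": 0.35, "C": 0.25})
        assert v.dominant_family is None

    def test_exactly_half_is_not_dominant(self):
        v = dominant_phenotype({"A": 0.50, "B": 0.50})
        assert v.dominant_family is None

    def test_scale_invariance(self):
        mapping = {"A": ("Unknown", 60.0), "B": ("Unknown", 40.0)}
        scaled = {f: (c, 1e6 * v) for f, (c, v) in mapping.items()}
        v1 = dominant_phenotype(composition_shares(mapping))
        v2 = dominant_phenotype(composition_shares(scaled))
        assert v1.dominant_family == v2.dominant_family == "A"


class TestPanel:
    def test_absent_family_reported_zero(self):
        assignments = [_assign("c1", "ShK-like", "Neurotoxins"),
                       _assign("c2", "Actinoporins", "Pore forming")]
        fam = {"ShK-like": ("Neurotoxins", 80.0),
               "Actinoporins": ("Pore forming", 20.0)}
        rep = panel_analysis(assignments, fam)
        assert rep.cluster_counts["NEP6"] == 0
        assert rep.shares["NEP6"] == 0.0
        assert rep.verdict.dominant_family == "ShK-like"

    def test_counts_equal_direct_filter(self, default_run):
        rep = default_run.panel
        direct = {f: sum(1 for a in default_run.assignments if a.family == f)
                  for f in SMITH_PANEL}
        assert rep.cluster_counts == direct

    def test_full_panel_matches_composition(self):
        fam = {"A": ("Unknown", 60.0), "B": ("Neurotoxins", 40.0)}
        rep = panel_analysis([], fam, panel=("A", "B"))
        shares = composition_shares(fam)
        assert rep.shares == pytest.approx(shares.family_shares)

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            panel_analysis([], {}, panel=())


class TestTable1:
    def _fixture(self):
        clusters = [GeneCluster(id=f"c{i}", protein_seq="M" * 40)
                    for i in range(10)]
        assignments = [_assign("c0", "Z3"), _assign("c1", "ShK-like",
                                                    "Neurotoxins")]
        signal = {"c0": True, "c2": True, "c1": False}
        hits = {"c0": BestHit("s1", 90.0, 1e-20, 100.0),
                "c1": BestHit("s2", 80.0, 1e-10, 80.0),
                "c3": BestHit("s1", 70.0, 1e-8, 60.0)}
        proteome = {"c0", "c3"}
        return clusters, assignments, signal, hits, proteome

    def test_tallies_match_direct_counts(self):
        clusters, assignments, signal, hits, proteome = self._fixture()
        t = table1_summary(clusters, assignments, signal, hits, proteome)
        assert t.rna["orf_sequences"] == 10
        assert t.rna["annotated_orfs"] == 3
        assert t.rna["unique_best_hit_subjects"] == 2
        assert t.rna["orfs_with_signal"] == 2
        assert t.rna["putative_toxin_orfs"] == 2
        assert t.rna["toxin_orfs_with_signal"] == 1
        assert t.rna["toxin_unique_best_hit_subjects"] == 2
        assert t.protein["orf_sequences"] == 2
        assert t.protein["putative_toxin_orfs"] == 1

    def test_missing_signal_map_flagged(self):
        clusters, assignments, _, hits, proteome = self._fixture()
        t = table1_summary(clusters, assignments, None, hits, proteome)
        assert t.signal_data_available is False
        assert t.rna["orfs_with_signal"] == 0

    def test_proteome_subset_enforced(self):
        clusters, assignments, signal, hits, _ = self._fixture()
        with pytest.raises(ValueError, match="subset"):
            table1_summary(clusters, assignments, signal, hits, {"ghost"})


class TestExport:
    def test_deterministic_and_roundtrip(self, tmp_path):
        we = worked_example()
        rows = we["recruitment_rows"]
        total = rows[0].__class__(
            "Total", sum(r.rna_clusters for r in rows),
            sum(r.rna_families for r in rows),
            sum(r.protein_clusters for r in rows),
            sum(r.protein_families for r in rows))
        kwargs = dict(
            recruitment=(rows, total),
            compositions={"rna_clusters": we["rna_cluster_shares"]},
            crossranks={"rna": we["crossrank_rna"]},
            verdicts={"rna": dominant_phenotype(we["rna_cluster_shares"])},
        )
        out1 = export_report(tmp_path / "r1", **kwargs)
        out2 = export_report(tmp_path / "r2", **kwargs)
        for name in ("summary.json", "recruitment.tsv",
                     "composition_rna_clusters.tsv", "crossrank_rna.tsv"):
            assert (tmp_path / "r1" / name).read_bytes() == \
                   (tmp_path / "r2" / name).read_bytes()
        back = read_recruitment_tsv(tmp_path / "r1" / "recruitment.tsv")
        assert [(r.category, r.rna_clusters, r.percentage) for r in back] == \
               [(r.category, r.rna_clusters, r.percentage)
                for r in rows + [total]]
        summary = json.loads(out1.read_text())
        assert set(summary) == {"recruitment", "composition", "crossrank",
                                "dominance"}
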