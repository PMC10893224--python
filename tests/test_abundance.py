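"""Median-of-ratios normalisation, family aggregation, toxin fractions."""

import math

import numpy as np
import pandas as pd
import pytest

from cnidotox.abundance import (AbundanceMatrix, detect_in_proteome,
                                family_abundance, normalise, size_factors,
                                toxin_fraction)
from cnidotox.rules import ToxinAssignment
from oracles import size_factor_oracle


def _matrix(data, kind="raw_rna", samples=None):
    df = pd.DataFrame(data).T if isinstance(data, dict) else pd.DataFrame(data)
    if samples is not None:
        df.columns = samples
    return AbundanceMatrix(values=df.astype(float), kind=kind)


def _assign(cid, family, category="Unknown"):
    return ToxinAssignment(cluster_id=cid, family=family, category=category,
                           evidence=[], architecture="")


class TestSizeFactors:
    def test_identical_samples_unit_factors(self):
        m = _matrix({"a": [10, 10], "b": [75, 75], "c": [3, 3]})
        sf = size_factors(m)
        assert np.allclose(sf.factors.to_numpy(), [1.0, 1.0])

    def test_column_doubling_closed_form(self):
        m = _matrix({"a": [10, 20], "b": [75, 150], "c": [3, 6]})
        sf = size_factors(m)
        assert sf.factors.iloc[0] == pytest.approx(1 / math.sqrt(2), rel=1e-12)
        assert sf.factors.iloc[1] == pytest.approx(math.sqrt(2), rel=1e-12)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(40.0, size=(200, 24)).astype(float)
        m = _matrix(counts)
        sf = size_factors(m)
        oracle = size_factor_oracle(
            {str(i): list(counts[i]) for i in range(counts.shape[0])})
        assert np.allclose(sf.factors.to_numpy(), oracle, rtol=1e-9)

    def test_zero_rows_excluded(self):
        m = _matrix({"a": [10, 20], "b": [0, 100], "c": [10, 20]})
        sf = size_factors(m)
        assert list(sf.included_clusters) == ["a", "c"]
        assert math.isnan(sf.geometric_means["b"])

    def test_no_positive_cluster_errors(self):
        m = _matrix({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="undefined"):
            size_factors(m)


class TestNormalise:
    def test_unit_factors_identity(self):
        m = _matrix({"a": [10, 10], "b": [75, 75]})
        out = normalise(m, size_factors(m))
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())
        assert out.kind == "normalised_rna"

    def test_doubled_column_collapses(self):
        m = _matrix({"a": [10, 20], "b": [75, 150], "c": [3, 6]})
        out = normalise(m, size_factors(m))
        col = out.values
        assert np.allclose(col.iloc[:, 0], col.iloc[:, 1])

    def test_median_ratio_is_one(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(30.0, size=(150, 6)).astype(float) + 1.0
        m = _matrix(counts)
        sf = size_factors(m)
        out = normalise(m, sf)
        ratios = out.values.loc[sf.included_clusters].div(
            sf.geometric_means[sf.included_clusters], axis=0)
        assert np.allclose(np.median(ratios, axis=0), 1.0)

    def test_scaling_one_column_only_rescales_globally(self):
        # Scaling one library rescales the normalised matrix by a single
        # global constant (c^(1/m)), so every downstream share is unchanged.
        rng = np.random.default_rng(3)
        counts = rng.poisson(50.0, size=(100, 5)).astype(float) + 1.0
        m1 = _matrix(counts.copy())
        scaled = counts.copy()
        scaled[:, 2] *= 7.5
        m2 = _matrix(scaled)
        out1 = normalise(m1, size_factors(m1)).values.to_numpy()
        out2 = normalise(m2, size_factors(m2)).values.to_numpy()
        ratio = out2 / out1
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-9)
        assert ratio.flat[0] == pytest.approx(7.5 ** (1 / 5), rel=1e-9)


class TestFamilyAbundance:
    def test_two_cluster_family_sum(self):
        m = _matrix({"a": [10, 10], "b": [5, 5]}, kind="normalised_rna")
        fa = family_abundance(m, [_assign("a", "Z3"), _assign("b", "Z3")])
        assert fa.table.loc["Z3", "abundance"] == pytest.approx(15.0)
        assert fa.table.loc["Z3", "n_clusters"] == 2

    def test_all_zero_family(self):
        m = _matrix({"a": [0] * 24}, kind="normalised_rna")
        fa = family_abundance(m, [_assign("a", "U15")])
        assert fa.table.loc["U15", "abundance"] == 0.0

    def test_matches_spreadsheet_oracle(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0, 100, size=(12, 4))
        ids = [f"c{i}" for i in range(12)]
        m = AbundanceMatrix(pd.DataFrame(values, index=ids), "normalised_rna")
        fams = ["F1", "F1", "F2", "F3", "F3", "F3", "F4", "F4", "F5",
                "F5", "F5", "F5"]
        assignments = [_assign(cid, f) for cid, f in zip(ids, fams)]
        fa = family_abundance(m, assignments)
        for fam in set(fams):
            rows = [i for i, f in enumerate(fams) if f == fam]
            expected = sum(values[i].mean() for i in rows)
            assert fa.table.loc[fam, "abundance"] == pytest.approx(expected)

    def test_conservation_over_families(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(0, 50, size=(30, 7))
        ids = [f"c{i}" for i in range(30)]
        m = AbundanceMatrix(pd.DataFrame(values, index=ids), "protein")
        assignments = [_assign(cid, f"F{i % 6}") for i, cid in enumerate(ids)]
        fa = family_abundance(m, assignments)
        assert fa.table["abundance"].sum() == pytest.approx(
            values.mean(axis=1).sum())

    def test_missing_cluster_errors_or_skips(self):
        m = _matrix({"a": [1, 2]}, kind="protein")
        with pytest.raises(ValueError, match="ghost"):
            family_abundance(m, [_assign("ghost", "F")])
        fa = family_abundance(m, [_assign("ghost", "F"), _assign("a", "G")],
                              missing="skip")
        assert list(fa.table.index) == ["G"]


class TestToxinFraction:
    def test_constant_share(self):
        m = _matrix({"t": [10] * 4, "b": [990] * 4}, kind="normalised_rna")
        tf = toxin_fraction(m, ["t"])
        assert tf.mean_pct == 1.0
        assert all(v == 1.0 for v in tf.per_sample_pct.values())

    def test_all_clusters_toxin(self):
        m = _matrix({"a": [5, 5], "b": [5, 5]}, kind="normalised_rna")
        tf = toxin_fraction(m, ["a", "b"])
        assert tf.mean == pytest.approx(1.0)

    def test_fractions_bounded(self):
        rng = np.random.default_rng(21)
        values = rng.uniform(0, 10, size=(40, 6)) + 0.01
        m = AbundanceMatrix(pd.DataFrame(values,
                                         index=[f"c{i}" for i in range(40)]),
                            "normalised_rna")
        tf = toxin_fraction(m, [f"c{i}" for i in range(0, 40, 3)])
        assert ((tf.per_sample >= 0) & (tf.per_sample <= 1)).all()

    def test_zero_column_named(self):
        m = _matrix({"a": [1, 0]}, kind="normalised_rna", samples=["s1", "s2"])
        with pytest.raises(ValueError, match="s2"):
            toxin_fraction(m, ["a"])


class TestDetectInProteome:
    def test_partial_recruitment(self):
        prot = _matrix({"a": [3.0]}, kind="protein")
        det = detect_in_proteome(prot, ["a", "b", "c", "d", "e"],
                                 ["a", "b", "c", "d", "e"])
        assert det.recruitment_pct == 20.0

    def test_empty_proteome(self):
        prot = AbundanceMatrix(
            pd.DataFrame(np.empty((0, 2)), columns=["v1", "v2"]), "protein")
        det = detect_in_proteome(prot, ["a", "b"], ["a", "b"])
        assert det.recruitment_pct == 0.0

    def test_study_scale_ratio(self):
        # 230 of 1251 toxin clusters detected -> 18.4%
        toxins = [f"t{i}" for i in range(1251)]
        prot = AbundanceMatrix(
            pd.DataFrame(np.ones((230, 7)), index=toxins[:230]), "protein")
        det = detect_in_proteome(prot, toxins, toxins)
        assert det.recruitment_pct == 18.4

    def test_orphan_proteome_id_errors(self):
        prot = _matrix({"x": [1.0]}, kind="protein")
        with pytest.raises(ValueError, match="absent"):
            detect_in_proteome(prot, ["a"], ["a", "b"])
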