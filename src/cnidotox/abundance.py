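"""Abundance normalisation and family-level aggregation.

RNA counts are normalised with the median-of-ratios method (the DESeq2 size
factor): each gene's geometric mean across samples forms a pseudo-reference,
and a sample's size factor is the median of its count-to-reference ratios.
Genes with any zero count have geometric mean zero and are excluded from the
median — the strict, classic definition.  Normalised counts (and the
delivered DIA protein abundances, which arrive already normalised) are then
averaged across samples per cluster and summed within each toxin protein
family to give family-level expression.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .rules import ToxinAssignment
from .util import round_half_up

KINDS = ("raw_rna", "normalised_rna", "protein")


@dataclass
class AbundanceMatrix:
    """Clusters x samples abundance values (k_ij), raw or normalised."""

    values: pd.DataFrame  # index: cluster ids, columns: sample ids
    kind: str

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"unknown matrix kind {self.kind!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative abundance values")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ValueError("duplicate cluster or sample ids")

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @classmethod
    def read_tsv(cls, path: str | Path, kind: str) -> "AbundanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(values=df, kind=kind)

    def to_tsv(self, path: str | Path, float_format: Optional[str] = None) -> None:
        self.values.to_csv(path, sep="\t", index_label="cluster_id",
                           float_format=float_format)


@dataclass
class SizeFactors:
    """Per-sample scale factors s_j and the per-cluster reference g_i."""

    factors: pd.Series            # s_j > 0, indexed by sample id
    geometric_means: pd.Series    # g_i over all clusters; NaN where any count is 0
    included_clusters: pd.Index   # clusters with all-positive counts


def size_factors(raw: AbundanceMatrix) -> SizeFactors:
    """Median-of-ratios size factors from a raw count matrix.

    g_i = (prod_j k_ij)^(1/m); clusters containing any zero are excluded from
    the median; s_j = median over included clusters of k_ij / g_i.
    """
    if raw.kind != "raw_rna":
        raise ValueError("size factors are defined on raw RNA counts")
    if raw.values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    k = raw.values.to_numpy(dtype=float)
    all_positive = (k > 0).all(axis=1)
    if not all_positive.any():
        raise ValueError("no cluster with all-positive counts; "
                         "size factors are undefined")
    g = np.full(k.shape[0], np.nan)
    g[all_positive] = np.exp(np.log(k[all_positive]).mean(axis=1))
    ratios = k[all_positive] / g[all_positive, None]
    s = np.median(ratios, axis=0)
    return SizeFactors(
        factors=pd.Series(s, index=raw.values.columns),
        geometric_means=pd.Series(g, index=raw.values.index),
        included_clusters=raw.values.index[all_positive],
    )


def normalise(raw: AbundanceMatrix, factors: SizeFactors) -> AbundanceMatrix:
    """Divide each sample column by its size factor."""
    if raw.kind != "raw_rna":
        raise ValueError("normalise expects raw RNA counts")
    if list(factors.factors.index) != list(raw.values.columns):
        raise ValueError("size factors do not match the matrix samples")
    return AbundanceMatrix(values=raw.values / factors.factors, kind="normalised_rna")


@dataclass
class FamilyAbundance:
    """family -> (category, summed mean abundance A_f, n_clusters)."""

    table: pd.DataFrame  # index family; columns: category, abundance, n_clusters
    kind: str            # which matrix it was aggregated from

    def as_mapping(self) -> dict[str, tuple[str, float]]:
        return {fam: (row["category"], float(row["abundance"]))
                for fam, row in self.table.iterrows()}

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", index_label="family")


def family_abundance(matrix: AbundanceMatrix,
                     assignments: Iterable[ToxinAssignment],
                     missing: str = "error") -> FamilyAbundance:
    """Aggregate cluster abundance to the toxin-family level.

    Per cluster: arithmetic mean across all samples (zeros included); per
    family: sum of cluster means.  ``missing='skip'`` drops assignments whose
    cluster is not in the matrix — the proteome matrix legitimately holds
    only the detected subset.
    """
    if matrix.kind == "raw_rna":
        raise ValueError("aggregate normalised RNA or protein abundance, not raw counts")
    means = matrix.values.mean(axis=1)
    rows: dict[str, list] = {}
    for a in assignments:
        if a.cluster_id not in means.index:
            if missing == "skip":
                continue
            raise ValueError(f"assignment references cluster {a.cluster_id!r} "
                             f"absent from the matrix")
        entry = rows.setdefault(a.family, [a.category, 0.0, 0])
        entry[1] += float(means[a.cluster_id])
        entry[2] += 1
    table = pd.DataFrame.from_dict(rows, orient="index",
                                   columns=["category", "abundance", "n_clusters"])
    table = table.sort_values("abundance", ascending=False)
    return FamilyAbundance(table=table, kind=matrix.kind)


@dataclass
class ToxinFraction:
    per_sample: pd.Series   # proportion of sample total, in [0, 1]
    mean: float             # arithmetic mean over samples

    @property
    def per_sample_pct(self) -> dict[str, float]:
        return {s: round_half_up(100.0 * v, 1) for s, v in self.per_sample.items()}

    @property
    def mean_pct(self) -> float:
        return round_half_up(100.0 * self.mean, 1)


def toxin_fraction(matrix: AbundanceMatrix,
                   toxin_ids: Iterable[str]) -> ToxinFraction:
    """Per-sample share of total abundance contributed by toxin clusters."""
    toxin_ids = set(toxin_ids)
    totals = matrix.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero sample column(s): {list(zero.index)}")
    toxin_rows = matrix.values.loc[matrix.values.index.isin(toxin_ids)]
    frac = toxin_rows.sum(axis=0) / totals
    return ToxinFraction(per_sample=frac, mean=float(frac.mean()))


@dataclass
class ProteomeDetection:
    detected: dict[str, bool]   # per toxin cluster
    n_detected: int
    n_toxin: int

    @property
    def recruitment_pct(self) -> float:
        if self.n_toxin == 0:
            return 0.0
        return round_half_up(100.0 * self.n_detected / self.n_toxin, 1)


def detect_in_proteome(protein: AbundanceMatrix,
                       toxin_ids: Sequence[str],
                       transcriptome_ids: Iterable[str]) -> ProteomeDetection:
    """Flag toxin clusters detected in the venom proteome.

    Detected = present in the protein matrix with >0 abundance in at least
    one venom sample.  Every proteome row must exist in the transcriptome
    (the spectral library is built from transcriptome-encoded sequences).
    """
    transcriptome_ids = set(transcriptome_ids)
    orphans = [cid for cid in protein.cluster_ids if cid not in transcriptome_ids]
    if orphans:
        raise ValueError(
            f"proteome cluster(s) absent from transcriptome: {orphans[:5]}")
    positive = set(protein.values.index[(protein.values > 0).any(axis=1)])
    detected = {cid: cid in positive for cid in toxin_ids}
    return ProteomeDetection(detected=detected,
                             n_detected=sum(detected.values()),
                             n_toxin=len(detected))


def write_size_factors(factors: SizeFactors, path: str | Path) -> None:
    factors.factors.to_frame("size_factor").to_csv(path, sep="\t",
                                                   index_label="sample_id")
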