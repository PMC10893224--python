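"""Ground-truthed synthetic venomics inputs.

Emulates the statistical structure the analysis assumes, at desk scale:
a few thousand gene clusters of which a small fraction carry a planted toxin
family (each family realised as a PROSITE pattern instance or a cysteine
scaffold embedded in i.i.d. background residues), 24 tentacle RNA-seq
samples of negative-binomial counts with per-sample library-size scaling,
and a 7-sample milked-venom proteome of log-normal abundances restricted to
the clusters "recruited" into venom.  Toxin expression is scaled so planted
toxins contribute the study-like shares of total abundance (1.8% of RNA
counts, 14% of venom protein) in expectation, and recruitment flags are
drawn per cluster (18.4% for toxins) so the recruitment table has an exact
planted truth.

By default every emitted sequence is re-scanned against all planted family
descriptors and resampled if it accidentally matches a foreign one, so the
default scenario is noiseless by construction: the classifier's planted-label
recovery is then a deterministic 100%/100% floor, not a probabilistic one.
Disable ``reject_cross_hits`` to study background false-positive rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .defaults import default_models
from .domains import CompiledPattern, ModelDef, ScaffoldDef
from .seqio import GeneCluster, write_fasta, write_signal_table

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {  # one codon per residue is enough for reverse translation
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

# Synthetic N-terminal signal-like segment (hydrophobic core, no cysteine);
# only the bookkeeping of signal-peptide evidence is modelled, not SignalP.
SIGNAL_MOTIF = "MKFLSVVLALLAVSA"


@dataclass(frozen=True)
class FamilySpec:
    """One plantable toxin family: rule-set family name, category, the
    signature model planted in its sequences, and its relative weight (used
    both for family prevalence and per-cluster expression)."""

    name: str
    category: str
    model: str
    weight: float

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError(f"family {self.name!r}: weight must be > 0")


# Qualitative emulation of the study's venom profile: scaffold families and
# ShK-like high, enzymes mid, panel neurotoxins low, NEP6 absent entirely.
DEFAULT_FAMILY_TABLE: tuple[FamilySpec, ...] = (
    FamilySpec("Z3", "Unknown", "Z3", 10.0),
    FamilySpec("Sea Anemone 8", "Unknown", "SeaAnem8", 9.0),
    FamilySpec("ShK-like", "Neurotoxins", "ShK", 8.0),
    FamilySpec("IG-like", "Unknown", "IG-like", 6.0),
    FamilySpec("EGF-like", "Unknown", "EGF-like", 5.0),
    FamilySpec("PLA2", "Mixed function enzymes", "PLA2", 4.0),
    FamilySpec("Peptidase M12A", "Auxiliary", "Astacin", 3.5),
    FamilySpec("Coagulation factor V-like", "Haemostatic and haemorrhagic", "FA5B", 3.5),
    FamilySpec("CREC", "Unknown", "CREC_dom", 3.0),
    FamilySpec("Peptidase S1", "Haemostatic and haemorrhagic", "Trypsin", 3.0),
    FamilySpec("Venom Kunitz-type family", "Protease inhibitors", "Kunitz", 2.5),
    FamilySpec("U15", "Unknown", "U15", 2.5),
    FamilySpec("U12", "Unknown", "U12", 2.0),
    FamilySpec("Ficolin lectin family", "Haemostatic and haemorrhagic", "Fibrinogen_C", 2.0),
    FamilySpec("CAP", "Allergen and innate immunity", "CAP", 2.0),
    FamilySpec("Actinoporins", "Pore forming", "Actinoporin", 2.0),
    FamilySpec("NEP3", "Neurotoxins", "NEP3_dom", 1.0),
    FamilySpec("KTx2", "Neurotoxins", "KTx2_dom", 1.0),
    FamilySpec("NaTx", "Neurotoxins", "NaTx_dom", 0.8),
    FamilySpec("KTx5", "Neurotoxins", "KTx5_dom", 0.8),
    FamilySpec("KTx3", "Neurotoxins", "KTx3_dom", 0.5),
)


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic scenario.

    Defaults mirror the emulated study where it states them: 24 RNA-seq
    samples, 7 venom samples, toxin recruitment probability 0.184 (230/1251),
    toxin signal-peptide probability 0.41 (515/1251), background detection
    ~0.0185 and background signal ~0.042 (the transcriptome-wide rates), RNA
    toxin share 0.018 and protein toxin share 0.14 (the study's averages).
    """

    n_clusters: int = 2000
    toxin_fraction: float = 0.05
    family_table: tuple[FamilySpec, ...] = DEFAULT_FAMILY_TABLE
    n_rna_samples: int = 24
    n_venom_samples: int = 7
    nb_dispersion: float = 0.2
    library_size_range: tuple[float, float] = (0.7, 1.3)
    detection_prob_toxin: float = 0.184
    detection_prob_background: float = 0.0185
    signal_peptide_prob: float = 0.41
    signal_peptide_prob_background: float = 0.042
    rna_toxin_share: float = 0.018
    protein_toxin_share: float = 0.14
    background_mean_expression: float = 50.0
    background_expression_sigma: float = 1.0
    protein_background_mean: float = 1e5
    protein_noise_sigma: float = 0.5
    length_median: float = 140.0
    length_sigma: float = 0.6
    min_length: int = 40
    max_length: int = 600
    background_freq: Optional[dict[str, float]] = None
    make_transcripts: bool = False
    reject_cross_hits: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be positive")
        for name in ("toxin_fraction", "detection_prob_toxin",
                     "detection_prob_background", "signal_peptide_prob",
                     "signal_peptide_prob_background", "rna_toxin_share",
                     "protein_toxin_share"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a proportion in [0, 1], got {v}")
        if self.n_rna_samples < 2:
            raise ValueError("need at least 2 RNA samples")
        if self.n_venom_samples < 1:
            raise ValueError("need at least 1 venom sample")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        lo, hi = self.library_size_range
        if not (0 < lo <= hi):
            raise ValueError("library_size_range must be positive and ordered")
        if self.background_freq is not None:
            total = sum(self.background_freq.values())
            if not math.isclose(total, 1.0, rel_tol=1e-6):
                raise ValueError("background_freq must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "family_table" in raw:
            raw["family_table"] = tuple(
                FamilySpec(**f) for f in raw["family_table"])
        if "library_size_range" in raw:
            raw["library_size_range"] = tuple(raw["library_size_range"])
        return cls(**raw)


@dataclass
class SimTruth:
    """Per-cluster ground truth of one synthetic scenario."""

    df: pd.DataFrame  # index cluster_id; family, category, has_signal,
                      # detected, mean_expression, signature_start

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def toxin_ids(self) -> list[str]:
        return list(self.df.index[self.df["family"] != ""])

    @property
    def detected_ids(self) -> list[str]:
        return list(self.df.index[self.df["detected"]])

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="cluster_id")

    @classmethod
    def read_tsv(cls, path: str | Path) -> "SimTruth":
        df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False)
        df["has_signal"] = df["has_signal"].astype(bool)
        df["detected"] = df["detected"].astype(bool)
        return cls(df=df)


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # Independent, order-insensitive streams per generation stage.
    return np.random.default_rng([config.seed, stage])


def gen_truth(config: SimConfig) -> SimTruth:
    """Draw cluster labels, signal flags, recruitment flags and mean
    expression; deterministic given the config seed."""
    rng = _rng(config, 0)
    n = config.n_clusters
    ids = [f"CL{i:05d}" for i in range(n)]
    is_toxin = rng.random(n) < config.toxin_fraction
    families = np.array([""] * n, dtype=object)
    categories = np.array([""] * n, dtype=object)
    n_toxin = int(is_toxin.sum())
    table = config.family_table
    if n_toxin and not table:
        raise ValueError("toxin_fraction > 0 requires a non-empty family table")
    if n_toxin:
        weights = np.array([f.weight for f in table], dtype=float)
        draw = rng.choice(len(table), size=n_toxin, p=weights / weights.sum())
        families[is_toxin] = [table[i].name for i in draw]
        categories[is_toxin] = [table[i].category for i in draw]
    p_signal = np.where(is_toxin, config.signal_peptide_prob,
                        config.signal_peptide_prob_background)
    has_signal = rng.random(n) < p_signal
    p_detect = np.where(is_toxin, config.detection_prob_toxin,
                        config.detection_prob_background)
    detected = rng.random(n) < p_detect
    mean_expr = rng.lognormal(np.log(config.background_mean_expression),
                              config.background_expression_sigma, size=n)
    if n_toxin and n_toxin < n:
        # Scale planted toxin means so their expected share of total counts
        # equals rna_toxin_share (library factors cancel in the share).
        w = np.array([next(f.weight for f in table if f.name == fam)
                      for fam in families[is_toxin]])
        bg_total = mean_expr[~is_toxin].sum()
        r = config.rna_toxin_share
        alpha = (r / (1.0 - r)) * bg_total / w.sum() if r < 1 else 1.0
        mean_expr[is_toxin] = alpha * w
    df = pd.DataFrame({
        "family": families,
        "category": categories,
        "has_signal": has_signal,
        "detected": detected,
        "mean_expression": mean_expr,
        "signature_start": np.full(n, -1, dtype=int),
    }, index=pd.Index(ids, name="cluster_id"))
    return SimTruth(df=df)


def _freq_arrays(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    if config.background_freq is None:
        letters = np.array(list(_AA))
        probs = np.full(len(_AA), 1.0 / len(_AA))
    else:
        letters = np.array(list(config.background_freq))
        probs = np.array(list(config.background_freq.values()))
    return letters, probs


def _sample_scaffold_instance(sdef: ScaffoldDef, rng: np.random.Generator,
                              letters: np.ndarray, probs: np.ndarray) -> str:
    pool = letters != "C"
    fill_letters, fill_probs = letters[pool], probs[pool]
    fill_probs = fill_probs / fill_probs.sum()
    parts = ["C"]
    for lo, hi in sdef.gap_ranges:
        gap = int(rng.integers(lo, hi + 1))
        parts.append("".join(rng.choice(fill_letters, size=gap, p=fill_probs)))
        parts.append("C")
    return "".join(parts)


def _sample_signature(model: ModelDef, rng: np.random.Generator,
                      letters: np.ndarray, probs: np.ndarray) -> str:
    if model.kind == "prosite":
        assert isinstance(model.matcher, CompiledPattern)
        return model.matcher.sample(rng)
    if model.kind == "scaffold":
        return _sample_scaffold_instance(model.matcher, rng, letters, probs)
    raise ValueError(f"cannot plant an instance of hmm model {model.name!r}; "
                     f"use a pattern or scaffold signature")


_MAX_RESAMPLE = 200


def gen_sequences(truth: SimTruth, config: SimConfig,
                  models: Optional[dict[str, ModelDef]] = None,
                  ) -> list[GeneCluster]:
    """Emit one protein (and optional transcript) per cluster.

    Planted clusters carry exactly one instance of their family's signature
    at a recorded position; signal-flagged clusters start with the synthetic
    signal segment; everything else is i.i.d. background.  With
    ``reject_cross_hits`` (default) sequences matching a foreign family
    descriptor are resampled, so descriptor scanning recovers the planted
    labels exactly.
    """
    if models is None:
        models = default_models()
    fam_models = {f.name: models[f.model] for f in config.family_table
                  if f.model in models}
    for f in config.family_table:
        if f.model not in models:
            raise ValueError(f"family {f.name!r} references unknown model {f.model!r}")
    # The cross-hit screen covers every scannable model, planted or not:
    # a background sequence matching ANY descriptor would otherwise be
    # classified and break the noiseless-recovery guarantee.
    screen_models = {name: m for name, m in models.items()
                     if m.kind in ("prosite", "scaffold")}
    model_of_family = {f.name: f.model for f in config.family_table}
    rng = _rng(config, 1)
    letters, probs = _freq_arrays(config)
    clusters: list[GeneCluster] = []
    sig_starts: dict[str, int] = {}

    def background(n: int) -> str:
        return "".join(rng.choice(letters, size=n, p=probs)) if n > 0 else ""

    for cid, row in truth.df.iterrows():
        fam = row["family"]
        prefix = SIGNAL_MOTIF if row["has_signal"] else ""
        for attempt in range(_MAX_RESAMPLE):
            length = int(round(float(rng.lognormal(
                np.log(config.length_median), config.length_sigma))))
            length = min(max(length, config.min_length), config.max_length)
            if fam:
                instance = _sample_signature(fam_models[fam], rng, letters, probs)
                if len(prefix) + len(instance) + 2 > length:
                    length = len(prefix) + len(instance) + 10
                body_len = length - len(prefix) - len(instance)
                offset = int(rng.integers(0, body_len + 1))
                seq = (prefix + background(offset) + instance
                       + background(body_len - offset))
                sig_start = len(prefix) + offset + 1  # 1-based
            else:
                seq = prefix + background(length - len(prefix))
                sig_start = -1
            if not config.reject_cross_hits:
                break
            own_model = model_of_family.get(fam)
            probe = GeneCluster(id=cid, protein_seq=seq)
            clean = all(not model.scan(probe)
                        for name, model in screen_models.items()
                        if name != own_model)
            if clean:
                break
        else:
            raise RuntimeError(
                f"{cid}: could not draw a sequence free of foreign signatures "
                f"after {_MAX_RESAMPLE} attempts — check descriptor overlap")
        transcript = None
        if config.make_transcripts:
            utr5 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 30))))
            utr3 = "".join(rng.choice(list("ACGT"), size=int(rng.integers(6, 30))))
            transcript = utr5 + "".join(_CODONS[r] for r in seq) + "TAA" + utr3
        clusters.append(GeneCluster(id=cid, protein_seq=seq,
                                    transcript_seq=transcript,
                                    has_signal=bool(row["has_signal"])))
        sig_starts[cid] = sig_start
    truth.df["signature_start"] = [sig_starts[c] for c in truth.df.index]
    return clusters


def gen_counts(truth: SimTruth, config: SimConfig):
    """Raw RNA count matrix: NB counts with per-sample library scaling."""
    from .abundance import AbundanceMatrix
    rng = _rng(config, 2)
    m = config.n_rna_samples
    s = rng.uniform(*config.library_size_range, size=m)
    mu = truth.df["mean_expression"].to_numpy()[:, None] * s[None, :]
    phi = config.nb_dispersion
    if phi < 1e-12:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
        counts = rng.poisson(lam)
    df = pd.DataFrame(counts, index=truth.df.index.copy(),
                      columns=[f"RNA{j + 1:02d}" for j in range(m)])
    matrix = AbundanceMatrix(values=df, kind="raw_rna")
    matrix.planted_library_factors = pd.Series(s, index=df.columns)
    return matrix


def gen_proteome(truth: SimTruth, config: SimConfig):
    """Venom protein abundance matrix over the recruited (detected) clusters.

    Log-normal noise around family-weighted means, scaled so planted toxins
    contribute ``protein_toxin_share`` of total abundance in expectation.
    """
    from .abundance import AbundanceMatrix
    rng = _rng(config, 3)
    det = truth.df[truth.df["detected"]]
    cols = [f"VEN{j + 1}" for j in range(config.n_venom_samples)]
    if det.empty:
        return AbundanceMatrix(
            values=pd.DataFrame(np.empty((0, len(cols))),
                                index=pd.Index([], name="cluster_id"),
                                columns=cols),
            kind="protein")
    weights = {f.name: f.weight for f in config.family_table}
    is_toxin = (det["family"] != "").to_numpy()
    mu = rng.lognormal(np.log(config.protein_background_mean), 1.0,
                       size=len(det))
    if is_toxin.any() and (~is_toxin).any():
        w = np.array([weights[fam] for fam in det["family"][is_toxin]])
        r = config.protein_toxin_share
        beta = (r / (1.0 - r)) * mu[~is_toxin].sum() / w.sum() if r < 1 else 1.0
        mu[is_toxin] = beta * w
    sigma = config.protein_noise_sigma
    noise = rng.standard_normal((len(det), len(cols)))
    values = mu[:, None] * np.exp(sigma * noise - sigma ** 2 / 2.0)
    df = pd.DataFrame(values, index=det.index.copy(), columns=cols)
    return AbundanceMatrix(values=df, kind="protein")


def simulate_all(config: SimConfig, outdir: Optional[str | Path] = None):
    """Run every generation stage; optionally write the standard file set.

    Returns (clusters, truth, counts, proteome).  Written files: protein
    FASTA, optional transcript FASTA, counts TSV, proteome TSV, signal-call
    TSV and the truth table.
    """
    truth = gen_truth(config)
    clusters = gen_sequences(truth, config)
    counts = gen_counts(truth, config)
    proteome = gen_proteome(truth, config)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(clusters, outdir / "proteins.fasta")
        if config.make_transcripts:
            write_fasta(clusters, outdir / "transcripts.fasta", transcripts=True)
        counts.to_tsv(outdir / "counts.tsv")
        proteome.to_tsv(outdir / "proteome.tsv", float_format="%.6g")
        write_signal_table(
            {c.id: bool(c.has_signal) for c in clusters},
            outdir / "signal_calls.tsv")
        truth.to_tsv(outdir / "truth.tsv")
    return clusters, truth, counts, proteome
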