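"""Sequence I/O and per-cluster sequence features.

The pipeline's atomic unit is the *gene cluster*: a Corset-style grouping of
assembled transcripts treated as one putative gene, represented by a single
translated protein sequence (and optionally the transcript it came from).
This module reads and writes gene-cluster FASTA files, extracts open reading
frames from transcripts with the deliberately permissive >=30 aa cut-off used
to retain small disulfide-rich peptides, computes average molecular weights
for kDa size binning, and reads the two external evidence tables the pipeline
consumes as-is: signal-peptide calls (SignalP-style) and best-hit annotations
(12-column BLAST/MMseqs2 tabular).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Optional

from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .util import round_half_up

MIN_ORF_AA = 30

# ExPASy average (isotopically averaged) residue masses, daltons.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
# X stands for an unknown residue; score it as the unweighted mean so it
# cannot bias a sequence towards any bin.
AVERAGE_RESIDUE_MASS["X"] = sum(AVERAGE_RESIDUE_MASS.values()) / 20.0

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
_STOP_CODONS = set(_STANDARD_TABLE.stop_codons)


class BestHit(NamedTuple):
    subject: str
    identity: float
    evalue: float
    bitscore: float


@dataclass
class GeneCluster:
    """One putative gene: id, translated protein, optional evidence."""

    id: str
    protein_seq: str
    transcript_seq: Optional[str] = None
    has_signal: Optional[bool] = None  # three-valued: True/False/unknown
    best_hit: Optional[BestHit] = None

    @property
    def length_aa(self) -> int:
        return len(self.protein_seq)

    @property
    def mw_da(self) -> float:
        return molecular_weight(self.protein_seq)


def read_fasta(path: str | Path) -> list[GeneCluster]:
    """Read a protein FASTA into GeneClusters; ids are headers up to whitespace.

    Raises ``ValueError`` naming the offending id on duplicates.
    An empty file yields an empty list.
    """
    clusters: list[GeneCluster] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id in {path}: {rec.id!r}")
        seen.add(rec.id)
        clusters.append(GeneCluster(id=rec.id, protein_seq=str(rec.seq).upper()))
    return clusters


def write_fasta(clusters: Iterable[GeneCluster], path: str | Path,
                transcripts: bool = False) -> None:
    """Write clusters as FASTA (protein by default, transcripts on request)."""
    records = []
    for c in clusters:
        seq = c.transcript_seq if transcripts else c.protein_seq
        if seq is None:
            raise ValueError(f"cluster {c.id} has no transcript sequence")
        records.append(SeqRecord(Seq(seq), id=c.id, description=""))
    SeqIO.write(records, str(path), "fasta")


class OrfHit(NamedTuple):
    protein: str
    frame: int   # +1,+2,+3 forward; -1,-2,-3 reverse-complement offsets
    start: int   # 1-based inclusive, forward strand
    end: int     # includes the terminating stop codon when one exists


_VALID_NT = re.compile(r"^[ACGTN]*$")


def _translate_codon(codon: str) -> str:
    if codon in _STOP_CODONS:
        return "*"
    return _STANDARD_TABLE.forward_table.get(codon, "X")


def _frame_orfs(seq: str, offset: int) -> list[tuple[str, int, int]]:
    """Stop-free maximal ORFs in one forward frame.

    Returns (protein, start_nt, end_nt) with 0-based [start, end) coordinates
    on ``seq``; ``end`` covers the stop codon when the ORF is stop-terminated.
    """
    n_codons = (len(seq) - offset) // 3
    codons = [seq[offset + 3 * k: offset + 3 * k + 3] for k in range(n_codons)]
    orfs = []
    run_start = 0
    for k in range(n_codons + 1):
        at_stop = k < n_codons and codons[k] in _STOP_CODONS
        if at_stop or k == n_codons:
            if k > run_start:
                protein = "".join(_translate_codon(c) for c in codons[run_start:k])
                end_codon = k + 1 if at_stop else k  # include the stop codon
                orfs.append((protein,
                             offset + 3 * run_start,
                             offset + 3 * end_codon))
            run_start = k + 1
    return orfs


def extract_orfs(transcript: str, min_len_aa: int = MIN_ORF_AA,
                 require_met: bool = False) -> list[OrfHit]:
    """Six-frame ORF extraction.

    An ORF is a maximal stop-free stretch of codons in one of the six reading
    frames, translated with the standard genetic code, kept iff its translated
    length is >= ``min_len_aa``.  With ``require_met=False`` (the default)
    edge-truncated ORFs lacking an initial methionine are reported too — a
    transcript assembled a few nucleotides short of the true start would
    otherwise lose its protein.  Coordinates are 1-based inclusive on the
    forward strand and cover the terminating stop codon when present; frames
    are +1/+2/+3 (forward offsets) and -1/-2/-3 (reverse-complement offsets).
    """
    seq = transcript.upper()
    if not _VALID_NT.match(seq):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ValueError(f"invalid nucleotide character(s): {bad}")
    length = len(seq)
    rc = str(Seq(seq).reverse_complement())
    results: list[OrfHit] = []
    for strand, s in ((1, seq), (-1, rc)):
        for offset in range(3):
            for protein, start0, end0 in _frame_orfs(s, offset):
                if require_met:
                    m = protein.find("M")
                    if m < 0:
                        continue
                    protein = protein[m:]
                    start0 += 3 * m
                if len(protein) < min_len_aa:
                    continue
                if strand == 1:
                    start, end = start0 + 1, end0
                else:
                    start, end = length - end0 + 1, length - start0
                results.append(OrfHit(protein, strand * (offset + 1), start, end))
    return results


def molecular_weight(protein: str) -> float:
    """Average molecular weight in daltons: residue masses plus one water."""
    if not protein:
        raise ValueError("cannot compute molecular weight of an empty sequence")
    try:
        total = sum(AVERAGE_RESIDUE_MASS[r] for r in protein.upper())
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return total + WATER_MASS


@dataclass
class SizeBinReport:
    """Counts and percentages in the coarse kDa bins used for venom profiles.

    Bins: <10 kDa, [10, 50) kDa, >=50 kDa; clusters under 7 kDa (roughly the
    ~70 aa cut-off that stricter ORF thresholds would discard) are flagged
    separately as a subset of the first bin.
    """

    counts: dict[str, int] = field(default_factory=dict)
    percentages: dict[str, float] = field(default_factory=dict)
    under_7kda: int = 0
    total: int = 0


SIZE_BINS = (("<10 kDa", 0.0, 10_000.0),
             ("10-49 kDa", 10_000.0, 50_000.0),
             (">=50 kDa", 50_000.0, float("inf")))


def size_bin_report(clusters: Iterable[GeneCluster]) -> SizeBinReport:
    clusters = list(clusters)
    if not clusters:
        raise ValueError("size_bin_report requires at least one cluster")
    counts = {name: 0 for name, _, _ in SIZE_BINS}
    under7 = 0
    for c in clusters:
        mw = c.mw_da
        for name, lo, hi in SIZE_BINS:
            if lo <= mw < hi:  # closed left edge: 10.000 kDa is mid-bin
                counts[name] += 1
                break
        if mw < 7_000.0:
            under7 += 1
    total = len(clusters)
    pct = {name: round_half_up(100.0 * n / total, 1) for name, n in counts.items()}
    return SizeBinReport(counts=counts, percentages=pct,
                         under_7kda=under7, total=total)


def read_signal_table(path: str | Path) -> dict[str, bool]:
    """Read a TSV of signal-peptide calls: columns ``id``, ``signal_call``.

    Accepted call values: SP/OTHER (SignalP style) or true/false variants.
    Ids absent from the table stay unknown downstream (three-valued logic).
    """
    truthy = {"SP", "TRUE", "T", "1", "YES", "Y"}
    falsy = {"OTHER", "FALSE", "F", "0", "NO", "N"}
    out: dict[str, bool] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            cid, call = parts[0].strip(), parts[1].strip().upper()
            if cid.lower() == "id" and lineno == 1:
                continue  # optional header
            if call in truthy:
                out[cid] = True
            elif call in falsy:
                out[cid] = False
            else:
                raise ValueError(f"{path}:{lineno}: unparseable signal call {parts[1]!r}")
    return out


def write_signal_table(signal: dict[str, bool], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tsignal_call\n")
        for cid, val in signal.items():
            fh.write(f"{cid}\t{'SP' if val else 'OTHER'}\n")


def read_best_hits(path: str | Path) -> dict[str, BestHit]:
    """Read 12-column blast-tab (m8) rows, keeping one best hit per query.

    Best = smallest E-value; ties broken by highest bit score, then first
    occurrence in the file.  Used only for annotated/unique-hit tallies.
    """
    best: dict[str, BestHit] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}")
            query, subject = parts[0], parts[1]
            hit = BestHit(subject=subject, identity=float(parts[2]),
                          evalue=float(parts[10]), bitscore=float(parts[11]))
            cur = best.get(query)
            if cur is None or (hit.evalue, -hit.bitscore) < (cur.evalue, -cur.bitscore):
                best[query] = hit
    return best
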