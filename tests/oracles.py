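"""Independent brute-force oracles used to cross-check the implementation.

Each oracle is deliberately written in the most direct style possible
(string slicing, exhaustive enumeration, plain loops) and shares no code
with the package modules it checks.
"""

from __future__ import annotations

import math
import statistics
from itertools import combinations

# Standard genetic code, written as the classic TCAG-ordered string.
_BASES = "TCAG"
_AA_STRING = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRR"
              "IIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
CODON_TABLE = {
    b1 + b2 + b3: _AA_STRING[16 * i + 4 * j + k]
    for i, b1 in enumerate(_BASES)
    for j, b2 in enumerate(_BASES)
    for k, b3 in enumerate(_BASES)
}
_COMP = {"A": "T", "T": "A", "G": "C", "C": "G", "N": "N"}


def orf_oracle(seq: str, min_len_aa: int, require_met: bool = False):
    """Six-frame ORF enumeration by direct slicing and codon lookup.

    Returns a set of (protein, frame, start, end) tuples with the same
    coordinate conventions as the implementation: 1-based inclusive forward
    strand, terminating stop codon included in the span.
    """
    out = set()
    length = len(seq)
    rc = "".join(_COMP[c] for c in reversed(seq))
    for strand, s in ((1, seq), (-1, rc)):
        for off in range(3):
            n_codons = (len(s) - off) // 3
            codons = [s[off + 3 * k: off + 3 * k + 3] for k in range(n_codons)]
            aas = ["*" if CODON_TABLE.get(c) == "*"
                   else (CODON_TABLE[c] if "N" not in c else "X")
                   for c in codons]
            k = 0
            while k < len(aas):
                if aas[k] == "*":
                    k += 1
                    continue
                j = k
                while j < len(aas) and aas[j] != "*":
                    j += 1
                protein = "".join(aas[k:j])
                stop_terminated = j < len(aas)
                first, last = k, (j + 1 if stop_terminated else j)
                if require_met:
                    m = protein.find("M")
                    if m < 0:
                        k = j + 1
                        continue
                    protein = protein[m:]
                    first = k + m
                if len(protein) >= min_len_aa:
                    s0 = off + 3 * first          # 0-based inclusive
                    e0 = off + 3 * last           # 0-based exclusive
                    if strand == 1:
                        start, end = s0 + 1, e0
                    else:
                        start, end = length - e0 + 1, length - s0
                    out.add((protein, strand * (off + 1), start, end))
                k = j + 1
    return out


def scaffold_oracle(seq: str, n_cys: int, gap_ranges):
    """Exhaustive cysteine-subset enumeration.

    For every start cysteine, the lexicographically smallest gap-consistent
    chain of ``n_cys`` cysteines; returns sorted (start, end) spans, 1-based.
    """
    cys = [i for i, r in enumerate(seq) if r == "C"]
    best: dict[int, tuple] = {}
    for comb in combinations(cys, n_cys):
        ok = all(lo <= comb[k + 1] - comb[k] - 1 <= hi
                 for k, (lo, hi) in enumerate(gap_ranges))
        if ok and (comb[0] not in best or comb < best[comb[0]]):
            best[comb[0]] = comb
    return sorted((c[0] + 1, c[-1] + 1) for c in best.values())


def size_factor_oracle(table: dict[str, list[float]]):
    """Median-of-ratios by direct loops: table maps cluster -> counts row."""
    included = {cid: row for cid, row in table.items()
                if all(v > 0 for v in row)}
    if not included:
        raise ValueError("no all-positive cluster")
    gmeans = {cid: math.prod(row) ** (1.0 / len(row))
              for cid, row in included.items()}
    n_samples = len(next(iter(table.values())))
    return [statistics.median(row[j] / gmeans[cid]
                              for cid, row in included.items())
            for j in range(n_samples)]


def best_hit_oracle(rows):
    """Per-query minimum by sorting: rows are (query, subject, evalue, bits)."""
    out = {}
    for query in {r[0] for r in rows}:
        sub = [r for r in rows if r[0] == query]
        sub.sort(key=lambda r: (r[2], -r[3]))
        out[query] = sub[0]
    return out
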