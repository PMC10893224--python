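"""Domain-evidence layer for the toxin rule engine.

Three evidence sources feed the classifier, all normalised into
:class:`DomainHit` records:

* HMMER3 ``domtblout`` files (profile HMM searches run externally, e.g. with
  ``hmmsearch`` or pyhmmer) — parsed, never recomputed here;
* PROSITE-syntax sequence patterns, matched by a matcher implementing the
  ScanProsite grammar (dash-separated elements, ``x`` wildcards, ``[..]``
  alternatives, ``{..}`` exclusions, ``(n)``/``(n,m)`` repetitions and
  ``<``/``>`` terminal anchors);
* cysteine-scaffold descriptors — a cysteine count plus inter-cysteine
  spacing ranges, the field's shorthand for disulfide-rich peptide families
  whose conservation lives in the cysteine skeleton rather than in sequence.

Hits from HMMER carry the per-domain independent E-value and are subject to
the significance gate (E <= 1e-5, inclusive).  Pattern and scaffold hits are
exact descriptor matches without an E-value theory; they carry E-value 0 and
therefore always pass the gate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

DEFAULT_MAX_EVALUE = 1e-5


@dataclass(frozen=True)
class DomainHit:
    """One significant model-vs-sequence match.

    ``ali_start``/``ali_end`` are 1-based inclusive protein coordinates.
    """

    cluster_id: str
    model: str
    ali_start: int
    ali_end: int
    evalue: float
    score: float = 0.0
    source: str = "hmmer"  # hmmer | prosite | scaffold

    def __post_init__(self):
        if not (1 <= self.ali_start <= self.ali_end):
            raise ValueError(
                f"invalid alignment span {self.ali_start}..{self.ali_end}")
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass(frozen=True)
class SignificanceGate:
    max_evalue: float = DEFAULT_MAX_EVALUE

    def __post_init__(self):
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")


def filter_significant(hits: Iterable[DomainHit],
                       gate: SignificanceGate = SignificanceGate()) -> list[DomainHit]:
    """Keep hits with E-value <= the cut-off (inclusive); order-preserving."""
    return [h for h in hits if h.evalue <= gate.max_evalue]


# --------------------------------------------------------------------------
# HMMER3 domtblout
# --------------------------------------------------------------------------

# Column layout of HMMER3's per-domain table (hmmsearch --domtblout): the
# sequence is the target (col 0), the profile is the query (col 3); the
# per-domain independent E-value is col 12, the domain bit score col 13 and
# the alignment coordinates cols 17-18.  22 data columns precede the
# free-text description.
_DOMTBLOUT_MIN_COLS = 23


def read_domtblout(path: str | Path) -> list[DomainHit]:
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            cols = line.split()
            if len(cols) < _DOMTBLOUT_MIN_COLS:
                raise ValueError(
                    f"{path}:{lineno}: domtblout row has {len(cols)} columns, "
                    f"expected >= {_DOMTBLOUT_MIN_COLS}")
            hits.append(DomainHit(
                cluster_id=cols[0],
                model=cols[3],
                ali_start=int(cols[17]),
                ali_end=int(cols[18]),
                evalue=float(cols[12]),
                score=float(cols[13]),
                source="hmmer",
            ))
    return hits


def write_domtblout(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits in the HMMER3 domtblout dialect (fixture/interop writer).

    Lengths and envelope coordinates not tracked by :class:`DomainHit` are
    written as the alignment span; full-sequence statistics repeat the
    per-domain ones.  ``read_domtblout`` recovers every field it parses.
    """
    with open(path, "w") as fh:
        fh.write("# target name        accession   tlen query name           "
                 "accession   qlen   E-value  score  bias   #  of  c-Evalue  "
                 "i-Evalue  score  bias  from    to  from    to  from    to  "
                 "acc description of target\n#\n")
        for h in hits:
            fh.write(
                f"{h.cluster_id} - {h.ali_end} {h.model} - "
                f"{h.ali_end - h.ali_start + 1} {h.evalue:.2g} {h.score:.1f} 0.0 "
                f"1 1 {h.evalue:.2g} {h.evalue:.2g} {h.score:.1f} 0.0 "
                f"1 {h.ali_end - h.ali_start + 1} {h.ali_start} {h.ali_end} "
                f"{h.ali_start} {h.ali_end} 0.90 -\n")


# --------------------------------------------------------------------------
# PROSITE patterns
# --------------------------------------------------------------------------

class PatternSyntaxError(ValueError):
    pass


@dataclass(frozen=True)
class PatternDef:
    name: str
    prosite_expr: str


_AA = "ACDEFGHIKLMNPQRSTVWY"
_ELEMENT_RE = re.compile(
    r"^(?P<base>[A-Za-z]|\[[A-Z]+\]|\{[A-Z]+\})"
    r"(?:\((?P<n>\d+)(?:,(?P<m>\d+))?\))?$")


@dataclass
class _Element:
    kind: str          # literal | any | class | negclass
    residues: str      # member letters for class/negclass, the letter for literal
    min_rep: int
    max_rep: int

    def to_regex(self) -> str:
        if self.kind == "any":
            core = "."
        elif self.kind == "literal":
            core = self.residues
        elif self.kind == "class":
            core = f"[{self.residues}]"
        else:
            core = f"[^{self.residues}]"
        if (self.min_rep, self.max_rep) == (1, 1):
            return core
        if self.min_rep == self.max_rep:
            return f"{core}{{{self.min_rep}}}"
        return f"{core}{{{self.min_rep},{self.max_rep}}}"

    def sample(self, rng, alphabet_weights=None) -> str:
        """Draw one concrete instance (used by the synthetic generator)."""
        n = int(rng.integers(self.min_rep, self.max_rep + 1))
        if self.kind == "literal":
            return self.residues * n
        if self.kind == "any":
            pool = _AA
        elif self.kind == "class":
            pool = self.residues
        else:
            pool = "".join(a for a in _AA if a not in self.residues)
        return "".join(pool[int(rng.integers(len(pool)))] for _ in range(n))


@dataclass
class CompiledPattern:
    """A PROSITE pattern compiled to an equivalent regular expression."""

    name: str
    expr: str
    elements: list[_Element]
    anchored_start: bool
    anchored_end: bool
    regex: re.Pattern = field(repr=False, default=None)

    def sample(self, rng) -> str:
        return "".join(e.sample(rng) for e in self.elements)


def compile_pattern(pattern: PatternDef) -> CompiledPattern:
    """Compile a PROSITE expression; raises PatternSyntaxError naming the token."""
    expr = pattern.prosite_expr.strip().rstrip(".")
    if not expr:
        raise PatternSyntaxError(f"{pattern.name}: empty pattern")
    anchored_start = expr.startswith("<")
    if anchored_start:
        expr = expr[1:]
    anchored_end = expr.endswith(">")
    if anchored_end:
        expr = expr[:-1].rstrip("-")
    elements: list[_Element] = []
    for token in expr.split("-"):
        token = token.strip()
        if not token:
            raise PatternSyntaxError(f"{pattern.name}: empty element in {expr!r}")
        m = _ELEMENT_RE.match(token)
        if not m:
            raise PatternSyntaxError(f"{pattern.name}: bad element {token!r}")
        base = m.group("base")
        n = int(m.group("n")) if m.group("n") else 1
        mm = int(m.group("m")) if m.group("m") else n
        if mm < n or n < 0:
            raise PatternSyntaxError(f"{pattern.name}: bad repetition in {token!r}")
        if base in ("x", "X"):
            el = _Element("any", "", n, mm)
        elif len(base) == 1:
            if base.upper() not in _AA:
                raise PatternSyntaxError(f"{pattern.name}: unknown residue {base!r}")
            el = _Element("literal", base.upper(), n, mm)
        elif base.startswith("["):
            members = base[1:-1]
            if not members or any(c not in _AA for c in members):
                raise PatternSyntaxError(f"{pattern.name}: bad class {base!r}")
            el = _Element("class", members, n, mm)
        else:
            members = base[1:-1]
            if not members or any(c not in _AA for c in members):
                raise PatternSyntaxError(f"{pattern.name}: bad exclusion {base!r}")
            el = _Element("negclass", members, n, mm)
        elements.append(el)
    body = "".join(e.to_regex() for e in elements)
    rx = ("^" if anchored_start else "") + body + ("$" if anchored_end else "")
    return CompiledPattern(name=pattern.name, expr=pattern.prosite_expr,
                           elements=elements, anchored_start=anchored_start,
                           anchored_end=anchored_end, regex=re.compile(rx))


def scan_pattern(matcher: CompiledPattern, cluster, *,
                 overlapping: bool = False) -> list[DomainHit]:
    """All pattern matches in a cluster's protein, leftmost non-overlapping.

    With ``overlapping=True`` every start position is tried (lookahead scan).
    Pattern hits carry E-value 0: they are exact descriptor matches and always
    pass the significance gate.
    """
    seq = cluster.protein_seq if hasattr(cluster, "protein_seq") else str(cluster)
    cid = cluster.id if hasattr(cluster, "id") else "?"
    hits = []
    if overlapping and not (matcher.anchored_start or matcher.anchored_end):
        look = re.compile(f"(?=({matcher.regex.pattern}))")
        spans = [(m.start(1), m.start(1) + len(m.group(1)))
                 for m in look.finditer(seq)]
    else:
        spans = [m.span() for m in matcher.regex.finditer(seq)]
    for s, e in spans:
        if e == s:
            continue
        hits.append(DomainHit(cluster_id=cid, model=matcher.name,
                              ali_start=s + 1, ali_end=e, evalue=0.0,
                              source="prosite"))
    return hits


# --------------------------------------------------------------------------
# Cysteine scaffolds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldDef:
    """A disulfide-rich peptide descriptor: n cysteines with spacing ranges.

    ``gap_ranges[i]`` bounds the number of residues strictly between
    cysteine i and cysteine i+1 of the scaffold chain.
    ``flank_slack`` extends the reported span on both sides (clipped to the
    sequence) so downstream positional reasoning sees a domain-like window.
    """

    name: str
    n_cys: int
    gap_ranges: tuple[tuple[int, int], ...]
    flank_slack: int = 0

    def __post_init__(self):
        if self.n_cys < 2:
            raise ValueError("a cysteine scaffold needs at least 2 cysteines")
        if len(self.gap_ranges) != self.n_cys - 1:
            raise ValueError(
                f"{self.name}: expected {self.n_cys - 1} gap ranges, "
                f"got {len(self.gap_ranges)}")
        for lo, hi in self.gap_ranges:
            if lo < 0 or hi < lo:
                raise ValueError(f"{self.name}: bad gap range ({lo},{hi})")


def _chain_from(start_idx: int, cys_pos: Sequence[int],
                gap_ranges: Sequence[tuple[int, int]]) -> Optional[list[int]]:
    """First (lexicographically smallest) cysteine chain from one start.

    Depth-first over later cysteines, earliest candidate first, with
    backtracking — a hit exists iff *some* chain satisfies every gap range,
    which keeps hit existence monotone under gap widening.
    """
    chain = [cys_pos[start_idx]]

    def extend(idx: int, depth: int) -> bool:
        if depth == len(gap_ranges):
            return True
        lo, hi = gap_ranges[depth]
        prev = chain[-1]
        for j in range(idx + 1, len(cys_pos)):
            gap = cys_pos[j] - prev - 1
            if gap > hi:
                break
            if gap >= lo:
                chain.append(cys_pos[j])
                if extend(j, depth + 1):
                    return True
                chain.pop()
        return False

    return chain if extend(start_idx, 0) else None


def scan_scaffold(sdef: ScaffoldDef, cluster) -> list[DomainHit]:
    """One hit per cysteine that can start a gap-consistent chain.

    The span runs from the first to the last cysteine of the chain (extended
    by ``flank_slack``); overlapping hits from distinct starts are reported.
    """
    seq = cluster.protein_seq if hasattr(cluster, "protein_seq") else str(cluster)
    cid = cluster.id if hasattr(cluster, "id") else "?"
    cys_pos = [i for i, r in enumerate(seq) if r == "C"]
    hits = []
    for i in range(len(cys_pos)):
        chain = _chain_from(i, cys_pos, sdef.gap_ranges)
        if chain is None:
            continue
        start = max(0, chain[0] - sdef.flank_slack)
        end = min(len(seq) - 1, chain[-1] + sdef.flank_slack)
        hits.append(DomainHit(cluster_id=cid, model=sdef.name,
                              ali_start=start + 1, ali_end=end + 1,
                              evalue=0.0, source="scaffold"))
    return hits


# --------------------------------------------------------------------------
# Model definition file
# --------------------------------------------------------------------------

@dataclass
class ModelDef:
    """One named domain model: an HMM name, a PROSITE pattern or a scaffold."""

    name: str
    kind: str                       # hmm | prosite | scaffold
    matcher: object = None          # CompiledPattern | ScaffoldDef | None
    family_link: str = ""

    def scan(self, cluster) -> list[DomainHit]:
        if self.kind == "prosite":
            return scan_pattern(self.matcher, cluster)
        if self.kind == "scaffold":
            return scan_scaffold(self.matcher, cluster)
        return []  # hmm models are matched externally (domtblout)


def parse_scaffold_spec(name: str, spec: str) -> ScaffoldDef:
    """Parse ``ncys=6;gaps=1-3,8-10,...;flank=2`` into a ScaffoldDef."""
    fields = dict(part.split("=", 1) for part in spec.split(";") if part)
    try:
        n_cys = int(fields["ncys"])
        gaps = tuple(
            (int(g.split("-")[0]), int(g.split("-")[1])) if "-" in g
            else (int(g), int(g))
            for g in fields["gaps"].split(","))
    except (KeyError, ValueError, IndexError) as exc:
        raise ValueError(f"{name}: bad scaffold spec {spec!r}") from exc
    flank = int(fields.get("flank", 0))
    return ScaffoldDef(name=name, n_cys=n_cys, gap_ranges=gaps, flank_slack=flank)


def load_models(path: str | Path) -> dict[str, ModelDef]:
    """Read the model definition TSV: columns name, type, spec, family."""
    models: dict[str, ModelDef] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "name" and parts[1:2] == ["type"]:
                continue
            if len(parts) < 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns")
            name, kind, spec, family = (p.strip() for p in parts[:4])
            if name in models:
                raise ValueError(f"{path}:{lineno}: duplicate model {name!r}")
            if kind == "prosite":
                matcher = compile_pattern(PatternDef(name, spec))
            elif kind == "scaffold":
                matcher = parse_scaffold_spec(name, spec)
            elif kind == "hmm":
                matcher = None
            else:
                raise ValueError(f"{path}:{lineno}: unknown model type {kind!r}")
            models[name] = ModelDef(name=name, kind=kind, matcher=matcher,
                                    family_link=family)
    return models


def scan_all(models: dict[str, ModelDef], clusters) -> dict[str, list[DomainHit]]:
    """Scan every pattern/scaffold model over every cluster."""
    by_cluster: dict[str, list[DomainHit]] = {}
    for c in clusters:
        hits: list[DomainHit] = []
        for model in models.values():
            hits.extend(model.scan(c))
        if hits:
            by_cluster[c.id] = hits
    return by_cluster
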