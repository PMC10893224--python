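"""Rule-based toxin-family classification.

Each gene cluster is classified from its significant domain hits by an
ordered list of family rules.  A rule names the toxin protein family, its
venom function category, the domain models that must (and must not) be
present, and optional order/adjacency constraints between required models.
Rules fire in priority order — enzyme and multi-domain structured families
first, single-short-domain families next, cysteine-scaffold families after,
so that, for example, a large multi-domain protein that merely contains a
ShK-like domain is not mislabelled as a short ShK-like neurotoxin.

Clusters whose hits mix category-defining domains from two or more distinct
venom categories without satisfying any single rule are real toxin-like
sequences that cannot be placed: they become ``Uncharacterised toxins`` in
the ``Unknown`` category, flagged ``multi_category``.  A missing signal
peptide never blocks assignment — transcript assemblies frequently truncate
the true N-terminus — it only sets the ``no_signal_peptide`` flag.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional
import warnings

from .domains import DomainHit, ModelDef, compile_pattern, PatternDef
from .seqio import GeneCluster

VENOM_CATEGORIES = (
    "Allergen and innate immunity",
    "Auxiliary",
    "Haemostatic and haemorrhagic",
    "Mixed function enzymes",
    "Neurotoxins",
    "Pore forming",
    "Protease inhibitors",
    "Unknown",
)

UNCHARACTERISED = "Uncharacterised toxins"
CROSS_CATEGORY_TOKEN = "@cross"  # forbidden-list shorthand: any model defining another category


@dataclass(frozen=True)
class FamilyRule:
    family: str
    category: str
    priority: int
    required: tuple[tuple[str, int], ...]          # (model, min_count)
    forbidden: tuple[str, ...] = ()
    positional: tuple[tuple[str, str, str], ...] = ()  # (op, model_a, model_b); op: before|adjacent

    def __post_init__(self):
        if not self.required:
            raise ValueError(f"rule {self.family!r} has no required models")
        if self.category not in VENOM_CATEGORIES:
            raise ValueError(f"rule {self.family!r}: unknown category {self.category!r}")


@dataclass
class ToxinAssignment:
    cluster_id: str
    family: str
    category: str
    evidence: list[DomainHit]
    architecture: str
    flags: set[str] = field(default_factory=set)


class RuleSet:
    """Ordered family rules plus the derived category-defining model map.

    A model is *category-defining* when it is required by rules of exactly
    one non-Unknown category; models claimed by several categories, and all
    models of Unknown-category families, are treated as non-defining.
    """

    def __init__(self, rules: Iterable[FamilyRule]):
        rules = sorted(rules, key=lambda r: r.priority)
        if not rules:
            raise ValueError("a classifier with no rules is invalid")
        prios = [r.priority for r in rules]
        if len(set(prios)) != len(prios):
            dup = [p for p, n in Counter(prios).items() if n > 1]
            raise ValueError(f"duplicate rule priorities: {dup}")
        fams = [r.family for r in rules]
        if len(set(fams)) != len(fams):
            dup = [f for f, n in Counter(fams).items() if n > 1]
            raise ValueError(f"duplicate family names: {dup}")
        self.rules: list[FamilyRule] = rules
        claimed: dict[str, set[str]] = defaultdict(set)
        for r in rules:
            if r.category != "Unknown":
                for model, _ in r.required:
                    claimed[model].add(r.category)
        self.category_defining: dict[str, str] = {
            m: next(iter(cats)) for m, cats in claimed.items() if len(cats) == 1}

    @property
    def families(self) -> list[str]:
        return [r.family for r in self.rules]

    @property
    def categories(self) -> set[str]:
        return {r.category for r in self.rules}

    def category_of(self, family: str) -> str:
        if family == UNCHARACTERISED:
            return "Unknown"
        for r in self.rules:
            if r.family == family:
                return r.category
        raise KeyError(family)


def _parse_required(text: str) -> tuple[tuple[str, int], ...]:
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part:
            continue
        if ":" in part:
            model, count = part.rsplit(":", 1)
            out.append((model.strip(), int(count)))
        else:
            out.append((part, 1))
    return tuple(out)


def _parse_positional(text: str) -> tuple[tuple[str, str, str], ...]:
    out = []
    for part in text.split(";"):
        part = part.strip()
        if not part or part == "-":
            continue
        if "<" in part:
            a, b = part.split("<", 1)
            out.append(("before", a.strip(), b.strip()))
        elif "+" in part:
            a, b = part.split("+", 1)
            out.append(("adjacent", a.strip(), b.strip()))
        else:
            raise ValueError(f"bad positional constraint {part!r}")
    return tuple(out)


def load_rules(path: str | Path, models: Mapping[str, ModelDef]) -> RuleSet:
    """Load the rule TSV (family, category, priority, required, forbidden,
    positional) and validate model references against the definition file."""
    rules: list[FamilyRule] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "family" and parts[1:2] == ["category"]:
                continue
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns")
            family, category, priority, required, forbidden, positional = (
                p.strip() for p in parts[:6])
            req = _parse_required(required)
            forb = tuple(f.strip() for f in forbidden.split(";")
                         if f.strip() and f.strip() != "-")
            pos = _parse_positional(positional)
            for model, _ in req:
                if model not in models:
                    raise ValueError(
                        f"{path}:{lineno}: rule {family!r} references "
                        f"unknown model {model!r}")
            for model in forb:
                if model != CROSS_CATEGORY_TOKEN and model not in models:
                    raise ValueError(
                        f"{path}:{lineno}: rule {family!r} references "
                        f"unknown forbidden model {model!r}")
            for _, a, b in pos:
                for model in (a, b):
                    if model not in models:
                        raise ValueError(
                            f"{path}:{lineno}: rule {family!r} positional "
                            f"constraint references unknown model {model!r}")
            rules.append(FamilyRule(
                family=family, category=category, priority=int(priority),
                required=req, forbidden=forb, positional=pos))
    return RuleSet(rules)


def architecture_string(hits: Iterable[DomainHit]) -> str:
    """Canonical domain architecture: models in positional order, consecutive
    repeats collapsed to ``ModelxN`` (N omitted when 1)."""
    ordered = sorted(hits, key=lambda h: (h.ali_start, h.ali_end))
    parts: list[tuple[str, int]] = []
    for h in ordered:
        if parts and parts[-1][0] == h.model:
            parts[-1] = (h.model, parts[-1][1] + 1)
        else:
            parts.append((h.model, 1))
    return "+".join(m if n == 1 else f"{m}x{n}" for m, n in parts)


def _rule_matches(rule: FamilyRule, hits: list[DomainHit],
                  ruleset: RuleSet) -> bool:
    counts = Counter(h.model for h in hits)
    for model, min_count in rule.required:
        if counts[model] < min_count:
            return False
    present = set(counts)
    for forb in rule.forbidden:
        if forb == CROSS_CATEGORY_TOKEN:
            for m in present:
                cat = ruleset.category_defining.get(m)
                if cat is not None and cat != rule.category:
                    return False
        elif forb in present:
            return False
    if rule.positional:
        req_models = {m for m, _ in rule.required}
        ordered = [h.model for h in sorted(hits, key=lambda h: h.ali_start)
                   if h.model in req_models]
        for op, a, b in rule.positional:
            if a not in ordered or b not in ordered:
                return False
            if op == "before":
                if ordered.index(a) > ordered.index(b):
                    return False
            else:  # adjacent: an a immediately followed by a b
                if not any(x == a and y == b for x, y in zip(ordered, ordered[1:])):
                    return False
    return True


def _signal_flag(cluster: GeneCluster, flags: set[str]) -> None:
    # Three-valued: only a positive signal-peptide call clears the flag.
    if cluster.has_signal is not True:
        flags.add("no_signal_peptide")


def assign_cluster(cluster: GeneCluster, hits: list[DomainHit],
                   ruleset: RuleSet) -> Optional[ToxinAssignment]:
    """Classify one cluster from its significant hits.

    Returns ``None`` for clusters without toxin-associated evidence (or whose
    evidence satisfies no rule and spans fewer than two venom categories).
    """
    if not hits:
        return None
    for rule in ruleset.rules:
        if _rule_matches(rule, hits, ruleset):
            flags: set[str] = set()
            _signal_flag(cluster, flags)
            req_models = {m for m, _ in rule.required}
            req_hits = [h for h in hits if h.model in req_models]
            sources = {h.source for h in req_hits}
            if "prosite" in sources and "hmmer" not in sources:
                flags.add("rescued")
            return ToxinAssignment(
                cluster_id=cluster.id, family=rule.family,
                category=rule.category, evidence=list(hits),
                architecture=architecture_string(hits), flags=flags)
    cats = {ruleset.category_defining[h.model] for h in hits
            if h.model in ruleset.category_defining}
    if len(cats) >= 2:
        flags = {"multi_category"}
        _signal_flag(cluster, flags)
        return ToxinAssignment(
            cluster_id=cluster.id, family=UNCHARACTERISED, category="Unknown",
            evidence=list(hits), architecture=architecture_string(hits),
            flags=flags)
    return None


def check_catalytic_residues(cluster: GeneCluster, hit: DomainHit,
                             residue_spec: Iterable[tuple[str, str]]) -> bool:
    """Annotational check that catalytic residues sit inside a domain hit.

    ``residue_spec`` is a list of (residue letter, PROSITE anchor pattern);
    the check passes iff every anchor matches within the hit span and its
    match contains the residue.  An anchor found only outside the span warns
    and returns False; an empty spec is vacuously True.
    """
    span = cluster.protein_seq[hit.ali_start - 1: hit.ali_end]
    for residue, anchor_expr in residue_spec:
        matcher = compile_pattern(PatternDef(f"anchor:{residue}", anchor_expr))
        m = matcher.regex.search(span)
        if m is None or residue not in m.group(0):
            if matcher.regex.search(cluster.protein_seq):
                warnings.warn(
                    f"{cluster.id}: anchor for {residue!r} matches outside "
                    f"the {hit.model} hit span", stacklevel=2)
            return False
    return True


@dataclass
class AssignmentSummary:
    n_clusters: int
    n_toxin_clusters: int
    clusters_per_category: dict[str, int]
    families_per_category: dict[str, int]
    toxin_with_signal: int


def assign_all(clusters: Iterable[GeneCluster],
               hits_by_cluster: Mapping[str, list[DomainHit]],
               ruleset: RuleSet,
               signal_map: Optional[Mapping[str, bool]] = None,
               ) -> tuple[list[ToxinAssignment], AssignmentSummary]:
    """Classify a whole cluster collection; deterministic in input order."""
    clusters = list(clusters)
    ids = {c.id for c in clusters}
    for cid in hits_by_cluster:
        if cid not in ids:
            raise ValueError(f"hit references cluster {cid!r} absent from FASTA")
    assignments: list[ToxinAssignment] = []
    cat_clusters: Counter = Counter()
    cat_families: dict[str, set[str]] = defaultdict(set)
    with_signal = 0
    for c in clusters:
        if signal_map is not None and c.id in signal_map:
            c.has_signal = signal_map[c.id]
        a = assign_cluster(c, hits_by_cluster.get(c.id, []), ruleset)
        if a is None:
            continue
        assignments.append(a)
        cat_clusters[a.category] += 1
        cat_families[a.category].add(a.family)
        if c.has_signal is True:  # unknown counts as absent in tallies
            with_signal += 1
    summary = AssignmentSummary(
        n_clusters=len(clusters),
        n_toxin_clusters=len(assignments),
        clusters_per_category=dict(cat_clusters),
        families_per_category={k: len(v) for k, v in cat_families.items()},
        toxin_with_signal=with_signal,
    )
    return assignments, summary


def write_assignments(assignments: Iterable[ToxinAssignment],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tfamily\tcategory\tarchitecture\tflags\tmodels\n")
        for a in assignments:
            models = ";".join(sorted({h.model for h in a.evidence}))
            fh.write(f"{a.cluster_id}\t{a.family}\t{a.category}\t"
                     f"{a.architecture}\t{','.join(sorted(a.flags))}\t{models}\n")


def read_assignments(path: str | Path) -> list[ToxinAssignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("cluster_id\t"):
            raise ValueError(f"{path}: not an assignments table")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            cid, family, category, architecture, flags = parts[:5]
            out.append(ToxinAssignment(
                cluster_id=cid, family=family, category=category,
                evidence=[], architecture=architecture,
                flags=set(f for f in flags.split(",") if f)))
    return out
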