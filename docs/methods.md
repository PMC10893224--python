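# Methods

## Scope and units

The pipeline operates on *gene clusters* — Corset-style groupings of
assembled transcripts treated as one putative gene, each represented by a
translated protein sequence. It starts downstream of assembly, clustering
and database search: HMMER searches, SignalP calls and UniRef90 best hits
are consumed as files, never recomputed. Mass-spectrometry processing is
likewise out of scope; the DIA protein abundance matrix is used as
delivered (it is already normalised by the acquisition software and is not
re-normalised here).

## Domain evidence

Three evidence sources are normalised into a single `DomainHit` record
(cluster, model, 1-based alignment span, E-value, source):

* **HMMER3 domtblout.** The per-domain *independent* E-value (column 13) is
  parsed and gated, not the full-sequence E-value: the rule engine reasons
  about individual domain hits, so each hit must be individually
  significant. The gate is E ≤ 1 × 10⁻⁵, inclusive at the boundary. Column
  indices follow the HMMER3 specification; other dialects are rejected
  rather than guessed.
* **PROSITE patterns.** The ScanProsite grammar — dash-separated elements,
  residue letters, `x` wildcards, `[..]` alternatives, `{..}` exclusions,
  `(n)`/`(n,m)` bounded repetitions, `<`/`>` terminal anchors — is compiled
  element-by-element to an equivalent regular expression. Matching is
  leftmost non-overlapping by default (an `overlapping` flag scans every
  start position instead). The test suite checks extensional equality
  against an independently constructed regex translation on randomised
  pattern/sequence pairs.
* **Cysteine scaffolds.** Disulfide-rich peptide families (venom Kunitz
  type, the Z#/U# families) are described by a cysteine count and
  inter-cysteine spacing ranges. A hit starts at any cysteine from which
  *some* chain of cysteines satisfies every gap range (depth-first,
  earliest-candidate-first, with backtracking); one hit is reported per
  viable start, spanning first to last chain cysteine. Existential
  semantics were chosen over a no-backtracking greedy scan because they
  make hit existence monotone under gap widening — a property the test
  suite checks against an exhaustive subset-enumeration oracle.

Pattern and scaffold hits are exact descriptor matches with no E-value
theory; they carry E-value 0 and always pass the gate.

## The rule engine

Family rules are data (a TSV of family, category, priority, required
models with minimum counts, forbidden models, positional constraints), not
code. Rules are evaluated in priority order and the first satisfied rule
assigns the family and its venom function category. The shipped ordering
places enzyme/structured families first, single-short-domain peptide
families next, cysteine-scaffold families after, and IG-like last, so a
large multi-domain protein containing one ShK-like domain is not claimed
by the short-peptide rule.

The forbidden-model token `@cross` expands to "any model that defines a
different venom category", where a model is *category-defining* when it is
required by rules of exactly one non-Unknown category. Clusters whose hits
include defining models from two or more categories while no single rule
fires are assigned *Uncharacterised toxins* (category Unknown, flag
`multi_category`) — genuine toxin-like architectures that cannot be placed
in one category. Hits confined to a single category that satisfy no rule
yield no assignment (the evidence is insufficient rather than
conflicting). Positional constraints support order (`A<B`) and adjacency
(`A+B`) among required models, evaluated on hits sorted by alignment
start; richer geometric constraints are out of scope.

Signal-peptide evidence is three-valued (true/false/unknown). Absence
never blocks an assignment — transcript assemblies frequently truncate the
true N-terminus — it only sets the `no_signal_peptide` flag; unknown is
counted as absent only in summary tallies. Assignments whose required
evidence is pattern-sourced with no HMMER hit are flagged `rescued`,
mirroring a manual pattern-based rescue step feeding the same engine.

The shipped rule set (41 families across the eight categories) is a
representative stand-in: the descriptor content (patterns, scaffold
spacings) is invented, since the original family models are not published,
and both TSVs are user-replaceable. Catalytic-residue checks (e.g. the
trypsin His/Asp/Ser triad, the PLA2 His/Asp dyad) are annotational only
and never change a family assignment.

## Abundance integration

RNA counts are normalised by the classic median-of-ratios definition:
g_i = (∏_j k_ij)^(1/m) over samples, clusters with any zero count excluded
from the median (strict product definition, not log-mean-of-positives),
s_j = median_i(k_ij/g_i). Size factors are not rescaled to unit geometric
mean; every downstream quantity is a share or a ratio and therefore
scale-free. One consequence worth stating: multiplying one library by c
rescales the whole normalised matrix by the single constant c^(1/m), so
shares are invariant although raw normalised values are not.

Family-level abundance is the sum over member clusters of the per-cluster
arithmetic mean across all samples (zeros included), computed identically
for normalised RNA (24 samples) and protein (7 samples) matrices. Toxin
fractions are per-sample sums over toxin clusters divided by sample
totals. Recruitment is binary: a toxin cluster is detected if it appears
in the protein matrix with positive abundance in at least one venom
sample; the proteome is required to be a subset of the transcriptome, as a
spectral library built from transcriptome sequences enforces.

## Reporting conventions

Printed percentages are rounded half-up to one decimal (so 4/9 → 44.4);
integers are unrounded. Ranking ties break lexicographically by family
name; families absent from the other dataset are reported with the token
`Not present`. A venom phenotype is *dominant* only if one family's share
strictly exceeds 0.5. The eight-family panel analysis (actinoporins, NEP3,
NEP6, NaTx, KTx1 ≡ ShK-like, KTx2, KTx3, KTx5) re-normalises shares over
the panel and reports zero-cluster members explicitly. Molecular weights
use average (not monoisotopic) residue masses plus one water, with `X`
scored as the mean residue mass; kDa bins are <10, [10, 50), ≥50 with a
separate <7 kDa flag, computed on the full ORF (not the mature peptide).
Where a published count ratio disagrees with its published rounding
(537/1251 = 42.9% vs a printed 42.8%), the computed value is reported.

## The synthetic generator

The generator emulates the study design, not the biology: 2,000 gene
clusters (default), toxin fraction 0.05, 24 RNA-seq samples, 7 venom
samples. Study-stated rates are used where they exist — toxin recruitment
probability 0.184, toxin signal-peptide probability 0.41, background
detection 0.0185 and background signal 0.042 (the study-wide rates), and
expected toxin shares of 1.8% (RNA) and 14% (protein), achieved by solving
the toxin expression scale against the realised background means.

* Sequences: i.i.d. residues from a configurable frequency table (uniform
  over the 20 residues by default, which makes pattern false-positive
  rates analytically computable); planted clusters carry exactly one
  sampled instance of their family's descriptor at a recorded position;
  signal-flagged clusters start with a fixed synthetic signal-like
  segment (only the bookkeeping of signal evidence is modelled).
* Counts: negative binomial via gamma–Poisson mixing with dispersion 0.2
  and per-sample library factors uniform on [0.7, 1.3].
* Proteome: log-normal noise (σ = 0.5, mean-one correction) around
  family-weighted means, rows restricted to recruitment-flagged clusters.
* One weight per family drives both prevalence and per-cluster
  expression; per-family magnitudes are placeholders chosen once to give
  a study-like profile (scaffold families and ShK-like high, NEP6 absent),
  not estimates of the real animal.

By default every emitted sequence is re-scanned against *all* shipped
descriptors and resampled if it matches a foreign one (`reject_cross_hits`),
so the default scenario is noiseless by construction and the classifier's
100% precision/recall floor is deterministic rather than probabilistic.
Disabling rejection exposes the analytic background false-positive rates,
which the suite verifies at ±4σ Poisson tolerance.

What passing tests do **not** show about real data: the generator has no
assembly redundancy, no symbiont contamination, no homologous-family
sequence similarity (each family is a disjoint descriptor), no shared
domains between families, and detection is independent Bernoulli rather
than abundance-dependent. Perfect recovery on synthetic data is a
correctness floor for the engine, not an accuracy claim for real venoms.

## Numerical and degenerate-input choices

Deterministic throughout: every stochastic stage draws from
`numpy.random.default_rng([seed, stage])`, so stages are independent and
runs are byte-reproducible (the suite compares full double-run output
trees). Degenerate inputs fail loudly: empty FASTA yields an empty list
but duplicate ids error naming the id; a count matrix with no all-positive
cluster makes size factors undefined and errors; all-zero sample columns
error naming the sample; an empty rule file, duplicate priorities or
unresolvable model references are configuration errors. Scenario
configurations too small to detect any toxin in the proteome skip the
undefined protein-composition shares rather than failing the run.

## Problem sizes

Default synthetic scale is 2,000 clusters — large enough that every
default family is usually planted several times, small enough that a full
double run (for the reproducibility check) completes in seconds. Oracle
comparisons run at 200–600 element scales where exhaustive enumeration is
exact. The study-scale dataset (279,274 clusters, 5,375 venom proteins) is
represented by its published summary counts, shipped as package data, from
which all category-level percentages are recomputed.
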