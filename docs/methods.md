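# Methods

This note documents the models, procedures and design choices behind
`biggdraft`, in the order the pipeline runs them.

## GPR rules and the selection principles

A gene–protein–reaction (GPR) rule is a Boolean expression over gene ids
with `and` (all subunits of a complex required) and `or` (alternative
isozymes); `and` binds tighter than `or`, keywords are case-insensitive
whole words, and gene tokens are any run of characters excluding
whitespace and parentheses (BiGG gene ids contain dots and dashes).
Rules are stored verbatim on load and parsed on demand so a malformed
rule fails at evaluation time, with its reaction id, rather than
poisoning a whole model load.

Reaction selection follows four principles, one per rule shape:

* single gene — the ortholog must be present;
* OR-only — any one ortholog suffices (a partial GPR is assembled);
* AND-only — every ortholog must be present (a complete GPR);
* mixed — the rule is decomposed by OR into isozyme clauses
  (conjunctions) and each clause is treated as an AND-only rule.

`decompose_or` computes the minimal disjunctive normal form: duplicate
clauses collapse and clauses that are supersets of others are absorbed,
so the clause list is a canonical antichain and a rule is satisfied by a
gene set iff some clause is contained in it. DNF expansion is capped at
10,000 clauses per rule; exceeding the cap raises with the reaction id
(real template rules stay far below it, and silent truncation would
corrupt drafts). Under the default **strict** policy a reaction is
integrated iff at least one clause is *completely* mapped — a mixed rule
with one complete and one partial clause is included on the strength of
the complete clause. The non-strict policy also admits partially mapped
clauses (their mapped subset forms the conjunction) and flags the
reaction `partial`; the flag lives in reaction-level metadata, not in the
Boolean tree, keeping truth-table semantics clean. A template gene with
several query orthologs expands into one rewritten clause per
combination of choices, duplicates collapsed.

## Orthology

Homologous pairs are reciprocal best hits: after filtering both search
directions on e-value ≤ `max_evalue` (default 1e-20), bit score ≥
`min_bitscore` (default 50, inclusive floor) and query coverage ≥
`min_query_coverage` (default 0.75), a pair (t, q) is kept iff t is q's
top subject forward and q is t's top subject in reverse. Coverage is
alignment length over the *query* sequence length, applied in each
direction to that direction's query. Only the top-scoring HSP per
(query, subject) pair is considered — single-HSP coverage is
well-defined, summed-HSP coverage is not. Best-hit ties break by smaller
e-value, then lexicographically smaller subject id, making the map
deterministic. An "any reciprocal hit" mode is available for sensitivity
analysis.

The search itself is pluggable. `BlastEngine` shells out to `blastp`
with tabular output; `ExactMatchEngine` reports full-length hits between
identical sequences; `KmerEngine` scores a pair by the number of query
residues covered by shared k-mers (k = 12), with bit score two per
covered residue and a geometrically decaying e-value. The in-process
engines exist so the pipeline is testable end to end with no external
binary; their scoring conventions are their own and are not calibrated
to BLAST statistics.

## Deduplication

Template collections contain the same transformation written several
ways: in the opposite direction, with or without explicit protons, or
duplicated across compartments. The canonical key of a reaction is the
pair of sorted (base id, compartment, |coefficient|) multisets of its two
sides, protons (configurable base-id set, default `{"h"}`) removed,
direction normalized by placing the lexicographically smaller side
first. Coefficients are exact `Fraction`s throughout — which is why the
readers keep stoichiometry rational — so key equality is exact, never a
float tolerance. Charge differences alone never merge reactions.

Compartments are part of the key by default: a cytosolic and a
periplasmic copy of a reaction are genuinely different network edges, and
collapsing them would change topology. An opt-in flag instead compares
reactions up to a *consistent* relabelling of compartments (labels
renamed c0, c1, … in order of appearance on each orientation), which
merges faithful cross-compartment duplicates but not reactions that mix
compartments differently.

Within a key group, the representative is the member with the smallest
(reaction id, source model id); merged GPRs are OR-joined and minimised
by absorption (provenance records every merged source, so a first-seen
alternative is recoverable); the representative becomes reversible if
any variant was reversible or if two irreversible variants ran in
opposite directions — the union of the variants' capabilities.
Reactions with no GPR (typically spontaneous or boundary) are excluded
by default under the strict policy and re-admitted by flag; boundary
pseudo-reactions are recognised by the EX_/SK_/DM_ id prefixes or by
single-metabolite topology.

## Template modes and COG profiles

`build_draft` supports three template regimes: *all* (every available
template), *random* (k templates sampled uniformly without replacement
from a seeded generator; the seed is echoed in the run log so each
random draft is reproducible) and *selected* (the k organisms
metabolically closest to the query). Ortholog maps are computed per
template — gene ids are only unique within a model — and the selected
reactions are pooled before deduplication.

Metabolic closeness uses COG annotations consumed as TSV (protein id,
COG id, functional category letter, e-value); producing the annotation
is out of scope. Only COGs whose category letters intersect the
METABOLISM general category (C, G, E, F, H, I, P, Q) enter the binary
presence/absence matrix (rows organisms, columns COG ids). The distance
is Jaccard, 1 − |A∩B|/|A∪B|, by default — the natural choice for
presence sets, and a true metric — with Hamming available by flag; the
choice matters because it decides which templates are picked, so it is
surfaced prominently in the CLI. Two all-zero profiles are assigned
distance 0 with a warning. Ranking ties break lexicographically.

The PCA views (organism profiles and model-content matrices) drop
columns at or below a variance threshold (default exactly zero),
z-score the rest, and use a deterministic full-SVD PCA; component signs
are canonicalized so the largest-magnitude loading is positive, making
scores comparable across runs. PC1/PC2 scores and explained-variance
fractions are returned; plotting is a thin optional matplotlib helper.

## Assessment

Draft-vs-reference comparison is over reaction identifier sets,
restricted to comparable reactions: boundary pseudo-reactions are
excluded by prefix or topology. Identity is the exact id string —
matching by stoichiometric key is available by flag for references with
renamed ids, and `_copyN` suffix stripping is off by default since
silent normalization inflates TP. Precision, recall and F1 follow the
standard formulas; zero denominators yield 0 with a `degenerate` flag
rather than raising, so an empty draft still produces a report row.
Report rows print three decimals. Venn-region counts are exact
element-wise signature assignments for 2–7 labelled sets (beyond 7 the
regions are unrenderable and the call errors).

## The synthetic-data generator

`fixtures.generate` builds the study conditions every test runs under:
3 template models of 25 reactions and 18 genes each (80-residue random
proteins over the 20-residue alphabet — long enough that the k-mer
engine sees no spurious 12-mer matches), a shared 30-metabolite pool in
one compartment, GPR shapes drawn uniformly over the four principle
shapes with each shape guaranteed at least once per template, 80% of
template proteins copied into the query proteome (optionally with
point mutations) plus unrelated decoys, 3 planted duplicate groups
(reverse-written or protonated variants guarded by their own guaranteed
ortholog), and a reference model equal to the expected draft minus a
20% share (the draft's future false positives) plus 5 reactions no
homology evidence can reach (false negatives). All stoichiometries are
distinct by construction so the planted duplicate count is exactly the
number of merges deduplication must perform, and the expected draft and
its precision/recall/F1 against the reference are known in closed form
before any pipeline code runs. One integer seed determines every byte
of the output directory.

What the generator does *not* emulate: realistic BiGG content
statistics (reaction-count distributions, subsystem structure,
multi-compartment networks), sequence families with genuine
evolutionary divergence, or alignment score statistics. Passing tests
therefore demonstrate the correctness of the logic — selection,
reciprocity, deduplication, scoring — under controlled conditions, not
the biological quality of drafts built from real template collections.

## Numerical and degenerate-input choices

* Stoichiometric coefficients: exact rationals internally, decimals in
  SBML; JSON coefficients parse through their decimal string so 0.5
  stays 1/2.
* Metabolite ids split on the last underscore, preserving BiGG
  double-underscore base ids (`glc__D_c` → `glc__D`, `c`).
* FASTA and hit-table ids are case-sensitive and never normalized;
  duplicate FASTA ids and malformed hit rows fail with the offending
  id/line.
* A reaction consisting only of protons has no canonical key and raises.
* Empty GPR text means "no gene association", handled by policy, never a
  parse error.
* SBML SIds are sanitized copies of the original ids; originals are
  preserved as FBC gene-product labels and species suffixes, so round
  trips preserve identity, exact stoichiometry and GPR truth tables
  (rule strings may differ syntactically).

## Problem sizes

Tests and the acceptance script run on fixtures of 1–3 templates with
10–200 reactions, 1,000-rule truth-table sweeps (≤ 6 genes, depth ≤ 3),
and 100×100 hit sets — sizes chosen so the whole suite completes in
seconds on one CPU while still exercising every code path; the pipeline
itself is linear in total template reactions and quadratic only in the
(small) per-template proteome pair during in-process search.

## Known limitations

* No gap-filling, biomass synthesis, media definition or flux
  simulation; drafts need curation before simulation.
* No profile/HMM or nucleotide-level homology, and no synteny evidence.
* Legacy SBML Levels 1–2 and notes-field GPR encodings are not read.
* The "selected" mode requires the query and template organisms to share
  a COG annotation source; no taxonomy fallback is attempted.
* Reaction identity across models is nominal (id strings); structural
  matching is only as good as the shared namespace.
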