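# Methods

## The problem

Proteome-wide BLAST screens against large reference databases routinely flag
fungal proteins whose closest database matches are bacterial or plant
sequences. Only a small fraction of these anomalies are genuine interkingdom
horizontal gene transfers (HGT); the rest are vertical descent with sparse
taxon sampling, very ancient transfers (or ancestral presence) followed by
massive gene loss, or plain assembly contamination. `hgtscan` encodes the
manual decision procedure used to separate these explanations into a
deterministic, testable pipeline, together with a synthetic-data module that
plants each outcome with known ground truth.

## Lineages and taxonomic comparison

Every sequence carries an ordered ranked lineage over the fixed eight-rank
frame superkingdom → kingdom → phylum → class → order → family → genus →
species. Lineages may skip ranks (bacterial reference lineages usually lack
`kingdom`); all comparisons operate on `(rank, name)` pairs so a skipped rank
never aligns against a present one. Matching is exact and case-sensitive —
the inputs control their own names, and fuzzy matching invites silent
errors.

Two primitives matter downstream:

- **span rank** of a set of lineages: the most rootward rank at which the
  set disagrees (`uniform` if identical down to species). This measures how
  taxonomically wide a group of tree leaves is.
- **lineage overlap** of a subject against a query: the length of the
  longest shared root prefix of `(rank, name)` pairs divided by the query's
  lineage length. It is deliberately asymmetric — it reads as "how much of
  the query's taxonomic annotation does this hit confirm".

## The screening index (LPI)

For each query protein with a BLAST-style hit table, the lineage probability
index is the bitscore-weighted mean lineage overlap over eligible hits:

    LPI(q) = Σ_h  bitscore_h · overlap(q, h)  /  Σ_h bitscore_h

Eligibility: alignment coverage ≥ 0.7, at least 3 lineage terms, and (by
default) exclusion of hits from the query's own species — without the last
rule every query trivially scores near 1. A query is flagged as a candidate
iff LPI < 0.7 (strict) **and** the top eligible hit by bitscore (ties broken
by lower e-value, then subject id) lacks the focal kingdom term ("Fungi" by
default; configurable). The published tool that inspired this stage computes
its index with an unpublished two-pass ranking; the formula above is a
transparent surrogate with the same monotone behaviour — scores near 1 for
taxonomically close hit sets, near 0 for distant ones — and is documented as
such rather than as a reimplementation.

A separate, stricter filter selects the homolog set for tree building:
identity > 35 %, query coverage > 65 %, e-value < 1e-5 — all three bounds
strict. Exact duplicate amino-acid sequences are collapsed to one
representative (first in input order; a focal candidate always wins), with a
collapse map retaining the taxonomic identity of removed records.

## Topology classification

Gene trees are treated as unrooted. Monophyly on an unrooted tree is the
**clan** test: a leaf set is a clan iff it is one side of some edge
bipartition. The fungal leaves decompose into **patches** — maximal
all-fungal clans — which always partition the fungal leaf set (every fungal
leaf is at least its own pendant-edge singleton). The patch containing the
focal (candidate) leaf drives a fixed decision sequence:

1. fewer than `min_informative_leaves` (default 4) leaves → UNINFORMATIVE;
2. the focal leaf is the only fungal leaf → pattern D (no fungal homolog);
3. otherwise compute the focal patch P and its span rank S;
4. if S is at or rootward of `hgt_max_span_rank` (default `class`, i.e. the
   patch spans several classes or phyla): a *sparse* patch
   (|P| ≤ `sparse_max_patch`, default 10) whose span reaches
   `ancient_span_rank` (default `phylum`) → pattern C (ancient transfer or
   loss); anything dense → pattern B (vertical);
5. if S is tipward of `hgt_max_span_rank` (patch confined to one class):
   pattern A (HGT-compatible nesting) when no fungal leaves lie outside P
   and at least `min_donor_leaves` (default 3) non-fungal leaves are
   present; too few donors → UNINFORMATIVE; fungal leaves outside P →
   pattern B.

Two genuinely open design points and the conventions adopted:

- **A vs B when fungi form one clan.** The two archetypes differ by
  taxonomic restriction, not pure topology: accepted transfers are confined
  to a genus/family/order — one class — while vertical groups span classes.
  Encoded as the span-rank test plus the no-outside-fungi requirement.
- **Rule 5 sub-order.** When fungal leaves sit outside a single-class focal
  patch *and* donors are scarce, donor scarcity wins and the tree is
  UNINFORMATIVE; outside fungi force B only when enough donors are present
  to make the comparison meaningful.

An optional `support_collapse` threshold polytomizes internal edges with
support below it before classification; it defaults to off because no
support cutoff is part of the procedure being automated. All patch and
evidence lists are reported in sorted leaf-id order for reproducibility.

## Contamination triage and final calls

Candidates without fungal homologs (pattern D) are triaged by the kingdoms
of the best database hits of the features flanking the candidate on its
contig: *contaminated* when at least one flank has a hit and all flanks with
hits are non-fungal; *clean* when at least one flank has a fungal best hit;
*indeterminate* when no flank has any hit. Indeterminate is treated as
not-clean by default (the conservative choice — an unanchored contig is not
evidence of host origin); a flag (`indeterminate_is_clean`) flips this for
sensitivity analysis. Final calls: A → HGT (demoted to CONTAMINATION if a
checked contig is not clean); D + clean → HGT; D otherwise → CONTAMINATION;
B → VERTICAL; C → ANCIENT_TRANSFER_OR_LOSS. A final HGT call is impossible
for patterns B, C and UNINFORMATIVE by construction.

Accepted HGT calls are mapped to their **minimum transfer node**: the most
recent common ancestor, on a rooted species tree, of all species carrying
the transferred gene (a single receptor species maps to its own leaf). In
the synthetic pipeline the species tree mirrors the toy taxonomy, so
transfer nodes read as taxon names.

## Synthetic data

The generators emulate the *inputs* of the procedure, not molecular
evolution: no sequences are evolved, branch lengths are exponential(1)
placeholders, and supports are drawn uniform(0.8, 1.0) merely to exercise
the support-handling code paths.

- **Taxonomy**: a fixed toy hierarchy with 208 species — a Fungi kingdom
  (Ascomycota with five classes including a Pezizomycotina-like focal
  class, plus Basidiomycota, Chytridiomycota, Mucoromycota), a plant
  kingdom, and three bacterial phyla whose lineages skip the kingdom rank.
  Pezizomycotina (a subphylum in reality) sits at the class rank because
  the fixed eight-rank frame has no subphylum; only its role as "the focal
  taxon one level below phylum" matters to the classifier. Two orders ×
  two families × two genera × two species per class by default.
- **Gene trees**: random sequential joins within leaf compartments; the
  fungal compartment is grafted inside the donor subtree (patterns A, C, D)
  or attached as its sister (pattern B). Default sizes: A patches 2–8
  single-class leaves; B clans 20–40 leaves over 3–5 classes; C patches 2–6
  leaves spanning ≥ 2 fungal phyla; donors 8–20 bacterial leaves;
  uninformative trees have 3 leaves. These sizes sit well inside the
  classifier's thresholds so that planted-pattern recovery is exact.
- **Hit tables**: "low" fixtures combine dominant bacterial hits with at
  most two weak fungal hits (flagged by the screen); "high" fixtures use
  same-genus/family fungal hits (not flagged).
- **Contigs**: flank kingdoms planted to produce a requested verdict.

Every generator re-checks its fixture against the planted label before
returning and raises on mismatch — emission of a wrong-labelled fixture is
an error, never a warning. Because recovery is verified at generation time,
passing replication tests demonstrate that the pipeline implements the
decision procedure *consistently*, not that the procedure is correct on
real, noisy phylogenies: real trees have uncertain branches, rogue taxa and
taxonomies with missing ranks, which the generators deliberately idealize.

## Replication manifests

Two manifests fix the composition of the candidate sets the pipeline
reproduces end-to-end: `denovo` (246 scenarios: 1 no-fungal/clean-contig —
the single accepted de novo HGT — 134 vertical, 10 ancient, 101
no-fungal/contaminated) and `literature` (275 scenarios: 7 HGT nestings,
243 vertical, 21 ancient, 2 contaminated, 2 uninformative); `combined`
concatenates them (521). The de novo HGT case is planted as pattern D with a
clean contig — a lone fungal sequence among bacterial homologs whose contig
shows fungal context — and the seven literature cases as multi-leaf pattern
A; this is the only composition consistent with eight total HGT calls.
Per-scenario seeds derive from the manifest master seed by CRC-32 hashing of
the scenario id (always < 2³¹), so any scenario regenerates in isolation and
the whole run is byte-deterministic. Category percentages are reported with
half-up rounding to one decimal (8/521 = 1.535… → 1.5).

## Numerical and degenerate-input choices

- All threshold comparisons are strict where the procedure says "over",
  "above", "below", "less than"; boundary values are excluded and tested at
  the exact thresholds.
- LPI of an empty eligible-hit set is 0 (maximally anomalous — no close
  homolog confirms the annotation), and such queries are never flagged
  because the best-hit condition cannot be evaluated.
- Best-hit ties: higher bitscore, then lower e-value, then lexicographic
  subject id.
- An empty manifest yields all-zero counts and 0.0 percentages.
- Span of a single lineage (or identical lineages) is `uniform`; sets
  disagreeing at superkingdom span `superkingdom` — wide, not an error.

## Problem sizes

The replication presets total 521 gene trees of roughly 10–60 leaves; a full
combined run (generation, classification, triage, reporting and transfer
mapping) completes in about one second, and the whole test suite, including
brute-force bipartition enumeration over all subsets of trees up to 12
leaves, in well under a minute.

## Known limitations

- The LPI is a documented surrogate, not the published two-pass index; only
  its decision behaviour at the 0.7 threshold is exercised.
- Trees are consumed, never inferred: alignment, model selection and tree
  building are out of scope.
- Contamination triage consumes one best-hit kingdom per flanking feature;
  mixed-kingdom flank evidence is not modelled.
- Rooted gene-tree/species-tree reconciliation with explicit transfer costs
  is out of scope; the transfer node is a parsimony-style MRCA bound.
- The generators do not emulate alignment error, long-branch attraction or
  incomplete lineage sorting — the classic sources of *false* HGT signal —
  so recovery rates here say nothing about robustness to them.
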