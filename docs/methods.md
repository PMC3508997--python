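# Methods

## Detection model

The detector operates on one genome: gene records (1-based inclusive
coordinates, Ensembl convention; BED converted on read) and one peptide per
gene — where several isoforms exist, the longest is kept, ties broken by
smallest peptide id for determinism. Genes are ordered per chromosome by
(start, end, gene_id) and given 0-based ranks; all co-localisation logic
runs on ranks, never base pairs, so the window means the same thing on
gene-dense and gene-sparse chromosomes. Strand is carried through but plays
no role in detection.

For a peptide pair, the internal aligner produces the optimal local
alignment under BLOSUM62 with affine gaps (open 11, extend 1 — the
conventional protein-search defaults; the ambiguous residue X is rescored to
0 against everything). From the traceback we take L (columns, gaps
included), the identity count, and the residues of each sequence inside the
aligned region (n₁, n₂). The pair decision uses

- I = identities / L,
- I′ = I · min(n₁/L₁, n₂/L₂),
- threshold: 0.30 if L ≥ 150, else p(L) = 0.01·n + 4.8·L^(−0.32·(1+exp(−L/1000))) with n = 6.

n = 6 makes the two branches continuous at L = 150 (p(150) = 0.3030, i.e.
30 % at whole-percent precision). Numerically the curve is strictly
decreasing from very short lengths down to a shallow minimum near L ≈ 417
(≈ 0.291) and rises slightly after; only the L < 150 part is ever consulted.
For L ≲ 13 the curve exceeds 1, so extremely short alignments can never
pass — consistent with its twilight-zone origin; we deliberately do not
clamp it. The short branch compares I′ (not raw I) against the curve,
matching the long branch and the conservative intent of the coverage
weighting. An e-value threshold (≤ 0.2) applies only when alignments come
from an external search tool's tabular output; internal alignments carry no
e-value and skip that check, since its only purpose is discarding irrelevant
search hits. When a pair has several HSPs, the highest-scoring one is used
(ties: larger L, then lexicographic subject id).

Within each chromosome, every gene is a query and its downstream genes at
rank distance ≤ 100 are scanned in increasing order; the first passing hit
becomes the query's single link (`closest downstream`). Genes whose only
passing partners lie upstream are still captured by those partners' own
downstream scans, so restricting the scan to the downstream side changes no
resulting pair. An `all-pairs` mode links every passing pair in the window
for sensitivity analysis; because groups are transitive closures, the two
modes rarely differ at the group level. Genes without a peptide keep their
rank (the window describes genomic context) but are skipped as
query/subject, counted in the run report. Groups are connected components
(union-find) of the link graph; group ids are deterministic
(chromosome:first-member) and spans are max(end) − min(start) over members.

## Co-expression stage

Groups of ≤ 5 genes (configurable cap; larger groups are reported as skipped
— their expression data are typically too incomplete to test meaningfully)
are scored against a collection of expression matrices. A dataset is
eligible for a group when it has ≥ 3 samples, contains every member, and no
member profile is entirely missing or constant. Correlations are Pearson
with two-sided p-values from the t distribution (n − 2 df), computed
pairwise-complete over missing values; pairs with < 3 complete observations
or a constant profile are skipped and counted. The group score pools all
pair × dataset tests (significant/total at α = 0.05, no multiple-testing
correction — the quantity of interest is precisely the proportion of
nominally significant tests; a Benjamini–Hochberg option exists but is off
by default). A per-pair variant (fraction of datasets significant for each
pair) is also exposed. Class contrasts (duplicated vs co-localised
non-duplicated vs random controls, size-matched, seeded sampling) use
Welch's unequal-variance t-test; class variances are visibly unequal in this
design, and Welch is the safe default.

## GO similarity stage

Ontologies load from OBO (obsolete terms dropped; only `is_a` and `part_of`
edges carry semantic contribution, other relationship types are ignored with
the terms kept). The Wang measure: S_A(A) = 1 and, walking towards the root,
S_A(t) = max over child edges of w_edge · S_A(child), with w = 0.8 (`is_a`)
and 0.6 (`part_of`) — the customary factors for this measure; configurable.
Term similarity is Σ_{shared}(S_A + S_B) / (SV(A) + SV(B)), bounded in
[0, 1], 1 for identical terms. Gene pairs aggregate by best-match average
(max-of-pairs available); a gene unannotated in a namespace makes the pair
"not comparable" in that namespace rather than dissimilar — a group
contributes values wherever at least two members are annotated. Groups of
≤ 15 genes are scored (cap configurable). The constant `FAIRLY_SIMILAR =
0.5` labels the conventional boundary at which two genes are called fairly
similar. Annotations come from a GAF-style table (gene, term, evidence,
aspect, optional qualifier); NOT-qualified rows are dropped, all evidence
codes are kept, and the group's share of IEA-coded annotations is reported
so electronic-annotation inflation can be inspected alongside similarity
values.

## Synthetic fixtures: what they emulate, and what they do not

The generator plants duplicate families of known membership into an
otherwise random genome: family members share a random ancestor peptide,
each independently mutated at a fixed proportion of positions (substitutions
only, length preserved), and occupy consecutive rank slots a configurable
gap apart. Background peptides are uniform random sequences; unrelated
random proteins align far below the thresholds (short spurious local
alignments are additionally crushed by the coverage weighting), so planted
families are the only true positives by construction. Defaults — 5
chromosomes × 200 genes, 20 families of 2–5 genes at adjacent ranks,
divergence 0.1, peptide lengths 100–200 aa — give a genome-scale detection
problem that runs in under a minute on one core. Expression fixtures give
group members a shared per-dataset latent factor with loading √ρ (pairwise
correlation ρ in expectation, default ρ = 0.9, 10 datasets × 20 samples);
ontology fixtures build one complete tree per namespace (depth 3, branching
2 by default) and annotate group genes inside a single depth-1 subtree
versus uniform background annotation.

These fixtures establish correctness of the machinery, not realism: there
are no indels or rate heterogeneity in family evolution, no pseudogenes or
assembly artefacts, no heavy-tailed expression noise or batch structure, and
the ontology is far smaller and more regular than GO. Passing tests show the
pipeline recovers what its criteria define and that its statistics are
calibrated — not that the thresholds are optimal for any particular genome.

## Numerical and design choices

- Identity counts from tabular input are reconstructed as
  round(pident · L / 100), rounding half up.
- Empty local alignments (no positively scoring residue pair) are returned
  with L = 0 and never pass.
- Term-similarity of a term with itself short-circuits to exactly 1.0, and
  the ratio is clamped at 1.0, guarding summation-order rounding at the
  bound.
- α = 0.05 throughout by default; all thresholds, caps, weights and the
  window are exposed as function arguments and CLI flags.
- All generators and samplers take explicit seeds (numpy `default_rng`) and
  are bit-reproducible.
- Test problem sizes (e.g. the 1000-gene recovery fixture, 2 000+
  correlation tests for the null calibration, 20 random DAG seeds for the
  Wang oracle) were chosen as the smallest sizes at which the checked
  properties are statistically unambiguous.

## Known limitations

- Only intra-chromosomal (tandem/clustered) duplicates are detected; whole
  genome duplications and dispersed paralogs are out of scope by design.
- The closest-downstream link choice is one of several defensible readings
  of "closest hit"; the transitive closure makes group membership largely,
  but not provably, insensitive to it.
- No HSP chaining: a pair whose homology is split across several short HSPs
  in tabular input may be under-scored.
- Expression values are used as given — no normalisation, probe mapping or
  batch correction; supply matrices already keyed by gene id.
- The coverage fractions recovered from 12-column tabular input approximate
  nᵢ by coordinate spans; with the extended 14-column dialect (qlen/slen)
  the approximation error is limited to gap placement inside the aligned
  region.
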