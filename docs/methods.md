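# Methods

`chronograft` turns published divergence-time estimates into secondary
calibrations for a user-chosen topology. This note records the model and
procedure, the conventions and tolerances the implementation commits to,
what the synthetic generators do and do not emulate, and the design choices
made where more than one defensible option existed.

## Data model

A **chronogram** is a rooted ultrametric tree whose branch lengths are in
millions of years (Myr). Each node carries an **age** (time before present;
tips are at 0), computed as the maximum summed branch length from the node
down to a tip. Trees are accepted as chronograms only if all root-to-tip
path sums agree within a relative tolerance of 1e-6; published files carry
rounding noise below that level, while anything larger indicates a tree
whose branch lengths are not in consistent time units. Near-ultrametric
trees beyond tolerance are rejected rather than rescaled — silently
deforming a published chronogram would fabricate data.

Pairwise ages are stored as **patristic distance matrices**: the total
tip-to-tip path length, which for coeval terminal taxa is twice the age of
the pair's most recent common ancestor (MRCA). All age extraction goes
through this halving rule.

Polytomies are allowed everywhere and never resolved arbitrarily. Internal
node labels are preserved but unused. Unquoted underscores in newick decode
to spaces on input (binomials are conventionally underscore-encoded), with
a flag to disable; output encodes spaces back to underscores and orders
children canonically (by smallest descendant tip label), which makes writes
bit-stable and round trips lossless.

## Name standardization

Resolution is a fully local cascade against a pinned tabular taxonomy
(id, parent id, canonical name, rank, pipe-separated synonyms, plus a
version header): exact canonical match, then nomenclatural synonym, then
fuzzy match. Fuzzy similarity is `1 − edit_distance / max(len)` with a 0.90
acceptance threshold; ties prefer a candidate in the same genus, then the
lexicographically smallest. The threshold and tie rule are this package's
choices — no external reference prescribes them — and are deliberately
conservative: at 0.90 a binomial of typical length tolerates one or two
typos but will not jump genera. Database tip labels are canonicalized
against the same taxonomy at load time, so studies published under
synonymous names match a standardized query; fuzzy matching is *never*
applied to database tips, only to user input.

Inclusive taxon names (genus and above) either expand to their species-rank
descendants (subspecific variants excluded) or are dropped from the query
with an explicit notice, under the `get_species` flag.

## Search and congruification

A search returns every database record sharing at least two names with the
query, pruned to the matched taxa and converted to a patristic matrix.
Two is the minimum that determines an internal node; an empty result is a
valid, explicitly messaged outcome.

Congruification maps source ages onto the target: an internal target node
`v` with shared-tip descendant set `S` (|S| ≥ 2) receives a calibration
from a source iff

1. `v` is the target MRCA of `S` (otherwise the calibration belongs to a
   shallower surviving node), and
2. the shared tips below the source MRCA of `S` are exactly `S`
   (set-equality congruence — the strictest reading; a source that places
   any shared tip differently contributes nothing for that clade).

The source side is read directly off the matrix: the tips below the source
MRCA of `S` are exactly those within the diameter of `S`, so no source-tree
reconstruction is needed. The age is half the matrix entry of a witness
pair spanning the source MRCA; the lexicographically smallest spanning pair
is reported, making output deterministic. Incongruent nodes simply yield no
row.

Target nodes carry stable names `n1, n2, …`: root-down preorder, visiting
children by smallest descendant tip label in descending order. The
traversal depends only on structure and labels, never on the child order of
the newick the tree was read from, so isomorphic inputs name nodes
identically.

## Summaries

Per-node statistics over calibration ages: min, quartiles, median, mean,
max, sample variance (n−1 denominator) and SD. Quantiles use linear
interpolation at rank `h = (n−1)p + 1` (numpy default, R type 7). A node
with a single age reports that age for every location statistic and a
missing variance.

Pairwise summary matrices aggregate several sources cellwise (mean, median,
min, max) over the matrices covering each pair; uncovered cells stay
missing — no imputation, downstream consumers must handle NaN.

The **SDM summary** rescales each matrix by a positive factor before
averaging, minimizing the summed squared deviation of scaled shared cells
from their cellwise mean, subject to the factors summing to the number of
matrices. The objective is quadratic, so the constrained minimum is solved
exactly as a Lagrangian linear system (least-squares fallback for the
degenerate case of already-identical matrices, which keeps all factors
equal). Scale-only deformation is implemented; the full method in the
distance-matrix literature also allows additive terms, which are out of
scope here. Inputs must form a single grove, otherwise no common time scale
exists and the summary fails with a pointer to grove detection.

## Groves and supertrees

A grove is operationalized as a connected component of the graph whose
vertices are trees and whose edges join pairs sharing ≥ n taxa (n = 2 by
default). This is the standard sufficient overlap condition and an
approximation of the stricter combinatorial definition in the groves
literature. Grove selection defaults to most taxa; a `criterion="trees"`
flag selects most trees; ties break on the other criterion, then the
smallest member index.

The supertree of a grove is the topology from missing-value-aware
average-linkage agglomeration of the grove's SDM summary matrix
(cluster-to-cluster distance = mean over available cells). Clustering on
the summary matrix was chosen because it consumes the same object the
summary step already produces and yields a rooted tree; the method is
deliberately replaceable behind the `supertree` interface.

## Conflict filtering and root age

Summary ages become fixed calibrations after a root-down pass that discards
any age ≥ the age of its nearest retained ancestor (the more inclusive node
wins). A tip-up pass against retained descendants follows as a defensive
check; with ancestor precedence it is provably vacuous — after the first
pass every retained age is strictly below its nearest retained ancestor, so
no younger-than-descendant violation can survive — but the provenance code
for it exists and every discard is logged and recorded
(`discarded:older-than-ancestor` / `discarded:younger-than-descendant`).

The root age is resolved in order: a user-supplied value; the root's own
summary age; otherwise 1.1 × the oldest retained calibration, with a
conspicuous warning. The 10% headroom keeps the root strictly older than
every calibration without inventing a deep age. A randomized policy
(uniform between 1× and 2× the oldest calibration) is available behind an
explicit seed; silent randomness in a dating tool harms reproducibility, so
the deterministic rule is the default.

## BLADJ interpolation

Calibrated nodes are fixed at exactly their ages; tips at zero. Uncalibrated
internal nodes are assigned top-down: each node is placed between its
(already dated) parent and a chosen fixed descendant `D` at the first step
of an even division of the parent-to-`D` interval, where `D` is the fixed
descendant with the largest age, ties broken by fewest intervening unfixed
nodes, then smallest descendant label. On a chain of `m` unfixed nodes
between fixed ages `a` and `d` this reduces to the classic even spacing
`a − (a−d)·k/(m+1)`. Choosing `D` by largest age first is what guarantees
parent age > child age everywhere: preferring a nearer young tip over a
deeper old calibration could interpolate an ancestor below a retained
descendant age. Output is exactly ultrametric by construction (branch
lengths are age differences). The original branch-length-adjustment
program's node-visit order in tie cases is undocumented, so individual
interpolated ages may differ from it in polytomy-rich ties; fixed ages
never do.

Adapters for external dating programs emit their native calibration input
(a treePL-style config block, a MrBayes-style constraint/calibrate block)
as text only; nothing is executed and the formats are untested against the
binaries.

## Cross-validation

Leave-one-study-out: every chronogram of the held-out study is stripped to
its topology and re-dated from all other studies' ages, summarized by the
**mean** (the validation design uses average ages, unlike the median default
elsewhere; the discrepancy is preserved deliberately). Exclusion is at
study granularity — a study's every chronogram leaves the pool together.
Reported per node: original vs cross-validated age and the node's
descendant-tip count; the report gives Pearson correlation (raw ages;
undefined for constant columns) overall and per record, plus mean signed
error by depth bin to expose systematic deep-node bias.

## Synthetic data

The bundled six-species example reconstructs nine source chronograms from
their published per-node ages (each on the minimal topology consistent with
its witnessed taxon pairs; single-pair records are two-tip cherries), a
taxonomy carrying the *Emberiza elegans* → *Schoeniclus elegans* synonym,
and the target topology whose nodes n1–n5 match the published tables. It is
the single source of truth for the table-reproduction tests; its round trip
through the archive format is bit-stable.

Random databases draw pure-birth topologies (unit birth rate), extend every
tip branch by a common post-speciation sampling interval so internal ages
are strictly positive, and rescale to a root age uniform on 5–50 Myr —
spanning roughly the depths seen in family-level bird chronograms. The
noisy-replicates generator perturbs one true chronogram's node ages with
centered multiplicative noise (default ±20–25%), clamping to preserve
parent–child order. These generators emulate topology-concordant,
independently re-estimated studies; they do not emulate topological
conflict between studies, taxon-sampling bias, or systematically skewed
calibration strategies, so passing tests demonstrate correctness of the
machinery, not robustness to real inter-study conflict. The finch-like
taxonomy (289 synthetic species over 21 genera, a sprinkling of subspecific
variants) is a stand-in at the scale of a real family for name-expansion
tests; all its names are generated.

Problem sizes in the test-suite property checks — 200 random trees up to 15
tips for the congruification identity oracle, 50 random 2–4-matrix
instances for the SDM-vs-numeric-minimizer check, 200 seeded
noise-replicates of a 6-tip/3-study database for cross-validation — were
chosen as the smallest sets that exercise every branch of the logic while
keeping the default suite fast.

## Numerical choices

- Ultrametricity: relative 1e-6 on root-to-tip sums; entries traversing one
  source node must agree within the same relative tolerance.
- SDM: exact linear solve (no iteration); factors must be positive, else
  the inputs are too discordant to deform by scaling and the call fails.
- Quantiles: type 7; variance: n−1.
- All tie-breaks (witness pairs, BLADJ descendants, grove selection, node
  naming) are lexicographic after their primary criteria, making every
  output deterministic byte-for-byte.

## Known limitations

- Congruence is set-equality on shared tips: a single misplaced shared tip
  in a source voids that clade's contribution, which is conservative but
  discards partial signal.
- Pruning a target can legitimately create calibrations with no counterpart
  in the unpruned run: removing a tip shrinks a clade's shared set, and its
  source MRCA can drop to a shallower (younger) node. This is a property of
  shared-tip congruence itself, not an implementation artifact.
- Summary matrices may violate ultrametricity; dating therefore proceeds
  from per-node age summaries, and the matrices are exposed separately for
  inspection.
- No uncertainty propagation: the database stores point estimates and the
  summaries are point estimates; study quality weighting is out of scope.
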