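# Methods

This note documents the models, conventions and numerical choices
behind `tnfevol`, and what the synthetic-data tests do and do not
establish.

## Genome states and event replay

A `GenomeState` is an ordered list of chromosomes, each an ordered list
of gene copies `(id, origin, alive)`. Order is meaningful: tandem
duplicates sit adjacent to their template, and inversions reverse a
contiguous range. Event scripts are ordered lists of
`(branch, event)` pairs; without a species tree the branch labels form
a linear chain, and with one they must name tree nodes, a node's state
reflecting every event on its root-to-node path.

Conventions where the underlying history is stated only coarsely:

* Copies get deterministic ids — explicit `new_id` in the scripts, or
  `template-d<ordinal>` for local duplications and
  `template-b<ordinal>`/`-c<ordinal>` for genome multiplications — so
  replays are reproducible id-for-id.
* Whole-genome duplications copy every chromosome to a new chromosome
  named `old-b<ordinal>`; triplications add `-c<ordinal>`. Scripts may
  supply an `id_map` (and `origin_suffixes`) so that products carry the
  names used at each stage of the superfamily's history (V11 → V111 and
  V112 at WGD1; orthogroup names after WGD2). Duplication events may
  likewise rename their template (`relabel_target_*`): the pre-WGD1
  gene called V1 becomes V11 once its transposed duplicate V12 exists.
* Events listed on a branch that also carries a genome multiplication
  apply strictly in listed order; the packaged scripts encode
  "before/after the WGD" by ordering.
* Transposed copies append at the end of the destination chromosome
  (intra-chromosome insertion points are never specified upstream).
* Lost genes are retained with `alive=False` so genealogies can show
  losses; all counts skip them.

The derivation genealogy is a directed forest over gene ids: one edge
per created copy (tagged with the creating event) plus identity edges
for renames. Roots are exactly the initial-state genes, so every extant
gene traces to a unique root-era gene and to an ancestral class
(V11/V12/V21/V22) via its origin labels.

### Packaged scripts

Four JSON scripts under `tnfevol/data/` encode the evolutionary model;
all embed the same backbone (1 → 2 → 4 → 8 genes through two tandem
duplication/transposition stages and WGD1):

| script | terminal lineage | genes |
|---|---|---|
| `vertebrate_backbone` | post-WGD1 vertebrate ancestor | 8 |
| `cyclostomes` | cyclostome ancestor / *Petromyzon marinus* | 6 / 9 |
| `gnathostome_human` | post-WGD2 / gnathostome ancestor / human | 16 / 21 / 18 |
| `gnathostome_rhincodon` | gnathostome ancestor / *Rhincodon typus* | 21 / 33 |

The cyclostome ancestor loses three post-WGD1 genes and duplicates one
in tandem; the *Petromyzon* branch applies the cyclostome genome
triplication literally (18 copies), loses eleven of them, keeps a
second copy of TNFSF-C4 on a different chromosome, and adds two tandem
duplicates (TNFSF-C4b, TNFSF-C5b). The gnathostome ancestor arises
from WGD2 (16 genes) plus seven duplications and two losses; the exact
identities of those events are constrained by the per-class gene lists
(V11 gains four, V12 two, V22 one with one loss, V21 loses one) but
their placement among count-equivalent alternatives is a modelling
choice. Where hagfish and lamprey gene orders disagree, the tandem
arrangement of the first cyclostome pair follows the lamprey layout.

## Orthogroup calling

Supported clades are internal nodes with bootstrap ≥ the threshold
(default 95%). A basal polytomy marks a tree unrooted; rooting then
requires a declared outgroup or midpoint rooting — never a silent
default.

Synteny records hold signed neighbor offsets (−k…+k, no base
coordinates, no strand) mapping to `(ortholog symbol, human-chromosome
class)`. A gene's *location class* is the majority vote over its
neighbors' classes (ties break lexicographically), robust to one
misassigned neighbor.

Calling proceeds: (1) maximal supported clades seed groups; (2) a clade
is split along connected components of the graph linking members that
share a location class or ≥ `min_shared` neighbor symbols — so
splitting can never separate genes with shared synteny, and sequence
proximity never overrides location evidence; (3) groups and unplaced
genes merge when they share ≥ `min_shared` symbols *and* a location
class (both conditions, because merges must survive either line of
evidence failing); (4) leftovers are reported unassigned with no
guessing — fast-evolving genes that "escape" their true position stay
unassigned rather than being forced into a group. `min_shared`
defaults to 1 (a single shared flanking ortholog has chance probability
`1 − (1 − k/G)^m ≈ 2 × 10⁻⁴` in a 20,000-gene genome).

## Count parsimony with polyploidy

Per orthogroup, ancestral copy numbers 0…`max_count` are optimised by a
Sankoff dynamic program. A plain branch from parent count a to child
count b costs `w_dup·max(0, b−a) + w_loss·max(0, a−b)` (unit weights by
default — raw event counting implies equal weight; weights are
configurable). A branch with multipliers m₁…m_k costs the minimum over
the copy numbers held immediately before each multiplication; tallied
events are tagged `pre`/`post`.

Canonical tie-breaking: the root takes the smallest optimal count
(unless pinned via `root_count`, e.g. one per ancestral family), each
internal node then the smallest optimal state given its parent, and
polyploidy intermediates the smallest optimal value. Smaller deep
counts defer duplications tipward, matching the reading that events
are placed as late as the data allow. `max_count` defaults to twice
the largest tip count plus two.

`clade_event_totals` sums a clade's branch tallies including the branch
entering the clade root; `exclude_polyploid_lineages` drops every
branch at or below a polyploidy annotation, the convention used when
quoting lineage dynamics with WGD lineages set aside.

Caveat established by the simulator: parsimony lower-bounds the true
event count and recovers it exactly when each family carries at most
one event in total. Between one event per family and one per branch,
parsimony may legitimately undercut the truth — two parallel tip
duplications merge into one internal duplication, and a duplication
upstream of a loss cancels — so exact-recovery claims are made only on
the sub-ensemble where the guarantee holds.

## Ancestral function inference

Features are projected backward under a single-origin (Dollo) rule:
one emergence plus any number of losses is cheaper than repeated
independent gains (gain cost 1, losses free; the gain cost is
configurable). For each feature the inferred presence set is the
minimal connected subtree spanning the annotated genes: present at a
gene when at least two of its descendant lineages carry the feature
(the gene's own annotation counts as one lineage), and on every gene on
a path from such a junction down to an annotated gene. A feature seen
in a single gene is inferred nowhere above it. This labelling is the
unique minimum-gain, minimum-presence solution, and the tests verify it
against an independent ancestor-chain construction on random
genealogies.

Receptor-sharing reports trace each ligand to its ancestral class and
flag receptors whose ligands all share one origin. Functional
convergence could mimic shared ancestry; the report carries the labels,
not a certainty claim.

## Expression networks

Correlation edges use Spearman's rank correlation (mid-ranks for ties;
`NaN` sentinel for constant vectors), two-sided p-values from
`t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom, and
Benjamini–Hochberg FDR control (the FDR variant is configurable; BH is
the default). Edges require q < α (default 0.05) and, by default,
ρ > 0 — the figures under reproduction show positive correlations, and
any ρ-threshold is a data-dependent consequence of FDR, never a
hard-coded cutoff. Isolated genes remain as nodes.

The immune top-k overlap statistic ranks each gene's cell types by
expression (ties at the k-th value break by cell-type name), keeps the
top k (default 10), intersects with the immune subset (default 11 of 81
types) and links pairs sharing ≥ `min_shared` (default 3) immune types.
Its null probability is the binomial tail `P(X ≥ s)` with
`X ~ Binom(n_immune, (k/N)²)`: exact summation gives 5.33 × 10⁻⁴ at the
defaults. Two caveats are deliberate: the commonly quoted figure
(5.4 × 10⁻⁴) differs by ~2% from the exact tail of the same model; and
the binomial treats the immune types as independent trials, whereas the
actual ranking process is negatively dependent (each gene has only k
top slots), so the binomial null is conservative — simulation of full
random profiles yields ≈3 × 10⁻⁴. The stated binomial form is
implemented as specified and both gaps are tested.

## Synthetic data

The family simulator draws per-branch duplication and loss counts as
Poisson variables (defaults 0.2 expected events per branch per family,
a sparse regime; losses on extinct families are discarded, flooring at
zero), applies them in random order around any WGD point (recording the
realised order as truth), and derives tip counts, genealogy and
orthogroup membership by replaying the recorded scripts through the
same engine the user-facing replay uses. Synteny neighborhoods are
inherited with a 0.05 per-neighbor per-branch rearrangement probability
— high but imperfect conservation. The emitted gene tree mirrors the
true families as fully supported clades (support noise demotes a clade
below 95% with the configured probability) joined by a weak backbone.

The expression generator uses a Gaussian copula: genes in a module
share a latent cell-type profile with loading chosen via
`r = 2·sin(π·ρ_s/6)` so the realised pairwise Spearman correlation
matches the target (±0.05 at n = 81 over seeds); marginals are
log-normal to mimic TPM skew. Immune-high modules receive a rank shift
that places the immune types at the top of every member's ranking.

What a green synthetic test establishes: the statistical machinery is
correct on data with the assumed structure (clean family clades,
conserved neighborhoods, block correlation). What it does not: real
alignments, rate heterogeneity, assembly gaps, or real expression
atlases — the real-data link counts and mean degrees quoted in the
literature depend on an external atlas and are intentionally not
reproduced here.

## Reproducibility

All randomness flows from a single integer seed per generator; the
pipeline writes a run log with a config hash, and outputs carry that
hash in a comment header. Reruns with an unchanged config are
byte-identical.
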