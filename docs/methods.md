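# Methods

## Placement model

`meplace` treats read placement as a constrained minimum-evolution (ME)
problem.  The reference topology *T* (unrooted, strictly binary, *n* ≥ 4
leaves) is fixed; the only free choice is which edge *b* receives the read
*r*.  The criterion is the total OLS tree length of the (*n*+1)-taxon tree,
*S*<sub>*b*,*r*</sub>, minimised over all 2*n*−3 edges.  All branch lengths
of the joined tree are re-estimated (not just the local triplet): the cost
is the length of the *whole* resulting tree, so a placement that distorts
distant branch estimates is penalised accordingly.

Assumptions inherited from the distance framework:

* distances are additive in expectation on the true tree (violations —
  saturation, model misspecification — degrade placement like they degrade
  any distance method);
* the read covers enough alignment columns for its *n* reference distances
  to be meaningful (`min_overlap`, default 20 jointly unambiguous sites;
  below it the distance is refused, or imputed with the largest finite read
  distance under `--impute-max`);
* the reference tree is correct; errors in it translate directly into
  placement errors.

### Exactness of the scan

The per-edge OLS estimators (external: ½(d_iA + d_iB − d_AB); internal:
½[λ(d_AC+d_BD)+(1−λ)(d_AD+d_BC)−d_AB−d_CD] with
λ = (|A||D|+|B||C|)/((|A|+|B|)(|C|+|D|))) reproduce the normal-equation
solution exactly; the suite asserts this against `numpy.linalg.lstsq` on
non-additive inputs, which also pins the λ pairing (the two pairings are
indistinguishable on additive data).

The key structural fact used by the scan: the average distance between
*X* ∪ {*r*} and any disjoint set *Y* does not depend on *where* inside *X*
the read is attached.  Hence an edge's OLS length changes between two
insertion positions only if those positions fall in different subtrees
adjacent to that edge — i.e. only the five "local" lengths (pendant, the
two pieces of the split edge, and the other two edges at the shared node)
differ between adjacent insertions.  The scan therefore evaluates one
starting edge in O(*n*) and walks the edge-adjacency graph with O(1)
updates, after an O(*n*²) one-time table of subtree sizes and average
distances that is shared by all reads and all bootstrap replicates.  A
brute-force oracle (explicitly grown (*n*+1)-taxon tree, full OLS, O(*n*²)
per edge) is kept in the package both for testing (agreement to 1e−9
relative, far below the double-precision headroom of the O(*n*) additions
involved) and for `--oracle` verification runs.

Negative OLS branch lengths are kept in the sum by default (the classical
criterion); `--clamp-negative` floors each estimate at zero before summing.
Pendant and distal lengths written to jplace are clamped to ≥ 0 for output
only.  Ties in *S* are broken toward the smallest edge number so runs are
reproducible bit-for-bit.

### Balanced variant

`--balanced` switches to the balanced (equal-subtree-weight) criterion,
whose total length is Pauplin's formula Σ 2^(1−p_ij) D_ij.  Subtree
averages become 2^(−depth)-weighted, λ = ½, and the adjacent-edge update
takes the simple form ¼[d(r,Z') + d(Z,W) − d(r,Z) − d(Z',W)].  It is
verified against a direct Pauplin evaluation of the grown tree.  OLS
remains the default and is what all reported benchmarks use.

## Distances and bootstrap

Every distance is a function of a 4×4 matrix of nucleotide-pair counts over
columns where both sequences have an unambiguous A/C/G/T (pairwise
deletion; IUPAC ambiguity codes and N count as missing).  p-distance is the
default: it is defined for every pair, has low variance, and short-read
placement is dominated by exactly the short-distance comparisons where it
approximates model-based distances well — the benchmark below confirms it
out-places Γ-corrected TN93 at read lengths ≤ 500 bp.  TN93 (+Γ with shape
α, default 0.7) is provided; saturated pairs (non-positive log/power
argument) raise an explicit error rather than returning a number.

Bootstrap support is placement-level: for each replicate, every
read–reference pair's counts are resampled from Multinomial(N, c/N) with
that pair's own valid-site count N, the read distances are recomputed, and
the scan re-run; an edge's support is the fraction of replicates it wins,
so support sums to one per read.  The reference half of the matrix and the
topology are never resampled — the reference tree is taken as given, and
freezing it is what makes B=100 replicates cheap (only the read row of *D*
changes, so the O(*n*²) tables are reused).  Replicate streams are derived
by fixed sub-seeding from (seed, read index), making batches reproducible
and order-independent.

## The synthetic reference panel

The simulator emulates an rRNA-like panel of representatives spanning a
large, old radiation-rich phylogeny:

| parameter | default | meaning |
|---|---|---|
| `n_taxa` | 500 | reference panel size |
| `seq_len` | 2000 | alignment columns (no indels) |
| `relative_extinction` | 0.925 | extinction/speciation ratio of the chronogram |
| `source_pool_factor` | 3.22 | panel is a subsample of a 3.22× larger chronogram |
| `rate_low`–`rate_high` | 0.11–0.33 | per-branch rate multipliers, U(·,·) subs/Gy (±50% around a nominal 0.22) |
| `mean_branch_length` | 0.05 | subs/site; enforced exactly by global rescaling |
| `gamma_alpha`, `gamma_categories` | 0.7, 5 | discrete-Γ rate heterogeneity (equal-probability bins, bin-mean rates) |
| `p_invariant` | 0.008 | invariant sites (rate 0; no renormalisation of the variable-site rates) |
| `gtr_exchangeabilities`, `base_frequencies` | all equal | GTR defaults to JC-like unless parameters are supplied |
| `noise_sub/dup/del` | 0.01 each | per-base read errors |
| `read_lengths` | 125…2000 | contiguous blocks, uniform start |

Tree generation: a birth–death chronogram with `source_pool_factor × n_taxa`
extant tips is grown, `n_taxa` tips are sampled uniformly, each branch's
time span is multiplied by an independent U(0.11, 0.33) rate, and all
lengths are rescaled to the target mean.  The high relative extinction
produces many very short internal branches (deep radiations) and the
subsampling lengthens pendant branches, mimicking a panel of well-separated
representatives; 0.925 and the 3.22 pool factor were fixed once against the
published shape characteristics of such panels (tree diameter a little over
2 subs/site; a heavy left mode of near-zero internal branches) and are not
fitted to any accuracy number.

Read noise is applied per base, independently, in the order substitution →
duplication → deletion: substitutions draw uniformly from the three other
bases, a duplication ("stutter") inserts a copy of the possibly-substituted
base immediately after, and a deletion removes the original base (a stutter
copy survives deletion of its template), so the expected read length is
preserved at the default rates.  For placement the noisy read is expressed
in *true* alignment coordinates: deleted bases become gaps and stutter
copies, having no column of their own, are dropped.  Profile-HMM alignment
of the reads is deliberately outside this package; queries arrive
pre-aligned.

### What the emulation does *not* capture

* **Tree shape.**  Real panels drawn from the tree of life carry a far
  heavier load of effectively-zero internal branches (arbitrarily resolved
  radiations) than any birth–death model: after rescaling to mean 0.05, the
  emulated trees put ~3–4% of branches below 0.001 subs/site where real
  panels show roughly double that.  Placement difficulty is driven almost
  entirely by that left tail, so **accuracies measured on the emulated
  panels are optimistic** relative to panels with a heavier short-branch
  load, and the misplacements (being rarer and tied to isolated short
  branches) concentrate at node separation 1 instead of spreading across
  radiations.  The harness and metrics are faithful; the absolute numbers
  are tree-shape-dependent.
* **Alignment error.**  True coordinates are used; real pipelines align
  reads with a profile HMM and lose a few points of accuracy.
* **Sequence model.**  GTR defaults to equal rates/frequencies; fitted rRNA
  matrices (strong transition bias, skewed composition) carry less signal
  per site.  Indels and chimeric reads are not simulated.

## Evaluation harness

Leave-one-out: for each taxon, prune it from tree and alignment (the two
flanking edges merge; the merged edge is the single truth), cut reads from
its sequence, place against the remaining *n*−1 references, and score.
Known-sequence mode keeps the taxon and scores against its pendant edge.
Metrics: *f*<sub>c</sub> (fraction exactly correct), node separation
*S*<sub>N</sub> (distinct nodes on the path between truth and inferred
edge; 0 = correct, 1 = adjacent) and branch-length separation
*S*<sub>B</sub> (subs/site between edge midpoints, using the simulator's
true lengths).  Reads that fail hard (insufficient overlap/saturation) are
excluded from denominators and counted separately.

Problem sizes used by the shipped checks: the trend battery (accuracy and
misplacement-distance versus read length, bootstrap support versus read
length, p-distance versus TN93+Γ) runs on five replicate 200-taxon panels —
200 taxa give the same qualitative behaviour as 500 at a fraction of the
cost — while the headline full-length benchmark runs at the full 500 taxa ×
2000 bp on three replicate panels, ~1500 placements per experiment.

## Numerical choices

* 0-based, half-open column coordinates internally; 1-based only in
  user-facing messages.
* Edge numbers are assigned in preorder from the (deterministically chosen)
  trifurcating traversal root, making the numbering a pure function of the
  Newick string; jplace files round-trip it.
* Rooted input trees are silently unrooted by suppressing the degree-2
  root; polytomies are rejected.
* Oracle-agreement tolerance 1e−9 relative; OLS-vs-lstsq 1e−10 absolute.
* `min_overlap` = 20 sites: below ~20 sites a p-distance's sampling noise
  (SE ≳ 0.1) exceeds typical branch lengths by an order of magnitude.
* Degenerate inputs: empty query coverage, unknown edges, leaf/alignment
  mismatches and saturated pairs all raise typed errors naming the offender.

## Known limitations

Besides the emulation gaps above: no amino-acid distances; no de novo tree
search (the reference topology is never questioned); bootstrap support is a
resampling frequency, not a posterior probability, and is unreliable when
the true attachment branch is effectively zero-length — no method can place
a read informatively there, so support values near very short branches
should be read with care.
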