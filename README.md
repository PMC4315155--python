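# meplace

Exact minimum-evolution (ME) phylogenetic placement of sequencing reads onto
a fixed reference tree, with multinomial pair-count bootstrap support — plus
a simulation and leave-one-out harness for benchmarking placement accuracy.

## The problem

A central task in metagenomics is to classify reads from a mixed sample by
attaching each one to its correct position in an existing reference
phylogeny (e.g. an rRNA gene tree).  Likelihood-based placement tools exist;
`meplace` implements the distance-based alternative: because placement on a
*fixed* topology only moves one taxon, the ME criterion can be evaluated
**exactly on every edge, with no search heuristics**, from a matrix of
pairwise distances.

## The method

Inputs: an unrooted binary reference tree *T* on *n* taxa, a reference
multiple sequence alignment, and reads pre-aligned to the reference columns.

For a read *r* and each of the 2*n*−3 edges *b* of *T*, the placement cost is

> *S*<sub>*b*,*r*</sub> = total tree length of the (*n*+1)-taxon tree with
> *r* attached mid-edge on *b*, with **all** branch lengths re-estimated by
> ordinary least squares (OLS) from the distance matrix *D*.

The read is placed on the edge minimising *S*<sub>*b*,*r*</sub>.  The OLS
branch-length estimators are the classical closed forms: for an external
edge of leaf *i* whose neighbour splits the rest into subtrees *A*, *B*,

```
l_i = ½ (d_iA + d_iB − d_AB)
```

and for an internal edge separating *A*, *B* | *C*, *D*,

```
l  = ½ [ λ (d_AC + d_BD) + (1−λ)(d_AD + d_BC) − d_AB − d_CD ]
λ  = (|A||D| + |B||C|) / ((|A|+|B|)(|C|+|D|))
```

with *d*<sub>*XY*</sub> the average leaf-pair distance between the sets.
Reference–reference distances are computed once; per read only the *n*
read–reference distances are recomputed.  Because moving the insertion
point between adjacent edges changes only local terms, the full scan costs
O(*n*) per read after a shared O(*n*²) setup — and it is *exact*: the test
suite verifies it against a brute-force oracle (explicit (*n*+1)-taxon OLS)
to 1e−9 relative on every edge, and the OLS formulas themselves against the
least-squares normal equations.

Distances are p-distance by default (with pairwise deletion of gaps and
ambiguous bases); Tamura–Nei (TN93), optionally Γ-corrected, is available.
Support values come from a placement-level bootstrap: the 4×4 nucleotide
pair counts of each read–reference pair are resampled multinomially, the
read is re-placed, and each edge's support is its replicate frequency
(reference–reference distances stay frozen).  A balanced (equal subtree
weight, BME) criterion is available behind `--balanced`.

Results are written as jplace v3 (the `likelihood` field carries
−*S*<sub>*b*,*r*</sub>, `like_weight_ratio` the bootstrap support) and flat
TSV.

## Worked example

Simulate a 50-taxon reference panel (birth–death tree rescaled to a mean
branch length of 0.05 substitutions/site, 2000-bp GTR+Γ+I alignment), with
one noisy read per taxon per length:

```
$ meplace simulate --out-prefix demo --n-taxa 50 --seed 42
$ meplace place --tree demo.ref.nwk --align demo.ref.fasta \
      --queries demo.queries_500.fasta --bootstrap 100 --seed 7 \
      --out demo.jplace --tsv demo.tsv
$ head -4 demo.tsv
read_id      edge_num  S_cost       support  S_N_if_known
t00_L500     1         2.78013124   1
t01_L500     2         2.786531442  1
t02_L500     6         2.791968494  0.99
```

Each row is one read: the winning edge number (as annotated in the jplace
tree), its ME cost *S* (total OLS tree length, substitutions/site — smaller
is better), and the fraction of 100 bootstrap replicates that chose the
same edge.  Scoring the placements against the simulator's truth table:

```
$ meplace evaluate --tree demo.ref.nwk --truth demo.truth.tsv \
      --jplace demo.jplace --out eval.tsv --json-out eval.json
$ cat eval.json
{
 "n_reads": 50,
 "f_c": 0.8,
 ...
}
```

i.e. 80% of these 500-bp noisy reads were placed on exactly the right edge
(`eval.tsv` also reports each misplacement's node separation *S*<sub>N</sub>
and branch-length separation *S*<sub>B</sub> from the truth).  Two result
sets for the same tree can be intersected with `meplace consensus`, which
reports the agreement fraction and — when truth is known — the accuracy
inside the agreement subset.

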