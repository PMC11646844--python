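# Methods

`clonedelim` benchmarks methods for delimiting B-cell clonal families — the
groups of heavy-chain sequences descending from a single V(D)J
recombination event — on simulated repertoires where the true families are
known. It treats the problem as the single-locus species-delimitation
problem from phylogenetics: on a tree of all sequences, branching *between*
families (the historical diversification of germline genes plus
recombination) follows a different branch-length process than branching
*within* a family (somatic hypermutation during clonal expansion).

## Repertoire simulator

**Naive rearrangement.** One V, one D and one J germline gene are sampled
uniformly and concatenated with two junctional insertions (`np1`, `np2`) of
uniform-random ACGT bases, fixed length 6 by default. No palindromic
structure or trimming is modelled: the insertions stand in for both N and P
nucleotides, and the fixed length avoids frameshifts. The junction is
defined at the nucleotide level as `np1 + D + np2`, optionally extended by
a symmetric flank into V and J (`junction_flank`, default 0); the
amino-acid flank conventions of IMGT junction definitions are not modelled.

**Germline sets.** Either loaded from FASTA (segments inferred from
IGHV/IGHD/IGHJ header substrings), or generated synthetically with uniform
ACGT sequences at human locus scale lengths (V 290–320 nt, D 10–37 nt,
J 48–63 nt). A "fake V" variant corrupts every V gene with 3 deletions and
3 insertions of size 1–4 at non-overlapping positions (applied right to
left on the original coordinates) plus 20–40 point substitutions at
distinct positions — the scenario where a study population's germline
alleles do not match any reference directory. D and J genes pass through
unmodified because they are too short to host such edits.

**Clonal expansion and SHM.** Family sizes are geometric on {1, 2, ...}
with success probability 1/mean, so the configured mean is the expectation
and singleton families occur naturally. Each family grows on a random-join
(Kingman-shaped) rooted binary topology with i.i.d. exponential edge
lengths, rescaled per tree so that the **mean root-to-leaf path length
equals the SHM rate**. The SHM rate is therefore the expected per-site
substitution load of a sampled sequence relative to its naive ancestor:
at rates 0.05 and 0.1 the simulated leaves diverge ~5% and ~9% from the
naive sequence, the range usually quoted for antibody repertoires. (The
alternative convention — per-edge mean equal to the rate — multiplies
divergence by the tree depth and saturates sequences at the high end of
the rate grid; we measured ~17.5% divergence at rate 0.2 under the chosen
scaling versus near-saturation under the per-edge convention.)

Substitution is the only mutation type: on an edge of length `t` each
mutable site substitutes with probability `1 − exp(−t)` and the new base is
uniform over the three alternatives. Length conservation keeps all
within-family comparisons alignment-free. A `junction_only` scope
restricts mutation to the junction interval, with an option to exclude the
D gene (the literal reading of "junction excluding V, D, J"); the default
mutates `np1 + D + np2`.

**Determinism.** One master seed per repertoire; per-family substreams are
spawned by family index, so family `k` is reproducible independently of
how many families precede it. Sequence ids (`seq000001`, ...) carry no
family information; ground truth lives only in the exported AIRR-style
TSV's `clone_id` column.

**What the simulator does not emulate.** Gene-usage frequencies, hotspot-
biased SHM, SHM indels, clonal selection, isotypes, paired light chains,
and sequencing error are all absent. Passing benchmarks here show that a
delimiter recovers families under idealized substitution-only evolution
with uniform junctional insertions; they do not certify performance on
real AIRR-seq data, where junction-length variation within families and
annotation errors add failure modes the simulator cannot produce.

## Tree inference

Pairwise distances: Hamming proportion, Jukes–Cantor-corrected distance
`−(3/4) ln(1 − 4p/3)` (saturated pairs `p ≥ 0.75` set to a ceiling of 5.0),
or unit-cost global-alignment edit distance normalized by the longer
sequence (for repertoires whose families differ in length). Trees are
neighbor-joining (scikit-bio's implementation; negative branch estimates
clipped to zero) rooted at the midpoint of the longest tip-to-tip path.
Two-leaf midpoint rooting and fully degenerate trees (all distances zero)
are special-cased. Externally built Newick trees are accepted everywhere a
tree is consumed, for users who prefer maximum-likelihood topologies; the
delimitation stage needs only the backbone branching structure, which
distance methods recover well at these scales.

## Poisson-tree-process delimitation

A delimitation of a rooted binary tree is a parent-closed set `G` of
internal nodes containing the root (possibly empty). Edges whose parent is
in `G` are *speciation* edges; each child `c` hanging off `G` roots one
*coalescent* subtree consisting of the edges strictly below `c`. A leaf
attached directly to `G` is a singleton family with a zero-edge subtree
and no likelihood term. Branch lengths in each class are modelled as
exponential; the ML rate for a class is `n / Σ lengths` with log-likelihood
`n (ln rate − 1)`. Model selection is by `AIC = 2k − 2 log L` where `k`
counts the fitted rates:

* null model (`G` empty): one pooled fit over all edges, `k = 1`, one
  family containing every leaf;
* `single_rate`: one speciation fit plus one pooled coalescent fit,
  `k = 2` (the default, matching common usage of the published tool);
* `multi_rate`: one fit per coalescent subtree, `k = 1 + #subtrees`,
  allowing SHM-rate variation between families.

Edges shorter than `min_branch_length` (default 1e-9) are floored before
fitting. AIC ties favour fewer families, then the smaller speciation set.

**Search.** The number of delimitations is the tree recursion
`f(v) = 1 + f(left)·f(right)`, `f(leaf) = 1`; when it is at most 1e5 the
optimum is found by exhaustive enumeration. Larger trees use greedy
hill-climbing over single-node grow/shrink moves of the speciation
frontier, started from (a) the null model, (b) the best clade-height
threshold delimitation — for every candidate threshold `t`, score
`S_t = {internal v : clade height of v > t}` and keep the best — and
(c) optional random root-containing subtrees (`restarts`). The threshold
start matters in practice: on repertoire NJ trees the edges adjacent to
the midpoint root are often short, so a climb from the null model stalls
immediately while the between-family structure sits deeper in the tree.
This likelihood follows the operational description of the published
method (exponential fits to branch-length classes selected by AIC), not
its exact implementation; results can differ from the published binary.

A known behavior of this model family: selecting the best of
exponentially many delimitations against a 2-point AIC penalty overfits
heterogeneity in small i.i.d.-branch-length trees, so the null model is
*not* reliably selected on single-regime trees (we measured ~28% null
selection on 8-leaf trees by exhaustive minimization). Recovery is instead
excellent when the two regimes genuinely differ (≥ 100× rate ratio).

## Junction-based comparators

Two annotation-based delimiters, using the simulator's ground-truth
V/J calls (oracle annotation — the clustering rule itself is what is being
benchmarked; alignment-based annotation is out of scope):

* **identical** — group by (v_call, j_call), then exact junction-string
  equality defines families;
* **threshold** — group by (v_call, j_call, junction length), then
  single-linkage clustering on normalized Hamming distance between
  junctions, merging at distance ≤ threshold (default 0.15, i.e. 85%
  junction similarity, the conventional human-repertoire cutoff).

Records of different junction lengths are never merged in threshold mode.
An allele-normalization option strips `*suffix` text from V/J calls for
external AIRR data.

## Evaluation metrics

For each focal sequence, every other sequence is classified by
(same/different true family) × (same/different inferred family), giving
per-focal TP/FN/FP/TN with the focal excluded from its own counts (so
`tp + fn = true family size − 1`, which keeps singleton focals
well-defined). Precision `tp/(tp+fp)`, recall `tp/(tp+fn)`, specificity
`tn/(tn+fp)` and F1 `2tp/(2tp+fp+fn)` are averaged over all evaluated
sequences to give one value per repertoire. 0/0 ratios default to 1
(nothing wrongly merged / nothing to recover) and are configurable.
Inferred singletons are removed by default, and both partitions are then
restricted to the surviving ids so averages run over a common universe;
sequences a method failed to return can first be re-classified as
singletons. Family counts, median family sizes (even-sized lists: mean of
the central pair) and the MSE of the median family size across repertoires
complete the report.

## Ancestral reconstruction check

For each inferred family with more than two sequences: Hamming distances →
neighbor joining → midpoint rooting → per-site marginal ML root state under
Jukes–Cantor via the pruning recursion, ties broken lexicographically
(A < C < G < T) → Hamming distance and similarity (`1 − hamming/length`)
against the true naive sequence. The reconstruction model matches the
simulator's substitution process, so the check isolates the effect of
delimitation errors rather than model misspecification; a GTR model and
joint reconstruction are out of scope. Families of ≤ 2 sequences are
skipped with a recorded reason. Families mixing true families of different
lengths are projected onto their longest member by global alignment;
projected-gap columns are treated as missing data and excluded from
scoring. Only midpoint-rooted reconstruction is implemented (it was the
better-performing variant; unrooted input is out of scope).

## Experiment grid

`GridConfig` crosses SHM rates (default 0.001, 0.005, 0.01, 0.05, 0.1,
0.2) with mean family sizes (default 10, 20, 50, 100) at 16 families per
repertoire; 50 replicates per configuration gives the full 1200-repertoire
design. Replicates-per-cell is explicit (`n_replicates`). Each cell's seed
is the first 4 bytes of SHA-256 over `master_seed|rate|mean|replicate`,
so seeds are stable under reordering of config lists and reruns are
byte-identical. Cell failures are logged and recorded in the manifest
without aborting the grid.

## Problem sizes used by the bundled checks

The test suite and the acceptance script run desk-scale versions of the
design: single repertoires of 16 families at mean 10 leaves for the
specificity and self-evaluation checks; 100 replicate repertoires at
SHM 0.2 and mean 50 leaves (the mid-grid size, where families are large
enough for exact-junction survivors to be counted meaningfully) for the
oversplitting trend; 100 random ≤ 10-leaf trees for search-vs-enumeration
equivalence; and 100 two-regime trees of 8 families × 6 leaves for family-
count recovery. The synthetic germline used throughout is 20 V / 10 D /
6 J genes — large enough that distinct families essentially never share a
rearrangement, small enough to keep runs fast.

## Known limitations

* The PTP likelihood is the operational branch-length formulation, not the
  published tool's branching-process likelihood or its MCMC support
  values.
* Oracle V/J annotation sidesteps annotation error, which on real data is
  a major failure source for the junction-based methods.
* Substitution-only SHM means within-family junction-length variation —
  which threshold clustering cannot merge — never occurs in simulation.
* The edit-distance model for mixed-length repertoires is a stand-in for a
  proper multiple sequence alignment.
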