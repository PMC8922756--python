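# Methods

Models, default parameters, simulator scope, numerical choices and known
limitations of `plastidscape`. All defaults below are the package-wide
study conditions; they are set once in `SimulationConfig` /
`PipelineConfig` and never adjusted per run.

## 1. Synthetic data generator (`plastidscape.simulate`)

The generator plants known structure so that every downstream estimator
can be validated against ground truth.

**Species trees.** Yule (pure-birth) trees via dendropy's birth–death
sampler with death rate 0, conditioned on the number of extant tips
(default 12, labelled `t1..tN`). Tip edges are extended so all tips are
contemporaneous, then the tree is rescaled to height 1.

**Gene trees and discordance regimes.** A regime is a pair
`(n_genes, spr_moves)`. For each regime, `spr_moves` random
subtree-prune-and-regraft (SPR) moves are drawn *once* from a
regime-specific random stream and applied to a copy of the species tree;
every gene in the regime shares that perturbed backbone and receives
independent multiplicative branch-length jitter (lognormal, σ = 0.25).
Sharing the backbone is what makes regimes form separable locations in
Robinson–Foulds tree space — with per-gene independent SPR draws the
regimes form concentric shells around the species tree and are not
clusterable by any distance-based method. Each SPR move is constructed to
change the unrooted topology: regraft edges that would recreate the
pruned arrangement are excluded, and moves that would leave fewer than
three leaves outside the pruned subtree are rejected. Default regimes:
`[(20, 0), (20, 2), (20, 6)]`.

**Nucleotide alignments.** HKY (κ = 2) simulation along the gene tree
with stationary GC set to the target (default 0.38, an AT-rich plastome
value); branch lengths are rescaled so the root-to-tip height equals the
configured expected substitutions per site (default 0.05). Gene lengths
are drawn uniformly from a range (default 600–1200, rounded to codons).

**Codon alignments.** Single-nucleotide proposals along the tree;
proposals creating stop codons are always rejected, so sequences never
contain internal stops. Selection is imposed by two-sided thinning: for
ω ≤ 1 nonsynonymous proposals are accepted with probability ω; for
ω > 1 synonymous proposals are accepted with probability 1/ω. This makes
ω > 1 genes simulable (the positive-selection analogue used in the
acceptance checks). Realized ω carries a small negative bias
(≈ −3 % to −13 % over ω ∈ [0.1, 2] in calibration runs) because
multiple hits within a codon are not modelled exactly; the acceptance
criterion (±20 % median bias) absorbs this.

**Plastomes.** Circular layout LSC + IRb + SSC + IRa written as linear
GenBank-style records; IRa is the exact reverse complement of IRb
(default 25 kb), optionally contracted at the SSC end. 30 protein-coding
genes are planted in the single-copy regions, plus 2 genes duplicated in
the IR. SSRs are overwritten into intergenic single-copy background at
fixed positions (`A×12` at 2000, `AT×8` at 4500, `AGAT×4` at 6000 by
default), with flanking bases adjusted so no run extends beyond the
planted repeat. A configured `delete_gene` is removed from the last
record of a plastome set, planting exactly one loss event. Ground truth
(IR coordinates, SSR positions with canonical motifs, gene sequences) is
returned alongside every record.

## 2. Plastome characterization (`plastidscape.plastome`)

**Quadripartite detection.** Exact inverted repeats are found by k-mer
(k = 31) seed-and-extend against the reverse complement; the longest
repeat ≥ `min_ir_len` (default 1000 bp) defines the IR pair. The shorter
single-copy segment between the copies is labelled SSC; IRb is the copy
preceding the SSC. Junctions are reported as JLB, JSB, JSA, JLA with the
nearest gene, its signed offset, and — when a gene spans the junction —
the overlap in bp.

**Gene presence/absence.** A gene × taxon matrix from CDS features; a
*loss event* is a gene absent from a taxon but present in over half of
the taxa (so unique absences are losses, rare genes do not flag every
other taxon).

**Extraction.** CDS extraction honours strand, multi-interval `join`
coordinates and IR duplication (identical IR copies are reported once;
diverged copies are suffixed `_1`/`_2` with a warning; internal stop
codons warn but do not fail).

## 3. Sequence statistics (`plastidscape.seqstats`)

Nucleotide diversity π is the mean pairwise difference proportion with
pairwise deletion of gaps/N; segregating sites S counts columns with ≥ 2
distinct unambiguous bases; Pv = S / aligned length. The sliding-window
profile uses window 600 bp and step 100 bp; divergence hotspots are
maximal runs of adjacent windows with π strictly above 0.006. (Under the
simulator's default divergence of 0.05 substitutions/site the whole
concatenation exceeds this threshold; the threshold targets the much
lower within-genus divergence of real plastomes and is kept fixed rather
than tuned to the simulator.) SSR scanning reports maximal perfect
repeats of motif size 1–6 with minimum unit counts 10/5/4/3/3/3, motifs
canonicalized to their lexicographically smallest rotation, aperiodic
motifs only, and greedy longest-first overlap resolution.

## 4. Substitution rates (`plastidscape.molevol`)

Nei–Gojobori (1986) dN/dS: synonymous site fractions count mutations to
stop codons as nonsynonymous (so every codon has exactly 3 sites);
pairwise differences are averaged over all mutational pathways that
avoid stop codons; proportions are Jukes–Cantor corrected. Codons with
gaps, N, or stops in either sequence are skipped pairwise. ω is NaN when
dS = 0 or a proportion saturates. Genes with dN below `DN_FLOOR` =
0.0003 are flagged `low_dn` (their ω is numerically unstable). Group
comparisons use Welch's t-test on per-gene ω with standard significance
stars; groups with n < 2 are excluded with a warning.

## 5. Gene and species trees (`plastidscape.genetrees`)

Pairwise distances (p, JC69 — the default — or K2P) with pairwise
deletion; saturated pairs get ∞ and neighbor-joining refuses them naming
the pair. Bootstrap supports come from 1000 column resamplings (seeded,
deterministic); edges below 33 % support are collapsed into polytomies.
The species tree maximizes the quartet score (number of gene-tree
quartets matching the candidate): exhaustive over all unrooted
topologies for ≤ 9 taxa, greedy NNI hill-climbing from the
concatenation-style majority structure above that. Robinson–Foulds
distances are computed on canonical bipartition sets (each split encoded
by the side not containing the lexicographically smallest shared tip),
after pruning both trees to their shared tips.

## 6. Concordance (`plastidscape.concordance`)

For each internal edge (bipartition) of the species tree, each gene tree
is classified after restriction to shared taxa: *concordant* (the
restricted bipartition is present), *conflict* (a resolved incompatible
bipartition is present; the most frequent conflicting bipartition per
edge is reported as the top alternative), or *uninformative* (the gene
tree does not resolve the edge, e.g. polytomy, missing taxa making the
restriction trivial, or support below the cutoff). Category counts sum
to the number of gene trees by construction.

## 7. Tree space (`plastidscape.treespace`)

Classical PCoA on the RF matrix: double-centering −½·J·D²·J, symmetric
eigendecomposition, coordinates = eigenvectors × √λ. RF spaces are
generally non-Euclidean, so negative-eigenvalue axes are dropped and
their total magnitude reported as the distortion diagnostic; for
Euclidean-embeddable inputs the retained coordinates reproduce the
distances to < 1e−9. Clustering is Ward agglomeration on the RF matrix
with k selected by maximum mean silhouette over k ∈ 2..8; species-tree
points can sit in the embedding while being excluded from clustering;
all-zero matrices yield a single cluster with a warning. The
gene-discordance metric GD is the Euclidean distance of each gene-tree
point to the species-tree point on the first two principal coordinates.
Cluster property reports give per-cluster medians/quartiles and pairwise
Welch tests for GC, aligned length, Pv and ω; per-cluster concatenated
re-inference reports each cluster tree's RF to reference trees.

## 8. Pipeline (`plastidscape.pipeline`, CLI)

Six stages (characterize, genestats, rates, trees, concord, space) write
TSVs under one output folder. A `manifest.json` records a SHA-256 hash
of the full config and of every output file; a stage is skipped when its
manifest entry matches the current config and all outputs verify, unless
`--force`. Stages needing absent inputs (no GenBank folder → no
characterize; no codon alignments → no rates and no tree space) are
skipped. Floats are written with `%.10g`, making reruns byte-identical
for a given seed.

## 9. Randomness and numerics

Every stochastic routine takes an explicit integer seed; derived streams
come from `numpy.random.SeedSequence([seed, crc32(key), ...])`, so
subsystems are independent and runs are exactly reproducible. No global
random state is read or written. Logs of negative arguments (saturated
distances) return ∞ rather than raising; eigenvalues within 1e−10 of
zero (relative) are treated as zero in PCoA.

## 10. Limitations

- NG86 is a counting method: no codon frequencies, no transition/
  transversion weighting in pathway counting, and known downward bias of
  ω̂ at high divergence. Likelihood methods are out of scope.
- Neighbor joining with JC69/K2P distances stands in for ML/Bayesian
  tree inference; bootstrap supports are distance-based.
- The quartet-score species tree is exact only for ≤ 9 taxa; the greedy
  NNI search above that can stop in local optima.
- The codon simulator's thinning scheme yields a slightly biased
  realized ω (see §1); alignments are simulated gapless, so indel
  handling is exercised only through hand-built fixtures.
- The IR detector finds *exact* inverted repeats; biologically diverged
  IR copies (beyond the modelled contraction) would shorten or split the
  detected repeat.
- Mean GD ordering across discordance regimes is a stochastic property:
  a 2-move backbone occasionally lands further from the species tree
  than a 6-move one, so monotonicity holds in most but not all seeds.
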