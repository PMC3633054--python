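# Methods

This note documents the models, the numerical choices, and what the
synthetic-data experiments do and do not establish.

## The DNA compressor and its size functionals

The compression distances only ever consume three sizes — `C(x)`,
`C(xy)`, `C(x|y)` — so the compressor produces sizes, never a decodable
bitstream. It is a deterministic exact-match LZ77 parser with an
unbounded window over 2-bit-coded nucleotides:

* at each position the longest match against the already-processed text
  is sought (hash chains over 4-mers); ties in length are broken toward
  the smallest offset;
* a match of length ≥ 4 costs `1 + γ(offset) + γ(length)` bits, where
  `γ` is the Elias-gamma code length (`2⌊log₂ v⌋ + 1`);
* an A/C/G/T literal costs 3 bits (flag + 2 code bits); any other byte
  costs 10 bits (flag + escape + 8 raw bits), so sequences rich in `N`
  or other ambiguity codes compress badly — deliberately, since that is
  the behaviour of DNA-optimised dictionary compressors on non-ACGT
  input, and it is why dataset QC reports the fraction of sequences with
  undefined bases;
* `C(xy)` parses the plain concatenation; `C(x|y)` parses `x` with the
  match window preloaded with `y`, counting only the bits of `x`'s
  tokens.

Sizes are held in bits. The distances are ratios of sizes, so the unit
cancels; nothing downstream depends on bits versus bytes.

Consequences of this fixed cost model worth knowing. Random DNA parses
at ~4 bits/base, above the 2-bit i.i.d. baseline, because short spurious
matches (length 4–5 are abundant in any ~1 kb window) cost more than
the literals they replace; NCD of unrelated 650-mers therefore lands
slightly above 1 (values up to ~1.1 are normal for real compressors).
Similarly `C(x|y)` for an unrelated dictionary `y` exceeds `C(x)` by a
~10–25% offset surcharge (the search window doubles, so matched tokens
pay larger γ(offset)), rather than being equal to it. Both effects
cancel out of the *ordering* of distances, which is all that tree
building uses; the monotonicity of NCD and IBD in true divergence is
tested directly.

Asymmetry: `C(xy) ≠ C(yx)` and `C(x|y)` is directional, so the matrix
builder stores the mean of the two orientations and forces the diagonal
to zero, which is what NJ/UPGMA require. Gaps are stripped before
compression — the method's point is that it needs no alignment.

## Evolutionary distances

Kimura 2-parameter, Tajima–Nei (1984), Tamura 3-parameter (1992) and
Tamura–Nei (1993) are the standard closed forms over the transition
(`P`, split into A↔G and C↔T for TN93) and transversion (`Q`)
proportions, with pairwise deletion of any column holding a gap or
non-ACGT character in either sequence. Conventions follow the MEGA
family of tools: Tamura-3 uses `c = θ₁ + θ₂ − 2θ₁θ₂` over the two
sequences' G+C contents, and TN93 pools base frequencies over the pair.
(`ape::dist.dna` parameterises T92/TN93 slightly differently, so
cross-library agreement is exact for K2P and ~10⁻³ for the other two;
the tests pin both facts.)

Saturated pairs (a logarithm argument ≤ 0) raise an error and the
affected replicate is skipped with a logged reason rather than imputed —
silent imputation would bias the tree comparison. Rates are uniform
across sites; a gamma-shape parameter is exposed on TN93 but unused by
the pipeline defaults.

MCL estimates all pairwise distances and the shared TN93 parameters
(two transition/transversion rate ratios; base frequencies pooled over
the whole alignment) jointly, by maximising the sum of pairwise
log-likelihoods of the observed 4×4 divergence matrices. The optimiser
alternates bounded 1-D distance updates (initialised at the closed-form
TN93 value) with a Nelder–Mead update of the two rate ratios, until the
composite log-likelihood changes by < 10⁻⁸ (max 500 sweeps). Parameter
recovery and the collapse to K2P at equal frequencies are tested.

## Tree building

NJ (Saitou–Nei Q-criterion) and UPGMA (average linkage, node height =
cluster distance / 2) are implemented directly so that determinism is
guaranteed: ties in the Q-matrix and in the minimum search break toward
the lowest (row, column) pair in node-creation order, and negative
intermediate NJ branch lengths are clamped to 0 (the common MEGA/ape
behaviour). Trees are `dendropy.Tree` objects; NJ returns an unrooted
tree with a trifurcating seed node, UPGMA a rooted ultrametric tree.
Independent cross-checks: scikit-bio's NJ and scipy's average-linkage
agree with both on random matrices, and NJ reproduces additive matrices
exactly.

## Topology comparison

Robinson–Foulds is the symmetric difference of the informative split
sets (standard definition; rooted trees are unrooted for splitting, and
a degree-2 root contributes its split once).

The topology-similarity score follows Nye-style tree alignment: every
edge of the unrooted view — pendant edges included — induces a
bipartition; a pair of edges scores
`max over side-pairings of min(J(A₁,A₂), J(B₁,B₂))` with `J` the
Jaccard index; a maximum-weight one-to-one matching between the two
edge sets (Hungarian algorithm) is summed and divided by the larger
edge count. Identical topologies score exactly 1, and the score equals
1 only then.

Including pendant edges is a deliberate design choice. Edge-alignment
methods of this family align *all* branches, and a pendant branch
always finds its perfect partner, so the all-edge score rewards the
(large) agreeing periphery of two mostly-concordant trees instead of
scoring only their contested core. Restricting the same formula to
internal edges shifts the whole scale down by roughly 0.1 on the
simulated study (e.g. NJ means drop from ~0.86 to ~0.70) while leaving
orderings intact; the all-edge form is the one whose absolute values
line up with published edge-alignment scores. Brute-force enumeration
of all matchings verifies the assignment on small trees.

## The simulator

One replicate is: Yule species tree → multispecies-coalescent gene
tree → branch noise → HKY sequences. Defaults are the study conditions.

* **Yule**: pure-birth, waiting time Exp(k·λ) at k lineages (λ
  arbitrary), grown to the target tip count plus one final interval,
  then rescaled linearly so the root-to-tip depth is exactly the
  configured 10⁶ generations. The pre-rescale waiting-time law is
  tested against the analytic expectation.
* **Coalescent**: within each species-tree branch, each pair of the k
  resident lineages coalesces at rate `k(k−1)/2 / (2Ne)` per generation
  (diploid 2Ne convention, Ne = 10⁴ by default; the ploidy factor is a
  config switch); survivors enter the parent population, and the root
  population runs to completion. Pairwise TMRCA within one population
  has mean 2Ne, which the tests verify to 5%.
* **Noise**: every branch length ℓ becomes `ℓ + ε`,
  `ε ~ N(0, 0.7·ℓ)` independently; results below 10⁻⁸ × tree height are
  clamped (count logged). On branches of ~10⁵ generations this is a
  sub-percent perturbation, but short coalescent branches are perturbed
  appreciably and the gene tree stops being ultrametric.
* **HKY**: the generator is built from the stationary frequencies
  (0.3, 0.2, 0.2, 0.3) and a rate-ratio κ derived from the expected
  ts/tv ratio R = 3 via `κ = R·πRπY/(πAπG + πCπT)` (κ = 6.25 here),
  normalised to one expected substitution per site per unit branch
  length. The root sequence is drawn i.i.d. from π and each branch
  applies `exp(Qℓ)` site-independently; 650 bp, no indels, so the
  output is alignment-ready.
* **Time scale**: the protocol fixes the species-tree depth in
  generations but no mutation rate. The default conversion puts 0.1
  expected substitutions/site on the root-to-tip path (rate
  10⁻⁷/site/generation), which yields K2P distances in the range
  typical of COI barcodes (within-species diversity ~0.002, maximal
  between-species distances ~0.2–0.4). It is configurable
  (`root_to_tip_subs`).

Determinism: every stage of every replicate draws from
`SeedSequence(master_seed, spawn_key=(replicate, stage))`, so a single
replicate is reproducible in isolation and whole runs are
byte-identical. Replicates are fully independent (fresh species tree,
gene tree, noise and sequences each), so the 25-replicate mean
estimates the marginal expectation over the whole generative protocol
rather than being conditional on one tree draw.

## What the simulations do and do not show

The generator emulates clock-like speciation, neutral coalescent
population structure, and stationary HKY evolution without rate
heterogeneity, indels, selection, or sequencing artefacts. Simulated
sequences are gap-free, equal-length and fully defined, so the
evolutionary estimators see a perfect alignment and the compressor sees
ideal input. Passing the simulated-study checks therefore shows that
compression distances recover model-based tree structure under the
stated generative model; it says nothing about alignment quality,
heterogeneous rates, or the degraded compression of real records with
many undefined bases — the QC report and the high-undefined warning in
the real-data path exist precisely because those regimes are known to
hurt (datasets with ≳30% undefined-base sequences score visibly lower).

## Problem sizes and runtime

The default acceptance computation runs the 100- and 150-sequence
conditions at 25 replicates each (~4950 and ~11 175 pairs per
replicate, two parse orientations per pair) in about half a minute on
one CPU; the full five-model × two-distance × two-algorithm study grid
scales linearly in the number of evolutionary models, with MCL the only
expensive estimator (joint optimisation; intended for datasets of tens,
not hundreds, of sequences). Statistical unit tests use replicate
counts (2000–5000) at which their analytic expectations are resolved a
few times more finely than the asserted tolerances.

## Degenerate inputs and edge handling

Identical sequences give zero evolutionary distances and small positive
compression distances; both matrices are valid and the pipeline scores
them without special-casing (the resulting trees are tie-broken
deterministically). Empty sequences, empty FASTA files, duplicate
labels, non-symmetric or NaN matrices, mismatched leaf sets and
malformed Newick all raise immediately with the offending item named.
A cell of the study table with more than 20% skipped replicates is
flagged unreliable rather than silently averaged.
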