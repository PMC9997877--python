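# Methods

## Signal model

A DNA sequence of length N over {A,C,G,T} plus IUPAC ambiguity codes is
represented by four binary indicator vectors (Voss representation): the
base-b vector is 1 exactly where the residue is b. Ambiguous residues
(N, R, Y, …) contribute 0 to all four vectors — fractional schemes such as
R → ½A + ½G would break the binary definition, and real genomic spans can
carry hundreds of N's, so the rule is explicit rather than incidental.
The encoding is lossless at unambiguous positions.

Each indicator x[n] is discrete-Fourier transformed,
X[k] = Σ_{n=0}^{N−1} x[n] e^{−j2πkn/N} (computed by FFT; the contract is
agreement with the defining sum to 1e−8, which the tests enforce against a
naive O(N²) oracle), and squared into the power spectrum P[k] = |X[k]|².
Useful identities, all enforced as test invariants: X[0] equals the base
count; X[N−k] = conj(X[k]); Parseval, Σ x[n]² = (1/N) Σ P[k]; and |X[k]|
is invariant under cyclic shift and reversal of the sequence.

## Power-spectrum moments (PSM)

Sequences of different lengths have spectra on different frequency grids,
so each spectrum is condensed to a fixed-dimension moment descriptor over
the normalized frequency f = k/N. Per base b the block is
[T_b, m_1, …, m_J], J = 3 by default, 4·(J+1) = 16 features per sequence:

- **T_b = (Σ_{k=1}^{N−1} P_b[k]) / N** — normalized total AC power. For a
  binary vector with c ones this equals c(N−c)/N, so it carries the
  composition (and scales with length); the DC bin, which is pure
  composition squared, is excluded and enters only through this term.
- **m_1** — the spectral centroid Σ_k w[k] f[k], with weights w[k] the
  power over the *unique half* of the spectrum, k = 1 … ⌊N/2⌋, normalized
  to sum to one.
- **m_j, j ≥ 2** — signed j-th roots of the central moments
  Σ_k w[k] (f[k] − m_1)^j: a spread (j = 2) and skew (j = 3) analogue in
  normalized-frequency units.

Two design points deserve emphasis. First, the restriction to the half
spectrum is not cosmetic: conjugate symmetry gives P[k] = P[N−k], so any
moment over the full range k = 1…N−1 is pinned by the symmetry — the
full-range centroid is exactly 1/2 for *every* sequence and the higher
full-range moments are equally degenerate. Second, the j-th root (rather
than standardized moments like skewness = μ₃/σ³) keeps all entries in
[−1/2, 1/2], avoids the 0/0 of standardized skew on point-mass spectra,
and keeps every moment in the same frequency units. The cost is Hölder-1/3
continuity near zero: cancellation noise of order 1e−16 in a near-zero
third central moment surfaces at order 1e−5 in m_3, which is why the
shift/reversal-invariance tests assert 1e−4 rather than machine precision
(negligible against between-sequence differences, which sit at 1e−3 and
above). A plain non-central variant (m_j = Σ w f^j) remains available as
`kind="raw"`; `include_dc=True` admits the k = 0 bin into the weights.
Absent bases yield all-zero blocks.

## Distances and standardization

Distances are Euclidean in feature space. By default the feature columns
are z-scored across the dataset first (`--no-standardize` disables this).
The default is deliberate: T_b grows like length × composition variance
(hundreds, for kb-scale sequences) while the moments are normalized
frequencies below 1/2, so unstandardized Euclidean distance is numerically
a pure composition-and-length comparison and the spectral shape terms are
dead weight. Standardization puts the four composition terms and the
twelve shape terms on a common scale. Note the corollary: *without*
standardization, grouping is driven by length and base composition, which
reproduces the qualitative behaviour one sees on real gene panels where
clusters track gene length.

## Clustering

Agglomeration is Lance–Williams over the four classical updates: single
(minimum), complete (maximum), average/UPGMA (size-weighted mean) and
median/WPGMC (α = ½, ½, β = −¼ applied to squared distances). Median
heights are computed in squared space and square-rooted for reporting so
all four trees share the input distance scale; median is the one method
whose heights may invert, which the tree type tolerates and the Newick
writer handles by clamping negative branch lengths to zero with a warning.
WPGMC and "median" are the same method under two names and both are
accepted.

Determinism: among candidate pairs whose distance lies within a 1e−9
relative band of the minimum, the lexicographically smallest
(node-index, node-index) pair merges. The tolerance band makes the rule
robust to summation-order rounding when distances are mathematically tied
(e.g. equal averages of integer distances), so an independent from-scratch
agglomerator reproduces merge-for-merge identical output — the test suite
checks exactly that, plus cophenetic agreement with SciPy's hierarchy
module on tie-free inputs.

Trees are cut either to a target number of clusters k (undoing the last
k−1 merges; labels numbered by first leaf appearance) or at a height
threshold. The default k = 4 mirrors the four-group structure of the
motivating gene-panel analysis and is a flag, not an assumption. Dynamic
or hybrid tree cutting is intentionally out of scope.

## Evidence accumulation

Each base partition votes on every pair; the vote average is the
co-association matrix C (diagonal 1, entries on the grid {0, 1/M, …, 1}
for M base clusterings). The consensus tree is average-linkage clustering
of 1 − C — average linkage is the conventional learner in the
evidence-accumulation literature and is flag-selectable — and the
consensus partition is that tree cut at the same shared k. Partitions
(cut trees), not full dendrograms, are fused. With identical bases the
consensus reproduces them exactly; with noisy bases the consensus is at
least as close to every base as the most discordant pair of bases are to
each other (both properties are tested).

## Synthetic data generator

`simdata` emulates a panel of gene families at desk scale: per family an
i.i.d. random ancestor with P(G or C) = `gc_bias` (default 0.5 — neutral
composition, which is also the hardest case for composition-driven
separation), and per member i.i.d. substitutions at `substitution_rate`
plus per-site indel events at `indel_rate` with geometric(0.5) lengths.
Indels make member lengths unequal on purpose — the length-invariance of
the PSM descriptor is the method's central claim, so fixtures must not be
length-matched. Defaults: 4 families × 6 members, 3 kb ancestors, 2%
substitutions, 0.2% indel events, seed 20230309; at these settings the
default pipeline recovers the families exactly (ARI = 1), and recovery
degrades gracefully as substitutions increase (ARI ≥ 0.8 still at 5%).

What the generator does *not* emulate: realistic substitution processes
(no transition/transversion bias, no rate heterogeneity, no HKY/GTR),
exon–intron architecture, repeats, or ambiguity codes. Passing the
recovery tests therefore shows the pipeline separates families whose
spectra differ by accumulated point mutations and small indels — it does
not certify performance on real genomic panels, where divergence is
structured and composition biases are confounded with biology.

## Numerical and interface choices

- FFT via numpy; any algorithm agreeing with the defining sum is
  acceptable.
- GC% uses the ambiguity-inclusive denominator 100·(G+C)/length (the
  exclusive variant is a flag) and renders half-up to one decimal; full
  precision is kept internally.
- Distance matrices are written as square PHYLIP-style text at full float
  precision (round-trips below 1e−9); other tables at 10 significant
  digits. Reruns are byte-identical, and the run manifest records content
  hashes.
- Degenerate inputs: length-1 sequences transform but have no AC spectrum
  and are rejected by the moment stage (N ≥ 2 required); homopolymers and
  absent bases yield zero feature blocks; k outside 1…n is a validation
  error.

## Limitations

Moment descriptors are lossy: two spectra can share low-order moments
while differing in fine structure, so resolution degrades as sequences
diverge toward saturation. The method sees only sequence — no annotation,
synteny or expression — and its clusters are hypotheses for functional
follow-up, not homology calls. Median linkage's height inversions make
its dendrogram heights non-metric; they are reported as computed, with
clamping confined to Newick export.
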