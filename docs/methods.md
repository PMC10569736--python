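# Methods

This note documents the models implemented in phagekit, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical conventions and known limitations.

## Capsid geometry and packing density

The capsid is modelled as a regular icosahedron. TEM protocols that measure
the "diameter of the circle circumscribing the capsid" report the
vertex-to-vertex diameter, so the measured value is interpreted in the
circumscribed convention; values reported in other conventions are first
converted with the exact icosahedron ratios (circumradius 0.95106 a,
midradius 0.80902 a, inradius 0.75576 a for edge a). The DNA-filled cavity
is an icosahedron whose circumradius is the measured circumradius minus one
uniform shell thickness `t`:

    R_int = D/2 − t,   V_int = (5/12)(3+√5) a³,  a = 4 R_int / √(10+2√5),
    ρ = L / V_int   [bp/nm³].

`t` is a single free parameter. Published protein-shell thicknesses for
tailed phages vary by lineage, so the default is obtained by calibration:
1-D root finding (Brent, tolerance 1e-6 nm) of `ρ(t) = ρ_anchor` on one
anchor phage. Density is strictly increasing in `t`, so the root is unique
within any bracketing bounds. With the anchor Bc01 (D = 94 nm,
L = 100,841 bp, ρ = 0.54 bp/nm³) the calibrated value is t ≈ 5.09 nm, and
this single value predicts the densities of the other two isolates
(0.48, 0.56 bp/nm³) to two decimals — the model's joint-consistency check.
Reported densities are kept at full precision and rounded half-up to two
decimals only for comparison with published values. Measurement SD is
propagated by evaluating the density at D ± SD; no distributional assumption
is made.

The exact inscribed→circumscribed diameter correction is
0.95106/0.75576 − 1 = 25.8 %. Discussions of capsid sizing sometimes quote a
correction near 22 %; no icosahedral radius pair gives exactly that value
(circumscribed/midsphere is 17.6 %), so the exact ratios are implemented and
this discrepancy is simply documented.

## Cophylogenetic congruence test

Host and parasite distance matrices may come from MSAs (p-distance with
pairwise gap deletion by default — the default of the EMBOSS distmat tool
commonly used for this step — or Jukes-Cantor) or be supplied directly.
Both are made Euclidean-embeddable by the Cailliez correction: the smallest
constant `c ≥ 0` added to all off-diagonal distances such that principal
coordinates analysis yields no negative eigenvalues, computed as the largest
real eigenvalue of the standard 2n×2n companion matrix built from the
Gower-centred forms of −D²/2 and −D/2. PCoA uses Gower double-centring and
a symmetric eigendecomposition; axes with eigenvalue below 1e-8 × the
largest are dropped.

With host coordinates `B`, parasite coordinates `C` and binary links `A`
(parasite × host), the global statistic is the squared Frobenius norm of
`CᵀAB`. The null hypothesis of random association is simulated by
independently permuting, for each parasite, its row of `A` across hosts —
the same scheme as `ape::parafit`, against which the statistic is verified
in the test suite. The p-value uses the (x+1)/(N+1) estimator, upper tail;
a fixed seed makes the result bit-reproducible. For small systems an
exhaustive-enumeration routine computes the exact p over the scheme's full
product null space (4⁴ states for four one-to-one links), which the
Monte-Carlo p converges to.

Per-link tests (ParaFitLink1/2) and tree inference are out of scope; the
test operates purely on distances and links.

## Codon-based selection test

Sites are classified per codon position by degeneracy: 0-fold (no
single-base change synonymous), 4-fold (all three synonymous), else 2-fold;
changes to stop codons count as nonsynonymous for classification. For a
sequence pair, per-class site totals `L0, L2, L4` are means over the two
sequences across pairwise-complete codons (gapped or ambiguous codons
dropped). Differences at codons differing in 2–3 positions are averaged
over all minimal mutational pathways that avoid stop codons, equally
weighted (verified against brute-force enumeration over the whole codon
table); when the degeneracy of the changing position differs between the
two codons of a step, half a count goes to each class. Per class,
transitions `P_i` and transversions `Q_i` feed the Kimura two-parameter
components `A_i` (transitional) and `B_i` (transversional), and

    dS = (L2·A2 + L4·K4) / (L2/3 + L4),
    dN = (L2·B2 + L0·K0) / (2·L2/3 + L0),     K = A + B.

Saturated pairs (non-positive logarithm argument) are flagged invalid and
excluded. The z-test of strict neutrality averages dN and dS over all valid
pairs; the standard error of the difference comes from resampling codon
columns with replacement (default 100 bootstrap replicates, seeded) and the
p-value from the normal distribution, one- or two-tailed. The tail is an
explicit argument with no default: published analyses sometimes state a
positive-selection alternative while concluding purifying selection, so the
direction must be chosen deliberately.

**Known limitation.** Under a faithful stop-free neutral codon process
(ω = 1) this estimator is intrinsically biased: stop-adjacent positions
depress the realized nonsynonymous rate relative to their site counts, and
the anomalous Leu/Arg twofold sites (where the transition is nonsynonymous
and a transversion synonymous) inflate dS. The expected estimate is
dN/dS ≈ 0.95, so at 10 sequences × 300 codons and pairwise divergence
0.2 subs/site the neutrality z is centred near −0.65 and the two-sided
type-I error is ≈ 0.09 instead of 0.05. This is the historical motivation
for the 1993 revisions of the method (Li; Pamilo–Bianchi); the original
estimator is implemented as specified and the bias is reported, not
patched. Power against purifying selection (ω = 0.2) exceeds 0.99 at the
same size, and the pooled dN/dS recovers ω = 0.2 within ±0.05 at 3,000
codons.

## Orthogroups, ANI and the species rule

Orthogroup inference is consumed, not re-implemented: the input is an
OrthoFinder-dialect table. Host-exclusive orthogroups are those whose every
contributing genome maps to the given host and that span at least
`min_genomes` (default 2) genomes. Duplication retention is the fraction of
member genomes holding ≥ 2 copies; the flag uses an inclusive ≥ 0.5
threshold.

ANI follows the classic fragment scheme: the query is cut into 1,020-bp
consecutive fragments (a trailing remnant shorter than the 15-bp seed is
merged into the previous fragment so self-comparison is exactly 100/100).
Each fragment is placed on the reference by exact 15-mer diagonal voting
(probe step 7, band width 100 bp, at most 8 reference positions per k-mer)
and aligned end-to-end within the winning band by edlib; unseeded fragments
are unaligned. Fragments with ≥ 30 % identity over ≥ 70 % of their length
are retained; identity is the mean over retained fragments and coverage the
retained fraction of the query. All four parameters are exposed. Expected
shared-15-mer counts between unrelated 50-kb sequences are ≪ 1, so
unrelated genomes yield near-zero coverage, while 2 % divergence leaves
ample seeds and identity ≈ 98 %. The species rule is inclusive:
same species iff identity ≥ 95 % and coverage ≥ 85 %; undefined identity
(no retained fragment) yields an indeterminate call rather than "different".

## Genome triage

Candidates must exceed 90 kb strictly, carry the viral flag, and be
classified exactly "complete" (CheckV vocabulary). The winner per sample is
the highest-coverage candidate; ties break by length, then lexicographic
contig id (ties never arise in real coverage data; the rule just makes the
function deterministic). The output depends only on the input multiset.

## Synthetic generators

- **Codon alignments**: a continuous-time Markov process on the 61 sense
  codons, single-base exchanges only, transition rate κ, nonsynonymous
  changes scaled by ω, uniform codon frequencies, evolved on a star tree
  from a uniform random ancestor via one matrix exponential. Defaults:
  10 sequences × 300 codons, branch length 0.1 substitutions/site (pairwise
  divergence 0.2, typical of cross-genus orthogroup comparisons), κ = 1.
  κ defaults to 1 because under degeneracy-class counting a transition bias
  makes even a truly neutral process measure dN ≠ dS, which would conflate
  estimator properties with test calibration; κ is configurable for studies
  of that effect. The generator never emits stop codons and records the
  true ω. Not emulated: codon-frequency bias, rate variation across sites,
  recombination, non-star topologies — so calibration results transfer to
  real data only to the extent those features are negligible.
- **Cophylogenetic systems**: distances are Euclidean distances of
  standard-normal points in 3-D (guaranteeing valid metrics) rather than
  tree simulations, since only distances enter the statistic. Congruent
  mode copies the host matrix (plus optional symmetric Gaussian noise
  floored at 0) with one-to-one links; independent mode draws both
  structures independently and links each parasite to one uniform host.
- **Capsid measurements**: mean and SD of n Gaussian draws rounded to whole
  nm, matching TEM reporting precision.
- **Contig tables**: per sample one planted winner passing all criteria and
  four decoys each violating exactly one (too short, non-viral, not
  complete, lower coverage).

All generators are bit-reproducible under a fixed seed.

## Numerical conventions

- Distance matrices are validated symmetric to 1e-8 (file readers
  symmetrize with a warning up to 1e-6, reject beyond), zero-diagonal,
  non-negative.
- Cailliez constants below 1e-10 are treated as zero.
- Permutation p-values never reach zero ((x+1)/(N+1) estimator); statistic
  comparisons in the permutation tail use a 1e-12 absolute guard against
  floating-point ties.
- Sequences are upper-cased on input; U maps to T with a warning; ambiguity
  codes are allowed in genome sequences but rejected inside codon
  alignments.
- Calibration study sizes (200 independent / 100 congruent cophylogenetic
  systems at 999 permutations; 500 neutral / 100 purifying selection
  replicates) were chosen to give binomial confidence intervals tight
  enough to detect miscalibration of a 5 % test while keeping the whole
  suite fast on a single CPU.
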