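# Methods

## Model and scope

`pedident` computes single-locus, autosomal, pedigree-based relatedness
coefficients for diploid individuals, in pedigrees whose founders may carry
assigned inbreeding coefficients, and solves the inverse (constructibility)
problem of producing a finite pedigree realising prescribed coefficients.

The probability model is standard gene dropping at one autosomal locus.
Founders are mutually unrelated; a founder with assigned inbreeding
coefficient `f ∈ [0, 1]` is autozygous (carries two copies of one ancestral
allele) with probability `f`, independently of everything else, and
otherwise carries two non-IBD alleles.  Each nonfounder inherits one
uniformly chosen allele from each parent.  Two alleles are identical by
descent (IBD) when they descend from the same founder allele.  All
coefficients in the package are expectations under exactly this model, and
the Monte-Carlo simulator in `pedident.genedrop` implements the model
literally, which is why it serves as an independent oracle for every exact
computation.

The assigned founder `f` compresses an unrecorded ancestry into a single
number.  This is exact for all single-locus coefficients, which is the
package's scope; it is *not* sufficient for multi-locus (linked) IBD
coefficients, where different genealogies realising the same `f` give
different two-locus sharing (except for `f = 1`).  Founders may be inbred
but never related to each other; founder relatedness would invalidate the
all-founder boundary values and is out of scope.

## Exact coefficients

**Kinship** `φ_ab` is computed by the classical recursion, pivoting on the
argument with the larger generation index (index(child) = 1 + max of the
parents' indices, founders at 0), which guarantees the pivot is not an
ancestor of the other argument.  Boundary values: distinct founders have
`φ = 0`; self-kinship is `φ_aa = (1 + f_a)/2` with `f_a` the assigned `f`
for founders and the parents' kinship otherwise.  Wright's path formula
(sum over common ancestors `s` and non-overlapping path pairs of
`(1 + f_s) / 2^(|u|+|v|+1)`) is implemented by exhaustive path enumeration
(networkx simple paths) as an independent check, guarded to small
pedigrees.

**Generalized kinship.**  A sampling pattern is one or two groups with at
most four slots in total; its coefficient is the probability that the
alleles sampled per slot are IBD within each group.  For a nonfounder
pivot, the implementation conditions on which physical allele (paternal or
maternal) each of the pivot's slots received: each assignment replaces the
pivot's slots by at most one father-slot and one mother-slot per group, and
when both groups end up constraining the *same* physical allele their IBD
constraints merge into a single group.  Averaging the 2^k assignments
reproduces Karigl's twelve recursion rules, including the instantiations
with repeated arguments, without transcribing them line by line.  The
all-founder boundary values are: any group containing two distinct founders
is 0; k slots of one founder give 1, (1+f)/2, (1+3f)/4, (1+7f)/8 for
k = 1..4; two groups of the same founder (sizes 2+2) give (1+3f)/4; groups
on distinct founders multiply.  At `f = 0` these reduce to the classical
outbred values — a unit test asserts this reduction.

**Condensed identity coefficients.**  The nine Jacquard states are
represented as partitions of the four slots (a1, a2, b1, b2).  The 9×9
system has rows {normalization, f_a, f_b, φ_ab, φ_aab, φ_abb, φ_aabb,
φ_ab,ab, φ_aa,bb}; each matrix entry is the probability of the row's
sampling event conditional on the column's state, computed by exact
enumeration of the slot draws (fractions), not transcribed.  The matrix is
inverted once, exactly (sympy rationals), and `Δ = M⁻¹ · rhs`.  Validation:
the known φ_aab row, invertibility, and Monte-Carlo state-conditional
frequencies.  For noninbred pairs the first six states are impossible and
`(κ0, κ1, κ2) = (Δ9, Δ8, Δ7)`; requesting κ for an inbred individual is an
error naming the member.  Self-pairs go through the same machinery.

**Arithmetic.**  All recursion weights are `fractions.Fraction`, so results
are exact whenever founder coefficients are rational (the default for
parsed input); float founder values propagate to float results.  In float
mode, Δ components in `[-1e-12, 0)` are clamped to zero and the vector
renormalized; larger negativity raises.

## Constructibility

Half cousins `HC_m^f`: the pair is joined by one non-collapsing path of
`m` edges whose top member has inbreeding `f`, giving
`φ = (1 + f)/2^(m+1)`.  *Separation convention:* `m` is the total edge
count of the connecting path — operationally, the `m` for which the above
formula holds — so parent–child is `m = 1`, half siblings and
grandparent/grandchild are `m = 2`.  Builders are validated against the
formula, never against relationship names.

- `kinship_to_half_cousin` inverts the formula:
  `m = ⌈log2(1/φ)⌉ − 1`, `f = φ·2^(m+1) − 1`, with `(0, 1)` at `φ = 1` and
  infinite separation at `φ = 0`.  For dyadic `φ = 2^-k` both `(k−1, 0)`
  and `(k, 1)` satisfy the formula; the ceiling-formula output `(k−1, 0)` is
  returned and `prefer_inbred=True` selects the alternative.  The integer
  `m` is found by exact integer scaling of the rational value, never by
  floating-point logarithms; float inputs are converted exactly and snapped
  to a power of two only within 1e-9 relative noise.
- `kinship_chain` writes `φ` as a sum of distinct negative powers of two
  and `build_chain` stacks one outbred half-cousin layer per binary digit
  (layer separation `t_i − 1`; the top member of each layer is a child of
  the focal pair of the layer above; an increment of 1 collapses a layer to
  a single member, requiring selfing).  A dyadic `φ` is realised exactly;
  otherwise the expansion is truncated at `max_terms` (default 53 one-bits,
  matching double precision) and the recorded residual is below `2^(-s_k)`.
- `ibd_to_dhc` solves `κ0 = (1−φ1)(1−φ2)`, `κ2 = φ1 φ2` via the quadratic
  with `U = 1 + κ2 − κ0`, `D = U² − 4κ2 = κ1² − 4κ0 κ2`; `D < 0` beyond
  the `1e-12` tolerance means the target violates Thompson's admissibility
  inequality and is rejected; small negative `D` is clamped to the
  parabolic boundary.  Rational targets with perfect-square `D` stay exact.
  Each `φ` is then inverted to a (separation, founder-f) pair; the father
  side carries the smaller `φ` (larger separation).
- `build_dhc` joins a fathers-side half-cousin pedigree and an unrelated
  mothers-side one; the focal pair is noninbred by construction.  Infinite
  separations materialise as unrelated founders.
- The induced subdivision of the IBD triangle: `v_{i,j} =
  ((1−2^-i)(1−2^-j), 2^-i 2^-j)` and `V_{m,n}` the convex hull of the four
  neighbouring vertices.  `triangle_regions` tests membership with exact
  rational half-plane checks (boundary inclusive, so border points report
  every touching cell), searching `m, n ≤ ⌈log2(1/κ2)⌉ + 1` when `κ2 > 0`
  and handling the bottom-edge segments (`m = ∞`) and the unrelatedness
  vertex separately.  For each containing cell the bilinear weights
  `(f1 f2, f1 (1−f2), (1−f1) f2, (1−f1)(1−f2))` are returned in the vertex
  order `(v_{m,n}, v_{m,n+1}, v_{m+1,n}, v_{m+1,n+1})`, so the weighted
  vertex sum reproduces the point.
- `stationary_inbreeding(m) = 1/(2^(m+1) − 1)` is the fixed point of the
  half-cousin map `f ↦ (1+f)/2^(m+1)`; at the half-sib separation `m = 2`
  this is the classical 1/7 of sequential half-sib mating.

**Builder shape.**  Among the structurally different pedigrees realising a
given half-cousin relationship, builders always emit the canonical variant
with the path split as evenly as possible between the two sides (odd
remainder to `a`'s side); all variants carry the same coefficients, and a
fixed shape keeps outputs reproducible.  Path members take the focal sex so
a built pair can serve as the two fathers (or mothers) of a larger
construction; fresh unrelated mates are created at every step.

## Gene dropping

`genedrop` is vectorised over replicates (numpy); founder labels are
globally unique integers per founder (label equality = IBD), the
autozygosity event is an independent Bernoulli(f) per founder per
replicate, and condensed states are classified from the four labels of the
pair.  Estimates carry binomial standard errors, and agreement tests use a
4-standard-error band (with a floor of `sqrt(0.25/n)` on the SE so
zero-variance draws cannot produce a vacuous band), keeping the
false-failure rate of the suite negligible at the default replicate counts.
Identical seeds give identical results.  The simulator emulates exactly the
single-locus model the exact algorithms assume — founders unrelated,
autozygosity independent across founders and replicates — so passing
agreement tests validate the algebra, not the adequacy of that model for
linked loci or for related founders.

## Random-pedigree property suite

`random_pedigree` grows pedigrees member by member (founder with
probability 0.35, otherwise a child of two distinct existing members, no
selfing), drawing founder `f` from {0, 0, 1/4, 1/2, 1} so that exact
rational arithmetic applies.  Property tests run at up to 12 members —
large enough to produce loops, multiple common ancestors and inbred pairs,
small enough that Wright path enumeration and 10^5-replicate gene drops are
instantaneous.  Acceptance-level simulations use 10^5–2·10^5 replicates,
chosen so each Monte-Carlo check resolves the smallest tested coefficient
to a few percent.

## Known limitations

- Patterns with more than four sampled alleles are rejected.
- Founder relatedness is not representable (only founder inbreeding).
- X-chromosomal and multi-locus coefficients are out of scope.
- `triangle_regions` returns float weights for points whose discriminant
  is not a perfect square; membership itself is always exact.
- PED files hold a single pedigree; disconnected input is accepted and
  cross-component coefficients are simply 0.
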