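# Methods

## The generative model

A chitosan chain is modeled as a binary sequence over {A, D}, read from
the non-reducing end (position 1) to the reducing end (position DP).
Acetylation is an independent Bernoulli draw per position with a
position-dependent probability — a deliberately minimal model of a
probabilistic deacetylation process. Consequently the target F_A is exact
in expectation but individual chains scatter binomially (per-chain F_A
variance ≈ F_A(1−F_A)/DP); no exact-count sampling mode is offered.

### Pattern strength

The non-random patterns of interest put extra acetylation on an
every-third-position lattice (the *pattern units*). With lattice phase
r ∈ {0, 1, 2}, position i is a pattern unit when (i − r) mod 3 = 0.
Pattern units are acetylated with probability `p_pat`, all others with
`p_non`:

    p_pat = fa + s · (min(3·fa, 1) − fa)
    p_non = (3·fa − p_pat) / 2

The pattern strength s ∈ [0, 1] interpolates linearly between the two
defining endpoints — s = 0 is the fully random PA (`p_pat = p_non = fa`)
and s = 1 the strongest admissible lattice bias, which at fa = 1/3 is
exactly the ideal (DDA)ₙ repeat. The balance `p_pat + 2·p_non = 3·fa`
keeps the expected F_A equal to the target whenever DP is divisible by 3.
Linear interpolation is one admissible parametrization of the in-between
regime (only the endpoints are externally pinned down); it is the simplest
rule satisfying both endpoints with exact mean-F_A conservation, and is
documented here as the package's choice. For DP not divisible by 3 the
lattice is truncated mid-motif and the expected F_A carries an O(1/DP)
bias; at the default DP 1000 this is below 10⁻³ and is accepted rather
than corrected.

The phase r is drawn uniformly per chain by default. All statistics the
package computes (diads, triads, fragment DPs) are phase-invariant, and a
population-wide fixed phase would be an artificial alignment between
molecules; a fixed phase (`phase_mode="fixed:r"`) remains available for
deterministic fixtures.

### Capped time course

Heterogeneous deacetylation that protects pattern units is emulated by
pinning the pattern-unit acetylation probability to a cap (default 0.75)
while the overall F_A steps down: `p_pat = cap`,
`p_non = (3·fa − cap)/2`, feasible for 0 ≤ 3·fa − cap ≤ 2. Note that the
unbiased member of this family is cap = fa (then p_pat = p_non), while
cap = 3·fa is maximal bias (p_non = 0).

### Defaults

The default experiment scale is 500 chains of DP 1000. At that scale the
pooled statistics rest on 5·10⁵ units, putting binomial sampling error on
F_A near 6.6·10⁻⁴ and on the PA value near 3·10⁻³, while every pipeline
finishes in seconds on one CPU.

## Cleavage rules

A cleavage agent is a 4-tuple of requirements over {A, D, X} for the
subsites (−2, −1, +1, +2) flanking the scissile glycosidic bond, written
`LL|RR`. Site k (the bond between units k and k+1) is eligible iff every
non-X requirement matches the unit at its mapped position k−1, k, k+1,
k+2 — and that position exists: an agent must bind a real sugar at every
required subsite, so a non-X requirement falling off a chain end disables
the site (the physically conservative reading; X subsites may hang off
the end freely).

Digestion is *end-point* by default: eligibility is evaluated once on the
intact chain and all realized sites are cut simultaneously, which models a
reaction run to completion and avoids any cut-order dependence. An
*iterative* mode (cut one randomly chosen site at a time, re-evaluating
eligibility within the resulting fragments) is available for specificities
whose −2/+2 requirements can be destroyed by earlier cuts; for `DA|XX`
the two modes provably coincide, which the tests exploit as a
cross-check.

Partial cleavage is an independent Bernoulli(q) decision per eligible
site. q is exposed because chemical depolymerizations are routinely
stopped early; the partial-deamination experiment defaults to q = 0.25,
a value in the regime where the DP 7–15 window of interest is well
populated. Nitrous-acid cleavage (`XD|XX`, deaminating) additionally
relabels the −1 D-unit of each realized cut as M (2,5-anhydro-D-mannose);
M counts toward fragment DP and as a D-unit in every composition
statistic. TFA hydrolysis is modeled with the simplified absolute `XA|XX`
specificity, not the milder rate preference of the real chemistry; no
kinetics, processivity or concentration effects are modeled anywhere.

## Statistics

**DP distributions** are molar by default (each fragment counted once),
matching how simulated product amounts are naturally expressed; mass
weighting (each fragment weighted by its DP) is provided as a proxy for
refractive-index detection, which responds to mass, and is the default
only in the deamination experiment where the in vitro comparison is an RI
trace. **Triad strength** is (c₃+c₆)/(c₂+c₄+c₅) on the chosen weighting;
DP 1 and DP > 6 products are tallied but never enter the ratio, and a
zero denominator raises an error rather than returning 0 or ∞.

**Diad/triad frequencies** pool ordered adjacent pairs/triples within
chains — no wraparound, no cross-chain pairs — so
|F_AD − F_DA| ≤ (number of chains)/(total diads) by construction. The
**PA value** uses the symmetric form (F_AD + F_DA)/(2·F_A·F_D). NMR
practice often uses the directional F_AD alone; the two are
asymptotically identical (F_AD and F_DA differ by at most one transition
per chain) and the symmetric form reproduces all four calibration anchors
exactly or to O(1/DP): 0 (block-wise), 1 (random), 1.5 (ideal (DDA)
repeat), 2 (alternating).

**Block sizes** come in two routes. The direct route run-length-encodes
the chains and averages A-run and D-run lengths. The profile route uses
only a `DA|XX` digest's composition profile: each product carries exactly
one D-block, and its reducing-end A plus the next product's leading
A-units reassemble one A-block, so the number-average n_A and n_D per
product estimate the block sizes with an O(1/DP) chain-end bias. The two
routes agree within 2% at DP 1000 (tested); on random chains both match
the geometric run-length laws 1/(1−F_A) and 1/F_A.

**Analytic oracle.** For complete `DA|XX` digestion of an infinite random
chain, every interior fragment has the form AˣDʸA (x ≥ 0, y ≥ 1), giving

    P(DP = n) = Σ_{y=1}^{n−1} fa^(n−y) (1−fa)^y ,  n ≥ 2

with mean fragment DP 1/(fa·(1−fa)). The simulated digest matches this
law with max absolute deviation < 0.01 per DP at the default scale; the
residual deviation is the chain-end effect (one first fragment per chain,
≈ 0.5% of products at DP 1000, does not follow the interior law).

## What the synthetic populations do and do not capture

The generator emulates sequence-level structure only: monodisperse DP,
Bernoulli composition, a single three-periodic bias family. Real
chitosans have broad DP and per-chain-F_A dispersity, possible block
structure from crystalline-phase deacetylation, and products are observed
through SEC separation, RI response and ionization efficiency — none of
which are modeled (mass weighting is the only detector proxy). Passing
tests therefore validate the method's behavior on its stated sequence
model, not quantitative agreement with any particular instrument trace;
in vitro triad strengths depend on real samples and detection physics and
are out of scope.

## Numerical and design notes

* All randomness flows through `numpy.random.default_rng(seed)`; child
  seeds for multi-run experiments derive from one master seed via
  `SeedSequence`, so every table is bit-reproducible from config + seed.
* `generate_random` delegates to the patterned generator with s = 0, so
  both share one PRNG policy and coincide stream-for-stream.
* Derived probabilities are validated into [0, 1] with a 10⁻¹² tolerance
  against floating-point spill before clamping.
* Landscape cells whose digest yields no DP 2/4/5 products report NaN
  (missing), never 0.
* Undefined statistics (PA of a homopolymer, block size of a run-free
  population) raise or report absent values explicitly.
* Experiment tables are long-format (fa, s, spec, metric, value,
  n_chains, seed), one row per statistic, to keep every number traceable.

## Known limitations

* The linear pattern-strength interpolation is one admissible reading of
  the in-between regime; other monotone interpolations would move
  mid-range triad-strength values somewhat (the endpoints are fixed).
* The profile-route block-size estimator is only meaningful for `DA|XX`
  end-point digests; it is not validated for other specificities.
* Subsite preferences (as opposed to absolute requirements) and cleavage
  kinetics are not modeled; enzymes with graded preferences are
  approximated by their simplified absolute specificities.
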