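# Methods

## The sandwich-plate model

A lamina strip is idealised as a symmetric three-layer sandwich: two
epidermis faces of equal thickness and Young's modulus `E_f`, and a
mesophyll core of modulus `E_c` occupying a fraction `α` of the total
thickness `d`. Under linear elasticity and the superposition principle, the
whole-strip moduli measured in tension and in three-point bending are the
area-weighted and second-moment-weighted mixtures

    E_T = (1 − α) E_f + α E_c
    E_B = (1 − α³) E_f + α³ E_c ,

the `α³` arising because a central core of fractional thickness `α`
carries `α³` of the section's second moment of area (`I = w d³/12` for a
rectangle). Two measurements and one anatomical ratio therefore determine
both layer moduli:

    E_f = (E_B − α² E_T) / (1 − α²)
    E_c = ((1 + α + α²) E_T − E_B) / (α (1 + α)) .

The model's assumptions, and where they bite:

- **Linear elasticity, small strains.** Only the initial slope of each
  force–displacement record is used. Turgor pre-stress, strain stiffening
  of the epidermis and the tension/compression asymmetry of soft tissues
  are all outside the model; they are the leading explanations for measured
  `E_B/E_T` ratios slightly above the theoretical bound.
- **Symmetric faces.** Upper and lower epidermis are pooled into one face
  modulus. Adaxial and abaxial bending tests are averaged per leaf before
  inversion, which empirically is safe (the two sides agree with an SMA
  slope ≈ 1 on real data).
- **Perfect bonding, no shear or core-buckling failure.** Three-point
  bending at span:thickness ≳ 20 keeps shear deflection negligible; the
  package warns below that ratio (configurable — the thickest real leaves
  sit near 15 and were judged acceptable in practice).
- **Negative `E_c` is reported, not repaired.** When the measured ratio
  exceeds `1 + α + α²` the inversion necessarily returns `E_c < 0`
  (the two conditions are algebraically equivalent; the package tests this
  sign equivalence). Results carry a `physical` flag and a warning; values
  are never clamped, because the magnitude of the violation is diagnostic.

The ratio `E_B/E_T` equals 1 for a homogeneous plate (β = E_c/E_f = 1),
is bounded by `1 + α + α²` (→ 3 as α → 1), and at fixed β is maximised at
the α solving `2(1−β)α³ − 3α² + 1 = 0`; `optimal_alpha` finds this root by
bracketed bisection on (0, 1] (tolerance 1e−12, grid-search-verified) and
returns the boundary supremum α = 1 exactly at β = 0. `alpha ∈ {0, 1}` is
rejected by the inversion rather than regularised: the formulas are
singular there and silent regularisation would hide data errors.

Units are N, mm, MPa throughout (1 MPa = 1 N/mm²); conversions happen only
at I/O boundaries.

## Slope extraction from force–displacement records

The tests record force every 100 ms at a constant crosshead speed of
25 mm/min (0.0417 mm per sample). The modulus formulas need the initial
stiffness `k`:

    tension:  E_T = k l₀ / (w d)
    bending:  E_B = k L³ / (48 I) .

Real records have a toe region (clamp slack, contact settling) and
pre-failure softening, and there is no universally agreed definition of
"initial slope". The default policy:

1. trim the toe — samples before force first exceeds 2% of peak;
2. restrict to forces below 50% of peak;
3. among contiguous windows spanning ≥ 15% of the eligible samples
   (≥ 10 points), pick the one with the best linear-fit r², preferring
   longer windows on ties; report its least-squares slope, window and r².

On an exactly linear record every candidate window has r² = 1 and the
longest-window tie-break returns the analytic slope, so the policy is exact
where exactness is possible. Window search uses prefix sums over a
decimated grid of ≤ 40 starts × 40 ends, so cost is independent of record
length. Two simpler policies (`first_fraction`, `max_secant`) are
selectable for sensitivity analysis, and an optional auto-zero re-bases
displacement at the toe threshold (it never affects the slope). Tensile
strength is peak force over cross-section; it needs no windowing.

## Anatomical fractions

`α` is (palisade + spongy)/total thickness, with "total" including
cuticles and epidermises; the "epidermis layer" always means epidermal
tissue plus cuticle. The variant `α′` moves the inner part of each
epidermis (cells minus the outer periclinal wall) into the core, keeping
cuticle + outer wall as the effective stiff face — the configuration in
which most measured ratios fall back inside the theoretical bound. The
cuticle is kept on the face side of the split because the cuticle and
outer wall dominate face stiffness; the alternative split is computable
but not used in reports. Minor veins inside the mesophyll are not
subtracted from α: it is a thickness ratio, and veins near the neutral
axis contribute little to bending anyway.

The air fraction treats the lamina as water + solid + air, with specific
gravities 1 and 1.5 g/cm³ for water and solid tissue: per unit area, air
fraction = 1 − [(fresh − dry)/1 + dry/1.5] / (1000 · thickness_mm) with
masses in g/m². Negative results (inconsistent inputs) are returned with a
warning.

## Comparative statistics

- **Transform screen.** Each trait is log10-transformed iff Shapiro–Wilk
  rejects normality at P < 0.05; the decision is recorded as a 0/1 flag and
  reused consistently for ANOVA, correlations and contrasts. Non-positive
  values make the log branch an error naming the offending species (the
  mesophyll modulus, which can be negative, therefore always stays on the
  raw scale).
- **Group comparison.** One-way ANOVA across functional groups
  (herbaceous/woody × deciduous/evergreen), pairwise pooled-variance t
  tests with Bonferroni family-wise correction over all group pairs.
  Groups below 2 members are rejected as degenerate.
- **SMA regression.** slope = sign(r)·sd(y)/sd(x); 95% CI via
  B = F₁,ₙ₋₂(0.95)·(1−r²)/(n−2), limits slope·(√(B+1) ± √B). Equals the
  geometric mean of the two OLS slopes; symmetric under axis swap.
- **Independent contrasts.** Felsenstein's pruning algorithm. Polytomies
  are resolved with zero-length internal branches before the pass, so n
  tips always yield n − 1 contrasts; contrast signs follow alphabetical
  ordering of each node's children by smallest tip label (deterministic).
  PIC correlations are computed through the origin with n − 2 … n − 1
  degrees of freedom convention (t on n_contrasts − 1).
- **Moran's I.** Weights are inverse patristic distances (diagonal 0,
  unnormalized); expectation −1/(n−1); the analytic P uses the
  randomization-assumption (kurtosis-corrected) variance, which matches
  the standard R implementation; an optional permutation P shuffles the
  trait across tips. The weight choice is conventional rather than forced:
  it is configurable in principle and documented as a modelling decision.
- **Branch lengths.** Unit lengths by default — appropriate when
  divergence times are unknown — and the packaged tree uses them
  throughout; user trees may carry their own lengths.

## The packaged dataset and tree

The trait table holds species means (n = 5 replicate leaves) for 36
broad-leaved angiosperms in four functional groups (13 deciduous
herbaceous, 2 evergreen herbaceous, 12 deciduous woody, 9 evergreen
woody). Its ratio column is the replicate-mean of `E_B/E_T`, which
is not identical to the ratio of the tabulated species-mean moduli — both
facts are preserved as recorded, and summaries use the ratio column
consistently. Because the tabulated layer moduli are means of per-replicate
inversions (a nonlinear map), re-inverting species-mean `E_T`, `E_B`, `α`
reproduces them only approximately: within 0.3% for the stiffest species
but ~15% for the softest, where the inversion is most ill-conditioned.

The species tree is synthetic in topology above the family level: tips and
family memberships are real, congeners and confamilials are sisters, and
the arrangement of families follows standard angiosperm relationships, but
the exact resolution is an arbitrary fixed choice. Phylogenetic tests
against this tree therefore check statistical properties (contrast counts,
Brownian-motion behaviour, autocorrelation direction), not published
contrast values.

## The virtual testing machine

The simulator emulates the study design end to end: by default 36 species
× 5 replicates, each replicate one tensile strip (free length 50 mm) and
two bending strips (span 15 mm, adaxial + abaxial), strip width 5.2 mm.
Species parameters are drawn inside the envelopes of the real table —
log-uniform `E_f` in [10, 500] MPa, β uniform in [0, 0.1] (so `E_c` ≤
about 35 MPa), α uniform in [0.65, 0.92], thickness uniform in
[0.15, 0.6] mm — and anatomy tables and mass samples are generated
consistently with each species' α and thickness, with air fractions inside
the observed 7–41% range.

Each record is a straight line of the analytic stiffness with a 0.1 mm
flat toe and multiplicative Gaussian force noise (default sd 1% of local
force; instrument error scales with signal — an additive variant is
available). All randomness flows from a single mandatory seed; identical
configs are bit-identical on re-run.

What the simulator does *not* emulate: viscoelastic drift, humidity
coupling, clamp slippage beyond the toe, thickness non-uniformity, plate
curvature, or any nonlinear constitutive behaviour. Passing recovery tests
therefore demonstrates the correctness and conditioning of the estimation
chain under the model's own assumptions, not robustness to the biological
effects listed above — those are precisely the effects the `physical` flag
and bound diagnostics are designed to surface on real data.

Recovery behaviour (measured by `recovery_experiment` and the test suite):
noiseless studies are recovered to machine precision (≤ 1e−6 relative);
at 1% force noise the species-level face modulus has median relative error
well under 5%; core-modulus error is absolute rather than relative (it is
a small difference of large numbers) and the fraction of negative `Ê_c`
estimates rises as true β → 0, reproducing the negative-core artefact seen
in real tables.

## Problem sizes and numerical choices

Test-suite simulations use reduced designs (e.g. 12–40 species, 1–3
replicates) where the property under test does not need the full design;
the recovery acceptance check runs the full 36 × 5 study at 1% noise. The
inversion round-trip is verified to 1e−9 relative error over 1000 random
draws; `optimal_alpha` against a 1e−5 grid oracle within 1e−4; slope
extraction is exact on linear input by construction. Ties in window
selection prefer longer, earlier windows; degenerate inputs (zero
displacement range, constant traits, zero-variance groups) raise errors
naming the offending quantity rather than propagating NaNs.

## Known limitations

- The inversion's conditioning degrades as α → 1 and as β → 0; `E_c` is
  the difference of comparably sized terms and inherits the absolute error
  of `E_B` and `E_T`. Treat small `E_c` values as order-of-magnitude.
- The initial-slope policy is a convention; policy sensitivity should be
  checked on any new instrument or species (the `SlopePolicy` options
  exist for exactly that).
- The comparative layer assumes species means; within-species replicate
  variance is not propagated into the cross-species statistics.
- The packaged tree's above-family topology is a fixed convention, and
  unit branch lengths are an assumption, not an estimate.
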