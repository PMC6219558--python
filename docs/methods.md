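# Methods

## The spacing ratio

Input is a set of digitized points per leaf (or leaflet): a midvein axis
(base and tip, optionally intermediate nodes) and the points where
lateral secondary veins bifurcate from the midvein.  Coordinates are
image pixels with y increasing downward; nothing downstream depends on
the convention, because every quantity is built from relative positions.

Each origin is projected orthogonally onto the nearest axis segment;
its axial position `s` is the arc length from the base to the foot of
the projection.  The side label is the sign of the cross product of the
local axis tangent (base→tip) with the offset vector; points exactly on
the axis cannot be sided and are excluded with a warning.  Origins are
then ordered by `s` (ties broken by side, then input order).

For an origin at `s` on side σ:

* `d_same` — distance to the nearest origin with side σ and `s' > s`
  (strictly apical);
* `d_opposite` — distance to the nearest origin with side ≠ σ and
  `s' ≥ s` (apical or coincident, so an exactly facing partner gives
  `d_opposite = 0` and `r = 0`);
* `r = d_opposite / d_same`.

Distances are euclidean between the two bifurcation points by default;
an axial variant (`|s' − s|`) is available.  Midveins are near-straight
and digitized origins sit within a few pixels of the axis, so the two
metrics nearly coincide (unit-tested: lateral offsets ≤ 2% of the
internode keep `|Δr| ≤ 0.05`); euclidean is the default because it is
the most literal reading of "distance between the points".  Origins
missing either neighbour (the apical boundary of each side) are reported
as undefined rather than imputed, since the ratio simply does not exist
there.  `r = 1` exactly is *not* irregular — irregular is strictly
`r > 1` — and no upper cap is applied: two very close same-side veins
legitimately produce extreme ratios, and capping them would distort the
pooled distribution.  Same-side origins digitized at identical axial
positions make `d_same = 0`; such records are flagged invalid with a
warning naming the leaf.

## Dip statistic

The dip of a sample is the smallest sup-norm distance between its
empirical CDF and any unimodal CDF (convex left of the mode, concave
right of it, with a jump permitted at the mode itself).  It is computed
exactly, in count units on the distinct values `z_0 < … < z_{m−1}` with
upper/lower cumulative counts `c_k`, `cl_k`:

1. **Per-side needs.**  A nondecreasing convex function fits the
   vertical windows `[c_j − nd, cl_j + nd]` on a prefix `z_0..z_k` iff
   `nd ≥ leftNeed(k) = ½·max_{j<k} (c_j − A_k(z_j))`, where `A_k` is the
   lower convex hull of the points `(z_i, cl_i)`, `i ≤ k` — the hull
   shifted up by `nd` is the pointwise-largest convex candidate, so the
   gap below the window floors is exactly what must be bridged.
   `rightNeed(k)` is the mirror image for the concave suffix.  Both
   profiles are built in one incremental hull sweep each: pushing a
   point rebuilds only the final hull segment, under which the gaps can
   only have grown, so a running maximum over the rebuilt span is exact.
2. **Mode junction.**  The convex piece ends at a left limit `v`, the
   concave piece starts at `w`, and a CDF needs `v ≤ w`.  A window floor
   at `z_j2` lying above a window ceiling at `z_j1 < z_j2` forces a
   positive entry slope that convexity cannot shed, so the smallest
   achievable `v` at mode `k` is a max of linear extrapolations of such
   pairs; `w`'s largest achievable value is the mirror.  Feasibility of
   a given `d` is the existence of a mode where both side-needs are met
   and the junction closes.
3. `n·dip = min_k max(leftNeed, rightNeed)` is a lower bound and is
   returned directly when the junction is already slack there (the
   common case); otherwise the monotone feasibility predicate is
   bisected to an absolute tolerance of `1e−11·n` counts.  The result is
   floored at `1/(2n)`, the classical lower bound, which the
   decomposition attains automatically for any sample with at least two
   distinct values; only a fully degenerate (all-equal) sample is lifted
   to the floor.

The implementation is validated against an independent brute-force
oracle — one small linear program per candidate mode knot, minimizing
the sup-distance over piecewise-linear unimodal CDFs — to 1e−9 over
thousands of random and adversarial samples (uniform, normal, clustered
trimodal, heavy ties, log-normal).  The kernel is plain Python JIT-ed by
numba when available (~10 ms per dip at n = 300) and falls back to the
interpreter otherwise.

**p-values** are Monte-Carlo: `p = (1 + #{null dips ≥ observed}) /
(reps + 1)` with null dips drawn from uniform(0, 1) samples of the
observed size (the classical null convention), default `reps = 10 000`,
seeded and cached per `(n, reps, seed)` so species of equal sample size
share one null table.  The add-one form avoids `p = 0`.  Monte Carlo was
chosen over interpolating the published quantile table: it is
self-contained, reproducible, and exact up to simulation error.

## Brunner–Munzel

The two-sample comparison uses pooled midranks (average ranks for ties),
the relative effect `p̂ = P(X < Y) + ½P(X = Y)` estimated from mean
ranks, rank-based variance estimates, and a t reference distribution
with Satterthwaite degrees of freedom, two-sided.  It is implemented
in-package because the result type exposes `p̂` and the degrees of
freedom; the statistic and p-value are cross-checked against
`scipy.stats.brunnermunzel` in the tests, and `p̂` against direct pair
enumeration.  Zero rank variance (complete separation or all-tied data)
yields a flagged degenerate result instead of an infinite statistic.

## Density summaries

Violin curves are Gaussian KDEs (Silverman bandwidth by default; a fixed
bandwidth can be supplied and is always reported in the output) on a
512-point grid spanning `[min − 2h, max + 2h]`; modes are strict local
maxima of the gridded density.  An (effectively) zero-variance pool is
flagged degenerate and reported as a single mode at the common value —
this is exactly what the noiseless ideal-alternate archetype produces.

## Synthetic arrangements

The generator emulates ordered left/right vein origins along a straight
vertical midvein:

| parameter | meaning | default |
| --- | --- | --- |
| `n_pairs` | left/right origin pairs | 15 |
| `internode_mean` | mean axial spacing (px) | 30 |
| `internode_cv` | CV of internodes (truncated normal, redrawn until > 0) | 0.15 |
| `phase` | right-side offset as a fraction of the local internode; 0 = opposite, 0.5 = alternate | 0.5 |
| `jitter_sd` | SD of additive axial noise, fraction of mean internode | 0 |
| `irregular_prob` | per-vein probability of an extra same-side insertion midway to the next same-side origin | 0 |
| `lateral_offset` | perpendicular distance from the axis (px) | 0.3 |
| `irregular_mode` | `insert` an extra origin or `delete` the opposite partner | insert |

Defaults follow the study conditions the package is built around:
15 pairs ≈ 28–30 defined ratios per leaf, so ten leaves pool to ~300
ratios, matching the observed per-species range of a few hundred; the
lateral offset is ~1% of the internode so the euclidean and axial
metrics nearly coincide.  The truncated-normal internode model is a
minimal two-parameter stand-in — no spacing distribution is implied by
real leaves — and is a reported, swappable policy.  Irregulars are
modelled as insertions because a same-side succession is what the
irregular archetype shows directly; deletion of the facing partner is
available as a variant.  Noiseless settings reproduce the archetypes
exactly: `phase=0.5, jitter=0` gives every defined r = 0.5, and
`phase=ε` gives exactly the two values ε and 1−ε.

Compound (ternate) fixtures draw three leaflets independently; with
`mirrored_irregulars=True` the right-positioned leaflet receives its
irregular insertions at the same relative positions as the
left-positioned one with sides flipped — the systematic-rule scenario
the mirror-image analysis must recognize.

What the generator does **not** emulate: curved midveins, basal/apical
internode gradients, digitization error correlated along the leaf,
intersecondary veins mistakenly digitized as laterals, and any
species-level heterogeneity beyond its explicit parameters.  Passing
tests therefore certify the statistical machinery under the stated
generative model, not the biology of any particular species.

## Species-level analysis and group comparison

All defined r of a species are pooled across leaves (leaflets are
treated as leaves; a leaflet-position filter reproduces the
terminal-only design variant) and the dip test runs on the full pool,
including r > 1 — truncation (e.g. at r ≤ 1.5) is available but is a
display variant only.  Group comparisons take exactly one dip p-value
per species.  The mirror-image analysis maps each irregular case on a
left/right leaflet pair to a signed coordinate (−position on the left
leaflet, +position on the right; bases at 0, tips at ∓1) and calls a
case matched when the other leaflet has an irregular case within a
tolerance τ of the same relative position; τ defaults to 0.1 of the
leaflet length (mirror-image judgement in the source material was
visual, so no τ is implied; the default is reported in output and swept
in the tests), and a pair's verdict is "mirror" only when both leaflets
have irregulars and every case is matched.

## Test problem sizes and numerical choices

Calibration tests use 2 000 Monte-Carlo replicates and 500 null draws at
n = 300 (the per-species pool size the generator defaults produce);
phase-recovery tests use 100 seeded runs per phase at 5% jitter; the
group-comparison type-I check simulates 200 replicates of 18-vs-12
species with identical parameters.  The type-I scenario uses the
alternate regime (`phase = 0.5`): there the dip p-values vary over
(0, 1], which is the premise of a rank test on p-values.  (In a strongly
bimodal regime every species' p-value ties at the Monte-Carlo minimum
and the Brunner–Munzel variance collapses — the implementation then
returns its flagged degenerate result rather than a spurious number.)

## Known limitations

* The dip's junction refinement is a bisection, exact to ~1e−11·n
  counts rather than closed-form; the oracle-equivalence tests bound the
  error at 1e−9 on the dip scale.
* A loader for the archived raw-scan deposit of the original
  measurement campaign is not included: the deposit's file layout is not
  machine-readable from the publication, and the benchmark-style tests
  run on clearly-labelled synthetic stand-ins instead.
* The dip p-value null is uniform(0, 1); the dip is distribution-free
  over continuous samples, but heavy ties (quantized coordinates) shift
  the null downward, so pooled ratios should be kept at full floating
  precision.
* `compare_groups` requires both group levels to have ≥ 2 species and
  treats the species as independent; phylogenetic structure is ignored.
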