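# Methods

## Model

`exclusim` simulates a two-species hard-core interacting particle system in
the Widom–Rowlinson tradition, used as a minimal model of contact inhibition
in a tumor/normal cell co-culture. Cells occupy vertices of an L × L square
grid; distance is the graph metric (minimal number of unit edges, i.e. the
L1 metric). A configuration is *admissible* when each vertex holds at most
one cell and every pair of cells of types i and j is at distance at least
D(i, j). The self-exclusion diameter D(i, i) encodes the degree of contact
inhibition: the densest single-type packing has interior density 1 for
D = 1, 1/2 (a parity checkerboard) for D = 2, and in general 2/d² (even d)
or 2/(d² + 1) (odd d). The default table D = (D11, D12, D22) = (1, 3, 2)
makes the tumor type the most tolerant of close neighbours and keeps mixed
pairs farthest apart; its direct geometric consequence is the observed
morphology of tumor clusters separated from the surrounding normal phase by
a one-to-two-vertex empty halo.

Dynamics are a discrete-time Markov chain on admissible configurations.
Each step selects one vertex uniformly among all L² (border vertices
included; they are held empty throughout and resolve to no-ops, which
suppresses boundary artefacts).

At an **occupied** vertex of type i the outcome law is

    quiescence      alpha_i / Q
    death           rho_i / Q
    migration       delta_i / Q per admissible destination
    Q = alpha_i + n_e * delta_i + rho_i

where n_e counts empty vertices on the ring at distance D(i, i) that can
receive the cell admissibly once its source is vacated, and the destination
is uniform among them.

At an **empty** vertex x,

    stay empty      (rho_1 + rho_2) / R
    birth of i      n_i * alpha_i * I(i) / R
    immigration     delta_i * I(i) / R per donor (the source is vacated)
    R = rho_1 + rho_2 + sum_i n_i * (alpha_i + delta_i) * I(i)

with n_i the number of type-i cells on the ring at distance D(i, i) from x
and I(i) the indicator that x can admissibly receive type i. When R equals
rho_1 + rho_2 the vertex stays empty with probability one.

Interpretation choices that the verbal model statement leaves open, fixed
here once:

* the donor neighbourhood of an empty vertex is the ring at exactly
  D(i, i) — symmetric with the receiver definition and the closest
  admissible parent–daughter separation (an annulus reading is possible but
  not adopted);
* quiescence changes nothing; divisions add cells only through the
  empty-vertex rule, and the dividing parent is not tracked (parents
  persist, so the outcomes are identical);
* immigration checks placement with the chosen source disregarded; since
  deleting a cell from an admissible configuration never creates a
  violation (removal monotonicity, property-tested), vacating the source
  first is sound;
* the stay-empty weight is rho_1 + rho_2 verbatim — it could be
  parameterised separately but is kept to avoid an extra rate;
* densities are occupied fractions of all L² vertices by default; an
  `interior_density` flag switches the denominator to (L − 2)², which
  matters at small L (the capacity checks use it).

## Parameters

| parameter | meaning | default | notes |
|---|---|---|---|
| D(1,1), D(1,2), D(2,2) | exclusion distances (lattice units) | 1, 3, 2 | positive integers; symmetric |
| alpha_i | division weight | 0.1 | dimensionless sampling weights, |
| delta_i | migration weight | 0.001 | not physical rates per time |
| rho_i | death weight | 0.01 | alpha_i + rho_i > 0 required |
| L | grid side (vertices) | 200 | full-scale; tests use 25–100 |
| init densities | occupied fractions at start | 0.01 / 0.09 | tumor / normal, the 10:1-style co-culture seeding |

Initial configurations place round(density · L²) cells of each type at
uniformly random interior vertices by sequential insertion with
admissibility rejection, the larger-exclusion species first (order
configurable); targets above 90% of the analytic packing capacity are
refused rather than risking a jam. Markov steps are not experimental time:
one step performs at most one transition, whereas a culture advances in
parallel, so step counts are never mapped to days.

## Implementation and numerics

The inner loop is numba-compiled, operating on an int8 grid at roughly
190 ns per step on one core. Sampling at occupied vertices uses an exact
short-circuit: Q is bounded between alpha + rho and alpha + rho + 4·D·delta
whatever n_e turns out to be, so a uniform draw that falls outside the
ambiguous band decides quiescence or death before the receiver ring is
inspected; only draws inside the band trigger the ring scan, after which
the same draw is reused against exact thresholds. This leaves the law
unchanged (the same uniform variable is compared against the same exact
cumulative boundaries) and roughly halves the cost.

A pure-Python reference path (`engine="reference"`) builds the exact
per-vertex outcome distribution (`UpdateDistribution`) and samples it with
a NumPy `Generator`. The compiled and reference engines implement the same
law but consume different random streams; reproducibility is therefore
same-seed *and* same-engine. The test suite checks the compiled resolver
against the analytic distribution by frequency comparison (4 Monte-Carlo
standard errors per outcome over 10⁵ draws) and the two engines against
each other statistically. Admissibility is guaranteed constructively by the
placement indicator; long-run tests re-verify it with an independent
all-pairs brute-force checker.

One RNG stream per run is seeded from the run's integer seed; replicate
and sweep seeds derive from a `SeedSequence` of the base seed, so results
do not depend on scheduling order. All seeds stay below 2³¹.

## Pattern analyses

Occupancy heatmaps average the type-indicator over a window of snapshots;
cluster masks default to a 0.5 threshold and 8-connectivity (tolerant of
single-pixel necks; 4-connectivity available), dropping components below
2 px. Shape descriptors: area = pixel count; perimeter = number of unit
pixel edges against the background (unambiguous on a lattice, in contrast
to contour-length estimators); solidity = Area/ConvexArea with the convex
area the pixelised filled hull (ratio ≤ 1 by construction); aspect ratio =
major/minor axis of the second-central-moment ellipse with pixels treated
as unit squares (each contributes 1/12 variance), so a single pixel is
isotropic (ratio 1) and a 1 × N row has ratio √(12·var + 1) exactly —
5 for N = 5. The pixel-to-micrometre scale defaults to √93 ≈ 9.64 um per
pixel (the "~10 um" calibration that equates one heatmap pixel with
~93 um²) and is a parameter everywhere.

Distance distributions histogram all unordered same-type pairwise Euclidean
centroid distances (default bin width 5 um for point patterns); the mode —
the center of the most populated bin, smallest on ties — operationalises
the most frequent separation, which for a hard-core pattern reflects its
minimal allowed distance. Density-by-distance profiles tile the field into
50 × 50 um² quadrats, attach to each the distance from its center to the
nearest tumor centroid, group quadrat counts of normal cells into bands
(default 0–50, 50–100, 100–150 um), report median/IQR per band and fit
count(d) = A·exp(−λd) to the band means at band midpoints (log-linear
initialisation, then nonlinear least squares).

Growth curves are fitted with the three-parameter symmetric logistic
N(t) = K / (1 + exp(−r(t − τ))) by nonlinear least squares (start values:
K₀ = max value, τ₀ = time nearest K₀/2, r₀ from the early log-linear
slope); standard errors come from the Jacobian covariance at the optimum,
and capacity ratios K_A/K_B carry a first-order delta-method error.
Richards-type asymmetric forms are out of scope. Degenerate inputs (flat or
non-positive series, fewer than four points) are rejected.

## Synthetic data

The point-pattern generator emulates a post-confluence co-culture field of
view: tumor centroids pack a disc (default radius 35 um) with a hard-core
spacing of 8 um — nucleus-scale crowding — while normal centroids fill the
rest of a 400 um field with an 18 um spacing, a clearance of 12 um from
tumor points, both by sequential hard-core thinning of Poisson proposals.
It reproduces the signature the analyses are designed to detect (the tumor
same-type distance mode falls below the normal mode) but not other features
of real micrographs: no segmentation error, no cell-size variation, no
anisotropy, and an idealised circular cluster boundary, so passing tests
validate the measurement pipeline rather than any biological claim. The
growth-curve generator adds homoscedastic Gaussian noise to an exact
logistic; the fit-recovery study uses a 6-hourly schedule over an 8-day
window (33 points) so that the plateau carries enough samples for the
capacity to be identifiable at the 5%-of-K noise level — with daily
sampling the capacity standard error alone exceeds the 2% recovery bound
the study checks.

## Scale choices and the robustness sweep

Full-scale study conditions are a 200 × 200 grid, 100 repetitions and
horizons of 3·10⁹ steps and beyond — cluster-scale work. The packaged
experiments run desk-scale versions: the co-culture reversal uses L = 100
with 10⁷ steps × 10 seeds, and the division-rate sweep (alpha2/alpha1 ∈
1..10) uses L = 40, 10 repetitions and 2.4·10⁷ steps per run, keeping the
full-scale ratio of horizon to grid side (375 sweeps per lattice unit) so
that the slow phase-takeover race is comparably resolved.

The sweep's headline quantities — the ratio with closest-to-equal mean
final densities and the smallest ratio at which the strongly inhibited type
prevails — are strongly scale-dependent, and this is a known limitation
rather than an implementation artefact. Two mechanisms govern them. First,
survival: the tumor type starts at density 0.01 and is heavily shadowed by
the 9× denser normal type, so it persists only where seeding left locally
dense pockets; the number of such pockets scales with the absolute count
0.01·L² (400 cells at L = 200 versus 16 at L = 40), and at desk grids the
tumor type goes extinct at moderate alpha2/alpha1 where at full scale it
would survive. Second, the takeover race: a surviving tumor cluster
advances its interface at a speed that falls with alpha2, and wins only if
the horizon outlasts the crossing time, which grows with L. Matching both
mechanisms simultaneously requires full scale. At desk scale both push the
equal-density crossing and the first type-2 prevalence to lower ratios
(measured at ~2–4 across L = 40–60 over a wide range of horizons) than at
full scale (~6 and ~10). The alternative axial-only reading of the donor
neighbourhood moves the crossing by at most one ratio step, so the
interpretation choice above is not the cause.

## Known limitations

* Two cell types, square lattice, empty (non-periodic) border only;
  continuous-time and off-lattice variants are out of scope, as are
  mechanical (spring-type) cell interactions and normal→tumor conversion.
* Dense packings (and hence capacity-guarded initialisation) are
  constructed only for self-exclusion diameters 1 and 2.
* The empty state is the only truly absorbing configuration, so all
  "steady states" reported by long runs are quasi-stationary; horizons are
  explicit parameters, never auto-detected.
* Sweep summary statistics are scale-dependent as described above.
* The cluster pipeline quantifies simulated heatmaps or already-extracted
  centroid tables; it does not segment images.
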