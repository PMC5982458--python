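# Methods

## The screening model

A filament passing the pinch rollers of an FDM printing head is a slender
column under axial compression. The screening test reproduces that loading
on a texture analyzer: a 5 cm specimen of 1.75 mm filament, held vertically
in conical end caps that allow free rotation of the ends, is compressed
15 mm at 3.15 mm/s and released, with recording triggered at 0.05 N. The
resulting force–distance curve (the flexibility profile) carries the
mechanical signature that decides feedability:

* a **pliable** filament loads elastically until the axial force reaches
  the Euler critical load of the column, then buckles and bends while
  keeping its structural integrity, and partially recovers on release —
  these feed;
* a **brittle** filament fractures at its peak force, either sharply
  (force drops to nothing) or after bearing some strain (a small residual
  resistance persists) — these snap in the head;
* a **floppy**, over-plasticized filament cannot hold a straight column at
  all, never reaches the trigger force, and cannot be tested — it coils in
  the head.

Feedability is treated strictly as a Boolean: the pipeline reports a mean
correlation score, but only the rounded 0/1 call is the screening outcome,
and no "more feedable" ordering is claimed.

## Normalization and comparison

Raw curves from materials of very different hardness are not directly
comparable, so each curve is (1) linearly interpolated onto a fixed grid of
distance stations — 128 for the compression stroke (0 → 15 mm) and 128 for
the release stroke (15 → 0 mm) — and (2) sum-normalized, dividing every
point by the curve total so the vector sums to one. Sum normalization is
invariant under any positive rescaling of force, and Pearson correlation is
additionally invariant under the normalization itself; both properties are
asserted in the test suite. The practical consequence is that a filament
requiring ~120 N to deform and one requiring 2 N receive identical scores
if their curve *shapes* agree.

Grid density is a free choice (the instrument's native sampling rate is a
property of the hardware, not the method); 128 + 128 stations make linear
interpolation error negligible for these smooth piecewise curves while
keeping correlation and PCA cheap. Distance zero is aligned to the first
sample at or above the trigger force, matching the instrument's trigger
semantics. Stations beyond a prematurely ended compression record (a
fractured specimen) hold the last recorded force when the record ends in a
drop — fractured filaments keep exerting the minor resistance last seen —
and zero otherwise. Replicates (the protocol runs triplicates) are combined
by pointwise mean and renormalization, with per-replicate scores still
available upstream.

Two readings of the comparison input exist: the normalized curve itself and
its cumulative-area transform. The curve is the default; the transform is
available via `ProfileNormalizer(cumulative=True)`. Likewise the release
stroke is included in the comparison vector by default (the PCA uses the
full curves) with `include_release=False` covering the compression-only
alternative.

## Scoring and the rounding rule

Correlation is Pearson product-moment (the flavor of spreadsheet analysis
tools; Spearman is available behind a flag). The score of a candidate is
the arithmetic mean of its correlations with every library reference. The
classifier rounds: below 0.5 → 0, above 0.5 → 1. The rule as stated covers
only strict inequalities; a score of exactly 0.5 rounds *up* here and is
flagged borderline, as is any score within a configurable margin (default
0.05) of the cut. Display values are rounded to two decimals half away from
zero, the spreadsheet convention (−1.19/3 prints as −0.40).

A reference whose mean correlation with the other references falls below a
threshold (default 0.55) is flagged as a library outlier. The treatment is
deliberately asymmetric, mirroring how a dissimilar dissolvable support
filament was handled in the original study: an outlier reference still
contributes to the scoring mean but is dropped from the PCA panel. With
the published consistency pattern (0.62/0.92/0.51) the dissolvable
reference's mean off-diagonal is 0.565, so the default threshold keeps it
and a threshold of 0.6 excludes it; both settings are exercised in tests.

## PCA with varimax rotation

The panel matrix takes **filaments as variables** and grid stations as
observations — the orientation consistent with the published eigenvalue
magnitudes (10.13 + 3.57 + 1.51 with a sub-1 tail sums toward a ~19-variable
trace, not a hundreds-of-stations one). Columns are standardized and the
eigendecomposition of the filament correlation matrix taken; loadings are
scaled so squared loadings per component sum to the eigenvalue, and each
component's sign is fixed so its largest-magnitude loading is positive
(platform determinism). Components with eigenvalue ≥ 1 are retained
(Kaiser rule, boundary inclusive).

Varimax rotation maximizes the variance of squared loadings per component
over orthogonal rotations, with Kaiser row normalization (each variable's
loading row scaled to unit communality during iteration — the default of
the major statistics suites), an iteration cap of 25 and a relative
criterion tolerance of 1e-6. Orthogonality preserves per-variable
communalities; the suite asserts this to 1e-8 and checks the k = 2 case
against a brute-force scan over the single rotation angle at 1e-4 rad
resolution, plus a cross-check against statsmodels' raw varimax. Rotated
loadings are emitted as per-filament space-plot coordinates; clusters are
identified visually (or by a silhouette statistic on labels), never by an
automatic clustering step, because the method's published use is visual
sorting.

Exact reproduction of the published eigenvalues, loadings and space-plot
coordinates is out of scope: the raw instrument curves behind them were
never deposited. What the package asserts instead are the arithmetic
identities (trace = variable count, communality conservation), the
published-table arithmetic, and cluster separation on synthetic panels.

## The profile simulator

The simulator generates the four phenotypes with ground-truth labels.

* Geometry and physics: the Euler critical load is the exact closed form
  F_cr = π²EI/(KL)² with I = πd⁴/64 and effective-length factor K = 1
  (pinned–pinned; the conical end caps allow end rotation; K is
  config-exposed). At the protocol geometry, E = 1 GPa gives F_cr ≈ 1.82 N,
  and E ≲ 3 MPa puts F_cr below the 0.05 N trigger — the floppy phenotype
  falls out of the same closed form.
* Loading ramp: an ideal straight column of these dimensions has axial
  stiffness E·A/L ≈ 50 N/mm and would traverse its elastic ramp in tens of
  micrometres, while measured ramps span millimetres. The simulator
  therefore scales the ideal stiffness by a lumped rig/imperfection
  compliance factor (default 2 × 10⁻², per-filament jitterable): the ramp
  slope is phenomenological, the buckling force exact.
* Phenotype envelopes: pliable curves transition at F_cr to a gently
  varying post-buckling plateau (default slope 0.02 N/mm) and release at a
  recovery fraction (default 0.5) of the compression forces; sharp-brittle
  curves ramp to the yield force exactly at the fracture distance and drop
  to zero; strain-bearing brittle curves drop to a residual fraction (in
  (0, 0.3]) of the peak with a slow creep-down; floppy specimens emit a
  sub-trigger trace that the reader re-flags as not testable. Brittle
  fracture is modeled phenomenologically (ramp + drop), not with fracture
  mechanics — only the curve shape matters to the method.
* Noise: additive Gaussian on the force, default SD 0.02 N (small against
  the 0.05 N trigger), from a named per-filament generator; identical
  seeds give bit-identical profiles.
* Presets: the reference library stand-ins are three pliable filaments —
  ABS-like and PLA-like with similar stiffness (mutually correlated near
  1), and a deliberately dissimilar dissolvable-like preset (much softer,
  higher rig compliance, mildly decaying plateau, stronger recovery) whose
  mean correlation with the others lands near 0.65, reproducing the
  qualitative outlier pattern of the published consistency matrix. A
  stiff "Mowiflex-like" preset has its effective modulus set so the
  deformation force is 120 N, to exercise scale-freeness. Commercial force
  scales other than that one are plausible ranges, not calibrated values.

What the simulator does **not** emulate: melt-zone rheology and
printability beyond feeding, instrument compliance drift, specimen
diameter variation along the length, humidity/aging effects, and the
irregular post-buckling oscillations of real curves (the plateau is smooth
plus noise). Passing the synthetic recovery tests therefore demonstrates
that the pipeline's arithmetic and decision rules work as specified on
curves with the observed gross morphologies — not that the 0.5 cut is
optimal for any particular real material.

## Problem sizes and numerical choices

The end-to-end acceptance experiment uses 100 seeded panels of 3 pliable +
3 sharp-brittle + 3 strain-bearing + 2 floppy filaments each (900 scored
filaments, 200 floppy-path checks), a size at which the whole suite runs
in well under a minute while the binomial noise on a ≥99% recovery
criterion is already negligible at the observed 100% recovery. Degenerate
inputs fail loudly and early: all-zero force vectors, flat (zero-variance)
profiles, single-point phases, mismatched grids and sub-trigger (floppy)
profiles each raise a dedicated exception rather than propagating NaNs.
Eigen-solver ties are broken by descending eigenvalue then variable index;
rotation and eigenvector signs are canonicalized as described above, so
every fitted result is deterministic for a fixed input.
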