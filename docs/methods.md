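# Methods

`mvcpair` implements mesh-to-mesh value comparison (MVC) for pair-matching
bilateral skeletal elements — deciding, for a commingled assemblage of left
and right bones, which left and which right belong to the same individual.
This note records the models, the numerical choices, and what the synthetic
test bed does and does not establish.

## The mesh-to-mesh value

Two bone surfaces are compared by rigid registration. Right-side elements
are first reflected ("mirrored-rights") so that a right bone can be overlaid
directly on a left. The dissimilarity of a registered pair is a single
scalar in millimetres, the *mesh-to-mesh value*: points are sampled on the
moving mesh uniformly by surface area, their exact Euclidean distances to
the fixed mesh's triangles are computed, the largest `1 − trim_fraction` of
the distances are discarded, and the rest are summarised as

- `rms` (default): sqrt(mean of squared retained distances), the standard
  registration residual, or
- `root_of_mean`: sqrt(mean of retained distances), kept as an option for
  sensitivity analysis because the verbal definition of the statistic
  ("square root of the mean distances") is ambiguous between the two.

Lower values mean more similar shapes; the premise of the method is that a
true bilateral pair is more similar than two bones from different people.

## Registration

**Coarse stage.** Automated initial alignment replaces the manual
pre-alignment an operator would do in interactive software: the moving
mesh's centroid is translated onto the fixed mesh's, principal axes of the
vertex clouds are matched (eigenvectors of the covariance, descending
eigenvalue order), and the four proper-rotation sign assignments of the axes
are disambiguated by the lowest trimmed (lower 80%) RMS nearest-neighbour
distance on a 500-point surface subsample. The trimming makes the flip
choice robust to localized shape defects. A degenerate covariance (rank
< 3, e.g. a planar mesh) is rejected.

**Partial overlap.** A fragment's centroid does not correspond to the whole
bone's, so for fragment-tagged moving meshes (or untagged ones with less
than half of the fixed mesh's surface area — two complete bones of different
size are a size mismatch, not a partial overlap, and plain coarse alignment
handles them) the coarse stage additionally scans 7 evenly spaced offsets along the
fixed mesh's first principal axis (spanning the length difference). The 12
best-scoring candidate poses are polished in two stages (8 accelerated
trimmed-ICP iterations at 400 points for all, 15 more for the best 4) and
the lowest trimmed RMS wins. This multi-start treatment is the standard
remedy for the axial local minima that fragment-to-whole registration
exhibits.

**Overshoot acceleration.** Point-to-surface ICP slides slowly when the
remaining error is a translation along an elongated surface: each update
step is small but persistently in the same direction. When the per-step
improvement drops below 10% of the current trimmed RMS, the update increment
is additionally applied 2x and 4x and the variant with the lowest trimmed
RMS is kept — the classic accelerated-ICP idea, applied only when it
provably (by evaluation) helps, so the monotone trimmed-RMS property is
preserved. Acceleration is enabled on the partial-overlap path, where the
sliding regime dominates; ordinary whole-bone registrations converge quickly
without it.

**Fine stage: trimmed ICP.** Each iteration transforms the (fixed, seeded)
sample of the moving surface, finds each point's closest point on the fixed
surface, retains the `floor(trim_fraction · n_points)` smallest distances,
and updates the pose by the closed-form least-squares rigid fit (SVD of the
cross-covariance; reflections excluded by forcing determinant +1) to the
retained footpoints. Iteration stops when the trimmed RMS changes by less
than `convergence_tol`, falls below it outright, or `max_iterations` is
reached. In exact arithmetic the trimmed RMS sequence is non-increasing.

Defaults: `trim_fraction = 0.95`, `n_points = 5000`, `max_iterations = 100`,
`convergence_tol = 1e-5` mm. The trim keeps the residual robust to small
segmentation defects while using nearly all the surface; all four parameters
are exposed in the `icp:` block of the pipeline configuration. Partial
overlap is handled by sampling only the fragment (the moving side), so every
sampled point has a genuine counterpart region on the whole bone.

**Exact point-to-surface distances.** Distances are point-to-triangle
(interior, edge, or vertex of the closest triangle), not point-to-point, so
the value is insensitive to differing mesh resolutions. The query structure
is a KD-tree over triangle centroids; oversized triangles (end-cap fans)
are subdivided inside the index only — children tile the parent exactly —
so the certificate radius stays tight. A query is certified exact when no
unseen triangle's bounding sphere can beat the best candidate distance; the
candidate set grows (k, 8k, …, all triangles) until the certificate holds.
Inside the ICP loop a fast uncertified k = 12 candidate query is used
instead: on quasi-uniform meshes it differs from the exact result for well
under 0.1% of points, and a rare marginally-too-long distance only perturbs
one correspondence (usually a trimmed one). The *final* retained distances,
and hence every reported mesh-to-mesh value, always come from the certified
exact query. A compiled (numba) point-triangle kernel accelerates both
paths; a pure-numpy implementation is the fallback and the reference.

## The comparison matrix and the match rule

All lefts are registered against all mirrored-rights, giving an
`n_left × n_right` matrix of mesh-to-mesh values. A registration failure
poisons only its own cell (+inf, logged).

**Lowest common value (LCV).** A pair is proposed iff its cell is strictly
the minimum of its row (this left's best partner) *and* of its column (this
right's best partner). Tied minima abstain — ties are measure-zero for
continuous values, and abstention is the conservative forensic choice. A
`rank_window = k` variant (greedy sweep, ascending value, each element used
once, cell must rank in the top k of both its row and column) mirrors the
worksheet practice of inspecting the lowest three matches; the default
remains mutual rank 1.

**True negatives.** A fully paired cohort has no true negatives, so a
fraction (default 20%) of individuals is deleted on one side: the element
(whole row or column) is removed from the matrix and the survivor's ground
truth becomes NONE. Deletion operates on individuals, choosing the side at
random, because a true negative is an element whose partner is absent — a
deleted matrix cell alone would not produce one.

**Scoring.** Every element (each row and each column) receives exactly one
determination: TP if proposed with its true partner, FP if proposed with a
wrong one, FN if unproposed though its partner is present, TN if unproposed
and truly partnerless. A correct mutual match therefore contributes two TPs
(one per side). Sensitivity = TP/(TP+FN); specificity = TN/(TN+FP),
reported as not-applicable when no negatives exist.

## ROC analysis

Each finite matrix cell is an observation labelled true-pair or non-pair.
The classifier predicts "pair" when the value is at or below a threshold
(smaller value ⇒ more likely pair — the method's premise fixes the
orientation). The curve is built over all distinct observed values plus a
sentinel; AUC by the trapezoidal rule, which equals the Mann–Whitney
concordance with ties counted half. The AUC standard error uses the
Hanley–McNeil distribution-free formula (DeLong's placement-value variance
is available as an option); the p-value is a two-sided normal test of
AUC = 0.5. The reported operating point maximises the Youden index
J = sensitivity + specificity − 1. `threshold_at_sensitivity` returns the
smallest threshold reaching a target sensitivity — at target 1.0 this is the
triage cut-off that keeps every true pair while excluding as many non-pairs
as possible before confirmatory (e.g. DNA) testing. A stratified percentile
bootstrap (resampling within each label class) gives the AUC confidence
interval.

## Synthetic cohorts

No CT-derived bone models ship with the package; a parametric generator
provides cohorts with the statistical structure the method assumes.

Each clavicle-like bone is a swept tube over t ∈ [0, 1]: centreline
`(L·t, A₁·sin 2πt, A₂·sin πt)` (S-curve in plan view, superior bow),
elliptical cross-section of radius
`r(t) = r_shaft · (1 + α_m e^{−t/0.08} + α_l e^{−(1−t)/0.08})` with the
ellipse aspect falling linearly from 1.0 (medial, t = 0) to 0.6 (lateral),
capped at both ends. Population defaults (mm): length 140 ± 10, S-curve
amplitude 10 ± 3, superior bow 2 ± 1, shaft radius 6 ± 0.8, medial flare
0.4 ± 0.05, lateral flare 0.1 ± 0.15. The lateral flare is deliberately the
largest relative variance component, encoding the anatomical observation
that the lateral (acromial) end is among the most individuating regions of
the bone; this is what makes the fragment-type ordering a testable
generator property. The flare means are chosen so the medial (sternal) end
is reliably the broader one, which lets the long-axis parameterisation
orient a bone from geometry alone when the generator's orientation tag
(`medial_vertex:<index>`, robust to rigid motion and I/O because vertex
order is preserved) is absent.

Within-pair structure: the right side reuses the left's parameters plus a
Gaussian jitter with sd = `asymmetry_fraction` × each parameter's population
sd (default 0.1), *not* an independent redraw — pairs must be more similar
than non-pairs for the problem to be well-posed. Per-vertex Gaussian noise
(0.15 mm, along normals) stands in for segmentation error. Every exported
mesh receives a random rigid pose so alignment is always exercised. A
minority of elements (prevalence 9/160 ≈ 0.056) receives a healed-fracture
callus: local radius multiplied by `1 + h·exp(−(t−t₀)²/2w²)`, h ~ U(0.2,
0.5), t₀ ~ U(0.25, 0.75), w = 0.05, applied along vertex normals. An
`internal_debris` option adds a disjoint interior shell so the hollowing
step (largest-connected-component retention, the mesh analogue of removing
trabecular data) has work to do; it is off by default. All per-individual
randomness is drawn unconditionally so cohorts differing only in pathology
prevalence stay paired element-for-element.

**What the generator does not emulate:** real cortical surface texture,
age- and sex-structured covariation, scanner artefacts, taphonomic damage,
and any empirical clavicle shape statistics (no quantitative shape data were
available to fit). Passing tests therefore demonstrate that the *pipeline*
recovers known structure under controlled noise — not that any particular
accuracy will be attained on real skeletal material.

## Fragments

Three fragment types crop a whole bone by its normalised long-axis
parameter t (first principal axis, oriented medial → lateral): *sternal*
keeps t ∈ [0, f], *acromial* keeps t ∈ [1−f, 1], *midshaft* keeps a window
of width f centred at c ~ U(0.4, 0.6) (two cuts). The retained fraction f
is drawn from (0.25, 0.40) by default — recognisably partial yet
registrable. Cut loops are re-capped by centroid fan triangulation so
fragments stay watertight. Fragments are compared against whole bones of
the opposite side, never fragment-to-fragment.

## Numerical choices and degenerate inputs

- Mirror plane: YZ plane through the mesh centroid (any plane gives a
  congruent result; centroid anchoring keeps coordinates near the data).
- Duplicate-vertex tolerance and round-trip tolerance: 1e-6 mm.
- Rigid transforms are validated orthonormal with det +1 to 1e-8.
- Tied row/column minima in LCV: abstain (no proposal).
- Collinear correspondence sets, planar meshes, zero-area meshes, and
  single-class ROC inputs raise typed errors rather than returning garbage.
- Youden ties resolve to the smallest threshold (deterministic).
- The bootstrap is stratified, so single-class resamples cannot occur.

## Simulation-study problem sizes

Library defaults are sized for desk-scale single comparisons (5000 points,
120 × 48 meshes). The packaged simulation studies (test suite and
`scripts/acceptance.py`) run cohorts of 40 individuals (16 for the fragment
study) at 40 × 16 mesh resolution with 600 ICP sample points, 30 iterations
and 1e-3 mm tolerance — sizes chosen so a full all-vs-all study is a
minutes-scale, single-core computation while preserving the
between/within-variance structure that the conclusions depend on. The
fragment study uses fewer individuals because its multi-start registration
is several times costlier per cell.

## Known limitations

- Absolute mesh-to-mesh values depend on sampling density, trim fraction and
  stopping rule; only their ranking behaviour (pairs vs non-pairs) is
  comparable across implementations of the method.
- Point-to-surface ICP can converge slowly when a near-complete fragment
  slides axially along its counterpart; symmetric or point-to-plane variants
  are out of scope by design.
- The hollowing surrogate assumes internal surfaces are disconnected from
  the outer shell, which matches CT-segmented bone but not meshes whose
  internal structure touches the cortex.
- LCV specificity is undefined (reported as not-applicable) when deletion
  leaves no true negatives, and is highly granular for small cohorts.
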