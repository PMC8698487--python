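# mvcpair

Pair-matching of bilateral skeletal elements from 3D surface meshes by
**mesh-to-mesh value comparison (MVC)**.

Forensic anthropologists and bioarchaeologists confronted with commingled
remains must decide which left and which right bone of a paired element
(clavicles, humeri, …) derive from the same individual. MVC answers this
with geometry alone: every right bone is mirrored, every left is rigidly
registered onto every mirrored right with a trimmed iterative-closest-point
(ICP) algorithm, and each registration is summarised as a scalar residual in
millimetres — the *mesh-to-mesh value*

&nbsp;&nbsp;&nbsp;&nbsp;MVC(L, R) = sqrt( mean of the retained squared point-to-surface distances ),

where the retained set keeps the `trim_fraction` smallest of n area-uniform
surface samples (trimming makes the residual robust to segmentation defects
and fragmentary margins). Two bones from the same individual are more alike
than two bones from different people, so true pairs sit at the low end of
the resulting all-vs-all comparison matrix. Decisions are made by the
**lowest-common-value rule** — propose (i, j) iff cell (i, j) is strictly the
minimum of both its row and its column — and evaluated as per-element
TP/TN/FP/FN tallies (sensitivity = TP/(TP+FN), specificity = TN/(TN+FP))
and by ROC analysis over the matrix values (trapezoidal AUC, Hanley–McNeil
standard error, Youden-index operating point, fixed-sensitivity triage
thresholds).

The package also ships a **synthetic bilateral-bone generator** (parametric
clavicle-like swept tubes with controlled between-individual variation,
within-pair asymmetry, segmentation noise and optional healed-fracture
calluses) and a **fragment simulator** (sternal / midshaft / acromial crops
with watertight re-capping), so the whole pipeline is testable without CT
data. See `docs/methods.md` for the models and numerical choices.

## Worked example

Simulate a small cohort, run the pipeline, and read the summary:

```bash
mvcpair simulate --n 10 --seed 7 --out scratch/cohort --resolution 40 16
cat > scratch/config.yaml <<EOF
manifest: scratch/cohort/manifest.csv
output_dir: scratch/run
icp:        {n_points: 600, trim_fraction: 0.95, convergence_tol: 1.0e-4, seed: 3}
matching:   {rank_window: 1, deletion_fraction: 0.2, seed: 5}
roc:        {n_boot: 500, seed: 9}
EOF
mvcpair pipeline --config scratch/config.yaml
```

which prints (abridged):

```json
{
  "lcv": {"tp": 16, "tn": 2, "fp": 0, "fn": 0,
          "sensitivity": 1.0, "specificity": 1.0,
          "deleted_ids": ["IND006-L", "IND008-R"]},
  "roc": {"auc": 1.0, "p_value": 0.0,
          "criterion_mm": 0.2246, "criterion_sensitivity": 1.0,
          "criterion_specificity": 1.0},
  "n_lefts": 10, "n_rights": 10
}
```

Reading: of 10 simulated individuals, 20% were deleted on one side to create
true negatives (here IND006's left and IND008's right, so each survivor of
those pairs is truly partnerless); the mutual lowest-value rule matched all
8 surviving pairs (16 per-element true positives, sensitivity 1.0) and left
both partnerless elements unmatched (2 true negatives, specificity 1.0).
The ROC analysis separates pair from non-pair cells perfectly (AUC 1.0)
with a Youden-optimal criterion of ≈ 0.22 mm — values at or below that
residual would be called pairs. With
realistic within-pair asymmetry the numbers degrade gracefully; the test
suite exercises that degradation.

The same stages are available as `simulate`, `fragment`, `compare`, `match`
and `roc` subcommands, and as plain library calls
(`build_comparison_matrix`, `lcv_match`, `score_matches`, `roc_curve`, …).

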