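# Methods

This note documents the models, conventions and numerical choices behind
painnet, in the order data flows through the pipeline. Nothing here states a
result the test suite or `scripts/acceptance.py` does not itself compute.

## Connectivity construction

**Volume discarding.** The first 3 volumes of each scan are discarded
(field equilibrium) before anything else; the paired motion trace is cut
identically so frames stay aligned. A 202-volume scan therefore yields 199
analyzed frames.

**Framewise displacement (FD).** No single formula is universal for
"frame-to-frame displacement over 6 DOF"; we adopt the sum-of-absolute-
differences convention: `FD_t = Σ|Δtrans_i| + Σ r·|Δrot_j|`, rotations in
radians converted to arc length on a sphere of radius `r = 50 mm` (the
standard convention for cortical-scale atlases; config-exposed).

**Scrubbing.** A transition with FD *strictly* greater than 1.5 mm marks the
*latter* frame of the pair as excluded; FD exactly at threshold retains.
Excluding only the latter frame is the minimal reading of "time points were
excluded"; a config flag (`scrub_drop_preceding`) optionally also drops the
earlier frame.

**Motion covariate.** Mean absolute frame-to-frame difference per parameter
(rotations converted to mm via the same 50 mm radius), averaged over the six
parameters. Computed on the post-discard trace, before scrubbing, so it
summarizes movement across the analyzed scan.

**Correlation and Fisher transform.** Pearson correlation over retained
frames only; at least 3 retained frames are required, and a zero-variance
region is a named error rather than a silent NaN (NaNs would propagate
invisibly into the graph metrics). Off-diagonal `|r| = 1` is rejected
(maps to ±∞ under arctanh). The adjacency is symmetric with an exactly zero
diagonal.

## Graph topology

**Weight→length conversion.** Connection strength `w > 0` becomes length
`1/w`. Non-positive Fisher-z weights are treated as absent edges by default
(`negative_policy="zero"`); the magnitude variant (`"abs"`) is available.
This is the single most result-relevant unstated convention in this family
of analyses — the classical weighted-efficiency/betweenness routines assume
non-negative weights — so the policy is config-exposed and recorded in every
run manifest rather than hard-wired.

**Shortest paths.** One Dijkstra sweep per source, vectorized so all
sources advance in lockstep (for dense functional networks the O(n²)
scan-based Dijkstra is the right complexity class; the whole 264-node
all-pairs computation is a few hundred milliseconds). Path-length ties are
judged at a *relative* tolerance of 1e-10 so shortest-path counts are stable
in floating point; equal-length alternatives accumulate into the count.

**Global efficiency.** Mean of `1/d(i,j)` over ordered pairs, with
`1/∞ = 0`. Closed forms used as fixtures: a complete uniform graph of weight
`w` has `GE = w`; an edgeless graph has `GE = 0`.

**Betweenness centrality.** Accumulated through the dependency identity
`σ_st(v) = σ_sv·σ_vt` when `d(s,v) + d(v,t) = d(s,t)` (same tie tolerance),
reported on the unordered-pair scale for undirected graphs (a 4-node star's
center scores 3). Equality with exhaustive simple-path enumeration and with
an independent Brandes implementation is asserted in the tests to 1e-9 on
random graphs.

**Per-participant normalization and summaries.** BC is computed once on the
whole-brain graph, z-scored across all of its nodes with the population
(n-denominator) SD — the sample-SD variant is config-exposed (`zscore_ddof`)
since either convention is defensible — and then averaged within each
subnetwork. Computing or z-scoring BC *within* a subnetwork would force its
mean to zero identically and carry no between-subject information, which is
why the whole-brain-first order is the only coherent one. Subnetwork GE uses
the induced subgraph (paths confined to the subnetwork) by default; the
alternative reading (whole-brain distances restricted to subnetwork pairs)
is available as `subnetwork_ge_mode="restricted"`. The whole brain gets GE
only: its mean z-BC is zero by construction.

## Node sets

Node sets are 0-based index sets into the 264-node whole-brain ordering,
shipped as editable JSON (`{"name", "n_total", "indices", "labels"?}`):
whole brain (264), DMN (58), pain network (16 positive-weight neural pain
signature regions; their anatomical names ship with the set). The *index
assignments* of the pain and DMN sets are documented placeholders — the
published atlas index tables are not bundled — and every computation is
index-set-generic, so substituting exact indices is a data edit, not a code
change. Sphere-ROI extraction from 4-D NIfTI (voxel-center-in-sphere
membership, world coordinates through the image affine, mean over member
voxels, default radius 5 mm) is provided as an optional ingestion path for
users with their own preprocessed volumes.

## Synthetic cohorts

The generator emulates the study design the pipeline targets: 24 patients
scanned twice (ON and OFF medication), 27 controls scanned once, 264 regions,
199 analyzed frames (the pipeline demo simulates 202 and discards 3).

**Signal model.** Zero-mean multivariate normal per frame with target
correlation `baseline_r = 0.10` between all pairs and an elevated value
within the pain block (`0.45` patients, `0.30` controls), plus independent
Gaussian sensor noise (`noise_sd = 0.5`). The target matrix is verified
positive semi-definite and rejected otherwise with the offending parameters
named. Each subject draws their own pain-block correlation from
`N(group value, pain_r_sd = 0.10)` (clipped to [0, 0.9]): without
between-subject variation in the generating topology there would be no
within-group association for the regression stage to recover, so this spread
is what makes the planted-link design meaningful.

**Motion model.** AR(1) drift per parameter (coefficient 0.95, innovation SD
0.02 mm for translations and 0.02° for rotations, stored in radians) plus
translation spikes of 2.0 mm with probability 0.02 per frame — drift FD sits
well below the 1.5 mm threshold and spikes well above it, so scrubbing
exercises both branches.

**Pain scores.** `NWC = round(max(0, β·GE_true + ε))` with `β = 40` per GE
unit and `ε ~ N(0, 2)`; `GE_true` is the global efficiency of the noise-free
generating pain block (a complete uniform Fisher-z graph, so
`GE_true = arctanh(r_subject)`), giving a planted positive association with
signal-to-noise ≈ 2.5 at the default spread. A config switch
(`link_target="bc"`) plants the link on mean pain-network z-BC of the
generating graph instead. NWC and the chronic-pain flag are subject-level
(the questionnaire is answered once); the two 0–100 colored-analogue-scale
ratings are session-level, drawn from clipped exponentials whose means
differ by group. Chronic-pain prevalence is 75% (patients) / 40.7%
(controls).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: hemodynamic autocorrelation and filtering,
physiological noise, spatial smoothness, scanner artifacts, realistic
pain-score distributions beyond group ordering, any ON/OFF difference in
network coupling, and non-Gaussian tails. Recovery results are statements
about the pipeline's correctness under its own generating model, not about
effect sizes in patients.

## Statistics

**Mann–Whitney U** reports the U of the first-listed sample (printed U
values depend on this unstated convention, so it is fixed and documented);
p is exact by enumeration when `n1·n2 ≤ 400` with no ties, else the
tie-corrected normal approximation. **Chi-square** is the uncorrected
Pearson statistic (no Yates correction) — required to reproduce the
in-text worked example `χ²(1) = 6.080, p = 0.014` from the 18/24 vs 11/27
chronic-pain table. **ANCOVA** fits `DV ~ group + covariate` per measure
and tests the group term with type-III sums of squares (with two groups and
one covariate this coincides with the sequential test); a zero-variance
covariate degenerates cleanly to one-way ANOVA. Wilks' lambda across the DV
set is reported when at least two DVs are given and their sample covariance
is nonsingular (mean z-BCs of subnetworks that jointly exhaust the brain are
exactly linearly dependent — z-scores sum to zero — and the multivariate
test is then undefined and omitted). Group comparisons are run as two
two-group models (controls vs each patient session), which reproduces the
(1, 48) degrees-of-freedom structure at the target sample sizes; treating
the repeated patient sessions as independent samples is a known statistical
caveat of that design, inherited deliberately rather than resolved.

**Forward stepwise.** Step 1 is the forced covariate-only model; at each
later step the candidate with the smallest entry p (its coefficient t-test
given the current model, equivalent to the partial F) enters when
`p ≤ 0.05`. Pure forward selection by default — no removal step — with an
optional removal threshold (`p_remove`, e.g. 0.10) for the common
statistical-package default. Reported per step: unstandardized B, SE,
standardized B (`B·sd(x)/sd(y)`), per-term p, model R²/F/p. Exact
collinearity among candidates is a named error. No multiple-testing
correction is applied anywhere (α = 0.05, two-sided, per test), and each run
manifest records the number of tests.

## Monte-Carlo scales and pre-committed bounds

The acceptance-level simulations use scaled-down cohorts chosen once:
40-node graphs with a 16-node pain block, 24 OFF-phase patients, 202 frames,
100 replicate cohorts per condition. Statistical bounds were fixed before
running from the binomial sampling error of the replicate counts: planted
recovery asserted at ≥ 80%; the no-entry rate under two null candidates has
expectation `(1 − 0.05)² ≈ 0.90` and is asserted 2 binomial SDs below
(≥ 0.84 at 100 replicates); the null GE-selection rate (expectation ≈ 5%)
is asserted at the ~10% design bound plus 2 SDs (≤ 16%).

## Known limitations

- Placeholders for the pain-16 / DMN-58 atlas indices (see above); results
  on real data require substituting the published assignments.
- The negative-weight policy, z-score denominator and subnetwork-GE reading
  are conventions, not ground truth; all are config-exposed and logged.
- Scaled-down designs in which the named subnetworks cover every node make
  the subnetwork mean z-BCs exactly collinear; the multivariate test is
  omitted there by design.
- The generator's independence of frames (no temporal autocorrelation)
  makes correlation estimates slightly less variable than real BOLD at the
  same frame count.
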