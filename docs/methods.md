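# Methods

## Model and decomposition

The pipeline models a cohort's natural-log expression matrix (samples `k` ×
analytes `i`) as a steady-state term minus a sum of unbalanced-process
terms,

    ln X_i(k) = ln X_i^0(k) − Σ_α G_iα λ_α(k),

and obtains the terms from the exact singular value decomposition of the
ln-matrix. The rank-one component with the largest singular value is
designated the steady-state/baseline term. This is justified on expression
data because the shared expression profile dominates every sample: the
baseline's per-sample weights are near-constant, and we report both the
analyte pattern and those weights (`baseline_log_levels` is the pattern
times the mean weight). The remaining components, in descending singular
value, are the candidate processes. Conventions that make the decomposition
unique and reproducible:

* `G` columns are unit-norm; singular values are absorbed into `λ`, so
  amplitudes are comparable across processes.
* Each `G` column is oriented so its largest-magnitude loading is positive
  (`λ` flips in tandem); the baseline is oriented to positive mean weight.
* Exactly tied singular values are ordered by lexicographically smaller
  `G` column. Sub-tolerance components (relative singular value < 1e-12)
  are dropped with a warning.

A matrix read with `scale="log"` (e.g. TCPA level-4 RPPA, already log-like
normalised and possibly negative) is factored verbatim; `scale="linear"`
input is ln-transformed after the preprocessing step enforces positivity.
Whether further normalisation of ln X before factorization would be
preferable cannot be decided from the available description of the original
analyses; we factor ln X directly and expose both input scales.

## Missing data

The source datasets' missing-data handling is not documented, so the policy
here is deliberately simple and auditable: analytes missing in more than
`max_missing_frac` (default 0.3) of samples are dropped; remaining gaps are
filled with the analyte's median; on linear input the whole matrix is
shifted by `pseudocount − min` if any value is ≤ 0 (order-preserving).
`preprocess` returns a report of everything it changed and is idempotent.

## Number of processes and error limits

`estimate_num_processes` offers two estimators:

* `noise_floor` (default): accept process `r+1` while its singular value
  exceeds `multiplier` (default 2.0) times the root-mean-square of the
  remaining spectrum, which estimates the noise level; ranks dropped for
  rank deficiency count as zero-noise trailing values.
* `permutation`: sequential parallel analysis. Process `r+1` is tested on
  the residual after deflating the baseline and the `r` accepted processes:
  its singular value must exceed the 95th percentile of top singular values
  of column-permuted copies of that residual. Permuting the raw matrix
  instead would fold accepted signal variance into the null and mask weaker
  true processes. Default 200 resamples; at 60 resamples the 95th-percentile
  estimate is noisy enough that occasional off-by-one results occur.

Amplitude error limits `T_α` are per-process scalars shared by all samples.
The default method, `noise_edge`, sets `T_α = multiplier × SD` of the
amplitudes of the *strongest* non-retained component: pure noise produces
amplitude patterns up to its spectral edge, so an amplitude is
distinguishable from noise only beyond what the largest noise component
generates — the same logic by which parallel analysis compares against the
top of the null spectrum. Two alternatives are provided: `trailing_noise`
(multiplier × pooled SD over *all* non-retained amplitudes — the bulk noise
floor, roughly 1.9× smaller than the edge at 200×150, hence more permissive
and more false activations) and `resample` (analyte bootstrap). The
original error-limit procedure is published only by reference and is not
reproduced here; cohort-level counts of processes and barcodes on real data
are therefore threshold-sensitive, and the significance report records
every setting used.

Significant proteins per process are the top `g_param` fraction by
`|G_iα|` (`quantile`, default 0.05) or those above `g_param` × SD of
noise-process loadings (`noise_sd`); ties break by analyte order.

## Barcodes, subgroups, targeting, treatment comparison

Barcode entries are `sign(λ_α(k))` where `|λ_α(k)| > T_α`, else 0;
amplitudes exactly at the limit are insignificant (strict inequality).
Patterns serialise over `{-, 0, +}`. Subgroups are exact-match groups,
ordered by descending size, ties by lexicographic pattern ('+' precedes
'0' precedes '-'); subgroup numbering is a frequency rank, nothing more.

Target selection ranks a process's significant proteins by `|G_iα|` and
chooses the top one that is upregulated in the sample (direction
`sign(−G_iα λ_α(k))`, the model's minus sign) and present in the drug map;
inhibitors act on induced activity, hence the upregulation preference. This
is a deliberate, reproducible substitute for network-centrality-based hub
selection, which would require an external interaction service. Every
active process must be covered; processes without a qualifying target are
flagged, never silently dropped. A `max_targets_per_process` option
nominates additional hubs for highly active processes; no automatic
trigger is set because no principled amplitude cutoff for "highly active"
is available.

Pre/post-treatment comparison requires barcoding both timepoints against
one pooled factorization, the only way process indices stay aligned. The
per-(patient, process) classification is a pure function of the two ternary
states: abolished (≠0→0), induced (0→≠0), persistent (x→x), sign-flipped
(x→−x), inactive (0→0); it is antisymmetric under swapping the timepoints
(abolished ↔ induced). Per-analyte direction annotations use
`sign(−G_iα Δλ_α)` and are a readout of the fitted model, not a new fit.

## Synthetic cohorts

`generate_cohort` builds `ln X = baseline + λ Gᵀ + ε` with known ground
truth. Defaults — the conditions every recovery claim refers to — are 200
samples × 150 analytes, 3 processes, support 20 analytes per process with
20% overlap between consecutive supports, activation probability 0.3 per
(sample, process), planted threshold 1.0 in amplitude units, active
`|λ| ~ U(2, 3)` × a per-process strength, SNR 10. Noise is i.i.d. Gaussian
on the log scale with SD = mean active amplitude of the weakest process /
SNR (0.25 at SNR 10). Heavier-tailed or antibody-structured RPPA noise is
not simulated, so passing tests demonstrate correctness of the machinery
under the model's own assumptions, not robustness to real RPPA artefacts.

Identifiability shapes several generator choices. A spectral method can
only recover individual factors that are actually identifiable, so the
generator plants:

* **Separated process strengths** (geometric ladder, step 2.0, strongest
  first), mirroring the decreasing abundance of real processes; exactly
  degenerate strengths would leave rotations within the signal subspace
  arbitrary. The step is wide enough that the pooled spectrum stays
  separated even when a treatment effect silences one process in half of a
  paired cohort (a 1/√2 factor in pooled scale).
* **Orthogonal structure**: `G` columns are Gram-Schmidt-orthogonalized
  against the baseline pattern and each other (non-orthogonal parts would
  be absorbed by the baseline or rotated between processes — unrecoverable
  in principle). Amplitude columns are made mean-free and mutually
  orthogonal by alternating projections that adjust only active entries,
  keeping inactive amplitudes exactly zero and active ones inside a band
  above the threshold. At the default size this converges to exact
  orthogonality; cohorts under ~100 samples keep the residual correlation
  their sample size forces, which is why exact noiseless recovery is stated
  (and tested) at the default size.
* **Balanced activation signs** per process: a net sign imbalance would
  shift the process mean into the unidentifiable baseline, offsetting every
  inactive sample's estimated amplitude.
* **Participation weights bounded away from zero** (`U(0.5, 1.5)` signed):
  an analyte with negligible weight does not meaningfully participate, and
  planted supports should be recoverable by any sensible significance rule.
* **Inactive amplitudes exactly zero**: an uninvolved sample deviates only
  through noise; any planted "small but nonzero" inactive band becomes
  detectable once the noise floor drops below it, making recovery
  non-monotone in SNR.

`score_recovery` matches estimated to planted processes one-to-one by
maximal `|corr(G_est, G_true)|` (Hungarian assignment), aligns each match's
sign (process orientation is a convention), and reports the matched-G mean
`|r|`, barcode sensitivity (truly active entries recovered with correct
sign) and specificity (truly inactive called inactive), and the adjusted
Rand index between the partitions induced by estimated and true barcodes.

Paired cohorts add a `TreatmentEffect` (processes abolished in all
patients; processes induced with given probability in previously inactive
patients, sign-balanced), decorrelate the stacked before+after amplitudes
jointly (the pooled factorization sees one cohort), and record planted
per-patient transition classes.

## Problem sizes and numerical notes

The acceptance script and tests use 100 generator seeds at the default
200×150 conditions for recovery rates, 50×30 random matrices for the
factorization identities, and 60 patient pairs for the treatment check —
sizes at which every statistic is stable and the whole suite runs in
seconds on one core. Dense LAPACK SVD is used throughout (target data are
at most a few thousand × a few hundred). Reconstruction identities hold to
~1e-14 relative; orthogonality of `G` to 1e-10. Degenerate inputs are
handled explicitly: constant matrices yield a baseline with zero processes
(warning), rank-deficient inputs retain the available rank (warning), and a
zero-process estimate warns that the data are indistinguishable from noise.

## Known limitations

* Real-cohort headline counts (number of processes, number of distinct
  barcodes in a given tumor panel) depend on the threshold settings;
  reproducing published counts requires the original data tables and the
  original (unpublished) threshold code, so they are reported with settings
  rather than asserted.
* Process signatures from two different decompositions are comparable only
  up to sign (`process_signature_similarity` reports both raw and absolute
  correlation).
* The drug map shipped as package data is a small convenience fixture of
  well-known target→inhibitor pairs, not a curated pharmacopoeia; supply a
  full map for real analyses.
* No dosing, toxicity or drug-interaction modelling; the combination is a
  coverage statement over processes, and clinical selection among
  equivalent hubs is out of scope.
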