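# Methods

This note documents the models, the numerical choices, and what the
synthetic generators do and do not emulate. Parameter names refer to
`AtlasSimConfig`, `ClusterParams`, `QCThresholds`, `BreathModel`,
`VentilationProtocol`, and `BurstParams`.

## Synthetic expression atlas (`psn_atlas.sim.atlas`)

**Model.** Expression is log-normal in log2(TPM+1) space: each (cell type,
gene) pair has a mean on the log2 scale; cells draw independent Gaussian
deviates (population `dispersion`, default 0.5 log2 units) which are
clipped at zero, exponentiated, and renormalized so every cell sums to 1e6
(TPM). No count/dropout model is implied — the downstream analyses operate
on continuous TPM, so the distributional form is a declared stand-in.
Housekeeping genes (default 20, including Gapdh/Actb stand-ins) are planted
at high abundance (log2 mean 15–16) with dispersion 0.1; besides emulating
"no dropout, minimal variance" controls, they carry most of the library
mass so that each cell's linear sum is already ≈1e6 and the final TPM
renormalization is a small correction that does not distort the planted
log-scale geometry. (With low-abundance housekeeping the renormalization
factor is large and the log2(TPM+1) re-expansion inflates the variance of
low-expressed genes several-fold, burying the planted structure.)

**Structure.** The default configuration plants, among 123 QC-passing
neurons (8 populations PSN1–8, the 2-cell PSN9, a 9-cell PSN2/PSN3 hybrid
bridge): 20 markers per population at log2 mean 6.0 against a base of 0.5;
two shared super-group programs (PSN1–5 vs PSN6–9, 30 genes each) that make
the first split separate the super-groups; and a 20-gene PSN8/PSN9 program
so the rare PSN9 pair co-clusters with PSN8 until rescued. The hybrid
bridge's parents (PSN2/PSN3) deliberately carry fewer (10) and milder
(log2 mean 2.5) markers, and hybrid mixing weights are uniform on
(0.2, 0.8): hybrid cells are strictly intermediate (a weight of 0 or 1
would be a parent replica), and the moderate parent contrast makes the
pair's cluster boundary genuinely dependent on the HVG subset — the
defining behavior of a hybrid state. With a strong contrast the boundary is
pinned (no cell ever flips) or the bridge resolves as its own stable leaf;
neither matches an intermediate continuum. Hybrid profiles are convex
mixtures λ·A + (1−λ)·B **in log space**, matching the gradual per-gene
gradients the heatmap view of such bridges shows.

**Covariates.** Depth covariates (`mapped_read_pairs` in 2.4–12.4 M,
`expressed_gene_count` in 10,300–14,000) are drawn independently of the
matrix; 5 + 3 extra cells are forced below the QC thresholds and 5
glial-contaminated cells (population profile plus a 30-gene glial program
at log2 mean 6) complete the 136-cell input. Soma diameter, Nefh tier, and
Phox2b (absent in the neural-crest populations PSN1/PSN9) are planted per
population for the annotation and cell-size analyses.

**Not emulated:** batch effects, UMI/droplet noise, read-level artifacts,
doublets, ambient RNA, and realistic mean–variance coupling. Passing tests
demonstrate that the pipeline recovers structure of this planted kind at
study scale; they do not certify performance on real Smart-seq2 data.

## QC (`psn_atlas.qc`)

Cells with < 2,000,000 mapped read pairs or < 10,000 expressed genes
(TPM ≥ 1 is the single detectability threshold used package-wide) are
excluded; thresholds are inclusive lower bounds. Glial contamination is
scored as the cell's coordinate on PC1 of the gene-standardized
log2(TPM+1) glial-panel submatrix, signed so that higher = more glial;
cells with standardized score z > 2.5 are removed. The 2.5 cutoff is a
conservative outlier rule (normal tail ≈ 0.6 % false removal) chosen
because the removal procedure beyond "PCA on glial genes" is not otherwise
specified; it is configurable. Removals are attributed to the first failed
criterion in the order reads → genes → glial. A cutoff of +inf disables
glial removal (vacuous threshold); NaN is rejected.

## Iterative clustering (`psn_atlas.cluster`)

- **HVGs** (`n_hvg` = 500): variance of log2(TPM+1) after removing a
  quadratic trend of log-variance on mean expression; ties broken by raw
  variance; variances ≤ 1e-12 count as constant.
- **Embedding:** gene-standardized HVG submatrix; Horn-style parallel
  analysis (20 column permutations, 95th percentile) keeps at most
  `max_pcs` = 5 PCs, at least 1.
- **2-means:** initialized from the two maximally separated cells plus 9
  k-means++ restarts; best objective wins; labels canonicalized so the
  cluster containing the lowest cell index is cluster 0.
- **Stability:** 100 bootstrap resamples; each refit is a Lloyd descent
  *from the reference centroids* on the resampled cells, after which every
  cell is assigned to the nearest refit centroid. Free-restart refits were
  rejected: whenever a node still contains more than two populations they
  hop between near-equivalent cuts, zeroing every cell's stability and
  halting the recursion; descent from the reference centroids measures the
  stability of *this* partition under resampling, which is the quantity the
  promotion rule needs. Clean two-cluster nodes still yield stability 1.0
  for every cell, and bridge cells still drop out as gray.
- **Significance:** the between/within sum-of-squares ratio of the
  2-means partition, compared with 199 permutations in which each HVG is
  shuffled independently across cells and the *identical* procedure (same
  PC count, same restart budget) is re-run; p = (1+#{perm ≥ obs})/200,
  α = 0.01. The permutation count is a desk-scale choice (it resolves
  p < 0.01; raise `n_perm` for a finer floor). Equal restart budgets
  matter: optimizing the observed statistic harder than the null
  replicates makes the test anti-conservative and splits pure populations.
- **Termination:** non-significant separation, or a putative group (before
  or after removing gray cells) smaller than `min_size` = 5.
- **Rare rescue:** within each leaf, distance to the coordinate-wise
  median profile in global-HVG log space; cells beyond `rescue_factor`
  = 2.5 × the leaf's median distance that are mutual nearest neighbours
  form rare clusters (≥ 2 cells allowed below `min_size`). The median
  center keeps a 2-cell outlier pair from dragging the centroid toward
  itself.
- **Hybrids:** for every mutual-nearest pair of leaves (centroid distance
  in global HVG space), the split is re-run 50 times on random halves of
  the pair's own HVG set; cells flipping on 25–75 % of runs are hybrids.
  Mutual-nearest pairing replaces a strict "both children are leaves"
  sibling rule because the recursion order interleaves (a third population
  may split off between the two parents), leaving the true parent pair
  non-sibling in the tree. Gray cells attach to their nearest leaf
  centroid and participate. Gradient position is the projection onto the
  segment from parent A's to parent B's centroid, clipped to [0, 1].

## Markers and repertoires (`psn_atlas.markers`)

Pairwise DE uses the two-sided Mann–Whitney rank-sum on log2(TPM+1) with
the tie-corrected normal approximation (vectorized across genes) and BH
correction within each pair; effects are log2 fold changes of mean
(TPM+1). This is a deliberate, documented replacement for heavier
single-cell Bayesian error models; the defining computation — intersecting
the per-pair DE lists so a marker must win against *every* other subtype —
is preserved exactly. One consequence is handled explicitly: against a
2-cell subtype the rank-sum/BH combination cannot certify any gene
(the exact two-sided p floor is 2/C(n,2), and BH across thousands of genes
pushes even floor-level p far above α), so such comparisons would veto
every marker genome-wide. A pairwise comparison therefore counts as
*powered* only if it certified at least one gene (min q ≤ α); unpowered
comparisons fall back to the fold-change criterion alone, and a subtype
with no powered comparison at all (the 2-cell rare cluster) receives no
marker list. Dot-plot means are taken over **all** cells of a subtype, not
only expressing cells. Fiber-type cut points default to terciles of the
subtype Nefh medians (qualitative low/intermediate/high tiers); pass
explicit cut points for calibrated data. Ligand–receptor pairing applies
the strict prevalence rule (> 50 % of cells in ≥ 1 subtype) on the neuron
side and frac ≥ min_frac on the immune side, in both directions.

## Synthetic physiology (`psn_atlas.sim.physio`)

Breaths are half-sine inspirations (positive flow by convention; a CLI
flag inverts on input) with a volume-balancing half-sine expiration, so
TV = (2/π)·PIF·Ti exactly. Defaults: Ti 0.133 s, Te 0.267 s (150
breaths/min), TV 0.2 mL — conventional mouse-scale placeholders; the
analyses consume relative changes, not absolute volumes. Per-breath
lognormal jitter (σ: Ti 0.05, Te 0.05, PIF 0.08); sniffing bouts at 2–4×
rate and 50 % amplitude occupy ~20 % of the record. Truth tables label a
breath eupneic only if it is in a quiet epoch **and** at least 4 breaths
(`transition_guard`) from a bout: breaths flanking a sniffing bout are
transitions, not quiet breathing, and any centered regularity window that
touches a bout is correctly rejected by the selector.

Scenario presets encode the ablation phenotypes as multipliers on eupneic
breaths: `psn6_ablation` Ti ×1.11; `psn7_ablation` PIF ×1.13 and Ti ×1.018
(their product gives the ~15 % tidal-volume change). EMG burst duration
under an inflation hold at pressure p is scaled by the preset's
`emg_ti_curve` (control: 0.85/0.72/0.55/0 at 6/8/10/20 cmH2O; the
PSN6-ablation curve is flattened to 1.0 at 6 and 8 cmH2O only; 0 means
apnea), and burst rate falls with pressure. Note that the planted 1.8 % Ti
component of the PSN7 preset, though physiologically "effectively
unchanged", is real and is detected as significant by an exact
Mann–Whitney on low-noise simulated cohorts — significance flags on
near-null parameters of this simulator should be read accordingly.
Calcium traces implement five response classes (sustained type I/II,
rapidly adapting with τ = 0.5 s, inflation-suppressed, non-responding);
the default cohort is 29 cells: 7 type I, 4 type II, 18 non-responders,
with type-I somata drawn large (≈34 µm).

## Breath analysis (`psn_atlas.breath`)

Zero-phase 4th-order Butterworth low-pass at 20 Hz; hysteresis band ±2 % of
trace SD around zero; TV by trapezoidal integration of inspiratory flow;
PIF/PEF from the filtered extrema (the filter's attenuation is common to
pre and post conditions and cancels in the ratio-based effect statistic).
The eupnea rule (window 9 breaths, CV ≤ 0.15 on period and TV) is the
minimal reading of "computationally selected for regular breathing" and is
fully configurable. KDE peaks use a Gaussian kernel with Silverman
bandwidth on a 512-point grid spanning [min−3h, max+3h]; with ~1000
eupneic breaths the per-animal peak estimate has an SD near 1.5 % of its
value, which is why effects are reported as cohort means. Group comparison
uses the exact Mann–Whitney null for ≤ 8 animals per group (no ties) and
the tie-corrected normal approximation otherwise; an all-tied degenerate
input returns p = 1.

## EMG and calcium quantification (`psn_atlas.stim`)

Burst detection: rectify, 25 ms moving RMS, threshold at quiescent
baseline mean + 3 SD, supra-threshold runs ≥ 20 ms, bursts merged when
separated by < 30 ms (runs are length-filtered *before* merging, so noise
blips cannot chain into pseudo-bursts). The quiescent baseline pools every
0.25 s window whose mean envelope level is at or below the 20th percentile
of window levels, and the mean/SD are taken from the **rectified signal**
in those windows (for Gaussian noise: mean 0.80 σ, SD 0.60 σ, putting the
threshold near 2.6 σ of the raw noise — above any smoothed-envelope
excursion, so pure noise yields no bursts). Envelope-based SDs were
rejected: selecting quiet windows truncates them and parks the threshold
at the envelope's own fluctuation scale. Detected durations are within one
RMS window of truth; the additive widening is common to baseline and hold
bursts and largely cancels in ΔTi.

Calcium calls use the 5 s before the first hold as baseline; responder
and deflation-decrease thresholds are ±3 baseline SDs and the slow/rapid
adaptation cut is 0.5 on the last-vs-first-second response ratio of the
20 cmH2O hold — the qualitative definitions ("sustained the holding
period") made operational; both are configurable. Classification is
invariant to adding a constant to the trace. Soma diameter is the
equivalent-circle diameter of the largest cross-sectional area in the
optical stack. `hold_anova` provides the two-way ANOVA with
Šidák-corrected per-pressure contrasts as a reporting utility; the factor
coding (group × pressure, per-animal rows) is this package's choice.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; pipeline artifacts are plain text with sorted
keys, and each run writes a manifest of SHA-256 content hashes, so reruns
are byte-identical. The default problem sizes — 2,000 genes (not the full
~12,500-gene transcriptome), 123 neurons, 199 split permutations, 100
bootstrap resamples, 50 half-HVG runs, ~2,000 breaths per simulated
recording, 6 animals per arm — are desk-scale choices that preserve the
structure of the full analyses; every one is a parameter.

## Known limitations

- The clustering significance test assumes gene-wise exchangeability under
  the null; strongly correlated null structure (e.g. cell-cycle programs)
  would inflate splits.
- The rank-sum DE stand-in has no dropout model; marker calls against
  very small clusters rely on fold change alone (see above).
- The eupnea selector's CV rule has no apnea/sigh classes; irregular
  breathing other than the simulated sniffing bouts is untested.
- KDE-peak effects are biased for strongly skewed or multimodal parameter
  distributions if pre and post shapes differ.
- The physiology simulators are phenomenological (no airway mechanics,
  no pressure–volume loop), so only relative effect recovery is meaningful.
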