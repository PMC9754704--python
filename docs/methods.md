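# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations behind `nupdi`. It is written for users who need to judge
what the package's validation does and does not establish about real data.

## Detachment index (DI)

The DI of one nucleus at one timepoint is the mean nucleoplasmic intensity of
the tagged nucleoporin divided by its mean nuclear-envelope intensity,
measured on a single mid-nucleus z-slice. It is dimensionless and invariant
under global intensity scaling, which is what makes it comparable across
cells and imaging sessions. Reported DI values are usually normalized to the
mean DI of a reference group (for example a pre-anaphase timepoint, or a
transmembrane nucleoporin at the matched stage), so the reference group's
mean normalized DI is exactly 1.

### Mask method (`imaging_quant`)

1. **Background subtraction** — rolling-ball, default radius 15 px, output
   clipped at 0. Note a structural caveat: the rolling ball partially climbs
   onto wide plateaus, so a nucleoplasmic plateau wider than about twice the
   ball radius is slightly suppressed. At nucleus radii near the ball radius
   this depresses the nucleoplasmic mean by up to roughly 20% of the plateau
   height. Both DI methods read the same subtracted image, so the effect
   largely cancels in *comparisons*; it is one reason DI is treated as a
   relative index and normalized to a reference group.
2. **Mid-slice selection** — the z-slice maximizing histone-channel nuclear
   area above a single Otsu threshold computed over the whole z-stack; ties
   break to the lower index.
3. **Nuclear mask** — Otsu threshold on the background-subtracted histone
   slice, hole filling, then the largest connected component (restricted to
   a per-cell crop window in multi-cell fields).
4. **Compartments** — nucleoplasm = nuclear mask eroded by a disk
   (default radius 4 px); envelope region = nuclear mask dilated by a disk
   (default 2 px) minus the nucleoplasm. The defaults give a ~6 px annulus,
   comfortably covering a diffraction-limited envelope rim at ~0.1 µm/px;
   both radii are exposed in every API and in the CLI. Erosion leaving
   fewer than 25 nucleoplasmic pixels sets a QC flag; erosion that empties
   the mask, or a configuration with an empty envelope region, is an error.
5. **DI** — `mean(nup | nucleoplasm) / env_mean` where
   `env_mean = (sum(nup | total) − sum(nup | nucleoplasm)) / (area(total) −
   area(nucleoplasm))`. "Total" defaults to the dilated region — the reading
   under which subtracting the nucleoplasmic signal leaves exactly the
   envelope annulus — with the bare nuclear mask available as a sensitivity
   variant (`total_region="nuclear"`). Negative or NaN-free inputs are
   enforced; pixels are clipped at 0 before the ratio.

Because any annulus wider than the true envelope shell averages in
off-shell pixels, the mask method carries a geometry-dependent bias of
order (1 px / shell thickness). The validation suite therefore separates
two claims: (a) with the annulus aligned to the rendered shell, DI matches
simulation truth within 5%; (b) the erosion/dilation segmentation chain
reproduces an independent brute-force morphology oracle exactly. Absolute
DI from the default chain is *not* claimed unbiased — consistent with
treating DI as a normalized, within-experiment index. Nuclear geometry
itself also shifts DI (a lobed anaphase mass has a different
surface-to-volume sampling than a sphere), so a mask-circularity covariate
is reported alongside every mask DI rather than corrected for.

### Line-profile method (`line_profile`)

A 5-px-wide profile across the nucleus (bilinear interpolation, samples at
1-px spacing, perpendicular averaging) shows the envelope as two peaks.
Peaks are detected with a prominence floor of 10% of the profile's dynamic
range (configurable); more than two candidates are pruned to the two most
prominent and QC-flagged — an automated stand-in for manual review of
misidentified peaks; fewer than two is an error carrying the candidate
list. Peak positions are integer sample indices (no sub-pixel
interpolation). DI = mean intensity over the middle 50% of the inter-peak
span (computed in continuous position, inclusive of the window endpoints,
which still excludes both peaks whenever the peak separation is ≥ 4
samples) divided by the mean of the two peak heights. Min–max profile
normalization maps a profile to [0, 1] and rejects constant profiles.

## Event calling (`event_timing`)

* **Anaphase onset** — first frame where the histone-mask circularity
  4πA/P² drops below 0.85, or the mask splits into two components,
  whichever comes first. The split rule is unambiguous; the circularity
  threshold catches pre-split elongation the way a visual "distortion from
  spherical" staging does. 0.85 sits safely below the ~0.95–1.05 range that
  digitized disks of realistic radius produce.
* **SPB separation** — first frame with ≥ 2 local maxima above an intensity
  floor separated by ≥ 3 px. The floor defaults to halfway between the
  frame median and frame maximum, evaluated per frame: before separation
  the two puncta superpose and nearly double the peak intensity, so a
  global floor would be biased by pre-separation frames. The non-maximum
  suppression radius is kept below the separation threshold so puncta at
  exactly the threshold distance are retained, with the separation enforced
  by an explicit pairwise-distance check.
* **Detachment / reattachment** — "near-maximal relocalization" is
  operationalized as the DI series crossing
  `baseline + f·(peak − baseline)` with f = 0.8 (configurable; sweeping
  0.7–0.9 moves calls by at most one frame on synthetic cohorts).
  Baseline is the series median, computed on a 3-point median-filtered
  copy when smoothing is enabled (default); the peak and the crossings are
  evaluated on the raw series, because a 3-point median erases genuine
  single-frame events — common when ~10-min events are sampled every
  5 min. Detachment is the first frame at/above threshold, reattachment
  the first frame after the peak below it. Series whose excursion stays
  under `min_excursion` (default 0.3 on normalized DI) give a no-event
  call; an event still above threshold at the last frame is censored
  (detachment set, reattachment absent, QC flag). No survival-analysis
  treatment of censored events is attempted beyond the flag.
* **Summaries** — per replicate and pooled: mean, SD, n of durations and of
  offsets to the chosen anchor, plus the pooled fraction of cells whose
  detachment falls within 5 min of the anchor.

All called times live on the acquisition grid, so a called duration is
accurate to within one frame interval of the programmed truth; with event
phase uniform relative to the grid the quantization is unbiased on average.

## Group statistics (`group_stats`)

Dunn's multiple-comparison z against a reference group uses pooled
mid-ranks with the standard tie correction
T = Σ(t³−t)/(12(N−1)):
`z = (R̄_g − R̄_ref) / sqrt((N(N+1)/12 − T)(1/n_g + 1/n_ref))`, two-sided
normal p-values, Holm-adjusted by default (Bonferroni and
Benjamini–Hochberg selectable — the adjustment choice is deliberately
explicit because Dunn implementations differ silently on this point).
The Wilcoxon signed-rank test drops zero differences (Pratt handling
selectable) and uses the exact null for ≤ 25 retained pairs without ties,
switching to a continuity-corrected normal approximation above; the
rank-sum test is exact for samples of ≤ 10 without cross-sample ties.
Both delegate to scipy.stats behind this policy layer. Calibration is
checked empirically: all three tests reject at 3.5–6.5% at α = 0.05 over
2,000 null simulations.

## Phosphoproteomics post-processing (`phospho_pipeline`)

The chain starts from a precursor × sample intensity matrix (conditions
kinase-active "Cdc5" vs. kinase-dead "Cdc5KD", biological triplicates,
hourly timepoints) and runs:

1. **log2 + mean-centering** — each sample's mean over present values is
   shifted to the grand mean of sample means. Centering to zero would
   differ only by a constant; the grand mean keeps values on the intensity
   scale. *Caveat*: centering assumes differential effects are sparse or
   sign-balanced. If a noticeable fraction of features moves in one
   direction, centering transfers a fraction of that shift onto every null
   feature; the operation-level recovery tests therefore run on uncentered
   log2 data, and the caveat applies equally to real experiments.
2. **2-of-3 replicate filter** — a precursor is kept iff some condition ×
   timepoint triplicate has ≥ 2 present values (per-condition pooling of
   timepoints available behind a flag, since "at least one condition" is
   ambiguous on this point). Dropped rows are logged with the reason.
3. **Two-branch imputation** — per missing value: if its triplicate has
   ≥ 1 observation, draw from Normal(triplicate mean, σ); if the
   triplicate is fully missing, draw from Normal(precursor minimum −
   log2 3, σ), i.e. centered threefold lower on the linear scale
   (left-censoring emulation). σ is the mean within-triplicate SD of
   present values across the whole table. Present values are never
   overwritten; imputed values are not truncated (negative log2 values are
   allowed); a fixed seed makes the table reproducible. Imputation runs
   strictly after filtering and cannot resurrect dropped rows.
   *Caveat*: branch B manufactures condition differences when one
   condition's triplicates are fully missing and the other's are not —
   under intensity-dependent missingness this inflates discoveries near
   the detection limit, which is inherent to the scheme, not a bug.
4. **Protein aggregation** — linear-scale sum of precursor intensities per
   protein, re-logged (for non-enriched data).
5. **Site merging** — monophosphorylated precursors are median-merged per
   (protein, residue position); multiphosphorylated precursors are split
   into constituent sites and retained only for sites absent from the
   monophosphorylated set, with provenance recorded. Duplicate precursors
   resolve high-confidence localization over low, then first-seen.
   Conflicting residue letters at one position are an error.
6. **Differential scoring** — per site, matched differences (active −
   control at the same replicate × timepoint) over the post-induction
   window (default 2–5 h); log2FC is their mean. The paired design is the
   default because the triplicates were collected in parallel for both
   strains; an unpaired variant sits behind a flag. Site variances are
   shrunk toward an empirical-Bayes prior fitted by method of moments on
   log variances (digamma/trigamma moment matching, with a Newton
   trigamma inverse); the moderated t gains the prior degrees of freedom.
   Prior df of 0 reduces exactly to the ordinary paired t; infinite prior
   df forces a common variance and a normal reference. P-values are
   two-sided, BH-adjusted; "candidate" marks adjusted p ≤ 0.01 (the
   volcano plot's dark-dot class) and a 0.05 screen is reported alongside.

## Synthetic data

### Imaging (`synthetic_imaging`)

Nuclei are rendered as anti-aliased annular shells (concentration c_ne)
plus filled interiors (c_np) over a constant background, with Gaussian
and/or Poisson noise; the marker channel is a histone disk that elongates
into an ellipse and then splits into two lobes on a programmed schedule,
or a pair of Gaussian SPB puncta with programmed separation. Anti-aliased
(area-weighted) edges keep sub-pixel placement from aliasing the intensity
truth. Ground truth DI is c_np/c_ne by construction. Partition schedules
move fluorophore between shell and interior conserving the total; the
pixel-exact compartment areas are available so conservation holds to
floating-point precision on rendered frames. The default pixel scale
(0.107 µm/px) is an arbitrary but realistic wide-field value and is
configurable.

Cohort generators for timing studies draw per-cell event parameters from
the study conditions: detachment durations Normal(10.3, 2.9) min truncated
at 0 (durations are nonnegative), SPB-to-detachment offsets
Normal(24.2, 5.4) min, onsets continuous-uniform so events land off the
5-min acquisition grid as in real movies. DI traces step between a
baseline (0.2) and a detached level (1.0) with small Gaussian measurement
noise (SD 0.02); SPB movies place two puncta 3.5 px apart at separation,
drifting apart at 0.3 px/min.

What the simulator does **not** model: optics-accurate PSFs, 3-D
deconvolution artifacts, photobleaching, autofluorescence gradients, cell
movement, or gradual (non-step) relocalization kinetics. Passing tests
show the estimators recover programmed truth under idealized image
formation — they bound algorithmic error, not acquisition error.

### Phosphoproteomics (`phospho_synthetic`)

Log-normal precursor baselines (log2 mean 14, SD 2), per-precursor
offsets, replicate noise (SD 0.5 log2 units), planted one-sided effects
switching on at the induction timepoint, missingness as a
completely-at-random rate plus an optional logistic term in true intensity
(lower → more missing, emulating DIA detection limits). The truth table
lists every planted site. Not modeled: retention-time drift,
fragment-level interference, identification-level FDR, correlated
missingness across precursors of one peptide.

## Problem sizes used in validation

Timing recovery runs 200-cell cohorts (the scale of one real replicate of
~60–90 cells, doubled for stability); statistical calibration uses 2,000
null simulations per test; BH null behavior uses 200 repeats of 200-site
tables; power uses 500–1,000 sites with 25–50 planted effects. These sizes
put Monte-Carlo standard errors well inside the asserted tolerances while
keeping the full suite a few minutes on one CPU.

## Known limitations

* No cell tracking: cell identity comes from crop boxes or simulator truth.
* No 3-D DI; the measurement is deliberately single-slice.
* Absolute mask-method DI is geometry-biased (see above); use normalized
  values and the reported circularity covariate.
* The moderated-t prior fit assumes site variances are exchangeable; with
  very few sites (< ~20) the method-of-moments fit is noisy and prior df
  may swing widely.
* The imputation scheme's branch B is a point of known FDR risk under
  heavy left-censoring; interpret discoveries near the detection limit
  accordingly.
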