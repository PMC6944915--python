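# Methods

This note documents the models, estimators and numerical choices behind
`recoverkit`, what the synthetic data do and do not emulate, and the design
decisions taken where more than one reasonable convention exists.

## Screen statistics

**Model.** Each well of the screen yields a mitotic fraction (pHH3- or
MPM2-positive cells / total). For hit ranking, a well's readout *x* is
standardized as *z = (x − m)/s*, where *m* and *s* are the mean and sample
standard deviation (divisor *n − 1*) of a reference population. The
reference is, by default, the **non-control wells of the same plate within
the same replicate**: plate effects dominate 96-well screens, and control
wells (which carry deliberate phenotypes such as PPM1D knockdown) would
contaminate the null. Both choices are switchable (`scope="per_screen"`,
`include_controls=True`). Per-gene scores are the unweighted mean of the
per-replicate z (`aggregate="median"` optional).

**Hit calling.** Asymmetric inclusive cutoffs: *z̄ ≥ 2* calls increased
recovery, *z̄ ≤ −1* decreased. The boundary counts as a hit ("a cutoff of
2" is read as a threshold attained). The looser down-cutoff deliberately
trades specificity for sensitivity on the side of the biology of interest;
the screen design compensates with a deconvolution round. Because a
one-sided |z̄| ≥ 1 region admits ≈ 4% of null genes with three replicates,
a false-discovery bound is only meaningful at the stricter symmetric cutoff
(2, 2); the parameter-recovery test evaluates sensitivity and FDP there,
and evaluates sensitivity and direction accuracy at the screening cutoffs
(2, 1).

**Deconvolution.** For single-oligo rescreens, an oligo is *altered* in one
experiment when its readout deviates from the mean of that experiment's
negative-control (luciferase) wells by more than 0.5 × the controls' sample
SD — the "0.5 SD" is interpreted as the control-well SD of that experiment,
the only SD available per experiment; the multiplier is configurable. An
oligo validates when altered in ≥ 2 experiments; a gene validates with ≥ 2
of 4 validated oligos.

**Ratios.** RME = (mitotic cells after IR)/(mitotic cells untreated),
survival = irradiated/untreated optical density, repair efficiency =
marker-positive/transfected cells; each is divided by the corresponding
negative-control ratio, so the control is exactly 1. Empty denominators are
errors, not NaNs. Group comparisons use the classical equal-variance
two-tailed t-test with *n₁ + n₂ − 2* df; zero pooled variance is an error.

No multiple-testing correction is applied at the screening stage (the
deconvolution round serves that role); Benjamini–Hochberg-adjusted Gaussian
tail probabilities can be emitted as a clearly-labeled optional column.

## IRIF detection

**Pipeline.** DAPI and the focus channel are maximum-intensity projected
(identity for single-plane images). Nuclei: median filter (disk radius 2 px
default) → Otsu threshold (absolute threshold available for
reproducibility) → watershed on the negated Euclidean distance transform,
seeded at distance-transform maxima with a minimum seed separation of
~half a nucleus radius (10 px default) → removal of objects under
`min_nucleus_area` (200 px) → border-touching nuclei dropped (a QC stand-in
for manual curation of segmentation mistakes). Labels are renumbered 1..K
in raster order, so numbering is deterministic.

**Detection rule.** The focus channel is band-passed with a
Difference-of-Gaussians filter, σ = (1, 3) px by default, suited to foci of
~3–6 px diameter; DoG output keeps its negative values (clamping would bias
background statistics). Per nucleus, the background signal is the median of
its DoG pixels, and its spread is estimated robustly as 1.4826 × MAD so
that true foci (bright outliers) do not inflate it; a plain-SD variant is
available. The image-wide reference SD is the **median over nuclei** of
these per-nucleus SDs, matching a rule stated in terms of "the median
background standard deviation of all nuclei in the image"; a per-nucleus-SD
variant exists as config. A pixel belongs to a focus when its DoG value
exceeds (nucleus median + k·reference SD) **and** a user-set absolute
minimum; k defaults to 3 (typical range 2–4, tuned per experiment in
practice). Foci are 8-connected components (4-connected optional) of
passing pixels within one nucleus with area ≥ 3 px — "larger than two
pixels" read strictly; an inclusive ≥ 2 variant is a flag. Nuclei under 10
px are excluded from background estimation with a warning. Centroids are
intensity-weighted on the clamped-positive DoG signal, 0-based (row, col).

**Invariances.** Counts are invariant to label renumbering and to constant
per-region intensity offsets (annihilated by the band-pass away from step
edges), and monotone non-increasing in k, the absolute floor, and the
minimum area. The detector is tested for exact equality against a
brute-force oracle (explicit per-pixel rule + naive flood fill).

## Junction classification

**Anchoring.** A read is anchored by its longest exact prefix match and
longest exact suffix match to the reference. Exact matching is appropriate
for Sanger reads of single clones; a mismatch-tolerant mode is not enabled
by default. Both maximal anchors must reach `min_anchor` (10 nt default) or
the read is reported as *unclassified* — an explicit bin rather than a
forced call. The right anchor is then trimmed until the anchors overlap
neither on the read nor on the reference, preferring the longer left
anchor; the reference gap between anchors is the deletion and the unmatched
read middle the insertion. Categories follow directly: direct (no gap, no
insert), deletion, insertion, delins.

**Microhomology.** For a deletion [a, b), the microhomology length is the
number of alternative equal-size deletion placements producing the
identical repaired sequence, minus one, capped at the deletion size. It is
computed by walking outward from the junction (left plus right maximal
extensions) and verified in tests against brute-force enumeration of all
same-size deletions. Deletion placement is canonicalized to the leftmost
equivalent interval; the microhomology length itself is placement-invariant.
Microhomology is scored for simple deletions only; deletion-size spectra
cover deletions and delins (both configurable). Default bins — sizes 1,
2–5, 6–20, 21–100, > 100 nt; microhomology 0, 1–2, 3–5, ≥ 6 nt — are
placeholders chosen to span typical end-joining spectra and are fully
configurable, as the original bin edges are not published.

## Synthetic data

Each generator draws from its own `numpy` Generator seeded by
`SeedSequence([artifact_key, seed])`, so artifacts are independent and
byte-reproducible.

**Screens.** 529 genes × 4 oligos, 96-well plates with one luciferase
(negative) and two positive-control wells (PPM1D, βTrCP, planted at −4 SD)
per plate, 3 replicates; pooled (one SMARTpool well per gene) or per-oligo
layout. The null readout is Gaussian on the mitotic fraction, mean 0.25,
SD 0.04, truncated to [0, 1] — stated modelling assumptions, as no
distributional parameters are published. Planted hits shift their wells by
`effect_size_sd` × null SD. The canonical hit structure (28 decreased, 13
increased) spreads hit genes evenly through the library with interleaved
directions, since a library is not ordered by phenotype; clustering
same-direction hits on one plate would bias that plate's reference mean.
The default planted effect is 5 null-SDs — a strong knockdown (e.g.
near-complete loss of recovery, a 0.20 shift on the default scale). This
default also reflects an operating-characteristic constraint of Z-score
screens: with 41/529 true hits the screen SD self-inflates by
√(1 + 0.078·e²), so a hit planted at *e* null-SDs measures only
e/√(1 + 0.078·e²) ≈ 2.9 at e = 5 (saturating at 3.6 as e → ∞); weaker
planted effects sit too close to the cutoff for a sensitivity ≥ 0.95 claim
to be stable. What passing recovery tests shows is therefore recovery of
*strong* effects under Gaussian plate noise — not power against subtle
hits, plate-position artifacts, or non-Gaussian well failures, none of
which are simulated.

**Images.** Nuclei are filled ellipses (semiaxes 18–28 × 14–22 px at the
default ~0.3 µm/px scale), non-overlapping, border-clear; DAPI foreground
150 over background 20. Foci are isotropic 2D Gaussians (σ 1.5 px) at
recorded coordinates, ≥ 7 px apart, inside an eroded nucleus so the whole
spot fits; amplitude is expressed in units of the noise SD (default 8×) so
SNR-based claims are well defined. Noise is additive Gaussian (SD 10) by
default, Poisson optional; z-stacks place each focus in one plane to
exercise the projection. Not emulated: realistic PSFs, illumination
gradients, nucleoli and chromatin texture, overlapping foci, or
out-of-focus light — detection metrics on these scenes are upper bounds on
real-image performance.

**Junctions.** A synthetic ~240 nt reference amplicon (labelled synthetic;
the real reporter sequence is not published) carries a few short direct
repeats around the cut so non-zero microhomology deletions are realizable.
Reads apply one event at the cut: deletions sample (size, target-MH) pairs
and search placements realizing the target exactly (resampling up to a
retry cap, then erroring); insertion ends are constrained to mismatch the
junction-adjacent reference bases so anchors terminate exactly at the
planted junction and round-trips are exact. Per-base substitution errors
are off by default (clone Sanger reads), available as a rate.

## Problem sizes and runtime

The shipped tests and the acceptance script use desk-scale problem sizes
chosen to estimate each metric stably: full-size screens (529 genes, 3
replicates; 20 screens for the FDP property), 10 images × 5 nuclei
(50 nuclei, ~500 foci) for detection metrics, 1,000 junction reads, and
1,000 random references for the microhomology oracle. The whole suite runs
in well under a minute on one CPU.

## Known limitations

- The deconvolution direction summary uses the mean control-SD displacement
  across oligos and experiments; discordant oligo directions within one
  gene are not flagged.
- Watershed seeding assumes roughly convex nuclei of similar scale; heavily
  clumped or irregular nuclei will over- or under-split.
- The junction caller reports the parsimonious interpretation of each read;
  an insertion that happens to match reference flank sequence is absorbed
  into the anchors (e.g. a templated insert adjoining the junction can be
  re-read as a smaller deletion). This mirrors the ambiguity inherent to
  junction sequences, not an implementation defect.
- The one-sided screening cutoff at 1 SD is intentionally permissive; its
  false-positive load is documented rather than corrected, deferring to
  deconvolution.
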