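# Methods

## Scope and model

`htpi` implements the informatics of a high-throughput proteoform-imaging
workflow: MALDI mass-spectrometry-imaging (MSI) spectra of a tissue
section, acquired pixel by pixel over m/z 2500–20000 on a linear TOF, are
annotated at the intact-mass level against *region-specific* top-down
proteoform identification tables, and proteoform abundances are compared
between groups (wild-type vs 5×FAD Alzheimer's-model mice in the motivating
application) by label-free statistics.

The units of analysis are proteoforms: a gene product restricted to an
inclusive residue range with a multiset of whole-molecule PTMs
(acetylation, methylation, phosphorylation, oxidation in the built-in
registry), written `Gene(start–end)@Mod...`, e.g. `Pcp4(2–62)@Ac@Phospho`.

### Mass calculus

Monoisotopic and average masses are computed by residue-table summation
(residue tables derived from pyteomics element data) plus water plus
modification deltas. Linear-TOF peaks of 3–20 kDa proteins are unresolved
isotope envelopes centred on the *average* mass, while top-down
identifications carry *monoisotopic* neutral masses. At 10 kDa the
mono/average gap is ~6 Da ≈ 0.06%, larger than the ±0.05% annotation
tolerance, so annotation converts every database record to a theoretical
average [M+H]+ (sequence-exact when the sequence is known; otherwise via
the Senko averagine ratio 111.1254/111.0543 ≈ 1.00064) and matches in that
space. Whether the tolerance is applied to neutral mass or [M+H]+ is
indistinguishable at 0.05%; observed [M+H]+ m/z is used throughout, and
neutral masses appear only inside the annotation module.

### Peak selection

Per ROI, the mean TIC-normalized spectrum is smoothed with a 3-bin moving
average, local maxima (plateau-aware) above a relative-abundance threshold
are kept, maxima closer than the local expected FWHM (m/800) merge keeping
the taller, and each apex is refined by an intensity-weighted centroid over
the contiguous region above half-maximum, weighting by height *above* the
half-max level (this suppresses the discretisation bias of a plain centroid
when σ is comparable to the 1 Da bin width; worst-case error ≈ 0.07 bins).
"1% relative abundance" is interpreted against the base peak of the ROI
mean spectrum, the standard meaning of relative abundance; a summed-TIC
fraction reading is available via `mode="tic"`.

### Region-specific annotation

Each ROI's peaks are matched only against that ROI's own identification
table (sorted mass index, relative range query). This is the core design
point: region-specific databases keep tissue heterogeneity from producing
cross-region false matches, and a proteoform identified only in region A
can never annotate a region-B peak even at identical m/z. All candidates
within tolerance are kept, ranked by |relative error| (ties < 1e-6 break by
fewer modifications, then name); rank 1 feeds quantitation. An independent
brute-force all-pairs matcher exists in the test suite and must agree
exactly with the indexed path.

### Segmentation

ROIs can come from a supplied label mask or from marker-ion segmentation:
each marker image is scaled to its own maximum and a pixel joins the argmax
region when the winning scaled value reaches `min_fraction` (default 0.2,
chosen so clear marker expression wins while background stays unassigned).
This replaces interactive manual ROI drawing with a deterministic rule; no
claim is made that the automated boundaries equal any hand-drawn ones.

### Differential quantitation

Replicate-level intensity of a proteoform in an ROI is the ROI-pixel mean
of the trapezoidal ion-image integral over ±tolerance around the
theoretical m/z, divided by the ROI's summed TIC and rescaled by a fixed
constant (1e4) for readability. A proteoform is significant when fold
change (AD/WT means) ≥ 1.2 or ≤ 1/1.2 **and** the unpaired two-tailed
t-test gives p < 0.05, with no multiple-testing correction by default;
Benjamini–Hochberg is available (`adjust="bh"`) and recommended for wide
panels. When the WT mean is zero (AD-only species such as amyloid-β) a
pseudo-intensity of 1% of the table's smallest nonzero group mean stands in
for the denominator.

The default t-test is Student's pooled-variance form. At n = 3 per group,
Welch–Satterthwaite degrees of freedom are strongly conservative (empirical
size ≈ 0.034 at nominal 0.05 in a 400k-draw calibration under the
generator's lognormal noise), which would distort the pipeline's type-I
behaviour; Student's form is exact under the near-normal noise at this CV
(empirical size ≈ 0.049). Welch remains available (`test="welch"`) for
heteroscedastic designs with more replicates.

## The synthetic phantom

The generator produces ground-truthed imzML phantoms at desk scale:
120×160 px whole sagittal section (CTX cap, TH, ST, and hippocampal
subregions DG/CA1/CA2/CA3/SUB as ellipse cartoons) or 60×80 px
hippocampus-only. These stand in for 100 µm and 50 µm rasters at a size
that keeps a full run in seconds while preserving region geometry.

Each proteoform contributes one Gaussian envelope at its average [M+H]+
with FWHM/m = 1/800 (linear-TOF-like; no isotope structure, since these
envelopes are unresolved anyway) on a uniform 1 Da axis over m/z
2500–20000. Pixel spectra are: region base intensity × section-wide
replicate factor × per-(pixel, proteoform) lognormal factor
(`pixel_cv` = 0.10) + constant baseline (0.05), all times a per-pixel
lognormal TIC factor (`tic_cv` = 0.15). All lognormal factors are
unit-mean. Everything is deterministic given (seed, group, replicate
seed).

`replicate_cv` (default 0.10) is the **between-acquisition section factor**
— the global intensity variation (matrix deposition, laser performance)
that ROI-TIC normalization is designed to cancel. Proteoform-level
*biological* replicate variability is deliberately not imaged: it is
exercised at the statistics level through `sample_replicate_intensities`,
which draws replicate intensities from the same lognormal kernel. This is
the phantom's most important limitation: passing recovery tests shows the
pipeline recovers planted spatial/differential structure under acquisition
noise, not that n = 3 animal studies are immune to biological variance.

The default panel plants, with WT/AD mean amplitudes per region:

- the three segmentation markers (`Sncb(1–64)@Ac` hippocampus-dominant,
  `Tmsb4x(2–44)@Ac` striatum-dominant, `Pcp4(2–50)@Ac` thalamus-dominant);
- six Pcp4 proteoforms with distinct ST/TH/CTX patterns, four of them with
  AD effects (down in HP and TH, truncated forms up in TH);
- amyloid-β 1–38/1–40/1–42 (real Aβ42 sequence, gene spelled `Abeta`),
  present **only** in the AD group and only in SUB (plus CTX/TH in the
  whole-brain layout);
- the ubiquitin set `Ubb(1–76/1–74/1–72)` (real 76-residue sequence; the
  1–74 and 1–72 fragments are the insulin-degrading-enzyme cleavage
  products), with 1–76 up in CTX/bulk-HP but down in SUB, the fragments up
  in SUB and 1–72 SUB-exclusive;
- enough further SUB-differential proteoforms to total exactly 6 down- and
  8 up-regulated (proteoform, SUB) pairs, all true folds ≥ 1.5 (actual
  values 1.8–2.5, or AD-only, mirroring clearly separated volcano hits);
- an Mbp proteoform reduced in bulk hippocampus and cortex/thalamus;
- 50 null decoys spread over the m/z range (~300 Da grid, ≥ 70 Da from any
  named species), present in every region with no group effect.

All gene sequences other than Ubb and Abeta are deterministic synthetic
stand-ins generated to hit planned target masses so that every panel peak
is resolvable (minimum spacing > 40 Da enforced) — they are not estimates
of real sequences, and the planted amplitudes are free parameters, not
estimates of tissue abundance. Planted up/down amplitude deltas are
approximately TIC-balanced per region (Σ up amplitude×σ ≈ Σ down), the
same "most of the signal is unchanged" assumption TIC normalization itself
makes; without it the normalization imposes a small spurious global fold on
every null species.

## Numerical and I/O choices

- imzML: continuous mode written/read losslessly (shared axis, 32-bit
  intensities); processed-mode files are resampled by linear interpolation
  onto the first pixel's axis and flagged as lossy. Masks travel as
  plain-text integer grids with a legend sidecar.
- TIC values are trapezoidal integrals over the m/z axis; TIC
  normalization scales each pixel to the dataset's mean raw TIC, excluding
  (and flagging) zero-TIC pixels.
- Ion-image windows are relative (± the annotation tolerance by default);
  at these peak widths the window captures a fixed ~2/3 of the envelope
  area, which cancels in all ratios.
- Ties in marker segmentation break by marker order; annotation ties by
  modification count, then name; all sorts are stable, so repeated runs
  are byte-identical (verified by test).
- Degenerate inputs: flat spectra yield empty peak lists; empty ROIs,
  all-zero datasets, windows outside the axis, and grid mismatches raise
  typed errors naming the offender; zero-variance equal-mean group
  comparisons report p = 1.

## Problem sizes used

The packaged study conditions are n = 3 sections per group, 60×80 px
hippocampus phantoms (4 800 pixels × 17 500 m/z bins) for the differential
analysis and one 120×160 px whole-brain section for annotation and
segmentation checks; the type-I calibration uses 500 Monte-Carlo repeats
of 200 null proteoforms at the statistics level. A full
simulate→quantify run completes in well under a minute on one CPU.

## Known limitations

- No proteoform-level biological replicate variance in the imaged phantom
  (see above); no spatial autocorrelation of noise, mass-axis drift,
  matrix/ionisation physics, or section-to-section deformation.
- Annotation handles [M+H]+ only — no other adducts, no multiply charged
  species, no MS/MS confirmation; modification *sites* are not modelled.
- The headline identification counts of a real tissue study (hundreds of
  proteoforms per region) depend on real acquisitions and are out of reach
  of any phantom; recovery here is of planted truth, at miniature scale.
- Uncorrected significance at n = 3 with ~60 tested species is faithful to
  common practice but anti-conservative; the BH option exists for a
  reason.
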