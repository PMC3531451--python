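# Methods

## The analysis model

The pipeline targets pooled-gel 2-DE comparisons: one silver-stained
gel per group (case and control), no replicates, so no
significance testing — the effect statistic is the fold change of
normalized spot intensity. The chain is

1. background correction and spot segmentation on the digitized gel;
2. integrated optical density (IOD) per spot;
3. per-gel normalization to parts per million of total spot
   intensity, `ppm_i = IOD_i / Σ_j IOD_j × 10⁶`, which removes any
   global multiplicative staining/exposure factor exactly;
4. cross-gel spot correspondence, then classification: a spot is
   differential when its case/control ppm ratio is ≥ 2 or ≤ 0.5.

Because ppm is compositional, a ratio on ppm equals the ratio of
abundance *shares*, not of absolute abundances. With equal protein
load per gel (the standard 2-DE practice this pipeline assumes) the
two coincide up to the load normalization.

### Edge policies

* The two-fold boundary is inclusive: ratio exactly 2.0 or 0.5
  passes ("at least two-fold").
* A spot detected on one gel only is a presence/absence event:
  control 0 with positive case gives ratio +∞, direction up,
  passing; the converse gives ratio 0, down, passing; both are
  flagged `presence_absence` rather than silently mixed with finite
  ratios. Spots absent on both sides never pass.
* Ratio exactly 1 is "unchanged" (forced by the up/down/unchanged
  trichotomy).
* Overlap between two comparisons is keyed on spot id, not protein
  accession, because distinct isoform spots of one protein can move
  in different directions.

## Spot quantification

* **Background**: greyscale morphological opening with a square
  window of side `2·radius + 1` (default radius 25 px, an order of
  magnitude above the spot SD), Gaussian-smoothed (σ = radius/4).
  The opening rides the lower noise envelope, so the residual median
  is subtracted as well; the residual MAD (×1.4826) is recorded as
  the noise estimate. Output is floored at zero.
* **Detection**: local maxima ≥ `min_separation` (8 px) apart and
  above `threshold_k` (5) × noise SD seed a watershed on the
  inverted image, masked to pixels above `mask_k` (2) × noise SD.
  Masks are disjoint by construction. Two maxima closer than the
  separation merge into the higher one. Regions under `min_area`
  (5 px) are discarded: a physical spot (SD ≈ 2 px) spans tens of
  pixels, a lone noise spike does not.
* **Integration**: IOD is the sum of corrected intensities over the
  mask; the intensity-weighted centroid is mapped to (pI, MW) through
  the axis calibration. On noiseless scenes the recovered total IOD
  is within 2% of the true rendered volume (mask truncation at the
  2σ-noise contour accounts for the loss, amplitude-dependent but
  small).

Detector parameters live in function signatures with the defaults
above; every run records them in report provenance.

## Synthetic scenes

The generator emulates the statistical structure the analysis
assumes, not gel physics (no electrophoretic migration, staining
kinetics, or membrane transport modelling):

* ~300 spots per gel (default), pI uniform on the linear pH 3–10
  axis, MW log-uniform on 10–100 kDa truncated at the 100 kDa
  membrane cutoff; spot centres rejection-sampled to a 16 px minimum
  separation (the published gels' ~300 spots on a 180×245 mm gel are
  mostly resolved; co-migration stress tests can lower this).
* baseline volumes log-normal (σ_log = 0.8) clipped to [200, 15000]
  intensity units — spot volumes in real silver-stained gels span
  orders of magnitude.
* a designated 20% of spots are differential with |log2 ratio|
  uniform on [1, 3]; the rest draw a truncated-normal log2 ratio
  (SD 0.15, |·| ≤ 0.5), safely inside the two-fold band.
* **equal protein load**: case volumes are rescaled to the control
  total, mirroring equal-load gels; the recorded true ratio is the
  post-rescaling (compositional) ratio, which is exactly what ppm
  measures. A fixed-point iteration keeps designated spots at ≥
  two-fold after rescaling.
* rendering: each spot is an isotropic Gaussian (SD 2 px) whose
  discrete integral equals volume × per-gel scale factor (defaults
  1.0 / 1.3, emulating staining differences); constant background
  (60) plus Gaussian noise (SD 0.8, i.e. the weakest spot's peak
  amplitude is 10× noise — the benchmark's SNR); optional Poisson
  noise; values clipped to the 12-bit detector range with the
  clipped fraction reported (zero on default scenes).

Everything is driven by one integer seed; identical configs and
seeds give bit-identical truth tables and images.

What passing synthetic tests does **not** show: robustness to spot
overlap/streaking, spatially varying background, saturation, or
warping between gels — real-gel phenomena outside the generator.
Per-spot noise levels on real silver stains are uncharacterized here;
the defaults above are repository conventions reported with every
simulated result.

## Sequence physicochemistry

* Masses come from a packaged residue-mass table (monoisotopic and
  average), shared by implementation and test oracles. Peptide mass =
  Σ residue masses + water (+ modification deltas:
  carbamidomethyl-C +57.02146 Da mono fixed, oxidation-M +15.9949 Da
  variable, ≤1 per peptide by default to bound the expansion).
* Protein MW is the average mass of the full canonical chain with
  the initiator Met retained (matching how sequence databases report
  it), displayed in kDa to 1 decimal.
* pI: bisection on [0, 14] (tolerance 0.01 pH) of the
  Henderson–Hasselbalch net charge; the charge is continuous,
  strictly decreasing, positive at pH 0 and negative at pH 14, so
  the root exists and is unique. The pKa set is explicit
  configuration (EMBOSS default, Bjellqvist selectable): no single
  set reproduces database pI values for all proteins, so the choice
  is reported rather than hidden.
* Trypsin: cleave after K or R except before P; the chain's final
  residue is never a site. For `n` internal sites the number of
  peptides with exactly `m` missed cleavages is `max(0, n + 1 − m)`,
  checked against brute force in the tests.

## Fingerprint search

Peaks are matched to theoretical digest masses within 50 ppm
(monoisotopic, the MALDI reflectron convention). Each observed peak
consumes at most one theoretical peptide per protein — closest wins,
exact ties to the lower mass — preventing double counting. The
ranking score is MOWSE-style: Σ over matched peptides of
−log10(frequency of theoretical peptides in that peptide's 100 Da
mass bin across the whole search collection). It is
repository-defined, deterministic, used for ranking only, and never
compared to probabilistic search-engine scores. Ties in score break
by matched count, then accession.

The tandem-MS acceptance rule is a pure filter over externally
supplied per-peptide (score, expectation) pairs: identified ⇔ at
least 3 peptides with score > 25 and expectation < 1 (both strict).
Catalog rows that fail the rule (e.g. single-peptide
identifications) are flagged non-conforming but never removed — the
catalog is reported as published.

Sequences for the catalog's accessions were never deposited; apart
from the real canonical myoglobin entry (P02144, the one record
asserted against a database mass), the identification layer is
exercised on seeded synthetic sequences and residue-shuffled decoys
(composition-preserving null), all labelled synthetic.

## Problem sizes and numerical choices

Tests and the acceptance script run the default 300-spot scene
(768×1024 px, ~7 s per end-to-end evaluation), 1000 random chains for
digestion identities, and the full catalog (59 unique accessions)
against 50 decoys for self-identification — sizes chosen so the whole
suite completes in well under a minute of simulation time while the
empirical rates (recall, false-pass, ratio error) are stable across
seeds. Floating-point policies: ppm closure is asserted at 1e-6
relative; scale invariance at 1e-9 relative; published fixture ppm
values are taken as given (they are printed subsets of full gels, so
closure is only enforced on freshly normalized tables).

## Known limitations

* Spot correspondence across gels is coordinate-based (mutual nearest
  neighbour in pI × log10 MW within an elliptical tolerance); there
  is no image warping/registration, so strong positional distortion
  between gels would break matching before it breaks classification.
* The commercial imaging system used for the published tables is not
  reproduced numerically — only its contract (background-corrected
  IOD, ppm normalization) is.
* The generator places spots independently; co-migrating isoform
  trains (several spots of one protein at shifted pI, ~half the
  published catalog) are not modelled, and no PTM chemistry is.
* Pooled single gels mean the fold-change filter has no error model;
  the synthetic benchmark quantifies pipeline-induced error only.
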