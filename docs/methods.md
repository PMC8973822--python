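# Methods

This note documents the models, defaults and numerical conventions behind
`celloc`, and what the synthetic benchmark does and does not demonstrate.

## Synthetic scene model

Each field of view contains `n_cells` (default 4) non-overlapping ellipses
placed by rejection sampling on a 512×512 grid, with major semi-axis drawn
uniformly from 30–45 px, axis ratio 1–1.25 (bounded eccentricity), and an
enforced 8 px gap plus full containment in the image, so scenes are
"well separated" by construction. Touching or overlapping cells are
deliberately not rendered; curated-mask overrides
(`segment.apply_mask_override`) are the supported route for such data.

Per cell, two unit-amplitude templates are rendered:

- **Membrane template** — a ring of width 5 px at the cell boundary
  (difference of concentric ellipses) at intensity 1.0, plus a uniform
  interior pedestal of 0.25. The pedestal models internalized marker /
  cytosolic background and gives the cell a contiguous above-background
  footprint, which is what makes whole-cell segmentation on the protein
  channel well posed even for strongly membrane-dominant cells.
- **ER template** — band-pass-filtered (difference-of-Gaussians, scale
  3 px) white noise, min–max normalized per cell and mapped to
  0.35 + 0.65·texture over the interior (zero on the ring). This
  reproduces a reticular intracellular pattern without modeling organelle
  geometry.

The protein channel of a cell with membrane fraction `alpha` is
`amplitude · (alpha · membrane + (1 − alpha) · ER)`; the comarker channel
renders the pure template for the requested role (PM or ER); the nuclei
channel is one Gaussian blob per cell (visualization only — segmentation
never uses it). A constant background (default 20) is added, the field is
blurred with a Gaussian PSF (σ = 1.5 px), and detector noise applied:
Poisson with gain 1.0 followed by additive Gaussian (σ = 5), clipped at 0.
Amplitudes default to 300, giving a realistic confocal-like dynamic range
once exported as 16-bit at the fixed scale 100 (one global scale for all
images, mirroring constant acquisition settings).

Per-cell `alpha` is jittered (σ = 0.03, clipped to [0, 1]) to emulate
expression-level variability between transfected cells; set
`alpha_jitter_sd=0` for the exact-linearity limit in which per-cell r
equals 1 when `alpha ∈ {0, 1}`, noise is off and the PSF is disabled.

Default genotype map: wild type and the four likely-benign/protective
variants at `alpha = 0.8` (membrane-dominant but with visible intracellular
signal), the ten predicted-damaging missense mutants at `alpha = 0.1`
(ER-retained). These are the study conditions for every downstream
calibration; they are not tuned per experiment.

Determinism: a scene is a pure function of its spec (seed included);
dataset seeds derive from `SeedSequence([base_seed, genotype, image])`, so
any scene can be regenerated in isolation.

## Segmentation

`extract_rois` = circular median filter (radius 4) → Huang threshold →
binarize (≥ t) → 8-connected components → size filter (default
min_area = 800 px², no upper bound) → relabel in raster order.

- The median neighborhood is a Euclidean disk; at image borders the
  neighborhood truncates to in-image pixels. The interior uses the scipy C
  kernel, a border band of width = radius is recomputed exactly.
- Huang's threshold minimizes fuzzy entropy on a 256-bin min–max-scaled
  histogram: for a candidate t, below/above-class means μ₀, μ₁ define
  memberships μ(g) = 1/(1 + |g − μ_class|/C) with C the gray range, and
  S(t) = Σ h(g)[−μ ln μ − (1 − μ) ln(1 − μ)] is minimized; ties break to
  the lowest t. Constant images raise (no threshold exists).
- min_area = 800 px² is roughly one-third of the smallest rendered cell
  (~2300 px²): debris and noise fragments drop, true cells never do.
  Border-touching cells are kept by default and flagged per cell.
- Known limitation: Huang assumes a bimodal histogram. On fields with no
  real foreground it thresholds inside the background mode and returns
  arbitrary large components; the particle-size filter is the only guard.

On default scenes the pipeline recovers the true cell count exactly and
per-cell Jaccard overlap with ground truth of ≥ 0.7 (typically 0.77–0.85;
the loss is PSF blur plus the dim outer rim falling below threshold).

## Colocalization

Per-cell r is the plain two-pass Pearson coefficient over exactly the
pixels of one ROI — no sub-thresholding inside the ROI, no background
subtraction by default (a constant-subtraction option exists but is off).
Cells in which either channel is constant are dropped and logged. The unit
of analysis is the cell, not the image mean: figures of this kind plot
per-cell distributions with a ≥ 30 cells/genotype floor, and per-cell
records retain more information (image-level aggregation can be done from
the measurement table if preferred).

The optional randomization test permutes `block`×`block` tiles (default 8,
reflect-padded to a multiple of the block) of the comarker crop within the
ROI bounding box and reports the add-one-smoothed fraction of replicates
with r* ≥ r. It is off by default; it is calibrated (uniform p under an
independent comarker) but conservative for very small ROIs.

## Group inference

Welch one-way ANOVA: weights wᵢ = nᵢ/sᵢ², F as the weighted between-group
mean square over 1 + 2(k−2)/(k²−1)·Λ with Λ = Σ(1−wᵢ/W)²/(nᵢ−1),
df₂ = (k²−1)/(3Λ). Games-Howell: per pair, SE = √(sᵢ²/nᵢ + sⱼ²/nⱼ),
Welch–Satterthwaite df, q = √2·|t| referred to the studentized-range
distribution **with the full group count k**, so the correction is
familywise over all plotted comparisons even when only the vs-WT subset is
reported. At k = 2 both procedures reduce exactly to the Welch t-test
(verified to 10 and 6 significant digits respectively). Inference is
two-sided throughout; groups need n ≥ 2 and positive variance, and a
min-cells gate (default 30) guards against underpowered genotypes.
Quartiles in the box summaries use linear interpolation between order
statistics (type-7), the numpy default.

## Cohort arithmetic

Rarity filter: keep variants outside segmental-duplication/repeat/
homopolymer regions whose every available population MAF is ≤ 1%
(inclusive); absence from all databases passes, since absence is itself
evidence of rarity. Classification is HGVS-string-driven only (no
transcript model): intronic offsets beyond ±2 are noncanonical splice,
canonical-site changes count as premature-termination class, del/dup/ins
are indels (frameshifts included), stop-gain substitutions are PTC,
amino-acid exchanges are missense.

Carrier frequencies are reported as 100·count/size rounded half-up to two
decimals alongside the exact fraction; per-class tallies count
variant-carriage occurrences (an individual with two missense variants
contributes two), the convention behind published screened-cohort
frequencies, while compound-carrier counts are per individual. The default
contingency test is the two-sided Fisher exact (minimum-likelihood rule,
summed hypergeometric tail), with ad/bc odds ratio, Woolf logit 95% CI and
a flagged Haldane–Anscombe 0.5 correction when a cell is zero. The bundled
Belgian roster is synthetic at the individual level: it is the minimal
assignment reconciling all published marginal tallies, and only those
margins are meaningful.

## What the synthetic benchmark shows — and what it does not

Passing tests demonstrate that the measurement chain (segmentation →
per-cell Pearson → Welch/Games-Howell) is numerically exact against
brute-force oracles, calibrated under the null (type-I error at nominal
level over 2000 replicates), and powerful enough to recover a large
engineered membrane-loss effect (alpha 0.8 vs 0.1, ≈ 40 cells/genotype,
all post-hoc comparisons < 0.001). They do not validate performance on
real micrographs: the generator renders no touching cells, no out-of-focus
light, no autofluorescence, no chromatic shift or crosstalk, no
photobleaching and no 3D structure, and its ER texture is a stationary
noise field rather than organelle geometry. Problem sizes in the shipped
tests (4 cells × 10 images × 11 genotypes) are the package defaults chosen
to keep the ≥ 30 cells/genotype floor with margin.

## Numerical conventions and degenerate inputs

- Pearson r is clipped to [−1, 1] against round-off; undefined r (constant
  channel) is an error at the single-ROI API and a logged drop in batch.
- Huang tie-break: lowest candidate threshold; binarization uses ≥.
- Empty segmentations are valid empty masks, not errors; constant images
  are errors.
- Placement failure (too many/large cells) raises after 200 rejection
  attempts per cell rather than degrading into overlap.
- All percentages round half-up (`decimal`), avoiding banker's rounding
  surprises in reported tables.
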