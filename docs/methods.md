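# Methods

This note documents the models, conventions and numerical choices behind
`plaqueband`, in the order of the measurement chain.

## Image model and segmentation

Sections are multi-channel intensity arrays (`channels × [z ×] y × x`)
with an isotropic in-plane pixel size in µm. All analysis happens on the
maximum-intensity projection of each channel. Preprocessing follows the
conventional fluorescence pipeline: background subtraction by a
rolling-ball-style operator, then Gaussian denoising.

*Rolling ball.* The background estimate is the grayscale **opening** of
the image with a flat disk — a documented approximation of the rolling
ball that is exact for flat structuring elements and shares its key
property: structures smaller than the disk survive subtraction
unchanged, and the result is invariant to a constant offset. The radius
is configurable (default 25 px); drivers scale it to the physical pixel
size (e.g. 8 px ≈ 12–20 µm at the simulated resolutions). Opening with
an exact disk is O(radius²) per pixel, which is why the simulated
experiments use moderate radii.

*Auto-thresholds.* Otsu, Li, Intermodes and Moments are implemented from
their canonical definitions over a 256-bin histogram ("8-bit
semantics"): integer images spanning ≤ 256 levels keep their native
levels (thresholds are then exact gray values); float images are binned
uniformly over the observed range and thresholds reported at bin
resolution. Conventions fixed once and used everywhere: foreground is
strictly `pixel > t`; the threshold is the representative value of the
last background bin; equal optima break to the smallest threshold
(Otsu). Degenerate (constant) images raise an error, as does an
intermodes histogram that never becomes bimodal within the iteration
cap. Tests verify Otsu against an exhaustive 256-candidate scan, Li as a
fixed point of the cross-entropy iteration, Moments by reconstructing
the first three moments from the solved two-level image (≤ 1e-6
relative), and cross-check Otsu against an independent library
implementation.

Default method per channel role mirrors the staining protocol: Otsu
(plaque dye), Intermodes (neurite marker), Moments (microglial and
lysosomal markers); Li is used on the microglia channel for the
skeleton path. Thresholds are computed per image; sharing a threshold
across a group is possible by applying one channel's `ThresholdResult`
to others.

## Plaque geometry

Plaques are 8-connected components of the plaque mask; components with
equivalent diameter 2·√(A/π) ≤ 9.9 µm are discarded. Pixel centers sit
at integer coordinates; areas are pixel counts × (pixel size)². The
proximity band of a plaque is the set of pixels whose Euclidean
distance-transform distance from the plaque pixel set is in (0, 30 µm] —
the open annulus, excluding the interior; interior quantities are always
reported separately, since "within X µm of the outline" is ambiguous
about the interior. Bands of neighboring plaques are computed
independently (a pixel may belong to two bands). Bands are evaluated on
a window just large enough to contain them, so cost does not scale with
section size. Border-clipped plaques are flagged and excluded from
per-plaque statistics by default.

Band quantification reports: marker-positive area inside the plaque and
in the band; mean intensity over **all** band pixels (not only
marker-positive ones); and the number of marker-mask connected
components touching the band. Microglial somata are marker-mask
components with area ≥ 20 µm² (the automated proxy for "clearly visible
soma"); a soma centroid on a plaque pixel counts as *within*, in the
band as *around*, and a soma in two bands goes to the plaque with the
nearer outline (ties to the lower plaque id).

## Skeleton morphometry

Masks are thinned with two-subiteration homotopic thinning run to
completion (maximally thin; component count preserved). Metrics follow
the conventions of the standard skeleton-analysis plugin: endpoints are
skeleton pixels with ≤ 1 neighbor in the 8-neighborhood (an isolated
pixel is one endpoint, zero length); junctions are 8-connected clusters
of pixels with ≥ 3 neighbors (adjacent junction pixels count once);
length sums each adjacent pixel pair once, 1 px orthogonal and √2 px
diagonal. Non-thin input is rejected by a rotation-invariant structural
test (a filled 2×3 block); 2×2 blocks ringing a 1-px hole are accepted
because homotopic thinning cannot remove them.

Thinning a soma disk with attached processes can leave short spur
endpoints *inside* the cell body; these are thinning artifacts, not
process tips, so per-cell process-endpoint counting
(`process_endpoint_count`) excludes endpoints within the soma radius
(+1 px) of the soma center. Single-cell selection — a visual step in
practice — is automated as: keep skeleton components with total length
in a configurable range that claim exactly one soma; components spanning
several somata are flagged "merged" and rejected. This proxy is
validated only on synthetic ground truth.

## Statistics

Two-way between-subject ANOVA uses Type II sums of squares (identical to
Type I/III when balanced), fitted via ordinary least squares; the
balanced-design decomposition SS_A + SS_B + SS_AB + SS_err = SS_total is
tested to 1e-9 relative, and F values are tested against an independent
from-scratch sums-of-squares computation. Mann-Whitney U uses mid-ranks;
p is exact (enumeration-verified) when n₁+n₂ ≤ 14 without ties, else the
tie-corrected normal approximation. Kruskal-Wallis applies the tie
correction and returns H = 0, p = 1 for all-identical data. Fisher's
exact test reports the sample odds ratio ad/bc (∞ with a zero cell) and
the conditional hypergeometric p; the two-sided p sums table
probabilities ≤ the observed one. Printed percentages round half-up
(matching conventions like 5/22 → 23 %); BMI is computed in decimal
arithmetic so half-way cases (80/1.60² = 31.25 → 31.3) round exactly.
No multiple-testing correction is applied by default; a
Benjamini-Hochberg helper exists for transcriptomic tables.

The response-concordance classifier takes per-gene Z statistics for two
contrasts and a cutoff (default 2.5): *concordant* — both exceed the
cutoff with the same sign; *discordant* — |z₁| > cutoff but |z₂| ≤
cutoff (a response lost under the second condition); *enhanced* — the
mirror case; *neither* — everything else, including opposite-sign
double-exceedances. The four classes partition the input exhaustively
and exclusively; the genome-wide Pearson correlation of (z₁, z₂) is
reported alongside.

The biopsy-cohort table ships as a packaged CSV. The published average
row of the obese non-T2D group does not recompute from its three
members (e.g. mean BMI 33.4 vs printed 32.6; mean height 164 vs 166);
that group is flagged (`INCONSISTENT_SUMMARY_GROUPS`) and excluded from
exact-reproduction checks — the table itself is shipped as printed, not
"corrected". Similarly, the recorded proportion "20/24 (69 %)" is
arithmetically 83 %; the package always computes exact proportions.
HOMA-IR has two explicit unit variants (mmol/L·µU/mL / 22.5 and
mg/dL·µU/mL / 405) and no silent default, because published values often
leave the glucose unit implicit.

## Synthetic sections

The generator emulates the statistical structure the analysis assumes,
not the optics of a microscope:

- **Plaques**: Poisson count (density per mm²), log-normal diameters
  (default µ = ln 18, σ = 0.35, truncated to [10.5, 45] µm), rendered as
  a plateau with a narrow Gaussian shoulder (σ = 0.35 px) whose
  half-maximum sits exactly at the nominal radius — so any threshold
  between roughly 5 % and 95 % of peak recovers the equivalent diameter
  within one pixel. Placement enforces a minimum outline gap (default
  65 µm) so proximity bands of neighboring plaques are disjoint and
  per-plaque recovery is well-defined.
- **Dystrophic neurites**: per-plaque Poisson counts with mean
  α + β·diameter (defaults α = 1, β = 0.25 µm⁻¹, planting the positive
  diameter–count relation), placed uniformly by area in the band with a
  small margin; rendered as flat-top puncta (plateau + shoulder) so the
  neurite channel has a genuine second intensity mode for the
  intermodes threshold.
- **Microglia**: per-plaque Poisson counts scaled by the **condition
  factor** (1.0 = control; 0.6 models the diet/T2D suppression of
  plaque-associated microglia), somata placed within the plaque (25 %)
  or in the band, plus background cells far from all bands; each cell is
  a soma disk (8–12 µm) with 2–6 fixed-step random-walk processes with
  directional persistence. Walks stop rather than run onto or beside
  other processes of the same cell (including their own earlier path),
  so each cell's skeleton topology — endpoint count and chain length —
  is recorded exactly at generation time. Lysosomal puncta are placed
  inside somata at a Poisson rate also scaled by the condition factor.
- **Nuisance**: a smooth linear background ramp of configurable
  peak-to-peak amplitude and additive Gaussian noise, added after ground
  truth is recorded; intensities are arbitrary units clipped to
  [0, 255]. Optional z-stacks replicate the section with per-slice
  intensity jitter whose brightest slice equals the 2D render, so ground
  truth is defined on the projection.

Per-section seeds in cohorts derive from the master seed by a
counter-based scheme (`SeedSequence(seed, spawn_key=(group, index))`),
so any section regenerates independently of order. Identical config and
seed give bit-identical output.

What the generator does **not** model — PSF blur and deconvolution,
photobleaching, chromatic shifts, tissue autofluorescence texture,
overlapping/merged plaques, truly ramified (branching) microglial
processes, DAB brightfield color — bounds what the passing tests show:
they demonstrate that the measurement chain is correct under the stated
model, not that it is robust to every artifact of real tissue.

## Simulated experiments (problem sizes)

Fixed in `plaqueband.experiments`:

- *Noise-free recovery*: 400×400 µm at 1 µm/px, ~4–10 plaques, well-
  separated cells with short processes; no denoising. Recovery of plaque
  count, per-plaque neurite and microglia counts, and per-cell process
  endpoints is exact; equivalent diameters agree within one pixel.
  Degenerate Poisson draws (too few objects) advance the seed
  deterministically.
- *Diameter–neurite relation*: 2×2 mm at 2.5 µm/px, ~200–250 plaques
  per seed, realistic noise; the measured Pearson r (typically ≈ 0.5)
  is positive in ≥ 99 of 100 seeds.
- *Condition power*: two groups of n = 6 sections (one section per
  animal, 420×420 µm at 1.5 µm/px, ~8 plaques each), factor 0.6 vs 1.0;
  per-section mean plaque-associated microglia compared by Mann-Whitney.
  Power ≈ 0.9 at α = 0.05 over 100 replicates; with identical groups the
  rejection rate is consistent with the nominal level. One section per
  animal (rather than averaging three) keeps the experiment light; the
  per-animal aggregation path exists in `run_pipeline` for real data
  organized as multiple sections per subject.

## Known limitations

- The rolling-ball approximation (flat-disk opening) differs from the
  literal rolling-ball surface for non-flat structuring elements.
- Intermodes fails on genuinely unimodal histograms by design; callers
  needing robustness should prefer Otsu/Moments for such channels.
- Microglia counting by component centroid undercounts when cells touch
  (merged components); the generator's separation defaults make this
  rare, but dense real tissue will need watershed-style splitting,
  which is out of scope.
- Manual plaque outlining (for stains without a plaque dye) is
  supported only by accepting an externally supplied plaque mask; no
  interactive tooling is included.
- Threshold behavior is defined at 256-bin resolution; sub-bin
  threshold differences are not meaningful.
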