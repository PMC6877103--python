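# Methods

This note records the models, parameter choices and numerical decisions
behind `hypercyte`, and what the synthetic benchmarks do and do not
establish about real microscopy data.

## DNA-content model and ploidy gating

The per-cell DNA proxy is the integrated Hoechst intensity
`I = area × mean nuclear intensity` (an exact identity in every record, not
a measured quantity). For a near-triploid line the G1 peak is declared 3N
and G2 6N; nothing in the pipeline depends on the absolute calibration, only
on the anchor, so all gates are **scale-equivariant**: multiplying every
Hoechst intensity by c > 0 and refitting moves every threshold by c and
changes no label.

**Anchor fitting.** The 3N anchor is the dominant mode of a Gaussian KDE of
control integrated intensities. The KDE uses a fixed bandwidth factor of
0.05 × sample SD — the default Scott factor is computed from the full
multi-modal sample and smears the G1 peak into the S/G2 arc. The G1
coefficient of variation comes from the mode's full width at half maximum
with the kernel width deconvolved
(`σ² = max(σ_FWHM² − bw², (0.005·mode)²)`); typical recovered cv on
synthetic controls with true cv 0.06 is 0.06 ± 0.005.

**Windows.** G1/G2 windows are `anchor·(1 ± k·cv)` with `k = 2.5`
(configurable); the hyperploid boundary is the upper edge of the G2 window
— at default parameters ≈ 6.9N, implementing a supraG2 gate placed at the
right end of the G2 region. EdU-positive cells are S regardless of DNA
content; EdU-negative cells between windows stay UNASSIGNED rather than
being forced into S, because intermediate non-replicating cells are
ambiguous. UNASSIGNED is kept in the denominator of class fractions
(typically 0.5–2% of viable cells at default noise).

**Debris.** Sub-G1 debris is integrated intensity < 0.25 × 3N anchor.

## Threshold rules

* **Bimodal midpoint** (pH3, and the default for PI/caspase/EdU): a
  two-component Gaussian mixture on log intensities; bimodality requires
  component separation ≥ 2 pooled SDs, otherwise the caller falls back to
  the percentile rule. The two component means are mapped back to the
  intensity scale and the threshold is their arithmetic midpoint. Input is
  winsorized at the 0.1/99.9 percentiles so a handful of extreme values
  cannot stretch one component and defeat the separation check.
* **Control percentile** (pH2A.X and fallbacks): the q-th percentile
  (linear interpolation, numpy convention) of untreated viable controls;
  positivity is strictly above. By construction ≈ (100−q)% of the control
  itself is flagged.
* **Cleaved-PARP 2-D rule**: one percentile level applied to both axes
  (mean nuclear intensity, N:C ratio); a cell is positive if above **both**
  cutoffs. The level is scanned (50–99.95) so that the flagged fraction of
  the control bulk is as close as possible to 2%, the stated calibration of
  the gate. With independent axes this lands near the 86th percentile.

All thresholds are intended to be fit per plate/day batch (staining is not
calibrated across plates); the CLI refits on each run's vehicle wells.

## Segmentation and features

Gaussian pre-smooth (σ = 1 px) → global Otsu (or fixed) threshold → hole
fill → distance-transform watershed → small-object removal (≥ 20 px²).
The watershed peak separation defaults to 18 px: hyperploid nuclei are
rendered (and in tissue appear) as lobated blobs, and at ~10 px the lobes of
one nucleus split into separate G2-sized objects; genuinely touching round
nuclei (center distance ≳ 30 px) still split. Border objects are kept by
default (configurable).

Per-channel means are background-corrected by subtracting the median of
non-object pixels; without this the integrated-intensity proxy absorbs
`area × background` and ploidy ratios are destroyed at realistic background
levels. The cytoplasmic ring is the band within 3 px of each nucleus,
excluding all nuclei, with contested pixels assigned to the nearest nucleus;
`nc_ratio = nuclear mean / ring mean`. Coordinates are 0-based, origin
top-left, x = column; areas in px² with optional µm² when a pixel size is
configured.

On noise-free synthetic fields, detection recall is ≥ 98% with per-object
area error ≤ 10% and integrated-intensity error ≤ 3%; with default noise and
blur (PSF σ 1 px, background 2 ± 0.5) recall is ~96–97% and the median DNA
error ~3%, dominated by flux blurred outside the mask.

## Synthetic data generator

The generator draws what the analysis assumes, not a mechanistic model:

* classes (G1/S/G2/HYPER) from per-cell uniforms against cumulative
  fractions; G1 DNA = 3N·(1+ε), G2 = 6N·(1+ε), S uniform on (3N, 6N) with
  EdU-positive state, HYPER uniform on 2.2–4.0 × 3N (the dispersion of >6N
  content is unreported anywhere we know of; this range is a modeling
  choice);
* nuclear area = 400 px² · (relative ploidy)^1 · lognormal noise (cv 0.08),
  so ~12N cells are four-fold larger than 3N cells by construction, matching
  the observed area/ploidy relation; the exponent is configurable;
* viability classes drawn independently of cycle class; PI/caspase states
  follow the class; marker intensities are two-component **log-normal**
  mixtures moment-matched to (mean, SD) — fluorescence is strictly positive,
  and clipped-normal draws create a floor pile-up whose log outliers break
  mixture fitting;
* optional extras: `fragment_fraction` (sub-G1 debris at ~5% of G1 content)
  and `mitotic_fraction` (pH3-positive state, default 3%).

**Rendering.** Nuclei are ellipses (axis ratio 0.7–0.95, random
orientation); hyperploid nuclei are 2–3 overlapping lobes. Noise-free
rendering conserves each nucleus's summed Hoechst intensity exactly (uniform
fill of `DNA/n_pixels`). Antibody channels get a uniform nuclear value and a
dim cytoplasmic halo at `mean/nc_ratio`. PSF blur, Gaussian background and
optional Poisson noise follow. Placement enforces non-overlap at 1.35 ×
equivalent radius; 300 nuclei fit a 1024×1024 field at roughly the density
of a confluent high-content field.

**Movies.** Defaults: 30-min frames, 21 frames (10 h). Cells random-walk
(σ = 2 px/frame) with excluded volume — initial minimum separation 24 px,
and steps bringing two nuclei closer than 0.9 × the sum of their radii are
rejected. This matters: unconstrained placement produces physically
impossible co-located nuclei whose identity swaps corrupt any tracker.
Events per cell per hour: division (parent → two daughters at ±8 px, half
DNA each), mitotic catastrophe (PI onset + fragmentation, then removal),
slippage (two half-DNA lobes for two frames, re-merging into one nucleus at
1.45 × the pre-mitotic area), non-mitotic death. Mitosis entries carry a
rounding flag (area drop + the flag column) so classification can be tested
independently of entry detection. No event initiates in the last four frames,
so every program resolves within the recording and
`n_end = n_start + divisions − deaths` holds exactly against the event log.

What the generator does **not** emulate: optical crowding/overlap,
focus drift, uneven illumination, channel crosstalk, cell morphology beyond
ellipses/lobes, S-phase DNA-EdU joint structure beyond the uniform arc, and
spatially correlated fates. Passing benchmarks therefore demonstrate
correctness of the gating/tracking logic under the stated statistical
structure, not segmentation robustness on difficult real images.

## Tracking and fate classification

Greedy ascending-distance nearest-neighbor linking under a 25 px gate
(roughly the expected 30-min displacement), with one addition: a candidate
link whose integrated Hoechst changes more than 1.4-fold is vetoed. A
halving or doubling of DNA content marks a mitotic product — daughter or
re-merged slippage nucleus — and treating such a link as a continuation
masks division splits and chains identities; position alone cannot make
this distinction. New nuclei left unlinked become daughters of their nearest
previous nucleus (the parent track ends DIVIDED and its greedy continuation
is reassigned as a sibling), which also realizes tripolar divisions.
Disappearances end DIED if the last observation was PI-positive, else LOST.

Per mitosis entry (flag, or area-drop + Hoechst-rise heuristic), within a
6-frame window: ≥2 daughters persisting ≥3 frames → successful division;
track death → mitotic catastrophe; exactly two short-lived lobes where one
ends as the pair re-merges into a nucleus ≥ 0.9 × the pre-mitotic area →
slippage; everything else (including stalls past the window and
out-of-field losses) → unclear. On simulator defaults (100 cells, 20/10/5
forced events) classification accuracy against the event log averages ~96%
(min 89% over 30 seeds); errors come from simultaneous adjacent events whose
products entangle — the same cases that are ambiguous by eye.

Death accounting is pure integer arithmetic and is exact whenever detection
is perfect; the death rate is `%` of starting nuclei per hour.

## Population endpoints

Suppression rules are pure count thresholds, all at five: per-well summaries
(≥5 viable cells), per-class median areas (≥5 nuclei in class), checkpoint
ratio (≥5 G2 cells), mitotic breakdowns (≥5 mitotic nuclei), outcome
percentages (≥5 mitotic events). Each is unit-tested at 4 vs 5.

The checkpoint-strength ratio normalizes each marker by the same-day bulk
control mean before dividing
(`(pCHK1_G2/pCHK1_bulk)/(pH2AX_G2/pH2AX_bulk)`); normalizing first and
dividing after is algebraically identical to dividing first and normalizing
by the bulk's own ratio, so the order stated here is a presentation choice,
not a numerical one. The ratio equals 1 exactly when the G2 subset's means
equal the bulk means.

Dose-response is a least-squares 4PL `y = bottom + (top−bottom)/(1+(d/IC50)^h)`
fit with a log-IC50 parameterization (scipy `curve_fit`); the vehicle dose
enters the fit directly (the model evaluates to `top` at d = 0). Zero-noise
recovery is exact to ~1e-9; with 5% multiplicative noise at 8 doses the
median relative IC50 error is ~5–6%. `ICq = IC50·(q/(100−q))^{1/h}` in
closed form. In generated plates the *viable-count* IC50 sits below the
plating IC50 because PI-positivity also rises with dose — the readout
compounds both effects, as the assay does.

Regrowth uses summed segmented nuclear areas over the well area (union of
mask pixels would differ only where nuclei overlap, which the generator
excludes), normalized to the well with the largest covered area.

## Problem sizes and determinism

Defaults used by the test suite and `scripts/acceptance.py`: 5000-cell
tables for fraction recovery; 12 fields × 300 nuclei at 1024×1024 px for the
image round trip (~35 s total); 20 movies × 100 cells × 21 frames for death
accounting; one 35-event movie for fate accuracy; 100 replicate fits for
dose-response. Every stage derives its RNG stream from one master seed with
fixed offsets; identical configuration and seed reproduce every output byte
for byte.
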