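# Methods

## Scope and data model

The package quantifies total tau and phospho-tau separately in neuronal cell
bodies and neurites from four-channel 2D fluorescence fields (DNA stain,
βIII-tubulin, total tau, phospho-tau), organised as 96-well plates with a
fixed number of fields acquired per well (default 25, indexed 0–24 in
row-major order; the acquisition geometry itself is not modelled). Pixel
indexing is 0-based row-major; all masks share the image grid exactly and
there is no sub-pixel geometry. Channel identity always comes from an
explicit channel map, never from plane order.

## Synthetic fields

The generator emulates the phenomena that make dense human neuronal
cultures hard to segment, with exact ground truth for every one of them:

- **Live neuronal nuclei** are filled discs (radius 5.5–7.5 px) with an
  attached soma disc (radius 7–10 px); **non-neuronal nuclei** are identical
  discs without somata or cytoskeletal signal; **dead (pyknotic) nuclei**
  are strictly smaller (radius 3.5–5 px), much brighter in the DNA channel
  (1500 vs 600 a.u.) and rendered as spiky star polygons so their solidity
  is low — the three cues (size, brightness, ruggedness) the exclusion rule
  keys on.
- **Neurite trees** grow from the soma boundary as random walks (heading
  noise 0.25 rad per 3-px step, per-step branch probability 0.05, total
  length 60–200 px per primary tree, 2–4 primaries per neuron). A
  configurable fraction (0.3) of trees is *minor*: 1 px wide and roughly
  half the intensity of the 3-px-wide majors. With probability 0.08 a tree
  is steered through a foreign soma to exercise the crossing-exclusion
  rule. Strokes are drawn at integer width with no anti-aliasing, so true
  areas are exact pixel counts.
- **Clumps** are groups of ≥3 neuronal nuclei fused at one site with
  elevated local background (1.75×); their somata overlap and their members
  grow no neurites. The truth clump mask is the dilated union of the member
  nuclei.
- **Intensities** are painted per compartment and channel (background 80,
  somata 300–500, major neurites 500–550, minor neurites 240–260 a.u.);
  in the cytoskeletal channels the soma covers its nucleus (as in a
  projection image) and neurites are painted last, so the per-compound
  multiplicative effects on phospho-tau (per compartment) and on neurite
  length scale the ground-truth means *exactly*. Noise is Poisson shot
  noise on the clean signal followed by additive Gaussian read noise
  (σ = 8); both are toggleable, and an optional Gaussian optics blur is off
  by default so ground-truth geometry stays crisp.

Determinism: one integer master seed; per-field seeds derive from a stable
hash of (seed, well, field index), so plates of any size reproduce exactly
and wells can be regenerated independently.

What the generator does **not** emulate: uneven illumination and flat-field
error, optics PSF beyond the optional blur, staining gradients within a
compartment, debris and non-cellular fluorescence, 3D structure, or
photobleaching. Passing recovery tests on this simulator therefore shows
the pipeline implements its stated rules correctly and recovers known
signals under realistic noise — not that it is robust to every artefact of
real instrument data.

## Segmentation

All intensity cutoffs are derived per field from robust statistics
(median and 1.4826×MAD) of the relevant image or response, multiplied by at
most three run-level adjustment factors (`dna`, `soma`, `neurite`). This
makes the pipeline equivariant under global intensity changes and keeps
run-to-run compensation down to three explicit, logged numbers.

1. **Nuclei.** The DNA channel is lightly smoothed (σ = 0.8 px) and edges
   are taken from the Sobel gradient magnitude with hysteresis linking
   (high threshold 8 noise-σ, low 0.4×high); contours are closed with a
   2-px disc and filled. Because the edge ring inflates objects, each
   object is then restricted to its intensity core — pixels above the
   midpoint between the field median and the object's 90th-percentile
   intensity, on the raw channel — so area, mean intensity and solidity
   describe the nucleus itself. Objects are classed **dead** when area
   ≤ 55 px², mean DNA intensity ≥ 1.5× the median of size-qualified nuclei
   and solidity ≤ 0.85 (all three together); sub-nuclear debris is dropped;
   everything else is provisionally live. These thresholds were calibrated
   on the simulator and are exposed in the config.
2. **Cell bodies.** Support = pixels where *both* tubulin and total tau
   exceed median + 8σ. A binary opening with a 2-px disc removes
   neurite-width support so growth cannot leak along processes; each live
   nucleus then grows geodesically through the opened support (8-connected,
   pixels assigned to the nearest nucleus, radius capped by the soma area
   maximum, and trimmed to the nearest pixels if the cap is exceeded). A
   candidate must land in the 100–450 px² area range with ≥ 70% per-channel
   support, otherwise the nucleus is classed non-neuronal and no soma is
   emitted.
3. **Neurites.** The response is a white top-hat (5-px disc) of the
   per-pixel maximum of tubulin, total tau and phospho-tau — a
   local-contrast operator that passes thin ridges and suppresses wide
   blobs (somata, clumps). Ten passes apply a geometrically relaxing cutoff
   (1.0 → 0.4 of 12 response-σ). The first, strictest pass seeds the mask
   with every super-threshold pixel; each later pass admits only pixels
   8-connected to the accumulated mask or to somata. The mask therefore
   grows monotonically, late passes recover dim minor neurites and close
   path gaps, and on a pure-noise field essentially nothing is detected
   (stringency is deliberately biased toward false negatives).
4. **Segment test.** Connected segments not touching a soma survive only if
   their mean composite intensity is ≥ 1.2× the local background mean
   (a ring around the segment) *and* their skeleton is ≥ 20 px long. This
   is also where antibody-dependent background is absorbed: diffuse
   false-positive patches fail the local-contrast test.
5. **Gap closing.** Skeleton endpoints in different components closer than
   10 px are bridged only when each endpoint's local tangent (estimated
   from the last 5 skeleton pixels) points toward the other within 0.5 rad;
   the bridge is a straight path dilated to the local neurite width.
   Distance alone never bridges, and the operation is idempotent.
6. **Clumps.** Detected nucleus blobs are closed with a 3-px disc; a region
   is a clump when it fuses ≥ 3 detected nuclei or its area reaches the
   live-nucleus area maximum (fused nuclei usually merge into one object,
   so the area rule is the common trigger); the mask is dilated by 6 px and
   member nuclei are reclassified as clump-excluded.
7. **Finalisation.** Neurite quantification mask = final neurite mask minus
   all soma pixels minus clumps; cell-body quantification labels = somata
   minus neurite crossings (plain intersection with the neurite mask) minus
   clumps. Disjointness of the two quantification masks is asserted on
   every run.

## Quantification

Mean intensities follow the total-over-area construction: summed intensity
over the quantification mask divided by its pixel count, with soma pixels
pooled across the field rather than averaged per cell (the per-cell
alternative is not computed; pooling matches the total/area construction of
the field-level measure). The phospho/total tau ratio is the ratio of those
two means per field. Empty masks yield NaN — an explicit undefined marker —
and the field is flagged and excluded from well aggregation rather than
imputed. No background subtraction is applied before summing; a local
background option exists but is off by default. Well-level SDs are reported
only for n ≥ 2 fields.

## Screen statistics

- **Responsiveness (rule a):** plate excluded when the *raw* (unnormalised)
  ratio of DMSO to positive-control mean neurite phospho-tau falls below
  1.3.
- **Field QC (rules b, c):** a field is excluded when its neurite area lies
  below the lower 95% confidence bound of its own well (b) or of the
  plate's pooled DMSO fields (c). "Lower 95% CI" is read as the lower
  t-based confidence bound of the **mean**, `x̄ − t₀.₉₇₅,ₙ₋₁·s/√n`; an
  empirical-percentile alternative sits behind `ci_mode="percentile"`.
  Both rules are evaluated on the original field set and the union of
  exclusions taken, so they commute; a field failing both is recorded under
  both reasons. With few fields per well the pooled-DMSO bound is
  aggressive (it sits ≈ 0.5 within-well SD below the mean); a treatment
  whose every field is excluded remains in the output table flagged
  unusable rather than disappearing.
- **Normalisation:** fold change = field value / mean over all DMSO fields
  pooled across the plate (so DMSO normalises to exactly 1 on average);
  pooling was chosen over per-well references for stability.
- **Z′-factor:** `1 − 3(σ₊+σ₋)/|μ₊−μ₋|` with sample SDs, computed on
  well-level means (one value per control well), not field-level values.
- **Toxicity:** neurite-area fold change < 0.8 (a > 20% decrease).
- **Hits:** fold change below the positive-control fold change in *both*
  compartments, non-toxic, QC-passing. Compounds active in only one
  compartment are flagged neurite- or soma-selective, never as hits. No
  multiple-testing correction is applied — the threshold is the measured
  positive-control effect, not a p-value.

## Dose–response

The 4PL family `y = bottom + (top−bottom)/(1 + 10^((log IC₅₀ − log₁₀ x)·h))`
(the log-agonist, variable-slope parameterisation; inhibition curves take
negative h) is fitted by bounded trust-region least squares with
multi-start initialisation over a grid of log IC₅₀ and both slope signs,
keeping the lowest SSE. Because responses are fold changes, default bounds
are top ∈ [0.5, 1.5], bottom ≥ 0, |h| ≤ 10, log IC₅₀ within the dose range
± 3 decades; all overridable. Flat responses raise an explicit
no-dose-dependence error; ≥ 4 distinct positive doses are required; a fit
touching a bound is flagged.

## Problem sizes

The default field is 1024×1024 px. The test suite and the acceptance script
run the same pipeline at reduced sizes chosen to keep full end-to-end runs
at desk scale while preserving the default cell density and SNR:
512×512 px fields with 30 neurons + 10 non-neuronal + 5 dead nuclei for
segmentation/intensity/effect recovery (20 fields; 25 fields per well for
the effect-size check), and a 49-well screen plate (4 DMSO, 4 positive
control, 41 compounds) at 320×320 px with 8 fields per well — 392 segmented
fields per screen run. Eight fields per well keeps the per-well CI
exclusion rule from ever consuming a whole well, which 25-field wells make
astronomically unlikely and 4-field wells do not.

## Known limitations

- The iterative extractor reproduces the described behaviour (iterative
  growth under relaxing cutoffs, minor/major distinction, gap closing,
  clump and crossing exclusion), not numeric parity with any proprietary
  implementation whose per-iteration operators are undisclosed.
- Soma/neurite crossing exclusion uses the plain mask intersection; no
  path tracing through the soma is attempted.
- Nucleus splitting within fused blobs is not performed; fused groups are
  handled by the clump rules instead.
- Per-cell (as opposed to pooled-pixel) cell-body statistics are not
  computed.
- The simulator's morphology distributions are calibration choices, stated
  in `SynthFieldConfig`; they are not measurements of any real culture.
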