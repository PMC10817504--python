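# Methods

## Pipeline model

The pipeline treats forest disturbance detection as a per-pixel anomaly
problem on an annual time step. For every year a cloud-free median
composite is built from all scenes in the vegetation window; the year's
NDVI is computed from that composite (composites first, indices second —
the median of reflectance, not the median of per-scene NDVI). The
standardized anomaly

    z_t = (NDVI_t − mean_{years}(NDVI)) / std_{years}(NDVI)

is computed **per pixel**: the baseline mean and standard deviation are
the statistics of that pixel's own annual NDVI series, not a regional
constant. This is what makes the anomaly map spatially interpretable —
each pixel is compared with its own history — but it also fixes the
anomaly scale per pixel, with consequences discussed below. The standard
deviation is the population form (divide by n), matching the convention
of the cloud-platform reducer this pipeline mirrors; the choice is
documented here and switchable in `reduce`.

### Conventions and tie-breaks

- Date windows are half-open `[start, end)`.
- The scene-level cloud filter is inclusive (≤ 5%).
- Pixel-in-polygon is centre containment everywhere (ROI filtering,
  report rasterization, zonal statistics), so pixel counts are exact and
  additive over non-overlapping polygons.
- A pixel is damage when `z < −0.5` (strictly below). A compartment is
  reference damage when its damage ratio is `≥ 30%`: the field rule
  assigns "below 30%" to no-damage and "above 30%" to damage, leaving
  exactly 30 unassigned; the tie resolves toward damage.
- Internally 1 = damage in every binary map; the field convention that
  codes damage as 0 on the anomaly raster is an export/import flag
  (`to_field_coding` / `from_field_coding`).
- Zonal majority ties break to the lowest class code and are flagged.
- Degenerate inputs are nodata, never silent zeros: `std = 0` pixels have
  no anomaly scale; `NIR + RED = 0` has no NDVI; pixels valid in fewer
  than two years have no baseline spread. Compartments with no valid
  pixel are excluded from the species accuracy with a warning.
- Reported percentages are rounded to 2 dp half-up (the convention of the
  spreadsheet-style accuracy tables this mirrors, where a mean of 99.625
  prints as 99.63). The RGB stretch rounds half-to-even (`np.rint`).

### An inherent property of short-baseline standardization

With a 4-year baseline the per-pixel z-scores satisfy Σz = 0 and
Σz² = 4. It follows algebraically that **no pixel can have all four
years above −0.5** (three years at −0.5 and one at +1.5 give Σz² = 3 < 4):
every undisturbed, noise-only pixel is classified damaged in at least
one year, and the per-year false-positive rate of the −0.5 threshold on
pure noise is ≈ 35%. High producer's accuracy combined with materially
lower user's accuracy is therefore structural for this method, not a
tuning artifact. It also means a damage-year total accuracy above 90% is
only achievable when most of the validated area is genuinely damaged in
that year, which is the situation the default scenario models (and which
matches the published reference shares this pipeline's validation design
follows, where 56–75% of compared pixels were reference damage).

## Synthetic archive

The generator emulates what the pipeline consumes, not radiative
transfer:

- **Grid**: 60×60 pixels at 10 m (local metric frame, north-up).
- **Compartments**: 36 rectangles from randomized binary-space
  partitioning of the grid (pixel-aligned split lines, so areas and pixel
  counts agree exactly). Species are assigned by largest-remainder counts
  from the mixture (15% black locust, 20% Scots pine, 35% pedunculate
  oak, 20% red oak, 10% clearcut), shuffled by the seed.
- **Phenology**: per-species double-sigmoid NDVI curves between a dormant
  baseline and a summer peak (deciduous peaks 0.84–0.90, reached in
  midsummer; Scots pine flatter with a high evergreen baseline; clearcut
  low throughout). Fixed per-species blue/green/red reflectances plus the
  NDVI target determine NIR via `NIR = RED (1+n)/(1−n)`. Field spectra
  are not modelled; the signatures are free parameters chosen to be
  plausible and mutually separable, and are documented as such.
- **Acquisitions**: 12 dates per year, every 16 days, at days-of-year
  105–281 — inside the mid-April–mid-October window in both leap and
  common years, so every year keeps an identical date set and a
  noise-free archive has exactly zero interannual variance.
- **Damage**: an event depresses NIR by its severity over the first
  `ceil(fraction · n)` compartment pixels in a deterministic west-to-east
  sweep; the exact depressed-pixel set is exposed (`damage_truth`) for
  recall/precision bookkeeping. The default scenario puts severity-0.85
  whole-compartment events on ~80% of compartment area in 2019 (a
  widespread severe drought/frost year) and two small sub-threshold
  events (20% of a compartment) in 2017 to exercise the below-30% path.
  Severity needs to be large because NDVI is insensitive to NIR loss when
  RED is small: at severity 0.6 a black-locust pixel only drops from
  NDVI 0.90 to 0.77, at 0.85 it drops to ≈ 0.5.
- **Noise**: i.i.d. Gaussian reflectance noise per band, pixel, and scene
  (sd 0.02 by default), clipped to [0, 1]. Noise on the small RED band
  dominates the NDVI noise budget (sd ≈ 0.05–0.1 per scene for bright
  canopies), reduced by the within-year median.
- **Clouds**: random ellipses (2–6 px semi-axes) accumulated until a
  target fraction drawn from U(0, 0.05) is reached; both QA bits 10 and
  11 are set together, and the scene metadata percentage is computed from
  the mask itself, so metadata and bitmask are consistent by
  construction.
- **Seeding**: one master seed; per-scene substreams keyed by
  (seed, year, day-of-year), so adding a date never perturbs other
  scenes; compartment geometry uses its own substream.

What the generator does **not** emulate — and what passing tests
therefore do not show about real data: atmospheric and BRDF effects,
topography, mixed-species compartments, spatially correlated noise,
within-compartment species heterogeneity, mis-registered or partial
field reports, and the reporting lag between a disturbance and its
ground survey. On real archives the species classes are far less
separable and the reference maps far less reliable than here; the
synthetic accuracies are upper bounds that validate the *machinery*, not
forecasts of field performance.

## Species classification choices

Features are *all* bands present in the composite (four in the minimal
synthetic archive, so the 10-variables-per-split default clamps to 4
with a warning). Training points are auto-sampled from ground-truth
compartments with fixed per-class counts (15/27/40/22/19, total 123),
mirroring a manual field-point protocol. The composite year is a
configuration parameter (`species_year`, default the last year). The
compartment accuracy is reported both over all compartments and with
clearcuts excluded; tie compartments are included (resolved
deterministically) and their count is reported alongside.

## Problem sizes and determinism

The bundled study runs on a 60×60 grid × 4 years × 12 scenes ≈ 3.5 M
band-pixels, which keeps a full pipeline run under a second and the
ten-replicate acceptance computation under a minute, while every
compartment still has ≥ 20 pixels and the confusion matrices compare
3 600 pixels per year. Reruns with the same configuration are
byte-identical (CSV) and bit-identical (arrays); the run manifest records
the configuration hash, seed, and library versions.

## Known limitations

- The anomaly baseline includes the year being standardized (a 4-year
  series is too short to hold one year out), which shrinks large
  anomalies; with one severe year in four this still yields z ≈ −1.7 at
  damaged pixels, comfortably below the threshold.
- Real scene archives with heavy spring cloud cover can leave composite
  gaps that propagate to nodata anomalies; the pipeline reports per-pixel
  observation counts (`n_scenes_used`) but does not gap-fill.
- The normality check on synthetic anomaly maps typically *rejects*
  normality: the maps are mixtures (damaged vs undamaged populations,
  species-specific responses), which is faithful to what the check is
  for — flagging when the anomaly field is not a single homogeneous
  population.
- Reprojection is out of scope: all inputs of a run must share one
  coordinate frame, and mismatches are rejected loudly.
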