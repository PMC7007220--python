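# Methods

This note documents the models behind each module, the defaults and why they
were chosen, the numerical conventions, and what the synthetic generators do
and do not emulate.

## Coordinate and unit conventions

All positions are in μm, times in seconds, frequencies in Hz, fractions
either in [0, 1] (grid/dorsal fractions, clustering index) or percent
(silent fraction, band split). The anatomical frame is x = mediolateral
(positive lateral, midline at x = 0) and y = dorsoventral (positive dorsal);
in images, row 0 is the dorsal edge and columns increase laterally away from
the midline on the ipsilateral side. Sample indices are 0-based internally;
user-facing positions are seconds/μm.

## Nerve-burst analysis (`phrenic.bursts`)

**Filtering.** Zero-phase 4th-order Butterworth band-pass (default
10 Hz–3 kHz, applied forward–backward with `sosfiltfilt`), mean-subtracted.
Zero-phase filtering is used so burst boundaries are not shifted by filter
delay. The upper edge is clipped to 0.45 × fs with a warning when the
recording was sampled too slowly.

**Burst detection.** A moving-RMS envelope (50 ms window) is thresholded at
the median of its quietest quartile plus `k_sd` (default 5) robust SDs of
the burst-free envelope; the robust SD comes from the sub-75th-percentile
envelope via 1.4826 × MAD, so bursts themselves cannot inflate it, and a
small dynamic-range floor handles noiseless signals. Suprathreshold regions
closer than 100 ms merge; regions shorter than 100 ms are dropped. Because
a centered RMS window smears each edge by up to half its width, boundaries
are then refined on the rectified signal: each edge snaps to the first/last
sample exceeding 6 robust SDs of the baseline within ±1–3 windows of the
coarse edge. On simulated recordings this places boundaries within ~3 ms of
truth (the contract tested is ±20 ms).

**Per-preparation summaries.** Burst frequency is counted over 5 min of
recording; duration, silent fraction, and spectra are summarized over the
first five analyzed bursts, mirroring the standard protocol. The settling
window before the five-burst selection defaults to 0 s (simulated recordings
begin mid-protocol); `select_bursts(..., settle_s=30)` reproduces a
bench-style settling period.

**Unit activity and silent fraction.** Within a burst, the rectified signal
is compared to 4 × (1.4826 × MAD) of the inter-burst baseline; the
suprathreshold mask is morphologically closed at the spike-width scale
(1 ms) so the zero crossing inside a biphasic spike does not read as
silence, with edge padding so closing cannot erode segment borders. The
silent fraction counts only silent runs of ≥ 5 ms — the gap between 30 Hz
volleys is ~33 ms, so genuine inter-volley silence is counted while
inter-spike gaps within a volley are not. Because both thresholds are
data-relative, the silent fraction is invariant to uniform amplitude
scaling. The mask-level computation is exactly equivalent to run-length
enumeration (tested against an independent oracle).

**Spectra.** One Hann-tapered periodogram per burst, zero-padded to a fixed
`nfft = fs / bin_width` (default bin width 1.25 Hz, satisfying the ≤ 2.5 Hz
requirement for unambiguous 75 Hz band assignment) so spectra from bursts of
unequal detected length live on one grid and can be averaged; segments
longer than `nfft` are truncated (warned above 1.5 × `nfft`). Bins outside
10–400 Hz are discarded *before* normalization; each spectrum's retained
relative powers sum to 1 (tolerance 1e-9). The band split assigns a bin to
"below" when its centre is below the split frequency, so below + above =
100% exactly. Spectra are computed on the raw (band-passed) signal by
default; `rectify=True` is available since some acquisition chains analyze
rectified traces. Single periodograms have exponentially distributed bins
(max/mean over ~300 bins is expected to reach 5–6), so "no dominant bin"
statements are only meaningful for the five-burst averaged estimator, which
is what the package reports.

## Firing-pattern generator (`phrenic.synth.firing`)

The generator is phenomenological, not biophysical: it reproduces the
statistical structure of neonatal fictive inspiration at the level of spike
times and a compound signal, without conductance-based dynamics, gap
junctions, or 3-D tissue.

**Control regime.** Bursts of 0.8 s at 8/min (a plausible neonatal fictive
rhythm; both configurable) with ~100 ms start jitter. Within a burst a
global 30 Hz clock runs with phase continuity; each of 250 units fires at
each tick with probability 0.85 and Gaussian timing jitter (SD 5 ms), plus
an asynchronous 5 Hz/unit background confined to activity periods. Eight
scheduled silent gaps, centred at fractions 0.1…0.9 of the burst with
durations growing linearly 12 → 42 ms, delete all spikes they cover —
silent periods that progressively lengthen through the burst. Unit count
matters quantitatively: the phrenic nerve carries a few hundred motor axons
at birth, and with ~250 units the coherent 30 Hz volley line dominates the
spike-shot-noise background of the raw-signal spectrum (a 1 ms biphasic
spike has |W(f)|² ∝ f² over the analysis band, which otherwise favors high
frequencies). The 5 ms jitter sets the harmonic decay so the 30 Hz
fundamental beats the 60 Hz harmonic by ~3–4× in power.

**Mutant regime.** The same burst envelope, but each unit is an independent
homogeneous Poisson process at 40 Hz with no gaps and no clock — continuous,
unsynchronized firing. The **disinhibited** regime is the mutant process
applied to the control unit pool, emulating local picrotoxin/strychnine
application; with matched unit counts it is distributionally identical to
the mutant, which is exactly the equivalence the analysis chain is expected
to report.

**Rendering and ground truth.** The compound signal is the exact sum of a
biphasic difference-of-Gaussians waveform (1 ms support, truncated so
rendering is strictly linear in the spike set) evaluated analytically at
each sample time, plus Gaussian noise (SD 0.1 vs unit spike amplitude 1).
Ground truth includes burst intervals, per-unit spike times, and a
population activity mask (true where ≥1 unit fires within a 1 ms coincidence
window). Under the defaults, the mask-level silent fraction of control
bursts lands at ~27–30% — scheduled gaps contribute ~27%, inter-volley
silence the rest — within the 20–60% range typical of patterned neonatal
bursts, while mutant bursts stay below 5%.

**What passing tests show.** Separation and recovery results demonstrate
that the analysis chain measures what it claims on data with this
statistical structure (volley synchrony, Poisson disintegration, additive
Gaussian noise). Real recordings add electrode drift, movement artifacts,
amplitude inhomogeneity across units, and non-stationary rhythms that the
generator does not emulate; the detection thresholds are data-relative
precisely so that such differences degrade gracefully rather than silently.

## Soma clustering (`phrenic.topography`)

Contact index: neuron i is in contact with j when centre distance ≤
r_i + r_j + tol (default tol 0); the index is contacts/n, with n = 1 scoring
0 by convention. Point (nuclear) data without membrane outlines get an
effective radius of 5 μm. The occupied area of the column is the convex hull
of nucleus centres — "connect nuclei to their nearest neighbour to form a
perimeter" does not define a closed polygon for arbitrary point sets, so the
hull is adopted as the area dialect, with an alpha-shape option (Delaunay
triangles with circumradius < α, default 30 μm) for concave columns; the
choice is recorded in each report's parameters. Density index =
1000 × n / area. Degenerate maps (n < 3, collinear) raise for area/density
rather than returning 0; `cluster_report` reports them as missing. The
clustered-map generator packs each soma tangent to a previous one (placed
1 nμm into overlap so exact-tangency never fails a zero-tolerance contact
test under floating point); the dispersed generator enforces separations
above 2r + margin.

## Dendritic orientation (`phrenic.dendrites`)

"Spanning 200 μm in each direction" is read as half-width 200 μm from the
soma centroid per cardinal direction: a 400 × 400 μm grid of nine
~133 μm squares. The centre square holds the cell bodies and is excluded;
fractions are normalized to the summed peripheral intensity, so they sum to
1 and are invariant to uniform intensity scaling. The square numbering is a
loadable layout table; the default places 5+6 as the dorsolateral pair and 8
as the medial (midline-facing) square, with column bands flipped
automatically when the ipsilateral side is on the low-column side. Pixels
are assigned to squares by their integer coordinates, so fractions equal
direct per-square pixel sums exactly; with ~1.3 px-wide boundary
quantization, symmetry statements (e.g. uniform field → 0.125 per square)
are exact only when square edges align with pixel edges. Dorsal fraction =
intensity in rows strictly dorsal to the soma row / total; dorsal + ventral
= 1 exactly. Midline crossing: Otsu binarization by default (fixed threshold
available; constant images have no foreground), 8-connected components
counted when they have foreground strictly on both sides of the midline
column, distance = farthest contralateral column reach × pixel size.
Coverage = suprathreshold pixel count × pixel area. The generator renders
Gaussian-profile rays (σ 12 μm) from the centroid with ±3° angle jitter per
seed, and integrates its *analytic* intensity on a 3× supersampled, offset
grid for ground-truth square fractions, dorsal share, and footprint — so
truth is independent of the rendering raster (recovery contract: ±0.03 per
square).

## Synaptic appositions (`phrenic.puncta`)

Detection is Laplacian-of-Gaussian blob detection on the normalized channel,
with the sigma range implied by the diameter gates (blob radius ≈ √2 σ) and
sub-pixel refinement by local intensity-weighted centroid (observed accuracy
~0.1 px on rendered spots). Matching is greedy closest-first one-to-one
pairing within 0.5 μm — an Airyscan-scale juxtaposition criterion declared
as a stand-in for the manual judgement used at the bench — with ties broken
by lowest indices for determinism; on non-degenerate instances it equals
exhaustive distance-ordered enumeration. Counting assigns an apposition to a
soma when its midpoint lies within 2 μm of the membrane polygon (inside or
outside, boundary inclusive); overlapping shells assign to the nearest
membrane with a warning. Analysis is 2-D, single optical sections; no
z-linking. The generator places pairs in the perisomatic shell with pair
separation ≤ the apposition radius and keeps unpaired distractors ≥ 1.5 μm
from every other punctum, recording the minimum unpaired pre–post distance
so tests can choose matching radii with guaranteed zero false positives.

## Breathing (`phrenic.breathing`)

Cycles are trough-to-trough on a 20 ms-smoothed trace (prominence gate at a
quarter of the robust 5–95% range; cycles shorter than 80 ms rejected); each
detected trough starts one cycle, so a noiseless trace at rate r over
duration T yields exactly r × T cycles. TV is the mean peak-to-trough
amplitude per complete cycle measured on the same smoothed trace (the 20 ms
window attenuates a 2.5 Hz sinusoid by < 0.5%); f is the onset count scaled
to breaths/min; MV = TV × f exactly at the single-session level. Units are
the trace's calibrated units — conversion to mL is the caller's
responsibility. Resting-breath selection by direct observation cannot be
replicated, so a movement-artifact gate drops cycles whose amplitude is a
3×IQR outlier (with a 1% relative floor so near-constant amplitude trains
are never culled). Multi-day averaging averages each metric independently —
the averaged MV can differ from averaged-TV × averaged-f, and the recomputed
product is reported alongside (`extras["mv_from_means"]`). Fold-control and
hypercapnia responses are per-metric ratios. `compare_groups` is the
equal-variance unpaired two-tailed t test; zero-variance degenerate inputs
return (0, 1) for equal means and (±inf, 0) otherwise. Generator noise
defaults to SD 0.005 on a 0.2-unit tidal volume (2.5%), typical of a clean
pressure-transducer chain, which keeps TV/f recovery within 2% noiseless and
5% noisy.

## Pipeline, I/O, and problem sizes

The pipeline simulates and analyzes all five modalities under control and
perturbed conditions and emits a tidy table (stage, id, metric, value,
units, params_hash); the hash is over the resolved configuration and seed,
and runs are byte-reproducible given both. Configurations reject unknown
keys before execution. Interchange formats: delimited text or float32
binary + JSON sidecar for time series, TIFF + JSON sidecar for images
(pixel size mandatory, never guessed), CSV for tables.

Default problem sizes are desk-scale choices: 45 s recordings at 10 kHz
(≥ 5 bursts at 8/min; 50 kHz acquisition is a selectable preset), 300×300 px
dendrite images at 2 μm/px, 60 μm puncta fields at 0.1 μm/px, 30 s breath
traces at 1 kHz. Test suites that iterate over 20 seeds shorten recordings
to 35 s — the smallest window holding the five analyzed bursts.

## Known limitations

- No spike sorting: "unit activity" is population-level threshold crossing.
- Rhythmicity beyond burst frequency (cycle-to-cycle variability scores) is
  out of scope, as are bilateral cross-correlations.
- The apposition criterion is a geometric stand-in; absolute counts depend
  on the chosen radius and shell (both reported with the results).
- Plethysmographic pressure-to-volume calibration physics, apnea scoring,
  and sigh/gasp classification are out of scope.
- The generators share the analysis modules' geometric conventions (grid
  layout, mask run-length rules); ground-truth quantities are nevertheless
  computed by independent paths (supersampled analytic integration,
  enumeration) wherever a shared convention could hide a bug.
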