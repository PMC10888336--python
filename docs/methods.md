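# Methods

`gelfun` reimplements, as a tested pipeline, the mechano-functional
characterization of primary neuronal networks cultured inside PEGylated
fibrin hydrogels: bulk rheology of the gel reduced to a Young's modulus, and
calcium-imaging recordings reduced to spike rasters, effective connectivity
and network traits.  The original recordings and sweep tables are not
public, so a first-class synthetic-data module generates every input with
known ground truth; all quantitative claims in the test suite are
parameter-recovery statements about that generator, not about real data.

## 1. Functional pipeline

### 1.1 Imaging geometry and the synthetic recording

The emulated setup is wide-field single-plane fluorescence imaging of a
GCaMP6s-labelled 3D culture: a 7.1 × 7.1 mm² field at 5.9 μm/pixel, 8-bit,
recorded 15 min at 33 frames/s.  Analysis overlays a fixed grid of square
ROIs of 14 × 14 μm², up to 30 × 30 = 900 per field.  (These two printed
figures are mutually inconsistent — 900 ROIs of 14 μm would tile only
0.42 mm — so the grid is implemented as ≤ 30 × 30 ROI *centres* evenly
spaced across the field, each ROI `round(14/5.9) = 2` px square.)

The ground-truth network places ~100 neurons uniformly in a cylinder
(radius 3550 μm, height 800 μm) matching the imaged gel volume.  Directed
edges are drawn independently with probability proportional to
`affinity(c_i, c_j) · exp(−d_ij/λ)`, rescaled so the expected edge density
equals the requested value; communities are contiguous angular sectors, so
they are also spatially compact, as observed for soft-gel cultures.  80% of
neurons are excitatory.  Edge weights are gamma-distributed, shape 10 and
mean 1 (CV ≈ 0.32): coupling strengths surely vary in reality, but strong
dispersion mostly probes the weight distribution rather than the topology,
which is why the estimator-validation experiments (below) use unit weights.

**Spiking model.**  Real neurons were recorded, not modelled, so the
simulator is the minimal process whose only directed temporal structure is
the ground-truth edge set: a discrete-time stochastic cascade.  Per frame
of length dt, a non-refractory neuron fires with probability
`baseline_rate·dt + coupling_scale · Σ_presyn w·active(t − delay)`, clipped
to [0, 1].  Couplings are additive by default; a `signed_coupling` flag
makes inhibitory neurons subtract their weight instead (off by default —
at these firing rates inhibitory edges carry essentially no detectable
information, see §1.4).  The default transmission delay is two frames
(0.061 s), i.e. exactly one connectivity-analysis bin, so a cause lands in
the bin after its source.  Network-wide synchronous events (the sharp
population-activity peaks seen in soft gels) are a Poisson drive that
recruits a uniform random 60–90% of the population in one frame; this is
phenomenology, not a biophysical burst model.

**Calcium rendering.**  Each spike adds a difference-of-exponentials
transient (rise 0.2 s, decay 1.0 s — published GCaMP6s kinetics; both
overridable) with peak `amplitude_per_spike · F0` (defaults 0.8 ΔF/F,
F0 = 20 a.u.), evaluated at the exact spike time.  Gaussian camera noise
(default sd 0.5 a.u.) and a slow sinusoidal drift are added.  The paper
gives no noise or kinetics figures; these defaults are stated assumptions.
Optionally the traces are rendered into an 8-bit TIFF stack with one
Gaussian spot per neuron, or embedded directly into the 900-ROI trace
matrix (background ROIs carry baseline + noise only) — the latter is the
pipeline default since the pixel round trip is validated separately.

### 1.2 Trace processing

* **ΔF/F.**  The rest level F₀ is the 10th percentile of the raw trace
  (robust to transients).  Slow drift is removed by subtracting a running
  10th-percentile baseline over 30-s windows (evaluated on a coarse grid
  and interpolated), re-anchored at F₀; `ΔF/F = (F − baseline)/F₀`, and
  the transform is invertible given the stored baseline.  The corrector
  tracks drift slow relative to the 30-s window (e.g. thermal/focus drift
  over minutes); it is not intended for fluctuations of comparable period.
* **Schmitt trigger.**  Hysteretic two-threshold detection on ΔF/F: an
  event opens at the first sample above the high threshold and closes when
  the trace falls below the low one; no retriggering in between.  The
  thresholds are not printed in the source study; defaults are
  median + 4σ / + 2σ per trace with σ from the MAD.  A 5-frame (0.15 s)
  centred boxcar is applied before thresholding — well under the 0.2-s
  indicator rise time, so onsets are not distorted, while frame-noise
  crossing jitter drops by ~√5.  Events shorter than 7 frames (0.21 s)
  above the low threshold are discarded; a real transient dwells ~1.7 s
  above it, pure-noise excursions of the smoothed trace almost never reach
  0.21 s.  Any threshold detector on a 0.2-s-rise indicator fires a fixed
  ~0.2 s after the true spike; accuracy statements therefore refer to the
  jitter about that constant latency (±2 frames at SNR 5), not to the raw
  offset.
* **Activity filter.**  A ROI is kept when its peak ΔF/F reaches 0.1 *and*
  the detector finds ≥ 1 event; on the synthetic 900-ROI field with ~100
  embedded neurons this reduces the set to ≈ 100, as in the study.
* **Population activity.**  Fraction of neurons with ≥ 1 event in a 0.5-s
  window stepped by 0.1 s; the last full window starts at
  duration − window.  Synchronization peaks are local maxima above
  mean + 3σ of the series **and** above an absolute floor of 0.2: a
  synchronization event is collective by definition, and without the floor
  the shot noise of a sparse asynchronous culture generates dozens of
  spurious "peaks" while genuinely bursty recordings (whose σ is large)
  generate few — inverting every between-condition comparison.  Peaks
  closer than one window are merged.

### 1.3 Effective connectivity

Rasters are binarized into 2-frame bins (0.061 s; a bin is 1 if it holds
≥ 1 event).  For every ordered pair, transfer entropy

TE(X→Y) = Σ p(y_{t+1}, y_t^{(k)}, x_t^{(k)}) log₂ [ p(y_{t+1}|y_t^{(k)}, x_t^{(k)}) / p(y_{t+1}|y_t^{(k)}) ]

is estimated with a plug-in joint histogram over binary order-k histories
(default k = 2, source lag 1 bin, no same-bin term).  No bias correction is
applied: alphabets are binary, recordings long, and the z-normalization
absorbs the common bias.  Estimates are standardized against the pooled
distribution of all ordered-pair estimates of the same recording,

z(I→J) = (TE(I→J) − ⟨TE⟩_pairs) / σ_pairs,

and an edge requires z strictly greater than 2.  The pooled-pairs null is
the default reading of this normalization; a circular-shift surrogate
ensemble is available (`TEConfig.null="shuffle"`) but measured badly
miscalibrated on cascades — its σ is the estimator noise floor, so every
indirect correlation becomes significant (precision ≈ 0.2) — which is why
pooled-pairs is the default.  Optional burst conditioning
(`conditioning: exclude-burst-windows`) drops prediction bins inside
detected synchronization peaks, removing common-drive coincidences before
estimation; the pipeline enables it whenever peaks are found.

**Calibration caveat.**  With z > 2 on the pooled distribution the nominal
false-positive budget is ~5% and holds when each pair's histogram gathers
enough events for the pool to be approximately normal (measured 3.5% at 8
activations/min, 0.03-s bins, 15 min).  For very sparse trains
(~3 activations/min at 0.03-s bins) the plug-in estimate is dominated by
single chance coincidences, the pool becomes heavy-tailed, and the
false-positive rate roughly doubles; the pipeline's default 0.06-s bins
bring the same recordings back to ~3%.  Recordings much shorter than
15 min would need surrogate-based nulls.

**Validation regime.**  The estimator-recovery experiment uses cascade
networks with n = 30, density 0.1, unit weights, coupling 0.12 (one
presynaptic spike multiplies next-bin firing odds ≈ 7×), baseline 0.29 Hz,
refractory 0.12 s, 15 min.  Two of these choices matter and were fixed by
analysis of what limits pooled-z recall: the refractory period must not
exceed the k·bin history window (otherwise refractory and ready states mix
within one conditioning context and the measured TE of true edges is
diluted), and the cascade gain (coupling × mean in-degree) must stay well
below 1 (supercritical amplification spreads source rates over a decade,
and since TE scales with source activity the pooled σ inflates until
moderate true edges fall below z = 2).  In this regime mean precision is
≈ 1.0 and mean recall 0.74–0.80 over independent 10-seed sets.  At
culture-like rates (2–3 activations/min) a 15-min recording simply does
not contain enough coincidences per pair for comparable recall — a
limitation of the method at that recording length, not of the
implementation.

### 1.4 Inhibition

With signed coupling enabled, inhibitory-source edges suppress a target
baseline of ~0.01 per bin — an information difference far below the
pooled-z detection threshold (measured z ≈ −0.3 for every inhibitory edge).
TE on sparse binarized calcium rasters recovers excitatory structure;
claims of inhibitory-edge recovery would be hollow, so the default cascade
is purely additive and the recovery experiments treat the additive edge
set as truth.

### 1.5 Network traits

For the binarized directed adjacency A (diagonal zero):

* average connectivity ⟨k⟩ = L/N, each directed edge counted once;
* global efficiency GE = 1/(N(N−1)) Σ_{i≠j} 1/d_ij with d_ij the directed
  shortest hop count and 1/∞ = 0; GE is 1 for a complete digraph and 0 for
  an edgeless one;
* modularity Q = 1/(2m) Σ_ij (A_ij − k_i k_j/(2m)) δ(c_i, c_j) with
  k_i = Σ_j A_ij and m = ΣA/2, evaluated exactly as written on the
  directed matrix (a `symmetrize` flag first replaces A by its binarized
  symmetric part, the convention of some connectivity toolboxes — the
  source study does not say which it used, so both are provided);
* communities from the Louvain algorithm (networkx implementation,
  seeded; ties broken by the seed), with the reported Q always re-evaluated
  through the formula above on the returned partition.

GE and Q are authored here and checked against independent oracles
(Floyd–Warshall all-pairs paths; naive O(N²) double sum; exhaustive
partition enumeration for N ≤ 8) to 1e-12.

## 2. Rheology pipeline

Small-amplitude oscillatory shear, γ(t) = γ₀ sin(ωt), yields the storage
and loss moduli G′(ω), G″(ω).  Three standard tests at 37 °C: time sweep
(ω = 2π rad/s, γ₀ = 5%, 15 min), strain sweep (γ₀ = 0.1–100%, ω = 2π),
frequency sweep (ω = 0.6–600 rad/s, γ₀ = 5%).  The instrument cannot
resolve oscillation torques below 2 nN·m; rows under that floor are
discarded before any reduction.

* **Synthetic sweeps.**  G′ has a low-frequency plateau with
  `G′(ω) = G_p (1 + (ω/ω_c)^α)` (default ω_c = 50 rad/s, α = 2 — the
  source shows an abrupt thickening past ~50 rad/s but does not
  parameterize it); G″ = 0.1·G′ (the gels are strongly elastic); time
  sweeps relax exponentially from a 30% undershoot with the time constant
  chosen so the ±5% band is entered exactly at the nominal transient time;
  strain sweeps have a slight negative log-log slope (0.03).  Noise is
  multiplicative log-normal (geometric CV, default 5%), and the synthetic
  torque is proportional to |G*|·γ₀ so low-strain points genuinely fall
  below the floor.
* **Transient time t_T.**  Earliest time after which G′ stays within ±5%
  of the terminal plateau (mean of the last 25% of samples) for the rest
  of the record.  The trace is pre-smoothed with a centred rolling mean
  whose window adapts to the noise level estimated from second differences:
  noise-free records are left untouched (the crossing then matches the
  analytic value exactly), noisy ones get a window that brings residual
  noise inside the band.  Even so, the band-entry time of a slow
  exponential whose noise is comparable to the band width carries
  irreducible jitter (~10% at CV 5%); recovery statements are therefore
  about the 10-seed mean error.
* **Plateau moduli.**  Geometric mean of G′ (and G″) over ω ≤ 10 rad/s —
  moduli scatter multiplicatively, so the geometric mean pairs with the
  log-normal noise model.  Thickening onset is the first ω where G′
  exceeds the plateau by 50%.
* **Young's modulus.**  E = 2|G*|(1+ν) with |G*| = √(G′² + G″²) and
  ν = 0.25 for fibrin.  |G*| enters plateau-averaged (whether the source
  used a single frequency or an average is not stated).
* **Stages.**  Estimates are grouped by culture age: early DIV 1–3, young
  4–8, mature 13–20 (DIV 9–12 are flagged unassigned); pairwise two-sided
  equal-variance Student's t-tests (Welch behind a flag), stars at
  p < 0.05 and p < 0.01.

**Presets.**  `T1-like` (soft, fast-softening: plateau G′ 120 → 80 Pa,
t_T 150 s), `T2-like` (stiff, gradually decaying: 235 → 135 Pa, t_T 300 s)
and `T3-like` (flat 100 Pa) follow
`G′(DIV) = G_late + (G_early − G_late)·e^{−(DIV−1)/τ}`; through
E = 2.5·|G*| these reproduce the reported stage means (≈300→200,
≈590→340, ≈250 Pa).  The measurement schedule is DIV
{1,2,3,4,6,8,13,16,20} with 3 replicates, 5% measurement noise and 15%
log-normal sample-to-sample scatter (the replicate dispersion visible in
the study's stage boxplots).  A flat preset analysed repeatedly still
produces p < 0.05 in ~14% of draws (three correlated tests at α = 0.05),
so "no significant differences" is asserted on the median p across seeded
draws, while the decaying preset's early-vs-mature significance is
asserted per draw (≥ 90/100).

## 3. Functional presets and problem sizes

`T1-like` (soft gel): 100 neurons, edge density 0.10, synchronous drive
1/45 s⁻¹, baseline 1.2 min⁻¹, coupling 0.05 — measured ≈ 3.3
activations/min with 14–23 synchronization peaks per 15 min.  `T2-like`
(stiff gel): density 0.06, no drive, baseline 1.5 min⁻¹ — ≈ 2.5/min, no
peaks.  Both couplings are equal so inference quality is comparable and
the density contrast alone drives the ⟨k⟩ and GE orderings; baselines were
set by forward calculation of the cascade amplification so measured rates
land near the reported 2.9 vs 2.1 activations/min.  Full preset runs
(900-ROI embedding, filter, TE on ~95 neurons) take ~10 s each; ordering
comparisons use 10 seed-paired runs and are asserted on means.

## 4. Reproducibility

Every generator and every pipeline stage is a pure function of its
parameters and a seed; `run_functional`/`run_rheology` re-run with the same
config produce byte-identical artifacts.  All outputs are plain text (CSV,
JSON, GraphML/GEXF; TIFF only for rendered stacks) and every file carries a
`.meta.json` sidecar with the full configuration and sha256 checksums of
its inputs.

## 5. Known limitations

* The generator omits photobleaching, optical PSF/scattering, motion, and
  biophysical burst dynamics; passing recovery tests bound estimator
  behaviour under the stated noise model only.
* TE recovery figures apply to the validation firing regime; 15-min
  recordings at culture-like rates are too sparse for comparable recall.
* The pooled-z false-positive budget degrades for very sparse trains at
  fine bins (§1.3).
* Louvain on directed graphs optimizes the directed variant internally
  while Q is reported from the printed (undirected-form) formula applied
  to the directed matrix; on near-symmetric effective networks the
  difference is small, but the two conventions are not interchangeable in
  general.
* Inhibitory connectivity is not recoverable from these data (§1.4).
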