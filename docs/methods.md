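# Methods

This note documents the scientific model implemented by `seqrec`, the
default parameters, and the measurements behind the non-obvious choices.
Everything below is testable against planted ground truth because the
package generates its own data.

## Generative model

Sensor data follow the standard linear MEG observation model

```
B(t) = Σ_n l_n · q_n(t) + ξ(t)
```

- **Source grid.** A regular lattice inside an ellipsoidal "head" mask
  (default ±60 mm box, 14 mm spacing, ~300 voxels at pipeline scale;
  tests mostly use 20 mm / ~110 voxels).
- **Leadfield.** A synthetic stand-in for a single-shell forward model:
  channel `c`'s sensitivity to source `s` in orientation `o` is the
  `o`-th orientation basis component scaled by a Gaussian of
  source–sensor distance, `exp(−d²/2σ²)` with σ = 80 mm. It preserves
  the properties the inverse method relies on (linearity, smooth
  distance fall-off, three orientation columns per source) without
  claiming anatomical realism. Sensors: 32 magnetometers + 16 planar
  gradiometer pairs on a 110 mm Fibonacci sphere.
- **Planted effects.** A midline "memory" region carries a slow
  (0.1–1 Hz) envelope with amplitude M > N peaking mid-sequence; two
  bilateral "auditory" regions carry a fast (2–8 Hz) response per tone
  with amplitude N > M. Gaussian sensor noise, optional AR(1)
  coloring. Condition-mean waveforms and active voxel sets are returned
  as ground truth.
- **Per-region latency jitter** (default SD 20 ms). Without it the two
  auditory regions are driven by one identical waveform — coherence
  exactly 1.0 — and a minimum-variance beamformer cancels perfectly
  correlated sources, increasingly so at higher SNR. The jitter
  decorrelates the hemispheres the way physiological latency
  variability would. This was diagnosed by a unilateral control
  simulation (single auditory region: recovery p ≈ 0.002 in all
  windows; bilateral coherent: p ≈ 0.03 and worsening with trial
  count) and fixed in the generator rather than by retuning analysis
  thresholds.

Symbolic five-tone melodies are generated from first-order Markov
transition matrices; an n-gram model with add-k smoothing and
shortest-context fallback supplies per-event information content and
entropy.

## Preprocessing

- Notch at 50 Hz (IIR notch, forward–backward), polyphase downsampling
  to 150 Hz, zero-phase windowed-sinc FIR band-pass (Hamming, ~3.3/Δf
  taps; the slow band needs ≈ 9,900 taps and therefore ≥ 66 s of
  continuous data).
- Epoching uses a half-open `[start, end)` window: −0.1–3.5 s at
  150 Hz is exactly 540 samples. Per-trial baseline subtraction;
  trials extending past the recording are rejected with a logged
  warning.
- Planar gradiometer pairs are combined by root-sum-of-squares;
  magnetometers pass through.
- Morlet wavelet TFR (7 cycles) for spectral checks.

## Inverse solution

Unit-gain LCMV beamformer per band:

1. Channel-type balancing (per-role unit average variance) so
   magnetometers and gradiometers contribute comparably to the
   covariance.
2. Sensor covariance from epoched data with diagonal loading
   λ = 5% of the mean sensor variance; rank deficiency is warned
   about and handled by the loading.
3. Orientation reduction: per source, form `M = l C⁻¹ lᵀ` (3×3) and
   keep the eigenvector of the **smallest non-zero** eigenvalue —
   the output-power-maximizing orientation. Restricting to non-zero
   eigenvalues matters: for rank-deficient `M` (e.g. a source with
   sensitivity in one orientation only) the literal smallest
   eigenvector lies in the null space and yields a zero reduced
   leadfield.
4. Weights `W_n = (L_nᵀ C⁻¹ L_n)⁻¹ L_nᵀ C⁻¹` (unit gain:
   `W_n · L_n = 1`), applied per trial, then rectified (absolute
   value), since evoked polarity is not interpretable after
   orientation reduction.

## Group statistics

- **First level:** two-column condition-indicator GLM per subject; the
  COPEs equal condition trial means.
- **Second level:** one-sample t over subjects per voxel with
  spatially smoothed variance — the per-voxel sample variance is
  convolved with a 3D Gaussian (50 mm FWHM, row-normalized kernel)
  before `t = mean / sqrt(var_smooth / n)`. `fwhm=0` recovers the
  textbook t-test.
- **Tone windows:** contrasts are averaged in five 250 ms windows
  covering the sequence, and each window is tested separately; the
  cluster α is Bonferroni-corrected over the tone × band family
  (5 × 3 = 15 tests → α = 0.003 at pipeline defaults).
- **Cluster inference:** voxels with `p < 0.05` are binarized and
  grouped into sign-consistent connected components.
  - *Adjacency:* face (6-)connectivity on the lattice. With
    26-connectivity a uniformly scattered significance map percolates
    into giant chance clusters already at ~10% occupancy, destroying
    the contrast between compact real clusters and the permutation
    null on desk-scale grids.
  - *Null distribution:* the pipeline default permutes **subject
    signs** (sign-flip of the contrast COPEs, re-computing the map per
    flip) and records the maximal cluster statistic. An alternative
    scheme that shuffles the binarized map uniformly over voxels is
    provided (`mcs_scheme="map_shuffle"`) but is strongly
    anti-conservative on spatially correlated t-fields — and
    beamformed maps are always spatially correlated (leakage plus
    variance smoothing). Measured on pure-noise correlated fields
    (12 subjects, Gaussian spatial covariance, 20 replicates): the
    map-shuffle scheme flags a spurious cluster in 11/20 runs at
    nominal α = 0.05, the sign-flip scheme in 0/20. On full null
    pipeline simulations the sign-flip family-wise error rate is
    0.02–0.03. A regression test
    (`test_map_shuffle_anticonservative_on_correlated_nulls`) pins this
    behavior.
  - *Resolution:* a sign-flip null can resolve p no finer than
    ≈ 2/2ⁿ for n subjects (the all-same flips reproduce |t| exactly),
    and any permutation p is floored at 1/(1+n_perm). Small-cohort
    analyses must budget subjects and permutations against their
    corrected α.
  - Cluster p = (1 + #exceedances)/(1 + n_perm); size and mass
    statistics available.
- **Parcel × time contrasts:** two-sample t per parcel and timepoint
  (paired variant available), clustered with time-contiguity-within-
  parcel adjacency at α = 0.001.
- **Baseline robustness:** the slow-band contrast is re-run with 500,
  1,000 and 2,000 ms baselines and the significant-voxel sets compared
  by Jaccard overlap; with a noiseless planted effect the sets are
  identical (Jaccard 1.0).

## Parcellation

Two-stage k-means on the group-mean rectified source activity:

1. **Functional stage** on one scalar feature per voxel — peak latency
   index for the slow band (activity shifts across regions over the
   sequence), peak amplitude for the fast band — z-scored, k swept
   2–20 with 50 k-means++ restarts.
2. **Spatial stage** re-clusters each functional parcel's member
   coordinates (k 2–10) so that spatially separated regions sharing a
   functional profile become distinct parcels.

Model selection (`choose_k`) offers three heuristics: `elbow`
(maximal second difference of the SSE curve), `silhouette` (argmax
mean silhouette), and `combined` (silhouette argmax within ±1 of the
elbow). The orchestration defaults to **silhouette** for both stages:
the raw-SSE second difference is systematically biased toward small k
on multi-cluster 1D features (SSE(k) ≈ C/k² is convex everywhere), and
measured on five well-separated planted latency populations the
combined rule picks k = 4 while the silhouette peak at the true k = 5
is unambiguous (0.915 vs 0.744).

A spatial split is accepted only if its best silhouette exceeds a floor
of **0.6**. This is a measured boundary: k-means on spatially
unstructured parcels (compact Gaussian blobs or uniform boxes of a few
dozen voxels) reaches silhouettes of 0.25–0.50 by chance alone, while
genuinely separated sub-regions (two blobs 60 mm apart) score ≥ 0.87;
0.6 also matches the Kaufman–Rousseeuw "reasonable structure"
threshold. Singleton parcels pass through unsplit. Parcel timeseries
are the mean over member voxels, per subject and condition.

## Reproducibility

All randomness derives from one master seed through
`numpy.random.default_rng` with stage-specific spawn keys. `RunConfig`
round-trips through YAML and hashes to SHA-256; the run manifest
records the hash, per-stage timings, artifact checksums and the
adjacency/permutation-scheme choices. Re-running with the same
configuration reproduces cluster reports exactly.

## Desk-scale problem sizes

The defaults are sized so the full pipeline (3 bands, 20 subjects,
80 trials, ~300 voxels, 1,000 permutations) completes in minutes on one
CPU, and the acceptance suite's replicate-based tests (200 null
replicates; 20 direction-recovery replicates) complete within a test
budget of ~10 minutes. These scales are deliberate stand-ins for a
full MEG analysis; none of the planted amplitudes, noise levels or
thresholds were tuned against test outcomes — generator fixes were
made only for identified physical artifacts (see latency jitter above)
with detection thresholds untouched.
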