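# seqrec

MEG evoked-response analysis of **memorized versus novel auditory
sequences**, built end-to-end on synthetic data with known ground truth:
forward simulation, band-specific unit-gain beamforming, cluster-based
Monte-Carlo statistics, and two-stage k-means functional parcellation.

## The problem

A listener hears five-tone sequences that are either previously
memorized (`M`) or novel (`N`). MEG sensor recordings `B(t)` are modeled
as a linear mixture of dipolar brain sources plus noise,

```
B(t) = Σ_n  l_n · q_n(t) + ξ(t)
```

where `l_n` is the leadfield of source `n` (its projection to every
sensor for each of three dipole orientations) and `q_n(t)` its moment.
The analysis asks *where* and *in which frequency band* the two
conditions differ:

1. **Preprocess** — notch filter, downsample, band-pass into slow
   (0.1–1 Hz), fast (2–8 Hz) and alpha (8–12 Hz) bands, epoch around
   sequence onset, baseline-correct.
2. **Beamform** — an LCMV unit-gain spatial filter per voxel,
   `W_n = (L_nᵀ C⁻¹ L_n)⁻¹ L_nᵀ C⁻¹`, after reducing the three dipole
   orientations to the power-maximizing one; source timeseries are
   rectified.
3. **First level** — a two-column indicator GLM per subject gives
   condition effects (COPEs) per voxel and timepoint.
4. **Group level** — a one-sample t-test over subjects with spatially
   smoothed variance (50 mm FWHM), averaged within five 250 ms tone
   windows, followed by a cluster-based Monte-Carlo correction
   (subject sign-flip permutations, Bonferroni α over the
   tone × band family).
5. **Parcellation** — two-stage k-means: cluster voxels on a functional
   feature (peak latency for the slow band, peak amplitude for the fast
   band), then sub-cluster each functional parcel on its 3D coordinates;
   parcel timeseries are contrasted over time with a 2D cluster
   correction.

Because the input is simulated, every stage can be checked against the
planted truth: a "memory network" region carries a slow M > N effect
and two bilateral "auditory" regions carry a fast N > M effect.

## Worked example

A reduced cohort (12 subjects, 12 trials per condition, ~110-voxel
grid) runs in under a minute:

```python
import numpy as np
from seqrec import RunConfig, run_pipeline

cfg = RunConfig(
    grid_spacing=20.0,                 # ~110-voxel grid for a quick demo
    n_subjects=12, n_trials_per_condition=12,
    bands=(("slow", 0.1, 1.0), ("fast", 2.0, 8.0)),
    n_perm=500, seed=3000,
)
res = run_pipeline(cfg, out_dir="demo_out")

for band, br in res.bands.items():
    for w, rep in enumerate(br.tone_reports):
        for c in rep.significant:
            print(f"{band:5s} tone {w + 1}: {c.size:3d} voxels, "
                  f"mean t = {c.mean_t:+.2f}, p = {c.p:.4f}")
    if br.parcels is not None:
        print(f"{band:5s} parcellation: {br.parcels.n_parcels} parcels "
              f"(functional k = {br.parcels.provenance['functional_k']})")
```

Output:

```
slow  tone 1:  16 voxels, mean t = -2.86, p = 0.0040
slow  tone 3:  35 voxels, mean t = +5.93, p = 0.0020
slow  parcellation: 3 parcels (functional k = 3)
fast  tone 1:  86 voxels, mean t = -4.60, p = 0.0020
fast  tone 2:  84 voxels, mean t = -4.68, p = 0.0020
fast  tone 3: 105 voxels, mean t = -4.36, p = 0.0020
fast  tone 4:  82 voxels, mean t = -4.28, p = 0.0020
fast  parcellation: 2 parcels (functional k = 2)
```

The planted asymmetry is recovered: the slow band shows a strong
positive (M > N) cluster peaking mid-sequence over the memory region,
while the fast band shows sustained negative (N > M) clusters over the
auditory regions. `demo_out/` receives the run configuration, cluster
reports (JSON/TSV), t-maps and parcel labels as NIfTI volumes, a parcel
timeseries figure, and a manifest with config hash and checksums.

### Stimulus information profiles

The package also scores symbolic sequences with an n-gram model —
information content `IC = log2(1/p)` of each event and Shannon entropy
`H` of the distribution it was drawn from:

```python
import numpy as np
from seqrec import simulate_melodies, fit_ngram, profile_melody

T = np.array([[0.7, 0.2, 0.1],
              [0.1, 0.7, 0.2],
              [0.2, 0.1, 0.7]])
train = simulate_melodies(3, length=20, transition_matrix=T, n=100, seed=0)
model = fit_ngram(train, order=1, smoothing=1.0)

prof = profile_melody(model, [0, 0, 1, 1, 2])
for i, (ic, h) in enumerate(zip(prof.ic, prof.entropy)):
    print(f"event {i}: IC = {ic:.3f} bits, H = {h:.3f} bits")
```

Output:

```
event 0: IC = 1.589 bits, H = 1.584 bits
event 1: IC = 0.587 bits, H = 1.211 bits
event 2: IC = 2.081 bits, H = 1.211 bits
event 3: IC = 0.545 bits, H = 1.193 bits
event 4: IC = 2.294 bits, H = 1.193 bits
```

Repetitions (events 1 and 3) are cheap under the self-transition-heavy
model; switches (events 2 and 4) are surprising.

## Command line

```bash
seqrec run            --seed 0 --out out/            # full pipeline
seqrec simulate       --seed 0 --out sim/            # write datasets to HDF5
seqrec preprocess     sim/subject00.h5 --band fast   # filter + epoch
seqrec parcellate     src.h5 forward.h5 --band slow  # two-stage k-means
seqrec baseline-check --baselines 500 1000 2000      # robustness report
seqrec stimulus-info  melodies.txt                   # per-tone IC/entropy
```

## Reproducing results

Every run is driven by one `RunConfig` (YAML round-trip, SHA-256 config
hash) and a single master seed; re-running with the same seed reproduces
cluster reports bit-for-bit. The pinned analytic acceptance value
(entropy of a degenerate next-event distribution = 0 bits) is recomputed
from scratch by:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the scientific methods, default parameters and
the calibration measurements behind the non-obvious choices.
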