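# difftrack

Single-particle-tracking analysis of membrane-receptor mobility and
cortical actin flow. `difftrack` classifies short trajectory segments into
discrete diffusive states by perturbation-expectation-maximization (pEM)
with BIC model selection, estimates diffusivities with the covariance-based
estimator (CVE) that is unbiased under localization noise and motion blur,
measures the spatial pair correlation g(r) of state-sorted molecules inside
a cell mask, and maps cortical flow with spatio-temporal image correlation
spectroscopy (STICS) plus a directional-coherence statistic. A first-class
synthetic-data module generates trajectories, single-molecule movies and
advected speckle movies with known ground truth, so every stage is testable
without raw imaging data.

**Who it is for:** quantitative cell biologists and biophysicists analysing
single-molecule TIRF/iSIM time-lapse data of membrane receptors (e.g. the
B-cell receptor imaged in 1000-frame bursts at 33 Hz) and cytoskeletal flow
movies — or anyone who needs a tested, seeded reference implementation of
CVE, pEM, Monte-Carlo-normalized g(r) or STICS.

## The core models

**CVE.** For a trajectory with frame interval Δt, blur coefficient
R (= 1/6 for full-frame exposure) and per-axis displacements dₙ:

    D̂  = ⟨dₙ²⟩/(2Δt) + ⟨dₙdₙ₊₁⟩/Δt
    σ̂² = R⟨dₙ²⟩ + (2R−1)⟨dₙdₙ₊₁⟩

No regression, unbiased under static noise σ and blur; negative estimates
are retained by design.

**pEM.** Trajectories of 15–105 frames are cut into 15-frame segments;
each segment's 14 displacements per axis are zero-mean Gaussian with
tridiagonal covariance `a = 2DΔt − 4RDΔt + 2σ²`, `b = 2RDΔt − σ²`.
A K-state mixture is fitted by EM with random reinitializations and
parameter perturbations to escape local maxima; the state count minimizes
`BIC(K) = −2·loglik + (3K−1)·ln N`. Segments get maximum-posterior labels,
states are numbered slowest → fastest, population fractions carry Wilson
95% intervals, and state transitions are counted between consecutive
segments of tracks longer than 30 frames.

**g(r).** Pair correlation of each particle's first position, normalized
by a ≥20× denser uniform reference drawn in the same mask (Monte-Carlo edge
correction); g = 1 is complete spatial randomness, g > 1 at short r means
clustering.

**STICS.** 8×8-pixel subregions, 5-frame time-of-interest windows, a
20-frame immobile filter; the velocity is the slope of the correlation-peak
displacement versus time lag. Directional coherence is the cosine between
a flow vector and the direction to the cell centroid (+1 inward, −1
outward); inward/outward fractions are compared with a two-proportion
z-test.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

Simulate three diffusive states spanning two decades (0.003, 0.03,
0.3 μm²/s with 20/40/80 nm localization noise, 33 Hz, R = 1/6) and recover
them:

```python
import numpy as np
import difftrack as dtk
from difftrack import pem

cfg = dtk.SimConfig(
    state_diffusivities=[0.003, 0.03, 0.3],   # um^2/s
    state_loc_sigma=[0.02, 0.04, 0.08],       # um
    initial_fractions=[1/3, 1/3, 1/3],
    track_length_law=("fixed", 15),
    n_tracks=1800, frames_per_burst=15,
    mask=dtk.DiskMask(50.0), seed=0,
)
tracks = dtk.simulate_trackset(cfg)
segments = dtk.filter_and_segment(tracks)
rec = dtk.cve_estimate_segments(segments, cfg.frame_interval, cfg.blur_R)
print(f"segments: {segments.segment_id.nunique()}, "
      f"mean CVE D = {rec.D_hat.mean():.4f} um^2/s")

ids, dx, dy = dtk.segment_displacements(segments)
models, best_K = pem.pem_search(dx, dy, cfg.frame_interval, cfg.blur_R,
                                K_max=5, n_reinit=6, n_perturb=20, seed=1)
best = models[best_K]
print(f"BIC selects K = {best_K}")
for k in range(best.K):
    print(f"  state {k+1}: D = {best.D[k]:.4f} um^2/s, "
          f"sigma = {1e3*np.sqrt(best.sigma2[k]):.0f} nm, "
          f"pi = {best.pi[k]:.3f}")
```

Output:

```
segments: 1800, mean CVE D = 0.1166 um^2/s
BIC selects K = 3
  state 1: D = 0.0031 um^2/s, sigma = 20 nm, pi = 0.324
  state 2: D = 0.0306 um^2/s, sigma = 40 nm, pi = 0.329
  state 3: D = 0.3043 um^2/s, sigma = 78 nm, pi = 0.347
```

The mean CVE D (0.117 μm²/s) is the population average over all three
states; pEM resolves the mixture, recovering each state's diffusivity
within a few percent, the per-state localization noise (20/40/78 nm vs the
true 20/40/80 nm — noise grows with mobility, as pEM estimates it should),
and the equal thirds occupancy.

## Command line

Each stage is also a subcommand of the `difftrack` CLI:

```bash
difftrack simulate --n-tracks 100 --seed 1 --out tracks.csv
difftrack track --stack movie.tif --mask mask.tif --threshold 50 --maxdisp 0.5 --out tracks.csv
difftrack segment --tracks tracks.csv --out segments.csv
difftrack diffusivity --segments segments.csv --dt 0.0303 --out cve.csv
difftrack classify --segments segments.csv --kmax 15 --reinit 20 --perturb 150 --seed 1 --out model.json
difftrack gr --segments segments.csv --labels labels.csv --out gr.csv
difftrack stics --stack actin.tif --sub 8 --subshift 2 --toi 5 --toishift 3 --immobile 20 --out velocity.csv
difftrack report --config pipeline.yaml   # full pipeline, byte-reproducible bundle
```

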