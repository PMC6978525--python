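# Methods

`difftrack` analyses single-particle trajectories of membrane receptors
(e.g. the B-cell antigen receptor imaged at 33 Hz in TIRF) and the cortical
flow of the underlying actin network. This note records the models, the
estimators, the numerical choices, and what the synthetic-data generator
does and does not emulate.

## Motion and observation model

A molecule in diffusive state *k* performs 2-D Brownian motion with
diffusion coefficient `D_k` (um^2/s). The camera reports, once per frame
interval `dt` (default 1/33 s), the average position over the exposure
window plus isotropic Gaussian localization noise of standard deviation
`sigma_k` (static error, 20-80 nm). For uniform exposure over a fraction
`f` of the frame interval the motion-blur coefficient is `R = f/6`
(R = 1/6 for a fully open shutter). Under this model the per-axis
displacement sequence `d_n` of a segment is zero-mean Gaussian with a
symmetric tridiagonal Toeplitz covariance

    a = Var(d_n)        = 2 D dt - 4 R D dt + 2 sigma^2
    b = Cov(d_n, d_n+1) = 2 R D dt - sigma^2

and the two-dimensional ensemble MSD is
`MSD(n) = 4 D n dt + 4 sigma^2 - 8 R D dt`.

## Covariance-based estimator (CVE)

Per axis, `D_hat = <d^2>/(2 dt) + <d_n d_{n+1}>/dt` and
`sigma2_hat = R <d^2> + (2R - 1) <d_n d_{n+1}>`; x and y are averaged.
The estimator is unbiased under noise and blur precisely because negative
estimates are retained — they are never clipped, and they appear in all
distributions and CDFs. An MSD-regression fit is kept in the test suite as
an independent oracle on ensembles, never as the primary estimator.

## Track filtering and segmentation

Linked trajectories shorter than 15 frames are discarded (too little
information), and longer than 105 frames as well: slow molecules cross
paths less often, survive linking longer, and would otherwise be
over-counted. Survivors are cut into consecutive non-overlapping 15-frame
segments (a trailing remainder is dropped); the segment is the unit of
classification, short enough that most segments sit in one state.

Linking itself is greedy mutual-nearest-neighbour within a search radius,
with no gap closing. Any ambiguity — two detections in range of one track
end or vice versa — terminates all tracks involved and starts new ones, so
close encounters interrupt trajectories instead of risking identity swaps.
The ambiguity radius equals the search radius; a sensible default for the
radius is `3 sqrt(4 D_max dt)` for the fastest expected state.

## pEM: mixture of diffusive states

Segments are modelled as a K-component mixture; component k has the
covariance above with parameters `(D_k, sigma2_k)` and weight `pi_k`, with
x and y treated as independent, identically distributed axes (isotropy).
EM alternates:

* E-step: posteriors `gamma_ik ∝ pi_k exp(loglik_ik)` via log-sum-exp.
* M-step: `pi_k = mean(gamma_k)`; `(D_k, sigma2_k)` from the
  gamma-weighted moments of `(a, b)` inverted through the two formulas
  above, projected to `D >= 0, sigma2 >= 0`. The moment update is accepted
  only if it increases the expected complete-data log-likelihood Q;
  otherwise a short Nelder-Mead refinement in log-parameters runs, and if
  that fails too the previous parameters are kept. This "generalized EM"
  guard makes the total log-likelihood provably non-decreasing at every
  iteration — a property the test suite asserts on every run.

States whose expected occupancy falls below one segment are dropped
(K reduced, flagged). Convergence: `|delta loglik| < tol` (default 1e-3)
or 150 iterations.

Local maxima are escaped in two ways: `n_reinit` random restarts (D drawn
log-uniformly over the 5th-95th percentile range of naive per-segment CVE
values) and `n_perturb` perturbations of the best fit (log-normal jitter of
scale 0.5 on `D_k` and `sigma2_k`, Dirichlet jitter of `pi`), each polished
by a short EM run. For each K the search also warm-starts from the best
(K-1)-state model with its heaviest state split, which in practice makes
`loglik(K+1) >= loglik(K)` hold at the reported optima.

The number of states minimizes `BIC(K) = -2 loglik + (3K - 1) ln N`
(K diffusivities, K noise variances, K-1 free weights; ties go to the
smaller K). Protocol defaults follow the acquisition this package targets:
`K_max = 15`, 20 reinitializations, 150 perturbations, 14 covariance
parameters per segment. The bundled acceptance checks run a reduced search
(`K_max = 5`, 6 reinitializations, 20 perturbations, 10 seeded repeats) —
sizes chosen so the whole recovery experiment runs in minutes on one core
while still selecting the true K in >= 9/10 runs.

Hard assignment is by maximum posterior; states are renumbered ascending in
D (state 1 = slowest). Population fractions per burst ("minute") carry
Wilson 95% intervals — Wilson rather than Wald because per-state counts can
be small and near the 0/1 boundary. Transitions between consecutive
segments of one parent track are tallied only for tracks longer than 30
frames (at least two segments plus context), then row-normalized.

## Pair correlation g(r)

To avoid over-weighting slow molecules (which contribute many segments),
only the first position of each distinct particle enters, labeled by the
majority state over its segments (ties toward the slower state). States
are pooled in diffusivity-adjacent pairs ({1,2}, {3,4}, ...; an odd K
leaves the last state alone). The estimator is the pair-count ratio

    g(r) = [DD(r) / (n(n-1)/2)] / [RR(r) / (m(m-1)/2)]

where RR comes from `ref_factor >= 20` times as many uniform points drawn
inside the same mask — Monte-Carlo edge correction that cancels arbitrary
contour geometry, instead of an analytic isotropic correction that assumes
a convex window. Bins are closed on the right (`lo < d <= hi`), 50 nm wide
to 5 um by default; bins with zero reference pairs are flagged invalid.
Data pair counts are exact (KD-tree), so they reproduce an O(N^2)
enumeration bit-for-bit.

## STICS velocimetry

Static structure is removed first by the immobile filter: subtraction of
each pixel's 20-frame moving average (a Fourier DC-removal variant is
available). Then, per 8x8-pixel subregion (stride 2) and 5-frame TOI
window (stride 3):

1. The 8x8 template is cross-correlated against a larger search window
   (margin = sub/2 + 2 pixels) of the frame `tau` later, for
   `tau = 1..toi-1`. Every shift in the search range then has full
   template overlap, so the correlation needs no overlap normalization and
   has no window-induced bias toward zero shift.
2. Planes are averaged over a template set common to all `tau`
   (templates `t in [0, toi - max_tau)`, searches `t + tau`). A small
   window over a random texture mis-places the correlation peak by a
   window-specific offset; using the same templates for every `tau` makes
   that offset constant in `tau`, where the intercept of the
   displacement-versus-`tau` line absorbs it. This one choice reduced
   per-vector speed errors from ~18% to ~4% on synthetic uniform flows.
3. The peak of each plane is localized to sub-pixel precision by a
   least-squares 2-D Gaussian fit on the 5x5 neighbourhood of the discrete
   maximum (batched damped Gauss-Newton; a 3-point log-Gaussian
   interpolation was evaluated and rejected — 2-4x worse scatter for the
   broad peaks arising here).
4. Velocity is the least-squares slope of peak displacement versus `tau`,
   converted to um/min.

Quality control, in the spirit of discarding vectors that "exceed the
subregion threshold": a vector is invalid when the discrete maximum sits at
the subregion half-size boundary, the Gaussian fit fails or lands > 1.5 px
from the maximum, the peak amplitude is below 2x the MAD of its plane, or
fewer than two lags survive. Invalid vectors carry no speed.

Directional coherence of a valid vector is the cosine of the angle between
it and the direction from its position to the cell centroid: +1 inward,
-1 outward. Summaries are the inward fraction (c > 0.9), outward fraction
(c < -0.9), and PDF-normalized histograms; two conditions are compared with
a pooled two-proportion z-test (two-sided; degenerate pooled proportions
return p = 1 with a flag). Early/late activation windows are burst-index
partitions of the input stacks.

## Synthetic-data generator

`simulate_trackset` emulates the acquisition the analysis assumes: bursts
of 1000 frames at 33 Hz per minute-indexed time point, ~100 tracks per
burst with geometric track lengths of mean 40 frames, per-frame Markov
switching between K states spanning orders of magnitude in D, per-state
localization noise (20-80 nm), and motion blur as the average of 10
equally spaced sub-frame positions across the exposure window (the
discrete average converges to the continuous R = f/6; with 10 samples the
residual mismatch is ~1%, visible only in sigma2_hat at the percent
level). Trajectories reflect at the mask edge (TIRF footprints keep
molecules in view); particles born in a designated "cluster" state are
confined to small disks scattered in the mask, which produces g(r) > 1 at
short range for the slow states. An optional block-wise switching mode
(`switch_every`) steps the Markov chain only every m frames so that
per-segment transition probabilities are exact ground truth for the
transition analysis.

`render_spot_movie` renders localizations as integrated 2-D Gaussians
(erf differences over pixels, support 6 sigma) with optional Poisson shot
noise and Gaussian read noise. `simulate_flow_stack` advects a frozen
Gaussian-filtered speckle texture (grain sigma 0.1 um by default, the iSIM
resolution scale) by a uniform or radial field — uniform fields are sampled
exactly from the base texture with periodic boundaries, radial fields by
per-frame semi-Lagrangian warping — and returns the true field alongside.

What the generator does **not** model: photophysics (blinking/bleaching
beyond the track-length law), anomalous diffusion, 3-D motion, spatially
varying backgrounds, actin turnover in flow movies, or detection artefacts
of real cameras. Passing tests therefore demonstrate correctness of the
estimators under the stated model, not robustness to every property of
real movies.

## Numerical choices and degenerate inputs

* Covariance positive-definiteness is checked by Cholesky; non-PD
  parameter combinations score -inf and are avoided by the projected
  M-step (`D >= 1e-9`, `sigma2 >= 0`).
* Kruskal-Wallis condition comparisons run on seeded random subsets
  (default 200 per group, the median p over 25 draws reported with the
  spread) because at full SPT sample sizes any difference is
  "significant". Each draw re-seeds an identical RNG per group, so
  comparing a group with itself yields all ties and p = 1 exactly.
* All-tied Kruskal draws, zero-length flow vectors, empty bursts, empty
  transition rows, saturated/flat frames, and zero-variance proportions
  are handled explicitly (warning + defined output, never an exception).
* Determinism: every stochastic routine takes a seed or Generator; the
  pipeline derives all stage seeds from one config seed and writes
  sorted-key JSON and fixed-format CSVs, so a rerun of the same config is
  byte-identical. Every output file carries the SHA-256 hash of the
  canonical config.

## Known limitations

* The EM likelihood treats a segment as belonging to one state; within-
  segment switching (an HMM) is out of scope by design and blurs recovered
  parameters when switching is fast relative to 15 frames.
* CVE variance is large for single segments (sd comparable to D itself);
  inference relies on ensembles, as intended.
* The crossing-interruption linker is deliberately conservative in dense
  fields: it fragments tracks rather than arbitrating ambiguity, biasing
  track length down as density rises.
* STICS assumes locally uniform flow within an 8x8 px window and 5-frame
  TOI; strong shear or speeds beyond half the subregion per TOI alias.
* The radial flow generator accumulates interpolation smoothing over
  frames (semi-Lagrangian warping), slightly damping texture contrast at
  late times; direction recovery is unaffected.
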