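# Methods

This note records the model as implemented, the numerical choices behind
it, what the synthetic generators do and do not emulate, and the known
limitations.  Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`.

## Model

The state x ∈ ℝᵐ follows the gradient system dx/dt = -∇V(x, t).  The
landscape is driven by the stimulus stream η(t) and relaxes elastically:

    ∂U/∂t = -g(x - η(t)) - k U,        V(x, t) = U(x, t) / t,
    ∂V/∂t = -(1/t)(V + g(x - η(t))) - k V,

with the dent kernel, per coordinate,

    g(z) = (2π σ_z²)^(-1/2) exp(-z² / σ_z²).

Two conventions deserve emphasis:

* **The kernel's exponent has no factor ½.**  It is a Gaussian *shape*
  with peak (2πσ_z²)^(-1/2), integral 1/√2 and standard deviation
  σ_z/√2 — not a unit-mass density.  Nothing downstream needs a unit
  integral: the asymptotic landscape is -(g ∗ p), which carries the same
  normalization, and minima locations are unaffected.  (Verified against
  quadrature in `tests/test_kernel.py`.)
* **The m-dimensional kernel is the product of 1-D kernels**, one per
  coordinate, all with the same σ_z.  A joint normalizer would only
  rescale depths uniformly.

With k = 0 and a stationary ergodic stimulus of density p, the time
average of -g(x - η(t)) converges to -(g ∗ p)(x), so V converges to the
negative kernel-smoothed stimulus density: each density mode becomes a
point attractor (a memory prototype) and its basin a category.  With
k > 0 the balance between imprinting and elastic relaxation bounds the
landscape and forgets stale structure; after stimulation ceases the
homogeneous equation gives the exact decay V(t) = V(t₁)(t₁/t)e^{-k(t-t₁)}.

## Integrators

Stimuli are piecewise-constant over each sampling interval dt ("drops"
at discrete times).  This makes the U-equation exactly solvable per
interval by the integrating factor:

    U ← U e^{-k dt} - g(x - η)(1 - e^{-k dt})/k     (k > 0; U - g dt at k = 0).

The same exact update has a **mesh-free** representation
V(x) = -(1/t) Σᵢ wᵢ g(x - ηᵢ): absorbing one sample multiplies existing
weights by e^{-k dt} and appends the interval weight.  Grid and
mesh-free routes compute the same sum and agree to ~1e-13; this
equivalence is an acceptance check.  Weights decayed below 1e-12 of the
maximum are pruned (at k = 0 nothing is ever pruned).

The V-form PDE is integrated by explicit Euler with the 1/t factor at
the left endpoint.  The 1/t singularity is removed by starting at
t₀ = dt with V = -g(x - η(first)), which is the exact U/t value after one
interval at k = 0.  The Euler route is first-order: its sup-norm gap to
the exact route halves when the substep halves (asserted in the tests).
It exists to represent the continuous-time PDE faithfully; quantitative
experiments use the exact route.

Grids support m = 1 and 2 (memory grows exponentially in m); the domain
is the observed stimulus range padded by 4σ_z per side, with ~8 nodes
per kernel width, and the kernel is always evaluated analytically (never
truncated at the boundary).  The 4-D phrase landscape uses the mesh-free
form only.

## Descent, recognition, minima discovery

Descent is explicit Euler x ← x - ∇V·step with a backtracking safeguard
(halve the step whenever V would increase; double it after an accepted
move) and a displacement cap of σ_z/2 per iteration so a trajectory
cannot tunnel across a dent.  V is therefore non-increasing along every
trajectory by construction.  Termination: gradient norm below an
essentially-zero tolerance, displacement below 1e-9 σ_z, or stagnation
(a backtracked move that lowers V by less than 1e-12 relative) — the
last two mean "minimum at numerical resolution".  Grid landscapes are
evaluated through cubic splines (1-D: `CubicSpline`, 2-D:
`RectBivariateSpline`) so minima are resolved below the node spacing.

The geometric step growth matters: far from all dents the gradient is
exponentially small, and a fixed-step integrator would stall on the flat
foam.  With doubling, a start anywhere in the domain reaches a dent in
logarithmically many iterations; starts where the gradient underflows to
an outright floating-point zero stop immediately at depth ≈ 0 and are
removed by the depth filter below.

`find_minima` descends from `n_starts` seeded uniform draws over the
domain (or from user-supplied starts), merges converged endpoints by
single-linkage clustering at `merge_radius` (default σ_z/2 — dents
closer than σ_z fuse into one minimum anyway), and reports cluster
centroids with depths and basin counts, deepest first.  Two filters
reject non-memories:

* clusters shallower than `depth_frac` (default 1%) of the deepest —
  flat-plateau endpoints;
* optionally, clusters shallower than an absolute `min_depth`.  The
  phrase pipeline sets `min_depth = 2.5 g(0)/n`: a single absorbed
  sample presses a dent of depth exactly g(0)/n, so this keeps only
  memories imprinted by more than a couple of stimulus events and
  rejects micro-dents pressed by lone jitter outliers.

In high dimension uniform starts almost surely land on flat foam (the
dents fill a vanishing volume fraction), so the phrase pipeline draws
its restarts from the embedded stimulus samples themselves — the
stimulus stream is by construction dense in the dented region.

Recognition implements the reset protocol: set x to the incoming
stimulus, descend the frozen landscape, return the catalogued minimum
reached (or "unknown").  Recognition never modifies the landscape; in
the online loop (`run_online`) learning is the absorption that every
sample performs anyway, and recognition passes are read-only.  The
phrase-reconstruction step matches endpoints at 6σ_z: the radius must
cover performer jitter including outliers that settle in a filtered
micro-dent, and stays far below half the minimal category separation
(G4→A4 is 48 Hz ≈ 21σ_z), so no ambiguity is possible.

## Synthetic stimuli

* **i.i.d. bimodal** — η = A tanh(β(ξ - μ)) + c(ξ - μ), ξ ~ N(0,1),
  defaults A = 1.5, β = 2, c = 0.1, μ = 0.3.  Strictly monotone, so the
  density follows in closed form by change of variables: two peaks near
  ±1.6 with masses 0.635/0.365.  This is the quantitative oracle for the
  ergodic-limit tests.
* **Correlated double-well** — overdamped Langevin motion
  dx = -W'(x)dt + √(2D)dW in W = a₄x⁴/4 - a₂x²/2 + εx, Euler–Maruyama
  with step h.  Defaults a₄ = 1, a₂ = 2.56, ε = 0.2, D = 0.8, h = 0.02
  put the wells at ±1.6 (matching the i.i.d. modes), make the left well
  heavier (0.67/0.33), give lag-1 autocorrelation ≈ 0.99, and keep the
  discretization bias of the sampled stationary density e^{-W/D}/Z
  below ~1% (KS ≈ 0.01 at 10⁶ samples).  One stimulus is emitted per
  integration step.
* **Melody** — 6 repetitions of a 32-beat three-note arrangement of
  "Mary had a little lamb" (held notes expanded to beats; B×15, A×11,
  G×6), beat 0.75 s, equal-temperament tuning G4 = 392, A4 = 440,
  B4 = 493.88 Hz, emitted at 8 Hz with i.i.d. Gaussian pitch jitter of
  2 Hz per sample standing in for performer intonation and measurement
  noise.  1152 samples total.

What the generators do **not** emulate: the exact nonlinear transform
and SDE coefficients behind the original simulated stimuli are not
published, so the first two generators are declared substitutes that
reproduce the described qualitative structure (two modes of unequal
mass; correlated vs uncorrelated), and the quantitative checks target
the convergence law V → -(g ∗ p) rather than any specific density.  The
melody generator has no note-onset transients, vibrato, harmonics or
silence; the jitter is white.  A green synthetic test therefore
establishes the mechanism (note/phrase discovery, ranking, recognition)
at realistic jitter levels, not robustness to real recording artifacts.

## Audio front-end

Pitch is tracked as the highest spectral peak of a sliding 0.75 s
window (matched to the beat), Hann-windowed by default (a rectangular
option exists), hop 0.125 s so the track comes out directly at 8 Hz;
the peak is refined by parabolic interpolation of log-magnitudes over
the three bins around the maximum (sub-bin accuracy ≪ 1 Hz on pure
tones against the 1.33 Hz bin width).  The search is restricted to
80–2000 Hz to reject DC and noise-floor artifacts.  Silent windows
yield a missing value and are dropped, not interpolated.  Phrases are
coded by sliding delay embedding η(t) = (f(t), f(t+τ), …) at the track
rate; a beat-aligned subset is used for song reconstruction.

## Design choices where the design was open

* The V-equation's initial condition (U-consistent start at t₀ = dt)
  and the Euler integrator for it; the exact integrating-factor route is
  the reference.
* Uniform-box restarts by default; data-drawn restarts in ≥3 dimensions.
* Recognition interval in the online loop defaults to every sample.
* `merge_radius` = σ_z/2; dents closer than σ_z merge on their own.
* The synthetic-generator defaults above were fixed once; the prescribed
  i.i.d. defaults produce a kernel-smoothing bias (next section) that is
  reported, not papered over.

## Known limitations

* **Kernel-smoothing bias of the prescribed bimodal generator.**  With
  σ_z² = 0.1 the asymptotic landscape -(g ∗ p) has minima at -1.547 and
  +1.483, displaced 0.086 and 0.131 from the density modes at -1.633 and
  +1.612: the asymmetric right peak's heavier inner tail pulls its
  smoothed minimum inward.  The learned landscape converges to the
  smoothed field, so the acceptance check demanding minima within 0.1 of
  the *raw* modes fails for the right mode — by mathematics, not by
  implementation.  The corresponding unit tests assert the computed
  (smoothed) locations.
* **The recorded-performance targets need the original recording.**  The
  printed note frequencies (434/490/388 Hz) reflect one amateur flute
  performance; the recording is third-party supplementary material and
  is not shipped.  The full WAV pipeline is exercised end-to-end on
  synthesized audio instead, where it recovers the tuning frequencies
  within 2 Hz; the acceptance test for the recorded numbers fails with
  an explanatory message unless a copy is placed at `data/audio_A1.wav`.
* Descent uses explicit Euler with backtracking, adequate for gradient
  flows into smooth dents; no saddle or basin-boundary analysis is
  provided beyond the 1-D scans used as test oracles.
* Grid landscapes stop at m = 2; higher dimensions are mesh-free only,
  whose evaluation cost grows linearly with the number of absorbed
  (unpruned) samples.
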