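"""Synthetic stimulus generators with closed-form ground truth.

Three stimulus families exercise the learning dynamics:

* an i.i.d. stream with a two-peak density of unequal mass, obtained by a
  strictly monotone nonlinear transform of Gaussian white noise — the
  exact density follows by change of variables, giving a quantitative
  target for the learned landscape;
* a correlated stream from an overdamped Langevin particle in a tilted
  double-well potential, whose stationary density is exp(-W/D) up to
  normalization — same two-category structure, but consecutive samples
  are strongly dependent;
* a jittered pitch track emulating several repetitions of a 32-beat
  three-note children's song, for the note- and phrase-discovery
  experiments.

All generators are deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError, StabilityError
from .series import StimulusSeries

__all__ = [
    "BimodalTransformSpec",
    "DoubleWellSpec",
    "MelodySpec",
    "Density",
    "gen_iid_bimodal",
    "true_density_iid",
    "gen_langevin",
    "langevin_stationary_density",
    "gen_melody",
    "DEFAULT_SEQUENCE",
]


# ---------------------------------------------------------------- i.i.d.


@dataclass(frozen=True)
class BimodalTransformSpec:
    """eta = A tanh(beta (xi - mu)) + c (xi - mu) with xi ~ N(0, 1).

    The tanh saturates at +-A, piling mass near +-A into two peaks; the
    linear leak c keeps the transform strictly monotone (so the density is
    available in closed form) and gives the peaks finite width; mu skews
    the masses of the two peaks.
    """

    A: float = 1.5
    beta: float = 2.0
    c: float = 0.1
    mu: float = 0.3

    def __post_init__(self):
        if self.A <= 0 or self.beta <= 0 or self.c <= 0:
            raise InvalidInputError("need A > 0, beta > 0, c > 0 for a monotone transform")

    def transform(self, xi):
        xi = np.asarray(xi, dtype=float)
        return self.A * np.tanh(self.beta * (xi - self.mu)) + self.c * (xi - self.mu)

    def dtransform(self, xi):
        xi = np.asarray(xi, dtype=float)
        return self.A * self.beta / np.cosh(self.beta * (xi - self.mu)) ** 2 + self.c


class Density:
    """A 1-D probability density tabulated on a dense grid.

    Provides vectorized evaluation (``__call__``), the cdf/ppf pair, mode
    locations (interior local maxima) and the probability mass attached to
    each mode (split at the interior minima of the density).
    """

    def __init__(self, grid: np.ndarray, pdf: np.ndarray):
        if np.any(pdf < 0):
            raise InvalidInputError("density values must be non-negative")
        self.grid = np.asarray(grid, dtype=float)
        norm = np.trapezoid(pdf, grid)
        self.pdf = np.asarray(pdf, dtype=float) / norm
        c = np.concatenate([[0.0], np.cumsum(np.diff(grid) * 0.5 * (self.pdf[1:] + self.pdf[:-1]))])
        self._cdf = c / c[-1]

    def __call__(self, x):
        return np.interp(np.asarray(x, dtype=float), self.grid, self.pdf, left=0.0, right=0.0)

    def cdf(self, x):
        return np.interp(np.asarray(x, dtype=float), self.grid, self._cdf)

    def ppf(self, q):
        return np.interp(np.asarray(q, dtype=float), self._cdf, self.grid)

    def modes(self) -> np.ndarray:
        p = self.pdf
        i = np.where((p[1:-1] > p[:-2]) & (p[1:-1] >= p[2:]))[0] + 1
        return self.grid[i]

    def mode_masses(self) -> np.ndarray:
        """Mass of each mode's cell, split at interior density minima."""
        p = self.pdf
        j = np.where((p[1:-1] < p[:-2]) & (p[1:-1] <= p[2:]))[0] + 1
        cuts = np.concatenate([[self.grid[0]], self.grid[j], [self.grid[-1]]])
        return np.diff(self.cdf(cuts))


def true_density_iid(spec: BimodalTransformSpec, n_grid: int = 8001, xi_span: float = 8.0) -> Density:
    """Closed-form density of the i.i.d. generator by change of variables:
    p(eta) = phi(xi(eta)) / T'(xi(eta)) with T the monotone transform."""
    xi = np.linspace(-xi_span, xi_span, n_grid)
    eta = spec.transform(xi)
    if np.any(np.diff(eta) <= 0):
        raise InvalidInputError("transform is not strictly increasing; cannot form a density")
    phi = np.exp(-0.5 * xi**2) / np.sqrt(2.0 * np.pi)
    p = phi / spec.dtransform(xi)
    # resample onto a uniform eta grid for easy downstream use
    grid = np.linspace(eta[0], eta[-1], n_grid)
    return Density(grid, np.interp(grid, eta, p))


def gen_iid_bimodal(
    n: int, spec: BimodalTransformSpec = BimodalTransformSpec(), seed: int = 0, dt: float = 1.0
) -> StimulusSeries:
    """n i.i.d. draws eta_i = T(xi_i), xi_i ~ N(0, 1), as a stimulus stream."""
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return StimulusSeries(values=spec.transform(rng.standard_normal(n)), dt=dt)


# ------------------------------------------------------------- Langevin


@dataclass(frozen=True)
class DoubleWellSpec:
    """Overdamped Langevin motion dx = -W'(x) dt + sqrt(2 D) dW in the
    tilted double well W(x) = a4 x^4/4 - a2 x^2/2 + eps x.

    Defaults put the wells near +-1.6 (matching the i.i.d. generator's
    modes) with the left well deeper (eps > 0), noise D strong enough to
    hop between wells on a ~10-time-unit scale, and an Euler-Maruyama step
    h small enough that the discretization bias in the sampled stationary
    density is a fraction of a percent.
    """

    a4: float = 1.0
    a2: float = 2.56
    eps: float = 0.2
    D: float = 0.8
    h: float = 0.02

    def __post_init__(self):
        if self.a4 <= 0:
            raise InvalidInputError("a4 must be > 0 (confining quartic)")
        if self.h <= 0 or self.D <= 0:
            raise InvalidInputError("h and D must be > 0")

    def potential(self, x):
        x = np.asarray(x, dtype=float)
        return self.a4 * x**4 / 4.0 - self.a2 * x**2 / 2.0 + self.eps * x

    def force(self, x):
        return -(self.a4 * x**3 - self.a2 * x + self.eps)


def langevin_stationary_density(spec: DoubleWellSpec, n_grid: int = 4001, span: float = 5.0) -> Density:
    """Stationary density of the overdamped Langevin equation,
    p(x) proportional to exp(-W(x)/D)."""
    grid = np.linspace(-span, span, n_grid)
    w = spec.potential(grid)
    return Density(grid, np.exp(-(w - w.min()) / spec.D))


def gen_langevin(
    n: int,
    spec: DoubleWellSpec = DoubleWellSpec(),
    seed: int = 0,
    dt: float = 1.0,
    x0: float | None = None,
    guard: float = 1e3,
) -> StimulusSeries:
    """n Euler-Maruyama samples of the double-well particle (one stimulus
    per integration step; ``dt`` is the stimulus-stream tick presented to
    the landscape, the SDE's own step is ``spec.h``).

    Consecutive samples are positively correlated.  Divergence (|x| beyond
    ``guard``) raises :class:`StabilityError` suggesting a smaller h.
    """
    if n < 1:
        raise InvalidInputError("n must be >= 1")
    rng = np.random.default_rng(seed)
    noise = np.sqrt(2.0 * spec.D * spec.h) * rng.standard_normal(n)
    if x0 is None:
        x0 = -np.sqrt(spec.a2 / spec.a4) if spec.a2 > 0 else 0.0
    x = float(x0)
    out = np.empty(n)
    a4, a2, eps, h = spec.a4, spec.a2, spec.eps, spec.h
    for i in range(n):
        x = x - (a4 * x * x * x - a2 * x + eps) * h + noise[i]
        out[i] = x
        if not (-guard < x < guard):
            raise StabilityError(
                f"Langevin trajectory diverged (|x| > {guard}) at step {i}; reduce the step h"
            )
    return StimulusSeries(values=out, dt=dt)


# --------------------------------------------------------------- melody

# 32-beat three-note arrangement of "Mary had a little lamb" (held notes
# expanded to repeated beats), transposed so only G4, A4, B4 appear.
DEFAULT_SEQUENCE = (
    "B", "A", "G", "A", "B", "B", "B", "B",
    "A", "A", "A", "A", "B", "B", "B", "B",
    "B", "A", "G", "A", "B", "B", "B", "B",
    "A", "A", "B", "A", "G", "G", "G", "G",
)

DEFAULT_TUNING = {"A": 440.0, "B": 493.88, "G": 392.0}


@dataclass(frozen=True)
class MelodySpec:
    """A repeated 32-beat song over three equal-temperament notes, emitted
    as a pitch stream with per-sample Gaussian frequency jitter emulating
    performer and measurement variability."""

    sequence: tuple = DEFAULT_SEQUENCE
    tuning: dict = field(default_factory=lambda: dict(DEFAULT_TUNING))
    beat: float = 0.75
    jitter_sd: float = 2.0
    reps: int = 6
    rate: float = 8.0

    def __post_init__(self):
        if len(self.sequence) != 32:
            raise InvalidInputError(f"sequence must have 32 beats, got {len(self.sequence)}")
        unknown = sorted(set(self.sequence) - set(self.tuning))
        if unknown:
            raise InvalidInputError(f"unknown note name(s) {unknown}; tuning defines {sorted(self.tuning)}")
        if any(f <= 0 for f in self.tuning.values()):
            raise InvalidInputError("tuning frequencies must be positive")
        if self.jitter_sd < 0 or self.reps < 1 or self.beat <= 0 or self.rate <= 0:
            raise InvalidInputError("need jitter_sd >= 0, reps >= 1, beat > 0, rate > 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.reps * len(self.sequence) * self.beat * self.rate))

    def note_at_time(self, t) -> np.ndarray:
        """Note names at times t (periodic repetition of the sequence)."""
        beat_idx = (np.floor(np.asarray(t, dtype=float) / self.beat).astype(int)) % len(self.sequence)
        return np.asarray(self.sequence, dtype=object)[beat_idx]

    def clean_track(self) -> np.ndarray:
        """Jitter-free pitch per sample over all repetitions."""
        t = np.arange(self.n_samples) / self.rate
        return np.asarray([self.tuning[nm] for nm in self.note_at_time(t)])


def gen_melody(spec: MelodySpec = MelodySpec(), seed: int = 0) -> StimulusSeries:
    """The jittered scalar pitch stream f(t) of the repeated song (Hz)."""
    f = spec.clean_track()
    if spec.jitter_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + spec.jitter_sd * rng.standard_normal(len(f))
    return StimulusSeries(values=f, dt=1.0 / spec.rate)
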