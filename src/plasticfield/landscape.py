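"""The plastic energy landscape and its evolution rules.

A stream of stimuli eta(t) deforms a scalar energy field the way drops
deform memory foam: each sample presses a bell-shaped dent ``g(x - eta)``
into the field, while an elasticity term with rate ``k`` pulls the field
back toward flat (forgetting).  Two algebraically equivalent descriptions
are implemented:

* the raw field U(x, t), obeying  dU/dt = -g(x - eta(t)) - k U,
  which drifts linearly downward under sustained stimulation;
* the de-trended field V(x, t) = U(x, t)/t, obeying
  dV/dt = -(1/t)(V + g(x - eta(t))) - k V,
  which for a stationary stimulus converges to the negative of the
  kernel-smoothed stimulus density, -(g * p).

Stimuli are treated as piecewise-constant over each sampling interval, so
the U-equation admits an exact integrating-factor update per interval.  The
V-equation is integrated by explicit Euler and is used to expose its O(dt)
agreement with the exact route.

Two containers are provided.  :class:`GridLandscape` stores the field on a
regular grid (1-D or 2-D) and is the workhorse for visualization and for
dense comparisons with the asymptotic limit.  :class:`MeshfreeLandscape`
stores the exact kernel expansion  V(x) = -(1/t) sum_i w_i g(x - eta_i)
and scales to any stimulus dimension; it is the only practical form for
the 4-D phrase landscapes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .errors import FormatError, InvalidInputError, SingularTimeError
from .kernel import Kernel
from .series import StimulusSeries

__all__ = [
    "GridLandscape",
    "MeshfreeLandscape",
    "step_U",
    "U_to_V",
    "step_V",
    "meshfree_absorb",
    "meshfree_eval",
    "asymptotic_landscape",
    "learn",
]

_U, _V = "U", "V"


def _check_eta(eta, dim: int) -> np.ndarray:
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    if eta.shape != (dim,):
        raise InvalidInputError(f"stimulus has shape {eta.shape}, landscape expects ({dim},)")
    if not np.all(np.isfinite(eta)):
        raise InvalidInputError("stimulus value must be finite")
    return eta


@dataclass
class GridLandscape:
    """Scalar energy field sampled on a regular 1-D or 2-D grid.

    ``form`` distinguishes the raw field U from the de-trended V = U/t.
    ``values`` has shape ``n_nodes`` (per-axis counts).  ``k`` is the
    elasticity (forgetting) rate in 1/time.
    """

    bounds: tuple
    n_nodes: tuple
    values: np.ndarray
    kernel: Kernel
    k: float = 0.0
    time: float = 0.0
    form: str = _U

    def __post_init__(self):
        self.bounds = tuple((float(a), float(b)) for a, b in np.atleast_2d(self.bounds))
        self.n_nodes = tuple(int(n) for n in np.atleast_1d(self.n_nodes))
        dim = len(self.bounds)
        if dim not in (1, 2):
            raise InvalidInputError("grid landscapes support 1 or 2 dimensions; use the mesh-free form beyond that")
        if len(self.n_nodes) != dim:
            raise InvalidInputError("bounds and n_nodes disagree on dimension")
        for (lo, hi), n in zip(self.bounds, self.n_nodes):
            if not (lo < hi):
                raise InvalidInputError(f"need lower < upper on every axis, got ({lo}, {hi})")
            if n < 2:
                raise InvalidInputError("need at least 2 nodes per axis")
        if self.kernel.dim != dim:
            raise InvalidInputError(f"kernel dim {self.kernel.dim} != grid dim {dim}")
        if self.k < 0:
            raise InvalidInputError("elasticity k must be >= 0")
        if self.form not in (_U, _V):
            raise InvalidInputError(f"form must be 'U' or 'V', got {self.form!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.n_nodes:
            raise InvalidInputError(f"values shape {self.values.shape} != n_nodes {self.n_nodes}")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("field values must be finite")
        self._interp = None

    # -- construction -------------------------------------------------

    @classmethod
    def zero(cls, bounds, n_nodes, kernel: Kernel, k: float = 0.0, form: str = _U) -> "GridLandscape":
        """A flat (memory-free) landscape."""
        nn = tuple(int(n) for n in np.atleast_1d(n_nodes))
        return cls(bounds=bounds, n_nodes=nn, values=np.zeros(nn), kernel=kernel, k=k, form=form)

    @classmethod
    def for_series(
        cls,
        series: StimulusSeries,
        kernel: Kernel,
        k: float = 0.0,
        form: str = _U,
        n_nodes=None,
        pad_sigmas: float = 4.0,
    ) -> "GridLandscape":
        """Flat landscape whose domain covers the observed stimulus range
        padded by ``pad_sigmas`` kernel widths per side (default 4)."""
        if kernel.dim != series.m:
            raise InvalidInputError(f"kernel dim {kernel.dim} != stimulus dim {series.m}")
        bounds = series.bounds(pad=pad_sigmas * kernel.sigma_z)
        if n_nodes is None:
            # ~8 nodes per kernel width, capped to keep 2-D grids tractable
            nn = []
            for lo, hi in bounds:
                n = int(np.ceil(8.0 * (hi - lo) / kernel.sigma_z)) + 1
                nn.append(min(max(n, 51), 2001 if series.m == 1 else 401))
            n_nodes = tuple(nn)
        return cls.zero(bounds, n_nodes, kernel, k=k, form=form)

    # -- geometry ------------------------------------------------------

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def axes(self) -> tuple:
        return tuple(
            np.linspace(lo, hi, n) for (lo, hi), n in zip(self.bounds, self.n_nodes)
        )

    def node_points(self) -> np.ndarray:
        """All grid nodes as an (N, dim) array (C order)."""
        mesh = np.meshgrid(*self.axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def kernel_field(self, eta) -> np.ndarray:
        """g(x - eta) on the grid, via separability of the product kernel."""
        eta = _check_eta(eta, self.dim)
        parts = [self.kernel.g1d(ax - e) for ax, e in zip(self.axes, eta)]
        if self.dim == 1:
            return parts[0]
        return np.multiply.outer(parts[0], parts[1])

    # -- evolution -----------------------------------------------------

    def absorb(self, eta, dt: float, substeps: int = 1) -> "GridLandscape":
        """Absorb one stimulus sample held for an interval ``dt``.

        U-form: exact integrating-factor update.  V-form: explicit Euler
        (``substeps`` sub-intervals); at time zero the field is initialized
        to -g(x - eta) at t = dt, the exact U/t value after one interval.
        """
        if self.form == _U:
            return step_U(self, eta, dt)
        if self.time == 0.0:
            sub = dt / substeps
            self.values = -self.kernel_field(eta)
            self.time = sub
            self._interp = None
            for _ in range(substeps - 1):
                step_V(self, eta, sub)
            return self
        for _ in range(substeps):
            step_V(self, eta, dt / substeps)
        return self

    # -- evaluation ----------------------------------------------------

    def _build_interp(self):
        from scipy.interpolate import CubicSpline, RectBivariateSpline

        if self.dim == 1:
            spl = CubicSpline(self.axes[0], self.values, bc_type="natural")
            der = spl.derivative()
            self._interp = ("1d", spl, der)
        else:
            spl = RectBivariateSpline(self.axes[0], self.axes[1], self.values, kx=3, ky=3)
            self._interp = ("2d", spl, None)

    def value_and_grad(self, x):
        """Smooth (cubic-spline) field value and gradient at point(s) ``x``.

        ``x`` may be a single point of shape (dim,) or a batch (n, dim).
        """
        if self._interp is None:
            self._build_interp()
        x = np.asarray(x, dtype=float)
        single = x.ndim <= 1
        pts = np.atleast_2d(x)
        if pts.shape[-1] != self.dim:
            raise InvalidInputError(f"point dimension {pts.shape[-1]} != landscape dim {self.dim}")
        kind, spl, der = self._interp
        if kind == "1d":
            v = spl(pts[:, 0])
            gr = der(pts[:, 0])[:, np.newaxis]
        else:
            v = spl.ev(pts[:, 0], pts[:, 1])
            gr = np.stack(
                [spl.ev(pts[:, 0], pts[:, 1], dx=1), spl.ev(pts[:, 0], pts[:, 1], dy=1)],
                axis=-1,
            )
        if single:
            return float(v[0]), gr[0]
        return v, gr

    def domain_bounds(self) -> list:
        return [tuple(b) for b in self.bounds]

    # -- serialization -------------------------------------------------

    def to_csv(self, path) -> None:
        """Header lines (key,value) describing the geometry, then one node
        value per line in C order."""
        buf = io.StringIO()
        buf.write(f"# form,{self.form}\n")
        buf.write(f"# time,{float(self.time)!r}\n")
        buf.write(f"# k,{float(self.k)!r}\n")
        buf.write(f"# sigma_z,{float(self.kernel.sigma_z)!r}\n")
        buf.write(f"# dim,{self.dim}\n")
        for (lo, hi), n in zip(self.bounds, self.n_nodes):
            buf.write(f"# axis,{float(lo)!r},{float(hi)!r},{n}\n")
        buf.write("value\n")
        for v in self.values.ravel():
            buf.write(f"{float(v)!r}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())

    @classmethod
    def from_csv(cls, path) -> "GridLandscape":
        meta, vals = {}, []
        axes = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line == "value":
                    continue
                if line.startswith("#"):
                    parts = [p.strip() for p in line[1:].split(",")]
                    if parts[0] == "axis":
                        axes.append((float(parts[1]), float(parts[2]), int(parts[3])))
                    else:
                        meta[parts[0]] = parts[1]
                else:
                    vals.append(float(line))
        try:
            bounds = tuple((lo, hi) for lo, hi, _ in axes)
            nn = tuple(n for _, _, n in axes)
            kern = Kernel(sigma_z=float(meta["sigma_z"]), dim=len(axes))
            return cls(
                bounds=bounds,
                n_nodes=nn,
                values=np.asarray(vals).reshape(nn),
                kernel=kern,
                k=float(meta["k"]),
                time=float(meta["time"]),
                form=meta["form"],
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: not a grid-landscape CSV ({exc})") from exc


def step_U(L: GridLandscape, eta, dt: float) -> GridLandscape:
    """Advance the U-form field by one stimulus-holding interval.

    Uses the exact solution of dU/dt = -g - kU for constant eta over
    [t, t + dt]:  U <- U e^{-k dt} - g (1 - e^{-k dt})/k  (k > 0), or
    U <- U - g dt (k = 0).  Mutates and returns ``L``.
    """
    if L.form != _U:
        raise InvalidInputError("step_U requires a U-form landscape")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    G = L.kernel_field(eta)
    if L.k > 0:
        decay = np.exp(-L.k * dt)
        L.values = L.values * decay - G * (1.0 - decay) / L.k
    else:
        L.values = L.values - G * dt
    L.time += dt
    L._interp = None
    return L


def U_to_V(L: GridLandscape) -> GridLandscape:
    """De-trend: return a new V-form landscape with values U/t."""
    if L.form != _U:
        raise InvalidInputError("U_to_V requires a U-form landscape")
    if L.time == 0.0:
        raise SingularTimeError("V = U/t is undefined at t = 0")
    return GridLandscape(
        bounds=L.bounds,
        n_nodes=L.n_nodes,
        values=L.values / L.time,
        kernel=L.kernel,
        k=L.k,
        time=L.time,
        form=_V,
    )


def step_V(L: GridLandscape, eta, dt: float) -> GridLandscape:
    """One explicit-Euler step of dV/dt = -(1/t)(V + g(x - eta)) - kV.

    The 1/t factor is evaluated at the left endpoint; evolution must have
    been started at t0 = dt with V = -g(x - eta_first) (see ``absorb``).
    Mutates and returns ``L``.
    """
    if L.form != _V:
        raise InvalidInputError("step_V requires a V-form landscape")
    if L.time == 0.0:
        raise SingularTimeError("the V-equation is singular at t = 0; seed with V = -g at t0 = dt")
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    G = L.kernel_field(eta)
    t = L.time
    L.values = L.values + dt * (-(L.values + G) / t - L.k * L.values)
    L.time = t + dt
    L._interp = None
    return L


@dataclass
class MeshfreeLandscape:
    """Exact kernel-expansion form of the landscape, for any dimension.

    Represents V(x) = -(1/time) sum_i w_i g(x - eta_i): every absorbed
    sample contributes one center with a weight that decays under the
    elasticity k.  Centers whose weight has decayed below
    ``prune_frac * max(w)`` are dropped.
    """

    kernel: Kernel
    k: float = 0.0
    time: float = 0.0
    centers: np.ndarray = None
    weights: np.ndarray = None
    prune_frac: float = 1e-12

    def __post_init__(self):
        if self.k < 0:
            raise InvalidInputError("elasticity k must be >= 0")
        if self.centers is None:
            self.centers = np.empty((0, self.kernel.dim))
        self.centers = np.asarray(self.centers, dtype=float).reshape(-1, self.kernel.dim)
        if self.weights is None:
            self.weights = np.empty((0,))
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if len(self.centers) != len(self.weights):
            raise InvalidInputError("centers and weights must have equal length")
        if np.any(self.weights < 0):
            raise InvalidInputError("weights must be non-negative")

    @property
    def dim(self) -> int:
        return self.kernel.dim

    @property
    def n_centers(self) -> int:
        return len(self.weights)

    def absorb(self, eta, dt: float) -> "MeshfreeLandscape":
        return meshfree_absorb(self, eta, dt)

    def value_and_grad(self, x):
        return meshfree_eval(self, x)

    def domain_bounds(self, pad_sigmas: float = 2.0) -> list:
        if self.n_centers == 0:
            raise InvalidInputError("empty landscape has no domain")
        pad = pad_sigmas * self.kernel.sigma_z
        lo = self.centers.min(axis=0) - pad
        hi = self.centers.max(axis=0) + pad
        return [(float(a), float(b)) for a, b in zip(lo, hi)]

    def to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(self.centers, columns=[f"eta{j + 1}" for j in range(self.dim)])
        df["weight"] = self.weights
        with open(path, "w") as fh:
            fh.write(
                f"# time,{float(self.time)!r}\n# k,{float(self.k)!r}\n"
                f"# sigma_z,{float(self.kernel.sigma_z)!r}\n"
            )
            fh.write(f"# dim,{self.dim}\n")
            df.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeshfreeLandscape":
        import pandas as pd

        meta = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if line.startswith("#"):
                    key, val = [p.strip() for p in line[1:].split(",")[:2]]
                    meta[key] = val
                    pos = fh.tell()
                else:
                    fh.seek(pos)
                    break
            df = pd.read_csv(fh, float_precision="round_trip")
        try:
            dim = int(meta["dim"])
            kern = Kernel(sigma_z=float(meta["sigma_z"]), dim=dim)
            return cls(
                kernel=kern,
                k=float(meta["k"]),
                time=float(meta["time"]),
                centers=df[[f"eta{j + 1}" for j in range(dim)]].to_numpy(),
                weights=df["weight"].to_numpy(),
            )
        except (KeyError, ValueError) as exc:
            raise FormatError(f"{path}: not a mesh-free landscape CSV ({exc})") from exc


def meshfree_absorb(M: MeshfreeLandscape, eta, dt: float) -> MeshfreeLandscape:
    """Exact absorption of one piecewise-constant stimulus interval.

    Existing weights decay by e^{-k dt}; the new center gets the exact
    integral weight (1 - e^{-k dt})/k (or dt when k = 0).  Mutates and
    returns ``M``.
    """
    if dt <= 0:
        raise InvalidInputError("dt must be positive")
    eta = _check_eta(eta, M.dim)
    if M.k > 0:
        decay = np.exp(-M.k * dt)
        w_new = (1.0 - decay) / M.k
        M.weights = M.weights * decay
    else:
        w_new = dt
    M.centers = np.vstack([M.centers, eta[np.newaxis, :]])
    M.weights = np.append(M.weights, w_new)
    M.time += dt
    if M.prune_frac > 0 and M.n_centers:
        keep = M.weights >= M.prune_frac * M.weights.max()
        if not keep.all():
            M.centers = M.centers[keep]
            M.weights = M.weights[keep]
    return M


def meshfree_eval(M: MeshfreeLandscape, x):
    """Field value and gradient of the kernel expansion at point(s) ``x``.

    Returns ``(V, gradV)``; for a batch of points of shape (n, dim) the
    results have shapes (n,) and (n, dim).
    """
    if M.time == 0.0:
        raise SingularTimeError("V = U/t is undefined at t = 0")
    x = np.asarray(x, dtype=float)
    if M.dim == 1:
        single = x.ndim == 0 or x.shape == (1,)
        pts = x.reshape(-1, 1)
    else:
        single = x.ndim == 1
        pts = np.atleast_2d(x)
    if pts.shape[-1] != M.dim:
        raise InvalidInputError(f"point dimension {pts.shape[-1]} != landscape dim {M.dim}")
    if M.n_centers == 0:
        V = np.zeros(len(pts))
        G = np.zeros_like(pts)
    else:
        diff = pts[:, np.newaxis, :] - M.centers[np.newaxis, :, :]  # (n, c, m)
        g = (2.0 * np.pi * M.kernel.sigma_z**2) ** (-M.dim / 2.0) * np.exp(
            -np.sum(diff**2, axis=-1) / M.kernel.sigma_z**2
        )
        wg = g * M.weights[np.newaxis, :]
        V = -wg.sum(axis=1) / M.time
        G = (wg[:, :, np.newaxis] * (2.0 * diff / M.kernel.sigma_z**2)).sum(axis=1) / M.time
    if single:
        return float(V[0]), G[0]
    return V, G


def learn(landscape, series: StimulusSeries, substeps: int = 1, snapshot_every: int | None = None):
    """Stream a stimulus series into a landscape, sample by sample.

    Each sample is held for the series' sampling interval ``dt``.  With
    ``snapshot_every = s`` a list of (time, copy-of-values) snapshots is
    collected every s samples (grid form) or (time, centers, weights)
    (mesh-free form); otherwise the snapshot list is empty.

    Fast paths: for a k = 0 grid U-form landscape and for the mesh-free
    form the final state is assembled by vectorized summation, which is
    algebraically identical to stepping (same exact sums).
    """
    snaps = []
    dt = series.dt

    take_snaps = snapshot_every is not None
    if isinstance(landscape, MeshfreeLandscape) and not take_snaps:
        _learn_meshfree_fast(landscape, series)
        return landscape, snaps
    if (
        isinstance(landscape, GridLandscape)
        and landscape.form == _U
        and not take_snaps
    ):
        _learn_grid_U_fast(landscape, series)
        return landscape, snaps

    for i in range(series.n):
        if isinstance(landscape, GridLandscape):
            landscape.absorb(series.values[i], dt, substeps=substeps)
        else:
            landscape.absorb(series.values[i], dt)
        if take_snaps and ((i + 1) % snapshot_every == 0 or i == series.n - 1):
            if isinstance(landscape, GridLandscape):
                snaps.append((landscape.time, landscape.values.copy()))
            else:
                snaps.append((landscape.time, landscape.centers.copy(), landscape.weights.copy()))
    return landscape, snaps


def _interval_weight(k: float, dt: float) -> float:
    return dt if k == 0 else (1.0 - np.exp(-k * dt)) / k


def _learn_meshfree_fast(M: MeshfreeLandscape, series: StimulusSeries) -> None:
    n, dt = series.n, series.dt
    w0 = _interval_weight(M.k, dt)
    # weight of sample i after all n intervals: w0 * e^{-k dt (n - 1 - i)}
    decay = np.exp(-M.k * dt * (n - 1 - np.arange(n))) if M.k > 0 else np.ones(n)
    M.weights = np.concatenate([M.weights * (np.exp(-M.k * dt * n) if M.k > 0 else 1.0), w0 * decay])
    M.centers = np.vstack([M.centers, series.values])
    M.time += n * dt
    if M.prune_frac > 0:
        keep = M.weights >= M.prune_frac * M.weights.max()
        M.centers, M.weights = M.centers[keep], M.weights[keep]


def _learn_grid_U_fast(L: GridLandscape, series: StimulusSeries, chunk: int = 2048) -> None:
    n, dt = series.n, series.dt
    w0 = _interval_weight(L.k, dt)
    decay = np.exp(-L.k * dt * (n - 1 - np.arange(n))) if L.k > 0 else np.ones(n)
    if L.k > 0:
        L.values = L.values * np.exp(-L.k * dt * n)
    acc = np.zeros_like(L.values)
    for s in range(0, n, chunk):
        e = min(s + chunk, n)
        w = w0 * decay[s:e]
        parts = [
            L.kernel.g1d(series.values[s:e, j][:, np.newaxis] - ax[np.newaxis, :])
            for j, ax in enumerate(L.axes)
        ]
        if L.dim == 1:
            acc += w @ parts[0]
        else:
            acc += np.einsum("i,ix,iy->xy", w, parts[0], parts[1], optimize=True)
    L.values = L.values - acc
    L.time += n * dt
    L._interp = None


def asymptotic_landscape(p, kernel: Kernel, bounds, n_nodes, quad_factor: int = 8, pad_sigmas: float = 6.0) -> GridLandscape:
    """The t -> infinity, k = 0 limit field -(g * p) on a grid.

    ``p`` is either a callable density (vectorized over the last axis being
    the coordinate for dim 2, or plain arrays for dim 1), or a pair
    ``(atoms, weights)`` describing a discrete distribution (e.g. a point
    mass).  The convolution is computed by trapezoidal quadrature on a grid
    refined ``quad_factor``-fold and padded by ``pad_sigmas`` kernel widths,
    with the kernel always evaluated analytically.
    """
    L = GridLandscape.zero(bounds, n_nodes, kernel, k=0.0, form=_V)
    if isinstance(p, tuple) and len(p) == 2 and not callable(p):
        atoms = np.atleast_2d(np.asarray(p[0], dtype=float))
        wts = np.asarray(p[1], dtype=float).ravel()
        if np.any(wts < 0):
            raise InvalidInputError("discrete density weights must be non-negative")
        vals = np.zeros(L.n_nodes)
        for a, w in zip(atoms, wts):
            vals -= w * L.kernel_field(a)
        L.values = vals
        L.time = 1.0
        return L

    pad = pad_sigmas * kernel.sigma_z
    qaxes = []
    for (lo, hi), n in zip(L.bounds, L.n_nodes):
        nq = quad_factor * (n - 1) + 1
        extra = int(np.ceil(pad / ((hi - lo) / (nq - 1))))
        step = (hi - lo) / (nq - 1)
        qaxes.append(np.linspace(lo - extra * step, hi + extra * step, nq + 2 * extra))
    if L.dim == 1:
        y = qaxes[0]
        py = np.asarray(p(y), dtype=float)
        if np.any(py < -1e-12):
            raise InvalidInputError("density is negative on the quadrature grid")
        A = kernel.g1d(L.axes[0][:, np.newaxis] - y[np.newaxis, :])
        L.values = -np.trapezoid(A * py[np.newaxis, :], y, axis=1)
    else:
        y1, y2 = qaxes
        mesh = np.stack(np.meshgrid(y1, y2, indexing="ij"), axis=-1)
        P = np.asarray(p(mesh.reshape(-1, 2)), dtype=float).reshape(len(y1), len(y2))
        if np.any(P < -1e-12):
            raise InvalidInputError("density is negative on the quadrature grid")
        A = kernel.g1d(L.axes[0][:, np.newaxis] - y1[np.newaxis, :])
        B = kernel.g1d(L.axes[1][:, np.newaxis] - y2[np.newaxis, :])
        dy1, dy2 = y1[1] - y1[0], y2[1] - y2[0]
        L.values = -(A @ P @ B.T) * dy1 * dy2
    L.time = 1.0
    return L
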