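"""Reading out the landscape: gradient descent, recognition, minima discovery.

The state obeys dx/dt = -grad V, so from any start it slides into the local
minimum of the basin it occupies.  Recognition resets the state to an
incoming stimulus and reports which catalogued minimum the descent reaches;
the full memory inventory is recovered by descending from many random
starts and clustering the endpoints.

Descent is explicit Euler with a backtracking safeguard: whenever a trial
step would raise V the step is halved, so along a frozen landscape V is
non-increasing by construction.  Steps are also capped at half a kernel
width so a trajectory can never tunnel across a dent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyResultError, InvalidInputError
from .series import StimulusSeries

__all__ = ["Trajectory", "MinimaSet", "descend", "recognize", "find_minima", "run_online"]


@dataclass
class Trajectory:
    """A gradient-descent path.  ``states`` has shape (n_steps + 1, dim)."""

    times: np.ndarray
    states: np.ndarray
    terminal_grad_norm: float
    converged: bool

    @property
    def endpoint(self) -> np.ndarray:
        return self.states[-1]

    def to_csv(self, path) -> None:
        dim = self.states.shape[1]
        df = pd.DataFrame(self.states, columns=[f"x{j + 1}" for j in range(dim)])
        df.insert(0, "time", self.times)
        df.to_csv(path, index=False)


@dataclass
class MinimaSet:
    """Discovered memories: minima locations with depths and basin counts.

    Ordered by depth ascending (deepest, i.e. most negative, first).
    ``basin_counts[i]`` is the number of converged restarts whose descent
    ended in cluster i.
    """

    locations: np.ndarray
    depths: np.ndarray
    basin_counts: np.ndarray
    merge_radius: float

    def __len__(self) -> int:
        return len(self.depths)

    def match(self, x, radius: float | None = None) -> int | None:
        """Index of the minimum within ``radius`` (default ``merge_radius``)
        of ``x``, or None."""
        if len(self) == 0:
            return None
        if radius is None:
            radius = self.merge_radius
        d = np.linalg.norm(self.locations - np.asarray(x, dtype=float), axis=1)
        i = int(np.argmin(d))
        return i if d[i] <= radius else None

    def to_csv(self, path) -> None:
        dim = self.locations.shape[1]
        df = pd.DataFrame(self.locations, columns=[f"x{j + 1}" for j in range(dim)])
        df["depth"] = self.depths
        df["basin_count"] = self.basin_counts
        df.to_csv(path, index=False)


def _default_step(landscape) -> float:
    # descent "time" step; with backtracking + growth the start value only
    # sets the first iteration's scale
    return float(landscape.kernel.sigma_z**2)


def _default_tol(landscape) -> float:
    # tiny fraction of the steepest slope of a single full-depth dent; far
    # below any plateau gradient that is not an outright floating-point
    # zero, so distant starts crawl toward a dent (the geometric step
    # growth makes the crawl cheap) instead of stopping on flat foam
    s = landscape.kernel.sigma_z
    return 1e-250 * landscape.kernel.g0 * np.sqrt(2.0) / s


def _default_xtol(landscape) -> float:
    # accepted displacements below this mean the point no longer moves at
    # numerical resolution
    return 1e-9 * landscape.kernel.sigma_z


def descend(
    landscape,
    x0,
    step: float | None = None,
    tol: float | None = None,
    max_iter: int = 2000,
    record_path: bool = True,
) -> Trajectory:
    """Integrate dx/dt = -grad V from ``x0`` until the gradient is below ``tol``.

    Explicit Euler with backtracking: a trial update x - step * grad V is
    accepted only if V does not increase, otherwise the step is halved; the
    step doubles after each accepted move, so shallow far-field gradients
    are crossed in logarithmically many iterations.  Displacements are
    capped at sigma_z / 2 per iteration so a trajectory cannot tunnel
    through a dent.  A point that stops moving at numerical resolution
    (accepted displacement below 1e-9 sigma_z, or no decrease possible)
    counts as converged.  Failure to settle within ``max_iter`` flags
    ``converged=False`` rather than raising.
    """
    x = np.atleast_1d(np.asarray(x0, dtype=float))
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("starting point must be finite")
    if step is None:
        step = _default_step(landscape)
    if step <= 0:
        raise InvalidInputError("step must be positive")
    if tol is None:
        tol = _default_tol(landscape)
    max_disp = landscape.kernel.sigma_z / 2.0
    xtol = _default_xtol(landscape)

    v, gr = landscape.value_and_grad(x)
    path = [x.copy()] if record_path else None
    times = [0.0] if record_path else None
    t = 0.0
    gnorm = float(np.linalg.norm(gr))
    converged = gnorm < tol
    it = 0
    while not converged and it < max_iter:
        it += 1
        moved = False
        halved = False
        for _ in range(60):  # backtracking
            dx = -gr * step
            dnorm = float(np.linalg.norm(dx))
            if dnorm > max_disp:
                dx *= max_disp / dnorm
                dnorm = max_disp
            x_new = x + dx
            v_new, gr_new = landscape.value_and_grad(x_new)
            if v_new <= v:
                moved = True
                break
            step *= 0.5
            halved = True
        # stagnation: backtracking was needed yet V barely moved -- the
        # point is oscillating inside the numerical minimum
        stagnant = moved and halved and (v - v_new) <= abs(v) * 1e-12
        if not moved or dnorm < xtol or stagnant:
            # the point no longer moves at numerical resolution: minimum
            converged = True
            if moved:
                t += step
                x, v, gr = x_new, v_new, gr_new
                gnorm = float(np.linalg.norm(gr))
            break
        t += step
        x, v, gr = x_new, v_new, gr_new
        step *= 2.0
        if record_path:
            path.append(x.copy())
            times.append(t)
        gnorm = float(np.linalg.norm(gr))
        converged = gnorm < tol
    if record_path:
        states = np.asarray(path)
        tarr = np.asarray(times)
    else:
        states = x[np.newaxis, :]
        tarr = np.asarray([t])
    return Trajectory(times=tarr, states=states, terminal_grad_norm=gnorm, converged=bool(converged))


def _descend_batch(landscape, X0: np.ndarray, step0: float, tol: float, max_iter: int, xtol: float):
    """Vectorized multi-start descent (endpoints only), same rule as
    :func:`descend`: accept/halve with per-point step sizes, double after
    acceptance, displacement capped at sigma_z / 2."""
    X = np.array(X0, dtype=float)
    n = len(X)
    V, G = landscape.value_and_grad(X)
    step = np.full(n, step0)
    gnorm = np.linalg.norm(G, axis=1)
    converged = gnorm < tol
    active = ~converged
    was_rejected = np.zeros(n, dtype=bool)
    max_disp = landscape.kernel.sigma_z / 2.0
    step_floor = step0 * 2.0**-70
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.where(active)[0]
        dx = -G[idx] * step[idx, np.newaxis]
        dnorm = np.linalg.norm(dx, axis=1)
        big = dnorm > max_disp
        if big.any():
            dx[big] *= (max_disp / dnorm[big])[:, np.newaxis]
            dnorm[big] = max_disp
        Xn = X[idx] + dx
        Vn, Gn = landscape.value_and_grad(Xn)
        ok = Vn <= V[idx]
        acc = idx[ok]
        # stagnation: a previously backtracked point whose accepted move
        # barely lowers V is oscillating inside the numerical minimum
        stagnant = was_rejected[acc] & ((V[acc] - Vn[ok]) <= np.abs(V[acc]) * 1e-12)
        X[acc] = Xn[ok]
        V[acc] = Vn[ok]
        G[acc] = Gn[ok]
        gnorm[acc] = np.linalg.norm(Gn[ok], axis=1)
        step[acc] *= 2.0
        was_rejected[acc] = False
        rej = idx[~ok]
        step[rej] *= 0.5
        was_rejected[rej] = True
        # settled: gradient below tol, displacement at resolution,
        # stagnation, or the step has collapsed (no decrease possible)
        done_acc = acc[(gnorm[acc] < tol) | (dnorm[ok] < xtol) | stagnant]
        done_rej = rej[step[rej] < step_floor]
        converged[done_acc] = True
        converged[done_rej] = True
        active[done_acc] = False
        active[done_rej] = False
    return X, V, converged


def find_minima(
    landscape,
    n_starts: int = 200,
    seed: int = 0,
    merge_radius: float | None = None,
    bounds=None,
    starts=None,
    depth_frac: float = 0.01,
    min_depth: float | None = None,
    step: float | None = None,
    tol: float | None = None,
    max_iter: int = 2000,
) -> MinimaSet:
    """Discover all memorized minima by random-restart descent.

    Restarts are drawn uniformly from ``bounds`` (default: the landscape's
    own domain, i.e. the observed stimulus range padded by two kernel
    widths for the mesh-free form), or taken from ``starts`` explicitly
    (e.g. the stimulus samples themselves, useful in high dimension where
    uniform draws land in flat territory).  Converged endpoints are merged
    by single-linkage clustering at ``merge_radius`` (default sigma_z / 2);
    clusters shallower than ``depth_frac`` times the deepest depth are
    discarded as flat-plateau artifacts, since a vanishing gradient on an
    untouched stretch of foam also satisfies the convergence test.  An
    absolute depth floor ``min_depth`` can additionally be given, e.g. a
    small multiple of the single-event dent depth g(0) * dt / t, to reject
    micro-dents pressed by a lone outlying sample.

    Deterministic for a fixed seed.  Raises :class:`EmptyResultError` when
    no restart converges.
    """
    if n_starts < 1:
        raise InvalidInputError("n_starts must be >= 1")
    if merge_radius is None:
        merge_radius = landscape.kernel.sigma_z / 2.0
    rng = np.random.default_rng(seed)
    if starts is None:
        if bounds is None:
            bounds = landscape.domain_bounds()
        lo = np.asarray([b[0] for b in bounds])
        hi = np.asarray([b[1] for b in bounds])
        starts = lo + (hi - lo) * rng.random((n_starts, len(bounds)))
    else:
        starts = np.atleast_2d(np.asarray(starts, dtype=float))
        if len(starts) > n_starts:
            starts = starts[rng.choice(len(starts), size=n_starts, replace=False)]

    X, V, conv = _descend_batch(
        landscape,
        starts,
        step0=step if step is not None else _default_step(landscape),
        tol=tol if tol is not None else _default_tol(landscape),
        max_iter=max_iter,
        xtol=_default_xtol(landscape),
    )
    if not conv.any():
        raise EmptyResultError("no restart of the minima search converged")
    ends = X[conv]
    depths = V[conv]

    labels = _single_linkage(ends, merge_radius)
    locs, deps, counts = [], [], []
    for lab in np.unique(labels):
        mask = labels == lab
        centroid = ends[mask].mean(axis=0)
        v, _ = landscape.value_and_grad(centroid)
        locs.append(centroid)
        deps.append(v)
        counts.append(int(mask.sum()))
    locs = np.asarray(locs)
    deps = np.asarray(deps)
    counts = np.asarray(counts)

    deepest = deps.min()
    if deepest < 0:
        keep = deps <= depth_frac * deepest
        locs, deps, counts = locs[keep], deps[keep], counts[keep]
    if min_depth is not None:
        keep = deps <= -min_depth
        if keep.any():
            locs, deps, counts = locs[keep], deps[keep], counts[keep]
    order = np.argsort(deps, kind="stable")
    return MinimaSet(
        locations=locs[order],
        depths=deps[order],
        basin_counts=counts[order],
        merge_radius=float(merge_radius),
    )


def _single_linkage(points: np.ndarray, radius: float) -> np.ndarray:
    if len(points) == 1:
        return np.zeros(1, dtype=int)
    from scipy.cluster.hierarchy import fcluster, linkage

    Z = linkage(points, method="single")
    return fcluster(Z, t=radius, criterion="distance")


def recognize(landscape, eta, minima: MinimaSet, **descent_kwargs) -> int | None:
    """Label a stimulus: reset the state to ``eta``, descend, and return the
    index of the catalogued minimum reached (None = unknown category)."""
    if len(minima) == 0:
        raise InvalidInputError("minima catalogue is empty")
    tr = descend(landscape, eta, record_path=False, **descent_kwargs)
    return minima.match(tr.endpoint)


def run_online(
    stimuli: StimulusSeries,
    landscape,
    recognition_interval: int = 1,
    merge_radius: float | None = None,
    **descent_kwargs,
) -> tuple:
    """Online unsupervised learning with simultaneous recognition.

    Every sample deforms the landscape (learning); every
    ``recognition_interval``-th sample additionally triggers a recognition
    pass: the state is reset to the current stimulus and descends the
    *frozen* landscape (read-only) to an attractor.  Endpoints are matched
    against a running category catalogue: an endpoint within
    ``merge_radius`` of a known category re-labels (and re-centers) it,
    otherwise a new category index is minted.

    Returns ``(landscape, log)`` where ``log`` is a DataFrame with one row
    per recognition event: time, stimulus components, endpoint components
    and category index (-1 marks an unknown/non-converged event).
    """
    if merge_radius is None:
        merge_radius = landscape.kernel.sigma_z / 2.0
    cat_centers: list[np.ndarray] = []
    rows = []
    dt = stimuli.dt
    for i in range(stimuli.n):
        eta = stimuli.values[i]
        landscape.absorb(eta, dt)
        if (i + 1) % recognition_interval == 0:
            tr = descend(landscape, eta, record_path=False, **descent_kwargs)
            cat = -1
            if tr.converged:
                for j, c in enumerate(cat_centers):
                    if np.linalg.norm(tr.endpoint - c) <= merge_radius:
                        cat = j
                        cat_centers[j] = tr.endpoint.copy()
                        break
                else:
                    cat_centers.append(tr.endpoint.copy())
                    cat = len(cat_centers) - 1
            row = {"time": stimuli.t0 + i * dt, "category": cat}
            for j in range(stimuli.m):
                row[f"eta{j + 1}"] = eta[j]
                row[f"end{j + 1}"] = tr.endpoint[j]
            rows.append(row)
    return landscape, pd.DataFrame(rows)
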