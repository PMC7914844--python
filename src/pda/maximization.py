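"""Local maximization of p(R) and attribution of samples to basins.

Instead of maximizing p, -ln p is minimized: it shares all critical
points and basins with p but is numerically better behaved. The
minimization has two phases:

1. A step-length-limited, monotone steepest-descent phase (per-electron
   steps capped at ``max_step``) that guarantees locality: a sample
   never leaves its basin of attraction. Electron-nucleus cusps are
   handled by a capture rule - an electron entering the capture radius
   of a nucleus with its descent direction pointing at it is snapped
   onto the nucleus and frozen there. Each capture restarts the latency
   period.
2. After a latency period without captures the remaining free electrons
   are refined with bounded quasi-Newton (L-BFGS-B) steps, frozen
   electrons staying fixed, followed by a final capture sweep.

Accepted moves never increase -ln p (backtracking line search in phase
one; the quasi-Newton result is only adopted when it improves).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .configurations import ElectronConfiguration
from .errors import ContractError
from .sampling import SampleSet
from .wavefunctions import DensityModel


@dataclass
class MaximizerOptions:
    max_step: float = 0.1          # per-electron descent step cap, bohr
    capture_radius: float = 0.05   # nuclear capture radius, bohr
    latency: int = 20              # steepest-descent steps between captures
    gtol: float = 1e-6             # free-electron gradient max-norm tolerance
    trust_radius: float = 0.05     # per-round quasi-Newton box half-width, bohr
    step_tol: float = 1e-8         # step max-norm tolerance
    max_descent_iters: int = 5000
    lbfgs_maxiter: int = 150
    max_backtracks: int = 45


@dataclass
class Maximum:
    """A local maximum R* of p with its basin statistics."""

    configuration: ElectronConfiguration
    value: float                     # -ln p at R*, up to the model constant
    count: int = 0                   # samples attributed to the basin
    frozen: np.ndarray = field(default=None)  # per-electron nuclear attachment
    converged: bool = True
    trajectory: list | None = None   # -ln p after each accepted step

    def __post_init__(self) -> None:
        if self.frozen is None:
            self.frozen = np.zeros(self.configuration.n, dtype=bool)
        self.frozen = np.asarray(self.frozen, dtype=bool)


# ----------------------------------------------------------------- batch core
def _capture_sweep(model, x, spins, frozen, lp, radius, grad=None, require_direction=True):
    """Snap electrons inside a nuclear capture radius onto the nucleus.

    Snaps are only kept when they do not lower ln p; with
    ``require_direction`` the (ascent) gradient must point at the
    nucleus. Returns the number of new captures.
    """
    opts_radius = radius
    nuclei = model.geometry.positions
    captures = 0
    for nuc in nuclei:
        delta = nuc - x                       # (m, n, 3)
        dist = np.linalg.norm(delta, axis=-1)
        cand = (dist < opts_radius) & ~frozen & (dist > 0)
        if require_direction and grad is not None:
            toward = np.sum(grad * delta, axis=-1) > 0
            cand &= toward
        exact = (dist == 0) & ~frozen         # already sitting on the nucleus
        frozen |= exact
        rows = np.unique(np.nonzero(cand)[0])
        if rows.size == 0:
            continue
        trial = x[rows].copy()
        trial_mask = cand[rows]
        trial[trial_mask] = nuc
        lp_trial = model._log_density(trial, spins)
        keep = lp_trial >= lp[rows] - 1e-12
        kept_rows = rows[keep]
        x[kept_rows] = trial[keep]
        lp[kept_rows] = lp_trial[keep]
        frozen[kept_rows] |= cand[kept_rows]
        captures += int(keep.sum())
    return captures


def _descend_batch(model, x, spins, opts, record=False, frozen_init=None):
    """Monotone capped steepest descent of -ln p on a batch.

    Returns (x, frozen, lp, needs_refine, converged, trajectory).
    ``needs_refine`` marks samples whose latency period expired with
    free electrons remaining (to be handed to L-BFGS-B).
    """
    model.validate_spins(spins)
    m, n, _ = x.shape
    frozen = (
        np.zeros((m, n), dtype=bool)
        if frozen_init is None
        else np.array(frozen_init, dtype=bool, copy=True)
    )
    lp = model._log_density(x, spins)
    eta = np.full(m, 1.0)
    since_capture = np.zeros(m, dtype=int)
    needs_refine = np.zeros(m, dtype=bool)
    converged = np.zeros(m, dtype=bool)
    traj = [[-v] for v in lp] if record else None

    # initial sweep: a sample may start inside a capture radius
    grad0 = model._grad_log_density(x, spins)
    _capture_sweep(model, x, spins, frozen, lp, opts.capture_radius, grad0, require_direction=True)

    active = ~(frozen.all(axis=1))
    for _ in range(opts.max_descent_iters):
        idx = np.flatnonzero(active & ~needs_refine & ~converged)
        if idx.size == 0:
            break
        g = model._grad_log_density(x[idx], spins)
        g[frozen[idx]] = 0.0
        g[~np.isfinite(g)] = 0.0
        gmax = np.linalg.norm(g, axis=-1).max(axis=1)
        done_g = gmax <= opts.gtol
        converged[idx[done_g]] = True
        expired = since_capture[idx] >= opts.latency
        needs_refine[idx[expired & ~done_g]] = True
        sub = ~done_g & ~expired
        if not sub.any():
            continue
        rows = idx[sub]
        gs = g[sub]
        xi = x[rows].copy()
        lpi = lp[rows].copy()
        tr_eta = eta[rows].copy()
        ok_all = np.zeros(rows.size, dtype=bool)
        for _bt in range(opts.max_backtracks):
            step = gs * tr_eta[:, None, None]
            mag = np.linalg.norm(step, axis=-1, keepdims=True)
            step = step * np.minimum(1.0, opts.max_step / np.maximum(mag, 1e-300))
            trial = xi + np.where(ok_all[:, None, None], 0.0, step)
            lp_new = model._log_density(trial, spins)
            good = (lp_new >= lpi) & ~ok_all
            xi[good] = trial[good]
            lpi[good] = lp_new[good]
            ok_all |= good
            tr_eta[~ok_all] *= 0.5
            if ok_all.all():
                break
        eta[rows] = np.where(ok_all, np.minimum(tr_eta * 1.5, 16.0), tr_eta)
        # a sample that cannot make progress goes to the refinement phase
        needs_refine[rows[~ok_all]] = True
        moved = np.linalg.norm(xi - x[rows], axis=-1).max(axis=1)
        x[rows] = xi
        lp[rows] = lpi
        since_capture[rows] += 1
        small = ok_all & (moved <= opts.step_tol)
        converged[rows[small]] = True
        # capture electrons arriving at nuclei; reset their latency clock
        g2 = model._grad_log_density(x[rows], spins)
        before = frozen[rows].copy()
        fr = frozen[rows]
        lpr = lp[rows]
        xr = x[rows]
        _capture_sweep(model, xr, spins, fr, lpr, opts.capture_radius, g2, require_direction=True)
        newly = (fr & ~before).any(axis=1)
        x[rows] = xr
        lp[rows] = lpr
        frozen[rows] = fr
        since_capture[rows[newly]] = 0
        if record:
            for k, r in enumerate(rows):
                traj[r].append(float(-lp[r]))
        active = ~(frozen.all(axis=1))
    else:
        needs_refine[active & ~converged & ~needs_refine] = True
    converged |= frozen.all(axis=1)
    return x, frozen, lp, needs_refine, converged, traj


def _refine_lbfgs(model, x, spins, frozen, lp_val, opts):
    """Quasi-Newton refinement of one sample's free electrons."""
    n = x.shape[0]
    for _round in range(3):
        free = np.flatnonzero(~frozen)
        if free.size == 0:
            break

        def fun(z):
            pos = x.copy()
            pos[free] = z.reshape(-1, 3)
            val, grad = model._log_density_and_grad(pos[None], spins)
            val = val[0]
            if not np.isfinite(val) or val <= -1e299:
                return 1e300, np.zeros(free.size * 3)
            g = grad[0][free].ravel()
            g[~np.isfinite(g)] = 0.0
            return -val, -g

        # the trust box keeps the quasi-Newton move as local as a capped
        # descent step: an unbounded line search could jump across a
        # nodal surface of Psi into a neighboring basin
        x0 = x[free].ravel()
        bounds = [(v - opts.trust_radius, v + opts.trust_radius) for v in x0]
        res = minimize(
            fun,
            x0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opts.lbfgs_maxiter, "gtol": opts.gtol / 2.0,
                     "maxfun": 4 * opts.lbfgs_maxiter},
        )
        if np.isfinite(res.fun) and -res.fun >= lp_val - 1e-12:
            x[free] = res.x.reshape(-1, 3)
            lp_val = float(-res.fun)
        # final capture sweep (no direction requirement after refinement)
        xb = x[None].copy()
        fr = frozen[None].copy()
        lpb = np.array([lp_val])
        snapped = _capture_sweep(model, xb, spins, fr, lpb, opts.capture_radius, None, require_direction=False)
        x = xb[0]
        frozen = fr[0]
        lp_val = float(lpb[0])
        if snapped == 0:
            break
    free = np.flatnonzero(~frozen)
    if free.size:
        g = model._grad_log_density(x[None], spins)[0][free]
        gmax = float(np.linalg.norm(g, axis=-1).max())
        converged = gmax <= max(opts.gtol, 1e-5)
    else:
        converged = True
    return x, frozen, lp_val, converged


def _escape_saddles(model, x, spins, frozen, lp, h=0.02):
    """Deterministic saddle probe for converged samples.

    A vanishing gradient also occurs at saddle points of p, whose
    basins have measure zero; a sample stopping there must be moved on.
    Each free electron is nudged by h along +-x, +-y, +-z, and any
    strict improvement of ln p is accepted (the probe never lowers p,
    so monotonicity is preserved). Returns the mask of moved samples.
    """
    m, n, _ = x.shape
    moved = np.zeros(m, dtype=bool)
    for i in range(n):
        rows = np.flatnonzero(~frozen[:, i])
        if rows.size == 0:
            continue
        for axis in range(3):
            for sign in (+1.0, -1.0):
                trial = x[rows].copy()
                trial[:, i, axis] += sign * h
                lp_trial = model._log_density(trial, spins)
                better = lp_trial > lp[rows] + 1e-10
                upd = rows[better]
                x[upd] = trial[better]
                lp[upd] = lp_trial[better]
                moved[upd] = True
    return moved


def _maximize_batch(model, positions, spins, opts, record=False):
    x = np.array(positions, dtype=float, copy=True)
    x, frozen, lp, needs_refine, converged, traj = _descend_batch(
        model, x, spins, opts, record=record
    )
    # alternate trust-boxed quasi-Newton refinement, saddle probing, and
    # renewed descent phases: a refinement that ends on its box (or
    # stalls at a cusp short of the capture radius) hands back to capped
    # descent, which walks the electron onward without leaving the basin
    verified = np.zeros(len(x), dtype=bool)
    for _cycle in range(12):
        todo = np.flatnonzero(needs_refine & ~converged)
        for i in todo:
            xi, fri, lpi, conv = _refine_lbfgs(
                model, x[i].copy(), spins, frozen[i].copy(), float(lp[i]), opts
            )
            x[i] = xi
            frozen[i] = fri
            lp[i] = lpi
            converged[i] = conv
            if record:
                traj[i].append(float(-lpi))
        needs_refine[todo] = False

        check = np.flatnonzero(converged & ~frozen.all(axis=1) & ~verified)
        if check.size:
            xc = x[check]
            lpc = lp[check]
            moved = _escape_saddles(model, xc, spins, frozen[check], lpc)
            x[check] = xc
            lp[check] = lpc
            verified[check[~moved]] = True
            converged[check[moved]] = False
            if record:
                for i in check[moved]:
                    traj[i].append(float(-lp[i]))

        retry = np.flatnonzero(~converged & ~needs_refine)
        if retry.size == 0 and not (needs_refine & ~converged).any():
            break
        if retry.size:
            xr, fr, lpr, re_refine, re_conv, _ = _descend_batch(
                model, x[retry].copy(), spins, opts, frozen_init=frozen[retry]
            )
            x[retry] = xr
            frozen[retry] = fr
            lp[retry] = lpr
            converged[retry] |= re_conv & ~re_refine
            needs_refine[retry] = re_refine
            if record:
                for i in retry:
                    traj[i].append(float(-lp[i]))
    return x, frozen, lp, converged, traj


# ------------------------------------------------------------------ public API
def maximize(
    model: DensityModel,
    start: ElectronConfiguration,
    options: MaximizerOptions | None = None,
    record_trajectory: bool = False,
) -> Maximum:
    """Locally maximize p from ``start``; returns the basin's maximum.

    The recorded trajectory of -ln p values (one entry per accepted
    move) is non-increasing.
    """
    opts = options or MaximizerOptions()
    lp0 = model.log_density(start)
    if not np.isfinite(lp0) or lp0 <= -1e299:
        raise ContractError("start configuration has vanishing density")
    x, frozen, lp, converged, traj = _maximize_batch(
        model, start.positions[None], start.spins, opts, record=record_trajectory
    )
    return Maximum(
        configuration=ElectronConfiguration(x[0], start.spins.copy()),
        value=float(-lp[0]),
        count=0,
        frozen=frozen[0],
        converged=bool(converged[0]),
        trajectory=traj[0] if record_trajectory else None,
    )


def attribute_samples(
    model: DensityModel,
    samples: SampleSet,
    options: MaximizerOptions | None = None,
    merge_radius: float = 0.01,
    chunk_size: int = 20000,
) -> list[Maximum]:
    """Attribute every sampled configuration to the basin it descends to.

    Each converged sample increments the count of exactly one maximum;
    maxima identical within ``merge_radius`` (metric D) are unified by
    greedy spherical pre-clustering. Non-converged samples are excluded
    from the counts with a warning.
    """
    from .clustering import pre_cluster

    if len(samples) == 0:
        raise ContractError("empty sample set")
    opts = options or MaximizerOptions()
    spins = samples.spins
    all_x, all_lp, all_frozen, all_conv = [], [], [], []
    for lo in range(0, len(samples), chunk_size):
        chunk = samples.positions[lo : lo + chunk_size]
        x, frozen, lp, converged, _ = _maximize_batch(model, chunk, spins, opts)
        all_x.append(x)
        all_lp.append(lp)
        all_frozen.append(frozen)
        all_conv.append(converged)
    x = np.concatenate(all_x)
    lp = np.concatenate(all_lp)
    frozen = np.concatenate(all_frozen)
    converged = np.concatenate(all_conv)
    n_bad = int((~converged).sum())
    if n_bad:
        warnings.warn(
            f"{n_bad} of {len(samples)} samples did not converge; "
            "they are excluded from basin counts"
        )
    keep = np.flatnonzero(converged)
    raw = [
        Maximum(
            configuration=ElectronConfiguration(x[i], spins.copy()),
            value=float(-lp[i]),
            count=1,
            frozen=frozen[i],
        )
        for i in keep
    ]
    return pre_cluster(raw, merge_radius)


def axis_grid_starts(
    model: DensityModel, n_points: int = 20, margin: float = 1.0
) -> list[ElectronConfiguration]:
    """Deterministic multistart grid along the internuclear axis.

    Every electron is placed on each of ``n_points`` equidistant points
    of the axis through the first two nuclei (extended by ``margin`` on
    both sides); the starts are the Cartesian product over electrons.
    Intended for few-electron systems (n_points**n starts).
    """
    if len(model.geometry) < 2:
        raise ContractError("axis grid needs at least two nuclei")
    a, b = model.geometry.positions[:2]
    ts = np.linspace(-margin, np.linalg.norm(b - a) + margin, n_points)
    direction = (b - a) / np.linalg.norm(b - a)
    points = a + ts[:, None] * direction
    n = model.n_electrons
    spins = model.spins
    starts = []
    grids = np.meshgrid(*[np.arange(n_points)] * n, indexing="ij")
    for combo in zip(*[g.ravel() for g in grids]):
        starts.append(ElectronConfiguration(points[list(combo)], spins))
    return starts


def grid_multistart(
    model: DensityModel,
    starts: list[ElectronConfiguration],
    options: MaximizerOptions | None = None,
    dedupe_radius: float = 1e-3,
) -> list[Maximum]:
    """Maximize from every start; return the distinct maxima found."""
    from .clustering import pre_cluster

    opts = options or MaximizerOptions()
    spins = starts[0].spins
    positions = np.stack([s.positions for s in starts])
    lp0 = model.log_density_batch(positions, spins)
    ok = lp0 > -1e299  # skip starts on a node
    x, frozen, lp, converged, _ = _maximize_batch(model, positions[ok], spins, opts)
    raw = [
        Maximum(
            configuration=ElectronConfiguration(x[i], spins.copy()),
            value=float(-lp[i]),
            count=1,
            frozen=frozen[i],
        )
        for i in range(len(x))
        if converged[i]
    ]
    return pre_cluster(raw, dedupe_radius)
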