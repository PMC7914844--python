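"""Metropolis sampling of electron configurations from p(R).

A standard variational-Monte-Carlo-style random walk: every step
proposes an isotropic Gaussian displacement of all electrons at once
and accepts with the Metropolis ratio p(R')/p(R). Only log-density
differences are used, so the model constant never enters.

Several statistically independent walkers can be run side by side
(``walkers > 1``); recorded configurations are interleaved round-robin
across walkers. The stationary distribution is the same for any walker
count; a single walker is the default.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .configurations import ElectronConfiguration
from .errors import ContractError, StepSizeError
from .wavefunctions import DensityModel

_MIN_STEP = 1e-3
_MAX_STEP = 10.0


@dataclass
class SampleSet:
    """Recorded Metropolis samples plus chain metadata."""

    positions: np.ndarray        # (n_samples, n, 3) bohr
    spins: np.ndarray            # (n,) spin labels shared by all samples
    seed: int
    model_id: str
    acceptance_ratio: float
    step: float                  # proposal width actually used, bohr
    burn_in: int = 1000
    thinning: int = 1
    walkers: int = 1

    def __post_init__(self) -> None:
        if not (0.0 < self.acceptance_ratio < 1.0):
            raise ContractError("acceptance ratio must lie strictly in (0, 1)")

    def __len__(self) -> int:
        return len(self.positions)

    def configuration(self, i: int) -> ElectronConfiguration:
        return ElectronConfiguration(self.positions[i].copy(), self.spins.copy())


def tune_step(
    model: DensityModel,
    target_acceptance: float = 0.5,
    seed: int = 0,
    pilot_steps: int = 2000,
    tolerance: float = 0.1,
) -> float:
    """Proposal width reaching ``target_acceptance`` (+-tolerance) on a pilot chain.

    Geometric bisection on the step size; the acceptance rate of the
    all-electron Gaussian proposal decreases monotonically with it.
    Extreme targets that no step in [1e-3, 10] a0 reaches are answered
    with the best boundary step and a warning.
    """
    if not (0.0 < target_acceptance < 1.0):
        raise ContractError("target acceptance must lie in (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x57E9]))

    def pilot(step: float) -> float:
        x = model.initial_positions(rng)[None]
        spins = model.spins
        lp = model.log_density_batch(x, spins)
        accepted = 0
        for _ in range(pilot_steps):
            prop = x + rng.normal(scale=step, size=x.shape)
            lp_new = model.log_density_batch(prop, spins)
            if np.log(rng.random()) < lp_new[0] - lp[0]:
                x, lp = prop, lp_new
                accepted += 1
        return accepted / pilot_steps

    lo, hi = _MIN_STEP, _MAX_STEP
    if pilot(lo) < target_acceptance - tolerance:
        warnings.warn(
            f"target acceptance {target_acceptance} unreachable; "
            f"returning smallest allowed step {lo}"
        )
        return lo
    if pilot(hi) > target_acceptance + tolerance:
        warnings.warn(
            f"target acceptance {target_acceptance} unreachable; "
            f"returning largest allowed step {hi}"
        )
        return hi
    step = float(np.sqrt(lo * hi))
    best_step, best_gap = step, np.inf
    for _ in range(25):
        acc = pilot(step)
        gap = abs(acc - target_acceptance)
        if gap < best_gap:
            best_step, best_gap = step, gap
        if gap <= tolerance:
            return step
        if acc > target_acceptance:
            lo = step
        else:
            hi = step
        step = float(np.sqrt(lo * hi))
    return best_step


def sample(
    model: DensityModel,
    n_samples: int,
    seed: int,
    step: float | str = "auto",
    burn_in: int = 1000,
    thinning: int = 1,
    walkers: int = 1,
    target_acceptance: float = 0.5,
) -> SampleSet:
    """Draw ``n_samples`` configurations from p(R) by Metropolis walk.

    One configuration is recorded every ``thinning`` steps after
    ``burn_in`` equilibration steps (per walker). The same seed yields
    a bit-for-bit identical :class:`SampleSet`. A chain whose overall
    acceptance falls below 1% aborts with a :class:`StepSizeError`.
    """
    if n_samples < 1:
        raise ContractError("n_samples must be >= 1")
    if thinning < 1 or burn_in < 0 or walkers < 1:
        raise ContractError("bad chain parameters")
    master = np.random.SeedSequence(seed)
    if step == "auto":
        step = tune_step(model, target_acceptance, seed=seed)
    step = float(step)
    if step <= 0:
        raise ContractError("step must be positive")
    rng = np.random.default_rng(master)
    spins = model.spins
    n = model.n_electrons
    x = np.stack([model.initial_positions(rng) for _ in range(walkers)])
    lp = model.log_density_batch(x, spins)
    accepted = 0
    total = 0

    def advance(n_steps: int, record: np.ndarray | None = None, offset: int = 0) -> int:
        nonlocal x, lp, accepted, total
        written = 0
        for t in range(n_steps):
            prop = x + rng.normal(scale=step, size=x.shape)
            lp_new = model.log_density_batch(prop, spins)
            accept = np.log(rng.random(size=walkers)) < lp_new - lp
            x = np.where(accept[:, None, None], prop, x)
            lp = np.where(accept, lp_new, lp)
            accepted += int(accept.sum())
            total += walkers
            if record is not None and (t + 1) % thinning == 0:
                take = min(walkers, len(record) - offset - written)
                record[offset + written : offset + written + take] = x[:take]
                written += take
                if offset + written >= len(record):
                    break
        return written

    advance(burn_in)
    if total and accepted / total < 0.01:
        raise StepSizeError(
            f"chain stuck during burn-in: acceptance "
            f"{accepted / total:.4f} < 1% at step size {step}"
        )
    positions = np.empty((n_samples, n, 3))
    written = 0
    while written < n_samples:
        written += advance(thinning * max(1, (n_samples - written) // walkers + 1),
                           record=positions, offset=written)
    ratio = accepted / total
    if ratio < 0.01:
        raise StepSizeError(
            f"chain stuck: acceptance {ratio:.4f} < 1% at step size {step}"
        )
    return SampleSet(
        positions=positions,
        spins=spins,
        seed=seed,
        model_id=model.model_id,
        acceptance_ratio=float(ratio),
        step=step,
        burn_in=burn_in,
        thinning=thinning,
        walkers=walkers,
    )
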