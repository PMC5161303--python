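"""Monte-Carlo outcome statistics, parameter sweeps and screens.

Replicates are seeded ``base_seed .. base_seed + n_reps - 1`` and run
independently, so results do not depend on execution order and any
replicate can be reproduced in isolation. Binomial proportions carry
Wilson score confidence intervals at significance 0.05.

Every sweep accepts an injectable ``runner(params, seed) -> outcome``
so the statistical machinery can be tested against synthetic outcome
generators; the default runner executes a full two-cell collision
simulation and classifies the trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from . import engine
from .domain import make_stripe
from .outcomes import (OUTCOMES, NoContactError, Thresholds,
                       classify_outcome)
from .params import GridSpec, ModelParams

__all__ = [
    "run_collision", "outcome_statistics", "sticking_transition",
    "width_scan", "treatment_screen", "wilson_ci", "SweepResult",
    "default_runner", "make_cached_runner",
]


def wilson_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for k successes out of n."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return (float(lo), float(hi))


@dataclass
class SweepResult:
    """Outcome counts per parameter tuple of a sweep."""

    rows: list[dict] = field(default_factory=list)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def run_collision(p: ModelParams, seed: int,
                  grid: GridSpec | None = None,
                  T_sim: float | None = None,
                  sample_every: float = 25.0,
                  relaxed=None,
                  thresholds: Thresholds | None = None):
    """One seeded collision: set up, simulate, classify.

    Numerical failures and no-contact runs are reported as 'ambiguous'
    and 'no_contact' records rather than raised, so sweeps keep going.
    """
    if T_sim is None:
        T_sim = p.T_sim
    try:
        state = engine.setup_collision(p, grid=grid, seed=seed,
                                       relaxed=relaxed)
        traj = engine.run_simulation(state, T_sim,
                                     sample_every=sample_every)
        rec = classify_outcome(traj, thresholds, seed=seed)
    except NoContactError:
        from .outcomes import CollisionRecord
        rec = CollisionRecord("no_contact", None, None, 0, seed=seed)
    except FloatingPointError as err:
        from .outcomes import CollisionRecord
        rec = CollisionRecord("ambiguous", None, None, 0, seed=seed,
                              details={"failure": str(err)})
    rec.params_digest = p.digest()
    return rec


def default_runner(p: ModelParams, seed: int, **kw) -> str:
    return run_collision(p, seed, **kw).outcome


def make_cached_runner(T_sim: float | None = None,
                       sample_every: float = 25.0,
                       thresholds: Thresholds | None = None):
    """Runner that relaxes the initial cell once per parameter set.

    The relaxation protocol is noise-free, hence deterministic, so a
    single relaxed cell can seed every replicate; per-replicate
    variability comes from the seeded inhibitor noise of the collision
    run itself.
    """
    cache: dict[str, object] = {}

    def runner(p: ModelParams, seed: int) -> str:
        grid = engine.default_collision_grid(p)
        key = p.replace(eta=0.0, k_CR=0.0, k_FR=0.0, sigma=0.0).digest()
        if key not in cache:
            pattern = make_stripe(grid, p.d, p.edge_w)
            relaxed, _ = engine.relax_single_cell(
                p, GridSpec(nx=grid.nx, ny=grid.ny, dx=grid.dx,
                            dt=grid.dt),
                pattern=pattern, eta=0.0)
            cache[key] = relaxed
        rel = cache[key].copy()
        return run_collision(p, seed, grid=grid, T_sim=T_sim,
                             sample_every=sample_every, relaxed=rel,
                             thresholds=thresholds).outcome

    return runner


def outcome_statistics(p: ModelParams, n_reps: int, base_seed: int = 1,
                       runner=None, alpha: float = 0.05) -> dict:
    """Outcome fractions with Wilson CIs over ``n_reps`` seeded replicates."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if runner is None:
        runner = make_cached_runner()
    counts: dict[str, int] = {}
    for seed in range(base_seed, base_seed + n_reps):
        out = runner(p, seed)
        counts[out] = counts.get(out, 0) + 1
    result = {"n_reps": n_reps, "base_seed": base_seed, "counts": counts,
              "fractions": {}, "ci": {}}
    for out in sorted(set(list(counts) + list(OUTCOMES))):
        k = counts.get(out, 0)
        result["fractions"][out] = k / n_reps
        result["ci"][out] = wilson_ci(k, n_reps, alpha)
    return result


def _logit(f: float, eps: float = 1e-3) -> float:
    f = min(max(f, eps), 1.0 - eps)
    return float(np.log(f / (1.0 - f)))


def find_half_crossing(xs: np.ndarray, fracs: np.ndarray) -> float:
    """First 50% upward crossing by linear interpolation in logit space."""
    xs = np.asarray(xs, dtype=float)
    fracs = np.asarray(fracs, dtype=float)
    for i in range(len(xs) - 1):
        f1, f2 = fracs[i], fracs[i + 1]
        if f1 < 0.5 <= f2:
            l1, l2 = _logit(f1), _logit(f2)
            if l2 == l1:
                return float(0.5 * (xs[i] + xs[i + 1]))
            w = (0.0 - l1) / (l2 - l1)
            return float(xs[i] + w * (xs[i + 1] - xs[i]))
    raise ValueError("no 50% crossing inside the swept range")


def sticking_transition(alphas, sigmas, n_reps: int, base_seed: int = 1,
                        base_params: ModelParams | None = None,
                        runner=None) -> dict:
    """Locate the 50% sticking adhesion for each propulsion strength.

    For every alpha, sweeps sigma, estimates the sticking fraction and
    finds the 50% crossing (logit interpolation); then fits the line
    sigma_trans = intercept + slope * alpha by least squares.
    """
    alphas = list(alphas)
    if len(alphas) < 2:
        raise ValueError("need at least two alpha values for the fit")
    if base_params is None:
        base_params = ModelParams()
    if runner is None:
        runner = make_cached_runner()
    sweep = SweepResult()
    crossings = []
    for a in alphas:
        fracs = []
        for s in sigmas:
            p = base_params.replace(alpha=float(a), sigma=float(s))
            stats = outcome_statistics(p, n_reps, base_seed, runner=runner)
            f = stats["fractions"].get("sticking", 0.0)
            fracs.append(f)
            sweep.rows.append({"alpha": a, "sigma": s,
                               "sticking_fraction": f,
                               **{f"n_{k}": v
                                  for k, v in stats["counts"].items()}})
        crossings.append(find_half_crossing(np.asarray(sigmas),
                                            np.asarray(fracs)))
    slope, intercept = np.polyfit(alphas, crossings, 1)
    return {"alphas": list(alphas), "sigma_trans": crossings,
            "slope": float(slope), "intercept": float(intercept),
            "sweep": sweep}


def width_scan(d_values, p: ModelParams, n_reps: int, base_seed: int = 1,
               runner=None) -> dict:
    """Walk-past fraction (with Wilson CI) as a function of stripe width."""
    if runner is None:
        runner = make_cached_runner()
    out = {"d": [], "walk_past_fraction": [], "ci": [], "counts": []}
    for d in d_values:
        pd_ = p.replace(d=float(d))
        stats = outcome_statistics(pd_, n_reps, base_seed, runner=runner)
        out["d"].append(float(d))
        out["walk_past_fraction"].append(
            stats["fractions"].get("walk_past", 0.0))
        out["ci"].append(stats["ci"].get("walk_past", (0.0, 0.0)))
        out["counts"].append(stats["counts"])
    return out


def treatment_screen(base_params: ModelParams, param_name: str, deltas,
                     n_reps: int, base_seed: int = 1, target: float = 0.5,
                     runner=None) -> dict:
    """Smallest relative perturbation of one parameter that pushes the
    sticking fraction above ``target``.

    ``deltas`` are relative changes (e.g. -0.8 for -80%), scanned in
    order of increasing magnitude; returns the first achieving the
    target, or ``None`` if none does.
    """
    if not hasattr(base_params, param_name):
        raise AttributeError(f"unknown parameter {param_name!r}")
    if runner is None:
        runner = make_cached_runner()
    base_val = getattr(base_params, param_name)
    scanned = []
    found = None
    for delta in sorted(deltas, key=abs):
        p = base_params.replace(**{param_name: base_val * (1.0 + delta)})
        stats = outcome_statistics(p, n_reps, base_seed, runner=runner)
        frac = stats["fractions"].get("sticking", 0.0)
        scanned.append({"delta": delta, "sticking_fraction": frac})
        if frac > target and found is None:
            found = delta
            break
    return {"param": param_name, "delta_required": found,
            "scanned": scanned}
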