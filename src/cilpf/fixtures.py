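"""Synthetic labelled trajectories for exercising the outcome classifier.

These tracks are built from piecewise-analytic centre-of-mass motion
plus matching overlap and polarity series — no simulation involved — so
the classifier can be validated against known ground truth, including
the double walk-past counting rule.
"""

from __future__ import annotations

import numpy as np

from .engine import Trajectory
from .outcomes import OUTCOMES

__all__ = ["make_fixture_trajectory", "make_fixture_trajectories"]

_SPEED = 0.04          # um/s, typical single-cell speed
_LX = 160.0
_T_END = 2000.0
_DT = 25.0
_CONTACT_X = 9.0       # COM separation below which cells touch (um)


def _assemble(t, x0, x1, y0, y1, pol0, pol1, overlap) -> Trajectory:
    n = len(t)
    com = np.zeros((2, n, 2))
    com[0, :, 0] = x0 % _LX
    com[1, :, 0] = x1 % _LX
    com[0, :, 1] = y0
    com[1, :, 1] = y1
    xu = np.stack([x0, x1])
    vel = np.zeros((2, n, 2))
    for i in range(2):
        vel[i, :, 0] = np.gradient(xu[i], t)
        vel[i, :, 1] = np.gradient(com[i, :, 1], t)
    pol = np.zeros((2, n, 2))
    pol[0] = pol0
    pol[1] = pol1
    per = np.full((2, n), 56.5)
    rf = np.full((2, n), 1.4)
    rb = np.full((2, n), 0.01)
    ov = overlap[None, :]
    return Trajectory(t, com, xu, vel, pol, per, rf, rb, ov, [(0, 1)],
                      _LX, meta={"synthetic": True})


def _overlap_from_distance(dist: np.ndarray) -> np.ndarray:
    """Smoothly increasing overlap as COM distance falls below contact."""
    return 12.0 * np.clip((_CONTACT_X + 3.0 - dist) / 6.0, 0.0, 1.0) ** 2


def make_fixture_trajectory(kind: str, seed: int = 0,
                            crossings: int = 1) -> Trajectory:
    """One synthetic two-cell head-on trajectory with a known outcome.

    kind: one of 'reversal', 'sticking', 'walk_past', 'chaining',
    'ambiguous'. For walk_past, ``crossings`` sets how often the cells
    exchange x-order (2 = double walk-past, still labelled walk_past).
    """
    if kind not in OUTCOMES:
        raise ValueError(f"unknown outcome kind {kind!r}")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, _T_END + _DT, _DT)
    n = len(t)
    v = _SPEED
    gap0 = 30.0
    xc = _LX / 2.0
    t_meet = (gap0 - _CONTACT_X) / (2 * v)
    y0 = np.full(n, 20.0)
    y1 = np.full(n, 20.0)
    pol0 = np.zeros((n, 2))
    pol1 = np.zeros((n, 2))

    if kind == "reversal":
        t_leave = t_meet + 300.0
        x0 = np.where(t < t_meet, -gap0 / 2 + v * t,
                      np.where(t < t_leave, -gap0 / 2 + v * t_meet,
                               -gap0 / 2 + v * t_meet - v * (t - t_leave)))
        x1 = -x0
        pol0[:, 0] = np.where(t < t_meet + 150.0, 1.0, -1.0)
        pol1[:, 0] = -pol0[:, 0]
    elif kind == "walk_past":
        # cells slide past each other ``crossings`` times while staying
        # in contact, then separate; after an odd number of passes they
        # continue in their original directions, after an even number
        # they back out the way they came (still a walk-past by the
        # double-pass counting rule)
        t_pass = t_meet + 300.0 * crossings
        phase = np.clip((t - t_meet) / (t_pass - t_meet), 0.0, 1.0)
        half = _CONTACT_X / 2.0
        rel0 = -half * np.cos(crossings * np.pi * phase)
        x0 = np.where(t < t_meet, -gap0 / 2 + v * t, rel0)
        x1 = np.where(t < t_meet, gap0 / 2 - v * t, -rel0)
        after = t > t_pass
        end0 = half if crossings % 2 == 1 else -half
        sgn = 1.0 if crossings % 2 == 1 else -1.0
        x0 = np.where(after, end0 + sgn * v * (t - t_pass), x0)
        x1 = np.where(after, -end0 - sgn * v * (t - t_pass), x1)
        y0 = 20.0 - 4.0 * np.abs(np.sin(crossings * np.pi * phase))
        y1 = 20.0 + 4.0 * np.abs(np.sin(crossings * np.pi * phase))
        pol0[:, 0] = 1.0
        pol1[:, 0] = -1.0
    elif kind == "sticking":
        x0 = np.where(t < t_meet, -gap0 / 2 + v * t,
                      -gap0 / 2 + v * t_meet)
        x1 = -x0
        pol0[:, 0] = np.where(t < t_meet + 200.0, 1.0, -1.0)
        pol1[:, 0] = -pol0[:, 0]
    elif kind == "chaining":
        x0 = np.where(t < t_meet, -gap0 / 2 + v * t,
                      -gap0 / 2 + v * t_meet - v * (t - t_meet))
        x1 = np.where(t < t_meet, gap0 / 2 - v * t,
                      gap0 / 2 - v * t_meet - v * (t - t_meet))
        pol0[:, 0] = np.where(t < t_meet, 1.0, -1.0)
        pol1[:, 0] = -1.0
    else:  # ambiguous: permanent contact, slow erratic drift
        x0 = np.where(t < t_meet, -gap0 / 2 + v * t,
                      -gap0 / 2 + v * t_meet)
        x1 = -x0
        # joint wobble: fast enough not to read as sticking, but with
        # anti-aligned polarities it is neither chaining
        drift = 3.0 * np.sin(2 * np.pi * t / 600.0) \
            + np.cumsum(rng.normal(0.0, 0.05, n))
        x0 = x0 + np.where(t >= t_meet, drift, 0.0)
        x1 = x1 + np.where(t >= t_meet, drift, 0.0)
        pol0[:, 1] = 1.0
        pol1[:, 1] = -1.0

    x0 = x0 + xc
    x1 = x1 + xc
    dist = np.hypot(x1 - x0, y1 - y0)
    overlap = _overlap_from_distance(dist)
    if kind in ("sticking", "chaining", "ambiguous"):
        overlap[t >= t_meet] = np.maximum(overlap[t >= t_meet], 5.0)
    # small measurement noise on the tracks
    jitter = rng.normal(0.0, 0.02, (2, len(t)))
    return _assemble(t, x0 + jitter[0], x1 + jitter[1], y0, y1,
                     pol0, pol1, overlap)


def make_fixture_trajectories(kind: str, n: int, seed: int = 0):
    """n labelled fixtures of one outcome archetype."""
    out = []
    for i in range(n):
        crossings = 2 if (kind == "walk_past" and i % 2 == 1) else 1
        out.append((make_fixture_trajectory(kind, seed=seed + i,
                                            crossings=crossings), kind))
    return out
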