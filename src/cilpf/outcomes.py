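"""Automatic classification of two-cell collision outcomes.

A head-on collision on a stripe ends in one of four canonical outcomes —
reversal, sticking, walk-past, chaining — or is labelled ambiguous. The
decision rules work on sampled trajectories only (centre-of-mass tracks,
velocities, polarity vectors and the pairwise overlap):

* contact:   overlap > theta_c;
* separated: overlap < theta_c/10, held for at least t_hold up to the end;
* reversal:  separated, both cells' post-separation x-velocities opposite
  to their pre-contact signs, and the cells' x-order unchanged;
* walk-past: separated after the cells swapped x-order an odd number of
  times while travelling on in their original directions; a double
  swap (two walk-pasts) followed by separation also counts as walk-past;
* sticking:  still in contact at the end with the pair centre of mass
  (nearly) immobile;
* chaining:  still in contact, pair migrating fast with both polarity
  vectors aligned for most of the final window;
* ambiguous: anything else (rotating pairs, repeated depolarization...).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import Trajectory

__all__ = ["Thresholds", "CollisionRecord", "NoContactError",
           "classify_outcome", "polarity_vector", "speed_trace",
           "OUTCOMES"]

OUTCOMES = ("reversal", "sticking", "walk_past", "chaining", "ambiguous")


class NoContactError(ValueError):
    """The trajectory never reached the contact threshold."""


@dataclass
class Thresholds:
    """Config-exposed decision thresholds of the classifier.

    theta_c : contact overlap (um^2); separation requires overlap to fall
        below theta_c/10.
    t_hold : minimum time (s) the pair must remain separated at the end
        of the run for "separated" to hold.
    v_stick : pair-COM speed (um/s) below which a permanent-contact pair
        counts as sticking (mean over the final quarter of the run).
    v_chain : pair-COM speed above which a permanent-contact pair counts
        as chaining.
    align_dot : minimal polarity-polarity dot product for "aligned".
    align_frac : fraction of the final window that must be aligned.
    x_hyst : hysteresis (um) on the cell-order coordinate so grid jitter
        does not count as an order swap.
    """

    theta_c: float = 0.5
    t_hold: float = 100.0
    v_stick: float = 0.01
    v_chain: float = 0.02
    align_dot: float = 0.7
    align_frac: float = 0.75
    x_hyst: float = 1.0


@dataclass
class CollisionRecord:
    outcome: str
    t_contact: float | None
    t_separation: float | None
    n_walkpast_events: int
    seed: int | None = None
    params_digest: str | None = None
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "t_contact": self.t_contact,
            "t_separation": self.t_separation,
            "n_walkpast_events": self.n_walkpast_events,
            "seed": self.seed,
            "params_digest": self.params_digest,
        }


def polarity_vector(pol_sample: np.ndarray) -> np.ndarray:
    """Normalize a sampled polarity vector; zero vector if degenerate."""
    v = np.asarray(pol_sample, dtype=float)
    n = np.hypot(*v)
    if n < 1e-9:
        return np.zeros(2)
    return v / n


def speed_trace(traj: Trajectory, cell_idx: int,
                smooth_w: int = 1) -> np.ndarray:
    """|v|(t) of one cell, optionally boxcar-smoothed over ``smooth_w``
    samples (a window of 1 is the identity)."""
    v = np.hypot(traj.vel[cell_idx, :, 0], traj.vel[cell_idx, :, 1])
    if smooth_w <= 1:
        return v
    kernel = np.ones(smooth_w) / smooth_w
    return np.convolve(v, kernel, mode="same")


def _count_order_swaps(delta_x: np.ndarray, hyst: float) -> int:
    """Sign changes of x1 - x0 with a +-hyst dead band."""
    state = 0
    swaps = 0
    for d in delta_x:
        if d > hyst:
            s = 1
        elif d < -hyst:
            s = -1
        else:
            continue
        if state == 0:
            state = s
        elif s != state:
            swaps += 1
            state = s
    return swaps


def classify_outcome(traj: Trajectory,
                     thresholds: Thresholds | None = None,
                     seed: int | None = None) -> CollisionRecord:
    """Apply the decision rules to a sampled two-cell trajectory."""
    th = thresholds or Thresholds()
    if traj.n_cells != 2 or not traj.pairs:
        raise ValueError("classification requires a two-cell trajectory")
    t = traj.t
    ov = traj.overlaps[0]
    in_contact = ov > th.theta_c
    if not in_contact.any():
        raise NoContactError(
            f"no contact: overlap never exceeded theta_c={th.theta_c}")
    k_contact = int(np.argmax(in_contact))
    t_contact = float(t[k_contact])

    # final separation: last sample with overlap above the release level
    released = ov < th.theta_c / 10.0
    k_last_touch = int(len(ov) - 1 - np.argmax(~released[::-1]))
    separated_at_end = bool(released[-1]) and k_last_touch < len(ov) - 1 \
        and (t[-1] - t[k_last_touch]) >= th.t_hold
    t_sep = float(t[min(k_last_touch + 1, len(t) - 1)]) \
        if separated_at_end else None

    # pre-contact / post-separation mean x-velocities
    pre = slice(0, max(k_contact, 2))
    v_pre = traj.vel[:, pre, 0].mean(axis=1)
    dx_rel = traj.x_unwrapped[1] - traj.x_unwrapped[0]
    swaps = _count_order_swaps(dx_rel, th.x_hyst)

    record = CollisionRecord("ambiguous", t_contact, t_sep, 0, seed=seed,
                             params_digest=traj.meta.get("params_digest"))
    n_tail = max(2, len(t) // 4)
    if separated_at_end:
        k_from = min(k_last_touch + 1, len(t) - 2)
        v_post = traj.vel[:, k_from:, 0].mean(axis=1)
        same_dir = np.sign(v_post) == np.sign(v_pre)
        opp_dir = np.sign(v_post) == -np.sign(v_pre)
        if swaps % 2 == 1 and bool(same_dir.all()):
            record.outcome = "walk_past"
            record.n_walkpast_events = swaps
        elif swaps >= 2:
            # multiple order exchanges followed by separation count as
            # walk-past regardless of the final directions (the
            # double-pass rule)
            record.outcome = "walk_past"
            record.n_walkpast_events = swaps
        elif swaps == 0 and bool(opp_dir.all()):
            record.outcome = "reversal"
        else:
            record.outcome = "ambiguous"
    else:
        # pair still in contact at the end of the run
        pair_x = 0.5 * (traj.x_unwrapped[0] + traj.x_unwrapped[1])
        pair_y = 0.5 * (traj.com[0, :, 1] + traj.com[1, :, 1])
        vx = np.gradient(pair_x[-n_tail:], t[-n_tail:])
        vy = np.gradient(pair_y[-n_tail:], t[-n_tail:])
        pair_speed = float(np.hypot(vx, vy).mean())
        dots = np.einsum("ij,ij->i", traj.polarity[0, -n_tail:],
                         traj.polarity[1, -n_tail:])
        aligned_frac = float((dots > th.align_dot).mean())
        record.details["pair_speed"] = pair_speed
        record.details["aligned_frac"] = aligned_frac
        if pair_speed < th.v_stick:
            record.outcome = "sticking"
        elif pair_speed >= th.v_chain and aligned_frac >= th.align_frac:
            record.outcome = "chaining"
        else:
            record.outcome = "ambiguous"
    record.details["swaps"] = swaps
    record.details["v_pre"] = v_pre.tolist()
    return record
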