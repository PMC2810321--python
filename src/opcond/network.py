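"""PFC / BG-PMC rate network with dopamine and locus-coeruleus modulation.

The PFC layer (80 units by default) receives the stimulus STM traces and
a clamped-negative dopamine weight: a burst inhibits the layer overall
while the D1/NMDA synergism excites the single most afferent-driven unit
in proportion to both the burst and its afferent drive.  A
winner-take-all rule silences all but the strongest unit.

The BG-PMC output layer (3 response units) combines the PFC winner, a
direct stimulus->response pathway gated by tonic locus-coeruleus (LC)
activity, and the same dopamine brake/synergism.  The first response
unit to exceed the release threshold within a trial is executed; if none
crosses, a uniformly random response is forced at trial end
(probability 1/3 each).

All activities pass through a logistic squashing function onto [0,1].
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig


@dataclass
class NetworkState:
    """Plastic weight matrices, their momentum buffers, and LC bookkeeping."""

    w_in_pfc: np.ndarray      # (n_pfc, n_stim)
    w_pfc_bg: np.ndarray      # (n_resp, n_pfc)
    w_direct: np.ndarray      # (n_resp, n_stim), fixed (LC-gated exploratory path)
    dw_in_pfc: np.ndarray     # momentum buffers
    dw_pfc_bg: np.ndarray
    basal_pfc_vec: np.ndarray  # fixed heterogeneous baseline rates (n_pfc,)
    lc_level: float
    reward_window: deque = field(default_factory=deque)


def init_state(params: NetworkConfig, n_stim: int, rng: np.random.Generator) -> NetworkState:
    """Small positive uniform initial weights, zero momentum, full LC tone.

    Each PFC unit stands for a functional cluster; their baseline rates
    carry fixed unit-to-unit variability (drawn once per model) so the
    identity of the most excitable, afferent-driven cluster is stable
    against the slow drift of the plastic input weights.
    """
    shape_in = (params.n_pfc, n_stim)
    shape_bg = (params.n_resp, params.n_pfc)
    basal = params.basal_pfc + params.basal_jitter_pfc * rng.standard_normal(params.n_pfc)
    return NetworkState(
        w_in_pfc=rng.uniform(0.0, params.init_scale, shape_in),
        w_pfc_bg=rng.uniform(0.0, params.init_scale, shape_bg),
        w_direct=np.full((params.n_resp, n_stim), params.direct_scale),
        dw_in_pfc=np.zeros(shape_in),
        dw_pfc_bg=np.zeros(shape_bg),
        basal_pfc_vec=np.maximum(basal, 0.0),
        lc_level=params.lc_max,
        reward_window=deque(maxlen=params.n_lc),
    )


def squash(u: np.ndarray | float, slope: float) -> np.ndarray | float:
    """Logistic nonlinearity onto [0,1]."""
    return 1.0 / (1.0 + np.exp(-slope * np.asarray(u, dtype=float)))


def pfc_step(
    stm_trace: np.ndarray,
    state: NetworkState,
    params: NetworkConfig,
    da: float,
) -> tuple[np.ndarray, int]:
    """One PFC step: afferent drive, dopamine inhibition, winner synergism.

    Returns the full activity vector (before winner-take-all) and the
    winner index (argmax of drive, lowest index on ties).
    """
    if not np.isfinite(da):
        raise ValueError("dopamine level must be finite")
    afferent = state.w_in_pfc @ stm_trace
    drive = afferent + params.w_vta_pfc * da + state.basal_pfc_vec
    winner = int(np.argmax(drive))
    boost = np.zeros_like(drive)
    # D1/NMDA synergism needs both dopamine and glutamatergic afferent drive
    boost[winner] = params.b_winner * da * max(afferent[winner], 0.0)
    activity = squash(drive + boost, params.sigma_slope)
    return activity, winner


def winner_take_all(activity: np.ndarray) -> np.ndarray:
    """Keep the maximum entry (lowest index on ties), zero the rest."""
    activity = np.asarray(activity, dtype=float)
    if activity.size == 0:
        raise ValueError("activity vector must be nonempty")
    masked = np.zeros_like(activity)
    i = int(np.argmax(activity))
    masked[i] = activity[i]
    return masked


def lc_tonic(reward_window, params: NetworkConfig) -> float:
    """Tonic LC level: lc_max * (1 - reward rate over the last n_lc trials).

    An empty window (start of training) counts as zero reward rate.
    """
    rewards = list(reward_window)
    rate = float(np.mean(rewards)) if rewards else 0.0
    return float(np.clip(params.lc_max * (1.0 - rate), 0.0, params.lc_max))


def bgpmc_step(
    pfc_activity: np.ndarray,
    stm_trace: np.ndarray,
    state: NetworkState,
    params: NetworkConfig,
    da: float,
    lc_level: float,
) -> np.ndarray:
    """One BG-PMC step: PFC drive + LC-gated direct path, dopamine brake,
    winner synergism.  Returns response activities in [0,1]."""
    lc_gain = lc_level / params.lc_max if params.lc_max > 0 else 0.0
    afferent = state.w_pfc_bg @ pfc_activity + lc_gain * (state.w_direct @ stm_trace)
    drive = afferent + params.w_vta_bg * da + params.basal_bgpmc
    winner = int(np.argmax(drive))
    boost = np.zeros_like(drive)
    boost[winner] = params.b_winner * da * max(afferent[winner], 0.0)
    return squash(drive + boost, params.sigma_slope)


def select_response(
    z_steps: np.ndarray,
    params: NetworkConfig,
    rng: np.random.Generator,
) -> tuple[int, int, bool]:
    """Release the first response whose activity crosses the threshold.

    ``z_steps`` has one row per lever-out step.  Returns
    (response index, latency in steps, forced flag).  If no step crosses
    the threshold a uniformly random response is forced at trial end with
    latency equal to the full lever-out duration.
    """
    z_steps = np.atleast_2d(np.asarray(z_steps, dtype=float))
    if z_steps.shape[0] < 1:
        raise ValueError("trial must have at least one step")
    for t in range(z_steps.shape[0]):
        if z_steps[t].max() > params.theta_resp:
            return int(np.argmax(z_steps[t])), t, False
    return int(rng.integers(params.n_resp)), z_steps.shape[0], True
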