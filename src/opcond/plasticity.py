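"""Dopamine-gated Hebbian / anti-Hebbian plasticity with first-order momentum.

While the gate is open the weight change on each synapse is the product
of presynaptic and postsynaptic activity, signed by the gate mode
(Hebbian = LTP, anti-Hebbian = LTD), plus a first-order momentum term:

    dW = mu * dW_prev + s * nu * outer(post, pre)      s in {+1, -1, 0}

Weights are clipped to fixed bounds after every update.  The per-trial
plasticity readout is the sum of |dW| over steps and synapses, so LTP
and LTD contribute with their absolute values and do not cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .td_dopamine import GateState


@dataclass(frozen=True)
class LearningParams:
    """Momentum constants and learning rates for the two plastic layers."""

    mu_pfc: float = 0.7
    mu_bgpmc: float = 0.7
    nu_pfc: float = 0.0005
    nu_bgpmc: float = 0.0013

    def __post_init__(self) -> None:
        for mu in (self.mu_pfc, self.mu_bgpmc):
            if not 0 <= mu < 1:
                raise ValueError("momentum constants must be in [0,1)")
        for nu in (self.nu_pfc, self.nu_bgpmc):
            if nu <= 0:
                raise ValueError("learning rates must be > 0")


def hebbian_update(
    w: np.ndarray,
    dw_prev: np.ndarray,
    pre: np.ndarray,
    post: np.ndarray,
    gate: GateState,
    mu: float,
    nu: float,
    bounds: tuple[float, float] = (-1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """One gated update of a (post x pre) weight matrix.

    Returns the clipped new matrix and the raw increment dW (also the
    new momentum buffer).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if w.shape != (post.size, pre.size) or dw_prev.shape != w.shape:
        raise ValueError("inconsistent weight/activity dimensions")
    s = gate.sign
    dw = mu * dw_prev + s * nu * np.outer(post, pre)
    w_new = np.clip(w + dw, bounds[0], bounds[1])
    return w_new, dw


def trial_plasticity(
    dw_records: Iterable[np.ndarray] | Sequence[np.ndarray],
) -> float:
    """Sum of |dW| over all update records of one trial (LTP + LTD magnitudes)."""
    total = 0.0
    for dw in dw_records:
        total += float(np.abs(dw).sum())
    return total
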