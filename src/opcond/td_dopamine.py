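"""Temporal-difference dopamine unit and the plasticity gating window.

The VTA/SNc block is a tabular TD(0) learner over a serial-compound
(tapped-delay-line) representation of the CS: feature (c, k) is active
iff CS channel c switched on k steps ago.  Its prediction error

    delta(t) = r(t+1) + gamma * V(t+1) - V(t)

mimics phasic dopamine: a burst at unpredicted reward, a dip when a
predicted reward is omitted, and a burst that transfers to CS onset as
the association is learned.  Large |delta| opens a gating window during
which Hebbian (delta > theta_hebb) or anti-Hebbian
(delta < theta_antihebb) learning operates in PFC and BG-PMC.  The
Hebbian window length grows with the burst amplitude up to a cap; the
anti-Hebbian window has a fixed length (15 steps by default, matching
the slower recovery of the dopamine dip).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .protocol import StimulusFrame


@dataclass(frozen=True)
class TDState:
    """TD weights over serial-compound features plus learning constants."""

    w: np.ndarray
    gamma: float = 0.98
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0 < self.gamma <= 1:
            raise ValueError("gamma must be in (0,1]")
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if not np.isfinite(self.w).all():
            raise ValueError("weights must be finite")


@dataclass(frozen=True)
class GateState:
    """Plasticity gate: current mode and remaining open steps."""

    mode: str = "off"  # "hebb" | "antihebb" | "off"
    steps_remaining: int = 0
    theta_hebb: float = 0.1
    theta_antihebb: float = -0.1
    t_max: int = 10
    t_slope: float = 10.0
    antihebb_steps: int = 15

    def __post_init__(self) -> None:
        if self.mode not in ("hebb", "antihebb", "off"):
            raise ValueError(f"invalid gate mode {self.mode!r}")
        if self.steps_remaining < 0:
            raise ValueError("steps_remaining must be >= 0")
        if not (self.theta_antihebb < 0 < self.theta_hebb):
            raise ValueError("need theta_antihebb < 0 < theta_hebb")

    @property
    def sign(self) -> int:
        """+1 Hebbian, -1 anti-Hebbian, 0 closed."""
        return {"hebb": 1, "antihebb": -1, "off": 0}[self.mode]


def serial_compound(frames: Sequence[StimulusFrame]) -> np.ndarray:
    """Tapped-delay-line features for a within-trial frame history.

    Returns a (n_channels * len(frames)) one-hot vector in which feature
    (c, k) is set iff channel c turned on exactly k steps before the most
    recent frame (onset = first frame at which the channel is active).
    """
    if len(frames) == 0:
        raise ValueError("history must contain at least one frame")
    n_ch = len(np.asarray(frames[0].cs))
    horizon = len(frames)
    x = np.zeros(n_ch * horizon)
    now = horizon - 1
    for c in range(n_ch):
        onset = next((i for i, f in enumerate(frames) if f.cs[c] > 0), None)
        if onset is not None:
            k = now - onset
            x[c * horizon + k] = 1.0
    return x


def td_error(state: TDState, x_t: np.ndarray | None, x_t1: np.ndarray | None,
             r_t1: float) -> float:
    """Prediction error for the transition x_t -> x_t1 with reward r_t1.

    ``None`` stands for the terminal (zero-value) state.
    """
    v_t = 0.0 if x_t is None else _value(state, x_t)
    v_t1 = 0.0 if x_t1 is None else _value(state, x_t1)
    return float(r_t1 + state.gamma * v_t1 - v_t)


def td_update(state: TDState, delta: float, x_t: np.ndarray | None) -> TDState:
    """Apply w <- w + alpha * delta * x_t (no-op at the terminal state)."""
    if not math.isfinite(delta):
        raise ValueError("delta must be finite")
    if x_t is None:
        return state
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != state.w.shape:
        raise ValueError(f"feature shape {x_t.shape} != weight shape {state.w.shape}")
    return replace(state, w=state.w + state.alpha * delta * x_t)


def update_gate(gate: GateState, delta: float) -> GateState:
    """One gate step driven by the current prediction error.

    A qualifying burst (dip) opens a Hebbian (anti-Hebbian) window.  A
    new event of the opposite sign takes over immediately; a new event
    of the same sign extends the window but never shortens it (extra
    dopamine transients cannot curtail plasticity already under way).
    Otherwise an open window counts down by one step and closes at zero.
    """
    if delta > gate.theta_hebb:
        length = min(gate.t_max, math.ceil(gate.t_slope * delta))
        if gate.mode == "hebb":
            length = max(length, gate.steps_remaining)
        return replace(gate, mode="hebb", steps_remaining=length)
    if delta < gate.theta_antihebb:
        length = gate.antihebb_steps
        if gate.mode == "antihebb":
            length = max(length, gate.steps_remaining)
        return replace(gate, mode="antihebb", steps_remaining=length)
    if gate.steps_remaining > 1:
        return replace(gate, steps_remaining=gate.steps_remaining - 1)
    return replace(gate, mode="off", steps_remaining=0)


def _value(state: TDState, x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if x.shape != state.w.shape:
        raise ValueError(f"feature shape {x.shape} != weight shape {state.w.shape}")
    return float(state.w @ x)
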