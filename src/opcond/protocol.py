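"""Operant-conditioning trial protocol and short-term-memory traces.

A trial exposes the conditioned stimulus (the extended lever plus cue
light) for a fixed number of 100 ms steps; a lever press (response R1)
delivers one food pellet on the following step and advances the trial to
the inter-trial interval.  Cue-selective input units carry a short-term
memory (STM) of each stimulus: the trace is reset to 1 whenever the
stimulus is present and decays exponentially otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class TrialSpec:
    """Timing and contingency of a single trial.

    steps are 100 ms each; defaults compress the 60 s lever-out / 20 s
    inter-trial phases tenfold.
    """

    steps_lever_out: int = 60
    steps_iti: int = 20
    reward_magnitude: float = 1.0
    correct_response: int = 0  # R1

    def __post_init__(self) -> None:
        if self.steps_lever_out < 1:
            raise ValueError("steps_lever_out must be >= 1")
        if self.steps_iti < 0:
            raise ValueError("steps_iti must be >= 0")
        if self.reward_magnitude < 0:
            raise ValueError("reward_magnitude must be >= 0")

    @property
    def total_steps(self) -> int:
        """Trial length when no response interrupts the lever-out phase."""
        return self.steps_lever_out + self.steps_iti


@dataclass(frozen=True)
class SessionSpec:
    trials: tuple[TrialSpec, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def total_steps(self) -> int:
        return sum(t.total_steps for t in self.trials)


@dataclass(frozen=True)
class StimulusFrame:
    """Binary stimulus frame: CS channels and the reward (US) indicator."""

    cs: np.ndarray
    us: int

    def __post_init__(self) -> None:
        cs = np.asarray(self.cs)
        if not np.isin(cs, (0, 1)).all() or self.us not in (0, 1):
            raise ValueError("stimulus entries must be 0 or 1")


@dataclass(frozen=True)
class STMState:
    """Decaying short-term-memory traces, one per stimulus channel."""

    trace: np.ndarray
    decay: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.decay < 1:
            raise ValueError("decay must be in (0,1)")
        tr = np.asarray(self.trace, dtype=float)
        if (tr < 0).any() or (tr > 1).any():
            raise ValueError("traces must lie in [0,1]")


def make_session(spec: TrialSpec, n_trials: int) -> SessionSpec:
    """An ordered session of ``n_trials`` identical trials."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    return SessionSpec(trials=(spec,) * int(n_trials))


def stimulus_at(
    trial: TrialSpec,
    t: int,
    response_step: int | None = None,
    correct: bool = False,
) -> StimulusFrame:
    """Stimulus frame at step ``t`` of a trial.

    The CS is on during the lever-out phase up to and including the
    response step; a correct response delivers the US exactly one step
    later.  ``response_step=None`` means no response has occurred yet.
    """
    if not 0 <= t < trial.steps_lever_out + trial.steps_iti + 2:
        raise ValueError(f"step {t} outside trial")
    cs_on = t < trial.steps_lever_out and (response_step is None or t <= response_step)
    us = int(correct and response_step is not None and t == response_step + 1)
    return StimulusFrame(cs=np.array([int(cs_on)]), us=us)


def update_stm(state: STMState, active: np.ndarray) -> STMState:
    """One STM step: reset channels with an active stimulus to 1, decay
    the rest multiplicatively."""
    active = np.asarray(active)
    trace = np.where(active > 0, 1.0, state.trace * state.decay)
    return STMState(trace=trace, decay=state.decay)
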