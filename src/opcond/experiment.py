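"""Full operant-conditioning simulations and ensemble analysis.

``run_model`` trains one network on the lever-press task trial by trial,
wiring protocol -> TD dopamine -> PFC/BG-PMC network -> gated plasticity.
``run_ensemble`` repeats this over independent seeds (100 models by
default) and aggregates per-trial performance and plasticity as
mean +/- SEM.  Per-trial plasticity is the summed |dW| on the stimulus->
PFC afferent matrix (optionally also PFC->BG-PMC).

The ensemble readouts mirror the behavioural anchors the model is tuned
to: ~65% correct around trial 70 and ~100% around trial 120, with the
plasticity trajectory rising to an interior maximum near trial 80 and
declining afterwards.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .config import ConfigurationError, RunConfig
from .network import NetworkConfig, init_state, lc_tonic, squash
from .td_dopamine import GateState, update_gate


@dataclass(frozen=True)
class TrialOutcome:
    """Result of one trial: choice, reward, latency, summed plasticity."""

    response: int
    correct: bool
    reward: float
    latency_steps: int
    forced: bool
    plasticity: float        # sum |dW| on stimulus->PFC synapses
    plasticity_bg: float     # sum |dW| on PFC->BG-PMC synapses

    @property
    def latency_s(self) -> float:
        return self.latency_steps * 0.1


@dataclass
class Trajectory:
    """Per-trial ensemble series: performance and plasticity, mean +/- SEM."""

    mean_perf: np.ndarray
    sem_perf: np.ndarray
    mean_plast: np.ndarray
    sem_plast: np.ndarray
    n_models: int
    seeds: np.ndarray

    @property
    def n_trials(self) -> int:
        return len(self.mean_perf)


def run_model(config: RunConfig, seed: int) -> list[TrialOutcome]:
    """Train a single model; deterministic given (config, seed)."""
    config.validate()
    p, td, net, lrn = config.protocol, config.td, config.network, config.learning
    rng = np.random.default_rng(seed)

    L = p.steps_lever_out
    hold = net.response_hold_steps
    lam = p.lambda_stm
    state = init_state(net, n_stim=1, rng=rng)
    w_td = np.zeros(L + 1)  # serial-compound values, delay 0..L from CS onset
    gate = GateState(
        theta_hebb=td.theta_hebb,
        theta_antihebb=td.theta_antihebb,
        t_max=td.t_max,
        t_slope=td.t_slope,
        antihebb_steps=td.antihebb_steps,
    )
    bounds = (lrn.w_min, lrn.w_max)
    bounds_in = (lrn.w_min_in, lrn.w_max)
    stm_cs = 0.0
    stm_resp = np.zeros(net.n_resp)

    outcomes: list[TrialOutcome] = []
    for _ in range(p.n_trials):
        lc_level = lc_tonic(state.reward_window, net)
        lc_gain = lc_level / net.lc_max if net.lc_max > 0 else 0.0

        responded = -1
        resp_step = -1
        latency = L
        forced = False
        correct = False
        plast = 0.0
        plast_bg = 0.0
        x_prev = -1  # terminal
        t = 0
        while True:
            cs_on = responded < 0 and t < L
            reward_now = p.reward_magnitude if (correct and t == resp_step + 1) else 0.0

            # stimulus STM
            stm_cs = 1.0 if cs_on else stm_cs * lam

            # TD over the within-trial delay line; episode terminates at
            # the outcome step (one step after the response)
            if responded >= 0 and t >= resp_step + 1:
                x_t = -1
            else:
                x_t = t
            v_t = w_td[x_t] if x_t >= 0 else 0.0
            v_prev = w_td[x_prev] if x_prev >= 0 else 0.0
            delta = reward_now + td.gamma * v_t - v_prev
            if x_prev >= 0:
                w_td[x_prev] += td.alpha * delta
            gate = update_gate(gate, delta)
            da = delta if delta > 0.0 else 0.0

            # PFC: inhibition + winner synergism + WTA
            afferent = state.w_in_pfc[:, 0] * stm_cs
            drive = afferent + net.w_vta_pfc * da + state.basal_pfc_vec
            winner = int(np.argmax(drive))
            act_w = squash(
                drive[winner] + net.b_winner * da * max(afferent[winner], 0.0),
                net.sigma_slope,
            )
            pfc_wta = np.zeros(net.n_pfc)
            pfc_wta[winner] = act_w

            # BG-PMC drive and response release
            if responded < 0 and t < L:
                aff_bg = state.w_pfc_bg[:, winner] * act_w + lc_gain * (
                    state.w_direct[:, 0] * stm_cs
                )
                drive_bg = aff_bg + net.w_vta_bg * da + net.basal_bgpmc
                k = int(np.argmax(drive_bg))
                boost = np.zeros(net.n_resp)
                boost[k] = net.b_winner * da * max(aff_bg[k], 0.0)
                z = squash(drive_bg + boost, net.sigma_slope)
                if z.max() > net.theta_resp:
                    responded = int(np.argmax(z))
                    resp_step = t
                    latency = t
                    forced = False
                    correct = responded == 0
                elif t == L - 1:
                    responded = int(rng.integers(net.n_resp))
                    resp_step = t
                    latency = L
                    forced = True
                    correct = responded == 0

            # response STM: executed response held at 1 for `hold` steps
            stm_resp *= lam
            if responded >= 0 and resp_step <= t < resp_step + hold:
                stm_resp[responded] = 1.0
            resp_wta = np.zeros(net.n_resp)
            j = int(np.argmax(stm_resp))
            resp_wta[j] = stm_resp[j]

            # gated Hebbian / anti-Hebbian updates with momentum
            s = gate.sign
            if s != 0 or np.abs(state.dw_in_pfc).max() > 1e-12:
                state.dw_in_pfc = lrn.mu_pfc * state.dw_in_pfc
                if s != 0:
                    state.dw_in_pfc[:, 0] += s * lrn.nu_pfc * pfc_wta * stm_cs
                state.w_in_pfc = np.clip(state.w_in_pfc + state.dw_in_pfc, *bounds_in)
                plast += float(np.abs(state.dw_in_pfc).sum())
            if s != 0 or np.abs(state.dw_pfc_bg).max() > 1e-12:
                state.dw_pfc_bg = lrn.mu_bgpmc * state.dw_pfc_bg
                if s != 0:
                    state.dw_pfc_bg[:, winner] += s * lrn.nu_bgpmc * resp_wta * act_w
                state.w_pfc_bg = np.clip(state.w_pfc_bg + state.dw_pfc_bg, *bounds)
                plast_bg += float(np.abs(state.dw_pfc_bg).sum())

            x_prev = x_t
            t += 1
            if responded >= 0 and t > resp_step + 1 + p.steps_iti:
                break

        reward = p.reward_magnitude if correct else 0.0
        state.reward_window.append(1.0 if correct else 0.0)
        outcomes.append(
            TrialOutcome(
                response=responded,
                correct=correct,
                reward=reward,
                latency_steps=latency,
                forced=forced,
                plasticity=plast,
                plasticity_bg=plast_bg,
            )
        )
    return outcomes


def run_ensemble(
    config: RunConfig, n_models: int = 100, base_seed: int = 1
) -> Trajectory:
    """Independent models with seeds base_seed..base_seed+n_models-1,
    aggregated per trial as mean +/- SEM."""
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    seeds = np.arange(base_seed, base_seed + n_models)
    n_trials = config.protocol.n_trials
    include_bg = config.learning.include_bgpmc_in_metric
    perf = np.empty((n_models, n_trials))
    plast = np.empty((n_models, n_trials))
    for i, s in enumerate(seeds):
        outcomes = run_model(config, int(s))
        perf[i] = [o.correct for o in outcomes]
        plast[i] = [
            o.plasticity + (o.plasticity_bg if include_bg else 0.0) for o in outcomes
        ]
    return Trajectory(
        mean_perf=perf.mean(axis=0),
        sem_perf=_sem(perf),
        mean_plast=plast.mean(axis=0),
        sem_plast=_sem(plast),
        n_models=n_models,
        seeds=seeds,
    )


def performance_curve(outcomes: list[TrialOutcome], bin_size: int = 25) -> np.ndarray:
    """Fraction of correct responses per consecutive bin of trials."""
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    correct = np.array([o.correct for o in outcomes], dtype=float)
    return np.array(
        [correct[i : i + bin_size].mean() for i in range(0, len(correct), bin_size)]
    )


def session_summaries(
    outcomes: list[TrialOutcome], trials_per_session: int = 25
) -> list[tuple[float, float]]:
    """(fraction correct, mean latency in s) per session of trials."""
    out = []
    for i in range(0, len(outcomes), trials_per_session):
        chunk = outcomes[i : i + trials_per_session]
        frac = float(np.mean([o.correct for o in chunk]))
        lat = float(np.mean([o.latency_s for o in chunk]))
        out.append((frac, lat))
    return out


def stage_criteria(
    summaries: list[tuple[float, float]],
    latency_criterion_s: float = 5.0,
) -> dict[str, int | None]:
    """Behavioural stage labels from per-session summaries (1-based).

    The incomplete-learning stage (50%CR) is the first session with a
    correct-response fraction in [0.50, 0.65]; the learned stage (100%CR)
    is the third consecutive session with all responses correct and mean
    latency below the criterion.
    """
    if len(summaries) < 1:
        raise ValueError("need at least one session summary")
    fifty = None
    hundred = None
    streak = 0
    for i, (frac, lat) in enumerate(summaries, start=1):
        if fifty is None and 0.50 <= frac <= 0.65:
            fifty = i
        if frac >= 1.0 and lat < latency_criterion_s:
            streak += 1
            if streak >= 3 and hundred is None:
                hundred = i
        else:
            streak = 0
    return {"fifty_cr_session": fifty, "hundred_cr_session": hundred}


def smooth(x: np.ndarray, window: int = 11) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    kernel = np.ones(window)
    num = np.convolve(x, kernel, mode="same")
    den = np.convolve(np.ones_like(x), kernel, mode="same")
    return num / den


def windowed_performance(traj: Trajectory, trial: int, window: int = 10) -> float:
    """Mean ensemble performance over a centered window of trials
    (1-based trial index; the window is clipped at the series edges)."""
    if not 1 <= trial <= traj.n_trials:
        raise ValueError(f"trial {trial} outside trajectory")
    half = window // 2
    lo = max(0, min(trial - half - 1, traj.n_trials - window))
    hi = min(traj.n_trials, lo + window)
    return float(traj.mean_perf[lo:hi].mean())


def plasticity_peak_trial(traj: Trajectory, window: int = 11) -> int:
    """1-based argmax trial of the smoothed ensemble-mean plasticity."""
    return int(np.argmax(smooth(traj.mean_plast, window))) + 1


def scale_to_anchor(
    traj: Trajectory,
    anchor_value: float,
    anchor_trial: int = 70,
    window: int = 11,
) -> np.ndarray:
    """Scale the smoothed plasticity series so its value at the anchor
    trial equals ``anchor_value`` (shape-preserving)."""
    if not 1 <= anchor_trial <= traj.n_trials:
        raise ValueError(f"anchor trial {anchor_trial} outside trajectory")
    smoothed = smooth(traj.mean_plast, window)
    ref = smoothed[anchor_trial - 1]
    if ref <= 0:
        raise ValueError("plasticity at the anchor trial is zero; cannot scale")
    return smoothed * (anchor_value / ref)


def tune_parameters(
    config: RunConfig,
    grid: dict[str, list],
    targets: tuple[tuple[int, float], ...] = ((70, 0.65), (120, 1.0)),
    n_models: int = 20,
    base_seed: int = 1,
) -> tuple[RunConfig, list[dict]]:
    """Grid search over dotted config paths, minimizing the squared
    deviation of windowed ensemble performance from the behavioural
    anchors.  Returns the winning configuration and a per-point report."""
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("grid must be a nonempty mapping of nonempty lists")
    keys = sorted(grid)
    report = []
    best = None
    for values in itertools.product(*(grid[k] for k in keys)):
        cand = config.replace(**dict(zip(keys, values)))
        traj = run_ensemble(cand, n_models=n_models, base_seed=base_seed)
        loss = 0.0
        perfs = {}
        for trial, target in targets:
            got = windowed_performance(traj, trial, config.perf_window)
            perfs[trial] = got
            loss += (got - target) ** 2
        entry = {"params": dict(zip(keys, values)), "loss": loss, "performance": perfs}
        report.append(entry)
        if best is None or loss < best[0]:
            best = (loss, cand)
    return best[1], report


def _sem(a: np.ndarray) -> np.ndarray:
    n = a.shape[0]
    if n < 2:
        return np.zeros(a.shape[1])
    return a.std(axis=0, ddof=1) / math.sqrt(n)
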