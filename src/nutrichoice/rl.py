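"""Nutrient-sensitive Rescorla-Wagner simulation in a reversal task.

A standard delta-rule learner values every delivered reward equally
(outcome value 1).  The nutrient-sensitive extension increments the
outcome value of the high-nutrient reward through a sensitivity
parameter eta: r_high = r_low / (1 - eta), so eta = 0.2 raises the
outcome value from 1.0 to 1.25 and eta = 0 reduces exactly to the
standard model.  Agents choose between a high- and a low-nutrient
option by softmax on the learned values; reward probabilities reverse
mid-task.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._glm import sigmoid


@dataclass
class RLAgentParams:
    """Learning rate, softmax temperature and nutrient sensitivity."""

    alpha: float = 0.2  # learning rate, (0, 1]
    beta: float = 5.0  # softmax inverse temperature, >= 0
    eta: float = 0.0  # nutrient sensitivity, [0, 1)
    r_low: float = 1.0  # baseline outcome value of the low-nutrient reward

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if not 0 <= self.eta < 1:
            raise ValueError("eta must be in [0, 1)")


@dataclass
class ReversalSchedule:
    """Two-armed bandit with a mid-task reward-probability reversal.

    The high-nutrient option pays with probability ``p_high_pre``
    before ``reversal_trial`` and ``p_high_post`` after; the
    low-nutrient option pays with the complementary probability unless
    ``p_low`` overrides it.
    """

    n_trials: int = 100
    p_high_pre: float = 0.6
    p_high_post: float = 0.4
    reversal_trial: int | None = None  # default: midpoint
    p_low: float | None = None  # default: 1 - p_high (complementary)

    def __post_init__(self) -> None:
        for p in (self.p_high_pre, self.p_high_post):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")
        if self.reversal_trial is None:
            self.reversal_trial = self.n_trials // 2
        if not 0 < self.reversal_trial < self.n_trials:
            raise ValueError("reversal_trial must lie strictly inside the task")

    def probs_at(self, trial: int) -> tuple[float, float]:
        """(p_reward_high, p_reward_low) on a given trial."""
        p_h = self.p_high_pre if trial < self.reversal_trial else self.p_high_post
        p_l = self.p_low if self.p_low is not None else 1.0 - p_h
        return p_h, p_l


def outcome_value(params: RLAgentParams, is_high_nutrient: bool) -> float:
    """Subjective value of a delivered reward.

    Low-nutrient rewards are worth ``r_low``; high-nutrient rewards are
    worth r_low / (1 - eta), the unique simple form in which eta = 0.2
    turns a baseline of 1.0 into 1.25 and eta = 0 recovers the
    nutrient-blind model.
    """
    if params.eta >= 1:
        raise ValueError("eta must be < 1")
    if is_high_nutrient:
        return params.r_low / (1.0 - params.eta)
    return params.r_low


def rw_update(value: float, outcome: float, alpha: float) -> float:
    """Delta-rule update: value + alpha * (outcome - value)."""
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    return value + alpha * (outcome - value)


def simulate_reversal(
    params: RLAgentParams,
    schedule: ReversalSchedule,
    n_reps: int = 1000,
    seed: int | None = None,
) -> dict:
    """Simulate the reversal task, vectorized over repetitions.

    Per trial and repetition: P(choose high) = logistic(beta * (v_high
    - v_low)); the chosen option pays a Bernoulli reward under the
    schedule, the outcome enters as its nutrient-dependent value
    (unrewarded outcomes are 0), and only the chosen option's value is
    updated.  Returns the mean choice curve, per-rep totals of rewarded
    trials (R) and high-nutrient rewarded trials (N, counting
    deliveries), and the post-reversal switch latency (trials until the
    mean choice curve drops below 0.5).
    """
    rng = np.random.default_rng(seed)
    v = np.zeros((n_reps, 2))  # column 0: high-nutrient, 1: low-nutrient
    r_high = outcome_value(params, True)
    r_low = outcome_value(params, False)
    choice_high = np.zeros((schedule.n_trials, n_reps), bool)
    rewarded = np.zeros((schedule.n_trials, n_reps), bool)
    for t in range(schedule.n_trials):
        p_h, p_l = schedule.probs_at(t)
        u_choice = rng.random(n_reps)
        u_reward = rng.random(n_reps)
        p_choose_high = sigmoid(params.beta * (v[:, 0] - v[:, 1]))
        high = u_choice < p_choose_high
        p_reward = np.where(high, p_h, p_l)
        rew = u_reward < p_reward
        outcome = np.where(rew, np.where(high, r_high, r_low), 0.0)
        chosen = np.where(high, 0, 1)
        idx = np.arange(n_reps)
        v[idx, chosen] += params.alpha * (outcome - v[idx, chosen])
        choice_high[t] = high
        rewarded[t] = rew
    curve = choice_high.mean(axis=1)
    R = rewarded.sum(axis=0)
    N = (rewarded & choice_high).sum(axis=0)
    post = curve[schedule.reversal_trial :]
    below = np.flatnonzero(post < 0.5)
    latency = int(below[0]) if len(below) else len(post)
    return {
        "choice_curve": curve,
        "R": R,
        "N": N,
        "mean_R": float(R.mean()),
        "mean_N": float(N.mean()),
        "switch_latency": latency,
        "values_final": v,
        "params": params,
        "schedule": schedule,
        "seed": seed,
    }


def asymptotic_choice_probability(params: RLAgentParams, p_high: float, p_low: float) -> float:
    """Stationary softmax of the fixed-point values v* = p * r.

    With a constant schedule the delta rule converges in expectation to
    p_reward * outcome_value for each arm (ignoring choice-dependent
    sampling noise); the stationary choice probability is the softmax
    of those fixed points.
    """
    v_high = p_high * outcome_value(params, True)
    v_low = p_low * outcome_value(params, False)
    return float(sigmoid(np.array(params.beta * (v_high - v_low))))
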