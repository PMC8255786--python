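"""Choice-strategy comparison: nutrient valuation vs. energy maximization.

Cumulative intake trajectories visualize how an agent distributes its
choices between two rewards; reference agents that maximize calories,
fat, sugar or magnitude on every trial bound the achievable
trajectories.  A polar transform maps trajectories into fat-sugar
nutrient space (both axes in kcal, so isocaloric designs put equal-
energy trade-offs on the 45-degree diagonal).  Formal comparison pits a
single energy-content regressor against separate fat and sugar
regressors by AIC, and an isocaloric coefficient contrast tests whether
equal calories from fat and sugar are valued equally.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from ._glm import fit_logistic
from .datatypes import ATWATER_FAT, ATWATER_SUGAR, Session, StimulusTable, Trial
from .values import fit_nutrient_model

STRATEGIES = ("calories", "fat", "sugar", "magnitude")


def cumulative_trajectory(session: Session, stimuli: StimulusTable) -> pd.DataFrame:
    """Per-trial running totals of chosen magnitude and nutrient intake.

    Columns: cumulative chosen magnitude per stimulus (mL), cumulative
    fat/sugar/protein (g) and energy (kcal).  Only chosen options count.
    """
    stim_ids = sorted(session.stimulus_ids)
    mag = {s: 0.0 for s in stim_ids}
    fat = sugar = protein = energy = 0.0
    rows = []
    for t in session.trials:
        s = stimuli[t.chosen_stim]
        m = t.chosen_mag
        mag[t.chosen_stim] += m
        intake = s.nutrient_intake(m)
        fat += intake["fat"]
        sugar += intake["sugar"]
        protein += intake["protein"]
        energy += intake["energy"]
        row = {"trial": t.index, "fat_g": fat, "sugar_g": sugar,
               "protein_g": protein, "energy_kcal": energy}
        for sid in stim_ids:
            row[f"mag_{sid}"] = mag[sid]
        rows.append(row)
    return pd.DataFrame(rows)


def _target_density(stim, strategy: str) -> float:
    if strategy == "calories":
        return stim.energy_density
    if strategy == "fat":
        return stim.fat / 100.0
    if strategy == "sugar":
        return stim.sugar / 100.0
    if strategy == "magnitude":
        return 1.0
    raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")


def reference_agent(
    session: Session,
    stimuli: StimulusTable,
    strategy: str,
    seed: int | None = None,
) -> Session:
    """Replay a session's offers with a per-trial maximizing agent.

    The agent chooses argmax of magnitude x per-mL target content
    (calories, fat, sugar, or plain magnitude); exact ties are broken
    uniformly at random under the given seed.  Returns a new session
    with the same offers and the reference agent's choices.
    """
    rng = np.random.default_rng(seed)
    new_trials = []
    for t in session.trials:
        ql = t.mag_left * _target_density(stimuli[t.stim_left], strategy)
        qr = t.mag_right * _target_density(stimuli[t.stim_right], strategy)
        if ql > qr:
            choice = "left"
        elif qr > ql:
            choice = "right"
        else:
            choice = "left" if rng.random() < 0.5 else "right"
        new_trials.append(
            Trial(
                session_id=session.id,
                index=t.index,
                stim_left=t.stim_left,
                stim_right=t.stim_right,
                mag_left=t.mag_left,
                mag_right=t.mag_right,
                choice=choice,
            )
        )
    return Session(
        id=f"{session.id}:{strategy}",
        agent_id=f"ref_{strategy}",
        flavor=session.flavor,
        trials=new_trials,
        meta={"strategy": strategy, "source_session": session.id},
    )


def to_nutrient_polar(trajectory: pd.DataFrame) -> pd.DataFrame:
    """Transform a cumulative trajectory into fat-sugar polar coordinates.

    The Cartesian point is (cumulative fat kcal, cumulative sugar kcal);
    the angle (degrees) is measured from the fat (horizontal) axis and
    the radius is the Euclidean norm, tracking trial progression.
    Trials with zero total intake get a missing angle.
    """
    fat_kcal = ATWATER_FAT * trajectory["fat_g"].to_numpy()
    sugar_kcal = ATWATER_SUGAR * trajectory["sugar_g"].to_numpy()
    radius = np.hypot(fat_kcal, sugar_kcal)
    with np.errstate(invalid="ignore"):
        angle = np.degrees(np.arctan2(sugar_kcal, fat_kcal))
    angle = np.where(radius > 0, angle, np.nan)
    return pd.DataFrame(
        {
            "trial": trajectory["trial"],
            "fat_kcal": fat_kcal,
            "sugar_kcal": sugar_kcal,
            "radius": radius,
            "angle_deg": angle,
        }
    )


def average_trajectories(trajectories: Sequence[pd.DataFrame], n_points: int = 100) -> pd.DataFrame:
    """Average cumulative trajectories by interpolating to a common trial grid."""
    grid = np.linspace(0, 1, n_points)
    cols = [c for c in trajectories[0].columns if c != "trial"]
    acc = {c: np.zeros(n_points) for c in cols}
    for traj in trajectories:
        frac = traj["trial"].to_numpy() / max(traj["trial"].iloc[-1], 1)
        for c in cols:
            acc[c] += np.interp(grid, frac, traj[c].to_numpy())
    out = pd.DataFrame({c: v / len(trajectories) for c, v in acc.items()})
    out.insert(0, "trial_fraction", grid)
    return out


def compare_energy_vs_nutrient(
    sessions: Sequence[Session],
    stimuli: StimulusTable,
    **fit_kwargs,
) -> dict:
    """AIC comparison of an energy-maximization vs. a nutrient choice model.

    The energy model collapses nutrient content and magnitude into a
    single offered-energy regressor, logistic(choice ~ dlog energy +
    side); the nutrient model keeps separate magnitude, fat and sugar
    regressors.  dAIC = AIC_energy - AIC_nutrient, positive when the
    nutrient model wins.
    """
    nutrient_fit = fit_nutrient_model(sessions, stimuli, **fit_kwargs)

    rows, y = [], []
    for sess in sessions:
        for t in sess.trials:
            el = t.mag_left * stimuli[t.stim_left].energy_density
            er = t.mag_right * stimuli[t.stim_right].energy_density
            rows.append([1.0, math.log(el) - math.log(er)])
            y.append(1.0 if t.choice == "left" else 0.0)
    X = np.asarray(rows)
    y = np.asarray(y)
    beta, llf, _ = fit_logistic(X, y)
    aic_energy = 2 * X.shape[1] - 2 * llf
    return {
        "AIC_energy": float(aic_energy),
        "AIC_nutrient": float(nutrient_fit.aic),
        "delta_AIC": float(aic_energy - nutrient_fit.aic),
        "ll_energy": float(llf),
        "ll_nutrient": float(nutrient_fit.llf),
        "energy_params": {"const": float(beta[0]), "dlog_energy": float(beta[1])},
        "nutrient_fit": nutrient_fit,
    }


def isocaloric_coefficient_test(
    sessions: Sequence[Session],
    stimuli: StimulusTable,
) -> dict:
    """Wilcoxon test of sugar vs. fat sensitivity on isocaloric offers.

    Within a session offering a single high-fat/high-sugar isocaloric
    pair, the dichotomous fat- and sugar-level regressors are exactly
    opposed, so only their contrast is identifiable; each session is
    fitted with choice ~ dlog magnitude + contrast (z-scored level
    coding) and the per-session (sugar - fat) contrast is tested
    against zero with a paired Wilcoxon signed-rank (exact distribution
    for n <= 25, normal approximation with continuity correction
    above).  Energy maximization predicts a zero median contrast.
    """
    if len(sessions) < 6:
        raise ValueError("need >= 6 sessions")
    contrasts = []
    for sess in sessions:
        rows, y = [], []
        for t in sess.trials:
            sl, sr = stimuli[t.stim_left], stimuli[t.stim_right]
            sug_l = 1.0 if sl.sugar_level == "high" else 0.0
            sug_r = 1.0 if sr.sugar_level == "high" else 0.0
            fat_l = 1.0 if sl.fat_level == "high" else 0.0
            fat_r = 1.0 if sr.fat_level == "high" else 0.0
            rows.append([1.0, math.log(t.mag_left) - math.log(t.mag_right),
                         (sug_l - sug_r) - (fat_l - fat_r)])
            y.append(1.0 if t.choice == "left" else 0.0)
        X = np.asarray(rows)
        y = np.asarray(y)
        sd = X[:, 2].std(ddof=0)
        if sd == 0:
            raise ValueError(f"session {sess.id!r}: no isocaloric fat/sugar contrast present")
        X[:, 2] = (X[:, 2] - X[:, 2].mean()) / sd
        msd = X[:, 1].std(ddof=0)
        if msd > 0:
            X[:, 1] = (X[:, 1] - X[:, 1].mean()) / msd
        beta, _, _ = fit_logistic(X, y, ridge=1e-6)
        contrasts.append(float(beta[2]))
    contrasts = np.asarray(contrasts)
    n = len(contrasts)
    method = "exact" if n <= 25 else "approx"
    res = scipy.stats.wilcoxon(contrasts, correction=(method == "approx"), method=method)
    return {
        "median_delta_coef": float(np.median(contrasts)),
        "wilcoxon_p": float(res.pvalue),
        "n_sessions": n,
        "contrasts": contrasts,
    }
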