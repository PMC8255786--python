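"""Path analysis: do viscosity and sliding friction mediate fat preference?

Fat content cannot be tasted directly; it correlates with oral texture
(thicker, more slippery liquids).  The mediation model decomposes the
total effect of a nutrient on choice (path c, from a logistic model
with magnitude + nutrient regressors) into a direct effect (path c',
with texture regressors added) and an indirect, texture-mediated route
(stimulus-level paths a: texture on nutrient; choice-level paths b:
texture coefficients).  All regressors are standardized before fitting
so coefficients are comparable across models; the indirect effect is
summarized as c - c'.  Significance comes from a session-level
(cluster) percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._glm import fit_logistic, fit_logistic_batched
from .datatypes import Session, StimulusTable

TEXTURE_FIELDS = ("viscosity", "csf")
NUTRIENTS = ("fat", "sugar")


def texture_on_nutrients(stimuli: StimulusTable) -> dict:
    """OLS of each texture parameter on fat and, separately, on sugar.

    Estimated across the stimulus set (path a of the mediation model).
    Requires >= 3 distinct fat concentrations; with only two the texture
    and fat columns are exactly collinear at the choice level and the
    mediation paths are unidentifiable.
    """
    stims = list(stimuli.values())
    fats = sorted({s.fat for s in stims})
    if len(fats) < 3:
        raise ValueError("texture and fat collinear; mediation unidentifiable "
                         "(need >= 3 distinct fat concentrations)")
    out = {}
    for texture in TEXTURE_FIELDS:
        yvals = np.array([getattr(s, texture) for s in stims], float)
        if np.any(~np.isfinite(yvals)):
            raise ValueError(f"stimuli lack {texture} measurements")
        for nutrient in NUTRIENTS:
            x = np.array([getattr(s, nutrient) for s in stims], float)
            X = sm.add_constant(x)
            res = sm.OLS(yvals, X).fit()
            sx = x.std(ddof=0)
            sy = yvals.std(ddof=0)
            out[(texture, nutrient)] = {
                "slope": float(res.params[1]),
                "se": float(res.bse[1]),
                "intercept": float(res.params[0]),
                "r2": float(res.rsquared),
                "p": float(res.pvalues[1]),
                "slope_std": float(res.params[1] * sx / sy) if sy > 0 else float("nan"),
                "ci": tuple(np.asarray(res.conf_int())[1]),
            }
    return out


@dataclass
class PathModel:
    """Mediation path coefficients with bootstrap confidence intervals.

    ``a`` maps (texture, nutrient) to stimulus-level slopes; ``b`` maps
    texture to its standardized choice coefficient; ``c`` and
    ``c_prime`` map nutrient to total and direct standardized effects.
    ``indirect`` = c - c'.  ``ci`` holds 95% percentile bootstrap
    intervals keyed by coefficient name; ``verdict`` per nutrient is
    'complete', 'partial' or 'none'.
    """

    a: dict
    b: dict
    c: dict
    c_prime: dict
    indirect: dict
    ci: dict
    verdict: dict
    n_bootstrap: int
    n_sessions: int
    seed: int | None = None
    textures: tuple = TEXTURE_FIELDS
    extras: dict = field(default_factory=dict)


def _trial_design(
    sessions: Sequence[Session],
    stimuli: StimulusTable,
    textures: Sequence[str],
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    rows, y, sids = [], [], []
    for sess in sessions:
        for t in sess.trials:
            sl, sr = stimuli[t.stim_left], stimuli[t.stim_right]
            row = {
                "const": 1.0,
                "dlog_mag": math.log(t.mag_left) - math.log(t.mag_right),
                "dfat": sl.fat - sr.fat,
                "dsugar": sl.sugar - sr.sugar,
            }
            for tx in textures:
                vl, vr = getattr(sl, tx), getattr(sr, tx)
                if vl is None or vr is None:
                    raise ValueError(f"stimulus pair lacks {tx} values")
                row[f"d{tx}"] = vl - vr
            rows.append(row)
            y.append(1.0 if t.choice == "left" else 0.0)
            sids.append(sess.id)
    return pd.DataFrame(rows), np.asarray(y), np.asarray(sids)


def _check_collinearity(X: pd.DataFrame) -> None:
    cols = [c for c in X.columns if c != "const"]
    Z = X[cols].to_numpy()
    sd = Z.std(axis=0)
    zero = [c for c, s in zip(cols, sd) if s == 0]
    if zero:
        raise ValueError(f"constant column(s) after standardization: {', '.join(zero)}")
    corr = np.corrcoef(Z, rowvar=False)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if abs(corr[i, j]) > 1 - 1e-10:
                raise ValueError(
                    f"perfect collinearity between {cols[i]} and {cols[j]}; "
                    "mediation paths unidentifiable"
                )


def mediation_fit(
    sessions: Sequence[Session],
    stimuli: StimulusTable,
    n_bootstrap: int = 1000,
    seed: int | None = None,
    textures: Sequence[str] = TEXTURE_FIELDS,
    alpha: float = 0.05,
) -> PathModel:
    """Fit the texture-mediation path model with a cluster bootstrap.

    The total-effect logistic model (choice ~ dmagnitude + dfat +
    dsugar) yields paths c; adding standardized texture-difference
    regressors yields the direct paths c' and texture paths b.
    Sessions are resampled with replacement (trials within a session
    share a stimulus pair, so the session is the exchangeable unit) and
    all choice-level paths recomputed per resample; 95% percentile
    intervals determine significance.  Path a comes from the
    stimulus-level regressions of :func:`texture_on_nutrients`.
    """
    a_paths = texture_on_nutrients(stimuli)
    X, y, sids = _trial_design(sessions, stimuli, textures)
    # standardize so coefficients are comparable across nested models
    for col in X.columns:
        if col == "const":
            continue
        sd = X[col].std(ddof=0)
        if sd > 0:
            X[col] = (X[col] - X[col].mean()) / sd
    _check_collinearity(X)

    total_cols = ["const", "dlog_mag", "dfat", "dsugar"]
    aug_cols = total_cols + [f"d{t}" for t in textures]
    Mt = X[total_cols].to_numpy()
    Ma = X[aug_cols].to_numpy()

    beta_t, _, _ = fit_logistic(Mt, y, ridge=1e-8)
    beta_a, _, _ = fit_logistic(Ma, y, ridge=1e-8)
    c = {"fat": beta_t[2], "sugar": beta_t[3]}
    c_prime = {"fat": beta_a[2], "sugar": beta_a[3]}
    b = {t: beta_a[4 + i] for i, t in enumerate(textures)}

    # cluster bootstrap over sessions
    rng = np.random.default_rng(seed)
    uniq = pd.unique(sids)
    session_idx = [np.flatnonzero(sids == s) for s in uniq]
    lengths = {len(ix) for ix in session_idx}
    draws = rng.integers(0, len(uniq), size=(n_bootstrap, len(uniq)))
    names = ["c_fat", "c_sugar", "cprime_fat", "cprime_sugar"] + [f"b_{t}" for t in textures]
    boot = np.empty((n_bootstrap, len(names)))
    if len(lengths) == 1:
        stacked = np.stack(session_idx)  # (S, L)
        rows = stacked[draws].reshape(n_bootstrap, -1)  # (B, n)
        bt = fit_logistic_batched(Mt[rows], y[rows], beta0=beta_t, tol=1e-6, max_iter=15)
        ba = fit_logistic_batched(Ma[rows], y[rows], beta0=beta_a, tol=1e-6, max_iter=15)
        boot[:, 0], boot[:, 1] = bt[:, 2], bt[:, 3]
        boot[:, 2], boot[:, 3] = ba[:, 2], ba[:, 3]
        for i in range(len(textures)):
            boot[:, 4 + i] = ba[:, 4 + i]
    else:
        for bnum in range(n_bootstrap):
            rows = np.concatenate([session_idx[k] for k in draws[bnum]])
            bt, _, _ = fit_logistic(Mt[rows], y[rows], ridge=1e-8)
            ba, _, _ = fit_logistic(Ma[rows], y[rows], ridge=1e-8)
            boot[bnum] = [bt[2], bt[3], ba[2], ba[3]] + [ba[4 + i] for i in range(len(textures))]

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    ci = {}
    for i, nm in enumerate(names):
        ci[nm] = tuple(np.percentile(boot[:, i], [lo_q, hi_q]))
    for nut, ic, icp in (("fat", 0, 2), ("sugar", 1, 3)):
        diff = boot[:, ic] - boot[:, icp]
        ci[f"indirect_{nut}"] = tuple(np.percentile(diff, [lo_q, hi_q]))

    def excludes_zero(interval) -> bool:
        return interval[0] > 0 or interval[1] < 0

    verdict = {}
    for nut in NUTRIENTS:
        c_sig = excludes_zero(ci[f"c_{nut}"])
        cp_sig = excludes_zero(ci[f"cprime_{nut}"])
        # mediation requires the indirect effect to be significant AND
        # directionally consistent with the total effect; logistic
        # coefficients grow in magnitude when strong predictors are
        # added (non-collapsibility), which can push c - c' negative
        # for purely direct effects
        ind_sig = excludes_zero(ci[f"indirect_{nut}"]) and (
            np.sign(c[nut] - c_prime[nut]) == np.sign(c[nut])
        )
        if c_sig and not cp_sig and ind_sig:
            verdict[nut] = "complete"
        elif c_sig and cp_sig and ind_sig:
            verdict[nut] = "partial"
        else:
            verdict[nut] = "none"

    return PathModel(
        a={k: v for k, v in a_paths.items()},
        b=b,
        c=c,
        c_prime=c_prime,
        indirect={n: c[n] - c_prime[n] for n in NUTRIENTS},
        ci=ci,
        verdict=verdict,
        n_bootstrap=n_bootstrap,
        n_sessions=len(uniq),
        seed=seed,
        textures=tuple(textures),
    )
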