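"""Cross-context choice prediction and preference dissimilarity.

A fitted nutrient-value model from one context (flavor, agent) is used
to predict choices in another.  Generalization is scored by held-out
McFadden pseudo-R^2; dissimilarity between two agents' preferences is
the preference dissimilarity index (PDI), a symmetric per-trial
log-likelihood-ratio of mutual cross-predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .datatypes import Session, StimulusTable
from .values import ChoiceModelFit, _null_loglik, nutrient_design


@dataclass
class PDIResult:
    """Preference dissimilarity between two agents, in nats per trial."""

    agent_i: str
    agent_j: str
    pdi: float
    components: dict
    n_i: int
    n_j: int


def cross_context_predict(
    fit: ChoiceModelFit,
    sessions: Sequence[Session],
    stimuli: StimulusTable,
    null: str = "target",
) -> float:
    """Held-out McFadden pseudo-R^2 of a model on another context's choices.

    pseudo-R^2 = 1 - LL(target | fit) / LL(target | null).  By default
    the null (intercept-only) model is fitted on the target data; pass
    ``null='transferred'`` to use the fit's own side-bias constant as
    the null instead.
    """
    ll = fit.loglik(sessions, stimuli)
    _, y, _ = nutrient_design(sessions, stimuli, **fit.spec)
    if null == "target":
        ll0 = _null_loglik(y)
    elif null == "transferred":
        from ._glm import bernoulli_loglik, sigmoid

        b0 = float(fit.params["const"])
        ll0 = float(bernoulli_loglik(y, np.full(len(y), float(sigmoid(np.array(b0))))))
    else:
        raise ValueError("null must be 'target' or 'transferred'")
    if ll0 == 0.0:
        return float("nan")
    return 1.0 - ll / ll0


def pdi(
    model_i: ChoiceModelFit,
    sessions_i: Sequence[Session],
    model_j: ChoiceModelFit,
    sessions_j: Sequence[Session],
    stimuli: StimulusTable,
    agent_i: str = "i",
    agent_j: str = "j",
) -> PDIResult:
    """Preference dissimilarity index between two agents.

    PDI = 1/2 [ (LL(i|i) - LL(i|j)) / n_i + (LL(j|j) - LL(j|i)) / n_j ],
    the average per-trial log-likelihood ratio of each agent's own model
    against the other agent's model on the same choices.  Identical
    models give exactly 0; the expectation is non-negative whenever each
    agent's own model is its maximum-likelihood fit.
    """
    n_i = sum(len(s) for s in sessions_i)
    n_j = sum(len(s) for s in sessions_j)
    ll_ii = model_i.loglik(sessions_i, stimuli)
    ll_ij = model_j.loglik(sessions_i, stimuli)
    ll_jj = model_j.loglik(sessions_j, stimuli)
    ll_ji = model_i.loglik(sessions_j, stimuli)
    comp_i = (ll_ii - ll_ij) / n_i
    comp_j = (ll_jj - ll_ji) / n_j
    return PDIResult(
        agent_i=agent_i,
        agent_j=agent_j,
        pdi=0.5 * (comp_i + comp_j),
        components={"i_given_j": comp_i, "j_given_i": comp_j},
        n_i=n_i,
        n_j=n_j,
    )


def pdi_contribution(
    sessions_i: Sequence[Session],
    sessions_j: Sequence[Session],
    stimuli: StimulusTable,
    added: Sequence[str] = ("fat", "sugar", "both"),
    fit_kwargs: dict | None = None,
) -> dict:
    """Percentage increase in PDI from adding nutrient regressors.

    The base regression carries only magnitude and side bias; fat,
    sugar, or both nutrient regressors are then added and the PDI
    between the two agents recomputed.  A nutrient that differentiates
    the agents' preferences raises the PDI because each agent's own
    augmented model gains more likelihood on its own choices than the
    other agent's model does.
    """
    fit_kwargs = dict(fit_kwargs or {})

    def restricted_pdi(keep: set[str]) -> float:
        drop = {"dfat", "dsugar"} - keep
        f_i = _fit_restricted(sessions_i, stimuli, drop, fit_kwargs)
        f_j = _fit_restricted(sessions_j, stimuli, drop, fit_kwargs)
        return pdi(f_i, sessions_i, f_j, sessions_j, stimuli).pdi

    base = restricted_pdi(set())
    out = {"pdi_base": base}
    name_map = {"fat": {"dfat"}, "sugar": {"dsugar"}, "both": {"dfat", "dsugar"}}
    for key in added:
        aug = restricted_pdi(name_map[key])
        out[f"pdi_{key}"] = aug
        if base == 0.0:
            out[f"pct_increase_{key}"] = float("nan")  # undefined, not infinite
        else:
            out[f"pct_increase_{key}"] = 100.0 * (aug - base) / base
    return out


def _fit_restricted(sessions, stimuli, drop: set[str], fit_kwargs: dict) -> ChoiceModelFit:
    """Fit the nutrient model with some nutrient columns removed."""
    from ._glm import fit_logistic
    import pandas as pd
    from .values import fit_nutrient_model

    full = fit_nutrient_model(sessions, stimuli, **fit_kwargs)
    if not drop:
        return full
    X, y = full.design_for(sessions, stimuli)
    names = list(full.params.index)
    keep_idx = [i for i, nm in enumerate(names) if nm not in drop]
    beta, llf, _ = fit_logistic(X[:, keep_idx], y)
    params = np.zeros(len(names))
    for b, i in zip(beta, keep_idx):
        params[i] = b
    restricted = ChoiceModelFit(
        params=pd.Series(params, index=names),
        bse=full.bse * np.nan,
        llf=llf,
        ll_null=full.ll_null,
        aic=2 * len(keep_idx) - 2 * llf,
        pseudo_r2=1.0 - llf / full.ll_null if full.ll_null != 0 else np.nan,
        nobs=full.nobs,
        session_effects=full.session_effects,
        spec=full.spec,
        scaling=full.scaling,
    )
    return restricted


def triangle_layout(d_ij: float, d_ik: float, d_jk: float) -> dict:
    """Planar coordinates of three agents from pairwise dissimilarities.

    Places i at the origin and j on the positive x axis; k is solved
    from the two remaining distances.  If the triangle inequality fails
    the layout is flagged degenerate and k is placed collinearly.
    """
    sides = sorted([d_ij, d_ik, d_jk])
    degenerate = sides[2] > sides[0] + sides[1] + 1e-12
    xi = np.array([0.0, 0.0])
    xj = np.array([d_ij, 0.0])
    if d_ij > 0:
        xk_x = (d_ij**2 + d_ik**2 - d_jk**2) / (2 * d_ij)
        h2 = d_ik**2 - xk_x**2
        xk = np.array([xk_x, math.sqrt(max(h2, 0.0))])
    else:
        xk = np.array([d_ik, 0.0])
    return {
        "coordinates": {"i": xi, "j": xj, "k": xk},
        "side_lengths": {"ij": d_ij, "ik": d_ik, "jk": d_jk},
        "degenerate": bool(degenerate),
    }
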