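"""Geometric Framework for Nutrition: mixture-triangle analysis.

Stimuli and realized intakes are mapped to mixture coordinates — the
percentage of total energy contributed by fat, sugar (carbohydrate) and
protein, using Atwater factors.  Because the protein share is roughly
constant by design, analysis works in the 2-D (pct_fat, pct_sugar)
plane; the full three-component composition is retained in outputs.
A session's nutrient balance is an energy-weighted convex combination
of the two offered compositions, so it always lies on the segment
between them; dietary reference points are projected onto that segment
to find the closest achievable composition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats

from .datatypes import (
    ATWATER_FAT,
    ATWATER_PROTEIN,
    ATWATER_SUGAR,
    Session,
    Stimulus,
    StimulusTable,
)


@dataclass
class MixturePoint:
    """Percentages of total energy from fat, sugar and protein (sum 100)."""

    pct_fat: float
    pct_sugar: float
    pct_protein: float

    def __post_init__(self) -> None:
        total = self.pct_fat + self.pct_sugar + self.pct_protein
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"mixture percentages must sum to 100 (got {total})")

    @property
    def xy(self) -> np.ndarray:
        """Working-plane coordinates (pct_fat, pct_sugar)."""
        return np.array([self.pct_fat, self.pct_sugar])


@dataclass
class ReferencePoint:
    """A named dietary reference composition (e.g. recommended diet, milk)."""

    name: str
    point: MixturePoint


def mixture_coordinates(stimulus: Stimulus) -> MixturePoint:
    """Energy-proportional composition of a stimulus (Atwater factors)."""
    e_fat = ATWATER_FAT * stimulus.fat
    e_sugar = ATWATER_SUGAR * stimulus.sugar
    e_protein = ATWATER_PROTEIN * stimulus.protein
    total = e_fat + e_sugar + e_protein
    if total <= 0:
        raise ValueError(f"stimulus {stimulus.id!r} has zero energy; mixture undefined")
    return MixturePoint(
        pct_fat=100.0 * e_fat / total,
        pct_sugar=100.0 * e_sugar / total,
        pct_protein=100.0 * e_protein / total,
    )


def choice_balance(
    session: Session, stimuli: StimulusTable, method: str = "intake"
) -> MixturePoint:
    """Nutrient balance of a session's realized intake.

    ``method='intake'`` computes the composition of the summed nutrient
    intake directly; ``method='convex'`` forms the energy-intake-
    weighted convex combination of the two offered stimuli's mixture
    points.  The two routes are algebraically identical.
    """
    if method == "intake":
        fat = sugar = protein = 0.0
        for t in session.trials:
            intake = stimuli[t.chosen_stim].nutrient_intake(t.chosen_mag)
            fat += intake["fat"]
            sugar += intake["sugar"]
            protein += intake["protein"]
        e_fat, e_sugar, e_protein = (
            ATWATER_FAT * fat,
            ATWATER_SUGAR * sugar,
            ATWATER_PROTEIN * protein,
        )
        total = e_fat + e_sugar + e_protein
        if total <= 0:
            raise ValueError("zero energy intake; balance undefined")
        return MixturePoint(
            100.0 * e_fat / total, 100.0 * e_sugar / total, 100.0 * e_protein / total
        )
    if method == "convex":
        energy_by_stim: dict[str, float] = {}
        for t in session.trials:
            e = stimuli[t.chosen_stim].nutrient_intake(t.chosen_mag)["energy"]
            energy_by_stim[t.chosen_stim] = energy_by_stim.get(t.chosen_stim, 0.0) + e
        total = sum(energy_by_stim.values())
        if total <= 0:
            raise ValueError("zero energy intake; balance undefined")
        pf = ps = pp = 0.0
        for sid, e in energy_by_stim.items():
            mp = mixture_coordinates(stimuli[sid])
            w = e / total
            pf += w * mp.pct_fat
            ps += w * mp.pct_sugar
            pp += w * mp.pct_protein
        return MixturePoint(pf, ps, pp)
    raise ValueError("method must be 'intake' or 'convex'")


def project_reference(
    ref: ReferencePoint | MixturePoint,
    stim_a: Stimulus,
    stim_b: Stimulus,
) -> dict:
    """Project a reference composition onto the offered-reward segment.

    Orthogonal projection in the (pct_fat, pct_sugar) plane onto the
    segment from stimulus a to stimulus b, clamped to the endpoints;
    returns the projected point, the position t along the segment
    (0 = a, 1 = b), and the Euclidean residual distance.
    """
    point = ref.point if isinstance(ref, ReferencePoint) else ref
    pa = mixture_coordinates(stim_a).xy
    pb = mixture_coordinates(stim_b).xy
    seg = pb - pa
    seg_len2 = float(seg @ seg)
    if seg_len2 < 1e-18:
        raise ValueError("identical stimulus compositions; projection undefined")
    t = float((point.xy - pa) @ seg / seg_len2)
    t = min(max(t, 0.0), 1.0)
    proj_xy = pa + t * seg
    pct_protein = 100.0 - proj_xy[0] - proj_xy[1]
    projected = MixturePoint(float(proj_xy[0]), float(proj_xy[1]), float(pct_protein))
    distance = float(np.linalg.norm(point.xy - proj_xy))
    return {"projected": projected, "t": t, "distance": distance}


def balance_ellipse(balances: Sequence[MixturePoint], level: float = 0.95) -> dict:
    """95% confidence ellipse for the mean nutrient balance.

    Bivariate-normal ellipse in the (pct_fat, pct_sugar) plane at the
    chi-squared (2 df) quantile of the covariance of the mean.  Returns
    center, semi-axis lengths, orientation (degrees of the major axis)
    and a degeneracy flag for singular covariance.
    """
    if len(balances) < 3:
        raise ValueError("need >= 3 session balances")
    pts = np.array([b.xy for b in balances])
    n = len(pts)
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False) / n  # covariance of the mean
    q = scipy.stats.chi2.ppf(level, df=2)
    evals, evecs = np.linalg.eigh(cov)
    degenerate = bool(evals[0] <= 1e-12 * max(evals[1], 1.0))
    axes = np.sqrt(np.clip(evals, 0, None) * q)
    angle = float(np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1])))
    return {
        "center": center,
        "semi_axes": axes[::-1],  # major first
        "angle_deg": angle,
        "cov_mean": cov,
        "n": n,
        "degenerate": degenerate,
        "level": level,
    }


def ellipse_contains(ellipse: dict, point: np.ndarray) -> bool:
    """Whether a (pct_fat, pct_sugar) point lies inside a confidence ellipse."""
    d = np.asarray(point, float) - ellipse["center"]
    cov = ellipse["cov_mean"]
    md2 = float(d @ np.linalg.solve(cov, d))
    q = scipy.stats.chi2.ppf(ellipse["level"], df=2)
    return md2 <= q


def deviation_from_reference(
    balances: Sequence[MixturePoint] | MixturePoint,
    ref: ReferencePoint | MixturePoint,
    stim_low: Stimulus,
    stim_high: Stimulus,
) -> dict:
    """Signed deviation of realized balances from a projected reference.

    Both the balances and the reference are located along the segment
    from the low-nutrient to the high-nutrient stimulus; the deviation
    is (t_balance - t_reference) scaled to percentage-energy units of
    the dominant varying nutrient (the axis with the larger composition
    change).  Positive deviations point toward the high-nutrient
    stimulus.
    """
    if isinstance(balances, MixturePoint):
        balances = [balances]
    proj = project_reference(ref, stim_low, stim_high)
    pa = mixture_coordinates(stim_low).xy
    pb = mixture_coordinates(stim_high).xy
    seg = pb - pa
    axis = int(np.argmax(np.abs(seg)))  # 0 = fat, 1 = sugar
    scale = abs(seg[axis])
    devs = []
    for b in balances:
        t_b = float((b.xy - pa) @ seg / (seg @ seg))
        devs.append((t_b - proj["t"]) * scale)
    return {
        "deviations": np.asarray(devs),
        "mean_deviation": float(np.mean(devs)),
        "nutrient_axis": "fat" if axis == 0 else "sugar",
        "reference_t": proj["t"],
        "segment_span_pct": float(scale),
    }
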