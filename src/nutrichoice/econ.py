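"""Reward-space vs. nutrient-space economics.

A bundle of two rewards maps to a fat-sugar vector through a 2x2
nutrient-composition matrix (columns = rewards, rows = nutrient per
unit of reward).  Utility is defined on nutrient space only, so any
two reward sets that span the same nutrient space induce the same
preference ranking: transforming bundles from one reward space through
nutrient space into another (via an inverse composition matrix)
preserves the ranking by construction.  Indifference curves are level
sets of the utility, traceable in nutrient space or pulled back into a
reward space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class CompositionMatrix:
    """Nutrient content per unit of each of two rewards.

    ``matrix[i, j]`` is the amount of nutrient i (0 = fat, 1 = sugar)
    per unit of reward j.  Entries are non-negative; reverse transforms
    require invertibility (nutritionally distinguishable rewards).
    """

    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float)
        if self.matrix.shape != (2, 2):
            raise ValueError("composition matrix must be 2x2")
        if np.any(self.matrix < 0):
            raise ValueError("composition entries must be >= 0")

    @property
    def invertible(self) -> bool:
        return abs(np.linalg.det(self.matrix)) > 1e-12


@dataclass
class UtilityFunction:
    """Monotone utility over (fat, sugar) intake: linear or Cobb-Douglas."""

    form: str = "linear"
    w_fat: float = 1.0
    w_sugar: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in ("linear", "cobb_douglas"):
            raise ValueError("form must be 'linear' or 'cobb_douglas'")
        if self.w_fat <= 0 or self.w_sugar <= 0:
            raise ValueError("utility weights must be > 0")

    def __call__(self, nutrients: np.ndarray) -> np.ndarray:
        n = np.asarray(nutrients, float)
        fat, sugar = n[..., 0], n[..., 1]
        if self.form == "linear":
            return self.w_fat * fat + self.w_sugar * sugar
        return fat**self.w_fat * sugar**self.w_sugar


def bundle_to_nutrients(bundle: np.ndarray, M: CompositionMatrix) -> np.ndarray:
    """Nutrient vector n = M @ a for a bundle a of two reward amounts."""
    a = np.asarray(bundle, float)
    if np.any(a < 0):
        raise ValueError("bundle amounts must be >= 0")
    return M.matrix @ a


def nutrients_to_bundle(nutrients: np.ndarray, M_prime: CompositionMatrix) -> dict:
    """Bundle in a target reward space realizing a nutrient vector.

    a' = M'^{-1} n.  A negative component means the nutrient profile is
    unreachable with non-negative amounts of the target rewards; the
    result is returned with ``reachable=False`` rather than raised.
    """
    if not M_prime.invertible:
        raise ValueError("rewards nutritionally indistinguishable (singular composition matrix)")
    a = np.linalg.solve(M_prime.matrix, np.asarray(nutrients, float))
    return {"bundle": a, "reachable": bool(np.all(a >= -1e-10))}


def ranking_preserved(
    bundles: np.ndarray,
    M: CompositionMatrix,
    M_prime: CompositionMatrix,
    u: UtilityFunction,
) -> dict:
    """Verify that reward-space transforms preserve the preference ranking.

    Bundles in the source reward space are mapped to nutrient space
    (utilities computed there), then into the target reward space and
    back.  Because utility is a function of nutrient content alone and
    the transforms are exact inverses, the utilities — and hence the
    ranking — are identical before and after the round trip.
    """
    bundles = np.atleast_2d(np.asarray(bundles, float))
    nutrients = (M.matrix @ bundles.T).T
    utils_before = u(nutrients)
    target = np.array([nutrients_to_bundle(n, M_prime)["bundle"] for n in nutrients])
    nutrients_back = (M_prime.matrix @ target.T).T
    utils_after = u(nutrients_back)
    order_before = np.argsort(-utils_before, kind="stable")
    order_after = np.argsort(-utils_after, kind="stable")
    preserved = bool(
        np.allclose(utils_before, utils_after, rtol=1e-9, atol=1e-12)
        and np.array_equal(order_before, order_after)
    )
    return {
        "preserved": preserved,
        "utilities": utils_before,
        "utilities_roundtrip": utils_after,
        "ranking": order_before,
        "target_bundles": target,
        "nutrients": nutrients,
    }


def indifference_curves(
    u: UtilityFunction,
    utility_levels: np.ndarray,
    space: str = "nutrient",
    M: CompositionMatrix | None = None,
    fat_range: tuple[float, float] = (1e-3, 10.0),
    n_points: int = 200,
) -> dict[float, np.ndarray]:
    """Trace indifference curves as polylines.

    In nutrient space each level set is solved in closed form: linear
    utility gives parallel straight lines with slope -w_fat/w_sugar;
    Cobb-Douglas gives convex hyperbola-like curves.  In a reward space
    the nutrient-space polyline is pulled back through the inverse
    composition matrix (points outside the non-negative orthant are
    dropped).
    """
    levels = np.atleast_1d(np.asarray(utility_levels, float))
    if np.any(levels <= 0):
        raise ValueError("utility levels must be > 0")
    if space == "reward":
        if M is None:
            raise ValueError("a composition matrix is required for reward space")
        if not M.invertible:
            raise ValueError("rewards nutritionally indistinguishable (singular composition matrix)")
    elif space != "nutrient":
        raise ValueError("space must be 'nutrient' or 'reward(M)'")

    fat = np.linspace(fat_range[0], fat_range[1], n_points)
    curves = {}
    for c in levels:
        if u.form == "linear":
            sugar = (c - u.w_fat * fat) / u.w_sugar
        else:
            sugar = (c / fat**u.w_fat) ** (1.0 / u.w_sugar)
        pts = np.column_stack([fat, sugar])
        pts = pts[pts[:, 1] >= 0]
        if space == "reward":
            pts = (np.linalg.inv(M.matrix) @ pts.T).T
            pts = pts[np.all(pts >= -1e-12, axis=1)]
        curves[float(c)] = pts
    return curves
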