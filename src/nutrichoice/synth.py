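"""Synthetic choice-data generator.

Emulates a binary nutrient-choice task: an agent repeatedly chooses
between two liquid rewards from a 2x2 fat x sugar factorial stimulus
set, offered at pseudorandomly varying magnitudes.  The generative
choice model is log-linear in magnitude and nutrient content,

    log v = log(magnitude) + log rho(stimulus)
    log rho = w_fat * fat + w_sugar * sugar (+ interaction or texture terms)
    P(choose left) = logistic(tau * (log v_left - log v_right) + side_bias)

so that the indifference point for a stimulus pair is the pure value
ratio rho_target / rho_reference in closed form, and a trial-level
logistic regression on (dlog magnitude, dfat, dsugar) recovers
(tau, tau*w_fat, tau*w_sugar).  This generative model is the exact
inverse of the estimation models in :mod:`nutrichoice.values`.

Default stimulus levels are dairy-realistic: skimmed vs. whole milk fat
(0.1 vs. 3.6 g/100 mL), lactose-level vs. sweetened sugar chosen so the
high-fat/low-sugar and low-fat/high-sugar liquids are exactly
isocaloric (9*dfat = 4*dsugar), and constant milk protein (3.4 g/100 mL,
~20% of energy in the mid-energy stimuli).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from ._glm import sigmoid
from .datatypes import Session, Stimulus, Trial, stimulus_table

DEFAULT_FAT_LEVELS = (0.1, 3.6)  # g/100 mL, skimmed vs. whole milk
DEFAULT_SUGAR_LEVELS = (5.0, 12.875)  # g/100 mL; high level makes HFLS/LFHS isocaloric
DEFAULT_PROTEIN = 3.4  # g/100 mL, constant across stimuli
DEFAULT_MAGNITUDE_GRID = tuple(np.round(np.arange(0.1, 1.01, 0.1), 10))  # mL


@dataclass
class NutrientValueFunction:
    """Per-agent mapping from stimulus content to log relative value.

    Exactly one value mode is active: nutrient-driven (w_fat, w_sugar,
    w_interaction) or texture-driven (w_visc, w_csf, with sugar still
    valued directly through taste).  ``temperature`` is the inverse
    choice noise (softmax slope on log value differences); ``side_bias``
    is a logit offset toward the left option.  Optional choice-history
    feedback adds h_fat/h_sugar times an exponentially decaying count of
    recent high-fat/high-sugar choices to the logit.
    """

    agent_id: str
    w_fat: float = 0.0
    w_sugar: float = 0.0
    w_interaction: float = 0.0
    w_visc: float | None = None
    w_csf: float | None = None
    temperature: float = 1.0
    side_bias: float = 0.0
    h_fat: float = 0.0
    h_sugar: float = 0.0
    history_k: int = 5
    history_decay: float = 0.5

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError("temperature must be > 0")
        if self.texture_driven and (self.w_fat != 0.0 or self.w_interaction != 0.0):
            raise ValueError(
                "exactly one value mode may be active: texture-driven agents "
                "must not carry fat/interaction weights"
            )

    @property
    def texture_driven(self) -> bool:
        return self.w_visc is not None or self.w_csf is not None

    def log_rho(self, stim: Stimulus) -> float:
        """Log relative value per unit magnitude of a stimulus."""
        lr = self.w_sugar * stim.sugar
        if self.texture_driven:
            if self.w_visc is not None:
                if stim.viscosity is None:
                    raise ValueError(f"stimulus {stim.id!r} lacks viscosity for texture agent")
                lr += self.w_visc * stim.viscosity
            if self.w_csf is not None:
                if stim.csf is None:
                    raise ValueError(f"stimulus {stim.id!r} lacks csf for texture agent")
                lr += self.w_csf * stim.csf
        else:
            lr += self.w_fat * stim.fat + self.w_interaction * stim.fat * stim.sugar
        return lr

    def rho_ratio(self, target: Stimulus, reference: Stimulus) -> float:
        """Generative indifference point for reference-vs-target offers."""
        return math.exp(self.log_rho(target) - self.log_rho(reference))

    def truth(self) -> dict:
        """Ground-truth parameters for recovery tests (JSON-safe)."""
        return {
            "agent_id": self.agent_id,
            "w_fat": self.w_fat,
            "w_sugar": self.w_sugar,
            "w_interaction": self.w_interaction,
            "w_visc": self.w_visc,
            "w_csf": self.w_csf,
            "temperature": self.temperature,
            "side_bias": self.side_bias,
            "h_fat": self.h_fat,
            "h_sugar": self.h_sugar,
        }


@dataclass
class TextureModel:
    """Viscosity and sliding friction as affine functions of fat content.

    Viscosity (mPa·s) rises with fat; the water-normalised coefficient
    of sliding friction falls (high fat is slippery).  Gaussian noise of
    scale ``noise_visc`` / ``noise_csf`` emulates measurement error.
    """

    visc_intercept: float = 1.0
    visc_slope: float = 0.35
    csf_intercept: float = 1.0
    csf_slope: float = -0.055
    noise_visc: float = 0.0
    noise_csf: float = 0.0

    def __post_init__(self) -> None:
        if self.visc_slope < 0:
            raise ValueError("viscosity slope must be >= 0")
        if self.csf_slope > 0:
            raise ValueError("csf slope must be <= 0 (high fat is slippery)")


DEFAULT_TEXTURE_MODEL = TextureModel()


def make_factorial_stimuli(
    fat_levels: Sequence[float] = DEFAULT_FAT_LEVELS,
    sugar_levels: Sequence[float] = DEFAULT_SUGAR_LEVELS,
    protein: float = DEFAULT_PROTEIN,
    flavor: str = "peach",
    id_prefix: str = "",
) -> dict[str, Stimulus]:
    """Build the 2x2 fat x sugar factorial stimulus set (LFLS/HFLS/LFHS/HFHS)."""
    fat_lo, fat_hi = fat_levels
    sug_lo, sug_hi = sugar_levels
    if not (fat_lo < fat_hi and sug_lo < sug_hi):
        raise ValueError("levels must be ordered low < high")
    codes = {
        "LFLS": (fat_lo, sug_lo),
        "HFLS": (fat_hi, sug_lo),
        "LFHS": (fat_lo, sug_hi),
        "HFHS": (fat_hi, sug_hi),
    }
    stimuli = []
    for code, (fat, sugar) in codes.items():
        stimuli.append(
            Stimulus(
                id=id_prefix + code,
                flavor=flavor,
                fat=fat,
                sugar=sugar,
                protein=protein,
                fat_level="high" if fat == fat_hi else "low",
                sugar_level="high" if sugar == sug_hi else "low",
            )
        )
    return stimulus_table(stimuli)


def make_texture_battery(
    n_stimuli: int = 13,
    fat_range: tuple[float, float] = (0.0, 10.0),
    sugar_levels: Sequence[float] = (5.0, 12.875),
    protein: float = DEFAULT_PROTEIN,
    flavor: str = "peach",
    seed: int | None = None,
    id_prefix: str = "T",
) -> dict[str, Stimulus]:
    """A wider stimulus battery spanning many fat concentrations.

    Emulates the kind of measurement set used for texture regressions
    (factorial liquids plus creams, juices and water): fat varies over
    ``fat_range`` on an even grid while sugar alternates between the
    given levels, so fat and sugar are uncorrelated by design and the
    texture-on-fat slope is identifiable.
    """
    rng = np.random.default_rng(seed)
    fats = np.linspace(fat_range[0], fat_range[1], n_stimuli)
    sugars = np.array([sugar_levels[i % len(sugar_levels)] for i in range(n_stimuli)])
    rng.shuffle(sugars)
    stimuli = []
    for i in range(n_stimuli):
        stimuli.append(
            Stimulus(
                id=f"{id_prefix}{i:02d}",
                flavor=flavor,
                fat=float(fats[i]),
                sugar=float(sugars[i]),
                protein=protein,
                fat_level="high" if fats[i] > np.median(fats) else "low",
                sugar_level="high" if sugars[i] > np.median(sugars) else "low",
            )
        )
    return stimulus_table(stimuli)


def apply_texture(
    stimuli: dict[str, Stimulus],
    texture_model: TextureModel = DEFAULT_TEXTURE_MODEL,
    seed: int | None = None,
) -> dict[str, Stimulus]:
    """Attach viscosity and CSF values, affine in fat content plus noise."""
    rng = np.random.default_rng(seed)
    out = {}
    for sid, s in stimuli.items():
        visc = texture_model.visc_intercept + texture_model.visc_slope * s.fat
        csf = texture_model.csf_intercept + texture_model.csf_slope * s.fat
        if texture_model.noise_visc > 0:
            visc += rng.normal(0, texture_model.noise_visc)
        if texture_model.noise_csf > 0:
            csf += rng.normal(0, texture_model.noise_csf)
        out[sid] = Stimulus(
            id=s.id,
            flavor=s.flavor,
            fat=s.fat,
            sugar=s.sugar,
            protein=s.protein,
            fat_level=s.fat_level,
            sugar_level=s.sugar_level,
            viscosity=max(visc, 1e-3),
            csf=max(csf, 1e-3),
        )
    return out


def _history_signs(a: Stimulus, b: Stimulus) -> tuple[float, float]:
    """Direction of the left option in the fat and sugar dimensions."""
    s_fat = float(np.sign(a.fat - b.fat))
    s_sugar = float(np.sign(a.sugar - b.sugar))
    return s_fat, s_sugar


def simulate_session(
    value_fn: NutrientValueFunction,
    stim_pair: tuple[Stimulus, Stimulus],
    n_trials: int,
    magnitude_grid: Sequence[float] = DEFAULT_MAGNITUDE_GRID,
    seed: int | None = None,
    session_id: str = "sim",
) -> Session:
    """Simulate one session of binary choices for a stimulus pair.

    Offered magnitudes are drawn uniformly from ``magnitude_grid``; the
    left/right placement of the two stimuli is counterbalanced
    pseudorandomly (exactly half the trials each way, order shuffled).
    A fixed seed reproduces the session exactly.
    """
    if len(magnitude_grid) == 0:
        raise ValueError("magnitude_grid must be non-empty")
    grid = np.asarray(magnitude_grid, float)
    rng = np.random.default_rng(seed)
    stim_a, stim_b = stim_pair
    # counterbalanced: stim_a on the left on exactly half the trials
    a_left = np.zeros(n_trials, bool)
    a_left[: n_trials // 2] = True
    rng.shuffle(a_left)
    mags = grid[rng.integers(0, len(grid), size=(n_trials, 2))]
    log_rho_a = value_fn.log_rho(stim_a)
    log_rho_b = value_fn.log_rho(stim_b)
    lr_left = np.where(a_left, log_rho_a, log_rho_b)
    lr_right = np.where(a_left, log_rho_b, log_rho_a)
    dlogv = np.log(mags[:, 0]) + lr_left - (np.log(mags[:, 1]) + lr_right)
    tau = value_fn.temperature
    u = rng.random(n_trials)
    use_history = value_fn.h_fat != 0.0 or value_fn.h_sugar != 0.0
    if not use_history:
        if math.isinf(tau):
            p_left = np.where(dlogv > 0, 1.0, np.where(dlogv < 0, 0.0, 0.5))
        else:
            p_left = sigmoid(tau * dlogv + value_fn.side_bias)
        chose_left = u < p_left
    else:
        s_fat_a, s_sugar_a = _history_signs(stim_a, stim_b)
        decay = value_fn.history_decay ** np.arange(value_fn.history_k)
        fat_hist = np.zeros(value_fn.history_k)  # +1 chose fat side, -1 chose other
        sugar_hist = np.zeros(value_fn.history_k)
        chose_left = np.zeros(n_trials, bool)
        for t in range(n_trials):
            s_fat_left = s_fat_a if a_left[t] else -s_fat_a
            s_sugar_left = s_sugar_a if a_left[t] else -s_sugar_a
            hist_term = value_fn.h_fat * float(decay @ fat_hist) * s_fat_left
            hist_term += value_fn.h_sugar * float(decay @ sugar_hist) * s_sugar_left
            logit = tau * dlogv[t] + value_fn.side_bias + hist_term
            p = 1.0 if logit > 0 else 0.0 if logit < 0 else 0.5
            if not math.isinf(tau):
                p = float(sigmoid(np.array(logit)))
            chose_left[t] = u[t] < p
            chose_a = chose_left[t] == a_left[t]
            fat_hist = np.roll(fat_hist, 1)
            sugar_hist = np.roll(sugar_hist, 1)
            fat_hist[0] = s_fat_a if chose_a else -s_fat_a
            sugar_hist[0] = s_sugar_a if chose_a else -s_sugar_a
    trials = [
        Trial(
            session_id=session_id,
            index=t,
            stim_left=stim_a.id if a_left[t] else stim_b.id,
            stim_right=stim_b.id if a_left[t] else stim_a.id,
            mag_left=float(mags[t, 0]),
            mag_right=float(mags[t, 1]),
            choice="left" if chose_left[t] else "right",
        )
        for t in range(n_trials)
    ]
    return Session(
        id=session_id,
        agent_id=value_fn.agent_id,
        flavor=stim_a.flavor,
        trials=trials,
        meta={"seed": seed, "stim_pair": (stim_a.id, stim_b.id)},
    )


def make_dataset(
    agents: Sequence[NutrientValueFunction],
    schedule: Sequence[tuple[tuple[Stimulus, Stimulus], int]],
    seed: int | None = None,
    magnitude_grid: Sequence[float] = DEFAULT_MAGNITUDE_GRID,
) -> list[Session]:
    """One session per schedule entry per agent, with per-session child seeds.

    Child seeds derive deterministically from the master seed via
    ``numpy.random.SeedSequence.spawn``, so the full dataset is
    reproducible and sessions are pairwise independent.
    """
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(agents) * len(schedule))
    sessions = []
    k = 0
    for agent in agents:
        for i, (pair, n_trials) in enumerate(schedule):
            child_seed = int(children[k].generate_state(1)[0] % (2**31))
            sessions.append(
                simulate_session(
                    agent,
                    pair,
                    n_trials,
                    magnitude_grid=magnitude_grid,
                    seed=child_seed,
                    session_id=f"{agent.agent_id}_s{i:03d}",
                )
            )
            k += 1
    return sessions
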