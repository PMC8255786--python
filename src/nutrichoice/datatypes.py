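"""Core domain types for nutrient-choice experiments.

The experimental unit is a binary choice trial between two liquid rewards
("stimuli") that differ in macronutrient composition (fat, sugar, protein,
in g/100 mL) and, optionally, in measured oral-texture properties
(viscosity in mPa·s and the water-normalised coefficient of sliding
friction, CSF).  Trials are grouped into sessions, one stimulus pair per
session, with reward magnitudes (mL) varying from trial to trial.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Sequence

# Atwater energy factors, kcal per gram of fat / carbohydrate / protein.
ATWATER_FAT = 9.0
ATWATER_SUGAR = 4.0
ATWATER_PROTEIN = 4.0


def energy_density(fat: float, sugar: float, protein: float) -> float:
    """Energy density in kcal/mL for concentrations given in g/100 mL."""
    return (ATWATER_FAT * fat + ATWATER_SUGAR * sugar + ATWATER_PROTEIN * protein) / 100.0


@dataclass
class Stimulus:
    """A nutrient-defined liquid reward.

    Concentrations are g per 100 mL.  ``energy_density`` (kcal/mL) is
    derived from the Atwater factors (9/4/4 kcal per g of
    fat/carbohydrate/protein) when not supplied.  ``viscosity`` (mPa·s)
    and ``csf`` (dimensionless, water-normalised sliding friction) are
    optional texture measurements.
    """

    id: str
    flavor: str = ""
    fat: float = 0.0
    sugar: float = 0.0
    protein: float = 0.0
    fat_level: str | None = None
    sugar_level: str | None = None
    energy_density: float | None = None
    viscosity: float | None = None
    csf: float | None = None

    def __post_init__(self) -> None:
        for name in ("fat", "sugar", "protein"):
            if getattr(self, name) < 0:
                raise ValueError(f"stimulus {self.id!r}: negative {name} concentration")
        if self.energy_density is None:
            self.energy_density = energy_density(self.fat, self.sugar, self.protein)
        if self.csf is not None and self.csf <= 0:
            raise ValueError(f"stimulus {self.id!r}: csf must be positive when present")

    def nutrient_intake(self, magnitude_ml: float) -> dict[str, float]:
        """Grams of each nutrient and kcal delivered by ``magnitude_ml`` mL."""
        return {
            "fat": magnitude_ml * self.fat / 100.0,
            "sugar": magnitude_ml * self.sugar / 100.0,
            "protein": magnitude_ml * self.protein / 100.0,
            "energy": magnitude_ml * self.energy_density,
        }


@dataclass
class Trial:
    """One binary choice between two offered magnitudes of two stimuli."""

    session_id: str
    index: int
    stim_left: str
    stim_right: str
    mag_left: float
    mag_right: float
    choice: str  # "left" or "right"

    def __post_init__(self) -> None:
        if self.index < 0:
            raise ValueError("trial index must be >= 0")
        if self.mag_left <= 0 or self.mag_right <= 0:
            raise ValueError(
                f"trial {self.session_id}/{self.index}: magnitudes must be strictly positive"
            )
        if self.choice not in ("left", "right"):
            raise ValueError(f"trial {self.session_id}/{self.index}: choice must be left/right")

    @property
    def chosen_stim(self) -> str:
        return self.stim_left if self.choice == "left" else self.stim_right

    @property
    def chosen_mag(self) -> float:
        return self.mag_left if self.choice == "left" else self.mag_right


@dataclass
class Session:
    """An ordered run of trials for one agent and one stimulus pair."""

    id: str
    agent_id: str = ""
    flavor: str = ""
    trials: list[Trial] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, t in enumerate(self.trials):
            if t.index != i:
                raise ValueError(
                    f"session {self.id!r}: trial indices must be contiguous from 0 "
                    f"(found {t.index} at position {i})"
                )

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def stimulus_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for t in self.trials:
            seen.setdefault(t.stim_left)
            seen.setdefault(t.stim_right)
        return tuple(seen)


StimulusTable = Mapping[str, Stimulus]


def stimulus_table(stimuli: Iterable[Stimulus]) -> dict[str, Stimulus]:
    """Index stimuli by id, rejecting duplicates."""
    table: dict[str, Stimulus] = {}
    for s in stimuli:
        if s.id in table:
            raise ValueError(f"duplicate stimulus id {s.id!r}")
        table[s.id] = s
    return table


def validate_sessions(sessions: Sequence[Session], stimuli: StimulusTable) -> None:
    """Check that every trial references a known stimulus."""
    for sess in sessions:
        for sid in sess.stimulus_ids:
            if sid not in stimuli:
                raise ValueError(f"session {sess.id!r} references unknown stimulus {sid!r}")


@dataclass
class RunConfig:
    """Analysis run configuration; the seed is recorded in all outputs."""

    seed: int = 0
    paths: dict = field(default_factory=dict)
    n_bootstrap: int = 1000
    cv_folds: int = 10
    n_bins: int = 10
    options: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
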