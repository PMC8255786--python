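"""Shared fixtures: stimulus sets and toy sessions built programmatically."""

from __future__ import annotations

import pytest

from nutrichoice.datatypes import Session, Stimulus, Trial
from nutrichoice import synth


@pytest.fixture(scope="session")
def factorial_stimuli() -> dict[str, Stimulus]:
    """Default 2x2 fat x sugar factorial set (HFLS/LFHS isocaloric)."""
    return synth.make_factorial_stimuli()


@pytest.fixture(scope="session")
def textured_stimuli(factorial_stimuli) -> dict[str, Stimulus]:
    """Factorial set with noise-free affine texture values."""
    return synth.apply_texture(factorial_stimuli, synth.TextureModel(), seed=0)


def build_session(
    trial_specs: list[tuple[str, str, float, float, str]],
    session_id: str = "toy",
    agent_id: str = "toy_agent",
) -> Session:
    """Build a session from (stim_left, stim_right, mag_left, mag_right, choice) tuples."""
    trials = [
        Trial(
            session_id=session_id,
            index=i,
            stim_left=sl,
            stim_right=sr,
            mag_left=ml,
            mag_right=mr,
            choice=ch,
        )
        for i, (sl, sr, ml, mr, ch) in enumerate(trial_specs)
    ]
    return Session(id=session_id, agent_id=agent_id, trials=trials)


@pytest.fixture(scope="session")
def toy_hfls_session() -> Session:
    """Fixed 4-trial session: agent always chooses HFLS against LFLS offers."""
    return build_session(
        [
            ("HFLS", "LFLS", 1.0, 2.0, "left"),
            ("LFLS", "HFLS", 2.0, 1.0, "right"),
            ("HFLS", "LFLS", 1.0, 2.0, "left"),
            ("LFLS", "HFLS", 2.0, 1.0, "right"),
        ]
    )
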