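"""Readers and writers for trial, stimulus and configuration files.

Trial files are comma-delimited UTF-8 with a header; stimulus tables are
accepted as CSV or JSON; run configuration as YAML or JSON.  All
downstream analysis modules consume the in-memory types from
:mod:`nutrichoice.datatypes` — no analysis stage reads files directly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .datatypes import RunConfig, Session, Stimulus, Trial, stimulus_table

TRIAL_COLUMNS = ["session_id", "trial", "stim_left", "stim_right", "mag_left", "mag_right", "choice"]
STIMULUS_FIELDS = [f.name for f in dataclasses.fields(Stimulus)]


class FormatError(ValueError):
    """A file does not match the expected schema."""


def read_trials(path: str | Path) -> list[Session]:
    """Read a trial CSV into sessions ordered by trial index.

    Required columns: session_id, trial, stim_left, stim_right,
    mag_left, mag_right, choice.  Optional columns ``agent_id`` and
    ``flavor`` populate the session metadata; any other extra columns
    are preserved in ``Session.meta['extra_columns']``.
    """
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial file {path}: missing required column(s) {', '.join(missing)}")
    bad = df.index[(df["mag_left"] <= 0) | (df["mag_right"] <= 0)]
    if len(bad):
        # +2: header line plus 1-based row numbering, matching what a user sees in the file
        raise FormatError(f"trial file {path}: non-positive magnitude on row {bad[0] + 2}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS + ["agent_id", "flavor"]]
    sessions = []
    for sid, grp in df.groupby("session_id", sort=False):
        grp = grp.sort_values("trial")
        trials = [
            Trial(
                session_id=str(sid),
                index=int(r.trial),
                stim_left=str(r.stim_left),
                stim_right=str(r.stim_right),
                mag_left=float(r.mag_left),
                mag_right=float(r.mag_right),
                choice=str(r.choice),
            )
            for r in grp.itertuples()
        ]
        meta = {}
        if extra:
            meta["extra_columns"] = grp[extra].reset_index(drop=True)

        def _opt(col: str) -> str:
            if col not in grp or pd.isna(grp[col].iloc[0]):
                return ""
            return str(grp[col].iloc[0])

        sessions.append(
            Session(
                id=str(sid),
                agent_id=_opt("agent_id"),
                flavor=_opt("flavor"),
                trials=trials,
                meta=meta,
            )
        )
    return sessions


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    """Flatten sessions to one row per trial."""
    rows = []
    for sess in sessions:
        for t in sess.trials:
            rows.append(
                {
                    "session_id": sess.id,
                    "agent_id": sess.agent_id,
                    "flavor": sess.flavor,
                    "trial": t.index,
                    "stim_left": t.stim_left,
                    "stim_right": t.stim_right,
                    "mag_left": t.mag_left,
                    "mag_right": t.mag_right,
                    "choice": t.choice,
                }
            )
    return pd.DataFrame(rows)


def write_trials(sessions: Sequence[Session], path: str | Path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_stimuli(path: str | Path, isocaloric_tol: float = 1e-6) -> dict[str, Stimulus]:
    """Read a stimulus table from CSV or JSON.

    Energy density is filled from the Atwater formula when absent.
    Isocaloric pairs (|Δ energy density| < ``isocaloric_tol`` kcal/mL)
    are recorded on each stimulus-table entry via
    :func:`isocaloric_pairs`.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        if isinstance(records, dict):
            records = list(records.values())
    else:
        df = pd.read_csv(path)
        records = df.to_dict("records")
    stimuli = []
    for rec in records:
        kwargs = {k: v for k, v in rec.items() if k in STIMULUS_FIELDS and not pd.isna(v)}
        stimuli.append(Stimulus(**kwargs))
    return stimulus_table(stimuli)


def write_stimuli(stimuli: dict[str, Stimulus], path: str | Path) -> None:
    path = Path(path)
    records = [dataclasses.asdict(s) for s in stimuli.values()]
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(records, indent=2))
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def isocaloric_pairs(
    stimuli: dict[str, Stimulus], tol: float = 1e-6
) -> list[tuple[str, str]]:
    """All unordered stimulus pairs matched in energy density within ``tol``."""
    ids = list(stimuli)
    pairs = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if abs(stimuli[a].energy_density - stimuli[b].energy_density) < tol:
                pairs.append((a, b))
    return pairs


def read_config(path: str | Path) -> RunConfig:
    """Load run configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    known = {f.name for f in dataclasses.fields(RunConfig)}
    kwargs = {k: v for k, v in data.items() if k in known}
    kwargs.setdefault("options", {})
    kwargs["options"].update({k: v for k, v in data.items() if k not in known})
    return RunConfig(**kwargs)
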