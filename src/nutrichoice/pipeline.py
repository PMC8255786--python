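"""End-to-end pipeline: simulate -> fit -> cross-predict -> mediate ->
strategy -> geometry -> rl-sim -> econ-map.

Each stage reads its inputs from files written by earlier stages and
writes CSV/JSON outputs plus a log line, so stages can be re-run and
inspected independently.  A single master seed drives every source of
randomness; rerunning with the same config and seed reproduces all
outputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import RunConfig, Session, stimulus_table
from .io import read_stimuli, read_trials, write_stimuli, write_trials
from . import crosspred, econ, geometry, mediation, rl, strategy, synth, values

STAGES = ["simulate", "fit", "cross_predict", "mediate", "strategy", "geometry", "rl_sim", "econ_map"]


@dataclasses.dataclass
class PipelineReport:
    seed: int
    config_hash: str
    version: str
    outputs: dict
    summaries: dict
    stages_run: list


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline halted at stage {stage!r}: {cause}")
        self.stage = stage
        self.cause = cause


def default_agents() -> list[synth.NutrientValueFunction]:
    """Three nutrient-driven agents with individually different weights.

    All prefer sugar over fat per gram (sugar weights exceed fat
    weights), with one agent markedly more sugar-driven — the pattern
    of individual differences the cross-prediction stage quantifies.
    """
    return [
        synth.NutrientValueFunction("A1", w_fat=0.10, w_sugar=0.16, temperature=2.0),
        synth.NutrientValueFunction("A2", w_fat=0.06, w_sugar=0.30, temperature=2.0),
        synth.NutrientValueFunction("A3", w_fat=0.14, w_sugar=0.10, temperature=2.0),
    ]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    if isinstance(o, pd.Series):
        return o.to_dict()
    return str(o)


def _dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, default=_json_default))


def stage_simulate(config: RunConfig, out: Path) -> dict:
    opts = config.options
    n_trials = int(opts.get("n_trials", 200))
    n_sessions = int(opts.get("n_sessions_per_pair", 2))
    agents = default_agents()
    stims = synth.apply_texture(synth.make_factorial_stimuli(), seed=config.seed)
    pairs = [("LFLS", "HFLS"), ("LFLS", "LFHS"), ("HFLS", "LFHS"), ("LFLS", "HFHS")]
    schedule = [((stims[a], stims[b]), n_trials) for a, b in pairs for _ in range(n_sessions)]
    sessions = synth.make_dataset(agents, schedule, seed=config.seed)

    # texture battery for the mediation stage, driven by a texture agent
    # texture measurement noise ~10-15% of the battery's texture range:
    # per-stimulus deviations from the affine texture-fat line are what
    # make the fat and friction paths separately identifiable
    battery = synth.apply_texture(
        synth.make_texture_battery(seed=config.seed),
        synth.TextureModel(noise_visc=0.5, noise_csf=0.0825),
        seed=config.seed + 1,
    )
    tex_agent = synth.NutrientValueFunction(
        "TX", w_sugar=0.12, w_csf=-6.0, w_visc=0.0, temperature=1.0
    )
    ids = sorted(battery)
    rng = np.random.default_rng(config.seed + 2)
    tex_pairs = [tuple(rng.choice(ids, 2, replace=False)) for _ in range(20)]
    tex_schedule = [((battery[a], battery[b]), n_trials) for a, b in tex_pairs]
    sessions += synth.make_dataset([tex_agent], tex_schedule, seed=config.seed + 3)

    all_stims = {**stims, **battery}
    write_trials(sessions, out / "trials.csv")
    write_stimuli(all_stims, out / "stimuli.csv")
    _dump({a.agent_id: a.truth() for a in agents + [tex_agent]}, out / "truth.json")
    return {
        "outputs": {"trials": out / "trials.csv", "stimuli": out / "stimuli.csv"},
        "summary": {"n_sessions": len(sessions), "n_trials_total": sum(len(s) for s in sessions)},
    }


def _load(out: Path) -> tuple[list[Session], dict]:
    return read_trials(out / "trials.csv"), read_stimuli(out / "stimuli.csv")


def _agent_sessions(sessions: Sequence[Session]) -> dict[str, list[Session]]:
    by: dict[str, list[Session]] = {}
    for s in sessions:
        by.setdefault(s.agent_id, []).append(s)
    return by


def stage_fit(config: RunConfig, out: Path) -> dict:
    sessions, stims = _load(out)
    by_agent = _agent_sessions(sessions)
    results = {}
    for agent_id, sess in by_agent.items():
        if agent_id == "TX":
            continue
        entry = {"psychometric": {}, "nutrient_model": {}}
        for target in ("HFLS", "LFHS", "HFHS"):
            try:
                fit = values.psychometric_fit(
                    sess, "LFLS", target, n_bootstrap=config.n_bootstrap, seed=config.seed
                )
                entry["psychometric"][target] = dataclasses.asdict(fit)
            except ValueError:
                continue
        model = values.fit_nutrient_model(sess, stims, session_effects="fixed")
        entry["nutrient_model"] = {
            "params": model.params.to_dict(),
            "bse": model.bse.to_dict(),
            "llf": model.llf,
            "aic": model.aic,
            "pseudo_r2": model.pseudo_r2,
        }
        results[agent_id] = entry
    _dump(results, out / "fits.json")
    return {"outputs": {"fits": out / "fits.json"}, "summary": {"agents": list(results)}}


def stage_cross_predict(config: RunConfig, out: Path) -> dict:
    sessions, stims = _load(out)
    by_agent = {k: v for k, v in _agent_sessions(sessions).items() if k != "TX"}
    ids = sorted(by_agent)
    models = {a: values.fit_nutrient_model(by_agent[a], stims) for a in ids}
    rows = []
    pdis = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            res = crosspred.pdi(models[a], by_agent[a], models[b], by_agent[b], stims, a, b)
            pdis[(a, b)] = res.pdi
            contrib = crosspred.pdi_contribution(by_agent[a], by_agent[b], stims)
            rows.append(
                {
                    "agent_i": a,
                    "agent_j": b,
                    "pdi": res.pdi,
                    **{k: v for k, v in contrib.items() if k.startswith("pct_")},
                }
            )
    pd.DataFrame(rows).to_csv(out / "pdi.csv", index=False)
    summary: dict = {"pdi": {f"{a}-{b}": v for (a, b), v in pdis.items()}}
    if len(ids) == 3:
        layout = crosspred.triangle_layout(
            pdis[(ids[0], ids[1])], pdis[(ids[0], ids[2])], pdis[(ids[1], ids[2])]
        )
        summary["triangle_degenerate"] = layout["degenerate"]
    return {"outputs": {"pdi": out / "pdi.csv"}, "summary": summary}


def stage_mediate(config: RunConfig, out: Path) -> dict:
    sessions, stims = _load(out)
    tex_sessions = _agent_sessions(sessions).get("TX", [])
    tex_stims = stimulus_table(
        [s for s in stims.values() if s.viscosity is not None and s.id.startswith("T")]
    )
    path = mediation.mediation_fit(
        tex_sessions, tex_stims, n_bootstrap=config.n_bootstrap, seed=config.seed
    )
    _dump(
        {
            "c": path.c,
            "c_prime": path.c_prime,
            "b": path.b,
            "indirect": path.indirect,
            "ci": {k: list(v) for k, v in path.ci.items()},
            "verdict": path.verdict,
            "a": {f"{t}_on_{n}": v for (t, n), v in path.a.items()},
        },
        out / "mediation.json",
    )
    return {"outputs": {"mediation": out / "mediation.json"}, "summary": {"verdict": path.verdict}}


def stage_strategy(config: RunConfig, out: Path) -> dict:
    sessions, stims = _load(out)
    by_agent = {k: v for k, v in _agent_sessions(sessions).items() if k != "TX"}
    iso = [
        s
        for sess_list in by_agent.values()
        for s in sess_list
        if set(s.stimulus_ids) == {"HFLS", "LFHS"}
    ]
    rows = []
    for sess in iso:
        traj = strategy.cumulative_trajectory(sess, stims)
        polar = strategy.to_nutrient_polar(traj)
        rows.append(
            {
                "session": sess.id,
                "agent": sess.agent_id,
                "final_angle_deg": polar["angle_deg"].iloc[-1],
                "final_energy_kcal": traj["energy_kcal"].iloc[-1],
            }
        )
    pd.DataFrame(rows).to_csv(out / "trajectories.csv", index=False)
    comparisons = {}
    for agent_id, sess_list in by_agent.items():
        comp = strategy.compare_energy_vs_nutrient(sess_list, stims)
        comparisons[agent_id] = {k: comp[k] for k in ("AIC_energy", "AIC_nutrient", "delta_AIC")}
    iso_test = strategy.isocaloric_coefficient_test(iso, stims) if len(iso) >= 6 else None
    _dump(
        {
            "model_comparison": comparisons,
            "isocaloric_test": None
            if iso_test is None
            else {k: iso_test[k] for k in ("median_delta_coef", "wilcoxon_p", "n_sessions")},
        },
        out / "strategy.json",
    )
    return {
        "outputs": {"trajectories": out / "trajectories.csv", "strategy": out / "strategy.json"},
        "summary": {"delta_AIC": {a: c["delta_AIC"] for a, c in comparisons.items()}},
    }


def stage_geometry(config: RunConfig, out: Path) -> dict:
    sessions, stims = _load(out)
    refs = config.options.get(
        "reference_points",
        {"optimal_diet": [15.0, 60.0, 25.0], "macaque_milk": [50.0, 35.0, 15.0]},
    )
    ref_points = {
        name: geometry.ReferencePoint(name, geometry.MixturePoint(*vals))
        for name, vals in refs.items()
    }
    rows = []
    balances_by_pair: dict[tuple[str, str], list] = {}
    for sess in sessions:
        if sess.agent_id == "TX":
            continue
        bal = geometry.choice_balance(sess, stims)
        pair = tuple(sorted(sess.stimulus_ids))
        balances_by_pair.setdefault(pair, []).append(bal)
        rows.append(
            {
                "session": sess.id,
                "agent": sess.agent_id,
                "pair": "-".join(pair),
                "pct_fat": bal.pct_fat,
                "pct_sugar": bal.pct_sugar,
                "pct_protein": bal.pct_protein,
            }
        )
    pd.DataFrame(rows).to_csv(out / "balances.csv", index=False)
    ellipses = {}
    deviations = {}
    for pair, balances in balances_by_pair.items():
        if len(balances) >= 3:
            e = geometry.balance_ellipse(balances)
            ellipses["-".join(pair)] = {
                "center": e["center"],
                "semi_axes": e["semi_axes"],
                "angle_deg": e["angle_deg"],
                "degenerate": e["degenerate"],
            }
        a, b = pair
        low, high = (a, b) if stims[a].energy_density <= stims[b].energy_density else (b, a)
        if abs(stims[low].energy_density - stims[high].energy_density) < 1e-9:
            low, high = sorted(pair)
        try:
            dev = geometry.deviation_from_reference(
                balances, ref_points["optimal_diet"], stims[low], stims[high]
            )
            deviations["-".join(pair)] = {
                "mean_deviation": dev["mean_deviation"],
                "nutrient_axis": dev["nutrient_axis"],
            }
        except ValueError:
            continue
    _dump({"ellipses": ellipses, "deviation_from_optimal": deviations}, out / "geometry.json")
    return {
        "outputs": {"balances": out / "balances.csv", "geometry": out / "geometry.json"},
        "summary": {"n_pairs": len(balances_by_pair)},
    }


def stage_rl_sim(config: RunConfig, out: Path) -> dict:
    opts = config.options
    schedule = rl.ReversalSchedule(
        n_trials=int(opts.get("rl_trials", 100)),
        p_high_pre=float(opts.get("p_high_pre", 0.6)),
        p_high_post=float(opts.get("p_high_post", 0.4)),
    )
    n_reps = int(opts.get("rl_reps", 1000))
    results = {}
    curves = {}
    for label, eta in (("standard", 0.0), ("nutrient_sensitive", float(opts.get("eta", 0.2)))):
        params = rl.RLAgentParams(
            alpha=float(opts.get("alpha", 0.2)), beta=float(opts.get("beta", 5.0)), eta=eta
        )
        res = rl.simulate_reversal(params, schedule, n_reps=n_reps, seed=config.seed)
        results[label] = {
            "mean_R": res["mean_R"],
            "mean_N": res["mean_N"],
            "switch_latency": res["switch_latency"],
            "eta": eta,
        }
        curves[label] = res["choice_curve"]
    pd.DataFrame(curves).to_csv(out / "rl_curves.csv", index=False)
    _dump(results, out / "rl_summary.json")
    return {
        "outputs": {"curves": out / "rl_curves.csv", "summary": out / "rl_summary.json"},
        "summary": results,
    }


def stage_econ_map(config: RunConfig, out: Path) -> dict:
    M = econ.CompositionMatrix(np.array(config.options.get("M", [[3.0, 0.5], [1.0, 4.0]])))
    M2 = econ.CompositionMatrix(np.array(config.options.get("M_prime", [[1.0, 2.0], [3.0, 1.0]])))
    u = econ.UtilityFunction(form=config.options.get("utility", "cobb_douglas"), w_fat=0.4, w_sugar=0.6)
    bundles = np.array([[1.0, 0.5], [0.4, 0.8], [0.8, 0.2], [0.2, 0.3]])
    res = econ.ranking_preserved(bundles, M, M2, u)
    curves = econ.indifference_curves(u, np.quantile(res["utilities"], [0.25, 0.5, 0.75]))
    rows = []
    for level, pts in curves.items():
        for fat, sugar in pts:
            rows.append({"utility": level, "fat": fat, "sugar": sugar})
    pd.DataFrame(rows).to_csv(out / "indifference_curves.csv", index=False)
    _dump(
        {
            "preserved": res["preserved"],
            "utilities": res["utilities"],
            "ranking": res["ranking"],
        },
        out / "econ.json",
    )
    return {
        "outputs": {"curves": out / "indifference_curves.csv", "econ": out / "econ.json"},
        "summary": {"ranking_preserved": res["preserved"]},
    }


_STAGE_FUNCS: dict[str, Callable[[RunConfig, Path], dict]] = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "cross_predict": stage_cross_predict,
    "mediate": stage_mediate,
    "strategy": stage_strategy,
    "geometry": stage_geometry,
    "rl_sim": stage_rl_sim,
    "econ_map": stage_econ_map,
}


def run_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    stages: Sequence[str] | None = None,
) -> PipelineReport:
    """Execute the requested stages in dependency order.

    A stage failure halts the pipeline with the failing stage named;
    outputs of completed stages are preserved on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(stages) if stages else list(STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    outputs: dict = {}
    summaries: dict = {}
    log_path = out / "pipeline.log"
    with open(log_path, "a") as log:
        log.write(
            f"run seed={config.seed} config_hash={config.config_hash()} "
            f"version={__version__} stages={','.join(stages)}\n"
        )
        for stage in stages:
            t0 = time.time()
            try:
                result = _STAGE_FUNCS[stage](config, out)
            except Exception as exc:
                log.write(f"stage {stage} FAILED: {exc}\n")
                raise StageError(stage, exc) from exc
            outputs[stage] = {k: str(v) for k, v in result["outputs"].items()}
            summaries[stage] = result["summary"]
            log.write(f"stage {stage} ok ({time.time() - t0:.1f}s)\n")
    report = PipelineReport(
        seed=config.seed,
        config_hash=config.config_hash(),
        version=__version__,
        outputs=outputs,
        summaries=summaries,
        stages_run=stages,
    )
    _dump(dataclasses.asdict(report), out / "report.json")
    return report
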