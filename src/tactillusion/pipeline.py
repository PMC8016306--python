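"""End-to-end orchestration of the three desk-scale experiments.

Experiment 1 (in silico): solve the fingertip-sphere contact model over a
stimulus grid, extract the cutaneous cue profiles (interface stress, SED,
surface deflection) at every scheduled load, quantify pairwise cue
distances, and flag the elasticity-curvature illusion (the illusion pair
closer than the illusion-vs-distinct pair for every cutaneous cue) while
the force-displacement curves stay separated.

Experiment 2 (measurement analytics): quantify contact areas from a
directory of ink-stamp images with sidecar annotations, aggregate per
stimulus and force level, and test illusion vs distinct areas
(Mann-Whitney U, |Cohen's d|, bootstrap CIs) after per-participant
sigmoidal normalization.

Experiment 3 (psychophysics): score a same-different trial table per
condition and stimulus pair, compute differencing-rule d', and compare
conditions pairwise on per-participant percent correct.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import mechanics as mech
from . import psychophysics as psy
from .contact_area import load_ink_image, measure_contact_area
from .stats import bootstrap_ci, cohens_d, mann_whitney_u, sigmoid_normalize

__all__ = [
    "StudyConfig",
    "parse_stimulus_id",
    "run_experiment1",
    "run_experiment2",
    "run_experiment3",
    "load_study_config",
    "save_report",
]

CUTANEOUS_CUES = ("stress", "sed", "deflection")


def parse_stimulus_id(stimulus_id: str) -> mech.StimulusTip:
    """'10kPa-4mm' -> StimulusTip(radius=4, shear_modulus=10)."""
    try:
        mod_s, rad_s = stimulus_id.split("-")
        g = float(mod_s.removesuffix("kPa"))
        r = float(rad_s.removesuffix("mm"))
    except Exception as exc:
        raise ValueError(f"malformed stimulus id {stimulus_id!r}") from exc
    return mech.StimulusTip(radius=r, shear_modulus=g)


@dataclass(frozen=True)
class StudyConfig:
    """Stimulus set, loads, and solver scale for an in-silico study."""

    radii: tuple[float, ...] = (4.0, 6.0, 8.0)
    moduli: tuple[float, ...] = (10.0, 50.0, 90.0)
    illusion_ids: tuple[str, ...] = ("10kPa-4mm", "90kPa-6mm", "90kPa-8mm")
    distinct_id: str = "10kPa-8mm"
    loads: tuple[float, ...] = (0.25, 0.5, 1.0, 2.0)
    coarse_mesh: bool = True
    stimulus_mesh_scale: float = 2.0
    stress_measure: str = "von_mises"
    seed: int = 0

    def __post_init__(self):
        grid = {f"{g:g}kPa-{r:g}mm" for g in self.moduli for r in self.radii}
        if not set(self.illusion_ids) <= grid:
            raise ValueError("illusion set must be part of the stimulus grid")
        if self.distinct_id in self.illusion_ids:
            raise ValueError("the distinct stimulus cannot be in the illusion set")

    @property
    def grid_ids(self) -> tuple[str, ...]:
        return tuple(f"{g:g}kPa-{r:g}mm" for g in self.moduli for r in self.radii)


def _cue_profiles(state, model, measure, sid):
    return {
        "stress": mech.interface_stress_profile(state, model, measure=measure,
                                                stimulus_id=sid),
        "sed": mech.interface_sed_profile(state, model, stimulus_id=sid),
        "deflection": mech.surface_deflection_profile(state, model, stimulus_id=sid),
    }


def run_experiment1(config: StudyConfig | None = None,
                    stimuli: tuple[str, ...] | None = None,
                    fd_stimuli: tuple[str, ...] | None = None) -> dict:
    """Simulate the stimulus grid and quantify cue discriminability.

    ``stimuli`` restricts the grid (defaults to all nine); ``fd_stimuli``
    selects which stimuli get an additional active-mode solve for the
    proprioceptive force-displacement curve (defaults to the illusion pair
    plus the distinct stimulus).  Solver failures for individual stimuli
    are recorded in the report without aborting the run.

    Returns a dict with DataFrames ``profiles``, ``distances``, ``fd``
    and a ``summary`` with per-cue illusion flags.
    """
    config = config or StudyConfig()
    ids = tuple(stimuli) if stimuli is not None else config.grid_ids
    if not ids:
        raise ValueError("empty stimulus grid")
    if fd_stimuli is None:
        fd_stimuli = ("10kPa-4mm", "90kPa-8mm", config.distinct_id)
        fd_stimuli = tuple(dict.fromkeys(s for s in fd_stimuli if s in ids))
    model = mech.build_fingertip_model(
        mech.default_fingertip_config(coarse=config.coarse_mesh))

    prof_rows, failures = [], {}
    profiles: dict[tuple[str, str, float], mech.CueProfile] = {}
    fd_rows = []
    for sid in ids:
        tip = parse_stimulus_id(sid)
        try:
            sol = mech.solve_contact(mech.ContactProblem(
                fingertip=model, stimulus=tip, mode="passive",
                load_schedule=config.loads,
                stimulus_mesh_scale=config.stimulus_mesh_scale))
        except mech.SolverError as exc:
            failures[sid] = str(exc)
            continue
        for state, sched_load in zip(sol, config.loads):
            cues = _cue_profiles(state, model, config.stress_measure, sid)
            for cue, prof in cues.items():
                profiles[(sid, cue, sched_load)] = prof
                for loc, val in zip(prof.locations, prof.values):
                    prof_rows.append({"stimulus_id": sid, "cue": cue,
                                      "load_N": sched_load,
                                      "achieved_load_N": state.load,
                                      "location_mm": loc, "value": val})
        if sid in fd_stimuli:
            try:
                sol_a = mech.solve_contact(mech.ContactProblem(
                    fingertip=model, stimulus=tip, mode="active",
                    load_schedule=config.loads,
                    stimulus_mesh_scale=config.stimulus_mesh_scale))
                fd = mech.force_displacement_curve(sol_a)
                for fN, dmm in zip(fd.force, fd.displacement):
                    fd_rows.append({"stimulus_id": sid, "force_N": fN,
                                    "displacement_mm": dmm})
            except mech.SolverError as exc:
                failures[sid + ":active"] = str(exc)

    dist_rows = []
    solved_ids = sorted({k[0] for k in profiles})
    for cue in CUTANEOUS_CUES:
        for load in config.loads:
            for i, a in enumerate(solved_ids):
                for b in solved_ids[i + 1:]:
                    ka, kb = (a, cue, load), (b, cue, load)
                    if ka in profiles and kb in profiles:
                        dist_rows.append({
                            "cue": cue, "load_N": load, "id_a": a, "id_b": b,
                            "distance": mech.cue_distance(profiles[ka], profiles[kb]),
                        })
    distances = pd.DataFrame(dist_rows)

    def _dist(cue, load, a, b):
        if distances.empty:
            return np.nan
        sel = distances[(distances.cue == cue) & (distances.load_N == load)
                        & (((distances.id_a == a) & (distances.id_b == b))
                           | ((distances.id_a == b) & (distances.id_b == a)))]
        return float(sel.distance.iloc[0]) if len(sel) else np.nan

    pair = ("10kPa-4mm", "90kPa-8mm")
    illusion_flags = {}
    for cue in CUTANEOUS_CUES:
        flags = []
        for load in config.loads:
            d_ill = _dist(cue, load, *pair)
            d_dis = _dist(cue, load, pair[0], config.distinct_id)
            flags.append(bool(d_ill < d_dis) if np.isfinite(d_ill) and
                         np.isfinite(d_dis) else False)
        illusion_flags[cue] = all(flags)

    fd_df = pd.DataFrame(fd_rows)
    fd_separated = None
    if not fd_df.empty and set(pair) <= set(fd_df.stimulus_id):
        at2 = {}
        for sid in pair:
            sub = fd_df[fd_df.stimulus_id == sid]
            at2[sid] = float(np.interp(max(config.loads), sub.force_N,
                                       sub.displacement_mm))
        fd_separated = bool(at2[pair[0]] > 1.05 * at2[pair[1]])

    return {
        "profiles": pd.DataFrame(prof_rows),
        "distances": distances,
        "fd": fd_df,
        "summary": {
            "stimuli": list(solved_ids),
            "loads_N": list(config.loads),
            "illusion_by_cue": illusion_flags,
            "illusion_all_cues": all(illusion_flags.get(c, False)
                                     for c in CUTANEOUS_CUES),
            "fd_pair_separated": fd_separated,
            "failures": failures,
        },
    }


def run_experiment2(data_dir: str | Path,
                    illusion_ids=("10kPa-4mm", "90kPa-6mm", "90kPa-8mm"),
                    distinct_id: str = "10kPa-8mm",
                    seed: int = 0) -> dict:
    """Ink-based contact-area analytics over a study directory.

    ``data_dir`` holds ``images/*.png`` with sidecar ``*.json`` files
    (bar pixels, ROI, stimulus id, force level, participant).  Unreadable
    images are skipped with a warning and counted.  Areas are normalized
    per participant with the sigmoidal membership function before the
    illusion-vs-distinct comparison.
    """
    data_dir = Path(data_dir)
    image_files = sorted((data_dir / "images").glob("*.png")) + \
        sorted((data_dir / "images").glob("*.tif*"))
    if not image_files:
        raise FileNotFoundError(f"no ink images found under {data_dir}/images")
    rows, n_failed = [], 0
    for path in image_files:
        try:
            image, sidecar = load_ink_image(path)
            area = measure_contact_area(
                image, tuple(sidecar["roi_center"]), sidecar["roi_radius"])
            rows.append({
                "image": path.name,
                "participant": sidecar.get("participant", 0),
                "stimulus_id": sidecar.get("stimulus_id", "unknown"),
                "force_N": sidecar.get("force_N", np.nan),
                "mode": sidecar.get("mode", "passive"),
                "area_cm2": area,
            })
        except Exception as exc:  # unreadable image: report, continue
            n_failed += 1
            warnings.warn(f"skipping {path.name}: {exc}", stacklevel=2)
    if not rows:
        raise RuntimeError("no ink image could be analyzed")
    areas = pd.DataFrame(rows)

    # per-participant sigmoidal normalization before aggregation
    areas["area_norm"] = np.nan
    for (pid, mode), idx in areas.groupby(["participant", "mode"]).groups.items():
        sub = areas.loc[idx, "area_cm2"]
        areas.loc[idx, "area_norm"] = sigmoid_normalize(sub.to_numpy()).normalized

    by_stimulus = areas.groupby(["stimulus_id", "force_N"])["area_cm2"] \
        .agg(["mean", "std", "count"]).reset_index()

    stats_out = {}
    ill = areas[areas.stimulus_id.isin(illusion_ids)]["area_norm"].to_numpy()
    dis = areas[areas.stimulus_id == distinct_id]["area_norm"].to_numpy()
    if len(ill) and len(dis):
        mw = mann_whitney_u(ill, dis)
        stats_out = {
            "U": mw.u, "p_value": mw.p_value, "significant": mw.significant,
            "cohens_d": cohens_d(ill, dis) if min(len(ill), len(dis)) > 1 else None,
            "illusion_mean_area_cm2": float(
                areas[areas.stimulus_id.isin(illusion_ids)].area_cm2.mean()),
            "distinct_mean_area_cm2": float(
                areas[areas.stimulus_id == distinct_id].area_cm2.mean()),
            "illusion_area_ci": bootstrap_ci(
                areas[areas.stimulus_id.isin(illusion_ids)].area_cm2.to_numpy(),
                seed=seed),
            "distinct_area_ci": bootstrap_ci(
                areas[areas.stimulus_id == distinct_id].area_cm2.to_numpy(),
                seed=seed + 1),
        }
    return {"areas": areas, "by_stimulus": by_stimulus,
            "stats": stats_out, "n_failed_images": n_failed}


def run_experiment3(trials: pd.DataFrame | str | Path) -> dict:
    """Psychophysics scoring of a same-different trial table.

    ``trials`` is a DataFrame or CSV with columns participant, condition,
    first, second, response (and optionally correct, which is recomputed).
    Malformed rows are skipped and counted.  Returns the per-condition /
    per-pair report, per-participant percent correct, pairwise condition
    tests, and 75%-threshold flags.
    """
    if not isinstance(trials, pd.DataFrame):
        trials = pd.read_csv(trials)
    records, per_participant, n_bad = [], [], 0
    for row in trials.itertuples():
        try:
            rec = psy.TrialRecord.from_response(
                psy.StimulusPair(str(row.first), str(row.second)),
                str(row.condition), str(row.response))
            records.append((getattr(row, "participant", 0), rec))
        except Exception:
            n_bad += 1
    if not records:
        raise ValueError("no valid trials found")
    report = psy.condition_report([r for _, r in records])

    pp_rows = []
    df = pd.DataFrame([{"participant": p, "condition": r.condition,
                        "correct": r.correct} for p, r in records])
    for (pid, cond), sub in df.groupby(["participant", "condition"]):
        pp_rows.append({"participant": pid, "condition": cond,
                        "percent_correct": 100.0 * sub.correct.mean()})
    per_participant = pd.DataFrame(pp_rows)

    comparisons = []
    conds = sorted(per_participant.condition.unique())
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            xa = per_participant[per_participant.condition == a].percent_correct.to_numpy()
            xb = per_participant[per_participant.condition == b].percent_correct.to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            mw = mann_whitney_u(xa, xb)
            try:
                d = cohens_d(xa, xb)
            except ValueError:
                d = np.nan
            comparisons.append({"condition_a": a, "condition_b": b,
                                "U": mw.u, "p_value": mw.p_value,
                                "significant": mw.significant, "cohens_d": d})
    pooled = report[report.pair == "all"][
        ["condition", "percent_correct", "dprime", "mean_pair_dprime",
         "threshold_reached"]]
    return {
        "report": report,
        "per_participant": per_participant,
        "condition_comparisons": pd.DataFrame(comparisons),
        "summary": pooled.reset_index(drop=True),
        "n_malformed": n_bad,
    }


def load_study_config(path: str | Path) -> StudyConfig:
    """Read a :class:`StudyConfig` from a structured text (JSON) file.

    Recognized keys mirror the dataclass fields (radii, moduli,
    illusion_ids, distinct_id, loads, coarse_mesh, stimulus_mesh_scale,
    stress_measure, seed); unknown keys raise.
    """
    payload = json.loads(Path(path).read_text())
    known = set(StudyConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("radii", "moduli", "illusion_ids", "loads"):
        if key in payload:
            payload[key] = tuple(payload[key])
    return StudyConfig(**payload)


def save_report(report: dict, out_dir: str | Path, prefix: str = "") -> None:
    """Write a run_experiment* report as CSV tables plus a JSON summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary = {}
    for key, val in report.items():
        if isinstance(val, pd.DataFrame):
            val.to_csv(out / f"{prefix}{key}.csv", index=False)
        else:
            summary[key] = val
    if summary:
        with open(out / f"{prefix}summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, default=str)
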