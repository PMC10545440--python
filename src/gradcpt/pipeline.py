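"""Pipeline orchestration: simulate -> analyze -> group.

``run_simulate`` writes a fixture directory of synthetic sessions (events
TSV + keypress TSV + ground-truth JSON per run, plus a manifest).
``run_analyze`` reads such a directory and produces per-participant
performance metrics, per-run VTC series, and per-run design-matrix tables.
``run_group`` correlates metrics with covariates and reports r, p, BF10,
credible interval and evidence category per pair.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import assignment, bayes, metrics, observer, regressors, schedule, vtc
from .config import Config

logger = logging.getLogger(__name__)

MODALITIES = ("auditory", "visual")


@dataclass(frozen=True)
class RunBundle:
    """Paths and metadata locating one run of one participant."""

    events_path: Path
    keypress_path: Path
    participant: str
    modality: str
    run_index: int
    soa: float
    run_duration: float


def _observer_for(modality: str, cfg: Config, seed: int, **overrides) -> observer.ObserverParams:
    if modality == "auditory":
        return observer.auditory_observer(seed=seed, **overrides)
    return observer.ObserverParams(seed=seed, **overrides)


def run_simulate(
    out_dir: str | Path,
    config: Config | None = None,
    n_participants: int = 1,
    n_runs: int | None = None,
    modalities: Sequence[str] = MODALITIES,
    observer_overrides: dict | None = None,
) -> list[RunBundle]:
    """Generate a synthetic-session fixture directory.

    Layout: ``<out>/<participant>/<modality>/run-<k>_events.tsv`` (+
    ``_keypresses.tsv`` and ``_truth.json``), plus a top-level
    ``manifest.json``.  Deterministic under ``config.seed``: participant,
    modality and run indices are folded into per-run child seeds.
    """
    cfg = config or Config()
    n_runs = cfg.n_runs if n_runs is None else n_runs
    overrides = observer_overrides or {}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    bundles: list[RunBundle] = []
    manifest = {"config": cfg.to_dict(), "runs": []}
    root = np.random.SeedSequence(cfg.seed)
    for p in range(n_participants):
        pid = f"sub-{p + 1:02d}"
        for m, modality in enumerate(modalities):
            soa = cfg.soa(modality)
            run_dir = out / pid / modality
            run_dir.mkdir(parents=True, exist_ok=True)
            for k in range(n_runs):
                child = np.random.SeedSequence(
                    entropy=root.entropy, spawn_key=(p, m, k)
                )
                sched_seed, obs_seed = (
                    int(s) % (2**31) for s in child.generate_state(2)
                )
                sched = schedule.make_schedule(
                    run_duration=cfg.run_duration,
                    soa=soa,
                    nogo_rate=cfg.nogo_rate,
                    seed=sched_seed,
                )
                params = _observer_for(modality, cfg, obs_seed, **overrides)
                log = observer.simulate_observer(sched, params)

                ev = run_dir / f"run-{k + 1}_events.tsv"
                kp = run_dir / f"run-{k + 1}_keypresses.tsv"
                schedule.write_events(sched, ev)
                observer.write_keypresses(log, kp)
                truth = params.to_dict()
                (run_dir / f"run-{k + 1}_truth.json").write_text(
                    json.dumps(truth, indent=1, sort_keys=True)
                )
                bundles.append(
                    RunBundle(ev, kp, pid, modality, k, soa, cfg.run_duration)
                )
                manifest["runs"].append(
                    {
                        "participant": pid,
                        "modality": modality,
                        "run": k,
                        "events": str(ev.relative_to(out)),
                        "keypresses": str(kp.relative_to(out)),
                        "soa": soa,
                    }
                )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return bundles


def discover_bundles(in_dir: str | Path) -> list[RunBundle]:
    """Rebuild RunBundles from a fixture directory's manifest."""
    root = Path(in_dir)
    manifest_path = root / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {root}")
    manifest = json.loads(manifest_path.read_text())
    duration = manifest["config"]["run_duration"]
    bundles = []
    for rec in manifest["runs"]:
        ev = root / rec["events"]
        kp = root / rec["keypresses"]
        for path in (ev, kp):
            if not path.exists():
                raise FileNotFoundError(f"manifest references missing file {path}")
        bundles.append(
            RunBundle(ev, kp, rec["participant"], rec["modality"], rec["run"],
                      rec["soa"], duration)
        )
    return bundles


def analyze_session(
    run_tables: list[pd.DataFrame], soa: float, cfg: Config
) -> tuple[metrics.SessionMetrics, list[vtc.VTCSeries]]:
    """Metrics + VTC + fluctuation frequency for one participant x modality."""
    m = metrics.session_metrics(run_tables)
    series = [vtc.vtc_from_table(t, soa=soa, fwhm=cfg.fwhm) for t in run_tables]
    freq = vtc.fluctuation_frequency(
        [sv.smoothed_vtc for sv in series], soa=soa, band=(cfg.band_low, cfg.band_high)
    )
    m = metrics.SessionMetrics(**{**m.to_dict(), "fluct_freq": freq})
    return m, series


def run_analyze(
    bundles: Sequence[RunBundle],
    out_dir: str | Path,
    config: Config | None = None,
) -> pd.DataFrame:
    """Analyze run bundles; write metrics CSV, VTC TSVs, design matrices.

    Returns the participant x modality metrics table with the standard
    column set (hit %, FA %, d', median RT ms, fluctuation frequency Hz).
    """
    cfg = config or Config()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    rows = []
    groups: dict[tuple[str, str], list[RunBundle]] = {}
    for b in bundles:
        groups.setdefault((b.participant, b.modality), []).append(b)

    for (pid, modality), runs in sorted(groups.items()):
        runs = sorted(runs, key=lambda b: b.run_index)
        soa = runs[0].soa
        tables = []
        scheds = []
        for b in runs:
            sched = schedule.read_events(b.events_path, run_duration=b.run_duration)
            log = observer.read_keypresses(b.keypress_path, b.run_duration)
            tables.append(assignment.assign_presses(sched, log))
            scheds.append(sched)
        m, series = analyze_session(tables, soa, cfg)

        mdir = out / pid / modality
        mdir.mkdir(parents=True, exist_ok=True)
        for k, (b, sv, table, sched) in enumerate(zip(runs, series, tables, scheds)):
            vtc.write_vtc(sv, mdir / f"run-{k + 1}_vtc.tsv")
            assignment.write_trial_table(table, mdir / f"run-{k + 1}_trials.tsv")
            sticks = regressors.stick_regressors(
                table, run_duration=b.run_duration, dt=cfg.hrf_dt,
                tr=cfg.tr, n_scans=cfg.n_scans, t0=cfg.t0,
            )
            sticks["vtc"] = regressors.vtc_regressor(
                sv.raw_vtc, sched, dt=cfg.hrf_dt, tr=cfg.tr,
                n_scans=cfg.n_scans, t0=cfg.t0,
            )
            regressors.design_matrix(sticks).to_csv(
                mdir / f"run-{k + 1}_design.tsv", sep="\t", index=False,
                float_format="%.6f",
            )
        rows.append(
            {
                "participant": pid,
                "modality": modality,
                "hit_pct": 100 * m.hit_rate,
                "fa_pct": 100 * m.fa_rate,
                "d_prime": m.d_prime,
                "median_rt_ms": 1000 * m.median_rt,
                "fluct_freq_hz": m.fluct_freq,
                "n_go": m.n_go,
                "n_nogo": m.n_nogo,
            }
        )

    table = pd.DataFrame(rows)
    table.to_csv(out / "metrics.csv", index=False, float_format="%.6f")
    return table


def run_group(
    metrics_table: pd.DataFrame,
    covariates: pd.DataFrame,
    pairs: Sequence[tuple[str, str]],
    config: Config | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Correlation report over requested variable pairs.

    Tables are joined on ``participant``; each pair uses pairwise-complete
    cases.  Rows with fewer than ``min_n`` complete cases are flagged and
    left uncomputed.
    """
    cfg = config or Config()
    bcfg = bayes.BayesConfig(kappa=cfg.bayes_kappa, cauchy_scale=cfg.bayes_cauchy_scale)
    merged = metrics_table.merge(covariates, on="participant", how="inner") \
        if "participant" in covariates.columns else metrics_table.join(covariates)

    rows = []
    for x_col, y_col in pairs:
        for col in (x_col, y_col):
            if col not in merged.columns:
                raise KeyError(f"column {col!r} not found")
        cols = [x_col] if x_col == y_col else [x_col, y_col]
        sub = merged[cols].dropna()
        n = len(sub)
        if n < min_n:
            rows.append({"x": x_col, "y": y_col, "n": n, "status": "insufficient-n"})
            continue
        res = bayes.correlate(sub[x_col], sub[y_col], bcfg)
        rows.append(
            {
                "x": x_col, "y": y_col, "n": n, "status": "ok",
                "r": res.r, "p": res.p_two_tailed, "bf10": res.bf10,
                "ci95_low": res.ci95[0], "ci95_high": res.ci95[1],
                "evidence": res.evidence,
            }
        )
    return pd.DataFrame(rows)
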