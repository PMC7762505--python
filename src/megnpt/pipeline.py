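"""End-to-end orchestration: simulate → spectra → scores → associate.

``run_pipeline`` drives the full chain on a synthetic cohort and writes the
run directory: per-stage TSV tables plus a JSON manifest with seeds, the
configuration hash, and generator ground truth.  All randomness flows from
the single seed in the configuration, so a rerun reproduces byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cognitive import derive_scores
from .io import write_recording_text, write_table
from .spectral import SpectralConfig, summarize_recording
from .stats import pairwise_association_scan
from .synth import CohortSpec, SignalSpec, simulate_cohort, simulate_recording

__all__ = [
    "DEFAULT_FAMILY",
    "build_run_config",
    "spectral_summary_table",
    "wide_table",
    "run_pipeline",
]

logger = logging.getLogger("megnpt")

# the declared variable family of the association scan: age, treatment
# exposure, both instruments' raw and derived scores, and the three
# spectral parameters
DEFAULT_FAMILY = [
    "age",
    "npt_period_days",
    "n_sessions",
    "npt_frequency",
    "mmse_initial",
    "mmse_last",
    "mmse_estimated",
    "mmse_outcome",
    "mmse_est_change",
    "adas_initial",
    "adas_last",
    "adas_estimated",
    "adas_outcome",
    "adas_est_change",
    "mf",
    "iaf",
    "se",
]


def build_run_config(raw: dict) -> dict:
    """Validate a raw configuration mapping and fill defaults.

    A seed is mandatory — every stochastic stage derives from it.
    """
    if "seed" not in raw:
        raise ValueError("configuration must declare a seed")
    cfg = {
        "seed": int(raw["seed"]),
        "synth": {
            "cohort": dict(raw.get("synth", {}).get("cohort", {})),
            "signal": dict(raw.get("synth", {}).get("signal", {})),
        },
        "spectral": dict(raw.get("spectral", {})),
        "stats": {
            "n_resamples": 20000,
            "q_level": 0.05,
            "two_sided": False,
            "family": list(DEFAULT_FAMILY),
            **raw.get("stats", {}),
        },
        "write_recordings": bool(raw.get("write_recordings", False)),
        "full_scale": bool(raw.get("full_scale", False)),
    }
    return cfg


def _signal_spec(cfg: dict) -> SignalSpec:
    kwargs = dict(cfg["synth"]["signal"])
    if cfg.get("full_scale"):
        kwargs.setdefault("fs", 2000.0)
        kwargs.setdefault("duration", 300.0)
        kwargs.setdefault("n_channels", 160)
    return SignalSpec(**kwargs)


def spectral_summary_table(
    specs: list[SignalSpec],
    participant_ids: list[str],
    spectral_cfg: SpectralConfig,
) -> pd.DataFrame:
    """Simulate each participant's recording and summarise its spectrum."""
    rows = []
    for pid, spec in zip(participant_ids, specs):
        rec = simulate_recording(spec)
        summ = summarize_recording(rec, spectral_cfg)
        row = {
            "participant_id": pid,
            "mf": summ.mf,
            "iaf": summ.iaf,
            "iaf_peak_found": summ.iaf_peak_found,
            "se": summ.se,
        }
        row.update({f"relpower_{k}": v for k, v in summ.band_relpower.items()})
        rows.append(row)
    return pd.DataFrame(rows)


def wide_table(scores: pd.DataFrame, spectra: pd.DataFrame) -> pd.DataFrame:
    """Pivot the long-format derived-score table and join the spectral summary.

    One row per participant with per-instrument score columns
    (``mmse_initial`` ... ``adas_est_change``), the shared covariates, and
    MF/IAF/SE.
    """
    per_inst = scores.pivot(
        index="participant_id",
        columns="instrument",
        values=[
            "initial_score",
            "last_score",
            "estimated_score",
            "outcome",
            "estimated_score_change",
        ],
    )
    rename = {
        "initial_score": "initial",
        "last_score": "last",
        "estimated_score": "estimated",
        "outcome": "outcome",
        "estimated_score_change": "est_change",
    }
    per_inst.columns = [f"{inst}_{rename[val]}" for val, inst in per_inst.columns]
    shared_cols = ["participant_id", "npt_period_days", "n_sessions", "npt_frequency"]
    if "age" in scores.columns:
        shared_cols.append("age")
    shared = scores[shared_cols].drop_duplicates("participant_id")
    wide = shared.merge(per_inst, on="participant_id")
    return wide.merge(spectra, on="participant_id")


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(cfg: dict, out_dir: str | Path) -> Path:
    """Run simulate → spectra → scores → associate and write the run directory.

    Writes ``cohort.tsv``, ``spectral.tsv``, ``scores.tsv``,
    ``associations.tsv`` and ``manifest.json`` under ``out_dir``; returns the
    run directory path.
    """
    cfg = build_run_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    logger.info("stage simulate: generating cohort")
    cohort_kwargs = dict(cfg["synth"]["cohort"])
    cohort_kwargs.setdefault("seed", cfg["seed"])
    for key in ("npt_period_range", "session_count_range", "meg_delay_range"):
        if key in cohort_kwargs:
            cohort_kwargs[key] = tuple(cohort_kwargs[key])
    cspec = CohortSpec(**cohort_kwargs)
    template = _signal_spec(cfg)
    cohort, specs, info = simulate_cohort(cspec, signal_template=template)
    write_table(cohort, out / "cohort.tsv")

    if cfg["write_recordings"]:
        rec_dir = out / "recordings"
        rec_dir.mkdir(exist_ok=True)
        for pid, spec in zip(cohort["participant_id"].unique(), specs):
            write_recording_text(simulate_recording(spec), rec_dir / f"{pid}.txt")

    logger.info("stage spectra: %d recordings", len(specs))
    spectral_cfg = SpectralConfig(**cfg["spectral"])
    pids = list(cohort["participant_id"].unique())
    spectra = spectral_summary_table(specs, pids, spectral_cfg)
    write_table(spectra, out / "spectral.tsv")
    n_edge = int((~spectra["iaf_peak_found"]).sum())
    if n_edge:
        logger.warning("IAF peak not found for %d recording(s)", n_edge)

    logger.info("stage scores: deriving outcomes")
    scores = derive_scores(cohort)
    write_table(scores, out / "scores.tsv")

    logger.info("stage associate: bootstrap correlation scan")
    wide = wide_table(scores, spectra)
    family = [v for v in cfg["stats"]["family"] if v in wide.columns]
    assoc = pairwise_association_scan(
        wide,
        family,
        n_resamples=int(cfg["stats"]["n_resamples"]),
        seed=cfg["seed"],
        q_level=float(cfg["stats"]["q_level"]),
        two_sided=bool(cfg["stats"]["two_sided"]),
    )
    write_table(assoc, out / "associations.tsv")
    write_table(wide, out / "wide.tsv")

    manifest = {
        "megnpt_version": __version__,
        "seed": cfg["seed"],
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "n_participants": int(cspec.n_participants),
        "realized_latent_corr": {
            k: (None if np.isnan(v) else float(v))
            for k, v in info.realized_latent_corr.items()
        },
        "score_clipping_events": info.n_clipped,
        "n_iaf_edge_flags": n_edge,
        "n_rejected": int(assoc["reject"].sum()),
        "family": family,
        "signal_template": dataclasses.asdict(template),
    }
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    logger.info("run complete: %s", out)
    return out
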