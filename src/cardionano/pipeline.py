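"""Batch orchestration: run the full synthetic two-condition analysis.

A run config (YAML) declares per-condition generator parameters and the
analysis settings for every stage. ``run_pipeline`` generates the data,
runs Ripley/NNA/persistence on the patterns and beat analysis on the
calcium traces, compares conditions with Student's t-test, and writes a
machine-readable ``summary.json`` (plus per-stage CSVs and a log). For a
fixed master seed the summary is byte-identical across reruns; wall-clock
information goes only to the log.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .compare import students_t, summarize
from .core import CardionanoError, Window
from .kinetics import beat_metrics, segment_beats
from .pointstats import nna, ripley_k
from .synthgen import ClusterModel, TransientModel, gen_calcium_trace, gen_clustered
from .topohomology import bar_endpoint_histogram, default_hole_bins, rips_persistence

logger = logging.getLogger("cardionano")


class StageError(CardionanoError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


DEFAULT_CONFIG: dict = {
    "seed": 20260925,
    "window_nm": 2000.0,
    "n_replicates": 4,
    "conditions": {},
    "ripley": {"r_max": 300.0, "step": 5.0, "edge_mode": "torus"},
    "persistence": {"max_radius": 150.0, "subsample": 400},
    "nna": {"bin_width": 5.0},
    "calcium_sample_rate": 100.0,
    "inputs": [],
}


def _merge_defaults(user: dict) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            merged = dict(cfg[key])
            merged.update(val)
            cfg[key] = merged
        else:
            cfg[key] = val
    return cfg


def load_config(path: str | Path) -> dict:
    return _merge_defaults(yaml.safe_load(Path(path).read_text()) or {})


def _derive_seed(master: int, *indices: int) -> int:
    ss = np.random.SeedSequence([int(master), *[int(i) for i in indices]])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31 - 1))


def _round(x: float, digits: int = 10) -> float:
    return float(round(float(x), digits))


def _analyze_pattern(cfg: dict, cond_cfg: dict, seed: int) -> dict:
    window = Window.square(float(cfg["window_nm"]))
    model = ClusterModel(window=window, seed=seed, **cond_cfg["clusters"])
    pattern = gen_clustered(model)
    rip = cfg["ripley"]
    radii = np.arange(0.0, rip["r_max"] + rip["step"] / 2, rip["step"])
    res = ripley_k(pattern, radii, edge_mode=rip["edge_mode"])
    per = cfg["persistence"]
    diagram = rips_persistence(
        pattern, per["max_radius"], subsample_threshold=per["subsample"], seed=seed
    )
    h1 = diagram.bars(1)
    finite = h1[np.isfinite(h1[:, 1])]
    hist = bar_endpoint_histogram(diagram, 1, default_hole_bins(per["max_radius"]))
    nn = nna(pattern, bin_width=cfg["nna"]["bin_width"])
    return {
        "n_points": pattern.n,
        "ripley_peak_radius_nm": _round(res.peak_radius),
        "ripley_peak_value_nm": _round(res.peak_value),
        "h1_mean_death_nm": _round(finite[:, 1].mean()) if len(finite) else np.nan,
        "n_holes": int(hist.counts.sum() + hist.n_outside),
        "nna_mode_nm": _round(nn.mode_radius),
        "nna_mode_height": _round(nn.mode_height),
    }


def _analyze_calcium(cfg: dict, cond_cfg: dict, seed: int) -> dict:
    params = dict(cond_cfg["calcium"])
    params.setdefault("sample_rate", cfg["calcium_sample_rate"])
    model = TransientModel(seed=seed, **params)
    trace = gen_calcium_trace(model)
    windows = segment_beats(trace, mode="paced")
    _, avg = beat_metrics(trace, windows)
    return {
        "diastolic": _round(avg.diastolic),
        "systolic": _round(avg.systolic),
        "ca_amplitude": _round(avg.amplitude),
        "rise_time_s": _round(avg.rise_time),
        "release_rate": _round(avg.release_rate),
        "tau_s": _round(avg.tau),
        "reuptake_rate_per_s": _round(avg.reuptake_rate),
    }


def run_pipeline(
    config: dict | str | Path, out_dir: str | Path, seed: int | None = None
) -> dict:
    """Execute the configured stages and write the report bundle.

    Returns the summary dictionary that is also written to
    ``out_dir/summary.json``.
    """
    config = load_config(config) if not isinstance(config, dict) else _merge_defaults(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(seed if seed is not None else config.get("seed", 0))

    # pre-flight: every referenced input must exist before any computation
    for ref in config.get("inputs", []):
        if not Path(ref).exists():
            raise StageError("preflight", f"missing input file {ref}")
    if len(config.get("conditions", {})) < 1:
        raise StageError("preflight", "config declares no conditions")

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info(
        "cardionano %s on python %s; master seed %d",
        __version__, platform.python_version(), master,
    )
    logger.info("config: %s", json.dumps(config, sort_keys=True, default=str))

    metrics: dict[str, dict[str, list[float]]] = {}
    rows = []
    try:
        for ci, (cond, cond_cfg) in enumerate(sorted(config["conditions"].items())):
            metrics[cond] = {}
            for rep in range(int(config["n_replicates"])):
                rec: dict = {"condition": cond, "replicate": rep}
                if "clusters" in cond_cfg:
                    try:
                        rec.update(
                            _analyze_pattern(
                                config, cond_cfg, _derive_seed(master, ci, rep, 0)
                            )
                        )
                    except Exception as exc:  # noqa: BLE001
                        raise StageError(f"pointstats[{cond}/{rep}]", str(exc))
                if "calcium" in cond_cfg:
                    try:
                        rec.update(
                            _analyze_calcium(
                                config, cond_cfg, _derive_seed(master, ci, rep, 1)
                            )
                        )
                    except Exception as exc:  # noqa: BLE001
                        raise StageError(f"kinetics[{cond}/{rep}]", str(exc))
                rows.append(rec)
                for key, val in rec.items():
                    if key in ("condition", "replicate"):
                        continue
                    metrics[cond].setdefault(key, []).append(float(val))
                logger.info("condition %s replicate %d done", cond, rep)
    finally:
        logger.removeHandler(handler)
        handler.close()

    per_rep = pd.DataFrame(rows)
    per_rep.to_csv(out / "per_replicate_metrics.csv", index=False)

    summary: dict = {"master_seed": master, "config": config, "groups": {}, "comparisons": {}}
    for cond, vals in metrics.items():
        summary["groups"][cond] = {
            key: {"values": v, **dataclasses.asdict(summarize(v))}
            for key, v in vals.items()
        }
    conds = sorted(metrics)
    if len(conds) >= 2:
        a, b = conds[0], conds[1]
        shared = sorted(set(metrics[a]) & set(metrics[b]))
        for key in shared:
            cmp_ = students_t(metrics[a][key], metrics[b][key], a, b)
            summary["comparisons"][key] = dataclasses.asdict(cmp_)

    text = json.dumps(summary, sort_keys=True, indent=2, allow_nan=True, default=str)
    (out / "summary.json").write_text(text)
    return summary
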