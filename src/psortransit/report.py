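"""Transition diagrams, result tables, and end-to-end pipeline orchestration.

Diagrams are emitted as Graphviz DOT text (one node per severity stage, one
labeled edge per transition probability at or above a threshold) together
with a machine-readable JSON twin carrying full-precision estimates and
confidence bounds.  ``run_pipeline`` chains
simulate → impute → match → transitions → pool → report from a single YAML
or dict config, writing a manifest that makes the run exactly repeatable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import STAGE_LABELS, THERAPIES, DEFAULT_WINDOWS
from . import io as cio
from .impute import impute, locf_check
from .match import balance_diagnostics, match_three_groups
from .pool import ContrastResult, PooledResult, contrast, pool_rubin
from .simulate import TruthParameters, apply_missingness, generate_cohort, write_truth
from .transitions import POPULATIONS, estimate_transitions

logger = logging.getLogger(__name__)

CONTRAST_PAIRS = (("biologic", "traditional"),
                  ("biologic", "systemic"),
                  ("traditional", "systemic"))

#: Structural schema of the diagram JSON twin.
DIAGRAM_SCHEMA = {
    "type": "object",
    "required": ["therapy", "window", "m", "threshold", "stages", "edges"],
    "edge_required": ["from", "to", "p", "ci_lo", "ci_hi"],
}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


def render_diagram(pooled: PooledResult, threshold: float = 0.0) -> tuple:
    """Render a pooled matrix as (DOT text, JSON payload).

    Edges are emitted in row-major order for every cell with a defined
    probability >= ``threshold``; output is fully deterministic.
    """
    lines = [
        f"digraph transitions_{pooled.therapy}_{pooled.window} {{",
        "  rankdir=LR;",
        '  node [shape=circle, fontsize=11];',
    ]
    for label in STAGE_LABELS:
        lines.append(f'  {label} [label="{label}"];')
    edges = []
    for i, src in enumerate(STAGE_LABELS):
        for j, dst in enumerate(STAGE_LABELS):
            p = pooled.p[i, j]
            if np.isnan(p) or p < threshold:
                continue
            lines.append(f'  {src} -> {dst} [label="{p:.2f}"];')
            edges.append({"from": src, "to": dst, "p": float(p),
                          "ci_lo": float(pooled.ci_lo[i, j]),
                          "ci_hi": float(pooled.ci_hi[i, j])})
    lines.append("}")
    payload = {"therapy": pooled.therapy, "window": pooled.window,
               "m": pooled.m, "threshold": threshold,
               "stages": list(STAGE_LABELS), "edges": edges}
    return "\n".join(lines) + "\n", payload


def validate_diagram_payload(payload: dict) -> dict:
    """Check a diagram JSON payload against the shipped schema."""
    for key in DIAGRAM_SCHEMA["required"]:
        if key not in payload:
            raise ValueError(f"diagram payload missing key {key!r}")
    if payload["stages"] != list(STAGE_LABELS):
        raise ValueError("diagram payload has wrong stage set")
    if len(payload["edges"]) > 16:
        raise ValueError("a 4-stage diagram has at most 16 edges")
    for edge in payload["edges"]:
        for key in DIAGRAM_SCHEMA["edge_required"]:
            if key not in edge:
                raise ValueError(f"edge missing key {key!r}")
        if not 0.0 <= edge["p"] <= 1.0:
            raise ValueError("edge probabilities must lie in [0, 1]")
    return payload


DEFAULT_CONFIG = {
    "n": 2000,
    "seed": 20201,
    "m": 20,
    "cycles": 10,
    "pmm_k": 5,
    "threshold": 0.0,
    "ci_reference": "normal",
    "apply_missingness": True,
    "input": None,          # directory with patients.csv/visits.csv to ingest
    "truth": {},            # TruthParameters overrides for simulation
}


def load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        config = yaml.safe_load(Path(config).read_text()) or {}
    cfg = dict(DEFAULT_CONFIG)
    cfg.update(config)
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _pooled_frame(res: PooledResult | ContrastResult, value: str) -> pd.DataFrame:
    est = res.p if value == "p" else res.d
    rows = []
    for i, src in enumerate(STAGE_LABELS):
        for j, dst in enumerate(STAGE_LABELS):
            rows.append({"from": src, "to": dst,
                         "estimate": round(float(est[i, j]), 2),
                         "ci_lo": round(float(res.ci_lo[i, j]), 2),
                         "ci_hi": round(float(res.ci_hi[i, j]), 2)})
    return pd.DataFrame(rows)


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
    return wrap


def run_pipeline(config, out_dir) -> dict:
    """Execute the full analysis and write all artifacts under ``out_dir``.

    Returns a dict with the pooled and contrast results keyed by
    (population, window) / (arm_a, arm_b, window).  Deterministic: the same
    config yields identical output files and manifest hash.
    """
    cfg = load_config(config)
    if cfg["m"] < 2:
        raise PipelineError(
            "stage 'pool' precondition violated: Rubin pooling requires m >= 2 "
            f"imputed data sets (got m={cfg['m']})")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    windows = dict(DEFAULT_WINDOWS)

    # -- simulate or ingest ------------------------------------------------
    if cfg["input"]:
        logger.info("ingesting cohort from %s", cfg["input"])
        cohort = _stage("ingest")(cio.read_cohort, cfg["input"])
        truth = None
    else:
        params = TruthParameters(n=cfg["n"], seed=cfg["seed"],
                                 **cfg["truth"])
        cohort, truth = _stage("simulate")(generate_cohort, params)
        if cfg["apply_missingness"]:
            cohort = _stage("simulate")(apply_missingness, cohort, params)
        windows = {k: tuple(v) for k, v in params.windows.items()}
        cio.write_cohort(cohort, out / "cohort")
        write_truth(truth, out / "cohort" / cio.TRUTH_FILE)

    # -- impute ------------------------------------------------------------
    imputed = _stage("impute")(impute, cohort, m=cfg["m"], cycles=cfg["cycles"],
                               seed=cfg["seed"], pmm_k=cfg["pmm_k"])
    check = locf_check(imputed)
    if not check["ok"]:
        raise PipelineError(f"stage 'impute' failed: visits altered {check}")
    imp_dir = out / "imputed"
    imp_dir.mkdir(exist_ok=True)
    for i, c in enumerate(imputed.cohorts):
        c.patients.sort_index().to_csv(imp_dir / f"patients_m{i}.csv",
                                       index_label="id", float_format="%.10g",
                                       lineterminator="\n")

    # -- match -------------------------------------------------------------
    match_dir = out / "matched"
    match_dir.mkdir(exist_ok=True)
    matched_sets = []
    for i, c in enumerate(imputed.cohorts):
        matched = _stage("match")(match_three_groups, c, imputation_index=i)
        matched_sets.append(matched)
        matched.triples.to_csv(match_dir / f"triples_m{i}.csv", index=False,
                               lineterminator="\n")
        balance = _stage("match")(balance_diagnostics, c, matched)
        balance.to_csv(match_dir / f"balance_m{i}.csv", index=False,
                       float_format="%.6g", lineterminator="\n")

    # -- transitions -------------------------------------------------------
    est_dir = out / "est"
    est_dir.mkdir(exist_ok=True)
    estimates = {}
    for pop in POPULATIONS:
        for window in windows:
            per_imp = []
            for i, (c, matched) in enumerate(zip(imputed.cohorts, matched_sets)):
                est = _stage("transitions")(estimate_transitions, c, matched,
                                            pop, window, windows)
                per_imp.append(est)
                frame = pd.DataFrame(
                    [{"from": STAGE_LABELS[a], "to": STAGE_LABELS[b],
                      "p": est.p[a, b], "var": est.var[a, b],
                      "n": est.n_row[a]}
                     for a in range(4) for b in range(4)])
                frame.to_csv(est_dir / f"est_{pop}_{window}_m{i}.csv",
                             index=False, float_format="%.10g",
                             lineterminator="\n")
            estimates[(pop, window)] = per_imp

    # -- pool + contrast ---------------------------------------------------
    res_dir = out / "results"
    res_dir.mkdir(exist_ok=True)
    pooled = {}
    for (pop, window), per_imp in estimates.items():
        pooled[(pop, window)] = _stage("pool")(
            pool_rubin, per_imp, ci_reference=cfg["ci_reference"])
        _pooled_frame(pooled[(pop, window)], "p").to_csv(
            res_dir / f"pooled_{pop}_{window}.csv", index=False,
            lineterminator="\n")
    contrasts = {}
    for a, b in CONTRAST_PAIRS:
        for window in windows:
            res = _stage("pool")(contrast, estimates[(a, window)],
                                 estimates[(b, window)],
                                 ci_reference=cfg["ci_reference"])
            contrasts[(a, b, window)] = res
            _pooled_frame(res, "d").to_csv(
                res_dir / f"contrast_{a}_vs_{b}_{window}.csv", index=False,
                lineterminator="\n")

    # -- report ------------------------------------------------------------
    dia_dir = res_dir / "diagrams"
    dia_dir.mkdir(exist_ok=True)
    full_precision = {}
    for (pop, window), res in pooled.items():
        dot, payload = _stage("report")(render_diagram, res, cfg["threshold"])
        validate_diagram_payload(payload)
        (dia_dir / f"diagram_{pop}_{window}.dot").write_text(dot)
        (dia_dir / f"diagram_{pop}_{window}.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n")
        full_precision[f"{pop}_{window}"] = {
            "p": res.p.tolist(), "ci_lo": res.ci_lo.tolist(),
            "ci_hi": res.ci_hi.tolist(), "total_var": res.total_var.tolist()}
    for (a, b, window), res in contrasts.items():
        full_precision[f"contrast_{a}_vs_{b}_{window}"] = {
            "d": res.d.tolist(), "ci_lo": res.ci_lo.tolist(),
            "ci_hi": res.ci_hi.tolist()}
    (res_dir / "results.json").write_text(
        json.dumps(full_precision, indent=2, sort_keys=True) + "\n")

    manifest = {
        "config": cfg,
        "config_sha256": _config_hash(cfg),
        "package_version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "n_patients": int(cohort.n),
        "windows": {k: list(v) for k, v in windows.items()},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    return {"pooled": pooled, "contrasts": contrasts, "manifest": manifest,
            "out_dir": out}
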