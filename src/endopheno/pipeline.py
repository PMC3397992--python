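"""End-to-end pipeline: preprocess -> rank selection -> NMF -> transcript
selection -> downstream analyses, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import select_rank
from .downstream import differential_expression, mgl_qtl, u_allele_frequencies
from .io import align_samples, read_expression, read_genotypes, write_matrix
from .nmf import KLNMF
from .preprocess import filter_snps_maf, preprocess_expression
from .selection import select_optimal_t

log = logging.getLogger("endopheno")

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "out_dir": "endopheno_run",
    "expression": None,          # path; required
    "genotypes": None,           # path; optional
    "controls": None,            # path to control expression; optional
    "preprocess": {"enabled": False, "max_missing_frac": 0.30,
                   "mean_pct": 70.0, "var_pct": 50.0,
                   "interpretation": "top-fraction"},
    "rank": {"k_min": 2, "k_max": 5, "n_runs": 50},
    "k": None,                   # fixed rank; otherwise selected
    "selection": {"t_grid": [50, 100, 150, 200, 250, 300, 400, 800],
                  "ari_threshold": 0.95},
    "qtl": {"alpha": 1e-4, "min_maf": 0.10},
    "de": {"alpha": 1e-4},
    "nmf": {"max_iter": 2000, "tol": 1e-6, "restarts": 5},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict) -> dict:
    """Execute the full analysis described by ``config``.

    Stages run in a fixed order; any failure halts with the stage name.
    Every persisted artifact is listed in ``manifest.json`` with its
    parameters, seeds and content hash, so a rerun with the same config
    yields identical hashes.
    """
    cfg = _merge(DEFAULT_CONFIG, config)
    if not cfg["expression"]:
        raise ValueError("config requires an 'expression' path")
    for key in ("expression", "genotypes", "controls"):
        if cfg[key] and not Path(cfg[key]).exists():
            raise ValueError(f"config path for '{key}' does not exist: {cfg[key]}")
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest: dict = {"tool_version": __version__, "config": cfg, "stages": [], "files": {}}
    stage = "read"

    def emit(name: str, frame: pd.DataFrame, **params) -> None:
        path = out_dir / name
        write_matrix(frame, path, seed=seed, **params)
        manifest["files"][name] = _sha256(path)

    try:
        expr = read_expression(cfg["expression"])
        geno = read_genotypes(cfg["genotypes"]) if cfg["genotypes"] else None

        if cfg["preprocess"]["enabled"]:
            stage = "preprocess"
            t0 = time.time()
            pp = cfg["preprocess"]
            expr, report = preprocess_expression(
                expr, max_missing_frac=pp["max_missing_frac"],
                mean_pct=pp["mean_pct"], var_pct=pp["var_pct"],
                interpretation=pp["interpretation"])
            emit("expression_preprocessed.tsv", expr)
            emit("filter_report.tsv", report.table())
            manifest["stages"].append({"stage": stage, "seconds": time.time() - t0})

        if geno is not None:
            stage = "genotype_filter"
            geno, _ = filter_snps_maf(geno, cfg["qtl"]["min_maf"])
            expr, geno = align_samples(expr, geno)

        if cfg["k"] is None:
            stage = "select_rank"
            t0 = time.time()
            rk = cfg["rank"]
            ranksel = select_rank(expr, rk["k_min"], rk["k_max"],
                                  n_runs=rk["n_runs"], seed=seed,
                                  max_iter=cfg["nmf"]["max_iter"], tol=cfg["nmf"]["tol"])
            emit("rho_by_k.tsv", ranksel.table)
            k = ranksel.best_k
            manifest["stages"].append({"stage": stage, "k_star": k,
                                       "seconds": time.time() - t0})
        else:
            k = int(cfg["k"])

        stage = "nmf"
        t0 = time.time()
        fit = KLNMF(expr, k).fit_best(
            cfg["nmf"].get("restarts", 5),
            seed=np.random.SeedSequence((seed, 1)),
            max_iter=cfg["nmf"]["max_iter"], tol=cfg["nmf"]["tol"])
        emit("W.tsv", fit.W_frame())
        emit("H.tsv", fit.H_frame())
        labels = fit.assign_clusters()
        emit("labels.tsv", pd.DataFrame({"sample": expr.columns, "subtype": labels})
             .set_index("sample"))
        manifest["stages"].append({"stage": stage, "k": k, "n_iter": fit.n_iter,
                                   "final_divergence": fit.final_divergence,
                                   "seconds": time.time() - t0})

        stage = "select_transcripts"
        t0 = time.time()
        sel = cfg["selection"]
        report = select_optimal_t(expr, k, t_grid=sel["t_grid"],
                                  ari_threshold=sel["ari_threshold"], seed=seed,
                                  max_iter=cfg["nmf"]["max_iter"], tol=cfg["nmf"]["tol"],
                                  reference=fit)
        emit("selection_report.tsv", report.table)
        specific = pd.DataFrame(
            [(mg, tid) for mg, ids in report.metagene_specific.items() for tid in ids],
            columns=["metagene", "transcript"])
        emit("metagene_specific.tsv", specific.set_index("metagene")
             if len(specific) else specific)
        manifest["stages"].append({"stage": stage, "chosen_t": report.chosen_t,
                                   "seconds": time.time() - t0})

        if cfg["controls"]:
            stage = "differential_expression"
            controls = read_expression(cfg["controls"]).loc[expr.index]
            de_rows = [differential_expression(expr, controls, cfg["de"]["alpha"])
                       .assign(group="all")]
            for c in range(1, k + 1):
                de_rows.append(differential_expression(
                    expr.loc[:, labels == c], controls, cfg["de"]["alpha"])
                    .assign(group=f"MS{c}"))
            emit("de_results.tsv", pd.concat(de_rows))
            manifest["stages"].append({"stage": stage})

        if geno is not None:
            stage = "qtl"
            t0 = time.time()
            qtl_tables = {f"MGL{a + 1}": mgl_qtl(fit.H[a], geno, cfg["qtl"]["alpha"])
                          for a in range(k)}
            emit("qtl_results.tsv", pd.concat(qtl_tables, names=["mgl", "snp"]))
            emit("u_allele_summary.tsv",
                 u_allele_frequencies(qtl_tables, geno, labels))
            manifest["stages"].append({"stage": stage, "seconds": time.time() - t0})
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    # serialize config tuples etc. safely
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, default=str, indent=1, sort_keys=True))
    return manifest
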