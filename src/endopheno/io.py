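"""Delimited-matrix readers/writers, truth JSON and run configs.

Matrices are tab-separated with a header row of sample ids and a first
column of feature ids; missing expression values are written as ``NA``.
Output tables carry ``#``-prefixed provenance header lines (tool version,
seed, parameters) which readers skip.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .simulate import SimulationConfig, SimulationTruth

__all__ = [
    "read_expression",
    "read_genotypes",
    "write_matrix",
    "write_truth",
    "read_truth",
    "read_config",
    "align_samples",
]


def _read_matrix(path, value_name: str) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#",
                        na_values=["NA"], keep_default_na=False)
    if frame.index.has_duplicates:
        dupes = frame.index[frame.index.duplicated()].unique()
        raise ValueError(f"duplicate {value_name} ids in {path}: {list(dupes[:5])}")
    if frame.columns.has_duplicates:
        raise ValueError(f"duplicate sample ids in {path}")
    non_numeric = frame.apply(lambda c: ~c.map(
        lambda v: isinstance(v, (int, float, np.integer, np.floating)) or pd.isna(v)))
    if non_numeric.any(axis=None):
        raise ValueError(f"non-numeric cells in {path}")
    return frame.astype(float)


def read_expression(path) -> pd.DataFrame:
    """Transcripts x samples matrix; NA cells become NaN (the missing mask)."""
    return _read_matrix(path, "transcript")


def read_genotypes(path) -> pd.DataFrame:
    """SNPs x samples additive-dosage matrix with codes in {0, 1, 2}."""
    frame = _read_matrix(path, "snp")
    if frame.isna().any(axis=None):
        raise ValueError(f"missing genotype codes in {path}")
    values = frame.to_numpy()
    if not np.isin(values, (0.0, 1.0, 2.0)).all():
        bad = sorted(set(values.ravel()) - {0.0, 1.0, 2.0})
        raise ValueError(f"genotype codes outside {{0,1,2}} in {path}: {bad[:5]}")
    return frame.astype(int)


def provenance_header(seed=None, **params) -> str:
    parts = [f"# endopheno v{__version__}"]
    if seed is not None:
        parts.append(f"# seed: {seed}")
    if params:
        parts.append("# params: " + json.dumps(params, default=str, sort_keys=True))
    return "\n".join(parts) + "\n"


def write_matrix(frame: pd.DataFrame, path, *, seed=None, na_rep: str = "NA",
                 **params) -> None:
    """Write a matrix with provenance header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(provenance_header(seed=seed, **params))
        frame.to_csv(fh, sep="\t", na_rep=na_rep)


def write_truth(truth: SimulationTruth, path) -> None:
    payload = {
        "subtype_labels": truth.subtype_labels.tolist(),
        "sample_ids": truth.sample_ids,
        "informative_gene_index": {str(k): v for k, v in truth.informative_gene_index.items()},
        "informative_snp_index": {str(k): v for k, v in truth.informative_snp_index.items()},
        "rho_blocks": truth.rho_blocks,
        "config": dataclasses.asdict(truth.config),
        "tool_version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SimulationTruth:
    payload = json.loads(Path(path).read_text())
    cfg_dict = payload["config"]
    cfg_dict["corr_range"] = tuple(cfg_dict["corr_range"])
    config = SimulationConfig(**cfg_dict)
    return SimulationTruth(
        subtype_labels=np.asarray(payload["subtype_labels"]),
        sample_ids=payload["sample_ids"],
        informative_gene_index={int(k): v for k, v in payload["informative_gene_index"].items()},
        informative_snp_index={int(k): v for k, v in payload["informative_snp_index"].items()},
        config=config,
        rho_blocks=payload["rho_blocks"],
    )


def read_config(path) -> dict:
    """YAML or JSON run/simulation configuration."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    return yaml.safe_load(text)


def align_samples(expr: pd.DataFrame, geno: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reorder genotype columns to the expression sample order.

    A differing order is tolerated with a warning; differing sample sets
    are an error.
    """
    if list(expr.columns) == list(geno.columns):
        return expr, geno
    if set(expr.columns) != set(geno.columns):
        missing = set(expr.columns) ^ set(geno.columns)
        raise ValueError(f"expression/genotype sample sets differ: {sorted(missing)[:5]}")
    import warnings
    warnings.warn("genotype sample order differs from expression; realigning by id",
                  stacklevel=2)
    return expr, geno.loc[:, expr.columns]


def dump_yaml_config(obj, path) -> None:
    Path(path).write_text(yaml.safe_dump(obj, sort_keys=False))
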