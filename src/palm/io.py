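"""Readers/writers for summary statistics, annotations, results and models."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .trees import TreeEnsembleModel
from .two_groups import P_FLOOR

logger = logging.getLogger("palm")

_SNP_NAMES = {"snp", "rsid", "rs_id", "id", "variant_id", "marker", "markername"}
_P_NAMES = {"p", "pval", "pvalue", "p_value", "p.value"}
_Z_NAMES = {"z", "zscore", "z_score", "stat"}


def _sniff_sep(path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ("," if "," in header else r"\s+")


def _find_col(columns, wanted, explicit):
    if explicit is not None:
        if explicit not in columns:
            raise ValueError(f"column {explicit!r} not found; available: {list(columns)}")
        return explicit
    for c in columns:
        if c.lower() in wanted:
            return c
    return None


def read_sumstats(path, snp_col: str | None = None, p_col: str | None = None,
                  z_col: str | None = None) -> pd.DataFrame:
    """Read a delimited sumstats file into a frame with columns (snp, p).

    The p column is used when present; otherwise a z column is converted via
    p = 2*(1 - Phi(|z|)). Unparseable p rows are dropped with a warning; p
    values are clipped into [1e-300, 1] and the number of clipped entries logged.
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    snp = _find_col(df.columns, _SNP_NAMES, snp_col)
    if snp is None:
        raise ValueError(f"no SNP identifier column found; available: {list(df.columns)}")
    pc = _find_col(df.columns, _P_NAMES, p_col)
    if pc is not None:
        p = pd.to_numeric(df[pc], errors="coerce")
    else:
        zc = _find_col(df.columns, _Z_NAMES, z_col)
        if zc is None:
            raise ValueError(
                f"need a p-value or z-score column; available: {list(df.columns)}")
        z = pd.to_numeric(df[zc], errors="coerce")
        p = pd.Series(2.0 * norm.sf(np.abs(z)), index=df.index)
    out = pd.DataFrame({"snp": df[snp].astype(str), "p": p})
    n_bad = int(out["p"].isna().sum())
    if n_bad:
        logger.warning("dropped %d rows with unparseable p-values", n_bad)
        out = out.dropna(subset=["p"])
    n_clip = int(((out["p"] < P_FLOOR) | (out["p"] > 1)).sum())
    if n_clip:
        logger.warning("clipped %d p-values into [%g, 1]", n_clip, P_FLOOR)
    out["p"] = out["p"].clip(P_FLOOR, 1.0)
    if out["snp"].duplicated().any():
        raise ValueError("duplicate SNP identifiers in sumstats")
    return out.reset_index(drop=True)


def read_annotations(path, snp_ids) -> tuple[np.ndarray, list]:
    """Read an annotation table (first column = SNP id) aligned to ``snp_ids``.

    Blank/NA tokens become NaN; SNPs absent from the file get all-missing rows
    (they are routed by each split's default direction at prediction time).
    Returns (M x L float matrix, annotation names).
    """
    df = pd.read_csv(path, sep=_sniff_sep(path))
    id_col = df.columns[0]
    df[id_col] = df[id_col].astype(str)
    names = list(df.columns[1:])
    df = df.set_index(id_col)
    snp_ids = pd.Index(pd.Series(snp_ids).astype(str))
    overlap = snp_ids.intersection(df.index)
    if overlap.empty:
        raise ValueError("no overlapping SNP identifiers between sumstats and annotations")
    n_absent = len(snp_ids) - len(overlap)
    if n_absent:
        logger.warning("%d SNPs missing from annotation file; rows set all-missing", n_absent)
    aligned = df.reindex(snp_ids)
    A = aligned.apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return A, names


def write_results(path, snp_ids, p, prior, result) -> None:
    """Write the per-SNP results table (row order preserved from input)."""
    df = pd.DataFrame({
        "snp": snp_ids,
        "p": p,
        "prior": prior,
        "posterior": result.q1,
        "local_fdr": result.local_fdr,
        "global_Fdr_at_rank": result.cum_fdr,
        "rejected": result.rejected.astype(int),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def save_model(path, model: TreeEnsembleModel) -> None:
    Path(path).write_text(json.dumps(model.to_dict()))


def load_model(path) -> TreeEnsembleModel:
    return TreeEnsembleModel.from_dict(json.loads(Path(path).read_text()))


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, config: dict, inputs: dict) -> None:
    """JSON run manifest: config, seed, library versions and input checksums."""
    manifest = {
        "config": config,
        "inputs": {k: {"path": str(v), "sha256": file_checksum(v)}
                   for k, v in inputs.items()},
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2))
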