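"""Canonical CSV schema for meta-analytic corpora, with validation.

One row per effect size.  Required columns: meta_id, study_id, obs_id,
metric, es, and var or se (both allowed if consistent).  Optional: n_e,
n_c (group sizes, SMD/lnRR), n_total (Zr), year.  Each meta-analysis must
use a single metric and unique (meta_id, study_id, obs_id) keys.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .effect_sizes import METRICS

__all__ = ["CorpusValidationError", "load_corpus", "validate_corpus", "write_corpus"]

REQUIRED = ["meta_id", "study_id", "obs_id", "metric", "es"]
OPTIONAL = ["var", "se", "n_e", "n_c", "n_total", "year"]
_SE_TOL = 1e-8


class CorpusValidationError(ValueError):
    """The corpus table violates the documented schema."""


def validate_corpus(df: pd.DataFrame) -> pd.DataFrame:
    """Validate (and lightly normalize) a corpus table.

    Returns a copy with both var and se present and consistent.  Raises
    CorpusValidationError naming offending rows on any violation.
    """
    missing = [c for c in REQUIRED if c not in df.columns]
    if missing:
        raise CorpusValidationError(f"missing required columns: {missing}")
    if "var" not in df.columns and "se" not in df.columns:
        raise CorpusValidationError("need a 'var' or 'se' column")
    out = df.copy()
    if "var" not in out.columns:
        out["var"] = out["se"].astype(float) ** 2
    out["var"] = out["var"].astype(float)
    if "se" not in out.columns:
        out["se"] = np.sqrt(out["var"])
    out["se"] = out["se"].astype(float)

    bad = out.index[~(out["var"] > 0) | ~np.isfinite(out["var"])]
    if len(bad):
        raise CorpusValidationError(f"non-positive or non-finite sampling variance at rows {list(bad[:10])}")
    mismatch = out.index[np.abs(out["se"] - np.sqrt(out["var"])) > _SE_TOL * np.maximum(out["se"], 1.0)]
    if len(mismatch):
        raise CorpusValidationError(f"se inconsistent with sqrt(var) at rows {list(mismatch[:10])}")

    keys = out[["meta_id", "study_id", "obs_id"]].astype(str)
    dup = keys.duplicated()
    if dup.any():
        raise CorpusValidationError(
            f"duplicate (meta_id, study_id, obs_id) keys at rows {list(out.index[dup][:10])}"
        )

    bad_metric = out.index[~out["metric"].isin(METRICS)]
    if len(bad_metric):
        raise CorpusValidationError(
            f"unknown metric (expected {METRICS}) at rows {list(bad_metric[:10])}"
        )
    mixed = out.groupby("meta_id")["metric"].nunique()
    mixed = mixed[mixed > 1]
    if len(mixed):
        raise CorpusValidationError(
            f"mixed metrics within meta-analyses: {list(mixed.index[:10])}"
        )

    if "n_total" in out.columns:
        zr = out[(out["metric"] == "Zr") & out["n_total"].notna()]
        bad_n = zr.index[zr["n_total"] <= 3]
        if len(bad_n):
            raise CorpusValidationError(f"Zr rows with n_total <= 3 at rows {list(bad_n[:10])}")
    if "year" in out.columns:
        yr = out["year"].dropna()
        bad_year = yr.index[(yr < 1800) | (yr > 2200)]
        if len(bad_year):
            raise CorpusValidationError(f"implausible years at rows {list(bad_year[:10])}")
    return out


def load_corpus(path: str | Path) -> pd.DataFrame:
    """Read and validate a corpus CSV."""
    df = pd.read_csv(path)
    return validate_corpus(df)


def write_corpus(df: pd.DataFrame, path: str | Path) -> None:
    """Write a corpus table in the canonical column order."""
    cols = [c for c in REQUIRED + OPTIONAL if c in df.columns]
    df[cols].to_csv(path, index=False)
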