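"""End-to-end orchestration: corpus in, results bundle out.

The pipeline runs, per meta-analysis, the uncorrected multilevel fit, the
linear detection and quadratic correction meta-regressions and the
decision tree; refits everything on the standardized scale; pools the
standardized slopes across meta-analyses (full and expected-direction
reduced datasets, with an effect-size-type moderator); computes and pools
folded-normal shrinkage; evaluates power / Type S / Type M per effect
size and per meta-analysis under uncorrected and corrected truths, with
and without the post hoc filter; and tallies the headline counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .bias import analyze_meta
from .design import (
    aggregate_meta_level,
    aggregate_sampling_level,
    design_metrics,
)
from .io import validate_corpus
from .pooling import pool_coefficients, standardize_case
from .shrinkage import backtransform_summary, difference_and_fold, pool_differences

logger = logging.getLogger("metabias")

__all__ = ["PipelineConfig", "CountSummary", "ResultsBundle", "run_pipeline", "summarize_counts"]


@dataclass
class PipelineConfig:
    """Every analysis toggle in one place (all defaults are the main path)."""

    alpha: float = 0.05
    predictor_mode: str = "auto"          # auto | effective_n | se
    correction_variant: str = "main_text"  # main_text | figure_caption
    inference: str = "z"                   # z | t
    corrected_estimate: str = "type2"      # which corrected intercept feeds truths
    fold_r: float = 1.0                    # correlation of SEs in Var(D)
    min_k: int = 4
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CountSummary:
    """Counts and integer percentages of bias evidence across the corpus."""

    n_cases: int
    n_sig_small_study: int
    pct_sig_small_study: int
    n_expected_dir_small_study: int
    pct_expected_dir_small_study: int
    n_sig_decline: int
    pct_sig_decline: int
    n_expected_dir_decline: int
    pct_expected_dir_decline: int
    n_sig_overall: int
    n_sig_to_nonsig: int
    pct_sig_to_nonsig: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_counts(bias_cases: pd.DataFrame, alpha: float = 0.05) -> CountSummary:
    """Tally significant and expected-direction slopes and significance
    transitions of the overall mean after correction."""
    n = len(bias_cases)

    def pct(x):
        return int(round(100.0 * x / n)) if n else 0

    b1 = bias_cases["beta1_small_study"]
    p1 = bias_cases["p_beta1"]
    exp1 = bias_cases["expected_sign_beta1"]
    has1 = b1.notna()
    sig1 = int(((p1 < alpha) & has1).sum())
    dir1 = int(((np.sign(b1) == exp1) & has1 & (exp1 != 0)).sum())

    b2 = bias_cases["beta2_time_lag"]
    p2 = bias_cases["p_beta2"]
    exp2 = bias_cases["expected_sign_beta2"]
    has2 = b2.notna()
    sig2 = int(((p2 < alpha) & has2).sum())
    dir2 = int(((np.sign(b2) == exp2) & has2 & (exp2 != 0)).sum())

    sig0 = bias_cases["p_overall"] < alpha
    n_sig0 = int(sig0.sum())
    trans = int((sig0 & (bias_cases["p_corrected_type2"] >= alpha)).sum())
    pct_trans = int(round(100.0 * trans / n_sig0)) if n_sig0 else 0

    return CountSummary(
        n_cases=n,
        n_sig_small_study=sig1,
        pct_sig_small_study=pct(sig1),
        n_expected_dir_small_study=dir1,
        pct_expected_dir_small_study=pct(dir1),
        n_sig_decline=sig2,
        pct_sig_decline=pct(sig2),
        n_expected_dir_decline=dir2,
        pct_expected_dir_decline=pct(dir2),
        n_sig_overall=n_sig0,
        n_sig_to_nonsig=trans,
        pct_sig_to_nonsig=pct_trans,
    )


@dataclass
class ResultsBundle:
    """Everything the pipeline computed, serializable to a report directory."""

    bias_cases: pd.DataFrame
    standardized_cases: pd.DataFrame
    folded_differences: pd.DataFrame
    second_order: dict
    shrinkage: dict
    design_sampling: pd.DataFrame
    design_meta: pd.DataFrame
    design_aggregates: dict
    counts: CountSummary
    skip_log: list
    config: PipelineConfig
    version: str = _pkg_version

    def summaries(self) -> dict:
        """JSON-ready digest of the pooled and aggregated results."""
        return {
            "version": self.version,
            "config": self.config.to_dict(),
            "counts": self.counts.to_dict(),
            "second_order": {k: s.to_dict() for k, s in self.second_order.items()},
            "shrinkage": {
                k: (s.to_dict() if hasattr(s, "to_dict") else s)
                for k, s in self.shrinkage.items()
            },
            "design_aggregates": {
                k: a.to_dict() for k, a in self.design_aggregates.items()
            },
            "skip_log": self.skip_log,
        }

    def to_dir(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.bias_cases.to_csv(outdir / "bias_cases.csv", index=False)
        self.standardized_cases.to_csv(outdir / "standardized_cases.csv", index=False)
        self.folded_differences.to_csv(outdir / "folded_differences.csv", index=False)
        self.design_sampling.to_csv(outdir / "design_sampling.csv", index=False)
        self.design_meta.to_csv(outdir / "design_meta.csv", index=False)
        with open(outdir / "summaries.json", "w") as fh:
            json.dump(self.summaries(), fh, indent=2, default=float)


def _per_case_tables(corpus, cfg):
    bias_rows, std_rows, skip = [], [], []
    for meta_id, df in corpus.groupby("meta_id", sort=True):
        df = df.reset_index(drop=True)
        if len(df) < cfg.min_k:
            skip.append({"meta_id": str(meta_id), "reason": f"k={len(df)} < {cfg.min_k}"})
            continue
        try:
            case = analyze_meta(
                df,
                predictor_mode=cfg.predictor_mode,
                variant=cfg.correction_variant,
                inference=cfg.inference,
            )
            std = standardize_case(
                df,
                predictor_mode=cfg.predictor_mode,
                variant=cfg.correction_variant,
                inference=cfg.inference,
            )
        except Exception as exc:  # per-case failures are logged, not fatal
            logger.warning("skipping %s: %s", meta_id, exc)
            skip.append({"meta_id": str(meta_id), "reason": str(exc)})
            continue
        bias_rows.append(case.to_dict())
        std_rows.append(std.to_dict())
    return pd.DataFrame(bias_rows), pd.DataFrame(std_rows), skip


def _pool_standardized(std: pd.DataFrame, cfg) -> dict:
    """Second-order pooling of standardized slopes, full and reduced."""
    out = {}
    specs = [
        ("small_study", "eta1_small_effect", "se_eta1", "expected_sign_eta1"),
        ("decline", "eta2_time_lag", "se_eta2", "expected_sign_eta2"),
    ]
    for label, col, se_col, exp_col in specs:
        has = std[col].notna() & std[se_col].notna()
        full = std[has]
        out[f"{label}_full"] = pool_coefficients(
            full[col], full[se_col], moderator=full["metric"],
            coefficient=f"{label}_full", inference=cfg.inference,
        )
        reduced = full[np.sign(full[col]) == full[exp_col]]
        if len(reduced) >= 2:
            out[f"{label}_reduced"] = pool_coefficients(
                reduced[col], reduced[se_col], moderator=reduced["metric"],
                coefficient=f"{label}_reduced", inference=cfg.inference,
            )
    return out


def _fold_cases(std: pd.DataFrame, cfg) -> tuple[pd.DataFrame, dict]:
    rows = []
    for variant, est_col, se_col in (
        ("full", "eta0_corrected_type1", "se_eta0_corrected_type1"),
        ("reduced", "eta0_corrected_type2", "se_eta0_corrected_type2"),
    ):
        for _, row in std.iterrows():
            fd = difference_and_fold(
                row["eta0_overall"],
                row["se_eta0_overall"],
                row[est_col],
                row[se_col],
                r=cfg.fold_r,
                meta_id=row["meta_id"],
                metric=row["metric"],
                sd_response=row["sd_response"],
            )
            rec = fd.to_dict()
            rec["variant"] = variant
            rows.append(rec)
    folded = pd.DataFrame(rows)
    shrink = {}
    for variant, sub in folded.groupby("variant"):
        shrink[f"pooled_{variant}"] = pool_differences(sub, moderator=True, inference=cfg.inference)
        shrink[f"backtransformed_{variant}"] = backtransform_summary(sub).to_dict()
    return folded, shrink


def _truth_column(bias: pd.DataFrame, cfg, mode: str) -> pd.Series:
    if mode == "uncorrected":
        return bias["beta0_overall"]
    col = "beta0_corrected_type2" if cfg.corrected_estimate == "type2" else "beta0_corrected_type1"
    return bias[col]


def _design_tables(corpus, bias, cfg):
    merged = corpus.merge(
        bias[
            [
                "meta_id", "beta0_overall", "se_overall", "p_overall",
                "beta0_corrected_type1", "beta0_corrected_type2", "k",
            ]
        ],
        on="meta_id",
        how="inner",
    )
    merged["study_uid"] = merged["meta_id"].astype(str) + "/" + merged["study_id"].astype(str)
    merged["overall_significant"] = merged["p_overall"] < cfg.alpha

    sampling_frames, meta_frames = [], []
    for mode in ("uncorrected", "corrected"):
        truth_by_meta = _truth_column(bias, cfg, mode)
        truth_map = dict(zip(bias["meta_id"], truth_by_meta))
        rows = []
        for _, r in merged.iterrows():
            dm = design_metrics(truth_map[r["meta_id"]], float(np.sqrt(r["var"])), cfg.alpha)
            rows.append(
                {
                    "meta_id": r["meta_id"],
                    "study_uid": r["study_uid"],
                    "metric": r["metric"],
                    "truth_mode": mode,
                    "true_effect": dm.true_effect,
                    "se": dm.se,
                    "power": dm.power,
                    "type_s": dm.type_s,
                    "type_m": dm.type_m,
                    "overall_significant": bool(r["overall_significant"]),
                }
            )
        sampling_frames.append(pd.DataFrame(rows))

        rows = []
        for _, b in bias.iterrows():
            dm = design_metrics(float(truth_map[b["meta_id"]]), float(b["se_overall"]), cfg.alpha)
            rows.append(
                {
                    "meta_id": b["meta_id"],
                    "metric": b["metric"],
                    "truth_mode": mode,
                    "k": int(b["k"]),
                    "true_effect": dm.true_effect,
                    "se": dm.se,
                    "power": dm.power,
                    "type_s": dm.type_s,
                    "type_m": dm.type_m,
                    "overall_significant": bool(b["p_overall"] < cfg.alpha),
                }
            )
        meta_frames.append(pd.DataFrame(rows))

    sampling = pd.concat(sampling_frames, ignore_index=True)
    meta = pd.concat(meta_frames, ignore_index=True)

    aggregates = {}
    for mode in ("uncorrected", "corrected"):
        for filt in (False, True):
            key = f"sampling_{mode}" + ("_filtered" if filt else "")
            try:
                aggregates[key] = aggregate_sampling_level(
                    sampling[sampling["truth_mode"] == mode], mode, post_hoc_filter=filt
                )
            except ValueError as exc:
                logger.warning("aggregation %s failed: %s", key, exc)
            key = f"meta_{mode}" + ("_filtered" if filt else "")
            try:
                aggregates[key] = aggregate_meta_level(
                    meta[meta["truth_mode"] == mode], mode, post_hoc_filter=filt
                )
            except ValueError as exc:
                logger.warning("aggregation %s failed: %s", key, exc)
    return sampling, meta, aggregates


def run_pipeline(corpus: pd.DataFrame, config: PipelineConfig | None = None) -> ResultsBundle:
    """Run the full two-level analysis on a validated corpus table."""
    cfg = config or PipelineConfig()
    corpus = validate_corpus(corpus)
    bias, std, skip = _per_case_tables(corpus, cfg)
    if bias.empty:
        raise ValueError("no analysable meta-analyses in the corpus")
    second_order = _pool_standardized(std, cfg)
    folded, shrinkage = _fold_cases(std, cfg)
    sampling, meta, aggregates = _design_tables(corpus, bias, cfg)
    counts = summarize_counts(bias, cfg.alpha)
    return ResultsBundle(
        bias_cases=bias,
        standardized_cases=std,
        folded_differences=folded,
        second_order=second_order,
        shrinkage=shrinkage,
        design_sampling=sampling,
        design_meta=meta,
        design_aggregates=aggregates,
        counts=counts,
        skip_log=skip,
        config=cfg,
    )
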