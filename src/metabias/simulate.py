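"""Synthetic meta-analytic literatures with known ground truth.

The generator emulates the hierarchical structure the analysis pipeline
assumes: effect sizes nested in studies nested in meta-analyses, a shared
true effect, between-study and observation-level heterogeneity, sampling
variances derived from simulated group sizes via the exact metric
formulas, publication years, and — optionally — selective publication of
significant results, with a time-relaxing variant that induces a decline
effect among published records.

The empirical corpus this emulates was observational, so every generative
choice here is a stand-in: two-group experiments are simulated with unit
population SD (SMD), constant coefficient of variation (lnRR), or as
bivariate-normal correlations (Zr).  Selection retains a non-significant
record with probability ``exp(-selection_strength)``, the simplest
monotone mechanism producing small-study signatures; the decline variant
lets that strength fall linearly to zero at the latest publication year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .effect_sizes import METRICS, fisher_z, hedges_g, log_response_ratio

__all__ = [
    "GeneratorConfig",
    "DegenerateCorpusError",
    "generate_corpus",
    "generate_meta_analysis",
    "apply_selection",
]


class DegenerateCorpusError(RuntimeError):
    """Selection removed so many records the dataset is unusable."""


def _as_range(value, name: str) -> tuple[int, int]:
    if np.isscalar(value):
        lo = hi = int(value)
    else:
        lo, hi = int(value[0]), int(value[1])
    if lo > hi or lo < 1:
        raise ValueError(f"invalid range for {name}: {value!r}")
    return lo, hi


@dataclass
class GeneratorConfig:
    """Conditions under which a synthetic literature is generated.

    Defaults describe a mid-sized ecological literature: 30 meta-analyses
    of 10–30 studies contributing 1–3 effect sizes each, a moderate true
    effect of 0.3 with between-study SD 0.2 and observation-level SD 0.1
    (heterogeneity comparable to the sampling noise of typical group sizes
    of 5–50 per arm), publication years spanning two decades, and no
    selection unless asked for.
    """

    n_meta: int = 30
    studies_per_meta: int | tuple[int, int] = (10, 30)
    effects_per_study: int | tuple[int, int] = (1, 3)
    metric: str = "SMD"              # "SMD", "lnRR", "Zr" or "mixed"
    true_effect: float = 0.3
    between_study_sd: float = 0.2
    within_study_sd: float = 0.1
    group_size_range: tuple[int, int] = (5, 50)
    year_range: tuple[int, int] = (2000, 2020)
    selection_strength: float = 0.0
    decline_slope: float = 0.0       # direct drift of the true effect per year
    decline_selection: bool = False  # selection relaxing toward the latest year
    lnrr_control_mean: float = 10.0
    lnrr_cv: float = 0.3
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_meta < 1:
            raise ValueError("n_meta must be >= 1")
        if self.between_study_sd < 0 or self.within_study_sd < 0:
            raise ValueError("heterogeneity SDs must be non-negative")
        if self.selection_strength < 0:
            raise ValueError("selection_strength must be >= 0")
        if self.metric not in METRICS + ("mixed",):
            raise ValueError(f"metric must be one of {METRICS} or 'mixed'")
        lo, hi = _as_range(self.group_size_range, "group_size_range")
        if lo < 3:
            raise ValueError("group sizes must be >= 3")
        y0, y1 = self.year_range
        if y1 < y0:
            raise ValueError("year_range is empty")
        _as_range(self.studies_per_meta, "studies_per_meta")
        _as_range(self.effects_per_study, "effects_per_study")

    def to_dict(self) -> dict:
        return asdict(self)


def _sample_sd(rng, pop_sd: float, n: int) -> float:
    """Sample SD of n normal draws with population SD pop_sd (chi dist)."""
    return pop_sd * math.sqrt(rng.chisquare(n - 1) / (n - 1))


def _simulate_record(rng, metric: str, theta: float, cfg: GeneratorConfig):
    """One observed effect size with metric-appropriate sampling noise."""
    lo, hi = _as_range(cfg.group_size_range, "group_size_range")
    if metric == "SMD":
        n_e = int(rng.integers(lo, hi + 1))
        n_c = int(rng.integers(lo, hi + 1))
        mean_c = rng.normal(0.0, 1.0 / math.sqrt(n_c))
        mean_e = rng.normal(theta, 1.0 / math.sqrt(n_e))
        sd_c = _sample_sd(rng, 1.0, n_c)
        sd_e = _sample_sd(rng, 1.0, n_e)
        es, var = hedges_g(mean_e, sd_e, n_e, mean_c, sd_c, n_c)
        return es, var, n_e, n_c, np.nan
    if metric == "lnRR":
        n_e = int(rng.integers(lo, hi + 1))
        n_c = int(rng.integers(lo, hi + 1))
        mu_c = cfg.lnrr_control_mean
        mu_e = mu_c * math.exp(theta)
        sd_pop_c = cfg.lnrr_cv * mu_c
        sd_pop_e = cfg.lnrr_cv * mu_e
        mean_c = max(rng.normal(mu_c, sd_pop_c / math.sqrt(n_c)), 1e-6)
        mean_e = max(rng.normal(mu_e, sd_pop_e / math.sqrt(n_e)), 1e-6)
        sd_c = max(_sample_sd(rng, sd_pop_c, n_c), 1e-8)
        sd_e = max(_sample_sd(rng, sd_pop_e, n_e), 1e-8)
        es, var = log_response_ratio(mean_e, sd_e, n_e, mean_c, sd_c, n_c)
        return es, var, n_e, n_c, np.nan
    # Zr: one sample of n pairs from a bivariate normal with rho = tanh(theta)
    n = max(int(rng.integers(lo, hi + 1)) + int(rng.integers(lo, hi + 1)), 5)
    rho = math.tanh(theta)
    x = rng.standard_normal(n)
    z = rng.standard_normal(n)
    w = rho * x + math.sqrt(1.0 - rho**2) * z
    r = float(np.corrcoef(x, w)[0, 1])
    r = min(max(r, -0.999999), 0.999999)
    es, var = fisher_z(r, n)
    return es, var, np.nan, np.nan, n


def generate_meta_analysis(
    cfg: GeneratorConfig, meta_id: str, metric: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate one meta-analysis' record table (before any selection)."""
    s_lo, s_hi = _as_range(cfg.studies_per_meta, "studies_per_meta")
    e_lo, e_hi = _as_range(cfg.effects_per_study, "effects_per_study")
    n_studies = int(rng.integers(s_lo, s_hi + 1))
    y0, y1 = cfg.year_range
    rows = []
    for j in range(n_studies):
        study_id = f"{meta_id}_S{j + 1:03d}"
        year = int(rng.integers(y0, y1 + 1))
        s_j = rng.normal(0.0, cfg.between_study_sd)
        n_eff = int(rng.integers(e_lo, e_hi + 1))
        for i in range(n_eff):
            o_ji = rng.normal(0.0, cfg.within_study_sd)
            theta = (
                cfg.true_effect
                + cfg.decline_slope * (year - y0)
                + s_j
                + o_ji
            )
            es, var, n_e, n_c, n_total = _simulate_record(rng, metric, theta, cfg)
            rows.append(
                {
                    "meta_id": meta_id,
                    "study_id": study_id,
                    "obs_id": f"{study_id}_E{i + 1}",
                    "metric": metric,
                    "es": es,
                    "var": var,
                    "se": math.sqrt(var),
                    "n_e": n_e,
                    "n_c": n_c,
                    "n_total": n_total,
                    "year": year,
                }
            )
    return pd.DataFrame(rows)


def apply_selection(
    df: pd.DataFrame,
    selection_strength: float,
    decline_mode: bool = False,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Selectively retain records, mimicking publication of significant results.

    Statistically significant records (two-sided p < alpha from es / se) are
    always retained; a non-significant record survives with probability
    ``exp(-s)``, where s is `selection_strength`, or, with `decline_mode`,
    that strength scaled by ``(year_latest - year) / (year_latest -
    year_earliest)`` so selection relaxes to zero at the latest year (late
    non-significant effects are published more readily, producing a decline
    in the published record).

    Raises DegenerateCorpusError if fewer than 2 studies survive.
    """
    if selection_strength < 0:
        raise ValueError("selection_strength must be >= 0")
    if selection_strength == 0:
        return df
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    se = np.sqrt(df["var"].to_numpy(float))
    z = df["es"].to_numpy(float) / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    significant = pvals < alpha
    strength = np.full(len(df), float(selection_strength))
    if decline_mode:
        year = df["year"].to_numpy(float)
        span = year.max() - year.min()
        if span > 0:
            strength = selection_strength * (year.max() - year) / span
        else:
            strength[:] = 0.0
    retain_prob = np.exp(-strength)
    keep = significant | (rng.random(len(df)) < retain_prob)
    out = df.loc[keep]
    if out["study_id"].nunique() < 2:
        raise DegenerateCorpusError(
            f"selection left {out['study_id'].nunique()} studies in "
            f"{df['meta_id'].iloc[0]}; corpus degenerate"
        )
    return out.reset_index(drop=True)


def generate_corpus(cfg: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a corpus of meta-analyses plus its ground-truth sidecar.

    Returns (corpus, truth): the corpus in the canonical record schema and
    one truth row per meta-analysis with the generating parameters.
    Deterministic given cfg.seed; each meta-analysis has its own child
    seed so it can be regenerated in isolation.
    """
    master = np.random.SeedSequence(cfg.seed)
    children = master.spawn(cfg.n_meta)
    corpora, truths = [], []
    for m, child in enumerate(children):
        rng = np.random.default_rng(child)
        meta_id = f"MA{m + 1:03d}"
        if cfg.metric == "mixed":
            metric = METRICS[m % len(METRICS)]
        else:
            metric = cfg.metric
        df = generate_meta_analysis(cfg, meta_id, metric, rng)
        if cfg.selection_strength > 0:
            df = apply_selection(
                df,
                cfg.selection_strength,
                decline_mode=cfg.decline_selection,
                seed=rng,
                alpha=cfg.alpha,
            )
        corpora.append(df)
        truths.append(
            {
                "meta_id": meta_id,
                "metric": metric,
                "true_effect": cfg.true_effect,
                "sigma2_study": cfg.between_study_sd**2,
                "sigma2_obs": cfg.within_study_sd**2,
                "selection_strength": cfg.selection_strength,
                "decline_slope": cfg.decline_slope,
                "decline_selection": cfg.decline_selection,
            }
        )
    return pd.concat(corpora, ignore_index=True), pd.DataFrame(truths)
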