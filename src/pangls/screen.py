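"""Pangenome-wide PGLS screen of trait–copy-number associations.

For every orthogroup that passes the variance and prevalence filters, the
trait is regressed on copy number under three error structures — Pagel's λ
profiled over [0, 1], λ fixed to 0 (independent residuals) and λ fixed to 1
(Brownian) — and the model with the lowest AIC is selected (ties go to the
fixed-λ model, which spends one fewer parameter).  An orthogroup is called
significant when, in its selected model, the slope standard error is below
``se_max``, the slope exceeds ``slope_min`` (signed, by default positive),
and the whitened residuals do not reject Shapiro–Wilk normality.

No per-orthogroup p-value threshold is applied: significance is defined by
the SE/slope/normality filters alone, and no multiple-testing correction
across orthogroups is performed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import DataValidationError, Phylogeny, align_matrix_to_tree
from .phylo import (NumericalError, gls_fit, lambda_transform, phylo_covariance,
                    profile_lambda)

logger = logging.getLogger(__name__)

MODEL_NAMES = ("lambda_free", "lambda_0", "lambda_1")


@dataclass
class ScreenConfig:
    """Filter thresholds of the association screen.

    ``variance_min`` and ``prevalence_min`` gate which orthogroups are
    analyzed at all (population copy-number variance > 0.25 and presence in
    at least a quarter of genomes, rounded up).  ``se_max``/``slope_min``/
    ``sw_alpha`` are the post-fit robustness filters applied to the selected
    model.  Thresholds are on the raw copy-number scale.
    """

    variance_min: float = 0.25
    prevalence_min: float = 0.25
    se_max: float = 0.25
    slope_min: float = 0.25
    sw_alpha: float = 0.05
    slope_sign: str = "positive"    # or "absolute"
    reml: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.prevalence_min <= 1.0:
            raise ValueError("prevalence_min must be in (0, 1]")
        for name in ("variance_min", "se_max", "slope_min", "sw_alpha"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.slope_sign not in ("positive", "absolute"):
            raise ValueError("slope_sign must be 'positive' or 'absolute'")


def filter_orthogroups(matrix: pd.DataFrame,
                       config: ScreenConfig) -> tuple[pd.DataFrame, dict]:
    """Keep orthogroups with variance > variance_min and sufficient prevalence.

    Variance is the population (divisor n) variance across genomes;
    prevalence requires presence (count >= 1) in at least
    ceil(prevalence_min * n_genomes) genomes.  Returns the retained
    sub-matrix and a per-rule report of drop counts.
    """
    n = matrix.shape[1]
    variance = matrix.var(axis=1, ddof=0)
    prevalence = (matrix >= 1).sum(axis=1)
    threshold = math.ceil(config.prevalence_min * n)
    keep_var = variance > config.variance_min
    keep_prev = prevalence >= threshold
    kept = matrix.loc[keep_var & keep_prev]
    report = {
        "n_input": int(matrix.shape[0]),
        "n_dropped_variance": int((~keep_var).sum()),
        "n_dropped_prevalence": int((~keep_prev).sum()),
        "n_retained": int(kept.shape[0]),
        "prevalence_threshold": threshold,
    }
    if kept.shape[0] == 0:
        raise DataValidationError("no orthogroups pass filters")
    return kept, report


def fit_association_models(y: np.ndarray, x: np.ndarray, V: np.ndarray,
                           reml: bool = False) -> dict:
    """Fit trait ~ copy number under λ profiled, λ = 0 and λ = 1.

    Returns a flat record with slope/SE/λ/lnL/AIC per model, the AIC-selected
    model, and the Shapiro–Wilk statistic of its whitened residuals.  AIC
    counts intercept, slope and σ², plus one for a profiled λ.
    """
    X = np.column_stack([np.ones_like(x, dtype=float), x.astype(float)])
    record: dict = {}
    fits: dict = {}
    for name in MODEL_NAMES:
        try:
            if name == "lambda_free":
                prof = profile_lambda(y, X, V, reml=reml)
                fit, lam = prof.fit, prof.lam
                record["profile_flat"] = prof.profile_flat
            else:
                lam = 0.0 if name == "lambda_0" else 1.0
                fit = gls_fit(y, X, lambda_transform(V, lam), reml=reml)
            k = fit.n_params + (1 if name == "lambda_free" else 0)
            fits[name] = fit
            record.update({
                f"{name}_slope": float(fit.beta[1]),
                f"{name}_se": float(fit.se[1]),
                f"{name}_lambda": lam,
                f"{name}_loglik": fit.loglik,
                f"{name}_aic": 2.0 * k - 2.0 * fit.loglik,
            })
        except NumericalError as exc:
            record[f"{name}_error"] = str(exc)
    fitted = [m for m in MODEL_NAMES if f"{m}_aic" in record]
    if not fitted:
        record["fit_failed"] = True
        return record
    # min AIC; ties favor the later (fixed-λ, fewer-parameter) models
    best = min(reversed(fitted), key=lambda m: record[f"{m}_aic"])
    record["selected_model"] = best
    record["slope"] = record[f"{best}_slope"]
    record["se"] = record[f"{best}_se"]
    record["lambda"] = record[f"{best}_lambda"]
    record["aic"] = record[f"{best}_aic"]
    resid = fits[best].whitened_residuals
    try:
        w, p_sw = stats.shapiro(resid)
        record["shapiro_w"], record["shapiro_p"] = float(w), float(p_sw)
    except ValueError:
        record["shapiro_w"] = record["shapiro_p"] = np.nan
    record["fit_failed"] = False
    return record


def apply_robustness_filters(record: dict, config: ScreenConfig) -> dict:
    """Attach pass/fail flags for the SE, slope and normality filters."""
    out = dict(record)
    if record.get("fit_failed", False):
        out.update({"pass_se": False, "pass_slope": False, "pass_normality": False,
                    "significant": False})
        return out
    slope = record["slope"]
    if config.slope_sign == "absolute":
        slope = abs(slope)
    out["pass_se"] = bool(record["se"] < config.se_max)
    out["pass_slope"] = bool(slope > config.slope_min)
    p_sw = record.get("shapiro_p", np.nan)
    out["pass_normality"] = bool(np.isfinite(p_sw) and p_sw >= config.sw_alpha)
    out["significant"] = out["pass_se"] and out["pass_slope"] and out["pass_normality"]
    return out


RESULT_COLUMNS = [
    "variance", "prevalence",
    "lambda_free_slope", "lambda_free_se", "lambda_free_lambda",
    "lambda_free_loglik", "lambda_free_aic",
    "lambda_0_slope", "lambda_0_se", "lambda_0_loglik", "lambda_0_aic",
    "lambda_1_slope", "lambda_1_se", "lambda_1_loglik", "lambda_1_aic",
    "selected_model", "slope", "se", "lambda", "aic",
    "shapiro_w", "shapiro_p",
    "pass_se", "pass_slope", "pass_normality", "significant", "fit_failed",
]


def run_screen(matrix: pd.DataFrame, trait: pd.Series, phylogeny: Phylogeny,
               config: ScreenConfig | None = None,
               outgroup: str | None = None) -> tuple[pd.DataFrame, dict]:
    """The full screen: filter, fit three models per orthogroup, flag passes.

    The screen is deterministic — it involves no random draws.  Returns a
    per-orthogroup result table sorted by orthogroup id and a summary dict
    (counts analyzed / with λ > 0 / passing, plus data-scale diagnostics).
    """
    config = config or ScreenConfig()
    matrix, tree = align_matrix_to_tree(matrix, phylogeny, outgroup=outgroup)
    missing = [g for g in matrix.columns if g not in trait.index]
    if missing:
        raise DataValidationError(f"trait missing for genomes: {missing[:5]}")
    y = trait.loc[list(matrix.columns)].to_numpy(float)
    _, V = phylo_covariance(tree)
    analyzed, filter_report = filter_orthogroups(matrix, config)
    records = {}
    for og, row in analyzed.iterrows():
        x = row.to_numpy(float)
        rec = fit_association_models(y, x, V, reml=config.reml)
        rec = apply_robustness_filters(rec, config)
        rec["variance"] = float(np.var(x))
        rec["prevalence"] = int((x >= 1).sum())
        records[og] = rec
    table = pd.DataFrame.from_dict(records, orient="index").sort_index()
    table.index.name = "orthogroup"
    table = table.reindex(columns=[c for c in RESULT_COLUMNS if c in table.columns])
    lam = table.get("lambda", pd.Series(dtype=float))
    summary = {
        **filter_report,
        "n_analyzed": int(table.shape[0]),
        "n_fit_failed": int(table.get("fit_failed", pd.Series(dtype=bool)).sum()),
        "n_lambda_positive": int((lam.fillna(0.0) > 1e-6).sum()),
        "n_significant": int(table["significant"].sum()),
        "trait_sd": float(np.std(y)),
        "mean_predictor_sd": float(np.sqrt(analyzed.var(axis=1, ddof=0)).mean()),
    }
    logger.info("screen: analyzed %(n_analyzed)d orthogroups, "
                "%(n_lambda_positive)d with lambda>0, "
                "%(n_significant)d significant", summary)
    return table, summary
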