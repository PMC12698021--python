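"""Drought-enrichment scoring and plant-benefit phenotype effects.

The drought-enrichment (DE) score of an isolate is

    DE = log2( mean drought abundance / mean water abundance )

computed on the abundance scale from qPCR replicates (arithmetic means, four
replicates per condition in the original design; any n >= 2 is accepted).
Positive DE means the isolate is enriched in roots under drought, negative
means depleted.  Per-isolate drought-vs-water differences are tested with a
two-sided Welch t-test and Benjamini–Hochberg adjusted across isolates.

Plant-benefit effects are mean differences of dry shoot biomass (per
condition) and of percent shoot water content (drought only) against
mock-inoculated control plants, with the same Welch + BH machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import CONDITIONS, DataValidationError

logger = logging.getLogger(__name__)


@dataclass
class StandardCurve:
    """log-linear qPCR standard curve Cq = intercept + slope * log10(quantity)."""

    slope: float
    intercept: float
    r_squared: float


def fit_standard_curve(points: list[tuple[float, float]]) -> StandardCurve:
    """OLS fit of Cq on log10 quantity from (log10 quantity, Cq) standards."""
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise DataValidationError("standard curve needs >= 2 distinct quantities")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise DataValidationError("standard curve slope is zero")
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue) ** 2)


def interpolate_abundance(curve: StandardCurve, cq: float | np.ndarray) -> np.ndarray:
    """Invert the standard curve: quantity = 10^((Cq − intercept) / slope)."""
    return np.power(10.0, (np.asarray(cq, dtype=float) - curve.intercept) / curve.slope)


def bh_adjust(p_values: np.ndarray | pd.Series) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values; NaN p-values stay NaN."""
    p = np.asarray(p_values, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def _welch(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test; zero variance in both groups -> (nan, nan)."""
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, 1.0
        return np.nan, np.nan
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def _check_replicates(table: pd.DataFrame) -> None:
    counts = table.groupby(["isolate", "condition"])["abundance"].size()
    for isolate in table["isolate"].unique():
        for cond in CONDITIONS:
            if counts.get((isolate, cond), 0) < 2:
                raise DataValidationError(
                    f"isolate {isolate!r} needs >= 2 {cond} replicates"
                )


def compute_de_scores(table: pd.DataFrame, fdr: float = 0.05,
                      pseudocount: bool = False) -> pd.DataFrame:
    """DE scores with per-isolate Welch tests and BH adjustment.

    Parameters
    ----------
    table
        Long qPCR table with columns isolate, condition, replicate, abundance.
    fdr
        FDR level for the ``significant`` flag.
    pseudocount
        If True, add half the smallest positive abundance to every value
        (rescues zero means); by default a zero mean is a hard error.

    Returns a DataFrame indexed by isolate with columns mean_drought,
    mean_water, de, t, p, q, significant.
    """
    table = table.copy()
    _check_replicates(table)
    if pseudocount:
        eps = 0.5 * float(table.loc[table["abundance"] > 0, "abundance"].min())
        logger.info("applying pseudocount %.6g", eps)
        table["abundance"] = table["abundance"] + eps
    rows = {}
    for isolate, grp in table.groupby("isolate", sort=True):
        d = grp.loc[grp["condition"] == "drought", "abundance"].to_numpy(float)
        w = grp.loc[grp["condition"] == "water", "abundance"].to_numpy(float)
        dbar, wbar = float(np.mean(d)), float(np.mean(w))
        if dbar <= 0 or wbar <= 0:
            raise DataValidationError(
                f"isolate {isolate!r} has non-positive mean abundance; "
                "enable pseudocount to proceed"
            )
        t, p = _welch(d, w)
        rows[isolate] = {"mean_drought": dbar, "mean_water": wbar,
                         "de": float(np.log2(dbar / wbar)), "t": t, "p": p}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "isolate"
    out["q"] = bh_adjust(out["p"])
    out["significant"] = out["q"] < fdr
    return out


def test_de_significance(table: pd.DataFrame) -> pd.DataFrame:
    """Per-isolate Welch t and p for drought vs water replicate abundances."""
    return compute_de_scores(table)[["t", "p", "q", "significant"]]


def water_content_percent(fresh: np.ndarray, dry: np.ndarray) -> np.ndarray:
    """Percent shoot water content: (fresh − dry) / fresh × 100."""
    fresh = np.asarray(fresh, dtype=float)
    dry = np.asarray(dry, dtype=float)
    return (fresh - dry) / fresh * 100.0


def compute_phenotype_deltas(pheno: pd.DataFrame, fdr: float = 0.05) -> pd.DataFrame:
    """Mean treatment effects vs mock for dry biomass and drought water content.

    For each isolate: Δ biomass = mean dry mass (treated) − mean dry mass
    (mock), per condition; Δ water content (drought only) likewise on the
    percent scale.  Welch t-tests vs mock, BH-adjusted within each trait
    family.  Returns tidy rows (isolate, condition, trait, delta, t, p, q,
    significant).
    """
    pheno = pheno.copy()
    pheno["water_content"] = water_content_percent(pheno["fresh_mass"],
                                                   pheno["dry_mass"])
    rows = []
    for cond in CONDITIONS:
        sub = pheno[pheno["condition"] == cond]
        mock = sub[sub["isolate"] == "mock"]
        if mock.shape[0] < 2:
            raise DataValidationError(f"missing mock group for condition {cond!r}")
        traits = ["dry_mass"] + (["water_content"] if cond == "drought" else [])
        for trait in traits:
            m = mock[trait].to_numpy(float)
            for isolate, grp in sub[sub["isolate"] != "mock"].groupby("isolate"):
                v = grp[trait].to_numpy(float)
                if v.size < 2:
                    raise DataValidationError(
                        f"isolate {isolate!r} needs >= 2 replicates under {cond!r}"
                    )
                t, p = _welch(v, m)
                rows.append({"isolate": isolate, "condition": cond,
                             "trait": trait,
                             "delta": float(np.mean(v) - np.mean(m)),
                             "t": t, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    for (cond, trait), idx in out.groupby(["condition", "trait"]).groups.items():
        out.loc[idx, "q"] = bh_adjust(out.loc[idx, "p"])
    out["significant"] = out["q"] < fdr
    return out.sort_values(["trait", "condition", "isolate"]).reset_index(drop=True)


def correlate_de_phenotype(de: pd.Series, delta: pd.Series) -> tuple[float, float]:
    """Spearman correlation (average ranks for ties) between two trait vectors.

    Vectors are aligned on their index; missing entries are dropped with a
    warning.  Needs >= 4 complete pairs and non-constant inputs.
    """
    joined = pd.concat([de, delta], axis=1, join="inner").dropna()
    dropped = max(len(de), len(delta)) - joined.shape[0]
    if dropped:
        logger.warning("dropped %d incomplete pairs from correlation", dropped)
    if joined.shape[0] < 4:
        raise DataValidationError("need >= 4 complete pairs for correlation")
    x, y = joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataValidationError("constant vector: Spearman rho undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
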