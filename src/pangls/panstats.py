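"""Descriptive pangenome statistics: ANI levels, sharing, fluidity, rarefaction.

Taxonomic levels follow the ANI convention genus < 95%, species 95–99%,
strain > 99% (boundary values 95 and 99 both classify as species).  Genome
fluidity is the mean over unordered genome pairs of the orthogroups unique
to either genome divided by the total orthogroups of the pair — a 0–1
gene-content dissimilarity.  Pan/core rarefaction permutes genome order and
tracks the cumulative union/intersection of orthogroup repertoires; the mean
pan curve is fit to Heaps' power law κ·N^γ (γ < 1 flags an open pangenome)
and the mean core curve to an exponential decay A·exp(−N/τ) + Ω.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import DataValidationError


class FitError(RuntimeError):
    """A nonlinear curve fit failed to converge."""


def classify_ani(ani: float) -> str:
    """Taxonomic level of one ANI value: genus <95, species 95–99, strain >99."""
    if not 0.0 < ani <= 100.0:
        raise DataValidationError(f"ANI {ani} outside (0, 100]")
    if ani < 95.0:
        return "genus"
    if ani <= 99.0:
        return "species"
    return "strain"


def classify_ani_pairs(ani: pd.DataFrame) -> pd.DataFrame:
    """Long table (genome_a, genome_b, ani, level) for all unordered pairs."""
    rows = [
        {"genome_a": a, "genome_b": b, "ani": float(ani.loc[a, b]),
         "level": classify_ani(float(ani.loc[a, b]))}
        for a, b in combinations(ani.index, 2)
    ]
    return pd.DataFrame(rows)


def pair_sharing_counts(matrix: pd.DataFrame, genome_a: str,
                        genome_b: str) -> tuple[int, int]:
    """(shared, unshared) orthogroup counts for one genome pair.

    Presence is count >= 1; unshared counts orthogroups present in exactly
    one of the two genomes.
    """
    for g in (genome_a, genome_b):
        if g not in matrix.columns:
            raise DataValidationError(f"unknown genome {g!r}")
    a = matrix[genome_a].to_numpy() >= 1
    b = matrix[genome_b].to_numpy() >= 1
    return int((a & b).sum()), int((a ^ b).sum())


def pairwise_sharing(matrix: pd.DataFrame,
                     ani: pd.DataFrame | None = None) -> pd.DataFrame:
    """Shared/unshared counts for all pairs, with ANI level when available."""
    P = (matrix.to_numpy() >= 1)
    genomes = list(matrix.columns)
    S = P.T.astype(np.int64) @ P.astype(np.int64)   # shared counts
    m = P.sum(axis=0)                               # per-genome repertoire size
    rows = []
    for i, j in combinations(range(len(genomes)), 2):
        shared = int(S[i, j])
        row = {"genome_a": genomes[i], "genome_b": genomes[j],
               "shared": shared,
               "unshared": int(m[i] + m[j] - 2 * shared)}
        if ani is not None:
            val = float(ani.loc[genomes[i], genomes[j]])
            row["ani"] = val
            row["level"] = classify_ani(val)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class FluidityEstimate:
    fluidity: float
    pair_ratios: pd.DataFrame   # genome_a, genome_b, ratio
    group: str | None = None


def genome_fluidity(matrix: pd.DataFrame,
                    subset: list[str] | None = None,
                    group: str | None = None) -> FluidityEstimate:
    """Genome fluidity φ = mean over pairs of (U_k + U_l) / (M_k + M_l).

    U is the count of orthogroups unique to one genome within the pair and M
    its total repertoire.  φ = 0 for identical repertoires, 1 for disjoint.
    """
    sub = matrix[subset] if subset is not None else matrix
    if sub.shape[1] < 2:
        raise DataValidationError("fluidity needs >= 2 genomes")
    P = (sub.to_numpy() >= 1)
    m = P.sum(axis=0)
    if (m == 0).any():
        empty = [g for g, size in zip(sub.columns, m) if size == 0]
        raise DataValidationError(f"genomes with zero orthogroups: {empty}")
    S = P.T.astype(np.int64) @ P.astype(np.int64)
    genomes = list(sub.columns)
    rows = []
    for i, j in combinations(range(len(genomes)), 2):
        ratio = (m[i] + m[j] - 2 * S[i, j]) / (m[i] + m[j])
        rows.append({"genome_a": genomes[i], "genome_b": genomes[j],
                     "ratio": float(ratio)})
    pairs = pd.DataFrame(rows)
    return FluidityEstimate(fluidity=float(pairs["ratio"].mean()),
                            pair_ratios=pairs, group=group)


def fluidity_by_level(matrix: pd.DataFrame, ani: pd.DataFrame) -> pd.DataFrame:
    """Per-pair fluidity ratios annotated with their ANI taxonomic level."""
    est = genome_fluidity(matrix)
    pairs = est.pair_ratios.copy()
    pairs["ani"] = [float(ani.loc[a, b])
                    for a, b in zip(pairs["genome_a"], pairs["genome_b"])]
    pairs["level"] = pairs["ani"].map(classify_ani)
    return pairs


@dataclass
class RarefactionCurves:
    curves: pd.DataFrame        # N, pan_mean, pan_sd, core_mean, core_sd
    n_permutations: int
    heaps: dict | None = None   # kappa, gamma, sse
    core_decay: dict | None = None  # A, tau, omega, sse


def rarefy_pangenome(matrix: pd.DataFrame, n_perm: int = 100,
                     seed: int = 0,
                     core_fraction: float = 1.0) -> RarefactionCurves:
    """Pan/core rarefaction over random genome orderings.

    For each permutation and each N, pan size is the union of present
    orthogroups among the first N genomes and core size the set present in
    at least ``core_fraction`` of them (1.0 = strict core).
    """
    if n_perm < 10:
        raise ValueError("need n_perm >= 10")
    P = (matrix.to_numpy() >= 1)
    n_genomes = P.shape[1]
    rng = np.random.default_rng(seed)
    pan = np.empty((n_perm, n_genomes), dtype=np.int64)
    core = np.empty((n_perm, n_genomes), dtype=np.int64)
    for p in range(n_perm):
        order = rng.permutation(n_genomes)
        cum = np.cumsum(P[:, order], axis=1)
        N = np.arange(1, n_genomes + 1)
        pan[p] = (cum >= 1).sum(axis=0)
        core[p] = (cum >= np.ceil(core_fraction * N)).sum(axis=0)
    curves = pd.DataFrame({
        "N": np.arange(1, n_genomes + 1),
        "pan_mean": pan.mean(axis=0), "pan_sd": pan.std(axis=0, ddof=1),
        "core_mean": core.mean(axis=0), "core_sd": core.std(axis=0, ddof=1),
    })
    return RarefactionCurves(curves=curves, n_permutations=n_perm)


def fit_heaps_law(N: np.ndarray, pan: np.ndarray) -> dict:
    """Fit pan(N) = κ·N^γ by nonlinear least squares.

    Also returns the log-log linear fit as a diagnostic.  γ < 1 indicates an
    open pangenome.
    """
    N = np.asarray(N, dtype=float)
    pan = np.asarray(pan, dtype=float)
    if N.size < 3 or np.any(pan <= 0):
        raise DataValidationError("need >= 3 positive curve points")
    loglog = np.polyfit(np.log(N), np.log(pan), 1)
    p0 = (float(np.exp(loglog[1])), float(loglog[0]))
    try:
        popt, _ = curve_fit(lambda n, k, g: k * n ** g, N, pan, p0=p0,
                            maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"Heaps fit failed from start {p0}") from exc
    kappa, gamma = float(popt[0]), float(popt[1])
    sse = float(np.sum((pan - kappa * N ** gamma) ** 2))
    return {"kappa": kappa, "gamma": gamma, "sse": sse,
            "loglog_gamma": float(loglog[0]),
            "loglog_kappa": float(np.exp(loglog[1]))}


def fit_core_decay(N: np.ndarray, core: np.ndarray) -> dict:
    """Fit core(N) = A·exp(−N/τ) + Ω by nonlinear least squares."""
    N = np.asarray(N, dtype=float)
    core = np.asarray(core, dtype=float)
    if N.size < 3 or np.any(core <= 0):
        raise DataValidationError("need >= 3 positive curve points")
    omega0 = float(core[-1])
    a0 = max(float(core[0] - core[-1]), 1.0)
    tau0 = max(float(N[-1]) / 3.0, 1.0)
    p0 = (a0, tau0, omega0)
    try:
        popt, _ = curve_fit(lambda n, a, tau, om: a * np.exp(-n / tau) + om,
                            N, core, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise FitError(f"core decay fit failed from start {p0}") from exc
    A, tau, omega = map(float, popt)
    sse = float(np.sum((core - (A * np.exp(-N / tau) + omega)) ** 2))
    return {"A": A, "tau": tau, "omega": omega, "sse": sse}


def pangenome_summary(matrix: pd.DataFrame) -> dict:
    """Total pan and strict-core orthogroup counts of the full matrix."""
    P = (matrix.to_numpy() >= 1)
    return {"pan_size": int((P.any(axis=1)).sum()),
            "core_size": int((P.all(axis=1)).sum()),
            "n_genomes": int(P.shape[1])}
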