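"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates the study design end to end: an ultrametric pure-birth
(Yule) isolate phylogeny with an optional long-branch outgroup; a latent
drought-enrichment trait with tunable phylogenetic signal λ and variance σ²;
an orthogroup-by-genome copy-number matrix in which a small planted subset of
orthogroups is genuinely associated with the trait; four-replicate qPCR
abundances per condition with multiplicative (log-normal) noise; COG
annotations with one category at elevated odds among the planted set; plant
phenotype tables; and a tree-derived synthetic ANI matrix.

Trait/copy-number coupling.  The latent trait u is drawn first from
N(0, σ²·V(λ)); planted orthogroup counts are Poisson with mean
μ_p + κ·(u/s), where s = sd(u) and κ solves

    κ²·β − κ·s + β·μ_p = 0        (smaller root)

so that the population regression slope of u on a planted column equals the
configured effect β.  Non-planted columns are negative-binomial draws
independent of the trait.  This generative direction keeps every planted
orthogroup individually recoverable (slope ≈ β with small SE) while leaving
nulls exactly null — see docs/methods.md for why the coupling is generative
rather than an additive sum of planted effects.
"""

from __future__ import annotations

import hashlib
import math
import random
import string
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from . import io as pio
from .io import Phylogeny
from .phylo import lambda_transform, phylo_covariance

#: letters used by the annotation generator (the commonly populated COG classes)
ANNOTATION_LETTERS = list("CDEFGHIJKLMNOPQRSTUV")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from one master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic generator.

    Defaults mirror the emulated study: 48 isolates, 4 qPCR replicates per
    condition, a trait variance of 1.16 (the observed DE variance), a
    minority of planted DE-associated orthogroups, and one COG category
    (I, lipid transport and metabolism) enriched among them.
    """

    n_tips: int = 48
    birth_rate: float = 1.0
    lambda_true: float = 0.0        # the study found essentially no signal in DE
    sigma2: float = 1.16            # trait variance on the DE (log2) scale
    n_orthogroups: int = 500
    n_planted: int = 20
    beta_true: float = 0.5          # target regression slope trait ~ copy number
    dispersion: float = 2.0         # negative-binomial shape of null counts
    baseline_mean: float = 3.0      # mean copy number of present null orthogroups
    planted_mean: float = 3.0       # baseline Poisson mean of planted orthogroups
    core_fraction: float = 0.4      # null orthogroups present in every genome
    occupancy_beta: tuple[float, float] = (0.3, 0.7)  # accessory frequency spectrum
    qpcr_tau: float = 0.3           # log-scale sd of replicate noise
    water_mean: float = 1e4         # abundance scale under irrigation
    n_replicates: int = 4
    enriched_letter: str = "I"
    enrichment_odds: float = 5.0
    annotated_fraction: float = 0.9
    outgroup_label: str | None = "outgroup"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_planted > self.n_orthogroups:
            raise ValueError("n_planted cannot exceed n_orthogroups")
        if not 0.0 <= self.lambda_true <= 1.0:
            raise ValueError("lambda_true must be in [0, 1]")
        for name in ("birth_rate", "dispersion", "baseline_mean", "planted_mean"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.sigma2 < 0 or self.qpcr_tau < 0:
            raise ValueError("variances must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("need >= 2 replicates per condition")
        if not 0.0 <= self.core_fraction <= 1.0:
            raise ValueError("core_fraction must be in [0, 1]")
        if self.enriched_letter not in string.ascii_uppercase:
            raise ValueError("enriched_letter must be an uppercase COG letter")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------


def simulate_yule_tree(n_tips: int, birth_rate: float = 1.0,
                       seed: int = 0,
                       outgroup_label: str | None = None) -> Phylogeny:
    """Ultrametric pure-birth tree with tips iso001..iso{n}.

    The simulator stops at the n-th birth, which would leave the last two
    sister tips with zero-length branches; all terminal branches are
    therefore extended by one Exponential(n·birth_rate) waiting time, which
    preserves ultrametricity.  If ``outgroup_label`` is given, an outgroup
    tip is attached below a new root with a branch 1.5× the ingroup depth.
    """
    if n_tips < 3:
        raise ValueError("need n_tips >= 3")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(birth_rate=birth_rate, death_rate=0.0,
                                    num_extant_tips=n_tips, rng=rng)
    extra = rng.expovariate(n_tips * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length += extra
    tree.seed_node.edge.length = None
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"iso{i:03d}"
    newick = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if outgroup_label is not None:
        depth = next(tree.leaf_node_iter()).distance_from_root()
        inner = newick.rstrip(";")
        newick = (f"({inner}:{0.5 * depth:.10f},"
                  f"{outgroup_label}:{1.5 * depth:.10f});")
    return pio.read_newick(newick)


def jitter_terminal_branches(phylogeny: Phylogeny, sd: float,
                             seed: int = 0) -> Phylogeny:
    """Non-ultrametric variant: multiply each terminal branch by exp(N(0, sd))."""
    rng = np.random.default_rng(seed)
    tree = phylogeny.tree.clone(depth=1)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length *= float(np.exp(rng.normal(0.0, sd)))
    return Phylogeny(tree=tree)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_bm_trait(phylogeny: Phylogeny, lambda_true: float, sigma2: float,
                      seed: int = 0, name: str = "trait") -> pd.Series:
    """Draw one trait from N(0, σ²·V(λ)) over the tree's tips."""
    labels, V = phylo_covariance(phylogeny)
    if sigma2 == 0.0:
        return pd.Series(np.zeros(len(labels)), index=labels, name=name)
    Vl = sigma2 * lambda_transform(V, lambda_true)
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(Vl)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "V(lambda) is not positive definite; the tree is degenerate"
        ) from exc
    values = L @ rng.standard_normal(len(labels))
    return pd.Series(values, index=labels, name=name)


def _planted_coupling(s: float, beta: float, nu: float) -> float:
    """Smaller root of κ²β − κs + βν = 0: coupling giving slope β.

    Falls back to the vertex κ = s/(2β) (maximum attainable slope) when the
    target β is not reachable for this trait scale.
    """
    if beta == 0.0:
        return 0.0
    disc = s * s - 4.0 * beta * beta * nu
    if disc < 0:
        return s / (2.0 * beta)
    return (s - math.sqrt(disc)) / (2.0 * beta)


def simulate_copy_number_matrix(
    phylogeny: Phylogeny, config: SimConfig, seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, list[str]]:
    """Copy-number matrix, latent trait, and ground-truth planted set.

    Uses only the ingroup tips (the configured outgroup is excluded from the
    genome set).  Returns (orthogroup × genome int DataFrame, trait Series
    over genomes, sorted planted orthogroup ids).
    """
    tree = phylogeny
    if config.outgroup_label and config.outgroup_label in phylogeny.tip_labels:
        tree = phylogeny.drop_tips([config.outgroup_label])
    genomes = tree.tip_labels
    n = len(genomes)
    rng = np.random.default_rng(seed)
    trait = simulate_bm_trait(tree, config.lambda_true, config.sigma2,
                              seed=derive_seed(seed, "trait"), name="de")
    u = trait.to_numpy()
    s = float(np.std(u))
    if s == 0.0:
        s = 1.0

    og_ids = [f"OG{i:07d}" for i in range(1, config.n_orthogroups + 1)]
    planted = sorted(rng.choice(og_ids, size=config.n_planted, replace=False))
    planted_set = set(planted)

    theta = config.dispersion
    kappa = _planted_coupling(s, config.beta_true, config.planted_mean)
    counts = np.empty((config.n_orthogroups, n), dtype=np.int64)
    for i, og in enumerate(og_ids):
        if og in planted_set:
            mean = np.clip(config.planted_mean + kappa * (u / s), 0.05, None)
            counts[i] = rng.poisson(mean)
        else:
            # Null pangenome structure: a core fraction present everywhere,
            # accessory orthogroups with a U-shaped (Beta) occupancy spectrum.
            mu = rng.lognormal(math.log(config.baseline_mean), 0.4)
            p = theta / (theta + max(mu - 1.0, 0.1))
            per_copy = 1 + rng.negative_binomial(theta, p, size=n)
            if rng.random() < config.core_fraction:
                present = np.ones(n, dtype=bool)
            else:
                occ = rng.beta(*config.occupancy_beta)
                present = rng.random(n) < occ
            counts[i] = np.where(present, per_copy, 0)
    matrix = pd.DataFrame(counts, index=pd.Index(og_ids, name="orthogroup"),
                          columns=genomes)
    return matrix, trait, list(planted)


# ---------------------------------------------------------------------------
# qPCR, annotations, phenotypes, ANI
# ---------------------------------------------------------------------------


def simulate_qpcr_experiment(true_de: pd.Series, water_mean: float = 1e4,
                             tau: float = 0.3, n_reps: int = 4,
                             seed: int = 0) -> pd.DataFrame:
    """Replicate qPCR abundances whose noiseless DE equals ``true_de``.

    Water replicates are LogNormal(ln water_mean, τ) and drought replicates
    LogNormal(ln(water_mean · 2^DE), τ); at τ = 0 the arithmetic replicate
    means invert exactly to the true DE.
    """
    if tau < 0 or n_reps < 2:
        raise ValueError("need tau >= 0 and n_reps >= 2")
    rng = np.random.default_rng(seed)
    rows = []
    for isolate, de in true_de.items():
        means = {"water": water_mean, "drought": water_mean * 2.0 ** de}
        for cond in ("drought", "water"):
            draws = means[cond] * np.exp(rng.normal(0.0, tau, size=n_reps)) \
                if tau > 0 else np.full(n_reps, means[cond])
            for r, val in enumerate(draws, start=1):
                rows.append({"isolate": isolate, "condition": cond,
                             "replicate": r, "abundance": float(val)})
    return pd.DataFrame(rows)


def simulate_annotations(orthogroup_ids: list[str], planted_ids: list[str],
                         enriched_letter: str = "I", odds: float = 5.0,
                         background_rate: float = 0.1,
                         annotated_fraction: float = 0.9,
                         seed: int = 0) -> dict[str, frozenset[str]]:
    """COG annotations with one category at elevated odds among planted ids.

    Each annotated orthogroup carries ``enriched_letter`` with probability
    ``background_rate`` (a moderately common COG class); for planted
    orthogroups the carrier odds are multiplied by ``odds``, so the
    planted-vs-background odds ratio of carrying the category equals
    ``odds`` exactly and odds = 1 reproduces the null.  Every annotated
    orthogroup additionally gets one letter drawn uniformly from the other
    categories (plus a second with probability 0.25).
    """
    if not 0.0 < background_rate < 1.0:
        raise ValueError("background_rate must be in (0, 1)")
    rng = np.random.default_rng(seed)
    planted_set = set(planted_ids)
    others = [l for l in ANNOTATION_LETTERS if l != enriched_letter]
    odds0 = background_rate / (1.0 - background_rate)
    p_planted = odds * odds0 / (1.0 + odds * odds0)
    out: dict[str, frozenset[str]] = {}
    for og in orthogroup_ids:
        if rng.random() > annotated_fraction:
            continue
        carrier_p = p_planted if og in planted_set else background_rate
        cats = set()
        if rng.random() < carrier_p:
            cats.add(enriched_letter)
        cats.add(others[rng.integers(len(others))])
        if rng.random() < 0.25:
            cats.add(others[rng.integers(len(others))])
        out[og] = frozenset(cats)
    return out


def simulate_phenotypes(isolates: list[str],
                        biomass_effects: pd.DataFrame | None = None,
                        wc_effects: pd.Series | None = None,
                        n_reps: int = 4, noise_sd: float = 0.05,
                        seed: int = 0) -> pd.DataFrame:
    """Plant fresh/dry shoot masses for mock and inoculated plants.

    Mock dry mass averages 0.60 g under water and 0.40 g under drought, with
    water contents of 85% and 70%.  ``biomass_effects`` (isolate × condition,
    grams) and ``wc_effects`` (isolate, percent, drought only) shift the
    treated means; at ``noise_sd`` → 0 the realized deltas converge to those
    shifts.  Small random effects are drawn when none are supplied.
    """
    rng = np.random.default_rng(seed)
    base_dry = {"water": 0.60, "drought": 0.40}
    base_wc = {"water": 85.0, "drought": 70.0}
    if biomass_effects is None:
        biomass_effects = pd.DataFrame(
            rng.normal(0.0, 0.05, size=(len(isolates), 2)),
            index=isolates, columns=["water", "drought"])
    if wc_effects is None:
        wc_effects = pd.Series(rng.normal(0.0, 2.0, size=len(isolates)),
                               index=isolates)
    rows = []
    for cond in ("water", "drought"):
        for isolate in ["mock"] + list(isolates):
            dry_mean = base_dry[cond]
            wc_mean = base_wc[cond]
            if isolate != "mock":
                dry_mean += float(biomass_effects.loc[isolate, cond])
                if cond == "drought":
                    wc_mean += float(wc_effects.loc[isolate])
            for r in range(1, n_reps + 1):
                dry = max(0.01, dry_mean + rng.normal(0.0, noise_sd))
                wc = float(np.clip(wc_mean + rng.normal(0.0, noise_sd * 20), 1.0, 99.0))
                fresh = dry / (1.0 - wc / 100.0)
                rows.append({"isolate": isolate, "condition": cond,
                             "replicate": r, "fresh_mass": fresh,
                             "dry_mass": dry})
    return pd.DataFrame(rows)


def simulate_ani(phylogeny: Phylogeny, span: float = 8.0,
                 noise_sd: float = 0.1, seed: int = 0,
                 outgroup_label: str | None = None) -> pd.DataFrame:
    """Synthetic ANI mapped linearly from patristic distance.

    The most distant ingroup pair sits ``span`` percentage points below 100,
    so a span of 8 yields a mix of strain (>99), species (95–99) and genus
    (<95) level pairs.  Purely a plumbing stand-in for real fastANI output.
    """
    tree = phylogeny
    if outgroup_label and outgroup_label in phylogeny.tip_labels:
        tree = phylogeny.drop_tips([outgroup_label])
    labels, V = phylo_covariance(tree)
    d = np.add.outer(np.diag(V), np.diag(V)) - 2.0 * V   # patristic distances
    dmax = float(d.max())
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=d.shape)
    noise = (noise + noise.T) / 2.0
    ani = 100.0 - span * d / dmax + noise
    ani = np.clip(ani, 75.0, 100.0)
    np.fill_diagonal(ani, 100.0)
    return pd.DataFrame(ani, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# Full simulated study
# ---------------------------------------------------------------------------


def simulate_study(config: SimConfig) -> dict:
    """Generate every artifact of one synthetic study from ``config.seed``."""
    seed = config.seed
    tree = simulate_yule_tree(config.n_tips, config.birth_rate,
                              seed=derive_seed(seed, "tree"),
                              outgroup_label=config.outgroup_label)
    matrix, trait, planted = simulate_copy_number_matrix(
        tree, config, seed=derive_seed(seed, "counts"))
    qpcr = simulate_qpcr_experiment(trait, water_mean=config.water_mean,
                                    tau=config.qpcr_tau,
                                    n_reps=config.n_replicates,
                                    seed=derive_seed(seed, "qpcr"))
    annotations = simulate_annotations(list(matrix.index), planted,
                                       enriched_letter=config.enriched_letter,
                                       odds=config.enrichment_odds,
                                       annotated_fraction=config.annotated_fraction,
                                       seed=derive_seed(seed, "annotations"))
    phenotypes = simulate_phenotypes(list(matrix.columns),
                                     seed=derive_seed(seed, "phenotypes"))
    ani = simulate_ani(tree, seed=derive_seed(seed, "ani"),
                       outgroup_label=config.outgroup_label)
    return {"tree": tree, "matrix": matrix, "trait": trait, "planted": planted,
            "qpcr": qpcr, "annotations": annotations, "phenotypes": phenotypes,
            "ani": ani, "config": config}


def write_study(study: dict, out_dir: str | Path) -> dict[str, Path]:
    """Write a simulated study to the pipeline's external file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in [
        ("tree", "tree.nwk"), ("gene_counts", "gene_counts.tsv"),
        ("annotations", "annotations.tsv"), ("qpcr", "qpcr.tsv"),
        ("phenotypes", "phenotypes.tsv"), ("ani", "ani.tsv"),
        ("truth", "truth.tsv")]}
    study["tree"].write_newick(paths["tree"])
    gc = study["matrix"].copy()
    gc["Total"] = gc.sum(axis=1)
    gc.to_csv(paths["gene_counts"], sep="\t")
    pio.write_annotation_table(study["annotations"], paths["annotations"],
                               all_ids=list(study["matrix"].index))
    study["qpcr"].to_csv(paths["qpcr"], sep="\t", index=False,
                         float_format="%.12g")
    study["phenotypes"].to_csv(paths["phenotypes"], sep="\t", index=False,
                               float_format="%.12g")
    study["ani"].to_csv(paths["ani"], sep="\t", float_format="%.12g")
    cfg = study["config"]
    truth = pd.DataFrame({"orthogroup": study["planted"],
                          "beta_true": cfg.beta_true,
                          "lambda_true": cfg.lambda_true})
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.12g")
    return paths
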