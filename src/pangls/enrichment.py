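"""Hypergeometric COG-category enrichment of a significant orthogroup set.

Each COG letter present in the annotated background is tested with an upper
hypergeometric tail: out of N annotated background orthogroups of which K
carry the letter, how surprising is drawing k carriers among the n annotated
significant orthogroups?  Multi-letter annotations (e.g. "IQ") count once
per letter; unannotated orthogroups are excluded from both n and N by
default.  BH adjustment runs across the tested letters only.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .traits import bh_adjust

logger = logging.getLogger(__name__)

#: COG functional category labels (2020 scheme)
COG_LABELS = {
    "A": "RNA processing and modification",
    "B": "Chromatin structure and dynamics",
    "C": "Energy production and conversion",
    "D": "Cell cycle control, cell division, chromosome partitioning",
    "E": "Amino acid transport and metabolism",
    "F": "Nucleotide transport and metabolism",
    "G": "Carbohydrate transport and metabolism",
    "H": "Coenzyme transport and metabolism",
    "I": "Lipid transport and metabolism",
    "J": "Translation, ribosomal structure and biogenesis",
    "K": "Transcription",
    "L": "Replication, recombination and repair",
    "M": "Cell wall/membrane/envelope biogenesis",
    "N": "Cell motility",
    "O": "Posttranslational modification, protein turnover, chaperones",
    "P": "Inorganic ion transport and metabolism",
    "Q": "Secondary metabolites biosynthesis, transport and catabolism",
    "R": "General function prediction only",
    "S": "Function unknown",
    "T": "Signal transduction mechanisms",
    "U": "Intracellular trafficking, secretion, and vesicular transport",
    "V": "Defense mechanisms",
    "W": "Extracellular structures",
    "X": "Mobilome: prophages, transposons",
    "Y": "Nuclear structure",
    "Z": "Cytoskeleton",
}


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N = population size, K = successes in population, n = draws, k =
    observed successes.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValueError(f"inconsistent hypergeometric margins "
                         f"k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cog_enrichment(significant: Iterable[str], background: Iterable[str],
                   annotations: Mapping[str, frozenset[str]],
                   expand_letters: bool = True,
                   annotated_background_only: bool = True) -> pd.DataFrame:
    """Per-letter enrichment of ``significant`` against ``background``.

    Parameters
    ----------
    expand_letters
        Count a multi-letter orthogroup once per letter (default); if False,
        only the first letter of the sorted set is used.
    annotated_background_only
        If True (default) the universe N counts only annotated orthogroups;
        if False all background orthogroups count, with unannotated ones as
        non-carriers of every letter.

    Returns rows (letter, label, k, n, K, N, p, q) sorted by p.
    """
    sig = set(significant)
    bg = set(background)
    if not sig <= bg:
        raise ValueError("significant set must be a subset of the background")

    def letters_of(og: str) -> frozenset[str]:
        cats = annotations.get(og, frozenset())
        if not expand_letters and cats:
            return frozenset([sorted(cats)[0]])
        return cats

    annotated_bg = {og for og in bg if letters_of(og)}
    annotated_sig = sig & annotated_bg
    N = len(annotated_bg) if annotated_background_only else len(bg)
    n = len(annotated_sig) if annotated_background_only else len(sig)
    if not annotated_sig:
        logger.warning("no annotated orthogroups in the significant set")
        return pd.DataFrame(columns=["letter", "label", "k", "n", "K", "N",
                                     "p", "q"])
    rows = []
    letters = sorted({l for og in annotated_bg for l in letters_of(og)})
    for letter in letters:
        K = sum(1 for og in annotated_bg if letter in letters_of(og))
        k = sum(1 for og in annotated_sig if letter in letters_of(og))
        rows.append({"letter": letter, "label": COG_LABELS.get(letter, ""),
                     "k": k, "n": n, "K": K, "N": N,
                     "p": hypergeometric_tail(k, K, n, N)})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"])
    return out.sort_values(["p", "letter"], kind="mergesort").reset_index(drop=True)
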