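"""Readers and writers for the pipeline's external formats.

Everything downstream works on a small set of in-memory containers:

* :class:`Phylogeny` — a rooted dendropy tree with mandatory branch lengths.
* Copy-number matrix — a ``pandas.DataFrame`` (orthogroups x genomes, int).
* Annotation map — ``dict[str, frozenset[str]]`` of COG category letters.
* ANI matrix — a symmetric ``pandas.DataFrame`` on the 0–100 scale.
* qPCR / phenotype tables — long-format ``pandas.DataFrame``.

All tabular formats are tab-separated with '.' decimals; lines starting with
'#' are comments.  Tip/genome label matching is exact string equality.
"""

from __future__ import annotations

import io as _io
import logging
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COG_ALPHABET = frozenset(string.ascii_uppercase)

QPCR_COLUMNS = ["isolate", "condition", "replicate", "abundance"]
PHENOTYPE_COLUMNS = ["isolate", "condition", "replicate", "fresh_mass", "dry_mass"]
CONDITIONS = ("drought", "water")


class DataValidationError(ValueError):
    """An input violated a structural invariant of its format."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


@dataclass
class Phylogeny:
    """Rooted phylogeny with branch lengths; thin wrapper around dendropy.

    Tip labels are unique; every non-seed edge has a non-negative length.
    Trees need not be ultrametric.
    """

    tree: dendropy.Tree
    tip_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        labels = [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise DataValidationError(f"duplicate tip labels: {dupes}")
        for node in self.tree.preorder_node_iter():
            if node is self.tree.seed_node:
                continue
            if node.edge.length is None:
                raise DataValidationError(
                    "missing branch length on an edge; lengths are required"
                )
            if node.edge.length < 0:
                raise DataValidationError(
                    f"negative branch length {node.edge.length}"
                )
        self.tip_labels = labels

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    def drop_tips(self, labels: Iterable[str]) -> "Phylogeny":
        """Return a copy with the given tips pruned (e.g., an outgroup)."""
        drop = set(labels)
        missing = drop - set(self.tip_labels)
        if missing:
            raise DataValidationError(f"cannot drop unknown tips: {sorted(missing)}")
        keep = [t for t in self.tree.taxon_namespace if t.label not in drop]
        pruned = self.tree.extract_tree_with_taxa(taxa=keep)
        return Phylogeny(tree=pruned)

    def write_newick(self, path: str | Path | None = None) -> str:
        text = self.tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip() + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def read_newick(source: str | Path) -> Phylogeny:
    """Parse a Newick string (or file path) into a :class:`Phylogeny`.

    Branch lengths are mandatory on every non-root edge; duplicate tip
    labels are an error.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and not source.lstrip().startswith("(")
    ):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted error classes
        raise DataValidationError(f"Newick parse failure: {exc}") from exc
    n_tips = sum(1 for _ in tree.leaf_node_iter())
    if n_tips < 2:
        raise DataValidationError("tree must have at least 2 tips")
    return Phylogeny(tree=tree)


def write_newick(phylogeny: Phylogeny, path: str | Path) -> None:
    phylogeny.write_newick(path)


# ---------------------------------------------------------------------------
# Gene count table (OrthoFinder Orthogroups.GeneCount.tsv dialect)
# ---------------------------------------------------------------------------


def read_gene_count_table(source: str | Path | _io.IOBase) -> pd.DataFrame:
    """Read an OrthoFinder-style gene-count TSV.

    First column ``Orthogroup``, one integer column per genome; an optional
    trailing ``Total`` column is dropped.  Returns an orthogroup-by-genome
    DataFrame of non-negative ints, row and column order preserved.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str)
    if df.shape[0] == 0:
        raise DataValidationError("no orthogroups in gene-count table")
    if df.shape[1] < 2:
        raise DataValidationError("gene-count table needs an id column and >=1 genome")
    id_col = df.columns[0]
    ids = df[id_col]
    if ids.duplicated().any():
        raise DataValidationError(
            f"duplicate orthogroup ids: {sorted(ids[ids.duplicated()].unique())}"
        )
    body = df.drop(columns=[id_col])
    if body.columns[-1] == "Total":
        body = body.drop(columns=["Total"])
    if body.shape[1] == 0:
        raise DataValidationError("gene-count table has no genome columns")
    try:
        counts = body.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise DataValidationError(f"non-integer cell in gene-count table: {exc}") from exc
    if (body.apply(pd.to_numeric) != counts).any().any():
        raise DataValidationError("non-integer cell in gene-count table")
    if (counts < 0).any().any():
        raise DataValidationError("negative count in gene-count table")
    counts.index = pd.Index(ids, name="orthogroup")
    return counts


# ---------------------------------------------------------------------------
# ANI
# ---------------------------------------------------------------------------


def _validate_ani_values(values: np.ndarray) -> None:
    if np.any(~np.isfinite(values)) or np.any(values <= 0) or np.any(values > 100):
        raise DataValidationError("ANI values must lie in (0, 100]")


def read_ani_matrix(source: str | Path | _io.IOBase) -> pd.DataFrame:
    """Read ANI as fastANI 5-column long output or a labeled square matrix.

    The two fastANI directions are symmetrized by their arithmetic mean; a
    single observed direction is used as-is.  Self-pairs are forced to 100.
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text(encoding="utf-8")
    else:
        text = source.read()
    lines = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    if not lines:
        raise DataValidationError("empty ANI input")
    first = lines[0].split("\t")
    is_long = len(first) in (3, 5) and _is_number(first[2] if len(first) > 2 else "")
    if is_long:
        return _read_ani_long(lines)
    return _read_ani_square(text)


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _read_ani_long(lines: list[str]) -> pd.DataFrame:
    sums: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], int] = {}
    labels: list[str] = []
    for line in lines:
        parts = line.split("\t")
        if len(parts) < 3:
            raise DataValidationError(f"malformed fastANI row: {line!r}")
        q, r, ani = parts[0], parts[1], float(parts[2])
        _validate_ani_values(np.array([ani]))
        for lab in (q, r):
            if lab not in labels:
                labels.append(lab)
        key = (q, r) if q <= r else (r, q)
        sums[key] = sums.get(key, 0.0) + ani
        counts[key] = counts.get(key, 0) + 1
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for (a, b), s in sums.items():
        mat.loc[a, b] = mat.loc[b, a] = s / counts[(a, b)]
    np.fill_diagonal(mat.values, 100.0)
    if mat.isna().any().any():
        missing = [
            (a, b)
            for a in labels
            for b in labels
            if a < b and np.isnan(mat.loc[a, b])
        ]
        raise DataValidationError(f"missing ANI for pairs: {missing[:5]}")
    _validate_ani_values(mat.values)
    return mat


def _read_ani_square(text: str) -> pd.DataFrame:
    df = pd.read_csv(_io.StringIO(text), sep="\t", comment="#", index_col=0)
    if list(df.index) != list(df.columns):
        raise DataValidationError(
            "square ANI matrix must have identical row and column labels"
        )
    values = df.values.astype(float)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 100.0)
    _validate_ani_values(values)
    return pd.DataFrame(values, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def read_annotation_table(source: str | Path | _io.IOBase) -> dict[str, frozenset[str]]:
    """Read (orthogroup_id, COG letters) rows into an annotation map.

    Multi-letter strings like ``"IQ"`` become ``{I, Q}``.  An empty category
    cell means *unannotated*: the orthogroup is omitted from the map rather
    than mapped to an empty set.
    """
    df = pd.read_csv(source, sep="\t", comment="#", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise DataValidationError("annotation table needs id and category columns")
    out: dict[str, frozenset[str]] = {}
    for og, cats in zip(df.iloc[:, 0], df.iloc[:, 1]):
        cats = cats.strip()
        if cats in ("", "-"):
            continue
        letters = frozenset(cats)
        bad = letters - COG_ALPHABET
        if bad:
            raise DataValidationError(
                f"invalid COG letters {sorted(bad)} for orthogroup {og!r}"
            )
        out[og] = letters
    return out


def write_annotation_table(annotations: Mapping[str, frozenset[str]],
                           path: str | Path,
                           all_ids: Iterable[str] | None = None) -> None:
    """Write an annotation map as TSV; unannotated ids get an empty cell."""
    ids = sorted(all_ids) if all_ids is not None else sorted(annotations)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("orthogroup\tCOG_category\n")
        for og in ids:
            letters = "".join(sorted(annotations.get(og, frozenset())))
            fh.write(f"{og}\t{letters}\n")


# ---------------------------------------------------------------------------
# qPCR and phenotype tables
# ---------------------------------------------------------------------------


def read_qpcr_table(source: str | Path | _io.IOBase) -> pd.DataFrame:
    """Read the long-format qPCR table (isolate, condition, replicate, abundance)."""
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"qPCR table missing columns: {missing}")
    df = df[QPCR_COLUMNS].copy()
    bad = ~df["condition"].isin(CONDITIONS)
    if bad.any():
        raise DataValidationError(
            f"unknown condition labels: {sorted(df.loc[bad, 'condition'].unique())}"
        )
    if df.duplicated(["isolate", "condition", "replicate"]).any():
        raise DataValidationError("duplicate (isolate, condition, replicate) rows")
    if (df["abundance"] <= 0).any():
        raise DataValidationError("abundances must be > 0")
    return df


def read_phenotype_table(source: str | Path | _io.IOBase) -> pd.DataFrame:
    """Read the phenotype table (isolate, condition, replicate, fresh_mass, dry_mass).

    The ``isolate`` column uses the literal label ``"mock"`` for uninoculated
    control plants.
    """
    df = pd.read_csv(source, sep="\t", comment="#")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"phenotype table missing columns: {missing}")
    df = df[PHENOTYPE_COLUMNS].copy()
    if (df["dry_mass"] <= 0).any():
        raise DataValidationError("dry mass must be > 0")
    if (df["dry_mass"] > df["fresh_mass"]).any():
        raise DataValidationError("dry mass cannot exceed fresh mass")
    return df


# ---------------------------------------------------------------------------
# Results writer and label alignment
# ---------------------------------------------------------------------------


def write_results_table(df: pd.DataFrame, path: str | Path,
                        sort_by: str | None = None) -> None:
    """Write a results DataFrame as UTF-8 TSV with deterministic row order.

    Floats are rendered with 12 significant digits so a write/read round
    trip preserves values to that precision.
    """
    out = df.copy()
    if sort_by is None and out.index.name is not None:
        out = out.sort_index()
    elif sort_by is not None:
        out = out.sort_values(sort_by, kind="mergesort")
    out.to_csv(path, sep="\t", float_format="%.12g",
               index=out.index.name is not None, encoding="utf-8")


def read_results_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def align_matrix_to_tree(matrix: pd.DataFrame, phylogeny: Phylogeny,
                         outgroup: str | None = None) -> tuple[pd.DataFrame, Phylogeny]:
    """Match gene-count genome columns 1:1 to tree tips and order them alike.

    If ``outgroup`` is given it is pruned from the tree first.  Any mismatch
    after that is an error: label matching is exact, no fuzzy rescue.
    """
    tree = phylogeny
    if outgroup is not None and outgroup in phylogeny.tip_labels:
        tree = phylogeny.drop_tips([outgroup])
        logger.info("pruned outgroup tip %r", outgroup)
    tips = set(tree.tip_labels)
    genomes = set(matrix.columns)
    if tips != genomes:
        only_tree = sorted(tips - genomes)
        only_matrix = sorted(genomes - tips)
        raise DataValidationError(
            f"genome/tip label mismatch; only in tree: {only_tree[:5]}, "
            f"only in matrix: {only_matrix[:5]}"
        )
    return matrix[tree.tip_labels], tree
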