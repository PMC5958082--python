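"""Readers, writers and validated containers for every external format the
pipeline touches.

Expression matrices are tab-delimited, features in rows (first column holds
the feature ID), samples in columns, values on the log2 scale (RMA-style
summaries).  Gene sets use the Broad GMT dialect; the otherwise free-text
description field optionally encodes a regulator family as ``family=<id>``.
Protein-protein interactions and sample designs are two-column TSV.

All readers validate and reject malformed input rather than coercing it;
every writer round-trips losslessly with its reader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The four phenotypes contrasted by the pipeline: healthy control, active
#: disease untreated, active disease on therapy, inactive disease on therapy.
PHENOTYPES = ("HC", "ADU", "ADT", "ID")

#: Patient phenotypes, i.e. every contrast is <phenotype> vs HC.
CASE_PHENOTYPES = ("ADU", "ADT", "ID")

FEATURE_KINDS = ("mRNA", "miRNA")
REGULATOR_KINDS = ("miRNA", "TF")


class ParseError(ValueError):
    """Malformed input file (message names the offending line/field)."""


@dataclass
class ExpressionMatrix:
    """A dense log2 feature-by-sample expression matrix.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with sample IDs as columns; all
        entries finite floats on the log2 scale.
    feature_kind
        ``"mRNA"`` or ``"miRNA"``.
    """

    values: pd.DataFrame
    feature_kind: str

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"feature_kind must be one of {FEATURE_KINDS}, "
                             f"got {self.feature_kind!r}")
        self.values = self.values.astype(float)
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dupes = sorted(idx[idx.duplicated()].unique())
            raise ValueError(f"duplicate feature IDs: {dupes[:5]}"
                             " (collapse features first)")
        if cols.has_duplicates:
            raise ValueError("duplicate sample IDs: "
                             f"{sorted(cols[cols.duplicated()].unique())}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                "non-finite value at feature "
                f"{idx[bad[0]]!r}, sample {cols[bad[1]]!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def equals(self, other: "ExpressionMatrix") -> bool:
        return (self.feature_kind == other.feature_kind
                and self.values.equals(other.values))


@dataclass
class SampleDesign:
    """Assignment of each sample to one of the four phenotypes."""

    phenotype_of: dict[str, str]

    def __post_init__(self) -> None:
        for sample, phe in self.phenotype_of.items():
            if phe not in PHENOTYPES:
                raise ValueError(
                    f"sample {sample!r} has unknown phenotype {phe!r}; "
                    f"expected one of {PHENOTYPES}")

    def samples(self, phenotype: str) -> list[str]:
        if phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {phenotype!r}")
        return [s for s, p in self.phenotype_of.items() if p == phenotype]

    def validate_against(self, matrix: ExpressionMatrix) -> None:
        """Every matrix sample must carry exactly one phenotype label."""
        missing = [s for s in matrix.sample_ids if s not in self.phenotype_of]
        if missing:
            raise ValueError(f"samples without phenotype: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.phenotype_of)


@dataclass(frozen=True)
class GeneSet:
    """One regulator's annotated target genes."""

    name: str
    kind: str  # "miRNA" | "TF"
    members: tuple[str, ...]
    family: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in REGULATOR_KINDS:
            raise ValueError(f"regulator kind must be one of "
                             f"{REGULATOR_KINDS}, got {self.kind!r}")
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """An ordered collection of uniquely named gene sets."""

    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for gs in self.sets:
            if gs.name in seen:
                raise ValueError(f"duplicate gene set name {gs.name!r}")
            seen.add(gs.name)

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for gs in self.sets:
            if gs.name == name:
                return gs
        raise KeyError(name)

    def of_kind(self, kind: str) -> "GeneSetCollection":
        return GeneSetCollection([g for g in self.sets if g.kind == kind])


PPIEdgeList = list  # of 2-tuples (gene_a, gene_b), a < b, deduplicated


# ---------------------------------------------------------------------------
# expression matrices

def read_expression(path: str | Path, feature_kind: str,
                    linear_input: bool = False) -> ExpressionMatrix:
    """Read a TSV expression matrix (header row of sample IDs, first column
    feature IDs).

    With ``linear_input`` the body is log2-transformed; nonpositive values
    are then an error.  Missing cells, non-numeric cells and ragged rows are
    rejected with the offending line number.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}: empty file")
        cols = header.split("\t")[1:]
        if len(cols) != len(set(cols)):
            raise ParseError(f"{path}: duplicate sample IDs in header")
        feature_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols) + 1:
                raise ParseError(
                    f"{path}:{lineno}: expected {len(cols) + 1} fields, "
                    f"got {len(fields)}")
            feature_ids.append(fields[0])
            row = []
            for j, tok in enumerate(fields[1:]):
                try:
                    val = float(tok)
                except ValueError:
                    val = float("nan")
                if not np.isfinite(val):
                    raise ParseError(
                        f"{path}:{lineno}: non-numeric or missing value "
                        f"{tok!r} for feature {fields[0]!r}, "
                        f"sample {cols[j]!r}")
                row.append(val)
            rows.append(row)
    if not feature_ids:
        raise ParseError(f"{path}: no data rows")
    values = pd.DataFrame(rows, index=feature_ids, columns=cols, dtype=float)
    if linear_input:
        if (values.to_numpy() <= 0).any():
            raise ParseError(
                f"{path}: nonpositive value cannot be log2-transformed")
        values = np.log2(values)
    return ExpressionMatrix(values=values, feature_kind=feature_kind)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t", lineterminator="\n")


def collapse_features(matrix: ExpressionMatrix,
                      feature_to_gene: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse probe sets / isoforms to genes by averaging log2 values.

    Genes measured by several features get, per sample, the arithmetic mean
    of their features' log2 summaries.  Every feature must map to exactly
    one gene; output rows are in lexicographic gene order.
    """
    unmapped = [f for f in matrix.feature_ids if f not in feature_to_gene]
    if unmapped:
        raise ValueError(f"features without gene mapping: {unmapped[:10]}")
    genes = [feature_to_gene[f] for f in matrix.feature_ids]
    collapsed = matrix.values.groupby(pd.Index(genes, name="gene")).mean()
    collapsed = collapsed.sort_index()
    return ExpressionMatrix(values=collapsed, feature_kind=matrix.feature_kind)


# ---------------------------------------------------------------------------
# sample design

def read_design(path: str | Path) -> SampleDesign:
    """Read a two-column TSV (sample_id, phenotype)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[:2] == ["sample_id", "phenotype"]:
                continue  # optional header
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, "
                                 f"got {len(fields)}")
            sample, phe = fields
            if sample in mapping:
                raise ParseError(f"{path}:{lineno}: duplicate sample "
                                 f"{sample!r}")
            if phe not in PHENOTYPES:
                raise ParseError(f"{path}:{lineno}: unknown phenotype "
                                 f"{phe!r}")
            mapping[sample] = phe
    if not mapping:
        raise ParseError(f"{path}: no samples")
    return SampleDesign(mapping)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tphenotype\n")
        for sample, phe in design.phenotype_of.items():
            fh.write(f"{sample}\t{phe}\n")


# ---------------------------------------------------------------------------
# gene sets (GMT)

def read_gmt(path: str | Path, regulator_kind: str) -> GeneSetCollection:
    """Read a GMT file: ``name TAB description TAB member...``.

    A description formatted ``family=<id>`` is parsed as the regulator's
    family identifier (used for one-per-family collapsing in networks);
    anything else is ignored.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member")
            name, desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} "
                                 "has no members")
            family = desc[len("family="):] if desc.startswith("family=") \
                else None
            sets.append(GeneSet(name=name, kind=regulator_kind,
                                members=tuple(members), family=family))
    try:
        return GeneSetCollection(sets)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            desc = f"family={gs.family}" if gs.family else "na"
            fh.write("\t".join([gs.name, desc, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# protein-protein interactions

def read_ppi(path: str | Path) -> PPIEdgeList:
    """Read a two-column TSV of undirected gene pairs.

    Self-loops are rejected; reversed duplicates collapse onto one edge.
    Edges come back sorted with each pair in lexicographic order.
    """
    path = Path(path)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 fields, "
                                 f"got {len(fields)}")
            a, b = fields
            if a == b:
                raise ParseError(f"{path}:{lineno}: self-loop {a!r}")
            edges.add((a, b) if a < b else (b, a))
    return sorted(edges)


def write_ppi(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in edges:
            fh.write(f"{a}\t{b}\n")
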