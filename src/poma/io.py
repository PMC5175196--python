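"""Flat-file ingestion and export for the biomarker pipeline.

Everything the pipeline touches on disk is plain TSV or newline text:
expression matrices with a two-column sample annotation, miRNA-mRNA
interaction tables exported from target databases, gene lists (transcription
factors, disease-associated genes), miRNA association lists, GMT gene-set
collections, and the per-miRNA score table. Lines starting with ``#`` are
treated as comments in every format.

Identifier conventions
----------------------
miRNA IDs are normalized by stripping a leading ``hsa-`` species prefix and
otherwise keeping the ID as printed (``hsa-miR-34a-5p`` and ``miR-34a-5p``
collapse to ``miR-34a-5p``). Gene symbols are uppercased. Interaction tables
from different databases therefore merge on a common key.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

__all__ = [
    "ExpressionMatrix",
    "InteractionSet",
    "GeneSet",
    "normalize_mirna",
    "normalize_gene",
    "read_expression",
    "read_interactions",
    "read_gene_set",
    "read_mirna_list",
    "read_gmt",
    "read_probe_map",
    "write_score_table",
    "read_score_table",
    "PomaIOError",
    "ValidationError",
]


class PomaIOError(ValueError):
    """Malformed input file (parse failure, bad cell, wrong column count)."""


class ValidationError(ValueError):
    """Structurally parseable input that violates a pipeline invariant."""


def normalize_mirna(mirna_id: str) -> str:
    """Strip a leading ``hsa-`` prefix; keep the remainder's case as printed."""
    s = mirna_id.strip()
    if s.lower().startswith("hsa-"):
        s = s[4:]
    return s


def normalize_gene(symbol: str) -> str:
    """Uppercase and strip a gene symbol."""
    return symbol.strip().upper()


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix with a two-group sample annotation.

    ``values`` is a DataFrame indexed by gene (or probe, pre-collapse) ID with
    one column per sample; ``groups`` maps every sample ID to ``"case"`` or
    ``"control"``. Intensities are linear-scale, non-negative and finite.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValidationError("duplicate sample IDs in expression matrix")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene/probe IDs in expression matrix")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValidationError(f"samples without group label: {missing[:5]}")
        self.groups = self.groups.loc[list(self.values.columns)]
        bad = set(self.groups.unique()) - {CASE, CONTROL}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        for g in (CASE, CONTROL):
            if int((self.groups == g).sum()) < 2:
                raise ValidationError(
                    f"group '{g}' has fewer than 2 samples; t-test needs variance"
                )
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValidationError("non-finite intensity values")
        if (arr < 0).any():
            raise ValidationError("negative intensity values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, group: str) -> pd.DataFrame:
        """Sub-matrix of the samples in ``group``."""
        cols = [s for s in self.values.columns if self.groups[s] == group]
        return self.values[cols]


@dataclass
class InteractionSet:
    """Merged miRNA->gene interaction records with unioned source tags.

    One record per distinct (miRNA, gene) pair after ID normalization;
    ``sources`` holds the union of source tags over all files that listed
    the pair.
    """

    records: pd.DataFrame  # columns: mirna, gene, sources (frozenset)

    def __post_init__(self) -> None:
        if len(self.records) == 0:
            raise ValidationError("empty interaction set")
        pairs = self.records[["mirna", "gene"]]
        if pairs.duplicated().any():
            raise ValidationError("duplicate (miRNA, gene) pairs after merge")

    @property
    def mirnas(self) -> set[str]:
        return set(self.records["mirna"])

    @property
    def genes(self) -> set[str]:
        return set(self.records["gene"])

    def pairs(self) -> list[tuple[str, str]]:
        return list(zip(self.records["mirna"], self.records["gene"]))


@dataclass
class GeneSet:
    """Named set of normalized gene symbols (or miRNA IDs)."""

    name: str
    members: frozenset[str]
    universe_hint: int | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.members, frozenset):
            self.members = frozenset(self.members)
        if len(self.members) == 0:
            raise ValidationError(f"gene set '{self.name}' has no members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, item: str) -> bool:
        return item in self.members


def _data_lines(path: Path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line


def read_expression(matrix_path: str | Path, annotation_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (header = sample IDs) plus its annotation.

    The annotation is a two-column TSV mapping sample ID to ``case`` or
    ``control``. Samples present in the matrix but missing from the
    annotation are dropped with a warning.
    """
    matrix_path, annotation_path = Path(matrix_path), Path(annotation_path)
    lines = list(_data_lines(matrix_path))
    if not lines:
        raise PomaIOError(f"{matrix_path}: no data lines")
    header = lines[0][1].split("\t")
    samples = header[1:]
    if len(samples) == 0:
        raise PomaIOError(f"{matrix_path}: header has no sample columns")
    gene_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in lines[1:]:
        fields = line.split("\t")
        if len(fields) != len(header):
            raise PomaIOError(
                f"{matrix_path}:{lineno}: expected {len(header)} fields, got {len(fields)}"
            )
        gene_ids.append(fields[0].strip())
        try:
            rows.append([float(x) for x in fields[1:]])
        except ValueError as exc:
            raise PomaIOError(f"{matrix_path}:{lineno}: non-numeric cell ({exc})") from None
    values = pd.DataFrame(rows, index=gene_ids, columns=samples, dtype=float)

    groups: dict[str, str] = {}
    for lineno, line in _data_lines(annotation_path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise PomaIOError(f"{annotation_path}:{lineno}: expected 2 columns")
        groups[fields[0].strip()] = fields[1].strip().lower()
    unannotated = [s for s in samples if s not in groups]
    if unannotated:
        logger.warning(
            "dropping %d unannotated sample(s): %s", len(unannotated), unannotated[:5]
        )
        values = values.drop(columns=unannotated)
    return ExpressionMatrix(values, pd.Series(groups, dtype=object))


def read_interactions(paths: Sequence[str | Path]) -> InteractionSet:
    """Read and merge one or more interaction TSVs (miRNA, gene[, source]).

    Duplicate pairs collapse to a single record with unioned source tags;
    extra columns beyond the third are ignored. Records with a blank miRNA
    or gene field are skipped with a counted warning. The merge result is
    independent of file order.
    """
    merged: dict[tuple[str, str], set[str]] = {}
    n_skipped = 0
    for path in paths:
        path = Path(path)
        default_source = path.stem
        for lineno, line in _data_lines(path):
            fields = line.split("\t")
            if len(fields) < 2:
                raise PomaIOError(f"{path}:{lineno}: expected at least 2 columns")
            mirna = normalize_mirna(fields[0])
            gene = normalize_gene(fields[1])
            if not mirna or not gene:
                n_skipped += 1
                continue
            source = fields[2].strip() if len(fields) >= 3 and fields[2].strip() else default_source
            merged.setdefault((mirna, gene), set()).add(source)
    if n_skipped:
        logger.warning("skipped %d interaction record(s) with blank fields", n_skipped)
    if not merged:
        raise ValidationError("no interaction records after merging")
    pairs = sorted(merged)
    records = pd.DataFrame(
        {
            "mirna": [p[0] for p in pairs],
            "gene": [p[1] for p in pairs],
            "sources": [frozenset(merged[p]) for p in pairs],
        }
    )
    return InteractionSet(records)


def read_gene_set(path: str | Path, name: str, *, mirna: bool = False) -> GeneSet:
    """Read a newline-delimited symbol list into a named GeneSet.

    ``#`` comment lines are ignored; symbols are normalized (gene symbols
    uppercased, or the ``hsa-`` rule when ``mirna=True``) and deduplicated.
    """
    path = Path(path)
    norm = normalize_mirna if mirna else normalize_gene
    members: set[str] = set()
    n_read = 0
    for _, line in _data_lines(path):
        n_read += 1
        sym = norm(line.split("\t")[0])
        if sym:
            members.add(sym)
    if not members:
        raise ValidationError(f"{path}: gene set '{name}' is empty")
    logger.info("read %d lines, kept %d unique members for set '%s'", n_read, len(members), name)
    return GeneSet(name, frozenset(members))


def read_mirna_list(path: str | Path, name: str = "associated") -> GeneSet:
    """Read a newline-delimited miRNA ID list (``hsa-`` prefixes stripped)."""
    return read_gene_set(path, name, mirna=True)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read a GMT gene-set collection: name, description, then members.

    Lines with fewer than three fields are skipped with a warning; duplicate
    set names are kept and disambiguated with a numeric suffix.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: dict[str, int] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            logger.warning("%s:%d: GMT line with <3 fields skipped", path, lineno)
            continue
        name = fields[0].strip()
        members = frozenset(normalize_gene(g) for g in fields[2:] if g.strip())
        if not members:
            logger.warning("%s:%d: GMT set '%s' has no members; skipped", path, lineno, name)
            continue
        if name in seen:
            seen[name] += 1
            logger.warning("%s:%d: duplicate set name '%s'", path, lineno, name)
            name = f"{name}_{seen[name]}"
        else:
            seen[name] = 1
        sets.append(GeneSet(name, members))
    return sets


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a probe-to-gene TSV mapping (probe_id \\t gene_symbol)."""
    path = Path(path)
    mapping: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise PomaIOError(f"{path}:{lineno}: expected 2 columns")
        probe, gene = fields[0].strip(), normalize_gene(fields[1])
        if probe and gene:
            mapping[probe] = gene
    if not mapping:
        raise ValidationError(f"{path}: empty probe map")
    return mapping


SCORE_COLUMNS = [
    "rank",
    "mirna_id",
    "NOD",
    "NOD_p",
    "TFP",
    "TFP_p",
    "AGP",
    "AGP_p",
    "stage_flags",
]


def _fmt(x: object) -> str:
    if isinstance(x, float):
        return f"{x:.10g}"
    return str(x)


def write_score_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a per-miRNA score table as TSV with the canonical column order.

    ``table`` must carry the columns in :data:`SCORE_COLUMNS`; floats are
    written with 10 significant digits so a round-trip read agrees to 1e-9.
    """
    if len(table) == 0:
        raise ValidationError("refusing to write an empty score table")
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"score table missing columns: {missing}")
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join(SCORE_COLUMNS) + "\n")
        for _, row in table.iterrows():
            fh.write("\t".join(_fmt(row[c]) for c in SCORE_COLUMNS) + "\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read back a score-table TSV written by :func:`write_score_table`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise PomaIOError(f"{path}: score table missing columns: {missing}")
    return df[SCORE_COLUMNS]
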