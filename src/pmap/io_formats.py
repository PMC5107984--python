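"""Readers and writers for the external formats the pipeline touches.

Formats: expression matrices (plain TSV or GCT #1.2), EC50 tables, PPI edge
lists (plain two-column TSV or PSI-MI TAB-like), GMT gene-set collections and
generic TSV/JSON result tables.

Identifier policy: everything joins on a single case-sensitive gene-symbol
namespace.  PSI-MI TAB alias cells resolve by precedence
gene symbol > locus tag > accession.  Duplicate expression rows collapse by
per-sample maximum (probe-to-gene many-to-one); every such repair is logged,
never silent.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pmap.errors import DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Log2 expression values, genes x samples, with optional sample metadata.

    ``values`` is a float matrix of shape ``(len(genes), len(samples))``.
    ``sample_meta`` maps sample id -> {"drug": ..., "group": ...} style
    annotations; absent entries are permitted.
    """

    genes: list[str]
    samples: list[str]
    values: np.ndarray
    sample_meta: dict[str, dict[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise DataError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise DataError("duplicate gene ids in ExpressionMatrix")
        if len(set(self.samples)) != len(self.samples):
            raise DataError("duplicate sample ids in ExpressionMatrix")
        if not np.all(np.isfinite(self.values)):
            raise DataError("non-finite values in ExpressionMatrix")
        self._gene_index = {g: i for i, g in enumerate(self.genes)}
        self._sample_index = {s: j for j, s in enumerate(self.samples)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def gene_row(self, gene: str) -> np.ndarray:
        return self.values[self._gene_index[gene]]

    def subset_samples(self, sample_ids: Sequence[str]) -> np.ndarray:
        """Column-subset of the matrix in the given sample order."""
        cols = [self._sample_index[s] for s in sample_ids]
        return self.values[:, cols]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


EC50_COLUMNS = ["sample_id", "drug", "group", "ec50"]


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.genes)


class GeneSetCollection(dict):
    """Mapping set name -> GeneSet with unique members per set."""

    def add(self, gs: GeneSet) -> None:
        self[gs.name] = gs


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def read_expression(path: str | Path, dialect: str = "tsv") -> ExpressionMatrix:
    """Read a genes-by-samples matrix from TSV or GCT (#1.2).

    TSV layout: header row of sample ids, first column gene symbols.
    GCT layout: '#1.2' line, dimensions line, then NAME / Description columns
    followed by sample columns.

    Duplicate gene rows are collapsed by per-sample maximum (logged).
    Non-numeric cells and empty matrices raise :class:`DataError` with
    coordinates.
    """
    path = Path(path)
    if dialect == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        meta_dropped = 0
    elif dialect == "gct":
        with open(path) as fh:
            version = fh.readline().strip()
            if version != "#1.2":
                raise DataError(f"{path}: expected GCT #1.2 header, got {version!r}")
            fh.readline()  # dimensions line; trusted but not enforced
            frame = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
        # GCT carries a Description column before the samples
        if frame.shape[1] and frame.columns[0].lower() == "description":
            frame = frame.drop(columns=frame.columns[0])
        meta_dropped = 1
    else:
        raise DataError(f"unknown expression dialect {dialect!r}")

    if frame.empty or frame.shape[1] == 0:
        raise DataError(f"{path}: empty expression matrix")

    values = np.empty(frame.shape, dtype=float)
    for j, col in enumerate(frame.columns):
        for i, raw in enumerate(frame[col].to_numpy()):
            try:
                values[i, j] = float(raw)
            except (TypeError, ValueError):
                raise DataError(
                    f"{path}: non-numeric cell at gene {frame.index[i]!r}, "
                    f"sample {col!r}: {raw!r}"
                ) from None

    genes = [str(g) for g in frame.index]
    numeric = pd.DataFrame(values, index=genes, columns=frame.columns)
    n_dups = len(genes) - numeric.index.nunique()
    if n_dups:
        logger.info(
            "collapsing %d duplicate gene row(s) by per-sample max in %s",
            n_dups, path,
        )
        numeric = numeric.groupby(level=0, sort=False).max()

    if not np.all(np.isfinite(numeric.to_numpy())):
        bad = np.argwhere(~np.isfinite(numeric.to_numpy()))[0]
        raise DataError(
            f"{path}: non-finite value at gene {numeric.index[bad[0]]!r}, "
            f"sample {numeric.columns[bad[1]]!r}"
        )
    logger.debug("read expression %s: %s (meta cols dropped: %d)",
                 path, numeric.shape, meta_dropped)
    return ExpressionMatrix(
        genes=list(numeric.index),
        samples=[str(c) for c in numeric.columns],
        values=numeric.to_numpy(),
    )


def write_expression(mat: ExpressionMatrix, path: str | Path) -> None:
    mat.to_frame().to_csv(path, sep="\t", index_label="gene", lineterminator="\n")


# ---------------------------------------------------------------------------
# EC50 tables
# ---------------------------------------------------------------------------


def read_ec50(path: str | Path) -> pd.DataFrame:
    """Read a per-sample EC50 table (sample_id, drug, group, ec50 [, units])."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "drug": str, "group": str})
    missing = [c for c in EC50_COLUMNS if c not in table.columns]
    if missing:
        raise DataError(f"{path}: missing EC50 columns {missing}")
    table["ec50"] = pd.to_numeric(table["ec50"], errors="coerce")
    if table["ec50"].isna().any() or (table["ec50"] <= 0).any():
        bad = table.index[~(table["ec50"] > 0)].tolist()[:5]
        raise DataError(f"{path}: non-positive or non-numeric EC50 at rows {bad}")
    dup = table.duplicated(subset=["sample_id", "drug"])
    if dup.any():
        raise DataError(
            f"{path}: duplicate (sample_id, drug) rows at {table.index[dup].tolist()[:5]}"
        )
    return table


def write_ec50(table: pd.DataFrame, path: str | Path) -> None:
    cols = EC50_COLUMNS + [c for c in table.columns if c not in EC50_COLUMNS]
    table[cols].to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

# PSI-MI TAB style identifier cell: pipe-separated db:value tokens.
_ALIAS_PRECEDENCE = (
    re.compile(r"^(?:hgnc|genesymbol|gene[ _-]?symbol|symbol):(.+)$", re.I),
    re.compile(r"^(?:locuslink|entrez ?gene/locuslink|locus[ _-]?tag):(.+)$", re.I),
    re.compile(r"^(?:uniprotkb|refseq|ensembl|ddbj/embl/genbank|chebi):(.+)$", re.I),
)


def _resolve_identifier(cell: str) -> str:
    """Resolve a PSI-MI TAB identifier cell to one symbol.

    Precedence: gene symbol > locus tag > accession; a bare token (no ``db:``
    prefix) is taken verbatim.
    """
    tokens = [t.strip() for t in cell.split("|") if t.strip()]
    if not tokens:
        raise DataError(f"empty identifier cell: {cell!r}")
    for pattern in _ALIAS_PRECEDENCE:
        for token in tokens:
            m = pattern.match(token)
            if m:
                return m.group(1).strip().strip('"')
    first = tokens[0]
    if ":" in first:
        return first.split(":", 1)[1].strip().strip('"')
    return first


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    """Read and clean an undirected PPI edge list.

    Accepts a plain two-column TSV (optional header) or PSI-MI TAB-like rows
    whose first two columns are identifier cells.  Self-loops and duplicate
    unordered pairs are removed; removal counts are logged.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    n_self = 0
    seen: set[tuple[str, str]] = set()
    n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise DataError(f"{path}:{lineno}: expected >= 2 columns")
            if lineno == 1 and parts[0].lower() in {"gene_a", "ida", "#ida", "source"}:
                continue
            a = _resolve_identifier(parts[0])
            b = _resolve_identifier(parts[1])
            if a == b:
                n_self += 1
                continue
            pair = (a, b) if a < b else (b, a)
            if pair in seen:
                n_dup += 1
                continue
            seen.add(pair)
            edges.append(pair)
    if not edges and n_self == 0 and n_dup == 0:
        raise DataError(f"{path}: empty PPI edge list")
    logger.info(
        "read PPI %s: %d edges (removed %d self-loops, %d duplicates)",
        path, len(edges), n_self, n_dup,
    )
    return sorted(edges)


def write_ppi(edges: Iterable[tuple[str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name <TAB> description <TAB> member...)."""
    path = Path(path)
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: GMT line has < 3 fields")
            name, description = parts[0], parts[1]
            members: list[str] = []
            seen: set[str] = set()
            for g in parts[2:]:
                if not g:
                    continue
                if g in seen:
                    logger.warning(
                        "%s:%d: duplicate member %r in set %r dropped",
                        path, lineno, g, name,
                    )
                    continue
                seen.add(g)
                members.append(g)
            collection.add(GeneSet(name=name, description=description,
                                   genes=tuple(members)))
    return collection


def write_gmt(collection: Mapping[str, GeneSet], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in sorted(collection):
            gs = collection[name]
            fh.write("\t".join([gs.name, gs.description, *gs.genes]) + "\n")


# ---------------------------------------------------------------------------
# Generic result writers
# ---------------------------------------------------------------------------


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with stable column order and '\\n' endings."""
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj: object, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def read_json(path: str | Path) -> object:
    with open(path) as fh:
        return json.load(fh)


def _json_default(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
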