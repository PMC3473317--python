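"""Input/output for expression atlases, gene lists, signature databases and result tables.

An expression atlas is a probes x samples intensity matrix spanning many purified
cell types or tissues with biological replicates; together with a probe annotation
(probe -> Entrez ID, gene symbol) and a replicate map (sample -> cell type) it is
the raw material from which a HECS (highly expressed, cell-specific) signature
database is built.

File dialects
-------------
- expression matrix: TSV/CSV, row labels = probe ids, column labels = sample ids;
- probe annotation: TSV with columns (probe_id, entrez_id, symbol), empty fields
  allowed -- probes without annotation are retained in the atlas but can never
  become signature genes;
- replicate map: TSV with columns (sample_id, cell_type);
- gene lists: plain text, one id per line (``single``), two-column long form
  (list-name, id), or wide form with one column per list and list names in the
  header row;
- HECS database: TSV with columns (cell_type, entrez_id, symbol) preceded by a
  ``#``-prefixed header block (species, threshold, universe size, cell-type
  registry).  Universe genes that belong to no signature are written with an
  empty cell_type field so that read(write(db)) == db.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    FormatError,
    NoGenesFoundError,
    ParameterError,
    ParseError,
    ValidationError,
)
from .hecs_db import HECSDatabase

NO_GENES_MESSAGE = "No genes found in the database"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ExpressionAtlas:
    """A validated probes x samples expression matrix with replicate structure.

    Parameters
    ----------
    values
        Non-negative intensity matrix, rows indexed by probe id, columns by
        sample id (linear intensity units, not log).
    sample_cell_type
        Map sample id -> cell-type label; every matrix column must appear.
    probe_annotation
        Map probe id -> (entrez_id or None, symbol or None).  Probes absent
        from the map (or mapped to (None, None)) are unannotated.
    species
        Free label; ``mouse``, ``human`` or ``synthetic`` in practice.
    """

    values: pd.DataFrame
    sample_cell_type: dict[str, str]
    probe_annotation: dict[str, tuple[str | None, str | None]]
    species: str = "synthetic"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValidationError(f"duplicate probe id {dup!r}")
        missing = [s for s in self.values.columns if s not in self.sample_cell_type]
        if missing:
            raise ValidationError(
                f"sample(s) missing from replicate map: {', '.join(map(str, missing))}"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix is not numeric")
        if not np.isfinite(arr).all():
            raise ValidationError("expression matrix contains non-finite values")
        if (arr < 0).any():
            probe = self.values.index[np.where(arr < 0)[0][0]]
            raise ValidationError(f"negative expression value at probe {probe!r}")

    @property
    def cell_types(self) -> list[str]:
        """Sorted distinct cell-type labels among the matrix samples."""
        return sorted({self.sample_cell_type[s] for s in self.values.columns})

    def samples_of(self, cell_type: str) -> list[str]:
        return [s for s in self.values.columns if self.sample_cell_type[s] == cell_type]

    def annotation_of(self, probe: str) -> tuple[str | None, str | None]:
        return self.probe_annotation.get(probe, (None, None))

    def is_annotated(self, probe: str) -> bool:
        return self.annotation_of(probe)[0] is not None

    @property
    def unannotated_probes(self) -> list[str]:
        return [p for p in self.values.index if not self.is_annotated(p)]


@dataclass
class GeneList:
    """A named, deduplicated list of identifiers with a declared identifier type.

    ``ids`` preserves first-occurrence order; ``n_input`` records the token
    count before deduplication (needed by :class:`MappingReport`).
    """

    name: str
    ids: tuple[str, ...]
    id_type: str  # "symbol" | "entrez"
    n_input: int = -1

    def __post_init__(self) -> None:
        if self.id_type not in ("symbol", "entrez"):
            raise ParameterError(f"id_type must be 'symbol' or 'entrez', got {self.id_type!r}")
        if len(set(self.ids)) != len(self.ids):
            raise ValidationError(f"gene list {self.name!r} contains duplicates")
        if self.n_input < 0:
            self.n_input = len(self.ids)


@dataclass
class MappingEntry:
    n_input: int
    n_unique: int
    n_mapped: int
    flagged: bool  # True when n_mapped == 0: "No genes found in the database"


@dataclass
class MappingReport:
    """Per-list counts of input / unique / database-mapped identifiers."""

    per_list: dict[str, MappingEntry] = field(default_factory=dict)

    def flagged_lists(self) -> list[str]:
        return [name for name, e in self.per_list.items() if e.flagged]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "list": name,
                "n_input": e.n_input,
                "n_unique": e.n_unique,
                "n_mapped": e.n_mapped,
                "note": NO_GENES_MESSAGE if e.flagged else "",
            }
            for name, e in self.per_list.items()
        ]
        return pd.DataFrame(rows, columns=["list", "n_input", "n_unique", "n_mapped", "note"])


# ---------------------------------------------------------------------------
# atlas reading / writing
# ---------------------------------------------------------------------------

def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV or CSV, sniffing the delimiter from the extension/content."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    sep = {"csv": ","}.get(path.suffix.lstrip(".").lower(), "\t")
    try:
        return pd.read_csv(path, sep=sep, **kwargs)
    except pd.errors.ParserError as exc:
        raise FormatError(f"malformed table {path}: {exc}") from exc


def read_atlas(
    matrix_path: str | Path,
    annotation_path: str | Path,
    replicate_map_path: str | Path,
    species: str = "synthetic",
) -> ExpressionAtlas:
    """Load and validate an expression atlas from its three files.

    Probes lacking annotation are retained: they participate in top-k% test
    lists but can never yield signature genes.
    """
    matrix = _read_delimited(matrix_path, index_col=0)
    matrix.index = matrix.index.astype(str)
    matrix.index.name = None
    matrix.columns = matrix.columns.astype(str)
    bad = matrix.columns[matrix.isna().any(axis=0)]
    if len(bad):
        first_bad = matrix.index[matrix[bad[0]].isna()][0]
        raise FormatError(f"non-numeric or missing value in row {first_bad!r} of {matrix_path}")
    try:
        matrix = matrix.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric expression matrix {matrix_path}: {exc}") from exc

    ann = _read_delimited(annotation_path, dtype=str, keep_default_na=False)
    required = {"probe_id", "entrez_id", "symbol"}
    if not required.issubset(ann.columns):
        raise FormatError(
            f"annotation {annotation_path} must have columns {sorted(required)}"
        )
    probe_annotation: dict[str, tuple[str | None, str | None]] = {}
    for probe, entrez, symbol in zip(ann["probe_id"], ann["entrez_id"], ann["symbol"]):
        probe_annotation[str(probe)] = (entrez or None, symbol or None)

    rep = _read_delimited(replicate_map_path, dtype=str, keep_default_na=False)
    if not {"sample_id", "cell_type"}.issubset(rep.columns):
        raise FormatError(
            f"replicate map {replicate_map_path} must have columns ['sample_id', 'cell_type']"
        )
    sample_cell_type = dict(zip(rep["sample_id"], rep["cell_type"]))

    return ExpressionAtlas(matrix, sample_cell_type, probe_annotation, species)


def write_atlas(
    atlas: ExpressionAtlas,
    matrix_path: str | Path,
    annotation_path: str | Path,
    replicate_map_path: str | Path,
) -> None:
    """Serialize an atlas into the three TSV files :func:`read_atlas` consumes."""
    atlas.values.to_csv(matrix_path, sep="\t", index_label="probe_id")
    ann = pd.DataFrame(
        [
            {"probe_id": p, "entrez_id": e or "", "symbol": s or ""}
            for p, (e, s) in atlas.probe_annotation.items()
        ],
        columns=["probe_id", "entrez_id", "symbol"],
    )
    ann.to_csv(annotation_path, sep="\t", index=False)
    rep = pd.DataFrame(
        [{"sample_id": s, "cell_type": c} for s, c in atlas.sample_cell_type.items()],
        columns=["sample_id", "cell_type"],
    )
    rep.to_csv(replicate_map_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene-list parsing
# ---------------------------------------------------------------------------

def _normalize_token(token: str, id_type: str) -> str:
    token = token.strip()
    if id_type == "symbol":
        return token.upper()
    if not token.isdigit():
        raise ParseError(
            f"identifier {token!r} is not a valid Entrez gene id (digits only); "
            "check that the correct identifier type is selected"
        )
    return token


def _dedup(tokens: Iterable[str]) -> tuple[str, ...]:
    seen: dict[str, None] = {}
    for t in tokens:
        seen.setdefault(t, None)
    return tuple(seen)


def parse_gene_lists(
    source: str,
    id_type: str,
    dialect: str = "single",
    separator: str = "\t",
) -> list[GeneList]:
    """Parse user gene-list text into one or more :class:`GeneList`.

    Dialects: ``single`` (one id per line, list named "list1"), ``long``
    (two columns: list-name, id), ``wide`` (one column per list, list names in
    the header row; blank cells skipped).  Duplicates within a list are removed
    keeping the first occurrence; symbols are upper-cased, Entrez ids must be
    all-digit strings.
    """
    if id_type not in ("symbol", "entrez"):
        raise ParameterError(f"unknown id_type {id_type!r}")
    if dialect not in ("single", "long", "wide"):
        raise ParameterError(f"unknown dialect {dialect!r}")
    lines = [ln for ln in source.splitlines() if ln.strip()]
    if not lines:
        raise ParseError("empty gene-list input")

    if dialect == "single":
        raw = [ln.strip() for ln in lines]
        ids = _dedup(_normalize_token(t, id_type) for t in raw)
        lists = [GeneList("list1", ids, id_type, n_input=len(raw))]
    elif dialect == "long":
        grouped: dict[str, list[str]] = {}
        for ln in lines:
            parts = ln.split(separator)
            if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
                raise ParseError(f"long-dialect line lacks (list, id) fields: {ln!r}")
            grouped.setdefault(parts[0].strip(), []).append(
                _normalize_token(parts[1], id_type)
            )
        lists = [
            GeneList(name, _dedup(toks), id_type, n_input=len(toks))
            for name, toks in grouped.items()
        ]
    else:  # wide
        header = [h.strip() for h in lines[0].split(separator)]
        if not any(header):
            raise ParseError("wide-dialect header row is empty")
        columns: list[list[str]] = [[] for _ in header]
        for ln in lines[1:]:
            for i, cell in enumerate(ln.split(separator)):
                if i < len(header) and cell.strip():
                    columns[i].append(_normalize_token(cell, id_type))
        lists = [
            GeneList(name, _dedup(toks), id_type, n_input=len(toks))
            for name, toks in zip(header, columns)
            if name
        ]

    lists = [gl for gl in lists if gl.ids]
    if not lists:
        raise ParseError("no identifiers found after parsing")
    return lists


def serialize_gene_lists(lists: Sequence[GeneList], separator: str = "\t") -> str:
    """Write lists back out in the long dialect (idempotent under re-parsing)."""
    out = io.StringIO()
    for gl in lists:
        for gid in gl.ids:
            out.write(f"{gl.name}{separator}{gid}\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# mapping report
# ---------------------------------------------------------------------------

def mapping_report(lists: Sequence[GeneList], db: HECSDatabase) -> MappingReport:
    """Count, per list, how many unique identifiers map into the database universe.

    Lists with no mapped genes are flagged ("No genes found in the database")
    rather than raising, so multi-list sessions continue past a bad list.
    """
    report = MappingReport()
    for gl in lists:
        mapped = db.map_to_universe(gl.ids, gl.id_type)
        report.per_list[gl.name] = MappingEntry(
            n_input=gl.n_input,
            n_unique=len(gl.ids),
            n_mapped=len(mapped),
            flagged=len(mapped) == 0,
        )
    return report


# ---------------------------------------------------------------------------
# HECS database serialization
# ---------------------------------------------------------------------------

_DB_MAGIC = "cten-hecs-db"


def write_hecs_db(db: HECSDatabase, path: str | Path) -> None:
    """Write a signature database as headered TSV (see module docstring)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# format: {_DB_MAGIC} v1\n")
        fh.write(f"# species: {db.species}\n")
        fh.write(f"# threshold: {db.threshold!r}\n")
        fh.write(f"# universe_size: {len(db.universe)}\n")
        fh.write(f"# cell_types: {'|'.join(sorted(db.signatures))}\n")
        fh.write("cell_type\tentrez_id\tsymbol\n")
        in_signature: set[str] = set()
        for ct in sorted(db.signatures):
            for gid in sorted(db.signatures[ct]):
                fh.write(f"{ct}\t{gid}\t{db.symbols.get(gid) or ''}\n")
                in_signature.add(gid)
        for gid in sorted(db.universe - in_signature):
            fh.write(f"\t{gid}\t{db.symbols.get(gid) or ''}\n")


def read_hecs_db(path: str | Path) -> HECSDatabase:
    """Read a database written by :func:`write_hecs_db`; inverse on all fields."""
    path = Path(path)
    header: dict[str, str] = {}
    rows: list[tuple[str, str, str]] = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                header[key.strip()] = value.strip()
            elif line and not line.startswith("cell_type\t"):
                parts = line.split("\t")
                if len(parts) != 3:
                    raise FormatError(f"bad database row in {path}: {line!r}")
                rows.append((parts[0], parts[1], parts[2]))
    for required in ("species", "threshold", "universe_size", "cell_types"):
        if required not in header:
            raise FormatError(f"database {path} missing header field {required!r}")

    signatures: dict[str, set[str]] = {
        ct: set() for ct in header["cell_types"].split("|") if ct
    }
    symbols: dict[str, str | None] = {}
    universe: set[str] = set()
    for ct, gid, symbol in rows:
        universe.add(gid)
        symbols[gid] = symbol or None
        if ct:
            signatures.setdefault(ct, set()).add(gid)
    db = HECSDatabase(
        species=header["species"],
        threshold=float(header["threshold"]),
        signatures={ct: frozenset(g) for ct, g in signatures.items()},
        universe=frozenset(universe),
        symbols=symbols,
    )
    if len(db.universe) != int(header["universe_size"]):
        raise FormatError(
            f"database {path}: universe_size header {header['universe_size']} "
            f"does not match {len(db.universe)} rows"
        )
    return db


# ---------------------------------------------------------------------------
# result tables with provenance headers
# ---------------------------------------------------------------------------

def write_table(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
    index: bool = False,
    na_rep: str = "",
) -> None:
    """Write a result table as TSV, preceded by ``#``-prefixed provenance lines."""
    from . import __version__

    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# cten {__version__}\n")
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=index, na_rep=na_rep)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`, skipping provenance lines."""
    return pd.read_csv(path, sep="\t", comment="#")
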