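"""Annotation parsing and binary presence/absence feature encoding.

Each genome (isolate genome or MAG) arrives as a functional annotation
table in the eggNOG-mapper dialect.  A genome is encoded as a binary vector
over the gene catalog: a catalog gene is *present* (1) when any annotation
row matches its symbol/alias (case-insensitive) or one of its KEGG
Orthology identifiers, and *absent* (0) otherwise.  Missing annotations are
absences — high-quality genomes are assumed, so an unobserved gene is
treated as genuinely missing from the genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import NEGATIVE_LABEL, POSITIVE_LABEL, log
from .catalog import GeneCatalog

_KO_TOKEN_RE = re.compile(r"^(?:ko:)?(K\d{5})$")


class AnnotationSchemaError(ValueError):
    """Annotation file header does not expose the required columns."""


class MatrixError(ValueError):
    """Feature-matrix construction or alignment failure."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One ORF annotation row."""

    query_id: str
    evalue: float | None = None
    preferred_name: str | None = None
    ko_ids: frozenset[str] = frozenset()


@dataclass
class FeatureMatrix:
    """Genomes × catalog-genes binary matrix with optional phenotype labels.

    ``gene_symbols`` always equals the catalog order of the catalog whose
    checksum is recorded in ``catalog_checksum``; rows are keyed by unique
    ``genome_ids``.
    """

    genome_ids: list[str]
    gene_symbols: list[str]
    values: np.ndarray
    labels: dict[str, str] | None = None
    catalog_checksum: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.genome_ids),
            len(self.gene_symbols),
        ):
            raise MatrixError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genome_ids)} genomes × {len(self.gene_symbols)} genes"
            )
        if not np.isin(self.values, (0, 1)).all():
            raise MatrixError("matrix entries must be 0 or 1")
        if len(set(self.genome_ids)) != len(self.genome_ids):
            dupes = sorted(
                g for g in set(self.genome_ids) if self.genome_ids.count(g) > 1
            )
            raise MatrixError(f"duplicate genome ids: {dupes}")
        if self.labels:
            bad = {v for v in self.labels.values()} - {POSITIVE_LABEL, NEGATIVE_LABEL}
            if bad:
                raise MatrixError(
                    f"labels must be {POSITIVE_LABEL!r} or {NEGATIVE_LABEL!r}; "
                    f"got {sorted(bad)}"
                )

    @property
    def n_genomes(self) -> int:
        return len(self.genome_ids)

    @property
    def n_genes(self) -> int:
        return len(self.gene_symbols)

    def label_array(self) -> np.ndarray:
        """Numeric labels (1 = Sporulating) for the labeled rows, row order."""
        if not self.labels:
            raise MatrixError("matrix carries no labels")
        missing = [g for g in self.genome_ids if g not in self.labels]
        if missing:
            raise MatrixError(f"genomes without labels: {missing[:5]}...")
        return np.array(
            [1 if self.labels[g] == POSITIVE_LABEL else 0 for g in self.genome_ids],
            dtype=np.int64,
        )

    def subset(self, ids: list[str]) -> "FeatureMatrix":
        pos = {g: i for i, g in enumerate(self.genome_ids)}
        unknown = [g for g in ids if g not in pos]
        if unknown:
            raise MatrixError(f"unknown genome ids: {unknown[:5]}")
        rows = [pos[g] for g in ids]
        return FeatureMatrix(
            genome_ids=list(ids),
            gene_symbols=list(self.gene_symbols),
            values=self.values[rows],
            labels=(
                {g: self.labels[g] for g in ids if g in self.labels}
                if self.labels
                else None
            ),
            catalog_checksum=self.catalog_checksum,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.values, index=pd.Index(self.genome_ids, name="genome_id"),
            columns=self.gene_symbols,
        )
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        labels: dict[str, str] | None = None,
        catalog_checksum: str = "",
    ) -> "FeatureMatrix":
        return cls(
            genome_ids=[str(g) for g in df.index],
            gene_symbols=[str(c) for c in df.columns],
            values=df.to_numpy(),
            labels=labels,
            catalog_checksum=catalog_checksum,
        )

    @classmethod
    def from_csv(
        cls, path: str | Path, labels: dict[str, str] | None = None
    ) -> "FeatureMatrix":
        df = pd.read_csv(path, index_col="genome_id")
        return cls.from_frame(df, labels=labels)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read a two-column ``genome_id <tab> phenotype`` table."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if not {"genome_id", "phenotype"} <= set(df.columns):
        raise MatrixError(
            f"labels file needs columns genome_id and phenotype; got {list(df.columns)}"
        )
    labels = dict(zip(df["genome_id"], df["phenotype"]))
    bad = set(labels.values()) - {POSITIVE_LABEL, NEGATIVE_LABEL}
    if bad:
        raise MatrixError(f"invalid phenotype value(s): {sorted(bad)}")
    return labels


def parse_emapper(
    path: str | Path, max_evalue: float | None = None
) -> list[AnnotationRecord]:
    """Parse an eggNOG-mapper annotation table into records.

    Lines starting with ``#`` are comments, except the header line starting
    with ``#query`` which names the columns.  The ``KEGG_ko`` cell is ``-``
    or a comma-joined list of ``ko:KXXXXX`` tokens.  Rows with an e-value
    above ``max_evalue`` (when given) are dropped, mirroring the upstream
    annotation-confidence filter.
    """
    path = Path(path)
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                if line.startswith("#query"):
                    header = line.lstrip("#").split("\t")
                continue
            rows.append(line.split("\t"))
    if header is None:
        if not rows:
            return []
        raise AnnotationSchemaError(f"{path}: no '#query' header line found")
    cols = {name: i for i, name in enumerate(header)}
    if "query" not in cols or (
        "Preferred_name" not in cols and "KEGG_ko" not in cols
    ):
        raise AnnotationSchemaError(
            f"{path}: header must name 'query' and at least one of "
            f"'Preferred_name'/'KEGG_ko'; observed header: {header}"
        )

    def cell(row: list[str], name: str) -> str | None:
        i = cols.get(name)
        if i is None or i >= len(row):
            return None
        v = row[i].strip()
        return None if v in ("", "-") else v

    records: list[AnnotationRecord] = []
    for row in rows:
        ev_raw = cell(row, "evalue")
        evalue = float(ev_raw) if ev_raw is not None else None
        if max_evalue is not None and evalue is not None and evalue > max_evalue:
            continue
        ko_raw = cell(row, "KEGG_ko")
        kos = set()
        if ko_raw:
            for token in ko_raw.split(","):
                m = _KO_TOKEN_RE.match(token.strip())
                if m:
                    kos.add(m.group(1))
        records.append(
            AnnotationRecord(
                query_id=cell(row, "query") or "",
                evalue=evalue,
                preferred_name=cell(row, "Preferred_name"),
                ko_ids=frozenset(kos),
            )
        )
    return records


def encode_genome(
    records: list[AnnotationRecord], catalog: GeneCatalog
) -> np.ndarray:
    """Binary presence vector over the catalog for one genome.

    A gene is present iff any record matches its symbol/alias
    (case-insensitive) or intersects its KO set; multiplicity is ignored.
    """
    vec = np.zeros(len(catalog), dtype=np.uint8)
    by_name = catalog.name_index()
    by_ko = catalog.ko_index()
    for rec in records:
        if rec.preferred_name:
            i = by_name.get(rec.preferred_name.lower())
            if i is not None:
                vec[i] = 1
        for ko in rec.ko_ids:
            i = by_ko.get(ko)
            if i is not None:
                vec[i] = 1
    return vec


def build_matrix(
    annotation_dir: str | Path,
    catalog: GeneCatalog,
    labels: dict[str, str] | None = None,
    max_evalue: float | None = None,
) -> FeatureMatrix:
    """Encode every annotation file in a directory into one feature matrix.

    The genome id is the filename stem; rows are sorted by genome id so
    repeated runs are byte-identical.
    """
    annotation_dir = Path(annotation_dir)
    files = sorted(
        p for p in annotation_dir.iterdir()
        if p.is_file() and not p.name.startswith(".")
    )
    if not files:
        raise MatrixError(f"no annotation files in {annotation_dir}")
    stems = [p.stem for p in files]
    if len(set(stems)) != len(stems):
        dupes = sorted(s for s in set(stems) if stems.count(s) > 1)
        raise MatrixError(f"duplicate genome ids from filenames: {dupes}")
    order = np.argsort(stems)
    ids, vectors = [], []
    for k in order:
        records = parse_emapper(files[k], max_evalue=max_evalue)
        vec = encode_genome(records, catalog)
        ids.append(stems[k])
        vectors.append(vec)
        log.info("encoded %s: %d/%d catalog genes present",
                 stems[k], int(vec.sum()), len(catalog))
    kept_labels = None
    if labels is not None:
        stray = sorted(set(labels) - set(ids))
        if stray:
            log.warning("labels for genomes not in directory ignored: %s", stray)
        kept_labels = {g: labels[g] for g in ids if g in labels}
    return FeatureMatrix(
        genome_ids=ids,
        gene_symbols=catalog.gene_symbols,
        values=np.vstack(vectors),
        labels=kept_labels,
        catalog_checksum=catalog.checksum,
    )


def align_matrix(matrix: FeatureMatrix, catalog: GeneCatalog) -> FeatureMatrix:
    """Reorder/repair a matrix's columns to exactly match a catalog.

    Catalog genes absent from the input are zero-filled (warning); columns
    unknown to the catalog are dropped (warning).  If fewer than half the
    catalog genes are present in the input the matrix is rejected — it is
    almost certainly the wrong table.
    """
    by_name = catalog.name_index()
    col_of = {}
    dropped = []
    for j, sym in enumerate(matrix.gene_symbols):
        i = by_name.get(sym.lower())
        if i is None:
            dropped.append(sym)
        else:
            col_of[i] = j
    if len(col_of) < len(catalog) / 2:
        raise MatrixError(
            f"only {len(col_of)} of {len(catalog)} catalog genes found in the "
            "input matrix; refusing to align (wrong matrix?)"
        )
    if dropped:
        log.warning("dropping %d non-catalog column(s): %s",
                    len(dropped), dropped[:10])
    missing = [e.gene_symbol for i, e in enumerate(catalog.entries)
               if i not in col_of]
    if missing:
        log.warning("zero-filling %d catalog gene(s) missing from input: %s",
                    len(missing), missing[:10])
    out = np.zeros((matrix.n_genomes, len(catalog)), dtype=np.uint8)
    for i, j in col_of.items():
        out[:, i] = matrix.values[:, j]
    return FeatureMatrix(
        genome_ids=list(matrix.genome_ids),
        gene_symbols=catalog.gene_symbols,
        values=out,
        labels=dict(matrix.labels) if matrix.labels else None,
        catalog_checksum=catalog.checksum,
    )
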