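"""Catalog of sporulation-associated genes.

The feature space of the classifier is fixed by a catalog of 160 genes with
conserved roles in the Firmicutes sporulation program, each tagged with the
sporulation stage (or regulon) it belongs to and with the KEGG Orthology
identifiers under which annotation pipelines report it.  The catalog row
order defines the feature-column order everywhere downstream, so catalogs
are immutable and carry a content checksum that is propagated into feature
matrices and model bundles.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ._utils import sha256_text

#: Closed-world set of sporulation-stage categories, in canonical order.
STAGES = (
    "sporulation onset and checkpoints",
    "Spo0A regulon",
    "engulfment",
    "SigF regulon",
    "SigE regulon",
    "SigG regulon",
    "SigK regulon",
    "spore cortex",
    "spore coat",
    "germination",
)

#: Number of genes in the reference catalog.
CATALOG_SIZE = 160

_KO_RE = re.compile(r"^K\d{5}$")


class CatalogError(ValueError):
    """Schema or validation failure while building a catalog."""


@dataclass(frozen=True)
class GeneCatalogEntry:
    """One sporulation-associated gene.

    Parameters
    ----------
    gene_symbol : canonical short symbol, e.g. ``"spoVD"``.
    ko_ids : KEGG Orthology identifiers (``K`` + 5 digits) mapping to this
        gene; may be empty when no KO is curated.
    aliases : alternative symbols under which annotation tools report the
        gene; matching is case-insensitive.
    stage : sporulation-stage category, one of :data:`STAGES`.
    """

    gene_symbol: str
    ko_ids: frozenset[str] = frozenset()
    aliases: frozenset[str] = frozenset()
    stage: str = STAGES[0]

    def __post_init__(self) -> None:
        if not self.gene_symbol:
            raise CatalogError("gene_symbol must be non-empty")
        if self.stage not in STAGES:
            raise CatalogError(
                f"unknown stage {self.stage!r} for gene {self.gene_symbol!r}; "
                f"expected one of {list(STAGES)}"
            )
        for ko in self.ko_ids:
            if not _KO_RE.match(ko):
                raise CatalogError(
                    f"malformed KO id {ko!r} for gene {self.gene_symbol!r}"
                )


@dataclass(frozen=True)
class GeneCatalog:
    """Ordered, validated collection of :class:`GeneCatalogEntry`."""

    entries: tuple[GeneCatalogEntry, ...]
    version_tag: str = "unversioned"
    checksum: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        seen_symbols: dict[str, str] = {}
        seen_kos: dict[str, str] = {}
        for e in self.entries:
            key = e.gene_symbol.lower()
            if key in seen_symbols:
                raise CatalogError(
                    f"duplicate gene symbol (case-insensitive): "
                    f"{seen_symbols[key]!r} and {e.gene_symbol!r}"
                )
            seen_symbols[key] = e.gene_symbol
            for ko in e.ko_ids:
                if ko in seen_kos:
                    raise CatalogError(
                        f"KO {ko} is claimed by both {seen_kos[ko]!r} "
                        f"and {e.gene_symbol!r}"
                    )
                seen_kos[ko] = e.gene_symbol
        if not self.checksum:
            object.__setattr__(self, "checksum", self._content_checksum())

    def _content_checksum(self) -> str:
        lines = [
            "\t".join(
                (
                    e.gene_symbol,
                    ",".join(sorted(e.ko_ids)),
                    ",".join(sorted(e.aliases)),
                    e.stage,
                )
            )
            for e in self.entries
        ]
        return sha256_text("\n".join(lines))[:16]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def gene_symbols(self) -> list[str]:
        return [e.gene_symbol for e in self.entries]

    def name_index(self) -> dict[str, int]:
        """Lowercased symbol/alias -> column index."""
        idx: dict[str, int] = {}
        for i, e in enumerate(self.entries):
            idx[e.gene_symbol.lower()] = i
            for a in e.aliases:
                idx.setdefault(a.lower(), i)
        return idx

    def ko_index(self) -> dict[str, int]:
        """KO identifier -> column index (injective by validation)."""
        return {ko: i for i, e in enumerate(self.entries) for ko in e.ko_ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_symbol": [e.gene_symbol for e in self.entries],
                "ko_ids": [",".join(sorted(e.ko_ids)) for e in self.entries],
                "aliases": [",".join(sorted(e.aliases)) for e in self.entries],
                "stage": [e.stage for e in self.entries],
            }
        )


_REQUIRED_COLUMNS = ("gene_symbol", "ko_ids", "aliases", "stage")


def load_catalog(path: str | Path, version_tag: str | None = None) -> GeneCatalog:
    """Load a gene catalog from a tab-separated file.

    The file must carry a header ``gene_symbol  ko_ids  aliases  stage``;
    ``ko_ids`` and ``aliases`` are comma-joined (empty string for none).
    Row order in the file fixes the feature-column order.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CatalogError(
            f"catalog file {path} is missing required column(s) {missing}; "
            f"found {list(df.columns)}"
        )
    entries = []
    for _, row in df.iterrows():
        entries.append(
            GeneCatalogEntry(
                gene_symbol=row["gene_symbol"].strip(),
                ko_ids=frozenset(
                    t.strip() for t in row["ko_ids"].split(",") if t.strip()
                ),
                aliases=frozenset(
                    t.strip() for t in row["aliases"].split(",") if t.strip()
                ),
                stage=row["stage"].strip(),
            )
        )
    return GeneCatalog(
        entries=tuple(entries),
        version_tag=version_tag or f"file:{path.name}",
    )


def write_catalog(catalog: GeneCatalog, path: str | Path) -> None:
    """Write a catalog in the TSV dialect read by :func:`load_catalog`."""
    catalog.to_frame().to_csv(path, sep="\t", index=False)


# Genes named in the published analysis: the nine genes found in every
# predicted spore-former, and the sixteen consensus genes with positive
# Shapley contributions in both base models.  Stage assignments here follow
# the genes' known roles in the B. subtilis sporulation program.
CORE_GENES = (
    ("pth", "sporulation onset and checkpoints"),
    ("yaaT", "sporulation onset and checkpoints"),
    ("spoIIAB", "SigF regulon"),
    ("spoIIIAE", "engulfment"),
    ("spoIIIAD", "engulfment"),
    ("ctpB", "SigK regulon"),
    ("ftsW", "engulfment"),
    ("spoVD", "spore cortex"),
    ("lgt", "spore coat"),
)

CONSENSUS_GENES = (
    ("lytH", "spore cortex"),
    ("cotP", "spore coat"),
    ("spoIIIAG", "engulfment"),
    ("spoIIR", "SigF regulon"),
    ("spoVAD", "germination"),
    ("gerC", "germination"),
    ("yabP", "spore coat"),
    ("yqfD", "spore coat"),
    ("gerD", "germination"),
    ("spoVAA", "germination"),
    ("gpr", "germination"),
    ("ytaF", "spore cortex"),
    ("gdh", "SigG regulon"),
    ("ypeB", "germination"),
    ("spoVID", "spore coat"),
    ("ymfJ", "SigE regulon"),
)


def default_catalog() -> GeneCatalog:
    """Deterministic synthetic stand-in for the curated 160-gene catalog.

    Contains the 25 genes named in the published analysis plus
    deterministically named filler genes (``sporgene_026`` ...), each with a
    synthetic KO identifier (K90001 ...) and, for fillers, a stage assigned
    round-robin over the category set.  The synthetic KOs are placeholders
    for testing and simulation only — they are not curated ground truth —
    which the ``version_tag`` flags.
    """
    named = list(CORE_GENES) + list(CONSENSUS_GENES)
    entries: list[GeneCatalogEntry] = []
    for i, (symbol, stage) in enumerate(named):
        entries.append(
            GeneCatalogEntry(
                gene_symbol=symbol,
                ko_ids=frozenset({f"K{90001 + i:05d}"}),
                stage=stage,
            )
        )
    for j in range(len(named), CATALOG_SIZE):
        entries.append(
            GeneCatalogEntry(
                gene_symbol=f"sporgene_{j + 1:03d}",
                ko_ids=frozenset({f"K{90001 + j:05d}"}),
                stage=STAGES[(j - len(named)) % len(STAGES)],
            )
        )
    return GeneCatalog(
        entries=tuple(entries),
        version_tag="synthetic-default-catalog-v1 (placeholder KO ids)",
    )
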