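"""Readers, writers and the canonical in-memory data model.

The pipeline consumes three kinds of input:

* a differential-expression (DE) summary table — one row per gene with a
  log2 fold change and raw/adjusted p-values (the output of limma, DESeq2,
  edgeR or similar; this package never fits DE models itself);
* gene sets in GMT format (one pathway per line);
* a miRNA→target map, either a plain two-column TSV or a TargetScan-style
  "Predicted_Targets" export.

Gene identifiers are matched as symbols. Canonicalization is deliberately
minimal — uppercase and strip — because alias/ortholog resolution is
database-version-dependent and out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "ValidationError",
    "canonical_symbol",
    "GeneSet",
    "DifferentialExpressionTable",
    "TargetMap",
    "DEFAULT_DIALECT",
    "read_de_table",
    "read_gmt",
    "write_gmt",
    "read_target_map",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """Parsed content violates a data-model invariant."""


def canonical_symbol(symbol: str) -> str:
    """Canonical form of a gene symbol: surrounding whitespace stripped,
    uppercased. Idempotent by construction."""
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class GeneSet:
    """A named set of canonicalized gene symbols."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        canon = frozenset(canonical_symbol(g) for g in self.genes)
        object.__setattr__(self, "genes", canon)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return canonical_symbol(gene) in self.genes

    def intersect(self, other: set[str] | frozenset[str]) -> "GeneSet":
        return GeneSet(self.name, self.genes & frozenset(other))


class DifferentialExpressionTable:
    """Per-gene DE summary: ``log2_fc``, ``p_raw``, ``p_adj``.

    Wraps a DataFrame indexed by canonical gene symbol. The number of rows
    is the gene universe size N of the enrichment statistic ("total number
    of genes analyzed").
    """

    COLUMNS = ("log2_fc", "p_raw", "p_adj")

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise FormatError(f"DE table missing required column(s): {missing}")
        if len(frame) == 0:
            raise ValidationError("DE table has no rows")
        frame = frame.copy()
        frame.index = pd.Index(
            [canonical_symbol(g) for g in frame.index], name="gene_id"
        )
        for col in ("p_raw", "p_adj"):
            vals = frame[col].to_numpy(dtype=float)
            if np.isnan(vals).any():
                idx = int(np.flatnonzero(np.isnan(vals))[0])
                raise ValidationError(
                    f"missing {col} at row {idx} (gene {frame.index[idx]})"
                )
            bad = (vals < 0) | (vals > 1)
            if bad.any():
                idx = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{col} outside [0,1] at row {idx} (gene {frame.index[idx]},"
                    f" value {vals[idx]!r})"
                )
        fc = frame["log2_fc"].to_numpy(dtype=float)
        if not np.isfinite(fc).all():
            idx = int(np.flatnonzero(~np.isfinite(fc))[0])
            raise ValidationError(
                f"non-finite log2_fc at row {idx} (gene {frame.index[idx]})"
            )
        if frame.index.has_duplicates:
            frame = _resolve_duplicates(frame)
        self.frame = frame[list(self.COLUMNS)].astype(float)
        self._universe = frozenset(self.frame.index)

    @property
    def n_genes(self) -> int:
        """Universe size N."""
        return len(self.frame)

    @property
    def universe(self) -> frozenset[str]:
        return self._universe

    def log2_fc(self, gene: str) -> float:
        return float(self.frame.at[canonical_symbol(gene), "log2_fc"])

    def p_adj(self, gene: str) -> float:
        return float(self.frame.at[canonical_symbol(gene), "p_adj"])

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DifferentialExpressionTable):
            return NotImplemented
        return self.frame.sort_index().equals(other.frame.sort_index())


def _resolve_duplicates(frame: pd.DataFrame) -> pd.DataFrame:
    """Keep, per duplicated gene id, the row with smallest p_adj; ties broken
    by smallest p_raw, then first occurrence."""
    n_dup = int(frame.index.duplicated().sum())
    log.warning("DE table has %d duplicate gene id rows; keeping most significant", n_dup)
    order = np.arange(len(frame))
    tmp = frame.assign(_order=order)
    tmp = tmp.sort_values(["p_adj", "p_raw", "_order"], kind="stable")
    tmp = tmp[~tmp.index.duplicated(keep="first")]
    return tmp.sort_values("_order").drop(columns="_order")


@dataclass
class TargetMap:
    """Mapping miRNA id → set of canonical target gene symbols.

    Per-miRNA target-set size intersected with the DE universe is the M of
    the enrichment statistic.
    """

    targets: dict[str, frozenset[str]]
    name: str = "targets"

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for mirna, genes in self.targets.items():
            genes = frozenset(canonical_symbol(g) for g in genes)
            if not genes:
                raise ValidationError(f"miRNA {mirna!r} has an empty target set")
            clean[str(mirna).strip()] = genes
        self.targets = clean

    def __len__(self) -> int:
        return len(self.targets)

    def __contains__(self, mirna_id: str) -> bool:
        return mirna_id in self.targets

    def __getitem__(self, mirna_id: str) -> frozenset[str]:
        return self.targets[mirna_id]

    def items(self):
        return self.targets.items()

    def mirnas(self) -> list[str]:
        return list(self.targets)


#: canonical field -> column name in the file
DEFAULT_DIALECT: dict[str, str] = {
    "gene": "gene",
    "log2_fc": "log2FoldChange",
    "p_raw": "pvalue",
    "p_adj": "padj",
}


def _read_table(path) -> pd.DataFrame:
    sep = "," if str(path).lower().endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, header=0, dtype={0: str})


def read_de_table(path, dialect: dict[str, str] | None = None) -> DifferentialExpressionTable:
    """Read a DE results table (TSV or CSV, header required).

    ``dialect`` maps the canonical fields ``gene``, ``log2_fc``, ``p_raw``,
    ``p_adj`` to the column names used in the file; unspecified fields fall
    back to :data:`DEFAULT_DIALECT` (DESeq2-style names).
    """
    d = dict(DEFAULT_DIALECT)
    if dialect:
        d.update(dialect)
    raw = _read_table(path)
    for canonical, colname in d.items():
        if colname not in raw.columns:
            raise FormatError(
                f"{path}: missing required column {colname!r} (maps to {canonical!r})"
            )
    frame = pd.DataFrame(
        {
            "log2_fc": pd.to_numeric(raw[d["log2_fc"]], errors="coerce").to_numpy(),
            "p_raw": pd.to_numeric(raw[d["p_raw"]], errors="coerce").to_numpy(),
            "p_adj": pd.to_numeric(raw[d["p_adj"]], errors="coerce").to_numpy(),
        },
        index=pd.Index(raw[d["gene"]].astype(str).to_numpy()),
    )
    table = DifferentialExpressionTable(frame)
    log.info("read DE table %s: N=%d genes", path, table.n_genes)
    return table


def write_de_table(table: DifferentialExpressionTable, path) -> None:
    out = table.frame.reset_index()
    out.columns = ["gene", "log2FoldChange", "pvalue", "padj"]
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_gmt(path) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >=3"
                )
            sets.append(GeneSet(fields[0], frozenset(fields[2:])))
    return sets


def write_gmt(sets: list[GeneSet], path, description: str = "na") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *sorted(gs.genes)]) + "\n")


_TARGETSCAN_MIRNA_COLS = ("mir family", "mirna", "mirna_id", "mir")
_TARGETSCAN_GENE_COLS = ("gene symbol", "gene_id", "gene", "target")


def read_target_map(
    path,
    min_targets: int = 10,
    universe: frozenset[str] | GeneSet | None = None,
    name: str | None = None,
) -> TargetMap:
    """Read a miRNA→target map.

    Accepts a headerless two-column TSV (mirna_id, gene_id), the same with a
    recognizable header, or a TargetScan predicted-targets export ("miR
    Family" / "Gene Symbol" columns). When ``universe`` is given, target sets
    are intersected with it before the ``min_targets`` retention filter is
    applied (M is defined within the genes analyzed); miRNAs with fewer than
    ``min_targets`` surviving targets are dropped.
    """
    if isinstance(universe, GeneSet):
        universe = universe.genes
    pairs: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\r\n") for ln in fh if ln.strip()]
    if not lines:
        return TargetMap({}, name=name or "targets")
    header = [f.strip().lower() for f in lines[0].split("\t")]
    mirna_col = gene_col = None
    for i, col in enumerate(header):
        if col in _TARGETSCAN_MIRNA_COLS and mirna_col is None:
            mirna_col = i
        if col in _TARGETSCAN_GENE_COLS and gene_col is None:
            gene_col = i
    if mirna_col is not None and gene_col is not None:
        body = lines[1:]
    else:
        mirna_col, gene_col = 0, 1
        body = lines
    for lineno, line in enumerate(body, start=2 if body is not lines else 1):
        fields = line.split("\t")
        if len(fields) <= max(mirna_col, gene_col):
            raise FormatError(
                f"{path}:{lineno}: expected at least {max(mirna_col, gene_col) + 1} "
                f"tab-separated fields, got {len(fields)}"
            )
        pairs.append((fields[mirna_col].strip(), canonical_symbol(fields[gene_col])))
    grouped: dict[str, set[str]] = {}
    for mirna, gene in pairs:
        grouped.setdefault(mirna, set()).add(gene)
    kept: dict[str, frozenset[str]] = {}
    for mirna, genes in grouped.items():
        if universe is not None:
            genes = genes & universe
        if len(genes) >= min_targets:
            kept[mirna] = frozenset(genes)
    log.info(
        "read target map %s: %d miRNAs retained of %d (min_targets=%d)",
        path, len(kept), len(grouped), min_targets,
    )
    return TargetMap(kept, name=name or "targets")


def write_target_map(tmap: TargetMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for mirna in sorted(tmap.targets):
            for gene in sorted(tmap.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


RESULT_COLUMNS = [
    "mirna_id", "N", "M", "D", "O", "overlap_genes", "p_value", "p_adjusted",
]


def write_results(records, path) -> None:
    """Write ranked enrichment records as TSV (full float precision so a
    round trip reproduces values to well below 1e-12)."""
    rows = [
        {
            "mirna_id": r.mirna_id,
            "N": r.n_universe,
            "M": r.m_targets,
            "D": r.d_down,
            "O": r.o_overlap,
            "overlap_genes": ",".join(sorted(r.overlap_genes)),
            "p_value": r.p_value,
            "p_adjusted": r.p_adjusted,
        }
        for r in records
    ]
    frame = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    frame.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_results(path):
    """Read back a results TSV written by :func:`write_results`."""
    from .enrichment import EnrichmentRecord  # local import: avoid cycle

    frame = pd.read_csv(
        path, sep="\t", dtype={"mirna_id": str, "overlap_genes": str},
        float_precision="round_trip",
    )
    records = []
    for row in frame.itertuples(index=False):
        overlap = frozenset(
            g for g in str(row.overlap_genes).split(",") if g and g != "nan"
        ) if not pd.isna(row.overlap_genes) else frozenset()
        records.append(
            EnrichmentRecord(
                mirna_id=row.mirna_id,
                n_universe=int(row.N),
                m_targets=int(row.M),
                d_down=int(row.D),
                o_overlap=int(row.O),
                overlap_genes=overlap,
                p_value=float(row.p_value),
                p_adjusted=float(row.p_adjusted),
            )
        )
    return records
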