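"""Data model and I/O for CGI-centric methylation and chromatin analyses.

The atomic analysis unit is the CpG island (CGI), a GC-rich genomic
interval. All coordinates are 0-based, half-open (BED convention);
1-based inputs must be converted at the boundary.

Matrices are thin, validated wrappers around :class:`pandas.DataFrame`:

* :class:`BetaMatrix` — CGI x sample methylation beta values in [0, 1],
  with a subtype/normal group label per sample.
* :class:`SignalMatrix` — CGI x (mark, context) nonnegative mean signals,
  the input ``V`` of the chromatin-signature factorization.
* :class:`ExpressionMatrix` — gene x sample (or gene x cell) nonnegative
  TPM-like values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CGI",
    "GeneModel",
    "CgiAnnotation",
    "BetaMatrix",
    "SignalMatrix",
    "ExpressionMatrix",
    "SurvivalTable",
    "read_cgi_bed",
    "read_genes_bed",
    "read_matrix",
    "annotate_cgis",
    "write_table",
    "read_table",
]


@dataclass(frozen=True)
class CGI:
    """A CpG island: genomic interval with optional CpG dinucleotide count."""

    chrom: str
    start: int
    end: int
    id: str
    n_cpg: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"CGI {self.id!r}: start ({self.start}) must be < end ({self.end})"
            )
        if self.n_cpg is not None and self.n_cpg < 1:
            raise ValueError(f"CGI {self.id!r}: n_cpg must be >= 1, got {self.n_cpg}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True)
class GeneModel:
    """Minimal gene model: TSS plus gene body on a strand."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    tss: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (self.start <= self.tss < self.end or self.tss in (self.start, self.end)):
            raise ValueError(
                f"gene {self.gene_id!r}: TSS {self.tss} outside body "
                f"[{self.start}, {self.end})"
            )


@dataclass(frozen=True)
class CgiAnnotation:
    """Genomic context of a CGI relative to a gene set.

    ``context`` follows precedence promoter > intragenic > intergenic.
    ``tss_distance`` is the distance from the CGI midpoint to the nearest
    TSS (``None`` when no genes were supplied).
    """

    cgi_id: str
    context: str
    target_genes: frozenset[str] = field(default_factory=frozenset)
    tss_distance: int | None = None

    def __post_init__(self) -> None:
        if self.context not in ("promoter", "intragenic", "intergenic"):
            raise ValueError(f"unknown context {self.context!r}")
        if self.context == "promoter" and not self.target_genes:
            raise ValueError(f"CGI {self.cgi_id!r}: promoter context requires target genes")
        if self.tss_distance is not None and self.tss_distance < 0:
            raise ValueError("tss_distance must be nonnegative")


def _check_unique(names: Iterable[str], what: str) -> None:
    seen: set[str] = set()
    for name in names:
        if name in seen:
            raise ValueError(f"duplicate {what}: {name!r}")
        seen.add(name)


class _MatrixBase:
    """Shared behaviour of the validated matrix wrappers."""

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            raise ValueError("duplicate row ids in matrix")
        if values.columns.has_duplicates:
            raise ValueError("duplicate column names in matrix")
        self.values = values.astype(float)
        self._validate()

    def _validate(self) -> None:  # pragma: no cover - overridden
        raise NotImplementedError

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def columns(self) -> pd.Index:
        return self.values.columns


class BetaMatrix(_MatrixBase):
    """CGI x sample beta values in [0, 1] with per-sample group labels."""

    def __init__(self, values: pd.DataFrame, sample_groups: Mapping[str, str] | pd.Series):
        groups = pd.Series(dict(sample_groups) if not isinstance(sample_groups, pd.Series)
                           else sample_groups, dtype=object)
        missing = [s for s in values.columns if s not in groups.index]
        if missing:
            raise ValueError(f"samples without group label: {missing}")
        self.sample_groups = groups.reindex(values.columns)
        super().__init__(values)

    def _validate(self) -> None:
        arr = self.values.to_numpy()
        bad = (arr < 0) | (arr > 1)
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"beta value out of [0,1] at ({self.values.index[i]}, "
                f"{self.values.columns[j]}): {arr[i, j]}"
            )

    def samples_in_group(self, group: str | Sequence[str]) -> list[str]:
        groups = [group] if isinstance(group, str) else list(group)
        return [s for s in self.values.columns if self.sample_groups[s] in groups]


class SignalMatrix(_MatrixBase):
    """CGI x (mark, context) nonnegative mean-signal matrix."""

    def _validate(self) -> None:
        arr = self.values.to_numpy()
        bad = arr < 0
        if np.any(bad & ~np.isnan(arr)):
            i, j = np.argwhere(bad & ~np.isnan(arr))[0]
            raise ValueError(
                f"negative signal at ({self.values.index[i]}, "
                f"{self.values.columns[j]}): {arr[i, j]}"
            )


class ExpressionMatrix(_MatrixBase):
    """Gene x sample (or cell) nonnegative expression matrix, TPM-like."""

    def __init__(self, values: pd.DataFrame, unit: str = "TPM"):
        self.unit = unit
        super().__init__(values)

    _validate = SignalMatrix._validate


@dataclass
class SurvivalTable:
    """Right-censored survival data with one continuous covariate."""

    data: pd.DataFrame  # columns: sample, time, event, covariate

    def __post_init__(self) -> None:
        required = {"sample", "time", "event", "covariate"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"survival table missing columns: {sorted(missing)}")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise ValueError("event indicator must be 0/1")


def read_cgi_bed(path: str | Path) -> list[CGI]:
    """Read CGIs from a BED3+ file.

    Column 4 (if present) is the CGI id, column 5 the CpG count. Missing
    ids default to ``chrom:start-end``. Input order is preserved.
    """
    cgis: list[CGI] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}, line {lineno}: expected >= 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}, line {lineno}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(
                    f"{path}, line {lineno}: start ({start}) must be < end ({end})"
                )
            cgi_id = fields[3] if len(fields) >= 4 and fields[3] not in ("", ".") \
                else f"{chrom}:{start}-{end}"
            n_cpg = None
            if len(fields) >= 5 and fields[4] not in ("", "."):
                n_cpg = int(fields[4])
            cgis.append(CGI(chrom, start, end, cgi_id, n_cpg))
    _check_unique((c.id for c in cgis), "CGI id")
    return cgis


def read_genes_bed(path: str | Path) -> list[GeneModel]:
    """Read gene models from BED6 (name = gene id, strand in column 6).

    The TSS is the 5' end of the interval: ``start`` on '+', ``end - 1``
    on '-'.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"{path}, line {lineno}: BED6 required for genes")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            name, strand = fields[3], fields[5]
            tss = start if strand == "+" else end - 1
            genes.append(GeneModel(name, name, chrom, strand, tss, start, end))
    _check_unique((g.gene_id for g in genes), "gene id")
    return genes


_MATRIX_KINDS = {"beta", "signal", "expression"}


def read_matrix(
    path: str | Path,
    kind: str,
    sample_groups: Mapping[str, str] | None = None,
) -> BetaMatrix | SignalMatrix | ExpressionMatrix:
    """Read a TSV matrix (row ids in first column, header of column names).

    ``kind`` selects the domain check: ``beta`` values must lie in [0, 1],
    ``signal`` and ``expression`` must be nonnegative. Missing values are
    preserved, never imputed.
    """
    if kind not in _MATRIX_KINDS:
        raise ValueError(f"kind must be one of {sorted(_MATRIX_KINDS)}, got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = df.columns[[not np.issubdtype(dt, np.number) for dt in df.dtypes]]
    if len(non_numeric):
        raise ValueError(f"{path}: non-numeric entries in columns {list(non_numeric)}")
    if kind == "beta":
        if sample_groups is None:
            sample_groups = {s: "unknown" for s in df.columns}
        return BetaMatrix(df, sample_groups)
    if kind == "signal":
        return SignalMatrix(df)
    return ExpressionMatrix(df)


def _promoter_window(gene: GeneModel, upstream: int, downstream: int) -> tuple[int, int]:
    # Half-open windows that mirror exactly under coordinate reflection.
    if gene.strand == "+":
        return gene.tss - upstream, gene.tss + downstream
    return gene.tss - downstream + 1, gene.tss + upstream + 1


def annotate_cgis(
    cgis: Sequence[CGI],
    genes: Sequence[GeneModel],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
) -> dict[str, CgiAnnotation]:
    """Assign a genomic context to each CGI relative to a gene set.

    Context precedence is promoter > intragenic > intergenic. The promoter
    window is strand-aware: [TSS - upstream, TSS + downstream) on '+',
    mirrored on '-'. ``target_genes`` collects genes whose promoter window
    or body overlaps the CGI; ``tss_distance`` is the minimum distance from
    the CGI midpoint to any TSS on the same chromosome (falling back to any
    chromosome, and ``None`` with a logged flag if no genes exist).
    """
    if not genes:
        logger.warning("annotate_cgis: empty gene set; all CGIs flagged intergenic")
        return {
            c.id: CgiAnnotation(c.id, "intergenic", frozenset(), None) for c in cgis
        }

    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: dict[str, CgiAnnotation] = {}
    for cgi in cgis:
        chrom_genes = by_chrom.get(cgi.chrom, [])
        promoter_hits: set[str] = set()
        body_hits: set[str] = set()
        for g in chrom_genes:
            p0, p1 = _promoter_window(g, promoter_upstream, promoter_downstream)
            if cgi.start < p1 and p0 < cgi.end:
                promoter_hits.add(g.gene_id)
            if cgi.start < g.end and g.start < cgi.end:
                body_hits.add(g.gene_id)
        if promoter_hits:
            context = "promoter"
        elif body_hits:
            context = "intragenic"
        else:
            context = "intergenic"
        ref_genes = chrom_genes if chrom_genes else genes
        tss_distance = min(abs(cgi.midpoint - g.tss) for g in ref_genes)
        out[cgi.id] = CgiAnnotation(
            cgi.id, context, frozenset(promoter_hits | body_hits), tss_distance
        )
    return out


def annotations_to_frame(annotations: Mapping[str, CgiAnnotation]) -> pd.DataFrame:
    """Tabular view of a set of annotations (one row per CGI)."""
    rows = [
        {
            "cgi_id": a.cgi_id,
            "context": a.context,
            "target_genes": ",".join(sorted(a.target_genes)),
            "tss_distance": a.tss_distance,
        }
        for a in annotations.values()
    ]
    return pd.DataFrame(rows, columns=["cgi_id", "context", "target_genes", "tss_distance"])


def write_table(result: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with deterministic column order.

    Byte-for-byte reproducible for identical inputs; floats use the
    shortest round-tripping representation so ``read_table`` restores
    values to full stored precision.
    """
    result.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a table written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
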