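"""Cell-state expression analysis: module scores, marker targeting,
methylation-expression coupling, bulk deconvolution and sparse
single-cell methylation summaries.

The module score follows the binned-control construction used by the
standard single-cell toolchains: genes are binned by dataset-average
expression, and a gene set's score in a cell is the mean expression of
the set minus the mean expression of control genes sampled from the
matching bins — so a random gene set scores ~0 regardless of its
expression magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import BetaMatrix, ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "module_score",
    "cimp_expression_score",
    "score_log2fc",
    "marker_target_fraction",
    "select_markers",
    "deconvolve",
    "paired_target_expression",
    "meth_expr_correlation",
    "sc_methylation_fraction",
]


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def _expr_frame(expr) -> pd.DataFrame:
    return expr.values if isinstance(expr, ExpressionMatrix) else expr


def module_score(
    expr,
    gene_set: GeneSet,
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Binned-control module score per cell.

    Genes are split into ``n_bins`` bins of equal size by their average
    expression over all cells; for each set gene, ``n_ctrl`` control
    genes are sampled (with replacement) from its bin. Score = mean
    expression of set genes - mean expression of the control pool.
    Deterministic under ``seed``.
    """
    df = _expr_frame(expr)
    if len(df) < n_bins:
        raise ValueError(f"need >= {n_bins} genes to form expression bins")
    set_genes = [g for g in sorted(gene_set.genes) if g in df.index]
    if not set_genes:
        raise ValueError(f"gene set {gene_set.name!r} shares no genes with the matrix")

    avg = df.mean(axis=1)
    order = avg.sort_values(kind="mergesort").index
    bin_of = pd.Series(
        np.repeat(np.arange(n_bins), np.diff(np.linspace(0, len(order), n_bins + 1).astype(int))),
        index=order,
    )
    bins = {b: bin_of.index[bin_of == b] for b in range(n_bins)}

    rng = np.random.default_rng(seed)
    set_lookup = set(set_genes)
    controls: list[str] = []
    for g in set_genes:
        pool = bins[int(bin_of[g])]
        # control genes come from the same expression bin but never from
        # the query set itself (fall back to the full bin if necessary)
        pool_wo = pool[~pool.isin(set_lookup)]
        if len(pool_wo):
            pool = pool_wo
        controls.extend(rng.choice(pool, size=n_ctrl, replace=True))
    ctrl_mean = df.loc[controls].mean(axis=0)
    set_mean = df.loc[set_genes].mean(axis=0)
    return (set_mean - ctrl_mean).rename(gene_set.name)


def cimp_expression_score(
    expr,
    call_set,
    annotations: dict,
    phenotype: str,
    contexts: tuple[str, ...] = ("promoter",),
    n_bins: int = 24,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Module score of the genes targeted by a phenotype's CIMP CGIs.

    Target genes are collected from the annotations of called CGIs whose
    context is in ``contexts`` (promoter-only by default).
    """
    called = list(call_set.called_ids) if hasattr(call_set, "called_ids") else list(call_set)
    if not called:
        raise ValueError(f"no CIMP CGIs called for phenotype {phenotype!r}")
    targets: set[str] = set()
    for cid in called:
        ann = annotations.get(cid)
        if ann is not None and ann.context in contexts:
            targets |= set(ann.target_genes)
    if not targets:
        raise ValueError(
            f"phenotype {phenotype!r}: called CGIs have no target genes in contexts {contexts}"
        )
    gs = GeneSet(f"{phenotype}-CIMP-targets", frozenset(targets), provenance="CIMP targets")
    return module_score(expr, gs, n_bins=n_bins, n_ctrl=n_ctrl, seed=seed)


def score_log2fc(score_a: pd.Series, score_b: pd.Series, eps: float = 1e-9) -> pd.Series:
    """Per-cell log2 fold change of two scores, clamping negatives to 0."""
    a = score_a.clip(lower=0.0)
    b = score_b.reindex(score_a.index).clip(lower=0.0)
    return np.log2((a + eps) / (b + eps)).rename("log2fc")


def marker_target_fraction(
    marker_sets: dict[str, GeneSet] | list[GeneSet],
    call_set,
    annotations: dict,
    contexts: tuple[str, ...] = ("promoter", "intragenic"),
) -> pd.DataFrame:
    """Percent of each marker set's genes targeted by a called CIMP CGI.

    A gene is targeted when a called CGI lists it as a target gene in a
    promoter or intragenic context. The background rate is the targeted
    fraction among all CGI-associated genes not hit by a CIMP CGI-set
    marker, reported side by side.
    """
    if isinstance(marker_sets, dict):
        sets = list(marker_sets.values())
    else:
        sets = list(marker_sets)
    if not sets:
        raise ValueError("no marker sets supplied")

    called = set(call_set.called_ids) if hasattr(call_set, "called_ids") else set(call_set)
    targeted_genes: set[str] = set()
    all_genes: set[str] = set()
    for cid, ann in annotations.items():
        if ann.context in contexts:
            all_genes |= set(ann.target_genes)
            if cid in called:
                targeted_genes |= set(ann.target_genes)

    background_genes = all_genes - targeted_genes
    background_rate = (
        100.0 * len(targeted_genes) / len(all_genes) if all_genes else np.nan
    )
    rows = []
    for gs in sets:
        hit = len(gs.genes & targeted_genes)
        rows.append(
            {
                "set": gs.name,
                "n_genes": len(gs.genes),
                "n_targeted": hit,
                "pct_targeted": 100.0 * hit / len(gs.genes),
                "background_pct": background_rate,
            }
        )
    return pd.DataFrame(rows)


def select_markers(
    de_table: pd.DataFrame,
    q_max: float = 0.01,
    lfc_min: float = 1.0,
    label_map: dict[str, str] | None = None,
    gene_col: str = "gene",
    q_col: str = "q",
    lfc_col: str = "lfc",
    label_col: str = "population",
) -> pd.DataFrame:
    """Filter a differential-expression table to marker genes.

    Keeps rows with q <= ``q_max`` and lfc strictly > ``lfc_min``;
    optionally collapses subpopulation labels via ``label_map``.
    """
    for col in (gene_col, q_col, lfc_col):
        if col not in de_table.columns:
            raise ValueError(f"missing column {col!r} in DE table")
    kept = de_table[(de_table[q_col] <= q_max) & (de_table[lfc_col] > lfc_min)].copy()
    if label_map is not None and label_col in kept.columns:
        kept[label_col] = kept[label_col].map(lambda x: label_map.get(x, x))
    return kept.reset_index(drop=True)


def deconvolve(
    reference: pd.DataFrame,
    bulk,
    method: str = "ols",
) -> dict[str, pd.DataFrame]:
    """Estimate cell-state proportions in bulk expression.

    Per bulk sample, regresses the sample's expression on the reference
    gene x state profile matrix. 'ols' uses unconstrained least squares
    whose coefficients are then clamped at 0 and renormalized to sum to
    1; 'nnls' solves the nonnegative problem directly. Returns both the
    raw coefficients and the post-processed proportions.
    """
    from scipy.optimize import nnls

    bulk_df = _expr_frame(bulk)
    genes = reference.index.intersection(bulk_df.index)
    if len(genes) < reference.shape[1]:
        raise ValueError("fewer shared genes than states")
    A = reference.loc[genes].to_numpy(dtype=float)
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("reference matrix is rank deficient")
    B = bulk_df.loc[genes].to_numpy(dtype=float)

    coefs = np.empty((bulk_df.shape[1], A.shape[1]))
    if method == "ols":
        coefs[:] = np.linalg.lstsq(A, B, rcond=None)[0].T
    elif method == "nnls":
        for j in range(B.shape[1]):
            coefs[j], _ = nnls(A, B[:, j])
    else:
        raise ValueError(f"unknown method {method!r}")

    clipped = np.clip(coefs, 0.0, None)
    sums = clipped.sum(axis=1, keepdims=True)
    if np.any(sums == 0):
        raise ValueError("a sample has all-nonpositive coefficients")
    props = clipped / sums
    cols = list(reference.columns)
    samples = list(bulk_df.columns)
    return {
        "proportions": pd.DataFrame(props, index=samples, columns=cols),
        "raw_coefficients": pd.DataFrame(coefs, index=samples, columns=cols),
    }


def paired_target_expression(
    expr_bulk,
    markers: GeneSet,
    target_flags: pd.Series,
    log_transform: bool = True,
) -> dict:
    """Per-sample mean expression of CIMP-targeted vs non-targeted markers.

    ``target_flags`` maps each marker gene to True (targeted by a called
    CIMP CGI) or False. Returns the per-sample means of both strata and
    a paired two-sided Wilcoxon signed-rank test on their differences.
    """
    df = _expr_frame(expr_bulk)
    genes = [g for g in sorted(markers.genes) if g in df.index]
    flags = target_flags.reindex(genes)
    targeted = [g for g in genes if flags[g]]
    untargeted = [g for g in genes if not flags[g]]
    if not targeted or not untargeted:
        raise ValueError("both targeted and non-targeted strata must be nonempty")
    vals = np.log2(df + 1) if log_transform else df
    mean_t = vals.loc[targeted].mean(axis=0)
    mean_u = vals.loc[untargeted].mean(axis=0)
    diff = mean_t - mean_u
    if np.allclose(diff, 0):
        p = 1.0
    else:
        _, p = stats.wilcoxon(mean_t, mean_u, alternative="two-sided")
    return {
        "targeted_mean": mean_t,
        "untargeted_mean": mean_u,
        "difference": diff,
        "wilcoxon_p": float(p),
    }


def meth_expr_correlation(
    beta: BetaMatrix,
    expr,
    cgi_gene_map: pd.Series,
    group_a: str,
    group_b: str,
    min_samples: int = 4,
) -> dict:
    """Per-gene Spearman correlation of CGI beta vs expression, by group.

    Computes the correlation within each sample group for every
    CGI-gene pair, then compares the paired per-gene correlations
    between the groups with a two-sided Wilcoxon signed-rank test.
    Genes with a constant beta or expression vector in a group are
    skipped with a logged count.
    """
    expr_df = _expr_frame(expr)
    out = {group_a: {}, group_b: {}}
    n_skipped = 0
    for group in (group_a, group_b):
        samples = beta.samples_in_group(group)
        if len(samples) < min_samples:
            raise ValueError(f"group {group!r} has < {min_samples} samples")
        shared = [s for s in samples if s in expr_df.columns]
        for cgi_id, gene in cgi_gene_map.items():
            if cgi_id not in beta.row_ids or gene not in expr_df.index:
                continue
            b = beta.values.loc[cgi_id, shared].to_numpy(float)
            e = expr_df.loc[gene, shared].to_numpy(float)
            ok = ~(np.isnan(b) | np.isnan(e))
            if ok.sum() < min_samples or np.std(b[ok]) == 0 or np.std(e[ok]) == 0:
                n_skipped += 1
                continue
            rho, _ = stats.spearmanr(b[ok], e[ok])
            out[group][gene] = rho
    if n_skipped:
        logger.info("meth_expr_correlation: skipped %d gene-group pairs", n_skipped)
    rho_a = pd.Series(out[group_a], name=group_a)
    rho_b = pd.Series(out[group_b], name=group_b)
    common = rho_a.index.intersection(rho_b.index)
    if len(common) == 0:
        raise ValueError("no genes with correlations in both groups")
    d = rho_a[common] - rho_b[common]
    p = 1.0 if np.allclose(d, 0) else float(stats.wilcoxon(rho_a[common], rho_b[common])[1])
    return {"rho_a": rho_a, "rho_b": rho_b, "wilcoxon_p": p}


def sc_methylation_fraction(
    cpg_calls: pd.DataFrame,
    regions,
    cell_groups: pd.Series | dict | None = None,
    as_ratio: bool = False,
) -> pd.DataFrame:
    """Per cell-group, per-CGI methylation from pooled sparse CpG calls.

    Pools covered CpGs over all cells of a group within each CGI and
    reports m / (m + u) (or the literal methylated:unmethylated ratio
    m / u when ``as_ratio``). CGIs with zero coverage in a group are
    reported missing.
    """
    region_ids = [r.id if hasattr(r, "id") else r for r in regions]
    if not region_ids:
        raise ValueError("region set is empty")
    calls = cpg_calls[cpg_calls["cgi_id"].isin(region_ids)].copy()
    if cell_groups is not None:
        calls["group"] = calls["cell"].map(dict(cell_groups))
    elif "group" not in calls.columns:
        calls["group"] = "all"

    grouped = calls.groupby(["group", "cgi_id"])["methylated"].agg(["sum", "count"])
    if as_ratio:
        with np.errstate(divide="ignore"):
            frac = grouped["sum"] / (grouped["count"] - grouped["sum"])
    else:
        frac = grouped["sum"] / grouped["count"]
    table = frac.unstack("cgi_id").reindex(columns=region_ids)
    return table
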