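"""CIMP-CGI calling, supporting statistics, methylation score and survival.

A CGI is called CIMP for a candidate tumor subtype when three criteria
hold simultaneously:

(i)   hypermethylation relative to the pooled CIMP-negative subtypes
      (delta beta > 0.2 by default; an absolute-difference variant is
      available),
(ii)  low methylation in the normal reference (mean beta < 0.75), and
(iii) subtype-specific significance (Kruskal-Wallis across the tumor
      subtype groups, adjusted p < 0.001, Benjamini-Hochberg by default).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import BetaMatrix, SurvivalTable

logger = logging.getLogger(__name__)

__all__ = [
    "CimpThresholds",
    "CimpCallSet",
    "group_means",
    "kruskal_wallis",
    "kruskal_wallis_matrix",
    "adjust_pvalues",
    "call_cimp",
    "combine_calls",
    "cimp_methylation_score",
    "cox_ph",
    "classify_cpg_change",
    "context_enrichment",
]


@dataclass(frozen=True)
class CimpThresholds:
    """The three calling thresholds, in beta / adjusted-p units."""

    delta_min: float = 0.2
    normal_max: float = 0.75
    adj_p_max: float = 0.001
    use_abs_delta: bool = False

    def __post_init__(self) -> None:
        for name in ("delta_min", "normal_max", "adj_p_max"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")


@dataclass
class CimpCallSet:
    """Per-CGI criterion values and the resulting labels.

    ``table`` columns: cgi_id, delta_beta, normal_beta, kw_stat, p, adj_p,
    called (bool). ``label`` (after :func:`combine_calls`) is one of
    IDH-CIMP / RTK2-CIMP / both / none.
    """

    candidate: str
    thresholds: CimpThresholds
    table: pd.DataFrame

    @property
    def called_ids(self) -> pd.Index:
        return self.table.index[self.table["called"]]


def group_means(beta: BetaMatrix, groups: list[str] | None = None) -> pd.DataFrame:
    """Per-CGI, per-group mean beta over non-missing entries.

    A group with no data for a CGI yields a missing mean for that CGI.
    """
    if groups is None:
        groups = list(pd.unique(beta.sample_groups))
    out = {}
    for g in groups:
        samples = beta.samples_in_group(g)
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
        out[g] = beta.values[samples].mean(axis=1, skipna=True)
    return pd.DataFrame(out)


def kruskal_wallis(values: np.ndarray, group_labels: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-square p-value.

    Degenerate all-identical input returns (0, 1) rather than erroring.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    groups = [values[group_labels == g] for g in pd.unique(group_labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 groups, each with >= 1 observation")
    if np.all(values == values[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def kruskal_wallis_matrix(values: np.ndarray, group_labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Kruskal-Wallis over a matrix (rows = CGIs, cols = samples).

    Vectorized rank-based evaluation with tie correction; rows containing
    missing values fall back to the per-row path on available samples.
    """
    values = np.asarray(values, dtype=float)
    group_labels = np.asarray(group_labels)
    uniq = pd.unique(group_labels)
    df = len(uniq) - 1
    n_rows, n = values.shape

    has_nan = np.isnan(values).any(axis=1)
    H = np.full(n_rows, np.nan)
    P = np.full(n_rows, np.nan)

    clean = ~has_nan
    if clean.any():
        v = values[clean]
        ranks = stats.rankdata(v, axis=1)
        ssq = np.zeros(v.shape[0])
        for g in uniq:
            mask = group_labels == g
            rsum = ranks[:, mask].sum(axis=1)
            ssq += rsum**2 / mask.sum()
        h = 12.0 / (n * (n + 1)) * ssq - 3 * (n + 1)
        # tie correction per row
        sv = np.sort(v, axis=1)
        same = np.hstack([np.zeros((v.shape[0], 1), bool), sv[:, 1:] == sv[:, :-1]])
        tie_term = np.zeros(v.shape[0])
        for i in range(v.shape[0]):
            if same[i].any():
                _, counts = np.unique(sv[i], return_counts=True)
                tie_term[i] = np.sum(counts**3 - counts)
        correction = 1.0 - tie_term / (n**3 - n)
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(correction > 0, h / correction, 0.0)
        H[clean] = h
        P[clean] = stats.chi2.sf(h, df)
        degenerate = clean.copy()
        degenerate[clean] = correction <= 0
        P[degenerate] = 1.0

    for i in np.nonzero(has_nan)[0]:
        ok = ~np.isnan(values[i])
        try:
            H[i], P[i] = kruskal_wallis(values[i, ok], group_labels[ok])
        except ValueError:
            H[i], P[i] = np.nan, np.nan
    return H, P


def adjust_pvalues(p_list, method: str = "bh") -> np.ndarray:
    """Multiple-testing adjustment (Benjamini-Hochberg step-up by default).

    Adjusted values are monotone, each >= its raw p, and capped at 1.
    ``method`` may be 'bh' or 'bonferroni'.
    """
    p = np.asarray(p_list, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"bh": "fdr_bh", "fdr_bh": "fdr_bh", "bonferroni": "bonferroni"}[method.lower()]
    ok = ~np.isnan(p)
    adj = np.full_like(p, np.nan)
    if ok.any():
        adj[ok] = multipletests(p[ok], method=key)[1]
    return adj


def call_cimp(
    beta: BetaMatrix,
    candidate_group: str,
    negative_groups: list[str],
    normal_group: str = "Normal",
    thresholds: CimpThresholds = CimpThresholds(),
    kw_groups: list[str] | None = None,
    adjust_method: str = "bh",
) -> CimpCallSet:
    """Call CIMP CGIs for one candidate subtype.

    delta_beta is the candidate group mean minus the pooled mean over all
    CIMP-negative samples (pooling at the sample level). The
    Kruskal-Wallis test runs per CGI across the tumor-subtype groups
    (``kw_groups``; defaults to candidate + negatives) on per-sample
    betas, with BH adjustment across all tested CGIs. CGIs with a missing
    criterion value are excluded from calling with a logged count.
    """
    if candidate_group in negative_groups:
        raise ValueError("candidate group must not be among the negative groups")
    normal_samples = beta.samples_in_group(normal_group)
    if not normal_samples:
        raise ValueError(f"normal group {normal_group!r} absent: criterion (ii) unevaluable")

    cand_samples = beta.samples_in_group(candidate_group)
    neg_samples = beta.samples_in_group(negative_groups)
    if not cand_samples or not neg_samples:
        raise ValueError("candidate and negative groups must be nonempty")

    cand_mean = beta.values[cand_samples].mean(axis=1, skipna=True)
    neg_mean = beta.values[neg_samples].mean(axis=1, skipna=True)
    normal_mean = beta.values[normal_samples].mean(axis=1, skipna=True)
    delta = cand_mean - neg_mean

    if kw_groups is None:
        kw_groups = [candidate_group] + list(negative_groups)
    kw_samples = beta.samples_in_group(kw_groups)
    labels = beta.sample_groups[kw_samples].to_numpy()
    H, p = kruskal_wallis_matrix(beta.values[kw_samples].to_numpy(), labels)

    adj_p = adjust_pvalues(p, method=adjust_method)
    eff_delta = np.abs(delta) if thresholds.use_abs_delta else delta

    evaluable = (~delta.isna()) & (~normal_mean.isna()) & ~np.isnan(adj_p)
    n_dropped = int((~evaluable).sum())
    if n_dropped:
        logger.info("call_cimp[%s]: %d CGIs excluded (missing criterion values)",
                    candidate_group, n_dropped)

    called = (
        evaluable
        & (eff_delta > thresholds.delta_min)
        & (normal_mean < thresholds.normal_max)
        & (adj_p < thresholds.adj_p_max)
    )
    table = pd.DataFrame(
        {
            "delta_beta": delta,
            "normal_beta": normal_mean,
            "kw_stat": H,
            "p": p,
            "adj_p": adj_p,
            "called": called,
        },
        index=beta.row_ids,
    )
    return CimpCallSet(candidate_group, thresholds, table)


def combine_calls(calls: dict[str, CimpCallSet]) -> pd.Series:
    """Combine per-phenotype call sets into one label per CGI.

    A CGI called for two phenotypes is labelled 'both'; for one, the
    phenotype's CIMP label; otherwise 'none'.
    """
    index = next(iter(calls.values())).table.index
    labels = pd.Series("none", index=index, dtype=object)
    for pheno, cs in calls.items():
        hit = cs.table["called"].reindex(index, fill_value=False)
        labels = labels.where(
            ~hit, labels.map(lambda cur, p=pheno: f"{p}-CIMP" if cur == "none" else "both")
        )
    return labels


def cimp_methylation_score(beta: BetaMatrix, cimp_set) -> pd.Series:
    """Per-sample mean beta over a CIMP-CGI set (missing-aware)."""
    ids = pd.Index(list(cimp_set))
    if ids.empty:
        raise ValueError("CIMP set is empty")
    missing = ids.difference(beta.row_ids)
    if len(missing):
        raise KeyError(f"CGIs absent from beta matrix: {list(missing)[:5]}")
    score = beta.values.loc[ids].mean(axis=0, skipna=True)
    n_missing = int(score.isna().sum())
    if n_missing:
        logger.info("cimp_methylation_score: %d samples with all-missing score", n_missing)
    return score.rename("cimp_score")


def cox_ph(survival: SurvivalTable, alpha: float = 0.05) -> dict[str, float]:
    """Cox proportional-hazards fit of event risk on a continuous score.

    Partial-likelihood maximization with Efron tie handling (the standard
    survival-toolchain default). Returns coefficient, SE, hazard-ratio
    confidence bounds and the Wald p-value.
    """
    from lifelines import CoxPHFitter

    df = survival.data
    if df["event"].sum() < 2:
        raise ValueError("need >= 2 events for a Cox fit")
    if df["covariate"].nunique() < 2:
        raise ValueError("constant covariate: no information")
    fitter = CoxPHFitter(alpha=alpha)
    fitter.fit(df[["time", "event", "covariate"]], duration_col="time", event_col="event")
    s = fitter.summary.loc["covariate"]
    return {
        "coef": float(s["coef"]),
        "se": float(s["se(coef)"]),
        "hr": float(s["exp(coef)"]),
        "hr_ci_low": float(s[f"exp(coef) lower {100 * (1 - alpha):g}%"]),
        "hr_ci_high": float(s[f"exp(coef) upper {100 * (1 - alpha):g}%"]),
        "p": float(s["p"]),
        "n": int(len(df)),
        "n_events": int(df["event"].sum()),
    }


def classify_cpg_change(
    beta_ctrl: float, beta_kd: float, eps: float = 1e-3, thr: float = 0.01
) -> str:
    """Classify a CpG's methylation change between control and perturbation.

    lfc = log2((beta_kd + eps) / (beta_ctrl + eps)); 'gain' above +thr,
    'loss' below -thr, otherwise 'unchanged'. The eps pseudocount guards
    beta = 0.
    """
    for b in (beta_ctrl, beta_kd):
        if not 0 <= b <= 1:
            raise ValueError(f"beta out of [0, 1]: {b}")
    lfc = math.log2((beta_kd + eps) / (beta_ctrl + eps))
    if lfc > thr:
        return "gain"
    if lfc < -thr:
        return "loss"
    return "unchanged"


def context_enrichment(
    set_a, set_b, annotations, context: str = "intergenic"
) -> tuple[float, float, float]:
    """Compare the genomic-context proportion of two CGI sets.

    Tests whether set_a's proportion of ``context`` CGIs exceeds set_b's
    proportion, treating the latter as the null rate of an exact one-sided
    binomial test. Returns (prop_a, prop_b, p).
    """
    ids_a, ids_b = list(set_a), list(set_b)
    if not ids_a or not ids_b:
        raise ValueError("both CGI sets must be nonempty")
    in_ctx = lambda cid: annotations[cid].context == context
    k_a = sum(in_ctx(c) for c in ids_a)
    k_b = sum(in_ctx(c) for c in ids_b)
    prop_a, prop_b = k_a / len(ids_a), k_b / len(ids_b)
    null = min(max(prop_b, 1e-12), 1 - 1e-12)
    p = stats.binomtest(k_a, len(ids_a), null, alternative="greater").pvalue
    return prop_a, prop_b, float(p)
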