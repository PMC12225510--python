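"""NMF chromatin signatures: decomposition, exposures, assignment, enrichment.

The CGI x (mark, context) signal matrix V is factorized as V ~ W @ H with
W (CGI x k) holding per-CGI signature exposures and H (k x features) the
signature definitions. Factorization uses multiplicative updates for the
squared Frobenius objective (Lee-Seung), best of several random
nonnegative initializations. Exposures are row-max normalized and a CGI
is assigned to every signature whose normalized exposure reaches the
threshold (default 0.8), which guarantees at least one assignment per
CGI; CGIs reaching it in more than one signature are multiply assigned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import linear_sum_assignment

from .core_io import SignalMatrix

__all__ = [
    "SignatureModel",
    "AssignmentTable",
    "nmf_decompose",
    "rank_survey",
    "normalize_exposures",
    "assign_signatures",
    "signature_enrichment",
    "match_signatures",
]

_EPS = 1e-12


@dataclass
class SignatureModel:
    V: pd.DataFrame
    W: pd.DataFrame          # CGI x k
    H: pd.DataFrame          # k x features
    k: int
    init_errors: np.ndarray  # final Frobenius error per initialization
    chosen_init: int
    error_trace: np.ndarray  # error checkpoints of the chosen run
    n_iter: int
    n_init: int
    seed: int

    @property
    def frobenius_error(self) -> float:
        return float(self.init_errors[self.chosen_init])

    @property
    def relative_error(self) -> float:
        return self.frobenius_error / np.linalg.norm(self.V.to_numpy())

    @property
    def explained_variance(self) -> float:
        return 1.0 - self.relative_error**2


@dataclass
class AssignmentTable:
    """Per-CGI signature assignments with a multiplicity flag."""

    assignments: pd.Series   # cgi_id -> frozenset of signature names
    threshold: float

    @property
    def multiplicity(self) -> pd.Series:
        return self.assignments.map(len) > 1

    def fraction_per_signature(self) -> pd.Series:
        """Fractions uniquely assigned per signature plus 'multiple'; sums to 1."""
        def label(s):
            return "multiple" if len(s) > 1 else next(iter(s))
        return self.assignments.map(label).value_counts(normalize=True)


def _mu_factorize(V, k, n_iter, tol, rng, check_every=10):
    """One multiplicative-update run from a random nonnegative start."""
    n, p = V.shape
    scale = np.sqrt(V.mean() / k)
    W = rng.uniform(0, 1, size=(n, k)) * scale + _EPS
    H = rng.uniform(0, 1, size=(k, p)) * scale + _EPS
    trace = []
    prev = np.inf
    for it in range(n_iter):
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        H *= (W.T @ V) / ((W.T @ W) @ H + _EPS)
        if (it + 1) % check_every == 0 or it == n_iter - 1:
            err = np.linalg.norm(V - W @ H)
            trace.append(err)
            if prev < np.inf and prev - err < tol * max(prev, _EPS):
                break
            prev = err
    return W, H, np.asarray(trace)


def nmf_decompose(
    V: SignalMatrix | pd.DataFrame,
    k: int = 4,
    n_init: int = 20,
    n_iter: int = 10_000,
    tol: float = 1e-6,
    seed: int = 0,
) -> SignatureModel:
    """Factorize a nonnegative signal matrix into k chromatin signatures.

    Runs ``n_init`` random initializations of the multiplicative-update
    algorithm (squared Frobenius objective) and keeps the one with the
    lowest final reconstruction error; each run stops early once the
    relative error improvement between checkpoints falls below ``tol``.
    The per-iteration error is nonincreasing by construction of the
    updates.
    """
    Vdf = V.values if isinstance(V, SignalMatrix) else V
    arr = Vdf.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("V must be nonnegative")
    if k >= min(arr.shape):
        raise ValueError(f"k={k} must be < min(V.shape)={min(arr.shape)}")
    if k < 1:
        raise ValueError("k must be >= 1")

    ss = np.random.SeedSequence(seed).spawn(n_init)
    best = None
    errors = np.empty(n_init)
    for i in range(n_init):
        W, H, trace = _mu_factorize(arr, k, n_iter, tol, np.random.default_rng(ss[i]))
        errors[i] = trace[-1]
        if best is None or errors[i] < errors[best[0]]:
            best = (i, W, H, trace)

    idx, W, H, trace = best
    sig_names = [f"sig{j + 1}" for j in range(k)]
    return SignatureModel(
        V=Vdf,
        W=pd.DataFrame(W, index=Vdf.index, columns=sig_names),
        H=pd.DataFrame(H, index=sig_names, columns=Vdf.columns),
        k=k,
        init_errors=errors,
        chosen_init=idx,
        error_trace=trace,
        n_iter=n_iter,
        n_init=n_init,
        seed=seed,
    )


def rank_survey(
    V: SignalMatrix | pd.DataFrame,
    k_range=range(3, 11),
    n_init: int = 20,
    n_iter: int = 10_000,
    tol: float = 1e-6,
    seed: int = 0,
    silhouette_max_n: int = 2000,
) -> pd.DataFrame:
    """Factorization-quality diagnostics across candidate ranks.

    For each k: best reconstruction error, explained variance and the
    mean silhouette of CGIs clustered by their dominant exposure. No
    automatic selection is performed — the rank is a user decision.
    """
    from sklearn.metrics import silhouette_score

    rows = []
    for k in k_range:
        model = nmf_decompose(V, k=k, n_init=n_init, n_iter=n_iter, tol=tol, seed=seed)
        W = model.W.to_numpy()
        labels = W.argmax(axis=1)
        sil = np.nan
        if len(np.unique(labels)) > 1:
            if W.shape[0] > silhouette_max_n:
                rng = np.random.default_rng(seed)
                sub = rng.choice(W.shape[0], silhouette_max_n, replace=False)
                Ws, ls = W[sub], labels[sub]
                if len(np.unique(ls)) > 1:
                    sil = silhouette_score(Ws, ls)
            else:
                sil = silhouette_score(W, labels)
        rows.append(
            {
                "k": k,
                "frobenius_error": model.frobenius_error,
                "explained_variance": model.explained_variance,
                "silhouette": float(sil) if not np.isnan(sil) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def normalize_exposures(W: pd.DataFrame) -> pd.DataFrame:
    """Divide each CGI's exposure row by its row maximum (row max -> 1)."""
    arr = W.to_numpy(dtype=float)
    if np.any(arr < 0):
        raise ValueError("exposures must be nonnegative")
    row_max = arr.max(axis=1)
    zero = row_max == 0
    if zero.any():
        raise ValueError(f"all-zero exposure row for CGI {W.index[np.nonzero(zero)[0][0]]!r}")
    return W.div(row_max, axis=0)


def assign_signatures(W_norm: pd.DataFrame, threshold: float = 0.8) -> AssignmentTable:
    """Assign each CGI to every signature with normalized exposure >= threshold.

    Because exposures are row-max normalized, every CGI reaches 1.0 in at
    least one signature, so the assigned set is nonempty by construction.
    """
    arr = W_norm.to_numpy(dtype=float)
    if not np.allclose(arr.max(axis=1), 1.0):
        raise ValueError("W_norm rows must be max-normalized (row max == 1)")
    sig_names = np.asarray(W_norm.columns)
    assigned = pd.Series(
        [frozenset(sig_names[row >= threshold]) for row in arr],
        index=W_norm.index,
    )
    return AssignmentTable(assigned, threshold)


def signature_enrichment(
    assignments: AssignmentTable,
    query_set,
    background_set,
    signature: str,
) -> dict[str, float]:
    """Enrichment of a CGI set in one signature versus a background.

    Builds the 2x2 table (query vs background-minus-query) x (assigned to
    the signature or not), reports both proportions, the log2 odds ratio
    (Haldane-Anscombe 0.5 correction when any cell is zero) and the
    two-sided Fisher exact p.
    """
    query = set(query_set)
    background = set(background_set) - query
    if not query or not background:
        raise ValueError("query and background must be nonempty and distinct")
    in_sig = assignments.assignments.map(lambda s: signature in s)
    a = sum(in_sig.get(c, False) for c in query)
    b = len(query) - a
    c = sum(in_sig.get(x, False) for x in background)
    d = len(background) - c
    if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
        raise ValueError("degenerate 2x2 table (zero margin)")
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2)
    return {
        "prop_query": a / len(query),
        "prop_background": c / len(background),
        "odds_ratio": float(odds),
        "log2_odds_ratio": float(np.log2(odds)),
        "fisher_p": float(p),
    }


def match_signatures(H_est: np.ndarray, H_true: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal permutation matching of estimated to planted signatures.

    NMF is identifiable only up to permutation and diagonal rescaling, so
    comparisons to planted factors maximize the summed cosine similarity
    of H rows over permutations (Hungarian algorithm). Returns the
    permutation (est row for each true row) and the matched cosine
    similarities.
    """
    def unit(M):
        norms = np.linalg.norm(M, axis=1, keepdims=True)
        return M / np.maximum(norms, _EPS)

    sim = unit(np.asarray(H_true, float)) @ unit(np.asarray(H_est, float)).T
    rows, cols = linear_sum_assignment(-sim)
    return cols, sim[rows, cols]
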