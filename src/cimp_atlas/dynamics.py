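"""Epigenetic dynamics: Bayesian-network structure and rank-difference analysis.

Structure learning over the seven epigenetic features (DNA methylation
plus six histone marks) at the affected CGIs uses greedy hill-climbing
that maximizes the Gaussian BIC network score, with nonparametric
bootstrapping over CGIs to attach a strength (fraction of resamples
containing the edge in either direction) and a direction confidence to
every consensus edge. Edge signs are the signs of the Pearson
correlation of the incident features.

The rank-difference analysis compares tumor to progenitor: per feature,
CGIs are ranked with rank 1 = highest signal (ties broken "first", i.e.
by input order) and diff = rank_tumor - rank_np. A negative difference
means the CGI moved up in the tumor (signal gain); DNAme and H3K27me3
differences place each CGI in a gain/loss quadrant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "EpiNetwork",
    "learn_structure",
    "bootstrap_network",
    "edge_signs",
    "rank_transform",
    "rank_difference",
    "quadrant_classify",
]


@dataclass
class EpiNetwork:
    """Consensus bootstrapped network over epigenetic features."""

    nodes: list[str]
    edges: pd.DataFrame  # columns: source, target, strength, direction_conf, sign
    R: int
    threshold: float

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for _, row in self.edges.iterrows():
            g.add_edge(row["source"], row["target"], strength=row["strength"])
        return g

    def strength(self, a: str, b: str) -> float:
        """Bootstrap strength of the undirected edge {a, b} (0 if absent)."""
        m = self.edges
        hit = ((m["source"] == a) & (m["target"] == b)) | (
            (m["source"] == b) & (m["target"] == a)
        )
        return float(m.loc[hit, "strength"].max()) if hit.any() else 0.0


def _node_bic(data: np.ndarray, node: int, parents: tuple[int, ...], cache: dict) -> float:
    """Gaussian BIC contribution of one node given its parents.

    Log-likelihood of the node's linear-Gaussian local model minus
    (k/2) log n for its k free parameters (coefficients, intercept,
    variance).
    """
    key = (node, parents)
    if key in cache:
        return cache[key]
    n = data.shape[0]
    y = data[:, node]
    if parents:
        X = np.column_stack([data[:, list(parents)], np.ones(n)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
    else:
        resid = y - y.mean()
    sigma2 = max(float(resid @ resid) / n, 1e-300)
    ll = -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)
    n_params = len(parents) + 2
    score = ll - 0.5 * n_params * np.log(n)
    cache[key] = score
    return score


def learn_structure(data: pd.DataFrame, max_parents: int | None = None) -> nx.DiGraph:
    """Greedy hill-climbing over DAGs maximizing the Gaussian BIC score.

    Moves are single-edge additions, deletions and reversals; candidate
    moves are enumerated in sorted node order and the best strictly
    improving move is applied, which makes the search deterministic for a
    given dataset. Constant features are excluded with a log message.
    """
    keep = [c for c in data.columns if data[c].nunique() > 1]
    dropped = [c for c in data.columns if c not in keep]
    if dropped:
        logger.info("learn_structure: excluded constant features %s", dropped)
    cols = sorted(keep)
    if len(cols) < 2:
        raise ValueError("need at least 2 non-constant features")
    arr = data[cols].to_numpy(dtype=float)
    idx = {c: i for i, c in enumerate(cols)}
    cache: dict = {}

    g = nx.DiGraph()
    g.add_nodes_from(cols)

    def parents_of(node):
        return tuple(sorted(idx[p] for p in g.predecessors(node)))

    improved = True
    while improved:
        improved = False
        best_gain, best_move = 1e-9, None
        for a in cols:
            for b in cols:
                if a == b:
                    continue
                if not g.has_edge(a, b):
                    if g.has_edge(b, a):
                        continue
                    if nx.has_path(g, b, a):  # would create a cycle
                        continue
                    if max_parents is not None and g.in_degree(b) >= max_parents:
                        continue
                    old = _node_bic(arr, idx[b], parents_of(b), cache)
                    new_parents = tuple(sorted(parents_of(b) + (idx[a],)))
                    gain = _node_bic(arr, idx[b], new_parents, cache) - old
                    if gain > best_gain:
                        best_gain, best_move = gain, ("add", a, b)
                else:
                    # deletion
                    old = _node_bic(arr, idx[b], parents_of(b), cache)
                    rem = tuple(p for p in parents_of(b) if p != idx[a])
                    gain = _node_bic(arr, idx[b], rem, cache) - old
                    if gain > best_gain:
                        best_gain, best_move = gain, ("del", a, b)
                    # reversal
                    g.remove_edge(a, b)
                    cyclic = nx.has_path(g, a, b)
                    g.add_edge(a, b)
                    if not cyclic and (max_parents is None or g.in_degree(a) < max_parents):
                        old_b = _node_bic(arr, idx[b], parents_of(b), cache)
                        old_a = _node_bic(arr, idx[a], parents_of(a), cache)
                        new_b = _node_bic(arr, idx[b], rem, cache)
                        new_a = _node_bic(
                            arr, idx[a], tuple(sorted(parents_of(a) + (idx[b],))), cache
                        )
                        gain = (new_a + new_b) - (old_a + old_b)
                        if gain > best_gain:
                            best_gain, best_move = gain, ("rev", a, b)
        if best_move is not None:
            op, a, b = best_move
            if op == "add":
                g.add_edge(a, b)
            elif op == "del":
                g.remove_edge(a, b)
            else:
                g.remove_edge(a, b)
                g.add_edge(b, a)
            improved = True
    return g


def bootstrap_network(
    data: pd.DataFrame,
    R: int = 200,
    strength_threshold: float = 0.5,
    seed: int = 0,
    max_parents: int | None = None,
) -> EpiNetwork:
    """Bootstrap-averaged network over CGIs.

    Learns a structure on each of R resamples of the rows; edge strength
    is the fraction of resamples containing the edge in either
    direction, direction confidence the fraction of those resamples
    supporting the majority direction. The consensus keeps edges with
    strength >= ``strength_threshold``, oriented by majority; any cycle
    is broken by dropping its weakest edge.
    """
    if R < 2:
        raise ValueError("need R >= 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    n = len(data)
    und_counts: dict[frozenset, int] = {}
    dir_counts: dict[tuple, int] = {}
    nodes: list[str] = []
    for _ in range(R):
        sample = data.iloc[rng.integers(0, n, size=n)]
        g = learn_structure(sample, max_parents=max_parents)
        nodes = sorted(set(nodes) | set(g.nodes))
        for a, b in g.edges:
            und_counts[frozenset((a, b))] = und_counts.get(frozenset((a, b)), 0) + 1
            dir_counts[(a, b)] = dir_counts.get((a, b), 0) + 1

    rows = []
    for pair, count in und_counts.items():
        a, b = sorted(pair)
        strength = count / R
        if strength < strength_threshold:
            continue
        fwd, rev = dir_counts.get((a, b), 0), dir_counts.get((b, a), 0)
        if fwd >= rev:
            src, tgt, conf = a, b, fwd / count
        else:
            src, tgt, conf = b, a, rev / count
        rows.append({"source": src, "target": tgt, "strength": strength,
                     "direction_conf": conf})
    edges = pd.DataFrame(rows, columns=["source", "target", "strength", "direction_conf"])
    edges = edges.sort_values(["strength", "source", "target"],
                              ascending=[False, True, True]).reset_index(drop=True)

    # break any cycle by removing its weakest edge
    g = nx.DiGraph()
    g.add_nodes_from(nodes)
    for _, row in edges.iterrows():
        g.add_edge(row["source"], row["target"], strength=row["strength"])
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        weakest = min(cycle, key=lambda e: g.edges[e[0], e[1]]["strength"])
        logger.info("bootstrap_network: breaking cycle by dropping %s -> %s", *weakest[:2])
        g.remove_edge(weakest[0], weakest[1])
        keep = edges.apply(lambda r: g.has_edge(r["source"], r["target"]), axis=1)
        edges = edges[keep].reset_index(drop=True)

    edges["sign"] = ""
    return EpiNetwork(nodes=nodes, edges=edges, R=R, threshold=strength_threshold)


def edge_signs(network: EpiNetwork, data: pd.DataFrame) -> EpiNetwork:
    """Annotate each edge with the sign of the Pearson correlation."""
    signs = []
    for _, row in network.edges.iterrows():
        a, b = row["source"], row["target"]
        x, y = data[a].to_numpy(float), data[b].to_numpy(float)
        if np.std(x) == 0 or np.std(y) == 0:
            raise ValueError(f"zero-variance feature on edge {a} -> {b}")
        r, _ = stats.pearsonr(x, y)
        signs.append("+" if r >= 0 else "-")
    network.edges = network.edges.assign(sign=signs)
    return network


def rank_transform(values) -> np.ndarray:
    """Descending ranks (1 = highest value); ties broken by input order."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    return stats.rankdata(-values, method="ordinal").astype(int)


def rank_difference(tumor: pd.DataFrame, np_ref: pd.DataFrame) -> pd.DataFrame:
    """Per-CGI, per-feature rank difference tumor minus progenitor.

    Both inputs are CGI x feature tables over the same CGIs and features.
    diff < 0 means the CGI ranks higher (more signal) in the tumor.
    """
    if set(tumor.index) != set(np_ref.index):
        raise ValueError("tumor and reference must cover the same CGI set")
    if list(tumor.columns) != list(np_ref.columns):
        raise ValueError("tumor and reference must share the same features")
    np_ref = np_ref.reindex(tumor.index)
    out = {}
    for feat in tumor.columns:
        rt = rank_transform(tumor[feat].to_numpy())
        rn = rank_transform(np_ref[feat].to_numpy())
        out[f"{feat}_rank_tumor"] = rt
        out[f"{feat}_rank_np"] = rn
        out[f"{feat}_diff"] = rt - rn
    return pd.DataFrame(out, index=tumor.index)


def quadrant_classify(dname_diff, k27_diff) -> pd.Series:
    """Quadrant of each CGI from its DNAme and H3K27me3 rank differences.

    gain = negative rank difference (rank moved toward 1 in the tumor),
    loss = positive; exact zero is 'neutral' and excluded from quadrant
    counts.
    """
    dn = np.asarray(dname_diff)
    k27 = np.asarray(k27_diff)
    if dn.shape != k27.shape:
        raise ValueError("rank differences must align")

    def side(d):
        return np.where(d < 0, "gain", np.where(d > 0, "loss", "neutral"))

    sdn, sk = side(dn), side(k27)
    labels = np.where(
        (sdn == "neutral") | (sk == "neutral"),
        "neutral",
        np.char.add(np.char.add(sdn.astype(str), "/"), sk.astype(str)),
    )
    index = dname_diff.index if isinstance(dname_diff, pd.Series) else None
    return pd.Series(labels, index=index, name="quadrant")
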