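"""Synthetic cohorts with planted ground truth for every pipeline stage.

Each generator emulates the structure of one input of the analysis:

* a subtype-structured CGI x sample beta matrix with planted
  hypermethylated (CIMP) CGI sets per phenotype,
* a nonnegative CGI x (mark, context) signal matrix with planted
  signature structure ``V ~ W @ H``,
* expression negatively coupled to target-CGI methylation,
* single-cell expression organized into the four glioblastoma malignant
  cell states (AC/MES/NPC/OPC-like),
* proportional-hazards survival driven by a methylation score,
* sparse per-cell CpG methylation calls.

One seed governs everything: sub-streams are spawned deterministically
per generator via :class:`numpy.random.SeedSequence`, so a fixed seed
yields bitwise-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import BetaMatrix, ExpressionMatrix, SignalMatrix, SurvivalTable

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_methylation_cohort",
    "simulate_chromatin_signals",
    "simulate_expression",
    "simulate_single_cells",
    "make_bulk_mixtures",
    "simulate_survival",
    "simulate_sparse_cpg_calls",
]

#: The cohort of the motivating study: four DNA-methylation subtypes of
#: glioblastoma plus normal brain references.
DEFAULT_GROUP_SIZES = {"IDH": 12, "MES": 18, "RTK1": 12, "RTK2": 18, "Normal": 6}

CELL_STATES = ("AC", "MES", "NPC", "OPC")

# Named sub-streams so each generator draws from an independent,
# reproducible stream of the master seed.
_STREAMS = {
    "methylation": 0,
    "signals": 1,
    "expression": 2,
    "cells": 3,
    "survival": 4,
    "cpg_calls": 5,
    "mixtures": 6,
}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(seed).spawn(len(_STREAMS))[_STREAMS[stream]]
    )


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the cohort the pipeline targets: 12/18/12/18 tumors of
    the IDH/MES/RTK1/RTK2 subtypes plus 6 normals, with a planted
    hypermethylation effect of delta_beta = 0.3 beta units over a
    measurement noise of sd 0.05.
    """

    n_cgi: int = 20_000
    group_sizes: Mapping[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    n_planted_idh: int = 1_000
    n_planted_rtk2: int = 1_000
    delta_beta: float = 0.3
    beta_noise_sd: float = 0.05
    n_signatures: int = 4
    n_features: int = 14
    signature_sparsity: float = 0.05
    signal_noise_sd: float = 0.1
    expression_coupling: float = 2.0
    expression_noise_sd: float = 0.3
    n_cells_per_state: int = 100
    n_module_genes: int = 30
    n_background_genes: int = 200
    state_shift: float = 2.0
    hazard_coef: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [self.n_cgi, self.n_planted_idh, self.n_planted_rtk2,
                  self.n_signatures, self.n_features, self.n_cells_per_state]
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not 0 <= self.delta_beta < 1:
            raise ValueError("delta_beta must lie in [0, 1)")
        if self.n_planted_idh + self.n_planted_rtk2 > self.n_cgi:
            raise ValueError("planted sets exceed n_cgi")


@dataclass
class SimTruth:
    """Planted ground truth paired with a simulated dataset."""

    cimp_labels: pd.Series | None = None          # per CGI: IDH-CIMP/RTK2-CIMP/none
    W: np.ndarray | None = None                   # planted exposures (CGI x k)
    H: np.ndarray | None = None                   # planted loadings (k x features)
    signature_membership: np.ndarray | None = None
    cell_states: pd.Series | None = None          # per cell
    state_modules: dict[str, list[str]] | None = None
    state_means: pd.DataFrame | None = None       # gene x state expression profile
    proportions: pd.DataFrame | None = None       # bulk sample x state
    hazard_coef: float | None = None
    cgi_gene_map: pd.Series | None = None         # cgi_id -> gene_id
    baseline_means: pd.Series | None = None


def simulate_methylation_cohort(config: SimConfig) -> tuple[BetaMatrix, SimTruth]:
    """Subtype-structured beta matrix with planted CIMP CGI sets.

    Background CGIs draw a per-CGI baseline mean from a bimodal beta
    mixture shared across all groups (CGIs are typically either lowly or
    highly methylated). Planted IDH-CIMP CGIs receive a mean shift of
    ``+delta_beta`` in IDH samples only; planted RTK2-CIMP CGIs in RTK2
    samples only. Planted baselines are kept low enough that the normal
    group stays below 0.75 beta. Per-sample values add Gaussian noise
    around the group mean and clip to [0, 1].
    """
    rng = _rng(config.seed, "methylation")
    n = config.n_cgi
    cgi_ids = pd.Index([f"cgi_{i:05d}" for i in range(n)], name="cgi_id")

    # bimodal background: ~half lowly, ~half highly methylated CGIs
    low = rng.beta(2, 8, size=n)
    high = rng.beta(8, 2, size=n)
    is_low = rng.random(n) < 0.5
    baseline = np.where(is_low, low, high)

    labels = pd.Series("none", index=cgi_ids, dtype=object)
    planted = rng.choice(n, size=config.n_planted_idh + config.n_planted_rtk2,
                         replace=False)
    idh_idx = planted[: config.n_planted_idh]
    rtk2_idx = planted[config.n_planted_idh:]
    labels.iloc[idh_idx] = "IDH-CIMP"
    labels.iloc[rtk2_idx] = "RTK2-CIMP"
    # planted baselines drawn low so +delta stays below the 0.75 normal cap
    hi_cap = min(0.45, 0.75 - config.delta_beta - 0.05)
    hi_cap = max(hi_cap, 0.15)
    baseline[planted] = rng.uniform(0.05, hi_cap, size=planted.size)

    samples, groups = [], {}
    for group, size in config.group_sizes.items():
        for j in range(size):
            name = f"{group}_{j + 1:02d}"
            samples.append(name)
            groups[name] = group

    means = np.tile(baseline[:, None], (1, len(samples)))
    for j, s in enumerate(samples):
        if groups[s] == "IDH":
            means[idh_idx, j] += config.delta_beta
        elif groups[s] == "RTK2":
            means[rtk2_idx, j] += config.delta_beta
    if np.any(means > 1):
        means = np.clip(means, 0.0, 1.0)

    values = means + rng.normal(0.0, config.beta_noise_sd, size=means.shape)
    values = np.clip(values, 0.0, 1.0)
    beta = BetaMatrix(pd.DataFrame(values, index=cgi_ids, columns=samples), groups)
    truth = SimTruth(cimp_labels=labels, baseline_means=pd.Series(baseline, index=cgi_ids))
    return beta, truth


def simulate_chromatin_signals(config: SimConfig) -> tuple[SignalMatrix, SimTruth]:
    """Nonnegative signal matrix with planted signature structure V = W @ H.

    Each signature loads strongly on a small block of (mark, context)
    features (H rows sparse); each CGI belongs to one signature (W rows
    near one-hot) with a small nonspecific floor. Additive half-normal
    noise keeps V nonnegative.
    """
    if config.n_signatures < 2:
        raise ValueError("need at least 2 signatures")
    rng = _rng(config.seed, "signals")
    k, n, p = config.n_signatures, config.n_cgi, config.n_features

    marks = ["DNAme", "H3K27ac", "H3K4me1", "H3K4me3", "H3K27me3", "H3K9me3", "H3K36me3"]
    contexts = ["NP", "GBM"]
    features = [f"{m}|{c}" for c in contexts for m in marks][:p]
    if len(features) < p:
        features += [f"feat_{i}" for i in range(len(features), p)]

    # disjoint feature blocks per signature, leftovers spread round-robin
    order = rng.permutation(p)
    blocks = np.array_split(order, k)
    H = rng.uniform(0, config.signature_sparsity, size=(k, p))
    for sig, block in enumerate(blocks):
        H[sig, block] = rng.uniform(1.0, 2.0, size=block.size)

    membership = rng.integers(0, k, size=n)
    W = rng.uniform(0, config.signature_sparsity, size=(n, k))
    W[np.arange(n), membership] = rng.uniform(0.75, 1.25, size=n)

    V = W @ H + np.abs(rng.normal(0.0, config.signal_noise_sd, size=(n, p)))
    cgi_ids = pd.Index([f"cgi_{i:05d}" for i in range(n)], name="cgi_id")
    signal = SignalMatrix(pd.DataFrame(V, index=cgi_ids, columns=features))
    truth = SimTruth(W=W, H=H, signature_membership=membership)
    return signal, truth


def simulate_expression(
    beta: BetaMatrix,
    truth: SimTruth,
    coupling: float = 2.0,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> tuple[ExpressionMatrix, SimTruth]:
    """Expression negatively coupled to target-CGI methylation.

    One gene per CGI; its expression in sample s is
    ``baseline * exp(-coupling * beta) * exp(noise)``, the simplest
    silencing model in which promoter hypermethylation represses the
    downstream gene. ``coupling=0`` gives no association.
    """
    rng = _rng(seed, "expression")
    b = beta.values.to_numpy()
    n_genes, n_samples = b.shape
    gene_ids = pd.Index([f"gene_{cid}" for cid in beta.row_ids], name="gene_id")
    baseline = rng.lognormal(mean=2.0, sigma=0.5, size=n_genes)
    noise = rng.normal(0.0, noise_sd, size=b.shape)
    meth = np.nan_to_num(b, nan=np.nanmean(b))
    values = baseline[:, None] * np.exp(-coupling * meth) * np.exp(noise)
    expr = ExpressionMatrix(
        pd.DataFrame(values, index=gene_ids, columns=beta.columns)
    )
    truth.cgi_gene_map = pd.Series(gene_ids, index=beta.row_ids)
    return expr, truth


def simulate_single_cells(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Single-cell expression with four planted malignant cell states.

    Each cell belongs to one of the AC/MES/NPC/OPC-like states; the genes
    of its state module are upshifted by ``state_shift`` log units on a
    lognormal background. Module memberships are disjoint.
    """
    rng = _rng(config.seed, "cells")
    modules = {
        state: [f"{state}_mod_{i:02d}" for i in range(config.n_module_genes)]
        for state in CELL_STATES
    }
    background = [f"bg_{i:03d}" for i in range(config.n_background_genes)]
    genes = [g for m in modules.values() for g in m] + background

    cells, states = [], []
    for state in CELL_STATES:
        for j in range(config.n_cells_per_state):
            cells.append(f"{state}_cell_{j:03d}")
            states.append(state)

    log_expr = rng.normal(1.0, 0.5, size=(len(genes), len(cells)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for j, state in enumerate(states):
        idx = [gene_pos[g] for g in modules[state]]
        log_expr[idx, j] += config.state_shift
    values = np.exp(log_expr)
    expr = ExpressionMatrix(pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                                         columns=cells))

    state_means = pd.DataFrame(
        {s: expr.values.loc[:, [c for c, st in zip(cells, states) if st == s]].mean(axis=1)
         for s in CELL_STATES}
    )
    truth = SimTruth(
        cell_states=pd.Series(states, index=cells),
        state_modules=modules,
        state_means=state_means,
    )
    return expr, truth


def make_bulk_mixtures(
    state_means: pd.DataFrame,
    n_samples: int = 50,
    noise_sd: float = 0.1,
    seed: int = 0,
    alpha: float = 2.0,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Bulk pseudo-samples as known Dirichlet mixtures of state means.

    Multiplicative lognormal noise of sd ``noise_sd`` is applied on the
    log-expression scale. Returns the bulk matrix and the planted
    proportions (rows sum to 1).
    """
    rng = _rng(seed, "mixtures")
    states = list(state_means.columns)
    props = rng.dirichlet([alpha] * len(states), size=n_samples)
    clean = state_means.to_numpy() @ props.T
    noisy = clean * np.exp(rng.normal(0.0, noise_sd, size=clean.shape))
    samples = [f"bulk_{i:02d}" for i in range(n_samples)]
    bulk = ExpressionMatrix(pd.DataFrame(noisy, index=state_means.index, columns=samples))
    prop_df = pd.DataFrame(props, index=samples, columns=states)
    return bulk, prop_df


def simulate_survival(
    scores: pd.Series,
    coef: float = 1.0,
    baseline_hazard: float = 0.01,
    censor_hazard: float = 0.0,
    seed: int = 0,
) -> SurvivalTable:
    """Exponential survival times with hazard = baseline * exp(coef * score).

    Censoring times are drawn independently from an exponential with rate
    ``censor_hazard`` (0 disables censoring).
    """
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    rng = _rng(seed, "survival")
    rate = baseline_hazard * np.exp(coef * scores.to_numpy(dtype=float))
    t_event = rng.exponential(1.0 / rate)
    if censor_hazard > 0:
        t_censor = rng.exponential(1.0 / censor_hazard, size=len(scores))
    else:
        t_censor = np.full(len(scores), np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    df = pd.DataFrame(
        {"sample": scores.index, "time": np.maximum(time, 1e-9), "event": event,
         "covariate": scores.to_numpy(dtype=float)}
    )
    return SurvivalTable(df)


def simulate_sparse_cpg_calls(
    true_fractions: pd.Series,
    n_cpg_per_cgi: int = 50,
    n_cells: int = 100,
    coverage: float = 0.05,
    cell_groups: Mapping[str, str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Sparse per-cell CpG methylation calls, emulating low-coverage scWGBS.

    For each cell, each CpG of each CGI is covered with probability
    ``coverage``; a covered CpG is methylated with the CGI's true
    fraction. Returns a long table (cell, cgi_id, cpg_index, methylated);
    CGIs with zero coverage simply have no rows.
    """
    rng = _rng(seed, "cpg_calls")
    cells = [f"cell_{i:03d}" for i in range(n_cells)]
    records = []
    for cgi_id, frac in true_fractions.items():
        covered = rng.random((n_cells, n_cpg_per_cgi)) < coverage
        meth = rng.random((n_cells, n_cpg_per_cgi)) < frac
        ci, pi = np.nonzero(covered)
        for c, p in zip(ci, pi):
            records.append((cells[c], cgi_id, int(p), int(meth[c, p])))
    df = pd.DataFrame(records, columns=["cell", "cgi_id", "cpg_index", "methylated"])
    if cell_groups is not None:
        df["group"] = df["cell"].map(dict(cell_groups))
    return df
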