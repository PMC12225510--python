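"""Planted-truth benchmark scenarios for every pipeline stage.

Each function generates synthetic data with a known ground truth via
:mod:`cimp_atlas.synthetic`, runs the corresponding analysis stage, and
scores the result against the planted truth (recall/FDR of CIMP calls,
factor similarity, classifier calibration, network skeleton recovery,
quadrant placement, deconvolution error, hazard-coefficient recovery).
All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import cimp, dynamics, prediction, signatures, synthetic
from .cellstate import deconvolve
from .core_io import BetaMatrix
from .synthetic import SimConfig

__all__ = [
    "evaluate_cimp_recovery",
    "evaluate_kw_calibration",
    "evaluate_bh_fdr",
    "evaluate_nmf_recovery",
    "evaluate_classifier_calibration",
    "evaluate_chain_network",
    "evaluate_rank_quadrants",
    "evaluate_deconvolution",
    "evaluate_cox_recovery",
]


def evaluate_cimp_recovery(
    seed: int = 0,
    n_cgi: int = 20_000,
    n_planted: int = 1_000,
    delta_beta: float = 0.3,
    noise_sd: float = 0.05,
) -> dict[str, float]:
    """Recall and false-positive rate of the CIMP caller on planted truth."""
    config = SimConfig(
        n_cgi=n_cgi,
        n_planted_idh=n_planted,
        n_planted_rtk2=n_planted,
        delta_beta=delta_beta,
        beta_noise_sd=noise_sd,
        seed=seed,
    )
    beta, truth = synthetic.simulate_methylation_cohort(config)
    out: dict[str, float] = {"n_cgi": n_cgi}
    for pheno in ("IDH", "RTK2"):
        calls = cimp.call_cimp(
            beta,
            candidate_group=pheno,
            negative_groups=["MES", "RTK1"],
            normal_group="Normal",
        )
        truth_pos = truth.cimp_labels == f"{pheno}-CIMP"
        called = calls.table["called"]
        tp = int((called & truth_pos).sum())
        fp = int((called & ~truth_pos).sum())
        out[f"recall_{pheno.lower()}"] = tp / int(truth_pos.sum())
        out[f"fpr_{pheno.lower()}"] = fp / int((~truth_pos).sum())
    return out


def evaluate_kw_calibration(
    seed: int = 0, n_null: int = 10_000, alpha: float = 0.05
) -> dict[str, float]:
    """Type-I error of the per-CGI Kruskal-Wallis test under the null."""
    rng = np.random.default_rng(seed)
    sizes = {"IDH": 12, "MES": 18, "RTK1": 12, "RTK2": 18}
    labels = np.repeat(list(sizes), list(sizes.values()))
    values = rng.normal(size=(n_null, labels.size))
    _, p = cimp.kruskal_wallis_matrix(values, labels)
    return {"rejection_rate": float(np.mean(p < alpha)), "n_null": n_null}


def evaluate_bh_fdr(
    seed: int = 0,
    n_reps: int = 20,
    n_tests: int = 1_000,
    n_alt: int = 200,
    q: float = 0.1,
    effect: float = 1.5,
) -> dict[str, float]:
    """Realized false-discovery proportion of BH at nominal level q.

    Mixture simulation: ``n_alt`` tests draw a shifted alternative, the
    rest the null; mean FDP over replicates should not exceed q.
    """
    rng = np.random.default_rng(seed)
    sizes = {"A": 12, "B": 18}
    labels = np.repeat(list(sizes), list(sizes.values()))
    fdps = []
    for _ in range(n_reps):
        values = rng.normal(size=(n_tests, labels.size))
        values[:n_alt, labels == "B"] += effect
        _, p = cimp.kruskal_wallis_matrix(values, labels)
        adj = cimp.adjust_pvalues(p, method="bh")
        rejected = adj < q
        n_rej = int(rejected.sum())
        false_rej = int(rejected[n_alt:].sum())
        fdps.append(false_rej / n_rej if n_rej else 0.0)
    return {"mean_fdp": float(np.mean(fdps)), "nominal_q": q, "n_reps": n_reps}


def evaluate_nmf_recovery(
    seed: int = 0,
    n_cgi: int = 5_000,
    n_features: int = 14,
    k: int = 4,
    noise_sd: float = 0.1,
    n_init: int = 20,
    n_iter: int = 2_000,
) -> dict[str, float]:
    """Factor and assignment recovery of the planted signature structure."""
    config = SimConfig(
        n_cgi=n_cgi, n_features=n_features, n_signatures=k,
        signal_noise_sd=noise_sd, seed=seed,
    )
    signal, truth = synthetic.simulate_chromatin_signals(config)
    model = signatures.nmf_decompose(
        signal, k=k, n_init=n_init, n_iter=n_iter, seed=seed
    )
    perm, cosines = signatures.match_signatures(model.H.to_numpy(), truth.H)
    inv = np.empty(k, dtype=int)
    inv[perm] = np.arange(k)  # est signature index -> planted index

    W_norm = signatures.normalize_exposures(model.W)
    assignment = signatures.assign_signatures(W_norm, threshold=0.8)
    est_membership = inv[W_norm.to_numpy().argmax(axis=1)]
    accuracy = float(np.mean(est_membership == truth.signature_membership))
    all_assigned = bool(assignment.assignments.map(len).min() >= 1)
    return {
        "min_matched_cosine": float(cosines.min()),
        "assignment_accuracy": accuracy,
        "all_assigned": all_assigned,
        "relative_error": model.relative_error,
        "n_cgi": n_cgi,
    }


def _separable_features(
    rng: np.random.Generator, n_per_class: int, shift_sd: float = 2.0, n_informative: int = 3
) -> pd.DataFrame:
    cols = list(prediction.FEATURE_COLUMNS)
    X0 = rng.normal(size=(n_per_class, len(cols)))
    X1 = rng.normal(size=(n_per_class, len(cols)))
    X1[:, :n_informative] += shift_sd  # class means differ by shift_sd sd
    df = pd.DataFrame(np.vstack([X0, X1]), columns=cols)
    df["label"] = ["IDH-CIMP"] * n_per_class + ["RTK2-CIMP"] * n_per_class
    df.index = [f"cgi_{i:05d}" for i in range(len(df))]
    # features must be nonnegative-looking where it matters; the forest is
    # scale-free so a location shift suffices
    return df


def evaluate_classifier_calibration(
    seed: int = 0,
    n_per_class: int = 300,
    n_trees: int = 300,
    cv_folds: int = 5,
    cv_repeats: int = 2,
    n_null_seeds: int = 10,
) -> dict[str, float]:
    """Separable-case AUC and permuted-label null AUC of the classifier."""
    rng = np.random.default_rng(seed)
    features = _separable_features(rng, n_per_class)
    report = prediction.train_cimp_classifier(
        features, n_trees=n_trees, cv_folds=cv_folds, cv_repeats=cv_repeats, seed=seed
    )

    null_aucs = []
    for i in range(n_null_seeds):
        null_rng = np.random.default_rng(seed + 1 + i)
        null_features = _separable_features(null_rng, n_per_class // 2, shift_sd=2.0)
        null_features["label"] = null_rng.permutation(null_features["label"].to_numpy())
        null_report = prediction.train_cimp_classifier(
            null_features, n_trees=max(100, n_trees // 2), cv_folds=cv_folds,
            cv_repeats=1, seed=seed + 1 + i,
        )
        null_aucs.append(null_report.auc)
    return {
        "separable_auc": report.auc,
        "null_auc_mean": float(np.mean(null_aucs)),
        "importance_sum": float(report.importances.sum()),
        "n_per_class": n_per_class,
    }


def evaluate_chain_network(
    seed: int = 0, n: int = 2_000, R: int = 100
) -> dict[str, float]:
    """Skeleton recovery of a linear chain X -> Y -> Z by the bootstrap net."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = x + 0.5 * rng.normal(size=n)
    z = y + 0.5 * rng.normal(size=n)
    data = pd.DataFrame({"X": x, "Y": y, "Z": z})
    net = dynamics.bootstrap_network(data, R=R, strength_threshold=0.5, seed=seed)
    return {
        "xy_strength": net.strength("X", "Y"),
        "yz_strength": net.strength("Y", "Z"),
        "xz_strength": net.strength("X", "Z"),
        "n": n,
        "R": R,
    }


def evaluate_rank_quadrants(
    seed: int = 0, n_cgi: int = 2_000, n_planted: int = 200
) -> dict[str, float]:
    """Planted DNAme-gain / H3K27me3-loss CGIs land in the right quadrant.

    Planted CGIs gain +0.3 beta of DNA methylation and lose half their
    H3K27me3 signal in the tumor relative to the progenitor.
    """
    rng = np.random.default_rng(seed)
    ids = pd.Index([f"cgi_{i:05d}" for i in range(n_cgi)])
    np_dname = rng.uniform(0, 1, n_cgi)
    np_k27 = rng.uniform(0, 1, n_cgi)
    planted = rng.choice(n_cgi, n_planted, replace=False)
    np_dname[planted] = rng.uniform(0.05, 0.4, n_planted)
    np_k27[planted] = rng.uniform(0.5, 1.0, n_planted)

    tumor_dname = np_dname.copy()
    tumor_dname[planted] = np.clip(tumor_dname[planted] + 0.3, 0, 1)
    tumor_k27 = np_k27.copy()
    tumor_k27[planted] *= 0.5

    tumor = pd.DataFrame({"DNAme": tumor_dname, "H3K27me3": tumor_k27}, index=ids)
    ref = pd.DataFrame({"DNAme": np_dname, "H3K27me3": np_k27}, index=ids)
    diffs = dynamics.rank_difference(tumor, ref)
    quad = dynamics.quadrant_classify(diffs["DNAme_diff"], diffs["H3K27me3_diff"])
    frac = float((quad.iloc[planted] == "gain/loss").mean())
    return {
        "gain_loss_fraction": frac,
        "sum_dname_diff": int(diffs["DNAme_diff"].sum()),
        "n_cgi": n_cgi,
    }


def evaluate_deconvolution(
    seed: int = 0, n_samples: int = 50, noise_sd: float = 0.1
) -> dict[str, float]:
    """RMSE of recovered cell-state proportions on noisy planted mixtures."""
    config = SimConfig(seed=seed)
    expr, truth = synthetic.simulate_single_cells(config)
    bulk, props = synthetic.make_bulk_mixtures(
        truth.state_means, n_samples=n_samples, noise_sd=noise_sd, seed=seed
    )
    result = deconvolve(truth.state_means, bulk, method="ols")
    est = result["proportions"][props.columns]
    rmse = float(np.sqrt(np.mean((est.to_numpy() - props.to_numpy()) ** 2)))
    sums = est.sum(axis=1)
    return {
        "rmse": rmse,
        "max_sum_deviation": float(np.abs(sums - 1).max()),
        "n_samples": n_samples,
    }


def evaluate_cox_recovery(
    seed: int = 0,
    coef: float = 1.0,
    n: int = 500,
    n_reps: int = 50,
    n_null_reps: int = 100,
    n_null: int = 300,
) -> dict[str, float]:
    """Hazard-coefficient recovery and null CI coverage of the Cox fit."""
    rng = np.random.default_rng(seed)
    coefs = []
    for r in range(n_reps):
        scores = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        table = synthetic.simulate_survival(
            scores, coef=coef, baseline_hazard=0.01, seed=int(rng.integers(2**31))
        )
        coefs.append(cimp.cox_ph(table)["coef"])

    covered = 0
    for r in range(n_null_reps):
        scores = pd.Series(rng.normal(size=n_null), index=[f"s{i}" for i in range(n_null)])
        table = synthetic.simulate_survival(
            scores, coef=0.0, baseline_hazard=0.01, seed=int(rng.integers(2**31))
        )
        fit = cimp.cox_ph(table)
        if fit["hr_ci_low"] <= 1.0 <= fit["hr_ci_high"]:
            covered += 1
    return {
        "mean_coef": float(np.mean(coefs)),
        "null_coverage": covered / n_null_reps,
        "n": n,
        "n_reps": n_reps,
        "n_null_reps": n_null_reps,
    }
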