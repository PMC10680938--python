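"""Canned simulation studies exercising the full pipeline.

These are the package's reference experiments on synthetic cohorts; each is
a deterministic function of its seed and returns plain dictionaries of
numbers, so they double as reproducibility checks.

The cohort conditions are fixed study conditions, not tuning knobs: 300
genes on an Erdos-Renyi network of mean degree 25 (matching the degree range
of curated signaling networks), two classes of 100 samples, 20 planted genes
with a 1.5-SD class shift, GDA scores 0.9 on planted vs 0.05 on background
genes, and K = 40 selected genes.  Training uses the GSC weight
lambda_gsc = 1 for the recovery study (the regime where the knowledge prior
is informative and meant to steer selection), 60-epoch cap and patience 8 —
sizes chosen so a study runs in minutes on one CPU.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .interpretation import planted_enrichment_pvalue, rank_biomarkers
from .model import ModelConfig
from .spectral import lowpass_profile
from .synthetic import SimConfig, generate_cohort, permute_labels
from .training import TrainConfig, cross_validate, train_model

__all__ = [
    "recovery_conditions",
    "recovery_experiment",
    "null_experiment",
    "gsc_effect_experiment",
    "spectral_contrast_experiment",
]

_RECOVERY_K = 40


def recovery_conditions(seed: int) -> tuple[SimConfig, TrainConfig]:
    sim = SimConfig(
        n_genes=300,
        n_samples_per_class=100,
        n_classes=2,
        mean_degree=25.0,
        n_planted=20,
        effect_size=1.5,
        gda_planted=0.9,
        gda_background=0.05,
        noise_sd=1.0,
        seed=seed,
    )
    train = TrainConfig(
        k=_RECOVERY_K,
        lambda_gsc=1.0,
        max_epochs=60,
        patience=8,
        batch_size=32,
        folds=5,
        seed=seed + 1,
    )
    return sim, train


def recovery_experiment(seed: int = 0) -> dict:
    """Planted-gene recovery: 5-fold CV accuracy plus biomarker enrichment.

    Trains one model per CV fold on the planted synthetic cohort, then one
    model on the full cohort for the biomarker ranking, and reports the CV
    mean/sd accuracy and macro-F1, the fraction of planted genes found in the
    top-K ranking, and the hypergeometric enrichment p-value of that overlap.
    """
    sim, tc = recovery_conditions(seed)
    cohort, gda, planted = generate_cohort(sim)
    cv = cross_validate(cohort, gda, tc)
    model, _ = train_model(cohort, gda, tc)
    ranking = rank_biomarkers(model)
    top = {g for g, _, _ in ranking[:_RECOVERY_K]}
    recovered = len(top & planted) / len(planted)
    pval = planted_enrichment_pvalue(top, set(planted), len(cohort.universe))
    return {
        "cv_mean_accuracy": cv.mean_accuracy,
        "cv_sd_accuracy": cv.sd_accuracy,
        "cv_mean_f1": cv.mean_f1,
        "planted_recovered_fraction": recovered,
        "planted_enrichment_pvalue": pval,
        "n_samples": cohort.n_samples,
    }


def null_experiment(seed: int = 0) -> dict:
    """Label-permutation control: CV accuracy must sit at chance level."""
    sim, tc = recovery_conditions(seed)
    cohort, gda, _ = generate_cohort(sim)
    null_cohort = permute_labels(cohort, seed=seed + 7)
    cv = cross_validate(null_cohort, gda, tc)
    return {
        "cv_mean_accuracy": cv.mean_accuracy,
        "cv_sd_accuracy": cv.sd_accuracy,
        "chance_level": 1.0 / cohort.n_classes,
        "n_samples": cohort.n_samples,
    }


def gsc_effect_experiment(seed: int = 0) -> dict:
    """Effect of the GSC regularizer on the prior-association of the subset.

    Trains twice on the same cohort, with lambda_gsc = 0 and 1, and compares
    the mean GDA score e(v) of the selected top-K genes.  With the GDA mass
    concentrated on a known subset, turning the regularizer on must increase
    the mean prior association of the selection.
    """
    from dataclasses import replace

    sim, tc = recovery_conditions(seed)
    cohort, gda, _ = generate_cohort(sim)

    def mean_top_gda(lambda_gsc: float) -> float:
        model, _ = train_model(cohort, gda, replace(tc, lambda_gsc=lambda_gsc))
        top = rank_biomarkers(model)[:_RECOVERY_K]
        return float(np.mean([e for _, _, e in top]))

    off = mean_top_gda(0.0)
    on = mean_top_gda(1.0)
    return {"mean_gda_lambda0": off, "mean_gda_lambda1": on, "delta": on - off}


def _mode_signal_cohort(
    rng: np.random.Generator,
    basis_vectors: np.ndarray,
    modes: list[int],
    n_per_class: int,
    effect: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Node-signal samples with a class shift on selected eigenmode coefficients."""
    n = basis_vectors.shape[0]
    xs, ys = [], []
    for c in (0, 1):
        for _ in range(n_per_class):
            coef = rng.normal(0.0, 1.0, size=n)
            coef[modes] += c * effect
            xs.append(basis_vectors @ coef)
            ys.append(c)
    return np.array(xs), np.array(ys)


def spectral_contrast_experiment(seed: int = 0) -> dict:
    """The low-pass-nature contrast of the frequency-limited probe.

    Two node-signal cohorts share one random graph: one hides the class
    signal in the three lowest-frequency Laplacian eigenmodes, the other in
    the three highest.  The 2-layer MLP probe on frequency-limited features
    saturates at small fractions for the former and stays at chance until
    almost all modes are kept for the latter.
    """
    from .spectral import spectral_basis

    rng = np.random.default_rng(seed)
    n_nodes, n_per_class, effect = 60, 600, 2.0
    graph = nx.gnp_random_graph(n_nodes, 8.0 / (n_nodes - 1), seed=int(seed) + 13)
    basis = spectral_basis(graph, nodelist=sorted(graph.nodes))
    fractions = [0.05, 0.1, 0.2, 0.4, 0.6, 0.8, 0.95, 1.0]

    low_x, low_y = _mode_signal_cohort(rng, basis.eigenvectors, [0, 1, 2], n_per_class, effect)
    high_x, high_y = _mode_signal_cohort(
        rng, basis.eigenvectors, [n_nodes - 3, n_nodes - 2, n_nodes - 1], n_per_class, effect
    )
    low = lowpass_profile(
        low_x, low_y, graph, fractions, nodelist=sorted(graph.nodes), seed=seed, alpha=1.0
    )
    high = lowpass_profile(
        high_x, high_y, graph, fractions, nodelist=sorted(graph.nodes), seed=seed, alpha=1.0
    )
    return {
        "fractions": fractions,
        "low_curve": low.accuracy.tolist(),
        "high_curve": high.accuracy.tolist(),
        "low_acc_at_0.1": float(low.accuracy[low.fraction == 0.1].iloc[0]),
        "low_acc_full": float(low.accuracy[low.fraction == 1.0].iloc[0]),
        "high_acc_below_0.8_max": float(high.accuracy[high.fraction <= 0.8].max()),
        "high_acc_full": float(high.accuracy[high.fraction == 1.0].iloc[0]),
        "chance_level": 0.5,
    }
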