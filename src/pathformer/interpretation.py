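"""Biomarker ranking, attention co-effect matrices and subset-overlap reports.

The selected genes of a trained model are its identified targets; their
ranking is by selection probability eps(v) averaged over samples (identical
to the lambda ranking when every gene is present in every sample, since eps
is a per-sample renormalization of the shared importance vector).  The
population co-effect of a gene pair averages the PAM attention weights over
samples and encoder layers; pairs co-selected in only part of the population
are averaged over their contributing (sample, layer) matrices, with coverage
counts reported, so rarely co-selected pairs are not deflated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .cohort_io import Sample, SignalingCohort
from .model import AttentionTrace, PathFormerModel
from .sortpool import select_top_k, selection_probabilities

__all__ = [
    "rank_biomarkers",
    "planted_enrichment_pvalue",
    "CoeffectMatrix",
    "coeffect_matrix",
    "subset_overlap",
    "nestedness_report",
]


def rank_biomarkers(
    model: PathFormerModel, samples: list[Sample] | None = None
) -> list[tuple[str, float, float]]:
    """Rank all universe genes by mean selection probability.

    Returns (gene, mean_eps, gda_score) sorted by mean_eps descending, ties
    broken by canonical order.  Genes absent from every sample get eps 0.
    """
    if samples is None:
        samples = model.cohort.samples
    universe = model.universe
    acc = np.zeros(len(universe))
    for present in {s.present_genes for s in samples}:
        rep = next(s for s in samples if s.present_genes == present)
        count = sum(1 for s in samples if s.present_genes == present)
        eps = selection_probabilities(model.selection, rep)
        for g, p in eps.items():
            acc[universe.h(g)] += p * count
    acc /= len(samples)
    order = np.lexsort((np.arange(len(universe)), -acc))
    return [(universe.genes[i], float(acc[i]), float(model.selection.e[i])) for i in order]


def planted_enrichment_pvalue(
    top_genes: set[str], planted: set[str], universe_size: int
) -> float:
    """Hypergeometric tail probability of >= |top & planted| planted genes in
    a draw of |top| from a universe containing |planted| planted genes."""
    overlap = len(top_genes & planted)
    return float(hypergeom.sf(overlap - 1, universe_size, len(planted), len(top_genes)))


@dataclass
class CoeffectMatrix:
    """Population co-effect alpha over gene pairs plus coverage counts."""

    genes: list[str]
    alpha: np.ndarray  # G x G, alpha[i, j] in [0, 1]
    coverage: np.ndarray  # G x G ints: contributing (sample, layer) pairs

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.alpha, index=self.genes, columns=self.genes)

    def symmetrized(self) -> "CoeffectMatrix":
        return CoeffectMatrix(
            genes=self.genes,
            alpha=(self.alpha + self.alpha.T) / 2.0,
            coverage=self.coverage + self.coverage.T,
        )


def coeffect_matrix(traces: list[AttentionTrace]) -> CoeffectMatrix:
    """Average attention over samples and layers into pairwise co-effects.

    alpha[i, j] = mean over contributing (sample, layer) matrices of the
    attention weight from gene i to gene j; a (sample, layer) contributes to
    pair (i, j) iff both genes were selected in that sample.  With every pair
    present everywhere this reduces to the plain 1/(N*L) average.
    """
    if not traces:
        raise ValueError("no attention traces given")
    genes = sorted({g for t in traces for g in t.subset})
    gi = {g: i for i, g in enumerate(genes)}
    n = len(genes)
    total = np.zeros((n, n))
    cover = np.zeros((n, n), dtype=int)
    for t in traces:
        idx = np.array([gi[g] for g in t.subset])
        for att in t.layers:
            total[np.ix_(idx, idx)] += att
            cover[np.ix_(idx, idx)] += 1
    with np.errstate(invalid="ignore"):
        alpha = np.where(cover > 0, total / np.maximum(cover, 1), 0.0)
    return CoeffectMatrix(genes=genes, alpha=alpha, coverage=cover)


def subset_overlap(
    subsets: dict[str, set[str]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise intersection sizes and Jaccard indices between gene subsets.

    `subsets` maps a dataset/run label to its gene set.  Returns (overlap
    counts, Jaccard) as labeled DataFrames.
    """
    if len(subsets) < 2:
        raise ValueError("need at least two subsets")
    labels = list(subsets)
    n = len(labels)
    counts = np.zeros((n, n), dtype=int)
    jac = np.zeros((n, n))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            inter = len(subsets[a] & subsets[b])
            union = len(subsets[a] | subsets[b])
            counts[i, j] = inter
            jac[i, j] = inter / union if union else 1.0
    return (
        pd.DataFrame(counts, index=labels, columns=labels),
        pd.DataFrame(jac, index=labels, columns=labels),
    )


def nestedness_report(model: PathFormerModel, ks: list[int], sample: Sample | None = None) -> pd.DataFrame:
    """Containment fractions between top-K subsets for ascending K.

    For one fixed trained importance vector the top-K lists are prefixes of a
    single sorted ranking, so every fraction is exactly 1.0; the report
    exists to quantify deviations when subsets come from separately trained
    models instead.
    """
    if sorted(ks) != list(ks):
        raise ValueError("ks must be ascending")
    if sample is None:
        sample = model.cohort.samples[0]
    state = model.selection
    subsets = {}
    for k in ks:
        old_k = state.k
        state.k = min(k, len(sample.present_genes))
        subsets[k] = set(select_top_k(state, sample))
        state.k = old_k
    rows = []
    for k_small, k_large in zip(ks[:-1], ks[1:]):
        inter = len(subsets[k_small] & subsets[k_large])
        rows.append(
            {
                "k_small": k_small,
                "k_large": k_large,
                "containment": inter / len(subsets[k_small]),
            }
        )
    return pd.DataFrame(rows)
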