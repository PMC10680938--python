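"""Knowledge-guided Disease-specific Sortpool (KD-Sortpool).

A single trainable importance score per gene in the universe S drives gene
selection for *every* sample: for sample n with present genes Vn, the
selection probability of gene v is

    eps(v) = lambda_h(v) / sum_{u in Vn} lambda_h(u),

where lambda = softplus(theta) is kept strictly positive by
reparameterization.  Selection is deliberately independent of expression
values — group-based expression statistics can point in opposite directions
across datasets of the same disease, whereas a shared importance vector
regularized toward prior gene-disease-association (GDA) knowledge yields
reproducible subsets.  The hard top-K of eps (ties broken by the canonical
order h) is the selected subset Sn, and

    A(Sn) = sum_{v in Sn} eps(v) * e(v)

estimates the expected association between the subset and the disease, with
e(v) the frozen GDA prior.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Parameter, Tensor
from .cohort_io import GdaTable, GeneUniverse, Sample

__all__ = ["SelectionState", "selection_probabilities", "select_top_k", "expected_association"]

# softplus(theta0) = 1: all genes a priori equally important
_THETA0 = float(np.log(np.expm1(1.0)))


class SelectionState:
    """Trainable selection state: theta over S, subset size K, GDA prior."""

    def __init__(self, universe: GeneUniverse, k: int, gda: GdaTable):
        if k < 1:
            raise ValueError("K must be >= 1")
        self.universe = universe
        self.k = int(k)
        self.gda = gda
        self.theta = Parameter(np.full(len(universe), _THETA0))
        # frozen prior e(v) in canonical order
        self.e = np.array([gda(g) for g in universe.genes])

    @property
    def lambda_imp(self) -> np.ndarray:
        """Current positive importance vector lambda = softplus(theta)."""
        return np.logaddexp(0.0, self.theta.data)

    def lambda_tensor(self) -> Tensor:
        return self.theta.softplus()

    def present_indices(self, sample: Sample) -> np.ndarray:
        """Indices h(v) of the sample's present genes, ascending."""
        if not sample.present_genes:
            raise ValueError(f"sample {sample.sample_id} has no present genes")
        return np.array(sorted(self.universe.h(g) for g in sample.present_genes), dtype=int)

    # -- differentiable path --------------------------------------------------
    def eps_tensor(self, sample: Sample) -> tuple[Tensor, np.ndarray]:
        """Selection probabilities over the present genes as an autodiff node.

        Returns (eps, idx) where eps[i] corresponds to universe index idx[i].
        """
        idx = self.present_indices(sample)
        lam = self.lambda_tensor()[idx]
        return lam / lam.sum(), idx


def selection_probabilities(state: SelectionState, sample: Sample) -> dict[str, float]:
    """eps(v) for every present gene of the sample (plain floats).

    Depends only on the importance vector and on *which* genes are present,
    never on expression values.
    """
    idx = state.present_indices(sample)
    lam = state.lambda_imp[idx]
    eps = lam / lam.sum()
    genes = state.universe.genes
    return {genes[i]: float(p) for i, p in zip(idx, eps)}


def select_top_k(state: SelectionState, sample: Sample) -> list[str]:
    """The ordered subset Sn: top-K genes by eps, ties broken by ascending h.

    Returns min(K, |Vn|) genes.  Deterministic: sorting is on the exact
    (eps, h) key, so reruns and platform changes cannot reorder the subset.
    """
    idx = state.present_indices(sample)
    lam = state.lambda_imp[idx]
    eps = lam / lam.sum()
    # descending eps, ascending h on ties
    order = np.lexsort((idx, -eps))
    k = min(state.k, idx.size)
    genes = state.universe.genes
    return [genes[idx[j]] for j in order[:k]]


def expected_association(state: SelectionState, sample: Sample, subset: list[str]) -> float:
    """A(Sn) = sum_{v in Sn} eps(v) e(v), in [0, 1]."""
    eps = selection_probabilities(state, sample)
    return float(sum(eps[g] * state.gda(g) for g in subset))
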