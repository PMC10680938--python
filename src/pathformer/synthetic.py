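"""Synthetic signaling cohorts with planted discriminative genes.

The generator emulates the structure of patient-cohort signaling-network
datasets: one interaction network shared by all samples, TPM-like positive
expression values, class labels, and a prior gene-disease-association (GDA)
table.  A chosen subset of *planted* genes carries a class-dependent mean
shift (in units of the noise SD, applied on the log scale before
exponentiation to TPM-like values) and an elevated GDA score, so both the
expression signal and the knowledge prior point at the same genes.  Every
quantity is reproducible from the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .cohort_io import GdaTable, Sample, SignalingCohort, canonical_order

__all__ = ["SimConfig", "generate_cohort", "permute_labels"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated cohort.

    effect_size is the between-class mean shift on planted genes, in SD units
    of the log-scale noise; gda_planted / gda_background are the GDA scores
    assigned to planted and background genes (each jittered by +/-0.02 and
    clipped to [0,1]).
    """

    n_genes: int = 300
    n_samples_per_class: int = 100
    n_classes: int = 2
    mean_degree: float = 25.0
    n_planted: int = 20
    effect_size: float = 1.5
    gda_planted: float = 0.9
    gda_background: float = 0.05
    noise_sd: float = 1.0
    seed: int = 0
    topology: str = "er"  # or "ba" (preferential attachment)
    dropout_genes: float = 0.0  # per-sample probability of hiding a gene

    def validate(self) -> None:
        if self.n_genes < 2:
            raise ValueError("n_genes must be >= 2")
        if not 0 < self.n_planted <= self.n_genes:
            raise ValueError("n_planted must satisfy 0 < n_planted <= n_genes")
        if not 0 < self.mean_degree < self.n_genes - 1:
            raise ValueError("mean_degree must satisfy 0 < mean_degree < n_genes - 1")
        for name in ("gda_planted", "gda_background", "dropout_genes"):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} must lie in [0,1], got {x}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        if self.topology not in ("er", "ba"):
            raise ValueError("topology must be 'er' or 'ba'")


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n - 1)))
    return [f"G{i:0{width}d}" for i in range(n)]


def _draw_edges(rng: np.random.Generator, cfg: SimConfig) -> set[frozenset[str]]:
    names = _gene_names(cfg.n_genes)
    edges: set[frozenset[str]] = set()
    if cfg.topology == "er":
        # G(n, p) with p chosen so the expected degree is mean_degree
        p = cfg.mean_degree / (cfg.n_genes - 1)
        iu, ju = np.triu_indices(cfg.n_genes, k=1)
        keep = rng.random(iu.size) < p
        for i, j in zip(iu[keep], ju[keep]):
            edges.add(frozenset((names[i], names[j])))
    else:
        # preferential attachment with m = mean_degree/2 edges per new node
        m = max(1, int(round(cfg.mean_degree / 2)))
        targets = list(range(m))
        repeated: list[int] = list(range(m))
        for new in range(m, cfg.n_genes):
            for t in targets:
                edges.add(frozenset((names[new], names[t])))
                repeated.extend((new, t))
            targets = list(rng.choice(repeated, size=m, replace=False))
    return edges


def generate_cohort(config: SimConfig) -> tuple[SignalingCohort, GdaTable, frozenset[str]]:
    """Generate a cohort; returns (cohort, gda_table, planted_gene_set).

    Expression model per gene g and sample n of class c:
    ``TPM = exp(mu_cg + noise)`` with ``noise ~ N(0, noise_sd^2)`` and
    ``mu_cg = c * effect_size * noise_sd`` for planted genes, 0 otherwise.
    Because the classifier front-end applies a monotone log transform, the
    learning problem is equivalent to the additive Gaussian one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    names = _gene_names(config.n_genes)
    universe = canonical_order(names)

    edges = _draw_edges(rng, config)
    planted = frozenset(rng.choice(names, size=config.n_planted, replace=False).tolist())

    # GDA: enriched on planted genes, near-zero elsewhere, jitter +/-0.02
    scores = {}
    for g in names:
        base = config.gda_planted if g in planted else config.gda_background
        scores[g] = float(np.clip(base + rng.uniform(-0.02, 0.02), 0.0, 1.0))
    gda = GdaTable(scores=scores)

    n_per = config.n_samples_per_class
    samples: list[Sample] = []
    class_names = [f"class{c}" for c in range(config.n_classes)]
    planted_mask = np.array([g in planted for g in names])
    for c in range(config.n_classes):
        shift = np.where(planted_mask, c * config.effect_size * config.noise_sd, 0.0)
        for i in range(n_per):
            log_expr = shift + rng.normal(0.0, config.noise_sd, size=config.n_genes)
            tpm = np.exp(log_expr)
            if config.dropout_genes > 0:
                visible = rng.random(config.n_genes) >= config.dropout_genes
                if not visible.any():
                    visible[rng.integers(config.n_genes)] = True
            else:
                visible = np.ones(config.n_genes, dtype=bool)
            expression = {g: float(t) for g, t, vis in zip(names, tpm, visible) if vis}
            samples.append(
                Sample(
                    sample_id=f"S{c}_{i:04d}",
                    present_genes=frozenset(expression),
                    expression=expression,
                    label=c,
                )
            )

    cohort = SignalingCohort(
        universe=universe, edges=frozenset(edges), samples=samples, class_names=class_names
    )
    return cohort, gda, planted


def permute_labels(cohort: SignalingCohort, seed: int) -> SignalingCohort:
    """Return a copy of the cohort with labels randomly permuted across samples.

    Class counts are preserved; expression, network and sample order are
    untouched.  This is the null-control construction: any classifier's
    cross-validated accuracy on the permuted cohort should be at chance.
    """
    rng = np.random.default_rng(seed)
    labels = [s.label for s in cohort.samples]
    perm = rng.permutation(len(labels))
    new_samples = [
        dataclasses.replace(s, label=labels[perm[i]]) for i, s in enumerate(cohort.samples)
    ]
    return SignalingCohort(
        universe=cohort.universe,
        edges=cohort.edges,
        samples=new_samples,
        class_names=list(cohort.class_names),
    )
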