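"""Data model and file I/O for gene signaling-network cohorts.

A cohort couples a shared, undirected gene-gene interaction network with
per-sample gene expression vectors and class labels.  The central objects are

* :class:`GeneUniverse` — the ordered global gene set ``S`` with the canonical
  (lexicographic) order function ``h``;
* :class:`SignalingCohort` — shared edge set plus per-sample data; every
  sample's network is the subgraph of the shared network induced by the
  sample's present genes (the *shared-connection* property of signaling
  networks: an interaction between two genes holds in every sample where both
  genes are measured);
* :class:`GdaTable` — prior gene-disease-association scores in ``[0, 1]``
  (DisGeNET GDA-score convention); unlisted genes score 0.

File formats are plain TSV/whitespace text: an expression matrix
(genes x samples, TPM), a two-column edge list, a two-column GDA table and a
two-column sample-label table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneUniverse",
    "Sample",
    "SignalingCohort",
    "GdaTable",
    "canonical_order",
    "load_cohort",
    "write_cohort",
    "write_gene_ranking",
    "read_gene_ranking",
    "ExpressionTransform",
]


def _norm(symbol: str) -> str:
    """Case-normalize a gene symbol (interaction/GDA databases vary in case)."""
    return symbol.strip().upper()


@dataclass(frozen=True)
class GeneUniverse:
    """The ordered global gene set S with canonical order function h.

    ``h(v)`` is the rank of gene ``v`` in the byte-wise lexicographic sort of
    the (uppercased) symbols — a bijection onto ``{0, ..., |S|-1}`` that is
    identical across runs and platforms.
    """

    genes: tuple[str, ...]
    order: Mapping[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.genes)

    def h(self, gene: str) -> int:
        return self.order[gene]

    def __contains__(self, gene: str) -> bool:
        return gene in self.order


def canonical_order(gene_symbols: Iterable[str]) -> GeneUniverse:
    """Build the gene universe with h = rank in lexicographic symbol order.

    Symbols are uppercased and deduplicated first.  Raises ``ValueError`` on
    an empty gene set.
    """
    genes = sorted({_norm(g) for g in gene_symbols if _norm(g)})
    if not genes:
        raise ValueError("empty gene set")
    return GeneUniverse(genes=tuple(genes), order={g: i for i, g in enumerate(genes)})


@dataclass
class Sample:
    """One patient/sample: present genes Vn, TPM expression on Vn, class label."""

    sample_id: str
    present_genes: frozenset[str]
    expression: dict[str, float]
    label: int

    def validate(self, universe: GeneUniverse) -> None:
        if set(self.expression) != set(self.present_genes):
            raise ValueError(
                f"sample {self.sample_id}: expression keys must equal present genes"
            )
        for g, x in self.expression.items():
            if g not in universe:
                raise ValueError(f"sample {self.sample_id}: gene {g} not in universe")
            if x < 0 or not np.isfinite(x):
                raise ValueError(f"sample {self.sample_id}: negative/non-finite TPM for {g}")


@dataclass
class SignalingCohort:
    """Shared interaction network + per-sample expression and labels."""

    universe: GeneUniverse
    edges: frozenset[frozenset[str]]
    samples: list[Sample]
    class_names: list[str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for e in self.edges:
            if len(e) != 2:
                raise ValueError("self-loop or malformed edge")
            for g in e:
                if g not in self.universe:
                    raise ValueError(f"edge endpoint {g} not in universe")
        for s in self.samples:
            s.validate(self.universe)
            if not 0 <= s.label < len(self.class_names):
                raise ValueError(f"sample {s.sample_id}: label out of range")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=int)

    def induced_edges(self, sample: Sample) -> frozenset[frozenset[str]]:
        """Edge set of the sample's network: global edges restricted to Vn."""
        pg = sample.present_genes
        return frozenset(e for e in self.edges if all(g in pg for g in e))


@dataclass(frozen=True)
class GdaTable:
    """Gene-disease-association scores in [0,1]; missing genes score 0."""

    scores: Mapping[str, float]

    def __post_init__(self) -> None:
        for g, s in self.scores.items():
            if not 0.0 <= s <= 1.0:
                raise ValueError(f"GDA score for {g} outside [0,1]: {s}")

    def __call__(self, gene: str) -> float:
        return self.scores.get(_norm(gene), 0.0)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_edges(edge_path: str | Path) -> set[frozenset[str]]:
    edges: set[frozenset[str]] = set()
    n_lines = 0
    with open(edge_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"malformed edge line: {line!r}")
            u, v = _norm(parts[0]), _norm(parts[1])
            if u == v:
                continue  # self-loops are dropped
            n_lines += 1
            edges.add(frozenset((u, v)))
    if n_lines > len(edges):
        logger.warning(
            "edge file %s: %d duplicate/reciprocal edge lines deduplicated",
            edge_path,
            n_lines - len(edges),
        )
    return edges


def load_cohort(
    expression_path: str | Path,
    edge_path: str | Path,
    gda_path: str | Path,
    label_path: str | Path,
) -> tuple[SignalingCohort, GdaTable]:
    """Load a cohort from its four text files.

    The gene universe is the union of expression-matrix genes and edge
    endpoints; edges are symmetrized and deduplicated; class labels are mapped
    to contiguous indices in sorted class-name order.  A labeled sample absent
    from the expression matrix is an error.
    """
    expr = pd.read_csv(expression_path, sep="\t", index_col=0)
    expr.index = [_norm(g) for g in expr.index.astype(str)]
    expr.columns = expr.columns.astype(str)

    edges = _read_edges(edge_path)

    gda_df = pd.read_csv(gda_path, sep="\t", header=None, names=["gene", "score"], comment="#")
    gda = GdaTable(scores={_norm(g): float(s) for g, s in zip(gda_df.gene, gda_df.score)})

    lab_df = pd.read_csv(label_path, sep="\t", header=None, names=["sample_id", "class_name"])
    lab_df.sample_id = lab_df.sample_id.astype(str)
    missing = set(lab_df.sample_id) - set(expr.columns)
    if missing:
        raise ValueError(f"labeled samples missing from expression matrix: {sorted(missing)}")

    class_names = sorted(set(lab_df.class_name.astype(str)))
    class_index = {c: i for i, c in enumerate(class_names)}

    edge_genes = {g for e in edges for g in e}
    universe = canonical_order(list(expr.index) + sorted(edge_genes))

    samples = []
    for sid, cname in zip(lab_df.sample_id, lab_df.class_name.astype(str)):
        col = expr[sid]
        expression = {g: float(x) for g, x in col.items() if np.isfinite(x)}
        samples.append(
            Sample(
                sample_id=sid,
                present_genes=frozenset(expression),
                expression=expression,
                label=class_index[cname],
            )
        )

    cohort = SignalingCohort(
        universe=universe,
        edges=frozenset(edges),
        samples=samples,
        class_names=class_names,
    )
    return cohort, gda


def write_cohort(
    cohort: SignalingCohort,
    gda: GdaTable,
    out_dir: str | Path,
    prefix: str = "cohort",
) -> dict[str, Path]:
    """Write the four cohort text files; returns the paths keyed by role."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / f"{prefix}_expression.tsv",
        "edges": out / f"{prefix}_edges.txt",
        "gda": out / f"{prefix}_gda.tsv",
        "labels": out / f"{prefix}_labels.tsv",
    }

    sample_ids = [s.sample_id for s in cohort.samples]
    mat = pd.DataFrame(
        {s.sample_id: pd.Series(s.expression) for s in cohort.samples},
        columns=sample_ids,
    )
    mat = mat.reindex(sorted(mat.index))
    mat.index.name = "gene"
    mat.to_csv(paths["expression"], sep="\t", float_format="%.17g")

    with open(paths["edges"], "w") as fh:
        for u, v in sorted(tuple(sorted(e)) for e in cohort.edges):
            fh.write(f"{u}\t{v}\n")

    with open(paths["gda"], "w") as fh:
        for g in sorted(gda.scores):
            fh.write(f"{g}\t{gda.scores[g]:.17g}\n")

    with open(paths["labels"], "w") as fh:
        for s in cohort.samples:
            fh.write(f"{s.sample_id}\t{cohort.class_names[s.label]}\n")

    return paths


def write_gene_ranking(
    path: str | Path,
    ranking: Sequence[tuple[str, float]],
    universe: GeneUniverse | None = None,
    gda: GdaTable | None = None,
) -> None:
    """Write a biomarker ranking TSV: gene, epsilon_score, rank, gda_score.

    Sorted by score descending; ties broken by canonical order h (or
    lexicographically when no universe is given — identical outcome).
    """
    for g, s in ranking:
        if not np.isfinite(s):
            raise ValueError(f"non-finite score for gene {g}")
    key = (lambda gs: (-gs[1], universe.h(gs[0]))) if universe else (lambda gs: (-gs[1], gs[0]))
    ordered = sorted(ranking, key=key)
    with open(path, "w") as fh:
        fh.write("gene\tepsilon_score\trank\tgda_score\n")
        for rank, (g, s) in enumerate(ordered, start=1):
            e = gda(g) if gda is not None else 0.0
            fh.write(f"{g}\t{s:.10g}\t{rank}\t{e:.10g}\n")


def read_gene_ranking(path: str | Path) -> list[tuple[str, float]]:
    df = pd.read_csv(path, sep="\t")
    return [(str(g), float(s)) for g, s in zip(df.gene, df.epsilon_score)]


# ---------------------------------------------------------------------------
# expression transform
# ---------------------------------------------------------------------------


class ExpressionTransform:
    """``log2(1+TPM)`` then optional per-gene z-scoring fit on training samples.

    ``kind`` is one of ``none`` (raw TPM), ``log2p1``, ``zscore``
    (log2p1 followed by per-gene standardization).  Statistics are estimated
    with :meth:`fit` on training samples only and reused at inference, so no
    test-set information leaks into the transform.
    """

    def __init__(self, kind: str = "log2p1"):
        if kind not in ("none", "log2p1", "zscore"):
            raise ValueError(f"unknown expression transform {kind!r}")
        self.kind = kind
        self.mean_: dict[str, float] = {}
        self.std_: dict[str, float] = {}

    def fit(self, samples: Sequence[Sample]) -> "ExpressionTransform":
        if self.kind != "zscore":
            return self
        acc: dict[str, list[float]] = {}
        for s in samples:
            for g, x in s.expression.items():
                acc.setdefault(g, []).append(np.log2(1.0 + x))
        for g, xs in acc.items():
            arr = np.asarray(xs)
            self.mean_[g] = float(arr.mean())
            sd = float(arr.std())
            self.std_[g] = sd if sd > 0 else 1.0
        return self

    def __call__(self, gene: str, tpm: float) -> float:
        if self.kind == "none":
            return float(tpm)
        x = float(np.log2(1.0 + tpm))
        if self.kind == "log2p1":
            return x
        return (x - self.mean_.get(gene, 0.0)) / self.std_.get(gene, 1.0)
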