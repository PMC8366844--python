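"""Phylogenetic eigenvector regression (PVR) support.

A phylogeny with branch lengths induces a patristic distance matrix between
species.  Principal coordinates analysis (PCoA) of that matrix yields
orthogonal axes — phylogenetic eigenvectors (PV1, PV2, ...) — whose scores
can be used as species-level covariates that absorb phylogenetic similarity.
The broken-stick null spectrum decides how many leading axes carry more
structure than expected by chance.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "DistanceMatrix",
    "EigenvectorSet",
    "patristic_distances",
    "pcoa",
    "broken_stick",
    "pv_design",
]


@dataclass
class DistanceMatrix:
    """Square patristic distance matrix in branch-length units."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if v.shape[0] != len(self.labels):
            raise ValueError("label count does not match matrix size")
        if not np.all(np.isfinite(v)):
            raise ValueError("distance matrix contains non-finite entries")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have a zero diagonal")
        self.values = v

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class EigenvectorSet:
    """PCoA decomposition of a distance matrix.

    ``vectors`` holds coordinates for the positive-eigenvalue axes, scaled so
    each column's sum of squares equals its eigenvalue.  ``eigenvalues``
    retains the full spectrum (descending); ``relative_eigenvalues`` are the
    positive eigenvalues divided by their sum.  ``retained`` are the indices
    (0-based) of axes kept by the broken-stick rule.
    """

    labels: list[str]
    eigenvalues: np.ndarray
    relative_eigenvalues: np.ndarray
    vectors: np.ndarray
    retained: list[int] = field(default_factory=list)
    cumulative_variance_retained: float = 0.0

    @property
    def n_positive(self) -> int:
        return self.vectors.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"PV{k + 1}": self.vectors[:, k] for k in range(self.n_positive)}
        return pd.DataFrame(cols, index=pd.Index(self.labels, name="species_id"))

    def eigenvalue_table(self) -> pd.DataFrame:
        npos = len(self.relative_eigenvalues)
        bs = _broken_stick_expectations(npos) if npos else np.array([])
        return pd.DataFrame(
            {
                "axis": np.arange(1, npos + 1),
                "eigenvalue": self.eigenvalues[:npos],
                "relative_eigenvalue": self.relative_eigenvalues,
                "broken_stick_expectation": bs,
                "retained": [k in self.retained for k in range(npos)],
            }
        )


def read_newick(source: str) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    if source.strip().startswith("("):
        return dendropy.Tree.get(data=source, schema="newick")
    return dendropy.Tree.get(path=source, schema="newick")


def patristic_distances(tree: dendropy.Tree | str) -> DistanceMatrix:
    """Pairwise path-length distances between the leaves of ``tree``.

    Entry (a, b) is the sum of branch lengths along the unique path joining
    leaves a and b.  Labels are sorted for a deterministic ordering.
    """
    if isinstance(tree, str):
        tree = read_newick(tree)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a missing branch length")
        if edge.length < 0:
            raise ValueError("tree has a negative branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(pdm.taxon_iter(), key=lambda t: t.label)
    labels = [t.label for t in taxa]
    if len(set(labels)) != len(labels):
        raise ValueError("leaf labels are not unique")
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=labels, values=values)


def pcoa(dm: DistanceMatrix, eig_tol: float = 1e-10) -> EigenvectorSet:
    """Principal coordinates analysis via Gower double centering.

    The matrix ``-D**2 / 2`` is double-centered and eigendecomposed; axes are
    ordered by descending eigenvalue.  Coordinates are eigenvectors scaled by
    the square root of their eigenvalue, so squared Euclidean distances over
    all positive axes reconstruct ``D**2`` when D is metric (tree distances
    are).  Each column's sign is fixed so its largest-magnitude loading is
    positive.
    """
    d = dm.values
    n = dm.n
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    b = a - row - col + a.mean()
    eigval, eigvec = scipy.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]

    scale = max(abs(eigval[0]), 1.0) if n else 1.0
    positive = eigval > eig_tol * scale
    npos = int(positive.sum())
    coords = eigvec[:, :npos] * np.sqrt(eigval[:npos])
    # eigenvector sign is arbitrary; pin it for determinism
    for k in range(npos):
        i = np.argmax(np.abs(coords[:, k]))
        if coords[i, k] < 0:
            coords[:, k] = -coords[:, k]
    pos_sum = eigval[:npos].sum()
    rel = eigval[:npos] / pos_sum if npos else np.array([])

    es = EigenvectorSet(
        labels=list(dm.labels),
        eigenvalues=eigval,
        relative_eigenvalues=rel,
        vectors=coords,
    )
    es.retained = broken_stick(rel) if npos else []
    es.cumulative_variance_retained = float(rel[es.retained].sum()) if es.retained else 0.0
    return es


def _broken_stick_expectations(s: int) -> np.ndarray:
    """b_k = (1/S) * sum_{i=k..S} 1/i, the expected share of stick piece k."""
    inv = 1.0 / np.arange(1, s + 1)
    return np.cumsum(inv[::-1])[::-1] / s


def broken_stick(relative_eigenvalues: np.ndarray) -> list[int]:
    """Leading run of axes whose relative eigenvalue exceeds the broken-stick share.

    Retention stops at the first axis k with lambda_k_rel <= b_k, so the
    retained set is always a contiguous block starting at axis 1 (possibly
    empty).
    """
    rel = np.asarray(relative_eigenvalues, dtype=float)
    if rel.size == 0:
        raise ValueError("empty eigenvalue vector")
    b = _broken_stick_expectations(rel.size)
    retained: list[int] = []
    for k in range(rel.size):
        if rel[k] > b[k]:
            retained.append(k)
        else:
            break
    return retained


def pv_design(
    es: EigenvectorSet,
    n_axes: int | None = None,
    species_order: list[str] | None = None,
) -> pd.DataFrame:
    """Species-by-axis matrix of PV scores aligned to ``species_order``.

    ``n_axes=None`` uses the broken-stick retention; ``n_axes=0`` yields an
    empty design (body-mass-only species regression).
    """
    if n_axes is None:
        n_axes = len(es.retained)
    if n_axes > es.n_positive:
        raise ValueError(
            f"requested {n_axes} axes but only {es.n_positive} positive axes exist"
        )
    frame = es.to_frame().iloc[:, :n_axes]
    if species_order is not None:
        missing = set(species_order) - set(es.labels)
        if missing:
            raise ValueError(f"species absent from the tree: {sorted(missing)}")
        frame = frame.loc[species_order]
    return frame
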