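"""Allele-allele similarity from pseudo-sequences and from E-score profiles.

Alleles are compared two ways: (i) by their 34-residue binding-cleft
pseudo-sequences under BLOSUM62, and (ii) functionally, by the cosine
distance between their E-score vectors over a shared peptide pool.  The
functional distances feed hierarchical clustering and a 2-D UMAP embedding.

Note on the pseudo-sequence measure: the printed form
1 - sum(sim12) / (sum(sim11) * sum(sim22)) has a product (not root-product)
denominator, so even identical sequences get a nonzero value.  Both that
form (``as_printed``) and the cosine-style root-product normalization
(``sqrt_normalized``, self-distance zero) are provided; outputs are named
distances since larger values mean less similar.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

PSEUDO_LENGTH = 34

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def blosum62(a: str, b: str) -> float:
    return float(_BLOSUM62[a, b])


def sequence_similarity(s1: str, s2: str, mode: str = "sqrt_normalized"
                        ) -> float:
    """BLOSUM62-normalized distance between two 34-mer pseudo-sequences."""
    for s in (s1, s2):
        if len(s) != PSEUDO_LENGTH:
            raise ValueError(
                f"pseudo-sequence must be {PSEUDO_LENGTH} residues, got {len(s)}")
    try:
        s12 = sum(blosum62(a, b) for a, b in zip(s1, s2))
        s11 = sum(blosum62(a, a) for a in s1)
        s22 = sum(blosum62(a, a) for a in s2)
    except IndexError as exc:
        raise ValueError("residue outside the BLOSUM62 alphabet") from exc
    if mode == "as_printed":
        return 1.0 - s12 / (s11 * s22)
    if mode == "sqrt_normalized":
        return 1.0 - s12 / np.sqrt(s11 * s22)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class DistanceMatrix:
    alleles: list
    values: np.ndarray
    metric: str = "cosine"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.alleles), len(self.alleles)):
            raise ValueError("distance matrix shape does not match allele list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.alleles,
                            columns=self.alleles)


def pseudo_sequence_distances(pseudo: pd.DataFrame | dict,
                              mode: str = "sqrt_normalized") -> DistanceMatrix:
    """All-pairs pseudo-sequence distances (TSV columns: allele, pseudo)."""
    if isinstance(pseudo, pd.DataFrame):
        pseudo = dict(zip(pseudo["allele"], pseudo["pseudo"]))
    alleles = list(pseudo)
    n = len(alleles)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            d = sequence_similarity(pseudo[alleles[i]], pseudo[alleles[j]],
                                    mode=mode)
            out[i, j] = out[j, i] = d
    return DistanceMatrix(alleles=alleles, values=out, metric=f"blosum62_{mode}")


def escore_cosine_distances(escores: pd.DataFrame) -> DistanceMatrix:
    """Cosine distances between allele E-score profiles.

    ``escores`` is a peptides x alleles frame.  Alleles whose profile is
    all-zero (cosine undefined) are excluded with a warning.
    """
    mat = escores.to_numpy(dtype=float).T  # alleles x peptides
    alleles = list(escores.columns)
    norms = np.linalg.norm(np.nan_to_num(mat), axis=1)
    keep = norms > 0
    if not keep.all():
        dropped = [a for a, k in zip(alleles, keep) if not k]
        warnings.warn(f"alleles with all-zero profiles excluded: {dropped}")
        mat = mat[keep]
        alleles = [a for a, k in zip(alleles, keep) if k]
    mat = np.nan_to_num(mat)
    dist = squareform(pdist(mat, metric="cosine"))
    np.fill_diagonal(dist, 0.0)
    return DistanceMatrix(alleles=alleles, values=dist, metric="cosine")


def embed_2d(distances: DistanceMatrix, n_neighbors: int = 5,
             min_dist: float = 0.01, seed: int = 42) -> pd.DataFrame:
    """2-D UMAP embedding of alleles from a precomputed distance matrix."""
    import umap  # deferred: heavy import

    n = len(distances.alleles)
    if n < n_neighbors + 1:
        raise ValueError(
            f"need at least {n_neighbors + 1} alleles for n_neighbors={n_neighbors}")
    reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                        min_dist=min_dist, random_state=seed,
                        metric="precomputed")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = reducer.fit_transform(distances.values)
    return pd.DataFrame({"allele": distances.alleles,
                         "x": coords[:, 0], "y": coords[:, 1]})


@dataclass
class ClusterOrder:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    display_matrix: pd.DataFrame


def cluster_heatmap_order(escores: pd.DataFrame, threshold: float = 3.8,
                          clip: tuple[float, float] = (2.0, 5.0),
                          method: str = "average") -> ClusterOrder:
    """Hierarchical ordering of a peptides x alleles E-score matrix.

    Peptides lacking any above-threshold score are removed; values are
    clipped to the display range (default [2, 5]); rows and columns are
    clustered on cosine distance and leaf orders returned.
    """
    keep = (escores > threshold).any(axis=1)
    filtered = escores.loc[keep]
    if filtered.empty:
        raise ValueError("no peptide has an above-threshold score")
    display = filtered.clip(lower=clip[0], upper=clip[1])
    row_link = hierarchy.linkage(pdist(filtered.to_numpy(), metric="cosine"),
                                 method=method)
    col_link = hierarchy.linkage(pdist(filtered.to_numpy().T, metric="cosine"),
                                 method=method)
    row_order = [filtered.index[i] for i in hierarchy.leaves_list(row_link)]
    col_order = [filtered.columns[i] for i in hierarchy.leaves_list(col_link)]
    return ClusterOrder(row_order=row_order, col_order=col_order,
                        row_linkage=row_link, col_linkage=col_link,
                        display_matrix=display)
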