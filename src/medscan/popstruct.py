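"""Kinship, principal-coordinate analysis and eigenvector phenotypes.

Population structure enters the association model twice: as fixed
principal components and as a kinship-structured random effect.  The
same decomposition supplies the eigenvector phenotypes scanned to find
loci driving subpopulation differentiation: an accession's score on a
leading axis summarises its ancestry, so markers associated with that
score are markers whose frequencies separate the subpopulations.

Kinship uses the centred-dosage cross-product (trace-normalised
``centered_ibs`` by default, or the classical ``vanraden`` scaling);
PCoA is classical metric scaling of the squared allele-sharing distance
1 - IBS.  Missing calls are mean-imputed per marker for these
computations only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh

from .genio import GenotypeMatrix


@dataclass
class KinshipMatrix:
    values: np.ndarray
    accession_ids: list[str]
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.accession_ids,
                            columns=self.accession_ids)


@dataclass
class PcoaResult:
    eigenvectors: np.ndarray       # accession x axis scores (scaled by sqrt(eigenvalue))
    eigenvalues: np.ndarray        # sorted non-increasing
    accession_ids: list[str]

    @property
    def pct_variance(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0].sum()
        if pos <= 0:
            return np.zeros_like(self.eigenvalues)
        return 100.0 * np.where(self.eigenvalues > 0, self.eigenvalues, 0.0) / pos

    def scores_frame(self, k: int | None = None) -> pd.DataFrame:
        k = k or self.eigenvectors.shape[1]
        return pd.DataFrame(self.eigenvectors[:, :k], index=self.accession_ids,
                            columns=[f"axis{i + 1}" for i in range(k)])


def kinship(G: GenotypeMatrix, method: str = "centered_ibs") -> KinshipMatrix:
    """Genomic relationship matrix from centred additive dosages.

    ``centered_ibs``: K = WW' / (trace(WW')/n), mean diagonal 1.
    ``vanraden``: K = WW' / (2 * sum p(1-p)) with p the alternate-allele
    frequency.  Both are symmetric PSD by construction.
    """
    if G.n_markers == 0:
        raise ValueError("kinship of a zero-marker matrix")
    X = G.dosage()
    p = X.mean(axis=0) / 2.0
    W = X - 2.0 * p
    XXt = W @ W.T
    if method == "centered_ibs":
        denom = np.trace(XXt) / G.n_accessions
        if denom <= 0:
            denom = 1.0
    elif method == "vanraden":
        denom = 2.0 * np.sum(p * (1.0 - p))
        if denom <= 0:
            denom = 1.0
    else:
        raise ValueError(f"unknown kinship method {method!r}")
    K = XXt / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(K, list(G.accession_ids), method)


def ibs_distance(G: GenotypeMatrix) -> np.ndarray:
    """1 - allele-sharing proportion between accession pairs.

    IBS between two accessions at one marker is (2 - |g_i - g_j|)/2 in
    allele-sharing units; the distance averages 1 - IBS over markers.
    """
    X = G.dosage()
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        D[i] = np.abs(X - X[i]).mean(axis=1) / 2.0
    return (D + D.T) / 2.0


def pcoa(dist_or_G, accession_ids=None) -> PcoaResult:
    """Classical scaling (metric MDS) of a squared distance matrix.

    Accepts a GenotypeMatrix (allele-sharing distance computed first) or a
    precomputed square distance matrix.  Double-centres -D^2/2 and
    eigen-decomposes; axis scores are eigenvectors scaled by
    sqrt(eigenvalue), each axis oriented so the first accession's loading
    is non-negative.
    """
    if isinstance(dist_or_G, GenotypeMatrix):
        D = ibs_distance(dist_or_G)
        accession_ids = list(dist_or_G.accession_ids)
    else:
        D = np.asarray(dist_or_G, float)
        if accession_ids is None:
            accession_ids = [f"obs{i + 1}" for i in range(D.shape[0])]
    n = D.shape[0]
    if n < 2:
        raise ValueError("PCoA needs at least two accessions")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    B = (B + B.T) / 2.0
    vals, vecs = eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    vals[np.abs(vals) < 1e-10] = 0.0
    scores = vecs * np.sqrt(np.clip(vals, 0.0, None))
    # reproducible orientation: first accession loads non-negatively
    flip = scores[0, :] < 0
    scores[:, flip] = -scores[:, flip]
    return PcoaResult(scores, vals, list(accession_ids))


def eigen_phenotypes(p: PcoaResult, k: int = 5) -> pd.DataFrame:
    """TraitTable of the top-k PCoA axis scores, named eigen1..eigenk."""
    if k <= 0:
        raise ValueError("k must be positive")
    n_pos = int((p.eigenvalues > 0).sum())
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the {n_pos} positive axes")
    return pd.DataFrame(
        p.eigenvectors[:, :k], index=p.accession_ids,
        columns=[f"eigen{i + 1}" for i in range(k)])


def pca_covariates(G: GenotypeMatrix, n_pcs: int = 6) -> pd.DataFrame:
    """Fixed-effect principal components from centred dosages (SVD scores)."""
    X = G.dosage()
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    scores = U[:, :n_pcs] * s[:n_pcs]
    for j in range(scores.shape[1]):
        if scores[0, j] < 0:
            scores[:, j] = -scores[:, j]
    return pd.DataFrame(scores, index=G.accession_ids,
                        columns=[f"PC{i + 1}" for i in range(scores.shape[1])])
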