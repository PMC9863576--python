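"""Mixed-linear-model association scans (PCA + K) for three trait families.

The engine fits, per trait, the null mixed model

    y = X beta + g + e,   g ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I)

with X an intercept plus fixed principal components and K a kinship
matrix, by REML profiled over the variance ratio via a single
eigen-decomposition of K.  Under the default P3D strategy the null
variance components are reused for every marker: the phenotype, the
covariates and each marker dosage are whitened by V^{-1/2} and the
marker term is tested with an exact F-test in the transformed model.
Markers whose whitened dosage is constant (monomorphic after imputation
or collinear with the covariates) are skipped and counted.

Three scan families share the engine and differ only in their phenotypes:
P (phenology BLUPs), C (climate variables of the country of origin) and
E (PCoA eigenvectors); for family E the fixed-PC set drops the component
matching the eigenvector under test so an axis is never regressed on
itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .genio import GenotypeMatrix
from .popstruct import KinshipMatrix

TRAIT_CLASSES = ("P", "C", "E")


@dataclass
class AssocConfig:
    n_pcs_fixed: int = 6
    threshold_logp: float = 3.0
    p3d: bool = True
    compression_groups: int | None = None
    drop_collinear_pc_for_eigen: bool = True

    def __post_init__(self) -> None:
        if self.threshold_logp <= 0:
            raise ValueError("threshold_logp must be positive")
        if self.n_pcs_fixed < 0:
            raise ValueError("n_pcs_fixed must be >= 0")


@dataclass
class Mta:
    """One marker-trait association above the significance threshold."""

    marker_id: str
    chromosome: str | None
    cm: float | None
    bp: float | None
    trait_name: str
    trait_class: str
    minus_log10_p: float
    r2: float
    effect: float


def mtas_to_frame(mtas: Sequence[Mta]) -> pd.DataFrame:
    return pd.DataFrame([vars(m) for m in mtas],
                        columns=["marker_id", "chromosome", "cm", "bp", "trait_name",
                                 "trait_class", "minus_log10_p", "r2", "effect"])


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    loglik: float
    # cached spectral pieces for P3D reuse
    eigenvalues: np.ndarray = field(repr=False, default=None)
    rotation: np.ndarray = field(repr=False, default=None)

    @property
    def ratio(self) -> float:
        return self.sigma_g2 / self.sigma_e2 if self.sigma_e2 > 0 else np.inf


@dataclass
class ScanResult:
    """Thresholded associations plus per-marker diagnostics."""

    mtas: list[Mta]
    table: pd.DataFrame            # all markers: p, minus_log10_p, r2, effect, skip
    n_skipped: int

    def __iter__(self) -> Iterator[Mta]:
        return iter(self.mtas)

    def __len__(self) -> int:
        return len(self.mtas)


def _reml_loglik(log_gamma: float, y_r: np.ndarray, X_r: np.ndarray,
                 D: np.ndarray) -> float:
    gamma = 10.0 ** log_gamma
    w = gamma * D + 1.0
    n, p = X_r.shape
    Xw = X_r / w[:, None]
    XtWX = X_r.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ y_r)
    r = y_r - X_r @ beta
    rss = r @ (r / w)
    sign, logdet_x = np.linalg.slogdet(XtWX)
    if sign <= 0 or rss <= 0:
        return -np.inf
    sigma_e2 = rss / (n - p)
    return -0.5 * ((n - p) * np.log(2.0 * np.pi * sigma_e2) + np.log(w).sum()
                   + logdet_x + (n - p))


def _check_K(K: np.ndarray) -> None:
    vals = np.linalg.eigvalsh((K + K.T) / 2.0)
    if vals.min() < -1e-6 * max(vals.max(), 1.0):
        raise ValueError("kinship matrix is not positive semi-definite")


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, float)


def fit_null_mlm(y: np.ndarray | pd.Series, pcs: np.ndarray | pd.DataFrame | None,
                 K) -> VarianceComponents:
    """REML variance components of the no-marker mixed model.

    Profiles the restricted likelihood over the genetic:residual variance
    ratio on the spectrum of K (one eigen-decomposition total); a coarse
    log-grid bracket is refined by bounded scalar minimisation.
    """
    y = np.asarray(y, float)
    if np.ptp(y) == 0:
        raise ValueError("zero phenotypic variance")
    Km = _as_matrix(K)
    _check_K(Km)
    n = len(y)
    X = np.ones((n, 1))
    if pcs is not None and np.size(pcs):
        X = np.hstack([X, np.asarray(pcs, float)])
    D, U = np.linalg.eigh((Km + Km.T) / 2.0)
    D = np.clip(D, 0.0, None)
    y_r, X_r = U.T @ y, U.T @ X

    grid = np.linspace(-6.0, 6.0, 49)
    lls = np.array([_reml_loglik(g, y_r, X_r, D) for g in grid])
    best = int(np.argmax(lls))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(
        lambda g: -_reml_loglik(g, y_r, X_r, D), bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8})
    log_gamma = float(res.x)
    gamma = 10.0 ** log_gamma
    w = gamma * D + 1.0
    Xw = X_r / w[:, None]
    beta = np.linalg.solve(X_r.T @ Xw, Xw.T @ y_r)
    r = y_r - X_r @ beta
    sigma_e2 = float(r @ (r / w)) / (n - X.shape[1])
    return VarianceComponents(
        sigma_g2=gamma * sigma_e2, sigma_e2=sigma_e2,
        loglik=float(-res.fun), eigenvalues=D, rotation=U)


def compress_kinship(K: np.ndarray, g: int):
    """Group accessions by average-linkage clustering on kinship distance.

    Returns (membership array, group-averaged kinship).  Used by the
    optional compression mode in which the mixed model is fitted at the
    group level; g = n reduces to no compression.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = K.shape[0]
    if not 1 <= g <= n:
        raise ValueError(f"compression groups must lie in [1, {n}]")
    d = np.max(K) - K
    np.fill_diagonal(d, 0.0)
    Z = linkage(squareform((d + d.T) / 2.0, checks=False), method="average")
    member = fcluster(Z, t=g, criterion="maxclust") - 1
    n_groups = member.max() + 1
    M = np.zeros((n_groups, n))
    for i, m in enumerate(member):
        M[m, i] = 1.0
    M /= M.sum(axis=1, keepdims=True)
    return member, M @ K @ M.T, M


def _whiten(vc: VarianceComponents):
    w = vc.sigma_g2 * vc.eigenvalues + vc.sigma_e2
    return vc.rotation / np.sqrt(w)[None, :]   # columns scaled: T = diag(1/sqrt) U'


def scan(y, G: GenotypeMatrix, pcs, K, cfg: AssocConfig | None = None,
         marker_map: pd.DataFrame | None = None, trait_name: str = "trait",
         trait_class: str = "P", null: VarianceComponents | None = None) -> ScanResult:
    """Per-marker generalized-least-squares tests given fixed PCs and kinship.

    Returns a :class:`ScanResult` whose ``mtas`` hold the records with
    -log10 p above ``cfg.threshold_logp``; ``table`` carries every
    marker's p-value, partial r^2 and allele-substitution effect for
    calibration work.  r^2 is the squared partial correlation between the
    whitened marker and whitened phenotype given the whitened covariates.
    """
    cfg = cfg or AssocConfig()
    y_arr = np.asarray(y, float)
    if isinstance(y, pd.Series):
        if list(y.index) != list(G.accession_ids):
            y_arr = y.reindex(G.accession_ids).to_numpy(float)
            if np.isnan(y_arr).any():
                raise ValueError("phenotype missing for some accessions")
    if len(y_arr) != G.n_accessions:
        raise ValueError("phenotype / genotype dimension mismatch")
    pcs_arr = None
    if pcs is not None and np.size(pcs):
        pcs_arr = np.asarray(pcs, float)
        if pcs_arr.ndim == 1:
            pcs_arr = pcs_arr[:, None]
        if pcs_arr.shape[0] != G.n_accessions:
            raise ValueError("covariate / genotype dimension mismatch")

    Km = _as_matrix(K)
    dosage = G.dosage()
    if cfg.compression_groups is not None:
        _, Km, M = compress_kinship(Km, cfg.compression_groups)
        y_arr = M @ y_arr
        dosage = M @ dosage
        if pcs_arr is not None:
            pcs_arr = M @ pcs_arr

    if null is None or not cfg.p3d:
        null = fit_null_mlm(y_arr, pcs_arr, Km)
    Tt = _whiten(null)          # n x n, whitener transpose: x_w = Tt.T @ x
    X = np.ones((len(y_arr), 1))
    if pcs_arr is not None:
        X = np.hstack([X, pcs_arr])

    Xw = Tt.T @ X
    yw = Tt.T @ y_arr
    Gw = Tt.T @ dosage

    Q, _ = np.linalg.qr(Xw)
    y_t = yw - Q @ (Q.T @ yw)
    G_t = Gw - Q @ (Q.T @ Gw)

    n, p = Xw.shape
    df = n - p - 1
    gg = np.einsum("ij,ij->j", G_t, G_t)
    gy = G_t.T @ y_t
    yy = float(y_t @ y_t)

    scale = np.einsum("ij,ij->j", Gw, Gw)
    skip = gg <= 1e-10 * np.maximum(scale, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(~skip, gy**2 / np.maximum(gg * yy, 1e-300), np.nan)
        effect = np.where(~skip, gy / np.maximum(gg, 1e-300), np.nan)
        fstat = np.where(~skip & (r2 < 1.0), df * r2 / (1.0 - r2), np.inf)
    pvals = np.where(skip, np.nan, stats.f.sf(fstat, 1, df))
    mlogp = -np.log10(np.clip(pvals, 1e-300, None))

    mmap = None
    if marker_map is not None:
        mmap = marker_map.set_index("marker")

    mtas: list[Mta] = []
    reasons = np.where(skip, "zero_whitened_variance", "")
    for j in np.flatnonzero(~skip & (mlogp > cfg.threshold_logp)):
        mk = G.marker_ids[j]
        chrom = cm = bp = None
        if mmap is not None and mk in mmap.index:
            row = mmap.loc[mk]
            chrom, cm = row["chrom"], float(row["cm"])
            bp = float(row["bp"]) if pd.notna(row["bp"]) else None
        mtas.append(Mta(mk, chrom, cm, bp, trait_name, trait_class,
                        float(mlogp[j]), float(r2[j]), float(effect[j])))

    table = pd.DataFrame({
        "marker": G.marker_ids, "p": pvals, "minus_log10_p": mlogp,
        "r2": r2, "effect": effect, "skip_reason": reasons,
    })
    n_skipped = int(skip.sum())
    if n_skipped == G.n_markers:
        warnings.warn("every marker was skipped in the scan", stacklevel=2)
    return ScanResult(mtas=mtas, table=table, n_skipped=n_skipped)


@dataclass
class PopulationStructure:
    """Fixed PCs and kinship shared by the three scan families."""

    pcs: pd.DataFrame
    K: KinshipMatrix


def run_scan_family(traits: pd.DataFrame, trait_class: str, G: GenotypeMatrix,
                    structure: PopulationStructure, cfg: AssocConfig | None = None,
                    marker_map: pd.DataFrame | None = None) -> list[Mta]:
    """Scan every column of a TraitTable under one trait class (P, C or E).

    For class E with ``drop_collinear_pc_for_eigen`` on, the fixed-PC set
    excludes the principal component whose rank matches the eigenvector
    under test (eigen3 drops PC3), avoiding regressing an axis on itself.
    """
    if trait_class not in TRAIT_CLASSES:
        raise ValueError(f"unknown trait class {trait_class!r}; expected {TRAIT_CLASSES}")
    cfg = cfg or AssocConfig()
    out: list[Mta] = []
    pcs_full = structure.pcs.iloc[:, : cfg.n_pcs_fixed]
    for trait in traits.columns:
        pcs = pcs_full
        if trait_class == "E" and cfg.drop_collinear_pc_for_eigen:
            axis = trait.replace("eigen", "")
            drop = f"PC{axis}" if axis.isdigit() else None
            if drop in pcs_full.columns:
                pcs = pcs_full.drop(columns=drop)
        res = scan(traits[trait], G, pcs, structure.K, cfg, marker_map=marker_map,
                   trait_name=trait, trait_class=trait_class)
        out.extend(res.mtas)
    return out
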