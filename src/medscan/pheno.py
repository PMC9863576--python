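"""Per-accession trait values: REML BLUPs from augmented field designs and
climate phenotypes from country-of-origin normals.

The field model is the classical augmented-design mixed model: replicated
check cultivars enter as fixed effects, field rows, field columns and the
unreplicated test accessions as independent random effects,

    y = X beta + Z_row u_row + Z_col u_col + Z_acc u_acc + e,

fitted per environment (year) by EM-REML on Henderson's mixed-model
equations.  The accession BLUPs (shrunken deviations) are the association
phenotypes; year fits are averaged.

Climate phenotypes assign each accession the long-term value of its
country of origin for a chosen variable and averaging window: SA
(sowing to anthesis, 20 Nov - 31 Mar) or AM (anthesis to maturity,
1 Apr - 30 Jun).  Rainfall is totalled over the window, all other
variables are daily means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Calendar windows as (month, day) inclusive bounds; SA wraps the new year.
WINDOWS = {"SA": ((11, 20), (3, 31)), "AM": ((4, 1), (6, 30))}

#: Variables accumulated (summed) rather than averaged over a window.
SUMMED_VARIABLES = {"Rain"}


class DegenerateModelError(RuntimeError):
    """Mixed-model system is singular; the message names the term."""


@dataclass
class FieldTrialFit:
    """One environment's REML fit of the augmented-design model."""

    beta: pd.Series                    # intercept + per-check fixed effects
    varcomps: dict[str, float]         # sigma^2 per random term + 'residual'
    blups: pd.Series                   # accession BLUPs (random-effect solutions)
    row_effects: pd.Series
    col_effects: pd.Series
    loglik_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else np.nan


def _restricted_loglik(y, X, Zs, sigmas, sigma_e2) -> float:
    n, p = X.shape
    V = sigma_e2 * np.eye(n)
    for Z, s2 in zip(Zs, sigmas):
        V += s2 * (Z @ Z.T)
    sign, logdet_v = np.linalg.slogdet(V)
    if sign <= 0:
        return -np.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdet_x = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return -np.inf
    b = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ b
    return -0.5 * (logdet_v + logdet_x + r @ Vi @ r + (n - p) * np.log(2.0 * np.pi))


def solve_mixed(y, X, Zs, sigmas, sigma_e2):
    """Solve Henderson's mixed-model equations at fixed variance components.

    Returns (beta, [u_i], C_inv, W) where C_inv is the inverse MME
    coefficient matrix (used for EM traces and prediction error variances).
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Zs = [np.asarray(Z, float) for Z in Zs]
    W = np.hstack([X] + Zs)
    p = X.shape[1]
    qs = [Z.shape[1] for Z in Zs]
    C = W.T @ W
    off = p
    for q, s2 in zip(qs, sigmas):
        lam = sigma_e2 / max(s2, 1e-12)
        C[off:off + q, off:off + q] += lam * np.eye(q)
        off += q
    try:
        C_inv = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise DegenerateModelError(f"singular mixed-model equations: {err}") from err
    sol = C_inv @ (W.T @ y)
    beta = sol[:p]
    us, off = [], p
    for q in qs:
        us.append(sol[off:off + q])
        off += q
    return beta, us, C_inv, W


def em_reml(y, X, Zs, term_names: Sequence[str] | None = None,
            max_iter: int = 2000, tol: float = 1e-8):
    """EM-REML for a Gaussian mixed model with independent random terms.

    Returns (sigmas, sigma_e2, beta, us, loglik_trace).  EM guarantees a
    non-decreasing restricted log-likelihood, which is recorded per
    iteration.  Convergence: successive variance-component changes < tol.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    Zs = [np.asarray(Z, float) for Z in Zs]
    term_names = list(term_names) if term_names else [f"term{i}" for i in range(len(Zs))]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise DegenerateModelError("fixed-effect design is rank deficient")
    for name, Z in zip(term_names, Zs):
        if Z.shape[1] < 1:
            raise DegenerateModelError(f"random term {name!r} has no levels")

    v0 = float(np.var(y)) or 1.0
    sigmas = [v0 / (len(Zs) + 1)] * len(Zs)
    sigma_e2 = v0 / (len(Zs) + 1)
    trace: list[float] = []
    beta, us = None, None
    for it in range(max_iter):
        trace.append(_restricted_loglik(y, X, Zs, sigmas, sigma_e2))
        beta, us, C_inv, W = solve_mixed(y, X, Zs, sigmas, sigma_e2)
        new_sigmas = []
        off = p
        for Z, u, s2 in zip(Zs, us, sigmas):
            q = Z.shape[1]
            tr = np.trace(C_inv[off:off + q, off:off + q])
            new_sigmas.append(max((u @ u + sigma_e2 * tr) / q, 1e-12))
            off += q
        fitted_inner = beta @ (X.T @ y)
        for Z, u in zip(Zs, us):
            fitted_inner += u @ (Z.T @ y)
        new_sigma_e2 = max((y @ y - fitted_inner) / (n - p), 1e-12)
        delta = max(abs(a - b) for a, b in zip(new_sigmas + [new_sigma_e2],
                                              list(sigmas) + [sigma_e2]))
        sigmas, sigma_e2 = new_sigmas, new_sigma_e2
        if delta < tol:
            break
    trace.append(_restricted_loglik(y, X, Zs, sigmas, sigma_e2))
    beta, us, _, _ = solve_mixed(y, X, Zs, sigmas, sigma_e2)
    return sigmas, sigma_e2, beta, us, trace


def _design_for_year(df: pd.DataFrame):
    checks = sorted(df.loc[df["is_check"], "genotype_id"].unique())
    if len(checks) < 2:
        raise DegenerateModelError("need >= 2 replicated check genotypes")
    counts = df[df["is_check"]].groupby("genotype_id").size()
    unreplicated = counts[counts < 2].index.tolist()
    if unreplicated:
        raise DegenerateModelError(f"unreplicated checks: {unreplicated}")
    accs = sorted(df.loc[~df["is_check"], "genotype_id"].unique())
    rows = sorted(df["row"].unique())
    cols = sorted(df["col"].unique())

    X = np.ones((len(df), 1 + len(checks)))
    for j, ck in enumerate(checks):
        X[:, 1 + j] = (df["genotype_id"] == ck).to_numpy(float)

    def dummies(values, levels):
        idx = {v: i for i, v in enumerate(levels)}
        Z = np.zeros((len(values), len(levels)))
        Z[np.arange(len(values)), [idx[v] for v in values]] = 1.0
        return Z

    Z_row = dummies(df["row"].tolist(), rows)
    Z_col = dummies(df["col"].tolist(), cols)
    Z_acc = np.zeros((len(df), len(accs)))
    aidx = {a: i for i, a in enumerate(accs)}
    for i, (gid, ck) in enumerate(zip(df["genotype_id"], df["is_check"])):
        if not ck:
            Z_acc[i, aidx[gid]] = 1.0
    return X, [Z_row, Z_col, Z_acc], checks, rows, cols, accs


def fit_field_trial(plots: pd.DataFrame, trait: str, year=None) -> FieldTrialFit:
    """REML fit of one environment's augmented design for one trait."""
    df = plots[plots["trait"] == trait]
    if year is not None:
        df = df[df["year"] == year]
    if df.empty:
        raise ValueError(f"no plot records for trait {trait!r}")
    df = df.reset_index(drop=True)
    y = df["value"].to_numpy(float)
    X, Zs, checks, rows, cols, accs = _design_for_year(df)
    sigmas, sigma_e2, beta, us, trace = em_reml(
        y, X, Zs, term_names=["row", "col", "accession"])
    return FieldTrialFit(
        beta=pd.Series(beta, index=["intercept"] + [f"check:{c}" for c in checks]),
        varcomps={"row": sigmas[0], "col": sigmas[1], "accession": sigmas[2],
                  "residual": sigma_e2},
        blups=pd.Series(us[2], index=accs, name=trait),
        row_effects=pd.Series(us[0], index=rows),
        col_effects=pd.Series(us[1], index=cols),
        loglik_trace=trace,
        n_iter=len(trace) - 1,
    )


def reml_blup(plots: pd.DataFrame, trait: str, per_year: bool = False):
    """Accession BLUPs for one trait; one REML fit per year, averaged.

    Returns a Series (accession -> BLUP) or, with ``per_year``, a frame
    with one column per year.
    """
    years = sorted(plots.loc[plots["trait"] == trait, "year"].unique())
    if not years:
        raise ValueError(f"no plot records for trait {trait!r}")
    fits = {yr: fit_field_trial(plots, trait, year=yr) for yr in years}
    table = pd.DataFrame({yr: f.blups for yr, f in fits.items()})
    if per_year:
        return table
    out = table.mean(axis=1)
    out.name = trait
    return out


def blup_table(plots: pd.DataFrame, traits: Sequence[str] | None = None) -> pd.DataFrame:
    """Wide TraitTable (accession x trait) of across-year mean BLUPs."""
    traits = list(traits) if traits is not None else sorted(plots["trait"].unique())
    return pd.DataFrame({t: reml_blup(plots, t) for t in traits})


# ---------------------------------------------------------------------------
# climate windows

def _in_window(dates: pd.Series, window: str) -> np.ndarray:
    if window not in WINDOWS:
        raise ValueError(f"unknown window {window!r}; expected one of {list(WINDOWS)}")
    (m1, d1), (m2, d2) = WINDOWS[window]
    md = dates.dt.month * 100 + dates.dt.day
    lo, hi = m1 * 100 + d1, m2 * 100 + d2
    if lo <= hi:
        return ((md >= lo) & (md <= hi)).to_numpy()
    return ((md >= lo) | (md <= hi)).to_numpy()


def window_average(daily: pd.DataFrame, window: str, variable: str = "Tmean") -> float:
    """Aggregate a daily series over a growth-period window.

    ``daily`` needs columns (date, value).  Rainfall is summed over the
    window (published totals, e.g. 663.4 mm, are seasonal accumulations);
    every other variable is a daily arithmetic mean.
    """
    daily = daily.copy()
    daily["date"] = pd.to_datetime(daily["date"])
    sel = daily.loc[_in_window(daily["date"], window), "value"]
    if sel.empty:
        raise ValueError(f"no daily records inside window {window!r}")
    if variable in SUMMED_VARIABLES:
        return float(sel.sum())
    return float(sel.mean())


def climate_phenotype(meta: pd.DataFrame, climate: pd.DataFrame,
                      variable: str, period: str) -> pd.Series:
    """Assign each accession its country's climate value as a phenotype.

    Accessions sharing a country receive identical values; a missing
    country raises with the full list of unmatched countries.
    """
    sub = climate[(climate["variable"] == variable) & (climate["period"] == period)]
    lookup = sub.set_index("country")["value"]
    missing = sorted(set(meta["country"]) - set(lookup.index))
    if missing:
        raise KeyError(
            f"no {variable}/{period} climate value for countries: {missing}")
    out = meta.set_index("accession_id")["country"].map(lookup)
    out.name = f"{variable}_{period}"
    return out.astype(float)


def climate_trait_table(meta: pd.DataFrame, climate: pd.DataFrame) -> pd.DataFrame:
    """Wide TraitTable with one column per (variable, period) combination."""
    cols = {}
    for (var, period), _ in climate.groupby(["variable", "period"]):
        cols[f"{var}_{period}"] = climate_phenotype(meta, climate, var, period)
    return pd.DataFrame(cols)
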