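"""Fixed-effect-model (FEM) fitting and the genome scan.

Two models are used throughout:

* the *scan* model, which tests one marker at a time with an intercept, any
  common covariates (e.g. principal components), and the current pseudo-QTN
  set as additional covariates; the reported P value is the two-sided t test
  (equivalently the 1-df partial F) on the marker effect; and
* the *covariates-only* model, whose Gaussian maximum-likelihood deviance
  (-2LL with residual variance profiled out as RSS/n) feeds the information
  criteria used for pseudo-QTN selection.

The scan is computed with the Frisch-Waugh-Lovell residualisation: the
covariate block is orthogonalised once per iteration and every marker test
then reduces to a simple regression of residualised phenotype on
residualised marker, numerically identical to a full per-marker refit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import MISSING, GenotypeData, impute_missing

# relative tolerance for treating a residualised column as zero (collinear)
_COLLINEAR_RTOL = 1e-9
# floor applied to RSS before taking logs, relative to total sum of squares
_RSS_FLOOR_RTOL = 1e-12


class DegenerateModelError(ValueError):
    """Raised when a design has no residual degrees of freedom."""


@dataclass
class ModelFit:
    """An OLS fit with its Gaussian ML deviance.

    ``neg2_log_likelihood`` uses the profiled ML residual variance RSS/n
    (not REML), so nested fits have non-increasing deviance by construction.
    ``k`` counts pseudo QTNs only — the intercept and common covariates are
    excluded from information-criterion penalties.
    """

    neg2_log_likelihood: float
    k: int
    n: int
    residual_variance: float
    params: np.ndarray
    rss: float
    rank: int
    dropped_columns: list[int] = field(default_factory=list)
    perfect_fit: bool = False


def neg2_loglik(rss: float, n: int, tss: float = 1.0) -> tuple[float, bool]:
    """Gaussian ML deviance -2LL = n(ln(2*pi*RSS/n) + 1), with an RSS floor.

    Returns the deviance and a flag marking a (floored) perfect fit.
    """
    floor = _RSS_FLOOR_RTOL * max(tss, 1.0)
    perfect = rss < floor
    rss_eff = max(rss, floor)
    return float(n * (np.log(2.0 * np.pi * rss_eff / n) + 1.0)), perfect


def fit_fem(y: np.ndarray, X: np.ndarray, n_pseudo_qtns: int = 0) -> ModelFit:
    """Ordinary least squares with deterministic rank handling.

    Columns of ``X`` that are (numerically) in the span of earlier columns
    are dropped — first occurrence kept — and reported in
    ``dropped_columns``; their coefficients are set to zero.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.shape[0]:
        raise ValueError("rows of X must match y")
    n, p = X.shape
    keep, dropped = _independent_columns(X)
    Xk = X[:, keep]
    rank = len(keep)
    if n <= rank:
        raise DegenerateModelError(
            f"n={n} observations cannot fit a rank-{rank} design"
        )
    beta_k, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta_k
    rss = float(resid @ resid)
    tss = float(y @ y)
    n2ll, perfect = neg2_loglik(rss, n, tss)
    params = np.zeros(p)
    params[keep] = beta_k
    return ModelFit(
        neg2_log_likelihood=n2ll,
        k=n_pseudo_qtns,
        n=n,
        residual_variance=rss / n,
        params=params,
        rss=rss,
        rank=rank,
        dropped_columns=dropped,
        perfect_fit=perfect,
    )


def _independent_columns(X: np.ndarray) -> tuple[list[int], list[int]]:
    """Greedy left-to-right selection of linearly independent columns."""
    keep: list[int] = []
    dropped: list[int] = []
    Q = np.empty((X.shape[0], 0))
    for j in range(X.shape[1]):
        col = X[:, j].astype(float)
        norm0 = np.linalg.norm(col)
        r = col - Q @ (Q.T @ col)
        r = r - Q @ (Q.T @ r)  # reorthogonalise
        nr = np.linalg.norm(r)
        if norm0 == 0 or nr <= _COLLINEAR_RTOL * norm0:
            dropped.append(j)
        else:
            keep.append(j)
            Q = np.hstack([Q, (r / nr)[:, None]])
    return keep, dropped


def pvalue_from_t(t_stat: float, df: int) -> float:
    """Two-sided Student-t tail probability."""
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(2.0 * stats.t.sf(np.abs(t_stat), df))


@dataclass
class ScanResult:
    """Per-marker association results from one FEM scan.

    ``p_value`` is NaN (undefined) exactly when the marker is constant, or
    collinear with the covariates, on the analysed individuals.
    """

    marker_id: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    effect: np.ndarray
    standard_error: np.ndarray
    test_statistic: np.ndarray
    p_value: np.ndarray
    n_used: np.ndarray

    def __len__(self) -> int:
        return len(self.marker_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker_id": self.marker_id,
                "chromosome": self.chromosome,
                "position": self.position,
                "effect": self.effect,
                "se": self.standard_error,
                "t": self.test_statistic,
                "p": self.p_value,
                "n_used": self.n_used,
            }
        )

    def write(self, path, header_lines: list[str] | None = None) -> None:
        """Tab-separated serialisation; undefined values printed as NA."""
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, na_rep="NA")


def _covariate_basis(n: int, covariates: np.ndarray | None,
                     pseudo_block: np.ndarray | None) -> np.ndarray:
    """Orthonormal basis of [intercept | covariates | pseudo QTNs]."""
    blocks = [np.ones((n, 1))]
    if covariates is not None and covariates.size:
        blocks.append(np.atleast_2d(covariates).reshape(n, -1))
    if pseudo_block is not None and pseudo_block.size:
        blocks.append(pseudo_block.reshape(n, -1))
    X0 = np.hstack(blocks)
    keep, _ = _independent_columns(X0)
    Q, _ = np.linalg.qr(X0[:, keep])
    return Q


def _marginal_test(g: np.ndarray, y: np.ndarray, Q: np.ndarray
                   ) -> tuple[float, float, float, float]:
    """Effect, SE, t and P of one marker given the orthonormal basis Q."""
    n = y.shape[0]
    df = n - Q.shape[1] - 1
    if df < 1:
        return (np.nan,) * 4
    rg = g - Q @ (Q.T @ g)
    rg = rg - Q @ (Q.T @ rg)
    sgg = float(rg @ rg)
    scale = float(g @ g) if float(g @ g) > 0 else 1.0
    if sgg <= _COLLINEAR_RTOL**2 * scale:
        return (np.nan,) * 4
    ry = y - Q @ (Q.T @ y)
    beta = float(rg @ ry) / sgg
    rss = float(ry @ ry) - beta * beta * sgg
    rss = max(rss, 0.0)
    sigma2 = rss / df
    se = np.sqrt(max(sigma2, 0.0) / sgg)
    if se == 0:
        return beta, 0.0, np.inf, 0.0
    t = beta / se
    return beta, se, t, pvalue_from_t(t, df)


def scan_markers(
    geno: GenotypeData,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
    pseudo_qtns=None,
    dosages: np.ndarray | None = None,
) -> ScanResult:
    """Test every marker in a FEM with covariates and pseudo QTNs.

    When the scanned marker *is* one of the pseudo QTNs (or is exactly
    collinear with one), that pseudo QTN is removed from the covariate set
    for its own test, so pseudo QTNs still receive a defined P value.

    ``dosages`` may supply a pre-imputed float matrix to avoid recomputing
    it per iteration; otherwise mean imputation is applied here.
    """
    y = np.asarray(y, dtype=float)
    n = geno.n_individuals
    if y.shape[0] != n:
        raise ValueError(
            f"phenotype length {y.shape[0]} != {n} genotyped individuals"
        )
    if dosages is None:
        dosages = impute_missing(geno, "mean")
    if pseudo_qtns is None:
        pseudo_idx: list[int] = []
    elif hasattr(pseudo_qtns, "marker_indices"):
        pseudo_idx = [int(i) for i in pseudo_qtns.marker_indices]
    else:
        pseudo_idx = [int(i) for i in pseudo_qtns]
    pseudo_block = dosages[pseudo_idx].T if pseudo_idx else None
    Q = _covariate_basis(n, covariates, pseudo_block)
    df = n - Q.shape[1] - 1
    m = geno.n_markers
    eff = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)

    if df >= 1:
        G = dosages
        ry = y - Q @ (Q.T @ y)
        QtG = Q.T @ G.T                      # (p0, m)
        RG = G - QtG.T @ Q.T                 # residualised markers, (m, n)
        RG = RG - (Q.T @ RG.T).T @ Q.T       # reorthogonalise
        sgg = np.einsum("ij,ij->i", RG, RG)
        scale = np.maximum(np.einsum("ij,ij->i", G, G), 1.0)
        ok = sgg > _COLLINEAR_RTOL**2 * scale
        beta = np.zeros(m)
        beta[ok] = (RG[ok] @ ry) / sgg[ok]
        rss = float(ry @ ry) - beta**2 * sgg
        rss = np.maximum(rss, 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            se_all = np.sqrt(rss / df / sgg)
        eff[ok] = beta[ok]
        se[ok] = se_all[ok]
        with np.errstate(invalid="ignore", divide="ignore"):
            t_ok = np.where(se_all[ok] > 0, beta[ok] / se_all[ok], np.inf)
        tstat[ok] = t_ok
        pval[ok] = 2.0 * stats.t.sf(np.abs(t_ok), df)

    # self-test rule: retest pseudo QTNs, and markers exactly collinear with
    # one, against a covariate set that excludes the offending pseudo QTN
    if pseudo_idx:
        undefined = np.flatnonzero(np.isnan(pval))
        for j in undefined:
            if j in pseudo_idx:
                continue
            g = dosages[j]
            if float(np.var(g)) * n <= _COLLINEAR_RTOL**2:
                continue  # constant marker: undefined regardless of covariates
            res = _retest_without_pseudo(j, dosages, y, covariates, pseudo_idx)
            if res is not None:
                eff[j], se[j], tstat[j], pval[j] = res
    for j in pseudo_idx:
        res = _retest_without_pseudo(j, dosages, y, covariates, pseudo_idx)
        if res is not None:
            eff[j], se[j], tstat[j], pval[j] = res

    return ScanResult(
        marker_id=geno.map["marker_id"].to_numpy(),
        chromosome=geno.map["chromosome"].to_numpy(),
        position=geno.map["position"].to_numpy(),
        effect=eff,
        standard_error=se,
        test_statistic=tstat,
        p_value=pval,
        n_used=np.full(m, n, dtype=int),
    )


def _retest_without_pseudo(j, dosages, y, covariates, pseudo_idx):
    """Retest marker j after dropping it (or a collinear member) from the
    pseudo-QTN covariates; returns None if no exclusion yields a defined test."""
    n = y.shape[0]
    g = dosages[j]
    if j in pseudo_idx:
        reduced = [q for q in pseudo_idx if q != j]
        Q = _covariate_basis(n, covariates,
                             dosages[reduced].T if reduced else None)
        out = _marginal_test(g, y, Q)
        return out if not np.isnan(out[3]) else None
    for q in pseudo_idx:
        reduced = [p for p in pseudo_idx if p != q]
        Q = _covariate_basis(n, covariates,
                             dosages[reduced].T if reduced else None)
        out = _marginal_test(g, y, Q)
        if not np.isnan(out[3]):
            return out
    return None
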