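"""Pseudo-QTN selection: P-value filtering, LD pruning, criterion search.

Candidate markers are those passing a Bonferroni threshold (alpha / M) in
the current scan, sorted most-significant first.  A greedy sweep then
removes every candidate whose absolute Pearson correlation with an
already-kept candidate exceeds the LD threshold, so the surviving markers
are mutually in low LD.  Finally the covariates-only model is fitted with
the first k survivors for k = 0..t and the k minimising an information
criterion (BIC by default) is chosen.

The BIC here applies its penalty with a coefficient of 2 per parameter,
2*k*ln(n) — twice the textbook value — following the method's published
definition; ``bic_penalty_factor`` exposes the standard form as well.  k
counts pseudo QTNs only, never the intercept or common covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .fem import ScanResult, neg2_loglik, _COLLINEAR_RTOL
from .io import GenotypeData, impute_missing


class ConstantVectorError(ValueError):
    """Pearson correlation is undefined for a constant vector."""


def _impute_rows(codes: np.ndarray) -> np.ndarray:
    """Mean-impute a block of raw genotype code rows."""
    from .io import MISSING
    out = codes.astype(float)
    miss = codes == MISSING
    if miss.any():
        n_obs = np.maximum((~miss).sum(axis=1), 1)
        fill = np.where(miss, 0, codes).sum(axis=1) / n_obs
        out[miss] = np.broadcast_to(fill[:, None], out.shape)[miss]
    return out


@dataclass
class PseudoQtnSet:
    """An ordered pseudo-QTN set with its selection provenance.

    ``marker_indices`` are row indices into the scanned genotype matrix,
    most significant first.  ``criterion_trace`` records (k, -2LL,
    criterion value) for every evaluated model size; ``chosen_k`` minimises
    the criterion (ties to the smaller k).
    """

    marker_indices: tuple[int, ...]
    source_p_values: tuple[float, ...]
    criterion: str = "bic"
    criterion_trace: list[tuple[int, float, float]] = field(default_factory=list)
    chosen_k: int = 0
    collinear_dropped: tuple[int, ...] = ()

    def __len__(self) -> int:
        return len(self.marker_indices)

    def __eq__(self, other) -> bool:
        return isinstance(other, PseudoQtnSet) and \
            self.marker_indices == other.marker_indices

    def __hash__(self) -> int:
        return hash(self.marker_indices)

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.criterion_trace,
                            columns=["k", "neg2LL", self.criterion])


def candidate_filter(scan: ScanResult, alpha: float = 0.01,
                     M: int | None = None) -> np.ndarray:
    """Indices of markers passing the Bonferroni threshold alpha / M.

    Sorted ascending by P value; ties broken by (chromosome, position,
    marker_id) so the order is deterministic.
    """
    if len(scan) == 0:
        raise ValueError("empty scan")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if M is None:
        M = len(scan)
    cutoff = alpha / M
    p = scan.p_value
    ok = np.flatnonzero(np.isfinite(p) & (p <= cutoff))
    order = np.lexsort((
        scan.marker_id[ok].astype(str),
        scan.position[ok],
        scan.chromosome[ok].astype(str),
        p[ok],
    ))
    return ok[order]


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation of two (mean-imputed) genotype vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ConstantVectorError("correlation undefined for a constant vector")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def ld_prune(candidates: np.ndarray, geno: GenotypeData, beta: float = 0.7,
             dosages: np.ndarray | None = None) -> np.ndarray:
    """Greedy LD pruning of significance-ordered candidates.

    Keep the head; remove every later candidate with |r| > ``beta`` against
    it; recurse on the remainder.  The output preserves the significance
    order and contains no pair with |r| > beta.
    """
    if not 0.0 < beta <= 1.0:
        raise ValueError("LD threshold must lie in (0, 1]")
    candidates = np.asarray(candidates, dtype=int)
    if candidates.size == 0:
        return candidates
    if dosages is None:
        G = _impute_rows(geno.codes[candidates])
    else:
        G = dosages[candidates]
    Gc = G - G.mean(axis=1, keepdims=True)
    norms = np.sqrt(np.einsum("ij,ij->i", Gc, Gc))
    kept: list[int] = []
    active = np.arange(len(candidates))
    while active.size:
        head = active[0]
        kept.append(head)
        rest = active[1:]
        if rest.size == 0:
            break
        if norms[head] == 0:
            active = rest  # constant head correlates with nothing
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Gc[rest] @ Gc[head]) / (norms[rest] * norms[head])
        r = np.nan_to_num(r, nan=0.0)
        active = rest[np.abs(r) <= beta]
    return candidates[np.asarray(kept, dtype=int)]


def information_criterion(fit, criterion: str = "bic", M: int | None = None,
                          gamma: float = 0.5,
                          bic_penalty_factor: float = 2.0) -> float:
    """Information-criterion value for a covariates-only model fit.

    bic  : -2LL + bic_penalty_factor * k * ln(n)
    aic  : -2LL + 2k
    ebic : bic + 2 * gamma * ln C(M, k)
    """
    n2ll = fit.neg2_log_likelihood
    k, n = fit.k, fit.n
    criterion = criterion.lower()
    if criterion == "aic":
        return float(n2ll + 2.0 * k)
    bic = float(n2ll + bic_penalty_factor * k * np.log(n))
    if criterion == "bic":
        return bic
    if criterion == "ebic":
        if M is None:
            raise ValueError("eBIC requires the total marker count M")
        if not 0.0 <= gamma <= 1.0:
            raise ValueError("eBIC gamma must lie in [0, 1]")
        if k > M:
            raise ValueError("k cannot exceed the predictor-space size M")
        log_choose = gammaln(M + 1) - gammaln(k + 1) - gammaln(M - k + 1)
        return float(bic + 2.0 * gamma * log_choose)
    raise ValueError(f"unknown criterion: {criterion!r}")


def criterion_penalty(k: int, n: int, criterion: str = "bic",
                      M: int | None = None, gamma: float = 0.5,
                      bic_penalty_factor: float = 2.0) -> float:
    """Closed-form penalty criterion(k) - (-2LL(k)) for a given k."""
    class _F:  # minimal stand-in carrying only what the formula needs
        neg2_log_likelihood = 0.0
    f = _F()
    f.k, f.n = k, n
    return information_criterion(f, criterion, M=M, gamma=gamma,
                                 bic_penalty_factor=bic_penalty_factor)


@dataclass
class _NestedSearch:
    """RSS of the covariates-only model as candidates are added in order."""

    rss_by_k: list[float]
    collinear_dropped: list[int]


def _nested_rss(y: np.ndarray, covariates: np.ndarray | None,
                candidate_dosages: np.ndarray) -> _NestedSearch:
    """Incremental Gram-Schmidt giving RSS for every nested model size.

    Adding an orthogonalised column q reduces RSS by (q . y)^2 exactly, so
    the sequence is non-increasing by construction.  A candidate column
    already in the span of the current design is recorded and skipped
    (first occurrence kept), contributing no RSS reduction and no
    parameter.
    """
    n = y.shape[0]
    base = [np.ones((n, 1))]
    if covariates is not None and np.size(covariates):
        base.append(np.atleast_2d(covariates).reshape(n, -1))
    X0 = np.hstack(base)
    Q, _ = np.linalg.qr(X0)
    resid = y - Q @ (Q.T @ y)
    rss = float(resid @ resid)
    rss_by_k = [rss]
    dropped: list[int] = []
    basis = [Q[:, i] for i in range(Q.shape[1])]
    for idx, col in enumerate(candidate_dosages):
        v = col.astype(float).copy()
        norm0 = np.linalg.norm(v)
        for q in basis:
            v -= (q @ v) * q
        for q in basis:
            v -= (q @ v) * q
        nv = np.linalg.norm(v)
        if norm0 == 0 or nv <= _COLLINEAR_RTOL * norm0:
            dropped.append(idx)
            continue
        q = v / nv
        proj = float(q @ resid)
        resid = resid - proj * q
        rss = max(rss - proj * proj, 0.0)
        basis.append(q)
        rss_by_k.append(rss)
    return _NestedSearch(rss_by_k, dropped)


def select_pseudo_qtns(
    candidates: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None,
    geno: GenotypeData,
    criterion: str = "bic",
    M: int | None = None,
    gamma: float = 0.5,
    bic_penalty_factor: float = 2.0,
    source_p_values: np.ndarray | None = None,
    include_k0: bool = True,
    dosages: np.ndarray | None = None,
) -> PseudoQtnSet:
    """Choose the nested pseudo-QTN model size minimising the criterion.

    ``candidates`` must already be LD-pruned and sorted most-significant
    first.  k = 0 (covariates only) is always evaluated so a run can
    discard every pseudo QTN; ties go to the smaller k.  Candidates beyond
    n - c - 2 (c = common covariate count) are dropped so every fit keeps
    positive residual degrees of freedom.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    candidates = np.asarray(candidates, dtype=int)
    c = 0 if covariates is None else np.atleast_2d(covariates).reshape(n, -1).shape[1]
    t_max = max(n - c - 2, 0)
    if candidates.size > t_max:
        candidates = candidates[:t_max]
    if dosages is None:
        cd = impute_missing(geno, "mean")[candidates] if candidates.size \
            else np.empty((0, n))
    else:
        cd = dosages[candidates]
    if M is None:
        M = geno.n_markers
    search = _nested_rss(y, covariates, cd)
    # candidate positions surviving the collinearity screen, in order
    surviving_pos = [i for i in range(candidates.size)
                     if i not in set(search.collinear_dropped)]
    surviving = candidates[surviving_pos]
    tss = float(y @ y)
    trace: list[tuple[int, float, float]] = []
    k_start = 0 if include_k0 else min(1, len(search.rss_by_k) - 1)
    for k in range(k_start, len(search.rss_by_k)):
        n2ll, _ = neg2_loglik(search.rss_by_k[k], n, tss)
        pen = criterion_penalty(k, n, criterion, M=M, gamma=gamma,
                                bic_penalty_factor=bic_penalty_factor)
        trace.append((k, n2ll, n2ll + pen))
    crit_vals = [row[2] for row in trace]
    chosen_k = trace[int(np.argmin(crit_vals))][0]  # argmin takes first = smaller k
    chosen = surviving[:chosen_k]
    if source_p_values is not None:
        pv = np.asarray(source_p_values)[surviving_pos]
        src = tuple(float(p) for p in pv[:chosen_k])
    else:
        src = ()
    return PseudoQtnSet(
        marker_indices=tuple(int(i) for i in chosen),
        source_p_values=src,
        criterion=criterion,
        criterion_trace=trace,
        chosen_k=int(chosen_k),
        collinear_dropped=tuple(int(candidates[i])
                                for i in search.collinear_dropped),
    )
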