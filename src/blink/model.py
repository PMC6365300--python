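"""The iterative multi-locus association model and its results object.

:class:`Blink` ties the pieces together in the iterated loop that gives the
method its power: scan every marker in a fixed-effect model, filter the
scan by a Bonferroni threshold, prune the survivors by linkage
disequilibrium, pick the best nested model size by an information
criterion, and repeat with the chosen markers as covariates until the
pseudo-QTN set stops changing.  The pseudo-QTN covariates absorb the
polygenic background that otherwise inflates single-marker tests, without
any variance-component machinery.

Usage::

    model = Blink(geno, pheno, covariates=pcs)
    res = model.fit()
    print(res.summary())
    hits = res.significant()            # Bonferroni at alpha=0.01
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fem import ScanResult, scan_markers
from .io import (CovariateData, GenotypeData, PhenotypeData, align_samples,
                 filter_maf, impute_missing)
from .selection import (PseudoQtnSet, candidate_filter, ld_prune,
                        select_pseudo_qtns)


@dataclass
class BlinkConfig:
    """All tunables of a run, with the method's default settings.

    maf_threshold      markers with MAF at or below this are dropped (0.05)
    alpha              Bonferroni family-wise level for both the candidate
                       filter and the final significance call (0.01)
    ld_threshold       |Pearson r| above which two candidates are treated
                       as one signal (0.7)
    criterion          pseudo-QTN model-size criterion: bic | aic | ebic
    bic_penalty_factor penalty coefficient per parameter in the BIC
                       (2 = the method's published form; 1 = textbook BIC)
    ebic_gamma         weight of the combinatorial eBIC term
    max_iterations     hard stop for the outer loop
    bin_sizes_bp       bin widths used by the evaluation helpers
    """

    maf_threshold: float = 0.05
    alpha: float = 0.01
    ld_threshold: float = 0.7
    criterion: str = "bic"
    bic_penalty_factor: float = 2.0
    ebic_gamma: float = 0.5
    max_iterations: int = 10
    bin_sizes_bp: tuple[int, ...] = (1, 1_000, 10_000, 100_000)
    seed: int | None = None

    def validate(self) -> None:
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0.0 < self.ld_threshold <= 1.0:
            raise ValueError("ld_threshold must lie in (0, 1]")
        if self.criterion.lower() not in ("bic", "aic", "ebic"):
            raise ValueError("criterion must be bic, aic or ebic")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")

    def as_dict(self) -> dict:
        return {
            "maf_threshold": self.maf_threshold,
            "alpha": self.alpha,
            "ld_threshold": self.ld_threshold,
            "criterion": self.criterion,
            "bic_penalty_factor": self.bic_penalty_factor,
            "ebic_gamma": self.ebic_gamma,
            "max_iterations": self.max_iterations,
            "bin_sizes_bp": list(self.bin_sizes_bp),
            "seed": self.seed,
        }


@dataclass
class IterationRecord:
    """One outer-loop iteration: counts and the accepted pseudo-QTN set."""

    iteration: int
    n_candidates: int
    n_pruned: int
    pseudo_qtns: PseudoQtnSet
    criterion_value: float


@dataclass
class BlinkResults:
    """Fitted results: final scan, pseudo QTNs, and the iteration history.

    The final scan is recomputed under the converged pseudo-QTN set, so the
    reported P values always correspond to the final model; pseudo QTNs
    carry the P value of their own exclusion test.
    """

    model: "Blink"
    scan: ScanResult
    pseudo_qtns: PseudoQtnSet
    iteration_history: list[IterationRecord]
    converged: bool
    stop_reason: str  # stable_set | max_iterations | cycle_detected

    @property
    def n_iterations(self) -> int:
        return len(self.iteration_history)

    @property
    def final_scan(self) -> ScanResult:
        return self.scan

    def to_frame(self) -> pd.DataFrame:
        return self.scan.to_frame()

    def qtn_frame(self) -> pd.DataFrame:
        """The final pseudo QTNs with map coordinates and final P values."""
        idx = list(self.pseudo_qtns.marker_indices)
        df = self.scan.to_frame().iloc[idx].reset_index(drop=True)
        df.insert(0, "rank", np.arange(1, len(idx) + 1))
        return df

    def significant(self, alpha: float | None = None) -> pd.DataFrame:
        cfg = self.model.config
        return declare_significant(self.scan,
                                   alpha if alpha is not None else cfg.alpha)

    def summary(self) -> str:
        """A plain-text run summary in the spirit of a regression summary."""
        cfg = self.model.config
        m = len(self.scan)
        hits = self.significant()
        lines = [
            "Iterative multi-locus GWAS (pseudo-QTN fixed-effect scan)",
            "=" * 60,
            f"markers scanned:        {m}",
            f"individuals:            {self.model.n_individuals}",
            f"common covariates:      {self.model.n_covariates}",
            f"criterion:              {cfg.criterion.upper()}"
            f" (penalty factor {cfg.bic_penalty_factor:g})",
            f"LD threshold |r|:       {cfg.ld_threshold:g}",
            f"Bonferroni level:       {cfg.alpha:g} / {m}"
            f" = {cfg.alpha / m:.3e}",
            f"iterations:             {self.n_iterations}"
            f" (stop: {self.stop_reason})",
            f"pseudo QTNs selected:   {len(self.pseudo_qtns)}",
            f"significant markers:    {len(hits)}",
        ]
        if len(self.pseudo_qtns):
            lines.append("-" * 60)
            lines.append("pseudo QTNs (rank, marker, chrom, pos, effect, p):")
            for _, r in self.qtn_frame().iterrows():
                lines.append(
                    f"  {int(r['rank']):>3} {r.marker_id:<14}"
                    f" {r.chromosome:<4} {int(r.position):>10}"
                    f" {r.effect:>9.4f} {r.p:.3e}"
                )
        return "\n".join(lines)


class Blink(object):
    """Multi-locus association model for one quantitative trait.

    Parameters
    ----------
    geno : GenotypeData
        Additive genotype codes with a marker map.
    pheno : PhenotypeData or array-like
        The trait.  An array is accepted when it is already aligned with
        ``geno.individual_ids``.
    covariates : CovariateData or array-like, optional
        Common covariates fitted in every model (never penalised).
    config : BlinkConfig, optional
        Tunables; keyword overrides are applied on top.

    The constructor aligns samples (sorted id intersection, missing
    phenotypes dropped) and applies the MAF filter, so ``fit`` always sees
    clean inputs.
    """

    def __init__(self, geno: GenotypeData, pheno, covariates=None,
                 config: BlinkConfig | None = None, **overrides):
        cfg = config if config is not None else BlinkConfig()
        if overrides:
            cfg = replace(cfg, **overrides)
        cfg.validate()
        self.config = cfg
        if not isinstance(pheno, PhenotypeData):
            pheno = PhenotypeData(geno.individual_ids,
                                  np.asarray(pheno, dtype=float))
        if covariates is not None and not isinstance(covariates, CovariateData):
            covariates = CovariateData(pheno.individual_ids,
                                       np.asarray(covariates, dtype=float))
        geno, pheno, covariates = align_samples(geno, pheno, covariates)
        if cfg.maf_threshold > 0:
            geno = filter_maf(geno, cfg.maf_threshold)
        self.geno = geno
        self.pheno = pheno
        self.covariates = covariates
        self._dosages = impute_missing(geno, "mean")

    @classmethod
    def from_files(cls, geno_path, pheno_path, covar_path=None,
                   geno_format: str = "numeric_table", trait=None, **kwargs):
        from .io import read_covariates, read_genotypes, read_phenotype
        geno = read_genotypes(geno_path, geno_format)
        pheno = read_phenotype(pheno_path, trait)
        covar = read_covariates(covar_path) if covar_path else None
        return cls(geno, pheno, covar, **kwargs)

    @property
    def n_individuals(self) -> int:
        return self.geno.n_individuals

    @property
    def n_markers(self) -> int:
        return self.geno.n_markers

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else self.covariates.values.shape[1]

    def _covar_matrix(self) -> np.ndarray | None:
        return None if self.covariates is None else self.covariates.values

    def fit(self, callback=None) -> BlinkResults:
        """Run the iterated scan/select loop until the pseudo-QTN set is
        stable, a cycle is revisited, or ``max_iterations`` is reached."""
        cfg = self.config
        y = self.pheno.values
        C = self._covar_matrix()
        geno, dosages = self.geno, self._dosages
        M = geno.n_markers

        empty = PseudoQtnSet(marker_indices=(), source_p_values=(),
                             criterion=cfg.criterion)
        current = empty  # iteration 1 scans with no pseudo QTNs
        seen: dict[tuple[int, ...], int] = {}
        history: list[IterationRecord] = []
        converged = False
        stop_reason = "max_iterations"

        for it in range(1, cfg.max_iterations + 1):
            scan = scan_markers(geno, y, C, current, dosages=dosages)
            cand = candidate_filter(scan, cfg.alpha, M)
            pruned = ld_prune(cand, geno, cfg.ld_threshold, dosages=dosages)
            new_set = select_pseudo_qtns(
                pruned, y, C, geno,
                criterion=cfg.criterion, M=M, gamma=cfg.ebic_gamma,
                bic_penalty_factor=cfg.bic_penalty_factor,
                source_p_values=scan.p_value[pruned],
                dosages=dosages,
            )
            crit_val = min(r[2] for r in new_set.criterion_trace)
            history.append(IterationRecord(
                iteration=it, n_candidates=int(cand.size),
                n_pruned=int(pruned.size), pseudo_qtns=new_set,
                criterion_value=float(crit_val),
            ))
            if callback is not None:
                callback(history[-1])
            if new_set.marker_indices == current.marker_indices:
                converged = True
                stop_reason = "stable_set"
                current = new_set
                break
            key = new_set.marker_indices
            if key in seen:
                # revisiting a previous set: keep the best-criterion set seen
                stop_reason = "cycle_detected"
                best = min(history, key=lambda r: r.criterion_value)
                current = best.pseudo_qtns
                break
            seen[key] = it
            current = new_set

        final_scan = scan_markers(geno, y, C, current, dosages=dosages)
        return BlinkResults(
            model=self, scan=final_scan, pseudo_qtns=current,
            iteration_history=history, converged=converged,
            stop_reason=stop_reason,
        )


def run_blink(geno: GenotypeData, pheno, covariates=None,
              config: BlinkConfig | None = None, **overrides) -> BlinkResults:
    """Functional entry point: build the model and fit it in one call."""
    return Blink(geno, pheno, covariates, config, **overrides).fit()


def declare_significant(scan: ScanResult, alpha: float = 0.01,
                        M: int | None = None) -> pd.DataFrame:
    """Markers at or below the Bonferroni cutoff alpha / M, with map info."""
    if M is None:
        M = len(scan)
    df = scan.to_frame()
    if M == 0 or len(df) == 0:
        return df.iloc[0:0]
    cutoff = alpha / M
    return df[np.isfinite(df["p"]) & (df["p"] <= cutoff)].reset_index(drop=True)


def compute_pcs(geno: GenotypeData, q: int) -> CovariateData:
    """First q principal components of the individuals-by-markers matrix.

    The mean-imputed dosage matrix is column-centred (per marker) and
    decomposed by SVD.  Sign convention: within each component, the entry
    of largest magnitude is made positive, so results are deterministic.
    """
    if q < 0 or q >= min(geno.n_markers, geno.n_individuals):
        if q != 0:
            raise ValueError(
                f"q={q} out of range for {geno.n_markers} markers x "
                f"{geno.n_individuals} individuals"
            )
    X = impute_missing(geno, "mean").T  # individuals x markers
    X = X - X.mean(axis=0, keepdims=True)
    if q == 0:
        return CovariateData(geno.individual_ids,
                             np.empty((geno.n_individuals, 0)), names=[])
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    pcs = U[:, :q] * s[:q]
    for j in range(q):
        i = int(np.argmax(np.abs(pcs[:, j])))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return CovariateData(geno.individual_ids, pcs,
                         names=[f"PC{i + 1}" for i in range(q)])
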