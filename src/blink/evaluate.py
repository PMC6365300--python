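"""Bin-based power, FDR and type-I-error evaluation, plus enrichment nulls.

Simulation scoring aggregates markers into fixed-width genomic bins (1 bp,
1 kb, 100 kb are the conventional widths; 10 kb is the default report
width).  A bin is a QTN bin if it contains at least one simulated causal
marker; a bin's P value is that of its most significant marker.  Sweeping
a significance threshold over the observed bin P values yields
(cost, power) curves with cost either FDR (false positives among declared
positives) or type I error (the empirical tail of the non-QTN-bin null),
and the area under each curve over the full cost domain [0, 1] summarises
a method's operating range in one number.

The enrichment null answers a different question: how surprising is it
that a set of associated loci overlaps a class of annotated regions
covering a known fraction of the genome?  A closed-form binomial tail and
a Monte-Carlo resampling estimate of the same tail are both provided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fem import ScanResult


@dataclass
class EvalCurve:
    """A (cost, power) operating curve and its area under the curve.

    ``axis`` names the cost: ``FDR`` or ``type_I_error``.  Points are
    sorted by cost with power non-decreasing; the curve is closed at
    (0, 0) and extended horizontally to cost 1 before the trapezoid AUC.
    """

    axis: str
    points: np.ndarray  # (n, 2) columns: cost, power
    auc: float
    bin_size_bp: int

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.points, columns=["cost", "power"])


def bin_markers(gmap: pd.DataFrame, qtn_indices, bin_size_bp: int
                ) -> pd.DataFrame:
    """Assign every marker to a (chromosome, bin) and flag QTN bins.

    Bin index is floor((position - 1) / bin_size_bp), so 1 bp bins reduce
    to single positions.  Returns one row per marker with columns
    ``bin_chrom``, ``bin_index`` and ``is_qtn_bin`` (true for every marker
    in a bin containing at least one QTN).
    """
    if bin_size_bp < 1:
        raise ValueError("bin size must be >= 1 bp")
    qtn_indices = np.asarray(qtn_indices, dtype=int)
    binned = pd.DataFrame({
        "bin_chrom": gmap["chromosome"].to_numpy(),
        "bin_index": (gmap["position"].to_numpy() - 1) // bin_size_bp,
    })
    is_qtn_marker = np.zeros(len(gmap), dtype=bool)
    is_qtn_marker[qtn_indices] = True
    key = list(zip(binned["bin_chrom"], binned["bin_index"]))
    qtn_bins = {k for k, q in zip(key, is_qtn_marker) if q}
    binned["is_qtn_bin"] = [k in qtn_bins for k in key]
    return binned


def bin_pvalues(scan: ScanResult, bins: pd.DataFrame
                ) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin minimum P value and QTN-bin flags.

    Bins whose members are all undefined (NaN) are excluded.
    """
    df = pd.DataFrame({
        "chrom": bins["bin_chrom"],
        "bin": bins["bin_index"],
        "qtn": bins["is_qtn_bin"],
        "p": scan.p_value,
    })
    grouped = df.groupby(["chrom", "bin"], sort=False).agg(
        p=("p", "min"), qtn=("qtn", "any"))
    grouped = grouped[np.isfinite(grouped["p"])]
    return grouped["p"].to_numpy(), grouped["qtn"].to_numpy()


def _curve(bin_p: np.ndarray, is_qtn_bin: np.ndarray, axis: str,
           bin_size_bp: int) -> EvalCurve:
    is_qtn_bin = np.asarray(is_qtn_bin, dtype=bool)
    n_qtn = int(is_qtn_bin.sum())
    n_null = int((~is_qtn_bin).sum())
    if n_qtn == 0:
        raise ValueError("no QTN bins: cannot compute power")
    if n_null == 0:
        raise ValueError("no non-QTN bins: cost axis undefined")
    thresholds = np.unique(bin_p)
    # counts of bins at or below each threshold, by class
    tp = np.searchsorted(np.sort(bin_p[is_qtn_bin]), thresholds, side="right")
    fp = np.searchsorted(np.sort(bin_p[~is_qtn_bin]), thresholds, side="right")
    power = tp / n_qtn
    if axis == "FDR":
        pos = tp + fp
        with np.errstate(invalid="ignore", divide="ignore"):
            cost = np.where(pos > 0, fp / np.maximum(pos, 1), 0.0)
    elif axis == "type_I_error":
        cost = fp / n_null
    else:
        raise ValueError(f"unknown axis: {axis!r}")
    pts = np.column_stack([cost, power])
    pts = np.vstack([[0.0, 0.0], pts])
    order = np.lexsort((pts[:, 1], pts[:, 0]))
    pts = pts[order]
    pts[:, 1] = np.maximum.accumulate(pts[:, 1])  # power envelope over cost
    if pts[-1, 0] < 1.0:
        pts = np.vstack([pts, [1.0, pts[-1, 1]]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return EvalCurve(axis=axis, points=pts, auc=auc, bin_size_bp=bin_size_bp)


def power_fdr_curve(bin_p: np.ndarray, is_qtn_bin: np.ndarray,
                    bin_size_bp: int = 10_000) -> EvalCurve:
    """Statistical power against FDR, swept over the observed bin P values."""
    return _curve(np.asarray(bin_p, float), is_qtn_bin, "FDR", bin_size_bp)


def power_type1_curve(bin_p: np.ndarray, is_qtn_bin: np.ndarray,
                      bin_size_bp: int = 10_000) -> EvalCurve:
    """Statistical power against empirical type I error (non-QTN-bin tail)."""
    return _curve(np.asarray(bin_p, float), is_qtn_bin, "type_I_error",
                  bin_size_bp)


def evaluate_scan(scan: ScanResult, qtn_indices,
                  bin_sizes_bp=(1, 1_000, 10_000, 100_000)) -> pd.DataFrame:
    """AUC summary over bin sizes and both cost axes for one scan."""
    gmap = pd.DataFrame({
        "chromosome": scan.chromosome,
        "position": scan.position,
    })
    rows = []
    for bs in bin_sizes_bp:
        bins = bin_markers(gmap, qtn_indices, bs)
        bp, qb = bin_pvalues(scan, bins)
        for axis, fn in (("FDR", power_fdr_curve),
                         ("type_I_error", power_type1_curve)):
            curve = fn(bp, qb, bin_size_bp=bs)
            rows.append({"bin_size_bp": bs, "axis": axis, "auc": curve.auc,
                         "n_qtn_bins": int(np.sum(qb)),
                         "n_bins": int(len(bp))})
    return pd.DataFrame(rows)


def enrichment_null(
    n_loci: int,
    region_fraction: float,
    n_overlap_min: int,
    mode: str = "binomial",
    n_samples: int = 100_000,
    seed=0,
    genome_positions: int = 1_000_000,
) -> float:
    """Tail probability of observing >= ``n_overlap_min`` of ``n_loci``
    randomly placed loci inside regions covering ``region_fraction`` of the
    genome.

    ``binomial`` returns the closed form P(X >= x), X ~ Bin(n_loci, f);
    ``monte_carlo`` samples locus sets uniformly over a genome-sized
    position grid carrying a region mask of the same coverage and
    estimates the same tail empirically.
    """
    if not 0.0 < region_fraction < 1.0:
        raise ValueError("region_fraction must lie in (0, 1)")
    if n_overlap_min > n_loci:
        raise ValueError("cannot require more overlaps than loci")
    if n_overlap_min <= 0:
        return 1.0
    if mode == "binomial":
        return float(stats.binom.sf(n_overlap_min - 1, n_loci,
                                    region_fraction))
    if mode == "monte_carlo":
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        n_in = int(round(region_fraction * genome_positions))
        mask = np.zeros(genome_positions, dtype=bool)
        mask[rng.choice(genome_positions, size=n_in, replace=False)] = True
        hits = 0
        batch = 1000
        done = 0
        while done < n_samples:
            b = min(batch, n_samples - done)
            draws = rng.integers(0, genome_positions, size=(b, n_loci))
            overlaps = mask[draws].sum(axis=1)
            hits += int((overlaps >= n_overlap_min).sum())
            done += b
        return hits / n_samples
    raise ValueError(f"unknown mode: {mode!r}")


def overlap_count(loci: pd.DataFrame, genes: pd.DataFrame,
                  window_bp: int = 50_000) -> int:
    """Number of loci within ``window_bp`` (inclusive) of any gene position
    on the same chromosome.

    Both frames need ``chromosome`` and ``position`` columns.
    """
    count = 0
    by_chrom = {c: np.sort(g["position"].to_numpy())
                for c, g in genes.groupby("chromosome")}
    for _, row in loci.iterrows():
        gp = by_chrom.get(row["chromosome"])
        if gp is None:
            continue
        i = np.searchsorted(gp, row["position"])
        near = []
        if i < gp.size:
            near.append(abs(int(gp[i]) - int(row["position"])))
        if i > 0:
            near.append(abs(int(gp[i - 1]) - int(row["position"])))
        if near and min(near) <= window_bp:
            count += 1
    return count
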