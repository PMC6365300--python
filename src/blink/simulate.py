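"""Synthetic genotypes and phenotypes with controlled heritability.

Genotypes are independent biallelic SNPs: each marker's alternate-allele
frequency is drawn uniformly from a configurable range and individual
codes are Binomial(2, freq) draws (Hardy-Weinberg, no LD beyond what
finite sampling induces).  Optional discrete population structure gives
each subpopulation its own allele frequencies around the global one.

Phenotypes follow the standard additive simulation: a set of causal
markers (QTNs) receives normally distributed effects; their dosage-weighted
sum is the genetic value; a normal residual is added whose variance is set
from the *realised* genetic variance so the assigned additive proportion
equals the target heritability.  QTNs can be sampled freely or in pairs
constrained to lie within a fixed distance (default 300 kb), emulating the
clustered genetic architectures that defeat bin-based covariate selection.

All randomness flows from one seed through per-operation child streams, so
a partial re-run of any single operation is stable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GenotypeData


def _rng(seed, salt: int) -> np.random.Generator:
    """Child generator for one operation; pass-through for Generators."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(np.random.SeedSequence([int(seed), salt]))


@dataclass
class SimulatedTrait:
    """A simulated phenotype with its ground truth.

    realized_h2 is var(genetic) / var(phenotype) on this sample; it
    scatters around target_h2 because the residual draw is finite.
    """

    phenotype: np.ndarray
    qtn_indices: np.ndarray
    qtn_effects: np.ndarray
    genetic_values: np.ndarray
    target_h2: float
    realized_h2: float
    seed: int | None

    def truth_frame(self, geno: GenotypeData) -> pd.DataFrame:
        rows = geno.map.iloc[self.qtn_indices].reset_index(drop=True)
        return pd.DataFrame({
            "marker_id": rows["marker_id"],
            "chromosome": rows["chromosome"],
            "position": rows["position"],
            "effect": self.qtn_effects,
        })


def simulate_genotypes(
    n_individuals: int,
    n_markers: int,
    n_chromosomes: int = 10,
    chrom_length_bp: int = 50_000_000,
    maf_range: tuple[float, float] = (0.05, 0.5),
    population_structure: dict | None = None,
    seed=0,
) -> GenotypeData:
    """Independent biallelic SNP genotypes.

    ``population_structure`` may hold ``k_subpops`` and ``divergence`` (an
    F_ST-like scale in (0, 1)); subpopulation frequencies are then drawn
    from a Beta distribution centred on the global frequency with variance
    divergence * p * (1 - p), the Balding-Nichols construction.
    """
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must lie within (0, 0.5]")
    rng = _rng(seed, 1)
    freqs = rng.uniform(lo, hi, size=n_markers)
    if population_structure:
        k = int(population_structure.get("k_subpops", 2))
        fst = float(population_structure.get("divergence", 0.1))
        labels = rng.integers(0, k, size=n_individuals)
        a = freqs * (1.0 - fst) / fst
        b = (1.0 - freqs) * (1.0 - fst) / fst
        sub_freqs = rng.beta(a[:, None], b[:, None], size=(n_markers, k))
        sub_freqs = np.clip(sub_freqs, 1e-6, 1 - 1e-6)
        per_ind = sub_freqs[:, labels]
        codes = rng.binomial(2, per_ind).astype(np.int8)
    else:
        codes = rng.binomial(2, freqs[:, None],
                             size=(n_markers, n_individuals)).astype(np.int8)
    chroms = rng.integers(1, n_chromosomes + 1, size=n_markers)
    positions = rng.integers(1, chrom_length_bp + 1, size=n_markers)
    # zero-padded labels so lexical chromosome order matches numeric order
    gmap = pd.DataFrame({
        "marker_id": [f"snp{i + 1}" for i in range(n_markers)],
        "chromosome": [f"{c:02d}" for c in chroms],
        "position": positions,
    })
    individual_ids = np.array([f"ind{i + 1:06d}" for i in range(n_individuals)],
                              dtype=object)
    return GenotypeData(codes, gmap, individual_ids)


def sample_qtns(
    geno: GenotypeData,
    n_qtn: int,
    clustered: bool = False,
    cluster_distance_bp: int = 300_000,
    seed=0,
    max_retries: int = 1000,
) -> np.ndarray:
    """Sample causal-marker rows, optionally in nearby pairs.

    Unclustered: a simple random sample without replacement.  Clustered:
    n_qtn/2 anchors are drawn and each is paired with a distinct marker on
    the same chromosome within ``cluster_distance_bp``; anchors with no
    eligible partner are redrawn.
    """
    if n_qtn > geno.n_markers:
        raise ValueError("cannot sample more QTNs than markers")
    rng = _rng(seed, 2)
    if not clustered:
        return np.sort(rng.choice(geno.n_markers, size=n_qtn, replace=False))
    if n_qtn % 2:
        raise ValueError("clustered sampling requires an even QTN count")
    chroms = geno.map["chromosome"].to_numpy()
    pos = geno.map["position"].to_numpy()
    chosen: set[int] = set()
    pairs_needed = n_qtn // 2
    retries = 0
    while len(chosen) < n_qtn:
        if retries > max_retries * pairs_needed:
            raise RuntimeError(
                f"could not place {pairs_needed} QTN pairs within "
                f"{cluster_distance_bp} bp; marker map too sparse"
            )
        anchor = int(rng.integers(geno.n_markers))
        retries += 1
        if anchor in chosen:
            continue
        near = np.flatnonzero(
            (chroms == chroms[anchor])
            & (np.abs(pos - pos[anchor]) <= cluster_distance_bp)
        )
        near = near[(near != anchor)
                    & ~np.isin(near, np.fromiter(chosen, int, len(chosen)))]
        if near.size == 0:
            continue
        partner = int(rng.choice(near))
        chosen.add(anchor)
        chosen.add(partner)
    return np.sort(np.fromiter(chosen, int, len(chosen)))


def simulate_phenotype(
    geno: GenotypeData,
    qtn_indices: np.ndarray,
    h2: float = 0.75,
    effect_sd: float = 1.0,
    seed=0,
) -> SimulatedTrait:
    """Additive phenotype with the assigned heritability.

    Effects ~ Normal(0, effect_sd^2); genetic value g_i is the dosage sum;
    residuals ~ Normal(0, var(g) * (1 - h2) / h2) with var(g) the realised
    (population) variance of the genetic values across individuals.
    """
    if not 0.0 < h2 <= 1.0:
        raise ValueError("heritability must lie in (0, 1]")
    qtn_indices = np.asarray(qtn_indices, dtype=int)
    rng = _rng(seed, 3)
    effects = rng.normal(0.0, effect_sd, size=qtn_indices.size)
    from .selection import _impute_rows
    dos = _impute_rows(geno.codes[qtn_indices])
    genetic = effects @ dos
    var_g = float(np.var(genetic))
    if var_g <= 0:
        raise ValueError("zero genetic variance (monomorphic QTNs?)")
    if h2 == 1.0:
        resid = np.zeros_like(genetic)
    else:
        resid_var = var_g * (1.0 - h2) / h2
        resid = rng.normal(0.0, np.sqrt(resid_var), size=genetic.size)
    phenotype = genetic + resid
    realized = var_g / float(np.var(phenotype))
    return SimulatedTrait(
        phenotype=phenotype,
        qtn_indices=qtn_indices,
        qtn_effects=effects,
        genetic_values=genetic,
        target_h2=float(h2),
        realized_h2=float(realized),
        seed=seed if isinstance(seed, int) else None,
    )
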