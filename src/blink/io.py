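"""Genotype, phenotype and covariate containers and file I/O.

Genotypes are biallelic SNPs in additive coding: each cell counts copies of
the alternate allele (0, 1 or 2), with a reserved sentinel for missing calls.
Markers are rows and individuals are columns, matching the per-marker access
pattern of a genome scan.  Marker maps use 1-based base-pair positions.

Supported on-disk dialects:

* ``numeric_table`` — tab- or comma-separated; header row of individual ids;
  first three columns ``marker_id``, ``chromosome``, ``position``; remaining
  cells in {0, 1, 2} or a missing token (``NA``, ``N``, ``-9``, ``.``).
* PLINK 1 binary (``.bed`` variant-major + ``.bim`` + ``.fam``), read and
  written here directly; the code counts A1 alleles (het = 1, hom-A1 = 2).
* phenotype / covariate tables — header row; first column individual id;
  remaining columns numeric.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype call (distinct from the valid codes 0/1/2).
MISSING: int = -9

_MISSING_TOKENS = {"NA", "N", "-9", ".", "nan", ""}

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenotypeError(ValueError):
    """Raised on malformed or inconsistent genotype input."""


@dataclass
class GenotypeData:
    """Additive genotype codes with a marker map.

    Parameters
    ----------
    codes : ndarray of int8, shape (n_markers, n_individuals)
        Counts of the alternate allele; :data:`MISSING` marks no-calls.
    map : DataFrame with columns ``marker_id``, ``chromosome``, ``position``
        One row per marker, aligned with ``codes`` rows.  Sorted by
        (chromosome, position) on construction.
    individual_ids : array of str
    """

    codes: np.ndarray
    map: pd.DataFrame
    individual_ids: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        if self.codes.ndim != 2:
            raise GenotypeError("codes must be a 2-D (markers x individuals) matrix")
        m, n = self.codes.shape
        if len(self.map) != m:
            raise GenotypeError(
                f"map has {len(self.map)} rows but codes has {m} markers"
            )
        if len(self.individual_ids) != n:
            raise GenotypeError(
                f"{len(self.individual_ids)} individual ids for {n} genotype columns"
            )
        if self.map["marker_id"].duplicated().any():
            dup = self.map["marker_id"][self.map["marker_id"].duplicated()].iloc[0]
            raise GenotypeError(f"duplicate marker id: {dup!r}")
        if pd.Index(self.individual_ids).duplicated().any():
            raise GenotypeError("duplicate individual ids")
        if (self.map["position"] < 0).any():
            raise GenotypeError("positions must be non-negative")
        bad = ~np.isin(self.codes, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenotypeError(
                f"invalid genotype code {self.codes[i, j]} at marker row {i}, column {j}"
            )
        # canonical order: (chromosome, position), stable
        order = self.map.reset_index(drop=True).sort_values(
            ["chromosome", "position"], kind="stable"
        ).index.to_numpy()
        if not np.array_equal(order, np.arange(m)):
            self.codes = self.codes[order]
            self.map = self.map.iloc[order].reset_index(drop=True)
        else:
            self.map = self.map.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return self.codes.shape[0]

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[1]

    def take_markers(self, rows: np.ndarray) -> "GenotypeData":
        """Subset to the given marker rows (order preserved by re-sorting)."""
        rows = np.asarray(rows)
        return GenotypeData(
            self.codes[rows].copy(),
            self.map.iloc[rows].reset_index(drop=True),
            self.individual_ids.copy(),
        )

    def take_individuals(self, cols: np.ndarray) -> "GenotypeData":
        cols = np.asarray(cols)
        return GenotypeData(
            self.codes[:, cols].copy(),
            self.map.copy(),
            self.individual_ids[cols].copy(),
        )


@dataclass
class PhenotypeData:
    """A single numeric trait; NaN marks missing observations."""

    individual_ids: np.ndarray
    values: np.ndarray
    name: str = "trait"

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.individual_ids.shape:
            raise GenotypeError("phenotype length must match individual ids")
        if np.isfinite(self.values).sum() < 2:
            raise GenotypeError("need at least 2 non-missing phenotype values")


@dataclass
class CovariateData:
    """Numeric covariates (e.g. principal components); no intercept column."""

    individual_ids: np.ndarray
    values: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.individual_ids):
            self.values = self.values.reshape(len(self.individual_ids), -1)
        if not self.names:
            self.names = [f"cov{i + 1}" for i in range(self.values.shape[1])]


# ---------------------------------------------------------------------------
# numeric-table dialect


def _sniff_sep(path: Path) -> str:
    with open(path) as fh:
        first = fh.readline()
        while first.startswith("#"):
            first = fh.readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_genotypes(path, format: str = "numeric_table") -> GenotypeData:
    """Read genotypes from ``numeric_table`` or ``plink_bed``.

    For ``plink_bed`` the path may be the ``.bed`` file or the shared prefix.
    Unknown cell characters in the numeric table become :data:`MISSING`.
    """
    path = Path(path)
    if format == "numeric_table":
        return _read_numeric_table(path)
    if format == "plink_bed":
        return read_plink(path)
    raise ValueError(f"unknown genotype format: {format!r}")


def _read_numeric_table(path: Path) -> GenotypeData:
    sep = _sniff_sep(path)
    with open(path) as fh:
        lineno = 0
        line = "#"
        while line.startswith("#"):  # skip comment header
            line = fh.readline()
            lineno += 1
        header = line.rstrip("\n").split(sep)
        if len(header) < 4:
            raise GenotypeError(
                f"{path}: header needs marker_id, chromosome, position + individuals"
            )
        individual_ids = header[3:]
        ids, chroms, poss, rows = [], [], [], []
        for lineno, line in enumerate(fh, start=lineno + 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) != len(header):
                raise GenotypeError(
                    f"{path}:{lineno}: expected {len(header)} fields, got {len(parts)}"
                )
            ids.append(parts[0])
            chroms.append(parts[1])
            try:
                poss.append(int(parts[2]))
            except ValueError as exc:
                raise GenotypeError(
                    f"{path}:{lineno}: position {parts[2]!r} is not an integer"
                ) from exc
            row = np.full(len(individual_ids), MISSING, dtype=np.int8)
            for j, tok in enumerate(parts[3:]):
                if tok in ("0", "1", "2"):
                    row[j] = int(tok)
                # any other token (incl. NA/N/-9/.) -> MISSING
            rows.append(row)
    codes = np.vstack(rows) if rows else np.empty((0, len(individual_ids)), np.int8)
    gmap = pd.DataFrame(
        {"marker_id": ids, "chromosome": chroms, "position": poss}
    )
    return GenotypeData(codes, gmap, np.asarray(individual_ids, dtype=object))


def write_genotypes(geno: GenotypeData, path, sep: str = "\t",
                    header_lines: list[str] | None = None) -> None:
    """Write the numeric-table dialect (MISSING printed as NA)."""
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(sep.join(["marker_id", "chromosome", "position",
                           *map(str, geno.individual_ids)]) + "\n")
        for i in range(geno.n_markers):
            row = geno.map.iloc[i]
            cells = [str(c) if c != MISSING else "NA" for c in geno.codes[i]]
            fh.write(sep.join([str(row.marker_id), str(row.chromosome),
                               str(row.position), *cells]) + "\n")


# ---------------------------------------------------------------------------
# PLINK 1 binary (.bed/.bim/.fam), variant-major

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK code -> A1-allele count; 0b01 is the missing code
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)


def _plink_paths(path: Path) -> tuple[Path, Path, Path]:
    prefix = path.with_suffix("") if path.suffix == ".bed" else path
    return (prefix.with_suffix(".bed"), prefix.with_suffix(".bim"),
            prefix.with_suffix(".fam"))


def read_plink(path) -> GenotypeData:
    """Read a PLINK .bed/.bim/.fam triple (variant-major .bed only)."""
    bed, bim, fam = _plink_paths(Path(path))
    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chromosome", "marker_id", "cm", "position", "a1", "a2"],
        dtype={"chromosome": str, "marker_id": str},
    )
    fam_df = pd.read_csv(fam, sep=r"\s+", header=None, dtype=str)
    individual_ids = fam_df.iloc[:, 1].to_numpy(dtype=object)
    n, m = len(individual_ids), len(bim_df)
    raw = np.fromfile(bed, dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeError(f"{bed}: not a variant-major PLINK .bed file")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != m * bpv:
        raise GenotypeError(f"{bed}: size inconsistent with .bim/.fam")
    body = body.reshape(m, bpv)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    two_bit = (body[:, :, None] >> shifts) & 0b11
    codes = _BED_DECODE[two_bit.reshape(m, -1)[:, :n]]
    gmap = bim_df[["marker_id", "chromosome", "position"]].copy()
    return GenotypeData(codes, gmap, individual_ids)


def write_plink(geno: GenotypeData, prefix) -> None:
    """Write .bed/.bim/.fam (fixture/export helper; A1 = alternate allele)."""
    bed, bim, fam = _plink_paths(Path(prefix))
    m, n = geno.codes.shape
    enc = np.zeros((m, n), dtype=np.uint8)
    enc[geno.codes == 2] = 0b00
    enc[geno.codes == 1] = 0b10
    enc[geno.codes == 0] = 0b11
    enc[geno.codes == MISSING] = 0b01
    bpv = (n + 3) // 4
    padded = np.zeros((m, bpv * 4), dtype=np.uint8)
    padded[:, :n] = enc
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
    with open(bed, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.astype(np.uint8).tobytes())
    with open(bim, "w") as fh:
        for i in range(m):
            row = geno.map.iloc[i]
            fh.write(f"{row.chromosome}\t{row.marker_id}\t0\t{row.position}\tA\tG\n")
    with open(fam, "w") as fh:
        for iid in geno.individual_ids:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# phenotype / covariate dialect


def read_phenotype(path, trait: str | None = None) -> PhenotypeData:
    """Read a phenotype table; ``trait`` selects a column (default: first)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#",
                     dtype={0: str}, na_values=sorted(_MISSING_TOKENS))
    col = trait if trait is not None else df.columns[1]
    return PhenotypeData(df.iloc[:, 0].to_numpy(dtype=object),
                         pd.to_numeric(df[col], errors="coerce").to_numpy(),
                         name=str(col))


def write_phenotype(pheno: PhenotypeData, path,
                    header_lines: list[str] | None = None) -> None:
    with open(path, "w") as fh:
        for line in header_lines or []:
            fh.write(f"# {line}\n")
        fh.write(f"individual_id\t{pheno.name}\n")
        for iid, v in zip(pheno.individual_ids, pheno.values):
            fh.write(f"{iid}\t{'NA' if not np.isfinite(v) else repr(float(v))}\n")


def read_covariates(path) -> CovariateData:
    df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype={0: str})
    vals = df.iloc[:, 1:].apply(pd.to_numeric).to_numpy(dtype=float)
    return CovariateData(df.iloc[:, 0].to_numpy(dtype=object), vals,
                         names=list(df.columns[1:]))


# ---------------------------------------------------------------------------
# per-marker statistics and filtering


def compute_maf(geno: GenotypeData, marker_index: int) -> float:
    """Minor allele frequency of one marker over non-missing calls."""
    row = geno.codes[marker_index]
    obs = row[row != MISSING]
    if obs.size == 0:
        raise GenotypeError(
            f"marker {geno.map.marker_id.iloc[marker_index]!r} has no non-missing calls"
        )
    alt = obs.sum() / (2 * obs.size)
    return float(min(alt, 1.0 - alt))


def compute_maf_all(geno: GenotypeData) -> np.ndarray:
    """Vectorised MAF for every marker (NaN where all calls are missing)."""
    miss = geno.codes == MISSING
    n_obs = (~miss).sum(axis=1)
    alt_sum = np.where(miss, 0, geno.codes).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt = alt_sum / (2.0 * n_obs)
    maf = np.minimum(alt, 1.0 - alt)
    maf[n_obs == 0] = np.nan
    return maf


def filter_maf(geno: GenotypeData, threshold: float = 0.05,
               keep_strictly_greater: bool = True) -> GenotypeData:
    """Drop markers with MAF at or below ``threshold``.

    The default semantics keep strictly greater frequencies, i.e. a marker
    whose MAF equals the threshold is removed.
    """
    if not 0.0 <= threshold <= 0.5:
        raise ValueError("MAF threshold must lie in [0, 0.5]")
    maf = compute_maf_all(geno)
    if keep_strictly_greater:
        keep = maf > threshold
    else:
        keep = maf >= threshold
    keep &= np.isfinite(maf)
    return geno.take_markers(np.flatnonzero(keep))


def impute_missing(geno: GenotypeData, policy: str = "mean") -> np.ndarray:
    """Return a dense float matrix with MISSING cells filled per policy.

    ``mean`` fills with the per-marker mean code (keeps correlations and OLS
    well-behaved); ``major_allele`` fills with the per-marker modal code.
    The original integer codes are never modified.
    """
    miss = geno.codes == MISSING
    if (miss.all(axis=1)).any():
        raise GenotypeError("all-missing marker present; filter markers first")
    out = geno.codes.astype(float)
    if not miss.any():
        return out
    if policy == "mean":
        n_obs = (~miss).sum(axis=1)
        fill = np.where(miss, 0, geno.codes).sum(axis=1) / n_obs
    elif policy == "major_allele":
        fill = np.empty(geno.n_markers)
        for i in np.flatnonzero(miss.any(axis=1)):
            obs = geno.codes[i][~miss[i]]
            counts = np.bincount(obs, minlength=3)
            fill[i] = np.argmax(counts)  # ties -> smallest code
        fill[~miss.any(axis=1)] = 0  # unused
    else:
        raise ValueError(f"unknown imputation policy: {policy!r}")
    out[miss] = np.broadcast_to(fill[:, None], out.shape)[miss]
    return out


def align_samples(
    geno: GenotypeData,
    pheno: PhenotypeData,
    covar: CovariateData | None = None,
) -> tuple[GenotypeData, PhenotypeData, CovariateData | None]:
    """Restrict all inputs to shared individuals with observed phenotypes.

    The analysis set is the sorted intersection of ids, minus individuals
    whose phenotype is missing, so the output order is deterministic
    regardless of input order.
    """
    ids = set(geno.individual_ids) & set(pheno.individual_ids)
    if covar is not None:
        ids &= set(covar.individual_ids)
    p_idx = {iid: i for i, iid in enumerate(pheno.individual_ids)}
    ids = {i for i in ids if np.isfinite(pheno.values[p_idx[i]])}
    if not ids:
        raise GenotypeError("no shared individuals with observed phenotypes")
    ordered = sorted(ids)
    g_idx = {iid: i for i, iid in enumerate(geno.individual_ids)}
    geno_a = geno.take_individuals(np.array([g_idx[i] for i in ordered]))
    pheno_a = PhenotypeData(
        np.asarray(ordered, dtype=object),
        pheno.values[[p_idx[i] for i in ordered]],
        name=pheno.name,
    )
    covar_a = None
    if covar is not None:
        c_idx = {iid: i for i, iid in enumerate(covar.individual_ids)}
        vals = covar.values[[c_idx[i] for i in ordered]]
        if vals.shape[1] and (vals.std(axis=0) == 0).any():
            j = int(np.flatnonzero(vals.std(axis=0) == 0)[0])
            raise GenotypeError(
                f"covariate {covar.names[j]!r} is constant on the analysis set"
            )
        covar_a = CovariateData(np.asarray(ordered, dtype=object), vals,
                                names=list(covar.names))
    return geno_a, pheno_a, covar_a
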