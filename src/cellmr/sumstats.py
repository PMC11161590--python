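"""Reading, validation and regional subsetting of GWAS/eQTL summary statistics.

Summary statistics live in pandas DataFrames with canonical columns

    snp, chr, pos, ea, oa, eaf, beta, se, p, n        (GWAS)
    ... plus gene, context                            (eQTL)

Coordinates are 1-based GRCh37 on input; regions are normalized to
half-open ``[start, end)`` internally.  Alleles are upper-case single
bases, with ``beta`` expressed per copy of the effect allele ``ea``.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical column order for GWAS and eQTL tables
GWAS_COLUMNS = ["snp", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "p", "n"]
EQTL_COLUMNS = GWAS_COLUMNS + ["gene", "context"]

#: MHC region excluded from colocalization (GRCh37, closed interval)
MHC_CHROM = "6"
MHC_START = 28477797
MHC_END = 33448354

VALID_ALLELES = frozenset("ACGT")


class InputError(ValueError):
    """Malformed or unusable input data."""


class ConfigurationError(ValueError):
    """Invalid column mapping or parameter configuration."""


@dataclass
class ColumnMap:
    """Maps canonical field names to the column headers of an input file.

    Parameters
    ----------
    mapping
        ``{canonical_name: header_in_file}``.  All canonical required
        fields for the table kind must be present.
    na_values
        Strings treated as missing (in addition to pandas defaults).
    p_floor
        Underflowed p-values (including literal 0) are floored here so
        that log transforms stay finite.
    """

    mapping: dict[str, str]
    na_values: tuple[str, ...] = ("NA", "", ".")
    p_floor: float = 1e-300

    def require(self, fields: list[str]) -> None:
        missing = [f for f in fields if f not in self.mapping]
        if missing:
            raise ConfigurationError(
                f"column map lacks required canonical fields: {missing}"
            )

    @classmethod
    def identity(cls, kind: str = "gwas") -> "ColumnMap":
        cols = EQTL_COLUMNS if kind == "eqtl" else GWAS_COLUMNS
        return cls(mapping={c: c for c in cols})


@dataclass
class Region:
    """A genomic interval, half-open ``[start, end)`` after normalization."""

    chrom: str
    start: int
    end: int
    anchor_gene: str | None = None

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        if self.start > self.end:
            raise InputError(f"region start {self.start} > end {self.end}")

    @classmethod
    def around_gene(
        cls, chrom: str, gene_start: int, gene_end: int, flank: int = 100_000,
        anchor_gene: str | None = None,
    ) -> "Region":
        """Gene body plus ``flank`` bp either side, clamped at position 1."""
        start = max(1, gene_start - flank)
        end = gene_end + flank
        return cls(chrom=str(chrom), start=start, end=end, anchor_gene=anchor_gene)


@dataclass
class LDMatrix:
    """Pairwise genotype correlations for an ordered SNP list."""

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)

    def validate(self, tol: float = 1e-6) -> None:
        p = len(self.snp_ids)
        if self.r.shape != (p, p):
            raise InputError(
                f"LD matrix shape {self.r.shape} does not match {p} SNP ids"
            )
        if not np.allclose(np.diag(self.r), 1.0, atol=tol):
            raise InputError("LD matrix diagonal deviates from 1")
        if not np.allclose(self.r, self.r.T, atol=tol):
            raise InputError("LD matrix is not symmetric")

    def subset(self, snp_ids: list[str]) -> "LDMatrix":
        index = {s: i for i, s in enumerate(self.snp_ids)}
        missing = [s for s in snp_ids if s not in index]
        if missing:
            raise InputError(f"SNPs absent from LD matrix: {missing[:5]}...")
        idx = np.array([index[s] for s in snp_ids])
        return LDMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def r2(self, a: str, b: str) -> float:
        index = {s: i for i, s in enumerate(self.snp_ids)}
        return float(self.r[index[a], index[b]] ** 2)


@dataclass
class ReadReport:
    """Per-file validation bookkeeping from :func:`read_sumstats`."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)


def _validate_frame(df: pd.DataFrame, p_floor: float) -> tuple[pd.DataFrame, ReadReport]:
    report = ReadReport(n_read=len(df))
    df = df.copy()
    df["ea"] = df["ea"].astype(str).str.upper()
    df["oa"] = df["oa"].astype(str).str.upper()
    df["chr"] = df["chr"].astype(str).str.removeprefix("chr")

    for col in ("pos", "eaf", "beta", "se", "p", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    # underflowed p prints as 0 or denormal; floor keeps -log10 finite
    df.loc[df["p"].notna() & (df["p"] < p_floor), "p"] = p_floor

    checks = {
        "bad_alleles": ~(df["ea"].isin(VALID_ALLELES) & df["oa"].isin(VALID_ALLELES))
        | (df["ea"] == df["oa"]),
        "bad_se": ~(df["se"] > 0),
        "bad_p": ~((df["p"] > 0) & (df["p"] <= 1)),
        "bad_pos": ~(df["pos"] >= 1),
        "bad_n": ~(df["n"] > 0),
        "bad_eaf": df["eaf"].notna() & ~df["eaf"].between(0, 1),
        "missing_beta": df["beta"].isna(),
    }
    bad = pd.Series(False, index=df.index)
    for reason, mask in checks.items():
        newly = mask & ~bad
        if newly.any():
            report.dropped[reason] = int(newly.sum())
        bad |= mask
    df = df[~bad]

    # duplicate snp ids: deterministic resolution, keep the smallest p
    if df["snp"].duplicated().any():
        n_dup = int(df["snp"].duplicated().sum())
        report.dropped["duplicate_snp"] = n_dup
        df = df.sort_values(["p", "snp"], kind="mergesort").drop_duplicates("snp")

    df = df.sort_values(["chr", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    df["n"] = df["n"].astype(float)
    report.n_kept = len(df)
    return df, report


def read_sumstats(
    path: str | Path,
    colmap: ColumnMap | None = None,
    kind: str = "gwas",
) -> tuple[pd.DataFrame, ReadReport]:
    """Read a delimited summary-statistics file into canonical form.

    Rows violating the type invariants (``se <= 0``, invalid alleles,
    p outside ``(0, 1]``, ...) are dropped and counted in the returned
    :class:`ReadReport`.  Tab- and comma-delimited text is accepted,
    gzip-transparently.
    """
    if kind not in ("gwas", "eqtl"):
        raise ConfigurationError(f"unknown table kind {kind!r}")
    colmap = colmap or ColumnMap.identity(kind)
    required = EQTL_COLUMNS if kind == "eqtl" else GWAS_COLUMNS
    colmap.require(required)

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    raw = pd.read_csv(
        path, sep=None, engine="python", na_values=list(colmap.na_values),
        compression="infer",
    )
    missing = [colmap.mapping[f] for f in required if colmap.mapping[f] not in raw.columns]
    if missing:
        raise ConfigurationError(f"mapped columns absent from {path.name}: {missing}")
    df = raw.rename(columns={v: k for k, v in colmap.mapping.items()})[required]

    df, report = _validate_frame(df, colmap.p_floor)
    if report.n_kept == 0:
        raise InputError(f"no valid rows in {path}")
    logger.info(
        "read %s: %d rows, %d kept, dropped %s",
        path.name, report.n_read, report.n_kept, report.dropped or "none",
    )
    return df, report


def write_sumstats(df: pd.DataFrame, path: str | Path) -> None:
    """Write canonical TSV (gzip if the suffix says so)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def extract_region(df: pd.DataFrame, region: Region) -> pd.DataFrame:
    """Rows with matching chromosome and ``start <= pos < end``."""
    mask = (
        (df["chr"].astype(str) == region.chrom)
        & (df["pos"] >= region.start)
        & (df["pos"] < region.end)
    )
    return df[mask].reset_index(drop=True)


def exclude_mhc(df: pd.DataFrame) -> pd.DataFrame:
    """Drop variants in the MHC region chr6:28,477,797-33,448,354 (GRCh37).

    The interval is closed on both ends, matching the convention of the
    published coordinates.
    """
    mask = (
        (df["chr"].astype(str) == MHC_CHROM)
        & (df["pos"] >= MHC_START)
        & (df["pos"] <= MHC_END)
    )
    return df[~mask].reset_index(drop=True)


def load_ld(matrix_file: str | Path, snp_file: str | Path) -> LDMatrix:
    """Load an LD matrix from a whitespace-delimited square matrix plus a
    one-id-per-line SNP list, validating symmetry and unit diagonal."""
    r = np.loadtxt(matrix_file, ndmin=2)
    snp_ids = [line.strip() for line in Path(snp_file).read_text().splitlines() if line.strip()]
    ld = LDMatrix(snp_ids, r)
    ld.validate(tol=1e-6)
    return ld


def ld_from_genotypes(vcf_path: str | Path, snp_ids: list[str]) -> LDMatrix:
    """Compute an LD matrix as the Pearson correlation of allele dosages
    from a reference VCF.

    Multiallelic and monomorphic sites are skipped with a warning; SNPs
    absent from the VCF are reported in the log and excluded.  Requires
    at least two samples.
    """
    from cyvcf2 import VCF

    wanted = set(snp_ids)
    dosages: dict[str, np.ndarray] = {}
    vcf = VCF(str(vcf_path), gts012=True)
    if len(vcf.samples) < 2:
        raise InputError("LD estimation needs at least 2 reference samples")
    for variant in vcf:
        vid = variant.ID
        if vid not in wanted:
            continue
        if len(variant.ALT) != 1:
            logger.warning("skipping multiallelic site %s", vid)
            continue
        gt = np.asarray(variant.gt_types, dtype=float)
        gt[gt == 3] = np.nan  # unknown genotype sentinel under gts012
        if np.nanstd(gt) == 0:
            logger.warning("monomorphic site %s dropped from LD", vid)
            continue
        dosages[vid] = gt
    vcf.close()

    present = [s for s in snp_ids if s in dosages]
    absent = [s for s in snp_ids if s not in dosages]
    if absent:
        logger.info("%d SNPs absent from the reference VCF: %s", len(absent), absent[:5])
    if not present:
        raise InputError("none of the requested SNPs usable for LD")
    mat = np.vstack([dosages[s] for s in present])
    if len(present) == 1:
        return LDMatrix(present, np.ones((1, 1)))
    # pairwise-complete Pearson correlation of dosages
    masked = np.ma.masked_invalid(mat)
    r = np.ma.corrcoef(masked).filled(0.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(present, r)
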