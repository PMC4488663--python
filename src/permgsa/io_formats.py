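"""Readers and writers for the external file formats.

PLINK 1 binary trios (.bed/.bim/.fam, SNP-major only), whitespace-delimited
gene-set files (one set per line: name followed by gene symbols), gene
location tables, PLINK-style covariate files, two-column summary-statistic
files, and the tab-separated results table.

The .bed codec follows the PLINK 1 spec: magic bytes 0x6C 0x1B, mode byte
0x01, then one SNP per record, two bits per sample packed little-endian
(00 = hom allele1, 01 = missing, 10 = het, 11 = hom allele2), mapped here
to counts of allele1 {2, missing, 1, 0}.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    MISSING_GENOTYPE,
    CovariateTable,
    GeneLocation,
    GeneSetCollection,
    GenotypeDataset,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B])
_BED_SNP_MAJOR = 0x01

# 2-bit code -> count of allele1 (A1); -1 = missing
_CODE_TO_COUNT = np.array([2, MISSING_GENOTYPE, 1, 0], dtype=np.int8)
_COUNT_TO_CODE = {2: 0b00, MISSING_GENOTYPE: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported PLINK binary files."""


def _decode_phenotype(raw: pd.Series) -> tuple[np.ndarray, bool]:
    """PLINK .fam phenotype column -> (float vector, binary flag).

    1 = control, 2 = case, -9/0 = missing; anything else quantitative.
    """
    vals = pd.to_numeric(raw, errors="raise").to_numpy(dtype=float)
    nonmissing = vals[(vals != -9) & (vals != 0)]
    binary = len(nonmissing) == 0 or bool(np.isin(nonmissing, [1.0, 2.0]).all())
    out = vals.copy()
    if binary:
        out[(vals == -9) | (vals == 0)] = np.nan
        out[vals == 1] = 0.0
        out[vals == 2] = 1.0
    else:
        out[vals == -9] = np.nan
    return out, binary


def _encode_phenotype(phenotype: np.ndarray, binary: bool) -> np.ndarray:
    out = np.where(np.isnan(phenotype), -9.0, phenotype)
    if binary:
        out = np.where(np.isnan(phenotype), -9.0, phenotype + 1.0)
    return out


def read_plink_binary(prefix) -> GenotypeDataset:
    """Read a PLINK binary trio ``prefix``.bed/.bim/.fam into memory."""
    prefix = Path(prefix)
    paths = {ext: prefix.with_suffix(f".{ext}") for ext in ("bed", "bim", "fam")}
    for ext, path in paths.items():
        if not path.exists():
            raise FileNotFoundError(f"missing PLINK {ext} file: {path}")

    fam = pd.read_csv(
        paths["fam"],
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    bim = pd.read_csv(
        paths["bim"],
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "allele1", "allele2"],
        dtype={"chrom": str, "snp_id": str, "allele1": str, "allele2": str},
    )
    n_samples, n_snps = len(fam), len(bim)

    raw = paths["bed"].read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise PlinkFormatError(f"{paths['bed']}: bad magic bytes, not a PLINK .bed file")
    if raw[2] != _BED_SNP_MAJOR:
        raise PlinkFormatError(
            f"{paths['bed']}: mode byte 0x{raw[2]:02X}; only SNP-major (0x01) is supported"
        )
    bytes_per_snp = (n_samples + 3) // 4
    expected = 3 + bytes_per_snp * n_snps
    if len(raw) != expected:
        raise PlinkFormatError(
            f"{paths['bed']}: payload is {len(raw) - 3} bytes but .bim/.fam imply "
            f"{bytes_per_snp * n_snps} ({n_snps} SNPs x {bytes_per_snp} bytes)"
        )

    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_snps, bytes_per_snp)
    # unpack the four 2-bit fields of every byte, low bits first
    codes = np.empty((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (packed >> (2 * k)) & 0b11
    genotypes = _CODE_TO_COUNT[codes[:, :n_samples]].T.copy()  # samples x snps

    phen, binary = _decode_phenotype(fam["phenotype"])
    samples = pd.DataFrame({"fid": fam["fid"], "iid": fam["iid"], "phenotype": phen})
    snps = bim[["snp_id", "chrom", "pos_bp", "allele1", "allele2"]].copy()
    return GenotypeDataset(samples=samples, snps=snps, genotypes=genotypes, binary_trait=binary)


def write_plink_binary(data: GenotypeDataset, prefix) -> None:
    """Write ``data`` as a PLINK binary trio (SNP-major .bed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    phen = _encode_phenotype(data.phenotype, data.binary_trait)
    fam = pd.DataFrame(
        {
            "fid": data.samples["fid"],
            "iid": data.samples["iid"],
            "pat": "0",
            "mat": "0",
            "sex": 0,
            "phenotype": phen,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)
    bim = pd.DataFrame(
        {
            "chrom": data.snps["chrom"],
            "snp_id": data.snps["snp_id"],
            "cm": 0,
            "pos_bp": data.snps["pos_bp"],
            "allele1": data.snps["allele1"],
            "allele2": data.snps["allele2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    n_samples, n_snps = data.genotypes.shape
    bytes_per_snp = (n_samples + 3) // 4
    code_lut = np.zeros(4, dtype=np.uint8)
    for count, code in _COUNT_TO_CODE.items():
        code_lut[count % 4] = code  # -1 -> index 3
    codes = code_lut[data.genotypes.T % 4]  # snps x samples
    padded = np.zeros((n_snps, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n_samples] = codes
    packed = np.zeros((n_snps, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(bytes([_BED_SNP_MAJOR]))
        fh.write(packed.tobytes())


def read_gene_sets(path) -> GeneSetCollection:
    """Read a whitespace-delimited gene-set file.

    One set per line: the first token is the set name, remaining tokens are
    gene symbols.  Duplicate genes within a line are collapsed with a
    warning; a duplicate set name is an error.
    """
    sets: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            name, genes = tokens[0], tokens[1:]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) < len(genes):
                logger.warning(
                    "%s:%d: set %s lists %d duplicate gene(s); collapsed",
                    path, lineno, name, len(genes) - len(deduped),
                )
            if not deduped:
                logger.warning("%s:%d: set %s has an empty gene list", path, lineno, name)
            sets[name] = deduped
    return GeneSetCollection(sets=sets)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection:
            fh.write("\t".join([name, *genes]) + "\n")


def read_gene_locations(path) -> list[GeneLocation]:
    """Read a gene-location table: gene_id, chrom, start, end[, strand].

    Coordinates are normalized so start <= end (swapped with a warning).
    """
    genes: list[GeneLocation] = []
    seen: set = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens or tokens[0].startswith("#"):
                continue
            if len(tokens) < 4:
                raise ValueError(f"{path}:{lineno}: expected >= 4 columns, got {len(tokens)}")
            gene_id, chrom = tokens[0], tokens[1]
            try:
                start, end = int(tokens[2]), int(tokens[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinate") from exc
            strand = tokens[4] if len(tokens) > 4 else None
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if start > end:
                logger.warning("%s:%d: %s start > end; coordinates swapped", path, lineno, gene_id)
                start, end = end, start
            genes.append(GeneLocation(gene_id=gene_id, chrom=chrom, tss=start, tes=end, strand=strand))
    return genes


def write_gene_locations(genes: list[GeneLocation], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            strand = g.strand if g.strand is not None else "."
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.tss}\t{g.tes}\t{strand}\n")


def read_covariates(path) -> CovariateTable:
    """Read a PLINK-style covariate file: FID IID then numeric columns."""
    df = pd.read_csv(path, sep=r"\s+", dtype={0: str, 1: str})
    cols = list(df.columns)
    if [c.upper() for c in cols[:2]] != ["FID", "IID"]:
        raise ValueError(f"{path}: first two columns must be FID and IID (got {cols[:2]})")
    df = df.rename(columns={cols[0]: "fid", cols[1]: "iid"})
    df = df.set_index(["fid", "iid"])
    return CovariateTable(table=df.astype(float))


def read_summary_stats(path) -> dict:
    """Read a two-column summary-statistics file: snp_id, p-value."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["snp_id", "p"],
                     dtype={"snp_id": str}, comment="#")
    pvals = pd.to_numeric(df["p"], errors="coerce")
    if len(df) and np.isnan(pvals.iloc[0]):  # tolerate one header line
        df, pvals = df.iloc[1:], pvals.iloc[1:]
    if pvals.isna().any():
        raise ValueError(f"{path}: non-numeric p-value entries")
    bad = (pvals <= 0) | (pvals > 1)
    if bad.any():
        raise ValueError(f"{path}: p-values outside (0, 1]")
    return dict(zip(df["snp_id"], pvals.astype(float)))


RESULT_COLUMNS = [
    "set_name", "n_genes", "n_snps", "n_eff_snps", "statistic",
    "p_self", "p_competitive", "n_perm", "n_draws",
]


def _fmt(x) -> str:
    if x is None:
        return ""
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def write_results(results, path) -> None:
    """Write gene-set results as a TSV table (floats at 6 significant digits)."""
    if not results:
        raise ValueError("no results to write")
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for r in results:
            row = [
                r.set_name, r.n_genes, r.m_obs, _fmt(r.m_eff), _fmt(float(r.statistic)),
                _fmt(r.p_self), _fmt(r.p_comp), r.nperms, r.n_draws,
            ]
            fh.write("\t".join(str(_fmt(v)) if not isinstance(v, str) else v for v in row) + "\n")


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    return pd.read_csv(path, sep="\t")
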