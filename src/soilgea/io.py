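"""Genotype, metadata and soil-table containers plus readers/writers.

Genotypes are diploid allele dosages (0/1/2 copies of the alternate
allele) with missing calls stored as -1 in an int8 matrix.  The
:class:`GenotypeMatrix` is the universal response object passed between
all analysis stages; soil chemistry travels as a plain
:class:`pandas.DataFrame` indexed by site/population id.
"""

from __future__ import annotations

import io as _io
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: canonical metadata columns
META_COLUMNS = ["sample_id", "population", "longitude", "latitude", "elevation", "scale"]


class SoilGEAError(Exception):
    """Base error for this package."""


class ConfigurationError(SoilGEAError):
    pass


@dataclass
class GenotypeMatrix:
    """Samples x loci diploid dosage matrix.

    Parameters
    ----------
    dosage : ndarray of int8, shape (n_samples, n_loci)
        Alternate-allele counts in {0, 1, 2}; ``-1`` marks a missing call.
    sample_ids, locus_ids : sequences of str
    """

    dosage: np.ndarray
    sample_ids: list = field(default_factory=list)
    locus_ids: list = field(default_factory=list)
    ploidy: int = 2

    def __post_init__(self):
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        self.sample_ids = list(self.sample_ids)
        self.locus_ids = list(self.locus_ids)
        n, m = self.dosage.shape
        if len(self.sample_ids) != n or len(self.locus_ids) != m:
            raise ConfigurationError(
                f"dimension mismatch: dosage {self.dosage.shape}, "
                f"{len(self.sample_ids)} sample ids, {len(self.locus_ids)} locus ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ConfigurationError("duplicate sample ids")
        if len(set(self.locus_ids)) != m:
            raise ConfigurationError("duplicate locus ids")
        bad = (self.dosage < MISSING) | (self.dosage > self.ploidy)
        if bad.any():
            raise ConfigurationError("dosage values outside {0,1,2} u {missing}")

    # ------------------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def missing_mask(self) -> np.ndarray:
        return self.dosage == MISSING

    def dosage_float(self) -> np.ndarray:
        """Dosages as float with NaN for missing calls."""
        out = self.dosage.astype(float)
        out[self.missing_mask] = np.nan
        return out

    def subset_loci(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:  # locus ids
            pos = {l: i for i, l in enumerate(self.locus_ids)}
            idx = np.array([pos[l] for l in keep], dtype=int)
        return GenotypeMatrix(
            self.dosage[:, idx],
            self.sample_ids,
            [self.locus_ids[i] for i in idx],
        )

    def subset_samples(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        elif keep.dtype.kind in "iu":
            idx = keep
        else:
            pos = {s: i for i, s in enumerate(self.sample_ids)}
            idx = np.array([pos[s] for s in keep], dtype=int)
        return GenotypeMatrix(
            self.dosage[idx], [self.sample_ids[i] for i in idx], self.locus_ids
        )

    def reorder_samples(self, sample_ids) -> "GenotypeMatrix":
        return self.subset_samples(np.asarray(sample_ids, dtype=object))

    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per locus over non-missing calls."""
        d = self.dosage_float()
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / self.ploidy

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.copy(), list(self.sample_ids), list(self.locus_ids))


# ----------------------------------------------------------------------
# VCF
# ----------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=soilgea
##contig=<ID=1>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""

_GT_CODES = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(G: GenotypeMatrix, path: str) -> str:
    """Write an uncompressed VCFv4.2 with unphased diploid GT fields."""
    buf = _io.StringIO()
    buf.write(_VCF_HEADER)
    buf.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
    buf.write("\t".join(str(s) for s in G.sample_ids))
    buf.write("\n")
    for j, locus in enumerate(G.locus_ids):
        calls = "\t".join(_GT_CODES[int(g)] for g in G.dosage[:, j])
        buf.write(f"1\t{j + 1}\t{locus}\tA\tT\t.\t.\t.\tGT\t{calls}\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
    return path


def read_vcf(path: str) -> GenotypeMatrix:
    """Read diploid GT dosages from a VCF via cyvcf2."""
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    loci, rows = [], []
    for var in vcf:
        loci.append(var.ID if var.ID else f"{var.CHROM}:{var.POS}")
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2; 3 = unknown
        gt[gt == 3] = MISSING
        rows.append(gt)
    vcf.close()
    dosage = np.vstack(rows).T if rows else np.zeros((len(samples), 0), dtype=np.int8)
    return GenotypeMatrix(dosage, samples, loci)


# ----------------------------------------------------------------------
# Dosage TSV / metadata / soil
# ----------------------------------------------------------------------

def write_dosage_tsv(G: GenotypeMatrix, path: str) -> str:
    df = pd.DataFrame(G.dosage, index=G.sample_ids, columns=G.locus_ids)
    df = df.replace(MISSING, pd.NA)
    df.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")
    return path


def read_dosage_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values="NA")
    dosage = df.to_numpy(dtype=float)
    out = np.where(np.isnan(dosage), MISSING, dosage).astype(np.int8)
    return GenotypeMatrix(out, [str(s) for s in df.index], list(df.columns))


def read_metadata(path: str) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    missing = [c for c in META_COLUMNS if c not in meta.columns]
    if missing:
        raise ConfigurationError(f"metadata file {path} lacks columns {missing}")
    return meta


def write_metadata(meta: pd.DataFrame, path: str) -> str:
    meta.to_csv(path, sep="\t", index=False)
    return path


def read_soil(path: str) -> pd.DataFrame:
    soil = pd.read_csv(path, index_col=0)
    soil.index = soil.index.astype(str)
    if soil.isna().any().any():
        raise ConfigurationError(f"soil table {path} contains missing cells")
    return soil


def write_soil(soil: pd.DataFrame, path: str) -> str:
    soil.to_csv(path, index_label="site")
    return path


def align(G: GenotypeMatrix, meta: pd.DataFrame) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Align genotypes and metadata on sample id (metadata order wins)."""
    ids = [s for s in meta["sample_id"] if s in set(G.sample_ids)]
    if len(ids) != G.n_samples or len(ids) != len(meta):
        missing_g = set(meta["sample_id"]) - set(G.sample_ids)
        missing_m = set(G.sample_ids) - set(meta["sample_id"])
        if missing_g or missing_m:
            raise ConfigurationError(
                f"sample id mismatch: {sorted(missing_g)[:5]} absent from genotypes, "
                f"{sorted(missing_m)[:5]} absent from metadata"
            )
    meta = meta.set_index("sample_id").loc[ids].reset_index()
    return G.reorder_samples(ids), meta


def soil_by_sample(soil: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Broadcast a site-level soil table to one row per sample."""
    pops = meta["population"].astype(str)
    missing = set(pops) - set(soil.index)
    if missing:
        raise ConfigurationError(f"soil table lacks populations {sorted(missing)}")
    out = soil.loc[pops].reset_index(drop=True)
    out.index = meta["sample_id"]
    return out
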