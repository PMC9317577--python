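"""Streaming reader/writer for PLINK 1.9 binary genotype filesets.

The .bed file is SNP-major, two bits per genotype, little-endian within
each byte: 00 = homozygous A1, 01 = missing, 10 = heterozygous,
11 = homozygous A2; each SNP's genotypes are padded to a whole number of
bytes.  Dosages are returned as minor-allele counts in {0, 1, 2} with -1
for missing; genotypes are decoded one SNP at a time so the peak genotype
memory is O(N) regardless of the number of SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PlinkFormatError", "GenotypePanel", "open_plink", "snp_maf", "write_plink"]

_MAGIC = bytes([0x6C, 0x1B])
#: 2-bit code -> count of the A1 allele (-1 = missing)
_CODE_TO_A1_COUNT = np.array([2, -1, 1, 0], dtype=np.int8)
_A1_COUNT_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """A PLINK fileset violates the binary format contract."""


@dataclass(frozen=True)
class SnpRecord:
    index: int
    snp: str
    chrom: str
    pos: int
    minor_allele: str
    major_allele: str
    flipped: bool  # True when A2 is the minor allele


class GenotypePanel:
    """Lazy per-SNP access to a PLINK .bed/.bim/.fam fileset."""

    def __init__(self, prefix: str):
        self.prefix = str(prefix)
        self.bim = pd.read_csv(
            f"{prefix}.bim", sep=r"\s+", header=None, names=BIM_COLUMNS,
            dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
        )
        self.fam = pd.read_csv(
            f"{prefix}.fam", sep=r"\s+", header=None, names=FAM_COLUMNS,
            dtype={"fid": str, "iid": str},
        )
        if self.fam.iid.duplicated().any():
            dup = self.fam.iid[self.fam.iid.duplicated()].iloc[0]
            raise PlinkFormatError(f"{prefix}.fam: duplicate sample ID {dup!r}")
        self.n_samples = len(self.fam)
        self.n_snps = len(self.bim)
        self._bytes_per_snp = (self.n_samples + 3) // 4
        with open(f"{prefix}.bed", "rb") as fh:
            header = fh.read(3)
            fh.seek(0, 2)
            size = fh.tell()
        if header[:2] != _MAGIC:
            raise PlinkFormatError(f"{prefix}.bed: bad magic bytes {header[:2]!r}")
        if header[2] != 0x01:
            raise PlinkFormatError(
                f"{prefix}.bed: only SNP-major mode (0x01) is supported"
            )
        expected = 3 + self._bytes_per_snp * self.n_snps
        if size != expected:
            raise PlinkFormatError(
                f"{prefix}.bed: {size} bytes on disk, expected {expected} "
                f"for {self.n_samples} samples x {self.n_snps} SNPs"
            )
        self._fh = open(f"{prefix}.bed", "rb")

    @property
    def sample_ids(self):
        return list(self.fam.iid)

    def raw_a1_counts(self, idx: int) -> np.ndarray:
        """A1-allele counts for SNP ``idx`` ({0,1,2}, -1 missing), length N."""
        self._fh.seek(3 + idx * self._bytes_per_snp)
        buf = np.frombuffer(self._fh.read(self._bytes_per_snp), dtype=np.uint8)
        codes = np.empty(self._bytes_per_snp * 4, dtype=np.uint8)
        for k in range(4):  # little-endian 2-bit fields
            codes[k::4] = (buf >> (2 * k)) & 0b11
        return _CODE_TO_A1_COUNT[codes[: self.n_samples]]

    def dosages(self, idx: int):
        """Minor-allele dosages for SNP ``idx`` plus its metadata record."""
        g = self.raw_a1_counts(idx).copy()
        row = self.bim.iloc[idx]
        obs = g >= 0
        n_obs = int(obs.sum())
        flipped = False
        if n_obs:
            freq_a1 = g[obs].sum() / (2.0 * n_obs)
            if freq_a1 > 0.5:
                flipped = True
                g[obs] = 2 - g[obs]
        minor, major = (row.a2, row.a1) if flipped else (row.a1, row.a2)
        rec = SnpRecord(
            index=idx, snp=row.snp, chrom=row.chrom, pos=int(row.pos),
            minor_allele=str(minor), major_allele=str(major), flipped=flipped,
        )
        return rec, g

    def __iter__(self):
        for idx in range(self.n_snps):
            yield self.dosages(idx)

    def close(self):
        self._fh.close()

    def __enter__(self):
        return self

    def __exit__(self, *exc):
        self.close()


def open_plink(prefix: str) -> GenotypePanel:
    """Open a PLINK binary fileset for lazy per-SNP streaming."""
    return GenotypePanel(prefix)


def snp_maf(g) -> tuple[float, int]:
    """Minor-allele frequency and effective N of a dosage vector.

    Missing dosages (negative) are excluded; the returned frequency is
    always <= 0.5.  A monomorphic SNP returns f = 0.
    """
    g = np.asarray(g)
    obs = g >= 0
    n_eff = int(obs.sum())
    if n_eff == 0:
        return 0.0, 0
    f = float(g[obs].sum()) / (2.0 * n_eff)
    return min(f, 1.0 - f), n_eff


def write_plink(prefix: str, dosages: np.ndarray, sample_ids=None, bim: pd.DataFrame | None = None) -> None:
    """Write dosage rows (SNP-major, {0,1,2}, -1 missing) as a PLINK fileset.

    Dosages are stored as A1-allele counts, so a decode round-trips exactly.
    """
    dosages = np.asarray(dosages)
    m, n = dosages.shape
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n)]
    fam = pd.DataFrame(
        {"fid": sample_ids, "iid": sample_ids, "father": 0, "mother": 0,
         "sex": 0, "phenotype": -9}
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)
    if bim is None:
        bim = pd.DataFrame(
            {"chrom": "1", "snp": [f"snp{j + 1}" for j in range(m)], "cm": 0,
             "pos": np.arange(1, m + 1) * 1000, "a1": "A", "a2": "B"}
        )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    nbytes = (n + 3) // 4
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_MAGIC + bytes([0x01]))
        for j in range(m):
            codes = np.zeros(nbytes * 4, dtype=np.uint8)
            for i, dose in enumerate(dosages[j]):
                codes[i] = _A1_COUNT_TO_CODE[int(dose)]
            buf = np.zeros(nbytes, dtype=np.uint8)
            for k in range(4):
                buf |= codes[k::4] << (2 * k)
            fh.write(buf.tobytes())
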