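"""Genotype input/output: VCF reading, -1/0/1 coding, MAF filtering, SNP-set definitions.

Genotypes are coded -1 (homozygous reference), 0 (heterozygous), 1
(homozygous alternative).  Only bi-allelic diploid SNPs are supported;
missing calls are rejected rather than imputed — run an imputation tool
upstream if the VCF has gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MarkerGenotypes:
    """An n-samples x m-markers genotype-code matrix plus a marker map.

    Attributes
    ----------
    samples : list of str
        Sample identifiers, length n.
    markers : list of str
        Marker identifiers, length m.
    chrom : ndarray of str
        Per-marker chromosome label.
    pos : ndarray of int
        Per-marker physical position, base pairs, 1-based.
    ref_allele, alt_allele : ndarray of str
        Per-marker allele strings.
    codes : ndarray, shape (n, m), int8
        Genotype codes in {-1, 0, 1}.
    """

    samples: list[str]
    markers: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    codes: np.ndarray

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def validate(self) -> None:
        """Check the container invariants; raise ValueError on violation."""
        n, m = self.codes.shape
        if n != len(self.samples) or m != len(self.markers):
            raise ValueError("codes shape does not match samples/markers")
        if not np.isin(self.codes, (-1, 0, 1)).all():
            raise ValueError("genotype codes must be in {-1, 0, 1}")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(m)):
            raise ValueError("markers must be sorted by (chrom, pos)")
        key = list(zip(self.chrom, self.pos, self.alt_allele))
        if len(set(key)) != m:
            raise ValueError("duplicate (chrom, pos, alt) marker")

    def subset_markers(self, idx: np.ndarray) -> "MarkerGenotypes":
        """Return a new container restricted to marker indices ``idx`` (order kept)."""
        idx = np.asarray(idx)
        return MarkerGenotypes(
            samples=list(self.samples),
            markers=[self.markers[i] for i in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            codes=self.codes[:, idx],
        )


@dataclass
class SnpSet:
    """An ordered group of markers tested jointly as one variance component.

    ``marker_indices`` index into a :class:`MarkerGenotypes`; the span is the
    1-based inclusive base-pair interval covered by the members.
    """

    set_id: str
    marker_indices: np.ndarray
    chrom: str
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        self.marker_indices = np.asarray(self.marker_indices, dtype=int)
        if self.marker_indices.size < 1:
            raise ValueError(f"SNP-set {self.set_id}: empty")
        if np.any(np.diff(self.marker_indices) <= 0):
            raise ValueError(f"SNP-set {self.set_id}: indices not strictly increasing")

    @property
    def size(self) -> int:
        return int(self.marker_indices.size)


_GT_CODE = {(0, 0): -1, (0, 1): 0, (1, 0): 0, (1, 1): 1}


def read_vcf(path: str, maf_min: float = 0.025) -> MarkerGenotypes:
    """Read a VCF into -1/0/1 codes, keeping bi-allelic SNPs with MAF >= ``maf_min``.

    Multi-allelic records are dropped (count logged).  Missing or
    half-missing genotype calls raise ``ValueError`` naming the record and
    sample: imputation is deliberately out of scope.
    """
    from cyvcf2 import VCF

    if not 0.0 <= maf_min <= 0.5:
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)
    rows: list[dict] = []
    codes_cols: list[np.ndarray] = []
    n_multi = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        col = np.empty(n, dtype=np.int8)
        for j, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                raise ValueError(
                    f"missing genotype at {rec.CHROM}:{rec.POS} sample {samples[j]}"
                    " (imputation is out of scope; impute upstream)"
                )
            col[j] = _GT_CODE[(min(a, 1), min(b, 1))]
        rows.append(
            {
                "id": rec.ID if rec.ID else f"{rec.CHROM}_{rec.POS}",
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref": rec.REF,
                "alt": rec.ALT[0],
            }
        )
        codes_cols.append(col)
    if n_multi:
        logger.info("dropped %d multi-allelic records", n_multi)
    if not rows:
        raise ValueError(f"no bi-allelic SNP records in {path}")
    tab = pd.DataFrame(rows)
    codes = np.column_stack(codes_cols)
    order = np.lexsort((tab["pos"].to_numpy(), tab["chrom"].to_numpy()))
    tab = tab.iloc[order].reset_index(drop=True)
    codes = codes[:, order]
    geno = MarkerGenotypes(
        samples=samples,
        markers=tab["id"].tolist(),
        chrom=tab["chrom"].to_numpy(dtype=object),
        pos=tab["pos"].to_numpy(dtype=int),
        ref_allele=tab["ref"].to_numpy(dtype=object),
        alt_allele=tab["alt"].to_numpy(dtype=object),
        codes=codes,
    )
    geno = filter_maf(geno, maf_min)
    if geno.n_markers == 0:
        raise ValueError(f"no markers left after MAF >= {maf_min} filter")
    return geno


def minor_allele_freq(geno: MarkerGenotypes) -> np.ndarray:
    """Per-marker minor allele frequency, min(f, 1-f) with f the alt-allele frequency."""
    n = geno.n_samples
    if n == 0:
        raise ValueError("no samples")
    # alt-allele count per marker: code +1 gives the alt dosage in {0,1,2}
    f = (geno.codes + 1).sum(axis=0) / (2.0 * n)
    return np.minimum(f, 1.0 - f)


def filter_maf(geno: MarkerGenotypes, maf_min: float) -> MarkerGenotypes:
    """Drop markers with MAF below ``maf_min``; idempotent."""
    keep = np.flatnonzero(minor_allele_freq(geno) >= maf_min)
    if keep.size == geno.n_markers:
        return geno
    return geno.subset_markers(keep)


def read_plink_blocks(path: str, geno: MarkerGenotypes) -> list[SnpSet]:
    """Read PLINK ``.blocks.det`` haplotype blocks, resolved against ``geno``.

    Block members absent from ``geno`` (for example removed by the MAF
    filter) are dropped with a warning; rows left with no resolvable member
    are skipped.
    """
    tab = pd.read_csv(path, sep=r"\s+")
    required = {"CHR", "BP1", "BP2", "KB", "NSNPS", "SNPS"}
    if not required.issubset(tab.columns):
        raise ValueError(
            f"malformed .blocks.det header: need {sorted(required)}, got {list(tab.columns)}"
        )
    id_to_idx = {mid: i for i, mid in enumerate(geno.markers)}
    sets: list[SnpSet] = []
    for k, row in tab.iterrows():
        ids = str(row["SNPS"]).split("|")
        idx = sorted(id_to_idx[i] for i in ids if i in id_to_idx)
        n_missing = len(ids) - len(idx)
        if n_missing:
            logger.warning(
                "block %s:%s-%s: %d member SNP(s) not in genotype data",
                row["CHR"], row["BP1"], row["BP2"], n_missing,
            )
        if not idx:
            logger.warning("block %s:%s-%s skipped: no resolvable members", row["CHR"], row["BP1"], row["BP2"])
            continue
        sets.append(
            SnpSet(
                set_id=f"block{k + 1}",
                marker_indices=np.array(idx),
                chrom=str(row["CHR"]),
                span_start=int(row["BP1"]),
                span_end=int(row["BP2"]),
            )
        )
    return sets


def sliding_window_sets(geno: MarkerGenotypes, window_size: int, step: int) -> list[SnpSet]:
    """Sliding windows of ``window_size`` markers advanced by ``step``, per chromosome.

    A final shorter window keeps trailing markers; windows never cross a
    chromosome boundary.
    """
    if window_size < 1 or step < 1:
        raise ValueError("window_size and step must be >= 1")
    sets: list[SnpSet] = []
    k = 0
    for chrom in pd.unique(geno.chrom):
        on_chrom = np.flatnonzero(geno.chrom == chrom)
        start = 0
        while start < on_chrom.size:
            idx = on_chrom[start : start + window_size]
            k += 1
            sets.append(
                SnpSet(
                    set_id=f"win{k}",
                    marker_indices=idx,
                    chrom=str(chrom),
                    span_start=int(geno.pos[idx].min()),
                    span_end=int(geno.pos[idx].max()),
                )
            )
            if start + window_size >= on_chrom.size:
                break
            start += step
    return sets


def read_phenotypes(path: str, sep: str | None = None) -> pd.DataFrame:
    """Read a delimited phenotype table: column 1 = sample ID, then one column per trait."""
    tab = pd.read_csv(path, sep=sep, engine="python")
    tab = tab.set_index(tab.columns[0])
    return tab.apply(pd.to_numeric)


_CODE_GT = {-1: "0/0", 0: "0/1", 1: "1/1"}


def write_vcf(geno: MarkerGenotypes, path: str) -> None:
    """Write the coded genotypes as a minimal VCF 4.2 text file (round-trips with read_vcf)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in pd.unique(geno.chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(geno.samples) + "\n")
        for j in range(geno.n_markers):
            gts = "\t".join(_CODE_GT[int(c)] for c in geno.codes[:, j])
            fh.write(
                f"{geno.chrom[j]}\t{geno.pos[j]}\t{geno.markers[j]}\t"
                f"{geno.ref_allele[j]}\t{geno.alt_allele[j]}\t.\t.\t.\tGT\t{gts}\n"
            )
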