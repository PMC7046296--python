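import numpy as np
import pytest

from blocklmm.genotype_io import MarkerGenotypes, SnpSet
from blocklmm.kernels import additive_grm, structure_eigenvectors
from blocklmm.simulate import GenotypeSimSpec, simulate_genotypes


def make_geno(codes: np.ndarray, chrom=None, pos=None) -> MarkerGenotypes:
    """Build a MarkerGenotypes container around a plain code matrix."""
    codes = np.asarray(codes, dtype=np.int8)
    n, m = codes.shape
    return MarkerGenotypes(
        samples=[f"s{i}" for i in range(n)],
        markers=[f"rs{j + 1}" for j in range(m)],
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.asarray(pos if pos is not None else np.arange(1, m + 1) * 1000),
        ref_allele=np.array(["A"] * m, dtype=object),
        alt_allele=np.array(["T"] * m, dtype=object),
        codes=codes,
    )


@pytest.fixture(scope="session")
def small_panel():
    """A small simulated panel shared across tests: 150 samples, 25 blocks."""
    spec = GenotypeSimSpec(n_samples=150, n_blocks=25, seed=2024)
    geno, sets = simulate_genotypes(spec)
    return geno, sets


@pytest.fixture(scope="session")
def small_panel_kc(small_panel):
    geno, sets = small_panel
    Kc = additive_grm(geno.codes, ids=geno.samples)
    structure = structure_eigenvectors(Kc, 2)
    return Kc, structure


def write_tiny_vcf(path, gts, chrom=None, pos=None, alt=None):
    """Write a hand-rolled VCF from a list of per-record GT-string lists."""
    n = len(gts[0])
    m = len(gts)
    chrom = chrom or ["1"] * m
    pos = pos or [100 * (j + 1) for j in range(m)]
    alt = alt or ["T"] * m
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in dict.fromkeys(chrom):
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(f"s{i}" for i in range(n))
            + "\n"
        )
        for j in range(m):
            fh.write(
                f"{chrom[j]}\t{pos[j]}\trs{j + 1}\tA\t{alt[j]}\t.\t.\t.\tGT\t"
                + "\t".join(gts[j])
                + "\n"
            )
    return path
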