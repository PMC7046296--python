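"""Synthetic genotypes with structure and block LD, and QTN phenotype scenarios.

The genotype generator emulates the salient features of a structured crop
diversity panel: subpopulations with divergent allele frequencies
(family relatedness / structure), haplotype blocks of strong internal LD
with LD that decays — rather than vanishes — across block boundaries
(individual haplotypes are mosaics of a small founder pool), and a
minor-allele-frequency floor applied after sampling.

Phenotypes follow a three-QTN architecture: two causal variants (QTN1,
QTN2) inside a single haplotype block whose combined effect variance is
four times that of a third, unlinked variant (QTN3), plus a polygenic term
drawn from the additive GRM and iid residual noise.  Two scenarios set the
sign relation of the linked pair: "coupling" aligns the effect directions
with the sign of the genotype correlation rho12, "repulsion" opposes them —
repulsion is the regime where single-SNP tests lose power because the two
effects cancel along the LD axis while a joint set test does not.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from blocklmm.genotype_io import MarkerGenotypes, SnpSet, filter_maf
from blocklmm.kernels import additive_grm


@dataclass
class GenotypeSimSpec:
    """Parameters of the synthetic genotype panel.

    Defaults give a desk-scale stand-in for a structured inbred panel:
    300 individuals in 3 subpopulations, 50 haplotype blocks of 4-10 SNPs,
    8 founder haplotypes per subpopulation, a within-block founder switch
    probability of 0.02 per SNP, and the MAF >= 0.025 marker filter.
    """

    n_samples: int = 300
    n_subpops: int = 3
    n_blocks: int = 50
    snps_per_block: tuple[int, int] = (4, 10)
    founder_haplotypes_per_subpop: int = 8
    mosaic_switch_rate: float = 0.02
    maf_min: float = 0.025
    fst: float = 0.1
    founder_mutation_rate: float = 0.03
    inter_block_remix_rate: float = 0.1
    ancestral_haplotypes_per_block: int = 4
    tag_split_fraction: float = 0.8
    intra_block_bp: int = 2_000
    inter_block_bp: int = 30_000
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_subpops, self.n_blocks,
               self.founder_haplotypes_per_subpop) < 1:
            raise ValueError("all counts must be >= 1")
        if not 0.0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must be in [0, 0.5)")


@dataclass
class PhenotypeSim:
    """A simulated trait with its causal ground truth."""

    y: np.ndarray
    qtn1_idx: int
    qtn2_idx: int
    qtn3_idx: int
    beta1: float
    beta2: float
    beta3: float
    scenario: str
    polygenic: np.ndarray
    residual: np.ndarray
    h2_qtn: float
    h2_polygenic: float
    rho12: float
    causal_set_id: str
    seed: int

    def truth_json(self) -> str:
        return json.dumps(
            {
                "qtn1_idx": int(self.qtn1_idx),
                "qtn2_idx": int(self.qtn2_idx),
                "qtn3_idx": int(self.qtn3_idx),
                "beta1": self.beta1,
                "beta2": self.beta2,
                "beta3": self.beta3,
                "scenario": self.scenario,
                "h2_qtn": self.h2_qtn,
                "h2_polygenic": self.h2_polygenic,
                "rho12": self.rho12,
                "causal_set_id": self.causal_set_id,
                "seed": int(self.seed),
            },
            indent=2,
        )


def _sample_haplotypes(rng, spec, n_snps_per_block):
    """Founder pool + mosaic copying; returns haplotypes (2n, m) in {0, 1}.

    Each block carries a small pool of ancestral haplotypes (default 4);
    every founder haplotype is a mutated copy of one of them, with the
    ancestral-haplotype frequencies diverging across subpopulations
    (Dirichlet with dispersion set by Fst).  Sites inside a block are
    random bi-allelic splits of the ancestral pool, so within-block r2 is
    strong but heterogeneous: sites sharing a split are near-perfect
    proxies of each other, sites on different splits are only moderately
    correlated — the LD texture that produces synthetic associations in
    real panels.  A founder's ancestral pick persists across adjacent
    blocks with probability 1 - inter_block_remix_rate, so LD decays
    between neighboring blocks rather than vanishing at the boundary;
    founder mutations and the mosaic switching erode r2 further.
    """
    m = int(np.sum(n_snps_per_block))
    n = spec.n_samples
    nf = spec.founder_haplotypes_per_subpop
    nh = spec.ancestral_haplotypes_per_block
    mu = spec.founder_mutation_rate
    subpop = np.repeat(np.arange(spec.n_subpops), -(-n // spec.n_subpops))[:n]
    block_of = np.repeat(np.arange(spec.n_blocks), n_snps_per_block)
    founders = np.empty((spec.n_subpops, nf, m), dtype=np.int8)
    pick = None
    for b in range(spec.n_blocks):
        cols = np.flatnonzero(block_of == b)
        # a fraction of sites are "tag" splits, thresholds on the ancestral
        # index: they are strong mutual proxies (within-class r2 near 1)
        # and keep block mean codes correlated wherever founder picks
        # persist; the rest are arbitrary bi-allelic splits of the pool
        anc = np.empty((nh, cols.size), dtype=np.int8)
        for c in range(cols.size):
            if rng.random() < spec.tag_split_fraction:
                t = rng.integers(1, nh)
                anc[:, c] = np.arange(nh) >= t
            else:
                anc[:, c] = rng.integers(0, 2, size=nh)
        base = rng.dirichlet(np.ones(nh))
        alpha = np.maximum(base * (1.0 - spec.fst) / spec.fst, 1e-3)
        p_sub = np.vstack([rng.dirichlet(alpha) for _ in range(spec.n_subpops)])
        cum = np.cumsum(p_sub, axis=1)
        fresh = (rng.random((spec.n_subpops, nf, 1)) > cum[:, None, :]).sum(axis=2)
        if pick is None:
            pick = fresh
        else:
            remix = rng.random((spec.n_subpops, nf)) < spec.inter_block_remix_rate
            pick = np.where(remix, fresh, pick)
        block_founders = anc[pick]  # (n_subpops, nf, block size)
        flips = rng.random(block_founders.shape) < mu
        founders[:, :, cols] = np.where(flips, 1 - block_founders, block_founders)
    haps = np.empty((2 * n, m), dtype=np.int8)
    for i in range(2 * n):
        sp = subpop[i // 2]
        cur = rng.integers(nf)
        for j in range(m):
            if rng.random() < spec.mosaic_switch_rate:
                cur = rng.integers(nf)
            haps[i, j] = founders[sp, cur, j]
    return haps


def simulate_genotypes(spec: GenotypeSimSpec) -> tuple[MarkerGenotypes, list[SnpSet]]:
    """Simulate a structured panel; returns genotypes and the true block partition.

    Markers failing the MAF filter are dropped and the returned SnpSets are
    re-indexed against the filtered marker panel; blocks left empty vanish.
    """
    rng = np.random.default_rng(spec.seed)
    n_snps_per_block = rng.integers(
        spec.snps_per_block[0], spec.snps_per_block[1] + 1, size=spec.n_blocks
    )
    haps = _sample_haplotypes(rng, spec, n_snps_per_block)
    codes = (haps[0::2] + haps[1::2] - 1).astype(np.int8)
    m = codes.shape[1]
    pos = np.empty(m, dtype=int)
    cur = 1
    k = 0
    block_bounds = []
    for b, nb in enumerate(n_snps_per_block):
        start = cur
        for _ in range(nb):
            pos[k] = cur
            cur += spec.intra_block_bp
            k += 1
        block_bounds.append((start, cur - spec.intra_block_bp))
        cur += spec.inter_block_bp
    block_of = np.repeat(np.arange(spec.n_blocks), n_snps_per_block)
    geno = MarkerGenotypes(
        samples=[f"ind{i:04d}" for i in range(spec.n_samples)],
        markers=[f"snp{j + 1}" for j in range(m)],
        chrom=np.array(["1"] * m, dtype=object),
        pos=pos,
        ref_allele=np.array(["A"] * m, dtype=object),
        alt_allele=np.array(["T"] * m, dtype=object),
        codes=codes,
    )
    filtered = filter_maf(geno, spec.maf_min)
    if filtered.n_markers == 0:
        raise ValueError("no markers survive the MAF filter; loosen the simulation spec")
    kept = {mid: i for i, mid in enumerate(filtered.markers)}
    old_kept = [j for j, mid in enumerate(geno.markers) if mid in kept]
    sets: list[SnpSet] = []
    for b in range(spec.n_blocks):
        idx = [kept[geno.markers[j]] for j in old_kept if block_of[j] == b]
        if not idx:
            continue
        sets.append(
            SnpSet(
                set_id=f"block{b + 1}",
                marker_indices=np.array(sorted(idx)),
                chrom="1",
                span_start=int(filtered.pos[idx].min()),
                span_end=int(filtered.pos[idx].max()),
            )
        )
    return filtered, sets


def choose_qtns(
    geno: MarkerGenotypes, sets: list[SnpSet], seed: int
) -> tuple[int, int, int, SnpSet]:
    """Pick the causal markers: a linked pair inside one block, plus one free QTN.

    QTN1 and QTN2 are drawn without replacement from a randomly chosen
    SNP-set with more than 4 members (>= 5); QTN3 is drawn uniformly from
    all remaining markers.  Returns (qtn1, qtn2, qtn3, chosen_set).
    """
    rng = np.random.default_rng(seed)
    eligible = [s for s in sets if s.size >= 5]
    if not eligible:
        raise ValueError("no SNP-set with more than 4 members")
    chosen = eligible[rng.integers(len(eligible))]
    q1, q2 = rng.choice(chosen.marker_indices, size=2, replace=False)
    others = np.setdiff1d(np.arange(geno.n_markers), [q1, q2])
    q3 = int(rng.choice(others))
    return int(q1), int(q2), q3, chosen


def assign_effect_signs(rho12: float, beta2: float, scenario: str) -> float:
    """Sign rule linking the two block-internal QTN effects.

    coupling:  beta1 =  beta2 if rho12 >= 0 else -beta2
    repulsion: beta1 = -beta2 if rho12 >= 0 else  beta2
    """
    if scenario == "coupling":
        return beta2 if rho12 >= 0 else -beta2
    if scenario == "repulsion":
        return -beta2 if rho12 >= 0 else beta2
    raise ValueError(f"unknown scenario {scenario!r}")


def simulate_phenotype(
    geno: MarkerGenotypes,
    sets: list[SnpSet],
    scenario: str = "coupling",
    h2_qtn: float = 0.3,
    h2_polygenic: float = 0.3,
    seed: int = 0,
    grm=None,
) -> PhenotypeSim:
    """Simulate y = X1 b1 + X2 b2 + X3 b3 + u + e under a QTN scenario.

    |b1| = |b2| with signs from :func:`assign_effect_signs`.  Effect
    magnitudes are calibrated in-sample under the sign-aligned (coupling)
    configuration: there the combined QTN1+QTN2 term has realized variance
    exactly 4x that of the QTN3 term and the variance fractions of the QTN
    block, polygenic term and residual are exactly
    (h2_qtn, h2_polygenic, 1 - h2_qtn - h2_polygenic).  The repulsion
    scenario reuses the same magnitudes, polygenic draw and residual draw
    and only flips the sign of b1, so its realized QTN signal is genuinely
    smaller — the same-effects-different-signs contrast the two scenarios
    are meant to probe.
    """
    if h2_qtn < 0 or h2_polygenic < 0 or h2_qtn + h2_polygenic >= 1:
        raise ValueError("heritability fractions must be >= 0 and sum < 1")
    rng = np.random.default_rng(seed)
    qtn_seed = int(rng.integers(2**31))
    n = geno.n_samples
    for attempt in range(100):
        q1, q2, q3, chosen = choose_qtns(geno, sets, seed=qtn_seed + attempt)
        X1 = geno.codes[:, q1].astype(float)
        X2 = geno.codes[:, q2].astype(float)
        X3 = geno.codes[:, q3].astype(float)
        if X1.std() > 0 and X2.std() > 0 and X3.std() > 0:
            break
    else:
        raise ValueError("could not draw non-degenerate QTNs in 100 attempts")
    rho12 = float(np.corrcoef(X1, X2)[0, 1])
    beta2 = 1.0
    # calibrate magnitudes with sign-aligned effects, then apply the
    # scenario's sign rule: both scenarios share |b1| = |b2| and b3
    beta1_aligned = assign_effect_signs(rho12, beta2, "coupling")
    v12 = float(np.var(X1 * beta1_aligned + X2 * beta2))
    beta3 = float(rng.choice([-1.0, 1.0])) * np.sqrt(v12 / 4.0 / np.var(X3))
    vg = float(np.var(X1 * beta1_aligned + X2 * beta2 + X3 * beta3))
    scale_q = np.sqrt(h2_qtn / vg) if h2_qtn > 0 else 0.0
    beta1 = assign_effect_signs(rho12, beta2, scenario) * scale_q
    beta2 = beta2 * scale_q
    beta3 = beta3 * scale_q
    g = X1 * beta1 + X2 * beta2 + X3 * beta3

    if h2_polygenic > 0:
        K = (grm if grm is not None else additive_grm(geno.codes, ids=geno.samples)).values
        w, V = np.linalg.eigh(K)
        u = V @ (np.sqrt(np.clip(w, 0, None)) * rng.standard_normal(n))
        su = u.std()
        u = u / su * np.sqrt(h2_polygenic) if su > 0 else np.zeros(n)
    else:
        u = np.zeros(n)
    e = rng.standard_normal(n)
    e = e / e.std() * np.sqrt(1.0 - h2_qtn - h2_polygenic)
    y = g + u + e
    return PhenotypeSim(
        y=y,
        qtn1_idx=q1,
        qtn2_idx=q2,
        qtn3_idx=q3,
        beta1=float(beta1),
        beta2=float(beta2),
        beta3=float(beta3),
        scenario=scenario,
        polygenic=u,
        residual=e,
        h2_qtn=h2_qtn,
        h2_polygenic=h2_polygenic,
        rho12=rho12,
        causal_set_id=chosen.set_id,
        seed=seed,
    )
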