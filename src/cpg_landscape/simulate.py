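"""Seeded generators for genomes, CDS sets and region fixtures with known truth.

The genome generator is a first-order Markov chain over {A, C, G, T} that
decouples the three quantities the dinucleotide statistic responds to:
total GC fraction pi_GC, strand bias s = G/(G+C), and a CpG-depletion factor
lambda (lambda = 1: neutral; lambda = 0: no CG dinucleotide can occur).
Bases are drawn from pi_A = pi_T = (1 - pi_GC)/2, pi_C = pi_GC (1 - s),
pi_G = pi_GC s, except that after a C the G probability is multiplied by
lambda and the row renormalized. The stationary CpG content
#CG/(#CG + #GC) of this chain has the exact closed form

    content(lambda) = lambda / (lambda + 1 - pi_GC (1 - lambda)),

verified against the stationary eigen-distribution and brute-force
simulation; :func:`invert_lambda` solves it for lambda, enabling parameter
recovery from measured content.

The CDS generator draws sense codons from configurable usage weights with an
analogous CpG penalty (each CG a codon would create, internally or across
the junction with the previous codon, multiplies its weight by lambda),
optional separate lambdas for the first/last 33 codons, and per-dicodon
adjustment factors applied as first-order transition reweighting. Sequences
always start with ATG, end with a single stop, and contain no internal stop.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .genetic_code import CodonTable
from .overlap import RegionSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def expected_cpg_content(cpg_depletion: float, gc_fraction: float) -> float:
    """Stationary CpG content of the Markov genome model."""
    lam, g = cpg_depletion, gc_fraction
    return lam / (lam + 1.0 - g * (1.0 - lam))


def invert_lambda(content: float, gc_fraction: float) -> float:
    """Solve the stationary-content formula for the depletion factor."""
    r, g = content, gc_fraction
    denom = 1.0 - r * (1.0 + g)
    if denom <= 0:
        raise ValueError("content too high for this GC fraction (lambda diverges)")
    return r * (1.0 - g) / denom


def lambda_standard_error(content: float, gc_fraction: float, n_windows: int) -> float:
    """Delta-method SE of the recovered lambda.

    Treats #CG | (#CG + #GC = n_windows) as binomial with rate ``content``;
    SE(lambda) = |d lambda / d content| * SE(content).
    """
    r, g = content, gc_fraction
    se_r = np.sqrt(max(r * (1.0 - r), 1e-12) / n_windows)
    deriv = (1.0 - g) / (1.0 - r * (1.0 + g)) ** 2
    return deriv * se_r


@dataclass(frozen=True)
class SyntheticGenomeSpec:
    """Markov-genome parameters; defaults emulate a vertebrate-like genome
    (GC ~0.41, no strand bias, strong CpG depletion)."""

    lengths: Tuple[int, ...] = (1_000_000,)
    gc_fraction: float = 0.41
    strand_bias: float = 0.5
    cpg_depletion: float = 0.3

    @property
    def n_chromosomes(self) -> int:
        return len(self.lengths)

    def base_probs(self) -> np.ndarray:
        gc, s = self.gc_fraction, self.strand_bias
        pi = np.array([(1 - gc) / 2, gc * (1 - s), gc * s, (1 - gc) / 2])
        if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError("invalid base probabilities")
        return pi


def _markov_chromosome(pi: np.ndarray, lam: float, n: int, rng: np.random.Generator) -> str:
    c_row = pi.copy()
    c_row[2] *= lam
    c_row /= c_row.sum()
    # pre-draw both candidate streams; the loop only selects by previous state
    draws_iid = rng.choice(4, size=n, p=pi)
    draws_after_c = rng.choice(4, size=n, p=c_row)
    seq = np.empty(n, dtype=np.int64)
    prev = draws_iid[0]
    seq[0] = prev
    for i in range(1, n):
        prev = draws_after_c[i] if prev == 1 else draws_iid[i]
        seq[i] = prev
    return _BASES[seq].tobytes().decode("ascii")


def generate_genome(
    spec: SyntheticGenomeSpec, seed: int
) -> Tuple[Dict[str, str], Dict]:
    """Generate {chromosome: sequence} plus a truth record of all parameters."""
    rng = np.random.default_rng(seed)
    pi = spec.base_probs()
    chroms = {
        f"chr{i + 1}": _markov_chromosome(pi, spec.cpg_depletion, length, rng)
        for i, length in enumerate(spec.lengths)
    }
    truth = {
        "model": "first-order Markov, CpG-penalized",
        "lengths": list(spec.lengths),
        "gc_fraction": spec.gc_fraction,
        "strand_bias": spec.strand_bias,
        "cpg_depletion": spec.cpg_depletion,
        "expected_cpg_content": expected_cpg_content(spec.cpg_depletion, spec.gc_fraction),
        "seed": seed,
    }
    return chroms, truth


@dataclass(frozen=True)
class SyntheticCdsSpec:
    """CDS-set parameters.

    Lengths are in body codons (excluding the fixed ATG start and stop);
    the default Poisson(100) + 67 floor keeps every CDS ≥ 207 nt, clearing
    the 200-nt terminal-window rule. ``cpg_lambda`` penalizes every CG a
    codon draw would create; ``lambda_5prime``/``lambda_3prime`` override it
    in the first/last 33 codons; ``dicodon_factors`` multiply the transition
    weight of specific hexamers. ``symbolless_fraction`` of genes get
    LOC-style headers that the gene filter rejects.
    """

    n_genes: int = 500
    mean_body_codons: int = 167
    min_body_codons: int = 67
    codon_weights: Optional[Dict[str, float]] = None  # default: uniform over 61
    cpg_lambda: float = 1.0
    lambda_5prime: Optional[float] = None
    lambda_3prime: Optional[float] = None
    terminal_codons: int = 33
    dicodon_factors: Dict[str, float] = field(default_factory=dict)
    symbolless_fraction: float = 0.0


class _CodonSampler:
    """Sequential codon sampler with CpG penalties and dicodon factors.

    Transition weight of codon c after prev in a region with penalty lam:
    w(c) * lam^(internal CGs in c) * lam^(1 if prev ends C and c starts G)
    * dicodon_factor(prev + c). Cumulative-weight tables are cached per
    (lambda, prev-ends-C, prev codon class), so sampling is a binary search.
    """

    def __init__(self, table: CodonTable, spec: SyntheticCdsSpec):
        self.codons = sorted(table.sense_codons)
        self.index = {c: i for i, c in enumerate(self.codons)}
        if spec.codon_weights is None:
            w = np.ones(len(self.codons))
        else:
            w = np.array([spec.codon_weights.get(c, 0.0) for c in self.codons], float)
            if w.sum() <= 0:
                raise ValueError("codon weights sum to zero")
        self.base_w = w / w.sum()
        self.internal_cg = np.array(["CG" in c for c in self.codons])
        self.g_start = np.array([c.startswith("G") for c in self.codons])
        self.spec = spec
        self._cache: Dict[tuple, np.ndarray] = {}
        self.factor_prevs = {d[:3] for d in spec.dicodon_factors}

    def _cdf(self, lam: float, prev: str) -> np.ndarray:
        prev_ends_c = prev.endswith("C")
        key_prev = prev if prev in self.factor_prevs else None
        key = (lam, prev_ends_c, key_prev)
        if key not in self._cache:
            w = self.base_w.copy()
            if lam != 1.0:
                w[self.internal_cg] *= lam
                if prev_ends_c:
                    w[self.g_start] *= lam
            elif prev_ends_c:
                pass
            if key_prev is not None:
                for dic, f in self.spec.dicodon_factors.items():
                    if dic[:3] == prev:
                        w[self.index[dic[3:]]] *= f
            self._cache[key] = np.cumsum(w / w.sum())
        return self._cache[key]

    def draw(self, lam: float, prev: str, u: float) -> str:
        cdf = self._cdf(lam, prev)
        return self.codons[min(int(np.searchsorted(cdf, u, side="right")), len(cdf) - 1)]


def generate_cds_set(
    spec: SyntheticCdsSpec, seed: int, table: Optional[CodonTable] = None
) -> Tuple[List[Tuple[str, str, str]], Dict]:
    """Generate a CDS set as (gene_id, symbol, sequence) triples plus truth.

    Only sense codons are drawn for the body, so internal stops cannot
    occur; each gene is ATG + body + one stop codon.
    """
    table = table or CodonTable.standard()
    rng = np.random.default_rng(seed)
    sampler = _CodonSampler(table, spec)
    stops = sorted(table.stops)
    genes: List[Tuple[str, str, str]] = []
    term = spec.terminal_codons
    lam5 = spec.lambda_5prime if spec.lambda_5prime is not None else spec.cpg_lambda
    lam3 = spec.lambda_3prime if spec.lambda_3prime is not None else spec.cpg_lambda
    n_symbolless = int(round(spec.symbolless_fraction * spec.n_genes))
    for g in range(spec.n_genes):
        n_body = spec.min_body_codons + int(
            rng.poisson(max(spec.mean_body_codons - spec.min_body_codons, 0))
        )
        neutral = (
            spec.cpg_lambda == 1.0 and lam5 == 1.0 and lam3 == 1.0
            and not spec.dicodon_factors
        )
        if neutral:
            # no sequential dependence: draw the whole body at once
            idx = rng.choice(len(sampler.codons), size=n_body, p=sampler.base_w)
            body = [sampler.codons[i] for i in idx]
        else:
            us = rng.random(n_body)
            prev = "ATG"
            body = []
            for i in range(n_body):
                if i < term:
                    lam = lam5
                elif i >= n_body - term:
                    lam = lam3
                else:
                    lam = spec.cpg_lambda
                prev = sampler.draw(lam, prev, us[i])
                body.append(prev)
        stop = stops[int(rng.integers(len(stops)))]
        seq = "ATG" + "".join(body) + stop
        if g < n_symbolless:
            symbol = f"LOC{300000 + g}"
        else:
            symbol = f"GEN{g:05d}"
        genes.append((f"g{g:05d}", symbol, seq))
    truth = {
        "model": "codon-usage draw with CpG penalty",
        "n_genes": spec.n_genes,
        "cpg_lambda": spec.cpg_lambda,
        "lambda_5prime": lam5,
        "lambda_3prime": lam3,
        "terminal_codons": term,
        "dicodon_factors": dict(spec.dicodon_factors),
        "symbolless_fraction": spec.symbolless_fraction,
        "seed": seed,
    }
    return genes, truth


def dicodon_factor_normalization(
    spec: SyntheticCdsSpec, dicodon: str, table: Optional[CodonTable] = None
) -> float:
    """Renormalization multiplier linking an injected dicodon factor to its
    measured enrichment under otherwise-neutral sampling.

    With transition reweighting, P(c2 | c1) = w(c2) f / Z(c1) where
    Z(c1) = 1 - w(c2)(1 - f); the marginal codon frequencies are essentially
    unperturbed, so the measured enrichment is ≈ f · (1/Z(c1)). This returns
    1/Z(c1); it is verified by brute-force simulation in the test suite.
    """
    table = table or CodonTable.standard()
    sampler = _CodonSampler(table, spec)
    f = spec.dicodon_factors[dicodon]
    w2 = sampler.base_w[sampler.index[dicodon[3:]]]
    z = 1.0 - w2 * (1.0 - f)
    return 1.0 / z


def write_fasta(records, path, symbol_style: str = "gene") -> None:
    """Write (id, symbol, seq) triples as FASTA with RefSeq-style
    ``[gene=SYMBOL]`` description tags."""
    with open(path, "w") as fh:
        for gene_id, symbol, seq in records:
            fh.write(f">{gene_id} [{symbol_style}={symbol}]\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_genome_fasta(chroms: Dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name in chroms:
            fh.write(f">{name}\n")
            seq = chroms[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def generate_region_fixture(
    genome: Dict[str, int],
    subject_coverage: float = 0.1,
    query_n: int = 100,
    query_length=200,
    enrichment_level: float = 0.5,
    seed: int = 0,
    n_subject_blocks_per_chrom: int = 10,
) -> Tuple[RegionSet, RegionSet, Dict]:
    """Query/subject region fixture with controlled overlap enrichment.

    Subject blocks tile ``subject_coverage`` of each chromosome at regular
    spacing. Each query region lands fully inside the subject with
    probability ``enrichment_level`` (uniform over in-subject placements)
    and fully outside otherwise, so ``enrichment_level == subject_coverage``
    is the calibration null (up to edge effects of order
    query_length/chromosome_length) and higher values enrich the overlap.

    ``query_length`` is either a fixed length or a ``(lo, hi)`` range drawn
    uniformly per region. Varied lengths keep overlap totals off a coarse
    lattice, which matters for calibration studies: with identical lengths
    many permutations tie the observed overlap exactly and the inclusive
    empirical p-value becomes conservative.
    """
    if not 0.0 < subject_coverage < 1.0:
        raise ValueError("subject_coverage must be in (0, 1)")
    if not 0.0 <= enrichment_level <= 1.0:
        raise ValueError("enrichment_level must be in [0, 1]")
    if isinstance(query_length, (tuple, list)):
        len_lo, len_hi = int(query_length[0]), int(query_length[1])
    else:
        len_lo = len_hi = int(query_length)
    rng = np.random.default_rng(seed)
    subject: Dict[str, list] = {}
    for chrom, length in genome.items():
        period = length // n_subject_blocks_per_chrom
        block = int(round(period * subject_coverage))
        if block < len_hi:
            raise ValueError("subject blocks too small for the query length")
        subject[chrom] = [
            (i * period, i * period + block) for i in range(n_subject_blocks_per_chrom)
        ]
    subject_set = RegionSet.from_intervals(subject, genome)

    chroms = sorted(genome)
    chrom_w = np.array([genome[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    query: Dict[str, list] = {c: [] for c in chroms}
    n_inside = 0
    for _ in range(query_n):
        chrom = chroms[int(rng.choice(len(chroms), p=chrom_w))]
        blocks = subject[chrom]
        qlen = int(rng.integers(len_lo, len_hi + 1)) if len_hi > len_lo else len_lo
        if rng.random() < enrichment_level:
            n_inside += 1
            bs, be = blocks[int(rng.integers(len(blocks)))]
            start = int(rng.integers(bs, be - qlen + 1))
        else:
            # uniform over placements fully outside the subject blocks
            gaps = []
            prev_end = 0
            for bs, be in blocks + [(genome[chrom], genome[chrom])]:
                if bs - prev_end >= qlen:
                    gaps.append((prev_end, bs - qlen))
                prev_end = be
            widths = np.array([g1 - g0 + 1 for g0, g1 in gaps], dtype=float)
            g0, g1 = gaps[int(rng.choice(len(gaps), p=widths / widths.sum()))]
            start = int(rng.integers(g0, g1 + 1))
        query[chrom].append((start, start + qlen))
    query_set = RegionSet.from_intervals(query, genome)
    truth = {
        "subject_coverage": subject_coverage,
        "query_n": query_n,
        "query_length": [len_lo, len_hi],
        "enrichment_level": enrichment_level,
        "n_queries_inside_subject": n_inside,
        "seed": seed,
    }
    return query_set, subject_set, truth
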