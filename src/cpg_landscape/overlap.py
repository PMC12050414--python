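"""Permutation test of overlap between two genomic region sets.

Assesses whether the overlap between a query region set (e.g. gene bodies)
and a subject set (e.g. chromatin-state segments) exceeds what random
placement would produce: each query region is independently re-placed
uniformly at random on its own chromosome (length preserved), the overlap is
recomputed, and an empirical p-value with add-one correction is reported.

Regions are 0-based half-open intervals; overlapping input intervals are
merged on load; strand is ignored (CpG is strand-symmetric). Permuted
regions may overlap each other — no rejection sampling — matching the
common circular/random-placement convention of region-randomization tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np


def _merge(intervals: np.ndarray) -> Tuple[np.ndarray, bool]:
    """Sort and merge an (n, 2) interval array; report whether merging
    changed anything."""
    if len(intervals) == 0:
        return intervals.reshape(0, 2), False
    order = np.lexsort((intervals[:, 1], intervals[:, 0]))
    ivs = intervals[order]
    merged = [list(ivs[0])]
    changed = False
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            changed = True
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64), changed


@dataclass
class RegionSet:
    """Named intervals on named chromosomes, with chromosome lengths."""

    genome: Dict[str, int]                  # chromosome -> length
    intervals: Dict[str, np.ndarray]        # chromosome -> merged (n, 2)
    merged_on_load: bool = False

    @classmethod
    def from_intervals(cls, intervals: Dict[str, Sequence], genome: Dict[str, int]) -> "RegionSet":
        clean: Dict[str, np.ndarray] = {}
        merged_any = False
        for chrom, ivs in intervals.items():
            if chrom not in genome:
                raise ValueError(f"chromosome {chrom!r} not in genome")
            arr = np.asarray(list(ivs), dtype=np.int64).reshape(-1, 2)
            if len(arr) and not (
                (arr[:, 0] >= 0).all()
                and (arr[:, 0] < arr[:, 1]).all()
                and (arr[:, 1] <= genome[chrom]).all()
            ):
                raise ValueError(f"interval out of bounds on {chrom}")
            arr, changed = _merge(arr)
            merged_any |= changed
            clean[chrom] = arr
        for chrom in genome:
            clean.setdefault(chrom, np.empty((0, 2), dtype=np.int64))
        return cls(dict(genome), clean, merged_any)

    @classmethod
    def from_bed(cls, bed_path, genome: Dict[str, int]) -> "RegionSet":
        """Load a BED file (first three columns; extra columns ignored)."""
        intervals: Dict[str, list] = {}
        with open(bed_path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                chrom, start, end = line.split("\t")[:3]
                intervals.setdefault(chrom, []).append((int(start), int(end)))
        return cls.from_intervals(intervals, genome)

    def to_bed(self, path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")

    @property
    def total_bases(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self.intervals.values()))

    @property
    def n_regions(self) -> int:
        return int(sum(len(a) for a in self.intervals.values()))


def read_chrom_sizes(path) -> Dict[str, int]:
    """Two-column TSV: chromosome name, length."""
    genome: Dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            name, size = line.split("\t")[:2]
            genome[name] = int(size)
    return genome


def _coverage_prefix(b: np.ndarray):
    """Cumulative covered bases of merged intervals up to each start/end."""
    lengths = b[:, 1] - b[:, 0]
    cum = np.concatenate([[0], np.cumsum(lengths)])
    return cum


def _overlap_bases_chrom(a: np.ndarray, b: np.ndarray) -> int:
    """Intersected bases of two merged, sorted interval arrays.

    Uses F(x) = covered b-bases in [0, x): per a-interval the overlap is
    F(end) − F(start), vectorized with prefix sums over b."""
    if len(a) == 0 or len(b) == 0:
        return 0
    cum = _coverage_prefix(b)

    def F(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(b[:, 0], x, side="right") - 1
        safe = np.maximum(idx, 0)
        inside = np.minimum(np.maximum(x - b[safe, 0], 0), b[safe, 1] - b[safe, 0])
        return np.where(idx >= 0, cum[safe] + inside, 0)

    return int(np.sum(F(a[:, 1]) - F(a[:, 0])))


def _count_overlapping_chrom(a: np.ndarray, b: np.ndarray) -> int:
    if len(a) == 0 or len(b) == 0:
        return 0
    # a-region [s, e) hits some b iff a b-interval starting before e ends after s
    idx = np.searchsorted(b[:, 0], a[:, 1], side="left") - 1
    hit = np.zeros(len(a), dtype=bool)
    # nearest b starting strictly before a.end; overlap iff its end > a.start
    valid = idx >= 0
    hit[valid] = b[idx[valid], 1] > a[valid, 0]
    # also handle b fully inside a when the nearest-start b ends early:
    # merged intervals are disjoint+sorted, so the nearest-start test suffices
    return int(hit.sum())


def observed_overlap(a: RegionSet, b: RegionSet, mode: str = "bases") -> int:
    """Overlap between two region sets sharing a genome definition.

    ``mode="bases"``: total intersected length (symmetric in a and b).
    ``mode="count"``: number of a-regions intersecting at least one b-region.
    """
    if a.genome != b.genome:
        raise ValueError("region sets are defined on different genomes")
    total = 0
    for chrom in a.genome:
        ia, ib = a.intervals[chrom], b.intervals[chrom]
        if mode == "bases":
            total += _overlap_bases_chrom(ia, ib)
        elif mode == "count":
            total += _count_overlapping_chrom(ia, ib)
        else:
            raise ValueError("mode must be 'bases' or 'count'")
    return total


def permute_regions(
    a: RegionSet,
    seed_or_rng,
    cross_chromosome: bool = False,
) -> RegionSet:
    """Re-place every region uniformly at random, preserving its length.

    By default each region stays on its own chromosome (start drawn uniformly
    from [0, L_chrom − L_region]); ``cross_chromosome=True`` first draws a
    chromosome with probability proportional to its length among those that
    can hold the region. Deterministic given the seed.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    chroms = sorted(a.genome)
    new: Dict[str, list] = {c: [] for c in chroms}
    for chrom in chroms:
        for s, e in a.intervals[chrom]:
            length = int(e - s)
            if cross_chromosome:
                fits = [c for c in chroms if a.genome[c] >= length]
                weights = np.array([a.genome[c] for c in fits], dtype=float)
                target = fits[rng.choice(len(fits), p=weights / weights.sum())]
            else:
                target = chrom
            max_start = a.genome[target] - length
            if max_start < 0:
                raise ValueError(f"region of length {length} exceeds {target}")
            start = int(rng.integers(0, max_start + 1))
            new[target].append((start, start + length))
    return RegionSet.from_intervals(new, a.genome)


@dataclass
class PermTestResult:
    """Result of the permutation overlap test."""

    observed_overlap: int
    null_overlaps: np.ndarray
    p_value: float
    z_score: Optional[float]
    n_permutations: int
    alternative: str
    mode: str

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_overlaps))


def permutation_test(
    a: RegionSet,
    b: RegionSet,
    n_perm: int = 1000,
    mode: str = "bases",
    alternative: str = "greater",
    seed: Optional[int] = None,
    cross_chromosome: bool = False,
) -> PermTestResult:
    """Empirical significance of the overlap between ``a`` and ``b``.

    p = (1 + #{null ≥ observed}) / (1 + n_perm) for ``alternative="greater"``
    (≤ for "less"), so the smallest attainable p is 1/(n_perm + 1).
    z = (observed − mean(null)) / sd(null); None when sd(null) = 0.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    rng = np.random.default_rng(seed)
    obs = observed_overlap(a, b, mode)
    null = np.empty(n_perm, dtype=np.int64)
    for i in range(n_perm):
        null[i] = observed_overlap(permute_regions(a, rng), b, mode)
    if alternative == "greater":
        extreme = int((null >= obs).sum())
    else:
        extreme = int((null <= obs).sum())
    p = (1 + extreme) / (1 + n_perm)
    sd = float(np.std(null))
    z = (obs - float(np.mean(null))) / sd if sd > 0 else None
    return PermTestResult(obs, null, p, z, n_perm, alternative, mode)
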