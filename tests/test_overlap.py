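"""Region-set arithmetic and the permutation overlap test."""

import numpy as np
import pytest
from scipy import stats

from cpg_landscape.overlap import (
    RegionSet,
    observed_overlap,
    permutation_test,
    permute_regions,
    read_chrom_sizes,
)


def _bitmap_overlap(a, b, genome, mode):
    """Boolean-mask oracle for interval overlap."""
    total = 0
    for chrom, length in genome.items():
        ma = np.zeros(length, dtype=bool)
        mb = np.zeros(length, dtype=bool)
        for s, e in a.intervals[chrom]:
            ma[s:e] = True
        for s, e in b.intervals[chrom]:
            mb[s:e] = True
        if mode == "bases":
            total += int((ma & mb).sum())
        else:
            total += sum(
                1 for s, e in a.intervals[chrom] if (ma[s:e] & mb[s:e]).any()
            )
    return total


def _random_set(rng, genome, max_regions=8):
    intervals = {}
    for chrom, length in genome.items():
        n = int(rng.integers(0, max_regions))
        ivs = []
        for _ in range(n):
            s = int(rng.integers(0, length - 1))
            e = int(rng.integers(s + 1, min(s + 50, length) + 1))
            ivs.append((s, e))
        intervals[chrom] = ivs
    return RegionSet.from_intervals(intervals, genome)


@pytest.mark.parametrize("mode", ["bases", "count"])
def test_overlap_matches_bitmap_oracle(rng, mode):
    genome = {"chr1": 300, "chr2": 150}
    for _ in range(120):
        a = _random_set(rng, genome)
        b = _random_set(rng, genome)
        assert observed_overlap(a, b, mode) == _bitmap_overlap(a, b, genome, mode)


def test_overlap_examples():
    genome = {"chr1": 100}
    a = RegionSet.from_intervals({"chr1": [(0, 10)]}, genome)
    b = RegionSet.from_intervals({"chr1": [(5, 15)]}, genome)
    assert observed_overlap(a, b, "bases") == 5
    assert observed_overlap(a, b, "count") == 1
    assert observed_overlap(a, a, "bases") == a.total_bases
    c = RegionSet.from_intervals({"chr1": [(50, 60)]}, genome)
    assert observed_overlap(a, c, "bases") == 0


def test_overlap_symmetric_in_bases_mode(rng):
    genome = {"chr1": 500}
    for _ in range(30):
        a = _random_set(rng, genome)
        b = _random_set(rng, genome)
        assert observed_overlap(a, b, "bases") == observed_overlap(b, a, "bases")


def test_mismatched_genomes_rejected():
    a = RegionSet.from_intervals({"chr1": [(0, 5)]}, {"chr1": 10})
    b = RegionSet.from_intervals({"chr1": [(0, 5)]}, {"chr1": 20})
    with pytest.raises(ValueError):
        observed_overlap(a, b)


def test_merge_on_load_flagged():
    genome = {"chr1": 100}
    merged = RegionSet.from_intervals({"chr1": [(0, 10), (5, 20)]}, genome)
    assert merged.merged_on_load
    assert merged.intervals["chr1"].tolist() == [[0, 20]]
    clean = RegionSet.from_intervals({"chr1": [(0, 10), (20, 30)]}, genome)
    assert not clean.merged_on_load


def test_out_of_bounds_rejected():
    with pytest.raises(ValueError):
        RegionSet.from_intervals({"chr1": [(0, 200)]}, {"chr1": 100})
    with pytest.raises(ValueError):
        RegionSet.from_intervals({"chrX": [(0, 5)]}, {"chr1": 100})


def test_bed_round_trip(tmp_path):
    genome = {"chr1": 100, "chr2": 50}
    a = RegionSet.from_intervals({"chr1": [(0, 10), (30, 40)], "chr2": [(5, 15)]}, genome)
    bed = tmp_path / "a.bed"
    a.to_bed(bed)
    sizes = tmp_path / "genome.sizes"
    sizes.write_text("chr1\t100\nchr2\t50\n")
    b = RegionSet.from_bed(bed, read_chrom_sizes(sizes))
    for chrom in genome:
        assert a.intervals[chrom].tolist() == b.intervals[chrom].tolist()


def test_permute_preserves_lengths_and_is_deterministic():
    genome = {"chr1": 1000, "chr2": 400}
    a = RegionSet.from_intervals(
        {"chr1": [(0, 50), (100, 300)], "chr2": [(10, 30)]}, genome
    )
    p1 = permute_regions(a, 7)
    p2 = permute_regions(a, 7)
    for chrom in genome:
        assert p1.intervals[chrom].tolist() == p2.intervals[chrom].tolist()
        lengths = sorted((e - s) for s, e in p1.intervals[chrom])
        assert lengths == sorted((e - s) for s, e in a.intervals[chrom])


def test_permute_forced_placement():
    genome = {"chr1": 50}
    a = RegionSet.from_intervals({"chr1": [(0, 50)]}, genome)
    p = permute_regions(a, 3)
    assert p.intervals["chr1"].tolist() == [[0, 50]]


def test_permute_start_positions_uniform(rng):
    """10^3 placements of a 100-bp region on a 10^5 chromosome pass a KS
    test against the uniform placement law."""
    genome = {"chr1": 100_000}
    a = RegionSet.from_intervals({"chr1": [(0, 100)]}, genome)
    master = np.random.default_rng(99)
    starts = [int(permute_regions(a, master).intervals["chr1"][0, 0]) for _ in range(1000)]
    d, p = stats.kstest(starts, stats.uniform(loc=0, scale=100_000 - 100).cdf)
    assert p > 0.01


def test_permutation_test_p_formula_and_degenerate_null():
    genome = {"chr1": 100}
    a = RegionSet.from_intervals({"chr1": [(0, 100)]}, genome)  # whole chromosome
    b = RegionSet.from_intervals({"chr1": [(0, 100)]}, genome)
    res = permutation_test(a, b, n_perm=49, seed=1)
    # every permutation is forced to full overlap: p = 1, sd = 0
    assert res.p_value == 1.0
    assert res.z_score is None


def test_permutation_test_detects_self_enrichment():
    genome = {"chr1": 100_000}
    ivs = [(i * 10_000, i * 10_000 + 100) for i in range(10)]
    a = RegionSet.from_intervals({"chr1": ivs}, genome)
    res = permutation_test(a, a, n_perm=199, seed=2)
    assert res.observed_overlap == a.total_bases
    assert res.p_value == pytest.approx(1 / 200)
    assert res.z_score > 3


def test_permutation_alternative_less():
    genome = {"chr1": 10_000}
    a = RegionSet.from_intervals({"chr1": [(0, 100)]}, genome)
    b = RegionSet.from_intervals({"chr1": [(5000, 10_000)]}, genome)
    res = permutation_test(a, b, n_perm=99, alternative="less", seed=3)
    assert 0 < res.p_value <= 1
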