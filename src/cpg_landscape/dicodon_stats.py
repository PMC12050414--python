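"""In-frame codon and dicodon counting and observed/expected enrichment.

A dicodon is an ordered pair of adjacent in-frame codons (a hexamer). Its
expected frequency under codon-usage independence is the product of the two
pooled codon frequencies; the enrichment ratio observed/expected exposes
selection for or against particular codon neighborhoods — most prominently
the depletion of dicodons that create a CpG across the codon junction.

Conventions: codon pairs slide by one codon within each CDS and never span
CDS boundaries; stop codons and codons containing non-ACGT bases are
excluded from both counts and frequencies; pooling is across the whole CDS
set (per-species).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .genetic_code import CodonTable

_ACGT = frozenset("ACGT")


def _iter_cds(cds_set) -> Iterable[Tuple[str, str]]:
    """Accept {id: seq}, iterable of (id, seq), or iterable of seqs."""
    if isinstance(cds_set, dict):
        yield from cds_set.items()
        return
    for i, item in enumerate(cds_set):
        if isinstance(item, str):
            yield f"cds{i}", item
        else:
            yield item


def _codons(seq: str) -> List[str]:
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


@dataclass
class CodonCounts:
    """Pooled codon tallies over a CDS set; stops tracked separately."""

    counts: Counter = field(default_factory=Counter)        # sense codons
    stop_counts: Counter = field(default_factory=Counter)
    skipped: List[str] = field(default_factory=list)        # frame violations

    @property
    def total_sense(self) -> int:
        return sum(self.counts.values())

    def frequency(self, codon: str) -> float:
        total = self.total_sense
        return self.counts[codon] / total if total else 0.0


def count_codons(cds_set, table: Optional[CodonTable] = None) -> CodonCounts:
    """Tally in-frame codons over a CDS set.

    Sequences whose length is not a multiple of 3 are skipped and recorded in
    ``skipped``; codons with non-ACGT bases are ignored.
    """
    table = table or CodonTable.standard()
    out = CodonCounts()
    for cds_id, seq in _iter_cds(cds_set):
        seq = seq.upper()
        if len(seq) % 3 != 0:
            out.skipped.append(cds_id)
            continue
        for codon in _codons(seq):
            if not _ACGT.issuperset(codon):
                continue
            if codon in table.stops:
                out.stop_counts[codon] += 1
            else:
                out.counts[codon] += 1
    return out


def count_dicodons(cds_set, table: Optional[CodonTable] = None) -> Counter:
    """Count adjacent in-frame codon pairs (hexamers), sliding by one codon.

    Pairs involving a stop codon or a non-ACGT codon are excluded; pairs never
    span CDS boundaries. Frame-violating sequences are skipped, matching
    :func:`count_codons`.
    """
    table = table or CodonTable.standard()
    pairs: Counter = Counter()
    stops = table.stops
    for _, seq in _iter_cds(cds_set):
        seq = seq.upper()
        if len(seq) % 3 != 0:
            continue
        cods = _codons(seq)
        for c1, c2 in zip(cods, cods[1:]):
            if c1 in stops or c2 in stops:
                continue
            if not (_ACGT.issuperset(c1) and _ACGT.issuperset(c2)):
                continue
            pairs[c1 + c2] += 1
    return pairs


@dataclass(frozen=True)
class EnrichmentRecord:
    """Observed/expected statistics for one dicodon."""

    dicodon: str
    aa1: str
    aa2: str
    observed: int
    expected: float
    enrichment: float  # observed / expected; inf when expected == 0 < observed
    cpg_within_codon1: bool
    cpg_within_codon2: bool
    cpg_junction: bool
    low_expected: bool  # expected below the configured floor

    @property
    def has_cpg(self) -> bool:
        return self.cpg_within_codon1 or self.cpg_within_codon2 or self.cpg_junction


def cpg_flags(dicodon: str) -> Tuple[bool, bool, bool]:
    """CpG placement flags (within codon 1, within codon 2, junction) read
    directly off the hexamer."""
    return "CG" in dicodon[0:3], "CG" in dicodon[3:6], dicodon[2:4] == "CG"


def dicodon_enrichment(
    codon_counts: CodonCounts,
    dicodon_counts: Counter,
    table: Optional[CodonTable] = None,
    expected_floor: float = 5.0,
) -> List[EnrichmentRecord]:
    """Enrichment ratio for every ordered sense-codon pair.

    expected(c1, c2) = N · f(c1) · f(c2) with N the total observed pairs and
    f the pooled sense-codon frequencies. Records with expected below
    ``expected_floor`` are flagged low-confidence (unstable ratios). The
    result covers all 61² pairs, sorted by ascending enrichment then
    lexicographically, so under-represented dicodons come first.
    """
    table = table or CodonTable.standard()
    n_pairs = sum(dicodon_counts.values())
    if n_pairs <= 0:
        raise ValueError("no dicodon observations")
    sense = sorted(table.sense_codons)
    freq = {c: codon_counts.frequency(c) for c in sense}
    records = []
    for c1 in sense:
        for c2 in sense:
            dic = c1 + c2
            obs = dicodon_counts.get(dic, 0)
            exp = n_pairs * freq[c1] * freq[c2]
            if exp > 0:
                enr = obs / exp
            else:
                enr = math.inf if obs else 0.0
            w1, w2, junc = cpg_flags(dic)
            records.append(
                EnrichmentRecord(
                    dic, table.mapping[c1], table.mapping[c2], obs, exp, enr,
                    w1, w2, junc, exp < expected_floor,
                )
            )
    records.sort(key=lambda r: (r.enrichment, r.dicodon))
    return records


def top_enriched(
    records: List[EnrichmentRecord], k: int = 3, direction: str = "under",
    include_low_expected: bool = False,
) -> List[EnrichmentRecord]:
    """Top-k under- or over-represented dicodons (low-expected records are
    dropped by default)."""
    pool = [r for r in records if include_low_expected or not r.low_expected]
    pool.sort(key=lambda r: (r.enrichment, r.dicodon))
    if direction == "under":
        return pool[:k]
    if direction == "over":
        return sorted(pool, key=lambda r: (-r.enrichment, r.dicodon))[:k]
    raise ValueError("direction must be 'under' or 'over'")
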