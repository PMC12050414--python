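"""Dinucleotide counting and the normalized CpG-content statistic.

CpG content is measured as #CpG / (#CpG + #GpC): the fraction of CpG among
the two palindromic C/G dinucleotides. GpC has the same base content as CpG
but is not a methylation target, so the ratio is insensitive to GC fraction
and strand bias; under base independence its expectation is 0.5, and
methylation-driven CpG loss pushes it below. The statistic is
strand-symmetric because CG and GC are each their own reverse complement.

Counting conventions: overlapping windows with step 1; any window containing
a non-ACGT base (N runs etc.) is voided and not counted in the denominator
of window totals; lowercase (soft-masked) bases count normally.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

_A, _C, _G, _T = 65, 67, 71, 84  # ASCII codes


def _as_codes(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)


@dataclass(frozen=True)
class DinucCounts:
    """Overlapping CG / GC window tallies for one sequence or window."""

    n_cpg: int
    n_gpc: int
    n_windows: int  # dinucleotide windows with both bases in {A,C,G,T}
    length: int

    def __post_init__(self):
        if not (0 <= self.n_cpg + self.n_gpc <= self.n_windows <= max(self.length - 1, 0)):
            raise ValueError(f"inconsistent dinucleotide counts: {self}")


def count_dinucleotides(sequence: str) -> DinucCounts:
    """Count overlapping CG and GC dinucleotides (step 1, case-insensitive)."""
    n = len(sequence)
    if n < 2:
        return DinucCounts(0, 0, 0, n)
    b = _as_codes(sequence)
    valid = (b == _A) | (b == _C) | (b == _G) | (b == _T)
    left, right = b[:-1], b[1:]
    pair_ok = valid[:-1] & valid[1:]
    n_cpg = int(np.count_nonzero((left == _C) & (right == _G)))
    n_gpc = int(np.count_nonzero((left == _G) & (right == _C)))
    return DinucCounts(n_cpg, n_gpc, int(np.count_nonzero(pair_ok)), n)


@dataclass(frozen=True)
class CpgContent:
    """Normalized CpG content ratio; ``value`` is None when undefined
    (no CpG and no GpC present — callers must exclude such records)."""

    value: Optional[float]
    counts: DinucCounts

    @property
    def defined(self) -> bool:
        return self.value is not None


def cpg_content(counts: DinucCounts) -> CpgContent:
    """CpG content = n_cpg / (n_cpg + n_gpc), in [0, 1]; undefined at 0/0."""
    denom = counts.n_cpg + counts.n_gpc
    if denom == 0:
        return CpgContent(None, counts)
    return CpgContent(counts.n_cpg / denom, counts)


def cpg_content_of(sequence: str) -> CpgContent:
    return cpg_content(count_dinucleotides(sequence))


@dataclass(frozen=True)
class ExpectedCpg:
    """Expected per-window CpG probability under base independence."""

    p_cpg: float
    neutral_content: float = 0.5  # P(CG) = P(GC) under independence


def expected_cpg_frequency(gc_fraction: float, strand_bias: float) -> ExpectedCpg:
    """P(CpG) = P(C)·P(G) = gc²·s·(1−s) for GC fraction gc and strand bias
    s = G/(G+C), assuming independent bases.

    The implied neutral CpG content is always 0.5: independence makes CG and
    GC equally likely regardless of composition.
    """
    if not (0.0 <= gc_fraction <= 1.0 and 0.0 <= strand_bias <= 1.0):
        raise ValueError("gc_fraction and strand_bias must lie in [0, 1]")
    p_c = gc_fraction * (1.0 - strand_bias)
    p_g = gc_fraction * strand_bias
    return ExpectedCpg(p_c * p_g)


@dataclass(frozen=True)
class CompositionStats:
    """Single-strand base composition; ``strand_bias`` and
    ``gc_excluding_cpg_gpc`` are None when their denominators vanish."""

    gc_fraction: float
    strand_bias: Optional[float]
    gc_excluding_cpg_gpc: Optional[float]


def gc_content_excluding_cpg_gpc(sequence: str) -> CompositionStats:
    """Base composition with CpG/GpC-participating bases masked out.

    Every base inside an overlapping CG or GC window is masked; the
    ``gc_excluding_cpg_gpc`` fraction is computed over the remaining ACGT
    bases (None if none remain). ``gc_fraction`` and ``strand_bias`` are
    computed over all ACGT bases of the unmasked sequence.
    """
    b = _as_codes(sequence)
    is_a, is_c = b == _A, b == _C
    is_g, is_t = b == _G, b == _T
    valid = is_a | is_c | is_g | is_t
    n_valid = int(valid.sum())
    n_c, n_g = int(is_c.sum()), int(is_g.sum())
    gc_fraction = (n_c + n_g) / n_valid if n_valid else 0.0
    strand_bias = n_g / (n_c + n_g) if (n_c + n_g) else None

    mask = np.zeros(len(b), dtype=bool)
    if len(b) >= 2:
        cg = (b[:-1] == _C) & (b[1:] == _G)
        gc = (b[:-1] == _G) & (b[1:] == _C)
        hit = cg | gc
        mask[:-1] |= hit
        mask[1:] |= hit
    keep = valid & ~mask
    n_keep = int(keep.sum())
    if n_keep == 0:
        gc_excl = None
    else:
        gc_excl = int((keep & (is_c | is_g)).sum()) / n_keep
    return CompositionStats(gc_fraction, strand_bias, gc_excl)


@dataclass(frozen=True)
class FragmentRecord:
    """One genomic tile with its dinucleotide statistics."""

    seq_id: str
    start: int  # 0-based half-open
    end: int
    counts: DinucCounts
    content: CpgContent
    excluded: bool
    exclusion_reason: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start


def tile_sequence(sequence: str, width: int = 5000, seq_id: str = "") -> List[FragmentRecord]:
    """Cut a scaffold into consecutive non-overlapping tiles of ``width``
    bases (default 5 kb), anchored at coordinate 0; the final tile may be
    shorter. Tiles lacking both CpG and GpC are emitted flagged-excluded
    (zero denominator) rather than dropped.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    records = []
    for start in range(0, len(sequence), width):
        chunk = sequence[start : start + width]
        counts = count_dinucleotides(chunk)
        content = cpg_content(counts)
        records.append(
            FragmentRecord(
                seq_id,
                start,
                start + len(chunk),
                counts,
                content,
                excluded=not content.defined,
                exclusion_reason=None if content.defined else "zero_denominator",
            )
        )
    return records


class SequenceTooShortError(ValueError):
    """Raised when a CDS is too short for distinct terminal windows."""


def terminal_windows(cds_sequence: str, width: int = 99) -> tuple:
    """First and last ``width`` coding bases of a CDS (default 99 = 33
    codons each).

    Requires length ≥ 2·width + 2 (200 nt at the default) so the 5' and 3'
    windows are distinct; shorter sequences raise ``SequenceTooShortError``.
    """
    min_len = 2 * width + 2
    if len(cds_sequence) < min_len:
        raise SequenceTooShortError(
            f"CDS of length {len(cds_sequence)} < {min_len}: terminal windows not distinct"
        )
    return cds_sequence[:width], cds_sequence[-width:]


def reverse_complement(sequence: str) -> str:
    table = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")
    return sequence.translate(table)[::-1]
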