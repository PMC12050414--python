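"""Per-gene / per-fragment CpG statistics and the named comparisons.

Orchestrates the empirical analyses on a CDS FASTA and a genome FASTA:

* gene filtering — only genes with an informative gene symbol (location-index
  placeholders like ``LOC123456`` are treated as unnamed) and a defined CpG
  content are retained; every exclusion is recorded in a ledger so the
  retained set and the ledger exactly partition the input;
* coding vs genomic contrast — per-gene CpG content against per-5-kb-fragment
  content, Mann-Whitney U (two-sided);
* CpG content vs GC content (excluding CpG/GpC bases) — Kendall tau plus an
  ordinary least-squares line, on genes of 150-2000 nt only;
* 5' vs 3' contrast — CpG content of the first vs last 99 coding bases,
  Wilcoxon signed-rank on genes >= 200 nt.

The per-figure length filters apply only to their own comparison; global
analyses use all retained genes. All tests are two-sided and no
multiple-testing correction is applied across this small fixed set.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

from . import __version__ as _pkg_version
from .dicodon_stats import count_codons, count_dicodons, dicodon_enrichment
from .seq_metrics import (
    CompositionStats,
    CpgContent,
    DinucCounts,
    FragmentRecord,
    SequenceTooShortError,
    count_dinucleotides,
    cpg_content,
    gc_content_excluding_cpg_gpc,
    terminal_windows,
    tile_sequence,
)

DEFAULT_SYMBOL_RE = re.compile(r"\[gene=([^\]]+)\]")
DEFAULT_UNNAMED_RE = re.compile(r"^LOC\d+$")


@dataclass
class GeneRecord:
    """One CDS with its dinucleotide statistics and exclusion flags."""

    gene_id: str
    gene_symbol: Optional[str]
    sequence: str
    counts: DinucCounts
    content: CpgContent
    composition: CompositionStats
    first99: Optional[CpgContent]
    last99: Optional[CpgContent]
    flags: Tuple[str, ...]  # subset of {no_symbol, zero_denominator, short, frame_violation}

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def retained(self) -> bool:
        return "no_symbol" not in self.flags and "zero_denominator" not in self.flags


def extract_symbol(description: str, symbol_re: re.Pattern = DEFAULT_SYMBOL_RE) -> Optional[str]:
    """Pull a gene symbol out of a FASTA description line.

    Default pattern matches the RefSeq-style ``[gene=SYMBOL]`` tag; falls
    back to a bare ``gene=SYMBOL`` token. Returns None when nothing matches.
    """
    m = symbol_re.search(description)
    if m:
        return m.group(1)
    m = re.search(r"\bgene[=:]([\w.-]+)", description)
    return m.group(1) if m else None


def build_gene_record(
    gene_id: str,
    description: str,
    sequence: str,
    terminal_width: int = 99,
    symbol_re: re.Pattern = DEFAULT_SYMBOL_RE,
    unnamed_re: re.Pattern = DEFAULT_UNNAMED_RE,
) -> GeneRecord:
    sequence = str(sequence).upper()
    symbol = extract_symbol(description, symbol_re)
    flags = []
    if symbol is None or unnamed_re.match(symbol):
        flags.append("no_symbol")
    counts = count_dinucleotides(sequence)
    content = cpg_content(counts)
    if not content.defined:
        flags.append("zero_denominator")
    if len(sequence) % 3 != 0:
        flags.append("frame_violation")
    first = last = None
    try:
        w5, w3 = terminal_windows(sequence, terminal_width)
        c5 = cpg_content(count_dinucleotides(w5))
        c3 = cpg_content(count_dinucleotides(w3))
        first, last = c5, c3
    except SequenceTooShortError:
        flags.append("short")
    comp = gc_content_excluding_cpg_gpc(sequence)
    return GeneRecord(
        gene_id, symbol, sequence, counts, content, comp, first, last, tuple(flags)
    )


def load_genes(cds_fasta, terminal_width: int = 99, **kw) -> List[GeneRecord]:
    records = []
    for rec in SeqIO.parse(str(cds_fasta), "fasta"):
        records.append(
            build_gene_record(rec.id, rec.description, str(rec.seq), terminal_width, **kw)
        )
    return records


def filter_genes(records: Iterable[GeneRecord]) -> Tuple[List[GeneRecord], pd.DataFrame]:
    """Split gene records into the retained set and an exclusion ledger.

    Retention requires an informative symbol and a defined CpG content.
    The ledger lists every input gene with its outcome and reasons, so
    retained + excluded exactly partition the input. ``short`` and
    ``frame_violation`` are advisory (they gate only specific analyses).
    """
    records = list(records)
    retained = [r for r in records if r.retained]
    ledger = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "gene_symbol": [r.gene_symbol or "" for r in records],
            "length": [r.length for r in records],
            "retained": [r.retained for r in records],
            "flags": [",".join(r.flags) for r in records],
        }
    )
    return retained, ledger


@dataclass
class TestResult:
    """One named statistical comparison."""

    test_name: str
    statistic: float
    p_value: Optional[float]
    n: int
    direction: Optional[str] = None
    medians: Optional[Tuple[float, float]] = None
    slope: Optional[float] = None
    intercept: Optional[float] = None
    slope_p: Optional[float] = None
    note: Optional[str] = None

    def to_dict(self) -> Dict:
        d = asdict(self)
        return {k: v for k, v in d.items() if v is not None}


def coding_vs_genomic(
    gene_contents: Iterable[float], fragment_contents: Iterable[float]
) -> TestResult:
    """Two-sided Mann-Whitney U: per-gene vs per-fragment CpG content."""
    x = np.asarray(list(gene_contents), dtype=float)
    y = np.asarray(list(fragment_contents), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    mx, my = float(np.median(x)), float(np.median(y))
    direction = "coding>genomic" if mx > my else ("coding<genomic" if mx < my else "equal")
    return TestResult(
        "mann_whitney_u", float(stat), float(p), len(x) + len(y), direction, (mx, my)
    )


def content_gc_correlation(
    genes: Iterable[GeneRecord], min_len: int = 150, max_len: int = 2000
) -> TestResult:
    """Kendall tau + OLS between CpG content and GC content excluding
    CpG/GpC bases, on genes within [min_len, max_len] nt."""
    pairs = [
        (g.content.value, g.composition.gc_excluding_cpg_gpc)
        for g in genes
        if min_len <= g.length <= max_len
        and g.content.defined
        and g.composition.gc_excluding_cpg_gpc is not None
    ]
    if len(pairs) < 3:
        raise ValueError("need at least 3 genes after the length filter")
    x = np.array([p[1] for p in pairs])  # GC content (excluding CpG/GpC)
    y = np.array([p[0] for p in pairs])  # CpG content
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(
            "kendall_tau_ols", float("nan"), None, len(pairs), note="degenerate_constant_input"
        )
    tau, tau_p = stats.kendalltau(x, y)
    ols = stats.linregress(x, y)
    direction = "positive" if tau > 0 else ("negative" if tau < 0 else "none")
    return TestResult(
        "kendall_tau_ols",
        float(tau),
        float(tau_p),
        len(pairs),
        direction,
        slope=float(ols.slope),
        intercept=float(ols.intercept),
        slope_p=float(ols.pvalue),
    )


def start_vs_end(genes: Iterable[GeneRecord]) -> TestResult:
    """Paired Wilcoxon signed-rank on (first-99, last-99) CpG content.

    Genes shorter than 200 nt or with an undefined content in either window
    are dropped (and countable from the returned n).
    """
    pairs = [
        (g.first99.value, g.last99.value)
        for g in genes
        if g.first99 is not None
        and g.last99 is not None
        and g.first99.defined
        and g.last99.defined
    ]
    if len(pairs) < 1:
        raise ValueError("no valid gene pairs for the terminal-window contrast")
    first = np.array([p[0] for p in pairs])
    last = np.array([p[1] for p in pairs])
    diffs = first - last
    if np.all(diffs == 0):
        stat, p = 0.0, 1.0
    else:
        stat, p = stats.wilcoxon(first, last, alternative="two-sided")
    m5, m3 = float(np.median(first)), float(np.median(last))
    direction = "start>end" if m5 > m3 else ("start<end" if m5 < m3 else "equal")
    return TestResult(
        "wilcoxon_signed_rank", float(stat), float(p), len(pairs), direction, (m5, m3)
    )


def _genes_frame(records: List[GeneRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "gene_symbol": [r.gene_symbol or "" for r in records],
            "length": [r.length for r in records],
            "n_cpg": [r.counts.n_cpg for r in records],
            "n_gpc": [r.counts.n_gpc for r in records],
            "cpg_content": [r.content.value for r in records],
            "gc_fraction": [r.composition.gc_fraction for r in records],
            "strand_bias": [r.composition.strand_bias for r in records],
            "gc_excluding_cpg_gpc": [r.composition.gc_excluding_cpg_gpc for r in records],
            "first99_content": [r.first99.value if r.first99 else None for r in records],
            "last99_content": [r.last99.value if r.last99 else None for r in records],
            "flags": [",".join(r.flags) for r in records],
        }
    )


def _fragments_frame(fragments: List[FragmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "seq_id": [f.seq_id for f in fragments],
            "start": [f.start for f in fragments],
            "end": [f.end for f in fragments],
            "length": [f.length for f in fragments],
            "n_cpg": [f.counts.n_cpg for f in fragments],
            "n_gpc": [f.counts.n_gpc for f in fragments],
            "cpg_content": [f.content.value for f in fragments],
            "excluded": [f.excluded for f in fragments],
            "exclusion_reason": [f.exclusion_reason or "" for f in fragments],
        }
    )


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_species(
    cds_fasta,
    genome_fasta,
    out_dir,
    fragment_size: int = 5000,
    terminal_width: int = 99,
    corr_min_len: int = 150,
    corr_max_len: int = 2000,
    dicodon_top: int = 3,
) -> Dict:
    """Run the full per-species analysis and write a deterministic bundle.

    Outputs in ``out_dir``: genes.tsv, fragments.tsv, exclusions.tsv,
    dicodons.tsv (all sense pairs with enrichment), tests.json and
    manifest.json. Byte-identical across repeated runs on the same inputs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    genes = load_genes(cds_fasta, terminal_width)
    genes.sort(key=lambda g: g.gene_id)
    if not genes:
        raise ValueError(f"no sequences in {cds_fasta}")
    retained, ledger = filter_genes(genes)
    if not retained:
        _write_tsv(ledger, out / "exclusions.tsv")
        raise ValueError("no genes retained after filtering (see exclusions.tsv)")

    fragments: List[FragmentRecord] = []
    for rec in sorted(SeqIO.parse(str(genome_fasta), "fasta"), key=lambda r: r.id):
        fragments.extend(tile_sequence(str(rec.seq).upper(), fragment_size, rec.id))

    gene_contents = [g.content.value for g in retained]
    frag_contents = [f.content.value for f in fragments if f.content.defined]

    results: Dict[str, TestResult] = {}
    results["coding_vs_genomic"] = coding_vs_genomic(gene_contents, frag_contents)
    try:
        results["content_gc_correlation"] = content_gc_correlation(
            retained, corr_min_len, corr_max_len
        )
    except ValueError as err:
        results["content_gc_correlation"] = TestResult(
            "kendall_tau_ols", float("nan"), None, 0, note=str(err)
        )
    try:
        results["start_vs_end"] = start_vs_end(retained)
    except ValueError as err:
        results["start_vs_end"] = TestResult(
            "wilcoxon_signed_rank", float("nan"), None, 0, note=str(err)
        )

    in_frame = {g.gene_id: g.sequence for g in retained if "frame_violation" not in g.flags}
    dic_df = pd.DataFrame()
    if in_frame:
        codons = count_codons(in_frame)
        dicodons = count_dicodons(in_frame)
        if sum(dicodons.values()) > 0:
            enr = dicodon_enrichment(codons, dicodons)
            dic_df = pd.DataFrame(
                {
                    "dicodon": [r.dicodon for r in enr],
                    "aa1": [r.aa1 for r in enr],
                    "aa2": [r.aa2 for r in enr],
                    "observed": [r.observed for r in enr],
                    "expected": [r.expected for r in enr],
                    "enrichment": [r.enrichment for r in enr],
                    "cpg_within_codon1": [r.cpg_within_codon1 for r in enr],
                    "cpg_within_codon2": [r.cpg_within_codon2 for r in enr],
                    "cpg_junction": [r.cpg_junction for r in enr],
                    "low_expected": [r.low_expected for r in enr],
                }
            )

    _write_tsv(_genes_frame(genes), out / "genes.tsv")
    _write_tsv(_fragments_frame(fragments), out / "fragments.tsv")
    _write_tsv(ledger, out / "exclusions.tsv")
    _write_tsv(dic_df, out / "dicodons.tsv")

    tests_json = {name: res.to_dict() for name, res in sorted(results.items())}
    (out / "tests.json").write_text(json.dumps(tests_json, indent=2, sort_keys=True) + "\n")

    config = {
        "fragment_size": fragment_size,
        "terminal_width": terminal_width,
        "corr_min_len": corr_min_len,
        "corr_max_len": corr_max_len,
        "dicodon_top": dicodon_top,
    }
    manifest = {
        "package": "cpg-landscape",
        "version": _pkg_version,
        "config": config,
        "config_hash": hashlib.sha256(
            json.dumps(config, sort_keys=True).encode()
        ).hexdigest(),
        "n_genes_input": len(genes),
        "n_genes_retained": len(retained),
        "n_fragments": len(fragments),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {"tests": results, "manifest": manifest, "n_retained": len(retained)}
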