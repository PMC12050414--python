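"""Exact combinatorics of CpG dinucleotides in the standard genetic code.

CpG is the only dinucleotide the standard genetic code can avoid entirely:
every amino acid, and every dipeptide junction, has at least one encoding
that contains no 5'-CG-3'. This module enumerates the relevant codon classes
(within-codon CpG at positions 1-2 and 2-3, C-ending codons that can seed a
junction CpG, G-starting codons that can complete one), constructs the
CpG-free codon repertoire, classifies the six possible CpG SNP polymorphism
classes, and measures how many synonymous single-nucleotide steps are needed
to escape a CpG codon.

All codons are DNA (T, not U), uppercase. The standard code table comes from
Biopython (NCBI translation table 1).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from itertools import product
from typing import Optional

from Bio.Data.CodonTable import unambiguous_dna_by_id

BASES = "ACGT"
ALL_CODONS = tuple("".join(p) for p in product(BASES, repeat=3))


@dataclass(frozen=True)
class CodonTable:
    """A genetic code: mapping of sense codons to one-letter amino acids.

    Invariants: the 64 codons partition into sense ∪ stops; the mapping is
    total on sense codons; every amino acid has at least one codon.
    """

    code_id: int
    mapping: dict  # sense codon -> amino acid
    stops: frozenset
    starts: frozenset

    def __post_init__(self):
        if set(self.mapping) | set(self.stops) != set(ALL_CODONS):
            raise ValueError("sense + stop codons must partition the 64 codons")
        if set(self.mapping) & set(self.stops):
            raise ValueError("sense and stop codons overlap")

    @classmethod
    def standard(cls) -> "CodonTable":
        t = unambiguous_dna_by_id[1]
        return cls(
            code_id=1,
            mapping=dict(t.forward_table),
            stops=frozenset(t.stop_codons),
            starts=frozenset(t.start_codons),
        )

    @property
    def sense_codons(self):
        return frozenset(self.mapping)

    @property
    def amino_acids(self):
        return frozenset(self.mapping.values())

    def synonyms(self, codon: str):
        aa = self.mapping[codon]
        return frozenset(c for c, a in self.mapping.items() if a == aa)


@dataclass(frozen=True)
class CpgCodonReport:
    """Codon classes relevant to CpG occurrence in coding DNA."""

    within_pos12: frozenset  # CG at codon bases 1-2 (CGN)
    within_pos23: frozenset  # CG at codon bases 2-3 (NCG)
    c_ending: frozenset      # base 3 = C: may seed a junction CpG
    g_starting: frozenset    # base 1 = G: may complete a junction CpG
    within_pos12_aas: frozenset
    within_pos23_aas: frozenset
    c_ending_aas: frozenset
    g_starting_aas: frozenset

    @property
    def within_codon(self) -> frozenset:
        return self.within_pos12 | self.within_pos23

    @property
    def within_codon_aas(self) -> frozenset:
        return self.within_pos12_aas | self.within_pos23_aas


def enumerate_cpg_codons(table: Optional[CodonTable] = None) -> CpgCodonReport:
    """Split sense codons by how they can participate in a CpG dinucleotide.

    For the standard code: 8 codons carry a within-codon CpG (the four CGN
    arginine codons plus ACG/TCG/CCG/GCG, i.e. five amino acids R,T,S,P,A);
    16 codons end in C (15 amino acids) and 16 start with G (5 amino acids).
    """
    table = table or CodonTable.standard()
    sense = table.mapping
    p12 = frozenset(c for c in sense if c[0:2] == "CG")
    p23 = frozenset(c for c in sense if c[1:3] == "CG")
    cend = frozenset(c for c in sense if c[2] == "C")
    gstart = frozenset(c for c in sense if c[0] == "G")
    aas = lambda s: frozenset(sense[c] for c in s)
    return CpgCodonReport(p12, p23, cend, gstart, aas(p12), aas(p23), aas(cend), aas(gstart))


def never_cpg_amino_acids(table: Optional[CodonTable] = None) -> frozenset:
    """Amino acids that can never contribute a base to a CpG dinucleotide.

    An amino acid qualifies iff none of its codons contains CG, ends in C
    (junction CpG as the C side), or starts with G (junction CpG as the G
    side). For the standard code this yields {K, M, Q, W}: lysine's codons
    (AAA, AAG) contain no cytosine at all and their only guanine sits at the
    third position behind an A, so lysine — like M, Q and W — cannot occur in
    a CpG context.
    """
    table = table or CodonTable.standard()
    sense = table.mapping
    in_context = {
        sense[c]
        for c in sense
        if "CG" in c or c.endswith("C") or c.startswith("G")
    }
    return frozenset(table.amino_acids - in_context)


@dataclass(frozen=True)
class CpgFreeSet:
    codons: frozenset
    covers_all_amino_acids: bool


def cpg_free_codon_set(table: Optional[CodonTable] = None) -> CpgFreeSet:
    """Sense codons from which CpG-free polypeptide chains can be built.

    Remove the codons with a within-codon CG, then every remaining C-ending
    codon (a C-ending codon followed by any G-starting codon forms a junction
    CpG; G-starting codons themselves must be kept because valine is
    encodable only by GTN). For the standard code 61 − 8 − 15 = 38 codons
    remain, no retained codon ends in C, and every amino acid keeps at least
    one codon, so any protein can in principle be encoded CpG-free.
    """
    table = table or CodonTable.standard()
    keep = frozenset(
        c for c in table.sense_codons if "CG" not in c and not c.endswith("C")
    )
    covered = frozenset(table.mapping[c] for c in keep)
    return CpgFreeSet(keep, covered == table.amino_acids)


@dataclass(frozen=True)
class DicodonSpaceSizes:
    all_sense_pairs: int
    cpg_free_pairs: int
    reduction_percent: float


def dicodon_space_sizes(table: Optional[CodonTable] = None) -> DicodonSpaceSizes:
    """Count ordered codon pairs in the full vs CpG-free repertoire.

    Standard code: 61² = 3721 sense dicodons, 38² = 1444 CpG-free dicodons —
    a reduction of more than 60%.
    """
    table = table or CodonTable.standard()
    n_sense = len(table.sense_codons)
    n_free = len(cpg_free_codon_set(table).codons)
    all_pairs = n_sense * n_sense
    free_pairs = n_free * n_free
    return DicodonSpaceSizes(all_pairs, free_pairs, 100.0 * (1 - free_pairs / all_pairs))


def min_synonymous_steps_to_cpg_free(
    codon: str, table: Optional[CodonTable] = None
) -> Optional[int]:
    """Shortest path of synonymous single-nucleotide substitutions to a
    CG-free codon of the same amino acid.

    Every intermediate must be a sense codon for the same amino acid;
    junction-formed CpG is ignored (the question is codon-internal). Returns
    0 if the codon is already CG-free, ``None`` if no synonymous route
    exists. In the standard code only arginine needs two steps (CGT, CGC →
    CGA/CGG → AGA/AGG); CGA, CGG and all NCG codons escape in one.
    """
    table = table or CodonTable.standard()
    codon = codon.upper()
    if codon in table.stops:
        raise ValueError(f"stop codon {codon} has no amino acid")
    if codon not in table.mapping:
        raise ValueError(f"not a codon: {codon!r}")
    if "CG" not in codon:
        return 0
    syn = table.synonyms(codon)
    seen = {codon}
    queue = deque([(codon, 0)])
    while queue:
        cur, d = queue.popleft()
        for i in range(3):
            for b in BASES:
                if b == cur[i]:
                    continue
                nxt = cur[:i] + b + cur[i + 1 :]
                if nxt not in syn or nxt in seen:
                    continue
                if "CG" not in nxt:
                    return d + 1
                seen.add(nxt)
                queue.append((nxt, d + 1))
    return None


@dataclass(frozen=True)
class MutationEffect:
    source_codon: str
    target_codon: str
    position: int  # 1-based position of the mutated base within the codon
    kind: str      # synonymous | nonsynonymous | nonsense
    source_aa: str
    target_aa_or_stop: str


def _effect(table: CodonTable, source: str, target: str, position: int) -> MutationEffect:
    src_aa = table.mapping[source]
    if target in table.stops:
        return MutationEffect(source, target, position, "nonsense", src_aa, "*")
    tgt_aa = table.mapping[target]
    kind = "synonymous" if tgt_aa == src_aa else "nonsynonymous"
    return MutationEffect(source, target, position, kind, src_aa, tgt_aa)


def methylation_mutation_effect(
    codon: str,
    cpg_start: int,
    deaminated_strand: str = "coding",
    table: Optional[CodonTable] = None,
) -> MutationEffect:
    """Effect of a methylation-driven deamination at a within-codon CpG.

    ``cpg_start`` is the 1-based codon position of the C of the CpG (1 for
    CGN, 2 for NCG). ``deaminated_strand`` selects which strand's methylated
    cytosine deaminates: ``"coding"`` mutates the C itself (CpG → TpG on the
    coding strand), ``"template"`` mutates the paired G (CpG → CpA, i.e. the
    opposite-strand C → T seen as G → A here).

    Raises ``ValueError`` when the stated position does not hold a CG.
    """
    table = table or CodonTable.standard()
    codon = codon.upper()
    if codon not in table.mapping:
        raise ValueError(f"not a sense codon: {codon!r}")
    if cpg_start not in (1, 2):
        raise ValueError("cpg_start must be 1 (CGN) or 2 (NCG)")
    i = cpg_start - 1
    if codon[i : i + 2] != "CG":
        raise ValueError(f"{codon} has no CpG at positions {cpg_start}-{cpg_start + 1}")
    if deaminated_strand == "coding":
        pos = i
        target = codon[:pos] + "T" + codon[pos + 1 :]
    elif deaminated_strand == "template":
        pos = i + 1
        target = codon[:pos] + "A" + codon[pos + 1 :]
    else:
        raise ValueError("deaminated_strand must be 'coding' or 'template'")
    return _effect(table, codon, target, pos + 1)


def junction_mutation_effects(
    codon_c: str, codon_g: str, table: Optional[CodonTable] = None
) -> tuple:
    """Effects of deamination at a CpG spanning a codon junction.

    ``codon_c`` must end in C and ``codon_g`` start with G. Returns a pair of
    ``MutationEffect``: the C→T change at position 3 of the first codon
    (always synonymous in the standard code — every NNC has an NNT synonym)
    and the G→A change at position 1 of the second (always nonsynonymous).
    """
    table = table or CodonTable.standard()
    codon_c, codon_g = codon_c.upper(), codon_g.upper()
    if not codon_c.endswith("C") or not codon_g.startswith("G"):
        raise ValueError(f"no junction CpG in {codon_c}|{codon_g}")
    c_side = _effect(table, codon_c, codon_c[:2] + "T", 3)
    g_side = _effect(table, codon_g, "A" + codon_g[1:], 1)
    return c_side, g_side


@dataclass(frozen=True)
class SnpClassification:
    """One row of the six possible CpG SNP polymorphism classes.

    ``high_mutation_rate`` marks the two methylation-driven deamination
    products (CpG↔TpG and CpG↔CpA). ``gc_conversion_acting`` marks
    polymorphisms with a G/C vs A/T heterozygote, where GC-biased gene
    conversion favors restoring the CpG.
    """

    polymorphism: str
    gc_conversion_acting: bool
    high_mutation_rate: bool
    synonymous_at_3rd: str  # always | possible | never
    synonymous_at_1st: str


_SNP_TABLE = {
    "GpG": SnpClassification("CpG<->GpG", False, False, "possible", "never"),
    "ApG": SnpClassification("CpG<->ApG", True, False, "possible", "possible"),
    "TpG": SnpClassification("CpG<->TpG", True, True, "always", "never"),
    "CpA": SnpClassification("CpG<->CpA", True, True, "always", "never"),
    "CpT": SnpClassification("CpG<->CpT", True, False, "always", "never"),
    "CpC": SnpClassification("CpG<->CpC", False, False, "always", "never"),
}


def classify_cpg_snp(polymorphism: str) -> SnpClassification:
    """Classify a CpG SNP by its non-CpG allele (e.g. ``"TpG"`` or
    ``"CpG<->TpG"``)."""
    key = polymorphism.replace("CpG", "").replace("<->", "").replace("↔", "").strip()
    key = key or polymorphism
    if key not in _SNP_TABLE:
        raise KeyError(
            f"unknown CpG polymorphism {polymorphism!r}; expected one of {sorted(_SNP_TABLE)}"
        )
    return _SNP_TABLE[key]


def all_cpg_snp_classes() -> tuple:
    """All six CpG SNP polymorphism classes, in canonical order."""
    return tuple(_SNP_TABLE[k] for k in ("GpG", "ApG", "TpG", "CpA", "CpT", "CpC"))


@dataclass(frozen=True)
class AlternativeEncoding:
    """Non-CpG alternative encoding for an amino acid or dipeptide."""

    query: str
    context: str  # CGN | NCG | junction | none
    alternatives: tuple  # codons (or codon pairs for junctions)
    single_synonymous_change: str  # always | partial | n.a.
    gc_neutral: str  # yes | no | partially | n.a.


def cpg_free_alternatives(
    query: str, table: Optional[CodonTable] = None
) -> tuple:
    """Non-CpG alternative encodings for an amino acid or a dipeptide.

    Single amino acid: returns one ``AlternativeEncoding`` per CpG context the
    amino acid can occur in. Arginine's CGN codons fall back to AGA/AGG (only
    CGA/CGG reach them in one synonymous step; not GC-neutral); the NCG codons
    of S, P, T, A fall back to their NCH synonyms (always one step,
    GC-neutral); K, M, Q and W have no CpG context at all.

    Dipeptide (two letters): if the pair can form a junction CpG (first amino
    acid has a C-ending codon, second a G-starting one), returns the
    NNT+GNN re-encoding of each CpG-forming codon pair (always a single
    synonymous change on the C side; GC-neutrality only partial since C→T
    loses one G+C).
    """
    table = table or CodonTable.standard()
    query = query.upper()
    if len(query) == 1:
        if query not in table.amino_acids:
            raise KeyError(f"unknown amino acid {query!r}")
        out = []
        codons = sorted(table.synonyms(next(c for c, a in table.mapping.items() if a == query)))
        cgn = [c for c in codons if c[0:2] == "CG"]
        ncg = [c for c in codons if c[1:3] == "CG"]
        if cgn:
            alts = tuple(sorted(c for c in codons if "CG" not in c))
            out.append(AlternativeEncoding(query, "CGN", alts, "partial", "no"))
        if ncg:
            # NCH synonyms of the NCG codon share its first two bases
            for c in ncg:
                alts = tuple(sorted(s for s in codons if s[:2] == c[:2] and s[2] != "G"))
                out.append(AlternativeEncoding(c, "NCG", alts, "always", "yes"))
        cend = [c for c in codons if c.endswith("C")]
        if cend:
            alts = tuple(sorted(c[:2] + "T" for c in cend))
            out.append(AlternativeEncoding(query, "junction", alts, "always", "partially"))
        if not out:
            out.append(AlternativeEncoding(query, "none", (), "n.a.", "n.a."))
        return tuple(out)
    if len(query) == 2:
        aa1, aa2 = query
        for aa in (aa1, aa2):
            if aa not in table.amino_acids:
                raise KeyError(f"unknown amino acid {aa!r}")
        codons1 = sorted(c for c, a in table.mapping.items() if a == aa1)
        codons2 = sorted(c for c, a in table.mapping.items() if a == aa2)
        pairs = [
            (c1, c2)
            for c1 in codons1
            for c2 in codons2
            if c1.endswith("C") and c2.startswith("G")
        ]
        if not pairs:
            return (AlternativeEncoding(query, "none", (), "n.a.", "n.a."),)
        alts = tuple((c1[:2] + "T", c2) for c1, c2 in pairs)
        return (AlternativeEncoding(query, "junction", alts, "always", "partially"),)
    raise ValueError("query must be one amino acid or a dipeptide")
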