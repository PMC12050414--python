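"""Genetic-code CpG combinatorics against brute-force enumeration oracles."""

from itertools import product

import networkx as nx
import pytest

from cpg_landscape.genetic_code import (
    ALL_CODONS,
    CodonTable,
    all_cpg_snp_classes,
    classify_cpg_snp,
    cpg_free_alternatives,
    cpg_free_codon_set,
    dicodon_space_sizes,
    enumerate_cpg_codons,
    junction_mutation_effects,
    methylation_mutation_effect,
    min_synonymous_steps_to_cpg_free,
    never_cpg_amino_acids,
)


def test_partition_counts_against_exhaustive_enumeration(table):
    """Sense/CG/C-ending/G-starting codon class sizes from a raw scan of all
    64 trinucleotide strings."""
    sense = {c for c in ALL_CODONS if c not in table.stops}
    assert len(sense) == 61
    assert sum(1 for c in sense if "CG" in c) == 8
    assert sum(1 for c in sense if c.endswith("C")) == 16
    assert sum(1 for c in sense if c.startswith("G")) == 16

    rep = enumerate_cpg_codons(table)
    assert rep.within_codon == {c for c in sense if "CG" in c}
    assert rep.c_ending == {c for c in sense if c.endswith("C")}
    assert rep.g_starting == {c for c in sense if c.startswith("G")}


def test_within_codon_cpg_classes(table):
    rep = enumerate_cpg_codons(table)
    assert rep.within_pos12 == {"CGT", "CGC", "CGA", "CGG"}
    assert rep.within_pos12_aas == {"R"}
    assert rep.within_pos23_aas == {"S", "P", "T", "A"}
    assert not rep.within_pos12 & rep.within_pos23
    assert len(rep.within_codon) == 8
    assert len(rep.within_codon_aas) == 5
    assert len(rep.c_ending_aas) == 15
    assert rep.g_starting_aas == {"V", "A", "D", "E", "G"}


def test_never_cpg_amino_acids_matches_rule_oracle(table):
    """An amino acid escapes CpG context iff every codon of it lacks CG,
    a terminal C, and an initial G — recomputed here from scratch."""
    by_aa = {}
    for codon, aa in table.mapping.items():
        by_aa.setdefault(aa, []).append(codon)
    oracle = {
        aa
        for aa, codons in by_aa.items()
        if all(
            "CG" not in c and not c.endswith("C") and not c.startswith("G")
            for c in codons
        )
    }
    result = never_cpg_amino_acids(table)
    assert result == oracle
    # lysine has no cytosine in either codon, so it is CpG-context-free too
    assert result == {"K", "M", "Q", "W"}
    assert not result & {"R", "S", "P", "T", "A"}


def test_never_cpg_degenerate_table():
    """A code whose every amino acid owns a CG codon has no escapers."""
    mapping = {c: "X" for c in ALL_CODONS if c not in ("TAA", "TAG", "TGA")}
    t = CodonTable(0, mapping, frozenset(("TAA", "TAG", "TGA")), frozenset(("ATG",)))
    assert never_cpg_amino_acids(t) == frozenset()


def test_cpg_free_codon_set_is_junction_safe(table):
    """All 38^2 ordered concatenations of the CpG-free repertoire must be
    CG-free hexamers, and every amino acid must stay encodable."""
    free = cpg_free_codon_set(table)
    assert len(free.codons) == 38
    assert free.covers_all_amino_acids
    for c in free.codons:
        assert "CG" not in c and not c.endswith("C")
    for c1, c2 in product(free.codons, repeat=2):
        assert "CG" not in c1 + c2


def test_dicodon_space_sizes(table):
    sizes = dicodon_space_sizes(table)
    assert sizes.all_sense_pairs == 3721
    assert sizes.cpg_free_pairs == 1444
    assert sizes.reduction_percent > 60


def _bfs_oracle(table):
    """Independent shortest-path oracle over the synonymous substitution
    graph, via networkx."""
    g = nx.Graph()
    g.add_nodes_from(table.mapping)
    for c1 in table.mapping:
        for i in range(3):
            for b in "ACGT":
                c2 = c1[:i] + b + c1[i + 1 :]
                if c2 != c1 and table.mapping.get(c2) == table.mapping[c1]:
                    g.add_edge(c1, c2)
    out = {}
    for codon in table.mapping:
        targets = [c for c in table.synonyms(codon) if "CG" not in c]
        best = None
        for t in targets:
            try:
                d = nx.shortest_path_length(g, codon, t)
            except nx.NetworkXNoPath:
                continue
            best = d if best is None else min(best, d)
        out[codon] = best
    return out


def test_min_synonymous_steps_matches_graph_oracle(table):
    oracle = _bfs_oracle(table)
    for codon in sorted(table.mapping):
        assert min_synonymous_steps_to_cpg_free(codon, table) == oracle[codon], codon


@pytest.mark.parametrize(
    "codon,expected",
    [("CGC", 2), ("CGT", 2), ("CGA", 1), ("CGG", 1), ("GCG", 1), ("TCG", 1), ("TTT", 0)],
)
def test_min_synonymous_steps_known_values(codon, expected):
    assert min_synonymous_steps_to_cpg_free(codon) == expected


def test_min_synonymous_steps_rejects_stops():
    with pytest.raises(ValueError):
        min_synonymous_steps_to_cpg_free("TGA")


@pytest.mark.parametrize(
    "codon,start,strand,target,kind",
    [
        ("CGA", 1, "coding", "TGA", "nonsense"),
        ("CGT", 1, "coding", "TGT", "nonsynonymous"),
        ("CGT", 1, "template", "CAT", "nonsynonymous"),
        ("ACG", 2, "template", "ACA", "synonymous"),
        ("ACG", 2, "coding", "ATG", "nonsynonymous"),
        ("TCG", 2, "template", "TCA", "synonymous"),
    ],
)
def test_methylation_mutation_effect_examples(codon, start, strand, target, kind):
    eff = methylation_mutation_effect(codon, start, strand)
    assert eff.target_codon == target
    assert eff.kind == kind


def test_methylation_effect_third_position_always_synonymous(table):
    """CpG at codon positions 2-3: the G sits at a 4-fold degenerate third
    position, so its deamination (CpG -> CpA) never changes the protein.
    At CGN positions 1-2 no deamination is synonymous."""
    for codon in ("ACG", "TCG", "CCG", "GCG"):
        assert methylation_mutation_effect(codon, 2, "template").kind == "synonymous"
        assert methylation_mutation_effect(codon, 2, "coding").kind != "synonymous"
    for codon in ("CGT", "CGC", "CGA", "CGG"):
        for strand in ("coding", "template"):
            assert methylation_mutation_effect(codon, 1, strand).kind != "synonymous"


def test_methylation_effect_requires_cpg_at_position():
    with pytest.raises(ValueError):
        methylation_mutation_effect("AAA", 1, "coding")
    with pytest.raises(ValueError):
        methylation_mutation_effect("CGA", 2, "coding")


def test_junction_effects_always_syn_on_c_side_nonsyn_on_g_side(table):
    rep = enumerate_cpg_codons(table)
    for c1 in rep.c_ending:
        for c2 in rep.g_starting:
            c_side, g_side = junction_mutation_effects(c1, c2)
            assert c_side.kind == "synonymous", (c1, c2)
            assert g_side.kind == "nonsynonymous", (c1, c2)


@pytest.mark.parametrize(
    "key,gc,high,syn3,syn1",
    [
        ("GpG", False, False, "possible", "never"),
        ("ApG", True, False, "possible", "possible"),
        ("TpG", True, True, "always", "never"),
        ("CpA", True, True, "always", "never"),
        ("CpT", True, False, "always", "never"),
        ("CpC", False, False, "always", "never"),
    ],
)
def test_classify_cpg_snp_rows(key, gc, high, syn3, syn1):
    row = classify_cpg_snp(f"CpG<->{key}")
    assert row.gc_conversion_acting is gc
    assert row.high_mutation_rate is high
    assert row.synonymous_at_3rd == syn3
    assert row.synonymous_at_1st == syn1


def test_classify_cpg_snp_high_rate_only_for_deamination_products():
    high = {s.polymorphism for s in all_cpg_snp_classes() if s.high_mutation_rate}
    assert high == {"CpG<->TpG", "CpG<->CpA"}
    with pytest.raises(KeyError):
        classify_cpg_snp("CpG<->ApA")


def test_cpg_free_alternatives():
    r = cpg_free_alternatives("R")
    cgn = next(a for a in r if a.context == "CGN")
    assert set(cgn.alternatives) == {"AGA", "AGG"}
    assert cgn.single_synonymous_change == "partial"
    assert cgn.gc_neutral == "no"

    s = cpg_free_alternatives("S")
    ncg = next(a for a in s if a.context == "NCG")
    assert ncg.query == "TCG"
    assert set(ncg.alternatives) == {"TCT", "TCA", "TCC"}
    assert ncg.single_synonymous_change == "always"
    assert ncg.gc_neutral == "yes"

    for aa in "MQW":
        (alt,) = cpg_free_alternatives(aa)
        assert alt.context == "none"

    (junc,) = cpg_free_alternatives("FV")
    assert junc.context == "junction"
    assert all(c1.endswith("T") for c1, _ in junc.alternatives)
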