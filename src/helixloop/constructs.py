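"""The 93-nt cyclization constructs used in the smFRET experiments.

Each construct is a pair of annotated 5'->3' sequence strings exactly as
synthesized: a Cy5- and internally biotin-labelled DNA strand (the
``**T**`` marker is the biotin-dT) plus its Cy3-labelled complementary
DNA or RNA strand.  The first 10 nt of every strand form a 5' overhang;
the two overhangs of a construct are mutually complementary, so after
annealing the duplex can cyclize into a 93-bp circle (83-bp duplex +
10-bp hybridized overhang).

The four RDH constructs take their sequence from two positive-GC-skew
regions of the human APOE CpG-island promoter; in each region both
hybrid polarities were synthesized (C-rich DNA / G-rich RNA and the
complementary G-rich DNA / C-rich RNA).
"""

from __future__ import annotations

from .seqkit import AnnealedDuplex, Oligo, anneal, parse_oligo

__all__ = ["CONSTRUCTS", "construct_oligos", "construct_duplex"]

# fmt: off
CONSTRUCTS: dict[str, tuple[str, str]] = {
    # same-sequence DNA/DNA control duplex
    "dsDNA": (
        "Cy5-acggattctgtgaaacggtggaggtgagga**T**agtcatgggtcaattagaagtcataggagaagtattaag"
        "ggagtctatattgaggtactagc",
        "Cy3-cagaatccgtgctagtacctcaatatagactcccttaatacttctcctatgacttctaattgacccatga"
        "ctatcctcacctccaccgtttca",
    ),
    # RNA-DNA hybrid with the same DNA strand
    "RDH": (
        "Cy5-acggattctgtgaaacggtggaggtgagga**T**agtcatgggtcaattagaagtcataggagaagtattaag"
        "ggagtctatattgaggtactagc",
        "Cy3-cagaauccgugcuaguaccucaauauagacucccuuaauacuucuccuaugacuucuaauugacc"
        "caugacuauccucaccuccaccguuuca",
    ),
    # APOE promoter region with GC skew 0.53, both hybrid polarities
    "C-DNA/G-RNA RDH-53": (
        "Cy5-cctccagtggctccaccttcacctgtggc**T**gagactcaactgtcaccccctcctctggctccatcccttc"
        "cgtccccttttgcctctttctct",
        "Cy3-ccacuggaggagagaaagaggcaaaaggggacggaagggauggagccagaggagggggugacagu"
        "ugagucucagccacaggugaagguggag",
    ),
    "G-DNA/C-RNA RDH-53": (
        "Cy5-agagaaagaggcaaaaggggacggaaggga**T**ggagccagaggagggggtgacagttgagtctcagccaca"
        "ggtgaaggtggagccactggagg",
        "Cy3-cucuuucucuccuccaguggcuccaccuucaccuguggcugagacucaacugucacccccuccuc"
        "uggcuccaucccuuccguccccuuuugc",
    ),
    # APOE promoter region with GC skew 0.49
    "C-DNA/G-RNA RDH-49": (
        "Cy5-tccagaggcttcatctccggctccactggc**T**ccatcgcctccgtccctggctccatcattgccatctgtc"
        "ccttttcttttttcctcttcttc",
        "Cy3-agccucuggagaagaagaggaaaaaagaaaagggacagauggcaaugauggagccagggacggag"
        "gcgauggagccaguggagccggagauga",
    ),
    "G-DNA/C-RNA RDH-49": (
        "Cy5-gaagaagaggaaaaaagaaaagggacaga**T**ggcaatgatggagccagggacggaggcgatggagccagtg"
        "gagccggagatgaagcctctgga",
        "Cy3-ccucuucuucuccagaggcuucaucuccggcuccacuggcuccaucgccuccgucccuggcucca"
        "ucauugccaucugucccuuuucuuuuuu",
    ),
}
# fmt: on


def construct_oligos(name: str) -> tuple[Oligo, Oligo]:
    """Parse one construct into its (Cy5 strand, Cy3 strand) oligos."""
    text1, text2 = CONSTRUCTS[name]
    safe = name.replace("/", "_").replace(" ", "_")
    return (
        parse_oligo(text1, oligo_id=f"{safe}|cy5"),
        parse_oligo(text2, oligo_id=f"{safe}|cy3"),
    )


def construct_duplex(name: str) -> AnnealedDuplex:
    """Anneal one construct's two strands."""
    o1, o2 = construct_oligos(name)
    return anneal(o1, o2)
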