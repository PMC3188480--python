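"""Packaged metabolite subgroup lists.

Ids are lowercase common names, matching the fixture molecules and the
default id convention of descriptor tables.  The lists are plain tuples so a
caller can extend or replace them when their tables use other id schemes.
"""

#: The 20 proteinogenic amino acids.
AMINO_ACIDS: tuple[str, ...] = (
    "alanine",
    "arginine",
    "asparagine",
    "aspartate",
    "cysteine",
    "glutamate",
    "glutamine",
    "glycine",
    "histidine",
    "isoleucine",
    "leucine",
    "lysine",
    "methionine",
    "phenylalanine",
    "proline",
    "serine",
    "threonine",
    "tryptophan",
    "tyrosine",
    "valine",
)

#: Phosphorylated nucleotides (mono-, di-, tri-phosphates of the common bases).
PHOSPHORYLATED_NUCLEOTIDES: tuple[str, ...] = (
    "amp", "adp", "atp",
    "gmp", "gdp", "gtp",
    "cmp", "cdp", "ctp",
    "ump", "udp", "utp",
)

#: Phosphate-group count per nucleotide, for the fold-per-phosphate analysis.
PHOSPHATE_COUNTS: dict[str, int] = {
    name: 1 + ("dp" in name) + 2 * ("tp" in name) for name in PHOSPHORYLATED_NUCLEOTIDES
}
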