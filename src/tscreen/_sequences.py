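"""Fixed cassette segments and codon tables shared across modules.

The editing oligos are assembled from constant segments flanking the
variable (strain-identifying) region; the same constants serve as exact
anchors when barcode reads are trimmed back to that region.
"""

# Constant segments of the 200-nt editing oligo, in assembly order.
SPACER5 = "TCCTCTGGCGGAAAGCC"
SPACER_MID = "GATC"
PROMOTER_J23119 = "TTGACAGCTAGCTCAGTCCTAGGTATAATACTAGT"
SGRNA_HANDLE = "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAG"

HOMOLOGY_ARM_LEN = 85
PROTOSPACER_LEN = 20
OLIGO_MAX_LEN = 200

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# Highest-frequency E. coli K-12 codon per amino acid (used for the
# introduced mutation; silent PAM edits only need synonymy, checked via
# CODON_TABLE below).
PREFERRED_CODON = {
    "A": "GCG", "R": "CGC", "N": "AAC", "D": "GAT", "C": "TGC",
    "Q": "CAG", "E": "GAA", "G": "GGC", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCG",
    "S": "AGC", "T": "ACC", "W": "TGG", "Y": "TAT", "V": "GTG",
    "*": "TAA",
}

# Standard genetic code.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate(cds: str) -> str:
    return "".join(
        CODON_TABLE.get(cds[i : i + 3].upper(), "X")
        for i in range(0, len(cds) - len(cds) % 3, 3)
    )
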