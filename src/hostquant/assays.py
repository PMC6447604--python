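"""Assay catalog: primer pairs, amplitude thresholds, and reference standards.

Seven EvaGreen ddPCR assays quantify host and bacterial DNA in stool: four
human targets (two LINE-1 repeat amplicons of 55 and 60 bp, and the
mitochondrial ND5 83-bp and CO2 77-bp amplicons), two mouse LINE-1 targets
(58 and 62 bp), and a bacterial 16S rRNA gene target.  Fluorescence-amplitude
thresholds separating positive from negative droplets are fixed per assay
group: 3400 for the human targets, 6300 for 16S, 3000 for the mouse targets.

Two synthetic gBlock double-stranded DNA standards carry the 60-bp LINE-1 and
83-bp ND5 amplicons with an engineered internal EcoRI site each; they serve as
templates of known copy number for linearity and yield validation.
"""

from __future__ import annotations

from dataclasses import dataclass

from .insilico import IUPAC_SETS

HUMAN_THRESHOLD = 3400.0
BACTERIAL_16S_THRESHOLD = 6300.0
MOUSE_THRESHOLD = 3000.0


@dataclass(frozen=True)
class Assay:
    """One ddPCR assay: primer pair, expected amplicon, calling threshold."""

    assay_id: str
    species: str
    forward_primer: str
    reverse_primer: str
    amplicon_length: int
    threshold: float
    anneal_temp: float
    note: str = ""

    def __post_init__(self) -> None:
        for p in (self.forward_primer, self.reverse_primer):
            if not p or any(c not in IUPAC_SETS for c in p.upper()):
                raise ValueError(f"primer {p!r} is not an IUPAC DNA string")
        if self.amplicon_length < len(self.forward_primer) + len(self.reverse_primer):
            raise ValueError("amplicon shorter than the two primers")
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")


ASSAYS: dict[str, Assay] = {
    a.assay_id: a
    for a in [
        Assay("hLINE1-55", "human", "CTCCACCCCAAATCAACAGAAT", "AATAGGTGTGGTGTGGTGCT",
              55, HUMAN_THRESHOLD, 60.0),
        Assay("hLINE1-60", "human", "AAGACAGTGTGGCGATTCCT", "GATGGCTGGGTCAAATGGTAT",
              60, HUMAN_THRESHOLD, 60.0),
        Assay("hND5-83", "human", "AAAACCTGCCCCTACTCCTC", "GGTGGAGATTTGGTGCTGTG",
              83, HUMAN_THRESHOLD, 60.0),
        Assay("hCO2-77", "human", "CATCCTAGTCCTCATCGCCC", "TGGTAAGGGAGGGATCGTTG",
              77, HUMAN_THRESHOLD, 60.0),
        # Amplicon length reported inconsistently at source (173 vs 172 bp);
        # 173 stored, the alternative kept in the note.
        Assay("bact16S-173", "bacterial", "CGGTGAATACGTTCYCGG", "AAGGAGGTGATCCRGCCGCA",
              173, BACTERIAL_16S_THRESHOLD, 60.0,
              note="length also reported as 172 bp"),
        Assay("mLINE1-58", "mouse", "AGGCAACGCTGGAGATAGAA", "ATGCTCGCATCTATGGTTCC",
              58, MOUSE_THRESHOLD, 59.0),
        Assay("mLINE1-62", "mouse", "GGAGCTAAAGGGAACTGCAA", "CCGGGGTACTGCTTAGTTCA",
              62, MOUSE_THRESHOLD, 59.0),
    ]
}

DEFAULT_THRESHOLDS: dict[str, float] = {aid: a.threshold for aid, a in ASSAYS.items()}

# Synthetic gBlock standards.  The LINE-1 gBlock is nominally 126 bp but the
# available transcription totals 125 nt; the embedded 60-bp amplicon
# (primer 20 + gap 19 + primer 21) is internally consistent, so length checks
# on the full fragment are advisory while amplicon checks are exact.
LINE1_GBLOCK_ID = "gBlock-LINE1-60bp"
LINE1_GBLOCK = (
    "ACTGTGAACTAGTTCAACCATTGTGG"
    "AAGACAGTGTGGCGATTCCT"       # forward primer binding site
    "GAGGGATCTAGAATTCGAA"        # engineered EcoRI site inside
    "ATACCATTTGACCCAGCCATC"      # reverse-complement of reverse primer
    "CCATTACTGGGTATATACCCAAAGGATTATAAATCATGC"
)

ND5_GBLOCK_ID = "gBlock-ND5-83bp"
ND5_GBLOCK = (
    "TCTAGGCCTTCTTACGAGCC"
    "AAAACCTGCCCCTACTCCTC"       # forward primer binding site
    "CTAGACCTAACCTGACTAGAAAAGCTATTACCTAAAAGAATTC"  # engineered EcoRI at 3' end
    "CACAGCACCAAATCTCCACC"       # reverse-complement of reverse primer
    "TCCATCATCACCTCAACCCAAAAAGGCATAATTAAACTTTACTTCCTCTCTTTCTTCTTCCCACTCATCCTAACCCTACTCCTAATCACATAA"
)

GBLOCKS: dict[str, str] = {LINE1_GBLOCK_ID: LINE1_GBLOCK, ND5_GBLOCK_ID: ND5_GBLOCK}
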