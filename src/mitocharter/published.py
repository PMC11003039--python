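"""Published annotation tables for the Cymbidium ensifolium mitogenome.

These are the reported gene inventory, C-to-U editing-site spectrum and SSR
class counts for the 19-chromosome C. ensifolium mitochondrial genome
(GenBank OR754263-OR754281). They serve as worked-example inputs for the
summary operations in this package; none of the detection code depends on
them.
"""

from __future__ import annotations

#: Protein-coding genes: (gene, CDS length bp, start codon, stop codon, copies).
#: Codons written "X(Y)" are genomic codons converted to Y by C-to-U editing.
CENSIFOLIUM_PCGS: list[dict] = [
    {"gene": "atp1", "length": 1530, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "atp4", "length": 579, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "atp6", "length": 969, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "atp8", "length": 480, "start_codon": "ATG", "stop_codon": "TAA", "copies": 1},
    {"gene": "atp9", "length": 225, "start_codon": "ATG", "stop_codon": "CGA(TGA)", "copies": 1},
    {"gene": "ccmB", "length": 621, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "ccmC", "length": 723, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "ccmFc", "length": 1317, "start_codon": "ATG", "stop_codon": "CGA(TGA)", "copies": 1},
    {"gene": "ccmFn", "length": 1707, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "cob", "length": 1182, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "cox1", "length": 1584, "start_codon": "ATG", "stop_codon": "TAA", "copies": 1},
    {"gene": "cox2", "length": 801, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "cox3", "length": 798, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "matR", "length": 1899, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "mttB", "length": 351, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "nad1", "length": 978, "start_codon": "ACG(ATG)", "stop_codon": "TAA", "copies": 3},
    {"gene": "nad2", "length": 1509, "start_codon": "ATG", "stop_codon": "TGA", "copies": 2},
    {"gene": "nad3", "length": 357, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "nad4", "length": 1488, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "nad4L", "length": 303, "start_codon": "ATG", "stop_codon": "TAA", "copies": 1},
    {"gene": "nad5", "length": 2016, "start_codon": "ATG", "stop_codon": "TAA", "copies": 3},
    {"gene": "nad6", "length": 747, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "nad7", "length": 1185, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "nad9", "length": 573, "start_codon": "ATG", "stop_codon": "TAA", "copies": 1},
    {"gene": "rpl16", "length": 348, "start_codon": "ATG", "stop_codon": "TAA", "copies": 1},
    {"gene": "rpl5", "length": 546, "start_codon": "ATG", "stop_codon": "TAA", "copies": 1},
    {"gene": "rps12", "length": 378, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "rps13", "length": 351, "start_codon": "ATG", "stop_codon": "TGA", "copies": 1},
    {"gene": "rps14", "length": 303, "start_codon": "ATG", "stop_codon": "TAG", "copies": 1},
    {"gene": "rps7", "length": 447, "start_codon": "ATG", "stop_codon": "TAA", "copies": 1},
]

#: Reported C-to-U editing-site spectrum: (genomic codon, edited codon) -> sites.
#: 29 codon transitions, 530 sites in total, all C->T at codon positions 1-2.
CENSIFOLIUM_EDITING_SPECTRUM: dict[tuple[str, str], int] = {
    ("CAC", "TAC"): 10,
    ("CAT", "TAT"): 18,
    ("CGC", "TGC"): 11,
    ("CGT", "TGT"): 31,
    ("ACA", "ATA"): 5,
    ("ACG", "ATG"): 7,
    ("ACT", "ATT"): 5,
    ("CGG", "TGG"): 32,
    ("TCA", "TTA"): 76,
    ("TCC", "TTC"): 37,
    ("TCG", "TTG"): 41,
    ("TCT", "TTT"): 55,
    ("CGA", "TGA"): 2,
    ("CCA", "TCA"): 8,
    ("CCC", "TCC"): 14,
    ("CCG", "TCG"): 7,
    ("CCT", "TCT"): 20,
    ("CCA", "CTA"): 48,
    ("CCC", "CTC"): 10,
    ("CCC", "TTC"): 6,
    ("CCG", "CTG"): 26,
    ("CCT", "CTT"): 26,
    ("CCT", "TTT"): 12,
    ("CTC", "TTC"): 5,
    ("CTT", "TTT"): 9,
    ("GCA", "GTA"): 1,
    ("GCC", "GTC"): 1,
    ("GCG", "GTG"): 4,
    ("GCT", "GTT"): 3,
}

#: Reported SSR tally by canonical motif class (complement-aware classes).
CENSIFOLIUM_SSR_CLASSES: dict[str, int] = {
    # monomer
    "A/T": 53,
    # dimer
    "AC/GT": 2, "AG/CT": 13, "AT/AT": 9,
    # trimer
    "AAC/GTT": 1, "AAG/CTT": 19, "AAT/ATT": 1, "ACT/AGT": 3,
    "AGC/CTG": 2, "AGG/CCT": 1, "ATC/ATG": 2,
    # tetramer
    "AAAC/GTTT": 1, "AAAG/CTTT": 24, "AACT/AGTT": 1, "AAGC/CTTG": 1,
    "AAGG/CCTT": 1, "AAGT/ACTT": 1, "AATG/ATTC": 4, "ACAG/CTGT": 1,
    "ACAT/ATGT": 1, "ACCG/CGGT": 1, "ACGG/CCGT": 1, "ACGT/ACGT": 1,
    "ACTC/AGTG": 2, "ACTG/AGTC": 4, "AGAT/ATCT": 4, "AGCC/CTGG": 1,
    "AGCG/CGCT": 1, "AGCT/AGCT": 1, "ATCC/ATGG": 1, "CCGG/CCGG": 1,
    # pentamer
    "AGAGG/CCTCT": 2, "ATATC/ATATG": 1,
}

#: Reported dispersed-repeat orientation split.
CENSIFOLIUM_DISPERSED = {"forward": 376, "palindromic": 539}

#: Reported genome-level figures.
CENSIFOLIUM_GENOME = {
    "n_chromosomes": 19,
    "total_length_bp": 560_647,
    "min_chrom_bp": 21_995,
    "max_chrom_bp": 48_212,
    "gc_percent": 43.89,
}
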