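"""Regenerate the packaged synthetic germline V/J reference.

The reference is synthetic: 10 V segments (random stop-free ORFs of 98
codons ending in the conserved Cys104) carrying the V-gene labels seen in
the hybridoma panel, and 4 J segments reverse-translated from murine-JH-like
amino-acid sequences containing the W(F)GxG motif. It is representative
plumbing for desk-scale testing, not the IMGT database.

Run from the repository root:  python scripts/make_germline.py
"""

from pathlib import Path

import numpy as np

from ighclone.germline import GermlineDB, GermlineGene, write_germline

V_NAMES = ["V5-17", "V1-82", "V1-7", "V1-26", "V2-2", "V1-81", "V5-9-1", "V9-4", "V1-9", "V7-3"]
# (name, amino acids, 0-based codon offset of the W(F)GxG Trp)
J_SPECS = [
    ("J1", "YWYFDVWGAGTTVTVSS", 6),
    ("J2", "YFDYWGQGTTLTVSS", 4),
    ("J3", "WFAYWGQGTLVTVSA", 4),
    ("J4", "YYAMDYWGQGTSVTVSS", 6),
]
N_CODONS_V = 98  # Cys104 is the final codon (index 97)

CODON_OF = {
    "A": "GCT", "C": "TGC", "D": "GAT", "E": "GAA", "F": "TTC", "G": "GGA",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAG", "R": "AGA", "S": "AGC", "T": "ACT", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}
STOPS = {"TAA", "TAG", "TGA"}
BASES = "ACGT"


def random_codon(rng: np.random.Generator) -> str:
    while True:
        codon = "".join(rng.choice(list(BASES), size=3))
        if codon not in STOPS:
            return codon


def main() -> None:
    rng = np.random.default_rng(20180705)
    db = GermlineDB()
    for name in V_NAMES:
        codons = [random_codon(rng) for _ in range(N_CODONS_V - 1)] + ["TGT"]
        db.add(GermlineGene(name=name, segment="V", nt_seq="".join(codons), anchor_codon_index=N_CODONS_V - 1))
    for name, aa, offset in J_SPECS:
        nt = "".join(CODON_OF[a] for a in aa)
        db.add(GermlineGene(name=name, segment="J", nt_seq=nt, anchor_codon_index=offset))
    out = Path(__file__).resolve().parent.parent / "src" / "ighclone" / "data"
    out.mkdir(parents=True, exist_ok=True)
    write_germline(db, out / "germline.fasta", out / "germline_anchors.tsv")
    print(f"wrote {len(db)} genes to {out}")


if __name__ == "__main__":
    main()
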