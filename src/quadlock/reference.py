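"""Published reference data for the AT26 family of irregular G4 oligos.

These are experimental inputs (sequences, NMR topology assignments and CD
melting temperatures reported for the AT26 intra-locked G-quadruplex and
its variants), used by the analysis drivers and as worked-example inputs.
"""

from __future__ import annotations

#: 28-mer d[(TGG)4TTG(TGG)3TTGT]; 16 guanines in seven G2 tracts plus two
#: isolated single guanines
AT26 = "TGGTGGTGGTGGTTGTGGTGGTGGTTGT"

#: 26-mer anti-proliferative aptamer the AT-series derives from
AGRO100 = "GGTGGTGGTGGTTGTGGTGGTGGTGG"

#: NMR-derived tetrad compositions of AT26, bottom to top, each in cyclic
#: Hoogsteen donor->acceptor order
AT26_TETRADS = (
    ("G2", "G6", "G9", "G12"),
    ("G15", "G5", "G8", "G11"),
    ("G20", "G23", "G3", "G17"),
    ("G21", "G24", "G27", "G18"),
)

#: guanines with syn glycosidic conformation in AT26
AT26_SYN = ("G2", "G15", "G27")

#: G3 has an intermediate glycosidic angle and receives no dihedral
#: restraint
AT26_CHI_EXCLUDED = ("G3",)

#: all guanine labels of AT26 in sequence order
AT26_GUANINES = tuple(
    f"G{i + 1}" for i, b in enumerate(AT26) if b == "G"
)

#: CD melting temperatures (mean, mean deviation, degrees C) of AT26 and
#: loop/bulge variants under ~150 mM K+
MELTING_TM = {
    "AT26": (40.8, 0.5),
    "insT27": (44.0, 0.5),
    "insT27,28": (35.7, 1.2),
    "insT15": (37.6, 0.7),
    "insT15,16": (34.0, 0.8),
    "delT4": (57.0, 0.0),
    "delT16": (50.6, 0.3),
    "delT4,16": (66.2, 0.5),
}
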