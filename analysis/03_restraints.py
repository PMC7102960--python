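#!/usr/bin/env python
"""Generate the NMR restraint table for the AT26 topology.

From the published tetrad compositions and glycosidic assignments of the
AT26 intra-locked G4 (three syn guanines; G3 left unrestrained because its
angle falls between syn and anti), produces the Hoogsteen hydrogen-bond,
glycosidic dihedral and tetrad planarity restraints and writes them as a
tidy TSV plus an XPLOR-flavoured text under results/restraints/.
"""

from pathlib import Path

from quadlock.reference import (AT26_CHI_EXCLUDED, AT26_GUANINES, AT26_SYN,
                                AT26_TETRADS)
from quadlock.restraints import (dihedral_restraints, hoogsteen_restraints,
                                 planarity_groups, restraint_table,
                                 to_xplor)

OUT = Path(__file__).resolve().parent.parent / "results" / "restraints"
OUT.mkdir(parents=True, exist_ok=True)

hb = hoogsteen_restraints(AT26_TETRADS)
classes = {g: ("syn" if g in AT26_SYN else "anti")
           for g in AT26_GUANINES if g not in AT26_CHI_EXCLUDED}
dih = dihedral_restraints(classes, AT26_CHI_EXCLUDED)
plan = planarity_groups(AT26_TETRADS, weight=1.0)

df = restraint_table(hb, dih, plan)
df.to_csv(OUT / "at26_restraints.tsv", sep="\t", index=False)
(OUT / "at26_restraints.xplor").write_text(to_xplor(hb, dih))

n_syn = sum(1 for r in dih if r.target == 60.0)
print(f"hydrogen-bond restraints: {len(hb)} "
      f"(4 tetrads x 4 pairs x 4 distances)")
print(f"dihedral restraints:      {len(dih)} "
      f"({n_syn} syn at 60 +/- 70 deg, {len(dih) - n_syn} anti at "
      "240 +/- 70 deg; G3 excluded)")
print(f"planarity groups:         {len(plan)}")
print(f"table written to {OUT / 'at26_restraints.tsv'}")
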