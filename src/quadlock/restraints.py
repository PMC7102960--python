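"""NMR-style restraint tables for G-quadruplex structure calculation.

Generates the standard restraint classes used to calculate a G4 solution
structure from a declared topology: Hoogsteen hydrogen-bond distance
restraints for each donor->acceptor pair of every tetrad, glycosidic
dihedral restraints per syn/anti classification, NOE distance-class bounds,
and tetrad planarity groups.  Output is an engine-neutral table (TSV/JSON);
an XPLOR-flavoured text rendering is available behind a flag for
convenience (bit-exactness with any particular engine input is not
claimed).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "DistanceRestraint",
    "DihedralRestraint",
    "PlanarityGroup",
    "NOE_BOUNDS",
    "HOOGSTEEN_DISTANCES",
    "CHI_TARGETS",
    "hoogsteen_restraints",
    "dihedral_restraints",
    "noe_bounds",
    "planarity_groups",
    "restraint_table",
    "to_xplor",
]

#: Hoogsteen H-bond distance targets per donor->acceptor guanine pair:
#: (donor atom, acceptor atom, target A, tolerance A)
HOOGSTEEN_DISTANCES = (
    ("H21", "N7", 2.0, 0.2),
    ("N2", "N7", 2.9, 0.3),
    ("H1", "O6", 2.0, 0.2),
    ("N1", "O6", 2.9, 0.3),
)

#: NOE intensity classes: (target, tolerance) in Angstrom
NOE_BOUNDS = {
    False: {  # non-exchangeable protons
        "strong": (2.7, 0.8),
        "medium": (3.8, 0.9),
        "medium_weak": (4.6, 1.2),
        "weak": (5.5, 1.7),
    },
    True: {  # exchangeable protons
        "strong": (4.0, 1.2),
        "medium": (4.8, 1.4),
        "weak": (5.5, 1.7),
    },
}

#: methyl-involved restraints are loosened by this much (A)
METHYL_LOOSENING = 0.5

#: glycosidic dihedral targets per class: (target deg, tolerance deg)
CHI_TARGETS = {"anti": (240.0, 70.0), "syn": (60.0, 70.0)}

CHI_ATOMS = ("O4'", "C1'", "N9", "C4")


@dataclass(frozen=True)
class DistanceRestraint:
    atom_a: tuple[str, str]  # (residue label, atom name)
    atom_b: tuple[str, str]
    target: float
    tolerance: float
    category: str  # noe_nonexchangeable | noe_exchangeable | hbond

    def __post_init__(self) -> None:
        if self.target <= 0 or self.tolerance < 0:
            raise ValueError("invalid distance restraint bounds")


@dataclass(frozen=True)
class DihedralRestraint:
    residue: str
    atoms: tuple[str, str, str, str]
    target: float
    tolerance: float


@dataclass(frozen=True)
class PlanarityGroup:
    guanines: tuple[str, str, str, str]
    weight: float = 1.0  # recorded, not used computationally


def hoogsteen_restraints(
    tetrads: Sequence[Sequence[str]],
) -> list[DistanceRestraint]:
    """Four distance restraints per donor->acceptor pair, 16 per tetrad.

    Each tetrad is a 4-tuple of residue labels in cyclic donor->acceptor
    order.  A guanine appearing in more than one tetrad is an error.
    """
    seen: set[str] = set()
    for tet in tetrads:
        if len(tet) != 4:
            raise ValueError(f"tetrad must have 4 guanines, got {tet}")
        for g in tet:
            if g in seen:
                raise ValueError(f"guanine {g} appears in multiple tetrads")
            seen.add(g)
    out = []
    for tet in tetrads:
        for i in range(4):
            donor, acceptor = tet[i], tet[(i + 1) % 4]
            for da, aa, target, tol in HOOGSTEEN_DISTANCES:
                out.append(
                    DistanceRestraint(
                        (donor, da), (acceptor, aa), target, tol, "hbond"
                    )
                )
    return out


def dihedral_restraints(
    chi_classes: dict[str, str],
    exclusions: Iterable[str] = (),
) -> list[DihedralRestraint]:
    """One glycosidic dihedral restraint per non-excluded guanine.

    ``chi_classes`` maps residue labels to 'syn' or 'anti'; excluded
    residues (e.g. one with an intermediate, undefined glycosidic angle)
    get no restraint.  A residue both classified and excluded is an error.
    """
    excl = set(exclusions)
    both = excl & set(chi_classes)
    if both:
        raise ValueError(
            f"residues both classified and excluded: {sorted(both)}"
        )
    out = []
    for residue, klass in chi_classes.items():
        if klass not in CHI_TARGETS:
            raise ValueError(
                f"residue {residue}: class must be syn or anti, "
                f"got {klass!r}"
            )
        target, tol = CHI_TARGETS[klass]
        out.append(DihedralRestraint(residue, CHI_ATOMS, target, tol))
    return out


def noe_bounds(
    class_name: str, exchangeable: bool, methyl_involved: bool = False
) -> tuple[float, float]:
    """Distance bound (target, tolerance) for an NOE intensity class.

    Exchangeable-proton NOEs have no medium_weak class.  Restraints
    involving thymine methyl protons are loosened by 0.5 A.
    """
    table = NOE_BOUNDS[bool(exchangeable)]
    if class_name not in table:
        raise ValueError(
            f"no {class_name!r} class for "
            f"{'exchangeable' if exchangeable else 'non-exchangeable'} NOEs"
        )
    target, tol = table[class_name]
    if methyl_involved:
        tol += METHYL_LOOSENING
    return target, tol


def planarity_groups(
    tetrads: Sequence[Sequence[str]], weight: float = 1.0
) -> list[PlanarityGroup]:
    """One planarity group per declared tetrad."""
    return [PlanarityGroup(tuple(t), weight) for t in tetrads]


def restraint_table(
    distance: Sequence[DistanceRestraint] = (),
    dihedral: Sequence[DihedralRestraint] = (),
    planarity: Sequence[PlanarityGroup] = (),
) -> pd.DataFrame:
    """All restraints as one tidy table (one row per restraint)."""
    rows = []
    for r in distance:
        rows.append(
            {
                "type": "distance",
                "category": r.category,
                "selection_a": f"{r.atom_a[0]}:{r.atom_a[1]}",
                "selection_b": f"{r.atom_b[0]}:{r.atom_b[1]}",
                "target": r.target,
                "tolerance": r.tolerance,
            }
        )
    for d in dihedral:
        rows.append(
            {
                "type": "dihedral",
                "category": "chi",
                "selection_a": d.residue + ":" + "-".join(d.atoms),
                "selection_b": "",
                "target": d.target,
                "tolerance": d.tolerance,
            }
        )
    for p in planarity:
        rows.append(
            {
                "type": "planarity",
                "category": "tetrad",
                "selection_a": "+".join(p.guanines),
                "selection_b": "",
                "target": 0.0,
                "tolerance": 0.0,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["type", "category", "selection_a", "selection_b",
                 "target", "tolerance"],
    )


def parse_restraint_table(df: pd.DataFrame):
    """Inverse of :func:`restraint_table` (round-trip support)."""
    distance, dihedral, planarity = [], [], []
    for _, row in df.iterrows():
        if row["type"] == "distance":
            ra, aa = row["selection_a"].split(":")
            rb, ab = row["selection_b"].split(":")
            distance.append(
                DistanceRestraint((ra, aa), (rb, ab), float(row["target"]),
                                  float(row["tolerance"]), row["category"])
            )
        elif row["type"] == "dihedral":
            res, atoms = row["selection_a"].split(":")
            dihedral.append(
                DihedralRestraint(res, tuple(atoms.split("-")),
                                  float(row["target"]),
                                  float(row["tolerance"]))
            )
        elif row["type"] == "planarity":
            planarity.append(
                PlanarityGroup(tuple(row["selection_a"].split("+")))
            )
    return distance, dihedral, planarity


def _xplor_sel(residue: str, atom: str) -> str:
    return f"(resid {residue.lstrip('GTAC')} and name {atom})"


def to_xplor(
    distance: Sequence[DistanceRestraint] = (),
    dihedral: Sequence[DihedralRestraint] = (),
) -> str:
    """Render restraints in an XPLOR-flavoured text format."""
    lines = []
    for r in distance:
        lines.append(
            f"assign {_xplor_sel(*r.atom_a)} {_xplor_sel(*r.atom_b)} "
            f"{r.target:.2f} {r.tolerance:.2f} {r.tolerance:.2f}"
        )
    for d in dihedral:
        sels = " ".join(_xplor_sel(d.residue, a) for a in d.atoms)
        lines.append(
            f"assign {sels} 1.0 {d.target:.1f} {d.tolerance:.1f} 2"
        )
    return "\n".join(lines) + ("\n" if lines else "")
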