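"""Synthetic fixtures with known ground truth.

Three generators cover the package's input domains without any downloads:

* planted-motif FASTA files with a truth BED (background drawn from
  {A,C,T} so no accidental G-tract can arise),
* idealized multi-layer G-quadruplex coordinate sets with known glycosidic
  angles, tetrad compositions, polarities and loop types, and
* two-state van't Hoff melting curves with linear baselines and Gaussian
  noise.

The idealized G4 geometry is an analyzer-grade idealization, not a
force-field structure: guanine bases use standard base dimensions, each
tetrad is a planar cyclic Hoogsteen quartet with N2-N7 and N1-O6 contacts
near 2.9 A, layers stack at a fixed rise and helical twist, and sugar O4'
atoms are placed to realize the planned glycosidic torsion exactly.
"""

from __future__ import annotations

import functools
import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from .geometry import place_atom
from .structure_topology import Residue, StructureModel

__all__ = [
    "PlantSpec",
    "FixtureTopology",
    "plant_motifs_fasta",
    "build_ideal_g4",
    "simulate_melting_curve",
    "fixture_single_tetrad",
    "fixture_parallel",
    "fixture_bilayer_vs",
    "fixture_at26_like",
    "fixture_two_block_single_linker",
]

GAS_CONSTANT_KCAL = 1.987204259e-3  # kcal / (mol K)

#: guanine base + C1' in the standard reference frame (z = base plane)
GUANINE_FRAME = {
    "C1'": np.array([-2.477, 5.399, 0.000]),
    "N9": np.array([-1.289, 4.551, 0.000]),
    "C8": np.array([0.023, 4.962, 0.000]),
    "N7": np.array([0.870, 3.969, 0.000]),
    "C5": np.array([0.071, 2.833, 0.000]),
    "C6": np.array([0.424, 1.460, 0.000]),
    "O6": np.array([1.554, 0.955, 0.000]),
    "N1": np.array([-0.700, 0.641, 0.000]),
    "C2": np.array([-1.999, 1.087, 0.000]),
    "N2": np.array([-2.949, 0.139, -0.001]),
    "N3": np.array([-2.342, 2.364, 0.001]),
    "C4": np.array([-1.265, 3.177, 0.000]),
}

CHI_BY_CLASS = {"syn": 60.0, "anti": 210.0, "undefined": 317.0}


# ---------------------------------------------------------------------------
# Planted-motif FASTA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantSpec:
    """What to plant: a motif instance, how many copies, spacing, seed."""

    motif_text: str
    count: int
    min_gap: int = 10
    seed: int = 0
    query_label: str = "planted"


def plant_motifs_fasta(
    n_records: int,
    record_length: int,
    spec: PlantSpec,
    fasta_path=None,
    bed_path=None,
):
    """Generate background sequence with planted motif instances.

    The background is drawn uniformly from {A,C,T}, so it contains no
    guanine and therefore no accidental G-tract match; planted instances
    are non-overlapping and separated by at least ``min_gap``.  Returns
    (records, truth) where records is a list of (id, sequence) and truth a
    list of (record_id, start, end, label) BED-like rows.  Deterministic
    given the spec's seed.
    """
    motif = spec.motif_text.upper()
    L = len(motif)
    need = spec.count * L + max(spec.count - 1, 0) * spec.min_gap
    if need > record_length:
        raise ValueError(
            f"cannot place {spec.count} x {L} nt with gaps >= "
            f"{spec.min_gap} in {record_length} nt"
        )
    rng = np.random.default_rng(spec.seed)
    bg = np.array(list("ACT"))
    records, truth = [], []
    for ri in range(n_records):
        seq = rng.choice(bg, size=record_length)
        rec_id = f"synth{ri + 1}"
        if spec.count > 0:
            slack = record_length - need
            extra = rng.multinomial(
                slack, np.full(spec.count + 1, 1.0 / (spec.count + 1))
            )
            pos = 0
            for pi in range(spec.count):
                pos += extra[pi] + (spec.min_gap if pi > 0 else 0)
                seq[pos:pos + L] = list(motif)
                truth.append((rec_id, pos, pos + L, spec.query_label))
                pos += L
        records.append((rec_id, "".join(seq)))
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for rec_id, seq in records:
                fh.write(f">{rec_id}\n")
                for i in range(0, len(seq), 70):
                    fh.write(seq[i:i + 70] + "\n")
    if bed_path is not None:
        with open(bed_path, "w") as fh:
            for rec_id, s, e, label in truth:
                fh.write(f"{rec_id}\t{s}\t{e}\t{label}\t0\t+\n")
    return records, truth


# ---------------------------------------------------------------------------
# Idealized G4 coordinate sets
# ---------------------------------------------------------------------------

@functools.lru_cache(maxsize=1)
def _tetrad_placement() -> tuple[float, float, float]:
    """In-plane placement (theta, tx, ty) of the reference guanine so that
    four copies related by 90-degree rotations form a Hoogsteen quartet with
    N2-N7 and N1-O6 near 2.9 A, carbonyl O6 ring near the axis and C1'
    corners at a realistic radius."""
    names = list(GUANINE_FRAME)
    P = np.vstack([GUANINE_FRAME[n] for n in names])

    def rz(deg):
        t = np.radians(deg)
        return np.array(
            [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0],
             [0, 0, 1]]
        )

    def copies(x):
        th, tx, ty = x
        q = (rz(th) @ P.T).T + np.array([tx, ty, 0.0])
        return [dict(zip(names, (rz(90 * k) @ q.T).T)) for k in range(4)]

    def resid(x):
        a, b = copies(x)[:2]
        # the two bond lengths are hard targets; the radial terms only
        # select among the one-parameter family of solutions
        return [
            10.0 * (np.linalg.norm(a["N2"] - b["N7"]) - 2.9),
            10.0 * (np.linalg.norm(a["N1"] - b["O6"]) - 2.9),
            0.1 * (np.linalg.norm(a["O6"][:2]) - 2.45),
            0.1 * (np.linalg.norm(a["C1'"][:2]) - 6.9),
        ]

    sol = least_squares(resid, [280.0, 0.5, 2.7])
    return tuple(float(v) for v in sol.x)


def _rz(deg: float) -> np.ndarray:
    t = np.radians(deg)
    return np.array(
        [[np.cos(t), -np.sin(t), 0], [np.sin(t), np.cos(t), 0], [0, 0, 1]]
    )

_FLIP_X = np.diag([1.0, -1.0, -1.0])  # proper rotation: layer turned over


@dataclass(frozen=True)
class FixtureTopology:
    """A realizable plan for an idealized G4 coordinate fixture.

    ``strand_path`` walks 5'->3' through the molecule: ``("G", layer,
    corner)`` places a tetrad guanine at that slot, ``("T", n)`` inserts n
    thymine spacer residues.  Layers count from the bottom (0), corners
    cyclically 0-3 in the Hoogsteen donor->acceptor order of the bottom
    layer.  ``polarity_pattern`` holds +1/-1 per layer; -1 layers are built
    turned over, which reverses their circulation as seen along the common
    axis.  ``chi_plan`` maps residue numbers to syn/anti/undefined or to an
    explicit torsion in degrees (default anti).
    """

    n_layers: int
    polarity_pattern: tuple[int, ...]
    strand_path: tuple
    loop_plan: tuple[tuple[str, int], ...] = ()
    chi_plan: dict = field(default_factory=dict)
    rise: float = 3.3
    twist: float = 30.0

    def __post_init__(self) -> None:
        if len(self.polarity_pattern) != self.n_layers:
            raise ValueError("polarity_pattern length must equal n_layers")
        slots = [e[1:] for e in self.strand_path if e[0] == "G"]
        if len(slots) != len(set(slots)):
            raise ValueError("strand_path reuses a tetrad slot")
        expected = {(l, c) for l in range(self.n_layers) for c in range(4)}
        if set(slots) != expected:
            raise ValueError(
                "strand_path must fill every (layer, corner) slot exactly "
                "once for the planned number of layers"
            )


def _slot_geometry(plan: FixtureTopology):
    """Base-atom coordinates for every (layer, corner) slot of the plan."""
    th, tx, ty = _tetrad_placement()
    names = list(GUANINE_FRAME)
    P = np.vstack([GUANINE_FRAME[n] for n in names])
    ring = [n for n in names if n != "C1'"]
    base = (_rz(th) @ P.T).T + np.array([tx, ty, 0.0])
    # reference corner angle of copy 0
    bc0 = np.mean(
        [base[names.index(n)] for n in ring], axis=0
    )
    ref_angle = np.degrees(np.arctan2(bc0[1], bc0[0])) % 360.0
    slots = {}
    for layer in range(plan.n_layers):
        m = _rz(plan.twist * layer)
        if plan.polarity_pattern[layer] < 0:
            m = m @ _FLIP_X
        shift = np.array([0.0, 0.0, plan.rise * layer])
        for k in range(4):
            pts = (m @ (_rz(90 * k) @ base.T)).T + shift
            atoms = dict(zip(names, pts))
            bc = np.mean([atoms[n] for n in ring], axis=0)
            ang = (
                np.degrees(np.arctan2(bc[1], bc[0]))
                - plan.twist * layer
            ) % 360.0
            corner = int(np.round((ang - ref_angle) / 90.0)) % 4
            slots[(layer, corner)] = atoms
    if len(slots) != 4 * plan.n_layers:
        raise ValueError("corner assignment collision while building slots")
    return slots


def _check_clashes(residues: Sequence[Residue], min_dist: float = 1.5):
    for ra, rb in itertools.combinations(residues, 2):
        if ra.chain == rb.chain and abs(ra.number - rb.number) < 2:
            continue  # bonded neighbours may approach freely
        pa = np.vstack(list(ra.atoms.values()))
        pb = np.vstack(list(rb.atoms.values()))
        d = np.linalg.norm(pa[:, None, :] - pb[None, :, :], axis=-1)
        if d.min() < min_dist:
            raise ValueError(
                f"steric clash ({d.min():.2f} A) between "
                f"{ra.name}{ra.number} and {rb.name}{rb.number}"
            )


def build_ideal_g4(
    plan: FixtureTopology,
    n_models: int = 1,
    jitter_sd: float = 0.0,
    seed: int = 0,
    chain: str = "A",
) -> tuple[list[StructureModel], dict]:
    """Build idealized coordinates plus a truth record from a plan.

    Model 1 is the clean construction; further models are rigid random
    reorientations with optional Gaussian coordinate jitter (deterministic
    per seed).  Raises on unrealizable plans and on steric clashes below
    1.5 A between non-bonded residues.
    """
    slots = _slot_geometry(plan)
    residues: list[Residue] = []
    num = 0
    g_positions: list[int] = []
    for elem in plan.strand_path:
        if elem[0] == "G":
            num += 1
            _, layer, corner = elem
            atoms = {k: v.copy() for k, v in slots[(layer, corner)].items()}
            chi = plan.chi_plan.get(num, "anti")
            chi_deg = CHI_BY_CLASS.get(chi, chi)
            atoms["O4'"] = place_atom(
                atoms["C4"], atoms["N9"], atoms["C1'"],
                bond=1.42, angle_deg=108.0, torsion_deg=float(chi_deg),
            )
            residues.append(Residue(chain, num, "DG", atoms))
            g_positions.append(len(residues) - 1)
        elif elem[0] == "T":
            for _ in range(elem[1]):
                num += 1
                residues.append(Residue(chain, num, "DT", {}))
        else:
            raise ValueError(f"unknown strand_path element: {elem}")

    # spacer thymines: exterior arc between the C1' atoms of the nearest
    # placed guanines (or extended past the termini)
    n_res = len(residues)
    g_c1 = {
        i: residues[i].atoms["C1'"] for i in g_positions
    }
    for i, res in enumerate(residues):
        if res.name != "DT":
            continue
        prev_g = max((j for j in g_positions if j < i), default=None)
        next_g = min((j for j in g_positions if j > i), default=None)
        if prev_g is not None and next_g is not None:
            f = (i - prev_g) / (next_g - prev_g)
            p = (1 - f) * g_c1[prev_g] + f * g_c1[next_g]
        elif next_g is not None:  # 5' overhang
            p = g_c1[next_g] + np.array([0.0, 0.0, -2.5 * (next_g - i)])
        else:  # 3' overhang
            p = g_c1[prev_g] + np.array([0.0, 0.0, 2.5 * (i - prev_g)])
        r_xy = np.linalg.norm(p[:2])
        scale = 11.0 / r_xy if r_xy > 1e-6 else 0.0
        p = np.array([p[0] * scale, p[1] * scale, p[2]])
        radial = p / max(np.linalg.norm(p[:2]), 1e-6)
        res.atoms["C1'"] = p
        res.atoms["N1"] = p + 1.5 * np.array([radial[0], radial[1], 0.0])
        res.atoms["C2"] = p + np.array([0.0, 0.0, 1.2])
    _check_clashes(residues)

    rng = np.random.default_rng(seed)
    models = []
    for mi in range(1, n_models + 1):
        if mi == 1:
            copies = [
                Residue(r.chain, r.number, r.name,
                        {k: v.copy() for k, v in r.atoms.items()})
                for r in residues
            ]
        else:
            rot = Rotation.random(random_state=rng).as_matrix()
            shift = rng.uniform(-5, 5, size=3)
            copies = []
            for r in residues:
                atoms = {}
                for k, v in r.atoms.items():
                    p = rot @ v + shift
                    if jitter_sd > 0:
                        p = p + rng.normal(0.0, jitter_sd, size=3)
                    atoms[k] = p
                copies.append(Residue(r.chain, r.number, r.name, atoms))
        models.append(StructureModel(index=mi, residues=copies))

    rel = [
        "same" if plan.polarity_pattern[i] == plan.polarity_pattern[i + 1]
        else "reverse"
        for i in range(plan.n_layers - 1)
    ]
    blocks: list[list[int]] = [[0]]
    for i, r in enumerate(rel):
        blocks[-1].append(i + 1) if r == "same" else blocks.append([i + 1])
    tetrad_truth = []
    for layer in range(plan.n_layers):
        members = sorted(
            f"G{n}" for n, e in _numbered_g(plan) if e[1] == layer
        )
        tetrad_truth.append(members)
    truth = {
        "n_layers": plan.n_layers,
        "polarity_pattern": list(plan.polarity_pattern),
        "relative_polarity": rel,
        "tetrads": tetrad_truth,
        "loops": [
            {"kind": k, "length": ln} for k, ln in plan.loop_plan
        ],
        "chi": {
            f"G{n}": (
                c if isinstance(c, str) else float(c)
            )
            for n, _ in _numbered_g(plan)
            for c in [plan.chi_plan.get(n, "anti")]
        },
        "n_blocks": len(blocks),
        "blocks": blocks,
    }
    return models, truth


def _numbered_g(plan: FixtureTopology):
    num = 0
    out = []
    for elem in plan.strand_path:
        if elem[0] == "G":
            num += 1
            out.append((num, elem))
        else:
            num += elem[1]
    return out


# ---------------------------------------------------------------------------
# Fixture factories
# ---------------------------------------------------------------------------

def fixture_single_tetrad() -> FixtureTopology:
    """One layer, four guanines, no loops (direct slot walk)."""
    path = tuple(("G", 0, c) for c in range(4))
    return FixtureTopology(1, (1,), path)


def fixture_parallel(n_layers: int = 3, loop_len: int = 1) -> FixtureTopology:
    """All-parallel stack: four tracts running top->bottom down each corner
    column, joined by exterior connectors (classic propeller loops)."""
    path: list = []
    loops = []
    for c in range(4):
        if c:
            path.append(("T", loop_len))
            loops.append(("propeller", loop_len))
        for layer in range(n_layers - 1, -1, -1):
            path.append(("G", layer, c))
    return FixtureTopology(
        n_layers, tuple([1] * n_layers), tuple(path), tuple(loops)
    )


def fixture_bilayer_vs() -> FixtureTopology:
    """Two same-polarity layers where the last corner column is filled by
    two isolated, non-sequential guanines: the final 2-nt connector arrives
    at an unsupported column slot and is a V_S loop spanning two layers."""
    path = (
        ("G", 0, 0),                      # isolated bottom corner
        ("T", 1),
        ("G", 1, 1), ("G", 0, 1),
        ("T", 1),
        ("G", 1, 2), ("G", 0, 2),
        ("T", 1),
        ("G", 1, 3), ("G", 0, 3),
        ("T", 2),
        ("G", 1, 0),                      # isolated top corner
    )
    loops = (
        ("propeller", 1), ("propeller", 1), ("propeller", 1), ("V_S", 2),
    )
    return FixtureTopology(2, (1, 1), path, loops)


def fixture_at26_like() -> FixtureTopology:
    """Four layers in two opposite-polarity bi-layer blocks fastened by
    three bridges: a 0-nt V_R connector spanning three layers, and two
    1-nt bulges.  Mirrors the intra-locked architecture of an irregular
    short-G-tract G4: loops are 4 propellers, 1 edgewise, one V_S (span 2)
    and one V_R (span 3), plus the two bulges."""
    path = (
        ("T", 1),
        ("G", 0, 0),            # 2
        ("G", 2, 1),            # 3   0-nt V_R bridge from residue 2
        ("T", 1),               # 4   bulge
        ("G", 1, 1), ("G", 0, 1),       # 5, 6
        ("T", 1),               # 7   propeller
        ("G", 1, 2), ("G", 0, 2),       # 8, 9
        ("T", 1),               # 10  propeller
        ("G", 1, 3), ("G", 0, 3),       # 11, 12
        ("T", 2),               # 13, 14  V_S
        ("G", 1, 0),            # 15
        ("T", 1),               # 16  bulge
        ("G", 2, 0), ("G", 3, 0),       # 17, 18
        ("T", 1),               # 19  propeller
        ("G", 2, 3), ("G", 3, 3),       # 20, 21
        ("T", 1),               # 22  propeller
        ("G", 2, 2), ("G", 3, 2),       # 23, 24
        ("T", 2),               # 25, 26  edgewise
        ("G", 3, 1),            # 27
        ("T", 1),               # 28
    )
    loops = (
        ("V_R", 0), ("bulge", 1), ("propeller", 1), ("propeller", 1),
        ("V_S", 2), ("bulge", 1), ("propeller", 1), ("propeller", 1),
        ("edgewise", 2),
    )
    chi_plan = {2: "syn", 15: "syn", 27: "syn", 3: "undefined"}
    return FixtureTopology(4, (1, 1, -1, -1), path, loops, chi_plan)


def fixture_two_block_single_linker() -> FixtureTopology:
    """Two independent opposite-polarity bi-layer blocks joined by a single
    2-nt linker: two blocks but only one bridge, so not intra-locked."""
    path = (
        ("G", 1, 0), ("G", 0, 0),
        ("T", 1),
        ("G", 1, 1), ("G", 0, 1),
        ("T", 1),
        ("G", 1, 2), ("G", 0, 2),
        ("T", 1),
        ("G", 1, 3), ("G", 0, 3),
        ("T", 2),               # the single inter-block linker
        ("G", 2, 0), ("G", 3, 0),
        ("T", 1),
        ("G", 2, 1), ("G", 3, 1),
        ("T", 1),
        ("G", 2, 2), ("G", 3, 2),
        ("T", 1),
        ("G", 2, 3), ("G", 3, 3),
    )
    loops = (
        ("propeller", 1), ("propeller", 1), ("propeller", 1),
        ("V_R", 2),
        ("propeller", 1), ("propeller", 1), ("propeller", 1),
    )
    return FixtureTopology(4, (1, 1, -1, -1), tuple(path), loops)


# ---------------------------------------------------------------------------
# Melting curves
# ---------------------------------------------------------------------------

def simulate_melting_curve(
    tm_celsius: float,
    dh_kcal: float = -45.0,
    folded_baseline: tuple[float, float] = (1.0, 0.0),
    unfolded_baseline: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    seed: int = 0,
    t_min: float = 15.0,
    t_max: float = 90.0,
    step: float = 0.5,
    branch: str = "heating",
):
    """Two-state van't Hoff melting curve with linear baselines.

    theta(T) = 1 / (1 + exp((dH/R)(1/T - 1/Tm))) with absolute
    temperatures; the observed signal interpolates between the folded and
    unfolded baselines (each given as (intercept, slope per degree C)) and
    carries Gaussian noise of the given standard deviation.  dH < 0 is the
    folding enthalpy, so theta decreases with temperature.
    """
    from .melting import MeltingCurve

    if not (t_min < tm_celsius < t_max):
        raise ValueError("tm must lie inside the temperature range")
    if dh_kcal >= 0:
        raise ValueError("folding enthalpy must be negative")
    rng = np.random.default_rng(seed)
    temps = np.arange(t_min, t_max + step / 2, step)
    if branch == "cooling":
        temps = temps[::-1]
    tk = temps + 273.15
    tmk = tm_celsius + 273.15
    theta = 1.0 / (1.0 + np.exp((dh_kcal / GAS_CONSTANT_KCAL)
                                * (1.0 / tk - 1.0 / tmk)))
    s_f = folded_baseline[0] + folded_baseline[1] * temps
    s_u = unfolded_baseline[0] + unfolded_baseline[1] * temps
    signal = theta * s_f + (1.0 - theta) * s_u
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return MeltingCurve(
        temperature=temps.astype(float),
        signal=signal.astype(float),
        branch=branch,
    )
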