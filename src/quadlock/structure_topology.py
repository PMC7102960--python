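"""Topology analysis of G-quadruplex structures from atomic coordinates.

Given one or more models of a folded DNA oligonucleotide, this module
computes glycosidic torsions and their syn/anti classification, detects
G-tetrads as directed 4-cycles of Hoogsteen hydrogen bonds (N1->O6 and
N2->N7 donor/acceptor geometry), orders the tetrads along the stacking axis
and assigns each a hydrogen-bond circulation sign ("polarity"), classifies
the connecting segments of the strand (propeller, edgewise, diagonal,
V-shaped, bulge), detects the intra-locked two-block architecture, and
measures pairwise ensemble RMSD after optimal superposition.

Polarity here is the circulation sense of the donor->acceptor Hoogsteen
cycle viewed along the common stacking axis; two stacked tetrads have
"same" or "reverse" relative polarity according to whether their
circulation signs agree.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
from scipy.stats import circmean, circstd

from .geometry import dihedral_deg, fit_plane, superpose_rmsd, unit

__all__ = [
    "Residue",
    "StructureModel",
    "ChiAssignment",
    "HoogsteenEdge",
    "Tetrad",
    "StackReport",
    "LoopAnnotation",
    "G4Topology",
    "StackingError",
    "compute_chi",
    "classify_chi",
    "detect_hoogsteen_edges",
    "assemble_tetrads",
    "order_stack_and_polarity",
    "assign_columns",
    "classify_loops",
    "detect_intralock",
    "ensemble_rmsd",
    "analyze_model",
    "analyze_topology",
]

GUANINE_NAMES = {"DG", "G", "GUA"}
#: heavy atoms of the guanine base (ring + exocyclic O6/N2)
GUANINE_RING_ATOMS = (
    "N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4",
)

DEFAULT_HBOND_CUTOFF = 3.5       # Angstrom, heavy-atom donor-acceptor
DEFAULT_PLANARITY_RMSD = 0.75    # Angstrom, base heavy atoms to best plane
STACK_MIN_SEP = 2.5              # Angstrom, adjacent tetrad centroids
STACK_MAX_SEP = 5.0
DEFAULT_COLUMN_CUTOFF = 3.5      # Angstrom, projected base-centroid pairing


class StackingError(ValueError):
    """Raised when tetrads do not form a single contiguous stack."""

    def __init__(self, message: str, blocks=None):
        super().__init__(message)
        self.blocks = blocks or []


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class Residue:
    """One residue of one model; atoms keyed by PDB atom name."""

    chain: str
    number: int
    name: str
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int]:
        return (self.chain, self.number)

    @property
    def is_guanine(self) -> bool:
        return self.name in GUANINE_NAMES

    def atom(self, name: str) -> np.ndarray:
        try:
            return self.atoms[name]
        except KeyError:
            raise KeyError(
                f"residue {self.name}{self.number} (chain {self.chain}) "
                f"is missing atom {name}"
            ) from None

    def base_centroid(self) -> np.ndarray:
        pts = [self.atoms[a] for a in GUANINE_RING_ATOMS if a in self.atoms]
        if not pts:
            raise ValueError(
                f"residue {self.name}{self.number} has no base atoms"
            )
        return np.mean(pts, axis=0)

    def label(self) -> str:
        one = {"DG": "G", "GUA": "G", "DT": "T", "THY": "T",
               "DA": "A", "DC": "C"}.get(self.name, self.name[-1])
        return f"{one}{self.number}"


@dataclass(eq=False)
class StructureModel:
    """All residues of one model, in file order."""

    index: int
    residues: list[Residue] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_key = {r.key: r for r in self.residues}

    def residue(self, chain: str, number: int) -> Residue:
        return self._by_key[(chain, number)]

    @property
    def guanines(self) -> list[Residue]:
        return [r for r in self.residues if r.is_guanine]

    def sorted_residues(self) -> list[Residue]:
        return sorted(self.residues, key=lambda r: (r.chain, r.number))


@dataclass(frozen=True)
class ChiAssignment:
    residue_label: str
    chi_deg: float
    klass: str  # syn / anti / undefined


@dataclass(eq=False)
class HoogsteenEdge:
    donor: Residue
    acceptor: Residue
    d_N2_N7: float
    d_N1_O6: float


@dataclass(eq=False)
class Tetrad:
    """Four guanines in donor->acceptor cyclic order."""

    guanines: tuple[Residue, Residue, Residue, Residue]
    plane_normal: np.ndarray
    planarity_rmsd: float
    layer_index: Optional[int] = None

    def centroid(self) -> np.ndarray:
        return np.mean([g.base_centroid() for g in self.guanines], axis=0)

    def residue_keys(self) -> frozenset:
        return frozenset(g.key for g in self.guanines)

    def composition(self) -> tuple[str, ...]:
        return tuple(g.label() for g in self.guanines)


@dataclass(eq=False)
class StackReport:
    tetrads: list[Tetrad]                    # ordered bottom -> top
    axis: np.ndarray                         # unit stacking axis
    polarity_signs: list[int]                # +1 / -1 per tetrad
    relative_polarity: list[str]             # same / reverse, len n-1


@dataclass(eq=False)
class LoopAnnotation:
    residues: list[Residue]
    flank5: Residue
    flank3: Residue
    kind: str  # propeller/edgewise/diagonal/V_S/V_R/bulge/step/linker
    span_layers: int
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "residues": [r.label() for r in self.residues],
            "flank5": self.flank5.label(),
            "flank3": self.flank3.label(),
            "kind": self.kind,
            "span_layers": self.span_layers,
        }


@dataclass(eq=False)
class G4Topology:
    """Full structural report for one model or an ensemble consensus."""

    chi: list[ChiAssignment]
    stack: StackReport
    loops: list[LoopAnnotation]
    blocks: list[list[int]]
    bridging_linkers: list[LoopAnnotation]
    intra_locked: bool

    def to_dict(self) -> dict:
        return {
            "chi": [
                {"residue": c.residue_label, "chi_deg": round(c.chi_deg, 1),
                 "class": c.klass}
                for c in self.chi
            ],
            "tetrads": [
                {"layer": t.layer_index,
                 "composition": list(t.composition()),
                 "planarity_rmsd": round(t.planarity_rmsd, 3)}
                for t in self.stack.tetrads
            ],
            "relative_polarity": self.stack.relative_polarity,
            "loops": [lp.to_dict() for lp in self.loops],
            "blocks": self.blocks,
            "bridging_linkers": [b.to_dict() for b in self.bridging_linkers],
            "intra_locked": self.intra_locked,
        }


# ---------------------------------------------------------------------------
# Glycosidic torsion
# ---------------------------------------------------------------------------

def compute_chi(residue: Residue) -> float:
    """Glycosidic torsion O4'-C1'-N9-C4 of a purine, in [0, 360) degrees."""
    pts = [residue.atom(a) for a in ("O4'", "C1'", "N9", "C4")]
    for name, p in zip(("O4'", "C1'", "N9", "C4"), pts):
        if not np.all(np.isfinite(p)):
            raise ValueError(
                f"non-finite coordinates for atom {name} of "
                f"{residue.name}{residue.number}"
            )
    return dihedral_deg(*pts)


def classify_chi(chi_deg: float) -> str:
    """syn for 0 < chi < 90, anti for 180 < chi < 240, otherwise undefined.

    Boundaries are open: 0, 90, 180 and 240 all classify as undefined.
    """
    if 0.0 < chi_deg < 90.0:
        return "syn"
    if 180.0 < chi_deg < 240.0:
        return "anti"
    return "undefined"


# ---------------------------------------------------------------------------
# Hoogsteen edges and tetrads
# ---------------------------------------------------------------------------

def detect_hoogsteen_edges(
    model: StructureModel, cutoff: float = DEFAULT_HBOND_CUTOFF
) -> list[HoogsteenEdge]:
    """Directed guanine-guanine Hoogsteen contacts.

    An edge donor->acceptor requires both heavy-atom distances
    d(N2_donor, N7_acceptor) and d(N1_donor, O6_acceptor) within the cutoff.
    Each guanine keeps at most one outgoing and one incoming edge; conflicts
    resolve to the geometrically closest pair.
    """
    gs = [g for g in model.guanines
          if all(a in g.atoms for a in ("N1", "N2", "N7", "O6"))]
    candidates = []
    for d, a in itertools.permutations(gs, 2):
        d1 = float(np.linalg.norm(d.atom("N2") - a.atom("N7")))
        d2 = float(np.linalg.norm(d.atom("N1") - a.atom("O6")))
        if d1 <= cutoff and d2 <= cutoff:
            candidates.append((d1 + d2, d, a, d1, d2))
    candidates.sort(key=lambda c: (c[0], c[1].key, c[2].key))
    out_used: set = set()
    in_used: set = set()
    edges = []
    for _, d, a, d1, d2 in candidates:
        if d.key in out_used or a.key in in_used:
            continue
        out_used.add(d.key)
        in_used.add(a.key)
        edges.append(HoogsteenEdge(d, a, d1, d2))
    return edges


def assemble_tetrads(
    edges: Sequence[HoogsteenEdge],
    planarity_threshold: float = DEFAULT_PLANARITY_RMSD,
) -> list[Tetrad]:
    """Group Hoogsteen edges into planar directed 4-cycles.

    Cycles of any other length are reported as warnings and discarded, as
    are 4-cycles whose bases deviate from a common plane by more than the
    RMSD threshold.
    """
    succ = {e.donor.key: e.acceptor for e in edges}
    res_by_key = {e.donor.key: e.donor for e in edges}
    for e in edges:
        res_by_key.setdefault(e.acceptor.key, e.acceptor)
    seen: set = set()
    tetrads = []
    for start_key in sorted(succ):
        if start_key in seen:
            continue
        cycle = [start_key]
        cur = start_key
        closed = False
        while True:
            nxt = succ.get(cur)
            if nxt is None:
                break
            if nxt.key == start_key:
                closed = True
                break
            if nxt.key in cycle:
                break
            cycle.append(nxt.key)
            cur = nxt.key
            if len(cycle) > len(succ):
                break
        if not closed:
            continue
        seen.update(cycle)
        if len(cycle) != 4:
            warnings.warn(
                f"Hoogsteen cycle of length {len(cycle)} ignored: "
                + ",".join(str(k) for k in cycle)
            )
            continue
        gs = tuple(res_by_key[k] for k in cycle)
        pts = np.vstack(
            [g.atoms[a] for g in gs for a in GUANINE_RING_ATOMS
             if a in g.atoms]
        )
        normal, rmsd = fit_plane(pts)
        if rmsd > planarity_threshold:
            warnings.warn(
                f"non-planar 4-cycle (RMSD {rmsd:.2f} A) ignored: "
                + ",".join(g.label() for g in gs)
            )
            continue
        # canonical cyclic order: start at the smallest residue key
        i0 = min(range(4), key=lambda i: gs[i].key)
        gs = gs[i0:] + gs[:i0]
        tetrads.append(Tetrad(gs, normal, rmsd))
    return tetrads


# ---------------------------------------------------------------------------
# Stacking order and polarity
# ---------------------------------------------------------------------------

def order_stack_and_polarity(tetrads: Sequence[Tetrad]) -> StackReport:
    """Order tetrads along the stacking axis and sign their circulation.

    The axis is the first principal direction of the tetrad centroids.
    Adjacent layers must be 2.5-5.0 A apart; otherwise the tetrads form
    more than one stack and a :class:`StackingError` lists the groups.
    The polarity sign of a layer is the sense of its donor->acceptor cycle
    viewed along the global axis.
    """
    if len(tetrads) < 2:
        raise ValueError("need at least two tetrads to define a stack")
    centroids = np.vstack([t.centroid() for t in tetrads])
    centered = centroids - centroids.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    # deterministic sign: largest-magnitude component positive
    if axis[np.argmax(np.abs(axis))] < 0:
        axis = -axis
    proj = centered @ axis
    order = np.argsort(proj)
    ordered = [tetrads[i] for i in order]
    seps = np.diff(np.sort(proj))
    if np.any(seps < STACK_MIN_SEP) or np.any(seps > STACK_MAX_SEP):
        blocks, cur = [], [ordered[0]]
        for t, s in zip(ordered[1:], seps):
            if STACK_MIN_SEP <= s <= STACK_MAX_SEP:
                cur.append(t)
            else:
                blocks.append(cur)
                cur = [t]
        blocks.append(cur)
        raise StackingError(
            "tetrads do not form a single stack; detected groups: "
            + "; ".join(
                "+".join("/".join(t.composition()) for t in b) for b in blocks
            ),
            blocks=[[t.composition() for t in b] for b in blocks],
        )
    signs = []
    for li, t in enumerate(ordered):
        t.layer_index = li
        c = t.centroid()
        v = [g.atom("N9") - c for g in t.guanines]
        s = sum(
            float(np.dot(np.cross(v[i], v[(i + 1) % 4]), axis))
            for i in range(4)
        )
        signs.append(1 if s > 0 else -1)
    rel = [
        "same" if signs[i] == signs[i + 1] else "reverse"
        for i in range(len(signs) - 1)
    ]
    return StackReport(ordered, axis, signs, rel)


# ---------------------------------------------------------------------------
# Corner columns
# ---------------------------------------------------------------------------

def assign_columns(
    stack: StackReport, cutoff: float = DEFAULT_COLUMN_CUTOFF
) -> dict:
    """Group tetrad guanines into corner columns.

    Base-ring centroids are projected onto the plane perpendicular to the
    stacking axis; guanines of *adjacent* layers pair by mutual nearest
    neighbour within the cutoff, and columns are the connected components of
    those pairings.  Restricting pairing to adjacent layers keeps helical
    twist from bridging distinct corners across distant layers.

    Returns a dict with ``column_of`` (residue key -> column id),
    ``column_order`` (column ids in the cyclic corner order of the bottom
    tetrad) and ``slots`` ((layer, column) -> Residue).
    """
    axis = stack.axis
    origin = np.mean([t.centroid() for t in stack.tetrads], axis=0)

    def project(g: Residue) -> np.ndarray:
        p = g.base_centroid() - origin
        return p - np.dot(p, axis) * axis

    parent: dict = {}

    def find(k):
        while parent[k] != k:
            parent[k] = parent[parent[k]]
            k = parent[k]
        return k

    def union(a, b):
        parent[find(a)] = find(b)

    for t in stack.tetrads:
        for g in t.guanines:
            parent[g.key] = g.key
    for lower, upper in zip(stack.tetrads, stack.tetrads[1:]):
        lo = [(g, project(g)) for g in lower.guanines]
        hi = [(g, project(g)) for g in upper.guanines]
        for gl, pl in lo:
            dists = [float(np.linalg.norm(pl - ph)) for _, ph in hi]
            j = int(np.argmin(dists))
            if dists[j] > cutoff:
                continue
            gh, ph = hi[j]
            back = [float(np.linalg.norm(ph - p2)) for _, p2 in lo]
            if lo[int(np.argmin(back))][0] is gl:  # mutual nearest
                union(gl.key, gh.key)

    roots = {}
    column_of = {}
    for t in stack.tetrads:
        for g in t.guanines:
            r = find(g.key)
            if r not in roots:
                roots[r] = len(roots)
            column_of[g.key] = roots[r]
    # cyclic order of columns from the bottom tetrad's guanine cycle
    column_order = [column_of[g.key] for g in stack.tetrads[0].guanines]
    slots = {}
    for t in stack.tetrads:
        for g in t.guanines:
            slots[(t.layer_index, column_of[g.key])] = g
    return {
        "column_of": column_of,
        "column_order": column_order,
        "slots": slots,
    }


# ---------------------------------------------------------------------------
# Loop classification
# ---------------------------------------------------------------------------

def _connectors(model: StructureModel, stack: StackReport, columns: dict):
    """All same-chain connectors between sequence-consecutive tetrad guanines.

    Yields (flank5, flank3, run_of_residues_between).
    """
    in_tetrad = {
        g.key: t for t in stack.tetrads for g in t.guanines
    }
    for chain_id, residues in itertools.groupby(
        model.sorted_residues(), key=lambda r: r.chain
    ):
        residues = list(residues)
        prev = None
        run: list[Residue] = []
        for r in residues:
            if r.key in in_tetrad:
                if prev is not None:
                    yield prev, r, run
                prev = r
                run = []
            elif prev is not None:
                run.append(r)


def classify_loops(
    model: StructureModel,
    stack: StackReport,
    columns: Optional[dict] = None,
    include_steps: bool = False,
) -> list[LoopAnnotation]:
    """Classify every strand connector between consecutive tetrad guanines.

    Kinds: ``edgewise`` (same layer, cycle-adjacent corners), ``diagonal``
    (same layer, opposite corners), ``propeller`` (adjacent corners of
    different layers with the destination column covalently supported),
    ``V_S``/``V_R`` (connector reaching a column slot whose support guanine
    is not sequentially bonded: V-shaped loop, subtyped by the relative
    polarity of the two connected layers), ``bulge`` (non-empty run between
    directly stacked guanines of one column), ``step`` (empty run between
    directly stacked guanines, i.e. an ordinary tract continuation; only
    returned when ``include_steps``), ``linker`` (anything else).
    """
    if columns is None:
        columns = assign_columns(stack)
    col_of = columns["column_of"]
    order = columns["column_order"]
    slots = columns["slots"]
    layer_of = {
        g.key: t.layer_index for t in stack.tetrads for g in t.guanines
    }
    cyclepos = {
        g.key: (t.layer_index, i)
        for t in stack.tetrads
        for i, g in enumerate(t.guanines)
    }
    n_cols = len(set(col_of.values()))
    col_pos = {c: i for i, c in enumerate(order)}

    def cols_adjacent(c1, c2) -> bool:
        if c1 not in col_pos or c2 not in col_pos:
            return False
        d = abs(col_pos[c1] - col_pos[c2])
        return min(d, n_cols - d) == 1

    out: list[LoopAnnotation] = []
    for g5, g3, run in _connectors(model, stack, columns):
        l5, l3 = layer_of[g5.key], layer_of[g3.key]
        c5, c3 = col_of[g5.key], col_of[g3.key]
        dlayer = abs(l5 - l3)
        span = dlayer + 1
        kind = "linker"
        note = ""
        if l5 == l3:
            t = stack.tetrads[l5]
            if g5 in t.guanines and g3 in t.guanines:
                i5 = t.guanines.index(g5)
                i3 = t.guanines.index(g3)
                d = abs(i5 - i3)
                kind = "edgewise" if min(d, 4 - d) == 1 else "diagonal"
            else:
                note = "same layer index but different tetrads"
        elif c5 == c3:
            if dlayer == 1:
                kind = "step" if not run else "bulge"
            else:
                same_pol = (
                    stack.polarity_signs[l5] == stack.polarity_signs[l3]
                )
                kind = "V_S" if same_pol else "V_R"
        else:
            if not cols_adjacent(c5, c3):
                note = "flanks in non-adjacent columns"
            else:
                # propeller iff the destination column continues covalently
                # from the 3' flank toward the source layer (the G-G support
                # column); a non-sequential or absent support column makes
                # the connector V-shaped
                toward = 1 if l5 > l3 else -1
                supported = True
                for t in range(1, dlayer + 1):
                    s = slots.get((l3 + t * toward, c3))
                    if (s is None or s.chain != g3.chain
                            or s.number != g3.number + t):
                        supported = False
                        break
                if supported:
                    kind = "propeller"
                else:
                    same_pol = (
                        stack.polarity_signs[l5] == stack.polarity_signs[l3]
                    )
                    kind = "V_S" if same_pol else "V_R"
        if kind == "step" and not include_steps:
            continue
        out.append(LoopAnnotation(run, g5, g3, kind, span, note))
    return out


# ---------------------------------------------------------------------------
# Intra-lock detection
# ---------------------------------------------------------------------------

def detect_intralock(
    model: StructureModel,
    stack: StackReport,
    columns: Optional[dict] = None,
):
    """Find stacked blocks and the linkers bridging them.

    Blocks are maximal groups of adjacent layers not separated by a polarity
    reversal.  Bridging linkers are connectors (loops, bulges or covalent
    G-G steps) whose flanking guanines lie in different blocks.  The
    structure is intra-locked when two or more blocks are fastened by two or
    more bridges.
    """
    if columns is None:
        columns = assign_columns(stack)
    blocks: list[list[int]] = [[0]]
    for i, rel in enumerate(stack.relative_polarity):
        if rel == "same":
            blocks[-1].append(i + 1)
        else:
            blocks.append([i + 1])
    block_of = {
        layer: bi for bi, b in enumerate(blocks) for layer in b
    }
    layer_of = {
        g.key: t.layer_index for t in stack.tetrads for g in t.guanines
    }
    all_connectors = classify_loops(
        model, stack, columns, include_steps=True
    )
    bridges = [
        lp for lp in all_connectors
        if block_of[layer_of[lp.flank5.key]]
        != block_of[layer_of[lp.flank3.key]]
    ]
    intra_locked = len(blocks) >= 2 and len(bridges) >= 2
    return blocks, bridges, intra_locked


# ---------------------------------------------------------------------------
# Ensemble RMSD
# ---------------------------------------------------------------------------

def _is_hydrogen(atom_name: str) -> bool:
    stripped = atom_name.lstrip("0123456789")
    return stripped[:1] in ("H", "D")


def ensemble_rmsd(
    models: Sequence[StructureModel],
    atom_subset: Literal["tetrad_core_heavy", "all_heavy"] = "all_heavy",
    tetrad_residue_keys: Optional[Iterable] = None,
) -> tuple[float, float]:
    """Mean and sd of pairwise RMSD over all model pairs.

    Each unordered pair of models is superposed by least squares on the
    selected atoms before measuring the RMSD.  ``tetrad_core_heavy``
    restricts to all heavy atoms of the tetrad guanine nucleotides, which
    must be supplied as residue keys (or are detected from the first model).
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    if atom_subset == "tetrad_core_heavy":
        if tetrad_residue_keys is None:
            edges = detect_hoogsteen_edges(models[0])
            tetrads = assemble_tetrads(edges)
            tetrad_residue_keys = {
                g.key for t in tetrads for g in t.guanines
            }
        keys = set(tetrad_residue_keys)
        selector = lambda r: r.key in keys
    elif atom_subset == "all_heavy":
        selector = lambda r: True
    else:
        raise ValueError(f"unknown atom subset: {atom_subset}")

    inventories = []
    for m in models:
        inv = sorted(
            (r.chain, r.number, a)
            for r in m.residues if selector(r)
            for a in r.atoms if not _is_hydrogen(a)
        )
        inventories.append(inv)
    ref = inventories[0]
    for m, inv in zip(models[1:], inventories[1:]):
        if inv != ref:
            diff = set(ref).symmetric_difference(inv)
            raise ValueError(
                f"atom inventory mismatch between model {models[0].index} "
                f"and model {m.index}: {sorted(diff)[:10]}"
            )
    coords = []
    for m in models:
        by_key = {r.key: r for r in m.residues}
        coords.append(
            np.vstack([by_key[(c, n)].atoms[a] for c, n, a in ref])
        )
    vals = [
        superpose_rmsd(coords[i], coords[j])
        for i, j in itertools.combinations(range(len(models)), 2)
    ]
    vals = np.asarray(vals)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return float(vals.mean()), sd


# ---------------------------------------------------------------------------
# Whole-model and ensemble analysis
# ---------------------------------------------------------------------------

def analyze_model(
    model: StructureModel,
    hbond_cutoff: float = DEFAULT_HBOND_CUTOFF,
    planarity_threshold: float = DEFAULT_PLANARITY_RMSD,
    column_cutoff: float = DEFAULT_COLUMN_CUTOFF,
) -> G4Topology:
    """Run the full topology pipeline on a single model."""
    chi = []
    for g in model.guanines:
        try:
            x = compute_chi(g)
        except KeyError:
            continue
        chi.append(ChiAssignment(g.label(), x, classify_chi(x)))
    edges = detect_hoogsteen_edges(model, cutoff=hbond_cutoff)
    tetrads = assemble_tetrads(edges, planarity_threshold=planarity_threshold)
    stack = order_stack_and_polarity(tetrads)
    columns = assign_columns(stack, cutoff=column_cutoff)
    loops = classify_loops(model, stack, columns)
    blocks, bridges, locked = detect_intralock(model, stack, columns)
    return G4Topology(chi, stack, loops, blocks, bridges, locked)


def analyze_topology(
    models: Sequence[StructureModel],
    consensus_fraction: float = 0.5,
    **kwargs,
) -> dict:
    """Per-model analysis with ensemble consensus.

    A structural feature (tetrad composition, loop kind, lock status) is
    reported at ensemble level when present in more than ``consensus_fraction``
    of the models; glycosidic angles are summarised as circular mean and
    circular sd across models.  Returns a dict with the consensus report,
    per-model topologies and ensemble RMSD values.
    """
    per_model = [analyze_model(m, **kwargs) for m in models]
    n = len(models)
    need = consensus_fraction * n

    chi_by_res: dict[str, list[float]] = {}
    for topo in per_model:
        for c in topo.chi:
            chi_by_res.setdefault(c.residue_label, []).append(c.chi_deg)
    chi_summary = {}
    for label, vals in chi_by_res.items():
        arr = np.asarray(vals)
        mean = float(circmean(arr, high=360.0))
        sd = float(circstd(arr, high=360.0)) if len(arr) > 1 else 0.0
        chi_summary[label] = {
            "mean_deg": round(mean, 1),
            "sd_deg": round(sd, 1),
            "class": classify_chi(mean),
            "n_models": len(arr),
        }

    def majority(counter: dict) -> list:
        return [k for k, v in counter.items() if v > need]

    tetrad_votes: dict = {}
    loop_votes: dict = {}
    lock_votes = 0
    for topo in per_model:
        for t in topo.stack.tetrads:
            key = tuple(sorted(t.composition()))
            tetrad_votes[key] = tetrad_votes.get(key, 0) + 1
        for lp in topo.loops:
            key = (lp.flank5.label(), lp.flank3.label(), lp.kind,
                   lp.span_layers)
            loop_votes[key] = loop_votes.get(key, 0) + 1
        lock_votes += int(topo.intra_locked)

    consensus = {
        "tetrads": sorted(majority(tetrad_votes)),
        "loops": sorted(
            [
                {"flank5": k[0], "flank3": k[1], "kind": k[2],
                 "span_layers": k[3]}
                for k in majority(loop_votes)
            ],
            key=lambda d: (d["flank5"], d["flank3"]),
        ),
        "intra_locked": lock_votes > need,
        "chi": chi_summary,
    }
    result = {
        "n_models": n,
        "consensus": consensus,
        "per_model": per_model,
    }
    if n >= 2:
        try:
            result["rmsd"] = {
                "tetrad_core_heavy": ensemble_rmsd(
                    models, "tetrad_core_heavy"
                ),
                "all_heavy": ensemble_rmsd(models, "all_heavy"),
            }
        except ValueError as exc:
            result["rmsd"] = {"error": str(exc)}
    return result
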