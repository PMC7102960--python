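"""File input/output: FASTA, PDB/mmCIF structures, BED, JSON reports.

All outputs are deterministic (sorted, newline-terminated) so that runs are
byte-for-byte reproducible given the same inputs and parameters; every CLI
run can emit a :class:`RunManifest` recording parameters and input checksums.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

from .structure_topology import Residue, StructureModel

NUCLEIC_RESIDUES = {
    "DA", "DC", "DG", "DT", "DU", "A", "C", "G", "T", "U",
    "ADE", "CYT", "GUA", "THY", "URA",
}

__all__ = [
    "read_fasta",
    "read_fasta_lines",
    "read_structure",
    "write_structure",
    "write_bed",
    "write_report",
    "RunManifest",
]


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path, respect_softmask: bool = False):
    """Yield (id, sequence) from a FASTA file, optionally gzipped.

    Record IDs are taken up to the first whitespace.  Sequences are
    uppercased unless ``respect_softmask`` is set, in which case the original
    case is preserved so callers can treat lowercase as masked.  Duplicated
    record IDs raise ``ValueError``.
    """
    seen: set[str] = set()
    rec_id = None
    chunks: list[str] = []
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                if rec_id is not None:
                    yield rec_id, "".join(chunks)
                rec_id = line[1:].split()[0] if len(line) > 1 else ""
                if not rec_id:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                if rec_id in seen:
                    raise ValueError(
                        f"duplicated FASTA record id {rec_id!r} "
                        f"at line {lineno}"
                    )
                seen.add(rec_id)
                chunks = []
            else:
                if rec_id is None:
                    raise ValueError(
                        f"sequence data before first header at line {lineno}"
                    )
                chunks.append(line if respect_softmask else line.upper())
    if rec_id is not None:
        yield rec_id, "".join(chunks)


def read_fasta_lines(path) -> Iterator[tuple[str, str, int]]:
    """Yield (record_id, sequence_line, offset_in_record) per FASTA line.

    Preserves the file's own line structure, which is what line-oriented
    tools such as grep operate on.
    """
    rec_id = None
    offset = 0
    with _open_text(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                rec_id = line[1:].split()[0] if len(line) > 1 else ""
                if not rec_id:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                offset = 0
            else:
                if rec_id is None:
                    raise ValueError(
                        f"sequence data before first header at line {lineno}"
                    )
                yield rec_id, line, offset
                offset += len(line)


# ---------------------------------------------------------------------------
# Structures
# ---------------------------------------------------------------------------

def _normalize_atom_name(name: str) -> str:
    # old PDB files use * for the prime in sugar atom names
    return name.replace("*", "'").strip()


def read_structure(path, include_hetero: bool = False) -> list[StructureModel]:
    """Read a (possibly multi-model) PDB or mmCIF file into model containers.

    Models are indexed from 1.  Waters and, by default, heteroatom residues
    are excluded; alternate locations collapse to the first conformer.
    Raises ``ValueError`` if the file holds no nucleic-acid residues.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    models: list[StructureModel] = []
    for mi, model in enumerate(st, start=1):
        residues: list[Residue] = []
        for chain in model:
            for res in chain:
                if res.name in ("HOH", "WAT"):
                    continue
                if not include_hetero and res.het_flag == "H" \
                        and res.name not in NUCLEIC_RESIDUES:
                    continue
                atoms: dict[str, np.ndarray] = {}
                for atom in res:
                    name = _normalize_atom_name(atom.name)
                    if name in atoms:
                        continue  # first altloc wins
                    atoms[name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                    )
                residues.append(
                    Residue(chain=chain.name, number=res.seqid.num,
                            name=res.name, atoms=atoms)
                )
        models.append(StructureModel(index=mi, residues=residues))
    if not any(r.name in NUCLEIC_RESIDUES
               for m in models for r in m.residues):
        raise ValueError(f"no nucleic-acid residues found in {path}")
    return models


def write_structure(models: Iterable[StructureModel], path) -> None:
    """Write model containers to PDB or mmCIF (chosen by file extension)."""
    path = Path(path)
    st = gemmi.Structure()
    st.name = path.stem
    for sm in models:
        model = gemmi.Model(sm.index)
        chains: dict[str, gemmi.Chain] = {}
        for res in sm.residues:
            ch = chains.get(res.chain)
            if ch is None:
                ch = gemmi.Chain(res.chain)
                chains[res.chain] = ch
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.number, " ")
            for aname, pos in res.atoms.items():
                at = gemmi.Atom()
                at.name = aname
                at.element = gemmi.Element(aname[0])
                at.pos = gemmi.Position(*map(float, pos))
                at.occ = 1.0
                gres.add_atom(at)
            ch.add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    if path.suffix.lower() in (".cif", ".mmcif"):
        st.make_mmcif_document().write_file(str(path))
    else:
        st.write_pdb(str(path))


# ---------------------------------------------------------------------------
# BED / JSON output
# ---------------------------------------------------------------------------

def write_bed(hits, path) -> None:
    """Write motif hits as BED6 (0-based half-open), sorted, one per line."""
    rows = sorted(hits, key=lambda h: h.sort_key)
    with open(path, "w") as fh:
        for h in rows:
            fh.write(
                f"{h.sequence_id}\t{h.start}\t{h.end}\t"
                f"{h.query_label}\t0\t{h.strand}\n"
            )


def read_bed(path):
    """Read a BED6 file back into (seqid, start, end, name, strand) tuples."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3],
                         f[5] if len(f) > 5 else "+"))
    return rows


def write_report(obj, path) -> None:
    """Write a JSON report deterministically (sorted keys, trailing \\n)."""
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of one tool invocation, sufficient to reproduce it."""

    subcommand: str
    parameters: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    tool_version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__
        if not self.timestamp:
            self.timestamp = time.strftime(
                "%Y-%m-%dT%H:%M:%S", time.gmtime()
            )

    def add_input(self, path) -> None:
        self.input_checksums[str(path)] = sha256_of(path)

    def to_dict(self) -> dict:
        return {
            "subcommand": self.subcommand,
            "parameters": self.parameters,
            "input_checksums": self.input_checksums,
            "tool_version": self.tool_version,
            "timestamp": self.timestamp,
        }

    def write(self, path) -> None:
        write_report(self.to_dict(), path)
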