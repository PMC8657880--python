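"""PDB and FASTA input/output for backbone-only models.

Parsing and record formatting are delegated to gemmi; this layer enforces the
pipeline's conventions: only main-chain atoms (N, CA, C, O), contiguous
1-based renumbering on ingestion, altloc 'A'/blank kept, insertion codes
rejected rather than silently dropped.
"""

from __future__ import annotations

from pathlib import Path

import gemmi
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import ATOM_NAMES, BackboneModel

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}
ONE_TO_THREE["X"] = "UNK"

ELEMENT_OF = {"N": "N", "CA": "C", "C": "C", "O": "O"}


def _model_from_gemmi(
    st: gemmi.Structure, gmodel: gemmi.Model, chain: str, path: str, label: str
) -> BackboneModel:
    gchain = gmodel.find_chain(chain)
    if gchain is None:
        raise ValueError(f"chain {chain!r} not found in {path}")
    rows = []
    seq = []
    seqid_to_new: dict[int, int] = {}
    new_index = 0
    for res in gchain:
        if res.het_flag == "W" or res.name == "HOH":
            continue
        if res.seqid.icode not in (" ", "\x00", ""):
            raise ValueError(
                f"insertion code {res.seqid.icode!r} at residue {res.seqid.num} in {path}: not supported"
            )
        new_index += 1
        coords = {}
        for atom in res:
            if atom.altloc not in ("", "A", "\x00"):
                continue
            if atom.name in ATOM_NAMES and atom.name not in coords:
                coords[atom.name] = [atom.pos.x, atom.pos.y, atom.pos.z]
        for name in ATOM_NAMES:
            if name not in coords:
                raise ValueError(f"missing atom {name} at residue {new_index}")
        rows.append([coords[name] for name in ATOM_NAMES])
        seq.append(THREE_TO_ONE.get(res.name, "X"))
        seqid_to_new[res.seqid.num] = new_index
    if not rows:
        raise ValueError(f"chain {chain!r} in {path} contains no residues")
    return BackboneModel(
        coords=np.array(rows, dtype=float),
        sequence="".join(seq),
        helices=_helices_from_structure(st, chain, seqid_to_new),
        label=label,
    )


def _helices_from_structure(
    st: gemmi.Structure, chain: str, seqid_to_new: dict[int, int]
) -> list[tuple[int, int]]:
    out = []
    for h in st.helices:
        if h.start.chain_name != chain:
            continue
        s = seqid_to_new.get(h.start.res_id.seqid.num)
        e = seqid_to_new.get(h.end.res_id.seqid.num)
        if s is not None and e is not None:
            out.append((s, e))
    return sorted(out)


def _read_structure(path: str | Path) -> gemmi.Structure:
    return gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)


def read_backbone(path: str | Path, chain: str = "A") -> BackboneModel:
    """Read a single-model backbone from a PDB file.

    Residues are renumbered contiguously 1..L preserving file order; every
    residue must carry all four main-chain atoms.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    st = _read_structure(path)
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    return _model_from_gemmi(st, st[0], chain, str(path), label=path.stem)


def read_trajectory(path: str | Path, chain: str = "A") -> list[BackboneModel]:
    """Read a multi-model PDB as an ordered list of snapshots.

    All snapshots must have identical length and atom composition.
    """
    path = Path(path)
    st = _read_structure(path)
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    snaps = [
        _model_from_gemmi(st, gm, chain, str(path), label=f"{path.stem}#{i}")
        for i, gm in enumerate(st)
    ]
    L = len(snaps[0])
    seq = snaps[0].sequence
    for i, s in enumerate(snaps[1:], start=2):
        if len(s) != L or s.sequence != seq:
            raise ValueError(f"snapshot {i} in {path} differs in length or composition")
    return snaps


def _gemmi_structure(models: list[BackboneModel], chain_id: str) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = models[0].label or "model"
    for i, model in enumerate(models, start=1):
        gm = gemmi.Model(str(i))
        gc = gemmi.Chain(chain_id)
        for r in range(len(model)):
            res = gemmi.Residue()
            res.name = ONE_TO_THREE.get(model.sequence[r], "UNK")
            res.seqid = gemmi.SeqId(r + 1, " ")
            for j, name in enumerate(ATOM_NAMES):
                at = gemmi.Atom()
                at.name = name
                at.element = gemmi.Element(ELEMENT_OF[name])
                x, y, z = model.coords[r, j]
                at.pos = gemmi.Position(float(x), float(y), float(z))
                at.occ = 1.0
                at.b_iso = 0.0
                res.add_atom(at)
            gc.add_residue(res)
        gm.add_chain(gc)
        st.add_model(gm)
    for k, (s, e) in enumerate(models[0].helices, start=1):
        h = gemmi.Helix()
        name_s = ONE_TO_THREE.get(models[0].sequence[s - 1], "UNK")
        name_e = ONE_TO_THREE.get(models[0].sequence[e - 1], "UNK")
        h.start = gemmi.AtomAddress(chain_id, gemmi.SeqId(s, " "), name_s, "")
        h.end = gemmi.AtomAddress(chain_id, gemmi.SeqId(e, " "), name_e, "")
        h.length = e - s + 1
        h.pdb_helix_class = 1
        st.helices.append(h)
    st.setup_entities()
    return st


def write_backbone(model: BackboneModel, path: str | Path, chain_id: str = "A") -> None:
    """Write standard fixed-width PDB ATOM records (occupancy 1.00, B 0.00).

    Helix annotations are emitted as HELIX records; read_backbone of the
    output reproduces coordinates to the format precision (1e-3 A).
    """
    st = _gemmi_structure([model], chain_id)
    st.write_pdb(str(path))


def write_trajectory(models: list[BackboneModel], path: str | Path, chain_id: str = "A") -> None:
    """Write snapshots as a multi-model PDB with MODEL/ENDMDL records."""
    if not models:
        raise ValueError("no snapshots to write")
    st = _gemmi_structure(models, chain_id)
    st.write_pdb(str(path))


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
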