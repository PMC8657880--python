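"""Domain types shared by every stage of the fusion-partner screening pipeline.

Coordinate conventions: orthonormal Cartesian axes in Angstrom, right-handed,
membrane normal along +z (OPM convention).  "Main chain" means the four
backbone atoms N, CA, C, O everywhere an RMSD or SASA is computed; residue
numbering is 1-based and contiguous after ingestion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Fixed atom ordering used in every coordinate array of shape (L, 4, 3).
ATOM_NAMES = ("N", "CA", "C", "O")

# Validation tolerances for covalent backbone geometry, in Angstrom.
N_CA_RANGE = (1.2, 1.8)
CA_C_RANGE = (1.3, 1.8)


@dataclass(frozen=True)
class BackboneResidue:
    """One residue's main-chain atoms.

    index is the 1-based residue number; aa is a one-letter amino-acid code
    ('X' when unassigned); coords maps atom name -> 3-vector in Angstrom.
    """

    index: int
    aa: str
    coords: dict[str, np.ndarray]


@dataclass
class BackboneModel:
    """An ordered backbone-only protein model.

    coords has shape (L, 4, 3) with atoms in :data:`ATOM_NAMES` order;
    sequence is a length-L string of one-letter codes; helices is a sorted
    list of inclusive 1-based (start, end) pairs.
    """

    coords: np.ndarray
    sequence: str
    helices: list[tuple[int, int]] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (4, 3):
            raise ValueError("coords must have shape (L, 4, 3)")
        if len(self.sequence) != len(self.coords):
            raise ValueError("sequence length does not match coordinate array")
        self.helices = [(int(a), int(b)) for a, b in self.helices]

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def residues(self) -> list[BackboneResidue]:
        return [
            BackboneResidue(
                index=i + 1,
                aa=self.sequence[i],
                coords={name: self.coords[i, j].copy() for j, name in enumerate(ATOM_NAMES)},
            )
            for i in range(len(self))
        ]

    @property
    def ca(self) -> np.ndarray:
        """Cα coordinates, shape (L, 3)."""
        return self.coords[:, 1, :]

    def atoms_flat(self) -> np.ndarray:
        """All main-chain atoms as a flat (4L, 3) array in residue order."""
        return self.coords.reshape(-1, 3)

    def window_atoms(self, start: int, width: int = 3) -> np.ndarray:
        """Main-chain atoms of residues start..start+width-1 (1-based), flat (4*width, 3)."""
        if start < 1 or start + width - 1 > len(self):
            raise IndexError(f"window [{start}, {start + width - 1}] outside model 1..{len(self)}")
        return self.coords[start - 1 : start - 1 + width].reshape(-1, 3)

    def copy(self, **changes) -> "BackboneModel":
        out = replace(
            self,
            coords=self.coords.copy(),
            helices=list(self.helices),
            **changes,
        )
        return out


@dataclass(frozen=True)
class MembraneSlab:
    """Membrane region as a slab z_min <= z <= z_max (OPM convention, normal +z)."""

    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not self.z_min < self.z_max:
            raise ValueError(f"z_min ({self.z_min}) must be < z_max ({self.z_max})")


@dataclass
class ReceptorScaffold:
    """Receptor backbone with declared TM5/TM6 fusion windows and membrane slab.

    tm5_range / tm6_range are inclusive 1-based index pairs in the receptor's
    renumbered frame; for the adenosine A2A receptor scaffold the conventional
    cytoplasmic-side windows are 204-211 (TM5) and 219-229 (TM6).
    """

    model: BackboneModel
    tm5_range: tuple[int, int]
    tm6_range: tuple[int, int]
    slab: MembraneSlab

    def __post_init__(self) -> None:
        L = len(self.model)
        for name, (lo, hi) in (("tm5_range", self.tm5_range), ("tm6_range", self.tm6_range)):
            if hi - lo + 1 < 3:
                raise ValueError(f"{name} must span at least 3 residues")
            if lo < 1 or hi > L:
                raise ValueError(f"{name} [{lo},{hi}] outside receptor 1..{L}")
        a, b = sorted([self.tm5_range, self.tm6_range])
        if a[1] >= b[0]:
            raise ValueError("tm5_range and tm6_range must be disjoint")


@dataclass
class FusionMatch:
    """Best window-pair assignment from the sliding-window superposition screen.

    The four start indices are 1-based, each naming a 3-residue window; the
    rigid transform maps design coordinates into the receptor frame.
    """

    n_start: int
    c_start: int
    tm5_start: int
    tm6_start: int
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


def validate_model(model: BackboneModel) -> list[str]:
    """Check type invariants; returns a list of human-readable violations.

    Never raises: an empty list means the model is valid.
    """
    violations: list[str] = []
    L = len(model)
    n_ca = np.linalg.norm(model.coords[:, 1] - model.coords[:, 0], axis=1)
    ca_c = np.linalg.norm(model.coords[:, 2] - model.coords[:, 1], axis=1)
    for i in range(L):
        if not (N_CA_RANGE[0] <= n_ca[i] <= N_CA_RANGE[1]):
            violations.append(f"residue {i + 1}: N-CA distance {n_ca[i]:.2f} A outside {N_CA_RANGE}")
        if not (CA_C_RANGE[0] <= ca_c[i] <= CA_C_RANGE[1]):
            violations.append(f"residue {i + 1}: CA-C distance {ca_c[i]:.2f} A outside {CA_C_RANGE}")
    if not np.isfinite(model.coords).all():
        violations.append("non-finite coordinates present")
    prev_end = 0
    for start, end in model.helices:
        if start > end:
            violations.append(f"helix [{start},{end}]: start after end")
        if start < 1 or end > L:
            violations.append(f"helix [{start},{end}]: outside 1..{L}")
        if start <= prev_end:
            violations.append(f"helix [{start},{end}]: overlaps or is unsorted relative to previous helix")
        prev_end = max(prev_end, end)
    return violations
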