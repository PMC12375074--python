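"""Coordinate-level validation: Calpha distances, region RMSD, label margins.

Links PRE-derived spin-label distances to structural models: the distance
between the Calpha atoms of the two labelled residues (Rrp41-Asp113 and
Rrp42-Ala106 in the study this package models) discriminates the open loop
conformation (tens of Angstrom) from the closed one (~14 A model distance vs
the ~6.8 A NMR label-label distance).  Because the labels sit on flexible
arms that the models do not contain, a Calpha-Calpha distance is compared to
NMR through :func:`label_distance_margin`, which widens it by the two
label-arm lengths.

PDB and mmCIF files are parsed with gemmi; author residue numbering is used
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

__all__ = ["StructureModel", "read_structure", "ca_distance", "region_rmsd",
           "label_distance_margin", "TFMF_ARM", "TEMPO_ARM"]

#: maximum reach of the CF3 carbon from the host Calpha, Angstrom
TFMF_ARM = 7.0
#: maximum reach of the nitroxide nitrogen from the host Calpha, Angstrom
TEMPO_ARM = 6.0


@dataclass
class StructureModel:
    """One model's coordinates with (chain, residue number, atom) lookup."""

    source: str
    _atoms: dict          # (chain, resnum, atom name) -> xyz array

    def atom(self, chain: str, resnum: int, atom_name: str = "CA") -> np.ndarray:
        key = (chain, int(resnum), atom_name)
        if key not in self._atoms:
            raise KeyError(f"atom {atom_name} of {chain}:{resnum} not found "
                           f"in {self.source}")
        return self._atoms[key]

    @property
    def n_atoms(self) -> int:
        return len(self._atoms)

    def ca_trace(self, chain: str, res_range: tuple[int, int]) -> np.ndarray:
        """Calpha coordinates for an inclusive residue range, in order."""
        coords = [self.atom(chain, i) for i in
                  range(res_range[0], res_range[1] + 1)]
        return np.array(coords)


def read_structure(path: str | Path, model_index: int = 0) -> StructureModel:
    """Parse a PDB or mmCIF file; multi-model files use the first model."""
    path = Path(path)
    st = gemmi.read_structure(str(path))
    if len(st) == 0:
        raise ValueError(f"{path}: no models found")
    atoms = {}
    for chain in st[model_index]:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, atom.name)
                xyz = np.array([atom.pos.x, atom.pos.y, atom.pos.z])
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"{path}: non-finite coordinates at {key}")
                if key in atoms and atom.altloc in ("", "A"):
                    raise ValueError(f"{path}: duplicate atom {key}")
                atoms[key] = xyz
    return StructureModel(source=str(path), _atoms=atoms)


def ca_distance(model: StructureModel, selA: tuple[str, int],
                selB: tuple[str, int]) -> float:
    """Euclidean Calpha-Calpha distance in Angstrom; symmetric in arguments."""
    a = model.atom(selA[0], selA[1], "CA")
    b = model.atom(selB[0], selB[1], "CA")
    return float(np.linalg.norm(a - b))


def _kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping P onto Q."""
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, qc - R @ pc


def region_rmsd(coordsA: np.ndarray, coordsB: np.ndarray,
                superpose: bool = False,
                reference_A: np.ndarray | None = None,
                reference_B: np.ndarray | None = None) -> float:
    """Calpha RMSD between two matched coordinate sets (Angstrom).

    With ``superpose``, a least-squares superposition is computed first —
    on (reference_A, reference_B) if given (e.g. the rigid core), else on
    the compared coordinates themselves — and applied to coordsA.
    """
    A = np.asarray(coordsA, dtype=float)
    B = np.asarray(coordsB, dtype=float)
    if A.shape != B.shape or A.ndim != 2 or A.shape[1] != 3:
        raise ValueError("coordinate sets must be matched (n, 3) arrays")
    if superpose:
        refA = A if reference_A is None else np.asarray(reference_A, float)
        refB = B if reference_B is None else np.asarray(reference_B, float)
        R, t = _kabsch(refA, refB)
        A = (R @ A.T).T + t
    return float(np.sqrt(np.mean(np.sum((A - B) ** 2, axis=1))))


def label_distance_margin(ca_dist: float, arm_a: float = TFMF_ARM,
                          arm_b: float = TEMPO_ARM) -> tuple[float, float]:
    """Label-accessible distance interval for a Calpha-Calpha distance.

    The two labels can each reach up to their arm length from the host
    Calpha, so an NMR label-label distance is compatible with the model if
    it falls within [max(0, d - arm_a - arm_b), d + arm_a + arm_b].
    """
    if ca_dist < 0 or arm_a < 0 or arm_b < 0:
        raise ValueError("distances and arm lengths must be >= 0")
    m = arm_a + arm_b
    return (max(0.0, ca_dist - m), ca_dist + m)
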