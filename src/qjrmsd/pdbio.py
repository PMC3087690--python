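"""Structure ensemble input and similarity-matrix output.

Ensembles are read from multi-model PDB files or directories of
single-model PDB files (lexicographic order), through gemmi.  Only ATOM
records contribute; HETATM is ignored, and where alternate locations exist
only the first conformer of each atom is kept.  Atom order within each
member is preserved and *is* the correspondence used downstream, so the
selection is applied identically to every member and uniform atom counts
are enforced.

Similarity matrices are written as condensed text, square CSV, or a small
binary container that round-trips the condensed values bit-exactly.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np

from .core import CoordinateSet
from .errors import EnsembleError, FormatError
from .pairwise import Ensemble, SimilarityMatrix

__all__ = [
    "AtomSelection",
    "read_ensemble",
    "write_ensemble",
    "write_matrix",
    "read_matrix",
]

_MAGIC = b"QJSM0001"


@dataclass(frozen=True)
class AtomSelection:
    """Which atoms of each member enter the comparison.

    mode
        ``"all"`` keeps every ATOM record; ``"ca"`` keeps alpha-carbons.
    residue_range
        optional (first, last) residue numbers, 1-based inclusive.
    """

    mode: str = "all"
    residue_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("all", "ca"):
            raise ValueError(f"selection mode must be 'all' or 'ca', got {self.mode!r}")
        if self.residue_range is not None:
            lo, hi = self.residue_range
            if lo > hi:
                raise ValueError(f"bad residue range {self.residue_range}")


def _model_coords(model, selection: AtomSelection, label: str) -> CoordinateSet | None:
    xyz = []
    for chain in model:
        for residue in chain:
            if residue.het_flag == "H":
                continue
            if selection.residue_range is not None:
                lo, hi = selection.residue_range
                if not (lo <= residue.seqid.num <= hi):
                    continue
            seen: set[str] = set()
            for atom in residue:
                if atom.name in seen:      # keep first altloc only
                    continue
                if selection.mode == "ca" and atom.name != "CA":
                    continue
                seen.add(atom.name)
                xyz.append((atom.pos.x, atom.pos.y, atom.pos.z))
    if not xyz:
        return None
    return CoordinateSet(np.array(xyz), label)


def _read_models(path: Path, selection: AtomSelection) -> list[CoordinateSet]:
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    out = []
    for model in st:
        label = f"{path.name}" if len(st) == 1 else f"{path.name}#{model.num}"
        cs = _model_coords(model, selection, label)
        if cs is not None:
            out.append(cs)
    return out


def read_ensemble(source, selection: AtomSelection = AtomSelection()) -> Ensemble:
    """Read an ensemble from a multi-model PDB file or a directory of PDBs.

    Directory entries are taken in lexicographic order.  Heterogeneous atom
    counts after selection raise an :class:`EnsembleError` naming the first
    offending member.
    """
    src = Path(source)
    if not src.exists():
        raise EnsembleError(f"input path does not exist: {src}")
    members: list[CoordinateSet] = []
    if src.is_dir():
        files = sorted(p for p in src.iterdir()
                       if p.is_file() and p.suffix.lower() in (".pdb", ".ent"))
        if not files:
            raise EnsembleError(f"no PDB files in directory {src}")
        for f in files:
            members.extend(_read_models(f, selection))
    else:
        members = _read_models(src, selection)
    if not members:
        raise EnsembleError(f"no atoms selected from {src}")
    return Ensemble.from_coordsets(members)


def write_ensemble(ensemble: Ensemble, path,
                   atoms_per_residue: int = 8) -> None:
    """Write an ensemble as a multi-model PDB file.

    Pseudo-atoms are grouped ``atoms_per_residue`` per residue; the first
    atom of each residue is named CA so alpha-carbon selection works on
    fixtures, the rest C2, C3, ...  Coordinates outside the fixed-column
    range of the PDB format (|x| >= 10000) are rejected.
    """
    if np.abs(ensemble.coords).max() >= 9999.9995:
        raise FormatError("coordinates exceed PDB fixed-column range")
    st = gemmi.Structure()
    st.name = "qjrmsd-ensemble"
    for m in range(len(ensemble)):
        model = gemmi.Model(m + 1)
        chain = gemmi.Chain("A")
        res = None
        for k in range(ensemble.n_atoms):
            if k % atoms_per_residue == 0:
                res = gemmi.Residue()
                res.name = "ALA"
                res.seqid = gemmi.SeqId(k // atoms_per_residue + 1, " ")
                chain.add_residue(res)
                res = chain[-1]
            atom = gemmi.Atom()
            idx = k % atoms_per_residue
            atom.name = "CA" if idx == 0 else f"C{idx + 1}"
            atom.element = gemmi.Element("C")
            x, y, z = ensemble.coords[m, k]
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 0.0
            res.add_atom(atom)
        model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def write_matrix(m: SimilarityMatrix, path, format: str = "condensed") -> None:
    """Write a similarity matrix.

    ``condensed``: header ``# M=<M> method=<name>`` then one ``i j rmsd``
    line per pair (4 decimals).  ``csv``: full square symmetric matrix with
    zero diagonal.  ``binary``: magic, M, JSON labels, then the condensed
    float64 values verbatim (bit-exact round trip).
    """
    path = Path(path)
    if format == "condensed":
        with open(path, "w") as fh:
            fh.write(f"# M={m.M} method={m.method}\n")
            k = 0
            for i in range(m.M - 1):
                for j in range(i + 1, m.M):
                    fh.write(f"{i} {j} {m.condensed[k]:.4f}\n")
                    k += 1
    elif format == "csv":
        np.savetxt(path, m.to_square(), delimiter=",", fmt="%.6f")
    elif format == "binary":
        labels = json.dumps(m.labels).encode()
        with open(path, "wb") as fh:
            fh.write(_MAGIC)
            fh.write(struct.pack("<QQ", m.M, len(labels)))
            fh.write(labels)
            fh.write(m.condensed.astype("<f8", copy=False).tobytes())
    else:
        raise ValueError(f"unknown matrix format {format!r}")


def read_matrix(path) -> SimilarityMatrix:
    """Read back a binary similarity-matrix container."""
    path = Path(path)
    with open(path, "rb") as fh:
        if fh.read(8) != _MAGIC:
            raise FormatError(f"{path}: not a qjrmsd binary matrix")
        M, nlab = struct.unpack("<QQ", fh.read(16))
        labels = json.loads(fh.read(nlab).decode())
        data = np.frombuffer(fh.read(), dtype="<f8").copy()
    return SimilarityMatrix(data, int(M), "unknown", "unknown", labels)
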