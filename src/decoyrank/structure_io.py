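"""Reading and writing the file formats the pipeline touches.

Structures are reduced to ordered CA traces (:class:`StructureModel`); decoy
files are expected to be minimal single-model PDB coordinate files, so only
``ATOM`` records of the first model are honoured, the first altLoc wins, and
``HETATM`` records are skipped.  Sequence profiles are read from the PSI-BLAST
ASCII PSSM dialect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Atom import DisorderedAtom

from .errors import ConsistencyError, PDBFormatError, PSSMFormatError

__all__ = [
    "StructureModel",
    "PSSMProfile",
    "DecoySet",
    "read_pdb_ca",
    "write_pdb_ca",
    "read_pssm",
    "write_pssm",
    "load_decoy_set",
]

#: the 20 amino-acid columns of a PSI-BLAST profile, in file order
PSSM_ALPHABET = "ARNDCQEGHILKMFPSTWYV"

_AA3 = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class StructureModel:
    """One protein conformation as an ordered CA trace.

    Attributes
    ----------
    id : str
        Label for the model (typically the decoy file stem).
    residue_names : list of str
        Three-letter residue codes, one per CA.
    coords : (N, 3) float ndarray
        CA coordinates in Å, ordered by residue sequence number.
    """

    id: str
    residue_names: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise PDBFormatError(
                f"{self.id}: coords must be (N, 3), got {self.coords.shape}"
            )
        if len(self.residue_names) != len(self.coords):
            raise ConsistencyError(
                f"{self.id}: {len(self.residue_names)} residue names for "
                f"{len(self.coords)} coordinates"
            )
        if len(self.coords) < 3:
            raise PDBFormatError(
                f"{self.id}: a CA trace needs at least 3 residues, "
                f"got {len(self.coords)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise PDBFormatError(f"{self.id}: non-finite coordinates")

    def __len__(self) -> int:
        return len(self.coords)


@dataclass
class PSSMProfile:
    """Position-specific scoring matrix: N residue rows × M log-odds columns."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        if self.scores.ndim != 2:
            raise PSSMFormatError("PSSM scores must be a 2-D matrix")

    @property
    def length(self) -> int:
        return self.scores.shape[0]

    @property
    def n_columns(self) -> int:
        return self.scores.shape[1]


@dataclass
class DecoySet:
    """A protein's decoys, optional native structure, and optional profile."""

    protein_id: str
    decoys: list[StructureModel]
    native: Optional[StructureModel] = None
    pssm: Optional[PSSMProfile] = None
    #: free-form extras, e.g. the hidden noise level of synthetic decoys
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(d) for d in self.decoys}
        if self.native is not None:
            lengths.add(len(self.native))
        if len(lengths) > 1:
            offending = sorted(
                {d.id: len(d) for d in self.decoys}.items(), key=lambda kv: kv[1]
            )
            raise ConsistencyError(
                f"{self.protein_id}: decoys have inconsistent residue counts "
                f"{dict(offending)}"
            )
        if self.pssm is not None and self.decoys:
            if self.pssm.length != len(self.decoys[0]):
                raise ConsistencyError(
                    f"{self.protein_id}: PSSM has {self.pssm.length} rows for "
                    f"{len(self.decoys[0])}-residue decoys"
                )

    @property
    def length(self) -> int:
        return len(self.decoys[0]) if self.decoys else len(self.native)

    def decoy_ids(self) -> list[str]:
        return [d.id for d in self.decoys]

    def decoy_by_id(self, decoy_id: str) -> StructureModel:
        for d in self.decoys:
            if d.id == decoy_id:
                return d
        raise KeyError(decoy_id)


def read_pdb_ca(path, chain: Optional[str] = None, model_id: Optional[str] = None
                ) -> StructureModel:
    """Read the CA trace of a PDB file.

    Only ``ATOM`` records of the first model are used.  When *chain* is not
    given, the first chain encountered is taken.  Residues are ordered by
    residue sequence number (insertion code as tiebreak); for alternate
    locations only the first altLoc code is kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(path.stem, str(path))
    try:
        model = next(structure.get_models())  # first model only
    except StopIteration:
        raise PDBFormatError(f"{path}: no models found") from None

    if chain is None:
        chains = list(model.get_chains())
        if not chains:
            raise PDBFormatError(f"{path}: no chains found")
        target = chains[0]
    else:
        if chain not in model:
            raise PDBFormatError(f"{path}: chain {chain!r} not present")
        target = model[chain]

    entries = []
    for residue in target:
        hetflag, resseq, icode = residue.id
        if hetflag != " ":  # skip HETATM
            continue
        if "CA" not in residue:
            continue
        atom = residue["CA"]
        if isinstance(atom, DisorderedAtom):
            # first altLoc code (alphabetical == first record in standard files)
            altloc = sorted(atom.disordered_get_id_list())[0]
            atom = atom.disordered_get(altloc)
        entries.append(((resseq, icode), residue.get_resname(), atom.get_coord()))

    entries.sort(key=lambda e: e[0])
    if len(entries) < 3:
        raise PDBFormatError(
            f"{path}: found only {len(entries)} CA atoms, need at least 3"
        )
    names = [e[1] for e in entries]
    coords = np.array([e[2] for e in entries], dtype=float)
    return StructureModel(id=model_id or path.stem, residue_names=names,
                          coords=coords)


def write_pdb_ca(model: StructureModel, path, chain: str = "A") -> None:
    """Write a CA trace as fixed-column PDB ``ATOM`` records."""
    lines = []
    for i, (name, (x, y, z)) in enumerate(
        zip(model.residue_names, model.coords), start=1
    ):
        lines.append(
            f"ATOM  {i:5d}  CA  {name:<3s} {chain}{i:4d}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C"
        )
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pssm(path) -> PSSMProfile:
    """Read a PSI-BLAST ASCII PSSM.

    Header lines are skipped; each residue row carries the position index, the
    residue letter, then 20 log-odds integers (columns 3–22 of the row).  The
    trailing statistics footer and blank lines are ignored.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[list[int]] = []
    expected_index = 0
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        tokens = line.split()
        if len(tokens) < 2 or not tokens[0].isdigit():
            if rows:
                break  # footer reached
            continue  # header
        expected_index += 1
        values = tokens[2:22]
        try:
            row = [int(v) for v in values]
        except ValueError as exc:
            raise PSSMFormatError(
                f"{path}:{lineno}: non-integer log-odds value ({exc})"
            ) from None
        if len(row) != 20:
            raise PSSMFormatError(
                f"{path}:{lineno}: expected 20 log-odds integers, got {len(row)}"
            )
        rows.append(row)
    if not rows:
        raise PSSMFormatError(f"{path}: no PSSM rows found")
    return PSSMProfile(scores=np.array(rows, dtype=int))


def write_pssm(profile: PSSMProfile, path, residue_letters: Optional[Sequence[str]] = None
               ) -> None:
    """Write a profile in the PSI-BLAST ASCII dialect (log-odds block only)."""
    if residue_letters is None:
        residue_letters = ["A"] * profile.length
    lines = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "   ".join(PSSM_ALPHABET),
    ]
    for i, (letter, row) in enumerate(zip(residue_letters, profile.scores), start=1):
        lines.append(
            f"{i:5d} {letter} " + " ".join(f"{v:3d}" for v in row)
        )
    lines.append("")
    Path(path).write_text("\n".join(lines) + "\n")


def load_decoy_set(
    directory,
    native_name: Optional[str] = None,
    pssm_name: Optional[str] = None,
    protein_id: Optional[str] = None,
) -> DecoySet:
    """Load a directory of decoy PDB files into a :class:`DecoySet`.

    Decoys are read in lexicographic filename order (deterministic across
    calls).  When *native_name* matches one of the files, that structure is
    separated out as the native.  A length mismatch among the loaded
    structures raises :class:`ConsistencyError` naming the offending models.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(directory)
    pdb_files = sorted(p for p in directory.iterdir()
                       if p.suffix.lower() in {".pdb", ".ent"})
    if not pdb_files:
        raise PDBFormatError(f"{directory}: no PDB files found")

    native = None
    decoys = []
    for p in pdb_files:
        model = read_pdb_ca(p)
        if native_name is not None and p.name == native_name:
            native = model
        else:
            decoys.append(model)
    if native_name is not None and native is None:
        raise FileNotFoundError(directory / native_name)

    lengths = {d.id: len(d) for d in decoys}
    if native is not None:
        lengths[native.id] = len(native)
    if len(set(lengths.values())) > 1:
        from collections import Counter

        majority = Counter(lengths.values()).most_common(1)[0][0]
        offenders = sorted(k for k, v in lengths.items() if v != majority)
        raise ConsistencyError(
            f"{directory.name}: residue-count mismatch in {offenders} "
            f"(majority length {majority})"
        )

    pssm = None
    if pssm_name is not None:
        pssm = read_pssm(directory / pssm_name)
    else:
        for candidate in ("pssm.txt", "pssm.pssm", f"{directory.name}.pssm"):
            if (directory / candidate).exists():
                pssm = read_pssm(directory / candidate)
                break
    if pssm is not None and decoys and pssm.length != len(decoys[0]):
        warnings.warn(
            f"{directory.name}: PSSM length {pssm.length} does not match decoy "
            f"length {len(decoys[0])}; profile ignored"
        )
        pssm = None

    return DecoySet(
        protein_id=protein_id or directory.name,
        decoys=decoys,
        native=native,
        pssm=pssm,
    )
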