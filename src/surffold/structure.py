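"""Protein structure containers, PDB/FASTA I/O and synthetic test structures.

The synthetic generator builds polypeptides with ideal covalent geometry
(N-Ca 1.46 A, Ca-C 1.52 A, C-N 1.33 A, trans peptide bonds) at prescribed
backbone phi/psi (helix or strand) and places side-chain atoms out to the
atoms defining chi1..chi4 at prescribed torsions, so every downstream
geometric feature has a known ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"  # canonical 20-letter vocabulary, fixed order
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

# Side-chain atoms along the primary chain beyond CB, in chi order: the k-th
# entry is the fourth atom of the chi_k dihedral.  Branched residues list only
# the branch that defines chi (e.g. CG1 for Val/Ile, OG1 for Thr).
SIDECHAIN_CHAIN: dict[str, list[str]] = {
    "A": [], "R": ["CG", "CD", "NE", "CZ"], "N": ["CG", "OD1"], "D": ["CG", "OD1"],
    "C": ["SG"], "Q": ["CG", "CD", "OE1"], "E": ["CG", "CD", "OE1"], "G": [],
    "H": ["CG", "ND1"], "I": ["CG1", "CD1"], "L": ["CG", "CD1"],
    "K": ["CG", "CD", "CE", "NZ"], "M": ["CG", "SD", "CE"], "F": ["CG", "CD1"],
    "P": ["CG", "CD"], "S": ["OG"], "T": ["OG1"], "W": ["CG", "CD1"],
    "Y": ["CG", "CD1"], "V": ["CG1"],
}


def chi_atom_quadruples(residue_type: str) -> list[tuple[str, str, str, str]]:
    """Standard atom quadruples defining chi1..chi_n for a residue type."""
    chain = SIDECHAIN_CHAIN.get(residue_type, [])
    if residue_type == "G" or not chain:
        return []
    atoms = ["N", "CA", "CB"] + chain
    return [tuple(atoms[k : k + 4]) for k in range(len(chain))]


def n_chi(residue_type: str) -> int:
    return len(chi_atom_quadruples(residue_type))


def element_of(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element from atom name {atom_name!r}")


@dataclass
class AtomRecord:
    """One atom: element, PDB atom name, residue ordinal, chain, position (A)."""

    element: str
    atom_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=np.float64)
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if not self.atom_name:
            raise ValueError("atom_name must be nonempty")
        if self.residue_index < 0:
            raise ValueError("residue_index must be nonnegative")


@dataclass
class Residue:
    """A residue: one-letter code (X for nonstandard) and its atoms by name."""

    name: str
    chain_id: str
    index: int  # 0-based, contiguous after filtering
    atoms: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def ca(self) -> np.ndarray:
        return self.atoms["CA"]

    def has_backbone(self) -> bool:
        return all(a in self.atoms for a in ("N", "CA", "C"))


@dataclass
class ProteinStructure:
    """Ordered residues with typed atoms; the unit every module consumes."""

    residues: list[Residue]
    identifier: str = "protein"

    def __post_init__(self):
        for new_index, res in enumerate(self.residues):
            res.index = new_index

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    @property
    def sequence(self) -> str:
        return "".join(r.name for r in self.residues)

    def ca_coords(self) -> np.ndarray:
        return np.array([r.ca for r in self.residues], dtype=np.float64).reshape(-1, 3)

    def iter_atoms(self) -> Iterable[AtomRecord]:
        for res in self.residues:
            for name, pos in res.atoms.items():
                yield AtomRecord(element_of(name), name, res.index, res.chain_id, pos)

    @property
    def atoms(self) -> list[AtomRecord]:
        return list(self.iter_atoms())


class EmptyStructureError(ValueError):
    """No residue survived backbone-completeness filtering."""


def read_pdb(
    path: str | Path,
    chain_filter: Sequence[str] | None = None,
    include_hetero: bool = False,
) -> ProteinStructure:
    """Read a PDB file into a :class:`ProteinStructure`.

    Residues missing any of N/CA/C are dropped (and logged); nonstandard
    residue names map to ``X``; alternate locations resolve to the highest
    occupancy; HETATM records are ignored unless ``include_hetero``.
    """
    from biotite.structure.io.pdb import PDBFile

    pdb_file = PDBFile.read(str(path))
    arr = pdb_file.get_structure(model=1, altloc="occupancy")
    if not include_hetero:
        arr = arr[~arr.hetero]
    if chain_filter is not None:
        keep = np.isin(arr.chain_id, list(chain_filter))
        arr = arr[keep]

    residues: list[Residue] = []
    dropped = 0
    current_key = None
    res: Residue | None = None
    for i in range(arr.array_length()):
        key = (arr.chain_id[i], int(arr.res_id[i]), arr.ins_code[i])
        if key != current_key:
            if res is not None:
                if res.has_backbone():
                    residues.append(res)
                else:
                    dropped += 1
                    logger.warning("dropping residue %s: incomplete backbone", current_key)
            current_key = key
            name = AA3_TO_1.get(arr.res_name[i], "X")
            res = Residue(name=name, chain_id=str(arr.chain_id[i]), index=0)
        assert res is not None
        res.atoms.setdefault(str(arr.atom_name[i]), np.array(arr.coord[i], dtype=np.float64))
    if res is not None:
        if res.has_backbone():
            residues.append(res)
        else:
            dropped += 1
            logger.warning("dropping residue %s: incomplete backbone", current_key)

    if not residues:
        raise EmptyStructureError(f"{path}: no residue with complete N/CA/C backbone")
    if dropped:
        logger.warning("%s: dropped %d residue(s) with incomplete backbone", path, dropped)
    return ProteinStructure(residues=residues, identifier=Path(path).stem)


def write_pdb(structure: ProteinStructure, path: str | Path) -> None:
    """Write standard fixed-width ATOM records via biotite."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if structure.n_residues == 0:
        raise ValueError("cannot write an empty structure")
    records = structure.atoms
    arr = struc.AtomArray(len(records))
    for i, a in enumerate(records):
        arr.coord[i] = a.position
        arr.chain_id[i] = a.chain_id
        arr.res_id[i] = a.residue_index + 1  # 1-based serials on write
        arr.res_name[i] = AA1_TO_3.get(structure.residues[a.residue_index].name, "UNK")
        arr.atom_name[i] = a.atom_name
        arr.element[i] = a.element
        arr.hetero[i] = False
    pdb_file = PDBFile()
    pdb_file.set_structure(arr)
    pdb_file.write(str(path))


def write_fasta(ids: Sequence[str], sequences: Sequence[str], path: str | Path, width: int = 80) -> None:
    """Write sequences as FASTA with fixed-width line wrapping."""
    if len(ids) != len(sequences):
        raise ValueError(f"{len(ids)} ids but {len(sequences)} sequences")
    with open(path, "w") as fh:
        for name, seq in zip(ids, sequences):
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> tuple[list[str], list[str]]:
    ids: list[str] = []
    seqs: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                ids.append(line[1:].split()[0] if len(line) > 1 else "")
                seqs.append("")
            else:
                seqs[-1] += line
    return ids, seqs


# --------------------------------------------------------------- synthetic
@dataclass
class SyntheticSpec:
    """Recipe for a deterministic synthetic protein.

    ``chi_angles`` maps residue ordinal (within the concatenated chain order)
    to prescribed torsions in radians; unspecified torsions are drawn from the
    seeded RNG.  ``sequence`` fixes residue types, otherwise they are drawn
    uniformly from the 20 canonical amino acids.
    """

    n_residues: int
    secondary_motif: str = "helix"
    chi_angles: Mapping[int, Sequence[float]] | None = None
    n_chains: int = 1
    seed: int = 0
    sequence: str | None = None

    def __post_init__(self):
        if self.n_residues < 1:
            raise ValueError("n_residues must be >= 1")
        if self.secondary_motif not in ("helix", "strand", "mixed"):
            raise ValueError(f"unknown secondary_motif {self.secondary_motif!r}")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.sequence is not None and len(self.sequence) != self.n_residues * self.n_chains:
            raise ValueError("sequence length must equal n_residues * n_chains")
        if self.chi_angles:
            for angles in self.chi_angles.values():
                for a in angles:
                    if not (-np.pi < float(a) <= np.pi + 1e-12):
                        raise ValueError("prescribed torsions must lie in (-pi, pi]")


# Ideal covalent geometry (A / degrees), standard trans-polypeptide values.
BOND_N_CA = 1.46
BOND_CA_C = 1.52
BOND_C_N = 1.33
BOND_C_O = 1.23
ANGLE_N_CA_C = np.deg2rad(111.0)
ANGLE_CA_C_N = np.deg2rad(116.2)
ANGLE_C_N_CA = np.deg2rad(121.7)
ANGLE_CA_C_O = np.deg2rad(120.8)
PHI_PSI = {"helix": (np.deg2rad(-57.0), np.deg2rad(-47.0)),
           "strand": (np.deg2rad(-120.0), np.deg2rad(120.0))}

BOND_SIDECHAIN = 1.52
ANGLE_SIDECHAIN = np.deg2rad(111.0)
BOND_CA_CB = 1.53
ANGLE_N_CA_CB = np.deg2rad(110.5)
DIHEDRAL_C_N_CA_CB = np.deg2rad(-122.0)


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle: float, torsion: float) -> np.ndarray:
    """Natural-extension-reference-frame placement of atom D.

    Returns D such that |C-D| = bond, angle(B,C,D) = angle and the dihedral
    (A,B,C,D) equals ``torsion`` under the IUPAC sign convention.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed dihedral angle of four points in (-pi, pi] (IUPAC convention)."""
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2)))
    ang = float(np.arctan2(y, x))
    return np.pi if ang <= -np.pi + 1e-15 else ang


def _build_chain(sequence: str, motif: str, chi_spec: dict[int, Sequence[float]],
                 chain_id: str, offset: np.ndarray, rng: np.random.Generator,
                 ordinal_base: int) -> list[Residue]:
    L = len(sequence)
    phis = np.empty(L)
    psis = np.empty(L)
    for i in range(L):
        m = motif
        if motif == "mixed":
            m = "helix" if i < L // 2 else "strand"
        phis[i], psis[i] = PHI_PSI[m]

    n_pos = np.zeros((L, 3))
    ca_pos = np.zeros((L, 3))
    c_pos = np.zeros((L, 3))
    n_pos[0] = [0.0, 0.0, 0.0]
    ca_pos[0] = [BOND_N_CA, 0.0, 0.0]
    c_pos[0] = ca_pos[0] + BOND_CA_C * np.array(
        [-np.cos(ANGLE_N_CA_C), np.sin(ANGLE_N_CA_C), 0.0]
    )
    for i in range(1, L):
        n_pos[i] = place_atom(n_pos[i - 1], ca_pos[i - 1], c_pos[i - 1],
                              BOND_C_N, ANGLE_CA_C_N, psis[i - 1])
        ca_pos[i] = place_atom(ca_pos[i - 1], c_pos[i - 1], n_pos[i],
                               BOND_N_CA, ANGLE_C_N_CA, np.pi)  # trans omega
        c_pos[i] = place_atom(c_pos[i - 1], n_pos[i], ca_pos[i],
                              BOND_CA_C, ANGLE_N_CA_C, phis[i])

    residues: list[Residue] = []
    for i, aa in enumerate(sequence):
        res = Residue(name=aa, chain_id=chain_id, index=0)
        res.atoms["N"] = n_pos[i] + offset
        res.atoms["CA"] = ca_pos[i] + offset
        res.atoms["C"] = c_pos[i] + offset
        res.atoms["O"] = place_atom(n_pos[i], ca_pos[i], c_pos[i],
                                    BOND_C_O, ANGLE_CA_C_O, psis[i] + np.pi) + offset

        ordinal = ordinal_base + i
        chain_atoms = SIDECHAIN_CHAIN[aa]
        prescribed = chi_spec.get(ordinal)
        if aa == "G":
            if prescribed is not None:
                raise ValueError(f"chi prescribed for glycine at residue {ordinal}")
            residues.append(res)
            continue
        # CB off the backbone, then the chi-defining chain placed at the
        # prescribed (or randomly drawn) torsions.
        res.atoms["CB"] = place_atom(c_pos[i], n_pos[i], ca_pos[i],
                                     BOND_CA_CB, ANGLE_N_CA_CB, DIHEDRAL_C_N_CA_CB) + offset
        if prescribed is not None and len(prescribed) > len(chain_atoms):
            raise ValueError(
                f"residue {ordinal} ({aa}) defines {len(chain_atoms)} chi angle(s), "
                f"{len(prescribed)} prescribed"
            )
        frame = ["N", "CA", "CB"]
        for k, atom_name in enumerate(chain_atoms):
            if prescribed is not None and k < len(prescribed):
                chi = float(prescribed[k])
            else:
                chi = float(rng.uniform(-np.pi, np.pi))
            a, b, c = (res.atoms[frame[k]], res.atoms[frame[k + 1]], res.atoms[frame[k + 2]])
            res.atoms[atom_name] = place_atom(a, b, c, BOND_SIDECHAIN, ANGLE_SIDECHAIN, chi)
            frame.append(atom_name)
        residues.append(res)
    return residues


def make_synthetic_structure(spec: SyntheticSpec) -> ProteinStructure:
    """Deterministic synthetic protein from a :class:`SyntheticSpec`.

    A pure function of the spec: identical specs yield bit-identical
    coordinates.  Chains are laid out side by side with a 30 A offset.
    """
    rng = np.random.default_rng(spec.seed)
    total = spec.n_residues * spec.n_chains
    if spec.sequence is not None:
        seq = spec.sequence.upper()
        bad = set(seq) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"non-canonical residue codes in sequence: {sorted(bad)}")
    else:
        seq = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=total))
    chi_spec = dict(spec.chi_angles or {})

    residues: list[Residue] = []
    for c in range(spec.n_chains):
        chain_id = chr(ord("A") + c)
        offset = np.array([0.0, 0.0, 30.0 * c])
        chain_seq = seq[c * spec.n_residues : (c + 1) * spec.n_residues]
        residues.extend(
            _build_chain(chain_seq, spec.secondary_motif, chi_spec, chain_id,
                         offset, rng, ordinal_base=c * spec.n_residues)
        )
    return ProteinStructure(residues=residues, identifier=f"synthetic-{spec.seed}")
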