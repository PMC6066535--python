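"""Reading protein–ligand complexes and defining the binding site.

A complex is a plain PDB file containing the receptor (``ATOM`` records) and
one or more copies of the ligand (``HETATM`` records).  The ligand is located
by its HETATM residue name (or by an explicit chain + residue number), its
bond orders and formal charges are taken from the packaged SDF template when
the element sequence matches, and the binding site is the set of receptor
residues with at least one heavy atom within a cutoff radius of *any* ligand
heavy atom.  Hydrogens are dropped everywhere; coordinates are in Å and
residue numbering is kept verbatim from the file.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
from biotite.structure import AtomArray
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree

from .template import load_template_mol, template_elements, template_bonds, template_charges

__all__ = [
    "AtomRecord",
    "LigandPose",
    "BindingSite",
    "ComplexModel",
    "LigandNotFoundError",
    "AmbiguousLigandError",
    "read_complex",
    "read_all_ligand_copies",
    "define_binding_site",
    "write_complex_pdb",
]

DEFAULT_LIGAND_RESNAME = "BER"
DEFAULT_SITE_RADIUS = 7.0  # Å; anchored to the contact shell used for interaction detection


class LigandNotFoundError(ValueError):
    """No HETATM residue matches the ligand selector."""


class AmbiguousLigandError(ValueError):
    """More than one ligand copy matches and no site was specified."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a structure."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_number: int
    position: np.ndarray  # (3,) Å
    formal_charge: int = 0
    is_hetero: bool = False

    def __post_init__(self):
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)


@dataclass
class LigandPose:
    """Ligand heavy atoms with template-derived bonds and charges.

    ``canonical_order[i]`` gives the template index of pose atom ``i`` so that
    poses from different files can be put in exact correspondence.
    """

    atoms: list[AtomRecord]
    bonds: list[tuple[int, int, int]] = field(default_factory=list)  # (i, j, order)
    canonical_order: list[int] | None = None
    charged_nitrogen_index: int | None = None

    def __post_init__(self):
        n = len(self.atoms)
        for i, j, _ in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError("bond index out of range")
        k = self.charged_nitrogen_index
        if k is not None:
            a = self.atoms[k]
            if a.element != "N" or a.formal_charge != 1:
                raise ValueError("charged_nitrogen_index must point at an N with charge +1")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms])

    def centroid(self) -> np.ndarray:
        return self.coords.mean(axis=0)

    def canonical_coords(self) -> np.ndarray:
        """Coordinates reordered to the template ordering."""
        if self.canonical_order is None:
            raise ValueError("pose has no canonical mapping to the template")
        out = np.empty((len(self.atoms), 3))
        for i, t in enumerate(self.canonical_order):
            out[t] = self.atoms[i].position
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LigandPose":
        atoms = [
            replace(a, position=rotation @ a.position + translation) for a in self.atoms
        ]
        return LigandPose(
            atoms=atoms,
            bonds=list(self.bonds),
            canonical_order=None if self.canonical_order is None else list(self.canonical_order),
            charged_nitrogen_index=self.charged_nitrogen_index,
        )


@dataclass
class BindingSite:
    center: np.ndarray  # ligand heavy-atom centroid, Å
    radius: float
    residues: list[tuple[str, int, str]]  # (chain, residue_number, residue_name)
    site_label: str = "site I"

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("binding-site radius must be > 0")
        self.center = np.asarray(self.center, dtype=float)


@dataclass
class ComplexModel:
    receptor_atoms: list[AtomRecord]
    ligand: LigandPose
    site: BindingSite
    source_id: str = ""

    def site_atoms(self) -> list[AtomRecord]:
        members = set((c, r) for c, r, _ in self.site.residues)
        return [a for a in self.receptor_atoms if (a.chain, a.residue_number) in members]


# ---------------------------------------------------------------------------
# parsing

def _array_from_pdb_text(text: str) -> AtomArray:
    pdb = PDBFile.read(io.StringIO(text))
    arr = pdb.get_structure(model=1)
    # heavy atoms only
    return arr[(arr.element != "H") & (arr.element != "D")]


def _atom_records(arr: AtomArray) -> list[AtomRecord]:
    records = []
    for i in range(arr.array_length()):
        records.append(
            AtomRecord(
                serial=i + 1,
                name=str(arr.atom_name[i]),
                element=str(arr.element[i]).capitalize(),
                residue_name=str(arr.res_name[i]),
                chain=str(arr.chain_id[i]),
                residue_number=int(arr.res_id[i]),
                position=arr.coord[i],
                is_hetero=bool(arr.hetero[i]),
            )
        )
    return records


def _perceive_bonds_by_distance(atoms: list[AtomRecord]) -> list[tuple[int, int, int]]:
    """Distance-based single-bond perception (covalent-radius sum + 0.45 Å)."""
    radii = {"C": 0.76, "N": 0.71, "O": 0.66, "S": 1.05, "P": 1.07, "F": 0.57,
             "Cl": 1.02, "Br": 1.20, "I": 1.39}
    bonds = []
    for i in range(len(atoms)):
        for j in range(i + 1, len(atoms)):
            d = np.linalg.norm(atoms[i].position - atoms[j].position)
            rmax = radii.get(atoms[i].element, 0.77) + radii.get(atoms[j].element, 0.77) + 0.45
            if d <= rmax:
                bonds.append((i, j, 1))
    return bonds


def _build_ligand_pose(atoms: list[AtomRecord]) -> LigandPose:
    """Assign template bonds/charges when the element sequence matches the
    packaged template in file order; otherwise fall back to distance-based
    bond perception (cation = nitrogen with ≥3 heavy neighbours)."""
    elements = [a.element for a in atoms]
    if elements == template_elements():
        order = list(range(len(atoms)))
        charges = template_charges()
        atoms = [replace(a, formal_charge=charges[i]) for i, a in enumerate(atoms)]
        bonds = template_bonds()
        n_plus = next(
            (i for i, a in enumerate(atoms) if a.element == "N" and a.formal_charge == 1), None
        )
        return LigandPose(atoms, bonds, order, n_plus)
    bonds = _perceive_bonds_by_distance(atoms)
    degree = np.zeros(len(atoms), dtype=int)
    for i, j, _ in bonds:
        degree[i] += 1
        degree[j] += 1
    n_plus = None
    candidates = [i for i, a in enumerate(atoms) if a.element == "N" and degree[i] >= 3]
    if candidates:
        n_plus = max(candidates, key=lambda i: degree[i])
        atoms = [replace(a, formal_charge=1) if i == n_plus else a for i, a in enumerate(atoms)]
    return LigandPose(atoms, bonds, None, n_plus)


def _ligand_copies(records, resname=None, chain=None, resnum=None):
    """Group matching hetero atoms into copies keyed by (chain, residue_number)."""
    copies: dict[tuple[str, int], list[AtomRecord]] = {}
    for a in records:
        if not a.is_hetero or a.residue_name == "HOH":
            continue
        if resname is not None and a.residue_name != resname:
            continue
        if chain is not None and a.chain != chain:
            continue
        if resnum is not None and a.residue_number != resnum:
            continue
        copies.setdefault((a.chain, a.residue_number), []).append(a)
    return dict(sorted(copies.items()))


def read_complex(
    structure_text: str,
    ligand_resname: str | None = DEFAULT_LIGAND_RESNAME,
    *,
    chain: str | None = None,
    resnum: int | None = None,
    site_radius: float = DEFAULT_SITE_RADIUS,
    source_id: str = "",
) -> ComplexModel:
    """Parse PDB text and return the complex for a single ligand copy.

    Raises :class:`LigandNotFoundError` if the selector matches nothing and
    :class:`AmbiguousLigandError` if it matches several copies and no
    chain/resnum disambiguation is given (use :func:`read_all_ligand_copies`
    to get one model per copy, labelled "site I", "site II", …).
    """
    records = _atom_records(_array_from_pdb_text(structure_text))
    copies = _ligand_copies(records, ligand_resname, chain, resnum)
    if not copies:
        raise LigandNotFoundError(f"ligand not found (selector {ligand_resname!r})")
    if len(copies) > 1:
        keys = ", ".join(f"{c}/{r}" for c, r in copies)
        raise AmbiguousLigandError(
            f"ambiguous ligand copy ({keys}), specify chain/resnum"
        )
    (key, ligand_atoms), = copies.items()
    return _assemble(records, ligand_atoms, site_radius, source_id, "site I")


def read_all_ligand_copies(
    structure_text: str,
    ligand_resname: str | None = DEFAULT_LIGAND_RESNAME,
    *,
    site_radius: float = DEFAULT_SITE_RADIUS,
    source_id: str = "",
) -> list[ComplexModel]:
    """One ComplexModel per ligand copy, labelled "site I", "site II" in file order."""
    records = _atom_records(_array_from_pdb_text(structure_text))
    copies = _ligand_copies(records, ligand_resname)
    if not copies:
        raise LigandNotFoundError(f"ligand not found (selector {ligand_resname!r})")
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII"]
    out = []
    for k, (key, ligand_atoms) in enumerate(copies.items()):
        out.append(_assemble(records, ligand_atoms, site_radius, source_id, f"site {roman[k]}"))
    return out


def _assemble(records, ligand_atoms, site_radius, source_id, site_label) -> ComplexModel:
    ligand_keys = {(a.chain, a.residue_number, a.serial) for a in ligand_atoms}
    ligand_res = {(a.chain, a.residue_number) for a in ligand_atoms}
    receptor = [
        a for a in records
        if (a.chain, a.residue_number, a.serial) not in ligand_keys
        and (a.chain, a.residue_number) not in ligand_res
    ]
    pose = _build_ligand_pose(ligand_atoms)
    model = ComplexModel(receptor, pose, BindingSite(pose.centroid(), site_radius, []), source_id)
    model.site = define_binding_site(model, site_radius)
    model.site.site_label = site_label
    return model


def define_binding_site(complex: ComplexModel, radius: float = DEFAULT_SITE_RADIUS) -> BindingSite:
    """Receptor residues with ≥1 heavy atom within ``radius`` of any ligand atom.

    Membership uses the nearest ligand-atom distance rather than distance to a
    sphere centre, so elongated ligands keep their full contact shell.  The
    residue list is ordered by (chain, residue_number).
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    if not complex.ligand.atoms:
        raise ValueError("ligand is empty")
    lig = complex.ligand.coords
    tree = cKDTree(lig)
    members: dict[tuple[str, int], str] = {}
    for a in complex.receptor_atoms:
        d, _ = tree.query(a.position)
        if d <= radius:
            members.setdefault((a.chain, a.residue_number), a.residue_name)
    residues = sorted((c, r, members[(c, r)]) for c, r in members)
    return BindingSite(complex.ligand.centroid(), radius, residues)


# ---------------------------------------------------------------------------
# writing (fixtures / round-trips)

def write_complex_pdb(complex: ComplexModel) -> str:
    """Serialise a ComplexModel back to PDB text (receptor ATOM + ligand HETATM)."""
    n = len(complex.receptor_atoms) + len(complex.ligand.atoms)
    arr = AtomArray(n)
    for i, a in enumerate(complex.receptor_atoms + complex.ligand.atoms):
        arr.coord[i] = a.position
        arr.atom_name[i] = a.name
        arr.element[i] = a.element.upper()
        arr.res_name[i] = a.residue_name
        arr.chain_id[i] = a.chain
        arr.res_id[i] = a.residue_number
        arr.hetero[i] = a.is_hetero
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()
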