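"""Ligand–receptor interaction perception.

Detects the four interaction classes that drive cationic-alkaloid binding:
attractive charge (ligand N+ to a receptor carboxylate or phosphate), π–π
stacking, π-alkyl contacts, and hydrogen bonds.  Receptor chemistry is typed
from residue/atom names; ligand chemistry comes from the packaged template.
Distances are centroid–centroid for charge and ring contacts and heavy-atom
for hydrogen bonds; no angular terms are applied (distance-only criteria,
recorded in report metadata).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .complex_io import ComplexModel

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionGroup",
    "Interaction",
    "InteractionCutoffs",
    "perceive_groups",
    "receptor_groups",
    "ligand_groups",
    "detect_interactions",
    "nplus_anion_distance",
]

GROUP_KINDS = (
    "aromatic_ring",
    "aliphatic_hydrophobe",
    "cation",
    "anion",
    "hbond_donor",
    "hbond_acceptor",
)

NUCLEIC_RESNAMES = {"DA", "DC", "DG", "DT", "DU", "A", "C", "G", "U"}
PYRIMIDINES = {"DC", "DT", "DU", "C", "U"}
PURINES = {"DA", "DG", "A", "G"}

_SIDECHAIN_ANIONS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
_SIDECHAIN_CATIONS = {"LYS": ("NZ",), "ARG": ("NE", "CZ", "NH1", "NH2")}
_AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CE2", "CD2", "CE3", "CZ3", "CH2", "CZ2")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}
_HYDROPHOBES = {
    "ALA": ("CB",),
    "VAL": ("CB", "CG1", "CG2"),
    "LEU": ("CB", "CG", "CD1", "CD2"),
    "ILE": ("CB", "CG1", "CG2", "CD1"),
    "MET": ("CB", "CG", "SD", "CE"),
    "PRO": ("CB", "CG", "CD"),
}
_SIDECHAIN_DONORS = {
    "SER": ("OG",), "THR": ("OG1",), "TYR": ("OH",), "TRP": ("NE1",),
    "ASN": ("ND2",), "GLN": ("NE2",), "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"), "HIS": ("ND1", "NE2"), "CYS": ("SG",),
}
_SIDECHAIN_ACCEPTORS = {
    "ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2"), "SER": ("OG",),
    "THR": ("OG1",), "TYR": ("OH",), "ASN": ("OD1",), "GLN": ("OE1",),
    "HIS": ("ND1", "NE2"), "MET": ("SD",),
}
_KNOWN_RESNAMES = (
    set(_SIDECHAIN_ANIONS) | set(_SIDECHAIN_CATIONS) | set(_AROMATIC_RINGS)
    | set(_HYDROPHOBES) | set(_SIDECHAIN_DONORS) | set(_SIDECHAIN_ACCEPTORS)
    | NUCLEIC_RESNAMES | {"GLY", "CYS", "ASN", "GLN", "SER", "THR"}
)


@dataclass(frozen=True)
class InteractionGroup:
    kind: str
    owner: str  # "ligand" | "receptor"
    member_atoms: tuple[int, ...]
    centroid: np.ndarray
    normal: np.ndarray | None = None
    label: str = ""

    def __post_init__(self):
        if self.kind not in GROUP_KINDS:
            raise ValueError(f"unknown group kind {self.kind!r}")
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))
        if self.normal is not None:
            n = np.asarray(self.normal, dtype=float)
            object.__setattr__(self, "normal", n / np.linalg.norm(n))


@dataclass(frozen=True)
class Interaction:
    kind: str  # attractive_charge | pi_pi | pi_alkyl | hydrogen_bond
    ligand_group: InteractionGroup
    receptor_group: InteractionGroup
    distance: float


@dataclass(frozen=True)
class InteractionCutoffs:
    """Distance cutoffs in Å.  The 7 Å charge cutoff is the anchor radius
    within which the cationic ligand engages neighbouring residues; the ring
    and H-bond cutoffs mirror common pharmacophore-software defaults."""

    attractive_charge: float = 7.0
    pi_pi: float = 6.0
    pi_alkyl: float = 5.5
    hydrogen_bond: float = 3.5


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    centred = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centred)
    n = vt[-1]
    # deterministic sign: first component with |x| > 1e-9 made positive
    for x in n:
        if abs(x) > 1e-9:
            return n if x > 0 else -n
    return n


def receptor_groups(
    complex: ComplexModel, *, protonated_histidines: frozenset = frozenset()
) -> list[InteractionGroup]:
    """Type the binding-site residues into interaction groups.

    His rings are aromatic always and cationic only when the (chain, resnum)
    is listed in ``protonated_histidines`` — no pKa model is applied.
    Residues outside the typing tables are skipped with a warning.
    """
    atoms = complex.receptor_atoms
    site = {(c, r) for c, r, _ in complex.site.residues}
    by_res: dict[tuple[str, int, str], dict[str, int]] = {}
    for i, a in enumerate(atoms):
        if (a.chain, a.residue_number) in site:
            by_res.setdefault((a.chain, a.residue_number, a.residue_name), {})[a.name] = i

    groups: list[InteractionGroup] = []

    def add(kind, idxs, label, normal=None):
        pos = np.array([atoms[i].position for i in idxs])
        groups.append(InteractionGroup(kind, "receptor", tuple(idxs), pos.mean(axis=0),
                                       normal, label))

    for (chain, resnum, resname), names in sorted(by_res.items()):
        label = f"{resname}{resnum}:{chain}"
        if resname not in _KNOWN_RESNAMES:
            logger.warning("unknown residue %s skipped during group perception", label)
            continue
        if resname in _SIDECHAIN_ANIONS:
            idxs = [names[n] for n in _SIDECHAIN_ANIONS[resname] if n in names]
            if idxs:
                add("anion", idxs, label)
        if resname in NUCLEIC_RESNAMES:
            idxs = [names[n] for n in ("OP1", "OP2", "O1P", "O2P") if n in names]
            if idxs:
                add("anion", idxs, label + ":phosphate")
        if resname in _SIDECHAIN_CATIONS:
            idxs = [names[n] for n in _SIDECHAIN_CATIONS[resname] if n in names]
            if idxs:
                add("cation", idxs, label)
        if resname == "HIS" and (chain, resnum) in protonated_histidines:
            idxs = [names[n] for n in ("ND1", "NE2") if n in names]
            if idxs:
                add("cation", idxs, label)
        ring_sets = list(_AROMATIC_RINGS.get(resname, []))
        if resname in PYRIMIDINES:
            ring_sets.append(("N1", "C2", "N3", "C4", "C5", "C6"))
        elif resname in PURINES:
            ring_sets.append(("N1", "C2", "N3", "C4", "C5", "C6"))
            ring_sets.append(("C4", "C5", "N7", "C8", "N9"))
        for ring in ring_sets:
            if all(n in names for n in ring):
                idxs = [names[n] for n in ring]
                pos = np.array([atoms[i].position for i in idxs])
                add("aromatic_ring", idxs, label, _ring_normal(pos))
        if resname in _HYDROPHOBES:
            idxs = [names[n] for n in _HYDROPHOBES[resname] if n in names]
            if idxs:
                add("aliphatic_hydrophobe", idxs, label)
        if resname in _SIDECHAIN_DONORS:
            for n in _SIDECHAIN_DONORS[resname]:
                if n in names:
                    add("hbond_donor", [names[n]], f"{label}:{n}")
        if resname in _SIDECHAIN_ACCEPTORS:
            for n in _SIDECHAIN_ACCEPTORS[resname]:
                if n in names:
                    add("hbond_acceptor", [names[n]], f"{label}:{n}")
        # backbone amide (proteins only)
        if resname not in NUCLEIC_RESNAMES:
            if "N" in names and resname != "PRO":
                add("hbond_donor", [names["N"]], f"{label}:N")
            if "O" in names:
                add("hbond_acceptor", [names["O"]], f"{label}:O")
    return groups


def ligand_groups(complex: ComplexModel) -> list[InteractionGroup]:
    """Ligand-side groups from template chemistry (canonical poses) or from
    the perceived pose (cation + O acceptors) otherwise."""
    pose = complex.ligand
    coords = pose.coords
    groups: list[InteractionGroup] = []

    def add(kind, idxs, label, normal=None):
        pos = coords[list(idxs)]
        groups.append(InteractionGroup(kind, "ligand", tuple(idxs), pos.mean(axis=0),
                                       normal, label))

    if pose.canonical_order is not None:
        from .template import template_chemistry

        chem = template_chemistry()
        inv = {t: i for i, t in enumerate(pose.canonical_order)}
        for k, system in enumerate(chem["aromatic_systems"]):
            idxs = [inv[t] for t in system]
            add("aromatic_ring", idxs, f"ring{k + 1}",
                _ring_normal(coords[idxs]))
        if chem["cation"] is not None:
            add("cation", [inv[chem["cation"]]], "N+")
        for t in chem["acceptors"]:
            add("hbond_acceptor", [inv[t]], f"O{t}")
        for t in chem["hydrophobes"]:
            add("aliphatic_hydrophobe", [inv[t]], f"C{t}")
        return groups

    if pose.charged_nitrogen_index is not None:
        add("cation", [pose.charged_nitrogen_index], "N+")
    for i, a in enumerate(pose.atoms):
        if a.element == "O":
            add("hbond_acceptor", [i], f"O{i}")
    for ring in _perceived_planar_rings(pose):
        add("aromatic_ring", ring, "ring", _ring_normal(coords[list(ring)]))
    return groups


def _perceived_planar_rings(pose) -> list[tuple[int, ...]]:
    """5/6-membered C/N rings from perceived bonds, kept if planar (<0.15 Å RMS)."""
    from rdkit import Chem

    em = Chem.RWMol()
    for a in pose.atoms:
        em.AddAtom(Chem.Atom(a.element))
    for i, j, _ in pose.bonds:
        em.AddBond(i, j, Chem.BondType.SINGLE)
    rings = []
    for ring in Chem.GetSymmSSSR(em):
        ring = tuple(ring)
        if len(ring) not in (5, 6):
            continue
        if any(pose.atoms[i].element not in ("C", "N") for i in ring):
            continue
        coords = pose.coords[list(ring)]
        centred = coords - coords.mean(axis=0)
        sv = np.linalg.svd(centred, compute_uv=False)
        if sv[-1] / np.sqrt(len(ring)) < 0.15:
            rings.append(ring)
    return rings


def perceive_groups(complex: ComplexModel, **kwargs) -> list[InteractionGroup]:
    """All interaction groups of the complex: ligand side then receptor side."""
    return ligand_groups(complex) + receptor_groups(complex, **kwargs)


def _min_atom_distance(g1, g2, c1, c2) -> float:
    p1 = np.array([c1[i] for i in g1.member_atoms])
    p2 = np.array([c2[i] for i in g2.member_atoms])
    return float(np.min(np.linalg.norm(p1[:, None, :] - p2[None, :, :], axis=-1)))


def detect_interactions(
    complex: ComplexModel,
    cutoffs: InteractionCutoffs = InteractionCutoffs(),
    **group_kwargs,
) -> list[Interaction]:
    """All ligand–receptor interactions within the per-kind distance cutoffs.

    Emits attractive_charge (ligand cation ↔ receptor anion, centroid
    distance), pi_pi (ring ↔ ring, centroid), pi_alkyl (ring ↔ hydrophobe in
    either direction, centroid), hydrogen_bond (donor ↔ acceptor, nearest
    heavy-atom distance).  Sorted by distance.
    """
    lig = ligand_groups(complex)
    rec = receptor_groups(complex, **group_kwargs)
    lig_coords = complex.ligand.coords
    rec_coords = np.array([a.position for a in complex.receptor_atoms]) \
        if complex.receptor_atoms else np.zeros((0, 3))

    out: list[Interaction] = []

    def centroid_pairs(kind, lkinds, rkinds, cutoff):
        for lg in lig:
            if lg.kind not in lkinds:
                continue
            for rg in rec:
                if rg.kind not in rkinds:
                    continue
                d = float(np.linalg.norm(lg.centroid - rg.centroid))
                if d <= cutoff:
                    out.append(Interaction(kind, lg, rg, d))

    centroid_pairs("attractive_charge", {"cation"}, {"anion"}, cutoffs.attractive_charge)
    centroid_pairs("pi_pi", {"aromatic_ring"}, {"aromatic_ring"}, cutoffs.pi_pi)
    centroid_pairs("pi_alkyl", {"aromatic_ring"}, {"aliphatic_hydrophobe"}, cutoffs.pi_alkyl)
    centroid_pairs("pi_alkyl", {"aliphatic_hydrophobe"}, {"aromatic_ring"}, cutoffs.pi_alkyl)
    for lg in lig:
        if lg.kind not in ("hbond_donor", "hbond_acceptor"):
            continue
        partner = "hbond_acceptor" if lg.kind == "hbond_donor" else "hbond_donor"
        for rg in rec:
            if rg.kind != partner:
                continue
            d = _min_atom_distance(lg, rg, lig_coords, rec_coords)
            if d <= cutoffs.hydrogen_bond:
                out.append(Interaction("hydrogen_bond", lg, rg, d))
    out.sort(key=lambda x: (x.distance, x.kind, x.ligand_group.label, x.receptor_group.label))
    return out


def nplus_anion_distance(complex: ComplexModel, *, mode: str = "atom") -> float:
    """Minimum distance (Å) from the ligand N+ to a binding-site anion group.

    ``mode="atom"`` (default) measures to the nearest anion-group atom, the
    usual crystal-structure convention; ``mode="centroid"`` measures to the
    group centroid.
    """
    pose = complex.ligand
    if pose.charged_nitrogen_index is None:
        raise ValueError("ligand has no cation")
    n_pos = pose.atoms[pose.charged_nitrogen_index].position
    anions = [g for g in receptor_groups(complex) if g.kind == "anion"]
    if not anions:
        raise ValueError("no key anion found in binding site")
    best = np.inf
    for g in anions:
        if mode == "centroid":
            best = min(best, float(np.linalg.norm(n_pos - g.centroid)))
        else:
            for i in g.member_atoms:
                best = min(best, float(np.linalg.norm(
                    n_pos - complex.receptor_atoms[i].position)))
    return best
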