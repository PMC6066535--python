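"""Packaged rigid ligand template (berberine-like tetracyclic cation).

The template carries the connectivity, formal charges and a frozen 3D
conformation of a C20H18NO4+ isoquinolinium alkaloid.  It is the canonical
frame every ligand pose is mapped onto, and the source of the ligand-side
chemistry (aromatic systems, the quaternary N+, ether oxygens as H-bond
acceptors, sp3 carbons as hydrophobes) that PDB files cannot express.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
from rdkit import Chem

_TEMPLATE_RESOURCE = "berberine_like.sdf"


@lru_cache(maxsize=1)
def load_template_mol() -> Chem.Mol:
    with resources.files("mbmscreen.data").joinpath(_TEMPLATE_RESOURCE).open("r") as fh:
        block = fh.read()
    mol = Chem.MolFromMolBlock(block, removeHs=True)
    if mol is None:
        raise RuntimeError("packaged ligand template failed to parse")
    return mol


def template_elements() -> list[str]:
    return [a.GetSymbol() for a in load_template_mol().GetAtoms()]


def template_charges() -> list[int]:
    return [a.GetFormalCharge() for a in load_template_mol().GetAtoms()]


def template_bonds() -> list[tuple[int, int, int]]:
    mol = load_template_mol()
    out = []
    for b in mol.GetBonds():
        order = 1 if b.GetIsAromatic() else int(b.GetBondTypeAsDouble())
        out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(), max(order, 1)))
    return out


def template_coords() -> np.ndarray:
    mol = load_template_mol()
    conf = mol.GetConformer()
    return np.array([list(conf.GetAtomPosition(i)) for i in range(mol.GetNumAtoms())])


@lru_cache(maxsize=1)
def template_chemistry() -> dict:
    """Ligand-side interaction groups as template atom-index lists.

    Returns a dict with keys ``aromatic_systems`` (fused aromatic ring
    systems), ``cation`` (index of the N+), ``acceptors`` (O/N with lone
    pairs) and ``hydrophobes`` (sp3 carbons, one group per atom).
    """
    mol = load_template_mol()
    ri = mol.GetRingInfo()
    arom_rings = [
        set(r) for r in ri.AtomRings()
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
    ]
    # merge fused aromatic rings into systems
    systems: list[set[int]] = []
    for ring in arom_rings:
        merged = ring
        rest = []
        for s in systems:
            if s & merged:
                merged = merged | s
            else:
                rest.append(s)
        systems = rest + [merged]
    systems = [sorted(s) for s in sorted(systems, key=min)]

    cation = next(
        (a.GetIdx() for a in mol.GetAtoms()
         if a.GetSymbol() == "N" and a.GetFormalCharge() == 1),
        None,
    )
    acceptors = [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetSymbol() == "O" and a.GetFormalCharge() <= 0
    ]
    hydrophobes = [
        a.GetIdx() for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and not a.GetIsAromatic()
        and a.GetTotalNumHs() >= 2
    ]
    return {
        "aromatic_systems": systems,
        "cation": cation,
        "acceptors": acceptors,
        "hydrophobes": hydrophobes,
    }
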