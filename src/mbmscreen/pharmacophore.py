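"""Pharmacophore models: typed 3D features with tolerances, plus JSON I/O.

A pharmacophore abstracts one complex into the steric and electronic features
the ligand presents to its receptor.  Features are placed at the *ligand*
group centroids (ligand-anchored convention) so that pharmacophores from
different targets all live on the common ligand scaffold and can be
superimposed exactly via the shared ligand pose.  The persistent format is a
versioned JSON schema, "mbm-pharmacophore/1".
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .complex_io import ComplexModel, LigandPose, AtomRecord
from .interactions import InteractionCutoffs, detect_interactions

__all__ = [
    "FEATURE_KINDS",
    "PharmacophoreFeature",
    "Pharmacophore",
    "EmptyPharmacophoreError",
    "SchemaError",
    "pharmacophore_from_complex",
    "merge_duplicate_features",
    "write_pharmacophore",
    "read_pharmacophore",
]

FEATURE_KINDS = (
    "aromatic_ring",
    "hydrophobe",
    "cation",
    "anion",
    "hbond_acceptor",
    "hbond_donor",
)

SCHEMA_VERSION = "mbm-pharmacophore/1"
DEFAULT_TOLERANCE = 1.6  # Å, feature sphere radius
MERGE_RADIUS = 0.5  # Å, same-kind duplicates closer than this collapse

# ligand interaction-group kind -> feature kind
_GROUP_TO_FEATURE = {
    "aromatic_ring": "aromatic_ring",
    "aliphatic_hydrophobe": "hydrophobe",
    "cation": "cation",
    "anion": "anion",
    "hbond_acceptor": "hbond_acceptor",
    "hbond_donor": "hbond_donor",
}


class EmptyPharmacophoreError(ValueError):
    """No interactions → no features; an empty pharmacophore is refused."""


class SchemaError(ValueError):
    """JSON does not conform to the mbm-pharmacophore schema."""


@dataclass(frozen=True)
class PharmacophoreFeature:
    kind: str
    position: np.ndarray  # (3,) Å
    tolerance: float = DEFAULT_TOLERANCE
    direction: np.ndarray | None = None
    provenance: str = ""

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.direction is not None:
            d = np.asarray(self.direction, dtype=float)
            object.__setattr__(self, "direction", d / np.linalg.norm(d))

    def moved(self, rotation: np.ndarray, translation: np.ndarray) -> "PharmacophoreFeature":
        d = None if self.direction is None else rotation @ self.direction
        return PharmacophoreFeature(self.kind, rotation @ self.position + translation,
                                    self.tolerance, d, self.provenance)


@dataclass
class Pharmacophore:
    features: list[PharmacophoreFeature]
    ligand_pose: LigandPose
    frame: str = "file"  # "file" | "ligand-canonical"
    source_id: str = ""

    def __post_init__(self):
        if not self.features:
            raise EmptyPharmacophoreError("no features; empty pharmacophore refused")

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features])


def _sort_key(f: PharmacophoreFeature):
    return (f.kind, round(f.position[0], 6), round(f.position[1], 6), round(f.position[2], 6))


def merge_duplicate_features(
    features: list[PharmacophoreFeature], radius: float = MERGE_RADIUS
) -> list[PharmacophoreFeature]:
    """Collapse same-kind features closer than ``radius`` (greedy, in stable
    sorted order) to their centroid; idempotent for radius-separated output."""
    out: list[PharmacophoreFeature] = []
    for f in sorted(features, key=_sort_key):
        merged = False
        for k, g in enumerate(out):
            if g.kind == f.kind and np.linalg.norm(g.position - f.position) < radius:
                pos = (g.position + f.position) / 2
                prov = g.provenance if f.provenance in ("", g.provenance) \
                    else f"{g.provenance}+{f.provenance}"
                out[k] = PharmacophoreFeature(g.kind, pos, max(g.tolerance, f.tolerance),
                                              g.direction, prov)
                merged = True
                break
        if not merged:
            out.append(f)
    return sorted(out, key=_sort_key)


def pharmacophore_from_complex(
    complex: ComplexModel,
    cutoffs: InteractionCutoffs = InteractionCutoffs(),
    *,
    tolerance: float = DEFAULT_TOLERANCE,
    merge_radius: float = MERGE_RADIUS,
) -> Pharmacophore:
    """Generate the receptor–ligand pharmacophore of one complex.

    One feature per ligand-side interacting group, at that group's centroid:
    a cation feature for the N+ of each attractive-charge contact, an
    aromatic-ring feature per ring engaged in π–π or π-alkyl, a hydrophobe
    per aliphatic group in π-alkyl, and H-bond donor/acceptor features per
    hydrogen bond.  Same-kind duplicates within ``merge_radius`` are merged.
    Deterministic: features sorted by (kind, position).
    """
    interactions = detect_interactions(complex, cutoffs)
    feats: list[PharmacophoreFeature] = []
    for itx in interactions:
        lg = itx.ligand_group
        kind = _GROUP_TO_FEATURE[lg.kind]
        direction = lg.normal if lg.kind == "aromatic_ring" else None
        feats.append(PharmacophoreFeature(
            kind, lg.centroid, tolerance, direction,
            provenance=f"{itx.kind}:{itx.receptor_group.label}"))
    if not feats:
        raise EmptyPharmacophoreError("no features; empty pharmacophore refused")
    feats = merge_duplicate_features(feats, merge_radius)
    return Pharmacophore(feats, complex.ligand, "file", complex.source_id)


# ---------------------------------------------------------------------------
# JSON serialisation

def _pose_to_json(pose: LigandPose) -> dict:
    return {
        "atoms": [
            {
                "serial": a.serial, "name": a.name, "element": a.element,
                "residue_name": a.residue_name, "chain": a.chain,
                "residue_number": a.residue_number,
                "position": [float(x) for x in a.position],
                "formal_charge": a.formal_charge, "is_hetero": a.is_hetero,
            }
            for a in pose.atoms
        ],
        "bonds": [list(b) for b in pose.bonds],
        "canonical_order": pose.canonical_order,
        "charged_nitrogen_index": pose.charged_nitrogen_index,
    }


def _pose_from_json(d: dict) -> LigandPose:
    atoms = [AtomRecord(**{**a, "position": np.array(a["position"])}) for a in d["atoms"]]
    return LigandPose(
        atoms, [tuple(b) for b in d["bonds"]], d.get("canonical_order"),
        d.get("charged_nitrogen_index"),
    )


def pharmacophore_to_dict(p: Pharmacophore) -> dict:
    return {
        "version": SCHEMA_VERSION,
        "source_id": p.source_id,
        "frame": p.frame,
        "features": [
            {
                "kind": f.kind,
                "position": [float(x) for x in f.position],
                "tolerance": f.tolerance,
                **({"direction": [float(x) for x in f.direction]}
                   if f.direction is not None else {}),
                "provenance": f.provenance,
            }
            for f in p.features
        ],
        "ligand_pose": _pose_to_json(p.ligand_pose),
    }


def write_pharmacophore(p: Pharmacophore) -> str:
    """Serialise to canonical JSON text (sorted keys, fixed float repr)."""
    return json.dumps(pharmacophore_to_dict(p), indent=1, sort_keys=True)


def pharmacophore_from_dict(d: dict) -> Pharmacophore:
    if d.get("version") != SCHEMA_VERSION:
        raise SchemaError(f"missing or unsupported version (expected {SCHEMA_VERSION!r})")
    if "features" not in d or not isinstance(d["features"], list) or not d["features"]:
        raise SchemaError("missing 'features'")
    feats = []
    for fd in d["features"]:
        kind = fd.get("kind")
        if kind not in FEATURE_KINDS:
            raise SchemaError(f"unknown feature kind {kind!r}")
        try:
            feats.append(PharmacophoreFeature(
                kind, np.array(fd["position"], dtype=float), fd.get("tolerance", DEFAULT_TOLERANCE),
                np.array(fd["direction"]) if "direction" in fd else None,
                fd.get("provenance", "")))
        except (KeyError, TypeError, ValueError) as e:
            raise SchemaError(f"bad feature entry: {e}") from e
    if "ligand_pose" not in d:
        raise SchemaError("missing 'ligand_pose'")
    pose = _pose_from_json(d["ligand_pose"])
    return Pharmacophore(feats, pose, d.get("frame", "file"), d.get("source_id", ""))


def read_pharmacophore(text: str) -> Pharmacophore:
    try:
        d = json.loads(text)
    except json.JSONDecodeError as e:
        raise SchemaError(f"not valid JSON: {e}") from e
    if not isinstance(d, dict):
        raise SchemaError("top level must be an object")
    return pharmacophore_from_dict(d)
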