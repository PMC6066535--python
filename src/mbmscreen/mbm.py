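"""Consensus multi-target binding motif (MBM) construction.

Pharmacophores extracted from several complexes that share one ligand are
superimposed by rigid least-squares (Kabsch) alignment of the common ligand
pose onto a reference pose — the shared scaffold makes the frame exact, so
no feature-cloud matching is needed.  Same-kind features from different
sources are then single-linkage clustered; every cluster supported by at
least ``min_support`` sources becomes one consensus feature at the member
centroid, with tolerance equal to the largest member tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.transform import Rotation

from .complex_io import LigandPose
from .pharmacophore import (
    Pharmacophore,
    PharmacophoreFeature,
    SchemaError,
    SCHEMA_VERSION,
    _pose_from_json,
    _pose_to_json,
)

__all__ = [
    "RigidTransform",
    "MBM",
    "NoConsensusError",
    "TemplateMismatchError",
    "align_to_reference",
    "build_mbm",
    "write_mbm",
    "read_mbm",
]

DEFAULT_CLUSTER_RADIUS = 1.5  # Å, single-linkage cutoff
DEFAULT_MIN_SUPPORT = 2


class NoConsensusError(ValueError):
    """No feature cluster reaches min_support."""


class TemplateMismatchError(ValueError):
    """Poses do not map onto the same canonical template."""


@dataclass(frozen=True)
class RigidTransform:
    rotation: np.ndarray  # (3,3), det +1
    translation: np.ndarray  # (3,)
    superposition_rmsd: float

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det +1)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", np.asarray(self.translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.rotation.T + self.translation


@dataclass
class MBM:
    """Consensus feature set in the reference-ligand frame."""

    features: list[PharmacophoreFeature]
    support: list[int]  # per-feature count of contributing pharmacophores
    n_sources: int
    reference_ligand: LigandPose
    min_support: int = DEFAULT_MIN_SUPPORT
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS
    source_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if len(self.support) != len(self.features):
            raise ValueError("support must parallel features")
        for s in self.support:
            if not (1 <= s <= self.n_sources):
                raise ValueError("support out of [1, n_sources]")

    def positions(self) -> np.ndarray:
        return np.array([f.position for f in self.features])


def align_to_reference(pose: LigandPose, reference: LigandPose) -> RigidTransform:
    """Least-squares rigid superposition of ``pose`` onto ``reference``.

    Both poses must map onto the same canonical template ordering; the Kabsch
    rotation is solved over heavy atoms in canonical correspondence.
    """
    if pose.canonical_order is None or reference.canonical_order is None:
        raise TemplateMismatchError("template mismatch: pose lacks canonical mapping")
    if len(pose.atoms) != len(reference.atoms):
        raise TemplateMismatchError("template mismatch: atom counts differ")
    P = pose.canonical_coords()
    Q = reference.canonical_coords()
    p0, q0 = P.mean(axis=0), Q.mean(axis=0)
    rot, rssd = Rotation.align_vectors(Q - q0, P - p0)
    R = rot.as_matrix()
    t = q0 - R @ p0
    rmsd = float(rssd / np.sqrt(len(P)))
    return RigidTransform(R, t, rmsd)


def _feature_sort_key(item):
    f, s = item
    return (f.kind, -s, round(f.position[0], 6), round(f.position[1], 6),
            round(f.position[2], 6))


def build_mbm(
    pharmacophores: list[Pharmacophore],
    min_support: int = DEFAULT_MIN_SUPPORT,
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS,
    reference: LigandPose | None = None,
) -> MBM:
    """Superimpose pharmacophores via their shared ligand and emit the MBM.

    ``reference`` defaults to the first pharmacophore's ligand pose.  Support
    counts distinct contributing pharmacophores per cluster.  Deterministic
    under permutation of the input list (for a fixed reference pose).
    """
    if len(pharmacophores) < 2:
        raise ValueError("need at least 2 pharmacophores to build a consensus")
    ref = reference if reference is not None else pharmacophores[0].ligand_pose

    # transform every feature set into the reference ligand frame
    placed: list[tuple[PharmacophoreFeature, int]] = []  # (feature, source index)
    for k, p in enumerate(pharmacophores):
        tf = align_to_reference(p.ligand_pose, ref)
        for f in p.features:
            placed.append((f.moved(tf.rotation, tf.translation), k))
    placed.sort(key=lambda it: (_feature_sort_key((it[0], 0)), it[1]))

    consensus: list[tuple[PharmacophoreFeature, int]] = []
    kinds = sorted({f.kind for f, _ in placed})
    for kind in kinds:
        members = [(f, k) for f, k in placed if f.kind == kind]
        coords = np.array([f.position for f, _ in members])
        if len(members) == 1:
            labels = np.array([1])
        else:
            Z = linkage(coords, method="single")
            labels = fcluster(Z, t=cluster_radius, criterion="distance")
        for lab in sorted(set(labels)):
            idx = [i for i, l in enumerate(labels) if l == lab]
            sources = {members[i][1] for i in idx}
            if len(sources) < min_support:
                continue
            pos = coords[idx].mean(axis=0)
            tol = max(members[i][0].tolerance for i in idx)
            prov = ";".join(sorted({members[i][0].provenance for i in idx if
                                    members[i][0].provenance})[:4])
            consensus.append((
                PharmacophoreFeature(kind, pos, tol, None, prov), len(sources)))
    if not consensus:
        raise NoConsensusError("no consensus; lower min_support")
    consensus.sort(key=_feature_sort_key)
    feats = [f for f, _ in consensus]
    support = [s for _, s in consensus]
    return MBM(feats, support, len(pharmacophores), ref, min_support, cluster_radius,
               [p.source_id for p in pharmacophores])


# ---------------------------------------------------------------------------
# persistence (same schema as pharmacophores, with consensus extras)

def write_mbm(m: MBM) -> str:
    import json

    d = {
        "version": SCHEMA_VERSION,
        "kind": "mbm",
        "frame": "ligand-canonical",
        "n_sources": m.n_sources,
        "min_support": m.min_support,
        "cluster_radius": m.cluster_radius,
        "source_ids": m.source_ids,
        "features": [
            {
                "kind": f.kind,
                "position": [float(x) for x in f.position],
                "tolerance": f.tolerance,
                "provenance": f.provenance,
                "support": s,
            }
            for f, s in zip(m.features, m.support)
        ],
        "ligand_pose": _pose_to_json(m.reference_ligand),
    }
    return json.dumps(d, indent=1, sort_keys=True)


def read_mbm(text: str) -> MBM:
    import json

    try:
        d = json.loads(text)
    except json.JSONDecodeError as e:
        raise SchemaError(f"not valid JSON: {e}") from e
    if d.get("version") != SCHEMA_VERSION or d.get("kind") != "mbm":
        raise SchemaError("missing or unsupported version/kind for MBM")
    feats, support = [], []
    for fd in d.get("features", []):
        feats.append(PharmacophoreFeature(
            fd["kind"], np.array(fd["position"]), fd["tolerance"],
            None, fd.get("provenance", "")))
        support.append(int(fd["support"]))
    if not feats:
        raise SchemaError("missing 'features'")
    return MBM(feats, support, int(d["n_sources"]), _pose_from_json(d["ligand_pose"]),
               int(d.get("min_support", DEFAULT_MIN_SUPPORT)),
               float(d.get("cluster_radius", DEFAULT_CLUSTER_RADIUS)),
               list(d.get("source_ids", [])))
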