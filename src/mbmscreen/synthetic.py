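"""Synthetic fixtures: toy complexes, planted-motif pharmacophore sets, and
affinity observations drawn under the assumed BP–K_D link.

Everything here is generated programmatically and deterministically from a
seed, standing in for crystal structures and binding assays: (a) minimal PDB
complexes placing receptor side-chain fragments at prescribed distances from
the packaged rigid cationic ligand, (b) multi-target pharmacophore sets that
share a planted consensus constellation (with Gaussian positional jitter)
plus per-target decoy features, with the ground truth recorded, and (c)
(n, RMSD, K_D) observations that are self-consistent with a known
(alpha, beta, kappa) so calibration can be validated by exact recovery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .complex_io import AtomRecord, LigandPose
from .mbm import DEFAULT_CLUSTER_RADIUS
from .pharmacophore import (
    DEFAULT_TOLERANCE,
    FEATURE_KINDS,
    Pharmacophore,
    PharmacophoreFeature,
)
from .screening import DEFAULT_PAIR_CUTOFF, KdObservation, ReciprocalKdLink, ScoringParams
from .template import template_charges, template_chemistry, template_coords, template_elements

logger = logging.getLogger(__name__)

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "Placement",
    "template_ligand_pose",
    "default_planted_features",
    "make_complex_fixture",
    "make_pharmacophore_set",
    "make_kd_observations",
]


# ---------------------------------------------------------------------------
# ligand pose from the packaged template

def template_ligand_pose(
    rotation: np.ndarray | None = None, translation: np.ndarray | None = None
) -> LigandPose:
    """The packaged ligand as a LigandPose (optionally rigidly moved),
    centred so the heavy-atom centroid sits at the origin before moving."""
    coords = template_coords()
    coords = coords - coords.mean(axis=0)
    if rotation is not None:
        coords = coords @ np.asarray(rotation).T
    if translation is not None:
        coords = coords + np.asarray(translation)
    elements = template_elements()
    charges = template_charges()
    counters: dict[str, int] = {}
    atoms = []
    for i, (el, q) in enumerate(zip(elements, charges)):
        counters[el] = counters.get(el, 0) + 1
        atoms.append(AtomRecord(
            serial=i + 1, name=f"{el}{counters[el]}", element=el,
            residue_name="BER", chain="L", residue_number=1,
            position=coords[i], formal_charge=q, is_hetero=True))
    from .template import template_bonds

    n_plus = next((i for i, q in enumerate(charges) if q == 1 and elements[i] == "N"), None)
    return LigandPose(atoms, template_bonds(), list(range(len(atoms))), n_plus)


def _anchor_position(pose: LigandPose, anchor: str) -> np.ndarray:
    chem = template_chemistry()
    coords = pose.coords
    if anchor == "nplus":
        return coords[pose.charged_nitrogen_index]
    if anchor.startswith("ring"):
        k = int(anchor[4:]) - 1
        idxs = [pose.canonical_order.index(t) for t in chem["aromatic_systems"][k]]
        return coords[idxs].mean(axis=0)
    if anchor == "centroid":
        return pose.centroid()
    if anchor == "surface":
        raise ValueError("'surface' anchor is resolved per-direction by the caller")
    raise ValueError(f"unknown anchor {anchor!r}")


# ---------------------------------------------------------------------------
# toy PDB complexes

@dataclass(frozen=True)
class Placement:
    """One receptor fragment placed at an exact distance from the ligand.

    ``anchor``: "nplus" (the N+ atom), "ring1"/"ring2" (aromatic-system
    centroid), "centroid" (ligand centroid) or "surface" (nearest ligand
    atom in the placement direction — gives an exact nearest-atom distance).
    """

    residue_name: str
    distance: float
    anchor: str = "surface"
    key: str = "atom"  # "atom": nearest fragment atom at the exact distance;
    # "group_centroid": the fragment's charged-group centroid at the distance

    def __post_init__(self):
        if self.distance <= 1.5:
            raise ValueError("placement distance must exceed 1.5 Å (clash)")


# side-chain fragments in local coordinates: key atom at the origin, the
# rest at +z (pointing away from the ligand after placement)
_FRAGMENTS: dict[str, list[tuple[str, str, tuple[float, float, float]]]] = {
    "GLU": [("OE1", "O", (0.0, 0.0, 0.0)), ("CD", "C", (0.0, 0.6, 1.1)),
            ("OE2", "O", (0.0, 0.0, 2.2)), ("CG", "C", (0.0, 2.0, 1.4)),
            ("CB", "C", (0.0, 2.6, 2.8))],
    "ASP": [("OD1", "O", (0.0, 0.0, 0.0)), ("CG", "C", (0.0, 0.6, 1.1)),
            ("OD2", "O", (0.0, 0.0, 2.2)), ("CB", "C", (0.0, 2.0, 1.4))],
    "ALA": [("CB", "C", (0.0, 0.0, 0.0))],
    "LYS": [("NZ", "N", (0.0, 0.0, 0.0)), ("CE", "C", (0.0, 0.6, 1.3)),
            ("CD", "C", (0.0, 0.0, 2.6))],
    "SER": [("OG", "O", (0.0, 0.0, 0.0)), ("CB", "C", (0.0, 0.6, 1.3))],
    "LEU": [("CB", "C", (0.0, 0.0, 0.0)), ("CG", "C", (0.0, 0.6, 1.3)),
            ("CD1", "C", (0.0, 1.8, 2.0)), ("CD2", "C", (0.0, -0.5, 2.5))],
}

_RING_NAMES = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")


def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.arange(6) * math.pi / 3.0
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


def _pyrimidine_local() -> list[tuple[str, str, tuple[float, float, float]]]:
    hexa = _hexagon(1.35)
    names = ("N1", "C2", "N3", "C4", "C5", "C6")
    elems = ("N", "C", "N", "C", "C", "C")
    return [(n, e, tuple(p)) for n, e, p in zip(names, elems, hexa)]


def _orthonormal_frame(u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    u = u / np.linalg.norm(u)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    v = np.cross(u, helper)
    v /= np.linalg.norm(v)
    w = np.cross(u, v)
    return v, w, u


# well-separated unit directions used for successive placements
_DIRECTIONS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
    [1, 1, 1], [-1, -1, 1], [1, -1, -1], [-1, 1, -1],
], dtype=float)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)


def make_complex_fixture(placements: list[Placement]) -> str:
    """Minimal PDB text: the rigid ligand at the origin plus side-chain
    fragments at the requested exact distances, each along its own direction.

    The key atom of each fragment (carboxylate O, ring centroid, CB, …) lands
    exactly ``distance`` from the anchor; remaining fragment atoms point away
    from the ligand so the key atom stays the nearest one.
    """
    from .complex_io import BindingSite, ComplexModel, write_complex_pdb

    pose = template_ligand_pose()
    lig_coords = pose.coords
    receptor: list[AtomRecord] = []
    serial = 100
    for k, pl in enumerate(placements):
        if pl.residue_name not in set(_FRAGMENTS) | {"PHE", "TYR", "DC"}:
            raise ValueError(f"unsupported residue {pl.residue_name!r}")
        u = _DIRECTIONS[k % len(_DIRECTIONS)]
        if pl.anchor == "surface":
            extreme = lig_coords[np.argmax(lig_coords @ u)]
            key_pos = extreme + pl.distance * u
        else:
            key_pos = _anchor_position(pose, pl.anchor) + pl.distance * u
        v, w, uu = _orthonormal_frame(u)
        R = np.stack([v, w, uu], axis=1)  # local (x,y,z) -> world

        origin = key_pos
        if pl.key == "group_centroid" and pl.residue_name in ("GLU", "ASP"):
            # carboxylate O..O centroid sits at local (0, 0, 1.1)
            origin = key_pos - R @ np.array([0.0, 0.0, 1.1])

        def world(p_local):
            return origin + R @ np.asarray(p_local, dtype=float)

        resnum = 10 + k
        if pl.residue_name in ("PHE", "TYR"):
            # ring centroid is the key point; ring plane faces the ligand
            for name, p in zip(_RING_NAMES, _hexagon()):
                receptor.append(AtomRecord(serial, name, "C", pl.residue_name, "A",
                                           resnum, world(p)))
                serial += 1
            receptor.append(AtomRecord(serial, "CB", "C", pl.residue_name, "A",
                                       resnum, world((0.0, 2.5, 1.2))))
            serial += 1
            if pl.residue_name == "TYR":
                receptor.append(AtomRecord(serial, "OH", "O", pl.residue_name, "A",
                                           resnum, world((0.0, -2.8, 0.3))))
                serial += 1
        elif pl.residue_name == "DC":
            # cytosine ring (key point = ring centroid) plus a 5' phosphate
            for name, el, p in _pyrimidine_local():
                receptor.append(AtomRecord(serial, name, el, "DC", "A", resnum, world(p)))
                serial += 1
            for name, p in (("P", (0.0, 3.2, 1.2)), ("OP1", (0.0, 3.9, 0.1)),
                            ("OP2", (0.0, 3.9, 2.4))):
                receptor.append(AtomRecord(serial, name, "P" if name == "P" else "O",
                                           "DC", "A", resnum, world(p)))
                serial += 1
        else:
            for name, el, p in _FRAGMENTS[pl.residue_name]:
                receptor.append(AtomRecord(serial, name, el, pl.residue_name, "A",
                                           resnum, world(p)))
                serial += 1

    model = ComplexModel(receptor, pose,
                         BindingSite(pose.centroid(), 7.0, []), "fixture")
    return write_complex_pdb(model)


# ---------------------------------------------------------------------------
# planted-motif pharmacophore sets

def default_planted_features() -> list[PharmacophoreFeature]:
    """Four-feature constellation on the ligand scaffold, in the canonical
    (centred) ligand frame: the N+ cation, both aromatic-system centroids,
    and one ether oxygen as H-bond acceptor."""
    pose = template_ligand_pose()
    coords = pose.coords
    chem = template_chemistry()
    feats = [PharmacophoreFeature("cation", coords[pose.charged_nitrogen_index],
                                  DEFAULT_TOLERANCE, provenance="planted:N+")]
    for k, system in enumerate(chem["aromatic_systems"][:2]):
        idxs = [pose.canonical_order.index(t) for t in system]
        feats.append(PharmacophoreFeature("aromatic_ring", coords[idxs].mean(axis=0),
                                          DEFAULT_TOLERANCE, provenance=f"planted:ring{k+1}"))
    feats.append(PharmacophoreFeature("hbond_acceptor", coords[chem["acceptors"][0]],
                                      DEFAULT_TOLERANCE, provenance="planted:O"))
    return feats


@dataclass
class FixtureSpec:
    """Study conditions for the synthetic generators (all seeded)."""

    seed: int = 0
    n_targets: int = 6  # as many sources as the proven-complex set (5 + one dual site)
    planted_features: list[PharmacophoreFeature] = field(
        default_factory=default_planted_features)
    jitter_sigma: float = 0.3  # Å, positional noise per planted feature
    decoys_per_target: int = 2
    link_params: ScoringParams = field(default_factory=ScoringParams)
    noise_sigma: float = 0.0  # link-scale noise for K_D observations
    n_observations: int = 50
    cluster_radius: float = DEFAULT_CLUSTER_RADIUS
    pair_cutoff: float = DEFAULT_PAIR_CUTOFF

    def __post_init__(self):
        if self.jitter_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class GroundTruth:
    """What was planted: consensus positions in the reference (canonical
    ligand) frame and the per-target noiseless match statistics."""

    planted: list[PharmacophoreFeature]
    n_true: list[int]  # per target: planted features within pair_cutoff of truth
    rmsd_true: list[float]  # per target: RMS jitter over those features
    jitter_distances: list[list[float]]


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def make_pharmacophore_set(spec: FixtureSpec) -> tuple[list[Pharmacophore], GroundTruth]:
    """Pharmacophores for ``n_targets`` synthetic targets sharing the planted
    constellation, each in its own rigidly moved frame, with jitter and decoys.

    Target 0 keeps the identity frame, so the reference frame of an MBM built
    on this set coincides with the planted frame.  Decoys are sampled
    uniformly in a 4–10 Å shell around the ligand centroid with kinds uniform
    over the six feature kinds, excluded within 2×cluster_radius of any
    planted feature so the ground truth stays unambiguous.
    """
    if spec.n_targets < 2:
        raise ValueError("need n_targets >= 2")
    rng = np.random.default_rng(spec.seed)
    planted_pos = np.array([f.position for f in spec.planted_features])
    pharmacophores: list[Pharmacophore] = []
    n_true, rmsd_true, jitters_all = [], [], []
    decoy_positions: list[np.ndarray] = []  # reference frame, across all targets
    for t in range(spec.n_targets):
        if t == 0:
            R, trans = np.eye(3), np.zeros(3)
        else:
            R, trans = _random_rotation(rng), rng.uniform(-10, 10, size=3)
        pose = template_ligand_pose(R, trans)
        feats = []
        jit = rng.normal(scale=spec.jitter_sigma, size=planted_pos.shape) \
            if spec.jitter_sigma > 0 else np.zeros_like(planted_pos)
        dists = np.linalg.norm(jit, axis=1)
        for f, j in zip(spec.planted_features, jit):
            pos = R @ (f.position + j) + trans
            feats.append(PharmacophoreFeature(f.kind, pos, f.tolerance,
                                              provenance=f.provenance))
        placed, attempts = 0, 0
        while placed < spec.decoys_per_target:
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError("decoy placement failed: exclusion zones too dense")
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            radius = rng.uniform(4.0, 10.0)
            cand = direction * radius
            # exclusion zone: decoys stay 2×cluster_radius away from planted
            # features AND from every other decoy (any target), so no decoy can
            # join or form a consensus cluster — ground truth stays unambiguous
            blocked = planted_pos if not decoy_positions else \
                np.vstack([planted_pos, np.array(decoy_positions)])
            if np.min(np.linalg.norm(blocked - cand, axis=1)) < 2 * spec.cluster_radius:
                continue
            kind = FEATURE_KINDS[rng.integers(len(FEATURE_KINDS))]
            feats.append(PharmacophoreFeature(kind, R @ cand + trans,
                                              DEFAULT_TOLERANCE, provenance="decoy"))
            decoy_positions.append(cand)
            placed += 1
        pharmacophores.append(Pharmacophore(feats, pose, "file", f"synthetic-{t}"))
        keep = dists <= spec.pair_cutoff
        n_true.append(int(keep.sum()))
        rmsd_true.append(float(np.sqrt(np.mean(dists[keep] ** 2))) if keep.any() else 0.0)
        jitters_all.append([float(d) for d in dists])
    truth = GroundTruth(list(spec.planted_features), n_true, rmsd_true, jitters_all)
    return pharmacophores, truth


# ---------------------------------------------------------------------------
# affinity observations

def make_kd_observations(
    spec: FixtureSpec, link: ReciprocalKdLink = ReciprocalKdLink()
) -> tuple[list[KdObservation], int]:
    """(n, RMSD, K_D) observations self-consistent with ``spec.link_params``.

    Draws n uniform on 3..8 and RMSD uniform on [0.05, 0.12] Å — the region
    where the default link yields positive K_D under the calibrated
    constants — computes BP, maps it through the link with seeded Gaussian
    noise of sd ``noise_sigma`` on the link scale, and skips any draw whose
    K_D comes out non-positive.  Returns (observations, n_skipped).
    """
    rng = np.random.default_rng(spec.seed)
    p = spec.link_params
    out: list[KdObservation] = []
    skipped = 0
    for k in range(spec.n_observations):
        n = int(rng.integers(3, 9))
        rmsd = float(rng.uniform(0.05, 0.12))
        bp = n ** p.alpha * rmsd ** p.beta
        resp = math.log10(bp) + p.kappa
        if spec.noise_sigma > 0:
            resp += float(rng.normal(scale=spec.noise_sigma))
        if resp <= 0:
            skipped += 1
            logger.warning("observation %d skipped: link gives non-positive K_D", k)
            continue
        out.append(KdObservation(f"obs-{k}", n, rmsd, 1.0 / resp))
    return out, skipped
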