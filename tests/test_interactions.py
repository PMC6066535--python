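"""Interaction-group typing and distance-based contact detection."""

import numpy as np
import pytest

from mbmscreen.interactions import (
    InteractionCutoffs,
    detect_interactions,
    ligand_groups,
    nplus_anion_distance,
    receptor_groups,
)
from mbmscreen.complex_io import read_complex
from mbmscreen.synthetic import Placement, make_complex_fixture

from conftest import random_rigid, transform_complex


def test_glu_gives_one_carboxylate_anion(glu_complex):
    anions = [g for g in receptor_groups(glu_complex) if g.kind == "anion"]
    assert len(anions) == 1
    assert len(anions[0].member_atoms) == 2
    assert all(glu_complex.receptor_atoms[i].element == "O"
               for i in anions[0].member_atoms)


def test_phe_gives_one_six_atom_ring_with_unit_normal(phe_complex):
    rings = [g for g in receptor_groups(phe_complex) if g.kind == "aromatic_ring"]
    assert len(rings) == 1
    assert len(rings[0].member_atoms) == 6
    assert np.linalg.norm(rings[0].normal) == pytest.approx(1.0)


def test_cytosine_with_phosphate_types_anion_and_ring():
    model = read_complex(make_complex_fixture([Placement("DC", 5.0, "centroid")]))
    groups = receptor_groups(model)
    assert any(g.kind == "anion" for g in groups)
    assert any(g.kind == "aromatic_ring" for g in groups)


def test_ligand_side_chemistry(glu_complex):
    """The cationic alkaloid presents 2 aromatic systems, one N+, four O
    acceptors and its sp3 carbons as hydrophobes."""
    groups = ligand_groups(glu_complex)
    by_kind = {}
    for g in groups:
        by_kind.setdefault(g.kind, []).append(g)
    assert len(by_kind["aromatic_ring"]) == 2
    assert len(by_kind["cation"]) == 1
    assert len(by_kind["hbond_acceptor"]) == 4
    assert len(by_kind.get("aliphatic_hydrophobe", [])) >= 2


@pytest.mark.parametrize("distance,expected", [(6.9, 1), (7.1, 0)])
def test_attractive_charge_cutoff_boundary(distance, expected):
    """Anion centroid just inside / outside the 7 Å charge shell."""
    model = read_complex(make_complex_fixture(
        [Placement("ASP", distance, "nplus", key="group_centroid")]))
    charges = [i for i in detect_interactions(model) if i.kind == "attractive_charge"]
    assert len(charges) == expected
    if expected:
        assert charges[0].distance == pytest.approx(distance, abs=1e-3)


def test_pi_stack_detected_at_3p8(phe_complex):
    pipi = [i for i in detect_interactions(phe_complex) if i.kind == "pi_pi"]
    assert len(pipi) == 1
    assert pipi[0].distance == pytest.approx(3.8, abs=1e-3)


def test_emitted_distances_respect_cutoffs(mixed_complex):
    cutoffs = InteractionCutoffs()
    for itx in detect_interactions(mixed_complex, cutoffs):
        assert itx.distance <= getattr(cutoffs, itx.kind)


def test_raising_cutoffs_never_removes_interactions(mixed_complex):
    small = detect_interactions(mixed_complex, InteractionCutoffs(5.0, 4.0, 4.0, 3.0))
    large = detect_interactions(mixed_complex, InteractionCutoffs(9.0, 8.0, 7.0, 4.0))

    def keys(lst):
        return {(i.kind, i.ligand_group.label, i.receptor_group.label) for i in lst}

    assert keys(small) <= keys(large)


def test_detection_rigid_motion_invariant(mixed_complex):
    rng = np.random.default_rng(17)
    ref = [(i.kind, i.ligand_group.label, i.receptor_group.label,
            round(i.distance, 6)) for i in detect_interactions(mixed_complex)]
    for _ in range(3):
        R, t = random_rigid(rng)
        moved = transform_complex(mixed_complex, R, t)
        got = [(i.kind, i.ligand_group.label, i.receptor_group.label,
                round(i.distance, 6)) for i in detect_interactions(moved)]
        assert got == ref


def test_detection_equals_all_pairs_brute_force(mixed_complex):
    """On a small fixture the detector must equal exhaustive enumeration of
    all type-compatible group pairs under the same distance rules."""
    cutoffs = InteractionCutoffs()
    lig = ligand_groups(mixed_complex)
    rec = receptor_groups(mixed_complex)
    lig_c = mixed_complex.ligand.coords
    rec_c = np.array([a.position for a in mixed_complex.receptor_atoms])
    expected = set()
    for lg in lig:
        for rg in rec:
            d = float(np.linalg.norm(lg.centroid - rg.centroid))
            if lg.kind == "cation" and rg.kind == "anion" and d <= cutoffs.attractive_charge:
                expected.add(("attractive_charge", lg.label, rg.label))
            if lg.kind == "aromatic_ring" and rg.kind == "aromatic_ring" and d <= cutoffs.pi_pi:
                expected.add(("pi_pi", lg.label, rg.label))
            if {lg.kind, rg.kind} == {"aromatic_ring", "aliphatic_hydrophobe"} \
                    and d <= cutoffs.pi_alkyl:
                expected.add(("pi_alkyl", lg.label, rg.label))
            if {lg.kind, rg.kind} == {"hbond_donor", "hbond_acceptor"} \
                    and lg.kind in ("hbond_donor", "hbond_acceptor"):
                dm = min(np.linalg.norm(lig_c[i] - rec_c[j])
                         for i in lg.member_atoms for j in rg.member_atoms)
                if dm <= cutoffs.hydrogen_bond:
                    expected.add(("hydrogen_bond", lg.label, rg.label))
    got = {(i.kind, i.ligand_group.label, i.receptor_group.label)
           for i in detect_interactions(mixed_complex, cutoffs)}
    assert got == expected


def test_nplus_anion_distance_constructed(glu_complex):
    assert nplus_anion_distance(glu_complex) == pytest.approx(4.29, abs=1e-3)


def test_nplus_anion_distance_errors(phe_complex):
    with pytest.raises(ValueError, match="no key anion"):
        nplus_anion_distance(phe_complex)


def test_interactions_sorted_by_distance(mixed_complex):
    d = [i.distance for i in detect_interactions(mixed_complex)]
    assert d == sorted(d)
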