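"""Complex parsing, ligand identification and binding-site definition."""

import numpy as np
import pytest

from mbmscreen.complex_io import (
    AmbiguousLigandError,
    LigandNotFoundError,
    define_binding_site,
    read_all_ligand_copies,
    read_complex,
    write_complex_pdb,
)
from mbmscreen.synthetic import Placement, make_complex_fixture

from conftest import random_rigid, transform_complex


def test_ligand_has_25_heavy_atoms_and_charged_nitrogen(glu_complex):
    """The packaged C20H18NO4+ scaffold parses to 25 heavy atoms with exactly
    one +1 formal charge, sitting on a nitrogen."""
    lig = glu_complex.ligand
    assert len(lig.atoms) == 25
    charged = [a for a in lig.atoms if a.formal_charge == 1]
    assert len(charged) == 1 and charged[0].element == "N"
    assert lig.charged_nitrogen_index is not None
    assert lig.atoms[lig.charged_nitrogen_index].element == "N"
    assert len(glu_complex.site.residues) == 1


def test_missing_ligand_raises():
    pdb = make_complex_fixture([Placement("GLU", 4.0, "nplus")])
    no_het = "\n".join(l for l in pdb.splitlines() if not l.startswith("HETATM"))
    with pytest.raises(LigandNotFoundError):
        read_complex(no_het)


def test_two_ligand_copies_yield_two_labelled_sites():
    """RamR-style duplicated ligand: the plain reader refuses the ambiguity,
    the multi-copy reader returns one model per copy in file order."""
    base = make_complex_fixture([Placement("GLU", 4.0, "nplus")])
    lines = [l for l in base.splitlines() if l.startswith(("ATOM", "HETATM"))]
    shifted = []
    for l in lines:
        if l.startswith("HETATM"):
            x = float(l[30:38]) + 40.0
            l = l[:21] + "M" + l[22:30] + f"{x:8.3f}" + l[38:]
        shifted.append(l)
    doubled = "\n".join(lines + [l for l in shifted if l.startswith("HETATM")]) + "\nEND\n"
    with pytest.raises(AmbiguousLigandError):
        read_complex(doubled)
    models = read_all_ligand_copies(doubled)
    assert [m.site.site_label for m in models] == ["site I", "site II"]
    one = read_complex(doubled, chain="L", resnum=1)
    assert len(one.ligand.atoms) == 25


@pytest.mark.parametrize(
    "distance,radius,expected",
    [(6.5, 7.0, 1), (6.5, 5.0, 0)],
)
def test_site_membership_boundary(distance, radius, expected):
    """A residue whose nearest atom sits at 6.5 Å is inside a 7 Å shell and
    outside a 5 Å one (nearest ligand-atom convention)."""
    model = read_complex(make_complex_fixture([Placement("ALA", distance, "surface")]))
    site = define_binding_site(model, radius)
    assert len(site.residues) == expected


def test_site_counts_match_brute_force_distances():
    """Three residues at nearest-atom distances 3/6/9 Å: a 7 Å site keeps
    exactly the first two, matching an all-pairs distance check."""
    model = read_complex(make_complex_fixture([
        Placement("ALA", 3.0, "surface"),
        Placement("ALA", 6.0, "surface"),
        Placement("ALA", 9.0, "surface"),
    ]))
    site = define_binding_site(model, 7.0)
    assert len(site.residues) == 2
    # brute force: per residue, min over all atom pairs
    lig = model.ligand.coords
    for chain, resnum, _ in site.residues:
        pos = np.array([a.position for a in model.receptor_atoms
                        if (a.chain, a.residue_number) == (chain, resnum)])
        dmin = np.min(np.linalg.norm(pos[:, None] - lig[None], axis=-1))
        assert dmin <= 7.0


def test_site_radius_monotonicity(mixed_complex):
    prev = set()
    for r in (2.0, 4.0, 6.0, 8.0, 12.0):
        cur = {(c, n) for c, n, _ in define_binding_site(mixed_complex, r).residues}
        assert prev <= cur
        prev = cur


def test_invalid_radius_rejected(glu_complex):
    with pytest.raises(ValueError):
        define_binding_site(glu_complex, 0.0)


def test_site_membership_rigid_motion_invariant(mixed_complex):
    rng = np.random.default_rng(5)
    before = [(c, n) for c, n, _ in mixed_complex.site.residues]
    for _ in range(3):
        R, t = random_rigid(rng)
        moved = transform_complex(mixed_complex, R, t)
        assert [(c, n) for c, n, _ in moved.site.residues] == before


def test_pdb_round_trip_preserves_coordinates(mixed_complex):
    """write → read reproduces every coordinate to PDB precision (3 dp)."""
    text = write_complex_pdb(mixed_complex)
    again = read_complex(text)
    a = np.vstack([mixed_complex.ligand.coords,
                   [x.position for x in mixed_complex.receptor_atoms]])
    b = np.vstack([again.ligand.coords, [x.position for x in again.receptor_atoms]])
    assert a.shape == b.shape
    assert np.allclose(np.sort(a, axis=0), np.sort(b, axis=0), atol=5e-4)


def test_fixture_distance_is_exact():
    model = read_complex(make_complex_fixture([Placement("GLU", 4.29, "nplus")]))
    npos = model.ligand.atoms[model.ligand.charged_nitrogen_index].position
    oe1 = [a for a in model.receptor_atoms if a.name == "OE1"][0]
    assert np.linalg.norm(npos - oe1.position) == pytest.approx(4.29, abs=1e-3)
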