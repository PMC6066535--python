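import itertools
from dataclasses import replace

import numpy as np
import pytest

from mbmscreen.complex_io import BindingSite, ComplexModel, define_binding_site, read_complex
from mbmscreen.synthetic import Placement, make_complex_fixture


@pytest.fixture(scope="session")
def glu_complex():
    """Ligand + one GLU whose nearest carboxylate O sits 4.29 Å from the N+."""
    return read_complex(make_complex_fixture([Placement("GLU", 4.29, "nplus")]))


@pytest.fixture(scope="session")
def phe_complex():
    """Ligand + one PHE ring stacked 3.8 Å from the first aromatic system."""
    return read_complex(make_complex_fixture([Placement("PHE", 3.8, "ring1")]))


@pytest.fixture(scope="session")
def mixed_complex():
    """Charge + stack + hydrophobe site used for multi-feature pharmacophores."""
    text = make_complex_fixture([
        Placement("GLU", 4.29, "nplus"),
        Placement("PHE", 3.8, "ring1"),
        Placement("ALA", 4.0, "ring2"),
    ])
    return read_complex(text)


def random_rigid(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20, 20, size=3)
    return R, t


def transform_complex(model: ComplexModel, R, t) -> ComplexModel:
    """Apply one rigid motion to every atom and re-derive the binding site."""
    receptor = [replace(a, position=R @ a.position + t) for a in model.receptor_atoms]
    ligand = model.ligand.transformed(R, t)
    ligand.canonical_order = model.ligand.canonical_order
    moved = ComplexModel(receptor, ligand,
                         BindingSite(ligand.centroid(), model.site.radius, []),
                         model.source_id)
    moved.site = define_binding_site(moved, model.site.radius)
    return moved


def brute_force_assignment(cand_feats, mbm_feats, cutoff):
    """Exhaustive max-n / min-total-distance matching over type-compatible
    injections; tractable for <= 6 features per side.  Returns (n, total)."""
    kinds = {f.kind for f in cand_feats} & {f.kind for f in mbm_feats}
    n_total, d_total = 0, 0.0
    for kind in sorted(kinds):
        ci = [f for f in cand_feats if f.kind == kind]
        mi = [f for f in mbm_feats if f.kind == kind]
        d = np.array([[np.linalg.norm(a.position - b.position) for b in mi] for a in ci])
        best_n, best_d = 0, 0.0
        kmax = min(len(ci), len(mi))
        for k in range(kmax, 0, -1):
            found = None
            for rows in itertools.combinations(range(len(ci)), k):
                for cols in itertools.permutations(range(len(mi)), k):
                    ds = [d[r, c] for r, c in zip(rows, cols)]
                    if all(x <= cutoff for x in ds):
                        tot = sum(ds)
                        if found is None or tot < found:
                            found = tot
            if found is not None:
                best_n, best_d = k, found
                break
        n_total += best_n
        d_total += best_d
    return n_total, d_total
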