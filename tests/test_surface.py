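"""Shrake-Rupley surface areas: closed-form oracles, partition, invariances."""

import math

import numpy as np
import pytest

from metaconc import MoleculeRecord, embed_3d, protonate_ph7, surface_areas
from metaconc.chem import RadiusTable, fibonacci_sphere, per_atom_areas
from metaconc.errors import EmbeddingError, MetaconcError, MissingRadiusError


def sphere_area(r, probe=1.4):
    return 4.0 * math.pi * (r + probe) ** 2


def test_isolated_atom_matches_closed_form_within_one_percent():
    for element, radius in (("C", 1.70), ("O", 1.52)):
        areas = per_atom_areas(np.zeros((1, 3)), [element], n_points=960)
        assert areas[0] == pytest.approx(sphere_area(radius), rel=0.01)


def test_occluded_pair_converges_to_spherical_cap_formula():
    # two equal spheres of expanded radius R at distance d: each loses a cap
    # of height h = R - d/2, leaving exposed area 2*pi*R*(R + d/2)
    R, d = 1.70 + 1.4, 3.0
    exact = 2.0 * math.pi * R * (R + d / 2.0)
    coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
    errs = []
    for n in (100, 400, 1600):
        areas = per_atom_areas(coords, ["C", "C"], n_points=n)
        errs.append(abs(areas[0] - exact) / exact)
    assert errs[2] < errs[0]
    assert errs[2] < 0.005


def test_polar_partition_for_isolated_atoms():
    # a single O atom is entirely polar surface; a single C entirely non-polar
    o = embed_3d(MoleculeRecord.from_smiles("[O]", id="o"))
    total, psa, npsa = surface_areas(o)
    assert psa == pytest.approx(total)
    assert npsa == pytest.approx(0.0, abs=1e-9)


def test_distant_atoms_are_additive():
    coords = np.array([[0.0, 0.0, 0.0], [50.0, 0.0, 0.0]])
    areas = per_atom_areas(coords, ["C", "O"], n_points=960)
    assert areas[0] == pytest.approx(sphere_area(1.70), rel=0.01)
    assert areas[1] == pytest.approx(sphere_area(1.52), rel=0.01)


def test_psa_plus_npsa_equals_total_exactly(fixtures_by_id):
    rec = embed_3d(protonate_ph7(fixtures_by_id["glutamate"]), seed=3)
    total, psa, npsa = surface_areas(rec)
    assert total == pytest.approx(psa + npsa, abs=1e-9)
    assert psa > 0 and npsa > 0


def test_translation_exact_and_rotation_approximate_invariance():
    rng = np.random.default_rng(0)
    coords = rng.uniform(-2, 2, size=(5, 3))
    elements = ["C", "O", "N", "C", "H"]
    base = per_atom_areas(coords, elements)
    shifted = per_atom_areas(coords + np.array([10.0, -3.0, 7.0]), elements)
    np.testing.assert_allclose(shifted, base, rtol=0, atol=1e-9)

    # rotation moves atoms relative to the fixed lattice: equal only within
    # the sampling tolerance
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    rotated = per_atom_areas(coords @ q.T, elements)
    assert rotated.sum() == pytest.approx(base.sum(), rel=0.02)


def test_occlusion_monotonicity_when_adding_an_atom():
    rng = np.random.default_rng(1)
    coords = rng.uniform(-1.5, 1.5, size=(4, 3))
    elements = ["C", "N", "O", "C"]
    before = per_atom_areas(coords, elements)
    grown = np.vstack([coords, [[0.5, 0.5, 0.5]]])
    after = per_atom_areas(grown, elements + ["O"])
    assert np.all(after[:4] <= before + 1e-9)


def test_missing_radius_names_the_element():
    with pytest.raises(MissingRadiusError, match="Se"):
        per_atom_areas(np.zeros((1, 3)), ["Se"], radii=RadiusTable(radii={"C": 1.7}))


def test_surface_requires_coordinates(fixtures_by_id):
    with pytest.raises(MetaconcError, match="3D"):
        surface_areas(fixtures_by_id["glycine"])


# ------------------------------------------------------------------ embedding
def test_embedding_is_deterministic_for_fixed_seed(fixtures_by_id):
    a = embed_3d(fixtures_by_id["citrate"], seed=11)
    b = embed_3d(fixtures_by_id["citrate"], seed=11)
    np.testing.assert_array_equal(a.coords3d, b.coords3d)


def test_single_atom_embeds_at_origin():
    rec = embed_3d(MoleculeRecord.from_smiles("[Ne]", id="ne"))
    np.testing.assert_array_equal(rec.coords3d, np.zeros((1, 3)))


def test_diatomic_bond_length_is_physical():
    rec = embed_3d(MoleculeRecord.from_smiles("O=O", id="o2"), seed=5)
    d = float(np.linalg.norm(rec.coords3d[0] - rec.coords3d[1]))
    assert d == pytest.approx(1.21, rel=0.20)  # standard O=O bond length


def test_lattice_points_lie_on_unit_sphere():
    pts = fibonacci_sphere(960)
    np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)
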