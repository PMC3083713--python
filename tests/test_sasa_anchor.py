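"""Shrake-Rupley engine accuracy and anchor-residue classification."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from idpanchor.sasa_anchor import (
    RadiiTable,
    RadiusLookupError,
    classify_anchors,
    ensemble_sasa,
    fibonacci_sphere,
    residue_sasa,
    shrake_rupley_coords,
    unbound_sasa_from_complex,
)
from idpanchor.structure_io import Ensemble, select
from idpanchor.synthetic_ensembles import (
    GeneratorSpec,
    build_peptide,
    build_synthetic_complex,
    sample_ensemble,
)

PROBE = 1.4


def sphere_area(r):
    return 4.0 * np.pi * r * r


def two_sphere_exposed_area(r_a, r_b, d):
    """Analytic exposed area of sphere A: full area minus the buried cap."""
    cos_h = (d * d + r_a * r_a - r_b * r_b) / (2 * d * r_a)
    cap_height = r_a - r_a * cos_h
    return sphere_area(r_a) - 2.0 * np.pi * r_a * cap_height


def test_isolated_sphere_closed_form():
    got = shrake_rupley_coords(np.zeros((1, 3)), np.array([1.9]), PROBE, 960)[0]
    exact = sphere_area(1.9 + PROBE)
    assert abs(got - exact) / exact < 0.005


def test_disjoint_atoms_are_additive():
    coords = np.array([[0.0, 0, 0], [100.0, 0, 0]])
    got = shrake_rupley_coords(coords, np.array([1.9, 1.9]), PROBE, 960)
    single = shrake_rupley_coords(np.zeros((1, 3)), np.array([1.9]), PROBE, 960)[0]
    assert got[0] == pytest.approx(single, abs=1e-9)
    assert got.sum() == pytest.approx(2 * single, abs=1e-9)


@pytest.mark.parametrize("d", [1.5, 2.5, 4.0, 5.5])
def test_two_sphere_cap_formula(d):
    r_a, r_b = 1.87 + PROBE, 1.65 + PROBE
    coords = np.array([[0.0, 0, 0], [d, 0, 0]])
    got = shrake_rupley_coords(coords, np.array([1.87, 1.65]), PROBE, 960)[0]
    exact = two_sphere_exposed_area(r_a, r_b, d)
    assert abs(got - exact) / sphere_area(r_a) < 0.02


def test_monte_carlo_surface_oracle(rng):
    """Random 8-atom cluster: engine vs uniform random surface sampling."""
    coords = rng.normal(size=(8, 3)) * 2.0
    radii = rng.uniform(1.4, 1.9, size=8)
    got = shrake_rupley_coords(coords, radii, PROBE, 3840)
    n_mc = 20000
    for i in range(8):
        r_i = radii[i] + PROBE
        pts = rng.normal(size=(n_mc, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts = coords[i] + r_i * pts
        others = [j for j in range(8) if j != i]
        d2 = ((pts[:, None, :] - coords[others][None]) ** 2).sum(axis=2)
        exposed = np.all(d2 > ((radii[others] + PROBE) ** 2)[None, :], axis=1)
        p = exposed.mean()
        mc = sphere_area(r_i) * p
        se = sphere_area(r_i) * np.sqrt(max(p * (1 - p), 1e-6) / n_mc)
        assert abs(got[i] - mc) < 3 * se + 0.02 * sphere_area(r_i) / np.sqrt(3840)


def test_point_set_convergence(helix_peptide):
    coarse = residue_sasa(helix_peptide, n_points=960).table["sasa_total"]
    fine = residue_sasa(helix_peptide, n_points=3840).table["sasa_total"]
    rel = np.abs(coarse - fine) / fine
    assert rel.max() < 0.02


def test_adding_atoms_never_increases_sasa(rng):
    coords = rng.normal(size=(12, 3)) * 3.0
    radii = np.full(12, 1.7)
    base = shrake_rupley_coords(coords[:8], radii[:8], PROBE, 240)
    grown = shrake_rupley_coords(coords, radii, PROBE, 240)
    assert np.all(grown[:8] <= base + 1e-9)


def test_per_atom_sasa_bounds(rng):
    coords = rng.normal(size=(20, 3)) * 2.5
    radii = rng.uniform(1.4, 1.9, size=20)
    sasa = shrake_rupley_coords(coords, radii, PROBE, 240)
    assert np.all(sasa >= 0)
    assert np.all(sasa <= sphere_area(radii + PROBE) + 1e-9)


def test_fibonacci_sphere_is_unit_and_deterministic():
    a = fibonacci_sphere(960)
    np.testing.assert_allclose(np.linalg.norm(a, axis=1), 1.0, atol=1e-12)
    np.testing.assert_array_equal(a, fibonacci_sphere(960))
    assert np.abs(a.mean(axis=0)).max() < 1e-2  # well balanced


def test_engine_parameter_validation():
    with pytest.raises(ValueError):
        shrake_rupley_coords(np.zeros((1, 3)), np.ones(1), -0.1, 960)
    with pytest.raises(ValueError):
        shrake_rupley_coords(np.zeros((1, 3)), np.ones(1), PROBE, 10)
    with pytest.raises(RadiusLookupError):
        RadiiTable().radius("Xx")


def test_cross_check_against_independent_engine(helix_peptide):
    """Same coordinates and radii through biotite's Shrake-Rupley."""
    biotite_structure = pytest.importorskip("biotite.structure")
    pairs = helix_peptide.atoms(include_hydrogens=False)
    coords = np.array([a.coord for _, a in pairs])
    table = RadiiTable()
    radii = np.array([table.radius(a.element, a.name) for _, a in pairs])
    mine = shrake_rupley_coords(coords, radii, PROBE, 960)

    arr = biotite_structure.AtomArray(len(pairs))
    arr.coord = coords.astype(np.float32)
    for i, (res, at) in enumerate(pairs):
        arr.chain_id[i] = res.chain_id
        arr.res_id[i] = res.seq_id
        arr.res_name[i] = res.name
        arr.atom_name[i] = at.name
        arr.element[i] = at.element
    theirs = biotite_structure.sasa(arr, probe_radius=PROBE, point_number=960,
                                    vdw_radii=radii.astype(np.float32))
    assert abs(mine.sum() - np.nansum(theirs)) / mine.sum() < 0.02


def test_residue_sums_partition_total(helix_peptide):
    prof = residue_sasa(helix_peptide, n_points=240)
    pairs = helix_peptide.atoms(include_hydrogens=False)
    from idpanchor.sasa_anchor import shrake_rupley
    total = shrake_rupley(helix_peptide, n_points=240).sum()
    assert prof.table["sasa_total"].sum() == pytest.approx(total, abs=1e-9)
    assert np.all(prof.table["sasa_side_chain"] <= prof.table["sasa_total"] + 1e-9)


def test_tripeptide_fully_exposed():
    ggg = build_peptide("GGG", backbone="extended")
    prof = residue_sasa(ggg, n_points=240)
    assert (prof.table["sasa_total"] > 10.0).all()


def test_caged_residue_loses_its_surface(helix_peptide):
    caged = build_synthetic_complex(helix_peptide, [23])
    prof = residue_sasa(caged, selection={"chain_ids": ["A"]}, n_points=240)
    assert prof.total("A", 23) < 5.0


def test_unbound_from_complex_monotone_and_identity(cage_complex, helix_peptide):
    sel = {"chain_ids": ["A"]}
    bound = residue_sasa(cage_complex, selection=sel, n_points=240)
    unbound = unbound_sasa_from_complex(cage_complex, sel, n_points=240)
    for key in bound.residues():
        assert unbound.total(*key) >= bound.total(*key) - 1e-9
    # isolated peptide: removing "nothing" is the plain per-residue SASA
    alone = unbound_sasa_from_complex(helix_peptide, sel, n_points=240)
    plain = residue_sasa(helix_peptide, n_points=240)
    np.testing.assert_allclose(alone.table["sasa_total"], plain.table["sasa_total"],
                               atol=1e-9)


def test_pocket_residue_has_largest_delta(cage_complex):
    sel = {"chain_ids": ["A"]}
    bound = residue_sasa(cage_complex, selection=sel, n_points=240)
    unbound = unbound_sasa_from_complex(cage_complex, sel, n_points=240)
    report = classify_anchors(bound, unbound)
    top3 = {seq for _, seq in report.table.index[:3]}
    assert top3 == {19, 23, 26}


def test_ensemble_sasa_statistics(helix_peptide):
    ens = Ensemble(frames=[helix_peptide] * 3)
    prof = ensemble_sasa(ens, selection=None, n_points=240)
    assert np.allclose(prof.table["sasa_sd"], 0.0)
    single = residue_sasa(helix_peptide, n_points=240)
    np.testing.assert_allclose(prof.table["sasa_total"], single.table["sasa_total"],
                               atol=1e-9)


def test_coil_exposes_more_surface_than_helix():
    spec_h = GeneratorSpec(n_frames=4, backbone="helix", seed=11)
    spec_c = GeneratorSpec(n_frames=4, backbone="coil", seed=11)
    ens_h, _ = sample_ensemble(spec_h)
    ens_c, _ = sample_ensemble(spec_c)
    ph = ensemble_sasa(ens_h, n_points=240).table["sasa_total"]
    pc = ensemble_sasa(ens_c, n_points=240).table["sasa_total"]
    core = [("A", s) for s in range(19, 27)]
    assert (pc.loc[core].mean() > ph.loc[core].mean())


def test_anchor_threshold_rules():
    import pandas as pd
    idx = pd.MultiIndex.from_tuples([("A", 1), ("A", 2)],
                                    names=["chain_id", "seq_id"])
    from idpanchor.sasa_anchor import ResidueSASAProfile
    bound = ResidueSASAProfile(pd.DataFrame(
        {"name": ["PHE", "LEU"], "sasa_total": [0.0, 20.0],
         "sasa_side_chain": [0.0, 15.0]}, index=idx))
    unbound = ResidueSASAProfile(pd.DataFrame(
        {"name": ["PHE", "LEU"], "sasa_total": [120.0, 150.0],
         "sasa_side_chain": [100.0, 120.0]}, index=idx))
    rep = classify_anchors(bound, unbound)
    assert rep.anchor_seq_ids() == {1}  # 20 A^2 bound is never an anchor


def test_anchor_classification_rotation_invariant(helix_peptide, rng):
    import copy
    cage = build_synthetic_complex(helix_peptide, [19, 26])
    rot = Rotation.random(rng=rng)
    shift = rng.normal(size=3) * 20
    moved = copy.deepcopy(cage)
    for res in moved.residues:
        for a in res.atoms:
            a.coord = rot.apply(a.coord) + shift
    sel = {"chain_ids": ["A"]}
    for st in (cage, moved):
        rep = classify_anchors(
            residue_sasa(st, selection=sel, n_points=240),
            unbound_sasa_from_complex(st, sel, n_points=240))
        assert rep.anchor_seq_ids() == {19, 26}
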