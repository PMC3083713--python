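"""Region classification, populations, joint occupancy and transitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

from idpanchor.conformational_states import (
    BoundReference,
    RegionConfigError,
    StateRegion,
    StateRegionSet,
    UndefinedPopulationError,
    UnsupportedResidueError,
    classify_frames,
    compare_with_library,
    count_transitions,
    extract_chi_series,
    fold_symmetric_chi2,
    joint_population,
    load_rotamer_library,
    population,
)
from idpanchor.structure_io import Ensemble
from idpanchor.synthetic_ensembles import GeneratorSpec, build_peptide, sample_ensemble


def labels_for(chi1, region_set, chi2=None):
    return classify_frames(np.atleast_1d(chi1),
                           None if chi2 is None else np.atleast_1d(chi2),
                           region_set)


@pytest.fixture(scope="module")
def phe_regions():
    return StateRegionSet(("A", 19), [
        StateRegion("A", (120.0, -120.0)),
        StateRegion("B", (-120.0, 0.0)),
        StateRegion("C", (0.0, 120.0)),
    ])


def test_symmetry_folding_of_aromatic_chi2():
    assert fold_symmetric_chi2(150.0) == pytest.approx(-30.0)
    assert fold_symmetric_chi2(71.0) == pytest.approx(71.0)
    assert fold_symmetric_chi2(-95.0) == pytest.approx(85.0)
    assert fold_symmetric_chi2(90.0) == pytest.approx(-90.0)  # half-open [-90, 90)


def test_bound_angle_falls_in_trans_region(phe_regions):
    assert labels_for(177.0, phe_regions)[0] == "A"


def test_boundary_goes_to_lower_labelled_region(phe_regions):
    # half-open [lo, hi): each boundary belongs to exactly one region
    assert labels_for(120.0, phe_regions)[0] == "A"   # lower edge of A, not in C
    assert labels_for(0.0, phe_regions)[0] == "C"     # lower edge of C, not in B
    assert labels_for(-120.0, phe_regions)[0] == "B"  # lower edge of B, not in A


def test_classification_matches_brute_force_on_degree_grid(phe_regions, region_config):
    region_sets, _ = region_config
    grid = np.arange(-180.0, 180.0, 1.0)
    got = classify_frames(grid, None, phe_regions)
    for angle, lab in zip(grid, got):
        expect = "unassigned"
        for region in phe_regions.regions:  # first matching = lower label
            lo, hi = region.chi1
            if (angle - lo) % 360.0 < (hi - lo) % 360.0:
                expect = region.label
                break
        assert lab == expect
    # 2-D version for the Trp region set, on a coarse grid
    trp = region_sets[23]
    g1, g2 = np.meshgrid(np.arange(-180, 180, 7.0), np.arange(-180, 180, 7.0))
    got = classify_frames(g1.ravel(), g2.ravel(), trp)
    for a1, a2, lab in zip(g1.ravel(), g2.ravel(), got):
        expect = "unassigned"
        for region in trp.regions:
            lo, hi = region.chi1
            l2, h2 = region.chi2
            if ((a1 - lo) % 360 < (hi - lo) % 360) and ((a2 - l2) % 360 < (h2 - l2) % 360):
                expect = region.label
                break
        assert lab == expect


def test_overlapping_regions_rejected_at_load():
    with pytest.raises(RegionConfigError):
        StateRegionSet(("A", 1), [
            StateRegion("A", (0.0, 120.0)),
            StateRegion("B", (100.0, 200.0)),
        ])


def test_population_all_match_and_counting_oracle(phe_regions, rng):
    labels = np.array(["A"] * 50, dtype=object)
    est = population("A", labels=labels)
    assert est.fraction == 1.0 and est.se == 0.0
    # random labels vs direct recount
    labels = rng.choice(["A", "B", "C", "unassigned"], size=500).astype(object)
    est = population("B", labels=labels)
    assert est.fraction == np.mean(labels == "B")
    assert est.n_defined == 500


def test_population_fractions_partition_to_one(phe_regions, rng):
    chi1 = rng.uniform(-180, 180, size=1000)
    chi1[rng.choice(1000, 50, replace=False)] = np.nan  # missing frames
    labels = classify_frames(chi1, None, phe_regions)
    total = sum(population(lab, labels=labels).fraction
                for lab in [*phe_regions.labels, "unassigned"])
    assert total == pytest.approx(1.0, abs=1e-12)


def test_population_undefined_without_frames(phe_regions):
    with pytest.raises(UndefinedPopulationError):
        population("A", labels=np.array([""] * 5, dtype=object))


def test_bound_reference_population_recovers_target(rng):
    """Seeded Phe-like generator at the published helix population 0.595."""
    ref = BoundReference(("A", 19), "p53N-MDM2", 177.0, 71.0, tolerance=40.0)
    n = 2000
    target = 0.595
    hits = rng.random(n) < target
    chi1 = np.where(hits, 177 + rng.uniform(-10, 10, n), -65 + rng.uniform(-10, 10, n))
    chi2 = np.where(hits, 71 + rng.uniform(-10, 10, n), -30 + rng.uniform(-10, 10, n))
    est = population(ref, chi1=chi1, chi2=chi2)
    se = np.sqrt(target * (1 - target) / n)
    assert abs(est.fraction - target) < 3 * se
    assert est.count == int(hits.sum())


def test_joint_population_perfect_correlation():
    a = np.array(["A", "A", "B", "A"], dtype=object)
    b = np.array(["1", "1", "3", "1"], dtype=object)
    mat = joint_population(a, b)
    assert mat.loc["A", "1"] == pytest.approx(0.75)
    assert mat.loc["A", "3"] == 0.0
    assert mat.loc["A", "1"] == mat.sum(axis=1)["A"] == mat.sum(axis=0)["1"]


def test_joint_population_independence_and_frechet(rng):
    a = rng.choice(["A", "B", "C"], p=[0.5, 0.3, 0.2], size=20000).astype(object)
    b = rng.choice(["1", "2"], p=[0.6, 0.4], size=20000).astype(object)
    mat = joint_population(a, b)
    pa = mat.sum(axis=1)
    pb = mat.sum(axis=0)
    for x in pa.index:
        for y in pb.index:
            assert mat.loc[x, y] <= min(pa[x], pb[y]) + 1e-12  # Frechet bound
            assert abs(mat.loc[x, y] - pa[x] * pb[y]) < 0.015  # independence
    assert mat.to_numpy().sum() == pytest.approx(1.0, abs=1e-12)


def test_joint_marginals_recover_singles_exactly(rng):
    a = rng.choice(["A", "B", "C"], size=3000).astype(object)
    b = rng.choice(list("123456"), size=3000).astype(object)
    mat = joint_population(a, b)
    assert mat.shape == (3, 6)  # the 18-cell combination matrix
    for lab in "ABC":
        single = population(lab, labels=a)
        assert abs(mat.sum(axis=1)[lab] - single.fraction) < 1e-12
    for lab in "123456":
        single = population(lab, labels=b)
        assert abs(mat.sum(axis=0)[lab] - single.fraction) < 1e-12


def test_joint_length_mismatch():
    with pytest.raises(ValueError, match="length"):
        joint_population(np.array(["A"], dtype=object),
                         np.array(["1", "2"], dtype=object))


def test_transition_counting_basics():
    assert count_transitions(["A", "A", "B", "A", "B"], 1) == 3
    assert count_transitions(["A"] * 10, 1) == 0
    assert count_transitions([], 1) == 0


def test_transition_counting_markov_and_debounce_oracle(rng):
    for _ in range(50):
        n = rng.integers(100, 2000)
        labels = rng.choice(["x", "y"], size=n)
        raw = int(np.sum(labels[1:] != labels[:-1]))
        assert count_transitions(labels, 1) == raw
        # debounced vs independent run-length oracle
        dwell = int(rng.integers(2, 6))
        runs = []
        for l in labels:
            if runs and runs[-1][0] == l:
                runs[-1][1] += 1
            else:
                runs.append([l, 1])
        kept = [l for l, c in runs if c >= dwell]
        oracle = sum(1 for i in range(1, len(kept)) if kept[i] != kept[i - 1])
        assert count_transitions(labels, dwell) == oracle


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st_.lists(st_.sampled_from("abc"), max_size=60),
       st_.integers(1, 4))
def test_transitions_invariant_to_relabel_and_time_reversal(labels, dwell):
    relabelled = [{"a": "z", "b": "q", "c": "m"}[l] for l in labels]
    assert count_transitions(labels, dwell) == count_transitions(relabelled, dwell)
    assert count_transitions(labels, dwell) == count_transitions(labels[::-1], dwell)


def test_chi_series_from_generator_matches_script():
    spec = GeneratorSpec(n_frames=12, backbone="helix",
                         rotamer_targets={19: {"A": 0.5, "B": 0.5}}, seed=42)
    ens, gt = sample_ensemble(spec)
    chi1, chi2 = extract_chi_series(ens, "A", 19)
    want1 = gt.chi_values[19][:, 0]
    want2 = fold_symmetric_chi2(gt.chi_values[19][:, 1])
    np.testing.assert_allclose(
        np.mod(chi1 - want1 + 180, 360) - 180, 0.0, atol=1e-6)
    np.testing.assert_allclose(
        np.mod(chi2 - want2 + 180, 360) - 180, 0.0, atol=1e-6)


def test_chi_series_constant_for_identical_frames(helix_peptide):
    ens = Ensemble(frames=[helix_peptide] * 4)
    chi1, chi2 = extract_chi_series(ens, "A", 23)
    assert np.ptp(chi1) == 0.0 and np.ptp(chi2) == 0.0


def test_raw_aromatic_chi2_is_reported_folded(helix_peptide):
    import copy
    st = build_peptide(chi_assignments={19: {"chi1": 177.0, "chi2": 150.0}})
    chi1, chi2 = extract_chi_series(Ensemble(frames=[st]), "A", 19)
    assert chi2[0] == pytest.approx(-30.0, abs=1e-6)


def test_unsupported_residue_type(helix_peptide):
    ens = Ensemble(frames=[build_peptide("AGA", backbone="extended")])
    with pytest.raises(UnsupportedResidueError):
        extract_chi_series(ens, "A", 18)


def test_library_comparison_flags_phe_reversal():
    lib = load_rotamer_library()
    # helix-state populations: MDM2-bound-like dominates, Taz2-bound-like rare
    pops = {("Phe19", "p53N-MDM2"): 0.595, ("Phe19", "p53N-Taz2"): 0.122}
    rep = compare_with_library(pops, lib)
    assert rep["reversed"].all()  # library prefers the Taz2 conformation instead
    lib_mdm2 = rep.loc[rep["complex"] == "p53N-MDM2", "library_pct"].iloc[0]
    lib_taz2 = rep.loc[rep["complex"] == "p53N-Taz2", "library_pct"].iloc[0]
    assert lib_mdm2 == pytest.approx(31.71) and lib_taz2 == pytest.approx(47.08)


def test_library_comparison_identity_and_offsets():
    lib = pd.DataFrame({
        "residue": ["X", "X"], "complex": ["c1", "c2"],
        "library_pct": [40.0, 10.0], "qualifier": ["", ""],
    })
    same = compare_with_library({("X", "c1"): 0.40, ("X", "c2"): 0.10}, lib)
    assert not same["reversed"].any()
    np.testing.assert_allclose(same["ensemble_pct"] - same["library_pct"], 0.0)
    shifted = compare_with_library({("X", "c1"): 0.55, ("X", "c2"): 0.02}, lib)
    diff = (shifted["ensemble_pct"] - shifted["library_pct"]).to_numpy()
    np.testing.assert_allclose(diff, [15.0, -8.0], atol=1e-9)
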