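"""Unit and property tests for the compositional-data engine."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from onioncnd.compositions import (
    DEFAULT_KAPPA,
    NUTRIENTS,
    PARTS,
    ClrVector,
    Composition,
    CompositionError,
    ClosureViolationError,
    DegenerateStandardError,
    IncompatibleVectorsError,
    InsufficientDataError,
    clr_back_transform,
    clr_distance,
    clr_transform,
    close_composition,
    fit_standard,
    nearest_balanced_neighbors,
    nutrient_indices,
)

D = len(PARTS)


def random_composition(rng, kappa=DEFAULT_KAPPA):
    conc = rng.uniform(0.01, 40.0, size=len(NUTRIENTS))
    return close_composition(dict(zip(NUTRIENTS, conc)), kappa=kappa)


positive_parts = st.lists(
    st.floats(min_value=1e-3, max_value=60.0, allow_nan=False), min_size=11, max_size=11
)


class TestClosure:
    def test_filling_value_is_complement(self):
        comp = close_composition({p: 100.0 / 11 for p in NUTRIENTS}, kappa=1000.0)
        assert comp.fv == pytest.approx(900.0)
        assert comp.parts().sum() == pytest.approx(1000.0)

    def test_caete_centroid_filling_value(self):
        conc = dict(zip(NUTRIENTS, [30.7, 4.3, 25.7, 10.1, 3.3, 7.7,
                                    0.038, 0.034, 0.063, 0.129, 0.066]))
        comp = close_composition(conc)
        assert comp.fv == pytest.approx(917.9, abs=0.05)

    def test_zero_concentration_rejected(self):
        conc = {p: 5.0 for p in NUTRIENTS}
        conc["Zn"] = 0.0
        with pytest.raises(CompositionError, match="Zn"):
            close_composition(conc)

    def test_closure_violation_rejected(self):
        with pytest.raises(ClosureViolationError):
            close_composition({p: 100.0 for p in NUTRIENTS}, kappa=1000.0)

    def test_mapping_reordered_to_canonical_order(self):
        conc = {p: i + 1.0 for i, p in enumerate(reversed(NUTRIENTS))}
        comp = close_composition(conc)
        assert comp.labels == NUTRIENTS
        assert comp["Fe"] == pytest.approx(conc["Fe"])


class TestClrTransform:
    def test_uniform_composition_maps_to_zero(self):
        comp = close_composition({p: 1000.0 / 12 for p in NUTRIENTS})
        assert np.allclose(clr_transform(comp).values, 0.0, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(positive_parts)
    def test_clr_sums_to_zero(self, parts):
        comp = close_composition(dict(zip(NUTRIENTS, parts)))
        assert abs(clr_transform(comp).values.sum()) < 1e-9

    def test_matches_mean_pairwise_log_ratio_expansion(self):
        # clr_i = (1/D) sum_j ln(x_i/x_j), checked by explicit double loop
        rng = np.random.default_rng(42)
        for _ in range(5):
            comp = random_composition(rng)
            x = comp.parts()
            expected = np.array(
                [sum(np.log(x[i] / x[j]) for j in range(D)) / D for i in range(D)]
            )
            assert np.allclose(clr_transform(comp).values, expected, atol=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(positive_parts)
    def test_back_transform_round_trip(self, parts):
        comp = close_composition(dict(zip(NUTRIENTS, parts)))
        back = clr_back_transform(clr_transform(comp))
        assert np.allclose(back.parts(), comp.parts(), atol=1e-9)

    def test_zero_clr_vector_back_transforms_to_uniform(self):
        comp = clr_back_transform(ClrVector(PARTS, np.zeros(D)))
        assert np.allclose(comp.parts(), 1000.0 / 12)

    def test_back_transform_absorbs_constant_offset(self):
        rng = np.random.default_rng(3)
        comp = random_composition(rng)
        clr = clr_transform(comp)
        shifted = ClrVector(PARTS, clr.values + 2.5)
        assert np.allclose(
            clr_back_transform(shifted).parts(), comp.parts(), atol=1e-9
        )

    def test_non_finite_input_rejected(self):
        values = np.zeros(D)
        values[0] = np.inf
        with pytest.raises(ValueError):
            clr_back_transform(values, labels=PARTS)


class TestClrDistance:
    def test_identity_and_pythagorean_case(self):
        a = ClrVector(PARTS, np.zeros(D))
        v = np.zeros(D)
        v[0], v[1] = 1.0, -1.0
        b = ClrVector(PARTS, v)
        assert clr_distance(a, a) == 0.0
        assert clr_distance(a, b) == pytest.approx(np.sqrt(2))

    def test_matches_element_loop(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=D), rng.normal(size=D)
        a, b = ClrVector(PARTS, x), ClrVector(PARTS, y)
        expected = sum((xi - yi) ** 2 for xi, yi in zip(x, y)) ** 0.5
        assert clr_distance(a, b) == pytest.approx(expected, rel=1e-12)

    def test_label_mismatch_rejected(self):
        a = ClrVector(PARTS, np.zeros(D))
        b = ClrVector(tuple(reversed(PARTS)), np.zeros(D))
        with pytest.raises(IncompatibleVectorsError):
            clr_distance(a, b)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_metric_axioms_on_random_triples(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (ClrVector(PARTS, rng.normal(size=D)) for _ in range(3))
        dab, dba = clr_distance(a, b), clr_distance(b, a)
        assert dab >= 0
        assert dab == pytest.approx(dba, rel=1e-12)
        assert clr_distance(a, c) <= dab + clr_distance(b, c) + 1e-12


class TestFitStandard:
    def test_requires_two_specimens(self):
        clr = clr_transform(close_composition({p: 5.0 for p in NUTRIENTS}))
        with pytest.raises(InsufficientDataError):
            fit_standard([clr], "Caete")

    def test_alpha_bounds(self):
        clr = clr_transform(close_composition({p: 5.0 for p in NUTRIENTS}))
        with pytest.raises(ValueError):
            fit_standard([clr, clr], "Caete", alpha=1.5)

    def test_identical_specimens_are_degenerate(self):
        comp = close_composition({p: 5.0 for p in NUTRIENTS})
        clr = clr_transform(comp)
        with pytest.warns(UserWarning, match="zero clr variance"):
            std = fit_standard([clr] * 4, "Caete")
        assert std.degenerate
        assert np.allclose(std.clr_mean, clr.values)
        assert np.allclose(std.clr_sd, 0.0)
        assert np.allclose(std.centroid.parts(), comp.parts(), atol=1e-9)

    def test_monte_carlo_mean_recovery(self):
        # sum-zero Gaussian draws around a known centre: sample mean within
        # 3 SE per part, centroid within 1% of the back-transformed truth
        rng = np.random.default_rng(2024)
        center = np.array([2.9, 0.9, 2.7, 1.8, 0.7, 1.5, -3.8, -3.9, -3.3, -2.6, -3.2])
        center = np.append(center, -center.sum())
        n, sd = 10_000, 0.2
        draws = center + sd * rng.standard_normal((n, D))
        draws -= draws.mean(axis=1, keepdims=True)
        specimens = [ClrVector(PARTS, row) for row in draws]
        std = fit_standard(specimens, "synthetic-cultivar")
        se = std.clr_sd / np.sqrt(n)
        assert np.all(np.abs(std.clr_mean - center) <= 3 * se + 1e-12)
        truth = clr_back_transform(ClrVector(PARTS, center)).parts()
        assert np.all(np.abs(std.centroid.parts() / truth - 1) < 0.01)
        assert np.all(std.ci_low < std.clr_mean) and np.all(std.clr_mean < std.ci_high)
        assert abs(std.clr_mean.sum()) < 1e-9

    def test_standard_at_reference_midpoints_reproduces_centroid(self):
        from onioncnd.reference import CENTROIDS, reference_clr_midpoints

        mids = reference_clr_midpoints("Caete").values
        delta = np.zeros(D)
        delta[0], delta[1] = 0.01, -0.01
        specimens = [ClrVector(PARTS, mids + delta), ClrVector(PARTS, mids - delta)]
        std = fit_standard(specimens, "Caete")
        printed = np.array(CENTROIDS["Caete"])
        macro = printed >= 1.0
        assert np.all(np.abs(std.centroid.parts()[macro] - printed[macro]) < 0.1)
        assert np.all(np.abs(std.centroid.parts()[~macro] - printed[~macro]) < 0.001)


class TestNutrientIndices:
    def _standard(self, rng):
        center = rng.normal(size=D)
        center -= center.mean()
        draws = center + 0.2 * rng.standard_normal((50, D))
        draws -= draws.mean(axis=1, keepdims=True)
        return fit_standard([ClrVector(PARTS, r) for r in draws], "x")

    def test_zero_at_the_mean_and_unit_deviation(self):
        std = self._standard(np.random.default_rng(8))
        at_mean = nutrient_indices(ClrVector(PARTS, std.clr_mean.copy()), std)
        assert np.allclose(list(at_mean.values()), 0.0, atol=1e-12)
        shifted = std.clr_mean.copy()
        shifted[5] += std.clr_sd[5]
        indices = nutrient_indices(ClrVector(PARTS, shifted), std)
        assert indices[PARTS[5]] == pytest.approx(1.0)
        others = [v for p, v in indices.items() if p != PARTS[5]]
        assert np.allclose(others, 0.0, atol=1e-12)

    def test_matches_hand_loop(self):
        rng = np.random.default_rng(9)
        std = self._standard(rng)
        specimen = ClrVector(PARTS, rng.normal(size=D))
        indices = nutrient_indices(specimen, std)
        for i, part in enumerate(PARTS):
            expected = (specimen.values[i] - std.clr_mean[i]) / std.clr_sd[i]
            assert indices[part] == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_under_pre_closure_scaling(self):
        # multiplying all concentrations by c before closure leaves clr of the
        # nutrient subvector unchanged only through the filling value; with a
        # common kappa the indices must agree when fv scales too
        rng = np.random.default_rng(10)
        std = self._standard(rng)
        conc = rng.uniform(0.5, 30.0, len(NUTRIENTS))
        comp1 = close_composition(dict(zip(NUTRIENTS, conc)), kappa=1000.0)
        comp2 = close_composition(dict(zip(NUTRIENTS, 2.0 * conc)), kappa=2000.0)
        i1 = nutrient_indices(clr_transform(comp1), std)
        i2 = nutrient_indices(clr_transform(comp2), std)
        for part in PARTS:
            assert i1[part] == pytest.approx(i2[part], abs=1e-9)

    def test_degenerate_standard_rejected(self):
        comp = close_composition({p: 5.0 for p in NUTRIENTS})
        clr = clr_transform(comp)
        with pytest.warns(UserWarning):
            std = fit_standard([clr] * 3, "x")
        with pytest.raises(DegenerateStandardError):
            nutrient_indices(clr, std)


class TestNearestNeighbors:
    def test_self_is_first_with_zero_distance(self):
        rng = np.random.default_rng(11)
        bank = [ClrVector(PARTS, rng.normal(size=D)) for _ in range(10)]
        hits = nearest_balanced_neighbors(bank[3], bank, k=3)
        assert hits[0] == (3, 0.0)

    def test_k_larger_than_bank_returns_whole_bank_sorted(self):
        rng = np.random.default_rng(12)
        bank = [ClrVector(PARTS, rng.normal(size=D)) for _ in range(4)]
        query = ClrVector(PARTS, rng.normal(size=D))
        hits = nearest_balanced_neighbors(query, bank, k=10)
        assert len(hits) == 4
        assert sorted(h[1] for h in hits) == [h[1] for h in hits]

    def test_matches_exhaustive_sort(self):
        rng = np.random.default_rng(13)
        bank = [ClrVector(PARTS, rng.normal(size=D)) for _ in range(50)]
        query = ClrVector(PARTS, rng.normal(size=D))
        hits = nearest_balanced_neighbors(query, bank, k=50)
        brute = sorted(
            ((i, clr_distance(query, b)) for i, b in enumerate(bank)),
            key=lambda t: (t[1], t[0]),
        )
        assert [h[0] for h in hits] == [b[0] for b in brute]

    def test_empty_bank_rejected(self):
        query = ClrVector(PARTS, np.zeros(D))
        with pytest.raises(ValueError):
            nearest_balanced_neighbors(query, [], k=1)
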