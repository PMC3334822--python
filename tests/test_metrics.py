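import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bcmnorm import metrics
from bcmnorm.metrics import (
    coverage,
    coverage_error_map,
    dispersal,
    field_responses,
    lifetime_sparseness,
    orthogonality,
    population_sparseness,
    rank,
    sinusoid_basis,
)


class TestFieldResponses:
    def test_matched_filter(self, patchset):
        # a field equal to a patch gives the maximal response over the set
        f = patchset.data[3:4]
        resp = field_responses(f, patchset).responses[0]
        assert np.argmax(resp) == 3
        assert np.isclose(resp[3], 64.0)  # g^2 * corr(1) with g=8

    def test_orthogonal_zero(self):
        f = np.array([[1.0, 0.0, 0.0, 0.0]])
        p = np.array([[0.0, 1.0, 0.0, 0.0]])
        assert field_responses(f, p).responses[0, 0] == 0.0

    def test_linearity(self, rng):
        f = rng.standard_normal((3, 16))
        p1 = rng.standard_normal(16)
        p2 = rng.standard_normal(16)
        combo = field_responses(f, (2.0 * p1 + 3.0 * p2)[None, :]).responses
        parts = (
            2.0 * field_responses(f, p1[None, :]).responses
            + 3.0 * field_responses(f, p2[None, :]).responses
        )
        np.testing.assert_allclose(combo, parts, rtol=1e-12)

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            field_responses(np.ones((2, 9)), np.ones((3, 16)))


class TestSparseness:
    def test_constant_responses_zero(self):
        r = np.full((3, 50), 2.5)
        per, mean = lifetime_sparseness(r)
        np.testing.assert_allclose(per, 0.0, atol=1e-12)
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_closed_form(self):
        n = 40
        r = np.zeros((1, n))
        r[0, 7] = 3.0
        per, _ = lifetime_sparseness(r)
        assert per[0] == pytest.approx(1 - 1 / n)

    def test_exponential_monte_carlo(self):
        # |r| ~ Exp(1): E[r]^2/E[r^2] = 1/2 exactly, so S -> 0.5
        rng = np.random.default_rng(0)
        r = rng.exponential(1.0, size=(1, 100_000))
        _, mean = lifetime_sparseness(r)
        assert abs(mean - 0.5) < 0.01

    def test_rectification_of_signed_responses(self):
        # symmetric +/- responses have the sparseness of their magnitudes
        r = np.array([[1.0, -1.0, 1.0, -1.0]])
        per, _ = lifetime_sparseness(r)
        assert per[0] == pytest.approx(0.0, abs=1e-12)

    def test_all_zero_row_reported_missing(self):
        r = np.vstack([np.zeros(10), np.ones(10)])
        per, mean = lifetime_sparseness(r)
        assert np.isnan(per[0])
        assert mean == pytest.approx(0.0, abs=1e-12)

    def test_population_is_transpose(self, rng):
        r = rng.standard_normal((6, 20))
        pl, ml = lifetime_sparseness(r.T)
        pp, mp = population_sparseness(r)
        np.testing.assert_allclose(pl, pp)
        assert ml == mp

    def test_one_active_neuron_per_image(self):
        j = 8
        r = np.eye(j)
        _, mean = population_sparseness(r)
        assert mean == pytest.approx(1 - 1 / j)

    def test_identical_rows_population_zero(self, rng):
        row = np.abs(rng.standard_normal(30)) + 0.1
        r = np.tile(row, (5, 1))
        per, mean = population_sparseness(r)
        np.testing.assert_allclose(per, 0.0, atol=1e-12)


class TestDispersal:
    def test_equal_sigmas(self, rng):
        r = rng.standard_normal((256, 100))
        r /= r.std(axis=1, keepdims=True)
        assert dispersal(r) == pytest.approx(256.0)

    def test_single_responsive_neuron(self):
        r = np.zeros((5, 30))
        r[2] = np.random.default_rng(0).standard_normal(30)
        assert dispersal(r) == pytest.approx(1.0)

    def test_arithmetic(self):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(4000)
        r = np.vstack([a / a.std(), 0.5 * a / a.std()])
        assert dispersal(r) == pytest.approx(1.5, abs=1e-9)

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            dispersal(np.zeros((3, 10)))


class TestOrthogonality:
    def test_orthogonal_set(self):
        assert orthogonality(np.eye(5)) == pytest.approx(1.0)

    def test_identical_fields(self):
        f = np.tile(np.arange(1.0, 10.0), (4, 1))
        assert orthogonality(f) == pytest.approx(0.0)

    def test_known_cosine(self):
        f = np.array([[1.0, 0.0], [0.5, np.sqrt(3) / 2]])  # cos = 0.5
        assert orthogonality(f) == pytest.approx(0.5)

    def test_zero_field_error(self):
        with pytest.raises(ValueError):
            orthogonality(np.vstack([np.zeros(4), np.ones(4)]))

    def test_scale_invariance(self, rng):
        f = rng.standard_normal((6, 25))
        scaled = f * rng.uniform(0.5, 3.0, size=(6, 1))
        assert orthogonality(f) == pytest.approx(orthogonality(scaled))


class TestRank:
    def test_orthogonal_standardized_full_rank(self):
        g = 16
        basis, _ = sinusoid_basis(g)
        fields = basis * g  # row norm g, mimicking standardized fields
        assert rank(fields) == g * g

    def test_duplicated_prototype(self, rng):
        proto = rng.standard_normal(64) * 8
        f = np.tile(proto, (10, 1))
        assert rank(f) == 1

    def test_against_svd_oracle(self, rng):
        for _ in range(5):
            f = rng.standard_normal((20, 64)) * rng.uniform(0.2, 3)
            oracle = int(np.sum(np.linalg.svd(f, compute_uv=False) > 2.5))
            assert rank(f) == oracle

    def test_k_orthogonal_plus_copies(self, rng):
        g = 8
        basis, _ = sinusoid_basis(g)
        k = 10
        block = basis[:k] * g
        f = np.vstack([block, block[np.zeros(22, dtype=int)]])
        assert rank(f) == k


class TestSinusoidBasis:
    def test_count_and_norms(self):
        basis, freqs = sinusoid_basis(16)
        assert basis.shape == (256, 256)
        assert len(freqs) == 256
        np.testing.assert_allclose(
            np.linalg.norm(basis, axis=1), 1.0, atol=1e-12
        )

    def test_orthogonality(self):
        basis, _ = sinusoid_basis(8)
        gram = basis @ basis.T
        np.testing.assert_allclose(gram, np.eye(64), atol=1e-10)

    def test_completeness(self, rng):
        basis, _ = sinusoid_basis(8)
        img = rng.standard_normal(64)
        recon = basis.T @ (basis @ img)
        np.testing.assert_allclose(recon, img, atol=1e-10)

    def test_odd_grid_rejected(self):
        with pytest.raises(ValueError):
            sinusoid_basis(15)


class TestCoverage:
    def test_complete_basis_perfect(self):
        g = 8
        basis, _ = sinusoid_basis(g)
        fields = basis * g
        r, m = coverage(fields)
        assert r == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(m, 0.0, atol=1e-9)

    def test_half_basis(self):
        g = 8
        basis, _ = sinusoid_basis(g)
        fields = basis[: g * g // 2] * g
        r, m = coverage(fields)
        assert r == pytest.approx(0.5, abs=1e-9)
        assert np.isclose(m[: g * g // 2], 0.0, atol=1e-9).all()
        assert np.isclose(m[g * g // 2 :], 1.0, atol=1e-9).all()

    def test_rank_zero_fields(self):
        f = np.full((4, 64), 1e-6)
        f[:, 0] = -63e-6  # zero mean, tiny norm, all sv below tolerance
        r, m = coverage(f)
        assert r == pytest.approx(0.0, abs=1e-9)

    def test_against_least_squares_oracle(self, rng):
        # R == 1 - mean squared projection residual from dense lstsq on the
        # singular subspace above tolerance (independent of the pinv path)
        g = 8
        f = rng.standard_normal((20, g * g)) * 3
        r, m = coverage(f)
        u, sv, vt = np.linalg.svd(f, full_matrices=False)
        span = vt[sv > 2.5].T  # basis of decodable subspace
        basis, _ = sinusoid_basis(g)
        resid = []
        for x in basis:
            coef, *_ = np.linalg.lstsq(span, x, rcond=None)
            resid.append(np.sum((x - span @ coef) ** 2))
        np.testing.assert_allclose(m, resid, atol=1e-8)
        assert r == pytest.approx(1 - np.mean(resid), abs=1e-8)

    def test_error_map_layout(self):
        g = 8
        basis, _ = sinusoid_basis(g)
        _, m = coverage(basis[:1] * g)
        emap = coverage_error_map(m, g)
        assert emap.shape == (g, g)
        assert np.nanmax(emap) <= 1.0 + 1e-9

    def test_monotonicity(self, rng):
        g = 8
        f = rng.standard_normal((10, g * g)) * 3
        extra = rng.standard_normal((1, g * g)) * 3
        r1, _ = coverage(f)
        r2, _ = coverage(np.vstack([f, extra]))
        assert r2 >= r1 - 1e-12
        assert rank(np.vstack([f, extra])) >= rank(f)


class TestCodingReport:
    def test_orthonormal_fixture(self, patchset):
        g = 8
        basis, _ = sinusoid_basis(g)
        fields = basis * g
        rep = metrics.coding_report(fields, patchset)
        assert rep.coverage == pytest.approx(1.0, abs=1e-9)
        assert rep.orthogonality == pytest.approx(1.0, abs=1e-9)
        assert rep.rank == g * g

    def test_invariants_on_random_fields(self, rng, patchset):
        f = rng.standard_normal((12, 64))
        f = (f - f.mean(axis=1, keepdims=True)) / f.std(axis=1, keepdims=True)
        f *= 8
        rep = metrics.coding_report(f, patchset)
        assert 0.0 <= rep.lifetime_sparseness <= 1.0
        assert 0.0 <= rep.population_sparseness <= 1.0
        assert rep.coverage <= 1.0
        assert 1.0 <= rep.dispersal_raw <= 12.0
        assert 0 <= rep.rank <= 12
        assert rep.dispersal == pytest.approx(rep.dispersal_raw / 12)

    def test_json_roundtrip(self, rng, patchset, tmp_path):
        import json

        f = rng.standard_normal((5, 64)) * 8
        rep = metrics.coding_report(f, patchset)
        rep.to_json(tmp_path / "r.json")
        back = json.loads((tmp_path / "r.json").read_text())
        assert back["rank"] == rep.rank
        assert "Orthogonality" in rep.table()


@given(st.integers(0, 2**32 - 1))
@settings(max_examples=10, deadline=None)
def test_sparseness_bounds_property(seed):
    rng = np.random.default_rng(seed)
    r = rng.standard_normal((5, 40))
    per, mean = lifetime_sparseness(r)
    assert np.all((per >= -1e-12) & (per <= 1.0))
    assert -1e-12 <= mean <= 1.0
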