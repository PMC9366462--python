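import numpy as np
import pytest

import nonrev as nv
from nonrev.substitution_model import (DegenerateModelError,
                                       _expm_taylor_scaling_squaring,
                                       read_paml_dat, read_rate_matrix,
                                       write_rate_matrix)

from helpers import pearson_oracle


def two_state(a, b):
    """Generic 2-state chain [[-a, a], [b, -b]] (operations are state-count
    agnostic, which makes closed forms testable)."""
    return nv.normalize(np.array([[0.0, a], [b, 0.0]]))


class TestNormalize:
    def test_scale_invariance(self, jc20):
        doubled = nv.normalize(2.0 * jc20.rates)
        np.testing.assert_allclose(doubled.rates, jc20.rates, atol=1e-12)

    def test_jukes_cantor_off_diagonals(self):
        raw = np.ones((20, 20))
        model = nv.normalize(raw)
        off = model.rates[~np.eye(20, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 19.0, atol=1e-12)

    def test_unit_mean_rate(self, nq_strong):
        assert abs(nq_strong.mean_rate - 1.0) < 1e-10

    def test_all_zero_matrix_rejected(self):
        with pytest.raises(DegenerateModelError):
            nv.normalize(np.zeros((20, 20)))

    @pytest.mark.parametrize("seed", range(40))
    def test_random_matrix_invariants(self, seed):
        m = nv.random_nonreversible_matrix(seed, asymmetry=1.0)
        assert np.abs(m.rates.sum(axis=1)).max() < 1e-10
        assert np.abs(m.frequencies @ m.rates).max() < 1e-8
        assert abs(m.mean_rate - 1.0) < 1e-10
        assert m.frequencies.min() >= 0
        assert abs(m.frequencies.sum() - 1.0) < 1e-12


class TestStationaryDistribution:
    def test_symmetric_gives_uniform(self):
        raw = np.ones((20, 20))
        np.fill_diagonal(raw, 0)
        np.fill_diagonal(raw, -raw.sum(axis=1))
        pi = nv.stationary_distribution(raw)
        np.testing.assert_allclose(pi, 0.05, atol=1e-12)

    @pytest.mark.parametrize("a,b", [(1.0, 2.0), (0.3, 0.7), (5.0, 0.1)])
    def test_two_state_closed_form(self, a, b):
        q = np.array([[-a, a], [b, -b]])
        pi = nv.stationary_distribution(q)
        np.testing.assert_allclose(pi, [b / (a + b), a / (a + b)], atol=1e-12)

    def test_matches_power_iteration(self):
        m = nv.random_nonreversible_matrix(11, asymmetry=1.5)
        p = m.transition(0.1).probs
        for _ in range(12):  # P(0.1 * 2^12) by repeated squaring
            p = p @ p
        np.testing.assert_allclose(m.frequencies, p[0], atol=1e-7)

    def test_reducible_matrix_rejected(self):
        q = np.zeros((4, 4))
        q[0, 1] = q[1, 0] = 1.0
        q[2, 3] = q[3, 2] = 1.0  # two closed classes
        np.fill_diagonal(q, -q.sum(axis=1))
        with pytest.raises(DegenerateModelError):
            nv.stationary_distribution(q)


class TestTransitionProbabilities:
    def test_zero_time_is_identity(self, nq_strong):
        np.testing.assert_array_equal(nv.transition_probabilities(
            nq_strong, 0.0).probs, np.eye(20))

    def test_negative_time_rejected(self, nq_strong):
        with pytest.raises(ValueError):
            nv.transition_probabilities(nq_strong, -0.1)

    def test_ergodic_limit(self, nq_strong):
        p = nv.transition_probabilities(nq_strong, 1000.0).probs
        np.testing.assert_allclose(p, np.tile(nq_strong.frequencies, (20, 1)),
                                   atol=1e-6)

    def test_two_state_closed_form(self):
        a, b, t = 1.0, 2.0, 0.5
        model = nv.normalize(np.array([[0.0, a], [b, 0.0]]))
        mu = (2 * a * b) / (a + b)  # normalization factor of the 2-state chain
        p = model.transition(t).probs
        expected = b / (a + b) + (a / (a + b)) * np.exp(-(a + b) * t / mu)
        assert abs(p[0, 0] - expected) < 1e-12

    @pytest.mark.parametrize("seed", range(10))
    def test_chapman_kolmogorov(self, seed):
        rng = np.random.default_rng(seed)
        m = nv.random_nonreversible_matrix(seed, asymmetry=1.0)
        s, t = rng.uniform(0, 5, size=2)
        lhs = m.transition(s).probs @ m.transition(t).probs
        rhs = m.transition(s + t).probs
        np.testing.assert_allclose(lhs, rhs, atol=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_stationarity_invariance(self, seed):
        m = nv.random_nonreversible_matrix(seed, asymmetry=1.0)
        for t in (0.01, 0.5, 3.0):
            pi = m.frequencies
            np.testing.assert_allclose(pi @ m.transition(t).probs, pi,
                                       atol=1e-8)

    @pytest.mark.parametrize("t", [0.01, 0.3, 1.0, 4.0])
    def test_eigen_agrees_with_scaling_squaring(self, nq_strong, t):
        eig_path = nv.transition_probabilities(nq_strong, t).probs
        taylor = _expm_taylor_scaling_squaring(nq_strong.rates * t)
        np.testing.assert_allclose(eig_path, taylor, atol=1e-6)


class TestBuildReversible:
    def test_lg_detailed_balance(self, lg):
        flux = lg.frequencies[:, None] * lg.rates
        assert np.abs(flux - flux.T).max() < 1e-12

    def test_asymmetric_input_rejected(self):
        r = np.ones((20, 20))
        r[0, 1] = 2.0
        with pytest.raises(ValueError):
            nv.build_reversible(r, np.full(20, 0.05))

    def test_uniform_gives_jukes_cantor(self, jc20):
        off = jc20.rates[~np.eye(20, dtype=bool)]
        np.testing.assert_allclose(off, 1.0 / 19.0, atol=1e-12)


class TestFreeParameterCount:
    def test_counts(self, lg, nq_strong):
        assert nv.free_parameter_count(nq_strong) == 379
        assert nv.free_parameter_count(lg) == 208
        assert nv.free_parameter_count(lg, count_frequencies=False) == 189


class TestMatrixCorrelation:
    def test_self_correlation(self, lg):
        assert nv.matrix_correlation(lg, lg) == pytest.approx(1.0)

    def test_scale_invariance(self, nq_strong):
        scaled = nv.normalize(1.0000001 * nq_strong.rates)
        assert nv.matrix_correlation(nq_strong, scaled) == pytest.approx(
            1.0, abs=1e-12)

    def test_matches_pearson_oracle(self):
        a = nv.random_nonreversible_matrix(1)
        b = nv.random_nonreversible_matrix(2)
        expected = pearson_oracle(a.off_diagonal(), b.off_diagonal())
        assert nv.matrix_correlation(a, b) == pytest.approx(expected, abs=1e-12)
        assert nv.matrix_correlation(b, a) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self, jc20):
        with pytest.raises(ValueError):
            nv.matrix_correlation(jc20, jc20)


class TestMatrixIO:
    def test_builtin_models_load(self):
        for name in ("LG", "WAG", "JTT"):
            m = nv.load_builtin(name)
            assert m.is_reversible and m.name == name
            assert abs(m.mean_rate - 1.0) < 1e-10

    def test_nonreversible_roundtrip(self, tmp_path, nq_strong):
        path = tmp_path / "m.nq"
        write_rate_matrix(nq_strong, path)
        back = read_rate_matrix(path)
        np.testing.assert_allclose(back.rates, nq_strong.rates, atol=1e-9)
        np.testing.assert_allclose(back.frequencies, nq_strong.frequencies,
                                   atol=1e-9)

    def test_frequency_disagreement_warns(self, tmp_path, nq_strong):
        path = tmp_path / "m.nq"
        lines = [" ".join(f"{v:.10g}" for v in row) for row in nq_strong.rates]
        lines.append(" ".join(["0.05"] * 20))
        path.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning):
            read_rate_matrix(path)

    def test_dat_ignores_trailing_comments(self, tmp_path, lg):
        import importlib.resources
        ref = importlib.resources.files("nonrev") / "matrices" / "LG.dat"
        text = ref.read_text() + "\nsome literature reference, ignored\n"
        p = tmp_path / "LG2.dat"
        p.write_text(text)
        m = read_paml_dat(p)
        np.testing.assert_allclose(m.rates, lg.rates, atol=1e-12)
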