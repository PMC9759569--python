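"""Surrogate-community construction and the CPE_env x CPE_int split."""

import numpy as np
import pytest

from commstab import (
    CommunityMatrix, DegenerateDataError, InputError, SecondaryDecomposition,
    decompose, rescale_to_reference, secondary_decompose,
    surrogate_stability_from_monocultures, surrogate_stability_from_plots,
)
from conftest import orthogonal_community


def _copy_as(X, plot_id):
    return CommunityMatrix(values=X.values.copy(), species=list(X.species),
                           times=list(X.times), plot_id=plot_id, site_id=X.site_id)


class TestRescale:
    def test_target_moments_exact_and_order_preserved(self):
        out = rescale_to_reference(np.array([0.0, 2.0]), 10.0, 1.0)
        assert out.mean() == pytest.approx(10.0, abs=1e-12)
        assert out.std(ddof=1) == pytest.approx(1.0, rel=1e-12)
        assert out[0] < out[1]

    def test_identity_when_already_at_reference(self, rng):
        z = rng.normal(5, 2, 20)
        out = rescale_to_reference(z, z.mean(), z.std(ddof=1))
        np.testing.assert_allclose(out, z, rtol=1e-12)

    def test_zero_reference_sd_gives_constant(self):
        out = rescale_to_reference(np.array([1.0, 4.0, 2.0]), 3.0, 0.0)
        np.testing.assert_array_equal(out, 3.0)

    def test_constant_donor_errors(self):
        with pytest.raises(DegenerateDataError, match="constant donor"):
            rescale_to_reference(np.ones(5), 0.0, 1.0)

    def test_rescaling_is_idempotent_under_affine_donor_change(self, rng):
        z = rng.normal(0, 1, 15)
        a = rescale_to_reference(z, 7.0, 2.0)
        b = rescale_to_reference(5.0 - 3.0 * z, 7.0, 2.0)
        # an affine donor transform changes at most the sign of the pattern
        assert (np.allclose(a, b, rtol=1e-10)
                or np.allclose(a + b, 2 * 7.0, rtol=1e-10))


class TestDonorPlots:
    def test_self_donor_reproduces_the_focal_covariance(self, toy_community, rng):
        donor = _copy_as(toy_community, "other")
        s_sur, sc = surrogate_stability_from_plots(toy_community, [donor], rng)
        c = decompose(toy_community)
        m_cov = np.cov(toy_community.values, rowvar=False, ddof=1)
        np.testing.assert_allclose(sc.C, m_cov, atol=1e-12)
        assert s_sur == pytest.approx(c.s_com, rel=1e-10)
        assert sc.donor_map == {"a": "other", "b": "other"}

    def test_orthogonal_donor_hits_independence_limit(self, rng):
        focal = orthogonal_community(2, start_col=1)
        donor = orthogonal_community(2, start_col=3, plot_id="donor")
        s_sur, sc = surrogate_stability_from_plots(focal, [donor], rng)
        # off-diagonals exactly zero -> S_com_sur = S_com_ip
        off = sc.C[~np.eye(2, dtype=bool)]
        np.testing.assert_allclose(off, 0.0, atol=1e-10)
        mu_tot = focal.values.mean(axis=0).sum()
        s_ip = mu_tot / np.sqrt(np.diag(sc.C).sum())
        assert s_sur == pytest.approx(s_ip, rel=1e-10)

    def test_diagonal_is_focal_variances_exactly(self, rng):
        focal = orthogonal_community(3, scale=[1.0, 2.0, 3.0])
        donor = orthogonal_community(3, start_col=4, plot_id="donor")
        _, sc = surrogate_stability_from_plots(focal, [donor], rng)
        np.testing.assert_array_equal(
            np.diag(sc.C), np.var(focal.values, axis=0, ddof=1))

    def test_species_without_donor_falls_back_to_independence(self, toy_community, rng):
        donor = CommunityMatrix(values=toy_community.values[:, :1].copy(),
                                species=["a"], times=list(toy_community.times),
                                plot_id="partial", site_id=toy_community.site_id)
        s_sur, sc = surrogate_stability_from_plots(toy_community, [donor], rng)
        assert sc.donor_map["b"] == "none"
        assert sc.C[0, 1] == 0.0

    def test_no_donors_is_an_input_error(self, toy_community, rng):
        with pytest.raises(InputError):
            surrogate_stability_from_plots(toy_community, [], rng)


class TestMonocultures:
    def test_self_monocultures_reproduce_s_com(self, toy_community, rng):
        monos = {sp: [toy_community.series(sp)] for sp in toy_community.species}
        s_sur = surrogate_stability_from_monocultures(toy_community, monos, rng)
        assert s_sur == pytest.approx(decompose(toy_community).s_com, rel=1e-10)

    def test_orthogonal_monocultures_hit_independence_limit(self, rng):
        focal = orthogonal_community(2, start_col=1)
        other = orthogonal_community(2, start_col=3)
        monos = {"s0": [other.values[:, 0]], "s1": [other.values[:, 1]]}
        s_sur = surrogate_stability_from_monocultures(focal, monos, rng)
        m = np.var(focal.values, axis=0, ddof=1)
        s_ip = focal.values.mean(axis=0).sum() / np.sqrt(m.sum())
        assert s_sur == pytest.approx(s_ip, rel=1e-10)

    def test_missing_monoculture_errors(self, toy_community, rng):
        with pytest.raises(InputError, match="no monoculture"):
            surrogate_stability_from_monocultures(
                toy_community, {"a": [toy_community.series("a")]}, rng)

    def test_affine_donor_invariance(self, toy_community, rng):
        monos1 = {sp: [toy_community.series(sp)] for sp in toy_community.species}
        monos2 = {sp: [2.5 * toy_community.series(sp) + 11.0]
                  for sp in toy_community.species}
        s1 = surrogate_stability_from_monocultures(
            toy_community, monos1, np.random.default_rng(0))
        s2 = surrogate_stability_from_monocultures(
            toy_community, monos2, np.random.default_rng(0))
        assert s2 == pytest.approx(s1, rel=1e-12)


class TestSecondaryDecomposition:
    def test_single_repeat_product_identity_donor(self, rng):
        focal = orthogonal_community(3, scale=[1.0, 2.0, 1.5])
        donor = orthogonal_community(3, start_col=4, plot_id="d1")
        comp = secondary_decompose(focal, method="donor_plot", donors=[donor],
                                   n_repeats=1, random_state=0)
        assert comp.cpe_env * comp.cpe_int == pytest.approx(comp.cpe, rel=1e-10)

    def test_single_repeat_product_identity_monoculture(self, toy_community):
        monos = {sp: [toy_community.series(sp)[::-1].copy()]
                 for sp in toy_community.species}
        comp = secondary_decompose(toy_community, method="monoculture",
                                   monocultures=monos, n_repeats=1, random_state=0)
        assert comp.cpe_env * comp.cpe_int == pytest.approx(comp.cpe, rel=1e-10)

    def test_self_donor_gives_unit_interaction_effect(self, toy_community):
        donor = _copy_as(toy_community, "other")
        comp = secondary_decompose(toy_community, method="donor_plot",
                                   donors=[donor], n_repeats=1, random_state=0)
        assert comp.cpe_int == pytest.approx(1.0, rel=1e-10)
        assert comp.cpe_env == pytest.approx(comp.cpe, rel=1e-10)

    def test_geometric_average_preserves_product_across_repeats(self, toy_community, rng):
        monos = {sp: [toy_community.series(sp)[::-1].copy(),
                      rng.normal(5, 2, toy_community.n_times)]
                 for sp in toy_community.species}
        comp = secondary_decompose(toy_community, method="monoculture",
                                   monocultures=monos, n_repeats=50,
                                   average="geometric", random_state=3)
        assert comp.cpe_env * comp.cpe_int == pytest.approx(comp.cpe, rel=1e-10)

    def test_default_repeats_by_method(self):
        assert SecondaryDecomposition(method="monoculture").n_repeats is None
        est = SecondaryDecomposition(method="bogus")
        with pytest.raises(InputError):
            est.fit(np.ones((3, 2)))

    def test_seed_reproducibility(self, toy_community, rng):
        monos = {sp: [toy_community.series(sp)[::-1].copy(),
                      rng.normal(5, 2, toy_community.n_times)]
                 for sp in toy_community.species}
        c1 = secondary_decompose(toy_community, method="monoculture",
                                 monocultures=monos, n_repeats=20, random_state=42)
        c2 = secondary_decompose(toy_community, method="monoculture",
                                 monocultures=monos, n_repeats=20, random_state=42)
        assert c1.cpe_env == c2.cpe_env and c1.cpe_int == c2.cpe_int
        assert c1.seed == 42
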