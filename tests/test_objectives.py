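"""Objective values against brute-force enumeration oracles, gradients
against central finite differences, and the degenerate-family reductions."""

import itertools

import numpy as np
import pytest

from clmdca import (
    PottsParameters,
    SubsetFamily,
    add_l2_penalty,
    composite_loglik,
    exact_loglik,
    pairwise_composite_loglik,
    pseudo_loglik,
    sequence_energy,
)
from clmdca.objectives import CapacityError
from tests.conftest import fd_gradient_max_rel_error, random_msa, random_params


def enumerate_joint(params):
    """Brute-force joint distribution over all q**L configurations."""
    configs = np.array(
        list(itertools.product(range(params.q), repeat=params.length))
    )
    en = np.array([sequence_energy(params, c) for c in configs])
    p = np.exp(en - en.max())
    return configs, p / p.sum()


def brute_conditional(configs, joint, fixed_cols, fixed_vals, target_cols, target_vals):
    """P(X_target = target_vals | X_fixed = fixed_vals) by summation."""
    mask = np.ones(len(configs), dtype=bool)
    for c, v in zip(fixed_cols, fixed_vals):
        mask &= configs[:, c] == v
    num = mask.copy()
    for c, v in zip(target_cols, target_vals):
        num &= configs[:, c] == v
    return joint[num].sum() / joint[mask].sum()


class TestTrivialValues:
    def test_exact_uniform_model(self, rng):
        p = PottsParameters.zeros(3, 2)
        msa = random_msa(rng, 5, 3, 2)
        assert exact_loglik(p, msa).value == pytest.approx(-3 * np.log(2), abs=1e-12)

    def test_pseudo_uniform_model(self, rng):
        p = PottsParameters.zeros(4, 3)
        msa = random_msa(rng, 5, 4, 3)
        assert pseudo_loglik(p, msa).value == pytest.approx(-4 * np.log(3), abs=1e-12)

    def test_pairwise_uniform_model(self, rng):
        length, q = 4, 3
        p = PottsParameters.zeros(length, q)
        msa = random_msa(rng, 5, length, q)
        expected = -(length * (length - 1) / 2) * 2 * np.log(q)
        assert pairwise_composite_loglik(p, msa).value == pytest.approx(
            expected, abs=1e-12
        )


class TestAgainstEnumeration:
    def test_pseudo_matches_brute_conditionals(self, rng):
        length, q, m = 3, 2, 6
        p = random_params(rng, length, q)
        msa = random_msa(rng, m, length, q)
        configs, joint = enumerate_joint(p)
        expected = 0.0
        for row in msa:
            for i in range(length):
                others = [k for k in range(length) if k != i]
                expected += np.log(
                    brute_conditional(configs, joint, others, row[others], [i], [row[i]])
                )
        expected /= m
        assert pseudo_loglik(p, msa).value == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("engine", ["numpy", "compiled"])
    def test_pairwise_matches_brute_conditionals(self, rng, engine):
        length, q, m = 3, 2, 6
        p = random_params(rng, length, q)
        msa = random_msa(rng, m, length, q)
        configs, joint = enumerate_joint(p)
        expected = 0.0
        for row in msa:
            for i in range(length):
                for j in range(i + 1, length):
                    rest = [k for k in range(length) if k not in (i, j)]
                    expected += np.log(
                        brute_conditional(
                            configs, joint, rest, row[rest], [i, j], row[[i, j]]
                        )
                    )
        expected /= m
        got = pairwise_composite_loglik(p, msa, engine=engine).value
        assert got == pytest.approx(expected, abs=1e-12)

    def test_exact_matches_direct_joint(self, rng):
        length, q, m = 4, 3, 5
        p = random_params(rng, length, q)
        msa = random_msa(rng, m, length, q)
        configs, joint = enumerate_joint(p)
        expected = np.mean(
            [
                np.log(joint[(configs == row).all(axis=1)].sum())
                for row in msa
            ]
        )
        assert exact_loglik(p, msa).value == pytest.approx(expected, abs=1e-12)

    def test_exact_equals_pairwise_at_l2(self, rng):
        # at L = 2 the single pair conditional is the full joint
        p = random_params(rng, 2, 4)
        msa = random_msa(rng, 8, 2, 4)
        assert pairwise_composite_loglik(p, msa).value == pytest.approx(
            exact_loglik(p, msa).value, abs=1e-12
        )

    def test_capacity_cap_enforced(self, rng):
        p = random_params(rng, 30, 21)
        msa = random_msa(rng, 3, 30, 21)
        with pytest.raises(CapacityError):
            exact_loglik(p, msa)


class TestReductions:
    @pytest.mark.parametrize("seed", range(5))
    def test_family_degenerations(self, seed):
        rng = np.random.default_rng(seed)
        length, q = int(rng.integers(3, 6)), int(rng.integers(2, 4))
        p = random_params(rng, length, q)
        msa = random_msa(rng, 7, length, q)
        w = rng.random(7) + 0.05
        single = composite_loglik(p, msa, w, family=SubsetFamily.singletons(length))
        assert single.value == pytest.approx(pseudo_loglik(p, msa, w).value, abs=1e-12)
        pairsf = composite_loglik(p, msa, w, family=SubsetFamily.all_pairs(length))
        assert pairsf.value == pytest.approx(
            pairwise_composite_loglik(p, msa, w).value, abs=1e-12
        )
        full = composite_loglik(p, msa, w, family=SubsetFamily.full(length))
        assert full.value == pytest.approx(exact_loglik(p, msa, w).value, abs=1e-12)

    def test_three_order_family_runs(self, rng):
        p = random_params(rng, 4, 2)
        msa = random_msa(rng, 5, 4, 2)
        fam = SubsetFamily(list(itertools.combinations(range(4), 3)))
        assert fam.order == 3
        v = composite_loglik(p, msa, family=fam)
        assert np.isfinite(v.value)

    def test_engines_agree(self, rng):
        p = random_params(rng, 6, 3)
        msa = random_msa(rng, 11, 6, 3)
        w = rng.random(11) + 0.1
        a = pairwise_composite_loglik(p, msa, w, engine="numpy")
        b = pairwise_composite_loglik(p, msa, w, engine="compiled")
        assert a.value == pytest.approx(b.value, abs=1e-10)
        np.testing.assert_allclose(
            a.gradient.to_vector(), b.gradient.to_vector(), atol=1e-10
        )


class TestGradients:
    @pytest.mark.parametrize(
        "maker",
        [
            pytest.param(lambda p, msa, w: pseudo_loglik(p, msa, w), id="pseudo"),
            pytest.param(
                lambda p, msa, w: pairwise_composite_loglik(p, msa, w), id="pairwise"
            ),
            pytest.param(lambda p, msa, w: exact_loglik(p, msa, w), id="exact"),
            pytest.param(
                lambda p, msa, w: composite_loglik(
                    p, msa, w, family=SubsetFamily([(0, 1, 2), (1, 2, 3)])
                ),
                id="three-order",
            ),
        ],
    )
    def test_finite_differences(self, rng, maker):
        length, q, m = 4, 3, 6
        p = random_params(rng, length, q)
        msa = random_msa(rng, m, length, q)
        w = rng.random(m) + 0.1
        err = fd_gradient_max_rel_error(lambda pp: maker(pp, msa, w), p, 20, rng)
        assert err < 1e-4


class TestWeightsAndInvariance:
    def test_row_permutation_invariance(self, rng):
        p = random_params(rng, 4, 3)
        msa = random_msa(rng, 9, 4, 3)
        w = rng.random(9) + 0.1
        perm = rng.permutation(9)
        for fn in (pseudo_loglik, pairwise_composite_loglik, exact_loglik):
            assert fn(p, msa, w).value == pytest.approx(
                fn(p, msa[perm], w[perm]).value, abs=1e-12
            )

    def test_reproducible(self, rng):
        p = random_params(rng, 4, 3)
        msa = random_msa(rng, 9, 4, 3)
        assert (
            pairwise_composite_loglik(p, msa).value
            == pairwise_composite_loglik(p, msa).value
        )


class TestL2Penalty:
    def test_zero_strength_is_identity(self, rng):
        p = random_params(rng, 3, 2)
        msa = random_msa(rng, 4, 3, 2)
        obj = pseudo_loglik(p, msa)
        pen = add_l2_penalty(obj, p, 0.0, 0.0)
        assert pen.value == obj.value
        np.testing.assert_array_equal(
            pen.gradient.to_vector(), obj.gradient.to_vector()
        )

    def test_hand_computed_penalty(self, rng):
        p = PottsParameters.zeros(3, 2)
        p.h[1, 0] = 2.0
        msa = random_msa(rng, 4, 3, 2)
        obj = pseudo_loglik(p, msa)
        pen = add_l2_penalty(obj, p, lambda_h=0.5, lambda_e=0.0)
        assert obj.value - pen.value == pytest.approx(2.0, abs=1e-12)

    def test_negative_strength_errors(self, rng):
        p = random_params(rng, 3, 2)
        obj = pseudo_loglik(p, random_msa(rng, 4, 3, 2))
        with pytest.raises(ValueError):
            add_l2_penalty(obj, p, lambda_h=-0.1)
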