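import dataclasses

import numpy as np
import pytest
from scipy.stats import multivariate_normal

from mixdoc import (
    ClassLabel,
    MeanStructure,
    MixingProportions,
    ModelParameters,
    ModelSpec,
    NonPositiveDefiniteError,
    PosteriorMatrix,
    ScenarioConfig,
    TwinDataset,
    Variant,
    Zygosity,
    collapse_to_directions,
    implied_covariance,
    implied_means,
    mixture_loglik,
    posterior_probabilities,
    relative_entropy,
    simulate,
)
from tests.conftest import DEFAULT_PATHS

MIX4 = ModelSpec(variant=Variant.MIX4)


def default_theta(delta=1.0, weights=None):
    labels = ClassLabel.causal_classes()
    if weights is None:
        mixing = MixingProportions.equal(labels)
    else:
        mixing = MixingProportions(labels=labels, mz=weights, dz=weights)
    return ModelParameters(
        paths=DEFAULT_PATHS,
        means=MeanStructure(0.0, 0.0, delta, delta),
        mixing=mixing,
    )


def brute_force_loglik(data: TwinDataset, theta, spec) -> float:
    """Independent oracle: direct per-pair, per-class density sum (no
    log-sum-exp, scipy densities)."""
    total = 0.0
    for _, row in data.frame.iterrows():
        zyg = Zygosity(row["zygosity"])
        y = np.array([row["x1"], row["y1"], row["x2"], row["y2"]])
        w = theta.weights(spec, zyg)
        dens = 0.0
        for j, label in enumerate(spec.active_classes):
            mu = implied_means(theta.means, label)
            sigma = implied_covariance(theta.paths, label, zyg)
            dens += w[j] * multivariate_normal(mean=mu, cov=sigma).pdf(y)
        total += np.log(dens)
    return total


@pytest.fixture(scope="module")
def ten_pairs():
    return simulate(ScenarioConfig(n_mz=5, n_dz=5, seed=99))


class TestMixtureLoglik:
    def test_matches_brute_force_oracle(self, ten_pairs):
        theta = default_theta(delta=0.5)
        ours = mixture_loglik(ten_pairs, theta, MIX4)
        oracle = brute_force_loglik(ten_pairs, theta, MIX4)
        assert ours == pytest.approx(oracle, rel=1e-10)

    def test_single_class_collapses_to_plain_gaussian(self, ten_pairs):
        spec = ModelSpec(variant=Variant.DOC_XY)
        theta = ModelParameters(paths=DEFAULT_PATHS,
                                means=MeanStructure(0.1, 0.2, 0.1, 0.2))
        ours = mixture_loglik(ten_pairs, theta, spec)
        direct = 0.0
        for zyg in Zygosity:
            Y = ten_pairs.matrix(zyg)
            mu = implied_means(theta.means, ClassLabel.XY_XY)
            sigma = implied_covariance(theta.paths, ClassLabel.XY_XY, zyg)
            direct += multivariate_normal(mean=mu, cov=sigma).logpdf(Y).sum()
        assert ours == pytest.approx(direct, rel=1e-12)

    def test_duplicating_pairs_doubles_loglik(self, ten_pairs):
        theta = default_theta()
        import pandas as pd

        doubled = TwinDataset.from_frame(
            pd.concat([ten_pairs.frame, ten_pairs.frame], ignore_index=True)
        )
        assert mixture_loglik(doubled, theta, MIX4) == pytest.approx(
            2.0 * mixture_loglik(ten_pairs, theta, MIX4), rel=1e-12
        )

    def test_invariant_to_pair_order(self, ten_pairs):
        theta = default_theta()
        shuffled = TwinDataset.from_frame(
            ten_pairs.frame.sample(frac=1.0, random_state=5)
        )
        assert mixture_loglik(shuffled, theta, MIX4) == pytest.approx(
            mixture_loglik(ten_pairs, theta, MIX4), rel=1e-12
        )

    def test_non_positive_definite_class_is_identified(self, ten_pairs):
        degenerate = dataclasses.replace(DEFAULT_PATHS, a_x=0.0, c_x=0.0, e_x=0.0)
        theta = dataclasses.replace(default_theta(), paths=degenerate)
        with pytest.raises(NonPositiveDefiniteError) as err:
            mixture_loglik(ten_pairs, theta, MIX4)
        assert err.value.label in ClassLabel
        assert err.value.zyg in Zygosity


class TestPosteriors:
    def test_degenerate_prior_forces_posterior_column(self, ten_pairs):
        theta = default_theta(weights=(1.0, 0.0, 0.0, 0.0))
        post = posterior_probabilities(ten_pairs, theta, MIX4)
        np.testing.assert_allclose(post.probabilities[:, 0], 1.0)

    def test_identical_components_give_uniform_posteriors(self, ten_pairs):
        # no causation and no mean offsets: the two classes are identical
        spec = ModelSpec(variant=Variant.MIX2)
        theta = ModelParameters(
            paths=dataclasses.replace(DEFAULT_PATHS, b_yx=0.0, b_xy=0.0),
            means=MeanStructure(0.0, 0.0, 0.0, 0.0),
            mixing=MixingProportions.equal(spec.active_classes),
        )
        post = posterior_probabilities(ten_pairs, theta, spec)
        np.testing.assert_allclose(post.probabilities, 0.5, atol=1e-12)

    def test_matches_bayes_rule_brute_force(self, ten_pairs):
        theta = default_theta(delta=0.8)
        post = posterior_probabilities(ten_pairs, theta, MIX4)
        for i, (_, row) in enumerate(ten_pairs.frame.iterrows()):
            zyg = Zygosity(row["zygosity"])
            y = np.array([row["x1"], row["y1"], row["x2"], row["y2"]])
            w = theta.weights(MIX4, zyg)
            dens = np.array([
                w[j] * multivariate_normal(
                    mean=implied_means(theta.means, lbl),
                    cov=implied_covariance(theta.paths, lbl, zyg),
                ).pdf(y)
                for j, lbl in enumerate(MIX4.active_classes)
            ])
            np.testing.assert_allclose(post.probabilities[i], dens / dens.sum(),
                                       rtol=1e-9)

    def test_rows_are_probability_vectors(self, ten_pairs):
        post = posterior_probabilities(ten_pairs, default_theta(), MIX4)
        np.testing.assert_allclose(post.probabilities.sum(axis=1), 1.0,
                                   atol=1e-12)


class TestRelativeEntropy:
    def test_indicator_rows_give_one(self):
        P = np.eye(4)[np.random.default_rng(0).integers(0, 4, size=50)]
        post = PosteriorMatrix(probabilities=P, labels=("a", "b", "c", "d"))
        assert relative_entropy(post) == pytest.approx(1.0)

    def test_uniform_rows_give_zero(self):
        post = PosteriorMatrix(probabilities=np.full((30, 4), 0.25),
                               labels=("a", "b", "c", "d"))
        assert relative_entropy(post) == pytest.approx(0.0, abs=1e-12)

    def test_single_class_is_undefined(self):
        post = PosteriorMatrix(probabilities=np.ones((5, 1)), labels=("a",))
        with pytest.raises(ValueError, match="single class"):
            relative_entropy(post)

    def test_invariant_to_row_and_column_permutations(self):
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(4), size=40)
        post = PosteriorMatrix(probabilities=P, labels=("a", "b", "c", "d"))
        ent = relative_entropy(post)
        P2 = P[rng.permutation(40)][:, [2, 0, 3, 1]]
        post2 = PosteriorMatrix(probabilities=P2, labels=("c", "a", "d", "b"))
        assert relative_entropy(post2) == pytest.approx(ent, rel=1e-12)

    def test_collapse_to_directions(self):
        labels = tuple(l.value for l in ClassLabel.causal_classes())
        P = np.array([[1.0, 0.0, 0.0, 0.0],  # both twins XY
                      [0.0, 0.0, 0.0, 1.0],  # both twins YX
                      [0.0, 1.0, 0.0, 0.0]])  # twin1 XY, twin2 YX
        post = collapse_to_directions(
            PosteriorMatrix(probabilities=P, labels=labels)
        )
        assert post.probabilities.shape == (6, 2)
        np.testing.assert_allclose(post.probabilities.sum(axis=1), 1.0)
        np.testing.assert_allclose(
            post.probabilities[:, 0], [1, 0, 1, 1, 0, 0]
        )
        assert relative_entropy(post) == pytest.approx(1.0)
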