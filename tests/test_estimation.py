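import dataclasses
import warnings

import numpy as np
import pytest

from mixdoc import (
    ClassLabel,
    ConfoundMode,
    MeanStructure,
    MixingProportions,
    ModelParameters,
    ModelSpec,
    NotNestedError,
    ScenarioConfig,
    TwinDataset,
    Variant,
    count_free_parameters,
    embed_parameters,
    fit,
    fit_statistics,
    likelihood_ratio_test,
    mixture_loglik,
    simulate,
)
from mixdoc.estimation import (
    DegenerateMixtureWarning,
    _check_degeneracy,
    _MomentKernel,
    _pack_structural,
    _unpack_structural,
)
from mixdoc.likelihood import class_moments
from mixdoc.model import Zygosity
from tests.conftest import DEFAULT_PATHS, concordant_xy_config


class TestParameterAccounting:
    @pytest.mark.parametrize(
        "variant, confound, k",
        [
            (Variant.MIX4, ConfoundMode.NONE, 16),
            (Variant.MIX2, ConfoundMode.NONE, 14),
            (Variant.DOC_XY, ConfoundMode.NONE, 9),
            (Variant.DOC_YX, ConfoundMode.NONE, 9),
            (Variant.DOC_BIDIR, ConfoundMode.NONE, 10),
            (Variant.CORRELATED_FACTORS, ConfoundMode.NONE, 11),
            (Variant.MIX4, ConfoundMode.RA_EQUATED, 17),
            (Variant.MIX4, ConfoundMode.RA_BY_CLASS, 20),
            (Variant.MIX2, ConfoundMode.RA_BY_CLASS, 16),
            (Variant.DOC_XY, ConfoundMode.RA_EQUATED, 10),
        ],
    )
    def test_free_parameter_counts(self, variant, confound, k):
        spec = ModelSpec(variant=variant, confound_mode=confound)
        assert count_free_parameters(spec) == k

    def test_invalid_spec_combinations_raise(self):
        with pytest.raises(ValueError):
            ModelSpec(variant=Variant.CORRELATED_FACTORS,
                      confound_mode=ConfoundMode.RA_EQUATED)
        with pytest.raises(ValueError):
            ModelSpec(variant=Variant.DOC_XY,
                      confound_mode=ConfoundMode.RA_BY_CLASS)

    def test_mix4_without_discordant_equality_frees_one_more_weight_per_group(self):
        tied = count_free_parameters(ModelSpec(variant=Variant.MIX4))
        free = count_free_parameters(
            ModelSpec(variant=Variant.MIX4, discordant_equality=False)
        )
        assert free - tied == 2


class TestMomentKernelConsistency:
    """The vectorised optimisation kernel must agree with the scalar
    path-diagram route (two independent implementations of the moments)."""

    @pytest.mark.parametrize("variant, confound", [
        (Variant.MIX4, ConfoundMode.NONE),
        (Variant.MIX4, ConfoundMode.RA_EQUATED),
        (Variant.MIX4, ConfoundMode.RA_BY_CLASS),
        (Variant.MIX2, ConfoundMode.NONE),
        (Variant.DOC_BIDIR, ConfoundMode.NONE),
        (Variant.CORRELATED_FACTORS, ConfoundMode.NONE),
    ])
    def test_kernel_matches_path_diagram_moments(self, variant, confound):
        spec = ModelSpec(variant=variant, confound_mode=confound)
        theta = ModelParameters(
            paths=dataclasses.replace(DEFAULT_PATHS, b_yx=0.4, b_xy=0.25,
                                      r_A=0.3, r_C=-0.1, r_E=0.15),
            means=MeanStructure(0.1, -0.2, 0.9, 1.1),
            r_A_by_class=(0.1, 0.2, 0.25, 0.3)[:spec.n_classes]
            if confound is ConfoundMode.RA_BY_CLASS else None,
        )
        x = _pack_structural(theta, spec)
        mus_k, sig_k = _MomentKernel(spec).moments(x[None, :])
        # scalar route on the same effective (spec-constrained) parameters
        theta_eff = _unpack_structural(x, spec)
        ref = class_moments(theta_eff, spec)
        for zi, zyg in enumerate(Zygosity):
            mus_r, sig_r = ref[zyg]
            np.testing.assert_allclose(mus_k[0], mus_r, atol=1e-10)
            np.testing.assert_allclose(sig_k[0, zi], sig_r, atol=1e-10)


class TestFitStatistics:
    @pytest.mark.parametrize("minus2ll, k, aic", [
        (144_293.4, 16, 144_325.4),
        (148_372.6, 14, 148_400.6),
        (44_300.56, 9, 44_318.56),
        (45_933.44, 10, 45_953.44),
        (100.0, 0, 100.0),
    ])
    def test_aic_identity(self, minus2ll, k, aic):
        assert minus2ll + 2 * k == pytest.approx(aic, abs=1e-9)

    def test_fit_statistics_from_fit(self, separated_mix4_fit):
        st = fit_statistics(separated_mix4_fit, separated_mix4_fit.n_pairs)
        assert st["df"] == 4 * separated_mix4_fit.n_pairs - 16
        assert st["aic"] == pytest.approx(st["minus2LL"] + 32)


class TestFit:
    def test_truth_start_never_worsens_objective(self, separated_dataset):
        spec = ModelSpec(variant=Variant.MIX4)
        truth = ModelParameters(
            paths=DEFAULT_PATHS,
            means=MeanStructure(0.0, 0.0, 1.5, 1.5),
            mixing=MixingProportions.equal(ClassLabel.causal_classes()),
        )
        truth_m2ll = -2.0 * mixture_loglik(separated_dataset, truth, spec)
        res = fit(separated_dataset, spec, n_starts=1, seed=0,
                  extra_starts=(truth,))
        assert res.minus2LL <= truth_m2ll + 1e-6

    def test_row_permutation_reproduces_minus2ll(self, separated_dataset):
        spec = ModelSpec(variant=Variant.DOC_XY)
        base = fit(separated_dataset, spec, n_starts=1, seed=0)
        shuffled = TwinDataset.from_frame(
            separated_dataset.frame.sample(frac=1.0, random_state=11)
        )
        perm = fit(shuffled, spec, n_starts=1, seed=0)
        assert perm.minus2LL == pytest.approx(base.minus2LL, abs=1e-6)

    def test_aic_ordering_is_location_invariant(self, separated_dataset):
        shifted_frame = separated_dataset.frame.copy()
        for col in ("x1", "y1", "x2", "y2"):
            shifted_frame[col] += 10.0
        shifted = TwinDataset.from_frame(shifted_frame)
        gaps = []
        for data in (separated_dataset, shifted):
            f1 = fit(data, ModelSpec(variant=Variant.DOC_XY), n_starts=1, seed=0)
            f2 = fit(data, ModelSpec(variant=Variant.CORRELATED_FACTORS),
                     n_starts=1, seed=0)
            gaps.append(f1.aic - f2.aic)
        assert gaps[0] == pytest.approx(gaps[1], abs=1e-2)

    def test_unidirectional_recovery_at_large_n(self):
        data = simulate(concordant_xy_config(n_mz=10_000, n_dz=10_000, seed=77))
        res = fit(data, ModelSpec(variant=Variant.DOC_XY), n_starts=2, seed=1,
                  compute_se=True)
        assert res.converged
        se = res.se["b_yx"]
        assert 0 < se < 0.1
        assert abs(res.params.paths.b_yx - 0.5) < 3 * se
        # variance paths recovered up to sign normalisation
        assert res.params.paths.a_x == pytest.approx(np.sqrt(0.5), abs=0.05)

    def test_requires_both_zygosities(self):
        data = simulate(ScenarioConfig(n_mz=20, n_dz=20, seed=1))
        mz_only = TwinDataset.from_frame(
            data.frame[data.frame["zygosity"] == "MZ"]
        )
        with pytest.raises(ValueError, match="pairs per zygosity"):
            fit(mz_only, ModelSpec(variant=Variant.DOC_XY))

    def test_degenerate_concordant_classes_warn(self):
        theta = ModelParameters(
            paths=dataclasses.replace(DEFAULT_PATHS, b_yx=0.0, b_xy=0.0),
            means=MeanStructure(0.0, 0.0, 0.0, 0.0),
            mixing=MixingProportions.equal(ClassLabel.causal_classes()),
        )
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            _check_degeneracy(theta, ModelSpec(variant=Variant.MIX4))
        assert any(issubclass(w.category, DegenerateMixtureWarning)
                   for w in caught)


@pytest.fixture(scope="module")
def homogeneous_fits():
    data = simulate(concordant_xy_config(n_mz=1000, n_dz=1000, seed=5))
    out = {}
    for variant in (Variant.DOC_XY, Variant.DOC_BIDIR,
                    Variant.CORRELATED_FACTORS):
        out[variant] = fit(data, ModelSpec(variant=variant),
                           n_starts=2, seed=2)
    return out


class TestLikelihoodRatioTest:
    def test_self_comparison_is_null(self, homogeneous_fits):
        f = homogeneous_fits[Variant.DOC_XY]
        res = likelihood_ratio_test(f, f)
        assert res.statistic == 0.0
        assert res.delta_df == 0
        assert res.p_value == 1.0

    def test_nested_statistic_nonnegative(self, homogeneous_fits):
        res = likelihood_ratio_test(homogeneous_fits[Variant.DOC_XY],
                                    homogeneous_fits[Variant.DOC_BIDIR])
        assert res.statistic >= 0.0
        assert res.delta_df == 1
        assert not res.caveat

    def test_non_nested_pair_raises(self, homogeneous_fits):
        with pytest.raises(NotNestedError, match="AIC"):
            likelihood_ratio_test(homogeneous_fits[Variant.DOC_BIDIR],
                                  homogeneous_fits[Variant.CORRELATED_FACTORS])

    def test_mixture_comparison_sets_caveat(self, separated_dataset):
        f2 = fit(separated_dataset, ModelSpec(variant=Variant.MIX2),
                 n_starts=1, seed=0)
        f4 = fit(separated_dataset, ModelSpec(variant=Variant.MIX4),
                 n_starts=1, seed=0)
        res = likelihood_ratio_test(f2, f4)
        assert res.caveat

    def test_null_distribution_against_chi2_oracle(self):
        # under doc_xy truth, 2 * (ll_cf - ll_docxy) ~ chi-square(2)
        stats = []
        for rep in range(30):
            data = simulate(concordant_xy_config(n_mz=400, n_dz=400,
                                                 seed=1000 + rep))
            f_x = fit(data, ModelSpec(variant=Variant.DOC_XY), n_starts=1, seed=rep)
            f_cf = fit(data, ModelSpec(variant=Variant.CORRELATED_FACTORS),
                       n_starts=1, seed=rep,
                       extra_starts=(embed_parameters(
                           f_x.params, f_x.spec,
                           ModelSpec(variant=Variant.CORRELATED_FACTORS)),))
            stats.append(likelihood_ratio_test(f_x, f_cf).statistic)
        stats = np.asarray(stats)
        assert np.all(stats >= -1e-6)
        # chi2(2): mean 2, sd 2 -> 3 Monte-Carlo SEs of the mean
        assert abs(stats.mean() - 2.0) < 3 * 2.0 / np.sqrt(len(stats))


def test_embed_parameters_transfers_between_variants():
    theta = ModelParameters(paths=DEFAULT_PATHS,
                            means=MeanStructure(0.0, 0.0, 1.0, 1.0))
    target = ModelSpec(variant=Variant.CORRELATED_FACTORS)
    emb = embed_parameters(theta, ModelSpec(variant=Variant.DOC_XY), target)
    assert emb.paths.b_yx == 0.0 and emb.paths.b_xy == 0.0
    mix_target = ModelSpec(variant=Variant.MIX4)
    emb2 = embed_parameters(theta, ModelSpec(variant=Variant.DOC_XY), mix_target)
    assert emb2.mixing is not None
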