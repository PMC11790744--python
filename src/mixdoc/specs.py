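"""Model variants and their free-parameter accounting.

Six variants are fitted and compared:

``mix4``
    the 4-class-per-zygosity mixture: twin pairs concordant X->Y, the two
    discordant configurations, and concordant Y->X, with mixing proportions
    estimated separately for MZ and DZ pairs.
``mix2``
    the concordant-pairs-only reduced mixture (two classes).
``doc_xy`` / ``doc_yx``
    single-class unidirectional direction-of-causation models.
``doc_bidir``
    single-class model with both causal paths free.
``correlated_factors``
    the standard bivariate ACE model: no causal paths, all trait covariance
    carried by the factor correlations ``r_A, r_C, r_E``.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass

from .model import ClassLabel


class Variant(str, enum.Enum):
    MIX4 = "mix4"
    MIX2 = "mix2"
    DOC_XY = "doc_xy"
    DOC_YX = "doc_yx"
    DOC_BIDIR = "doc_bidir"
    CORRELATED_FACTORS = "correlated_factors"


class ConfoundMode(str, enum.Enum):
    NONE = "none"                  #: r_A = r_C = r_E = 0
    RA_EQUATED = "rA_equated"      #: r_A free, shared across classes
    RA_BY_CLASS = "rA_by_class"    #: one r_A per mixture class

MIXTURE_VARIANTS = (Variant.MIX4, Variant.MIX2)


@dataclass(frozen=True)
class ModelSpec:
    """A fittable model: variant, confounding mode, discordant-weight tie."""

    variant: Variant
    confound_mode: ConfoundMode = ConfoundMode.NONE
    discordant_equality: bool = True

    def __post_init__(self) -> None:
        variant = Variant(self.variant)
        mode = ConfoundMode(self.confound_mode)
        object.__setattr__(self, "variant", variant)
        object.__setattr__(self, "confound_mode", mode)
        if variant is Variant.CORRELATED_FACTORS and mode is not ConfoundMode.NONE:
            raise ValueError(
                "correlated_factors frees r_A, r_C, r_E intrinsically; "
                "confound_mode must be 'none'"
            )
        if mode is ConfoundMode.RA_BY_CLASS and variant not in MIXTURE_VARIANTS:
            raise ValueError("rA_by_class applies only to mixture variants")

    @property
    def is_mixture(self) -> bool:
        return self.variant in MIXTURE_VARIANTS

    @property
    def active_classes(self) -> tuple[ClassLabel, ...]:
        if self.variant is Variant.MIX4:
            return ClassLabel.causal_classes()
        if self.variant is Variant.MIX2:
            return (ClassLabel.XY_XY, ClassLabel.YX_YX)
        if self.variant is Variant.DOC_XY:
            return (ClassLabel.XY_XY,)
        if self.variant is Variant.DOC_YX:
            return (ClassLabel.YX_YX,)
        if self.variant is Variant.DOC_BIDIR:
            return (ClassLabel.BI_BI,)
        # correlated_factors: single class with both causal paths fixed at zero,
        # so the nominal label is irrelevant to the implied moments.
        return (ClassLabel.XY_XY,)

    @property
    def n_classes(self) -> int:
        return len(self.active_classes)

    @property
    def free_causal_paths(self) -> tuple[str, ...]:
        return {
            Variant.MIX4: ("b_yx", "b_xy"),
            Variant.MIX2: ("b_yx", "b_xy"),
            Variant.DOC_XY: ("b_yx",),
            Variant.DOC_YX: ("b_xy",),
            Variant.DOC_BIDIR: ("b_yx", "b_xy"),
            Variant.CORRELATED_FACTORS: (),
        }[self.variant]

    @property
    def free_confound_params(self) -> tuple[str, ...]:
        if self.variant is Variant.CORRELATED_FACTORS:
            return ("r_A", "r_C", "r_E")
        if self.confound_mode is ConfoundMode.NONE:
            return ()
        if self.confound_mode is ConfoundMode.RA_EQUATED:
            return ("r_A",)
        return tuple(f"r_A[{lbl.value}]" for lbl in self.active_classes)

    @property
    def free_mean_params(self) -> tuple[str, ...]:
        if self.is_mixture:
            return ("mu_x_XY", "mu_y_XY", "mu_x_YX", "mu_y_YX")
        return ("mu_x", "mu_y")

    @property
    def free_weight_params(self) -> tuple[str, ...]:
        """Names of the free mixing-weight coordinates (softmax scale)."""
        if not self.is_mixture:
            return ()
        if self.variant is Variant.MIX2:
            per_zyg = 1
        elif self.discordant_equality:
            per_zyg = 2  # (concordant XY, pooled discordant, concordant YX)
        else:
            per_zyg = 3
        return tuple(
            f"w_{zyg}_{i}" for zyg in ("MZ", "DZ") for i in range(per_zyg)
        )


def parameter_names(spec: ModelSpec) -> tuple[str, ...]:
    """Ordered names of all free parameters of a model spec."""
    return (
        ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y")
        + spec.free_causal_paths
        + spec.free_confound_params
        + spec.free_mean_params
        + spec.free_weight_params
    )


def count_free_parameters(spec: ModelSpec) -> int:
    """Number of free parameters k; df = 4 * n_pairs - k."""
    return len(parameter_names(spec))
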