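"""Structural layer of the bivariate direction-of-causation (DoC) twin model.

A twin pair contributes a 4-vector of observations ordered ``(x1, y1, x2, y2)``:
trait X and trait Y for twin 1, then for twin 2.  Each trait is driven by latent
additive-genetic (A), shared-environment (C) and unique-environment (E) factors
with path coefficients ``a, c, e`` on the standard-deviation scale, and the two
traits may be linked by a direct causal regression in either direction
(``b_yx``: X causes Y; ``b_xy``: Y causes X) and/or by correlations between the
latent factors of the two traits (``r_A, r_C, r_E``).

Cross-twin sharing of the latent factors is what identifies the model: A is
fully shared for monozygotic pairs and half shared for dizygotic pairs, C is
fully shared for both, E is unshared.  The model-implied covariance is

    Sigma = (I - B)^-1 Psi (I - B)^-T

where ``B`` holds the causal regressions between the observed phenotypes
(block-diagonal over twins; no cross-twin causal paths) and ``Psi`` is the
pre-causal (residual) covariance of the 4-vector.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

#: Fixed ordering of the observed variables in every matrix, vector and file.
OBS_ORDER: tuple[str, ...] = ("x1", "y1", "x2", "y2")

LOG_2PI = np.log(2.0 * np.pi)


class NonRecursiveModelError(ValueError):
    """Raised when (I - B) is singular, i.e. a bidirectional causal loop with
    ``b_yx * b_xy`` at or beyond 1 leaves the system without a reduced form."""


class Direction(enum.Enum):
    """Causal direction governing one individual."""

    XY = "XY"  #: X causes Y
    YX = "YX"  #: Y causes X
    BI = "BI"  #: both directions active (data-generating robustness class only)


class ClassLabel(enum.Enum):
    """Causal configuration of a twin pair: twin 1's direction, twin 2's direction.

    The four unidirectional configurations are the estimable mixture classes;
    ``BI_BI`` exists only as a data-generating class for robustness studies and
    is never part of a fitted mixture.
    """

    XY_XY = "XY_XY"
    XY_YX = "XY_YX"
    YX_XY = "YX_XY"
    YX_YX = "YX_YX"
    BI_BI = "BI_BI"

    @property
    def twin1(self) -> Direction:
        return Direction[self.value.split("_")[0]]

    @property
    def twin2(self) -> Direction:
        return Direction[self.value.split("_")[1]]

    @property
    def is_discordant(self) -> bool:
        return self in (ClassLabel.XY_YX, ClassLabel.YX_XY)

    @property
    def is_concordant(self) -> bool:
        return self in (ClassLabel.XY_XY, ClassLabel.YX_YX)

    @classmethod
    def causal_classes(cls) -> tuple["ClassLabel", ...]:
        """The four estimable classes, in canonical order."""
        return (cls.XY_XY, cls.XY_YX, cls.YX_XY, cls.YX_YX)


class Zygosity(enum.Enum):
    """Twin-pair zygosity; ``alpha`` is the cross-twin additive-genetic sharing."""

    MZ = "MZ"
    DZ = "DZ"

    @property
    def alpha(self) -> float:
        return 1.0 if self is Zygosity.MZ else 0.5


@dataclass(frozen=True)
class PathParameters:
    """Structural path coefficients of the bivariate DoC twin model.

    ``a_*, c_*, e_*`` are standard-deviation-scale loadings of the A, C, E
    factors on each trait, *before* causal transmission.  ``b_yx``/``b_xy`` are
    the phenotype-level causal regressions.  ``r_A, r_C, r_E`` are correlations
    between the trait-X and trait-Y latent factors; they model non-causal
    (confounding) sources of trait covariance.  Only three of
    ``{b_yx, b_xy, r_A, r_C, r_E}`` can be simultaneously free in an
    identified model.
    """

    a_x: float = 0.0
    c_x: float = 0.0
    e_x: float = 1.0
    a_y: float = 0.0
    c_y: float = 0.0
    e_y: float = 1.0
    b_yx: float = 0.0
    b_xy: float = 0.0
    r_A: float = 0.0
    r_C: float = 0.0
    r_E: float = 0.0

    def validate(self) -> None:
        if not (self.e_x != 0.0 and self.e_y != 0.0):
            raise ValueError("e_x and e_y must be nonzero for a positive-definite model")
        for name in ("r_A", "r_C", "r_E"):
            r = getattr(self, name)
            if abs(r) > 1.0:
                raise ValueError(f"{name}={r} outside [-1, 1]")

    def normalized_signs(self) -> "PathParameters":
        """Equivalent parameter set with nonnegative A/C/E paths.

        Each loading is sign-indeterminate; flipping a loading of trait X and
        simultaneously flipping the corresponding factor correlation (times the
        sign of the trait-Y loading) leaves the likelihood unchanged.
        """
        s = {n: (1.0 if getattr(self, n) >= 0 else -1.0)
             for n in ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y")}
        return replace(
            self,
            a_x=abs(self.a_x), c_x=abs(self.c_x), e_x=abs(self.e_x),
            a_y=abs(self.a_y), c_y=abs(self.c_y), e_y=abs(self.e_y),
            r_A=self.r_A * s["a_x"] * s["a_y"],
            r_C=self.r_C * s["c_x"] * s["c_y"],
            r_E=self.r_E * s["e_x"] * s["e_y"],
        )


@dataclass(frozen=True)
class MeanStructure:
    """Phenotypic means per causal direction.

    Means are equated across twin order and zygosity within a direction, and a
    twin in a discordant pair takes the means of the matching concordant
    direction, so the mixture has at most four free means in total.
    """

    mu_x_XY: float = 0.0
    mu_y_XY: float = 0.0
    mu_x_YX: float = 0.0
    mu_y_YX: float = 0.0

    def for_direction(self, d: Direction) -> tuple[float, float]:
        # The bidirectional generating class sits at the X->Y baseline means.
        if d is Direction.YX:
            return (self.mu_x_YX, self.mu_y_YX)
        return (self.mu_x_XY, self.mu_y_XY)


def build_causal_matrix(label: ClassLabel, params: PathParameters) -> np.ndarray:
    """4x4 regression matrix B over ``(x1, y1, x2, y2)`` for one class.

    Within each twin's 2x2 block, an X->Y individual has ``b_yx`` in the (y, x)
    cell and a Y->X individual has ``b_xy`` in the (x, y) cell; the
    bidirectional generating class has both.  All cross-twin cells are zero.
    """
    B = np.zeros((4, 4))
    for offset, d in ((0, label.twin1), (2, label.twin2)):
        if d in (Direction.XY, Direction.BI):
            B[offset + 1, offset] = params.b_yx
        if d in (Direction.YX, Direction.BI):
            B[offset, offset + 1] = params.b_xy
    return B


def precausal_covariance(
    params: PathParameters, zyg: Zygosity, r_A: float | None = None
) -> np.ndarray:
    """Pre-causal covariance Psi of ``(x1, y1, x2, y2)``.

    ``r_A`` may be overridden per class for the class-specific genetic
    confounding variant.
    """
    rA = params.r_A if r_A is None else r_A
    alpha = zyg.alpha
    ax, cx, ex = params.a_x, params.c_x, params.e_x
    ay, cy, ey = params.a_y, params.c_y, params.e_y
    vx = ax * ax + cx * cx + ex * ex
    vy = ay * ay + cy * cy + ey * ey
    within = rA * ax * ay + params.r_C * cx * cy + params.r_E * ex * ey
    cross_x = alpha * ax * ax + cx * cx
    cross_y = alpha * ay * ay + cy * cy
    cross_xt = alpha * rA * ax * ay + params.r_C * cx * cy
    return np.array(
        [
            [vx, within, cross_x, cross_xt],
            [within, vy, cross_xt, cross_y],
            [cross_x, cross_xt, vx, within],
            [cross_xt, cross_y, within, vy],
        ]
    )


def implied_covariance(
    params: PathParameters,
    label: ClassLabel,
    zyg: Zygosity,
    r_A: float | None = None,
) -> np.ndarray:
    """Model-implied 4x4 covariance: ``(I - B)^-1 Psi (I - B)^-T``."""
    B = build_causal_matrix(label, params)
    ImB = np.eye(4) - B
    det = np.linalg.det(ImB)
    if abs(det) < 1e-12:
        raise NonRecursiveModelError(
            f"singular (I - B) for class {label.value}: bidirectional loop with "
            f"b_yx*b_xy = {params.b_yx * params.b_xy:.6g} has no reduced form"
        )
    M = np.linalg.inv(ImB)
    sigma = M @ precausal_covariance(params, zyg, r_A=r_A) @ M.T
    return 0.5 * (sigma + sigma.T)


def implied_means(mean_struct: MeanStructure, label: ClassLabel) -> np.ndarray:
    """Model-implied mean 4-vector for one class.

    Twin i takes the phenotypic means of its own causal direction, so the two
    discordant classes borrow their member means from the concordant classes.
    """
    m1 = mean_struct.for_direction(label.twin1)
    m2 = mean_struct.for_direction(label.twin2)
    return np.array([m1[0], m1[1], m2[0], m2[1]])
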