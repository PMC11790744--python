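"""Finite-mixture likelihood, posterior classification and entropy.

The observed-data density of a twin pair ``y`` in zygosity group ``z`` is

    f(y) = sum_j  omega_jz * phi(y; mu_j, Sigma_jz)

where the sum runs over the active causal classes, ``omega_jz`` are the
zygosity-specific mixing proportions and ``phi`` is the 4-variate normal
density with the class's model-implied moments.  Classification quality is
summarised by the relative entropy index

    Ent = 1 - (1 / (N ln C)) * sum_i sum_j ( -p_ij ln p_ij )

which is 1 when every posterior row is degenerate (perfect assignment) and 0
when every row is uniform (no information).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .data import TwinDataset
from .model import (
    LOG_2PI,
    ClassLabel,
    MeanStructure,
    PathParameters,
    Zygosity,
    implied_covariance,
    implied_means,
)
from .specs import ConfoundMode, ModelSpec

#: probabilities below this are treated as exact zeros in entropy sums
_ENTROPY_FLOOR = 1e-300


class NonPositiveDefiniteError(ValueError):
    """Implied covariance of a specific (class, zygosity) cell is not PD."""

    def __init__(self, label: ClassLabel, zyg: Zygosity):
        self.label = label
        self.zyg = zyg
        super().__init__(
            f"implied covariance not positive definite for class "
            f"{label.value}, zygosity {zyg.value}"
        )


@dataclass(frozen=True)
class MixingProportions:
    """Per-zygosity mixture weights over the active classes."""

    labels: tuple[ClassLabel, ...]
    mz: tuple[float, ...]
    dz: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, w in (("mz", self.mz), ("dz", self.dz)):
            w = np.asarray(w, dtype=float)
            if len(w) != len(self.labels):
                raise ValueError(f"{name} weights do not match class labels")
            if np.any(w < -1e-12) or np.any(w > 1 + 1e-12):
                raise ValueError(f"{name} weights outside [0, 1]: {w}")
            if abs(w.sum() - 1.0) > 1e-8:
                raise ValueError(f"{name} weights sum to {w.sum()}, not 1")

    @classmethod
    def equal(cls, labels: tuple[ClassLabel, ...]) -> "MixingProportions":
        w = tuple([1.0 / len(labels)] * len(labels))
        return cls(labels=tuple(labels), mz=w, dz=w)

    def for_zygosity(self, zyg: Zygosity) -> np.ndarray:
        return np.asarray(self.mz if zyg is Zygosity.MZ else self.dz, dtype=float)

    def discordant_weights_equal(self, tol: float = 1e-10) -> bool:
        idx = [i for i, lbl in enumerate(self.labels) if lbl.is_discordant]
        if len(idx) != 2:
            return True
        return (abs(self.mz[idx[0]] - self.mz[idx[1]]) <= tol
                and abs(self.dz[idx[0]] - self.dz[idx[1]]) <= tol)


@dataclass(frozen=True)
class ModelParameters:
    """Full parameter set of one model: structure, means and weights.

    ``r_A_by_class`` (aligned with the spec's active classes) is only used by
    the class-specific genetic-confounding variant.
    """

    paths: PathParameters
    means: MeanStructure
    mixing: MixingProportions | None = None
    r_A_by_class: tuple[float, ...] | None = None

    def weights(self, spec: ModelSpec, zyg: Zygosity) -> np.ndarray:
        if spec.n_classes == 1 or self.mixing is None:
            return np.ones(spec.n_classes) / spec.n_classes
        return self.mixing.for_zygosity(zyg)


@dataclass(frozen=True)
class PosteriorMatrix:
    """Posterior class-membership probabilities, one row per sampling unit."""

    probabilities: np.ndarray  # (N, C)
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        p = self.probabilities
        if p.ndim != 2 or p.shape[1] != len(self.labels):
            raise ValueError("posterior matrix shape does not match labels")
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValueError("posterior probabilities outside [0, 1]")
        rows = p.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise ValueError("posterior rows do not sum to 1")

    @property
    def n_classes(self) -> int:
        return len(self.labels)


def class_moments(
    theta: ModelParameters, spec: ModelSpec
) -> dict[Zygosity, tuple[np.ndarray, np.ndarray]]:
    """Implied means (C, 4) and covariances (C, 4, 4) per zygosity."""
    labels = spec.active_classes
    out: dict[Zygosity, tuple[np.ndarray, np.ndarray]] = {}
    for zyg in Zygosity:
        mus = np.empty((len(labels), 4))
        sigmas = np.empty((len(labels), 4, 4))
        for j, lbl in enumerate(labels):
            rA = None
            if (spec.confound_mode is ConfoundMode.RA_BY_CLASS
                    and theta.r_A_by_class is not None):
                rA = theta.r_A_by_class[j]
            mus[j] = implied_means(theta.means, lbl)
            sigmas[j] = implied_covariance(theta.paths, lbl, zyg, r_A=rA)
        out[zyg] = (mus, sigmas)
    return out


def _log_densities(
    Y: np.ndarray, mus: np.ndarray, sigmas: np.ndarray,
    labels: tuple[ClassLabel, ...], zyg: Zygosity,
) -> np.ndarray:
    """(N, C) matrix of log multivariate-normal densities, via Cholesky."""
    N = Y.shape[0]
    C = mus.shape[0]
    out = np.empty((N, C))
    for j in range(C):
        try:
            L = np.linalg.cholesky(sigmas[j])
        except np.linalg.LinAlgError as exc:
            raise NonPositiveDefiniteError(labels[j], zyg) from exc
        # forward substitution on the (4, N) residuals
        resid = (Y - mus[j]).T
        w = np.empty_like(resid)
        # L is 4x4 lower triangular: unrolled solve is faster than scipy call
        w[0] = resid[0] / L[0, 0]
        w[1] = (resid[1] - L[1, 0] * w[0]) / L[1, 1]
        w[2] = (resid[2] - L[2, 0] * w[0] - L[2, 1] * w[1]) / L[2, 2]
        w[3] = (resid[3] - L[3, 0] * w[0] - L[3, 1] * w[1] - L[3, 2] * w[2]) / L[3, 3]
        logdet_half = np.log(np.diag(L)).sum()
        out[:, j] = -0.5 * (4 * LOG_2PI + (w * w).sum(axis=0)) - logdet_half
    return out


def _group_log_weighted_densities(
    data: TwinDataset, theta: ModelParameters, spec: ModelSpec
) -> dict[Zygosity, np.ndarray]:
    """Per zygosity group: (N_z, C) matrix of log(omega_j * phi_j(y_i))."""
    moments = class_moments(theta, spec)
    out: dict[Zygosity, np.ndarray] = {}
    for zyg in Zygosity:
        Y = data.matrix(zyg)
        if Y.shape[0] == 0:
            continue
        mus, sigmas = moments[zyg]
        logd = _log_densities(Y, mus, sigmas, spec.active_classes, zyg)
        w = theta.weights(spec, zyg)
        with np.errstate(divide="ignore"):
            out[zyg] = logd + np.log(w)
    return out


def mixture_loglik(
    data: TwinDataset, theta: ModelParameters, spec: ModelSpec
) -> float:
    """Observed-data log-likelihood of the finite mixture (log-sum-exp form)."""
    total = 0.0
    for lw in _group_log_weighted_densities(data, theta, spec).values():
        total += float(logsumexp(lw, axis=1).sum())
    return total


def posterior_probabilities(
    data: TwinDataset, theta: ModelParameters, spec: ModelSpec
) -> PosteriorMatrix:
    """Bayes-rule posterior class probabilities per pair, in input row order."""
    C = spec.n_classes
    P = np.full((data.n_pairs, C), np.nan)
    groups = _group_log_weighted_densities(data, theta, spec)
    for zyg, lw in groups.items():
        norm = logsumexp(lw, axis=1, keepdims=True)
        P[data.zygosity_mask(zyg)] = np.exp(lw - norm)
    return PosteriorMatrix(
        probabilities=P, labels=tuple(lbl.value for lbl in spec.active_classes)
    )


def relative_entropy(post: PosteriorMatrix) -> float:
    """Relative entropy index Ent in [0, 1]; higher = sharper classification."""
    C = post.n_classes
    if C < 2:
        raise ValueError("relative entropy is undefined for a single class")
    P = post.probabilities
    N = P.shape[0]
    plogp = np.where(P > _ENTROPY_FLOOR, P * np.log(np.clip(P, _ENTROPY_FLOOR, None)), 0.0)
    return float(1.0 + plogp.sum() / (N * np.log(C)))


def collapse_to_directions(post: PosteriorMatrix) -> PosteriorMatrix:
    """Reduce 4-class pair posteriors to 2-class per-twin direction posteriors.

    Each twin is assigned its own probability of being governed by the X->Y
    process; the result has 2N rows (twin 1 rows then twin 2 rows) and the two
    direction classes as columns.
    """
    labels = [ClassLabel(v) for v in post.labels]
    P = post.probabilities
    t1_xy = sum(
        (P[:, j] for j, lbl in enumerate(labels) if lbl.twin1.value == "XY"),
        start=np.zeros(P.shape[0]),
    )
    t2_xy = sum(
        (P[:, j] for j, lbl in enumerate(labels) if lbl.twin2.value == "XY"),
        start=np.zeros(P.shape[0]),
    )
    twin_rows = np.concatenate(
        [np.stack([t1_xy, 1.0 - t1_xy], axis=1), np.stack([t2_xy, 1.0 - t2_xy], axis=1)]
    )
    return PosteriorMatrix(probabilities=twin_rows, labels=("XY", "YX"))
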