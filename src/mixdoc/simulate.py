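"""Simulation of twin-pair data under the mixDoC generating model.

Datasets are drawn from the finite mixture of 4-variate Gaussians implied by a
scenario: for each zygosity group and each active causal class, pair counts
are allocated (exactly, by largest remainder, or multinomially), 4-vectors are
sampled from the class's implied moments, and the per-class blocks are merged
and shuffled.  True class labels are retained for validation.

Scenario defaults (held fixed unless a sweep varies them):

* pre-causal variance proportions, trait X: A=0.5, C=0.2, E=0.3 and
  trait Y: A=0.2, C=0.3, E=0.5 — distinct modes of inheritance, which the
  direction-of-causation design requires for resolution;
* causal effects b_yx = b_xy = 0.5;
* phenotypic means 0 for the X->Y direction, with offsets (delta_x, delta_y)
  added to the Y->X direction means (only the difference is identified);
* no latent confounding (r_A = r_C = r_E = 0);
* equal 25% class proportions, 2500 MZ + 2500 DZ pairs.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import TwinDataset
from .likelihood import MixingProportions
from .model import (
    ClassLabel,
    MeanStructure,
    PathParameters,
    Zygosity,
    implied_covariance,
    implied_means,
)

_SWEEP_NAMES = (
    "mixing_proportion",
    "bidirectional",
    "mean_difference",
    "causal_effect",
    "heritability_y",
    "genetic_confounding",
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Generating conditions for one simulated dataset."""

    n_mz: int = 2500
    n_dz: int = 2500
    #: generating class weights over the four unidirectional classes
    proportions: MixingProportions = field(
        default_factory=lambda: MixingProportions.equal(ClassLabel.causal_classes())
    )
    #: optional per-zygosity fraction of pairs generated under the
    #: bidirectional class (robustness scenario); the remaining pairs follow
    #: ``proportions``
    bidir_fraction_mz: float | None = None
    bidir_fraction_dz: float | None = None
    #: phenotypic mean offsets of the Y->X direction relative to X->Y
    delta_x: float = 0.5
    delta_y: float = 0.5
    b_yx: float = 0.5
    b_xy: float = 0.5
    #: pre-causal variance proportions (A and C; E is the remainder)
    h2_x: float = 0.5
    c2_x: float = 0.2
    h2_y: float = 0.2
    c2_y: float = 0.3
    r_A: float = 0.0
    r_C: float = 0.0
    r_E: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz < 1 or self.n_dz < 1:
            raise ValueError("need at least one pair per zygosity")
        for name in ("bidir_fraction_mz", "bidir_fraction_dz"):
            f = getattr(self, name)
            if f is not None and not (0.0 <= f <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        for trait in ("x", "y"):
            h2 = getattr(self, f"h2_{trait}")
            c2 = getattr(self, f"c2_{trait}")
            if h2 < 0 or c2 < 0 or h2 + c2 >= 1.0:
                raise ValueError(
                    f"variance proportions of trait {trait} must be nonnegative "
                    f"with h2 + c2 < 1 (E is the remainder)"
                )

    def path_parameters(self) -> PathParameters:
        return PathParameters(
            a_x=math.sqrt(self.h2_x),
            c_x=math.sqrt(self.c2_x),
            e_x=math.sqrt(1.0 - self.h2_x - self.c2_x),
            a_y=math.sqrt(self.h2_y),
            c_y=math.sqrt(self.c2_y),
            e_y=math.sqrt(1.0 - self.h2_y - self.c2_y),
            b_yx=self.b_yx,
            b_xy=self.b_xy,
            r_A=self.r_A,
            r_C=self.r_C,
            r_E=self.r_E,
        )

    def mean_structure(self) -> MeanStructure:
        return MeanStructure(mu_x_XY=0.0, mu_y_XY=0.0,
                             mu_x_YX=self.delta_x, mu_y_YX=self.delta_y)

    def to_dict(self) -> dict:
        return {
            "n_mz": self.n_mz,
            "n_dz": self.n_dz,
            "proportions_mz": list(self.proportions.mz),
            "proportions_dz": list(self.proportions.dz),
            "bidir_fraction_mz": self.bidir_fraction_mz,
            "bidir_fraction_dz": self.bidir_fraction_dz,
            "delta_x": self.delta_x,
            "delta_y": self.delta_y,
            "b_yx": self.b_yx,
            "b_xy": self.b_xy,
            "h2_x": self.h2_x,
            "c2_x": self.c2_x,
            "h2_y": self.h2_y,
            "c2_y": self.c2_y,
            "r_A": self.r_A,
            "r_C": self.r_C,
            "r_E": self.r_E,
            "seed": self.seed,
        }


def _largest_remainder(weights: np.ndarray, n: int) -> np.ndarray:
    """Integer allocation of n units at exact proportions."""
    raw = weights * n
    base = np.floor(raw).astype(int)
    short = n - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base))
        base[order[:short]] += 1
    return base


def _class_plan(config: ScenarioConfig, zyg: Zygosity) -> list[tuple[ClassLabel, float]]:
    """(label, weight) pairs for one zygosity, including the optional
    bidirectional generating class."""
    frac = (config.bidir_fraction_mz if zyg is Zygosity.MZ
            else config.bidir_fraction_dz)
    w = config.proportions.for_zygosity(zyg)
    plan = list(zip(config.proportions.labels, w))
    if frac is not None:
        plan = [(lbl, wi * (1.0 - frac)) for lbl, wi in plan]
        plan.append((ClassLabel.BI_BI, frac))
    return [(lbl, wi) for lbl, wi in plan if wi > 0]


def simulate(config: ScenarioConfig, allocation: str = "fixed") -> TwinDataset:
    """Draw one dataset; seeded runs are bit-reproducible.

    ``allocation='fixed'`` realises class counts at exact proportions
    (largest-remainder rounding); ``'multinomial'`` draws them, for
    sampling-variability studies.
    """
    if allocation not in ("fixed", "multinomial"):
        raise ValueError("allocation must be 'fixed' or 'multinomial'")
    rng = np.random.default_rng(config.seed)
    params = config.path_parameters()
    means = config.mean_structure()
    rows = []
    fid = 0
    for zyg, n in ((Zygosity.MZ, config.n_mz), (Zygosity.DZ, config.n_dz)):
        plan = _class_plan(config, zyg)
        weights = np.array([w for _, w in plan])
        weights = weights / weights.sum()
        if allocation == "fixed":
            counts = _largest_remainder(weights, n)
        else:
            counts = rng.multinomial(n, weights)
        for (label, _), count in zip(plan, counts):
            if count == 0:
                continue
            mu = implied_means(means, label)
            L = np.linalg.cholesky(implied_covariance(params, label, zyg))
            Y = rng.standard_normal((count, 4)) @ L.T + mu
            block = pd.DataFrame(Y, columns=["x1", "y1", "x2", "y2"])
            block.insert(0, "zygosity", zyg.value)
            block["true_class"] = label.value
            rows.append(block)
    frame = pd.concat(rows, ignore_index=True)
    order = rng.permutation(len(frame))
    frame = frame.iloc[order].reset_index(drop=True)
    frame.insert(0, "family_id", np.arange(1, len(frame) + 1))
    return TwinDataset.from_frame(frame)


def _proportions(p_plus: float, discordant: float = 0.0) -> MixingProportions:
    conc = 1.0 - discordant
    w = (p_plus * conc, discordant / 2.0, discordant / 2.0, (1.0 - p_plus) * conc)
    return MixingProportions(labels=ClassLabel.causal_classes(), mz=w, dz=w)


def scenario_grid(name: str, base: ScenarioConfig | None = None) -> list[ScenarioConfig]:
    """Parameter grid for a named one-dimensional sweep.

    Each sweep varies exactly one generating quantity; all other fields stay at
    the ``ScenarioConfig`` defaults (or at ``base`` if given).
    """
    base = base or ScenarioConfig()
    if name == "mixing_proportion":
        # concordant-direction split per zygosity: P+ from 0.10 to 0.60
        return [
            replace(base, proportions=_proportions(p))
            for p in (0.10, 0.20, 0.30, 0.40, 0.50, 0.60)
        ]
    if name == "bidirectional":
        return [
            replace(base, bidir_fraction_mz=f, bidir_fraction_dz=f)
            for f in (0.10, 0.15, 0.20)
        ]
    if name == "mean_difference":
        return [
            replace(base, delta_x=dx, delta_y=dy)
            for dx, dy in ((0.1, 0.1), (0.5, 0.1), (1.5, 0.1), (0.5, 0.5), (1.5, 1.5))
        ]
    if name == "causal_effect":
        return [
            replace(base, b_yx=byx, b_xy=bxy)
            for byx, bxy in ((0.1, 0.1), (0.1, 0.5), (0.1, 0.8), (0.5, 0.5), (0.8, 0.8))
        ]
    if name == "heritability_y":
        # additive-genetic variance of X fixed at 0.7 (C:E split kept at 2:3);
        # remaining variance of Y split C:E at the default 3:5 ratio
        out = []
        for a2y in (0.1, 0.3, 0.4, 0.5, 0.6):
            rest = 1.0 - a2y
            out.append(
                replace(base, h2_x=0.7, c2_x=0.12, h2_y=a2y, c2_y=rest * 3.0 / 8.0)
            )
        return out
    if name == "genetic_confounding":
        return [replace(base, r_A=r) for r in (0.10, 0.15, 0.20, 0.25, 0.30)]
    raise ValueError(f"unknown scenario sweep {name!r}; choose from {_SWEEP_NAMES}")
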