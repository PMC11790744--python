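"""Scenario runners: the six-model AIC comparison and the entropy sweeps.

``run_model_comparison`` simulates one dataset and fits all six variants,
assembling a table of df, -2LL, AIC and delta-AIC (recomputed from the AIC
column, ties broken toward fewer parameters).  ``run_entropy_sweep`` repeats
mixture fits across replications of each grid point and reports both the mean
per-replication entropy and the entropy of a fresh dataset evaluated at
replication-averaged estimates, each with Monte-Carlo standard errors.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .data import TwinDataset
from .estimation import (
    ConvergenceError,
    FitResult,
    ModelSpec,
    Variant,
    embed_parameters,
    fit,
)
from .likelihood import (
    MixingProportions,
    ModelParameters,
    posterior_probabilities,
    relative_entropy,
)
from .model import MeanStructure, PathParameters
from .simulate import ScenarioConfig, simulate

#: fitting order; later variants can reuse earlier solutions as warm starts
COMPARISON_VARIANTS: tuple[Variant, ...] = (
    Variant.DOC_XY,
    Variant.DOC_YX,
    Variant.DOC_BIDIR,
    Variant.CORRELATED_FACTORS,
    Variant.MIX2,
    Variant.MIX4,
)

#: which earlier fits seed which later variant (nesting-aware warm starts)
_WARM_CHAIN: dict[Variant, tuple[Variant, ...]] = {
    Variant.DOC_BIDIR: (Variant.DOC_XY, Variant.DOC_YX),
    Variant.CORRELATED_FACTORS: (),
    Variant.MIX2: (Variant.DOC_XY, Variant.DOC_YX),
    Variant.MIX4: (Variant.MIX2,),
}


@dataclass(frozen=True)
class ComparisonTable:
    """Per-variant fit statistics for one dataset."""

    rows: pd.DataFrame
    config: dict
    seed: int

    def __post_init__(self) -> None:
        d = self.rows.loc[self.rows["converged"], "delta_aic"]
        if len(d) and d.min() < -1e-9:
            raise ValueError("delta_aic must be nonnegative")

    @property
    def best_variant(self) -> str:
        """Minimum-AIC converged variant; exact ties go to fewer parameters."""
        ok = self.rows[self.rows["converged"]]
        best = ok.sort_values(["aic", "k"], kind="stable").iloc[0]
        return str(best["variant"])

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6f")


def run_model_comparison(
    config: ScenarioConfig,
    seed: int,
    *,
    n_starts: int = 4,
    data: TwinDataset | None = None,
) -> ComparisonTable:
    """Simulate one dataset (unless given) and fit all six model variants."""
    cfg = replace(config, seed=seed)
    if data is None:
        data = simulate(cfg)
    fits: dict[Variant, FitResult] = {}
    records = []
    rng = np.random.default_rng(seed)
    for variant in COMPARISON_VARIANTS:
        spec = ModelSpec(variant=variant)
        extra = tuple(
            embed_parameters(fits[src].params, fits[src].spec, spec)
            for src in _WARM_CHAIN.get(variant, ())
            if src in fits
        )
        try:
            result = fit(
                data, spec,
                n_starts=n_starts,
                seed=int(rng.integers(2**31 - 1)),
                extra_starts=extra,
            )
            fits[variant] = result
            records.append(
                dict(variant=variant.value, df=result.df, minus2LL=result.minus2LL,
                     aic=result.aic, k=result.k, converged=True,
                     entropy=result.entropy)
            )
        except ConvergenceError:
            records.append(
                dict(variant=variant.value, df=np.nan, minus2LL=np.nan,
                     aic=np.nan, k=np.nan, converged=False, entropy=None)
            )
    rows = pd.DataFrame.from_records(records)
    ok = rows["converged"]
    rows["delta_aic"] = np.nan
    if ok.any():
        # always recomputed from the AIC column
        rows.loc[ok, "delta_aic"] = rows.loc[ok, "aic"] - float(rows.loc[ok, "aic"].min())
    return ComparisonTable(rows=rows, config=cfg.to_dict(), seed=seed)


@dataclass(frozen=True)
class SweepResult:
    """Entropy summary for one grid point of a sweep."""

    config: dict
    swept: dict
    n_replications: int
    n_converged: int
    mean_entropy: float
    entropy_se: float
    entropy_at_averaged_estimates: float
    seeds: tuple[int, ...]
    usable: bool

    def to_dict(self) -> dict:
        return {
            "swept": self.swept,
            "n_replications": self.n_replications,
            "n_converged": self.n_converged,
            "mean_entropy": self.mean_entropy,
            "entropy_se": self.entropy_se,
            "entropy_at_averaged_estimates": self.entropy_at_averaged_estimates,
            "usable": self.usable,
        }


def _average_parameters(fits: list[FitResult]) -> ModelParameters:
    """Field-wise average of sign-normalised estimates across replications."""
    def mean_attr(getter):
        return float(np.mean([getter(f.params) for f in fits]))

    path_fields = ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y",
                   "b_yx", "b_xy", "r_A", "r_C", "r_E")
    paths = PathParameters(**{
        n: mean_attr(lambda p, n=n: getattr(p.paths, n)) for n in path_fields
    })
    mean_fields = ("mu_x_XY", "mu_y_XY", "mu_x_YX", "mu_y_YX")
    means = MeanStructure(**{
        n: mean_attr(lambda p, n=n: getattr(p.means, n)) for n in mean_fields
    })
    labels = fits[0].params.mixing.labels
    mz = tuple(np.mean([f.params.mixing.mz for f in fits], axis=0))
    dz = tuple(np.mean([f.params.mixing.dz for f in fits], axis=0))
    return ModelParameters(paths=paths, means=means,
                           mixing=MixingProportions(labels=labels, mz=mz, dz=dz))


def run_entropy_sweep(
    grid: list[ScenarioConfig],
    n_reps: int,
    seed: int,
    *,
    spec: ModelSpec | None = None,
    n_starts: int = 2,
    swept_fields: tuple[str, ...] = (),
) -> list[SweepResult]:
    """Fit the mixture to ``n_reps`` replications of every grid point."""
    if not grid:
        raise ValueError("empty scenario grid")
    if n_reps < 2:
        raise ValueError("need at least 2 replications per grid point")
    spec = spec or ModelSpec(variant=Variant.MIX4)
    root = np.random.default_rng(seed)
    results = []
    for config in grid:
        rep_seeds = [int(root.integers(2**31 - 1)) for _ in range(n_reps + 1)]
        entropies = []
        fits = []
        for r in range(n_reps):
            cfg = replace(config, seed=rep_seeds[r])
            data = simulate(cfg)
            try:
                result = fit(data, spec, n_starts=n_starts, seed=rep_seeds[r])
            except ConvergenceError:
                continue
            fits.append(result)
            entropies.append(result.entropy)
        n_conv = len(entropies)
        if n_conv:
            avg_theta = _average_parameters(fits)
            eval_data = simulate(replace(config, seed=rep_seeds[-1]))
            post = posterior_probabilities(eval_data, avg_theta, spec)
            ent_avg = relative_entropy(post)
            mean_ent = float(np.mean(entropies))
            se = float(np.std(entropies, ddof=1) / np.sqrt(n_conv)) if n_conv > 1 else np.nan
        else:
            ent_avg = mean_ent = se = np.nan
        results.append(
            SweepResult(
                config=config.to_dict(),
                swept={f: getattr(config, f) for f in swept_fields},
                n_replications=n_reps,
                n_converged=n_conv,
                mean_entropy=mean_ent,
                entropy_se=se,
                entropy_at_averaged_estimates=ent_avg,
                seeds=tuple(rep_seeds),
                usable=n_conv >= max(1, n_reps // 2),
            )
        )
    return results


def sweep_frame(results: list[SweepResult]) -> pd.DataFrame:
    """Tabular view of sweep results."""
    rows = []
    for r in results:
        row = dict(r.swept)
        row.update(
            n_replications=r.n_replications,
            n_converged=r.n_converged,
            mean_entropy=r.mean_entropy,
            entropy_se=r.entropy_se,
            entropy_at_averaged_estimates=r.entropy_at_averaged_estimates,
            usable=r.usable,
        )
        rows.append(row)
    return pd.DataFrame(rows)
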