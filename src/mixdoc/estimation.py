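"""Maximum-likelihood fitting of the mixDoC model family.

Mixture variants are fitted by expectation-maximisation: the E-step computes
posterior class probabilities, the weight update is closed form (with the
discordant classes pooled when the equality constraint is active), and the
M-step maximises the expected complete-data log-likelihood numerically over
the structural parameters.  Because every pair in a (class, zygosity) cell
shares one implied mean vector and covariance matrix, the M-step objective
depends on the data only through weighted first and second moments, so its
cost is independent of sample size.

Single-class variants are fitted by direct quasi-Newton maximisation of the
Gaussian log-likelihood expressed through per-zygosity sufficient statistics,
which is exact for multivariate-normal models.

Both routes maximise the same observed-data likelihood that
:func:`mixdoc.likelihood.mixture_loglik` evaluates; the reported -2LL is
always recomputed from that function at the final estimates.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize, stats
from scipy.special import logsumexp

from .data import TwinDataset
from .likelihood import (
    MixingProportions,
    ModelParameters,
    PosteriorMatrix,
    class_moments,
    mixture_loglik,
    posterior_probabilities,
    relative_entropy,
)
from .model import (
    LOG_2PI,
    ClassLabel,
    MeanStructure,
    PathParameters,
    Zygosity,
)
from .specs import ConfoundMode, ModelSpec, Variant, count_free_parameters, parameter_names

__all__ = [
    "ConvergenceError",
    "DegenerateMixtureWarning",
    "FitResult",
    "LRTResult",
    "NotNestedError",
    "ModelSpec",
    "Variant",
    "ConfoundMode",
    "count_free_parameters",
    "fit",
    "fit_statistics",
    "likelihood_ratio_test",
    "embed_parameters",
]


class ConvergenceError(RuntimeError):
    """No optimisation start converged; ``diagnostics`` holds one entry per start."""

    def __init__(self, message: str, diagnostics: list[dict]):
        super().__init__(message)
        self.diagnostics = diagnostics


class DegenerateMixtureWarning(UserWarning):
    """The concordant classes' implied moments coincide: the mixture is
    unidentified at the solution."""


class NotNestedError(ValueError):
    """The two fits are not nested; compare them with AIC instead."""


# --------------------------------------------------------------------------
# parameter vector <-> ModelParameters
#
# The unconstrained vector holds: 6 variance paths (raw), causal paths (raw),
# confound correlations (atanh scale), means (raw).  Mixing weights are kept
# out of the structural vector: EM updates them in closed form.

_PATH_NAMES = ("a_x", "c_x", "e_x", "a_y", "c_y", "e_y")


def _structural_names(spec: ModelSpec) -> tuple[str, ...]:
    return (_PATH_NAMES + spec.free_causal_paths + spec.free_confound_params
            + spec.free_mean_params)


def _unpack_structural(x: np.ndarray, spec: ModelSpec) -> ModelParameters:
    i = 6
    kw = dict(zip(_PATH_NAMES, x[:6]))
    for name in spec.free_causal_paths:
        kw[name] = x[i]
        i += 1
    r_by_class = None
    if spec.confound_mode is ConfoundMode.RA_BY_CLASS:
        n = spec.n_classes
        r_by_class = tuple(np.tanh(x[i:i + n]))
        i += n
    else:
        for name in spec.free_confound_params:
            kw[name] = float(np.tanh(x[i]))
            i += 1
    paths = PathParameters(**kw)
    if spec.is_mixture:
        means = MeanStructure(mu_x_XY=x[i], mu_y_XY=x[i + 1],
                              mu_x_YX=x[i + 2], mu_y_YX=x[i + 3])
        i += 4
    else:
        means = MeanStructure(mu_x_XY=x[i], mu_y_XY=x[i + 1],
                              mu_x_YX=x[i], mu_y_YX=x[i + 1])
        i += 2
    return ModelParameters(paths=paths, means=means, mixing=None,
                           r_A_by_class=r_by_class)


def _atanh_safe(r: float) -> float:
    return float(np.arctanh(np.clip(r, -0.999, 0.999)))


def _pack_structural(theta: ModelParameters, spec: ModelSpec) -> np.ndarray:
    p = theta.paths
    x = [getattr(p, n) for n in _PATH_NAMES]
    x += [getattr(p, n) for n in spec.free_causal_paths]
    if spec.confound_mode is ConfoundMode.RA_BY_CLASS:
        rs = theta.r_A_by_class or tuple([p.r_A] * spec.n_classes)
        x += [_atanh_safe(r) for r in rs]
    else:
        x += [_atanh_safe(getattr(p, n)) for n in spec.free_confound_params]
    m = theta.means
    if spec.is_mixture:
        x += [m.mu_x_XY, m.mu_y_XY, m.mu_x_YX, m.mu_y_YX]
    else:
        x += [m.mu_x_XY, m.mu_y_XY]
    return np.asarray(x, dtype=float)


# --------------------------------------------------------------------------
# weighted-moment objective (negative expected complete-data log-likelihood,
# up to the weight term); also the exact -loglik for single-class variants.
# Evaluated on batches of parameter vectors so the finite-difference gradient
# costs one vectorised pass instead of 2k scalar passes.

_BIG = 1e12
_ZYG_ORDER = (Zygosity.MZ, Zygosity.DZ)
_ALPHAS = np.array([1.0, 0.5])


class _MomentKernel:
    """Vectorised implied moments and weighted-moment objective for one spec.

    Parameter vectors follow the structural layout of
    :func:`_pack_structural`: 6 variance paths, free causal paths, confound
    correlations on the atanh scale, then means.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.labels = spec.active_classes
        self.C = len(self.labels)
        i = 6
        self.i_byx = self.i_bxy = None
        for name in spec.free_causal_paths:
            if name == "b_yx":
                self.i_byx = i
            else:
                self.i_bxy = i
            i += 1
        self.by_class = spec.confound_mode is ConfoundMode.RA_BY_CLASS
        self.i_rA = self.i_rC = self.i_rE = None
        self.sl_rA_class = None
        if self.by_class:
            self.sl_rA_class = slice(i, i + self.C)
            i += self.C
        else:
            for name in spec.free_confound_params:
                setattr(self, "i_" + name.replace("_", ""), i)
                i += 1
        self.i_means = i
        self.n_means = 4 if spec.is_mixture else 2
        self.n_struct = i + self.n_means

    def _col(self, X: np.ndarray, idx: int | None, tanh: bool = False) -> np.ndarray:
        if idx is None:
            return np.zeros(X.shape[0])
        return np.tanh(X[:, idx]) if tanh else X[:, idx]

    def moments(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """mus (B, C, 4) and sigmas (B, 2, C, 4, 4); zygosity axis is (MZ, DZ)."""
        B, C = X.shape[0], self.C
        ax, cx, ex, ay, cy, ey = (X[:, j] for j in range(6))
        byx = self._col(X, self.i_byx)
        bxy = self._col(X, self.i_bxy)
        rC = self._col(X, self.i_rC, tanh=True)
        rE = self._col(X, self.i_rE, tanh=True)
        if self.by_class:
            rA = np.tanh(X[:, self.sl_rA_class])  # (B, C)
        else:
            rA = self._col(X, self.i_rA, tanh=True)[:, None]  # (B, 1)
        vx = ax * ax + cx * cx + ex * ex
        vy = ay * ay + cy * cy + ey * ey
        axy = ax * ay
        within = rA * axy[:, None] + (rC * cx * cy + rE * ex * ey)[:, None]  # (B, Cr)
        cross_x = _ALPHAS[None, :] * (ax * ax)[:, None] + (cx * cx)[:, None]  # (B, 2)
        cross_y = _ALPHAS[None, :] * (ay * ay)[:, None] + (cy * cy)[:, None]
        cross_xt = (_ALPHAS[None, :, None] * rA[:, None, :] * axy[:, None, None]
                    + (rC * cx * cy)[:, None, None])  # (B, 2, Cr)

        psi = np.zeros((B, 2, C, 4, 4))
        psi[..., 0, 0] = psi[..., 2, 2] = vx[:, None, None]
        psi[..., 1, 1] = psi[..., 3, 3] = vy[:, None, None]
        w_b = np.broadcast_to(within[:, None, :], (B, 2, within.shape[1]))
        psi[..., 0, 1] = psi[..., 1, 0] = psi[..., 2, 3] = psi[..., 3, 2] = w_b
        psi[..., 0, 2] = psi[..., 2, 0] = cross_x[:, :, None]
        psi[..., 1, 3] = psi[..., 3, 1] = cross_y[:, :, None]
        psi[..., 0, 3] = psi[..., 3, 0] = psi[..., 1, 2] = psi[..., 2, 1] = cross_xt

        from .model import Direction  # local to avoid cycle at module import

        M = np.zeros((B, C, 4, 4))
        M[..., range(4), range(4)] = 1.0
        for j, label in enumerate(self.labels):
            for o, d in ((0, label.twin1), (2, label.twin2)):
                if d is Direction.XY:
                    M[:, j, o + 1, o] = byx
                elif d is Direction.YX:
                    M[:, j, o, o + 1] = bxy
                else:  # bidirectional generating class
                    det = 1.0 - byx * bxy
                    safe = np.where(np.abs(det) < 1e-12, np.nan, det)
                    M[:, j, o, o] = M[:, j, o + 1, o + 1] = 1.0 / safe
                    M[:, j, o + 1, o] = byx / safe
                    M[:, j, o, o + 1] = bxy / safe
        Mb = M[:, None, :, :, :]
        sig = Mb @ psi @ Mb.swapaxes(-1, -2)
        sig = 0.5 * (sig + sig.swapaxes(-1, -2))

        mus = np.empty((B, C, 4))
        mcols = X[:, self.i_means:self.i_means + self.n_means]
        if self.spec.is_mixture:
            mu_dir = {"XY": mcols[:, 0:2], "YX": mcols[:, 2:4], "BI": mcols[:, 0:2]}
        else:
            mu_dir = {"XY": mcols, "YX": mcols, "BI": mcols}
        for j, label in enumerate(self.labels):
            mus[:, j, 0:2] = mu_dir[label.twin1.value]
            mus[:, j, 2:4] = mu_dir[label.twin2.value]
        return mus, sig

    def neg_q(
        self,
        X: np.ndarray,
        group_stats: dict[Zygosity, tuple[np.ndarray, np.ndarray, np.ndarray]],
    ) -> np.ndarray:
        """(B,) of sum over (zygosity, class) cells of
        0.5 * N_w * (4 log 2pi + log|Sigma| + tr(Sigma^-1 (S + d d'))).
        Non-positive-definite cells yield a large penalty value."""
        B = X.shape[0]
        mus, sigmas = self.moments(X)
        out = np.zeros(B)
        bad = ~np.all(np.isfinite(sigmas.reshape(B, -1)), axis=1)
        sigmas = np.where(bad[:, None, None, None, None], np.eye(4), sigmas)
        for zi, zyg in enumerate(_ZYG_ORDER):
            if zyg not in group_stats:
                continue
            Nw, m, S = group_stats[zyg]
            Sg = sigmas[:, zi]  # (B, C, 4, 4)
            logdet, pd_bad = _batch_logdet(Sg)
            bad |= pd_bad
            d = m[None, :, :] - mus  # (B, C, 4)
            A = S[None, :, :, :] + np.einsum("bci,bcj->bcij", d, d)
            Sg_safe = np.where(pd_bad[:, None, None, None], np.eye(4), Sg)
            tr = np.einsum("bcii->bc", np.linalg.solve(Sg_safe, A))
            out += 0.5 * (Nw[None, :] * (4 * LOG_2PI + logdet + tr)).sum(axis=1)
        out = np.where(bad | ~np.isfinite(out), _BIG, out)
        return out

    def objective(self, group_stats):
        """(fun, jac) pair for scipy.optimize on the structural vector."""

        def fun(x: np.ndarray) -> float:
            return float(self.neg_q(x[None, :], group_stats)[0])

        def jac(x: np.ndarray) -> np.ndarray:
            k = len(x)
            h = 1e-6 * np.maximum(1.0, np.abs(x))
            E = np.diag(h)
            Xb = np.vstack([x + E, x - E])
            f = self.neg_q(Xb, group_stats)
            return (f[:k] - f[k:]) / (2.0 * h)

        return fun, jac


def _batch_logdet(Sg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """log-determinants of a (B, C, 4, 4) stack via Cholesky, with a
    positive-definiteness mask (True = failed)."""
    B = Sg.shape[0]
    try:
        L = np.linalg.cholesky(Sg)
        diag = np.einsum("...ii->...i", L)
        return 2.0 * np.log(diag).sum(axis=-1), np.zeros(B, dtype=bool)
    except np.linalg.LinAlgError:
        logdet = np.zeros(Sg.shape[:2])
        bad = np.zeros(B, dtype=bool)
        for b in range(B):
            try:
                L = np.linalg.cholesky(Sg[b])
                logdet[b] = 2.0 * np.log(np.einsum("cii->ci", L)).sum(axis=-1)
            except np.linalg.LinAlgError:
                bad[b] = True
        return logdet, bad


def _sample_stats(data: TwinDataset) -> dict[Zygosity, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Single-class sufficient statistics: (count, mean, ML scatter) per zygosity."""
    out = {}
    for zyg in Zygosity:
        Y = data.matrix(zyg)
        if Y.shape[0] == 0:
            continue
        m = Y.mean(axis=0)
        R = Y - m
        S = R.T @ R / Y.shape[0]
        out[zyg] = (np.array([float(Y.shape[0])]), m[None, :], S[None, :, :])
    return out


# --------------------------------------------------------------------------
# EM for mixture variants


def _update_weights(
    post: np.ndarray, labels: tuple[ClassLabel, ...], equality: bool
) -> np.ndarray:
    w = post.sum(axis=0) / post.shape[0]
    if equality:
        idx = [j for j, lbl in enumerate(labels) if lbl.is_discordant]
        if len(idx) == 2:
            pooled = 0.5 * (w[idx[0]] + w[idx[1]])
            w[idx[0]] = w[idx[1]] = pooled
    # guard against exact zeros that would kill a class irrecoverably
    w = np.clip(w, 1e-12, None)
    return w / w.sum()


def _log_density_stack(Yz: np.ndarray, mus: np.ndarray, sigmas: np.ndarray) -> np.ndarray | None:
    """(N, C) log-density matrix, or None if any class covariance is not PD."""
    C = mus.shape[0]
    out = np.empty((Yz.shape[0], C))
    try:
        L = np.linalg.cholesky(sigmas)  # (C, 4, 4)
    except np.linalg.LinAlgError:
        return None
    for j in range(C):
        resid = (Yz - mus[j]).T
        w = np.empty_like(resid)
        Lj = L[j]
        w[0] = resid[0] / Lj[0, 0]
        w[1] = (resid[1] - Lj[1, 0] * w[0]) / Lj[1, 1]
        w[2] = (resid[2] - Lj[2, 0] * w[0] - Lj[2, 1] * w[1]) / Lj[2, 2]
        w[3] = (resid[3] - Lj[3, 0] * w[0] - Lj[3, 1] * w[1] - Lj[3, 2] * w[2]) / Lj[3, 3]
        out[:, j] = (-0.5 * (4 * LOG_2PI + (w * w).sum(axis=0))
                     - np.log(np.diag(Lj)).sum())
    return out


def _em_single_start(
    data: TwinDataset,
    spec: ModelSpec,
    x0: np.ndarray,
    w0: dict[Zygosity, np.ndarray],
    tol: float,
    max_iter: int,
    inner_maxiter: int,
) -> dict:
    labels = spec.active_classes
    kernel = _MomentKernel(spec)
    Y = {zyg: data.matrix(zyg) for zyg in Zygosity}
    Y = {z: y for z, y in Y.items() if y.shape[0] > 0}
    x = np.array(x0, dtype=float)
    weights = {z: np.array(w, dtype=float) for z, w in w0.items()}
    ll_prev = -np.inf
    ll = -np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        mus_b, sig_b = kernel.moments(x[None, :])
        # E-step
        ll = 0.0
        stats_w: dict[Zygosity, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        failed = False
        for zi, zyg in enumerate(_ZYG_ORDER):
            if zyg not in Y:
                continue
            Yz = Y[zyg]
            logd = _log_density_stack(Yz, mus_b[0], sig_b[0, zi])
            if logd is None:
                failed = True
                break
            with np.errstate(divide="ignore"):
                lw = logd + np.log(weights[zyg])
            norm = logsumexp(lw, axis=1)
            ll += float(norm.sum())
            post = np.exp(lw - norm[:, None])
            weights[zyg] = _update_weights(post, labels, spec.discordant_equality)
            Nw = post.sum(axis=0)
            m = (post.T @ Yz) / np.clip(Nw, 1e-300, None)[:, None]
            S = np.empty((len(labels), 4, 4))
            for j in range(len(labels)):
                R = Yz - m[j]
                S[j] = (R * post[:, j:j + 1]).T @ R / max(Nw[j], 1e-300)
            stats_w[zyg] = (Nw, m, S)
        if failed:
            return dict(loglik=-np.inf, x=x, weights=weights, converged=False,
                        n_iter=n_iter, message="non-positive-definite moments")
        if ll - ll_prev <= tol * (abs(ll) + 1.0) and n_iter > 1:
            converged = bool(np.isfinite(ll))
            break
        ll_prev = ll
        # M-step (generalised: a few warm-started quasi-Newton steps)
        fun, jac = kernel.objective(stats_w)
        res = optimize.minimize(
            fun, x, jac=jac, method="BFGS",
            options={"maxiter": inner_maxiter, "gtol": 1e-7},
        )
        if res.fun <= fun(x):
            x = res.x
    return dict(loglik=ll, x=x, weights=weights, converged=converged,
                n_iter=n_iter, message="ok" if converged else "max_iter reached")


# --------------------------------------------------------------------------
# starting values


def _moment_start(
    data: TwinDataset, spec: ModelSpec, rng: np.random.Generator, jitter: float
) -> tuple[np.ndarray, dict[Zygosity, np.ndarray]]:
    """Method-of-moments-style start: Falconer-type variance decomposition,
    regression-based causal paths, quantile-split class means."""
    persons_x = np.concatenate([data.frame["x1"], data.frame["x2"]]).astype(float)
    persons_y = np.concatenate([data.frame["y1"], data.frame["y2"]]).astype(float)
    var_x = max(float(np.var(persons_x)), 1e-6)
    var_y = max(float(np.var(persons_y)), 1e-6)
    mean_x = float(np.mean(persons_x))
    mean_y = float(np.mean(persons_y))
    cov_xy = float(np.cov(persons_x, persons_y)[0, 1])

    def cross_twin(zyg: Zygosity, col: str) -> float:
        Y = data.matrix(zyg)
        i = {"x": (0, 2), "y": (1, 3)}[col]
        if Y.shape[0] < 2:
            return 0.0
        return float(np.cov(Y[:, i[0]], Y[:, i[1]])[0, 1])

    comps = {}
    for trait, var in (("x", var_x), ("y", var_y)):
        cmz = cross_twin(Zygosity.MZ, trait)
        cdz = cross_twin(Zygosity.DZ, trait)
        a2 = np.clip(2.0 * (cmz - cdz), 0.05 * var, 0.85 * var)
        c2 = np.clip(2.0 * cdz - cmz, 0.02 * var, 0.85 * var)
        e2 = np.clip(var - a2 - c2, 0.05 * var, None)
        comps[trait] = (np.sqrt(a2), np.sqrt(c2), np.sqrt(e2))

    b_yx = 0.5 * cov_xy / var_x
    b_xy = 0.5 * cov_xy / var_y
    paths = PathParameters(
        a_x=comps["x"][0], c_x=comps["x"][1], e_x=comps["x"][2],
        a_y=comps["y"][0], c_y=comps["y"][1], e_y=comps["y"][2],
        b_yx=b_yx if "b_yx" in spec.free_causal_paths else 0.0,
        b_xy=b_xy if "b_xy" in spec.free_causal_paths else 0.0,
    )
    if spec.is_mixture:
        lo_x, hi_x = np.quantile(persons_x, [0.3, 0.7])
        lo_y, hi_y = np.quantile(persons_y, [0.3, 0.7])
        means = MeanStructure(mu_x_XY=lo_x, mu_y_XY=lo_y, mu_x_YX=hi_x, mu_y_YX=hi_y)
    else:
        means = MeanStructure(mean_x, mean_y, mean_x, mean_y)
    theta = ModelParameters(paths=paths, means=means)
    x = _pack_structural(theta, spec)
    if jitter > 0:
        scale = np.full_like(x, 0.15)
        n_means = 4 if spec.is_mixture else 2
        scale[-n_means:] = 0.3 * np.sqrt([var_x, var_y, var_x, var_y][:n_means])
        x = x + rng.normal(0.0, jitter, size=x.shape) * scale
    C = spec.n_classes
    w = np.full(C, 1.0 / C)
    if jitter > 0 and C > 1:
        w = rng.dirichlet(np.full(C, 20.0))
        w = _update_weights(w[None, :], spec.active_classes, spec.discordant_equality)
    return x, {Zygosity.MZ: w.copy(), Zygosity.DZ: w.copy()}


def _causal_to_correlated(p: PathParameters) -> PathParameters:
    """Exact correlated-factors representation of a unidirectional model.

    With X -> Y (coefficient b), the downstream trait's factor contributions
    become (f_y + b f_x) for f in {A, C, E}; the new loadings and factor
    correlations reproduce the implied covariance exactly.
    """
    if p.b_yx != 0.0:
        b, up = p.b_yx, "x"
    else:
        b, up = p.b_xy, "y"
    down = "y" if up == "x" else "x"
    rs = {}
    loads = {}
    for factor, r in (("a", p.r_A), ("c", p.r_C), ("e", p.r_E)):
        lu = getattr(p, f"{factor}_{up}")
        ld = getattr(p, f"{factor}_{down}")
        new_ld = np.sqrt(ld * ld + b * b * lu * lu + 2.0 * b * r * lu * ld)
        loads[f"{factor}_{down}"] = new_ld
        loads[f"{factor}_{up}"] = lu
        rs[factor] = 0.0 if new_ld == 0.0 or lu == 0.0 else float(
            np.clip((r * ld + b * lu) / new_ld, -1.0, 1.0)
        )
    return replace(
        p, b_yx=0.0, b_xy=0.0,
        a_x=loads["a_x"], c_x=loads["c_x"], e_x=loads["e_x"],
        a_y=loads["a_y"], c_y=loads["c_y"], e_y=loads["e_y"],
        r_A=rs["a"], r_C=rs["c"], r_E=rs["e"],
    )


def embed_parameters(
    source: ModelParameters, source_spec: ModelSpec, target_spec: ModelSpec
) -> ModelParameters:
    """Re-express a fitted parameter set as a starting point for another
    (typically larger, nesting) model variant.

    A unidirectional causal solution is converted exactly into its
    correlated-factors representation (the causal path is absorbed into the
    downstream trait's factor loadings and the factor correlations), so the
    embedding attains the same likelihood in the nesting model.
    """
    paths = source.paths
    if (target_spec.variant is Variant.CORRELATED_FACTORS
            and (paths.b_yx == 0.0) != (paths.b_xy == 0.0)):
        paths = _causal_to_correlated(paths)
    if "b_yx" not in target_spec.free_causal_paths:
        paths = replace(paths, b_yx=0.0)
    if "b_xy" not in target_spec.free_causal_paths:
        paths = replace(paths, b_xy=0.0)
    means = source.means
    mixing = None
    if target_spec.is_mixture:
        mixing = MixingProportions.equal(target_spec.active_classes)
    r_by_class = None
    if target_spec.confound_mode is ConfoundMode.RA_BY_CLASS:
        r_by_class = tuple([paths.r_A] * target_spec.n_classes)
    return ModelParameters(paths=paths, means=means, mixing=mixing,
                           r_A_by_class=r_by_class)


# --------------------------------------------------------------------------
# results


@dataclass(frozen=True)
class FitResult:
    """Estimates and fit statistics of one maximum-likelihood fit."""

    spec: ModelSpec
    params: ModelParameters
    minus2LL: float
    k: int
    df: int
    aic: float
    converged: bool
    n_starts_used: int
    best_start_seed: int
    n_iter: int
    n_pairs: int
    posteriors: PosteriorMatrix | None = None
    entropy: float | None = None
    se: dict[str, float] | None = None
    start_diagnostics: tuple[dict, ...] = ()

    @property
    def loglik(self) -> float:
        return -0.5 * self.minus2LL

    def estimates_dict(self) -> dict[str, float]:
        p, m = self.params.paths, self.params.means
        out = {n: float(getattr(p, n)) for n in _PATH_NAMES}
        for n in self.spec.free_causal_paths:
            out[n] = float(getattr(p, n))
        if self.spec.confound_mode is ConfoundMode.RA_BY_CLASS:
            for lbl, r in zip(self.spec.active_classes, self.params.r_A_by_class):
                out[f"r_A[{lbl.value}]"] = float(r)
        else:
            for n in self.spec.free_confound_params:
                out[n] = float(getattr(p, n))
        if self.spec.is_mixture:
            out.update(mu_x_XY=m.mu_x_XY, mu_y_XY=m.mu_y_XY,
                       mu_x_YX=m.mu_x_YX, mu_y_YX=m.mu_y_YX)
            for zyg in Zygosity:
                for lbl, w in zip(self.spec.active_classes,
                                  self.params.mixing.for_zygosity(zyg)):
                    out[f"omega_{zyg.value}_{lbl.value}"] = float(w)
        else:
            out.update(mu_x=m.mu_x_XY, mu_y=m.mu_y_XY)
        return out

    def to_dict(self) -> dict:
        d = {
            "variant": self.spec.variant.value,
            "confound_mode": self.spec.confound_mode.value,
            "discordant_equality": self.spec.discordant_equality,
            "n_pairs": self.n_pairs,
            "minus2LL": self.minus2LL,
            "k": self.k,
            "df": self.df,
            "aic": self.aic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "best_start_seed": self.best_start_seed,
            "n_iter": self.n_iter,
            "entropy": self.entropy,
            "estimates": self.estimates_dict(),
        }
        if self.se is not None:
            d["standard_errors"] = self.se
        return d

    def to_report(self) -> str:
        lines = [
            f"mixDoC fit report: variant={self.spec.variant.value} "
            f"confound={self.spec.confound_mode.value}",
            f"pairs={self.n_pairs}  converged={self.converged}  "
            f"starts={self.n_starts_used}  best_start={self.best_start_seed}  "
            f"iterations={self.n_iter}",
            f"-2LL={self.minus2LL:.4f}  k={self.k}  df={self.df}  "
            f"AIC={self.aic:.4f}",
        ]
        if self.entropy is not None:
            lines.append(f"relative entropy={self.entropy:.4f}")
        lines.append("estimates:")
        for name, value in self.estimates_dict().items():
            se = ""
            if self.se and name in self.se:
                se = f"  (se {self.se[name]:.4f})"
            lines.append(f"  {name:>22s} = {value: .6f}{se}")
        return "\n".join(lines)


# --------------------------------------------------------------------------
# main entry point


def _normalize_signs(theta: ModelParameters) -> ModelParameters:
    signs = {n: (1.0 if getattr(theta.paths, n) >= 0 else -1.0)
             for n in ("a_x", "a_y")}
    paths = theta.paths.normalized_signs()
    r_by_class = theta.r_A_by_class
    if r_by_class is not None:
        flip = signs["a_x"] * signs["a_y"]
        r_by_class = tuple(r * flip for r in r_by_class)
    return replace(theta, paths=paths, r_A_by_class=r_by_class)


def _check_degeneracy(theta: ModelParameters, spec: ModelSpec, tol: float = 1e-6) -> None:
    labels = spec.active_classes
    conc = [j for j, lbl in enumerate(labels) if lbl.is_concordant]
    if len(conc) < 2:
        return
    moments = class_moments(theta, spec)
    for zyg in Zygosity:
        mus, sigmas = moments[zyg]
        if (np.max(np.abs(mus[conc[0]] - mus[conc[1]])) < tol
                and np.max(np.abs(sigmas[conc[0]] - sigmas[conc[1]])) < tol):
            warnings.warn(
                "concordant classes have coinciding implied moments; the "
                "mixture is unidentified at this solution",
                DegenerateMixtureWarning,
                stacklevel=3,
            )
            return


def fit(
    data: TwinDataset,
    spec: ModelSpec,
    *,
    n_starts: int = 10,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 2000,
    inner_maxiter: int = 8,
    extra_starts: tuple[ModelParameters, ...] = (),
    compute_se: bool = False,
) -> FitResult:
    """Fit one model variant by maximum likelihood with multiple starts.

    Start 0 is a method-of-moments-style start; further starts are jittered.
    ``extra_starts`` (e.g. a nested model's solution re-embedded with
    :func:`embed_parameters`) are appended after the random starts.
    """
    counts = data.n_pairs_by_zygosity()
    for zyg, n in counts.items():
        if n < 2:
            raise ValueError(
                f"need at least 2 pairs per zygosity; got {n} {zyg.value} pairs"
            )
    rng = np.random.default_rng(seed)
    starts: list[tuple[np.ndarray, dict[Zygosity, np.ndarray]]] = []
    for s in range(max(1, n_starts)):
        starts.append(_moment_start(data, spec, rng, jitter=0.0 if s == 0 else 1.0))
    for theta0 in extra_starts:
        x0 = _pack_structural(theta0, spec)
        if theta0.mixing is not None:
            w0 = {z: theta0.mixing.for_zygosity(z) for z in Zygosity}
        else:
            w0 = {z: np.full(spec.n_classes, 1.0 / spec.n_classes) for z in Zygosity}
        starts.append((x0, w0))

    diagnostics: list[dict] = []
    results: list[dict] = []
    for idx, (x0, w0) in enumerate(starts):
        if spec.is_mixture:
            res = _em_single_start(data, spec, x0, w0, tol, max_iter, inner_maxiter)
        else:
            stats0 = _sample_stats(data)
            fun, jac = _MomentKernel(spec).objective(stats0)
            opt = optimize.minimize(
                fun, x0, jac=jac, method="BFGS",
                options={"maxiter": max_iter, "gtol": 1e-8},
            )
            ok = bool(opt.success) or (
                np.isfinite(opt.fun) and np.max(np.abs(opt.jac)) < 1e-3
            )
            res = dict(loglik=-float(opt.fun), x=opt.x,
                       weights={z: np.ones(1) for z in Zygosity},
                       converged=ok, n_iter=int(opt.nit), message=str(opt.message))
        res["start"] = idx
        results.append(res)
        diagnostics.append({k: res[k] for k in ("start", "loglik", "converged",
                                                "n_iter", "message")})
    converged = [r for r in results if r["converged"] and np.isfinite(r["loglik"])]
    if not converged:
        raise ConvergenceError(
            f"no start converged for variant {spec.variant.value}", diagnostics
        )
    best = max(converged, key=lambda r: r["loglik"])

    theta = _unpack_structural(best["x"], spec)
    if spec.is_mixture:
        mixing = MixingProportions(
            labels=spec.active_classes,
            mz=tuple(best["weights"][Zygosity.MZ]),
            dz=tuple(best["weights"][Zygosity.DZ]),
        )
        theta = replace(theta, mixing=mixing)
    theta = _normalize_signs(theta)
    if spec.is_mixture:
        _check_degeneracy(theta, spec)

    ll = mixture_loglik(data, theta, spec)
    k = count_free_parameters(spec)
    n_pairs = data.n_pairs
    minus2ll = -2.0 * ll
    posteriors = entropy = None
    if spec.is_mixture:
        posteriors = posterior_probabilities(data, theta, spec)
        entropy = relative_entropy(posteriors)
    se = _observed_information_se(data, theta, spec) if compute_se else None
    return FitResult(
        spec=spec,
        params=theta,
        minus2LL=minus2ll,
        k=k,
        df=4 * n_pairs - k,
        aic=minus2ll + 2 * k,
        converged=True,
        n_starts_used=len(starts),
        best_start_seed=int(best["start"]),
        n_iter=int(best["n_iter"]),
        n_pairs=n_pairs,
        posteriors=posteriors,
        entropy=entropy,
        se=se,
        start_diagnostics=tuple(diagnostics),
    )


# --------------------------------------------------------------------------
# full-vector representation (weights included) for standard errors


def _weight_logits(w: np.ndarray, labels, equality: bool) -> np.ndarray:
    if len(w) == 2:
        return np.array([np.log(w[0] / w[1])])
    if equality:
        cats = np.array([w[0], w[1] + w[2], w[3]])
        return np.log(cats[:2] / cats[2])
    return np.log(w[:3] / w[3])


def _weights_from_logits(z: np.ndarray, n_classes: int, equality: bool) -> np.ndarray:
    if n_classes == 2:
        cats = np.exp(np.array([z[0], 0.0]) - max(z[0], 0.0))
        cats /= cats.sum()
        return cats
    full = np.concatenate([z, [0.0]])
    cats = np.exp(full - full.max())
    cats /= cats.sum()
    if equality:
        return np.array([cats[0], 0.5 * cats[1], 0.5 * cats[1], cats[2]])
    return cats


def _pack_full(theta: ModelParameters, spec: ModelSpec) -> np.ndarray:
    x = _pack_structural(theta, spec)
    if spec.is_mixture:
        for zyg in Zygosity:
            w = np.clip(theta.mixing.for_zygosity(zyg), 1e-10, None)
            x = np.concatenate(
                [x, _weight_logits(w, spec.active_classes, spec.discordant_equality)]
            )
    return x


def _unpack_full(x: np.ndarray, spec: ModelSpec) -> ModelParameters:
    n_struct = len(_structural_names(spec))
    theta = _unpack_structural(x[:n_struct], spec)
    if not spec.is_mixture:
        return theta
    per_zyg = (len(x) - n_struct) // 2
    ws = []
    for g in range(2):
        z = x[n_struct + g * per_zyg: n_struct + (g + 1) * per_zyg]
        ws.append(_weights_from_logits(z, spec.n_classes, spec.discordant_equality))
    mixing = MixingProportions(labels=spec.active_classes,
                               mz=tuple(ws[0]), dz=tuple(ws[1]))
    return replace(theta, mixing=mixing)


def _observed_information_se(
    data: TwinDataset, theta: ModelParameters, spec: ModelSpec
) -> dict[str, float]:
    """Numerical-Hessian (observed information) standard errors.

    Reported on the internal transformed scale for weights/correlations; path,
    causal and mean parameters are on their natural scale.
    """
    x0 = _pack_full(theta, spec)
    h = 1e-4 * np.maximum(1.0, np.abs(x0))

    def nll(x):
        return -mixture_loglik(data, _unpack_full(x, spec), spec)

    k = len(x0)
    H = np.empty((k, k))
    f0 = nll(x0)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            fpp = nll(x0 + ei + ej)
            fpm = nll(x0 + ei - ej)
            fmp = nll(x0 - ei + ej)
            fmm = nll(x0 - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    try:
        cov = np.linalg.inv(H)
        ses = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        ses = np.full(k, np.nan)
    return dict(zip(parameter_names(spec), ses.tolist()))


# --------------------------------------------------------------------------
# fit statistics and model comparison


def fit_statistics(fit_result: FitResult, n_pairs: int) -> dict[str, float]:
    """-2LL, df = 4*n_pairs - k, and AIC = -2LL + 2k for a converged fit."""
    if not fit_result.converged:
        raise ValueError("fit statistics require a converged fit")
    k = fit_result.k
    return {
        "minus2LL": fit_result.minus2LL,
        "df": 4 * n_pairs - k,
        "aic": fit_result.minus2LL + 2 * k,
    }


#: nested (reduced, full) variant pairs; mixture-involved pairs violate the
#: usual chi-square regularity conditions and are flagged with a caveat.
_NESTED_PAIRS: frozenset[tuple[Variant, Variant]] = frozenset(
    {
        (Variant.DOC_XY, Variant.DOC_BIDIR),
        (Variant.DOC_YX, Variant.DOC_BIDIR),
        (Variant.DOC_XY, Variant.CORRELATED_FACTORS),
        (Variant.DOC_YX, Variant.CORRELATED_FACTORS),
        (Variant.MIX2, Variant.MIX4),
        (Variant.DOC_XY, Variant.MIX2),
        (Variant.DOC_YX, Variant.MIX2),
        (Variant.DOC_XY, Variant.MIX4),
        (Variant.DOC_YX, Variant.MIX4),
    }
)

_CONFOUND_ORDER = {ConfoundMode.NONE: 0, ConfoundMode.RA_EQUATED: 1,
                   ConfoundMode.RA_BY_CLASS: 2}


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    delta_df: int
    p_value: float
    caveat: bool  #: True when chi-square regularity conditions are in doubt


def _is_nested(nested: ModelSpec, full: ModelSpec) -> bool:
    if nested.variant == full.variant:
        return _CONFOUND_ORDER[nested.confound_mode] < _CONFOUND_ORDER[full.confound_mode]
    if (nested.variant, full.variant) not in _NESTED_PAIRS:
        return False
    return _CONFOUND_ORDER[nested.confound_mode] <= _CONFOUND_ORDER[full.confound_mode]


def likelihood_ratio_test(fit_nested: FitResult, fit_full: FitResult) -> LRTResult:
    """Chi-square likelihood-ratio test of a nested pair of converged fits."""
    if not (fit_nested.converged and fit_full.converged):
        raise ValueError("likelihood-ratio test requires two converged fits")
    same = (fit_nested.spec == fit_full.spec)
    if not same and not _is_nested(fit_nested.spec, fit_full.spec):
        raise NotNestedError(
            f"{fit_nested.spec.variant.value} is not nested in "
            f"{fit_full.spec.variant.value}; compare these models with AIC"
        )
    delta_df = fit_full.k - fit_nested.k
    statistic = fit_nested.minus2LL - fit_full.minus2LL
    if statistic < 0 and statistic > -1e-6 * (abs(fit_full.minus2LL) + 1):
        statistic = 0.0  # optimizer tolerance
    p = 1.0 if delta_df == 0 else float(stats.chi2.sf(max(statistic, 0.0), delta_df))
    caveat = (fit_nested.spec.is_mixture != fit_full.spec.is_mixture) or (
        fit_nested.spec.is_mixture and fit_full.spec.is_mixture
        and fit_nested.spec.n_classes != fit_full.spec.n_classes
    )
    return LRTResult(statistic=float(statistic), delta_df=delta_df,
                     p_value=p, caveat=caveat)
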