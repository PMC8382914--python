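"""Maximum-likelihood fitting of M0 and branch-site Model A, and the LRT.

Test 2 of the branch-site model compares the alternative Model A
(omega2 >= 1 free on the foreground branch) against its null
(omega2 = 1) with a chi-square test on one degree of freedom.  Because
the null pins omega2 to the boundary of the alternative's parameter
space, the statistic is asymptotically a 50:50 mixture of a point mass
at 0 and chi-square(1); statistics numerically equal to zero are
reported as p = 1.

Optimization is bounded quasi-Newton (L-BFGS-B) with seeded random
restarts.  Class proportions are optimized through an unconstrained
softmax transform; omega0 is confined to (0, 1) and omega2 to [1, 999].
Branch lengths are either optimized jointly with the model parameters
(default, using the analytic branch-length gradient for M0), held at
the single-ratio M0 estimates ("m0" — the tractable choice for large
simulation cohorts; the null/alternative comparison stays nested
because both models see the same lengths), or fixed at the input
tree's lengths ("fixed").
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import minimize
from scipy.stats import chi2

from .alignment import CodonAlignment
from .likelihood import (
    LikelihoodEngine,
    M0Spec,
    ModelAParams,
    ModelASpec,
    mixture_site_log_lik,
)
from .trees import LabeledTree

__all__ = [
    "FitSettings",
    "M0Fit",
    "ModelAFit",
    "LRTResult",
    "fit_m0",
    "fit_branch_site",
    "branch_site_lrt",
]

#: LRT statistics below this are reported as exactly zero (p = 1).
ZERO_STAT_TOL = 1e-6

_BOUNDS = {
    "kappa": (0.1, 20.0),
    "omega": (1e-4, 20.0),  # M0 omega
    "omega0": (1e-4, 0.999),
    "omega2": (1.0, 999.0),
    "mix": (-15.0, 15.0),
    "t": (1e-7, 20.0),
}


@dataclass(frozen=True)
class FitSettings:
    """Optimizer configuration for per-gene model fitting."""

    n_starts: int = 3
    seed: int | None = None
    branch_mode: str = "joint"
    ftol: float = 1e-10
    maxiter: int = 500

    def __post_init__(self):
        if self.branch_mode not in {"joint", "m0", "fixed"}:
            raise ValueError(f"unknown branch_mode {self.branch_mode!r}")


@dataclass(frozen=True)
class M0Fit:
    kappa: float
    omega: float
    lnL: float
    branch_lengths: np.ndarray
    converged: bool


@dataclass(frozen=True)
class ModelAFit:
    params: ModelAParams
    lnL: float
    branch_lengths: np.ndarray
    converged: bool


@dataclass(frozen=True)
class LRTResult:
    """Likelihood-ratio test of Model A alternative vs. null (df = 1)."""

    lnL_null: float
    lnL_alt: float
    stat: float
    p: float
    is_zero: bool
    df: int = 1

    @classmethod
    def from_lnls(cls, lnL_null: float, lnL_alt: float) -> "LRTResult":
        stat = max(0.0, 2.0 * (lnL_alt - lnL_null))
        is_zero = stat < ZERO_STAT_TOL
        if is_zero:
            stat = 0.0
            p = 1.0
        else:
            p = float(chi2.sf(stat, df=1))
        return cls(lnL_null=lnL_null, lnL_alt=lnL_alt, stat=stat, p=p, is_zero=is_zero)


def _softmax3(a: float, b: float) -> tuple[float, float]:
    """(a, b) -> (p0, p1) with p0, p1 > 0 and p0 + p1 < 1."""
    z = np.array([a, b, 0.0])
    z -= z.max()
    w = np.exp(z)
    w /= w.sum()
    eps = 1e-9
    p0, p1 = float(w[0]), float(w[1])
    p0 = min(max(p0, eps), 1 - 2 * eps)
    p1 = min(max(p1, eps), 1 - p0 - eps)
    return p0, p1


def _inv_softmax3(p0: float, p1: float) -> tuple[float, float]:
    p2 = max(1.0 - p0 - p1, 1e-9)
    return float(np.log(max(p0, 1e-9) / p2)), float(np.log(max(p1, 1e-9) / p2))


def _proportions(p0: float, p1: float) -> np.ndarray:
    p2 = 1.0 - p0 - p1
    return np.array([p0, p1, p2 * p0 / (p0 + p1), p2 * p1 / (p0 + p1)])


def _minimize(fun, x0, bounds, settings: FitSettings, jac=None):
    options = {"ftol": settings.ftol, "maxiter": settings.maxiter}
    if jac is None:
        # explicit FD step: large enough to dominate evaluation noise
        options["eps"] = 1e-6
    return minimize(
        fun,
        x0,
        method="L-BFGS-B",
        jac=jac,
        bounds=bounds,
        options=options,
    )


def fit_m0(
    aln: CodonAlignment,
    ltree: LabeledTree,
    settings: FitSettings = FitSettings(),
    engine: LikelihoodEngine | None = None,
) -> M0Fit:
    """Fit the single-ratio model, optionally optimizing branch lengths.

    Branch lengths use the analytic gradient; kappa and omega use
    forward finite differences.
    """
    engine = engine or LikelihoodEngine(aln, ltree)
    arrays = engine.arrays
    t0 = np.clip(arrays.branch_lengths, 1e-4, _BOUNDS["t"][1])
    opt_lengths = settings.branch_mode != "fixed"

    if opt_lengths:

        def fun_and_grad(x):
            kappa, omega, lengths = x[0], x[1], x[2:]
            lnL, tgrad = engine.m0_loglik_and_length_grad(kappa, omega, lengths)
            h = 1e-6
            lk = engine.log_likelihood(M0Spec(kappa=kappa + h, omega=omega), lengths)
            lw = engine.log_likelihood(M0Spec(kappa=kappa, omega=omega + h), lengths)
            grad = np.concatenate([[(lk - lnL) / h, (lw - lnL) / h], tgrad])
            return -lnL, -grad

        bounds = [_BOUNDS["kappa"], _BOUNDS["omega"]] + [_BOUNDS["t"]] * len(t0)
        x0 = np.concatenate([[2.0, 0.4], t0])
        jac = True
        fun = fun_and_grad
    else:

        def fun(x):
            return -engine.log_likelihood(M0Spec(kappa=x[0], omega=x[1]), t0)

        bounds = [_BOUNDS["kappa"], _BOUNDS["omega"]]
        x0 = np.array([2.0, 0.4])
        jac = None

    rng = np.random.default_rng(settings.seed)
    best = None
    for start in range(1 + settings.n_starts):
        x_init = x0.copy()
        if start > 0:
            x_init[0] = rng.uniform(0.5, 8.0)
            x_init[1] = rng.uniform(0.02, 2.0)
            if opt_lengths:
                x_init[2:] = t0 * rng.uniform(0.5, 2.0, size=len(t0))
        res = _minimize(fun, x_init, bounds, settings, jac=jac)
        if best is None or res.fun < best.fun:
            best = res
    kappa, omega = float(best.x[0]), float(best.x[1])
    lengths = np.asarray(best.x[2:] if opt_lengths else t0, dtype=float).copy()
    return M0Fit(
        kappa=kappa,
        omega=omega,
        lnL=-float(best.fun),
        branch_lengths=lengths,
        converged=bool(best.success),
    )


def _fit_model_a(
    engine: LikelihoodEngine,
    settings: FitSettings,
    null: bool,
    lengths0: np.ndarray,
    starts: list[tuple[ModelAParams, np.ndarray]],
) -> ModelAFit:
    """Fit Model A (null or alternative) by bounded quasi-Newton.

    The head parameters are the softmax-transformed proportions,
    omega0, kappa and (alternative only) omega2; branch lengths join
    the vector in "joint" mode and stay at ``lengths0`` otherwise.
    """
    opt_lengths = settings.branch_mode == "joint"
    n_t = len(lengths0) if opt_lengths else 0

    def unpack(x):
        p0, p1 = _softmax3(x[0], x[1])
        params = ModelAParams(
            p0=p0, p1=p1, omega0=x[2], kappa=x[3],
            omega2=1.0 if null else x[4], null=null,
        )
        return params, (x[5:] if opt_lengths else lengths0)

    def pack(params, lengths):
        a, b = _inv_softmax3(params.p0, params.p1)
        head = [a, b, params.omega0, params.kappa, 1.0 if null else params.omega2]
        return np.concatenate([head, lengths if opt_lengths else []])

    def nll(x):
        params, lengths = unpack(x)
        return -engine.log_likelihood(ModelASpec(params), lengths)

    bounds = [
        _BOUNDS["mix"], _BOUNDS["mix"], _BOUNDS["omega0"], _BOUNDS["kappa"],
        (1.0, 1.0) if null else _BOUNDS["omega2"],
    ] + [_BOUNDS["t"]] * n_t

    best = None
    for params, lengths in starts:
        res = _minimize(nll, pack(params, lengths), bounds, settings)
        if best is None or res.fun < best.fun:
            best = res
    params, lengths = unpack(best.x)
    return ModelAFit(
        params=params,
        lnL=-float(best.fun),
        branch_lengths=np.asarray(lengths, dtype=float).copy(),
        converged=bool(best.success),
    )


def _random_params(rng, kappa0: float, null: bool) -> ModelAParams:
    p0 = rng.uniform(0.3, 0.8)
    p1 = min(rng.uniform(0.05, 0.3), 0.95 - p0)
    return ModelAParams(
        p0=p0,
        p1=p1,
        omega0=rng.uniform(0.02, 0.5),
        kappa=float(np.clip(kappa0 * rng.uniform(0.7, 1.4), *_BOUNDS["kappa"])),
        omega2=1.0 if null else rng.uniform(1.5, 8.0),
        null=null,
    )


def fit_branch_site(
    aln: CodonAlignment,
    ltree: LabeledTree,
    settings: FitSettings = FitSettings(),
) -> tuple[ModelAFit, ModelAFit, LRTResult]:
    """Fit null and alternative branch-site Model A and form the LRT.

    The null is fitted first (from an M0-informed start); the
    alternative then starts from the null optimum with omega2 = 1 plus
    an omega2 > 1 probe start, which guarantees lnL_alt >= lnL_null up
    to optimizer tolerance and makes the clamped statistic meaningful.
    When the alternative optimum sits on the omega2 = 1 boundary it is
    a valid null-model point, so the null log-likelihood is raised to
    match if the alternative search found a better optimum there.
    """
    engine = LikelihoodEngine(aln, ltree)
    if not np.any(engine.arrays.is_foreground):
        raise ValueError("branch-site test requires a tree with a foreground branch")
    rng = np.random.default_rng(settings.seed)

    m0 = fit_m0(aln, ltree, settings, engine=engine)
    lengths0 = m0.branch_lengths

    omega0_init = float(np.clip(m0.omega, 0.01, 0.9))
    init_null = ModelAParams(
        p0=0.7, p1=0.2, omega0=omega0_init, omega2=1.0, kappa=m0.kappa, null=True
    )
    null_starts = [init_null] + [
        _random_params(rng, m0.kappa, True) for _ in range(settings.n_starts)
    ]
    fit_null = _fit_model_a(
        engine, settings, True, lengths0, [(p, lengths0) for p in null_starts]
    )

    init_alt = replace(fit_null.params, null=False, omega2=1.0)
    probe = replace(fit_null.params, null=False, omega2=3.0)
    alt_starts = [init_alt, probe] + [
        _random_params(rng, m0.kappa, False) for _ in range(settings.n_starts)
    ]
    alt_lengths = fit_null.branch_lengths if settings.branch_mode == "joint" else lengths0
    fit_alt = _fit_model_a(
        engine, settings, False, alt_lengths, [(p, alt_lengths) for p in alt_starts]
    )

    # The alternative's optimum with omega2 forced back to 1 is a valid
    # null-model point; if it beats the null fit, the null search was
    # stuck, so re-polish the null from there before forming the LRT.
    cand = replace(fit_alt.params, null=True, omega2=1.0)
    cand_lnL = engine.log_likelihood(ModelASpec(cand), fit_alt.branch_lengths)
    if fit_null.lnL < cand_lnL <= fit_null.lnL + 1e-7:
        fit_null = ModelAFit(
            params=cand, lnL=cand_lnL,
            branch_lengths=fit_alt.branch_lengths, converged=fit_alt.converged,
        )
    elif cand_lnL > fit_null.lnL:
        repolish = _fit_model_a(
            engine, settings, True, fit_alt.branch_lengths,
            [(cand, fit_alt.branch_lengths)],
        )
        if repolish.lnL < cand_lnL:
            repolish = ModelAFit(
                params=cand, lnL=cand_lnL,
                branch_lengths=fit_alt.branch_lengths, converged=fit_alt.converged,
            )
        fit_null = repolish
    if fit_alt.lnL < fit_null.lnL:
        # the alternative contains the null; never report a deficit
        fit_alt = ModelAFit(
            params=replace(fit_null.params, null=False, omega2=1.0),
            lnL=fit_null.lnL,
            branch_lengths=fit_null.branch_lengths,
            converged=fit_null.converged,
        )
    lrt = LRTResult.from_lnls(fit_null.lnL, fit_alt.lnL)
    return fit_null, fit_alt, lrt


def branch_site_lrt(aln, ltree, settings: FitSettings = FitSettings()) -> LRTResult:
    """Convenience wrapper returning only the LRT."""
    return fit_branch_site(aln, ltree, settings)[2]
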