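"""Multi-start regularized fitting of the renal tissue models.

The inverse problem — ten free parameters from two tissue curves — is
non-convex, so a single descent run can land in a local minimum.  The
procedure used here:

1. draw ``n_starts`` initial parameter sets uniformly within the
   physiological ranges;
2. from each start run an *unconstrained* regularized least-squares fit
   of cortex and medulla curves jointly (positive parameters are
   log-transformed and fractions logit-transformed, so the unconstrained
   optimizer cannot produce negative transit times or fractions outside
   [0, 1], while no hard bounds act during the descent);
3. keep only solutions with every parameter inside the physiological
   bounds;
4. among the survivors return the one with the lowest chi-square
   (the unregularized data term, so selection compares fits to data).

Regularization is a weak quadratic pull toward the start values in the
transformed parameter space; its weight is expressed relative to the
data sum of squares so the objective is scale equivariant.  Ties in
chi-square resolve to the lowest start index, making the whole
procedure deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .curves import Curve
from .kinetic import (
    PARAM_NAMES,
    TWO_COMP_PARAM_NAMES,
    DerivedFlows,
    ParameterBounds,
    SevenCompParams,
    TwoCompParams,
    _seven_comp_values,
    _two_comp_values,
    derived_flows,
)
from .util import rng_stream

__all__ = [
    "FitConfig",
    "FitResult",
    "CandidateSolution",
    "single_fit",
    "iterated_fit",
    "fit_two_comp",
]

_POS_FLOOR = 1e-12
_FRAC_EPS = 1e-9


@dataclass(frozen=True)
class FitConfig:
    """Settings of the iterated fitting procedure.

    ``n_starts`` random initializations are drawn uniformly within
    ``init_ranges`` (defaulting to the physiological bounds used for the
    post-hoc filter).  ``regularization_weight`` is relative to the data
    sum of squares; the default 1e-6 makes the penalty a conditioner and
    tie-breaker that does not detectably bias parameters or scatter
    repeated runs, while larger values (1e-4..1e-3) give a visibly
    stronger pull toward the start values.  ``fixed_params`` pins named
    parameters at given values and removes them from the optimization.
    """

    n_starts: int = 100
    bounds: ParameterBounds | None = None
    init_ranges: ParameterBounds | None = None
    regularization_weight: float = 1e-6
    rng_seed: int = 0
    max_iterations: int = 200
    convergence_tolerance: float = 1e-8
    fixed_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        if self.regularization_weight < 0:
            raise ValueError("regularization_weight must be >= 0")


@dataclass(frozen=True)
class CandidateSolution:
    """One multi-start candidate: raw parameter vector + data chi-square."""

    x: np.ndarray
    chi_square: float
    converged: bool
    start_index: int = -1


@dataclass(frozen=True)
class FitResult:
    """Outcome of the iterated fit.

    ``status`` is ``"ok"`` when an in-bounds solution exists, in which
    case ``params`` minimizes the data chi-square among in-bounds
    candidates; ``"no_in_bounds_solution"`` carries the best out-of-bounds
    candidate for diagnostics; ``"failed"`` means no start converged.
    """

    params: SevenCompParams | TwoCompParams | None
    derived: DerivedFlows | None
    chi_square: float
    n_starts_converged: int
    n_in_bounds: int
    selected_start_index: int
    status: str
    model: str
    best_out_of_bounds: CandidateSolution | None = None

    def to_dict(self) -> dict:
        d = {
            "model": self.model,
            "status": self.status,
            "chi_square": self.chi_square,
            "n_starts_converged": self.n_starts_converged,
            "n_in_bounds": self.n_in_bounds,
            "selected_start_index": self.selected_start_index,
            "params": None if self.params is None else self.params.to_dict(),
        }
        if self.derived is not None:
            d["derived"] = {"f_med": self.derived.f_med, "f_t": self.derived.f_t}
        return d


# ---------------------------------------------------------------------------
# parameter transforms


class _ModelSpace:
    """Maps between physical parameters and the unconstrained fit space."""

    def __init__(self, names, logit_mask, forward, default_bounds):
        self.names = names
        self.logit_mask = np.asarray(logit_mask, dtype=bool)
        self.forward = forward
        self.default_bounds = default_bounds

    def to_internal(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        u = np.empty_like(x)
        pos = ~self.logit_mask
        u[pos] = np.log(np.maximum(x[pos], _POS_FLOOR))
        f = np.clip(x[self.logit_mask], _FRAC_EPS, 1.0 - _FRAC_EPS)
        u[self.logit_mask] = np.log(f / (1.0 - f))
        return u

    def to_physical(self, u: np.ndarray) -> np.ndarray:
        # clip keeps exp finite when the optimizer takes a wild step
        u = np.clip(np.asarray(u, dtype=float), -80.0, 80.0)
        x = np.empty_like(u)
        pos = ~self.logit_mask
        x[pos] = np.exp(u[pos])
        x[self.logit_mask] = expit(u[self.logit_mask])
        return x


def _seven_forward(x: np.ndarray, aif: Curve) -> tuple[np.ndarray, np.ndarray]:
    return _seven_comp_values(x, aif.v, aif.dt)


def _two_forward(x: np.ndarray, aif: Curve) -> tuple[np.ndarray, np.ndarray]:
    return _two_comp_values(x, aif.v, aif.dt), np.empty(0)


_SEVEN_SPACE = _ModelSpace(
    names=PARAM_NAMES,
    logit_mask=[False] * 8 + [True, True],
    forward=_seven_forward,
    default_bounds=ParameterBounds.seven_comp_default,
)

_TWO_SPACE = _ModelSpace(
    names=TWO_COMP_PARAM_NAMES,
    logit_mask=[False] * 4,
    forward=_two_forward,
    default_bounds=ParameterBounds.two_comp_default,
)


# ---------------------------------------------------------------------------
# single descent run


def _fit_from_start(
    space: _ModelSpace,
    data: np.ndarray,
    aif: Curve,
    x_init: np.ndarray,
    cfg: FitConfig,
    start_index: int = -1,
) -> CandidateSolution:
    names = space.names
    free = np.array([n not in cfg.fixed_params for n in names])
    x_full = np.asarray(x_init, dtype=float).copy()
    for n, v in cfg.fixed_params.items():
        if n not in names:
            raise ValueError(f"unknown fixed parameter {n!r}")
        x_full[list(names).index(n)] = v

    u0_full = space.to_internal(x_full)
    u0 = u0_full[free]

    ss_data = float(np.dot(data, data))
    n_free = int(free.sum())
    lam = cfg.regularization_weight * ss_data / max(n_free, 1)
    sqrt_lam = np.sqrt(lam)

    def residuals(u):
        u_full = u0_full.copy()
        u_full[free] = u
        x = space.to_physical(u_full)
        a, b = space.forward(x, aif)
        model = np.concatenate([a, b])
        r = model - data
        if sqrt_lam > 0:
            r = np.concatenate([r, sqrt_lam * (u - u0)])
        return r

    try:
        sol = least_squares(
            residuals,
            u0,
            method="lm",
            xtol=cfg.convergence_tolerance,
            ftol=cfg.convergence_tolerance,
            gtol=cfg.convergence_tolerance,
            max_nfev=cfg.max_iterations * (n_free + 1),
        )
        u_full = u0_full.copy()
        u_full[free] = sol.x
        x_hat = space.to_physical(u_full)
        a, b = space.forward(x_hat, aif)
        chi2 = float(np.sum((np.concatenate([a, b]) - data) ** 2))
        return CandidateSolution(x_hat, chi2, bool(sol.status > 0), start_index)
    except Exception:
        return CandidateSolution(x_full, np.inf, False, start_index)


def single_fit(
    c_cor: Curve,
    c_med: Curve,
    aif_plasma: Curve,
    init: SevenCompParams,
    cfg: FitConfig,
) -> CandidateSolution:
    """One regularized unconstrained descent of the 7-compartment model.

    Minimizes the joint sum of squares over cortex and medulla (equal
    weighting) plus the weak quadratic pull toward ``init``, in
    log/logit-transformed space.  Returns the candidate with its data
    chi-square; optimizer failure flags the candidate, it is not fatal.
    """
    _check_grids(aif_plasma, c_cor, c_med)
    data = np.concatenate([c_cor.v, c_med.v])
    return _fit_from_start(_SEVEN_SPACE, data, aif_plasma, init.to_array(), cfg)


def _check_grids(aif: Curve, *others: Curve) -> None:
    for c in others:
        if not aif.same_grid(c):
            raise ValueError("all curves must share one time grid")


# ---------------------------------------------------------------------------
# multi-start procedure


def _sample_starts(space, cfg: FitConfig, n_params: int) -> np.ndarray:
    init_b = cfg.init_ranges or cfg.bounds or space.default_bounds()
    rng = rng_stream(cfg.rng_seed, "starts")
    return rng.uniform(init_b.lower, init_b.upper, size=(cfg.n_starts, n_params))


def _select(space, candidates, bounds, model: str) -> FitResult:
    converged = [c for c in candidates if c.converged]
    in_bounds = [c for c in converged if bounds.contains(c.x)]
    n_conv, n_ib = len(converged), len(in_bounds)

    if not converged:
        return FitResult(None, None, np.inf, 0, 0, -1, "failed", model)

    def _pack(x):
        if model == "7c":
            p = SevenCompParams.from_array(x)
            return p, derived_flows(p)
        return TwoCompParams.from_array(x), None

    if not in_bounds:
        best = min(converged, key=lambda c: (c.chi_square, c.start_index))
        return FitResult(
            None, None, np.inf, n_conv, 0, -1,
            "no_in_bounds_solution", model, best_out_of_bounds=best,
        )

    best = min(in_bounds, key=lambda c: (c.chi_square, c.start_index))
    params, der = _pack(best.x)
    return FitResult(
        params, der, best.chi_square, n_conv, n_ib, best.start_index, "ok", model
    )


def _iterated(space, data, aif, cfg: FitConfig, model: str) -> FitResult:
    bounds = cfg.bounds or space.default_bounds()
    starts = _sample_starts(space, cfg, len(space.names))
    candidates = [
        _fit_from_start(space, data, aif, starts[i], cfg, start_index=i)
        for i in range(cfg.n_starts)
    ]
    return _select(space, candidates, bounds, model)


def iterated_fit(
    c_cor: Curve,
    c_med: Curve,
    aif_plasma: Curve,
    cfg: FitConfig,
) -> FitResult:
    """The full multi-start procedure for the 7-compartment model.

    ``cfg.n_starts`` independent descents from random starts, a
    physiological-bounds filter, then lowest-chi-square selection.
    Deterministic given ``cfg.rng_seed``.  All-zero tissue curves
    short-circuit to a zero-flow result.
    """
    _check_grids(aif_plasma, c_cor, c_med)
    if not np.any(c_cor.v) and not np.any(c_med.v):
        bounds = cfg.bounds or ParameterBounds.seven_comp_default()
        mid = 0.5 * (bounds.lower + bounds.upper)
        mid[7:] = 0.0  # f_cor, e_med, e_ff
        p = SevenCompParams.from_array(mid)
        return FitResult(p, derived_flows(p), 0.0, cfg.n_starts, cfg.n_starts, 0, "ok", "7c")
    data = np.concatenate([c_cor.v, c_med.v])
    return _iterated(_SEVEN_SPACE, data, aif_plasma, cfg, "7c")


def fit_two_comp(c_parenchyma: Curve, aif_plasma: Curve, cfg: FitConfig) -> FitResult:
    """Multi-start fit of the two-compartment filtration model.

    The input curve is the cortex curve or a volume-weighted parenchyma
    curve — the caller chooses.  ``cfg.bounds``/``init_ranges`` must be
    4-parameter bounds (``f_p, t_p, f_t, t_t``) or None for defaults.
    """
    _check_grids(aif_plasma, c_parenchyma)
    if not np.any(c_parenchyma.v):
        p = TwoCompParams(0.0, 10.0, 0.0, 60.0)
        return FitResult(p, None, 0.0, cfg.n_starts, cfg.n_starts, 0, "ok", "2c")
    return _iterated(_TWO_SPACE, c_parenchyma.v.copy(), aif_plasma, cfg, "2c")
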