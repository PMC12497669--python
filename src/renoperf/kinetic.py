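"""Compartmental impulse responses and forward renal tissue models.

The kidney is described as seven well-mixed compartments in series/parallel:
three plasma spaces — arterial plasma (PA, cortex), vasa recta (VR, medulla)
and venous plasma (PV, cortex) — and four tubular spaces — proximal tubules
(PT, cortex), loop of Henle (LH, medulla), distal tubules (DT, cortex) and
collecting ducts (CD, medulla).  Tracer entering the cortex with plasma flow
``F_cor`` is either filtered into the tubular chain (fraction ``E_FF``, the
filtration fraction) or stays vascular; unfiltered plasma either passes
through the vasa recta (fraction ``E_med`` of the unfiltered flow, the
medullary flow fraction) or drains directly to venous plasma.

Each compartment has an exponential residue function
``R_X(t) = exp(-t/MTT_X)`` and propagator ``H_X = R_X / MTT_X``; chains of
compartments act by convolution.  The measurable cortex and medulla
concentration curves are sums over the compartments in each region; the
fractional volumes cancel in those sums and are never represented.

Derived quantities:

* tubular flow (GFR per 100 mL of tissue)  ``F_T  = E_FF · F_cor``
* inner-medullary perfusion                ``F_med = E_med · (1 − E_FF) · F_cor``

Flows are reported in mL/100mL/min and converted internally to fractional
flow per second (divide by 6000) so that flow × time × concentration is a
concentration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter

from .curves import Curve

__all__ = [
    "SevenCompParams",
    "TwoCompParams",
    "DerivedFlows",
    "ParameterBounds",
    "FLOW_PER_SECOND",
    "exp_propagate",
    "exp_residue",
    "seven_comp_tissue",
    "two_comp_tissue",
    "derived_flows",
]

#: mL/100mL/min -> fractional flow per second
FLOW_PER_SECOND = 1.0 / 6000.0

#: order of the free parameters everywhere (vectors, bounds, fit space)
PARAM_NAMES = (
    "mtt_pa",
    "mtt_pv",
    "mtt_vr",
    "mtt_pt",
    "mtt_lh",
    "mtt_dt",
    "mtt_cd",
    "f_cor",
    "e_med",
    "e_ff",
)

TWO_COMP_PARAM_NAMES = ("f_p", "t_p", "f_t", "t_t")


@dataclass(frozen=True)
class SevenCompParams:
    """The 10 free parameters of the seven-compartment model.

    Mean transit times in seconds, ``f_cor`` in mL/100mL/min, ``e_med``
    and ``e_ff`` dimensionless fractions in [0, 1].
    """

    mtt_pa: float
    mtt_pv: float
    mtt_vr: float
    mtt_pt: float
    mtt_lh: float
    mtt_dt: float
    mtt_cd: float
    f_cor: float
    e_med: float
    e_ff: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES[:7]:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.f_cor < 0:
            raise ValueError("f_cor must be >= 0")
        if not 0.0 <= self.e_med <= 1.0:
            raise ValueError("e_med must be in [0, 1]")
        if not 0.0 <= self.e_ff <= 1.0:
            raise ValueError("e_ff must be in [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @staticmethod
    def from_array(x: np.ndarray) -> "SevenCompParams":
        return SevenCompParams(**dict(zip(PARAM_NAMES, map(float, x))))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}


@dataclass(frozen=True)
class TwoCompParams:
    """Plasma + tubule filtration model parameters.

    ``f_p``/``f_t`` in mL/100mL/min, ``t_p``/``t_t`` (mean transit times)
    in seconds.
    """

    f_p: float
    t_p: float
    f_t: float
    t_t: float

    def __post_init__(self) -> None:
        if self.f_p < 0 or self.f_t < 0:
            raise ValueError("flows must be >= 0")
        if self.t_p <= 0 or self.t_t <= 0:
            raise ValueError("transit times must be > 0")

    def to_array(self) -> np.ndarray:
        return np.array([self.f_p, self.t_p, self.f_t, self.t_t], dtype=float)

    @staticmethod
    def from_array(x: np.ndarray) -> "TwoCompParams":
        return TwoCompParams(*map(float, x))

    def to_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in TWO_COMP_PARAM_NAMES}


@dataclass(frozen=True)
class DerivedFlows:
    """Inner-medullary perfusion and tubular flow, mL/100mL/min."""

    f_med: float
    f_t: float


@dataclass(frozen=True)
class ParameterBounds:
    """Physiological lower/upper bounds per free parameter.

    Defaults are the published physiological ranges: MTT_PA 0–15 s,
    MTT_PV 1–20 s, MTT_VR 50–200 s, tubular MTTs 1–100 s, F_cor
    0–1000 mL/100mL/min, fractions 0–1.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float)
        hi = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape:
            raise ValueError("lower and upper must have the same shape")
        if not np.all(lo < hi):
            raise ValueError("need lower < upper elementwise")

    @staticmethod
    def seven_comp_default() -> "ParameterBounds":
        return ParameterBounds(
            lower=np.array([0.0, 1.0, 50.0, 1.0, 1.0, 1.0, 1.0, 0.0, 0.0, 0.0]),
            upper=np.array([15.0, 20.0, 200.0, 100.0, 100.0, 100.0, 100.0, 1000.0, 1.0, 1.0]),
        )

    @staticmethod
    def two_comp_default() -> "ParameterBounds":
        # plasma flow / MTT, tubular flow / MTT: broad renal ranges
        return ParameterBounds(
            lower=np.array([0.0, 0.1, 0.0, 1.0]),
            upper=np.array([1000.0, 100.0, 1000.0, 600.0]),
        )

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))


# ---------------------------------------------------------------------------
# exponential-kernel convolution


def _check_mtt(mtt: float) -> float:
    mtt = float(mtt)
    if not np.isfinite(mtt) or mtt <= 0:
        raise ValueError(f"mtt must be positive and finite, got {mtt}")
    return mtt


def _prop_conv(v: np.ndarray, dt: float, mtt: float) -> np.ndarray:
    """H∗v on a uniform grid via the exact piecewise-linear recursion."""
    x = dt / mtt
    E = np.exp(-x)
    # (1-E)/x via expm1 for accuracy at small x
    one_minus_E_over_x = -np.expm1(-x) / x
    w1 = 1.0 - one_minus_E_over_x
    w0 = one_minus_E_over_x - E
    # recursion == IIR filter; correct for lfilter's implicit y[0] = w1*v[0]
    z = lfilter([w1, w0], [1.0, -E], v)
    if v[0] != 0.0:
        z = z - w1 * v[0] * E ** np.arange(len(v))
    z[0] = 0.0
    return z


def exp_propagate(c: Curve, mtt: float) -> Curve:
    """Convolve ``c`` with the normalized propagator ``H(t)=exp(-t/mtt)/mtt``.

    Uses the exact recursion for a piecewise-linear input: with
    ``x = dt/mtt`` and ``E = exp(-x)``,

        y[i+1] = E·y[i] + w0·c[i] + w1·c[i+1],
        w1 = 1 - (1-E)/x,   w0 = (1-E)/x - E,

    which is unconditionally stable and exact for linear interpolants of
    ``c`` — no Riemann-sum time-step bias.  Unit preserving: for an input
    of finite area the output area converges to it as the horizon grows.
    """
    mtt = _check_mtt(mtt)
    return c.with_values(_prop_conv(c.v, c.dt, mtt))


def exp_residue(c: Curve, mtt: float) -> Curve:
    """Convolve ``c`` with the residue function ``R(t)=exp(-t/mtt)``.

    Identically ``mtt × exp_propagate(c, mtt)`` since ``R = MTT·H``.
    """
    mtt = _check_mtt(mtt)
    out = exp_propagate(c, mtt)
    return out.with_values(mtt * out.v)


# ---------------------------------------------------------------------------
# forward tissue models


def _seven_comp_values(
    x: np.ndarray, aif_v: np.ndarray, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Array-level forward model (hot path for fitting; no validation).

    ``x`` in the PARAM_NAMES order; returns (cortex, medulla) values.
    """
    mtt_pa, mtt_pv, mtt_vr, mtt_pt, mtt_lh, mtt_dt, mtt_cd, f_cor, e_med, e_ff = x
    F = f_cor * FLOW_PER_SECOND

    h_pa = _prop_conv(aif_v, dt, mtt_pa)
    c_pa = mtt_pa * h_pa

    h_vr = _prop_conv(h_pa, dt, mtt_vr)
    c_vr = mtt_vr * h_vr
    c_pv_direct = mtt_pv * _prop_conv(h_pa, dt, mtt_pv)
    c_pv_via_vr = mtt_pv * _prop_conv(h_vr, dt, mtt_pv)

    h_pt = _prop_conv(h_pa, dt, mtt_pt)
    c_pt = mtt_pt * h_pt
    h_lh = _prop_conv(h_pt, dt, mtt_lh)
    c_lh = mtt_lh * h_lh
    h_dt = _prop_conv(h_lh, dt, mtt_dt)
    c_dt = mtt_dt * h_dt
    c_cd = mtt_cd * _prop_conv(h_dt, dt, mtt_cd)

    w_direct = (1.0 - e_ff) * (1.0 - e_med)
    w_medvasc = (1.0 - e_ff) * e_med

    cor = F * (c_pa + w_direct * c_pv_direct + w_medvasc * c_pv_via_vr + e_ff * (c_pt + c_dt))
    med = F * (w_medvasc * c_vr + e_ff * (c_lh + c_cd))
    return cor, med


def _two_comp_values(x: np.ndarray, aif_v: np.ndarray, dt: float) -> np.ndarray:
    f_p, t_p, f_t, t_t = x
    h_p = _prop_conv(aif_v, dt, t_p)
    c_p = t_p * h_p
    c_t = t_t * _prop_conv(h_p, dt, t_t)
    return FLOW_PER_SECOND * (f_p * c_p + f_t * c_t)


def seven_comp_tissue(p: SevenCompParams, aif_plasma: Curve) -> tuple[Curve, Curve]:
    """Cortex and medulla concentration curves for a plasma AIF.

    The tracer influx ``F·C_A`` (F the fractional plasma flow per second)
    passes PA; its outflow splits into the filtered tubular chain
    PT→LH→DT→CD (weight ``E_FF``), the vasa recta→venous path (weight
    ``E_med(1−E_FF)``) and the direct venous path (weight
    ``(1−E_med)(1−E_FF)``).  Cortex = PA + PV + PT + DT; medulla =
    VR + LH + CD; fractional volumes cancel in the sums.
    """
    cor, med = _seven_comp_values(p.to_array(), aif_plasma.v, aif_plasma.dt)
    return aif_plasma.with_values(cor), aif_plasma.with_values(med)


def two_comp_tissue(p: TwoCompParams, aif_plasma: Curve) -> Curve:
    """Two-compartment filtration model: plasma feeding a tubular space.

    ``C(t) = F_p·R_p∗C_A + F_t·R_t∗H_p∗C_A`` — the seven-compartment
    model restricted to its PA→PT sub-chain.
    """
    return aif_plasma.with_values(
        _two_comp_values(p.to_array(), aif_plasma.v, aif_plasma.dt)
    )


def derived_flows(p: SevenCompParams) -> DerivedFlows:
    """Inner-medullary perfusion and tubular flow from the free parameters."""
    return DerivedFlows(
        f_med=p.e_med * (1.0 - p.e_ff) * p.f_cor,
        f_t=p.e_ff * p.f_cor,
    )
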