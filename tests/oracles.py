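"""Independent reference implementations used only for verification.

These deliberately avoid the package's fast recursions: convolution by
direct trapezoidal quadrature, and the tissue models by numerically
integrating the coupled compartment mass-balance ODEs with a stiff
solver.  They are slow and exist solely as oracles.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from renoperf.curves import Curve
from renoperf.kinetic import FLOW_PER_SECOND, SevenCompParams, TwoCompParams


def quadrature_conv(kernel, c: Curve, oversample: int = 1) -> np.ndarray:
    """y(t_i) = ∫_0^{t_i} K(t_i − s)·c(s) ds by trapezoidal quadrature.

    ``oversample`` refines the quadrature grid by linear interpolation of
    ``c`` (the integrand K·c is not piecewise-linear, so the trapezoid
    rule on the acquisition grid carries its own O(dt²) bias; refining
    the grid shrinks it without changing the continuous problem).
    """
    t, v = c.t, c.v
    n_fine = (len(t) - 1) * oversample + 1
    t_f = np.linspace(t[0], t[-1], n_fine)
    v_f = np.interp(t_f, t, v)
    y = np.zeros_like(v)
    for i in range(1, len(t)):
        j = i * oversample
        s = t_f[: j + 1]
        y[i] = np.trapezoid(kernel(t[i] - s) * v_f[: j + 1], s)
    return y


def _aif_interp(aif: Curve):
    return lambda tt: np.interp(tt, aif.t, aif.v)


def ode_seven_comp(p: SevenCompParams, aif: Curve) -> tuple[np.ndarray, np.ndarray]:
    """Cortex/medulla curves by integrating the 7 coupled mass balances.

    State: tracer amount per unit tissue volume in PA, VR, PV, PT, LH,
    DT, CD.  The arterial outflow splits into the filtered tubular chain
    (E_FF), the vasa recta route (E_med(1−E_FF)) and the direct venous
    route; each compartment drains with rate 1/MTT.
    """
    F = p.f_cor * FLOW_PER_SECOND
    ca = _aif_interp(aif)

    def rhs(t, q):
        q_pa, q_vr, q_pv, q_pt, q_lh, q_dt, q_cd = q
        out_pa = q_pa / p.mtt_pa
        return [
            F * ca(t) - out_pa,
            p.e_med * (1 - p.e_ff) * out_pa - q_vr / p.mtt_vr,
            (1 - p.e_med) * (1 - p.e_ff) * out_pa + q_vr / p.mtt_vr - q_pv / p.mtt_pv,
            p.e_ff * out_pa - q_pt / p.mtt_pt,
            q_pt / p.mtt_pt - q_lh / p.mtt_lh,
            q_lh / p.mtt_lh - q_dt / p.mtt_dt,
            q_dt / p.mtt_dt - q_cd / p.mtt_cd,
        ]

    sol = solve_ivp(
        rhs,
        (aif.t[0], aif.t[-1]),
        np.zeros(7),
        t_eval=aif.t,
        method="LSODA",
        rtol=1e-9,
        atol=1e-13,
        max_step=aif.dt,
    )
    q_pa, q_vr, q_pv, q_pt, q_lh, q_dt, q_cd = sol.y
    cor = q_pa + q_pv + q_pt + q_dt
    med = q_vr + q_lh + q_cd
    return cor, med


def ode_two_comp(p: TwoCompParams, aif: Curve) -> np.ndarray:
    """Plasma→tubule series model by ODE integration."""
    fp = p.f_p * FLOW_PER_SECOND
    ft = p.f_t * FLOW_PER_SECOND
    ca = _aif_interp(aif)

    def rhs(t, q):
        q_p, q_t = q
        # q_p is the plasma amount for unit inflow; tubular influx samples
        # the plasma *outflow* concentration scaled by the tubular flow
        return [ca(t) - q_p / p.t_p, q_p / p.t_p - q_t / p.t_t]

    sol = solve_ivp(
        rhs,
        (aif.t[0], aif.t[-1]),
        np.zeros(2),
        t_eval=aif.t,
        method="LSODA",
        rtol=1e-9,
        atol=1e-13,
        max_step=aif.dt,
    )
    q_p, q_t = sol.y
    return fp * q_p + ft * q_t


def anova_icc(M: np.ndarray, form: str) -> float:
    """ICC from an explicit two-way ANOVA decomposition (loops, no shortcuts)."""
    M = np.asarray(M, dtype=float)
    n, k = M.shape
    grand = M.sum() / (n * k)
    ss_r = sum(k * (M[i].mean() - grand) ** 2 for i in range(n))
    ss_c = sum(n * (M[:, j].mean() - grand) ** 2 for j in range(k))
    ss_e = 0.0
    for i in range(n):
        for j in range(k):
            ss_e += (M[i, j] - M[i].mean() - M[:, j].mean() + grand) ** 2
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    if form == "consistency":
        return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
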