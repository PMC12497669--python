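"""Reliability and accuracy statistics, and the simulation experiment drivers.

Covers the statistics used to characterize the fitting procedure:

* coefficient of variation (CoV = sample SD / mean) of repeated fits —
  zero for a perfectly stable iterated fit;
* intraclass correlation coefficients from the two-way ANOVA mean
  squares, in the consistency form (insensitive to a systematic offset
  between raters) and the absolute-agreement form (penalizing it);
* ordinary least-squares regression with R², and Bland–Altman limits of
  agreement for method comparison;

and the experiment drivers that apply them: the stability experiment
(repeat the multi-start fit with different seeds, CoV per parameter),
the accuracy experiment (fit vs. ground truth, % deviation and ICC) and
the 7- vs 2-compartment model comparison.

Conventions: sample SD uses the n−1 denominator throughout; quantiles
(for IQRs) use linear interpolation; CoV with a zero mean is reported
as missing and excluded from medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import FitConfig, FitResult, fit_two_comp, iterated_fit
from .signalmodel import AcquisitionSpec, signal_to_contrast
from .synthetic import SyntheticDataset
from .util import stream_seed

__all__ = [
    "cov",
    "icc",
    "linfit_r2",
    "bland_altman",
    "StabilityReport",
    "AccuracyReport",
    "ComparisonReport",
    "run_stability_experiment",
    "run_accuracy_experiment",
    "run_model_comparison",
]

#: parameters tracked in reports: the 10 free ones plus the derived flows
REPORT_PARAMS = (
    "f_med",
    "f_cor",
    "f_t",
    "mtt_pa",
    "mtt_pv",
    "mtt_vr",
    "mtt_pt",
    "mtt_lh",
    "mtt_dt",
    "mtt_cd",
    "e_med",
    "e_ff",
)


# ---------------------------------------------------------------------------
# scalar statistics


def cov(values) -> float:
    """Coefficient of variation: sample SD (n−1) over mean."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("cov needs at least 2 values")
    m = v.mean()
    if m == 0:
        raise ValueError("cov undefined for zero mean")
    return float(v.std(ddof=1) / m)


def _anova_mean_squares(M: np.ndarray):
    n, k = M.shape
    grand = M.mean()
    rows = M.mean(axis=1)
    cols = M.mean(axis=0)
    ms_r = k * np.sum((rows - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = M - rows[:, None] - cols[None, :] + grand
    ms_e = np.sum(resid**2) / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def icc(matrix, form: str = "consistency") -> float:
    """Single-measurement intraclass correlation from two-way ANOVA.

    ``matrix`` is subjects × raters.  ``consistency`` =
    (MS_R−MS_E)/(MS_R+(k−1)MS_E); ``agreement`` additionally carries the
    rater variance term k(MS_C−MS_E)/n in the denominator.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("matrix must be subjects x raters with n>=2, k>=2")
    n, k = M.shape
    ms_r, ms_c, ms_e = _anova_mean_squares(M)
    denom = ms_r + (k - 1) * ms_e
    if form == "agreement":
        denom = denom + k * (ms_c - ms_e) / n
    elif form != "consistency":
        raise ValueError("form must be 'consistency' or 'agreement'")
    if denom == 0:
        raise ValueError("degenerate variance: ICC undefined")
    return float((ms_r - ms_e) / denom)


def linfit_r2(x, y) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (slope, intercept, R²).

    R² is the squared Pearson correlation; for constant y (nothing to
    explain) slope is 0 and R² is reported as 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.var(x) == 0:
        raise ValueError("zero variance in x")
    if np.var(y) == 0:
        return 0.0, float(y.mean()), 0.0
    slope, intercept = np.polyfit(x, y, 1)
    r = np.corrcoef(x, y)[0, 1]
    return float(slope), float(intercept), float(r**2)


def bland_altman(x, y) -> tuple[float, float, float]:
    """Mean difference (y−x) and 95% limits of agreement (±1.96 SD)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    d = y - x
    m = float(d.mean())
    sd = float(d.std(ddof=1))
    return m, m - 1.96 * sd, m + 1.96 * sd


# ---------------------------------------------------------------------------
# report containers


def _summarize(table: pd.DataFrame, value_col: str) -> pd.DataFrame:
    rows = []
    for p in REPORT_PARAMS:
        vals = table.loc[table["parameter"] == p, value_col].dropna().to_numpy()
        if len(vals) == 0:
            rows.append({"parameter": p, "median": np.nan, "q25": np.nan, "q75": np.nan})
        else:
            q25, med, q75 = np.percentile(vals, [25, 50, 75])
            rows.append({"parameter": p, "median": med, "q25": q25, "q75": q75})
    return pd.DataFrame(rows).set_index("parameter")


@dataclass(frozen=True)
class StabilityReport:
    """Per-curve, per-parameter CoV over repeated iterated fits (in %)."""

    table: pd.DataFrame  # columns: dataset, parameter, cov_pct
    summary: pd.DataFrame  # index parameter: median/q25/q75 of cov_pct
    n_repeats: int

    def median_cov_pct(self, parameter: str) -> float:
        return float(self.summary.loc[parameter, "median"])


@dataclass(frozen=True)
class AccuracyReport:
    """Per-curve % deviation from truth, with ICC and regression for F_med."""

    table: pd.DataFrame  # columns: dataset, parameter, fitted, true, deviation_pct
    summary: pd.DataFrame  # index parameter: median/q25/q75 of deviation_pct
    icc_f_med: float
    regression_f_med: tuple[float, float, float]  # slope, intercept, r2
    n_failed: int

    def median_deviation_pct(self, parameter: str) -> float:
        return float(self.summary.loc[parameter, "median"])


@dataclass(frozen=True)
class ComparisonReport:
    """Paired 7- vs 2-compartment estimates of F_cor and F_T."""

    table: pd.DataFrame  # columns: dataset, f_cor_7c, f_cor_2c, f_t_7c, f_t_2c
    stats: dict  # per quantity: icc_consistency, regression, bland_altman


# ---------------------------------------------------------------------------
# experiment drivers


def _fit_params_dict(res: FitResult) -> dict | None:
    if res.status != "ok" or res.params is None:
        return None
    d = res.params.to_dict()
    d["f_med"] = res.derived.f_med
    d["f_t"] = res.derived.f_t
    return d


def _prepare_curves(ds: SyntheticDataset, spec: AcquisitionSpec):
    """Noisy curves through the measurement convention: baseline-subtracted."""
    aif = signal_to_contrast(ds.noisy["aif"], spec)
    c_cor = signal_to_contrast(ds.noisy["c_cor"], spec)
    c_med = signal_to_contrast(ds.noisy["c_med"], spec)
    return aif, c_cor, c_med


def run_stability_experiment(
    datasets: list[SyntheticDataset],
    n_repeats: int = 50,
    cfg: FitConfig | None = None,
    spec: AcquisitionSpec | None = None,
    seed: int = 0,
) -> StabilityReport:
    """Sensitivity to initial values: repeat the iterated fit per dataset.

    Each repeat re-runs the full multi-start procedure with a different
    seed (hence different random starts) on the *same* noisy curves; the
    CoV over repeats, per parameter, quantifies fit stability (0 = the
    procedure always lands on the same solution).  Fit failures are
    recorded as missing, not fatal.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    cfg = cfg or FitConfig()
    spec = spec or AcquisitionSpec()
    rows = []
    for d_idx, ds in enumerate(datasets):
        aif, c_cor, c_med = _prepare_curves(ds, spec)
        repeats: list[dict] = []
        for r in range(n_repeats):
            rcfg = FitConfig(
                n_starts=cfg.n_starts,
                bounds=cfg.bounds,
                init_ranges=cfg.init_ranges,
                regularization_weight=cfg.regularization_weight,
                rng_seed=stream_seed(seed, "stability", d_idx, r),
                max_iterations=cfg.max_iterations,
                convergence_tolerance=cfg.convergence_tolerance,
                fixed_params=cfg.fixed_params,
            )
            p = _fit_params_dict(iterated_fit(c_cor, c_med, aif, rcfg))
            if p is not None:
                repeats.append(p)
        for param in REPORT_PARAMS:
            vals = np.array([rep[param] for rep in repeats]) if repeats else np.empty(0)
            if len(vals) < 2 or vals.mean() == 0:
                c = np.nan
            else:
                c = 100.0 * cov(vals)
            rows.append({"dataset": d_idx, "parameter": param, "cov_pct": c})
    table = pd.DataFrame(rows)
    return StabilityReport(table, _summarize(table, "cov_pct"), n_repeats)


def run_accuracy_experiment(
    datasets: list[SyntheticDataset],
    cfg: FitConfig | None = None,
    spec: AcquisitionSpec | None = None,
    seed: int = 0,
    use_noisy: bool = True,
) -> AccuracyReport:
    """One iterated fit per dataset, compared against the ground truth.

    Reports the % deviation (fitted−true)/true·100 per parameter, its
    median and IQR across curves, and — for the target parameter, the
    inner-medullary perfusion — the absolute-agreement ICC and the
    fitted-vs-true regression line.
    """
    if not datasets:
        raise ValueError("need at least one dataset")
    cfg = cfg or FitConfig()
    spec = spec or AcquisitionSpec()
    rows = []
    fitted_fmed, true_fmed = [], []
    n_failed = 0
    from .kinetic import derived_flows

    for d_idx, ds in enumerate(datasets):
        if use_noisy:
            aif, c_cor, c_med = _prepare_curves(ds, spec)
        else:
            aif, (c_cor, c_med) = ds.aif, ds.clean
        rcfg = FitConfig(
            n_starts=cfg.n_starts,
            bounds=cfg.bounds,
            init_ranges=cfg.init_ranges,
            regularization_weight=cfg.regularization_weight,
            rng_seed=stream_seed(seed, "accuracy", d_idx),
            max_iterations=cfg.max_iterations,
            convergence_tolerance=cfg.convergence_tolerance,
            fixed_params=cfg.fixed_params,
        )
        fit = _fit_params_dict(iterated_fit(c_cor, c_med, aif, rcfg))
        truth = ds.truth.to_dict()
        der = derived_flows(ds.truth)
        truth["f_med"], truth["f_t"] = der.f_med, der.f_t
        if fit is None:
            n_failed += 1
            continue
        fitted_fmed.append(fit["f_med"])
        true_fmed.append(truth["f_med"])
        for param in REPORT_PARAMS:
            tv = truth[param]
            dev = np.nan if tv == 0 else 100.0 * (fit[param] - tv) / tv
            rows.append(
                {
                    "dataset": d_idx,
                    "parameter": param,
                    "fitted": fit[param],
                    "true": tv,
                    "deviation_pct": dev,
                }
            )
    table = pd.DataFrame(
        rows, columns=["dataset", "parameter", "fitted", "true", "deviation_pct"]
    )
    if len(fitted_fmed) >= 2:
        icc_fm = icc(np.column_stack([true_fmed, fitted_fmed]), form="agreement")
    else:
        icc_fm = np.nan
    reg = (
        linfit_r2(true_fmed, fitted_fmed)
        if len(fitted_fmed) >= 3
        else (np.nan, np.nan, np.nan)
    )
    return AccuracyReport(table, _summarize(table, "deviation_pct"), icc_fm, reg, n_failed)


def run_model_comparison(
    datasets: list[SyntheticDataset],
    cfg: FitConfig | None = None,
    spec: AcquisitionSpec | None = None,
    seed: int = 0,
    cortex_fraction: float = 0.7,
) -> ComparisonReport:
    """Paired 7- vs 2-compartment estimates of cortical perfusion and F_T.

    The 2-compartment filtration model is fitted to a volume-weighted
    parenchymal curve (``cortex_fraction``·cortex + rest·medulla,
    default 0.7 — the cortex dominates parenchymal volume).  Reports
    consistency ICC, OLS regression and Bland–Altman limits for each
    shared quantity.  An empty dataset list yields an empty report.
    """
    cfg = cfg or FitConfig()
    spec = spec or AcquisitionSpec()
    rows = []
    for d_idx, ds in enumerate(datasets):
        aif, c_cor, c_med = _prepare_curves(ds, spec)
        parenchyma = c_cor.with_values(
            cortex_fraction * c_cor.v + (1.0 - cortex_fraction) * c_med.v
        )
        cfg7 = FitConfig(
            n_starts=cfg.n_starts,
            bounds=cfg.bounds,
            init_ranges=cfg.init_ranges,
            regularization_weight=cfg.regularization_weight,
            rng_seed=stream_seed(seed, "cmp7", d_idx),
            max_iterations=cfg.max_iterations,
            convergence_tolerance=cfg.convergence_tolerance,
        )
        cfg2 = FitConfig(
            n_starts=cfg.n_starts,
            regularization_weight=cfg.regularization_weight,
            rng_seed=stream_seed(seed, "cmp2", d_idx),
            max_iterations=cfg.max_iterations,
            convergence_tolerance=cfg.convergence_tolerance,
        )
        r7 = iterated_fit(c_cor, c_med, aif, cfg7)
        r2c = fit_two_comp(parenchyma, aif, cfg2)
        if r7.status != "ok" or r2c.status != "ok":
            continue
        rows.append(
            {
                "dataset": d_idx,
                "f_cor_7c": r7.params.f_cor,
                "f_cor_2c": r2c.params.f_p,
                "f_t_7c": r7.derived.f_t,
                "f_t_2c": r2c.params.f_t,
            }
        )
    table = pd.DataFrame(
        rows, columns=["dataset", "f_cor_7c", "f_cor_2c", "f_t_7c", "f_t_2c"]
    )
    stats: dict = {}
    for q in ("f_cor", "f_t"):
        a = table[f"{q}_2c"].to_numpy()
        b = table[f"{q}_7c"].to_numpy()
        if len(a) >= 3 and np.var(a) > 0:
            stats[q] = {
                "icc_consistency": icc(np.column_stack([a, b]), form="consistency"),
                "regression": linfit_r2(a, b),
                "bland_altman": bland_altman(a, b),
            }
        else:
            stats[q] = None
    return ComparisonReport(table, stats)
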