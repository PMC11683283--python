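"""Quantification formulas for the downstream assays.

* 4-parameter-logistic (4PL) dose-response fitting with a relative
  (inflection-point) IC50, multi-start least squares and a seeded bootstrap
  confidence interval;
* IC50 fold ratios with explicit nM/µM unit handling;
* scratch-wound healing rate;
* qPCR relative quantification by 2^-ΔΔCT;
* caliper tumor volume (V = width² x length / 2) and per-group growth
  summaries;
* ELISA-style fold activity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

logger = logging.getLogger(__name__)

__all__ = [
    "DoseResponseFit",
    "QPCRResult",
    "fit_4pl",
    "four_pl_curve",
    "absolute_ic50",
    "ic50_fold_ratio",
    "wound_healing_rate",
    "ddct_fold",
    "tumor_volume",
    "growth_summary",
    "fold_activity",
]

_UNIT_TO_NM = {"nM": 1.0, "uM": 1000.0, "µM": 1000.0, "μM": 1000.0, "pM": 1e-3, "mM": 1e6}


def four_pl_curve(dose, top: float, bottom: float, ic50: float, hill: float):
    """y = bottom + (top - bottom) / (1 + (dose/ic50)^hill); decreasing for hill > 0."""
    d = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (d / ic50) ** hill)


@dataclass(frozen=True)
class DoseResponseFit:
    top: float
    bottom: float
    hill: float
    ic50: float  # relative IC50 = inflection concentration, dose units
    rss: float
    converged: bool
    ci_ic50: tuple[float, float] | None = None
    message: str = ""


@dataclass(frozen=True)
class QPCRResult:
    ddct: float
    fold: float


def _residuals(params: np.ndarray, log_d: np.ndarray, y: np.ndarray) -> np.ndarray:
    top, bottom, log_ic50, hill = params
    pred = bottom + (top - bottom) / (1.0 + np.exp(hill * (log_d - log_ic50) * np.log(10.0)))
    # hill enters via 10^(hill*(log d - log ic50)) so the fit is scale-equivariant
    return pred - y


def fit_4pl(
    doses: Sequence[float],
    responses: Sequence[float],
    n_boot: int = 200,
    seed: int = 0,
) -> DoseResponseFit:
    """Least-squares 4PL fit in log-dose space with multi-start initialization.

    `doses` and `responses` are parallel vectors (replicates appear as
    repeated doses).  Initialization scans a grid of log10(IC50) values over
    the dose range combined with hill slopes {0.5, 1, 2}; the lowest-RSS
    solution wins.  The bootstrap CI resamples observations within each dose
    (seeded).  If the data show no transition inside the dose range the fit
    is flagged ``converged=False`` with a diagnostic message.
    """
    d = np.asarray(doses, dtype=float)
    y = np.asarray(responses, dtype=float)
    if d.size != y.size:
        raise ValueError("doses and responses lengths differ")
    if np.unique(d).size < 4:
        raise ValueError("need at least 4 distinct doses")
    if (d <= 0).any():
        raise ValueError("doses must be positive")
    log_d = np.log10(d)

    def _single_fit(ld: np.ndarray, yy: np.ndarray):
        span = yy.max() - yy.min()
        best = None
        lo, hi = ld.min(), ld.max()
        bounds = (
            [yy.min() - span, yy.min() - span, lo - 3.0, 0.05],
            [yy.max() + span, yy.max() + span, hi + 3.0, 20.0],
        )
        for lic in np.linspace(lo, hi, 7):
            for hill0 in (0.5, 1.0, 2.0):
                x0 = np.array([yy.max(), yy.min(), lic, hill0])
                try:
                    sol = least_squares(_residuals, x0, args=(ld, yy), bounds=bounds)
                except ValueError:
                    continue
                rss = float(np.sum(sol.fun**2))
                if best is None or rss < best[1]:
                    best = (sol, rss)
        return best

    best = _single_fit(log_d, y)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                               message="optimizer failed from every start")
    sol, rss = best
    top, bottom, log_ic50, hill = sol.x
    ic50 = float(10.0**log_ic50)

    msg = ""
    converged = bool(sol.success)
    if not (d.min() <= ic50 <= d.max()):
        converged = False
        msg = "no transition inside the dose range (fitted IC50 outside tested doses)"
    elif abs(top - bottom) < 3.0 * np.sqrt(rss / max(d.size - 4, 1)):
        converged = False
        msg = "response span indistinguishable from residual noise"

    ci = None
    if converged and n_boot > 0:
        rng = np.random.default_rng(seed)
        groups = {dv: np.flatnonzero(d == dv) for dv in np.unique(d)}
        boots = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [rng.choice(ix, size=ix.size, replace=True) for ix in groups.values()]
            )
            b = _single_fit(log_d[idx], y[idx])
            if b is not None and b[0].success:
                boots.append(10.0 ** b[0].x[2])
        if len(boots) >= 20:
            ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))

    return DoseResponseFit(
        top=float(top), bottom=float(bottom), hill=float(hill), ic50=ic50,
        rss=rss, converged=converged, ci_ic50=ci, message=msg,
    )


def absolute_ic50(fit: DoseResponseFit, reference: float = 100.0) -> float:
    """Dose at which the fitted curve crosses half of `reference` (absolute IC50)."""
    half = reference / 2.0
    if not (min(fit.bottom, fit.top) < half < max(fit.bottom, fit.top)):
        raise ValueError("curve never crosses 50% of the reference")
    frac = (fit.top - half) / (half - fit.bottom)
    return float(fit.ic50 * frac ** (1.0 / fit.hill))


def ic50_fold_ratio(
    a: float,
    b: float,
    unit_a: str = "nM",
    unit_b: str = "nM",
    digits: int | None = None,
) -> float:
    """a/b after converting both to nM; round-half-even to `digits` if given."""
    if unit_a not in _UNIT_TO_NM or unit_b not in _UNIT_TO_NM:
        raise ValueError(f"unsupported unit(s): {unit_a!r}, {unit_b!r}")
    if b <= 0:
        raise ValueError("denominator concentration must be positive")
    ratio = (a * _UNIT_TO_NM[unit_a]) / (b * _UNIT_TO_NM[unit_b])
    return round(ratio, digits) if digits is not None else ratio


def wound_healing_rate(area_t0: float, area_t: float) -> float:
    """WHR % = 100 x (area_t0 - area_t) / area_t0; negative means wound growth."""
    if area_t0 <= 0:
        raise ValueError("baseline wound area must be positive")
    whr = 100.0 * (area_t0 - area_t) / area_t0
    if whr < 0:
        logger.warning("negative wound healing rate (%.1f %%): wound grew", whr)
    return whr


def ddct_fold(
    ct_target_treated: Sequence[float] | float,
    ct_ref_treated: Sequence[float] | float,
    ct_target_control: Sequence[float] | float,
    ct_ref_control: Sequence[float] | float,
) -> QPCRResult:
    """Relative quantification by the 2^-ΔΔCT method (replicate-averaged).

    ΔΔCT = (CT_target - CT_ref)_treated - (CT_target - CT_ref)_control;
    fold = 2^-ΔΔCT (fold < 1 means the target is knocked down).
    """
    arrs = [np.atleast_1d(np.asarray(x, dtype=float))
            for x in (ct_target_treated, ct_ref_treated, ct_target_control, ct_ref_control)]
    if any(not np.isfinite(a).all() for a in arrs):
        raise ValueError("CT values must be finite")
    tt, rt, tc, rc = (float(a.mean()) for a in arrs)
    ddct = (tt - rt) - (tc - rc)
    return QPCRResult(ddct=ddct, fold=float(2.0**-ddct))


def tumor_volume(width_mm: float, length_mm: float) -> float:
    """Caliper volume V = width² x length / 2 (mm³); swaps if width > length."""
    if width_mm <= 0 or length_mm <= 0:
        raise ValueError("tumor dimensions must be positive")
    if width_mm > length_mm:
        logger.warning("width %.1f > length %.1f mm: swapping", width_mm, length_mm)
        width_mm, length_mm = length_mm, width_mm
    return width_mm**2 * length_mm / 2.0


def growth_summary(caliper: pd.DataFrame) -> dict[str, object]:
    """Per-group tumor volume curves plus final-day treated/control ratios.

    Expects columns group, mouse, day, width_mm, length_mm.  Tumor weight is
    proxied by volume (constant-density assumption), so the final-weight
    ratio equals the final-volume ratio computed from caliper data alone.
    """
    df = caliper.copy()
    df["volume_mm3"] = [
        tumor_volume(w, l) for w, l in zip(df["width_mm"], df["length_mm"])
    ]
    curves = (
        df.groupby(["group", "day"])["volume_mm3"]
        .agg(mean="mean", sd="std")
        .reset_index()
    )
    last_day = df["day"].max()
    final = df[df["day"] == last_day].groupby("group")["volume_mm3"].mean()
    ratio = float(final["treated"] / final["control"])
    return {
        "curves": curves,
        "final_day": int(last_day),
        "final_volume_ratio": ratio,
        "final_weight_ratio": ratio,
    }


def fold_activity(treated_signal: float, control_signal: float) -> float:
    """Treated/control signal ratio (caspase-3 ELISA-style fold activity)."""
    if control_signal <= 0:
        raise ValueError("control signal must be positive")
    return treated_signal / control_signal
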