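"""Plate-reader assay computations: ROS normalisation, BCA protein
quantification, four-parameter-logistic dose-response with IC10
extrapolation, and one-way ANOVA with Tukey HSD comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator


def ros_fold_change(sample_rfu: float, sample_protein_ug: float,
                    control_rfu: float, control_protein_ug: float) -> float:
    """ROS fold change: (RFU/µg protein) of sample over control."""
    if sample_protein_ug <= 0 or control_protein_ug <= 0:
        raise ValueError("protein mass must be positive")
    return (sample_rfu / sample_protein_ug) / (control_rfu / control_protein_ug)


def quantify_protein(absorbances, standards) -> np.ndarray:
    """Protein concentrations from a BCA standard curve.

    ``standards`` is a sequence of (concentration, absorbance) pairs (>= 3);
    an ordinary least-squares line absorbance ~ concentration is inverted
    for the samples. Negative inversions are clipped to 0 with a warning.
    """
    standards = np.asarray(standards, dtype=float)
    if standards.shape[0] < 3:
        raise ValueError("need at least 3 standards")
    conc, absb = standards[:, 0], standards[:, 1]
    if np.ptp(conc) == 0:
        raise ValueError("degenerate standards: zero concentration spread")
    slope, intercept = np.polyfit(conc, absb, 1)
    if slope == 0:
        raise ValueError("degenerate standard curve: zero slope")
    out = (np.asarray(absorbances, dtype=float) - intercept) / slope
    if np.any(out < 0):
        warnings.warn("negative inverted concentrations clipped to 0", stacklevel=2)
        out = np.clip(out, 0.0, None)
    return out


# ------------------------------------------------------------- dose-response

def four_pl(dose, top: float, bottom: float, c50: float, slope: float):
    """y = bottom + (top - bottom) / (1 + (x / c50)^slope)."""
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / c50) ** slope)


@dataclass
class DoseResponseFit:
    """Fitted 4PL parameters plus the IC10 read-out.

    ``ic10`` is the dose at which the fitted viability crosses 90% (an
    absolute 10% drop from full viability, not 10% of the fitted top
    asymptote); ``extrapolated`` flags an IC10 outside the tested dose
    range; ``flat`` marks curves indistinguishable from a constant (F-test),
    for which the IC10 is undefined.
    """

    top: float
    bottom: float
    c50: float
    slope: float
    residual_sd: float
    ic10: float | None
    extrapolated: bool
    flat: bool


def _ic_from_params(top: float, bottom: float, c50: float, slope: float,
                    level: float = 90.0) -> float | None:
    """Closed-form dose where the fitted 4PL equals ``level`` % viability."""
    if level == bottom or top == bottom:
        return None
    ratio = (top - level) / (level - bottom)
    if ratio <= 0:
        return None
    return float(c50 * ratio ** (1.0 / slope))


class FourParamLogistic(BaseEstimator):
    """Bounded least-squares 4PL fit of viability (%) against dose.

    Parameter bounds: top in [50, 150], bottom in [-20, 80], slope > 0, and
    c50 within the tested dose range times [0.01, 100]. ``ic_level`` sets
    the viability crossing reported (90 => IC10).

    Attributes
    ----------
    fit_ : :class:`DoseResponseFit`
    """

    def __init__(self, ic_level: float = 90.0, flat_alpha: float = 0.05):
        self.ic_level = ic_level
        self.flat_alpha = flat_alpha

    def fit(self, doses, viability, y=None):
        doses = np.asarray(doses, dtype=float)
        viability = np.asarray(viability, dtype=float)
        if np.unique(doses).size < 5:
            raise ValueError("need at least 5 dose levels")
        if np.any(doses <= 0):
            raise ValueError("doses must be positive")

        lo, hi = doses.min(), doses.max()
        bounds = ([50.0, -20.0, lo * 0.01, 1e-3], [150.0, 80.0, hi * 100.0, 50.0])
        p0 = [min(max(viability.max(), 51.0), 149.0),
              min(max(viability.min(), -19.0), 79.0),
              float(np.sqrt(lo * hi)), 1.0]
        p0 = np.clip(p0, bounds[0], bounds[1])
        try:
            popt, _ = optimize.curve_fit(four_pl, doses, viability, p0=p0,
                                         bounds=bounds, maxfev=20000)
            fitted = four_pl(doses, *popt)
        except RuntimeError:
            popt, fitted = None, None

        n = doses.size
        flat = True
        if popt is not None:
            rss_fit = float(np.sum((viability - fitted) ** 2))
            rss_const = float(np.sum((viability - viability.mean()) ** 2))
            df_fit = n - 4
            if df_fit > 0 and rss_fit > 0:
                F = ((rss_const - rss_fit) / 3.0) / (rss_fit / df_fit)
                p_flat = stats.f.sf(F, 3, df_fit)
                flat = bool(p_flat > self.flat_alpha)
            else:
                flat = rss_const <= rss_fit if rss_fit > 0 else np.isclose(rss_const, 0.0)
            residual_sd = float(np.sqrt(rss_fit / max(df_fit, 1)))
        else:
            residual_sd = float("nan")

        if popt is None or flat:
            self.fit_ = DoseResponseFit(
                top=float(popt[0]) if popt is not None else float("nan"),
                bottom=float(popt[1]) if popt is not None else float("nan"),
                c50=float(popt[2]) if popt is not None else float("nan"),
                slope=float(popt[3]) if popt is not None else float("nan"),
                residual_sd=residual_sd, ic10=None, extrapolated=False, flat=True,
            )
            return self

        # significant dose dependence: report parameters and the IC crossing
        top, bottom, c50, slope = (float(v) for v in popt)
        ic = _ic_from_params(top, bottom, c50, slope, level=self.ic_level)
        extrapolated = bool(ic is not None and not (lo <= ic <= hi))
        self.fit_ = DoseResponseFit(top=top, bottom=bottom, c50=c50, slope=slope,
                                    residual_sd=residual_sd, ic10=ic,
                                    extrapolated=extrapolated, flat=False)
        return self


def fit_dose_response(doses, viability, ic_level: float = 90.0) -> DoseResponseFit:
    """Functional wrapper over :class:`FourParamLogistic`."""
    return FourParamLogistic(ic_level=ic_level).fit(doses, viability).fit_


def ic10(fit: DoseResponseFit) -> float:
    """The fitted IC10 dose; raises if the curve was flat/undefined."""
    if fit.ic10 is None:
        raise ValueError("IC10 undefined: flat response or no 90% crossing")
    return fit.ic10


# ------------------------------------------------------------- ANOVA + Tukey

def anova_tukey(groups: dict[str, np.ndarray]) -> dict:
    """One-way ANOVA F/p plus Tukey HSD pairwise adjusted p-values.

    ``groups`` maps condition name -> 1-D measurements (each n >= 2).
    Returns {"F", "p", "pairwise": {(a, b): adjusted p}} with pairs in
    sorted name order. Identical groups give F = 0 and pairwise p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    names = sorted(groups)
    arrays = [np.asarray(groups[n], dtype=float) for n in names]
    for n, a in zip(names, arrays):
        if a.size < 2:
            raise ValueError(f"group {n!r} has fewer than 2 measurements")
    if np.ptp(np.concatenate(arrays)) == 0:
        F, p = 0.0, 1.0
        pairwise = {(a, b): 1.0 for i, a in enumerate(names) for b in names[i + 1:]}
        return {"F": F, "p": p, "pairwise": pairwise}
    F, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    pairwise = {}
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            pairwise[(a, names[j])] = float(res.pvalue[i, j])
    return {"F": float(F), "p": float(p), "pairwise": pairwise}
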