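"""Gene-level differential-expression statistics.

Two-group linear contrasts per gene, empirical-Bayes shrinkage of the
residual variances toward a global prior, moderated t-tests, and volcano
classification. The model per gene g is the standard hierarchical one:

    s2_g | sigma2_g ~ sigma2_g * chisq(d_g) / d_g
    1 / sigma2_g    ~ chisq(d0) / (d0 * s0_sq)

so the posterior variance is the precision-weighted blend

    s2_post_g = (d0 * s0_sq + d_g * s2_g) / (d0 + d_g)

and the moderated t = log2FC / sqrt(s2_post * v) is referred to a Student t
with d0 + d_g degrees of freedom. The hyperparameters (d0, s0_sq) are
estimated by moment matching on the log variances, solving the trigamma
equation numerically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator

#: df cap standing in for an infinite-prior-df t reference (still Student t,
#: never the Normal directly)
MAX_DF = 1e6


@dataclass
class VarianceShrinkage:
    """Empirical-Bayes variance-shrinkage result."""

    d0: float  # prior degrees of freedom; np.inf when the spread of log
    # variances is fully explained by sampling noise
    s0_sq: float  # prior (location) variance
    s2_post: np.ndarray  # posterior variances, one per gene


def fit_gene_models(dataset, contrast: tuple[str, str]) -> pd.DataFrame:
    """Per-gene two-group contrast: effect, pooled variance, df.

    Parameters
    ----------
    dataset : ExpressionDataset
    contrast : (test_label, control_label)
        e.g. ``("NAFL", "Healthy")``; log2FC = mean(test) - mean(control).

    Returns a DataFrame indexed by gene with columns ``log2fc``, ``s2``
    (pooled residual variance), ``df`` (n1 + n2 - 2), and ``v`` (1/n1 + 1/n2,
    the unit variance of the contrast).
    """
    test_label, control_label = contrast
    test_cols = dataset.group_columns(test_label)
    ctrl_cols = dataset.group_columns(control_label)
    for label, cols in ((test_label, test_cols), (control_label, ctrl_cols)):
        if len(cols) == 0:
            raise ValueError(f"no samples with status {label!r} in the dataset")
    n1, n2 = len(test_cols), len(ctrl_cols)
    if n1 + n2 < 3:
        raise ValueError("need n1 + n2 >= 3 samples for a residual degree of freedom")

    X1 = dataset.values[test_cols].to_numpy(dtype=float)
    X2 = dataset.values[ctrl_cols].to_numpy(dtype=float)
    m1, m2 = X1.mean(axis=1), X2.mean(axis=1)
    ss1 = ((X1 - m1[:, None]) ** 2).sum(axis=1)
    ss2 = ((X2 - m2[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    s2 = (ss1 + ss2) / df
    return pd.DataFrame(
        {"log2fc": m1 - m2, "s2": s2, "df": float(df), "v": 1.0 / n1 + 1.0 / n2},
        index=dataset.genes,
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration.

    Monotone decreasing target; the iteration below (on 1/x, where trigamma
    is close to linear) converges in a handful of steps. Tolerance 1e-8,
    at most 100 iterations.
    """
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(100):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-8 * x:
            break
    return float(x)


def squeeze_variances(s2, df) -> VarianceShrinkage:
    """Estimate (d0, s0_sq) by moment matching on log variances; shrink.

    Following the standard scaled-F hierarchy: with z_g = log(s2_g),
    E[z_g] = log(sigma2) + digamma(d_g/2) - log(d_g/2) and the excess
    spread of e_g = z_g - digamma(d_g/2) + log(d_g/2) over the sampling
    contribution trigamma(d_g/2) identifies trigamma(d0/2). Zero variances
    are legal in the posterior formula but are excluded from hyperparameter
    estimation (their log is undefined).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).copy()
    usable = (df >= 1) & np.isfinite(s2)
    if int(usable.sum()) < 10:
        raise ValueError("insufficient genes: need >= 10 with at least 1 residual df")
    if np.all(s2[usable] == 0):
        raise ValueError("all residual variances are zero; cannot estimate a variance prior")

    pos = usable & (s2 > 0)
    z = np.log(s2[pos])
    dg = df[pos]
    e = z - special.digamma(dg / 2.0) + np.log(dg / 2.0)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1))
    excess = evar - float(np.mean(special.polygamma(1, dg / 2.0)))

    if excess <= 0:
        d0 = np.inf
        if np.ptp(z) == 0:
            # exactly zero spread: no sampling scatter to correct for, the
            # common variance IS the prior
            s0_sq = float(np.exp(np.mean(z)))
        else:
            s0_sq = float(np.exp(emean))
    else:
        d0 = 2.0 * _trigamma_inverse(excess)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))

    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return VarianceShrinkage(d0=d0, s0_sq=s0_sq, s2_post=s2_post)


def _b_statistic(t: np.ndarray, df_total: np.ndarray, v: np.ndarray,
                 proportion: float = 0.01) -> np.ndarray:
    """Log posterior odds of differential expression (optional diagnostic).

    Uses a fixed prior DE proportion and an empirical prior variance for
    the DE effect sizes (method-of-moments on the largest |t|); reported
    for completeness, never consulted downstream.
    """
    v = np.broadcast_to(np.asarray(v, float), t.shape)
    # effect-variance prior from the upper tail of t^2 (clipped positive)
    q = np.quantile(t**2, 0.99)
    v0_ratio = max(q - 1.0, 1.0)  # var(effect)/var(noise) on the t scale
    r = 1.0 + v0_ratio
    with np.errstate(over="ignore"):
        log_dens_alt = stats.t.logpdf(t / np.sqrt(r), df_total) - 0.5 * np.log(r)
        log_dens_null = stats.t.logpdf(t, df_total)
    return np.log(proportion / (1.0 - proportion)) + log_dens_alt - log_dens_null


def moderated_t_test(models: pd.DataFrame, shrinkage: VarianceShrinkage,
                     include_b: bool = False) -> pd.DataFrame:
    """Moderated t-statistics, p-values, and BH-adjusted p-values.

    ``models`` is the output of :func:`fit_gene_models`. Degrees of freedom
    are ``d0 + df`` per gene, capped at a large finite value when the prior
    df is infinite. Genes with zero posterior variance get infinite t and
    p = 0, with a warning.
    """
    from statsmodels.stats.multitest import multipletests

    d0 = shrinkage.d0
    df_total = (MAX_DF if np.isinf(d0) else d0) + models["df"].to_numpy()
    df_total = np.minimum(df_total, MAX_DF)
    s2_post = shrinkage.s2_post
    v = models["v"].to_numpy()
    fc = models["log2fc"].to_numpy()

    denom = np.sqrt(s2_post * v)
    zero = denom == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} genes have zero posterior variance; "
                      "their moderated t is infinite", stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero, np.sign(fc) * np.inf, fc / np.where(zero, 1.0, denom))
        t = np.where(zero & (fc == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.where(np.isinf(t), 0.0, p)
    p = np.where(zero & (fc == 0), 1.0, p)
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")

    out = models.copy()
    out["s2_post"] = s2_post
    out["t_mod"] = t
    out["p"] = p
    out["p_adj"] = p_adj
    if include_b:
        finite = np.isfinite(t)
        b = np.full_like(p, np.nan)
        b[finite] = _b_statistic(t[finite], df_total[finite], v[finite])
        out["b"] = b
    return out


def classify_volcano(table: pd.DataFrame, fc_cut: float = 1.0, p_cut: float = 0.05) -> pd.Series:
    """Volcano rule: up iff log2FC > fc_cut and p <= p_cut; down symmetric.

    The fold-change comparison is strict, the p comparison inclusive. The
    raw p-value (not the BH-adjusted one) feeds the rule; the adjusted
    column is reported for downstream consumers.
    """
    fc = table["log2fc"]
    p = table["p"]
    cls = pd.Series("not", index=table.index, dtype=object)
    cls[(fc > fc_cut) & (p <= p_cut)] = "up"
    cls[(fc < -fc_cut) & (p <= p_cut)] = "down"
    return cls


GENE_STATS_COLUMNS = ["log2fc", "s2", "df", "s2_post", "t_mod", "p", "p_adj", "de_class"]


class ModeratedTTest(BaseEstimator):
    """Two-group moderated t-test with empirical-Bayes variance shrinkage.

    A scikit-learn-style estimator: ``fit`` takes an
    :class:`~sigrepo.datatypes.ExpressionDataset` and produces the full
    gene-statistics table with fitted attributes.

    Parameters
    ----------
    contrast : (test, control) status labels, default ("NAFL", "Healthy").
    fc_cut, p_cut : volcano thresholds (|log2FC| strict, p inclusive).
    include_b : also report the log-posterior-odds diagnostic column.

    Attributes
    ----------
    d0_, s0_sq_ : estimated prior df and prior variance.
    results_ : DataFrame with columns ``GENE_STATS_COLUMNS`` indexed by gene.
    """

    def __init__(self, contrast: tuple[str, str] = ("NAFL", "Healthy"),
                 fc_cut: float = 1.0, p_cut: float = 0.05, include_b: bool = False):
        self.contrast = contrast
        self.fc_cut = fc_cut
        self.p_cut = p_cut
        self.include_b = include_b

    def fit(self, dataset, y=None):
        models = fit_gene_models(dataset, tuple(self.contrast))
        shrink = squeeze_variances(models["s2"].to_numpy(), models["df"].to_numpy())
        table = moderated_t_test(models, shrink, include_b=self.include_b)
        table["de_class"] = classify_volcano(table, self.fc_cut, self.p_cut)
        self.d0_ = shrink.d0
        self.s0_sq_ = shrink.s0_sq
        self.results_ = table
        return self

    def to_tsv(self, path, header: str | None = None) -> None:
        """Write the gene-stats table in the fixed column order."""
        from .io import _write_with_header

        cols = [c for c in GENE_STATS_COLUMNS if c in self.results_.columns]
        if "b" in self.results_.columns:
            cols.append("b")
        txt = self.results_[cols].rename_axis("gene").to_csv(sep="\t")
        _write_with_header(path, txt, header)
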