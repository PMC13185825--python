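"""X-versus-autosome distribution diagnostics for repeat-mediated SVs.

Per-chromosome counts of rep-SVs and non-rep-SVs are compared by OLS
regression with influence diagnostics (externally studentized residuals,
Bonferroni single-outlier p, Cook's distance), swept over SV size
thresholds; density ratios (X density over pooled autosomal density) profile
how the X deviation grows with SV size; a Grubbs single-outlier test (with a
Shapiro–Wilk normality pre-check) asks whether the X chromosome is the
outlying chromosome; and per-individual large/small ratios feed a PCA that
separates subspecies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.outliers_influence import OLSInfluence

logger = logging.getLogger(__name__)

#: split between "small" and "large" SVs in the X-bias analyses
LARGE_SV_THRESHOLD = 8000

#: default grid of minimum-size thresholds for sweeps
DEFAULT_THRESHOLDS = (50, 100, 200, 500, 1000, 2000, 4000, 8000, 16000)


def chromosome_counts(annotations: pd.DataFrame, genome, min_size: int = 50) -> pd.DataFrame:
    """Per-chromosome length and rep/nonrep SV counts for SVs >= ``min_size`` bp."""
    lens = genome.lengths
    unknown = set(annotations["chrom"]) - set(lens)
    if unknown:
        raise ValueError(f"annotations contain unknown chromosomes: {sorted(unknown)}")
    sel = annotations[annotations["svlen"] >= min_size]
    rep = sel[sel["is_rep"]].groupby("chrom").size()
    nonrep = sel[~sel["is_rep"]].groupby("chrom").size()
    out = pd.DataFrame(
        {
            "length": [lens[c] for c in genome.names],
            "rep": [int(rep.get(c, 0)) for c in genome.names],
            "nonrep": [int(nonrep.get(c, 0)) for c in genome.names],
        },
        index=pd.Index(genome.names, name="chrom"),
    )
    out["is_x"] = out.index == genome.x_name
    return out


@dataclass
class RegressionOutlierResult:
    slope: float
    intercept: float
    r2: float
    studentized: np.ndarray      # externally studentized residuals
    cooks_d: np.ndarray
    outlier_index: int
    bonferroni_p: float


def regression_outlier_test(x, y) -> RegressionOutlierResult:
    """OLS of y on x with a Bonferroni-adjusted max-|studentized-residual| outlier test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    if fit.ssr <= 1e-12 * max(fit.centered_tss, 1.0):
        # exact fit: all residual diagnostics are zero by convention
        rstud = np.zeros(n)
        cooks = np.zeros(n)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            infl = OLSInfluence(fit)
            rstud = np.nan_to_num(np.asarray(infl.resid_studentized_external))
            cooks = np.nan_to_num(np.asarray(infl.cooks_distance[0]))
    i = int(np.argmax(np.abs(rstud)))
    # two-sided t tail at df = n - k - 1 = n - 3, Bonferroni over n tests
    p = min(1.0, n * 2 * stats.t.sf(abs(rstud[i]), n - 3))
    return RegressionOutlierResult(
        float(fit.params[1]), float(fit.params[0]), float(fit.rsquared),
        rstud, cooks, i, float(p),
    )


@dataclass
class BiasDiagnostics:
    threshold: int
    chroms: list
    cooks_d: np.ndarray
    studentized: np.ndarray
    outlier_index: int
    bonferroni_p: float
    rep_density_ratio: float
    nonrep_density_ratio: float
    grubbs_g: float
    grubbs_p: float
    grubbs_flagged: str
    shapiro_w: float
    shapiro_p: float


def _density_ratio(counts: pd.DataFrame, col: str) -> float:
    x = counts[counts["is_x"]]
    a = counts[~counts["is_x"]]
    denom = a[col].sum() / a["length"].sum()
    if denom == 0:
        return np.nan
    return float((x[col].sum() / x["length"].sum()) / denom)


def _mean_model_influence(y: np.ndarray):
    """Studentized residuals, Cook's D and Bonferroni p for the intercept-only model."""
    n = len(y)
    e = y - y.mean()
    h = 1.0 / n
    mse = float(e @ e) / (n - 1)
    rstud = np.zeros(n)
    cooks = np.zeros(n)
    if mse > 0:
        for i in range(n):
            s2i = (e @ e - e[i] ** 2 / (1 - h)) / (n - 2)
            rstud[i] = e[i] / np.sqrt(max(s2i, 1e-300) * (1 - h))
            ri = e[i] / np.sqrt(mse * (1 - h))
            cooks[i] = ri**2 * h / (1 - h)
    i = int(np.argmax(np.abs(rstud)))
    p = min(1.0, n * 2 * stats.t.sf(abs(rstud[i]), n - 2))
    return rstud, cooks, i, float(p)


def cook_distance_sweep(
    annotations: pd.DataFrame,
    genome,
    thresholds=DEFAULT_THRESHOLDS,
    mode: str = "ratio",
) -> list[BiasDiagnostics]:
    """Influence diagnostics across SV size thresholds.

    ``mode="ratio"`` (default) measures each chromosome's influence on the
    mean per-chromosome rep/nonrep count ratio (intercept-only model);
    ``mode="counts"`` regresses rep counts on nonrep counts.  Thresholds
    that leave fewer than 4 usable chromosomes are skipped with a warning.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    out = []
    for thr in thresholds:
        counts = chromosome_counts(annotations, genome, min_size=thr)
        usable = counts[(counts["rep"] + counts["nonrep"]) > 0]
        if mode == "ratio":
            usable = usable[usable["nonrep"] > 0]
        if len(usable) < 4:
            warnings.warn(f"threshold {thr}: fewer than 4 usable chromosomes; skipped")
            continue
        if mode == "ratio":
            yv = (usable["rep"] / usable["nonrep"]).to_numpy(dtype=float)
            rstud, cooks, oi, bp = _mean_model_influence(yv)

            class reg:  # noqa: N801 - simple result carrier
                studentized = rstud
                cooks_d = cooks
                outlier_index = oi
                bonferroni_p = bp
            ratios = yv
        elif mode == "counts":
            xv = usable["nonrep"].to_numpy(dtype=float)
            yv = usable["rep"].to_numpy(dtype=float)
            reg = regression_outlier_test(xv, yv)
            ratios = (usable["rep"] / usable["nonrep"]).to_numpy(dtype=float)
        else:
            raise ValueError(f"unknown mode {mode!r}")
        try:
            g, gp, flagged, shp = grubbs_single_outlier(ratios, labels=list(usable.index))
            sw = float(stats.shapiro(ratios).statistic)
        except ValueError:
            g, gp, flagged, shp, sw = np.nan, np.nan, "", np.nan, np.nan
        out.append(
            BiasDiagnostics(
                threshold=int(thr),
                chroms=list(usable.index),
                cooks_d=reg.cooks_d,
                studentized=reg.studentized,
                outlier_index=reg.outlier_index,
                bonferroni_p=reg.bonferroni_p,
                rep_density_ratio=_density_ratio(counts, "rep"),
                nonrep_density_ratio=_density_ratio(counts, "nonrep"),
                grubbs_g=g,
                grubbs_p=gp,
                grubbs_flagged=flagged,
                shapiro_w=sw,
                shapiro_p=shp,
            )
        )
    return out


def density_ratio_profile(annotations, genome, thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """(X density)/(pooled autosomal density) for rep and nonrep SVs per threshold."""
    rows = []
    for thr in thresholds:
        counts = chromosome_counts(annotations, genome, min_size=thr)
        rows.append(
            {
                "threshold": int(thr),
                "rep_ratio": _density_ratio(counts, "rep"),
                "nonrep_ratio": _density_ratio(counts, "nonrep"),
            }
        )
    return pd.DataFrame(rows)


def grubbs_single_outlier(values, labels=None):
    """Two-sided Grubbs test for a single outlier.

    G = max|x - mean| / sd; the p-value comes from the closed-form relation
    between the Grubbs statistic and the t distribution with n-2 df.  A
    Shapiro–Wilk p is returned alongside (warning if < 0.05: the test
    assumes normality).  Returns (G, p, flagged_label, shapiro_p).
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 values")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate sample: zero standard deviation")
    dev = np.abs(x - x.mean())
    i = int(np.argmax(dev))
    g = float(dev[i] / sd)
    # invert G = (n-1)/sqrt(n) * sqrt(t^2/(n-2+t^2))
    denom = (n - 1) ** 2 - n * g * g
    if denom <= 0:
        p = 0.0
    else:
        t = np.sqrt((n - 2) * n * g * g / denom)
        p = float(min(1.0, 2 * n * stats.t.sf(t, n - 2)))
    shapiro_p = float(stats.shapiro(x).pvalue)
    if shapiro_p < 0.05:
        logger.warning("Grubbs input fails Shapiro-Wilk normality (p=%.3g)", shapiro_p)
    flagged = labels[i] if labels is not None else str(i)
    return g, p, flagged, shapiro_p


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    variance_explained: np.ndarray


def individual_ratio_pca(features: pd.DataFrame, scale: bool = False) -> PCAResult:
    """PCA of a per-individual feature table (rows = individuals).

    Features are centered (optionally unit-scaled); decomposition by SVD;
    each component's sign is fixed so its largest-|loading| entry is
    positive.  Variance-explained fractions sum to 1.
    """
    X = features.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 1:
        raise ValueError("need >= 2 individuals and >= 1 feature")
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("constant feature with scaling enabled")
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    for j in range(vt.shape[0]):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    ncomp = vt.shape[0]
    cols = [f"PC{j + 1}" for j in range(ncomp)]
    return PCAResult(
        scores=pd.DataFrame(u * s, index=features.index, columns=cols),
        loadings=pd.DataFrame(vt.T, index=features.columns, columns=cols),
        variance_explained=frac,
    )


def per_individual_x_ratio(
    annotations: pd.DataFrame,
    callset,
    genome,
    threshold: int = LARGE_SV_THRESHOLD,
) -> pd.DataFrame:
    """Per individual: carried X-chromosome rep-SVs above vs below ``threshold``.

    Returns columns n_large, n_small, ratio (pseudocount 1 in the
    denominator keeps individuals with no small X rep-SVs finite).
    """
    on_x = (annotations["chrom"] == genome.x_name) & annotations["is_rep"]
    large = on_x & (annotations["svlen"] > threshold)
    small = on_x & (annotations["svlen"] <= threshold)
    pres = callset.presence_matrix() == 1
    n_large = pres[large.to_numpy()].sum(axis=0)
    n_small = pres[small.to_numpy()].sum(axis=0)
    return pd.DataFrame(
        {
            "n_large": n_large,
            "n_small": n_small,
            "ratio": n_large / np.maximum(n_small, 1),
        },
        index=callset.samples,
    )
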