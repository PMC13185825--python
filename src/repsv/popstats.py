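"""Population differentiation and genotype–phenotype association on SV genotypes.

F_ST follows the Weir & Cockerham (1984) two-level variance-component
estimator for diploid biallelic sites (the presence allele versus the
reference allele): per site the components a (among populations),
b (among individuals within populations) and c (within individuals) are
computed from sample-size-corrected allele frequencies and observed
heterozygosity, with theta-hat = a/(a+b+c).  The multi-site summary is the
weighted ratio of sums, sum(a)/sum(a+b+c).  Negative per-site estimates are
preserved, not clipped.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sv_io import MISSING

logger = logging.getLogger(__name__)


@dataclass
class FstResult:
    per_site: pd.DataFrame   # columns a, b, c, theta (NaN where undefined)
    overall: float           # ratio of sums
    n_sites_used: int
    n_sites_skipped: int


def weir_cockerham_fst(genotypes, groups, group_labels=None) -> FstResult:
    """Weir–Cockerham F_ST from a (sites x individuals) alt-count matrix.

    ``genotypes`` holds diploid alternate-allele counts (0/1/2, ``-1``
    missing); ``groups`` labels each individual; ``group_labels`` optionally
    restricts/orders the populations compared (default: the two or more
    distinct labels present).  Sites with an entirely-missing group or
    monomorphic across all groups are skipped (counted, reported NaN).
    """
    G = np.asarray(genotypes)
    grp = np.asarray(groups)
    if group_labels is None:
        group_labels = sorted(pd.unique(grp))
    r = len(group_labels)
    if r < 2:
        raise ValueError("need at least 2 groups")
    masks = [grp == g for g in group_labels]
    if any(m.sum() < 1 for m in masks):
        raise ValueError("every group needs at least one individual")

    n_sites = G.shape[0]
    a = np.full(n_sites, np.nan)
    b = np.full(n_sites, np.nan)
    c = np.full(n_sites, np.nan)

    # per-population per-site sample sizes, allele frequencies, het frequencies
    n_i = np.zeros((r, n_sites))
    p_i = np.zeros((r, n_sites))
    h_i = np.zeros((r, n_sites))
    for k, m in enumerate(masks):
        sub = G[:, m]
        called = sub != MISSING
        n_i[k] = called.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(called, sub, 0).sum(axis=1) / (2 * n_i[k])
            h_i[k] = np.where(called & (sub == 1), 1, 0).sum(axis=1) / n_i[k]

    ok = np.all(n_i >= 1, axis=0)
    nbar = n_i.mean(axis=0)
    nsum = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (nsum - (n_i**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n_i * p_i).sum(axis=0) / nsum
        s2 = (n_i * (p_i - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(axis=0) / nsum

        poly = ok & (pbar > 0) & (pbar < 1)
        av = (nbar / nc) * (
            s2
            - (1.0 / (nbar - 1))
            * (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4.0)
        )
        bv = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
        cv = hbar / 2.0

    a[poly], b[poly], c[poly] = av[poly], bv[poly], cv[poly]
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(np.abs(denom) > 0, a / denom, np.nan)
    per_site = pd.DataFrame({"a": a, "b": b, "c": c, "theta": theta})
    used = int(np.sum(poly))
    tot = float(np.nansum(a[poly])) / float(np.nansum(denom[poly])) if used else np.nan
    return FstResult(per_site, tot, used, n_sites - used)


def group_frequency_contrast(values, groups, group_labels=None):
    """Two-sided Wilcoxon rank-sum contrast of a per-individual quantity.

    Uses exact enumeration when both groups have <= 10 observations,
    otherwise the normal approximation with tie correction.  Returns
    (U statistic, p).  All values tied across groups -> p = 1.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    if group_labels is None:
        group_labels = sorted(pd.unique(g))
    if len(group_labels) != 2:
        raise ValueError("need exactly 2 groups")
    x = v[g == group_labels[0]]
    y = v[g == group_labels[1]]
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2), 1.0
    method = "exact" if (len(x) <= 10 and len(y) <= 10 and
                         len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float
    group_means: pd.Series


def genotype_anova(genotypes, phenotypes) -> AnovaResult:
    """One-way fixed-effects ANOVA of a phenotype across genotype classes.

    Genotype classes with a single observation are dropped with a warning;
    missing genotypes (< 0) are excluded.  Degenerate cases are guarded:
    equal class means give F = 0 / p = 1; zero within-class variance with
    unequal means gives F = inf / p = 0.
    """
    g = np.asarray(genotypes)
    y = np.asarray(phenotypes, dtype=float)
    keep = (g >= 0) & np.isfinite(y)
    g, y = g[keep], y[keep]
    classes = []
    for cls in np.unique(g):
        yy = y[g == cls]
        if len(yy) < 2:
            warnings.warn(f"genotype class {cls} has a single observation; dropped")
            continue
        classes.append((cls, yy))
    if len(classes) < 2:
        raise ValueError("need >= 2 genotype classes with >= 2 observations")
    grand = np.concatenate([yy for _, yy in classes]).mean()
    n = sum(len(yy) for _, yy in classes)
    k = len(classes)
    ss_between = sum(len(yy) * (yy.mean() - grand) ** 2 for _, yy in classes)
    ss_within = sum(((yy - yy.mean()) ** 2).sum() for _, yy in classes)
    df_b, df_w = k - 1, n - k
    if ss_between <= 1e-300:
        f, p = 0.0, 1.0
    elif ss_within <= 1e-300:
        f, p = float("inf"), 0.0
    else:
        f = (ss_between / df_b) / (ss_within / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    means = pd.Series({cls: yy.mean() for cls, yy in classes})
    return AnovaResult(float(f), df_b, df_w, p, means)


def proportion_chisq(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction."""
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(obs.sum(axis=0) == 0) or np.any(obs.sum(axis=1) == 0):
        raise ValueError("zero marginal total")
    chi2, p, dof, _ = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(dof), float(p)
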