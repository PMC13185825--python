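"""SV length spectra, modal peak detection, and REP-type enrichment within peaks.

Lengths are binned on log10(bp); peaks are local maxima of the smoothed
density with a prominence floor, each with a window spanning the region
above half prominence.  Enrichment of a REP type within a length window is
read off an across-type OLS regression of in-window composition on overall
composition: a type whose externally studentized residual survives a
Bonferroni-corrected two-sided t test deviates from the shared trend.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .chrom_bias import regression_outlier_test

logger = logging.getLogger(__name__)

#: the four modal windows of the repeat-SV length spectrum (bp)
DEFAULT_PEAK_WINDOWS = ((125, 158), (252, 316), (1018, 1263), (7686, 9689))


@dataclass
class SizePeak:
    center: float
    lo: float
    hi: float
    n: int

    def __post_init__(self):
        if not (self.lo < self.center < self.hi):
            raise ValueError("peak window must bracket its center")


def length_density(svlens, bin_width: float = 0.05, smooth_sigma: float = 1.0) -> pd.DataFrame:
    """Histogram of log10(length) plus a Gaussian-smoothed density.

    Returns a frame with columns log10_bp, bp, density, smoothed; the
    density integrates to 1 over log10(bp).
    """
    v = np.asarray(svlens, dtype=float)
    if len(v) == 0:
        warnings.warn("empty length vector")
        return pd.DataFrame(columns=["log10_bp", "bp", "density", "smoothed"])
    if np.any(v < 50):
        raise ValueError("lengths < 50 bp present")
    lv = np.log10(v)
    lo = np.floor(lv.min() / bin_width) * bin_width
    hi = np.ceil(lv.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    h, edges = np.histogram(lv, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(h) > 1:
        w = signal.windows.gaussian(int(8 * smooth_sigma) | 1, smooth_sigma)
        sm = signal.convolve(h, w / w.sum(), mode="same")
    else:
        sm = h.astype(float)
    return pd.DataFrame(
        {"log10_bp": centers, "bp": 10**centers, "density": h, "smoothed": sm}
    )


def detect_peaks(density: pd.DataFrame, min_prominence: float = 0.0) -> list[SizePeak]:
    """Local maxima of the smoothed density; windows at half prominence."""
    y = density["smoothed"].to_numpy()
    if len(y) < 3:
        return []
    idx, props = signal.find_peaks(y, prominence=(min_prominence if min_prominence > 0 else None))
    if min_prominence <= 0 and len(idx) == 0:
        idx, props = signal.find_peaks(y)  # every local max
    widths, _, lips, rips = signal.peak_widths(y, idx, rel_height=0.5)
    lx = density["log10_bp"].to_numpy()
    step = lx[1] - lx[0] if len(lx) > 1 else 0.05
    peaks = []
    for j, i in enumerate(idx):
        center = 10 ** lx[i]
        lo = 10 ** (lx[0] + lips[j] * step)
        hi = 10 ** (lx[0] + rips[j] * step)
        lo = min(lo, center * 0.999)
        hi = max(hi, center * 1.001)
        peaks.append(SizePeak(center, lo, hi, n=0))
    return sorted(peaks, key=lambda p: p.center)


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per REP type: overall/in-window proportion, residual, p_bonf, flagged
    slope: float
    intercept: float
    r2: float
    n_window: int
    low_power: bool


def peak_type_enrichment(annotations: pd.DataFrame, window) -> EnrichmentResult:
    """Which REP types are over/under-represented among rep-SVs inside a length window."""
    lo, hi = window
    rep = annotations[annotations["is_rep"]]
    types = sorted(set(rep["rep_type"]))
    if len(types) < 3:
        raise ValueError("need at least 3 REP types")
    inwin = rep[(rep["svlen"] >= lo) & (rep["svlen"] <= hi)]
    n_window = len(inwin)
    low_power = n_window < 10
    if low_power:
        warnings.warn(f"window [{lo}, {hi}] contains only {n_window} SVs; low power")
    overall = rep["rep_type"].value_counts(normalize=True).reindex(types, fill_value=0.0)
    inprop = inwin["rep_type"].value_counts(normalize=True).reindex(types, fill_value=0.0)
    m = len(types)
    if m >= 4:
        reg = regression_outlier_test(overall.to_numpy(), inprop.to_numpy())
        p = np.minimum(1.0, m * 2 * stats.t.sf(np.abs(reg.studentized), m - 3))
        slope, intercept, r2, rstud = reg.slope, reg.intercept, reg.r2, reg.studentized
    else:
        # 3 types leave no residual degrees of freedom for the outlier test
        warnings.warn("only 3 REP types: enrichment flags unavailable")
        b, a = np.polyfit(overall.to_numpy(), inprop.to_numpy(), 1)
        yhat = a + b * overall.to_numpy()
        sst = float(((inprop - inprop.mean()) ** 2).sum())
        ssr = float(((inprop.to_numpy() - yhat) ** 2).sum())
        slope, intercept, r2 = float(b), float(a), (1 - ssr / sst if sst else 1.0)
        rstud = np.full(m, np.nan)
        p = np.full(m, np.nan)
    table = pd.DataFrame(
        {
            "overall_prop": overall.to_numpy(),
            "window_prop": inprop.to_numpy(),
            "studentized": rstud,
            "p_bonf": p,
            "flagged": p < 0.05,
        },
        index=pd.Index(types, name="rep_type"),
    )
    return EnrichmentResult(table, slope, intercept, r2, n_window, low_power)


@dataclass
class YoungVsRestResult:
    chi2: float
    chi2_p: float
    contingency: pd.DataFrame   # rep/nonrep x young/rest
    per_type: pd.DataFrame      # per REP type: young/rest counts, residual, p_bonf, flagged
    exact_fallback: bool


def compare_young_vs_rest(annotations: pd.DataFrame) -> YoungVsRestResult:
    """Do young (single-carrier) SVs differ from the rest?

    A 2x2 chi-square (rep/nonrep x young/rest, no continuity correction;
    Fisher's exact test when an expected cell is < 1) plus a per-REP-type
    count-on-count regression-residual test analogous to
    :func:`peak_type_enrichment`.
    """
    young = annotations["is_young"]
    tab = pd.DataFrame(
        {
            "young": [int((young & annotations["is_rep"]).sum()),
                      int((young & ~annotations["is_rep"]).sum())],
            "rest": [int((~young & annotations["is_rep"]).sum()),
                     int((~young & ~annotations["is_rep"]).sum())],
        },
        index=["rep", "nonrep"],
    )
    obs = tab.to_numpy()
    exact = False
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected < 1):
        exact = True
        logger.info("expected cell < 1: falling back to Fisher's exact test")
        chi2 = np.nan
        p = float(stats.fisher_exact(obs)[1])
    else:
        chi2, p, _, _ = stats.chi2_contingency(obs, correction=False)
        chi2, p = float(chi2), float(p)

    rep = annotations[annotations["is_rep"]]
    types = sorted(set(rep["rep_type"]))
    yc = rep[rep["is_young"]]["rep_type"].value_counts().reindex(types, fill_value=0)
    rc = rep[~rep["is_young"]]["rep_type"].value_counts().reindex(types, fill_value=0)
    if len(types) >= 4:
        reg = regression_outlier_test(rc.to_numpy(dtype=float), yc.to_numpy(dtype=float))
        m = len(types)
        pt = np.minimum(1.0, m * 2 * stats.t.sf(np.abs(reg.studentized), m - 3))
        per_type = pd.DataFrame(
            {
                "young": yc.to_numpy(),
                "rest": rc.to_numpy(),
                "studentized": reg.studentized,
                "p_bonf": pt,
                "flagged": pt < 0.05,
            },
            index=pd.Index(types, name="rep_type"),
        )
    else:
        per_type = pd.DataFrame(
            {"young": yc.to_numpy(), "rest": rc.to_numpy()},
            index=pd.Index(types, name="rep_type"),
        )
    return YoungVsRestResult(chi2, p, tab, per_type, exact)
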