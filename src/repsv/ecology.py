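"""Community-ecology profiling of REP-type composition matrices.

The unit of analysis is an individuals x REP-type count matrix.  Alpha
diversity is the Shannon index in natural log units with Pielou's evenness
J = H/ln(S); beta diversity is Bray–Curtis on raw counts; unconstrained
ordination of the distance matrix is classical PCoA; the DCA axis-1 gradient
length (in SD units, computed from correspondence analysis with species-
tolerance standardisation and without nonlinear rescaling) decides between
linear (RDA, length < 3) and unimodal (CCA) ordination; and redundancy
analysis with a free row-permutation test quantifies how much compositional
variance a categorical constraint explains.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from . import model_select

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts) -> float:
    """Shannon index H = -sum p_i ln p_i (natural log) of a count vector."""
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("negative counts")
    total = c.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    p = c[c > 0] / total
    return float(-(p * np.log(p)).sum())


def pielou(counts) -> float:
    """Pielou's evenness J = H / ln S; NaN (with a warning) when S <= 1."""
    c = np.asarray(counts, dtype=float)
    s = int((c > 0).sum())
    if s <= 1:
        warnings.warn("S <= 1: Pielou's J undefined")
        return float("nan")
    return shannon(c) / np.log(s)


def diversity_profile(matrices: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per individual x state: Shannon H, richness S, Pielou J.

    ``matrices`` maps a state label to a composition matrix; individuals
    whose row is all zero for a state are skipped.
    """
    rows = []
    for state, mat in matrices.items():
        for ind, row in mat.iterrows():
            c = row.to_numpy(dtype=float)
            if c.sum() == 0:
                continue
            s = int((c > 0).sum())
            h = shannon(c)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                j = pielou(c) if s >= 2 else np.nan
            rows.append({"individual": ind, "state": state,
                         "shannon": h, "richness": s, "pielou_j": j})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# beta diversity + unconstrained ordination
# ---------------------------------------------------------------------------

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity on raw counts."""
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows")
    if np.any(X < 0):
        raise ValueError("negative cells")
    zero = np.flatnonzero(X.sum(axis=1) == 0)
    if zero.size:
        raise ValueError(f"all-zero row(s): {list(matrix.index[zero])}")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=matrix.index, columns=matrix.index)


def pcoa_on_distance(distance: pd.DataFrame):
    """Classical metric scaling of a distance matrix.

    Returns (scores frame, variance-explained fractions, eigenvalues).
    Negative eigenvalues are reported but excluded from the variance
    fractions; component signs are fixed (largest-|score| entry positive).
    """
    D = distance.to_numpy(dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    scores = vecs[:, pos] * np.sqrt(vals[pos])
    for j in range(scores.shape[1]):
        i = np.argmax(np.abs(scores[:, j]))
        if scores[i, j] < 0:
            scores[:, j] *= -1
    frac = vals[pos] / vals[pos].sum() if pos.any() else np.array([])
    cols = [f"PCo{j + 1}" for j in range(scores.shape[1])]
    return pd.DataFrame(scores, index=distance.index, columns=cols), frac, vals


# ---------------------------------------------------------------------------
# gradient length (DCA decision rule)
# ---------------------------------------------------------------------------

def gradient_length(matrix: pd.DataFrame):
    """DCA axis-1 gradient length in SD units and the RDA/CCA recommendation.

    Computed from correspondence analysis with Hill's scaling: axis-1 site
    standard coordinates (weighted variance 1) are multiplied by
    sqrt(lambda/(1 - lambda)), which calibrates within-species score
    dispersion to roughly one SD unit, and the length is the range of the
    scaled scores.  Detrending only affects later axes; nonlinear rescaling
    is omitted, which leaves short (noise) gradients in close numerical
    agreement with the detrended reference implementation and overestimates
    very long gradients — the "< 3 -> linear methods" decision, the only
    consumer of this value, is unaffected.  RDA is recommended iff
    length < 3.
    """
    N = matrix.to_numpy(dtype=float)
    if np.any(N < 0):
        raise ValueError("negative cells")
    if np.any(N.sum(axis=1) == 0) or np.any(N.sum(axis=0) == 0):
        raise ValueError("all-zero rows or columns")
    P = N / N.sum()
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, s, vt = np.linalg.svd(S, full_matrices=False)
    if len(s) < 1 or s[0] < 1e-10:
        warnings.warn("matrix rank < 2: gradient length 0")
        return 0.0, "RDA"
    lam = float(s[0] ** 2)
    phi = u[:, 0] / np.sqrt(r)          # site scores, weighted variance 1
    hill = phi * np.sqrt(lam / max(1.0 - lam, 1e-12))
    length = float(hill.max() - hill.min())
    return length, ("RDA" if length < 3 else "CCA")


# ---------------------------------------------------------------------------
# redundancy analysis
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    eigenvalues: np.ndarray
    site_scores: pd.DataFrame
    species_scores: pd.DataFrame
    constrained_fraction: float
    axis_fractions: np.ndarray
    permutation_p: float
    n_permutations: int
    seed: int | None
    pseudo_f: float


def _design(groups: pd.Series):
    """Dummy coding (drop-first) plus intercept; collinear columns dropped."""
    d = pd.get_dummies(pd.Series(groups).astype("category"), drop_first=True, dtype=float)
    if d.shape[1] == 0:
        raise ValueError("constraint has a single level")
    X = np.column_stack([np.ones(len(d)), d.to_numpy()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("collinear dummy columns dropped")
        keep = [0]
        names = []
        for j in range(1, X.shape[1]):
            cand = X[:, keep + [j]]
            if np.linalg.matrix_rank(cand) == len(keep) + 1:
                keep.append(j)
                names.append(d.columns[j - 1])
        X = X[:, keep]
    else:
        names = list(d.columns)
    return X, X.shape[1] - 1, names


def rda(
    response: pd.DataFrame,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
    hellinger: bool = False,
) -> OrdinationResult:
    """Redundancy analysis of a composition matrix on a categorical constraint.

    The response is column-centered (optionally Hellinger-transformed
    first); fitted values from least squares on the dummy-coded constraint
    are eigendecomposed; significance comes from a free permutation of
    response rows using the pseudo-F statistic,
    p = (1 + #{perm >= observed}) / (1 + n_perm).
    """
    Y = response.to_numpy(dtype=float)
    n, p = Y.shape
    if hellinger:
        Y = np.sqrt(Y / np.maximum(Y.sum(axis=1, keepdims=True), 1e-300))
    Y = Y - Y.mean(axis=0)
    X, q, dummy_names = _design(pd.Series(np.asarray(groups), index=response.index))
    if q < 1:
        raise ValueError("constraint has no informative levels")
    ss_tot = float((Y**2).sum())
    H, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ H
    ss_fit = float((fitted**2).sum())
    resid_df = n - 1 - q

    def pseudo_f(ssf):
        ssr = ss_tot - ssf
        return (ssf / q) / (ssr / resid_df) if resid_df > 0 and ssr > 1e-300 else np.inf

    f_obs = pseudo_f(ss_fit)

    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s**2 > max(1e-10, 1e-12 * (s[0] ** 2 if len(s) else 1))
    s, u, vt = s[keep], u[:, keep], vt[keep]
    for j in range(len(s)):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            vt[j] *= -1
            u[:, j] *= -1
    eig = s**2 / (n - 1)
    site = u * s
    species = vt.T * (s / np.sqrt(max(n - 1, 1)))
    frac = (s**2) / ss_tot if ss_tot > 0 else np.zeros_like(s)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Hp, *_ = np.linalg.lstsq(X, Y[perm], rcond=None)
        ssf = float(((X @ Hp) ** 2).sum())
        if pseudo_f(ssf) >= f_obs - 1e-12:
            count += 1
    pval = (1 + count) / (1 + n_perm)

    cols = [f"RDA{j + 1}" for j in range(len(s))]
    return OrdinationResult(
        eigenvalues=eig,
        site_scores=pd.DataFrame(site, index=response.index, columns=cols),
        species_scores=pd.DataFrame(species, index=response.columns, columns=cols),
        constrained_fraction=ss_fit / ss_tot if ss_tot > 0 else 0.0,
        axis_fractions=frac,
        permutation_p=pval,
        n_permutations=n_perm,
        seed=seed,
        pseudo_f=f_obs,
    )


# ---------------------------------------------------------------------------
# evenness vs REP content
# ---------------------------------------------------------------------------

@dataclass
class GroupRegression:
    fit: model_select.ModelFitResult
    slope: float
    slope_ci: tuple
    n: int


def evenness_content_regression(content, evenness, groups, level: float = 0.95):
    """Per-group linear fit of Pielou's J on REP content.

    Delegates to the Linear candidate model; returns a dict
    group -> GroupRegression with the slope and its t-based CI.
    """
    content = pd.Series(content)
    evenness = pd.Series(evenness)
    groups = pd.Series(groups)
    out = {}
    for g in sorted(groups.unique()):
        m = (groups == g).to_numpy()
        x, y = content[m].to_numpy(float), evenness[m].to_numpy(float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if len(x) < 3:
            logger.warning("group %s: fewer than 3 points; skipped", g)
            continue
        fit = model_select.fit_model(x, y, "Linear")
        se = float(np.sqrt(fit.cov[1, 1]))
        tq = stats.t.ppf(0.5 + level / 2, fit.gof.n - fit.gof.k)
        b = float(fit.params[1])
        out[g] = GroupRegression(fit, b, (b - tq * se, b + tq * se), len(x))
    return out
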