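"""Spatial and comparative statistics: Mantel tests, distance-decay and
latitude-diversity regressions with bootstrap slope inference, and
group-similarity contrasts.

Community similarity is 1 - Bray-Curtis throughout.  All bootstrap
procedures resample SAMPLES (not pair entries) so that the dependence
structure of distance matrices is respected, and every procedure is
reproducible bit-for-bit from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance in km between two points given in degrees."""
    if not (-90 <= lat1 <= 90 and -90 <= lat2 <= 90):
        raise ValueError("latitude outside [-90, 90]")
    if not (-180 <= lon1 <= 180 and -180 <= lon2 <= 180):
        raise ValueError("longitude outside [-180, 180]")
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dp / 2) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def geographic_distance_matrix(meta: pd.DataFrame) -> np.ndarray:
    """Pairwise haversine distances (km) from metadata lat/lon, sample order."""
    lat = meta["latitude"].to_numpy(float)
    lon = meta["longitude"].to_numpy(float)
    n = len(meta)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return d


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MantelResult:
    r: float
    p: float
    n_perm: int


def _as_square(m) -> np.ndarray:
    a = np.asarray(getattr(m, "data", m), dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("expected a square matrix")
    if not np.allclose(a, a.T):
        raise ValueError("matrix is not symmetric")
    return a


def _condensed(a: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(a.shape[0], 1)
    return a[iu]


def mantel(dx, dy, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Mantel correlation between two distance matrices.

    r is the Pearson correlation of the off-diagonal entries; p is the
    one-sided permutation probability (1 + #{r_perm >= r_obs}) / (1 + n_perm)
    under simultaneous row/column permutation of ``dy``.
    """
    ax, ay = _as_square(dx), _as_square(dy)
    if ax.shape != ay.shape:
        raise ValueError("matrices must have the same order")
    x = _condensed(ax)
    if np.std(x) == 0 or np.std(_condensed(ay)) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    r_obs = float(np.corrcoef(x, _condensed(ay))[0, 1])
    rng = np.random.default_rng(seed)
    n = ax.shape[0]
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        yp = _condensed(ay[np.ix_(idx, idx)])
        if np.std(yp) == 0:
            continue
        if np.corrcoef(x, yp)[0, 1] >= r_obs:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm)


def _residualize(v: np.ndarray, z: np.ndarray) -> np.ndarray:
    slope, intercept = np.polyfit(z, v, 1)
    return v - (slope * z + intercept)


def partial_mantel(dx, dy, dz, n_perm: int = 999, seed: int = 0) -> MantelResult:
    """Partial Mantel: correlation of dx and dy after removing the linear
    effect of dz from both (residuals of the off-diagonal entries); the
    permutation scheme permutes dy as in :func:`mantel`."""
    ax, ay, az = _as_square(dx), _as_square(dy), _as_square(dz)
    if not (ax.shape == ay.shape == az.shape):
        raise ValueError("matrices must have the same order")
    z = _condensed(az)
    x, y = _condensed(ax), _condensed(ay)
    rx = _residualize(x, z)
    ry = _residualize(y, z)

    def _safe_corr(u, v, scale_u, scale_v):
        # residuals that are numerically zero carry no signal
        if np.std(u) <= 1e-10 * max(scale_u, 1e-300) or \
           np.std(v) <= 1e-10 * max(scale_v, 1e-300):
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    r_obs = _safe_corr(rx, ry, np.std(x), np.std(y))
    rng = np.random.default_rng(seed)
    n = ax.shape[0]
    count = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        yp = _condensed(ay[np.ix_(idx, idx)])
        rp = _safe_corr(rx, _residualize(yp, z), np.std(x), np.std(yp))
        if rp >= r_obs:
            count += 1
    return MantelResult(r_obs, (1 + count) / (1 + n_perm), n_perm)


# ---------------------------------------------------------------------------
# Regressions with bootstrap slope inference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    boot_slopes: np.ndarray = field(repr=False)
    ci95: tuple = (np.nan, np.nan)

    @property
    def n_boot(self) -> int:
        return len(self.boot_slopes)


def _finish_regression(slope, intercept, r, boot_slopes) -> RegressionResult:
    boot_slopes = np.asarray(boot_slopes, float)
    ci = tuple(np.percentile(boot_slopes, [2.5, 97.5]))
    if np.std(boot_slopes, ddof=1) == 0:
        p = 1.0 if slope == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(boot_slopes, 0.0).pvalue)
    return RegressionResult(slope, intercept, r, p, boot_slopes, ci)


def distance_decay(sim, geo, pairs_filter=None, n_boot: int = 1000,
                   seed: int = 0) -> RegressionResult:
    """OLS of pairwise community similarity on geographic distance (km).

    ``pairs_filter`` may be a boolean sample-pair matrix selecting which
    pairs enter the fit.  Bootstrap resamples samples with replacement,
    rebuilding the pair set each time (self-pairs of a repeated sample are
    excluded); p tests slope != 0 by a t test on the bootstrap slopes.
    """
    s = _as_square(sim)
    g = _as_square(geo)
    if s.shape != g.shape:
        raise ValueError("matrices must have the same order")
    n = s.shape[0]
    mask = np.ones((n, n), bool) if pairs_filter is None else np.asarray(pairs_filter, bool)
    iu = np.triu_indices(n, 1)
    sel = mask[iu]
    x, y = g[iu][sel], s[iu][sel]
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct geographic distances")
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ii, jj = np.meshgrid(idx, idx, indexing="ij")
        tri = np.triu_indices(n, 1)
        a, b = ii[tri], jj[tri]
        keep = (a != b) & mask[a, b]
        xb, yb = g[a[keep], b[keep]], s[a[keep], b[keep]]
        if np.unique(xb).size < 2:
            boot.append(0.0)
            continue
        boot.append(stats.linregress(xb, yb).slope)
    return _finish_regression(fit.slope, fit.intercept, fit.rvalue, boot)


def bootstrap_regression(x, y, n_boot: int = 1000, seed: int = 0) -> RegressionResult:
    """OLS of a per-sample response on a per-sample predictor (e.g. alpha
    diversity on latitude), with sample-bootstrap slope inference."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("x and y must be equal length, >= 3")
    if np.unique(x).size < 2:
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    rng = np.random.default_rng(seed)
    n = x.size
    boot = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        if np.unique(x[idx]).size < 2:
            boot.append(0.0)
            continue
        boot.append(stats.linregress(x[idx], y[idx]).slope)
    return _finish_regression(fit.slope, fit.intercept, fit.rvalue, boot)


def slope_difference_test(res_a: RegressionResult, res_b: RegressionResult,
                          paired: bool = False):
    """Difference between two regression slopes, tested on their bootstrap
    replicate distributions (unpaired t by default)."""
    if res_a.n_boot != res_b.n_boot:
        raise ValueError("bootstrap vectors must have the same length")
    delta = res_a.slope - res_b.slope
    if paired:
        diffs = res_a.boot_slopes - res_b.boot_slopes
        if np.std(diffs, ddof=1) == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            p = float(stats.ttest_1samp(diffs, 0.0).pvalue)
    else:
        if np.std(res_a.boot_slopes, ddof=1) == 0 and np.std(res_b.boot_slopes, ddof=1) == 0:
            p = 1.0 if delta == 0 else 0.0
        else:
            p = float(stats.ttest_ind(res_a.boot_slopes, res_b.boot_slopes).pvalue)
    return delta, p


# ---------------------------------------------------------------------------
# Group similarity contrasts
# ---------------------------------------------------------------------------

def host_pair_group(row_i: pd.Series, row_j: pd.Series) -> str:
    hi, hj = str(row_i["host_species"]), str(row_j["host_species"])
    return f"within {hi}" if hi == hj else "between hosts"


def host_site_pair_group(row_i: pd.Series, row_j: pd.Series) -> str:
    same_h = str(row_i["host_species"]) == str(row_j["host_species"])
    same_s = str(row_i["site"]) == str(row_j["site"])
    return (f"{'S' if same_h else 'D'}.host&{'S' if same_s else 'D'}.site")


def group_similarity_contrast(sim, meta: pd.DataFrame, group_of_pair,
                              reference: str, n_boot: int = 1000,
                              seed: int = 0) -> pd.DataFrame:
    """Mean pairwise similarity per pair group and percent change vs a
    reference group, with sample-bootstrap CIs and Student's t p-values.

    ``group_of_pair(meta_row_i, meta_row_j)`` labels each pair (None
    excludes it); percent change = 100 (mean_g - mean_ref) / mean_ref.
    """
    s = _as_square(sim)
    n = s.shape[0]
    if len(meta) != n:
        raise ValueError("metadata and similarity matrix order disagree")
    rows = [meta.iloc[i] for i in range(n)]
    label = np.full((n, n), None, dtype=object)
    for i in range(n):
        for j in range(i + 1, n):
            label[i, j] = label[j, i] = group_of_pair(rows[i], rows[j])

    def group_means(sample_idx):
        vals = {}
        kk = np.asarray(sample_idx)
        for ai in range(len(kk)):
            for aj in range(ai + 1, len(kk)):
                i, j = kk[ai], kk[aj]
                if i == j:
                    continue
                lab = label[i, j]
                if lab is not None:
                    vals.setdefault(lab, []).append(s[i, j])
        return {k: float(np.mean(v)) for k, v in vals.items()}

    obs = group_means(np.arange(n))
    if reference not in obs:
        raise ValueError(f"reference group {reference!r} has no pairs")
    rng = np.random.default_rng(seed)
    boot = {g: [] for g in obs}
    for _ in range(n_boot):
        gm = group_means(rng.integers(0, n, size=n))
        if reference not in gm:
            continue
        for g in boot:
            if g in gm:
                boot[g].append(100.0 * (gm[g] - gm[reference]) / gm[reference])
    iu = np.triu_indices(n, 1)
    values = {g: s[iu][np.array([label[i, j] == g for i, j in zip(*iu)])]
              for g in obs}
    recs = []
    for g in sorted(obs):
        pct = 100.0 * (obs[g] - obs[reference]) / obs[reference]
        bs = np.asarray(boot[g]) if boot[g] else np.array([pct])
        lo, hi = np.percentile(bs, [2.5, 97.5])
        if g == reference:
            p = np.nan
        else:
            p = float(stats.ttest_ind(values[g], values[reference]).pvalue)
        recs.append({"group": g, "mean_similarity": obs[g],
                     "pct_change": pct, "ci_lo": lo, "ci_hi": hi,
                     "p": p, "n_pairs": len(values[g])})
    return pd.DataFrame(recs)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must be in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
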