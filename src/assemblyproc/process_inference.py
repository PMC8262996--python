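"""Five-way ecological-process classification and group-level summaries.

Each sample pair is assigned the process dominating its turnover from its
(betaNTI, RC) coordinates, selection being evaluated before dispersal:

* betaNTI < -2         -> homogeneous selection
* betaNTI >  2         -> variable selection
* |betaNTI| <= 2, RC < -0.95 -> homogeneous dispersal
* |betaNTI| <= 2, RC >  0.95 -> dispersal limitation
* otherwise            -> undominated (drift)

Pairs are then grouped by shared/different host and site, fractions of each
process are summarized per group with bootstrap confidence intervals, and
host-/site-induced shifts in those fractions are tested (bootstrap + t test,
Benjamini-Hochberg adjusted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import OtuTable
from .null_models import NullConfig, bnti_matrix, raup_crick_bray

PROCESS_LABELS = (
    "homogeneous_selection",
    "variable_selection",
    "homogeneous_dispersal",
    "dispersal_limitation",
    "undominated",
)
UNCLASSIFIED = "unclassified"

PAIR_GROUPS = ("S.host&S.site", "S.host&D.site", "D.host&S.site", "D.host&D.site")


@dataclass(frozen=True)
class ClassifierThresholds:
    bnti_cut: float = 2.0
    rc_cut: float = 0.95

    def __post_init__(self):
        if self.bnti_cut <= 0 or self.rc_cut <= 0:
            raise ValueError("thresholds must be positive")


def classify_pair(bnti: float, rc: float,
                  thresholds: ClassifierThresholds = ClassifierThresholds()) -> str:
    """Assign one pair's dominant process; boundaries are inclusive toward
    the non-selection / non-dispersal side (betaNTI = 2 is not selection,
    RC = 0.95 is not dispersal)."""
    if math.isnan(bnti) or math.isnan(rc):
        return UNCLASSIFIED
    if bnti < -thresholds.bnti_cut:
        return "homogeneous_selection"
    if bnti > thresholds.bnti_cut:
        return "variable_selection"
    if rc < -thresholds.rc_cut:
        return "homogeneous_dispersal"
    if rc > thresholds.rc_cut:
        return "dispersal_limitation"
    return "undominated"


def infer_processes(tables, tree, meta=None,
                    null_config: NullConfig = NullConfig(),
                    thresholds: ClassifierThresholds = ClassifierThresholds(),
                    aggregation: str = "mean") -> pd.DataFrame:
    """Per-pair betaNTI and RC across rarefied replicate tables, aggregated,
    then classified.

    With ``aggregation='mean'`` (default) the indices are averaged over
    replicates and the means classified once; ``'vote'`` classifies each
    replicate and takes the modal label.  Replicates where a pair's null is
    degenerate are dropped from that pair's aggregate (count retained in
    ``n_replicates_used``).
    """
    if isinstance(tables, OtuTable):
        tables = [tables]
    if not tables:
        raise ValueError("need at least one table")
    if aggregation not in ("mean", "vote"):
        raise ValueError("aggregation must be 'mean' or 'vote'")
    ids = list(tables[0].sample_ids)
    for t in tables:
        if list(t.sample_ids) != ids:
            raise ValueError("replicate tables must share sample ids and order")

    children = np.random.SeedSequence(null_config.seed).spawn(len(tables))
    bnti_stack, rc_stack = [], []
    for t, child in zip(tables, children):
        sb, sr = child.spawn(2)
        cfg_b = NullConfig(null_config.n_randomizations,
                           int(sb.generate_state(1)[0] % (2**31)),
                           null_config.abundance_transform, null_config.tie_weight)
        cfg_r = NullConfig(null_config.n_randomizations,
                           int(sr.generate_state(1)[0] % (2**31)),
                           null_config.abundance_transform, null_config.tie_weight)
        bnti_stack.append(bnti_matrix(t, tree, cfg_b).to_numpy())
        rc_stack.append(raup_crick_bray(t, cfg_r).to_numpy())
    bnti_stack = np.stack(bnti_stack)
    rc_stack = np.stack(rc_stack)

    recs = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            b = bnti_stack[:, i, j]
            r = rc_stack[:, i, j]
            ok = ~(np.isnan(b) | np.isnan(r))
            n_used = int(ok.sum())
            if n_used == 0:
                mb = mr = float("nan")
                label = UNCLASSIFIED
            elif aggregation == "mean":
                mb, mr = float(b[ok].mean()), float(r[ok].mean())
                label = classify_pair(mb, mr, thresholds)
            else:
                mb, mr = float(b[ok].mean()), float(r[ok].mean())
                votes = [classify_pair(bb, rr, thresholds)
                         for bb, rr in zip(b[ok], r[ok])]
                label = max(sorted(set(votes)), key=votes.count)
            recs.append({
                "sample_i": ids[i], "sample_j": ids[j],
                "bnti": mb, "rc": mr,
                "bnti_sd": float(np.nanstd(b[ok], ddof=1)) if n_used > 1 else 0.0,
                "rc_sd": float(np.nanstd(r[ok], ddof=1)) if n_used > 1 else 0.0,
                "process": label, "n_replicates_used": n_used,
            })
    pair_df = pd.DataFrame(recs)
    if meta is not None:
        pair_df = group_pairs(meta, pair_df)
    return pair_df


def group_pairs(meta: pd.DataFrame, pair_table: pd.DataFrame) -> pd.DataFrame:
    """Label each pair by shared/different host and site, e.g. 'S.host&D.site'."""
    needed = set(pair_table["sample_i"]) | set(pair_table["sample_j"])
    missing = sorted(needed - set(meta.index))
    if missing:
        raise ValueError(f"samples missing from metadata: {missing[:5]}")
    bad = meta.loc[sorted(needed), ["host_species", "site"]].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"missing host/site for: {list(bad[bad].index)[:5]}")
    host = meta["host_species"].astype(str)
    site = meta["site"].astype(str)
    out = pair_table.copy()
    hi = host.loc[out["sample_i"]].to_numpy()
    hj = host.loc[out["sample_j"]].to_numpy()
    si = site.loc[out["sample_i"]].to_numpy()
    sj = site.loc[out["sample_j"]].to_numpy()
    out["host_i"], out["host_j"] = hi, hj
    out["site_i"], out["site_j"] = si, sj
    out["pair_group"] = np.where(
        hi == hj,
        np.where(si == sj, "S.host&S.site", "S.host&D.site"),
        np.where(si == sj, "D.host&S.site", "D.host&D.site"),
    )
    return out


def _fractions(labels: np.ndarray) -> np.ndarray:
    return np.array([(labels == lab).mean() for lab in PROCESS_LABELS])


def summarize_fractions(pair_table: pd.DataFrame, grouping: str = "pair_group",
                        n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Relative importance of each process per pair group.

    Fractions are over classified pairs only and sum to 1 within each group;
    95% CIs are percentile bootstrap over pairs.  ``grouping=None`` pools
    all pairs into one group ("all").
    """
    df = pair_table.copy()
    if grouping is None:
        df["_group"] = "all"
        grouping = "_group"
    rng = np.random.default_rng(seed)
    recs = []
    for group, sub in df.groupby(grouping, sort=True):
        labels = sub.loc[sub["process"] != UNCLASSIFIED, "process"].to_numpy()
        n_pairs = labels.size
        if n_pairs == 0:
            continue
        frac = _fractions(labels)
        boot = np.empty((n_boot, len(PROCESS_LABELS)))
        for b in range(n_boot):
            boot[b] = _fractions(rng.choice(labels, size=n_pairs, replace=True))
        lo, hi = np.percentile(boot, [2.5, 97.5], axis=0)
        for k, lab in enumerate(PROCESS_LABELS):
            recs.append({"group": group, "process": lab, "fraction": frac[k],
                         "ci_lo": lo[k], "ci_hi": hi[k], "n_pairs": n_pairs})
    return pd.DataFrame(recs)


_CONTRAST_GROUPS = {
    # induced shift = fraction(varied factor differs) - fraction(baseline),
    # the other factor held at "same"
    "host": ("S.host&S.site", "D.host&S.site"),
    "site": ("S.host&S.site", "S.host&D.site"),
}


def process_shift(pair_table: pd.DataFrame, contrast: str,
                  n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Host- or site-induced change of each process's relative importance.

    delta = fraction in the changed-factor group minus fraction in the
    same-host-same-site baseline; 95% percentile CI and two-sided p from a
    one-sample t test on the bootstrap deltas.  Degenerate (zero-variance)
    bootstraps get an exact 0/1 p and a flag.
    """
    try:
        ref_name, alt_name = _CONTRAST_GROUPS[contrast]
    except KeyError:
        raise ValueError(f"contrast must be one of {sorted(_CONTRAST_GROUPS)}")
    df = pair_table[pair_table["process"] != UNCLASSIFIED]
    ref = df.loc[df["pair_group"] == ref_name, "process"].to_numpy()
    alt = df.loc[df["pair_group"] == alt_name, "process"].to_numpy()
    if ref.size == 0 or alt.size == 0:
        raise ValueError(f"contrast {contrast!r}: empty group "
                         f"({ref_name}: {ref.size}, {alt_name}: {alt.size})")
    rng = np.random.default_rng(seed)
    deltas = np.empty((n_boot, len(PROCESS_LABELS)))
    for b in range(n_boot):
        fr = _fractions(rng.choice(ref, size=ref.size, replace=True))
        fa = _fractions(rng.choice(alt, size=alt.size, replace=True))
        deltas[b] = fa - fr
    point = _fractions(alt) - _fractions(ref)
    lo, hi = np.percentile(deltas, [2.5, 97.5], axis=0)
    recs = []
    for k, lab in enumerate(PROCESS_LABELS):
        col = deltas[:, k]
        degenerate = bool(np.std(col, ddof=1) == 0)
        if degenerate:
            p = 1.0 if point[k] == 0 else 0.0
        else:
            p = float(stats.ttest_1samp(col, 0.0).pvalue)
        recs.append({"contrast": contrast, "process": lab, "delta": point[k],
                     "ci_lo": lo[k], "ci_hi": hi[k], "p": p,
                     "degenerate": degenerate,
                     "n_ref": ref.size, "n_alt": alt.size})
    return pd.DataFrame(recs)


def process_shifts(pair_table: pd.DataFrame, n_boot: int = 1000,
                   seed: int = 0) -> pd.DataFrame:
    """Both host- and site-induced shifts, BH-adjusted across the
    10-test family (5 processes x 2 contrasts)."""
    from .geo_stats import bh_adjust

    ss = np.random.SeedSequence(seed).spawn(2)
    parts = [
        process_shift(pair_table, c, n_boot,
                      int(s.generate_state(1)[0] % (2**31)))
        for c, s in zip(("host", "site"), ss)
    ]
    out = pd.concat(parts, ignore_index=True)
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
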