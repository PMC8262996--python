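"""Rarefaction, alpha diversity, Bray-Curtis and core-OTU identification.

Uneven sequencing depth biases every between-sample comparison, so the
whole pipeline works on tables rarefied to a common depth.  Rarefaction is
replicated (default 100 tables at 19,600 reads/sample) and downstream
quantities are averaged over the replicates rather than computed on a
single arbitrary draw.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix, TreeNode
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import faith_pd as _skbio_faith_pd

from .io_formats import OtuTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RarefactionConfig:
    """Replicated-rarefaction settings (defaults mirror the honeybee study:
    100 tables at 19,600 reads per sample)."""

    depth: int = 19600
    n_tables: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.n_tables < 1:
            raise ValueError("depth and n_tables must be positive")


@dataclass(frozen=True)
class CoreOtuRule:
    """Local core-OTU thresholds: mean relative abundance >= 0.1% and
    occurrence in >= 80% of a site's samples (>= ceil(0.8 n))."""

    min_rel_abundance: float = 0.001
    min_occurrence: float = 0.8

    def __post_init__(self):
        for v in (self.min_rel_abundance, self.min_occurrence):
            if not (0 < v <= 1):
                raise ValueError("rule thresholds must be in (0, 1]")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int, strict: bool = False) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Uses the multivariate hypergeometric distribution, i.e. an exact uniform
    draw of ``depth`` reads from each sample's observed library.  Samples
    with fewer than ``depth`` reads are dropped (error under ``strict``).
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    totals = table.sample_totals()
    shallow = totals < depth
    if shallow.any():
        names = [s for s, f in zip(table.sample_ids, shallow) if f]
        if strict:
            raise ValueError(f"sample(s) below depth {depth}: {names}")
        logger.warning("dropping %d sample(s) below depth %d", len(names), depth)
    keep = ~shallow
    rng = np.random.default_rng(seed)
    counts = table.counts[keep]
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        out[i] = rng.multivariate_hypergeometric(row, depth)
    ids = tuple(s for s, k in zip(table.sample_ids, keep) if k)
    return OtuTable(ids, table.otu_ids, out)


def rarefy_replicates(table: OtuTable, config: RarefactionConfig) -> list:
    """``config.n_tables`` independent rarefactions, reproducible from
    ``config.seed`` (per-replicate seeds are spawned from it)."""
    children = np.random.SeedSequence(config.seed).spawn(config.n_tables)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    return [rarefy(table, config.depth, seed=s) for s in seeds]


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if not (counts > 0).any():
        return 0.0
    return float(_skbio_chao1(counts, bias_corrected=True))


def faith_pd(sample_counts, tree: TreeNode, otu_ids=None, include_stem=True) -> float:
    """Faith's phylogenetic diversity of one sample.

    Sum of branch lengths of the minimal subtree spanning the root and all
    present tips (root-inclusive by default; ``include_stem=False`` removes
    the root-to-MRCA path).
    """
    counts = np.asarray(sample_counts)
    if otu_ids is None:
        otu_ids = [t.name for t in tree.tips()]
    if not (counts > 0).any():
        return 0.0
    pd_val = float(_skbio_faith_pd(counts, taxa=list(otu_ids), tree=tree))
    if not include_stem:
        present = [o for o, c in zip(otu_ids, counts) if c > 0]
        node = tree.lca(present) if len(present) > 1 else tree.find(present[0])
        stem = 0.0
        while node is not tree and node.parent is not None:
            stem += node.length or 0.0
            node = node.parent
        pd_val -= stem
    return pd_val


def alpha_diversity_frame(tables, tree: TreeNode) -> pd.DataFrame:
    """Per-sample Chao1 and Faith PD, averaged across rarefied replicates."""
    if isinstance(tables, OtuTable):
        tables = [tables]
    acc = {}
    for t in tables:
        order = [tip.name for tip in tree.tips()]
        col_of = {o: i for i, o in enumerate(t.otu_ids)}
        idx = [col_of[o] for o in order]
        for s, row in zip(t.sample_ids, t.counts):
            rec = acc.setdefault(s, {"chao1": [], "faith_pd": []})
            rec["chao1"].append(chao1(row))
            rec["faith_pd"].append(faith_pd(row[idx], tree, otu_ids=order))
    out = pd.DataFrame(
        {
            "chao1": {s: np.mean(v["chao1"]) for s, v in acc.items()},
            "faith_pd": {s: np.mean(v["faith_pd"]) for s, v in acc.items()},
        }
    )
    out.index.name = "sample_id"
    return out


# ---------------------------------------------------------------------------
# Beta diversity
# ---------------------------------------------------------------------------

def bray_curtis_matrix(table: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, BC = sum|x-y| / sum(x+y).

    Community similarity used elsewhere in the pipeline is 1 - BC.
    """
    if table.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    if np.isnan(d).any():
        raise ValueError("undefined Bray-Curtis entry (pair of all-zero samples)")
    return DistanceMatrix(d, ids=list(table.sample_ids))


# ---------------------------------------------------------------------------
# Core OTUs
# ---------------------------------------------------------------------------

def local_core_otus(table: OtuTable, meta: pd.DataFrame, site, rule: CoreOtuRule,
                    abundance_scope: str = "site_mean") -> set:
    """OTUs core to one site: occurrence >= ceil(min_occurrence * n_samples)
    and relative abundance above threshold.

    ``abundance_scope`` selects how the abundance filter reads: the default
    applies it to the within-site mean relative abundance; ``any_sample``
    requires the threshold in at least one sample (the display-tree variant).
    """
    samples = [s for s in table.sample_ids if str(meta.loc[s, "site"]) == str(site)]
    if not samples:
        raise ValueError(f"unknown or empty site {site!r}")
    sub = table.select_samples(samples)
    rel = sub.relative_abundance()
    occurrence = (sub.counts > 0).sum(axis=0)
    min_n = math.ceil(rule.min_occurrence * len(samples))
    occ_ok = occurrence >= min_n
    if abundance_scope == "site_mean":
        ab_ok = rel.mean(axis=0) >= rule.min_rel_abundance
    elif abundance_scope == "any_sample":
        ab_ok = (rel >= rule.min_rel_abundance).any(axis=0)
    else:
        raise ValueError(f"unknown abundance_scope {abundance_scope!r}")
    return {o for o, a, b in zip(sub.otu_ids, occ_ok, ab_ok) if a and b}


@dataclass(frozen=True)
class CoreOtuResult:
    otus: frozenset
    abundance_fraction: float


def regional_core_otus(table: OtuTable, meta: pd.DataFrame,
                       rule: CoreOtuRule = CoreOtuRule(),
                       abundance_scope: str = "site_mean") -> dict:
    """Per-host regional core OTUs: local core at every site, plus the mean
    relative abundance the core set accounts for in that host's samples."""
    out = {}
    for host in sorted(meta["host_species"].astype(str).unique()):
        samples = [s for s in table.sample_ids
                   if str(meta.loc[s, "host_species"]) == host]
        sub = table.select_samples(samples)
        sub_meta = meta.loc[samples]
        sites = sorted(sub_meta["site"].astype(str).unique())
        core = None
        for site in sites:
            local = local_core_otus(sub, sub_meta, site, rule, abundance_scope)
            core = local if core is None else core & local
        core = core or set()
        rel = sub.relative_abundance()
        cols = [i for i, o in enumerate(sub.otu_ids) if o in core]
        frac = float(rel[:, cols].sum(axis=1).mean()) if cols else 0.0
        out[host] = CoreOtuResult(frozenset(core), frac)
    return out
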