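"""Reading, validation and alignment of the three pipeline inputs.

The pipeline consumes a sample-by-OTU count table (TSV or BIOM-v1 JSON), a
rooted newick tree whose tips are OTU ids, and a per-sample metadata CSV
(host species, site, coordinates, climate, haplotype).  Everything downstream
assumes the three are id-aligned; :func:`align_inputs` enforces that once so
the statistical modules never re-check.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

METADATA_COLUMNS = (
    "sample_id",
    "host_species",
    "site",
    "latitude",
    "longitude",
    "mat",
    "map_mm",
    "haplotype",
)
_REQUIRED_METADATA = METADATA_COLUMNS[:-1]  # haplotype is optional


class FormatError(ValueError):
    """Raised when an input file violates the declared dialect."""


@dataclass(frozen=True)
class OtuTable:
    """Integer count matrix, rows = samples, columns = OTUs.

    Counts must be non-negative integers (rarefaction draws reads without
    replacement, so fractional "counts" are rejected rather than rounded)
    and every sample must contain at least one read.
    """

    sample_ids: tuple = field()
    otu_ids: tuple = field()
    counts: np.ndarray = field()

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "otu_ids", tuple(str(o) for o in self.otu_ids))
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if np.issubdtype(counts.dtype, np.floating) and np.all(
                counts == np.floor(counts)
            ):
                counts = counts.astype(np.int64)
            else:
                raise FormatError("counts must be integers (no rounding is applied)")
        counts = counts.astype(np.int64, copy=True)
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)
        for name, ids in (("sample", self.sample_ids), ("OTU", self.otu_ids)):
            dupes = _duplicates(ids)
            if dupes:
                raise FormatError(f"duplicate {name} id(s): {sorted(dupes)}")
        if (counts < 0).any():
            raise FormatError("negative counts are not allowed")
        empty = [s for s, t in zip(self.sample_ids, counts.sum(axis=1)) if t == 0]
        if empty:
            raise FormatError(f"sample(s) with zero total counts: {empty}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        totals = self.sample_totals().astype(float)
        return self.counts / totals[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.asarray(self.counts), index=list(self.sample_ids), columns=list(self.otu_ids)
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy())

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(tuple(sample_ids), self.otu_ids, self.counts[idx])

    def select_otus(self, otu_ids) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(self.sample_ids, tuple(otu_ids), self.counts[:, idx])

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=0) > 0
        ids = tuple(o for o, k in zip(self.otu_ids, keep) if k)
        return OtuTable(self.sample_ids, ids, self.counts[:, keep])


def _duplicates(ids):
    seen, dup = set(), set()
    for i in ids:
        (dup if i in seen else seen).add(i)
    return dup


# ---------------------------------------------------------------------------
# OTU table I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, format="tsv", transpose=None, known_sample_ids=None) -> OtuTable:
    """Read a count table.

    TSV dialect: first column holds sample ids and the header row the OTU ids.
    ``transpose=True`` declares the opposite orientation (rows = OTUs).  With
    ``transpose=None`` and ``known_sample_ids`` given, the orientation is
    auto-detected by matching header tokens against the known sample ids.
    BIOM-v1 JSON stores observations (OTUs) as rows by definition.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if transpose is None and known_sample_ids is not None:
            known = set(map(str, known_sample_ids))
            header_hits = sum(str(c) in known for c in df.columns)
            index_hits = sum(str(i) in known for i in df.index)
            transpose = header_hits > index_hits
        if transpose:
            df = df.T
        _check_numeric(df, path)
        return OtuTable.from_dataframe(df)
    elif format == "biom-json":
        with open(path) as fh:
            doc = json.load(fh)
        return _biom_to_table(doc)
    raise ValueError(f"unknown format {format!r}")


def _check_numeric(df: pd.DataFrame, path):
    bad = df.columns[[not np.issubdtype(d, np.number) for d in df.dtypes]]
    if len(bad):
        raise FormatError(f"{path}: non-numeric column(s) {list(bad)}")


def _biom_to_table(doc) -> OtuTable:
    otu_ids = tuple(r["id"] for r in doc["rows"])
    sample_ids = tuple(c["id"] for c in doc["columns"])
    n_r, n_c = doc["shape"]
    mat = np.zeros((n_r, n_c), dtype=np.int64)
    if doc.get("matrix_type", "sparse") == "dense":
        mat[:] = np.asarray(doc["data"])
    else:
        for r, c, v in doc["data"]:
            mat[r, c] = v
    # BIOM rows are observations -> transpose to samples x OTUs
    return OtuTable(sample_ids, otu_ids, mat.T)


def write_otu_table(table: OtuTable, path, format="tsv") -> None:
    if format == "tsv":
        table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom-json":
        rows, cols = [], []
        data = []
        mat = table.counts.T  # observations x samples
        for i, o in enumerate(table.otu_ids):
            rows.append({"id": o, "metadata": None})
        for j, s in enumerate(table.sample_ids):
            cols.append({"id": s, "metadata": None})
        nz = np.nonzero(mat)
        for r, c in zip(*nz):
            data.append([int(r), int(c), int(mat[r, c])])
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": [len(rows), len(cols)],
            "rows": rows,
            "columns": cols,
            "data": data,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Tree I/O
# ---------------------------------------------------------------------------

_COMMENT_RE = re.compile(r"\[[^\]\[]*\]")


def read_tree(path, missing_lengths="error") -> TreeNode:
    """Read a single rooted newick tree.

    Bracketed comments are stripped before parsing.  Missing branch lengths
    are an error by default; ``missing_lengths="zero"`` substitutes 0 with a
    warning (the root's own length may always be absent).
    """
    with open(path) as fh:
        text = fh.read()
    return parse_tree(text, missing_lengths=missing_lengths)


def parse_tree(text: str, missing_lengths="error") -> TreeNode:
    text = _COMMENT_RE.sub("", text)
    try:
        tree = TreeNode.read([text])
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"unparsable newick: {exc}") from exc
    tips = [t.name for t in tree.tips()]
    dupes = _duplicates(tips)
    if dupes:
        raise FormatError(f"duplicate tip label(s): {sorted(dupes)}")
    if any(t is None for t in tips):
        raise FormatError("unlabeled tip in tree")
    missing = [
        n for n in tree.traverse(include_self=False) if n.length is None
    ]
    if missing:
        if missing_lengths == "zero":
            logger.warning("%d branch(es) without length set to 0", len(missing))
            for n in missing:
                n.length = 0.0
        else:
            raise FormatError(f"{len(missing)} branch(es) lack branch lengths")
    if tree.length is None:
        tree.length = 0.0
    neg = [n for n in tree.traverse() if (n.length or 0) < 0]
    if neg:
        raise FormatError("negative branch length(s)")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Metadata I/O
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read the sample metadata CSV; returns a frame indexed by sample_id."""
    df = pd.read_csv(path, dtype={"sample_id": str, "site": str})
    return validate_metadata(df)


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    if df.index.name == "sample_id":
        df = df.reset_index()
    missing = [c for c in _REQUIRED_METADATA if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing column(s): {missing}")
    if "haplotype" not in df.columns:
        df = df.assign(haplotype=pd.NA)
    dupes = _duplicates(df["sample_id"].astype(str))
    if dupes:
        raise FormatError(f"duplicate sample_id(s) in metadata: {sorted(dupes)}")
    lat, lon = df["latitude"], df["longitude"]
    if ((lat < -90) | (lat > 90)).any():
        raise FormatError("latitude outside [-90, 90]")
    if ((lon < -180) | (lon > 180)).any():
        raise FormatError("longitude outside [-180, 180]")
    out = df.set_index(df["sample_id"].astype(str)).drop(columns=["sample_id"])
    out.index.name = "sample_id"
    return out


def write_metadata(meta: pd.DataFrame, path) -> None:
    meta.reset_index().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Alignment
# ---------------------------------------------------------------------------

def align_inputs(table: OtuTable, tree: TreeNode, meta: pd.DataFrame,
                 allow_missing_tips=False):
    """Restrict table/tree/metadata to their common ids.

    The table keeps only samples present in the metadata (table order); the
    tree is pruned to the table's OTUs.  OTUs missing from the tree are an
    error by default; with ``allow_missing_tips`` they are dropped from the
    table and the count is logged.  Idempotent.
    """
    meta = validate_metadata(meta.copy())
    common = [s for s in table.sample_ids if s in meta.index]
    if not common:
        raise FormatError("no samples shared between table and metadata")
    table = table.select_samples(common)
    meta = meta.loc[common]

    tip_names = {t.name for t in tree.tips()}
    missing = [o for o in table.otu_ids if o not in tip_names]
    if missing:
        if not allow_missing_tips:
            raise FormatError(
                f"{len(missing)} OTU(s) absent from tree, e.g. {missing[:5]}"
            )
        logger.warning("dropping %d OTU(s) absent from tree", len(missing))
        keep = [o for o in table.otu_ids if o in tip_names]
        table = table.select_otus(keep)
        empties = table.counts.sum(axis=1) == 0
        if empties.any():
            raise FormatError(
                "dropping tree-missing OTUs left sample(s) empty: "
                f"{[s for s, e in zip(table.sample_ids, empties) if e]}"
            )
    if tip_names != set(table.otu_ids):
        tree = tree.shear(list(table.otu_ids))
        tree.prune()
        if tree.length is None:
            tree.length = 0.0
    return table, tree, meta


def write_pairwise_long(matrix: np.ndarray, ids, path, value_columns=None) -> None:
    """Write pairwise matrices as long TSV (sample_i, sample_j, metrics)."""
    mats = matrix if isinstance(matrix, dict) else {"value": matrix}
    if value_columns:
        mats = dict(zip(value_columns, mats.values()))
    n = len(ids)
    recs = []
    for i in range(n):
        for j in range(i + 1, n):
            recs.append([ids[i], ids[j]] + [m[i, j] for m in mats.values()])
    pd.DataFrame(recs, columns=["sample_i", "sample_j", *mats.keys()]).to_csv(
        path, sep="\t", index=False
    )
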