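"""Model/Results surface tying the pipeline together.

:class:`AssemblyModel` holds the aligned inputs plus configuration;
:meth:`AssemblyModel.fit` runs rarefaction replication, both null models,
classification and group summaries, returning an :class:`AssemblyResults`
with the per-pair table, the process fractions per pair group (with
bootstrap CIs), the host-/site-induced shifts, and a text summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import diversity, io_formats, process_inference
from .diversity import RarefactionConfig
from .io_formats import OtuTable
from .null_models import NullConfig
from .process_inference import ClassifierThresholds, PROCESS_LABELS


class AssemblyModel:
    """Community-assembly process inference for one study.

    Parameters
    ----------
    table, tree, meta
        OTU count table, rooted tree over its OTUs, per-sample metadata.
        They are id-aligned on construction.
    rarefaction
        Replicated-rarefaction settings; ``None`` skips rarefaction and the
        table is analysed as-is (useful for pre-rarefied input).
    null, thresholds
        Null-model randomization settings and classification cutoffs.

    Examples
    --------
    >>> from assemblyproc import AssemblyModel, sim_study_design
    >>> bundle = sim_study_design(seed=7, n_replicates=3)
    >>> model = AssemblyModel(bundle.table, bundle.tree, bundle.meta,
    ...                       rarefaction=None)
    >>> res = model.fit(n_boot=200, seed=1)       # doctest: +SKIP
    >>> print(res.summary())                      # doctest: +SKIP
    """

    def __init__(self, table: OtuTable, tree, meta: pd.DataFrame,
                 rarefaction: RarefactionConfig | None = RarefactionConfig(),
                 null: NullConfig = NullConfig(),
                 thresholds: ClassifierThresholds = ClassifierThresholds(),
                 allow_missing_tips: bool = False):
        self.table, self.tree, self.meta = io_formats.align_inputs(
            table, tree, meta, allow_missing_tips=allow_missing_tips
        )
        self.rarefaction = rarefaction
        self.null = null
        self.thresholds = thresholds

    @classmethod
    def from_files(cls, table_path, tree_path, meta_path, table_format="tsv",
                   **kwargs) -> "AssemblyModel":
        meta = io_formats.read_metadata(meta_path)
        table = io_formats.read_otu_table(
            table_path, format=table_format, known_sample_ids=list(meta.index)
        )
        tree = io_formats.read_tree(tree_path)
        return cls(table, tree, meta, **kwargs)

    def rarefied_tables(self):
        if self.rarefaction is None:
            return [self.table]
        return diversity.rarefy_replicates(self.table, self.rarefaction)

    def fit(self, n_boot: int = 1000, seed: int = 0,
            aggregation: str = "mean") -> "AssemblyResults":
        tables = self.rarefied_tables()
        # samples below rarefaction depth may have been dropped
        kept = tables[0].sample_ids
        meta = self.meta.loc[list(kept)]
        pair_table = process_inference.infer_processes(
            tables, self.tree, meta, null_config=self.null,
            thresholds=self.thresholds, aggregation=aggregation,
        )
        ss = np.random.SeedSequence(seed).spawn(2)
        fractions = process_inference.summarize_fractions(
            pair_table, "pair_group", n_boot=n_boot,
            seed=int(ss[0].generate_state(1)[0] % (2**31)),
        )
        shifts = process_inference.process_shifts(
            pair_table, n_boot=n_boot,
            seed=int(ss[1].generate_state(1)[0] % (2**31)),
        )
        return AssemblyResults(self, pair_table, fractions, shifts,
                               n_replicates=len(tables))


@dataclass
class AssemblyResults:
    """Fitted process-inference results."""

    model: AssemblyModel = field(repr=False)
    pair_table: pd.DataFrame = field(repr=False)
    fractions: pd.DataFrame = field(repr=False)
    shifts: pd.DataFrame = field(repr=False)
    n_replicates: int = 1

    def overall_fractions(self) -> pd.Series:
        df = self.pair_table
        labels = df.loc[df["process"] != process_inference.UNCLASSIFIED, "process"]
        return labels.value_counts(normalize=True).reindex(
            PROCESS_LABELS, fill_value=0.0
        )

    def summary(self) -> str:
        lines = [
            "Community assembly process inference",
            "====================================",
            f"samples: {self.model.table.n_samples}   OTUs: {self.model.table.n_otus}"
            f"   rarefied replicates: {self.n_replicates}",
            f"null randomizations: {self.model.null.n_randomizations}"
            f"   thresholds: |betaNTI| > {self.model.thresholds.bnti_cut},"
            f" |RC| > {self.model.thresholds.rc_cut}",
            "",
            "Process fractions over all classified pairs:",
        ]
        for lab, frac in self.overall_fractions().items():
            lines.append(f"  {lab:<24s} {frac:6.1%}")
        lines.append("")
        lines.append("Per pair-group fractions (95% bootstrap CI):")
        for _, row in self.fractions.iterrows():
            lines.append(
                f"  {row['group']:<16s} {row['process']:<24s}"
                f" {row['fraction']:6.1%}  [{row['ci_lo']:.1%}, {row['ci_hi']:.1%}]"
                f"  n={row['n_pairs']}"
            )
        lines.append("")
        lines.append("Host-/site-induced shifts (BH-adjusted):")
        for _, row in self.shifts.iterrows():
            lines.append(
                f"  {row['contrast']:<5s} {row['process']:<24s}"
                f" delta={row['delta']:+.3f}"
                f"  CI=[{row['ci_lo']:+.3f}, {row['ci_hi']:+.3f}]"
                f"  p_adj={row['p_adj']:.3g}"
            )
        return "\n".join(lines)

    def plot_fractions(self, ax=None):
        """Stacked-bar chart of process fractions per pair group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 4))
        piv = self.fractions.pivot(index="group", columns="process",
                                   values="fraction").reindex(
            columns=list(PROCESS_LABELS)).fillna(0.0)
        bottom = np.zeros(len(piv))
        for lab in PROCESS_LABELS:
            ax.bar(piv.index, piv[lab], bottom=bottom, label=lab)
            bottom += piv[lab].to_numpy()
        ax.set_ylabel("relative importance")
        ax.set_ylim(0, 1)
        ax.legend(fontsize=8, loc="upper right")
        return ax
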