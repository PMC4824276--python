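"""Score HET outlier output against simulation truth.

An upper outlier is a hybrid signal iff it was caused by excluding the
hybrid group and sits at a node whose clade contains descendants of one of
the hybrid's parent lineages (counted once per indicated lineage). A
"maximum BS, but not outlier" signal is a hybrid-exclusion cell that is the
strict unique maximum of its row's numeric jackknife cells while inside the
k = 1.5 fence. A parent-exclusion signal is an upper outlier caused by
excluding a parent-lineage taxon at a node containing that taxon's samples.
Every other upper outlier is a false positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .matrices import TaxonGrouping
from .simulate import HybridTruth
from .support import SupportTable, boxplot_outliers

__all__ = ["EvaluationCounts", "classify_signals"]


@dataclass
class EvaluationCounts:
    """Per-run signal counts mirroring the simulation-study table layout."""

    hybrid_outliers_1p5: int = 0
    hybrid_outliers_3: int = 0
    hybrid_parent_lineages_1p5: tuple = ()
    hybrid_max_bs_not_outlier: int = 0
    max_bs_parent_lineages: tuple = ()
    parent_exclusion_outliers_1p5: int = 0
    false_positives_1p5: int = 0
    false_positives_3: int = 0
    false_positives_min2_1p5: int = 0
    lower_outliers_1p5: int = 0
    false_negative: bool = True
    mean_full_bs: float = 0.0

    def __post_init__(self):
        assert self.hybrid_outliers_3 <= self.hybrid_outliers_1p5
        assert self.false_positives_3 <= self.false_positives_1p5
        assert self.false_positives_min2_1p5 <= self.false_positives_1p5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def _clade_groups(clade, grouping: TaxonGrouping) -> set:
    return {grouping.group_of(s) for s in clade}


def _indicated_lineages(clade_groups, truth: HybridTruth) -> list:
    return [
        k for k, taxa in enumerate(truth.parent_taxa)
        if clade_groups & set(taxa)
    ]


def classify_signals(
    table: SupportTable,
    truth: HybridTruth | None,
    grouping: TaxonGrouping,
) -> EvaluationCounts:
    """Classify upper outliers of a support table into hybrid signals,
    parent-exclusion signals and false positives, at k = 1.5 and k = 3."""
    hybrid = truth.hybrid_group if truth else None
    if hybrid is not None and hybrid not in grouping.groups():
        raise ValueError(f"truth hybrid group {hybrid!r} absent from run")
    parent_groups = (
        set(truth.parent_taxa[0]) | set(truth.parent_taxa[1]) if truth else set()
    )

    counts = EvaluationCounts()
    full_vals = [
        float(v) for v in table.df["full"] if not isinstance(v, str)
    ]
    counts.mean_full_bs = sum(full_vals) / len(full_vals) if full_vals else 0.0

    summaries = {
        k: boxplot_outliers(table, k=k) for k in (1.5, 3.0)
    }
    min2_nodes = {
        s.node_id
        for s in summaries[1.5]
        if len(_clade_groups(s.clade, grouping)) >= 2
    }

    hyb_lineages: set = set()
    max_lineages: list = []
    for k, summ in summaries.items():
        for s in summ:
            cg = _clade_groups(s.clade, grouping)
            for rec in s.upper_outliers:
                lineages = _indicated_lineages(cg, truth) if truth else []
                if hybrid is not None and rec.exclusion == hybrid and lineages:
                    if k == 1.5:
                        counts.hybrid_outliers_1p5 += len(lineages)
                        hyb_lineages.update(lineages)
                    else:
                        counts.hybrid_outliers_3 += len(lineages)
                elif (
                    truth is not None
                    and rec.exclusion in parent_groups
                    and rec.exclusion in cg
                ):
                    if k == 1.5:
                        counts.parent_exclusion_outliers_1p5 += 1
                else:
                    if k == 1.5:
                        counts.false_positives_1p5 += 1
                        if s.node_id in min2_nodes:
                            counts.false_positives_min2_1p5 += 1
                    else:
                        counts.false_positives_3 += 1
            if k == 1.5:
                counts.lower_outliers_1p5 += len(s.lower_outliers)
                # "maximum BS but not outlier" at parental nodes
                if hybrid is not None:
                    vals = s.values
                    hv = vals.get(hybrid)
                    lineages = _indicated_lineages(cg, truth)
                    if (
                        hv is not None
                        and lineages
                        and hv <= s.upper_fence
                        and sum(1 for v in vals.values() if v >= hv) == 1
                    ):
                        counts.hybrid_max_bs_not_outlier += len(lineages)
                        max_lineages.extend(lineages)

    counts.hybrid_parent_lineages_1p5 = tuple(sorted(hyb_lineages))
    counts.max_bs_parent_lineages = tuple(sorted(set(max_lineages)))
    counts.false_negative = truth is not None and counts.hybrid_outliers_1p5 == 0
    return counts
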