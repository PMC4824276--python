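"""Support accounting across jackknife analyses.

Every internal node of the full tree is mapped into each jackknife analysis:

* SC (support carryover): the node is the sister clade of the excluded
  group. Removing a taxon inflates its sister's support regardless of
  hybridization, so these cells are never scored and never enter outlier
  statistics.
* NA: the node had joined the excluded taxon — its restriction to the
  remaining leaves is trivial (fewer than 2 leaves on either side) or
  collapses onto another node's restriction (the attachment node of an
  excluded clade collapses onto the sister).
* otherwise the node is scored by the frequency of its restricted
  bipartition in that jackknife's bootstrap tree series (0 if absent).

Outliers in the per-node distributions of jackknife BS values are detected
with Tukey boxplot fences: values beyond k*IQR from the hinges (k = 1.5 or
3 in published applications).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .jackknife import HETResult

__all__ = [
    "SC",
    "NA",
    "SupportTable",
    "BoxplotSummary",
    "OutlierRecord",
    "AltNodeRegistry",
    "restrict_node",
    "compile_support_table",
    "tukey_hinges",
    "boxplot_outliers",
    "query_custom_node",
    "alt_nodes",
]

SC = "SC"
NA = "NA"
MIN_CELLS = 5


# ---------------------------------------------------------------------------
# node restriction


def _root_reference(leaves, grouping, excluded=frozenset()):
    """Leaf used to orient bipartitions as rooted clades: an outgroup sample
    when available, else the smallest non-excluded label."""
    candidates = None
    if grouping is not None and grouping.outgroup is not None:
        og = [s for s in grouping.groups()[grouping.outgroup]
              if s in leaves and s not in excluded]
        if og:
            candidates = og
    if candidates is None:
        candidates = [s for s in leaves if s not in excluded]
    return min(candidates)


def _orient(splits, ref, full):
    """Re-orient canonical splits so no clade contains ``ref``. Returns
    oriented-clade -> original split."""
    out = {}
    for s in splits:
        c = frozenset(full - s) if ref in s else frozenset(s)
        out[c] = s
    return out


def restrict_statuses(full_splits, leaves, excluded, grouping=None):
    """Status of every full-tree node under one exclusion.

    Returns original split -> SC | NA | frozenset (the restricted clade to
    be looked up in the jackknife series).

    Splits are treated as clades of the tree rooted at the outgroup (or at
    the smallest non-excluded leaf when no outgroup is given). When an
    excluded clade's attachment edge collapses, the rooting decides which
    of the two merging rows reads SC (the sister) and which reads NA (the
    node that had joined the excluded taxon); neither is ever scored, so
    the outlier statistics do not depend on the rooting choice.
    """
    full = set(leaves)
    E = frozenset(excluded)
    ref = _root_reference(full, grouping, E)
    oriented = _orient(full_splits, ref, full)
    clades = set(oriented)

    # sister of the excluded set, when it forms a clade in the full tree
    sister = None
    if E in clades or len(E) == 1:
        supersets = [c for c in clades if E < c]
        parent = min(supersets, key=len) if supersets else frozenset(full - {ref})
        cand = parent - E
        if len(cand) >= 2 and cand in clades:
            sister = cand

    remaining = full - E
    by_restriction: dict = {}
    status: dict = {}
    for c in clades:
        r = c - E
        rest = remaining - r
        if len(r) < 2 or len(rest) < 2:
            status[c] = NA
            continue
        by_restriction.setdefault(r, []).append(c)

    for r, cs in by_restriction.items():
        unchanged = [c for c in cs if c == r]
        if unchanged:
            keep = unchanged[0]
        else:
            keep = min(cs, key=lambda c: (len(c), tuple(sorted(c))))
        for c in cs:
            status[c] = r if c == keep else NA
        if sister is not None and sister in cs:
            status[sister] = SC
            # the attachment node (and any other duplicate) stays NA

    return {oriented[c]: st for c, st in status.items()}


def restrict_node(full_clade, excluded, full_tree, grouping=None):
    """SC / NA / restricted-clade status of one full-tree node under an
    exclusion. ``full_tree`` is the full reference :class:`~hetscan.nj.Tree`.
    """
    splits = full_tree.splits()
    leaves = full_tree.leaf_names
    from .nj import canonical_split

    key = canonical_split(set(full_clade), leaves)
    if key not in splits:
        raise ValueError("full_clade is not an internal node of the full tree")
    return restrict_statuses(splits, leaves, excluded, grouping)[key]


# ---------------------------------------------------------------------------
# support table


@dataclass
class SupportTable:
    """Nodes x (full + exclusions) table of BS% with SC/NA markers.

    ``df`` holds cells (float, 'SC' or 'NA'); rows are node ids; ``clades``
    maps node id to the full-tree clade (frozenset of sample ids, oriented
    away from the root reference leaf).
    """

    df: pd.DataFrame
    clades: dict
    restricted: dict  # exclusion name -> set of restricted clades (all nodes)

    @property
    def node_ids(self) -> list:
        return list(self.df.index)

    @property
    def exclusion_names(self) -> list:
        return [c for c in self.df.columns if c != "full"]

    def jackknife_values(self, node_id) -> dict:
        """Numeric jackknife cells of one row (excludes 'full', SC, NA)."""
        row = self.df.loc[node_id]
        return {
            c: float(row[c])
            for c in self.exclusion_names
            if not isinstance(row[c], str)
        }

    def to_tsv(self, path):
        out = self.df.copy()
        out.insert(0, "clade", [
            ",".join(sorted(self.clades[i])) for i in out.index
        ])
        out.to_csv(path, sep="\t", index_label="node")


def compile_support_table(result: HETResult) -> SupportTable:
    """Assemble the nodes x exclusion-experiments support table."""
    full_series = result.full
    leaves = full_series.leaf_ids
    splits = full_series.ref_tree.splits()
    grouping = result.grouping
    ref = _root_reference(set(leaves), grouping)
    oriented = _orient(splits, ref, set(leaves))
    # deterministic node order: small clades first, then lexicographic
    order = sorted(oriented, key=lambda c: (len(c), tuple(sorted(c))))
    node_ids = [f"N{k + 1}" for k in range(len(order))]
    clades = dict(zip(node_ids, order))
    split_of = {nid: oriented[c] for nid, c in clades.items()}

    columns: dict = {}
    columns["full"] = [
        round(full_series.support(split_of[nid]), 1) for nid in node_ids
    ]
    restricted_by_excl: dict = {}
    for name, es in result.exclusion_sets.items():
        series = result.jackknife[name]
        statuses = restrict_statuses(splits, leaves, es.sample_ids, grouping)
        col = []
        restricted_all = set()
        for nid in node_ids:
            st = statuses[split_of[nid]]
            if isinstance(st, str):
                col.append(st)
            else:
                col.append(round(series.support(st), 1))
            # every nontrivial restriction is "explained" by a full-tree node
            c = clades[nid]
            r = c - set(es.sample_ids)
            if len(r) >= 2:
                restricted_all.add(series.canon(r))
        restricted_by_excl[name] = restricted_all
        columns[name] = col

    df = pd.DataFrame(columns, index=node_ids)
    return SupportTable(df=df, clades=clades, restricted=restricted_by_excl)


# ---------------------------------------------------------------------------
# Tukey boxplots and outliers


def tukey_hinges(values) -> tuple:
    """(lower hinge, median, upper hinge) by Tukey's fourths."""
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    if n < 2:
        v = float(x[0]) if n else np.nan
        return v, v, v
    med = float(np.median(x))
    d = (np.floor((n + 1) / 2) + 1) / 2.0  # hinge depth
    lo = 0.5 * (x[int(np.floor(d)) - 1] + x[int(np.ceil(d)) - 1])
    hi = 0.5 * (x[n - int(np.floor(d))] + x[n - int(np.ceil(d))])
    return float(lo), med, float(hi)


@dataclass
class OutlierRecord:
    node_id: str
    clade: frozenset
    direction: str  # "upper" | "lower"
    value: float
    exclusion: str
    fence: float
    k: float


@dataclass
class BoxplotSummary:
    node_id: str
    clade: frozenset
    q1: float
    median: float
    q3: float
    iqr: float
    k: float
    lower_fence: float
    upper_fence: float
    values: dict = field(default_factory=dict)  # exclusion -> BS
    upper_outliers: list = field(default_factory=list)
    lower_outliers: list = field(default_factory=list)


def _quartiles(x, method):
    if method == "tukey":
        return tukey_hinges(x)
    q1, med, q3 = np.percentile(np.asarray(x, float), [25, 50, 75])
    return float(q1), float(med), float(q3)


def boxplot_outliers(
    table: SupportTable,
    k: float = 1.5,
    node_filter: str = "all",
    grouping=None,
    quartile_method: str = "tukey",
) -> list:
    """Per-node Tukey boxplot summaries with annotated outliers.

    The sample for each node is its numeric jackknife cells (SC/NA and the
    full-tree column excluded). Nodes with fewer than 5 numeric cells are
    skipped with a warning. ``node_filter='min_two_groups'`` restricts
    reporting to nodes whose clade contains samples of at least two groups
    (requires ``grouping``).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if node_filter not in ("all", "min_two_groups"):
        raise ValueError(f"unknown node_filter {node_filter!r}")
    summaries = []
    for nid in table.node_ids:
        clade = table.clades[nid]
        if node_filter == "min_two_groups":
            if grouping is None:
                raise ValueError("node_filter='min_two_groups' needs grouping")
            n_groups = len({grouping.group_of(s) for s in clade})
            if n_groups < 2:
                continue
        vals = table.jackknife_values(nid)
        if len(vals) < MIN_CELLS:
            warnings.warn(
                f"node {nid} has only {len(vals)} numeric cells; skipped",
                stacklevel=2,
            )
            continue
        q1, med, q3 = _quartiles(list(vals.values()), quartile_method)
        iqr = q3 - q1
        lo_f = q1 - k * iqr
        hi_f = q3 + k * iqr
        s = BoxplotSummary(
            node_id=nid, clade=clade, q1=q1, median=med, q3=q3, iqr=iqr,
            k=k, lower_fence=lo_f, upper_fence=hi_f, values=dict(vals),
        )
        for name, v in vals.items():
            if v > hi_f:
                s.upper_outliers.append(
                    OutlierRecord(nid, clade, "upper", v, name, hi_f, k)
                )
            elif v < lo_f:
                s.lower_outliers.append(
                    OutlierRecord(nid, clade, "lower", v, name, lo_f, k)
                )
        summaries.append(s)
    return summaries


def outlier_table(summaries) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for rec in s.upper_outliers + s.lower_outliers:
            rows.append(
                {
                    "node": s.node_id,
                    "clade": ",".join(sorted(s.clade)),
                    "full_bs": np.nan,
                    "q1": s.q1,
                    "q3": s.q3,
                    "iqr": s.iqr,
                    "k": s.k,
                    "direction": rec.direction,
                    "outlier_value": rec.value,
                    "exclusion": rec.exclusion,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "node", "clade", "full_bs", "q1", "q3", "iqr", "k",
            "direction", "outlier_value", "exclusion",
        ],
    )


# ---------------------------------------------------------------------------
# custom node queries and alternative-topology registry


def query_custom_node(leafset, result: HETResult) -> dict:
    """BS% of an arbitrary bipartition in every series.

    Series whose exclusion intersects the leaf set report NA.
    """
    leafset = frozenset(leafset)
    if len(leafset) < 2:
        raise ValueError("leafset needs at least 2 leaves")
    unknown = leafset - set(result.full.leaf_ids)
    if unknown:
        raise ValueError(f"unknown samples: {sorted(unknown)}")
    out = {"full": round(result.full.support(leafset), 1)}
    for name, es in result.exclusion_sets.items():
        if leafset & set(es.sample_ids):
            out[name] = NA
        else:
            out[name] = round(result.jackknife[name].support(leafset), 1)
    return out


@dataclass
class AltNodeRegistry:
    """Bipartitions absent from the full tree but supported in a series."""

    entries: dict  # frozenset -> {series name -> BS%}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "clade": ",".join(sorted(split)),
                "series": series,
                "bs": bs,
            }
            for split, per in sorted(
                self.entries.items(), key=lambda kv: (len(kv[0]), tuple(sorted(kv[0])))
            )
            for series, bs in per.items()
        ]
        return pd.DataFrame(rows, columns=["clade", "series", "bs"])


def alt_nodes(result: HETResult, min_support: float = 50.0,
              table: SupportTable | None = None) -> AltNodeRegistry:
    """Bipartitions with BS >= min_support in some series that are not
    restrictions of full-tree nodes for that series."""
    if table is None:
        table = compile_support_table(result)
    full_splits = result.full.ref_tree.splits()
    entries: dict = {}
    # full series: anything beyond the reference tree's own splits
    for split, cnt in result.full.counts.items():
        bs = 100.0 * cnt / result.B
        if bs >= min_support and split not in full_splits:
            entries.setdefault(split, {})["full"] = round(bs, 1)
    for name in result.jackknife:
        series = result.jackknife[name]
        known = table.restricted[name]
        for split, cnt in series.counts.items():
            bs = 100.0 * cnt / series.B
            if bs >= min_support and split not in known:
                entries.setdefault(split, {})[name] = round(bs, 1)
    return AltNodeRegistry(entries=entries)
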