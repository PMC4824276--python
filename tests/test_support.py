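"""Support carryover accounting, Tukey boxplot outliers, node queries."""

import warnings

import numpy as np
import pandas as pd
import pytest

from hetscan.distances import DistanceMatrix
from hetscan.matrices import TaxonGrouping
from hetscan.nj import canonical_split, nj_tree
from hetscan.support import (
    NA,
    SC,
    SupportTable,
    alt_nodes,
    boxplot_outliers,
    compile_support_table,
    query_custom_node,
    restrict_node,
    tukey_hinges,
)


def brute_force_outliers(values, k, method="tukey"):
    """Independent oracle: sort, hinge by Tukey's fourths, fence, scan."""
    x = sorted(values)
    n = len(x)
    med = (x[(n - 1) // 2] + x[n // 2]) / 2
    d = (((n + 1) // 2) + 1) / 2  # hinge depth for integer halves
    import math

    lo = (x[math.floor(d) - 1] + x[math.ceil(d) - 1]) / 2
    hi = (x[n - math.floor(d)] + x[n - math.ceil(d)]) / 2
    iqr = hi - lo
    upper = [v for v in values if v > hi + k * iqr]
    lower = [v for v in values if v < lo - k * iqr]
    return lo, med, hi, sorted(upper), sorted(lower)


@pytest.fixture
def five_leaf_tree():
    """NJ tree (((A,B),C),(D,E)) from additive distances, displayed rooted
    on the E side (E plays the outgroup)."""
    #  A,B close; C near them; D,E on the far side
    labels = list("ABCDE")
    D = np.array(
        [
            [0.0, 0.2, 0.5, 1.1, 1.2],
            [0.2, 0.0, 0.5, 1.1, 1.2],
            [0.5, 0.5, 0.0, 1.0, 1.1],
            [1.1, 1.1, 1.0, 0.0, 0.3],
            [1.2, 1.2, 1.1, 0.3, 0.0],
        ]
    )
    tree = nj_tree(DistanceMatrix(labels, D))
    grouping = TaxonGrouping(
        {"A": "A", "B": "B", "C": "C", "D": "D", "E": "out"},
        outgroup="out",
    )
    return tree, grouping


class TestRestrictNode:
    def test_sister_of_excluded_leaf_is_sc(self, five_leaf_tree):
        tree, g = five_leaf_tree
        assert restrict_node({"A", "B"}, {"C"}, tree, g) == SC

    def test_attachment_node_is_na(self, five_leaf_tree):
        # {A,B,C} collapses onto {A,B} after excluding C
        tree, g = five_leaf_tree
        assert restrict_node({"A", "B", "C"}, {"C"}, tree, g) == NA

    def test_restriction_below_two_leaves_is_na(self, five_leaf_tree):
        tree, g = five_leaf_tree
        assert restrict_node({"A", "B"}, {"A"}, tree, g) == NA

    def test_untouched_node_is_scored(self, five_leaf_tree):
        tree, g = five_leaf_tree
        got = restrict_node({"A", "B"}, {"D"}, tree, g)
        assert got == frozenset({"A", "B"})

    def test_excluding_clade_set(self, five_leaf_tree):
        # excluded set {A, B} is a clade; sister C is a leaf -> no SC cell,
        # {A,B} itself is NA, {A,B,C} restricts to single leaf -> NA
        tree, g = five_leaf_tree
        assert restrict_node({"A", "B"}, {"A", "B"}, tree, g) == NA
        assert restrict_node({"A", "B", "C"}, {"A", "B"}, tree, g) == NA

    def test_non_clade_exclusion_has_no_sc(self, five_leaf_tree):
        # {A, C} is not a clade: no sister defined, {A,B} restricts to one
        # leaf (NA); {A,B,C} restricts to {B} (NA)
        tree, g = five_leaf_tree
        assert restrict_node({"A", "B"}, {"A", "C"}, tree, g) == NA
        assert restrict_node({"A", "B", "C"}, {"A", "C"}, tree, g) == NA

    def test_unknown_node_rejected(self, five_leaf_tree):
        tree, g = five_leaf_tree
        with pytest.raises(ValueError, match="not an internal node"):
            restrict_node({"A", "D"}, {"C"}, tree, g)


class TestTukeyHinges:
    def test_hand_example(self):
        """Row 80..87 plus 99: hinges 82/86, IQR 4; 99 is an upper outlier
        at k=1.5 (fence 92) and at k=3 (fence 98)."""
        row = [80, 81, 82, 83, 84, 85, 86, 87, 99]
        lo, med, hi = tukey_hinges(row)
        assert (lo, med, hi) == (82, 84, 86)
        for k, fence in ((1.5, 92.0), (3.0, 98.0)):
            table = _table_from_rows({"n1": row})
            (summ,) = boxplot_outliers(table, k=k)
            assert summ.upper_fence == fence
            assert [r.value for r in summ.upper_outliers] == [99]

    def test_even_count_hinges(self):
        assert tukey_hinges([1, 2, 3, 4]) == (1.5, 2.5, 3.5)

    def test_matches_brute_force_on_random_rows(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            n = int(rng.integers(5, 30))
            row = list(np.round(rng.uniform(0, 100, size=n), 1))
            lo, med, hi = tukey_hinges(row)
            blo, bmed, bhi, bup, blow = brute_force_outliers(row, 1.5)
            assert (lo, med, hi) == pytest.approx((blo, bmed, bhi))


def _table_from_rows(rows, clades=None, full=None):
    """Build a SupportTable directly from {node: [jackknife values]}."""
    ncol = max(len(v) for v in rows.values())
    cols = [f"x{i}" for i in range(ncol)]
    data = {}
    data["full"] = [full[n] if full else 50.0 for n in rows]
    for i, c in enumerate(cols):
        data[c] = [rows[n][i] if i < len(rows[n]) else NA for n in rows]
    df = pd.DataFrame(data, index=list(rows))
    clades = clades or {
        n: frozenset({f"{n}a_{n}", f"{n}b_{n}"}) for n in rows
    }
    return SupportTable(df=df, clades=clades, restricted={})


class TestBoxplotOutliers:
    def test_identical_values_no_outliers(self):
        table = _table_from_rows({"n1": [70.0] * 8})
        (s,) = boxplot_outliers(table, k=1.5)
        assert s.iqr == 0 and not s.upper_outliers and not s.lower_outliers

    def test_few_cells_skipped_with_warning(self):
        table = _table_from_rows({"n1": [10.0, 20.0, 30.0, 40.0]})
        with pytest.warns(UserWarning, match="only 4 numeric"):
            assert boxplot_outliers(table, k=1.5) == []

    def test_nonpositive_k_rejected(self):
        table = _table_from_rows({"n1": [1.0] * 6})
        with pytest.raises(ValueError, match="k must be positive"):
            boxplot_outliers(table, k=0)

    def test_k3_subset_of_k15(self):
        """The stricter criterion only removes outliers, never adds."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            n = int(rng.integers(6, 25))
            row = list(np.round(rng.uniform(0, 100, size=n), 1))
            t = _table_from_rows({"n1": row})
            (s15,) = boxplot_outliers(t, k=1.5)
            (s3,) = boxplot_outliers(t, k=3)
            up15 = {(r.exclusion, r.value) for r in s15.upper_outliers}
            up3 = {(r.exclusion, r.value) for r in s3.upper_outliers}
            lo15 = {(r.exclusion, r.value) for r in s15.lower_outliers}
            lo3 = {(r.exclusion, r.value) for r in s3.lower_outliers}
            assert up3 <= up15 and lo3 <= lo15

    def test_min_two_groups_filter(self):
        from hetscan.matrices import TaxonGrouping

        rows = {"n1": [50.0, 60, 55, 58, 52, 90], "n2": [50.0, 60, 55, 58, 52, 90]}
        clades = {
            "n1": frozenset({"a_g1", "b_g1"}),            # one group
            "n2": frozenset({"a_g1", "c_g2"}),            # two groups
        }
        grouping = TaxonGrouping(
            {"a_g1": "g1", "b_g1": "g1", "c_g2": "g2", "d_g3": "g3"}
        )
        t = _table_from_rows(rows, clades=clades)
        out = boxplot_outliers(t, k=1.5, node_filter="min_two_groups",
                               grouping=grouping)
        assert [s.node_id for s in out] == ["n2"]


class TestOnRealRuns:
    def test_sc_cells_absent_from_boxplot_samples(self, nohybrid_run):
        """Every SC cell is excluded from its node's outlier sample."""
        res, grouping, mx = nohybrid_run
        table = compile_support_table(res)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            summaries = boxplot_outliers(table, k=1.5)
        by_node = {s.node_id: s for s in summaries}
        n_sc = 0
        for nid in table.node_ids:
            for col in table.exclusion_names:
                if table.df.loc[nid, col] == SC:
                    n_sc += 1
                    if nid in by_node:
                        assert col not in by_node[nid].values
        assert n_sc > 0

    def test_one_sc_per_monophyletic_group_column(self, nohybrid_run):
        """When the excluded group is a clade with an internal-node sister,
        its column has exactly one SC cell; never more than one."""
        res, grouping, mx = nohybrid_run
        table = compile_support_table(res)
        full_clades = set(table.clades.values())
        group_samples = {
            g: frozenset(s for s in mx.sample_ids
                         if s.rsplit("_", 1)[1] == g)
            for g in grouping.ingroup_groups()
        }
        for col in table.exclusion_names:
            sc_cells = [nid for nid in table.node_ids
                        if table.df.loc[nid, col] == SC]
            assert len(sc_cells) <= 1
            if group_samples[col] in full_clades:
                # sister may be a leaf; SC only when sister is internal
                assert len(sc_cells) <= 1

    def test_full_column_numeric(self, hybrid_run):
        res, *_ = hybrid_run
        table = compile_support_table(res)
        assert not any(isinstance(v, str) for v in table.df["full"])

    def test_query_matches_table_rows(self, hybrid_run):
        """Querying a full-tree node reproduces its table row wherever the
        row is numeric."""
        res, *_ = hybrid_run
        table = compile_support_table(res)
        nid = table.node_ids[0]
        q = query_custom_node(table.clades[nid], res)
        for col in table.df.columns:
            cell = table.df.loc[nid, col]
            if not isinstance(cell, str):
                assert q[col] == cell

    def test_query_na_when_intersecting_exclusion(self, hybrid_run):
        res, truth, grouping, mx = hybrid_run
        hyb = [s for s in mx.sample_ids if s.endswith("_hyb")]
        q = query_custom_node(set(hyb) | {mx.sample_ids[0]}, res)
        assert q[truth.hybrid_group] == NA

    def test_query_rejects_single_leaf(self, hybrid_run):
        res, *_ = hybrid_run
        with pytest.raises(ValueError, match="at least 2"):
            query_custom_node({res.full.leaf_ids[0]}, res)

    def test_parent_exclusion_frees_hybrid_monophyly(self, hybrid_run):
        """Excluding a parent taxon raises support for hybrid monophyly
        (the tug-of-war releases)."""
        res, truth, grouping, mx = hybrid_run
        hyb = {s for s in mx.sample_ids if s.endswith("_hyb")}
        q = query_custom_node(hyb, res)
        parents = [t[0] for t in truth.parent_taxa]
        assert max(q[p] for p in parents) > q["full"]

    def test_alt_nodes_registry(self, hybrid_run):
        res, *_ = hybrid_run
        table = compile_support_table(res)
        reg = alt_nodes(res, min_support=40, table=table)
        # no registry entry duplicates a restriction of a full-tree node
        for split, per in reg.entries.items():
            for series_name in per:
                if series_name == "full":
                    assert split not in res.full.ref_tree.splits()
                else:
                    assert split not in table.restricted[series_name]
        assert alt_nodes(res, min_support=101, table=table).entries == {}


def test_alt_nodes_empty_on_degenerate_series():
    """Duplicated-locus data: every bootstrap tree equals the reference
    tree in every series, so the registry is empty."""
    from hetscan.jackknife import run_het
    from hetscan.matrices import LocusMatrix, TaxonGrouping

    col = np.array([1, 1, 1, 0, 0, 1, 0, 0], dtype=np.int8)
    ids = [f"s{i}_g{i // 2}" for i in range(8)]
    m = LocusMatrix(ids, np.repeat(col[:, None], 6, axis=1))
    grouping = TaxonGrouping({s: s.rsplit("_", 1)[1] for s in ids})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = run_het(m, grouping, B=10, seed=2)
    reg = alt_nodes(res, min_support=50)
    assert reg.entries == {}
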