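"""File dialects and result output.

Marker tables are whitespace- or tab-separated, one sample per row, the
sample id in the first column, with an optional header row of locus names
and ``#`` comment lines. Genotype tokens are two-character strings
("AG" == "GA"), binary tokens 0/1, code tokens 0/1/2 (= AA/AB/BB). Missing
tokens default to {"?", "NA", "-", "??"}.

Groupings are either a two-column file (sample, group) or derived from the
final "_"-delimited token of each sample name.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .matrices import (
    GenotypeMatrix,
    LocusMatrix,
    TaxonGrouping,
    ValidationError,
    genotype_matrix_from_pairs,
)

__all__ = [
    "read_marker_table",
    "write_marker_table",
    "read_grouping",
    "write_outputs",
    "read_support_table",
    "DEFAULT_MISSING",
]

DEFAULT_MISSING = ("?", "NA", "-", "??")

DIALECTS = ("binary", "snp_nucleotide", "genotype_code")


class ParseError(ValueError):
    pass


def _rows(path):
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            yield ln, line.split()


def _is_data_token(tok, dialect, missing):
    if tok in missing:
        return True
    if dialect == "binary":
        return tok in ("0", "1")
    if dialect == "genotype_code":
        return tok in ("0", "1", "2")
    return len(tok) == 2 and all(c in "ACGT" for c in tok.upper())


def read_marker_table(path, dialect, missing_tokens=DEFAULT_MISSING):
    """Parse a marker table into a :class:`LocusMatrix` (binary dialect) or
    :class:`GenotypeMatrix` (snp_nucleotide / genotype_code dialects).

    The header row (locus names) is detected automatically: a first row
    whose non-id tokens are not all legal data tokens is taken as a header.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    missing = set(missing_tokens)
    rows = list(_rows(path))
    if not rows:
        raise ParseError(f"{path}: no data rows")
    locus_names = None
    first_ln, first = rows[0]
    if len(first) > 1 and not all(
        _is_data_token(t, dialect, missing) for t in first[1:]
    ):
        locus_names = first[1:]
        rows = rows[1:]
    if not rows:
        raise ParseError(f"{path}: header but no data rows")

    ids = []
    L = len(rows[0][1]) - 1
    if locus_names is not None and len(locus_names) != L:
        raise ParseError(
            f"{path}: header names {len(locus_names)} loci but rows have {L}"
        )
    table = []
    for ln, toks in rows:
        sid, data = toks[0], toks[1:]
        if len(data) != L:
            raise ParseError(
                f"{path}:{ln}: sample {sid!r} has {len(data)} loci, "
                f"expected {L}"
            )
        ids.append(sid)
        table.append(data)

    if dialect == "binary":
        values = np.empty((len(ids), L), dtype=np.int8)
        for i, data in enumerate(table):
            for l, tok in enumerate(data):
                if tok in missing:
                    values[i, l] = -1
                elif tok in ("0", "1"):
                    values[i, l] = int(tok)
                else:
                    raise ParseError(
                        f"{path}: illegal binary token {tok!r} for sample "
                        f"{ids[i]!r}, locus {l + 1}"
                    )
        return LocusMatrix(ids, values, locus_names)

    code_pairs = {"0": ("A", "A"), "1": ("A", "B"), "2": ("B", "B")}
    pairs = []
    for i, data in enumerate(table):
        row = []
        for l, tok in enumerate(data):
            if tok in missing:
                row.append(None)
            elif dialect == "genotype_code":
                if tok not in code_pairs:
                    raise ParseError(
                        f"{path}: illegal genotype code {tok!r} for sample "
                        f"{ids[i]!r}, locus {l + 1}"
                    )
                row.append(code_pairs[tok])
            else:
                t = tok.upper()
                if len(t) != 2 or any(c not in "ACGT" for c in t):
                    raise ParseError(
                        f"{path}: illegal genotype token {tok!r} for sample "
                        f"{ids[i]!r}, locus {l + 1}"
                    )
                row.append(tuple(sorted(t)))  # AG == GA
        pairs.append(row)
    if dialect == "genotype_code":
        return genotype_matrix_from_pairs(
            ids, pairs, alphabet=("A", "B"), dialect=dialect,
            locus_names=locus_names,
        )
    return genotype_matrix_from_pairs(ids, pairs, locus_names=locus_names)


def write_marker_table(matrix, path):
    """Write a matrix in the dialect it was read/built with ('?' for
    missing); re-reading reproduces values and missing mask exactly."""
    with open(path, "w") as fh:
        if matrix.locus_names:
            fh.write("sample " + " ".join(matrix.locus_names) + "\n")
        if isinstance(matrix, LocusMatrix):
            for i, sid in enumerate(matrix.sample_ids):
                toks = ["?" if v < 0 else str(int(v))
                        for v in matrix.values[i]]
                fh.write(sid + " " + " ".join(toks) + "\n")
        else:
            for i, sid in enumerate(matrix.sample_ids):
                toks = [matrix.genotype_str(i, l)
                        for l in range(matrix.n_loci)]
                fh.write(sid + " " + " ".join(toks) + "\n")


def read_grouping(source, samples, outgroup=None,
                  exclusion_file=None) -> TaxonGrouping:
    """Grouping from a two-column file, or from the suffix convention when
    ``source`` is None (final "_"-delimited token of the sample name)."""
    samples = list(samples)
    if source is None:
        assignments = {}
        for s in samples:
            if "_" not in s:
                raise ValidationError(
                    f"sample {s!r} has no '_' group suffix and no grouping "
                    "file was given"
                )
            assignments[s] = s.rsplit("_", 1)[1]
    else:
        assignments = {}
        for ln, toks in _rows(source):
            if len(toks) != 2:
                raise ParseError(
                    f"{source}:{ln}: expected 'sample group', got {toks}"
                )
            assignments[toks[0]] = toks[1]
        missing = [s for s in samples if s not in assignments]
        if missing:
            raise ValidationError(
                f"grouping file omits samples: {missing}"
            )
        assignments = {s: assignments[s] for s in samples}
    exclusion_sets = {}
    if exclusion_file:
        for ln, toks in _rows(exclusion_file):
            joined = " ".join(toks)
            if "\t" in joined:
                name, members = joined.split("\t", 1)
            else:
                name, members = toks[0], " ".join(toks[1:])
            exclusion_sets[name.strip()] = [
                m for m in members.replace(",", " ").split() if m
            ]
    return TaxonGrouping(assignments, outgroup=outgroup,
                         exclusion_sets=exclusion_sets)


# ---------------------------------------------------------------------------
# result output


def write_outputs(result, outdir, k=1.5, node_filter="all", plots=True,
                  min_alt_support=50.0):
    """Write the complete output file set of a HET run.

    newick trees (full + one per exclusion, support as node labels), the
    support table with SC/NA markers, the outlier table, the
    alternative-node registry, the all-bipartitions table, and (optionally)
    per-node boxplot graphics as a PDF.
    """
    from .support import (
        alt_nodes,
        boxplot_outliers,
        compile_support_table,
        outlier_table,
    )

    os.makedirs(outdir, exist_ok=True)
    trees_dir = os.path.join(outdir, "trees")
    os.makedirs(trees_dir, exist_ok=True)

    def write_tree(series, name):
        sup = {s: round(v, 1) for s, v in series.reference_supports().items()}
        with open(os.path.join(trees_dir, name), "w") as fh:
            fh.write(series.ref_tree.newick(support=sup) + "\n")

    write_tree(result.full, "full.nwk")
    for name, series in result.jackknife.items():
        write_tree(series, f"excl_{name}.nwk")

    table = compile_support_table(result)
    table.to_tsv(os.path.join(outdir, "support_table.tsv"))

    summaries = boxplot_outliers(
        table, k=k, node_filter=node_filter, grouping=result.grouping
    )
    ot = outlier_table(summaries)
    full_bs = {nid: result_full_bs for nid, result_full_bs in
               zip(table.df.index, table.df["full"])}
    if len(ot):
        ot["full_bs"] = [full_bs[n] for n in ot["node"]]
    ot.to_csv(os.path.join(outdir, "outliers.tsv"), sep="\t", index=False)

    registry = alt_nodes(result, min_support=min_alt_support, table=table)
    registry.to_frame().to_csv(
        os.path.join(outdir, "alt_nodes.tsv"), sep="\t", index=False
    )

    rows = []
    for name in result.series_names:
        series = result.series(name)
        for split, cnt in sorted(
            series.counts.items(), key=lambda kv: (-kv[1], tuple(sorted(kv[0])))
        ):
            rows.append({
                "series": name,
                "clade": ",".join(sorted(split)),
                "count": cnt,
                "bs": round(100.0 * cnt / series.B, 1),
            })
    pd.DataFrame(rows, columns=["series", "clade", "count", "bs"]).to_csv(
        os.path.join(outdir, "all_bipartitions.tsv"), sep="\t", index=False
    )

    with open(os.path.join(outdir, "groups.tsv"), "w") as fh:
        for s, g in result.grouping.assignments.items():
            fh.write(f"{s}\t{g}\n")
    with open(os.path.join(outdir, "exclusions.tsv"), "w") as fh:
        for name, es in result.exclusion_sets.items():
            fh.write(f"{name}\t{','.join(es.sample_ids)}\t{es.kind}\n")

    meta = {
        "B": result.B,
        "seed": result.seed,
        "distance": result.distance_name,
        "k": k,
        "node_filter": node_filter,
        "n_exclusions": len(result.exclusion_sets),
    }
    with open(os.path.join(outdir, "run_meta.tsv"), "w") as fh:
        for key, val in meta.items():
            fh.write(f"{key}\t{val}\n")

    if plots:
        from .plotting import plot_node_boxplots

        plot_node_boxplots(
            table, summaries, os.path.join(outdir, "boxplots.pdf")
        )
    return table, summaries


def read_support_table(path):
    """Re-read a written support table (cells float or 'SC'/'NA')."""
    from .support import SupportTable

    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    clades = {
        nid: frozenset(df.loc[nid, "clade"].split(","))
        for nid in df.index
    }
    df = df.drop(columns=["clade"])

    def cell(v):
        return v if v in ("SC", "NA") else float(v)

    df = df.map(cell)
    return SupportTable(df=df, clades=clades, restricted={})
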