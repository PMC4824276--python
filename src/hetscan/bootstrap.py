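"""Bootstrap-across-loci tree series and bipartition counting.

Node support is the relative frequency of a bipartition among B trees, each
built from a matrix whose loci were resampled with replacement. A resample
can leave some sample pair with no jointly observed locus (only possible
with missing data); such a replicate is discarded and redrawn, keeping B
constant, with at most ``MAX_REDRAWS`` consecutive redraws.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .distances import PairwiseDeletionError, bootstrap_columns, encoding_for
from .nj import Tree, canonical_split, nj_split_indices, nj_tree

__all__ = ["BootstrapSeries", "bootstrap_series", "support_on_reference"]

MAX_REDRAWS = 100


@dataclass
class BootstrapSeries:
    """Reference tree plus bipartition counts over B bootstrap trees."""

    leaf_ids: list
    ref_tree: Tree
    counts: dict
    B: int
    seed: int
    n_redraws: int = 0
    meta: dict = field(default_factory=dict)

    def canon(self, leafset) -> frozenset:
        return canonical_split(leafset, self.leaf_ids)

    def support(self, split) -> float:
        """Bootstrap percentage of a bipartition (0 if never seen)."""
        return 100.0 * self.counts.get(self.canon(split), 0) / self.B

    def reference_supports(self) -> dict:
        """Canonical split of the reference tree -> BS%."""
        return {s: self.support(s) for s in self.ref_tree.splits()}


def bootstrap_series(matrix, B: int, seed: int, distance=None) -> BootstrapSeries:
    """Full-matrix reference tree plus B bootstrap NJ trees.

    ``distance`` may be a prepared encoding (internal fast path) or None to
    dispatch on the matrix type.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if B < 100:
        warnings.warn(
            f"B={B} bootstrap replicates; support values will be coarse",
            stacklevel=2,
        )
    enc = distance if distance is not None else encoding_for(matrix)
    ref = nj_tree(enc.distances())
    counts: Counter = Counter()
    rng = np.random.default_rng(seed)
    L = enc.n_loci
    labels = list(enc.ids)
    done = 0
    redraws = 0
    n_redraws_total = 0
    while done < B:
        cols = bootstrap_columns(L, rng)
        try:
            d = enc.distances(cols)
        except PairwiseDeletionError:
            redraws += 1
            n_redraws_total += 1
            if redraws > MAX_REDRAWS:
                raise RuntimeError(
                    f"{MAX_REDRAWS} consecutive bootstrap resamples left a "
                    "sample pair with no jointly observed locus"
                )
            continue
        redraws = 0
        counts.update(nj_split_indices(d.values, len(labels)))
        done += 1
    # convert index splits to canonical label splits once per series
    label_counts: Counter = Counter()
    for idx_split, c in counts.items():
        side = {labels[i] for i in idx_split}
        label_counts[canonical_split(side, labels)] += c
    return BootstrapSeries(
        leaf_ids=labels,
        ref_tree=ref,
        counts=dict(label_counts),
        B=B,
        seed=seed,
        n_redraws=n_redraws_total,
    )


def support_on_reference(series: BootstrapSeries) -> dict:
    """BS% for each internal edge of the reference tree."""
    return series.reference_supports()
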