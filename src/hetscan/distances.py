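"""Pairwise genetic distances with pairwise deletion of missing loci.

Two distances are provided, matching the two marker families:

* the Nei-Li (1979) restriction-fragment distance for binary data,
  D = 1 - 2*n_xy / (n_x + n_y), where n_xy counts loci where both samples
  show the band and n_x, n_y the per-sample band counts over jointly
  observed loci (shared absence never counts);
* the allele-sharing distance for diploid genotypes,
  D = 1 - (1 / (2 * L_obs)) * sum_l s_l, where s_l in {0, 1, 2} is the
  multiset intersection of the two unordered genotypes at locus l.

Missing loci are deleted pairwise: every pair of samples uses exactly the
loci where both are observed. A pair with no jointly observed locus raises
:class:`PairwiseDeletionError`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrices import GenotypeMatrix, LocusMatrix

__all__ = [
    "DistanceMatrix",
    "PairwiseDeletionError",
    "nei_li_distance",
    "allele_sharing_distance",
    "resample_loci",
    "distance_for",
]


class PairwiseDeletionError(ValueError):
    """A sample pair has no jointly observed locus."""

    def __init__(self, pair):
        self.pair = pair
        super().__init__(
            f"samples {pair[0]!r} and {pair[1]!r} share no observed locus"
        )


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances plus pairwise-deletion locus counts."""

    ids: list
    values: np.ndarray
    n_loci_used: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix is not symmetric")

    def to_tsv(self, path):
        import pandas as pd

        pd.DataFrame(self.values, index=self.ids, columns=self.ids).to_csv(
            path, sep="\t", float_format="%.6f"
        )

    def take(self, keep) -> "DistanceMatrix":
        idx = [self.ids.index(s) for s in keep]
        nl = (
            self.n_loci_used[np.ix_(idx, idx)]
            if self.n_loci_used is not None
            else None
        )
        return DistanceMatrix(list(keep), self.values[np.ix_(idx, idx)], nl)


def _check_joint(ids, n_obs):
    off = n_obs.copy()
    np.fill_diagonal(off, 1)
    if (off < 1).any():
        i, j = np.argwhere(off < 1)[0]
        raise PairwiseDeletionError((ids[i], ids[j]))


class BinaryEncoding:
    """Indicator planes for fast bootstrap distance evaluation.

    Matrix products over 0/1 indicator columns give, for every pair at
    once, the shared-band counts and the per-sample band counts restricted
    to the partner's observed loci.
    """

    def __init__(self, m: LocusMatrix):
        self.ids = list(m.sample_ids)
        self.present = (m.values == 1).astype(np.float32)
        self.observed = (m.values >= 0).astype(np.float32)
        self.log_transform = False

    @property
    def n_loci(self) -> int:
        return self.present.shape[1]

    def distances(self, cols=None) -> DistanceMatrix:
        P = self.present if cols is None else self.present[:, cols]
        O = self.observed if cols is None else self.observed[:, cols]
        n_obs = np.rint(O @ O.T).astype(np.int64)
        _check_joint(self.ids, n_obs)
        n_xy = P @ P.T
        n_x = P @ O.T  # n_x[i, j]: bands of i over loci observed in both
        tot = n_x + n_x.T
        with np.errstate(divide="ignore", invalid="ignore"):
            s = np.where(tot > 0, 2.0 * n_xy / np.maximum(tot, 1), 1.0)
        if self.log_transform:
            with np.errstate(divide="ignore"):
                d = np.where(s > 0, -np.log(np.minimum(s, 1.0)), np.inf)
        else:
            d = 1.0 - s
        d = np.asarray(d, dtype=float)
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        np.clip(d, 0.0, None, out=d)
        return DistanceMatrix(self.ids, d, n_obs)


class GenotypeEncoding:
    """>=1 / >=2 allele-count indicator planes for allele sharing.

    With per-allele counts c in {0, 1, 2}, min(c_i, c_j) decomposes as
    [c_i>=1][c_j>=1] + [c_i>=2][c_j>=2], so the total number of shared
    alleles over all loci is two matrix products.
    """

    def __init__(self, g: GenotypeMatrix):
        self.ids = list(g.sample_ids)
        n, L, A = g.counts.shape
        self._L = L
        self._A = A
        self.ge1 = (g.counts >= 1).astype(np.float32)
        self.ge2 = (g.counts >= 2).astype(np.float32)
        self.observed = (~g.missing).astype(np.float32)

    @property
    def n_loci(self) -> int:
        return self._L

    def distances(self, cols=None) -> DistanceMatrix:
        if cols is None:
            g1, g2, O = self.ge1, self.ge2, self.observed
        else:
            g1, g2 = self.ge1[:, cols], self.ge2[:, cols]
            O = self.observed[:, cols]
        n = len(self.ids)
        L = O.shape[1]
        n_obs = np.rint(O @ O.T).astype(np.int64)
        _check_joint(self.ids, n_obs)
        f1 = g1.reshape(n, L * self._A)
        f2 = g2.reshape(n, L * self._A)
        shared = f1 @ f1.T + f2 @ f2.T
        d = 1.0 - shared / (2.0 * np.maximum(n_obs, 1))
        d = (d + d.T) / 2.0
        np.fill_diagonal(d, 0.0)
        np.clip(d, 0.0, 1.0, out=d)
        return DistanceMatrix(self.ids, d, n_obs)


def nei_li_distance(m: LocusMatrix, log_transform: bool = False) -> DistanceMatrix:
    """Nei-Li distance for a binary matrix.

    With ``log_transform`` the -ln(S) variant is returned instead of 1 - S.
    A pair of identical all-absent profiles has D = 0.
    """
    enc = BinaryEncoding(m)
    enc.log_transform = log_transform
    return enc.distances()


def allele_sharing_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Allele-sharing distance for a genotype matrix."""
    return GenotypeEncoding(g).distances()


def encoding_for(matrix):
    if isinstance(matrix, LocusMatrix):
        return BinaryEncoding(matrix)
    if isinstance(matrix, GenotypeMatrix):
        return GenotypeEncoding(matrix)
    raise TypeError(f"no distance defined for {type(matrix).__name__}")


def distance_for(matrix) -> DistanceMatrix:
    """Dispatch: Nei-Li for binary data, allele sharing for genotypes."""
    return encoding_for(matrix).distances()


def resample_loci(matrix, seed: int):
    """Draw L loci with replacement (uniform over columns), keeping samples.

    Deterministic for a fixed seed; the same draw is used by the bootstrap
    engine, so a replicate can be reproduced through this public function.
    """
    L = matrix.n_loci
    if L < 1:
        raise ValueError("matrix has no loci")
    cols = bootstrap_columns(L, np.random.default_rng(seed))
    return matrix.take_loci(cols)


def bootstrap_columns(L: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, L, size=L)
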