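"""Taxon-jackknife dataset generation and analysis orchestration.

A run consists of the full-data bootstrap series plus one series per
exclusion set. Default exclusion sets remove one ingroup group at a time
(the outgroup is never excluded); the user may add custom sets and random
cross-group individual pairs. Per-set seeds are derived by hashing the
master seed with the set name, so results are identical whether series run
serially or in parallel.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .bootstrap import BootstrapSeries, bootstrap_series
from .distances import encoding_for
from .matrices import TaxonGrouping, ValidationError

__all__ = ["ExclusionSet", "HETResult", "make_exclusion_sets", "run_het"]

MIN_GROUPS_WARN = 7


@dataclass(frozen=True)
class ExclusionSet:
    name: str
    sample_ids: tuple
    kind: str  # "group" | "custom" | "random_pair"

    def __post_init__(self):
        if not self.sample_ids:
            raise ValidationError(f"exclusion set {self.name!r} is empty")
        if self.kind not in ("group", "custom", "random_pair"):
            raise ValidationError(f"unknown exclusion kind {self.kind!r}")


@dataclass
class HETResult:
    """Full + per-exclusion bootstrap series with run metadata."""

    full: BootstrapSeries
    jackknife: dict  # set name -> BootstrapSeries
    exclusion_sets: dict  # set name -> ExclusionSet
    grouping: TaxonGrouping
    B: int
    seed: int
    distance_name: str = "auto"
    meta: dict = field(default_factory=dict)

    @property
    def series_names(self) -> list:
        return ["full"] + list(self.jackknife)

    def series(self, name: str) -> BootstrapSeries:
        return self.full if name == "full" else self.jackknife[name]


def derive_seed(master: int, name: str) -> int:
    """Schedule-independent per-series seed from the master seed."""
    h = hashlib.sha256(f"{master}:{name}".encode()).digest()
    return int.from_bytes(h[:8], "big") % (2**63)


def make_exclusion_sets(
    grouping: TaxonGrouping,
    random_pairs: int = 0,
    seed: int = 0,
    min_remaining: int = 3,
    n_samples_total: int | None = None,
) -> list:
    """One set per ingroup group, plus custom sets, plus random cross-group
    individual pairs (no pair emitted twice)."""
    groups = grouping.groups()
    ingroup = grouping.ingroup_samples()
    n_total = n_samples_total or len(grouping.samples)
    sets: list = []
    for g in grouping.ingroup_groups():
        members = tuple(groups[g])
        if n_total - len(members) < min_remaining:
            raise ValidationError(
                f"excluding group {g!r} leaves fewer than {min_remaining} samples"
            )
        sets.append(ExclusionSet(name=g, sample_ids=members, kind="group"))
    for name, members in grouping.exclusion_sets.items():
        sets.append(ExclusionSet(name=name, sample_ids=tuple(members),
                                 kind="custom"))
    if random_pairs:
        group_of = grouping.assignments
        cross = [
            (a, b)
            for i, a in enumerate(ingroup)
            for b in ingroup[i + 1:]
            if group_of[a] != group_of[b]
        ]
        if random_pairs > len(cross):
            raise ValidationError(
                f"requested {random_pairs} random pairs but only "
                f"{len(cross)} distinct cross-group pairs exist"
            )
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(cross))
        for k in range(random_pairs):
            a, b = cross[order[k]]
            sets.append(
                ExclusionSet(
                    name=f"pair{k + 1:02d}_{a}+{b}",
                    sample_ids=(a, b),
                    kind="random_pair",
                )
            )
    return sets


def _run_series(matrix, keep, B, seed, name):
    sub = matrix.take_samples(keep)
    enc = encoding_for(sub)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return bootstrap_series(sub, B=B, seed=seed, distance=enc)


def run_het(
    matrix,
    grouping: TaxonGrouping,
    B: int = 1000,
    seed: int = 0,
    random_pairs: int = 0,
    threads: int = 1,
    exclusion_sets: list | None = None,
) -> HETResult:
    """Full analysis: full-data series plus one series per exclusion set.

    Jackknife matrices are the full matrix restricted to the remaining
    samples; loci are never re-filtered after an exclusion, so the locus
    universe is identical across series.
    """
    samples = set(matrix.sample_ids)
    missing = [s for s in grouping.samples if s not in samples]
    if missing:
        raise ValidationError(f"grouping names unknown samples: {missing}")
    ungrouped = [s for s in matrix.sample_ids if s not in grouping.assignments]
    if ungrouped:
        raise ValidationError(f"samples without a group: {ungrouped}")
    if B < 100:
        warnings.warn(f"B={B} is below the recommended 100", stacklevel=2)
    n_ing = len(grouping.ingroup_groups())
    if n_ing < MIN_GROUPS_WARN:
        warnings.warn(
            f"only {n_ing} ingroup groups; outlier detection over so few "
            "jackknife values is unreliable",
            stacklevel=2,
        )

    if exclusion_sets is None:
        exclusion_sets = make_exclusion_sets(
            grouping, random_pairs=random_pairs, seed=derive_seed(seed, "@pairs")
        )
    all_ids = list(matrix.sample_ids)
    jobs = [("full", all_ids)]
    for es in exclusion_sets:
        keep = [s for s in all_ids if s not in set(es.sample_ids)]
        if len(keep) < 3:
            raise ValidationError(
                f"exclusion set {es.name!r} leaves fewer than 3 samples"
            )
        jobs.append((es.name, keep))

    seeds = {name: derive_seed(seed, name) for name, _ in jobs}
    if threads > 1:
        from joblib import Parallel, delayed

        results = Parallel(n_jobs=threads)(
            delayed(_run_series)(matrix, keep, B, seeds[name], name)
            for name, keep in jobs
        )
    else:
        results = [
            _run_series(matrix, keep, B, seeds[name], name)
            for name, keep in jobs
        ]
    by_name = dict(zip([name for name, _ in jobs], results))
    return HETResult(
        full=by_name.pop("full"),
        jackknife=by_name,
        exclusion_sets={es.name: es for es in exclusion_sets},
        grouping=grouping,
        B=B,
        seed=seed,
        distance_name=type(matrix).__name__,
    )
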