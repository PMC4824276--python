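"""Marker-matrix containers and the taxon grouping.

Three input dialects are supported:

* binary presence/absence markers (AFLP/RFLP bands), entries 0/1;
* SNP genotypes as unordered two-letter nucleotide states ("AG GG TC AA"),
  with more than two alleles per locus permitted;
* bi-allelic genotype codes 0 (AA), 1 (AB), 2 (BB).

Missingness is per locus per sample (the whole genotype is missing, never a
single allele).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LocusMatrix",
    "GenotypeMatrix",
    "TaxonGrouping",
    "MIN_SAMPLES",
    "ValidationError",
]

MIN_SAMPLES = 4

NUCLEOTIDES = ("A", "C", "G", "T")


class ValidationError(ValueError):
    """Input data violates a structural requirement."""


def _check_ids(sample_ids) -> list:
    ids = list(sample_ids)
    if len(ids) != len(set(ids)):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate sample ids: {dupes}")
    if len(ids) < MIN_SAMPLES:
        raise ValidationError(
            f"need at least {MIN_SAMPLES} samples, got {len(ids)}"
        )
    return ids


@dataclass
class LocusMatrix:
    """Samples x loci binary marker matrix.

    ``values`` is int8 with entries 0, 1, or -1 for missing.
    """

    sample_ids: list
    values: np.ndarray
    locus_names: list | None = None

    def __post_init__(self):
        self.sample_ids = _check_ids(self.sample_ids)
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.sample_ids):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples"
            )
        bad = ~np.isin(self.values, (-1, 0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"illegal binary entry {self.values[i, j]} for sample "
                f"{self.sample_ids[i]!r}, locus {j}"
            )

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    @property
    def missing(self) -> np.ndarray:
        return self.values < 0

    def take_samples(self, keep) -> "LocusMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return LocusMatrix(list(keep), self.values[idx], self.locus_names)

    def take_loci(self, idx) -> "LocusMatrix":
        names = (
            [self.locus_names[i] for i in idx] if self.locus_names else None
        )
        return LocusMatrix(self.sample_ids, self.values[:, idx], names)


@dataclass
class GenotypeMatrix:
    """Samples x loci unordered diploid genotypes as allele-count tensors.

    ``counts[i, l, a]`` is how many copies (0..2) of allele ``alphabet[a]``
    sample ``i`` carries at locus ``l``; rows of a non-missing genotype sum
    to 2. ``missing[i, l]`` marks whole-genotype missingness (counts all 0).
    ``dialect`` records whether the source was nucleotide pairs or 0/1/2
    codes, which only matters for writing the matrix back out.
    """

    sample_ids: list
    counts: np.ndarray
    missing: np.ndarray
    alphabet: tuple = NUCLEOTIDES
    dialect: str = "snp_nucleotide"
    locus_names: list | None = None

    def __post_init__(self):
        self.sample_ids = _check_ids(self.sample_ids)
        self.counts = np.asarray(self.counts, dtype=np.uint8)
        self.missing = np.asarray(self.missing, dtype=bool)
        n, L = self.missing.shape
        if self.counts.shape != (n, L, len(self.alphabet)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"({n}, {L}, {len(self.alphabet)})"
            )
        sums = self.counts.sum(axis=2)
        ok = (sums == 2) | (self.missing & (sums == 0))
        if not ok.all():
            i, j = np.argwhere(~ok)[0]
            raise ValidationError(
                f"genotype of sample {self.sample_ids[i]!r} at locus {j} "
                "is neither a diploid pair nor missing"
            )

    @property
    def n_loci(self) -> int:
        return self.missing.shape[1]

    def genotype_str(self, i: int, l: int) -> str:
        """Canonical token for one cell ('AG', '0'/'1'/'2', or '?')."""
        if self.missing[i, l]:
            return "?"
        alleles = []
        for a, c in enumerate(self.counts[i, l]):
            alleles.extend([self.alphabet[a]] * int(c))
        if self.dialect == "genotype_code":
            # alphabet ("A", "B"): counts of B give the 0/1/2 code
            return str(int(self.counts[i, l, 1]))
        return "".join(sorted(alleles))

    def take_samples(self, keep) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        return GenotypeMatrix(
            list(keep), self.counts[idx], self.missing[idx],
            self.alphabet, self.dialect, self.locus_names,
        )

    def take_loci(self, idx) -> "GenotypeMatrix":
        names = (
            [self.locus_names[i] for i in idx] if self.locus_names else None
        )
        return GenotypeMatrix(
            self.sample_ids, self.counts[:, idx], self.missing[:, idx],
            self.alphabet, self.dialect, names,
        )


def genotype_matrix_from_pairs(sample_ids, pairs, alphabet=NUCLEOTIDES,
                               dialect="snp_nucleotide", locus_names=None):
    """Build a :class:`GenotypeMatrix` from per-cell allele pairs.

    ``pairs[i][l]`` is a 2-tuple of allele symbols or ``None`` for missing.
    """
    ids = list(sample_ids)
    n = len(ids)
    L = len(pairs[0]) if n else 0
    a_index = {a: k for k, a in enumerate(alphabet)}
    counts = np.zeros((n, L, len(alphabet)), dtype=np.uint8)
    missing = np.zeros((n, L), dtype=bool)
    for i, row in enumerate(pairs):
        if len(row) != L:
            raise ValidationError(
                f"row for sample {ids[i]!r} has {len(row)} loci, expected {L}"
            )
        for l, pair in enumerate(row):
            if pair is None:
                missing[i, l] = True
                continue
            for al in pair:
                if al not in a_index:
                    raise ValidationError(
                        f"illegal allele {al!r} for sample {ids[i]!r}, "
                        f"locus {l}"
                    )
                counts[i, l, a_index[al]] += 1
    return GenotypeMatrix(ids, counts, missing, tuple(alphabet), dialect,
                          locus_names)


@dataclass
class TaxonGrouping:
    """Map each sample to a taxon group; optionally name an outgroup.

    ``exclusion_sets`` are optional named custom exclusion sets (lists of
    sample ids) used in addition to the one-group-at-a-time jackknife.
    """

    assignments: dict
    outgroup: str | None = None
    exclusion_sets: dict = field(default_factory=dict)

    def __post_init__(self):
        self.assignments = dict(self.assignments)
        groups = set(self.assignments.values())
        if self.outgroup is not None and self.outgroup not in groups:
            raise ValidationError(
                f"outgroup {self.outgroup!r} is not a group "
                f"(groups: {sorted(groups)})"
            )
        ingroup = self.ingroup_samples()
        for name, members in self.exclusion_sets.items():
            members = list(members)
            if not members:
                raise ValidationError(f"exclusion set {name!r} is empty")
            unknown = [s for s in members if s not in self.assignments]
            if unknown:
                raise ValidationError(
                    f"exclusion set {name!r} names unknown samples {unknown}"
                )
            outg = [s for s in members if s not in ingroup]
            if outg:
                raise ValidationError(
                    f"exclusion set {name!r} contains outgroup samples {outg}"
                )
            if set(members) >= set(ingroup):
                raise ValidationError(
                    f"exclusion set {name!r} would remove the whole ingroup"
                )
            self.exclusion_sets[name] = members

    @property
    def samples(self) -> list:
        return list(self.assignments)

    def groups(self) -> dict:
        """group label -> list of sample ids, in input order."""
        out: dict = {}
        for s, g in self.assignments.items():
            out.setdefault(g, []).append(s)
        return out

    def ingroup_groups(self) -> list:
        return [g for g in self.groups() if g != self.outgroup]

    def ingroup_samples(self) -> list:
        return [s for s, g in self.assignments.items() if g != self.outgroup]

    def group_of(self, sample) -> str:
        return self.assignments[sample]
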