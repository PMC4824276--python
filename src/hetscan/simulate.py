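"""Multispecies-coalescent simulation of SNP and AFLP datasets.

Species trees are parameterised on the substitutions scale: node divergence
times tau (expected substitutions/site; tips at 0) and per-branch population
parameters theta = 4*Ne*mu. Each taxon contributes a fixed number of diploid
individuals (default 2, i.e. 4 haplotypes). Per requested locus one gene
tree is drawn under the coalescent; a SNP locus is a single site evolved
under Jukes-Cantor from a uniform-random ancestral base, an AFLP locus is a
10-position restriction-recognition sequence whose joint intactness defines
a dominant band. Loci monomorphic across the sampled individuals are
discarded, and simulation continues until the requested polymorphic-locus
count is reached or the raw-locus budget is exhausted.

A hybrid taxon is planted by running two parallel simulations -- one with
the hybrid branching off each parent lineage at the hybridization time
tau_h -- for half the loci each, and concatenating the two matrices, so
the parents contribute equally to the hybrid's mosaic genome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _coalescent as _kern
from .matrices import GenotypeMatrix, LocusMatrix, TaxonGrouping

__all__ = [
    "SpeciesTreeModel",
    "HybridSpec",
    "HybridTruth",
    "GeneTree",
    "simulate_gene_tree",
    "simulate_gene_trees",
    "simulate_snp_dataset",
    "simulate_aflp_dataset",
    "make_hybrid_dataset",
    "single_population_model",
    "tropheini_like_model",
    "radiation_model",
    "HYBRID_SCENARIOS",
]

AFLP_SITES = 10
DEFAULT_BUDGET_FACTOR = 1000


@dataclass
class SpeciesTreeModel:
    """Rooted species tree as flat arrays (one entry per node).

    ``theta[v]`` is the population parameter of the branch above node v
    (for the root: of the ancestral population above the root).
    """

    names: list          # node names; tips carry taxon names
    parent: np.ndarray   # int, -1 for root
    tau: np.ndarray      # float, node divergence times
    theta: np.ndarray
    samples_per_taxon: int = 2
    outgroup: str | None = None

    def __post_init__(self):
        self.parent = np.asarray(self.parent, dtype=np.int32)
        self.tau = np.asarray(self.tau, dtype=np.float64)
        self.theta = np.asarray(self.theta, dtype=np.float64)
        if (self.theta <= 0).any():
            raise ValueError("theta must be positive on every branch")
        n_children = np.zeros(len(self.names), dtype=int)
        for v, p in enumerate(self.parent):
            if p >= 0:
                if self.tau[p] <= self.tau[v]:
                    raise ValueError(
                        f"tau of node {p} must exceed tau of child {v}"
                    )
                n_children[p] += 1
        self._is_tip = n_children == 0
        if (self.tau[self._is_tip] != 0).any():
            raise ValueError("tips must have tau = 0")

    # -- derived structure -------------------------------------------------

    @property
    def is_tip(self) -> np.ndarray:
        return self._is_tip

    @property
    def taxa(self) -> list:
        return [self.names[v] for v in np.flatnonzero(self._is_tip)]

    @property
    def n_haplotypes_per_taxon(self) -> int:
        return 2 * self.samples_per_taxon

    def _kernel_arrays(self):
        S = len(self.names)
        tip_count = np.where(self._is_tip, self.n_haplotypes_per_taxon, 0
                             ).astype(np.int32)
        tip_offset = np.zeros(S, dtype=np.int32)
        off = 0
        for v in range(S):
            if tip_count[v]:
                tip_offset[v] = off
                off += tip_count[v]
        order = np.argsort(self.tau, kind="stable").astype(np.int64)
        return (self.parent, self.tau, self.theta, order, tip_count,
                tip_offset, int(off))

    def sample_ids(self) -> list:
        """Diploid individual ids, suffixed with their taxon group."""
        ids = []
        for t in self.taxa:
            for i in range(self.samples_per_taxon):
                ids.append(f"{t}{i + 1}_{t}")
        return ids

    def grouping(self) -> TaxonGrouping:
        return TaxonGrouping(
            {s: s.rsplit("_", 1)[1] for s in self.sample_ids()},
            outgroup=self.outgroup,
        )

    def node_by(self, spec) -> int:
        """Node index from a taxon name or a tuple of taxa (their MRCA)."""
        if isinstance(spec, str):
            for v, nm in enumerate(self.names):
                if nm == spec and self._is_tip[v]:
                    return v
            raise KeyError(f"no taxon {spec!r}")
        want = set(spec)
        below = self.descendant_taxa()
        candidates = [v for v in range(len(self.names))
                      if want <= set(below[v])]
        return min(candidates, key=lambda v: len(below[v]))

    def descendant_taxa(self) -> list:
        below = [set() for _ in self.names]
        order = np.argsort(self.tau, kind="stable")
        for v in order:
            if self._is_tip[v]:
                below[v].add(self.names[v])
            if self.parent[v] >= 0:
                below[self.parent[v]] |= below[v]
        return [tuple(sorted(b)) for b in below]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, theta: float, samples_per_taxon: int = 2,
                    outgroup: str | None = None) -> "SpeciesTreeModel":
        """Parse a newick string whose internal node labels are tau values.

        Tips have tau 0; ``theta`` is applied uniformly to all branches
        (per-branch values can be set on the returned model's array).
        """
        import dendropy

        tree = dendropy.Tree.get(data=newick, schema="newick")
        names, parents, taus = [], [], []
        index = {}

        def visit(node, parent_idx):
            v = len(names)
            index[id(node)] = v
            if node.is_leaf():
                names.append(node.taxon.label if node.taxon else node.label)
                taus.append(0.0)
            else:
                label = node.label
                if label is None:
                    raise ValueError(
                        "internal node without a tau label in species tree"
                    )
                names.append(f"anc{v}")
                taus.append(float(label))
            parents.append(parent_idx)
            for ch in node.child_nodes():
                visit(ch, v)

        visit(tree.seed_node, -1)
        th = np.full(len(names), float(theta))
        return cls(names=names, parent=np.array(parents), tau=np.array(taus),
                   theta=th, samples_per_taxon=samples_per_taxon,
                   outgroup=outgroup)

    def with_hybrid(self, attach, hybrid_name: str, tau_h: float
                    ) -> "SpeciesTreeModel":
        """Graft a hybrid tip onto the branch above ``attach`` at tau_h."""
        v = self.node_by(attach)
        p = self.parent[v]
        hi = self.tau[p] if p >= 0 else math.inf
        if not (self.tau[v] < tau_h < hi):
            raise ValueError(
                f"tau_h={tau_h} not inside the branch above node {attach!r} "
                f"({self.tau[v]} .. {hi})"
            )
        names = list(self.names)
        parent = list(self.parent)
        tau = list(self.tau)
        theta = list(self.theta)
        mid = len(names)
        names.append(f"anc_h{mid}")
        parent.append(int(p))
        tau.append(float(tau_h))
        theta.append(float(self.theta[v]))
        parent[v] = mid
        tip = len(names)
        names.append(hybrid_name)
        parent.append(mid)
        tau.append(0.0)
        theta.append(float(self.theta[v]))
        return SpeciesTreeModel(
            names=names, parent=np.array(parent), tau=np.array(tau),
            theta=np.array(theta), samples_per_taxon=self.samples_per_taxon,
            outgroup=self.outgroup,
        )


@dataclass(frozen=True)
class HybridSpec:
    """Instantaneous hybrid origin between two parent lineages at tau_h.

    Each parent lineage is a taxon name or a tuple of taxa (their MRCA).
    The admixture proportion is fixed at 0.5 (equal locus counts from each
    side of the merge).
    """

    parent_a: object
    parent_b: object
    tau_h: float
    hybrid_name: str = "hyb"


@dataclass
class HybridTruth:
    """What was planted, for scoring HET signals afterwards."""

    hybrid_group: str
    parent_taxa: tuple  # (taxa under lineage A, taxa under lineage B)
    tau_h: float

    def to_tsv(self, path):
        with open(path, "w") as fh:
            fh.write("hybrid_group\t" + self.hybrid_group + "\n")
            fh.write("parent_a\t" + ",".join(self.parent_taxa[0]) + "\n")
            fh.write("parent_b\t" + ",".join(self.parent_taxa[1]) + "\n")
            fh.write(f"tau_h\t{self.tau_h:g}\n")

    @classmethod
    def from_tsv(cls, path) -> "HybridTruth":
        kv = {}
        with open(path) as fh:
            for line in fh:
                if line.strip():
                    k, v = line.rstrip("\n").split("\t", 1)
                    kv[k] = v
        return cls(
            hybrid_group=kv["hybrid_group"],
            parent_taxa=(tuple(kv["parent_a"].split(",")),
                         tuple(kv["parent_b"].split(","))),
            tau_h=float(kv["tau_h"]),
        )


# ---------------------------------------------------------------------------
# gene trees


@dataclass
class GeneTree:
    """A coalescent gene tree: tips 0..n-1 at time 0, internal nodes in
    coalescence order, times in expected substitutions/site."""

    parent: np.ndarray
    time: np.ndarray
    tip_labels: list

    @property
    def n_tips(self) -> int:
        return (len(self.parent) + 1) // 2

    @property
    def total_length(self) -> float:
        p = self.parent[:-1]
        return float((self.time[p] - self.time[:-1]).sum())

    def mrca_time(self, i: int, j: int) -> float:
        anc = set()
        u = i
        while u >= 0:
            anc.add(u)
            u = self.parent[u]
        u = j
        while u not in anc:
            u = self.parent[u]
        return float(self.time[u])

    def pairwise_divergence(self, i: int, j: int) -> float:
        """Path length between two tips (= 2 * MRCA time)."""
        return 2.0 * self.mrca_time(i, j)

    def to_newick(self) -> str:
        children: dict = {}
        for u, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(u)

        def rec(u):
            if u < self.n_tips:
                name = self.tip_labels[u]
            else:
                name = ""
            if u in children:
                inner = ",".join(
                    f"{rec(c)}:{self.time[u] - self.time[c]:.8g}"
                    for c in children[u]
                )
                return f"({inner}){name}"
            return name

        return rec(len(self.parent) - 1) + ";"


def _tip_labels(model: SpeciesTreeModel) -> list:
    labels = []
    for t in model.taxa:
        labels.extend(
            f"{t}^{h + 1}" for h in range(model.n_haplotypes_per_taxon)
        )
    return labels


def simulate_gene_trees(model: SpeciesTreeModel, n: int, seed: int) -> list:
    """n independent gene trees under the model."""
    (parent, tau, theta, order, tip_count, tip_offset,
     n_tips) = model._kernel_arrays()
    out_parent = np.empty((n, 2 * n_tips - 1), dtype=np.int32)
    out_time = np.empty((n, 2 * n_tips - 1), dtype=np.float64)
    _kern.gene_tree_batch(_u32(seed), n, parent, tau, theta, order,
                          tip_count, tip_offset, n_tips, out_parent, out_time)
    labels = _tip_labels(model)
    return [GeneTree(out_parent[i], out_time[i], labels) for i in range(n)]


def simulate_gene_tree(model: SpeciesTreeModel, seed: int) -> GeneTree:
    return simulate_gene_trees(model, 1, seed)[0]


# ---------------------------------------------------------------------------
# datasets


def _u32(seed) -> int:
    return int(seed) % (2**32 - 1)


class LocusBudgetError(RuntimeError):
    def __init__(self, target, got, budget):
        self.target, self.got, self.budget = target, got, budget
        super().__init__(
            f"raw-locus budget of {budget} exhausted: {got} polymorphic "
            f"loci of {target} requested"
        )


def _accumulate(model, n_loci, seed, raw_budget, batch_kernel, width, fill):
    """Shared polymorphic-locus accumulation loop."""
    arrays = model._kernel_arrays()
    n_tips = arrays[-1]
    rng = np.random.default_rng(seed)
    collected = []
    got = 0
    used = 0
    budget = raw_budget or DEFAULT_BUDGET_FACTOR * n_loci
    while got < n_loci:
        batch = int(min(8192, budget - used))
        if batch <= 0:
            raise LocusBudgetError(n_loci, got, budget)
        out = np.empty((batch, width(n_tips)), dtype=np.int8)
        poly = np.empty(batch, dtype=np.bool_)
        batch_kernel(int(rng.integers(0, 2**31)), batch, *arrays[:-1],
                     n_tips, out, poly)
        keep = out[poly]
        got += keep.shape[0]
        used += batch
        collected.append(keep)
    stacked = np.concatenate(collected, axis=0)[:n_loci]
    return fill(stacked)


def simulate_snp_dataset(model: SpeciesTreeModel, n_loci: int, seed: int,
                         raw_budget: int | None = None) -> GenotypeMatrix:
    """Polymorphic single-site SNP loci as diploid nucleotide genotypes."""

    def fill(states):
        # states: (L, n_tips); haplotype pairs (2i, 2i+1) form individual i
        L, n_tips = states.shape
        h1 = states[:, 0::2]
        h2 = states[:, 1::2]
        onehot = np.eye(4, dtype=np.uint8)
        counts = onehot[h1] + onehot[h2]          # (L, n_ind, 4)
        counts = counts.transpose(1, 0, 2).copy()  # (n_ind, L, 4)
        ids = model.sample_ids()
        missing = np.zeros((len(ids), L), dtype=bool)
        return GenotypeMatrix(ids, counts, missing)

    return _accumulate(model, n_loci, seed, raw_budget, _kern.snp_batch,
                       lambda n_tips: n_tips, fill)


def simulate_aflp_dataset(model: SpeciesTreeModel, n_loci: int, seed: int,
                          raw_budget: int | None = None) -> LocusMatrix:
    """Polymorphic dominant binary loci (band presence/absence)."""

    def kernel(seed_, batch, parent, tau, theta, order, tip_count,
               tip_offset, n_tips, out, poly):
        _kern.aflp_batch(seed_, batch, parent, tau, theta, order, tip_count,
                         tip_offset, n_tips, AFLP_SITES, out, poly)

    def fill(bands):
        return LocusMatrix(model.sample_ids(), bands.T.astype(np.int8))

    return _accumulate(model, n_loci, seed, raw_budget, kernel,
                       lambda n_tips: n_tips // 2, fill)


def make_hybrid_dataset(model: SpeciesTreeModel, hybrid: HybridSpec,
                        n_loci: int, seed: int, marker: str = "SNP",
                        raw_budget: int | None = None):
    """Merged dataset with a planted hybrid taxon, plus the truth record.

    Two simulations are run, the hybrid grafted onto each parent lineage at
    tau_h, each contributing half the loci (odd counts rounded up to even).
    """
    if n_loci % 2:
        import warnings

        warnings.warn(f"odd locus count {n_loci} rounded up to {n_loci + 1}",
                      stacklevel=2)
        n_loci += 1
    half = n_loci // 2
    model_a = model.with_hybrid(hybrid.parent_a, hybrid.hybrid_name,
                                hybrid.tau_h)
    model_b = model.with_hybrid(hybrid.parent_b, hybrid.hybrid_name,
                                hybrid.tau_h)
    sim = simulate_snp_dataset if marker.upper() == "SNP" else simulate_aflp_dataset
    half_budget = raw_budget // 2 if raw_budget else None
    rng = np.random.default_rng(seed)
    sa, sb = (int(x) for x in rng.integers(0, 2**31, size=2))
    ma = sim(model_a, half, sa, half_budget)
    mb = sim(model_b, half, sb, half_budget)
    mb = mb.take_samples(ma.sample_ids)
    if isinstance(ma, LocusMatrix):
        merged = LocusMatrix(ma.sample_ids,
                             np.concatenate([ma.values, mb.values], axis=1))
    else:
        merged = GenotypeMatrix(
            ma.sample_ids,
            np.concatenate([ma.counts, mb.counts], axis=1),
            np.concatenate([ma.missing, mb.missing], axis=1),
            ma.alphabet, ma.dialect,
        )
    below = model.descendant_taxa()
    truth = HybridTruth(
        hybrid_group=hybrid.hybrid_name,
        parent_taxa=(below[model.node_by(hybrid.parent_a)],
                     below[model.node_by(hybrid.parent_b)]),
        tau_h=hybrid.tau_h,
    )
    return merged, truth


# ---------------------------------------------------------------------------
# presets


def single_population_model(theta: float, n_haplotypes: int = 2
                            ) -> SpeciesTreeModel:
    """One panmictic population (for calibration checks)."""
    if n_haplotypes % 2:
        raise ValueError("n_haplotypes must be even (diploid individuals)")
    return SpeciesTreeModel(
        names=["pop"], parent=np.array([-1]), tau=np.array([0.0]),
        theta=np.array([theta]), samples_per_taxon=n_haplotypes // 2,
    )


# 18 ingroup taxa + 1 outgroup. The branching order and the internal tau
# values between the printed anchors (ingroup root 0.000225, most recent
# splits 0.00001) are this package's own depth-interpolated choice; the
# taxon letters follow the hybridization scenarios below.
TROPHEINI_NEWICK = (
    "((((((r,q)0.00001,(k,(a,b)0.00001)0.00003)0.00005,"
    "((l,(m,n)0.00001)0.00002,(s,(c,d)0.00001)0.00002)0.00006)0.0001,"
    "(e,(f,g)0.00001)0.00008)0.00015,"
    "(o,(w,(x,y)0.00001)0.00006)0.00012)0.000225,out)0.0003;"
)


def tropheini_like_model(theta: float = 0.0005, samples_per_taxon: int = 2
                         ) -> SpeciesTreeModel:
    """Cichlid-tribe-like 18-ingroup-taxon tree used for the simulations."""
    return SpeciesTreeModel.from_newick(
        TROPHEINI_NEWICK, theta=theta, samples_per_taxon=samples_per_taxon,
        outgroup="out",
    )


def radiation_model(theta: float = 0.0005, samples_per_taxon: int = 2,
                    n_taxa: int = 18) -> SpeciesTreeModel:
    """Near-simultaneous radiation: splits evenly spread over
    tau = 0.00005 .. 0.000058, approximately equal distances among taxa."""
    taxa = [f"t{i + 1:02d}" for i in range(n_taxa)]
    lo, hi = 0.00005, 0.000058
    taus = np.linspace(lo, hi, n_taxa - 1)
    nwk = f"({taxa[0]},{taxa[1]}){taus[0]:.8f}"
    for i in range(2, n_taxa):
        nwk = f"({nwk},{taxa[i]}){taus[i - 1]:.8f}"
    nwk = f"({nwk},out)0.000225;"
    return SpeciesTreeModel.from_newick(
        nwk, theta=theta, samples_per_taxon=samples_per_taxon, outgroup="out",
    )


# The four hybridization scenarios studied on the tree above: recent and
# very recent l x s, intermediate (r,q) x k, ancient (r,q) x (l,m,n).
HYBRID_SCENARIOS = {
    "l_x_s": HybridSpec("l", "s", 0.00001),
    "l_x_s_very_recent": HybridSpec("l", "s", 0.000002),
    "rq_x_k": HybridSpec(("r", "q"), "k", 0.000025),
    "rq_x_lmn": HybridSpec(("r", "q"), ("l", "m", "n"), 0.000037),
}
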