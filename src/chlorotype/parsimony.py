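"""Maximum parsimony on small nucleotide matrices.

Exact inference for the genome-scale phylogenies this package deals in
(seven ingroup plastomes plus outgroups): Fitch small-parsimony scoring,
exhaustive enumeration of all (2n-5)!! unrooted binary topologies for up to
10 taxa, strict consensus of the optimal set, site-resampling bootstrap and
outgroup rooting.  All characters are equally weighted; gaps and N are
treated as fully missing (any state).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

_STATE_MASK = {"A": 1, "C": 2, "G": 4, "T": 8}
_MISSING = 15  # N, gap, ? : unconstrained


def state_mask(symbol: str) -> int:
    return _STATE_MASK.get(symbol.upper(), _MISSING)


@dataclass
class CharacterMatrix:
    """Taxa × sites nucleotide matrix; rows are equal-length state strings."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("ragged matrix")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    @property
    def nsites(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0

    def site_masks(self) -> list[dict[str, int]]:
        """Per-site taxon -> state bitmask."""
        return [
            {t: state_mask(self.sequences[t][i]) for t in self.sequences}
            for i in range(self.nsites)
        ]

    def resample_sites(self, rng: np.random.Generator) -> "CharacterMatrix":
        idx = rng.integers(0, self.nsites, size=self.nsites)
        return CharacterMatrix(
            {t: "".join(s[i] for i in idx) for t, s in self.sequences.items()}
        )

    @classmethod
    def from_fasta(cls, path) -> "CharacterMatrix":
        from Bio import SeqIO
        return cls({r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")})


# ---------------------------------------------------------------------------
# topology representation
# ---------------------------------------------------------------------------
#
# An unrooted binary topology over taxa [t0, t1, ...] is stored as a nested
# tuple over the remaining taxa, anchored at t0: the unrooted tree is the
# anchor leaf joined to the nested tuple's root edge.

@dataclass(frozen=True)
class Topology:
    anchor: str
    rep: object  # nested 2-tuples of taxon labels

    def leaves(self) -> set[str]:
        out = {self.anchor}
        stack = [self.rep]
        while stack:
            t = stack.pop()
            if isinstance(t, tuple):
                stack.extend(t)
            else:
                out.add(t)
        return out

    def splits(self) -> frozenset[frozenset[str]]:
        """Nontrivial bipartitions in canonical form.

        Each split is reported as the side that does not hold the
        lexicographically smallest taxon, so splits compare equal across
        differently anchored (rerooted) representations.
        """
        leaves = self.leaves()
        n = len(leaves)
        pivot = min(leaves)
        out = []

        def walk(t) -> set[str]:
            if not isinstance(t, tuple):
                return {t}
            leafset = walk(t[0]) | walk(t[1])
            if 2 <= len(leafset) <= n - 2:
                side = leaves - leafset if pivot in leafset else leafset
                if 2 <= len(side) <= n - 2:
                    out.append(frozenset(side))
            return leafset

        walk(self.rep)  # the rep's own edge is the anchor's pendant: size n-1
        return frozenset(out)

    def newick(self) -> str:
        def fmt(t) -> str:
            if isinstance(t, tuple):
                return f"({fmt(t[0])},{fmt(t[1])})"
            return str(t)
        return f"({self.anchor},{fmt(self.rep)});"


def enumerate_topologies(taxa: list[str]):
    """Yield all (2n-5)!! unrooted binary topologies by stepwise addition."""
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")
    anchor, rest = taxa[0], taxa[1:]

    def insertions(tree, x):
        yield (tree, x)
        if isinstance(tree, tuple):
            a, b = tree
            for ta in insertions(a, x):
                yield (ta, b)
            for tb in insertions(b, x):
                yield (a, tb)

    reps = [rest[0]]
    for x in rest[1:]:
        reps = [t for rep in reps for t in insertions(rep, x)]
    for rep in reps:
        yield Topology(anchor, rep)


def count_topologies(n: int) -> int:
    """(2n-5)!! — the number of unrooted binary topologies on n taxa."""
    out = 1
    for k in range(3, 2 * n - 4, 2):
        out *= k
    return out


# ---------------------------------------------------------------------------
# Fitch scoring
# ---------------------------------------------------------------------------

def _fitch_site(tree, masks: dict[str, int]) -> tuple[int, int]:
    if not isinstance(tree, tuple):
        return masks[tree], 0
    ma, sa = _fitch_site(tree[0], masks)
    mb, sb = _fitch_site(tree[1], masks)
    inter = ma & mb
    if inter:
        return inter, sa + sb
    return ma | mb, sa + sb + 1


def fitch_length(tree: Topology, matrix: CharacterMatrix) -> int:
    """Minimum number of state changes over all sites (Fitch algorithm)."""
    if tree.leaves() != set(matrix.taxa):
        raise ValueError("tree leaves do not match matrix taxa")
    score = 0
    for masks in matrix.site_masks():
        rooted = (tree.rep, tree.anchor)
        _mask, s = _fitch_site(rooted, masks)
        score += s
    return score


# ---------------------------------------------------------------------------
# exhaustive search, consensus, bootstrap
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    best_score: int
    optimal: list[Topology]
    consensus_splits: frozenset[frozenset[str]]
    taxa: list[str]
    n_topologies: int
    bootstrap_support: dict[frozenset[str], float] = field(default_factory=dict)

    def consensus_newick(self) -> str:
        return splits_to_newick(self.consensus_splits, self.taxa,
                                self.bootstrap_support or None)


def exhaustive_search(matrix: CharacterMatrix) -> SearchResult:
    """Score every unrooted binary topology; keep the full optimal set.

    Exact for 3..10 taxa; beyond that the enumeration is refused (a
    heuristic search is out of scope here).
    """
    taxa = matrix.taxa
    if not 3 <= len(taxa) <= 10:
        raise ValueError("exhaustive search supports 3..10 taxa")
    best: list[Topology] = []
    best_score = None
    count = 0
    site_masks = matrix.site_masks()
    for topo in enumerate_topologies(taxa):
        count += 1
        score = 0
        rooted = (topo.rep, topo.anchor)
        for masks in site_masks:
            score += _fitch_site(rooted, masks)[1]
            if best_score is not None and score > best_score:
                break
        if best_score is None or score < best_score:
            best, best_score = [topo], score
        elif score == best_score:
            best.append(topo)
    consensus = frozenset.intersection(*(t.splits() for t in best))
    return SearchResult(best_score=int(best_score), optimal=best,
                        consensus_splits=consensus, taxa=taxa,
                        n_topologies=count)


def bootstrap(matrix: CharacterMatrix, replicates: int, seed: int) -> dict[frozenset[str], float]:
    """Site-resampling bootstrap support (percent) per split.

    Each replicate resamples sites with replacement, re-runs the exhaustive
    search and takes the strict consensus of its optimal trees; ties
    therefore propagate as unresolved and contribute support to no
    conflicting split.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(replicates):
        result = exhaustive_search(matrix.resample_sites(rng))
        for split in result.consensus_splits:
            counts[split] = counts.get(split, 0) + 1
    return {split: 100.0 * k / replicates for split, k in counts.items()}


# ---------------------------------------------------------------------------
# rooting
# ---------------------------------------------------------------------------

def _adjacency(topo: Topology) -> dict:
    """Explicit adjacency of the unrooted tree; internal nodes are ints."""
    adj: dict[object, list] = {}
    counter = itertools.count()

    def connect(a, b):
        adj.setdefault(a, []).append(b)
        adj.setdefault(b, []).append(a)

    def walk(t):
        if not isinstance(t, tuple):
            return t
        node = ("i", next(counter))
        connect(walk(t[0]), node)
        connect(walk(t[1]), node)
        return node

    top = walk(topo.rep)
    connect(topo.anchor, top)
    return adj


def root_with_outgroup(topo: Topology, outgroup: str):
    """Root the topology on the outgroup's pendant edge.

    Returns a rooted nested tuple ``(outgroup, ingroup_subtree)``.
    Unrooting the result (via :func:`unroot`) recovers the original
    topology's splits.
    """
    if outgroup not in topo.leaves():
        raise KeyError(f"unknown taxon {outgroup!r}")
    adj = _adjacency(topo)

    def subtree(node, parent):
        children = [n for n in adj[node] if n != parent]
        if not children:
            return node
        parts = [subtree(c, node) for c in children]
        out = parts[0]
        for p in parts[1:]:
            out = (out, p)
        return out

    (neighbor,) = adj[outgroup]
    return (outgroup, subtree(neighbor, outgroup))


def unroot(rooted: tuple) -> Topology:
    """Collapse a rooted ``(outgroup, rest)`` pair back to an unrooted topology."""
    outgroup, rest = rooted
    if isinstance(outgroup, tuple):
        raise ValueError("expected (leaf, subtree) rooting")
    return Topology(anchor=outgroup, rep=rest)


def rooted_newick(rooted: tuple) -> str:
    def fmt(t) -> str:
        if isinstance(t, tuple):
            return f"({fmt(t[0])},{fmt(t[1])})"
        return str(t)
    return fmt(rooted) + ";"


def is_monophyletic(topo: Topology, group: set[str], outgroup: str) -> bool:
    """Whether ``group`` forms a clade when rooted on ``outgroup``."""
    group = frozenset(group)
    others = frozenset(topo.leaves()) - group - {outgroup}
    if not others or len(group) <= 1:
        return True
    for split in topo.splits():
        other_side = frozenset(topo.leaves()) - split
        for side in (split, other_side):
            if side == group and outgroup not in side:
                return True
    return False


# ---------------------------------------------------------------------------
# consensus tree construction from compatible splits
# ---------------------------------------------------------------------------

def splits_to_newick(
    splits,
    taxa: list[str],
    support: dict[frozenset[str], float] | None = None,
) -> str:
    """Build a (possibly multifurcating) Newick string from compatible splits."""
    splits = sorted(splits, key=len)

    def build(leafset, available):
        maximal = []
        used: set[str] = set()
        for s in sorted(available, key=len, reverse=True):
            if s < leafset and not s & used:
                maximal.append(s)
                used |= s
        parts = []
        for s in maximal:
            inner = build(s, [t for t in available if t < s])
            tag = ""
            if support and s in support:
                tag = f"{support[s]:.0f}"
            parts.append(f"{inner}{tag}")
        for leaf in sorted(leafset - used):
            parts.append(str(leaf))
        return "(" + ",".join(parts) + ")"

    return build(frozenset(taxa), list(splits)) + ";"
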