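"""Haplotype character coding and reduced-median network construction.

Character coding follows the single-step mutation convention for plastid
microsatellites: a multi-state SSR locus becomes an *ordered* character whose
states are motif repeat counts (one mutation = one repeat step), while
presence/absence of any other indel is a *binary* character.  Loci combining
an indel and a microsatellite emit one character of each kind; CAPS loci are
excluded by default (they are homoplastic at the lineage level and were not
used in the published network).

Ordered characters are expanded into ladders of cumulative threshold
indicators (one binary character per unit step between the observed minimum
and maximum), which preserves pairwise distances exactly and lets the
reduced-median construction operate on binary data.

The reduced-median construction itself: identical binary columns are
condensed (weights add); incompatible character pairs whose
frequency-weighted support ratio reaches the reduction parameter ``r`` are
resolved in favour of the better-supported character by splitting the weaker
character into two independent mutations; the median closure (iterative
majority medians of triples) is then computed and nodes differing in exactly
one condensed character are joined.  Inferred median nodes carry no
frequency; identical nodes merge.  Ties resolve by (higher summed haplotype
frequency, then lexicographic node id), making the output deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .markers import CAPS, INDEL, MIXED, SSR, Panel, size_to_repeat_count

ORDERED = "ordered_multistate"
BINARY = "binary"


@dataclass
class CodedMatrix:
    """Haplotypes × characters with per-character kind and weight."""

    data: pd.DataFrame                      # haplotypes × characters, integer states
    kinds: dict[str, str]                   # character -> ORDERED | BINARY
    weights: dict[str, float]
    frequencies: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for char, kind in self.kinds.items():
            col = self.data[char]
            if (col != col.astype(int)).any():
                raise ValueError(f"character {char}: non-integer states")
            if kind == BINARY and not set(col.astype(int)) <= {0, 1}:
                raise ValueError(f"binary character {char}: states outside {{0,1}}")
            if self.weights.get(char, 1.0) <= 0:
                raise ValueError(f"character {char}: nonpositive weight")


@dataclass
class BinaryExpansion:
    """Back-map from expanded binary indicator characters to originals.

    Each expanded character maps to (original character, threshold); an
    ordered character with observed span [lo, hi] yields indicators
    ``char>=t`` for t in lo+1..hi.  Hamming distance on the expansion equals
    the summed absolute state difference on the originals (weights carried
    over), exactly.
    """

    back_map: dict[str, tuple[str, int | None]]


def encode_matrix(
    profiles: dict[str, dict],
    panel: Panel,
    include_caps: bool = False,
    frequencies: dict[str, float] | None = None,
) -> CodedMatrix:
    """Code haplotype profiles into an ordered/binary character matrix.

    ``profiles`` maps haplotype name -> {locus id -> allele value}.  SSR
    allele values may be fragment sizes (converted to repeat counts through
    the locus anchor) or repeat counts directly; indel/gel values are
    presence states (1/0 or 'present'/'absent'); mixed loci take a
    ``(ssr_value, indel_presence)`` pair and emit two characters; CAPS
    values are 'cut'/'uncut' (binary, off by default).
    """
    names = list(profiles)
    loci = sorted({locus for p in profiles.values() for locus in p}, key=str)
    columns: dict[str, list[int]] = {}
    kinds: dict[str, str] = {}

    def ssr_state(locus, value) -> int:
        lc = panel[locus] if locus in panel else None
        if lc is not None and lc.anchor is not None and isinstance(value, (int, float)):
            lo = lc.size_range[0] if lc.size_range else lc.anchor[0]
            if value >= lo - 10:  # looks like a fragment size, not a count
                return size_to_repeat_count(int(value), lc)
        return int(value)

    def binary_state(value) -> int:
        if value in (0, 1):
            return int(value)
        return {"present": 1, "absent": 0, "cut": 1, "uncut": 0}[value]

    for locus in loci:
        kind = panel[locus].kind if locus in panel else SSR
        if kind == CAPS and not include_caps:
            continue
        values = [profiles[n].get(locus) for n in names]
        if any(v is None for v in values):
            raise ValueError(f"locus {locus}: profiles must be complete for coding")
        if kind == MIXED:
            columns[f"{locus}:ssr"] = [ssr_state(locus, v[0]) for v in values]
            kinds[f"{locus}:ssr"] = ORDERED
            columns[f"{locus}:indel"] = [binary_state(v[1]) for v in values]
            kinds[f"{locus}:indel"] = BINARY
        elif kind == SSR:
            columns[str(locus)] = [ssr_state(locus, v) for v in values]
            kinds[str(locus)] = ORDERED
        else:  # indel, gel-scored or CAPS (when included)
            columns[str(locus)] = [binary_state(v) for v in values]
            kinds[str(locus)] = BINARY

    data = pd.DataFrame(columns, index=names)
    weights = {c: 1.0 for c in data.columns}
    return CodedMatrix(data=data, kinds=kinds, weights=weights,
                       frequencies=dict(frequencies or {}))


def binary_expand(matrix: CodedMatrix) -> tuple[pd.DataFrame, dict[str, float], BinaryExpansion]:
    """Expand ordered characters into cumulative threshold indicators."""
    cols: dict[str, list[int]] = {}
    weights: dict[str, float] = {}
    back: dict[str, tuple[str, int | None]] = {}
    for char in matrix.data.columns:
        states = matrix.data[char].astype(int)
        if matrix.kinds[char] == BINARY:
            cols[char] = states.tolist()
            weights[char] = matrix.weights[char]
            back[char] = (char, None)
            continue
        lo, hi = int(states.min()), int(states.max())
        for t in range(lo + 1, hi + 1):
            name = f"{char}>={t}"
            cols[name] = (states >= t).astype(int).tolist()
            weights[name] = matrix.weights[char]
            back[name] = (char, t)
    binary = pd.DataFrame(cols, index=matrix.data.index, dtype=int)
    return binary, weights, BinaryExpansion(back_map=back)


# ---------------------------------------------------------------------------
# reduced-median construction
# ---------------------------------------------------------------------------

class MedianNetwork:
    """A reduced-median network over observed haplotypes and inferred medians.

    Wraps a :class:`networkx.Graph`; node attributes: ``labels`` (observed
    haplotype names, empty for medians), ``inferred``, ``frequency``,
    ``lineage``.  Edge attribute ``characters`` lists the original character
    names (decoded through the binary expansion) the edge flips.
    """

    def __init__(self, graph: nx.Graph, observed: dict[str, str]):
        self.graph = graph
        self.observed = observed  # haplotype name -> node id

    @property
    def nodes(self):
        return self.graph.nodes

    @property
    def edges(self):
        return self.graph.edges


def _majority(u: tuple, v: tuple, w: tuple) -> tuple:
    return tuple(1 if a + b + c >= 2 else 0 for a, b, c in zip(u, v, w))


def _incompatible(col_i: np.ndarray, col_j: np.ndarray) -> bool:
    gametes = {(a, b) for a, b in zip(col_i, col_j)}
    return len(gametes) == 4


def reduced_median(
    binary: pd.DataFrame,
    weights: dict[str, float] | None = None,
    frequencies: dict[str, float] | None = None,
    r: float = 2.0,
    expansion: BinaryExpansion | None = None,
) -> MedianNetwork:
    """Build a reduced-median network from a binary haplotype matrix.

    ``r`` is the reduction parameter: for each incompatible character pair,
    if one character's frequency-weighted support is at least ``r`` times
    the other's, the weaker character is treated as recurrent (split into
    two independent mutations) instead of generating reticulation medians.
    Homoplasy-free input therefore reproduces the unique perfect phylogeny
    exactly, for any ``r``.
    """
    if r < 1:
        raise ValueError("reduction parameter r must be >= 1")
    weights = dict(weights or {c: 1.0 for c in binary.columns})
    freqs = {h: float(frequencies.get(h, 1.0)) if frequencies else 1.0
             for h in binary.index}
    back = expansion.back_map if expansion else {c: (c, None) for c in binary.columns}

    # drop constant columns; they carry no signal
    work = binary.loc[:, binary.nunique() > 1].astype(int).copy()

    # character-splitting reduction for strongly asymmetric conflicts
    def support(col: pd.Series, w: float) -> float:
        f1 = sum(freqs[h] for h in work.index if col[h] == 1)
        f0 = sum(freqs[h] for h in work.index if col[h] == 0)
        return w * min(f0, f1)

    for _round in range(len(work.columns) ** 2 + 1):
        split_done = False
        cols = list(work.columns)
        for ci, cj in itertools.combinations(cols, 2):
            if ci not in work.columns or cj not in work.columns:
                continue
            if not _incompatible(work[ci].values, work[cj].values):
                continue
            si, sj = support(work[ci], weights[ci]), support(work[cj], weights[cj])
            if si >= r * sj:
                strong, weak = ci, cj
            elif sj >= r * si:
                strong, weak = cj, ci
            else:
                continue
            for side, tag in ((1, "a"), (0, "b")):
                name = f"{weak}|{tag}"
                work[name] = ((work[weak] == 1) & (work[strong] == side)).astype(int)
                weights[name] = weights[weak]
                back[name] = back.get(weak, (weak, None))
            work = work.drop(columns=[weak])
            work = work.loc[:, work.nunique() > 1]
            split_done = True
            break
        if not split_done:
            break

    # condense columns identical up to complementation: they carry the same
    # split of the haplotypes, and only the split matters for the network
    condensed: dict[tuple, dict] = {}
    for col in work.columns:
        key = tuple(work[col])
        if key and key[0] == 1:
            key = tuple(1 - v for v in key)
        entry = condensed.setdefault(key, {"weight": 0.0, "chars": []})
        entry["weight"] += weights[col]
        entry["chars"].append(back.get(col, (col, None))[0])
    patterns = list(condensed)
    char_labels = [sorted(set(condensed[p]["chars"])) for p in patterns]

    vec_of = {h: tuple(p[i] for p in patterns)
              for i, h in enumerate(work.index)}

    # median closure: iteratively add majority medians of node triples
    nodes: dict[tuple, float] = {}
    order = sorted(work.index, key=lambda h: (-freqs[h], str(h)))
    for h in order:
        nodes.setdefault(vec_of[h], 0.0)
        nodes[vec_of[h]] += freqs[h]
    changed = True
    while changed:
        changed = False
        current = sorted(nodes, key=lambda v: (-nodes[v], v))
        for u, v, w in itertools.combinations(current, 3):
            m = _majority(u, v, w)
            if m not in nodes:
                nodes[m] = 0.0
                changed = True

    # build the graph: edges join nodes differing in one condensed character
    graph = nx.Graph()
    node_ids: dict[tuple, str] = {}
    hap_node: dict[str, str] = {}
    inferred_counter = itertools.count(1)
    for vec in sorted(nodes, key=lambda v: (-nodes[v], v)):
        labels = sorted(h for h in work.index if vec_of[h] == vec)
        nid = "/".join(labels) if labels else f"mv{next(inferred_counter)}"
        node_ids[vec] = nid
        graph.add_node(nid, labels=labels, inferred=not labels,
                       frequency=nodes[vec])
        for h in labels:
            hap_node[h] = nid
    for u, v in itertools.combinations(node_ids, 2):
        diff = [i for i in range(len(u)) if u[i] != v[i]]
        if len(diff) == 1:
            graph.add_edge(node_ids[u], node_ids[v],
                           characters=char_labels[diff[0]],
                           weight=condensed[patterns[diff[0]]]["weight"])
    return MedianNetwork(graph, hap_node)


# ---------------------------------------------------------------------------
# export and lineage reports
# ---------------------------------------------------------------------------

def network_export(net: MedianNetwork, fmt: str, path) -> None:
    """Write the network as GraphML or DOT with node/edge attributes."""
    if fmt == "graphml":
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(n, labels=",".join(d["labels"]), inferred=d["inferred"],
                       frequency=float(d["frequency"]),
                       lineage=str(d.get("lineage", "")))
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, characters=",".join(map(str, d["characters"])),
                       weight=float(d["weight"]))
        nx.write_graphml(g, str(path))
    elif fmt == "dot":
        lines = ["graph haplotype_network {"]
        for n, d in net.graph.nodes(data=True):
            shape = "point" if d["inferred"] else "ellipse"
            lines.append(f'  "{n}" [shape={shape}, frequency="{d["frequency"]}"];')
        for u, v, d in net.graph.edges(data=True):
            label = ",".join(map(str, d["characters"]))
            lines.append(f'  "{u}" -- "{v}" [label="{label}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def annotate_lineages(net: MedianNetwork, lineage_of: dict[str, str]) -> None:
    """Attach a lineage attribute to each observed node (from haplotype names)."""
    for n, d in net.graph.nodes(data=True):
        lineages = sorted({lineage_of[h] for h in d["labels"] if h in lineage_of})
        d["lineage"] = "/".join(lineages)


def lineage_clusters(net: MedianNetwork, lineage_of: dict[str, str]) -> dict:
    """Per-lineage connectivity after removing other lineages' observed nodes.

    Median (inferred) nodes are retained.  Also flags characters appearing
    on more than one edge — the signature of homoplasy across the network.
    """
    report: dict[str, object] = {"lineages": {}, "homoplastic_characters": []}
    lineages = sorted(set(lineage_of.values()))
    for lineage in lineages:
        own_nodes = {net.observed[h] for h, lin in lineage_of.items()
                     if lin == lineage and h in net.observed}
        other_nodes = {net.observed[h] for h, lin in lineage_of.items()
                       if lin != lineage and h in net.observed} - own_nodes
        keep = set(net.graph.nodes) - other_nodes
        sub = net.graph.subgraph(keep)
        connected = (
            len(own_nodes) <= 1
            or any(own_nodes <= comp for comp in nx.connected_components(sub))
        )
        report["lineages"][lineage] = {
            "haplotype_nodes": sorted(own_nodes),
            "connected": bool(connected),
        }
    char_edges: dict[str, int] = {}
    for _u, _v, d in net.graph.edges(data=True):
        for c in d["characters"]:
            char_edges[c] = char_edges.get(c, 0) + 1
    report["homoplastic_characters"] = sorted(
        c for c, k in char_edges.items() if k > 1
    )
    return report
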