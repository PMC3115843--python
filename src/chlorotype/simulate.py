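"""Synthetic plastome and population-genotype simulation with known truth.

Every downstream stage of the package (scanning, typing, haplotype calling,
networks, trees) is validated against data generated here, where the planted
events are known exactly.

Two generators are provided:

* :func:`build_root_genome` + :func:`evolve_genomes` — a plastome-like root
  sequence with planted microsatellite (SSR) tracts, evolved along a known
  genealogy under per-site substitutions, single-step SSR mutations and
  indel events (7-12 bp motif duplications, other short indels, and long
  deletions at designated sites, emulating the 225/342-bp diagnostic
  deletions of olive cpDNA lineages).  Output is a gapped multiple alignment
  plus a truth table of every event.
* :func:`genotype_population` — per-individual multilocus genotype tables
  drawn from specified haplotype frequencies, with missing data and ±1 bp
  fragment-sizing noise, emulating a fragment-analysis genotyping run.

Randomness: a single integer seed fans out through ``numpy`` SeedSequence
spawning, in documented order: stream 0 = root sequence, stream 1 = branch
events (pre-order traversal), stream 2 = population sampling, stream 3 =
noise/missingness.

Mutation events are globally non-overlapping (rejection sampling): an event
whose footprint touches a previously used range, a planted SSR tract (unless
it is that tract's own step mutation) or a reserved long-deletion site is
re-drawn.  This keeps the truth-to-alignment mapping unambiguous, at the
price of mildly repelling events at high rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .alignment import GeneInterval, MultiAlignment

ALPHABET = np.array(list("ACGT"))

MOTIF_DUPLICATION = "motif_duplication"
OTHER_SHORT = "other_short"
LONG_DELETION = "long_deletion"


# ---------------------------------------------------------------------------
# specifications
# ---------------------------------------------------------------------------

@dataclass
class RootGenomeSpec:
    """Blueprint for the root (reference-like) genome.

    Positions are 1-based.  SSR loci are (position, motif, repeat_count);
    the tract occupies ``position .. position + len(motif)*count - 1``.
    """

    length: int
    ssr_loci: list[tuple[int, str, int]] = field(default_factory=list)
    gene_intervals: list[tuple[int, int, str, str]] = field(default_factory=list)
    long_indel_sites: list[tuple[int, int]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        ranges = []
        for pos, motif, count in self.ssr_loci:
            if not 1 <= len(motif) <= 6:
                raise ValueError(f"motif length must be 1..6: {motif!r}")
            end = pos + len(motif) * count - 1
            if pos < 1 or end > self.length:
                raise ValueError(f"SSR at {pos} exceeds genome bounds")
            ranges.append((pos, end))
        ranges.sort()
        for (s1, e1), (s2, _) in zip(ranges, ranges[1:]):
            if s2 <= e1:
                raise ValueError(f"overlapping SSR placements at {s1} and {s2}")
        for start, end, _strand, name in self.gene_intervals:
            if start < 1 or end > self.length or start > end:
                raise ValueError(f"gene interval {name} out of bounds")
        for pos, ln in self.long_indel_sites:
            if pos < 1 or pos + ln - 1 > self.length:
                raise ValueError(f"long indel site at {pos} out of bounds")


@dataclass
class MutationModel:
    """Per-branch-length-unit mutation rates and the indel length mixture."""

    sub_rate: float = 1e-3        # expected substitutions per site per unit
    ssr_step_rate: float = 0.2    # expected ±1-repeat events per locus per unit
    indel_rate: float = 0.5       # expected indel events per genome per unit
    indel_length_law: dict[str, float] = field(
        default_factory=lambda: {
            MOTIF_DUPLICATION: 0.4,
            OTHER_SHORT: 0.4,
            LONG_DELETION: 0.2,
        }
    )

    def __post_init__(self) -> None:
        if min(self.sub_rate, self.ssr_step_rate, self.indel_rate) < 0:
            raise ValueError("rates must be nonnegative")
        total = sum(self.indel_length_law.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("indel mixture weights must sum to 1")


class SimGenealogy:
    """A rooted genealogy with branch lengths, parsed from Newick."""

    def __init__(self, newick: str):
        self.tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=False
        )
        labels = [lf.taxon.label for lf in self.tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")
        self.leaf_labels = labels
        # stable internal-node labels for reproducible truth tables
        counter = 0
        for node in self.tree.preorder_node_iter():
            if node.taxon is None and not node.label:
                counter += 1
                node.label = f"n{counter}"

    def preorder_branches(self):
        """(node, parent, branch_length) for every non-root node, pre-order."""
        for node in self.tree.preorder_node_iter():
            if node.parent_node is None:
                continue
            bl = node.edge.length if node.edge.length is not None else 0.0
            yield node, node.parent_node, float(bl)

    @staticmethod
    def node_label(node) -> str:
        return node.taxon.label if node.taxon is not None else node.label


@dataclass
class TruthEvent:
    branch: str          # label of the child node of the branch
    type: str            # substitution | ssr_step | indel
    ref_position: int    # 1-based on the root genome
    detail: dict


@dataclass
class TruthTable:
    events: list[TruthEvent] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"branch": e.branch, "type": e.type,
                 "ref_position": e.ref_position, **e.detail}
                for e in self.events
            ]
        )

    def of_type(self, kind: str) -> list[TruthEvent]:
        return [e for e in self.events if e.type == kind]


@dataclass
class PopulationSpec:
    """Populations with haplotype frequencies plus noise/missingness knobs."""

    populations: list[tuple[str, int, dict[str, float]]]
    missing_rate: float = 0.0
    size_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, size, freqs in self.populations:
            if size < 1:
                raise ValueError(f"population {name}: size must be >= 1")
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError(f"population {name}: frequencies must sum to 1")


# ---------------------------------------------------------------------------
# root genome
# ---------------------------------------------------------------------------

def build_root_genome(spec: RootGenomeSpec) -> tuple[str, dict]:
    """Seeded random genome with SSR motifs planted verbatim.

    Returns the sequence and an annotation dict with the planted SSR tracts,
    gene intervals (as :class:`GeneInterval`) and reserved long-indel sites.
    Accidental background tracts that would meet the default detection
    thresholds are broken by a single base change, so planted tracts are the
    only ones present.
    """
    from .scan import DEFAULT_SSR_THRESHOLDS, detect_ssr

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[0])
    seq = rng.choice(ALPHABET, size=spec.length)
    planted_ranges = []
    for pos, motif, count in spec.ssr_loci:
        tract = np.array(list(motif * count))
        seq[pos - 1:pos - 1 + len(tract)] = tract
        planted_ranges.append((pos, pos + len(tract) - 1))
        # pin the flanking bases so the tract cannot extend by chance:
        # a left flank equal to the motif's last base (or a right flank
        # equal to its first) would lengthen the detected repeat
        if pos >= 2 and seq[pos - 2] == motif[-1]:
            seq[pos - 2] = rng.choice([b for b in "ACGT" if b != motif[-1]])
        end = pos - 1 + len(tract)
        if end < spec.length and seq[end] == motif[0]:
            seq[end] = rng.choice([b for b in "ACGT" if b != motif[0]])

    # break accidental tracts outside the planted ones
    for _ in range(20):
        dirty = False
        for ann in detect_ssr("".join(seq), DEFAULT_SSR_THRESHOLDS):
            span = (ann.ref_start, ann.ref_end)
            if any(s <= span[1] and span[0] <= e for s, e in planted_ranges):
                continue
            mid = (ann.ref_start + ann.ref_end) // 2
            current = seq[mid - 1]
            seq[mid - 1] = rng.choice([b for b in "ACGT" if b != current])
            dirty = True
        if not dirty:
            break

    genes = [GeneInterval(s, e, strand, name) for s, e, strand, name in spec.gene_intervals]
    annotation = {
        "ssr_loci": list(spec.ssr_loci),
        "genes": genes,
        "long_indel_sites": list(spec.long_indel_sites),
    }
    return "".join(seq), annotation


# ---------------------------------------------------------------------------
# evolution along the genealogy
# ---------------------------------------------------------------------------

class _Reserved:
    """Global registry of 1-based ranges no new event may touch."""

    def __init__(self):
        self.ranges: list[tuple[int, int]] = []

    def overlaps(self, start: int, end: int) -> bool:
        return any(s <= end and start <= e for s, e in self.ranges)

    def add(self, start: int, end: int) -> None:
        self.ranges.append((start, end))


def evolve_genomes(
    root: str,
    annotation: dict,
    tree: SimGenealogy,
    model: MutationModel,
    seed: int = 0,
) -> tuple[MultiAlignment, TruthTable]:
    """Evolve the root down the genealogy and project a gapped alignment.

    Each genome is represented as one cell per root position; substitutions
    replace a cell's base, deletions empty cells, insertions append to the
    anchoring cell.  Alignment columns are emitted per root position, padded
    to the widest cell, so planted events project to recoverable column
    ranges.  The root itself is included as taxon ``root`` and is the
    alignment reference.
    """
    length = len(root)
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(4)[1])
    reserved = _Reserved()
    ssr_loci = annotation.get("ssr_loci", [])
    long_sites = list(annotation.get("long_indel_sites", []))
    for pos, motif, count in ssr_loci:
        reserved.add(pos - 1, pos + len(motif) * count)  # tract plus 1-bp buffer
    for pos, ln in long_sites:
        reserved.add(pos, pos + ln - 1)
    ssr_available = {i for i in range(len(ssr_loci))}
    long_available = set(range(len(long_sites)))

    truth = TruthTable()
    root_cells = list(root)
    genomes: dict[str, list[str]] = {}

    node_cells = {id(tree.tree.seed_node): root_cells}
    for node, parent, bl in tree.preorder_branches():
        cells = list(node_cells[id(parent)])
        label = SimGenealogy.node_label(node)
        _mutate_branch(
            cells, label, bl, model, rng, reserved,
            ssr_loci, ssr_available, long_sites, long_available, truth, length,
        )
        node_cells[id(node)] = cells
        if node.is_leaf():
            genomes[node.taxon.label] = cells

    taxa = ["root"] + tree.leaf_labels
    all_cells = [root_cells] + [genomes[t] for t in tree.leaf_labels]
    widths = [max(len(c[i]) for c in all_cells) for i in range(length)]
    rows = [
        "".join(c[i].ljust(widths[i], "-") for i in range(length))
        for c in all_cells
    ]
    aln = MultiAlignment(taxa, rows, reference="root")
    return aln, truth


def _mutate_branch(
    cells, label, bl, model, rng, reserved,
    ssr_loci, ssr_available, long_sites, long_available, truth, length,
):
    # substitutions
    n_sub = rng.poisson(model.sub_rate * length * bl)
    for _ in range(n_sub):
        for _try in range(200):
            pos = int(rng.integers(1, length + 1))
            if not reserved.overlaps(pos, pos):
                break
        else:
            continue
        old = cells[pos - 1][0] if cells[pos - 1] else None
        if old is None:
            continue
        new = str(rng.choice([b for b in "ACGT" if b != old]))
        cells[pos - 1] = new + cells[pos - 1][1:]
        reserved.add(pos, pos)
        truth.events.append(
            TruthEvent(label, "substitution", pos, {"from": old, "to": new})
        )

    # single-step SSR mutations (at most one event per locus, globally)
    for locus_i in sorted(ssr_available):
        if rng.poisson(model.ssr_step_rate * bl) == 0:
            continue
        pos, motif, count = ssr_loci[locus_i]
        k = len(motif)
        step = int(rng.choice([-1, 1])) if count > 1 else 1
        tract_end = pos - 1 + k * count  # 0-based exclusive
        if step == 1:
            cells[tract_end - 1] = cells[tract_end - 1] + motif
        else:
            for j in range(tract_end - k, tract_end):
                cells[j] = ""
        ssr_available.discard(locus_i)
        truth.events.append(
            TruthEvent(
                label, "ssr_step", pos,
                {"motif": motif, "delta": step, "root_count": count},
            )
        )

    # indels
    n_indel = rng.poisson(model.indel_rate * bl)
    classes = list(model.indel_length_law)
    weights = np.array([model.indel_length_law[c] for c in classes])
    for _ in range(n_indel):
        kind = str(rng.choice(classes, p=weights / weights.sum()))
        if kind == LONG_DELETION:
            if not long_available:
                continue
            site_i = sorted(long_available)[int(rng.integers(len(long_available)))]
            long_available.discard(site_i)
            pos, ln = long_sites[site_i]
            for j in range(pos - 1, pos - 1 + ln):
                cells[j] = ""
            truth.events.append(
                TruthEvent(label, "indel", pos, {"class": LONG_DELETION, "length": ln})
            )
            continue
        if kind == MOTIF_DUPLICATION:
            ln = int(rng.integers(7, 13))
        else:
            ln = int(rng.integers(1, 7))
        for _try in range(200):
            pos = int(rng.integers(ln + 1, length - ln))
            if not reserved.overlaps(pos - ln, pos + ln):
                break
        else:
            continue
        if kind == MOTIF_DUPLICATION:
            block = "".join(cells[pos - ln:pos])  # the ln bases ending at pos
            if len(block) != ln:
                continue
            cells[pos - 1] = cells[pos - 1] + block
            reserved.add(pos - ln, pos + 1)
            truth.events.append(
                TruthEvent(label, "indel", pos,
                           {"class": MOTIF_DUPLICATION, "length": ln})
            )
        else:
            for j in range(pos - 1, pos - 1 + ln):
                cells[j] = ""
            reserved.add(pos - 1, pos + ln)
            truth.events.append(
                TruthEvent(label, "indel", pos, {"class": OTHER_SHORT, "length": ln})
            )


# ---------------------------------------------------------------------------
# population genotypes
# ---------------------------------------------------------------------------

def genotype_population(
    catalog: dict[str, dict[str, object]],
    spec: PopulationSpec,
) -> tuple[pd.DataFrame, pd.Series]:
    """Draw individual genotype tables from haplotype frequencies.

    ``catalog`` maps haplotype name -> {locus id -> allele value (fragment
    size in bp, or a CAPS/indel state string)}.  Returns a wide table (one
    row per individual, one column per locus, plus a ``population`` column)
    and the truth assignment (individual -> source haplotype).

    Noise model: with probability ``size_noise`` a numeric cell is shifted
    by ±1 bp (pre-binning mis-sizing); with probability ``missing_rate`` a
    cell is set missing (``None``).
    """
    for _name, _size, freqs in spec.populations:
        unknown = set(freqs) - set(catalog)
        if unknown:
            raise KeyError(f"unknown haplotype name(s): {sorted(unknown)}")

    loci = sorted({locus for profile in catalog.values() for locus in profile})
    ss = np.random.SeedSequence(spec.seed).spawn(4)
    rng_pop = np.random.default_rng(ss[2])
    rng_noise = np.random.default_rng(ss[3])

    rows, truth_idx, truth_val = [], [], []
    for pop_name, size, freqs in spec.populations:
        names = sorted(freqs)
        probs = np.array([freqs[n] for n in names])
        draws = rng_pop.choice(names, size=size, p=probs / probs.sum())
        for i, hap in enumerate(draws):
            ind = f"{pop_name}_{i + 1:04d}"
            profile = catalog[hap]
            row: dict[str, object] = {"individual": ind, "population": pop_name}
            for locus in loci:
                value = profile.get(locus)
                if value is not None and spec.size_noise and isinstance(value, (int, float)):
                    if rng_noise.random() < spec.size_noise:
                        value = value + int(rng_noise.choice([-1, 1]))
                if spec.missing_rate and rng_noise.random() < spec.missing_rate:
                    value = None
                row[locus] = value
            rows.append(row)
            truth_idx.append(ind)
            truth_val.append(hap)

    table = pd.DataFrame(rows).set_index("individual")
    truth = pd.Series(truth_val, index=pd.Index(truth_idx, name="individual"),
                      name="haplotype")
    return table, truth
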