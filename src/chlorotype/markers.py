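"""The cpDNA marker typing system: locus definitions, allele binning and
multiplex panel validation/design.

The typing system models 62 length-polymorphism loci (51 with variable
microsatellite motifs) plus two CAPS loci.  Fragment-analysis loci carry a
fluorescent dye and an allele size range; panels of loci are pooled per dye
for co-electrophoresis, which requires size ranges within one dye to be
pairwise disjoint.  Long diagnostic deletions (loci 8 and 61, the 342-bp
and 225-bp deletions) are scored on gel as binary presence/absence; CAPS
loci are scored cut/uncut.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import olive_data

SSR = "ssr"
INDEL = "indel"
CAPS = "caps"
MIXED = "mixed"
KINDS = {SSR, INDEL, CAPS, MIXED}
DYES = {"HEX", "6-FAM", "NED", "none"}


@dataclass(frozen=True)
class MarkerLocus:
    """One typing locus.

    ``anchor`` ties a known fragment size (bp) to a known repeat count so
    fragment sizes convert to repeat counts; required for ssr/mixed loci.
    """

    id: object                     # integer 1..64 or "CAPS-XapI"/"CAPS-EcoRI"
    kind: str
    dye: str = "none"
    size_range: tuple[int, int] | None = None
    motif: str | None = None
    anchor: tuple[int, int] | None = None   # (size bp, repeat count)
    gel_scored: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown locus kind {self.kind!r}")
        if self.dye not in DYES:
            raise ValueError(f"unknown dye {self.dye!r}")
        if self.size_range is not None and self.size_range[0] > self.size_range[1]:
            raise ValueError(f"locus {self.id}: inverted size range")
        if self.kind in (SSR, MIXED) and self.motif is None:
            raise ValueError(f"locus {self.id}: ssr/mixed loci need a motif")

    @property
    def is_length_locus(self) -> bool:
        return self.kind in (SSR, INDEL, MIXED) and not self.gel_scored


@dataclass(frozen=True)
class AlleleCall:
    locus: object
    allele: object                  # int bp, or binary state string
    repeat_count: int | None = None
    off_ladder: bool = False


class Panel:
    """An ordered collection of marker loci, keyed by id."""

    def __init__(self, loci: list[MarkerLocus] | None = None):
        self.loci: dict[object, MarkerLocus] = {}
        for locus in loci or ():
            self.add(locus)

    def add(self, locus: MarkerLocus) -> None:
        if locus.id in self.loci:
            raise ValueError(f"duplicate locus id {locus.id}")
        self.loci[locus.id] = locus

    def __getitem__(self, locus_id):
        return self.loci[locus_id]

    def __contains__(self, locus_id) -> bool:
        return locus_id in self.loci

    def __len__(self) -> int:
        return len(self.loci)

    def __iter__(self):
        return iter(self.loci.values())


# ---------------------------------------------------------------------------
# configuration I/O
# ---------------------------------------------------------------------------

def load_locus_definitions(config) -> Panel:
    """Build a panel from a YAML/JSON file path, or a parsed list of dicts.

    Each entry carries: id, kind, dye, size_range [min, max], motif, anchor
    [size, repeats], gel_scored, notes.  Unknown keys (e.g. primers) are
    kept as opaque notes.
    """
    if isinstance(config, (str, Path)):
        text = Path(config).read_text()
        config = (json.loads(text) if str(config).endswith(".json")
                  else yaml.safe_load(text)) or []
    panel = Panel()
    for entry in config:
        extra = {k: v for k, v in entry.items()
                 if k not in {"id", "kind", "dye", "size_range", "motif",
                              "anchor", "gel_scored", "notes"}}
        panel.add(
            MarkerLocus(
                id=entry["id"],
                kind=entry.get("kind", SSR),
                dye=entry.get("dye", "none"),
                size_range=tuple(entry["size_range"]) if entry.get("size_range") else None,
                motif=entry.get("motif"),
                anchor=tuple(entry["anchor"]) if entry.get("anchor") else None,
                gel_scored=bool(entry.get("gel_scored", False)),
                notes=entry.get("notes", "") + (f" {extra}" if extra else ""),
            )
        )
    return panel


def default_panel() -> Panel:
    """The packaged default panel: the six published multiplexes (35 loci),
    the separately amplified locus 10, the two gel-scored long-deletion
    loci and the two CAPS loci.  Loci absent from the published multiplex
    table are range-unknown."""
    panel = Panel()
    for group, entries in olive_data.MULTIPLEXES.items():
        dye = olive_data.MULTIPLEX_DYES[group]
        for lid, lo, hi in entries:
            kind = MIXED if lid in olive_data.MIXED_LOCI else SSR
            panel.add(
                MarkerLocus(
                    id=lid, kind=kind, dye=dye, size_range=(lo, hi),
                    motif="T", anchor=(lo, lo % 50 + 5),
                    notes=f"multiplex {group}",
                )
            )
    panel.add(MarkerLocus(id=10, kind=MIXED, dye="none", motif="T",
                          anchor=(100, 8), notes="amplified separately"))
    for lid, ln in olive_data.GEL_SCORED_LOCI.items():
        panel.add(MarkerLocus(id=lid, kind=INDEL, dye="none", gel_scored=True,
                              notes=f"{ln}-bp deletion, agarose gel"))
    panel.add(MarkerLocus(id=19, kind=SSR, dye="none", motif="T",
                          anchor=(120, 9), notes="stutter-suppression tag; run separately"))
    for name in olive_data.CAPS_LOCI:
        panel.add(MarkerLocus(id=name, kind=CAPS, notes="restriction assay"))
    return panel


# ---------------------------------------------------------------------------
# allele calling
# ---------------------------------------------------------------------------

def bin_fragment_sizes(raw_size: float, locus: MarkerLocus,
                       tolerance: float = 1.0) -> AlleleCall:
    """Round a raw fragment size to the nearest integer bp (half up).

    Calls farther than ``tolerance`` bp outside the locus size range are
    flagged off-ladder.
    """
    if not locus.is_length_locus:
        raise ValueError(f"locus {locus.id} is not a length locus")
    if raw_size < 0:
        raise ValueError("negative fragment size")
    import math
    allele = int(math.floor(raw_size + 0.5))  # ties round half up
    off = False
    if locus.size_range is not None:
        lo, hi = locus.size_range
        off = allele < lo - tolerance or allele > hi + tolerance
    repeat = None
    if locus.kind in (SSR, MIXED) and locus.anchor and not off:
        try:
            repeat = size_to_repeat_count(allele, locus)
        except ValueError:
            repeat = None
    return AlleleCall(locus=locus.id, allele=allele, repeat_count=repeat,
                      off_ladder=off)


def size_to_repeat_count(allele_size: int, locus: MarkerLocus) -> int:
    """Convert an integer fragment size to a motif repeat count via the anchor.

    count = anchor_count + (size - anchor_size) / motif_length; a
    non-integer quotient means the size is inconsistent with the motif.
    """
    if locus.anchor is None or locus.motif is None:
        raise ValueError(f"locus {locus.id} has no anchor/motif")
    anchor_size, anchor_count = locus.anchor
    step, rem = divmod(allele_size - anchor_size, len(locus.motif))
    if rem:
        raise ValueError(
            f"size {allele_size} inconsistent with motif {locus.motif!r} "
            f"at locus {locus.id}"
        )
    count = anchor_count + step
    if count < 0:
        raise ValueError(f"size {allele_size} implies negative repeat count")
    return count


def repeat_count_to_size(count: int, locus: MarkerLocus) -> int:
    anchor_size, anchor_count = locus.anchor
    return anchor_size + (count - anchor_count) * len(locus.motif)


# ---------------------------------------------------------------------------
# multiplex panels
# ---------------------------------------------------------------------------

@dataclass
class PanelAssignment:
    """Named multiplex groups plus a per-locus dye map."""

    groups: dict[str, list[object]] = field(default_factory=dict)
    dye_of: dict[object, str] = field(default_factory=dict)
    standalone: list[object] = field(default_factory=list)
    unassignable: list[object] = field(default_factory=list)

    def assigned_loci(self) -> list[object]:
        return [lid for group in self.groups.values() for lid in group]


def table3_assignment() -> PanelAssignment:
    """The published six-multiplex assignment."""
    assignment = PanelAssignment()
    for group, entries in olive_data.MULTIPLEXES.items():
        assignment.groups[group] = [lid for lid, _, _ in entries]
        for lid, _, _ in entries:
            assignment.dye_of[lid] = olive_data.MULTIPLEX_DYES[group]
    assignment.standalone = list(olive_data.SEPARATE_RAPID_LOCI)
    return assignment


def validate_panel(
    assignment: PanelAssignment,
    panel: Panel,
    max_group_size: int = 6,
) -> tuple[bool, list[str]]:
    """Check the within-dye non-overlap and group-size constraints.

    Within one dye, pooled across all co-electrophoresed groups, every pair
    of locus size ranges must be disjoint; every group must hold at most
    ``max_group_size`` loci.
    """
    violations: list[str] = []
    for name, loci in assignment.groups.items():
        if len(loci) > max_group_size:
            violations.append(f"group {name}: {len(loci)} loci > {max_group_size}")
        for lid in loci:
            if lid not in panel:
                raise KeyError(f"unknown locus id {lid}")
    by_dye: dict[str, list[object]] = {}
    for lid, dye in assignment.dye_of.items():
        by_dye.setdefault(dye, []).append(lid)
    for dye, loci in by_dye.items():
        ranged = [(panel[lid].size_range, lid) for lid in loci
                  if panel[lid].size_range is not None]
        ranged.sort()
        for ((lo1, hi1), a), ((lo2, hi2), b) in zip(ranged, ranged[1:]):
            if lo2 <= hi1:
                violations.append(
                    f"dye {dye}: loci {a} ({lo1}-{hi1}) and {b} ({lo2}-{hi2}) overlap"
                )
    return (not violations), violations


def design_multiplex(
    panel: Panel,
    dyes: list[str] = ("NED", "HEX", "6-FAM"),
    max_group_size: int = 6,
) -> PanelAssignment:
    """Greedy dye-aware multiplex design by interval-graph coloring.

    Loci are sorted by ascending size-range start and first-fit packed onto
    dye tracks (one track per dye, holding pairwise disjoint ranges); each
    track is then split into groups of at most ``max_group_size`` loci.
    Deterministic and always valid; loci fitting no dye track are reported
    unassignable.  Optimality is not claimed.
    """
    loci = [lc for lc in panel if lc.is_length_locus]
    assignment = PanelAssignment()
    # range-unknown loci cannot be pooled; they are run standalone
    assignment.standalone = [lc.id for lc in loci if lc.size_range is None]
    loci = [lc for lc in loci if lc.size_range is not None]
    loci.sort(key=lambda lc: (lc.size_range, str(lc.id)))

    tracks: dict[str, list[MarkerLocus]] = {d: [] for d in dyes}
    for lc in loci:
        placed = False
        for dye in dyes:
            track = tracks[dye]
            if all(lc.size_range[0] > other.size_range[1]
                   or lc.size_range[1] < other.size_range[0]
                   for other in track):
                track.append(lc)
                assignment.dye_of[lc.id] = dye
                placed = True
                break
        if not placed:
            assignment.unassignable.append(lc.id)

    for dye in dyes:
        track = sorted(tracks[dye], key=lambda lc: lc.size_range)
        for gi in range(0, len(track), max_group_size):
            chunk = track[gi:gi + max_group_size]
            name = f"{dye}-{gi // max_group_size + 1}"
            assignment.groups[name] = [lc.id for lc in chunk]
    return assignment


# ---------------------------------------------------------------------------
# replicate concordance
# ---------------------------------------------------------------------------

def replicate_concordance(
    table: pd.DataFrame,
    replicate_map: dict[str, list[str]],
) -> pd.DataFrame:
    """Per-locus fraction of replicate sets with identical calls.

    ``table`` is a wide genotype table (individuals × loci, plus optional
    ``population`` column); ``replicate_map`` maps an accession name to the
    individual ids of its repeated runs.
    """
    loci = [c for c in table.columns if c != "population"]
    if not replicate_map:
        return pd.DataFrame(columns=["locus", "concordant_sets", "total_sets",
                                     "concordance"])
    rows = []
    for locus in loci:
        concordant = total = 0
        for _accession, individuals in replicate_map.items():
            calls = [table.at[ind, locus] for ind in individuals]
            total += 1
            if len({repr(c) for c in calls}) == 1:
                concordant += 1
        rows.append({"locus": locus, "concordant_sets": concordant,
                     "total_sets": total,
                     "concordance": concordant / total})
    return pd.DataFrame(rows)
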