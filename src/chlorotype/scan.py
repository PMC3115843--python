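"""Polymorphism scanning of aligned plastid genomes.

Detects substitutions, indels and microsatellite (SSR) length variation in a
:class:`~chlorotype.alignment.MultiAlignment`, classifies indels into the
diagnostic classes used for plastome comparisons (SSR-step, 7-12 bp
repeated-motif duplication, other short, long), and computes divergence and
substitution-rate summaries.

Conventions
-----------
* Coordinates are 1-based on the designated reference taxon; insertions
  relative to the reference anchor to the preceding reference base.
* Columns containing any gap are excluded from substitution counting, both
  globally and pairwise: substitutions and indels are tallied separately.
* A site is parsimony-informative iff at least two states are each carried
  by at least two taxa.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alignment import GAP, GeneInterval, MultiAlignment

BASES = set("ACGT")

SSR_MOTIF = "ssr_motif"
REPEATED_MOTIF = "repeated_motif_7_12"
OTHER_SHORT = "other_short"
LONG = "long"

#: minimum repeat counts per motif length (1..6); configurable per call
DEFAULT_SSR_THRESHOLDS = {1: 8, 2: 5, 3: 4, 4: 4, 5: 4, 6: 4}


@dataclass
class VariantRecord:
    """One polymorphism with per-taxon states.

    ``states`` maps taxon -> base (substitutions), presence 0/1 (indels,
    1 = sequence present) or repeat count (SSR length variants); missing
    states are ``None``.
    """

    ref_position: int
    type: str  # "substitution" | "indel" | "ssr_length"
    states: dict[str, object]
    indel_class: str | None = None
    informative: bool = False
    gene_context: str | None = None
    length: int = 0  # indel length in bp; 0 for substitutions

    def distinct_states(self) -> list[object]:
        return sorted({s for s in self.states.values() if s is not None}, key=str)


@dataclass
class SsrAnnotation:
    """A microsatellite tract on the reference with per-taxon repeat counts."""

    motif: str
    ref_start: int
    ref_repeat_count: int
    repeat_counts: dict[str, int] = field(default_factory=dict)

    @property
    def ref_end(self) -> int:
        return self.ref_start + len(self.motif) * self.ref_repeat_count - 1


@dataclass(frozen=True)
class PairwiseDivergence:
    taxon_a: str
    taxon_b: str
    substitutions: int
    shared_length: int

    @property
    def proportion(self) -> float:
        return self.substitutions / self.shared_length if self.shared_length else 0.0


@dataclass(frozen=True)
class RateEstimate:
    substitutions: int
    genome_length: int
    divergence_time: float  # years

    @property
    def rate(self) -> float:
        """Substitutions per site per year: (subs/length)/T."""
        return (self.substitutions / self.genome_length) / self.divergence_time


# ---------------------------------------------------------------------------
# substitutions
# ---------------------------------------------------------------------------

def is_informative(states) -> bool:
    """Parsimony-informative: >=2 states each present in >=2 taxa."""
    counts: dict[object, int] = {}
    for s in states:
        if s is not None:
            counts[s] = counts.get(s, 0) + 1
    return sum(1 for c in counts.values() if c >= 2) >= 2


def scan_substitutions(aln: MultiAlignment) -> list[VariantRecord]:
    """One record per gap-free column holding >=2 distinct bases (N ignored)."""
    arr = np.array([list(r) for r in aln.rows])
    records = []
    for col in range(aln.ncols):
        column = arr[:, col]
        if GAP in column:
            continue
        bases = [b if b in BASES else None for b in column]
        distinct = {b for b in bases if b is not None}
        if len(distinct) < 2:
            continue
        states = dict(zip(aln.taxa, bases))
        records.append(
            VariantRecord(
                ref_position=aln.ref_position(col),
                type="substitution",
                states=states,
                informative=is_informative(bases),
            )
        )
    return records


def informative_sites(records) -> list[VariantRecord]:
    return [r for r in records if is_informative(list(r.states.values()))]


# ---------------------------------------------------------------------------
# indels
# ---------------------------------------------------------------------------

def scan_indels(aln: MultiAlignment) -> list[VariantRecord]:
    """Merge maximal runs of gap columns with identical taxon presence pattern.

    Each event carries its length in columns and per-taxon presence
    (1 = sequence present at the event, 0 = gapped).
    """
    events: list[VariantRecord] = []
    run_start = None
    run_pattern = None
    for col in range(aln.ncols + 1):
        pattern = None
        if col < aln.ncols:
            column = aln.column(col)
            if GAP in column:
                pattern = tuple(0 if c == GAP else 1 for c in column)
        if pattern != run_pattern:
            if run_pattern is not None:
                # event anchors to the reference base preceding the run
                events.append(
                    VariantRecord(
                        ref_position=aln.ref_position(run_start),
                        type="indel",
                        states=dict(zip(aln.taxa, run_pattern)),
                        length=col - run_start,
                    )
                )
            run_start = col if pattern is not None else None
            run_pattern = pattern
    return events


def classify_indel(
    event: VariantRecord,
    ssr_annotations: list[SsrAnnotation] | None = None,
    aln: MultiAlignment | None = None,
) -> str:
    """Assign an indel event to one of the four diagnostic classes.

    ``ssr_motif``
        the event lies inside an annotated SSR tract and its length is a
        multiple of the motif length;
    ``repeated_motif_7_12``
        length 7-12 bp and the indel block duplicates the immediately
        adjacent flanking sequence (one or two motif copies);
    ``long``
        length > 12 bp (e.g. the 225-bp and 342-bp diagnostic deletions);
    ``other_short``
        everything else up to 12 bp.
    """
    n = event.length
    for ssr in ssr_annotations or ():
        if ssr.ref_start <= event.ref_position <= ssr.ref_end and n % len(ssr.motif) == 0:
            return SSR_MOTIF
    if n > 12:
        return LONG
    if 7 <= n <= 12 and aln is not None and _duplicates_flank(event, aln):
        return REPEATED_MOTIF
    return OTHER_SHORT


def _duplicates_flank(event: VariantRecord, aln: MultiAlignment) -> bool:
    """True if the indel block equals the adjacent upstream or downstream block."""
    carrier = next(
        (t for t, present in event.states.items() if present == 1), None
    )
    if carrier is None:
        return False
    row = aln.row(carrier)
    # locate the gap run: deletions anchor at the first deleted reference
    # base (a gap column itself); insertions at the preceding reference base
    try:
        start = aln.column_of(event.ref_position) if event.ref_position else 0
    except IndexError:
        return False
    while start < aln.ncols and GAP not in aln.column(start):
        start += 1
    end = start + event.length
    if end > aln.ncols:
        return False
    block = row[start:end].replace(GAP, "")
    if len(block) != event.length:
        return False
    up = row[max(0, start - event.length):start].replace(GAP, "")
    down = row[end:end + event.length].replace(GAP, "")
    return block == up or block == down


# ---------------------------------------------------------------------------
# microsatellites
# ---------------------------------------------------------------------------

def _is_primitive(motif: str) -> bool:
    for k in range(1, len(motif)):
        if len(motif) % k == 0 and motif == motif[:k] * (len(motif) // k):
            return False
    return True


def detect_ssr(
    sequence_or_aln,
    thresholds: dict[int, int] | None = None,
) -> list[SsrAnnotation]:
    """Find maximal non-overlapping primitive-motif tracts meeting thresholds.

    Accepts a plain (ungapped) sequence or a :class:`MultiAlignment`; in the
    latter case tracts are detected on the reference and per-taxon repeat
    counts are read through the alignment.
    """
    thresholds = thresholds or DEFAULT_SSR_THRESHOLDS
    aln = sequence_or_aln if isinstance(sequence_or_aln, MultiAlignment) else None
    seq = aln.ungapped(aln.reference) if aln else str(sequence_or_aln).upper()

    found: list[SsrAnnotation] = []
    i, n = 0, len(seq)
    while i < n:
        best = None  # (tract_length, -motif_length, motif, count)
        for k in range(1, 7):
            if i + 2 * k > n:
                break
            motif = seq[i:i + k]
            if not _is_primitive(motif) or not set(motif) <= BASES:
                continue
            count = 1
            while seq[i + count * k:i + (count + 1) * k] == motif:
                count += 1
            if count >= thresholds.get(k, math.inf):
                cand = (count * k, -k, motif, count)
                if best is None or cand > best:
                    best = cand
        if best is None:
            i += 1
            continue
        _, _, motif, count = best
        ann = SsrAnnotation(motif=motif, ref_start=i + 1, ref_repeat_count=count)
        if aln:
            ann.repeat_counts = _read_repeat_counts(aln, ann)
        found.append(ann)
        i += count * len(motif)
    return found


def _read_repeat_counts(aln: MultiAlignment, ann: SsrAnnotation) -> dict[str, int]:
    """Per-taxon repeat counts of an SSR tract, read through the alignment.

    The tract's alignment window is widened to adjacent columns that are
    gapped in the reference (insertions), so expansions in other taxa are
    counted too.
    """
    k = len(ann.motif)
    c0 = aln.column_of(ann.ref_start)
    c1 = aln.column_of(ann.ref_end)
    ref_row = aln.row(aln.reference)
    while c0 > 0 and ref_row[c0 - 1] == GAP:
        c0 -= 1
    while c1 + 1 < aln.ncols and ref_row[c1 + 1] == GAP:
        c1 += 1
    counts = {}
    for taxon in aln.taxa:
        segment = aln.row(taxon)[c0:c1 + 1].replace(GAP, "")
        count = 0
        while segment[count * k:(count + 1) * k] == ann.motif:
            count += 1
        counts[taxon] = count
    return counts


def ssr_length_variants(aln: MultiAlignment, thresholds=None) -> list[VariantRecord]:
    """SSR tracts whose repeat count varies across taxa, as variant records."""
    out = []
    for ann in detect_ssr(aln, thresholds):
        if len(set(ann.repeat_counts.values())) > 1:
            out.append(
                VariantRecord(
                    ref_position=ann.ref_start,
                    type="ssr_length",
                    states=dict(ann.repeat_counts),
                    informative=is_informative(list(ann.repeat_counts.values())),
                )
            )
    return out


# ---------------------------------------------------------------------------
# divergence summaries
# ---------------------------------------------------------------------------

def pairwise_substitution_matrix(aln: MultiAlignment) -> pd.DataFrame:
    """Symmetric matrix of substitution counts over mutually ungapped columns."""
    if aln.ntaxa < 2:
        raise ValueError("need at least two taxa")
    arr = np.array([list(r) for r in aln.rows])
    mat = pd.DataFrame(0, index=aln.taxa, columns=aln.taxa, dtype=int)
    for (i, a), (j, b) in itertools.combinations(enumerate(aln.taxa), 2):
        ra, rb = arr[i], arr[j]
        ok = (ra != GAP) & (rb != GAP) & (ra != "N") & (rb != "N")
        count = int(np.sum(ok & (ra != rb)))
        mat.loc[a, b] = mat.loc[b, a] = count
    return mat


def pairwise_divergence(aln: MultiAlignment, a: str, b: str) -> PairwiseDivergence:
    ra = np.array(list(aln.row(a)))
    rb = np.array(list(aln.row(b)))
    ok = (ra != GAP) & (rb != GAP) & (ra != "N") & (rb != "N")
    return PairwiseDivergence(a, b, int(np.sum(ok & (ra != rb))), int(np.sum(ok)))


def percent_divergence(count: int, length: int) -> float:
    """Percentage divergence 100*count/length, reported at two decimals."""
    if length <= 0:
        raise ValueError("length must be positive")
    return round(100.0 * count / length, 2)


def substitution_rate(substitutions: int, genome_length: int, divergence_time: float) -> RateEstimate:
    """Per-site per-year substitution rate: (substitutions/length)/T.

    Reported downstream at two significant figures.  A zero substitution
    count is valid (rate 0); nonpositive length or time is not.
    """
    if genome_length <= 0 or divergence_time <= 0:
        raise ValueError("genome length and divergence time must be positive")
    if substitutions < 0:
        raise ValueError("substitution count must be nonnegative")
    return RateEstimate(substitutions, genome_length, divergence_time)


def round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


# ---------------------------------------------------------------------------
# coding effect
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def coding_effect(
    record: VariantRecord,
    annotations: list[GeneInterval],
    reference_sequence: str,
) -> str:
    """Classify a substitution as synonymous / non-synonymous / non-coding.

    Translates the containing codon in the annotated frame and strand for
    each observed state and compares the amino acids.
    """
    from Bio.Seq import Seq

    if record.type != "substitution":
        raise ValueError("coding_effect applies to substitutions")
    pos = record.ref_position
    gene = next((g for g in annotations if g.contains(pos)), None)
    if gene is None:
        return "non-coding"
    seq = reference_sequence.upper()
    states = {s for s in record.states.values() if s is not None}
    aminos = set()
    for state in states:
        mutated = seq[:pos - 1] + str(state) + seq[pos:]
        cds = mutated[gene.start - 1 + gene.frame:gene.end]
        if gene.strand == "-":
            cds = mutated[gene.start - 1:gene.end - gene.frame]
            cds = cds.translate(_COMPLEMENT)[::-1]
            offset = gene.end - gene.frame - pos
        else:
            offset = pos - (gene.start + gene.frame)
        codon_i = offset // 3
        codon = cds[3 * codon_i:3 * codon_i + 3]
        if len(codon) < 3:
            return "non-coding"
        aminos.add(str(Seq(codon).translate()))
    return "synonymous" if len(aminos) == 1 else "non-synonymous"


# ---------------------------------------------------------------------------
# column accounting
# ---------------------------------------------------------------------------

def classify_columns(aln: MultiAlignment) -> dict[str, int]:
    """Partition alignment columns into invariant / substitution / gap-involved.

    Every column lands in exactly one class; counts sum to the alignment
    length.  N-only variation counts as invariant.
    """
    counts = {"invariant": 0, "substitution": 0, "gap_involved": 0}
    for col in range(aln.ncols):
        column = aln.column(col)
        if GAP in column:
            counts["gap_involved"] += 1
        elif len({c for c in column if c in BASES}) >= 2:
            counts["substitution"] += 1
        else:
            counts["invariant"] += 1
    return counts


def variants_to_frame(records: list[VariantRecord], taxa: list[str]) -> pd.DataFrame:
    """Tabular (TSV-ready) view of variant records."""
    rows = []
    for r in records:
        row = {
            "ref_position": r.ref_position,
            "type": r.type,
            "class": r.indel_class or "",
            "length": r.length,
            "informative": r.informative,
            "gene_context": r.gene_context or "",
        }
        for t in taxa:
            row[t] = r.states.get(t)
        rows.append(row)
    return pd.DataFrame(rows)
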