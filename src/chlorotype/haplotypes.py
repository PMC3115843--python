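"""Multilocus cpDNA haplotype calling, frequency tables and diversity.

A haplotype (chlorotype) is a distinct multilocus profile over the
polymorphic locus set.  Haplotypes are named with a maternal-lineage prefix
(E1/E2/E3/M/... from lineage-diagnostic characters such as the 342-bp ycf1
deletion for E3) plus an ordinal assigned by descending frequency when the
catalog is built; ordinals are frozen once a catalog is published so added
samples never rename existing haplotypes.

Diversity is summarised by the discriminating power D = 1 - Σ p_i², the
probability that two individuals sampled at random carry different
haplotypes (plug-in frequencies, no small-sample correction).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

MISSING = None


def _profile_of(row: pd.Series, loci: list[str]) -> tuple:
    import numpy as np

    vals = []
    for locus in loci:
        v = row[locus]
        if not isinstance(v, (list, tuple)) and pd.isna(v):
            v = MISSING
        elif isinstance(v, np.generic):
            v = v.item()
        vals.append(v)
    return tuple(vals)


def _consistent(partial: tuple, complete: tuple) -> bool:
    return all(p is MISSING or p == c for p, c in zip(partial, complete))


@dataclass
class DiagnosticRule:
    """Lineage diagnostic: profiles with ``value`` at ``locus`` get ``prefix``."""

    prefix: str
    locus: str
    value: object


@dataclass
class HaplotypeCatalog:
    """Distinct complete profiles with stable, lineage-prefixed names."""

    loci: list[str]
    profiles: dict[str, tuple] = field(default_factory=dict)  # name -> profile
    diagnostics: list[DiagnosticRule] = field(default_factory=list)

    def name_of(self, profile: tuple) -> str | None:
        for name, known in self.profiles.items():
            if known == profile:
                return name
        return None

    def lineage_prefix(self, profile: tuple) -> str:
        for rule in self.diagnostics:
            if rule.locus in self.loci:
                i = self.loci.index(rule.locus)
                if profile[i] == rule.value:
                    return rule.prefix
        return "U"

    def add(self, profile: tuple) -> str:
        """Register a new complete profile and return its assigned name."""
        existing = self.name_of(profile)
        if existing:
            return existing
        prefix = self.lineage_prefix(profile)
        ordinals = [
            int(name.split(".", 1)[1]) for name in self.profiles
            if name.startswith(prefix + ".")
        ]
        name = f"{prefix}.{max(ordinals, default=0) + 1}"
        self.profiles[name] = profile
        return name

    # -- persistence (frozen ordinals survive re-runs) ----------------------

    def to_json(self, path) -> None:
        payload = {
            "loci": self.loci,
            "profiles": {k: list(v) for k, v in self.profiles.items()},
            "diagnostics": [
                {"prefix": r.prefix, "locus": r.locus, "value": r.value}
                for r in self.diagnostics
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "HaplotypeCatalog":
        payload = json.loads(Path(path).read_text())
        cat = cls(loci=payload["loci"])
        cat.profiles = {k: tuple(v) for k, v in payload["profiles"].items()}
        cat.diagnostics = [DiagnosticRule(**d) for d in payload["diagnostics"]]
        return cat


def assign_haplotypes(
    table: pd.DataFrame,
    catalog: HaplotypeCatalog | None = None,
    diagnostics: list[DiagnosticRule] | None = None,
    max_missing: float = 0.5,
) -> tuple[pd.Series, HaplotypeCatalog]:
    """Collapse a typed genotype table into named haplotypes.

    Individuals with identical complete profiles share a haplotype; new
    complete profiles are added to the catalog (ordinals by descending
    frequency among the new profiles).  An individual with missing calls is
    matched to an existing haplotype only if exactly one catalogued profile
    is consistent with its non-missing calls — otherwise it is left
    unassigned (``None``), as is any individual missing more than
    ``max_missing`` of its calls.
    """
    loci = [c for c in table.columns if c != "population"]
    if catalog is None:
        catalog = HaplotypeCatalog(loci=loci, diagnostics=diagnostics or [])
    elif catalog.loci != loci:
        raise ValueError("catalog locus order does not match table")

    profiles = {ind: _profile_of(table.loc[ind], loci) for ind in table.index}
    complete = {ind: p for ind, p in profiles.items() if MISSING not in p}

    # register new complete profiles by descending observed frequency
    counts: dict[tuple, int] = {}
    for p in complete.values():
        counts[p] = counts.get(p, 0) + 1
    for profile in sorted(counts, key=lambda p: (-counts[p], str(p))):
        catalog.add(profile)

    assignment: dict[str, str | None] = {}
    for ind, profile in profiles.items():
        n_missing = sum(1 for v in profile if v is MISSING)
        if n_missing == 0:
            assignment[ind] = catalog.name_of(profile)
            continue
        if loci and n_missing / len(loci) > max_missing:
            assignment[ind] = None
            continue
        matches = [
            name for name, known in catalog.profiles.items()
            if _consistent(profile, known)
        ]
        assignment[ind] = matches[0] if len(matches) == 1 else None
    return pd.Series(assignment, name="haplotype"), catalog


def name_haplotype(profile: tuple, catalog: HaplotypeCatalog) -> str:
    """The catalogued name for a profile, registering it if new."""
    return catalog.name_of(profile) or catalog.add(profile)


# ---------------------------------------------------------------------------
# frequencies, diversity, sharing
# ---------------------------------------------------------------------------

def haplotype_frequencies(
    assignment: pd.Series,
    groups: pd.Series,
    pooled: bool = False,
) -> pd.DataFrame:
    """Per-group haplotype counts and proportions.

    Returns a long DataFrame (group, haplotype, count, frequency); add a
    pooled column over all groups with ``pooled=True``.  Unassigned
    individuals are excluded; empty groups are dropped.
    """
    df = pd.DataFrame({"haplotype": assignment, "group": groups}).dropna()
    rows = []
    group_iter = list(df.groupby("group", sort=True))
    if pooled:
        group_iter.append(("pooled", df))
    for group, sub in group_iter:
        n = len(sub)
        for hap, count in sub["haplotype"].value_counts().sort_index().items():
            rows.append({"group": group, "haplotype": hap,
                         "count": int(count), "frequency": count / n, "n": n})
    return pd.DataFrame(rows)


def discriminating_power(frequencies, tol: float = 1e-6) -> float:
    """D = 1 - Σ p_i²: probability two random samples differ in haplotype.

    ``frequencies`` is a sequence of proportions summing to 1 (within
    ``tol``); plug-in estimator, no (n/(n-1)) correction.
    """
    p = [float(x) for x in frequencies]
    if any(x < 0 for x in p):
        raise ValueError("negative frequency")
    if abs(sum(p) - 1.0) > tol:
        raise ValueError(f"frequencies sum to {sum(p):.6f}, not 1")
    return 1.0 - sum(x * x for x in p)


def discriminating_power_from_counts(counts) -> float:
    total = sum(counts)
    if total <= 0:
        raise ValueError("empty sample")
    return discriminating_power([c / total for c in counts])


def diversity_report(
    assignment: pd.Series,
    groups: pd.Series,
) -> pd.DataFrame:
    """Per-group D plus a pooled D computed from pooled counts."""
    df = pd.DataFrame({"haplotype": assignment, "group": groups}).dropna()
    rows = []
    for group, sub in list(df.groupby("group", sort=True)) + [("pooled", df)]:
        counts = sub["haplotype"].value_counts()
        rows.append({
            "group": group, "n": len(sub), "haplotypes": len(counts),
            "D": round(discriminating_power_from_counts(counts.tolist()), 2),
        })
    return pd.DataFrame(rows)


def sharing_summary(
    freq_table: pd.DataFrame,
    partition: dict[str, list[str]],
) -> dict[str, int]:
    """Haplotype sharing between two sides of a group partition.

    ``partition`` maps side name (e.g. 'cultivated', 'wild') to its groups.
    Returns total/unique/shared counts plus the per-side haplotype counts.
    """
    if len(partition) != 2:
        raise ValueError("partition must have exactly two sides")
    covered = {g for groups in partition.values() for g in groups}
    present = set(freq_table["group"].unique()) - {"pooled"}
    if not present <= covered:
        raise ValueError(f"groups not covered by partition: {present - covered}")
    (side_a, groups_a), (side_b, groups_b) = partition.items()
    haps_a = set(freq_table[freq_table["group"].isin(groups_a)]["haplotype"])
    haps_b = set(freq_table[freq_table["group"].isin(groups_b)]["haplotype"])
    return {
        "total": len(haps_a | haps_b),
        side_a: len(haps_a),
        side_b: len(haps_b),
        "shared": len(haps_a & haps_b),
        f"unique_{side_a}": len(haps_a - haps_b),
        f"unique_{side_b}": len(haps_b - haps_a),
    }
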