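"""Reference datasets from the Mediterranean olive cpDNA survey.

Bundled as package data so analyses and the reproduction scripts can run
self-contained:

* ``INFORMATIVE_SITES`` / ``INFORMATIVE_SITE_MATRIX`` — the nine
  parsimony-informative nucleotide sites of the Mediterranean/North-African
  clade (Cp-II), across the seven Olea europaea plastomes plus the
  O. woodiana outgroup, with positions on the 'Manzanilla de Sevilla'
  sequence.
* ``HAPLOTYPE_FREQUENCIES`` — published haplotype frequencies (percent) for
  186 cultivars and five oleaster (wild olive) populations totalling 129
  individuals.
* ``MULTIPLEXES`` — the six published multiplex PCR groups (35 loci with
  dye and allele size range); locus 10 is amplified separately and joins
  them for the recommended 36-locus rapid-characterisation set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# nine informative nucleotide sites (clade Cp-II) — positions are 1-based bp
# on the 'Manzanilla de Sevilla' plastome; gene context where annotated
# ---------------------------------------------------------------------------

INFORMATIVE_SITES = [9081, 31283, 48091, 51579, 52165, 67653, 83304, 112753, 122532]

INFORMATIVE_SITE_GENES = {51579: "psbG", 52165: "ndhC", 83304: "rpl14", 112753: "ndhF"}

#: taxon -> states at INFORMATIVE_SITES (same order)
INFORMATIVE_SITE_MATRIX: dict[str, str] = {
    "O_woodiana":            "CTCATTGAG",
    "Maui_1":                "CTCAGTGCG",
    "Almhiwit_5.1":          "CGCATTGCG",
    "Guangzhou_1":           "CTCATTTCG",
    "Gue_de_Constantine_20": "TTAATTGCG",
    "Imouzzer_S1":           "CTACTGGCT",
    "Haut_Atlas":            "TTACTGTAG",
    "Manzanilla_de_Sevilla": "TGCCGGTAT",
}

#: divergence summaries printed for the complete plastomes
GENOME_LENGTH_MIN = 155_531   # bp, lineage C2 (Almhiwit 5.1)
GENOME_LENGTH_MAX = 155_896   # bp, lineage M (Imouzzer S1)
MAX_INTRASPECIFIC_SUBSTITUTIONS = 106
TOTAL_INTRASPECIFIC_SUBSTITUTIONS = 218
OUTGROUP_SUBSTITUTIONS = (417, 432)
DIVERGENCE_TIME_MY = (14, 22)  # million years, Olea vs Ligustroides split

# ---------------------------------------------------------------------------
# haplotype frequency table (percent); '-' entries are 0
# ---------------------------------------------------------------------------

_HAPLOTYPES = [
    "E1.1", "E1.2", "E1.3", "E1.4", "E1.5", "E1.6", "E1.7", "E1.8", "E1.9",
    "L1.1",
    "E2.1", "E2.2", "E2.3", "E2.4", "E2.5", "E2.6", "E2.7", "E2.8",
    "E3.1", "E3.2",
]

#: group -> {haplotype: percent}; cultivars n=186, oleaster populations n=129 total
HAPLOTYPE_FREQUENCIES: dict[str, dict[str, float]] = {
    "Cultivars": {
        "E1.1": 77.0, "E1.2": 7.0, "E1.3": 1.1, "L1.1": 0.5,
        "E2.1": 3.2, "E2.2": 1.1, "E2.3": 0.5, "E2.4": 2.1,
        "E2.5": 0.5, "E2.6": 0.5, "E3.1": 1.1, "E3.2": 5.3,
    },
    "Bin_El_Ouidane": {
        "E1.1": 42.9, "E2.1": 4.8, "E2.3": 4.8, "E2.5": 14.3,
        "E2.6": 23.8, "E2.8": 14.3,
    },
    "Minorca": {"E2.2": 52.2, "E2.3": 4.3, "E3.1": 26.1, "E3.2": 17.4},
    "Pugnochiuso": {"E1.1": 4.5, "E2.1": 68.2, "E2.2": 27.3},
    "Gialova": {
        "E1.1": 21.6, "E1.6": 8.1, "E1.7": 10.8, "E1.8": 13.5,
        "E1.9": 13.5, "E2.7": 32.4,
    },
    "Rajo": {"E1.1": 46.2, "E1.2": 26.9, "E1.3": 3.8, "E1.4": 19.2, "E1.5": 3.8},
}

CULTIVAR_SAMPLE_SIZE = 186
OLEASTER_SAMPLE_SIZE = 129
OLEASTER_GROUPS = ["Bin_El_Ouidane", "Minorca", "Pugnochiuso", "Gialova", "Rajo"]


def frequency_frame() -> pd.DataFrame:
    """The haplotype × group percentage table as a DataFrame (0 for absent)."""
    df = pd.DataFrame(HAPLOTYPE_FREQUENCIES).reindex(_HAPLOTYPES).fillna(0.0)
    df.index.name = "haplotype"
    return df


def reconstruct_counts(
    percentages: dict[str, float],
    max_n: int = 400,
    known_n: int | None = None,
) -> tuple[dict[str, int], int]:
    """Recover integer haplotype counts from printed percentages.

    Finds the smallest sample size n (or validates ``known_n``) under which
    every percentage is within printing precision of an integer count.  If
    the rounded counts do not sum to n — which happens when the printed
    column contains a typo — the count with the largest rounding discrepancy
    is adjusted by one (ties broken toward the last haplotype in column
    order), and the adjustment is reported via the returned counts simply
    not matching ``round(p*n/100)`` for that entry.
    """
    haps = list(percentages)
    pcts = np.array([percentages[h] for h in haps], dtype=float)

    def near_integer(n: int) -> bool:
        exact = pcts * n / 100.0
        tol = max(0.05 * n / 100.0, 0.011) + 1e-9
        return bool(np.all(np.abs(exact - np.round(exact)) <= tol))

    candidates = [known_n] if known_n else [
        n for n in range(max(2, len(haps)), max_n + 1) if near_integer(n)
    ]
    if not candidates:
        raise ValueError("no sample size is consistent with the percentages")
    exact_ns = [n for n in candidates
                if int(np.round(pcts * n / 100.0).sum()) == n]
    n = exact_ns[0] if exact_ns else candidates[0]
    counts = np.round(pcts * n / 100.0).astype(int)
    # repair a single-entry rounding/typo inconsistency
    while counts.sum() != n:
        step = 1 if counts.sum() < n else -1
        exact = pcts * n / 100.0
        dev = (exact - counts) * step
        idx = int(np.flatnonzero(dev == dev.max())[-1])
        counts[idx] += step
    return dict(zip(haps, (int(c) for c in counts))), n


def oleaster_counts() -> dict[str, dict[str, int]]:
    """Integer haplotype counts for the five oleaster populations.

    Per-population sample sizes are reconstructed so that the five totals
    sum to the published 129 wild individuals.
    """
    out: dict[str, dict[str, int]] = {}
    total = 0
    for group in OLEASTER_GROUPS:
        counts, n = reconstruct_counts(HAPLOTYPE_FREQUENCIES[group])
        out[group] = counts
        total += n
    if total != OLEASTER_SAMPLE_SIZE:
        raise AssertionError(
            f"reconstructed oleaster total {total} != {OLEASTER_SAMPLE_SIZE}"
        )
    return out


def cultivar_counts() -> dict[str, int]:
    counts, n = reconstruct_counts(
        HAPLOTYPE_FREQUENCIES["Cultivars"], known_n=CULTIVAR_SAMPLE_SIZE
    )
    assert n == CULTIVAR_SAMPLE_SIZE
    return counts


# ---------------------------------------------------------------------------
# multiplex panels: group -> dye, [(locus id, size min, size max)]
# ---------------------------------------------------------------------------

MULTIPLEX_DYES = {"A-1": "NED", "A-2": "NED", "B-1": "HEX", "B-2": "HEX",
                  "C-1": "6-FAM", "C-2": "6-FAM"}

MULTIPLEXES: dict[str, list[tuple[int, int, int]]] = {
    "A-1": [(46, 110, 112), (1, 121, 124), (9, 135, 136), (51, 139, 146),
            (22, 158, 159), (41, 169, 171)],
    "A-2": [(17, 178, 179), (28, 182, 183), (56, 188, 190), (53, 203, 204),
            (50, 227, 228), (33, 235, 236)],
    "B-1": [(39, 105, 106), (27, 112, 113), (23, 120, 121), (11, 126, 136),
            (42, 137, 139), (2, 148, 150)],
    "B-2": [(48, 158, 159), (25, 174, 177), (36, 182, 183), (52, 191, 203),
            (58, 234, 236)],
    "C-1": [(21, 103, 104), (38, 109, 111), (31, 131, 133), (15, 137, 138),
            (47, 154, 157), (59, 164, 165)],
    "C-2": [(6, 173, 174), (49, 181, 182), (24, 187, 189), (29, 203, 204),
            (57, 224, 227), (54, 231, 239)],
}

#: locus 10 is amplified separately but joins the rapid-characterisation set
SEPARATE_RAPID_LOCI = [10]

#: loci scored on agarose gel as long-deletion presence/absence
GEL_SCORED_LOCI = {8: 342, 61: 225}  # locus -> diagnostic deletion length (bp)

#: loci combining an indel and a microsatellite motif (coded as two characters)
MIXED_LOCI = [10, 11, 54, 57]

CAPS_LOCI = ["CAPS-XapI", "CAPS-EcoRI"]


def rapid_set_loci() -> list[int]:
    """The recommended rapid-characterisation locus set (36 loci)."""
    loci = [lid for group in MULTIPLEXES.values() for lid, _, _ in group]
    return sorted(loci + SEPARATE_RAPID_LOCI)
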