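"""End-to-end orchestration: simulate → scan → type → haplotypes → network → tree.

A run is driven by a :class:`RunConfig` (YAML/JSON-loadable), executes the
enabled stages in dependency order, writes plain-text artifacts (FASTA,
GFF3, TSV, JSON, GraphML, Newick) into the output directory, and records a
manifest with a config hash and per-artifact SHA-256 checksums.  All
randomness flows from the config seeds, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import haplotypes as hap
from . import network as net
from . import parsimony as mp
from . import scan as gscan
from . import simulate as sim
from .alignment import MultiAlignment, write_gff3
from .markers import default_panel

log = logging.getLogger("chlorotype")

__version__ = "0.1.0"


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    outdir: str = "chlorotype_run"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "simulate", "scan", "type", "haplo", "network", "tree",
    ])
    # simulation
    genome_length: int = 5_000
    n_ssr: int = 6
    tree_newick: str = "((A:1,B:1):1,((C:1,D:1):1,(E:1,(F:1,G:1):1):1):1);"
    sub_rate: float = 2e-3
    ssr_step_rate: float = 0.3
    indel_rate: float = 0.6
    # population simulation
    catalog: dict = field(default_factory=dict)       # haplotype -> {locus: allele}
    populations: list = field(default_factory=list)   # [name, size, {hap: freq}]
    missing_rate: float = 0.0
    size_noise: float = 0.0
    # analysis options
    network_r: float = 2.0
    include_caps: bool = False
    bootstrap_replicates: int = 25

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        payload = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**payload)

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def default_synthetic_catalog() -> tuple[dict, list]:
    """A small olive-like haplotype catalog and population design.

    Three lineage-diagnostic structures mirror the real system: one lineage
    carries a long-deletion state at the gel-scored locus, one is separated
    by SSR steps, and one predominant haplotype dominates the 'cultivar'
    group, so that diversity contrasts resemble a crop/wild comparison.
    """
    catalog = {
        "E1.1": {"L1": 121, "L2": 148, "L3": 174, "L61": "absent"},
        "E1.2": {"L1": 122, "L2": 148, "L3": 174, "L61": "absent"},
        "E2.1": {"L1": 123, "L2": 149, "L3": 174, "L61": "absent"},
        "E3.1": {"L1": 121, "L2": 150, "L3": 175, "L61": "present"},
        "E3.2": {"L1": 122, "L2": 150, "L3": 175, "L61": "present"},
    }
    populations = [
        ("cultivars", 120, {"E1.1": 0.77, "E1.2": 0.08, "E2.1": 0.05,
                            "E3.1": 0.05, "E3.2": 0.05}),
        ("wild", 60, {"E1.1": 0.25, "E1.2": 0.2, "E2.1": 0.25,
                      "E3.1": 0.15, "E3.2": 0.15}),
    ]
    return catalog, populations


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages; returns the manifest dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    state: dict[str, object] = {}
    order = ["simulate", "scan", "type", "haplo", "network", "tree"]
    stages = [s for s in order if s in config.stages]

    for stage in stages:
        log.info("stage %s: start", stage)
        try:
            _STAGES[stage](config, outdir, artifacts, state)
        except StageError:
            raise
        except Exception as exc:  # re-tag with the failing stage
            raise StageError(stage, str(exc)) from exc
        log.info("stage %s: done", stage)

    manifest = {
        "tool": "chlorotype",
        "version": __version__,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "stages": stages,
        "artifacts": {name: _sha256(path) for name, path in sorted(artifacts.items())},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(config, outdir, artifacts, state):
    rng_positions = range(300, config.genome_length - 300,
                          max(1, (config.genome_length - 600) // max(1, config.n_ssr)))
    ssr_loci = [(pos, "T", 10) if i % 2 == 0 else (pos, "AT", 6)
                for i, pos in enumerate(list(rng_positions)[:config.n_ssr])]
    spec = sim.RootGenomeSpec(
        length=config.genome_length,
        ssr_loci=ssr_loci,
        gene_intervals=[(config.genome_length // 2,
                         config.genome_length // 2 + 299, "+", "toyA")],
        long_indel_sites=[(config.genome_length - 500, 225)],
        seed=config.seed,
    )
    root, annotation = sim.build_root_genome(spec)
    tree = sim.SimGenealogy(config.tree_newick)
    model = sim.MutationModel(sub_rate=config.sub_rate,
                              ssr_step_rate=config.ssr_step_rate,
                              indel_rate=config.indel_rate)
    aln, truth = sim.evolve_genomes(root, annotation, tree, model, seed=config.seed)
    aln.to_fasta(outdir / "alignment.fasta")
    write_gff3(annotation["genes"], outdir / "annotation.gff3")
    truth.to_frame().to_csv(outdir / "truth_events.tsv", sep="\t", index=False)
    artifacts["alignment.fasta"] = outdir / "alignment.fasta"
    artifacts["annotation.gff3"] = outdir / "annotation.gff3"
    artifacts["truth_events.tsv"] = outdir / "truth_events.tsv"
    state["alignment"] = aln
    state["annotation"] = annotation

    catalog = config.catalog or default_synthetic_catalog()[0]
    populations = config.populations or default_synthetic_catalog()[1]
    pspec = sim.PopulationSpec(
        populations=[tuple(p) for p in populations],
        missing_rate=config.missing_rate,
        size_noise=config.size_noise,
        seed=config.seed,
    )
    table, truth_assign = sim.genotype_population(catalog, pspec)
    table.to_csv(outdir / "genotypes.tsv", sep="\t")
    truth_assign.to_csv(outdir / "genotype_truth.tsv", sep="\t")
    artifacts["genotypes.tsv"] = outdir / "genotypes.tsv"
    artifacts["genotype_truth.tsv"] = outdir / "genotype_truth.tsv"
    state["genotypes"] = table
    state["catalog_profiles"] = catalog


def _stage_scan(config, outdir, artifacts, state):
    aln = state.get("alignment")
    if aln is None:
        fasta = Path(config.outdir) / "alignment.fasta"
        if not fasta.exists():
            raise StageError("scan", "no alignment available (run simulate or provide one)")
        aln = MultiAlignment.from_fasta(fasta)
    subs = gscan.scan_substitutions(aln)
    indels = gscan.scan_indels(aln)
    ssrs = gscan.detect_ssr(aln)
    for ev in indels:
        ev.indel_class = gscan.classify_indel(ev, ssrs, aln)
    records = subs + indels + gscan.ssr_length_variants(aln)
    gscan.variants_to_frame(records, aln.taxa).to_csv(
        outdir / "variants.tsv", sep="\t", index=False)
    gscan.pairwise_substitution_matrix(aln).to_csv(
        outdir / "pairwise_substitutions.tsv", sep="\t")
    summary = {
        "taxa": aln.ntaxa,
        "columns": aln.ncols,
        "substitution_records": len(subs),
        "informative_substitutions": len(gscan.informative_sites(subs)),
        "indel_events": len(indels),
        "ssr_tracts": len(ssrs),
        "column_classes": gscan.classify_columns(aln),
    }
    (outdir / "scan_summary.json").write_text(json.dumps(summary, indent=1))
    for name in ("variants.tsv", "pairwise_substitutions.tsv", "scan_summary.json"):
        artifacts[name] = outdir / name
    state["variants"] = records


def _stage_type(config, outdir, artifacts, state):
    table = state.get("genotypes")
    if table is None:
        path = Path(config.outdir) / "genotypes.tsv"
        if not path.exists():
            raise StageError("type", "no genotype table available")
        table = pd.read_csv(path, sep="\t", index_col=0)
    catalog = state.get("catalog_profiles") or config.catalog
    if catalog:
        known = {locus for profile in catalog.values() for locus in profile}
        unknown = set(table.columns) - known - {"population"}
        if unknown:
            raise StageError("type", f"undefined locus id(s): {sorted(unknown)}")
    typed = table.copy()
    for col in typed.columns:
        if col == "population":
            continue
        typed[col] = [
            int(v + 0.5) if isinstance(v, (int, float)) and pd.notna(v) else v
            for v in typed[col]
        ]
    typed.to_csv(outdir / "typed_genotypes.tsv", sep="\t")
    artifacts["typed_genotypes.tsv"] = outdir / "typed_genotypes.tsv"
    state["typed"] = typed


def _stage_haplo(config, outdir, artifacts, state):
    typed = state.get("typed")
    if typed is None:
        raise StageError("haplo", "typing stage did not run")
    diagnostics = [hap.DiagnosticRule("E3", "L61", "present")]
    assignment, catalog = hap.assign_haplotypes(typed, diagnostics=diagnostics)
    assignment.to_csv(outdir / "haplotype_assignment.tsv", sep="\t")
    freqs = hap.haplotype_frequencies(assignment, typed["population"], pooled=True)
    freqs.to_csv(outdir / "haplotype_frequencies.tsv", sep="\t", index=False)
    report = hap.diversity_report(assignment, typed["population"])
    report.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
    catalog.to_json(outdir / "catalog.json")
    for name in ("haplotype_assignment.tsv", "haplotype_frequencies.tsv",
                 "diversity.tsv", "catalog.json"):
        artifacts[name] = outdir / name
    state["assignment"] = assignment
    state["hap_catalog"] = catalog


def _stage_network(config, outdir, artifacts, state):
    catalog = state.get("hap_catalog")
    if catalog is None:
        raise StageError("network", "haplotype stage did not run")
    panel = default_panel()
    profiles = {}
    for name, profile in catalog.profiles.items():
        profiles[name] = {
            locus: (1 if v == "present" else 0) if isinstance(v, str) else v
            for locus, v in zip(catalog.loci, profile)
            if locus != "population"
        }
    assignment = state.get("assignment")
    freqs = assignment.value_counts().to_dict() if assignment is not None else {}
    # synthetic loci are not in the published panel: code sizes as ordered
    # characters and string states as binary
    from .network import BINARY, ORDERED, CodedMatrix, binary_expand, reduced_median
    names = list(profiles)
    loci = sorted({l for p in profiles.values() for l in p})
    data = {}
    kinds = {}
    for locus in loci:
        vals = [profiles[n][locus] for n in names]
        data[str(locus)] = vals
        kinds[str(locus)] = BINARY if set(vals) <= {0, 1} else ORDERED
    matrix = CodedMatrix(pd.DataFrame(data, index=names), kinds,
                         {c: 1.0 for c in data}, frequencies=freqs)
    binary, weights, expansion = binary_expand(matrix)
    network = reduced_median(binary, weights, matrix.frequencies,
                             r=config.network_r, expansion=expansion)
    net.network_export(network, "graphml", outdir / "network.graphml")
    artifacts["network.graphml"] = outdir / "network.graphml"
    state["network"] = network


def _stage_tree(config, outdir, artifacts, state):
    aln = state.get("alignment")
    if aln is None:
        raise StageError("tree", "no alignment available")
    # the simulated root is an ancestor, not a tip: score the leaves only
    taxa = [t for t in aln.taxa if t != "root"]
    if not 3 <= len(taxa) <= 10:
        raise StageError("tree", f"exhaustive search needs 3..10 taxa, got {len(taxa)}")
    subs = gscan.scan_substitutions(aln)
    cols = [aln.column_of(r.ref_position) for r in subs]
    matrix = mp.CharacterMatrix(
        {t: "".join(aln.row(t)[c] for c in cols) for t in taxa}
    )
    result = mp.exhaustive_search(matrix)
    result.bootstrap_support = mp.bootstrap(
        matrix, replicates=config.bootstrap_replicates, seed=config.seed)
    (outdir / "tree.nwk").write_text(result.consensus_newick() + "\n")
    (outdir / "tree_summary.json").write_text(json.dumps({
        "best_score": result.best_score,
        "n_optimal": len(result.optimal),
        "n_topologies": result.n_topologies,
    }, indent=1))
    artifacts["tree.nwk"] = outdir / "tree.nwk"
    artifacts["tree_summary.json"] = outdir / "tree_summary.json"
    state["tree"] = result


_STAGES = {
    "simulate": _stage_simulate,
    "scan": _stage_scan,
    "type": _stage_type,
    "haplo": _stage_haplo,
    "network": _stage_network,
    "tree": _stage_tree,
}


# ---------------------------------------------------------------------------
# published-table reproduction
# ---------------------------------------------------------------------------

def reproduce_table2(outdir=None) -> pd.DataFrame:
    """Recompute the haplotype frequency/diversity table from bundled data.

    Reconstructs integer counts from the published percentage table,
    recomputes per-group frequencies and discriminating power D (cultivars
    and pooled oleasters), and optionally writes the TSV.
    """
    from . import olive_data

    rows = []
    cult = olive_data.cultivar_counts()
    n_cult = sum(cult.values())
    for hname, count in sorted(cult.items()):
        rows.append({"group": "Cultivars", "haplotype": hname, "count": count,
                     "frequency": count / n_cult})
    pooled: dict[str, int] = {}
    for group, counts in olive_data.oleaster_counts().items():
        n = sum(counts.values())
        for hname, count in sorted(counts.items()):
            rows.append({"group": group, "haplotype": hname, "count": count,
                         "frequency": count / n})
            pooled[hname] = pooled.get(hname, 0) + count
    n_pool = sum(pooled.values())
    for hname, count in sorted(pooled.items()):
        rows.append({"group": "Oleasters_pooled", "haplotype": hname,
                     "count": count, "frequency": count / n_pool})
    table = pd.DataFrame(rows)

    d_report = pd.DataFrame([
        {"group": "Cultivars", "n": n_cult,
         "D": round(hap.discriminating_power_from_counts(list(cult.values())), 2)},
        {"group": "Oleasters_pooled", "n": n_pool,
         "D": round(hap.discriminating_power_from_counts(list(pooled.values())), 2)},
    ])
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        table.to_csv(outdir / "table2_frequencies.tsv", sep="\t", index=False)
        d_report.to_csv(outdir / "table2_diversity.tsv", sep="\t", index=False)
    table.attrs["diversity"] = d_report
    return table
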