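"""End-to-end orchestration: simulate -> discover -> classify -> consensus
-> date -> httest, as one reproducible run.

Every output file carries a ``#`` header with the package version, seed and
the parameters in force, so a run is auditable from its artifacts alone.
Identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from ._sequtils import write_fasta
from . import element_discovery as ed
from . import motif_scan as ms
from .consensus_identity import align_copies, build_consensus
from .dating import RateTable, divergence_landscape
from .ht_inference import ht_compare, pairwise_distance_table, summarize_distances
from .synthetic_data import (
    SimulationConfig,
    plant_copies,
    simulate_host_gene,
    write_simulation,
)
from .tree import SpeciesTree

logger = logging.getLogger("telandscape")

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "validate_formats"]


class ValidationError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Parameters of a full pipeline run; defaults are the family-standard
    thresholds (identity 80%, coverage 40%, 2 kb flanks, 3 copies minimum
    for a consensus)."""

    newick: str = "((A:5,B:5):5,(C:5,D:5):5);"
    outdir: str = "telandscape_run"
    seed: int = 0
    min_identity: float = 80.0
    min_coverage: float = 40.0
    flank: int = 2000
    word_size: int = 11
    min_copies: int = 3
    lineage: str = "Actinopterygii"
    distance_method: str = "mcl"
    margin: float = 1.0
    min_split: float = 0.0
    bin_width_myr: float = 0.5
    gene_length: int = 1500
    gene_rate: float = 1e-8  # matches the default TE neutral rate, so vertical TE pairs track the gene
    stages: tuple[str, ...] = (
        "simulate", "discover", "classify", "consensus", "date", "httest"
    )
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    def validate(self) -> None:
        if not 0 <= self.min_identity <= 100:
            raise ValidationError("min_identity must lie in [0, 100]")
        if not 0 <= self.min_coverage <= 100:
            raise ValidationError("min_coverage must lie in [0, 100]")
        if self.flank < 0 or self.word_size < 4:
            raise ValidationError("flank must be >= 0 and word_size >= 4")
        if self.min_copies < 1:
            raise ValidationError("min_copies must be >= 1")
        if self.margin <= 0:
            raise ValidationError("margin must be > 0")
        unknown = set(self.stages) - {
            "simulate", "discover", "classify", "consensus", "date", "httest"
        }
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")


@dataclass
class RunReport:
    seed: int
    version: str
    stage_counts: dict[str, int]
    parameters: dict
    inconsistencies: list[str]


def _header(config: PipelineConfig) -> str:
    return (f"# telandscape v{__version__}; seed={config.seed}; "
            f"min_identity={config.min_identity}; min_coverage={config.min_coverage}; "
            f"flank={config.flank}; min_copies={config.min_copies}; "
            f"method={config.distance_method}; margin={config.margin}\n")


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run the requested stages in dependency order and write all outputs."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = SpeciesTree.from_newick(config.newick)
    sim_cfg = dataclasses.replace(config.sim, seed=config.seed)
    counts: dict[str, int] = {}
    inconsistencies: list[str] = []

    logger.info("stage simulate: %d species", len(tree.leaf_names))
    result = plant_copies(tree, sim_cfg)
    write_simulation(result, outdir / "sim")
    gene = simulate_host_gene(tree, config.gene_length, config.gene_rate,
                              kappa=sim_cfg.kappa, seed=config.seed + 1)
    write_fasta(outdir / "sim" / "host_gene.aln.fa", sorted(gene.items()))
    counts["simulate"] = len(result.truth)

    if "discover" not in config.stages:
        return RunReport(config.seed, __version__, counts,
                         _echo_params(config), inconsistencies)

    query = result.master.sequence
    anchor = ms.default_anchor()
    all_hits: dict[str, list[ed.Hit]] = {}
    copies_by_species: dict[str, list[ed.ElementCopy]] = {}
    bed_lines = []
    tsv_lines = []
    for species in tree.leaf_names:
        genome = result.genomes[species]
        hits = ed.homology_search(
            genome, query, config.min_identity, config.min_coverage,
            config.word_size, genome_id=species,
        )
        all_hits[species] = hits
        copies = [ed.annotate_copy(genome, h, anchor=anchor) for h in hits]
        copies_by_species[species] = copies
        for idx, (h, c) in enumerate(zip(hits, copies)):
            name = f"{species}_copy{idx+1}"
            bed_lines.append(
                f"{species}\t{h.start}\t{h.end}\t{name}\t"
                f"{int(round(h.identity * 10))}\t{h.strand}\n"
            )
            tir = c.tir_pair
            tsv_lines.append(
                f"{name}\t{species}\t{h.start}\t{h.end}\t{h.strand}\t"
                f"{h.identity:.2f}\t{h.coverage:.2f}\t"
                f"{tir.length if tir else 0}\t{tir.mismatches if tir else 0}\t"
                f"{c.tsd or '.'}\t{c.status}\n"
            )
    counts["discover"] = sum(len(h) for h in all_hits.values())
    counts["classify"] = sum(len(c) for c in copies_by_species.values())
    if counts["discover"] != counts["classify"]:
        inconsistencies.append("copies discovered != copies classified")
    with open(outdir / "elements.bed", "w") as fh:
        fh.write(_header(config))
        fh.writelines(bed_lines)
    with open(outdir / "elements.tsv", "w") as fh:
        fh.write(_header(config))
        fh.write("copy_id\tspecies\tstart\tend\tstrand\tidentity\tcoverage\t"
                 "tir_len\ttir_mismatches\ttsd\tstatus\n")
        fh.writelines(tsv_lines)

    if "consensus" not in config.stages:
        return RunReport(config.seed, __version__, counts,
                         _echo_params(config), inconsistencies)

    consensi: dict[str, str] = {}
    for species, copies in copies_by_species.items():
        seqs = [(f"{species}_copy{i+1}", c.sequence) for i, c in enumerate(copies)]
        if not seqs:
            logger.warning("no copies discovered for %s; no consensus", species)
            continue
        if len(seqs) == 1:
            consensi[species] = seqs[0][1]
            continue
        model = build_consensus(align_copies(seqs), min_copies=config.min_copies)
        consensi[species] = model.sequence
    write_fasta(outdir / "consensus.fa", sorted(consensi.items()))
    counts["consensus"] = len(consensi)

    if "date" in config.stages:
        rates = RateTable(sim_cfg.rates)
        r = rates[config.lineage]
        with open(outdir / "dating.tsv", "w") as fh:
            fh.write(_header(config))
            fh.write("copy_id\tsites\tP\tQ\tk\tsaturated\tage_yr\tage_myr\n")
            n_dated = 0
            for species, copies in copies_by_species.items():
                if species not in consensi:
                    continue
                named = [(f"{species}_copy{i+1}", c.sequence)
                         for i, c in enumerate(copies)]
                if not named:
                    continue
                _, records = divergence_landscape(
                    named, consensi[species], r, config.bin_width_myr)
                for rec in records:
                    age_yr = "" if rec.age_years is None else f"{rec.age_years:.1f}"
                    age_myr = "" if rec.age_myr is None else f"{rec.age_myr:.3g}"
                    k = "" if rec.k is None else f"{rec.k:.6f}"
                    fh.write(f"{rec.copy_id}\t{rec.compared_sites}\t{rec.P:.6f}\t"
                             f"{rec.Q:.6f}\t{k}\t{int(rec.saturated)}\t"
                             f"{age_yr}\t{age_myr}\n")
                    n_dated += 1
        counts["date"] = n_dated

    if "httest" in config.stages and len(consensi) >= 2:
        te_aln = align_copies(sorted(consensi.items()))
        te_table = pairwise_distance_table(te_aln.rows, config.distance_method)
        gene_table = pairwise_distance_table(sorted(gene.items()),
                                             config.distance_method)
        comparisons, flagged, total = ht_compare(
            te_table, gene_table, tree.split_times(),
            min_split=config.min_split, margin=config.margin,
        )
        with open(outdir / "ht_comparisons.tsv", "w") as fh:
            fh.write(_header(config))
            fh.write("species_a\tspecies_b\td_te\td_gene\tsplit_myr\tht_flag\n")
            for c in comparisons:
                split = "" if c.split_myr is None else f"{c.split_myr:.2f}"
                fh.write(f"{c.species_a}\t{c.species_b}\t{c.d_te:.6f}\t"
                         f"{c.d_gene:.6f}\t{split}\t{int(c.ht_flag)}\n")
        summary = {
            "method": te_table.method,
            "flagged": flagged,
            "total": total,
            "te": dataclasses.asdict(summarize_distances(te_table)),
            "gene": dataclasses.asdict(summarize_distances(gene_table)),
        }
        (outdir / "ht_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
        counts["httest"] = total

    report = RunReport(config.seed, __version__, counts,
                       _echo_params(config), inconsistencies)
    (outdir / "run_report.json").write_text(
        json.dumps(dataclasses.asdict(report), indent=2, default=str) + "\n")
    return report


def _echo_params(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"]["age_distribution"] = [dataclasses.asdict(p) if dataclasses.is_dataclass(p)
                                    else p for p in config.sim.age_distribution]
    return d


# ---------------------------------------------------------------------------
# format validation


def validate_formats(path: str | Path, format_name: str) -> list[str]:
    """Check a file against the dialect rules the pipeline uses.

    Returns a list of diagnostics (empty = ok). Supported formats: fasta,
    aligned_fasta, bed, newick, tsv.
    """
    path = Path(path)
    if not path.exists():
        return [f"{path}: file does not exist"]
    lines = path.read_text().splitlines()
    diags: list[str] = []

    if format_name in ("fasta", "aligned_fasta"):
        seqs: list[tuple[int, str]] = []
        cur: list[str] | None = None
        cur_line = 0
        for i, line in enumerate(lines, 1):
            if line.startswith(">"):
                if cur is not None:
                    seqs.append((cur_line, "".join(cur)))
                cur = []
                cur_line = i
            elif cur is None:
                if line.strip():
                    diags.append(f"line {i}: sequence before first header")
            else:
                cur.append(line.strip())
        if cur is not None:
            seqs.append((cur_line, "".join(cur)))
        if not seqs:
            diags.append("no FASTA records found")
        for ln, s in seqs:
            if not s:
                diags.append(f"line {ln}: empty sequence")
        if format_name == "aligned_fasta" and seqs:
            ref = len(seqs[0][1])
            for ln, s in seqs[1:]:
                if len(s) != ref:
                    diags.append(
                        f"line {ln}: row length {len(s)} != {ref} (ragged alignment)")
    elif format_name == "bed":
        for i, line in enumerate(lines, 1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                diags.append(f"line {i}: fewer than 3 BED columns")
                continue
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                diags.append(f"line {i}: non-integer coordinates")
                continue
            if start >= end:
                diags.append(f"line {i}: start >= end ({start} >= {end})")
            if start < 0:
                diags.append(f"line {i}: negative start")
    elif format_name == "newick":
        try:
            SpeciesTree.from_newick("\n".join(lines))
        except Exception as exc:  # noqa: BLE001 - diagnostics, not control flow
            diags.append(f"newick: {exc}")
    elif format_name == "tsv":
        widths = set()
        for i, line in enumerate(lines, 1):
            if not line.strip() or line.startswith("#"):
                continue
            widths.add(len(line.split("\t")))
        if len(widths) > 1:
            diags.append(f"inconsistent column counts: {sorted(widths)}")
    else:
        diags.append(f"unknown format {format_name!r}")
    return diags
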