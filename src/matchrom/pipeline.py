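"""End-to-end orchestration: dataset -> divergence -> trees -> phases ->
suppression -> events -> rates -> report.

The pipeline is a pure function of (inputs, configuration, seed): rerunning
with the same arguments reproduces every output file byte for byte. A
single seed fans out to per-stage seeds through a stable hash of the stage
name, so adding a stage never perturbs the randomness of earlier ones.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import divergence as dv
from . import events as ev
from . import genealogy as gn
from . import suppression as sp
from .errors import ConfigError
from .io import (
    ChromosomeLayout,
    GeneAlignmentSet,
    Manifest,
    SupportedTree,
    read_coding_mask,
    read_gene_alignment,
    read_layout,
    read_manifest,
    read_newick_supported,
)
from .simulate import SimConfig, study_like_config, simulate_dataset

log = logging.getLogger(__name__)


def stage_seed(seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return int(
        np.random.SeedSequence(
            [int(seed) % (2**31), zlib.crc32(stage.encode())]
        ).generate_state(1)[0]
        % (2**31)
    )


@dataclass
class PipelineConfig:
    input_dir: Optional[str] = None  # dataset directory; None -> simulate
    out_dir: str = "out"
    trees_dir: Optional[str] = None  # user-supplied per-gene Newick trees
    thresholds: gn.SupportThresholds = field(default_factory=gn.SupportThresholds)
    min_diffs: int = 2
    together_max_dist: float = 0.005
    persistence: int = 2
    merge_max_diffs: int = 4
    direction_majority: float = 1.0
    strict_windows: bool = False
    counting: str = "per_event"
    n_lineages: Optional[int] = None  # default: counted from the manifest
    T: float = 4.6  # lineage divergence time, MY
    seed: int = 0
    sim_config: Optional[SimConfig] = None  # overrides the default when simulating

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        thr = raw.pop("thresholds", {})
        cfg = cls(**raw)
        if thr:
            cfg.thresholds = gn.SupportThresholds(**thr)
        return cfg


@dataclass
class PipelineResult:
    config: PipelineConfig
    manifest: Manifest
    layout: ChromosomeLayout
    alignments: dict[str, GeneAlignmentSet]
    records: list[dv.DivergenceRecord]
    trees: dict[str, SupportedTree]
    phases: gn.PhaseMatrix
    maps: dict[str, sp.SuppressionMap]
    conversions: list[ev.ConversionEvent]
    crossovers: list[ev.CrossoverEvent]
    rates: pd.DataFrame
    truth: object = None  # SimTruth when the dataset was simulated

    @property
    def inside_span_conversions(self) -> list[ev.ConversionEvent]:
        return [c for c in self.conversions if c.in_region]


def load_dataset(input_dir) -> tuple[dict[str, GeneAlignmentSet], Manifest, ChromosomeLayout]:
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise ConfigError(f"input directory {input_dir} does not exist")
    manifest_path = input_dir / "manifest.tsv"
    layout_path = input_dir / "layout.tsv"
    if not manifest_path.exists() or not layout_path.exists():
        raise ConfigError(
            f"{input_dir} must contain manifest.tsv and layout.tsv"
        )
    manifest = read_manifest(manifest_path)
    layout = read_layout(layout_path)
    masks = {}
    mask_path = input_dir / "mask.tsv"
    if mask_path.exists():
        masks = read_coding_mask(mask_path)
    alignments = {}
    for gene in layout.genes:
        fasta = input_dir / "genes" / f"{gene}.fasta"
        if fasta.exists():
            alignments[gene] = read_gene_alignment(
                fasta, mask=masks.get(gene), gene=gene, manifest=manifest
            )
    if not alignments:
        raise ConfigError(f"no per-gene FASTA files under {input_dir}/genes")
    return alignments, manifest, layout


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []

    def mark(stage: str) -> None:
        completed.append(stage)
        (out / "MANIFEST.json").write_text(
            json.dumps({"completed_stages": completed}, indent=1) + "\n"
        )

    try:
        return _run_stages(config, out, mark)
    except Exception:
        (out / "MANIFEST.json").write_text(
            json.dumps({"completed_stages": completed, "failed": True}, indent=1)
            + "\n"
        )
        raise


def _run_stages(config: PipelineConfig, out: Path, mark) -> PipelineResult:
    truth = None
    if config.input_dir is None:
        sim_cfg = config.sim_config or study_like_config(
            seed=stage_seed(config.seed, "simulate")
        )
        dataset = simulate_dataset(sim_cfg)
        dataset.write(out / "dataset")
        alignments, manifest, layout = (
            dataset.alignments,
            dataset.manifest,
            dataset.layout,
        )
        truth = dataset.truth
        log.info("simulated dataset: %d genes, %d strains (seed %d)",
                 len(alignments), len(manifest.strains), sim_cfg.rng_seed)
        mark("simulate")
    else:
        alignments, manifest, layout = load_dataset(config.input_dir)
        log.info("loaded dataset from %s: %d genes", config.input_dir,
                 len(alignments))
        mark("load")

    records = dv.divergence_table(alignments, layout, manifest)
    dv.write_divergence_tsv(records, out / "divergence.tsv")
    mark("divergence")

    trees: dict[str, SupportedTree] = {}
    trees_out = out / "trees"
    trees_out.mkdir(exist_ok=True)
    base = stage_seed(config.seed, "trees")
    for gi, gene in enumerate(layout.genes):
        if config.trees_dir is not None:
            nwk = Path(config.trees_dir) / f"{gene}.nwk"
            if nwk.exists():
                trees[gene] = read_newick_supported(nwk, gene=gene)
                continue
        aln = alignments.get(gene)
        if aln is None or len(aln.sequences) < 3:
            continue
        trees[gene] = gn.bootstrap_supports(
            aln,
            reps=config.thresholds.bootstrap_reps,
            seed=(base + gi) % (2**31),
            gene=gene,
        )
    for gene, tree in trees.items():
        tree.write(trees_out / f"{gene}.nwk")
    mark("trees")

    phases = gn.phase_matrix(
        trees, manifest, layout, config.thresholds, config.together_max_dist
    )
    phases.write_tsv(out / "phases.tsv")
    mark("phases")

    maps = sp.build_suppression_maps(records, layout, manifest, config.min_diffs)
    sp.write_suppression_tsv(maps, layout, out / "suppression.tsv")
    sp.compare_boundaries(maps, layout).to_csv(
        out / "boundaries.tsv", sep="\t", index=False
    )
    mark("suppression")

    raw_events = ev.detect_conversions(
        phases, maps, layout, strict_adjacency=config.strict_windows
    )
    conversions = ev.merge_ancestral_events(
        raw_events, alignments, manifest, config.merge_max_diffs
    )
    # template direction is read off the focal genealogy after merging so
    # that every affected pair's (donor-copy) alleles sit out of the vote
    for event in conversions:
        gene_tree = trees.get(event.gene)
        if gene_tree is not None:
            event.template = ev.infer_template_direction(
                gene_tree, sorted(event.affected_pairs), manifest,
                config.thresholds, config.direction_majority,
            )
    crossovers = ev.detect_crossovers(
        trees, manifest, layout, config.thresholds, config.persistence,
        config.direction_majority,
    )
    mark("events")

    n_lineages = config.n_lineages or len(manifest.lineages)
    rates = ev.rates_table(
        conversions, n_lineages, config.T, counting=config.counting
    )
    rates.to_csv(out / "rates.tsv", sep="\t", index=False, float_format="%.6g")
    mark("rates")

    result = PipelineResult(
        config=config,
        manifest=manifest,
        layout=layout,
        alignments=alignments,
        records=records,
        trees=trees,
        phases=phases,
        maps=maps,
        conversions=conversions,
        crossovers=crossovers,
        rates=rates,
        truth=truth,
    )
    (out / "events.json").write_text(events_json(result) + "\n")
    (out / "summary.txt").write_text(report(result))
    mark("report")
    return result


def events_json(result: PipelineResult) -> str:
    payload = {
        "conversions": [c.to_dict() for c in result.conversions],
        "crossovers": [c.to_dict() for c in sorted(
            result.crossovers, key=lambda x: (x.pair_id, x.interval)
        )],
        "rates": result.rates.to_dict(orient="records"),
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def report(result: PipelineResult) -> str:
    """Human-readable summary; deterministic (no timestamps)."""
    cfg = result.config
    n_lineages = cfg.n_lineages or len(result.manifest.lineages)
    lines = []
    lines.append("matchrom pipeline summary")
    lines.append("=========================")
    lines.append(
        f"parameters: seed={cfg.seed} bootstrap_reps={cfg.thresholds.bootstrap_reps} "
        f"bootstrap_min={cfg.thresholds.bootstrap_min} "
        f"posterior_min={cfg.thresholds.posterior_min} "
        f"min_diffs={cfg.min_diffs} together_max_dist={cfg.together_max_dist} "
        f"persistence={cfg.persistence} merge_max_diffs={cfg.merge_max_diffs} "
        f"T={cfg.T} n_lineages={n_lineages} counting={cfg.counting}"
    )
    lines.append("")
    lines.append("suppressed region per pair (outermost diverged genes):")
    for pair_id in result.manifest.pair_ids:
        m = result.maps[pair_id]
        if m.has_region:
            internal = (
                f"; internal homoallelic: {', '.join(m.internal_homoallelic_genes)}"
                if m.internal_homoallelic_genes
                else ""
            )
            lines.append(
                f"  {pair_id}: {m.region_start_gene} .. {m.region_end_gene}{internal}"
            )
        else:
            lines.append(f"  {pair_id}: no diverged genes")
    inside = result.inside_span_conversions
    lines.append("")
    lines.append(
        f"gene conversion events inside the suppressed span: {len(inside)}"
    )
    for c in inside:
        anc = (
            f" ancestral({','.join(sorted(c.lineages))})" if c.ancestral else ""
        )
        lines.append(
            f"  {c.gene}: pairs {', '.join(sorted(c.affected_pairs))} "
            f"template={c.template}{anc}"
        )
    lines.append(
        "note: events at the first/last gene of a suppressed span are "
        "undetectable by the three-genealogy window rule."
    )
    lines.append("")
    lines.append(f"crossovers: {len(result.crossovers)}")
    for x in result.crossovers:
        lines.append(
            f"  {x.pair_id}: between {x.interval[0]} and {x.interval[1]}"
        )
    lines.append("")
    lines.append(
        f"per-gene homogenization rates r = K/(2T), T={cfg.T} MY, "
        f"{n_lineages} lineages ({cfg.counting} counting):"
    )
    if len(result.rates):
        for _, row in result.rates.iterrows():
            lines.append(
                f"  {row['gene']}: events={row['events']} "
                f"(per-pair {row['events_per_pair']}) r={row['r']:.6f} "
                f"(rounded {row['r_rounded']:.3f})"
            )
    else:
        lines.append("  (no events)")
    return "\n".join(lines) + "\n"
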