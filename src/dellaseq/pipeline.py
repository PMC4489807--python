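"""End-to-end orchestration: simulate -> merge -> annotate -> motif-enrich,
plus the independent expression and qPCR branches.

All interchange between stages is via files; a run manifest records the
fully-resolved configuration and a content hash of every output, so reruns
with the same configuration are verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate, io, merging, motifs, qpcr, simulate, zscore

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration for a full pipeline run."""

    outdir: str = "pipeline_out"
    seed: int = 42
    alpha: float = 0.05
    simulation: simulate.SimulationConfig = field(
        default_factory=simulate.SimulationConfig
    )
    merge: merging.MergeParams = field(default_factory=merging.MergeParams)
    annotation: annotate.AnnotationParams = field(
        default_factory=annotate.AnnotationParams
    )
    scan: motifs.ScanParams = field(default_factory=motifs.ScanParams)
    n_background: int = 500
    stages: tuple[str, ...] = ("simulate", "merge", "annotate", "motif", "de", "qpcr")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sim = simulate.SimulationConfig(**raw.pop("simulation", {}))
        mrg = merging.MergeParams(**raw.pop("merge", {}))
        ann = annotate.AnnotationParams(**raw.pop("annotation", {}))
        scan_kwargs = raw.pop("scan", {})
        if "background_freqs" in scan_kwargs:
            scan_kwargs["background_freqs"] = tuple(scan_kwargs["background_freqs"])
        scn = motifs.ScanParams(**scan_kwargs)
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(simulation=sim, merge=mrg, annotation=ann, scan=scn, **raw)

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order and return the manifest.

    The synthetic-data stage writes every downstream input; merge ->
    annotate -> motif consume each other's files, while the differential
    expression and qPCR branches are independent.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    if sim.seed != config.seed:
        sim = simulate.SimulationConfig(**{**simulate.config_to_dict(sim), "seed": config.seed})
    produced: dict[str, Path] = {}

    def emit(name: str, path: Path):
        produced[name] = path
        logger.info("stage_output name=%s path=%s", name, path)

    stages = set(config.stages)
    paths = {
        "genome": out / "genome.fa",
        "gff": out / "annotation.gff3",
        "truth": out / "ground_truth.json",
        "pfm": out / "motifs.jaspar",
        "sites_bed": out / "binding_sites.bed",
        "members": out / "site_members.tsv",
        "assignments": out / "assignments.tsv",
        "locations": out / "location_summary.tsv",
        "motif_tsv": out / "motif_enrichment.tsv",
        "family_tsv": out / "family_enrichment.tsv",
        "expr": out / "expression.tsv",
        "design": out / "design.tsv",
        "contrasts": out / "zratio_contrasts.tsv",
        "classes": out / "gene_classes.tsv",
        "class_counts": out / "class_counts.tsv",
        "heatmap": out / "zscore_heatmap.tsv",
        "overlap": out / "binding_overlap.tsv",
        "qpcr_ct": out / "qpcr_ct.tsv",
        "qpcr_enr": out / "qpcr_enrichment.tsv",
        "qpcr_ratio": out / "qpcr_condition_ratio.tsv",
    }

    if "simulate" in stages:
        genome, ann = simulate.generate_genome(sim)
        pwms = simulate.default_motif_library()
        truth = simulate.GroundTruth()
        truth.true_site_positions = simulate.generate_true_sites(ann, sim)
        genome, truth.planted_motif_flags = simulate.plant_motif_instances(
            genome, truth.true_site_positions, pwms, sim
        )
        reps = simulate.generate_summit_replicates(
            truth.true_site_positions, sim, ann.chrom_lengths
        )
        matrix, design, truth.gene_classes = simulate.generate_expression_dataset(
            sorted(ann.genes), sim
        )
        truth.true_qpcr_enrichments = {"SCL3pro": 4.0, "TCSpro": 2.5, "NULLpro": 1.0}
        ct = simulate.generate_qpcr_dataset(
            truth.true_qpcr_enrichments, sim, conditions=("mock", "dex")
        )
        io.write_fasta(genome, paths["genome"])
        io.write_gff3(ann, paths["gff"])
        io.write_pfm(pwms, paths["pfm"])
        for i, rep in enumerate(reps):
            p = out / f"summits_rep{i + 1}.bed"
            io.write_summits_bed(rep, p)
            emit(f"summits_rep{i + 1}", p)
        matrix.to_csv(paths["expr"], sep="\t")
        design.to_csv(paths["design"], sep="\t")
        ct.to_csv(paths["qpcr_ct"], sep="\t", index=False)
        truth.to_json(paths["truth"])
        for k in ("genome", "gff", "pfm", "expr", "design", "qpcr_ct", "truth"):
            emit(k, paths[k])

    if "merge" in stages:
        rep_files = sorted(out.glob("summits_rep*.bed"))
        if len(rep_files) < 2:
            raise FileNotFoundError("merge stage needs >= 2 replicate summit BEDs")
        summit_sets = [io.read_summits_bed(p) for p in rep_files]
        ann = io.read_gff3(paths["gff"])
        clusters = merging.cluster_summits(summit_sets, config.merge, ann.chrom_lengths)
        sites = merging.define_binding_sites(clusters, config.merge, ann.chrom_lengths)
        merging.sites_to_frame(sites).to_csv(paths["sites_bed"], sep="\t", header=False, index=False)
        merging.members_to_frame(sites).to_csv(paths["members"], sep="\t", index=False)
        emit("sites_bed", paths["sites_bed"])
        emit("members", paths["members"])

    if "annotate" in stages or "motif" in stages:
        if not paths["gff"].exists():
            raise FileNotFoundError(f"annotation file missing: {paths['gff']}")
        ann = io.read_gff3(paths["gff"])
        sites = _read_sites(paths["sites_bed"])

    if "annotate" in stages:
        assignments = annotate.assign_sites_to_genes(sites, ann, config.annotation)
        annotate.assignments_to_frame(assignments).to_csv(
            paths["assignments"], sep="\t", index=False
        )
        annotate.summarize_locations(assignments).to_csv(
            paths["locations"], sep="\t", index=False
        )
        emit("assignments", paths["assignments"])
        emit("locations", paths["locations"])

    if "motif" in stages:
        genome = io.read_fasta(paths["genome"])
        pwms = io.read_pfm(paths["pfm"])
        windows = motifs.extract_central_windows(sites, genome, config.scan)
        rng = np.random.default_rng([7, config.seed])
        results = motifs.run_enrichment(
            windows, pwms, config.scan, alpha=config.alpha,
            n_background=config.n_background, rng=rng,
        )
        motifs.results_to_frame(results).to_csv(paths["motif_tsv"], sep="\t", index=False)
        fam = motifs.aggregate_by_family(results, windows, pwms, config.scan)
        fam.to_csv(paths["family_tsv"], sep="\t", index=False)
        emit("motif_tsv", paths["motif_tsv"])
        emit("family_tsv", paths["family_tsv"])

    if "de" in stages:
        matrix = pd.read_csv(paths["expr"], sep="\t", index_col=0)
        design = pd.read_csv(paths["design"], sep="\t", index_col=0)
        z = zscore.zscore_transform(matrix)
        high = zscore.zratio_contrast(
            z, design, {"DEX": "dex", "PAC": "+"}, {"DEX": "mock", "PAC": "+"},
            alpha=config.alpha, name="dex_effect_highDELLA",
        )
        low = zscore.zratio_contrast(
            z, design, {"DEX": "dex", "PAC": "-"}, {"DEX": "mock", "PAC": "-"},
            alpha=config.alpha, name="dex_effect_lowDELLA",
        )
        both = pd.concat(
            {high.contrast: high.table, low.contrast: low.table}, names=["contrast"]
        )
        both.to_csv(paths["contrasts"], sep="\t")
        classes = zscore.classify_arr1_della_targets(high, low)
        classes.to_frame().to_csv(paths["classes"], sep="\t")
        zscore.class_counts(classes).to_csv(paths["class_counts"], sep="\t", index=False)
        zscore.heatmap_matrix(z, classes).to_csv(paths["heatmap"], sep="\t")
        for k in ("contrasts", "classes", "class_counts", "heatmap"):
            emit(k, paths[k])
        if paths["assignments"].exists():
            asg = pd.read_csv(paths["assignments"], sep="\t")
            bound = set(asg["gene_id"].dropna())
            zscore.intersect_with_binding(classes, bound).to_csv(
                paths["overlap"], sep="\t", index=False
            )
            emit("overlap", paths["overlap"])

    if "qpcr" in stages:
        ct = pd.read_csv(paths["qpcr_ct"], sep="\t")
        enr = qpcr.relative_enrichment(ct, control_amplicon="HSF")
        enr.table.to_csv(paths["qpcr_enr"], sep="\t", index=False)
        emit("qpcr_enr", paths["qpcr_enr"])
        conds = list(dict.fromkeys(ct["condition"]))
        if len(conds) >= 2:
            ratio = qpcr.condition_ratio(qpcr.input_normalized(ct), conds[1], conds[0])
            ratio.to_csv(paths["qpcr_ratio"], sep="\t", index=False)
            emit("qpcr_ratio", paths["qpcr_ratio"])

    resolved = config.to_dict()
    resolved["simulation"] = simulate.config_to_dict(sim)
    manifest = {
        "config": _jsonable(resolved),
        "outputs": {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in sorted(produced.items())
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _read_sites(path: Path) -> list[merging.BindingSite]:
    """Load binding sites written by the merge stage."""
    if not path.exists():
        raise FileNotFoundError(f"binding-site BED missing: {path}")
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "name", "score", "strand", "mean_summit"],
    )
    sites = []
    for _, r in df.iterrows():
        sites.append(
            merging.BindingSite(
                chrom=str(r["chrom"]), mean_summit=int(r["mean_summit"]),
                start=int(r["start"]), end=int(r["end"]), site_id=str(r["name"]),
            )
        )
    return sites
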