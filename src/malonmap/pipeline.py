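"""End-to-end orchestration: quantify -> differential -> enrichment ->
motifs -> network/QC, with a YAML config, per-stage logging and a run
manifest.

All stages are deterministic pure functions of their inputs and the
configured thresholds; re-running any stage on the same inputs reproduces
its outputs byte for byte.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .differential import Thresholds, differential_table, heatmap_filter, top_n_sites
from .enrichment import EnrichmentMatrix, category_summary, q_group_enrichment
from .io_formats import (
    ProteinQuantTable,
    SiteIntensityTable,
    read_annotation,
    read_edge_table,
    read_fasta,
    read_protein_table,
    read_site_table,
)
from .motifs import (
    build_background,
    extract_windows,
    frequency_heatmap,
    motif_discovery,
    motif_table,
)
from .network_qc import NetworkView, QcSummary, build_network, qc_report
from .quantify import centralize, correct_by_protein, write_relquant

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineParams:
    """All thresholds the pipeline consumes, with the defaults the
    screening procedure defines (fc 1.5, cv 0.1, alpha 0.05, motif p 1e-6
    at >= 20 peptides, interaction score 0.7, top 50 hubs, 2/3 heatmap
    completeness, top 30 sites)."""

    thresholds: Thresholds = field(default_factory=Thresholds)
    protein_correction: bool = True
    heatmap_fraction: float = 2 / 3
    top_sites: int = 30
    motif_p_threshold: float = 1e-6
    motif_min_occ: int = 20
    modified_residue: str = "K"
    score_min: float = 0.7
    network_top_n: int = 50
    enrich_namespaces: tuple[str, ...] = ("KEGG", "GO-BP", "DOMAIN")
    alpha_enrich: float = 0.05

    def validate(self) -> None:
        if self.thresholds.fc <= 1:
            raise ValueError("fold-change threshold must exceed 1")
        for name, v in (
            ("cv", self.thresholds.cv),
            ("alpha", self.thresholds.alpha),
            ("motif_p_threshold", self.motif_p_threshold),
            ("score_min", self.score_min),
        ):
            if v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    site_R_raw: object
    site_R: object
    records: pd.DataFrame
    heatmap_sites: list[str]
    top_sites: list[str]
    enrichment: dict[str, EnrichmentMatrix]
    motifs: list
    motif_heatmap: pd.DataFrame | None
    network: NetworkView | None
    qc: QcSummary
    manifest: dict


def run_stages(
    site_table: SiteIntensityTable,
    protein_table: ProteinQuantTable | None,
    fasta_map: dict[str, str] | None,
    annotations: pd.DataFrame | None,
    edges: pd.DataFrame | None,
    group_treatment: str,
    group_control: str,
    params: PipelineParams = PipelineParams(),
) -> PipelineResult:
    """Run the full analysis in memory.

    The fold change is treatment over control. Stages whose optional
    inputs (FASTA, annotations, edges) are absent are skipped and noted in
    the manifest.
    """
    params.validate()
    t_start = time.perf_counter()
    manifest: dict = {
        "version": __version__,
        "thresholds": {
            "fc": params.thresholds.fc,
            "cv": params.thresholds.cv,
            "alpha": params.thresholds.alpha,
            "q_bins": list(params.thresholds.q_bins),
            "motif_p": params.motif_p_threshold,
            "motif_min_occ": params.motif_min_occ,
            "score_min": params.score_min,
            "network_top_n": params.network_top_n,
            "heatmap_fraction": params.heatmap_fraction,
        },
        "stages": {},
    }

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                self.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc
                log.info("stage %s: done in %.2fs", name,
                         time.perf_counter() - self.t0)
        return _Ctx()

    samples_a = site_table.samples_in_group(group_treatment)
    samples_b = site_table.samples_in_group(group_control)
    if not samples_a or not samples_b:
        raise PipelineError(
            f"stage 'quantify' failed: groups {group_treatment!r}/{group_control!r} "
            "have no samples"
        )

    with _stage("quantify"):
        site_R_raw = centralize(site_table)
        if params.protein_correction:
            if protein_table is None:
                raise ValueError("protein correction requires a protein table")
            protein_R = centralize(protein_table)
            site_R = correct_by_protein(site_R_raw, protein_R, site_table)
        else:
            site_R = site_R_raw
        manifest["stages"]["quantify"] = {
            "sites_read": len(site_table.sites),
            "sites_quantified": site_R.values.shape[0],
            "sites_dropped": site_R_raw.n_dropped,
            "protein_corrected": params.protein_correction,
        }

    with _stage("differential"):
        records = differential_table(
            site_R, samples_a, samples_b, site_table, params.thresholds
        )
        n_up = int((records["regulation"] == "UP").sum())
        n_down = int((records["regulation"] == "DOWN").sum())
        heatmap_sites = heatmap_filter(records, site_R, params.heatmap_fraction)
        top_sites = top_n_sites(
            records[records["regulation"] != "NS"], params.top_sites
        )
        manifest["stages"]["differential"] = {
            "sites_tested": len(records),
            "up": n_up,
            "down": n_down,
            "q_counts": records["q_group"].value_counts().to_dict(),
            "heatmap_sites": len(heatmap_sites),
            "top_sites": len(top_sites),
        }

    enrichment: dict[str, EnrichmentMatrix] = {}
    if annotations is not None:
        with _stage("enrichment"):
            for ns in params.enrich_namespaces:
                enrichment[ns] = q_group_enrichment(
                    records, annotations, ns, alpha=params.alpha_enrich
                )
            manifest["stages"]["enrichment"] = {
                ns: {
                    "terms_significant": int(mat.matrix.shape[0]),
                    "groups": list(mat.matrix.columns),
                }
                for ns, mat in enrichment.items()
            }
    else:
        manifest["stages"]["enrichment"] = "skipped (no annotations)"

    motifs, motif_hm = [], None
    if fasta_map is not None:
        with _stage("motifs"):
            fg = extract_windows(fasta_map, site_table)
            bg = build_background(fasta_map, params.modified_residue)
            motifs = motif_discovery(
                fg["window"], bg,
                p_threshold=params.motif_p_threshold,
                min_occ=params.motif_min_occ,
            )
            motif_hm = frequency_heatmap(fg["window"], bg)
            manifest["stages"]["motifs"] = {
                "fg_windows": len(fg),
                "bg_windows": len(bg),
                "motifs_found": len(motifs),
                "patterns": [m.pattern for m in motifs],
            }
    else:
        manifest["stages"]["motifs"] = "skipped (no FASTA)"

    network = None
    if edges is not None:
        with _stage("network"):
            network = build_network(
                edges, records, params.score_min, params.network_top_n
            )
            manifest["stages"]["network"] = {
                "nodes": len(network.nodes),
                "edges": len(network.edges),
            }
    else:
        manifest["stages"]["network"] = "skipped (no edges)"

    with _stage("qc"):
        qc = qc_report(site_R_raw, site_table)
        manifest["stages"]["qc"] = {
            "complete_sites": qc.n_complete_sites,
            "variance_explained": [round(float(v), 6)
                                   for v in qc.variance_explained],
        }

    manifest["runtime_s"] = round(time.perf_counter() - t_start, 3)
    return PipelineResult(
        site_R_raw=site_R_raw,
        site_R=site_R,
        records=records,
        heatmap_sites=heatmap_sites,
        top_sites=top_sites,
        enrichment=enrichment,
        motifs=motifs,
        motif_heatmap=motif_hm,
        network=network,
        qc=qc,
        manifest=manifest,
    )


@dataclass
class PipelineConfig:
    """File-level configuration for a full run (YAML-loadable)."""

    sites: Path
    out_dir: Path
    sample_groups: dict[str, str]
    group_treatment: str
    group_control: str
    proteins: Path | None = None
    fasta: Path | None = None
    annotations: Path | None = None
    edges: Path | None = None
    params: PipelineParams = field(default_factory=PipelineParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        base = Path(path).parent
        def _p(key):
            return (base / raw[key]).resolve() if raw.get(key) else None
        thr = raw.get("thresholds", {})
        thresholds = Thresholds(
            fc=float(thr.get("fc", 1.5)),
            cv=float(thr.get("cv", 0.1)),
            alpha=float(thr.get("alpha", 0.05)),
            q_bins=tuple(thr.get("q_bins", (0.5, 1 / 1.5, 1.5, 2.0))),
        )
        params = PipelineParams(
            thresholds=thresholds,
            protein_correction=bool(raw.get("protein_correction", True)),
            heatmap_fraction=float(raw.get("heatmap_fraction", 2 / 3)),
            top_sites=int(raw.get("top_sites", 30)),
            motif_p_threshold=float(raw.get("motif_p_threshold", 1e-6)),
            motif_min_occ=int(raw.get("motif_min_occ", 20)),
            score_min=float(raw.get("score_min", 0.7)),
            network_top_n=int(raw.get("network_top_n", 50)),
        )
        return cls(
            sites=_p("sites"),
            out_dir=(base / raw["out_dir"]).resolve(),
            sample_groups=dict(raw["sample_groups"]),
            group_treatment=raw["group_treatment"],
            group_control=raw["group_control"],
            proteins=_p("proteins"),
            fasta=_p("fasta"),
            annotations=_p("annotations"),
            edges=_p("edges"),
            params=params,
        )


def run_all(config: PipelineConfig) -> dict:
    """Load inputs, run every stage and write the report bundle.

    Returns the manifest. Any stage failure aborts with the stage name and
    cause; a configured-but-missing input aborts naming the stage that
    needs it.
    """
    _require(config.sites, "quantify")
    if config.params.protein_correction:
        _require(config.proteins, "quantify (protein correction)")
    if config.fasta is not None:
        _require(config.fasta, "motifs")
    if config.annotations is not None:
        _require(config.annotations, "enrichment")
    if config.edges is not None:
        _require(config.edges, "network")

    site_table = read_site_table(config.sites, config.sample_groups)
    protein_table = (
        read_protein_table(config.proteins) if config.proteins else None
    )
    fasta_map = read_fasta(config.fasta) if config.fasta else None
    annotations = read_annotation(config.annotations) if config.annotations else None
    edges = read_edge_table(config.edges) if config.edges else None

    result = run_stages(
        site_table, protein_table, fasta_map, annotations, edges,
        config.group_treatment, config.group_control, config.params,
    )
    write_outputs(result, site_table, config.out_dir)
    return result.manifest


def _require(path: Path | None, stage: str) -> None:
    if path is None or not Path(path).exists():
        raise PipelineError(
            f"stage {stage!r} prerequisite missing: input file {path}"
        )


def write_outputs(
    result: PipelineResult, site_table: SiteIntensityTable, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_relquant(result.site_R, out / "relquant.tsv")
    result.records.to_csv(out / "differential.tsv", sep="\t", na_rep="NA",
                          float_format="%.10g")
    hm = result.site_R.values.reindex(result.heatmap_sites)
    hm.to_csv(out / "heatmap_matrix.tsv", sep="\t", na_rep="NA",
              float_format="%.10g")
    result.records.reindex(result.top_sites).to_csv(
        out / "top_sites.tsv", sep="\t", na_rep="NA", float_format="%.10g"
    )
    for ns, mat in result.enrichment.items():
        mat.long.to_csv(out / f"enrichment_{ns}.tsv", sep="\t", index=False,
                        na_rep="NA", float_format="%.10g")
        mat.ordered.to_csv(out / f"enrichment_matrix_{ns}.tsv", sep="\t",
                           na_rep="NA", float_format="%.10g")
    if result.motifs is not None:
        motif_table(result.motifs).to_csv(out / "motifs.tsv", sep="\t",
                                          index=False, float_format="%.6g")
    if result.motif_heatmap is not None:
        result.motif_heatmap.to_csv(out / "motif_heatmap.tsv", sep="\t",
                                    float_format="%.6g")
    if result.network is not None:
        result.network.nodes.to_csv(out / "network_nodes.tsv", sep="\t")
        result.network.edges.to_csv(out / "network_edges.tsv", sep="\t",
                                    index=False, float_format="%.6g")
    result.qc.sample_stats.to_csv(out / "qc_samples.tsv", sep="\t",
                                  float_format="%.6g")
    pd.DataFrame(
        {
            "component": np.arange(1, len(result.qc.variance_explained) + 1),
            "variance_fraction": result.qc.variance_explained,
        }
    ).to_csv(out / "qc_pca.tsv", sep="\t", index=False, float_format="%.10g")
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
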