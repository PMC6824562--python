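"""One-command pipeline: ingest -> filter -> normalize -> biomarkers ->
kinase/module activity -> enrichment -> network, with a JSON run manifest.

The manifest records package version, a hash of the resolved configuration,
input checksums and the per-stage feature counts (identified -> artifact
filtered -> quantification filtered -> significant -> rescued), so a run can
be audited and reproduced; with fixed seeds a rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .abundance import housekeeping_set, rank_abundance
from .differential import (
    BiomarkerSets,
    anova_across_lines,
    common_oncogenic_markers,
    presence_absence_rescue,
    resistance_markers,
    up_down_sets,
    vs_reference,
)
from .enrichment import ora
from .ksea import build_site_scores, ksea, read_ks_map
from .maxquant import filter_artifacts, read_quant_table
from .network import biomarker_subgraph, build_complex_network, export_graph
from .preprocess import (
    cross_layer_correlation,
    hierarchical_cluster,
    log2_zscore,
    valid_value_filter,
)
from .roma import group_summary, read_gmt, score_collection
from .tables import PHOSPHO, PROTEOME, ConfigurationError, StudyDesign

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run; loadable from YAML."""

    proteome_table: str = ""
    phospho_table: str = ""
    design: str = ""
    group_map: dict[str, str] = field(default_factory=dict)
    gmt: str = ""
    ks_map: str = ""
    complexes: list[str] = field(default_factory=list)
    drop_samples: list[str] = field(default_factory=list)  # e.g. a divergent replicate

    min_valid: int = 2
    top_fraction: float = 0.10
    anova_alpha: float = 0.01
    pairwise_alpha: float = 0.1
    ora_alpha: float = 0.01
    roma_alpha: float = 0.01
    ksea_alpha: float = 0.05
    ksea_min_substrates: int = 3
    roma_n_null: int = 1000
    zscore_axis: str = "sample"
    t_flavor: str = "welch"
    seed: int = 17

    def __post_init__(self) -> None:
        for name in ("anova_alpha", "pairwise_alpha", "ora_alpha", "roma_alpha", "ksea_alpha",
                     "top_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ConfigurationError(f"{name} must be in (0, 1], not {v}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _layer_sets(norm, removed, alpha, flavor, out_dir: Path, tag: str):
    """Differential + rescue for one layer; writes per-comparison TSVs."""
    anova = anova_across_lines(norm, alpha=0.01)
    anova.to_csv(out_dir / f"{tag}_anova.tsv", sep="\t", index_label="feature_id")
    per_line = vs_reference(norm, alpha=alpha, flavor=flavor)
    pu, pdn = {}, {}
    for line, frame in per_line.items():
        frame.to_csv(out_dir / f"{tag}_{line}_vs_reference.tsv", sep="\t",
                     index_label="feature_id")
        pu[line], pdn[line] = up_down_sets(frame)
    cr_up, cr_down, frames = resistance_markers(norm, alpha=alpha, flavor=flavor)
    for line, frame in frames.items():
        frame.to_csv(out_dir / f"{tag}_{line}_vs_CS.tsv", sep="\t", index_label="feature_id")
    common_up, common_down = common_oncogenic_markers(pu, pdn)
    cr_only, cs_only = presence_absence_rescue(removed)
    sets = BiomarkerSets(
        anova_significant=sorted(anova.index[anova["significant"]]),
        per_line_up=pu, per_line_down=pdn,
        cr_up=cr_up, cr_down=cr_down,
        common_up=common_up, common_down=common_down,
        cr_only=cr_only, cs_only=cs_only,
    )
    sets.to_json(out_dir / f"{tag}_biomarkers.json")
    return sets


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute every stage; returns the manifest (also written to the run dir)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int | float | dict] = {}
    inputs = {}

    design = StudyDesign.from_tsv(config.design, group_map=config.group_map or None)
    for path_attr in ("proteome_table", "phospho_table", "design", "gmt", "ks_map"):
        p = getattr(config, path_attr)
        if p:
            inputs[path_attr] = {"path": str(p), "sha256": _checksum(p)}
    for p in config.complexes:
        inputs.setdefault("complexes", []).append({"path": str(p), "sha256": _checksum(p)})

    current_stage = "design"

    def stage(name: str) -> None:
        nonlocal current_stage
        current_stage = name
        log.info("stage: %s", name)

    try:
        manifest = _run_stages(config, out, counts, inputs, design, stage)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {current_stage!r} failed: {exc}") from exc
    return manifest


def _run_stages(config, out, counts, inputs, design, stage) -> dict:
    # --- ingest + artifact filter ------------------------------------------
    stage("ingest")
    prot = read_quant_table(config.proteome_table, design, PROTEOME)
    phos = read_quant_table(config.phospho_table, design, PHOSPHO)
    counts["proteins_identified"] = len(prot)
    counts["phosphosites_identified"] = len(phos)
    prot = filter_artifacts(prot)
    phos = filter_artifacts(phos)
    for sid in config.drop_samples:
        phos = phos.drop_sample(sid)
    counts["proteins_after_artifact_filter"] = len(prot)
    counts["phosphosites_after_artifact_filter"] = len(phos)

    # --- quantification filter + normalization -----------------------------
    stage("preprocess")
    prot_kept, prot_removed = valid_value_filter(prot, config.min_valid)
    phos_kept, phos_removed = valid_value_filter(phos, config.min_valid)
    counts["proteins_quantified"] = len(prot_kept)
    counts["phosphosites_quantified"] = len(phos_kept)
    norm_p = log2_zscore(prot_kept, axis=config.zscore_axis)
    norm_f = log2_zscore(phos_kept, axis=config.zscore_axis)
    norm_p.values.to_csv(out / "proteome_normalized.tsv", sep="\t", index_label="feature_id")
    norm_f.values.to_csv(out / "phospho_normalized.tsv", sep="\t", index_label="feature_id")
    dend = hierarchical_cluster(norm_p)
    (out / "proteome_dendrogram.nwk").write_text(dend.to_newick() + "\n")
    counts["replicate_coherence"] = dend.replicate_coherence
    corr, n_shared = cross_layer_correlation(norm_p, norm_f)
    corr.to_csv(out / "cross_layer_correlation.tsv", sep="\t", header=True)
    counts["shared_proteins_across_layers"] = n_shared

    # --- abundance / housekeeping ------------------------------------------
    stage("housekeeping")
    ranking = rank_abundance(prot)
    hk = housekeeping_set(ranking, config.top_fraction)
    counts["dynamic_range_orders"] = round(ranking.dynamic_range_orders, 3)
    counts["housekeeping_per_line"] = hk.top_size
    counts["housekeeping_common"] = len(hk.intersection)
    pd.Series(hk.intersection, name="protein").to_csv(out / "housekeeping.tsv",
                                                      sep="\t", index=False)

    # --- differential / rescue ---------------------------------------------
    stage("differential")
    prot_sets = _layer_sets(norm_p, prot_removed, config.pairwise_alpha,
                            config.t_flavor, out, "proteome")
    phos_sets = _layer_sets(norm_f, phos_removed, config.pairwise_alpha,
                            config.t_flavor, out, "phospho")
    counts["biomarkers"] = {
        "proteome": {
            "anova_significant": len(prot_sets.anova_significant),
            "CR_up": len(prot_sets.cr_up), "CR_down": len(prot_sets.cr_down),
            "common_up": len(prot_sets.common_up), "common_down": len(prot_sets.common_down),
            "CR_only": len(prot_sets.cr_only), "CS_only": len(prot_sets.cs_only),
        },
        "phospho": {
            "anova_significant": len(phos_sets.anova_significant),
            "CR_up": len(phos_sets.cr_up), "CR_down": len(phos_sets.cr_down),
            "CR_only": len(phos_sets.cr_only), "CS_only": len(phos_sets.cs_only),
        },
    }

    # --- kinase activity ----------------------------------------------------
    if config.ks_map:
        stage("ksea")
        scores = build_site_scores(phos)
        kt = ksea(scores, read_ks_map(config.ks_map),
                  min_substrates=config.ksea_min_substrates, alpha=config.ksea_alpha)
        kt.to_csv(out / "kinase_activity.tsv", sep="\t", index=False)
        counts["consistent_sites"] = len(scores)
        counts["significant_kinases"] = int(kt["significant"].sum())

    # --- module activity ----------------------------------------------------
    if config.gmt:
        stage("roma")
        results, table = score_collection(
            norm_p, read_gmt(config.gmt), n_null=config.roma_n_null,
            seed=config.seed, alpha=config.roma_alpha,
        )
        table.to_csv(out / "module_activity.tsv", sep="\t", index=False)
        if results:
            group_summary(results, design).to_csv(out / "module_group_scores.tsv", sep="\t")
        counts["overdispersed_modules"] = int(table["overdispersed"].sum())

    # --- enrichment ---------------------------------------------------------
    if config.gmt:
        stage("ora")
        background = sorted(set(prot_kept.primary_gene()))
        gene_of = prot.primary_gene()
        for label, features in (("CR_up", prot_sets.cr_up), ("CR_down", prot_sets.cr_down)):
            query = sorted({gene_of.get(f, f) for f in features})
            table = ora(query, read_gmt(config.gmt), background, alpha=config.ora_alpha)
            table.to_csv(out / f"ora_{label}.tsv", sep="\t", index=False)
            counts[f"ora_{label}_significant"] = int(table["significant"].sum())

    # --- network ------------------------------------------------------------
    if config.complexes:
        stage("network")
        net = build_complex_network(config.complexes)
        counts["network_nodes"] = net.number_of_nodes()
        counts["network_edges"] = net.number_of_edges()
        bg = biomarker_subgraph(
            net, prot_sets, phos_sets, expression=norm_p,
            protein_gene_map=prot.primary_gene(),
            site_gene_map=phos.gene_symbols,
        )
        export_graph(bg, "sif", out / "biomarker_network.sif")
        export_graph(bg, "graphml", out / "biomarker_network.graphml")
        counts["biomarker_network_nodes"] = bg.graph.number_of_nodes()
        counts["biomarker_network_edges"] = bg.graph.number_of_edges()
        counts["biomarker_network_largest_component"] = (
            bg.component_sizes[0] if bg.component_sizes else 0
        )

    manifest = {
        "phosphodiff_version": __version__,
        "config_digest": config.digest(),
        "config": asdict(config),
        "inputs": inputs,
        "counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
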