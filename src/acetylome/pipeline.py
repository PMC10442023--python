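"""End-to-end orchestration: simulate -> analysis stages -> JSON report.

The run configuration is a single flat mapping with namespaced keys
(``stage.param``, e.g. ``simulate.n_proteins``, ``motif.width``); unknown
keys are rejected before any stage runs, so a misspelled key never yields a
partial run.  All randomness flows from ``pipeline.seed`` through named
substreams, and a rerun with the same config and seed is bit-identical
(reports carry no timestamps).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Dict, Optional, Set

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import catalog_stats, conservation, crosstalk, enrichment, expression
from . import motifs as motifs_mod
from . import synthetic
from .io_tables import (AnnotationTable, Proteome, SiteCatalog, write_fasta,
                        write_site_table, write_tsv)

STAGES = ("simulate", "catalog", "entropy", "motif", "conserve",
          "crosstalk", "enrich")

_SIM_FIELDS = {f.name for f in dataclasses.fields(synthetic.SyntheticConfig)}

DEFAULTS: Dict[str, object] = {
    "pipeline.seed": 0,
    "pipeline.out_dir": "results/run",
    "pipeline.stages": "all",
    "catalog.overlap_method": "min",
    "motif.width": 15,
    "motif.background": "all_K_windows",
    "motif.p_thresh": 1e-6,
    "motif.min_count": 20,
    "conserve.rule": "all_species",
    "conserve.min_aligned_frac": 0.8,
    "crosstalk.d_max": 15,
    "crosstalk.n_boot": 1000,
    "crosstalk.anchor_scope": "kac_proteins",
}


class ConfigError(ValueError):
    pass


def load_config(path: Optional[str] = None,
                overrides: Optional[Dict[str, object]] = None) -> Dict[str, object]:
    """Merge defaults <- config file <- overrides; reject unknown keys."""
    config = dict(DEFAULTS)
    raw: Dict[str, object] = {}
    if path:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        raw.update(loaded)
    raw.update(overrides or {})
    unknown = []
    for key, value in raw.items():
        if key.startswith("simulate."):
            if key.split(".", 1)[1] not in _SIM_FIELDS:
                unknown.append(key)
                continue
        elif key not in DEFAULTS:
            unknown.append(key)
            continue
        config[key] = value
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    return config


def synthetic_config(config: Dict[str, object]) -> synthetic.SyntheticConfig:
    kwargs = {k.split(".", 1)[1]: v for k, v in config.items()
              if k.startswith("simulate.")}
    kwargs["seed"] = int(config["pipeline.seed"])
    return synthetic.SyntheticConfig(**kwargs)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in sorted(obj, key=str)] \
            if isinstance(obj, (set, frozenset)) else [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# ---------------------------------------------------------------------------
# stage runners (pure: inputs -> (summary dict, {name: DataFrame}))

def stage_catalog(catalog: SiteCatalog, overlap_method: str = "min"):
    hist, mean = catalog_stats.sites_per_protein(catalog)
    overlaps = catalog_stats.pairwise_replicate_overlaps(
        catalog, method=overlap_method)
    venn_site = catalog_stats.organ_venn(catalog, level="site")
    venn_prot = catalog_stats.organ_venn(catalog, level="protein")
    ratio_col = ("ratio_min" if overlap_method == "min" else "ratio_jaccard")
    summary = {
        "n_sites": len(catalog.site_keys(ptm_type="acetyl")),
        "n_proteins": len(catalog.protein_ids(ptm_type="acetyl")),
        "mean_sites_per_protein": mean,
        "replicate_overlap_mean": (float(overlaps[ratio_col].mean())
                                   if len(overlaps) else None),
        "replicate_overlap_jaccard_mean": (
            float(overlaps["ratio_jaccard"].mean()) if len(overlaps) else None),
        "overlap_method": overlap_method,
        "site_regions_all_organs": venn_site.all_organ_count(
            venn_site.organ_totals),
        "organ_specific_site_fraction": venn_site.organ_specific_fraction,
        "organ_specific_protein_fraction": venn_prot.organ_specific_fraction,
        "venn_excluded_rows": venn_site.n_excluded,
    }
    hist_df = pd.DataFrame(sorted(hist.items()),
                           columns=["sites_per_protein", "n_proteins"])
    venn_rows = [("+".join(sorted(region)), count, venn.level)
                 for venn in (venn_site, venn_prot)
                 for region, count in sorted(venn.regions.items(),
                                             key=lambda kv: sorted(kv[0]))]
    venn_df = pd.DataFrame(venn_rows, columns=["region", "count", "level"])
    tables = {"sites_per_protein": hist_df, "replicate_overlap": overlaps,
              "venn_regions": venn_df}
    try:
        ab = catalog_stats.normalize_abundance(catalog)
        organ_tab = ab.per_organ.set_axis(
            [f"{k.protein_id}:{k.position}" for k in ab.per_organ.index])
        if organ_tab.shape[0] >= 2 and organ_tab.shape[1] >= 2:
            row_order, col_order = catalog_stats.heatmap_order(organ_tab)
            organ_tab = organ_tab.loc[row_order, col_order]
        tables["abundance_by_organ"] = organ_tab.rename_axis("site") \
                                                .reset_index()
        summary["abundance_normalization"] = ab.normalization
    except ValueError:
        summary["abundance_normalization"] = "skipped: no abundances"
    return summary, tables


def stage_entropy(expr: pd.DataFrame, kac_genes: Set[str]):
    table = expression.entropy_table(expr, kac_genes)
    contrast = expression.compare_entropy(table)
    summary = {
        "max_entropy_bits": float(np.log2(expr.shape[1])),
        "n_samples": int(expr.shape[1]),
        "rank_test_p": contrast.rank_test_p,
        "hypergeom_p": contrast.hypergeom_p,
        "median_kac": contrast.median_kac,
        "median_non": contrast.median_non,
        "effect_direction": contrast.effect_direction,
        "n_zero_expression": table.attrs["n_zero_expression"],
    }
    return summary, {"entropy_table": table}


def stage_motif(catalog: SiteCatalog, proteome: Proteome, width: int = 15,
                background_mode: str = "all_K_windows",
                p_thresh: float = 1e-6, min_count: int = 20):
    windows = motifs_mod.extract_windows(catalog, proteome, w=width)
    background = motifs_mod.background_model(proteome, mode=background_mode,
                                             w=width)
    scores = motifs_mod.position_scores(windows, background)
    bg_windows = background.windows if background.windows else \
        motifs_mod.background_model(proteome, "all_K_windows", width).windows
    motifs = motifs_mod.extract_motifs(windows, bg_windows,
                                       p_thresh=p_thresh,
                                       min_count=min_count)
    sig = [s for s in scores if s.significant]
    top = max(sig, key=lambda s: s.score, default=None)
    summary = {
        "n_windows": len(windows),
        "background": background_mode,
        "n_significant_cells": len(sig),
        "top_enriched_cell": (f"{top.position:+d}/{top.residue}"
                              if top else None),
        "motifs": [m.text for m in motifs],
    }
    motif_df = pd.DataFrame(
        [(m.text, json.dumps(_jsonable(m.constraints)), m.fg_matches,
          m.fg_total, m.bg_matches, m.bg_total, m.p_value) for m in motifs],
        columns=["motif", "constraints", "fg_matches", "fg_total",
                 "bg_matches", "bg_total", "p_value"])
    return summary, {"position_scores": motifs_mod.scores_frame(scores),
                     "motifs": motif_df}


def stage_conserve(alignments, ack_truth, rule: str = "all_species",
                   min_aligned_frac: float = 0.8):
    records = conservation.classify_all(alignments, ack_truth,
                                        conservation_rule=rule,
                                        min_aligned_frac=min_aligned_frac)
    contrast = conservation.conservation_contrast(records)
    spectrum = conservation.substitution_spectrum(records)
    summary = {
        "n_ack": int(sum(r.is_ack and not r.excluded for r in records)),
        "n_non_ack": int(sum((not r.is_ack) and not r.excluded
                             for r in records)),
        "n_excluded": int(sum(r.excluded for r in records)),
        "frac_ack_conserved": contrast.frac_ack_conserved,
        "frac_non_conserved": contrast.frac_non_conserved,
        "chi2": contrast.chi2,
        "p_value": contrast.p_value,
        "substitution_spectrum": dict(sorted(spectrum.items())),
    }
    rec_df = pd.DataFrame(
        [(r.protein_id, r.reference_position, r.is_ack, r.n_species_aligned,
          r.n_species_with_k, r.conserved, r.excluded,
          "".join(sorted(r.substitutions.elements())))
         for r in records],
        columns=["protein_id", "position", "is_ack", "n_aligned", "n_with_k",
                 "conserved", "excluded", "substitutions"])
    spec_df = pd.DataFrame(sorted(spectrum.items()),
                           columns=["residue", "count"])
    return summary, {"conservation_records": rec_df,
                     "substitution_spectrum": spec_df}


def stage_crosstalk(proteome: Proteome, kac_catalog: SiteCatalog,
                    other_catalog: SiteCatalog,
                    annotation: Optional[AnnotationTable] = None,
                    d_max: int = 15, n_boot: int = 1000, seed: int = 0,
                    anchor_scope: str = "kac_proteins"):
    sets = {"acetyl": kac_catalog.protein_ids(ptm_type="acetyl")}
    for ptm in sorted(set(other_catalog.frame.ptm_type)):
        sets[ptm] = other_catalog.protein_ids(ptm_type=ptm)
    tests, regions = crosstalk.protein_overlap(sets, len(proteome))
    shared = crosstalk.site_overlap(kac_catalog, other_catalog)
    profile = crosstalk.positional_profile(
        proteome, kac_catalog.site_keys(ptm_type="acetyl"),
        other_catalog.site_keys(ptm_type="phospho"),
        d_max=d_max, n_boot=n_boot, seed=seed, anchor_scope=anchor_scope)
    summary = {
        "protein_overlap_pct": {
            f"{t.ptm_a}&{t.ptm_b}": t.percent_of_a for t in tests},
        "protein_overlap_p": {
            f"{t.ptm_a}&{t.ptm_b}": t.p_value for t in tests},
        "shared_site_counts": {ptm: cnt for ptm, (cnt, _) in shared.items()},
        "ack_phospho_fraction_d1": float(
            profile.query("anchor_class == 'acK' and residue == 'combined' "
                          "and d == 1")["fraction"].iloc[0]),
    }
    tables = {"positional_profile": profile,
              "protein_overlap": pd.DataFrame([vars(t) for t in tests])}
    if annotation is not None and "phospho" in sets:
        dual = crosstalk.dual_modification_enrichment(
            annotation, sets["acetyl"], sets["phospho"], set(proteome))
        tables["dual_modification_enrichment"] = dual
        summary["n_dual_terms_tested"] = int(len(dual))
    return summary, tables


def stage_enrich(kac_proteins: Set[str], annotation: AnnotationTable,
                 universe: Set[str]):
    result = enrichment.term_enrichment(kac_proteins & universe, annotation,
                                        universe)
    tally = enrichment.set_tally(kac_proteins, annotation)
    summary = {
        "n_terms_tested": int(len(result)),
        "top_terms": list(result.head(3)["term"]) if len(result) else [],
        "top_tally": list(tally.head(3)["term"]) if len(tally) else [],
    }
    return summary, {"term_enrichment": result, "term_tally": tally}


# ---------------------------------------------------------------------------

def run_pipeline(config: Dict[str, object],
                 out_dir: Optional[str] = None) -> dict:
    """Run simulate + every analysis stage on the synthetic data and write
    per-stage TSVs plus a deterministic JSON report."""
    config = load_config(overrides=config)
    out = Path(out_dir or str(config["pipeline.out_dir"]))
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config["pipeline.seed"])
    sim = synthetic_config(config)

    report: dict = {"config": _jsonable({**config, "pipeline.seed": seed}),
                    "version": __version__, "stages": {}, "warnings": {}}

    proteome0 = synthetic.generate_proteome(sim)
    acetylome = synthetic.generate_acetylome(proteome0, sim)
    proteome = acetylome.proteome
    truth_keys = acetylome.truth_keys_by_protein()
    others = synthetic.generate_ptm_sites(proteome, truth_keys, sim)
    kac_gene_ids = {proteome.gene_of(pid) for pid in truth_keys}
    gene_ids = [proteome.gene_of(pid) for pid in proteome]
    expr = synthetic.generate_expression(
        gene_ids, [g in kac_gene_ids for g in gene_ids], sim)
    alignments = synthetic.generate_alignments(
        proteome, truth_keys, sim, protein_ids=sorted(truth_keys))
    annotation = synthetic.generate_annotation(proteome, sim)
    report["warnings"].update(acetylome.warnings)

    sim_dir = out / "synthetic"
    sim_dir.mkdir(exist_ok=True)
    write_fasta(proteome, sim_dir / "proteome.fasta")
    write_site_table(acetylome.catalog, sim_dir / "sites_acetyl.tsv")
    write_site_table(others, sim_dir / "sites_other.tsv")
    write_tsv(acetylome.truth, sim_dir / "truth_acetyl.tsv")
    from .io_tables import (write_alignment_fasta, write_annotation,
                            write_expression_matrix)
    write_expression_matrix(expr, sim_dir / "expression.tsv")
    write_annotation(annotation, sim_dir / "annotation.tsv")
    aln_dir = sim_dir / "alignments"
    aln_dir.mkdir(exist_ok=True)
    for pid, aln in alignments.items():
        write_alignment_fasta(aln.reference_id, aln.reference_row,
                              aln.species, aln.rows,
                              aln_dir / f"{pid}.fasta")
    with open(sim_dir / "provenance.json", "w") as fh:
        json.dump({"seed": seed, "config": _jsonable(sim.to_dict())}, fh,
                  indent=2, sort_keys=True)
    report["stages"]["simulate"] = {
        "n_proteins": len(proteome),
        "n_true_sites": int(acetylome.truth.drop_duplicates(
            ["protein_id", "position"]).shape[0]),
        "n_observed_rows": len(acetylome.catalog),
        "n_other_ptm_rows": len(others),
    }

    stage_outputs = {
        "catalog": lambda: stage_catalog(
            acetylome.catalog, str(config["catalog.overlap_method"])),
        "entropy": lambda: stage_entropy(expr, kac_gene_ids),
        "motif": lambda: stage_motif(
            acetylome.catalog, proteome, int(config["motif.width"]),
            str(config["motif.background"]),
            float(config["motif.p_thresh"]), int(config["motif.min_count"])),
        "conserve": lambda: stage_conserve(
            alignments, truth_keys, str(config["conserve.rule"]),
            float(config["conserve.min_aligned_frac"])),
        "crosstalk": lambda: stage_crosstalk(
            proteome, acetylome.catalog, others, annotation,
            int(config["crosstalk.d_max"]), int(config["crosstalk.n_boot"]),
            seed, str(config["crosstalk.anchor_scope"])),
        "enrich": lambda: stage_enrich(
            acetylome.catalog.protein_ids(ptm_type="acetyl"), annotation,
            set(proteome)),
    }
    for stage, runner in stage_outputs.items():
        summary, tables = runner()
        report["stages"][stage] = _jsonable(summary)
        stage_dir = out / stage
        stage_dir.mkdir(exist_ok=True)
        for name, frame in tables.items():
            write_tsv(frame, stage_dir / f"{name}.tsv")

    with open(out / "report.json", "w") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True)
    return report
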