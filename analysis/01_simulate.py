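#!/usr/bin/env python
"""Generate the synthetic five-organ acetylome study and write its fixtures.

Produces, under results/synthetic/: the proteome FASTA (flanks of chosen
sites carry the +1 R/K/N/H bias), the observed acetyl site table with
organ/replicate/abundance context, the ground-truth site list, the
co-occurring phospho/Ub/SUMO table, the 158-sample expression matrix, a
compartment annotation, and a provenance record.
"""

import json
from pathlib import Path

from acetylome import pipeline, synthetic
from acetylome.io_tables import (write_annotation, write_expression_matrix,
                                 write_fasta, write_site_table, write_tsv)

SEED = 1
OUT = Path("results/synthetic")


def build_study(seed: int = SEED):
    cfg = pipeline.synthetic_config(
        pipeline.load_config(overrides={"pipeline.seed": seed}))
    proteome = synthetic.generate_proteome(cfg)
    acet = synthetic.generate_acetylome(proteome, cfg)
    truth_keys = acet.truth_keys_by_protein()
    others = synthetic.generate_ptm_sites(acet.proteome, truth_keys, cfg)
    kac_genes = {acet.proteome.gene_of(p) for p in truth_keys}
    gene_ids = [acet.proteome.gene_of(p) for p in acet.proteome]
    expr = synthetic.generate_expression(
        gene_ids, [g in kac_genes for g in gene_ids], cfg)
    alignments = synthetic.generate_alignments(
        acet.proteome, truth_keys, cfg, protein_ids=sorted(truth_keys))
    annotation = synthetic.generate_annotation(acet.proteome, cfg)
    return cfg, acet, others, expr, alignments, annotation, kac_genes


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    cfg, acet, others, expr, alignments, annotation, _ = build_study()
    write_fasta(acet.proteome, OUT / "proteome.fasta")
    write_site_table(acet.catalog, OUT / "sites_acetyl.tsv")
    write_site_table(others, OUT / "sites_other.tsv")
    write_tsv(acet.truth, OUT / "truth_acetyl.tsv")
    write_expression_matrix(expr, OUT / "expression.tsv")
    write_annotation(annotation, OUT / "annotation.tsv")
    with open(OUT / "provenance.json", "w") as fh:
        json.dump({"seed": cfg.seed, "config": cfg.to_dict()}, fh,
                  indent=2, sort_keys=True)
    n_sites = acet.truth.drop_duplicates(["protein_id", "position"]).shape[0]
    print(f"proteome: {len(acet.proteome)} proteins")
    print(f"true acetyl sites: {n_sites} on "
          f"{acet.truth.protein_id.nunique()} proteins "
          f"(~{n_sites / acet.truth.protein_id.nunique():.1f} per protein)")
    print(f"observed catalog rows: {len(acet.catalog)} "
          f"(organ x replicate observations at q={cfg.detection_prob})")
    print(f"other PTM rows: {len(others)}; fixtures under {OUT}/")


if __name__ == "__main__":
    main()
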