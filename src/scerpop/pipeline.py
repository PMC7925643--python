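"""End-to-end driver: simulate -> QC -> diversity -> RRHS -> pan-genome ->
allele scan -> enrichment, writing every declared output file.

This is the glue the ``scerpop pipeline`` CLI command calls; each stage is
just the corresponding library function, so the driver doubles as a worked
example of the API.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import allelescan, diversity, enrichment, io, pangenome, phylo, qc, simulate

logger = logging.getLogger(__name__)


def run_pipeline(
    config: simulate.SimulationConfig,
    outdir: str | Path,
    reps: int = 100,
    write_site_calls: bool = False,
) -> dict:
    """Run the whole synthetic analysis; returns a summary dict of outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"outputs": {}}

    def emit(name: str, path: Path) -> Path:
        summary["outputs"][name] = str(path)
        return path

    # --- simulate -----------------------------------------------------------
    gm, pm, truth = simulate.simulate_population(config)
    io.write_vcf(gm, emit("genotypes_vcf", outdir / "genotypes.vcf"))
    io.write_sample_sheet(pm, emit("sample_sheet", outdir / "samples.tsv"))
    calls_a = simulate.simulate_read_support(gm, config, caller_id="A")
    calls_b = simulate.simulate_read_support(gm, config, caller_id="B")
    if write_site_calls:
        io.write_site_calls(calls_a, emit("site_calls_a", outdir / "site_calls_A.tsv"))
        io.write_site_calls(calls_b, emit("site_calls_b", outdir / "site_calls_B.tsv"))

    # --- variant QC ---------------------------------------------------------
    gm_qc, qc_log = qc.run_qc_cascade(calls_a, calls_b, gm.sites, gm.isolates)
    qc_log.to_csv(emit("qc_log", outdir / "qc_log.tsv"), sep="\t", index=False)
    io.write_vcf(gm_qc, emit("snps_qc_vcf", outdir / "snps.qc.vcf"))
    summary["n_sites_raw"] = gm.n_sites
    summary["n_sites_qc"] = gm_qc.n_sites

    # --- heterozygosity and diversity --------------------------------------
    het = diversity.het_ratio(gm_qc, truth.consensus_sizes)
    het.to_csv(emit("het", outdir / "het.tsv"), sep="\t", index=False)
    div = diversity.diversity_table(gm_qc, pm, genome_length=config.genome_length)
    div.to_csv(emit("diversity", outdir / "diversity.tsv"), sep="\t", index=False)

    # --- structure: MAF + LD pruning, then PCA ------------------------------
    gm_struct = qc.structure_filters(gm_qc)
    coords, _ = diversity.snp_pca(gm_struct)
    coords.to_csv(emit("snp_pca", outdir / "snp_pca.tsv"), sep="\t", index_label="isolate")
    summary["n_sites_structure"] = gm_struct.n_sites

    # --- RRHS consensus phylogeny -------------------------------------------
    ct = phylo.rrhs_consensus(gm_qc, reps=reps, seed=config.seed)
    emit("consensus_tree", outdir / "consensus.nwk").write_text(ct.newick + "\n")
    splits = ct.splits.copy()
    splits["members"] = splits["members"].map(lambda s: ",".join(sorted(s)))
    splits.to_csv(emit("consensus_splits", outdir / "consensus_splits.tsv"), sep="\t", index=False)

    # --- pan-genome ----------------------------------------------------------
    orfs = simulate.simulate_orf_catalog(config, pm, truth)
    io.write_fasta(orfs.catalog, emit("orf_catalog", outdir / "orfs.fasta"))
    aln_dir = outdir / "alignments"
    io.write_alignment_tables(orfs.alignments, aln_dir)
    summary["outputs"]["alignment_dir"] = str(aln_dir)
    qlens = {o: len(s) for o, s in orfs.catalog.items()}
    presence = pangenome.call_orf_presence(orfs.alignments, qlens, pm.isolates)
    io.write_presence_matrix(presence, emit("presence", outdir / "presence.tsv"))
    presence_f = pangenome.rarity_filter(presence)
    venn = pangenome.venn_partition(presence_f, pm)
    pd.DataFrame(
        [("&".join(k), len(v)) for k, v in sorted(venn.items())],
        columns=["region", "n_orfs"],
    ).to_csv(emit("venn", outdir / "venn.tsv"), sep="\t", index=False)
    groups = pm.groups
    gm_rows = []
    for hi_grp in groups:
        for lo_grp in groups:
            if hi_grp != lo_grp:
                for orf in sorted(pangenome.group_majority_genes(presence_f, pm, hi_grp, lo_grp)):
                    gm_rows.append((hi_grp, lo_grp, orf))
    pd.DataFrame(gm_rows, columns=["group_hi", "group_lo", "orf"]).to_csv(
        emit("group_majority", outdir / "group_majority_genes.tsv"), sep="\t", index=False
    )
    lin_spec = pangenome.lineage_specific_genes(presence_f, pm)
    pd.DataFrame(
        [(lin, orf) for lin, orfs_ in sorted(lin_spec.items()) for orf in sorted(orfs_)],
        columns=["lineage", "orf"],
    ).to_csv(emit("lineage_specific", outdir / "lineage_specific_genes.tsv"), sep="\t", index=False)
    novel, _ = pangenome.classify_novel_orfs(
        orfs.predicted_alignments, orfs.predicted_ids, list(orfs.catalog), orfs.predicted_lengths
    )
    pd.DataFrame(sorted(novel), columns=["novel_orf"]).to_csv(
        emit("novel_orfs", outdir / "novel_orfs.tsv"), sep="\t", index=False
    )
    gc_coords, _ = pangenome.embed_presence(presence_f)
    gc_coords.to_csv(emit("gene_content_pca", outdir / "gene_content_pca.tsv"), sep="\t", index_label="isolate")

    # --- allele scan ---------------------------------------------------------
    genes = simulate.simulate_gene_intervals(config)
    io.write_bed(genes, emit("genes_bed", outdir / "genes.bed"))
    dom = config.domesticated_groups()
    n_avail = allelescan.sharing_filter(gm_qc).n_sites
    scan_p = allelescan.AlleleScanParams(
        subsample_n=min(10_000, n_avail), seed=config.seed
    )
    hits = allelescan.run_allele_scan(gm_qc, pm, dom[0], dom[1], genes=genes, p=scan_p)
    hits.to_csv(emit("allele_scan", outdir / "allele_scan.tsv"), sep="\t", index=False)

    # --- enrichment of genes harbouring group-specific alleles ---------------
    planted_sites = pd.DataFrame(
        [(c, p) for c, p in truth.planted_group_specific_sites], columns=["chrom", "pos"]
    )
    planted_genes = set(
        allelescan.map_snps_to_genes(planted_sites, genes)["gene"].dropna()
    )
    universe = set(genes["name"])
    terms = simulate.simulate_annotations(
        config, sorted(universe), planted_sets={"group_specific": planted_genes}
    )
    io.write_term_annotations(terms, emit("annotations", outdir / "annotations.tsv"))
    query = set()
    if "genes" in hits.columns:
        for cell in hits["genes"].dropna():
            query.update(cell.split(","))
    if query:
        results = enrichment.hypergeom_enrich(query, terms, universe)
        enrichment.results_table(results).to_csv(
            emit("enrichment", outdir / "enrichment.tsv"), sep="\t", index=False
        )
        _, nodes, edges = enrichment.build_enrichment_network(results, terms, universe)
        nodes.to_csv(emit("network_nodes", outdir / "network_nodes.tsv"), sep="\t", index=False)
        edges.to_csv(emit("network_edges", outdir / "network_edges.tsv"), sep="\t", index=False)
        summary["n_significant_terms"] = int(sum(r.significant for r in results))
    summary["n_group_specific_allele_sites"] = int(hits[["chrom", "pos"]].drop_duplicates().shape[0])
    summary["n_group_majority_genes"] = len(gm_rows)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
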