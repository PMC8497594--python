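"""End-to-end orchestrator: simulate -> align -> Ka/Ks -> synteny -> dating
meta-analysis -> enrichment -> popgen, with the analysis thresholds collected
in one configuration object.

The default thresholds are the canonical ones of the analysis this pipeline
reproduces: homology e-value 1e-10, blocks of >= 5 anchors with rank gaps
<= 25, alignment gates > 150 aa and >= 50% coverage (>= 100 aa for dating
families), Ks windows 0.2-0.6 (focal duplicates), 0.5-1.2 (outgroup
orthologs) and 0.05-0.30 (within-clade orthologs), MCMC burn-in 1000 samples
with ESS >= 200, 1000 bootstrap resamples, < 30% ambiguity at 5x depth for
gene presence, FDR 0.05.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from .dating import consensus_with_ci
from .divergence import estimate_ka_ks, ks_distribution_mode
from .enrichment import retention_enrichment_test, table2_style_report
from .popgen import diversity_summary, gene_presence_filter
from .seqalign import (
    alignment_passes_filters,
    backtranslate_alignment,
    clean_alignment_columns,
    global_protein_align,
    translate_cds,
)
from .simulate import (
    SimulationConfig,
    simulate_coverage_and_labels,
    simulate_coalescent_sample,
    simulate_family_ages,
    simulate_wgd_dataset,
)
from .synteny import (
    chain_collinear_blocks,
    classify_orthology,
    detect_tandem_duplicates,
    dotplot_table,
    find_homolog_anchors,
)


@dataclass
class AnalysisConfig:
    seed: int = 0
    evalue_cutoff: float = 1e-10
    min_block: int = 5
    max_gap: int = 25
    min_aln_len_aa: int = 150
    min_coverage: float = 0.5
    clean_flank: int = 3
    dup_ks_window: tuple = (0.2, 0.6)
    outgroup_ks_window: tuple = (0.5, 1.2)
    clade_ks_window: tuple = (0.05, 0.30)
    dating_min_aln_len_aa: int = 100
    burn_in: int = 1000
    min_ess: float = 200.0
    n_bootstrap: int = 1000
    max_ambiguous: float = 0.30
    min_depth: int = 5
    fdr_cutoff: float = 0.05
    max_event_ks: float = 5.0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def hash(self) -> str:
        return wio.config_hash(self.to_dict())


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: dict
    results: dict
    outputs: dict

    def percent(self, numerator_key: str, denominator_key: str) -> int:
        """Integer-rounded percentage between two recorded count fields."""
        return percent(self.counts[numerator_key], self.counts[denominator_key])

    def to_json(self) -> str:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "counts": self.counts,
            "results": self.results,
            "outputs": {k: str(v) for k, v in self.outputs.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True, default=float)


def percent(numerator: float, denominator: float) -> int:
    """Integer-rounded percentage as printed in summary reports."""
    if denominator == 0:
        raise ValueError("denominator count is zero")
    return int(round(100.0 * numerator / denominator))


def ka_ks_for_pair(cds_a: str, cds_b: str, cfg: AnalysisConfig, id_a: str = "a", id_b: str = "b"):
    """Align, back-translate, clean and (if the gates pass) estimate Ka/Ks.

    Returns (KsEstimate | None, passed_filters).  When the two coding
    sequences have equal length and translate without gaps against each other
    the alignment step is still executed so every pair goes through one code
    path.
    """
    prot_a, prot_b = translate_cds(cds_a), translate_cds(cds_b)
    paln = global_protein_align(prot_a, prot_b)
    caln = backtranslate_alignment(paln, cds_a, cds_b, id_a=id_a, id_b=id_b)
    cleaned = clean_alignment_columns(caln, flank=cfg.clean_flank)
    if not alignment_passes_filters(cleaned, cfg.min_aln_len_aa, cfg.min_coverage):
        return None, False
    return estimate_ka_ks(cleaned), True


def run_full_analysis(cfg: AnalysisConfig, outdir: str | Path | None = None) -> RunReport:
    """Run the whole analysis graph on a simulated dataset.

    Stages: dataset simulation; codon-level Ks estimation of the true WGD
    duplicate pairs (through the alignment/cleaning/filter path); synteny
    chaining and 1:1 / 1:2 orthology calls with tandem detection; the Ks-peak
    estimate; the consensus-age meta-analysis with bootstrap CI; the
    retention-by-expression enrichment test; coalescent diversity summaries
    and the gene presence filter.  Deterministic given cfg.seed.
    """
    rng_children = np.random.SeedSequence(cfg.seed).spawn(4)
    rng_ages, rng_boot, rng_coal, rng_cov = (np.random.default_rng(s) for s in rng_children)
    sim_cfg = dataclasses.replace(cfg.simulation, seed=cfg.seed)
    data = simulate_wgd_dataset(sim_cfg)
    counts: dict = {
        "simulated_ancestral_genes": int(sim_cfg.n_ancestral_genes),
        "ingroup_genes": int(len(data.ingroup_genes)),
        "true_retained_pairs": int(len(data.truth.pairs)),
    }
    results: dict = {}
    outputs: dict = {}

    # --- Ka/Ks over true duplicate pairs -------------------------------
    ks_rows = []
    n_filtered = 0
    for pr in data.truth.pairs.itertuples(index=False):
        est, passed = ka_ks_for_pair(
            data.ingroup_cds[pr.dup1], data.ingroup_cds[pr.dup2], cfg, id_a=pr.dup1, id_b=pr.dup2
        )
        if not passed:
            n_filtered += 1
            continue
        if est.saturated:
            continue
        ks_rows.append((pr.dup1, pr.dup2, est.ks, est.ka, est.omega))
    ks_df = pd.DataFrame(ks_rows, columns=["dup1", "dup2", "ks", "ka", "omega"])
    counts["duplicate_pairs_with_ks"] = int(len(ks_df))
    counts["duplicate_pairs_filtered"] = int(n_filtered)
    if len(ks_df) >= 2:
        mode, grid, dens = ks_distribution_mode(ks_df["ks"].to_numpy())
        results["ks_peak_mode"] = float(mode)

    # --- synteny ---------------------------------------------------------
    anchors = find_homolog_anchors(
        data.hits, data.outgroup_genes, data.ingroup_genes, evalue_cutoff=cfg.evalue_cutoff
    )
    blocks = chain_collinear_blocks(anchors, min_block=cfg.min_block, max_gap=cfg.max_gap)
    homolog_genes = set(data.hits["query"])
    groups, retention, excluded = classify_orthology(
        blocks, data.outgroup_genes, data.ingroup_genes, homolog_in_genes=homolog_genes
    )
    best_hits = (
        data.hits.sort_values(["query", "bitscore"], ascending=[True, False])
        .drop_duplicates("query")
        .set_index("query")["subject"]
        .to_dict()
    )
    tandem = detect_tandem_duplicates(data.ingroup_genes, best_hits, retention)
    counts["anchors"] = len(anchors)
    counts["collinear_blocks"] = len(blocks)
    counts["orthology_groups"] = len(groups)
    counts["one_to_two_groups"] = sum(1 for g in groups if g.relation == "one_to_two")
    counts["syntenic_genes"] = int((retention["category"] == "A").sum())
    counts["retained_genes"] = int(retention["retained"].sum())
    counts["tandem_genes"] = len(tandem)
    counts["excluded_multiblock_outgroup_genes"] = len(excluded)
    if counts["syntenic_genes"]:
        results["retained_pct_of_syntenic"] = percent(
            counts["retained_genes"], counts["syntenic_genes"]
        )

    # --- dating meta-analysis -------------------------------------------
    ages = simulate_family_ages(sim_cfg.wgd_age_ma, sim_cfg.n_families, sim_cfg.family_age_sd, rng_ages)
    ages = consensus_with_ci(ages, B=cfg.n_bootstrap, rng=rng_boot)
    results["consensus_age_ma"] = float(ages.mode)
    results["consensus_age_ci"] = [float(ages.ci[0]), float(ages.ci[1])]
    counts["dating_families"] = int(ages.medians.size)

    # --- enrichment ------------------------------------------------------
    gene_class = data.truth.genes.set_index("ancestral_id")["class"]
    in_genes = data.ingroup_genes[["gene_id"]].copy()
    in_genes["class"] = in_genes["gene_id"].str.extract(r"IN_(g\d+)")[0].map(gene_class)
    coverage, labels = simulate_coverage_and_labels(in_genes, sim_cfg.n_samples, sim_cfg, rng_cov)
    enr = retention_enrichment_test(retention, labels)
    for r in enr:
        results[f"enrichment_{r.direction}_p_adjusted"] = float(round(r.p_adjusted, 4))
    counts["de_up_genes"] = int((labels["direction"] == "up").sum())
    counts["de_down_genes"] = int((labels["direction"] == "down").sum())

    # --- popgen ----------------------------------------------------------
    n_hap, theta, L = sim_cfg.coalescent
    hap = simulate_coalescent_sample(int(n_hap), float(theta), int(L), rng_coal)
    div = diversity_summary(hap)
    results["pi_per_site"] = div.pi_per_site
    results["theta_w_per_site"] = div.theta_w_per_site
    results["tajimas_d"] = div.tajimas_d if div.d_defined else None
    counts["segregating_sites"] = div.S

    presence, conserved = gene_presence_filter(coverage, max_ambiguous=cfg.max_ambiguous)
    counts["conserved_genes"] = len(conserved)
    counts["coverage_tested_genes"] = int(len(coverage))
    results["conserved_pct"] = percent(counts["conserved_genes"], counts["coverage_tested_genes"])

    report = RunReport(config_hash=cfg.hash, seed=cfg.seed, counts=counts, results=results, outputs=outputs)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        prov = {"config_hash": cfg.hash, "seed": cfg.seed}
        wio.write_fasta(data.ingroup_cds, outdir / "ingroup_cds.fasta")
        wio.write_fasta(data.outgroup_cds, outdir / "outgroup_cds.fasta")
        wio.write_table(data.ingroup_genes, outdir / "ingroup_genes.tsv", prov)
        wio.write_table(data.outgroup_genes, outdir / "outgroup_genes.tsv", prov)
        wio.write_table(data.hits, outdir / "hits.tsv", prov)
        wio.write_table(ks_df, outdir / "duplicate_ks.tsv", prov)
        wio.write_table(dotplot_table(blocks), outdir / "dotplot.tsv", prov)
        wio.write_table(retention, outdir / "retention.tsv", prov)
        wio.write_table(labels, outdir / "de_labels.tsv", prov)
        (outdir / "report.json").write_text(report.to_json())
        for name in (
            "ingroup_cds.fasta",
            "outgroup_cds.fasta",
            "duplicate_ks.tsv",
            "dotplot.tsv",
            "retention.tsv",
            "report.json",
        ):
            report.outputs[name] = outdir / name
    return report


def table2_report(up: tuple[int, int, int, int], down: tuple[int, int, int, int]) -> pd.DataFrame:
    """Adjusted p-values for externally supplied up/down 2x2 counts."""
    return table2_style_report({"up": up, "down": down})
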