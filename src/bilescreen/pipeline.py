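"""End-to-end pipeline orchestration and bundled fixture generation.

``run_cohort_analysis`` is the library entry point every driver (the
numbered analysis scripts, the tests, the acceptance script) goes through:
screen → assign → cluster → abundance → statistics over an in-memory
cohort, returning tables.  ``run_pipeline`` wraps it with configuration
validation, output serialization (TSV, Newick, run log) and fail-fast
semantics; ``make_fixtures`` generates the small bundled synthetic dataset
used by the test suite.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as ab
from . import community as comm
from . import stats as st
from .clustering import ClusterModel, cluster_proteins, species_cluster_table
from .refdb import SearchConfig, write_genome_db, write_protein_db
from .search import two_pass_screen
from .synthetic import CohortResult, CohortSpec, simulate_cohort
from .taxonomy import GenomeSearchIndex, assign_hit_reads, summarize_assignment_rate
from .validation import extract_flanked_region, make_decoy_reference, specificity_by_sample

log = logging.getLogger(__name__)


@dataclass
class CohortAnalysis:
    """Everything the statistics stage consumes, plus stage counters."""

    abundance: pd.DataFrame  # long format
    assignment_rates: pd.DataFrame  # per sample × family totals
    cluster_model: ClusterModel
    stage_counts: pd.DataFrame  # per sample: reads, candidates, hits, assigned
    hit_tables: dict[str, pd.DataFrame]
    assignments: dict[str, pd.DataFrame]


def run_cohort_analysis(
    community: comm.Community,
    cohort: CohortResult,
    cfg: SearchConfig | None = None,
    *,
    cluster_k: int = 4,
    taxonomy_method: str = "seeded",
    keep_tables: bool = True,
) -> CohortAnalysis:
    """Screen, assign and stratify every sample of a cohort."""
    cfg = cfg or SearchConfig()
    model = cluster_proteins(community.proteins, k=cluster_k)
    genome_index = (
        GenomeSearchIndex(community.genomes) if taxonomy_method == "seeded" else None
    )
    per_sample = []
    rate_rows = []
    count_rows = []
    hit_tables: dict[str, pd.DataFrame] = {}
    assignment_tables: dict[str, pd.DataFrame] = {}
    for sample in cohort.samples:
        hits = two_pass_screen(sample, community.proteins, cfg)
        asg = assign_hit_reads(
            sample, hits, community.genomes, cfg,
            method=taxonomy_method, index=genome_index,
        )
        rates = summarize_assignment_rate(hits, asg)
        rates.insert(0, "sample_id", sample.sample_id)
        rates.insert(1, "group", sample.group)
        rate_rows.append(rates)
        count_rows.append(
            (
                sample.sample_id, sample.group, sample.n_reads,
                int(hits["read_index"].nunique()) if len(hits) else 0,
                len(hits),
                int((asg["genome_id"] != "").sum()) if len(asg) else 0,
            )
        )
        per_sample.append(
            (sample.sample_id, sample.group, hits, asg, sample.n_reads)
        )
        if keep_tables:
            hit_tables[sample.sample_id] = hits
            assignment_tables[sample.sample_id] = asg
    long = ab.cohort_abundance(per_sample, model.cluster_of)
    return CohortAnalysis(
        abundance=long,
        assignment_rates=pd.concat(rate_rows, ignore_index=True)
        if rate_rows
        else pd.DataFrame(),
        cluster_model=model,
        stage_counts=pd.DataFrame(
            count_rows,
            columns=["sample_id", "group", "reads", "hit_reads", "hits", "assigned_reads"],
        ),
        hit_tables=hit_tables,
        assignments=assignment_tables,
    )


def group_comparisons(
    long: pd.DataFrame, strata: list[tuple[str, str]] | None = None
) -> pd.DataFrame:
    """Mann–Whitney (2 groups) or Kruskal–Wallis (>=3) per family × stratum."""
    rows = []
    targets = (
        strata
        if strata is not None
        else sorted(set(zip(long["family"], long["stratum"])))
    )
    n_groups = long["group"].nunique()
    for family, stratum in targets:
        sub = long[(long["family"] == family) & (long["stratum"] == stratum)]
        if len(sub) == 0:
            continue
        values = sub["hits_per_million"].to_numpy()
        labels = sub["group"].to_numpy()
        if n_groups == 2:
            res = st.mann_whitney_u(values, labels)
        else:
            res = st.kruskal_wallis(values, labels)
        group_desc = "; ".join(
            f"{lab}: n={n}, MR={mr:.2f}" for lab, n, mr in res.rank_summary.groups
        )
        rows.append(
            (family, stratum, res.statistic, res.p_value, st.format_p(res.p_value),
             res.tie_correction, group_desc)
        )
    return pd.DataFrame(
        rows,
        columns=["family", "stratum", "statistic", "p", "p_printed",
                 "tie_correction", "mean_ranks"],
    )


# --------------------------------------------------------------------------
# configured, serialising pipeline
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    out_dir: str | Path = "pipeline_out"
    seed: int = 1
    community_seed: int = 20140
    genome_len: int = 50_000
    groups: tuple[tuple[str, int], ...] = (("control", 20), ("disease", 20))
    effect: float = 0.5
    read_count: int = 200_000
    error_rate: float = 0.01
    search: SearchConfig = field(default_factory=SearchConfig)
    cluster_k: int = 4
    alpha: float = 0.05
    alpha_strict: float = 0.01
    decoy_fraction: float = 0.0
    validation_regions_per_sample: int = 25
    write_reads: bool = False

    def validate(self) -> None:
        if not 0 < self.alpha_strict <= self.alpha < 1:
            raise ValueError("alpha levels must satisfy 0 < strict <= alpha < 1")
        if self.read_count < 1:
            raise ValueError("read_count must be positive")


def default_cohort_spec(config: PipelineConfig) -> CohortSpec:
    effects = (
        comm.disease_effects(config.effect)
        if any(label == "disease" for label, _ in config.groups)
        else {}
    )
    return CohortSpec(
        groups=list(config.groups),
        base_weights=comm.BASE_WEIGHTS,
        effects=effects,
        compensator="g_background",
        read_count=config.read_count,
        error_rate=config.error_rate,
        seed=config.seed,
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis under a config, writing outputs to out_dir.

    Outputs: abundance long/wide TSVs, per-family statistics TSV, Spearman
    heatmap TSV, species→cluster TSV, guide tree Newick, specificity TSV,
    reference database files, and a JSON run log with per-stage counts.
    A failure marker file is left behind if any stage raises.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    if marker.exists():
        marker.unlink()
    t0 = time.time()
    try:
        result = _run_pipeline_stages(config, out)
    except Exception as exc:
        marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    if marker.exists():
        marker.unlink()
    result["elapsed_s"] = round(time.time() - t0, 2)
    cfg_text = json.dumps(_config_dict(config), sort_keys=True)
    result["config_sha256"] = hashlib.sha256(cfg_text.encode()).hexdigest()
    (out / "run_log.json").write_text(json.dumps(result, indent=2, default=str))
    return result


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    d["out_dir"] = str(d["out_dir"])
    return d


def _run_pipeline_stages(config: PipelineConfig, out: Path) -> dict:
    community = comm.build_community(config.community_seed, config.genome_len)
    write_protein_db(community.proteins, out / "proteins.fasta")
    write_genome_db(
        community.genomes, out / "genomes.fasta", out / "gene_loci.tsv",
        out / "lineage.tsv",
    )
    spec = default_cohort_spec(config)
    cohort = simulate_cohort(spec, community.genomes)
    cohort.metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
    cohort.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
    if config.write_reads:
        reads_dir = out / "reads"
        reads_dir.mkdir(exist_ok=True)
        for s in cohort.samples:
            s.to_fasta(reads_dir / f"{s.sample_id}.fasta")

    analysis = run_cohort_analysis(
        community, cohort, config.search, cluster_k=config.cluster_k,
        keep_tables=True,
    )
    analysis.abundance.to_csv(out / "abundance_long.tsv", sep="\t", index=False)
    analysis.assignment_rates.to_csv(out / "assignment_rates.tsv", sep="\t", index=False)
    analysis.stage_counts.to_csv(out / "stage_counts.tsv", sep="\t", index=False)
    species_cluster_table(analysis.cluster_model, community.proteins).to_csv(
        out / "species_clusters.tsv", sep="\t", index=False
    )
    (out / "bsh_guide_tree.nwk").write_text(analysis.cluster_model.to_newick())

    stats_df = group_comparisons(analysis.abundance)
    stats_df.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)

    wide = ab.to_wide(analysis.abundance, "BSH", "cluster")
    indicator = (wide["group"] != "control").astype(int).to_numpy()
    heat = st.spearman_heatmap(
        wide.drop(columns="group"), indicator,
        alpha=config.alpha, alpha_strict=config.alpha_strict,
    )
    heat.to_csv(out / "spearman_bsh_clusters.tsv", sep="\t", index=False)

    specificity = _specificity_stage(config, community, cohort, analysis)
    specificity.to_csv(out / "specificity_bsh.tsv", sep="\t", index=False)

    return {
        "n_samples": len(cohort.samples),
        "reads_per_sample": config.read_count,
        "stage_counts": analysis.stage_counts.to_dict(orient="records"),
        "outputs": sorted(
            p.name for p in out.iterdir() if p.is_file() and p.name != "FAILED"
        ),
    }


def _specificity_stage(config, community, cohort, analysis) -> pd.DataFrame:
    reference = (
        make_decoy_reference(community.proteins, config.decoy_fraction, config.seed)
        if config.decoy_fraction > 0
        else community.proteins
    )
    per_sample_regions: dict[str, list[str]] = {}
    for s in cohort.samples:
        hits = analysis.hit_tables[s.sample_id]
        asg = analysis.assignments[s.sample_id]
        bsh_reads = set(hits.loc[hits["family"] == "BSH", "read_index"])
        rows = asg[(asg["genome_id"] != "") & (asg["read_index"].isin(bsh_reads))]
        rows = rows.head(config.validation_regions_per_sample)
        per_sample_regions[s.sample_id] = [
            extract_flanked_region(row, community.genomes, config.search.flank_nt)
            for _, row in rows.iterrows()
        ]
    return specificity_by_sample(per_sample_regions, reference, "BSH", config.search)


def make_fixtures(seed: int = 7, out_dir: str | Path | None = None):
    """Small synthetic dataset (13 genomes of 8 kb, 2×10 samples × 3000
    reads) that exercises every pipeline stage in seconds.

    Returns (community, cohort).  With ``out_dir`` the reads, metadata and
    databases are also written to disk.
    """
    community = comm.build_community(seed=20140, genome_len=8_000)
    spec = CohortSpec(
        groups=[("control", 10), ("disease", 10)],
        base_weights=comm.BASE_WEIGHTS,
        effects=comm.disease_effects(0.5),
        compensator="g_background",
        read_count=3_000,
        error_rate=0.01,
        seed=seed,
    )
    cohort = simulate_cohort(spec, community.genomes)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_protein_db(community.proteins, out / "proteins.fasta")
        write_genome_db(
            community.genomes, out / "genomes.fasta", out / "gene_loci.tsv",
            out / "lineage.tsv",
        )
        cohort.metadata.to_csv(out / "samples.tsv", sep="\t", index=False)
        cohort.ground_truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)
        for s in cohort.samples:
            s.to_fasta(out / f"{s.sample_id}.fasta")
    return community, cohort
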