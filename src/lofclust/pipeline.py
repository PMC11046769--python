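"""End-to-end orchestration of the positional-clustering analysis.

``run`` executes the full flow — profiles → clustering fit → role assignment
→ background QC exclusion → possible-pLoF projection → resampling null →
dataset/gene-set comparison → rescue annotation → per-gene plots — from a
single declarative :class:`RunConfig`, writing TSV/JSON outputs and a run
manifest (config, seed, package version, output hashes) sufficient to
reproduce every output byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from ._exceptions import ConfigurationError
from .cluster import PositionClusterer, assign, fit_clusterer, role_composition
from .compare import cross_dataset_table, gene_set_enrichment, read_gene_sets
from .profiles import (
    build_profiles,
    eligible_genes,
    qc_exclude_nonuniform_background,
    read_variant_table,
    write_profiles,
)
from .rescue import annotate_rescues, write_rescue_report
from .simulate import PositionPool, run_null_simulation, write_simulation_summary
from .stop_gains import possible_profiles_for, read_cds_fasta
from .transcripts import filter_by_tier, read_exon_table

logger = logging.getLogger(__name__)

STAGES = (
    "profiles",
    "cluster",
    "assign",
    "qc",
    "possible",
    "simulate",
    "compare",
    "rescue",
    "plots",
)


@dataclass
class RunConfig:
    """Declarative configuration of one analysis run."""

    exon_table: Path
    cds_fasta: Path
    variants: Path
    outdir: Path
    gene_sets: Path | None = None
    tiers: tuple[str, ...] = ("mane_select",)
    k: int = 7
    seed: int = 0
    min_per_class: int = 5
    n_reps: int = 1000
    empty_mass_threshold: float = 0.5
    depleted_quintile_threshold: float = 0.05
    class_mode: str = "primary"
    max_plots: int = 10
    make_plots: bool = True

    def __post_init__(self) -> None:
        for name in ("exon_table", "cds_fasta", "variants", "gene_sets"):
            value = getattr(self, name)
            if value is None:
                continue
            p = Path(value)
            object.__setattr__(self, name, p)
            if not p.exists():
                raise ConfigurationError(f"{name} path does not exist: {p}")
        self.outdir = Path(self.outdir)

    def to_json(self) -> dict:
        doc = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in doc.items()}


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    stage = "profiles"
    try:
        models = filter_by_tier(read_exon_table(config.exon_table), config.tiers)
        cds_seqs = {
            t: s for t, s in read_cds_fasta(config.cds_fasta).items() if t in models
        }
        variants = read_variant_table(config.variants)
        profiles = build_profiles(variants, models, class_mode=config.class_mode)
        write_profiles(profiles, out / "profiles.tsv")
        eligible = eligible_genes(profiles, config.min_per_class)

        stage = "cluster"
        pop = profiles[profiles["dataset"] == "population"]
        model = fit_clusterer(
            pop,
            n_clusters=config.k,
            random_state=config.seed,
            empty_mass_threshold=config.empty_mass_threshold,
            depleted_quintile_threshold=config.depleted_quintile_threshold,
        )
        model.save(out / "cluster_model.json")

        stage = "assign"
        assignments = assign(profiles, model)
        assignments.to_csv(out / "assignments.tsv", sep="\t", index=False)

        stage = "qc"
        pop_assign = assignments[assignments["dataset"] == "population"]
        excluded = qc_exclude_nonuniform_background(pop_assign)
        analysed = eligible - excluded
        (out / "eligible_genes.txt").write_text(
            "\n".join(sorted(analysed)) + ("\n" if analysed else "")
        )
        (out / "excluded_genes.txt").write_text(
            "\n".join(sorted(excluded)) + ("\n" if excluded else "")
        )
        plof_class = "plof_all" if config.class_mode == "primary" else "plof_snv"
        plof_assign = pop_assign[
            (pop_assign["class"] == plof_class)
            & pop_assign["gene_id"].isin(analysed)
        ]
        composition = role_composition(
            assignments[assignments["gene_id"].isin(analysed)]
        )
        composition.to_csv(out / "role_composition.tsv", sep="\t", index=False)

        stage = "possible"
        gene_of = {t: m.gene_id for t, m in models.items()}
        possible = possible_profiles_for(cds_seqs, gene_of)
        possible_assign = assign(possible, model)
        possible_assign.to_csv(out / "possible_assignments.tsv", sep="\t", index=False)

        stage = "simulate"
        pool = PositionPool.from_variants(
            variants[variants["dataset"] == "population"], models
        )
        per_gene_counts = {
            r.gene_id: int(r.n)
            for r in plof_assign.itertuples()
            if r.n >= 1
        }
        observed_nonuniform = int((plof_assign["role"] == "non_uniform").sum())
        sim = run_null_simulation(
            pool,
            per_gene_counts,
            model,
            n_reps=config.n_reps,
            seed=config.seed,
            observed_nonuniform=observed_nonuniform,
        )
        write_simulation_summary(sim, out / "simulation_summary.tsv")
        sim.per_count_fpr.to_csv(out / "simulation_fpr.tsv", sep="\t", index=False)

        stage = "compare"
        clin_assign = assignments[
            (assignments["dataset"] == "clinical")
            & (assignments["class"] == plof_class)
        ]
        comparison_rows = []
        if not clin_assign.empty:
            table = cross_dataset_table(
                plof_assign, clin_assign, config.min_per_class
            )
            table.per_gene.to_csv(out / "cross_dataset.tsv", sep="\t", index=False)
            comparison_rows.append(
                {
                    "comparison": "population_vs_clinical",
                    "n_genes": table.n_genes,
                    "n_uniform_a": table.n_uniform_a,
                    "n_uniform_b": table.n_uniform_b,
                    "n_discordant": len(table.discordant),
                    "binomial_p": table.binomial_p,
                }
            )
        if config.gene_sets is not None:
            sets = read_gene_sets(config.gene_sets)
            enrich = gene_set_enrichment(plof_assign, sets)
            enrich.to_csv(out / "gene_set_enrichment.tsv", sep="\t", index=False)
        pd.DataFrame(comparison_rows).to_csv(
            out / "comparisons.tsv", sep="\t", index=False
        )

        stage = "rescue"
        pop_variants = variants[
            (variants["dataset"] == "population")
            & variants["consequence_class"].isin(["plof_snv", "plof_indel"])
        ]
        rescue = annotate_rescues(pop_variants, models, cds_seqs)
        write_rescue_report(rescue, out / "rescue_report.tsv")

        stage = "plots"
        if config.make_plots:
            from .plots import gene_profile_plot
            from .rescue import all_inframe_atgs

            plot_dir = out / "plots"
            plot_dir.mkdir(exist_ok=True)
            shown = sorted(plof_assign[plof_assign["role"] == "non_uniform"]["gene_id"])
            for gene in shown[: config.max_plots]:
                tids = [t for t, m in models.items() if m.gene_id == gene]
                for tid in tids:
                    gene_profile_plot(
                        variants,
                        models[tid],
                        alt_start_codons=all_inframe_atgs(cds_seqs[tid]),
                        out_path=plot_dir / f"{gene}.png",
                    )
    except Exception as exc:
        raise type(exc)(f"stage {stage!r} failed: {exc}") from exc

    outputs = sorted(p for p in out.glob("*.tsv")) + [
        out / "cluster_model.json",
        out / "eligible_genes.txt",
        out / "excluded_genes.txt",
    ]
    manifest = {
        "package_version": __version__,
        "config": config.to_json(),
        "seed": config.seed,
        "n_eligible_genes": len(eligible),
        "n_excluded_genes": len(excluded),
        "n_analysed_genes": len(analysed),
        "observed_nonuniform": observed_nonuniform,
        "empirical_p": sim.empirical_p,
        "cluster_roles": list(model.roles_),
        "outputs": {str(p.name): _sha256(p) for p in outputs if p.exists()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
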