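"""End-to-end workflows: phylogenomics and synergy.

Each workflow takes a configuration mapping (one YAML file with
``phylogenomics:`` and/or ``synergy:`` sections; CLI flags override config
values) and writes a deterministic artifact set into an output directory.
A single global ``seed`` drives every stochastic stage through documented
per-stage child seeds (see :func:`phagekit.io.derive_seed`).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from phagekit import io as pkio
from phagekit.datatypes import Treatment
from phagekit.growthkill import auc_trapezoid, end_od, evaluate_combinations
from phagekit.pangenome import ClusteringParams, cluster_orthologs, pangenome_summary
from phagekit.phylo import cogrouping_consensus, core_gene_trees, jaccard_distances, neighbor_joining
from phagekit.simulate import GeneEvolutionParams, GrowthKillParams, simulate_growth_kill, simulate_pangenome

__all__ = ["run_phylogenomics", "run_synergy"]

logger = logging.getLogger(__name__)


def _stage_seed(seed: int, stage: str) -> int:
    return int(pkio.derive_seed(seed, stage).generate_state(1)[0] % (2 ** 31))


def run_phylogenomics(config: dict, outdir) -> dict:
    """Proteomes -> families -> Jaccard NJ dendrogram -> core-gene consensus.

    ``config["phylogenomics"]`` names either ``proteomes`` (FASTA paths) or
    ``synthetic`` (GeneEvolutionParams fields). Artifacts: family matrix and
    membership TSV, Jaccard distance TSV, dendrogram and consensus Newick,
    summary JSON.
    """
    cfg = config.get("phylogenomics", {})
    seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if "proteomes" in cfg:
        logger.info("reading %d proteome FASTAs", len(cfg["proteomes"]))
        genomes = pkio.read_proteome_fastas(cfg["proteomes"])
    else:
        params = GeneEvolutionParams(
            **{**cfg.get("synthetic", {}),
               "seed": _stage_seed(seed, "pangenome")}
        )
        logger.info("simulating synthetic pan-genome")
        genomes = simulate_pangenome(params)

    cparams = ClusteringParams(**cfg.get("clustering", {}))
    logger.info("clustering orthologs across %d genomes", len(genomes.genomes))
    matrix = cluster_orthologs(genomes, cparams)
    summary = pangenome_summary(matrix)
    pkio.write_family_matrix(
        matrix, outdir / "family_matrix.tsv", outdir / "family_membership.tsv"
    )

    dm = jaccard_distances(matrix)
    pkio.write_distance_matrix(dm, outdir / "jaccard_distances.tsv")
    dendro = neighbor_joining(dm)
    (outdir / "presence_absence_nj.nwk").write_text(dendro.to_newick() + "\n")

    logger.info("building core-gene trees")
    gene_trees = core_gene_trees(matrix, genomes)
    consensus_newick = None
    if len(gene_trees) >= 1 and len(matrix.genomes) >= 4:
        cgm, consensus = cogrouping_consensus(gene_trees)
        consensus_newick = consensus.to_newick()
        (outdir / "cogrouping_consensus.nwk").write_text(consensus_newick + "\n")
        pd.DataFrame(
            cgm.counts, index=cgm.labels, columns=cgm.labels
        ).to_csv(outdir / "cogrouping_counts.tsv", sep="\t", index_label="")

    payload = {
        "total_families": summary.total_families,
        "core_single_copy": summary.core_single_copy,
        "singletons": summary.singletons,
        "genes_per_genome": summary.genes_per_genome,
        "n_core_gene_trees": len(gene_trees),
        "dendrogram_newick": dendro.to_newick(),
        "consensus_newick": consensus_newick,
    }
    (outdir / "summary.json").write_text(json.dumps(payload, indent=2) + "\n")
    return payload


def _synthetic_treatments(scenario: dict) -> list[Treatment]:
    strain = scenario.get("strain_id", "AB01")
    mois = scenario.get("mois", [0.1, 1e-3, 1e-5, 1e-7])
    antibiotics = scenario.get("antibiotics", {})  # name -> [concs]
    arms = [Treatment(strain_id=strain)]  # untreated control
    for moi in mois:
        arms.append(Treatment(strain_id=strain, moi=float(moi)))
    for ab, concs in antibiotics.items():
        for c in concs:
            arms.append(Treatment(strain_id=strain, antibiotic=ab,
                                  concentration=float(c)))
            for moi in mois:
                arms.append(Treatment(strain_id=strain, moi=float(moi),
                                      antibiotic=ab, concentration=float(c)))
    return arms


def run_synergy(config: dict, outdir) -> pd.DataFrame:
    """Kill-curve grid -> per-arm metrics -> synergy test table.

    ``config["synergy"]`` names either ``plate_csv`` or a ``synthetic``
    scenario (model params plus MOI/antibiotic grid). Artifacts: tidy
    results CSV (one row per combination x metric) and a per-arm
    endOD/AUC table.
    """
    cfg = config.get("synergy", {})
    seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if "plate_csv" in cfg:
        series = pkio.read_plate_csv(cfg["plate_csv"])
    else:
        scenario = cfg.get("synthetic", {})
        params = GrowthKillParams(**scenario.get("params", {}))
        arms = _synthetic_treatments(scenario)
        logger.info("simulating %d arms", len(arms))
        series = simulate_growth_kill(
            params, arms,
            n_reps=int(scenario.get("n_reps", 3)),
            seed=_stage_seed(seed, "growthkill"),
            noise_sigma=float(scenario.get("noise_sigma", 0.01)),
        )
        pkio.write_plate_csv(series, outdir / "plate.csv")

    arm_rows = [
        {
            "arm": s.treatment.label,
            "replicate": s.replicate,
            "endOD": end_od(s),
            "AUC": auc_trapezoid(s),
        }
        for s in series
    ]
    pd.DataFrame(arm_rows).to_csv(outdir / "arm_metrics.csv", index=False)

    rule = cfg.get("baseline_rule", "phage_alone")
    alpha = float(cfg.get("alpha", 0.05))
    results = evaluate_combinations(series, baseline_rule=rule, alpha=alpha)
    if not results:
        logger.warning("no phage+antibiotic combination arms found")
    rows = [
        {
            "combination": r.combination.label,
            "baseline": r.baseline.label,
            "metric": r.metric,
            "t": r.t_stat,
            "p_one_sided": r.p_one_sided,
            "stars": r.stars,
            "enhanced": r.enhanced,
        }
        for r in results
    ]
    df = pd.DataFrame(
        rows, columns=["combination", "baseline", "metric", "t",
                       "p_one_sided", "stars", "enhanced"]
    )
    df.to_csv(outdir / "synergy_results.csv", index=False)
    return df
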