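"""Synthetic-data generators with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the real study inputs:

* gene expression — heavy-tailed baseline RPKM (log-normal) with a planted
  fraction of genes shifted down or up on the log2 scale, producing the
  down-regulated quadrant the transcript stage selects;
* protein abundances — replicate groups with Gaussian within-group noise
  and planted negative mean shifts, optionally decoupled from the mRNA
  labels to plant translational-repression cases;
* target predictions — negative mirSVR-like scores with a configurable
  fraction below the -0.2 selection boundary, enriched among down genes;
* interaction network — a scale-free or duplication-divergence background
  with one planted dense module hosting a functionally coherent category.

All draws derive from a single seed through independent substreams, so one
seed reproduces the whole fixture set bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = ["SimulationConfig", "GroundTruth", "simulate_expression",
           "simulate_proteins", "simulate_targets", "simulate_network",
           "simulate_all", "write_simulation"]


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for the synthetic study; defaults mirror the assumed real-data
    structure (triplicate proteomes, ~1.5-fold+ effects, heavy-tailed RPKM).
    """

    # expression
    n_genes: int = 2000
    frac_down: float = 0.10
    frac_up: float = 0.05
    fc_effect_mean: float = 2.0   # log2 units
    fc_effect_sd: float = 0.5
    null_fc_sd: float = 0.15
    rpkm_lognormal_mu: float = 3.0     # ln RPKM
    rpkm_lognormal_sigma: float = 1.2
    # proteome
    n_proteins: int = 600
    frac_protein_down: float = 0.10
    n_replicates: int = 3
    protein_baseline_mean: float = 20.0
    protein_within_sd: float = 1.0
    protein_effect_sd_units: float = 3.0  # shift in within-group sd units
    protein_tr_fraction: float = 0.3      # down proteins whose mRNA is NOT down
    # targets
    n_mirnas: int = 9
    targets_per_mirna: int = 120
    score_frac_below: float = 0.7         # fraction of scores < -0.2
    down_target_enrichment: float = 4.0   # sampling weight of down genes
    # network
    network_model: str = "scale-free"     # or "duplication-divergence"
    n_nodes: int = 300
    attachment_m: int = 2
    divergence_p: float = 0.35
    planted_module_size: int = 15
    planted_module_density: float = 0.6
    rng_seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_down <= 1 and 0 <= self.frac_up <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frac_down + self.frac_up > 1:
            raise ValueError("frac_down + frac_up must be <= 1")
        for name in ("n_genes", "n_proteins", "n_replicates", "n_mirnas",
                     "targets_per_mirna", "n_nodes", "planted_module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.planted_module_size > self.n_nodes:
            raise ValueError("planted_module_size exceeds n_nodes")
        if self.network_model not in ("scale-free", "duplication-divergence"):
            raise ValueError(f"unknown network model {self.network_model!r}")


@dataclass
class GroundTruth:
    gene_labels: dict        # gene -> down|up|null
    protein_labels: dict     # protein -> down|null
    true_targets: set        # (mirna, gene) pairs
    planted_module: set      # genes in the dense module

    def as_dict(self) -> dict:
        return {
            "gene_labels": self.gene_labels,
            "protein_labels": self.protein_labels,
            "true_targets": sorted(map(list, self.true_targets)),
            "planted_module": sorted(self.planted_module),
        }


def _streams(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _gene_names(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n)]


def simulate_expression(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate an SR/SEN expression table with planted down/up genes.

    SR is log-normal; SEN = SR * 2^e with e ~ N(-mu, sd) for down genes,
    N(+mu, sd) for up genes and N(0, small) for null genes.
    Returns (expression table, gene -> label).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n = config.n_genes
    genes = _gene_names(n)
    n_down = int(round(config.frac_down * n))
    n_up = int(round(config.frac_up * n))
    labels = np.array(["down"] * n_down + ["up"] * n_up + ["null"] * (n - n_down - n_up))
    rng.shuffle(labels)
    sr = rng.lognormal(config.rpkm_lognormal_mu, config.rpkm_lognormal_sigma, size=n)
    e = rng.normal(0.0, config.null_fc_sd, size=n)
    e[labels == "down"] = rng.normal(-config.fc_effect_mean, config.fc_effect_sd,
                                     size=(labels == "down").sum())
    e[labels == "up"] = rng.normal(config.fc_effect_mean, config.fc_effect_sd,
                                   size=(labels == "up").sum())
    sen = sr * np.exp2(e)
    table = pd.DataFrame(
        {
            "gene_symbol": genes,
            "transcript_id": [f"T{i:05d}" for i in range(n)],
            "sr_rpkm": sr,
            "sen_rpkm": sen,
        }
    )
    return table, dict(zip(genes, labels))


def simulate_proteins(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    gene_labels: dict | None = None,
) -> tuple[pd.DataFrame, dict, dict]:
    """Generate a replicate protein abundance matrix with planted down shifts.

    When ``gene_labels`` is given, protein ids are gene symbols and a
    fraction ``protein_tr_fraction`` of the planted down proteins is drawn
    from genes *not* down at the mRNA level — planted translational
    repression; the remainder are mRNA-down genes (degradation at both
    levels). Returns (matrix, design, protein -> label).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    n, r = config.n_proteins, config.n_replicates
    n_down = int(round(config.frac_protein_down * n))
    if gene_labels is not None:
        down_genes = sorted(g for g, l in gene_labels.items() if l == "down")
        other_genes = sorted(g for g, l in gene_labels.items() if l != "down")
        n_tr = int(round(config.protein_tr_fraction * n_down))
        n_deg = n_down - n_tr
        if n_deg > len(down_genes) or n_tr > len(other_genes):
            raise ValueError("not enough genes to host the planted protein effects")
        deg = list(rng.choice(down_genes, size=n_deg, replace=False))
        tr = list(rng.choice(other_genes, size=n_tr, replace=False))
        rest_pool = sorted(set(gene_labels) - set(deg) - set(tr))
        rest = list(rng.choice(rest_pool, size=n - n_down, replace=False))
        proteins = deg + tr + rest
        labels = ["down"] * n_down + ["null"] * (n - n_down)
    else:
        proteins = [f"P{i:05d}" for i in range(n)]
        labels = ["down"] * n_down + ["null"] * (n - n_down)
    base = rng.normal(config.protein_baseline_mean, 2.0, size=n)
    shift = np.where(
        np.array(labels) == "down",
        -config.protein_effect_sd_units * config.protein_within_sd,
        0.0,
    )
    sr = base[:, None] + rng.normal(0, config.protein_within_sd, size=(n, r))
    sen = (base + shift)[:, None] + rng.normal(0, config.protein_within_sd, size=(n, r))
    cols_sr = [f"SR_{j+1}" for j in range(r)]
    cols_sen = [f"SEN_{j+1}" for j in range(r)]
    mat = pd.DataFrame(
        np.hstack([sr, sen]), index=pd.Index(proteins, name="protein_id"),
        columns=cols_sr + cols_sen,
    )
    design = {**{c: "SR" for c in cols_sr}, **{c: "SEN" for c in cols_sen}}
    return mat, design, dict(zip(proteins, labels))


def simulate_targets(
    config: SimulationConfig,
    gene_labels: dict,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, set]:
    """Generate a miRNA->gene target table with mirSVR-like scores.

    Down-regulated genes are over-sampled as targets by
    ``down_target_enrichment``; a fraction ``score_frac_below`` of scores
    falls strictly below -0.2 (uniform on [-1.35, -0.201]), the rest on
    [-0.2, 0]. Returns (table, set of true (mirna, gene) pairs).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    genes = sorted(gene_labels)
    w = np.array(
        [config.down_target_enrichment if gene_labels[g] == "down" else 1.0 for g in genes]
    )
    w = w / w.sum()
    rows = []
    true_pairs = set()
    for mi in range(config.n_mirnas):
        mirna = f"mir-sim{mi + 1}-5p"
        chosen = rng.choice(len(genes), size=min(config.targets_per_mirna, len(genes)),
                            replace=False, p=w)
        for gi in sorted(chosen):
            gene = genes[gi]
            if rng.random() < config.score_frac_below:
                score = rng.uniform(-1.35, -0.201)
            else:
                score = rng.uniform(-0.2, 0.0)
            rows.append((mirna, gene, f"T{gi:05d}", round(float(score), 4)))
            true_pairs.add((mirna, gene))
    table = pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "transcript_id",
                                        "mirsvr_score"])
    return table, true_pairs


def simulate_network(
    config: SimulationConfig,
    gene_universe,
    rng: np.random.Generator | None = None,
) -> tuple[nx.Graph, set]:
    """Generate an interaction network with one planted dense module.

    The background is a scale-free (Barabási–Albert) or
    duplication-divergence graph over ``n_nodes`` genes; a random subset of
    ``planted_module_size`` nodes is rewired to pairwise edge probability
    ``planted_module_density``. Returns (graph, module gene set).
    """
    rng = rng if rng is not None else np.random.default_rng(config.rng_seed)
    universe = sorted(gene_universe)
    if config.n_nodes > len(universe):
        raise ValueError("n_nodes exceeds the gene universe")
    nodes = sorted(str(n) for n in rng.choice(universe, size=config.n_nodes, replace=False))
    nx_seed = int(rng.integers(0, 2**31 - 1))
    if config.network_model == "scale-free":
        base = nx.barabasi_albert_graph(config.n_nodes, config.attachment_m, seed=nx_seed)
    else:
        base = nx.duplication_divergence_graph(config.n_nodes, config.divergence_p,
                                               seed=nx_seed)
    g = nx.relabel_nodes(base, dict(enumerate(nodes)))
    nx.set_edge_attributes(g, 1.0, "confidence")
    module = sorted(str(n) for n in rng.choice(nodes, size=config.planted_module_size,
                                               replace=False))
    for i, u in enumerate(module):
        for v in module[i + 1:]:
            if rng.random() < config.planted_module_density:
                g.add_edge(u, v, confidence=1.0)
    g.remove_edges_from(nx.selfloop_edges(g))
    return g, set(module)


def simulate_all(config: SimulationConfig) -> dict:
    """Generate every pipeline input plus ground truth from one seed."""
    s_expr, s_prot, s_targ, s_net = _streams(config.rng_seed, 4)
    expression, gene_labels = simulate_expression(config, s_expr)
    proteins, design, protein_labels = simulate_proteins(config, s_prot, gene_labels)
    targets, true_pairs = simulate_targets(config, gene_labels, s_targ)
    network, module = simulate_network(config, list(gene_labels), s_net)
    truth = GroundTruth(gene_labels, protein_labels, true_pairs, module)
    # two gene sets: the planted coherent module and a scattered control
    scatter_rng = np.random.default_rng(np.random.SeedSequence(config.rng_seed).spawn(5)[4])
    non_module = sorted(set(network.nodes) - module)
    scattered = sorted(
        scatter_rng.choice(non_module, size=min(len(module), len(non_module)),
                           replace=False)
    )
    gene_sets = {"planted_module": sorted(module), "scattered_control": scattered}
    # simulated miRNAs alternate between the two host clusters
    mirnas = sorted({m for m, _ in true_pairs})
    annotation = {m: ("MIR17HG" if i % 2 == 0 else "MIR100HG")
                  for i, m in enumerate(mirnas)}
    return {
        "config": config,
        "mirna_clusters": annotation,
        "expression": expression,
        "proteins": proteins,
        "design": design,
        "targets": targets,
        "network": network,
        "gene_sets": gene_sets,
        "truth": truth,
    }


def write_simulation(sim: dict, outdir) -> dict:
    """Materialise a simulate_all() bundle in the pipeline's input dialects."""
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "proteins": outdir / "proteins.tsv",
        "design": outdir / "design.yaml",
        "targets": outdir / "targets.tsv",
        "network": outdir / "network.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
        "truth": outdir / "ground_truth.json",
        "config": outdir / "sim_config.json",
        "mirna_annot": outdir / "mirna_clusters.yaml",
    }
    sim["expression"].to_csv(paths["expression"], sep="\t", index=False)
    sim["proteins"].to_csv(paths["proteins"], sep="\t")
    import yaml

    with open(paths["design"], "w") as fh:
        yaml.safe_dump(sim["design"], fh)
    sim["targets"].to_csv(paths["targets"], sep="\t", index=False)
    sio.write_network(sim["network"], paths["network"])
    with open(paths["gene_sets"], "w") as fh:
        for name, genes in sim["gene_sets"].items():
            fh.write("\t".join([name, name, *genes]) + "\n")
    with open(paths["truth"], "w") as fh:
        json.dump(sim["truth"].as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["config"], "w") as fh:
        json.dump(dataclasses.asdict(sim["config"]), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(paths["mirna_annot"], "w") as fh:
        yaml.safe_dump(sim["mirna_clusters"], fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
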