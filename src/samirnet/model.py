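"""Model/Results interface tying the analysis stages together.

`SenescenceTargetModel` holds the study inputs (expression table, protein
matrix + design, target predictions, interaction network, functional gene
sets) and the analysis settings; `fit()` executes the stages in order —
transcript differential expression, protein differential abundance,
mirSVR-filtered target integration, Steiner-tree functional enrichment —
and returns a `SenescenceTargetResults` carrying every stage's table, the
Venn counts, per-category enrichment p-values and a printable summary.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from . import io as sio
from .integration import MirnaAnnotation, cotargeting_matrix, filter_targets, integrate
from .proteome_de import differential_abundance, select_down_proteins
from .steiner import enrich_categories
from .transcript_de import DEThresholds, differential_expression

log = logging.getLogger("samirnet")

__all__ = ["SenescenceTargetModel", "SenescenceTargetResults"]


@dataclass
class SenescenceTargetModel:
    """Integrated SR-vs-SEN miRNA-target analysis.

    Parameters
    ----------
    expression : DataFrame
        Gene-level SR/SEN RPKM table (``gene_symbol, transcript_id,
        sr_rpkm, sen_rpkm``).
    proteins : DataFrame, optional
        Protein x sample abundance matrix.
    design : dict, optional
        Sample column -> "SR"/"SEN" for the protein matrix.
    targets : DataFrame, optional
        miRNA target predictions with mirSVR scores.
    network : networkx.Graph, optional
        Undirected interaction network over gene symbols.
    gene_sets : GeneSetCollection or dict, optional
        Functional categories for the network enrichment.
    thresholds : DEThresholds
    score_threshold : float
        mirSVR selection boundary (strict <, default -0.2).
    alpha : float
        Protein-test significance level (default 0.05).
    n_sim : int
        Random Steiner networks per category (default 1000).
    min_gene_overlap : float
        Hard-error floor on the fraction of predicted target genes present
        in the expression table's gene space (default 0.0, disabled).
    """

    expression: pd.DataFrame
    proteins: pd.DataFrame | None = None
    design: dict | None = None
    targets: pd.DataFrame | None = None
    network: nx.Graph | None = None
    gene_sets: object | None = None
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    score_threshold: float = -0.2
    alpha: float = 0.05
    n_sim: int = 1000
    equal_var: bool = True
    null_universe: str = "graph"  # or "down" for SEN-downregulated genes
    annotation: MirnaAnnotation = field(default_factory=MirnaAnnotation)
    min_gene_overlap: float = 0.0

    @classmethod
    def from_files(cls, config: dict | str | Path) -> "SenescenceTargetModel":
        """Build the model from a YAML config (or its loaded dict).

        Recognised keys: ``expression``, ``proteins``, ``design``,
        ``targets``, ``network``, ``gene_sets`` (paths);
        ``expression_columns`` (mapping), ``min_confidence``,
        ``fc_min``, ``drpkm_min``, ``pseudocount``, ``score_threshold``,
        ``alpha``, ``n_sim``, ``equal_var``, ``null_universe``.
        """
        if not isinstance(config, dict):
            config = sio.load_config(config)
        if "expression" not in config:
            raise sio.ConfigError("config must name an 'expression' table")
        expression = sio.read_expression_table(
            config["expression"], config.get("expression_columns")
        )
        proteins = design = None
        if "proteins" in config:
            design_map = config.get("design")
            if isinstance(design_map, (str, Path)):
                design_map = sio.load_config(design_map)
            if not design_map:
                raise sio.ConfigError("a protein matrix requires a 'design' mapping")
            proteins, design = sio.read_protein_matrix(config["proteins"], design_map)
        targets = sio.read_target_table(config["targets"]) if "targets" in config else None
        network = (
            sio.read_network(config["network"], config.get("min_confidence", 0.0))
            if "network" in config
            else None
        )
        gene_sets = sio.read_gmt(config["gene_sets"]) if "gene_sets" in config else None
        annotation = MirnaAnnotation()
        if "mirna_annot" in config:
            annotation = MirnaAnnotation(clusters=sio.load_config(config["mirna_annot"]))
        thresholds = DEThresholds(
            fc_min=config.get("fc_min", 0.58),
            drpkm_min=config.get("drpkm_min", 5.0),
            pseudocount=config.get("pseudocount", 0.01),
        )
        return cls(
            expression=expression,
            proteins=proteins,
            design=design,
            targets=targets,
            network=network,
            gene_sets=gene_sets,
            thresholds=thresholds,
            score_threshold=config.get("score_threshold", -0.2),
            alpha=config.get("alpha", 0.05),
            n_sim=config.get("n_sim", 1000),
            equal_var=config.get("equal_var", True),
            null_universe=config.get("null_universe", "graph"),
            annotation=annotation,
            min_gene_overlap=config.get("min_gene_overlap", 0.0),
        )

    def fit(self, rng_seed: int = 0) -> "SenescenceTargetResults":
        """Run all stages; deterministic for a fixed seed and inputs."""
        warnings: list[str] = []
        de = differential_expression(self.expression, self.thresholds)
        down_mrna = set(de.loc[de["quadrant"] == "down", "gene_symbol"])
        up_mrna = set(de.loc[de["quadrant"] == "up", "gene_symbol"])

        protein_table = None
        down_protein: set = set()
        if self.proteins is not None:
            protein_table = differential_abundance(
                self.proteins, self.design, equal_var=self.equal_var
            )
            down_protein = set(select_down_proteins(protein_table, self.alpha))

        filtered = integrated = venn = incidence = gene_info = None
        if self.targets is not None:
            if self.min_gene_overlap > 0:
                tgenes = set(self.targets["gene_symbol"])
                egenes = set(self.expression["gene_symbol"])
                if tgenes:
                    frac = len(tgenes & egenes) / len(tgenes)
                    if frac < self.min_gene_overlap:
                        examples = sorted(tgenes - egenes)[:5]
                        raise sio.DataValidationError(
                            "gene-space mismatch between target and expression tables: "
                            f"overlap {frac:.2f} < floor {self.min_gene_overlap:.2f}; "
                            f"e.g. {examples}"
                        )
            filtered = filter_targets(self.targets, self.score_threshold)
            if filtered.empty:
                warnings.append("no target passed the mirSVR score filter")
            integrated, venn = integrate(
                filtered, down_mrna, down_protein, self.annotation
            )
            incidence, _, gene_info = cotargeting_matrix(integrated)

        subnetworks = enrichment = None
        if self.network is not None and self.gene_sets is not None:
            universe = None
            if self.null_universe == "down":
                # eligible null genes: SEN-downregulated plus the category
                # seeds themselves (they are always part of the pool)
                seed_genes = set().union(
                    *(set(gs.genes) for gs in self._iter_gene_sets())
                )
                universe = sorted(
                    ((down_mrna | down_protein) | seed_genes) & set(self.network.nodes)
                )
            subnetworks, enrichment = enrich_categories(
                self.network,
                self._iter_gene_sets(),
                n_sim=self.n_sim,
                rng=int(rng_seed),
                universe=universe,
            )
            for s in subnetworks:
                if s.dropped_seeds:
                    warnings.append(
                        f"category {s.category}: {len(s.dropped_seeds)} seed(s) not in graph"
                    )

        return SenescenceTargetResults(
            model=self,
            rng_seed=int(rng_seed),
            de_table=de,
            down_mrna=down_mrna,
            up_mrna=up_mrna,
            protein_table=protein_table,
            down_protein=down_protein,
            filtered_targets=filtered,
            integrated=integrated,
            venn=venn,
            incidence=incidence,
            gene_info=gene_info,
            subnetworks=subnetworks,
            enrichment=enrichment,
            warnings=warnings,
        )

    def _iter_gene_sets(self):
        gs = self.gene_sets
        if isinstance(gs, dict):
            from .io import GeneSet

            return [GeneSet(name, name, frozenset(g)) for name, g in gs.items()]
        return list(gs)


@dataclass
class SenescenceTargetResults:
    """Fitted results; every printed count is recomputable from the tables."""

    model: SenescenceTargetModel
    rng_seed: int
    de_table: pd.DataFrame
    down_mrna: set
    up_mrna: set
    protein_table: pd.DataFrame | None
    down_protein: set
    filtered_targets: pd.DataFrame | None
    integrated: list | None
    venn: object | None
    incidence: pd.DataFrame | None
    gene_info: pd.DataFrame | None
    subnetworks: list | None
    enrichment: list | None
    warnings: list

    def mode_counts(self) -> dict:
        if not self.integrated:
            return {}
        out: dict[str, int] = {}
        for t in self.integrated:
            out[t.mode] = out.get(t.mode, 0) + 1
        return out

    def report(self) -> dict:
        """JSON-ready report mirroring the per-stage quantities."""
        t = self.model.thresholds
        rep = {
            "settings": {
                "fc_min": t.fc_min,
                "drpkm_min": t.drpkm_min,
                "pseudocount": t.pseudocount,
                "score_threshold": self.model.score_threshold,
                "alpha": self.model.alpha,
                "n_sim": self.model.n_sim,
                "equal_var": self.model.equal_var,
                "null_universe": self.model.null_universe,
                "rng_seed": self.rng_seed,
            },
            "transcripts": {
                "n_genes": int(len(self.de_table)),
                "n_down": int(len(self.down_mrna)),
                "n_up": int(len(self.up_mrna)),
            },
            "warnings": list(self.warnings),
        }
        if self.protein_table is not None:
            rep["proteins"] = {
                "n_proteins": int(len(self.protein_table)),
                "n_down": int(len(self.down_protein)),
            }
        if self.venn is not None:
            rep["integration"] = {
                "venn": self.venn.as_dict(),
                "modes": self.mode_counts(),
            }
        else:
            rep["integration"] = {
                "venn": {"predicted_total": 0, "down_mrna_targets": 0,
                         "down_protein_targets": 0, "overlap": 0,
                         "predicted_total_transcripts": 0},
                "modes": {},
            }
        if self.enrichment is not None:
            rep["enrichment"] = [r.as_dict() for r in self.enrichment]
        return rep

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = ["Senescence-associated miRNA target analysis", "=" * 44]
        lines.append(
            f"Transcripts: {len(self.de_table)} genes; "
            f"{len(self.down_mrna)} down, {len(self.up_mrna)} up "
            f"(|FC| >= {self.model.thresholds.fc_min}, "
            f"|dRPKM| >= {self.model.thresholds.drpkm_min})"
        )
        if self.protein_table is not None:
            lines.append(
                f"Proteins:    {len(self.protein_table)} tested; "
                f"{len(self.down_protein)} down at alpha={self.model.alpha}"
            )
        if self.venn is not None:
            v = self.venn
            m = self.mode_counts()
            lines.append(
                f"Targets:     {v.predicted_total} predicted genes "
                f"(mirSVR < {self.model.score_threshold}); "
                f"{v.down_mrna_targets} mRNA-down, {v.down_protein_targets} "
                f"protein-down, {v.overlap} both"
            )
            lines.append(
                "Modes:       "
                + ", ".join(f"{k}={m.get(k, 0)}" for k in
                            ("degradation", "translational_repression", "both",
                             "predicted_only"))
            )
        if self.enrichment:
            lines.append("Network enrichment (random Steiner networks):")
            for r in self.enrichment:
                lines.append(
                    f"  {r.category:<24} seeds={r.n_seeds:<4} size={r.observed_size:<4} "
                    f"p={r.p_value:.4g} (n_sim={r.n_sim})"
                )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Materialise every stage output (TSV/JSON/GraphML) to ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        de_out = self.de_table.copy()
        paths["transcripts"] = outdir / "transcripts_de.tsv"
        de_out.to_csv(paths["transcripts"], sep="\t", index=False, float_format="%.6g")
        if self.protein_table is not None:
            paths["proteins"] = outdir / "proteins_de.tsv"
            self.protein_table.to_csv(paths["proteins"], sep="\t", float_format="%.6g")
        if self.gene_info is not None and not self.gene_info.empty:
            paths["targets"] = outdir / "integrated_targets.tsv"
            self.gene_info.to_csv(paths["targets"], sep="\t", float_format="%.6g")
            paths["cotargeting"] = outdir / "cotargeting_matrix.tsv"
            self.incidence.to_csv(paths["cotargeting"], sep="\t")
        if self.subnetworks is not None:
            paths["graphml"] = outdir / "subnetworks.graphml"
            sio.write_graphml(self.subnetworks, self.model.network, paths["graphml"])
        paths["report"] = outdir / "report.json"
        sio.write_report(self.report(), paths["report"])
        return {k: str(v) for k, v in paths.items()}


def input_hashes(config: dict) -> dict:
    """SHA-256 of every input file named in a pipeline config (provenance)."""
    out = {}
    for key in ("expression", "proteins", "design", "targets", "network", "gene_sets"):
        p = config.get(key)
        if isinstance(p, (str, Path)) and Path(p).is_file():
            out[key] = hashlib.sha256(Path(p).read_bytes()).hexdigest()
    return out
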