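"""Integrate predicted miRNA targets with the downregulated mRNA/protein sets.

Predicted target sites are kept only when their mirSVR score is strictly
below the threshold (-0.2 by default; more negative means stronger
predicted downregulation). Transcript-level predictions collapse to gene
level by the most negative score. Each predicted target gene is then
classified by regulation mode:

* ``degradation`` — gene is in the SEN-downregulated mRNA set only;
* ``translational_repression`` — protein down while the mRNA is not
  (the SMARCA5/HOXA1 pattern);
* ``both`` — down at both levels;
* ``predicted_only`` — predicted but observed down at neither level.

A gene x miRNA incidence matrix summarises co-targeting, and each gene is
annotated with the senescence-associated miRNA host clusters (MIR17HG,
MIR100HG) its targeting miRNAs come from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger("samirnet")

__all__ = [
    "MIR17HG_MIRNAS",
    "MIR100HG_MIRNAS",
    "MirnaAnnotation",
    "VennCounts",
    "IntegratedTarget",
    "filter_targets",
    "integrate",
    "cotargeting_matrix",
]

#: mature senescence-associated miRNAs by host cluster
MIR17HG_MIRNAS = frozenset(
    {"mir-17-5p", "mir-18a-5p", "mir-19a-3p", "mir-20a-5p", "mir-92a-1-5p", "mir-19b1-5p"}
)
MIR100HG_MIRNAS = frozenset({"mir-100-5p", "mir-125b-5p", "let-7a-2-3p"})

_WARNED_MIRNAS: set = set()


@dataclass(frozen=True)
class MirnaAnnotation:
    """Maps mature miRNA ids to their host cluster."""

    clusters: dict = field(
        default_factory=lambda: {
            **{m: "MIR17HG" for m in MIR17HG_MIRNAS},
            **{m: "MIR100HG" for m in MIR100HG_MIRNAS},
        }
    )

    def cluster_of(self, mirna_id: str) -> str:
        c = self.clusters.get(mirna_id)
        if c is None:
            if mirna_id not in _WARNED_MIRNAS:  # warn once per id
                _WARNED_MIRNAS.add(mirna_id)
                log.warning("miRNA %s not in cluster annotation; labelled 'other'", mirna_id)
            return "other"
        return c

    @staticmethod
    def strand_arm(mirna_id: str) -> str:
        return "3p" if mirna_id.endswith("3p") else "5p"


@dataclass(frozen=True)
class VennCounts:
    """Sizes for the predicted/mRNA-down/protein-down Venn diagram."""

    predicted_total: int
    down_mrna_targets: int
    down_protein_targets: int
    overlap: int
    predicted_total_transcripts: int = 0

    def as_dict(self) -> dict:
        return {
            "predicted_total": self.predicted_total,
            "down_mrna_targets": self.down_mrna_targets,
            "down_protein_targets": self.down_protein_targets,
            "overlap": self.overlap,
            "predicted_total_transcripts": self.predicted_total_transcripts,
        }


@dataclass
class IntegratedTarget:
    gene_symbol: str
    targeting_mirnas: frozenset
    best_score: float
    mode: str  # degradation | translational_repression | both | predicted_only
    clusters_hit: frozenset


def filter_targets(targets: pd.DataFrame, score_threshold: float = -0.2) -> pd.DataFrame:
    """Keep predictions with mirSVR score strictly below the threshold."""
    if not score_threshold < 0:
        raise ValueError("mirSVR score threshold must be negative")
    return targets[targets["mirsvr_score"] < score_threshold].reset_index(drop=True)


def integrate(
    targets: pd.DataFrame,
    down_mrna,
    down_protein,
    annotation: MirnaAnnotation | None = None,
) -> tuple[list[IntegratedTarget], VennCounts]:
    """Classify each predicted target gene by regulation mode.

    Parameters
    ----------
    targets : DataFrame
        Filtered target table (``mirna_id, gene_symbol, transcript_id,
        mirsvr_score``).
    down_mrna, down_protein : iterable of str
        SEN-downregulated gene/protein symbol sets (harmonised symbol space).
    annotation : MirnaAnnotation, optional

    Returns
    -------
    (list of IntegratedTarget sorted by gene, VennCounts)
    """
    annotation = annotation or MirnaAnnotation()
    down_mrna = {str(g).upper() for g in down_mrna}
    down_protein = {str(g).upper() for g in down_protein}
    if targets.empty:
        log.warning("empty target table; nothing to integrate")
        return [], VennCounts(0, 0, 0, 0, 0)
    targets = targets.assign(gene_symbol=targets["gene_symbol"].astype(str).str.upper())

    results = []
    for gene, grp in targets.groupby("gene_symbol", sort=True):
        mirnas = frozenset(grp["mirna_id"])
        in_mrna = gene in down_mrna
        in_protein = gene in down_protein
        if in_mrna and in_protein:
            mode = "both"
        elif in_mrna:
            mode = "degradation"
        elif in_protein:
            mode = "translational_repression"
        else:
            mode = "predicted_only"
        clusters = frozenset(
            c for c in (annotation.cluster_of(m) for m in mirnas) if c != "other"
        )
        results.append(
            IntegratedTarget(
                gene_symbol=gene,
                targeting_mirnas=mirnas,
                best_score=float(grp["mirsvr_score"].min()),
                mode=mode,
                clusters_hit=clusters,
            )
        )

    genes = {r.gene_symbol for r in results}
    counts = VennCounts(
        predicted_total=len(genes),
        down_mrna_targets=len(genes & down_mrna),
        down_protein_targets=len(genes & down_protein),
        overlap=len(genes & down_mrna & down_protein),
        predicted_total_transcripts=int(
            targets.drop_duplicates(["gene_symbol", "transcript_id"]).shape[0]
        ),
    )
    return results, counts


def cotargeting_matrix(
    integrated: list[IntegratedTarget],
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Build the gene x miRNA 0/1 incidence matrix and per-gene summaries.

    Returns
    -------
    incidence : DataFrame (genes x miRNAs, 0/1)
    mirna_count : Series, row sums (number of distinct targeting miRNAs)
    gene_info : DataFrame with ``mode``, ``best_score`` and boolean
        ``hit_MIR17HG`` / ``hit_MIR100HG`` columns.
    """
    if not integrated:
        empty = pd.DataFrame()
        return empty, pd.Series(dtype=int), pd.DataFrame()
    genes = sorted(t.gene_symbol for t in integrated)
    mirnas = sorted({m for t in integrated for m in t.targeting_mirnas})
    inc = pd.DataFrame(0, index=genes, columns=mirnas, dtype=int)
    info_rows = {}
    for t in integrated:
        for m in t.targeting_mirnas:
            inc.loc[t.gene_symbol, m] = 1
        info_rows[t.gene_symbol] = {
            "mode": t.mode,
            "best_score": t.best_score,
            "hit_MIR17HG": "MIR17HG" in t.clusters_hit,
            "hit_MIR100HG": "MIR100HG" in t.clusters_hit,
        }
    counts = inc.sum(axis=1)
    info = pd.DataFrame.from_dict(info_rows, orient="index").loc[genes]
    info["n_mirnas"] = counts
    assert np.array_equal(counts.to_numpy(), inc.to_numpy().sum(axis=1))
    return inc, counts, info
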