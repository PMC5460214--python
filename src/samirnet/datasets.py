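"""Bundled reference data.

`load_sa_mirna_targets` returns the published table of SEN-downregulated
mRNA targets of the senescence-associated miRNAs: per miRNA block, the
target gene, RefSeq transcript, mirSVR score, the SR and SEN RPKM values
and the printed derived statistics (dRPKM, FC, D). It serves as the
ground-truth fixture for the differential statistics and the mirSVR
filter boundary.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_sa_mirna_targets", "SA_MIRNA_IDS"]

#: the eight mature SA-miRNAs with tabulated targets, in block order
SA_MIRNA_IDS = (
    "mir-17-5p",
    "mir-18a-5p",
    "mir-19a-3p",
    "mir-20a-5p",
    "mir-100-5p",
    "mir-125b-5p",
    "mir-92a-1-5p",
    "let-7a-2-3p",
)


def load_sa_mirna_targets() -> pd.DataFrame:
    """Load the published SA-miRNA target table.

    Returns
    -------
    DataFrame with columns ``mirna_id, mimat_id, gene_symbol,
    transcript_id, mirsvr_score, sr_rpkm, sen_rpkm, drpkm, fc, d``
    (558 rows over 8 miRNA blocks). The ``drpkm``, ``fc`` and ``d``
    columns are the values as printed (2 dp).
    """
    with resources.files("samirnet.data").joinpath(
        "table1_sa_mirna_targets.tsv"
    ).open() as fh:
        return pd.read_csv(fh, sep="\t")
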