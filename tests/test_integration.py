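"""mirSVR filtering, mode classification, Venn counts and co-targeting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from samirnet.integration import (
    MirnaAnnotation,
    cotargeting_matrix,
    filter_targets,
    integrate,
)


def _targets(rows):
    return pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "transcript_id",
                                       "mirsvr_score"])


def test_filter_strict_boundary():
    t = _targets(
        [
            ("mir-17-5p", "TFPI2", "NM_006528", -0.25),
            ("mir-x", "A", "t1", -0.2),       # exactly at boundary: dropped
            ("mir-x", "B", "t2", -0.20001),   # just below: kept
            ("mir-x", "C", "t3", -0.1),
        ]
    )
    kept = filter_targets(t, -0.2)
    assert set(kept["gene_symbol"]) == {"TFPI2", "B"}


@given(st.floats(-1.0, -0.05), st.floats(0.0, 0.5))
@settings(max_examples=100, derandomize=True)
def test_filter_monotone_in_threshold(thr, step):
    rng = np.random.default_rng(3)
    t = _targets(
        [("m", f"G{i}", f"t{i}", s) for i, s in enumerate(rng.uniform(-1.3, 0, 60))]
    )
    loose = set(filter_targets(t, thr)["transcript_id"])
    tight = set(filter_targets(t, thr - step - 1e-9)["transcript_id"])
    assert tight <= loose


def test_mode_classification_toy_counts():
    t = _targets([("m1", g, f"t{g}", -0.5) for g in "ABCDE"])
    res, venn = integrate(t, down_mrna={"A", "B"}, down_protein={"B", "C"})
    modes = {r.gene_symbol: r.mode for r in res}
    assert modes == {
        "A": "degradation",
        "B": "both",
        "C": "translational_repression",
        "D": "predicted_only",
        "E": "predicted_only",
    }
    assert (venn.predicted_total, venn.down_mrna_targets,
            venn.down_protein_targets, venn.overlap) == (5, 2, 2, 1)


def test_smarca5_pattern_is_translational_repression():
    """Protein down without mRNA down, predicted by mir-100-5p."""
    t = _targets([("mir-100-5p", "SMARCA5", "NM_003601", -0.45)])
    res, _ = integrate(t, down_mrna=set(), down_protein={"SMARCA5"})
    assert res[0].mode == "translational_repression"
    assert res[0].clusters_hit == frozenset({"MIR100HG"})


def test_empty_target_table_warns(caplog):
    with caplog.at_level("WARNING", logger="samirnet"):
        res, venn = integrate(_targets([]), {"A"}, {"B"})
    assert res == [] and venn.predicted_total == 0
    assert "empty" in caplog.text


def test_gene_level_collapse_most_negative():
    t = _targets(
        [
            ("m1", "UFD1L", "NM_001035247", -0.98),
            ("m1", "UFD1L", "NM_005659", -0.99),
        ]
    )
    res, venn = integrate(t, set(), set())
    assert venn.predicted_total == 1
    assert venn.predicted_total_transcripts == 2
    assert res[0].best_score == pytest.approx(-0.99)


def test_venn_partition_inequalities(rng):
    """degradation + both <= |down_mrna|; TR + both <= |down_protein|."""
    genes = [f"G{i}" for i in range(40)]
    t = _targets([("m", g, f"t{g}", -0.5) for g in genes])
    dm = set(rng.choice(genes, 15, replace=False))
    dp = set(rng.choice(genes, 12, replace=False))
    res, venn = integrate(t, dm, dp)
    modes = [r.mode for r in res]
    assert modes.count("degradation") + modes.count("both") <= len(dm)
    assert modes.count("translational_repression") + modes.count("both") <= len(dp)
    assert venn.overlap <= min(venn.down_mrna_targets, venn.down_protein_targets)


def test_nap1l1_cotargeting_hits_both_clusters(table1):
    """NAP1L1 is predicted by miRNAs from both host clusters in the fixture."""
    sub = table1[table1["gene_symbol"] == "NAP1L1"][
        ["mirna_id", "gene_symbol", "transcript_id", "mirsvr_score"]
    ]
    res, _ = integrate(sub, {"NAP1L1"}, set())
    (r,) = res
    assert {"let-7a-2-3p", "mir-17-5p", "mir-18a-5p", "mir-19a-3p",
            "mir-20a-5p"} <= r.targeting_mirnas
    assert r.clusters_hit == frozenset({"MIR17HG", "MIR100HG"})


def test_cotargeting_matrix_equals_hand_built():
    t = _targets(
        [
            ("m1", "A", "tA", -0.5),
            ("m2", "A", "tA2", -0.4),
            ("m1", "B", "tB", -0.3),
            ("m3", "C", "tC", -0.9),
            ("m3", "D", "tD", -0.6),
            ("m2", "D", "tD2", -0.7),
        ]
    )
    res, _ = integrate(t, set(), set())
    inc, counts, info = cotargeting_matrix(res)
    expected = pd.DataFrame(
        [[1, 1, 0], [1, 0, 0], [0, 0, 1], [0, 1, 1]],
        index=list("ABCD"), columns=["m1", "m2", "m3"],
    )
    pd.testing.assert_frame_equal(inc, expected, check_dtype=False)
    assert counts.to_dict() == {"A": 2, "B": 1, "C": 1, "D": 2}
    assert info.loc["A", "n_mirnas"] == 2


def test_unknown_mirna_labelled_other():
    a = MirnaAnnotation()
    assert a.cluster_of("mir-17-5p") == "MIR17HG"
    assert a.cluster_of("mir-999-5p") == "other"
    assert MirnaAnnotation.strand_arm("mir-19a-3p") == "3p"


def test_table1_self_consistent_modes(table1):
    """With down_mrna = the table's own genes, every mode is degradation/both."""
    t = table1[["mirna_id", "gene_symbol", "transcript_id", "mirsvr_score"]]
    res, _ = integrate(t, set(table1["gene_symbol"]), set())
    assert all(r.mode in ("degradation", "both") for r in res)
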