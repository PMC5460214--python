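"""Synthetic-data generators: determinism, marginals and planted structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from samirnet.simulate import (
    SimulationConfig,
    simulate_all,
    simulate_expression,
    simulate_network,
    simulate_proteins,
    simulate_targets,
    write_simulation,
)
from samirnet.transcript_de import DEThresholds, classify_quadrant, compute_drpkm, compute_fc


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(frac_down=0.7, frac_up=0.5)
    with pytest.raises(ValueError):
        SimulationConfig(n_genes=0)
    with pytest.raises(ValueError):
        SimulationConfig(planted_module_size=50, n_nodes=10)
    with pytest.raises(ValueError):
        SimulationConfig(network_model="ring")


def test_same_seed_identical_bundle():
    a = simulate_all(SimulationConfig(rng_seed=5, n_genes=300, n_proteins=80,
                                      n_nodes=60, planted_module_size=8))
    b = simulate_all(SimulationConfig(rng_seed=5, n_genes=300, n_proteins=80,
                                      n_nodes=60, planted_module_size=8))
    pd.testing.assert_frame_equal(a["expression"], b["expression"])
    pd.testing.assert_frame_equal(a["proteins"], b["proteins"])
    pd.testing.assert_frame_equal(a["targets"], b["targets"])
    assert set(a["network"].edges) == set(b["network"].edges)
    assert a["truth"].gene_labels == b["truth"].gene_labels


def test_expression_marginals_and_recall(rng):
    cfg = SimulationConfig(n_genes=2000, frac_down=0.1, fc_effect_mean=2.0, rng_seed=1)
    table, labels = simulate_expression(cfg, np.random.default_rng(1))
    sr = table["sr_rpkm"].to_numpy()
    assert stats.skew(sr) > 1  # heavy right tail
    fc = compute_fc(sr, table["sen_rpkm"].to_numpy())
    lab = np.array([labels[g] for g in table["gene_symbol"]])
    # planted mean effect recovered within Monte-Carlo error
    down_fc = fc[lab == "down"]
    assert np.mean(down_fc) == pytest.approx(-2.0, abs=4 * 0.5 / np.sqrt(down_fc.size))
    q = classify_quadrant(fc, compute_drpkm(sr, table["sen_rpkm"].to_numpy()),
                          DEThresholds())
    recall = np.mean(q[lab == "down"] == "down")
    assert recall >= 0.8


def test_no_planted_down_means_low_false_positive_rate():
    cfg = SimulationConfig(n_genes=2000, frac_down=0.0, frac_up=0.0, rng_seed=2)
    table, labels = simulate_expression(cfg, np.random.default_rng(2))
    q = classify_quadrant(
        compute_fc(table["sr_rpkm"], table["sen_rpkm"]),
        compute_drpkm(table["sr_rpkm"], table["sen_rpkm"]),
        DEThresholds(),
    )
    assert all(l == "null" for l in labels.values())
    assert np.mean(q == "down") <= 0.05


def test_protein_type_i_error_with_no_shift():
    cfg = SimulationConfig(n_proteins=4000, frac_protein_down=0.0, rng_seed=3)
    mat, design, labels = simulate_proteins(cfg, np.random.default_rng(3))
    from samirnet.proteome_de import differential_abundance

    res = differential_abundance(mat, design)
    fpr = (res["p_value"] < 0.05).mean()
    assert 0.03 <= fpr <= 0.07


def test_protein_coupling_plants_translational_repression():
    cfg = SimulationConfig(n_genes=1500, n_proteins=400, frac_protein_down=0.25,
                           protein_tr_fraction=0.3, rng_seed=4)
    gene_rng, prot_rng = np.random.default_rng(4), np.random.default_rng(5)
    _, gene_labels = simulate_expression(cfg, gene_rng)
    mat, design, prot_labels = simulate_proteins(cfg, prot_rng, gene_labels)
    down = [p for p, l in prot_labels.items() if l == "down"]
    tr_planted = [p for p in down if gene_labels[p] != "down"]
    assert len(tr_planted) / len(down) == pytest.approx(0.3, abs=0.02)


def test_targets_score_fraction_binomial_bounds():
    cfg = SimulationConfig(n_mirnas=10, targets_per_mirna=100, score_frac_below=0.5,
                           rng_seed=6)
    _, labels = simulate_expression(cfg, np.random.default_rng(6))
    table, _ = simulate_targets(cfg, labels, np.random.default_rng(7))
    from samirnet.integration import filter_targets

    n = len(table)
    kept = len(filter_targets(table, -0.2))
    assert n == 1000
    assert abs(kept - 500) <= 50  # ~3 binomial sd


def test_targets_enriched_among_down_genes():
    cfg = SimulationConfig(n_genes=2000, frac_down=0.1, down_target_enrichment=4.0,
                           rng_seed=8)
    _, labels = simulate_expression(cfg, np.random.default_rng(8))
    table, pairs = simulate_targets(cfg, labels, np.random.default_rng(9))
    hit_down = np.mean([labels[g] == "down" for _, g in pairs])
    # weight 4 on 10% of genes -> expected down share 4*0.1/(4*0.1+0.9) ~ 0.31
    assert 0.2 <= hit_down <= 0.45


def test_network_planted_module_denser_than_background():
    cfg = SimulationConfig(n_nodes=200, planted_module_size=12,
                           planted_module_density=0.6, rng_seed=10)
    genes = [f"G{i:05d}" for i in range(500)]
    g, module = simulate_network(cfg, genes, np.random.default_rng(10))
    assert g.number_of_nodes() == 200
    assert len(module) == 12
    sub = g.subgraph(module)
    density = nx_density(sub)
    assert density >= 0.4
    assert density > 5 * nx_density(g)


def nx_density(g):
    import networkx as nx

    return nx.density(g)


def test_write_simulation_round_trip(tmp_path):
    from samirnet import io as sio

    sim = simulate_all(SimulationConfig(rng_seed=11, n_genes=200, n_proteins=60,
                                        n_nodes=50, planted_module_size=6,
                                        targets_per_mirna=30))
    paths = write_simulation(sim, tmp_path)
    expr = sio.read_expression_table(paths["expression"])
    assert len(expr) == 200
    targ = sio.read_target_table(paths["targets"])
    assert set(targ.columns) == {"mirna_id", "gene_symbol", "transcript_id",
                                 "mirsvr_score"}
    net = sio.read_network(paths["network"])
    assert {tuple(sorted(e)) for e in net.edges} == {
        tuple(sorted(e)) for e in sim["network"].edges}
    sets = sio.read_gmt(paths["gene_sets"])
    assert sets["planted_module"].genes == frozenset(sim["truth"].planted_module)
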