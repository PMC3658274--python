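"""Biclustering behavior: standardization, fixed points, recovery, nulls."""

import numpy as np
import pandas as pd
import pytest

from codim.isa import (
    IsaConfig,
    isa_iterate,
    isa_sweep,
    module_robustness,
    robustness_filter,
    standardize,
    threshold_grid,
)
from codim.stats import DomainError
from codim.synth import PlantedModule, generate_compendium


def _planted_input(n_genes=600, n_drugs=80, ng=30, nd=10, effect=3.0, seed=0):
    module = PlantedModule(
        "m",
        tuple(f"G{i:04d}" for i in range(ng)),
        tuple(f"D{i:03d}" for i in range(nd)),
        effect,
        (),
        ("CL1",),
    )
    comp = generate_compendium(
        n_genes=n_genes, n_drugs=n_drugs, n_cell_lines=1, rat=False,
        planted=[module], seed=seed,
    )
    return standardize(comp.datasets["CL1"].values), module


def test_threshold_grid_matches_published_defaults():
    cfg = IsaConfig()
    assert cfg.gene_thresholds[0] == 5.0 and cfg.gene_thresholds[-1] == 2.0
    assert cfg.drug_thresholds[0] == 4.0 and cfg.drug_thresholds[-1] == 1.0
    assert np.allclose(np.diff(cfg.gene_thresholds), -0.2)
    rat = IsaConfig.for_kind("liver")
    assert rat.drug_thresholds[-1] == 2.0
    assert threshold_grid(5.0, 2.0) == tuple(np.round(np.arange(5.0, 1.9, -0.2), 10))


def test_standardize_row_and_column_moments():
    rng = np.random.default_rng(0)
    inp = standardize(rng.normal(2.0, 3.0, size=(40, 15)))
    assert np.allclose(inp.E_G.mean(axis=1), 0, atol=1e-10)
    assert np.allclose(inp.E_G.std(axis=1), 1, atol=1e-10)
    assert np.allclose(inp.E_C.mean(axis=0), 0, atol=1e-10)
    assert np.allclose(inp.E_C.std(axis=0), 1, atol=1e-10)


def test_standardize_hand_matrix():
    E = np.array([[1.0, 3.0], [2.0, 6.0]])
    inp = standardize(E)
    assert np.allclose(inp.E_G, [[-1, 1], [-1, 1]])
    assert np.allclose(inp.E_C, [[-1, -1], [1, 1]])


def test_standardize_drops_constant_rows_with_warning():
    E = np.vstack([np.ones(10), np.random.default_rng(1).normal(size=(5, 10))])
    with pytest.warns(UserWarning):
        inp = standardize(E)
    assert inp.E.shape[0] == 5
    with pytest.raises(DomainError):
        standardize(np.ones((3, 3)))


def test_planted_checkerboard_recovered_from_inside_seed():
    inp, module = _planted_input(ng=50, nd=20, n_genes=1500, n_drugs=150)
    m = isa_iterate(inp, list(module.gene_ids)[:10], 3.0, 2.0)
    assert m is not None
    truth = set(module.gene_ids)
    jac = len(truth & m.gene_ids) / len(truth | m.gene_ids)
    assert jac >= 0.9
    assert m.condition_ids == set(module.drug_ids)


def test_converged_module_is_a_fixed_point():
    inp, module = _planted_input()
    m = isa_iterate(inp, list(module.gene_ids)[:8], 3.0, 2.0)
    refed = isa_iterate(inp, m.gene_scores, m.t_gene, m.t_drug)
    assert refed.gene_ids == m.gene_ids
    assert refed.condition_ids == m.condition_ids


def test_seed_sign_flip_gives_sign_flipped_module():
    inp, module = _planted_input()
    seed = {g: 1.0 for g in list(module.gene_ids)[:8]}
    m_pos = isa_iterate(inp, seed, 3.0, 2.0)
    m_neg = isa_iterate(inp, {g: -1.0 for g in seed}, 3.0, 2.0)
    assert m_pos.gene_ids == m_neg.gene_ids
    for g in m_pos.gene_scores:
        assert m_pos.gene_scores[g] == pytest.approx(-m_neg.gene_scores[g])


def test_pure_noise_with_high_thresholds_rarely_converges():
    rng = np.random.default_rng(7)
    inp = standardize(rng.normal(size=(200, 40)))
    hits = 0
    for k in range(100):
        seed_rng = np.random.default_rng(1000 + k)
        seed_genes = seed_rng.choice(200, size=5, replace=False)
        m = isa_iterate(inp, [inp.genes[i] for i in seed_genes], 4.0, 4.0)
        hits += m is not None
    assert hits <= 5


def test_sweep_deterministic_and_single_seed_equivalence():
    inp, module = _planted_input(n_genes=120, n_drugs=25, ng=20, nd=8)
    cfg = IsaConfig(
        gene_thresholds=(3.0,), drug_thresholds=(2.0,), n_seeds=5, seed=3
    )
    first = isa_sweep(inp, cfg)
    second = isa_sweep(inp, cfg)
    assert [m.gene_scores for m in first] == [m.gene_scores for m in second]
    assert [m.condition_scores for m in first] == [m.condition_scores for m in second]


def test_sweep_recovers_planted_module_and_recovery_grows_with_effect():
    rates = []
    for effect in (1.0, 2.0, 3.0):
        inp, module = _planted_input(effect=effect, seed=5)
        cfg = IsaConfig(
            gene_thresholds=threshold_grid(4.0, 3.0),
            drug_thresholds=threshold_grid(3.0, 2.0),
            n_seeds=40,
            seed=9,
        )
        mods = isa_sweep(inp, cfg)
        truth = set(module.gene_ids)
        best = max(
            (len(truth & m.gene_ids) / len(truth | m.gene_ids) for m in mods),
            default=0.0,
        )
        rates.append(best)
    assert rates == sorted(rates)  # recovery non-decreasing in effect size
    assert rates[-1] >= 0.8


def test_gene_count_shrinks_with_gene_threshold_statistically():
    inp, module = _planted_input(ng=40, nd=12, effect=3.0)
    sizes = {}
    for tg in (2.5, 3.5):
        counts = []
        for k in range(10):
            seed_rng = np.random.default_rng(k)
            seed_genes = [
                inp.genes[i]
                for i in seed_rng.choice(len(module.gene_ids), 5, replace=False)
            ]
            m = isa_iterate(inp, seed_genes, tg, 2.0)
            if m:
                counts.append(len(m.gene_ids))
        sizes[tg] = np.mean(counts)
    assert sizes[3.5] <= sizes[2.5]


def test_robustness_filter_removes_noise_keeps_planted():
    rng = np.random.default_rng(11)
    noise_inp = standardize(rng.normal(size=(200, 40)))
    cfg = IsaConfig(
        gene_thresholds=(2.0,), drug_thresholds=(1.0,), n_seeds=30, seed=2
    )
    noise_mods = isa_sweep(noise_inp, cfg)
    assert noise_mods, "low thresholds on noise should yield spurious fixed points"
    kept = robustness_filter(noise_mods, noise_inp, cfg)
    assert len(kept) <= 0.1 * len(noise_mods)

    inp, module = _planted_input(effect=5.0)
    cfg2 = IsaConfig(gene_thresholds=(3.0,), drug_thresholds=(2.0,), n_seeds=30, seed=2)
    mods = isa_sweep(inp, cfg2)
    kept2 = robustness_filter(mods, inp, cfg2)
    truth = set(module.gene_ids)
    assert any(len(truth & m.gene_ids) / len(truth | m.gene_ids) >= 0.9 for m in kept2)
    assert robustness_filter(mods, inp, cfg2, enabled=False) == mods


def test_module_robustness_positive_for_real_signal():
    inp, module = _planted_input()
    m = isa_iterate(inp, list(module.gene_ids)[:8], 3.0, 2.0)
    assert module_robustness(m, inp) > 0
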