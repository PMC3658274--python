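"""Cross-dataset linking, CODIM construction and the conservation test."""

import numpy as np
import pandas as pd
import pytest

from codim.compare import (
    ModuleCatalog,
    build_codims,
    conservation_permutation_test,
    drug_overlap_links,
    gene_overlap_links,
    reciprocal_best_hits,
)
from codim.datasets import OrthologyMap
from codim.isa import Module
from codim.stats import DomainError

GENES = [f"G{i:03d}" for i in range(200)]
DRUGS = [f"D{i:03d}" for i in range(50)]


def make_module(mid, genes, drugs):
    return Module(
        module_id=mid,
        gene_scores={g: 1.0 for g in genes},
        condition_scores={d: 1.0 for d in drugs},
        t_gene=3.0,
        t_drug=2.0,
    )


def catalog(ds_id, modules, kind="cellline", genes=GENES, drugs=DRUGS):
    return ModuleCatalog(
        dataset_id=ds_id, kind=kind, modules=modules,
        gene_universe=tuple(genes), drug_universe=tuple(drugs),
    )


@pytest.fixture
def twin_catalogs():
    mods_a = [
        make_module("a1", GENES[:30], DRUGS[:8]),
        make_module("a2", GENES[40:70], DRUGS[10:18]),
        make_module("a3", GENES[80:110], DRUGS[20:28]),
    ]
    mods_b = [make_module(m.module_id.replace("a", "b"), m.gene_ids, m.drug_ids)
              for m in mods_a]
    return catalog("A", mods_a), catalog("B", mods_b)


def test_identical_catalogs_link_each_module_to_its_copy(twin_catalogs):
    cat_a, cat_b = twin_catalogs
    links = gene_overlap_links(cat_a, cat_b)
    for l in links:
        same = l.module_a[1:] == l.module_b[1:]
        assert l.significant is same
        if same:
            assert l.overlap == 30


def test_disjoint_modules_never_significant():
    cat_a = catalog("A", [make_module("a1", GENES[:30], DRUGS[:8])])
    cat_b = catalog("B", [make_module("b1", GENES[100:130], DRUGS[:8])])
    (link,) = gene_overlap_links(cat_a, cat_b)
    assert link.p_gene == 1.0 and not link.significant


def test_symmetry_of_pair_pvalues(twin_catalogs):
    cat_a, cat_b = twin_catalogs
    ab = {(l.module_a, l.module_b): l.p_gene for l in gene_overlap_links(cat_a, cat_b)}
    ba = {(l.module_b, l.module_a): l.p_gene for l in gene_overlap_links(cat_b, cat_a)}
    assert ab.keys() == ba.keys()
    for k in ab:
        assert ab[k] == pytest.approx(ba[k])


def test_orthology_projection_bounds_overlap():
    omap = OrthologyMap(
        pd.DataFrame({"gene_a": GENES[:100], "gene_b": [f"R{g}" for g in GENES[:100]]})
    )
    cat_a = catalog("A", [make_module("a1", GENES[:30], DRUGS[:8])])
    cat_b = catalog(
        "B",
        [make_module("b1", [f"R{g}" for g in GENES[20:50]], DRUGS[:8])],
        kind="liver",
        genes=[f"R{g}" for g in GENES[:100]],
    )
    (link,) = gene_overlap_links(cat_a, cat_b, omap=omap)
    assert link.overlap == 10  # G020..G029 within the 100-gene shared universe
    assert link.overlap <= 30


def test_reciprocal_best_hits_pick_mutual_minima(twin_catalogs):
    cat_a, cat_b = twin_catalogs
    rbh = reciprocal_best_hits(gene_overlap_links(cat_a, cat_b))
    assert sorted((l.module_a, l.module_b) for l in rbh) == [
        ("a1", "b1"), ("a2", "b2"), ("a3", "b3"),
    ]
    assert all(l.reciprocal_best for l in rbh)


def test_one_to_two_overlap_keeps_strictly_better_link():
    cat_a = catalog("A", [make_module("a1", GENES[:30], DRUGS[:8])])
    cat_b = catalog(
        "B",
        [
            make_module("b_good", GENES[:28], DRUGS[:8]),
            make_module("b_weak", GENES[:30:2] + GENES[100:115], DRUGS[:8]),
        ],
    )
    rbh = reciprocal_best_hits(gene_overlap_links(cat_a, cat_b))
    assert [(l.module_a, l.module_b) for l in rbh] == [("a1", "b_good")]


def test_randomized_gene_sets_yield_no_rbh():
    rng = np.random.default_rng(0)
    fails = 0
    for seed in range(100):
        rng = np.random.default_rng(seed)
        mods_a = [make_module(f"a{k}", rng.choice(GENES, 25, replace=False), DRUGS[:8])
                  for k in range(3)]
        mods_b = [make_module(f"b{k}", rng.choice(GENES, 25, replace=False), DRUGS[:8])
                  for k in range(3)]
        rbh = reciprocal_best_hits(gene_overlap_links(catalog("A", mods_a),
                                                      catalog("B", mods_b)))
        fails += len(rbh) > 0
    assert fails <= 5


def test_build_codims_components_and_liver_annotation(twin_catalogs):
    cat_a, cat_b = twin_catalogs
    mods_c = [make_module("c1", GENES[:30], DRUGS[:8])]
    cat_c = catalog("C", mods_c)
    liver = catalog(
        "L", [make_module("l1", GENES[:30], DRUGS[:8])], kind="liver"
    )
    cats = {"A": cat_a, "B": cat_b, "C": cat_c, "L": liver}
    links = (
        gene_overlap_links(cat_a, cat_b)
        + gene_overlap_links(cat_a, cat_c)
        + gene_overlap_links(cat_b, cat_c)
        + gene_overlap_links(cat_a, liver)
    )
    rbh = reciprocal_best_hits(links)
    codims = build_codims(rbh, cats)
    triple = [c for c in codims if len(c.member_modules) == 3]
    assert len(triple) == 1  # a1-b1-c1 component
    assert triple[0].genes == frozenset(GENES[:30])
    assert triple[0].liver_partners == (("L", "l1"),)
    assert build_codims([], cats) == []


def test_drug_overlap_fisher_flags_shared_drug_sets(twin_catalogs):
    cat_a, cat_b = twin_catalogs
    cats = {"A": cat_a, "B": cat_b}
    links = drug_overlap_links(gene_overlap_links(cat_a, cat_b), cats)
    for l in links:
        same = l.module_a[1:] == l.module_b[1:]
        assert l.drug_overlap_significant is same
    liver = catalog("L", [make_module("l1", GENES[:30], DRUGS[:8])], kind="liver")
    with pytest.raises(DomainError):
        drug_overlap_links(
            gene_overlap_links(cat_a, liver), {"A": cat_a, "L": liver}
        )


class TestConservationPermutation:
    def test_identical_catalogs_reach_minimum_p(self, twin_catalogs):
        cat_a, cat_b = twin_catalogs
        obs, p = conservation_permutation_test(cat_a, cat_b, n_perm=99, seed=1)
        assert obs == 3
        assert p == pytest.approx(1 / 100)

    def test_null_calibration_is_roughly_uniform(self):
        rng_master = np.random.default_rng(10)
        ps = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            mods_a = [
                make_module(f"a{k}", rng.choice(GENES, 25, replace=False), DRUGS[:8])
                for k in range(3)
            ]
            mods_b = [
                make_module(f"b{k}", rng.choice(GENES, 25, replace=False), DRUGS[:8])
                for k in range(3)
            ]
            _, p = conservation_permutation_test(
                catalog("A", mods_a), catalog("B", mods_b), n_perm=49, seed=seed
            )
            ps.append(p)
        # under the null P should not pile up at small values
        assert np.mean(np.asarray(ps) <= 0.2) < 0.4
        assert np.mean(ps) > 0.3

    def test_nperm_validation(self, twin_catalogs):
        cat_a, cat_b = twin_catalogs
        with pytest.raises(DomainError):
            conservation_permutation_test(cat_a, cat_b, n_perm=0)
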