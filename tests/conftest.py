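import numpy as np
import pandas as pd
import pytest

from codim.filters import FilterConfig, apply_filters
from codim.isa import IsaConfig, isa_sweep, robustness_filter, standardize
from codim.pipeline import demo_truth
from codim.synth import generate_compendium


def discover_modules(ds, n_seeds=60, seed=11):
    """Full discovery chain for one dataset: sweep -> robustness -> filters."""
    inp = standardize(ds.values)
    cfg = IsaConfig.for_kind(ds.kind, n_seeds=n_seeds, seed=seed)
    mods = isa_sweep(inp, cfg, dataset_id=ds.dataset_id)
    mods = robustness_filter(mods, inp, cfg)
    drug_of = ds.drug_of_profile().to_dict()
    mods = [m.with_drug_map(drug_of) for m in mods]
    fcfg = FilterConfig.for_kind(ds.kind)
    return apply_filters(mods, ds.untreated, fcfg, list(inp.genes))


def gene_jaccard(a, b) -> float:
    a, b = set(a), set(b)
    return len(a & b) / len(a | b) if a | b else 0.0


@pytest.fixture(scope="session")
def small_compendium():
    """One cell line + liver, modest size, with the planted demo design."""
    return generate_compendium(
        n_genes=600,
        n_drugs=80,
        n_cell_lines=1,
        planted=demo_truth(),
        seed=42,
    )


@pytest.fixture(scope="session")
def hand_matrix():
    """Tiny deterministic genes x profiles matrix for arithmetic checks."""
    return pd.DataFrame(
        np.array(
            [
                [1.0, 2.0, 3.0, 4.0],
                [2.0, 2.0, 8.0, 4.0],
                [0.0, 1.0, 1.0, 2.0],
            ]
        ),
        index=["g1", "g2", "g3"],
        columns=["p1", "p2", "p3", "p4"],
    )
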