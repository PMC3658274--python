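"""Post-ISA module filtering: constitutive removal, size, redundancy.

Three bespoke filters turn the redundant pool of ISA fixed points into a
non-redundant catalog of drug-induced modules:

1. Constitutive filter: a module whose genes are strongly coexpressed in
   untreated samples reflects an intrinsic cellular program, not a drug
   response; it is removed when at least 10% of its gene pairs exceed
   Pearson r 0.6 in the untreated matrix.
2. Size filter: at least 20 genes and 5 drugs (10 for liver data).
3. Redundancy removal: modules are ordered by threshold-band priority
   (medium thresholds preferred), then sequentially kept only if distinct
   from everything kept so far, first by membership-score correlation
   (<= 0.3), then by gene-overlap hypergeometric P (>= 1e-5).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .isa import Module
from .stats import hypergeom_overlap_p

__all__ = [
    "FilterConfig",
    "constitutive_filter",
    "size_filter",
    "prioritize_modules",
    "remove_redundant",
    "apply_filters",
]

# priority bands, highest first; a module falls into the first band
# containing its threshold (bands quoted in the grid's own units)
CELL_GENE_BANDS = ((3.0, 4.0), (3.2, 5.0), (2.0, 2.8))
RAT_GENE_BANDS = ((2.0, 3.0), (3.2, 5.0))
CELL_DRUG_BANDS = ((2.0, 3.0), (3.2, 4.0), (1.0, 1.8))
RAT_DRUG_BANDS = ((2.0, 3.0), (3.2, 4.0))


@dataclass
class FilterConfig:
    constitutive_pair_fraction: float = 0.10
    constitutive_r: float = 0.60
    min_genes: int = 20
    min_drugs: int = 5  # 10 for liver data
    redundancy_corr: float = 0.30
    overlap_p_cut: float = 1e-5
    gene_bands: tuple = CELL_GENE_BANDS
    drug_bands: tuple = CELL_DRUG_BANDS

    @classmethod
    def for_kind(cls, kind: str, **kw) -> "FilterConfig":
        if kind == "liver":
            kw.setdefault("min_drugs", 10)
            kw.setdefault("gene_bands", RAT_GENE_BANDS)
            kw.setdefault("drug_bands", RAT_DRUG_BANDS)
        return cls(**kw)


def constitutive_filter(modules, untreated: pd.DataFrame, cfg: FilterConfig) -> list:
    """Remove modules whose genes are coexpressed in untreated samples.

    A module is removed iff the fraction of its gene pairs with Pearson
    r > ``constitutive_r`` in the untreated matrix is at least
    ``constitutive_pair_fraction`` (inclusive: "at least 10%"). Pairs with
    an undefined correlation (constant gene) or a gene absent from the
    untreated matrix count as not coexpressed; the denominator is always
    C(|genes|, 2) over the full module.
    """
    if untreated.shape[1] < 3:
        raise ValueError("need at least 3 untreated profiles")
    kept = []
    for m in modules:
        genes = sorted(m.gene_ids)
        present = [g for g in genes if g in untreated.index]
        if len(present) < len(genes):
            warnings.warn(
                f"{m.module_id}: {len(genes) - len(present)} genes absent from the "
                "untreated matrix; their pairs count as not coexpressed",
                stacklevel=2,
            )
        n_pairs = math.comb(len(genes), 2)
        if n_pairs == 0:
            kept.append(m)
            continue
        strong = 0
        if len(present) >= 2:
            X = untreated.loc[present].to_numpy(dtype=float)
            sd = X.std(axis=1)
            ok = sd > 0
            if ok.sum() >= 2:
                Xc = X[ok] - X[ok].mean(axis=1, keepdims=True)
                norm = np.linalg.norm(Xc, axis=1)
                R = (Xc @ Xc.T) / np.outer(norm, norm)
                iu = np.triu_indices(R.shape[0], 1)
                strong = int(np.count_nonzero(R[iu] > cfg.constitutive_r))
        if strong / n_pairs >= cfg.constitutive_pair_fraction:
            continue
        kept.append(m)
    return kept


def size_filter(modules, cfg: FilterConfig) -> list:
    """Keep modules with >= min_genes genes AND >= min_drugs drugs."""
    return [
        m
        for m in modules
        if len(m.gene_ids) >= cfg.min_genes and len(m.drug_ids) >= cfg.min_drugs
    ]


def _band_rank(value: float, bands) -> int:
    for rank, (lo, hi) in enumerate(bands):
        if lo - 1e-9 <= value <= hi + 1e-9:
            return rank
    return len(bands)


def prioritize_modules(modules, cfg: FilterConfig) -> list:
    """Stable sort by (gene-threshold band, drug-threshold band) priority.

    Medium threshold values are preferred: for cell lines gene thresholds
    4-3 beat 5-3.2 beat 2.8-2, drug thresholds 3-2 beat 4-3.2 beat 1.8-1
    (liver data drops the lowest bands). Ties keep sweep order.
    """
    modules = list(modules)
    for m in modules:
        if _band_rank(m.t_gene, cfg.gene_bands) == len(cfg.gene_bands) or _band_rank(
            m.t_drug, cfg.drug_bands
        ) == len(cfg.drug_bands):
            warnings.warn(
                f"{m.module_id}: thresholds ({m.t_gene}, {m.t_drug}) outside all "
                "priority bands; ranked last",
                stacklevel=2,
            )
    return sorted(
        modules,
        key=lambda m: (
            _band_rank(m.t_gene, cfg.gene_bands),
            _band_rank(m.t_drug, cfg.drug_bands),
        ),
    )


def _score_matrix(modules, universe_index) -> np.ndarray:
    S = np.zeros((len(modules), len(universe_index)))
    for i, m in enumerate(modules):
        for g, s in m.gene_scores.items():
            j = universe_index.get(g)
            if j is not None:
                S[i, j] = s
    return S


def remove_redundant(modules, cfg: FilterConfig, universe) -> list:
    """Two sequential passes over the priority order.

    Pass 1 keeps a module only if the Pearson correlation between its
    gene membership-score vector (over the gene universe, absent genes 0)
    and that of every already-kept module is <= ``redundancy_corr``
    (signed: anti-correlated modules describe opposite responses and are
    not redundant; global sign flips are already canonicalized by the
    sweep).
    Pass 2 keeps a module only if its gene-overlap hypergeometric P
    against every kept module is >= ``overlap_p_cut``.
    """
    modules = list(modules)
    if not modules:
        return []
    universe = list(universe)
    n_universe = len(universe)
    uindex = {g: i for i, g in enumerate(universe)}
    S = _score_matrix(modules, uindex)
    Sc = S - S.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Sc, axis=1)

    kept_idx: list[int] = []
    for i in range(len(modules)):
        if norms[i] == 0:
            continue
        redundant = False
        for j in kept_idx:
            r = float(Sc[i] @ Sc[j] / (norms[i] * norms[j]))
            if r > cfg.redundancy_corr:
                redundant = True
                break
        if not redundant:
            kept_idx.append(i)
    pass1 = [modules[i] for i in kept_idx]

    kept: list[Module] = []
    for m in pass1:
        genes = m.gene_ids
        redundant = False
        for k in kept:
            ov = len(genes & k.gene_ids)
            lo = max(0, len(genes) + len(k.gene_ids) - n_universe)
            p = hypergeom_overlap_p(
                max(ov, lo), len(genes), len(k.gene_ids), n_universe
            )
            if p < cfg.overlap_p_cut:
                redundant = True
                break
        if not redundant:
            kept.append(m)
    return kept


def apply_filters(
    modules, untreated: pd.DataFrame, cfg: FilterConfig, universe
) -> list:
    """Full chain: constitutive -> size -> prioritize -> redundancy."""
    out = constitutive_filter(modules, untreated, cfg)
    out = size_filter(out, cfg)
    out = prioritize_modules(out, cfg)
    return remove_redundant(out, cfg, universe)
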