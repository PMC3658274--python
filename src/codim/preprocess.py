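"""Preprocessing of drug-treatment expression compendia.

Two branches mirror the two kinds of source data:

* Cell-line branch (profiles arrive as batch-adjusted z-scores):
  replicate selection maximizing cross-cell-line consistency, a
  present-call expression filter, and random probe collapse.
* Liver branch (raw intensities): quantile normalization, missing-value
  exclusion/imputation, maximum-variance probe collapse, regularized
  z-scores against control samples, replicate averaging, and restriction
  to one-to-one orthologs of a reference gene set.

The fixed liver pipeline order is quantile_normalize -> impute_missing ->
collapse_probes_maxvar -> zscore_vs_controls -> average_replicates ->
restrict_to_orthologs.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datasets import ExpressionDataset, OrthologyMap, ValidationError

__all__ = [
    "select_replicates",
    "present_call_filter",
    "collapse_probes_random",
    "collapse_probes_maxvar",
    "quantile_normalize",
    "impute_missing",
    "zscore_vs_controls",
    "average_replicates",
    "restrict_to_orthologs",
    "preprocess_liver",
]

MAX_EXHAUSTIVE_COMBOS = 64


def _mean_pairwise_corr(X: np.ndarray) -> float:
    """Mean pairwise Pearson r over columns (profiles)."""
    k = X.shape[1]
    if k < 2:
        return 0.0
    sd = X.std(axis=0)
    if np.any(sd == 0):
        return -np.inf
    R = np.corrcoef(X.T)
    iu = np.triu_indices(k, 1)
    return float(R[iu].mean())


def select_replicates(ds_by_cellline: dict) -> dict:
    """One profile per (drug, cell line), maximizing cross-cell-line consistency.

    For every drug, the retained combination of replicates (one per cell
    line carrying the drug) maximizes the mean pairwise Pearson
    correlation of the drug's profiles across cell lines: exhaustive over
    all combinations when there are at most 64, greedy coordinate ascent
    seeded from the best single cross-cell-line pair otherwise. A cell
    line lacking the drug simply contributes nothing; a drug present in
    only one cell line keeps its first replicate (sorted profile order).
    """
    cell_lines = sorted(ds_by_cellline)
    profiles_of: dict = {}  # drug -> {cl: [profile ids]}
    for cl in cell_lines:
        meta = ds_by_cellline[cl].profile_meta
        drugs = meta["drug"] if "drug" in meta.columns else pd.Series(
            meta.index, index=meta.index
        )
        for prof, drug in drugs.items():
            profiles_of.setdefault(drug, {}).setdefault(cl, []).append(prof)
    chosen: dict = {cl: [] for cl in cell_lines}
    for drug in sorted(profiles_of):
        groups = {cl: sorted(ps) for cl, ps in profiles_of[drug].items()}
        cls = sorted(groups)
        if len(cls) == 1:
            chosen[cls[0]].append(groups[cls[0]][0])
            continue
        vecs = {
            cl: ds_by_cellline[cl].values[groups[cl]].to_numpy(dtype=float)
            for cl in cls
        }
        n_combos = int(np.prod([len(groups[cl]) for cl in cls]))
        if n_combos <= MAX_EXHAUSTIVE_COMBOS:
            best, best_score = None, -np.inf
            for combo in itertools.product(*(range(len(groups[cl])) for cl in cls)):
                X = np.column_stack([vecs[cl][:, j] for cl, j in zip(cls, combo)])
                score = _mean_pairwise_corr(X)
                if score > best_score:
                    best, best_score = combo, score
            combo = dict(zip(cls, best))
        else:
            combo = _greedy_combo(cls, vecs)
        for cl in cls:
            chosen[cl].append(groups[cl][combo[cl]])
    return {cl: ds_by_cellline[cl].subset_profiles(chosen[cl]) for cl in cell_lines}


def _greedy_combo(cls, vecs) -> dict:
    # best single cross-cell-line pair, then coordinate ascent
    best_pair, best_r = None, -np.inf
    for a, b in itertools.combinations(cls, 2):
        Ra = vecs[a] - vecs[a].mean(axis=0)
        Rb = vecs[b] - vecs[b].mean(axis=0)
        na = np.linalg.norm(Ra, axis=0)
        nb = np.linalg.norm(Rb, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            R = (Ra.T @ Rb) / np.outer(na, nb)
        R = np.nan_to_num(R, nan=-np.inf)
        i, j = np.unravel_index(np.argmax(R), R.shape)
        if R[i, j] > best_r:
            best_pair, best_r = {a: int(i), b: int(j)}, float(R[i, j])
    combo = dict(best_pair)
    for cl in cls:
        if cl not in combo:
            combo[cl] = 0
    for _ in range(10):
        changed = False
        for cl in cls:
            scores = []
            for j in range(vecs[cl].shape[1]):
                trial = dict(combo, **{cl: j})
                X = np.column_stack([vecs[c][:, trial[c]] for c in cls])
                scores.append(_mean_pairwise_corr(X))
            j_best = int(np.argmax(scores))
            if j_best != combo[cl]:
                combo[cl] = j_best
                changed = True
        if not changed:
            break
    return combo


def present_call_filter(ds_by_cellline: dict, threshold: float = 0.10) -> set:
    """Genes whose present-call ratio exceeds ``threshold`` in any cell line."""
    kept: set = set()
    for cl in sorted(ds_by_cellline):
        ds = ds_by_cellline[cl]
        if ds.present is None:
            raise ValidationError(f"dataset {cl!r} lacks a present-call matrix")
        ratio = ds.present.mean(axis=1)
        kept |= set(ratio.index[ratio > threshold])
    return kept


def _require_gene_map(ds: ExpressionDataset) -> pd.Series:
    if ds.gene_meta is None or "gene" not in ds.gene_meta.columns:
        raise ValidationError("probe collapse requires a gene_meta 'gene' column")
    return ds.gene_meta["gene"]


def _collapsed(ds: ExpressionDataset, picks: dict) -> ExpressionDataset:
    probes = [picks[g] for g in sorted(picks)]
    values = ds.values.loc[probes].copy()
    values.index = sorted(picks)
    present = None
    if ds.present is not None:
        present = ds.present.loc[probes].copy()
        present.index = sorted(picks)
    return ExpressionDataset(
        values=values,
        profile_meta=ds.profile_meta.copy(),
        gene_meta=None,
        untreated=None if ds.untreated is None else ds.untreated.copy(),
        present=present,
        scale=ds.scale,
        dataset_id=ds.dataset_id,
        kind=ds.kind,
    )


def collapse_probes_random(ds: ExpressionDataset, seed: int) -> ExpressionDataset:
    """One probe per gene chosen by a seeded RNG (avoids multi-probe bias)."""
    gene_of = _require_gene_map(ds)
    rng = np.random.default_rng(seed)
    picks = {}
    for gene, grp in sorted(gene_of.groupby(gene_of).groups.items()):
        probes = sorted(grp)
        picks[gene] = probes[int(rng.integers(len(probes)))]
    return _collapsed(ds, picks)


def collapse_probes_maxvar(ds: ExpressionDataset) -> ExpressionDataset:
    """Per gene, keep the probe with maximal variance across profiles.

    Ties break to the lexicographically smaller probe id.
    """
    gene_of = _require_gene_map(ds)
    var = ds.values.var(axis=1, ddof=1, skipna=True)
    picks = {}
    for gene, grp in sorted(gene_of.groupby(gene_of).groups.items()):
        probes = sorted(grp)  # lexicographic order; argmax keeps the first max
        v = var.loc[probes].to_numpy()
        picks[gene] = probes[int(np.argmax(v))]
    return _collapsed(ds, picks)


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the cross-column mean distribution.

    After the transform each column's sorted non-missing values equal the
    mean order statistics across columns; ties receive the mean of their
    target quantiles. Missing entries are excluded from rank pooling and
    restored as missing. A single column is returned unchanged with a
    warning.
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 columns; identity", stacklevel=2)
        return values.copy()
    X = values.to_numpy(dtype=float)
    out = np.full_like(X, np.nan)
    if not np.isnan(X).any():
        ref = np.sort(X, axis=0).mean(axis=1)
        n = X.shape[0]
        for j in range(X.shape[1]):
            r = rankdata(X[:, j], method="average")
            out[:, j] = np.interp(r, np.arange(1, n + 1), ref)
    else:
        # mean quantile function on a common grid, columns mapped through it
        grid = np.linspace(0.0, 1.0, X.shape[0])
        qf = np.nanmean(
            np.column_stack([np.nanquantile(X[:, j], grid) for j in range(X.shape[1])]),
            axis=1,
        )
        for j in range(X.shape[1]):
            col = X[:, j]
            obs = ~np.isnan(col)
            n_obs = int(obs.sum())
            if n_obs == 0:
                continue
            r = rankdata(col[obs], method="average")
            q = (r - 1) / (n_obs - 1) if n_obs > 1 else np.array([0.5])
            out[obs, j] = np.interp(q, grid, qf)
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def impute_missing(values: pd.DataFrame, max_missing_fraction: float = 0.10) -> pd.DataFrame:
    """Drop rows with more than ``max_missing_fraction`` missing (strict >),
    then fill remaining gaps with the row mean of observed values."""
    frac = values.isna().mean(axis=1)
    kept = values.loc[frac <= max_missing_fraction].copy()
    kept = kept.dropna(how="all")
    row_means = kept.mean(axis=1, skipna=True)
    return kept.apply(lambda row: row.fillna(row_means[row.name]), axis=1)


def zscore_vs_controls(
    values: pd.DataFrame, control_values: pd.DataFrame, sd_quantile: float = 0.10
) -> pd.DataFrame:
    """Regularized z-scores against control means.

    z_gi = (x_gi - mean_g(controls)) / (sd_g + q) with sd_g the gene's
    s.d. over ALL samples (treated and control) and q the
    ``sd_quantile``-quantile of the per-gene s.d. distribution. The
    additive q keeps constant genes finite and damps low-variance noise.
    """
    if control_values.shape[1] == 0:
        raise ValidationError("empty control matrix")
    common = values.index.intersection(control_values.index)
    if len(common) < len(values.index):
        raise ValidationError("control matrix does not cover all genes")
    controls = control_values.loc[values.index]
    allx = pd.concat([values, controls], axis=1)
    sd = allx.std(axis=1, ddof=1)
    q = float(np.quantile(sd.to_numpy(), sd_quantile))
    return values.sub(controls.mean(axis=1), axis=0).div(sd + q, axis=0)


def average_replicates(
    ds: ExpressionDataset, group_keys=("drug", "dose", "time")
) -> ExpressionDataset:
    """Mean profile per replicate group; dose/time combinations stay distinct.

    Different doses and time points of one drug are treated as independent
    experiments downstream, so they are NOT collapsed together - only
    replicates within a (drug, dose, time) group are averaged.
    """
    keys = [k for k in group_keys if k in ds.profile_meta.columns]
    if not keys:
        return ds
    meta = ds.profile_meta
    labels = meta[keys].astype(str).agg("|".join, axis=1)
    new_cols, new_vals, new_meta = [], [], []
    for label in sorted(labels.unique()):
        members = labels.index[labels == label]
        new_cols.append(label)
        new_vals.append(ds.values[members].mean(axis=1, skipna=True))
        new_meta.append(meta.loc[members[0], [c for c in meta.columns if c != "replicate"]])
    values = pd.concat(new_vals, axis=1)
    values.columns = new_cols
    return ExpressionDataset(
        values=values,
        profile_meta=pd.DataFrame(new_meta, index=pd.Index(new_cols, name="profile")),
        gene_meta=None if ds.gene_meta is None else ds.gene_meta.copy(),
        untreated=None if ds.untreated is None else ds.untreated.copy(),
        scale=ds.scale,
        dataset_id=ds.dataset_id,
        kind=ds.kind,
    )


def restrict_to_orthologs(
    ds: ExpressionDataset,
    omap: OrthologyMap,
    reference_genes,
    translate: bool = True,
) -> ExpressionDataset:
    """Keep genes with a one-to-one partner in ``reference_genes``.

    With ``translate`` the surviving genes are renamed into the reference
    namespace, making cross-species matrices directly comparable.
    """
    reference = set(reference_genes)
    b_to_a = omap.b_to_a()
    keep = [g for g in ds.values.index if b_to_a.get(g) in reference]
    if not keep:
        warnings.warn("no genes survive the orthology restriction", stacklevel=2)
    values = ds.values.loc[keep].copy()
    untreated = None if ds.untreated is None else ds.untreated.loc[
        [g for g in keep if g in ds.untreated.index]
    ].copy()
    if translate:
        values.index = [b_to_a[g] for g in keep]
        if untreated is not None:
            untreated.index = [b_to_a[g] for g in untreated.index]
    return ExpressionDataset(
        values=values,
        profile_meta=ds.profile_meta.copy(),
        untreated=untreated,
        scale=ds.scale,
        dataset_id=ds.dataset_id,
        kind=ds.kind,
    )


def preprocess_liver(
    ds: ExpressionDataset,
    omap: OrthologyMap | None = None,
    reference_genes=None,
    sd_quantile: float = 0.10,
    max_missing_fraction: float = 0.10,
) -> ExpressionDataset:
    """Full liver branch in the fixed order, raw probes in, z-scores out."""
    norm = quantile_normalize(ds.values)
    imputed = impute_missing(norm, max_missing_fraction)
    stage = ExpressionDataset(
        values=imputed,
        profile_meta=ds.profile_meta.copy(),
        gene_meta=None if ds.gene_meta is None else ds.gene_meta.loc[imputed.index].copy(),
        scale="raw",
        dataset_id=ds.dataset_id,
        kind=ds.kind,
    )
    if stage.gene_meta is not None:
        stage = collapse_probes_maxvar(stage)
    is_control = (
        ds.profile_meta["control"].astype(bool)
        if "control" in ds.profile_meta.columns
        else pd.Series(False, index=ds.profile_meta.index)
    )
    treated_cols = [p for p in stage.values.columns if not is_control.get(p, False)]
    control_cols = [p for p in stage.values.columns if is_control.get(p, False)]
    z = zscore_vs_controls(
        stage.values[treated_cols], stage.values[control_cols], sd_quantile
    )
    out = ExpressionDataset(
        values=z,
        profile_meta=stage.profile_meta.loc[treated_cols].copy(),
        scale="zscore",
        dataset_id=ds.dataset_id,
        kind=ds.kind,
    )
    out = average_replicates(out)
    if omap is not None and reference_genes is not None:
        out = restrict_to_orthologs(out, omap, reference_genes)
    return out
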