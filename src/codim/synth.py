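"""Synthetic drug-treatment compendia with planted ground truth.

The generator emulates the statistical structure of multi-cell-line drug
perturbation compendia: several "cell line" datasets sharing one gene and
drug namespace, a reduced-gene-space "liver" dataset linked through a
one-to-one orthology map and carrying several dose/time profiles per drug,
background noise, planted gene x drug biclusters (optionally shared across
datasets), and constitutive coexpression blocks that are also present in
untreated samples. Companion generators produce drug-annotation catalogs
with planted enrichments, drug fingerprint bit-vectors, and gene-gene
association networks with denser wiring inside planted modules.

Everything is deterministic under a fixed seed: random draws are made in a
fixed, documented order (datasets in declaration order, modules in list
order), each from an independent child generator spawned from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import AnnotationCatalog
from .coherence import AssociationNetwork
from .datasets import ExpressionDataset, OrthologyMap


class ConfigError(ValueError):
    """Generator configuration violates a dimension or naming constraint."""


@dataclass(frozen=True)
class PlantedModule:
    """Ground-truth bicluster planted into one or more datasets.

    ``sign_pattern`` gives the direction of the expression shift per gene
    (+1 up, -1 down), aligned with ``gene_ids``; a module may thus mix up-
    and down-regulated genes. ``constitutive`` modules additionally share a
    latent coexpression factor in untreated (and, weakly, treated) samples,
    which is the signature the constitutive filter is designed to catch.
    """

    module_id: str
    gene_ids: tuple
    drug_ids: tuple
    effect_size: float
    sign_pattern: tuple = ()
    datasets: tuple = ()
    constitutive: bool = False

    def __post_init__(self) -> None:
        if len(self.gene_ids) < 1 or len(self.drug_ids) < 1:
            raise ConfigError("planted module needs at least one gene and one drug")
        if self.effect_size < 0:
            raise ConfigError("effect size must be non-negative")
        if self.sign_pattern and len(self.sign_pattern) != len(self.gene_ids):
            raise ConfigError("sign pattern length must match gene count")

    @property
    def signs(self) -> np.ndarray:
        if self.sign_pattern:
            return np.asarray(self.sign_pattern, dtype=float)
        return np.ones(len(self.gene_ids))


@dataclass
class SyntheticCompendium:
    """Datasets plus orthology and the planted truth they were built from."""

    datasets: dict
    orthology: OrthologyMap
    truth: list = field(default_factory=list)

    def to_dir(self, path) -> None:
        from pathlib import Path

        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for ds_id, ds in self.datasets.items():
            ds.to_dir(path / ds_id)
        self.orthology.to_tsv(path / "orthology.tsv")
        import json

        truth = [
            {
                "module_id": m.module_id,
                "gene_ids": list(m.gene_ids),
                "drug_ids": list(m.drug_ids),
                "effect_size": m.effect_size,
                "sign_pattern": list(map(int, m.signs)),
                "datasets": list(m.datasets),
                "constitutive": m.constitutive,
            }
            for m in self.truth
        ]
        (path / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))


def gene_id(i: int) -> str:
    return f"G{i:04d}"


def drug_id(i: int) -> str:
    return f"D{i:03d}"


def _rng(seed, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


# stream codes for the independent child generators (documented order)
_STREAM_CELL = 1
_STREAM_RAT = 2
_STREAM_ANNOT = 3
_STREAM_NET = 4
_STREAM_RAW = 5


def generate_compendium(
    n_genes: int = 1500,
    n_drugs: int = 120,
    n_cell_lines: int = 3,
    planted=(),
    noise_sd: float = 1.0,
    batch_count: int = 6,
    replicate_count: int = 1,
    missing_rate: float = 0.0,
    seed: int = 0,
    rat: bool = True,
    rat_gene_fraction: float = 0.4,
    rat_drug_count: int | None = None,
    rat_profiles_per_drug: int = 4,
    n_untreated: int = 30,
    constitutive_factor_sd: float = 2.0,
    constitutive_treated_sd: float = 1.0,
) -> SyntheticCompendium:
    """Generate a multi-dataset compendium with planted biclusters.

    Cell-line datasets are emitted directly on the z-score scale
    (post-preprocessing): background entries ~ Normal(0, ``noise_sd``),
    planted cells shifted by ``sign * effect_size``. The liver-like dataset
    is restricted to ``rat_gene_fraction`` of the gene space through a
    one-to-one orthology map and profiles each drug at
    ``rat_profiles_per_drug`` dose/time combinations, treated downstream as
    independent experiments. Constitutive modules receive a shared latent
    factor (s.d. ``constitutive_factor_sd``) in the untreated matrix and a
    weaker one (``constitutive_treated_sd``) in treated profiles.

    For raw-scale data exercising the preprocessing branch, see
    :func:`generate_raw_dataset`.
    """
    genes = [gene_id(i) for i in range(n_genes)]
    drugs = [drug_id(i) for i in range(n_drugs)]
    gene_index = {g: i for i, g in enumerate(genes)}
    drug_index = {d: i for i, d in enumerate(drugs)}
    cell_lines = [f"CL{k + 1}" for k in range(n_cell_lines)]

    planted = list(planted)
    for m in planted:
        unknown_g = [g for g in m.gene_ids if g not in gene_index]
        unknown_d = [d for d in m.drug_ids if d not in drug_index]
        if unknown_g or unknown_d:
            raise ConfigError(
                f"module {m.module_id} references ids outside the compendium "
                f"dimensions (genes {unknown_g[:3]}, drugs {unknown_d[:3]})"
            )

    datasets: dict[str, ExpressionDataset] = {}
    for k, cl in enumerate(cell_lines):
        rng = _rng(seed, _STREAM_CELL, k)
        values = rng.normal(0.0, noise_sd, size=(n_genes, n_drugs))
        untreated = rng.normal(0.0, noise_sd, size=(n_genes, n_untreated))
        for m in planted:
            if m.datasets and cl not in m.datasets:
                continue
            gi = np.array([gene_index[g] for g in m.gene_ids])
            di = np.array([drug_index[d] for d in m.drug_ids])
            values[np.ix_(gi, di)] += m.signs[:, None] * m.effect_size
            if m.constitutive:
                f_un = rng.normal(0.0, constitutive_factor_sd, size=n_untreated)
                untreated[gi, :] += m.signs[:, None] * f_un[None, :]
                if constitutive_treated_sd > 0:
                    f_tr = rng.normal(0.0, constitutive_treated_sd, size=n_drugs)
                    values[gi, :] += m.signs[:, None] * f_tr[None, :]
        meta = pd.DataFrame(
            {
                "drug": drugs,
                "batch": [i % batch_count for i in range(n_drugs)],
                "replicate": 0,
                "control": False,
                "cell_line": cl,
            },
            index=pd.Index(drugs, name="profile"),
        )
        datasets[cl] = ExpressionDataset(
            values=pd.DataFrame(values, index=genes, columns=drugs),
            profile_meta=meta,
            untreated=pd.DataFrame(
                untreated, index=genes, columns=[f"U{j:03d}" for j in range(n_untreated)]
            ),
            scale="zscore",
            dataset_id=cl,
            kind="cellline",
        )

    # liver-like dataset on an orthologous gene subset
    rng = _rng(seed, _STREAM_RAT)
    n_rat_genes = int(round(rat_gene_fraction * n_genes))
    liver_truth_genes = sorted(
        {g for m in planted if "LIVER" in m.datasets for g in m.gene_ids}
    )
    liver_truth_drugs = sorted(
        {d for m in planted if "LIVER" in m.datasets for d in m.drug_ids}
    )
    if rat:
        if len(liver_truth_genes) > n_rat_genes:
            raise ConfigError("liver-planted genes exceed the rat gene space")
        pool = [g for g in genes if g not in set(liver_truth_genes)]
        fill = rng.choice(len(pool), size=n_rat_genes - len(liver_truth_genes), replace=False)
        rat_human_genes = sorted(liver_truth_genes + [pool[i] for i in sorted(fill)])
        rat_genes = [f"R{gene_index[g]:04d}" for g in rat_human_genes]
        orthology = OrthologyMap(
            pd.DataFrame({"gene_a": rat_human_genes, "gene_b": rat_genes})
        )
        if rat_drug_count is None:
            # a module's drugs must stay a modest fraction of the liver drug
            # list (as in real compendia) or its conditions cannot clear the
            # ISA threshold; two-thirds of the collection keeps planted
            # modules below ~20% while remaining a proper subset
            rat_drug_count = max(2 * n_drugs // 3, len(liver_truth_drugs))
        if len(liver_truth_drugs) > rat_drug_count:
            raise ConfigError("liver-planted drugs exceed the rat drug count")
        dpool = [d for d in drugs if d not in set(liver_truth_drugs)]
        dfill = rng.choice(
            len(dpool), size=rat_drug_count - len(liver_truth_drugs), replace=False
        )
        rat_drugs = sorted(liver_truth_drugs + [dpool[i] for i in sorted(dfill)])

        doses = [0.1, 1.0][: max(1, min(2, rat_profiles_per_drug))]
        times = [6, 24]
        combos = [(do, ti) for do in doses for ti in times][:rat_profiles_per_drug]
        while len(combos) < rat_profiles_per_drug:
            combos.append((doses[-1] * 10, times[-1] * 2))
        profiles, meta_rows = [], []
        for d in rat_drugs:
            for do, ti in combos:
                profiles.append(f"{d}|d{do:g}|t{ti:g}")
                meta_rows.append((d, 0, do, ti, 0, False, "LIVER"))
        rg_index = {g: i for i, g in enumerate(rat_human_genes)}
        values = rng.normal(0.0, noise_sd, size=(len(rat_genes), len(profiles)))
        untreated = rng.normal(0.0, noise_sd, size=(len(rat_genes), n_untreated))
        prof_drug = np.array([m[0] for m in meta_rows])
        for m in planted:
            if "LIVER" not in m.datasets:
                continue
            gi = np.array([rg_index[g] for g in m.gene_ids])
            cols = np.flatnonzero(np.isin(prof_drug, list(m.drug_ids)))
            values[np.ix_(gi, cols)] += m.signs[:, None] * m.effect_size
            if m.constitutive:
                f_un = rng.normal(0.0, constitutive_factor_sd, size=n_untreated)
                untreated[gi, :] += m.signs[:, None] * f_un[None, :]
        meta = pd.DataFrame(
            meta_rows,
            columns=["drug", "batch", "dose", "time", "replicate", "control", "cell_line"],
            index=pd.Index(profiles, name="profile"),
        )
        datasets["LIVER"] = ExpressionDataset(
            values=pd.DataFrame(values, index=rat_genes, columns=profiles),
            profile_meta=meta,
            untreated=pd.DataFrame(
                untreated,
                index=rat_genes,
                columns=[f"U{j:03d}" for j in range(n_untreated)],
            ),
            scale="zscore",
            dataset_id="LIVER",
            kind="liver",
        )
    else:
        orthology = OrthologyMap.identity(genes)

    return SyntheticCompendium(datasets=datasets, orthology=orthology, truth=planted)


def generate_raw_dataset(
    n_genes: int = 300,
    n_drugs: int = 20,
    planted=(),
    replicate_count: int = 3,
    n_controls: int = 12,
    probe_dup_fraction: float = 0.3,
    missing_rate: float = 0.02,
    noise_sd: float = 1.0,
    baseline_mean: float = 8.0,
    baseline_sd: float = 1.0,
    seed: int = 0,
) -> ExpressionDataset:
    """Raw-intensity dataset (probe level) for exercising preprocessing.

    Emits log-intensity-like values: per-gene baselines ~ Normal(8, 1),
    treated profiles shifted by ``sign * effect_size * noise_sd`` for
    planted cells, ``replicate_count`` replicates per treatment, a block of
    control profiles, a fraction of genes represented by two probes, and
    missing values at ``missing_rate`` (plus a few heavily-missing probes
    that the imputation step must drop).
    """
    rng = _rng(seed, _STREAM_RAW)
    genes = [gene_id(i) for i in range(n_genes)]
    drugs = [drug_id(i) for i in range(n_drugs)]
    gene_index = {g: i for i, g in enumerate(genes)}
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    # per-gene noise scales vary across genes, as on real arrays
    gene_sd = noise_sd * rng.uniform(0.7, 1.3, size=n_genes)

    profiles, meta_rows = [], []
    for d in drugs:
        for r in range(replicate_count):
            profiles.append(f"{d}|r{r}")
            meta_rows.append((d, 0, 1.0, 24, r, False))
    for j in range(n_controls):
        profiles.append(f"CTRL{j:02d}")
        meta_rows.append(("control", 0, 0.0, 24, j, True))

    shift = np.zeros((n_genes, len(profiles)))
    prof_drug = np.array([m[0] for m in meta_rows])
    for m in planted:
        gi = np.array([gene_index[g] for g in m.gene_ids])
        cols = np.flatnonzero(np.isin(prof_drug, list(m.drug_ids)))
        shift[np.ix_(gi, cols)] += m.signs[:, None] * m.effect_size * noise_sd

    gene_values = (
        baseline[:, None]
        + shift
        + rng.normal(0.0, 1.0, size=shift.shape) * gene_sd[:, None]
    )

    # probe layer: every gene has one probe; a fraction gets a noisier second
    n_dup = int(round(probe_dup_fraction * n_genes))
    dup_genes = sorted(rng.choice(n_genes, size=n_dup, replace=False))
    probe_rows, probe_gene = [], []
    values_rows = []
    for i, g in enumerate(genes):
        probe_rows.append(f"{g}_p1")
        probe_gene.append(g)
        values_rows.append(gene_values[i])
    for i in dup_genes:
        probe_rows.append(f"{genes[i]}_p2")
        probe_gene.append(genes[i])
        values_rows.append(
            gene_values[i] + rng.normal(0.0, 0.3 * gene_sd[i], size=len(profiles))
        )
    values = np.asarray(values_rows)

    mask = rng.random(values.shape) < missing_rate
    heavy = rng.choice(values.shape[0], size=max(1, values.shape[0] // 50), replace=False)
    for i in heavy:
        cols = rng.choice(values.shape[1], size=int(0.2 * values.shape[1]) + 1, replace=False)
        mask[i, cols] = True
    values = np.where(mask, np.nan, values)

    return ExpressionDataset(
        values=pd.DataFrame(values, index=probe_rows, columns=profiles),
        profile_meta=pd.DataFrame(
            meta_rows,
            columns=["drug", "batch", "dose", "time", "replicate", "control"],
            index=pd.Index(profiles, name="profile"),
        ),
        gene_meta=pd.DataFrame({"gene": probe_gene}, index=pd.Index(probe_rows, name="row")),
        scale="raw",
        dataset_id="RAW",
        kind="liver",
    )


DEFAULT_CATEGORIES = {
    "target": {"n_terms": 40, "background_rate": 0.04},
    "atc": {"n_terms": 20, "background_rate": 0.08},
    "side_effect": {"n_terms": 60, "background_rate": 0.05},
    "fragment": {"n_terms": 100, "background_rate": 0.05},
}


def generate_annotations(
    drugs,
    categories=None,
    planted_enrichments=(),
    modules=(),
    fingerprint_bits: int = 1024,
    fingerprint_density: float = 0.1,
    fingerprint_shared_modules=(),
    fingerprint_shared_bits: int = 64,
    seed: int = 0,
) -> AnnotationCatalog:
    """Annotation catalog (term -> drug sets per category) plus fingerprints.

    ``planted_enrichments`` is a list of ``(module_id, category, term,
    fraction)``: the term is assigned to at least ``fraction`` of that
    module's drugs on top of the category's background rate. ``modules``
    supplies the module_id -> drug set mapping (accepts
    :class:`PlantedModule` objects or ``(id, drugs)`` pairs). Fingerprints
    are random bit-vectors; drugs of modules listed in
    ``fingerprint_shared_modules`` additionally share a fixed random
    sub-pattern of ``fingerprint_shared_bits`` bits.
    """
    drugs = list(drugs)
    drug_index = {d: i for i, d in enumerate(drugs)}
    categories = dict(DEFAULT_CATEGORIES if categories is None else categories)
    module_drugs: dict[str, list] = {}
    for m in modules:
        if isinstance(m, PlantedModule):
            module_drugs[m.module_id] = list(m.drug_ids)
        else:
            mid, mdrugs = m
            module_drugs[mid] = list(mdrugs)
    for mid, cat, term, fraction in planted_enrichments:
        if mid not in module_drugs:
            raise ConfigError(f"unknown module id {mid!r} in planted enrichment")
        if not (0 < fraction <= 1):
            raise ConfigError("enrichment fraction must lie in (0, 1]")

    rng = _rng(seed, _STREAM_ANNOT)
    cat_terms: dict[str, dict[str, frozenset]] = {}
    for cat in sorted(categories):
        spec = categories[cat]
        n_terms = int(spec.get("n_terms", 20))
        rate = float(spec.get("background_rate", 0.05))
        terms = {}
        for t in range(n_terms):
            name = f"{cat}:T{t:03d}"
            members = {drugs[i] for i in np.flatnonzero(rng.random(len(drugs)) < rate)}
            terms[name] = members
        cat_terms[cat] = terms
    for mid, cat, term, fraction in planted_enrichments:
        members = cat_terms.setdefault(cat, {}).setdefault(term, set())
        mdrugs = [d for d in module_drugs[mid] if d in drug_index]
        k = int(math.ceil(fraction * len(mdrugs)))
        chosen = rng.choice(len(mdrugs), size=k, replace=False)
        cat_terms[cat][term] = set(members) | {mdrugs[i] for i in sorted(chosen)}
    cat_terms = {
        cat: {t: frozenset(m) for t, m in terms.items()} for cat, terms in cat_terms.items()
    }

    fps = {}
    fp = rng.random((len(drugs), fingerprint_bits)) < fingerprint_density
    for mid in fingerprint_shared_modules:
        bits = rng.choice(fingerprint_bits, size=fingerprint_shared_bits, replace=False)
        for d in module_drugs[mid]:
            if d in drug_index:
                fp[drug_index[d], bits] = True
    for d, row in zip(drugs, fp):
        fps[d] = row.copy()

    return AnnotationCatalog(categories=cat_terms, fingerprints=fps)


def generate_network(
    genes,
    within_module_density: float = 0.5,
    background_density: float = 0.01,
    planted=(),
    seed: int = 0,
    score_range=(0.4, 1.0),
) -> AssociationNetwork:
    """Gene association network: ER background + dense planted-module wiring.

    Undirected, no self-loops, scores uniform in ``score_range`` (default
    above the usual 0.4 confidence cutoff so the whole network survives
    score filtering).
    """
    if not (0 <= background_density <= 1 and 0 <= within_module_density <= 1):
        raise ConfigError("densities must lie in [0, 1]")
    genes = list(genes)
    n = len(genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    rng = _rng(seed, _STREAM_NET)
    adj = np.zeros((n, n), dtype=bool)
    iu, ju = np.triu_indices(n, 1)
    adj[iu, ju] = rng.random(iu.size) < background_density
    for m in planted:
        gi = np.array(sorted(gene_index[g] for g in m.gene_ids if g in gene_index))
        if gi.size < 2:
            continue
        si, sj = np.triu_indices(gi.size, 1)
        hit = rng.random(si.size) < within_module_density
        adj[gi[si[hit]], gi[sj[hit]]] = True
    ei, ej = np.nonzero(adj)
    lo, hi = score_range
    scores = lo + (hi - lo) * rng.random(ei.size)
    edges = pd.DataFrame(
        {
            "gene_a": [genes[i] for i in ei],
            "gene_b": [genes[j] for j in ej],
            "score": scores,
        }
    )
    return AssociationNetwork.from_edges(edges, genes=genes)
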