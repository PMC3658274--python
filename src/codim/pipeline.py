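"""End-to-end orchestration: datasets in, module catalogs, links, CODIMs,
coherence and enrichment tables out.

The pipeline runs, per dataset: standardize -> ISA threshold-grid sweep ->
robustness filter -> constitutive/size/redundancy filters; then across
datasets: gene-overlap links, reciprocal best hits, CODIM construction,
drug-overlap tests, conservation permutation tests; and finally optional
functional-coherence and drug-annotation enrichment stages.

All randomness flows from one global seed through named per-stage
substreams, so a run is reproducible bit for bit from its manifest. No
wall-clock information enters any output file: two runs with the same
configuration and seed produce byte-identical directories.
"""

from __future__ import annotations

import json
import sys
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import (
    AnnotationCatalog,
    enrich_terms,
    enrichment_table,
    filter_terms,
    read_fingerprints_tsv,
)
from .coherence import AssociationNetwork, coherence_test
from .compare import (
    ModuleCatalog,
    build_codims,
    conservation_permutation_test,
    drug_overlap_links,
    gene_overlap_links,
    reciprocal_best_hits,
)
from .datasets import ExpressionDataset, OrthologyMap
from .filters import FilterConfig, apply_filters
from .isa import IsaConfig, Module, isa_sweep, robustness_filter, standardize

__all__ = ["PipelineConfig", "run_pipeline", "make_demo", "demo_truth", "StageError"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# substream codes: every stage RNG seed is SeedSequence([seed, code, ...])
_SUB_ISA = 11
_SUB_ROBUST = 12
_SUB_CONSERVE = 13
_SUB_COHERENCE = 14


def _substream_seed(seed: int, *key) -> int:
    ss = np.random.SeedSequence([int(seed), *map(int, key)])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass
class PipelineConfig:
    """Run configuration with the published stage defaults."""

    out_dir: str = "codim_run"
    seed: int = 0
    data_dir: str | None = None  # compendium directory (per-dataset subdirs)
    isa: dict = field(default_factory=dict)  # n_seeds, convergence_eps, max_iter
    robustness: bool = True
    filters: dict = field(default_factory=dict)  # FilterConfig overrides
    compare: dict = field(default_factory=dict)  # q_gene, q_drug, n_perm
    coherence: dict | None = None  # network, min_score, n_random
    annotation: dict | None = None  # catalog, fingerprints, q, q_fragment, min_term_drugs

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        items = sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
        return [_jsonify(v) for v in items]
    if isinstance(obj, (np.floating, float)):
        return float(obj)
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    return obj


def _write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonify(obj), indent=1, sort_keys=True) + "\n")


def module_record(m: Module) -> dict:
    return {
        "module_id": m.module_id,
        "dataset_id": m.dataset_id,
        "t_gene": m.t_gene,
        "t_drug": m.t_drug,
        "gene_scores": m.gene_scores,
        "condition_scores": m.condition_scores,
        "drug_ids": sorted(m.drug_ids),
        "n_seeds": m.n_seeds,
        "n_iter": m.n_iter,
    }


def module_from_record(rec: dict) -> Module:
    return Module(
        module_id=rec["module_id"],
        dataset_id=rec.get("dataset_id", ""),
        gene_scores=rec["gene_scores"],
        condition_scores=rec["condition_scores"],
        t_gene=rec["t_gene"],
        t_drug=rec["t_drug"],
        drug_ids=frozenset(rec.get("drug_ids") or rec["condition_scores"]),
        n_seeds=rec.get("n_seeds", 1),
        n_iter=rec.get("n_iter", 0),
    )


def write_catalog(cat: ModuleCatalog, path) -> None:
    _write_json(
        {
            "dataset_id": cat.dataset_id,
            "kind": cat.kind,
            "n_gene_universe": len(cat.gene_universe),
            "n_drug_universe": len(cat.drug_universe),
            "gene_universe": sorted(cat.gene_universe),
            "drug_universe": sorted(cat.drug_universe),
            "modules": [module_record(m) for m in cat.modules],
        },
        path,
    )


def read_catalog(path) -> ModuleCatalog:
    rec = json.loads(Path(path).read_text())
    return ModuleCatalog(
        dataset_id=rec["dataset_id"],
        kind=rec["kind"],
        modules=[module_from_record(r) for r in rec["modules"]],
        gene_universe=tuple(rec["gene_universe"]),
        drug_universe=tuple(rec["drug_universe"]),
    )


def links_table(links) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                l.dataset_a, l.module_a, l.dataset_b, l.module_b, l.overlap,
                l.p_gene, l.q_gene, l.significant, l.reciprocal_best,
                l.p_drug, l.q_drug, l.drug_overlap_significant,
            )
            for l in links
        ],
        columns=[
            "dataset_a", "module_a", "dataset_b", "module_b", "overlap",
            "p_gene", "q_gene", "significant", "reciprocal_best",
            "p_drug", "q_drug", "drug_overlap_significant",
        ],
    )


def _log(fh, msg: str) -> None:
    fh.write(msg + "\n")
    print(msg, file=sys.stderr)


def load_compendium_dir(data_dir) -> tuple[dict, OrthologyMap | None]:
    data_dir = Path(data_dir)
    datasets = {}
    for sub in sorted(p for p in data_dir.iterdir() if (p / "values.tsv").exists()):
        ds = ExpressionDataset.from_dir(sub)
        datasets[ds.dataset_id] = ds
    omap = None
    if (data_dir / "orthology.tsv").exists():
        omap = OrthologyMap.from_tsv(data_dir / "orthology.tsv")
    return datasets, omap


def run_pipeline(
    cfg: PipelineConfig,
    datasets: dict | None = None,
    orthology: OrthologyMap | None = None,
    base_dir=None,
) -> Path:
    """Execute the full workflow; returns the run directory.

    Datasets may be passed in memory or loaded from ``cfg.data_dir``.
    Relative paths in the config are resolved against ``base_dir`` (so a
    run directory tree is relocatable and the manifest carries no
    machine-specific paths). Stage failures raise :class:`StageError`
    naming the stage; outputs written before the failure are preserved.
    """
    base = Path(base_dir) if base_dir is not None else Path(".")

    def _resolve(p):
        p = Path(p)
        return p if p.is_absolute() else base / p

    out = _resolve(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "modules").mkdir(exist_ok=True)
    log = open(out / "run.log", "w")
    stage = "load"
    try:
        if datasets is None:
            if cfg.data_dir is None:
                raise StageError("no datasets given and no data_dir configured")
            datasets, omap_loaded = load_compendium_dir(_resolve(cfg.data_dir))
            orthology = orthology or omap_loaded
        ds_ids = sorted(datasets)
        _log(log, f"[load] {len(ds_ids)} datasets: {', '.join(ds_ids)}")

        stage = "isa"
        catalogs: dict[str, ModuleCatalog] = {}
        for k, ds_id in enumerate(ds_ids):
            ds = datasets[ds_id]
            inp = standardize(ds.values)
            isa_cfg = IsaConfig.for_kind(
                ds.kind, seed=_substream_seed(cfg.seed, _SUB_ISA, k), **cfg.isa
            )
            modules = isa_sweep(inp, isa_cfg, dataset_id=ds_id)
            _log(log, f"[isa] {ds_id}: {len(modules)} raw fixed points")
            if cfg.robustness:
                modules = robustness_filter(modules, inp, isa_cfg)
                _log(log, f"[robustness] {ds_id}: {len(modules)} kept")
            drug_of = ds.drug_of_profile().to_dict()
            modules = [m.with_drug_map(drug_of) for m in modules]

            fcfg = FilterConfig.for_kind(ds.kind, **cfg.filters)
            if ds.untreated is None:
                raise StageError(f"dataset {ds_id} lacks an untreated matrix")
            modules = apply_filters(modules, ds.untreated, fcfg, list(inp.genes))
            modules = [
                Module(
                    module_id=f"{ds_id}-{i + 1}",
                    dataset_id=ds_id,
                    gene_scores=m.gene_scores,
                    condition_scores=m.condition_scores,
                    t_gene=m.t_gene,
                    t_drug=m.t_drug,
                    drug_ids=m.drug_ids,
                    n_seeds=m.n_seeds,
                    n_iter=m.n_iter,
                )
                for i, m in enumerate(modules)
            ]
            cat = ModuleCatalog(
                dataset_id=ds_id,
                kind=ds.kind,
                modules=modules,
                gene_universe=tuple(map(str, inp.genes)),
                drug_universe=tuple(sorted(set(drug_of.values()))),
            )
            catalogs[ds_id] = cat
            write_catalog(cat, out / "modules" / f"{ds_id}.json")
            _log(log, f"[filter] {ds_id}: {len(modules)} modules in catalog")

        stage = "compare"
        q_gene = cfg.compare.get("q_gene", 0.01)
        q_drug = cfg.compare.get("q_drug", 0.01)
        n_perm = cfg.compare.get("n_perm", 1000)
        all_links, rbh_links = [], []
        for i, a in enumerate(ds_ids):
            for b in ds_ids[i + 1:]:
                cat_a, cat_b = catalogs[a], catalogs[b]
                if cat_a.kind == "liver" and cat_b.kind == "cellline":
                    cat_a, cat_b = cat_b, cat_a
                omap = None
                if cat_b.kind == "liver" and orthology is not None:
                    omap = orthology
                links = gene_overlap_links(cat_a, cat_b, omap=omap, q_cut=q_gene)
                if cat_a.kind == cat_b.kind == "cellline" and links:
                    links = drug_overlap_links(links, catalogs, q_cut=q_drug)
                rbh = reciprocal_best_hits(links)
                all_links.extend(links)
                rbh_links.extend(rbh)
        links_table(all_links).to_csv(out / "links.tsv", sep="\t", index=False)
        codims = build_codims(rbh_links, catalogs)
        _write_json(
            [
                {
                    "codim_id": c.codim_id,
                    "member_modules": [list(m) for m in c.member_modules],
                    "genes": sorted(c.genes),
                    "drugs": sorted(c.drugs),
                    "liver_partners": [list(m) for m in c.liver_partners],
                }
                for c in codims
            ],
            out / "codims.json",
        )
        _log(log, f"[compare] {len(rbh_links)} RBH links, {len(codims)} CODIMs")

        stage = "conservation"
        rows = []
        liver_ids = [d for d in ds_ids if catalogs[d].kind == "liver"]
        for k, a in enumerate(d for d in ds_ids if catalogs[d].kind == "cellline"):
            for liver in liver_ids:
                if not catalogs[a].modules or not catalogs[liver].modules:
                    continue
                obs, p = conservation_permutation_test(
                    catalogs[a],
                    catalogs[liver],
                    omap=orthology,
                    n_perm=n_perm,
                    seed=_substream_seed(cfg.seed, _SUB_CONSERVE, k),
                    q_cut=q_gene,
                )
                rows.append((a, liver, obs, len(catalogs[a].modules), p))
        pd.DataFrame(
            rows, columns=["dataset", "versus", "conserved", "n_modules", "p_value"]
        ).to_csv(out / "conservation.tsv", sep="\t", index=False)

        stage = "coherence"
        if cfg.coherence:
            net = AssociationNetwork.from_tsv(_resolve(cfg.coherence["network"]))
            n_random = cfg.coherence.get("n_random", 1000)
            rows = []
            for ds_id in ds_ids:
                cat = catalogs[ds_id]
                for m in cat.modules:
                    genes = sorted(m.gene_ids)
                    prop, p = coherence_test(
                        genes, net, cat.gene_universe, n_random=n_random,
                        seed=_substream_seed(
                            cfg.seed, _SUB_COHERENCE, zlib.crc32(m.module_id.encode())
                        ),
                    )
                    rows.append(("module", m.module_id, len(genes), prop, p, p < 0.05))
            universe = sorted(
                {g for d in ds_ids if catalogs[d].kind == "cellline"
                 for g in catalogs[d].gene_universe}
            )
            for c in codims:
                genes = sorted(c.genes)
                prop, p = coherence_test(
                    genes, net, universe, n_random=n_random,
                    seed=_substream_seed(
                        cfg.seed, _SUB_COHERENCE, zlib.crc32(c.codim_id.encode())
                    ),
                )
                rows.append(("codim", c.codim_id, len(genes), prop, p, p < 0.05))
            pd.DataFrame(
                rows,
                columns=["scope", "id", "n_genes", "proportion", "p_value", "significant"],
            ).to_csv(out / "coherence.tsv", sep="\t", index=False)
            _log(log, f"[coherence] {len(rows)} gene sets tested")

        stage = "annotation"
        if cfg.annotation:
            catalog = AnnotationCatalog.from_tsv(
                _resolve(cfg.annotation["catalog"]),
                fingerprints_path=(
                    _resolve(cfg.annotation["fingerprints"])
                    if cfg.annotation.get("fingerprints")
                    else None
                ),
            )
            q = cfg.annotation.get("q", 0.1)
            q_frag = cfg.annotation.get("q_fragment", 0.01)
            min_term = cfg.annotation.get("min_term_drugs", 5)
            results = []
            for ds_id in ds_ids:
                cat = catalogs[ds_id]
                if cat.kind != "cellline":
                    continue
                universe = set(cat.drug_universe)
                filtered = filter_terms(catalog, min_drugs=min_term, drug_universe=universe)
                for m in cat.modules:
                    results.extend(
                        enrich_terms(
                            m.drug_ids, filtered, universe,
                            q_cut_default=q, q_cut_fragment=q_frag,
                            module_id=m.module_id,
                        )
                    )
            union_universe = {
                d for ds_id in ds_ids if catalogs[ds_id].kind == "cellline"
                for d in catalogs[ds_id].drug_universe
            }
            filtered = filter_terms(catalog, min_drugs=min_term, drug_universe=union_universe)
            for c in codims:
                if c.drugs:
                    results.extend(
                        enrich_terms(
                            c.drugs, filtered, union_universe,
                            q_cut_default=q, q_cut_fragment=q_frag,
                            module_id=c.codim_id,
                        )
                    )
            enrichment_table(results).to_csv(out / "enrichment.tsv", sep="\t", index=False)
            _log(log, f"[annotation] {len(results)} term tests")

        stage = "summary"
        conserved_of = {
            ds: len({l.module_a for l in rbh_links if l.dataset_a == ds}
                    | {l.module_b for l in rbh_links if l.dataset_b == ds})
            for ds in ds_ids
        }
        rows = [
            (
                ds,
                catalogs[ds].kind,
                len(catalogs[ds].modules),
                conserved_of[ds],
                round(conserved_of[ds] / len(catalogs[ds].modules), 4)
                if catalogs[ds].modules
                else 0.0,
            )
            for ds in ds_ids
        ]
        summary = pd.DataFrame(
            rows, columns=["dataset", "kind", "n_modules", "n_conserved", "conserved_fraction"]
        )
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
        _log(log, f"[summary] {len(codims)} CODIMs; catalog sizes "
                  f"{[len(catalogs[d].modules) for d in ds_ids]}")

        stage = "manifest"
        _write_json(
            {
                "version": __version__,
                "seed": cfg.seed,
                "config": asdict(cfg),
                "datasets": {
                    ds: {
                        "kind": catalogs[ds].kind,
                        "n_genes": len(catalogs[ds].gene_universe),
                        "n_drugs": len(catalogs[ds].drug_universe),
                        "n_modules": len(catalogs[ds].modules),
                    }
                    for ds in ds_ids
                },
                "n_codims": len(codims),
            },
            out / "manifest.json",
        )
    except StageError:
        raise
    except Exception as exc:
        raise StageError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.close()
    return out


def demo_truth(n_genes: int = 1500, n_drugs: int = 120):
    """The demo compendium's planted design: three drug-induced modules
    shared by all cell lines (one also planted in the liver dataset) and
    one constitutive module that the filters must remove."""
    from .synth import PlantedModule, drug_id, gene_id

    def block(g0, ng, d0, nd, n_down):
        genes = tuple(gene_id(i) for i in range(g0, g0 + ng))
        drugs = tuple(drug_id(i) for i in range(d0, d0 + nd))
        signs = tuple([1] * (ng - n_down) + [-1] * n_down)
        return genes, drugs, signs

    gA, dA, sA = block(0, 50, 0, 15, 20)
    gB, dB, sB = block(60, 45, 20, 12, 15)
    gC, dC, sC = block(120, 40, 36, 10, 0)
    gK, dK, sK = block(200, 30, 50, 8, 10)
    cell = ("CL1", "CL2", "CL3")
    return [
        PlantedModule("A", gA, dA, 3.0, sA, cell + ("LIVER",), False),
        PlantedModule("B", gB, dB, 3.0, sB, cell, False),
        PlantedModule("C", gC, dC, 3.0, sC, cell, False),
        PlantedModule("K", gK, dK, 3.0, sK, cell, True),
    ]


def make_demo(
    seed: int = 7,
    out_dir="codim_demo",
    n_genes: int = 1500,
    n_drugs: int = 120,
    n_seeds: int = 100,
    n_perm: int = 999,
    n_random: int = 1000,
) -> Path:
    """Generate a synthetic compendium, run the full pipeline on it.

    Three cell lines (n_genes x n_drugs) plus a liver-like dataset on 40%
    of the gene space with four dose/time profiles per drug; planted
    design from :func:`demo_truth`. Returns the run directory.
    """
    from .synth import generate_annotations, generate_compendium, generate_network

    out = Path(out_dir)
    data_dir = out / "data"
    truth = demo_truth(n_genes, n_drugs)
    comp = generate_compendium(
        n_genes=n_genes, n_drugs=n_drugs, planted=truth, seed=seed
    )
    comp.to_dir(data_dir)
    genes = [g for g in comp.datasets["CL1"].values.index]
    net = generate_network(
        genes, within_module_density=0.5, background_density=0.01,
        planted=[m for m in truth if not m.constitutive], seed=seed,
    )
    net.to_tsv(data_dir / "network.tsv")
    drugs = sorted(comp.datasets["CL1"].drugs)
    annot = generate_annotations(
        drugs,
        planted_enrichments=[("A", "target", "target:PLANTED", 0.8)],
        modules=truth,
        seed=seed,
    )
    annot.to_tsv(data_dir / "annotations.tsv")
    annot.fingerprints_to_tsv(data_dir / "fingerprints.tsv")

    cfg = PipelineConfig(
        out_dir="run",
        seed=seed,
        data_dir="data",
        isa={"n_seeds": n_seeds},
        compare={"n_perm": n_perm},
        coherence={"network": "data/network.tsv", "n_random": n_random},
        annotation={
            "catalog": "data/annotations.tsv",
            "fingerprints": "data/fingerprints.tsv",
        },
    )
    cfg.to_yaml(out / "config.yaml")
    run_pipeline(cfg, datasets=comp.datasets, orthology=comp.orthology, base_dir=out)
    return out
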