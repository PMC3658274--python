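"""Cross-dataset module matching, conserved-module construction and the
conservation permutation test.

Modules from two datasets are compared by the hypergeometric significance
of their gene overlap inside a shared universe (the intersection of the
two datasets' gene universes after one-to-one orthology translation),
BH-FDR-corrected per dataset pair. A reciprocal best hit (RBH) is a
significant link in which each module is the other's most significant
partner. Conserved drug-induced modules (CODIMs) are the connected
components of the RBH graph among cell-line modules, taking the union of
gene and drug members; liver links annotate cross-species conservation
but liver members are reported separately. Drug-set overlap of linked
cell-line modules is tested with one-sided Fisher tests. Whether a
catalog shares more modules with another than expected is judged by
permuting module gene memberships (random same-size gene sets) and
recounting RBHs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy import stats as _sps

from .datasets import OrthologyMap
from .stats import (
    ContingencyTable,
    DomainError,
    bh_fdr,
    empirical_p,
    fisher_exact_greater,
)

__all__ = [
    "ModuleCatalog",
    "ModuleLink",
    "CODIM",
    "gene_overlap_links",
    "reciprocal_best_hits",
    "build_codims",
    "drug_overlap_links",
    "conservation_permutation_test",
]


@dataclass
class ModuleCatalog:
    """A dataset's filtered modules plus its gene and drug universes."""

    dataset_id: str
    kind: str  # "cellline" or "liver"
    modules: list
    gene_universe: tuple
    drug_universe: tuple

    def module_by_id(self, module_id: str):
        for m in self.modules:
            if m.module_id == module_id:
                return m
        raise KeyError(module_id)


@dataclass(frozen=True)
class ModuleLink:
    """A scored cross-dataset module pair."""

    module_a: str
    dataset_a: str
    module_b: str
    dataset_b: str
    overlap: int
    p_gene: float
    q_gene: float
    significant: bool
    reciprocal_best: bool = False
    p_drug: float | None = None
    q_drug: float | None = None
    drug_overlap_significant: bool | None = None


@dataclass(frozen=True)
class CODIM:
    """Conserved drug-induced module: union over reciprocally linked modules."""

    codim_id: str
    member_modules: tuple  # ((dataset_id, module_id), ...)
    genes: frozenset
    drugs: frozenset
    liver_partners: tuple = ()


def _translate(genes, mapping) -> set:
    if mapping is None:
        return set(genes)
    return {mapping[g] for g in genes if g in mapping}


def _shared_universe(cat_a, cat_b, omap: OrthologyMap | None):
    """Universe and per-module gene sets of both catalogs, projected into
    catalog a's namespace."""
    b_to_a = None if omap is None else omap.b_to_a()
    shared = set(cat_a.gene_universe) & _translate(cat_b.gene_universe, b_to_a)
    if not shared:
        raise DomainError(
            f"empty shared gene universe between {cat_a.dataset_id} and {cat_b.dataset_id}"
        )
    sets_a = [set(m.gene_ids) & shared for m in cat_a.modules]
    sets_b = [_translate(m.gene_ids, b_to_a) & shared for m in cat_b.modules]
    return shared, sets_a, sets_b


def _pair_pvalues(sets_a, sets_b, universe_size: int):
    """Overlap counts and upper-tail hypergeometric P for every module pair."""
    n_a, n_b = len(sets_a), len(sets_b)
    O = np.zeros((n_a, n_b), dtype=int)
    for i, sa in enumerate(sets_a):
        for j, sb in enumerate(sets_b):
            O[i, j] = len(sa & sb)
    la = np.array([len(s) for s in sets_a])[:, None]
    lb = np.array([len(s) for s in sets_b])[None, :]
    P = _sps.hypergeom.sf(O - 1, universe_size, la, lb)
    return O, np.asarray(P, dtype=float)


def gene_overlap_links(
    cat_a: ModuleCatalog,
    cat_b: ModuleCatalog,
    omap: OrthologyMap | None = None,
    q_cut: float = 0.01,
) -> list:
    """Hypergeometric gene-overlap links between all module pairs.

    Memberships are projected into the shared universe; P values are
    BH-FDR-corrected across all pairs of this dataset pair; a link is
    significant iff q < ``q_cut``.
    """
    shared, sets_a, sets_b = _shared_universe(cat_a, cat_b, omap)
    if not cat_a.modules or not cat_b.modules:
        return []
    O, P = _pair_pvalues(sets_a, sets_b, len(shared))
    Q = bh_fdr(P.ravel()).q.reshape(P.shape)
    links = []
    for i, ma in enumerate(cat_a.modules):
        for j, mb in enumerate(cat_b.modules):
            links.append(
                ModuleLink(
                    module_a=ma.module_id,
                    dataset_a=cat_a.dataset_id,
                    module_b=mb.module_id,
                    dataset_b=cat_b.dataset_id,
                    overlap=int(O[i, j]),
                    p_gene=float(P[i, j]),
                    q_gene=float(Q[i, j]),
                    significant=bool(Q[i, j] < q_cut),
                )
            )
    return links


def reciprocal_best_hits(links) -> list:
    """Mark links where each module is the other's best (min-P) partner.

    Only significant links qualify. Returns the RBH links with the flag
    set, one per reciprocal pair.
    """
    links = list(links)
    best_a: dict = {}
    best_b: dict = {}
    for l in links:
        ka = (l.dataset_a, l.module_a, l.dataset_b)
        kb = (l.dataset_b, l.module_b, l.dataset_a)
        ta = (l.p_gene, -l.overlap, l.module_b)
        tb = (l.p_gene, -l.overlap, l.module_a)
        if ka not in best_a or ta < best_a[ka][0]:
            best_a[ka] = (ta, l)
        if kb not in best_b or tb < best_b[kb][0]:
            best_b[kb] = (tb, l)
    out = []
    for (ds_a, mod_a, ds_b), (_, l) in best_a.items():
        if not l.significant:
            continue
        kb = (l.dataset_b, l.module_b, l.dataset_a)
        if kb in best_b and best_b[kb][1] is l:
            out.append(replace(l, reciprocal_best=True))
    return out


def build_codims(rbh_links, catalogs: dict) -> list:
    """Connected components of the RBH graph among cell-line modules.

    Components with >= 2 member modules become CODIMs with union gene and
    drug sets (built from cell-line members only; liver modules linked by
    RBH to a member are recorded as ``liver_partners``).
    """
    kind = {ds: cat.kind for ds, cat in catalogs.items()}
    graph = nx.Graph()
    liver_edges = []
    for l in rbh_links:
        if not l.reciprocal_best:
            continue
        a, b = (l.dataset_a, l.module_a), (l.dataset_b, l.module_b)
        if kind.get(l.dataset_a) == "cellline" and kind.get(l.dataset_b) == "cellline":
            graph.add_edge(a, b)
        else:
            liver_edges.append((a, b))
    codims = []
    components = sorted(
        (sorted(comp) for comp in nx.connected_components(graph)), key=lambda c: c[0]
    )
    for idx, comp in enumerate(components, start=1):
        if len(comp) < 2:
            continue
        genes: set = set()
        drugs: set = set()
        for ds, mid in comp:
            m = catalogs[ds].module_by_id(mid)
            genes |= set(m.gene_ids)
            drugs |= set(m.drug_ids)
        members = set(comp)
        partners = sorted(
            {
                other
                for a, b in liver_edges
                for side, other in ((a, b), (b, a))
                if side in members and kind.get(other[0]) == "liver"
            }
        )
        codims.append(
            CODIM(
                codim_id=f"CODIM{idx}",
                member_modules=tuple(comp),
                genes=frozenset(genes),
                drugs=frozenset(drugs),
                liver_partners=tuple(partners),
            )
        )
    return codims


def drug_overlap_links(links, catalogs: dict, q_cut: float = 0.01) -> list:
    """Fisher drug-overlap test for links between cell-line datasets.

    The shared drug universe is the intersection of the two datasets' drug
    universes; BH-FDR per dataset pair. Liver datasets are refused: too
    few drugs are shared with them for the test to be meaningful.
    """
    links = list(links)
    for l in links:
        for ds in (l.dataset_a, l.dataset_b):
            if catalogs[ds].kind != "cellline":
                raise DomainError(
                    f"drug-overlap test refused for dataset {ds!r}: only cell-line "
                    "datasets share enough drugs for a meaningful comparison"
                )
    by_pair: dict = {}
    for idx, l in enumerate(links):
        by_pair.setdefault((l.dataset_a, l.dataset_b), []).append(idx)
    out = list(links)
    for (ds_a, ds_b), idxs in by_pair.items():
        universe = set(catalogs[ds_a].drug_universe) & set(catalogs[ds_b].drug_universe)
        if not universe:
            raise DomainError(f"empty shared drug universe for {ds_a} vs {ds_b}")
        N = len(universe)
        ps = []
        for i in idxs:
            l = links[i]
            da = set(catalogs[ds_a].module_by_id(l.module_a).drug_ids) & universe
            db = set(catalogs[ds_b].module_by_id(l.module_b).drug_ids) & universe
            k = len(da & db)
            p = fisher_exact_greater(
                ContingencyTable(k, len(da) - k, len(db) - k, N - len(da | db))
            )
            ps.append(p)
        q = bh_fdr(ps).q
        for i, p, qv in zip(idxs, ps, q):
            out[i] = replace(
                out[i],
                p_drug=float(p),
                q_drug=float(qv),
                drug_overlap_significant=bool(qv < q_cut),
            )
    return out


def _count_rbh(sets_a, sets_b, universe_size: int, q_cut: float) -> int:
    """Number of a-side modules with a significant reciprocal best hit."""
    if not sets_a or not sets_b:
        return 0
    O, P = _pair_pvalues(sets_a, sets_b, universe_size)
    Q = bh_fdr(P.ravel()).q.reshape(P.shape)
    # best partner per row/column: min P, ties by larger overlap then index
    count = 0
    for i in range(len(sets_a)):
        keys = list(zip(P[i], -O[i], range(len(sets_b))))
        j = min(range(len(sets_b)), key=lambda jj: keys[jj])
        if Q[i, j] >= q_cut:
            continue
        keys_b = list(zip(P[:, j], -O[:, j], range(len(sets_a))))
        i_back = min(range(len(sets_a)), key=lambda ii: keys_b[ii])
        if i_back == i:
            count += 1
    return count


def conservation_permutation_test(
    cat_a: ModuleCatalog,
    cat_b: ModuleCatalog,
    omap: OrthologyMap | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    q_cut: float = 0.01,
) -> tuple[int, float]:
    """Is the number of conserved catalog-a modules more than chance?

    Observed statistic: count of catalog-a modules with a significant
    reciprocal best hit in catalog b. Null: each a-module's gene set is
    replaced by a uniformly drawn gene set of the same size from
    catalog a's universe (projected into the shared universe) and the
    statistic recomputed; P by the add-one empirical rule. Returns
    (observed count, empirical P).
    """
    if n_perm < 1:
        raise DomainError("n_perm must be >= 1")
    shared, sets_a, sets_b = _shared_universe(cat_a, cat_b, omap)
    universe = sorted(shared)
    n_u = len(universe)
    observed = _count_rbh(sets_a, sets_b, n_u, q_cut)
    sizes = [len(s) for s in sets_a]
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    uni = np.array(universe, dtype=object)
    for t in range(n_perm):
        perm_sets = [
            set(uni[rng.choice(n_u, size=k, replace=False)]) if k else set()
            for k in sizes
        ]
        null[t] = _count_rbh(perm_sets, sets_b, n_u, q_cut)
    return observed, empirical_p(observed, null)
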