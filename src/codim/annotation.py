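"""Drug-set enrichment over annotation catalogs and repositioning selection.

A module's drug members are tested for over-representation of annotation
terms (drug targets, ATC therapeutic classes, side effects, chemical
fragments, or any custom catalog) with one-sided Fisher exact tests,
BH-FDR-corrected within each category. Structurally novel repositioning
candidates are module drugs lacking the target annotation whose chemical
fingerprints are dissimilar (Tanimoto < 0.5) to every annotated module
drug.

Fragment generation itself (exhaustive molecular fragmentation and
substructure search) is not performed here: fragment x drug matrices enter
as a catalog category, and fingerprints as bit-vectors, so any
cheminformatics toolkit can be plugged in upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import ContingencyTable, DomainError, bh_fdr, fisher_exact_greater

FINGERPRINT_BITS = 1024  # hashed-fingerprint default length


@dataclass
class AnnotationCatalog:
    """Named categories mapping terms to drug sets, plus drug fingerprints.

    ``categories``: category name -> {term -> frozenset of drug ids}.
    ``fingerprints``: drug id -> boolean bit-vector (uniform length).
    """

    categories: dict = field(default_factory=dict)
    fingerprints: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.fingerprints.values()}
        if len(lengths) > 1:
            raise DomainError(f"fingerprint lengths not uniform: {sorted(lengths)}")

    @property
    def drug_universe(self) -> set:
        drugs = set(self.fingerprints)
        for terms in self.categories.values():
            for members in terms.values():
                drugs |= set(members)
        return drugs

    def term_drugs(self, category: str, term: str) -> frozenset:
        return self.categories.get(category, {}).get(term, frozenset())

    def to_tsv(self, path) -> None:
        rows = [
            (cat, term, drug)
            for cat in sorted(self.categories)
            for term in sorted(self.categories[cat])
            for drug in sorted(self.categories[cat][term])
        ]
        pd.DataFrame(rows, columns=["category", "term", "drug"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, fingerprints_path=None) -> "AnnotationCatalog":
        df = pd.read_csv(path, sep="\t")
        categories: dict = {}
        for (cat, term), grp in df.groupby(["category", "term"]):
            categories.setdefault(cat, {})[term] = frozenset(grp["drug"])
        fps = {}
        if fingerprints_path is not None:
            fps = read_fingerprints_tsv(fingerprints_path)
        return cls(categories=categories, fingerprints=fps)

    def fingerprints_to_tsv(self, path) -> None:
        rows = []
        for drug in sorted(self.fingerprints):
            bits = np.asarray(self.fingerprints[drug], dtype=bool)
            rows.append((drug, _bits_to_hex(bits), bits.size))
        pd.DataFrame(rows, columns=["drug", "fingerprint_hex", "n_bits"]).to_csv(
            path, sep="\t", index=False
        )


def _bits_to_hex(bits: np.ndarray) -> str:
    return np.packbits(bits.astype(np.uint8)).tobytes().hex()


def _hex_to_bits(hexstr: str, n_bits: int) -> np.ndarray:
    return np.unpackbits(np.frombuffer(bytes.fromhex(hexstr), dtype=np.uint8))[
        :n_bits
    ].astype(bool)


def read_fingerprints_tsv(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    return {
        row.drug: _hex_to_bits(row.fingerprint_hex, int(row.n_bits))
        for row in df.itertuples()
    }


@dataclass(frozen=True)
class EnrichmentResult:
    """One term's enrichment in one module's drug set."""

    module_id: str
    category: str
    term: str
    k: int  # module drugs carrying the term
    K: int  # universe drugs carrying the term
    n: int  # module drugs
    N: int  # universe drugs
    p: float
    q: float = float("nan")
    significant: bool = False


def filter_terms(
    catalog: AnnotationCatalog, min_drugs: int = 5, drug_universe=None
) -> AnnotationCatalog:
    """Drop terms linked with fewer than ``min_drugs`` drugs.

    Membership is counted within ``drug_universe`` when given (terms are
    judged against the drugs actually present in the dataset).
    """
    universe = None if drug_universe is None else set(drug_universe)
    categories = {}
    for cat, terms in catalog.categories.items():
        kept = {}
        for term, members in terms.items():
            counted = members if universe is None else members & universe
            if len(counted) >= min_drugs:
                kept[term] = members
        categories[cat] = kept
    return AnnotationCatalog(categories=categories, fingerprints=catalog.fingerprints)


def enrich_terms(
    module_drugs,
    catalog: AnnotationCatalog,
    drug_universe,
    q_cut_default: float = 0.1,
    q_cut_fragment: float = 0.01,
    module_id: str = "module",
    fragment_category: str = "fragment",
) -> list[EnrichmentResult]:
    """Fisher enrichment of every catalog term in the module's drug set.

    One one-sided test per term; BH-FDR within each category; the
    significance flag applies the category-specific cutoff on the adjusted
    value (``q_cut_fragment`` for the fragment category, ``q_cut_default``
    elsewhere).
    """
    universe = set(drug_universe)
    module = set(module_drugs) & universe
    if not module:
        raise DomainError("module drug set is empty (within the universe)")
    n, N = len(module), len(universe)
    results: list[EnrichmentResult] = []
    for cat in sorted(catalog.categories):
        terms = catalog.categories[cat]
        names = sorted(terms)
        if not names:
            continue
        rows = []
        for term in names:
            members = set(terms[term]) & universe
            k = len(module & members)
            K = len(members)
            p = fisher_exact_greater(
                ContingencyTable(k, n - k, K - k, N - n - (K - k))
            )
            rows.append((term, k, K, p))
        q = bh_fdr([r[3] for r in rows]).q
        cut = q_cut_fragment if cat == fragment_category else q_cut_default
        for (term, k, K, p), qv in zip(rows, q):
            results.append(
                EnrichmentResult(
                    module_id=module_id,
                    category=cat,
                    term=term,
                    k=k,
                    K=K,
                    n=n,
                    N=N,
                    p=p,
                    q=float(qv),
                    significant=bool(qv < cut),
                )
            )
    return results


def enrichment_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.module_id, r.category, r.term, r.k, r.K, r.n, r.N, r.p, r.q, r.significant)
            for r in results
        ],
        columns=["module", "category", "term", "k", "K", "n", "N", "p", "q", "significant"],
    )


def tanimoto(fp_a, fp_b) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| of two fingerprint bit-vectors."""
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise DomainError("fingerprints must have equal length")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        raise DomainError("Tanimoto undefined for two all-zero fingerprints")
    return float(np.count_nonzero(a & b) / union)


def repositioning_candidates(
    module_drugs,
    target_term: str,
    catalog: AnnotationCatalog,
    category: str = "target",
    max_sim: float = 0.5,
) -> list:
    """Module drugs not annotated with the target and structurally novel.

    A candidate is a module drug lacking ``target_term`` whose maximum
    Tanimoto similarity to any annotated module drug is below ``max_sim``:
    the transcriptional module, not chemical similarity, is what links it
    to the target.
    """
    if target_term not in catalog.categories.get(category, {}):
        raise DomainError(f"term {target_term!r} not in category {category!r}")
    annotated_universe = catalog.term_drugs(category, target_term)
    module = sorted(set(module_drugs))
    annotated = [d for d in module if d in annotated_universe]
    if not annotated:
        warnings.warn(
            f"no module drug annotated with {target_term!r}; no similarity anchor",
            stacklevel=2,
        )
        return []
    candidates = []
    for d in module:
        if d in annotated_universe:
            continue
        if d not in catalog.fingerprints:
            continue
        sims = [
            tanimoto(catalog.fingerprints[d], catalog.fingerprints[a])
            for a in annotated
            if a in catalog.fingerprints
        ]
        if sims and max(sims) < max_sim:
            candidates.append(d)
    return candidates
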