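"""Overlap-enrichment screen: Fisher's exact test over drug-disease pairs.

For every (drug, disease) pair the screen asks whether the drug's target
genes are overrepresented among the disease's associated genes, relative
to a background gene universe. The 2x2 table for a pair is::

                       disease gene    not disease gene
    drug target             a                 b
    not drug target         c                 d

with a+b+c+d = N, the universe size. Under the null of no association,
`a` follows a hypergeometric distribution with the table's margins fixed;
the one-sided upper-tail Fisher exact P is the probability of an overlap
at least as large as observed. P-values are adjusted across all tested
pairs with the Benjamini-Hochberg step-up procedure, and pairs with
q < 0.05 (by default) are called significant predicted indications.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .networks import DGINetwork, DiseaseRecord, DrugRecord, GDANetwork, GeneRef

__all__ = [
    "ContingencyTable",
    "EnrichmentResult",
    "ScreenReport",
    "DegenerateTableError",
    "build_universe",
    "build_contingency",
    "fisher_exact_upper",
    "bh_adjust",
    "screen_all_pairs",
    "rank_for_disease",
    "write_screen_tsv",
    "EnrichmentScreen",
]

UNIVERSE_MODES = ("intersection", "gda_all", "union")


class DegenerateTableError(ValueError):
    """Drug or disease has no genes in the universe: the table is undefined."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table restricted to the background universe."""

    a: int  # drug targets that are disease genes
    b: int  # drug targets that are not disease genes
    c: int  # disease genes not targeted by the drug
    d: int  # universe genes in neither set

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            if getattr(self, name) < 0:
                raise ValueError(f"count {name} must be >= 0")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_targets(self) -> int:
        """Drug targets in the universe (row margin)."""
        return self.a + self.b

    @property
    def n_disease_genes(self) -> int:
        """Disease genes in the universe (column margin)."""
        return self.a + self.c

    def odds_ratio(self) -> float:
        """Unconditional ad/bc; descriptive only, never drives ranking."""
        if self.b * self.c == 0:
            return math.inf if self.a * self.d > 0 else 0.0
        return (self.a * self.d) / (self.b * self.c)


@dataclass
class EnrichmentResult:
    """One scored drug-disease pair."""

    drug_id: str
    mesh_id: str
    table: ContingencyTable
    overlap_genes: list[GeneRef]
    odds_ratio: float
    p_value: float
    q_value: float = math.nan
    rank: int | None = None
    drug_name: str = ""
    mesh_name: str = ""


@dataclass
class ScreenReport:
    """All tested pairs of one screen, BH-adjusted over exactly those pairs."""

    results: list[EnrichmentResult]
    universe_size: int
    q_cutoff: float = 0.05
    skipped_drugs: int = 0
    skipped_diseases: int = 0

    @property
    def n_pairs_tested(self) -> int:
        return len(self.results)

    @property
    def significant(self) -> list[EnrichmentResult]:
        return [r for r in self.results if r.q_value < self.q_cutoff]


def build_universe(dgi: DGINetwork, gda: GDANetwork,
                   mode: str = "intersection") -> set[GeneRef]:
    """Background gene universe for the 2x2 tables.

    ``intersection`` (default): genes that are both a target of at least
    one drug and associated with at least one disease. ``gda_all``: every
    disease-associated gene. ``union``: either side. The choice changes
    every P value, so screens record which mode was used.
    """
    if mode not in UNIVERSE_MODES:
        raise ValueError(f"unknown universe mode {mode!r}; use one of {UNIVERSE_MODES}")
    targets = dgi.target_genes
    disease_genes = gda.gene_universe
    if mode == "intersection":
        uni = targets & disease_genes
    elif mode == "gda_all":
        uni = set(disease_genes)
    else:
        uni = targets | disease_genes
    if not uni:
        raise ValueError("empty gene universe")
    return uni


def build_contingency(drug: DrugRecord, disease: DiseaseRecord,
                      universe: set[GeneRef]) -> ContingencyTable:
    """Overlap table for one pair; both gene sets are first restricted
    to the universe. Raises :class:`DegenerateTableError` when either
    restricted set is empty (the test is undefined for such pairs)."""
    if not universe:
        raise ValueError("empty universe")
    tset = drug.targets & universe
    dset = disease.genes & universe
    if not tset or not dset:
        raise DegenerateTableError(
            f"pair ({drug.drug_id}, {disease.mesh_id}) has an empty "
            "in-universe gene set"
        )
    a = len(tset & dset)
    b = len(tset) - a
    c = len(dset) - a
    d = len(universe) - a - b - c
    return ContingencyTable(a, b, c, d)


def _upper_tail_p(a: int, K: int, M: int, n: int) -> float:
    # P(X >= a), X ~ Hypergeom(n, K, M): exactly 1.0 when a is the minimal
    # feasible overlap (the tail is the whole support). The leading term is
    # computed by correctly-rounded big-integer division (int/int), the
    # remaining terms by the pmf ratio recurrence, and the tail summed with
    # compensated (fsum) summation: each term carries only O(k) ulp error,
    # so the tail is accurate to ~1e-13 even at n = 10^4.
    kmin = max(0, K + M - n)
    if a <= kmin:
        return 1.0
    kmax = min(K, M)
    term = (math.comb(K, a) * math.comb(n - K, M - a)) / math.comb(n, M)
    terms = [term]
    for k in range(a, kmax):
        term *= ((K - k) * (M - k)) / ((k + 1) * (n - K - M + k + 1))
        terms.append(term)
    return min(1.0, math.fsum(terms))


def fisher_exact_upper(table: ContingencyTable,
                       alternative: str = "greater") -> float:
    """Fisher's exact P for one table.

    ``greater`` (default) is the one-sided upper tail -- the enrichment
    hypothesis that the observed overlap or more arises by chance.
    ``two-sided`` is available for comparison and delegates to scipy.
    """
    if alternative == "two-sided":
        from scipy.stats import fisher_exact

        return float(
            fisher_exact(
                [[table.a, table.b], [table.c, table.d]], alternative="two-sided"
            )[1]
        )
    if alternative != "greater":
        raise ValueError(f"unknown alternative {alternative!r}")
    return _upper_tail_p(table.a, table.n_targets, table.n_disease_genes, table.n)


def bh_adjust(p_values, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``m`` is the size of the test family and defaults to ``len(p_values)``;
    it may be larger (e.g. when only a subset of a family's p-values is
    passed) but never smaller. q_(i) = min_{j>=i} p_(j) * m / j, capped at
    1, mapped back to the input order.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = p.size
    if m < p.size:
        raise ValueError(f"m={m} smaller than number of p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def screen_all_pairs(dgi: DGINetwork, gda: GDANetwork,
                     universe_mode: str = "intersection",
                     min_overlap: int = 1,
                     q_cutoff: float = 0.05,
                     alternative: str = "greater") -> ScreenReport:
    """Score every drug-disease pair with overlap >= ``min_overlap``.

    Pairs below the overlap floor never enter the test nor the BH family
    (zero-overlap pairs have P = 1 deterministically and would only dilute
    the correction); the BH ``m`` is exactly the number of pairs tested.
    Drugs or diseases with no genes in the universe are skipped and
    counted. The report is sorted by (q, p, drug_id, mesh_id).
    """
    universe = build_universe(dgi, gda, mode=universe_mode)
    uni_ids = {g.entrez_id for g in universe}
    gene_lookup = {g.entrez_id: g for g in universe}

    drug_sets: list[tuple[DrugRecord, frozenset[int]]] = []
    skipped_drugs = 0
    for drug_id in sorted(dgi.drugs):
        drug = dgi.drugs[drug_id]
        ids = frozenset(g.entrez_id for g in drug.targets) & uni_ids
        if ids:
            drug_sets.append((drug, frozenset(ids)))
        else:
            skipped_drugs += 1
    disease_sets: list[tuple[DiseaseRecord, frozenset[int]]] = []
    skipped_diseases = 0
    for mesh_id in sorted(gda.diseases):
        disease = gda.diseases[mesh_id]
        ids = frozenset(g.entrez_id for g in disease.genes) & uni_ids
        if ids:
            disease_sets.append((disease, frozenset(ids)))
        else:
            skipped_diseases += 1

    n_uni = len(uni_ids)
    results: list[EnrichmentResult] = []
    for drug, tids in drug_sets:
        nt = len(tids)
        for disease, dids in disease_sets:
            overlap = tids & dids
            a = len(overlap)
            if a < max(min_overlap, 1):
                continue
            table = ContingencyTable(a, nt - a, len(dids) - a,
                                     n_uni - nt - len(dids) + a)
            p = fisher_exact_upper(table, alternative=alternative)
            results.append(
                EnrichmentResult(
                    drug_id=drug.drug_id,
                    mesh_id=disease.mesh_id,
                    table=table,
                    overlap_genes=sorted(
                        (gene_lookup[i] for i in overlap),
                        key=lambda g: g.entrez_id,
                    ),
                    odds_ratio=table.odds_ratio(),
                    p_value=p,
                    drug_name=drug.name,
                    mesh_name=disease.mesh_name,
                )
            )
    if not results:
        warnings.warn("no testable drug-disease pairs", stacklevel=2)
    else:
        qs = bh_adjust([r.p_value for r in results])
        for r, q in zip(results, qs):
            r.q_value = float(q)
        results.sort(key=lambda r: (r.q_value, r.p_value, r.drug_id, r.mesh_id))
    return ScreenReport(
        results=results,
        universe_size=n_uni,
        q_cutoff=q_cutoff,
        skipped_drugs=skipped_drugs,
        skipped_diseases=skipped_diseases,
    )


def rank_for_disease(report: ScreenReport, mesh_id: str,
                     p_cutoff: float = 0.001) -> list[EnrichmentResult]:
    """Ranked indication list for one disease: tested drugs with
    P < ``p_cutoff``, ascending P (ties broken by q, then drug_id),
    rank field populated from 1."""
    rows = [r for r in report.results if r.mesh_id == mesh_id]
    if not rows:
        raise KeyError(f"disease {mesh_id!r} has no tested pairs in this report")
    rows = [r for r in rows if r.p_value < p_cutoff]
    rows.sort(key=lambda r: (r.p_value, r.q_value, r.drug_id))
    for i, r in enumerate(rows, start=1):
        r.rank = i
    return rows


def write_screen_tsv(report: ScreenReport, path) -> None:
    """Write a screen report as TSV (p/q in 6-significant-digit
    scientific notation, overlap genes as ';'-joined sorted symbols)."""
    import pandas as pd

    rows = []
    for r in report.results:
        rows.append(
            {
                "drug_id": r.drug_id,
                "drug_name": r.drug_name,
                "mesh_id": r.mesh_id,
                "mesh_name": r.mesh_name,
                "a": r.table.a,
                "n_targets_in_universe": r.table.n_targets,
                "n_disease_genes_in_universe": r.table.n_disease_genes,
                "universe_size": r.table.n,
                "odds_ratio": "inf" if math.isinf(r.odds_ratio) else f"{r.odds_ratio:.6g}",
                "p_value": f"{r.p_value:.6e}",
                "q_value": f"{r.q_value:.6e}",
                "overlap_genes": ";".join(sorted(g.symbol for g in r.overlap_genes)),
            }
        )
    cols = ["drug_id", "drug_name", "mesh_id", "mesh_name", "a",
            "n_targets_in_universe", "n_disease_genes_in_universe",
            "universe_size", "odds_ratio", "p_value", "q_value",
            "overlap_genes"]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


class EnrichmentScreen(BaseEstimator):
    """Estimator interface to the overlap-enrichment screen.

    Parameters
    ----------
    universe_mode : {"intersection", "gda_all", "union"}
        Background gene universe (see :func:`build_universe`).
    min_overlap : int
        Minimum drug-target / disease-gene overlap for a pair to be tested.
    q_cutoff : float
        BH q-value below which a pair is called a significant predicted
        indication.
    alternative : {"greater", "two-sided"}
        Sidedness of the Fisher test; the enrichment hypothesis is
        one-sided upper tail.

    After ``fit(dgi, gda)`` the fitted attributes are ``report_``
    (:class:`ScreenReport`), ``results_``, ``universe_`` and
    ``universe_size_``. ``score_pairs`` maps (drug_id, mesh_id) pairs to
    -log10(P) scores (0 for untested pairs), the score used for ROC
    benchmarking.
    """

    def __init__(self, universe_mode: str = "intersection",
                 min_overlap: int = 1, q_cutoff: float = 0.05,
                 alternative: str = "greater"):
        self.universe_mode = universe_mode
        self.min_overlap = min_overlap
        self.q_cutoff = q_cutoff
        self.alternative = alternative

    def fit(self, dgi: DGINetwork, gda: GDANetwork) -> "EnrichmentScreen":
        self.universe_ = build_universe(dgi, gda, mode=self.universe_mode)
        self.report_ = screen_all_pairs(
            dgi, gda,
            universe_mode=self.universe_mode,
            min_overlap=self.min_overlap,
            q_cutoff=self.q_cutoff,
            alternative=self.alternative,
        )
        self.results_ = self.report_.results
        self.universe_size_ = self.report_.universe_size
        return self

    def _check_fitted(self) -> None:
        if not hasattr(self, "report_"):
            raise RuntimeError("EnrichmentScreen is not fitted; call fit first")

    def score_pairs(self, pairs) -> np.ndarray:
        self._check_fitted()
        from .benchmark import score_pairs

        return score_pairs(self.report_, pairs)

    def rank_for_disease(self, mesh_id: str,
                         p_cutoff: float = 0.001) -> list[EnrichmentResult]:
        self._check_fitted()
        return rank_for_disease(self.report_, mesh_id, p_cutoff=p_cutoff)

    @property
    def significant_(self) -> list[EnrichmentResult]:
        self._check_fitted()
        return self.report_.significant
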