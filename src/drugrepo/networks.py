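"""Drug-gene and gene-disease network containers with TSV ingestion.

The screen operates on two bipartite edge lists: drug-gene interactions
(DGI), in which a drug is linked to the Entrez genes encoding its targets,
and gene-disease associations (GDA), in which genes are linked to MeSH
disease terms. Both are consumed as flat UTF-8 TSV exports with a header
row; identifiers are canonicalized (genes keyed by Entrez ID, diseases by
MeSH ID) and exact duplicate edges -- typically arising when the same pair
is reported by several source databases -- are collapsed on ingestion.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "NetworkFormatError",
    "GeneRef",
    "DrugRecord",
    "DiseaseRecord",
    "IngestStats",
    "DGINetwork",
    "GDANetwork",
    "read_dgi",
    "read_gda",
    "write_dgi",
    "write_gda",
    "network_summary",
    "DGI_DIALECT",
    "GDA_DIALECT",
]

#: canonical column names; override any entry via the ``dialect`` argument
DGI_DIALECT: dict[str, str] = {
    "drug_id": "drug_id",
    "name": "name",
    "atc": "atc",
    "mesh": "mesh",
    "entrez_id": "entrez_id",
    "symbol": "symbol",
}

GDA_DIALECT: dict[str, str] = {
    "entrez_id": "entrez_id",
    "symbol": "symbol",
    "mesh_id": "mesh_id",
    "mesh_name": "mesh_name",
    "source": "source",
}

#: multi-valued cells (ATC codes, MeSH terms) use this separator
MULTI_SEP = "|"


class NetworkFormatError(ValueError):
    """A TSV is structurally unusable (e.g. a required column is missing)."""


@dataclass(frozen=True, eq=False)
class GeneRef:
    """A gene, identified by its Entrez ID.

    Equality and hashing use the Entrez ID only; the official symbol is an
    annotation and never drives matching (symbols are ambiguous and change,
    integer Entrez IDs do not).
    """

    entrez_id: int
    symbol: str = ""

    def __post_init__(self) -> None:
        if int(self.entrez_id) <= 0:
            raise ValueError(f"entrez_id must be positive, got {self.entrez_id}")
        if not self.symbol:
            object.__setattr__(self, "symbol", str(self.entrez_id))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneRef):
            return NotImplemented
        return self.entrez_id == other.entrez_id

    def __hash__(self) -> int:
        return hash(self.entrez_id)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"GeneRef({self.entrez_id}, {self.symbol!r})"


@dataclass
class DrugRecord:
    """One drug and the set of genes encoding its known targets."""

    drug_id: str
    name: str = ""
    atc_codes: set[str] = field(default_factory=set)
    mesh_terms: set[str] = field(default_factory=set)
    targets: set[GeneRef] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.drug_id:
            raise ValueError("drug_id must be non-empty")


@dataclass
class DiseaseRecord:
    """One MeSH disease term and its associated gene set."""

    mesh_id: str
    mesh_name: str = ""
    genes: set[GeneRef] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.mesh_id:
            raise ValueError("mesh_id must be non-empty")


@dataclass
class IngestStats:
    """Row accounting from one TSV read.

    Invariant: ``raw_rows == kept + duplicates_removed + rows_rejected``
    where *kept* is the resulting network's ``n_pairs``.
    """

    raw_rows: int = 0
    duplicates_removed: int = 0
    rows_rejected: int = 0


@dataclass
class DGINetwork:
    """Drug-gene interaction network: drug_id -> DrugRecord."""

    drugs: dict[str, DrugRecord] = field(default_factory=dict)
    stats: IngestStats = field(default_factory=IngestStats)

    @property
    def n_pairs(self) -> int:
        return sum(len(d.targets) for d in self.drugs.values())

    @property
    def target_genes(self) -> set[GeneRef]:
        out: set[GeneRef] = set()
        for d in self.drugs.values():
            out |= d.targets
        return out


@dataclass
class GDANetwork:
    """Gene-disease association network: mesh_id -> DiseaseRecord."""

    diseases: dict[str, DiseaseRecord] = field(default_factory=dict)
    stats: IngestStats = field(default_factory=IngestStats)

    @property
    def n_pairs(self) -> int:
        return sum(len(d.genes) for d in self.diseases.values())

    @property
    def gene_universe(self) -> set[GeneRef]:
        out: set[GeneRef] = set()
        for d in self.diseases.values():
            out |= d.genes
        return out


def _read_table(path, required: Iterable[str], cols: Mapping[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for key in required:
        if cols[key] not in df.columns:
            raise NetworkFormatError(
                f"missing required column '{cols[key]}' in {path}"
            )
    return df

def _split_multi(cell: str) -> set[str]:
    return {tok.strip() for tok in cell.split(MULTI_SEP) if tok.strip()}

def _parse_entrez(raw: str) -> int:
    eid = int(raw.strip())
    if eid <= 0:
        raise ValueError(raw)
    return eid


def read_dgi(path, dialect: Mapping[str, str] | None = None,
             strict: bool = False) -> DGINetwork:
    """Read a drug-gene interaction TSV.

    Required columns (after dialect mapping): ``drug_id``, ``entrez_id``.
    Optional: ``name``, ``symbol``, ``atc``, ``mesh`` (ATC/MeSH cells may
    hold several ``|``-separated values). Exact duplicate (drug_id,
    entrez_id) edges are collapsed; annotations of duplicate rows are
    merged by set union. Rows with an unparsable or non-positive Entrez ID
    are rejected and counted unless ``strict`` is set, in which case they
    raise :class:`NetworkFormatError`.
    """
    cols = {**DGI_DIALECT, **(dialect or {})}
    df = _read_table(path, ("drug_id", "entrez_id"), cols)

    net = DGINetwork()
    seen: set[tuple[str, int]] = set()
    get = lambda key: (
        df[cols[key]].tolist() if cols[key] in df.columns else [""] * len(df)
    )
    rows = zip(get("drug_id"), get("name"), get("atc"), get("mesh"),
               get("entrez_id"), get("symbol"))
    for drug_id, name, atc, mesh, entrez_raw, symbol in rows:
        net.stats.raw_rows += 1
        drug_id = drug_id.strip()
        try:
            if not drug_id:
                raise ValueError("empty drug_id")
            eid = _parse_entrez(entrez_raw)
        except ValueError:
            if strict:
                raise NetworkFormatError(
                    f"unparsable row (drug_id={drug_id!r}, "
                    f"entrez_id={entrez_raw!r}) in {path}"
                ) from None
            net.stats.rows_rejected += 1
            continue
        rec = net.drugs.get(drug_id)
        if rec is None:
            rec = net.drugs[drug_id] = DrugRecord(drug_id=drug_id)
        if name and not rec.name:
            rec.name = name.strip()
        rec.atc_codes |= _split_multi(atc)
        rec.mesh_terms |= _split_multi(mesh)
        key = (drug_id, eid)
        if key in seen:
            net.stats.duplicates_removed += 1
            continue
        seen.add(key)
        rec.targets.add(GeneRef(eid, symbol.strip()))
    return net


def read_gda(path, dialect: Mapping[str, str] | None = None,
             strict: bool = False) -> GDANetwork:
    """Read a gene-disease association TSV.

    Required columns: ``entrez_id`` and ``mesh_id``; when a row's mesh_id
    cell is empty but a ``mesh_name`` is present, the name is matched
    case-insensitively against diseases seen so far (or used to mint a
    name-derived key), so heterogeneous exports still collapse onto one
    record per disease. The ``source`` column, if present, is ignored for
    edge identity: the same (gene, disease) pair reported by different
    source databases is a duplicate.
    """
    cols = {**GDA_DIALECT, **(dialect or {})}
    df = _read_table(path, ("entrez_id", "mesh_id"), cols)

    net = GDANetwork()
    seen: set[tuple[int, str]] = set()
    name_to_id: dict[str, str] = {}
    get = lambda key: (
        df[cols[key]].tolist() if cols[key] in df.columns else [""] * len(df)
    )
    rows = zip(get("entrez_id"), get("symbol"), get("mesh_id"), get("mesh_name"))
    for entrez_raw, symbol, mesh_id, mesh_name in rows:
        net.stats.raw_rows += 1
        mesh_id = mesh_id.strip()
        mesh_name = mesh_name.strip()
        try:
            eid = _parse_entrez(entrez_raw)
            if not mesh_id:
                if not mesh_name:
                    raise ValueError("no disease identifier")
                # fall back to case-insensitive name matching
                mesh_id = name_to_id.get(
                    mesh_name.casefold(), f"MESH:NAME:{mesh_name.upper()}"
                )
        except ValueError:
            if strict:
                raise NetworkFormatError(
                    f"unparsable row (entrez_id={entrez_raw!r}, "
                    f"mesh_id={mesh_id!r}) in {path}"
                ) from None
            net.stats.rows_rejected += 1
            continue
        if mesh_name:
            name_to_id.setdefault(mesh_name.casefold(), mesh_id)
        rec = net.diseases.get(mesh_id)
        if rec is None:
            rec = net.diseases[mesh_id] = DiseaseRecord(mesh_id=mesh_id)
        if mesh_name and not rec.mesh_name:
            rec.mesh_name = mesh_name
        key = (eid, mesh_id)
        if key in seen:
            net.stats.duplicates_removed += 1
            continue
        seen.add(key)
        rec.genes.add(GeneRef(eid, symbol.strip()))
    return net


def write_dgi(net: DGINetwork, path) -> None:
    """Write a DGI network as TSV, rows sorted by (drug_id, entrez_id)."""
    rows = []
    for drug_id in sorted(net.drugs):
        d = net.drugs[drug_id]
        atc = MULTI_SEP.join(sorted(d.atc_codes))
        mesh = MULTI_SEP.join(sorted(d.mesh_terms))
        for g in sorted(d.targets, key=lambda g: g.entrez_id):
            rows.append((drug_id, d.name, atc, mesh, g.entrez_id, g.symbol))
    pd.DataFrame(
        rows, columns=["drug_id", "name", "atc", "mesh", "entrez_id", "symbol"]
    ).to_csv(path, sep="\t", index=False)


def write_gda(net: GDANetwork, path) -> None:
    """Write a GDA network as TSV, rows sorted by (mesh_id, entrez_id)."""
    rows = []
    for mesh_id in sorted(net.diseases):
        d = net.diseases[mesh_id]
        for g in sorted(d.genes, key=lambda g: g.entrez_id):
            rows.append((g.entrez_id, g.symbol, mesh_id, d.mesh_name))
    pd.DataFrame(
        rows, columns=["entrez_id", "symbol", "mesh_id", "mesh_name"]
    ).to_csv(path, sep="\t", index=False)


def network_summary(dgi: DGINetwork, gda: GDANetwork,
                    universe_mode: str = "intersection") -> dict[str, int]:
    """Headline counts for a loaded network pair.

    Mirrors the shape of the numbers usually reported for such screens:
    drug/edge/target counts on the DGI side, disease/edge/gene counts on
    the GDA side, plus the size of the analysis universe under
    ``universe_mode`` (0 when the universe would be empty).
    """
    from .enrichment import build_universe  # local import: avoids cycle

    try:
        universe_size = len(build_universe(dgi, gda, mode=universe_mode))
    except ValueError:
        universe_size = 0
    return {
        "n_drugs": len(dgi.drugs),
        "n_dgi_pairs": dgi.n_pairs,
        "n_dgi_targets": len(dgi.target_genes),
        "n_diseases": len(gda.diseases),
        "n_gda_pairs": gda.n_pairs,
        "n_gda_genes": len(gda.gene_universe),
        "universe_size": universe_size,
    }
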