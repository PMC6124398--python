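"""Synthetic tripartite drug-gene-disease networks with planted signal.

The generator emulates the structure of real drug-target and
disease-gene exports: a gene pool with Entrez-like integer IDs, drugs
with fixed-size target sets, diseases with fixed-size associated gene
sets, and a configurable number of *planted* drug-disease pairs whose
drugs draw a controlled fraction of their targets from their disease's
gene set. Planted pairs are therefore genuinely overlap-enriched at a
known strength, giving every downstream module (screen, BH, ROC/CV)
a ground truth to recover, with matched null networks obtained by
setting ``n_planted = 0``.

All randomness flows through one numpy PCG64 generator seeded from the
config, so fixtures are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import ScreenReport, screen_all_pairs
from .networks import (DGINetwork, DiseaseRecord, DrugRecord, GDANetwork,
                       GeneRef, IngestStats, write_dgi, write_gda)

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate",
    "generate_null_pvalue_sample",
    "write_fixture",
]

#: first Entrez-like gene id emitted by the generator
_ENTREZ_BASE = 1000


def _as_range(value) -> tuple[int, int]:
    if isinstance(value, int):
        return (value, value)
    lo, hi = int(value[0]), int(value[1])
    return (lo, hi)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic network.

    Defaults are the standard benchmark conditions used throughout the
    test suite: a 5,000-gene pool, 500 drugs with 10 targets each, 50
    diseases with 100 associated genes each, and 50 planted drug-disease
    pairs in which 80% of the drug's targets come from the disease's
    gene set.
    """

    n_genes: int = 5000
    n_drugs: int = 500
    n_diseases: int = 50
    targets_per_drug: tuple[int, int] = (10, 10)
    genes_per_disease: tuple[int, int] = (100, 100)
    n_planted: int = 50
    planted_overlap_fraction: float = 0.8
    seed: int = 0
    #: pseudo-random algorithm fixed in metadata for reproducibility
    rng_algorithm: str = "PCG64"

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets_per_drug",
                           _as_range(self.targets_per_drug))
        object.__setattr__(self, "genes_per_disease",
                           _as_range(self.genes_per_disease))
        if min(self.n_genes, self.n_drugs, self.n_diseases) < 1:
            raise ValueError("n_genes, n_drugs, n_diseases must be >= 1")
        if not (0 <= self.n_planted <= min(self.n_drugs,
                                           self.n_drugs * self.n_diseases)):
            raise ValueError("n_planted out of range")
        if not (0.0 < self.planted_overlap_fraction <= 1.0):
            raise ValueError("planted_overlap_fraction must be in (0, 1]")
        for lo, hi in (self.targets_per_drug, self.genes_per_disease):
            if not (1 <= lo <= hi <= self.n_genes):
                raise ValueError("set-size range must lie within [1, n_genes]")
        if self.rng_algorithm != "PCG64":
            raise ValueError("only the PCG64 generator is supported")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["targets_per_drug"] = list(self.targets_per_drug)
        d["genes_per_disease"] = list(self.genes_per_disease)
        return d


@dataclass
class SyntheticTruth:
    """Ground truth and bookkeeping emitted alongside a synthetic network."""

    planted_pairs: set[tuple[str, str]]
    config: SyntheticConfig
    n_dgi_pairs: int = 0
    n_gda_pairs: int = 0

    def __post_init__(self) -> None:
        if len(self.planted_pairs) != self.config.n_planted:
            raise ValueError("planted pair count does not match config")


def _draw_size(rng: np.random.Generator, lohi: tuple[int, int]) -> int:
    lo, hi = lohi
    return lo if lo == hi else int(rng.integers(lo, hi + 1))


def generate(config: SyntheticConfig) -> tuple[DGINetwork, GDANetwork,
                                               SyntheticTruth]:
    """Generate one tripartite network from ``config``.

    Disease gene sets are drawn uniformly without replacement from the
    pool; unplanted drugs draw their targets the same way. Each planted
    pair's drug draws ceil(fraction * n_targets) of its targets from its
    disease's gene set and the remainder from the rest of the pool, so
    target sets keep their exact configured size (no within-drug
    collisions survive).
    """
    rng = np.random.default_rng(config.seed)
    entrez = np.arange(_ENTREZ_BASE + 1, _ENTREZ_BASE + config.n_genes + 1)
    genes = [GeneRef(int(e), f"G{int(e)}") for e in entrez]
    all_idx = np.arange(config.n_genes)

    # diseases first, so planted drugs can draw from their gene sets
    gda = GDANetwork()
    disease_gene_idx: list[np.ndarray] = []
    for j in range(config.n_diseases):
        size = _draw_size(rng, config.genes_per_disease)
        idx = np.sort(rng.choice(config.n_genes, size=size, replace=False))
        disease_gene_idx.append(idx)
        mesh_id = f"MESH:D{j + 1:04d}"
        gda.diseases[mesh_id] = DiseaseRecord(
            mesh_id=mesh_id,
            mesh_name=f"DISEASE{j + 1:04d}",
            genes={genes[i] for i in idx},
        )

    # assign planted (drug, disease) pairs: distinct drugs, diseases may repeat
    planted_drug_idx = rng.choice(config.n_drugs, size=config.n_planted,
                                  replace=False)
    planted_disease_idx = rng.integers(0, config.n_diseases,
                                       size=config.n_planted)
    planted_for_drug = dict(zip(planted_drug_idx.tolist(),
                                planted_disease_idx.tolist()))

    dgi = DGINetwork()
    planted_pairs: set[tuple[str, str]] = set()
    for i in range(config.n_drugs):
        n_targets = _draw_size(rng, config.targets_per_drug)
        drug_id = f"DRUG{i + 1:04d}"
        if i in planted_for_drug:
            j = planted_for_drug[i]
            pool = disease_gene_idx[j]
            k = min(n_targets,
                    math.ceil(config.planted_overlap_fraction * n_targets))
            if k > len(pool):
                raise ValueError(
                    f"planted draw infeasible: {k} targets requested from a "
                    f"disease gene set of size {len(pool)}"
                )
            inside = rng.choice(pool, size=k, replace=False)
            outside_pool = np.setdiff1d(all_idx, inside, assume_unique=False)
            outside = rng.choice(outside_pool, size=n_targets - k,
                                 replace=False)
            idx = np.concatenate([inside, outside])
            planted_pairs.add((drug_id, f"MESH:D{j + 1:04d}"))
        else:
            idx = rng.choice(config.n_genes, size=n_targets, replace=False)
        dgi.drugs[drug_id] = DrugRecord(
            drug_id=drug_id,
            name=f"drug-{i + 1:04d}",
            targets={genes[int(g)] for g in idx},
        )

    dgi.stats = IngestStats(raw_rows=dgi.n_pairs)
    gda.stats = IngestStats(raw_rows=gda.n_pairs)
    truth = SyntheticTruth(planted_pairs=planted_pairs, config=config,
                           n_dgi_pairs=dgi.n_pairs, n_gda_pairs=gda.n_pairs)
    return dgi, gda, truth


def generate_null_pvalue_sample(config: SyntheticConfig, n_reps: int,
                                **screen_kwargs) -> tuple[np.ndarray,
                                                          list[int]]:
    """Pooled tested-pair p-values from ``n_reps`` independent null
    networks (config must have ``n_planted == 0``), plus the per-replicate
    count of q < cutoff discoveries. Replicate r uses seed ``seed + r``.
    """
    if config.n_planted != 0:
        raise ValueError("null sampling requires n_planted == 0")
    pvals: list[float] = []
    discoveries: list[int] = []
    for rep in range(n_reps):
        cfg = dataclasses.replace(config, seed=config.seed + rep)
        dgi, gda, _ = generate(cfg)
        report: ScreenReport = screen_all_pairs(dgi, gda, **screen_kwargs)
        pvals.extend(r.p_value for r in report.results)
        discoveries.append(len(report.significant))
    return np.asarray(pvals), discoveries


def write_fixture(outdir, dgi: DGINetwork, gda: GDANetwork,
                  truth: SyntheticTruth) -> dict[str, Path]:
    """Write dgi.tsv, gda.tsv, truth.tsv, benchmark.tsv (planted pairs as
    positives) and a config-echo JSON into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {name: outdir / f"{name}.tsv"
             for name in ("dgi", "gda", "truth", "benchmark")}
    paths["config"] = outdir / "config.json"
    write_dgi(dgi, paths["dgi"])
    write_gda(gda, paths["gda"])
    planted = sorted(truth.planted_pairs)
    pd.DataFrame(planted, columns=["drug_id", "mesh_id"]).to_csv(
        paths["truth"], sep="\t", index=False)
    pd.DataFrame([(d, m, 1) for d, m in planted],
                 columns=["drug_id", "mesh_id", "label"]).to_csv(
        paths["benchmark"], sep="\t", index=False)
    echo = {"config": truth.config.to_dict(),
            "n_dgi_pairs": truth.n_dgi_pairs,
            "n_gda_pairs": truth.n_gda_pairs}
    paths["config"].write_text(json.dumps(echo, indent=2, sort_keys=True) + "\n")
    return paths
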