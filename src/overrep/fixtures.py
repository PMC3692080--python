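"""Seeded synthetic data: universes, collections, planted queries, DAGs, mappings.

Every generator is a pure function of a :class:`SimulationConfig`; one
integer seed drives a separate named RNG stream per generator, so adding a
generator never perturbs existing fixtures.  The default configuration
emulates a desk-scale enrichment study: a 5,000-gene universe, 200 gene
sets of 20-100 genes spread round-robin over the four categories, and a
150-gene query in which half the genes are drawn from one planted set —
the shape of a differential-expression hit list carrying a real signal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np

from .geneset_io import (Background, BackgroundSource, Category, GeneSet,
                         GeneSetCollection, write_gmt)
from .idmap import IdMappingTable, MappingRecord, write_mapping
from .ontology import AnnotationTable, OntologyGraph, write_obo

__all__ = [
    "SimulationConfig",
    "make_collection",
    "make_query",
    "make_dag",
    "make_mapping",
    "emit_fixture_dir",
]

# fixed per-generator stream tags (seed, tag) -> independent RNG
_STREAM_COLLECTION = 1
_STREAM_QUERY = 2
_STREAM_DAG = 3
_STREAM_MAPPING = 4


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs for all synthetic generators (defaults: the standard scenario)."""

    seed: int = 0
    universe_size: int = 5000
    n_sets: int = 200
    set_size_range: tuple[int, int] = (20, 100)
    planted_sets: int = 1
    query_size: int = 150
    signal_fraction: float = 0.5
    dag_terms: int = 50
    dag_max_parents: int = 3
    dag_annotation_rate: float = 3.0   # mean direct annotations per term
    symbols_per_locus: int = 2         # upper bound, inclusive
    probes_per_locus: int = 3          # upper bound, inclusive
    multi_locus_probe_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must lie in [0, 1]")
        lo, hi = self.set_size_range
        if not (0 < lo <= hi):
            raise ValueError("set_size_range must satisfy 0 < min <= max")
        if hi > self.universe_size:
            raise ValueError("set sizes cannot exceed the universe size")
        for fname in ("universe_size", "query_size", "dag_terms"):
            if getattr(self, fname) < 1:
                raise ValueError(f"{fname} must be positive")
        if self.n_sets < 0 or self.planted_sets < 0:
            raise ValueError("counts must be non-negative")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng((self.seed, stream))


def _universe(config: SimulationConfig) -> list[str]:
    width = max(6, len(str(config.universe_size)))
    return [f"g{i:0{width}d}" for i in range(1, config.universe_size + 1)]


def make_collection(config: SimulationConfig) -> tuple[GeneSetCollection, Background]:
    """Random gene sets over a synthetic universe, categories round-robin."""
    rng = config.rng(_STREAM_COLLECTION)
    genes = np.array(_universe(config))
    lo, hi = config.set_size_range
    cats = list(Category)
    sets = []
    for i in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets.append(GeneSet(
            name=f"SET_{i:04d}",
            description=f"synthetic gene set {i}",
            members=frozenset(members.tolist()),
            category=cats[i % len(cats)],
        ))
    background = Background(genes=frozenset(genes.tolist()),
                            source=BackgroundSource.precomputed_genome)
    return GeneSetCollection(sets=sets), background


def make_query(
    config: SimulationConfig,
    collection: GeneSetCollection,
    background: Background,
) -> tuple[list[str], dict]:
    """A query list with a planted enrichment signal plus ground truth.

    ceil(signal_fraction * query_size) genes come from the union of the
    planted sets; the remainder are uniform draws from the rest of the
    background.  Planted sets are chosen at random among sets large enough
    to carry their share of the signal, so the planted enrichment is always
    realizable; when no eligible choice exists the config is in error.
    The ground-truth record names the planted sets and the signal genes.
    """
    if config.planted_sets > len(collection):
        raise ValueError("planted_sets exceeds the number of sets")
    rng = config.rng(_STREAM_QUERY)
    n_signal = math.ceil(config.signal_fraction * config.query_size)
    per_set = math.ceil(n_signal / config.planted_sets) if config.planted_sets else 0
    eligible = [s.name for s in collection
                if len(s.members & background.genes) >= per_set]
    if len(eligible) < config.planted_sets:
        raise ValueError(
            f"planted sets' union cannot reach the signal portion "
            f"({n_signal} genes): only {len(eligible)} sets have >= "
            f"{per_set} background genes")
    planted_idx = rng.choice(len(eligible), size=config.planted_sets, replace=False)
    planted = [eligible[i] for i in sorted(planted_idx)]
    planted_union: set[str] = set()
    for name in planted:
        planted_union |= collection[name].members
    planted_union &= background.genes
    if n_signal > len(planted_union):
        raise ValueError(
            f"signal portion ({n_signal}) exceeds the planted sets' union "
            f"({len(planted_union)} genes)")
    signal = rng.choice(sorted(planted_union), size=n_signal, replace=False).tolist()
    rest_pool = sorted(background.genes - set(signal))
    n_rest = config.query_size - n_signal
    rest = rng.choice(rest_pool, size=n_rest, replace=False).tolist()
    query = signal + rest
    truth = {
        "planted_sets": planted,
        "signal_genes": sorted(signal),
        "signal_fraction": config.signal_fraction,
        "query_size": config.query_size,
    }
    return query, truth


def make_dag(config: SimulationConfig) -> tuple[OntologyGraph, AnnotationTable]:
    """Layered random DAG plus random direct gene annotations.

    Term 0 is the single root; every later term draws 1..dag_max_parents
    parents uniformly from earlier terms, so acyclicity holds by
    construction.  Direct annotations are Poisson-many genes per term.
    """
    rng = config.rng(_STREAM_DAG)
    width = max(7, len(str(config.dag_terms)))
    terms = [f"T{i:0{width}d}" for i in range(config.dag_terms)]
    g = nx.DiGraph()
    for i, term in enumerate(terms):
        g.add_node(term, name=f"synthetic term {i}", namespace="biological_process")
        if i == 0:
            continue
        n_parents = int(rng.integers(1, min(config.dag_max_parents, i) + 1))
        parents = rng.choice(i, size=n_parents, replace=False)
        for j in sorted(parents):
            rel = "is_a" if rng.random() < 0.8 else "part_of"
            g.add_edge(term, terms[j], relation=rel)
    genes = _universe(config)
    pairs: set[tuple[str, str]] = set()
    for term in terms:
        n_ann = int(rng.poisson(config.dag_annotation_rate))
        if n_ann == 0:
            continue
        chosen = rng.choice(len(genes), size=min(n_ann, len(genes)), replace=False)
        for gi in chosen:
            pairs.add((genes[gi], term))
    return OntologyGraph(graph=g), AnnotationTable(pairs=frozenset(pairs))


def make_mapping(config: SimulationConfig, n_loci: Optional[int] = None) -> IdMappingTable:
    """Locus/symbol/probe relations with many-to-many probe stress.

    Each locus gets 0..symbols_per_locus symbols and 0..probes_per_locus
    probes; a ``multi_locus_probe_fraction`` of probes are additionally
    attached to a second random locus.
    """
    rng = config.rng(_STREAM_MAPPING)
    loci = _universe(config)
    if n_loci is not None:
        loci = loci[:n_loci]
    records: set[MappingRecord] = set()
    probe_records: list[tuple[str, str]] = []  # (probe, locus) for re-assignment
    sym_i = prb_i = 0
    for locus in loci:
        n_sym = int(rng.integers(0, config.symbols_per_locus + 1))
        n_prb = int(rng.integers(0, config.probes_per_locus + 1))
        symbols = [f"SYM{(sym_i := sym_i + 1):05d}" for _ in range(n_sym)]
        probes = [f"PRB{(prb_i := prb_i + 1):05d}_at" for _ in range(n_prb)]
        if not symbols and not probes:
            records.add(MappingRecord(locus=locus))
            continue
        for s in symbols:
            records.add(MappingRecord(locus=locus, symbol=s))
        for p in probes:
            records.add(MappingRecord(locus=locus, probe=p))
            probe_records.append((p, locus))
    for probe, locus in probe_records:
        if rng.random() < config.multi_locus_probe_fraction:
            other = loci[int(rng.integers(0, len(loci)))]
            if other != locus:
                records.add(MappingRecord(locus=other, probe=probe))
    return IdMappingTable(records=frozenset(records))


def emit_fixture_dir(config: SimulationConfig, outdir: str | Path,
                     n_mapping_loci: int = 200) -> dict[str, Path]:
    """Write every synthetic artifact into a directory; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    collection, background = make_collection(config)
    query, truth = make_query(config, collection, background)
    onto, annotations = make_dag(config)
    mapping = make_mapping(config, n_loci=n_mapping_loci)
    paths = {
        "gmt": outdir / "collection.gmt",
        "background": outdir / "background.txt",
        "query": outdir / "query.txt",
        "obo": outdir / "ontology.obo",
        "annotations": outdir / "annotations.tsv",
        "mapping": outdir / "mapping.tsv",
        "truth": outdir / "truth.json",
        "sidecar": outdir / "sidecar.tsv",
    }
    write_gmt(collection, paths["gmt"])
    paths["background"].write_text(
        "\n".join(sorted(background.genes)) + "\n", encoding="utf-8")
    paths["query"].write_text("\n".join(query) + "\n", encoding="utf-8")
    write_obo(onto, paths["obo"])
    with paths["annotations"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene\tterm\n")
        for gene, term in sorted(annotations.pairs):
            fh.write(f"{gene}\t{term}\n")
    write_mapping(mapping, paths["mapping"])
    with paths["truth"].open("w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with paths["sidecar"].open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("name\tcategory\tpubmed_id\tauthor\tsource_db\turl\n")
        for s in collection:
            fh.write(f"{s.name}\t{s.category.value}\t\tsynthetic\t\t\n")
    return paths
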