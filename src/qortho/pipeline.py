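"""End-to-end pipeline: ingest -> filter -> BBH -> quartet scores -> calls
-> clustering -> annotation -> inparalogs, with deterministic TSV outputs.

Identical configuration and inputs produce byte-identical outputs: every
stage is deterministic (ties broken lexicographically) and all tables are
written in sorted order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .bbh import all_bbh_pairs
from .groups import OrthologousGroup, annotate_group, form_groups, ortholog_graph
from .inparalogs import co_ortholog_expansion, inparalog_groups
from .mcl import mcl
from .quartet import call_orthologs, score_pairs
from .registry import (
    attach_annotations,
    read_annotation_table,
    read_fasta_registry,
    read_lengths_table,
    read_species_table,
    registry_from_lengths,
)
from .similarity import build_store, parse_blast_tab, quality_filter

__all__ = ["PipelineConfig", "PipelineError", "RunResult", "run_pipeline", "read_groups_tsv", "query_groups"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run; round-trips through YAML."""

    species_table: str
    hits: str
    out_dir: str
    fasta: str | None = None
    lengths_table: str | None = None
    annotations: str | None = None
    omega: float = 20.0
    bit_threshold: float = 50.0
    coverage_threshold: float = 0.5
    inflation: float = 2.0
    missing_similarity_policy: str = "skip"
    annotated_only_denominator: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.coverage_threshold <= 1.0):
            raise ValueError(f"coverage_threshold must be in [0, 1], got {self.coverage_threshold}")
        if self.bit_threshold < 0:
            raise ValueError(f"bit_threshold must be non-negative, got {self.bit_threshold}")
        if self.inflation <= 1:
            raise ValueError(f"inflation must exceed 1, got {self.inflation}")
        if self.missing_similarity_policy not in ("skip", "impute_zero"):
            raise ValueError(f"unknown missing_similarity_policy {self.missing_similarity_policy!r}")
        if self.fasta is None and self.lengths_table is None:
            raise ValueError("one of fasta or lengths_table is required")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        """Hash of the scientific parameters (paths excluded, so the same
        analysis re-run elsewhere carries the same hash)."""
        d = self.to_dict()
        for key in ("species_table", "hits", "fasta", "lengths_table", "annotations", "out_dir"):
            d.pop(key)
        canonical = json.dumps(d, sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: PipelineConfig
    counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def _header(config: PipelineConfig) -> str:
    return f"# qortho {__version__}\n# config_hash={config.hash()}\n"


def run_pipeline(config: PipelineConfig, log=sys.stderr) -> RunResult:
    """Run every stage in order and write the artifact bundle.

    Any stage error aborts with the stage name and cause; files already
    written for this run are removed.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = RunResult(config)
    written: list[Path] = []
    stage = "init"

    def log_stage(name: str, t0: float, **counts) -> None:
        result.counts.update(counts)
        msg = " ".join(f"{k}={v}" for k, v in counts.items())
        print(f"[qortho] {name}: {msg} ({time.perf_counter() - t0:.2f}s)", file=log)

    try:
        stage = "ingest"
        t0 = time.perf_counter()
        species_map = read_species_table(config.species_table)
        if config.fasta is not None:
            registry = read_fasta_registry(config.fasta, species_map)
        else:
            registry = registry_from_lengths(read_lengths_table(config.lengths_table), species_map)
        if config.annotations is not None:
            attach_annotations(registry, read_annotation_table(config.annotations))
        log_stage(stage, t0, proteins=len(registry), species=len(registry.species()))

        stage = "filter"
        t0 = time.perf_counter()
        hits = parse_blast_tab(config.hits, registry)
        filtered = quality_filter(hits, config.bit_threshold, config.coverage_threshold)
        log_stage(stage, t0, hits=len(hits), filtered_hits=len(filtered))

        stage = "store"
        t0 = time.perf_counter()
        store = build_store(filtered, registry)
        log_stage(stage, t0, stored_pairs=len(store))

        stage = "bbh"
        t0 = time.perf_counter()
        putative = all_bbh_pairs(store)
        log_stage(stage, t0, putative_pairs=len(putative))

        stage = "score"
        t0 = time.perf_counter()
        scored = score_pairs(putative, store, config.missing_similarity_policy)
        n_evidence = sum(1 for p in scored if p.alpha_max is not None)
        log_stage(stage, t0, scored_pairs=len(scored), pairs_with_evidence=n_evidence)

        stage = "call"
        t0 = time.perf_counter()
        called = call_orthologs(scored, config.omega)
        called_set = {(p.x, p.y) for p in called}
        log_stage(stage, t0, called_orthologs=len(called))

        stage = "pairwise-output"
        path = out_dir / "pairwise_orthologs.tsv"
        written.append(path)
        with open(path, "wt") as fh:
            fh.write(_header(config))
            fh.write("protein_x\tprotein_y\tspecies_x\tspecies_y\tsimilarity\talpha_max\tis_ortholog\n")
            for p in scored:
                a = "NA" if p.alpha_max is None else _fmt(p.alpha_max)
                fh.write(
                    f"{p.x}\t{p.y}\t{registry.species_of(p.x)}\t{registry.species_of(p.y)}\t"
                    f"{_fmt(p.s_xy)}\t{a}\t{int((p.x, p.y) in called_set)}\n"
                )

        stage = "cluster"
        t0 = time.perf_counter()
        graph = ortholog_graph(called, registry)
        partition = mcl(graph, inflation=config.inflation)
        groups = form_groups(partition.clusters, registry)
        for g in groups:
            annotate_group(g, registry, annotated_only_denominator=config.annotated_only_denominator)
        log_stage(stage, t0, clusters=len(partition.clusters), groups=len(groups))

        stage = "groups-output"
        path = out_dir / "groups.tsv"
        written.append(path)
        with open(path, "wt") as fh:
            fh.write(_header(config))
            fh.write("group_id\tsize\tspecies_count\tmembers\tspecies\tconsensus_symbol\tconsensus_description\tconsensus_go\n")
            for g in groups:
                c = g.consensus
                fh.write(
                    f"{g.group_id}\t{g.size}\t{g.species_count}\t{';'.join(g.members)}\t{';'.join(g.species)}\t"
                    f"{(c.gene_symbol if c and c.gene_symbol else '')}\t"
                    f"{(c.description if c and c.description else '')}\t"
                    f"{';'.join(sorted(c.go_terms)) if c else ''}\n"
                )
        path = out_dir / "presence_matrix.tsv"
        written.append(path)
        all_species = registry.species()
        with open(path, "wt") as fh:
            fh.write(_header(config))
            fh.write("group_id\t" + "\t".join(all_species) + "\n")
            for g in groups:
                present = set(g.species)
                fh.write(g.group_id + "\t" + "\t".join("1" if s in present else "0" for s in all_species) + "\n")

        stage = "inparalogs"
        t0 = time.perf_counter()
        by_species = {sp: inparalog_groups(sp, store) for sp in registry.species()}
        n_inpar = sum(len(v) for v in by_species.values())
        expansion = co_ortholog_expansion(called, by_species, registry)
        log_stage(stage, t0, inparalog_groups=n_inpar)

        path = out_dir / "inparalogs.tsv"
        written.append(path)
        with open(path, "wt") as fh:
            fh.write(_header(config))
            fh.write("species\tgroup_index\tmembers\tmin_internal\tmax_external\n")
            for sp in registry.species():
                for i, grp in enumerate(by_species[sp], 1):
                    fh.write(
                        f"{sp}\t{i}\t{';'.join(grp.members)}\t{_fmt(grp.min_internal)}\t{_fmt(grp.max_external)}\n"
                    )
        path = out_dir / "co_orthologs.tsv"
        written.append(path)
        with open(path, "wt") as fh:
            fh.write(_header(config))
            fh.write("protein_x\tprotein_y\tco_ortholog_set_x\tco_ortholog_set_y\n")
            for (x, y) in sorted(expansion):
                sx, sy = expansion[(x, y)]
                fh.write(f"{x}\t{y}\t{';'.join(sx)}\t{';'.join(sy)}\n")

        stage = "report"
        path = out_dir / "report.jsonl"
        written.append(path)
        with open(path, "wt") as fh:
            fh.write(json.dumps({"tool": "qortho", "version": __version__, "config_hash": config.hash(), "seed": config.seed}) + "\n")
            for key in sorted(result.counts):
                fh.write(json.dumps({"count": key, "value": result.counts[key]}) + "\n")
        result.outputs = {p.name: str(p) for p in written}
        return result
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc


def read_groups_tsv(path) -> list[OrthologousGroup]:
    """Read a groups.tsv back into group objects (consensus text facets only)."""
    from .registry import Annotation

    groups: list[OrthologousGroup] = []
    with open(path, "rt") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("group_id\t"):
                continue
            fields = line.rstrip("\n").split("\t")
            gid, _size, _nsp, members, species, symbol, desc, go = fields
            consensus = None
            if symbol or desc or go:
                consensus = Annotation(symbol or None, desc or None, frozenset(t for t in go.split(";") if t))
            groups.append(OrthologousGroup(gid, members.split(";"), species.split(";"), consensus))
    return groups


def query_groups(
    groups: list[OrthologousGroup],
    species_filter: list[str] | None = None,
    mode: str = "any",
    text_filter: str | None = None,
    known_species: set[str] | None = None,
) -> list[OrthologousGroup]:
    """Filter groups by species membership and/or consensus description text.

    ``mode="any"`` keeps groups intersecting the species set; ``"all"``
    keeps groups covering it.  ``text_filter`` is a case-insensitive
    substring match on the consensus description.
    """
    if mode not in ("any", "all"):
        raise ValueError(f"mode must be 'any' or 'all', got {mode!r}")
    universe = known_species if known_species is not None else {s for g in groups for s in g.species}
    out = groups
    if species_filter:
        for sp in species_filter:
            if sp not in universe:
                raise ValueError(f"unknown species id {sp!r}")
        wanted = set(species_filter)
        if mode == "any":
            out = [g for g in out if wanted & set(g.species)]
        else:
            out = [g for g in out if wanted <= set(g.species)]
    if text_filter:
        needle = text_filter.lower()
        out = [
            g
            for g in out
            if g.consensus and g.consensus.description and needle in g.consensus.description.lower()
        ]
    return out
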