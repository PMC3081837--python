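"""End-to-end runs and the relational results store.

A run executes seqio -> precluster -> screen -> align -> cluster for every
requested cutoff and persists everything to an embedded single-file SQLite
store whose tables mirror the pipeline's relational schema: sequences,
preclusters and their members, pairwise distances, MOTU and their members
per cutoff, and (after annotation) taxonomy nodes and per-MOTU hits. The
store is queryable directly and exportable as a portable SQL dump, so
analyses from multiple datasets can be collated without a database server.
"""

from __future__ import annotations

import json
import logging
import os
import sqlite3
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import cluster as _cluster
from . import seqio as _seqio
from . import taxannot as _taxannot
from .align import ScoringScheme
from .synthgen import read_taxid_map

logger = logging.getLogger("motupipe")

_SCHEMA = """
CREATE TABLE IF NOT EXISTS runs (
    run_id INTEGER PRIMARY KEY AUTOINCREMENT,
    config TEXT NOT NULL,
    started TEXT DEFAULT CURRENT_TIMESTAMP,
    status TEXT NOT NULL DEFAULT 'incomplete'
);
CREATE TABLE IF NOT EXISTS sequences (
    id TEXT PRIMARY KEY, length INTEGER NOT NULL, source TEXT, residues TEXT
);
CREATE TABLE IF NOT EXISTS preclusters (rep_id TEXT PRIMARY KEY);
CREATE TABLE IF NOT EXISTS precluster_members (
    rep_id TEXT NOT NULL REFERENCES preclusters(rep_id),
    member_id TEXT NOT NULL REFERENCES sequences(id),
    PRIMARY KEY (rep_id, member_id)
);
CREATE TABLE IF NOT EXISTS distances (
    id_a TEXT NOT NULL, id_b TEXT NOT NULL,
    mismatches INTEGER NOT NULL, overlap_frac REAL NOT NULL,
    PRIMARY KEY (id_a, id_b)
);
CREATE TABLE IF NOT EXISTS motu (
    cutoff INTEGER NOT NULL, name TEXT NOT NULL, expanded_size INTEGER NOT NULL,
    PRIMARY KEY (cutoff, name)
);
CREATE TABLE IF NOT EXISTS motu_members (
    cutoff INTEGER NOT NULL, name TEXT NOT NULL,
    member_id TEXT NOT NULL REFERENCES sequences(id),
    PRIMARY KEY (cutoff, name, member_id)
);
CREATE TABLE IF NOT EXISTS tax_hits (
    motu_name TEXT NOT NULL, cutoff INTEGER NOT NULL, rank_index INTEGER NOT NULL,
    ref_id TEXT NOT NULL, identity REAL NOT NULL, taxid INTEGER NOT NULL,
    lineage TEXT NOT NULL,
    PRIMARY KEY (cutoff, motu_name, rank_index)
);
CREATE TABLE IF NOT EXISTS tax_nodes (
    taxid INTEGER PRIMARY KEY, parent INTEGER NOT NULL,
    rank TEXT NOT NULL, name TEXT NOT NULL
);
"""


@dataclass(frozen=True)
class RunConfig:
    """Everything one clustering run depends on."""

    inputs: tuple[str, ...]
    cutoffs: tuple[int, ...]
    store_path: str = ":memory:"
    min_length: int = 0
    min_overlap: float = 0.90
    min_identity: float = 0.95
    screen_mode: str = "kmer"
    word_size: int | None = None
    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not self.cutoffs:
            raise ValueError("cutoffs must be non-empty")

    def to_json(self) -> str:
        return json.dumps(
            {
                "inputs": list(self.inputs),
                "cutoffs": sorted(self.cutoffs),
                "min_length": self.min_length,
                "min_overlap": self.min_overlap,
                "min_identity": self.min_identity,
                "screen_mode": self.screen_mode,
                "word_size": self.word_size,
                "scoring": vars(self.scoring),
                "seed": self.seed,
            },
            sort_keys=True,
        )


class ResultsStore:
    """Thin wrapper over the SQLite results database."""

    def __init__(self, path: str | os.PathLike[str] = ":memory:"):
        self.path = os.fspath(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.executescript(_SCHEMA)

    # -- writers ------------------------------------------------------------

    def begin_run(self, config: RunConfig) -> int:
        cur = self.conn.execute(
            "INSERT INTO runs (config) VALUES (?)", (config.to_json(),)
        )
        self.conn.commit()
        return int(cur.lastrowid)

    def finish_run(self, run_id: int) -> None:
        self.conn.execute(
            "UPDATE runs SET status = 'complete' WHERE run_id = ?", (run_id,)
        )
        self.conn.commit()

    def save_pipeline(self, result: _cluster.PipelineResult) -> None:
        c = self.conn
        c.execute("DELETE FROM sequences")
        c.execute("DELETE FROM preclusters")
        c.execute("DELETE FROM precluster_members")
        c.execute("DELETE FROM distances")
        c.execute("DELETE FROM motu")
        c.execute("DELETE FROM motu_members")
        c.executemany(
            "INSERT INTO sequences VALUES (?,?,?,?)",
            [(r.id, r.length, r.source, r.residues) for r in result.records],
        )
        c.executemany(
            "INSERT INTO preclusters VALUES (?)",
            [(pc.rep_id,) for pc in result.preclusters],
        )
        c.executemany(
            "INSERT INTO precluster_members VALUES (?,?)",
            [
                (pc.rep_id, m)
                for pc in result.preclusters
                for m in sorted(pc.member_ids)
            ],
        )
        c.executemany(
            "INSERT INTO distances VALUES (?,?,?,?)",
            [
                (pd.id_a, pd.id_b, pd.mismatches, pd.overlap_frac)
                for pd in result.distances.values()
            ],
        )
        for cutoff, part in result.partitions.items():
            c.executemany(
                "INSERT INTO motu VALUES (?,?,?)",
                [
                    (cutoff, name, len(members))
                    for name, members in zip(part.names, part.expanded)
                ],
            )
            c.executemany(
                "INSERT INTO motu_members VALUES (?,?,?)",
                [
                    (cutoff, name, m)
                    for name, members in zip(part.names, part.expanded)
                    for m in sorted(members)
                ],
            )
        self.conn.commit()

    def save_annotation(
        self,
        hits_by_cutoff: Mapping[int, Mapping[str, Sequence[_taxannot.AnnotationHit]]],
        taxonomy: _taxannot.Taxonomy,
    ) -> None:
        c = self.conn
        c.execute("DELETE FROM tax_hits")
        c.execute("DELETE FROM tax_nodes")
        c.executemany(
            "INSERT INTO tax_nodes VALUES (?,?,?,?)",
            [
                (n.taxid, n.parent_taxid, n.rank, n.name)
                for n in taxonomy.nodes.values()
            ],
        )
        rows = []
        for cutoff, per_motu in hits_by_cutoff.items():
            for motu_name, hits in per_motu.items():
                for hit in hits:
                    lineage = ";".join(f"{r}:{n}" for r, n in hit.lineage)
                    rows.append(
                        (hit.motu_name, cutoff, hit.rank_index, hit.ref_id,
                         hit.identity, hit.taxid, lineage)
                    )
        c.executemany("INSERT INTO tax_hits VALUES (?,?,?,?,?,?,?)", rows)
        self.conn.commit()

    # -- readers ------------------------------------------------------------

    def cutoffs(self) -> list[int]:
        return [r[0] for r in self.conn.execute(
            "SELECT DISTINCT cutoff FROM motu ORDER BY cutoff"
        )]

    def motu_table(self, cutoff: int) -> list[tuple[str, int]]:
        return list(self.conn.execute(
            "SELECT name, expanded_size FROM motu WHERE cutoff = ? ORDER BY name",
            (cutoff,),
        ))

    def motu_members(self, cutoff: int) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for name, member in self.conn.execute(
            "SELECT name, member_id FROM motu_members WHERE cutoff = ?", (cutoff,)
        ):
            out.setdefault(name, set()).add(member)
        return {k: frozenset(v) for k, v in out.items()}

    def sequences(self) -> list[_seqio.SequenceRecord]:
        return [
            _seqio.SequenceRecord(id=i, residues=res, source=src or "")
            for i, _length, src, res in self.conn.execute(
                "SELECT id, length, source, residues FROM sequences ORDER BY id"
            )
        ]

    def check_partition_invariant(self) -> None:
        """Every cutoff's MOTU members must partition the stored sequences,
        and per-MOTU member counts must match the recorded expanded sizes."""
        all_ids = {r[0] for r in self.conn.execute("SELECT id FROM sequences")}
        for cutoff in self.cutoffs():
            members = self.motu_members(cutoff)
            sizes = dict(self.motu_table(cutoff))
            seen: set[str] = set()
            for name, ids in members.items():
                if len(ids) != sizes[name]:
                    raise AssertionError(
                        f"{name}: stored size {sizes[name]} != member count {len(ids)}"
                    )
                if seen & ids:
                    raise AssertionError(f"overlapping MOTU at cutoff {cutoff}")
                seen |= ids
            if seen != all_ids:
                raise AssertionError(
                    f"MOTU members at cutoff {cutoff} do not cover all sequences"
                )

    def sql_dump(self, path: str | os.PathLike[str]) -> None:
        with open(path, "w", encoding="utf-8") as handle:
            for line in self.conn.iterdump():
                handle.write(line + "\n")

    @classmethod
    def from_sql(cls, sql_path: str | os.PathLike[str]) -> "ResultsStore":
        store = cls(":memory:")
        with open(sql_path, encoding="utf-8") as handle:
            script = handle.read()
        store.conn.executescript("DROP TABLE IF EXISTS runs;" + _drop_all())
        store.conn.executescript(script)
        return store

    def close(self) -> None:
        self.conn.close()


def _drop_all() -> str:
    tables = (
        "sequences", "preclusters", "precluster_members", "distances",
        "motu", "motu_members", "tax_hits", "tax_nodes",
    )
    return "".join(f"DROP TABLE IF EXISTS {t};" for t in tables)


def run_cluster(config: RunConfig) -> ResultsStore:
    """Execute the full clustering pipeline and persist the results."""
    logging.basicConfig(level=config.log_level)
    records: list[_seqio.SequenceRecord] = []
    for path in config.inputs:
        records.extend(_seqio.read_input(path))
    logger.info("read %d sequences from %d input(s)", len(records), len(config.inputs))
    kept, removed = _seqio.filter_by_length(records, config.min_length)
    logger.info("length filter (>= %d): kept %d, removed %d",
                config.min_length, len(kept), len(removed))
    if not kept:
        raise ValueError("no sequences to cluster after the length filter")
    store = ResultsStore(config.store_path)
    run_id = store.begin_run(config)
    try:
        result = _cluster.cluster_records(
            kept, config.cutoffs, scoring=config.scoring,
            screen_mode=config.screen_mode, word_size=config.word_size,
            min_overlap=config.min_overlap, min_identity=config.min_identity,
        )
    except Exception as exc:
        raise RuntimeError(f"clustering stage failed: {exc}") from exc
    logger.info("preclusters: %d; candidate pairs: %d; aligned pairs stored: %d",
                len(result.preclusters), len(result.candidate_pairs),
                len(result.distances))
    for cutoff in sorted(result.partitions):
        logger.info("cutoff %d: %d MOTU", cutoff,
                    result.partitions[cutoff].motu_count)
    store.save_pipeline(result)
    store.finish_run(run_id)
    return store


def run_annotate(
    store: ResultsStore,
    ref_fasta: str | os.PathLike[str],
    taxid_map_path: str | os.PathLike[str],
    nodes_path: str | os.PathLike[str],
    names_path: str | os.PathLike[str],
    top_n: int = _taxannot.DEFAULT_TOP_N,
    min_identity: float = _taxannot.DEFAULT_MIN_IDENTITY,
) -> ResultsStore:
    """Annotate every stored MOTU at every stored cutoff; replaces prior hits."""
    refs = _seqio.read_fasta(ref_fasta)
    taxid_map = read_taxid_map(taxid_map_path)
    missing = [r.id for r in refs if r.id not in taxid_map]
    if missing:
        raise KeyError(f"reference ids without taxid mapping: {missing}")
    taxonomy = _taxannot.load_taxonomy(nodes_path, names_path)
    records = {r.id: r for r in store.sequences()}
    hits_by_cutoff: dict[int, dict[str, list[_taxannot.AnnotationHit]]] = {}
    for cutoff in store.cutoffs():
        per_motu: dict[str, list[_taxannot.AnnotationHit]] = {}
        for name, members in store.motu_members(cutoff).items():
            rep = _taxannot.pick_motu_representative(members, records)
            hits = _taxannot.annotate_motu(
                rep, refs, taxid_map, taxonomy,
                top_n=top_n, min_identity=min_identity, motu_name=name,
            )
            if hits:
                per_motu[name] = hits
        hits_by_cutoff[cutoff] = per_motu
        logger.info("cutoff %d: annotated %d of %d MOTU", cutoff,
                    len(per_motu), len(store.motu_members(cutoff)))
    store.save_annotation(hits_by_cutoff, taxonomy)
    return store


def export(
    store: ResultsStore,
    what: str,
    out_path: str | os.PathLike[str],
    cutoff: int | None = None,
) -> None:
    """Write one export: motu_text, motu_fasta, curve_tsv or sql_dump."""
    stored = store.cutoffs()
    if what in ("motu_text", "motu_fasta"):
        if cutoff not in stored:
            raise ValueError(f"cutoff {cutoff} not in store (have {stored})")
    if what == "motu_text":
        members = store.motu_members(cutoff)
        with open(out_path, "w", encoding="ascii") as handle:
            for name in sorted(members):
                ids = members[name]
                handle.write(f"{name}\t{len(ids)}\t{','.join(sorted(ids))}\n")
    elif what == "motu_fasta":
        records = {r.id: r for r in store.sequences()}
        reps = [
            _taxannot.pick_motu_representative(ids, records)
            for _name, ids in sorted(store.motu_members(cutoff).items())
        ]
        named = [
            _seqio.SequenceRecord(id=name, residues=rep.residues, source=rep.source)
            for (name, _ids), rep
            in zip(sorted(store.motu_members(cutoff).items()), reps)
        ]
        _seqio.write_fasta(named, out_path)
    elif what == "curve_tsv":
        with open(out_path, "w", encoding="ascii") as handle:
            handle.write("cutoff\tmotu_count\n")
            for c in stored:
                handle.write(f"{c}\t{len(store.motu_table(c))}\n")
    elif what == "sql_dump":
        store.sql_dump(out_path)
    else:
        raise ValueError(f"unknown export {what!r}")
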