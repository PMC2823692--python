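"""Readers and writers for the formats the pipeline touches.

FASTA in/out (70-column wrap on write, any wrap on read, line-numbered
parse errors), annotation-evidence and library-count TSV tables, Newick
serialization of :class:`sialome.phylo.Clade` trees, and the RunConfig
that stamps every output with the seed and a config hash.
"""

from __future__ import annotations

import hashlib
import io as _io
import json
import math
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .phylo import Clade

logger = logging.getLogger("sialome")

__version__ = "0.1.0"

NUCLEOTIDE_CHARS = frozenset("ACGTN")
PROTEIN_CHARS = frozenset("ACDEFGHIKLMNPQRSTVWYX")

__all__ = [
    "SequenceRecord",
    "EvidenceRow",
    "RunConfig",
    "FastaParseError",
    "read_fasta",
    "write_fasta",
    "read_evidence",
    "read_counts",
    "write_newick",
    "read_newick",
    "output_header",
]


class FastaParseError(ValueError):
    """FASTA parse failure, carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


@dataclass
class SequenceRecord:
    """A named sequence, nucleotide ({A,C,G,T,N}) or protein (20 aa + X)."""

    id: str
    seq: str
    description: str = ""
    alphabet: str = ""  # "nucleotide" | "protein"; inferred if empty
    validate: bool = True

    def __post_init__(self):
        if not self.id or any(ch.isspace() for ch in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.seq:
            raise ValueError(f"empty sequence for id {self.id!r}")
        self.seq = self.seq.upper()
        if not self.alphabet:
            chars = set(self.seq)
            self.alphabet = "nucleotide" if chars <= NUCLEOTIDE_CHARS else "protein"
        if self.validate:
            allowed = (NUCLEOTIDE_CHARS if self.alphabet == "nucleotide"
                       else PROTEIN_CHARS)
            bad = set(self.seq) - allowed
            if bad:
                raise ValueError(
                    f"illegal {self.alphabet} character(s) {sorted(bad)} "
                    f"in {self.id!r}")

    def __len__(self):
        return len(self.seq)


@dataclass
class EvidenceRow:
    """One row of the annotation-evidence table.

    Stands in for database-search output: the best-hit description (empty
    means no hit), domain tags, a signal-peptide call from an external
    predictor, and an optional curator category hint.
    """

    id: str
    best_hit_description: str = ""
    domain_tags: list[str] = field(default_factory=list)
    signal_peptide: str = "unknown"  # yes | no | unknown
    category_hint: str = ""

    def __post_init__(self):
        if self.signal_peptide not in ("yes", "no", "unknown"):
            raise ValueError(
                f"signal_peptide must be yes/no/unknown, got "
                f"{self.signal_peptide!r} for {self.id!r}")


@dataclass
class RunConfig:
    """Run-level configuration recorded in every output header."""

    seed: int = 0
    outdir: str = "."
    verbosity: int = 1
    params: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        blob = json.dumps(
            {"seed": self.seed, "params": self.params}, sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:12]


def output_header(stage: str, config: RunConfig | None = None) -> str:
    """Comment header for output files: tool version, stage, config hash."""
    lines = [f"# sialome {__version__} stage={stage}"]
    if config is not None:
        lines.append(f"# seed={config.seed} config_hash={config.config_hash}")
    return "\n".join(lines) + "\n"


def read_fasta(path) -> list[SequenceRecord]:
    """Parse a FASTA file into SequenceRecords, preserving order.

    Sequences are uppercased and concatenated across wrapped lines; a
    trailing '*' on protein sequences is stripped. Empty files, duplicate
    ids and illegal characters raise :class:`FastaParseError` naming the
    line.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: dict[str, int] = {}
    cur_id = cur_desc = None
    cur_seq: list[str] = []
    cur_line = 0

    def flush():
        if cur_id is None:
            return
        seq = "".join(cur_seq)
        if seq.endswith("*"):
            seq = seq[:-1]
        if not seq:
            raise FastaParseError(f"record {cur_id!r} has no sequence", cur_line)
        chars = set(seq.upper())
        alphabet = "nucleotide" if chars <= NUCLEOTIDE_CHARS else "protein"
        bad = chars - (NUCLEOTIDE_CHARS | PROTEIN_CHARS)
        if bad:
            raise FastaParseError(
                f"illegal character(s) {sorted(bad)} in record {cur_id!r}",
                cur_line)
        records.append(SequenceRecord(id=cur_id, seq=seq, description=cur_desc,
                                      alphabet=alphabet))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError("empty FASTA header", lineno)
                parts = header.split(None, 1)
                rid = parts[0]
                if rid in seen:
                    raise FastaParseError(
                        f"duplicate sequence id {rid!r} "
                        f"(first seen on line {seen[rid]})", lineno)
                seen[rid] = lineno
                cur_id, cur_desc = rid, (parts[1] if len(parts) > 1 else "")
                cur_seq, cur_line = [], lineno
            else:
                if cur_id is None:
                    raise FastaParseError("sequence data before first '>'", lineno)
                cur_seq.append(line.strip().upper())
        flush()
    if not records:
        raise FastaParseError(f"no FASTA records in {path}", None)
    return records


def write_fasta(records, path_or_handle, width: int = 70) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    own = isinstance(path_or_handle, (str, Path))
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        for rec in records:
            desc = f" {rec.description}" if rec.description else ""
            fh.write(f">{rec.id}{desc}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")
    finally:
        if own:
            fh.close()


def read_evidence(path) -> dict[str, EvidenceRow]:
    """Read the annotation-evidence TSV (header line; unknown columns ignored).

    Expected columns: id, best_hit_description, domain_tags
    (semicolon-separated), signal_peptide, category_hint. Missing optional
    columns default to empty/unknown.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str).fillna("")
    if "id" not in df.columns:
        raise ValueError(f"evidence table {path} lacks an 'id' column")
    rows: dict[str, EvidenceRow] = {}
    for _, r in df.iterrows():
        rid = r["id"].strip()
        if rid in rows:
            raise ValueError(f"duplicate id {rid!r} in evidence table")
        tags = [t for t in r.get("domain_tags", "").split(";") if t]
        rows[rid] = EvidenceRow(
            id=rid,
            best_hit_description=r.get("best_hit_description", "").strip(),
            domain_tags=tags,
            signal_peptide=(r.get("signal_peptide", "").strip() or "unknown"),
            category_hint=r.get("category_hint", "").strip(),
        )
    return rows


def read_counts(path) -> pd.DataFrame:
    """Read a library-count TSV with columns library, observed, total."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"library", "observed", "total"} - set(df.columns)
    if missing:
        raise ValueError(f"count table {path} lacks column(s) {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Newick


def _fmt_num(x: float) -> str:
    return format(x, "g")


def write_newick(tree: Clade) -> str:
    """Serialize a tree as Newick; bootstrap supports become internal labels.

    Raises ValueError on NaN branch lengths.
    """

    def render(node: Clade) -> str:
        if node.branch_length is not None and math.isnan(node.branch_length):
            raise ValueError("NaN branch length")
        bl = (f":{_fmt_num(node.branch_length)}"
              if node.branch_length is not None else "")
        if node.is_leaf:
            return f"{node.name}{bl}"
        inner = ",".join(render(c) for c in node.children)
        label = "" if node.support is None else str(node.support)
        return f"({inner}){label}{bl}"

    return render(tree) + ";"


def read_newick(text: str) -> Clade:
    """Parse a Newick string (internal labels read as integer supports)."""
    import dendropy

    dt = dendropy.Tree.get(data=text, schema="newick",
                           suppress_internal_node_taxa=True,
                           preserve_underscores=True)

    def convert(dnode) -> Clade:
        children = [convert(c) for c in dnode.child_nodes()]
        name = dnode.taxon.label if dnode.taxon else None
        support = None
        if children and dnode.label is not None:
            try:
                support = int(dnode.label)
            except ValueError:
                pass
        bl = dnode.edge.length
        return Clade(name=name, children=children,
                     branch_length=(float(bl) if bl is not None else None),
                     support=support)

    root = convert(dt.seed_node)
    return root
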