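"""Readers/writers for the formats the pipeline touches.

FASTA and Newick move sequences and gene trees between stages; relaxed
sequential PHYLIP is emitted for interoperability with classic ML tools
whose parsers cap identifier length; the per-gene study table (gene, clock
role, best-fit substitution model, transcript length, relative rate) is
read from TSV.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import pandas as pd

logger = logging.getLogger(__name__)

AA_CHARS = set("ACDEFGHIKLMNPQRSTVWY" "X-*")
NT_CHARS = set("ACGTU" "N-")


class Alphabet(str, Enum):
    aa = "aa"
    nt = "nt"


@dataclass(frozen=True)
class SequenceRecord:
    """A named sequence over a declared alphabet.

    ``id`` is the first whitespace-delimited token of a FASTA header and must
    be unique within a file or gene family.  Gaps ('-') and ambiguity codes
    ('X' for amino acids, 'N' for nucleotides) are permitted.
    """

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.aa

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"sequence id must be a nonempty token, got {self.id!r}")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")
        allowed = AA_CHARS if self.alphabet == Alphabet.aa else NT_CHARS
        bad = set(self.residues.upper()) - allowed
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters outside the "
                f"{self.alphabet.value} alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Msa:
    """A protein multiple sequence alignment (>= 2 rows, equal lengths)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"unequal alignment row lengths: {sorted(lengths)}")
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate ids in alignment: {dupes}")

    @property
    def n_cols(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def column(self, j: int) -> str:
        return "".join(r.residues[j] for r in self.records)


@dataclass(frozen=True)
class GeneTableRow:
    gene: str
    group: str  # "TTFL" | "PTM"
    model_name: str
    nucleotides: int
    relative_rate: float | None = None

    def __post_init__(self) -> None:
        if self.group not in ("TTFL", "PTM"):
            raise ValueError(f"unknown group label {self.group!r} for gene {self.gene!r}")
        if self.nucleotides <= 0:
            raise ValueError(f"nucleotide count must be positive for gene {self.gene!r}")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, alphabet: Alphabet = Alphabet.aa) -> list[SequenceRecord]:
    """Parse a (possibly multi-line) FASTA file.

    Ids are the first whitespace token of each header; order is preserved;
    duplicate ids raise ``ValueError`` naming the offender.
    """
    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    cur_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if cur_id is None:
            return
        residues = "".join(chunks)
        if cur_id in seen:
            raise ValueError(f"duplicate sequence id {cur_id!r}")
        seen.add(cur_id)
        records.append(SequenceRecord(cur_id, residues, alphabet))

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            cur_id = line[1:].split()[0] if line[1:].split() else ""
            chunks = []
        else:
            if cur_id is None:
                raise ValueError("FASTA data before first header")
            chunks.append(line)
    flush()
    if not records:
        raise ValueError("empty FASTA input")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 60) -> None:
    lines = []
    for r in records:
        lines.append(f">{r.id}")
        for i in range(0, len(r.residues), width):
            lines.append(r.residues[i : i + width])
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        Path(path).write_text(text)


def msa_from_records(records: Sequence[SequenceRecord]) -> Msa:
    return Msa(tuple(records))


# ---------------------------------------------------------------------------
# Newick

_TAXON_NAMESPACE_KW = dict(schema="newick", preserve_underscores=True)


def read_newick(text_or_path) -> dendropy.Tree:
    """Parse a single Newick tree.

    Missing branch lengths default to 0 (with a logged warning); quoted and
    underscore labels are preserved verbatim; internal node labels are kept
    but ignored by all distance computations downstream.
    """
    if isinstance(text_or_path, (str, Path)) and not str(text_or_path).lstrip().startswith("("):
        text = Path(text_or_path).read_text()
    else:
        text = str(text_or_path)
    _check_balanced(text)
    try:
        tree = dendropy.Tree.get(data=text, **_TAXON_NAMESPACE_KW)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    n_missing = 0
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            edge.length = 0.0
            n_missing += 1
    if n_missing:
        logger.warning("%d branch lengths missing in Newick input; defaulted to 0", n_missing)
    return tree


def _check_balanced(text: str) -> None:
    depth = 0
    for pos, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise ValueError(f"Newick parse error: unbalanced ')' at position {pos}")
    if depth != 0:
        raise ValueError(f"Newick parse error: {depth} unclosed '(' at end of input")


def write_newick(tree: dendropy.Tree) -> str:
    return (
        tree.as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
        ).strip()
    )


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(e.length or 0.0 for e in tree.preorder_edge_iter() if e.head_node is not tree.seed_node)


def leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [lf.taxon.label for lf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# PHYLIP


def default_id_map(ids: Sequence[str]) -> dict[str, str]:
    """Truncate identifiers to <= 10 characters, preserving the trailing
    gene/contig number.

    The rule keeps the numeric suffix intact and spends the remaining budget
    on the leading letters of the organism part, e.g.
    ``Aedes_AAEL012562`` -> ``AE012562``-style tokens.
    """
    mapping: dict[str, str] = {}
    for full in ids:
        if len(full) <= 10:
            mapping[full] = full
            continue
        m = re.search(r"(\d+)\D*$", full)
        if m:
            number = m.group(1)
            prefix_src = re.sub(r"[^A-Za-z]", "", full[: m.start(1)])
            keep = max(10 - len(number), 0)
            token = (prefix_src[:keep] + number)[-10:] if len(number) > 10 else prefix_src[:keep] + number
        else:
            token = full[:10]
        mapping[full] = token
    return mapping


def write_phylip(msa: Msa, id_map: Mapping[str, str] | None = None) -> tuple[str, dict[str, str]]:
    """Relaxed sequential PHYLIP text plus the id-mapping table used.

    Mapped names must be unique and <= 10 characters; a post-truncation
    collision raises ``ValueError`` listing the colliding originals.
    """
    if id_map is None:
        id_map = default_id_map(msa.ids)
    mapped = [id_map[r.id] for r in msa.records]
    for name in mapped:
        if len(name) > 10:
            raise ValueError(f"mapped id {name!r} exceeds 10 characters")
    if len(set(mapped)) != len(mapped):
        coll: dict[str, list[str]] = {}
        for orig, tok in zip(msa.ids, mapped):
            coll.setdefault(tok, []).append(orig)
        bad = {t: o for t, o in coll.items() if len(o) > 1}
        raise ValueError(f"id truncation collisions: {bad}")
    out = io.StringIO()
    out.write(f"{len(msa.records)} {msa.n_cols}\n")
    for name, rec in zip(mapped, msa.records):
        out.write(f"{name:<10s} {rec.residues}\n")
    return out.getvalue(), dict(zip(msa.ids, mapped))


def read_phylip(text: str, reverse_map: Mapping[str, str] | None = None) -> Msa:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    n, m = (int(x) for x in lines[0].split()[:2])
    records = []
    for ln in lines[1 : 1 + n]:
        name, seq = ln.split(None, 1)
        seq = seq.replace(" ", "")
        if reverse_map:
            name = reverse_map.get(name, name)
        records.append(SequenceRecord(name, seq, Alphabet.aa))
    msa = Msa(tuple(records))
    if msa.n_cols != m:
        raise ValueError(f"PHYLIP header says {m} columns, rows have {msa.n_cols}")
    return msa


# ---------------------------------------------------------------------------
# Study gene table


def read_gene_table(path=None) -> list[GeneTableRow]:
    """Read the per-gene study table (TSV).

    With no argument, the packaged 17-gene circadian clock table for the
    pitcher-plant mosquito study (9 TTFL, 8 PTM genes) is loaded.
    """
    if path is None:
        with resources.files("clockdiv.data").joinpath("clock_genes.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"gene", "group", "model", "nucleotides"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    rows = []
    for rec in df.itertuples(index=False):
        rows.append(
            GeneTableRow(
                gene=str(rec.gene),
                group=str(rec.group),
                model_name=str(rec.model),
                nucleotides=int(rec.nucleotides),
                relative_rate=float(rec.relative_rate) if "relative_rate" in df.columns else None,
            )
        )
    return rows
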