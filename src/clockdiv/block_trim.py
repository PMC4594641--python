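"""Conserved-block selection for protein alignments (Gblocks-style).

Columns are classified from identical-residue counts against two
conservation thresholds, then contiguous conserved blocks are carved out in
four ordered steps: long nonconserved stretches are rejected, flanks are
trimmed back to highly conserved columns, gapped columns are removed (with
re-splitting), and short blocks are discarded.  Defaults mirror the
canonical trimming tool: b1 = floor(n/2)+1, b2 = max(b1, floor(0.85*n)),
b3 = 8, b4 = 10, no gaps allowed in kept columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

from .io_formats import Msa, SequenceRecord

logger = logging.getLogger(__name__)

GAP_CHARS = set("-")


class Conservation(str, Enum):
    nonconserved = "nonconserved"
    conserved = "conserved"
    highly_conserved = "highly_conserved"


@dataclass(frozen=True)
class ColumnStatus:
    index: int
    conservation: Conservation
    has_gap: bool


@dataclass(frozen=True)
class BlockSelection:
    kept: tuple[tuple[int, int], ...]  # disjoint sorted half-open intervals
    params: dict

    @property
    def n_kept(self) -> int:
        return sum(b - a for a, b in self.kept)


def default_params(n_seqs: int) -> dict:
    b1 = n_seqs // 2 + 1
    b2 = max(b1, int(0.85 * n_seqs))
    return {"b1": b1, "b2": b2, "b3": 8, "b4": 10, "gap_policy": "none"}


def classify_columns(
    msa: Msa, b1: int | None = None, b2: int | None = None, gap_policy: str = "none"
) -> list[ColumnStatus]:
    """Classify each column from its maximum identical-residue count.

    nonconserved when max count < ``b1``; highly_conserved when >= ``b2``;
    conserved otherwise.  Gap characters never count as residues.  Under
    gap policy "none" any gap flags the column; under "half" only when more
    than half the rows are gaps.
    """
    n = len(msa.records)
    defaults = default_params(n)
    b1 = defaults["b1"] if b1 is None else b1
    b2 = defaults["b2"] if b2 is None else b2
    if b2 < b1:
        raise ValueError(f"b2 ({b2}) must be >= b1 ({b1})")
    if gap_policy not in ("none", "half"):
        raise ValueError(f"unknown gap policy {gap_policy!r}")
    statuses = []
    for j in range(msa.n_cols):
        col = msa.column(j).upper()
        counts: dict[str, int] = {}
        n_gap = 0
        for c in col:
            if c in GAP_CHARS:
                n_gap += 1
            else:
                counts[c] = counts.get(c, 0) + 1
        top = max(counts.values()) if counts else 0
        if top < b1:
            cons = Conservation.nonconserved
        elif top >= b2:
            cons = Conservation.highly_conserved
        else:
            cons = Conservation.conserved
        if gap_policy == "none":
            has_gap = n_gap > 0
        else:
            has_gap = n_gap > n / 2
        statuses.append(ColumnStatus(j, cons, has_gap))
    return statuses


def select_blocks(
    statuses: Sequence[ColumnStatus], b3: int = 8, b4: int = 10, params: dict | None = None
) -> BlockSelection:
    """Carve conserved blocks from classified columns.

    Steps, in order: (1) stretches of more than ``b3`` contiguous
    nonconserved columns are rejected, splitting the alignment; (2) each
    remaining segment is trimmed from both flanks until it starts and ends
    on a highly conserved column; (3) columns flagged for gaps are removed
    and segments re-split; (4) segments shorter than ``b4`` are discarded.
    """
    n = len(statuses)
    segments: list[list[int]] = []
    cur: list[int] = []
    run = 0
    pending: list[int] = []
    for st in statuses:
        if st.conservation == Conservation.nonconserved:
            run += 1
            pending.append(st.index)
            if run > b3:
                if cur:
                    segments.append(cur)
                    cur = []
                pending = []
        else:
            if pending and run <= b3:
                cur.extend(pending)
            pending = []
            run = 0
            cur.append(st.index)
    if cur:
        segments.append(cur)

    status_by_index = {st.index: st for st in statuses}

    def trim_flanks(seg: list[int]) -> list[int]:
        lo, hi = 0, len(seg)
        while lo < hi and status_by_index[seg[lo]].conservation != Conservation.highly_conserved:
            lo += 1
        while hi > lo and status_by_index[seg[hi - 1]].conservation != Conservation.highly_conserved:
            hi -= 1
        return seg[lo:hi]

    segments = [trim_flanks(s) for s in segments]

    # gap removal with re-splitting
    split: list[list[int]] = []
    for seg in segments:
        piece: list[int] = []
        for idx in seg:
            if status_by_index[idx].has_gap:
                if piece:
                    split.append(piece)
                    piece = []
            else:
                piece.append(idx)
        if piece:
            split.append(piece)

    kept: list[tuple[int, int]] = []
    for seg in split:
        if len(seg) < b4:
            continue
        # a segment may be non-contiguous only across removed gap columns;
        # emit maximal contiguous runs (their combined length met b4)
        start = seg[0]
        prev = seg[0]
        for idx in seg[1:]:
            if idx != prev + 1:
                kept.append((start, prev + 1))
                start = idx
            prev = idx
        kept.append((start, prev + 1))
    kept.sort()
    params = dict(params or {})
    params.update({"b3": b3, "b4": b4})
    return BlockSelection(tuple(kept), params)


def trim_alignment(msa: Msa, b1=None, b2=None, b3: int = 8, b4: int = 10, gap_policy: str = "none") -> BlockSelection:
    """classify_columns + select_blocks with shared defaults."""
    defaults = default_params(len(msa.records))
    b1 = defaults["b1"] if b1 is None else b1
    b2 = defaults["b2"] if b2 is None else b2
    if b2 < b1:
        logger.warning("b2 (%d) below b1 (%d); clamped", b2, b1)
        b2 = b1
    statuses = classify_columns(msa, b1=b1, b2=b2, gap_policy=gap_policy)
    return select_blocks(statuses, b3=b3, b4=b4, params={"b1": b1, "b2": b2, "gap_policy": gap_policy})


def apply_blocks(msa: Msa, selection: BlockSelection) -> tuple[Msa, float]:
    """Concatenate kept columns; returns (trimmed alignment, fraction kept).

    An empty selection is an error: relax b1/b2/b4 or allow gaps.
    """
    if not selection.kept:
        raise ValueError(
            "block selection kept no columns; relax the conservation thresholds "
            "(b1/b2), shorten the minimum block length (b4), or permit gapped columns"
        )
    for a, b in selection.kept:
        if not (0 <= a < b <= msa.n_cols):
            raise ValueError(f"interval [{a},{b}) outside alignment of {msa.n_cols} columns")
    records = []
    for rec in msa.records:
        residues = "".join(rec.residues[a:b] for a, b in selection.kept)
        records.append(SequenceRecord(rec.id, residues, rec.alphabet))
    out = Msa(tuple(records))
    return out, out.n_cols / msa.n_cols
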