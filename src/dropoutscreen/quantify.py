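"""Assign raw reads to sgRNA spacers with a bounded-mismatch matching contract.

A read is assignable to a guide if some window of the read (or of its reverse
complement, when enabled) equals the guide's spacer up to ``max_mismatches``
substitutions.  Mismatch means substitution only (Hamming distance): with
19–20-nt spacers that is the conventional reading of a one-mismatch budget,
and it keeps an exact brute-force oracle feasible.  Reads matching two or more
distinct guides within budget are ambiguous and, by default, discarded —
discarding never inflates a guide's count.

The default scans every window because staggered-primer designs place the
spacer at a variable offset; a fixed-offset fast path is available when the
vector's constant prefix makes the offset known.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO

from dropoutscreen.io import SgRnaLibrary

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QuantifyConfig:
    max_mismatches: int = 1
    search_both_strands: bool = True
    ambiguous_policy: str = "discard"  # or "first"
    read_offset: int | None = None  # fixed-offset fast path; None scans all windows

    def __post_init__(self) -> None:
        if self.max_mismatches not in (0, 1):
            raise ValueError("max_mismatches must be 0 or 1")
        if self.ambiguous_policy not in ("discard", "first"):
            raise ValueError("ambiguous_policy must be 'discard' or 'first'")
        if self.read_offset is not None and self.read_offset < 0:
            raise ValueError("read_offset must be non-negative")


@dataclass
class QuantifyStats:
    total_reads: int = 0
    assigned: int = 0
    ambiguous: int = 0
    unassigned: int = 0


class _SpacerIndex:
    """Pigeonhole index: a spacer within Hamming distance 1 of a window matches
    the window exactly on its first or second half."""

    def __init__(self, library: SgRnaLibrary):
        self.by_length: dict[int, dict] = {}
        for rec in library.records:
            L = len(rec.spacer)
            tbl = self.by_length.setdefault(
                L, {"exact": {}, "left": {}, "right": {}, "half": L // 2}
            )
            tbl["exact"].setdefault(rec.spacer, []).append(rec.sgrna_id)
            h = tbl["half"]
            tbl["left"].setdefault(rec.spacer[:h], []).append(rec)
            tbl["right"].setdefault(rec.spacer[h:], []).append(rec)

    def matches(self, window: str, max_mismatches: int) -> set[str]:
        """All sgrna_ids whose spacer has Hamming distance ≤ budget to window."""
        L = len(window)
        tbl = self.by_length.get(L)
        if tbl is None:
            return set()
        hits: set[str] = set(tbl["exact"].get(window, ()))
        if max_mismatches == 0:
            return hits
        h = tbl["half"]
        candidates = list(tbl["left"].get(window[:h], ()))
        candidates += tbl["right"].get(window[h:], ())
        for rec in candidates:
            if rec.sgrna_id in hits:
                continue
            mm = sum(a != b for a, b in zip(window, rec.spacer))
            if mm <= max_mismatches:
                hits.add(rec.sgrna_id)
        return hits


def _read_windows(seq: str, lengths: Iterable[int], offset: int | None):
    """Yield windows of each spacer length, positions left to right."""
    for L in sorted(lengths):
        if offset is not None:
            if offset + L <= len(seq):
                yield seq[offset : offset + L]
        else:
            for i in range(len(seq) - L + 1):
                yield seq[i : i + L]


def match_read(
    seq: str, index: _SpacerIndex, cfg: QuantifyConfig
) -> tuple[str, str | None]:
    """Classify one read: returns (status, sgrna_id or None) with status in
    {assigned, ambiguous, unassigned}."""
    seq = seq.upper()
    lengths = index.by_length.keys()
    sequences = [seq]
    if cfg.search_both_strands:
        sequences.append(reverse_complement(seq))
    hits: set[str] = set()
    first_hit: str | None = None
    for s in sequences:
        for window in _read_windows(s, lengths, cfg.read_offset):
            found = index.matches(window, cfg.max_mismatches)
            if found and first_hit is None:
                first_hit = min(found)
            hits |= found
            if cfg.ambiguous_policy == "discard" and len(hits) > 1:
                return "ambiguous", None
    if not hits:
        return "unassigned", None
    if len(hits) == 1:
        return "assigned", next(iter(hits))
    # policy == "first": first window position, forward strand first,
    # lexicographically smallest id within a window
    return "assigned", first_hit


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, encoding="ascii")


def count_reads(
    reads: str | Path | IO[str] | Iterable[str],
    library: SgRnaLibrary,
    cfg: QuantifyConfig | None = None,
) -> tuple[pd.Series, QuantifyStats]:
    """Count sgRNA spacer occurrences in raw reads.

    ``reads`` may be a FASTQ path (optionally .gz), an open text handle of
    FASTQ, or an iterable of plain sequences (useful in tests).  Returns one
    raw count column aligned to library order plus the conservation stats
    ``assigned + ambiguous + unassigned == total_reads``.
    """
    cfg = cfg or QuantifyConfig()
    index = _SpacerIndex(library)
    counts = pd.Series(0, index=library.sgrna_ids, dtype=np.int64, name="count")
    stats = QuantifyStats()

    if isinstance(reads, (str, Path)):
        handle = _open_maybe_gzip(reads)
        seq_iter: Iterable[str] = _fastq_sequences(handle)
    elif hasattr(reads, "read"):
        seq_iter = _fastq_sequences(reads)  # type: ignore[arg-type]
    else:
        seq_iter = reads  # plain sequences

    for seq in seq_iter:
        stats.total_reads += 1
        status, sgrna_id = match_read(seq, index, cfg)
        if status == "assigned":
            stats.assigned += 1
            counts[sgrna_id] += 1
        elif status == "ambiguous":
            stats.ambiguous += 1
        else:
            stats.unassigned += 1
    return counts, stats


def _fastq_sequences(handle: IO[str]) -> Iterator[str]:
    record_idx = 0
    try:
        for record in SeqIO.parse(handle, "fastq"):
            yield str(record.seq)
            record_idx += 1
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ record at index {record_idx}: {exc}") from exc
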