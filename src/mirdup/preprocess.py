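"""Adapter trimming and length filtering of raw small-RNA reads.

Trimming is error-free suffix matching: the leftmost position where a
prefix of the adapter (at least ``min_overlap`` long) matches the remainder
of the read exactly marks the insert end.  Trimmed reads of at least
``min_length`` nt (18 by default — reads longer than 17 bp are retained)
pass to mapping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from mirdup.config import TrimConfig
from mirdup.seqio import FastqRecord


@dataclass
class PreprocessStats:
    total_reads: int = 0
    trimmed_reads: int = 0   # reads in which an adapter was found
    retained_reads: int = 0


def trim_adapter(read_seq: str, config: TrimConfig) -> str:
    """Return the insert portion of a read, or the read unchanged.

    Scans left to right for the first position where the read's remaining
    suffix is a prefix of the adapter (or starts with the full adapter) of
    length >= ``min_overlap``; a read beginning with the adapter trims to
    the empty string.
    """
    adapter = config.adapter
    n, a = len(read_seq), len(adapter)
    for pos in range(0, n - config.min_overlap + 1):
        tail = n - pos
        k = min(tail, a)
        if read_seq[pos:pos + k] == adapter[:k]:
            return read_seq[:pos]
    return read_seq


def preprocess(reads: Iterable[FastqRecord], config: TrimConfig
               ) -> tuple[list[FastqRecord], PreprocessStats]:
    """Trim every read and retain those within the length window."""
    stats = PreprocessStats()
    retained: list[FastqRecord] = []
    for rec in reads:
        stats.total_reads += 1
        insert = trim_adapter(rec.seq, config)
        if len(insert) < len(rec.seq):
            stats.trimmed_reads += 1
        if len(insert) < config.min_length:
            continue
        if config.max_length is not None and len(insert) > config.max_length:
            continue
        stats.retained_reads += 1
        retained.append(FastqRecord(rec.id, insert, rec.qual[:len(insert)]))
    return retained, stats
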