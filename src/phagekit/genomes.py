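"""Record-level statistics of annotated genome records (GenBank flat files)."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

from Bio import SeqIO

__all__ = ["GenomeRecordStats", "genome_record_stats"]


@dataclass(frozen=True)
class GenomeRecordStats:
    """Length, GC content and feature counts of one genome record."""

    record_id: str
    length: int
    gc_percent: float   # rounded half-up to 2 decimals
    n_cds: int
    n_trna: int

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError("length must be > 0")
        if not 0 <= self.gc_percent <= 100:
            raise ValueError("gc_percent must lie in [0, 100]")


def _stats_of(record) -> GenomeRecordStats:
    seq = str(record.seq).upper()
    if not seq:
        raise ValueError(f"record {record.id!r} has no sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    unambiguous = sum(counts.values())
    if unambiguous == 0:
        raise ValueError(f"record {record.id!r} has no unambiguous bases")
    gc = 100.0 * (counts["G"] + counts["C"]) / unambiguous
    gc_rounded = float(
        Decimal(repr(gc)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP)
    )
    n_cds = sum(1 for f in record.features if f.type == "CDS")
    n_trna = sum(1 for f in record.features if f.type == "tRNA")
    return GenomeRecordStats(
        record_id=record.id,
        length=len(seq),
        gc_percent=gc_rounded,
        n_cds=n_cds,
        n_trna=n_trna,
    )


def genome_record_stats(path) -> GenomeRecordStats | list[GenomeRecordStats]:
    """Length, GC% and CDS/tRNA counts from a GenBank flat file.

    GC is (G+C)/(A+C+G+T) x 100 with ambiguity codes excluded from both
    numerator and denominator, rounded half-up to 2 decimals. A single-record
    file returns one :class:`GenomeRecordStats`; a multi-record file returns
    a list.
    """
    records = list(SeqIO.parse(str(Path(path)), "genbank"))
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    stats = [_stats_of(r) for r in records]
    return stats[0] if len(stats) == 1 else stats
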