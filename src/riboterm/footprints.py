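"""Footprint records, UMI deduplication, length filtering and P-site density.

Raw ribosome-protected fragments arrive as (transcript, 5' position,
length, UMI) records.  The pipeline collapses PCR duplicates on the UMI
key, keeps the size-selected 15–35 nt range, assigns each fragment's
P-site by a length-dependent 5' offset, and accumulates per-nucleotide
P-site counts into one density track per transcript.  All normalization
happens downstream in :mod:`riboterm.metrics`; tracks hold raw counts.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel

# size-selection bounds, inclusive on both ends
MIN_READ_LENGTH = 15
MAX_READ_LENGTH = 35


@dataclass(frozen=True, slots=True)
class FootprintRecord:
    """One aligned ribosome-protected fragment in transcript coordinates.

    ``umi`` concatenates the 5' four-nt and 3' six-nt unique molecular
    identifiers; it may be empty, in which case the record is never
    collapsed as a duplicate.
    """

    transcript_id: str
    five_prime_pos: int
    read_length: int
    umi: str = ""

    def key(self) -> tuple[str, int, int, str]:
        return (self.transcript_id, self.five_prime_pos, self.read_length, self.umi)


@dataclass(frozen=True)
class PsiteOffsetTable:
    """Read-length → P-site offset lookup.

    ``offsets`` maps a fragment length to the number of nucleotides added
    to its 5' end to reach the first nucleotide of the P-site codon.
    Lengths absent from the table either fall back to ``default_offset``
    or, when that is None (the default policy), drop the record.
    """

    offsets: Mapping[int, int] = field(
        default_factory=lambda: {n: 12 for n in range(25, 32)}
    )
    default_offset: Optional[int] = None

    def __post_init__(self) -> None:
        for length, off in self.offsets.items():
            if not 0 <= off < length:
                raise ValueError(f"offset {off} out of [0, {length}) for length {length}")

    def lookup(self, read_length: int) -> Optional[int]:
        off = self.offsets.get(read_length, self.default_offset)
        return off

    def to_dict(self) -> dict:
        return {"offsets": {str(k): v for k, v in sorted(self.offsets.items())},
                "default_offset": self.default_offset}

    @classmethod
    def from_dict(cls, d: Mapping) -> "PsiteOffsetTable":
        return cls(
            offsets={int(k): int(v) for k, v in d.get("offsets", {}).items()},
            default_offset=d.get("default_offset"),
        )


@dataclass
class DensityTrack:
    """Per-nucleotide P-site counts for one transcript in one condition."""

    transcript_id: str
    counts: np.ndarray  # int64, length == transcript length

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DensityReport:
    """Drop accounting for the record → track pipeline."""

    n_input: int = 0
    n_deduped: int = 0
    n_length_filtered: int = 0
    n_unknown_transcript: int = 0
    n_unassigned_psite: int = 0
    n_retained: int = 0


def deduplicate_by_umi(records: Iterable[FootprintRecord]) -> list[FootprintRecord]:
    """Collapse PCR duplicates: one record per unique
    (transcript_id, five_prime_pos, read_length, umi) key.  Records with an
    empty UMI carry no molecular identity and are all retained.  Output is
    sorted by key, making the operation order-independent and idempotent.
    """
    unique: dict[tuple, FootprintRecord] = {}
    no_umi: list[FootprintRecord] = []
    for rec in records:
        if rec.umi == "":
            no_umi.append(rec)
        else:
            unique.setdefault(rec.key(), rec)
    out = list(unique.values()) + no_umi
    out.sort(key=FootprintRecord.key)
    return out


def filter_by_length(
    records: Iterable[FootprintRecord],
    min_len: int = MIN_READ_LENGTH,
    max_len: int = MAX_READ_LENGTH,
) -> tuple[list[FootprintRecord], int]:
    """Keep records with min_len <= read_length <= max_len (both ends
    inclusive, matching gel size selection).  Returns (kept, n_dropped)."""
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    recs = list(records)
    kept = [r for r in recs if min_len <= r.read_length <= max_len]
    return kept, len(recs) - len(kept)


def assign_psite(
    record: FootprintRecord,
    offsets: PsiteOffsetTable,
    transcript_length: Optional[int] = None,
) -> Optional[int]:
    """P-site coordinate for one record, or None when the length has no
    offset under the drop policy or the offset lands out of bounds."""
    off = offsets.lookup(record.read_length)
    if off is None:
        return None
    pos = record.five_prime_pos + off
    if pos < 0:
        return None
    if transcript_length is not None and pos >= transcript_length:
        return None
    return pos


def build_density(
    records: Sequence[FootprintRecord],
    models: Sequence[TranscriptModel],
    offsets: PsiteOffsetTable | None = None,
    dedup: bool = True,
    length_filter: bool = True,
) -> tuple[dict[str, DensityTrack], DensityReport]:
    """Run dedup → length filter → P-site assignment and tally counts.

    Every model gets a track (zero track when no records map to it).
    Count conservation: the sum of track totals equals the number of
    records surviving all three steps, recorded as ``report.n_retained``.
    """
    if offsets is None:
        offsets = PsiteOffsetTable()
    report = DensityReport(n_input=len(records))

    recs = list(records)
    if dedup:
        deduped = deduplicate_by_umi(recs)
        report.n_deduped = len(recs) - len(deduped)
        recs = deduped
    if length_filter:
        recs, n_drop = filter_by_length(recs)
        report.n_length_filtered = n_drop

    tracks = {
        m.transcript_id: DensityTrack(m.transcript_id, np.zeros(m.length, dtype=np.int64))
        for m in models
    }
    lengths = {m.transcript_id: m.length for m in models}
    for rec in recs:
        tlen = lengths.get(rec.transcript_id)
        if tlen is None:
            report.n_unknown_transcript += 1
            continue
        pos = assign_psite(rec, offsets, tlen)
        if pos is None:
            report.n_unassigned_psite += 1
            continue
        tracks[rec.transcript_id].counts[pos] += 1
        report.n_retained += 1
    return tracks, report


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "read_length", "umi"]


def load_footprint_table(path: str | os.PathLike) -> list[FootprintRecord]:
    """Read the footprint TSV (transcript_id, five_prime_pos, read_length,
    umi); an empty/missing umi field means no UMI."""
    df = pd.read_csv(
        path, sep="\t", dtype={"transcript_id": str, "umi": str}, keep_default_na=False
    )
    missing = [c for c in FOOTPRINT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        FootprintRecord(r.transcript_id, int(r.five_prime_pos), int(r.read_length), r.umi)
        for r in df.itertuples(index=False)
    ]


def write_footprint_table(records: Iterable[FootprintRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(r.transcript_id, r.five_prime_pos, r.read_length, r.umi) for r in records],
        columns=FOOTPRINT_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def load_bam_footprints(path: str | os.PathLike) -> tuple[list[FootprintRecord], dict[str, int]]:
    """Optional ingestion of transcriptome-aligned BAM/SAM.

    Reference name is the transcript_id, the leftmost aligned position the
    5' end, and the UMI is parsed from the read name after the last "_"
    (empty when absent).  Secondary/supplementary alignments and reads
    whose CIGAR contains indels or clipping are dropped with counts.
    """
    import pysam

    drops = {"secondary_or_supplementary": 0, "unmapped": 0, "indel_or_clip": 0}
    records: list[FootprintRecord] = []
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as bam:
        for aln in bam:
            if aln.is_unmapped:
                drops["unmapped"] += 1
                continue
            if aln.is_secondary or aln.is_supplementary:
                drops["secondary_or_supplementary"] += 1
                continue
            if any(op != 0 for op, _ in (aln.cigartuples or [])):
                drops["indel_or_clip"] += 1
                continue
            name = aln.query_name or ""
            umi = name.rsplit("_", 1)[1] if "_" in name else ""
            records.append(
                FootprintRecord(
                    transcript_id=aln.reference_name,
                    five_prime_pos=aln.reference_start,
                    read_length=aln.query_length,
                    umi=umi,
                )
            )
    return records, drops
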