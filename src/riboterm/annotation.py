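"""Transcript models and the analysis regions derived from them.

Every termination metric in this package is computed over one of four
regions of a transcript:

* the CDS (start codon through the normal termination codon, NTC);
* the CDS *body* — the CDS excluding its first 15 and last 12 nucleotides,
  which removes initiation/termination-proximal ribosome pile-ups from the
  pause-score denominator;
* the stop codon (the 3 nt of the NTC);
* the readthrough *extension* — the 3'UTR segment between the NTC and the
  first downstream in-frame stop codon, which readthrough ribosomes
  translate before terminating again.

Coordinates are 0-based, half-open, in transcript space, running 5'→3'.
Strand is resolved when models are loaded and never reappears downstream.
The NTC is included inside the CDS interval: ``cds_end`` is the coordinate
one past the last nucleotide of the stop codon.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: minimum CDS length (nt) for a non-degenerate CDS body: 15 + 12 exclusion
#: plus at least one full codon
MIN_CDS_FOR_BODY = 30

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _normalize(seq: str) -> str:
    """Uppercase and fold RNA to DNA alphabet (U -> T)."""
    return seq.upper().replace("U", "T")


class AnnotationError(ValueError):
    """Malformed annotation input (file/record level)."""


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript's coordinate frame.

    ``cds_start`` is the first nucleotide of the start codon and
    ``cds_end`` is exclusive, so the NTC occupies
    ``[cds_end - 3, cds_end)``.  ``sequence`` is stored in the DNA
    alphabet; RNA input is folded at construction.
    """

    transcript_id: str
    length: int
    cds_start: int
    cds_end: int
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence))

    def validate(self) -> Optional[str]:
        """Return a reason code if an invariant is violated, else None."""
        if len(self.sequence) != self.length:
            return "sequence_length_mismatch"
        if not (0 <= self.cds_start < self.cds_end <= self.length):
            return "cds_bounds"
        cds_len = self.cds_end - self.cds_start
        if cds_len % 3 != 0:
            return "cds_not_codon_multiple"
        if cds_len < 18:
            return "cds_too_short"
        if self.sequence[self.cds_end - 3 : self.cds_end] not in STOP_CODONS:
            return "no_terminal_stop"
        return None

    @property
    def ntc_start(self) -> int:
        """Transcript coordinate of the first nucleotide of the NTC."""
        return self.cds_end - 3


@dataclass(frozen=True)
class RegionSet:
    """The four analysis regions of one transcript, as half-open intervals."""

    transcript_id: str
    cds: tuple[int, int]
    cds_body: tuple[int, int]
    stop_codon: tuple[int, int]
    extension: Optional[tuple[int, int]]
    next_stop_start: Optional[int]
    #: False when the CDS is too short for a non-degenerate body
    pause_eligible: bool


@dataclass
class LoadReport:
    """Bookkeeping for a model-loading pass."""

    n_loaded: int = 0
    n_dropped: int = 0
    dropped_by_reason: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.n_dropped += 1
        self.dropped_by_reason[reason] = self.dropped_by_reason.get(reason, 0) + 1


def find_next_inframe_stop(tm: TranscriptModel) -> Optional[int]:
    """Coordinate of the first in-frame stop codon at or downstream of
    ``cds_end``, scanning codon-by-codon in the CDS frame; None if no
    complete in-frame stop codon exists before the 3' end.

    A stop codon immediately after the NTC returns ``cds_end`` itself
    (zero-length extension region).
    """
    seq = tm.sequence
    for pos in range(tm.cds_end, tm.length - 2, 3):
        if seq[pos : pos + 3] in STOP_CODONS:
            return pos
    return None


def derive_regions(tm: TranscriptModel) -> RegionSet:
    """Derive all four analysis regions for a valid transcript model.

    The extension is present iff a downstream in-frame stop exists; an
    immediate in-frame stop yields a present-but-empty extension, which
    downstream scoring treats as a zero readthrough numerator rather than
    excluding the transcript.
    """
    reason = tm.validate()
    if reason is not None:
        raise AnnotationError(f"{tm.transcript_id}: invalid model ({reason})")
    cds = (tm.cds_start, tm.cds_end)
    body = (tm.cds_start + 15, tm.cds_end - 12)
    pause_eligible = (tm.cds_end - tm.cds_start) >= MIN_CDS_FOR_BODY
    if not pause_eligible:
        body = (tm.cds_start + 15, tm.cds_start + 15)  # degenerate, empty
    nss = find_next_inframe_stop(tm)
    extension = (tm.cds_end, nss) if nss is not None else None
    return RegionSet(
        transcript_id=tm.transcript_id,
        cds=cds,
        cds_body=body,
        stop_codon=(tm.cds_end - 3, tm.cds_end),
        extension=extension,
        next_stop_start=nss,
        pause_eligible=pause_eligible,
    )


# ---------------------------------------------------------------------------
# loading: simplified transcript table
# ---------------------------------------------------------------------------

TABLE_COLUMNS = ["transcript_id", "length", "cds_start", "cds_end", "sequence"]


def load_transcript_table(path: str | os.PathLike) -> tuple[list[TranscriptModel], LoadReport]:
    """Load models from the simplified TSV (transcript_id, length,
    cds_start, cds_end, sequence).  Invariant-violating records are
    dropped and counted in the report."""
    try:
        df = pd.read_csv(path, sep="\t", dtype={"transcript_id": str, "sequence": str})
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise AnnotationError(f"cannot parse transcript table {path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    report = LoadReport()
    models: list[TranscriptModel] = []
    seen: set[str] = set()
    for row in df.itertuples(index=False):
        if row.transcript_id in seen:
            report.drop("duplicate_transcript_id")
            continue
        tm = TranscriptModel(
            transcript_id=row.transcript_id,
            length=int(row.length),
            cds_start=int(row.cds_start),
            cds_end=int(row.cds_end),
            sequence=str(row.sequence),
        )
        reason = tm.validate()
        if reason is not None:
            report.drop(reason)
            continue
        seen.add(tm.transcript_id)
        models.append(tm)
        report.n_loaded += 1
    return models, report


def write_transcript_table(models: Iterable[TranscriptModel], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(m.transcript_id, m.length, m.cds_start, m.cds_end, m.sequence) for m in models],
        columns=TABLE_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# loading: GTF + FASTA
# ---------------------------------------------------------------------------


def load_gtf_models(
    gtf_path: str | os.PathLike,
    fasta_path: str | os.PathLike,
    fasta_is_genome: bool = True,
) -> tuple[list[TranscriptModel], LoadReport]:
    """Build transcript models from a GENCODE-dialect GTF plus FASTA.

    Exons are concatenated in transcript order (minus-strand transcripts
    reverse-complemented) so coordinates always run 5'→3'.  ``stop_codon``
    features, when annotated separately, are merged into the CDS, matching
    the convention that the NTC is the last CDS codon.  With
    ``fasta_is_genome=False`` the FASTA is taken to hold spliced transcript
    sequences keyed by transcript_id.
    """
    import gffutils
    from pyfaidx import Fasta

    try:
        db = gffutils.create_db(
            str(gtf_path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            keep_order=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise AnnotationError(f"cannot parse GTF {gtf_path}: {exc}") from exc

    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    report = LoadReport()
    models: list[TranscriptModel] = []

    for tx in db.features_of_type("transcript"):
        tid = tx.attributes.get("transcript_id", [tx.id])[0]
        exons = sorted(db.children(tx, featuretype="exon"), key=lambda f: f.start)
        if not exons:
            report.drop("no_exons")
            continue
        cds_feats = list(db.children(tx, featuretype="CDS"))
        stop_feats = list(db.children(tx, featuretype="stop_codon"))
        if not cds_feats:
            report.drop("no_cds")
            continue
        strand = tx.strand
        if strand not in {"+", "-"}:
            report.drop("unstranded")
            continue

        # genomic -> transcript coordinate map via cumulative exon offsets
        # (exons in transcript order: ascending genomic for +, descending for -)
        tx_exons = exons if strand == "+" else exons[::-1]
        offsets: list[tuple[int, int, int]] = []  # (gstart, gend, toffset) 1-based inclusive
        toff = 0
        for ex in tx_exons:
            offsets.append((ex.start, ex.end, toff))
            toff += ex.end - ex.start + 1
        tx_len = toff

        if fasta_is_genome:
            chrom = tx.seqid
            if chrom not in fasta:
                report.drop("missing_sequence")
                continue
            parts = []
            for ex in tx_exons:
                s = fasta[chrom][ex.start - 1 : ex.end]
                parts.append(reverse_complement(s) if strand == "-" else s)
            seq = "".join(parts)
        else:
            if tid not in fasta:
                report.drop("missing_sequence")
                continue
            seq = str(fasta[tid][:])

        def to_tx(gpos: int) -> Optional[int]:
            for gstart, gend, off in offsets:
                if gstart <= gpos <= gend:
                    if strand == "+":
                        return off + (gpos - gstart)
                    return off + (gend - gpos)
            return None

        # merge CDS + stop_codon genomic spans, mapped to transcript coords
        tx_coords: list[int] = []
        ok = True
        for f in cds_feats + stop_feats:
            a, b = to_tx(f.start), to_tx(f.end)
            if a is None or b is None:
                ok = False
                break
            tx_coords.extend((a, b))
        if not ok:
            report.drop("cds_outside_exons")
            continue
        cds_start = min(tx_coords)
        cds_end = max(tx_coords) + 1

        tm = TranscriptModel(
            transcript_id=tid,
            length=tx_len,
            cds_start=cds_start,
            cds_end=cds_end,
            sequence=seq,
        )
        reason = tm.validate()
        if reason is not None:
            report.drop(reason)
            continue
        models.append(tm)
        report.n_loaded += 1
    return models, report


def load_transcript_models(
    annotation: str | os.PathLike,
    fasta: str | os.PathLike | None = None,
    fasta_is_genome: bool = True,
) -> tuple[list[TranscriptModel], LoadReport]:
    """Dispatch on annotation type: ``.gtf``/``.gff`` (requires ``fasta``)
    or the simplified transcript table (any other extension)."""
    suffix = os.path.splitext(str(annotation))[1].lower()
    if suffix in {".gtf", ".gff", ".gff3"}:
        if fasta is None:
            raise AnnotationError("GTF/GFF annotation requires a FASTA path")
        return load_gtf_models(annotation, fasta, fasta_is_genome=fasta_is_genome)
    return load_transcript_table(annotation)
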