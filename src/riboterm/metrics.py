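"""Per-transcript termination statistics and the stop-aligned metagene.

Three statistics quantify termination behavior per transcript:

* **CDS density** — mean P-site counts per nucleotide over the CDS.
* **Stop-codon pause score** — density over the 3-nt NTC divided by the
  density over the CDS body (CDS excluding its first 15 and last 12 nt).
  A ribosome dwelling longer at termination inflates this ratio.
* **RRTS (Ribosome ReadThrough Score)** — density over the 3'UTR segment
  between the NTC and the first downstream in-frame stop codon, divided by
  the full-CDS density.  Readthrough ribosomes translating past the NTC
  inflate this ratio.

The metagene aligns all transcripts at the first nucleotide of the NTC
(position 0), normalizes each transcript's counts by its own mean CDS
density, and averages position-wise with equal weight per transcript, so
a uniform track contributes exactly 1 everywhere.

No pseudocounts are used anywhere: a zero denominator makes the score
ineligible (with a reason code) instead of silently biasing it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .annotation import RegionSet, TranscriptModel, derive_regions
from .footprints import DensityTrack

#: default minimum CDS read count for score eligibility; ratio estimates
#: from fewer reads are dominated by shot noise
DEFAULT_MIN_CDS_READS = 32


def region_density(track: DensityTrack, interval: tuple[int, int]) -> float:
    """Mean counts per nucleotide over a half-open interval.

    A zero-length interval contributes density 0 by convention (it can
    only appear as an empty readthrough extension).  An interval outside
    the track is an annotation/track mismatch and raises.
    """
    start, end = interval
    if start == end:
        return 0.0
    if start < 0 or end > len(track.counts) or start > end:
        raise ValueError(
            f"{track.transcript_id}: interval [{start}, {end}) outside track "
            f"of length {len(track.counts)}"
        )
    return float(track.counts[start:end].sum()) / (end - start)


@dataclass(frozen=True)
class ScoreRow:
    """All densities and scores for one transcript in one condition.

    Densities are always reported; ``pause_score``/``rrts`` are NaN when
    the corresponding eligibility flag is False (reason codes say why).
    """

    transcript_id: str
    cds_density: float
    cds_body_density: float
    stop_density: float
    extension_density: float  # NaN when no extension region exists
    pause_score: float
    rrts: float
    n_cds_reads: int
    eligible_pause: bool
    eligible_rrts: bool
    pause_reason: str = ""
    rrts_reason: str = ""


def score_transcript(
    track: DensityTrack,
    regions: RegionSet,
    min_cds_reads: int = DEFAULT_MIN_CDS_READS,
) -> ScoreRow:
    """Compute densities, pause score and RRTS for one transcript.

    Pause score = stop-codon density / CDS-body density.
    RRTS = extension density / full-CDS density (the two definitions name
    different denominators and both are honored).
    """
    if track.transcript_id != regions.transcript_id:
        raise ValueError("track/regions transcript mismatch")
    cds_density = region_density(track, regions.cds)
    body_density = region_density(track, regions.cds_body)
    stop_density = region_density(track, regions.stop_codon)
    ext_density = (
        region_density(track, regions.extension)
        if regions.extension is not None
        else math.nan
    )
    n_cds_reads = int(track.counts[regions.cds[0] : regions.cds[1]].sum())

    pause_reason = ""
    if not regions.pause_eligible:
        pause_reason = "cds_too_short"
    elif n_cds_reads < min_cds_reads:
        pause_reason = "low_cds_reads"
    elif body_density == 0.0:
        pause_reason = "zero_body_density"
    eligible_pause = pause_reason == ""
    pause_score = stop_density / body_density if eligible_pause else math.nan

    rrts_reason = ""
    if regions.extension is None:
        rrts_reason = "no_inframe_stop"
    elif n_cds_reads < min_cds_reads:
        rrts_reason = "low_cds_reads"
    elif cds_density == 0.0:
        rrts_reason = "zero_cds_density"
    eligible_rrts = rrts_reason == ""
    rrts = ext_density / cds_density if eligible_rrts else math.nan

    return ScoreRow(
        transcript_id=track.transcript_id,
        cds_density=cds_density,
        cds_body_density=body_density,
        stop_density=stop_density,
        extension_density=ext_density,
        pause_score=pause_score,
        rrts=rrts,
        n_cds_reads=n_cds_reads,
        eligible_pause=eligible_pause,
        eligible_rrts=eligible_rrts,
        pause_reason=pause_reason,
        rrts_reason=rrts_reason,
    )


@dataclass
class ScoreTable:
    """Per-transcript score rows plus provenance for one condition."""

    rows: list[ScoreRow]
    provenance: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.rows])

    def ineligible_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            for reason in (r.pause_reason, r.rrts_reason):
                if reason:
                    counts[reason] = counts.get(reason, 0) + 1
        return counts

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for key, val in sorted(self.provenance.items()):
                fh.write(f"# {key}={val}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")

    @staticmethod
    def read_tsv(path) -> "ScoreTable":
        provenance: dict = {}
        with open(path) as fh:
            pos = fh.tell()
            while True:
                line = fh.readline()
                if not line.startswith("#"):
                    fh.seek(pos)
                    break
                key, _, val = line[1:].strip().partition("=")
                provenance[key.strip()] = val
                pos = fh.tell()
            df = pd.read_csv(fh, sep="\t", keep_default_na=False, na_values=[""])
        rows = [
            ScoreRow(
                transcript_id=str(r.transcript_id),
                cds_density=float(r.cds_density),
                cds_body_density=float(r.cds_body_density),
                stop_density=float(r.stop_density),
                extension_density=float(r.extension_density),
                pause_score=float(r.pause_score),
                rrts=float(r.rrts),
                n_cds_reads=int(r.n_cds_reads),
                eligible_pause=bool(r.eligible_pause),
                eligible_rrts=bool(r.eligible_rrts),
                pause_reason=str(r.pause_reason),
                rrts_reason=str(r.rrts_reason),
            )
            for r in df.itertuples(index=False)
        ]
        return ScoreTable(rows=rows, provenance=provenance)


def score_table(
    tracks: Mapping[str, DensityTrack],
    models: Sequence[TranscriptModel],
    min_cds_reads: int = DEFAULT_MIN_CDS_READS,
    provenance: Optional[dict] = None,
) -> ScoreTable:
    """Score every model with a track, in deterministic transcript order."""
    rows = []
    for tm in sorted(models, key=lambda m: m.transcript_id):
        track = tracks.get(tm.transcript_id)
        if track is None:
            continue
        rows.append(score_transcript(track, derive_regions(tm), min_cds_reads))
    prov = dict(provenance or {})
    prov.setdefault("min_cds_reads", min_cds_reads)
    return ScoreTable(rows=rows, provenance=prov)


@dataclass
class MetageneProfile:
    """Mean normalized ribosome density by position relative to the NTC.

    Position 0 is the first nucleotide of the stop codon.  Each transcript
    contributes its CDS-density-normalized counts at every window position
    it covers; ``n_transcripts[i]`` records how many contributed there.
    """

    positions: np.ndarray  # contiguous ints, [-window_up, +window_down]
    mean_density: np.ndarray
    n_transcripts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean_density": self.mean_density,
                "n_transcripts": self.n_transcripts,
            }
        )

    def write_tsv(self, path, provenance: Optional[dict] = None) -> None:
        with open(path, "w") as fh:
            for key, val in sorted((provenance or {}).items()):
                fh.write(f"# {key}={val}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, float_format="%.10g")


def metagene(
    tracks: Mapping[str, DensityTrack],
    models: Sequence[TranscriptModel],
    window_up: int = 100,
    window_down: int = 100,
    min_cds_reads: int = DEFAULT_MIN_CDS_READS,
) -> MetageneProfile:
    """Stop-codon-aligned metagene over all eligible transcripts.

    Transcripts with zero CDS density or fewer than ``min_cds_reads`` CDS
    reads are excluded entirely.  Shorter transcripts contribute only to
    the window positions they cover.
    """
    n_pos = window_up + window_down + 1
    acc = np.zeros(n_pos)
    n_tx = np.zeros(n_pos, dtype=np.int64)
    positions = np.arange(-window_up, window_down + 1)
    for tm in sorted(models, key=lambda m: m.transcript_id):
        track = tracks.get(tm.transcript_id)
        if track is None:
            continue
        cds_counts = track.counts[tm.cds_start : tm.cds_end]
        n_reads = int(cds_counts.sum())
        cds_density = n_reads / (tm.cds_end - tm.cds_start)
        if n_reads < min_cds_reads or cds_density == 0.0:
            continue
        anchor = tm.ntc_start
        lo = max(0, anchor - window_up)
        hi = min(tm.length, anchor + window_down + 1)
        idx_lo = lo - (anchor - window_up)
        idx_hi = idx_lo + (hi - lo)
        acc[idx_lo:idx_hi] += track.counts[lo:hi] / cds_density
        n_tx[idx_lo:idx_hi] += 1
    if n_tx.max() == 0:
        raise ValueError("empty metagene: no eligible transcripts")
    with np.errstate(invalid="ignore"):
        mean = np.where(n_tx > 0, acc / np.maximum(n_tx, 1), np.nan)
    return MetageneProfile(positions=positions, mean_density=mean, n_transcripts=n_tx)
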