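"""Synthetic transcriptomes and ribosome footprints with known truth.

The generator provides ground-truth data for every pipeline stage under an
explicit model of elongation, terminal pausing and stop-codon readthrough:

* per transcript, an expression rate λ_t (counts per nt) is drawn from a
  gamma distribution, so position-level Poisson counts are marginally
  negative-binomial (overdispersed, as ribo-seq counts are);
* P-site counts at position p are Poisson(λ_t·m(p)) with multiplier
  m = 1 over the CDS, π (the pause multiplier) at the 3 NTC positions,
  r (the readthrough fraction) over the readthrough extension, π2·r at
  the second in-frame stop, and 0 elsewhere;
* each count becomes a footprint record whose 5' position is back-computed
  from the configured P-site offset table, so the pipeline recovers the
  intended P-site exactly regardless of offset configuration;
* PCR duplicates (identical record incl. UMI) are injected at a
  configurable rate, exercising UMI deduplication.

Under this model E[pause score] = π and E[RRTS] ≈ r, so condition
presets emulate the three experimental arms: a vehicle-like control
(π = 1), an aminoglycoside-like readthrough inducer (π < 1, r elevated:
less terminal pausing, populated 3'UTRs), and a termination-inhibitor-like
arm (π > 1, r basal: prolonged stop-codon pause without readthrough).
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .annotation import STOP_CODONS, TranscriptModel
from .footprints import FootprintRecord, PsiteOffsetTable

_NT = np.array(list("ACGT"))
_NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
]
_STOP_LIST = sorted(STOP_CODONS)

#: nucleotides kept downstream of the second stop so that the longest
#: footprint (35 nt, offset 12) never runs off the transcript end
_TAIL_NT = 27


def _check_dist(dist: tuple) -> tuple:
    dist = tuple(dist)
    if dist[0] == "uniform":
        _, lo, hi = dist
        if not 0 <= lo <= hi:
            raise ValueError(f"bad uniform bounds {dist}")
    elif dist[0] == "constant":
        if dist[1] < 0:
            raise ValueError(f"bad constant {dist}")
    else:
        raise ValueError(f"unknown distribution kind {dist[0]!r}")
    return dist


def _sample_dist(dist: tuple, rng: np.random.Generator) -> int:
    if dist[0] == "uniform":
        return int(rng.integers(dist[1], dist[2] + 1))
    return int(dist[1])


@dataclass(frozen=True)
class SimulationParams:
    """All knobs of the generative model.

    Lengths are in nucleotides; distributions are ("uniform", lo, hi) or
    ("constant", v).  CDS lengths are rounded down to multiples of 3.
    ``readthrough_fraction`` is the expected extension density relative to
    CDS density; ``pause_multiplier`` the same for the NTC.
    """

    n_transcripts: int = 1000
    cds_length: tuple = ("uniform", 120, 600)
    utr5_length: tuple = ("constant", 50)
    utr3_length: tuple = ("uniform", 90, 240)
    expression_shape: float = 2.0
    expression_scale: float = 1.0
    pause_multiplier: float = 1.0
    readthrough_fraction: float = 0.01
    second_stop_pause: float = 1.0
    extension_fraction: float = 0.9
    read_length: tuple = ("uniform", 25, 31)
    umi_length: int = 10
    duplication_rate: float = 0.0
    offsets: PsiteOffsetTable = field(default_factory=PsiteOffsetTable)

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        for name in ("cds_length", "utr5_length", "utr3_length", "read_length"):
            object.__setattr__(self, name, _check_dist(getattr(self, name)))
        if not (0 <= self.readthrough_fraction <= 1):
            raise ValueError("readthrough_fraction must be in [0, 1]")
        for name in ("pause_multiplier", "second_stop_pause", "expression_shape",
                     "expression_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.extension_fraction <= 1):
            raise ValueError("extension_fraction must be in [0, 1]")
        if not (0 <= self.duplication_rate < 1):
            raise ValueError("duplication_rate must be in [0, 1)")
        rl = self.read_length
        lo = rl[1]
        hi = rl[2] if rl[0] == "uniform" else rl[1]
        max_offset = 0
        for length in range(lo, hi + 1):
            off = self.offsets.lookup(length)
            if off is None:
                raise ValueError(
                    f"read length {length} has no P-site offset; simulated "
                    "records must survive the configured offset table"
                )
            max_offset = max(max_offset, off)
        if self.utr5_length[1] < max_offset:
            raise ValueError(
                "utr5_length lower bound must cover the largest P-site offset "
                "so 5' positions stay on the transcript"
            )

    def to_dict(self) -> dict:
        d = {
            "n_transcripts": self.n_transcripts,
            "cds_length": list(self.cds_length),
            "utr5_length": list(self.utr5_length),
            "utr3_length": list(self.utr3_length),
            "expression_shape": self.expression_shape,
            "expression_scale": self.expression_scale,
            "pause_multiplier": self.pause_multiplier,
            "readthrough_fraction": self.readthrough_fraction,
            "second_stop_pause": self.second_stop_pause,
            "extension_fraction": self.extension_fraction,
            "read_length": list(self.read_length),
            "umi_length": self.umi_length,
            "duplication_rate": self.duplication_rate,
            "offsets": self.offsets.to_dict(),
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        for name in ("cds_length", "utr5_length", "utr3_length", "read_length"):
            if name in d:
                d[name] = tuple(d[name])
        if "offsets" in d:
            d["offsets"] = PsiteOffsetTable.from_dict(d["offsets"])
        return cls(**d)


@dataclass(frozen=True)
class ConditionSpec:
    """One experimental arm: named overrides of π and r on a base model."""

    name: str
    pause_multiplier: Optional[float] = None
    readthrough_fraction: Optional[float] = None

    def apply(self, base: SimulationParams) -> SimulationParams:
        kwargs = {}
        if self.pause_multiplier is not None:
            kwargs["pause_multiplier"] = self.pause_multiplier
        if self.readthrough_fraction is not None:
            kwargs["readthrough_fraction"] = self.readthrough_fraction
        return replace(base, **kwargs) if kwargs else base


def default_conditions() -> list[ConditionSpec]:
    """The three-arm preset: vehicle control, readthrough-inducer-like
    (reduced terminal pause, elevated readthrough), and
    termination-inhibitor-like (elevated pause, basal readthrough)."""
    return [
        ConditionSpec("DMSO-like", pause_multiplier=1.0, readthrough_fraction=0.005),
        ConditionSpec("G418-like", pause_multiplier=0.5, readthrough_fraction=0.08),
        ConditionSpec("SRI-like", pause_multiplier=3.0, readthrough_fraction=0.005),
    ]


def _random_seq(n: int, rng: np.random.Generator) -> str:
    return "".join(_NT[rng.integers(0, 4, n)]) if n else ""


def _non_stop_codons(n: int, rng: np.random.Generator) -> str:
    if n == 0:
        return ""
    idx = rng.integers(0, len(_NON_STOP_CODONS), n)
    return "".join(_NON_STOP_CODONS[i] for i in idx)


def simulate_transcriptome(
    params: SimulationParams, seed: int
) -> list[TranscriptModel]:
    """Generate random transcript models, deterministic given the seed.

    Every transcript carries an NTC at ``cds_end - 3`` and no in-frame
    stop inside the CDS.  A fraction ``extension_fraction`` of transcripts
    gets an in-frame stop placed uniformly among the eligible codon starts
    of the 3'UTR (leaving a short tail so simulated footprints never run
    off the 3' end); the designated extension itself contains no in-frame
    stop.  The remaining transcripts have no in-frame 3'UTR stop at all.
    """
    rng = np.random.default_rng(seed)
    models: list[TranscriptModel] = []
    for i in range(params.n_transcripts):
        cds_len = max(30, _sample_dist(params.cds_length, rng) // 3 * 3)
        utr5 = _sample_dist(params.utr5_length, rng)
        utr3 = max(_sample_dist(params.utr3_length, rng), 3 + _TAIL_NT)
        has_ext = rng.random() < params.extension_fraction

        cds = "ATG" + _non_stop_codons(cds_len // 3 - 2, rng) + _STOP_LIST[rng.integers(0, 3)]
        if has_ext:
            max_ext_codons = (utr3 - 3 - _TAIL_NT) // 3
            ext_codons = int(rng.integers(0, max_ext_codons + 1))
            tail_nt = utr3 - 3 * ext_codons - 3
            utr3_seq = (
                _non_stop_codons(ext_codons, rng)
                + _STOP_LIST[rng.integers(0, 3)]
                + _random_seq(tail_nt, rng)
            )
            # the random tail may not introduce an earlier in-frame stop
            # than the designated one; it cannot (it is downstream), but it
            # is free to contain further stops
        else:
            # whole 3'UTR free of in-frame stops
            n_codons, rem = divmod(utr3, 3)
            utr3_seq = _non_stop_codons(n_codons, rng) + _random_seq(rem, rng)
        seq = _random_seq(utr5, rng) + cds + utr3_seq
        models.append(
            TranscriptModel(
                transcript_id=f"TX{i:05d}",
                length=len(seq),
                cds_start=utr5,
                cds_end=utr5 + cds_len,
                sequence=seq,
            )
        )
    return models


def _expected_rates(
    tm: TranscriptModel, params: SimulationParams, lam: float
) -> np.ndarray:
    """Per-position Poisson means m(p)·λ for one transcript."""
    from .annotation import find_next_inframe_stop

    rate = np.zeros(tm.length)
    rate[tm.cds_start : tm.cds_end - 3] = lam
    rate[tm.cds_end - 3 : tm.cds_end] = lam * params.pause_multiplier
    nss = find_next_inframe_stop(tm)
    if nss is not None:
        r = params.readthrough_fraction
        rate[tm.cds_end : nss] = lam * r
        rate[nss : nss + 3] = lam * r * params.second_stop_pause
    return rate


def simulate_footprints(
    models: Sequence[TranscriptModel],
    params: SimulationParams,
    seed: int,
) -> list[FootprintRecord]:
    """Sample footprint records from the Poisson occupancy model.

    Each P-site count is materialized as a record with a sampled read
    length, a 5' position back-computed from the offset table, and a fresh
    random UMI; PCR duplicates (identical copies) are appended with
    probability ``duplication_rate`` per record.
    """
    rng = np.random.default_rng(seed)
    records: list[FootprintRecord] = []
    rl_lo = params.read_length[1]
    rl_hi = params.read_length[2] if params.read_length[0] == "uniform" else rl_lo
    rl_choices = np.arange(rl_lo, rl_hi + 1)
    offset_by_len = {int(L): params.offsets.lookup(int(L)) for L in rl_choices}

    for tm in models:
        lam = rng.gamma(params.expression_shape, params.expression_scale)
        counts = rng.poisson(_expected_rates(tm, params, lam))
        nz = np.nonzero(counts)[0]
        if nz.size == 0:
            continue
        psites = np.repeat(nz, counts[nz])
        n = psites.size
        rls = rng.choice(rl_choices, size=n)
        umi_mat = _NT[rng.integers(0, 4, (n, params.umi_length))]
        # always drawn so the stream of random draws, and hence every
        # record, is identical across runs differing only in this rate
        dup = rng.random(n) < params.duplication_rate
        for j in range(n):
            rl = int(rls[j])
            rec = FootprintRecord(
                transcript_id=tm.transcript_id,
                five_prime_pos=int(psites[j]) - offset_by_len[rl],
                read_length=rl,
                umi="".join(umi_mat[j]),
            )
            records.append(rec)
            if dup[j]:
                records.append(rec)
    return records


@dataclass
class ExperimentOutput:
    """Paths and parameters of one simulated multi-arm experiment."""

    transcript_table: str
    footprint_tables: dict[str, str]
    manifest_path: str
    manifest: dict


def simulate_experiment(
    base: SimulationParams,
    conditions: Sequence[ConditionSpec],
    seed: int,
    outdir: str | os.PathLike,
) -> ExperimentOutput:
    """Simulate a shared transcriptome plus one footprint file per arm.

    The transcriptome is shared across conditions (pairing transcripts for
    the signed-rank comparison); count noise is independent per arm.  A
    manifest JSON records every parameter and derived seed.
    """
    os.makedirs(outdir, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    derived = [int(s) % (2**31) for s in ss.generate_state(1 + len(conditions))]
    tx_seed, cond_seeds = derived[0], derived[1:]

    models = simulate_transcriptome(base, tx_seed)
    from .annotation import write_transcript_table
    from .footprints import write_footprint_table

    tx_path = os.path.join(outdir, "transcripts.tsv")
    write_transcript_table(models, tx_path)

    fp_paths: dict[str, str] = {}
    for spec, cseed in zip(conditions, cond_seeds):
        cond_params = spec.apply(base)
        recs = simulate_footprints(models, cond_params, cseed)
        path = os.path.join(outdir, f"{spec.name}.footprints.tsv")
        write_footprint_table(recs, path)
        fp_paths[spec.name] = path

    manifest = {
        "seed": seed,
        "transcriptome_seed": tx_seed,
        "base_params": base.to_dict(),
        "conditions": [
            {
                "name": spec.name,
                "pause_multiplier": spec.pause_multiplier,
                "readthrough_fraction": spec.readthrough_fraction,
                "seed": cseed,
                "params": spec.apply(base).to_dict(),
            }
            for spec, cseed in zip(conditions, cond_seeds)
        ],
        "transcript_table": os.path.basename(tx_path),
        "footprint_tables": {k: os.path.basename(v) for k, v in fp_paths.items()},
    }
    manifest_path = os.path.join(outdir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ExperimentOutput(
        transcript_table=tx_path,
        footprint_tables=fp_paths,
        manifest_path=manifest_path,
        manifest=manifest,
    )
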