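"""Run configuration: one serializable object drives every pipeline stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .footprints import PsiteOffsetTable
from .metrics import DEFAULT_MIN_CDS_READS
from .simulate import ConditionSpec, SimulationParams, default_conditions


@dataclass(frozen=True)
class ComparisonSpec:
    """One ordered condition comparison.

    ``reference`` and ``treatment`` name conditions; the paired pause-score
    comparison uses a signed-rank test with ``pause_alternative`` and the
    RRTS comparison a Mann–Whitney U test of treatment vs reference with
    ``rrts_alternative`` (nothing is inferred from names or file order).
    """

    reference: str
    treatment: str
    pause_alternative: str = "two-sided"
    rrts_alternative: str = "greater"


_KNOWN_KEYS = {
    "annotation",
    "fasta",
    "fasta_is_genome",
    "footprints",
    "output_dir",
    "offsets",
    "min_cds_reads",
    "metagene_window_up",
    "metagene_window_down",
    "comparisons",
    "seed",
    "simulate",
}


@dataclass
class RunConfig:
    """Everything a scoring / metagene / simulation run needs."""

    annotation: Optional[str] = None
    fasta: Optional[str] = None
    fasta_is_genome: bool = True
    footprints: dict[str, str] = field(default_factory=dict)  # condition -> path
    output_dir: str = "riboterm_out"
    offsets: PsiteOffsetTable = field(default_factory=PsiteOffsetTable)
    min_cds_reads: int = DEFAULT_MIN_CDS_READS
    metagene_window_up: int = 100
    metagene_window_down: int = 100
    comparisons: list[ComparisonSpec] = field(default_factory=list)
    seed: int = 0
    simulate_params: SimulationParams = field(default_factory=SimulationParams)
    simulate_conditions: list[ConditionSpec] = field(default_factory=default_conditions)

    def to_dict(self) -> dict:
        return {
            "annotation": self.annotation,
            "fasta": self.fasta,
            "fasta_is_genome": self.fasta_is_genome,
            "footprints": dict(self.footprints),
            "output_dir": self.output_dir,
            "offsets": self.offsets.to_dict(),
            "min_cds_reads": self.min_cds_reads,
            "metagene_window_up": self.metagene_window_up,
            "metagene_window_down": self.metagene_window_down,
            "comparisons": [vars(c) for c in self.comparisons],
            "seed": self.seed,
            "simulate": {
                "params": self.simulate_params.to_dict(),
                "conditions": [
                    {
                        "name": c.name,
                        "pause_multiplier": c.pause_multiplier,
                        "readthrough_fraction": c.readthrough_fraction,
                    }
                    for c in self.simulate_conditions
                ],
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        sim = d.get("simulate", {})
        sim_unknown = set(sim) - {"params", "conditions"}
        if sim_unknown:
            raise ValueError(f"unknown simulate keys: {sorted(sim_unknown)}")
        return cls(
            annotation=d.get("annotation"),
            fasta=d.get("fasta"),
            fasta_is_genome=d.get("fasta_is_genome", True),
            footprints=dict(d.get("footprints", {})),
            output_dir=d.get("output_dir", "riboterm_out"),
            offsets=(
                PsiteOffsetTable.from_dict(d["offsets"])
                if "offsets" in d
                else PsiteOffsetTable()
            ),
            min_cds_reads=d.get("min_cds_reads", DEFAULT_MIN_CDS_READS),
            metagene_window_up=d.get("metagene_window_up", 100),
            metagene_window_down=d.get("metagene_window_down", 100),
            comparisons=[ComparisonSpec(**c) for c in d.get("comparisons", [])],
            seed=d.get("seed", 0),
            simulate_params=(
                SimulationParams.from_dict(sim["params"])
                if "params" in sim
                else SimulationParams()
            ),
            simulate_conditions=(
                [ConditionSpec(**c) for c in sim["conditions"]]
                if "conditions" in sim
                else default_conditions()
            ),
        )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """Stable short hash of the configuration, stamped into every
        output file's provenance header.  The output directory is not part
        of the hash: the same analysis written elsewhere is the same run.
        """
        d = self.to_dict()
        d.pop("output_dir", None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]
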