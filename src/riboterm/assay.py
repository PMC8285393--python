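"""Plate-screening and in-vitro pharmacology metrics.

Readthrough screens report each test well as % Activation on a scale
anchored by the per-plate control means (0% = cells-only negative control,
100% = positive-control mean), call hits against a statistical activity
threshold, and track assay quality with the Z'-factor, signal/background,
signal/noise and control %CV.  Cytotoxicity counter-screens report
% viability on the analogous low/high control scale.  Transwell
permeability assays report the apparent permeability
Papp = ΔQ/(Δt·A·C0) and the B→A over A→B efflux ratio.

Control standard deviations use the sample convention (n−1 denominator)
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

NEGATIVE = "negative_control"
POSITIVE = "positive_control"
TEST = "test"
_ROLES = (NEGATIVE, POSITIVE, TEST)

#: Z'-factor above which an assay run is considered reliable
Z_PRIME_RELIABLE = 0.5


class DegenerateControlsError(ValueError):
    """Controls cannot anchor the normalization (equal means etc.)."""


@dataclass
class PlateData:
    """Raw luminescence for one plate, with well roles."""

    plate_id: str
    raw_signal: dict[str, float]
    well_role: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.raw_signal) != set(self.well_role):
            raise ValueError("signal and role well sets differ")
        bad = {r for r in self.well_role.values()} - set(_ROLES)
        if bad:
            raise ValueError(f"unknown well roles {sorted(bad)}")
        if not all(np.isfinite(v) for v in self.raw_signal.values()):
            raise ValueError("non-finite signal")

    def wells(self, role: str) -> list[str]:
        return sorted(w for w, r in self.well_role.items() if r == role)

    def signals(self, role: str) -> np.ndarray:
        return np.array([self.raw_signal[w] for w in self.wells(role)])

    @classmethod
    def from_csv(cls, path) -> list["PlateData"]:
        """Read the plate CSV (plate_id, well, row, col, role, signal);
        one PlateData per plate_id, in file order."""
        df = pd.read_csv(path, dtype={"plate_id": str, "well": str, "role": str})
        needed = {"plate_id", "well", "role", "signal"}
        missing = needed - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing columns {sorted(missing)}")
        plates = []
        for pid, grp in df.groupby("plate_id", sort=False):
            plates.append(
                cls(
                    plate_id=str(pid),
                    raw_signal=dict(zip(grp.well, grp.signal.astype(float))),
                    well_role=dict(zip(grp.well, grp.role)),
                )
            )
        return plates


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if values.size > 1 else 0.0


def percent_activation(plate: PlateData) -> dict[str, float]:
    """% Activation = 100·(signal − neg mean)/(pos mean − neg mean) for
    every test well, using per-plate control means."""
    neg = plate.signals(NEGATIVE)
    pos = plate.signals(POSITIVE)
    if neg.size == 0 or pos.size == 0:
        raise ValueError(f"plate {plate.plate_id}: missing control wells")
    neg_mean, pos_mean = float(neg.mean()), float(pos.mean())
    if pos_mean == neg_mean:
        raise DegenerateControlsError(
            f"plate {plate.plate_id}: positive and negative control means equal"
        )
    span = pos_mean - neg_mean
    return {
        w: 100.0 * (plate.raw_signal[w] - neg_mean) / span for w in plate.wells(TEST)
    }


def control_activations(plate: PlateData, role: str = NEGATIVE) -> np.ndarray:
    """Control wells mapped onto the same % Activation scale."""
    neg = plate.signals(NEGATIVE)
    pos = plate.signals(POSITIVE)
    span = float(pos.mean() - neg.mean())
    if span == 0:
        raise DegenerateControlsError(f"plate {plate.plate_id}: degenerate controls")
    return 100.0 * (plate.signals(role) - float(neg.mean())) / span


def hit_threshold(
    all_test_activations: Sequence[float],
    negative_control_activations: Sequence[float],
) -> float:
    """Statistical threshold of activity: mean of all test-well
    % Activation plus three sample SDs of the negative controls'
    % Activation.  Accepts per-plate or campaign-pooled negatives."""
    test = np.asarray(all_test_activations, dtype=float)
    neg = np.asarray(negative_control_activations, dtype=float)
    if neg.size < 2:
        raise ValueError("need >= 2 negative-control values for an SD")
    return float(test.mean()) + 3.0 * _sd(neg)


def plate_qc(plate: PlateData) -> dict[str, float | bool]:
    """Assay-performance panel: Z' = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|,
    S/B, S/N and per-role %CV; ``qc_flag`` is raised when Z' ≤ 0.5."""
    neg = plate.signals(NEGATIVE)
    pos = plate.signals(POSITIVE)
    if neg.size < 2 or pos.size < 2:
        raise ValueError(f"plate {plate.plate_id}: need >= 2 wells per control role")
    mu_n, mu_p = float(neg.mean()), float(pos.mean())
    sd_n, sd_p = _sd(neg), _sd(pos)
    if mu_p == mu_n:
        raise DegenerateControlsError(f"plate {plate.plate_id}: equal control means")
    z_prime = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    out: dict[str, float | bool] = {
        "z_prime": z_prime,
        "s_n": (mu_p - mu_n) / sd_n if sd_n > 0 else float("inf"),
        "cv_pos": 100.0 * sd_p / mu_p if mu_p != 0 else float("inf"),
        "cv_neg": 100.0 * sd_n / mu_n if mu_n != 0 else float("inf"),
        "qc_flag": z_prime <= Z_PRIME_RELIABLE,
    }
    # S/B is undefined on a zero negative-control mean; the key is simply
    # absent rather than poisoning the rest of the panel
    if mu_n != 0:
        out["s_b"] = mu_p / mu_n
    return out


def z_prime(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Z'-factor from summary statistics (formula form of :func:`plate_qc`)."""
    if mu_pos == mu_neg:
        raise DegenerateControlsError("equal control means")
    return 1.0 - 3.0 * (sd_pos + sd_neg) / abs(mu_pos - mu_neg)


def percent_viability(test_signal: float, low_mean: float, high_mean: float) -> float:
    """% viability = 100·(test − low-control mean)/(high-control mean −
    low-control mean); 0% anchors at the killed (low) control, 100% at the
    untreated (high) control."""
    if high_mean == low_mean:
        raise DegenerateControlsError("high and low viability controls equal")
    return 100.0 * (test_signal - low_mean) / (high_mean - low_mean)


def rlu_per_ug(rlu: float, protein_ug: float) -> float:
    """Reporter luminescence normalized to lysate protein (RLU/µg)."""
    if protein_ug <= 0:
        raise ValueError("protein mass must be positive")
    return rlu / protein_ug


@dataclass(frozen=True)
class PermeabilityMeasurement:
    """One transwell flux measurement, pre-converted to consistent units:
    ``dq_dt`` in amount/s, ``area`` in cm², ``c0`` in amount/cm³."""

    dq_dt: float
    area: float
    c0: float
    direction: str = "AB"  # AB (apical→basolateral) or BA

    def __post_init__(self) -> None:
        if self.area <= 0 or self.c0 <= 0:
            raise ValueError("area and c0 must be positive")
        if self.dq_dt < 0:
            raise ValueError("dq_dt must be >= 0")
        if self.direction not in ("AB", "BA"):
            raise ValueError("direction must be AB or BA")


def apparent_permeability(m: PermeabilityMeasurement) -> float:
    """Papp = ΔQ/(Δt·A·C0), in cm/s given unit-consistent inputs.
    No unit inference is performed."""
    return m.dq_dt / (m.area * m.c0)


def efflux_ratio(papp_ba: float, papp_ab: float) -> float:
    """ER = Papp(B→A) / Papp(A→B)."""
    if papp_ab <= 0:
        raise ValueError("A→B permeability must be positive")
    return papp_ba / papp_ab
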