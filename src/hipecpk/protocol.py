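"""Dosing and sampling protocol for intraperitoneal (HIPEC) cisplatin.

The perfusion protocol modelled here is the one used in large-animal HIPEC
studies: a total dose prescribed per m² of body surface area, split into
fractional boluses added to the heated carrier solution at fixed times, a
90-minute perfusion, and interval-averaged microdialysis sampling on a fixed
schedule starting at perfusion start (time zero, minutes throughout).

Body surface area for pigs uses the power law ``SA = 0.0970 · W^0.633``
(SA in m², W in kg).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

__all__ = [
    "ProtocolSpec",
    "body_surface_area",
    "total_dose",
    "dose_events",
    "default_sampling_schedule",
    "DEFAULT_DOSE_FRACTIONS",
    "LLOQ_UG_PER_ML",
]

#: Lower limit of quantification of the cisplatin dialysate assay (µg/mL).
LLOQ_UG_PER_ML = 0.030

#: Default dose split: 50% at perfusion start, 25% at 30 min, 25% at 60 min.
DEFAULT_DOSE_FRACTIONS: tuple[tuple[float, float], ...] = (
    (0.0, 0.50),
    (30.0, 0.25),
    (60.0, 0.25),
)


def default_sampling_schedule() -> list[tuple[float, float]]:
    """Return the microdialysis collection intervals in minutes.

    Eight 30-min intervals covering 0–240 min followed by four 60-min
    intervals covering 240–480 min: 12 interval-averaged samples per catheter.
    """
    out = [(float(s), float(s + 30)) for s in range(0, 240, 30)]
    out += [(float(s), float(s + 60)) for s in range(240, 480, 60)]
    return out


@dataclass(frozen=True)
class ProtocolSpec:
    """Complete dosing + sampling protocol for one experiment.

    Parameters
    ----------
    body_weight_kg : float
        Animal body weight in kg (> 0).
    dose_per_m2 : float
        Prescribed dose intensity in mg per m² body surface area.
    dose_fractions : sequence of (time_min, fraction)
        Ordered bolus schedule; fractions must sum to 1 within 1e-9.
    perfusion_end_min : float
        Time at which the abdominal cavity is drained (min).
    sampling_intervals : sequence of (start_min, end_min)
        Contiguous, non-overlapping, strictly increasing collection intervals.
    lloq_ug_per_ml : float
        Assay lower limit of quantification (µg/mL).
    """

    body_weight_kg: float
    dose_per_m2: float = 100.0
    dose_fractions: tuple[tuple[float, float], ...] = DEFAULT_DOSE_FRACTIONS
    perfusion_end_min: float = 90.0
    sampling_intervals: tuple[tuple[float, float], ...] = field(
        default_factory=lambda: tuple(default_sampling_schedule())
    )
    lloq_ug_per_ml: float = LLOQ_UG_PER_ML

    def __post_init__(self) -> None:
        if not self.body_weight_kg > 0:
            raise ValueError(f"body_weight_kg must be > 0, got {self.body_weight_kg}")
        fracs = [f for _, f in self.dose_fractions]
        if not fracs or abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"dose fractions must sum to 1.0, got {sum(fracs)!r}")
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("each dose fraction must lie in [0, 1]")
        times = [t for t, _ in self.dose_fractions]
        if times != sorted(times):
            raise ValueError("dose fraction times must be non-decreasing")
        prev_end = None
        for start, end in self.sampling_intervals:
            if end <= start:
                raise ValueError(f"degenerate sampling interval ({start}, {end})")
            if prev_end is not None and abs(start - prev_end) > 1e-9:
                raise ValueError("sampling intervals must be contiguous")
            prev_end = end
        # normalize container types so the dataclass hashes/compares cleanly
        object.__setattr__(self, "dose_fractions", tuple((float(t), float(f)) for t, f in self.dose_fractions))
        object.__setattr__(
            self, "sampling_intervals", tuple((float(a), float(b)) for a, b in self.sampling_intervals)
        )

    # -- serialization --------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["dose_fractions"] = [list(x) for x in self.dose_fractions]
        d["sampling_intervals"] = [list(x) for x in self.sampling_intervals]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ProtocolSpec":
        d = dict(d)
        if "dose_fractions" in d:
            d["dose_fractions"] = tuple((float(t), float(f)) for t, f in d["dose_fractions"])
        if "sampling_intervals" in d:
            d["sampling_intervals"] = tuple((float(a), float(b)) for a, b in d["sampling_intervals"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        """Write the protocol as YAML (or JSON when the suffix is .json)."""
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def load(cls, path: str | Path) -> "ProtocolSpec":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data)


def body_surface_area(weight_kg: float) -> float:
    """Porcine body surface area (m²) from body weight (kg).

    ``SA = 0.0970 · W^0.633``; strictly increasing in weight.
    """
    if not weight_kg > 0:
        raise ValueError(f"weight must be > 0 kg, got {weight_kg}")
    return 0.0970 * weight_kg**0.633


def total_dose(spec: ProtocolSpec) -> float:
    """Total administered dose in mg: dose_per_m2 × body surface area."""
    return spec.dose_per_m2 * body_surface_area(spec.body_weight_kg)


def dose_events(spec: ProtocolSpec) -> list[tuple[float, float]]:
    """Bolus schedule as (time_min, dose_mg) pairs; conserves the total dose."""
    dose = total_dose(spec)
    return [(t, f * dose) for t, f in spec.dose_fractions]
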