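"""Small bespoke assay arithmetic: plate-normalized viability and in vitro
membrane-extraction efficiency.

Viability readings (luminescence from an ATP-based assay, or absorbance)
are normalized within cell line AND plate to a safe-harbor control guide,
so plate-to-plate reagent and seeding differences cancel.  Extraction
(dislocation) efficiency compares the eluted tail-anchored substrate to the
dilution-corrected input lane of the same gel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

DEFAULT_CONTROL_SGRNA = "sgAAVS1"


@dataclass(frozen=True)
class PlateReading:
    """One well-level viability reading."""

    cell_line: str
    plate_id: str
    sgrna: str
    value: float

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("reading value must be non-negative")


@dataclass(frozen=True)
class BandPair:
    """Densitometry signals for one extraction reaction.

    The input lane is conventionally loaded diluted relative to the
    elution lane; ``input_dilution`` is that fold-dilution (default 5x).
    """

    input_signal: float
    elution_signal: float
    input_dilution: float = 5.0

    def __post_init__(self) -> None:
        if self.input_dilution <= 0:
            raise ValueError("input_dilution must be positive")
        if self.input_signal < 0 or self.elution_signal < 0:
            raise ValueError("band signals must be non-negative")


def normalize_viability(
    readings: list[PlateReading],
    control_sgrna: str = DEFAULT_CONTROL_SGRNA,
) -> dict[tuple[str, str], float]:
    """Percent viability per (cell line, sgRNA), normalized to the control guide.

    Replicate wells on a plate are averaged first; the percent is
    100 * mean(test) / mean(control) computed within the same cell line and
    plate, then averaged across plates carrying that condition.  The
    control itself normalizes to 100 by construction.
    """
    by_plate: dict[tuple[str, str], dict[str, list[float]]] = {}
    for r in readings:
        by_plate.setdefault((r.cell_line, r.plate_id), {}).setdefault(r.sgrna, []).append(r.value)

    percents: dict[tuple[str, str], list[float]] = {}
    for (cell_line, plate_id), plate in by_plate.items():
        if control_sgrna not in plate:
            raise ValueError(
                f"no {control_sgrna!r} control on plate {plate_id!r} ({cell_line})"
            )
        control = sum(plate[control_sgrna]) / len(plate[control_sgrna])
        if control == 0:
            raise ValueError(f"zero control mean on plate {plate_id!r} ({cell_line})")
        for sgrna, values in plate.items():
            pct = 100.0 * (sum(values) / len(values)) / control
            percents.setdefault((cell_line, sgrna), []).append(pct)
    return {key: sum(v) / len(v) for key, v in percents.items()}


def extraction_efficiency(pair: BandPair) -> float:
    """Fraction of membrane-anchored substrate extracted into the elution.

    efficiency = elution / (input * input_dilution).  Values above 1 are
    physically impossible but can arise from densitometry noise or signal
    saturation; they are returned unclipped with a warning rather than
    silently truncated.
    """
    if pair.input_signal == 0:
        raise ValueError("input_signal must be positive")
    eff = pair.elution_signal / (pair.input_signal * pair.input_dilution)
    if eff > 1:
        warnings.warn(
            f"extraction efficiency {eff:.3g} exceeds 1; check for signal saturation",
            stacklevel=2,
        )
    return eff
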