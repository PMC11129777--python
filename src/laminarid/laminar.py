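"""Fusion of the CSD input-layer estimate and the phase-reversal depth.

The CSD sink gives the middle of the input layer (layer 4); the spike-LFP
phase flip marks the layer IV/V transition just below it.  When both are
available the flip is adopted as the IV/V boundary and the CSD estimate is
used as a consistency check; with the CSD alone, the boundary falls back to
the input-layer middle plus an assumed half layer-IV thickness.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

from .csd import CsdResult
from .spike_phase import PhaseMatrix

__all__ = ["LaminarEstimate", "NoEstimateError", "estimate_laminar"]


class NoEstimateError(ValueError):
    """Neither the CSD nor the phase matrix yields a laminar estimate."""


@dataclass(frozen=True)
class LaminarEstimate:
    """Fused laminar registration for one session."""

    input_layer_mid_um: float | None
    reversal_depth_um: float | None
    l4_l5_boundary_um: float
    consistent: bool
    provenance: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def estimate_laminar(
    csd: CsdResult | None,
    pm: PhaseMatrix | None,
    max_offset_um: float = 300.0,
    l4_half_thickness_um: float = 250.0,
) -> LaminarEstimate:
    """Fuse the two laminar markers into a layer IV/V boundary.

    The phase reversal, when present, takes precedence as the boundary;
    ``consistent`` is true when the reversal lies at or below the CSD
    input-layer middle and within ``max_offset_um`` of it.  With only the
    CSD, the boundary is the input-layer middle plus
    ``l4_half_thickness_um`` (a convention, not a measurement).
    """
    input_mid = csd.input_layer_depth_um if csd is not None else None
    reversal = pm.reversal_depth_um if pm is not None else None

    if input_mid is None and reversal is None:
        raise NoEstimateError("neither a CSD sink nor a phase reversal is available")

    if reversal is not None:
        boundary = float(reversal)
        if input_mid is None:
            provenance = "phase-only"
            consistent = True
        else:
            provenance = "csd+phase"
            offset = reversal - input_mid
            consistent = bool(0.0 <= offset <= max_offset_um)
            if reversal < input_mid:
                import warnings

                warnings.warn(
                    f"phase reversal ({reversal:.0f} um) lies above the CSD input-"
                    f"layer middle ({input_mid:.0f} um); estimates are inconsistent"
                )
    else:
        boundary = float(input_mid + l4_half_thickness_um)
        provenance = "csd-only"
        consistent = True

    return LaminarEstimate(
        input_layer_mid_um=None if input_mid is None else float(input_mid),
        reversal_depth_um=None if reversal is None else float(reversal),
        l4_l5_boundary_um=boundary,
        consistent=consistent,
        provenance=provenance,
    )
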