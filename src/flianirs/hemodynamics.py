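"""Post-exercise ankle-brachial index in the hip-flexed (competitive) posture.

Because the ankle lies below the arm when the athlete keeps the competitive
posture on the resting platform, the measured ankle pressure carries a
hydrostatic component that must be removed before forming the index:

    ABI_flexed = (SAP - dAB * 0.78) / SBP

with SAP the systolic ankle pressure (mmHg), SBP the systolic brachial
pressure (mmHg) and dAB the ankle-arm vertical height difference (cm;
1 cm of blood column = 0.78 mmHg).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError

log = logging.getLogger(__name__)

MMHG_PER_CM = 0.78
ABI_NORMAL_THRESHOLD = 0.54
SAP_DIFF_THRESHOLD_MMHG = 23.0


@dataclass(frozen=True)
class AbiMeasurement:
    """Systolic pressures (mmHg) and ankle-arm height difference (cm)."""

    sap: float
    sbp: float
    delta_ab: float = 0.0

    def __post_init__(self):
        if not np.isfinite([self.sap, self.sbp, self.delta_ab]).all():
            raise ParameterError("pressures and height offset must be finite")
        if self.sbp <= 0:
            raise ParameterError("systolic brachial pressure must be positive")


def abi_flexed(m: AbiMeasurement) -> float:
    """Height-corrected ankle-brachial index; no clamping is applied."""
    return (m.sap - m.delta_ab * MMHG_PER_CM) / m.sbp


@dataclass(frozen=True)
class AbiClassification:
    left_abnormal: Optional[bool]
    right_abnormal: Optional[bool]


def classify_abi(abi_left: Optional[float] = None,
                 abi_right: Optional[float] = None,
                 sap_left: Optional[float] = None,
                 sap_right: Optional[float] = None) -> AbiClassification:
    """Per-leg normal/abnormal flags for competitive athletes.

    A leg is abnormal when its height-corrected index falls below 0.54, or
    when the between-leg systolic ankle pressure difference exceeds 23 mmHg
    with that leg being the lower one. With a single measured leg only the
    index criterion applies (logged).
    """
    flags = {}
    for side, abi in (("left", abi_left), ("right", abi_right)):
        flags[side] = None if abi is None else bool(abi < ABI_NORMAL_THRESHOLD)
    if abi_left is None or abi_right is None:
        log.info("single-leg ABI input: pressure-difference criterion skipped")
    elif sap_left is not None and sap_right is not None:
        diff = sap_left - sap_right
        if abs(diff) > SAP_DIFF_THRESHOLD_MMHG:
            lower = "left" if diff < 0 else "right"
            flags[lower] = True
    return AbiClassification(left_abnormal=flags["left"],
                             right_abnormal=flags["right"])
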