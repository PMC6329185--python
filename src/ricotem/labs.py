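"""Laboratory phenotyping of von Willebrand disease.

The conventional work-up measures three VWF quantities, each as percent of
a normal reference plasma: antigen level (VWF:Ag), ristocetin cofactor
activity (VWF:RCo) and collagen-binding activity (VWF:CB). A 50% threshold
on all three rules VWD out; values below 30% define overt Type 1; VWF:Ag
below 3% defines Type 3 (virtual absence of VWF); Type 2 (qualitative
defect) is established by multimer gel electrophoresis, which this package
takes as a supplied flag, never computes.

Precedence is severity-first, so a panel with VWF:Ag < 3% and abnormal
multimers is Type 3, matching the antigen-alone definition of Type 3.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .errors import InvalidInputError, MissingDataError

__all__ = ["LabPanel", "VwdPhenotype", "classify_vwd", "has_vwd", "low_fviii_advisory"]


class VwdPhenotype(enum.Enum):
    """Laboratory VWD phenotype, ordered by increasing severity."""

    NO_VWD = "no_vwd"
    POSSIBLE_VWD = "possible_vwd"
    MILD_TYPE1 = "mild_type1"
    TYPE1 = "type1"
    TYPE2 = "type2"
    TYPE3 = "type3"

    @property
    def severity(self) -> int:
        order = ["no_vwd", "possible_vwd", "mild_type1", "type1", "type2", "type3"]
        return order.index(self.value)


@dataclass(frozen=True)
class LabPanel:
    """Conventional hemostasis values and flags for one patient.

    ``multimer_abnormal`` is ``None`` when gel electrophoresis was not done.
    """

    vwf_ag_pct: float
    vwf_rco_pct: float
    vwf_cb_pct: float
    fviii_pct: float
    pt_pct: float
    aptt_s: float
    fibrinogen_gL: float
    platelets_per_nL: float
    bleeding_history: bool = False
    multimer_abnormal: Optional[bool] = None

    def __post_init__(self) -> None:
        for name in ("vwf_ag_pct", "vwf_rco_pct", "vwf_cb_pct", "fviii_pct",
                     "pt_pct", "fibrinogen_gL", "platelets_per_nL"):
            v = getattr(self, name)
            if v is None:
                raise MissingDataError(f"lab panel is missing {name}")
            if v < 0:
                raise InvalidInputError(f"{name} must be non-negative, got {v}")
        if self.aptt_s is None:
            raise MissingDataError("lab panel is missing aptt_s")
        if self.aptt_s <= 0:
            raise InvalidInputError(f"aptt_s must be positive, got {self.aptt_s}")

    @property
    def vwf_values(self) -> tuple:
        return (self.vwf_ag_pct, self.vwf_rco_pct, self.vwf_cb_pct)


def classify_vwd(panel: LabPanel) -> VwdPhenotype:
    """Assign the laboratory phenotype by a severity-first precedence chain.

    1. Type 3 if VWF:Ag < 3%.
    2. Type 2 if the multimer pattern is abnormal.
    3. Type 1 if any VWF measure < 30%, or bleeding history with any
       VWF measure < 50%.
    4. Mild Type 1 if all three VWF measures lie in [30, 50).
    5. Possible VWD if one or two of the three measures are < 50% while the
       rest are >= 50%.
    6. No VWD otherwise (all three >= 50%).

    Every valid panel maps to exactly one phenotype.
    """
    vwf = panel.vwf_values
    if panel.vwf_ag_pct < 3.0:
        return VwdPhenotype.TYPE3
    if panel.multimer_abnormal is True:
        return VwdPhenotype.TYPE2
    n_below_50 = sum(v < 50.0 for v in vwf)
    if any(v < 30.0 for v in vwf) or (panel.bleeding_history and n_below_50 >= 1):
        return VwdPhenotype.TYPE1
    if all(30.0 <= v < 50.0 for v in vwf):
        return VwdPhenotype.MILD_TYPE1
    if n_below_50 >= 1:
        return VwdPhenotype.POSSIBLE_VWD
    return VwdPhenotype.NO_VWD


def has_vwd(phenotype: VwdPhenotype, include_possible: bool = False) -> bool:
    """Whether a phenotype counts as confirmed VWD for screening metrics.

    ``possible_vwd`` counts only when ``include_possible`` is set.
    """
    if phenotype is VwdPhenotype.NO_VWD:
        return False
    if phenotype is VwdPhenotype.POSSIBLE_VWD:
        return include_possible
    return True


def low_fviii_advisory(panel: LabPanel, threshold_pct: float = 50.0) -> bool:
    """Advisory flag for isolated low factor VIII with normal VWF measures.

    Such a panel (e.g. mild hemophilia A) is *not* VWD and classifies as
    ``no_vwd``; the flag signals that specialist FVIII work-up is indicated.
    """
    return panel.fviii_pct < threshold_pct and all(v >= 50.0 for v in panel.vwf_values)
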