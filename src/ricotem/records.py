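"""The per-patient record binding labs, traces and Ricotem scores together."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, TYPE_CHECKING

from .labs import LabPanel, VwdPhenotype, classify_vwd
from .scores import CutoffConfig, RicotemPanel, classify_responder
from .trace import RotemTrace

if TYPE_CHECKING:  # pragma: no cover
    from .simulate import PhenotypeParams


@dataclass
class PatientRecord:
    """One patient: identity, labs, assay panel and derived classifications.

    ``phenotype_class`` is the simulator's ground-truth class label when the
    record is synthetic, otherwise ``None``. ``phenotype`` is the phenotype
    assigned from the lab panel; ``responder`` the Ricotem responder group.
    """

    patient_id: str
    lab: LabPanel
    panel: Optional[RicotemPanel] = None
    traces: Dict[str, RotemTrace] = field(default_factory=dict)
    phenotype: Optional[VwdPhenotype] = None
    responder: Optional[str] = None
    phenotype_class: Optional[str] = None
    ground_truth: Optional["PhenotypeParams"] = None
    sex: Optional[str] = None
    age_y: Optional[float] = None
    abo: Optional[str] = None

    def classify(self, cfg: CutoffConfig = CutoffConfig()) -> "PatientRecord":
        """Fill ``phenotype`` (from labs) and ``responder`` (from the panel)."""
        self.phenotype = classify_vwd(self.lab)
        if self.panel is not None:
            self.responder = classify_responder(self.panel, cfg)
        return self
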