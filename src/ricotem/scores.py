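"""The Ricotem screening statistics and responder classification.

Three AUC30 values are measured per patient: the plain Extem assay
(``AUC_extem``), Extem after ristocetin preincubation (``AUC_rico``) and
Extem after VWF-concentrate (Haemate P) supplementation followed by
ristocetin (``AUC_rico+haemate``). Two ratios summarize them:

* ``Ricotem- = AUC_rico / AUC_extem * 100`` — low values mean ristocetin
  agglutinated the platelets, i.e. functional von Willebrand factor is
  present; 100% means ristocetin had no effect (suspected VWD).
* ``Ricotem+ = (AUC_rico - AUC_rico+haemate) / AUC_extem * 100`` — the
  recovery of the ristocetin response after VWF supplementation. Large
  values flag patients whose clot behaviour is restored by exogenous VWF
  and who may therefore benefit from VWF concentrate when bleeding. The
  value is signed and deliberately not clamped: a healthy subject whose
  AUC rises slightly after supplementation yields a small negative score.

Patients are grouped stepwise: ``normal`` responders by Ricotem- (at or
below a 25% cut-off), the remainder ``high`` (Ricotem+ at or above a 50%
cut-off, 35% as an emergency alternative) or ``low``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import InvalidInputError, InvalidParameterError, MissingDataError

__all__ = [
    "ricotem_minus",
    "ricotem_plus",
    "RicotemPanel",
    "CutoffConfig",
    "classify_responder",
    "RESPONDER_GROUPS",
]

RESPONDER_GROUPS = ("normal", "low", "high")


def ricotem_minus(auc_rico: float, auc_extem: float) -> float:
    """``AUC_rico / AUC_extem * 100`` in percent.

    100% means ristocetin did not induce platelet agglutination.
    """
    if auc_extem <= 0:
        raise InvalidInputError(f"AUC_extem must be positive, got {auc_extem}")
    if auc_rico < 0:
        raise InvalidInputError(f"AUC_rico must be non-negative, got {auc_rico}")
    return auc_rico / auc_extem * 100.0


def ricotem_plus(auc_rico: float, auc_rico_haemate: float, auc_extem: float) -> float:
    """``(AUC_rico - AUC_rico+haemate) / AUC_extem * 100`` in percent, signed.

    Returns exactly 0 when the two ristocetin AUCs are equal; negative when
    VWF supplementation *increased* the post-ristocetin AUC.
    """
    if auc_extem <= 0:
        raise InvalidInputError(f"AUC_extem must be positive, got {auc_extem}")
    if auc_rico < 0 or auc_rico_haemate < 0:
        raise InvalidInputError("ristocetin AUCs must be non-negative")
    return (auc_rico - auc_rico_haemate) / auc_extem * 100.0


@dataclass(frozen=True)
class CutoffConfig:
    """Screening cut-offs in percent.

    ``ricotem_minus_cutoff_pct``: at or below → normal responder (default 25).
    ``ricotem_plus_cutoff_pct``: at or above → high responder (default 50;
    35 is the documented lower alternative for emergency settings).
    """

    ricotem_minus_cutoff_pct: float = 25.0
    ricotem_plus_cutoff_pct: float = 50.0

    def __post_init__(self) -> None:
        for name in ("ricotem_minus_cutoff_pct", "ricotem_plus_cutoff_pct"):
            v = getattr(self, name)
            if not 0.0 < v < 100.0:
                raise InvalidParameterError(f"{name} must be in (0, 100), got {v}")


@dataclass(frozen=True)
class RicotemPanel:
    """The AUC triplet for one patient plus the derived scores.

    ``auc_rico_haemate`` may be ``None`` for normal responders: the stepwise
    procedure only runs the supplementation assay when Ricotem- exceeds its
    cut-off.
    """

    auc_extem: float
    auc_rico: float
    auc_rico_haemate: Optional[float] = None
    patient_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.auc_extem <= 0:
            raise InvalidInputError(
                f"AUC_extem must be positive, got {self.auc_extem}"
                + (f" (patient {self.patient_id})" if self.patient_id else "")
            )
        if self.auc_rico < 0:
            raise InvalidInputError("AUC_rico must be non-negative")
        if self.auc_rico_haemate is not None and self.auc_rico_haemate < 0:
            raise InvalidInputError("AUC_rico+haemate must be non-negative")

    @property
    def ricotem_minus(self) -> float:
        return ricotem_minus(self.auc_rico, self.auc_extem)

    @property
    def ricotem_plus(self) -> Optional[float]:
        if self.auc_rico_haemate is None:
            return None
        return ricotem_plus(self.auc_rico, self.auc_rico_haemate, self.auc_extem)


def classify_responder(panel: RicotemPanel, cfg: CutoffConfig = CutoffConfig()) -> str:
    """Assign the stepwise responder group: ``normal``, ``low`` or ``high``.

    Normal if Ricotem- is at or below its cut-off (ties to normal — the
    conservative screening side). Otherwise Ricotem+ is required: high if at
    or above its cut-off, else low. Negative Ricotem+ values classify as low.
    """
    rm = panel.ricotem_minus
    if rm <= cfg.ricotem_minus_cutoff_pct:
        return "normal"
    rp = panel.ricotem_plus
    if rp is None:
        who = panel.patient_id or "<unidentified patient>"
        raise MissingDataError(
            f"patient {who}: Ricotem- = {rm:.1f}% exceeds the "
            f"{cfg.ricotem_minus_cutoff_pct:g}% cut-off but the "
            "ristocetin+Haemate AUC needed for Ricotem+ is missing"
        )
    return "high" if rp >= cfg.ricotem_plus_cutoff_pct else "low"
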