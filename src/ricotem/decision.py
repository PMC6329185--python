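"""Advisory extension of a ROTEM-guided microvascular-bleeding algorithm.

Only the Ricotem+ branch is normative here: in a clinically relevant
bleeding, a Ricotem+ value at or above the configured cut-off suggests that
the patient's clot response is restored by exogenous VWF, so VWF
concentrate should be considered. Everything upstream of that branch (the
established fibrinogen/plasma-factor steps of institutional ROTEM
algorithms) is represented by a user-editable rule table of pass-through
advisories; this package deliberately ships no numeric clinical thresholds
for those steps.

All output is advisory research output, never a treatment instruction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Dict, List, Optional, Sequence

from .errors import InvalidInputError
from .scores import CutoffConfig

__all__ = [
    "BleedingCaseInput",
    "Recommendation",
    "recommend",
    "DEFAULT_RULE_TABLE",
    "DISCLAIMER",
    "TYPE2B_WARNING",
]

DISCLAIMER = (
    "Research software: advisory output only, not a clinical directive; "
    "all decisions rest with the treating physician."
)

TYPE2B_WARNING = (
    "Caveat: DDAVP is contraindicated in VWD Type 2B; subtype is not "
    "established by this assay."
)

#: Pass-through stubs for the established (non-Ricotem) algorithm steps.
#: Users supply their institutional thresholds via a YAML rule table with
#: entries {name, field, op (lt|le|gt|ge), threshold, action, rationale};
#: the shipped default intentionally contains a single generic advisory.
DEFAULT_RULE_TABLE: List[Dict[str, Any]] = [
    {
        "name": "base-algorithm-passthrough",
        "action": "follow-institutional-rotem-algorithm",
        "rationale": (
            "Standard viscoelastic findings (CT, Fibtem/Extem MCF) are managed "
            "by the institutional ROTEM algorithm; configure explicit rules to "
            "encode its thresholds."
        ),
    }
]

_OPS = {
    "lt": lambda a, b: a < b,
    "le": lambda a, b: a <= b,
    "gt": lambda a, b: a > b,
    "ge": lambda a, b: a >= b,
}


@dataclass(frozen=True)
class BleedingCaseInput:
    """One bleeding case: clinical gate, standard ROTEM findings, Ricotem+."""

    clinically_relevant_bleeding: bool
    extem_ct_s: Optional[float] = None
    fibtem_mcf_mm: Optional[float] = None
    extem_mcf_mm: Optional[float] = None
    ricotem_plus_pct: Optional[float] = None
    prior_steps_exhausted: bool = False

    def __post_init__(self) -> None:
        for name in ("extem_ct_s", "fibtem_mcf_mm", "extem_mcf_mm"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise InvalidInputError(f"{name} must be non-negative, got {v}")


@dataclass
class Recommendation:
    """Ordered advisory actions with their rationales and fired-rule trace."""

    actions: List[str] = field(default_factory=list)
    rationales: List[str] = field(default_factory=list)
    rule_trace: List[str] = field(default_factory=list)

    def add(self, action: str, rationale: str, rule: str) -> None:
        self.actions.append(action)
        self.rationales.append(rationale)
        self.rule_trace.append(rule)

    def as_dict(self) -> dict:
        return {
            "actions": list(self.actions),
            "rationales": list(self.rationales),
            "rule_trace": list(self.rule_trace),
            "disclaimer": DISCLAIMER if self.actions else None,
        }


def _apply_base_rules(
    case: BleedingCaseInput, rules: Sequence[Dict[str, Any]], rec: Recommendation
) -> None:
    for rule in rules:
        name = rule.get("name", "unnamed-rule")
        fld = rule.get("field")
        if fld is None:
            fired = True
        else:
            value = getattr(case, fld, None)
            if value is None:
                continue
            op = rule.get("op")
            if op not in _OPS:
                raise InvalidInputError(f"rule {name!r}: unknown op {op!r}")
            fired = _OPS[op](value, float(rule["threshold"]))
        if fired:
            rec.add(
                rule.get("action", name),
                rule.get("rationale", ""),
                f"base:{name}",
            )


def recommend(
    case: BleedingCaseInput,
    cfg: CutoffConfig = CutoffConfig(),
    rule_table: Optional[Sequence[Dict[str, Any]]] = None,
) -> Recommendation:
    """Pure advisory function of the case, cut-off config and rule table.

    No bleeding → empty recommendation. With bleeding, base-table rules fire
    first; then the Ricotem+ branch appends ``consider-VWF-concentrate`` when
    the score is at or above the cut-off. A missing Ricotem+ after exhausted
    prior steps yields a ``perform-ricotem-panel`` advisory, not an error.
    """
    rec = Recommendation()
    if not case.clinically_relevant_bleeding:
        return rec
    _apply_base_rules(case, DEFAULT_RULE_TABLE if rule_table is None else rule_table, rec)
    rp = case.ricotem_plus_pct
    if rp is None:
        if case.prior_steps_exhausted:
            rec.add(
                "perform-ricotem-panel",
                "Prior algorithm steps exhausted without a Ricotem+ result; the "
                "ristocetin/VWF-supplementation panel would establish whether "
                "VWF concentrate could help.",
                "ricotem:panel-missing",
            )
    elif rp >= cfg.ricotem_plus_cutoff_pct:
        rec.add(
            "consider-VWF-concentrate",
            f"Ricotem+ = {rp:.1f}% is at or above the {cfg.ricotem_plus_cutoff_pct:g}% "
            "cut-off: clot response is substantially restored by exogenous VWF, "
            f"suggesting functional VWF deficiency. {TYPE2B_WARNING}",
            "ricotem:plus-above-cutoff",
        )
    else:
        # explicitly traced negative finding; no action from this path
        rec.rule_trace.append("ricotem:plus-below-cutoff(no-action)")
    return rec
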