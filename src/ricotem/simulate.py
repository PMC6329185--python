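"""Mechanistic synthetic-data generator for ristocetin-modified ROTEM.

The clot amplitude of one channel is modelled as a lagged exponential
approach to a plateau::

    A(t) = M_eff * (1 - exp(-(t - lag) / tau))   for t >= lag, else 0

with optional multiplicative per-sample noise. ``M_eff`` depends on the
assay condition. Writing ``M`` for the total clot strength, ``phi`` for the
fibrinogen-dependent fraction of it (about 20% in whole blood), ``V`` for
the patient's functional VWF activity in percent of normal and ``K`` for a
half-saturation constant, the fraction of platelets that ristocetin
agglutinates (and thereby removes from clot formation) is

    g(V) = V / (V + K)

and the plateaus are

    extem:        M
    fibtem:       phi * M                      (platelets inhibited)
    rico:         M * (phi + (1 - phi) * (1 - g(V)))
    rico_haemate: M * (phi + (1 - phi) * (1 - g(V + dV))) + c

where ``dV`` is the VWF activity added by the Haemate P supplement (0.8 IU
into 0.4 mL of blood is roughly 200 IU/dL, i.e. +200%) and ``c`` a small
additive procoagulant firmness from the concentrate itself. The model
reproduces the assay's two key regimes: with absent VWF (``V = 0``)
ristocetin removes nothing and supplementation restores agglutination,
giving a large Ricotem+; with normal VWF the supplement changes little and
Ricotem+ stays small. Because the fibrinogen-dependent fraction ``phi``
survives full agglutination, noise-free Ricotem+ can never exceed
``(1 - phi) * 100`` — 80% at the default ``phi = 0.20``.

:func:`simulate_patient` additionally draws a class-consistent laboratory
panel so that :func:`ricotem.labs.classify_vwd` recovers the generating
phenotype class by construction, and :func:`simulate_cohort` reproduces a
27-patient screening cohort (7 controls, 9 Type 1, 6 Type 2A, 2 Type 3,
2 possible VWD, 1 mild hemophilia) for a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import InvalidParameterError
from .labs import LabPanel
from .records import PatientRecord
from .scores import RicotemPanel
from .trace import RotemTrace, auc30

__all__ = [
    "PhenotypeParams",
    "CohortSpec",
    "CONDITIONS",
    "PHENOTYPE_CLASSES",
    "agglutinated_fraction",
    "plateau_mm",
    "simulate_trace",
    "simulate_patient",
    "simulate_cohort",
]

CONDITIONS = ("extem", "rico", "rico_haemate", "fibtem")

_SEED_MOD = 2**31


@dataclass(frozen=True)
class PhenotypeParams:
    """Ground-truth mechanistic parameters for one simulated patient.

    vwf_activity_pct:
        Functional VWF activity ``V`` in percent of normal (100 = normal).
    fibrinogen_fraction:
        ``phi``, the fibrinogen-dependent fraction of total clot strength.
    mcf_total_mm:
        Total (Extem) clot-strength plateau ``M`` in mm.
    lag_s / tau_s:
        Onset lag (the ground-truth CT) and exponential time constant, s.
    haemate_increment_pct:
        ``dV``: VWF activity added by 0.8 IU Haemate P in 400 uL (~200%).
    haemate_procoagulant_mm:
        Small additive plateau firmness from the concentrate itself.
    agglutination_k_pct:
        Half-saturation ``K`` of the ristocetin agglutination response.
    noise_cv:
        Coefficient of variation of multiplicative per-sample amplitude noise.
    """

    vwf_activity_pct: float = 100.0
    fibrinogen_fraction: float = 0.20
    mcf_total_mm: float = 60.0
    lag_s: float = 120.0
    tau_s: float = 300.0
    haemate_increment_pct: float = 200.0
    haemate_procoagulant_mm: float = 2.0
    agglutination_k_pct: float = 30.0
    noise_cv: float = 0.05

    def __post_init__(self) -> None:
        if self.vwf_activity_pct < 0:
            raise InvalidParameterError("vwf_activity_pct must be >= 0")
        if not 0.0 < self.fibrinogen_fraction < 1.0:
            raise InvalidParameterError("fibrinogen_fraction must be in (0, 1)")
        for name in ("mcf_total_mm", "tau_s", "agglutination_k_pct"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        for name in ("lag_s", "haemate_increment_pct", "haemate_procoagulant_mm", "noise_cv"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


def agglutinated_fraction(vwf_activity_pct: float, k_pct: float) -> float:
    """Saturating fraction ``g(V) = V / (V + K)`` of platelets agglutinated."""
    if vwf_activity_pct < 0 or k_pct <= 0:
        raise InvalidParameterError("need V >= 0 and K > 0")
    return vwf_activity_pct / (vwf_activity_pct + k_pct)


def plateau_mm(params: PhenotypeParams, condition: str) -> float:
    """Noise-free amplitude plateau ``M_eff`` for one assay condition."""
    m, phi = params.mcf_total_mm, params.fibrinogen_fraction
    k = params.agglutination_k_pct
    if condition == "extem":
        return m
    if condition == "fibtem":
        return phi * m
    if condition == "rico":
        g = agglutinated_fraction(params.vwf_activity_pct, k)
        return m * (phi + (1.0 - phi) * (1.0 - g))
    if condition == "rico_haemate":
        g = agglutinated_fraction(
            params.vwf_activity_pct + params.haemate_increment_pct, k
        )
        return m * (phi + (1.0 - phi) * (1.0 - g)) + params.haemate_procoagulant_mm
    raise InvalidParameterError(
        f"unknown condition {condition!r}; expected one of {CONDITIONS}"
    )


def simulate_trace(
    params: PhenotypeParams,
    condition: str,
    duration_min: float = 35.0,
    dt_s: float = 1.0,
    seed: Optional[int] = None,
) -> RotemTrace:
    """Simulate one clot-amplitude trace for one assay condition.

    Deterministic for a given seed; with ``noise_cv = 0`` the closed form is
    returned exactly. Duration must cover the 30 min that AUC30 requires.
    """
    if dt_s <= 0:
        raise InvalidParameterError("dt_s must be positive")
    if duration_min < 30.0:
        raise InvalidParameterError(
            f"duration_min must be >= 30 (AUC30 needs 30 min), got {duration_min}"
        )
    m_eff = plateau_mm(params, condition)
    t = np.arange(0.0, duration_min * 60.0 + dt_s / 2.0, dt_s)
    rise = np.clip(t - params.lag_s, 0.0, None)
    a = m_eff * (1.0 - np.exp(-rise / params.tau_s))
    a[t < params.lag_s] = 0.0
    if params.noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(params.noise_cv**2))
        a = a * rng.lognormal(mean=-sigma**2 / 2.0, sigma=sigma, size=a.size)
    return RotemTrace(condition, t, a)


def closed_form_amplitude(
    params: PhenotypeParams, condition: str, t_s: float
) -> float:
    """Noise-free model amplitude at time ``t_s`` (the simulator's ground truth)."""
    m_eff = plateau_mm(params, condition)
    if t_s <= params.lag_s:
        return 0.0
    return m_eff * (1.0 - float(np.exp(-(t_s - params.lag_s) / params.tau_s)))


def ground_truth_ct_s(
    params: PhenotypeParams, condition: str = "extem", threshold_mm: float = 2.0
) -> Optional[float]:
    """Exact time the noise-free model amplitude reaches ``threshold_mm``.

    ``lag_s + tau_s * ln(M_eff / (M_eff - threshold))``; ``None`` when the
    plateau never reaches the threshold. This, not ``lag_s`` itself, is the
    clotting time the model generates: the exponential leaves the onset lag
    at zero amplitude and needs a finite rise time to cross any threshold.
    """
    m_eff = plateau_mm(params, condition)
    if m_eff <= threshold_mm:
        return None
    return params.lag_s + params.tau_s * float(np.log(m_eff / (m_eff - threshold_mm)))


# ---------------------------------------------------------------------------
# class-conditional laboratory draws

PHENOTYPE_CLASSES = (
    "control",
    "type1",
    "mild_type1",
    "type2a",
    "type3",
    "possible",
    "hemophilia_mild",
)

#: Uniform draw ranges per phenotype class, consistent with the 50/30/3%
#: classification thresholds so that classify_vwd recovers the class.
#: VWF values in percent of normal; fviii percent; aptt seconds.
CLASS_LAB_RANGES: Dict[str, Dict[str, Tuple[float, float]]] = {
    "control": {"vwf": (60.0, 150.0), "fviii": (60.0, 150.0), "aptt": (25.0, 36.0)},
    "type1": {"vwf": (8.0, 29.0), "fviii": (30.0, 80.0), "aptt": (28.0, 40.0)},
    "mild_type1": {"vwf": (31.0, 49.0), "fviii": (50.0, 120.0), "aptt": (26.0, 38.0)},
    "type2a": {"vwf_ag": (20.0, 60.0), "vwf_act": (5.0, 25.0),
               "fviii": (30.0, 90.0), "aptt": (28.0, 40.0)},
    "type3": {"vwf_ag": (0.3, 2.9), "vwf_act": (0.0, 5.0),
              "fviii": (1.0, 10.0), "aptt": (50.0, 80.0)},
    "possible": {"low": (36.0, 49.0), "normal": (55.0, 120.0),
                 "fviii": (55.0, 130.0), "aptt": (25.0, 36.0)},
    "hemophilia_mild": {"vwf": (60.0, 140.0), "fviii": (5.0, 40.0), "aptt": (40.0, 60.0)},
}


def _draw_labs(phenotype_class: str, rng: np.random.Generator) -> LabPanel:
    r = CLASS_LAB_RANGES[phenotype_class]
    u = rng.uniform

    def tri(lo: float, hi: float) -> Tuple[float, float, float]:
        return (u(lo, hi), u(lo, hi), u(lo, hi))

    bleeding = False
    multimer: Optional[bool] = False
    if phenotype_class in ("control", "hemophilia_mild"):
        ag, rco, cb = tri(*r["vwf"])
    elif phenotype_class in ("type1", "mild_type1"):
        ag, rco, cb = tri(*r["vwf"])
        if phenotype_class == "type1":
            bleeding = bool(rng.uniform() < 0.2)  # one of nine in a typical cohort
    elif phenotype_class == "type2a":
        # qualitative defect: activity (RCo, CB) disproportionately low vs antigen
        ag = u(*r["vwf_ag"])
        rco, cb = u(*r["vwf_act"]), u(*r["vwf_act"])
        multimer = True  # loss of large multimers on the gel
    elif phenotype_class == "type3":
        ag = u(*r["vwf_ag"])
        rco, cb = u(*r["vwf_act"]), u(*r["vwf_act"])
        bleeding = True
        multimer = None  # gel uninformative without antigen
    elif phenotype_class == "possible":
        # exactly one marker mildly reduced, the rest clearly normal
        vals = [u(*r["normal"]), u(*r["normal"]), u(*r["normal"])]
        vals[int(rng.integers(3))] = u(*r["low"])
        ag, rco, cb = vals
    else:
        raise InvalidParameterError(
            f"unknown phenotype class {phenotype_class!r}; "
            f"expected one of {PHENOTYPE_CLASSES}"
        )
    return LabPanel(
        vwf_ag_pct=round(float(ag), 1),
        vwf_rco_pct=round(float(rco), 1),
        vwf_cb_pct=round(float(cb), 1),
        fviii_pct=round(float(u(*r["fviii"])), 1),
        pt_pct=round(float(u(80.0, 120.0)), 1),
        aptt_s=round(float(u(*r["aptt"])), 1),
        fibrinogen_gL=round(float(u(1.8, 3.8)), 2),
        platelets_per_nL=round(float(u(150.0, 420.0)), 0),
        bleeding_history=bleeding,
        multimer_abnormal=multimer,
    )


def simulate_patient(
    phenotype_class: str,
    seed: int,
    patient_id: Optional[str] = None,
    base_params: Optional[PhenotypeParams] = None,
    with_traces: bool = True,
    duration_min: float = 35.0,
    dt_s: float = 1.0,
) -> PatientRecord:
    """Simulate one patient: labs, the three assay traces and derived scores.

    The trace generator's VWF activity is set from the drawn VWF:RCo, so the
    laboratory panel and the viscoelastic response are mechanistically
    coupled. Deterministic for a given seed.
    """
    if phenotype_class not in PHENOTYPE_CLASSES:
        raise InvalidParameterError(
            f"unknown phenotype class {phenotype_class!r}; "
            f"expected one of {PHENOTYPE_CLASSES}"
        )
    rng = np.random.default_rng(seed)
    sex = "F" if rng.uniform() < 16 / 27 else "M"
    age_y = round(float(rng.uniform(0.25, 62.0)), 1)
    abo = str(rng.choice(["A", "B", "O", "AB", "n/a"], p=[0.40, 0.11, 0.37, 0.05, 0.07]))
    lab = _draw_labs(phenotype_class, rng)
    params = dataclasses.replace(
        base_params or PhenotypeParams(), vwf_activity_pct=lab.vwf_rco_pct
    )
    record = PatientRecord(
        patient_id=patient_id or f"S{seed}",
        lab=lab,
        phenotype_class=phenotype_class,
        ground_truth=params,
        sex=sex,
        age_y=age_y,
        abo=abo,
    )
    if with_traces:
        traces = {
            cond: simulate_trace(
                params, cond, duration_min, dt_s,
                seed=int(rng.integers(_SEED_MOD)),
            )
            for cond in CONDITIONS
        }
        record.traces = traces
        record.panel = RicotemPanel(
            auc_extem=auc30(traces["extem"]),
            auc_rico=auc30(traces["rico"]),
            auc_rico_haemate=auc30(traces["rico_haemate"]),
            patient_id=record.patient_id,
        )
    record.classify()
    return record


@dataclass(frozen=True)
class CohortSpec:
    """Phenotype-class composition and seed of a simulated cohort.

    The defaults reproduce a 27-patient referral cohort: 7 controls, 9 VWD
    Type 1, 6 Type 2A, 2 Type 3, 2 possible VWD and 1 mild hemophilia.
    """

    controls: int = 7
    type1: int = 9
    mild_type1: int = 0
    type2a: int = 6
    type3: int = 2
    possible: int = 2
    hemophilia_mild: int = 1
    seed: int = 42
    base_params: PhenotypeParams = field(default_factory=PhenotypeParams)

    def __post_init__(self) -> None:
        for name in ("controls", "type1", "mild_type1", "type2a",
                     "type3", "possible", "hemophilia_mild"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} count must be >= 0")
        if self.total < 1:
            raise InvalidParameterError("cohort must contain at least one patient")

    @property
    def counts(self) -> Dict[str, int]:
        return {
            "control": self.controls,
            "type1": self.type1,
            "mild_type1": self.mild_type1,
            "type2a": self.type2a,
            "type3": self.type3,
            "possible": self.possible,
            "hemophilia_mild": self.hemophilia_mild,
        }

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @classmethod
    def from_dict(cls, d: Dict) -> "CohortSpec":
        d = dict(d)
        params = d.pop("base_params", None)
        known = {f.name for f in dataclasses.fields(cls)} - {"base_params"}
        unknown = set(d) - known
        if unknown:
            raise InvalidParameterError(
                f"unknown cohort-spec keys: {sorted(unknown)}; known: {sorted(known)}"
            )
        if params is not None:
            d["base_params"] = PhenotypeParams(**params)
        return cls(**d)


def simulate_cohort(
    spec: CohortSpec = CohortSpec(),
    with_traces: bool = True,
    duration_min: float = 35.0,
    dt_s: float = 1.0,
) -> List[PatientRecord]:
    """Simulate a full cohort; byte-reproducible for a fixed spec and seed.

    Per-patient seeds are derived from the spec seed by a fixed offset.
    """
    records: List[PatientRecord] = []
    index = 0
    for cls_name, n in spec.counts.items():
        for _ in range(n):
            index += 1
            patient_seed = (spec.seed * 1000 + index) % _SEED_MOD
            records.append(
                simulate_patient(
                    cls_name,
                    seed=patient_seed,
                    patient_id=f"P{index:02d}",
                    base_params=spec.base_params,
                    with_traces=with_traces,
                    duration_min=duration_min,
                    dt_s=dt_s,
                )
            )
    return records
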