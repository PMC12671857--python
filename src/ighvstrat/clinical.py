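"""Clinical instruments for SLE cohort analysis.

Implements the scoring and classification rules the stratification
analysis depends on:

* SLEDAI-2K — weighted sum over 24 clinical/laboratory descriptors
  (weights 8/4/2/1, maximum 105);
* LLDAS — lupus low disease activity state (SLEDAI-2K <= 4 without major
  organ activity, PGA <= 1, prednisolone <= 7.5 mg/day, standard
  maintenance therapy only);
* SELENA-SLEDAI flare index — classifies visit-to-visit change as
  none / mild-moderate / severe;
* low-complement flag — C3 or C4 below the institutional reference range;
* cohort exclusion rules — cyclophosphamide or rituximab within the past
  year, or prednisolone >= 21 mg/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Mapping, Sequence

from .errors import MissingDataError

__all__ = [
    "SLEDAI_2K_WEIGHTS",
    "PatientClinical",
    "FlareCategory",
    "FlareSnapshot",
    "FlareIndexConfig",
    "ComplementReferenceRange",
    "score_sledai2k",
    "assess_lldas",
    "classify_flare",
    "flag_low_complement",
    "apply_exclusions",
]

#: SLEDAI-2K descriptor weights. 8: CNS and vasculitis descriptors;
#: 4: musculoskeletal and renal; 2: mucocutaneous, serositis and serology;
#: 1: constitutional and haematological. Sum over all 24 items = 105.
SLEDAI_2K_WEIGHTS: Mapping[str, int] = {
    "seizure": 8,
    "psychosis": 8,
    "organic_brain_syndrome": 8,
    "visual_disturbance": 8,
    "cranial_nerve_disorder": 8,
    "lupus_headache": 8,
    "cva": 8,
    "vasculitis": 8,
    "arthritis": 4,
    "myositis": 4,
    "urinary_casts": 4,
    "haematuria": 4,
    "proteinuria": 4,
    "pyuria": 4,
    "rash": 2,
    "alopecia": 2,
    "mucosal_ulcers": 2,
    "pleurisy": 2,
    "pericarditis": 2,
    "low_complement": 2,
    "increased_dna_binding": 2,
    "fever": 1,
    "thrombocytopenia": 1,
    "leukopenia": 1,
}

#: Descriptors counted as major-organ activity for LLDAS (renal, CNS,
#: cardiopulmonary/serositis, vasculitis, fever).
LLDAS_MAJOR_ORGAN_ITEMS: frozenset[str] = frozenset(
    {
        "urinary_casts",
        "haematuria",
        "proteinuria",
        "pyuria",
        "seizure",
        "psychosis",
        "organic_brain_syndrome",
        "visual_disturbance",
        "cranial_nerve_disorder",
        "lupus_headache",
        "cva",
        "pleurisy",
        "pericarditis",
        "vasculitis",
        "fever",
    }
)

#: Maintenance immunosuppressants compatible with LLDAS.
STANDARD_MAINTENANCE_DRUGS: frozenset[str] = frozenset(
    {"tacrolimus", "ciclosporin", "mmf", "aza", "mtx", "hcq", "belimumab"}
)


class FlareCategory(IntEnum):
    """Flare severity, ordered NONE < MILD_MODERATE < SEVERE."""

    NONE = 0
    MILD_MODERATE = 1
    SEVERE = 2


@dataclass
class PatientClinical:
    """One patient's baseline clinical record.

    ``labs`` holds named numeric values (c3 and c4 in mg/dl, anti_dsdna in
    IU/ml, esr in mm, igg in mg/dl, albumin and haemoglobin in g/dl, ...).
    ``sledai_items`` maps SLEDAI-2K descriptor names to booleans.
    ``medications`` maps drug names to a dose (prednisolone, mg/day) or
    boolean flag; the keys ``cyc_within_1y`` and ``rituximab_within_1y``
    drive the exclusion rules. ``followup`` is a list of
    (days since baseline, FlareCategory) observations.
    """

    patient_id: str
    age: float | None = None
    sex: str | None = None
    disease_duration: float | None = None
    labs: dict[str, float] = field(default_factory=dict)
    sledai_items: dict[str, bool] | None = None
    pga: float | None = None
    medications: dict[str, object] = field(default_factory=dict)
    followup: list[tuple[float, FlareCategory]] = field(default_factory=list)
    weight_kg: float | None = None
    haemolytic_anaemia: bool = False
    gi_activity: bool = False

    @property
    def sledai_score(self) -> int:
        if self.sledai_items is None:
            raise MissingDataError(f"{self.patient_id}: SLEDAI items missing")
        return score_sledai2k(self.sledai_items)

    @property
    def prednisolone_mg(self) -> float | None:
        v = self.medications.get("prednisolone")
        return None if v is None else float(v)


def score_sledai2k(items: Mapping[str, bool]) -> int:
    """SLEDAI-2K total: sum of weights of the descriptors marked present."""
    score = 0
    for key, present in items.items():
        if key not in SLEDAI_2K_WEIGHTS:
            raise ValueError(f"unknown SLEDAI-2K descriptor: {key!r}")
        if present:
            score += SLEDAI_2K_WEIGHTS[key]
    return score


def assess_lldas(record: PatientClinical) -> bool:
    """Lupus low disease activity state.

    True iff SLEDAI-2K <= 4 with no major-organ activity (renal, CNS,
    cardiopulmonary, vasculitis, fever), no haemolytic anaemia or
    gastrointestinal activity, PGA <= 1, prednisolone <= 7.5 mg/day, and
    no non-maintenance immunosuppression (cyclophosphamide or rituximab
    within the past year). Missing required fields raise
    :class:`MissingDataError` rather than returning False silently.
    """
    if record.sledai_items is None:
        raise MissingDataError(f"{record.patient_id}: SLEDAI items required for LLDAS")
    if record.pga is None:
        raise MissingDataError(f"{record.patient_id}: PGA required for LLDAS")
    pred = record.prednisolone_mg
    if pred is None:
        raise MissingDataError(
            f"{record.patient_id}: prednisolone dose required for LLDAS"
        )
    if score_sledai2k(record.sledai_items) > 4:
        return False
    if any(record.sledai_items.get(item, False) for item in LLDAS_MAJOR_ORGAN_ITEMS):
        return False
    if record.haemolytic_anaemia or record.gi_activity:
        return False
    if record.pga > 1:
        return False
    if pred > 7.5:
        return False
    if record.medications.get("cyc_within_1y") or record.medications.get(
        "rituximab_within_1y"
    ):
        return False
    return True


@dataclass(frozen=True)
class FlareSnapshot:
    """Disease state at one visit, the unit the flare index compares."""

    sledai: int
    pga: float
    prednisolone_mg: float
    weight_kg: float | None = None
    items: Mapping[str, bool] | None = None
    new_immunosuppressant: bool = False
    hospitalized_for_sle: bool = False


@dataclass(frozen=True)
class FlareIndexConfig:
    """Tunable thresholds of the SELENA-SLEDAI flare index.

    ``prednisolone_severe_mg_per_kg`` is the dose-increase trigger for a
    severe flare; when body weight is unknown the absolute fallback dose
    is used instead (and should be reported by the caller).
    """

    prednisolone_severe_mg_per_kg: float = 0.5
    prednisolone_severe_fallback_mg: float = 30.0
    major_items: frozenset[str] = frozenset(
        {
            "seizure",
            "psychosis",
            "organic_brain_syndrome",
            "cva",
            "cranial_nerve_disorder",
            "vasculitis",
            "myositis",
            "urinary_casts",
            "haematuria",
            "proteinuria",
        }
    )


DEFAULT_FLARE_CONFIG = FlareIndexConfig()


def _severe_pred_threshold(snap: FlareSnapshot, config: FlareIndexConfig) -> float:
    if snap.weight_kg is not None:
        return config.prednisolone_severe_mg_per_kg * snap.weight_kg
    return config.prednisolone_severe_fallback_mg


def classify_flare(
    prev: FlareSnapshot,
    curr: FlareSnapshot,
    config: FlareIndexConfig = DEFAULT_FLARE_CONFIG,
) -> FlareCategory:
    """SELENA-SLEDAI flare classification of the change prev -> curr.

    Severe: SLEDAI increase > 12, a newly active major-organ descriptor,
    prednisolone increased beyond 0.5 mg/kg (absolute fallback when weight
    is unknown), a new immunosuppressant or SLE hospitalisation, or
    PGA > 2.5.

    Mild/moderate: SLEDAI increase of 3-12, a newly active non-major
    descriptor, any smaller prednisolone increase, or a PGA increase >= 1
    with PGA staying <= 2.5.
    """
    for name, snap in (("prev", prev), ("curr", curr)):
        if snap.sledai is None or snap.pga is None or snap.prednisolone_mg is None:
            raise MissingDataError(f"flare snapshot {name} incomplete")
    delta = curr.sledai - prev.sledai
    new_items: set[str] = set()
    if prev.items is not None and curr.items is not None:
        new_items = {
            k for k, v in curr.items.items() if v and not prev.items.get(k, False)
        }
    pred_increase = curr.prednisolone_mg > prev.prednisolone_mg

    severe = (
        delta > 12
        or bool(new_items & config.major_items)
        or (pred_increase and curr.prednisolone_mg > _severe_pred_threshold(curr, config))
        or curr.new_immunosuppressant
        or curr.hospitalized_for_sle
        or curr.pga > 2.5
    )
    if severe:
        return FlareCategory.SEVERE

    mild = (
        3 <= delta <= 12
        or bool(new_items - config.major_items)
        or pred_increase
        or (curr.pga - prev.pga >= 1 and curr.pga <= 2.5)
    )
    if mild:
        return FlareCategory.MILD_MODERATE
    return FlareCategory.NONE


@dataclass(frozen=True)
class ComplementReferenceRange:
    """Institutional lower reference limits for complement, mg/dl."""

    c3_low: float = 73.0
    c4_low: float = 11.0


DEFAULT_COMPLEMENT_REFS = ComplementReferenceRange()


def _absent(v: float | None) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def flag_low_complement(
    c3: float | None,
    c4: float | None,
    refs: ComplementReferenceRange = DEFAULT_COMPLEMENT_REFS,
) -> bool:
    """True iff C3 or C4 lies strictly below its lower reference limit.

    A value exactly at the limit is not low. With both analytes absent the
    flag is undefined and raises :class:`MissingDataError`.
    """
    if _absent(c3) and _absent(c4):
        raise MissingDataError("low-complement flag needs C3 or C4")
    low = False
    if not _absent(c3):
        low = low or c3 < refs.c3_low
    if not _absent(c4):
        low = low or c4 < refs.c4_low
    return low


PREDNISOLONE_EXCLUSION_MG = 21.0


def apply_exclusions(
    cohort: Iterable[PatientClinical],
) -> tuple[list[PatientClinical], list[dict[str, str]]]:
    """Apply the cohort exclusion rules.

    Excluded: cyclophosphamide or rituximab within the past year, or
    prednisolone >= 21 mg/day (inclusive). Missing medication data never
    excludes; it is noted in the log.
    """
    kept: list[PatientClinical] = []
    log: list[dict[str, str]] = []
    for rec in cohort:
        rule = None
        if rec.medications.get("cyc_within_1y"):
            rule = "cyclophosphamide within 1 year"
        elif rec.medications.get("rituximab_within_1y"):
            rule = "rituximab within 1 year"
        else:
            pred = rec.prednisolone_mg
            if pred is None:
                log.append(
                    {"patient_id": rec.patient_id, "rule": "missing prednisolone dose; retained"}
                )
            elif pred >= PREDNISOLONE_EXCLUSION_MG:
                rule = f"prednisolone >= {PREDNISOLONE_EXCLUSION_MG:g} mg/day"
        if rule is None:
            kept.append(rec)
        else:
            log.append({"patient_id": rec.patient_id, "rule": rule})
    return kept, log
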