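import numpy as np
import pytest

from ighvstrat.clinical import FlareCategory, PatientClinical
from ighvstrat.repertoire import BCellSubset, ClonotypeRecord, RepertoireSample
from ighvstrat.simulate import SimConfig, simulate_cohort


def make_sample(patient_id, subset, gene_cdr3_pairs, counts=None):
    counts = counts or [1] * len(gene_cdr3_pairs)
    records = tuple(
        ClonotypeRecord(v_gene=g, cdr3_nt=nt, count=c)
        for (g, nt), c in zip(gene_cdr3_pairs, counts)
    )
    return RepertoireSample(patient_id=patient_id, subset=subset, clonotypes=records)


@pytest.fixture
def small_sample():
    return make_sample(
        "P1",
        BCellSubset.USM,
        [
            ("IGHV4-34", "TGTGCGAAA"),
            ("IGHV4-34", "TGTGCGCCC"),
            ("IGHV1-2", "TGTGCGGGG"),
            ("IGHV3-23", "TGTGCGTTT"),
        ],
    )


def make_patient(
    pid="P1",
    items=None,
    pga=0.0,
    prednisolone=5.0,
    meds=None,
    followup=None,
    labs=None,
    **kw,
):
    medications = {"prednisolone": prednisolone, "hcq": True}
    medications.update(meds or {})
    return PatientClinical(
        patient_id=pid,
        labs=labs or {"c3": 90.0, "c4": 15.0},
        sledai_items=items or {},
        pga=pga,
        medications=medications,
        followup=followup if followup is not None else [(730.0, FlareCategory.NONE)],
        **kw,
    )


@pytest.fixture(scope="session")
def sim_cohort():
    """Mid-size synthetic cohort with the default (coupled) effects."""
    return simulate_cohort(SimConfig(n_patients=80), seed=7)
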