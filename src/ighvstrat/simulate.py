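"""Synthetic SLE repertoire + clinical cohort generator.

Emulates the structure of a five-subset sorted B-cell RNA-seq cohort: per
patient and subset a clonotype table with V-gene calls and CDR3
sequences, and a linked clinical record (complement, anti-dsDNA, SLEDAI-2K
items, PGA, medications, flare follow-up).

A single standard-normal latent *disease activity* score per patient
drives every association the analysis looks for: it shifts the logit of
the IGHV4-34 frequency in USM B cells, depresses C3/C4, raises
anti-dsDNA, raises SLEDAI item probabilities and PGA, and scales the
flare hazard. Sample-to-sample overdispersion of gene frequencies follows
a Dirichlet-multinomial: the focal-gene clonotype count is drawn from its
Beta-binomial marginal, and a full clonotype table (with CDR3 strings) is
realised lazily, conditioned on that count, only when the table itself is
needed. The fast usage matrix and the written fixture files therefore
agree exactly.

All randomness flows from one seed through numpy SeedSequence spawn keys,
so any single sample is reproducible in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .clinical import (
    DEFAULT_COMPLEMENT_REFS,
    ComplementReferenceRange,
    FlareCategory,
    PatientClinical,
    SLEDAI_2K_WEIGHTS,
    flag_low_complement,
    score_sledai2k,
)
from .repertoire import BCellSubset, ClonotypeRecord, RepertoireSample, write_clonotype_table

__all__ = ["SimConfig", "SimulatedCohort", "simulate_cohort"]

# Germline-plausible IGHV panel with rough relative usage weights. The
# IGHV4-34 weight is replaced per subset by the configured baseline.
DEFAULT_GENE_PANEL: dict[str, float] = {
    "IGHV1-2": 4.0, "IGHV1-3": 1.5, "IGHV1-8": 1.5, "IGHV1-18": 3.0,
    "IGHV1-46": 2.0, "IGHV1-69": 3.5, "IGHV2-5": 1.5, "IGHV3-7": 3.5,
    "IGHV3-9": 2.0, "IGHV3-11": 1.5, "IGHV3-15": 2.5, "IGHV3-21": 3.0,
    "IGHV3-23": 7.0, "IGHV3-30": 5.0, "IGHV3-33": 3.0, "IGHV3-48": 3.0,
    "IGHV3-53": 2.0, "IGHV3-74": 2.0, "IGHV4-4": 1.5, "IGHV4-31": 2.0,
    "IGHV4-34": 5.0, "IGHV4-39": 3.5, "IGHV4-59": 4.0, "IGHV4-61": 1.5,
    "IGHV5-51": 3.0, "IGHV6-1": 1.5,
}

#: Baseline (population-average) prevalence of each SLEDAI-2K descriptor in
#: an SLE maintenance cohort; low_complement and increased_dna_binding are
#: derived from the simulated labs instead of these Bernoulli draws.
DEFAULT_ITEM_PREVALENCE: dict[str, float] = {
    "seizure": 0.002, "psychosis": 0.002, "organic_brain_syndrome": 0.005,
    "visual_disturbance": 0.02, "cranial_nerve_disorder": 0.005,
    "lupus_headache": 0.01, "cva": 0.002, "vasculitis": 0.005,
    "arthritis": 0.18, "myositis": 0.01, "urinary_casts": 0.08,
    "haematuria": 0.12, "proteinuria": 0.15, "pyuria": 0.04,
    "rash": 0.20, "alopecia": 0.14, "mucosal_ulcers": 0.05,
    "pleurisy": 0.03, "pericarditis": 0.015, "fever": 0.12,
    "thrombocytopenia": 0.05, "leukopenia": 0.08,
}

DEFAULT_MED_PREVALENCE: dict[str, float] = {
    "tacrolimus": 0.20, "ciclosporin": 0.09, "mmf": 0.22, "aza": 0.085,
    "mtx": 0.015, "hcq": 0.45, "cyc_within_1y": 0.02, "rituximab_within_1y": 0.015,
}


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _logit(p):
    return np.log(p / (1.0 - p))


@dataclass
class SimConfig:
    """Study conditions of the simulated cohort.

    Defaults encode the cohort the analysis targets: 129 patients, five
    B-cell subsets, baseline IGHV4-34 usage of 7.4% in naive and 6.6% in
    USM B cells with the other subsets lower, and a latent-activity
    coupling that reproduces the qualitative usage-complement-activity-
    flare associations. Setting every ``effect_*``/slope parameter to 0
    yields a fully null cohort for calibration experiments.
    """

    n_patients: int = 129
    seed: int = 0

    gene_panel: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_GENE_PANEL))
    baseline_usage: dict[str, float] = field(
        default_factory=lambda: {"NAIVE": 0.074, "USM": 0.066, "SM": 0.035,
                                 "DN": 0.040, "PB": 0.030}
    )
    #: logit-scale shift of the focal-gene frequency per SD of latent activity
    effect_usage_on_activity: float = 0.35
    effect_subsets: tuple[str, ...] = ("USM",)
    #: Dirichlet concentration: sample-level overdispersion of gene frequencies
    dirichlet_concentration: float = 150.0
    clonotypes_mean: float = 400.0
    clonotypes_dispersion: float = 5.0  # negative-binomial shape parameter
    clonotypes_min: int = 50

    # clinical links (value = intercept + slope * activity + noise)
    c3_mean: float = 82.0
    c3_sd: float = 14.0
    c3_activity_slope: float = -12.0
    c4_mean: float = 15.0
    c4_sd: float = 4.5
    c4_activity_slope: float = -4.0
    dsdna_log_median: float = np.log(6.0)  # IU/ml
    dsdna_log_sd: float = 1.1
    dsdna_activity_slope: float = 0.9  # on the log scale
    dsdna_positive_iu: float = 12.0
    esr_mean: float = 20.0
    esr_sd: float = 10.0
    esr_activity_slope: float = 8.0
    igg_mean: float = 1450.0
    igg_sd: float = 350.0
    igg_activity_slope: float = 180.0
    albumin_mean: float = 3.9
    albumin_sd: float = 0.35
    albumin_activity_slope: float = -0.15
    haemoglobin_mean: float = 12.3
    haemoglobin_sd: float = 1.3
    haemoglobin_activity_slope: float = -0.4

    item_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ITEM_PREVALENCE)
    )
    item_activity_slope: float = 0.9  # logit scale, shared across items
    pga_intercept: float = 0.8
    pga_activity_slope: float = 0.45
    pga_sd: float = 0.35
    med_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MED_PREVALENCE)
    )
    prednisolone_log_median: float = np.log(5.0)
    prednisolone_log_sd: float = 0.5

    flare_base_rate_per_year: float = 0.35
    flare_activity_loghr: float = 0.5
    flare_hazard_ratio_high: float = 2.5
    flare_group_threshold: float = 0.059  # usage defining the high-hazard group
    flare_severe_fraction: float = 0.2
    followup_days: float = 730.0

    complement_refs: ComplementReferenceRange = field(
        default_factory=lambda: DEFAULT_COMPLEMENT_REFS
    )

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if any(w <= 0 or not np.isfinite(w) for w in self.gene_panel.values()):
            raise ValueError("gene-panel weights must be positive and finite")
        for subset, p in self.baseline_usage.items():
            BCellSubset(subset)
            if not 0 < p < 1:
                raise ValueError(f"baseline usage for {subset} must lie in (0,1)")
        if self.dirichlet_concentration <= 0:
            raise ValueError("dirichlet_concentration must be > 0")
        if self.clonotypes_min < 1 or self.clonotypes_mean < self.clonotypes_min:
            raise ValueError("invalid clonotype count distribution")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be > 0")
        for name, p in {**self.item_prevalence, **self.med_prevalence}.items():
            if not 0 <= p <= 1:
                raise ValueError(f"prevalence for {name} must lie in [0,1]")
        unknown = set(self.item_prevalence) - set(SLEDAI_2K_WEIGHTS)
        if unknown:
            raise ValueError(f"unknown SLEDAI items in item_prevalence: {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["complement_refs"] = dataclasses.asdict(self.complement_refs)
        d["effect_subsets"] = list(self.effect_subsets)
        return d


# spawn-key namespaces for the per-purpose random streams
_NS_COHORT = 0
_NS_REPERTOIRE = 1


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


_BASES = np.array(list("ACGT"))
_CODON_STOPS = {"TAA", "TAG", "TGA"}


def _random_cdr3_set(rng: np.random.Generator, n: int) -> list[str]:
    """``n`` distinct in-frame CDR3 nucleotide strings (start TGT = Cys)."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        lengths = rng.integers(9, 22, size=n - len(out))  # codons incl. TGT anchor
        for L in lengths:
            body = "".join(_BASES[rng.integers(0, 4, size=3 * (int(L) - 1))])
            s = "TGT" + body
            codons = {s[i : i + 3] for i in range(0, len(s), 3)}
            if codons & _CODON_STOPS or s in seen:
                continue
            seen.add(s)
            out.append(s)
    return out


class SimulatedCohort:
    """A realised synthetic cohort.

    Attributes
    ----------
    clinical : DataFrame
        One row per patient: demographics, labs, SLEDAI item flags
        (``item_*`` columns), derived SLEDAI-2K score, PGA, medications,
        and flare follow-up (time, event, severity).
    usage : DataFrame
        Long-format usage matrix (patient_id, subset, gene, usage,
        n_clonotypes) for the focal gene, exact for the clonotype tables
        :meth:`repertoire` realises.
    latent : DataFrame
        The ground-truth latent activity per patient.
    """

    def __init__(self, config: SimConfig, clinical: pd.DataFrame,
                 usage: pd.DataFrame, latent: pd.DataFrame,
                 counts: pd.DataFrame):
        self.config = config
        self.clinical = clinical
        self.usage = usage
        self.latent = latent
        self._counts = counts  # per (patient, subset): K total, k focal

    # -- clonotype-table realisation ------------------------------------

    def repertoire(self, patient_id: str, subset: BCellSubset | str) -> RepertoireSample:
        """Realise the full clonotype table for one (patient, subset).

        The IGHV4-34 clonotype count equals the count already drawn for
        the usage matrix; the remaining clonotypes are multinomial over
        the rest of the gene panel with Dirichlet-perturbed weights.
        Deterministic for a given config seed.
        """
        subset = BCellSubset(subset)
        cfg = self.config
        row = self._counts[
            (self._counts.patient_id == patient_id) & (self._counts.subset == subset.value)
        ]
        if row.empty:
            raise KeyError(f"no simulated sample for ({patient_id}, {subset.value})")
        i_pat = int(row.patient_index.iloc[0])
        i_sub = list(BCellSubset).index(subset)
        K, k_focal = int(row.n_clonotypes.iloc[0]), int(row.n_focal.iloc[0])
        rng = _rng(cfg.seed, _NS_REPERTOIRE, i_pat, i_sub)

        genes = [g for g in cfg.gene_panel if g != "IGHV4-34"]
        if not genes:  # degenerate single-gene panel
            k_focal = K
        gene_of_clone = ["IGHV4-34"] * k_focal
        if genes and K > k_focal:
            weights = np.array([cfg.gene_panel[g] for g in genes], dtype=float)
            alpha = cfg.dirichlet_concentration * weights / weights.sum()
            other_counts = rng.multinomial(K - k_focal, rng.dirichlet(alpha))
            for g, c in zip(genes, other_counts):
                gene_of_clone.extend([g] * int(c))
        cdr3s = _random_cdr3_set(rng, K)
        rng.shuffle(gene_of_clone)
        counts = rng.geometric(0.02, size=K)
        records = tuple(
            ClonotypeRecord(v_gene=g, cdr3_nt=s, j_gene="IGHJ4", count=int(c))
            for g, s, c in zip(gene_of_clone, cdr3s, counts)
        )
        return RepertoireSample(patient_id=patient_id, subset=subset, clonotypes=records)

    def repertoires(self) -> Iterable[RepertoireSample]:
        for row in self._counts.itertuples(index=False):
            yield self.repertoire(row.patient_id, row.subset)

    # -- clinical-record objects ----------------------------------------

    def patients(self) -> list[PatientClinical]:
        """Clinical rows as :class:`PatientClinical` objects."""
        out = []
        lab_cols = ["c3", "c4", "anti_dsdna", "esr", "igg", "albumin", "haemoglobin"]
        med_cols = list(self.config.med_prevalence) + ["prednisolone"]
        for row in self.clinical.itertuples(index=False):
            d = row._asdict()
            items = {
                k.removeprefix("item_"): bool(d[k])
                for k in d
                if k.startswith("item_")
            }
            followup = []
            if d["flare_event"]:
                followup.append((d["flare_time_days"], FlareCategory(int(d["flare_severity"]))))
            else:
                followup.append((d["flare_time_days"], FlareCategory.NONE))
            meds = {}
            for k in med_cols:
                meds[k] = float(d[k]) if k == "prednisolone" else bool(d[k])
            out.append(
                PatientClinical(
                    patient_id=d["patient_id"],
                    age=d["age"],
                    sex=d["sex"],
                    disease_duration=d["disease_duration"],
                    labs={k: float(d[k]) for k in lab_cols},
                    sledai_items=items,
                    pga=float(d["pga"]),
                    medications=meds,
                    followup=followup,
                )
            )
        return out

    # -- fixture writing -------------------------------------------------

    def write_fixture_set(self, outdir: str | Path) -> dict:
        """Write AIRR TSVs ({patient}_{subset}.tsv), clinical.csv, truth.json
        and manifest.json. Returns the manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files = []
        for sample in self.repertoires():
            path = outdir / f"{sample.patient_id}_{sample.subset.value}.tsv"
            write_clonotype_table(sample, path)
            files.append(path.name)
        self.clinical.to_csv(outdir / "clinical.csv", index=False)
        truth = {
            "latent_activity": dict(
                zip(self.latent.patient_id, self.latent.activity.round(10))
            ),
            "usage": {
                f"{r.patient_id}/{r.subset}": round(float(r.usage), 10)
                for r in self.usage.itertuples(index=False)
            },
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        cfg = self.config.to_dict()
        manifest = {
            "config": cfg,
            "config_hash": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=float).encode()
            ).hexdigest(),
            "seed": self.config.seed,
            "n_patients": int(self.config.n_patients),
            "repertoire_files": sorted(files),
            "clinical_file": "clinical.csv",
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True, default=float)
        )
        return manifest


def simulate_cohort(config: SimConfig | None = None, seed: int | None = None) -> SimulatedCohort:
    """Draw a full synthetic cohort. Deterministic given (config, seed).

    ``seed`` overrides ``config.seed`` when given.
    """
    config = config or SimConfig()
    if seed is not None:
        config = dataclasses.replace(config, seed=int(seed))
    config.validate()
    n = config.n_patients
    pids = [f"P{i:04d}" for i in range(n)]

    rng = _rng(config.seed, _NS_COHORT)
    activity = rng.standard_normal(n)

    # ---- repertoire usage (fast Beta-binomial path) --------------------
    subsets = list(BCellSubset)
    conc = config.dirichlet_concentration
    usage_rows = []
    count_rows = []
    for j, subset in enumerate(subsets):
        base = config.baseline_usage[subset.value]
        shift = (
            config.effect_usage_on_activity * activity
            if subset.value in config.effect_subsets
            else np.zeros(n)
        )
        mean_p = _sigmoid(_logit(base) + shift)
        p = rng.beta(conc * mean_p, conc * (1.0 - mean_p))
        disp = config.clonotypes_dispersion
        K = rng.negative_binomial(disp, disp / (disp + config.clonotypes_mean), size=n)
        K = np.maximum(K, config.clonotypes_min)
        k_focal = rng.binomial(K, p)
        for i in range(n):
            usage_rows.append(
                {
                    "patient_id": pids[i],
                    "subset": subset.value,
                    "gene": "IGHV4-34",
                    "usage": k_focal[i] / K[i],
                    "n_clonotypes": int(K[i]),
                }
            )
            count_rows.append(
                {
                    "patient_id": pids[i],
                    "patient_index": i,
                    "subset": subset.value,
                    "n_clonotypes": int(K[i]),
                    "n_focal": int(k_focal[i]),
                }
            )
    usage = pd.DataFrame(usage_rows)
    counts = pd.DataFrame(count_rows)

    # ---- clinical record ----------------------------------------------
    act = activity
    c3 = config.c3_mean + config.c3_activity_slope * act + rng.normal(0, config.c3_sd, n)
    c4 = config.c4_mean + config.c4_activity_slope * act + rng.normal(0, config.c4_sd, n)
    c3 = np.maximum(c3, 5.0)
    c4 = np.maximum(c4, 0.5)
    dsdna = np.exp(
        config.dsdna_log_median
        + config.dsdna_activity_slope * act
        + rng.normal(0, config.dsdna_log_sd, n)
    )
    esr = np.maximum(
        config.esr_mean + config.esr_activity_slope * act + rng.normal(0, config.esr_sd, n),
        1.0,
    )
    igg = np.maximum(
        config.igg_mean + config.igg_activity_slope * act + rng.normal(0, config.igg_sd, n),
        300.0,
    )
    albumin = np.clip(
        config.albumin_mean + config.albumin_activity_slope * act
        + rng.normal(0, config.albumin_sd, n),
        1.5, 5.5,
    )
    hb = np.clip(
        config.haemoglobin_mean + config.haemoglobin_activity_slope * act
        + rng.normal(0, config.haemoglobin_sd, n),
        6.0, 18.0,
    )

    items: dict[str, np.ndarray] = {}
    for name, prev in config.item_prevalence.items():
        logits = _logit(np.clip(prev, 1e-6, 1 - 1e-6)) + config.item_activity_slope * act
        items[name] = rng.random(n) < _sigmoid(logits)
    items["low_complement"] = np.array(
        [flag_low_complement(a, b, config.complement_refs) for a, b in zip(c3, c4)]
    )
    items["increased_dna_binding"] = dsdna > config.dsdna_positive_iu

    pga = np.clip(
        config.pga_intercept + config.pga_activity_slope * act + rng.normal(0, config.pga_sd, n),
        0.0, 3.0,
    )

    meds = {
        name: rng.random(n) < prev for name, prev in config.med_prevalence.items()
    }
    prednisolone = np.round(
        np.exp(config.prednisolone_log_median + rng.normal(0, config.prednisolone_log_sd, n)),
        1,
    )

    # flare follow-up: exponential first-flare time under a proportional
    # hazard in activity and in high USM usage, censored administratively
    usm_usage = usage.loc[usage.subset == "USM", "usage"].to_numpy()
    high = usm_usage >= config.flare_group_threshold
    rate_day = (
        config.flare_base_rate_per_year / 365.0
        * np.exp(config.flare_activity_loghr * act)
        * np.where(high, config.flare_hazard_ratio_high, 1.0)
    )
    raw_t = rng.exponential(1.0 / np.maximum(rate_day, 1e-12))
    event = raw_t <= config.followup_days
    t_obs = np.where(event, np.maximum(raw_t, 1.0), config.followup_days)
    severe = rng.random(n) < config.flare_severe_fraction
    severity = np.where(
        event,
        np.where(severe, int(FlareCategory.SEVERE), int(FlareCategory.MILD_MODERATE)),
        int(FlareCategory.NONE),
    )

    clinical = pd.DataFrame(
        {
            "patient_id": pids,
            "age": np.round(np.clip(rng.normal(45, 13, n), 18, 85), 0),
            "sex": np.where(rng.random(n) < 0.08, "M", "F"),
            "disease_duration": np.round(rng.gamma(2.0, 6.0, n), 1),
            "c3": np.round(c3, 1),
            "c4": np.round(c4, 1),
            "anti_dsdna": np.round(dsdna, 2),
            "esr": np.round(esr, 0),
            "igg": np.round(igg, 0),
            "albumin": np.round(albumin, 2),
            "haemoglobin": np.round(hb, 1),
            **{f"item_{k}": v for k, v in items.items()},
            "pga": np.round(pga, 2),
            "prednisolone": prednisolone,
            **meds,
            "flare_time_days": np.round(t_obs, 1),
            "flare_event": event,
            "flare_severity": severity,
        }
    )
    clinical["sledai_2k"] = [
        score_sledai2k({k: bool(clinical.at[i, f"item_{k}"]) for k in SLEDAI_2K_WEIGHTS})
        for i in range(n)
    ]
    latent = pd.DataFrame({"patient_id": pids, "activity": activity})
    return SimulatedCohort(config, clinical, usage, latent, counts)
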