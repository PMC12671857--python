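"""Model/results interface for the usage-based stratification analysis.

:class:`UsageStratification` is built from a per-sample usage matrix and a
patient clinical table; :meth:`~UsageStratification.fit` runs the ROC
analysis of USM IGHV4-34 usage against the low-complement label, selects
the closest-to-corner cutoff (or applies a preset one) and assigns
patients to HIGH/LOW usage groups. The returned
:class:`UsageStratificationResults` carries the curve, the operating
point and the assignments, and exposes the downstream batteries — the
Table-1/Table-2 style group comparison, the scaled joint regression of a
clinical outcome on all five subset usages, pairwise subset comparisons,
and the flare-free survival contrast among LLDAS achievers on a given
maintenance drug.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .association import (
    ComparisonVariable,
    group_comparison_table,
    scaled_regression,
    spearman,
)
from .clinical import (
    DEFAULT_COMPLEMENT_REFS,
    ComplementReferenceRange,
    PatientClinical,
    apply_exclusions,
    flag_low_complement,
)
from .errors import MissingDataError
from .repertoire import BCellSubset, RepertoireSample, read_clonotype_table
from .stratify import assign_groups, fit_roc
from .survival import build_survival_records, km_estimate, logrank
from .usage import compare_subsets, usage_matrix

__all__ = ["UsageStratification", "UsageStratificationResults", "DEFAULT_TABLE_VARIABLES"]

#: Default group-comparison battery: the activity-related continuous labs
#: plus every SLEDAI-2K descriptor carried by the clinical table.
DEFAULT_TABLE_VARIABLES: tuple[ComparisonVariable, ...] = tuple(
    [
        ComparisonVariable("age", "continuous"),
        ComparisonVariable("ESR", "continuous", "esr"),
        ComparisonVariable("albumin", "continuous"),
        ComparisonVariable("IgG", "continuous", "igg"),
        ComparisonVariable("C3", "continuous", "c3"),
        ComparisonVariable("C4", "continuous", "c4"),
        ComparisonVariable("anti-dsDNA", "continuous", "anti_dsdna"),
        ComparisonVariable("haemoglobin", "continuous"),
        ComparisonVariable("PGA", "continuous", "pga"),
        ComparisonVariable("SLEDAI-2K", "continuous", "sledai_2k"),
    ]
    + [
        ComparisonVariable(item, "categorical", f"item_{item}")
        for item in (
            "arthritis",
            "haematuria",
            "proteinuria",
            "urinary_casts",
            "rash",
            "fever",
            "low_complement",
            "increased_dna_binding",
        )
    ]
)


class UsageStratification:
    """ROC-cutoff stratification of SLE patients by USM IGHV4-34 usage.

    Parameters
    ----------
    usage : DataFrame
        Long-format usage matrix with columns patient_id, subset, usage
        (as produced by :func:`ighvstrat.usage.usage_matrix` or the
        synthetic generator).
    clinical : DataFrame
        One row per patient; must carry ``patient_id`` plus ``c3``/``c4``
        (mg/dl) for the low-complement label.
    gene, subset
        Scored gene and B-cell subset (defaults IGHV4-34 in USM).
    complement_refs
        Institutional lower reference limits defining "low complement".
    patients
        Optional :class:`PatientClinical` objects (needed for the
        survival analysis, which requires follow-up and LLDAS inputs).
    apply_exclusion_rules
        Drop patients on recent cyclophosphamide/rituximab or >= 21 mg/day
        prednisolone before fitting (requires ``patients``).
    """

    def __init__(
        self,
        usage: pd.DataFrame,
        clinical: pd.DataFrame,
        *,
        gene: str = "IGHV4-34",
        subset: str | BCellSubset = BCellSubset.USM,
        complement_refs: ComplementReferenceRange = DEFAULT_COMPLEMENT_REFS,
        patients: Sequence[PatientClinical] | None = None,
        apply_exclusion_rules: bool = False,
    ):
        self.gene = gene
        self.subset = BCellSubset(subset)
        self.complement_refs = complement_refs
        self.patients = list(patients) if patients is not None else None
        self.exclusion_log: list[dict[str, str]] = []

        clinical = clinical.copy()
        if "patient_id" not in clinical.columns:
            raise MissingDataError("clinical table must carry a patient_id column")
        if apply_exclusion_rules:
            if self.patients is None:
                raise MissingDataError("exclusion rules need PatientClinical records")
            self.patients, self.exclusion_log = apply_exclusions(self.patients)
            keep = {p.patient_id for p in self.patients}
            clinical = clinical[clinical.patient_id.isin(keep)]
        self.clinical = clinical.set_index("patient_id", drop=False)
        self.usage = usage[usage.patient_id.isin(self.clinical.index)].copy()

    # -- constructors ----------------------------------------------------

    @classmethod
    def from_samples(
        cls,
        samples: Iterable[RepertoireSample],
        clinical: pd.DataFrame,
        gene: str = "IGHV4-34",
        **kwargs,
    ) -> "UsageStratification":
        return cls(usage_matrix(samples, gene), clinical, gene=gene, **kwargs)

    @classmethod
    def from_fixture_dir(
        cls, path: str | Path, gene: str = "IGHV4-34", **kwargs
    ) -> "UsageStratification":
        """Build from a fixture tree of AIRR TSVs plus clinical.csv."""
        path = Path(path)
        samples = [
            read_clonotype_table(f, dialect="airr")
            for f in sorted(path.glob("*_*.tsv"))
        ]
        clinical = pd.read_csv(path / "clinical.csv")
        return cls.from_samples(samples, clinical, gene=gene, **kwargs)

    @classmethod
    def from_cohort(cls, cohort, **kwargs) -> "UsageStratification":
        """Build from a :class:`ighvstrat.simulate.SimulatedCohort`."""
        return cls(
            cohort.usage, cohort.clinical, patients=cohort.patients(), **kwargs
        )

    # -- fitting ----------------------------------------------------------

    def _subset_usage(self) -> pd.Series:
        sub = self.usage[self.usage.subset == self.subset.value]
        return pd.Series(sub.usage.to_numpy(), index=sub.patient_id, name="usage")

    def _low_complement_labels(self) -> pd.Series:
        labels = {}
        for pid, row in self.clinical.iterrows():
            c3 = row.get("c3")
            c4 = row.get("c4")
            try:
                labels[pid] = flag_low_complement(c3, c4, self.complement_refs)
            except MissingDataError:
                continue  # no complement data: excluded from ROC fitting
        return pd.Series(labels, dtype=bool)

    def fit(self, cutoff: float | None = None) -> "UsageStratificationResults":
        """Fit the ROC and assign groups.

        With ``cutoff`` given, the ROC is still computed (for the AUC and
        the curve) but the preset value is used for group assignment —
        the mode used to reproduce downstream stages without refitting.
        """
        usages = self._subset_usage()
        labels = self._low_complement_labels()
        common = usages.index.intersection(labels.index)
        roc = fit_roc(usages.loc[common].to_numpy(), labels.loc[common].to_numpy())
        if cutoff is not None:
            idx = int(np.argmin(np.abs(roc.thresholds - cutoff)))
            roc.cutoff = float(cutoff)
            roc.cutoff_sens = float(roc.sens[idx]) if np.isclose(
                roc.thresholds[idx], cutoff
            ) else None
            roc.cutoff_spec = float(roc.spec[idx]) if np.isclose(
                roc.thresholds[idx], cutoff
            ) else None
        all_patients = self.clinical.index
        full = usages.reindex(all_patients)
        groups = assign_groups(full, roc.cutoff)
        return UsageStratificationResults(self, roc, groups, usages, labels)


class UsageStratificationResults:
    """Fitted stratification: curve, cutoff, groups, downstream batteries."""

    def __init__(self, model, roc, groups, usages, labels):
        self.model = model
        self.roc = roc
        self.groups = groups
        self._usages = usages
        self._labels = labels

    # -- headline quantities ---------------------------------------------

    @property
    def cutoff(self) -> float:
        return self.roc.cutoff

    @property
    def auc(self) -> float:
        return self.roc.auc

    @property
    def sensitivity(self) -> float | None:
        return self.roc.cutoff_sens

    @property
    def specificity(self) -> float | None:
        return self.roc.cutoff_spec

    def group_map(self) -> dict[str, str]:
        g = self.groups.dropna(subset=["group"])
        return dict(zip(g.patient_id, g.group))

    @property
    def n_high(self) -> int:
        return int((self.groups.group == "HIGH").sum())

    @property
    def n_low(self) -> int:
        return int((self.groups.group == "LOW").sum())

    @property
    def n_unassigned(self) -> int:
        return int(self.groups.group.isna().sum())

    def summary(self) -> str:
        """Human-readable fit summary."""
        fmt = lambda v: "   n/a" if v is None else f"{100 * v:6.1f}%"
        lines = [
            "Usage stratification" + " " * 24 + "(score >= cutoff -> predicted low complement)",
            "=" * 78,
            f"Gene / subset:        {self.model.gene} / {self.model.subset.value}",
            f"ROC n (pos/neg):      {self.roc.n_pos} low-complement / {self.roc.n_neg} other",
            f"AUC:                  {self.auc:8.3f}",
            f"Cutoff (usage):       {100 * self.cutoff:7.2f}%  (closest-to-corner)"
            if self.roc.youden_cutoff is not None else "",
            f"Sensitivity at cutoff:{fmt(self.sensitivity)}",
            f"Specificity at cutoff:{fmt(self.specificity)}",
            f"Groups:               HIGH {self.n_high} / LOW {self.n_low}"
            f" / unassigned {self.n_unassigned}",
            "=" * 78,
        ]
        return "\n".join(line for line in lines if line)

    # -- downstream analyses ----------------------------------------------

    def compare_groups(
        self,
        variables: Sequence[ComparisonVariable] = DEFAULT_TABLE_VARIABLES,
        m: int | None = None,
    ) -> pd.DataFrame:
        """Table-1/2 style HIGH vs LOW comparison battery."""
        return group_comparison_table(
            self.model.clinical, self.group_map(), variables, m=m
        )

    def usage_correlation(self, lab: str) -> tuple[float, float]:
        """Spearman correlation of the scored subset's usage with a lab."""
        lab_v = self.model.clinical[lab].reindex(self._usages.index)
        return spearman(self._usages.to_numpy(), lab_v.to_numpy())

    def regression(self, outcome: str) -> pd.DataFrame:
        """Scaled multiple regression of a clinical outcome on all five
        subset usages jointly (one standardized coefficient per subset)."""
        wide = self.model.usage.pivot(
            index="patient_id", columns="subset", values="usage"
        )
        wide = wide[[s.value for s in BCellSubset if s.value in wide.columns]]
        y = self.model.clinical[outcome].reindex(wide.index).rename(outcome)
        return scaled_regression(y, wide)

    def subset_comparison(self) -> pd.DataFrame:
        """Pairwise Mann-Whitney comparisons of usage across subsets."""
        return compare_subsets(self.model.usage)

    def flare_survival(self, drug: str = "tacrolimus", require_lldas: bool = True):
        """KM flare-free survival + log-rank, HIGH vs LOW, among LLDAS
        achievers on ``drug``. Returns a :class:`FlareSurvival`."""
        if self.model.patients is None:
            raise MissingDataError(
                "survival analysis needs PatientClinical records with follow-up"
            )
        records = build_survival_records(
            self.model.patients, self.group_map(), drug=drug, require_lldas=require_lldas
        )
        return FlareSurvival(records, drug)

    # -- plotting ----------------------------------------------------------

    def plot_roc(self, ax=None):
        """ROC curve with the selected operating point marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4, 4))
        ax.plot(1 - self.roc.spec, self.roc.sens, drawstyle="steps-post", color="k")
        ax.plot([0, 1], [0, 1], ls=":", color="grey", lw=0.8)
        if self.sensitivity is not None:
            ax.plot([1 - self.specificity], [self.sensitivity], "o", color="crimson")
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"AUC = {self.auc:.3f}, cutoff = {100 * self.cutoff:.1f}%")
        return ax


class FlareSurvival:
    """Flare-free survival contrast between the HIGH and LOW groups."""

    def __init__(self, records, drug: str):
        self.records = records
        self.drug = drug
        self.high = [r for r in records if r.group == "HIGH"]
        self.low = [r for r in records if r.group == "LOW"]
        if self.high and self.low:
            self.chi2, self.p = logrank(self.high, self.low)
        else:
            warnings.warn(
                f"{drug}: one group empty (HIGH {len(self.high)} / LOW {len(self.low)}); "
                "log-rank not computed",
                stacklevel=2,
            )
            self.chi2, self.p = np.nan, np.nan

    @property
    def n(self) -> int:
        return len(self.records)

    def km_tables(self) -> dict[str, pd.DataFrame]:
        out = {}
        if self.high:
            out["HIGH"] = km_estimate(self.high)
        if self.low:
            out["LOW"] = km_estimate(self.low)
        return out

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        for label, recs, color in (("HIGH", self.high, "crimson"), ("LOW", self.low, "royalblue")):
            if not recs:
                continue
            km = km_estimate(recs)
            t = np.concatenate([[0], km.time.to_numpy()])
            s = np.concatenate([[1.0], km.survival.to_numpy()])
            ax.step(t, s, where="post", label=f"{label} (n={len(recs)})", color=color)
        ax.set_ylim(0, 1.05)
        ax.set_xlabel("days from baseline")
        ax.set_ylabel("flare-free survival")
        ax.legend()
        if np.isfinite(self.p):
            ax.set_title(f"{self.drug}: log-rank p = {self.p:.3f}")
        return ax
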