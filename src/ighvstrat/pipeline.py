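"""End-to-end pipeline orchestration with a config file and run manifest.

Stages (in dependency order): simulate -> usage -> stratify ->
{associate, survive} -> report. Each stage reads only the files earlier
stages wrote, so any stage can be re-run in isolation; with an unchanged
config and seed every primary output is byte-identical, and the manifest
records the config hash, cutoff, family sizes, row counts and warnings.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .clinical import ComplementReferenceRange
from .errors import PipelineDependencyError
from .model import DEFAULT_TABLE_VARIABLES, UsageStratification
from .repertoire import read_clonotype_table
from .simulate import SimConfig, SimulatedCohort, simulate_cohort
from .usage import compare_subsets, usage_matrix

__all__ = ["default_config", "load_config", "run_pipeline", "STAGES"]

STAGES = ("simulate", "usage", "stratify", "associate", "survive", "report")

_DEPENDENCIES: Mapping[str, str | None] = {
    "simulate": None,
    "usage": "simulate",
    "stratify": "usage",
    "associate": "stratify",
    "survive": "stratify",
    "report": "stratify",
}

_STAGE_SENTINELS = {
    "simulate": "fixtures/clinical.csv",
    "usage": "usage.tsv",
    "stratify": "groups.tsv",
    "associate": "group_comparisons.tsv",
    "survive": "logrank.json",
    "report": "report.txt",
}

_FLOAT_FMT = "%.10g"


def default_config() -> dict:
    return {
        "seed": 0,
        "gene": "IGHV4-34",
        "subset": "USM",
        "cutoff": None,  # None -> fit the closest-to-corner cutoff
        "drug": "tacrolimus",
        "complement_refs": {"c3_low": 73.0, "c4_low": 11.0},
        "bonferroni": {"subset_pairs": 10, "table": None},  # None -> rows tested
        "regression_outcomes": ["c4", "c3", "anti_dsdna", "sledai_2k"],
        "sim": {"n_patients": 129},
    }


def load_config(path: str | Path | None) -> dict:
    cfg = default_config()
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        for key, val in user.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=float).encode()
    ).hexdigest()


def _sim_config(cfg: dict) -> SimConfig:
    kwargs = dict(cfg.get("sim", {}))
    refs = cfg.get("complement_refs", {})
    kwargs.setdefault("seed", cfg.get("seed", 0))
    return SimConfig(
        complement_refs=ComplementReferenceRange(**refs), **kwargs
    )


def _require(outdir: Path, stage: str) -> None:
    dep = _DEPENDENCIES[stage]
    if dep and not (outdir / _STAGE_SENTINELS[dep]).exists():
        raise PipelineDependencyError(
            f"stage '{stage}' requires output of stage '{dep}' "
            f"({_STAGE_SENTINELS[dep]} not found in {outdir})"
        )


def run_pipeline(
    config: dict | str | Path | None = None,
    stages: Sequence[str] = STAGES,
    outdir: str | Path = "ighvstrat_out",
    seed: int | None = None,
    cutoff: float | None = None,
    drug: str | None = None,
) -> Path:
    """Execute the requested stages in dependency order; returns outdir."""
    if isinstance(config, dict):
        cfg = default_config()
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(cfg.get(key), dict):
                cfg[key].update(val)
            else:
                cfg[key] = val
    else:
        cfg = load_config(config)
    if seed is not None:
        cfg["seed"] = int(seed)
    if cutoff is not None:
        cfg["cutoff"] = float(cutoff)
    if drug is not None:
        cfg["drug"] = drug
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest_path = outdir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {}
    )
    manifest.update(
        {"config": cfg, "config_hash": _config_hash(cfg), "seed": cfg["seed"]}
    )
    manifest.setdefault("row_counts", {})
    manifest.setdefault("warnings", [])

    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        for stage in ordered:
            _require(outdir, stage)
            _STAGE_FUNCS[stage](cfg, outdir, manifest)
        caught = sorted({str(w.message) for w in wlist})
    manifest["warnings"] = caught
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True, default=str))
    return outdir


def _stage_simulate(cfg: dict, outdir: Path, manifest: dict) -> None:
    cohort = simulate_cohort(_sim_config(cfg))
    fx = outdir / "fixtures"
    cohort.write_fixture_set(fx)
    manifest["row_counts"]["simulate"] = int(len(cohort.clinical))
    manifest["input_files"] = sorted(p.name for p in fx.glob("*.tsv"))


def _stage_usage(cfg: dict, outdir: Path, manifest: dict) -> None:
    fx = outdir / "fixtures"
    samples = [read_clonotype_table(f, dialect="airr") for f in sorted(fx.glob("*_*.tsv"))]
    matrix = usage_matrix(samples, cfg["gene"])
    matrix.to_csv(outdir / "usage.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest["row_counts"]["usage"] = int(len(matrix))


def _fit(cfg: dict, outdir: Path):
    matrix = pd.read_csv(outdir / "usage.tsv", sep="\t")
    clinical = pd.read_csv(outdir / "fixtures" / "clinical.csv")
    cohort = simulate_cohort(_sim_config(cfg))  # for PatientClinical follow-up
    model = UsageStratification(
        matrix,
        clinical,
        gene=cfg["gene"],
        subset=cfg["subset"],
        complement_refs=ComplementReferenceRange(**cfg["complement_refs"]),
        patients=cohort.patients(),
    )
    return model.fit(cutoff=cfg.get("cutoff"))


def _stage_stratify(cfg: dict, outdir: Path, manifest: dict) -> None:
    res = _fit(cfg, outdir)
    res.roc.as_frame().to_csv(
        outdir / "roc.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    res.groups.to_csv(outdir / "groups.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest["cutoff"] = res.cutoff
    manifest["auc"] = res.auc
    manifest["row_counts"]["stratify"] = int(len(res.groups))


def _stage_associate(cfg: dict, outdir: Path, manifest: dict) -> None:
    res = _fit(cfg, outdir)
    table_m = cfg["bonferroni"].get("table")
    comp = res.compare_groups(m=table_m)
    comp.to_csv(
        outdir / "group_comparisons.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    subsets = res.subset_comparison()
    subsets.to_csv(
        outdir / "subset_comparisons.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    reg = pd.concat(
        [res.regression(outcome) for outcome in cfg["regression_outcomes"]],
        ignore_index=True,
    )
    reg.to_csv(outdir / "regression.tsv", sep="\t", index=False, float_format=_FLOAT_FMT)
    manifest["bonferroni_m"] = {
        "subset_pairs": int(len(subsets)),
        "table": int(table_m if table_m is not None else len(comp)),
    }
    manifest["row_counts"]["associate"] = int(len(comp))


def _stage_survive(cfg: dict, outdir: Path, manifest: dict) -> None:
    res = _fit(cfg, outdir)
    fs = res.flare_survival(drug=cfg["drug"])
    pd.DataFrame([dataclasses.asdict(r) for r in fs.records]).to_csv(
        outdir / "survival_records.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    for label, km in fs.km_tables().items():
        km.to_csv(
            outdir / f"km_{label}.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
        )
    (outdir / "logrank.json").write_text(
        json.dumps(
            {"drug": cfg["drug"], "n": fs.n, "n_high": len(fs.high),
             "n_low": len(fs.low), "chi2": fs.chi2, "p": fs.p},
            indent=1, sort_keys=True, default=float,
        )
    )
    manifest["row_counts"]["survive"] = int(fs.n)


def _stage_report(cfg: dict, outdir: Path, manifest: dict) -> None:
    res = _fit(cfg, outdir)
    lines = [res.summary(), ""]
    comp_path = outdir / "group_comparisons.tsv"
    if comp_path.exists():
        comp = pd.read_csv(comp_path, sep="\t")
        lines.append("Group comparison (HIGH vs LOW)")
        lines.append("-" * 78)
        for row in comp.itertuples(index=False):
            lines.append(
                f"{row.variable:<28}{row.summary_high:<22}{row.summary_low:<22}"
                f"p={row.p_raw:.3g} (adj {row.p_adj:.3g})"
            )
        lines.append("")
    lr_path = outdir / "logrank.json"
    if lr_path.exists():
        lr = json.loads(lr_path.read_text())
        lines.append(
            f"Flare-free survival ({lr['drug']}, LLDAS achievers): n={lr['n']} "
            f"(HIGH {lr['n_high']} / LOW {lr['n_low']}), "
            f"log-rank chi2={lr['chi2']:.3f}, p={lr['p']:.4f}"
        )
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")
    manifest["row_counts"]["report"] = len(lines)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "usage": _stage_usage,
    "stratify": _stage_stratify,
    "associate": _stage_associate,
    "survive": _stage_survive,
    "report": _stage_report,
}
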