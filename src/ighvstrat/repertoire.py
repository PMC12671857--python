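"""Clonotype table I/O: AIRR Rearrangement TSV and MiXCR clone-export TSV.

A *clonotype* is a unique B-cell receptor rearrangement. Rows of an input
table are collapsed onto a configurable clonotype key — by default the pair
(normalized V gene, CDR3 nucleotide sequence); a CDR3-nt-only mode is
provided because published repertoire studies differ on whether the V gene
is part of clonal identity. Counts are summed through the collapse even
though the downstream usage statistic is clonotype-unweighted.

Rows whose CDR3 is empty or whose V call cannot be parsed do not form a
clonotype key; they are dropped and tallied on the returned sample.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import SchemaError, VGeneParseError

__all__ = [
    "BCellSubset",
    "ClonotypeRecord",
    "RepertoireSample",
    "normalize_v_gene",
    "collapse_clonotypes",
    "read_clonotype_table",
    "write_clonotype_table",
]


class BCellSubset(str, Enum):
    """The five sorted peripheral-blood B-cell subsets.

    NAIVE: CD19+ IgD+ CD27-; USM (unswitched memory): CD19+ IgD+ CD27+;
    SM (switched memory): CD19+ IgD- CD27+; DN (double negative):
    CD19+ IgD- CD27-; PB (plasmablast): CD19+ IgD- CD27++ CD38+.
    """

    NAIVE = "NAIVE"
    USM = "USM"
    SM = "SM"
    DN = "DN"
    PB = "PB"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


SUBSETS: tuple[BCellSubset, ...] = tuple(BCellSubset)

# Gene symbol after normalization: IGHV4-34, IGHV1-69D, IGHV4-30-4, ...
_GENE_RE = re.compile(r"^[A-Za-z][A-Za-z0-9./-]*$")


def normalize_v_gene(v_call: str) -> str:
    """Reduce a raw V-call string to a bare gene symbol.

    Handles AIRR-style allele calls (``IGHV4-34*01``) and MiXCR multi-hit
    strings with alignment scores (``IGHV4-34*00(1290.5),IGHV4-59*00(811)``).
    For multi-hit strings the first-listed hit is taken; MiXCR orders hits
    by alignment score, so this is the best hit.

    Raises
    ------
    VGeneParseError
        If the call is empty or does not reduce to a plausible gene symbol.
    """
    if not isinstance(v_call, str) or not v_call.strip():
        raise VGeneParseError(f"empty or non-string V call: {v_call!r}")
    first = v_call.split(",")[0].strip()
    gene = first.split("*")[0].split("(")[0].strip()
    if not gene or not _GENE_RE.match(gene):
        raise VGeneParseError(f"cannot parse V call: {v_call!r}")
    return gene


@dataclass(frozen=True)
class ClonotypeRecord:
    """One clonotype: V/J gene call, CDR3 and clone/read count."""

    v_gene: str
    cdr3_nt: str
    cdr3_aa: str | None = None
    j_gene: str | None = None
    count: int = 1

    def __post_init__(self) -> None:
        if "*" in self.v_gene or "(" in self.v_gene:
            raise ValueError(f"v_gene must be allele-free: {self.v_gene!r}")
        if not self.cdr3_nt:
            raise ValueError("cdr3_nt must be non-empty")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")


def collapse_clonotypes(
    records: Iterable[ClonotypeRecord], clonotype_key: str = "v_nt"
) -> tuple[ClonotypeRecord, ...]:
    """Merge records sharing a clonotype key, summing counts.

    ``clonotype_key`` is ``"v_nt"`` (V gene + CDR3 nucleotide, default) or
    ``"nt"`` (CDR3 nucleotide only; the first-seen V gene is retained on
    the merged record).
    """
    if clonotype_key not in ("v_nt", "nt"):
        raise ValueError(f"unknown clonotype_key: {clonotype_key!r}")
    merged: dict[tuple, ClonotypeRecord] = {}
    for rec in records:
        key = (rec.v_gene, rec.cdr3_nt) if clonotype_key == "v_nt" else (rec.cdr3_nt,)
        prev = merged.get(key)
        if prev is None:
            merged[key] = rec
        else:
            merged[key] = replace(
                prev,
                count=prev.count + rec.count,
                cdr3_aa=prev.cdr3_aa or rec.cdr3_aa,
                j_gene=prev.j_gene or rec.j_gene,
            )
    return tuple(merged.values())


@dataclass
class RepertoireSample:
    """All clonotypes of one patient x one B-cell subset."""

    patient_id: str
    subset: BCellSubset
    clonotypes: tuple[ClonotypeRecord, ...] = ()
    n_dropped: int = 0
    clonotype_key: str = "v_nt"

    def __post_init__(self) -> None:
        self.subset = BCellSubset(self.subset)
        self.clonotypes = collapse_clonotypes(self.clonotypes, self.clonotype_key)

    def __len__(self) -> int:
        return len(self.clonotypes)

    @property
    def total_count(self) -> int:
        return sum(c.count for c in self.clonotypes)

    def gene_clonotype_counts(self) -> dict[str, int]:
        """Number of distinct clonotypes per V gene (count-unweighted)."""
        out: dict[str, int] = {}
        for c in self.clonotypes:
            out[c.v_gene] = out.get(c.v_gene, 0) + 1
        return out


_DIALECTS: Mapping[str, Mapping[str, Sequence[str] | Mapping[str, str]]] = {
    "airr": {
        "required": ("v_call", "junction"),
        "columns": {
            "v_call": "v_call",
            "cdr3_nt": "junction",
            "cdr3_aa": "junction_aa",
            "j_call": "j_call",
            "count": "duplicate_count",
        },
    },
    "mixcr": {
        "required": ("allVHitsWithScore", "nSeqCDR3", "cloneCount"),
        "columns": {
            "v_call": "allVHitsWithScore",
            "cdr3_nt": "nSeqCDR3",
            "cdr3_aa": "aaSeqCDR3",
            "j_call": "allJHitsWithScore",
            "count": "cloneCount",
        },
    },
}


def _infer_sample_identity(path: Path) -> tuple[str | None, BCellSubset | None]:
    """Infer (patient_id, subset) from a ``{patient}_{subset}.tsv`` stem."""
    stem = path.stem
    if "_" in stem:
        pid, _, tail = stem.rpartition("_")
        try:
            return pid, BCellSubset(tail.upper())
        except ValueError:
            pass
    return stem, None


def read_clonotype_table(
    path: str | Path,
    dialect: str = "airr",
    patient_id: str | None = None,
    subset: BCellSubset | str | None = None,
    clonotype_key: str = "v_nt",
) -> RepertoireSample:
    """Read one clonotype table into a :class:`RepertoireSample`.

    Parameters
    ----------
    path
        Tab-separated, UTF-8 table with a header row.
    dialect
        ``"airr"`` (AIRR Rearrangement: v_call, junction, junction_aa,
        j_call, duplicate_count) or ``"mixcr"`` (clone export:
        allVHitsWithScore, nSeqCDR3, aaSeqCDR3, cloneCount).
    patient_id, subset
        Sample identity; inferred from a ``{patient}_{subset}.tsv`` file
        name when omitted.

    Rows with an empty CDR3 or an unparseable V call are dropped and
    counted in ``sample.n_dropped``. Rows sharing a clonotype key are
    collapsed with summed counts.
    """
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect: {dialect!r} (expected 'airr' or 'mixcr')")
    spec = _DIALECTS[dialect]
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in spec["required"] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path.name}: missing required {dialect} columns: {', '.join(missing)}"
        )
    cols = spec["columns"]

    inferred_pid, inferred_subset = _infer_sample_identity(path)
    if patient_id is None:
        patient_id = inferred_pid
    if subset is None:
        if inferred_subset is None:
            raise ValueError(
                f"{path.name}: subset not given and not inferrable from file name"
            )
        subset = inferred_subset

    records: list[ClonotypeRecord] = []
    dropped = 0
    for row in df.itertuples(index=False):
        row = row._asdict()
        cdr3 = row.get(cols["cdr3_nt"])
        if not isinstance(cdr3, str) or not cdr3.strip():
            dropped += 1
            continue
        try:
            v_gene = normalize_v_gene(row.get(cols["v_call"]))
        except VGeneParseError:
            dropped += 1
            continue
        j_raw = row.get(cols["j_call"])
        try:
            j_gene = normalize_v_gene(j_raw) if isinstance(j_raw, str) else None
        except VGeneParseError:
            j_gene = None
        aa = row.get(cols["cdr3_aa"])
        count_raw = row.get(cols["count"])
        try:
            count = int(float(count_raw)) if count_raw not in (None, "") else 1
        except (TypeError, ValueError):
            count = 1
        records.append(
            ClonotypeRecord(
                v_gene=v_gene,
                cdr3_nt=cdr3.strip(),
                cdr3_aa=aa.strip() if isinstance(aa, str) and aa.strip() else None,
                j_gene=j_gene,
                count=count,
            )
        )
    return RepertoireSample(
        patient_id=patient_id,
        subset=subset,
        clonotypes=tuple(records),
        n_dropped=dropped,
        clonotype_key=clonotype_key,
    )


def write_clonotype_table(sample: RepertoireSample, path: str | Path) -> Path:
    """Write a sample as an AIRR Rearrangement TSV (round-trips losslessly)."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "v_call": [c.v_gene for c in sample.clonotypes],
            "j_call": [c.j_gene or "" for c in sample.clonotypes],
            "junction": [c.cdr3_nt for c in sample.clonotypes],
            "junction_aa": [c.cdr3_aa or "" for c in sample.clonotypes],
            "duplicate_count": [c.count for c in sample.clonotypes],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return path
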