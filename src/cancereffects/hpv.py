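"""HPV status calls from viral transcript read counts.

A tumor is HPV-positive when it shows strictly more than 100 HPV RNA viral
transcript reads per hundred million sequenced reads; otherwise negative.
Clinical p16/in-situ-hybridization overrides, where available, supersede the
read-count rule. TP53 mutation status is cross-tabulated as a descriptive
sanity check (HPV-driven tumors rarely carry TP53 substitutions, because the
viral oncoproteins inactivate p53 directly).
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .variant_io import VariantRecord

DEFAULT_THRESHOLD = 100.0


@dataclasses.dataclass(frozen=True)
class HpvCall:
    sample_id: str
    reads_per_hundred_million: float  # NaN when unavailable
    status: str  # positive / negative / unknown
    source: str = "reads"  # reads / clinical_override / missing
    tp53_mutated: bool | None = None


def classify_hpv(reads_per_hundred_million: float | None,
                 threshold: float = DEFAULT_THRESHOLD) -> str:
    """Positive iff reads strictly exceed the threshold; ties are negative."""
    if reads_per_hundred_million is None or (
        isinstance(reads_per_hundred_million, float)
        and math.isnan(reads_per_hundred_million)
    ):
        return "unknown"
    if reads_per_hundred_million < 0:
        raise ValueError("read count must be non-negative")
    return "positive" if reads_per_hundred_million > threshold else "negative"


def read_hpv_table(path: str | Path, threshold: float = DEFAULT_THRESHOLD) -> list[HpvCall]:
    """Read a TSV of ``sample_id, hpv_reads_per_1e8[, clinical_override]``."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns or "hpv_reads_per_1e8" not in df.columns:
        raise ValueError("HPV table needs columns sample_id and hpv_reads_per_1e8")
    calls = []
    has_override = "clinical_override" in df.columns
    for _, row in df.iterrows():
        reads = float(row["hpv_reads_per_1e8"]) if pd.notna(row["hpv_reads_per_1e8"]) else float("nan")
        override = row["clinical_override"] if has_override and pd.notna(row.get("clinical_override")) else None
        if override:
            if override not in ("positive", "negative"):
                raise ValueError(f"invalid clinical override {override!r}")
            calls.append(HpvCall(row["sample_id"], reads, override, source="clinical_override"))
        else:
            status = classify_hpv(reads, threshold)
            calls.append(
                HpvCall(row["sample_id"], reads, status,
                        source="reads" if status != "unknown" else "missing")
            )
    return calls


def labels_from_calls(calls: Iterable[HpvCall]) -> dict[str, str]:
    return {c.sample_id: c.status for c in calls}


def tp53_concordance_report(
    calls: Iterable[HpvCall],
    variants: Iterable[VariantRecord],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cross-tabulate HPV status against TP53 substitution carriage.

    Purely descriptive; no call is reclassified. Returns the per-sample table
    and a 2x3 summary (tp53 yes/no x status) whose cells sum to cohort size.
    """
    tp53_samples = {v.sample_id for v in variants if v.gene == "TP53"}
    rows = [
        {
            "sample_id": c.sample_id,
            "status": c.status,
            "tp53_mutated": c.sample_id in tp53_samples,
        }
        for c in calls
    ]
    per_sample = pd.DataFrame(rows, columns=["sample_id", "status", "tp53_mutated"])
    summary = (
        per_sample.groupby(["tp53_mutated", "status"]).size().unstack(fill_value=0)
        .reindex(index=[False, True], columns=["negative", "positive", "unknown"],
                 fill_value=0)
    )
    return per_sample, summary
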