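"""Reading, writing and hygiene of somatic variant tables (MAF dialect).

Consumes the tab-separated MAF dialect used by the NCI Genomic Data Commons
(1-based, fully-closed coordinates), annotates each SNV with its trinucleotide
context from an indexed FASTA, re-designates adjacent same-sample SNVs as
dinucleotide variants (DNVs) so they cannot masquerade as independent point
mutations, and tallies per-variant recurrence within HPV strata.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from pyfaidx import Fasta

from .channels import ChannelKey, pyrimidine_normalize

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Hugo_Symbol",
    "Variant_Classification",
)

#: MAF Variant_Classification -> coarse consequence vocabulary.
_CLASSIFICATION_MAP = {
    "Silent": "silent",
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Splice_Site": "splice_site",
    "Splice_Region": "splice_site",
    "RNA": "noncoding",
    "IGR": "noncoding",
    "Intron": "noncoding",
    "3'UTR": "noncoding",
    "5'UTR": "noncoding",
    "3'Flank": "noncoding",
    "5'Flank": "noncoding",
}

_VALID_BASES = frozenset("ACGT")

CONSEQUENCES = ("silent", "missense", "nonsense", "splice_site", "noncoding", "other")


class MafFormatError(ValueError):
    """A required column is missing or the file is not parseable."""


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One somatic single-nucleotide variant.

    ``trinuc_ref`` is the +-strand reference 3-mer centered on ``pos``; it is
    empty until context annotation has run.
    """

    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str = ""
    consequence: str = "other"
    aa_change: str = ""
    trinuc_ref: str = ""

    def __post_init__(self):
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at {self.chrom}:{self.pos}")
        if self.trinuc_ref and self.trinuc_ref[1] != self.ref:
            raise ValueError(
                f"context {self.trinuc_ref} does not center on ref {self.ref}"
            )
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")

    @property
    def variant_id(self) -> tuple[str, int, str, str]:
        """Nucleotide-level identity used for recurrence."""
        return (self.chrom, self.pos, self.ref, self.alt)

    @functools.cached_property
    def channel(self) -> ChannelKey:
        if not self.trinuc_ref:
            raise ValueError("record has no trinucleotide context annotation")
        return pyrimidine_normalize(self.trinuc_ref, self.ref, self.alt)


def classify_consequence(variant_classification: str) -> str:
    return _CLASSIFICATION_MAP.get(variant_classification, "other")


def _is_snv(ref: str, alt: str) -> bool:
    return (
        len(ref) == 1
        and len(alt) == 1
        and ref in _VALID_BASES
        and alt in _VALID_BASES
        and ref != alt
    )


def read_maf(
    path: str | Path,
    status_filter: tuple[str, str] | None = None,
) -> tuple[list[VariantRecord], pd.DataFrame, pd.DataFrame]:
    """Read a MAF-dialect TSV.

    Returns ``(snvs, side_channel, rejects)``: the list of parsed SNV records
    in file order, a DataFrame of rows that are valid but not single-nucleotide
    substitutions (indels, MNVs), and a DataFrame of rejected rows with a
    ``reject_reason`` column.

    ``status_filter``, when given, names a ``(column, allowed-values-csv)``
    pair used to drop rows whose value in that column is not allowed — this
    covers source datasets that flag non-primary variants.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [col for col in REQUIRED_COLUMNS if col not in df.columns]
    if missing:
        raise MafFormatError(
            f"MAF file {path} is missing required columns: {', '.join(missing)}"
        )
    if status_filter is not None:
        col, allowed = status_filter
        if col in df.columns:
            keep = df[col].isin([v.strip() for v in allowed.split(",")])
            logger.info("status filter on %s removed %d rows", col, int((~keep).sum()))
            df = df[keep]

    records: list[VariantRecord] = []
    side_rows: list[int] = []
    reject_rows: list[tuple[int, str]] = []
    has_aa = "HGVSp_Short" in df.columns
    for idx, row in df.iterrows():
        ref = row["Reference_Allele"].upper()
        alt = row["Tumor_Seq_Allele2"].upper()
        if len(ref) != 1 or len(alt) != 1 or ref == "-" or alt == "-":
            side_rows.append(idx)
            continue
        if not _is_snv(ref, alt):
            reject_rows.append((idx, "unknown_base_symbol"))
            continue
        try:
            pos = int(row["Start_Position"])
        except ValueError:
            reject_rows.append((idx, "non_integer_position"))
            continue
        if pos < 2:
            reject_rows.append((idx, "position_without_context"))
            continue
        records.append(
            VariantRecord(
                sample_id=row["Tumor_Sample_Barcode"],
                chrom=row["Chromosome"],
                pos=pos,
                ref=ref,
                alt=alt,
                gene=row["Hugo_Symbol"],
                consequence=classify_consequence(row["Variant_Classification"]),
                aa_change=row["HGVSp_Short"].removeprefix("p.") if has_aa else "",
            )
        )
    side = df.loc[side_rows] if side_rows else df.iloc[0:0]
    rejects = df.loc[[i for i, _ in reject_rows]].copy()
    rejects["reject_reason"] = [r for _, r in reject_rows]
    logger.info(
        "read_maf: %d SNVs, %d side-channel rows, %d rejects from %s",
        len(records), len(side), len(rejects), path,
    )
    return records, side, rejects


def write_maf(records: Iterable[VariantRecord], path: str | Path) -> None:
    """Write records back out in the same MAF dialect ``read_maf`` consumes."""
    rows = []
    for r in records:
        rows.append(
            {
                "Hugo_Symbol": r.gene,
                "Chromosome": r.chrom,
                "Start_Position": r.pos,
                "Reference_Allele": r.ref,
                "Tumor_Seq_Allele2": r.alt,
                "Tumor_Sample_Barcode": r.sample_id,
                "Variant_Classification": _inverse_classification(r.consequence),
                "HGVSp_Short": f"p.{r.aa_change}" if r.aa_change else "",
            }
        )
    pd.DataFrame(
        rows,
        columns=[
            "Hugo_Symbol", "Chromosome", "Start_Position", "Reference_Allele",
            "Tumor_Seq_Allele2", "Tumor_Sample_Barcode", "Variant_Classification",
            "HGVSp_Short",
        ],
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def _inverse_classification(consequence: str) -> str:
    for maf, cons in _CLASSIFICATION_MAP.items():
        if cons == consequence:
            return maf
    return "Targeted_Region"


def annotate_context(
    records: Iterable[VariantRecord],
    fasta_path: str | Path,
) -> tuple[list[VariantRecord], pd.DataFrame]:
    """Attach the +-strand trinucleotide context from an indexed FASTA.

    Records whose reference allele disagrees with the FASTA base at their
    position are rejected to the report rather than silently corrected; so are
    records whose context contains an ambiguous base.
    """
    fasta = Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
    annotated: list[VariantRecord] = []
    rejects: list[dict] = []
    for r in records:
        if r.chrom not in fasta:
            rejects.append(_reject_row(r, "chromosome_absent_from_reference"))
            continue
        seq = fasta[r.chrom]
        if r.pos < 2 or r.pos > len(seq) - 1:
            rejects.append(_reject_row(r, "position_without_context"))
            continue
        trinuc = seq[r.pos - 2 : r.pos + 1]  # 0-based half-open slice
        if any(b not in "ACGT" for b in trinuc):
            rejects.append(_reject_row(r, "ambiguous_reference_base"))
            continue
        if trinuc[1] != r.ref:
            rejects.append(_reject_row(r, "reference_allele_mismatch"))
            continue
        annotated.append(dataclasses.replace(r, trinuc_ref=trinuc))
    report = pd.DataFrame(
        rejects,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "reject_reason"],
    )
    if len(report):
        logger.info("annotate_context rejected %d records", len(report))
    return annotated, report


def _reject_row(r: VariantRecord, reason: str) -> dict:
    return {
        "sample_id": r.sample_id, "chrom": r.chrom, "pos": r.pos,
        "ref": r.ref, "alt": r.alt, "reject_reason": reason,
    }


def collapse_dnvs(
    records: list[VariantRecord],
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Split isolated SNVs from runs of adjacent same-sample variants.

    Any maximal run of two or more SNVs at consecutive positions on the same
    chromosome of the same sample is treated as one multi-nucleotide event and
    moved whole to the DNV list; only isolated SNVs survive for point-mutation
    inference. Record counts are conserved.
    """
    by_locus: dict[tuple[str, str], list[VariantRecord]] = defaultdict(list)
    for r in records:
        by_locus[(r.sample_id, r.chrom)].append(r)

    in_run: set[int] = set()
    for recs in by_locus.values():
        recs_sorted = sorted(recs, key=lambda r: r.pos)
        positions = {r.pos for r in recs_sorted}
        for r in recs_sorted:
            if (r.pos - 1) in positions or (r.pos + 1) in positions:
                in_run.add(id(r))

    snvs = [r for r in records if id(r) not in in_run]
    dnvs = [r for r in records if id(r) in in_run]
    if dnvs:
        logger.info("collapse_dnvs moved %d records to the DNV side channel", len(dnvs))
    return snvs, dnvs


STRATA = ("negative", "positive")


def tally_recurrence(
    snvs: list[VariantRecord],
    hpv_labels: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Count carrier samples per variant and per HPV stratum.

    A variant identity is (chrom, pos, ref, alt); a sample carries the variant
    at most once. Samples without an HPV label are assigned "unknown" and
    counted in neither stratum (but contribute to the pooled tally and the
    unknown stratum size).

    Returns
    -------
    (table, stratum_sizes)
        ``table`` has one row per distinct variant with columns ``chrom, pos,
        ref, alt, gene, aa_change, consequence, trinuc_ref, n_negative,
        n_positive, n_unknown, n_total, recurrent``; ``stratum_sizes`` maps
        {negative, positive, unknown} to sample counts (all labelled samples
        plus any sample appearing in ``snvs``, regardless of carriage).
    """
    samples = set(hpv_labels) | {r.sample_id for r in snvs}
    label = {s: hpv_labels.get(s, "unknown") for s in samples}
    for s, lab in label.items():
        if lab not in ("negative", "positive", "unknown"):
            raise ValueError(f"sample {s}: invalid HPV label {lab!r}")
    sizes = {
        "negative": sum(1 for v in label.values() if v == "negative"),
        "positive": sum(1 for v in label.values() if v == "positive"),
        "unknown": sum(1 for v in label.values() if v == "unknown"),
    }

    if not snvs:
        table = pd.DataFrame(
            columns=[
                "chrom", "pos", "ref", "alt", "gene", "aa_change", "consequence",
                "trinuc_ref", "n_negative", "n_positive", "n_unknown", "n_total",
                "recurrent",
            ]
        )
        return table, sizes

    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in snvs],
            "pos": [r.pos for r in snvs],
            "ref": [r.ref for r in snvs],
            "alt": [r.alt for r in snvs],
            "gene": [r.gene for r in snvs],
            "aa_change": [r.aa_change for r in snvs],
            "consequence": [r.consequence for r in snvs],
            "trinuc_ref": [r.trinuc_ref for r in snvs],
            "sample_id": [r.sample_id for r in snvs],
        }
    )
    df["stratum"] = df["sample_id"].map(label)
    vid_cols = ["chrom", "pos", "ref", "alt"]
    df = df.drop_duplicates(subset=vid_cols + ["sample_id"])
    counts = (
        df.groupby(vid_cols, sort=True)["stratum"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["negative", "positive", "unknown"], fill_value=0)
    )
    meta = df.groupby(vid_cols, sort=True)[
        ["gene", "aa_change", "consequence", "trinuc_ref"]
    ].first()
    table = meta.join(
        counts.rename(
            columns={"negative": "n_negative", "positive": "n_positive",
                     "unknown": "n_unknown"}
        )
    ).reset_index()
    table["n_total"] = table[["n_negative", "n_positive", "n_unknown"]].sum(axis=1)
    table["recurrent"] = table["n_total"] >= 2
    return table, sizes
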