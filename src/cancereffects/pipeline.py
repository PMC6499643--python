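"""End-to-end orchestration: cohort in, ranked effect sizes out.

``analyze_cohort`` is the in-memory composition of the stages (variant
hygiene, signature refitting, context profile, gene rates, per-site mu,
recurrence, selection intensities, attribution, net realized intensities,
cohort-level tests); ``run_all`` wraps it with file I/O, a structured config,
logging and TSV outputs stamped with the config hash. A run is a pure
function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from collections import defaultdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import hpv as hpv_mod
from . import rates as rates_mod
from . import selection as sel_mod
from . import signatures as sig_mod
from . import variant_io
from .catalog import load_signature_matrix, synthetic_signature_catalog
from .genes import GeneModel, toy_exome
from .signatures import SignatureFit

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Paths, thresholds and flags for a full run; echoed into every output."""

    maf: str = ""
    reference: str = ""  # FASTA; empty when records arrive pre-annotated
    signatures: str = ""  # COSMIC-style TSV; empty -> synthetic catalogue
    hpv_table: str = ""
    output_dir: str = "results"
    min_mutations: int = 50
    weight_cutoff: float = 0.06
    hpv_reads_threshold: float = 100.0
    recurrence_threshold: int = 2
    context_profile: str = "reconstructed"  # or "raw"
    welch_scale: str = "log"  # or "raw"
    mu_normalization: str = "silent"  # or "all_sites" (denominator anchor)
    abundance: str = "exome"  # or "none"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")  # where outputs land is not part of the analysis
        blob = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclasses.dataclass
class PipelineResult:
    fits: list
    context_profile: np.ndarray
    gene_rates: list
    mu_table: pd.DataFrame
    tally: pd.DataFrame
    stratum_sizes: dict
    selection: pd.DataFrame
    dnvs: list
    tcw_comparison: sel_mod.WelchResult | None = None
    net_realized: pd.DataFrame | None = None
    cluster_newick: str | None = None
    group_tests: sel_mod.GroupTestResults | None = None


def fit_cohort_signatures(
    records: Sequence[variant_io.VariantRecord],
    sigs: pd.DataFrame,
    min_mutations: int,
    weight_cutoff: float,
) -> tuple[list[SignatureFit], list[sig_mod.TrinucSpectrum]]:
    by_sample: dict[str, list] = defaultdict(list)
    for r in records:
        by_sample[r.sample_id].append(r)
    fits, spectra = [], []
    for sample in sorted(by_sample):
        spec = sig_mod.build_spectrum(by_sample[sample], sample_id=sample)
        spectra.append(spec)
        fits.append(sig_mod.deconvolve(spec, sigs, min_mutations, weight_cutoff))
    n_eligible = sum(f.eligible for f in fits)
    logger.info("signature fits: %d/%d tumors eligible", n_eligible, len(fits))
    return fits, spectra


def _mu_table(
    models: Sequence[GeneModel],
    gene_rates: list,
    weights: np.ndarray,
    mu_normalization: str,
) -> pd.DataFrame:
    rate_by_gene = {g.gene: g.r_g for g in gene_rates}
    frames = []
    for m in models:
        if m.gene not in rate_by_gene:
            continue
        sites = m.sites.copy()
        w = weights[sites["channel"].values]
        if mu_normalization == "silent":
            denom = w[sites["synonymous"].values].sum()
        elif mu_normalization == "all_sites":
            denom = w.sum()
        else:
            raise ValueError(f"unknown mu_normalization {mu_normalization!r}")
        if denom <= 0:
            logger.warning("gene %s: zero propensity mass, skipped", m.gene)
            continue
        frames.append(
            pd.DataFrame(
                {
                    "chrom": m.chrom, "pos": sites["pos"], "ref": sites["ref"],
                    "alt": sites["alt"], "gene": m.gene,
                    "channel": sites["channel"],
                    "mu": rate_by_gene[m.gene] * w / denom,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def analyze_cohort(
    records: Sequence[variant_io.VariantRecord],
    hpv_labels: dict[str, str],
    models: Sequence[GeneModel],
    sigs: pd.DataFrame,
    min_mutations: int = 50,
    weight_cutoff: float = 0.06,
    context_profile: str = "reconstructed",
    abundance: str = "exome",
    mu_normalization: str = "silent",
    injected_gene_rates: dict[str, float] | None = None,
    with_net_realized: bool = False,
    with_cluster: bool = False,
    with_group_tests: bool = False,
    welch_scale: str = "log",
) -> PipelineResult:
    """Run the analysis on context-annotated records (the library-level path)."""
    snvs, dnvs = variant_io.collapse_dnvs(list(records))
    fits, spectra = fit_cohort_signatures(snvs, sigs, min_mutations, weight_cutoff)

    if context_profile == "reconstructed":
        try:
            c = sig_mod.mean_context_profile(fits, sigs)
        except ValueError:
            logger.warning("no eligible fits; falling back to raw pooled spectrum")
            c = sig_mod.pooled_spectrum_profile(spectra)
    elif context_profile == "raw":
        c = sig_mod.pooled_spectrum_profile(spectra)
    else:
        raise ValueError(f"unknown context_profile {context_profile!r}")

    ab = rates_mod.exome_channel_abundance(models) if abundance == "exome" else None
    weights = rates_mod.context_site_weights(c, ab)

    n_tumors = len({s for s in hpv_labels} | {r.sample_id for r in snvs})
    if injected_gene_rates is not None:
        gene_rates = [
            rates_mod.GeneRate(gene=g, r_g=r, raw_count=-1, opportunity=np.nan,
                               prior_shape=np.nan, prior_mean=np.nan)
            for g, r in injected_gene_rates.items()
        ]
    else:
        known_genes = {m.gene for m in models}
        silent_genes = [
            r.gene for r in snvs
            if r.consequence == "silent" and r.gene in known_genes
        ]
        silent_counts = (
            pd.Series(silent_genes).value_counts()
            .reindex([m.gene for m in models], fill_value=0)
            .astype(float)
            if silent_genes
            else pd.Series({m.gene: 0.0 for m in models})
        )
        opportunities = pd.Series(
            {m.gene: rates_mod.synonymous_opportunity(m, weights) for m in models}
        )
        gene_rates = rates_mod.estimate_gene_silent_rates(
            silent_counts, opportunities, n_tumors
        )

    mu_table = _mu_table(models, gene_rates, weights, mu_normalization)
    tally, sizes = variant_io.tally_recurrence(snvs, hpv_labels)
    selection = sel_mod.selection_table(tally, sizes, mu_table)

    result = PipelineResult(
        fits=fits, context_profile=c, gene_rates=gene_rates, mu_table=mu_table,
        tally=tally, stratum_sizes=sizes, selection=selection, dnvs=dnvs,
    )

    rec = selection[selection["recurrent_pooled"]]
    amino = rec[rec["consequence"].isin(["missense", "nonsense"])]
    ok = amino[np.isfinite(amino["gamma_pooled"]) & (amino["gamma_pooled"] > 0)]
    if len(ok) >= 4:
        keys = [
            sig_mod.pyrimidine_normalize(t, r, a)
            for t, r, a in zip(ok["trinuc_ref"], ok["ref"], ok["alt"])
        ]
        mask = np.array([sig_mod.is_tcw_tkw(k) for k in keys])
        if mask.sum() >= 2 and (~mask).sum() >= 2:
            result.tcw_comparison = sel_mod.compare_selection_by_context(
                ok["gamma_pooled"][mask], ok["gamma_pooled"][~mask],
                log_scale=(welch_scale == "log"),
            )

    if with_net_realized:
        result.net_realized = _net_realized(snvs, fits, sigs, selection)
    if with_cluster and sum(f.eligible for f in fits) >= 2:
        _, _, newick = sig_mod.cluster_fits(fits)
        result.cluster_newick = newick
    if with_group_tests:
        result.group_tests = _cohort_group_tests(fits, hpv_labels)
    return result


def _net_realized(snvs, fits, sigs, selection) -> pd.DataFrame:
    fit_by_sample = {f.sample_id: f for f in fits}
    carriers: dict[tuple, list[str]] = defaultdict(list)
    meta: dict[tuple, variant_io.VariantRecord] = {}
    for r in snvs:
        carriers[r.variant_id].append(r.sample_id)
        meta.setdefault(r.variant_id, r)
    attributions = {}
    rec = selection[selection["recurrent_pooled"]]
    for _, v in rec.iterrows():
        vid = (v["chrom"], int(v["pos"]), v["ref"], v["alt"])
        key = meta[vid].channel
        alphas = []
        for sample in carriers[vid]:
            fit = fit_by_sample.get(sample)
            if fit is None or not fit.eligible or fit.weights is None:
                continue
            if fit.weights.sum() <= 0:
                continue
            alpha = sig_mod.attribute_signatures(fit, sigs, key)
            if alpha is not None:
                alphas.append(alpha)
        if alphas:
            attributions[vid] = sig_mod.median_attribution(alphas)
    return sel_mod.net_realized_table(rec, attributions)


def _cohort_group_tests(fits, hpv_labels) -> sel_mod.GroupTestResults | None:
    rows = []
    for f in fits:
        status = hpv_labels.get(f.sample_id, "unknown")
        if not f.eligible or status == "unknown":
            continue
        rows.append(
            (status == "positive", sig_mod.apobec_flag(f), f.apobec_weight,
             f.total_mutations)
        )
    if len(rows) < 4:
        return None
    df = pd.DataFrame(rows, columns=["hpv_pos", "apobec", "weight", "load"])
    table = [
        [int(((df.hpv_pos) & (df.apobec)).sum()), int(((df.hpv_pos) & (~df.apobec)).sum())],
        [int(((~df.hpv_pos) & (df.apobec)).sum()), int(((~df.hpv_pos) & (~df.apobec)).sum())],
    ]
    return sel_mod.group_tests(
        table,
        df.loc[df.apobec, "load"].tolist(),
        df.loc[~df.apobec, "load"].tolist(),
        df["weight"].tolist(),
        df["hpv_pos"].tolist(),
    )


def _write(df: pd.DataFrame, path: Path, config_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g",
                  lineterminator="\n")


def analyze_files(
    config: RunConfig,
    with_net_realized: bool = True,
    with_cluster: bool = True,
    with_group_tests: bool = True,
) -> tuple[PipelineResult, list, list]:
    """Read the configured inputs and run the analysis.

    Returns (result, annotated records, HPV calls); stage subcommands use
    this with cheaper flags than the full output bundle.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    if not config.reference:
        raise ValueError("context annotation needs a reference FASTA")
    records, side, rejects = variant_io.read_maf(config.maf)
    records, context_rejects = variant_io.annotate_context(records, config.reference)
    if len(context_rejects):
        _write(context_rejects, out / "rejects_context.tsv", chash)
    if len(rejects):
        _write(rejects, out / "rejects_parse.tsv", chash)

    sigs = (load_signature_matrix(config.signatures) if config.signatures
            else synthetic_signature_catalog())
    calls = hpv_mod.read_hpv_table(config.hpv_table, config.hpv_reads_threshold)
    labels = hpv_mod.labels_from_calls(calls)

    models = toy_exome()  # file-level runs target the bundled toy exome
    result = analyze_cohort(
        records, labels, models, sigs,
        min_mutations=config.min_mutations,
        weight_cutoff=config.weight_cutoff,
        context_profile=config.context_profile,
        abundance=config.abundance,
        mu_normalization=config.mu_normalization,
        with_net_realized=with_net_realized, with_cluster=with_cluster,
        with_group_tests=with_group_tests,
        welch_scale=config.welch_scale,
    )
    return result, records, calls


def run_all(config: RunConfig) -> PipelineResult:
    """File-level pipeline: read inputs, analyze, write the output bundle."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()

    result, records, calls = analyze_files(config)

    # HPV calls + TP53 concordance
    per_sample, summary = hpv_mod.tp53_concordance_report(calls, records)
    _write(per_sample, out / "hpv_calls.tsv", chash)

    # per-tumor weights
    weight_rows = []
    for f in result.fits:
        row = {"sample_id": f.sample_id, "eligible": f.eligible,
               "total_mutations": f.total_mutations,
               "residual_sse": f.residual_sse}
        if f.weights is not None:
            row.update({k: float(v) for k, v in f.weights.items()})
        weight_rows.append(row)
    _write(pd.DataFrame(weight_rows), out / "signature_fits.tsv", chash)
    if result.cluster_newick:
        (out / "signature_clusters.nwk").write_text(result.cluster_newick + "\n")

    _write(
        pd.DataFrame(
            [
                {"gene": g.gene, "r_g": g.r_g, "raw_count": g.raw_count,
                 "opportunity": g.opportunity, "prior_shape": g.prior_shape,
                 "prior_mean": g.prior_mean}
                for g in result.gene_rates
            ]
        ),
        out / "gene_rates.tsv", chash,
    )

    for stratum in ("negative", "positive"):
        ranked = result.selection[result.selection[f"recurrent_{stratum}"]]
        ranked = ranked.sort_values(
            f"gamma_{stratum}", ascending=False, ignore_index=True
        )
        cols = ["gene", "aa_change", "chrom", "pos", "ref", "alt",
                f"n_{stratum}", f"N_{stratum}", "mu",
                f"lambda_{stratum}", f"gamma_{stratum}"]
        _write(ranked[cols], out / f"selection_{stratum}.tsv", chash)

    if result.tcw_comparison is not None:
        _write(
            pd.DataFrame([dataclasses.asdict(result.tcw_comparison)]),
            out / "tcw_comparison.tsv", chash,
        )
    if result.net_realized is not None and len(result.net_realized):
        _write(
            result.net_realized.sort_values("total", ascending=False,
                                            ignore_index=True),
            out / "net_realized.tsv", chash,
        )
    if result.group_tests is not None:
        _write(
            pd.DataFrame([dataclasses.asdict(result.group_tests)]),
            out / "group_tests.tsv", chash,
        )
    logger.info("run complete; outputs in %s (config %s)", out, chash)
    return result
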