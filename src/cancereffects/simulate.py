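"""Generative cohort simulator with known ground truth.

Emulates exactly the statistical world the analysis assumes, inverted into a
generator: each tumor draws signature weights and a passenger mutation count,
passenger channels are sampled from the weight-mixed signature distribution
and placed uniformly among toy-exome sites carrying that channel, and planted
driver sites are carried with probability 1 - exp(-mu * gamma) — the inverse
of the Poisson-corrected prevalence relation, with mu the site's true
expected frequency under the passenger process. Adjacent-SNV (DNV)
contamination and HPV labels round out the inputs the pipeline consumes.

Everything is a pure function of the seed; identical seeds give byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import functools
import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .catalog import SIGNATURE_NAMES, synthetic_signature_catalog
from .channels import CHANNELS
from .genes import GeneModel, toy_exome
from .rates import exome_channel_abundance
from .variant_io import VariantRecord

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PlantedDriver:
    """A designated site under positive selection with known intensity."""

    gene: str
    pos: int  # 1-based contig position
    alt: str
    gamma: float  # selection intensity >= 0
    scope: str = "both"  # both / negative / positive


@dataclasses.dataclass
class CohortConfig:
    """The stated world of the simulator.

    Default stratum sizes and signature-weight means follow the HNSCC cohort
    the analysis was designed around: 451 HPV-negative and 69 HPV-positive
    tumors, APOBEC weights (signatures 2 and 13) averaging 0.11/0.13 in
    HPV-negative and 0.30/0.19 in HPV-positive tumors, with the remainder on
    the aging (1), tobacco (4) and 16 signatures. Per-tumor weights jitter
    around the stratum mean via a Dirichlet draw; per-tumor passenger counts
    are lognormal with median 150 (most tumors clear the >50 eligibility
    threshold, as in the cohort).
    """

    n_negative: int = 451
    n_positive: int = 69
    mean_weights_negative: dict = dataclasses.field(
        default_factory=lambda: {
            "Signature.1": 0.40, "Signature.2": 0.11, "Signature.13": 0.13,
            "Signature.4": 0.20, "Signature.16": 0.16,
        }
    )
    mean_weights_positive: dict = dataclasses.field(
        default_factory=lambda: {
            "Signature.1": 0.30, "Signature.2": 0.30, "Signature.13": 0.19,
            "Signature.4": 0.11, "Signature.16": 0.10,
        }
    )
    dirichlet_concentration: float = 30.0  # 0 disables jitter (fixed weights)
    log_mean_mutations: float = float(np.log(150.0))
    log_sigma_mutations: float = 0.5
    drivers: tuple[PlantedDriver, ...] = ()
    dnv_contamination_rate: float = 0.02
    hpv_reads_positive: tuple[float, float] = (200.0, 5000.0)  # uniform range
    hpv_reads_negative: tuple[float, float] = (0.0, 50.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_negative < 0 or self.n_positive < 0:
            raise ValueError("stratum sizes must be non-negative")
        if not 0 <= self.dnv_contamination_rate <= 1:
            raise ValueError("dnv_contamination_rate must be a probability")
        for d in self.drivers:
            if d.gamma < 0:
                raise ValueError(f"driver {d.gene}:{d.pos} has negative gamma")
            if d.scope not in ("both", "negative", "positive"):
                raise ValueError(f"driver scope {d.scope!r} invalid")


@dataclasses.dataclass
class SyntheticTruth:
    """Ground-truth ledger fully determining expected pipeline outputs."""

    tumor_weights: pd.DataFrame  # sample x 30, realized weights
    gene_rates: pd.Series  # true expected silent mutations per tumor, pooled
    drivers: pd.DataFrame  # gene,pos,ref,alt,gamma,mu per stratum, carriers
    mean_mutations: float  # E[passenger count per tumor]
    context_mixture: pd.DataFrame  # stratum x 96, expected channel mixture


@dataclasses.dataclass
class SimulatedCohort:
    records: list  # VariantRecord, context-annotated
    hpv_table: pd.DataFrame
    truth: SyntheticTruth
    models: list
    signatures: pd.DataFrame


def _weights_array(mean_weights: dict) -> np.ndarray:
    w = np.zeros(len(SIGNATURE_NAMES))
    for name, val in mean_weights.items():
        w[SIGNATURE_NAMES.index(name)] = val
    if w.sum() <= 0 or w.sum() > 1 + 1e-9:
        raise ValueError("mean weights must be positive and sum to at most 1")
    return w / w.sum()


@functools.lru_cache(maxsize=4)
def _site_index(models: tuple[GeneModel, ...]):
    """Flat arrays over every possible (site, alt) pair, grouped by channel."""
    frames = []
    for gi, m in enumerate(models):
        s = m.sites
        frames.append(
            pd.DataFrame(
                {
                    "gene_idx": gi, "pos": s["pos"], "ref": s["ref"],
                    "alt": s["alt"], "context": s["context"],
                    "channel": s["channel"], "consequence": s["consequence"],
                    "aa_change": s["aa_change"],
                }
            )
        )
    pairs = pd.concat(frames, ignore_index=True)
    order = np.argsort(pairs["channel"].values, kind="stable")
    pairs_sorted = pairs.iloc[order].reset_index(drop=True)
    starts = np.searchsorted(pairs_sorted["channel"].values, np.arange(len(CHANNELS) + 1))
    return pairs_sorted, starts


def true_site_mu(
    config: CohortConfig,
    models: Sequence[GeneModel],
    sigs: pd.DataFrame,
) -> dict[str, pd.DataFrame]:
    """True per-(site,alt) expected frequency per stratum.

    mu_h(site) = E[count_h] * q_h(channel) / n_pairs(channel), where q_h is
    the stratum's mean signature mixture restricted to channels that exist in
    the exome.
    """
    abundance = exome_channel_abundance(models)
    P = sigs.values
    mean_m = float(np.exp(config.log_mean_mutations + config.log_sigma_mutations ** 2 / 2))
    out = {}
    for stratum, mean_w in (
        ("negative", config.mean_weights_negative),
        ("positive", config.mean_weights_positive),
    ):
        q = _weights_array(mean_w) @ P
        q = np.where(abundance > 0, q, 0.0)
        q = q / q.sum()
        per_pair = np.zeros(len(CHANNELS))
        present = abundance > 0
        per_pair[present] = mean_m * q[present] / abundance[present]
        frames = []
        for m in models:
            s = m.sites
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": m.chrom, "pos": s["pos"], "ref": s["ref"],
                        "alt": s["alt"], "mu": per_pair[s["channel"].values],
                    }
                )
            )
        out[stratum] = pd.concat(frames, ignore_index=True)
    return out


def simulate_cohort(
    config: CohortConfig,
    models: Sequence[GeneModel] | None = None,
    sigs: pd.DataFrame | None = None,
) -> SimulatedCohort:
    """Generate one cohort; deterministic in ``config.seed``."""
    if models is None:
        models = toy_exome()
    if sigs is None:
        sigs = synthetic_signature_catalog()
    rng = np.random.default_rng(config.seed)
    P = sigs.values
    abundance = exome_channel_abundance(models)
    present = abundance > 0
    pairs, starts = _site_index(tuple(models))
    n_pairs_per_channel = (starts[1:] - starts[:-1]).astype(int)
    # plain arrays for fast row access in the per-tumor loop
    p_gene = pairs["gene_idx"].to_numpy()
    p_pos = pairs["pos"].to_numpy()
    p_ref = pairs["ref"].to_numpy()
    p_alt = pairs["alt"].to_numpy()
    p_ctx = pairs["context"].to_numpy()
    p_cons = pairs["consequence"].to_numpy()
    p_aa = pairs["aa_change"].to_numpy()

    samples = [f"T{idx:04d}" for idx in range(config.n_negative + config.n_positive)]
    strata = ["negative"] * config.n_negative + ["positive"] * config.n_positive

    mean_w = {
        "negative": _weights_array(config.mean_weights_negative),
        "positive": _weights_array(config.mean_weights_positive),
    }
    mu_by_stratum = true_site_mu(config, models, sigs)
    mu_lookup = {
        s: df.set_index(["chrom", "pos", "ref", "alt"])["mu"]
        for s, df in mu_by_stratum.items()
    }

    records: list[VariantRecord] = []
    weight_rows = []
    dropped_mass = []
    for sample, stratum in zip(samples, strata):
        base = mean_w[stratum]
        if config.dirichlet_concentration > 0:
            active = base > 0
            w = np.zeros_like(base)
            w[active] = rng.dirichlet(base[active] * config.dirichlet_concentration)
        else:
            w = base.copy()
        weight_rows.append(w)
        m_count = int(round(float(rng.lognormal(
            config.log_mean_mutations, config.log_sigma_mutations))))
        q = w @ P
        dropped_mass.append(float(q[~present].sum()))
        q = np.where(present, q, 0.0)
        q = q / q.sum()
        channels = rng.choice(len(CHANNELS), size=m_count, p=q)
        offsets = (rng.random(m_count) * n_pairs_per_channel[channels]).astype(int)
        pair_idx = np.unique(starts[channels] + offsets)  # one substitution per site
        for pi in pair_idx:
            model = models[int(p_gene[pi])]
            records.append(
                VariantRecord(
                    sample_id=sample, chrom=model.chrom, pos=int(p_pos[pi]),
                    ref=str(p_ref[pi]), alt=str(p_alt[pi]), gene=model.gene,
                    consequence=str(p_cons[pi]), aa_change=str(p_aa[pi]),
                    trinuc_ref=str(p_ctx[pi]),
                )
            )

    mean_dropped = float(np.mean(dropped_mass)) if dropped_mass else 0.0
    if mean_dropped > 0:
        logger.warning(
            "mean %.4f of channel mass had no matching toy-exome site and was "
            "resampled", mean_dropped,
        )

    # planted drivers: independent Bernoulli carriage per in-scope tumor
    driver_rows = []
    for d in config.drivers:
        model = next(m for m in models if m.gene == d.gene)
        site = model.sites[(model.sites["pos"] == d.pos) & (model.sites["alt"] == d.alt)]
        if site.empty:
            raise ValueError(f"driver {d.gene}:{d.pos}>{d.alt} is not a valid SNV")
        site = site.iloc[0]
        carriers = 0
        mus = {}
        for sample, stratum in zip(samples, strata):
            mu_h = float(mu_lookup[stratum].loc[(model.chrom, d.pos, site["ref"], d.alt)])
            mus[stratum] = mu_h
            if d.scope != "both" and stratum != d.scope:
                continue
            if rng.random() < 1.0 - np.exp(-mu_h * d.gamma):
                carriers += 1
                records.append(
                    VariantRecord(
                        sample_id=sample, chrom=model.chrom, pos=d.pos,
                        ref=site["ref"], alt=d.alt, gene=d.gene,
                        consequence=site["consequence"],
                        aa_change=site["aa_change"], trinuc_ref=site["context"],
                    )
                )
        driver_rows.append(
            {
                "gene": d.gene, "pos": d.pos, "ref": site["ref"], "alt": d.alt,
                "gamma": d.gamma, "scope": d.scope,
                "mu_negative": mus.get("negative", np.nan),
                "mu_positive": mus.get("positive", np.nan),
                "realized_carriers": carriers,
            }
        )

    # DNV contamination: an adjacent same-sample SNV pair
    for sample, stratum in zip(samples, strata):
        if rng.random() >= config.dnv_contamination_rate:
            continue
        model = models[int(rng.integers(0, len(models)))]
        i = int(rng.integers(0, len(model.cds) - 1))  # cds indices i, i+1
        for j in (i, i + 1):
            ref = model.cds[j]
            alts = [b for b in "ACGT" if b != ref]
            alt = alts[int(rng.integers(0, 3))]
            site = model.sites[
                (model.sites["cds_index"] == j) & (model.sites["alt"] == alt)
            ].iloc[0]
            records.append(
                VariantRecord(
                    sample_id=sample, chrom=model.chrom, pos=int(site["pos"]),
                    ref=ref, alt=alt, gene=model.gene,
                    consequence=site["consequence"],
                    aa_change=site["aa_change"], trinuc_ref=site["context"],
                )
            )

    # deduplicate any driver/passenger collision at the same site
    seen = set()
    deduped = []
    for r in records:
        key = (r.sample_id, r.chrom, r.pos, r.ref, r.alt)
        if key in seen:
            continue
        seen.add(key)
        deduped.append(r)
    records = sorted(deduped, key=lambda r: (r.sample_id, r.chrom, r.pos, r.alt))

    # HPV read counts consistent with the stratum labels
    reads = []
    for stratum in strata:
        lo, hi = (config.hpv_reads_positive if stratum == "positive"
                  else config.hpv_reads_negative)
        reads.append(float(np.round(rng.uniform(lo, hi), 3)))
    hpv_table = pd.DataFrame(
        {"sample_id": samples, "hpv_reads_per_1e8": reads}
    )

    # true pooled gene-level silent rates
    n_total = max(config.n_negative + config.n_positive, 1)
    gene_rates = {}
    for m in models:
        syn = m.sites[m.sites["synonymous"]]
        rate = 0.0
        for stratum, n_h in (("negative", config.n_negative),
                             ("positive", config.n_positive)):
            mu_s = mu_lookup[stratum]
            rate += (n_h / n_total) * float(
                mu_s.loc[[(m.chrom, int(p), r, a) for p, r, a in
                          zip(syn["pos"], syn["ref"], syn["alt"])]].sum()
            )
        gene_rates[m.gene] = rate

    mean_m = float(np.exp(config.log_mean_mutations + config.log_sigma_mutations ** 2 / 2))
    truth = SyntheticTruth(
        tumor_weights=pd.DataFrame(weight_rows, index=samples,
                                   columns=list(SIGNATURE_NAMES)),
        gene_rates=pd.Series(gene_rates, name="r_g_true"),
        drivers=pd.DataFrame(driver_rows),
        mean_mutations=mean_m,
        context_mixture=pd.DataFrame(
            {s: np.where(present, _weights_array(w) @ P, 0.0)
             / np.where(present, _weights_array(w) @ P, 0.0).sum()
             for s, w in (("negative", config.mean_weights_negative),
                          ("positive", config.mean_weights_positive))}
        ).T,
    )
    return SimulatedCohort(records=records, hpv_table=hpv_table, truth=truth,
                           models=list(models), signatures=sigs)


def truth_report(
    selection: pd.DataFrame,
    gene_rates: Sequence,
    fits: Sequence,
    truth: SyntheticTruth,
) -> pd.DataFrame:
    """Recovery metrics of pipeline estimates against the simulator's ledger.

    Rows: per-driver relative error of gamma (pooled stratum), per-gene
    relative error of the silent rate, and the mean L1 error of recovered
    signature weights over eligible tumors.
    """
    rows = []
    for _, d in truth.drivers.iterrows():
        hit = selection[
            (selection["chrom"] == d["gene"]) & (selection["pos"] == d["pos"])
            & (selection["alt"] == d["alt"])
        ]
        gamma_hat = float(hit["gamma_pooled"].iloc[0]) if len(hit) else np.nan
        rel = gamma_hat / d["gamma"] - 1.0 if d["gamma"] > 0 else np.nan
        rows.append(
            {
                "metric": "driver_gamma", "name": f"{d['gene']}:{d['pos']}{d['alt']}",
                "truth": d["gamma"], "estimate": gamma_hat, "relative_error": rel,
            }
        )
    for gr in gene_rates:
        true_r = truth.gene_rates.get(gr.gene, np.nan)
        rows.append(
            {
                "metric": "gene_rate", "name": gr.gene, "truth": true_r,
                "estimate": gr.r_g,
                "relative_error": gr.r_g / true_r - 1.0 if true_r > 0 else np.nan,
            }
        )
    l1 = []
    for f in fits:
        if not f.eligible or f.weights is None:
            continue
        true_w = truth.tumor_weights.loc[f.sample_id].values
        l1.append(float(np.abs(f.weights.values - true_w).sum()))
    if l1:
        rows.append(
            {
                "metric": "signature_weights_l1", "name": "mean_over_tumors",
                "truth": 0.0, "estimate": float(np.mean(l1)),
                "relative_error": np.nan,
            }
        )
    return pd.DataFrame(rows)


def synthetic_recurrent_variant_tables(seed: int = 314) -> pd.DataFrame:
    """SYNTHETIC stand-in for the published recurrent-substitution tables.

    The real supplementary tables of recurrent amino-acid substitutions in
    the 525-exome HNSCC cohort are not redistributable here; this constructs
    a table with the same census structure so the motif classifier and the
    shared-variant intersection can be exercised: 314 distinct recurrent
    amino-acid substitutions across the HPV-negative and HPV-positive sets,
    62 of them in TCW->TKW context, and exactly four variants shared between
    the strata (MAPK1 E322K, PIK3CA E542K, PIK3CA E545K, FBXW7 R505G). All
    coordinates and contexts other than the census constraints are fabricated.

    Columns: gene, aa_change, chrom, pos, ref, alt, context (pyrimidine
    strand 3-mer), context_alt (pyrimidine-strand alternate), hpv_negative,
    hpv_positive (recurrence flags per stratum).
    """
    rng = np.random.default_rng(seed)
    tcw_contexts = [("TCA", "T"), ("TCA", "G"), ("TCT", "T"), ("TCT", "G")]
    non_tkw = [
        (k.context, k.alt) for k in CHANNELS
        if not (k.context in ("TCA", "TCT") and k.alt in ("T", "G"))
    ]

    shared = [
        # the four substitutions recurrent in both strata; the PIK3CA helical
        # domain sites and FBXW7 R505G carry the APOBEC motif
        ("MAPK1", "E322K", "GCC", "T", False),
        ("PIK3CA", "E542K", "TCT", "T", True),
        ("PIK3CA", "E545K", "TCT", "T", True),
        ("FBXW7", "R505G", "TCA", "G", True),
    ]

    rows = []
    n_total, n_tkw = 314, 62
    n_tkw_remaining = n_tkw - sum(1 for s in shared if s[4])
    for gene, aa, ctx, alt, _ in shared:
        rows.append((gene, aa, ctx, alt, True, True))
    for i in range(n_total - len(shared)):
        is_tkw = i < n_tkw_remaining
        if is_tkw:
            ctx, alt = tcw_contexts[int(rng.integers(0, len(tcw_contexts)))]
        else:
            ctx, alt = non_tkw[int(rng.integers(0, len(non_tkw)))]
        gene = f"SYNG{i:03d}"
        aa = f"A{int(rng.integers(2, 900))}V"
        # HPV-negative recurrences dominate the published sets
        in_neg = bool(rng.random() < 0.92)
        in_pos = not in_neg
        rows.append((gene, aa, ctx, alt, in_neg, in_pos))

    df = pd.DataFrame(
        rows, columns=["gene", "aa_change", "context", "context_alt",
                       "hpv_negative", "hpv_positive"],
    )
    df.insert(2, "chrom", [f"chr{1 + i % 22}" for i in range(len(df))])
    df.insert(3, "pos", rng.integers(10_000, 5_000_000, size=len(df)))
    df.insert(4, "ref", [c[1] for c in df["context"]])
    df.insert(5, "alt", df["context_alt"])
    return df
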