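"""Expected mutation frequencies: gene-level silent rates to per-site mu.

The expected frequency mu of a specific nucleotide change, per tumor and
before selection, is built in two steps:

1. A gene-level silent mutation rate r_g (expected silent mutations per
   tumor in gene g) is estimated from cohort-wide silent counts by a
   gamma-Poisson empirical-Bayes model: count_g ~ Poisson(N * theta * O_g *
   u_g) with gene effect u_g ~ Gamma(shape k, mean 1). theta (exome-wide rate
   per unit synonymous opportunity) and k are fit by method of moments, and
   r_g is the posterior mean theta * O_g * (k + count_g) / (k + N*theta*O_g)
   — shrunken between the pooled prior mean and the per-gene MLE. This is a
   deliberately lean replacement for full covariate-regression machinery;
   externally computed per-gene rates can be injected instead.

2. r_g is distributed over the gene's possible single-nucleotide changes in
   proportion to a per-channel propensity derived from the cohort's
   trinucleotide context profile c, anchored on the synonymous sites:

       mu(site, alt) = r_g * w(key) / sum_{synonymous (s,a) in g} w(key(s,a))

   so that the synonymous mu's sum exactly to r_g, and non-synonymous sites
   inherit the calibration. By default w(k) = c(k) / A(k) where A(k) is the
   exome-wide count of (site, alt) pairs in channel k: c is a distribution
   over *mutations*, so the per-site propensity must divide out how many
   sites share the channel. w(k) = c(k) (no abundance normalization) is
   available via ``abundance=None``.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .channels import CHANNELS
from .genes import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_RATE_FLOOR = 1e-8  # theta floor when the cohort has zero silent counts


@dataclasses.dataclass(frozen=True)
class GeneRate:
    gene: str
    r_g: float  # expected silent mutations per tumor
    raw_count: int
    opportunity: float
    prior_shape: float  # k (inf = no shrinkage beyond pooling)
    prior_mean: float  # theta * O_g

    def __post_init__(self):
        if not (self.r_g >= 0 and np.isfinite(self.r_g)):
            raise ValueError(f"{self.gene}: invalid rate {self.r_g}")


def exome_channel_abundance(models: Sequence[GeneModel]) -> np.ndarray:
    """Exome-wide count of possible (site, alt) pairs per 96-channel."""
    counts = np.zeros(len(CHANNELS), dtype=float)
    for m in models:
        counts += np.bincount(m.sites["channel"].values, minlength=len(CHANNELS))
    return counts


def context_site_weights(c: np.ndarray, abundance: np.ndarray | None) -> np.ndarray:
    """Per-channel per-site propensity from the mutation-channel profile c.

    With ``abundance`` given, channels are down-weighted by how many exome
    sites share them (w = c / A); channels absent from the exome get weight 0.
    """
    c = np.asarray(c, dtype=float)
    if c.shape != (len(CHANNELS),):
        raise ValueError("context profile must have 96 channels")
    if not np.isclose(c.sum(), 1.0, atol=1e-6):
        raise ValueError("context profile must sum to 1")
    if abundance is None:
        return c.copy()
    w = np.zeros_like(c)
    present = abundance > 0
    w[present] = c[present] / abundance[present]
    return w


def synonymous_opportunity(model: GeneModel, weights: np.ndarray) -> float:
    """O_g: total per-site propensity mass on the gene's synonymous changes."""
    syn = model.sites.loc[model.sites["synonymous"], "channel"].values
    return float(weights[syn].sum())


def estimate_gene_silent_rates(
    silent_counts: pd.Series,
    opportunities: pd.Series,
    n_tumors: int,
    rate_floor: float = DEFAULT_RATE_FLOOR,
) -> list[GeneRate]:
    """Empirical-Bayes gene-level silent rates from cohort silent counts.

    ``silent_counts`` and ``opportunities`` are indexed by gene; genes with
    zero opportunity are excluded with a warning. Requires at least 2
    informative genes.
    """
    genes = opportunities.index
    silent_counts = silent_counts.reindex(genes).fillna(0).astype(int)
    informative = opportunities > 0
    excluded = list(genes[~informative])
    if excluded:
        logger.warning("genes with zero synonymous opportunity excluded: %s", excluded)
    O = opportunities[informative].astype(float)
    y = silent_counts[informative]
    if len(O) < 2:
        raise ValueError("need at least 2 genes with positive synonymous opportunity")

    total = int(y.sum())
    if total == 0:
        logger.warning("all silent counts zero; using configured rate floor")
        theta = rate_floor
        k = np.inf
    else:
        theta = total / (n_tumors * O.sum())
        m = n_tumors * theta * O  # expected counts under full pooling
        # moment estimate of the gamma shape from excess-Poisson dispersion
        dispersion = float(((y - m) ** 2 - m).sum() / (m ** 2).sum())
        if dispersion <= 0:
            logger.warning("no excess dispersion; gene effects fully pooled (k=inf)")
            k = np.inf
        else:
            k = 1.0 / dispersion

    rates = []
    for g in O.index:
        prior_mean = theta * O[g]
        if np.isinf(k):
            r = prior_mean
        else:
            r = prior_mean * (k + y[g]) / (k + n_tumors * theta * O[g])
        rates.append(
            GeneRate(
                gene=g, r_g=float(r), raw_count=int(y[g]),
                opportunity=float(O[g]), prior_shape=float(k),
                prior_mean=float(prior_mean),
            )
        )
    return rates


def read_gene_rate_table(path: str | Path) -> dict[str, float]:
    """Inject externally computed per-gene silent rates (TSV: gene, r_g)."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "r_g" not in df.columns:
        raise ValueError("rate table needs columns 'gene' and 'r_g'")
    return dict(zip(df["gene"], df["r_g"].astype(float)))


def site_frequency_table(
    model: GeneModel,
    r_g: float,
    weights: np.ndarray,
) -> pd.DataFrame:
    """mu for every possible SNV in the gene (columns of ``GeneModel.sites``
    plus ``mu``). The synonymous mu's sum to r_g exactly."""
    sites = model.sites.copy()
    w = weights[sites["channel"].values]
    denom = w[sites["synonymous"].values].sum()
    if denom <= 0:
        raise ValueError(
            f"gene {model.gene}: zero propensity mass on synonymous sites, "
            "mu undefined"
        )
    sites["mu"] = r_g * w / denom
    return sites


def site_mutation_frequency(
    model: GeneModel,
    r_g: float,
    weights: np.ndarray,
    pos: int,
    alt: str,
) -> float:
    """mu for one (contig position, alt) change in the gene."""
    table = site_frequency_table(model, r_g, weights)
    row = table[(table["pos"] == pos) & (table["alt"] == alt)]
    if row.empty:
        raise ValueError(f"gene {model.gene}: no SNV at pos {pos} alt {alt}")
    return float(row["mu"].iloc[0])
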