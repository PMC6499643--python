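"""Selection intensities and process-level (net realized) effect sizes.

The prevalence p = n/N of a recurrent variant understates the substitution
flux because a site can only be observed mutated once per tumor even though
mutations arrive as a Poisson stream; the per-tumor flux is recovered by the
exact inversion

    lambda = -ln(1 - p).

Dividing by the expected mutation frequency gives the selection intensity

    gamma = lambda / mu,

the factor by which somatic selection inflated the variant above mutational
expectation during intratumoral fixation. The net realized selection
intensity of a variant under a mutational process j is the prevalence-
weighted mean of alpha_j * gamma * p across the HPV strata:

    [p_1 (alpha_j gamma p_1) + p_2 (alpha_j gamma p_2)] / (p_1 + p_2)

where alpha_j is the (median, across carrier tumors) probability that the
underlying nucleotide change was generated by signature j.

Group comparisons used downstream: one-sided Welch t-test on log10 gamma
(APOBEC-motif vs other variants), Fisher's exact test by full hypergeometric
enumeration, tie-corrected Wilcoxon rank-sum, and a logistic regression of
HPV status on total APOBEC weight.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .catalog import SIGNATURE_NAMES

#: Signature groups reported for net realized selection intensities.
SIGNATURE_GROUPS = ("Signature.1", "Signature.2", "Signature.13",
                    "Signature.4", "Signature.16", "other")


def observed_frequency(n: int, N: int) -> float:
    """Poisson-corrected per-tumor substitution flux lambda = -ln(1 - n/N).

    Undefined (returns NaN) when every tumor carries the variant (n == N).
    """
    if not 0 <= n <= N:
        raise ValueError(f"carrier count {n} outside [0, {N}]")
    if n == N:
        return float("nan")
    return -math.log1p(-n / N)


def selection_intensity(lam: float, mu: float) -> float:
    """gamma = lambda / mu."""
    if mu <= 0:
        raise ValueError("mu must be positive (no mutation-rate support)")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    return lam / mu


def net_realized(p_h0: float, p_h1: float, alpha: float, gamma: float) -> float:
    """Prevalence-weighted mean of alpha*gamma*p over the two HPV strata."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    if gamma < 0:
        raise ValueError("gamma must be non-negative")
    if p_h0 + p_h1 <= 0:
        return float("nan")  # not recurrent in either stratum
    return (p_h0 * (alpha * gamma * p_h0) + p_h1 * (alpha * gamma * p_h1)) / (
        p_h0 + p_h1
    )


@dataclasses.dataclass
class WelchResult:
    statistic: float
    pvalue: float
    df: float
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    log_scale: bool


def compare_selection_by_context(
    gamma_tcw: Sequence[float],
    gamma_other: Sequence[float],
    log_scale: bool = True,
) -> WelchResult:
    """One-sided Welch t-test of mean(TCW->TKW gamma) < mean(other gamma).

    Run on log10-transformed gamma by default because selection intensities
    span orders of magnitude; the raw scale is available via ``log_scale``.
    """
    a = np.asarray(gamma_tcw, dtype=float)
    b = np.asarray(gamma_other, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 selection intensities per group")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if log_scale:
        if (a <= 0).any() or (b <= 0).any():
            raise ValueError("log-scale comparison requires positive gamma")
        a, b = np.log10(a), np.log10(b)
    res = scipy.stats.ttest_ind(a, b, equal_var=False, alternative="less")
    return WelchResult(
        statistic=float(res.statistic), pvalue=float(res.pvalue),
        df=float(res.df), n_a=len(a), n_b=len(b),
        median_a=med_a, median_b=med_b, log_scale=log_scale,
    )


def fisher_exact(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher's exact p for a 2x2 table by hypergeometric enumeration.

    Enumerates every table with the observed margins and sums the
    probabilities of tables no more probable than the observed one (with a
    relative tolerance guarding float ties).
    """
    (a, b), (c, d) = table
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    row1, col1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - n), min(row1, col1)
    rv = scipy.stats.hypergeom(n, col1, row1)
    probs = rv.pmf(np.arange(lo, hi + 1))
    p_obs = rv.pmf(a)
    return float(probs[probs <= p_obs * (1 + 1e-7)].sum())


@dataclasses.dataclass
class GroupTestResults:
    fisher_p: float
    wilcoxon_stat: float
    wilcoxon_p: float
    logistic_slope: float | None
    logistic_p: float | None
    logistic_separation: bool


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided rank-sum test, normal approximation with tie correction."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:  # degenerate group: no test
        return float("nan"), float("nan")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # all values tied: no evidence either way
        return 0.0, 1.0
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def logistic_hpv_on_apobec(
    apobec_weight: Sequence[float],
    hpv_positive: Sequence[bool],
) -> tuple[float | None, float | None, bool]:
    """Logistic regression (IRLS) of HPV status on total APOBEC weight.

    Returns (slope, Wald p, separation_flag); on (quasi-)separation the
    estimates are unreliable and reported as None.
    """
    import warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    x = sm.add_constant(np.asarray(apobec_weight, dtype=float))
    yv = np.asarray(hpv_positive, dtype=float)
    try:
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.GLM(yv, x, family=sm.families.Binomial()).fit(maxiter=100)
        if any(issubclass(w.category, PerfectSeparationWarning) for w in caught):
            return None, None, True
    except Exception:
        return None, None, True
    slope = float(fit.params[1])
    if not np.isfinite(slope) or abs(slope) > 1e3 or not np.isfinite(fit.bse[1]):
        return None, None, True
    return slope, float(fit.pvalues[1]), False


def group_tests(
    apobec_table: Sequence[Sequence[int]],
    load_with_apobec: Sequence[float],
    load_without_apobec: Sequence[float],
    apobec_weight: Sequence[float],
    hpv_positive: Sequence[bool],
) -> GroupTestResults:
    """The cohort-level association tests reported alongside the fits.

    ``apobec_table`` is the 2x2 of (HPV status x APOBEC signature presence);
    the two load vectors are per-tumor SNV counts split by APOBEC presence.
    """
    w_stat, w_p = wilcoxon_rank_sum(load_with_apobec, load_without_apobec)
    slope, p, sep = logistic_hpv_on_apobec(apobec_weight, hpv_positive)
    return GroupTestResults(
        fisher_p=fisher_exact(apobec_table),
        wilcoxon_stat=w_stat, wilcoxon_p=w_p,
        logistic_slope=slope, logistic_p=p, logistic_separation=sep,
    )


def selection_table(
    tally: pd.DataFrame,
    stratum_sizes: dict[str, int],
    mu_table: pd.DataFrame,
) -> pd.DataFrame:
    """Per-variant selection results across strata.

    ``tally`` is the output of ``variant_io.tally_recurrence``; ``mu_table``
    carries columns ``chrom, pos, ref, alt, mu``. Returns one row per variant
    with per-stratum prevalence/lambda/gamma (HPV-negative, HPV-positive,
    pooled over labelled samples) and per-stratum recurrence flags (carrier
    count >= 2 within the stratum being reported). Variants without positive
    mu support are dropped; variants carried by every tumor of a stratum get
    lambda (hence gamma) NaN there.
    """
    df = tally.merge(
        mu_table[["chrom", "pos", "ref", "alt", "mu"]],
        on=["chrom", "pos", "ref", "alt"],
        how="inner",
    )
    df = df[df["mu"] > 0].reset_index(drop=True)
    n_neg = stratum_sizes.get("negative", 0)
    n_pos = stratum_sizes.get("positive", 0)
    for stratum, n_carrier, N in (
        ("negative", df["n_negative"].to_numpy(), n_neg),
        ("positive", df["n_positive"].to_numpy(), n_pos),
        ("pooled", (df["n_negative"] + df["n_positive"]).to_numpy(), n_neg + n_pos),
    ):
        if N == 0:
            p = np.full(len(df), np.nan)
            lam = np.full(len(df), np.nan)
            rec = np.zeros(len(df), dtype=bool)
        else:
            p = n_carrier / N
            with np.errstate(divide="ignore"):
                lam = np.where(n_carrier == N, np.nan, -np.log1p(-np.minimum(p, 1 - 1e-15)))
                lam = np.where(n_carrier == 0, 0.0, lam)
            rec = n_carrier >= 2
        df[f"n_{stratum}"] = n_carrier
        df[f"N_{stratum}"] = N
        df[f"p_{stratum}"] = p
        df[f"lambda_{stratum}"] = lam
        df[f"gamma_{stratum}"] = lam / df["mu"].to_numpy()
        df[f"recurrent_{stratum}"] = rec
    return df


def net_realized_table(
    selection: pd.DataFrame,
    attributions: dict[tuple[str, int, str, str], np.ndarray],
) -> pd.DataFrame:
    """Net realized selection intensity per variant and signature group.

    Uses the pooled-cohort gamma with stratum prevalences. ``attributions``
    maps variant identity to its 30-long median attribution vector. Group
    columns for signatures {1, 2, 13, 4, 16} and 'other' sum to the
    all-signature total.
    """
    rows = []
    for _, v in selection.iterrows():
        vid = (v["chrom"], int(v["pos"]), v["ref"], v["alt"])
        alpha = attributions.get(vid)
        if alpha is None:
            continue
        gamma = v["gamma_pooled"]
        if not np.isfinite(gamma):
            continue
        p0, p1 = v["p_negative"], v["p_positive"]
        if not (np.isfinite(p0) and np.isfinite(p1)):
            continue
        row = {
            "chrom": vid[0], "pos": vid[1], "ref": vid[2], "alt": vid[3],
            "gene": v["gene"], "aa_change": v["aa_change"],
            "gamma_pooled": gamma,
        }
        per_sig = np.array(
            [net_realized(p0, p1, float(a), float(gamma)) for a in alpha]
        )
        total = float(per_sig.sum())
        for group in SIGNATURE_GROUPS[:-1]:
            row[group] = float(per_sig[SIGNATURE_NAMES.index(group)])
        row["other"] = total - sum(row[g] for g in SIGNATURE_GROUPS[:-1])
        row["total"] = total
        rows.append(row)
    return pd.DataFrame(rows)
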