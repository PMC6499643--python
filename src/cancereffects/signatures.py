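"""Spectrum construction and COSMIC signature refitting.

Each tumor's SNVs are binned into the 96 trinucleotide channels; tumors with
more than ``min_mutations`` SNVs are deconvolved against the fixed
30-signature catalogue by iterative forward selection: at every round each
candidate signature's weight is optimized on its feasible interval by
golden-section search with all other weights held fixed, the best-improving
signature is accepted, and selection stops when the residual-norm improvement
drops below tolerance. Weights below the discard cutoff (default 0.06) are
zeroed and the survivors re-optimized once — the refitting scheme popularized
by deconstructSigs, re-implemented here from scratch.

Also provides per-mutation signature attribution (the posterior probability
that a mutation in channel k arose from signature j given the tumor's
weights), the APOBEC presence flag (any weight on signatures 2 or 13), the
TCW->TKW motif classifier, and complete-linkage clustering of weight
profiles.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .catalog import APOBEC_SIGNATURES, SIGNATURE_NAMES, validate_signature_matrix
from .channels import (  # noqa: F401 (is_tcw_tkw/pyrimidine_normalize re-exported)
    CHANNEL_INDEX,
    CHANNELS,
    ChannelKey,
    is_tcw_tkw,
    pyrimidine_normalize,
)
from .variant_io import VariantRecord

DEFAULT_MIN_MUTATIONS = 50
DEFAULT_WEIGHT_CUTOFF = 0.06
# stop when adding a signature improves the residual NORM (sqrt SSE) by less
# than this; on the squared scale the same threshold would mask flat
# low-weight signatures entirely, since channel fractions are O(1/96)
_NORM_IMPROVEMENT_TOL = 1e-3
_GOLDEN = (np.sqrt(5) - 1) / 2


@dataclasses.dataclass
class TrinucSpectrum:
    """96-channel mutation counts for one sample."""

    counts: np.ndarray  # int, length 96, COSMIC channel order
    sample_id: str = ""

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.shape != (len(CHANNELS),):
            raise ValueError("spectrum must have 96 channels")
        if (self.counts < 0).any():
            raise ValueError("negative channel count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def fractions(self) -> np.ndarray:
        if self.total == 0:
            raise ValueError("fractions undefined for an empty spectrum")
        return self.counts / self.total


@dataclasses.dataclass
class SignatureFit:
    """Per-tumor signature weights; ``weights`` is None when ineligible."""

    sample_id: str
    weights: pd.Series | None
    residual_sse: float
    eligible: bool
    total_mutations: int

    def weight(self, name: str) -> float:
        if self.weights is None:
            raise ValueError(f"fit for {self.sample_id} is not eligible")
        return float(self.weights[name])

    @property
    def apobec_weight(self) -> float:
        return sum(self.weight(s) for s in APOBEC_SIGNATURES)


def build_spectrum(snvs: Iterable[VariantRecord], sample_id: str = "") -> TrinucSpectrum:
    """Bin context-annotated SNVs of one sample into the 96 channels."""
    counts = np.zeros(len(CHANNELS), dtype=int)
    for r in snvs:
        counts[CHANNEL_INDEX[r.channel]] += 1
    return TrinucSpectrum(counts, sample_id=sample_id)


def _golden_min(b: np.ndarray, a: np.ndarray, hi: np.ndarray,
                iterations: int = 34) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized golden-section minimization of g(x) = -2 b x + a x^2 on [0, hi].

    Returns (argmin, g(argmin)). ``a`` must be strictly positive. 34
    bracket contractions localize the optimum to ~1e-7 of the unit interval.
    """
    lo = np.zeros_like(hi, dtype=float)
    hi = hi.astype(float).copy()
    b2 = 2.0 * b
    for _ in range(iterations):
        span = _GOLDEN * (hi - lo)
        x1 = hi - span
        x2 = lo + span
        take_left = x1 * (a * x1 - b2) < x2 * (a * x2 - b2)
        hi = np.where(take_left, x2, hi)
        lo = np.where(take_left, lo, x1)
    x = (lo + hi) / 2.0
    return x, x * (a * x - b2)


def _golden_min_scalar(b: float, a: float, hi: float, iterations: int = 34) -> float:
    """Scalar twin of :func:`_golden_min`; returns the argmin only."""
    lo = 0.0
    b2 = 2.0 * b
    for _ in range(iterations):
        span = _GOLDEN * (hi - lo)
        x1 = hi - span
        x2 = lo + span
        if x1 * (a * x1 - b2) < x2 * (a * x2 - b2):
            hi = x2
        else:
            lo = x1
    return (lo + hi) / 2.0


def deconvolve(
    spectrum: TrinucSpectrum,
    sigs: pd.DataFrame,
    min_mutations: int = DEFAULT_MIN_MUTATIONS,
    weight_cutoff: float = DEFAULT_WEIGHT_CUTOFF,
) -> SignatureFit:
    """Refit one tumor spectrum against the signature catalogue.

    Tumors with ``total <= min_mutations`` are ineligible (the eligibility
    rule is strictly *greater than* the threshold). Weights are non-negative
    and sum to at most 1; every surviving weight is at least ``weight_cutoff``.
    """
    sigs = validate_signature_matrix(sigs)
    total = spectrum.total
    if total <= min_mutations:
        return SignatureFit(spectrum.sample_id, None, float("nan"), False, total)

    f = spectrum.fractions.astype(float)
    P = sigs.values  # (n_sig, 96)
    n_sig = P.shape[0]
    a = np.einsum("jk,jk->j", P, P)  # ||P_j||^2
    w = np.zeros(n_sig)

    def sse_of(wvec: np.ndarray) -> float:
        r = f - wvec @ P
        return float(r @ r)

    current_sse = sse_of(w)
    for _ in range(200):  # forward selection rounds
        r = f - w @ P
        rP = P @ r
        # candidate j re-optimizes its own weight with the rest held fixed
        b = rP + w * a
        base = current_sse + 2.0 * w * rP + (w ** 2) * a  # ||r_{-j}||^2
        cap = 1.0 - w.sum() + w
        x, g = _golden_min(b, a, cap)
        cand_sse = base + g
        j = int(np.argmin(cand_sse))
        if (np.sqrt(current_sse) - np.sqrt(max(cand_sse[j], 0.0))
                < _NORM_IMPROVEMENT_TOL):
            break
        w[j] = x[j]
        current_sse = sse_of(w)

    def reoptimize_once(wvec: np.ndarray) -> np.ndarray:
        wvec = wvec.copy()
        for j in np.flatnonzero(wvec > 0):
            r_minus = f - wvec @ P + wvec[j] * P[j]
            wvec[j] = _golden_min_scalar(
                float(r_minus @ P[j]), float(a[j]),
                1.0 - float(wvec.sum()) + float(wvec[j]),
            )
        return wvec

    w[w < weight_cutoff] = 0.0
    w = reoptimize_once(w)
    w[w < weight_cutoff] = 0.0  # a re-optimized weight may dip under the cutoff

    fit_w = pd.Series(w, index=list(sigs.index))
    return SignatureFit(spectrum.sample_id, fit_w, sse_of(w), True, total)


def apobec_flag(fit: SignatureFit) -> bool:
    """True iff the fit puts any weight on the APOBEC signatures (2 or 13)."""
    if not fit.eligible:
        raise ValueError(f"APOBEC flag undefined for ineligible fit {fit.sample_id}")
    return fit.apobec_weight > 0


def mean_context_profile(
    fits: Sequence[SignatureFit],
    sigs: pd.DataFrame,
) -> np.ndarray:
    """Tissue-wide 96-channel context profile from signature-reconstructed tumors.

    Each eligible tumor contributes its denoised channel distribution (its
    weight vector through the signature matrix, renormalized); the profile is
    the unweighted mean over tumors, renormalized to sum 1.
    """
    sigs = validate_signature_matrix(sigs)
    P = sigs.values
    recons = []
    for fit in fits:
        if not fit.eligible or fit.weights is None:
            continue
        w = fit.weights.reindex(list(sigs.index)).values
        if w.sum() <= 0:
            continue
        recon = w @ P
        recons.append(recon / recon.sum())
    if not recons:
        raise ValueError(
            "no eligible tumors with nonzero weights; fall back to the raw "
            "pooled spectrum profile (pooled_spectrum_profile) if intended"
        )
    c = np.mean(recons, axis=0)
    return c / c.sum()


def pooled_spectrum_profile(spectra: Sequence[TrinucSpectrum]) -> np.ndarray:
    """Raw-counts fallback for the tissue context profile."""
    counts = np.sum([s.counts for s in spectra], axis=0)
    total = counts.sum()
    if total == 0:
        raise ValueError("no mutations in pooled spectra")
    return counts / total


def attribute_signatures(
    fit: SignatureFit,
    sigs: pd.DataFrame,
    key: ChannelKey,
) -> np.ndarray | None:
    """Per-signature attribution of a mutation in channel ``key`` for one tumor.

    alpha_j = w_j P_j(key) / sum_j' w_j' P_j'(key); sums to 1. Returns None
    when the tumor's mixture has no mass on the channel.
    """
    if not fit.eligible or fit.weights is None:
        raise ValueError(f"attribution undefined for ineligible fit {fit.sample_id}")
    sigs = validate_signature_matrix(sigs)
    w = fit.weights.reindex(list(sigs.index)).values
    if w.sum() <= 0:
        raise ValueError(f"fit {fit.sample_id} has all-zero weights")
    col = sigs.values[:, CHANNEL_INDEX[key]]
    mass = w * col
    denom = mass.sum()
    if denom <= 0:
        return None
    return mass / denom


def median_attribution(alphas: Sequence[np.ndarray]) -> np.ndarray:
    """Componentwise median over carrier tumors, renormalized to sum 1."""
    if len(alphas) == 0:
        raise ValueError("no carrier attributions")
    med = np.median(np.vstack(alphas), axis=0)
    s = med.sum()
    if s <= 0:
        raise ValueError("median attribution degenerate (all zeros)")
    return med / s


def cluster_fits(
    fits: Sequence[SignatureFit],
) -> tuple[np.ndarray, list[str], str]:
    """Complete-linkage agglomeration of tumors in signature-weight space.

    Rows are sorted lexicographically by sample id before clustering so the
    result is independent of input order. Returns the scipy linkage matrix,
    the dendrogram leaf order (sample ids), and a Newick rendering.
    """
    eligible = sorted(
        (f for f in fits if f.eligible and f.weights is not None),
        key=lambda f: f.sample_id,
    )
    if len(eligible) < 2:
        raise ValueError("clustering needs at least 2 eligible tumors")
    ids = [f.sample_id for f in eligible]
    X = np.vstack([f.weights.reindex(list(SIGNATURE_NAMES)).values for f in eligible])
    Z = hierarchy.linkage(pdist(X, metric="euclidean"), method="complete")
    leaves = hierarchy.leaves_list(Z)
    leaf_order = [ids[i] for i in leaves]
    newick = _to_newick(hierarchy.to_tree(Z), ids)
    return Z, leaf_order, newick


def _to_newick(node, ids: list[str]) -> str:
    def render(n, parent_height: float) -> str:
        length = parent_height - n.dist
        if n.is_leaf():
            return f"{ids[n.id]}:{length:.6g}"
        left = render(n.left, n.dist)
        right = render(n.right, n.dist)
        return f"({left},{right}):{length:.6g}"

    left = render(node.left, node.dist)
    right = render(node.right, node.dist)
    return f"({left},{right});"
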