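"""Mutational-signature catalogue: loading, validation, and a synthetic stand-in.

The analysis refits tumor spectra against the fixed catalogue of 30 COSMIC
(v2) signatures. The catalogue itself is third-party reference data that may
not be redistributable or present; :func:`synthetic_signature_catalog` builds
a SYNTHETIC stand-in with the same shape and the qualitative character the
analysis relies on, and :func:`load_signature_matrix` accepts the real COSMIC
TSV when the user has it.

Internal representation: a DataFrame with one row per signature
(``Signature.1`` ... ``Signature.30``) and one column per channel in COSMIC
order (``A[C>A]A`` style); each row sums to 1.
"""

from __future__ import annotations

import weakref
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import CHANNELS, ChannelKey, parse_cosmic_label

N_SIGNATURES = 30
SIGNATURE_NAMES = tuple(f"Signature.{i}" for i in range(1, N_SIGNATURES + 1))
CHANNEL_LABELS = tuple(k.cosmic_label() for k in CHANNELS)

#: Signatures attributed to APOBEC cytidine deaminase activity.
APOBEC_SIGNATURES = ("Signature.2", "Signature.13")

_ROW_SUM_TOL = 1e-6
_canonical_cache: dict[int, pd.DataFrame] = {}


def validate_signature_matrix(sigs: pd.DataFrame) -> pd.DataFrame:
    """Check shape, non-negativity and row sums; return in canonical order.

    Frames that already passed validation return their cached canonical form
    (id-keyed, dropped on gc), so per-tumor refitting does not re-validate
    the same catalogue.
    """
    cached = _canonical_cache.get(id(sigs))
    if cached is not None:
        return cached
    original = sigs
    missing = [c for c in CHANNEL_LABELS if c not in sigs.columns]
    if missing:
        raise ValueError(f"signature matrix missing channels, e.g. {missing[:3]}")
    sigs = sigs.loc[:, list(CHANNEL_LABELS)]
    if (sigs.values < 0).any():
        raise ValueError("signature matrix has negative entries")
    sums = sigs.sum(axis=1)
    bad = sums[(sums - 1.0).abs() > _ROW_SUM_TOL]
    if len(bad):
        raise ValueError(f"signature rows do not sum to 1: {list(bad.index)[:3]}")
    _canonical_cache[id(original)] = sigs
    weakref.finalize(original, _canonical_cache.pop, id(original), None)
    return sigs


def load_signature_matrix(path: str | Path) -> pd.DataFrame:
    """Load a channels-by-signatures TSV (96 rows keyed ``A[C>A]A``-style)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    for label in df.index:
        parse_cosmic_label(str(label))  # raises on malformed keys
    if len(df.index) != len(CHANNELS):
        raise ValueError(f"expected {len(CHANNELS)} channel rows, got {len(df.index)}")
    return validate_signature_matrix(df.T)


def write_signature_matrix(sigs: pd.DataFrame, path: str | Path) -> None:
    sigs.T.to_csv(path, sep="\t", index_label="channel", lineterminator="\n")


def _peaked(channels: dict[ChannelKey, float], background: float,
            rng: np.random.Generator) -> np.ndarray:
    """A signature with stated peak mass plus a jittered uniform floor."""
    vec = np.full(len(CHANNELS), background / len(CHANNELS))
    vec *= rng.uniform(0.5, 1.5, size=len(CHANNELS))
    for key, mass in channels.items():
        vec[CHANNELS.index(key)] += mass
    return vec / vec.sum()


def synthetic_signature_catalog(seed: int = 20190115) -> pd.DataFrame:
    """A SYNTHETIC 30-signature catalogue (stand-in for COSMIC v2).

    This is not the COSMIC catalogue: it is a deterministic fabrication with
    the same 30 x 96 shape whose designed members carry the biological
    character the downstream analysis depends on —

    * ``Signature.1``  (aging): C>T concentrated at NCG contexts
      (5-methylcytosine deamination);
    * ``Signature.2``  (APOBEC): C>T at TCA/TCT (the TCW motif);
    * ``Signature.13`` (APOBEC): C>G at TCA/TCT;
    * ``Signature.4``  (tobacco): C>A spread broadly over contexts;
    * ``Signature.16``: T>C at ATN contexts.

    The remaining 25 signatures are seeded Dirichlet draws. Every row sums
    to 1. Use :func:`load_signature_matrix` to substitute the real catalogue.
    """
    rng = np.random.default_rng(seed)
    rows = {}

    rows["Signature.1"] = _peaked(
        {ChannelKey(f + "CG", "T"): 0.19 for f in "ACGT"}, 0.24, rng
    )
    rows["Signature.2"] = _peaked(
        {ChannelKey("TCA", "T"): 0.42, ChannelKey("TCT", "T"): 0.42}, 0.16, rng
    )
    rows["Signature.13"] = _peaked(
        {ChannelKey("TCA", "G"): 0.42, ChannelKey("TCT", "G"): 0.42}, 0.16, rng
    )
    rows["Signature.4"] = _peaked(
        {ChannelKey(f + "C" + t, "A"): 0.05 for f in "ACGT" for t in "ACGT"},
        0.20, rng,
    )
    rows["Signature.16"] = _peaked(
        {ChannelKey("AT" + t, "C"): 0.19 for t in "ACGT"}, 0.24, rng
    )

    for name in SIGNATURE_NAMES:
        if name in rows:
            continue
        vec = rng.dirichlet(np.full(len(CHANNELS), 0.25))
        vec = vec + 1e-4  # keep strictly positive mass everywhere
        rows[name] = vec / vec.sum()

    sigs = pd.DataFrame(
        [rows[n] for n in SIGNATURE_NAMES],
        index=list(SIGNATURE_NAMES),
        columns=list(CHANNEL_LABELS),
    )
    return validate_signature_matrix(sigs)
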