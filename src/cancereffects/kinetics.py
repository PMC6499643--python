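"""Single-exponential fits of deaminase time courses.

Enzymatic deamination assays report % product converted as a function of
time; each time course is fit to

    % product = A * (1 - exp(-k_obs * t))

with A the maximum % product and k_obs the observed catalytic rate per
minute. The fit is nonlinear least squares initialized from a deterministic
linearization (regressing -ln(1 - product/A0) on t with A0 = max product),
and the uncertainty on k_obs is the asymptotic standard error from the local
curvature of the loss.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


@dataclasses.dataclass
class KineticsFit:
    A: float  # maximum % product, (0, 100]
    k_obs: float  # per minute
    sd_A: float
    sd_k: float
    residuals: np.ndarray

    def __post_init__(self):
        if not 0 < self.A <= 100 + 1e-6:
            raise ValueError(f"implausible asymptote A={self.A}")
        if self.k_obs <= 0:
            raise ValueError(f"non-positive rate k_obs={self.k_obs}")

    def predict(self, t: np.ndarray) -> np.ndarray:
        return self.A * (1.0 - np.exp(-self.k_obs * np.asarray(t, dtype=float)))


def _model(t, A, k):
    return A * (1.0 - np.exp(-k * t))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Deterministic start: A0 = max(y); k0 from the linearized early phase."""
    A0 = float(y.max())
    mask = (y < 0.9 * A0) & (y >= 0) & (t > 0)
    if mask.sum() >= 2:
        z = -np.log1p(-np.clip(y[mask] / A0, 0, 1 - 1e-9))
        k0 = float(np.sum(z * t[mask]) / np.sum(t[mask] ** 2))  # through origin
    else:
        k0 = 1.0 / float(t[t > 0].min())
    return A0, max(k0, 1e-6)


def fit_exponential(timepoints, product) -> KineticsFit:
    """Least-squares (A, k_obs) for one time course.

    ``timepoints`` in minutes (at least 3, non-negative, at least one
    positive); ``product`` in % on the 0-100 scale.
    """
    t = np.asarray(timepoints, dtype=float)
    y = np.asarray(product, dtype=float)
    if t.shape != y.shape:
        raise ValueError("timepoints and product must have the same length")
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    if (t < 0).any() or not (t > 0).any():
        raise ValueError("timepoints must be non-negative with at least one > 0")
    if np.allclose(y, 0):
        raise ValueError("all-zero product: no conversion to fit")

    order = np.argsort(t, kind="stable")  # estimates invariant to input order
    t, y = t[order], y[order]
    p0 = _initial_guess(t, y)
    try:
        popt, pcov = curve_fit(
            _model, t, y, p0=p0,
            bounds=([1e-9, 1e-9], [110.0, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise RuntimeError(
            f"exponential fit did not converge (start A={p0[0]:.3g}, "
            f"k={p0[1]:.3g}): {exc}"
        ) from exc
    A, k = float(popt[0]), float(popt[1])
    sd = np.sqrt(np.diag(pcov))
    return KineticsFit(
        A=min(A, 100.0) if A <= 100 + 1e-6 else A,  # __post_init__ guards
        k_obs=k,
        sd_A=float(sd[0]),
        sd_k=float(sd[1]),
        residuals=y - _model(t, A, k),
    )


def fit_time_course_table(path: str | Path) -> pd.DataFrame:
    """Fit every substrate in a TSV of ``substrate, time_min, pct_product``.

    Optional ``replicate`` column: replicates of a substrate are pooled into
    one fit (the loss simply includes every point).
    """
    df = pd.read_csv(path, sep="\t")
    needed = {"substrate", "time_min", "pct_product"}
    if not needed.issubset(df.columns):
        raise ValueError(f"time-course table needs columns {sorted(needed)}")
    rows = []
    for substrate, grp in df.groupby("substrate", sort=True):
        fit = fit_exponential(grp["time_min"].values, grp["pct_product"].values)
        rows.append(
            {
                "substrate": substrate, "A": fit.A, "k_obs": fit.k_obs,
                "sd_A": fit.sd_A, "sd_k": fit.sd_k,
                "n_points": len(grp),
            }
        )
    return pd.DataFrame(rows)


#: 25-mer assay oligonucleotides. The two test substrates mimic the PIK3CA
#: helical-domain hotspot loci (the non-target cytosine of the overlapping
#: sister site is replaced by thymine so each oligo carries a single
#: deaminatable TC); the control is the AT-rich benchmark.
ASSAY_OLIGOS = {
    "E542": "TGCTTAGTGATTTCAGAGAGAGGAT",
    "E545": "TGCTCAGTGATTTTAGAGAGAGGAT",
    "control": "ATTATTATGGATCAATTATTTATTA",
}
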