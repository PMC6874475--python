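"""13C tracer mass-isotopomer analysis and global 5mC/5hmC quantification.

GC-MS side: integrated ion signals for the M0..Mn mass shifts of a
metabolite fragment are normalized by an internal standard (norvaline),
converted to a mass-isotopomer distribution (MID) by dividing each channel
by the channel sum, and corrected for natural 13C abundance by inverting a
binomial convolution matrix.  Labeled fractions (e.g. M2 alpha-ketoglutarate
from U-13C3 lactate) and TET-relevant abundance ratios (2HG/aKG,
fumarate/aKG) follow directly.

LC-MS side: global %5mC and %5hmC are read off ordinary least-squares
calibration lines of known spiked percentage versus MRM response ratio,
where the response ratio is the analyte peak area over the combined
C + 5mC + 5hmC peak areas.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.stats

#: natural abundance of 13C
CARBON_13_ABUNDANCE = 0.0107


@dataclass(frozen=True)
class IsotopomerSignal:
    """Raw integrated ion signals M0..Mn plus the internal-standard channel."""

    metabolite: str
    signals: np.ndarray
    internal_standard_signal: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "signals", np.asarray(self.signals, dtype=float))
        if (self.signals < 0).any():
            raise ValueError("ion signals must be nonnegative")

    @property
    def n_carbons(self) -> int:
        return len(self.signals) - 1


@dataclass(frozen=True)
class Mid:
    """Natural-abundance-corrected mass-isotopomer distribution."""

    metabolite: str
    fractions: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        object.__setattr__(self, "fractions", f)
        if (f < -1e-12).any():
            raise ValueError("MID fractions must be nonnegative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError("MID must sum to 1")


def normalize_by_internal_standard(signal: IsotopomerSignal) -> np.ndarray:
    """Divide every ion channel by the internal-standard (norvaline) signal."""
    if signal.internal_standard_signal <= 0:
        raise ValueError("internal standard signal must be positive")
    return signal.signals / signal.internal_standard_signal


def raw_mid(signals) -> np.ndarray:
    """Fractional isotopomer abundances: each channel over the channel sum."""
    x = np.asarray(signals, dtype=float)
    if (x < 0).any():
        raise ValueError("signals must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero signal vector")
    return x / total


def build_correction_matrix(
    n_carbons: int,
    abundance: float = CARBON_13_ABUNDANCE,
    n_atoms: int | None = None,
) -> np.ndarray:
    """Forward natural-abundance convolution matrix, (n+1) x (n+1).

    Entry [i, j] is the probability that a molecule with j tracer-labeled
    carbons is observed at mass shift i, i.e. Binomial(n_atoms - j, a)
    evaluated at i - j, truncated at shift n.  ``n_atoms`` defaults to the
    backbone carbon count; pass a larger value to include derivatization
    atoms in the correction.  With a = 0 the matrix is the identity.
    """
    if n_carbons < 1:
        raise ValueError("need at least one carbon")
    if not 0.0 <= abundance < 1.0:
        raise ValueError("abundance must lie in [0, 1)")
    n = n_carbons
    atoms = n if n_atoms is None else int(n_atoms)
    if atoms < n:
        raise ValueError("n_atoms must be >= n_carbons")
    m = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        pmf = scipy.stats.binom.pmf(np.arange(n - j + 1), atoms - j, abundance)
        m[j : n + 1, j] = pmf
    return m


def correct_natural_abundance(
    observed_mid, matrix: np.ndarray, clip_tol: float = 1e-6
) -> Mid:
    """Invert the natural-abundance convolution to recover the tracer MID.

    Solves matrix @ x = observed (the matrix is lower-triangular with
    positive diagonal, so the solve is exact least squares), clips negative
    components to zero and renormalizes.  ``clipped`` flags any component
    clipped by more than ``clip_tol``; clipping is reported, never silent.
    """
    y = np.asarray(observed_mid, dtype=float)
    m = np.asarray(matrix, dtype=float)
    if m.shape[0] != m.shape[1] or m.shape[0] != y.size:
        raise ValueError("dimension mismatch between MID and correction matrix")
    diag = np.diag(m)
    if (diag <= 0).any() or np.linalg.cond(m) > 1e12:
        raise ValueError("correction matrix is singular or ill-conditioned")
    x = scipy.linalg.solve_triangular(m, y, lower=True)
    clipped = bool((x < -clip_tol).any())
    x = np.clip(x, 0.0, None)
    s = x.sum()
    if s <= 0:
        raise ValueError("corrected MID collapsed to zero")
    return Mid("", x / s, clipped=clipped)


def labeled_fraction(mid: Mid, k: int) -> float:
    """The M_k component of a corrected MID (e.g. k=2 for M2 aKG)."""
    if not 0 <= k < len(mid.fractions):
        raise ValueError(f"isotopomer index {k} out of range")
    return float(mid.fractions[k])


def ratio_metrics(abundances: dict[str, float], denominator: str = "aKG") -> dict[str, float]:
    """Pairwise abundance ratios against a reference metabolite (aKG).

    Ratios of internal-standard-normalized total abundances; invariant to
    any common rescaling of the raw signals.
    """
    if denominator not in abundances:
        raise ValueError(f"missing denominator metabolite {denominator!r}")
    denom = abundances[denominator]
    if denom <= 0:
        raise ValueError(f"{denominator} abundance must be positive")
    return {
        f"{name}/{denominator}": value / denom
        for name, value in abundances.items()
        if name != denominator
    }


@dataclass(frozen=True)
class CalibrationCurve:
    """OLS line of MRM response ratio versus known analyte percentage."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    points: np.ndarray = field(repr=False, default=None)


def fit_calibration(analyte: str, percentages, response_ratios) -> CalibrationCurve:
    """Fit response ratio = slope * percentage + intercept by least squares."""
    x = np.asarray(percentages, dtype=float)
    y = np.asarray(response_ratios, dtype=float)
    if x.size < 2 or np.unique(x).size < 2:
        raise ValueError("need at least two distinct known percentages")
    fit = scipy.stats.linregress(x, y)
    return CalibrationCurve(
        analyte,
        float(fit.slope),
        float(fit.intercept),
        float(fit.rvalue**2),
        np.column_stack([x, y]),
    )


def response_ratios(areas: dict[str, float]) -> dict[str, float]:
    """MRM response ratios: analyte peak area over combined C+5mC+5hmC area."""
    total = areas["C"] + areas["5mC"] + areas["5hmC"]
    if total <= 0:
        raise ValueError("combined peak area must be positive")
    return {"5mC": areas["5mC"] / total, "5hmC": areas["5hmC"] / total}


def quantify_global(
    areas: dict[str, float], curves: dict[str, CalibrationCurve]
) -> dict[str, float]:
    """Percent 5mC and 5hmC of a sample from its peak areas and curves.

    percentage = (response ratio - intercept) / slope, floored at 0.
    """
    ratios = response_ratios(areas)
    out = {}
    for analyte, ratio in ratios.items():
        curve = curves[analyte]
        if curve.slope == 0:
            raise ValueError(f"zero calibration slope for {analyte}")
        out[f"pct_{analyte}"] = max(0.0, (ratio - curve.intercept) / curve.slope)
    return out
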