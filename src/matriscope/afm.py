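"""Hertz-model analysis of AFM force-indentation curves.

For a rigid conical indenter of half-angle ``alpha`` pressed depth
``delta`` into an elastic half-space of Young's modulus ``E`` and
Poisson ratio ``nu``, the Hertz contact law is

    F = (2 / pi) * tan(alpha) * E / (1 - nu^2) * delta^2

The modulus is estimated by least squares of force against
indentation-squared (optionally co-fitting a contact-point offset),
then aggregated per sample into mean +/- SD (kPa) and pairwise
fold-changes of the means.  Curves are assumed pre-baselined with
``delta = 0`` at contact; conversion from raw cantilever deflection and
piezo position (deflection sensitivity, spring constant) happens
upstream on the instrument.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import curve_fit

from matriscope.synthetic import SyntheticForceCurve, hertz_cone_force

hertz_force = hertz_cone_force

DEFAULT_POISSON_RATIO = 0.5  # incompressible soft-tissue convention
DEFAULT_TIP_HALF_ANGLE_DEG = 18.0  # typical sharp silicon conical probe


@dataclass
class ForceCurve:
    """Measured or synthetic force-indentation curve with provenance."""

    indentation_m: np.ndarray
    force_N: np.ndarray
    sample_id: str = ""
    spot_id: str = ""

    def __post_init__(self) -> None:
        self.indentation_m = np.asarray(self.indentation_m, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        if len(self.indentation_m) != len(self.force_N):
            raise ValueError("indentation and force must have equal length")
        if np.any(np.diff(self.indentation_m) < 0):
            raise ValueError("indentation must be non-decreasing")

    @classmethod
    def from_synthetic(cls, curve: SyntheticForceCurve,
                       sample_id: str = "", spot_id: str = "") -> "ForceCurve":
        return cls(curve.indentation_m, curve.force_N, sample_id, spot_id)


@dataclass
class ModulusEstimate:
    youngs_modulus_Pa: float
    fit_residual_N: float  # RMS force residual
    n_points_used: int
    sample_id: str = ""
    spot_id: str = ""
    zero_force: bool = False  # flagged when the curve carried no signal


@dataclass
class StiffnessSummary:
    """Per-sample modulus statistics (kPa) and fold-changes of means."""

    sample_ids: list[str]
    mean_kPa: np.ndarray
    sd_kPa: np.ndarray
    n: np.ndarray
    fold_matrix: np.ndarray  # [i, j] = mean_i / mean_j, unrounded
    fold_matrix_reported: np.ndarray = field(default=None)  # half-up, 1 decimal

    def fold(self, numerator: str, denominator: str, rounded: bool = True) -> float:
        i = self.sample_ids.index(numerator)
        j = self.sample_ids.index(denominator)
        m = self.fold_matrix_reported if rounded else self.fold_matrix
        return float(m[i, j])


def _prefactor(poisson_ratio: float, tip_half_angle_deg: float) -> float:
    if not 0 < tip_half_angle_deg < 90:
        raise ValueError("tip half-angle must be in (0, 90) degrees")
    if not 0 <= poisson_ratio <= 0.5:
        raise ValueError("Poisson ratio must be in [0, 0.5]")
    alpha = math.radians(tip_half_angle_deg)
    return (2.0 / math.pi) * math.tan(alpha) / (1.0 - poisson_ratio**2)


def fit_hertz(
    curve: ForceCurve | SyntheticForceCurve,
    poisson_ratio: float = DEFAULT_POISSON_RATIO,
    tip_half_angle_deg: float = DEFAULT_TIP_HALF_ANGLE_DEG,
    fit_contact_offset: bool = False,
) -> ModulusEstimate:
    """Least-squares Hertz fit of one curve.

    With ``fit_contact_offset`` the contact point ``delta_0`` is co-fitted
    via ``F = c E max(delta - delta_0, 0)^2``; otherwise the curve is
    taken as pre-baselined and the fit is linear in ``delta^2`` through
    the origin.  An all-zero force trace returns modulus 0 with a warning
    flag; a negative fitted modulus (wrong contact-point assignment)
    raises.
    """
    if isinstance(curve, SyntheticForceCurve):
        curve = ForceCurve.from_synthetic(curve)
    d = curve.indentation_m
    f = curve.force_N
    if len(d) < 10:
        raise ValueError("need at least 10 post-contact points")
    pref = _prefactor(poisson_ratio, tip_half_angle_deg)
    if np.all(f == 0):
        warnings.warn(
            f"curve {curve.sample_id}/{curve.spot_id}: zero force everywhere; "
            "reporting modulus 0",
            stacklevel=2,
        )
        return ModulusEstimate(0.0, 0.0, len(d), curve.sample_id,
                               curve.spot_id, zero_force=True)
    if fit_contact_offset:
        scale = max(abs(f).max() / pref / max(d.max(), 1e-30) ** 2, 1e-30)

        def model(x, e, d0):
            return pref * e * np.maximum(x - d0, 0.0) ** 2

        popt, _ = curve_fit(model, d, f, p0=[scale, 0.0])
        modulus, _d0 = popt
        resid = f - model(d, *popt)
    else:
        d2 = d * d
        denom = float(d2 @ d2)
        if denom == 0:
            raise ValueError("all indentation depths are zero")
        slope = float(f @ d2) / denom
        modulus = slope / pref
        resid = f - slope * d2
    if modulus < 0:
        raise ValueError(
            f"fitted modulus is negative ({modulus:.3g} Pa): invalid "
            "contact-point assignment or inverted force signal"
        )
    return ModulusEstimate(
        youngs_modulus_Pa=float(modulus),
        fit_residual_N=float(np.sqrt(np.mean(resid**2))),
        n_points_used=len(d),
        sample_id=curve.sample_id,
        spot_id=curve.spot_id,
    )


def round_fold(x: float) -> float:
    """Reporting convention: round half-up to one decimal."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_UP))


def fold_change(
    numerator_mean_kPa: float, denominator_mean_kPa: float, rounded: bool = True
) -> float:
    """Ratio of mean moduli; reported rounded half-up to one decimal."""
    if denominator_mean_kPa <= 0:
        raise ValueError("denominator mean must be positive")
    ratio = numerator_mean_kPa / denominator_mean_kPa
    return round_fold(ratio) if rounded else ratio


def summarize_moduli(
    estimates: dict[str, list[ModulusEstimate]] | list[ModulusEstimate],
    min_spots: int = 7,
) -> StiffnessSummary:
    """Per-sample mean +/- SD (kPa) and pairwise fold-change matrix.

    Accepts estimates grouped by sample or a flat list (grouped by their
    ``sample_id``).  Warns when a sample has fewer than ``min_spots``
    measuring spots.  Sample SD uses ddof=1 (0 for a single estimate).
    """
    if isinstance(estimates, list):
        grouped: dict[str, list[ModulusEstimate]] = {}
        for e in estimates:
            grouped.setdefault(e.sample_id, []).append(e)
        estimates = grouped
    if any(not v for v in estimates.values()):
        empty = [k for k, v in estimates.items() if not v]
        raise ValueError(f"samples with no estimates: {empty}")
    ids = list(estimates)
    means, sds, ns = [], [], []
    for sid in ids:
        vals = np.array([e.youngs_modulus_Pa for e in estimates[sid]]) / 1e3
        if len(vals) < min_spots:
            warnings.warn(
                f"sample {sid!r} has {len(vals)} spots (< {min_spots})",
                stacklevel=2,
            )
        means.append(vals.mean())
        sds.append(vals.std(ddof=1) if len(vals) > 1 else 0.0)
        ns.append(len(vals))
    means_arr = np.array(means)
    folds = means_arr[:, None] / means_arr[None, :]
    reported = np.vectorize(round_fold)(folds)
    return StiffnessSummary(
        sample_ids=ids,
        mean_kPa=means_arr,
        sd_kPa=np.array(sds),
        n=np.array(ns),
        fold_matrix=folds,
        fold_matrix_reported=reported,
    )


def summary_from_means(mean_kPa: dict[str, float]) -> StiffnessSummary:
    """Fold-change summary directly from published per-sample means."""
    ids = list(mean_kPa)
    means = np.array([mean_kPa[k] for k in ids], dtype=float)
    if np.any(means <= 0):
        raise ValueError("mean moduli must be positive")
    folds = means[:, None] / means[None, :]
    return StiffnessSummary(
        sample_ids=ids,
        mean_kPa=means,
        sd_kPa=np.zeros_like(means),
        n=np.ones(len(ids), dtype=int),
        fold_matrix=folds,
        fold_matrix_reported=np.vectorize(round_fold)(folds),
    )
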