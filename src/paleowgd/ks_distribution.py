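"""Ks distributions, peak location, lineage rate correction and dating.

The age structure of duplications in a genome shows up as peaks in the
distribution of Ks over duplicate pairs.  Peaks are located on the log-Ks
scale (Ks is positive and right-skewed), either by Gaussian KDE (Silverman
bandwidth, 512-point grid) or by a Gaussian mixture selected by BIC, taking
the heaviest component's location.

Because synonymous rates differ between lineages, Ks scales of two species
are aligned through their shared divergence against a common reference:
if both split from the reference at the same time, the two cross-species
divergence peaks estimate the same event, and the ratio
``C = reference_split_peak / other_split_peak`` rescales the other
lineage's Ks values onto the reference scale.

Dating uses the molecular-clock relation Ks = 2 r t: a calibration point
(Ks_cal at T_cal million years) fixes the per-lineage synonymous rate
r = Ks_cal / (2 T_cal), and an event peak Ks_e dates to
t = Ks_e / (2 r) = Ks_e * T_cal / Ks_cal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class KsSample:
    """A filtered set of Ks values under one label (species or species pair)."""

    label: str
    values: tuple[float, ...]
    filter_range: tuple[float, float] = (0.01, 3.0)

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PeakEstimate:
    """Location of the dominant Ks peak of a sample."""

    mode: float
    method: str  # "kde" | "gmm"
    components: tuple[tuple[float, float, float], ...] = ()  # (weight, loc, scale) on log scale
    bandwidth_or_bic: float = float("nan")
    n_components: int = 0


@dataclass(frozen=True)
class RateCorrection:
    """Multiplicative Ks rescaling aligning a lineage to the reference rate."""

    reference_split_peak: float
    other_split_peak: float

    @property
    def coefficient(self) -> float:
        return self.reference_split_peak / self.other_split_peak


@dataclass(frozen=True)
class DatingResult:
    """Ks = 2rt dating of an event peak against a calibration point."""

    event_peak: float
    calibration: tuple[float, float]  # (Ks_cal, T_cal in MY)
    r: float  # synonymous substitutions / site / MY (per pair of lineages)
    t: float  # event age, MY


def build_ks_sample(
    pairs,
    label: str = "sample",
    lo: float = 0.01,
    hi: float = 3.0,
) -> KsSample:
    """Collect finite in-range Ks values from pair objects or raw floats.

    Accepts a list of floats/None or of objects with a ``ks`` attribute.
    Undefined (None/NaN) and out-of-range values are dropped and counted in
    a logged message; an empty result is an error.
    """
    raw = []
    for p in pairs:
        ks = getattr(p, "ks", p)
        raw.append(ks)
    kept = [
        float(v)
        for v in raw
        if v is not None and math.isfinite(v) and lo <= v <= hi
    ]
    dropped = len(raw) - len(kept)
    if dropped:
        logger.info("%s: dropped %d/%d Ks values outside [%g, %g] or undefined",
                    label, dropped, len(raw), lo, hi)
    if not kept:
        raise ValueError(f"{label}: all {len(raw)} Ks values filtered out")
    return KsSample(label=label, values=tuple(kept), filter_range=(lo, hi))


def _kde_peak(log_values: np.ndarray) -> tuple[float, float]:
    """Mode of a Silverman-bandwidth Gaussian KDE on a 512-point grid."""
    if np.allclose(log_values, log_values[0]):
        return float(log_values[0]), 0.0
    kde = gaussian_kde(log_values, bw_method="silverman")
    pad = 3.0 * log_values.std()
    grid = np.linspace(log_values.min() - pad, log_values.max() + pad, 512)
    density = kde(grid)
    return float(grid[int(np.argmax(density))]), float(kde.factor)


def estimate_peak(
    sample: KsSample,
    method: str = "kde",
    k_max: int = 4,
    seed: int = 0,
) -> PeakEstimate:
    """Locate the dominant Ks peak of a sample on the log scale.

    ``kde``: mode of the Gaussian kernel density.  ``gmm``: EM mixtures with
    k = 1..k_max components, model chosen by BIC, peak = exp(mean) of the
    heaviest component.  Samples under 50 values fall back from gmm to kde
    with a warning.  Deterministic given ``seed``.
    """
    log_values = np.log(np.asarray(sample.values, dtype=float))
    if method == "gmm" and len(sample) < 50:
        logger.warning(
            "%s: %d values is too small for gmm, falling back to kde",
            sample.label, len(sample),
        )
        method = "kde"

    if method == "kde":
        log_mode, bw = _kde_peak(log_values)
        return PeakEstimate(
            mode=float(np.exp(log_mode)), method="kde", bandwidth_or_bic=bw
        )
    if method != "gmm":
        raise ValueError(f"unknown peak method {method!r}")

    x = log_values.reshape(-1, 1)
    best: GaussianMixture | None = None
    best_bic = math.inf
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", random_state=seed, n_init=3
        ).fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best_bic = bic
            best = gm
    assert best is not None
    weights = best.weights_.ravel()
    means = best.means_.ravel()
    scales = np.sqrt(best.covariances_.reshape(-1))
    heaviest = int(np.argmax(weights))
    components = tuple(
        (float(w), float(m), float(s)) for w, m, s in zip(weights, means, scales)
    )
    return PeakEstimate(
        mode=float(np.exp(means[heaviest])),
        method="gmm",
        components=components,
        bandwidth_or_bic=float(best_bic),
        n_components=int(best.n_components),
    )


def rate_correction(
    reference_split: PeakEstimate, other_split: PeakEstimate
) -> RateCorrection:
    """Correction coefficient C = reference split peak / other split peak."""
    if reference_split.mode <= 0 or other_split.mode <= 0:
        raise ValueError("split peaks must be positive")
    return RateCorrection(
        reference_split_peak=reference_split.mode,
        other_split_peak=other_split.mode,
    )


def apply_correction(sample: KsSample, corr: RateCorrection) -> KsSample:
    """Rescale every Ks value by C; the filter range is left untouched."""
    c = corr.coefficient
    if c <= 0:
        raise ValueError("correction coefficient must be positive")
    return replace(
        sample,
        label=f"{sample.label}|C={c:.4g}",
        values=tuple(v * c for v in sample.values),
    )


def date_event(
    event_peak: float, calibration: tuple[float, float]
) -> DatingResult:
    """Date an event Ks peak by the molecular clock Ks = 2 r t.

    ``calibration`` is (Ks_cal, T_cal): the Ks of a divergence peak of
    known age T_cal (million years).  Then r = Ks_cal / (2 T_cal) and
    t = event_peak / (2 r).
    """
    ks_cal, t_cal = calibration
    if event_peak <= 0 or ks_cal <= 0 or t_cal <= 0:
        raise ValueError("event peak and calibration must be positive")
    r = ks_cal / (2.0 * t_cal)
    t = event_peak / (2.0 * r)
    return DatingResult(
        event_peak=event_peak, calibration=(ks_cal, t_cal), r=r, t=t
    )
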