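"""First-order (histogram) statistics of pixel intensities.

These features describe the marginal intensity distribution of a patch or
channel, ignoring spatial arrangement: the level histogram and its mean,
variance, skewness and excess kurtosis, plus the min and max.  Moments use
the population (divide-by-n) convention, weighting each observed value by
its empirical probability; kurtosis is reported on the excess scale
(0 for a Gaussian).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class IntensityHistogram:
    """Per-level pixel tallies and their empirical probabilities."""

    counts: np.ndarray
    probabilities: np.ndarray
    levels: int
    n_pixels: int


@dataclass(frozen=True)
class FirstOrderFeatures:
    """Moments of the intensity distribution on the normalized [0, 1] scale.

    ``kurtosis`` is excess kurtosis.  For a constant input (zero variance)
    skewness and kurtosis are defined as 0 so degenerate patches flow
    through the pipeline rather than erroring.
    """

    mean: float
    variance: float
    skewness: float
    kurtosis: float
    min: float
    max: float


def histogram(values, levels: int) -> IntensityHistogram:
    """Tally quantized intensity levels into an L-bin histogram.

    ``values`` must already be integer levels in 0..L-1.  Probabilities are
    counts divided by the total pixel count, so they sum to 1.
    """
    v = np.asarray(values).ravel()
    if v.size == 0:
        raise ValueError("histogram requires at least one pixel")
    if not np.issubdtype(v.dtype, np.integer):
        raise ValueError("histogram expects integer-leveled values")
    if v.min() < 0 or v.max() >= levels:
        raise ValueError(f"values outside 0..{levels - 1}")
    counts = np.bincount(v, minlength=levels).astype(np.int64)
    probs = counts / v.size
    return IntensityHistogram(counts=counts, probabilities=probs,
                              levels=levels, n_pixels=int(v.size))


def first_order_features(values) -> FirstOrderFeatures:
    """Mean, variance, skewness, excess kurtosis, min and max of a sample.

    Computed on the raw (unquantized) values through their empirical
    distribution; each distinct value is weighted by its relative frequency,
    which is the same as averaging over pixels.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("first-order features require at least one pixel")
    mu = float(v.mean())
    centered = v - mu
    var = float(np.mean(centered**2))
    # Degenerate policy: a (numerically) constant sample has zero variance
    # and zero skewness/kurtosis rather than raising or amplifying rounding
    # dust into spurious moments.
    tol = 1e-12 * max(1.0, abs(mu))
    if np.ptp(v) == 0.0 or var <= tol * tol:
        var, skew, kurt = 0.0, 0.0, 0.0
    else:
        sd = np.sqrt(var)
        skew = float(np.mean(centered**3) / sd**3)
        kurt = float(np.mean(centered**4) / sd**4 - 3.0)
    return FirstOrderFeatures(mean=mu, variance=var, skewness=skew,
                              kurtosis=kurt, min=float(v.min()),
                              max=float(v.max()))
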