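"""Gray-level co-occurrence matrices and Haralick texture features.

A GLCM tallies, for a fixed displacement (distance d, angle theta), how
often a pixel of level i co-occurs with a pixel of level j.  Four scalar
summaries are derived from the normalized matrix:

* energy   E = sum p(i,j)^2            — local uniformity, in (0, 1];
* entropy  H = -sum p log2 p           — disorder, in bits;
* correlation rho                      — linear dependence of neighbor
  levels, in [-1, 1], computed from the row/column marginal moments;
* contrast C = sum (i-j)^2 p(i,j)      — local variation, in level^2 units.

Displacements follow the standard pixel-lattice convention with y growing
downward: 0 deg -> (+d, 0), 45 deg -> (+d, -d), 90 deg -> (0, -d),
135 deg -> (-d, -d) in (dx, dy).  Symmetric counting (each pair tallied in
both orders) is the default, which makes the two marginals identical and
keeps the correlation well-behaved.

Texture descriptors for a patch are aggregated as the arithmetic mean of
the per-(d, theta) features over all displacement combinations that yield
at least one pixel pair; by default d in 1..5 and the four angles above,
i.e. 20 combinations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .imaging import GrayImage

logger = logging.getLogger(__name__)

#: Default displacement grid: distances 1..5 at the four standard angles.
DEFAULT_DISTANCES = (1, 2, 3, 4, 5)
DEFAULT_ANGLES = (0, 45, 90, 135)

# (dx, dy) per angle, y increasing downward.
_ANGLE_OFFSETS = {0: (1, 0), 45: (1, -1), 90: (0, -1), 135: (-1, -1)}


class EmptyGLCMError(ValueError):
    """No pixel pair exists for the requested displacement on this patch."""

    def __init__(self, d: int, theta: int, shape):
        self.d, self.theta, self.shape = d, theta, shape
        super().__init__(
            f"no valid pixel pairs for d={d}, theta={theta} on a "
            f"{shape[0]}x{shape[1]} patch")


@dataclass(frozen=True)
class GLCM:
    """Co-occurrence counts, probabilities and marginal moments."""

    counts: np.ndarray
    probs: np.ndarray
    d: int
    theta: int
    levels: int
    symmetric: bool
    n_pairs: int
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float


@dataclass(frozen=True)
class HaralickFeatures:
    energy: float
    entropy: float
    correlation: float
    contrast: float


def compute_glcm(patch: GrayImage, d: int, theta: int,
                 symmetric: bool = True) -> GLCM:
    """Build the co-occurrence matrix of an integer-leveled patch.

    Raises :class:`EmptyGLCMError` when the displacement exceeds the patch
    extent (no pair can be formed).
    """
    if patch.normalized:
        raise ValueError("compute_glcm expects an integer-leveled gray image")
    if d < 1:
        raise ValueError("distance must be >= 1")
    if theta not in _ANGLE_OFFSETS:
        raise ValueError(f"angle must be one of {sorted(_ANGLE_OFFSETS)}, got {theta}")
    px = patch.pixels
    L = patch.levels
    h, w = px.shape
    dx, dy = (off * d for off in _ANGLE_OFFSETS[theta])

    # Reference pixels whose displaced partner stays inside the patch.
    x_lo, x_hi = max(0, -dx), min(w, w - dx)
    y_lo, y_hi = max(0, -dy), min(h, h - dy)
    if x_lo >= x_hi or y_lo >= y_hi:
        raise EmptyGLCMError(d, theta, px.shape)

    ref = px[y_lo:y_hi, x_lo:x_hi].ravel()
    nbr = px[y_lo + dy:y_hi + dy, x_lo + dx:x_hi + dx].ravel()
    counts = np.bincount(ref * L + nbr, minlength=L * L).reshape(L, L)
    if symmetric:
        counts = counts + counts.T
    n_pairs = int(counts.sum())
    probs = counts / n_pairs

    idx = np.arange(L, dtype=np.float64)
    p_x = probs.sum(axis=1)  # marginal of the reference (row) level
    p_y = probs.sum(axis=0)  # marginal of the neighbor (column) level
    mu_x = float(idx @ p_x)
    mu_y = float(idx @ p_y)
    sigma_x = float(np.sqrt(((idx - mu_x) ** 2) @ p_x))
    sigma_y = float(np.sqrt(((idx - mu_y) ** 2) @ p_y))
    return GLCM(counts=counts.astype(np.int64), probs=probs, d=d, theta=theta,
                levels=L, symmetric=symmetric, n_pairs=n_pairs,
                mu_x=mu_x, mu_y=mu_y, sigma_x=sigma_x, sigma_y=sigma_y)


def haralick_features(g: GLCM) -> HaralickFeatures:
    """Energy, entropy (bits), correlation and contrast of one GLCM.

    Entropy uses the 0*log0 := 0 convention.  When either marginal is
    degenerate (constant patch) the correlation is defined as 1 — the
    neighbor level is perfectly predictable.
    """
    if g.n_pairs <= 0:
        raise ValueError("GLCM has no counted pairs")
    p = g.probs
    energy = float(np.sum(p * p))
    nz = p[p > 0]
    entropy = float(-np.sum(nz * np.log2(nz)))
    idx = np.arange(g.levels, dtype=np.float64)
    ii, jj = np.meshgrid(idx, idx, indexing="ij")
    contrast = float(np.sum((ii - jj) ** 2 * p))
    denom = g.sigma_x * g.sigma_y
    if denom > 0:
        cov = float(np.sum(p * (ii - g.mu_x) * (jj - g.mu_y)))
        correlation = cov / denom
    else:
        correlation = 1.0
    return HaralickFeatures(energy=energy, entropy=entropy,
                            correlation=correlation, contrast=contrast)


def aggregate_texture(patch: GrayImage,
                      distances=DEFAULT_DISTANCES,
                      angles=DEFAULT_ANGLES,
                      symmetric: bool = True) -> HaralickFeatures:
    """Mean of each Haralick feature over all valid (d, theta) combinations.

    Combinations whose displacement exceeds the patch extent are skipped
    (and logged); if every combination is empty an error is raised.
    """
    feats = []
    for d in distances:
        for theta in angles:
            try:
                g = compute_glcm(patch, d, theta, symmetric=symmetric)
            except EmptyGLCMError:
                logger.debug("skipping empty GLCM combo d=%d theta=%d on %s",
                             d, theta, patch.pixels.shape)
                continue
            feats.append(haralick_features(g))
    if not feats:
        raise ValueError(
            f"no (d, theta) combination yields a pixel pair on a "
            f"{patch.pixels.shape[0]}x{patch.pixels.shape[1]} patch")
    return HaralickFeatures(
        energy=float(np.mean([f.energy for f in feats])),
        entropy=float(np.mean([f.entropy for f in feats])),
        correlation=float(np.mean([f.correlation for f in feats])),
        contrast=float(np.mean([f.contrast for f in feats])),
    )


def glcm_to_csv(g: GLCM, path) -> None:
    """Debug dump of the normalized matrix as an L x L CSV of probabilities."""
    np.savetxt(path, g.probs, delimiter=",", fmt="%.17g")
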