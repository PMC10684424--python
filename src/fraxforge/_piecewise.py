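"""Continuous piecewise-linear least squares on a truncated power basis.

The design matrix is [1, x, (x - k_1)_+, ..., (x - k_m)_+], which makes the
fitted function continuous at every knot by construction: the segment slope
to the right of knot k_j is the base slope plus the accumulated extra slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def design_matrix(x: np.ndarray, knots: tuple[float, ...]) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    cols = [np.ones_like(x), x]
    for k in knots:
        cols.append(np.maximum(0.0, x - k))
    return np.column_stack(cols)


@dataclass(frozen=True)
class ContinuousPiecewiseFit:
    """Least-squares continuous piecewise-linear fit with fixed knots.

    ``coef`` holds (intercept, base slope, extra slope per knot) on the
    truncated basis; ``segment_slopes``/``segment_intercepts`` give the
    conventional per-segment parameterisation y = a_i + b_i * x.
    """

    knots: tuple[float, ...]
    coef: tuple[float, ...]
    rss: float
    n_points: int
    weights_used: bool = field(default=False)

    @property
    def segment_slopes(self) -> tuple[float, ...]:
        slopes = [self.coef[1]]
        for extra in self.coef[2:]:
            slopes.append(slopes[-1] + extra)
        return tuple(slopes)

    @property
    def segment_intercepts(self) -> tuple[float, ...]:
        # continuity at each knot: a_{i+1} = a_i + (b_i - b_{i+1}) * k_i
        intercepts = [self.coef[0]]
        slopes = self.segment_slopes
        for i, k in enumerate(self.knots):
            intercepts.append(intercepts[-1] + (slopes[i] - slopes[i + 1]) * k)
        return tuple(intercepts)

    def predict(self, x) -> np.ndarray:
        X = design_matrix(np.atleast_1d(x), self.knots)
        out = X @ np.asarray(self.coef)
        return out if np.ndim(x) else float(out[0])

    def continuity_residuals(self) -> tuple[float, ...]:
        """Left/right prediction gap at each knot; ~0 by construction."""
        a = self.segment_intercepts
        b = self.segment_slopes
        return tuple(
            (a[i] + b[i] * k) - (a[i + 1] + b[i + 1] * k)
            for i, k in enumerate(self.knots)
        )


def fit_continuous_piecewise(
    x, y, knots, weights=None, min_points_per_segment: int = 2
) -> ContinuousPiecewiseFit:
    """Fit y ~ continuous piecewise-linear in x with fixed ``knots``.

    Parameters
    ----------
    weights : optional non-negative case weights (weighted least squares).
    min_points_per_segment : raise ``ValueError`` if any segment between
        consecutive knots holds fewer points than this.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    knots = tuple(sorted(float(k) for k in knots))
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2 + len(knots):
        raise ValueError(
            f"{x.size} points cannot identify {2 + len(knots)} parameters"
        )
    edges = (-np.inf, *knots, np.inf)
    for lo, hi in zip(edges[:-1], edges[1:]):
        n_seg = int(np.sum((x >= lo) & (x < hi)))
        if n_seg < min_points_per_segment:
            raise ValueError(
                f"segment [{lo}, {hi}) has {n_seg} points; "
                f"need at least {min_points_per_segment}"
            )
    X = design_matrix(x, knots)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("weights must be non-negative")
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        rss = float(np.sum(w * (y - X @ coef) ** 2))
    else:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = float(np.sum((y - X @ coef) ** 2))
    return ContinuousPiecewiseFit(
        knots=knots,
        coef=tuple(float(c) for c in coef),
        rss=rss,
        n_points=int(x.size),
        weights_used=weights is not None,
    )
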