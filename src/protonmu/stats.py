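"""Validation statistics and the uncertainty budget.

Predictions are compared to measurements as percent differences,
``(P - M) / M * 100``, summarized by mean, sample SD, extrema and a
histogram, and checked against the +-3% clinical acceptability band.  Models
evaluated on the same validation points are compared with a paired Student's
t-test by default (an unpaired pooled-variance variant is available).  The
overall uncertainty of a model is budgeted per factor and combined in
quadrature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import stats as sps

__all__ = [
    "ValidationReport",
    "UncertaintyBudget",
    "percent_diff",
    "summarize",
    "compare_models",
    "propagate_uncertainty",
]


def percent_diff(prediction: float, measurement: float) -> float:
    """(Prediction - Measurement) / Measurement * 100."""
    if np.any(np.asarray(measurement) <= 0):
        raise ValueError("measurement must be positive")
    return (prediction - measurement) / measurement * 100.0


@dataclass
class ValidationReport:
    """Summary of per-point percent differences for one model."""

    diffs: np.ndarray
    mean: float
    sd: float
    min: float
    max: float
    bin_edges: np.ndarray
    counts: np.ndarray
    tolerance: float
    n_within_tolerance: int
    passes: bool
    flags: dict[str, int] = dc_field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.diffs)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "min": self.min,
            "max": self.max,
            "tolerance": self.tolerance,
            "n_within_tolerance": self.n_within_tolerance,
            "passes": self.passes,
            "histogram": {
                "bin_edges": self.bin_edges.tolist(),
                "counts": self.counts.tolist(),
            },
            "flags": self.flags,
            "diffs": self.diffs.tolist(),
        }


def summarize(
    diffs,
    bin_width: float = 0.5,
    tolerance: float = 3.0,
    flags: dict[str, int] | None = None,
) -> ValidationReport:
    """Summarize percent differences: mean, sample SD (n-1), histogram with
    ``bin_width``-percent bins, and a pass/fail against ``tolerance``."""
    diffs = np.asarray(diffs, dtype=float)
    if diffs.size < 2:
        raise ValueError("need at least two validation records")
    lo = math.floor(diffs.min() / bin_width) * bin_width
    hi = math.ceil(diffs.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    nbins = int(round((hi - lo) / bin_width))
    counts, edges = np.histogram(diffs, bins=nbins, range=(lo, hi))
    within = int(np.sum(np.abs(diffs) <= tolerance))
    return ValidationReport(
        diffs=diffs,
        mean=float(diffs.mean()),
        sd=float(diffs.std(ddof=1)),
        min=float(diffs.min()),
        max=float(diffs.max()),
        bin_edges=edges,
        counts=counts,
        tolerance=tolerance,
        n_within_tolerance=within,
        passes=within == diffs.size,
        flags=flags or {},
    )


def compare_models(diffs_x, diffs_y, paired: bool = True) -> float:
    """Two-sided p-value of the Student's t-test between two models'
    percent-difference samples.

    Paired by default (the models are evaluated on the same validation
    points); ``paired=False`` uses the unpaired pooled-variance two-sample
    test.  Identical samples compare with p = 1.
    """
    import warnings

    x = np.asarray(diffs_x, dtype=float)
    y = np.asarray(diffs_y, dtype=float)
    with warnings.catch_warnings():
        # zero-variance samples (e.g. identical or constant diffs) are
        # legitimate degenerate inputs here; t goes to 0 or +-inf cleanly
        warnings.simplefilter("ignore", RuntimeWarning)
        if paired:
            if len(x) != len(y):
                raise ValueError("paired comparison requires equal-length samples")
            d = x - y
            if np.allclose(d, d[0]) and abs(d[0]) < 1e-300:
                return 1.0
            res = sps.ttest_rel(x, y)
        else:
            if np.array_equal(x, y):
                return 1.0
            res = sps.ttest_ind(x, y, equal_var=True)
    p = float(res.pvalue)
    return 1.0 if math.isnan(p) else p


@dataclass(frozen=True)
class UncertaintyBudget:
    """Named relative-uncertainty components (percent) and their quadrature sum."""

    components: dict[str, float]
    total: float

    def to_dict(self) -> dict:
        return {"components": dict(self.components), "total": self.total}


def propagate_uncertainty(components: dict[str, float]) -> UncertaintyBudget:
    """Combine per-factor percent uncertainties in quadrature.

    The factors multiply, so their relative uncertainties add in quadrature:
    ``total = sqrt(sum_i u_i^2)``.
    """
    for name, v in components.items():
        if v < 0:
            raise ValueError(f"negative uncertainty component {name!r}")
    total = math.sqrt(sum(v * v for v in components.values()))
    return UncertaintyBudget(components=dict(components), total=total)
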