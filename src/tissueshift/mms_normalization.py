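"""Bounded count normalization and peak extraction.

Raw TPM counts are unbounded and heavy-tailed. Each count is mapped into
[0, 1) by the micro-movement-spike (MMS) transform

    normalized = count / (count + C)

where the scale constant ``C`` is derived from two global statistics of
the whole matrix: the grand mean over all cells (``global_avg``) and the
grand maximum (``global_max``). The default reading nests the two,
``C = global_avg / global_max``; the ``avg`` variant uses
``C = global_avg`` alone, the form used for biorhythm waveforms in the
MMS literature. Both keep zero at zero and approach 1 from below as the
count grows, so the per-tissue series is comparable across tissues and
across genome versions.

Local peaks of the normalized series (strict local maxima over the gene
ordering) are the "spike" events; they can optionally replace the full
series as the sample fed to the rate fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import ExpressionMatrix
from .errors import DegenerateMatrixError

EQ1_VARIANTS = ("avg_over_max", "avg")


@dataclass
class NormalizedSeries:
    """Normalized counts of one tissue, in gene order, each in [0, 1)."""

    tissue_id: str
    values: np.ndarray
    global_avg: float
    global_max: float


@dataclass
class PeakSeries:
    """Strict local maxima of a normalized series."""

    tissue_id: str
    peak_indices: np.ndarray
    peak_values: np.ndarray


def global_stats(em: ExpressionMatrix) -> tuple[float, float]:
    """Grand mean and grand maximum over every cell of the matrix.

    These are the two scale constants of the normalization; they are
    recomputed on whichever matrix (full or post-removal) is being
    normalized unless the caller freezes them.
    """
    if em.values.size == 0:
        raise DegenerateMatrixError("empty matrix has no global statistics")
    g_max = float(em.values.max())
    if g_max == 0.0:
        raise DegenerateMatrixError("all-zero matrix: normalization undefined")
    return float(em.values.mean()), g_max


def _scale_constant(global_avg: float, global_max: float, variant: str) -> float:
    if variant not in EQ1_VARIANTS:
        raise ValueError(f"unknown normalization variant {variant!r}")
    if not (np.isfinite(global_avg) and np.isfinite(global_max)):
        raise ValueError("global statistics must be finite")
    if not (global_max >= global_avg > 0):
        raise ValueError("require global_max >= global_avg > 0")
    return global_avg / global_max if variant == "avg_over_max" else global_avg


def normalize_count(
    count,
    global_avg: float,
    global_max: float,
    variant: str = "avg_over_max",
):
    """Map a count (scalar or array) into [0, 1) via count / (count + C)."""
    c = _scale_constant(global_avg, global_max, variant)
    arr = np.asarray(count, dtype=float)
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    out = arr / (arr + c)
    # keep the half-open bound even when count/C overflows double precision
    out = np.minimum(out, np.nextafter(1.0, 0.0))
    return float(out) if np.isscalar(count) or arr.ndim == 0 else out


def normalize_tissue(
    em: ExpressionMatrix,
    tissue: str,
    global_avg: float,
    global_max: float,
    variant: str = "avg_over_max",
) -> NormalizedSeries:
    """Normalize one tissue's column, preserving gene order."""
    col = em.column(tissue)  # KeyError for unknown tissue
    vals = normalize_count(col, global_avg, global_max, variant)
    return NormalizedSeries(
        tissue_id=tissue, values=vals, global_avg=global_avg, global_max=global_max
    )


def extract_peaks(ns: NormalizedSeries) -> PeakSeries:
    """Strict interior local maxima: v[i-1] < v[i] > v[i+1].

    Plateaus produce no peak and the endpoints are never peaks, so the
    result is deterministic and bounded by floor((n-1)/2) events.
    """
    v = ns.values
    if v.size < 3:
        idx = np.empty(0, dtype=int)
    else:
        interior = (v[1:-1] > v[:-2]) & (v[1:-1] > v[2:])
        idx = np.nonzero(interior)[0] + 1
    return PeakSeries(tissue_id=ns.tissue_id, peak_indices=idx, peak_values=v[idx])
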