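"""Cross-disease aggregation: normalized Δλ matrix, binarization, moment space.

Per-disease shift results are stacked into a disease x tissue matrix
whose rows are Δλ divided by the row maximum, so every disease peaks at
1.0 at its most-affected tissue. Thresholding the normalized values
(strictly above 0.8 by default) yields an ON/OFF overlap map that makes
shared high-impact tissues across disease groups directly comparable.
A reference row of exact zeros — the full genome against itself — leads
the matrix. The gamma fits can additionally be embedded as points in a
(mean, variance, skewness) space with kurtosis as marker size and Δλ or
EMD as color.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .removal_ranking import ShiftResult
from .stochastic_fit import GammaFit

log = logging.getLogger(__name__)

REFERENCE_LABEL = "Full genome (reference)"


@dataclass
class SummaryMatrix:
    """Disease x tissue matrix of row-normalized Δλ and its binarization."""

    disease_ids: list[str]
    tissue_ids: list[str]
    raw_values: np.ndarray
    norm_values: np.ndarray
    binary: np.ndarray
    threshold: float

    def to_frame(self, which: str = "norm") -> pd.DataFrame:
        data = {"norm": self.norm_values, "raw": self.raw_values, "binary": self.binary}[which]
        return pd.DataFrame(data, index=self.disease_ids, columns=self.tissue_ids)

    def on_tissues(self, disease: str) -> set[str]:
        """Tissues ON (normalized Δλ strictly above threshold) for one disease."""
        try:
            i = self.disease_ids.index(disease)
        except ValueError:
            raise KeyError(f"unknown disease {disease!r}") from None
        return {t for t, on in zip(self.tissue_ids, self.binary[i]) if on}


@dataclass
class OverlapReport:
    """Tissues ON in every member of each group, and their set relations."""

    common_a: set[str]
    common_b: set[str]
    intersection: set[str]
    only_a: set[str]
    only_b: set[str]


@dataclass
class ParamSpacePoint:
    """One tissue's gamma-moment embedding plus a color value (Δλ or EMD)."""

    tissue_id: str
    mean: float
    variance: float
    skewness: float
    kurtosis: float
    color_value: float


def build_summary(
    results: list[ShiftResult],
    threshold: float = 0.8,
    include_reference: bool = True,
) -> SummaryMatrix:
    """Stack shift results into the row-normalized disease x tissue matrix.

    Columns are sorted alphabetically; every result must cover the same
    tissue set. Rows with an all-zero Δλ profile stay all zero (0/0 is
    not attempted) with a warning. Binarization uses strict inequality:
    ON iff normalized value > threshold.
    """
    if not results:
        raise ValueError("no shift results to summarize")
    tissues = sorted(results[0].tissue_ids)
    rows: list[np.ndarray] = []
    names: list[str] = []
    if include_reference:
        names.append(REFERENCE_LABEL)
        rows.append(np.zeros(len(tissues)))
    for sr in results:
        if sorted(sr.tissue_ids) != tissues:
            raise ValueError(f"result {sr.disease!r} has a different tissue set")
        series = sr.table.set_index("tissue_id")["delta_lambda"]
        rows.append(series.reindex(tissues).to_numpy(dtype=float))
        names.append(sr.disease)
    raw = np.vstack(rows)

    norm = np.zeros_like(raw)
    for i, name in enumerate(names):
        rmax = raw[i].max()
        if rmax > 0:
            norm[i] = raw[i] / rmax
        elif name != REFERENCE_LABEL or not include_reference:
            log.warning("disease %r has an all-zero Δλ row; leaving it unnormalized", name)
    binary = norm > threshold
    return SummaryMatrix(
        disease_ids=names,
        tissue_ids=tissues,
        raw_values=raw,
        norm_values=norm,
        binary=binary,
        threshold=threshold,
    )


def overlap_report(
    sm: SummaryMatrix, group_a: list[str], group_b: list[str]
) -> OverlapReport:
    """Compare the tissues ON across every member of two disease groups."""
    def common(group: list[str]) -> set[str]:
        sets = [sm.on_tissues(d) for d in group]
        return set.intersection(*sets) if sets else set()

    ca, cb = common(group_a), common(group_b)
    return OverlapReport(
        common_a=ca,
        common_b=cb,
        intersection=ca & cb,
        only_a=ca - cb,
        only_b=cb - ca,
    )


def param_space(
    fits: dict[str, GammaFit] | list[GammaFit],
    colors: dict[str, float],
) -> list[ParamSpacePoint]:
    """Embed gamma fits as moment-space points, one per colored tissue."""
    if not isinstance(fits, dict):
        fits = {f.tissue_id: f for f in fits}
    missing = set(colors) - set(fits)
    if missing:
        raise KeyError(f"no gamma fit for tissues: {sorted(missing)[:5]}")
    return [
        ParamSpacePoint(
            tissue_id=t,
            mean=fits[t].mean,
            variance=fits[t].variance,
            skewness=fits[t].skewness,
            kurtosis=fits[t].kurtosis,
            color_value=float(c),
        )
        for t, c in sorted(colors.items())
    ]


def write_summary_tsv(sm: SummaryMatrix, path: str | Path, which: str = "norm") -> None:
    df = sm.to_frame(which)
    if which == "binary":
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="disease", lineterminator="\n")


def write_param_space_tsv(points: list[ParamSpacePoint], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "tissue_id": p.tissue_id,
                "mean": p.mean,
                "variance": p.variance,
                "skewness": p.skewness,
                "kurtosis": p.kurtosis,
                "color_value": p.color_value,
            }
            for p in points
        ]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def plot_summary(sm: SummaryMatrix, path: str | Path, which: str = "norm") -> None:
    """Convenience heatmap of the summary matrix (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.2 * len(sm.tissue_ids)), max(3, 0.25 * len(sm.disease_ids))))
    data = sm.norm_values if which == "norm" else sm.binary.astype(float)
    im = ax.imshow(data, aspect="auto", cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(len(sm.tissue_ids)))
    ax.set_xticklabels(sm.tissue_ids, rotation=90, fontsize=5)
    ax.set_yticks(range(len(sm.disease_ids)))
    ax.set_yticklabels(sm.disease_ids, fontsize=6)
    fig.colorbar(im, ax=ax, label="normalized Δλ" if which == "norm" else "ON")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
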