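"""Gene-removal perturbation, per-tissue Δλ, and median-ranked blocks.

The interrogation proceeds per disease: confirm which disease genes the
matrix contains, delete those rows, renormalize both genomes, fit the
exponential rate per tissue in each, and take Δλ = |λ_full − λ_removed|.
Tissues are then sorted ascending by Δλ and cut into ``n_blocks``
rank blocks (four by default, a quartile-style split); the highest
block — the smallest when T is not divisible, e.g. 13 of 54 tissues —
is the "maximally affected" group that is compared across diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    AbsenceReport,
    ExpressionMatrix,
    GeneSet,
    TissueTaxonomy,
    intersect_with_matrix,
)
from .errors import DegenerateMatrixError
from .mms_normalization import extract_peaks, global_stats, normalize_tissue
from .stochastic_fit import (
    ExponentialFit,
    GammaFit,
    HistogramPair,
    delta_lambda,
    emd_1d,
    fit_exponential,
    fit_gamma,
)

#: fixed column order of the per-disease shift table / TSV
SHIFT_COLUMNS = [
    "tissue_id",
    "lambda_full",
    "lambda_removed",
    "delta_lambda",
    "emd",
    "rank",
    "block",
    "group",
    "gamma_shape",
    "gamma_scale",
    "gamma_mean",
    "gamma_variance",
    "gamma_skewness",
    "gamma_kurtosis",
]


@dataclass
class RankingConfig:
    """Knobs of the removal pipeline.

    n_blocks        number of rank blocks (4 = quartile split).
    eq1_variant     normalization scale constant: 'avg_over_max' or 'avg'.
    freeze_globals  reuse the full-genome normalization constants for the
                    removed genome instead of recomputing them.
    peaks_only      fit λ on the local-maxima events instead of the full
                    normalized series.
    n_bins          shared histogram bins for the EMD.
    gamma_zero_policy  'drop' or 'epsilon' handling of zero counts.
    with_gamma      also fit the gamma family per tissue (slower; off for
                    large replicate sweeps).
    """

    n_blocks: int = 4
    eq1_variant: str = "avg_over_max"
    freeze_globals: bool = False
    peaks_only: bool = False
    n_bins: int = 32
    gamma_zero_policy: str = "drop"
    with_gamma: bool = True

    def __post_init__(self) -> None:
        if self.n_blocks < 2:
            raise ValueError("n_blocks must be >= 2")


@dataclass
class ShiftResult:
    """Per-tissue shift statistics for one disease.

    ``table`` holds one row per tissue with columns ``SHIFT_COLUMNS``,
    sorted ascending by Δλ (ties broken by tissue name), rank 1..T and
    block 1..n_blocks assigned; block ``n_blocks`` is maximally
    affected. ``gamma_fits`` / ``gamma_fits_full`` map tissue to the
    gamma fit of the post-removal / full-genome series.
    """

    disease: str
    table: pd.DataFrame
    n_blocks: int
    absent_report: AbsenceReport | None = None
    gamma_fits: dict[str, GammaFit] = field(default_factory=dict)
    gamma_fits_full: dict[str, GammaFit] = field(default_factory=dict)

    @property
    def tissue_ids(self) -> list[str]:
        return list(self.table["tissue_id"])


def remove_genes(em: ExpressionMatrix, gs: GeneSet) -> ExpressionMatrix:
    """Matrix without the gene set's rows; tissues and row order otherwise kept."""
    if not gs.genes:
        return replace(em, gene_ids=list(em.gene_ids), values=em.values.copy())
    keep = [i for i, g in enumerate(em.gene_ids) if g not in gs.genes]
    if not keep:
        raise DegenerateMatrixError("removal would delete every gene")
    return ExpressionMatrix(
        gene_ids=[em.gene_ids[i] for i in keep],
        tissue_ids=list(em.tissue_ids),
        values=em.values[keep],
    )


def partition_blocks(n_tissues: int, n_blocks: int) -> list[int]:
    """Sizes of the ascending-rank blocks, as equal as possible.

    When T is not divisible by the block count the surplus goes to the
    low-rank blocks, so the top (maximally affected) block is the
    smallest: 54 tissues in 4 blocks -> [14, 14, 13, 13].
    """
    if n_blocks > n_tissues:
        raise ValueError(f"cannot split {n_tissues} tissues into {n_blocks} blocks")
    base, extra = divmod(n_tissues, n_blocks)
    return [base + 1] * extra + [base] * (n_blocks - extra)


def _rate_sample(series_values: np.ndarray, tissue: str, cfg: RankingConfig) -> np.ndarray:
    if not cfg.peaks_only:
        return series_values
    from .mms_normalization import NormalizedSeries

    peaks = extract_peaks(NormalizedSeries(tissue, series_values, 0.0, 0.0))
    if peaks.peak_values.size < 2:
        raise DegenerateMatrixError(
            f"tissue {tissue!r}: fewer than 2 peaks; cannot fit rate in peaks-only mode"
        )
    return peaks.peak_values


def compute_shift(
    em_full: ExpressionMatrix,
    gs: GeneSet,
    cfg: RankingConfig | None = None,
    taxonomy: TissueTaxonomy | None = None,
) -> ShiftResult:
    """Run the full per-disease interrogation and rank the tissues.

    An empty (or fully absent) gene set leaves the matrix untouched, so
    every Δλ and EMD is exactly zero — the full-genome reference row.
    """
    cfg = cfg or RankingConfig()
    taxonomy = taxonomy or TissueTaxonomy.default()
    if cfg.n_blocks > em_full.n_tissues:
        raise ValueError("n_blocks exceeds the number of tissues")

    present, report = intersect_with_matrix(gs, em_full)
    em_removed = remove_genes(em_full, present)

    avg_f, max_f = global_stats(em_full)
    if cfg.freeze_globals:
        avg_r, max_r = avg_f, max_f
    else:
        avg_r, max_r = global_stats(em_removed)

    rows = []
    gamma_fits: dict[str, GammaFit] = {}
    gamma_fits_full: dict[str, GammaFit] = {}
    for tissue in em_full.tissue_ids:
        ns_f = normalize_tissue(em_full, tissue, avg_f, max_f, cfg.eq1_variant)
        ns_r = normalize_tissue(em_removed, tissue, avg_r, max_r, cfg.eq1_variant)
        fit_f = fit_exponential(_rate_sample(ns_f.values, tissue, cfg), tissue)
        fit_r = fit_exponential(_rate_sample(ns_r.values, tissue, cfg), tissue)
        dlam = delta_lambda(fit_f, fit_r)
        emd = emd_1d(HistogramPair.from_samples(ns_f.values, ns_r.values, cfg.n_bins))
        row = {
            "tissue_id": tissue,
            "lambda_full": fit_f.lam,
            "lambda_removed": fit_r.lam,
            "delta_lambda": dlam,
            "emd": emd,
            "group": taxonomy.group_of(tissue),
        }
        if cfg.with_gamma:
            gf_full = fit_gamma(ns_f.values, tissue, cfg.gamma_zero_policy)
            gf_rem = fit_gamma(ns_r.values, tissue, cfg.gamma_zero_policy)
            gamma_fits_full[tissue] = gf_full
            gamma_fits[tissue] = gf_rem
            row.update(
                gamma_shape=gf_rem.shape,
                gamma_scale=gf_rem.scale,
                gamma_mean=gf_rem.mean,
                gamma_variance=gf_rem.variance,
                gamma_skewness=gf_rem.skewness,
                gamma_kurtosis=gf_rem.kurtosis,
            )
        else:
            row.update(
                gamma_shape=np.nan,
                gamma_scale=np.nan,
                gamma_mean=np.nan,
                gamma_variance=np.nan,
                gamma_skewness=np.nan,
                gamma_kurtosis=np.nan,
            )
        rows.append(row)

    df = pd.DataFrame(rows)
    df = df.sort_values(
        ["delta_lambda", "tissue_id"], ascending=True, kind="mergesort"
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    sizes = partition_blocks(len(df), cfg.n_blocks)
    df["block"] = np.repeat(np.arange(1, cfg.n_blocks + 1), sizes)
    df = df[SHIFT_COLUMNS]
    return ShiftResult(
        disease=gs.name,
        table=df,
        n_blocks=cfg.n_blocks,
        absent_report=report,
        gamma_fits=gamma_fits,
        gamma_fits_full=gamma_fits_full,
    )


def top_block(sr: ShiftResult) -> pd.DataFrame:
    """The maximally affected block, ordered descending by Δλ."""
    block = sr.table[sr.table["block"] == sr.n_blocks]
    return block.iloc[::-1].reset_index(drop=True)


def max_tissue(sr: ShiftResult) -> tuple[str, float]:
    """The single most-affected tissue: argmax Δλ, ties to the first name."""
    dmax = sr.table["delta_lambda"].max()
    tied = sr.table.loc[sr.table["delta_lambda"] == dmax, "tissue_id"]
    return min(tied), float(dmax)


def write_shift_tsv(sr: ShiftResult, path: str | Path) -> None:
    sr.table.to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_top_block_tsv(sr: ShiftResult, path: str | Path) -> None:
    top_block(sr).to_csv(path, sep="\t", index=False, lineterminator="\n")
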