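"""Synthetic GTEx-like matrices and disease gene sets with planted signal.

The generator emulates the statistical shape of a bulk-tissue median-TPM
matrix — heavy-tailed non-negative values (log-normal baseline), a
zero-inflation dropout, and GTEx-style tissue names so the taxonomy
patterns fire — together with disease gene sets whose members are
multiplicatively over-expressed in chosen target tissues. Because the
enrichment raises only the target tissues' counts for the set's genes,
removing the set provably shifts those tissues' mean normalized count
the most, which makes structure recovery (does the pipeline rank the
planted tissue on top?) quantifiable. An overlap plan forces a chosen
number of shared genes between pairs of sets, mirroring the small
overlaps real disease lists exhibit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import ExpressionMatrix, GeneSet, TissueTaxonomy, write_gct
from .removal_ranking import RankingConfig, compute_shift, max_tissue, top_block

#: GTEx v8-style tissue panel (54 names; 13 brain, 2 heart, skeletal muscle).
GTEX_LIKE_TISSUES = [
    "Adipose - Subcutaneous",
    "Adipose - Visceral (Omentum)",
    "Adrenal Gland",
    "Artery - Aorta",
    "Artery - Coronary",
    "Artery - Tibial",
    "Bladder",
    "Brain - Amygdala",
    "Brain - Anterior cingulate cortex (BA24)",
    "Brain - Caudate (basal ganglia)",
    "Brain - Cerebellar Hemisphere",
    "Brain - Cerebellum",
    "Brain - Cortex",
    "Brain - Frontal Cortex (BA9)",
    "Brain - Hippocampus",
    "Brain - Hypothalamus",
    "Brain - Nucleus accumbens (basal ganglia)",
    "Brain - Putamen (basal ganglia)",
    "Brain - Spinal cord (cervical c-1)",
    "Brain - Substantia nigra",
    "Breast - Mammary Tissue",
    "Cells - Cultured fibroblasts",
    "Cells - EBV-transformed lymphocytes",
    "Cervix - Ectocervix",
    "Cervix - Endocervix",
    "Colon - Sigmoid",
    "Colon - Transverse",
    "Esophagus - Gastroesophageal Junction",
    "Esophagus - Mucosa",
    "Esophagus - Muscularis",
    "Fallopian Tube",
    "Heart - Atrial Appendage",
    "Heart - Left Ventricle",
    "Kidney - Cortex",
    "Kidney - Medulla",
    "Liver",
    "Lung",
    "Minor Salivary Gland",
    "Muscle - Skeletal",
    "Nerve - Tibial",
    "Ovary",
    "Pancreas",
    "Pituitary",
    "Prostate",
    "Skin - Not Sun Exposed (Suprapubic)",
    "Skin - Sun Exposed (Lower leg)",
    "Small Intestine - Terminal Ileum",
    "Spleen",
    "Stomach",
    "Testis",
    "Thyroid",
    "Uterus",
    "Vagina",
    "Whole Blood",
]

_SCORE_CYCLE = ("1", "2", "3", "S")


@dataclass
class DiseaseSpec:
    """One planted disease gene set.

    ``size`` genes; members over-expressed ``enrichment_fold``-fold in
    each ``target_tissues`` entry (fold 1 = null, no planted signal).
    """

    name: str
    size: int = 100
    target_tissues: list[str] = field(default_factory=list)
    enrichment_fold: float = 1.0
    with_scores: bool = False

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise ValueError(f"set {self.name!r}: size must be positive")
        if self.enrichment_fold < 1.0:
            raise ValueError(f"set {self.name!r}: enrichment_fold must be >= 1")


@dataclass
class OverlapSpec:
    """Force ``n_shared`` common genes between two named sets."""

    set_a: str
    set_b: str
    n_shared: int


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset.

    Defaults emulate a down-scaled bulk-tissue matrix: 2,000 genes over
    the 54-name GTEx-style panel, log-normal(μ=0, σ=2) TPM baseline with
    30% dropout zeros, and disease sets of 100 genes (≈5% of the genome,
    the order of magnitude of curated disease lists relative to the
    full transcriptome). One seed fully determines every output.
    """

    n_genes: int = 2000
    tissue_names: list[str] = field(default_factory=lambda: list(GTEX_LIKE_TISSUES))
    mu: float = 0.0
    sigma: float = 2.0
    dropout: float = 0.3
    disease_sets: list[DiseaseSpec] = field(default_factory=list)
    overlaps: list[OverlapSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not self.tissue_names:
            raise ValueError("need at least one tissue")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        names = [d.name for d in self.disease_sets]
        if len(set(names)) != len(names):
            raise ValueError("disease set names must be unique")
        for d in self.disease_sets:
            unknown = set(d.target_tissues) - set(self.tissue_names)
            if unknown:
                raise ValueError(f"set {d.name!r}: unknown target tissues {sorted(unknown)}")
        for ov in self.overlaps:
            if ov.n_shared <= 0:
                raise ValueError("overlap n_shared must be positive")
            if ov.set_a not in names or ov.set_b not in names:
                raise ValueError(f"overlap refers to unknown set {ov.set_a!r}/{ov.set_b!r}")


def _gene_name(i: int) -> str:
    return f"GENE{i:05d}"


def _allocate_members(cfg: SyntheticConfig) -> dict[str, list[int]]:
    """Deterministic gene-index allocation honouring the overlap plan.

    Shared genes for each overlap pair are carved out first, then each
    set is filled with fresh indices; allocation is a pure function of
    the config, independent of the random seed.
    """
    members: dict[str, list[int]] = {d.name: [] for d in cfg.disease_sets}
    sizes = {d.name: d.size for d in cfg.disease_sets}
    cursor = 0
    for ov in cfg.overlaps:
        if ov.n_shared > min(sizes[ov.set_a] - len(members[ov.set_a]),
                             sizes[ov.set_b] - len(members[ov.set_b])):
            raise ValueError(
                f"overlap plan infeasible: {ov.n_shared} shared genes exceed the "
                f"remaining capacity of {ov.set_a!r} or {ov.set_b!r}"
            )
        shared = list(range(cursor, cursor + ov.n_shared))
        cursor += ov.n_shared
        members[ov.set_a].extend(shared)
        members[ov.set_b].extend(shared)
    for d in cfg.disease_sets:
        need = d.size - len(members[d.name])
        members[d.name].extend(range(cursor, cursor + need))
        cursor += need
    if cursor > cfg.n_genes:
        raise ValueError(
            f"disease sets need {cursor} distinct genes but n_genes={cfg.n_genes}"
        )
    return members


def generate_gene_sets(cfg: SyntheticConfig) -> list[GeneSet]:
    """Materialize the planted disease sets as :class:`GeneSet` objects."""
    members = _allocate_members(cfg)
    out = []
    for d in cfg.disease_sets:
        genes = {_gene_name(i) for i in members[d.name]}
        scores = (
            {g: _SCORE_CYCLE[k % len(_SCORE_CYCLE)] for k, g in enumerate(sorted(genes))}
            if d.with_scores
            else {}
        )
        out.append(GeneSet(name=d.name, genes=genes, scores=scores))
    return out


def generate_matrix(cfg: SyntheticConfig) -> ExpressionMatrix:
    """Draw the synthetic TPM matrix.

    Log-normal baseline with dropout zeros; each enriched disease set's
    member genes are multiplied by ``enrichment_fold`` in the set's
    target tissues and exempted from dropout there — a tissue-enriched
    gene is both over-expressed and reliably detected in its tissue, and
    the detection component is what survives the bounded normalization's
    saturation for large counts.
    """
    rng = np.random.default_rng(cfg.seed)
    n_t = len(cfg.tissue_names)
    values = rng.lognormal(cfg.mu, cfg.sigma, size=(cfg.n_genes, n_t))
    drop = (
        rng.random(size=values.shape) < cfg.dropout
        if cfg.dropout > 0
        else np.zeros(values.shape, dtype=bool)
    )
    members = _allocate_members(cfg)
    for d in cfg.disease_sets:
        if d.enrichment_fold == 1.0 or not d.target_tissues:
            continue
        rows = np.asarray(members[d.name])
        cols = np.asarray([cfg.tissue_names.index(t) for t in d.target_tissues])
        values[np.ix_(rows, cols)] *= d.enrichment_fold
        drop[np.ix_(rows, cols)] = False
    values[drop] = 0.0
    return ExpressionMatrix(
        gene_ids=[_gene_name(i) for i in range(cfg.n_genes)],
        tissue_ids=list(cfg.tissue_names),
        values=values,
    )


@dataclass
class RecoveryReport:
    """Structure-recovery rates over replicate seeds.

    ``frac_top_block``: fraction of (replicate, enriched set) trials in
    which every target tissue landed in the maximally affected block;
    ``frac_max_tissue``: fraction in which the single most-affected
    tissue was a planted target. CIs are exact Clopper–Pearson.
    """

    n_reps: int
    n_trials: int
    n_top_block: int
    n_max_tissue: int
    frac_top_block: float
    frac_max_tissue: float
    ci_top_block: tuple[float, float]
    ci_max_tissue: tuple[float, float]


def _binom_ci(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    from scipy.stats import binomtest

    ci = binomtest(k, n).proportion_ci(confidence_level=level, method="exact")
    return (float(ci.low), float(ci.high))


def recovery_experiment(
    cfg: SyntheticConfig,
    n_reps: int,
    ranking_cfg: RankingConfig | None = None,
) -> RecoveryReport:
    """Re-run the full pipeline across ``n_reps`` derived seeds and score
    how often the planted target tissues are recovered."""
    ranking_cfg = ranking_cfg or RankingConfig(with_gamma=False)
    enriched = [d for d in cfg.disease_sets if d.enrichment_fold > 1.0 and d.target_tissues]
    scored = enriched or [d for d in cfg.disease_sets if d.target_tissues]
    if n_reps == 0:
        return RecoveryReport(0, 0, 0, 0, float("nan"), float("nan"), (0.0, 1.0), (0.0, 1.0))
    if not scored:
        raise ValueError("no disease set with target tissues to score")

    n_trials = n_top = n_max = 0
    for rep in range(n_reps):
        rep_cfg = SyntheticConfig(
            n_genes=cfg.n_genes,
            tissue_names=list(cfg.tissue_names),
            mu=cfg.mu,
            sigma=cfg.sigma,
            dropout=cfg.dropout,
            disease_sets=cfg.disease_sets,
            overlaps=cfg.overlaps,
            seed=(cfg.seed + 1_000_003 * rep) % (2**31),
        )
        em = generate_matrix(rep_cfg)
        sets = {g.name: g for g in generate_gene_sets(rep_cfg)}
        for d in scored:
            sr = compute_shift(em, sets[d.name], ranking_cfg)
            targets = set(d.target_tissues)
            tb = set(top_block(sr)["tissue_id"])
            n_trials += 1
            n_top += targets <= tb
            n_max += max_tissue(sr)[0] in targets
    return RecoveryReport(
        n_reps=n_reps,
        n_trials=n_trials,
        n_top_block=n_top,
        n_max_tissue=n_max,
        frac_top_block=n_top / n_trials,
        frac_max_tissue=n_max / n_trials,
        ci_top_block=_binom_ci(n_top, n_trials),
        ci_max_tissue=_binom_ci(n_max, n_trials),
    )


def write_bundle(cfg: SyntheticConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a self-contained dataset (GCT + gene-set CSVs + taxonomy YAML)
    consumable by the main pipeline CLI unchanged."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    em = generate_matrix(cfg)
    gct = out_dir / "expression.gct"
    write_gct(em, gct)
    paths["gct"] = gct
    for gs in generate_gene_sets(cfg):
        p = out_dir / f"geneset_{_slug(gs.name)}.csv"
        with open(p, "w") as fh:
            fh.write("gene,score\n")
            for g in sorted(gs.genes):
                fh.write(f"{g},{gs.scores.get(g, '')}\n")
        paths[f"geneset:{gs.name}"] = p
    tax = out_dir / "taxonomy.yaml"
    TissueTaxonomy.default().to_yaml(tax)
    paths["taxonomy"] = tax
    return paths


def _slug(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_" else "_" for c in name)
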