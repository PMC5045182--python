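"""Variant → gene → drug → population deleteriousness scores.

The score hierarchy, per individual:

* ``V`` — the variant deleteriousness score, a SIFT-style prediction in
  [0, 1] where *lower* means more damaging, floored at a small ``epsilon``
  (default 0.001) so an exact zero cannot annihilate the geometric means
  above it while remaining maximally deleterious in effect.
* ``G`` — the gene deleteriousness score: the geometric mean of the V
  scores of the nonsynonymous variants the individual *carries* in that
  gene.  Carrying nothing leaves the gene unimpaired, G = 1.
* ``D`` — the drug deleteriousness score: the geometric mean of G over all
  the drug's PK/PD genes, equally weighted; genes with no carried variant
  contribute G = 1 and dilute the hits.
* ``P`` (AUC) — the population deleteriousness of a drug: the arithmetic
  mean of D over all individuals, which equals the area under the sorted
  per-person D-score curve.  ``1 - AUC`` is the drug's distance from a
  "genetically ideal" drug, one whose PK/PD genes carry no deleterious
  variant in anyone.
* ``V_t`` — the vulnerable fraction: the proportion of individuals whose D
  score lies strictly below a risk threshold ``t``.

All geometric means are computed in log space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    AnnotationSet,
    DrugGeneMap,
    DrugStatus,
    GenotypeCarriage,
    VariantAnnotation,
)

logger = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.001


def clamp_variant_score(sift: float, epsilon: float = DEFAULT_EPSILON) -> float:
    """Floor a SIFT-style score at ``epsilon``: ``V = max(sift, epsilon)``."""
    if not 0.0 <= sift <= 1.0:
        raise ValueError(f"sift score {sift} outside [0, 1]")
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon {epsilon} outside (0, 1)")
    return max(sift, epsilon)


def gene_score(v_scores: Sequence[float]) -> float:
    """Geometric mean of the carried variants' V scores; empty list → 1."""
    v = np.asarray(v_scores, dtype=float)
    if v.size == 0:
        return 1.0
    if (v <= 0).any():
        raise ValueError("gene_score requires V scores in (0, 1]; clamp first")
    if (v > 1).any():
        raise ValueError("gene_score requires V scores in (0, 1]")
    return float(np.exp(np.mean(np.log(v))))


def drug_score(g_scores: Sequence[float]) -> float:
    """Geometric mean of the drug's per-gene G scores (one per PK/PD gene)."""
    g = np.asarray(g_scores, dtype=float)
    if g.size == 0:
        raise ValueError("drug has no genes; it should have been excluded upstream")
    if (g <= 0).any() or (g > 1).any():
        raise ValueError("drug_score requires G scores in (0, 1]")
    return float(np.exp(np.mean(np.log(g))))


def population_auc(d_scores: Sequence[float]) -> float:
    """Population deleteriousness P: the mean of per-individual D scores.

    Equals the area under the ascending sorted D-score curve, so it is
    invariant to the order of individuals.
    """
    d = np.asarray(d_scores, dtype=float)
    if d.size == 0:
        raise ValueError("population_auc of an empty population")
    if (d <= 0).any() or (d > 1).any():
        raise ValueError("D scores must lie in (0, 1]")
    return float(d.mean())


def vulnerability_fraction(d_scores: Sequence[float], t: float) -> float:
    """V_t: the fraction of individuals with D strictly below threshold ``t``."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold {t} outside [0, 1]")
    d = np.asarray(d_scores, dtype=float)
    if d.size == 0:
        raise ValueError("vulnerability_fraction of an empty population")
    return float(np.count_nonzero(d < t) / d.size)


@dataclass
class ScoreMatrix:
    """Per-individual drug deleteriousness scores with gene-level intermediates."""

    individuals: list[str]
    drugs: list[str]
    d_scores: np.ndarray  # float, shape (n_individuals, n_drugs), in [epsilon, 1]
    genes: list[str] = field(default_factory=list)
    g_scores: np.ndarray | None = None  # (n_individuals, n_genes) or None
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        self.d_scores = np.asarray(self.d_scores, dtype=float)
        if self.d_scores.shape != (len(self.individuals), len(self.drugs)):
            raise ValueError("d_scores shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.d_scores, index=pd.Index(self.individuals, name="individual"),
            columns=self.drugs,
        )

    def gene_frame(self) -> pd.DataFrame:
        if self.g_scores is None:
            raise ValueError("gene scores were not retained")
        return pd.DataFrame(
            self.g_scores, index=pd.Index(self.individuals, name="individual"),
            columns=self.genes,
        )


def score_cohort(
    carriage: GenotypeCarriage,
    annotations: AnnotationSet | Sequence[VariantAnnotation],
    drug_map: DrugGeneMap,
    epsilon: float = DEFAULT_EPSILON,
    keep_gene_scores: bool = True,
) -> ScoreMatrix:
    """Compute every individual's D score for every included drug.

    For each (individual, gene), G is the geometric mean of the clamped SIFT
    scores of the annotated variants the individual carries in that gene
    (G = 1 when none).  For each (individual, drug), D is the geometric mean
    of G over exactly the drug's gene set; map genes with no annotated
    variant anywhere contribute G = 1 for everyone.  Deterministic given the
    inputs.
    """
    if not 0.0 < epsilon < 1.0:
        raise ValueError(f"epsilon {epsilon} outside (0, 1)")
    n_ind = len(carriage.individuals)
    col_of = {key: j for j, key in enumerate(carriage.variants)}

    # (gene, variant column) -> clamped log V; duplicates within a gene count once
    per_gene: dict[str, dict[int, float]] = {}
    n_clamped = 0
    n_unmatched = 0
    for ann in annotations:
        j = col_of.get(ann.key)
        if j is None:
            n_unmatched += 1
            continue
        v = clamp_variant_score(ann.sift, epsilon)
        if v != ann.sift:
            n_clamped += 1
        per_gene.setdefault(ann.gene, {})[j] = np.log(v)
    if n_unmatched:
        logger.debug("score_cohort: %d annotations without a genotype column", n_unmatched)
    if n_clamped:
        logger.info("score_cohort: clamped %d variant scores up to epsilon=%g",
                    n_clamped, epsilon)

    genes = sorted(per_gene)
    gene_idx = {g: k for k, g in enumerate(genes)}
    log_g = np.zeros((n_ind, len(genes)))
    for g, cols in per_gene.items():
        jj = np.fromiter(cols.keys(), dtype=int)
        logv = np.fromiter(cols.values(), dtype=float)
        sub = carriage.carriage[:, jj]
        counts = sub.sum(axis=1)
        sums = sub @ logv
        k = gene_idx[g]
        np.divide(sums, counts, out=log_g[:, k], where=counts > 0)

    drugs = drug_map.drugs
    d = np.zeros((n_ind, len(drugs)))
    n_unannotated_drugs = 0
    for m, drug in enumerate(drugs):
        gene_set = drug_map.entries[drug]
        cols = [gene_idx[g] for g in gene_set if g in gene_idx]
        if not cols:
            n_unannotated_drugs += 1
        # genes absent from the annotation contribute log G = 0 to the mean
        d[:, m] = np.exp(log_g[:, cols].sum(axis=1) / len(gene_set)) if cols else 1.0
    if n_unannotated_drugs:
        logger.warning(
            "score_cohort: %d drugs have no annotated variant in any gene; "
            "they score D = 1 for everyone (genetically ideal limit)",
            n_unannotated_drugs,
        )
    return ScoreMatrix(
        individuals=list(carriage.individuals),
        drugs=list(drugs),
        d_scores=d,
        genes=genes if keep_gene_scores else [],
        g_scores=np.exp(log_g) if keep_gene_scores else None,
        epsilon=epsilon,
    )


@dataclass
class PopulationSummary:
    """Per-drug population summary: AUC, 1 − AUC, and V_t at chosen thresholds."""

    frame: pd.DataFrame  # index drug_id; columns auc, distance, v_<t>..., n_individuals
    thresholds: tuple[float, ...]
    epsilon: float

    def auc(self, drug: str) -> float:
        return float(self.frame.loc[drug, "auc"])


def summarize_population(
    scores: ScoreMatrix,
    thresholds: Iterable[float] = (0.3, 0.7),
    status: DrugStatus | None = None,
) -> PopulationSummary:
    """Collapse a :class:`ScoreMatrix` over individuals.

    Reports, per drug: AUC (the P score), ``distance = 1 - auc``, one
    ``v_<t>`` column per requested risk threshold, and the cohort size.
    When ``status`` is given its five flags are joined in.
    """
    thresholds = tuple(float(t) for t in thresholds)
    for t in thresholds:
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"threshold {t} outside [0, 1]")
    n = len(scores.individuals)
    auc = scores.d_scores.mean(axis=0)
    data: dict[str, np.ndarray] = {"auc": auc, "distance": 1.0 - auc}
    for t in thresholds:
        data[f"v_{t:g}"] = (scores.d_scores < t).mean(axis=0)
    frame = pd.DataFrame(data, index=pd.Index(scores.drugs, name="drug_id"))
    frame["n_individuals"] = n
    if status is not None:
        flags = status.frame.reindex(frame.index).fillna(False).astype(bool)
        frame = frame.join(flags)
    return PopulationSummary(frame=frame, thresholds=thresholds, epsilon=scores.epsilon)


def write_score_matrix(scores: ScoreMatrix, path: str | Path,
                       header_comment: str | None = None) -> None:
    """Serialize the individual × drug D-score matrix as TSV."""
    _write_frame(scores.to_frame(), path, header_comment)


def write_population_summary(summary: PopulationSummary, path: str | Path,
                             header_comment: str | None = None) -> None:
    """Serialize the per-drug population summary as TSV."""
    _write_frame(summary.frame, path, header_comment)


def read_score_matrix(path: str | Path, epsilon: float = DEFAULT_EPSILON) -> ScoreMatrix:
    """Read back a D-score matrix written by :func:`write_score_matrix`."""
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return ScoreMatrix(
        individuals=[str(i) for i in frame.index],
        drugs=[str(c) for c in frame.columns],
        d_scores=frame.to_numpy(dtype=float),
        epsilon=epsilon,
    )


def _write_frame(frame: pd.DataFrame, path: str | Path, header_comment: str | None) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t")
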