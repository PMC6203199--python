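"""Background variant construction and the empirical null.

Raw scores have no absolute unit, so significance is empirical: a
variant's score is compared against the scores of a large set of
background variants of the same genomic class (intronic/intergenic)
scored under the same weights.  Background variants are common variants
purged of known pathogenic, GWAS-associated and enhancer-overlapping
sites by a fixed filter cascade.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pines.annotation_io import EXCLUDED, POOLED, AnnotationMatrix, VariantRecord
from pines.intervals import GenomicIntervals
from pines.scoring import (
    BackgroundModel,
    WeightVector,
    estimate_background_model,
    score_matrix,
)

logger = logging.getLogger(__name__)

CLINVAR_REMOVE = frozenset({"Pathogenic", "Likely pathogenic", "Uncertain significance"})
AF_THRESHOLD = 0.05


@dataclass
class BackgroundSet:
    """Filtered background variants plus their per-class sorted scores."""

    variants: list[VariantRecord]
    filter_log: pd.DataFrame
    scores: dict[str, np.ndarray] = field(default_factory=dict)  # class -> sorted ascending

    def set_scores(self, variant_class: str, raw_scores: np.ndarray) -> None:
        s = np.sort(np.asarray(raw_scores, dtype=float))
        if s.size == 0:
            raise ValueError(f"no background scores for class {variant_class!r}")
        self.scores[variant_class] = s


def construct_background(
    candidates: list[VariantRecord],
    clinvar_table: pd.DataFrame | None = None,
    gwas_catalog_table: pd.DataFrame | None = None,
    enhancers: GenomicIntervals | None = None,
    af_table: pd.DataFrame | None = None,
    af_threshold: float = AF_THRESHOLD,
) -> BackgroundSet:
    """Apply the background filter cascade, logging counts after each step.

    In order: drop candidates whose ClinVar status is Pathogenic /
    Likely pathogenic / Uncertain significance; drop candidates present
    in the GWAS-catalog table; drop candidates overlapping enhancer
    intervals; drop candidates with allele frequency <= ``af_threshold``
    in ANY provided continental column (a candidate with no AF record is
    dropped too, logged as missing-AF).
    """
    if not candidates:
        warnings.warn("empty candidate list: background set is empty", stacklevel=2)
    steps: list[tuple[str, int]] = [("candidates", len(candidates))]
    current = list(candidates)

    if clinvar_table is not None:
        sig = dict(
            zip(clinvar_table["id"].astype(str), clinvar_table["clinical_significance"].astype(str))
        )
        current = [v for v in current if sig.get(v.id) not in CLINVAR_REMOVE]
    steps.append(("clinvar", len(current)))

    if gwas_catalog_table is not None:
        gwas_ids = set(gwas_catalog_table["id"].astype(str))
        current = [v for v in current if v.id not in gwas_ids]
    steps.append(("gwas_catalog", len(current)))

    if enhancers is not None:
        current = [v for v in current if not enhancers.contains(v.chrom, v.pos - 1)]
    steps.append(("enhancer", len(current)))

    n_missing_af = 0
    if af_table is not None:
        af_cols = [c for c in af_table.columns if c != "id"]
        if not af_cols:
            raise ValueError("af_table has no allele-frequency columns")
        af = af_table.set_index(af_table["id"].astype(str))[af_cols].astype(float)
        survivors = []
        for v in current:
            if v.id not in af.index:
                n_missing_af += 1
                logger.info("background candidate %s removed: missing AF", v.id)
                continue
            if (af.loc[v.id] > af_threshold).all():  # any-ancestry rule
                survivors.append(v)
        current = survivors
    steps.append(("allele_frequency", len(current)))

    log = pd.DataFrame(steps, columns=["step", "remaining"])
    log["removed"] = (-log["remaining"].diff()).fillna(0).astype(int)
    if n_missing_af:
        logger.info("%d candidates removed for missing allele frequencies", n_missing_af)
    for _, row in log.iterrows():
        logger.info("background filter %-16s remaining=%d", row["step"], row["remaining"])
    return BackgroundSet(variants=current, filter_log=log)


def empirical_pvalue(score: float | np.ndarray, background_scores: np.ndarray) -> float | np.ndarray:
    """Add-one left-tail empirical p: (1 + #{b <= score}) / (N + 1).

    Smaller raw scores mean more evidence of function, so the left tail
    is the significant one.  Ties at the query score count as <=
    (conservative).  Never returns 0; a score below every background
    value gets 1/(N+1).
    """
    bg = np.asarray(background_scores, dtype=float)
    if bg.size == 0:
        raise ValueError("background score array is empty")
    if np.any(np.diff(bg) < 0):
        bg = np.sort(bg)
    counts = np.searchsorted(bg, score, side="right")
    p = (1.0 + counts) / (bg.size + 1.0)
    return float(p) if np.ndim(score) == 0 else p


def leave_one_out_pvalues(scores: np.ndarray) -> np.ndarray:
    """Each background score's add-one p against the other N−1 scores.

    Used to check null calibration: for continuous scores these are
    uniform on {1/N, ..., 1}.
    """
    s = np.asarray(scores, dtype=float)
    order = np.sort(s)
    counts_incl_self = np.searchsorted(order, s, side="right")
    return counts_incl_self / s.size  # (1 + (c - 1)) / ((N-1) + 1)


def score_variants(
    matrix: AnnotationMatrix,
    models: dict[str, BackgroundModel] | BackgroundModel,
    W: WeightVector | np.ndarray | None,
    background: BackgroundSet | dict[str, np.ndarray],
    weight_source: str | None = None,
) -> pd.DataFrame:
    """Score every variant against its own class's model and background.

    Returns a table with chrom, pos, id, variant_class, raw_score,
    empirical_p, weight_source.  Excluded-class variants are reported
    unscored (NaN).  Variants with undefined angles (zero-length
    projection) get raw_score NaN and empirical_p 1, flagged.
    """
    if isinstance(models, BackgroundModel):
        models = {models.variant_class: models}
    bg_scores = background.scores if isinstance(background, BackgroundSet) else background
    if weight_source is None:
        weight_source = W.source if isinstance(W, WeightVector) else "unweighted"

    classes = matrix.classes
    n = matrix.n_variants
    raw = np.full(n, np.nan)
    pvals = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    for cls in pd.unique(classes):
        idx = np.nonzero(classes == cls)[0]
        if cls == EXCLUDED:
            continue
        model = models.get(cls, models.get(POOLED))
        if model is None:
            raise KeyError(f"no background model for variant class {cls!r}")
        if cls not in bg_scores and POOLED not in bg_scores:
            raise KeyError(f"no background scores for variant class {cls!r}")
        bg = bg_scores.get(cls, bg_scores.get(POOLED))
        scores, undefined = score_matrix(matrix.values[idx], model, W)
        raw[idx] = scores
        ok = ~undefined
        pvals[idx[ok]] = empirical_pvalue(scores[ok], bg)
        pvals[idx[undefined]] = 1.0
        flags[idx[undefined]] = True
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in matrix.variants],
            "pos": [v.pos for v in matrix.variants],
            "id": [v.id for v in matrix.variants],
            "variant_class": classes,
            "raw_score": raw,
            "empirical_p": pvals,
            "undefined_angle": flags,
            "weight_source": weight_source,
        }
    )


def score_with_background(
    query: AnnotationMatrix | np.ndarray,
    background: AnnotationMatrix | np.ndarray,
    W: WeightVector | np.ndarray | None = None,
    k: int = 30,
) -> tuple[np.ndarray, np.ndarray, BackgroundModel]:
    """One-shot pooled pipeline for simulated data.

    Estimates a pooled background model from ``background``, scores the
    background under ``W`` to form the null, then returns the query
    variants' raw scores and empirical p-values (plus the model).
    The background is re-scored under each new W, so weighted p-values
    always use weighted background scores.
    """
    model = estimate_background_model(background, POOLED, k=k)
    bg_scores, bg_undef = score_matrix(background, model, W)
    null = np.sort(bg_scores[~bg_undef])
    q_scores, q_undef = score_matrix(query, model, W)
    pvals = np.where(q_undef, 1.0, empirical_pvalue(np.nan_to_num(q_scores, nan=np.inf), null))
    return q_scores, pvals, model
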