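"""Annotation weight vectors: identity, manual, or enrichment-learned.

Manual weighting places a user-specified constant (default 4, which
balances power towards the selected annotations against power on the
rest) on chosen columns and 1 elsewhere.  Enrichment weighting learns
weights from GWAS lead SNPs: each annotation's overlap count among the
leads is compared with 1000 draws of allele-frequency-matched variant
sets from a background universe, and the weight is −log10 of the
add-one empirical enrichment p-value.  Weights are floored strictly
above zero so no annotation is ever excluded from the model.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from pines.annotation_io import AnnotationMatrix
from pines.scoring import WeightVector
from pines.schema import AnnotationSchema

logger = logging.getLogger(__name__)

DEFAULT_CONSTANT = 4.0
DEFAULT_FLOOR = 0.1
DEFAULT_N_DRAWS = 1000
DEFAULT_AF_BIN_WIDTH = 0.05


def manual_weights(
    schema: AnnotationSchema,
    selected_annotation_ids: list[str],
    constant: float = DEFAULT_CONSTANT,
    floor: float = DEFAULT_FLOOR,
) -> WeightVector:
    """Constant up-weighting of selected columns; all others get 1.

    A constant of 1 reproduces the unweighted analysis.  The constant
    is floored at ``floor`` so every weight stays strictly positive
    (this lets weight sweeps start at 0 without excluding columns).
    """
    unknown = [a for a in selected_annotation_ids if a not in schema]
    if unknown:
        raise KeyError(f"unknown annotation ids: {unknown}")
    if not selected_annotation_ids:
        warnings.warn("empty selection: manual weights reduce to the unweighted vector", stacklevel=2)
    w = np.ones(schema.n_columns)
    w[schema.indices_of(selected_annotation_ids)] = max(float(constant), floor)
    return WeightVector(w, source="manual")


@dataclass
class EnrichmentResult:
    """Per-annotation overlap enrichment of lead SNPs over matched draws."""

    observed_overlap: np.ndarray  # (d,) ints
    null_overlaps: np.ndarray  # (n_draws, d) ints
    enrichment_p: np.ndarray  # (d,) in (0, 1]
    weights: WeightVector

    def to_frame(self, schema: AnnotationSchema) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "annotation_id": schema.ids,
                "observed_overlap": self.observed_overlap,
                "enrichment_p": self.enrichment_p,
                "weight": self.weights.weights,
            }
        )


def _af_bins(af: np.ndarray, bin_width: float) -> np.ndarray:
    af = np.asarray(af, dtype=float)
    if np.any(~np.isfinite(af)) or np.any(af < 0) or np.any(af > 1):
        raise ValueError("allele frequencies must lie in [0, 1]")
    bins = np.floor(af / bin_width).astype(int)
    # af exactly 1.0 falls into the last regular bin
    bins[af >= 1.0] = int(np.floor((1.0 - 1e-12) / bin_width))
    return bins


def enrichment_weights(
    lead_matrix: AnnotationMatrix | np.ndarray,
    lead_af: np.ndarray,
    universe_matrix: AnnotationMatrix | np.ndarray,
    universe_af: np.ndarray,
    n_draws: int = DEFAULT_N_DRAWS,
    af_bin_width: float = DEFAULT_AF_BIN_WIDTH,
    floor: float = DEFAULT_FLOOR,
    seed: int | np.random.Generator = 0,
) -> EnrichmentResult:
    """Learn per-annotation weights from lead-SNP overlap enrichment.

    For each of ``n_draws`` draws, a variant set of the same size and
    allele-frequency bin profile as the leads is sampled from the
    universe (without replacement within a bin when possible, with
    replacement otherwise — logged).  Per annotation:

        enrichment_p = (1 + #{draws with null overlap >= observed}) / (n_draws + 1)
        weight       = max(−log10(enrichment_p), floor)

    Deterministic given the seed; independent of universe row order.
    """
    L = lead_matrix.values if isinstance(lead_matrix, AnnotationMatrix) else np.asarray(lead_matrix, float)
    U = universe_matrix.values if isinstance(universe_matrix, AnnotationMatrix) else np.asarray(universe_matrix, float)
    if L.ndim != 2 or U.ndim != 2 or L.shape[1] != U.shape[1]:
        raise ValueError("lead and universe matrices must share the annotation dimension")
    if L.shape[0] == 0:
        raise ValueError("lead SNP set is empty")
    lead_af = np.asarray(lead_af, dtype=float)
    universe_af = np.asarray(universe_af, dtype=float)
    if len(lead_af) != L.shape[0] or len(universe_af) != U.shape[0]:
        raise ValueError("allele-frequency vectors must align with the matrices")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    L = np.nan_to_num(L)
    U = np.nan_to_num(U)
    observed = L.sum(axis=0).astype(int)

    lead_bins = _af_bins(lead_af, af_bin_width)
    uni_bins = _af_bins(universe_af, af_bin_width)
    # canonical universe order so results do not depend on row order
    bin_members: dict[int, np.ndarray] = {}
    for b in np.unique(lead_bins):
        members = np.nonzero(uni_bins == b)[0]
        if members.size == 0:
            raise ValueError(
                f"no universe variants in allele-frequency bin "
                f"[{b * af_bin_width:.2f}, {(b + 1) * af_bin_width:.2f})"
            )
        # canonical content order (af, then annotation bits): draws are
        # invariant to permutations of the universe rows
        keys = tuple(U[members, j] for j in range(U.shape[1] - 1, -1, -1)) + (universe_af[members],)
        bin_members[b] = members[np.lexsort(keys)]
    bin_counts = {b: int(np.sum(lead_bins == b)) for b in bin_members}
    for b, need in bin_counts.items():
        if len(bin_members[b]) < need:
            logger.info(
                "AF bin %d has %d universe variants for %d leads: sampling with replacement",
                b, len(bin_members[b]), need,
            )

    d = U.shape[1]
    null_overlaps = np.empty((n_draws, d), dtype=int)
    for t in range(n_draws):
        rows = []
        for b, need in bin_counts.items():
            pool = bin_members[b]
            replace = len(pool) < need
            rows.append(rng.choice(pool, size=need, replace=replace))
        idx = np.concatenate(rows)
        null_overlaps[t] = U[idx].sum(axis=0)

    exceed = (null_overlaps >= observed[None, :]).sum(axis=0)
    enrichment_p = (1.0 + exceed) / (n_draws + 1.0)
    weights = np.maximum(-np.log10(enrichment_p), floor)
    return EnrichmentResult(
        observed_overlap=observed,
        null_overlaps=null_overlaps,
        enrichment_p=enrichment_p,
        weights=WeightVector(weights, source="enrichment"),
    )
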