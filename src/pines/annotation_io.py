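"""Variant input, genomic-context classification, and the binary annotation matrix.

Variant positions are 1-based (VCF convention); interval tracks are
0-based half-open (BED convention); the conversion happens exactly once,
at the overlap test.  Indels and multi-nucleotide variants are annotated
by their leftmost position.

Variants are classified against a gene model before scoring: positions
inside an exon or UTR are *excluded* (the score is defined for noncoding
variants only), positions inside a transcript but outside its exons are
*intronic*, and everything else is *intergenic*.  Intronic and
intergenic variants are scored against separate backgrounds because
their annotation architectures differ.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from pines.intervals import GenomicIntervals, normalize_chrom
from pines.schema import AnnotationSchema

logger = logging.getLogger(__name__)

INTRONIC = "intronic"
INTERGENIC = "intergenic"
EXCLUDED = "excluded"
POOLED = "pooled"


@dataclass
class VariantRecord:
    chrom: str
    pos: int  # 1-based
    id: str
    variant_class: str | None = None
    tss_distance: int | None = None

    def __post_init__(self) -> None:
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos} for {self.id}")


@dataclass
class AnnotationMatrix:
    """Variants x annotations binary matrix; NaN marks missing data.

    Missingness is explicit (a column whose track is unavailable is NaN
    for every variant), never silently coerced to 0; downstream scoring
    imputes missing entries to the background column mean.
    """

    variants: list[VariantRecord]
    values: np.ndarray  # float array, entries in {0.0, 1.0, nan}
    schema: AnnotationSchema

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if self.values.shape != (len(self.variants), self.schema.n_columns):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.variants)} variants x {self.schema.n_columns} schema columns"
            )
        finite = self.values[np.isfinite(self.values)]
        if finite.size and not np.isin(finite, (0.0, 1.0)).all():
            raise ValueError("annotation entries must be 0, 1 or NaN")

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.values)

    @property
    def classes(self) -> np.ndarray:
        return np.array([v.variant_class for v in self.variants], dtype=object)

    def subset(self, rows: Sequence[int] | np.ndarray) -> "AnnotationMatrix":
        rows = np.asarray(rows)
        return AnnotationMatrix(
            [self.variants[i] for i in rows], self.values[rows], self.schema
        )

    def for_class(self, variant_class: str) -> "AnnotationMatrix":
        if variant_class == POOLED:
            keep = [i for i, v in enumerate(self.variants) if v.variant_class != EXCLUDED]
            return self.subset(keep) if len(keep) < self.n_variants else self
        return self.subset([i for i, v in enumerate(self.variants) if v.variant_class == variant_class])


def read_variants_tsv(path, chrom_style: str = "strip") -> list[VariantRecord]:
    """Read a 3-column tab-separated variant list: chrom, pos (1-based), id.

    A header line is tolerated (detected by a non-numeric second field).
    """
    out: list[VariantRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            if lineno == 1 and not fields[1].isdigit():
                continue  # header
            out.append(
                VariantRecord(normalize_chrom(fields[0], chrom_style), int(fields[1]), fields[2])
            )
    return out


def read_variants_vcf(path, chrom_style: str = "strip") -> list[VariantRecord]:
    """Read variants from a VCF; only CHROM, POS and ID are used."""
    from cyvcf2 import VCF

    out: list[VariantRecord] = []
    for i, v in enumerate(VCF(str(path))):
        vid = v.ID if v.ID else f"var{i}"
        out.append(VariantRecord(normalize_chrom(v.CHROM, chrom_style), v.POS, vid))
    return out


def build_annotation_matrix(
    variants: Sequence[VariantRecord],
    tracks: dict[str, GenomicIntervals],
    schema: AnnotationSchema,
) -> AnnotationMatrix:
    """Binary overlap matrix: entry (i, j) = 1 iff variant i lies in track j.

    The 1-based variant position is converted to 0-based before the
    half-open membership test, so a variant at a BED interval's end
    coordinate does not overlap it.  Schema columns without a track are
    missing-for-all (NaN).  A variant on a chromosome absent from every
    track gets an all-zero row and a warning, not an error.
    """
    unknown = set(tracks) - set(schema.ids)
    if unknown:
        raise KeyError(f"tracks not in schema: {sorted(unknown)}")
    n, d = len(variants), schema.n_columns
    values = np.full((n, d), np.nan)
    track_chroms: set[str] = set()
    for j, col in enumerate(schema.columns):
        track = tracks.get(col.annotation_id)
        if track is None:
            continue  # missing-for-all column
        track_chroms |= track.chromosomes
        values[:, j] = [1.0 if track.contains(v.chrom, v.pos - 1) else 0.0 for v in variants]
    orphan = sorted({v.chrom for v in variants} - track_chroms) if tracks else []
    if orphan:
        warnings.warn(
            f"{sum(v.chrom in orphan for v in variants)} variant(s) on chromosome(s) "
            f"{orphan} absent from all tracks; rows are all-zero",
            stacklevel=2,
        )
    return AnnotationMatrix(list(variants), values, schema)


# --- gene models -----------------------------------------------------------


@dataclass
class GeneModel:
    """Transcript spans, exon spans and TSS positions for classification.

    Spans are 0-based half-open; TSS positions are 1-based.
    """

    transcripts: GenomicIntervals
    exons: GenomicIntervals
    tss: dict[str, np.ndarray] = field(default_factory=dict)  # sorted 1-based positions

    def __post_init__(self) -> None:
        self.tss = {c: np.sort(np.asarray(p, dtype=int)) for c, p in self.tss.items()}

    @property
    def n_transcripts(self) -> int:
        return self.transcripts.n_intervals

    def nearest_tss_distance(self, chrom: str, pos: int) -> int | None:
        best: int | None = None
        for positions in ([self.tss[chrom]] if chrom in self.tss else self.tss.values()):
            i = np.searchsorted(positions, pos)
            for j in (i - 1, i):
                if 0 <= j < len(positions):
                    dist = abs(pos - int(positions[j]))
                    if best is None or dist < best:
                        best = dist
        return best


def read_gene_model_bed12(path, chrom_style: str = "strip") -> GeneModel:
    """Gene model from BED12: blocks are exons, TSS from strand."""
    transcripts = GenomicIntervals("transcripts")
    exons = GenomicIntervals("exons")
    tss: dict[str, list[int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 columns, got {len(f)}")
            chrom = normalize_chrom(f[0], chrom_style)
            start, end, strand = int(f[1]), int(f[2]), f[5]
            sizes = [int(s) for s in f[10].rstrip(",").split(",")]
            offsets = [int(s) for s in f[11].rstrip(",").split(",")]
            transcripts.add(chrom, start, end, chrom_style="none")
            for size, off in zip(sizes, offsets):
                exons.add(chrom, start + off, start + off + size, chrom_style="none")
            # TSS as 1-based position of the transcript's 5' end
            tss.setdefault(chrom, []).append(end if strand == "-" else start + 1)
    return GeneModel(transcripts, exons, {c: np.array(p) for c, p in tss.items()})


def read_gene_model_gff3(path, chrom_style: str = "strip") -> GeneModel:
    """Gene model from GFF3 via gffutils (in-memory database)."""
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts = GenomicIntervals("transcripts")
    exons = GenomicIntervals("exons")
    tss: dict[str, list[int]] = {}
    transcript_types = {"mRNA", "transcript"}
    for feat in db.all_features():
        chrom = normalize_chrom(feat.seqid, chrom_style)
        if feat.featuretype in transcript_types:
            transcripts.add(chrom, feat.start - 1, feat.end, chrom_style="none")
            tss.setdefault(chrom, []).append(feat.end if feat.strand == "-" else feat.start)
        elif feat.featuretype == "exon":
            exons.add(chrom, feat.start - 1, feat.end, chrom_style="none")
    return GeneModel(transcripts, exons, {c: np.array(p) for c, p in tss.items()})


def classify_variants(
    variants: Iterable[VariantRecord], gene_model: GeneModel
) -> list[VariantRecord]:
    """Fill ``variant_class`` and ``tss_distance`` in place.

    Inside an exon/UTR -> excluded; inside a transcript but outside all
    exons -> intronic; outside all transcripts -> intergenic.
    """
    if gene_model.n_transcripts == 0:
        raise ValueError("empty gene model: classification impossible")
    variants = list(variants)
    for v in variants:
        pos0 = v.pos - 1
        if gene_model.exons.contains(v.chrom, pos0):
            v.variant_class = EXCLUDED
        elif gene_model.transcripts.contains(v.chrom, pos0):
            v.variant_class = INTRONIC
        else:
            v.variant_class = INTERGENIC
        v.tss_distance = gene_model.nearest_tss_distance(v.chrom, v.pos)
    return variants
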