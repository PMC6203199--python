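"""Simulated annotation matrices and toy genomic fixtures.

Three simulation designs exercise the scoring model:

* ``simulate_celltype_specific`` — 5000 background variants with
  independent Bernoulli(0.3) annotations plus 100 cell-type-specific
  variants whose 10 "hot" annotations fire at Bernoulli(0.9) and the
  remaining 90 at Bernoulli(0.1).
* ``simulate_blocks`` — 10 blocks of 10 binary annotations each,
  correlated within a block (latent Gaussian copula, exchangeable
  correlation) and independent across blocks.
* ``simulate_correlated_annotations`` — 20,000 binary vectors over 100
  annotations with a random positive-definite correlation matrix from a
  random factor model.

``generate_fixture_tracks`` writes a small on-disk bundle (BED tracks,
VCF, gene models, filter tables) with known ground truth for testing
the I/O and background-construction paths.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from pines.annotation_io import AnnotationMatrix, VariantRecord
from pines.schema import AnnotationSchema, generic_schema


@dataclass
class SimulationConfig:
    """Parameters of the cell-type-specific simulation (defaults = study scale)."""

    n_background: int = 5000
    n_specific: int = 100
    n_annotations: int = 100
    n_hot: int = 10  # annotations characteristic of the specific cell type
    p_background: float = 0.3
    p_hot: float = 0.9
    p_cold: float = 0.1
    weight_constant: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_background", "p_hot", "p_cold"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {p}")
        if not 0 < self.n_hot <= self.n_annotations:
            raise ValueError("n_hot must lie in (0, n_annotations]")

    @property
    def hot_ids(self) -> list[str]:
        schema = generic_schema(self.n_annotations)
        return schema.ids[: self.n_hot]


def simulate_celltype_specific(
    config: SimulationConfig,
) -> tuple[AnnotationMatrix, np.ndarray]:
    """Background + cell-type-specific variants with independent Bernoulli entries.

    Returns the stacked matrix (background rows first) and boolean truth
    labels (True = cell-type-specific).
    """
    rng = np.random.default_rng(config.seed)
    d, h = config.n_annotations, config.n_hot
    bg = (rng.random((config.n_background, d)) < config.p_background).astype(float)
    spec = np.empty((config.n_specific, d))
    spec[:, :h] = rng.random((config.n_specific, h)) < config.p_hot
    spec[:, h:] = rng.random((config.n_specific, d - h)) < config.p_cold
    values = np.vstack([bg, spec])
    labels = np.r_[np.zeros(config.n_background, bool), np.ones(config.n_specific, bool)]
    schema = generic_schema(d)
    variants = [
        VariantRecord("1", i + 1, f"sim{i}", variant_class="intergenic")
        for i in range(len(values))
    ]
    return AnnotationMatrix(variants, values, schema), labels


def _equicorrelated_binary(
    rng: np.random.Generator, n: int, sizes: list[int], rho: float, p: float
) -> np.ndarray:
    """Blocks of correlated Bernoulli(p) columns via a latent Gaussian copula.

    Within a block the latent variables share one factor:
    zⱼ = sqrt(rho)·g + sqrt(1−rho)·eⱼ, giving exchangeable latent
    correlation rho; the binary value is 1 when z exceeds the upper-p
    normal quantile.  Blocks are mutually independent.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"within-block correlation must lie in [0, 1), got {rho}")
    if not 0.0 < p < 1.0:
        raise ValueError(f"marginal probability must lie in (0, 1), got {p}")
    thresh = stats.norm.ppf(1.0 - p)
    cols = []
    for size in sizes:
        g = rng.standard_normal((n, 1))
        e = rng.standard_normal((n, size))
        z = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
        cols.append((z > thresh).astype(float))
    return np.hstack(cols)


def simulate_blocks(
    n_variants: int = 10000,
    block_sizes: list[int] | None = None,
    within_block_correlation: float = 0.7,
    p: float = 0.3,
    seed: int = 0,
) -> AnnotationMatrix:
    """Block-correlated binary annotations (default 10 blocks of 10)."""
    if block_sizes is None:
        block_sizes = [10] * 10
    rng = np.random.default_rng(seed)
    values = _equicorrelated_binary(rng, n_variants, block_sizes, within_block_correlation, p)
    schema = generic_schema(sum(block_sizes))
    variants = [
        VariantRecord("1", i + 1, f"blk{i}", variant_class="intergenic")
        for i in range(n_variants)
    ]
    return AnnotationMatrix(variants, values, schema)


def random_correlation_matrix(
    n_annotations: int = 100,
    n_factors: int = 1,
    factor_scale: float = 2.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Random positive-definite correlation matrix from a factor model.

    Loadings are positive (|N(0, factor_scale²)|), producing the
    strongly positively correlated regime; a unit diagonal noise term
    guarantees positive definiteness before normalization.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    A = np.abs(rng.normal(0.0, factor_scale, size=(n_annotations, n_factors)))
    S = A @ A.T + np.eye(n_annotations)
    dinv = 1.0 / np.sqrt(np.diag(S))
    return S * dinv[:, None] * dinv[None, :]


def simulate_correlated_annotations(
    n_annotations: int = 100,
    n_variants: int = 20000,
    p: float = 0.5,
    n_factors: int = 1,
    seed: int = 0,
) -> tuple[AnnotationMatrix, np.ndarray]:
    """Binary vectors with a random dense positive correlation structure.

    Returns the matrix and the latent correlation matrix used.
    """
    rng = np.random.default_rng(seed)
    R = random_correlation_matrix(n_annotations, n_factors=n_factors, seed=rng)
    L = np.linalg.cholesky(R)
    z = rng.standard_normal((n_variants, n_annotations)) @ L.T
    values = (z > stats.norm.ppf(1.0 - p)).astype(float)
    schema = generic_schema(n_annotations)
    variants = [
        VariantRecord("1", i + 1, f"cor{i}", variant_class="intergenic")
        for i in range(n_variants)
    ]
    return AnnotationMatrix(variants, values, schema), R


# --- on-disk fixtures ------------------------------------------------------


@dataclass
class FixtureBundle:
    """Paths and ground truth of a generated toy fixture."""

    root: Path
    tracks_manifest: Path
    schema_tsv: Path
    variants_tsv: Path
    variants_vcf: Path
    gene_model_gff3: Path
    gene_model_bed12: Path
    clinvar_tsv: Path
    gwas_catalog_tsv: Path
    enhancer_bed: Path
    af_tsv: Path
    leads_tsv: Path
    truth: dict = field(default_factory=dict)


def generate_fixture_tracks(
    outdir,
    seed: int = 0,
    n_tracks: int = 4,
    n_variants: int = 20,
    chrom_length: int = 100_000,
) -> FixtureBundle:
    """Write a deterministic toy bundle of standard-format inputs.

    The bundle contains BED peak tracks, variants as both TSV and VCF,
    GFF3/BED12 gene models, ClinVar-like / GWAS-catalog-like / allele-
    frequency filter tables, an enhancer BED and a lead-SNP list.  The
    ground-truth overlap matrix and the expected background filter
    cascade counts are computed during generation and stored in
    ``truth`` (and as fixture_truth.json).
    """
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # annotation tracks
    schema_rows = []
    track_paths = {}
    intervals_by_track: dict[str, list[tuple[int, int]]] = {}
    for t in range(n_tracks):
        tid = f"mark{t}.cellA"
        schema_rows.append((tid, f"mark{t}", "cellA", "toy"))
        ivs = []
        pos = 0
        while pos < chrom_length - 2000:
            gap = int(rng.integers(500, 5000))
            width = int(rng.integers(200, 1500))
            start = pos + gap
            ivs.append((start, start + width))
            pos = start + width
        intervals_by_track[tid] = ivs
        path = root / f"track_{tid}.bed"
        with open(path, "w") as fh:
            for start, end in ivs:
                fh.write(f"chr1\t{start}\t{end}\t{tid}\n")
        track_paths[tid] = path

    schema_tsv = root / "schema.tsv"
    pd.DataFrame(schema_rows, columns=["annotation_id", "mark", "cell_type", "group"]).to_csv(
        schema_tsv, sep="\t", index=False
    )
    manifest = root / "tracks_manifest.tsv"
    pd.DataFrame(
        {"annotation_id": list(track_paths), "path": [str(p) for p in track_paths.values()]}
    ).to_csv(manifest, sep="\t", index=False)

    # variants (1-based positions)
    # spacing >= 100 bp so the 50-bp enhancer interval hits exactly one variant
    grid = np.arange(1, chrom_length, 100)
    positions = np.sort(rng.choice(grid, size=n_variants, replace=False))
    ids = [f"rs{1000 + i}" for i in range(n_variants)]
    variants_tsv = root / "variants.tsv"
    with open(variants_tsv, "w") as fh:
        fh.write("chrom\tpos\tid\n")
        for pos, vid in zip(positions, ids):
            fh.write(f"chr1\t{pos}\t{vid}\n")
    variants_vcf = root / "variants.vcf"
    with open(variants_vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1,length=%d>\n" % chrom_length)
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for pos, vid in zip(positions, ids):
            fh.write(f"chr1\t{pos}\t{vid}\tA\tG\t.\t.\t.\n")

    # ground-truth overlap by brute-force scan (independent of the
    # interval-tree query path)
    truth_matrix = np.zeros((n_variants, n_tracks))
    for j, tid in enumerate(track_paths):
        for i, pos in enumerate(positions):
            p0 = pos - 1
            truth_matrix[i, j] = float(any(s <= p0 < e for s, e in intervals_by_track[tid]))

    # gene model: two genes on chr1
    genes = [
        ("gene1", 10_000, 30_000, "+", [(10_000, 11_000), (29_000, 30_000)]),
        ("gene2", 60_000, 80_000, "-", [(60_000, 61_000), (79_000, 80_000)]),
    ]
    gene_model_gff3 = root / "genes.gff3"
    with open(gene_model_gff3, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, start, end, strand, exons in genes:
            fh.write(
                f"chr1\ttoy\tgene\t{start + 1}\t{end}\t.\t{strand}\t.\tID={name}\n"
            )
            fh.write(
                f"chr1\ttoy\tmRNA\t{start + 1}\t{end}\t.\t{strand}\t.\tID={name}.t1;Parent={name}\n"
            )
            for x, (es, ee) in enumerate(exons):
                fh.write(
                    f"chr1\ttoy\texon\t{es + 1}\t{ee}\t.\t{strand}\t.\t"
                    f"ID={name}.e{x};Parent={name}.t1\n"
                )
    gene_model_bed12 = root / "genes.bed12"
    with open(gene_model_bed12, "w") as fh:
        for name, start, end, strand, exons in genes:
            sizes = ",".join(str(ee - es) for es, ee in exons)
            offs = ",".join(str(es - start) for es, ee in exons)
            fh.write(
                f"chr1\t{start}\t{end}\t{name}\t0\t{strand}\t{start}\t{end}\t0\t"
                f"{len(exons)}\t{sizes}\t{offs}\n"
            )

    # filter tables: 2 pathogenic-like, 1 GWAS-catalog, 1 enhancer hit,
    # 2 low-frequency; remaining variants survive the cascade
    clinvar_ids = ids[:2]
    gwas_ids = [ids[2]]
    enhancer_id = ids[3]
    lowfreq_ids = ids[4:6]
    clinvar_tsv = root / "clinvar.tsv"
    pd.DataFrame(
        {
            "id": clinvar_ids + [ids[6]],
            "clinical_significance": ["Pathogenic", "Likely pathogenic", "Benign"],
        }
    ).to_csv(clinvar_tsv, sep="\t", index=False)
    gwas_catalog_tsv = root / "gwas_catalog.tsv"
    pd.DataFrame({"id": gwas_ids}).to_csv(gwas_catalog_tsv, sep="\t", index=False)
    enhancer_bed = root / "enhancers.bed"
    enh_pos = int(positions[ids.index(enhancer_id)])
    with open(enhancer_bed, "w") as fh:
        fh.write(f"chr1\t{enh_pos - 1}\t{enh_pos + 49}\tenh1\n")

    af_rows = []
    for vid in ids:
        if vid in lowfreq_ids:
            afs = [0.30, 0.25, 0.40, 0.04]  # fails the any-ancestry rule on EUR
        else:
            afs = list(np.round(rng.uniform(0.08, 0.5, size=4), 3))
        af_rows.append([vid] + afs)
    af_tsv = root / "af.tsv"
    pd.DataFrame(af_rows, columns=["id", "AFR", "AMR", "ASN", "EUR"]).to_csv(
        af_tsv, sep="\t", index=False
    )

    # lead SNPs: a handful of variants with reference AF
    lead_rows = []
    af_lookup = {r[0]: r[4] for r in af_rows}
    for vid in ids[6:10]:
        i = ids.index(vid)
        lead_rows.append(["chr1", int(positions[i]), vid, af_lookup[vid]])
    leads_tsv = root / "leads.tsv"
    pd.DataFrame(lead_rows, columns=["chrom", "pos", "id", "af"]).to_csv(
        leads_tsv, sep="\t", index=False
    )

    # expected filter cascade on the full variant list
    n0 = n_variants
    n1 = n0 - len(clinvar_ids)
    n2 = n1 - len(gwas_ids)
    n3 = n2 - 1  # the enhancer-overlapping variant
    n4 = n3 - len(lowfreq_ids)
    truth = {
        "overlap_matrix": truth_matrix.tolist(),
        "variant_ids": ids,
        "cascade_remaining": [n0, n1, n2, n3, n4],
    }
    with open(root / "fixture_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)

    return FixtureBundle(
        root=root,
        tracks_manifest=manifest,
        schema_tsv=schema_tsv,
        variants_tsv=variants_tsv,
        variants_vcf=variants_vcf,
        gene_model_gff3=gene_model_gff3,
        gene_model_bed12=gene_model_bed12,
        clinvar_tsv=clinvar_tsv,
        gwas_catalog_tsv=gwas_catalog_tsv,
        enhancer_bed=enhancer_bed,
        af_tsv=af_tsv,
        leads_tsv=leads_tsv,
        truth=truth,
    )
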