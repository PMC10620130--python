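"""Somatic-variant evidence filtering, tumour mutational burden, and
allele-specific expression (ASE) classification of somatic mutations.

A somatic variant passes the evidence filter when tumour coverage >= 50x,
control coverage >= 30x, tumour mutant allele frequency (MAF) >= 0.03 and at
least 5 tumour reads support the mutant allele (all inclusive).

Each filtered mutation joined to RNA evidence (gene expression in TPM and
RNA allele counts at the locus) is classified into one of four categories:

- ``NOT_COVERED``: no RNA reads overlap the locus; excluded from summaries.
- ``GENE_NOT_EXPRESSED``: gene TPM below 2.
- ``MUTATED_EXPRESSED``: gene TPM >= 2 and RNA variant allele fraction
  (VAF) strictly above 3%.
- ``MUTATED_NOT_EXPRESSED``: gene expressed but RNA VAF <= 3% — only the
  wild-type allele is expressed.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class SomaticVariant:
    sample_id: str
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    gene: str
    variant_class: str  # "SNV" or "INDEL"
    tumour_depth: int
    control_depth: int
    tumour_alt_reads: int

    def __post_init__(self) -> None:
        if self.variant_class not in ("SNV", "INDEL"):
            raise ValueError(f"variant_class must be SNV or INDEL, got {self.variant_class!r}")
        if self.tumour_alt_reads > self.tumour_depth:
            raise ValueError("tumour_alt_reads cannot exceed tumour_depth")
        if min(self.tumour_depth, self.control_depth, self.tumour_alt_reads) < 0:
            raise ValueError("depths and read counts must be non-negative")

    @property
    def tumour_maf(self) -> float:
        """Mutant allele frequency in the tumour sample."""
        return self.tumour_alt_reads / self.tumour_depth if self.tumour_depth else 0.0


@dataclass(frozen=True)
class FilterThresholds:
    tumour_depth_min: int = 50
    control_depth_min: int = 30
    maf_min: float = 0.03
    alt_reads_min: int = 5


def filter_somatic(
    variants: Sequence[SomaticVariant],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[SomaticVariant]:
    """Keep variants meeting all four evidence thresholds (each inclusive);
    input order preserved."""
    t = thresholds
    return [
        v
        for v in variants
        if v.tumour_depth >= t.tumour_depth_min
        and v.control_depth >= t.control_depth_min
        and v.tumour_maf >= t.maf_min
        and v.tumour_alt_reads >= t.alt_reads_min
    ]


def compute_tmb(n_protein_coding_mutations: int, target_size_mb: float) -> dict:
    """Tumour mutational burden in mutations per Mb of the sequenced target;
    low when strictly below 5/Mb."""
    if target_size_mb <= 0:
        raise ValueError("target_size_mb must be positive")
    if n_protein_coding_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    tmb = n_protein_coding_mutations / target_size_mb
    return {"tmb": tmb, "low_tmb": tmb < 5.0}


class AseClass(enum.Enum):
    MUTATED_EXPRESSED = "mutated_expressed"
    MUTATED_NOT_EXPRESSED = "mutated_not_expressed"
    GENE_NOT_EXPRESSED = "gene_not_expressed"
    NOT_COVERED = "not_covered"


@dataclass(frozen=True)
class AseObservation:
    """A somatic variant joined to its RNA evidence."""

    variant: SomaticVariant
    gene_tpm: float
    rna_ref_count: int
    rna_alt_count: int

    def __post_init__(self) -> None:
        if self.gene_tpm < 0:
            raise ValueError("gene_tpm must be non-negative")
        if self.rna_ref_count < 0 or self.rna_alt_count < 0:
            raise ValueError("RNA allele counts must be non-negative")

    @property
    def rna_depth(self) -> int:
        return self.rna_ref_count + self.rna_alt_count

    @property
    def rna_vaf(self) -> Optional[float]:
        """RNA variant allele fraction; None when the locus has no RNA reads."""
        return self.rna_alt_count / self.rna_depth if self.rna_depth else None


def classify_ase(
    obs: AseObservation, tpm_min: float = 2.0, vaf_min: float = 0.03
) -> AseClass:
    """Assign the ASE category of one mutation.

    The VAF comparison is strict (> vaf_min) for "expressed" and inclusive
    (<= vaf_min) for "not expressed"; the TPM comparison is >= tpm_min for
    an expressed gene and < tpm_min for a non-expressed gene.
    """
    if obs.rna_depth == 0:
        return AseClass.NOT_COVERED
    if obs.gene_tpm < tpm_min:
        return AseClass.GENE_NOT_EXPRESSED
    if obs.rna_vaf > vaf_min:
        return AseClass.MUTATED_EXPRESSED
    return AseClass.MUTATED_NOT_EXPRESSED


def ase_sample_summary(
    observations: Sequence[AseObservation],
    tpm_min: float = 2.0,
    vaf_min: float = 0.03,
) -> dict[AseClass, float]:
    """Proportion of each expressed/not-expressed/gene-not-expressed class
    among a sample's covered mutations (NOT_COVERED excluded from the
    denominator)."""
    classes = [classify_ase(o, tpm_min, vaf_min) for o in observations]
    covered = [c for c in classes if c is not AseClass.NOT_COVERED]
    if not covered:
        sample = observations[0].variant.sample_id if observations else "<empty>"
        raise ValueError(
            f"sample {sample}: no mutation is covered by RNA data"
        )
    counts = Counter(covered)
    n = len(covered)
    return {
        AseClass.MUTATED_EXPRESSED: counts[AseClass.MUTATED_EXPRESSED] / n,
        AseClass.MUTATED_NOT_EXPRESSED: counts[AseClass.MUTATED_NOT_EXPRESSED] / n,
        AseClass.GENE_NOT_EXPRESSED: counts[AseClass.GENE_NOT_EXPRESSED] / n,
    }


def ase_cohort_summary(
    observations: Iterable[AseObservation],
    tpm_min: float = 2.0,
    vaf_min: float = 0.03,
) -> pd.DataFrame:
    """Per-sample ASE proportions plus a variant-pooled row.

    Per-sample rows average nothing across samples; the ``pooled`` row
    divides class counts over all covered mutations of the cohort — the two
    conventions can differ and are reported separately.
    """
    by_sample: dict[str, list[AseObservation]] = {}
    for o in observations:
        by_sample.setdefault(o.variant.sample_id, []).append(o)
    rows = []
    pooled: Counter = Counter()
    pooled_n = 0
    for sample in sorted(by_sample):
        obs = by_sample[sample]
        props = ase_sample_summary(obs, tpm_min, vaf_min)
        covered = [
            c
            for c in (classify_ase(o, tpm_min, vaf_min) for o in obs)
            if c is not AseClass.NOT_COVERED
        ]
        pooled.update(covered)
        pooled_n += len(covered)
        rows.append(
            {
                "sample": sample,
                "n_covered": len(covered),
                "prop_mutated_expressed": props[AseClass.MUTATED_EXPRESSED],
                "prop_mutated_not_expressed": props[AseClass.MUTATED_NOT_EXPRESSED],
                "prop_gene_not_expressed": props[AseClass.GENE_NOT_EXPRESSED],
            }
        )
    if pooled_n:
        rows.append(
            {
                "sample": "pooled",
                "n_covered": pooled_n,
                "prop_mutated_expressed": pooled[AseClass.MUTATED_EXPRESSED] / pooled_n,
                "prop_mutated_not_expressed": pooled[AseClass.MUTATED_NOT_EXPRESSED] / pooled_n,
                "prop_gene_not_expressed": pooled[AseClass.GENE_NOT_EXPRESSED] / pooled_n,
            }
        )
    return pd.DataFrame(rows)


_VARIANT_COLUMNS = (
    "sample", "chrom", "pos", "ref", "alt", "gene", "variant_class",
    "tumour_depth", "control_depth", "tumour_alt_reads",
)


def read_variant_table(path) -> list[SomaticVariant]:
    """Read somatic variants from a TSV with the SomaticVariant columns."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample": str})
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    return [
        SomaticVariant(
            sample_id=str(r.sample),
            chrom=str(r.chrom),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            gene=str(r.gene),
            variant_class=str(r.variant_class),
            tumour_depth=int(r.tumour_depth),
            control_depth=int(r.control_depth),
            tumour_alt_reads=int(r.tumour_alt_reads),
        )
        for r in df.itertuples()
    ]


def read_ase_table(path, variants: Sequence[SomaticVariant]) -> list[AseObservation]:
    """Join an RNA-evidence TSV (``sample chrom pos gene_tpm rna_ref_count
    rna_alt_count``) onto variants by (sample, chrom, pos)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample": str})
    needed = ("sample", "chrom", "pos", "gene_tpm", "rna_ref_count", "rna_alt_count")
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s): {', '.join(missing)}")
    rna = {
        (str(r.sample), str(r.chrom), int(r.pos)): r
        for r in df.itertuples()
    }
    out = []
    for v in variants:
        r = rna.get((v.sample_id, v.chrom, v.pos))
        if r is None:
            continue
        out.append(
            AseObservation(
                variant=v,
                gene_tpm=float(r.gene_tpm),
                rna_ref_count=int(r.rna_ref_count),
                rna_alt_count=int(r.rna_alt_count),
            )
        )
    return out
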