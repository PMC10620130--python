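"""Synthetic segment profiles, ASE tables and DE tables with planted truth.

Because the sequencing data behind a typical allele-specific copy-number
study are rarely public, every pipeline stage here is exercised against
constructively generated inputs whose ground truth is known by design:
values are planted to satisfy the defining inequalities of their class with
a margin, not sampled from fitted distributions.  Realism knobs (segment
boundary jitter) are cosmetic.

The bundled fixture tables (`load_fixture`) describe a 21-sample high-risk
GIST cohort: the per-sample affected-chromosome counts with ploidies and
mitotic counts, and the chromothriptic chromosomes of the high-confidence
samples.  `cohort_spec_from_counts` turns the count table into profile
specs so the whole scoring stage can be re-run end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from gistcin.chromothripsis import (
    ChromothripsisCall,
    ChromothripsisConfig,
    max_switches_in_window,
)
from gistcin.cin_metrics import CinConfig, CinSummary, classify_complexity
from gistcin.expression_integration import (
    ExpressionRecord,
    MirnaRecord,
    TargetInteraction,
)
from gistcin.segment_io import CopyNumberSegment, GenomeBuild, SegmentedProfile, b37
from gistcin.variant_ase import AseClass, AseObservation, SomaticVariant

_FIXTURES = {
    "cohort_cin": "cohort_cin_table.tsv",
    "table2": "cohort_cin_table.tsv",
    "chromothripsis": "chromothripsis_table.tsv",
    "table3": "chromothripsis_table.tsv",
}


def load_fixture(name: str) -> pd.DataFrame:
    """Load a bundled fixture table (``cohort_cin`` or ``chromothripsis``)."""
    if name not in _FIXTURES:
        raise KeyError(f"unknown fixture {name!r}; available: cohort_cin, chromothripsis")
    ref = resources.files("gistcin.fixtures") / _FIXTURES[name]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")


@dataclass(frozen=True)
class ProfileSpec:
    """Planted ground truth for one synthetic sample.

    ``n_cnv_only`` / ``n_loh_only`` / ``n_both`` chromosomes receive,
    respectively, a copy-number gain, a copy-neutral LOH segment, or one of
    each; ``chromothriptic`` entries plant ``n_switches`` copy-number state
    switches whose breakpoints all fall within ``span_bp`` on the named
    chromosome.  Everything else stays diploid heterozygous (2, 1).
    """

    sample_id: str
    group: str = "unknown"
    ploidy: float = 2.0
    n_cnv_only: int = 0
    n_loh_only: int = 0
    n_both: int = 0
    chromothriptic: tuple[tuple[str, int, int], ...] = ()
    seed: int = 0
    sex: Optional[str] = None
    mitotic_count: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.n_cnv_only, self.n_loh_only, self.n_both) < 0:
            raise ValueError("role counts must be non-negative")
        for chrom, k, span in self.chromothriptic:
            if k < 0 or span <= 0:
                raise ValueError(f"bad chromothriptic entry ({chrom}, {k}, {span})")


@dataclass(frozen=True)
class CohortSpec:
    profiles: tuple[ProfileSpec, ...]
    build: GenomeBuild = field(default_factory=b37)
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [p.sample_id for p in self.profiles]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate sample id(s): {', '.join(dupes)}")


@dataclass(frozen=True)
class ProfileGroundTruth:
    """What was planted: the expected CIN summary and per-chromosome
    chromothripsis calls (computed from the planted breakpoint geometry)."""

    cin: CinSummary
    chromothripsis: dict[str, ChromothripsisCall]


def _neutral(chrom: str, start: int, end: int) -> CopyNumberSegment:
    return CopyNumberSegment(chrom, start, end, 2, 1, log_ratio=0.0)


def _plant_cnv(chrom: str, length: int, rng: np.random.Generator) -> list[CopyNumberSegment]:
    a = int(rng.integers(length // 10, length // 3))
    b = int(rng.integers(length // 2, length - length // 10))
    return [
        _neutral(chrom, 0, a),
        CopyNumberSegment(chrom, a, b, 3, 1, log_ratio=float(np.log2(1.5))),
        _neutral(chrom, b, length),
    ]


def _plant_loh(chrom: str, length: int, rng: np.random.Generator) -> list[CopyNumberSegment]:
    a = int(rng.integers(length // 10, length // 3))
    b = int(rng.integers(length // 2, length - length // 10))
    return [
        _neutral(chrom, 0, a),
        CopyNumberSegment(chrom, a, b, 2, 0, log_ratio=0.0),
        _neutral(chrom, b, length),
    ]


def _plant_both(chrom: str, length: int, rng: np.random.Generator) -> list[CopyNumberSegment]:
    q = length // 5
    a, b, c, d = q, 2 * q, 3 * q, 4 * q
    return [
        _neutral(chrom, 0, a),
        CopyNumberSegment(chrom, a, b, 3, 1, log_ratio=float(np.log2(1.5))),
        _neutral(chrom, b, c),
        CopyNumberSegment(chrom, c, d, 2, 0, log_ratio=0.0),
        _neutral(chrom, d, length),
    ]


def _chromothripsis_positions(
    k: int, span_bp: int, offset: int, config: ChromothripsisConfig
) -> list[int]:
    """Breakpoint positions for ``k`` switches within ``span_bp``.

    When the span fits inside the detection window the positions are spread
    evenly (any 50 Mb window then holds them all).  When the span exceeds
    the window, positions are packed into clusters of ``threshold - 1``
    whose sites sit more than one window apart, so no window reaches the
    threshold — geometrically possible only while k <= (threshold - 1) x
    number of sites; beyond that capacity the even spread is used and the
    planted chromosome is necessarily detectable.
    """
    if k == 0:
        return []
    if k == 1:
        return [offset + span_bp // 2]

    def even() -> list[int]:
        # spread over [offset, offset + span_bp) so that a span equal to the
        # detection window still fits inside one half-open window
        return [offset + (i * span_bp) // k for i in range(k)]

    if span_bp <= config.window_bp or k < config.switch_threshold:
        return even()

    cap = config.switch_threshold - 1
    cluster_width = min(2_000_000, span_bp // 20)
    gap = config.window_bp + max(cluster_width, config.window_bp // 10)
    n_sites = (span_bp - cluster_width) // gap + 1
    if k > cap * n_sites:
        return even()
    positions = []
    step = max(1, cluster_width // cap)
    for i in range(k):
        site, slot = divmod(i, cap)
        positions.append(offset + site * gap + slot * step)
    return sorted(positions)


def _plant_chromothripsis(
    chrom: str, length: int, k: int, span_bp: int, config: ChromothripsisConfig
) -> tuple[list[CopyNumberSegment], list[int]]:
    if span_bp > length:
        raise ValueError(f"span {span_bp} exceeds chromosome {chrom} length {length}")
    offset = min(5_000_000, (length - span_bp) // 2)
    positions = _chromothripsis_positions(k, span_bp, offset, config)
    bounds = [0] + positions + [length]
    segments = []
    for i, (s, e) in enumerate(zip(bounds, bounds[1:])):
        total = 2 if i % 2 == 0 else 3
        lr = 0.0 if total == 2 else float(np.log2(1.5))
        segments.append(CopyNumberSegment(chrom, s, e, total, 1, log_ratio=lr))
    return segments, positions


def simulate_profile(
    spec: ProfileSpec,
    build: Optional[GenomeBuild] = None,
    ct_config: ChromothripsisConfig = ChromothripsisConfig(),
    cin_config: CinConfig = CinConfig(),
) -> tuple[SegmentedProfile, ProfileGroundTruth]:
    """Generate one profile with its planted ground truth.

    Deterministic given ``spec.seed``.  Chromosome roles are disjoint:
    chromothriptic chromosomes are claimed first (by name), then CNV-only /
    LOH-only / both roles are assigned to the remaining chromosomes in build
    order.  A chromothriptic chromosome with at least one switch carries
    copy-number gains and therefore also counts as CNV-affected in the
    ground-truth CIN summary.
    """
    build = build or b37()
    rng = np.random.default_rng(spec.seed)

    ct_chroms = [c for c, _, _ in spec.chromothriptic]
    if len(set(ct_chroms)) != len(ct_chroms):
        raise ValueError(f"{spec.sample_id}: duplicate chromothriptic chromosome")
    for c in ct_chroms:
        if c not in build:
            raise ValueError(f"{spec.sample_id}: chromothriptic chromosome {c!r} not in build")

    available = [c for c in build.chrom_names if c not in ct_chroms]
    needed = spec.n_cnv_only + spec.n_loh_only + spec.n_both
    if needed > len(available):
        raise ValueError(
            f"{spec.sample_id}: {needed} role chromosomes requested but only "
            f"{len(available)} available in build {build.name}"
        )
    cnv_chroms = available[: spec.n_cnv_only]
    loh_chroms = available[spec.n_cnv_only : spec.n_cnv_only + spec.n_loh_only]
    both_chroms = available[spec.n_cnv_only + spec.n_loh_only : needed]

    profile = SegmentedProfile(
        sample_id=spec.sample_id,
        group=spec.group,
        ploidy=spec.ploidy,
        sex=spec.sex,
        mitotic_count=spec.mitotic_count,
    )
    ct_calls: dict[str, ChromothripsisCall] = {}
    n_ct_cnv = 0
    for chrom, k, span in spec.chromothriptic:
        length = build.length(chrom)
        segments, positions = _plant_chromothripsis(chrom, length, k, span, ct_config)
        for seg in segments:
            profile.add_segment(seg)
        in_window = max_switches_in_window(positions, ct_config.window_bp)
        ct_calls[chrom] = ChromothripsisCall(
            sample_id=spec.sample_id,
            chrom=chrom,
            n_switches_total=len(positions),
            max_switches_in_window=in_window,
            high_confidence=in_window >= ct_config.switch_threshold,
        )
        if k >= 1:
            n_ct_cnv += 1

    for chrom in cnv_chroms:
        for seg in _plant_cnv(chrom, build.length(chrom), rng):
            profile.add_segment(seg)
    for chrom in loh_chroms:
        for seg in _plant_loh(chrom, build.length(chrom), rng):
            profile.add_segment(seg)
    for chrom in both_chroms:
        for seg in _plant_both(chrom, build.length(chrom), rng):
            profile.add_segment(seg)
    for chrom in build.chrom_names:
        if chrom not in profile.segments:
            profile.add_segment(_neutral(chrom, 0, build.length(chrom)))

    n_cnv = spec.n_cnv_only + n_ct_cnv
    total = n_cnv + spec.n_loh_only + spec.n_both
    truth = ProfileGroundTruth(
        cin=CinSummary(
            sample_id=spec.sample_id,
            n_chr_cnv_only=n_cnv,
            n_chr_loh_only=spec.n_loh_only,
            n_chr_both=spec.n_both,
            n_chr_total=total,
            complexity=classify_complexity(total, cin_config.complexity_threshold),
        ),
        chromothripsis=ct_calls,
    )
    return profile, truth


def simulate_cohort(
    spec: CohortSpec,
    ct_config: ChromothripsisConfig = ChromothripsisConfig(),
    cin_config: CinConfig = CinConfig(),
) -> tuple[list[SegmentedProfile], dict[str, ProfileGroundTruth]]:
    """Generate a cohort; deterministic given the cohort seed (per-sample
    seeds are derived from it and the sample's position)."""
    profiles = []
    truths = {}
    for i, ps in enumerate(spec.profiles):
        derived = ProfileSpec(
            **{
                **ps.__dict__,
                "seed": (spec.seed * 100_003 + i * 7919 + ps.seed) % (2**31),
            }
        )
        profile, truth = simulate_profile(derived, spec.build, ct_config, cin_config)
        profiles.append(profile)
        truths[profile.sample_id] = truth
    return profiles, truths


def cohort_spec_from_counts(
    counts: pd.DataFrame, build: Optional[GenomeBuild] = None, seed: int = 0
) -> CohortSpec:
    """Build a cohort spec from a table with columns ``sample group
    n_chr_cnv n_chr_loh n_chr_cnv_loh [ploidy] [mitotic_count]`` (the
    bundled cohort fixture has exactly this shape)."""
    specs = []
    for r in counts.itertuples():
        specs.append(
            ProfileSpec(
                sample_id=str(r.sample),
                group=str(getattr(r, "group", "unknown")),
                ploidy=float(getattr(r, "ploidy", 2.0)),
                n_cnv_only=int(r.n_chr_cnv),
                n_loh_only=int(r.n_chr_loh),
                n_both=int(r.n_chr_cnv_loh),
                mitotic_count=(
                    float(r.mitotic_count)
                    if hasattr(r, "mitotic_count") and pd.notna(r.mitotic_count)
                    else None
                ),
            )
        )
    return CohortSpec(profiles=tuple(specs), build=build or b37(), seed=seed)


def split_segments_randomly(
    profile: SegmentedProfile, seed: int = 0, n_rounds: int = 1
) -> SegmentedProfile:
    """Segment-noise mode: randomly split segments into adjacent equal-state
    pieces.  Leaves every CIN count and chromothripsis call unchanged, which
    the invariance tests exploit."""
    rng = np.random.default_rng(seed)
    out = SegmentedProfile(
        sample_id=profile.sample_id,
        group=profile.group,
        ploidy=profile.ploidy,
        sex=profile.sex,
        mitotic_count=profile.mitotic_count,
    )
    for chrom in profile.chromosomes():
        segs = list(profile.segments[chrom])
        for _ in range(n_rounds):
            new: list[CopyNumberSegment] = []
            for seg in segs:
                if seg.length > 1 and rng.random() < 0.5:
                    cut = int(rng.integers(seg.start + 1, seg.end))
                    new.append(
                        CopyNumberSegment(
                            seg.chrom, seg.start, cut, seg.total_cn, seg.minor_cn, seg.log_ratio
                        )
                    )
                    new.append(
                        CopyNumberSegment(
                            seg.chrom, cut, seg.end, seg.total_cn, seg.minor_cn, seg.log_ratio
                        )
                    )
                else:
                    new.append(seg)
            segs = new
        for seg in segs:
            out.add_segment(seg)
    return out


def _dummy_variant(sample_id: str, i: int) -> SomaticVariant:
    return SomaticVariant(
        sample_id=sample_id,
        chrom=str(1 + i % 22),
        pos=1000 + i,
        ref="A",
        alt="G",
        gene=f"GENE{i:04d}",
        variant_class="SNV",
        tumour_depth=100,
        control_depth=60,
        tumour_alt_reads=30,
    )


def simulate_ase_table(
    n_per_class: dict[AseClass, int],
    seed: int = 0,
    sample_id: str = "SYN1",
    include_boundaries: bool = False,
    tpm_min: float = 2.0,
    vaf_min: float = 0.03,
) -> tuple[list[AseObservation], list[AseClass]]:
    """ASE observations planted to satisfy each class's defining
    inequalities with a margin away from the boundaries.

    With ``include_boundaries`` two extra observations sit exactly on the
    thresholds: gene TPM exactly at the expression cut-off with a clearly
    expressed allele (expected MUTATED_EXPRESSED, since the TPM rule is
    inclusive) and RNA VAF exactly at the cut-off with an expressed gene
    (expected MUTATED_NOT_EXPRESSED, since the VAF rule for "expressed" is
    strict).
    """
    rng = np.random.default_rng(seed)
    observations: list[AseObservation] = []
    labels: list[AseClass] = []
    i = 0

    def add(obs: AseObservation, label: AseClass) -> None:
        nonlocal i
        observations.append(obs)
        labels.append(label)
        i += 1

    for _ in range(n_per_class.get(AseClass.MUTATED_EXPRESSED, 0)):
        depth = int(rng.integers(30, 300))
        vaf = float(rng.uniform(2 * vaf_min, 0.95))
        alt = max(1, round(vaf * depth))
        add(
            AseObservation(
                variant=_dummy_variant(sample_id, i),
                gene_tpm=float(rng.uniform(2 * tpm_min, 200.0)),
                rna_ref_count=depth - alt,
                rna_alt_count=alt,
            ),
            AseClass.MUTATED_EXPRESSED,
        )
    for _ in range(n_per_class.get(AseClass.MUTATED_NOT_EXPRESSED, 0)):
        depth = int(rng.integers(150, 500))
        alt = int(rng.integers(0, max(1, int(depth * vaf_min / 2))))
        add(
            AseObservation(
                variant=_dummy_variant(sample_id, i),
                gene_tpm=float(rng.uniform(2 * tpm_min, 200.0)),
                rna_ref_count=depth - alt,
                rna_alt_count=alt,
            ),
            AseClass.MUTATED_NOT_EXPRESSED,
        )
    for _ in range(n_per_class.get(AseClass.GENE_NOT_EXPRESSED, 0)):
        depth = int(rng.integers(1, 50))
        alt = int(rng.integers(0, depth + 1))
        add(
            AseObservation(
                variant=_dummy_variant(sample_id, i),
                gene_tpm=float(rng.uniform(0.0, tpm_min / 2)),
                rna_ref_count=depth - alt,
                rna_alt_count=alt,
            ),
            AseClass.GENE_NOT_EXPRESSED,
        )
    for _ in range(n_per_class.get(AseClass.NOT_COVERED, 0)):
        add(
            AseObservation(
                variant=_dummy_variant(sample_id, i),
                gene_tpm=float(rng.uniform(0.0, 200.0)),
                rna_ref_count=0,
                rna_alt_count=0,
            ),
            AseClass.NOT_COVERED,
        )

    if include_boundaries:
        # TPM exactly at the cut-off: the gene counts as expressed
        add(
            AseObservation(
                variant=_dummy_variant(sample_id, i),
                gene_tpm=tpm_min,
                rna_ref_count=50,
                rna_alt_count=50,
            ),
            AseClass.MUTATED_EXPRESSED,
        )
        # VAF exactly at the cut-off: mutated allele counts as not expressed
        add(
            AseObservation(
                variant=_dummy_variant(sample_id, i),
                gene_tpm=10.0,
                rna_ref_count=97,
                rna_alt_count=3,
            ),
            AseClass.MUTATED_NOT_EXPRESSED,
        )
    return observations, labels


def simulate_de_tables(
    n_genes: int = 200,
    n_de_genes: int = 20,
    n_mirnas: int = 60,
    n_de_mirnas: int = 10,
    n_planted_pairs: int = 5,
    seed: int = 0,
) -> tuple[
    list[ExpressionRecord],
    list[MirnaRecord],
    list[TargetInteraction],
    list[tuple[str, str]],
]:
    """mRNA / miRNA statistic tables with planted opposite-sign target pairs.

    Planted pairs connect DE miRNAs to DE genes of opposite fold-change
    sign through allowed-confidence interaction rows.  Decoys include
    same-sign interacting DE pairs, opposite-sign DE pairs whose interaction
    confidence is too low, interactions touching non-DE molecules, and
    opposite-sign DE pairs with no interaction row at all.
    """
    if n_de_genes > n_genes or n_de_mirnas > n_mirnas:
        raise ValueError("DE counts cannot exceed totals")
    if n_planted_pairs > min(n_de_genes, n_de_mirnas):
        raise ValueError("cannot plant more pairs than DE molecules")
    rng = np.random.default_rng(seed)

    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    mirnas = [f"miR-{i:03d}" for i in range(n_mirnas)]

    mrna: list[ExpressionRecord] = []
    for gi, g in enumerate(genes):
        de = gi < n_de_genes
        if de:
            sign = 1 if gi % 2 == 0 else -1
            lfc = sign * float(rng.uniform(1.5, 4.0))
            p = float(rng.uniform(1e-8, 0.01))
            med_met, med_nomet = float(rng.uniform(5, 200)), float(rng.uniform(5, 200))
        elif gi % 5 == 0:  # below background in both groups
            lfc = float(rng.uniform(-0.5, 0.5))
            p = float(rng.uniform(0.2, 1.0))
            med_met, med_nomet = float(rng.uniform(0, 1.5)), float(rng.uniform(0, 1.5))
        else:
            lfc = float(rng.uniform(-0.8, 0.8))
            p = float(rng.uniform(0.1, 1.0))
            med_met, med_nomet = float(rng.uniform(3, 100)), float(rng.uniform(3, 100))
        mrna.append(ExpressionRecord(g, med_met, med_nomet, lfc, p))

    mirna: list[MirnaRecord] = []
    for mi, m in enumerate(mirnas):
        de = mi < n_de_mirnas
        if de:
            sign = 1 if mi % 2 == 0 else -1
            lfc = sign * float(rng.uniform(1.2, 3.5))
            q = float(rng.uniform(1e-6, 0.01))
            meds = [float(rng.uniform(100, 5000)) for _ in range(4)]
        elif mi % 5 == 0:  # below count background everywhere
            lfc = float(rng.uniform(-0.5, 0.5))
            q = float(rng.uniform(0.3, 1.0))
            meds = [float(rng.uniform(0, 40)) for _ in range(4)]
        else:
            lfc = float(rng.uniform(-0.8, 0.8))
            q = float(rng.uniform(0.1, 1.0))
            meds = [float(rng.uniform(50, 2000)) for _ in range(4)]
        mirna.append(MirnaRecord(m, meds[0], meds[1], meds[2], meds[3], lfc, q))

    de_genes_up = [r for r in mrna[:n_de_genes] if r.log2_fc > 0]
    de_genes_dn = [r for r in mrna[:n_de_genes] if r.log2_fc < 0]
    de_mir_up = [r for r in mirna[:n_de_mirnas] if r.log2_fc > 0]
    de_mir_dn = [r for r in mirna[:n_de_mirnas] if r.log2_fc < 0]

    interactions: list[TargetInteraction] = []
    planted: list[tuple[str, str]] = []
    gi_up = gi_dn = 0
    for i in range(n_planted_pairs):
        if i % 2 == 0 and gi_up < len(de_genes_up) and de_mir_dn:
            g = de_genes_up[gi_up]; gi_up += 1
            m = de_mir_dn[i % len(de_mir_dn)]
        elif gi_dn < len(de_genes_dn) and de_mir_up:
            g = de_genes_dn[gi_dn]; gi_dn += 1
            m = de_mir_up[i % len(de_mir_up)]
        elif gi_up < len(de_genes_up) and de_mir_dn:
            g = de_genes_up[gi_up]; gi_up += 1
            m = de_mir_dn[i % len(de_mir_dn)]
        else:
            raise ValueError("not enough opposite-sign DE molecules to plant pairs")
        conf = "experimentally_observed" if i % 2 == 0 else "highly_predicted"
        interactions.append(TargetInteraction(m.mirna, g.gene, conf))
        planted.append((m.mirna, g.gene))

    planted_set = set(planted)
    # decoy 1: same-sign interacting DE pair
    if de_mir_up and de_genes_up:
        interactions.append(
            TargetInteraction(de_mir_up[0].mirna, de_genes_up[0].gene, "highly_predicted")
        )
    if de_mir_dn and de_genes_dn:
        interactions.append(
            TargetInteraction(de_mir_dn[0].mirna, de_genes_dn[0].gene, "experimentally_observed")
        )
    # decoy 2: opposite-sign DE pair at too-low confidence
    for m_pool, g_pool in ((de_mir_up, de_genes_dn), (de_mir_dn, de_genes_up)):
        for m in m_pool:
            for g in g_pool:
                if (m.mirna, g.gene) not in planted_set:
                    interactions.append(TargetInteraction(m.mirna, g.gene, "other"))
                    break
            else:
                continue
            break
    # decoy 3: interactions touching non-DE molecules
    if n_genes > n_de_genes and n_mirnas > n_de_mirnas:
        interactions.append(
            TargetInteraction(mirnas[n_de_mirnas], genes[n_de_genes], "experimentally_observed")
        )
        if de_mir_up:
            interactions.append(
                TargetInteraction(de_mir_up[0].mirna, genes[n_de_genes], "highly_predicted")
            )
    return mrna, mirna, interactions, planted
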