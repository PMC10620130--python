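"""Chromosome-level CIN scoring and comparator CIN algorithms.

The primary score counts, per sample, the chromosomes carrying copy-number
variation (total copy number away from the diploid baseline) and/or
copy-neutral loss of heterozygosity (total copy number 2 with zero minor
allele copies), and labels the karyotype Complex when the total number of
affected chromosomes reaches a threshold (default 10).

Three comparator scores common in the CIN literature are also provided:
the count of aberrant segments (CNA count), the fraction of the genome
altered (FGA) and the total aberration index (TAI, the length-weighted mean
absolute segment log-ratio).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from gistcin.segment_io import (
    CopyNumberSegment,
    GenomeBuild,
    SegmentedProfile,
    b37,
)

logger = logging.getLogger(__name__)

SIMPLE = "Simple"
COMPLEX = "Complex"


@dataclass(frozen=True)
class CinConfig:
    """Tunables for aberration calling and karyotype classification.

    baseline_cn
        Total copy number considered neutral (2, the diploid state).
    baseline_mode
        ``diploid`` compares against ``baseline_cn``; ``nearest_integer_ploidy``
        compares against round(sample ploidy).
    min_aberrant_len_bp
        Segments shorter than this never flag a chromosome (default 0: any
        aberrant segment counts).
    complexity_threshold
        Affected-chromosome count at and above which a sample is Complex.
    log_ratio_threshold
        |log-ratio| above which a segment counts as altered for the CNA
        count and FGA comparator scores.
    count_x_for_cnloh
        Whether chromosome X is eligible for copy-neutral-LOH counting; when
        ``None`` it is resolved per sample (False for male samples, where a
        single X is hemizygous rather than LOH, True otherwise).
    """

    baseline_cn: int = 2
    baseline_mode: str = "diploid"
    min_aberrant_len_bp: int = 0
    complexity_threshold: int = 10
    log_ratio_threshold: float = 0.2
    count_x_for_cnloh: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.baseline_mode not in ("diploid", "nearest_integer_ploidy"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        if self.min_aberrant_len_bp < 0 or self.complexity_threshold < 0:
            raise ValueError("thresholds must be non-negative")
        if self.log_ratio_threshold < 0:
            raise ValueError("log_ratio_threshold must be non-negative")

    def baseline_for(self, profile: Optional[SegmentedProfile]) -> int:
        if self.baseline_mode == "nearest_integer_ploidy" and profile is not None:
            return max(1, round(profile.ploidy))
        return self.baseline_cn

    def cnloh_eligible(self, chrom: str, profile: Optional[SegmentedProfile]) -> bool:
        if chrom != "X":
            return True
        if self.count_x_for_cnloh is not None:
            return self.count_x_for_cnloh
        sex = (profile.sex or "").lower() if profile is not None else ""
        return sex not in ("male", "m")


@dataclass(frozen=True)
class ChromosomeStatus:
    chrom: str
    cnv_affected: bool
    cnloh_affected: bool

    @property
    def affected(self) -> bool:
        return self.cnv_affected or self.cnloh_affected


@dataclass(frozen=True)
class CinSummary:
    """Per-sample affected-chromosome counts and the Simple/Complex label."""

    sample_id: str
    n_chr_cnv_only: int
    n_chr_loh_only: int
    n_chr_both: int
    n_chr_total: int
    complexity: str

    def __post_init__(self) -> None:
        if self.n_chr_total != self.n_chr_cnv_only + self.n_chr_loh_only + self.n_chr_both:
            raise ValueError("n_chr_total must equal the sum of the three counts")
        if min(self.n_chr_cnv_only, self.n_chr_loh_only, self.n_chr_both) < 0:
            raise ValueError("counts must be non-negative")
        if self.complexity not in (SIMPLE, COMPLEX):
            raise ValueError(f"complexity must be Simple or Complex, got {self.complexity!r}")


@dataclass(frozen=True)
class CinMetricScores:
    """Comparator CIN scores for one sample."""

    sample_id: str
    cna_segment_count: int
    breakpoint_count: int
    fga: float
    tai: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.fga <= 1.0 + 1e-12):
            raise ValueError(f"fga must be in [0,1], got {self.fga}")
        if self.cna_segment_count < 0 or self.breakpoint_count < 0 or self.tai < 0:
            raise ValueError("counts and tai must be non-negative")


def chromosome_status(
    segments: Sequence[CopyNumberSegment],
    config: CinConfig = CinConfig(),
    profile: Optional[SegmentedProfile] = None,
) -> ChromosomeStatus:
    """Call CNV and copy-neutral-LOH status for one chromosome.

    A chromosome is CNV-affected when some segment of at least
    ``min_aberrant_len_bp`` has total copy number different from the baseline,
    and cnLOH-affected when some such segment has total copy number equal to
    the baseline with zero minor-allele copies (if the chromosome is eligible
    for cnLOH counting).
    """
    if not segments:
        raise ValueError("chromosome_status requires at least one segment")
    chroms = {s.chrom for s in segments}
    if len(chroms) != 1:
        raise ValueError(f"segments span multiple chromosomes: {sorted(chroms)}")
    chrom = next(iter(chroms))
    baseline = config.baseline_for(profile)
    cnv = False
    cnloh = False
    for seg in segments:
        if seg.length < config.min_aberrant_len_bp:
            continue
        if seg.total_cn != baseline:
            cnv = True
        elif seg.minor_cn == 0 and config.cnloh_eligible(chrom, profile):
            cnloh = True
    return ChromosomeStatus(chrom=chrom, cnv_affected=cnv, cnloh_affected=cnloh)


def classify_complexity(n_chr_total: int, threshold: int = 10) -> str:
    """``Complex`` iff the affected-chromosome total reaches the threshold."""
    if n_chr_total < 0:
        raise ValueError("n_chr_total must be non-negative")
    return COMPLEX if n_chr_total >= threshold else SIMPLE


def summarize_cin(
    profile: SegmentedProfile, config: CinConfig = CinConfig()
) -> CinSummary:
    """Count CNV-only / cnLOH-only / both-affected chromosomes for a sample
    and assign the Simple/Complex label."""
    n_cnv = n_loh = n_both = 0
    for chrom in profile.chromosomes():
        segs = profile.segments[chrom]
        if not segs:
            continue
        status = chromosome_status(segs, config, profile)
        if status.cnv_affected and status.cnloh_affected:
            n_both += 1
        elif status.cnv_affected:
            n_cnv += 1
        elif status.cnloh_affected:
            n_loh += 1
    total = n_cnv + n_loh + n_both
    return CinSummary(
        sample_id=profile.sample_id,
        n_chr_cnv_only=n_cnv,
        n_chr_loh_only=n_loh,
        n_chr_both=n_both,
        n_chr_total=total,
        complexity=classify_complexity(total, config.complexity_threshold),
    )


def _segment_log_ratio(seg: CopyNumberSegment, baseline: int) -> float:
    if seg.log_ratio is not None:
        return seg.log_ratio
    # derive from total copy number, flooring zero copies to 0.5 to keep finite
    return math.log2(max(seg.total_cn, 0.5) / baseline)


def cin_metric_scores(
    profile: SegmentedProfile,
    build: Optional[GenomeBuild] = None,
    config: CinConfig = CinConfig(),
    tai_masked: bool = False,
) -> CinMetricScores:
    """Compute the comparator CIN scores for one sample.

    ``cna_segment_count`` counts segments with |log-ratio| above the
    threshold; ``breakpoint_count`` counts adjacent same-chromosome segment
    pairs whose total copy number differs; ``fga`` is the altered fraction of
    the build's total length; ``tai`` is the length-weighted mean |log-ratio|
    over all segments (or over above-threshold segments when ``tai_masked``).
    """
    build = build or b37()
    baseline = config.baseline_for(profile)
    segs = profile.all_segments()
    if not segs:
        logger.warning("%s: empty profile, all CIN metric scores 0", profile.sample_id)
        return CinMetricScores(profile.sample_id, 0, 0, 0.0, 0.0)

    cna = 0
    altered_len = 0
    tai_num = 0.0
    tai_den = 0
    for seg in segs:
        lr = abs(_segment_log_ratio(seg, baseline))
        above = lr > config.log_ratio_threshold
        if above:
            cna += 1
            altered_len += seg.length
        if not tai_masked or above:
            tai_num += seg.length * lr
            tai_den += seg.length

    breakpoints = 0
    for chrom in profile.chromosomes():
        cs = profile.segments[chrom]
        breakpoints += sum(
            1 for a, z in zip(cs, cs[1:]) if a.total_cn != z.total_cn
        )

    fga = min(1.0, altered_len / build.total_length)
    tai = tai_num / tai_den if tai_den else 0.0
    return CinMetricScores(profile.sample_id, cna, breakpoints, fga, tai)


def cohort_cin_table(
    profiles: Iterable[SegmentedProfile],
    config: CinConfig = CinConfig(),
    build: Optional[GenomeBuild] = None,
) -> pd.DataFrame:
    """One row per sample: affected-chromosome counts, Simple/Complex label
    and the comparator scores; rows ordered by sample id."""
    profiles = list(profiles)
    ids = [p.sample_id for p in profiles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample id(s): {', '.join(dupes)}")
    rows = []
    for p in sorted(profiles, key=lambda p: p.sample_id):
        s = summarize_cin(p, config)
        m = cin_metric_scores(p, build, config)
        rows.append(
            {
                "sample": p.sample_id,
                "group": p.group,
                "n_chr_cnv": s.n_chr_cnv_only,
                "n_chr_loh": s.n_chr_loh_only,
                "n_chr_cnv_loh": s.n_chr_both,
                "n_chr_total": s.n_chr_total,
                "cin": s.complexity,
                "ploidy": p.ploidy,
                "mitotic_count": p.mitotic_count,
                "cna_segment_count": m.cna_segment_count,
                "breakpoint_count": m.breakpoint_count,
                "fga": m.fga,
                "tai": m.tai,
            }
        )
    columns = [
        "sample", "group", "n_chr_cnv", "n_chr_loh", "n_chr_cnv_loh",
        "n_chr_total", "cin", "ploidy", "mitotic_count",
        "cna_segment_count", "breakpoint_count", "fga", "tai",
    ]
    return pd.DataFrame(rows, columns=columns)
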