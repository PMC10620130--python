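"""Chromothripsis-like oscillation detection from segmented copy number.

A chromothriptic chromosome shows many switches between copy-number states
clustered in a limited region.  Per chromosome, the switches between adjacent
segments with differing state are counted and the maximum number of switches
falling inside any 50 Mb window is taken; a chromosome is called
chromothripsis-positive with high confidence when that maximum reaches the
switch threshold (default 10).

Adjacent segments are compared in sorted order even across inter-segment
gaps; the breakpoint coordinate is the end of the left segment.  The window
maximum is exact: for half-open windows it suffices to anchor a window at
each breakpoint position.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from gistcin.segment_io import CopyNumberSegment, SegmentedProfile


@dataclass(frozen=True)
class ChromothripsisConfig:
    switch_threshold: int = 10
    window_bp: int = 50_000_000
    state_mode: str = "total_cn"  # or "allele_specific"

    def __post_init__(self) -> None:
        if self.switch_threshold < 1:
            raise ValueError("switch_threshold must be >= 1")
        if self.window_bp < 1:
            raise ValueError("window_bp must be >= 1")
        if self.state_mode not in ("total_cn", "allele_specific"):
            raise ValueError(f"unknown state_mode {self.state_mode!r}")


@dataclass(frozen=True)
class ChromothripsisCall:
    sample_id: str
    chrom: str
    n_switches_total: int
    max_switches_in_window: int
    high_confidence: bool

    def __post_init__(self) -> None:
        if self.max_switches_in_window > self.n_switches_total:
            raise ValueError("window maximum cannot exceed the total switch count")


def switch_breakpoints(
    segments: Sequence[CopyNumberSegment], state_mode: str = "total_cn"
) -> list[int]:
    """Positions (bp) of state switches between adjacent segments on one
    chromosome; the position is the left segment's end."""
    if not segments:
        return []
    chroms = {s.chrom for s in segments}
    if len(chroms) != 1:
        raise ValueError(f"segments span multiple chromosomes: {sorted(chroms)}")
    for a, z in zip(segments, segments[1:]):
        if z.start < a.end:
            raise ValueError(
                f"segments not sorted/non-overlapping at {a.start}-{a.end} "
                f"vs {z.start}-{z.end}"
            )
    allele = state_mode == "allele_specific"
    return [
        a.end
        for a, z in zip(segments, segments[1:])
        if a.state(allele) != z.state(allele)
    ]


def max_switches_in_window(positions: Sequence[int], window_bp: int) -> int:
    """Maximum number of positions inside any half-open window
    ``[x, x + window_bp)``.

    Exact: a window can always be shifted right until its left edge sits on
    a position without losing any, so anchoring at each position suffices.
    """
    pos = list(positions)
    if any(a > b for a, b in zip(pos, pos[1:])):
        raise ValueError("positions must be sorted ascending")
    if not pos:
        return 0
    best = 0
    for i, p in enumerate(pos):
        j = bisect_left(pos, p + window_bp)
        best = max(best, j - i)
    return best


def call_chromothripsis(
    profile: SegmentedProfile,
    config: ChromothripsisConfig = ChromothripsisConfig(),
    include_zero_switch: bool = False,
) -> list[ChromothripsisCall]:
    """Per-chromosome chromothripsis calls for one sample.

    Chromosomes with zero switches are omitted unless
    ``include_zero_switch`` is set.
    """
    calls = []
    for chrom in profile.chromosomes():
        positions = switch_breakpoints(profile.segments[chrom], config.state_mode)
        if not positions and not include_zero_switch:
            continue
        in_window = max_switches_in_window(positions, config.window_bp)
        calls.append(
            ChromothripsisCall(
                sample_id=profile.sample_id,
                chrom=chrom,
                n_switches_total=len(positions),
                max_switches_in_window=in_window,
                high_confidence=in_window >= config.switch_threshold,
            )
        )
    return calls


def cohort_chromothripsis_table(
    profiles: Sequence[SegmentedProfile],
    config: ChromothripsisConfig = ChromothripsisConfig(),
    include_zero_switch: bool = False,
) -> pd.DataFrame:
    """Calls for a cohort as a tidy table (sample, group, chromosome,
    switch counts, high-confidence flag)."""
    rows = []
    for p in sorted(profiles, key=lambda p: p.sample_id):
        for c in call_chromothripsis(p, config, include_zero_switch):
            rows.append(
                {
                    "sample": c.sample_id,
                    "group": p.group,
                    "chrom": c.chrom,
                    "n_switches_total": c.n_switches_total,
                    "max_switches_in_window": c.max_switches_in_window,
                    "high_confidence": c.high_confidence,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "sample", "group", "chrom", "n_switches_total",
            "max_switches_in_window", "high_confidence",
        ],
    )
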