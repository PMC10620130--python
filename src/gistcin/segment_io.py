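"""Allele-specific copy-number segment tables and the genome model.

Internal coordinates are 0-based half-open; the on-disk default dialect is the
SEG convention (1-based, inclusive), with BED-style (0-based half-open) input
accepted behind a flag.  Chromosome names are normalised by stripping any
leading ``chr`` prefix, and ``23`` aliases to ``X`` (allele-specific segmenters
often emit numeric chromosomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)


class SegmentFormatError(ValueError):
    """A segment file is malformed (missing columns, bad dialect)."""


class SegmentValidationError(ValueError):
    """Segment content violates an invariant (overlap, minor > total, ...)."""


# GRCh37 / b37 chromosome lengths, autosomes 1-22 plus X.
_B37_LENGTHS = [
    ("1", 249_250_621),
    ("2", 243_199_373),
    ("3", 198_022_430),
    ("4", 191_154_276),
    ("5", 180_915_260),
    ("6", 171_115_067),
    ("7", 159_138_663),
    ("8", 146_364_022),
    ("9", 141_213_431),
    ("10", 135_534_747),
    ("11", 135_006_516),
    ("12", 133_851_895),
    ("13", 115_169_878),
    ("14", 107_349_540),
    ("15", 102_531_392),
    ("16", 90_354_753),
    ("17", 81_195_210),
    ("18", 78_077_248),
    ("19", 59_128_983),
    ("20", 63_025_520),
    ("21", 48_129_895),
    ("22", 51_304_566),
    ("X", 155_270_560),
]


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name: strip ``chr`` prefix, map ``23`` to ``X``."""
    s = str(name).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "23":
        s = "X"
    return s


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with their lengths in bp."""

    name: str
    chromosomes: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names in build")
        for c, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"chromosome {c} has non-positive length {length}")

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.chromosomes)

    def length(self, chrom: str) -> int:
        chrom = normalize_chrom(chrom)
        for c, length in self.chromosomes:
            if c == chrom:
                return length
        raise KeyError(f"chromosome {chrom!r} not in build {self.name}")

    def __contains__(self, chrom: str) -> bool:
        return normalize_chrom(chrom) in self.chrom_names

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    @classmethod
    def from_tsv(cls, path: str | Path, name: Optional[str] = None) -> "GenomeBuild":
        """Load a build from a two-column ``chrom  length`` TSV."""
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "length"], dtype={"chrom": str})
        chroms = tuple(
            (normalize_chrom(r.chrom), int(r.length)) for r in df.itertuples()
        )
        return cls(name=name or Path(path).stem, chromosomes=chroms)


def b37() -> GenomeBuild:
    """The bundled default build: b37 autosomes 1-22 plus X."""
    return GenomeBuild(name="b37", chromosomes=tuple(_B37_LENGTHS))


@dataclass(frozen=True)
class CopyNumberSegment:
    """One allele-specific copy-number segment (internal 0-based half-open).

    ``total_cn`` is the total copy number, ``minor_cn`` the minor-allele copy
    number (the lesser of the two alleles).  A copy-neutral LOH segment has
    ``total_cn == 2`` and ``minor_cn == 0``.
    """

    chrom: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    log_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"segment start {self.start} not before end {self.end}"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise ValueError(
                f"minor_cn {self.minor_cn} exceeds major allele "
                f"({self.total_cn - self.minor_cn}) for total_cn {self.total_cn}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def state(self, allele_specific: bool = False):
        """The copy-number state used for switch counting."""
        return (self.total_cn, self.minor_cn) if allele_specific else self.total_cn


GROUPS = ("metastatic", "non_metastatic", "unknown")


@dataclass
class SegmentedProfile:
    """A per-sample allele-specific segmented copy-number profile."""

    sample_id: str
    group: str = "unknown"
    ploidy: float = 2.0
    segments: dict[str, list[CopyNumberSegment]] = field(default_factory=dict)
    sex: Optional[str] = None
    mitotic_count: Optional[float] = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        for chrom, segs in self.segments.items():
            self.segments[chrom] = sorted(segs, key=lambda s: s.start)

    def chromosomes(self) -> list[str]:
        return list(self.segments)

    def all_segments(self) -> list[CopyNumberSegment]:
        return [s for segs in self.segments.values() for s in segs]

    def add_segment(self, seg: CopyNumberSegment) -> None:
        self.segments.setdefault(seg.chrom, []).append(seg)
        self.segments[seg.chrom].sort(key=lambda s: s.start)


def validate_profile(
    profile: SegmentedProfile, build: Optional[GenomeBuild] = None
) -> list[str]:
    """Return a list of human-readable invariant violations (empty if valid).

    Checks sortedness and non-overlap within each chromosome, copy-number
    sanity, and — when a build is given — chromosome membership and that
    segment ends do not exceed the chromosome length.
    """
    violations: list[str] = []
    if profile.ploidy <= 0:
        violations.append(f"{profile.sample_id}: non-positive ploidy {profile.ploidy}")
    for chrom, segs in profile.segments.items():
        if build is not None and chrom not in build:
            violations.append(
                f"{profile.sample_id}/{chrom}: chromosome not in build {build.name}"
            )
        prev = None
        for seg in segs:
            if seg.minor_cn > seg.total_cn - seg.minor_cn:
                violations.append(
                    f"{profile.sample_id}/{chrom}:{seg.start}-{seg.end}: "
                    f"minor_cn {seg.minor_cn} exceeds total-minor "
                    f"({seg.total_cn - seg.minor_cn})"
                )
            if build is not None and chrom in build and seg.end > build.length(chrom):
                violations.append(
                    f"{profile.sample_id}/{chrom}:{seg.start}-{seg.end}: "
                    f"end beyond chromosome length {build.length(chrom)}"
                )
            if prev is not None and seg.start < prev.end:
                violations.append(
                    f"{profile.sample_id}/{chrom}: segments "
                    f"{prev.start}-{prev.end} and {seg.start}-{seg.end} overlap"
                )
            prev = seg
    return violations


_REQUIRED_COLUMNS = ("sample", "chrom", "start", "end", "total_cn", "minor_cn")


def _to_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "seg":  # 1-based inclusive
        return start - 1, end
    if dialect == "bed":  # already 0-based half-open
        return start, end
    raise SegmentFormatError(f"unknown coordinate dialect {dialect!r}")


def _to_file(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "seg":
        return start + 1, end
    if dialect == "bed":
        return start, end
    raise SegmentFormatError(f"unknown coordinate dialect {dialect!r}")


def read_segment_table(
    path: str | Path,
    build: Optional[GenomeBuild] = None,
    coordinate_dialect: str = "seg",
    metadata: Optional[str | Path] = None,
) -> list[SegmentedProfile]:
    """Read a tab-delimited allele-specific segment table into profiles.

    The file must carry a header naming at least ``sample chrom start end
    total_cn minor_cn``; ``log_ratio`` is optional.  One profile is returned
    per distinct sample, segments sorted per chromosome.  An optional
    metadata TSV (``sample group ploidy [sex] [mitotic_count]``) attaches
    group, ploidy and sex.

    Raises :class:`SegmentFormatError` on missing columns and
    :class:`SegmentValidationError` on overlapping segments, unknown
    chromosomes or minor > total - minor.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str, "sample": str})
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SegmentFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    if df.empty:
        logger.warning("%s: segment table has a header but no rows", path)
        return []

    meta: dict[str, dict] = {}
    if metadata is not None:
        mdf = pd.read_csv(metadata, sep="\t", comment="#", dtype={"sample": str})
        for r in mdf.itertuples():
            meta[str(r.sample)] = {
                "group": getattr(r, "group", "unknown"),
                "ploidy": float(getattr(r, "ploidy", 2.0)),
                "sex": getattr(r, "sex", None),
                "mitotic_count": getattr(r, "mitotic_count", None),
            }

    profiles: list[SegmentedProfile] = []
    for sample, sub in df.groupby("sample", sort=True):
        m = meta.get(str(sample), {})
        sex = m.get("sex")
        mit = m.get("mitotic_count")
        profile = SegmentedProfile(
            sample_id=str(sample),
            group=str(m.get("group", "unknown")),
            ploidy=float(m.get("ploidy", 2.0)),
            sex=None if sex is None or pd.isna(sex) else str(sex),
            mitotic_count=None if mit is None or pd.isna(mit) else float(mit),
        )
        for row in sub.itertuples():
            chrom = normalize_chrom(row.chrom)
            if build is not None and chrom not in build:
                raise SegmentValidationError(
                    f"{path}: sample {sample}: unknown chromosome {row.chrom!r}"
                )
            start, end = _to_internal(int(row.start), int(row.end), coordinate_dialect)
            lr = getattr(row, "log_ratio", None)
            try:
                seg = CopyNumberSegment(
                    chrom=chrom,
                    start=start,
                    end=end,
                    total_cn=int(row.total_cn),
                    minor_cn=int(row.minor_cn),
                    log_ratio=None if lr is None or pd.isna(lr) else float(lr),
                )
            except ValueError as exc:
                raise SegmentValidationError(
                    f"{path}: sample {sample} chrom {chrom} "
                    f"{row.start}-{row.end}: {exc}"
                ) from exc
            profile.add_segment(seg)
        overlaps = [v for v in validate_profile(profile, build) if "overlap" in v]
        if overlaps:
            raise SegmentValidationError(
                f"{path}: overlapping segments: " + "; ".join(overlaps)
            )
        profiles.append(profile)
    return profiles


def write_segment_table(
    profiles: Iterable[SegmentedProfile],
    path: str | Path,
    coordinate_dialect: str = "seg",
) -> None:
    """Write profiles back to the tab-delimited segment format (round-trips
    with :func:`read_segment_table`)."""
    rows = []
    for p in profiles:
        for chrom in p.chromosomes():
            for seg in p.segments[chrom]:
                fs, fe = _to_file(seg.start, seg.end, coordinate_dialect)
                rows.append(
                    {
                        "sample": p.sample_id,
                        "chrom": seg.chrom,
                        "start": fs,
                        "end": fe,
                        "total_cn": seg.total_cn,
                        "minor_cn": seg.minor_cn,
                        "log_ratio": seg.log_ratio,
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["sample", "chrom", "start", "end", "total_cn", "minor_cn", "log_ratio"],
    )
    df.to_csv(path, sep="\t", index=False)


def write_metadata_table(profiles: Iterable[SegmentedProfile], path: str | Path) -> None:
    """Write the per-sample metadata companion TSV."""
    rows = [
        {
            "sample": p.sample_id,
            "group": p.group,
            "ploidy": p.ploidy,
            "sex": p.sex,
            "mitotic_count": p.mitotic_count,
        }
        for p in profiles
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
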