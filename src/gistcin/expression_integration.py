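"""Expression background/DE threshold filters and miRNA-target pairing.

mRNA records carry per-group median TPM, a log2 fold change and an adjusted
p-value; miRNA records carry per-group median read counts before and after
normalisation, a log2 fold change and a q-value.  DE statistics are consumed
as given — no model is fitted and no multiple-testing correction is applied
here.

The mRNA DE rule is strict (adjusted p < 0.05 and |logFC| > 1) and the miRNA
rule inclusive (q <= 0.05 and |logFC| >= 1); the asymmetry is deliberate and
configurable.  Differentially expressed miRNAs are paired with predicted
target mRNAs of opposite fold-change sign through an interaction table
restricted to experimentally observed and highly predicted interactions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

CONFIDENCE_LEVELS = ("experimentally_observed", "highly_predicted", "other")
DEFAULT_CONFIDENCE = frozenset({"experimentally_observed", "highly_predicted"})


@dataclass(frozen=True)
class ExpressionRecord:
    gene: str
    median_tpm_met: float
    median_tpm_nomet: float
    log2_fc: float
    adj_p: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.adj_p <= 1.0):
            raise ValueError(f"adj_p must be in [0,1], got {self.adj_p}")
        if self.median_tpm_met < 0 or self.median_tpm_nomet < 0:
            raise ValueError("median TPM values must be non-negative")


@dataclass(frozen=True)
class MirnaRecord:
    mirna: str
    median_raw_met: float
    median_raw_nomet: float
    median_norm_met: float
    median_norm_nomet: float
    log2_fc: float
    q_value: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q_value <= 1.0):
            raise ValueError(f"q_value must be in [0,1], got {self.q_value}")
        if min(self.median_raw_met, self.median_raw_nomet,
               self.median_norm_met, self.median_norm_nomet) < 0:
            raise ValueError("median counts must be non-negative")


@dataclass(frozen=True)
class TargetInteraction:
    mirna: str
    gene: str
    confidence: str = "highly_predicted"

    def __post_init__(self) -> None:
        if self.confidence not in CONFIDENCE_LEVELS:
            raise ValueError(f"unknown confidence {self.confidence!r}")


@dataclass(frozen=True)
class PairedInteraction:
    """A DE miRNA matched to an oppositely regulated DE target mRNA."""

    mirna: str
    gene: str
    mirna_log2_fc: float
    gene_log2_fc: float

    def __post_init__(self) -> None:
        if self.mirna_log2_fc * self.gene_log2_fc >= 0:
            raise ValueError("paired fold changes must have strictly opposite signs")


def filter_low_expression(
    records: Sequence[ExpressionRecord], tpm_min: float = 2.0
) -> list[ExpressionRecord]:
    """Drop genes expressed below background: median TPM < tpm_min in BOTH
    groups (a gene above background in either group is kept)."""
    return [
        r
        for r in records
        if not (r.median_tpm_met < tpm_min and r.median_tpm_nomet < tpm_min)
    ]


def select_de_mrna(
    records: Sequence[ExpressionRecord],
    adj_p_max: float = 0.05,
    abs_log2_fc_min: float = 1.0,
    strict: bool = True,
) -> list[ExpressionRecord]:
    """Differentially expressed genes: adjusted p strictly below the cut-off
    and |log2 FC| strictly above it (inclusive when ``strict`` is False)."""
    if strict:
        return [r for r in records if r.adj_p < adj_p_max and abs(r.log2_fc) > abs_log2_fc_min]
    return [r for r in records if r.adj_p <= adj_p_max and abs(r.log2_fc) >= abs_log2_fc_min]


def filter_mirna_background(
    records: Sequence[MirnaRecord],
    count_min: float = 45.0,
    mode: str = "all_four",
) -> list[MirnaRecord]:
    """Drop miRNAs below the count background.

    ``all_four`` (default, the most conservative removal rule): removed only
    when raw and normalised medians are below ``count_min`` in both groups.
    ``raw_only`` / ``norm_only`` consider a single quantity in both groups.
    """
    def below(r: MirnaRecord) -> bool:
        if mode == "all_four":
            return (
                r.median_raw_met < count_min
                and r.median_raw_nomet < count_min
                and r.median_norm_met < count_min
                and r.median_norm_nomet < count_min
            )
        if mode == "raw_only":
            return r.median_raw_met < count_min and r.median_raw_nomet < count_min
        if mode == "norm_only":
            return r.median_norm_met < count_min and r.median_norm_nomet < count_min
        raise ValueError(f"unknown background mode {mode!r}")

    return [r for r in records if not below(r)]


def select_de_mirna(
    records: Sequence[MirnaRecord],
    q_max: float = 0.05,
    abs_log2_fc_min: float = 1.0,
) -> list[MirnaRecord]:
    """Differentially expressed miRNAs: q <= cut-off and |log2 FC| >= cut-off
    (both inclusive)."""
    return [r for r in records if r.q_value <= q_max and abs(r.log2_fc) >= abs_log2_fc_min]


def pair_mirna_targets(
    de_mirnas: Sequence[MirnaRecord],
    de_mrnas: Sequence[ExpressionRecord],
    interactions: Iterable[TargetInteraction],
    allowed_confidence: frozenset[str] | set[str] = DEFAULT_CONFIDENCE,
) -> list[PairedInteraction]:
    """Match DE miRNAs to DE target genes of strictly opposite fold-change
    sign through the interaction table (zero fold change pairs with
    nothing); output sorted by (mirna, gene)."""
    mirna_fc = {r.mirna: r.log2_fc for r in de_mirnas}
    gene_fc = {r.gene: r.log2_fc for r in de_mrnas}
    pairs = []
    seen = set()
    for ix in interactions:
        key = (ix.mirna, ix.gene)
        if key in seen:
            continue
        seen.add(key)
        if ix.confidence not in allowed_confidence:
            continue
        mfc = mirna_fc.get(ix.mirna)
        gfc = gene_fc.get(ix.gene)
        if mfc is None or gfc is None:
            continue
        if mfc * gfc < 0:
            pairs.append(
                PairedInteraction(
                    mirna=ix.mirna, gene=ix.gene,
                    mirna_log2_fc=mfc, gene_log2_fc=gfc,
                )
            )
    pairs.sort(key=lambda p: (p.mirna, p.gene))
    return pairs


def read_mrna_table(path) -> list[ExpressionRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        ExpressionRecord(
            gene=str(r.gene),
            median_tpm_met=float(r.median_tpm_met),
            median_tpm_nomet=float(r.median_tpm_nomet),
            log2_fc=float(r.log2_fc),
            adj_p=float(r.adj_p),
        )
        for r in df.itertuples()
    ]


def read_mirna_table(path) -> list[MirnaRecord]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MirnaRecord(
            mirna=str(r.mirna),
            median_raw_met=float(r.median_raw_met),
            median_raw_nomet=float(r.median_raw_nomet),
            median_norm_met=float(r.median_norm_met),
            median_norm_nomet=float(r.median_norm_nomet),
            log2_fc=float(r.log2_fc),
            q_value=float(r.q_value),
        )
        for r in df.itertuples()
    ]


def read_interaction_table(path) -> list[TargetInteraction]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        TargetInteraction(
            mirna=str(r.mirna), gene=str(r.gene), confidence=str(r.confidence)
        )
        for r in df.itertuples()
    ]


def pairs_to_frame(pairs: Sequence[PairedInteraction]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mirna": p.mirna,
                "gene": p.gene,
                "mirna_log2_fc": p.mirna_log2_fc,
                "gene_log2_fc": p.gene_log2_fc,
            }
            for p in pairs
        ],
        columns=["mirna", "gene", "mirna_log2_fc", "gene_log2_fc"],
    )
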