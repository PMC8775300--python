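"""Instrument selection and outcome-side exclusion.

Instruments are SNPs robustly associated with the exposure at genome-wide
significance (p < 5e-8, strict inequality throughout). A SNP that is
absent from, or itself significantly associated with, the outcome GWAS is
excluded before estimation: an outcome-significant instrument is a prime
pleiotropy suspect, and an absent one simply cannot be harmonized.

LD independence of the instruments is assumed to be established upstream
by the source GWAS; no clumping is performed here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .gwas_io import SummaryTable

__all__ = [
    "GENOME_WIDE_SIGNIFICANCE",
    "InstrumentDrop",
    "select_instruments",
    "exclude_outcome_associated",
    "write_drop_report",
]

GENOME_WIDE_SIGNIFICANCE = 5e-8

#: Drop-reason tokens; the two reasons partition the dropped set.
REASON_ABSENT = "absent"
REASON_OUTCOME_SIGNIFICANT = "outcome-significant"


@dataclass(frozen=True)
class InstrumentDrop:
    snp_id: str
    reason: str
    outcome_pvalue: float | None = None


def select_instruments(
    table: SummaryTable, p_threshold: float = GENOME_WIDE_SIGNIFICANCE
) -> SummaryTable:
    """Keep records with exposure p-value strictly below ``p_threshold``.

    Order is preserved; the operation is idempotent and monotone in the
    threshold. An empty result is returned (with a warning) rather than
    raised, since downstream estimation is what actually requires
    instruments.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    kept = [r for r in table.records if r.pvalue < p_threshold]
    if not kept and table.records:
        warnings.warn(
            f"no instrument reaches p < {p_threshold:g}; downstream MR requires >= 1",
            stacklevel=2,
        )
    return SummaryTable(records=kept, trait=table.trait, provenance=table.provenance)


def exclude_outcome_associated(
    instruments: SummaryTable,
    outcome: SummaryTable,
    p_threshold: float = GENOME_WIDE_SIGNIFICANCE,
) -> tuple[SummaryTable, list[InstrumentDrop]]:
    """Drop instruments absent from, or significant in, the outcome GWAS.

    Returns the surviving instruments (input order preserved) together
    with an audit log recording each drop and its reason (``absent`` vs
    ``outcome-significant``).
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    kept = []
    drops: list[InstrumentDrop] = []
    for record in instruments.records:
        out = outcome.get(record.snp_id)
        if out is None:
            drops.append(InstrumentDrop(record.snp_id, REASON_ABSENT))
        elif out.pvalue < p_threshold:
            drops.append(
                InstrumentDrop(record.snp_id, REASON_OUTCOME_SIGNIFICANT, out.pvalue)
            )
        else:
            kept.append(record)
    survivors = SummaryTable(
        records=kept, trait=instruments.trait, provenance=instruments.provenance
    )
    return survivors, drops


def write_drop_report(drops: Iterable[InstrumentDrop], path: str | Path) -> None:
    """Emit the exclusion audit as a tab-separated drop report."""
    lines = ["snp_id\treason\toutcome_pvalue"]
    for d in drops:
        p = "NA" if d.outcome_pvalue is None else repr(d.outcome_pvalue)
        lines.append(f"{d.snp_id}\t{d.reason}\t{p}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
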