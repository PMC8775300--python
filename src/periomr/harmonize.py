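"""Allele harmonization: expressing exposure and outcome effects for each
SNP relative to a common effect allele.

Two GWASs may report the same SNP on different alleles or strands. Before
any ratio of outcome to exposure effect is meaningful, the outcome effect
must refer to the exposure's effect allele: a differing allele means the
outcome beta changes sign and its effect-allele frequency becomes its
complement.

Palindromic SNPs (A/T or C/G pairs) are the hard case — allele labels
alone cannot distinguish a strand flip from a genuine allele swap. The
default policy aligns them by effect-allele-frequency concordance when
both frequencies are informative (both minor-allele frequencies below an
ambiguity threshold) and drops them otherwise; a strict drop-all policy
is also available.

The bundled exposure instruments publish only the effect allele, so an
*effect-allele-only* mode is supported: a differing outcome effect allele
is treated as the other allele and sign-flipped, unless the two labels
are strand complements of each other, in which case the SNP is handled as
palindromic. Indel codes (``d``/``i``) and other non-ACGT alleles are
matched by literal string equality and never complemented.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .gwas_io import SummaryRecord, SummaryTable

__all__ = [
    "HarmonizationPolicy",
    "HarmonizedPair",
    "DropDecision",
    "HarmonizationAudit",
    "harmonize_pair",
    "harmonize_tables",
    "write_harmonized_table",
]

_COMPLEMENT = {"a": "t", "t": "a", "c": "g", "g": "c"}

REASON_PALINDROMIC = "palindromic"
REASON_PALINDROMIC_AMBIGUOUS = "palindromic-ambiguous"
REASON_ALLELE_MISMATCH = "allele-mismatch"


def complement(allele: str) -> str | None:
    """Strand complement of a single-base allele; None where undefined."""
    return _COMPLEMENT.get(allele.lower())


def is_palindromic_pair(a1: str, a2: str) -> bool:
    """True for A/T or C/G allele pairs (strand-ambiguous)."""
    return complement(a1) == a2.lower()


@dataclass(frozen=True)
class HarmonizationPolicy:
    """Resolution rules for ambiguous allele configurations.

    palindromic
        ``"freq"`` aligns palindromic SNPs by frequency concordance when
        both effect-allele frequencies are available and both minor-allele
        frequencies fall below ``freq_threshold``; ``"drop"`` removes all
        palindromic SNPs outright.
    freq_threshold
        Minor-allele-frequency ceiling below which frequency alignment is
        considered informative (default 0.42).
    """

    palindromic: str = "freq"
    freq_threshold: float = 0.42

    def __post_init__(self) -> None:
        if self.palindromic not in ("freq", "drop"):
            raise ValueError("palindromic policy must be 'freq' or 'drop'")
        if not (0.0 < self.freq_threshold <= 0.5):
            raise ValueError("freq_threshold must lie in (0, 0.5]")


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common effect allele."""

    snp_id: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    flipped: bool = False
    palindromic: bool = False
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None

    def __post_init__(self) -> None:
        if not (self.se_exposure > 0 and self.se_outcome > 0):
            raise ValueError("standard errors must be strictly positive")


@dataclass(frozen=True)
class DropDecision:
    snp_id: str
    reason: str


@dataclass
class HarmonizationAudit:
    n_kept: int = 0
    n_flipped: int = 0
    drops: list[DropDecision] = field(default_factory=list)

    @property
    def n_dropped(self) -> int:
        return len(self.drops)


def _freq_alignment(
    exposure: SummaryRecord, outcome: SummaryRecord, policy: HarmonizationPolicy
) -> bool | None:
    """Resolve a palindromic SNP by frequency concordance.

    Returns False (keep orientation), True (flip) or None (unresolvable).
    """
    if policy.palindromic == "drop":
        return None
    if exposure.eaf is None or outcome.eaf is None:
        return None
    maf_x = min(exposure.eaf, 1 - exposure.eaf)
    maf_y = min(outcome.eaf, 1 - outcome.eaf)
    if maf_x >= policy.freq_threshold or maf_y >= policy.freq_threshold:
        return None
    # same side of 0.5 -> the labels refer to the same allele
    return (exposure.eaf - 0.5) * (outcome.eaf - 0.5) < 0


def _decide(
    exposure: SummaryRecord, outcome: SummaryRecord, policy: HarmonizationPolicy
) -> tuple[bool, bool] | str:
    """Return (flip, palindromic) or a drop reason."""
    ea_x = exposure.effect_allele
    ea_y = outcome.effect_allele

    if exposure.other_allele is not None:
        oa_x = exposure.other_allele
        if is_palindromic_pair(ea_x, oa_x):
            if policy.palindromic == "drop":
                return REASON_PALINDROMIC
            flip = _freq_alignment(exposure, outcome, policy)
            if flip is None:
                return REASON_PALINDROMIC_AMBIGUOUS
            return flip, True
        if ea_y == ea_x or ea_y == complement(ea_x):
            return False, False
        if ea_y == oa_x or ea_y == complement(oa_x):
            return True, False
        return REASON_ALLELE_MISMATCH

    # effect-allele-only mode (the bundled-instrument situation)
    if ea_y == ea_x:
        return False, False
    if complement(ea_x) == ea_y:
        # could be a strand flip of the same allele or a true swap
        if policy.palindromic == "drop":
            return REASON_PALINDROMIC
        flip = _freq_alignment(exposure, outcome, policy)
        if flip is None:
            return REASON_PALINDROMIC_AMBIGUOUS
        return flip, True
    return True, False


def harmonize_pair(
    exposure: SummaryRecord,
    outcome: SummaryRecord,
    policy: HarmonizationPolicy | None = None,
) -> HarmonizedPair | DropDecision:
    """Harmonize one SNP's exposure and outcome records.

    Returns a :class:`HarmonizedPair` on the exposure's effect allele, or
    a :class:`DropDecision` when the allele configuration cannot be
    resolved under ``policy``. Standard errors and the exposure effect are
    never altered; a flip negates the outcome beta and complements its
    effect-allele frequency.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(
            f"snp_id mismatch: {exposure.snp_id!r} vs {outcome.snp_id!r}"
        )
    policy = policy or HarmonizationPolicy()
    decision = _decide(exposure, outcome, policy)
    if isinstance(decision, str):
        return DropDecision(exposure.snp_id, decision)
    flip, palindromic = decision
    beta_y = -outcome.beta if flip else outcome.beta
    eaf_y = outcome.eaf
    if flip and eaf_y is not None:
        eaf_y = 1.0 - eaf_y
    return HarmonizedPair(
        snp_id=exposure.snp_id,
        effect_allele=exposure.effect_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_y,
        se_outcome=outcome.se,
        flipped=flip,
        palindromic=palindromic,
        eaf_exposure=exposure.eaf,
        eaf_outcome=eaf_y,
    )


def harmonize_tables(
    exposure: SummaryTable,
    outcome: SummaryTable,
    policy: HarmonizationPolicy | None = None,
) -> tuple[list[HarmonizedPair], HarmonizationAudit]:
    """Harmonize every SNP present in both tables, in exposure order."""
    policy = policy or HarmonizationPolicy()
    pairs: list[HarmonizedPair] = []
    audit = HarmonizationAudit()
    for record in exposure.records:
        out = outcome.get(record.snp_id)
        if out is None:
            continue
        result = harmonize_pair(record, out, policy)
        if isinstance(result, DropDecision):
            audit.drops.append(result)
            continue
        pairs.append(result)
        audit.n_kept += 1
        if result.flipped:
            audit.n_flipped += 1
    return pairs, audit


def write_harmonized_table(pairs: Iterable[HarmonizedPair], path: str | Path) -> None:
    """Write harmonized pairs as a tab-separated file."""
    header = (
        "snp_id\teffect_allele\tbeta_exposure\tse_exposure"
        "\tbeta_outcome\tse_outcome\tflipped\tpalindromic"
    )
    lines = [header]
    for p in pairs:
        lines.append(
            f"{p.snp_id}\t{p.effect_allele}\t{p.beta_exposure!r}\t{p.se_exposure!r}"
            f"\t{p.beta_outcome!r}\t{p.se_outcome!r}\t{p.flipped}\t{p.palindromic}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
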