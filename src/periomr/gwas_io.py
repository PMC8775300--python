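"""Reading, validating and writing GWAS summary-statistic tables.

The canonical on-disk dialect is tab-separated, one header row, UTF-8,
with ``NA`` as the missing token and canonical column names
``snp_id, effect_allele, other_allele, eaf, beta, se, pvalue, n``.
Arbitrary source headers are supported through a column map, since
consortium files rarely agree on naming.

Validation is reject-and-log per row rather than abort-on-first-error:
real summary files contain sporadic malformed rows and a single bad line
must not discard an entire consortium download.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

__all__ = [
    "SummaryRecord",
    "SummaryTable",
    "RowRejection",
    "read_summary_table",
    "write_summary_table",
    "load_table1_fixture",
    "CANONICAL_COLUMNS",
    "MANDATORY_FIELDS",
    "TABLE1_TRAIT",
]

CANONICAL_COLUMNS = (
    "snp_id",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pvalue",
    "n",
)
MANDATORY_FIELDS = ("snp_id", "effect_allele", "beta", "se", "pvalue")

#: Trait label of the bundled exposure instruments (combined liability GWAS).
TABLE1_TRAIT = "dental caries and periodontitis"

_MISSING = "NA"
_FIXTURE_PATH = Path(__file__).parent / "data" / "table1_instruments.tsv"


class SummaryTableError(ValueError):
    """Configuration-level failure while reading a summary table."""


@dataclass(frozen=True)
class SummaryRecord:
    """One SNP's association with one trait.

    Alleles are stored verbatim as lower-case text. Single bases, indel
    codes (``d``/``i``) and multi-base alleles are all legal; no
    complementing or normalisation is applied here.
    """

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    pvalue: float
    other_allele: str | None = None
    eaf: float | None = None
    n: float | None = None
    trait: str = ""

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValueError("snp_id must be non-empty")
        if not self.effect_allele:
            raise ValueError("effect_allele must be non-empty")
        object.__setattr__(self, "effect_allele", self.effect_allele.lower())
        if self.other_allele is not None:
            object.__setattr__(self, "other_allele", self.other_allele.lower())
            if self.other_allele == self.effect_allele:
                raise ValueError("effect_allele and other_allele must differ")
        if not (math.isfinite(self.beta) and math.isfinite(self.se)):
            raise ValueError("beta and se must be finite")
        if not self.se > 0:
            raise ValueError("se must be strictly positive")
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError("pvalue must lie in (0, 1]")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValueError("eaf must lie in [0, 1]")


@dataclass(frozen=True)
class RowRejection:
    """Audit entry for one rejected input row."""

    row_number: int  # 1-based data-row index in the source file
    snp_id: str
    reason: str


@dataclass
class SummaryTable:
    """Ordered collection of :class:`SummaryRecord` for one trait."""

    records: list[SummaryRecord]
    trait: str = ""
    provenance: str = ""
    rejections: list[RowRejection] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate snp_id within table: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SummaryRecord]:
        return iter(self.records)

    def get(self, snp_id: str) -> SummaryRecord | None:
        return self._index().get(snp_id)

    def _index(self) -> dict[str, SummaryRecord]:
        return {r.snp_id: r for r in self.records}

    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Canonical-column DataFrame view (missing fields become NaN/None)."""
        rows = [
            {
                "snp_id": r.snp_id,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pvalue": r.pvalue,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_float(token: object, field_name: str) -> float | None:
    if token is None:
        return None
    text = str(token).strip()
    if text == "" or text.upper() in {"NA", "NAN", "NONE", "."}:
        return None
    try:
        return float(text)
    except ValueError as exc:
        raise ValueError(f"unparseable numeric in {field_name!r}: {text!r}") from exc


def read_summary_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "",
    provenance: str | None = None,
) -> SummaryTable:
    """Read a tab-separated summary-statistic file into a validated table.

    Parameters
    ----------
    path
        Tab-separated file with one header row.
    column_map
        Mapping from canonical field names (``snp_id``, ``effect_allele``,
        ``other_allele``, ``eaf``, ``beta``, ``se``, ``pvalue``, ``n``) to
        the headers used in the file. Omitted fields default to their
        canonical names; optional fields absent from the file are left
        unset on every record.
    trait, provenance
        Labels attached to the returned table (provenance defaults to the
        file path).

    Rows failing record validation are rejected, counted and recorded in
    ``SummaryTable.rejections`` with a per-row reason; a missing mandatory
    column raises :class:`SummaryTableError`.
    """
    path = Path(path)
    if not path.exists():
        raise SummaryTableError(f"no such file: {path}")
    cmap = {k: k for k in CANONICAL_COLUMNS}
    if column_map:
        unknown = set(column_map) - set(CANONICAL_COLUMNS)
        if unknown:
            raise SummaryTableError(f"unknown canonical fields in column_map: {sorted(unknown)}")
        cmap.update(column_map)

    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for field_name in MANDATORY_FIELDS:
        if cmap[field_name] not in frame.columns:
            raise SummaryTableError(
                f"mandatory column {cmap[field_name]!r} (field {field_name!r}) missing from {path}"
            )
    present = {f: cmap[f] for f in CANONICAL_COLUMNS if cmap[f] in frame.columns}

    records: list[SummaryRecord] = []
    rejections: list[RowRejection] = []
    seen: set[str] = set()
    for row_number, row in enumerate(frame.itertuples(index=False), start=1):
        raw = dict(zip(frame.columns, row))
        snp_id = str(raw.get(present.get("snp_id", ""), "")).strip()
        try:
            other = str(raw[present["other_allele"]]).strip() if "other_allele" in present else ""
            beta = _parse_float(raw[present["beta"]], "beta")
            se = _parse_float(raw[present["se"]], "se")
            pvalue = _parse_float(raw[present["pvalue"]], "pvalue")
            if beta is None or se is None or pvalue is None:
                raise ValueError("mandatory numeric field missing")
            record = SummaryRecord(
                snp_id=snp_id,
                effect_allele=str(raw[present["effect_allele"]]).strip(),
                other_allele=other if other and other.upper() != _MISSING else None,
                eaf=_parse_float(raw.get(present.get("eaf", "")), "eaf") if "eaf" in present else None,
                beta=beta,
                se=se,
                pvalue=pvalue,
                n=_parse_float(raw.get(present.get("n", "")), "n") if "n" in present else None,
                trait=trait,
            )
            if record.snp_id in seen:
                raise ValueError("duplicate snp_id")
        except (TypeError, ValueError) as exc:
            rejections.append(RowRejection(row_number, snp_id or "<blank>", str(exc)))
            continue
        seen.add(record.snp_id)
        records.append(record)

    return SummaryTable(
        records=records,
        trait=trait,
        provenance=provenance if provenance is not None else str(path),
        rejections=rejections,
    )


def _format_value(value: object) -> str:
    if value is None:
        return _MISSING
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_summary_table(table: SummaryTable, path: str | Path) -> None:
    """Write a table in the canonical tab-separated dialect.

    ``read_summary_table(write_summary_table(t))`` reproduces ``t``
    field-for-field; floats are emitted with ``repr`` so the round trip is
    exact, and unset optional fields become the explicit ``NA`` token.
    """
    path = Path(path)
    lines = ["\t".join(CANONICAL_COLUMNS)]
    for r in table.records:
        lines.append(
            "\t".join(
                _format_value(v)
                for v in (r.snp_id, r.effect_allele, r.other_allele, r.eaf, r.beta, r.se, r.pvalue, r.n)
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def load_table1_fixture() -> SummaryTable:
    """The 47 exposure instruments bundled with the package.

    These are the independent SNPs associated with dental caries and
    periodontitis from the largest published GWAS of the combined liability
    (GLIDE consortium + UK Biobank, n = 487,823), transcribed at printed
    precision. Only the effect allele is published, so ``other_allele`` is
    unset on every record; two instruments carry indel codes (``d``) and
    one a chr:pos token instead of an rsID.
    """
    table = read_summary_table(
        _FIXTURE_PATH,
        trait=TABLE1_TRAIT,
        provenance="bundled instrument fixture",
    )
    if table.rejections:
        raise RuntimeError(f"bundled fixture failed validation: {table.rejections}")
    return table


def write_rejection_log(rejections: Iterable[RowRejection], path: str | Path) -> None:
    """Emit the per-row rejection audit as a tab-separated report."""
    lines = ["row_number\tsnp_id\treason"]
    lines += [f"{r.row_number}\t{r.snp_id}\t{r.reason}" for r in rejections]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
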