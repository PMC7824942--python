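"""Readers and writers for per-cell TCR contig data and sample metadata.

Supports the 10x Cell Ranger ``filtered_contig_annotations.csv`` dialect
and AIRR Rearrangement TSVs.  Parsing is deliberately lossless: rows with
unusable CDR3s or non-TCR loci are retained and flagged so that downstream
filter effects stay auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

UNKNOWN_GROUP = "unknown"


class FormatError(ValueError):
    """Raised when an input table lacks required structure."""


@dataclass(frozen=True)
class ContigRecord:
    """One sequenced TCR contig for one cell.

    ``chain`` is one of ``"TRA"``, ``"TRB"`` or ``"other"`` (non-TCR or
    unrecognized loci).  A contig is *usable* when its CDR3 amino-acid
    string is non-empty and drawn from the 20 standard uppercase letters.
    """

    barcode: str
    sample_id: str
    chain: str
    cdr3_aa: str
    cdr3_nt: str | None = None
    v_gene: str | None = None
    j_gene: str | None = None
    productive: bool = False
    high_confidence: bool = True

    @property
    def usable(self) -> bool:
        return bool(self.cdr3_aa) and all(c in AA_ALPHABET for c in self.cdr3_aa)


@dataclass
class CellTCR:
    """All usable, productive TCR chains observed for one cell."""

    barcode: str
    sample_id: str
    alpha_chains: list[ContigRecord] = field(default_factory=list)
    beta_chains: list[ContigRecord] = field(default_factory=list)


@dataclass
class Repertoire:
    """A validated in-memory repertoire: cells plus sample metadata."""

    cells: list[CellTCR]
    metadata: pd.DataFrame
    provenance: dict = field(default_factory=dict)


_TRUE_STRINGS = {"true", "t", "yes", "1"}
_FALSE_STRINGS = {"false", "f", "no", "0", "none", "nan", ""}

# column-name synonyms, all matched case-insensitively
_SYNONYMS = {
    "barcode": ["barcode", "cell_id"],
    "chain": ["chain", "locus"],
    "cdr3_aa": ["cdr3", "junction_aa", "cdr3_aa"],
    "cdr3_nt": ["cdr3_nt", "junction"],
    "v_gene": ["v_gene", "v_call"],
    "j_gene": ["j_gene", "j_call"],
    "productive": ["productive"],
    "high_confidence": ["high_confidence", "is_cell"],
}


def _parse_bool(value) -> bool:
    if isinstance(value, bool):
        return value
    s = str(value).strip().lower()
    if s in _TRUE_STRINGS:
        return True
    if s in _FALSE_STRINGS:
        return False
    return False


def _clean_str(value) -> str:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return ""
    s = str(value).strip()
    if s.lower() in {"none", "nan", "na"}:
        return ""
    return s


def _resolve_columns(df: pd.DataFrame, required: Sequence[str]) -> dict[str, str]:
    lower_map = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for canonical, names in _SYNONYMS.items():
        for name in names:
            if name in lower_map:
                resolved[canonical] = lower_map[name]
                break
    for canonical in required:
        if canonical not in resolved:
            raise FormatError(
                f"missing required column {canonical!r} "
                f"(accepted names: {_SYNONYMS[canonical]})"
            )
    return resolved


def _classify_chain(raw: str) -> str:
    c = raw.strip().upper()
    if c in ("TRA", "TRB"):
        return c
    return "other"


def _records_from_frame(
    df: pd.DataFrame, sample_id: str, required: Sequence[str]
) -> list[ContigRecord]:
    cols = _resolve_columns(df, required)
    records = []
    for row in df.itertuples(index=False):
        row_d = dict(zip(df.columns, row))

        def get(canonical, default=None):
            col = cols.get(canonical)
            return row_d[col] if col is not None else default

        cdr3 = _clean_str(get("cdr3_aa")).upper() if get("cdr3_aa") is not None else ""
        records.append(
            ContigRecord(
                barcode=_clean_str(get("barcode")),
                sample_id=sample_id,
                chain=_classify_chain(_clean_str(get("chain"))),
                cdr3_aa=cdr3,
                cdr3_nt=_clean_str(get("cdr3_nt")) or None,
                v_gene=_clean_str(get("v_gene")) or None,
                j_gene=_clean_str(get("j_gene")) or None,
                productive=_parse_bool(get("productive", False)),
                high_confidence=_parse_bool(get("high_confidence", True)),
            )
        )
    return records


def contigs_from_frame(df: pd.DataFrame, sample_id: str) -> list[ContigRecord]:
    """Build contig records from an in-memory table in either dialect."""
    return _records_from_frame(
        df.astype(str), sample_id, ["barcode", "chain", "cdr3_aa", "productive"]
    )


def read_cellranger_contigs(path: str | Path, sample_id: str) -> list[ContigRecord]:
    """Read a 10x ``filtered_contig_annotations.csv``-dialect table.

    One :class:`ContigRecord` per row.  Non-TRA/TRB rows are kept with
    ``chain="other"``; rows with degenerate CDR3s (``"None"``, empty,
    stop codons) are flagged non-usable rather than dropped.

    Raises
    ------
    FormatError
        If a required column (barcode, chain, cdr3, productive) is absent.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty:
        if len(df.columns) == 0:
            raise FormatError(f"{path}: no header row")
        _resolve_columns(df, ["barcode", "chain", "cdr3_aa", "productive"])
        logger.warning("%s: no contig rows", path)
        return []
    return _records_from_frame(df, sample_id, ["barcode", "chain", "cdr3_aa", "productive"])


def read_airr(path: str | Path, sample_id: str) -> list[ContigRecord]:
    """Read an AIRR Rearrangement TSV (``junction_aa``/``locus``/``productive``).

    Same contract as :func:`read_cellranger_contigs`.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.empty:
        if len(df.columns) == 0:
            raise FormatError(f"{path}: no header row")
        _resolve_columns(df, ["barcode", "chain", "cdr3_aa", "productive"])
        logger.warning("%s: no rearrangement rows", path)
        return []
    return _records_from_frame(df, sample_id, ["barcode", "chain", "cdr3_aa", "productive"])


def assemble_cells(
    contigs: Iterable[ContigRecord], require_high_confidence: bool = True
) -> list[CellTCR]:
    """Group contigs by (sample_id, barcode) into :class:`CellTCR` objects.

    Only productive, usable TRA/TRB contigs populate the chain lists;
    ``other``-chain, non-productive and unusable contigs are excluded here
    (they were retained at parse time for auditability).  Barcodes are
    unique only within a sample.
    """
    cells: dict[tuple[str, str], CellTCR] = {}
    for contig in contigs:
        key = (contig.sample_id, contig.barcode)
        if key not in cells:
            cells[key] = CellTCR(barcode=contig.barcode, sample_id=contig.sample_id)
        if contig.chain not in ("TRA", "TRB"):
            continue
        if not (contig.productive and contig.usable):
            continue
        if require_high_confidence and not contig.high_confidence:
            continue
        cell = cells[key]
        if contig.chain == "TRA":
            cell.alpha_chains.append(contig)
        else:
            cell.beta_chains.append(contig)
    return list(cells.values())


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata CSV mapping sample_id to diagnosis_group.

    Extra columns are preserved.  Duplicate sample_ids are an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    lower = {c.lower(): c for c in df.columns}
    if "sample_id" not in lower or "diagnosis_group" not in lower:
        raise FormatError("metadata requires sample_id and diagnosis_group columns")
    df = df.rename(
        columns={lower["sample_id"]: "sample_id", lower["diagnosis_group"]: "diagnosis_group"}
    )
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise FormatError(f"duplicate sample_id in metadata: {dup!r}")
    return df


def build_repertoire(
    cells: list[CellTCR],
    metadata: pd.DataFrame | None,
    provenance: dict | None = None,
) -> Repertoire:
    """Attach metadata to assembled cells, back-filling unknown samples.

    Samples seen in cells but absent from the metadata are assigned the
    ``unknown`` diagnosis group with a warning.
    """
    seen = sorted({c.sample_id for c in cells})
    if metadata is None:
        metadata = pd.DataFrame({"sample_id": [], "diagnosis_group": []}, dtype=str)
    known = set(metadata["sample_id"])
    missing = [s for s in seen if s not in known]
    if missing:
        logger.warning("samples missing from metadata assigned group %r: %s", UNKNOWN_GROUP, missing)
        extra = pd.DataFrame({"sample_id": missing, "diagnosis_group": UNKNOWN_GROUP})
        metadata = pd.concat([metadata, extra], ignore_index=True)
    return Repertoire(cells=cells, metadata=metadata, provenance=provenance or {})


def group_of(repertoire: Repertoire) -> dict[str, str]:
    """sample_id -> diagnosis_group lookup."""
    return dict(
        zip(repertoire.metadata["sample_id"], repertoire.metadata["diagnosis_group"])
    )


_AIRR_COLUMNS = [
    "cell_id",
    "sample_id",
    "locus",
    "junction_aa",
    "junction",
    "v_call",
    "j_call",
    "productive",
]


def write_airr(repertoire: Repertoire | list[CellTCR], path: str | Path) -> None:
    """Write usable TRA/TRB contigs as an AIRR Rearrangement TSV.

    ``other``-chain contigs never reach :class:`CellTCR` objects, so the
    output contains exactly the usable contigs; an empty repertoire
    produces a header-only file.  Round-trips through :func:`read_airr`.
    """
    cells = repertoire.cells if isinstance(repertoire, Repertoire) else repertoire
    rows = []
    for cell in cells:
        for contig in cell.alpha_chains + cell.beta_chains:
            rows.append(
                {
                    "cell_id": contig.barcode,
                    "sample_id": contig.sample_id,
                    "locus": contig.chain,
                    "junction_aa": contig.cdr3_aa,
                    "junction": contig.cdr3_nt or "",
                    "v_call": contig.v_gene or "",
                    "j_call": contig.j_gene or "",
                    "productive": "T" if contig.productive else "F",
                }
            )
    df = pd.DataFrame(rows, columns=_AIRR_COLUMNS)
    df.to_csv(path, sep="\t", index=False)
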