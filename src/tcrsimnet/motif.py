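"""Sliding-window CDR3beta motif enumeration and specificity-database lookup.

Motifs are contiguous substrings of each clonal clonotype's CDR3beta after
trimming the conserved residues at both ends (two by default).  A motif's
frequency counts distinct supporting clonotypes, not cells or occurrences,
so clone sizes cannot dominate the ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MotifRecord:
    motif: str
    supporting: set[str] = field(default_factory=set)
    samples: set[str] = field(default_factory=set)
    groups: set[str] = field(default_factory=set)

    @property
    def length(self) -> int:
        return len(self.motif)

    @property
    def frequency(self) -> int:
        return len(self.supporting)


@dataclass
class SpecificityEntry:
    """One specificity-database row linking a CDR3beta to annotations."""

    cdr3b: str
    pathology: str = ""
    antigen: str = ""
    t_cell_type: str = ""
    extra: dict = field(default_factory=dict)


def enumerate_motifs(clonotypes, trim: int = 2, min_length: int = 3) -> list[MotifRecord]:
    """Enumerate all interior CDR3beta substrings across clonotypes.

    For each clonotype, the first and last ``trim`` residues of cdr3b are
    removed, then every contiguous substring of length >= ``min_length``
    is generated.  Each clonotype counts once per distinct motif
    regardless of multiplicity within its own sequence.  Clonotypes whose
    trimmed sequence is shorter than ``min_length`` contribute nothing.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    records: dict[str, MotifRecord] = {}
    skipped = 0
    for ct in clonotypes:
        core = ct.cdr3b[trim : len(ct.cdr3b) - trim] if trim else ct.cdr3b
        if len(core) < min_length:
            skipped += 1
            continue
        seen: set[str] = set()
        for length in range(min_length, len(core) + 1):
            for start in range(len(core) - length + 1):
                seen.add(core[start : start + length])
        for motif in seen:
            rec = records.setdefault(motif, MotifRecord(motif=motif))
            rec.supporting.add(ct.clonotype_id)
            rec.samples.update(ct.samples)
            rec.groups.update(ct.groups)
    if skipped:
        logger.info("enumerate_motifs: %d clonotypes too short after trim=%d", skipped, trim)
    return list(records.values())


# accepted CDR3beta column names in specificity databases (case-insensitive)
_DB_CDR3B_COLUMNS = ["cdr3.beta.aa", "cdr3b", "cdr3_beta", "cdr3", "junction_aa"]


def read_specificity_db(
    path, cdr3b_column: str | None = None
) -> list[SpecificityEntry]:
    """Read a McPAS-TCR-layout CSV of CDR3beta specificity annotations.

    Entries with empty or non-amino-acid CDR3beta are dropped (count
    logged).  Duplicate rows are kept; hits are counted at entry level.
    """
    from tcrsimnet.io import AA_ALPHABET, FormatError

    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding_errors="replace")
    lower = {c.lower(): c for c in df.columns}
    col = None
    if cdr3b_column is not None:
        col = lower.get(cdr3b_column.lower())
        if col is None:
            raise FormatError(f"specificity db lacks column {cdr3b_column!r}")
    else:
        for name in _DB_CDR3B_COLUMNS:
            if name in lower:
                col = lower[name]
                break
        if col is None:
            raise FormatError(
                f"no recognizable CDR3beta column (looked for {_DB_CDR3B_COLUMNS})"
            )
    pathology_col = lower.get("pathology")
    antigen_col = lower.get("antigen.protein") or lower.get("antigen") or lower.get("epitope.peptide")
    tcell_col = lower.get("t.cell.type") or lower.get("t_cell_type")
    entries = []
    dropped = 0
    for row in df.to_dict(orient="records"):
        cdr3b = str(row.get(col, "")).strip().upper()
        if cdr3b in {"NA", "N/A", "NAN", "NONE"}:  # missing-value tokens, not dipeptides
            cdr3b = ""
        if not cdr3b or not all(c in AA_ALPHABET for c in cdr3b):
            dropped += 1
            continue
        entries.append(
            SpecificityEntry(
                cdr3b=cdr3b,
                pathology=str(row.get(pathology_col, "")).strip() if pathology_col else "",
                antigen=str(row.get(antigen_col, "")).strip() if antigen_col else "",
                t_cell_type=str(row.get(tcell_col, "")).strip() if tcell_col else "",
                extra={k: v for k, v in row.items() if k != col},
            )
        )
    if dropped:
        logger.info("read_specificity_db: dropped %d entries with invalid CDR3beta", dropped)
    return entries


def search_motif(motif: str, db: list[SpecificityEntry]) -> dict:
    """Find database entries whose full CDR3beta contains ``motif``.

    Matching is substring containment on the untrimmed database CDR3beta,
    case-normalized to uppercase.  Returns the hit list plus pathology and
    T-cell-type tallies sorted by count descending (ties alphabetical).
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    needle = motif.upper()
    hits = [e for e in db if needle in e.cdr3b]

    def tally(values: list[str]) -> list[tuple[str, int]]:
        counts: dict[str, int] = {}
        for v in values:
            if v:
                counts[v] = counts.get(v, 0) + 1
        return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))

    return {
        "motif": needle,
        "n_hits": len(hits),
        "hits": hits,
        "by_pathology": tally([h.pathology for h in hits]),
        "by_t_cell_type": tally([h.t_cell_type for h in hits]),
    }


def motif_report(
    motifs: list[MotifRecord], length: int | None = None, top_n: int | None = None
) -> pd.DataFrame:
    """Rank motifs (optionally of one length) by clonotype frequency.

    Sorted by frequency descending, ties broken lexicographically by
    motif string; includes sample and group support columns.
    """
    selected = [m for m in motifs if length is None or m.length == length]
    selected.sort(key=lambda m: (-m.frequency, m.motif))
    if top_n is not None:
        selected = selected[:top_n]
    rows = [
        {
            "motif": m.motif,
            "length": m.length,
            "frequency": m.frequency,
            "clonotype_ids": ";".join(sorted(m.supporting)),
            "samples": ";".join(sorted(m.samples)),
            "groups": ";".join(sorted(m.groups)),
        }
        for m in selected
    ]
    return pd.DataFrame(
        rows, columns=["motif", "length", "frequency", "clonotype_ids", "samples", "groups"]
    )
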