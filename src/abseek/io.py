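"""Repertoire input/output: FASTA and AIRR-style tables, prefilters, result CSV.

Two database formats are supported: plain protein FASTA (whole sequences, no
region annotation) and the tab-separated rearrangement tables emitted by
IgBLAST-style annotators, with IMGT framework/CDR amino-acid columns
(``fwr1_aa`` ... ``cdr3_aa``), a productivity flag and a locus call.  Records
are prefiltered on productivity and on region lengths before any alignment.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .categories import STANDARD_AMINO_ACIDS

logger = logging.getLogger(__name__)

__all__ = [
    "REGIONS",
    "CDR_REGIONS",
    "RepertoireRecord",
    "RegionLengthFilter",
    "FormatError",
    "read_fasta",
    "read_igblast_table",
    "write_repertoire_table",
    "filter_productive",
    "filter_by_region_lengths",
    "write_results",
    "read_results",
]

#: Variable-domain regions in N-to-C order.
REGIONS: tuple[str, ...] = ("FW1", "CDR1", "FW2", "CDR2", "FW3", "CDR3")
CDR_REGIONS: tuple[str, ...] = ("CDR1", "CDR2", "CDR3")

#: Residues tolerated in database sequences (standard alphabet plus X).
_SEQ_ALPHABET = STANDARD_AMINO_ACIDS | {"X"}

#: Default AIRR rearrangement column names for each record field.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "record_id": "sequence_id",
    "productive": "productive",
    "locus": "locus",
    "FW1": "fwr1_aa",
    "CDR1": "cdr1_aa",
    "FW2": "fwr2_aa",
    "CDR2": "cdr2_aa",
    "FW3": "fwr3_aa",
    "CDR3": "cdr3_aa",
    "v_call": "v_call",
    "j_call": "j_call",
    "duplicate_count": "duplicate_count",
}

_OPTIONAL_COLUMNS = ("v_call", "j_call", "duplicate_count")


class FormatError(ValueError):
    """Input file does not follow the expected format."""


@dataclass(frozen=True)
class RepertoireRecord:
    """One B-cell-receptor sequence with optional region annotations."""

    record_id: str
    regions: Mapping[str, str] = field(default_factory=dict)
    full_sequence: str | None = None
    productive: bool | None = None
    locus: str | None = None
    v_call: str | None = None
    j_call: str | None = None
    duplicate_count: int | None = None

    def region(self, name: str) -> str | None:
        seq = self.regions.get(name)
        return seq if seq else None


@dataclass(frozen=True)
class RegionLengthFilter:
    """Per-region length window applied before alignment.

    A record passes iff for every participating region,
    ``|len(record region) - target| <= tolerance``.  Records missing a
    participating region are excluded (and counted by the caller's log).
    Defaults follow common practice for structure-derived queries: CDR lengths
    are well determined from backbone traces, so the three CDRs participate
    with a tight tolerance (0 for CDR3, 1 for CDR1/CDR2) and framework regions
    are opt-in.
    """

    targets: Mapping[str, int]
    tolerances: Mapping[str, int] = field(default_factory=dict)
    participating: tuple[str, ...] = CDR_REGIONS

    DEFAULT_TOLERANCES = {"CDR1": 1, "CDR2": 1, "CDR3": 0}

    def __post_init__(self) -> None:
        for region, tol in self.tolerances.items():
            if tol < 0:
                raise ValueError(f"negative tolerance for {region}: {tol}")
        unknown = set(self.participating) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown regions: {sorted(unknown)}")

    def tolerance(self, region: str) -> int:
        if region in self.tolerances:
            return self.tolerances[region]
        return self.DEFAULT_TOLERANCES.get(region, 0)

    def accepts(self, record: RepertoireRecord) -> bool:
        for region in self.participating:
            if region not in self.targets:
                continue
            seq = record.region(region)
            if seq is None:
                return False
            if abs(len(seq) - self.targets[region]) > self.tolerance(region):
                return False
        return True

    @classmethod
    def from_query_lengths(
        cls,
        lengths: Mapping[str, int],
        participating: Sequence[str] = CDR_REGIONS,
        tolerances: Mapping[str, int] | None = None,
    ) -> "RegionLengthFilter":
        return cls(
            targets=dict(lengths),
            tolerances=dict(tolerances or {}),
            participating=tuple(participating),
        )


def _check_sequence(record_id: str, seq: str, where: str) -> str:
    seq = seq.upper()
    bad = sorted(set(seq) - _SEQ_ALPHABET)
    if bad:
        raise FormatError(
            f"record {record_id!r}: invalid residue symbol(s) {bad} in {where}"
        )
    return seq


def read_fasta(path: str | Path) -> list[RepertoireRecord]:
    """Read a protein FASTA database; one record per entry.

    Identifiers are taken from the header up to the first whitespace and must
    be unique.  Sequences are uppercased; symbols outside the 20 standard
    residues plus ``X`` raise :class:`FormatError` naming the record.
    """
    records: list[RepertoireRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        rid = entry.id
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)
        seq = _check_sequence(rid, str(entry.seq), "sequence")
        records.append(RepertoireRecord(record_id=rid, full_sequence=seq))
    if not records:
        logger.warning("no FASTA records found in %s", path)
    return records


def _parse_productive(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip()
    if text in {"T", "TRUE", "true", "True"}:
        return True
    if text in {"F", "FALSE", "false", "False"}:
        return False
    if text == "":
        return None
    raise FormatError(f"unrecognized productivity flag {text!r}")


def read_igblast_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[RepertoireRecord]:
    """Read an IgBLAST/AIRR-style tab-separated rearrangement table.

    The header must contain (after applying ``column_map``, which defaults to
    AIRR names) a sequence identifier, a productivity flag, a locus and the six
    region amino-acid columns.  Rows lacking all six regions are dropped with a
    logged count.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["record_id", "productive", "locus", *REGIONS]
    for key in required:
        if cmap[key] not in df.columns:
            raise FormatError(f"{path}: missing required column {cmap[key]!r}")

    records: list[RepertoireRecord] = []
    seen: set[str] = set()
    n_dropped = 0
    for _, row in df.iterrows():
        rid = str(row[cmap["record_id"]])
        regions: dict[str, str] = {}
        for region in REGIONS:
            value = row.get(cmap[region])
            if isinstance(value, str) and value.strip():
                regions[region] = _check_sequence(rid, value.strip(), region)
        if not regions:
            n_dropped += 1
            continue
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r} in {path}")
        seen.add(rid)

        def _opt(key: str) -> str | None:
            col = cmap[key]
            if col in df.columns:
                value = row[col]
                if isinstance(value, str) and value.strip():
                    return value.strip()
            return None

        dup = _opt("duplicate_count")
        records.append(
            RepertoireRecord(
                record_id=rid,
                regions=regions,
                productive=_parse_productive(row[cmap["productive"]]),
                locus=_opt("locus"),
                v_call=_opt("v_call"),
                j_call=_opt("j_call"),
                duplicate_count=int(dup) if dup is not None else None,
            )
        )
    if n_dropped:
        logger.info("dropped %d row(s) lacking all region columns", n_dropped)
    return records


def write_repertoire_table(
    records: Iterable[RepertoireRecord], path: str | Path
) -> None:
    """Write records as an AIRR-style TSV readable by :func:`read_igblast_table`."""
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "sequence_id": rec.record_id,
            "productive": {True: "T", False: "F", None: ""}[rec.productive],
            "locus": rec.locus or "",
        }
        for region in REGIONS:
            row[DEFAULT_COLUMN_MAP[region]] = rec.regions.get(region, "")
        row["v_call"] = rec.v_call or ""
        row["j_call"] = rec.j_call or ""
        row["duplicate_count"] = (
            rec.duplicate_count if rec.duplicate_count is not None else ""
        )
        rows.append(row)
    columns = [
        "sequence_id", "productive", "locus",
        *(DEFAULT_COLUMN_MAP[r] for r in REGIONS),
        "v_call", "j_call", "duplicate_count",
    ]
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)


def filter_productive(records: Sequence[RepertoireRecord]) -> list[RepertoireRecord]:
    """Drop records flagged unproductive; keep unknowns with a warning."""
    kept = [r for r in records if r.productive is not False]
    n_unknown = sum(1 for r in kept if r.productive is None)
    if n_unknown:
        logger.warning(
            "%d record(s) have no productivity flag and were retained", n_unknown
        )
    return kept


def filter_by_region_lengths(
    records: Sequence[RepertoireRecord], length_filter: RegionLengthFilter
) -> list[RepertoireRecord]:
    """Retain records whose participating-region lengths fall in the window."""
    kept = [r for r in records if length_filter.accepts(r)]
    logger.info(
        "length prefilter kept %d / %d record(s)", len(kept), len(records)
    )
    return kept


# -- result CSV ---------------------------------------------------------------

_BASE_COLUMNS = [
    "rank", "record_id", "locus",
    "total_score", "cdr_only_score", "mismatch_total", "mismatch_cdr",
]
_TRAIL_COLUMNS = ["v_call", "j_call", "duplicate_count"]


def _result_columns(regions: Sequence[str]) -> list[str]:
    cols = list(_BASE_COLUMNS)
    for region in regions:
        cols += [f"{region}_score", f"{region}_offset", f"{region}_match_string"]
    return cols + _TRAIL_COLUMNS


def write_results(hits: Sequence, path: str | Path, regions: Sequence[str] = REGIONS) -> None:
    """Write ranked hits to CSV; row order equals rank order.

    ``hits`` are :class:`abseek.search.SearchHit` objects (typed loosely here to
    keep the IO layer free of engine imports).
    """
    columns = _result_columns(regions)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=columns)
        writer.writeheader()
        for hit in hits:
            row: dict[str, object] = {
                "rank": hit.rank,
                "record_id": hit.record_id,
                "locus": hit.locus or "",
                "total_score": f"{hit.total_score:.6g}",
                "cdr_only_score": f"{hit.cdr_only_score:.6g}",
                "mismatch_total": hit.mismatch_total,
                "mismatch_cdr": hit.mismatch_cdr,
                "v_call": hit.v_call or "",
                "j_call": hit.j_call or "",
                "duplicate_count": (
                    hit.duplicate_count if hit.duplicate_count is not None else ""
                ),
            }
            for region in regions:
                aln = hit.alignments.get(region)
                if aln is None:
                    row[f"{region}_score"] = ""
                    row[f"{region}_offset"] = ""
                    row[f"{region}_match_string"] = ""
                else:
                    row[f"{region}_score"] = f"{aln.score:.6g}"
                    row[f"{region}_offset"] = aln.offset
                    row[f"{region}_match_string"] = aln.match_string
            writer.writerow(row)


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a result CSV back as a DataFrame (round-trip of :func:`write_results`)."""
    return pd.read_csv(path, dtype={"record_id": str}, keep_default_na=False)
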