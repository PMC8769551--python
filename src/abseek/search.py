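"""Ungapped exhaustive alignment of ambiguity-category queries against repertoires.

The query is a per-region (FW1, CDR1, FW2, CDR2, FW3, CDR3) string of category
codes derived from a density map.  Each region is aligned independently and
without gaps against the matching region of every database record: every
register shift within a user bound (default 2 residues) is evaluated, a query
position matches iff the subject residue belongs to its category's member set,
each match contributes the inverse of the member-set size (1/X_i, from 1/20 for
the uninformative root to 1/1 for a confident singleton), mismatches contribute
0, and the register with the maximum score is kept.  Hits are ranked on CDR
length agreement, then total and CDR-only score, then mismatch counts (CDR
mismatches first), with the record identifier as a final deterministic
tie-break.  Light-chain queries searched independently against kappa and lambda
databases are classified by comparing the maximum and mean total scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .categories import CategoryTree
from .io import (
    CDR_REGIONS,
    REGIONS,
    FormatError,
    RegionLengthFilter,
    RepertoireRecord,
    filter_by_region_lengths,
    read_fasta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "StructuralQuery",
    "SearchParams",
    "SegmentAlignment",
    "SearchHit",
    "ChainClassification",
    "align_segment",
    "search_record",
    "search_database",
    "rank_hits",
    "classify_light_chain",
    "search_germline",
    "load_query",
    "write_query",
]

CHAIN_CLASSES = ("heavy", "light_unknown", "kappa", "lambda")


@dataclass(frozen=True)
class StructuralQuery:
    """Per-region category-code strings derived from a density map.

    ``segments`` maps each region to a tuple of category codes; regions not
    resolved in the map may be empty.  ``tree_ref`` names the category tree the
    codes belong to.
    """

    chain_class: str
    segments: Mapping[str, tuple[str, ...]]
    tree_ref: str = "default"

    def __post_init__(self) -> None:
        if self.chain_class not in CHAIN_CLASSES:
            raise ValueError(
                f"chain_class must be one of {CHAIN_CLASSES}, got {self.chain_class!r}"
            )
        unknown = set(self.segments) - set(REGIONS)
        if unknown:
            raise ValueError(f"unknown query regions: {sorted(unknown)}")

    def validate(self, tree: CategoryTree) -> None:
        """Check that every code resolves in ``tree``; raises on failure."""
        for region in REGIONS:
            for code in self.segments.get(region, ()):
                tree.node(code)

    def nonempty_regions(self) -> list[str]:
        return [r for r in REGIONS if self.segments.get(r)]

    def region_lengths(self) -> dict[str, int]:
        return {r: len(self.segments[r]) for r in self.nonempty_regions()}

    def concatenated(self) -> tuple[tuple[str, ...], dict[str, tuple[int, int]]]:
        """All codes in region order, plus each region's [start, end) span."""
        codes: list[str] = []
        spans: dict[str, tuple[int, int]] = {}
        for region in self.nonempty_regions():
            start = len(codes)
            codes.extend(self.segments[region])
            spans[region] = (start, len(codes))
        return tuple(codes), spans

    def total_length(self) -> int:
        return sum(self.region_lengths().values())


@dataclass(frozen=True)
class SearchParams:
    """Knobs of a database search.

    max_shift:
        Register shift allowed per region in regions mode, in residues
        (default 2).
    mode:
        ``regions`` (region-annotated table), ``fasta`` (whole sequences) or
        ``germline`` (allele FASTA; same alignment as fasta, score-only
        ranking).
    length_filter:
        Explicit prefilter; if ``None`` and ``apply_length_filter`` is set, one
        is derived from the query's CDR lengths with the default tolerances.
    """

    max_shift: int = 2
    mode: str = "regions"
    length_filter: RegionLengthFilter | None = None
    apply_length_filter: bool = True

    def __post_init__(self) -> None:
        if self.max_shift < 0:
            raise ValueError("max_shift must be non-negative")
        if self.mode not in ("regions", "fasta", "germline"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class SegmentAlignment:
    """Best ungapped placement of one query region on one subject string.

    ``offset`` is the subject position (0-based, signed) aligned to the first
    query position; query positions falling outside the subject are overhang
    (neither match nor mismatch, score 0) and are excluded from
    ``match_string``.
    """

    region: str
    offset: int
    match_string: str
    score: float
    n_match: int
    n_mismatch: int
    overhang: int

    @property
    def n_compared(self) -> int:
        return self.n_match + self.n_mismatch


@dataclass
class SearchHit:
    """One scored database record with per-region alignments."""

    record_id: str
    alignments: dict[str, SegmentAlignment]
    total_score: float
    cdr_only_score: float
    mismatch_total: int
    mismatch_cdr: int
    n_cdr_length_match: int = 0
    rank: int = 0
    locus: str | None = None
    v_call: str | None = None
    j_call: str | None = None
    duplicate_count: int | None = None


@dataclass(frozen=True)
class ChainClassification:
    """Kappa-vs-lambda verdict from two independent database searches."""

    kappa_max: float | None
    kappa_mean: float | None
    lambda_max: float | None
    lambda_mean: float | None
    decision: str  # kappa | lambda | ambiguous
    n_kappa: int = 0
    n_lambda: int = 0


# -- core alignment -------------------------------------------------------------


def _evaluate_offset(
    tree: CategoryTree,
    codes: Sequence[str],
    subject: str,
    offset: int,
) -> tuple[float, list[str], int, int, int]:
    """Score one register: query position i vs subject position i + offset."""
    score = 0.0
    symbols: list[str] = []
    n_match = n_mismatch = overhang = 0
    n_subject = len(subject)
    for i, code in enumerate(codes):
        j = i + offset
        if j < 0 or j >= n_subject:
            overhang += 1
            continue
        if tree.contains(code, subject[j]):
            score += tree.position_score(code)
            symbols.append("+")
            n_match += 1
        else:
            symbols.append("-")
            n_mismatch += 1
    return score, symbols, n_match, n_mismatch, overhang


def _best_alignment(
    tree: CategoryTree,
    codes: Sequence[str],
    subject: str,
    offsets: Iterable[int],
    region: str,
) -> SegmentAlignment:
    best: SegmentAlignment | None = None
    best_key: tuple | None = None
    for offset in offsets:
        score, symbols, n_match, n_mismatch, overhang = _evaluate_offset(
            tree, codes, subject, offset
        )
        # maximize score; prefer smaller shifts, then fewer mismatches, then
        # the leftmost register -- fully deterministic
        key = (-score, abs(offset), n_mismatch, offset)
        if best_key is None or key < best_key:
            best_key = key
            best = SegmentAlignment(
                region=region,
                offset=offset,
                match_string="".join(symbols),
                score=score,
                n_match=n_match,
                n_mismatch=n_mismatch,
                overhang=overhang,
            )
    assert best is not None
    return best


def align_segment(
    tree: CategoryTree,
    codes: Sequence[str],
    subject: str,
    max_shift: int = 2,
    region: str = "",
) -> SegmentAlignment:
    """Best ungapped alignment of one category-code region to one subject string.

    Every register ``offset`` in ``[-max_shift, +max_shift]`` is evaluated;
    query position ``i`` is compared to subject position ``i + offset``;
    positions falling outside the subject are overhang (score 0, not part of
    the match string).  The register with the maximum score wins.
    """
    if not codes:
        raise ValueError("query region must contain at least one category code")
    subject = subject.upper()
    return _best_alignment(
        tree, codes, subject, range(-max_shift, max_shift + 1), region
    )


def _align_sliding(
    tree: CategoryTree,
    query: StructuralQuery,
    subject: str,
) -> dict[str, SegmentAlignment]:
    """Whole-sequence mode: slide the concatenated query over the subject.

    Every start position with at least one overlapping residue is evaluated;
    the globally best register is then split back into per-region alignments
    (all sharing the same offset) so that region boundaries are preserved in
    the report.
    """
    codes, spans = query.concatenated()
    if not codes:
        raise ValueError("query has no resolved regions")
    subject = subject.upper()
    offsets = range(-(len(codes) - 1), len(subject))
    whole = _best_alignment(tree, codes, subject, offsets, region="")
    offset = whole.offset
    alignments: dict[str, SegmentAlignment] = {}
    for region, (start, end) in spans.items():
        score, symbols, n_match, n_mismatch, overhang = _evaluate_offset(
            tree, codes[start:end], subject, offset + start
        )
        alignments[region] = SegmentAlignment(
            region=region,
            offset=offset + start,
            match_string="".join(symbols),
            score=score,
            n_match=n_match,
            n_mismatch=n_mismatch,
            overhang=overhang,
        )
    return alignments


def _assemble_hit(
    query: StructuralQuery,
    record: RepertoireRecord,
    alignments: dict[str, SegmentAlignment],
    n_cdr_length_match: int,
) -> SearchHit:
    total = sum(a.score for a in alignments.values())
    cdr_only = sum(a.score for r, a in alignments.items() if r in CDR_REGIONS)
    mm_total = sum(a.n_mismatch for a in alignments.values())
    mm_cdr = sum(a.n_mismatch for r, a in alignments.items() if r in CDR_REGIONS)
    return SearchHit(
        record_id=record.record_id,
        alignments=alignments,
        total_score=total,
        cdr_only_score=cdr_only,
        mismatch_total=mm_total,
        mismatch_cdr=mm_cdr,
        n_cdr_length_match=n_cdr_length_match,
        locus=record.locus,
        v_call=record.v_call,
        j_call=record.j_call,
        duplicate_count=record.duplicate_count,
    )


def search_record(
    tree: CategoryTree,
    query: StructuralQuery,
    record: RepertoireRecord,
    params: SearchParams = SearchParams(),
) -> SearchHit:
    """Align every query region against one record and assemble the hit.

    In regions mode each region is aligned independently against the record's
    matching region; a record region missing for a non-empty query region
    scores 0 with full overhang.  In fasta/germline mode the concatenated
    query slides along the full sequence.
    """
    if params.mode == "regions":
        alignments: dict[str, SegmentAlignment] = {}
        n_len_match = 0
        for region in query.nonempty_regions():
            codes = query.segments[region]
            subject = record.region(region)
            if subject is None:
                logger.debug(
                    "record %s lacks region %s; scored 0", record.record_id, region
                )
                alignments[region] = SegmentAlignment(
                    region=region,
                    offset=0,
                    match_string="",
                    score=0.0,
                    n_match=0,
                    n_mismatch=0,
                    overhang=len(codes),
                )
                continue
            alignments[region] = align_segment(
                tree, codes, subject, params.max_shift, region
            )
            if region in CDR_REGIONS and len(subject) == len(codes):
                n_len_match += 1
        return _assemble_hit(query, record, alignments, n_len_match)

    if record.full_sequence is None:
        raise ValueError(
            f"record {record.record_id!r} has no full sequence for {params.mode} mode"
        )
    alignments = _align_sliding(tree, query, record.full_sequence)
    # full-sequence mode has no region annotations; count CDR regions whose
    # best placement is fully covered by the subject as the length-agreement
    # analog used by the ranking
    n_len_match = sum(
        1
        for r, a in alignments.items()
        if r in CDR_REGIONS and a.overhang == 0
    )
    return _assemble_hit(query, record, alignments, n_len_match)


def rank_hits(hits: Sequence[SearchHit]) -> list[SearchHit]:
    """Deterministic ranking: CDR length agreement, scores, mismatches, id.

    Sort key, in order: number of CDR regions whose length matches the query
    (descending), total score (descending), CDR-only score (descending), CDR
    mismatches (ascending), total mismatches (ascending), record id.
    """
    ordered = sorted(
        hits,
        key=lambda h: (
            -h.n_cdr_length_match,
            -h.total_score,
            -h.cdr_only_score,
            h.mismatch_cdr,
            h.mismatch_total,
            h.record_id,
        ),
    )
    for i, hit in enumerate(ordered, start=1):
        hit.rank = i
    return ordered


def _effective_length_filter(
    query: StructuralQuery, params: SearchParams
) -> RegionLengthFilter | None:
    if params.mode != "regions" or not params.apply_length_filter:
        return None
    if params.length_filter is not None:
        return params.length_filter
    lengths = query.region_lengths()
    participating = tuple(r for r in CDR_REGIONS if r in lengths)
    if not participating:
        return None
    return RegionLengthFilter.from_query_lengths(lengths, participating)


def search_database(
    tree: CategoryTree,
    query: StructuralQuery,
    records: Sequence[RepertoireRecord],
    params: SearchParams = SearchParams(),
    run_log: dict | None = None,
) -> list[SearchHit]:
    """Prefilter, exhaustively score, and rank every record of a database.

    Deterministic for fixed inputs.  ``run_log``, if given, is filled with the
    scanned/filtered counts and the effective parameters.
    """
    query.validate(tree)
    n_scanned = len(records)
    length_filter = _effective_length_filter(query, params)
    if length_filter is not None:
        records = filter_by_region_lengths(records, length_filter)
    if run_log is not None:
        run_log.update(
            {
                "mode": params.mode,
                "max_shift": params.max_shift,
                "records_scanned": n_scanned,
                "records_after_length_filter": len(records),
                "length_filter": (
                    {
                        "targets": dict(length_filter.targets),
                        "tolerances": {
                            r: length_filter.tolerance(r)
                            for r in length_filter.participating
                        },
                    }
                    if length_filter is not None
                    else None
                ),
            }
        )
    if not records:
        logger.warning("database empty after filtering; returning no hits")
        return []
    hits = [search_record(tree, query, rec, params) for rec in records]
    return rank_hits(hits)


def classify_light_chain(
    tree: CategoryTree,
    query: StructuralQuery,
    kappa_records: Sequence[RepertoireRecord],
    lambda_records: Sequence[RepertoireRecord],
    params: SearchParams = SearchParams(),
) -> ChainClassification:
    """Decide kappa vs lambda from two independent searches.

    The decision goes to the database that wins on BOTH the maximum and the
    mean total score; a split or tied verdict is reported as ambiguous, as is
    an empty database after filtering.
    """
    kappa_hits = search_database(tree, query, kappa_records, params)
    lambda_hits = search_database(tree, query, lambda_records, params)

    def _stats(hits: Sequence[SearchHit]) -> tuple[float | None, float | None]:
        if not hits:
            return None, None
        scores = [h.total_score for h in hits]
        return max(scores), sum(scores) / len(scores)

    k_max, k_mean = _stats(kappa_hits)
    l_max, l_mean = _stats(lambda_hits)
    if k_max is None or l_max is None:
        logger.warning("a light-chain database is empty after filtering")
        decision = "ambiguous"
    elif k_max > l_max and k_mean > l_mean:
        decision = "kappa"
    elif l_max > k_max and l_mean > k_mean:
        decision = "lambda"
    else:
        decision = "ambiguous"
    return ChainClassification(
        kappa_max=k_max,
        kappa_mean=k_mean,
        lambda_max=l_max,
        lambda_mean=l_mean,
        decision=decision,
        n_kappa=len(kappa_hits),
        n_lambda=len(lambda_hits),
    )


def search_germline(
    tree: CategoryTree,
    query: StructuralQuery,
    germline: str | Path | Sequence[RepertoireRecord],
) -> list[SearchHit]:
    """Search a germline allele FASTA; whole-sequence alignment, score ranking.

    Germline hits are ranked by total score only (record id as tie-break) --
    allele databases carry no CDR annotations or mismatch semantics beyond the
    raw alignment.
    """
    if isinstance(germline, (str, Path)):
        records = read_fasta(germline)
    else:
        records = list(germline)
    params = SearchParams(mode="germline", apply_length_filter=False)
    hits = [search_record(tree, query, rec, params) for rec in records]
    hits.sort(key=lambda h: (-h.total_score, h.record_id))
    for i, hit in enumerate(hits, start=1):
        hit.rank = i
    return hits


# -- query file ------------------------------------------------------------------
#
# YAML with fields chain_class, tree, and a segments mapping of region name to a
# whitespace-separated string of category codes.  Omitted regions are allowed.


def load_query(path: str | Path) -> StructuralQuery:
    """Read a structural query file (see module docs for the format)."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise FormatError(f"{path}: not valid query syntax: {exc}") from None
    if not isinstance(data, dict):
        raise FormatError(f"{path}: query file must be a mapping")
    chain_class = data.get("chain_class", "light_unknown")
    tree_ref = data.get("tree", "default")
    raw_segments = data.get("segments", {})
    if not isinstance(raw_segments, dict) or not raw_segments:
        raise FormatError(f"{path}: query file must define a non-empty 'segments' map")
    segments: dict[str, tuple[str, ...]] = {}
    for region, value in raw_segments.items():
        if region not in REGIONS:
            raise FormatError(f"{path}: unknown region {region!r}")
        if value is None:
            continue
        codes = tuple(str(value).split())
        if codes:
            segments[region] = codes
    return StructuralQuery(
        chain_class=str(chain_class), segments=segments, tree_ref=str(tree_ref)
    )


def write_query(query: StructuralQuery, path: str | Path) -> None:
    """Serialize a query in the format :func:`load_query` reads."""
    data = {
        "chain_class": query.chain_class,
        "tree": query.tree_ref,
        "segments": {
            region: " ".join(query.segments[region])
            for region in query.nonempty_regions()
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)
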