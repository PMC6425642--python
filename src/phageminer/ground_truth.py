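"""Three-category labeling of metagenomic contigs from phageome alignments.

A metagenomic contig that aligns well to the paired phageome assembly of the
same subject is, by construction, phage-derived: the phageome library was
sequenced from purified phage particles.  Alignments are first filtered
(e-value < 1e-5, identity > 98%), merged per contig pair, and the contig is
labeled:

* ``phage`` — some phageome contig pair has coverage > 0.80 of the shorter
  contig, or a merged aligned length > 10 kb;
* ``ambiguous`` — otherwise, some pair has coverage in [0.40, 0.80] or a
  merged aligned length in [4 kb, 10 kb];
* ``non_phage`` — no pair qualifies.

Coverage is the union of query-side alignment intervals divided by the
length of the shorter of the two contigs.  Any single pair may satisfy a
criterion; evidence is never summed across phageome contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .core_io import AlignmentRecord

EVALUE_MAX = 1e-5
IDENTITY_MIN = 98.0

PHAGE_COVERAGE = 0.80
PHAGE_ALN_LENGTH = 10_000
AMBIG_COVERAGE_LO = 0.40
AMBIG_ALN_LO = 4_000


class Label(str, Enum):
    PHAGE = "phage"
    AMBIGUOUS = "ambiguous"
    NON_PHAGE = "non_phage"


@dataclass(frozen=True)
class PairEvidence:
    """Merged alignment evidence for one (metagenome, phageome) contig pair."""

    meta_contig_id: str
    phage_contig_id: str
    merged_aligned_length: int
    coverage: float


@dataclass(frozen=True)
class ContigLabel:
    contig_id: str
    label: Label
    best_evidence: PairEvidence | None = None


def filter_alignments(
    records: Iterable[AlignmentRecord],
    evalue_max: float = EVALUE_MAX,
    identity_min: float = IDENTITY_MIN,
) -> list[AlignmentRecord]:
    """Keep records with e-value strictly below ``evalue_max`` and identity
    strictly above ``identity_min`` (both boundaries exclusive)."""
    return [
        r
        for r in records
        if r.evalue < evalue_max and r.identity_pct > identity_min
    ]


def _union_length(intervals: Sequence[tuple[int, int]]) -> int:
    """Total bp covered by the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    merged_len = 0
    cur_start, cur_end = None, None
    for start, end in sorted(intervals):
        if cur_end is None:
            cur_start, cur_end = start, end
        elif start <= cur_end + 1:
            cur_end = max(cur_end, end)
        else:
            merged_len += cur_end - cur_start + 1
            cur_start, cur_end = start, end
    merged_len += cur_end - cur_start + 1
    return merged_len


def merge_pair_evidence(
    records: Sequence[AlignmentRecord],
    contig_lengths: Mapping[str, int],
) -> PairEvidence:
    """Collapse all HSPs of one contig pair into a single evidence record.

    The merged aligned length is the union of query-side intervals, so
    overlapping HSPs are not double-counted.  Coverage divides by the length
    of the shorter contig and is capped at 1.
    """
    if not records:
        raise ValueError("merge_pair_evidence requires at least one record")
    query_id = records[0].query_id
    subject_id = records[0].subject_id
    for r in records:
        if r.query_id != query_id or r.subject_id != subject_id:
            raise ValueError("all records must share the same contig pair")
    for cid in (query_id, subject_id):
        if cid not in contig_lengths:
            raise KeyError(f"missing length for contig {cid!r}")
    merged = _union_length([(r.q_start, r.q_end) for r in records])
    shorter = min(contig_lengths[query_id], contig_lengths[subject_id])
    merged = min(merged, shorter)
    return PairEvidence(
        meta_contig_id=query_id,
        phage_contig_id=subject_id,
        merged_aligned_length=merged,
        coverage=merged / shorter,
    )


def assign_label(
    contig_id: str, evidence: Sequence[PairEvidence]
) -> ContigLabel:
    """Label one metagenomic contig from all of its pair evidence.

    Thresholds for ``phage`` are strict (> 0.80 coverage, > 10 kb); the
    ``ambiguous`` bands are inclusive on both ends ([0.40, 0.80] and
    [4 kb, 10 kb]), so coverage exactly 0.80 is ambiguous, not phage.
    """
    best = None
    if evidence:
        best = max(evidence, key=lambda e: (e.coverage, e.merged_aligned_length))
    for e in evidence:
        if e.coverage > PHAGE_COVERAGE or e.merged_aligned_length > PHAGE_ALN_LENGTH:
            return ContigLabel(contig_id, Label.PHAGE, best)
    for e in evidence:
        if (
            AMBIG_COVERAGE_LO <= e.coverage <= PHAGE_COVERAGE
            or AMBIG_ALN_LO <= e.merged_aligned_length <= PHAGE_ALN_LENGTH
        ):
            return ContigLabel(contig_id, Label.AMBIGUOUS, best)
    return ContigLabel(contig_id, Label.NON_PHAGE, best)


def label_contigs(
    records: Iterable[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    meta_contig_ids: Iterable[str],
    evalue_max: float = EVALUE_MAX,
    identity_min: float = IDENTITY_MIN,
) -> dict[str, ContigLabel]:
    """Run the full labeling pipeline: filter, merge per pair, assign.

    ``meta_contig_ids`` enumerates every metagenomic contig so that contigs
    with no qualifying alignment still receive a ``non_phage`` label.
    """
    kept = filter_alignments(records, evalue_max, identity_min)
    by_pair: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for r in kept:
        by_pair.setdefault((r.query_id, r.subject_id), []).append(r)
    evidence_by_contig: dict[str, list[PairEvidence]] = {}
    for (query_id, _), pair_records in by_pair.items():
        ev = merge_pair_evidence(pair_records, contig_lengths)
        evidence_by_contig.setdefault(query_id, []).append(ev)
    return {
        cid: assign_label(cid, evidence_by_contig.get(cid, []))
        for cid in meta_contig_ids
    }
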