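"""Virus quotients and taxon-signature calls for phage orthologous groups.

A phage orthologous group (POG) is a cluster of orthologous phage proteins.
Its virus quotient (VQ) is the fraction of the genomes it matches that are
viral, VQ = |viral genomes| / (|viral genomes| + |prokaryotic genomes|),
with prokaryotic genomes carrying known prophage regions excluded from the
denominator (their matches would otherwise inflate the prokaryotic side
with sequence that is itself viral).  Matches are counted at genome
granularity — a genome counts once no matter how many of its proteins hit
the group — so paralogs are not double-counted.  Groups with VQ strictly
above 0.85 are called virus-specific.

A taxon-signature POG marks the presence of one taxon: it occurs in (nearly
all) genomes of that taxon and nowhere else, in a single copy.  The calling
criteria are 100% precision, recall > 0.85, VQ > 0.85, and single copy per
genome.

Match tables are pre-filtered homology searches: a match qualifies at
e-value <= 0.001, bit score > 40, and an aligned region of >= 40 amino
acids.  Group construction itself (COG-style clustering) is an input, not
performed here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core_io import AlignmentRecord

VQ_VIRUS_SPECIFIC = 0.85  # strict >
SIGNATURE_RECALL_MIN = 0.85  # strict >
MATCH_EVALUE_MAX = 0.001  # inclusive
MATCH_BITSCORE_MIN = 40.0  # strict >
MATCH_ALN_AA_MIN = 40  # inclusive


@dataclass(frozen=True)
class PogRecord:
    pog_id: str
    viral_genome_matches: frozenset[str]
    prokaryotic_genome_matches: frozenset[str]
    vq: float
    virus_specific: bool
    copies_per_genome: dict[str, int] | None = None


@dataclass(frozen=True)
class TaxonSignatureResult:
    pog_id: str
    taxon: str
    precision: float
    recall: float
    single_copy: bool
    vq: float
    is_signature: bool


def filter_matches(
    records: Iterable[AlignmentRecord],
    evalue_max: float = MATCH_EVALUE_MAX,
    bit_score_min: float = MATCH_BITSCORE_MIN,
    aln_aa_min: int = MATCH_ALN_AA_MIN,
) -> list[AlignmentRecord]:
    """Retain matches with evalue <= 0.001, bit score > 40 and an aligned
    region of at least 40 amino acids."""
    return [
        r
        for r in records
        if r.evalue <= evalue_max
        and r.bit_score > bit_score_min
        and r.aln_length >= aln_aa_min
    ]


def compute_vq(
    viral_genomes: Iterable[str],
    prokaryotic_genomes: Iterable[str],
    excluded_genomes: Iterable[str] = (),
) -> float:
    """Virus quotient from matched genome id sets.

    Prokaryotic genomes on the exclusion list (prophage carriers) are
    dropped before the ratio.  Raises ``ValueError`` when no genome on
    either side remains (undefined VQ).
    """
    viral = set(viral_genomes)
    prok = set(prokaryotic_genomes) - set(excluded_genomes)
    total = len(viral) + len(prok)
    if total == 0:
        raise ValueError("VQ undefined: no genome matches on either side")
    return len(viral) / total


def build_pog_record(
    pog_id: str,
    viral_genomes: Iterable[str],
    prokaryotic_genomes: Iterable[str],
    excluded_genomes: Iterable[str] = (),
    copies_per_genome: Mapping[str, int] | None = None,
) -> PogRecord:
    viral = frozenset(viral_genomes)
    prok = frozenset(set(prokaryotic_genomes) - set(excluded_genomes))
    vq = compute_vq(viral, prok)
    return PogRecord(
        pog_id=pog_id,
        viral_genome_matches=viral,
        prokaryotic_genome_matches=prok,
        vq=vq,
        virus_specific=vq > VQ_VIRUS_SPECIFIC,
        copies_per_genome=dict(copies_per_genome) if copies_per_genome else None,
    )


def taxon_signature(
    pog: PogRecord,
    genome_taxonomy: Mapping[str, str],
    taxon: str,
) -> TaxonSignatureResult:
    """Evaluate one POG as a signature marker for one taxon.

    Precision: fraction of the POG's containing genomes that belong to the
    taxon (exact set membership — no tolerance).  Recall: fraction of the
    taxon's genomes that contain the POG.  Single-copy: every containing
    genome holds exactly one copy.  Containing genomes are the viral genome
    matches; ``copies_per_genome`` defaults to single copy when absent.
    """
    taxon_genomes = {g for g, t in genome_taxonomy.items() if t == taxon}
    if not taxon_genomes:
        raise ValueError(f"taxon {taxon!r} has no genomes in the taxonomy table")
    containing = pog.viral_genome_matches
    if not containing:
        precision, recall = 0.0, 0.0
    else:
        in_taxon = containing & taxon_genomes
        precision = len(in_taxon) / len(containing)
        recall = len(in_taxon) / len(taxon_genomes)
    copies = pog.copies_per_genome or {}
    single_copy = all(copies.get(g, 1) == 1 for g in containing)
    is_signature = (
        precision == 1.0
        and recall > SIGNATURE_RECALL_MIN
        and pog.vq > VQ_VIRUS_SPECIFIC
        and single_copy
        and bool(containing)
    )
    return TaxonSignatureResult(
        pog_id=pog.pog_id,
        taxon=taxon,
        precision=precision,
        recall=recall,
        single_copy=single_copy,
        vq=pog.vq,
        is_signature=is_signature,
    )


def records_from_match_table(
    records: Sequence[AlignmentRecord],
    viral_genome_ids: Iterable[str],
    prokaryotic_genome_ids: Iterable[str],
    excluded_genomes: Iterable[str] = (),
    prefiltered: bool = False,
) -> list[PogRecord]:
    """Build PogRecords from a POG-vs-genome match table.

    Each alignment row maps a POG (query) to a genome (subject).  Rows are
    threshold-filtered first unless ``prefiltered``.  Copies per genome are
    taken as the number of qualifying rows for the (POG, genome) pair.
    """
    viral_ids = set(viral_genome_ids)
    prok_ids = set(prokaryotic_genome_ids)
    if not prefiltered:
        records = filter_matches(records)
    by_pog: dict[str, dict[str, int]] = {}
    for r in records:
        if r.subject_id not in viral_ids and r.subject_id not in prok_ids:
            raise KeyError(f"genome {r.subject_id!r} is neither viral nor prokaryotic")
        counts = by_pog.setdefault(r.query_id, {})
        counts[r.subject_id] = counts.get(r.subject_id, 0) + 1
    out = []
    for pog_id in sorted(by_pog):
        counts = by_pog[pog_id]
        out.append(
            build_pog_record(
                pog_id,
                viral_genomes=[g for g in counts if g in viral_ids],
                prokaryotic_genomes=[g for g in counts if g in prok_ids],
                excluded_genomes=excluded_genomes,
                copies_per_genome={g: n for g, n in counts.items() if g in viral_ids},
            )
        )
    return out
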