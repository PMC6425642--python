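"""Per-contig predictor vectors for the phage classifier.

Ten predictors per contig: average read depth; the number of predicted
genes; the number of genes with hits to phage orthologous groups, viral
protein families, KO terms, Pfam domains, and viral hallmark genes; and the
fraction of genes annotated to viral protein families, KO, and Pfam.
Annotation hits qualify at e-value <= 1e-5, and each gene counts once per
database regardless of hit multiplicity.  Only contigs strictly longer than
the length cutoff (default 5 kb) enter the model; shorter cutoffs (1 kb,
3 kb) are supported for sensitivity analyses and only change which contigs
appear, never any feature value.

Percentage features are stored as fractions in [0, 1] rather than 0-100:
unit-free fractions are scale-invariant for tree models.  Contigs with zero
predicted genes keep all count and percentage features at 0 and are
retained — depth is still informative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import AnnotationHit, Contig, GeneCall, MappingSummary

ANNOTATION_EVALUE_MAX = 1e-5
MIN_CONTIG_LENGTH = 5_000  # strict >: a 5,000 bp contig is excluded

FEATURE_NAMES = (
    "f1_avg_depth",
    "f2_n_genes",
    "f3_n_upog",
    "f4_n_viral_family",
    "f5_pct_viral_family",
    "f6_n_ko",
    "f7_pct_ko",
    "f8_n_pfam",
    "f9_pct_pfam",
    "f10_n_hallmark",
)


@dataclass(frozen=True)
class ContigFeatureVector:
    contig_id: str
    f1_avg_depth: float
    f2_n_genes: int
    f3_n_upog: int
    f4_n_viral_family: int
    f5_pct_viral_family: float
    f6_n_ko: int
    f7_pct_ko: float
    f8_n_pfam: int
    f9_pct_pfam: float
    f10_n_hallmark: int

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, name) for name in FEATURE_NAMES)


def count_annotated_genes(
    gene_ids: Iterable[str],
    hits: Iterable[AnnotationHit],
    database_tag: str,
    evalue_max: float = ANNOTATION_EVALUE_MAX,
    known_genes: set[str] | None = None,
) -> int:
    """Number of distinct genes (among ``gene_ids``) with at least one hit in
    ``database_tag`` at e-value <= ``evalue_max`` (inclusive boundary).

    A hit referencing a gene absent from ``known_genes`` (when given) is an
    inconsistent input and raises ``KeyError``.
    """
    gene_set = set(gene_ids)
    annotated: set[str] = set()
    for h in hits:
        if h.database != database_tag or h.evalue > evalue_max:
            continue
        if known_genes is not None and h.gene_id not in known_genes:
            raise KeyError(
                f"annotation hit references unknown gene {h.gene_id!r}"
            )
        if h.gene_id in gene_set:
            annotated.add(h.gene_id)
    return len(annotated)


def extract_features(
    contig: Contig,
    gene_calls: Sequence[GeneCall],
    hits: Sequence[AnnotationHit],
    mapping: MappingSummary | None,
    min_length: int = MIN_CONTIG_LENGTH,
    evalue_max: float = ANNOTATION_EVALUE_MAX,
) -> ContigFeatureVector | None:
    """Build the 10-value predictor vector for one contig.

    Returns ``None`` when the contig is at or below ``min_length`` (strict
    ``>`` cutoff).  Raises ``ValueError`` when the mapping summary is
    missing for a retained contig.
    """
    if contig.length <= min_length:
        return None
    if mapping is None:
        raise ValueError(f"contig {contig.id!r}: missing mapping summary")
    genes = [g for g in gene_calls if g.contig_id == contig.id]
    gene_ids = {g.gene_id for g in genes}
    n_genes = len(genes)

    def count(tag: str) -> int:
        return count_annotated_genes(gene_ids, hits, tag, evalue_max)

    n_upog = count("uPOG")
    n_vf = count("viral_family")
    n_ko = count("KO")
    n_pfam = count("Pfam")
    n_hallmark = count("hallmark")
    frac = (lambda n: n / n_genes) if n_genes > 0 else (lambda n: 0.0)
    return ContigFeatureVector(
        contig_id=contig.id,
        f1_avg_depth=mapping.depth,
        f2_n_genes=n_genes,
        f3_n_upog=n_upog,
        f4_n_viral_family=n_vf,
        f5_pct_viral_family=frac(n_vf),
        f6_n_ko=n_ko,
        f7_pct_ko=frac(n_ko),
        f8_n_pfam=n_pfam,
        f9_pct_pfam=frac(n_pfam),
        f10_n_hallmark=n_hallmark,
    )


def build_feature_table(
    contigs: Sequence[Contig],
    gene_calls: Sequence[GeneCall],
    hits: Sequence[AnnotationHit],
    mappings: Mapping[str, MappingSummary],
    min_length: int = MIN_CONTIG_LENGTH,
    evalue_max: float = ANNOTATION_EVALUE_MAX,
) -> pd.DataFrame:
    """Feature vectors for every retained contig as a DataFrame indexed by
    contig id, with the 10 named feature columns."""
    genes_by_contig: dict[str, list[GeneCall]] = {}
    for g in gene_calls:
        genes_by_contig.setdefault(g.contig_id, []).append(g)
    gene_contig = {g.gene_id: g.contig_id for g in gene_calls}
    hits_by_contig: dict[str, list[AnnotationHit]] = {}
    for h in hits:
        cid = gene_contig.get(h.gene_id)
        if cid is None:
            raise KeyError(f"annotation hit references unknown gene {h.gene_id!r}")
        hits_by_contig.setdefault(cid, []).append(h)

    rows = []
    for contig in contigs:
        if contig.length <= min_length:
            continue
        vec = extract_features(
            contig,
            genes_by_contig.get(contig.id, []),
            hits_by_contig.get(contig.id, []),
            mappings.get(contig.id),
            min_length=min_length,
            evalue_max=evalue_max,
        )
        rows.append((vec.contig_id,) + vec.as_tuple())
    df = pd.DataFrame(rows, columns=("contig_id",) + FEATURE_NAMES)
    return df.set_index("contig_id")
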