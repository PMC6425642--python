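"""Seeded generator of a complete synthetic phage-mining study.

The generator emulates the structure of a paired metagenome/phageome cohort:
subjects sampled at several timepoints, each sample assembled into contigs
of which roughly 2% are phage.  Phage and bacterial contigs differ in their
annotation-hit profiles (phage contigs are enriched for phage orthologous
groups, viral protein families and hallmark genes; bacterial contigs for KO
and Pfam), read counts follow a lognormal abundance distribution, and the
phage fraction is echoed into a paired phageome assembly whose alignments
back to the metagenome drive the three-category labeling.  A small fraction
of bacterial contigs carry prophage-like regions that align partially
(40-80% coverage) and therefore label as ambiguous.

What it deliberately does not emulate: read-level sequencing error,
assembly fragmentation or chimerism, shared phage content across subjects,
or realistic phage gene architecture — contig sequences (when requested)
are i.i.d. random DNA except for planted CRISPR arrays and protospacers.

Three difficulty presets scale the annotation-rate gap between classes:
``easy`` (well separated, full phageome recovery), ``medium``, ``hard``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import core_io
from .core_io import (
    AlignmentRecord,
    AnnotationHit,
    Contig,
    GeneCall,
    MappingSummary,
)
from .crispr_host import CrisprParams

DATABASES = core_io.DATABASE_TAGS

# per-gene probability of a qualifying annotation hit, per database
EASY_RATES = {
    "phage": {"KO": 0.10, "Pfam": 0.25, "uPOG": 0.60, "viral_family": 0.50, "hallmark": 0.25},
    "bacterial": {"KO": 0.60, "Pfam": 0.70, "uPOG": 0.03, "viral_family": 0.01, "hallmark": 0.002},
}


def _blend(a: Mapping[str, float], b: Mapping[str, float], w: float) -> dict[str, float]:
    return {k: (1 - w) * a[k] + w * b[k] for k in a}


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 10
    n_samples_per_subject: int = 6
    n_contigs_per_sample: int = 100
    phage_fraction: float = 0.02
    prophage_fraction: float = 0.01  # bacterial contigs with partial phage homology
    length_log_mean: float = np.log(12_000.0)
    length_log_sigma: float = 0.6
    length_min: int = 5_200
    length_max: int = 120_000
    abundance_log_sigma: float = 1.5
    total_reads_per_sample: int = 1_000_000
    equal_reads: bool = False  # equal mapped reads per contig (weights cancel)
    annotation_rates: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in EASY_RATES.items()}
    )
    nonqualifying_hit_rate: float = 0.05  # hits above the e-value cutoff
    gene_length_mean: int = 900
    gene_spacing: int = 100
    phageome_recovery: float = 1.0  # fraction of phage contigs echoed into the phageome
    recovery_coverage_min: float = 0.85  # phageome alignment coverage range
    recovery_coverage_max: float = 1.0
    rng_seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.phage_fraction < 1:
            raise ValueError("phage_fraction must be in (0, 1)")
        if self.phage_fraction * self.n_contigs_per_sample < 1:
            raise ValueError(
                "infeasible config: fewer than one expected phage contig per sample"
            )


def preset(name: str, **overrides) -> SimConfig:
    """Named difficulty presets scaling the phage/bacterial annotation gap."""
    if name == "easy":
        cfg = SimConfig()
    elif name == "medium":
        rates = {
            "phage": _blend(EASY_RATES["phage"], EASY_RATES["bacterial"], 0.3),
            "bacterial": _blend(EASY_RATES["bacterial"], EASY_RATES["phage"], 0.3),
        }
        cfg = SimConfig(annotation_rates=rates, phageome_recovery=0.9)
    elif name == "hard":
        rates = {
            "phage": _blend(EASY_RATES["phage"], EASY_RATES["bacterial"], 0.45),
            "bacterial": _blend(EASY_RATES["bacterial"], EASY_RATES["phage"], 0.45),
        }
        cfg = SimConfig(annotation_rates=rates, phageome_recovery=0.8)
    else:
        raise ValueError(f"unknown preset {name!r}")
    return replace(cfg, **overrides)


@dataclass
class StudyBundle:
    """Everything a downstream analysis needs, in memory.

    ``truth`` has one row per metagenomic contig: contig_id, sample_id,
    subject_id, true_class (phage / bacterial / prophage), length,
    mapped_reads.
    """

    config: SimConfig
    contigs: list[Contig]
    phageome_contigs: list[Contig]
    gene_calls: list[GeneCall]
    hits: list[AnnotationHit]
    mappings: dict[str, MappingSummary]
    alignments: list[AlignmentRecord]
    truth: pd.DataFrame

    @property
    def contig_lengths(self) -> dict[str, int]:
        lengths = {c.id: c.length for c in self.contigs}
        lengths.update({c.id: c.length for c in self.phageome_contigs})
        return lengths

    @property
    def subjects(self) -> dict[str, str]:
        return dict(zip(self.truth["contig_id"], self.truth["subject_id"]))

    def write(self, out_dir: str | Path) -> None:
        """Emit every table in its core_io format plus the truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "contigs.tsv", "wt") as fh:
            for c in self.contigs:
                fh.write(f"{c.id}\t{c.sample_id}\t{c.length}\n")
        with open(out / "phageome_contigs.tsv", "wt") as fh:
            for c in self.phageome_contigs:
                fh.write(f"{c.id}\t{c.sample_id}\t{c.length}\n")
        core_io.write_gene_table(self.gene_calls, out / "genes.tsv")
        core_io.write_alignment_table(self.alignments, out / "meta_vs_phageome.tsv")
        core_io.write_mapping_counts(self.mappings.values(), out / "mapping.tsv")
        for tag in DATABASES:
            rows = [
                AlignmentRecord(
                    query_id=h.gene_id,
                    subject_id=h.subject_id,
                    identity_pct=h.identity_pct,
                    aln_length=h.aln_length,
                    mismatches=0,
                    gap_opens=0,
                    q_start=1,
                    q_end=h.aln_length,
                    s_start=1,
                    s_end=h.aln_length,
                    evalue=h.evalue,
                    bit_score=h.bit_score,
                )
                for h in self.hits
                if h.database == tag
            ]
            core_io.write_alignment_table(rows, out / f"hits_{tag}.tsv")
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
        with open(out / "sample_totals.tsv", "wt") as fh:
            totals = {
                m.sample_id: m.total_reads_in_sample for m in self.mappings.values()
            }
            for sample, total in sorted(totals.items()):
                fh.write(f"{sample}\t{total}\n")


def _draw_length(rng: np.random.Generator, cfg: SimConfig) -> int:
    raw = rng.lognormal(cfg.length_log_mean, cfg.length_log_sigma)
    return int(np.clip(raw, cfg.length_min, cfg.length_max))


def _make_genes(
    rng: np.random.Generator, contig_id: str, length: int, cfg: SimConfig
) -> list[GeneCall]:
    genes = []
    pos = 1 + int(rng.integers(0, cfg.gene_spacing + 1))
    i = 0
    while True:
        glen = max(150, int(rng.normal(cfg.gene_length_mean, 200)))
        end = pos + glen - 1
        if end > length:
            break
        genes.append(
            GeneCall(
                gene_id=f"{contig_id}_g{i}",
                contig_id=contig_id,
                start=pos,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        pos = end + 1 + int(rng.integers(0, cfg.gene_spacing + 1))
        i += 1
    return genes


def _make_hits(
    rng: np.random.Generator,
    genes: Sequence[GeneCall],
    true_class: str,
    cfg: SimConfig,
) -> list[AnnotationHit]:
    rate_class = "phage" if true_class == "phage" else "bacterial"
    rates = cfg.annotation_rates[rate_class]
    if true_class == "prophage":  # intermediate profile
        rates = _blend(cfg.annotation_rates["bacterial"], cfg.annotation_rates["phage"], 0.5)
    hits = []
    for g in genes:
        for tag in DATABASES:
            if rng.random() < rates[tag]:
                evalue = 10.0 ** (-float(rng.uniform(6, 30)))
            elif rng.random() < cfg.nonqualifying_hit_rate:
                evalue = 10.0 ** (-float(rng.uniform(1, 4.5)))  # fails the 1e-5 cutoff
            else:
                continue
            hits.append(
                AnnotationHit(
                    gene_id=g.gene_id,
                    database=tag,
                    subject_id=f"{tag}_{int(rng.integers(0, 5000)):05d}",
                    evalue=evalue,
                    bit_score=float(rng.uniform(50, 500)),
                    identity_pct=float(rng.uniform(40, 100)),
                    aln_length=int(rng.integers(40, 400)),
                )
            )
    return hits


def generate_study(config: SimConfig) -> StudyBundle:
    """Generate the full synthetic study; deterministic under the seed."""
    rng = np.random.default_rng(config.rng_seed)
    contigs: list[Contig] = []
    phageome: list[Contig] = []
    genes: list[GeneCall] = []
    hits: list[AnnotationHit] = []
    mappings: dict[str, MappingSummary] = {}
    alignments: list[AlignmentRecord] = []
    truth_rows = []

    for s in range(config.n_subjects):
        subject = f"S{s + 1:02d}"
        for t in range(config.n_samples_per_subject):
            sample = f"{subject}T{t + 1}"
            n = config.n_contigs_per_sample
            classes = np.full(n, "bacterial", dtype=object)
            u = rng.random(n)
            classes[u < config.phage_fraction] = "phage"
            classes[
                (u >= config.phage_fraction)
                & (u < config.phage_fraction + config.prophage_fraction)
            ] = "prophage"
            if not (classes == "phage").any():  # feasibility floor
                classes[int(rng.integers(0, n))] = "phage"

            lengths = [_draw_length(rng, config) for _ in range(n)]
            if config.equal_reads:
                weights = np.ones(n)
            else:
                weights = rng.lognormal(0.0, config.abundance_log_sigma, n)
            reads = np.floor(
                config.total_reads_per_sample * weights / weights.sum()
            ).astype(int)

            for i in range(n):
                cid = f"{sample}_c{i:04d}"
                contigs.append(Contig(id=cid, sample_id=sample, length=lengths[i]))
                contig_genes = _make_genes(rng, cid, lengths[i], config)
                genes.extend(contig_genes)
                hits.extend(_make_hits(rng, contig_genes, classes[i], config))
                mappings[cid] = MappingSummary.from_counts(
                    contig_id=cid,
                    sample_id=sample,
                    mapped_reads=int(reads[i]),
                    total_reads_in_sample=config.total_reads_per_sample,
                    contig_length=lengths[i],
                )
                truth_rows.append(
                    (cid, sample, subject, classes[i], lengths[i], int(reads[i]))
                )

                # phageome echo + alignment evidence
                if classes[i] == "phage" and rng.random() < config.phageome_recovery:
                    pid = f"{sample}_p{i:04d}"
                    phageome.append(
                        Contig(id=pid, sample_id=sample, length=lengths[i])
                    )
                    cov = float(
                        rng.uniform(
                            config.recovery_coverage_min, config.recovery_coverage_max
                        )
                    )
                    aln_len = max(1, int(cov * lengths[i]))
                    alignments.append(
                        AlignmentRecord(
                            query_id=cid,
                            subject_id=pid,
                            identity_pct=float(rng.uniform(98.5, 100.0)),
                            aln_length=aln_len,
                            mismatches=0,
                            gap_opens=0,
                            q_start=1,
                            q_end=aln_len,
                            s_start=1,
                            s_end=aln_len,
                            evalue=0.0,
                            bit_score=2 * aln_len,
                        )
                    )
                elif classes[i] == "prophage":
                    pid = f"{sample}_p{i:04d}"
                    phageome.append(
                        Contig(id=pid, sample_id=sample, length=lengths[i])
                    )
                    cov = float(rng.uniform(0.45, 0.75))
                    aln_len = min(int(cov * lengths[i]), 9_999)
                    cov = aln_len / lengths[i]
                    alignments.append(
                        AlignmentRecord(
                            query_id=cid,
                            subject_id=pid,
                            identity_pct=float(rng.uniform(98.5, 100.0)),
                            aln_length=aln_len,
                            mismatches=0,
                            gap_opens=0,
                            q_start=1,
                            q_end=aln_len,
                            s_start=1,
                            s_end=aln_len,
                            evalue=0.0,
                            bit_score=2 * aln_len,
                        )
                    )

    truth = pd.DataFrame(
        truth_rows,
        columns=["contig_id", "sample_id", "subject_id", "true_class", "length", "mapped_reads"],
    )
    return StudyBundle(
        config=config,
        contigs=contigs,
        phageome_contigs=phageome,
        gene_calls=genes,
        hits=hits,
        mappings=mappings,
        alignments=alignments,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Sequence-level generators (CRISPR and taxonomy tests)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def plant_crispr(
    bacterial_seq: str,
    phage_seq: str,
    n_spacers: int,
    rng: np.random.Generator,
    repeat_len: int = 28,
    spacer_len: int = 32,
    params: CrisprParams = CrisprParams(),
    mutate_spacers: int = 0,
) -> tuple[str, dict]:
    """Insert a repeat-spacer array into a bacterial contig whose spacers
    are substrings of the phage contig (protospacers).

    ``mutate_spacers`` introduces that many point mutations into each
    planted spacer (to exercise the identity filter downstream).  Returns
    the modified bacterial sequence and a truth dict with the repeat, the
    spacer sequences and the array insertion point.  ``n_spacers == 0``
    leaves the sequence unchanged.
    """
    if n_spacers == 0:
        return bacterial_seq, {"repeat": None, "spacers": [], "insert_at": None}
    if len(phage_seq) < spacer_len * n_spacers * 2:
        raise ValueError("phage contig too short to source distinct protospacers")
    array_len = (n_spacers + 1) * repeat_len + n_spacers * spacer_len
    if len(bacterial_seq) < array_len + 2:
        raise ValueError("bacterial contig too short to hold the array")

    repeat = random_dna(rng, repeat_len)
    # distinct, non-overlapping protospacer source positions; redraw until the
    # spacer boundary bases are not unanimous, so the planted repeat/spacer
    # boundary is unambiguous and recoverable exactly
    grid = np.arange(0, len(phage_seq) - spacer_len, spacer_len)
    for _ in range(200):
        starts = sorted(
            int(x) for x in rng.choice(grid, size=n_spacers, replace=False)
        )
        raw = [phage_seq[st : st + spacer_len] for st in starts]
        firsts = {s[0] for s in raw}
        lasts = {s[-1] for s in raw}
        if n_spacers == 1 or (len(firsts) > 1 and len(lasts) > 1):
            break
    spacers = []
    for st in starts:
        sp = phage_seq[st : st + spacer_len]
        if mutate_spacers:
            chars = list(sp)
            for pos in rng.choice(spacer_len, size=mutate_spacers, replace=False):
                old = chars[pos]
                chars[pos] = str(rng.choice([b for b in "ACGT" if b != old]))
            sp = "".join(chars)
        spacers.append(sp)
    array = repeat + "".join(s + repeat for s in spacers)
    insert_at = int(rng.integers(0, len(bacterial_seq) - array_len))
    modified = bacterial_seq[:insert_at] + array + bacterial_seq[insert_at:]
    return modified, {"repeat": repeat, "spacers": spacers, "insert_at": insert_at}


def generate_genus_genomes(
    n_genera: int,
    genome_length: int = 40_000,
    markov_order: int = 3,
    n_species_per_genus: int = 2,
    n_genomes_per_species: int = 2,
    seed: int = 0,
    shared_composition: bool = False,
    n_heldout_per_genus: int = 0,
) -> tuple[
    list[tuple[str, str]],
    dict[str, tuple[str, str]],
    list[tuple[str, str]],
]:
    """Reference genomes with genus-structured k-mer composition.

    Each genus draws its own random Markov transition matrix of the given
    order (Dirichlet rows), and genomes are sampled from it, so genomes of
    one genus share word composition that differs from other genera.  With
    ``shared_composition`` every genus uses the same matrix — a negative
    control with no taxonomic signal.  Returns (genome_id, sequence)
    training pairs, a genome -> (genus, species) lineage map, and
    ``n_heldout_per_genus`` extra (genus, sequence) genomes per genus drawn
    from the same matrices but never part of the training set (for
    recovery tests on unseen sequence).
    """
    if n_genera < 2 and not shared_composition:
        raise ValueError("need >= 2 genera for discrimination")
    rng = np.random.default_rng(seed)
    n_contexts = 4**markov_order if markov_order > 0 else 1
    shared = rng.dirichlet(np.ones(4) * 0.8, size=n_contexts)
    genomes: list[tuple[str, str]] = []
    lineage: dict[str, tuple[str, str]] = {}
    heldout: list[tuple[str, str]] = []
    for g in range(n_genera):
        genus = f"genus{g + 1}"
        matrix = shared if shared_composition else rng.dirichlet(
            np.ones(4) * 0.8, size=n_contexts
        )
        for sp in range(n_species_per_genus):
            species = f"{genus}_sp{sp + 1}"
            for rep in range(n_genomes_per_species):
                gid = f"{species}_gen{rep + 1}"
                genomes.append((gid, _sample_markov(rng, matrix, markov_order, genome_length)))
                lineage[gid] = (genus, species)
        for _ in range(n_heldout_per_genus):
            heldout.append((genus, _sample_markov(rng, matrix, markov_order, genome_length)))
    return genomes, lineage, heldout


def _sample_markov(
    rng: np.random.Generator, matrix: np.ndarray, order: int, length: int
) -> str:
    seq = np.empty(length, dtype=np.int64)
    context = 0
    mod = 4**order if order > 0 else 1
    # cumulative rows let us sample with one uniform draw per base
    cumrows = matrix.cumsum(axis=1)
    u = rng.random(length)
    for i in range(length):
        base = int(np.searchsorted(cumrows[context], u[i], side="right"))
        base = min(base, 3)
        seq[i] = base
        if order > 0:
            context = (context * 4 + base) % mod
    return "".join(_BASES[seq])
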