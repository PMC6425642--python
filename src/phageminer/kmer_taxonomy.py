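"""Naive-Bayes taxonomy assignment over 8-base words with bootstrap
confidence.

The classifier follows the word-presence naive-Bayes formulation used for
rRNA taxonomy: training genomes are reduced to the set of 8-mers they
contain, the prior for word ``w`` is ``P(w) = (n(w) + 0.5) / (N + 1)``
(``n(w)`` = number of training genomes containing ``w``, ``N`` = total
genomes), and the per-taxon conditional is
``P(w|t) = (m(w) + P(w)) / (M + 1)`` with ``m``/``M`` the analogous counts
within the taxon.  A query contig is assigned the taxon maximizing
``sum(log P(w|t))`` over its distinct words — presence/absence semantics,
so duplicated words do not change the call.

Confidence comes from a bootstrap: each of 100 trials rescores a random
subsample of ``ceil(W/8)`` of the contig's distinct words; the confidence
at a rank is the fraction of trials whose winner agrees with the full-word
assignment at that rank, so genus-level confidence is at least
species-level confidence.  Assignments with confidence <= 0.5 are
discarded (``retained=False``).

Phage genome strand is arbitrary, so words are merged with their reverse
complements (canonical form) by default; ``canonical=False`` disables this.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

WORD_SIZE = 8
N_WORDS = 4**WORD_SIZE

_BASE_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


def _revcomp_table() -> np.ndarray:
    idx = np.arange(N_WORDS, dtype=np.int64)
    rc = np.zeros(N_WORDS, dtype=np.int64)
    w = idx.copy()
    for _ in range(WORD_SIZE):
        rc = rc * 4 + (3 - (w % 4))
        w //= 4
    return rc


_RC = _revcomp_table()


def sequence_words(seq: str, canonical: bool = True) -> np.ndarray:
    """Sorted distinct 8-mer indices of a sequence; windows containing
    non-ACGT characters are skipped."""
    if len(seq) < WORD_SIZE:
        raise ValueError(f"sequence shorter than {WORD_SIZE} bp")
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(codes) - WORD_SIZE + 1
    windows = np.lib.stride_tricks.sliding_window_view(codes, WORD_SIZE)[:n]
    valid = (windows >= 0).all(axis=1)
    powers = 4 ** np.arange(WORD_SIZE - 1, -1, -1, dtype=np.int64)
    idx = (windows[valid] * powers).sum(axis=1)
    if canonical:
        idx = np.minimum(idx, _RC[idx])
    return np.unique(idx)


@dataclass(frozen=True)
class TaxonomyModel:
    taxa: tuple[tuple[str, str], ...]  # (genus, species) per leaf taxon
    log_conditional: np.ndarray  # (n_taxa, N_WORDS)
    word_prior: np.ndarray  # (N_WORDS,)
    training_counts: dict[str, int]  # species -> number of genomes
    canonical: bool = True

    @property
    def genera(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.taxa)

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(s for _, s in self.taxa)


@dataclass(frozen=True)
class TaxonomyAssignment:
    contig_id: str
    rank: str  # "genus" | "species"
    taxon: str
    confidence: float
    retained: bool


def train_taxonomy(
    genomes: Sequence[tuple[str, str]],
    taxonomy: Mapping[str, tuple[str, str]],
    canonical: bool = True,
) -> TaxonomyModel:
    """Fit the word-presence model from (genome_id, sequence) pairs.

    ``taxonomy`` maps genome id to a (genus, species) lineage.  Retraining
    on identical input yields an identical model (no randomness).
    """
    if not genomes:
        raise ValueError("no training genomes")
    for gid, _ in genomes:
        if gid not in taxonomy:
            raise ValueError(f"genome {gid!r} has no taxonomy entry")
    n_total = len(genomes)
    presence = np.zeros(N_WORDS, dtype=np.int64)
    words_by_genome: dict[str, np.ndarray] = {}
    for gid, seq in genomes:
        w = sequence_words(seq, canonical)
        words_by_genome[gid] = w
        presence[w] += 1
    prior = (presence + 0.5) / (n_total + 1)

    leaf_taxa = sorted({taxonomy[gid] for gid, _ in genomes})
    log_cond = np.empty((len(leaf_taxa), N_WORDS))
    counts: dict[str, int] = {}
    for t_idx, taxon in enumerate(leaf_taxa):
        members = [gid for gid, _ in genomes if taxonomy[gid] == taxon]
        counts[taxon[1]] = len(members)
        m = np.zeros(N_WORDS, dtype=np.int64)
        for gid in members:
            m[words_by_genome[gid]] += 1
        log_cond[t_idx] = np.log((m + prior) / (len(members) + 1))
    return TaxonomyModel(
        taxa=tuple(leaf_taxa),
        log_conditional=log_cond,
        word_prior=prior,
        training_counts=counts,
        canonical=canonical,
    )


def _best_taxon(model: TaxonomyModel, words: np.ndarray) -> int:
    scores = model.log_conditional[:, words].sum(axis=1)
    return int(np.argmax(scores))


def classify(
    contig_id: str,
    sequence: str,
    model: TaxonomyModel,
    n_bootstrap: int = 100,
    word_fraction: float = 1 / 8,
    rng_seed: int = 0,
    confidence_min: float = 0.5,
) -> dict[str, TaxonomyAssignment]:
    """Assign a contig at genus and species rank with bootstrap confidence.

    The full-word maximum-posterior taxon is the assignment; each bootstrap
    trial rescores ``ceil(W * word_fraction)`` distinct words sampled
    without replacement, and the per-rank confidence is the fraction of
    trials agreeing at that rank.  ``retained`` is True only for confidence
    strictly above ``confidence_min``.
    """
    words = sequence_words(sequence, model.canonical)
    full = _best_taxon(model, words)
    full_genus, full_species = model.taxa[full]

    rng = np.random.default_rng(rng_seed)
    subsample = max(1, int(np.ceil(len(words) * word_fraction)))
    genus_hits = species_hits = 0
    for _ in range(n_bootstrap):
        sub = rng.choice(words, size=subsample, replace=False)
        winner = _best_taxon(model, sub)
        g, s = model.taxa[winner]
        genus_hits += g == full_genus
        species_hits += s == full_species
    conf = {
        "genus": genus_hits / n_bootstrap,
        "species": species_hits / n_bootstrap,
    }
    taxon = {"genus": full_genus, "species": full_species}
    return {
        rank: TaxonomyAssignment(
            contig_id=contig_id,
            rank=rank,
            taxon=taxon[rank],
            confidence=conf[rank],
            retained=conf[rank] > confidence_min,
        )
        for rank in ("genus", "species")
    }
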