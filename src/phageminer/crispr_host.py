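"""CRISPR repeat-spacer detection and spacer-based phage-host prediction.

CRISPR arrays record past phage infections: a bacterium stores short phage
fragments (spacers) between near-identical direct repeats, so a spacer that
matches a phage contig (its protospacer) links that phage to its host.

Array detection follows the classic seed-and-extend recognition scheme:
exact seed words recurring at regular intervals are chained, each chain's
occurrences are extended outward into the full repeat while the copies stay
near-identical, and the inter-repeat gaps become spacers.  An array needs
at least 3 repeat copies, repeats of 19-38 bp, spacers of 19-48 bp, and
mutually dissimilar spacers (any two spacers > 90% identical mark a plain
tandem repeat and the candidate is rejected).

Spacer matching is ungapped: a spacer matches a phage contig where the full
spacer aligns (either strand) with at most ``floor(0.05 * length)``
mismatches, i.e. >= 95% identity.  E-values are database-size dependent, so
the match filter is an explicit mismatch budget instead; the mismatch
fraction is recorded as ``evalue_proxy``.  Only the single best match per
spacer is kept (highest identity, then longest, then lexicographically
smallest contig id), mirroring a best-hit search.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import AlignmentRecord, Contig

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class CrisprParams:
    min_repeats: int = 3
    repeat_len_min: int = 19
    repeat_len_max: int = 38
    spacer_len_min: int = 19
    spacer_len_max: int = 48
    max_repeat_mismatch: int = 1  # per repeat copy, vs the consensus
    spacer_similarity_max: float = 0.90  # any pair above this rejects the array


@dataclass(frozen=True)
class Spacer:
    seq: str
    start: int  # 1-based inclusive
    end: int


@dataclass(frozen=True)
class CrisprArray:
    contig_id: str
    repeat_consensus: str
    repeat_positions: tuple[tuple[int, int], ...]  # 1-based inclusive
    spacers: tuple[Spacer, ...]

    @property
    def span(self) -> tuple[int, int]:
        return self.repeat_positions[0][0], self.repeat_positions[-1][1]


@dataclass(frozen=True)
class SpacerMatch:
    spacer_id: str
    phage_contig_id: str
    identity_pct: float
    aligned_length: int
    evalue_proxy: float  # mismatch fraction
    strand: str = "+"


@dataclass(frozen=True)
class HostEdge:
    phage: str
    host: str
    sample_id: str
    subject_id: str
    support: int


# ---------------------------------------------------------------------------
# Bacterial contig selection
# ---------------------------------------------------------------------------


def select_bacterial_contigs(
    contig_ids: Iterable[str],
    prokaryote_hits: Iterable[AlignmentRecord],
    evalue_max: float = 1e-5,
) -> set[str]:
    """Contigs with >= 1 hit to a prokaryotic genome at e-value strictly
    below ``evalue_max``."""
    ids = set(contig_ids)
    return {
        h.query_id
        for h in prokaryote_hits
        if h.query_id in ids and h.evalue < evalue_max
    }


# ---------------------------------------------------------------------------
# Array detection
# ---------------------------------------------------------------------------


def _identity(a: str, b: str) -> float:
    """Ungapped identity of two short strings: positional matches over the
    longer length (the unaligned tail counts as mismatch)."""
    if not a or not b:
        return 0.0
    matches = sum(x == y for x, y in zip(a, b))
    return matches / max(len(a), len(b))


def _consensus(copies: Sequence[str]) -> str:
    length = min(len(c) for c in copies)
    out = []
    for i in range(length):
        col = [c[i] for c in copies]
        out.append(max(set(col), key=col.count))
    return "".join(out)


def _chain_positions(positions: Sequence[int], gap_min: int, gap_max: int,
                     min_repeats: int) -> list[list[int]]:
    """Maximal runs of seed positions with consecutive gaps in range."""
    chains: list[list[int]] = []
    current = [positions[0]]
    for pos in positions[1:]:
        gap = pos - current[-1]
        if gap_min <= gap <= gap_max:
            current.append(pos)
        elif gap < gap_min:
            continue  # overlapping re-occurrence of the seed; skip
        else:
            if len(current) >= min_repeats:
                chains.append(current)
            current = [pos]
    if len(current) >= min_repeats:
        chains.append(current)
    return chains


def _extend_chain(
    seq: str, starts: list[int], seed_len: int, params: CrisprParams
) -> tuple[list[tuple[int, int]], str] | None:
    """Grow each seed occurrence left/right into the full repeat.

    Extension continues while every copy agrees with the per-column majority
    base, allowing each copy at most ``max_repeat_mismatch`` total
    mismatches, and stops at the repeat-length cap, the sequence bounds, or
    when the inter-repeat gap would drop below the minimum spacer length.
    Returns 0-based half-open repeat intervals plus the consensus, or None
    when the result violates the length bounds.
    """
    n = len(starts)
    left = [s for s in starts]
    right = [s + seed_len for s in starts]
    mismatches = [0] * n

    def majority(idx: list[int]) -> str:
        col = [seq[i] for i in idx]
        return max(set(col), key=col.count)

    # rightward
    while right[-1] < len(seq) and (right[0] - left[0]) < params.repeat_len_max:
        gaps_ok = all(
            starts[i + 1] - (right[i] + 1) >= params.spacer_len_min
            for i in range(n - 1)
        )
        if not gaps_ok:
            break
        maj = majority(right)
        new_mm = [mismatches[i] + (seq[right[i]] != maj) for i in range(n)]
        if max(new_mm) > params.max_repeat_mismatch:
            break
        mismatches = new_mm
        right = [r + 1 for r in right]
    # leftward
    while left[0] > 0 and (right[0] - left[0]) < params.repeat_len_max:
        prev_ok = all(
            (left[i + 1] - 1) - right[i] >= params.spacer_len_min
            for i in range(n - 1)
        )
        if not prev_ok:
            break
        maj = majority([l - 1 for l in left])
        new_mm = [mismatches[i] + (seq[left[i] - 1] != maj) for i in range(n)]
        if max(new_mm) > params.max_repeat_mismatch:
            break
        mismatches = new_mm
        left = [l - 1 for l in left]

    # trim non-unanimous edge columns back to conserved sequence; tolerant
    # extension may otherwise creep one or two bases into the spacers
    def unanimous(idx: list[int]) -> bool:
        return len({seq[i] for i in idx}) == 1

    while (right[0] - left[0]) > params.repeat_len_min and not unanimous(
        [r - 1 for r in right]
    ):
        right = [r - 1 for r in right]
    while (right[0] - left[0]) > params.repeat_len_min and not unanimous(left):
        left = [l + 1 for l in left]

    rep_len = right[0] - left[0]
    if not params.repeat_len_min <= rep_len <= params.repeat_len_max:
        return None
    intervals = [(left[i], right[i]) for i in range(n)]
    consensus = _consensus([seq[a:b] for a, b in intervals])
    return intervals, consensus


def detect_arrays(
    contig_id: str,
    sequence: str,
    params: CrisprParams = CrisprParams(),
) -> list[CrisprArray]:
    """Find CRISPR repeat-spacer arrays in one contig sequence.

    Case-insensitive; returns arrays in genomic order, each with its repeat
    intervals (1-based inclusive), consensus repeat, and ordered spacers.
    """
    seq = sequence.upper()
    k = params.repeat_len_min
    if len(seq) < params.min_repeats * k:
        return []
    gap_min = params.repeat_len_min + params.spacer_len_min
    gap_max = params.repeat_len_max + params.spacer_len_max

    seed_positions: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        word = seq[i : i + k]
        if "N" in word:
            continue
        seed_positions.setdefault(word, []).append(i)

    claimed: list[tuple[int, int]] = []  # accepted array spans, 0-based
    arrays: list[CrisprArray] = []
    # deterministic order: by first occurrence
    for word in sorted(seed_positions, key=lambda w: seed_positions[w][0]):
        positions = seed_positions[word]
        if len(positions) < params.min_repeats:
            continue
        for chain in _chain_positions(positions, gap_min, gap_max, params.min_repeats):
            span = (chain[0], chain[-1] + k)
            if any(span[0] < e and a < span[1] for a, e in claimed):
                continue
            extended = _extend_chain(seq, chain, k, params)
            if extended is None:
                continue
            intervals, consensus = extended
            spacer_list: list[Spacer] = []
            ok = True
            for (a1, e1), (a2, _) in zip(intervals, intervals[1:]):
                s = seq[e1:a2]
                if not params.spacer_len_min <= len(s) <= params.spacer_len_max:
                    ok = False
                    break
                spacer_list.append(Spacer(seq=s, start=e1 + 1, end=a2))
            if not ok:
                continue
            # tandem-repeat guard: spacers must be mutually dissimilar
            reject = any(
                _identity(s1.seq, s2.seq) > params.spacer_similarity_max
                for i, s1 in enumerate(spacer_list)
                for s2 in spacer_list[i + 1 :]
            )
            if reject:
                continue
            claimed.append((intervals[0][0], intervals[-1][1]))
            arrays.append(
                CrisprArray(
                    contig_id=contig_id,
                    repeat_consensus=consensus,
                    repeat_positions=tuple((a + 1, e) for a, e in intervals),
                    spacers=tuple(spacer_list),
                )
            )
    arrays.sort(key=lambda arr: arr.span)
    return arrays


# ---------------------------------------------------------------------------
# Spacer matching
# ---------------------------------------------------------------------------


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_ungapped(spacer: np.ndarray, contig: np.ndarray) -> int | None:
    """Minimum mismatch count of the full spacer over all contig offsets, or
    None when the contig is shorter than the spacer."""
    m, n = len(spacer), len(contig)
    if n < m:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(contig, m)
    mismatches = (windows != spacer).sum(axis=1)
    return int(mismatches.min())


def match_spacers(
    spacers: Mapping[str, str],
    phage_contigs: Sequence[Contig],
    identity_min: float = 95.0,
    exact: bool = False,
) -> list[SpacerMatch]:
    """Match each spacer against the phage contig set; best hit per spacer.

    ``spacers`` maps spacer id to sequence.  The mismatch budget is
    ``floor((1 - identity_min/100) * len)`` (0 with ``exact``); both strands
    are searched.  Ties break to the highest identity, then longest spacer,
    then the lexicographically smallest contig id.
    """
    encoded = []
    for c in phage_contigs:
        if c.sequence is None:
            raise ValueError(f"phage contig {c.id!r} has no sequence")
        seq = c.sequence.upper()
        encoded.append((c.id, _encode(seq), _encode(reverse_complement(seq))))
    encoded.sort(key=lambda t: t[0])

    matches: list[SpacerMatch] = []
    for spacer_id in sorted(spacers):
        sp = spacers[spacer_id].upper()
        arr = _encode(sp)
        budget = 0 if exact else int((1 - identity_min / 100) * len(sp))
        best: SpacerMatch | None = None
        for contig_id, fwd, rev in encoded:
            for strand, target in (("+", fwd), ("-", rev)):
                mm = _best_ungapped(arr, target)
                if mm is None or mm > budget:
                    continue
                identity = 100.0 * (len(sp) - mm) / len(sp)
                cand = SpacerMatch(
                    spacer_id=spacer_id,
                    phage_contig_id=contig_id,
                    identity_pct=identity,
                    aligned_length=len(sp),
                    evalue_proxy=mm / len(sp),
                    strand=strand,
                )
                if best is None:
                    best = cand
                else:
                    key_c = (cand.identity_pct, cand.aligned_length)
                    key_b = (best.identity_pct, best.aligned_length)
                    if key_c > key_b or (
                        key_c == key_b
                        and cand.phage_contig_id < best.phage_contig_id
                    ):
                        best = cand
        if best is not None:
            matches.append(best)
    return matches


# ---------------------------------------------------------------------------
# Network construction
# ---------------------------------------------------------------------------


def build_network(
    matches: Sequence[SpacerMatch],
    spacer_host_contig: Mapping[str, str],
    phage_taxonomy: Mapping[str, str] | None = None,
    host_taxonomy: Mapping[str, str] | None = None,
    sample_of_spacer: Mapping[str, str] | None = None,
    subject_of_spacer: Mapping[str, str] | None = None,
    level: str = "contig",
) -> list[HostEdge]:
    """Aggregate spacer matches into phage-host edges.

    ``spacer_host_contig`` maps each spacer id to the bacterial contig
    carrying its array.  At ``level='contig'`` nodes are contigs; otherwise
    nodes are the taxa from the (possibly partial) taxonomy maps, with
    missing entries labeled ``unclassified``.  Support is the number of
    spacer matches behind the edge.
    """

    def node(contig: str, taxonomy: Mapping[str, str] | None) -> str:
        if level == "contig" or taxonomy is None:
            return contig if level == "contig" else "unclassified"
        return taxonomy.get(contig, "unclassified")

    counts: dict[tuple[str, str, str, str], int] = {}
    for m in matches:
        host_contig = spacer_host_contig[m.spacer_id]
        phage = m.phage_contig_id if level == "contig" else node(
            m.phage_contig_id, phage_taxonomy
        )
        host = host_contig if level == "contig" else node(host_contig, host_taxonomy)
        sample = (sample_of_spacer or {}).get(m.spacer_id, "")
        subject = (subject_of_spacer or {}).get(m.spacer_id, "")
        key = (phage, host, sample, subject)
        counts[key] = counts.get(key, 0) + 1
    return [
        HostEdge(phage=p, host=h, sample_id=sa, subject_id=su, support=n)
        for (p, h, sa, su), n in sorted(counts.items())
    ]


def to_networkx(edges: Sequence[HostEdge]):
    """Bipartite phage-host graph (networkx) for export, e.g. GraphML."""
    import networkx as nx

    g = nx.Graph()
    for e in edges:
        g.add_node(e.phage, kind="phage")
        g.add_node(e.host, kind="host")
        if g.has_edge(e.phage, e.host):
            g[e.phage][e.host]["support"] += e.support
        else:
            g.add_edge(e.phage, e.host, support=e.support)
    return g
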