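"""Mating-type locus comparison: anchors, synteny, and CAAX scanning.

Fungal mating-type (MAT) loci often differ between compatibility groups
by structural rearrangement rather than point divergence alone: an
inverted cassette, private insertions, and highly diverged receptor
genes, flanked by near-identical sequence.  This module compares two
locus-scale DNA sequences via maximal unique exact matches (MUM-style
anchors, both orientations), chains colinear anchors greedily, and
reports inversion intervals (query spans covered by reverse-orientation
chains) and indel intervals (inter-chain gaps carried by exactly one
sequence).  It also scans protein sequences for the C-terminal CAAX
prenylation motif typical of fungal pheromone precursors.

Anchors are found with a suffix-array/LCP sweep; the anchor finder is
exact (it agrees with brute-force enumeration of maximal unique
matches) rather than seeded/heuristic.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

#: The two pheromone-precursor proteins of the halophilic
#: *Wallemia ichthyophaga* study system (one private to the inverted
#: mating-locus orientation, one to the reference orientation); both
#: carry the CAAX prenylation signal at the C-terminus.  Bundled as
#: demonstration inputs for the CAAX scanner.
PHEROMONE_PRECURSORS: dict[str, str] = {
    "precursor_inverted_MAT": (
        "MEPETLKNIFFQEASQDHLKDEAILFETSIGMPEISSEDLANS"
        "NNPINDSTGGDNADTMYCIIV"
    ),
    "precursor_reference_MAT": "MIPEIEVSQIQVDQVHINVEREEPGENETYGSSSGCIIT",
}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclasses.dataclass(frozen=True)
class Anchor:
    """A maximal exact match unique in both sequences.

    Coordinates are 1-based inclusive and always given on the forward
    strand of both sequences; `orientation` is 'forward' when the query
    segment matches the subject segment directly and 'reverse' when it
    matches its reverse complement.
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    orientation: str
    length: int


@dataclasses.dataclass
class Chain:
    """A colinear run of same-orientation anchors."""

    orientation: str
    anchors: list[Anchor]

    @property
    def q_start(self) -> int:
        return self.anchors[0].q_start

    @property
    def q_end(self) -> int:
        return self.anchors[-1].q_end

    @property
    def s_low(self) -> int:
        return min(a.s_start for a in self.anchors)

    @property
    def s_high(self) -> int:
        return max(a.s_end for a in self.anchors)

    @property
    def matched_bp(self) -> int:
        return sum(a.length for a in self.anchors)

    @property
    def anchor_divergence(self) -> float:
        """1 - (anchor-covered fraction of the chain's query span); a
        coverage-based divergence proxy (no base-level alignment)."""
        span = self.q_end - self.q_start + 1
        return 1.0 - min(self.matched_bp / span, 1.0)


@dataclasses.dataclass
class SyntenyReport:
    """Chains, inversion intervals and indel intervals for one pair."""

    chains: list[Chain]
    inversion_intervals: list[tuple[int, int]]
    indel_intervals: list[dict]

    def to_dict(self) -> dict:
        return {
            "n_chains": len(self.chains),
            "chains": [
                {
                    "orientation": c.orientation,
                    "q_start": c.q_start,
                    "q_end": c.q_end,
                    "s_start": c.s_low,
                    "s_end": c.s_high,
                    "n_anchors": len(c.anchors),
                    "anchor_divergence": c.anchor_divergence,
                }
                for c in self.chains
            ],
            "inversion_intervals": list(self.inversion_intervals),
            "indel_intervals": list(self.indel_intervals),
        }


@dataclasses.dataclass
class MotifHit:
    """Result of a C-terminal CAAX scan on one protein."""

    sequence_id: str
    is_caax: bool
    terminal_residues: str
    rule_version: str = "C-aliphatic-aliphatic-X v1"


# ---------------------------------------------------------------------------
# suffix array machinery
# ---------------------------------------------------------------------------

def _suffix_array(t: np.ndarray) -> np.ndarray:
    """Suffix array by prefix doubling (numpy lexsort)."""
    n = len(t)
    if n == 1:
        return np.zeros(1, dtype=np.int64)
    _, rank = np.unique(t, return_inverse=True)
    rank = rank.astype(np.int64)
    k = 1
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r_ord, k_ord = rank[order], key2[order]
        changed = np.ones(n, dtype=bool)
        changed[1:] = (r_ord[1:] != r_ord[:-1]) | (k_ord[1:] != k_ord[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank.max() == n - 1:
            return order
        k *= 2


def _lcp_array(t: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """Kasai LCP: lcp[i] = longest common prefix of sa[i-1] and sa[i]."""
    n = len(t)
    rank = np.empty(n, dtype=np.int64)
    rank[sa] = np.arange(n)
    lcp = np.zeros(n, dtype=np.int64)
    h = 0
    tl = t.tolist()
    sal = sa.tolist()
    for i in range(n):
        r = rank[i]
        if r > 0:
            j = sal[r - 1]
            while i + h < n and j + h < n and tl[i + h] == tl[j + h]:
                h += 1
            lcp[r] = h
            if h:
                h -= 1
        else:
            h = 0
    return lcp


def _encode(seq: str, n_code_start: int) -> tuple[np.ndarray, int]:
    """Map A/C/G/T to 1..4 and each N to its own code so N never
    matches anything (including another N)."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).astype(np.int64)
    out = np.full(len(seq), -9, dtype=np.int64)
    for base, code in zip(b"ACGT", (1, 2, 3, 4)):
        out[codes == base] = code
    n_mask = codes == ord("N")
    n_count = int(n_mask.sum())
    out[n_mask] = np.arange(n_code_start, n_code_start + n_count)
    if (out == -9).any():
        bad = chr(int(codes[out == -9][0]))
        raise ValueError(f"invalid nucleotide {bad!r} (expected A/C/G/T/N)")
    return out, n_code_start + n_count


def _mums_one_orientation(query: str, subject: str, k: int) -> list[tuple[int, int, int]]:
    """All (q_start0, s_start0, length) maximal matches of length >= k
    whose matched string occurs exactly once in each sequence."""
    nq, ns = len(query), len(subject)
    qa, nxt = _encode(query, 10)
    sa_codes, _ = _encode(subject, nxt)
    sep = np.array([0], dtype=np.int64)
    t = np.concatenate([qa, sep, sa_codes])
    n = len(t)
    sa = _suffix_array(t)
    lcp = _lcp_array(t, sa)
    out: list[tuple[int, int, int]] = []
    for i in range(1, n):
        a, b = int(sa[i - 1]), int(sa[i])
        a_is_q, b_is_q = a < nq, b < nq
        if a_is_q == b_is_q:
            continue
        l = int(lcp[i])
        if l < k:
            continue
        # uniqueness of the length-l prefix: strictly longer than the
        # LCPs with the outside neighbours
        if i - 1 > 0 and lcp[i - 1] >= l:
            continue
        if i + 1 < n and lcp[i + 1] >= l:
            continue
        # left-maximality
        if a > 0 and b > 0 and t[a - 1] == t[b - 1]:
            continue
        qpos, spos = (a, b - nq - 1) if a_is_q else (b, a - nq - 1)
        out.append((qpos, spos, l))
    return out


def find_anchors(query: str, subject: str, k: int = 20) -> list[Anchor]:
    """Maximal unique exact matches of length >= k, both orientations.

    A match must be maximal (not extendable on either side) and unique
    in both the query and the (oriented) subject; N never matches.
    Reverse-orientation anchors are reported in forward coordinates on
    both sequences.  Anchors are sorted by (q_start, orientation).
    """
    if not query or not subject:
        raise ValueError("empty sequence")
    if k < 8:
        raise ValueError("k must be >= 8")
    query = query.upper()
    subject = subject.upper()
    anchors: list[Anchor] = []
    for qpos, spos, l in _mums_one_orientation(query, subject, k):
        anchors.append(
            Anchor(qpos + 1, qpos + l, spos + 1, spos + l, "forward", l)
        )
    rc = reverse_complement(subject)
    ls = len(subject)
    for qpos, spos, l in _mums_one_orientation(query, rc, k):
        s_end = ls - spos
        s_start = ls - (spos + l) + 1
        anchors.append(
            Anchor(qpos + 1, qpos + l, s_start, s_end, "reverse", l)
        )
    anchors.sort(key=lambda a: (a.q_start, a.orientation, a.s_start))
    return anchors


# ---------------------------------------------------------------------------
# chaining and reporting
# ---------------------------------------------------------------------------

def chain_and_report(
    anchors: list[Anchor], min_indel: int = 50, max_gap: int = 500
) -> SyntenyReport:
    """Greedy colinear chaining and structural-difference calling.

    Anchors (sorted by query position) are joined into a chain while
    they keep the same orientation and are diagonally consistent: the
    query gap and the subject gap to the next anchor are both at most
    `max_gap` (small overlaps are tolerated), and subject coordinates
    advance in the direction the orientation dictates.  Reverse chains
    become inversion intervals (their query span).  Between consecutive
    chains, an unmatched span of at least `min_indel` bp on exactly one
    sequence is reported as an indel interval naming the carrier.
    """
    if not anchors:
        warnings.warn("no anchors: empty synteny report", stacklevel=2)
        return SyntenyReport(chains=[], inversion_intervals=[], indel_intervals=[])
    ordered = sorted(anchors, key=lambda a: (a.q_start, a.q_end))
    chains: list[Chain] = []
    cur = Chain(orientation=ordered[0].orientation, anchors=[ordered[0]])
    for a in ordered[1:]:
        prev = cur.anchors[-1]
        q_gap = a.q_start - prev.q_end - 1
        if a.orientation == "forward":
            s_gap = a.s_start - prev.s_end - 1
            consistent = a.s_start > prev.s_start
        else:
            s_gap = prev.s_start - a.s_end - 1
            consistent = a.s_end < prev.s_end
        tol = -prev.length  # allow overlap up to an anchor length
        if (
            a.orientation == cur.orientation
            and consistent
            and tol <= q_gap <= max_gap
            and tol <= s_gap <= max_gap
        ):
            cur.anchors.append(a)
        else:
            chains.append(cur)
            cur = Chain(orientation=a.orientation, anchors=[a])
    chains.append(cur)

    inversions = [
        (c.q_start, c.q_end) for c in chains if c.orientation == "reverse"
    ]
    indels: list[dict] = []
    for c1, c2 in zip(chains, chains[1:]):
        q_gap = c2.q_start - c1.q_end - 1
        lows = sorted([(c1.s_low, c1.s_high), (c2.s_low, c2.s_high)])
        s_gap = max(lows[1][0] - lows[0][1] - 1, 0)
        q_big, s_big = q_gap >= min_indel, s_gap >= min_indel
        if q_big and not s_big:
            indels.append(
                {
                    "carrier": "query",
                    "start": c1.q_end + 1,
                    "end": c2.q_start - 1,
                    "length": q_gap,
                }
            )
        elif s_big and not q_big:
            indels.append(
                {
                    "carrier": "subject",
                    "start": lows[0][1] + 1,
                    "end": lows[1][0] - 1,
                    "length": s_gap,
                }
            )
    return SyntenyReport(
        chains=chains, inversion_intervals=inversions, indel_intervals=indels
    )


def aligned_divergence(seq_a: str, seq_b: str) -> float:
    """Proportion of differing positions between two aligned sequences.

    Columns with a gap ('-') in either sequence are excluded from both
    numerator and denominator.  Raises ValueError on length mismatch or
    when no gap-free columns remain.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a = seq_a.upper()
    b = seq_b.upper()
    comparable = 0
    diff = 0
    for ca, cb in zip(a, b):
        if ca == "-" or cb == "-":
            continue
        comparable += 1
        if ca != cb:
            diff += 1
    if comparable == 0:
        raise ValueError("no gap-free columns to compare")
    return diff / comparable


DEFAULT_ALIPHATIC = frozenset("AVILMF")


def caax_scan(
    protein: str,
    sequence_id: str = "",
    aliphatic: frozenset = DEFAULT_ALIPHATIC,
) -> MotifHit:
    """Scan a protein's C-terminus for the CAAX prenylation motif.

    The motif is the terminal tetrapeptide Cys - aliphatic - aliphatic
    - any residue; the aliphatic set defaults to {A, V, I, L, M, F}.
    Whitespace is stripped so sequences copied from wrapped text work
    as-is.  Raises ValueError for proteins shorter than 4 residues.
    """
    seq = "".join(protein.split()).upper()
    if len(seq) < 4:
        raise ValueError("protein shorter than 4 residues")
    tail = seq[-4:]
    is_caax = tail[0] == "C" and tail[1] in aliphatic and tail[2] in aliphatic
    return MotifHit(
        sequence_id=sequence_id, is_caax=is_caax, terminal_residues=tail
    )
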