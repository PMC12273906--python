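"""Circularity calling from RCA concatemer reads.

A rolling-circle-amplified circular molecule reads out as a tandem
concatemer of its monomer. This module detects that tandem structure in
each long read, estimates the number of amplification rounds, builds a
per-column majority-vote monomer consensus, and retains only reads with
more than one round of concatenation as evidence of circularity.

Period candidates are proposed from the distance spectrum of repeated
k-mer anchors and verified by alignment of successive period-length
segments; the smallest verifying period wins (with an explicit divisor
guard so a doubled monomer is never reported).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import edlib

from .simdata import revcomp

_AFFINE_REFINE = 3  # local search half-width around a candidate period (bp)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class PeriodEstimate:
    period: int
    rounds: float
    identity: float  # mean identity between successive period-length segments
    support: int     # number of segment comparisons


@dataclass
class MonomerCall:
    monomer_id: str
    source_read_id: str
    sequence: str
    rounds: float
    canonical_sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class CallSummary:
    total_reads: int = 0
    passed_filter: int = 0
    rejected_filter: int = 0
    aperiodic: int = 0
    below_min_rounds: int = 0
    consensus_failed: int = 0
    circular_calls: int = 0
    rejections: list[tuple[str, str]] = field(default_factory=list)  # (read_id, reason)

    def conserved(self) -> bool:
        return (self.total_reads == self.rejected_filter + self.aperiodic
                + self.below_min_rounds + self.consensus_failed + self.circular_calls)


# ---------------------------------------------------------------------------
# Read filtering
# ---------------------------------------------------------------------------

def filter_reads(reads, min_length: int = 3000, min_mean_quality: float = 30.0):
    """Pass reads meeting length and mean-base-quality thresholds.

    ``reads`` yields (read_id, sequence, qualities). Returns (passed,
    rejections) where rejections is a list of (read_id, reason). Emulates
    the instrument-side consensus-read filters (minimum insert length and
    predicted accuracy) as read-level thresholds.
    """
    if min_length < 0 or min_mean_quality < 0:
        raise ValueError("thresholds must be non-negative")
    passed, rejections = [], []
    for rid, seq, quals in reads:
        if len(seq) < min_length:
            rejections.append((rid, f"length {len(seq)} < {min_length}"))
        elif quals and sum(quals) / len(quals) < min_mean_quality:
            rejections.append((rid, f"mean quality below {min_mean_quality}"))
        else:
            passed.append((rid, seq, quals))
    return passed, rejections


# ---------------------------------------------------------------------------
# Canonical form of a circular sequence
# ---------------------------------------------------------------------------

def _least_rotation(s: str) -> int:
    """Booth's algorithm: index of the lexicographically least rotation, O(n)."""
    s2 = s + s
    n = len(s2)
    f = [-1] * n
    k = 0
    for j in range(1, n):
        sj = s2[j]
        i = f[j - k - 1]
        while i != -1 and sj != s2[k + i + 1]:
            if sj < s2[k + i + 1]:
                k = j - i - 1
            i = f[i]
        if sj != s2[k + i + 1]:
            if sj < s2[k]:
                k = j
            f[j - k] = -1
        else:
            f[j - k] = i + 1
    return k


def canonicalize(seq: str) -> str:
    """Rotation- and strand-invariant canonical form of a circular sequence.

    Returns the lexicographically least string among all rotations of
    ``seq`` and all rotations of its reverse complement. Idempotent.
    """
    if not seq:
        raise ValueError("cannot canonicalize an empty sequence")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    k = _least_rotation(seq)
    fwd = seq[k:] + seq[:k]
    rc = revcomp(seq)
    k = _least_rotation(rc)
    rev = rc[k:] + rc[:k]
    return min(fwd, rev)


# ---------------------------------------------------------------------------
# Period estimation
# ---------------------------------------------------------------------------

def _segment_identity(read: str, p: int, max_comparisons: int = 6) -> tuple[float, int]:
    """Mean identity of successive p-length segments vs the first; support count."""
    nseg = len(read) // p
    if nseg < 2:
        return 0.0, 0
    first = read[:p]
    idents = []
    for i in range(1, min(nseg, max_comparisons + 1)):
        seg = read[i * p:(i + 1) * p]
        d = edlib.align(seg, first, mode="NW", task="distance")["editDistance"]
        idents.append(1.0 - d / p)
    return sum(idents) / len(idents), len(idents)


def _quick_identity(read: str, p: int) -> float:
    """Single-comparison screen: identity of the second segment vs the first."""
    if len(read) < 2 * p:
        return 0.0
    d = edlib.align(read[p:2 * p], read[:p], mode="NW", task="distance")["editDistance"]
    return 1.0 - d / p


def _candidate_periods(read: str, min_monomer: int, k: int, top: int = 8) -> list[int]:
    """Modes of distances between successive occurrences of identical k-mers."""
    last: dict[str, int] = {}
    diffs: Counter[int] = Counter()
    half = len(read) // 2
    for i in range(len(read) - k + 1):
        km = read[i:i + k]
        j = last.get(km)
        if j is not None:
            d = i - j
            if min_monomer <= d <= half:
                diffs[d] += 1
        last[km] = i
    if not diffs:
        return []
    # merge the spectrum into bins of +-refine bp so indel jitter pools votes
    ranked = [d for d, _ in diffs.most_common()]
    picked: list[int] = []
    for d in ranked:
        if all(abs(d - q) > _AFFINE_REFINE for q in picked):
            picked.append(d)
        if len(picked) >= top:
            break
    return picked


def _refine_period(read: str, p0: int, min_monomer: int) -> tuple[int, float, int]:
    """Best (period, identity, support) within +-_AFFINE_REFINE of p0."""
    best = (0, -1.0, 0)
    half = len(read) // 2
    for p in range(max(min_monomer, p0 - _AFFINE_REFINE), min(half, p0 + _AFFINE_REFINE) + 1):
        ident, support = _segment_identity(read, p)
        if support and (ident > best[1] or (ident == best[1] and p < best[0])):
            best = (p, ident, support)
    return best


def estimate_period(read: str, min_monomer: int = 50, identity_floor: float = 0.90,
                    k: int = 13) -> PeriodEstimate | None:
    """Estimate the tandem-repeat period of a concatemer read.

    Returns the smallest verifying period as a :class:`PeriodEstimate`, or
    ``None`` when the read is aperiodic (no candidate reaches
    ``identity_floor``, or the read is shorter than two monomers).
    Sub-``min_monomer`` pseudo-periods (homopolymers, microsatellites) are
    excluded by the search floor.
    """
    L = len(read)
    if L < 2 * min_monomer:
        return None
    k_eff = min(k, max(2, min_monomer))
    verified: list[tuple[int, float, int]] = []
    best_period: int | None = None
    for p0 in sorted(_candidate_periods(read, min_monomer, k_eff)):
        if best_period is not None and p0 >= best_period:
            break  # candidates are ascending; a larger period cannot win
        if _quick_identity(read, p0) < identity_floor - 0.08:
            continue
        p, ident, support = _refine_period(read, p0, min_monomer)
        if not support or ident < identity_floor:
            continue
        # divisor guard: a doubled/tripled monomer also verifies; take the
        # smallest verifying sub-period
        best = (p, ident, support)
        for m in range(2, p // min_monomer + 1):
            q0 = int(round(p / m))
            if q0 < min_monomer:
                break
            if _quick_identity(read, q0) < identity_floor - 0.08:
                continue
            q, qident, qsupport = _refine_period(read, q0, min_monomer)
            if qsupport and qident >= identity_floor and q < best[0]:
                best = (q, qident, qsupport)
        verified.append(best)
        best_period = min(best_period or best[0], best[0])
    if not verified:
        return None
    period, ident, support = min(verified, key=lambda t: t[0])
    return PeriodEstimate(period=period, rounds=L / period, identity=ident, support=support)


# ---------------------------------------------------------------------------
# Consensus (deconcatenation)
# ---------------------------------------------------------------------------

def _cigar_ops(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _column_votes(seg: str, quals, backbone: str, mode: str):
    """Align one segment to the backbone; yield its per-column contributions.

    Returns (votes, inserts): votes maps backbone column -> (base or '-',
    quality); inserts maps backbone column j -> (inserted string, mean qual)
    for bases this segment places between columns j and j+1 (j == -1 for
    bases before the first column). Cigar convention: '=X' consume both,
    'I' consumes the query (segment), 'D' consumes the target (backbone).
    """
    res = edlib.align(seg, backbone, mode=mode, task="path")
    votes: dict[int, tuple[str, int]] = {}
    inserts: dict[int, tuple[str, float]] = {}
    qi = 0
    ti = 0
    for n, op in _cigar_ops(res["cigar"]):
        if op in "=X":
            for _ in range(n):
                votes[ti] = (seg[qi], quals[qi] if quals else 30)
                qi += 1
                ti += 1
        elif op == "D":  # backbone base missing from this segment
            for _ in range(n):
                q = quals[qi] if quals and qi < len(quals) else 30
                votes[ti] = ("-", q)
                ti += 1
        elif op == "I":  # extra bases in this segment between backbone columns
            ins = seg[qi:qi + n]
            q = (sum(quals[qi:qi + n]) / n) if quals else 30.0
            qi += n
            # left-align the insertion (indel placement is ambiguous inside
            # repeats; normalizing pools votes from different segments)
            j = ti - 1
            while j >= 0 and ins[-1] == backbone[j]:
                ins = backbone[j] + ins[:-1]
                j -= 1
            prev = inserts.get(j)
            if prev:
                tot = len(prev[0]) + n
                inserts[j] = (prev[0] + ins, (prev[1] * len(prev[0]) + q * n) / tot)
            else:
                inserts[j] = (ins, q)
    return votes, inserts


def _consensus_pass(segments, backbone: str, self_index: int | None) -> str:
    """One round of per-column majority voting of ``segments`` against
    ``backbone``.

    ``self_index`` marks the segment that IS the backbone (pass 1); it votes
    its own bases directly and is excluded from insertion denominators,
    because a sequence cannot witness an insertion relative to itself.
    Ties are broken by base quality, then by first-segment precedence.
    """
    p = len(backbone)
    col_votes: list[list[tuple[str, int, int]]] = [[] for _ in range(p)]
    ins_votes: dict[int, list[tuple[str, float]]] = {j: [] for j in range(-1, p)}
    cover_ins = [0] * p  # insertion-eligible voters per column

    for si, (seg, q, mode) in enumerate(segments):
        if si == self_index:
            votes, inserts = {j: (backbone[j], q[j] if q else 30) for j in range(p)}, {}
        else:
            votes, inserts = _column_votes(seg, q, backbone, mode)
        for j, (base, quality) in votes.items():
            col_votes[j].append((base, quality, si))
            if si != self_index:
                cover_ins[j] += 1
        for j, (ins, quality) in inserts.items():
            ins_votes[j].append((ins, quality))

    def _top(votes: list[tuple[str, float]]) -> tuple[str, int, float]:
        counts = Counter(s for s, _ in votes)
        best = None
        for s, cnt in counts.items():
            qual = max(q for t, q in votes if t == s)
            if best is None or (cnt, qual) > best[0]:
                best = ((cnt, qual), s)
        (cnt, qual), s = best
        return s, cnt, qual

    # Accepted insertions: majority among eligible voters, with vote pooling
    # across adjacent keys (a substitution inside the missing base shifts a
    # segment's placement by one column). At coverage <= 2 a lone insert is
    # accepted when high-quality — real bases carry high quality, insertion
    # errors low.
    accepted_ins: dict[int, str] = {}
    consumed: set[int] = set()
    for j in range(-1, p):
        if j in consumed or not ins_votes[j]:
            continue
        pool = list(ins_votes[j])
        pooled = pool + (ins_votes[j + 1] if j + 1 < p and ins_votes[j + 1] else [])
        s1, c1, q1 = _top(pool)
        s2, c2, q2 = _top(pooled)
        use_pool = c2 > c1
        s, cnt, qual = (s2, c2, q2) if use_pool else (s1, c1, q1)
        voters = cover_ins[j if j >= 0 else 0]
        if 2 * cnt > voters or (qual >= 30 and voters <= 2):
            accepted_ins[j] = s
            if use_pool:
                consumed.add(j + 1)

    out: list[str] = []
    if -1 in accepted_ins:
        out.append(accepted_ins[-1])
    for j in range(p):
        votes = col_votes[j]
        if not votes:
            continue
        counts = Counter(b for b, _, _ in votes)
        top = max(counts.values())
        tied = [b for b, c in counts.items() if c == top]
        if len(tied) == 1:
            base = tied[0]
        else:
            best = None
            for b, quality, si in votes:
                if b not in tied:
                    continue
                key = (quality, -si)
                if best is None or key > best[0]:
                    best = (key, b)
            base = best[1]
        if base != "-":
            out.append(base)
        if j in accepted_ins:
            out.append(accepted_ins[j])
    return "".join(out)


def deconcatenate(read: str, est: PeriodEstimate, quals=None, read_id: str = "read",
                  identity_floor: float = 0.90) -> MonomerCall | None:
    """Build the monomer consensus from a period-verified concatemer read.

    Successive period-length segments are aligned to the first and a
    per-column majority vote is taken over all aligned segments (the
    fractional trailing segment votes only on the columns it covers).
    Ties are broken by base quality, then by first-segment precedence.
    Majority-supported insertions relative to the first segment are
    restored, so an indel in the backbone segment does not propagate.
    Returns ``None`` (call rejected) when any full segment fails to align
    at ``identity_floor``.
    """
    if est.rounds <= 1:
        raise ValueError("deconcatenate requires rounds > 1")
    p = est.period
    L = len(read)
    slack = max(10, p // 50)
    # sharpen the period to base resolution: the distance from the read
    # start to the recurrence of its prefix IS the first round's length,
    # which a k-mer-spectrum period estimate only brackets to a few bp
    anchor_len = min(64, p // 2)
    if anchor_len >= 16:
        wlo = max(anchor_len, p - slack)
        whi = min(L, p + slack + anchor_len)
        res = edlib.align(read[:anchor_len], read[wlo:whi], mode="HW", task="locations")
        if 0 <= res["editDistance"] <= max(2, anchor_len // 5):
            p_anchor = wlo + res["locations"][0][0]
            if 2 * p_anchor <= L + slack:
                p = p_anchor
    # successive segments are re-anchored by aligning the first segment to
    # the remaining read, so a +-1-2 bp period error cannot accumulate into
    # a frame shift across rounds
    segments = [(read[:p], quals[:p] if quals else None, "NW")]
    pos = p
    while L - pos >= p - slack:
        window = read[pos:min(L, pos + p + slack)]
        res = edlib.align(read[:p], window, mode="SHW", task="locations")
        end = res["locations"][0][1] + 1
        seg = window[:end]
        q = quals[pos:pos + end] if quals else None
        segments.append((seg, q, "NW"))
        pos += end
    frac = read[pos:]
    if len(frac) >= max(20, p // 10):
        q = quals[pos:] if quals else None
        segments.append((frac, q, "SHW"))

    backbone = segments[0][0]
    for si, (seg, q, mode) in enumerate(segments):
        if si > 0 and mode == "NW":
            d = edlib.align(seg, backbone, mode="NW", task="distance")["editDistance"]
            if 1.0 - d / p < identity_floor:
                return None
    # pass 1: vote against the raw first segment; pass 2 polishes by voting
    # against the pass-1 consensus, where every segment is a real voter
    consensus = _consensus_pass(segments, backbone, self_index=0)
    if consensus:
        consensus = _consensus_pass(segments, consensus, self_index=None)
    if not consensus:
        return None
    return MonomerCall(
        monomer_id=f"{read_id}_monomer",
        source_read_id=read_id,
        sequence=consensus,
        rounds=est.rounds,
        canonical_sequence=canonicalize(consensus),
    )


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------

def call_circular(reads, min_length: int = 3000, min_mean_quality: float = 30.0,
                  min_monomer: int = 50, identity_floor: float = 0.90,
                  min_rounds: float = 1.0, k: int = 13):
    """filter -> estimate period -> deconcatenate; keep calls with rounds > min_rounds.

    ``reads`` yields (read_id, sequence, qualities). Returns (calls,
    summary). The summary conserves counts: every input read lands in
    exactly one of {rejected_filter, aperiodic, below_min_rounds,
    consensus_failed, circular_calls}.
    """
    reads = list(reads)
    summary = CallSummary(total_reads=len(reads))
    passed, rejections = filter_reads(reads, min_length, min_mean_quality)
    summary.passed_filter = len(passed)
    summary.rejected_filter = len(rejections)
    summary.rejections.extend(rejections)

    calls: list[MonomerCall] = []
    for rid, seq, quals in passed:
        est = estimate_period(seq, min_monomer=min_monomer,
                              identity_floor=identity_floor, k=k)
        if est is None:
            summary.aperiodic += 1
            summary.rejections.append((rid, "aperiodic"))
            continue
        if not est.rounds > min_rounds:
            summary.below_min_rounds += 1
            summary.rejections.append((rid, f"rounds {est.rounds:.3f} <= {min_rounds}"))
            continue
        call = deconcatenate(seq, est, quals=quals, read_id=rid,
                             identity_floor=identity_floor)
        if call is None:
            summary.consensus_failed += 1
            summary.rejections.append((rid, "segment alignment below identity floor"))
            continue
        calls.append(call)
        summary.circular_calls += 1
    return calls, summary
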