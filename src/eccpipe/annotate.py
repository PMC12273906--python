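"""Mapping and origin annotation of eccDNA monomers.

Maps monomer consensus sequences against genome, TE and CDS databases,
classifies each molecule's origin (TE > CDS > intergenic priority), its
TE completeness (full vs partial), whether it derives from a single
continuous genomic locus, and assigns it to a fixed-size chromosome
window for downstream profiling.

Two interchangeable mapping backends share one 12-column tabular-hit
contract: a reader for externally produced tabular local-alignment hits
(with the e-value filter applied verbatim), and a built-in exact-k-mer
seeded banded aligner for desk-scale synthetic data, which filters on
percent identity and alignment length as its e-value surrogate.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import pandas as pd

from .simdata import SimGenome, revcomp

TABULAR_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "alignment_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "e_value", "bit_score",
]


@dataclass
class AlignmentHit:
    """One local alignment in the 12-column tabular dialect.

    Subject coordinates are 1-based inclusive; ``s_start > s_end`` encodes
    a minus-strand hit.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float

    @property
    def strand(self) -> str:
        return "+" if self.s_start <= self.s_end else "-"

    def subject_interval(self) -> tuple[int, int]:
        """Subject interval as 0-based half-open (lo, hi)."""
        lo, hi = sorted((self.s_start, self.s_end))
        return lo - 1, hi


@dataclass
class EccAnnotation:
    monomer_id: str
    chrom: str
    start: int  # 0-based half-open best locus
    end: int
    strand: str
    window_chrom: str
    window_bin: int
    origin_class: str  # CDS | TE | intergenic
    te_id: str | None
    te_family: str | None
    te_superfamily: str | None
    te_completeness: str  # full | partial | none
    single_event: bool


# ---------------------------------------------------------------------------
# Backend (i): tabular-hit reader
# ---------------------------------------------------------------------------

def read_tabular_hits(path, evalue_max: float = 1e-50,
                      max_hsps_per_subject: int = 1) -> list[AlignmentHit]:
    """Read 12-column tabular local-alignment hits, filtered as the study
    pipeline filtered them: e-value <= ``evalue_max`` and at most
    ``max_hsps_per_subject`` HSPs per (query, subject) pair (best bit score
    kept)."""
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(f"{path}:{lineno}: expected 12 fields, got {len(parts)}")
            try:
                hit = AlignmentHit(
                    query_id=parts[0], subject_id=parts[1],
                    percent_identity=float(parts[2]), alignment_length=int(parts[3]),
                    mismatches=int(parts[4]), gap_opens=int(parts[5]),
                    q_start=int(parts[6]), q_end=int(parts[7]),
                    s_start=int(parts[8]), s_end=int(parts[9]),
                    e_value=float(parts[10]), bit_score=float(parts[11]),
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed tabular line: {exc}") from exc
            if hit.e_value <= evalue_max:
                hits.append(hit)
    if max_hsps_per_subject:
        best: dict[tuple[str, str], list[AlignmentHit]] = {}
        for h in hits:
            best.setdefault((h.query_id, h.subject_id), []).append(h)
        hits = []
        for group in best.values():
            group.sort(key=lambda h: (-h.bit_score, h.e_value))
            hits.extend(group[:max_hsps_per_subject])
    return hits


def write_tabular_hits(hits: list[AlignmentHit], path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        for h in hits:
            fh.write("\t".join(str(getattr(h, c)) for c in TABULAR_COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# Backend (ii): built-in k-mer seeded banded aligner
# ---------------------------------------------------------------------------

class KmerIndex:
    """Exact k-mer index over a sequence database."""

    def __init__(self, database: dict[str, str], k: int = 13):
        self.k = k
        self.db = database
        self.index: dict[str, list[tuple[str, int]]] = {}
        for sid, seq in database.items():
            for i in range(len(seq) - k + 1):
                self.index.setdefault(seq[i:i + k], []).append((sid, i))

    def seeds(self, query: str):
        k = self.k
        for qpos in range(len(query) - k + 1):
            for sid, spos in self.index.get(query[qpos:qpos + k], ()):
                yield sid, qpos, spos


def _chain_seeds(seeds, band: int = 25, max_gap: int = 2000):
    """Group (qpos, spos) seeds per subject into diagonal bands, then split
    bands at large subject gaps. Yields (qlo, qhi, slo, shi) candidate regions."""
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for sid, qpos, spos in seeds:
        by_subject.setdefault(sid, []).append((qpos, spos))
    for sid, pts in by_subject.items():
        pts.sort(key=lambda t: (t[1] - t[0], t[1]))  # by diagonal, then subject pos
        group: list[tuple[int, int]] = []
        for q, s in pts:
            if group and (abs((s - q) - (group[-1][1] - group[-1][0])) > band
                          or s - group[-1][1] > max_gap):
                yield sid, group
                group = []
            group.append((q, s))
        if group:
            yield sid, group


def _dedupe_contained(hits: list[AlignmentHit], slack: int = 10) -> list[AlignmentHit]:
    """Drop hits whose subject interval is contained (within ``slack``) in a
    higher-scoring hit on the same subject and strand — duplicate HSPs from
    overlapping seed chains."""
    keep: list[AlignmentHit] = []
    hits = sorted(hits, key=lambda h: (-h.bit_score, -h.alignment_length))
    for h in hits:
        lo, hi = h.subject_interval()
        contained = False
        for k in keep:
            if k.subject_id != h.subject_id or k.strand != h.strand:
                continue
            klo, khi = k.subject_interval()
            if lo >= klo - slack and hi <= khi + slack:
                contained = True
                break
        if not contained:
            keep.append(h)
    return keep


def map_sequences(queries: dict[str, str], database: dict[str, str],
                  min_identity: float = 0.90, min_length: int = 100,
                  k: int = 13, min_seeds: int = 3,
                  index: "KmerIndex | None" = None) -> list[AlignmentHit]:
    """Built-in local mapper: exact k-mer seeds, diagonal chaining, banded
    verification with edlib.

    Identity >= ``min_identity`` and alignment length >= ``min_length``
    serve as the e-value surrogate (``e_value`` is reported as 0.0 and
    ``bit_score`` as 2*matches - 3*(mismatches + gaps), a match-count
    surrogate adequate for best-hit ranking).
    """
    if not queries or not database:
        raise ValueError("both queries and database must be non-empty")
    idx = index if index is not None else KmerIndex(database, k=k)
    hits: list[AlignmentHit] = []
    for qid, qseq in queries.items():
        qhits: list[AlignmentHit] = []
        for strand, q in (("+", qseq), ("-", revcomp(qseq))):
            for sid, group in _chain_seeds(idx.seeds(q)):
                if len(group) < min_seeds:
                    continue
                qlo = min(p[0] for p in group)
                qhi = max(p[0] for p in group) + idx.k
                slo = min(p[1] for p in group)
                shi = max(p[1] for p in group) + idx.k
                sseq = idx.db[sid]
                pad = 30
                t_lo = max(0, slo - pad)
                t_hi = min(len(sseq), shi + pad)
                sub = q[qlo:qhi]
                res = edlib.align(sub, sseq[t_lo:t_hi], mode="HW", task="path")
                if res["editDistance"] < 0:
                    continue
                loc = res["locations"][0]
                matches = mism = gaps = gap_opens = 0
                prev = None
                num = ""
                for ch in res["cigar"]:
                    if ch.isdigit():
                        num += ch
                        continue
                    n = int(num)
                    num = ""
                    if ch == "=":
                        matches += n
                    elif ch == "X":
                        mism += n
                    else:
                        gaps += n
                        if prev != ch:
                            gap_opens += 1
                    prev = ch
                aln_len = matches + mism + gaps
                identity = matches / aln_len if aln_len else 0.0
                if aln_len < min_length or identity < min_identity:
                    continue
                s0 = t_lo + loc[0]  # 0-based
                s1 = t_lo + loc[1] + 1  # half-open
                if strand == "+":
                    qs, qe = qlo + 1, qhi
                    ss, se = s0 + 1, s1
                else:
                    # query coordinates reported on the forward query
                    qs = len(qseq) - qhi + 1
                    qe = len(qseq) - qlo
                    ss, se = s1, s0 + 1  # s_start > s_end encodes minus
                qhits.append(AlignmentHit(
                    query_id=qid, subject_id=sid,
                    percent_identity=round(identity * 100, 3),
                    alignment_length=aln_len, mismatches=mism,
                    gap_opens=gap_opens, q_start=qs, q_end=qe,
                    s_start=ss, s_end=se, e_value=0.0,
                    bit_score=float(2 * matches - 3 * (mism + gaps)),
                ))
        hits.extend(_dedupe_contained(qhits))
    return hits


# ---------------------------------------------------------------------------
# Hit selection and classification
# ---------------------------------------------------------------------------

def best_hit(hits: list[AlignmentHit]) -> AlignmentHit:
    """Deterministic best hit: highest bit score; ties broken by lowest
    e-value, longest alignment, then lexicographically smallest
    (subject_id, min(s_start, s_end))."""
    if not hits:
        raise ValueError("best_hit requires at least one hit")
    return min(hits, key=lambda h: (-h.bit_score, h.e_value, -h.alignment_length,
                                    h.subject_id, min(h.s_start, h.s_end)))


def classify_te_completeness(monomer_length: int, te_length: int,
                             te_coverage: int, cover_guard: float = 0.95) -> str:
    """Full vs partial TE call.

    Partial when the eccDNA is shorter than the TE; full when it is at
    least TE-length AND the alignment actually covers >= ``cover_guard`` of
    the TE (the coverage guard prevents a long eccDNA merely longer than an
    unrelated TE from being called full).
    """
    if monomer_length <= 0 or te_length <= 0 or te_coverage < 0:
        raise ValueError("lengths must be positive")
    if te_coverage > te_length:
        raise ValueError("te_coverage cannot exceed te_length")
    if monomer_length < te_length:
        return "partial"
    return "full" if te_coverage >= cover_guard * te_length else "partial"


def classify_origin(genome_hits, te_hits, cds_hits, family_map: dict[str, str] | None = None):
    """Origin class with TE > CDS > intergenic priority.

    Returns (origin_class, te_id, te_family, te_superfamily); requires at
    least one genome hit (unmapped monomers are handled upstream).
    """
    if not genome_hits:
        raise ValueError("classify_origin requires >=1 genome hit")
    if te_hits:
        top = best_hit(te_hits)
        te_id = top.subject_id
        family, superfamily = _split_te_label(te_id, family_map)
        return "TE", te_id, family, superfamily
    if cds_hits:
        return "CDS", None, None, None
    return "intergenic", None, None, None


def _split_te_label(te_id: str, family_map: dict[str, str] | None):
    """TE subject ids are '<te_id>|<family>'; superfamily joined from the map."""
    if "|" in te_id:
        _, family = te_id.split("|", 1)
    else:
        family = te_id
    if family_map is None or family not in family_map:
        return family, "unclassified"
    return family, family_map[family]


def merge_subject_intervals(hits: list[AlignmentHit], merge_gap: int = 100):
    """Merge hits on the same (subject, strand) whose intervals lie within
    ``merge_gap``. Returns [(subject_id, strand, lo, hi, covered_bp)]."""
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for h in hits:
        by_key.setdefault((h.subject_id, h.strand), []).append(h.subject_interval())
    loci = []
    for (sid, strand), ivs in by_key.items():
        ivs.sort()
        cur_lo, cur_hi = ivs[0]
        pieces = [(cur_lo, cur_hi)]
        for lo, hi in ivs[1:]:
            if lo <= cur_hi + merge_gap:
                cur_hi = max(cur_hi, hi)
                pieces.append((lo, hi))
            else:
                loci.append((sid, strand, cur_lo, cur_hi, _union_bp(pieces)))
                cur_lo, cur_hi = lo, hi
                pieces = [(lo, hi)]
        loci.append((sid, strand, cur_lo, cur_hi, _union_bp(pieces)))
    return loci


def _union_bp(intervals) -> int:
    total = 0
    cur_lo = cur_hi = None
    for lo, hi in sorted(intervals):
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                total += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        total += cur_hi - cur_lo
    return total


def classify_single_event(genome_hits: list[AlignmentHit], monomer_length: int,
                          merge_gap: int = 100, cover_fraction: float = 0.9) -> bool:
    """True iff one merged genomic locus covers >= ``cover_fraction`` of the
    monomer length (self-circularization of a single continuous fragment)."""
    if not genome_hits:
        raise ValueError("classify_single_event requires >=1 genome hit")
    loci = merge_subject_intervals(genome_hits, merge_gap)
    return any(cov >= cover_fraction * monomer_length for _, _, _, _, cov in loci)


def assign_window(chrom: str, start: int, end: int, window_size: int = 100_000,
                  chrom_lengths: dict[str, int] | None = None) -> tuple[str, int]:
    """Window index of a locus: floor(midpoint / window_size), 0-based
    half-open windows; the last window of a chromosome may be short."""
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if chrom_lengths is not None:
        if chrom not in chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > chrom_lengths[chrom]:
            raise ValueError(f"locus {chrom}:{start}-{end} outside chromosome bounds")
    mid = (start + end) // 2
    return chrom, mid // window_size


# ---------------------------------------------------------------------------
# Pipeline: annotate a set of monomers
# ---------------------------------------------------------------------------

def build_databases(genome: SimGenome):
    """Genome, TE and CDS sequence databases from a simulated genome.

    TE/CDS subject ids carry the family label after a '|' so downstream
    labeling needs no extra lookup table for the family itself.
    """
    genome_db = dict(genome.sequences)
    te_db = {f"{t.te_id}|{t.family}": genome.fetch(t.chrom, t.start, t.end, t.strand)
             for t in genome.te_features}
    cds_db = {c.cds_id: genome.fetch(c.chrom, c.start, c.end, c.strand)
              for c in genome.cds_features}
    return genome_db, te_db, cds_db


def annotate_monomers(
    monomers: dict[str, str],
    genome_db: dict[str, str],
    te_db: dict[str, str],
    cds_db: dict[str, str],
    family_map: dict[str, str],
    te_lengths: dict[str, int] | None = None,
    window_size: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
    min_identity: float = 0.90,
    min_length: int = 100,
    merge_gap: int = 100,
    cover_fraction: float = 0.9,
    cover_guard: float = 0.95,
    k: int = 13,
) -> tuple[list[EccAnnotation], list[str]]:
    """Annotate monomer sequences; returns (annotations, unmapped ids).

    Each monomer is mapped as its doubled sequence (monomer+monomer) so the
    arbitrary rotation phase of a circular consensus cannot split its locus
    into two HSPs at the junction; coordinates are then interpreted on the
    subject only.
    """
    if te_lengths is None:
        te_lengths = {sid: len(seq) for sid, seq in te_db.items()}
    genome_idx = KmerIndex(genome_db, k=k)
    te_idx = KmerIndex(te_db, k=k) if te_db else None
    cds_idx = KmerIndex(cds_db, k=k) if cds_db else None

    annotations: list[EccAnnotation] = []
    unmapped: list[str] = []
    for mid, seq in monomers.items():
        doubled = {mid: seq + seq}
        ghits = map_sequences(doubled, genome_db, min_identity, min_length,
                              k=k, index=genome_idx)
        # cap hit extents at the monomer length (a doubled query can at most
        # double-report the same subject interval; merging dedupes it)
        if not ghits:
            unmapped.append(mid)
            continue
        thits = (map_sequences(doubled, te_db, min_identity, min_length,
                               k=k, index=te_idx) if te_idx else [])
        chits = (map_sequences(doubled, cds_db, min_identity, min_length,
                               k=k, index=cds_idx) if cds_idx else [])
        origin, te_id, family, superfamily = classify_origin(ghits, thits, chits, family_map)

        completeness = "none"
        if origin == "TE":
            te_len = te_lengths[te_id]
            cov = 0
            for _, _, _, _, c in merge_subject_intervals(
                    [h for h in thits if h.subject_id == te_id], merge_gap):
                cov = max(cov, c)
            completeness = classify_te_completeness(len(seq), te_len,
                                                    min(cov, te_len), cover_guard)

        top = best_hit(ghits)
        lo, hi = top.subject_interval()
        # clip the best locus to one monomer length (doubled-query artifact)
        if hi - lo > len(seq):
            hi = lo + len(seq)
        single = classify_single_event(ghits, len(seq), merge_gap, cover_fraction)
        wchrom, wbin = assign_window(top.subject_id, lo, hi, window_size, chrom_lengths)
        annotations.append(EccAnnotation(
            monomer_id=mid, chrom=top.subject_id, start=lo, end=hi,
            strand=top.strand, window_chrom=wchrom, window_bin=wbin,
            origin_class=origin, te_id=te_id, te_family=family,
            te_superfamily=superfamily, te_completeness=completeness,
            single_event=single,
        ))
    return annotations, unmapped


def annotations_frame(annotations: list[EccAnnotation]) -> pd.DataFrame:
    from .io import dataclass_frame
    return dataclass_frame(annotations, EccAnnotation)
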