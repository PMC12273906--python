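"""Synthetic eccDNA study generator.

Builds a toy plant-like reference genome with planted transposable-element
(TE) and coding-sequence (CDS) annotation, simulates a population of
extrachromosomal circular DNAs (eccDNAs) drawn from TE, CDS and intergenic
loci, and emits rolling-circle-amplification (RCA) concatemer reads with
full ground-truth tables, so every downstream pipeline stage can be tested
without external data.

Defaults emulate the study conditions the pipeline targets: circles of
0.5-22 kb with mean length about 3.7 kb, concatemer reads of two or more
rounds with random rotation phase, substitution-dominated errors at the
0.1-1% level typical of high-accuracy circular-consensus reads, a minority
of chimeric (multi-locus) circles, and linear-fragment contaminants.

Coordinates are 0-based half-open throughout; exported GFF3 is 1-based
inclusive (see :mod:`eccpipe.io`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as eio

SUPERFAMILIES = (
    "RC/Helitron",
    "LTR/Copia",
    "LTR/Gypsy",
    "DNA/MuDR",
    "DNA/En-Spm",
    "LINE/L1",
)

#: Superfamily weights loosely mirroring the relative abundance of the major
#: TE superfamilies in a small crucifer genome (helitrons most numerous).
DEFAULT_SUPERFAMILY_WEIGHTS = {
    "RC/Helitron": 0.35,
    "DNA/MuDR": 0.20,
    "LTR/Gypsy": 0.15,
    "LTR/Copia": 0.15,
    "DNA/En-Spm": 0.10,
    "LINE/L1": 0.05,
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TEFeature:
    te_id: str
    family: str
    superfamily: str
    chrom: str
    start: int  # 0-based half-open
    end: int
    strand: str
    feature_type: str = "transposable_element"

    @property
    def feature_id(self) -> str:
        return self.te_id

    @property
    def length(self) -> int:
        return self.end - self.start

    def gff_attributes(self) -> str:
        return f"family={self.family};superfamily={self.superfamily}"


@dataclass
class CDSFeature:
    cds_id: str
    chrom: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"

    @property
    def feature_id(self) -> str:
        return self.cds_id

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class SimGenome:
    chrom_ids: list[str]
    sequences: dict[str, str]
    centromere_intervals: dict[str, tuple[int, int]]
    te_features: list[TEFeature]
    cds_features: list[CDSFeature]

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}

    def family_table(self) -> pd.DataFrame:
        rows = sorted({(t.family, t.superfamily) for t in self.te_features})
        return pd.DataFrame(rows, columns=["family", "superfamily"])

    def fetch(self, chrom: str, start: int, end: int, strand: str = "+") -> str:
        seq = self.sequences[chrom][start:end]
        return seq if strand == "+" else revcomp(seq)

    def write(self, outdir) -> dict[str, str]:
        """Write genome FASTA, GFF3 annotation, centromere BED, family TSV."""
        outdir = eio.ensure_dir(outdir)
        paths = {
            "genome_fasta": str(outdir / "genome.fa"),
            "annotation_gff3": str(outdir / "annotation.gff3"),
            "centromeres_bed": str(outdir / "centromeres.bed"),
            "family_tsv": str(outdir / "te_families.tsv"),
        }
        eio.write_fasta(self.sequences.items(), paths["genome_fasta"])
        eio.write_gff3(list(self.te_features) + list(self.cds_features), paths["annotation_gff3"])
        eio.write_bed(
            [(c, s, e, f"CEN_{c}") for c, (s, e) in self.centromere_intervals.items()],
            paths["centromeres_bed"],
        )
        eio.write_tsv(self.family_table(), paths["family_tsv"])
        return paths


@dataclass
class SimCircle:
    circle_id: str
    sequence: str
    origin_class: str  # TE_full | TE_partial | CDS | intergenic | chimeric
    origin_intervals: list[tuple[str, int, int, str]]
    source_te_id: str | None = None
    te_family: str | None = None
    te_superfamily: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimRead:
    read_id: str
    sequence: str
    qualities: list[int]
    true_circle_id: str | None
    true_rounds: float
    rotation_offset: int
    is_linear: bool


@dataclass
class TruthTable:
    """Ground-truth join of reads to circles and their origin labels."""

    circles: pd.DataFrame = field(default_factory=pd.DataFrame)
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)

    def write(self, outdir) -> dict[str, str]:
        outdir = eio.ensure_dir(outdir)
        paths = {
            "circles_tsv": str(outdir / "truth_circles.tsv"),
            "reads_tsv": str(outdir / "truth_reads.tsv"),
        }
        eio.write_tsv(self.circles, paths["circles_tsv"])
        eio.write_tsv(self.reads, paths["reads_tsv"])
        return paths


# ---------------------------------------------------------------------------
# Distribution specs
# ---------------------------------------------------------------------------

@dataclass
class ConstantDist:
    value: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return np.full(size, self.value, dtype=float)


@dataclass
class UniformDist:
    low: float
    high: float

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return rng.uniform(self.low, self.high, size=size)


@dataclass
class LognormalDist:
    """Lognormal length model clipped to a plausible molecule-size range.

    ``from_mean_median`` solves meanlog/sdlog from a target arithmetic mean
    and median: median = exp(mu), mean = exp(mu + sigma^2/2).
    """

    meanlog: float
    sdlog: float
    minimum: float = 500.0
    maximum: float = 22431.0

    @classmethod
    def from_mean_median(cls, mean: float, median: float, minimum: float = 500.0,
                         maximum: float = 22431.0) -> "LognormalDist":
        if mean <= median:
            raise ValueError("lognormal requires mean > median")
        mu = math.log(median)
        sigma = math.sqrt(2.0 * math.log(mean / median))
        return cls(meanlog=mu, sdlog=sigma, minimum=minimum, maximum=maximum)

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        x = rng.lognormal(self.meanlog, self.sdlog, size=size)
        return np.clip(x, self.minimum, self.maximum)


#: Default circle-length model: mean ~3,681 nt, median ~3,347 nt, clipped to
#: the 0.5-22.4 kb range of observed molecules.
DEFAULT_LENGTH_MODEL = LognormalDist.from_mean_median(3681.0, 3347.0)

#: Default concatemer rounds model: uniform 2-8 rounds.
DEFAULT_ROUNDS_MODEL = UniformDist(2.0, 8.0)

DEFAULT_CLASS_MIX = {"TE_full": 0.30, "TE_partial": 0.25, "CDS": 0.20, "intergenic": 0.25}


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------

_FAMILY_STEMS = {
    "RC/Helitron": "HELITRON",
    "LTR/Copia": "COPIA",
    "LTR/Gypsy": "GYPSY",
    "DNA/MuDR": "MUDR",
    "DNA/En-Spm": "ENSPM",
    "LINE/L1": "LINE1",
}


def _consensus_library(rng: np.random.Generator, superfamilies: list[str],
                       families_per_superfamily: int = 2) -> dict[str, tuple[str, str]]:
    """Per-family consensus sequences: {family: (superfamily, consensus)}."""
    lib: dict[str, tuple[str, str]] = {}
    for sf in superfamilies:
        stem = _FAMILY_STEMS.get(sf, sf.replace("/", "_"))
        for i in range(1, families_per_superfamily + 1):
            length = int(np.clip(rng.lognormal(math.log(1800), 0.5), 400, 6000))
            lib[f"{stem}{i}"] = (sf, _random_seq(rng, length))
    return lib


def _mutate(rng: np.random.Generator, seq: str, divergence: float) -> str:
    """Descend a consensus: substitutions at ``divergence``, indels at a tenth."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    sub = rng.random(codes.size) < divergence
    repl = rng.choice(_BASES, size=int(sub.sum()))
    codes[sub] = np.where(codes[sub] == repl, _BASES[(rng.integers(0, 4, repl.size))], repl)
    out = codes.tobytes().decode()
    n_indel = rng.poisson(divergence / 10 * len(out))
    for _ in range(n_indel):
        pos = int(rng.integers(0, len(out)))
        if rng.random() < 0.5 and len(out) > 50:
            out = out[:pos] + out[pos + 1:]
        else:
            out = out[:pos] + _random_seq(rng, 1) + out[pos:]
    return out


def _overlaps_any(start: int, end: int, intervals: list[tuple[int, int]], gap: int = 20) -> bool:
    return any(start < e + gap and s - gap < end for s, e in intervals)


def generate_genome(
    n_chroms: int = 2,
    chrom_length: int = 200_000,
    te_density: float = 0.25,
    superfamily_weights: dict[str, float] | None = None,
    centromere_fraction: float = 0.10,
    centromeric_multiplier: float = 5.0,
    te_divergence: float = 0.03,
    cds_per_100kb: float = 8.0,
    families_per_superfamily: int = 2,
    seed: int = 0,
) -> SimGenome:
    """Generate a toy genome with planted TE and CDS annotation.

    TE copies are mutated descendants of per-family consensus sequences;
    their placement probability per bp inside the centromere interval is
    ``centromeric_multiplier`` times the outside probability, emulating the
    centromeric/pericentromeric TE enrichment of repeat-rich plant genomes.

    Deterministic given ``seed``.
    """
    if superfamily_weights is None:
        superfamily_weights = dict(DEFAULT_SUPERFAMILY_WEIGHTS)
    if chrom_length < 50_000:
        raise ValueError("chrom_length must be >= 50,000 bp")
    if not 0.0 < te_density < 0.9:
        raise ValueError("te_density must lie in (0, 0.9)")
    if abs(sum(superfamily_weights.values()) - 1.0) > 1e-9:
        raise ValueError("superfamily_weights must sum to 1")
    rng = np.random.default_rng(seed)

    sfs = list(superfamily_weights)
    weights = np.array([superfamily_weights[s] for s in sfs], dtype=float)
    lib = _consensus_library(rng, sfs, families_per_superfamily)
    fams_by_sf = {sf: [f for f, (s, _) in lib.items() if s == sf] for sf in sfs}

    chrom_ids = [f"chr{i + 1}" for i in range(n_chroms)]
    cen_len = int(centromere_fraction * chrom_length)
    centromeres = {}
    for c in chrom_ids:
        mid = chrom_length // 2
        centromeres[c] = (mid - cen_len // 2, mid - cen_len // 2 + cen_len)
    max_te = max(len(cons) for _, cons in lib.values())
    if cen_len + max_te >= chrom_length:
        raise ValueError("chromosome too short for its centromere plus one TE")

    sequences = {c: np.frombuffer(_random_seq(rng, chrom_length).encode(), dtype=np.uint8).copy()
                 for c in chrom_ids}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_ids}

    te_features: list[TEFeature] = []
    target_bp = te_density * n_chroms * chrom_length
    planted_bp = 0
    te_idx = 0
    # region sampling weights: centromere bp count centromeric_multiplier times
    cen_w = centromeric_multiplier * cen_len
    arm_w = chrom_length - cen_len
    attempts = 0
    while planted_bp < target_bp and attempts < 50 * n_chroms * 1000:
        attempts += 1
        sf = sfs[int(rng.choice(len(sfs), p=weights))]
        fam = fams_by_sf[sf][int(rng.integers(0, len(fams_by_sf[sf])))]
        copy = _mutate(rng, lib[fam][1], te_divergence)
        L = len(copy)
        chrom = chrom_ids[int(rng.integers(0, n_chroms))]
        cs, ce = centromeres[chrom]
        in_cen = rng.random() < cen_w / (cen_w + arm_w)
        placed = False
        for _ in range(40):
            if in_cen:
                if ce - cs <= L:
                    break
                start = int(rng.integers(cs, ce - L))
            else:
                start = int(rng.integers(0, chrom_length - L))
                if start < ce and cs < start + L:
                    continue  # keep arm placements out of the centromere
            if _overlaps_any(start, start + L, occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            ins = copy if strand == "+" else revcomp(copy)
            sequences[chrom][start:start + L] = np.frombuffer(ins.encode(), dtype=np.uint8)
            te_idx += 1
            te_features.append(TEFeature(f"TE{te_idx:05d}", fam, sf, chrom, start, start + L, strand))
            occupied[chrom].append((start, start + L))
            planted_bp += L
            placed = True
            break
        if not placed:
            continue

    cds_features: list[CDSFeature] = []
    cds_idx = 0
    n_cds = int(cds_per_100kb * chrom_length / 100_000)
    for chrom in chrom_ids:
        cs, ce = centromeres[chrom]
        placed = 0
        tries = 0
        while placed < n_cds and tries < 50 * n_cds:
            tries += 1
            L = int(rng.integers(300, 3000))
            start = int(rng.integers(0, chrom_length - L))
            if start < ce and cs < start + L:
                continue  # genes live on the arms
            if _overlaps_any(start, start + L, occupied[chrom]):
                continue
            cds_idx += 1
            strand = "+" if rng.random() < 0.5 else "-"
            cds_features.append(CDSFeature(f"CDS{cds_idx:05d}", chrom, start, start + L, strand))
            occupied[chrom].append((start, start + L))
            placed += 1

    seqs = {c: a.tobytes().decode() for c, a in sequences.items()}
    return SimGenome(chrom_ids, seqs, centromeres, te_features, cds_features)


# ---------------------------------------------------------------------------
# Circle simulation
# ---------------------------------------------------------------------------

def _interval_overlaps_features(chrom, start, end, features, gap: int = 0) -> bool:
    return any(f.chrom == chrom and start < f.end + gap and f.start - gap < end
               for f in features)


def _circle_sequence(genome: SimGenome, intervals) -> str:
    return "".join(genome.fetch(c, s, e, st) for c, s, e, st in intervals)


def simulate_circles(
    genome: SimGenome,
    n: int,
    class_mix: dict[str, float] | None = None,
    length_model=None,
    chimeric_rate: float = 0.05,
    flank_max: int = 500,
    min_length: int = 300,
    seed: int = 0,
) -> tuple[list[SimCircle], TruthTable]:
    """Simulate an eccDNA circle population from a :class:`SimGenome`.

    Each circle's sequence is the concatenation of its origin intervals'
    genomic sequence (reverse-complemented on the minus strand). ``TE_full``
    circles fully contain a planted TE (with short random flanks that do not
    touch other features); ``TE_partial`` circles truncate one; ``CDS`` and
    ``intergenic`` circles draw their length from ``length_model``; a
    ``chimeric_rate`` fraction join two distant loci.
    """
    if class_mix is None:
        class_mix = dict(DEFAULT_CLASS_MIX)
    unknown = set(class_mix) - {"TE_full", "TE_partial", "CDS", "intergenic"}
    if unknown:
        raise ValueError(f"unknown circle classes: {sorted(unknown)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    if length_model is None:
        length_model = DEFAULT_LENGTH_MODEL
    rng = np.random.default_rng(seed)

    classes = list(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs = probs / probs.sum()
    if ("TE_full" in classes or "TE_partial" in classes) and not genome.te_features:
        raise ValueError("genome has no TE features but a TE circle class was requested")
    if "CDS" in classes and not genome.cds_features:
        raise ValueError("genome has no CDS features but the CDS circle class was requested")

    all_feats = list(genome.te_features) + list(genome.cds_features)
    chrom_lengths = genome.chrom_lengths
    circles: list[SimCircle] = []
    rows = []

    def sample_intergenic_interval(L: int):
        for _ in range(200):
            chrom = genome.chrom_ids[int(rng.integers(0, len(genome.chrom_ids)))]
            if chrom_lengths[chrom] <= L:
                continue
            start = int(rng.integers(0, chrom_lengths[chrom] - L))
            if not _interval_overlaps_features(chrom, start, start + L, all_feats):
                strand = "+" if rng.random() < 0.5 else "-"
                return (chrom, start, start + L, strand)
        return None

    i = 0
    guard = 0
    while i < n and guard < 100 * n:
        guard += 1
        cls = "chimeric" if rng.random() < chimeric_rate else classes[int(rng.choice(len(classes), p=probs))]
        intervals = None
        source_te = None
        if cls == "TE_full":
            te = genome.te_features[int(rng.integers(0, len(genome.te_features)))]
            lf = int(rng.integers(0, flank_max + 1))
            rf = int(rng.integers(0, flank_max + 1))
            start = max(0, te.start - lf)
            end = min(chrom_lengths[te.chrom], te.end + rf)
            others = [f for f in all_feats if f is not te]
            if _interval_overlaps_features(te.chrom, start, end, others):
                # shrink to the bare element; its immediate flanks stay clean
                start, end = te.start, te.end
                if _interval_overlaps_features(te.chrom, start, end, others):
                    continue
            strand = "+" if rng.random() < 0.5 else "-"
            intervals = [(te.chrom, start, end, strand)]
            source_te = te
        elif cls == "TE_partial":
            candidates = [t for t in genome.te_features if t.length >= max(2 * min_length, 400)]
            if not candidates:
                raise ValueError("genome lacks TEs long enough for TE_partial circles")
            te = candidates[int(rng.integers(0, len(candidates)))]
            frac = rng.uniform(0.3, 0.9)
            L = max(min_length, int(frac * te.length))
            L = min(L, te.length - 1)  # strictly shorter than the source TE
            start = te.start + int(rng.integers(0, te.length - L))
            strand = "+" if rng.random() < 0.5 else "-"
            intervals = [(te.chrom, start, start + L, strand)]
            source_te = te
        elif cls == "CDS":
            cds = genome.cds_features[int(rng.integers(0, len(genome.cds_features)))]
            L = int(max(min_length, length_model.sample(rng, 1)[0]))
            anchor = int(rng.integers(cds.start, cds.end))
            start = max(0, min(anchor - L // 2, chrom_lengths[cds.chrom] - L))
            end = start + L
            if _interval_overlaps_features(cds.chrom, start, end, genome.te_features):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            intervals = [(cds.chrom, start, end, strand)]
        elif cls == "intergenic":
            L = int(max(min_length, length_model.sample(rng, 1)[0]))
            iv = sample_intergenic_interval(L)
            if iv is None:
                continue
            intervals = [iv]
        else:  # chimeric
            L = int(max(2 * min_length, length_model.sample(rng, 1)[0]))
            iv1 = sample_intergenic_interval(L // 2)
            iv2 = sample_intergenic_interval(L - L // 2)
            if iv1 is None or iv2 is None:
                continue
            # require non-adjacent loci: different chromosome or >= 10 kb apart
            if iv1[0] == iv2[0] and abs(iv1[1] - iv2[1]) < 10_000:
                continue
            intervals = [iv1, iv2]

        i += 1
        cid = f"circle{i:05d}"
        seq = _circle_sequence(genome, intervals)
        circles.append(SimCircle(
            cid, seq, cls, intervals,
            source_te_id=source_te.te_id if source_te else None,
            te_family=source_te.family if source_te else None,
            te_superfamily=source_te.superfamily if source_te else None,
        ))
        rows.append({
            "circle_id": cid,
            "origin_class": cls,
            "length": len(seq),
            "origin_intervals": ";".join(f"{c}:{s}-{e}:{st}" for c, s, e, st in intervals),
            "source_te_id": source_te.te_id if source_te else "",
            "te_family": source_te.family if source_te else "",
            "te_superfamily": source_te.superfamily if source_te else "",
        })
    if i < n:
        raise ValueError("could not place the requested number of circles; genome too crowded")
    return circles, TruthTable(circles=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# RCA read simulation
# ---------------------------------------------------------------------------

def rotate(seq: str, k: int) -> str:
    """Rotate a circular sequence so it starts at position ``k``."""
    k %= len(seq)
    return seq[k:] + seq[:k]


def concatemerize(circle_seq: str, rounds: float, offset: int = 0) -> str:
    """Error-free RCA product: rotated circle repeated ``rounds`` times.

    The trailing repeat may be fractional; its length is rounded to the
    nearest base.
    """
    L = len(circle_seq)
    rotated = rotate(circle_seq, offset)
    full = int(rounds)
    frac_len = int(round((rounds - full) * L))
    return rotated * full + rotated[:frac_len]


def _apply_errors(rng: np.random.Generator, seq: str, error_rate: float,
                  mix=(8, 1, 1)) -> tuple[str, np.ndarray]:
    """Corrupt ``seq`` with i.i.d. substitutions/insertions/deletions.

    Returns (corrupted sequence, phred qualities). Error positions receive
    low phred values, correct positions high ones, emulating calibrated
    consensus-read quality strings.
    """
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    L = codes.size
    qual = np.clip(np.rint(rng.normal(37.0, 2.0, L)), 33, 41).astype(np.int16)
    if error_rate > 0 and L:
        err = rng.random(L) < error_rate
        idx = np.flatnonzero(err)
        kinds = rng.choice(3, size=idx.size, p=np.asarray(mix, float) / sum(mix))
        sub_idx = idx[kinds == 0]
        ins_idx = idx[kinds == 1]
        del_idx = idx[kinds == 2]
        if sub_idx.size:
            shift = rng.integers(1, 4, sub_idx.size)
            base_i = np.searchsorted(_BASES, codes[sub_idx])
            codes[sub_idx] = _BASES[(base_i + shift) % 4]
            qual[sub_idx] = np.clip(np.rint(rng.normal(15.0, 4.0, sub_idx.size)), 3, 25)
        counts = np.ones(L, dtype=np.int64)
        counts[del_idx] = 0
        counts[ins_idx] = 2
        out = np.repeat(codes, counts)
        qual_out = np.repeat(qual, counts)
        if ins_idx.size:
            # position of the duplicated copy inside the expanded array
            dup_pos = np.cumsum(counts)[ins_idx] - 1
            out[dup_pos] = rng.choice(_BASES, size=ins_idx.size)
            qual_out[dup_pos] = np.clip(np.rint(rng.normal(15.0, 4.0, ins_idx.size)), 3, 25)
        codes, qual = out, qual_out
    return codes.tobytes().decode(), qual


def simulate_rca_reads(
    circles: list[SimCircle],
    rounds_model=None,
    error_rate: float = 0.01,
    linear_contaminant_rate: float = 0.10,
    min_read_length: int = 3000,
    genome: SimGenome | None = None,
    reads_per_circle: int = 1,
    error_mix=(8, 1, 1),
    seed: int = 0,
) -> tuple[list[SimRead], TruthTable]:
    """Emit RCA concatemer reads (plus linear contaminants) with truth records.

    A circular read is the circle sequence rotated by a uniform random
    offset, tandemly repeated ``rounds`` times (fractional last repeat), then
    corrupted at ``error_rate`` with a substitution:insertion:deletion mix of
    ``error_mix`` (default 8:1:1 — consensus long reads are substitution
    dominated). Linear contaminants are genome fragments (``true_rounds`` 1).
    Reads shorter than ``min_read_length`` are dropped but logged in the
    truth table (``dropped`` column), so record counts are conserved.
    """
    if not 0.0 <= error_rate <= 0.05:
        raise ValueError("error_rate must lie in [0, 0.05]")
    if linear_contaminant_rate < 0:
        raise ValueError("linear_contaminant_rate must be non-negative")
    if linear_contaminant_rate > 0 and genome is None:
        raise ValueError("linear contaminants require the genome")
    if rounds_model is None:
        rounds_model = DEFAULT_ROUNDS_MODEL
    rng = np.random.default_rng(seed)

    reads: list[SimRead] = []
    rows = []
    ridx = 0

    def emit(read: SimRead, clean_length: int):
        nonlocal ridx
        dropped = len(read.sequence) < min_read_length
        rows.append({
            "read_id": read.read_id,
            "circle_id": read.true_circle_id or "",
            "true_rounds": read.true_rounds,
            "rotation_offset": read.rotation_offset,
            "is_linear": read.is_linear,
            "read_length": len(read.sequence),
            "clean_length": clean_length,
            "dropped": dropped,
        })
        if not dropped:
            reads.append(read)

    for circle in circles:
        L = circle.length
        for _ in range(reads_per_circle):
            ridx += 1
            rounds = float(rounds_model.sample(rng, 1)[0])
            if rounds <= 0:
                raise ValueError("rounds_model produced a non-positive value")
            offset = int(rng.integers(0, L))
            clean = concatemerize(circle.sequence, rounds, offset)
            true_rounds = len(clean) / L
            seq, qual = _apply_errors(rng, clean, error_rate, error_mix)
            emit(SimRead(f"read{ridx:06d}", seq, qual.tolist(), circle.circle_id,
                         true_rounds, offset, False), len(clean))

    n_linear = int(round(linear_contaminant_rate * len(circles) * reads_per_circle))
    if n_linear and circles:
        lengths = np.array([c.length for c in circles])
        for _ in range(n_linear):
            ridx += 1
            frag_len = int(lengths[int(rng.integers(0, lengths.size))] * rng.uniform(1.2, 3.0))
            chrom = genome.chrom_ids[int(rng.integers(0, len(genome.chrom_ids)))]
            clen = genome.chrom_lengths[chrom]
            frag_len = min(frag_len, clen - 1)
            start = int(rng.integers(0, clen - frag_len))
            strand = "+" if rng.random() < 0.5 else "-"
            clean = genome.fetch(chrom, start, start + frag_len, strand)
            seq, qual = _apply_errors(rng, clean, error_rate, error_mix)
            emit(SimRead(f"read{ridx:06d}", seq, qual.tolist(), None, 1.0, 0, True), len(clean))

    truth_reads = pd.DataFrame(rows)
    if len(truth_reads) and truth_reads["dropped"].mean() > 0.5:
        warnings.warn("min_read_length excludes more than half of the simulated reads")
    return reads, TruthTable(reads=truth_reads)


def reads_to_fastq(reads: list[SimRead], path) -> None:
    eio.write_fastq(((r.read_id, r.sequence, r.qualities) for r in reads), path)
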