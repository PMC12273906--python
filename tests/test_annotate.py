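"""Annotation: mapping backends, hit selection, origin/completeness/window calls."""

import numpy as np
import pytest

from eccpipe import annotate as an
from eccpipe import simdata as sd


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestBuiltinMapper:
    def test_exact_substring_hit(self):
        rng = np.random.default_rng(0)
        chrom = _random_seq(rng, 10_000)
        query = chrom[4000:5000]
        hits = an.map_sequences({"q": query}, {"chr1": chrom})
        assert len(hits) == 1
        h = hits[0]
        assert h.percent_identity == 100.0
        assert h.alignment_length == 1000
        assert (h.s_start, h.s_end) == (4001, 5000)  # 1-based inclusive
        assert h.strand == "+"

    def test_reverse_complement_encodes_minus_strand(self):
        rng = np.random.default_rng(1)
        chrom = _random_seq(rng, 10_000)
        query = sd.revcomp(chrom[4000:5000])
        hits = an.map_sequences({"q": query}, {"chr1": chrom})
        assert len(hits) == 1
        h = hits[0]
        assert h.s_start > h.s_end
        assert h.subject_interval() == (4000, 5000)

    def test_identity_and_length_filters(self):
        rng = np.random.default_rng(2)
        chrom = _random_seq(rng, 5_000)
        hits = an.map_sequences({"q": chrom[100:180]}, {"chr1": chrom}, min_length=100)
        assert hits == []  # 80 bp < surrogate length floor

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            an.map_sequences({}, {"chr1": "ACGT"})


class TestTabularReader:
    LINE = "q1\tchr1\t98.5\t1000\t10\t2\t1\t1000\t5001\t6000\t{e}\t1800.0"

    def _write(self, tmp_path, lines):
        p = tmp_path / "hits.tab"
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_evalue_filter_applied_verbatim(self, tmp_path):
        p = self._write(tmp_path, [self.LINE.format(e="1e-40"), self.LINE.format(e="1e-60")])
        hits = an.read_tabular_hits(p, evalue_max=1e-50)
        assert len(hits) == 1
        assert hits[0].e_value == 1e-60

    def test_one_hsp_per_subject(self, tmp_path):
        lines = [
            "q1\tchr1\t98.0\t900\t10\t2\t1\t900\t1\t900\t1e-60\t1500.0",
            "q1\tchr1\t99.0\t800\t5\t1\t1\t800\t2000\t2800\t1e-70\t1600.0",
        ]
        hits = an.read_tabular_hits(self._write(tmp_path, lines))
        assert len(hits) == 1
        assert hits[0].bit_score == 1600.0

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = self._write(tmp_path, ["q1\tchr1\tonly\tthree"])
        with pytest.raises(ValueError, match=":1:"):
            an.read_tabular_hits(p)

    def test_eleven_fields_rejected(self, tmp_path):
        p = self._write(tmp_path, ["\t".join(["x"] * 11)])
        with pytest.raises(ValueError, match="11"):
            an.read_tabular_hits(p)


def _hit(**kw):
    base = dict(query_id="q", subject_id="chr1", percent_identity=99.0,
                alignment_length=500, mismatches=1, gap_opens=0, q_start=1,
                q_end=500, s_start=1, s_end=500, e_value=1e-80, bit_score=900.0)
    base.update(kw)
    return an.AlignmentHit(**base)


class TestBestHit:
    def test_highest_bit_score_wins(self):
        assert an.best_hit([_hit(bit_score=500.0), _hit(bit_score=420.0)]).bit_score == 500.0

    def test_full_tie_lexicographic_subject(self):
        h = an.best_hit([_hit(subject_id="chr2"), _hit(subject_id="chr10")])
        assert h.subject_id == "chr10"

    def test_matches_bruteforce_ordering(self):
        rng = np.random.default_rng(3)
        def key(h):
            return (-h.bit_score, h.e_value, -h.alignment_length,
                    h.subject_id, min(h.s_start, h.s_end))
        for _ in range(1000):
            hits = [
                _hit(bit_score=float(rng.integers(1, 5)) * 100,
                     e_value=float(rng.choice([1e-80, 1e-60])),
                     alignment_length=int(rng.integers(1, 4)) * 100,
                     subject_id=f"chr{rng.integers(1, 4)}",
                     s_start=int(rng.integers(1, 1000)))
                for _ in range(int(rng.integers(1, 6)))
            ]
            assert an.best_hit(hits) is sorted(hits, key=key)[0]


class TestClassifiers:
    def test_te_completeness_length_rule(self):
        assert an.classify_te_completeness(1200, 1500, 1200) == "partial"
        assert an.classify_te_completeness(1500, 1500, 1500) == "full"
        # coverage guard: long eccDNA covering only 92% of an unrelated TE
        assert an.classify_te_completeness(5000, 1000, 920) == "partial"

    def test_te_completeness_input_validation(self):
        with pytest.raises(ValueError):
            an.classify_te_completeness(0, 100, 50)
        with pytest.raises(ValueError):
            an.classify_te_completeness(100, 100, 150)

    def test_origin_priority_te_over_cds(self):
        g = [_hit()]
        te = [_hit(subject_id="TE1|FAM")]
        cds = [_hit(subject_id="CDS1")]
        assert an.classify_origin(g, te, cds, {"FAM": "LTR/Copia"})[0] == "TE"
        assert an.classify_origin(g, [], cds)[0] == "CDS"
        assert an.classify_origin(g, [], [])[0] == "intergenic"

    def test_origin_requires_genome_hit(self):
        with pytest.raises(ValueError):
            an.classify_origin([], [], [])

    def test_unknown_family_labeled_unclassified(self):
        _, te_id, fam, sf = an.classify_origin([_hit()], [_hit(subject_id="TE9|NOVEL")], [],
                                               {"OTHER": "LTR/Gypsy"})
        assert fam == "NOVEL" and sf == "unclassified"

    def test_single_event_one_full_cover(self):
        assert an.classify_single_event([_hit(s_start=1, s_end=1000)], 1000)

    def test_single_event_split_loci(self):
        hits = [_hit(subject_id="chr1", s_start=1, s_end=500),
                _hit(subject_id="chr2", s_start=1, s_end=500)]
        assert not an.classify_single_event(hits, 1000)

    def test_single_event_merges_adjacent_hits(self):
        hits = [_hit(s_start=1, s_end=500), _hit(s_start=551, s_end=1050)]
        assert an.classify_single_event(hits, 1000, merge_gap=100)

    def test_assign_window(self):
        assert an.assign_window("chr1", 150_000, 151_000) == ("chr1", 1)
        assert an.assign_window("chr1", 199_500, 200_500) == ("chr1", 2)  # midpoint 200,000
        assert an.assign_window("chr1", 10, 50, window_size=1_000_000,
                                chrom_lengths={"chr1": 1_000_000}) == ("chr1", 0)
        with pytest.raises(ValueError):
            an.assign_window("chr1", -5, 100, chrom_lengths={"chr1": 1000})
        with pytest.raises(ValueError):
            an.assign_window("chrX", 0, 10, chrom_lengths={"chr1": 1000})


class TestAnnotationPipeline:
    def test_errorfree_labels_match_truth(self, errorfree_annotations, circle_population):
        """On error-free monomers every origin class, TE identity and
        full/partial label matches the simulator's ground truth."""
        annotations, unmapped = errorfree_annotations
        circles, _ = circle_population
        truth = {c.circle_id: c for c in circles}
        assert not unmapped
        expect = {"TE_full": "TE", "TE_partial": "TE", "CDS": "CDS",
                  "intergenic": "intergenic", "chimeric": "intergenic"}
        for a in annotations:
            t = truth[a.monomer_id]
            assert a.origin_class == expect[t.origin_class]
            if t.origin_class == "TE_full":
                assert a.te_completeness == "full"
                assert a.te_id.split("|")[0] == t.source_te_id
            if t.origin_class == "TE_partial":
                assert a.te_completeness == "partial"
                assert a.te_id.split("|")[0] == t.source_te_id

    def test_errorfree_single_event_matches_truth(self, errorfree_annotations,
                                                  circle_population):
        annotations, _ = errorfree_annotations
        circles, _ = circle_population
        truth = {c.circle_id: c for c in circles}
        agree = sum((truth[a.monomer_id].origin_class != "chimeric") == a.single_event
                    for a in annotations)
        assert agree / len(annotations) >= 0.95

    def test_every_monomer_annotated_or_unmapped(self, errorfree_annotations,
                                                 circle_population):
        annotations, unmapped = errorfree_annotations
        circles, _ = circle_population
        assert len(annotations) + len(unmapped) == len(circles)
        assert not (set(a.monomer_id for a in annotations) & set(unmapped))


class TestAgainstBlastOracle:
    def test_best_locus_agrees_with_blastn(self, genome, circle_population, tmp_path):
        """The built-in mapper's best locus matches blastn's on error-free
        single-locus monomers (independent external oracle)."""
        import shutil
        import subprocess
        if not (shutil.which("blastn") and shutil.which("makeblastdb")):
            pytest.skip("BLAST+ not on PATH")
        from eccpipe import io as eio
        circles, _ = circle_population
        single = [c for c in circles if c.origin_class in ("intergenic", "CDS")][:10]
        eio.write_fasta(genome.sequences.items(), tmp_path / "genome.fa")
        eio.write_fasta([(c.circle_id, c.sequence) for c in single], tmp_path / "q.fa")
        subprocess.run(["makeblastdb", "-in", str(tmp_path / "genome.fa"),
                        "-dbtype", "nucl"], check=True, capture_output=True)
        res = subprocess.run(
            ["blastn", "-query", str(tmp_path / "q.fa"), "-db", str(tmp_path / "genome.fa"),
             "-outfmt", "6", "-max_hsps", "1", "-max_target_seqs", "5"],
            check=True, capture_output=True, text=True)
        (tmp_path / "hits.tab").write_text(res.stdout)
        blast_hits = an.read_tabular_hits(tmp_path / "hits.tab", evalue_max=1e-50)
        blast_best = {}
        for qid in {h.query_id for h in blast_hits}:
            blast_best[qid] = an.best_hit([h for h in blast_hits if h.query_id == qid])
        own = an.map_sequences({c.circle_id: c.sequence for c in single},
                               dict(genome.sequences))
        for c in single:
            mine = an.best_hit([h for h in own if h.query_id == c.circle_id])
            oracle = blast_best[c.circle_id]
            assert mine.subject_id == oracle.subject_id
            olo, ohi = oracle.subject_interval()
            mlo, mhi = mine.subject_interval()
            assert abs(mlo - olo) <= 5 and abs(mhi - ohi) <= 5
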