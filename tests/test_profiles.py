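"""PSSM parsing, logistic scaling and column conservation statistics."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nabind.features import load_feature_table
from nabind.profiles import (
    AlignmentConsistencyError,
    PairwiseHit,
    PSSMFormatError,
    build_column_observations,
    column_feature_stats,
    conservation_profile,
    read_pairwise_tab,
    read_pssm,
    run_psiblast,
    scale_pssm_scores,
)
from nabind.synthetic import (
    PSIBLAST_ALPHABET,
    alignment_observations,
    pssm_from_alignment,
    synth_alignment,
    write_pssm_ascii,
)

TABLE = load_feature_table()


class TestReadPssm:
    def _write(self, tmp_path, rows, alphabet=PSIBLAST_ALPHABET):
        path = tmp_path / "q.pssm"
        lines = ["", "Last position-specific scoring matrix computed",
                 "            " + "  ".join(alphabet)]
        for i, (aa, scores) in enumerate(rows, start=1):
            lines.append(f"{i:5d} {aa}  " + " ".join(f"{s:3d}" for s in scores))
        path.write_text("\n".join(lines) + "\n")
        return path

    def test_row_and_score_counts(self, tmp_path):
        rows = [("A", [1] * 20)] * 5
        profile = read_pssm(self._write(tmp_path, rows))
        assert len(profile) == 5
        assert profile.scores.shape == (5, 20)

    def test_identity_cell_read_back(self, tmp_path):
        scores = [0] * 20
        scores[PSIBLAST_ALPHABET.index("A")] = 4
        profile = read_pssm(self._write(tmp_path, [("A", scores)]))
        assert profile.scores[0, PSIBLAST_ALPHABET.index("A")] == 4
        assert profile.query == "A"

    def test_short_row_raises_format_error(self, tmp_path):
        path = self._write(tmp_path, [("A", [1] * 19)])
        with pytest.raises(PSSMFormatError):
            read_pssm(path)

    def test_roundtrip_through_ascii_writer(self, tmp_path):
        rows = synth_alignment("ACDEFGHIKL", 8, [2, 3], seed=3)
        pssm = pssm_from_alignment("q", alignment_observations("ACDEFGHIKL", rows))
        write_pssm_ascii(pssm, tmp_path / "w.pssm")
        back = read_pssm(tmp_path / "w.pssm")
        assert np.array_equal(back.scores, pssm.scores)
        assert back.alphabet == pssm.alphabet


class TestScalePssm:
    def test_midpoint_and_known_value(self):
        assert scale_pssm_scores(0) == 0.5
        assert scale_pssm_scores(2) == pytest.approx(0.8807970779778823)

    @given(st.floats(min_value=-30, max_value=30))
    def test_symmetry_about_zero(self, x):
        assert scale_pssm_scores(x) + scale_pssm_scores(-x) == pytest.approx(1.0)

    def test_preserves_score_ordering(self, rng):
        raw = rng.integers(-10, 12, size=50)
        scaled = scale_pssm_scores(raw)
        assert np.array_equal(np.argsort(raw, kind="stable"),
                              np.argsort(scaled, kind="stable"))


class TestColumnObservations:
    def test_query_only_gives_singleton_columns(self):
        obs = build_column_observations("ACDEF")
        assert obs.counts().tolist() == [1, 1, 1, 1, 1]

    def test_msa_gap_excluded(self, tmp_path):
        aln = tmp_path / "a.fa"
        aln.write_text(">q\nACD\n>h1\nA-D\n>h2\nGCD\n")
        obs = build_column_observations("ACD", msa=aln)
        assert obs.counts().tolist() == [3, 2, 3]
        assert obs.columns[1] == ["C", "C"]

    def test_msa_query_mismatch_raises(self, tmp_path):
        aln = tmp_path / "a.fa"
        aln.write_text(">q\nACD\n>h1\nACD\n")
        with pytest.raises(AlignmentConsistencyError):
            build_column_observations("ACE", msa=aln)

    def test_pairwise_best_hsp_wins_per_position(self):
        # two overlapping local alignments from one homologue: the higher-
        # scoring one must supply the residue wherever both cover a position
        query = "ACDEFGHIK"
        hits = [
            PairwiseHit("q", "h1", 1, 5, 1, 5, "ACDEF", "AAAAA", score=10.0),
            PairwiseHit("q", "h1", 3, 9, 1, 7, "DEFGHIK", "CCCCCCC", score=20.0),
        ]
        obs = build_column_observations(query, pairwise=hits)
        expected = [["A"], ["A"], ["C"], ["C"], ["C"], ["C"], ["C"], ["C"], ["C"]]
        for i, extra in enumerate(expected):
            assert obs.columns[i] == [query[i]] + extra

    def test_pairwise_span_limits_contribution(self):
        hits = [PairwiseHit("q", "h1", 2, 3, 1, 2, "CD", "MW", score=1.0)]
        obs = build_column_observations("ACDEF", pairwise=hits)
        assert obs.counts().tolist() == [1, 2, 2, 1, 1]

    def test_pairwise_tab_roundtrip(self, tmp_path):
        path = tmp_path / "hits.tab"
        path.write_text("q\th1\t2\t3\t1\t2\tCD\tMW\t7.5\n")
        (hit,) = read_pairwise_tab(path)
        assert (hit.subject_id, hit.qstart, hit.score) == ("h1", 2, 7.5)


class TestColumnFeatureStats:
    def test_two_point_population_sd(self):
        # residues with raw H = 2.5 (C) and 4.5 (I): mean 3.5, sd 1.0
        mean, sd = column_feature_stats(["C", "I"], "H", TABLE)
        assert (mean, sd) == (pytest.approx(3.5), pytest.approx(1.0))

    def test_singleton_column(self):
        mean, sd = column_feature_stats(["R"], "K", TABLE)
        assert mean == pytest.approx(12.48)
        assert sd == 0.0

    def test_four_point_example(self):
        # synthetic feature values {1, 2, 3, 4}: mean 2.5, population sd
        # sqrt(5/4) ~= 1.1180
        values = {"A": 1.0, "C": 2.0, "D": 3.0, "E": 4.0}
        from nabind.features import STANDARD_AA, FeatureTable

        raw = {a: (values.get(a, 0.0), 0.0 if a != "W" else 1.0,
                   1.0 if a == "Y" else 0.0) for a in STANDARD_AA}
        table = FeatureTable(raw=raw)
        mean, sd = column_feature_stats(["A", "C", "D", "E"], "H", table)
        assert mean == pytest.approx(2.5)
        assert sd == pytest.approx(1.1180339887498949)

    def test_matches_two_pass_brute_force(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(50):
            col = list(rng.choice(letters, size=rng.integers(1, 12)))
            for feature in ("H", "K", "M"):
                mean, sd = column_feature_stats(col, feature, TABLE)
                vals = [TABLE.value(a, feature) for a in col]
                m = sum(vals) / len(vals)
                v = sum((x - m) ** 2 for x in vals) / len(vals)
                assert mean == pytest.approx(m, abs=1e-9)
                assert sd**2 == pytest.approx(v, abs=1e-9)

    def test_consensus_addition_never_increases_sd(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(25):
            col = list(rng.choice(letters, size=rng.integers(2, 8)))
            for feature in ("H", "K", "M"):
                vals = [TABLE.value(a, feature) for a in col]
                consensus = col[int(np.argmin([abs(v - np.mean(vals))
                                               for v in vals]))]
                _, sd0 = column_feature_stats(col, feature, TABLE)
                _, sd1 = column_feature_stats(col + [consensus], feature, TABLE)
                assert sd1 <= sd0 + 1e-12


class TestConservationProfile:
    def test_fully_conserved_alignment_has_zero_sd(self):
        query = "MKRLV"
        rows = [query] * 6  # zero mutation rate: perfect conservation
        obs = alignment_observations(query, rows)
        prof = conservation_profile(obs, TABLE)
        assert np.allclose(prof.sds, 0.0)
        for i, aa in enumerate(query):
            expected = [TABLE.value(aa, f) for f in ("H", "K", "M")]
            assert np.allclose(prof.means[i], expected)

    def test_scaled_descriptors_in_unit_interval(self, small_dataset):
        rec = small_dataset.records[0]
        prof = small_dataset.conservation(rec.id, TABLE)
        scaled = prof.scaled()
        assert scaled.shape == (len(rec.sequence), 6)
        assert scaled.min() >= 0.0 and scaled.max() <= 1.0


class TestRunPsiblast:
    def test_missing_executable_is_an_environment_error(self, tmp_path):
        from nabind.profiles import PsiBlastUnavailableError

        q = tmp_path / "q.fa"
        q.write_text(">q\nMKRLVTA\n")
        with pytest.raises(PsiBlastUnavailableError):
            run_psiblast(q, tmp_path / "db", tmp_path / "out",
                         executable="definitely-not-on-path")

    @pytest.mark.skipif(shutil.which("psiblast") is None
                        or shutil.which("makeblastdb") is None,
                        reason="BLAST+ not installed")
    def test_real_search_produces_parseable_outputs(self, tmp_path):
        query = ("MKRLVTAGHKRSDEQWYFNPLIVCMKRLVTAGHKRSDEQWYFNPLIVC"
                 "MKRLVTAGHKRSDEQW")
        db_fa = tmp_path / "db.fa"
        with open(db_fa, "w") as fh:
            fh.write(f">s1\n{query}\n")  # self-hit guaranteed
            fh.write(f">s2\n{query[:40]}AAAAAAAAAAAAAAAAAAAAAAAA\n")
            fh.write(">s3\nGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGGG\n")
        subprocess.run(
            ["makeblastdb", "-in", str(db_fa), "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        q = tmp_path / "q.fa"
        q.write_text(f">q\n{query}\n")
        pssm_path, tab_path = run_psiblast(q, db_fa, tmp_path / "search")
        profile = read_pssm(pssm_path)
        assert len(profile) == len(query)
        assert profile.query == query
        hits = read_pairwise_tab(tab_path)
        assert any(h.subject_id == "s1" for h in hits)  # self-hit present
        obs = build_column_observations(query, pairwise=hits)
        assert max(obs.counts()) >= 2
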