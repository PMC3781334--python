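"""PWM parsing, promoter scanning and single-site over-representation."""

import math

import numpy as np
import pandas as pd
import pytest

import stressclust as sc
from stressclust.errors import ParseError, StressclustError
from stressclust.motifs import (PWM, ScanResult, encode, estimate_background,
                                read_tss_bed)


def simple_pwm(consensus, name="TEST", dominant=97.0, minor=1.0):
    counts = np.full((4, len(consensus)), minor)
    for j, base in enumerate(consensus):
        counts["ACGT".index(base), j] = dominant
    return PWM(name, counts)


def revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPfmIO:
    def test_round_trip(self, tmp_path):
        pwms = sc.default_pwms()
        path = tmp_path / "m.pfm"
        sc.write_jaspar_pfm(pwms, path)
        back = sc.read_jaspar_pfm(path)
        assert [p.name for p in back] == [p.name for p in pwms]
        for a, b in zip(pwms, back):
            assert np.allclose(a.counts, b.counts)

    def test_bare_rows_accepted(self, tmp_path):
        path = tmp_path / "bare.pfm"
        path.write_text(">M1 M1\n10 0\n0 10\n0 0\n0 0\n")
        (pwm,) = sc.read_jaspar_pfm(path)
        assert pwm.width == 2
        assert pwm.consensus() == "AC"

    def test_degenerate_single_position(self, tmp_path):
        path = tmp_path / "one.pfm"
        path.write_text(">M1 M1\nA [10]\nC [0]\nG [0]\nT [0]\n")
        (pwm,) = sc.read_jaspar_pfm(path)
        assert pwm.consensus() == "A"
        lom = pwm.log_odds()
        assert lom[0, 0] == lom.max()

    def test_unequal_rows_error_with_line(self, tmp_path):
        path = tmp_path / "bad.pfm"
        path.write_text(">M1 M1\nA [1 2]\nC [1]\nG [1 2]\nT [1 2]\n")
        with pytest.raises(ParseError, match="bad.pfm"):
            sc.read_jaspar_pfm(path)

    def test_non_numeric_error_names_line(self, tmp_path):
        path = tmp_path / "bad2.pfm"
        path.write_text(">M1 M1\nA [1 x]\nC [1 1]\nG [1 1]\nT [1 1]\n")
        with pytest.raises(ParseError, match=":2"):
            sc.read_jaspar_pfm(path)

    def test_uniform_pwm_scores_everything_equally(self):
        pwm = PWM("U", np.full((4, 6), 5.0))
        lom = pwm.log_odds()
        assert np.allclose(lom, 0.0)
        with pytest.raises(StressclustError, match="degenerate"):
            pwm.score_range()


class TestScan:
    def exhaustive_hits(self, pwm, seq, threshold, background):
        """Per-position recomputation in plain Python, both strands."""
        lom = pwm.log_odds(background)
        lo, hi = pwm.score_range(background)
        w = pwm.width
        hits = {}
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            for i in range(len(s) - w + 1):
                window = s[i:i + w]
                if any(b not in "ACGT" for b in window):
                    continue
                score = sum(lom["ACGT".index(b), j]
                            for j, b in enumerate(window))
                rel = (score - lo) / (hi - lo)
                pos = i if strand == "+" else len(seq) - w - i
                if rel >= threshold:
                    prev = hits.get(pos)
                    if prev is None or rel > prev[1] + 1e-12:
                        hits[pos] = (strand, rel)
        return hits

    def test_matches_exhaustive_oracle_small_windows(self):
        rng = np.random.default_rng(6)
        pwm = simple_pwm("ACGTAC", dominant=20, minor=4)
        bg = np.full(4, 0.25)
        for trial in range(8):
            seq = "".join(rng.choice(list("ACGT"), size=50))
            promoters = {"g": seq}
            tss = {"g": 25}
            scan = sc.scan_promoters(pwm, promoters, tss, window=25,
                                     rel_threshold=0.75, background=bg)
            oracle = self.exhaustive_hits(pwm, seq, 0.75, bg)
            got = {row["position"] + 25: (row["strand"], row["rel_score"])
                   for _, row in scan.hits.iterrows()}
            assert set(got) == set(oracle)
            for pos in got:
                assert got[pos][0] == oracle[pos][0]
                assert got[pos][1] == pytest.approx(oracle[pos][1])

    def test_planted_consensus_found_at_exact_coordinate(self):
        pwm = simple_pwm("TTAGCCAATCAGAG")
        rng = np.random.default_rng(1)
        seq = list("".join(rng.choice(list("ACGT"), size=401)))
        seq[100:114] = "TTAGCCAATCAGAG"
        promoters = {"g": "".join(seq)}
        scan = sc.scan_promoters(pwm, promoters, {"g": 200}, window=200)
        hit = scan.hits[scan.hits["position"] == 100 - 200]
        assert len(hit) == 1
        assert hit.iloc[0]["strand"] == "+"

    def test_reverse_complement_preserves_hit_count(self):
        pwm = simple_pwm("TTAGCCAATCAGAG")
        rng = np.random.default_rng(2)
        seq = list("".join(rng.choice(list("ACGT"), size=301)))
        seq[40:54] = "TTAGCCAATCAGAG"
        seq = "".join(seq)
        fwd = sc.scan_promoters(pwm, {"g": seq}, {"g": 150}, window=150)
        rev = sc.scan_promoters(pwm, {"g": revcomp(seq)}, {"g": 150}, window=150)
        assert len(fwd.hits) == len(rev.hits) > 0
        assert set(fwd.hits["strand"]) == {"+"}
        assert set(rev.hits["strand"]) == {"-"}

    def test_translation_invariance(self):
        """Positions are TSS-relative: padding the sequence and shifting the
        TSS leaves hits unchanged."""
        pwm = simple_pwm("TTAGCCAATCAGAG")
        rng = np.random.default_rng(3)
        core = "".join(rng.choice(list("ACGT"), size=201))
        core = core[:90] + "TTAGCCAATCAGAG" + core[104:]
        pad = "".join(rng.choice(list("ACGT"), size=57))
        bg = np.full(4, 0.25)
        s1 = sc.scan_promoters(pwm, {"g": core}, {"g": 100}, window=80,
                               background=bg)
        s2 = sc.scan_promoters(pwm, {"g": pad + core}, {"g": 157}, window=80,
                               background=bg)
        assert sorted(s1.hits["position"]) == sorted(s2.hits["position"])

    def test_non_acgt_blocks_hits(self):
        pwm = simple_pwm("ACGTACGT")
        seq = "ACGTACGT" + "N" * 8 + "ACGTACGT"
        scan = sc.scan_promoters(pwm, {"g": seq}, {"g": 12}, window=12,
                                 background=np.full(4, 0.25))
        positions = set(scan.hits["position"] + 12)
        assert 0 in positions and 16 in positions
        assert not any(0 < p < 16 for p in positions)

    def test_short_sequence_scans_available_span(self, caplog):
        pwm = simple_pwm("ACGTAC")
        scan = sc.scan_promoters(pwm, {"g": "ACGTACGTAC"}, {"g": 5},
                                 window=2000, background=np.full(4, 0.25))
        assert scan.scanned.iloc[0]["n_positions"] == 5

    def test_background_estimated_from_sequences(self):
        freqs = estimate_background({"a": "AAAA", "b": "CCGG"})
        assert freqs == pytest.approx([0.5, 0.25, 0.25, 0.0])


class TestSingleSite:
    def make_scan(self, hits, scanned):
        return ScanResult(
            pd.DataFrame(hits, columns=["gene", "factor", "position",
                                        "strand", "rel_score"]),
            pd.DataFrame(scanned, columns=["gene", "factor", "n_positions"]),
            0.85)

    def test_self_comparison_is_null(self):
        genes = [f"g{i}" for i in range(6)]
        hits = [(g, "F1", 0, "+", 0.9) for g in genes[:3]]
        scanned = [(g, "F1", 1000) for g in genes]
        scan = self.make_scan(hits, scanned)
        res = sc.single_site_analysis(scan, genes, genes)
        row = res.iloc[0]
        assert row["x"] == row["background_hits"]
        assert abs(row["z"]) < 0.5  # only the continuity correction remains
        assert row["fisher_p"] == pytest.approx(1.0)

    def test_fisher_enumeration_2x2(self):
        """Target genes both hit, rest both unhit: one-tailed p = 1/6."""
        genes = ["a", "b", "c", "d"]
        hits = [("a", "F1", 0, "+", 0.9), ("b", "F1", 5, "+", 0.9)]
        scanned = [(g, "F1", 100) for g in genes]
        scan = self.make_scan(hits, scanned)
        res = sc.single_site_analysis(scan, ["a", "b"], genes)
        assert res.iloc[0]["fisher_p"] == pytest.approx(1 / 6)

    def test_z_strictly_increasing_in_x(self):
        genes = [f"g{i}" for i in range(20)]
        scanned = [(g, "F1", 500) for g in genes]
        zs = []
        for x in (2, 5, 9):
            hits = [(genes[i % 4], "F1", i, "+", 0.9) for i in range(x)]
            hits += [(genes[10 + i % 5], "F1", i, "+", 0.9) for i in range(6)]
            scan = self.make_scan(hits, scanned)
            res = sc.single_site_analysis(scan, genes[:4], genes)
            zs.append(res.iloc[0]["z"])
        assert zs[0] < zs[1] < zs[2]

    def test_sigma_zero_reports_reason(self):
        genes = ["a", "b"]
        scan = self.make_scan([], [(g, "F1", 100) for g in genes])
        res = sc.single_site_analysis(scan, ["a"], genes)
        assert math.isnan(res.iloc[0]["z"])
        assert res.iloc[0]["z_reason"] != ""

    def test_target_must_be_subset(self):
        scan = self.make_scan([], [("a", "F1", 10)])
        with pytest.raises(StressclustError):
            sc.single_site_analysis(scan, ["zz"], ["a"])


class TestPlantedFactorRecovery:
    def test_atf6_group_recovers_nfya_analogue_alone(self, promoter_scan, dataset):
        """The factor planted only in ATF6-profile promoters is the sole
        factor passing Z > 10 and Fisher < 0.01 for that group."""
        promoters, _, scan, truth = promoter_scan
        groups = truth.profiles["group"]
        background = sorted(promoters)
        target = set(groups[groups == "ATF6"].index)
        res = sc.single_site_analysis(scan, target, background)
        passing = set(res.loc[res["passes"], "factor"])
        assert passing == {"NFYA_SYN"}

    @pytest.mark.parametrize("group", ["B", "D", "F"])
    def test_hnf4a_analogue_passes_in_down_groups(self, promoter_scan, group):
        promoters, _, scan, truth = promoter_scan
        groups = truth.profiles["group"]
        res = sc.single_site_analysis(scan, set(groups[groups == group].index),
                                      sorted(promoters))
        passing = set(res.loc[res["passes"], "factor"])
        assert passing == {"HNF4A_SYN"}

    @pytest.mark.parametrize("group", ["I", "H", "G"])
    def test_hnf4a_analogue_absent_elsewhere(self, promoter_scan, group):
        promoters, _, scan, truth = promoter_scan
        groups = truth.profiles["group"]
        res = sc.single_site_analysis(scan, set(groups[groups == group].index),
                                      sorted(promoters))
        assert "HNF4A_SYN" not in set(res.loc[res["passes"], "factor"])


class TestNetworkExport:
    def test_edges_and_confirmed_labels(self, promoter_scan):
        promoters, _, scan, truth = promoter_scan
        groups = truth.profiles["group"]
        target = set(groups[groups == "F"].index)
        res = sc.single_site_analysis(scan, target, sorted(promoters))
        subset = sorted(target)[:5]
        confirmed = pd.DataFrame({"factor": ["HNF4A_SYN"], "gene": [subset[0]]})
        from stressclust.motifs import export_regulator_network
        edges = export_regulator_network(res, scan, subset, confirmed)
        assert set(edges["factor"]) == {"HNF4A_SYN"}
        assert set(edges["gene"]) <= set(subset)
        by_gene = edges.set_index("gene")["evidence"]
        if subset[0] in by_gene.index:
            assert by_gene[subset[0]] == "confirmed"
        assert (by_gene.drop(subset[0], errors="ignore") == "predicted").all()

    def test_empty_passing_set_empty_edges(self):
        from stressclust.motifs import export_regulator_network
        res = pd.DataFrame({"factor": ["F1"], "passes": [False]})
        scan = ScanResult(pd.DataFrame(columns=["gene", "factor", "position",
                                                "strand", "rel_score"]),
                          pd.DataFrame(columns=["gene", "factor", "n_positions"]),
                          0.85)
        edges = export_regulator_network(res, scan, ["g1"])
        assert len(edges) == 0


class TestTssBed:
    def test_read_bed(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("g1\t2000\t2001\tg1\t0\t+\ng2\t2000\t2001\tg2\t0\t+\n")
        df = read_tss_bed(p)
        assert list(df["name"]) == ["g1", "g2"]
        assert (df["end"] - df["start"] == 1).all()

    def test_bad_coordinate_errors(self, tmp_path):
        p = tmp_path / "t.bed"
        p.write_text("g1\tx\t2001\tg1\n")
        with pytest.raises(ParseError, match=":1"):
            read_tss_bed(p)
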