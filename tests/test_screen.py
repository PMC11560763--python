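"""DEG filtering, intersection, hub ranking, PWM scanning, composites."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import il6loop as il
from il6loop.screen import DEGRecord, hits_to_bed, tss_offset


# ---------------------------------------------------------------------------
# gene-level


class TestFilterDEGs:
    def test_empty_input(self):
        assert il.filter_degs([]) == set()

    def test_boundary_values_excluded(self):
        # both cut-offs are strict inequalities
        recs = [DEGRecord("A", -1.5, 0.04), DEGRecord("B", -1.6, 0.05),
                DEGRecord("C", -1.6, 0.04)]
        assert il.filter_degs(recs, p_cut=0.05, fc_cut=1.5) == {"C"}

    def test_directions(self):
        recs = [DEGRecord("DN", -2.0, 0.01), DEGRecord("UP", 2.0, 0.01),
                DEGRecord("NULL", 0.3, 0.01)]
        assert il.filter_degs(recs, direction="down") == {"DN"}
        assert il.filter_degs(recs, direction="up") == {"UP"}
        assert il.filter_degs(recs, direction="both") == {"DN", "UP"}

    def test_duplicates_keep_most_significant(self):
        recs = [DEGRecord("A", -2.0, 0.5), DEGRecord("A", -3.0, 0.001)]
        assert il.filter_degs(recs) == {"A"}
        # the significant record can also disqualify the gene
        recs = [DEGRecord("B", -2.0, 0.01), DEGRecord("B", 0.1, 0.001)]
        assert il.filter_degs(recs) == set()

    @given(st.lists(st.tuples(st.integers(0, 30),
                              st.floats(-6, 6, allow_nan=False),
                              st.floats(0, 1, allow_nan=False)),
                    max_size=100))
    def test_matches_brute_force(self, raw):
        recs = [DEGRecord(f"G{i}", fc, p) for i, fc, p in raw]
        # oracle: explicit per-record loop with dedup by minimal p
        best = {}
        for r in recs:
            if r.gene not in best or r.p_value < best[r.gene].p_value:
                best[r.gene] = r
        expected = {r.gene for r in best.values()
                    if r.p_value < 0.05 and r.fold_change < -1.5}
        assert il.filter_degs(recs) == expected

    def test_malformed_record(self):
        with pytest.raises(ValueError):
            DEGRecord("X", float("nan"), 0.01)
        with pytest.raises(ValueError):
            DEGRecord("X", -2.0, 1.5)


class TestIntersectCandidates:
    def test_disjoint_sets(self):
        out = il.intersect_candidates({"A"}, {"B"}, {"C"})
        assert out.genes == set() and out.n_candidates == 0

    def test_fraction_tf_in_immune(self):
        immune = {f"g{i}" for i in range(10)}
        tf = {f"g{i}" for i in range(7)} | {"x1", "x2"}
        out = il.intersect_candidates(tf, immune, immune)
        assert out.fraction_tf_in_immune == pytest.approx(0.7)
        assert out.genes == tf & immune

    def test_empty_immune_rejected(self):
        with pytest.raises(ValueError):
            il.intersect_candidates({"A"}, set(), {"A"})

    def test_counts_consistent(self):
        out = il.intersect_candidates({"A", "B"}, {"B", "C"}, {"B", "D"})
        assert out.n_candidates == len(out.genes) == 1
        assert out.n_candidates <= min(out.n_tf_targets, out.n_immune, out.n_deg_pass)


class TestHubRank:
    def test_star_graph_center_first(self):
        edges = [("HUB", f"L{i}", 0.9) for i in range(8)]
        out = il.hub_rank(edges, score_cut=0.4)
        assert out.hub == "HUB"
        assert int(out.ranking.iloc[0]["degree"]) == 8
        assert out.n_nodes == 9 and out.n_edges == 8

    def test_strict_cutoff_empties_graph(self):
        edges = [("A", "B", 0.4), ("B", "C", 0.2)]
        out = il.hub_rank(edges, score_cut=0.4)
        assert out.ranking.empty and out.n_nodes == 0

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            il.hub_rank([("A", "A", 0.9)])

    def test_ties_break_lexicographically(self):
        edges = [("B", "C", 0.9), ("A", "C", 0.9)]
        out = il.hub_rank(edges)
        assert list(out.ranking["gene"]) == ["C", "A", "B"]

    def test_degrees_match_adjacency_count(self):
        # oracle: hand-rolled adjacency sets on a random 50-node graph
        rng = np.random.default_rng(3)
        nodes = [f"N{i:02d}" for i in range(50)]
        edges = []
        for _ in range(300):
            a, b = rng.choice(50, size=2, replace=False)
            edges.append((nodes[a], nodes[b], float(rng.random())))
        out = il.hub_rank(edges, score_cut=0.4)
        adj: dict[str, set] = {}
        for a, b, w in edges:
            if w > 0.4:
                adj.setdefault(a, set()).add(b)
                adj.setdefault(b, set()).add(a)
        for row in out.ranking.itertuples(index=False):
            assert len(adj[row.gene]) == row.degree


# ---------------------------------------------------------------------------
# promoter-level


class TestRelativeScore:
    def test_consensus_scores_one(self, pwms):
        for pwm in pwms.values():
            assert il.relative_score(pwm, pwm.consensus) == pytest.approx(1.0)

    def test_worst_word_scores_zero(self, pwms):
        for pwm in pwms.values():
            assert il.relative_score(pwm, pwm.anticonsensus) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self, pwms):
        with pytest.raises(ValueError):
            il.relative_score(pwms["E2F1"], "ACGT")

    @given(st.text(alphabet="ACGTN", min_size=8, max_size=8))
    def test_matches_naive_summation(self, window):
        pwm = il.load_builtin_pwms()["E2F1"]
        # oracle: per-position python loop over the log-odds matrix
        base_row = {"A": 0, "C": 1, "G": 2, "T": 3}
        total = 0.0
        for j, b in enumerate(window):
            col = pwm.matrix[:, j]
            total += col.min() if b == "N" else col[base_row[b]]
        expected = (total - pwm.min_score) / (pwm.max_score - pwm.min_score)
        assert il.relative_score(pwm, window) == pytest.approx(expected, abs=1e-12)


def naive_scan(seq, pwm, threshold, both_strands):
    """O(L*w) reference scanner built on relative_score and string ops."""
    comp = str.maketrans("ACGTN", "TGCAN")
    out = []
    w = pwm.length
    for i in range(len(seq) - w + 1):
        window = seq[i:i + w]
        s = il.relative_score(pwm, window)
        if s >= threshold:
            out.append((i, "+", round(s, 9)))
        if both_strands:
            s = il.relative_score(pwm, window.translate(comp)[::-1])
            if s >= threshold:
                out.append((i, "-", round(s, 9)))
    return sorted(out)


class TestScanSequence:
    def test_planted_consensus_found(self, pwms):
        pwm = pwms["E2F1"]
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), size=120))
        seq = seq[:37] + pwm.consensus + seq[37 + pwm.length:]
        hits = il.scan_sequence(seq, pwm, threshold=0.85, factor="E2F1")
        assert any(h.start == 37 and h.relative_score == pytest.approx(1.0)
                   for h in hits)

    def test_threshold_zero_reports_all_windows(self, pwms):
        pwm = pwms["STAT3"]
        seq = "ACGT" * 20
        hits = il.scan_sequence(seq, pwm, threshold=0.0, both_strands=True)
        assert len(hits) == 2 * (len(seq) - pwm.length + 1)

    def test_matches_naive_scan_on_random_kb(self, pwms):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=1000))
        for factor, pwm in pwms.items():
            hits = il.scan_sequence(seq, pwm, threshold=0.75, factor=factor)
            got = sorted((h.start, h.strand, round(h.relative_score, 9)) for h in hits)
            assert got == naive_scan(seq, pwm, 0.75, True)

    def test_reverse_complement_symmetry(self, pwms):
        pwm = pwms["E2F1"]
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=300))
        comp = str.maketrans("ACGT", "TGCA")
        rc = seq.translate(comp)[::-1]
        fwd = il.scan_sequence(seq, pwm, threshold=0.8)
        rev = il.scan_sequence(rc, pwm, threshold=0.8)
        # a hit at start i on seq maps to start L - w - i with flipped strand
        L, w = len(seq), pwm.length
        mapped = sorted((L - w - h.start, {"+": "-", "-": "+"}[h.strand],
                         round(h.relative_score, 9)) for h in rev)
        assert mapped == sorted((h.start, h.strand, round(h.relative_score, 9))
                                for h in fwd)

    def test_sequence_shorter_than_motif(self, pwms):
        with pytest.raises(ValueError):
            il.scan_sequence("ACG", pwms["E2F1"])


class TestCompositeElements:
    def make_hit(self, start, factor, width=8, seq="p1"):
        from il6loop.screen import MotifHit

        return MotifHit(seq, start, "+", 1.0, 1.0, factor, width)

    def test_direct_distance(self):
        # E2F1 centred at 100, STAT3 at 118: one element of gap 18
        e = self.make_hit(100 - 3, "E2F1", width=7)   # center 100
        s = self.make_hit(118 - 3, "STAT3", width=7)  # center 118
        out = il.find_composite_elements([e], [s], max_gap=50)
        assert len(out) == 1
        assert out[0].center_gap == pytest.approx(18.0)
        assert out[0].orientation == "e2f1_upstream"

    def test_gap_cap(self):
        e = self.make_hit(97, "E2F1", width=7)
        s = self.make_hit(115, "STAT3", width=7)
        assert il.find_composite_elements([e], [s], max_gap=10) == []

    def test_mixed_sequence_ids_rejected(self):
        e = self.make_hit(10, "E2F1", seq="p1")
        s = self.make_hit(20, "STAT3", seq="p2")
        with pytest.raises(ValueError):
            il.find_composite_elements([e], [s], max_gap=50)

    @given(st.lists(st.integers(0, 480), min_size=0, max_size=20),
           st.lists(st.integers(0, 480), min_size=0, max_size=20))
    def test_matches_all_pairs_check(self, starts_a, starts_b):
        ha = [self.make_hit(s, "E2F1", width=8) for s in starts_a]
        hb = [self.make_hit(s, "STAT3", width=9) for s in starts_b]
        out = il.find_composite_elements(ha, hb, max_gap=25)
        expected = {(a.start, b.start) for a in ha for b in hb
                    if abs((b.start + 4.0) - (a.start + 3.5)) <= 25}
        assert {(c.e2f1_hit.start, c.stat3_hit.start) for c in out} == expected
        gaps = [abs(c.center_gap) for c in out]
        assert gaps == sorted(gaps)


class TestIOHelpers:
    def test_jaspar_roundtrip_consensus(self, pwms):
        assert pwms["E2F1"].consensus == "TTTCCCGC"
        assert pwms["STAT3"].consensus == "TTCCGGGAA"

    def test_tss_offsets_are_negative_upstream_positions(self, pwms):
        from il6loop.screen import MotifHit

        hit = MotifHit("p", start=375, strand="+", raw_score=1.0,
                       relative_score=1.0, factor="E2F1", width=8)
        # a 500 bp promoter ending at the TSS: hit at 375 starts 125 bp upstream
        assert tss_offset(hit, 500) == -125

    def test_bed_like_table(self, pwms):
        pwm = pwms["E2F1"]
        seq = "A" * 20 + pwm.consensus + "A" * 20
        hits = il.scan_sequence(seq, pwm, threshold=0.85, factor="E2F1",
                                sequence_id="chrP")
        bed = hits_to_bed(hits)
        assert {"sequence", "start", "end", "factor", "strand",
                "relative_score"} == set(bed.columns)
        row = bed[bed["start"] == 20].iloc[0]
        assert row["end"] == 28 and row["factor"] == "E2F1"

    def test_deg_table_io(self, tmp_path):
        from il6loop.screen import read_deg_table

        path = tmp_path / "degs.tsv"
        path.write_text("gene\tfold_change\tp_value\nIL6\t-3.3\t0.001\n")
        recs = read_deg_table(str(path))
        assert recs[0].gene == "IL6" and recs[0].fold_change == -3.3
        bad = tmp_path / "bad.tsv"
        bad.write_text("gene\tfc\np\n")
        with pytest.raises(ValueError):
            read_deg_table(str(bad))
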