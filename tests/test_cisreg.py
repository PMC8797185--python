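import itertools
import re

import numpy as np
import pytest

from spliceprog.cisreg import (
    AnchoredSequence,
    SpliceSiteModel,
    acceptor_site_sequence,
    agez,
    donor_site_sequence,
    exon_intron_lengths,
    extract_anchor_sequences,
    iupac_regex,
    load_splice_model,
    relative_score,
    rime,
    rna_map,
    rna_map_significance,
    train_toy_splice_model,
)
from spliceprog.io_core import ExonEvent, SequenceStore


def _event(alt=(300, 331), up=(100, 250), down=(631, 881), strand="+"):
    if strand == "+":
        return ExonEvent("e", "g", "c", "+", alt, up, down)
    return ExonEvent("e", "g", "c", "-", alt, down, up)


class TestLengthsAndRime:
    def test_length_table(self):
        df = exon_intron_lengths([_event()])
        row = df.loc["e"]
        assert row["alt_exon"] == 31
        assert row["upstream_intron"] == 50 and row["downstream_intron"] == 300
        assert row["upstream_exon"] == 150 and row["downstream_exon"] == 250

    def test_rime_worked_example(self):
        # alt 31, introns 200+300, flanks 150 and 250 -> 531/200
        ev = ExonEvent("e", "g", "c", "+", (350, 381), (0, 150), (681, 931))
        assert rime(ev) == pytest.approx(531 / 200)

    def test_rime_matches_straight_line_recomputation(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            e1 = int(rng.integers(50, 300))
            i1 = int(rng.integers(40, 500))
            a = int(rng.integers(3, 120))
            i2 = int(rng.integers(40, 500))
            e2 = int(rng.integers(50, 300))
            up = (0, e1)
            alt = (e1 + i1, e1 + i1 + a)
            down = (alt[1] + i2, alt[1] + i2 + e2)
            ev = ExonEvent("e", "g", "c", "+", alt, up, down)
            assert rime(ev) == pytest.approx((a + i1 + i2) / ((e1 + e2) / 2))


class TestAgez:
    def test_adjacent_ag_gives_zero(self):
        assert agez("CCCCAGAG") == (0, False)

    def test_no_upstream_ag_capped_at_scan_length(self):
        assert agez("GT" + "C" * 248 + "AG") == (248, True)

    def test_counts_nt_strictly_between_ags(self):
        # AG at positions -10..-9, terminal at -2..-1 -> 6 nt between
        seq = "CCCCCCCCAGCCCCCCAG"
        assert agez(seq) == (6, False)

    def test_matches_independent_scan(self):
        rng = np.random.default_rng(1)
        bases = np.array(list("ACGT"))
        for _ in range(500):
            seq = "".join(bases[rng.integers(0, 4, int(rng.integers(10, 120)))]) + "AG"
            got, capped = agez(seq)
            # brute force: distance from terminal AG to nearest upstream AG
            body = seq[:-2]
            hits = [m.start() for m in re.finditer("(?=AG)", body) if m.start() + 2 <= len(body)]
            if hits:
                assert not capped and got == len(body) - (max(hits) + 2)
            else:
                assert capped and got == len(body)

    def test_requires_terminal_ag(self):
        with pytest.raises(ValueError):
            agez("CCCCAT")


class TestSpliceModels:
    def test_uniform_model_scores_zero(self):
        p = {"type": "pwm", "probs": np.full((9, 4), 0.25)}
        model = SpliceSiteModel("donor", 9, p, p)
        assert model.score("CAGGTAAGT") == pytest.approx(0.0)

    def test_score_matches_table_product_oracle(self):
        rng = np.random.default_rng(3)
        fg = rng.dirichlet(np.ones(4), size=9)
        bg = rng.dirichlet(np.ones(4), size=9)
        model = SpliceSiteModel("donor", 9, {"type": "pwm", "probs": fg},
                                {"type": "pwm", "probs": bg})
        idx = {b: i for i, b in enumerate("ACGT")}
        for _ in range(50):
            seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 9)])
            pf = np.prod([fg[i, idx[b]] for i, b in enumerate(seq)])
            pb = np.prod([bg[i, idx[b]] for i, b in enumerate(seq)])
            assert model.score(seq) == pytest.approx(np.log2(pf / pb), abs=1e-9)

    def test_kmer_table_model(self, tmp_path):
        fgp = tmp_path / "fg.tsv"
        bgp = tmp_path / "bg.tsv"
        fgp.write_text("AAA\t0.5\nCCC\t0.5\n")
        bgp.write_text("AAA\t0.25\nCCC\t0.75\n")
        model = load_splice_model(fgp, bgp, "custom")
        assert model.score("AAA") == pytest.approx(1.0)
        with pytest.raises(ValueError):
            model.score("GGG")

    def test_trainer_recovers_consensus(self):
        sites = ["CAGGTAAGT"] * 100
        bg = ["ACGTACGTA"] * 100
        model = train_toy_splice_model(sites, bg, "donor", order=0)
        probs = model.fg["probs"]
        assert probs[0, 1] > 0.95  # C at position 0

    def test_trainer_recovers_known_tables(self):
        rng = np.random.default_rng(5)
        truth = rng.dirichlet(np.ones(4) * 2, size=9)
        bases = np.array(list("ACGT"))
        sites = ["".join(bases[[rng.choice(4, p=truth[i]) for i in range(9)]])
                 for _ in range(3000)]
        bg = ["".join(bases[rng.integers(0, 4, 9)]) for _ in range(3000)]
        model = train_toy_splice_model(sites, bg, "donor", order=0)
        assert np.abs(model.fg["probs"] - truth).max() < 0.04

    def test_background_equals_foreground_scores_zero(self):
        seqs = ["ACGTACGTA", "TTTTAAAAC", "CAGGTAAGT"] * 40
        model = train_toy_splice_model(seqs, list(seqs), "donor", order=1)
        for s in set(seqs):
            assert model.score(s) == pytest.approx(0.0, abs=1e-12)

    def test_wrong_length_and_ambiguous_base_rejected(self):
        p = {"type": "pwm", "probs": np.full((9, 4), 0.25)}
        model = SpliceSiteModel("donor", 9, p, p)
        with pytest.raises(ValueError):
            model.score("ACGT")
        with pytest.raises(ValueError):
            model.score("ACGTNACGT")

    def test_relative_score_centres_on_highpsi_median(self):
        high = [1.0, 2.0, 3.0]
        assert relative_score([2.0], high)[0] == pytest.approx(0.0)
        assert relative_score([5.0], high)[0] == pytest.approx(3.0)


class TestSiteExtraction:
    def _store(self):
        seq = (
            "A" * 100 + "C" * 150  # upstream exon [100,250)
            + "GT" + "T" * 46 + "AG"  # intron [250,300)
            + "G" * 31  # alt [300,331)
            + "GT" + "T" * 296 + "AG"  # intron [331,631)
            + "A" * 250 + "T" * 100
        )
        return SequenceStore({"c": seq})

    def test_donor_and_acceptor_windows(self):
        ev = _event()
        seqs = self._store()
        d = donor_site_sequence(ev, seqs, "alt_exon_end")
        assert len(d) == 9 and d[:3] == "GGG" and d[3:5] == "GT"
        a = acceptor_site_sequence(ev, seqs, "alt_exon_start")
        assert len(a) == 23 and a[18:20] == "AG" and a[20:] == "GGG"


def brute_force_coverage(seq, anchor, motif, window, positions):
    """Independent window scan for one sequence (regex, any overlap)."""
    half = window // 2
    pat = iupac_regex(motif)
    L = len(motif)
    out = {}
    for p in range(*positions):
        w0, w1 = anchor + p - half, anchor + p + half
        if w0 < 0 or w1 >= len(seq):
            out[p] = None
            continue
        hit = any(w0 <= m.start(1) and m.start(1) + L - 1 <= w1
                  for m in pat.finditer(seq))
        out[p] = 1.0 if hit else 0.0
    return out


class TestRnaMap:
    def test_motif_at_anchor_in_every_sequence(self):
        seqs = [AnchoredSequence("C" * 30 + "CTAAC" + "C" * 30, 30) for _ in range(5)]
        prof = rna_map(seqs, "CUAAY", window=27, positions=(-10, 10))
        assert prof.coverage[10] == 1.0  # position 0

    def test_absent_motif_zero_everywhere(self):
        seqs = [AnchoredSequence("C" * 80, 40)]
        prof = rna_map(seqs, "UGC", window=27, positions=(-20, 20))
        assert np.nansum(prof.coverage) == 0.0

    def test_single_sequence_profile_matches_brute_force(self):
        rng = np.random.default_rng(9)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)])
        a = AnchoredSequence(seq, 100)
        prof = rna_map([a], "YYYY", window=27, positions=(-80, 80))
        oracle = brute_force_coverage(seq, 100, "YYYY", 27, (-80, 80))
        for i, p in enumerate(prof.positions):
            if oracle[p] is None:
                assert prof.n_contrib[i] == 0
            else:
                assert prof.coverage[i] == oracle[p]

    def test_adding_occurrence_never_decreases_coverage(self):
        rng = np.random.default_rng(13)
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        base = base.replace("TGC", "AAA")
        seqs = [AnchoredSequence(base, 60), AnchoredSequence(base, 60)]
        before = rna_map(seqs, "UGC", positions=(-40, 40)).coverage
        enriched = base[:50] + "TGC" + base[53:]
        seqs2 = [AnchoredSequence(enriched, 60), AnchoredSequence(base, 60)]
        after = rna_map(seqs2, "UGC", positions=(-40, 40)).coverage
        ok = np.isfinite(before) & np.isfinite(after)
        assert (after[ok] >= before[ok] - 1e-12).all()

    def test_truncated_sequences_drop_out_of_both_counts(self):
        long = AnchoredSequence("C" * 100, 50)
        short = AnchoredSequence("C" * 40, 20)
        prof = rna_map([long, short], "UGC", window=27, positions=(-40, 40))
        # at position -35 the short sequence cannot host a full window
        i = list(prof.positions).index(-35)
        assert prof.n_contrib[i] == 1
        i0 = list(prof.positions).index(0)
        assert prof.n_contrib[i0] == 2


class TestRnaMapSignificance:
    def _seqs(self, rng, n, with_motif_prob, length=80, anchor=40):
        out = []
        bases = np.array(list("ACGT"))
        for _ in range(n):
            s = list("".join(bases[rng.integers(0, 4, length)]))
            if rng.random() < with_motif_prob:
                pos = anchor - 20
                s[pos:pos + 5] = list("CTAAC")
            out.append(AnchoredSequence("".join(s), anchor))
        return out

    def test_exchangeable_null_yields_no_significance(self):
        rng = np.random.default_rng(21)
        test = self._seqs(rng, 8, 0.5)
        ctrl = [AnchoredSequence(t.seq, t.anchor) for t in test]
        track = rna_map_significance(test, ctrl, "CUAAY", positions=(-30, 30),
                                     n_perm=500, seed=4)
        assert not track.significant.any()

    def test_shared_exon_objects_rejected(self):
        rng = np.random.default_rng(2)
        seqs = self._seqs(rng, 6, 0.5)
        with pytest.raises(ValueError, match="share"):
            rna_map_significance(seqs[:4], seqs[2:], "CUAAY")

    def test_sampled_p_matches_exact_enumeration_4v4(self):
        rng = np.random.default_rng(31)
        test = self._seqs(rng, 4, 0.9)
        ctrl = self._seqs(rng, 4, 0.1)
        n_perm = 3000
        track = rna_map_significance(test, ctrl, "CUAAY", positions=(-25, -15),
                                     n_perm=n_perm, seed=8)
        # exact permutation null over all C(8,4) assignments
        from spliceprog.cisreg import _presence_matrix

        pooled = test + ctrl
        mat = _presence_matrix(pooled, "CUAAY", 27, (-25, -15))
        for col, p_hat in enumerate(track.p):
            if not np.isfinite(p_hat):
                continue
            vals = mat[:, col]
            obs = np.nanmean(vals[:4]) - np.nanmean(vals[4:])
            count = total = 0
            for idx in itertools.combinations(range(8), 4):
                sel = np.zeros(8, dtype=bool)
                sel[list(idx)] = True
                stat = np.nanmean(vals[sel]) - np.nanmean(vals[~sel])
                total += 1
                count += abs(stat) >= abs(obs) - 1e-12
            p_exact = count / total
            mc_se = np.sqrt(p_exact * (1 - p_exact) / n_perm)
            assert abs(p_hat - p_exact) <= 2 * mc_se + 2 / n_perm

    def test_planted_enrichment_detected_in_window(self):
        rng = np.random.default_rng(41)
        test = self._seqs(rng, 50, 0.9)
        ctrl = self._seqs(rng, 50, 0.1)
        track = rna_map_significance(test, ctrl, "CUAAY", positions=(-40, 20),
                                     n_perm=1000, seed=3)
        sig = track.positions[track.significant]
        assert any(-30 <= p <= -10 for p in sig)

    def test_extracted_anchor_sequences_have_expected_geometry(self, small_sim):
        from spliceprog import io_core

        ann = io_core.read_annotation(small_sim["paths"]["gtf"])
        seqs = io_core.read_fasta(small_sim["paths"]["fasta"])
        events = ann.cassette_events()
        anch = extract_anchor_sequences(events[:10], seqs)
        for a in anch["alt_exon_start"]:
            # anchor sits just after the intron-terminal AG
            assert a.seq[a.anchor - 2:a.anchor] == "AG"
        for a in anch["alt_exon_end"]:
            assert a.seq[a.anchor:a.anchor + 2] == "GT"
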