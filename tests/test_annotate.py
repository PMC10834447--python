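"""Detector stand-ins and receptor classification."""

import numpy as np
import pytest

from lrrkit import annotate as an
from lrrkit.annotate import KYTE_DOOLITTLE, ReceptorClass
from lrrkit.config import AnalysisConfig
from lrrkit.io import DomainCall, ProteinRecord
from lrrkit import synthgen as sg


def tm_oracle(seq, window=19, threshold=1.6, cfg=None):
    """Independent brute-force sliding-window TM scan (naive loops)."""
    cfg = cfg or AnalysisConfig()
    n = len(seq)
    if n < window:
        return []
    # exact arithmetic: hydropathies have one decimal, so work in tenths
    deci = {aa: round(v * 10) for aa, v in KYTE_DOOLITTLE.items()}
    ok = []
    for s in range(n - window + 1):
        total = sum(deci[aa] for aa in seq[s:s + window])
        ok.append(total >= threshold * 10 * window)
    spans = []
    s = 0
    while s < len(ok):
        if ok[s]:
            e = s
            while e + 1 < len(ok) and ok[e + 1]:
                e += 1
            a, b = s, e + window - 1
            if b - a + 1 > cfg.tm_max_len:
                k = cfg.tm_trim_len
                best, best_v = a, -10**9
                for t in range(a, b - k + 2):
                    v = sum(deci[aa] for aa in seq[t:t + k])
                    if v > best_v:
                        best, best_v = t, v
                a, b = best, best + k - 1
            if b - a + 1 >= cfg.tm_min_len:
                spans.append((a + 1, b + 1))
            s = e + 1
        else:
            s += 1
    return spans


class TestDetectTM:
    def test_single_hydrophobic_run(self):
        seq = "S" * 30 + "I" * 21 + "S" * 30
        calls = an.detect_tm(seq, 19, 1.6)
        assert len(calls) == 1
        (tm,) = calls
        # the isoleucine run (31..51) is covered
        assert tm.start <= 31 and tm.end >= 51

    def test_all_polar_no_tm(self):
        assert an.detect_tm("S" * 60, 19, 1.6) == []

    def test_two_separated_runs(self):
        seq = "S" * 20 + "L" * 21 + "N" * 40 + "L" * 21 + "S" * 20
        calls = an.detect_tm(seq, 19, 1.6)
        assert len(calls) == 2
        assert calls[0].end < calls[1].start

    def test_short_sequence_warns_empty(self):
        with pytest.warns(UserWarning):
            assert an.detect_tm("ILVF", 19, 1.6) == []

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            an.detect_tm("S" * 40, 18, 1.6)

    def test_matches_bruteforce_oracle_on_random_sequences(self):
        # biased composition so hydrophobic stretches actually occur
        rng = np.random.default_rng(42)
        letters = list("ILVFSTNQDEKG")
        probs = np.array([3, 3, 3, 1, 2, 2, 2, 2, 1, 1, 1, 1], float)
        probs /= probs.sum()
        for _ in range(1000):
            n = int(rng.integers(19, 220))
            seq = "".join(rng.choice(letters, size=n, p=probs))
            got = [(c.start, c.end) for c in an.detect_tm(seq, 19, 1.6)]
            assert got == tm_oracle(seq)

    def test_mask_suppresses_calls(self):
        seq = "I" * 21 + "S" * 40
        assert an.detect_tm(seq, 19, 1.6) != []
        assert an.detect_tm(seq, 19, 1.6, mask=(1, 21)) == []


class TestSignalPeptide:
    def test_mk_leucine_run(self):
        seq = "MK" + "L" * 10 + "Q" * 200
        assert an.detect_signal_peptide(seq) == (1, 12)

    def test_polar_n_terminus_absent(self):
        assert an.detect_signal_peptide("Q" * 50) is None

    def test_late_run_absent(self):
        # hydrophobic run starting at residue 20 is past the N-terminal window
        seq = "Q" * 19 + "L" * 10 + "Q" * 100
        assert an.detect_signal_peptide(seq) is None

    def test_short_run_absent(self):
        assert an.detect_signal_peptide("MK" + "L" * 5 + "Q" * 100) is None

    def test_prepending_sp_never_changes_tm_count(self, rng):
        for _ in range(25):
            spec = sg.random_receptor_spec(rng)
            seq, _ = sg.make_receptor(spec, rng, validate=False)
            base = seq if not spec.has_signal_peptide else seq[len(sg.SIGNAL_PEPTIDE):]
            n_plain = len(an.detect_tm(base, 19, 1.6))
            with_sp = sg.SIGNAL_PEPTIDE + base
            sp = an.detect_signal_peptide(with_sp)
            assert sp is not None
            n_masked = len(an.detect_tm(with_sp, 19, 1.6, mask=sp))
            assert n_masked == n_plain


class TestDetectKinase:
    def test_generator_cassette_recovered_exactly(self, rng):
        cassette = sg._make_kinase_cassette(rng)
        prefix = "Q" * 50
        call = an.detect_kinase(prefix + cassette)
        assert call is not None
        assert (call.start, call.end) == (51, 50 + len(cassette))

    def test_missing_dfg_absent(self, rng):
        cassette = sg._make_kinase_cassette(rng).replace("DFG", "DEG")
        assert an.detect_kinase(cassette) is None

    def test_landmark_order_required(self, rng):
        # swap HRD and DFG: landmarks present but out of order
        cassette = sg._make_kinase_cassette(rng)
        swapped = cassette.replace("HRD", "XXX").replace("DFG", "HRD")
        swapped = swapped.replace("XXX", "DFG")
        assert an.detect_kinase(swapped) is None


class TestDetectLRR:
    def test_tandem_template_copies(self):
        seq = sg.LRR_TEMPLATE * 6
        calls = an.detect_lrr(seq)
        assert len(calls) == 6
        assert [(c.start, c.end) for c in calls] == [
            (1 + 24 * i, 24 * (i + 1)) for i in range(6)
        ]

    def test_polyalanine_no_calls(self):
        assert an.detect_lrr("A" * 200) == []

    def test_linker_separated_copies(self):
        seq = sg.LRR_TEMPLATE + "S" * 60 + sg.LRR_TEMPLATE
        calls = an.detect_lrr(seq)
        assert len(calls) == 2
        assert calls[1].start - calls[0].end - 1 == 60

    def test_x_never_matches(self):
        # X at the first core position kills the match
        assert an.detect_lrr(sg.LRR_TEMPLATE.replace("L", "X", 1)) == []
        assert an.detect_lrr("X" * 50) == []


class TestClassify:
    def _record(self, n, pid="p"):
        return ProteinRecord(pid, "sp", "A" * n)

    def test_rlk(self, cfg):
        rec = self._record(900)
        calls = [DomainCall("KINASE", 600, 850), DomainCall("TM", 500, 522)] + [
            DomainCall("LRR", 1 + 24 * i, 24 * (i + 1)) for i in range(6)
        ]
        assert an.classify(rec, calls, cfg).cls is ReceptorClass.RLK

    def test_rlp(self, cfg):
        rec = self._record(400)
        calls = [DomainCall("TM", 300, 322)] + [
            DomainCall("LRR", 1 + 24 * i, 24 * (i + 1)) for i in range(6)
        ]
        assert an.classify(rec, calls, cfg).cls is ReceptorClass.RLP

    def test_min_length_filter(self, cfg):
        rec = self._record(140)
        calls = [DomainCall("LRR", 1, 24)]
        out = an.classify(rec, calls, cfg)
        assert out.cls is ReceptorClass.OTHER
        assert out.filtered_reason == "min_length"

    def test_lrr_kinase_needs_250(self, cfg):
        rec = self._record(200)
        calls = [DomainCall("KINASE", 30, 190), DomainCall("TM", 10, 25),
                 DomainCall("LRR", 1, 9)]
        out = an.classify(rec, calls, cfg)
        assert out.cls is ReceptorClass.OTHER
        assert out.filtered_reason == "min_length"

    def test_three_tms_other(self, cfg):
        rec = self._record(900)
        calls = [DomainCall("KINASE", 600, 850)] + [
            DomainCall("TM", 100 * i, 100 * i + 22) for i in (1, 2, 3)
        ]
        assert an.classify(rec, calls, cfg).cls is ReceptorClass.OTHER

    def test_ectodomain_only(self, cfg):
        rec = self._record(200)
        calls = [DomainCall("LRR", 1 + 24 * i, 24 * (i + 1)) for i in range(4)]
        assert an.classify(rec, calls, cfg).cls is ReceptorClass.ECTODOMAIN_ONLY

    def test_order_invariant(self, cfg, rng):
        rec = self._record(900)
        calls = [DomainCall("KINASE", 600, 850), DomainCall("TM", 500, 522)] + [
            DomainCall("LRR", 1 + 24 * i, 24 * (i + 1)) for i in range(6)
        ]
        ref = an.classify(rec, calls, cfg)
        for _ in range(10):
            shuffled = [calls[i] for i in rng.permutation(len(calls))]
            out = an.classify(rec, shuffled, cfg)
            assert (out.cls, out.n_tm, out.has_kd, out.ecto_span, out.endo_span) == (
                ref.cls, ref.n_tm, ref.has_kd, ref.ecto_span, ref.endo_span)

    def test_span_outside_sequence_fails_with_id(self, cfg):
        rec = self._record(100, pid="broken1")
        with pytest.raises(ValueError, match="broken1"):
            an.classify(rec, [DomainCall("TM", 90, 150)], cfg)


class TestSplitEctoEndo:
    def test_rlp_lrrs_nterminal(self, cfg):
        rec = ProteinRecord("p", "sp", "A" * 500)
        calls = [DomainCall("TM", 401, 423)] + [
            DomainCall("LRR", 1 + 24 * i, 24 * (i + 1)) for i in range(6)
        ]
        cls = an.classify(rec, calls, cfg)
        assert cls.ecto_span == (1, 400)
        assert cls.endo_span == (424, 500)

    def test_rlk_ecto_opposite_kd(self, cfg):
        # KD C-terminal of the TM: ecto is the N-side regardless of LRRs
        rec = ProteinRecord("p", "sp", "A" * 900)
        calls = [DomainCall("TM", 500, 522), DomainCall("KINASE", 600, 850),
                 DomainCall("LRR", 530, 553)]
        cls = an.classify(rec, calls, cfg)
        assert cls.endo_span == (523, 900)
        assert cls.ecto_span == (1, 499)

    def test_two_tm_rlp_inter_tm_lrrs(self, cfg):
        rec = ProteinRecord("p", "sp", "A" * 600)
        calls = [DomainCall("TM", 101, 123), DomainCall("TM", 401, 423)] + [
            DomainCall("LRR", 150 + 24 * i, 173 + 24 * i) for i in range(6)
        ]
        cls = an.classify(rec, calls, cfg)
        assert cls.ecto_span == (124, 400)   # inter-TM stretch holds the LRRs
        assert cls.endo_span == (424, 600)   # longest flank

    def test_no_tm_is_error(self):
        rec = ProteinRecord("p", "sp", "A" * 300)
        with pytest.raises(ValueError):
            an.split_ecto_endo(rec, [], None)
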