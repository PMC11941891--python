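import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agpepscan import annot
from agpepscan.screen import (
    ScreenParams,
    apply_evidence,
    apply_repeat_and_domain_exclusion,
    count_dipeptide_repeats,
    length_past_filter,
    past_fraction,
    run_screen,
)
from agpepscan.seqio import ProteinRecord

AA = "ACDEFGHIKLMNPQRSTVWY"
seqs = st.text(alphabet=AA, min_size=1, max_size=120)


def brute_force_repeats(seq):
    return tuple(
        sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == pair)
        for pair in ("AP", "PA", "SP", "TP")
    )


class TestPastFraction:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("PAST", 100.0),
            ("GGGGGGG", 0.0),
            ("P" * 21 + "G" * 39, 35.0),  # 21/60
        ],
    )
    def test_examples(self, seq, expected):
        assert past_fraction(seq) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            past_fraction("")


class TestRepeatCounting:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("APAPA", (2, 2, 0, 0)),
            ("GGGG", (0, 0, 0, 0)),
            ("TPSPAP", (1, 1, 1, 1)),
        ],
    )
    def test_examples(self, seq, expected):
        assert count_dipeptide_repeats(seq) == expected

    @settings(max_examples=200, derandomize=True)
    @given(seqs)
    def test_matches_brute_force_enumeration(self, seq):
        assert count_dipeptide_repeats(seq) == brute_force_repeats(seq)


class TestLengthPastFilter:
    def test_length_boundaries_inclusive(self):
        short = ProteinRecord("short", "P" * 49)
        lo = ProteinRecord("lo", "P" * 50)
        hi = ProteinRecord("hi", "P" * 75)
        long = ProteinRecord("long", "P" * 76)
        kept = length_past_filter([short, lo, hi, long], ScreenParams())
        assert [p.id for p in kept] == ["lo", "hi"]

    def test_past_boundary_inclusive_on_unrounded_fraction(self):
        exactly35 = ProteinRecord("x", "P" * 21 + "G" * 39)  # 35.00% at 60 aa
        below = ProteinRecord("y", "P" * 20 + "G" * 40)
        kept = length_past_filter([exactly35, below], ScreenParams(min_len=50))
        assert [p.id for p in kept] == ["x"]

    def test_order_preserved(self, small_proteome):
        records, _ = small_proteome
        kept = length_past_filter(records)
        ids = [r.id for r in records]
        assert [r.id for r in kept] == [i for i in ids if i in {k.id for k in kept}]

    def test_relaxing_thresholds_never_shrinks_result(self, small_proteome):
        records, _ = small_proteome
        base = {p.id for p in length_past_filter(records, ScreenParams())}
        for relaxed in (
            ScreenParams(min_len=40),
            ScreenParams(max_len=90),
            ScreenParams(past_min_pct=20.0),
        ):
            assert base <= {p.id for p in length_past_filter(records, relaxed)}


class TestEvidenceJoin:
    recs = [ProteinRecord(f"p{i}", "PASTAPST" * 8) for i in range(3)]

    def test_require_sp_drops_negatives(self):
        sp = {"p0": True, "p1": True, "p2": False}
        rows = apply_evidence(self.recs, sp, {}, ScreenParams())
        assert [r.protein.id for r in rows] == ["p0", "p1"]

    def test_gpi_recorded_not_required_by_default(self):
        sp = {r.id: True for r in self.recs}
        gpi = {r.id: False for r in self.recs}
        rows = apply_evidence(self.recs, sp, gpi, ScreenParams())
        assert len(rows) == 3 and all(not r.gpi for r in rows)

    def test_require_gpi_flag(self):
        sp = {r.id: True for r in self.recs}
        gpi = {"p0": True, "p1": False, "p2": False}
        rows = apply_evidence(self.recs, sp, gpi, ScreenParams(require_gpi=True))
        assert [r.protein.id for r in rows] == ["p0"]

    def test_missing_calls_warn_by_default_and_error_in_strict(self):
        sp = {"p0": True}
        with pytest.warns(UserWarning, match="without predictor"):
            rows = apply_evidence(self.recs, sp, {}, ScreenParams())
        assert [r.protein.id for r in rows] == ["p0"]
        with pytest.raises(KeyError, match="p1"):
            apply_evidence(self.recs, sp, {}, ScreenParams(missing_policy="error"))

    def test_row_invariants(self):
        sp = {r.id: True for r in self.recs}
        for r in apply_evidence(self.recs, sp, {}, ScreenParams()):
            assert r.aa_size == len(r.protein.seq)
            assert r.past_pct == pytest.approx(
                round(past_fraction(r.protein.seq), 2), abs=0.005
            )


class TestRepeatAndDomainExclusion:
    def _rows(self):
        sp = {"a": True, "b": True}
        return apply_evidence(
            [ProteinRecord("a", "G" * 30 + "PAST" * 8), ProteinRecord("b", "GPGS" * 16)],
            sp, {}, ScreenParams(),
        )

    def test_repeat_total_threshold(self):
        rows = self._rows()
        assert {r.protein.id for r in rows} == {"a", "b"}
        kept = apply_repeat_and_domain_exclusion(rows, {}, ScreenParams(min_repeat_total=1))
        assert "b" not in {r.protein.id for r in kept}  # GPGS has no AP/PA/SP/TP

    def test_any_domain_excludes_with_empty_allowlist(self):
        rows = self._rows()
        kept = apply_repeat_and_domain_exclusion(
            rows, {"a": {"PF00234"}}, ScreenParams()
        )
        assert "a" not in {r.protein.id for r in kept}

    def test_allowlisted_domain_retained(self):
        rows = self._rows()
        kept = apply_repeat_and_domain_exclusion(
            rows, {"a": {"PF00234"}},
            ScreenParams(domain_allowlist=frozenset({"PF00234"})),
        )
        assert "a" in {r.protein.id for r in kept}


class TestFullScreen:
    def test_recovers_exactly_planted_peptides(self, small_proteome):
        records, truths = small_proteome
        sp, gpi = annot.heuristic_calls(records)
        rows = run_screen(records, sp, gpi)
        assert sorted(r.protein.id for r in rows) == sorted(
            t.protein.id for t in truths
        )

    def test_survivors_satisfy_thresholds(self, small_proteome):
        records, _ = small_proteome
        sp, gpi = annot.heuristic_calls(records)
        p = ScreenParams()
        for r in run_screen(records, sp, gpi, params=p):
            assert p.min_len <= r.aa_size <= p.max_len
            assert r.past_pct >= p.past_min_pct
            assert r.repeat_total >= p.min_repeat_total
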