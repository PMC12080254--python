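"""Rule engine: CLP cutoffs, tier combination, known-list lookup."""

from __future__ import annotations

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pmtscreen.io import KnownListEntry, PropertyRecord
from pmtscreen.rules import (
    CANDIDATE,
    NOT_ESTABLISHED,
    NOT_M,
    NOT_P,
    NOT_PMT_VPVM,
    P,
    PMT,
    PMT_AND_VPVM,
    T,
    UNKNOWN,
    UNRESOLVED,
    VM,
    VP,
    VPVM,
    M,
    CriterionTier,
    RuleConfig,
    assess_mobility,
    assess_persistence,
    assess_toxicity,
    combine_tiers,
    lookup_known,
)

from conftest import record


def props(hl=(), koc=(), flags=(), evidence="experimental") -> PropertyRecord:
    return PropertyRecord(
        compound_id="X",
        half_lives_freshwater_days=list(hl),
        log_koc_by_ph=list(koc),
        tox_flags=set(flags),
        evidence_quality=evidence,
    )


class TestPersistence:
    @pytest.mark.parametrize(
        "half_lives, expected",
        [
            ([50], P),          # between the 40 d and 60 d cutoffs
            ([1000], VP),
            ([], UNKNOWN),
            ([40], NOT_P),      # boundary: exactly 40 d is not persistent
            ([60], P),          # boundary: exactly 60 d is P but not vP
            ([61], VP),
            ([39.9], NOT_P),
        ],
    )
    def test_cutoffs(self, half_lives, expected):
        assert assess_persistence(props(hl=half_lives)) == expected

    def test_median_aggregation_default_max_optional(self):
        p = props(hl=[10, 50, 55])
        assert assess_persistence(p) == P  # median 50
        cfg = RuleConfig(half_life_aggregation="max")
        assert assess_persistence(p, cfg) == P  # max 55 still below 60
        assert assess_persistence(props(hl=[10, 10, 70]), cfg) == VP

    @settings(max_examples=50, derandomize=True)
    @given(
        hl=st.lists(st.floats(0.1, 500), min_size=1, max_size=5),
        bump=st.floats(0.0, 500),
    )
    def test_monotone_in_half_life(self, hl, bump):
        order = [NOT_P, P, VP]
        before = assess_persistence(props(hl=hl))
        after = assess_persistence(props(hl=[h + bump for h in hl]))
        assert order.index(after) >= order.index(before)


class TestMobility:
    @pytest.mark.parametrize(
        "koc, expected",
        [
            ([(7, 2.5)], M),
            ([(7, 3.0)], NOT_M),      # strict < 3.0
            ([(7, 2.0)], M),          # strict < 2.0, so exactly 2.0 is only M
            ([(7, 1.99)], VM),
            ([(5, 1.0), (8, 2.6)], VM),   # minimum over pH wins
            ([], UNKNOWN),
        ],
    )
    def test_cutoffs(self, koc, expected):
        assert assess_mobility(props(koc=koc)) == expected

    def test_min_aggregation_matches_bruteforce(self):
        pairs = [(4.5, 2.9), (6.0, 1.4), (8.5, 3.3)]
        # brute-force aggregation over listed pH pairs
        best = min(v for _, v in pairs)
        assert best == 1.4
        assert assess_mobility(props(koc=pairs)) == VM

    @settings(max_examples=50, derandomize=True)
    @given(
        koc=st.lists(st.tuples(st.floats(4, 9), st.floats(-1, 6)),
                     min_size=1, max_size=5),
        drop=st.floats(0.0, 5),
    )
    def test_monotone_in_log_koc(self, koc, drop):
        order = [NOT_M, M, VM]
        before = assess_mobility(props(koc=koc))
        lowered = [(ph, v - drop) for ph, v in koc]
        after = assess_mobility(props(koc=lowered))
        assert order.index(after) >= order.index(before)


class TestToxicity:
    def test_any_flag_is_toxic(self):
        assert assess_toxicity(props(flags={"endocrine_disruption"})) == T
        assert assess_toxicity(props(flags={"STOT_RE", "CMR"})) == T

    def test_no_flags_with_experimental_evidence(self):
        assert assess_toxicity(props()) == NOT_ESTABLISHED

    def test_no_evidence_is_unknown(self):
        assert assess_toxicity(props(evidence="none")) == UNKNOWN

    def test_adding_a_flag_never_removes_T(self):
        for flags in ({"CMR"}, {"CMR", "aquatic_tox"}):
            assert assess_toxicity(props(flags=flags)) == T


def oracle_combine(p: str, m: str, t: str) -> str:
    """Independent hand-enumerated tier combination.

    Written as explicit case analysis over the class definitions: PMT needs
    P+M+T, vPvM needs vP+vM only, both when both hold; a hard failure on P or
    M is negative regardless; otherwise missing information is unresolved.
    """
    if p == NOT_P or m == NOT_M:
        return NOT_PMT_VPVM
    p_ok = p in (P, VP)
    m_ok = m in (M, VM)
    very = (p == VP) and (m == VM)
    if p_ok and m_ok:
        if t == T:
            return PMT_AND_VPVM if very else PMT
        if very:
            return VPVM
        return NOT_PMT_VPVM if t == NOT_ESTABLISHED else UNRESOLVED
    return UNRESOLVED  # some tier unknown and nothing definitively failed


class TestCombineTiers:
    def test_exhaustive_truth_table(self):
        for p, m, t in itertools.product(
            (NOT_P, P, VP, UNKNOWN), (NOT_M, M, VM, UNKNOWN),
            (T, NOT_ESTABLISHED, UNKNOWN),
        ):
            got = combine_tiers(CriterionTier(p, m, t))
            assert got == oracle_combine(p, m, t), (p, m, t)

    @pytest.mark.parametrize(
        "tier, expected",
        [
            ((VP, VM, T), PMT_AND_VPVM),
            ((P, M, T), PMT),
            ((VP, VM, NOT_ESTABLISHED), VPVM),   # toxicity not needed for vPvM
            ((VP, VM, UNKNOWN), VPVM),
            ((P, M, NOT_ESTABLISHED), NOT_PMT_VPVM),
            ((UNKNOWN, VM, T), UNRESOLVED),
            ((NOT_P, VM, T), NOT_PMT_VPVM),
            ((P, M, UNKNOWN), UNRESOLVED),
        ],
    )
    def test_printed_cases(self, tier, expected):
        assert combine_tiers(CriterionTier(*tier)) == expected

    def test_candidate_class_reserved_for_ml(self):
        # the rule engine can never produce a candidate classification
        for p, m, t in itertools.product(
            (NOT_P, P, VP, UNKNOWN), (NOT_M, M, VM, UNKNOWN),
            (T, NOT_ESTABLISHED, UNKNOWN),
        ):
            assert combine_tiers(CriterionTier(p, m, t)) != CANDIDATE


class TestLookupKnown:
    KNOWN = [
        KnownListEntry(match_key="CCO", listed_class="vPvM"),
        KnownListEntry(match_key="50-00-0", listed_class="PMT"),
    ]

    def test_match_by_structure(self):
        hit = lookup_known(record("OCC", cid="A"), self.KNOWN)
        assert hit is not None
        assert hit.hazard_class == "vPvM" and hit.decided_by == "known_list"

    def test_match_by_cas_when_structure_differs(self):
        rec = record("C=O", cid="B")
        rec.cas = "50-00-0"
        hit = lookup_known(rec, self.KNOWN)
        assert hit is not None and hit.hazard_class == "PMT"

    def test_absent_compound_returns_none(self):
        assert lookup_known(record("CCCC", cid="C"), self.KNOWN) is None
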