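"""Candidate selection, matching, scoring law, ranking — with a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aifannot import (
    AIF,
    CandidateAnnotation,
    Feature,
    Library,
    LibraryFragment,
    LibraryRecord,
    MatchResult,
    PseudoPeak,
    PseudoSpectrum,
    ScoringConfig,
    Spectrum,
    annotate_feature,
    match_fragments,
    rank_candidates,
    score_candidate,
    select_candidates,
)
from aifannot.engine import IonMatch, ppm_error
from aifannot.simulate import CARBON_SPACING


def _record(name="X", adduct="[M+H]+", parent=500.0, frag_specs=()):
    frags = [LibraryFragment(mz, s, "") for mz, s in frag_specs]
    return LibraryRecord(name, adduct, "positive", parent,
                         parent_occurrence_score=1.0, fragments=frags)


def _pseudo(feature_mz, mzs, fallback=False, theta=0.8):
    feat = Feature(mz=feature_mz, rt=100.0)
    peaks = [PseudoPeak(m, 1000.0, None if fallback else 0.95) for m in mzs]
    return PseudoSpectrum(feature=feat, peaks=peaks, is_fallback=fallback, theta=theta)


def _aif(mzs):
    mzs = np.sort(np.asarray(mzs, dtype=float))
    return Spectrum(rt=100.0, channel=AIF, mz=mzs,
                    intensity=np.full(len(mzs), 500.0))


class TestSelectCandidates:
    def test_ppm_error_hand_computed(self):
        lib = Library([_record("PC(34:1)", parent=760.5851)], "positive")
        out = select_candidates(760.5860, lib, ppm_tol=25.0)
        assert len(out) == 1
        rec, match_type, e, matched_mz = out[0]
        # E = (760.5860 - 760.5851)/760.5851 * 1e6 = 1.1833... ppm, by hand
        assert e == pytest.approx(1.18, abs=0.01)
        assert match_type == "parent"
        assert matched_mz == pytest.approx(760.5851)

    def test_exact_match_zero_error(self):
        lib = Library([_record(parent=500.0)], "positive")
        out = select_candidates(500.0, lib)
        assert out[0][2] == 0.0

    def test_second_pass_in_source_fragment(self):
        lib = Library(
            [_record("PC(34:1)", parent=760.5851,
                     frag_specs=((184.0733, 1.0),))],
            "positive",
        )
        out = select_candidates(184.0733, lib, ppm_tol=25.0)
        assert len(out) == 1
        assert out[0][1] == "in-source fragment"
        assert out[0][3] == pytest.approx(184.0733)

    def test_first_pass_suppresses_second(self):
        # parent match exists -> fragment-only records are not consulted
        lib = Library(
            [
                _record("A", parent=500.0),
                _record("B", parent=900.0, frag_specs=((500.0, 1.0),)),
            ],
            "positive",
        )
        out = select_candidates(500.0, lib)
        assert [r.metabolite_name for r, *_ in out] == ["A"]

    def test_no_match_empty(self):
        lib = Library([_record(parent=500.0)], "positive")
        assert select_candidates(100.0, lib) == []


class TestMatchFragments:
    def test_pseudo_precedence_with_aif_fallback(self):
        rec = _record(parent=760.5851,
                      frag_specs=((184.0733, 1.0), (104.1070, 0.5)))
        pseudo = _pseudo(760.5851, [184.0730])
        aif = _aif([184.0733, 104.1070, 760.5851])
        match = match_fragments(rec, pseudo, aif, frag_tol=0.01)
        p_libs = {m.library_mz for m in match.P}
        a_libs = {m.library_mz for m in match.A}
        assert p_libs == {184.0733}
        assert 104.1070 in a_libs
        assert p_libs.isdisjoint(a_libs)

    def test_fallback_routes_everything_to_aif(self):
        rec = _record(parent=500.0, frag_specs=((184.0733, 1.0),))
        pseudo = _pseudo(500.0, [184.0733, 500.0], fallback=True)
        aif = _aif([184.0733, 500.0])
        match = match_fragments(rec, pseudo, aif)
        assert match.P == []
        assert {m.library_mz for m in match.A} == {500.0, 184.0733}
        assert match.parent_matched_in == "aif"

    def test_beyond_tolerance_not_matched(self):
        rec = _record(parent=500.0, frag_specs=((300.0000, 1.0),))
        match = match_fragments(rec, _pseudo(500.0, [300.0150]), _aif([300.0150]))
        assert all(m.library_mz != 300.0 for m in match.P + match.A)


class TestScoringLaw:
    @pytest.mark.parametrize("E,expected_smz", [
        (0.0, 1.0), (0.5, 1.0), (1.0, 1.0), (4.0, 0.25), (25.0, 0.04),
    ])
    def test_smz_is_reciprocal_error_bounded_at_unity(self, E, expected_smz):
        rec = _record()
        s_mz, _, _ = score_candidate(E, MatchResult(), rec)
        assert s_mz == pytest.approx(expected_smz, abs=1e-12)

    def test_worked_example(self):
        # E=4, P scores {1.0, 0.5}, A scores {1.0}, w=0.5
        rec = _record()
        match = MatchResult(
            P=[IonMatch("parent", 500.0, 500.0, 1.0),
               IonMatch("f1", 300.0, 300.0, 0.5)],
            A=[IonMatch("f2", 200.0, 200.0, 1.0)],
        )
        s_mz, s_ma, s = score_candidate(4.0, match, rec, ScoringConfig(w_mz=0.5))
        assert s_mz == pytest.approx(0.25)
        assert s_ma == pytest.approx(2.0)
        assert s == pytest.approx(1.125)

    def test_no_matches_scores_wmz_only(self):
        _, s_ma, s = score_candidate(10.0, MatchResult(), _record(),
                                     ScoringConfig(w_mz=0.5))
        assert s_ma == 0.0
        assert s == pytest.approx(0.05)

    def test_negative_error_rejected(self):
        with pytest.raises(ValueError):
            score_candidate(-1.0, MatchResult(), _record())

    @settings(derandomize=True, max_examples=60)
    @given(
        E=st.floats(0, 100, allow_nan=False),
        scores=st.lists(st.floats(0, 2), max_size=6),
        new_score=st.floats(0, 2),
    )
    def test_adding_any_match_never_decreases_s(self, E, scores, new_score):
        rec = _record()
        base = MatchResult(P=[IonMatch(f"i{k}", 100.0 + k, 100.0 + k, sc)
                              for k, sc in enumerate(scores)])
        _, _, s0 = score_candidate(E, base, rec)
        extra = IonMatch("new", 90.0, 90.0, new_score)
        for where in ("P", "A"):
            grown = MatchResult(P=list(base.P), A=list(base.A))
            getattr(grown, where).append(extra)
            _, _, s1 = score_candidate(E, grown, rec)
            assert s1 >= s0 - 1e-12

    @settings(derandomize=True, max_examples=60)
    @given(E=st.floats(0, 100), score=st.floats(0, 2))
    def test_promoting_a_match_to_pseudo_never_decreases_s(self, E, score):
        rec = _record()
        ion = IonMatch("f", 200.0, 200.0, score)
        _, _, s_aif = score_candidate(E, MatchResult(A=[ion]), rec)
        _, _, s_pseudo = score_candidate(E, MatchResult(P=[ion]), rec)
        assert s_pseudo >= s_aif - 1e-12


class TestRanking:
    def _cand(self, name, S, E=1.0, n_p=0):
        rec = _record(name=name)
        match = MatchResult(P=[IonMatch(f"i{k}", 100.0 + k, 100.0 + k, 1.0)
                               for k in range(n_p)])
        cand = CandidateAnnotation(
            record=rec, feature=Feature(mz=500.0, rt=1.0), match_type="parent",
            isotopologue=None, E=E, matched_library_mz=500.0, match=match,
        )
        cand.S = S
        return cand

    def test_descending_scores(self):
        ranked = rank_candidates([self._cand("a", 1.0), self._cand("b", 2.0)])
        assert [c.record.metabolite_name for c in ranked] == ["b", "a"]
        assert [c.rank for c in ranked] == [1, 2]

    def test_tie_broken_by_lower_error(self):
        ranked = rank_candidates([self._cand("a", 1.0, E=5.0),
                                  self._cand("b", 1.0, E=1.0)])
        assert ranked[0].record.metabolite_name == "b"

    def test_tie_then_more_pseudo_matches_then_name(self):
        ranked = rank_candidates([
            self._cand("z", 1.0, E=1.0, n_p=2),
            self._cand("a", 1.0, E=1.0, n_p=1),
            self._cand("b", 1.0, E=1.0, n_p=1),
        ])
        assert [c.record.metabolite_name for c in ranked] == ["z", "a", "b"]

    def test_single_candidate_rank_one(self):
        assert rank_candidates([self._cand("only", 0.3)])[0].rank == 1


# ---------------------------------------------------------------------------
# Brute-force oracle: exhaustive matching + direct arithmetic, no engine code.

def _oracle_match_and_score(record, pseudo_mzs, aif_mzs, is_fallback, cfg):
    """Enumerate every (library ion, observed peak) pair; nearest within tol wins.

    Pure-python re-derivation of the matching and scoring contract used to
    cross-check the engine exactly.
    """
    ions = [("parent", record.parent_mz, record.parent_occurrence_score)]
    ions += [(f"frag{i}", f.mz, f.occurrence_score)
             for i, f in enumerate(record.fragments)]
    P, A = [], []
    for label, lib_mz, s in ions:
        best_pseudo = None
        if not is_fallback:
            for obs in pseudo_mzs:
                d = abs(obs - lib_mz)
                if d <= cfg.frag_tol and (best_pseudo is None or d < abs(best_pseudo - lib_mz)):
                    best_pseudo = obs
        if best_pseudo is not None:
            P.append((label, s, best_pseudo))
            continue
        best_aif = None
        for obs in aif_mzs:
            d = abs(obs - lib_mz)
            if d <= cfg.frag_tol and (best_aif is None or d < abs(best_aif - lib_mz)):
                best_aif = obs
        if best_aif is not None:
            A.append((label, s, best_aif))
    return P, A


def _oracle_score(E, P, A, cfg):
    s_mz = 1.0 if E <= 1.0 else 1.0 / E
    s_ma = sum(s for _, s, _ in P) + sum(s for _, s, _ in A) / cfg.aif_downweight
    return s_mz, s_ma, cfg.w_mz * s_mz + (1.0 - cfg.w_mz) * s_ma


class TestBruteForceOracle:
    @pytest.mark.parametrize("seed", range(6))
    def test_engine_reproduces_oracle_exactly(self, seed):
        """Randomized candidate sets (<=10 candidates x <=10 ions) vs enumeration."""
        rng = np.random.default_rng(seed)
        cfg = ScoringConfig(w_mz=0.5)
        n_cand = int(rng.integers(1, 11))
        records = []
        for i in range(n_cand):
            n_frag = int(rng.integers(0, 10))
            parent = float(rng.uniform(400, 900))
            frag_specs = [
                (float(rng.uniform(80, 400)), float(rng.choice([0.25, 0.5, 1.0])))
                for _ in range(n_frag)
            ]
            # unique fragment m/z within a record
            seen, uniq = set(), []
            for mz, s in frag_specs:
                if round(mz, 4) not in seen:
                    seen.add(round(mz, 4))
                    uniq.append((mz, s))
            records.append(_record(name=f"C{i}", parent=parent, frag_specs=uniq))
        # observed peaks: jittered copies of some library ions + decoys
        all_ions = [mz for r in records for mz in r.ion_mzs]
        chosen = rng.choice(all_ions, size=min(8, len(all_ions)), replace=False)
        pseudo_mzs = [float(m + rng.uniform(-0.008, 0.008)) for m in chosen[: len(chosen) // 2]]
        aif_mzs = [float(m + rng.uniform(-0.008, 0.008)) for m in chosen] + [77.7]
        fallback = bool(rng.random() < 0.3)
        pseudo = _pseudo(500.0, pseudo_mzs, fallback=fallback)
        aif = _aif(aif_mzs)

        cands = []
        for rec in records:
            E = float(rng.uniform(0, 25))
            match = match_fragments(rec, pseudo, aif, frag_tol=cfg.frag_tol)
            s_mz, s_ma, s = score_candidate(E, match, rec, cfg)
            # oracle comparison of P/A sets and all three scores
            o_P, o_A = _oracle_match_and_score(rec, pseudo_mzs, aif_mzs, fallback, cfg)
            assert sorted((m.ion_label, m.occurrence_score) for m in match.P) == \
                sorted((lbl, s_) for lbl, s_, _ in o_P)
            assert sorted((m.ion_label, m.occurrence_score) for m in match.A) == \
                sorted((lbl, s_) for lbl, s_, _ in o_A)
            o_smz, o_sma, o_s = _oracle_score(E, o_P, o_A, cfg)
            assert s_mz == pytest.approx(o_smz, abs=1e-12)
            assert s_ma == pytest.approx(o_sma, abs=1e-12)
            assert s == pytest.approx(o_s, abs=1e-12)
            cand = CandidateAnnotation(
                record=rec, feature=Feature(mz=500.0, rt=1.0), match_type="parent",
                isotopologue=None, E=E, matched_library_mz=rec.parent_mz,
                match=match, S_mz=s_mz, S_ma=s_ma, S=s,
            )
            cands.append((cand, o_s))
        ranked = rank_candidates([c for c, _ in cands])
        # oracle ranking: same composite sort key
        oracle_order = sorted(
            cands,
            key=lambda t: (-t[1], t[0].E, -len(t[0].match.P),
                           t[0].record.metabolite_name, t[0].record.adduct),
        )
        assert [c.record.metabolite_name for c in ranked] == \
            [c.record.metabolite_name for c, _ in oracle_order]


class TestAnnotateFeatureEndToEnd:
    def test_clean_single_compound_rank1(self, clean_sim):
        t = clean_sim.truth_parents()[3]
        res = annotate_feature(
            clean_sim.run, Feature(mz=t.mz, rt=t.rt, id=t.feature_id),
            clean_sim.library, ScoringConfig(),
        )
        assert res.annotated
        assert res.top.record.metabolite_name == t.name
        assert res.top.rank == 1
        assert res.isotopologue.offset == 0

    def test_m_plus_one_feature_same_annotation(self, clean_sim):
        t = clean_sim.truth_parents()[3]
        res = annotate_feature(
            clean_sim.run,
            Feature(mz=t.mz + CARBON_SPACING, rt=t.rt, id="m1"),
            clean_sim.library, ScoringConfig(),
        )
        assert res.top.record.metabolite_name == t.name
        assert res.isotopologue.offset == 1

    def test_unknown_mz_not_annotated(self, clean_sim):
        t = clean_sim.truth_parents()[0]
        res = annotate_feature(
            clean_sim.run, Feature(mz=1111.1111, rt=t.rt, id="none"),
            clean_sim.library, ScoringConfig(),
        )
        assert not res.annotated

    def test_rt_class_filter_drops_out_of_window_candidates(self, clean_sim):
        from aifannot import RtClassWindow

        t = clean_sim.truth_parents()[3]
        window = RtClassWindow(class_pattern="CPD", rt_lo=t.rt + 100,
                               rt_hi=t.rt + 200)
        res = annotate_feature(
            clean_sim.run, Feature(mz=t.mz, rt=t.rt, id=t.feature_id),
            clean_sim.library, ScoringConfig(), rt_classes=[window],
        )
        assert not res.annotated


def test_ppm_error_definition():
    assert ppm_error(760.5860, 760.5851) == pytest.approx(
        (760.5860 - 760.5851) / 760.5851 * 1e6
    )
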