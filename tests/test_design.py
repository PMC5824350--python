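"""Design engine: strategy selection, the four procedures, constraints."""

import pytest

from miprimer import thermo
from miprimer.design import (
    FR_FPM,
    FR_OVERLAP,
    FR_RPM,
    UNI,
    DesignConfig,
    DesignError,
    _ForwardState,
    build_forward_core,
    build_reverse_specific,
    choose_discriminating_position,
    design,
    design_fr_fpm,
    design_fr_overlap,
    design_fr_rpm,
    design_uni,
    extend_tail_to_tm,
    predict_discrimination,
    reduce_dt_variant,
    select_strategy,
)
from miprimer.fixtures import FixtureSpec, generate_panel
from miprimer.seqio import MiRNA, SequencePanel, group_families, reverse_complement

# adversarial targets (constructed so that a specific remediation branch
# must fire; see the docstrings of the tests using them)
ADV_UNI = MiRNA("adv-uni", "ACGAAUUGCCUACGAUAAUUAA")  # 5' = rc of the universal 3' end
ADV_REV_DIMER = (  # family whose reverse primer spans a GC palindrome
    MiRNA("advR-a", "AUAUAAUUAUGCGCGCGCGCAU"),
    MiRNA("advR-b", "AUAUAAUUAUACGCGCGCGCAU"),
)
ADV_FWD_DIMER = (  # family whose forward core spans a GC palindrome
    MiRNA("advF-a", "GCGCGCGCGCAAUUAAUAUUAU"),
    MiRNA("advF-b", "GCGCGCGCGCAUUUAAUAUUAU"),
)


def _assert_constraints(r, cfg, floor):
    """The published design constraints, recomputed independently."""
    f, v = r.forward, r.reverse
    assert abs(f.tm - v.tm) <= cfg.tm_diff_max + cfg.tm_diff_tol
    assert f.tm >= floor - cfg.tm_diff_tol
    params = cfg.thermo_params()
    for dg in (
        thermo.self_dimer_delta_g(f.sequence, params).delta_g,
        thermo.self_dimer_delta_g(v.sequence, params).delta_g,
        thermo.duplex_delta_g(f.sequence, v.sequence, params).delta_g,
    ):
        assert thermo.dimer_check(dg, cfg.dg_threshold, cfg.dg_tolerance) in (
            "pass",
            "review",
        )


class TestSelectStrategy:
    def test_singleton_panel_is_uni(self, cfg):
        t = MiRNA("solo", "UGAGGUAGUAGGUUGUAUAGUU")
        assert select_strategy(t, SequencePanel(members=[t]), cfg) == UNI

    def test_below_threshold_is_uni(self, cfg, mir18_panel):
        # miR-122 has < 90% similarity to both miR-18 members
        t = mir18_panel.get("hsa-miR-122-5p")
        assert select_strategy(t, mir18_panel, cfg) == UNI

    def test_single_nucleotide_variant_is_fr(self, cfg, mir18_panel):
        t = mir18_panel.get("hsa-miR-18b-5p")
        assert select_strategy(t, mir18_panel, cfg) == FR_OVERLAP


class TestBuildForwardCore:
    def test_core_is_prefix_within_range(self, cfg):
        t = MiRNA("x", "UGAGGUAGUAGGUUGUAUAGUU")
        core = build_forward_core(t, cfg).segment("core")
        assert t.dna.startswith(core)
        assert 12 <= len(core) <= 18

    def test_short_target_clamps_to_its_length(self, cfg):
        t = MiRNA("short", "UGAGGUAGUAGGUUGU")  # 16 nt
        core = build_forward_core(t, cfg).segment("core")
        assert 12 <= len(core) <= 16

    def test_too_short_target_rejected(self, cfg):
        cfg2 = DesignConfig(fwd_core_len_range=(18, 18))
        with pytest.raises(DesignError):
            build_forward_core(MiRNA("s", "UGAGGUAGUAGGUUGU"), cfg2)

    def test_gc_rich_selects_shorter_or_equal_core(self, cfg):
        # equal length, same range: the Tm-proximity rule cannot pick a
        # longer core for the hotter (GC-rich) sequence
        at = MiRNA("at", "UAUAAUUAUAUUAAUAUUAUAA")
        gc = MiRNA("gc", "UGCGGCCGCAGCCGGCGCCGGC")
        len_at = len(build_forward_core(at, cfg).segment("core"))
        len_gc = len(build_forward_core(gc, cfg).segment("core"))
        assert len_gc <= len_at


class TestExtendTail:
    def test_noop_when_already_at_floor(self, cfg, params):
        t = MiRNA("x", "UGCGGCCGCAGCCGGCGCCGGC")  # hot GC-rich core
        state = _ForwardState(t, core_len=14, min_core=12)
        assert state.build(cfg, params).tm >= 57.0
        out, reached = extend_tail_to_tm(state, cfg, 57.0, params)
        assert reached and out == state

    def test_first_achievement_matches_exhaustive_scan(self, cfg, params):
        t = MiRNA("x", "UAUAAUUAUAUUAAUAUUAUAA")  # cold AT-rich core
        state = _ForwardState(t, core_len=14, min_core=12)
        out, reached = extend_tail_to_tm(state, cfg, cfg.tm_floor_uni_forward, params)
        from dataclasses import replace

        achievable = [
            tl
            for tl in range(0, 11)
            if replace(state, tail_len=tl).build(cfg, params).tm >= cfg.tm_target
        ]
        if achievable:
            assert reached and out.tail_len == min(achievable)
        else:
            assert not reached and out.tail_len == 10

    def test_fragment_is_tail_suffix(self, cfg, params):
        t = MiRNA("x", "UAUAAUUAUAUUAAUAUUAUAA")
        state = _ForwardState(t, core_len=14, min_core=12)
        out, _ = extend_tail_to_tm(state, cfg, cfg.tm_floor_uni_forward, params)
        frag = out.build(cfg, params).segment("tail_fragment")
        assert cfg.tail_expansions()[out.tail_idx].endswith(frag)


class TestBuildReverseSpecific:
    def test_construction_k4_dt20(self, cfg):
        t = MiRNA("x", "UGAGGUAGUAGGUUGUAACUGG")  # ends ...CUGG
        p = build_reverse_specific(t, k=4, dt=20, j=0, cfg=cfg)
        assert p.sequence == "T" * 20 + "CCAG"

    def test_universal_suffix_prepended(self, cfg):
        t = MiRNA("x", "UGAGGUAGUAGGUUGUAACUGG")
        p = build_reverse_specific(t, k=4, dt=20, j=3, cfg=cfg)
        assert p.sequence == "CGT" + "T" * 20 + "CCAG"
        assert p.segment("universal_fragment") == cfg.universal_reverse[-3:]

    def test_growing_j_raises_tm(self, cfg):
        # the trend is upward; individual AT-rich steps may dip a few
        # tenths of a degree (adding a low-stability stack to a hot duplex
        # lowers the two-state Tm), so strict monotonicity is not asserted
        t = MiRNA("x", "UGAGGUAGUAGGUUGUAACUGG")
        tms = [
            build_reverse_specific(t, k=6, dt=20, j=j, cfg=cfg).tm for j in range(0, 25)
        ]
        assert tms[-1] > tms[0] + 10.0
        assert all(b >= a - 0.5 for a, b in zip(tms, tms[1:]))

    def test_k_out_of_range_rejected(self, cfg):
        t = MiRNA("x", "UGAGGUAGUAGGUUGUAACUGG")
        with pytest.raises(DesignError):
            build_reverse_specific(t, k=9, dt=20, j=0, cfg=cfg)


class TestDesignUni:
    def test_seeded_singletons_all_satisfy_constraints(self, cfg):
        spec = FixtureSpec(rng_seed=3, n_singletons=30, family_sizes=())
        panel = generate_panel(spec)
        n_ok = 0
        for m in panel:
            r = design_uni(m, panel, cfg)
            if r.ok:
                n_ok += 1
                _assert_constraints(r, cfg, cfg.tm_floor_uni_forward)
                # forward 3' segment is a prefix copy of the target
                assert m.dna.startswith(r.forward.segment("core"))
        assert n_ok >= 28  # nearly every random singleton designs cleanly

    def test_adversarial_core_forces_replacement_reverse(self, cfg):
        """A target whose 5' end reverse-complements the universal primer
        cannot keep the universal reverse (hetero-dimer fails); the design
        must fall back to a redesigned specific reverse and succeed."""
        panel = SequencePanel(members=[ADV_UNI])
        r = design_uni(ADV_UNI, panel, cfg)
        assert any(e["rule"] == "uni:replacement_reverse_branch" for e in r.iteration_log)
        assert r.ok
        assert r.reverse.role == "reverse"
        assert r.dt_used == cfg.dt_length
        spec = r.reverse.segment("specific_3prime")
        assert reverse_complement(spec) == ADV_UNI.dna[-len(spec) :]
        k_lo, k_hi = cfg.rev_specific_len_range_uni
        assert k_lo <= len(spec) <= k_hi


class TestDesignFrOverlap:
    def test_overlap_at_difference_position(self, cfg):
        a = MiRNA("a", "UGAGGUAGUAGGUUGUAUAGUU")
        s = list(a.sequence)
        s[10] = "C"
        b = MiRNA("b", "".join(s))
        r = design_fr_overlap(a, [a, b], cfg, overlap=1)
        assert r.overlap_len == 1
        core = r.forward.segment("core")
        assert len(core) == 11  # spans 5' end through p = 10
        assert a.dna.startswith(core)
        spec = r.reverse.segment("specific_3prime")
        assert spec == reverse_complement(a.dna[10:])  # 3' base pairs at p

    def test_anchors_at_least_4nt(self, cfg, let7_like_family):
        for t in let7_like_family:
            r = design_fr_overlap(t, let7_like_family, cfg)
            core = r.forward.segment("core")
            spec = r.reverse.segment("specific_3prime")
            assert len(core) >= 4 and len(spec) >= 4

    def test_overlap_2_extends_forward_by_one(self, cfg):
        a = MiRNA("a", "UGAGGUAGUAGGUUGUAUAGUU")
        s = list(a.sequence)
        s[10] = "C"
        b = MiRNA("b", "".join(s))
        r1 = design_fr_overlap(a, [a, b], cfg, overlap=1)
        r2 = design_fr_overlap(a, [a, b], cfg, overlap=2)
        assert len(r2.forward.segment("core")) == len(r1.forward.segment("core")) + 1
        assert r2.reverse.segment("specific_3prime") == r1.reverse.segment(
            "specific_3prime"
        )

    def test_identical_sequences_rejected(self, cfg):
        a = MiRNA("a", "UGAGGUAGUAGGUUGUAUAGUU")
        b = MiRNA("b", "UGAGGUAGUAGGUUGUAUAGUU")
        with pytest.raises(DesignError):
            choose_discriminating_position(a, [a, b], cfg)


class TestEscalation:
    def test_reverse_dimer_escalates_to_fpm(self, cfg):
        """Family constructed so the overlap reverse spans a GC palindrome:
        its self-dimer fails, the ladder must land on FPM and clear it."""
        a, b = ADV_REV_DIMER
        panel = group_families(SequencePanel(members=[a, b]), 90.0)
        r = design(a, panel, cfg)
        assert r.strategy == FR_FPM
        assert r.ok
        rules = [e["rule"] for e in r.iteration_log]
        assert "escalate:overlap2" in rules and "escalate:FR_FPM" in rules
        # escalation soundness: a reverse-primer dimer failure was logged
        assert any(
            e["rule"] == "confirmation:dimer" and "self_R" in e.get("failures", [])
            for e in r.iteration_log
        )
        # forward covers a discriminating position; reverse keeps its anchor
        # or is exactly the universal primer
        core = r.forward.segment("core")
        diffs = [i for i, (x, y) in enumerate(zip(a.dna, b.dna)) if x != y]
        assert any(p < len(core) for p in diffs)
        spec = r.reverse.segment("specific_3prime")
        assert (len(spec) >= cfg.min_anchor_fr) or (
            r.reverse.sequence == cfg.universal_reverse
        )

    def test_forward_dimer_escalates_to_rpm(self, cfg):
        a, b = ADV_FWD_DIMER
        panel = group_families(SequencePanel(members=[a, b]), 90.0)
        r = design(a, panel, cfg)
        assert r.strategy == FR_RPM
        assert r.ok
        # reverse covers the discriminating position
        spec = r.reverse.segment("specific_3prime")
        start = len(a) - len(spec)
        diffs = [i for i, (x, y) in enumerate(zip(a.dna, b.dna)) if x != y]
        assert any(p >= start for p in diffs)
        # forward keeps >= 4 residues of the target's 5' sequence
        core = r.forward.segment("core")
        assert len(core) >= cfg.min_anchor_fr and a.dna.startswith(core)

    def test_escalation_order_never_skips(self, cfg):
        a, b = ADV_REV_DIMER
        panel = group_families(SequencePanel(members=[a, b]), 90.0)
        r = design(a, panel, cfg)
        rules = [e["rule"] for e in r.iteration_log if e["rule"].startswith("escalate")]
        assert rules == ["escalate:overlap2", "escalate:FR_FPM"]


class TestDesignOrchestration:
    def test_every_result_labelled_and_logged(self, cfg):
        spec = FixtureSpec(rng_seed=11, n_singletons=6, family_sizes=(2, 2))
        panel = group_families(generate_panel(spec), 90.0)
        for m in panel:
            r = design(m, panel, cfg)
            assert r.strategy in (UNI, FR_OVERLAP, FR_FPM, FR_RPM)
            assert r.iteration_log

    def test_determinism(self, cfg):
        spec = FixtureSpec(rng_seed=5, n_singletons=4, family_sizes=(2,))
        panel = group_families(generate_panel(spec), 90.0)
        rows1 = [
            (r.target_id, r.strategy, r.forward.sequence, r.reverse.sequence, r.status)
            for r in (design(m, panel, cfg) for m in panel)
        ]
        rows2 = [
            (r.target_id, r.strategy, r.forward.sequence, r.reverse.sequence, r.status)
            for r in (design(m, panel, cfg) for m in panel)
        ]
        assert rows1 == rows2


class TestReduceDtVariant:
    def _replacement_result(self, cfg):
        panel = SequencePanel(members=[ADV_UNI])
        return design_uni(ADV_UNI, panel, cfg)

    def test_reduces_to_15_and_rebalances(self, cfg):
        r = self._replacement_result(cfg)
        assert r.dt_used == 20
        v = reduce_dt_variant(r, cfg)
        assert v.dt_used == 15
        assert v.reverse.segment("dT_stretch") == "T" * 15
        # other segments unchanged
        assert v.reverse.segment("specific_3prime") == r.reverse.segment(
            "specific_3prime"
        )
        assert abs(v.forward.tm - v.reverse.tm) <= cfg.tm_diff_max + cfg.tm_diff_tol

    def test_reapplication_rejected(self, cfg):
        v = reduce_dt_variant(self._replacement_result(cfg), cfg)
        with pytest.raises(DesignError):
            reduce_dt_variant(v, cfg)

    def test_universal_reverse_result_rejected(self, cfg, mir18_panel):
        r = design_uni(mir18_panel.get("hsa-miR-122-5p"), mir18_panel, cfg)
        assert r.reverse.role == "universal_reverse"
        with pytest.raises(DesignError):
            reduce_dt_variant(r, cfg)


class TestPredictDiscrimination:
    def test_identical_off_target_not_discriminated(self, cfg, mir18_panel):
        t = mir18_panel.get("hsa-miR-18b-5p")
        fam = mir18_panel.family_of(t.id)
        r = design_fr_overlap(t, fam, cfg)
        twin = MiRNA("twin", t.sequence)
        assert predict_discrimination(r, [twin])["twin"] == "non-discriminating"

    def test_single_nucleotide_sibling_discriminated(self, cfg, mir18_panel):
        t = mir18_panel.get("hsa-miR-18b-5p")
        fam = mir18_panel.family_of(t.id)
        r = design_fr_overlap(t, fam, cfg)
        sib = mir18_panel.get("hsa-miR-18a-5p")
        assert predict_discrimination(r, [sib])[sib.id] == "discriminating"

    def test_let7_like_family_fully_discriminated(self, cfg, let7_like_family):
        for t in let7_like_family:
            r = design_fr_overlap(t, let7_like_family, cfg)
            others = [m for m in let7_like_family if m.id != t.id]
            classes = predict_discrimination(r, others)
            assert all(c == "discriminating" for c in classes.values()), (t.id, classes)
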