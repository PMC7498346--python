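"""Probe design: window selection, LNA placement rules, shortlisting and the
end-to-end pipeline, cross-checked against brute-force enumeration at toy scale."""

import itertools

import pytest

from painttools.config import load_docking_library
from painttools.errors import SequenceTooShortError, UnknownDockingError
from painttools.probe_design import (
    BackboneCandidate,
    DockingStrand,
    _vectorized_shortlist,
    assemble_probe,
    design,
    enumerate_lna_masks,
    screen_probe,
    select_backbones,
    shortlist,
    validate_lna_mask,
    write_order_sheet,
)
from painttools.thermo import (
    HybridizationConditions,
    LnaMask,
    hairpin,
    lna_tm,
    nn_thermo,
    reverse_complement,
    self_dimer,
)
from painttools.config import load_thermo_params
from painttools.sim import random_srna

from conftest import random_dna


# ------------------------------------------------------------ backbones

def test_backbone_window_count_for_24nt_target():
    cands = select_backbones("AUGGCUAGCAUCGGAUUCAGGAAU")
    # lengths 19..22 at all offsets: 6 + 5 + 4 + 3
    assert len(cands) == 18
    assert {len(c.sequence) for c in cands} == {19, 20, 21, 22}


def test_backbone_21nt_target_has_no_22mer_window():
    cands = select_backbones("AUGGCUAGCAUCGGAUUCAGG")
    assert max(len(c.sequence) for c in cands) == 21
    assert len(cands) == 3 + 2 + 1


def test_backbone_all_AT_target_all_under_ceiling_longest_first():
    cands = select_backbones("AUAUUAAUUAUAUAAUAUUAUAUA")
    assert all(c.under_ceiling for c in cands)
    assert len(cands[0].sequence) == 22
    # verified against the thermo module directly
    assert cands[0].tm_C == pytest.approx(nn_thermo(cands[0].sequence).tm_C)


def test_backbone_windows_are_revcomp_substrings():
    target = "AUGGCUAGCAUCGGAUUCAGGAAU"
    rc = reverse_complement(target)
    for c in select_backbones(target):
        assert rc[c.start : c.start + len(c.sequence)] == c.sequence


def test_backbone_too_short_target():
    with pytest.raises(SequenceTooShortError):
        select_backbones("AUGGCUAGCAUCGG")


# ------------------------------------------------------------ LNA masks

def test_validate_mask_accepts_eight_lnas_with_run_of_four():
    ok, reason = validate_lna_mask("ATATATATATATATATATA", LnaMask((0, 1, 2, 3, 8, 10, 12, 14)))
    assert ok and reason is None


def test_validate_mask_rejects_run_of_five():
    ok, reason = validate_lna_mask("ATATATATATATATATATA", LnaMask((0, 1, 2, 3, 4)))
    assert not ok and "run rule" in reason


def test_validate_mask_rejects_three_consecutive_gc_lnas():
    ok, reason = validate_lna_mask("GGGAATTAATTAATTAATT", LnaMask((0, 1, 2, 5, 8)))
    assert not ok and "G/C rule" in reason


def test_validate_mask_gc_rule_needs_consecutive_positions():
    # the three G/C LNAs are not a consecutive run of positions
    ok, _ = validate_lna_mask("GGGAATTAATTAATTAATT", LnaMask((0, 2, 4, 6, 8)))
    assert ok


def test_validate_mask_count_rule():
    ok, reason = validate_lna_mask("ATATATATATATATATATA", LnaMask((0, 2, 4, 6)))
    assert not ok and "count rule" in reason


def test_enumerate_masks_matches_brute_force_on_toy_backbone():
    backbone = "ATGCATGCAT"  # 10 nt
    yielded = list(enumerate_lna_masks(backbone, sizes=[5, 6]))
    brute = []
    for k in (5, 6):
        for combo in itertools.combinations(range(10), k):
            if validate_lna_mask(backbone, LnaMask(combo), (5, 6))[0]:
                brute.append(tuple(combo))
    assert [m.positions for m in yielded] == brute
    assert all(validate_lna_mask(backbone, m)[0] for m in yielded)


# ------------------------------------------------------------ shortlist

def _toy_stream(backbone_seq, sizes):
    bb = BackboneCandidate(backbone_seq, 0, nn_thermo(backbone_seq).tm_C, True)
    for m in enumerate_lna_masks(backbone_seq, sizes=sizes):
        yield bb, m


def test_shortlist_returns_all_when_k_large_and_sorted():
    backbone = "ATGCATGCATGCATGCATG"
    out = shortlist(_toy_stream(backbone, [5]), k=10**9)
    tms = [tm for _, _, tm in out]
    assert tms == sorted(tms, reverse=True)
    assert len(out) == len(list(enumerate_lna_masks(backbone, sizes=[5])))


def test_shortlist_top3_equals_brute_force():
    backbone = "ATGCATGCATGCATGCATG"
    params = load_thermo_params()
    all_pairs = list(_toy_stream(backbone, [5]))
    brute = sorted(
        all_pairs,
        key=lambda bm: (-(bm[0].tm_C + sum(params.lna_increments[backbone[p]]
                                           for p in bm[1].positions)),
                        bm[0].start, bm[1].positions),
    )[:3]
    got = shortlist(_toy_stream(backbone, [5]), k=3)
    assert [m.positions for _, m, _ in got] == [m.positions for _, m in brute]


def test_vectorized_shortlist_equals_streamed_path():
    backbone = BackboneCandidate("ATGCATGCATGCATG", 0, 50.0, True)
    params = load_thermo_params()
    fast = _vectorized_shortlist(backbone, 5, 40, params)
    slow = shortlist(((backbone, m) for m in
                      enumerate_lna_masks(backbone.sequence, sizes=[5])), k=40)
    assert [(m.positions, pytest.approx(tm)) for _, m, tm in slow] == \
           [(m.positions, tm) for _, m, tm in fast]


# ------------------------------------------------------------ assembly & screening

def test_assemble_lengths_and_linker_and_imager():
    lib = load_docking_library()
    bb = BackboneCandidate("ATGCATGCATGCATGCATGC", 0, 55.0, True)  # 20 nt
    d = DockingStrand("P0", lib["P0"])
    probe = assemble_probe(bb, LnaMask((0, 2, 4, 6, 8)), docking=d)
    assert len(probe.full_sequence) == 20 + 7 + 9
    assert probe.linker == "tattcgt"
    assert probe.imager == reverse_complement(d.sequence)


def test_unknown_docking_id_raises():
    from painttools.config import get_docking_sequence

    with pytest.raises(UnknownDockingError):
        get_docking_sequence(load_docking_library(), "P99")


def test_screen_scores_match_direct_thermo_calls():
    lib = load_docking_library()
    bb = BackboneCandidate("ATGCATGCATGCATGCATGC", 0, 55.0, True)
    mask = LnaMask((0, 2, 4, 6, 8))
    probe = assemble_probe(bb, mask, docking=DockingStrand("P1", lib["P1"]))
    screened = screen_probe(probe)
    full = probe.full_sequence.upper()
    assert screened.dimer_dG == self_dimer(full).dG
    assert screened.hairpin_dG == hairpin(full).dG
    assert screened.tm_refined_C == lna_tm(bb.sequence, mask, mode="refined").tm_C


def test_display_sequence_marks_lna_positions():
    lib = load_docking_library()
    bb = BackboneCandidate("ATGCA" * 4, 0, 55.0, True)
    probe = assemble_probe(bb, LnaMask((0, 3, 5, 7, 9)), docking=DockingStrand("P0", lib["P0"]))
    disp = probe.display_sequence()
    assert disp.startswith("+AT")
    assert disp.count("+") == 5
    assert "tattcgt" in disp


# ------------------------------------------------------------ full pipeline

def test_design_emitted_probes_satisfy_all_invariants(rng):
    lib = load_docking_library()
    for i in range(8):
        target = random_srna(int(rng.integers(21, 25)), seed=int(rng.integers(2**31)))
        res = design(target, docking_ids=["P0", "P1"], docking_library=lib)
        for did, probes in res.probes.items():
            assert len(probes) <= 10
            tms = [p.tm_refined_C for p in probes]
            assert tms == sorted(tms, reverse=True)
            for rank, p in enumerate(probes, start=1):
                assert p.rank == rank
                assert 19 <= len(p.backbone.sequence) <= 22
                assert 5 <= len(p.lna) <= 9
                assert validate_lna_mask(p.backbone.sequence, p.lna)[0]
                assert p.linker == "tattcgt"
                assert p.docking.sequence == lib[did]
                assert p.full_sequence.upper() == (
                    p.backbone.sequence + p.linker + p.docking.sequence
                ).upper()


def test_design_is_deterministic_byte_identical(tmp_path):
    target = "UUAGCCAAGGAUGACUUGCCGGUU"
    paths = []
    for i in (1, 2):
        res = design(target, docking_ids=["P1", "P2"])
        p = tmp_path / f"run{i}.tsv"
        write_order_sheet(res, "t1", p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_design_equals_brute_force_pipeline_at_toy_scale():
    """End-to-end oracle at reduced scale: 12-nt backbone cap, 5 LNAs."""
    target = "UUAGCCAAGGAUGACUUGCC"
    cond = HybridizationConditions()
    params = load_thermo_params()
    lib = load_docking_library()
    res = design(target, cond, docking_ids=["P1"], n_lna=5, lengths=(12, 12),
                 k_shortlist=50, top_n=5, docking_library=lib)

    # independent brute force: materialize everything
    rc = reverse_complement(target).upper()
    windows = [(rc[s : s + 12], s) for s in range(len(rc) - 11)]
    scored = [(seq, s, nn_thermo(seq, cond, params).tm_C) for seq, s in windows]
    under = [w for w in scored if w[2] < 60.0]
    chosen = sorted(under, key=lambda w: (w[2], w[1]))[0]
    masks = [LnaMask(c) for c in itertools.combinations(range(12), 5)
             if validate_lna_mask(chosen[0], LnaMask(c))[0]]
    approx = {m.positions: chosen[2] + sum(params.lna_increments[chosen[0][p]]
                                           for p in m.positions) for m in masks}
    top = sorted(masks, key=lambda m: (-approx[m.positions], m.positions))[:50]
    survivors = []
    full_base = chosen[0] + "TATTCGT" + lib["P1"]
    dimer = self_dimer(full_base, params).dG
    hp = hairpin(full_base, params=params).dG
    for m in top:
        if dimer < -9.0 or hp < -3.0:
            continue
        survivors.append((lna_tm(chosen[0], m, cond, "refined", params).tm_C, m))
    expected = sorted(survivors, key=lambda t: (-t[0], t[1].positions))[:5]

    got = res.probes["P1"]
    assert [p.lna.positions for p in got] == [m.positions for _, m in expected]
    assert [p.tm_refined_C for p in got] == pytest.approx([t for t, _ in expected])
    assert res.backbone.sequence == chosen[0]


def test_design_warns_and_continues_when_no_window_under_ceiling():
    # GC-saturated target: every window exceeds the ceiling
    target = "GGCCGGCCGGCCGGCCGGCCGGCC"
    res = design(target, docking_ids=["P1"])
    assert any("ceiling" in w for w in res.warnings)
    assert not res.backbone.under_ceiling
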