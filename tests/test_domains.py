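import numpy as np
import pytest

from paedomains.domains import (
    Architecture,
    DomainCall,
    call_domains,
    compare_architecture,
    detect_split_domains,
    fraction_display,
    label_by_reference,
)
from paedomains.model_io import ResidueRange, StructureModel
from paedomains.rigidity import RigidUnit
from paedomains.segmentation import STRUCTURED, Segment
from paedomains.synthetic import default_spec, generate_model, generate_pae
from paedomains.report import annotate


def unit(*ranges):
    return RigidUnit(
        [Segment(ResidueRange(a, b), STRUCTURED, 90.0) for a, b in ranges], "domain"
    )


def test_single_segment_single_range_call():
    calls = call_domains([unit((10, 150))])
    assert len(calls) == 1
    assert [(r.start, r.end) for r in calls[0].ranges] == [(10, 150)]


def test_separated_segments_make_multi_range_call():
    calls = call_domains([unit((10, 60), (200, 260))])
    assert [(r.start, r.end) for r in calls[0].ranges] == [(10, 60), (200, 260)]


def test_adjacent_segments_merged():
    calls = call_domains([unit((10, 60), (61, 100))])
    assert [(r.start, r.end) for r in calls[0].ranges] == [(10, 100)]


def test_split_flag_and_quarter_fractions():
    calls = detect_split_domains(
        [DomainCall("D1", [ResidueRange(1, 90), ResidueRange(121, 150)])],
        min_insertion=30,
    )
    call = calls[0]
    assert call.split
    assert call.part_fractions == pytest.approx([0.75, 0.25])
    assert [fraction_display(f) for f in call.part_fractions] == ["¾", "¼"]
    call.label = "RWD"
    assert call.part_labels() == ["¾RWD", "¼RWD"]


def test_short_gap_not_split():
    calls = detect_split_domains(
        [DomainCall("D1", [ResidueRange(1, 90), ResidueRange(96, 150)])],
        min_insertion=30,
    )
    assert not calls[0].split
    assert [(r.start, r.end) for r in calls[0].ranges] == [(1, 150)]


def test_fractions_exact_and_sum_to_one():
    calls = detect_split_domains(
        [DomainCall("D1", [ResidueRange(1, 70), ResidueRange(150, 182)])]
    )
    fracs = calls[0].part_fractions
    assert sum(fracs) == pytest.approx(1.0, abs=1e-9)
    assert fracs[0] == pytest.approx(70 / 103)  # display rounding never alters these


def test_planted_split_domain_recovery_over_seeds():
    """Over 25 seeds of the default chain, the split domain B is called as
    one two-range domain (sensitivity >= 0.9) and the unsplit domains are
    never split (false-split rate <= 0.05)."""
    split_found = 0
    false_split = 0
    for seed in range(25):
        spec = default_spec(seed=seed)
        model, truth = generate_model(spec)
        arch = annotate(model, generate_pae(spec))
        diff = compare_architecture(arch, truth.architecture, slack=5)
        ref_split = {c.domain_id for c in truth.architecture.domains if c.split}
        called = {c.domain_id: c for c in arch.domains}
        for m in diff.matches:
            if m.reference_id in ref_split and called[m.domain_id].split:
                split_found += 1
            if m.reference_id not in ref_split and called[m.domain_id].split:
                false_split += 1
    assert split_found / 25 >= 0.9
    assert false_split / 50 <= 0.05


# ---------------------------------------------------------------------------
# reference labelling


def toy_model(n=60, seed=0, entry="toy"):
    rng = np.random.default_rng(seed)
    coords = np.cumsum(3.8 * _unit_rows(rng, n), axis=0)
    return StructureModel(
        entry, "A", np.arange(1, n + 1), "A" * n, coords, np.full(n, 90.0)
    )


def _unit_rows(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def test_label_self_superposition():
    model = toy_model()
    call = DomainCall("D1", [ResidueRange(1, 60)])
    labelled = label_by_reference(
        call, model, model, [(i, i) for i in range(60)], label="KH"
    )
    assert labelled.label == "KH"
    assert labelled.label_rmsd == pytest.approx(0.0, abs=1e-10)
    assert labelled.label_core_atoms == 60


def test_label_excludes_displaced_residues():
    rng = np.random.default_rng(3)
    model = toy_model(n=80, seed=1)
    ref_coords = model.ca_coords + rng.normal(size=(80, 3)) * 0.2
    displaced = rng.choice(80, size=8, replace=False)
    ref_coords[displaced] += rng.normal(size=(8, 3)) * (10 / np.sqrt(3))
    reference = StructureModel(
        "ref", "A", model.residue_numbers, model.sequence, ref_coords, model.plddt
    )
    call = DomainCall("D1", [ResidueRange(1, 80)])
    labelled = label_by_reference(
        call, model, reference, [(i, i) for i in range(80)], label="RWD"
    )
    assert labelled.label_rmsd <= 1.0
    assert labelled.label_core_atoms <= 80 - 6


def test_small_pairing_skips_labelling(caplog):
    model = toy_model()
    call = DomainCall("D1", [ResidueRange(1, 10)])
    with caplog.at_level("WARNING"):
        out = label_by_reference(call, model, model, [(i, i) for i in range(10)], "KH")
    assert out.label == "unassigned"
    assert any("skipped" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# architecture comparison


def simple_arch(shift=0):
    return Architecture(
        entry_id="x",
        length=300,
        domains=[
            DomainCall("D1", [ResidueRange(1 + shift, 100 + shift)]),
            DomainCall("D2", [ResidueRange(151 + shift, 280 + shift)]),
        ],
        disordered=_fill_gaps(
            [(1 + shift, 100 + shift), (151 + shift, 280 + shift)], 300
        ),
    )


def _fill_gaps(domain_ranges, n):
    out, pos = [], 1
    for a, b in domain_ranges:
        if a > pos:
            out.append(ResidueRange(pos, a - 1))
        pos = b + 1
    if pos <= n:
        out.append(ResidueRange(pos, n))
    return out


def test_self_comparison_full_agreement():
    arch = simple_arch()
    diff = compare_architecture(arch, arch, slack=5)
    assert diff.agreement == 1.0
    assert diff.missing == diff.extra == []
    assert all(m.start_delta == m.end_delta == 0 for m in diff.matches)


def test_shift_within_slack_agrees():
    diff = compare_architecture(simple_arch(3), simple_arch(0), slack=5)
    assert diff.agreement == 1.0
    assert {m.start_delta for m in diff.matches} == {3}


def test_shift_beyond_slack_disagrees():
    diff = compare_architecture(simple_arch(8), simple_arch(0), slack=5)
    assert diff.agreement == 0.0
    assert len(diff.matches) == 2  # still matched, but outside slack


def test_matched_count_symmetric():
    a, b = simple_arch(4), simple_arch(0)
    assert len(compare_architecture(a, b, 5).matches) == len(
        compare_architecture(b, a, 5).matches
    )


def test_length_mismatch_rejected():
    arch = simple_arch()
    other = Architecture(entry_id="y", length=299, disordered=[ResidueRange(1, 299)])
    with pytest.raises(ValueError):
        compare_architecture(arch, other)


# ---------------------------------------------------------------------------
# packaged reference data


def test_packaged_parp_reference_consistent():
    """The packaged PARP annotation table parses and its ranges are valid."""
    from paedomains import load_parp_reference
    from paedomains.model_io import ResidueRange

    ref = load_parp_reference()
    assert ref["nomenclature"]["MZAP"]
    assert set(ref["label_sources"]) >= {"WGR", "HD", "ITIHL", "RWD", "KH", "MZAP"}
    for entry, payload in ref["entries"].items():
        for dom in payload.get("domains", []) + payload.get("features", []):
            for a, b in dom["ranges"]:
                r = ResidueRange(a, b)  # raises if invalid
                assert r.end <= payload["length"]
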