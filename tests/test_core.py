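"""Evidence core: frames, mass validation, Dempster combination, conflict k."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dsfusion import (
    CompleteConflictError,
    Frame,
    FrameMismatchError,
    MassFunction,
    MassNormalizationError,
    MassValidityError,
    combine_classical,
    conflict_factor,
    validate_mass,
)
from conftest import as_mass_list, random_masses


# ---------------------------------------------------------------- frames

def test_frame_rejects_degenerate_inputs():
    with pytest.raises(ValueError):
        Frame(("F",))
    with pytest.raises(ValueError):
        Frame(("F", "F"))
    with pytest.raises(ValueError):
        Frame(("F", ""))


def test_frame_order_is_fixed():
    f = Frame(("F", "G", "H"))
    assert f.labels == ("F", "G", "H")
    assert f.size == 3
    assert f.index("H") == 2
    with pytest.raises(KeyError):
        f.index("Z")


# ------------------------------------------------------------ validation

@pytest.mark.parametrize(
    "vec",
    [(1, 0, 0), (0.5, 0.2, 0.3), (0, 0.9, 0.1), (0.1, 0.15, 0.75)],
)
def test_validate_accepts_fixture_rows(frame3, vec):
    m = validate_mass(vec, frame3)
    assert isinstance(m, MassFunction)
    np.testing.assert_allclose(m.masses, vec)


def test_validate_rejects_bad_sum_and_reports_it(frame3):
    with pytest.raises(MassNormalizationError, match="1.4"):
        validate_mass((0.5, 0.6, 0.3), frame3)


def test_validate_names_offending_index(frame3):
    with pytest.raises(MassValidityError, match=r"mass\[1\]"):
        validate_mass((0.5, -0.1, 0.6), frame3)
    with pytest.raises(MassValidityError):
        validate_mass((1.2, -0.1, -0.1), frame3)


def test_validate_tolerance_and_renormalization(frame3):
    m = validate_mass((0.5, 0.2, 0.3000004), frame3)  # within 1e-6
    assert abs(m.masses.sum() - 1) < 1e-5
    m = validate_mass((0.5, 0.2, 0.3000004), frame3, renormalize=True)
    assert m.masses.sum() == pytest.approx(1.0, abs=1e-15)
    with pytest.raises(MassNormalizationError):
        validate_mass((0.5, 0.2, 0.31), frame3)


# ------------------------------------------------------- conflict factor

def test_conflict_factor_matches_printed_values(fixtures):
    assert conflict_factor(fixtures["zero_trust"]) == pytest.approx(0.99, abs=5e-3)
    assert conflict_factor(fixtures["one_trust"]) == pytest.approx(0.9998, abs=5e-5)
    assert conflict_factor(fixtures["high_conflict"]) == pytest.approx(0.99986, abs=5e-6)
    assert conflict_factor(fixtures["complete_conflict"]) == 1.0


def test_conflict_factor_zero_for_identical_point_masses(frame3):
    srcs = as_mass_list(frame3, [(1, 0, 0), (1, 0, 0)])
    assert conflict_factor(srcs) == 0.0


def test_conflict_factor_frame_mismatch():
    a = MassFunction(Frame(("F", "G")), (0.5, 0.5))
    b = MassFunction(Frame(("F", "H")), (0.5, 0.5))
    with pytest.raises(FrameMismatchError):
        conflict_factor([a, b])


# -------------------------------------------------- classical combination

def test_classical_zero_trust_matches_printed_fusion(fixtures):
    res = combine_classical(fixtures["zero_trust"])
    np.testing.assert_allclose(res.masses, (0.0, 0.73, 0.27), atol=5e-3)
    assert res.decision == "G"
    assert res.rule == "classical"
    assert res.n_sources == 4


def test_classical_one_trust_degenerates_to_point_mass(fixtures):
    res = combine_classical(fixtures["one_trust"])
    np.testing.assert_allclose(res.masses, (0.0, 1.0, 0.0), atol=1e-12)
    assert res.decision == "G"


def test_classical_high_conflict_matches_printed_fusion(fixtures):
    res = combine_classical(fixtures["high_conflict"])
    np.testing.assert_allclose(
        res.masses, (0.0, 0.3571, 0.4286, 0.0, 0.2143), atol=5e-5
    )
    assert res.decision == "H"


def test_classical_complete_conflict_raises(fixtures):
    with pytest.raises(CompleteConflictError, match="denominator"):
        combine_classical(fixtures["complete_conflict"])
    pair = as_mass_list(Frame(("F", "G", "H")), [(1, 0, 0), (0, 1, 0)])
    with pytest.raises(CompleteConflictError):
        combine_classical(pair)


def test_uniform_mass_is_neutral(frame3, rng):
    uniform = MassFunction(frame3, np.full(3, 1 / 3))
    for row in random_masses(rng, 3, 10):
        m = MassFunction(frame3, row)
        res = combine_classical([m, uniform])
        np.testing.assert_allclose(res.masses, row, atol=1e-12)


def test_needs_at_least_two_sources(frame3):
    with pytest.raises(ValueError):
        combine_classical([MassFunction(frame3, (1, 0, 0))])


# --------------------------------------------------- invariants/properties

def brute_force_combine(rows):
    """Independent oracle: enumerate label-product terms with explicit loops."""
    phi = len(rows[0])
    unnorm = []
    for label in range(phi):
        term = 1.0
        for src in rows:
            term *= src[label]
        unnorm.append(term)
    total = sum(unnorm)
    if total == 0:
        return None
    return [u / total for u in unnorm], 1.0 - total


def test_brute_force_oracle_agreement(rng):
    """Triple-loop enumeration reproduces combine_classical on random cases."""
    for _ in range(1000):
        phi = int(rng.integers(2, 6))
        n_src = int(rng.integers(2, 6))
        frame = Frame([f"L{i}" for i in range(phi)])
        rows = random_masses(rng, phi, n_src)
        expect = brute_force_combine(rows.tolist())
        if expect is None:
            with pytest.raises(CompleteConflictError):
                combine_classical(as_mass_list(frame, rows))
            continue
        fused, k = expect
        res = combine_classical(as_mass_list(frame, rows))
        np.testing.assert_allclose(res.masses, fused, atol=1e-12)
        assert res.k == pytest.approx(k, abs=1e-12)


def test_normalization_invariant(rng):
    for _ in range(50):
        frame = Frame(["a", "b", "c", "d"])
        rows = random_masses(rng, 4, 3, allow_zero=False)
        res = combine_classical(as_mass_list(frame, rows))
        assert abs(res.masses.sum() - 1.0) < 1e-9
        assert 0.0 <= res.k <= 1.0


def test_order_invariance(rng):
    frame = Frame(["a", "b", "c"])
    rows = random_masses(rng, 3, 4, allow_zero=False)
    srcs = as_mass_list(frame, rows)
    ref = combine_classical(srcs)
    for perm in itertools.permutations(range(4)):
        res = combine_classical([srcs[i] for i in perm])
        np.testing.assert_allclose(res.masses, ref.masses, atol=1e-12)
        assert res.k == pytest.approx(ref.k, abs=1e-12)


def test_incremental_equals_single_pass(rng):
    """Sequential pairwise fusion (normalizing each step) equals one pass."""
    frame = Frame(["a", "b", "c", "d", "e"])
    for _ in range(25):
        rows = random_masses(rng, 5, 4, allow_zero=False)
        srcs = as_mass_list(frame, rows)
        acc = srcs[0]
        for nxt in srcs[1:]:
            acc = MassFunction(frame, combine_classical([acc, nxt]).masses)
        single = combine_classical(srcs)
        np.testing.assert_allclose(acc.masses, single.masses, atol=1e-9)


def test_self_combination_sharpens_maximum(rng):
    """Dempster's rule is not idempotent: fusing m with itself sharpens it."""
    frame = Frame(["a", "b", "c"])
    for _ in range(25):
        row = random_masses(rng, 3, 1, allow_zero=False)[0]
        m = MassFunction(frame, row)
        fused = combine_classical([m, m])
        assert fused.masses.max() >= row.max() - 1e-12


@settings(deadline=None, derandomize=True, max_examples=100)
@given(
    st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
    st.lists(st.floats(0.01, 1.0), min_size=2, max_size=6),
)
def test_pairwise_fusion_properties(raw_a, raw_b):
    """Fused masses are a valid BPA and k matches its defining identity."""
    phi = min(len(raw_a), len(raw_b))
    a = np.array(raw_a[:phi]) / sum(raw_a[:phi])
    b = np.array(raw_b[:phi]) / sum(raw_b[:phi])
    frame = Frame([f"L{i}" for i in range(phi)])
    res = combine_classical([MassFunction(frame, a), MassFunction(frame, b)])
    assert abs(res.masses.sum() - 1.0) < 1e-9
    assert (res.masses >= 0).all()
    assert res.k == pytest.approx(1.0 - float((a * b).sum()), abs=1e-12)
    assert res.decision == frame.labels[int(np.argmax(res.masses))]


def test_tie_breaks_to_lowest_index_and_warns(frame3, caplog):
    m1 = MassFunction(frame3, (0.5, 0.5, 0.0))
    m2 = MassFunction(frame3, (0.5, 0.5, 0.0))
    with caplog.at_level("WARNING", logger="dsfusion.core"):
        res = combine_classical([m1, m2])
    assert res.decision == "F"
    assert any("tie" in r.message for r in caplog.records)


def test_fusion_result_json_round_trip(fixtures):
    import json

    res = combine_classical(fixtures["zero_trust"])
    payload = json.loads(res.to_json())
    assert payload["labels"] == ["F", "G", "H"]
    assert payload["decision"] == "G"
    assert payload["rule"] == "classical"
    assert payload["n_sources"] == 4
    np.testing.assert_allclose(payload["masses"], res.masses)


def test_bpa_csv_round_trip(tmp_path, fixtures):
    from dsfusion import read_bpa_csv, write_bpa_csv

    path = tmp_path / "bpa.csv"
    write_bpa_csv(path, fixtures["high_conflict"])
    back = read_bpa_csv(path)
    assert len(back) == 5
    for a, b in zip(back, fixtures["high_conflict"]):
        np.testing.assert_array_equal(a.masses, b.masses)


def test_bpa_csv_reports_bad_row(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("F,G,H\n0.5,0.2,0.3\n0.5,0.6,0.3\n")
    from dsfusion import read_bpa_csv

    with pytest.raises(MassNormalizationError, match="row 2"):
        read_bpa_csv(path)
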