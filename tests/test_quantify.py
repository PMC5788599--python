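import numpy as np
import pandas as pd
import pytest
from dataclasses import replace

from conftest import make_evidence
from lfqdiff import generate_design
from lfqdiff.quantify import (QuantMatrix, build_matrix, compute_empai,
                              compute_nsaf, compute_sin, filter_protein_fdr,
                              normalize_matrix)


# ----------------------------------------------------------------- NSAF

def test_nsaf_equal_ratio_symmetry():
    ev = make_evidence([
        dict(protein_id="A", spectral_count=10, protein_length=100),
        dict(protein_id="B", spectral_count=20, protein_length=200),
    ])
    vals, denom = compute_nsaf(ev)
    assert vals["A"] == pytest.approx(0.5) and vals["B"] == pytest.approx(0.5)
    assert denom == pytest.approx(0.2)


def test_nsaf_direct_evaluation():
    ev = make_evidence([
        dict(protein_id=p, spectral_count=s, protein_length=100)
        for p, s in [("A", 6), ("B", 3), ("C", 1)]
    ])
    vals, _ = compute_nsaf(ev)
    assert list(vals[["A", "B", "C"]]) == pytest.approx([0.6, 0.3, 0.1])


def test_nsaf_single_protein_and_missing():
    ev = make_evidence([
        dict(protein_id="A", spectral_count=7),
        dict(protein_id="B", spectral_count=0),
    ])
    vals, _ = compute_nsaf(ev)
    assert vals["A"] == pytest.approx(1.0)
    assert "B" not in vals.index


def test_nsaf_all_zero_run_warns_not_divides():
    ev = make_evidence([dict(protein_id="A", spectral_count=0)])
    with pytest.warns(UserWarning):
        vals, denom = compute_nsaf(ev)
    assert len(vals) == 0 and denom == 0.0


# ---------------------------------------------------------------- emPAI

def test_empai_values():
    ev = make_evidence([
        dict(protein_id="A", n_observed_peptides=10, n_observable_peptides=10),
        dict(protein_id="B", n_observed_peptides=3, n_observable_peptides=10),
        dict(protein_id="C", n_observed_peptides=1, n_observable_peptides=2),
        dict(protein_id="D", n_observed_peptides=2, n_observable_peptides=4),
        dict(protein_id="E", n_observed_peptides=0, n_observable_peptides=5),
    ])
    vals, denom = compute_empai(ev)
    assert vals["A"] == pytest.approx(9.0)
    assert vals["B"] == pytest.approx(10 ** 0.3 - 1)
    assert vals["C"] == vals["D"]  # ratio invariance
    assert "E" not in vals.index
    assert denom == 1.0


def test_empai_observed_exceeding_observable_rejected():
    ev = make_evidence([
        dict(protein_id="A", n_observed_peptides=5, n_observable_peptides=3)])
    with pytest.raises(ValueError):
        compute_empai(ev)


# ------------------------------------------------------------------ SIN

def test_sin_symmetry_and_direct_value():
    ev = make_evidence([
        dict(protein_id="A", summed_intensity=8e6, protein_length=400),
        dict(protein_id="B", summed_intensity=2e6, protein_length=100),
    ])
    vals, denom = compute_sin(ev)
    assert vals["A"] == pytest.approx(vals["B"])  # ratio 1.0
    assert vals["A"] == pytest.approx((8e6 / 1e7) / 400)
    assert denom == pytest.approx(1e7)


def test_sin_scale_invariance():
    rows = [dict(protein_id=f"P{i}", summed_intensity=float(v),
                 protein_length=100 + 7 * i)
            for i, v in enumerate([5, 17, 120, 3])]
    v1, _ = compute_sin(make_evidence(rows))
    scaled = [dict(r, summed_intensity=r["summed_intensity"] * 1000)
              for r in rows]
    v2, _ = compute_sin(make_evidence(scaled))
    assert np.allclose(v1.to_numpy(), v2.to_numpy(), rtol=0, atol=1e-9)


def test_indices_invariant_to_row_order():
    rows = [dict(protein_id=f"P{i}", spectral_count=i + 1,
                 summed_intensity=10.0 * (i + 1),
                 n_observed_peptides=i + 1, n_observable_peptides=12,
                 protein_length=100 + i) for i in range(6)]
    shuffled = [rows[i] for i in [3, 0, 5, 1, 4, 2]]
    for fn in (compute_nsaf, compute_empai, compute_sin):
        a, _ = fn(make_evidence(rows))
        b, _ = fn(make_evidence(shuffled))
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())


# --------------------------------------------------- target-decoy filter

def _ranked_evidence(n_targets, decoy_scores, target_top=100.0):
    rows = [dict(protein_id=f"T{i}", score=target_top - i)
            for i in range(n_targets)]
    rows += [dict(protein_id=f"D{i}", score=s, is_decoy=True)
             for i, s in enumerate(decoy_scores)]
    return make_evidence(rows)


def _brute_force_retained(ev, threshold):
    """Largest score-descending prefix with decoy/target ratio <= t."""
    grp = ev.sort_values(["score", "protein_id"],
                         ascending=[False, True], kind="mergesort")
    best = 0
    decoys = targets = 0
    for k, is_d in enumerate(grp["is_decoy"], start=1):
        decoys += bool(is_d)
        targets += not is_d
        if decoys / max(1, targets) <= threshold:
            best = k
    prefix = grp.iloc[:best]
    return set(prefix.loc[~prefix["is_decoy"], "protein_id"])


def test_filter_targets_above_single_decoy():
    # 99 targets above the decoy: prefix with the decoy has FDR 1/99 > 1%
    ev = _ranked_evidence(99, [0.5])
    filtered, _ = filter_protein_fdr(ev, 0.01)
    assert set(filtered["protein_id"]) == {f"T{i}" for i in range(99)}
    # 100 targets above the decoy: 1/100 <= 1%, decoy prefix accepted
    ev = _ranked_evidence(100, [0.5])
    filtered, _ = filter_protein_fdr(ev, 0.01)
    assert len(filtered) == 100 and not filtered["is_decoy"].any()


def test_filter_no_decoys_is_identity():
    ev = _ranked_evidence(10, [])
    filtered, unfiltered = filter_protein_fdr(ev, 0.01)
    assert len(filtered) == 10 and len(unfiltered) == 10


def test_filter_matches_brute_force_on_alternating_and_random():
    # alternating target/decoy ranks
    rows = []
    for i in range(20):
        rows.append(dict(protein_id=f"T{i}", score=100 - 2 * i))
        rows.append(dict(protein_id=f"D{i}", score=99 - 2 * i, is_decoy=True))
    ev = make_evidence(rows)
    for thr in (0.01, 0.34, 0.5, 0.9):
        filtered, _ = filter_protein_fdr(ev, thr)
        assert set(filtered["protein_id"]) == _brute_force_retained(ev, thr)
    # random fixture
    rng = np.random.default_rng(0)
    rows = [dict(protein_id=f"T{i}", score=float(rng.normal(2, 1)))
            for i in range(80)]
    rows += [dict(protein_id=f"D{i}", score=float(rng.normal(0, 1)),
                  is_decoy=True) for i in range(80)]
    ev = make_evidence(rows)
    sizes = []
    for thr in (0.01, 0.05, 0.1, 0.2, 0.5):
        filtered, _ = filter_protein_fdr(ev, thr)
        assert set(filtered["protein_id"]) == _brute_force_retained(ev, thr)
        sizes.append(len(filtered))
    assert sizes == sorted(sizes)  # monotone in threshold


def test_filter_respects_upstream_flag():
    rows = [dict(protein_id="A", score=10.0),
            dict(protein_id="B", score=9.0, passed_fdr_filter=False)]
    filtered, unfiltered = filter_protein_fdr(make_evidence(rows), 0.01)
    assert set(filtered["protein_id"]) == {"A"}
    assert set(unfiltered["protein_id"]) == {"A", "B"}


def test_filter_schema_error():
    ev = make_evidence([dict(protein_id="A")]).drop(columns=["score"])
    with pytest.raises(ValueError, match="columns"):
        filter_protein_fdr(ev, 0.01)


# ---------------------------------------------------------- matrix ops

def _toy_matrix(values, method="sin"):
    design = generate_design(1, values.shape[1] // 2)
    cols = design.run_ids
    df = pd.DataFrame(values, columns=cols,
                      index=[f"P{i}" for i in range(values.shape[0])])
    return QuantMatrix(values=df, design=design, method=method,
                       run_denominator=pd.Series(1.0, index=cols))


def test_normalize_fixed_point_and_idempotence():
    vals = np.array([[1.0, 2.0], [3.0, 2.0]])  # balanced columns
    m = _toy_matrix(vals)
    n1 = normalize_matrix(m)
    assert np.allclose(n1.values.to_numpy(), vals, atol=1e-12)
    n2 = normalize_matrix(n1)
    assert np.allclose(n2.values.to_numpy(), n1.values.to_numpy(),
                       atol=1e-12)


def test_normalize_removes_per_run_multiplier():
    rng = np.random.default_rng(5)
    vals = rng.uniform(1, 10, size=(6, 4))
    m = _toy_matrix(vals)
    perturbed = vals.copy()
    perturbed[:, 1] *= 10.0
    mp = _toy_matrix(perturbed)
    a = normalize_matrix(m).values.to_numpy()
    b = normalize_matrix(mp).values.to_numpy()
    # run totals differ, so grand-mean rescale differs by a common factor
    assert np.allclose(a / a[0, 0], b / b[0, 0], atol=1e-9)


def test_normalize_single_cell():
    m = _toy_matrix(np.array([[4.0, 4.0]]))
    n = normalize_matrix(m)
    assert np.allclose(n.values.to_numpy(), [[4.0, 4.0]])


def test_normalize_empty_run_errors():
    vals = np.array([[1.0, np.nan], [2.0, np.nan]])
    m = _toy_matrix(vals)
    with pytest.raises(ValueError, match="treated_b1_t1"):
        normalize_matrix(m)


def test_build_matrix_nsaf_sums_to_one(design10):
    from lfqdiff import draw_truth, simulate_evidence
    truth = draw_truth(50, seed=6)
    ev = simulate_evidence(truth, design10, seed=6)
    filtered, _ = filter_protein_fdr(ev, 0.01)
    m = build_matrix(filtered, design10, "nsaf")
    sums = m.values.sum(axis=0, skipna=True)
    assert np.allclose(sums.to_numpy(), 1.0, atol=1e-9)
    # matrix assembly is invariant to evidence row order
    m2 = build_matrix(filtered.sample(frac=1, random_state=0), design10,
                      "nsaf")
    pd.testing.assert_frame_equal(m.values, m2.values)


def test_negative_values_rejected():
    with pytest.raises(ValueError, match="non-negative"):
        _toy_matrix(np.array([[1.0, -0.5]]))
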