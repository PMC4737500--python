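"""Relationship matrices: GRM formulas, ERMs, degree classes, pruning."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famvc.genio import Pedigree
from famvc.relmat import (
    build_erm,
    classify_degree,
    compute_grm,
    degree_bounds,
    grm_eigenvectors,
    grm_prune,
    read_gcta_grm,
    threshold_grm,
    write_gcta_grm,
    RelationshipMatrix,
)
from famvc.errors import NumericalError

from conftest import make_geno


# ---------------------------------------------------------------------------
# GRM formulas
# ---------------------------------------------------------------------------


def test_grm_offdiagonal_printed_formula():
    # single SNP at p = 0.25 (freq fixed by the other two individuals):
    # entry(j, k) for x_j = 0, x_k = 2 is (0-0.5)(2-0.5)/(2*0.25*0.75) = -2
    geno = make_geno([[0], [2], [0], [0]])
    assert geno.freq[0] == pytest.approx(0.25)
    grm = compute_grm(geno)
    assert grm.values[0, 1] == pytest.approx(-2.0)


def test_grm_diagonal_printed_formula():
    # single SNP at p = 0.5, heterozygous individual:
    # 1 + (1 - (1+1)*1 + 2*0.25) / 0.5 = 0
    geno = make_geno([[1], [1], [0], [2]])
    assert geno.freq[0] == pytest.approx(0.5)
    grm = compute_grm(geno)
    assert grm.values[0, 0] == pytest.approx(0.0)


def _grm_double_loop(dosage, p):
    """Naive per-SNP double loop with pairwise missing handling."""
    n, m = dosage.shape
    denom = 2 * p * (1 - p)
    out = np.zeros((n, n))
    for j in range(n):
        for k in range(n):
            if j == k:
                acc = cnt = 0
                for i in range(m):
                    x = dosage[j, i]
                    if np.isnan(x):
                        continue
                    acc += (x * x - (1 + 2 * p[i]) * x + 2 * p[i] ** 2) / denom[i]
                    cnt += 1
                out[j, j] = 1 + acc / cnt
            else:
                acc = cnt = 0
                for i in range(m):
                    xj, xk = dosage[j, i], dosage[k, i]
                    if np.isnan(xj) or np.isnan(xk):
                        continue
                    acc += (xj - 2 * p[i]) * (xk - 2 * p[i]) / denom[i]
                    cnt += 1
                out[j, k] = acc / cnt
    return out


def test_grm_matches_double_loop_oracle(rng):
    d = rng.integers(0, 3, size=(15, 40)).astype(float)
    d[rng.random(d.shape) < 0.08] = np.nan
    geno = make_geno(d)
    grm = compute_grm(geno)
    oracle = _grm_double_loop(geno.dosage, geno.freq)
    np.testing.assert_allclose(grm.values, oracle, atol=1e-10)
    assert np.abs(grm.values - grm.values.T).max() < 1e-12


def test_grm_rejects_monomorphic():
    geno = make_geno([[0], [0], [0]])
    with pytest.raises(NumericalError):
        compute_grm(geno)


def test_grm_hwe_founder_expectations():
    """Unrelated founders in HWE: off-diagonals centre on the finite-sample
    value -1/(n-1) (sample-frequency centering makes each SNP's scores sum
    to zero exactly) and diagonals centre on 1."""
    from famvc.simgen import PedigreeDesign, simulate_genotypes, simulate_pedigree
    ped = simulate_pedigree(PedigreeDesign(n_families=0, n_singletons=400), 3)
    geno = simulate_genotypes(ped, n_snps=1500, seed=4)
    grm = compute_grm(geno)
    n = grm.n
    off = grm.values[np.triu_indices(n, 1)]
    assert abs(off.mean() + 1.0 / (n - 1)) < 3 * off.std() / np.sqrt(n)
    diag = np.diag(grm.values)
    assert abs(diag.mean() - 1.0) < 3 * diag.std() / np.sqrt(n)


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------


def test_threshold_strictly_below():
    ids = list("abc")
    v = np.eye(3)
    v[0, 1] = v[1, 0] = 0.024
    v[0, 2] = v[2, 0] = 0.025
    v[1, 2] = v[2, 1] = 0.5
    kin = threshold_grm(RelationshipMatrix(ids, v, "GRM_g"))
    assert kin.kind == "GRM_kin"
    assert kin.values[0, 1] == 0.0          # below threshold
    assert kin.values[0, 2] == 0.025        # boundary retained ("smaller than")
    assert kin.values[1, 2] == 0.5          # parent-offspring untouched
    assert (np.diag(kin.values) == 1.0).all()
    assert (kin.values <= v).all()          # never increases an entry
    assert np.abs(kin.values - kin.values.T).max() == 0.0


# ---------------------------------------------------------------------------
# environmental relationship matrices
# ---------------------------------------------------------------------------


def test_trio_erms(trio_pedigree):
    couple = build_erm(trio_pedigree, "couple")
    off = couple.values[np.triu_indices(3, 1)]
    assert off.sum() == 1.0  # exactly the father-mother pair
    assert couple.values[0, 1] == 1.0

    fam = build_erm(trio_pedigree, "family")
    np.testing.assert_array_equal(fam.values, np.ones((3, 3)))


def test_sib_erm_pattern():
    ped = Pedigree(pd.DataFrame({
        "iid": ["s1", "s2", "u", "dad", "mum"],
        "father": ["dad", "dad", "", "", ""],
        "mother": ["mum", "mum", "", "", ""],
        "sex": [1, 2, 1, 1, 2],
        "family": ["f", "f", "u", "f", "f"],
    }))
    sib = build_erm(ped, "sib", ids=["s1", "s2", "u"])
    off = sib.values[np.triu_indices(3, 1)]
    assert off.sum() == 1.0 and sib.values[0, 1] == 1.0


def test_erm_family_is_pairwise_max(small_cohort):
    ids = small_cohort.geno.sample_ids
    ped = small_cohort.ped
    fam = small_cohort.erms["F"].values
    expected = np.maximum.reduce([
        small_cohort.erms["S"].values,
        small_cohort.erms["C"].values,
        _po_indicator(ped, ids),
    ])
    np.testing.assert_array_equal(fam, expected)


def _po_indicator(ped, ids):
    pos = {iid: i for i, iid in enumerate(ids)}
    v = np.eye(len(ids))
    for a, b in ped.parent_offspring_pairs():
        v[pos[a], pos[b]] = v[pos[b], pos[a]] = 1.0
    return v


def test_erms_positive_semidefinite(small_cohort):
    for erm in small_cohort.erms.values():
        w = np.linalg.eigvalsh(erm.values)
        assert w.min() >= -1e-10


def test_erm_unknown_individual_is_singleton(trio_pedigree):
    with pytest.warns(UserWarning):
        m = build_erm(trio_pedigree, "couple",
                      ids=["dad", "mum", "kid", "ghost"])
    assert m.values[3, :3].sum() == 0.0
    assert m.values[3, 3] == 1.0


# ---------------------------------------------------------------------------
# degree classification
# ---------------------------------------------------------------------------


def test_degree_boundary_values():
    lo1, hi1 = degree_bounds(1)
    assert round(lo1, 3) == 0.354
    assert round(degree_bounds(5)[0], 3) == 0.022
    assert round(hi1, 3) == 0.707


@pytest.mark.parametrize("r,expected", [
    (0.5, 1), (0.25, 2), (0.125, 3), (0.0625, 4), (0.03125, 5),
    (0.01, "unrelated"), (0.022, "unrelated"), (0.3535, 2), (0.354, 1),
])
def test_degree_examples(r, expected):
    assert classify_degree(r) == expected


def test_degree_above_first_collapses_with_warning():
    with pytest.warns(UserWarning):
        assert classify_degree(1.0) == 1


@settings(max_examples=300, deadline=None)
@given(st.floats(min_value=0.5 ** 5.5, max_value=1.0,
                 exclude_min=True, allow_nan=False))
def test_degree_intervals_partition(r):
    """Every relatedness in (0.022, 1] maps to exactly one degree 1-5."""
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        deg = classify_degree(r)
    assert deg in (1, 2, 3, 4, 5)
    if deg > 1 or r <= 0.5 ** 0.5:
        lo, hi = degree_bounds(deg)
        assert lo < r <= hi


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------


def _mat(n, pairs):
    v = np.eye(n)
    for a, b, r in pairs:
        v[a, b] = v[b, a] = r
    return RelationshipMatrix([f"i{j}" for j in range(n)], v, "GRM_g")


def test_prune_single_pair():
    kept = grm_prune(_mat(3, [(0, 1, 0.5)]), cutoff=0.025)
    assert len(kept) == 2


def test_prune_noop():
    kept = grm_prune(_mat(4, [(0, 1, 0.01)]), cutoff=0.025)
    assert len(kept) == 4


def test_prune_chain_removes_middle():
    kept = grm_prune(_mat(3, [(0, 1, 0.5), (1, 2, 0.5)]), cutoff=0.025)
    assert kept == ["i0", "i2"]


def test_prune_achieves_cutoff(small_cohort):
    g = small_cohort.grm_g
    kept = grm_prune(g, cutoff=0.354)
    sub = g.subset(kept).values
    np.fill_diagonal(sub, 0.0)
    assert sub.max() <= 0.354


# ---------------------------------------------------------------------------
# eigenvectors
# ---------------------------------------------------------------------------


def test_eigenvectors_orthonormal(small_cohort):
    u = grm_eigenvectors(small_cohort.grm_g, 20)
    np.testing.assert_allclose(u.T @ u, np.eye(20), atol=1e-10)


def test_eigenvectors_block_structure():
    # two disjoint all-ones family blocks: leading eigenvectors are the
    # (normalized) block indicators
    v = np.zeros((8, 8))
    v[:4, :4] = 1.0
    v[4:, 4:] = 1.0
    m = RelationshipMatrix([f"i{j}" for j in range(8)], v, "GRM_g")
    u = grm_eigenvectors(m, 2)
    span = np.abs(u.T @ np.c_[np.r_[np.ones(4), np.zeros(4)] / 2,
                              np.r_[np.zeros(4), np.ones(4)] / 2])
    np.testing.assert_allclose(np.sort(span.ravel()), [0, 0, 1, 1], atol=1e-10)


def test_eigenvectors_sign_deterministic(small_cohort):
    u1 = grm_eigenvectors(small_cohort.grm_g, 5)
    u2 = grm_eigenvectors(small_cohort.grm_g, 5)
    np.testing.assert_array_equal(u1, u2)
    for j in range(5):
        assert u1[np.argmax(np.abs(u1[:, j])), j] > 0


def test_eigenvectors_k_too_large(small_cohort):
    with pytest.raises(ValueError):
        grm_eigenvectors(small_cohort.grm_g, small_cohort.grm_g.n + 1)


# ---------------------------------------------------------------------------
# GCTA binary I/O
# ---------------------------------------------------------------------------


def test_gcta_grm_roundtrip(tmp_path, small_cohort):
    g = small_cohort.grm_g
    write_gcta_grm(g, tmp_path / "g")
    back = read_gcta_grm(tmp_path / "g")
    assert back.ids == g.ids
    np.testing.assert_allclose(back.values, g.values, atol=1e-6)  # float32
    np.testing.assert_allclose(back.n_snps, g.n_snps, atol=0.5)
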