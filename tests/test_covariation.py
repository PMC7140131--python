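"""Covariation scorers against independent brute-force oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tmcontact import covariation as cov
from tmcontact.errors import ConfigurationError, ContractError, DegenerateColumnError
from tmcontact.seqio import AA20, MultipleAlignment

from conftest import msa_from_columns

# ---------------------------------------------------------------------------
# Independent oracles (pure Python, direct summation / exact integers)
# ---------------------------------------------------------------------------


def _valid_pairs(msa, i, j):
    out = []
    for _, seq in msa.rows:
        a, b = seq[i], seq[j]
        if a in AA20 and b in AA20:
            out.append((a, b))
    return out


def oracle_mi(msa, i, j):
    pairs = _valid_pairs(msa, i, j)
    n = len(pairs)
    total = 0.0
    for x in AA20:
        for y in AA20:
            pxy = sum(1 for a, b in pairs if (a, b) == (x, y)) / n
            px = sum(1 for a, _ in pairs if a == x) / n
            py = sum(1 for _, b in pairs if b == y) / n
            if pxy > 0:
                total += pxy * math.log2(pxy / (px * py))
    return total


def oracle_omes(msa, i, j):
    pairs = _valid_pairs(msa, i, j)
    n = len(pairs)
    total = 0.0
    for x in AA20:
        for y in AA20:
            obs = sum(1 for a, b in pairs if (a, b) == (x, y))
            exp = n * (sum(1 for a, _ in pairs if a == x) / n) * (
                sum(1 for _, b in pairs if b == y) / n
            )
            if exp > 0:
                total += (obs - exp) ** 2 / n
    return total


def _oracle_round_proportional(n_full, subset_size, n_total):
    ideal = {y: n_full[y] * subset_size / n_total for y in n_full}
    m = {y: min(n_full[y], math.floor(ideal[y] + 0.5)) for y in n_full}
    deficit = subset_size - sum(m.values())
    remainder = {y: ideal[y] - m[y] for y in n_full}
    order = sorted(n_full, key=lambda y: (-remainder[y], AA20.index(y)))
    while deficit > 0:
        for y in order:
            if deficit == 0:
                break
            if m[y] < n_full[y]:
                m[y] += 1
                deficit -= 1
    order = sorted(n_full, key=lambda y: (remainder[y], AA20.index(y)))
    while deficit < 0:
        for y in order:
            if deficit == 0:
                break
            if m[y] > 0:
                m[y] -= 1
                deficit += 1
    return m


def oracle_elsc_directed(msa, i, j):
    """Exact-integer binomial-coefficient product via math.comb/Fraction."""
    from fractions import Fraction

    pairs = _valid_pairs(msa, i, j)
    n_total = len(pairs)
    counts_i = {}
    for a, _ in pairs:
        counts_i[a] = counts_i.get(a, 0) + 1
    modal = min(
        (aa for aa in counts_i if counts_i[aa] == max(counts_i.values())),
        key=AA20.index,
    )
    subset = [b for a, b in pairs if a == modal]
    n_full = {}
    for _, b in pairs:
        n_full[b] = n_full.get(b, 0) + 1
    n_sub = {y: sum(1 for b in subset if b == y) for y in n_full}
    m = _oracle_round_proportional(n_full, len(subset), n_total)
    product = Fraction(1)
    for y in n_full:
        product *= Fraction(math.comb(n_full[y], n_sub[y]), math.comb(n_full[y], m[y]))
    return -math.log(product)


def oracle_elsc(msa, i, j):
    return 0.5 * (oracle_elsc_directed(msa, i, j) + oracle_elsc_directed(msa, j, i))


def random_msa(rng, nrows, ncols, gap_prob=0.1):
    rows = []
    for r in range(nrows):
        chars = [
            "-" if rng.random() < gap_prob else AA20[rng.integers(0, 20)]
            for _ in range(ncols)
        ]
        rows.append((f"r{r}", "".join(chars)))
    return MultipleAlignment(rows=tuple(rows), ncols=ncols)


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------


class TestColumnPairCounts:
    def test_direct_count(self, covarying_toy):
        joint, ni, nj, n = cov.column_pair_counts(covarying_toy, 0, 1)
        a, c, d, e = (AA20.index(x) for x in "ACDE")
        assert n == 4
        assert joint[a, d] == 2 and joint[c, e] == 2
        assert joint.sum() == 4

    def test_gap_row_excluded(self):
        msa = msa_from_columns("AA-C", "DDEE")
        joint, ni, nj, n = cov.column_pair_counts(msa, 0, 1)
        assert n == 3

    def test_all_gap_column_degenerate(self):
        msa = msa_from_columns("----", "DDEE")
        with pytest.raises(DegenerateColumnError):
            cov.column_pair_counts(msa, 0, 1)


# ---------------------------------------------------------------------------
# Closed-form examples
# ---------------------------------------------------------------------------


class TestClosedForms:
    def test_mi_constant_column_zero(self):
        msa = msa_from_columns("ACDE", "GGGG")
        assert cov.mutual_information(msa, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_mi_covarying_toy_one_bit(self, covarying_toy):
        assert cov.mutual_information(covarying_toy, 0, 1) == pytest.approx(1.0)

    def test_mi_independent_toy_zero(self, independent_toy):
        assert cov.mutual_information(independent_toy, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_omes_identical_rows_zero(self):
        msa = MultipleAlignment(tuple((f"r{k}", "ACDE") for k in range(5)), ncols=4)
        for i in range(4):
            for j in range(i + 1, 4):
                assert cov.omes(msa, i, j) == pytest.approx(0.0, abs=1e-12)

    def test_omes_covarying_toy_one(self, covarying_toy):
        # cells AD,CE: obs 2 exp 1; AE,CD: obs 0 exp 1 → sum 4 / n 4
        assert cov.omes(covarying_toy, 0, 1) == pytest.approx(1.0)

    def test_omes_independent_toy_zero(self, independent_toy):
        assert cov.omes(independent_toy, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_elsc_identical_rows_zero(self):
        msa = MultipleAlignment(tuple((f"r{k}", "ACDE") for k in range(5)), ncols=4)
        assert cov.elsc(msa, 0, 1) == pytest.approx(0.0, abs=1e-12)

    def test_elsc_constant_partner_zero(self):
        msa = msa_from_columns("AACCGG", "DDDDDD")
        assert cov.elsc(msa, 0, 1) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Oracle equivalence
# ---------------------------------------------------------------------------


class TestOracleEquivalence:
    def test_mi_omes_match_brute_force(self, rng):
        for _ in range(50):
            msa = random_msa(rng, int(rng.integers(3, 11)), int(rng.integers(2, 21)))
            i, j = sorted(rng.choice(msa.ncols, size=2, replace=False))
            try:
                mi_val = cov.mutual_information(msa, int(i), int(j))
                om_val = cov.omes(msa, int(i), int(j))
            except DegenerateColumnError:
                continue
            assert mi_val == pytest.approx(oracle_mi(msa, i, j), abs=1e-9)
            assert om_val == pytest.approx(oracle_omes(msa, i, j), abs=1e-9)

    def test_elsc_matches_exact_integer_oracle(self, rng):
        for _ in range(20):
            msa = random_msa(rng, 6, int(rng.integers(2, 8)), gap_prob=0.05)
            i, j = sorted(rng.choice(msa.ncols, size=2, replace=False))
            try:
                val = cov.elsc(msa, int(i), int(j))
            except DegenerateColumnError:
                continue
            assert val == pytest.approx(oracle_elsc(msa, int(i), int(j)), abs=1e-9)


# ---------------------------------------------------------------------------
# Matrix assembly and z-scoring
# ---------------------------------------------------------------------------


class TestCovariationMatrix:
    def test_two_column_msa(self, covarying_toy):
        m = cov.covariation_matrix(covarying_toy, "MI")
        assert m.scores[0, 1] == pytest.approx(1.0)
        assert m.scores[0, 1] == m.scores[1, 0]
        assert np.isnan(m.scores[0, 0])

    def test_symmetry(self, rng):
        msa = random_msa(rng, 8, 6, gap_prob=0.0)
        for method in cov.METHODS:
            m = cov.covariation_matrix(msa, method)
            np.testing.assert_allclose(m.scores, m.scores.T)

    def test_unknown_method(self, covarying_toy):
        with pytest.raises(ConfigurationError):
            cov.covariation_matrix(covarying_toy, "PSICOV")

    def test_planted_pair_is_maximum_all_methods(self):
        from tmcontact.synthetic import SyntheticSpec, generate_msa

        spec = SyntheticSpec(
            seed=5, seq_length=12, n_sequences=32, planted_pairs=((2, 9),), p_couple=1.0
        )
        msa = generate_msa(spec)
        for method in cov.METHODS:
            m = cov.covariation_matrix(msa, method)
            iu = np.triu_indices(12, k=1)
            assert m.scores[2, 9] == np.nanmax(m.scores[iu])


class TestZscore:
    def test_constant_matrix_all_zeros(self):
        msa = MultipleAlignment(tuple((f"r{k}", "ACDE") for k in range(5)), ncols=4)
        z = cov.zscore_standardize(cov.covariation_matrix(msa, "MI"))
        iu = np.triu_indices(4, k=1)
        assert np.all(z.scores[iu] == 0.0)

    def test_three_value_example(self):
        raw = np.full((3, 3), np.nan)
        for (i, j), v in zip([(0, 1), (0, 2), (1, 2)], [1.0, 2.0, 3.0]):
            raw[i, j] = raw[j, i] = v
        m = cov.CovariationMatrix(length=3, scores=raw, method="MI")
        z = cov.zscore_standardize(m)
        assert z.scores[0, 1] == pytest.approx(-1.2247, abs=1e-4)
        assert z.scores[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert z.scores[1, 2] == pytest.approx(1.2247, abs=1e-4)

    def test_mean_zero_sd_one(self, rng):
        msa = random_msa(rng, 10, 8, gap_prob=0.0)
        z = cov.zscore_standardize(cov.covariation_matrix(msa, "OMES"))
        iu = np.triu_indices(8, k=1)
        assert z.scores[iu].mean() == pytest.approx(0.0, abs=1e-9)
        assert z.scores[iu].std() == pytest.approx(1.0, abs=1e-9)

    def test_double_standardize_rejected(self, covarying_toy):
        z = cov.zscore_standardize(cov.covariation_matrix(covarying_toy, "MI"))
        with pytest.raises(ContractError):
            cov.zscore_standardize(z)


# ---------------------------------------------------------------------------
# Properties
# ---------------------------------------------------------------------------


@st.composite
def small_alignments(draw):
    nrows = draw(st.integers(3, 8))
    ncols = draw(st.integers(2, 6))
    rows = tuple(
        (
            f"r{r}",
            "".join(
                draw(st.sampled_from(AA20[:6] + "-")) for _ in range(ncols)
            ),
        )
        for r in range(nrows)
    )
    return MultipleAlignment(rows=rows, ncols=ncols)


@settings(max_examples=40, deadline=None)
@given(small_alignments(), st.data())
def test_scores_symmetric_and_nonnegative(msa, data):
    i = data.draw(st.integers(0, msa.ncols - 1))
    j = data.draw(st.integers(0, msa.ncols - 1).filter(lambda x: x != i))
    try:
        for scorer in (cov.mutual_information, cov.omes, cov.elsc):
            assert scorer(msa, i, j) == pytest.approx(scorer(msa, j, i), abs=1e-9)
            assert scorer(msa, i, j) >= -1e-9
    except DegenerateColumnError:
        pass


@settings(max_examples=40, deadline=None)
@given(small_alignments(), st.data())
def test_mi_bounded_by_min_entropy(msa, data):
    i = data.draw(st.integers(0, msa.ncols - 1))
    j = data.draw(st.integers(0, msa.ncols - 1).filter(lambda x: x != i))
    try:
        _, ni, nj, n = cov.column_pair_counts(msa, i, j)
    except DegenerateColumnError:
        return
    def entropy(counts):
        p = counts[counts > 0] / n
        return float(-(p * np.log2(p)).sum())
    assert cov.mutual_information(msa, i, j) <= min(entropy(ni), entropy(nj)) + 1e-9


def test_tsv_roundtrip(tmp_path, rng):
    msa = random_msa(rng, 6, 5, gap_prob=0.0)
    raw = cov.covariation_matrix(msa, "ELSC")
    z = cov.zscore_standardize(raw)
    p = tmp_path / "cov.tsv"
    cov.export_tsv(p, raw, z)
    back = cov.read_tsv(p, length=5, method="ELSC")
    iu = np.triu_indices(5, k=1)
    np.testing.assert_allclose(back.scores[iu], raw.scores[iu], rtol=1e-9)
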