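import numpy as np
import pytest

from psfmkit import (
    CANONICAL_ORDER,
    TransformError,
    dbt,
    dimension,
    edt,
    feature_name,
    feature_names,
    onehot_psfm,
    rpt,
    transform,
    tt,
)
from psfmkit.profile_io import AA_TO_INDEX, PSFM, ProteinSequence

from conftest import random_psfm


# ---------------------------------------------------------------------------
# Independent brute-force oracles (triple loops, no vectorization)
# ---------------------------------------------------------------------------

def rpt_brute(P, seq):
    L = len(seq)
    e = [[0.0] * 20 for _ in range(20)]
    for i in range(L):
        k = AA_TO_INDEX[seq[i]]
        for j in range(20):
            e[k][j] += P[i][j]
    flat = [e[i][j] / L for i in range(20) for j in range(20)]
    aac = [sum(P[i][j] for i in range(L)) / L for j in range(20)]
    return np.array(flat + aac)


def edt_brute(P, D):
    L = len(P)
    out = []
    for d in range(1, D + 1):
        for x in range(20):
            for y in range(20):
                s = sum((P[i][x] - P[i + d][y]) ** 2 for i in range(L - d))
                out.append(s / (L - d))
    return np.array(out)


def dbt_brute(P, D):
    L = len(P)
    out = []
    for d in range(0, D + 1):
        for x in range(20):
            for y in range(20):
                s = sum(P[i][x] * P[i + d][y] for i in range(L - d))
                out.append(s / (L - d))
    return np.array(out)


def tt_brute(P):
    L = len(P)
    out = []
    for x in range(20):
        for y in range(20):
            for z in range(20):
                out.append(
                    sum(P[i][x] * P[i + 1][y] * P[i + 2][z] for i in range(L - 2))
                )
    return np.array(out)


def uniform_psfm(L):
    return PSFM(id="uni", matrix=np.full((L, 20), 0.05))


# ---------------------------------------------------------------------------

class TestOracleEquivalence:
    """Vectorized transforms must match the brute-force loops exactly."""

    def test_random_profiles(self, rng):
        for k in range(10):
            L = int(rng.integers(5, 13))
            p = random_psfm(rng, L, id=f"o{k}")
            P = p.matrix.tolist()
            np.testing.assert_allclose(
                rpt(p).values, rpt_brute(P, p.sequence), atol=1e-12, rtol=0)
            np.testing.assert_allclose(
                edt(p, 3).values, edt_brute(P, 3), atol=1e-12, rtol=0)
            np.testing.assert_allclose(
                dbt(p, 3).values, dbt_brute(P, 3), atol=1e-12, rtol=0)
            np.testing.assert_allclose(
                tt(p).values, tt_brute(P), atol=1e-12, rtol=0)


class TestHandExamples:
    """Spot values evaluated by hand on the one-hot profile of 'ACA'."""

    def test_rpt_aca(self, aca_psfm):
        v = rpt(aca_psfm, "ACA")
        names = dict(zip(v.names, v.values))
        assert names["probeA:colA"] == pytest.approx(2 / 3)
        assert names["probeC:colC"] == pytest.approx(1 / 3)
        probe_block = v.values[:400]
        assert probe_block.sum() == pytest.approx(1.0)
        assert np.count_nonzero(probe_block) == 2
        assert names["aac:A"] == pytest.approx(2 / 3)
        assert names["aac:C"] == pytest.approx(1 / 3)

    def test_edt_aca_d1(self, aca_psfm):
        v = edt(aca_psfm, 1)
        names = dict(zip(v.names, v.values))
        assert names["d1:AA"] == pytest.approx(1.0)  # ((1-0)^2 + (0-1)^2)/2
        assert names["d1:AC"] == pytest.approx(0.0)

    def test_dbt_aca(self, aca_psfm):
        v = dbt(aca_psfm, 2)
        names = dict(zip(v.names, v.values))
        assert names["d0:AA"] == pytest.approx(2 / 3)
        assert names["d1:AC"] == pytest.approx(0.5)
        assert names["d2:AA"] == pytest.approx(1.0)

    def test_tt_aca(self, aca_psfm):
        v = tt(aca_psfm)
        names = dict(zip(v.names, v.values))
        assert names["ACA"] == pytest.approx(1.0)
        assert v.values.sum() == pytest.approx(1.0)  # all 7999 others are 0
        assert np.count_nonzero(v.values) == 1


class TestClosedForms:
    """Uniform profiles have exactly computable features."""

    @pytest.mark.parametrize("L,D", [(5, 1), (10, 4), (30, 7)])
    def test_uniform_dbt_all_1_over_400(self, L, D):
        v = dbt(uniform_psfm(L), D)
        np.testing.assert_allclose(v.values, np.full(v.omega, 1 / 400),
                                   atol=1e-15, rtol=0)

    @pytest.mark.parametrize("L,D", [(5, 2), (20, 7)])
    def test_uniform_edt_all_zero(self, L, D):
        v = edt(uniform_psfm(L), D)
        np.testing.assert_array_equal(v.values, np.zeros(v.omega))

    @pytest.mark.parametrize("L", [5, 12])
    def test_uniform_tt(self, L):
        v = tt(uniform_psfm(L))
        np.testing.assert_allclose(v.values, np.full(8000, (L - 2) / 8000),
                                   atol=1e-15, rtol=0)

    def test_uniform_rpt(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_ORDER), size=25))
        p = uniform_psfm(25)
        v = rpt(p, seq)
        counts = {aa: seq.count(aa) for aa in CANONICAL_ORDER}
        for name, val in zip(v.names, v.values):
            if name.startswith("probe"):
                aa = name[5]
                assert val == pytest.approx(counts[aa] / (20 * 25), abs=1e-15)
            else:
                assert val == pytest.approx(0.05, abs=1e-15)


class TestDimensions:
    @pytest.mark.parametrize("D", range(1, 11))
    def test_formulas(self, rng, D):
        L = int(rng.integers(D + 1, 61))
        p = random_psfm(rng, L)
        assert rpt(p).omega == dimension("rpt") == 420
        assert edt(p, D).omega == dimension("edt", D) == 400 * D
        assert dbt(p, D).omega == dimension("dbt", D) == 400 * (D + 1)
        assert tt(p).omega == dimension("tt") == 8000


class TestInvariants:
    def test_dbt_d0_diagonal_is_composition(self, rng):
        seq = "".join(rng.choice(list(CANONICAL_ORDER), size=40))
        p = onehot_psfm(ProteinSequence("s", seq))
        v = dbt(p, 2)
        d0 = v.values[:400].reshape(20, 20)
        comp = np.array([seq.count(aa) / 40 for aa in CANONICAL_ORDER])
        np.testing.assert_allclose(np.diag(d0), comp, atol=1e-12)
        assert np.allclose(d0, np.diag(np.diag(d0)))  # one-hot rows: off-diag 0

    def test_value_bounds(self, rng):
        for _ in range(5):
            p = random_psfm(rng, int(rng.integers(6, 30)))
            assert (edt(p, 3).values >= 0).all()
            assert (edt(p, 3).values <= 1).all()
            assert (dbt(p, 3).values >= 0).all()
            assert (tt(p).values >= 0).all()
            assert (rpt(p).values >= 0).all()

    def test_block_sums(self, rng):
        """Each DBT 400-block sums to 1 (rows are stochastic); TT sums to
        L-2; the RPT probe block sums to 1."""
        p = random_psfm(rng, 17)
        v = dbt(p, 4)
        for d in range(5):
            assert v.values[400 * d : 400 * (d + 1)].sum() == pytest.approx(1.0)
        assert tt(p).values.sum() == pytest.approx(15.0)
        assert rpt(p).values[:400].sum() == pytest.approx(1.0)

    def test_column_permutation_equivariance(self, rng):
        """Permuting residue columns permutes feature blocks, not values."""
        p = random_psfm(rng, 9)
        perm = rng.permutation(20)
        q = PSFM(id="perm", matrix=p.matrix[:, perm])
        for D in (0, 2):
            orig = dbt(p, D).values.reshape(D + 1, 20, 20)
            permd = dbt(q, D).values.reshape(D + 1, 20, 20)
            np.testing.assert_allclose(
                permd, orig[:, perm][:, :, perm], atol=1e-12)
        orig = tt(p).values.reshape(20, 20, 20)
        permd = tt(q).values.reshape(20, 20, 20)
        np.testing.assert_allclose(
            permd, orig[perm][:, perm][:, :, perm], atol=1e-12)


class TestNamingAndErrors:
    def test_feature_name_examples(self):
        assert feature_name("dbt", 0, 4) == "d0:AA"
        assert feature_name("tt", 7999) == "YYY"
        assert feature_name("rpt", 400) == "aac:A"
        assert feature_name("edt", 0, 7) == "d1:AA"

    def test_names_parallel_and_unique(self):
        for method, D in [("rpt", None), ("edt", 2), ("dbt", 2), ("tt", None)]:
            names = feature_names(method, D)
            assert len(names) == dimension(method, D)
            assert len(set(names)) == len(names)

    def test_name_out_of_range(self):
        with pytest.raises(TransformError, match="out of range"):
            feature_name("rpt", 420)

    def test_distance_too_large(self, rng):
        p = random_psfm(rng, 5)
        with pytest.raises(TransformError, match="too short"):
            edt(p, 5)
        with pytest.raises(TransformError, match="too short"):
            dbt(p, 5)

    def test_tt_too_short(self):
        p = PSFM(id="p", matrix=np.full((2, 20), 0.05))
        with pytest.raises(TransformError, match="L >= 3"):
            tt(p)

    def test_rpt_length_mismatch(self, rng):
        p = random_psfm(rng, 6)
        with pytest.raises(TransformError, match="length"):
            rpt(p, "ACA")

    def test_transform_dispatch_unknown(self, rng):
        with pytest.raises(TransformError, match="unknown"):
            transform(random_psfm(rng, 5), "bigram")
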