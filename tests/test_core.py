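import numpy as np
import pandas as pd
import pytest

from perturbsig import (
    SignatureMatrix,
    collapse_replicates,
    pairwise_correlation_matrix,
    read_gct,
    replicate_q75,
    spearman_correlation,
    write_gct,
)
from perturbsig.errors import (
    CorruptFileError,
    InvalidInputError,
    UnsupportedFormatError,
)


def brute_force_spearman(x, y):
    """Independent oracle: average-rank both vectors, then Pearson."""

    def midrank(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v)
        ranks = np.empty(len(v))
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            ranks[order[i: j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return ranks

    rx, ry = midrank(x), midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_identity_and_antitone(self):
        x = np.array([3.0, -1.0, 7.0, 0.5])
        assert spearman_correlation(x, x) == pytest.approx(1.0)
        assert spearman_correlation(x, -x) == pytest.approx(-1.0)

    def test_tied_example_matches_oracle(self):
        x = [1, 2, 2, 4]
        y = [1, 3, 3, 9]
        assert spearman_correlation(x, y) == pytest.approx(
            brute_force_spearman(x, y), abs=1e-12
        )

    def test_matches_brute_force_on_random_vectors_with_ties(self):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            # integer draws force frequent ties
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if len(set(x)) == 1 or len(set(y)) == 1:
                continue
            assert spearman_correlation(x, y) == pytest.approx(
                brute_force_spearman(x, y), abs=1e-12
            )

    def test_monotone_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=30), rng.normal(size=30)
        base = spearman_correlation(x, y)
        assert spearman_correlation(np.exp(x), y**3) == pytest.approx(base)

    @pytest.mark.parametrize("x,y", [([1, 2], [3, 4]), ([1, 2, 3], [1, 2])])
    def test_invalid_inputs_rejected(self, x, y):
        with pytest.raises(InvalidInputError):
            spearman_correlation(x, y)


class TestPairwiseMatrix:
    def test_matches_elementwise_loop(self, rng):
        vals = rng.normal(size=(20, 5))
        mat = pairwise_correlation_matrix(vals)
        for i in range(5):
            for j in range(5):
                expect = (1.0 if i == j
                          else spearman_correlation(vals[:, i], vals[:, j]))
                assert mat[i, j] == pytest.approx(expect, abs=1e-12)

    def test_symmetric_with_unit_diagonal(self, rng):
        mat = pairwise_correlation_matrix(rng.normal(size=(15, 4)))
        assert np.allclose(mat, mat.T)
        assert np.allclose(np.diag(mat), 1.0)

    def test_permutation_equivariance(self, rng):
        vals = rng.normal(size=(12, 4))
        perm = [2, 0, 3, 1]
        mat = pairwise_correlation_matrix(vals)
        permuted = pairwise_correlation_matrix(vals[:, perm])
        assert np.allclose(permuted, mat[np.ix_(perm, perm)])

    def test_identical_signatures(self):
        v = np.array([1.0, 5.0, 2.0])
        mat = pairwise_correlation_matrix(np.column_stack([v, v]))
        assert np.allclose(mat, 1.0)


class TestGct:
    def _matrix(self):
        data = pd.DataFrame(
            [[0.125, -3.5], [1e-17, 2.0]],
            index=["GB", "GA"], columns=["s1", "s2"],
        )
        return SignatureMatrix(data)

    def test_round_trip_is_exact(self, tmp_path):
        mat = self._matrix()
        path = tmp_path / "m.gct"
        write_gct(mat, path)
        back = read_gct(path)
        assert back.genes == mat.genes
        assert back.sigs == mat.sigs
        assert (back.data.to_numpy() == mat.data.to_numpy()).all()

    def test_output_header(self, tmp_path):
        path = tmp_path / "m.gct"
        write_gct(self._matrix(), path)
        lines = path.read_text().splitlines()
        assert lines[0] == "#1.3"
        assert lines[1].split("\t") == ["2", "2", "0", "0"]

    def test_wrong_version_rejected(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.2\n1\t1\nid\ts1\nG1\t0.5\n")
        with pytest.raises(UnsupportedFormatError):
            read_gct(path)

    def test_dimension_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.gct"
        path.write_text("#1.3\n3\t1\t0\t0\nid\ts1\nG1\t0.5\nG2\t0.25\n")
        with pytest.raises(CorruptFileError):
            read_gct(path)

    def test_zero_metadata_dialect_parses(self, tmp_path):
        path = tmp_path / "min.gct"
        path.write_text("#1.3\n1\t2\t0\t0\nid\ta\tb\nG1\t1.0\t2.0\n")
        mat = read_gct(path)
        assert mat.data.loc["G1", "b"] == 2.0

    def test_gene_order_canonicalized(self):
        mat = self._matrix()
        assert mat.genes == ["GA", "GB"]

    def test_empty_matrix_rejected(self, tmp_path):
        data = pd.DataFrame(index=["G1"], columns=[], dtype=float)
        mat = SignatureMatrix(data)
        with pytest.raises(InvalidInputError):
            write_gct(mat, tmp_path / "e.gct")

    def test_missing_values_rejected(self):
        data = pd.DataFrame([[1.0, np.nan]], index=["G1"], columns=["a", "b"])
        with pytest.raises(InvalidInputError):
            SignatureMatrix(data)


class TestCollapseReplicates:
    def test_identical_replicates_returned_unchanged(self):
        s = np.array([1.0, -2.0, 0.5, 3.0])
        collapsed, w = collapse_replicates(np.column_stack([s, s, s]))
        assert np.allclose(collapsed, s)
        assert w == pytest.approx([1 / 3] * 3)

    def test_two_replicates_gives_arithmetic_mean(self, rng):
        reps = rng.normal(size=(30, 2))
        collapsed, w = collapse_replicates(reps)
        assert w == pytest.approx([0.5, 0.5])
        assert np.allclose(collapsed, reps.mean(axis=1))

    def test_correlated_replicate_weighted_up(self, rng):
        # rep1 correlates strongly with rep2 and rep3; rep2-rep3 agree less
        base = rng.normal(size=200)
        rep1 = base + 0.1 * rng.normal(size=200)
        rep2 = base + 1.5 * rng.normal(size=200)
        rep3 = base + 1.5 * rng.normal(size=200)
        _, w = collapse_replicates(np.column_stack([rep1, rep2, rep3]))
        assert w[0] > w[1]
        assert w[0] > w[2]

    def test_single_replicate_warns(self):
        s = np.array([[1.0], [2.0], [3.0]])
        with pytest.warns(UserWarning):
            collapsed, w = collapse_replicates(s)
        assert np.allclose(collapsed, s[:, 0])
        assert w == pytest.approx([1.0])

    def test_output_in_convex_hull(self, rng):
        for _ in range(50):
            reps = rng.normal(size=(25, 4))
            collapsed, w = collapse_replicates(reps)
            assert (w >= 0).all()
            assert w.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.allclose(collapsed, reps @ w)


class TestReplicateQ75:
    def test_identical_replicates(self):
        s = np.array([1.0, 2.0, 5.0])
        assert replicate_q75(np.column_stack([s, s, s])) == pytest.approx(1.0)

    def test_two_replicates_single_pair(self, rng):
        reps = rng.normal(size=(40, 2))
        expect = spearman_correlation(reps[:, 0], reps[:, 1])
        assert replicate_q75(reps) == pytest.approx(expect)

    def test_linear_interpolation_rule(self, monkeypatch):
        # three pairwise correlations {0.1, 0.5, 0.9}: q75 under linear
        # interpolation is 0.5 + 0.5*(0.9-0.5) = 0.7
        import perturbsig.core as core

        fake = np.array([[1.0, 0.1, 0.5], [0.1, 1.0, 0.9], [0.5, 0.9, 1.0]])
        monkeypatch.setattr(core, "pairwise_correlation_matrix",
                            lambda reps: fake)
        assert core.replicate_q75(np.zeros((10, 3))) == pytest.approx(0.7)

    def test_too_few_replicates_rejected(self):
        with pytest.raises(InvalidInputError):
            replicate_q75(np.zeros((10, 1)))
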