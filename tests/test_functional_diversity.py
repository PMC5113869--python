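import itertools

import numpy as np
import pandas as pd
import pytest

from fragcomm import (
    CommunityMatrix,
    TraitTable,
    ValidationError,
    dominant_pc,
    fad,
    fad_glm,
    fad_records,
    fad_ses,
    load_taita_fragments,
    reduce_traits,
    zscore,
)
from fragcomm.functional_diversity import FAD_TRAITS, _GLM_TERMS
from fragcomm.synthetic_data import SyntheticScenario, generate_neutral, generate_traits


def fad_oracle(x: np.ndarray) -> float:
    """Brute-force pairwise Euclidean distance sum."""
    total = 0.0
    for i, j in itertools.combinations(range(x.shape[0]), 2):
        total += float(np.sqrt(np.sum((x[i] - x[j]) ** 2)))
    return total


class TestDominantPC:
    def test_rank_one_block_recovers_common_axis(self):
        col = np.array([1.0, 2, 3, 4, 5])
        block = np.column_stack([col, 2 * col])
        scores = dominant_pc(block)
        # scores proportional to the (standardized) column; positive on col 1
        z = (col - col.mean()) / col.std(ddof=1)
        assert np.allclose(scores, z * np.sqrt(2))

    def test_sign_convention_positive_first_column(self):
        rng = np.random.default_rng(0)
        block = rng.normal(size=(30, 3))
        block[:, 1] += 0.8 * block[:, 0]
        scores = dominant_pc(block)
        assert np.corrcoef(scores, block[:, 0])[0, 1] > 0

    def test_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(3)
        block = rng.normal(size=(10, 3)) @ np.array(
            [[1.0, 0.5, 0.2], [0, 1, 0.4], [0, 0, 1]]
        )
        z = (block - block.mean(0)) / block.std(0, ddof=1)
        corr = np.corrcoef(z, rowvar=False)
        w, v = np.linalg.eigh(corr)  # independent oracle: eigh on correlation
        axis = v[:, np.argmax(w)]
        if axis[0] < 0:
            axis = -axis
        assert np.allclose(dominant_pc(block), z @ axis, atol=1e-10)

    def test_zero_variance_column_named(self):
        block = pd.DataFrame({"a": [1.0, 2, 3], "b": [5.0, 5, 5]})
        with pytest.raises(ValidationError, match="b"):
            dominant_pc(block)


class TestFAD:
    def test_two_species_distance(self):
        x = np.array([[0.0, 0.0], [3.0, 4.0]])
        assert fad(x) == pytest.approx(5.0)

    def test_three_collinear(self):
        assert fad(np.array([[0.0], [1.0], [2.0]])) == pytest.approx(4.0)

    def test_fewer_than_two_species_is_zero(self):
        assert fad(np.array([[1.0, 2.0]])) == 0.0
        assert fad(np.empty((0, 2))) == 0.0

    def test_integer_grid_matches_bruteforce(self):
        x = np.array([[0, 0], [1, 0], [0, 1], [2, 2]], dtype=float)
        assert fad(x) == pytest.approx(fad_oracle(x), abs=1e-12)

    def test_permutation_and_rotation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(8, 3))
        base = fad(x)
        assert fad(x[rng.permutation(8)]) == pytest.approx(base)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert fad(x @ q) == pytest.approx(base)

    def test_missing_value_rejected(self):
        x = np.array([[1.0, np.nan], [0.0, 1.0]])
        with pytest.raises(ValidationError):
            fad(x)

    def test_one_dimensional_shortcut_matches_bruteforce(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=(20, 1))
        assert fad(x) == pytest.approx(fad_oracle(x), abs=1e-10)


class TestReduceTraits:
    def test_reduced_columns_present(self):
        traits = generate_traits(SyntheticScenario(seed=0))
        reduced = reduce_traits(traits)
        for col in FAD_TRAITS + ["diet_pc"]:
            assert col in reduced.table.columns

    def test_zscore_unit_moments(self):
        traits = reduce_traits(generate_traits(SyntheticScenario(seed=1)))
        z = zscore(traits.table[FAD_TRAITS])
        assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=1), 1, atol=1e-12)


class TestFADSES:
    def _pool(self, n=10, seed=0):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {"t1": rng.normal(size=n), "t2": rng.normal(size=n)},
            index=[f"s{i}" for i in range(n)],
        )

    def test_whole_pool_single_trait_reshuffle_invariant(self):
        # reshuffling within the full set permutes positions only: FAD
        # unchanged, SD zero, SES undefined-by-convention
        pool = self._pool()[["t1"]]
        obs, result, ens = fad_ses(pool, pool.index.tolist(), ["t1"], iterations=30, rng=0)
        assert ens.sd == pytest.approx(0.0)
        assert np.isnan(result.ses)

    def test_outlier_subset_scores_high(self):
        pool = self._pool(12, seed=2) * 0.01
        pool.iloc[0] = [10.0, 10.0]  # one far outlier, in the set
        obs, result, ens = fad_ses(
            pool, ["s0", "s1", "s2"], ["t1", "t2"], iterations=200, rng=1
        )
        # the reshuffling null only reaches the observed span when it
        # happens to draw the outlier, so most null scores sit below
        assert (ens.null_scores < obs).mean() > 0.7

    def test_small_set_rejected(self):
        pool = self._pool()
        with pytest.raises(ValidationError):
            fad_ses(pool, ["s0"], ["t1"], iterations=10, rng=0)

    def test_seeded_reproducibility(self):
        pool = self._pool()
        a = fad_ses(pool, ["s0", "s1", "s2"], None if False else ["t1", "t2"], 50, 3)
        b = fad_ses(pool, ["s0", "s1", "s2"], ["t1", "t2"], 50, 3)
        assert a[0] == b[0] and a[1].ses == b[1].ses


class TestRichnessDependence:
    """FAD grows mechanically with richness; SES-FAD must not."""

    def test_raw_fad_increases_with_subset_size(self):
        rng = np.random.default_rng(11)
        pool = pd.DataFrame(
            rng.normal(size=(30, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(30)],
        )
        z = zscore(pool)
        small = [fad(z[rng.choice(30, 5, replace=False)]) for _ in range(50)]
        large = [fad(z[rng.choice(30, 15, replace=False)]) for _ in range(50)]
        assert np.mean(large) > np.mean(small)

    def test_ses_fad_shows_no_richness_trend(self):
        from scipy import stats

        rng = np.random.default_rng(13)
        pool = pd.DataFrame(
            rng.normal(size=(30, 3)), columns=["a", "b", "c"],
            index=[f"s{i}" for i in range(30)],
        )
        sizes, scores = [], []
        for k in range(4, 28, 2):
            for _ in range(8):
                subset = rng.choice(pool.index, k, replace=False)
                _, r, _ = fad_ses(pool, subset, ["a", "b", "c"],
                                  iterations=100, rng=rng)
                sizes.append(k)
                scores.append(r.ses)
        reg = stats.linregress(sizes, scores)
        ci = 2 * reg.stderr
        assert reg.slope - ci < 0 < reg.slope + ci


def _glm_records(seed=0, n_frag=8, noise=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for guild in ("g1", "g2", "g3"):
        for trait in ("t1", "t2"):
            for f in range(n_frag):
                rows.append(
                    {
                        "guild": guild,
                        "trait": trait,
                        "group": "large" if f < n_frag // 2 else "small",
                        "n_species": int(rng.integers(2, 20)),
                        "fad": rng.normal(scale=noise),
                    }
                )
    return pd.DataFrame(rows)


class TestFADGLM:
    def test_exact_factor_response_saturates_eta2(self):
        rec = _glm_records(seed=1)
        means = {"g1": 1.0, "g2": 5.0, "g3": -2.0}
        rec["fad"] = rec["guild"].map(means)
        g = fad_glm(rec)
        assert g.terms["guild"][1] == pytest.approx(1.0)
        assert g.r_squared == pytest.approx(1.0)
        assert g.error_ss == pytest.approx(0.0, abs=1e-18)

    def test_pure_noise_low_eta2(self):
        rng = np.random.default_rng(7)
        rec = _glm_records(seed=2, n_frag=60)
        rec["fad"] = rng.normal(size=len(rec))
        g = fad_glm(rec)
        assert all(eta < 0.1 for _, eta in g.terms.values())

    def test_partial_eta2_matches_projection_oracle(self):
        """Full-vs-reduced SS via an explicit SVD projector oracle.

        The oracle computes SS_term = y'(P_full - P_reduced)y with hat
        matrices built from orthonormal bases of the column-dropped
        design, independent of the OLS fitting route.
        """
        import patsy

        rec = _glm_records(seed=3)
        rng = np.random.default_rng(4)
        rec["fad"] = rng.normal(size=len(rec)) + rec["n_species"] * 0.1
        g = fad_glm(rec)
        y = rec["fad"].to_numpy()
        rhs = " + ".join(t[1] for t in _GLM_TERMS)
        x = patsy.dmatrix(rhs, rec, return_type="dataframe")
        di = x.design_info
        xa = x.to_numpy()

        def explained_ss(mat):
            q, _ = np.linalg.qr(mat)
            proj = q @ (q.T @ y)
            return float(proj @ proj)

        ss_full = explained_ss(xa)
        sse_full = float(y @ y) - ss_full
        for name, formula_term in _GLM_TERMS:
            cols = list(range(*di.term_name_slices[formula_term].indices(xa.shape[1])))
            keep = [c for c in range(xa.shape[1]) if c not in cols]
            ss_term = ss_full - explained_ss(xa[:, keep])
            eta = ss_term / (ss_term + sse_full)
            assert g.terms[name][1] == pytest.approx(eta, abs=1e-10)

    def test_degrees_of_freedom(self):
        g = fad_glm(_glm_records(seed=5))
        assert g.terms["guild"][0] == 2  # 3 levels
        assert g.terms["trait"][0] == 1
        assert g.terms["size"][0] == 1
        assert g.terms["guild_x_trait"][0] == 2
        assert g.terms["species"][0] == 1
        assert g.error_df > 0

    def test_single_level_factor_rejected(self):
        rec = _glm_records()
        rec["group"] = "large"
        with pytest.raises(ValidationError, match="group"):
            fad_glm(rec)


class TestFADRecords:
    def test_records_structure_and_small_cells_dropped(self):
        scn = SyntheticScenario(seed=0)
        comm = generate_neutral(scn)
        reduced = reduce_traits(generate_traits(scn))
        rec = fad_records(
            comm, reduced, load_taita_fragments_like(), iterations=20, rng=0
        )
        assert (rec["n_species"] >= 2).all()
        assert set(rec["trait"].unique()) <= set(FAD_TRAITS)
        assert {"guild", "fragment_id", "group", "fad", "ses_fad"} <= set(rec.columns)
        assert (rec["fad"] >= 0).all()


def load_taita_fragments_like():
    """Study metadata with fragment ids renamed to the generator's labels."""
    ft = load_taita_fragments()
    t = ft.table.copy()
    t["fragment_id"] = [f"frag_{i + 1:02d}" for i in range(len(t))]
    from fragcomm.core_data import FragmentTable

    return FragmentTable(t)
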