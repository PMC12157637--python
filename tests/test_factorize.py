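import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import trisomod as tm
from trisomod.errors import GeneAlignmentError, InvalidConfigError, InvalidInputError

from conftest import small_config


def _frame(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


class TestZscoreRows:
    def test_simple_row(self):
        out = tm.zscore_rows(_frame([[1, 2, 3]]))
        assert np.allclose(out.to_numpy(), [[-1, 0, 1]])

    def test_constant_row_zeroed_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = tm.zscore_rows(_frame([[5, 5, 5], [1, 2, 3]]))
        assert (out.iloc[0] == 0).all()
        assert "constant" in caplog.text

    def test_output_moments(self, rng):
        out = tm.zscore_rows(_frame(rng.normal(size=(20, 15)))).to_numpy()
        assert np.abs(out.mean(axis=1)).max() < 1e-12
        assert np.abs(out.std(axis=1, ddof=1) - 1).max() < 1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(InvalidInputError):
            tm.zscore_rows(_frame([[1.0]]))


class TestEstimateNumComponents:
    def test_planted_rank_recovered(self, rng):
        Z = rng.normal(size=(500, 3))
        B = rng.normal(size=(3, 100))
        X = _frame(Z @ B + rng.normal(scale=0.01, size=(500, 100)))
        assert tm.estimate_num_components(X, seed=1) == 3

    def test_pure_noise_yields_at_most_one(self):
        hits = []
        base = np.random.default_rng(0)
        for seed in range(20):
            X = _frame(base.normal(size=(120, 60)))
            hits.append(tm.estimate_num_components(X, n_permutations=10, seed=seed))
        assert max(hits) <= 1

    def test_deterministic_given_seed(self, rng):
        X = _frame(rng.normal(size=(80, 40)))
        assert tm.estimate_num_components(X, seed=3) == \
            tm.estimate_num_components(X, seed=3)

    def test_invalid_permutation_count(self, rng):
        with pytest.raises(InvalidConfigError):
            tm.estimate_num_components(_frame(rng.normal(size=(10, 5))),
                                       n_permutations=0)


class TestFit:
    def test_zero_noise_reconstruction(self):
        cfg = small_config(noise_sd_expression=0.0, noise_sd_loadings=0.05,
                           sgm_effect=0.0, seed=6)
        ds = tm.generate_dataset(cfg)
        Xn = tm.zscore_rows(ds.expression)
        model = tm.fit(Xn, ds.truth.C_true, k=cfg.k_true, frac=0.7)
        X = Xn.to_numpy()
        R = X - model.Z_raw.to_numpy() @ model.B_raw.to_numpy()
        assert np.linalg.norm(R) / np.linalg.norm(X) < 0.05

    def test_objective_monotone_and_constraints(self, small_model):
        trace = np.asarray(small_model.objective_trace)
        assert np.all(np.diff(trace) <= 1e-8 * np.abs(trace[:-1]))
        assert small_model.U.to_numpy().min() >= 0
        assert small_model.Z_raw.to_numpy().min() >= 0

    def test_standardization_contract(self, small_model):
        Z = small_model.Z.to_numpy()
        B = small_model.B.to_numpy()
        nonconst = Z.std(axis=0) > 0
        assert np.abs(Z[:, nonconst].mean(axis=0)).max() < 1e-8
        assert np.abs(Z[:, nonconst].var(axis=0, ddof=1) - 1).max() < 1e-6
        nonconst = B.std(axis=1) > 0
        assert np.abs(B[nonconst].mean(axis=1)).max() < 1e-8
        assert np.abs(B[nonconst].var(axis=1, ddof=1) - 1).max() < 1e-6

    def test_planted_modules_recovered(self, small_dataset, small_model):
        matched = tm.match_modules(small_model.Z, small_dataset.truth.Z_true)
        assert matched["abs_corr"].mean() >= 0.8

    def test_gene_mismatch_rejected(self, small_dataset):
        Xn = tm.zscore_rows(small_dataset.expression)
        C = small_dataset.truth.C_true.iloc[::-1]
        with pytest.raises(GeneAlignmentError):
            tm.fit(Xn, C, k=3)

    def test_k_exceeding_dimensions_rejected(self, small_dataset):
        Xn = tm.zscore_rows(small_dataset.expression)
        with pytest.raises(InvalidConfigError):
            tm.fit(Xn, small_dataset.truth.C_true, k=10_000)

    def test_auto_penalty_hits_target_pathway_fraction(self, small_model):
        active = (small_model.U.to_numpy() > 0).any(axis=0).mean()
        assert abs(active - 0.7) <= 0.2

    def test_save_load_round_trip(self, tmp_path, small_model):
        small_model.save(tmp_path / "model", seed=4)
        loaded = tm.FactorModel.load(tmp_path / "model")
        pd.testing.assert_frame_equal(loaded.Z, small_model.Z,
                                      check_exact=False, rtol=1e-12,
                                      check_names=False)
        assert loaded.penalties == pytest.approx(small_model.penalties)
        assert loaded.converged == small_model.converged


class TestPathwayAlignment:
    def test_alignment_scores_bounded_and_informative(self, small_dataset, small_model):
        table = tm.pathway_alignment(small_model, small_dataset.truth.C_true,
                                     holdout_frac=0.2, seed=1)
        assert len(table) > 0
        assert table["auc"].between(0, 1).all()
        # the generator's aligned sets should score far above chance
        assert table["auc"].max() > 0.9

    def test_planted_alignment_detected(self, small_dataset, small_model):
        """The gene set used to build each module ranks as significantly
        aligned to its recovered counterpart."""
        table = tm.pathway_alignment(small_model, small_dataset.truth.C_true,
                                     holdout_frac=0.2, seed=1)
        matched = tm.match_modules(small_model.Z, small_dataset.truth.Z_true)
        lv_for_true = dict(zip(matched["true_module"], matched["lv"]))
        U_true = small_dataset.truth.U_true
        hits = 0
        total = 0
        for true_mod in U_true.columns:
            sets = list(U_true.index[U_true[true_mod] > 0])
            if not sets:
                continue
            total += 1
            sub = table[(table["lv"] == lv_for_true[true_mod])
                        & (table["gene_set"].isin(sets))]
            if len(sub) and (sub["fdr"] < 0.05).any() and (sub["auc"] > 0.6).any():
                hits += 1
        # hold-out sets carry only 2-5 genes at this scale, so FDR power is
        # limited; most, not all, planted alignments should clear both gates
        assert total > 0 and hits / total >= 0.5

    def test_null_loadings_give_chance_auc(self):
        """Loadings independent of membership average AUC 0.5."""
        rng = np.random.default_rng(11)
        aucs = []
        for _ in range(100):
            pos = rng.normal(size=30)
            neg = rng.normal(size=120)
            labels = np.r_[np.ones(30), np.zeros(120)].astype(int)
            aucs.append(tm.roc_auc(np.r_[pos, neg], labels))
        assert abs(np.mean(aucs) - 0.5) < 0.03

    def test_hand_counted_auc(self):
        # members {0.9, 0.3} vs non-members {0.8, 0.4}: 2 of 4 pairs concordant
        assert tm.roc_auc([0.9, 0.3, 0.8, 0.4], [1, 1, 0, 0]) == 0.5


class TestMatchModules:
    def test_permutation_recovered_exactly(self, rng):
        Z = pd.DataFrame(rng.normal(size=(50, 4)),
                         index=[f"g{i}" for i in range(50)],
                         columns=["LV1", "LV2", "LV3", "LV4"])
        perm = Z[["LV3", "LV1", "LV4", "LV2"]]
        perm.columns = ["M1", "M2", "M3", "M4"]
        matched = tm.match_modules(Z, perm)
        mapping = dict(zip(matched["lv"], matched["true_module"]))
        assert mapping == {"LV3": "M1", "LV1": "M2", "LV4": "M3", "LV2": "M4"}
        assert np.allclose(matched["abs_corr"], 1.0)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 1000))
def test_masking_is_deterministic_and_partial(seed):
    """mask_prior removes about holdout_frac of each set and reproduces exactly."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(40)]
    C = pd.DataFrame(0, index=genes, columns=["A", "B"], dtype=np.int8)
    C.loc[rng.choice(genes, 20, replace=False), "A"] = 1
    C.loc[rng.choice(genes, 10, replace=False), "B"] = 1
    m1, h1 = tm.mask_prior(C, 0.2, seed)
    m2, h2 = tm.mask_prior(C, 0.2, seed)
    pd.testing.assert_frame_equal(m1, m2)
    assert h1 == h2
    assert m1["A"].sum() == 16 and m1["B"].sum() == 8
    for name in ("A", "B"):
        assert all(C.loc[g, name] == 1 and m1.loc[g, name] == 0 for g in h1[name])
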