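"""Arithmetic and oracle checks for both preprocessing branches."""

import itertools

import numpy as np
import pandas as pd
import pytest

from codim.datasets import ExpressionDataset, OrthologyMap, ValidationError
from codim.preprocess import (
    average_replicates,
    collapse_probes_maxvar,
    collapse_probes_random,
    impute_missing,
    present_call_filter,
    preprocess_liver,
    quantile_normalize,
    restrict_to_orthologs,
    select_replicates,
    zscore_vs_controls,
)
from codim.synth import PlantedModule, generate_raw_dataset


def _dataset(values, drugs=None, replicates=None, present=None):
    values = pd.DataFrame(values) if not isinstance(values, pd.DataFrame) else values
    meta = pd.DataFrame(index=values.columns)
    meta["drug"] = drugs if drugs is not None else list(values.columns)
    if replicates is not None:
        meta["replicate"] = replicates
    return ExpressionDataset(values=values, profile_meta=meta, present=present)


class TestSelectReplicates:
    def test_single_replicate_identity(self):
        rng = np.random.default_rng(0)
        ds = {
            cl: _dataset(
                pd.DataFrame(rng.normal(size=(10, 2)), columns=["d1|r0", "d2|r0"]),
                drugs=["d1", "d2"],
            )
            for cl in ("A", "B")
        }
        out = select_replicates(ds)
        for cl in ds:
            assert list(out[cl].values.columns) == ["d1|r0", "d2|r0"]

    def test_consistent_replicates_beat_noise(self):
        rng = np.random.default_rng(1)
        shared = rng.normal(size=30)
        ds = {}
        for cl in ("A", "B", "C"):
            cols = {f"d|good_{cl}": shared, f"d|noise_{cl}": rng.normal(size=30)}
            ds[cl] = _dataset(pd.DataFrame(cols), drugs=["d", "d"])
        out = select_replicates(ds)
        for cl in ds:
            assert list(out[cl].values.columns) == [f"d|good_{cl}"]

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(2)
        ds = {
            cl: _dataset(
                pd.DataFrame(
                    rng.normal(size=(15, 2)), columns=[f"d|{cl}0", f"d|{cl}1"]
                ),
                drugs=["d", "d"],
            )
            for cl in ("A", "B", "C")
        }
        out = select_replicates(ds)
        chosen = tuple(out[cl].values.columns[0] for cl in sorted(ds))

        def mean_pairwise(cols):
            X = np.column_stack(cols)
            R = np.corrcoef(X.T)
            iu = np.triu_indices(3, 1)
            return R[iu].mean()

        best, best_score = None, -np.inf
        for combo in itertools.product(range(2), repeat=3):
            cols = [
                ds[cl].values.iloc[:, j].to_numpy()
                for cl, j in zip(sorted(ds), combo)
            ]
            score = mean_pairwise(cols)
            if score > best_score:
                best_score = score
                best = tuple(
                    ds[cl].values.columns[j] for cl, j in zip(sorted(ds), combo)
                )
        assert chosen == best


class TestPresentCallFilter:
    def test_threshold_is_strict_and_any_cell_line(self):
        present = pd.DataFrame(
            {f"p{i}": [0, 1, 1] for i in range(100)}, index=["g0", "g1", "g2"]
        )
        present.iloc[1, :] = [1] * 11 + [0] * 89  # 11% in this cell line only
        other = pd.DataFrame(0, index=present.index, columns=present.columns)
        ds = {
            "A": _dataset(pd.DataFrame(np.zeros((3, 100)), index=present.index,
                                       columns=present.columns), present=present),
            "B": _dataset(pd.DataFrame(np.zeros((3, 100)), index=present.index,
                                       columns=present.columns), present=other),
        }
        kept = present_call_filter(ds, threshold=0.10)
        assert "g0" not in kept  # present nowhere
        assert "g1" in kept  # 11% > 10% in one cell line
        assert "g2" in kept

    def test_missing_call_matrix_is_error(self):
        ds = {"A": _dataset(np.zeros((2, 3)))}
        with pytest.raises(ValidationError):
            present_call_filter(ds)


class TestProbeCollapse:
    def _probed(self, values, gene_of):
        ds = _dataset(values)
        ds.gene_meta = pd.DataFrame({"gene": gene_of}, index=values.index)
        return ds

    def test_random_is_seeded_and_uniform(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(size=(3, 4)), index=["p1", "p2", "p3"])
        ds = self._probed(values, ["g1", "g1", "g2"])
        first = collapse_probes_random(ds, seed=5)
        assert first.values.equals(collapse_probes_random(ds, seed=5).values)
        assert list(first.values.index) == ["g1", "g2"]
        counts = {"p1": 0, "p2": 0}
        for seed in range(400):
            out = collapse_probes_random(ds, seed=seed)
            chosen = "p1" if out.values.loc["g1"].equals(values.loc["p1"]) else "p2"
            counts[chosen] += 1
        # selection approximately uniform over a gene's probes
        assert 140 < counts["p1"] < 260

    def test_maxvar_picks_highest_variance_with_lex_tiebreak(self):
        values = pd.DataFrame(
            [[0.0, 1.0, 2.0], [0.0, 2.0, 4.0], [5.0, 6.0, 7.0], [1.0, 2.0, 3.0]],
            index=["pa", "pb", "pc", "pd"],
        )
        ds = self._probed(values, ["g1", "g1", "g2", "g2"])
        out = collapse_probes_maxvar(ds)
        assert out.values.loc["g1"].tolist() == [0.0, 2.0, 4.0]  # higher variance
        assert out.values.loc["g2"].tolist() == [5.0, 6.0, 7.0]  # tie -> 'pc' < 'pd'

    def test_maxvar_agrees_with_argmax_oracle(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.normal(size=(20, 8)),
                              index=[f"p{i:02d}" for i in range(20)])
        gene_of = [f"g{i % 7}" for i in range(20)]
        out = collapse_probes_maxvar(self._probed(values, gene_of))
        var = values.var(axis=1, ddof=1)
        for gene in sorted(set(gene_of)):
            probes = sorted(p for p, g in zip(values.index, gene_of) if g == gene)
            expected = probes[int(np.argmax(var.loc[probes].to_numpy()))]
            assert out.values.loc[gene].equals(values.loc[expected].rename(gene))


class TestQuantileNormalize:
    def test_hand_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0]})
        out = quantile_normalize(df)
        assert out["a"].tolist() == [2.5, 3.5, 4.5]
        assert out["b"].tolist() == [2.5, 3.5, 4.5]

    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [3.0, 1.0, 2.0], "b": [3.0, 1.0, 2.0]})
        assert quantile_normalize(df).equals(df)

    def test_column_distributions_identical_after_transform(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(50, 4)))
        out = quantile_normalize(df)
        ref = np.sort(out[0].to_numpy())
        for j in range(1, 4):
            assert np.allclose(np.sort(out[j].to_numpy()), ref)

    def test_single_column_warns_identity(self):
        df = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            assert quantile_normalize(df).equals(df)


class TestImputeMissing:
    def test_threshold_strict_and_row_mean_fill(self):
        df = pd.DataFrame(
            {
                "a": [1.0, 1.0, np.nan],
                "b": [np.nan, 2.0, np.nan],
                "c": [3.0, 3.0, np.nan],
                "d": [4.0, 4.0, np.nan],
                "e": [5.0, 5.0, np.nan],
                "f": [6.0, 6.0, np.nan],
                "g": [7.0, 7.0, np.nan],
                "h": [8.0, 8.0, np.nan],
                "i": [9.0, 9.0, np.nan],
                "j": [10.0, 10.0, np.nan],
            },
            index=["r10pct", "rfull", "rempty"],
        )
        out = impute_missing(df, max_missing_fraction=0.10)
        assert "r10pct" in out.index  # exactly 10% missing is kept
        assert "rempty" not in out.index
        expected_mean = np.nanmean(df.loc["r10pct"].to_numpy())
        assert out.loc["r10pct", "b"] == pytest.approx(expected_mean)
        # 2/10 missing exceeds the threshold
        df2 = df.copy()
        df2.loc["r10pct", "c"] = np.nan
        assert "r10pct" not in impute_missing(df2, 0.10).index

    def test_no_missing_identity(self):
        df = pd.DataFrame(np.arange(12, dtype=float).reshape(3, 4))
        assert impute_missing(df).equals(df)


class TestZscoreVsControls:
    def test_hand_computation(self):
        values = pd.DataFrame(
            [[1.0, 2.0], [5.0, 5.0], [0.0, 4.0]],
            index=["g1", "g2", "g3"], columns=["t1", "t2"],
        )
        controls = pd.DataFrame(
            [[1.0, 1.0], [5.0, 5.0], [2.0, 2.0]],
            index=["g1", "g2", "g3"], columns=["c1", "c2"],
        )
        allx = pd.concat([values, controls], axis=1)
        sd = allx.std(axis=1, ddof=1)
        q = np.quantile(sd, 0.10)
        out = zscore_vs_controls(values, controls, sd_quantile=0.10)
        for g in values.index:
            for c in values.columns:
                expected = (values.loc[g, c] - controls.loc[g].mean()) / (sd[g] + q)
                assert out.loc[g, c] == pytest.approx(expected)
        # constant gene stays finite thanks to the quantile regularizer
        assert np.isfinite(out.loc["g2"]).all()
        assert out.loc["g2"].tolist() == [0.0, 0.0]

    def test_empty_controls_error(self):
        values = pd.DataFrame(np.ones((2, 2)), index=["g1", "g2"])
        with pytest.raises(ValidationError):
            zscore_vs_controls(values, values.iloc[:, :0])


class TestAverageReplicates:
    def test_replicates_average_but_doses_stay_distinct(self):
        values = pd.DataFrame(
            [[1.0, 3.0, 10.0], [2.0, 4.0, 20.0]],
            index=["g1", "g2"], columns=["p1", "p2", "p3"],
        )
        meta = pd.DataFrame(
            {"drug": ["d", "d", "d"], "dose": [1, 1, 5], "time": [6, 6, 6],
             "replicate": [0, 1, 0]},
            index=values.columns,
        )
        ds = ExpressionDataset(values=values, profile_meta=meta)
        out = average_replicates(ds)
        assert out.values.shape[1] == 2  # dose 1 collapsed, dose 5 separate
        col_low = [c for c in out.values.columns if "|1|" in c][0]
        assert out.values[col_low].tolist() == [2.0, 3.0]

    def test_opposite_replicates_cancel(self):
        values = pd.DataFrame({"p1": [1.0, -2.0], "p2": [-1.0, 2.0]}, index=["g1", "g2"])
        meta = pd.DataFrame(
            {"drug": ["d", "d"], "dose": [1, 1], "time": [6, 6], "replicate": [0, 1]},
            index=values.columns,
        )
        out = average_replicates(ExpressionDataset(values=values, profile_meta=meta))
        assert np.allclose(out.values.to_numpy(), 0.0)


class TestRestrictToOrthologs:
    def test_translation_and_set_arithmetic(self):
        values = pd.DataFrame(np.eye(3), index=["r1", "r2", "r3"],
                              columns=["p1", "p2", "p3"])
        ds = _dataset(values)
        omap = OrthologyMap(pd.DataFrame({"gene_a": ["h1", "h2"], "gene_b": ["r1", "r2"]}))
        out = restrict_to_orthologs(ds, omap, reference_genes={"h1"})
        assert list(out.values.index) == ["h1"]
        full = OrthologyMap(
            pd.DataFrame({"gene_a": ["h1", "h2", "h3"], "gene_b": ["r1", "r2", "r3"]})
        )
        out2 = restrict_to_orthologs(ds, full, reference_genes={"h1", "h2", "h3"})
        assert len(out2.values.index) == 3

    def test_empty_map_warns_empty(self):
        ds = _dataset(pd.DataFrame(np.eye(2), index=["r1", "r2"], columns=["p1", "p2"]))
        omap = OrthologyMap(pd.DataFrame({"gene_a": [], "gene_b": []}))
        with pytest.warns(UserWarning):
            out = restrict_to_orthologs(ds, omap, reference_genes=set())
        assert out.values.empty

    def test_duplicated_map_is_validation_error(self):
        with pytest.raises(ValidationError):
            OrthologyMap(pd.DataFrame({"gene_a": ["h1", "h1"], "gene_b": ["r1", "r2"]}))


def test_liver_branch_end_to_end_preserves_planted_signal():
    """Planted cells keep their sign and >= 70% of the effect size, measured
    in units of the processed matrix's own background spread."""
    planted = PlantedModule(
        "m",
        tuple(f"G{i:04d}" for i in range(40)),
        tuple(f"D{i:03d}" for i in range(6)),
        3.0,
        tuple([1] * 25 + [-1] * 15),
        ("RAW",),
    )
    ds = generate_raw_dataset(n_genes=250, n_drugs=18, planted=[planted], seed=6)
    out = preprocess_liver(ds)
    assert out.scale == "zscore"
    assert not out.values.isna().any().any()
    z = out.values
    module_cols = [c for c in z.columns if c.split("|")[0] in set(planted.drug_ids)]
    genes = [g for g in planted.gene_ids if g in z.index]
    signs = {g: s for g, s in zip(planted.gene_ids, planted.signs)}
    block = z.loc[genes, module_cols]
    signed = block.mul(pd.Series(signs).loc[genes], axis=0)
    background = z.drop(index=genes)
    noise_sd = background.to_numpy().std()
    assert (signed.mean(axis=1) > 0).mean() > 0.95  # signs preserved
    assert signed.to_numpy().mean() / noise_sd >= 0.7 * 3.0
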