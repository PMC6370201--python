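import numpy as np
import pandas as pd
import pytest

from dyadsync import (
    crosstab_ir,
    enumerate_configs,
    kruskal_by_sequence,
    make_dataset,
    ordinal_ir_regression,
    run_grid,
)


class TestEnumerateConfigs:
    def test_default_grid_has_600_configurations(self):
        grid = enumerate_configs()
        assert len(grid) == 600
        assert len(set(grid.ids)) == 600  # ids are stable and unique

    def test_single_level_per_family(self):
        grid = enumerate_configs(
            {
                "method": ("WCLC",),
                "transform": ("raw",),
                "smoothing": ("none",),
                "bandwidth": (125,),
                "r2_cutoff": (0.25,),
            }
        )
        assert len(grid) == 1

    def test_product_of_family_sizes(self):
        grid = enumerate_configs(
            {
                "method": ("WCLC", "WCLR"),
                "transform": ("raw", "log1p"),
                "smoothing": ("none", "slight"),
                "bandwidth": (75, 125),
                "r2_cutoff": (0.0, 0.25),
            }
        )
        assert len(grid) == 32

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="no levels"):
            enumerate_configs({"method": ()})


def _synthetic_results(rng, n=200, beta_wclr=0.0):
    """IR table where a latent score orders classes; beta_wclr shifts WCLR."""
    rows = []
    for _ in range(n):
        method = rng.choice(["WCLC", "WCLR"])
        latent = rng.normal() + (beta_wclr if method == "WCLR" else 0.0)
        ir = "poor" if latent < -0.5 else ("acceptable" if latent < 0.5 else "good")
        rows.append(
            {
                "method": method,
                "transform": rng.choice(["raw", "log1p"]),
                "smoothing": rng.choice(["none", "slight"]),
                "bandwidth": int(rng.choice([75, 125])),
                "r2_cutoff": float(rng.choice([0.0, 0.25])),
                "ir_combined": ir,
            }
        )
    return pd.DataFrame(rows)


class TestCrosstabIR:
    def test_exact_2x2_fisher(self):
        df = pd.DataFrame(
            {
                "method": ["WCLC"] * 10 + ["WCLR"] * 10,
                "ir_combined": ["good"] * 10 + ["poor"] * 10,
            }
        )
        res = crosstab_ir(df, "method")
        # hypergeometric enumeration: only 2 of C(20,10) assignments are as
        # extreme as the observed all-or-nothing split
        assert res.fisher_p == pytest.approx(2 / 184756)
        assert res.cramers_v == pytest.approx(1.0)

    def test_independent_table_large_p(self, rng):
        df = _synthetic_results(rng, n=300, beta_wclr=0.0)
        res = crosstab_ir(df, "method", n_mc=20_000, seed=1)
        assert res.fisher_p > 0.05  # no association by construction

    def test_strong_association_small_p(self, rng):
        df = _synthetic_results(rng, n=300, beta_wclr=3.0)
        res = crosstab_ir(df, "method", n_mc=20_000, seed=1)
        assert res.fisher_p < 0.001
        assert res.cramers_v > 0.3

    def test_single_level_rejected(self):
        df = pd.DataFrame({"method": ["WCLC"] * 5, "ir_combined": ["good"] * 5})
        with pytest.raises(ValueError, match="single level"):
            crosstab_ir(df, "method")

    def test_mc_fisher_seeded_reproducible(self, rng):
        df = _synthetic_results(rng, n=100, beta_wclr=1.0)
        p1 = crosstab_ir(df, "method", n_mc=5_000, seed=9).fisher_p
        p2 = crosstab_ir(df, "method", n_mc=5_000, seed=9).fisher_p
        assert p1 == p2


class TestOrdinalIRRegression:
    def test_null_coefficient_within_two_se(self, rng):
        df = _synthetic_results(rng, n=400, beta_wclr=0.0)
        out = ordinal_ir_regression(df)
        row = out[out["term"] == "method[WCLR]"].iloc[0]
        assert abs(row["coef"]) <= 2 * row["se"] + 0.1

    def test_sign_contract_for_superior_method(self, rng):
        """When WCLR stochastically outranks WCLC, its dummy coefficient is
        positive and significant."""
        df = _synthetic_results(rng, n=400, beta_wclr=1.5)
        out = ordinal_ir_regression(df)
        row = out[out["term"] == "method[WCLR]"].iloc[0]
        assert row["coef"] > 0
        assert row["p_value"] < 0.01
        assert not row["separation_flag"]

    def test_complete_separation_flagged(self, rng):
        rows = []
        for _ in range(200):
            method = rng.choice(["WCLC", "WCLR"])
            rows.append(
                {
                    "method": method,
                    "transform": rng.choice(["raw", "log1p"]),
                    "smoothing": "none",
                    "bandwidth": 75,
                    "r2_cutoff": 0.25,
                    "ir_combined": "good" if method == "WCLR" else "poor",
                }
            )
        out = ordinal_ir_regression(pd.DataFrame(rows))
        assert out[out["term"] == "method[WCLR]"].iloc[0]["separation_flag"]

    def test_single_ir_class_rejected(self):
        df = pd.DataFrame(
            {
                "method": ["WCLC", "WCLR"] * 5,
                "transform": ["raw"] * 10,
                "smoothing": ["none"] * 10,
                "bandwidth": [75] * 10,
                "r2_cutoff": [0.25] * 10,
                "ir_combined": ["good"] * 10,
            }
        )
        with pytest.raises(ValueError, match="single observed class"):
            ordinal_ir_regression(df)


class TestKruskalBySequence:
    def frame(self, groups):
        rows = []
        for gid, values in groups.items():
            for v in values:
                rows.append({"dyad_id": gid, "sync_label": "sync", "score": v})
        return pd.DataFrame(rows)

    def test_hand_ranked_two_groups(self):
        """Values {1,2} vs {3,4}: ranks 1,2 | 3,4 give H = 2.4 by the
        explicit rank-sum formula."""
        h, p, _ = kruskal_by_sequence(self.frame({"s1": [1, 2], "s2": [3, 4]}))
        assert h == pytest.approx(2.4)

    def test_identical_values_warn_and_return_zero(self):
        with pytest.warns(UserWarning, match="identical"):
            h, p, _ = kruskal_by_sequence(self.frame({"s1": [1, 1], "s2": [1, 1]}))
        assert h == 0.0 and p == 1.0

    def test_strong_shift_detected(self, rng):
        groups = {
            "s1": rng.normal(0, 1, 50).tolist(),
            "s2": rng.normal(0, 1, 50).tolist(),
            "s3": (rng.normal(0, 1, 50) + 5).tolist(),
        }
        h, p, mean_ranks = kruskal_by_sequence(self.frame(groups))
        assert p < 0.001
        assert mean_ranks["s3"] > mean_ranks["s1"]

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_by_sequence(self.frame({"s1": [1, 2, 3]}))


@pytest.fixture(scope="module")
def small_run(params):
    dataset = make_dataset(params, n_sync=1, n_nosync=1, seed=3)
    grid = enumerate_configs(
        {
            "method": ("WCLC",),
            "transform": ("log1p", "raw"),
            "smoothing": ("none",),
            "bandwidth": (125,),
            "r2_cutoff": (0.25,),
        }
    )
    return dataset, grid, run_grid(dataset, grid, master_seed=2)


class TestRunGrid:
    def test_summary_has_one_row_per_config_condition(self, small_run):
        _, grid, result = small_run
        assert len(result.summary) == len(grid) * 3
        assert set(result.summary["condition"]) == {"embedded", "isolated", "artificial"}
        assert not result.summary["ir_combined"].isna().any()

    def test_per_dyad_rows_cover_every_task(self, small_run):
        dataset, grid, result = small_run
        assert len(result.per_dyad) == len(grid) * len(dataset)

    def test_round_trips_through_csv(self, small_run, tmp_path):
        from dyadsync.io import read_result_table, write_result_table

        _, _, result = small_run
        path = tmp_path / "summary.csv"
        write_result_table(result.summary, path)
        back = read_result_table(path)
        pd.testing.assert_frame_equal(back, result.summary)
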