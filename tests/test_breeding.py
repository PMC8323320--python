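import numpy as np
import pandas as pd
import pytest

from beegs.breeding import (
    BreedingConfig,
    InfeasibleConfigError,
    InfeasibleSelectionError,
    InvalidProportionError,
    phenotype_colony,
    run_breeding_program,
    sample_genotyped_sets,
    select_parents_cbs,
)
from beegs.genome import assign_qtl_effects
from beegs.trait_model import MOD, derive_trait_parameters

from conftest import SMALL_CONFIG


class TestConfig:
    def test_defaults_mirror_reference_program(self):
        cfg = BreedingConfig()
        assert cfg.n_bq_per_year == 1000
        assert cfg.n_stations * cfg.n_dpq_per_station == 400
        assert cfg.daughters_per_dam_bq == 5

    @pytest.mark.parametrize(
        "bad",
        [
            dict(n_dams_bq=7),  # does not divide 1000
            dict(n_dams_bq=40, n_stations=50, n_dams_dpq=50),  # < stations
            dict(n_dams_dpq=20),  # one dam per station required
            dict(years=0),
        ],
    )
    def test_inconsistent_sizes_rejected(self, bad):
        with pytest.raises(InfeasibleConfigError):
            BreedingConfig(**bad)


class TestSelection:
    def test_top_sets_are_nested(self):
        crit = pd.Series(
            np.arange(30)[::-1], index=[f"q{i:02d}" for i in range(30)]
        )
        bq, dpq = select_parents_cbs(crit, 10, 4)
        assert len(bq) == 10 and len(dpq) == 4
        assert set(dpq) <= set(bq)

    def test_ties_break_by_ascending_id(self):
        crit = pd.Series([1.0] * 6, index=["f", "d", "b", "a", "c", "e"])
        bq, dpq = select_parents_cbs(crit, 3, 2)
        assert bq == ["a", "b", "c"]
        assert dpq == ["a", "b"]

    def test_zero_request_gives_empty_sets(self):
        crit = pd.Series([2.0, 1.0], index=["a", "b"])
        assert select_parents_cbs(crit, 0, 0) == ([], [])

    def test_too_few_candidates_rejected(self):
        crit = pd.Series([1.0], index=["a"])
        with pytest.raises(InfeasibleSelectionError):
            select_parents_cbs(crit, 2, 1)


class TestPhenotype:
    def test_no_residual_no_year_effect_is_exact(self):
        rng = np.random.default_rng(0)
        y = phenotype_colony(1.25, -0.5, 0.0, 0.0, rng)
        assert y == pytest.approx(0.75)

    def test_residual_mean_is_zero(self):
        rng = np.random.default_rng(1)
        n = 100_000
        draws = np.array(
            [phenotype_colony(0.0, 0.0, 0.0, 1.0, rng) for _ in range(n)]
        )
        assert abs(draws.mean()) < 3 / np.sqrt(n)

    def test_year_effect_shifts_phenotype(self):
        rng = np.random.default_rng(2)
        assert phenotype_colony(0.0, 0.0, 4.0, 0.0, rng) == pytest.approx(4.0)


class TestProgramStructure:
    def test_pedigree_counts_match_design(self, small_history):
        cfg = small_history.config
        pf = small_history.pseudofathers
        # recorded stations: deployment years 3..9
        assert len(pf) == cfg.n_stations * (cfg.years - cfg.station_recording_start)
        dpq = small_history.queens[small_history.queens.kind == "DPQ"]
        assert len(dpq) == len(pf) * cfg.n_dpq_per_station
        bq = small_history.queens[small_history.queens.kind == "BQ"]
        assert len(bq) == cfg.years * cfg.n_bq_per_year
        assert len(small_history.worker_groups) == len(bq)

    def test_sister_bq_share_their_mating_station(self, small_history):
        q = small_history.queens
        bq = q[(q.kind == "BQ") & q.dam_id.notna()]
        per_dam = bq.groupby("dam_id").station_mated.nunique(dropna=False)
        assert (per_dam == 1).all()

    def test_pedigree_sire_is_pseudofather_never_dpq(self, small_history):
        ped = small_history.pedigree()
        kinds = {e.id: e.kind for e in ped.entries}
        for e in ped.entries:
            if e.sire is not None:
                assert kinds[e.sire] == "pseudofather"

    def test_last_year_colonies_unphenotyped(self, small_history):
        w = small_history.worker_groups
        last = small_history.config.years - 1
        assert w.loc[w.year == last, "phenotype"].isna().all()
        assert w.loc[w.year < last, "phenotype"].notna().all()

    def test_dpq_station_membership_is_sisters(self, small_history):
        q = small_history.queens
        dpq = q[q.kind == "DPQ"]
        dams_per_station = dpq.groupby("station_of").dam_id.nunique()
        assert (dams_per_station == 1).all()

    def test_no_selection_no_trend(self, small_panel):
        # with random dam choice the cohort-mean TBV performs a random walk
        # with zero drift: the mean trend over replicates vanishes
        cfg = BreedingConfig(
            years=6, n_bq_per_year=24, n_stations=4, n_dpq_per_station=3,
            n_dams_bq=8, n_dams_dpq=4, n_drones_per_queen=6, n_workers=10,
        )
        rng = np.random.default_rng(11)
        trends = []
        for _ in range(20):
            qtl = assign_qtl_effects(small_panel, 60, MOD.V_a, seed=rng)
            hist = run_breeding_program(
                cfg, small_panel, qtl, MOD, seed=rng, selection="random"
            )
            t0 = hist.tbv_of(hist.queen_ids(0)).sum(axis=1).mean()
            t5 = hist.tbv_of(hist.queen_ids(5)).sum(axis=1).mean()
            trends.append(t5 - t0)
        trends = np.array(trends)
        se = trends.std(ddof=1) / np.sqrt(len(trends))
        assert abs(trends.mean()) < 3 * se


class TestGenotypedSets:
    def test_full_proportion_counts(self, small_history):
        cfg = small_history.config
        sets = sample_genotyped_sets(small_history, 1.0, include_dpq=True, seed=0)
        # BQ of years 4..9 at the scaled size
        assert len(sets["bq"]) == 6 * cfg.n_bq_per_year
        # all DPQ deployed in years 4..9
        assert len(sets["dpq"]) == 6 * cfg.n_stations * cfg.n_dpq_per_station
        assert len(sets["pf"]) == 6 * cfg.n_stations

    def test_small_proportion_counts(self, small_history):
        cfg = small_history.config
        sets = sample_genotyped_sets(small_history, 0.1, seed=1)
        per_year = int(round(0.1 * cfg.n_bq_per_year))
        assert len(sets["bq"]) == 6 * per_year
        assert sets["pf"] == []

    def test_sampling_without_replacement(self, small_history):
        sets = sample_genotyped_sets(small_history, 0.5, seed=2)
        assert len(sets["bq"]) == len(set(sets["bq"]))

    @pytest.mark.parametrize("p", [0.0, -0.2, 1.5])
    def test_invalid_proportion_rejected(self, small_history, p):
        with pytest.raises(InvalidProportionError):
            sample_genotyped_sets(small_history, p)


class TestBaseCalibration:
    def test_base_cohort_queen_variance(self, small_panel):
        # realized TBV variance of year-0 queens matches sigma_Q2 = 2 (MOD)
        tp = derive_trait_parameters(MOD)
        cfg = BreedingConfig(
            years=1, n_bq_per_year=100, n_stations=10, n_dpq_per_station=4,
            n_dams_bq=20, n_dams_dpq=10, n_drones_per_queen=12, n_workers=5,
        )
        rng = np.random.default_rng(21)
        vs = []
        for _ in range(12):
            qtl = assign_qtl_effects(small_panel, 60, MOD.V_a, seed=rng)
            hist = run_breeding_program(cfg, small_panel, qtl, MOD, seed=rng)
            vs.append(hist.tbv_of(hist.queen_ids(0)).sum(axis=1).var(ddof=1))
        vs = np.array(vs)
        se = vs.std(ddof=1) / np.sqrt(len(vs))
        assert abs(vs.mean() - tp.sigma_Q2) < 3 * se
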