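"""Stochastic simulation of a closed honey-bee breeding population.

The default program mirrors classic colony-based selection (CBS) with
controlled mating: 1000 breeding queens (BQ) per year are reared, mated
on 50 isolated mating stations each hosting eight sister drone-producing
queens (DPQ), and phenotyped one year later.  Every queen mates with 12
drones whose dams are sampled uniformly from the station's DPQ.  From
year 2 (BQ) and year 3 (DPQ) onwards, the top 200 two-year-old BQ —
ranked by the pedigree-BLUP EBV sum (direct + maternal) of their worker
group — become dams of BQ with five daughters each, and the top 50
become dams of DPQ with eight daughters each; the eight sister DPQ of
one dam form a next-year mating station, recorded in the pedigree as a
pseudo-father.  Stations of the first years host unrelated base DPQ and
are not recorded.

A colony phenotype is ``y = mean(a_W) + m_Q + year_effect + e`` where
``mean(a_W)`` is the mean direct true breeding value of ``n_W``
individually simulated workers and ``m_Q`` the queen's maternal TBV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeSpec, HaplotypePanel, QTLEffects, _batch_gametes
from .relationship import (
    PSEUDOFATHER,
    QUEEN,
    WORKER_GROUP,
    Pedigree,
    PedigreeEntry,
)
from .trait_model import TraitBase

__all__ = [
    "BreedingConfig",
    "PopulationHistory",
    "run_breeding_program",
    "phenotype_colony",
    "select_parents_cbs",
    "sample_genotyped_sets",
]


class InfeasibleConfigError(ValueError):
    pass


class InfeasibleSelectionError(ValueError):
    pass


class InvalidProportionError(ValueError):
    pass


@dataclass(frozen=True)
class BreedingConfig:
    """Sizes and timing of the breeding program.

    The defaults reproduce the reference program: 1000 BQ on 50 stations
    of 8 DPQ, 200/50 selected dams, 12 drones per queen.  ``n_workers``
    is the number of individually simulated workers per colony; the
    relationship model treats worker groups in the infinite-size limit.
    """

    years: int = 10
    n_bq_per_year: int = 1000
    n_stations: int = 50
    n_dpq_per_station: int = 8
    n_dams_bq: int = 200
    n_dams_dpq: int = 50
    n_drones_per_queen: int = 12
    n_workers: int = 100
    bq_selection_start: int = 2
    dpq_selection_start: int = 3
    station_recording_start: int = 3  # first deployment year in the pedigree
    year_effects: tuple[float, ...] | float = 0.0

    def __post_init__(self) -> None:
        if min(self.years, self.n_bq_per_year, self.n_stations) < 1:
            raise InfeasibleConfigError("population sizes must be positive")
        if self.n_bq_per_year % self.n_dams_bq:
            raise InfeasibleConfigError("n_dams_bq must divide n_bq_per_year")
        if self.n_dams_bq % self.n_stations:
            raise InfeasibleConfigError(
                "sib groups must spread evenly over stations"
            )
        if self.n_dams_dpq > self.n_dams_bq:
            raise InfeasibleConfigError("dams of DPQ are a subset of dams of BQ")
        if self.n_dams_dpq != self.n_stations:
            raise InfeasibleConfigError("one dam of DPQ per mating station")

    @property
    def daughters_per_dam_bq(self) -> int:
        return self.n_bq_per_year // self.n_dams_bq

    def year_effect(self, year: int) -> float:
        if isinstance(self.year_effects, tuple):
            return self.year_effects[year] if year < len(self.year_effects) else 0.0
        return float(self.year_effects)


@dataclass
class PopulationHistory:
    """Complete record of one simulated breeding population."""

    config: BreedingConfig
    spec: GenomeSpec
    qtl: QTLEffects
    queens: pd.DataFrame = field(default_factory=pd.DataFrame)
    worker_groups: pd.DataFrame = field(default_factory=pd.DataFrame)
    pseudofathers: pd.DataFrame = field(default_factory=pd.DataFrame)
    genomes: dict[str, np.ndarray] = field(default_factory=dict)

    def queen_ids(self, year: int, kind: str = "BQ") -> list[str]:
        q = self.queens
        return list(q.loc[(q.birth_year == year) & (q.kind == kind), "id"])

    def wg_ids(self, year: int) -> list[str]:
        w = self.worker_groups
        return list(w.loc[w.year == year, "id"])

    def tbv_of(self, ids: list[str]) -> np.ndarray:
        """(n, 2) true breeding values (direct, maternal) of queens/groups."""
        lookup = pd.concat(
            [
                self.queens.set_index("id")[["tbv_a", "tbv_m"]],
                self.worker_groups.set_index("id")[["tbv_a", "tbv_m"]],
            ]
        )
        return lookup.loc[list(ids)].to_numpy(float)

    def pedigree(self, upto_year: int | None = None) -> Pedigree:
        """Recorded pedigree of BQ, pseudo-fathers and worker groups.

        Individual DPQ appear only through their pseudo-father; stations
        deployed before ``station_recording_start`` are unrecorded, so
        queens mated there have an unknown (base) sire.
        """
        cfg = self.config
        last = cfg.years - 1 if upto_year is None else upto_year
        ped = Pedigree()
        common = dict(
            n_drones=cfg.n_drones_per_queen,
            n_sire_members=cfg.n_dpq_per_station,
        )
        for year in range(last + 1):
            # a pseudo-father enters the pedigree in the year its member
            # DPQ are born (one year before deployment): entities sharing
            # a mating must precede any of the mating's descendants for
            # the shared-spermatheca terms to propagate correctly
            pf = self.pseudofathers
            for row in pf.loc[pf.year == year + 1].itertuples(index=False):
                ped.add(
                    PedigreeEntry(
                        id=row.id,
                        kind=PSEUDOFATHER,
                        dam=_opt(row.dam_id),
                        sire=_opt(row.sire_id),
                        year=year,
                        n_members=cfg.n_dpq_per_station,
                        **common,
                    )
                )
            q = self.queens
            for row in q.loc[
                (q.birth_year == year) & (q.kind == "BQ")
            ].itertuples(index=False):
                ped.add(
                    PedigreeEntry(
                        id=row.id,
                        kind=QUEEN,
                        dam=_opt(row.dam_id),
                        sire=_opt(row.sire_id),
                        year=year,
                        **common,
                    )
                )
            w = self.worker_groups
            for row in w.loc[w.year == year].itertuples(index=False):
                ped.add(
                    PedigreeEntry(
                        id=row.id,
                        kind=WORKER_GROUP,
                        dam=row.queen_id,
                        sire=_opt(row.station_id),
                        year=year,
                        **common,
                    )
                )
        return ped

    def phenotype_frame(self, upto_year: int | None = None) -> pd.DataFrame:
        """Phenotyped colonies established through ``upto_year``."""
        w = self.worker_groups
        out = w.loc[w.phenotype.notna()]
        if upto_year is not None:
            out = out.loc[out.year <= upto_year]
        return out[["id", "queen_id", "year", "phenotype"]].reset_index(drop=True)

    def genotype_dosage(self, ids: list[str]) -> np.ndarray:
        """0/1/2 dosage rows at all panel loci for the given queens."""
        return np.stack(
            [self.genomes[i].sum(axis=0, dtype=np.int16) for i in ids]
        ).astype(np.int8)

    def pf_members(self, pf_id: str) -> list[str]:
        q = self.queens
        return list(q.loc[q.station_of == pf_id, "id"])


def _opt(value) -> str | None:
    return None if value is None or (isinstance(value, float) and np.isnan(value)) else value


def phenotype_colony(
    tbv_a_mean: float,
    queen_tbv_m: float,
    year_effect: float,
    sigma_e2: float,
    rng: np.random.Generator,
) -> float:
    """Colony phenotype ``y = mean(a_W) + m_Q + year_effect + e``."""
    e = rng.normal(0.0, np.sqrt(sigma_e2)) if sigma_e2 > 0 else 0.0
    return float(tbv_a_mean + queen_tbv_m + year_effect + e)


def select_parents_cbs(
    criterion: pd.Series, n_dams_bq: int, n_dams_dpq: int
) -> tuple[list[str], list[str]]:
    """Truncation selection on the worker-group EBV sum.

    ``criterion`` is indexed by candidate queen id.  Returns the top
    ``n_dams_bq`` ids (dams of BQ) and top ``n_dams_dpq`` ids (dams of
    DPQ, a subset of the former when requested counts are nested).  Ties
    break deterministically by ascending id.
    """
    if n_dams_bq > len(criterion) or n_dams_dpq > len(criterion):
        raise InfeasibleSelectionError(
            f"{len(criterion)} candidates for {n_dams_bq}/{n_dams_dpq} dams"
        )
    ranked = criterion.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:n_dams_bq]), list(ranked.index[:n_dams_dpq])


def sample_genotyped_sets(
    history: PopulationHistory,
    p_ref: float,
    include_dpq: bool = False,
    seed: int | np.random.Generator | None = 0,
    bq_years: tuple[int, int] = (4, 7),
    extra_years: tuple[int, ...] = (8, 9),
    dpq_deploy_years: tuple[int, int] = (4, 9),
) -> dict[str, list[str]]:
    """Randomly choose queens for genotyping, stratified by year.

    A proportion ``p_ref`` of the BQ of each year in ``bq_years`` is
    sampled, and separately ``p_ref`` of the queens of each year in
    ``extra_years``.  With ``include_dpq`` every pseudo-father deployed
    in ``dpq_deploy_years`` contributes all its member DPQ.
    """
    if not 0.0 < p_ref <= 1.0:
        raise InvalidProportionError("p_ref must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bq: list[str] = []
    years = list(range(bq_years[0], bq_years[1] + 1)) + list(extra_years)
    for year in years:
        cohort = sorted(history.queen_ids(year, "BQ"))
        k = int(round(p_ref * len(cohort)))
        take = rng.choice(len(cohort), size=k, replace=False)
        bq.extend(cohort[i] for i in sorted(take))
    out = {"bq": bq, "pf": [], "dpq": []}
    if include_dpq:
        pf = history.pseudofathers
        lo, hi = dpq_deploy_years
        pf_ids = sorted(pf.loc[(pf.year >= lo) & (pf.year <= hi), "id"])
        out["pf"] = pf_ids
        for pid in pf_ids:
            out["dpq"].extend(sorted(history.pf_members(pid)))
    return out


class _Simulator:
    def __init__(
        self,
        config: BreedingConfig,
        panel: HaplotypePanel,
        qtl: QTLEffects,
        trait: TraitBase,
        rng: np.random.Generator,
        selection: str = "pblup",
    ):
        if qtl.qtl_indices.max() >= panel.spec.n_loci:
            raise InfeasibleConfigError("QTL indices outside the panel")
        self.cfg = config
        self.panel = panel
        self.spec = panel.spec
        self.qtl = qtl
        self.trait = trait
        self.rng = rng
        self.selection = selection  # "pblup" | "random"
        self.qtl_spec = self.spec.subset(qtl.qtl_indices)
        self.history = PopulationHistory(config=config, spec=self.spec, qtl=qtl)
        self.rows: dict[str, dict] = {}  # queen id -> record
        self.wg_rows: list[dict] = []
        self.pf_rows: list[dict] = []
        self._sperm: dict[str, np.ndarray] = {}  # queen id -> (n_drones, L)
        self._station_members: dict[str, list] = {}  # station id -> genomes/ids

    # -- genetics ----------------------------------------------------------
    def _panel_child(self) -> np.ndarray:
        g = self.panel.queen_genomes()
        i, j = self.rng.integers(0, self.panel.n_queens, size=2)
        return np.stack(
            [
                _batch_gametes(g[i], self.spec, self.rng, 1)[0],
                _batch_gametes(g[j], self.spec, self.rng, 1)[0],
            ]
        )

    def _tbv(self, genome: np.ndarray) -> np.ndarray:
        dosage = genome.sum(axis=0, dtype=np.int16)[self.qtl.qtl_indices]
        return self.qtl.tbv(dosage[None, :].astype(float))[0]

    def _add_queen(
        self, qid: str, kind: str, year: int, genome: np.ndarray,
        dam: str | None, sire: str | None,
    ) -> None:
        tbv = self._tbv(genome)
        self.history.genomes[qid] = genome
        self.rows[qid] = dict(
            id=qid, kind=kind, birth_year=year, dam_id=dam, sire_id=sire,
            station_mated=None, station_of=None, tbv_a=tbv[0], tbv_m=tbv[1],
        )

    def _mate(self, queen_id: str, station_id: str, recorded: bool) -> None:
        members = self._station_members[station_id]
        n_dr = self.cfg.n_drones_per_queen
        drones = np.empty((n_dr, self.spec.n_loci), dtype=np.uint8)
        for k in range(n_dr):
            member = members[self.rng.integers(0, len(members))]
            genome = self.history.genomes[member] if isinstance(member, str) else member
            drones[k] = _batch_gametes(genome, self.spec, self.rng, 1)[0]
        self._sperm[queen_id] = drones
        self.rows[queen_id]["station_mated"] = station_id if recorded else None

    def _daughter(self, dam_id: str) -> tuple[np.ndarray, str | None]:
        maternal = _batch_gametes(
            self.history.genomes[dam_id], self.spec, self.rng, 1
        )[0]
        sperm = self._sperm[dam_id]
        paternal = sperm[self.rng.integers(0, sperm.shape[0])]
        return np.stack([maternal, paternal]), self.rows[dam_id]["station_mated"]

    def _worker_group_tbv(self, queen_id: str) -> tuple[float, float]:
        n_w = self.cfg.n_workers
        qtl_idx = self.qtl.qtl_indices
        queen_qtl = self.history.genomes[queen_id][:, qtl_idx]
        maternal = _batch_gametes(queen_qtl, self.qtl_spec, self.rng, n_w)
        sperm_qtl = self._sperm[queen_id][:, qtl_idx]
        paternal = sperm_qtl[self.rng.integers(0, sperm_qtl.shape[0], size=n_w)]
        dosage = maternal.astype(np.int16) + paternal
        mean = self.qtl.tbv(dosage.astype(float)).mean(axis=0)
        return float(mean[0]), float(mean[1])

    # -- selection ---------------------------------------------------------
    def _flush(self) -> PopulationHistory:
        h = self.history
        h.queens = pd.DataFrame(
            list(self.rows.values()),
            columns=[
                "id", "kind", "birth_year", "dam_id", "sire_id",
                "station_mated", "station_of", "tbv_a", "tbv_m",
            ],
        )
        h.worker_groups = pd.DataFrame(
            self.wg_rows,
            columns=[
                "id", "queen_id", "station_id", "year",
                "tbv_a", "tbv_m", "phenotype", "n_workers",
            ],
        )
        h.pseudofathers = pd.DataFrame(
            self.pf_rows, columns=["id", "year", "dam_id", "sire_id"]
        )
        return h

    def _pblup_criterion(self, year: int, candidates: list[str]) -> pd.Series:
        from .genomic import run_analysis

        ebv = run_analysis(
            self._flush(), mode="PBLUP", trait=self.trait, upto_year=year - 1
        ).set_index("id")
        wg = self.history.worker_groups.set_index("queen_id")
        wg_ids = wg.loc[candidates, "id"]
        return pd.Series(
            ebv.loc[wg_ids, "ebv_sum"].to_numpy(), index=candidates
        )

    def _select_dams(self, year: int) -> tuple[list[str], list[str]]:
        cfg = self.cfg
        cand_year = max(year - 2, 0)
        cand = sorted(
            qid
            for qid, r in self.rows.items()
            if r["birth_year"] == cand_year and r["kind"] == "BQ"
        )
        truncate = self.selection == "pblup" and year >= cfg.bq_selection_start
        if not truncate:
            chosen = [cand[i] for i in self.rng.permutation(len(cand))]
            return chosen[: cfg.n_dams_bq], chosen[: cfg.n_dams_dpq]
        crit = self._pblup_criterion(year, cand)
        dams_bq, dams_dpq = select_parents_cbs(crit, cfg.n_dams_bq, cfg.n_dams_dpq)
        if year < cfg.dpq_selection_start:
            chosen = [cand[i] for i in self.rng.permutation(len(cand))]
            dams_dpq = chosen[: cfg.n_dams_dpq]
        return dams_bq, dams_dpq

    # -- main loop -----------------------------------------------------------
    def run(self) -> PopulationHistory:
        cfg = self.cfg
        dpq_next: dict[str, list[str]] = {}
        for year in range(cfg.years):
            stations = self._make_stations(year, dpq_next)
            dpq_next = {}

            if year == 0:
                new_bq = [
                    (self._spawn_base_bq(year, i), i // cfg.daughters_per_dam_bq)
                    for i in range(cfg.n_bq_per_year)
                ]
            else:
                dams_bq, dams_dpq = self._select_dams(year)
                new_bq = []
                for gi, dam in enumerate(dams_bq):
                    for j in range(cfg.daughters_per_dam_bq):
                        qid = f"Q{year}_{gi * cfg.daughters_per_dam_bq + j}"
                        genome, sire = self._daughter(dam)
                        self._add_queen(qid, "BQ", year, genome, dam, sire)
                        new_bq.append((qid, gi))
                if cfg.station_recording_start - 1 <= year <= cfg.years - 2:
                    for dam in dams_dpq:
                        members = []
                        for j in range(cfg.n_dpq_per_station):
                            did = f"D{year}_{dam}_{j}"
                            genome, sire = self._daughter(dam)
                            self._add_queen(did, "DPQ", year, genome, dam, sire)
                            members.append(did)
                        dpq_next[dam] = members

            self._mate_and_establish(year, new_bq, stations)
        return self._flush()

    def _spawn_base_bq(self, year: int, i: int) -> str:
        qid = f"Q{year}_{i}"
        self._add_queen(qid, "BQ", year, self._panel_child(), None, None)
        return qid

    def _make_stations(self, year: int, dpq_by_dam: dict[str, list[str]]) -> list[str]:
        cfg = self.cfg
        ids: list[str] = []
        if year < cfg.station_recording_start:
            for j in range(cfg.n_stations):
                sid = f"S{year}_{j}"
                self._station_members[sid] = [
                    self._panel_child() for _ in range(cfg.n_dpq_per_station)
                ]
                ids.append(sid)
        else:
            if len(dpq_by_dam) != cfg.n_stations:
                raise InfeasibleConfigError(
                    f"year {year}: {len(dpq_by_dam)} DPQ sib groups "
                    f"for {cfg.n_stations} stations"
                )
            for j, (dam, members) in enumerate(sorted(dpq_by_dam.items())):
                sid = f"S{year}_{j}"
                self.pf_rows.append(
                    dict(
                        id=sid,
                        year=year,
                        dam_id=dam,
                        sire_id=self.rows[dam]["station_mated"],
                    )
                )
                self._station_members[sid] = members
                for m in members:
                    self.rows[m]["station_of"] = sid
                ids.append(sid)
        return ids

    def _mate_and_establish(
        self, year: int, new_bq: list[tuple[str, int]], stations: list[str]
    ) -> None:
        cfg = self.cfg
        recorded = year >= cfg.station_recording_start
        group_station = self.rng.permutation(
            np.repeat(np.arange(cfg.n_stations), cfg.n_dams_bq // cfg.n_stations)
        )
        for qid, gi in new_bq:
            sid = stations[group_station[gi]]
            self._mate(qid, sid, recorded)
            a_w, m_w = self._worker_group_tbv(qid)
            phen = np.nan
            if year <= cfg.years - 2:
                phen = phenotype_colony(
                    a_w,
                    self.rows[qid]["tbv_m"],
                    cfg.year_effect(year),
                    self.trait.sigma_e2,
                    self.rng,
                )
            self.wg_rows.append(
                dict(
                    id=f"W{qid}",
                    queen_id=qid,
                    station_id=sid if recorded else None,
                    year=year,
                    tbv_a=a_w,
                    tbv_m=m_w,
                    phenotype=phen,
                    n_workers=cfg.n_workers,
                )
            )


def run_breeding_program(
    config: BreedingConfig,
    panel: HaplotypePanel,
    qtl: QTLEffects,
    trait: TraitBase,
    seed: int | np.random.Generator | None = 0,
    selection: str = "pblup",
) -> PopulationHistory:
    """Simulate the breeding population over ``config.years`` years.

    ``selection`` is ``"pblup"`` for colony-based truncation selection on
    pedigree-BLUP worker-group EBV sums (the default program) or
    ``"random"`` to disable selection (drift control).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _Simulator(config, panel, qtl, trait, rng, selection=selection).run()
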