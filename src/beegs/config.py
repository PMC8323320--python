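"""Run configuration and deterministic test fixtures.

A run configuration bundles the genome, trait, population, evaluation
and scheme sections of a full workbench run.  The ``desk`` scale preset
is a reduced population for interactive work and testing; the ``paper``
scale preset carries the full-size study conditions (1000 BQ/year over
10 years on a ~48k-SNP panel bred through 20,000 historical years) and
is only practical on long batch runs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .trait_model import PRESETS, TraitBase

__all__ = ["RunConfig", "generate_fixture"]


@dataclass
class RunConfig:
    seed: int = 1
    scale: str = "desk"
    genome: dict = field(default_factory=dict)
    trait: str | dict = "MOD"
    population: dict = field(default_factory=dict)
    evaluation: dict = field(default_factory=dict)
    scheme: dict = field(default_factory=dict)

    DESK = dict(
        genome=dict(
            n_loci=2000,
            n_chromosomes=16,
            total_length_mb=220.0,
            recombination_rate=19.0,
            mutation_rate=0.0005,
            historical_queens=30,
            historical_years=300,
            expansion_size=120,
            expansion_years=6,
            maf_threshold=0.05,
            n_qtl=200,
        ),
        population=dict(
            years=10,
            n_bq_per_year=100,
            n_stations=10,
            n_dpq_per_station=4,
            n_dams_bq=20,
            n_dams_dpq=10,
            n_drones_per_queen=12,
            n_workers=50,
        ),
        evaluation=dict(
            p_ref_grid=[0.05, 0.1, 0.2, 0.3, 0.5, 1.0],
            modes=["PBLUP", "ssGBLUP_BQ", "ssGBLUP_DPQ+BQ"],
            replicates=3,
        ),
        scheme=dict(budgets=list(range(0, 4001, 500))),
    )

    PAPER = dict(
        genome=dict(
            n_loci=100_000,
            n_chromosomes=16,
            total_length_mb=220.0,
            recombination_rate=19.0,
            mutation_rate=0.0005,
            historical_queens=50,
            historical_years=20_000,
            expansion_size=2400,
            expansion_years=6,
            maf_threshold=0.05,
            n_qtl=1000,
        ),
        population=dict(
            years=10,
            n_bq_per_year=1000,
            n_stations=50,
            n_dpq_per_station=8,
            n_dams_bq=200,
            n_dams_dpq=50,
            n_drones_per_queen=12,
            n_workers=100,
        ),
        evaluation=dict(
            p_ref_grid=[0.05, 0.1, 0.2, 0.3, 0.5, 1.0],
            modes=["PBLUP", "ssGBLUP_BQ", "ssGBLUP_DPQ+BQ"],
            replicates=100,
        ),
        scheme=dict(budgets=list(range(0, 4001, 500))),
    )

    def __post_init__(self) -> None:
        preset = self.PAPER if self.scale == "paper" else self.DESK
        for section in ("genome", "population", "evaluation", "scheme"):
            merged = dict(preset[section])
            merged.update(getattr(self, section) or {})
            setattr(self, section, merged)

    @property
    def trait_base(self) -> TraitBase:
        if isinstance(self.trait, str):
            try:
                return PRESETS[self.trait]
            except KeyError:
                raise ValueError(f"unknown trait preset {self.trait!r}") from None
        return TraitBase(**self.trait)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Deterministic fixtures


def _anchor_pedigree():
    from .relationship import Pedigree, PedigreeEntry

    ped = Pedigree()
    ped.add(PedigreeEntry("station0", "pseudofather", n_members=8))
    ped.add(PedigreeEntry("dam", "queen"))
    ped.add(PedigreeEntry("daughter", "queen", dam="dam", sire="station0"))
    ped.add(PedigreeEntry("workers", "worker_group", dam="dam", sire="station0"))
    ped.add(PedigreeEntry("pseudofather", "pseudofather", dam="dam", sire="station0"))
    ped.add(PedigreeEntry("unrelated_dam", "queen"))
    ped.add(
        PedigreeEntry(
            "station_daughter", "queen", dam="unrelated_dam", sire="pseudofather"
        )
    )
    anchors = {
        "dam_daughter": ("dam", "daughter"),
        "worker_worker": ("workers", "workers"),
        "daughter_pseudofather": ("station_daughter", "pseudofather"),
    }
    return ped, anchors


def _small_history(seed: int, **overrides):
    from .breeding import BreedingConfig, run_breeding_program
    from .genome import (
        GenomeSpec,
        assign_qtl_effects,
        filter_loci_by_maf,
        simulate_historical_panel,
    )
    from .trait_model import MOD

    rng = np.random.default_rng(seed)
    spec = GenomeSpec.uniform(n_loci=240, n_chromosomes=8)
    panel = simulate_historical_panel(spec, 12, 40, seed=rng)
    panel, _ = filter_loci_by_maf(panel, 0.05)
    qtl = assign_qtl_effects(panel, 30, MOD.V_a, seed=rng)
    cfg = BreedingConfig(
        years=overrides.pop("years", 5),
        n_bq_per_year=overrides.pop("n_bq_per_year", 12),
        n_stations=overrides.pop("n_stations", 3),
        n_dpq_per_station=overrides.pop("n_dpq_per_station", 3),
        n_dams_bq=overrides.pop("n_dams_bq", 3),
        n_dams_dpq=overrides.pop("n_dams_dpq", 3),
        n_drones_per_queen=overrides.pop("n_drones_per_queen", 6),
        n_workers=overrides.pop("n_workers", 20),
        **overrides,
    )
    return run_breeding_program(cfg, panel, qtl, MOD, seed=rng)


def generate_fixture(kind: str, seed: int = 0):
    """Deterministic miniature fixtures for tests and examples.

    ``pedigree-anchors``
        The three printed relationship configurations (dam-daughter,
        worker pair, daughter-pseudofather); returns ``(Pedigree,
        anchors)`` where anchors maps names to id pairs.
    ``mme-small``
        A small solvable population (tens of entities) with phenotypes,
        suitable for comparing the mixed-model solver to a GLS oracle;
        returns a :class:`~beegs.breeding.PopulationHistory`.
    ``grm-toy``
        The 3-queen single-locus genotype panel (0, 1, 2); returns a
        :class:`~beegs.genomic.GenotypeMatrix`.
    """
    if kind == "pedigree-anchors":
        return _anchor_pedigree()
    if kind == "mme-small":
        return _small_history(seed)
    if kind == "grm-toy":
        from .genomic import GenotypeMatrix

        return GenotypeMatrix(
            ids=["q1", "q2", "q3"], M=np.array([[0.0], [1.0], [2.0]])
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
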