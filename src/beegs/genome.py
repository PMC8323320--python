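"""Genome simulation: historical LD build-up, meiosis, MAF filter, QTL effects.

The simulated genome is a set of biallelic SNP loci on ``n_chromosomes``
chromosomes with physical positions in Mb and a uniform recombination
rate in cM/Mb.  Crossovers follow a Haldane (no-interference) model: per
meiosis and chromosome the crossover count is Poisson with mean equal to
the genetic length in Morgans and crossover positions are uniform.

Linkage disequilibrium is built by drifting a small closed population of
queens for many non-overlapping generations under honey-bee mating rules
(every queen mates 12 drones; a drone is a gamete of a uniformly chosen
queen of the parent generation), followed by an optional expansion phase
and a minor-allele-frequency filter.

QTL effects are bivariate (direct, maternal) draws from the mixture
``0.95 * Laplace(0, V_a) + 0.05 * Normal(0, V_a)`` and are subsequently
adjusted (centered and linearly transformed) so that the base-population
mean true breeding value is exactly (0, 0) and the empirical TBV
covariance is exactly ``V_a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeSpec",
    "HaplotypePanel",
    "QTLEffects",
    "simulate_historical_panel",
    "filter_loci_by_maf",
    "meiosis",
    "assign_qtl_effects",
]


class InvalidConfigError(ValueError):
    pass


class EmptyPanelError(ValueError):
    pass


class SingularAdjustmentError(ValueError):
    pass


@dataclass(frozen=True)
class GenomeSpec:
    """Physical and genetic layout of the simulated genome.

    ``positions`` are physical locus positions in Mb, strictly increasing
    within a chromosome; ``chrom`` maps each locus to its chromosome;
    ``chromosome_lengths`` are physical lengths in Mb.
    """

    chromosome_lengths: np.ndarray
    positions: np.ndarray
    chrom: np.ndarray
    recombination_rate: float = 19.0  # cM/Mb
    mutation_rate: float = 0.0005  # per locus per transmission

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "chromosome_lengths", np.asarray(self.chromosome_lengths, float)
        )
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        object.__setattr__(self, "chrom", np.asarray(self.chrom, np.intp))
        if self.n_loci == 0:
            raise InvalidConfigError("genome must contain at least one locus")
        if np.any(self.chromosome_lengths <= 0):
            raise InvalidConfigError("chromosome lengths must be positive")
        for c in range(self.n_chromosomes):
            pos = self.positions[self.chrom == c]
            if pos.size and np.any(np.diff(pos) <= 0):
                raise InvalidConfigError(
                    f"positions must be strictly increasing on chromosome {c}"
                )

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosome_lengths)

    @property
    def n_loci(self) -> int:
        return len(self.positions)

    @property
    def genetic_lengths(self) -> np.ndarray:
        """Per-chromosome genetic length in Morgans."""
        return self.chromosome_lengths * self.recombination_rate / 100.0

    @classmethod
    def uniform(
        cls,
        n_loci: int,
        n_chromosomes: int = 16,
        total_length_mb: float = 220.0,
        recombination_rate: float = 19.0,
        mutation_rate: float = 0.0005,
    ) -> "GenomeSpec":
        """Evenly spaced loci on equally sized chromosomes."""
        if n_loci < n_chromosomes:
            n_chromosomes = max(1, min(n_chromosomes, n_loci))
        lengths = np.full(n_chromosomes, total_length_mb / n_chromosomes)
        per = np.full(n_chromosomes, n_loci // n_chromosomes)
        per[: n_loci % n_chromosomes] += 1
        chrom = np.repeat(np.arange(n_chromosomes), per)
        positions = np.concatenate(
            [
                np.linspace(0.0, lengths[c], per[c] + 2)[1:-1]
                for c in range(n_chromosomes)
            ]
        )
        return cls(
            chromosome_lengths=lengths,
            positions=positions,
            chrom=chrom,
            recombination_rate=recombination_rate,
            mutation_rate=mutation_rate,
        )

    def subset(self, keep: np.ndarray) -> "GenomeSpec":
        """New spec restricted to the given locus indices (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        if keep.size == 0:
            raise EmptyPanelError("no loci retained")
        return GenomeSpec(
            chromosome_lengths=self.chromosome_lengths,
            positions=self.positions[keep],
            chrom=self.chrom[keep],
            recombination_rate=self.recombination_rate,
            mutation_rate=self.mutation_rate,
        )


@dataclass
class HaplotypePanel:
    """Binary haplotypes of a set of diploid queens (two rows per queen)."""

    spec: GenomeSpec
    haplotypes: np.ndarray  # (2 * n_queens, n_loci) uint8
    generation_label: str = ""

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.ndim != 2 or self.haplotypes.shape[0] % 2:
            raise InvalidConfigError("haplotypes must be (2*n_queens, n_loci)")
        if self.haplotypes.shape[1] != self.spec.n_loci:
            raise InvalidConfigError("haplotype width must match the genome spec")

    @property
    def n_queens(self) -> int:
        return self.haplotypes.shape[0] // 2

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=0)

    def queen_genomes(self) -> np.ndarray:
        """(n_queens, 2, n_loci) view of the diploid genomes."""
        return self.haplotypes.reshape(self.n_queens, 2, -1)

    def genotype_matrix(self) -> np.ndarray:
        """0/1/2 allele counts, one row per queen."""
        g = self.queen_genomes()
        return (g[:, 0, :].astype(np.int16) + g[:, 1, :]).astype(np.int8)

    def genotype_frame(self) -> pd.DataFrame:
        """Plain-text genotype export (locus columns, queen id index)."""
        cols = [f"L{i + 1}" for i in range(self.spec.n_loci)]
        ids = [f"Q{i + 1}" for i in range(self.n_queens)]
        return pd.DataFrame(self.genotype_matrix(), index=ids, columns=cols)


def _batch_gametes(
    parent: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
    n: int,
) -> np.ndarray:
    """n gametes of one diploid parent, shape (n, n_loci)."""
    parent = np.asarray(parent)
    out = np.empty((n, spec.n_loci), dtype=np.uint8)
    lengths = spec.chromosome_lengths
    lam = spec.genetic_lengths
    for c in range(spec.n_chromosomes):
        sel = spec.chrom == c
        if not np.any(sel):
            continue
        pos = spec.positions[sel]
        start = rng.integers(0, 2, size=n)
        counts = rng.poisson(lam[c], size=n)
        parity = np.zeros((n, pos.size), dtype=np.int64)
        for count in np.unique(counts):
            if count == 0:
                continue
            rows = counts == count
            xo = rng.uniform(0.0, lengths[c], size=(int(rows.sum()), count))
            parity[rows] = (xo[:, :, None] < pos[None, None, :]).sum(axis=1)
        hap_choice = (start[:, None] + parity) % 2
        out[:, sel] = np.where(hap_choice == 0, parent[0, sel], parent[1, sel])
    if spec.mutation_rate > 0:
        flips = rng.random(out.shape) < spec.mutation_rate
        out ^= flips.astype(np.uint8)
    return out


def meiosis(
    parent: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Produce ``n`` haploid gametes of a diploid parent.

    ``parent`` has shape (2, n_loci).  Returns (n, n_loci) (or (n_loci,)
    when ``n == 1``).  Crossovers are Poisson-counted and uniformly
    placed; each transmitted allele flips with the spec's mutation rate.
    """
    if parent.shape != (2, spec.n_loci):
        raise InvalidConfigError("parent must be diploid with spec.n_loci loci")
    gametes = _batch_gametes(parent, spec, rng, n)
    return gametes[0] if n == 1 else gametes


def _grouped_gametes(
    genomes: np.ndarray,
    parent_idx: np.ndarray,
    spec: GenomeSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """One gamete per requested parent index, batching repeated parents.

    ``genomes`` is (n_parents, 2, n_loci); ``parent_idx`` (m,) may repeat.
    """
    parent_idx = np.asarray(parent_idx, dtype=np.intp)
    out = np.empty((parent_idx.size, spec.n_loci), dtype=np.uint8)
    order = np.argsort(parent_idx, kind="stable")
    sorted_idx = parent_idx[order]
    bounds = np.flatnonzero(np.diff(sorted_idx)) + 1
    for block in np.split(np.arange(parent_idx.size)[order], bounds):
        p = sorted_idx_block = parent_idx[block[0]]
        out[block] = _batch_gametes(genomes[p], spec, rng, len(block))
    return out


def simulate_historical_panel(
    spec: GenomeSpec,
    queens_per_year: int,
    years: int,
    drones_per_queen: int = 12,
    seed: int | np.random.Generator | None = 0,
    expansion_size: int | None = None,
    expansion_years: int = 0,
    initial_freq: float | np.ndarray = 0.5,
) -> HaplotypePanel:
    """Drift a closed random-mating queen population to build LD.

    Each generation, every new queen receives a gamete of a uniformly
    chosen dam and the genome of one of the dam's ``drones_per_queen``
    stored drones; each drone is itself a gamete of a uniformly chosen
    queen of the parent generation.  After ``years`` generations the
    population is optionally expanded to ``expansion_size`` queens for
    ``expansion_years`` further generations of random mating.
    """
    if queens_per_year < 1 or years < 0:
        raise InvalidConfigError("population size and years must be positive")
    if drones_per_queen < 1:
        raise InvalidConfigError("queens mate at least one drone")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = queens_per_year
    freq = np.broadcast_to(np.asarray(initial_freq, float), (spec.n_loci,))
    genomes = (rng.random((n, 2, spec.n_loci)) < freq).astype(np.uint8)

    phases = [(queens_per_year, years)]
    if expansion_size is not None and expansion_years > 0:
        phases.append((expansion_size, expansion_years))

    for size, n_gen in phases:
        for _ in range(n_gen):
            n_parents = genomes.shape[0]
            dams = rng.integers(0, n_parents, size=size)
            # spermatheca: drone slot -> dam of that drone, per parent queen
            drone_slot = rng.integers(0, drones_per_queen, size=size)
            drone_dams_all = rng.integers(
                0, n_parents, size=(n_parents, drones_per_queen)
            )
            drone_keys = dams * drones_per_queen + drone_slot
            unique_keys, inverse = np.unique(drone_keys, return_inverse=True)
            drone_parent = drone_dams_all[
                unique_keys // drones_per_queen, unique_keys % drones_per_queen
            ]
            drone_pool = _grouped_gametes(genomes, drone_parent, spec, rng)
            maternal = _grouped_gametes(genomes, dams, spec, rng)
            genomes = np.stack([maternal, drone_pool[inverse]], axis=1)

    return HaplotypePanel(
        spec=spec,
        haplotypes=genomes.reshape(-1, spec.n_loci),
        generation_label=f"historical+{years}y"
        + (f"+exp{expansion_years}y" if expansion_years else ""),
    )


def filter_loci_by_maf(
    panel: HaplotypePanel, threshold: float = 0.05
) -> tuple[HaplotypePanel, np.ndarray]:
    """Drop loci whose minor-allele frequency is below ``threshold``.

    Returns the filtered panel and the indices of retained loci (into the
    input panel's locus order).
    """
    if not 0.0 <= threshold <= 0.5:
        raise InvalidConfigError("MAF threshold must be in [0, 0.5]")
    p = panel.allele_freqs
    maf = np.minimum(p, 1.0 - p)
    keep = np.flatnonzero(maf >= threshold)
    if keep.size == 0:
        raise EmptyPanelError("no locus passes the MAF filter")
    return (
        HaplotypePanel(
            spec=panel.spec.subset(keep),
            haplotypes=panel.haplotypes[:, keep],
            generation_label=panel.generation_label + f"|maf>={threshold}",
        ),
        keep,
    )


def adjacent_r2(panel: HaplotypePanel) -> float:
    """Mean squared correlation between neighbouring polymorphic loci."""
    h = panel.haplotypes.astype(float)
    p = h.mean(axis=0)
    poly = (p > 0) & (p < 1)
    r2 = []
    for c in range(panel.spec.n_chromosomes):
        sel = np.flatnonzero((panel.spec.chrom == c) & poly)
        if sel.size < 2:
            continue
        x = h[:, sel]
        x = (x - x.mean(axis=0)) / x.std(axis=0)
        r = (x[:, :-1] * x[:, 1:]).mean(axis=0)
        r2.append(r**2)
    if not r2:
        raise EmptyPanelError("no adjacent polymorphic locus pairs")
    return float(np.concatenate(r2).mean())


@dataclass
class QTLEffects:
    """Adjusted bivariate (direct, maternal) additive QTL allele effects.

    ``tbv(dosage)`` maps 0/1/2 QTL dosages (n, n_qtl) to true breeding
    values (n, 2); after adjustment the base population has mean TBV
    exactly (0, 0) and empirical TBV covariance exactly ``V_a``.
    """

    qtl_indices: np.ndarray
    effects: np.ndarray  # (n_qtl, 2)
    offset: np.ndarray  # (2,)
    adjustment_record: dict = field(default_factory=dict)

    def tbv(self, dosage: np.ndarray) -> np.ndarray:
        return np.asarray(dosage, float) @ self.effects + self.offset

    def tbv_haploid(self, alleles: np.ndarray) -> np.ndarray:
        """TBV-scale contribution of a haploid genome (e.g. a gamete)."""
        return np.asarray(alleles, float) @ self.effects


def _laplace_normal_mixture(
    n: int, V_a: np.ndarray, rng: np.random.Generator, laplace_share: float = 0.95
) -> np.ndarray:
    """Bivariate 0.95 Laplace / 0.05 normal mixture with covariance V_a.

    The elliptical Laplace is realized as a normal scale mixture with an
    Exponential(1) variance factor, so each mixture component has
    covariance exactly ``V_a``.
    """
    L = np.linalg.cholesky(V_a)
    z = rng.standard_normal((n, 2)) @ L.T
    is_laplace = rng.random(n) < laplace_share
    scale = np.where(is_laplace, np.sqrt(rng.exponential(1.0, size=n)), 1.0)
    return z * scale[:, None]


def assign_qtl_effects(
    panel: HaplotypePanel,
    n_qtl: int,
    V_a: np.ndarray,
    seed: int | np.random.Generator | None = 0,
) -> QTLEffects:
    """Sample QTL positions and effects, then adjust to the base population.

    The base population is the panel's queens.  Preliminary effects are
    drawn from the 0.95/0.05 Laplace/normal mixture with component
    covariance ``V_a``; a linear map and offset then make the empirical
    base-population TBV mean exactly (0, 0) and covariance (ddof=1)
    exactly ``V_a``.
    """
    V_a = np.asarray(V_a, float)
    if n_qtl > panel.spec.n_loci:
        raise InvalidConfigError("more QTL requested than panel loci")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    qtl = np.sort(rng.choice(panel.spec.n_loci, size=n_qtl, replace=False))

    if np.allclose(V_a, 0.0):
        return QTLEffects(
            qtl_indices=qtl,
            effects=np.zeros((n_qtl, 2)),
            offset=np.zeros(2),
            adjustment_record={"transform": np.eye(2).tolist(), "note": "V_a = 0"},
        )

    raw = _laplace_normal_mixture(n_qtl, V_a, rng)
    dosage = panel.genotype_matrix()[:, qtl].astype(float)
    tbv_pre = dosage @ raw
    S = np.cov(tbv_pre, rowvar=False, ddof=1)
    try:
        L_S = np.linalg.cholesky(S)
        L_V = np.linalg.cholesky(V_a)
    except np.linalg.LinAlgError as err:
        raise SingularAdjustmentError(
            "base-population genotypic (co)variance at the sampled QTL is singular"
        ) from err
    transform = L_V @ np.linalg.inv(L_S)
    effects = raw @ transform.T
    offset = -(dosage @ effects).mean(axis=0)
    return QTLEffects(
        qtl_indices=qtl,
        effects=effects,
        offset=offset,
        adjustment_record={
            "transform": transform.tolist(),
            "offset": offset.tolist(),
            "pre_covariance": S.tolist(),
        },
    )
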