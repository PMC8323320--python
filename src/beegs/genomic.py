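"""Genomic relationship matrices, single-step H-inverse, and the mixed model.

Breeding values are estimated from colony phenotypes with the linear
mixed model

    y = X b + Z_a a + Z_m m + e,

where each phenotype links the *direct* effect of the colony's worker
group and the *maternal* effect of its queen, ``b`` holds year fixed
effects, and

    Var(a, m) = [[sigma_a2 K, sigma_am K], [sigma_am K, sigma_m2 K]],
    Var(e) = sigma_e2 I,

with ``K`` the bee-specific pedigree relationship matrix ``A`` (PBLUP)
or the combined pedigree-genomic matrix ``H`` (single-step GBLUP).

The genomic pipeline follows the standard single-step recipe adapted to
honey bees: a VanRaden method-1 GRM over genotyped queens, optional
merging of individual DPQ genotypes into pseudo-father rows (group
means), mean-adjustment of the GRM to the corresponding pedigree
submatrix, blending with the pedigree submatrix for invertibility, and
the block-augmented H-inverse

    H^-1 = A^-1 + [[0, 0], [0, G_w^-1 - A_g^-1]].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
import scipy.linalg

from .relationship import (
    Pedigree,
    PedigreeEntry,
    RelationshipMatrix,
    build_numerator_A,
    extract_submatrix,
)
from .trait_model import TraitBase

if TYPE_CHECKING:  # pragma: no cover
    from .breeding import PopulationHistory

__all__ = [
    "GenotypeMatrix",
    "MMESpec",
    "build_grm",
    "adjust_grm",
    "blend_grm",
    "merge_pseudofathers_grm",
    "build_H_inverse",
    "solve_mixed_model",
    "run_analysis",
]

MODES = ("PBLUP", "ssGBLUP_BQ", "ssGBLUP_DPQ+BQ")


class DegeneratePanelError(ValueError):
    pass


class NonIdentifiableAdjustmentError(ValueError):
    pass


class SingularSystemError(ValueError):
    pass


class EmptyGroupError(ValueError):
    pass


@dataclass
class GenotypeMatrix:
    """0/1/2 marker matrix of genotyped queens with centering helpers."""

    ids: list[str]
    M: np.ndarray
    p: np.ndarray | None = None  # per-locus allele frequency

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M, float)
        if self.M.ndim != 2 or self.M.shape[0] != len(self.ids):
            raise ValueError("M must be (n_genotyped, n_loci)")
        if self.p is None:
            self.p = self.M.mean(axis=0) / 2.0
        self.p = np.asarray(self.p, float)

    @property
    def P(self) -> np.ndarray:
        return np.broadcast_to(2.0 * self.p, self.M.shape)

    @property
    def Z(self) -> np.ndarray:
        return self.M - self.P

    def to_frame(self) -> pd.DataFrame:
        cols = [f"L{i + 1}" for i in range(self.M.shape[1])]
        return pd.DataFrame(self.M.astype(int), index=self.ids, columns=cols)


def build_grm(geno: GenotypeMatrix) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix Z Z' / (2 sum p q)."""
    denom = 2.0 * np.sum(geno.p * (1.0 - geno.p))
    if denom <= 0:
        raise DegeneratePanelError("all loci are monomorphic")
    Z = geno.Z
    return (Z @ Z.T) / denom


def adjust_constants(G: np.ndarray, A_g: np.ndarray) -> tuple[float, float]:
    """Solve alpha, beta so that alpha + beta*G matches the mean diagonal
    and mean off-diagonal entries of the pedigree submatrix ``A_g``."""
    G = np.asarray(G, float)
    A_g = np.asarray(A_g, float)
    if G.shape != A_g.shape:
        raise ValueError("G and A_g must have matching shapes")
    n = G.shape[0]
    if n < 2:
        raise NonIdentifiableAdjustmentError("need at least two genotyped queens")
    diag_G, diag_A = np.trace(G) / n, np.trace(A_g) / n
    off_G = (G.sum() - np.trace(G)) / (n * (n - 1))
    off_A = (A_g.sum() - np.trace(A_g)) / (n * (n - 1))
    if abs(diag_G - off_G) < 1e-12:
        raise NonIdentifiableAdjustmentError(
            "mean diagonal equals mean off-diagonal in G"
        )
    beta = (diag_A - off_A) / (diag_G - off_G)
    alpha = off_A - beta * off_G
    return float(alpha), float(beta)


def adjust_grm(G: np.ndarray, A_g: np.ndarray) -> np.ndarray:
    """Rescale G as alpha + beta*G so its mean diagonal and mean
    off-diagonal entries equal those of the pedigree submatrix ``A_g``."""
    alpha, beta = adjust_constants(G, A_g)
    return alpha + beta * np.asarray(G, float)


def blend_grm(G_adj: np.ndarray, A_g: np.ndarray, weight: float = 0.95) -> np.ndarray:
    """Convex combination ``weight*G_adj + (1-weight)*A_g`` (invertibility)."""
    if not 0.0 < weight <= 1.0:
        raise ValueError("blend weight must be in (0, 1]")
    return weight * np.asarray(G_adj, float) + (1.0 - weight) * np.asarray(A_g, float)


def merge_pseudofathers_grm(
    G_tilde: np.ndarray, groups: list[list[int]]
) -> np.ndarray:
    """Merge individual-DPQ rows of a GRM into pseudo-father rows.

    ``groups`` lists, for every output row, the input row indices it
    averages: singletons for genotyped BQ, the member DPQ indices for a
    pseudo-father.  The merged matrix is ``T G_tilde T'`` with ``T`` the
    row-averaging map, so a pseudo-father/pseudo-father entry is the
    full member-grid mean and its entries to other animals are member
    means.
    """
    G_tilde = np.asarray(G_tilde, float)
    m = len(groups)
    T = np.zeros((m, G_tilde.shape[0]))
    for r, members in enumerate(groups):
        if len(members) == 0:
            raise EmptyGroupError(f"output row {r} has no members")
        T[r, members] = 1.0 / len(members)
    return T @ G_tilde @ T.T


def build_H_inverse(
    A_inv: np.ndarray,
    A_g_inv: np.ndarray,
    G_w_inv: np.ndarray,
    genotyped_idx: np.ndarray,
) -> np.ndarray:
    """Block-augmented single-step inverse relationship matrix.

    ``genotyped_idx`` places the genotyped block inside the full entity
    ordering of ``A_inv``.
    """
    H_inv = A_inv.copy()
    sel = np.ix_(genotyped_idx, genotyped_idx)
    H_inv[sel] += G_w_inv - A_g_inv
    return H_inv


def _inv_pd(mat: np.ndarray, what: str) -> np.ndarray:
    try:
        c, low = scipy.linalg.cho_factor(mat, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise SingularSystemError(f"{what} is not positive definite") from err
    return scipy.linalg.cho_solve((c, low), np.eye(mat.shape[0]), check_finite=False)


@dataclass
class MMESpec:
    """Data and variance structure of one mixed-model run.

    ``direct_idx``/``maternal_idx`` map each phenotype record to the
    entity whose direct (worker group) or maternal (queen) effect it
    carries; ``year`` labels the fixed-effect level of each record
    (cell-means coding, one level per phenotype year).
    """

    y: np.ndarray
    year: np.ndarray
    direct_idx: np.ndarray
    maternal_idx: np.ndarray
    entity_ids: list[str]
    trait: TraitBase
    K_inv: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, float)
        self.year = np.asarray(self.year)
        self.direct_idx = np.asarray(self.direct_idx, np.intp)
        self.maternal_idx = np.asarray(self.maternal_idx, np.intp)
        n_ent = len(self.entity_ids)
        if self.K_inv.shape != (n_ent, n_ent):
            raise ValueError("K_inv must match the entity count")
        if not (len(self.y) == len(self.year) == len(self.direct_idx) == len(self.maternal_idx)):
            raise ValueError("record vectors must share one length")


def solve_mixed_model(mme: MMESpec) -> tuple[pd.DataFrame, pd.Series]:
    """Solve Henderson's mixed-model equations for the direct+maternal model.

    Returns the EBV table (one row per entity: direct, maternal and their
    sum) and the estimated year effects.
    """
    t = mme.trait
    n_ent = len(mme.entity_ids)
    n_rec = len(mme.y)
    years, year_codes = np.unique(mme.year, return_inverse=True)
    nf = len(years)

    V_a = t.V_a
    try:
        V_a_inv = np.linalg.inv(V_a)
    except np.linalg.LinAlgError as err:
        raise SingularSystemError("genetic covariance matrix is singular") from err
    k11, k12, k22 = V_a_inv[0, 0], V_a_inv[0, 1], V_a_inv[1, 1]
    r_inv = 1.0 / t.sigma_e2 if t.sigma_e2 > 0 else 1.0

    # incidence cross-products, assembled densely via bincount
    dim = nf + 2 * n_ent
    C = np.zeros((dim, dim))
    rhs = np.zeros(dim)

    def scatter(rows: np.ndarray, cols: np.ndarray, out: np.ndarray) -> None:
        np.add.at(out, (rows, cols), r_inv)

    fa = nf + mme.direct_idx
    fm = nf + n_ent + mme.maternal_idx
    scatter(year_codes, year_codes, C)
    scatter(year_codes, fa, C)
    scatter(fa, year_codes, C)
    scatter(year_codes, fm, C)
    scatter(fm, year_codes, C)
    scatter(fa, fa, C)
    scatter(fm, fm, C)
    scatter(fa, fm, C)
    scatter(fm, fa, C)
    np.add.at(rhs, year_codes, r_inv * mme.y)
    np.add.at(rhs, fa, r_inv * mme.y)
    np.add.at(rhs, fm, r_inv * mme.y)

    sl_a = slice(nf, nf + n_ent)
    sl_m = slice(nf + n_ent, dim)
    C[sl_a, sl_a] += k11 * mme.K_inv
    C[sl_a, sl_m] += k12 * mme.K_inv
    C[sl_m, sl_a] += k12 * mme.K_inv
    C[sl_m, sl_m] += k22 * mme.K_inv

    try:
        cf = scipy.linalg.cho_factor(C, lower=True, check_finite=False)
    except np.linalg.LinAlgError as err:
        raise SingularSystemError(
            "mixed-model equations are singular (confounded effects?)"
        ) from err
    sol = scipy.linalg.cho_solve(cf, rhs, check_finite=False)

    ebv = pd.DataFrame(
        {
            "id": mme.entity_ids,
            "ebv_direct": sol[sl_a],
            "ebv_maternal": sol[sl_m],
        }
    )
    ebv["ebv_sum"] = ebv.ebv_direct + ebv.ebv_maternal
    fixed = pd.Series(sol[:nf], index=years, name="year_effect")
    return ebv, fixed


# ---------------------------------------------------------------------------
# Orchestration over a simulated population


def _mme_from_history(
    history: "PopulationHistory",
    pedigree: Pedigree,
    trait: TraitBase,
    K_inv: np.ndarray,
    upto_year: int | None,
) -> MMESpec:
    phen = history.phenotype_frame(upto_year)
    index = pedigree.index
    return MMESpec(
        y=phen.phenotype.to_numpy(float),
        year=phen.year.to_numpy(),
        direct_idx=np.array([index[i] for i in phen.id], np.intp),
        maternal_idx=np.array([index[i] for i in phen.queen_id], np.intp),
        entity_ids=pedigree.ids,
        trait=trait,
        K_inv=K_inv,
    )


def expanded_pedigree(
    history: "PopulationHistory", expand_pf_ids: set[str] | None = None
) -> Pedigree:
    """Pedigree variant where pseudo-fathers are kept as individual DPQ.

    Every recorded pseudo-father in ``expand_pf_ids`` (default: all) is
    replaced by queen entries for its member DPQ; references to it become
    explicit ``sire_group`` references.  Used to verify that merging DPQ
    into pseudo-fathers leaves the EBV of all other animals unchanged.
    """
    base = history.pedigree()
    expand = (
        {e.id for e in base.entries if e.kind == "pseudofather"}
        if expand_pf_ids is None
        else set(expand_pf_ids)
    )
    members = {pid: tuple(sorted(history.pf_members(pid))) for pid in expand}
    queens = history.queens.set_index("id")
    ped = Pedigree()
    for e in base.entries:
        sire, sire_group = e.sire, None
        if e.sire in expand:
            sire, sire_group = None, members[e.sire]
        if e.kind == "pseudofather" and e.id in expand:
            for m in members[e.id]:
                row = queens.loc[m]
                m_sire, m_group = row.sire_id, None
                if pd.notna(m_sire) and m_sire in expand:
                    m_sire, m_group = None, members[m_sire]
                ped.add(
                    PedigreeEntry(
                        id=m,
                        kind="queen",
                        dam=None if pd.isna(row.dam_id) else row.dam_id,
                        sire=None if pd.isna(m_sire) or m_group else m_sire,
                        sire_group=m_group,
                        year=int(row.birth_year),
                        n_drones=e.n_drones,
                        n_sire_members=e.n_sire_members,
                    )
                )
        else:
            ped.add(
                PedigreeEntry(
                    id=e.id,
                    kind=e.kind,
                    dam=e.dam,
                    sire=None if sire_group else sire,
                    sire_group=sire_group,
                    year=e.year,
                    n_members=e.n_members,
                    n_drones=e.n_drones,
                    n_sire_members=e.n_sire_members,
                )
            )
    return ped


def run_analysis(
    history: "PopulationHistory",
    mode: str,
    trait: TraitBase,
    genotyped: dict[str, list[str]] | None = None,
    upto_year: int | None = None,
    blend_weight: float = 0.95,
    merged: bool = True,
    return_details: bool = False,
):
    """Estimate breeding values for a simulated population.

    ``mode`` selects PBLUP, ssGBLUP over genotyped BQ, or ssGBLUP over
    genotyped BQ plus DPQ (merged into pseudo-fathers by default;
    ``merged=False`` keeps individual DPQ in both the pedigree and the
    GRM, which must leave BQ and worker-group EBV unchanged).  Returns
    the EBV table with an ``analysis`` label column.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    use_dpq = mode == "ssGBLUP_DPQ+BQ"
    g_bq = list(genotyped["bq"]) if genotyped else []
    g_pf = list(genotyped.get("pf", [])) if (genotyped and use_dpq) else []

    if use_dpq and not merged:
        pedigree = expanded_pedigree(history, set(g_pf))
    else:
        pedigree = history.pedigree(upto_year)
    R = build_numerator_A(pedigree)
    A_inv = _inv_pd(R.A, "pedigree relationship matrix")

    details: dict = {"pedigree": pedigree, "A": R}
    if mode == "PBLUP" or not (g_bq or g_pf):
        K_inv = A_inv
    else:
        if use_dpq and g_pf:
            dpq_by_pf = {pid: sorted(history.pf_members(pid)) for pid in g_pf}
            dpq_ids = [d for pid in g_pf for d in dpq_by_pf[pid]]
            geno = GenotypeMatrix(
                ids=g_bq + dpq_ids,
                M=history.genotype_dosage(g_bq + dpq_ids),
            )
            G_tilde = build_grm(geno)
            groups = [[i] for i in range(len(g_bq))]
            offset = len(g_bq)
            for pid in g_pf:
                k = len(dpq_by_pf[pid])
                groups.append(list(range(offset, offset + k)))
                offset += k
            if merged:
                G = merge_pseudofathers_grm(G_tilde, groups)
                g_ids = g_bq + g_pf
                A_g = R.submatrix(g_ids)
                G_adj = adjust_grm(G, A_g)
            else:
                # keep individual DPQ, but apply the adjustment constants
                # of the merged system: merging and adjustment then commute,
                # which is what makes the merged analysis equivalent
                G = G_tilde
                g_ids = g_bq + dpq_ids
                A_g = R.submatrix(g_ids)
                A_g_merged = merge_pseudofathers_grm(A_g, groups)
                alpha, beta = adjust_constants(
                    merge_pseudofathers_grm(G_tilde, groups), A_g_merged
                )
                G_adj = alpha + beta * G
        else:
            geno = GenotypeMatrix(ids=g_bq, M=history.genotype_dosage(g_bq))
            G = build_grm(geno)
            g_ids = g_bq
            A_g = R.submatrix(g_ids)
            G_adj = adjust_grm(G, A_g)
        G_w = blend_grm(G_adj, A_g, blend_weight)
        g_idx = np.array([R.index[i] for i in g_ids], np.intp)
        K_inv = build_H_inverse(
            A_inv, _inv_pd(A_g, "A_g"), _inv_pd(G_w, "blended GRM"), g_idx
        )
        details.update({"G": G, "G_w": G_w, "genotyped_ids": g_ids})

    details["K_inv"] = K_inv
    mme = _mme_from_history(history, pedigree, trait, K_inv, upto_year)
    ebv, fixed = solve_mixed_model(mme)
    kind = {e.id: e.kind for e in pedigree.entries}
    ebv.insert(1, "type", [kind[i] for i in ebv.id])
    ebv.insert(2, "analysis", mode)
    details["fixed_effects"] = fixed
    return (ebv, details) if return_details else ebv
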