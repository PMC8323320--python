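"""Deterministic prediction of genetic gain for breeding-scheme design.

One cycle of selection responds with ``R = i * rho * sigma`` (intensity
times accuracy times the TBV standard deviation of the candidates).  In
the honey-bee program two pathways contribute half each: dams of
drone-producing queens (DPQ) and dams of breeding queens (BQ), both
selected on colony phenotype information (colony-based selection, CBS):

    R_CBS = (i_DPQ_CBS / 2) rho_pW sigma_pW + (i_BQ_CBS / 2) rho_pW sigma_pW

Genomic preselection (GPS) of candidate DPQ and unfertilized BQ adds

    R_GPS = (i_DPQ_GPS p_DPQ / 2) rho_uQ sigma_uQ
          + (i_BQ_GPS p_BQ / 2) rho_uQ sigma_uQ,

where ``p_DPQ``/``p_BQ`` are the proportions of deployed DPQ / phenotyped
BQ that went through preselection, and ``R_GS = R_CBS + R_GPS``.  The
annual genotyping budget ``n_gpy`` is split between GPS candidates and
additional phenotyped BQ whose genotypes grow the reference population
(proportion ``p_ref``); accuracies are interpolated over ``p_ref`` from a
table of simulated accuracies.  Selection intensities use the
infinite-population truncation formula ``i = phi(z) / p``.

The generation interval is deliberately not part of the response
calculations: it is the same for every scheme compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "BaseProgram",
    "SchemeGrid",
    "SchemeConfig",
    "GainPrediction",
    "selection_intensity",
    "derive_scheme",
    "interpolate_accuracy",
    "predict_gain",
    "enumerate_and_optimize",
]


class InvalidFractionError(ValueError):
    pass


class OutOfRangeError(ValueError):
    pass


class MissingGridPointError(ValueError):
    pass


class EmptyFeasibleSetError(ValueError):
    pass


def selection_intensity(n_selected: int | np.ndarray, n_candidates: int | np.ndarray) -> float | np.ndarray:
    """Infinite-population truncation selection intensity phi(z)/p.

    ``p = n_selected / n_candidates`` is the selected proportion and
    ``z`` the standard-normal truncation point.  Selecting everyone
    gives 0.
    """
    n_selected = np.asarray(n_selected, float)
    n_candidates = np.asarray(n_candidates, float)
    if np.any(n_selected <= 0) or np.any(n_selected > n_candidates):
        raise InvalidFractionError("need 0 < n_selected <= n_candidates")
    p = n_selected / n_candidates
    z = norm.ppf(1.0 - p)
    i = np.where(p >= 1.0, 0.0, norm.pdf(z) / p)
    return float(i) if i.ndim == 0 else i


@dataclass(frozen=True)
class BaseProgram:
    """Constants of the underlying colony-based breeding program."""

    n_bq_per_year: int = 1000
    n_dams_bq: int = 200
    daughters_per_dam_bq: int = 5
    n_dams_dpq: int = 50
    daughters_per_dam_dpq: int = 8
    n_stations: int = 50
    n_dpq_deployed: int = 400

    @property
    def i_bq_cbs(self) -> float:
        return float(selection_intensity(self.n_dams_bq, self.n_bq_per_year))

    @property
    def i_dpq_cbs(self) -> float:
        return float(selection_intensity(self.n_dams_dpq, self.n_bq_per_year))


@dataclass(frozen=True)
class SchemeGrid:
    """Enumeration ranges for the scheme search."""

    budgets: tuple[int, ...] = tuple(range(0, 4001, 500))
    N_DPQ_GPS: tuple[int, int] = (0, 50)
    N_BQ_GPS: tuple[int, int] = (0, 200)
    n_DPQ_GPS: tuple[int, int] = (9, 64)
    n_BQ_GPS: tuple[int, int] = (6, 32)


@dataclass(frozen=True)
class SchemeConfig:
    """One breeding scheme with all derived quantities."""

    n_gpy: int
    N_DPQ_GPS: int
    n_DPQ_GPS: int
    N_BQ_GPS: int
    n_BQ_GPS: int
    p_DPQ: float
    p_BQ: float
    N_rest: float
    p_ref: float
    i_DPQ_GPS: float
    i_BQ_GPS: float
    i_DPQ_CBS: float
    i_BQ_CBS: float
    feasible: bool

    def as_dict(self) -> dict:
        return asdict(self)


def derive_scheme(
    n_gpy: int,
    N_DPQ_GPS: int,
    n_DPQ_GPS: int,
    N_BQ_GPS: int,
    n_BQ_GPS: int,
    base: BaseProgram = BaseProgram(),
    grid: SchemeGrid = SchemeGrid(),
) -> SchemeConfig:
    """Fill in all derived quantities of a candidate scheme.

    ``N_*_GPS`` dams are chosen for preselection, each producing
    ``n_*_GPS`` genotyped candidates of which the usual number per dam
    is kept.  Genotyping slots not used by candidates (``N_rest``) go to
    phenotyped BQ; ``p_ref`` is the resulting proportion of BQ entering
    the reference population per year (capped at 1).  Schemes whose
    candidates alone exceed the budget are marked infeasible.
    """
    if not (grid.N_DPQ_GPS[0] <= N_DPQ_GPS <= grid.N_DPQ_GPS[1]):
        raise OutOfRangeError("N_DPQ_GPS outside grid range")
    if not (grid.N_BQ_GPS[0] <= N_BQ_GPS <= grid.N_BQ_GPS[1]):
        raise OutOfRangeError("N_BQ_GPS outside grid range")
    if N_DPQ_GPS > 0 and not (grid.n_DPQ_GPS[0] <= n_DPQ_GPS <= grid.n_DPQ_GPS[1]):
        raise OutOfRangeError("n_DPQ_GPS outside grid range")
    if N_BQ_GPS > 0 and not (grid.n_BQ_GPS[0] <= n_BQ_GPS <= grid.n_BQ_GPS[1]):
        raise OutOfRangeError("n_BQ_GPS outside grid range")
    kd, kb = base.daughters_per_dam_dpq, base.daughters_per_dam_bq
    p_DPQ = kd * N_DPQ_GPS / base.n_dpq_deployed
    p_BQ = kb * N_BQ_GPS / base.n_bq_per_year
    cost = n_BQ_GPS * N_BQ_GPS + n_DPQ_GPS * N_DPQ_GPS
    N_rest = n_gpy - cost
    p_ref = min(1.0, max(0.0, (N_rest + kb * N_BQ_GPS) / base.n_bq_per_year))
    return SchemeConfig(
        n_gpy=n_gpy,
        N_DPQ_GPS=N_DPQ_GPS,
        n_DPQ_GPS=n_DPQ_GPS,
        N_BQ_GPS=N_BQ_GPS,
        n_BQ_GPS=n_BQ_GPS,
        p_DPQ=p_DPQ,
        p_BQ=p_BQ,
        N_rest=float(N_rest),
        p_ref=p_ref,
        i_DPQ_GPS=float(selection_intensity(kd, n_DPQ_GPS)) if N_DPQ_GPS else 0.0,
        i_BQ_GPS=float(selection_intensity(kb, n_BQ_GPS)) if N_BQ_GPS else 0.0,
        i_DPQ_CBS=base.i_dpq_cbs,
        i_BQ_CBS=base.i_bq_cbs,
        feasible=N_rest >= 0,
    )


def interpolate_accuracy(
    p_ref: float | np.ndarray,
    accuracy_table: pd.DataFrame,
    mode: str = "ssGBLUP_BQ",
) -> tuple[np.ndarray, np.ndarray]:
    """Piecewise-linear accuracies ``(rho_pW, rho_uQ)`` at ``p_ref``.

    ``accuracy_table`` has columns ``analysis``, ``p_ref``, ``rho_pW``,
    ``rho_uQ``; the PBLUP row anchors ``p_ref = 0`` and rows of the
    requested single-step analysis span the simulated grid.
    """
    tab = accuracy_table
    pb = tab.loc[tab.analysis == "PBLUP"]
    ss = tab.loc[tab.analysis == mode].sort_values("p_ref")
    if len(pb) == 0 or len(ss) == 0:
        raise MissingGridPointError(f"accuracy table lacks PBLUP or {mode} rows")
    nodes = np.concatenate([[0.0], ss.p_ref.to_numpy(float)])
    rho_pw = np.concatenate([pb.rho_pW.to_numpy(float)[:1], ss.rho_pW.to_numpy(float)])
    rho_uq = np.concatenate([pb.rho_uQ.to_numpy(float)[:1], ss.rho_uQ.to_numpy(float)])
    p = np.asarray(p_ref, float)
    return np.interp(p, nodes, rho_pw), np.interp(p, nodes, rho_uq)


@dataclass(frozen=True)
class GainPrediction:
    """Predicted one-cycle responses in selection-criterion units."""

    R_CBS: float
    R_GPS: float
    R_GS: float
    rho_pW: float
    rho_uQ: float
    sigma_pW: float
    sigma_uQ: float

    def as_dict(self) -> dict:
        return asdict(self)


def predict_gain(
    scheme: SchemeConfig,
    rho_pW: float,
    rho_uQ: float,
    sigma_pW: float,
    sigma_uQ: float,
) -> GainPrediction:
    """One-cycle genetic gain of a scheme: ``R_GS = R_CBS + R_GPS``."""
    if not scheme.feasible:
        raise EmptyFeasibleSetError("scheme exceeds the genotyping budget")
    r_cbs = 0.5 * (scheme.i_DPQ_CBS + scheme.i_BQ_CBS) * rho_pW * sigma_pW
    r_gps = 0.5 * (
        scheme.i_DPQ_GPS * scheme.p_DPQ + scheme.i_BQ_GPS * scheme.p_BQ
    ) * rho_uQ * sigma_uQ
    return GainPrediction(
        R_CBS=r_cbs,
        R_GPS=r_gps,
        R_GS=r_cbs + r_gps,
        rho_pW=rho_pW,
        rho_uQ=rho_uQ,
        sigma_pW=sigma_pW,
        sigma_uQ=sigma_uQ,
    )


def _grid_axes(grid: SchemeGrid, base: BaseProgram):
    nd = np.arange(grid.N_DPQ_GPS[0], grid.N_DPQ_GPS[1] + 1)
    nb = np.arange(grid.N_BQ_GPS[0], grid.N_BQ_GPS[1] + 1)
    cd = np.arange(grid.n_DPQ_GPS[0], grid.n_DPQ_GPS[1] + 1)
    cb = np.arange(grid.n_BQ_GPS[0], grid.n_BQ_GPS[1] + 1)
    return nd, cd, nb, cb


def enumerate_and_optimize(
    accuracy_table: pd.DataFrame,
    sigma_pW: float,
    sigma_uQ: float,
    base: BaseProgram = BaseProgram(),
    grid: SchemeGrid = SchemeGrid(),
    use_dpq_accuracy_when_all_preselected: bool = True,
) -> pd.DataFrame:
    """Enumerate every feasible scheme per budget; return per-budget optima.

    The search is vectorized over the four GPS parameters.  Gains use the
    ssGBLUP_BQ accuracy interpolated at the scheme's ``p_ref`` (PBLUP for
    ``p_ref = 0``); when all DPQ are preselected and the table carries
    ssGBLUP_DPQ+BQ rows, that analysis' accuracies are also evaluated and
    the better result kept.  The returned frame has one row per budget
    with the optimal scheme, its responses and the increase in genetic
    gain (IGG) relative to the previous budget's optimum.
    """
    nd, cd, nb, cb = _grid_axes(grid, base)
    kd, kb = base.daughters_per_dam_dpq, base.daughters_per_dam_bq
    sh = (len(nd), len(cd), len(nb), len(cb))

    i_dpq = selection_intensity(np.full_like(cd, kd), cd)
    i_bq = selection_intensity(np.full_like(cb, kb), cb)
    p_dpq = kd * nd / base.n_dpq_deployed
    p_bq = kb * nb / base.n_bq_per_year
    # GPS factor i*p per pathway; a pathway with zero dams contributes 0
    gps_d = np.where(nd[:, None] > 0, i_dpq[None, :] * p_dpq[:, None], 0.0)
    gps_b = np.where(nb[:, None] > 0, i_bq[None, :] * p_bq[:, None], 0.0)
    gps = (
        gps_d[:, :, None, None] + gps_b[None, None, :, :]
    ) * 0.5 * sigma_uQ
    cost = (
        (nd[:, None] * cd[None, :])[:, :, None, None]
        + (nb[:, None] * cb[None, :])[None, None, :, :]
    ).astype(np.int64) * np.ones(sh, dtype=np.int64)
    cbs_factor = 0.5 * (base.i_dpq_cbs + base.i_bq_cbs) * sigma_pW
    all_dpq = np.broadcast_to(
        (p_dpq >= 1.0)[:, None, None, None], sh
    )

    have_dpq_acc = (
        use_dpq_accuracy_when_all_preselected
        and (accuracy_table.analysis == "ssGBLUP_DPQ+BQ").any()
    )

    rows = []
    prev_best = None
    for budget in grid.budgets:
        n_rest = budget - cost
        feasible = n_rest >= 0
        if not feasible.any():
            raise EmptyFeasibleSetError(f"no feasible scheme for budget {budget}")
        p_ref = np.clip(
            (n_rest + (kb * nb)[None, None, :, None]) / base.n_bq_per_year,
            0.0,
            1.0,
        )
        rho_pw, rho_uq = interpolate_accuracy(p_ref, accuracy_table, "ssGBLUP_BQ")
        pblup_pw, pblup_uq = interpolate_accuracy(0.0, accuracy_table, "ssGBLUP_BQ")
        at_zero = p_ref <= 0.0
        rho_pw = np.where(at_zero, pblup_pw, rho_pw)
        rho_uq = np.where(at_zero, pblup_uq, rho_uq)
        r_gs = cbs_factor * rho_pw + gps * rho_uq
        analysis = np.full(sh, "ssGBLUP_BQ", dtype=object)
        if have_dpq_acc:
            rho_pw2, rho_uq2 = interpolate_accuracy(
                p_ref, accuracy_table, "ssGBLUP_DPQ+BQ"
            )
            r_gs2 = np.where(
                all_dpq & ~at_zero, cbs_factor * rho_pw2 + gps * rho_uq2, -np.inf
            )
            better = r_gs2 > r_gs
            analysis[better] = "ssGBLUP_DPQ+BQ"
            r_gs = np.maximum(r_gs, r_gs2)
        analysis[at_zero] = "PBLUP"
        r_gs = np.where(feasible, r_gs, -np.inf)
        best = r_gs.max()
        # tie-break: fewest genotypes used
        tied = np.argwhere(r_gs >= best - 1e-12)
        costs_tied = cost[tuple(tied.T)]
        pick = tuple(tied[np.argmin(costs_tied)])
        scheme = derive_scheme(
            budget,
            int(nd[pick[0]]),
            int(cd[pick[1]]),
            int(nb[pick[2]]),
            int(cb[pick[3]]),
            base=base,
            grid=grid,
        )
        row = scheme.as_dict()
        row.update(
            R_GS=float(r_gs[pick]),
            R_CBS=float(cbs_factor * rho_pw[pick])
            if analysis[pick] != "ssGBLUP_DPQ+BQ"
            else float(cbs_factor * rho_pw2[pick]),
            analysis=analysis[pick],
            IGG=float(r_gs[pick] - prev_best) if prev_best is not None else np.nan,
        )
        row["R_GPS"] = row["R_GS"] - row["R_CBS"]
        prev_best = float(r_gs[pick])
        rows.append(row)
    return pd.DataFrame(rows)
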