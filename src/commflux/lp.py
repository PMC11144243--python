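"""Linear-program core: FBA, parsimonious FBA, FVA and knockout screens.

All operations run against a generic contract: a model exposes an ordered
reaction collection, per-reaction bounds after applying a medium
(``lp_bounds``), a linear objective over reactions (``objective_map``) and
optional extra equality rows (``coupling_rows``).  Both single-strain models
and community models satisfy it, so every solver here works unchanged on
either.

The LPs are assembled as sparse matrices and solved with HiGHS through
scipy, configured deterministically (single-threaded dual simplex, tight
primal feasibility) so repeated runs reproduce fluxes bit-for-bit and
steady-state residuals stay at the 1e-9 level demanded of the community
balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.optimize import linprog

OPTIMAL = "optimal"
INFEASIBLE = "infeasible"
UNBOUNDED = "unbounded"

_HIGHS_OPTIONS = {
    "presolve": True,
    "primal_feasibility_tolerance": 1e-10,
    "dual_feasibility_tolerance": 1e-9,
}


@dataclass
class Tolerances:
    """Numeric thresholds shared across the pipeline.

    feasibility      — accepted residual of steady-state rows.
    optimality       — accepted slack when fixing an objective value.
    gamma            — objective fraction for pFBA/FVA/essentiality (0, 1].
    zero_flux        — reporting threshold below which a flux counts as zero.
    helpful_gain     — minimal relative gain for a "helpful" reaction.
    """

    feasibility: float = 1e-9
    optimality: float = 1e-7
    gamma: float = 1.0
    zero_flux: float = 1e-6
    helpful_gain: float = 0.01

    def __post_init__(self) -> None:
        for name in ("feasibility", "optimality", "gamma", "zero_flux", "helpful_gain"):
            if getattr(self, name) <= 0:
                raise ValueError(f"tolerance {name} must be strictly positive")
        if self.gamma > 1.0:
            raise ValueError("gamma must lie in (0, 1]")


DEFAULT_TOLERANCES = Tolerances()


@dataclass
class FluxSolution:
    status: str
    objective_value: float
    fluxes: Dict[str, float] = field(default_factory=dict)
    max_residual: float = 0.0
    #: summed flux through community import reactions (populated for pFBA
    #: on community models; 0 otherwise)
    total_import_flux: float = 0.0
    total_absolute_flux: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        )


@dataclass
class FVAInterval:
    reaction_id: str
    min_flux: float
    max_flux: float


class ObjectiveError(ValueError):
    """No usable objective reaction."""


# --------------------------------------------------------------------------
# assembly
# --------------------------------------------------------------------------

class _LP:
    """Flattened LP view of a model under a medium."""

    def __init__(self, model, medium=None):
        self.model = model
        self.rxn_ids: List[str] = list(model.reactions)
        self.index = {rid: j for j, rid in enumerate(self.rxn_ids)}
        met_ids = list(model.metabolites)
        met_index = {mid: i for i, mid in enumerate(met_ids)}

        rows, cols, vals = [], [], []
        for rid, rxn in model.reactions.items():
            j = self.index[rid]
            for mid, coef in rxn.stoichiometry.items():
                rows.append(met_index[mid])
                cols.append(j)
                vals.append(float(coef))
        n_extra = 0
        extra_rhs: List[float] = []
        for coeffs, rhs in model.coupling_rows():
            i = len(met_ids) + n_extra
            for rid, coef in coeffs.items():
                rows.append(i)
                cols.append(self.index[rid])
                vals.append(float(coef))
            extra_rhs.append(float(rhs))
            n_extra += 1
        self.n_rows = len(met_ids) + n_extra
        self.n_mets = len(met_ids)
        self.A_eq = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n_rows, len(self.rxn_ids))
        )
        self.b_eq = np.concatenate([np.zeros(len(met_ids)), np.asarray(extra_rhs)])
        bmap = model.lp_bounds(medium)
        self.lb = np.array([bmap[rid][0] for rid in self.rxn_ids])
        self.ub = np.array([bmap[rid][1] for rid in self.rxn_ids])

    def objective_vector(self, objective: Dict[str, float]) -> np.ndarray:
        c = np.zeros(len(self.rxn_ids))
        for rid, w in objective.items():
            if rid not in self.index:
                raise ObjectiveError(f"objective reaction {rid!r} not in model")
            c[self.index[rid]] = w
        return c

    def solve(
        self,
        c_max: np.ndarray,
        extra_lb: Optional[np.ndarray] = None,
        extra_ub: Optional[np.ndarray] = None,
        A_ub=None,
        b_ub=None,
    ) -> Tuple[str, float, Optional[np.ndarray]]:
        lb = self.lb if extra_lb is None else np.maximum(self.lb, extra_lb)
        ub = self.ub if extra_ub is None else np.minimum(self.ub, extra_ub)
        if np.any(lb > ub):
            return INFEASIBLE, 0.0, None
        res = linprog(
            -c_max,
            A_eq=self.A_eq,
            b_eq=self.b_eq,
            A_ub=A_ub,
            b_ub=b_ub,
            bounds=np.column_stack([lb, ub]),
            method="highs",
            options=dict(_HIGHS_OPTIONS),
        )
        if res.status == 0:
            return OPTIMAL, -res.fun, res.x
        if res.status == 2:
            return INFEASIBLE, 0.0, None
        if res.status == 3:
            return UNBOUNDED, float("inf"), None
        raise RuntimeError(f"LP solver failure: {res.message}")

    def residual(self, x: np.ndarray) -> float:
        r = self.A_eq @ x - self.b_eq
        return float(np.max(np.abs(r[: self.n_mets]))) if self.n_mets else 0.0


def _resolve_objective(model, objective_id: Optional[str]) -> Dict[str, float]:
    try:
        return model.objective_map(objective_id)
    except KeyError as exc:
        raise ObjectiveError(str(exc)) from exc


def _import_reaction_ids(model) -> List[str]:
    getter = getattr(model, "import_reaction_ids", None)
    return list(getter()) if getter else []


def _solution_from_x(lp: _LP, objective: Dict[str, float], x: np.ndarray) -> FluxSolution:
    fluxes = {rid: float(x[j]) for rid, j in lp.index.items()}
    obj = sum(w * fluxes[rid] for rid, w in objective.items())
    imports = _import_reaction_ids(lp.model)
    return FluxSolution(
        status=OPTIMAL,
        objective_value=obj,
        fluxes=fluxes,
        max_residual=lp.residual(x),
        total_import_flux=float(sum(fluxes[r] for r in imports)),
        total_absolute_flux=float(np.sum(np.abs(x))),
    )


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def fba(model, medium=None, objective_id: Optional[str] = None) -> FluxSolution:
    """Maximize an objective flux at steady state under bounds.

    The objective defaults to the model's own (the biomass reaction for a
    strain, the scenario-weighted biomass combination for a community).
    """
    objective = _resolve_objective(model, objective_id)
    lp = _LP(model, medium)
    status, value, x = lp.solve(lp.objective_vector(objective))
    if status != OPTIMAL:
        return FluxSolution(status=status, objective_value=value)
    return _solution_from_x(lp, objective, x)


def pfba(
    model,
    medium=None,
    objective_id: Optional[str] = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
    minimize: str = "all",
) -> FluxSolution:
    """Two-stage parsimonious FBA.

    Stage 1 maximizes the objective; stage 2 fixes the objective at
    ``gamma × optimum`` (as an inequality, for numerical robustness) and
    minimizes the summed absolute flux via non-negative flux splitting.
    ``minimize="exchange"`` restricts the stage-2 objective to boundary
    fluxes (exchanges, member–pool links and community imports) only.
    """
    if minimize not in {"all", "exchange"}:
        raise ValueError("minimize must be 'all' or 'exchange'")
    objective = _resolve_objective(model, objective_id)
    lp = _LP(model, medium)
    c = lp.objective_vector(objective)
    status, opt, x = lp.solve(c)
    if status != OPTIMAL:
        return FluxSolution(status=status, objective_value=opt)

    target = tolerances.gamma * opt
    n = len(lp.rxn_ids)
    # v = p - m, p, m >= 0; minimize sum of selected (p + m)
    pos_ub = np.maximum(lp.ub, 0.0)
    neg_ub = np.maximum(-lp.lb, 0.0)
    lb2 = np.concatenate([np.maximum(lp.lb, 0.0), np.maximum(-lp.ub, 0.0)])
    ub2 = np.concatenate([pos_ub, neg_ub])
    A_eq = sparse.hstack([lp.A_eq, -lp.A_eq], format="csr")
    # objective fixing row: c·v >= target - tol  ->  -c·(p - m) <= -(target - tol)
    A_ub = sparse.csr_matrix(np.concatenate([-c, c])[None, :])
    b_ub = np.array([-(target - tolerances.optimality)])
    if minimize == "all":
        weights = np.ones(n)
    else:
        boundary = set(getattr(model, "exchange_reaction_ids", []))
        boundary.update(_import_reaction_ids(model))
        boundary.update(getattr(model, "link_reaction_ids", lambda: [])())
        weights = np.array([1.0 if rid in boundary else 0.0 for rid in lp.rxn_ids])
    c2 = np.concatenate([weights, weights])
    res = linprog(
        c2,
        A_eq=A_eq,
        b_eq=lp.b_eq,
        A_ub=A_ub,
        b_ub=b_ub,
        bounds=np.column_stack([lb2, ub2]),
        method="highs",
        options=dict(_HIGHS_OPTIONS),
    )
    if res.status != 0:
        out = FluxSolution(status=INFEASIBLE, objective_value=opt)
        return out
    v = res.x[:n] - res.x[n:]
    solution = _solution_from_x(lp, objective, v)
    return solution


def fva(
    model,
    medium=None,
    gamma: float = 1.0,
    reaction_ids: Optional[Sequence[str]] = None,
    objective_id: Optional[str] = None,
    tolerances: Tolerances = DEFAULT_TOLERANCES,
) -> List[FVAInterval]:
    """Per-reaction flux range subject to ``objective >= gamma × optimum``."""
    objective = _resolve_objective(model, objective_id)
    lp = _LP(model, medium)
    c = lp.objective_vector(objective)
    status, opt, _ = lp.solve(c)
    if status != OPTIMAL:
        raise RuntimeError(f"FVA requires an optimal base solve, got {status}")
    A_ub = sparse.csr_matrix(-c[None, :])
    b_ub = np.array([-(gamma * opt - tolerances.optimality)])
    targets = list(reaction_ids) if reaction_ids is not None else list(lp.rxn_ids)
    intervals = []
    for rid in targets:
        if rid not in lp.index:
            raise KeyError(f"unknown reaction {rid!r}")
        e = np.zeros(len(lp.rxn_ids))
        e[lp.index[rid]] = 1.0
        lo_status, lo, _ = lp.solve(-e, A_ub=A_ub, b_ub=b_ub)
        hi_status, hi, _ = lp.solve(e, A_ub=A_ub, b_ub=b_ub)
        if lo_status != OPTIMAL or hi_status != OPTIMAL:
            raise RuntimeError(f"FVA sub-LP not optimal for {rid!r}")
        intervals.append(FVAInterval(rid, -lo, hi))
    return intervals


def single_knockouts(
    model,
    medium=None,
    reaction_ids: Optional[Sequence[str]] = None,
    objective_id: Optional[str] = None,
) -> Dict[str, float]:
    """Objective after constraining each listed reaction to zero, one at a
    time; the intact model is untouched.  Infeasible knockouts score 0."""
    objective = _resolve_objective(model, objective_id)
    lp = _LP(model, medium)
    c = lp.objective_vector(objective)
    targets = list(reaction_ids) if reaction_ids is not None else list(lp.rxn_ids)
    results: Dict[str, float] = {}
    for rid in targets:
        if rid not in lp.index:
            raise KeyError(f"unknown reaction {rid!r}")
        j = lp.index[rid]
        extra_lb = np.full(len(lp.rxn_ids), -np.inf)
        extra_ub = np.full(len(lp.rxn_ids), np.inf)
        extra_lb[j] = 0.0
        extra_ub[j] = 0.0
        status, value, _ = lp.solve(c, extra_lb=extra_lb, extra_ub=extra_ub)
        results[rid] = value if status == OPTIMAL else 0.0
    return results


def write_flux_tsv(solution: FluxSolution, path) -> None:
    solution.to_frame().to_csv(path, sep="\t", index=False)


def write_fva_tsv(intervals: Iterable[FVAInterval], path) -> None:
    pd.DataFrame(
        [{"reaction_id": i.reaction_id, "min": i.min_flux, "max": i.max_flux}
         for i in intervals]
    ).to_csv(path, sep="\t", index=False)
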