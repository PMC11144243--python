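"""Independent dense-LP brute-force oracle.

Builds the full dense stoichiometric matrix, medium bounds and scenario
coupling from the raw model fields by its own code path (no use of the
package's LP assembly) and solves with scipy's dual simplex.  Used to
cross-check every FBA/community-FBA objective on small fixtures.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linprog

from commflux.community import CommunityModel
from commflux.model import base_id


def dense_objective(model, medium) -> float:
    """Brute-force FBA optimum (scenario-aware for communities)."""
    rxn_ids = list(model.reactions)
    idx = {r: j for j, r in enumerate(rxn_ids)}
    met_ids = list(model.metabolites)
    midx = {m: i for i, m in enumerate(met_ids)}

    rows = []
    A = np.zeros((len(met_ids), len(rxn_ids)))
    for rid, rxn in model.reactions.items():
        for mid, coef in rxn.stoichiometry.items():
            A[midx[mid], idx[rid]] = coef
    rows.append(A)

    lb = np.array([r.lower_bound for r in model.reactions.values()])
    ub = np.array([r.upper_bound for r in model.reactions.values()])
    c = np.zeros(len(rxn_ids))

    if isinstance(model, CommunityModel):
        for met, rid in model.import_reactions.items():
            lb[idx[rid]] = 0.0
            ub[idx[rid]] = medium.uptake_allowance(met)
        bio = model.member_biomass
        sids = list(model.members)
        coupling = []
        if model.scenario.mode == "equal":
            for a, b in zip(sids, sids[1:]):
                row = np.zeros(len(rxn_ids))
                row[idx[bio[a]]], row[idx[bio[b]]] = 1.0, -1.0
                coupling.append(row)
        elif model.scenario.mode == "fixed":
            w = model.scenario.weights
            positive = [s for s in sids if w[s] > 0]
            for s in sids:
                if w[s] == 0:
                    row = np.zeros(len(rxn_ids))
                    row[idx[bio[s]]] = 1.0
                    coupling.append(row)
            for a, b in zip(positive, positive[1:]):
                row = np.zeros(len(rxn_ids))
                row[idx[bio[a]]], row[idx[bio[b]]] = w[b], -w[a]
                coupling.append(row)
        if coupling:
            rows.append(np.vstack(coupling))
        if model.scenario.mode == "target":
            c[idx[bio[model.scenario.target_strain]]] = 1.0
        elif model.scenario.mode == "fixed":
            first = next(s for s in sids if model.scenario.weights[s] > 0)
            c[idx[bio[first]]] = 1.0 / model.scenario.weights[first]
        else:
            for s in sids:
                c[idx[bio[s]]] = model.objective_weights[s]
    else:
        for ex_id in model.exchange_reaction_ids:
            (mid,) = model.reactions[ex_id].stoichiometry
            allowance = medium.uptake_allowance(base_id(mid))
            lb[idx[ex_id]] = max(lb[idx[ex_id]], -allowance)
        c[idx[model.biomass_reaction_id]] = 1.0

    A_eq = np.vstack(rows)
    b_eq = np.zeros(A_eq.shape[0])
    res = linprog(-c, A_eq=A_eq, b_eq=b_eq, bounds=list(zip(lb, ub)),
                  method="highs-ds")
    if res.status != 0:
        raise RuntimeError(f"oracle LP not optimal: {res.message}")
    return -res.fun
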