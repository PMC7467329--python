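"""Ligand-level metrics: selectivity entropy, best target, CNS desirability.

Selectivity entropy summarizes how a ligand's binding affinity is spread
across targets: with affinity weights :math:`a_i = 1/K_i` and shares
:math:`p_i = a_i / \\sum_j a_j`, the entropy is :math:`-\\sum_i p_i \\ln p_i`.
A perfectly selective ligand scores 0; a ligand equipotent on N targets
scores :math:`\\ln N`.  Only equilibrium binding rows (Ki/Kd) enter the
calculation.

The CNS multi-parameter desirability score sums six per-property piecewise
linear desirabilities (each in [0, 1]) over standard physicochemical
descriptors, giving a 0-6 scale where >= 4 is conventionally read as a
favorable central-nervous-system profile.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

from .records import LigandActivity

__all__ = [
    "CNS_MPO_BREAKPOINTS",
    "best_target",
    "cns_mpo",
    "piecewise_desirability",
    "selectivity_entropy",
]

_BINDING_TYPES = ("Ki", "Kd")

#: Default (favorable, unfavorable) breakpoints per CNS MPO property.
#: Desirability is 1 on the favorable side of the first bound, 0 beyond the
#: second, linear between.  TPSA is modeled by its descending arm (high polar
#: surface area is the CNS-limiting direction).
CNS_MPO_BREAKPOINTS: dict[str, tuple[float, float]] = {
    "cLogP": (3.0, 5.0),
    "cLogD": (2.0, 4.0),
    "MW": (360.0, 500.0),
    "TPSA": (90.0, 120.0),
    "HBD": (0.5, 3.5),
    "pKa": (8.0, 10.0),
}


def _binding_rows(activities: Sequence[LigandActivity]) -> list[LigandActivity]:
    rows = list(activities)
    if not rows:
        raise ValueError("no activity rows given")
    ligands = {r.ligand_id for r in rows}
    if len(ligands) > 1:
        raise ValueError(f"activity rows mix multiple ligands: {sorted(ligands)}")
    kept = [r for r in rows if r.activity_type in _BINDING_TYPES]
    if not kept:
        raise ValueError(
            "no Ki/Kd rows for this ligand; selectivity requires binding data"
        )
    return kept


def selectivity_entropy(activities: Sequence[LigandActivity], base: str = "e") -> float:
    """Shannon selectivity entropy of one ligand's Ki/Kd profile (nats).

    Rows must share a single ``ligand_id``; multiple rows on the same target
    are pooled by their best (lowest) potency.  ``base="2"`` switches to bits.
    """
    rows = _binding_rows(activities)
    best: dict[str, float] = {}
    for r in rows:
        best[r.target_id] = min(best.get(r.target_id, math.inf), r.value)
    weights = [1.0 / v for v in best.values()]
    total = sum(weights)
    log = math.log2 if base == "2" else math.log
    h = 0.0
    for w in weights:
        p = w / total
        h -= p * log(p)
    return max(h, 0.0)


def best_target(activities: Sequence[LigandActivity]) -> str:
    """Target on which the ligand is most potent (lowest Ki/Kd).

    Ties break to the lexicographically smallest target id.
    """
    rows = _binding_rows(activities)
    return min(rows, key=lambda r: (r.value, r.target_id)).target_id


def piecewise_desirability(value: float, breakpoints: tuple[float, float]) -> float:
    """Two-breakpoint linear desirability in [0, 1].

    ``breakpoints = (favorable, unfavorable)``: 1 at or beyond the favorable
    bound, 0 at or beyond the unfavorable bound, linear between.  The
    direction is inferred from the breakpoint order, so descending
    properties just swap the bounds.
    """
    fav, unfav = breakpoints
    if fav == unfav:
        raise ValueError(f"breakpoints must be distinct, got {breakpoints}")
    t = (value - fav) / (unfav - fav)  # 0 at favorable, 1 at unfavorable
    return float(min(max(1.0 - t, 0.0), 1.0))


def cns_mpo(
    properties: Mapping[str, float],
    breakpoints: Mapping[str, tuple[float, float]] | None = None,
) -> float:
    """Six-property CNS desirability sum in [0, 6].

    All configured properties must be present; a missing one is an error
    naming it.
    """
    bp = dict(breakpoints) if breakpoints is not None else CNS_MPO_BREAKPOINTS
    total = 0.0
    for name, bounds in bp.items():
        if name not in properties:
            raise ValueError(f"missing physicochemical property {name!r} for CNS MPO")
        total += piecewise_desirability(float(properties[name]), bounds)
    return total


def ligand_profile(activities: Iterable[LigandActivity]) -> dict[str, dict]:
    """Per-ligand binding summary over a bundle's Ki/Kd rows.

    Returns ``{ligand_id: {best_target, best_potency_nM, selectivity_entropy,
    n_targets, cns_mpo}}``; ligands with no binding rows are omitted, and the
    CNS score is None when the six descriptors are not all present.
    """
    by_ligand: dict[str, list[LigandActivity]] = {}
    for row in activities:
        if row.activity_type in _BINDING_TYPES:
            by_ligand.setdefault(row.ligand_id, []).append(row)
    out = {}
    for lig, rows in by_ligand.items():
        props = rows[0].properties
        try:
            cns = cns_mpo(props) if props else None
        except ValueError:
            cns = None
        out[lig] = {
            "best_target": best_target(rows),
            "best_potency_nM": min(r.value for r in rows),
            "selectivity_entropy": selectivity_entropy(rows),
            "n_targets": len({r.target_id for r in rows}),
            "cns_mpo": cns,
        }
    return out
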