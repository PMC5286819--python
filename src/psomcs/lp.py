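"""Linear-programming primitives: FBA, FVA, yield bounds, linear-region
feasibility and production envelopes.

All solves go through scipy's HiGHS backend, which is deterministic and
single-threaded — required for reproducible swarm runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

#: LP feasibility tolerance
FEAS_TOL = 1e-9

#: sentinel magnitude replacing unbounded FVA directions in serialized output
UNBOUNDED_SENTINEL = 1e3


class LPError(RuntimeError):
    pass


@dataclass
class LinearRegion:
    """A polyhedral flux region ``A r <= b`` over the network's reactions."""

    A: np.ndarray
    b: np.ndarray

    def __post_init__(self):
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.b = np.atleast_1d(np.asarray(self.b, dtype=float))
        if self.A.size == 0:
            self.A = self.A.reshape(0, self.A.shape[-1] if self.A.ndim == 2 else 0)
        if self.A.shape[0] != self.b.shape[0]:
            raise ValueError("row count of A does not match b")
        if not (np.all(np.isfinite(self.A)) and np.all(np.isfinite(self.b))):
            raise ValueError("region rows must be finite")

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    @property
    def n_cols(self) -> int:
        return self.A.shape[1]

    @classmethod
    def empty(cls, n_cols: int) -> "LinearRegion":
        return cls(A=np.zeros((0, n_cols)), b=np.zeros(0))

    def stack(self, other: "LinearRegion") -> "LinearRegion":
        return LinearRegion(np.vstack([self.A, other.A]), np.concatenate([self.b, other.b]))

    def fingerprint(self) -> bytes:
        return self.A.tobytes() + b"|" + self.b.tobytes()


@dataclass
class FluxRange:
    reaction_id: str
    min: float
    max: float

    def __post_init__(self):
        if self.min > self.max + 1e-9:
            raise ValueError(f"FluxRange min > max for {self.reaction_id}")


@dataclass
class LPResult:
    status: str  # optimal | infeasible | unbounded
    objective: float = np.nan
    fluxes: np.ndarray = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def _objective_vector(net, objective) -> np.ndarray:
    c = np.zeros(net.n_reactions)
    if isinstance(objective, str):
        objective = {objective: 1.0}
    for rid, coef in objective.items():
        c[net.index(rid)] += coef
    return c


def _solve(net, c, sense, fixed=None, knockouts=(), extra_ub=None, extra_eq=None):
    bounds = list(zip(net.lower_bound, net.upper_bound))
    if fixed:
        for rid, value in fixed.items():
            bounds[net.index(rid)] = (value, value)
    for rid in knockouts:
        bounds[net.index(rid)] = (0.0, 0.0)
    sign = -1.0 if sense == "max" else 1.0
    A_ub = b_ub = None
    if extra_ub is not None and extra_ub[0].shape[0]:
        A_ub, b_ub = extra_ub
    A_eq, b_eq = net.stoich, np.zeros(net.n_metabolites)
    if extra_eq is not None and extra_eq[0].shape[0]:
        A_eq = np.vstack([A_eq, extra_eq[0]])
        b_eq = np.concatenate([b_eq, extra_eq[1]])
    res = linprog(
        sign * c,
        A_ub=A_ub,
        b_ub=b_ub,
        A_eq=A_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
        options={"presolve": True},
    )
    if res.status == 0:
        return LPResult("optimal", sign * res.fun, np.asarray(res.x))
    if res.status == 2:
        return LPResult("infeasible")
    if res.status == 3:
        return LPResult("unbounded")
    raise LPError(f"LP solver failure: {res.message}")


def fba_optimize(net, objective, sense="max", fixed=None, knockouts=(), region=None):
    """Optimize a linear flux functional subject to ``N r = 0``, bounds,
    fixed fluxes, knockouts (``r_i = 0``) and an optional extra linear
    region.  Infeasibility and unboundedness are reported distinctly.
    """
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    c = _objective_vector(net, objective)
    extra_ub = (region.A, region.b) if region is not None else None
    return _solve(net, c, sense, fixed=fixed, knockouts=knockouts, extra_ub=extra_ub)


def flux_variability(net, reactions=None, fixed=None, knockouts=(), region=None):
    """Per-reaction [min, max] flux ranges.  Unbounded directions are
    reported as +/- ``UNBOUNDED_SENTINEL``."""
    if reactions is None:
        reactions = net.reaction_ids
    out = {}
    for rid in reactions:
        lohi = []
        for sense in ("min", "max"):
            res = fba_optimize(net, rid, sense=sense, fixed=fixed, knockouts=knockouts, region=region)
            if res.status == "infeasible":
                raise LPError("FVA on infeasible model")
            if res.status == "unbounded":
                lohi.append(-UNBOUNDED_SENTINEL if sense == "min" else UNBOUNDED_SENTINEL)
            else:
                lohi.append(res.objective)
        out[rid] = (min(lohi), max(lohi))
    return out


def _denominator_row(net, denominator) -> np.ndarray:
    row = np.zeros(net.n_reactions)
    if isinstance(denominator, str):
        denominator = [denominator]
    if isinstance(denominator, dict):
        for rid, coef in denominator.items():
            row[net.index(rid)] += coef
    else:
        for rid in denominator:
            row[net.index(rid)] += 1.0
    return row


def yield_bounds(net, objective_ratios) -> list[FluxRange]:
    """[min, max] achievable yield for each ``(numerator, denominators)``
    ratio, with total denominator flux fixed to 1."""
    out = []
    for numerator, denominator in objective_ratios:
        row = _denominator_row(net, denominator)
        c = _objective_vector(net, numerator)
        extra_eq = (row.reshape(1, -1), np.ones(1))
        lohi = []
        for sense in ("min", "max"):
            res = _solve(net, c, sense, extra_eq=extra_eq)
            if res.status == "infeasible":
                raise LPError(
                    f"denominator of objective {numerator!r} cannot carry unit flux"
                )
            lohi.append(
                res.objective
                if res.status == "optimal"
                else (-UNBOUNDED_SENTINEL if sense == "min" else UNBOUNDED_SENTINEL)
            )
        name = numerator if isinstance(numerator, str) else "+".join(sorted(numerator))
        out.append(FluxRange(name, min(lohi), max(lohi)))
    return out


_region_cache: dict = {}
_net_tokens = iter(range(10**18))


def _net_token(net) -> int:
    # id() can be recycled by the allocator; tag each network once instead
    token = getattr(net, "_lp_token", None)
    if token is None:
        token = next(_net_tokens)
        net._lp_token = token
    return token


def region_feasible(net, region: LinearRegion, knockouts=(), use_cache=True) -> bool:
    """True iff some flux vector satisfies ``N r = 0``, the network bounds,
    ``A r <= b`` and ``r_i = 0`` for all knockouts."""
    if region.n_cols != net.n_reactions:
        raise ValueError("region column count does not match network")
    key = None
    if use_cache:
        key = (_net_token(net), region.fingerprint(), tuple(sorted(knockouts)))
        hit = _region_cache.get(key)
        if hit is not None:
            return hit
    res = _solve(net, np.zeros(net.n_reactions), "min", knockouts=knockouts,
                 extra_ub=(region.A, region.b))
    feasible = res.status != "infeasible"
    if key is not None:
        if len(_region_cache) > 100_000:
            _region_cache.clear()
        _region_cache[key] = feasible
    return feasible


def production_envelope(net, product, growth, knockouts=(), n_points=20, reference=None):
    """FVA production envelope over a growth grid.

    Returns ``(rows, face)`` where ``rows`` is a list of
    ``(growth_value, product_min, product_max)`` for ``n_points`` growth
    values between 0 and the maximal growth, and ``face`` is the
    ``(product_min, product_max)`` pair at exactly maximal growth.  When
    ``reference`` names denominator reactions, their summed flux is fixed
    to 1 so all values are yields.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    extra_eq = None
    if reference is not None:
        row = _denominator_row(net, reference)
        extra_eq = (row.reshape(1, -1), np.ones(1))
    c_growth = _objective_vector(net, growth)
    res = _solve(net, c_growth, "max", knockouts=knockouts, extra_eq=extra_eq)
    if res.status == "infeasible":
        raise LPError("model infeasible under the given knockouts")
    mu_max = res.objective if res.status == "optimal" else UNBOUNDED_SENTINEL
    mu_min_res = _solve(net, c_growth, "min", knockouts=knockouts, extra_eq=extra_eq)
    mu_min = max(0.0, mu_min_res.objective) if mu_min_res.status == "optimal" else 0.0
    mu_max = max(mu_max, mu_min)

    c_prod = _objective_vector(net, product)
    rows = []
    for mu in np.linspace(mu_min, mu_max, n_points):
        eq_rows = [c_growth.reshape(1, -1)]
        eq_vals = [np.array([mu])]
        if extra_eq is not None:
            eq_rows.append(extra_eq[0])
            eq_vals.append(extra_eq[1])
        eq = (np.vstack(eq_rows), np.concatenate(eq_vals))
        lo = _solve(net, c_prod, "min", knockouts=knockouts, extra_eq=eq)
        hi = _solve(net, c_prod, "max", knockouts=knockouts, extra_eq=eq)
        if lo.status == "infeasible" or hi.status == "infeasible":
            continue
        pmin = lo.objective if lo.status == "optimal" else -UNBOUNDED_SENTINEL
        pmax = hi.objective if hi.status == "optimal" else UNBOUNDED_SENTINEL
        rows.append((float(mu), float(pmin), float(pmax)))
    face = (rows[-1][1], rows[-1][2]) if rows else (np.nan, np.nan)
    return rows, face
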