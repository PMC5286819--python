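"""Cut sets from the dual of the stoichiometric system.

The target region ``{r : N r = 0, r_irr >= 0, T r <= t}`` is infeasible
exactly when a Farkas certificate ``(u, w)`` exists with
``N^T u + T^T w = 0`` on reversible coordinates, ``>= 0`` on irreversible
ones, and ``t^T w <= -c`` for some ``c > 0``.  Relaxing the certificate
rows of knocked-out reactions with a signed slack pair ``vp - vn`` turns
the support of ``(vp, vn)`` into the knockout set: minimizing the number
of nonzero slacks (via binary indicators ``zp, zn``) yields a minimal cut
set.  Embedding the primal desired system ``N r = 0, D r <= d`` with the
coupling ``r_i = 0`` whenever reaction ``i`` is cut makes the result a
*constrained* MCS: the desired behaviour survives the knockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, Bounds, milp

from .lp import LinearRegion, fba_optimize, region_feasible
from .design import InterventionProblem

#: big-M for indicator linearization; too small a value can silently drop
#: cut sets whose certificates need large dual multipliers
BIG_M = 1000.0

#: fixed strictness constant of the certificate row t^T w <= -c; the dual
#: is homogeneous in (u, vp, vn, w), so any positive value gives the same
#: supports *provided* the big-M bounds leave headroom: certificates scale
#: like strict_c / (target strictness margin), so keep strict_c small
STRICT_C = 0.01

#: magnitude replacing infinite flux bounds inside the MILP
FLUX_CAP = 1000.0


class DualError(ValueError):
    pass


class BudgetExceeded(RuntimeError):
    """Solver hit its time/node budget; distinct from proven infeasibility."""


@dataclass
class CutSet:
    """A knockout set with validity/minimality status."""

    reactions: frozenset
    valid: bool = None
    minimal: bool = None
    witness_flux: np.ndarray = None

    def __post_init__(self):
        self.reactions = frozenset(self.reactions)

    @property
    def cardinality(self) -> int:
        return len(self.reactions)

    def sorted(self) -> list:
        return sorted(self.reactions)

    def __contains__(self, rid) -> bool:
        return rid in self.reactions


@dataclass
class DualSystem:
    """MILP instance data for one intervention problem.

    Variable layout: ``u (m) | vp (n) | vn (n) | w (t_rows) | r (n) |
    zp (n) | zn (n)``; the first four groups are the certificate, ``r`` the
    embedded desired-region flux vector, ``zp/zn`` the knockout indicators.
    """

    net: object
    problem: InterventionProblem
    max_cardinality: int
    big_m: float = BIG_M
    strict_c: float = STRICT_C

    def __post_init__(self):
        n, m = self.net.n_reactions, self.net.n_metabolites
        if self.problem.target.n_cols != n:
            raise DualError("intervention problem dimensions do not match network")
        self.m, self.n = m, n
        self.t_rows = self.problem.target.n_rows
        self.d_rows = self.problem.desired.n_rows
        self.off_u = 0
        self.off_vp = m
        self.off_vn = m + n
        self.off_w = m + 2 * n
        self.off_r = m + 2 * n + self.t_rows
        self.off_zp = self.off_r + n
        self.off_zn = self.off_zp + n
        self.n_vars = self.off_zn + n
        self.n_continuous = m + 3 * n + self.t_rows
        self.n_binary = 2 * n

    @property
    def core_row_count(self) -> int:
        """Rows of the combined certificate/primal block: n dual reaction
        rows + m steady-state rows + desired rows + the strictness row."""
        return self.n + self.m + self.d_rows + 1

    # -- constraint assembly ------------------------------------------

    def _core_constraints(self):
        net, n, m = self.net, self.n, self.m
        T, t = self.problem.target.A, self.problem.target.b
        D, d = self.problem.desired.A, self.problem.desired.b
        M = self.big_m

        rows, lo, hi = [], [], []

        def add(block, lb, ub):
            rows.append(block)
            lo.append(lb)
            hi.append(ub)

        eye = sparse.identity(n, format="csr")
        zeros = lambda r, c: sparse.csr_matrix((r, c))

        # dual reaction rows: N^T u + vp - vn + T^T w  (= 0 rev, >= 0 irr)
        dual_block = sparse.hstack(
            [sparse.csr_matrix(net.stoich.T), eye, -eye, sparse.csr_matrix(T.T),
             zeros(n, 3 * n)],
            format="csr",
        )
        rev = net.reversible
        add(dual_block, np.where(rev, 0.0, 0.0), np.where(rev, 0.0, np.inf))

        # strictness row: t^T w <= -c
        strict = sparse.hstack(
            [zeros(1, m + 2 * n), sparse.csr_matrix(t.reshape(1, -1)), zeros(1, 3 * n)],
            format="csr",
        )
        add(strict, np.array([-np.inf]), np.array([-self.strict_c]))

        # primal steady state: N r = 0
        prim = sparse.hstack(
            [zeros(m, m + 2 * n + self.t_rows), sparse.csr_matrix(net.stoich),
             zeros(m, 2 * n)],
            format="csr",
        )
        add(prim, np.zeros(m), np.zeros(m))

        # desired region: D r <= d
        if self.d_rows:
            des = sparse.hstack(
                [zeros(self.d_rows, m + 2 * n + self.t_rows), sparse.csr_matrix(D),
                 zeros(self.d_rows, 2 * n)],
                format="csr",
            )
            add(des, np.full(self.d_rows, -np.inf), d)

        # indicator linking: vp <= M zp, vn <= M zn
        link_p = sparse.hstack(
            [zeros(n, m), eye, zeros(n, n + self.t_rows + n), -M * eye, zeros(n, n)],
            format="csr",
        )
        add(link_p, np.full(n, -np.inf), np.zeros(n))
        link_n = sparse.hstack(
            [zeros(n, m + n), eye, zeros(n, self.t_rows + n + n), -M * eye],
            format="csr",
        )
        add(link_n, np.full(n, -np.inf), np.zeros(n))

        # exclusivity: zp + zn <= 1
        excl = sparse.hstack(
            [zeros(n, self.off_zp), eye, eye], format="csr"
        )
        add(excl, np.full(n, -np.inf), np.ones(n))

        # flux/knockout coupling: lb(1 - zp - zn) <= r <= ub(1 - zp - zn)
        lb_r, ub_r = self._flux_bounds()
        cup = sparse.hstack(
            [zeros(n, self.off_r), eye, sparse.diags(ub_r), sparse.diags(ub_r)],
            format="csr",
        )
        add(cup, np.full(n, -np.inf), ub_r)
        cdn = sparse.hstack(
            [zeros(n, self.off_r), eye, sparse.diags(lb_r), sparse.diags(lb_r)],
            format="csr",
        )
        add(cdn, lb_r, np.full(n, np.inf))

        # cardinality cap
        card = sparse.csr_matrix(
            (np.ones(2 * n), (np.zeros(2 * n, dtype=int),
                              np.arange(self.off_zp, self.n_vars))),
            shape=(1, self.n_vars),
        )
        add(card, np.array([-np.inf]), np.array([float(self.max_cardinality)]))

        return rows, lo, hi

    def _flux_bounds(self):
        lb = np.clip(self.net.lower_bound, -FLUX_CAP, FLUX_CAP)
        ub = np.clip(self.net.upper_bound, -FLUX_CAP, FLUX_CAP)
        return lb, ub

    def _variable_bounds(self, forced_out=()):
        M = self.big_m
        lo = np.concatenate(
            [
                np.full(self.m, -M),  # u
                np.zeros(2 * self.n),  # vp, vn
                np.zeros(self.t_rows),  # w
                self._flux_bounds()[0],  # r
                np.zeros(2 * self.n),  # zp, zn
            ]
        )
        hi = np.concatenate(
            [
                np.full(self.m, M),
                np.full(2 * self.n, M),
                np.full(self.t_rows, M),
                self._flux_bounds()[1],
                np.ones(2 * self.n),
            ]
        )
        blocked = ~self.net.knockout_allowed.copy()
        for rid in forced_out:
            blocked[self.net.index(rid)] = True
        hi[self.off_zp : self.off_zp + self.n][blocked] = 0.0
        hi[self.off_zn : self.off_zn + self.n][blocked] = 0.0
        return lo, hi

    def _z_row(self, indices):
        cols = np.concatenate(
            [self.off_zp + np.asarray(indices), self.off_zn + np.asarray(indices)]
        )
        return sparse.csr_matrix(
            (np.ones(cols.size), (np.zeros(cols.size, dtype=int), cols)),
            shape=(1, self.n_vars),
        )


def build_dual(net, problem: InterventionProblem, max_cardinality: int,
               big_m: float = BIG_M) -> DualSystem:
    """Assemble the combined certificate/primal MILP for one design point."""
    if max_cardinality < 0:
        raise DualError("max_cardinality must be >= 0")
    return DualSystem(net=net, problem=problem, max_cardinality=max_cardinality,
                      big_m=big_m)


def _solve_instance(dual: DualSystem, exclusions, forced_in, forced_out,
                    time_limit=None):
    rows, lo, hi = dual._core_constraints()
    for S in exclusions:
        reactions = S.reactions if isinstance(S, CutSet) else S
        idx = dual.net.indices(reactions)
        rows.append(dual._z_row(idx))
        lo.append(np.array([-np.inf]))
        hi.append(np.array([float(len(idx) - 1)]))
    for rid in forced_in:
        rows.append(dual._z_row([dual.net.index(rid)]))
        lo.append(np.array([1.0]))
        hi.append(np.array([1.0]))

    A = sparse.vstack(rows, format="csc")
    constraint = LinearConstraint(A, np.concatenate(lo), np.concatenate(hi))

    c = np.zeros(dual.n_vars)
    c[dual.off_zp :] = 1.0
    integrality = np.zeros(dual.n_vars)
    integrality[dual.off_zp :] = 1
    blo, bhi = dual._variable_bounds(forced_out=forced_out)

    options = {"mip_rel_gap": 0.0}
    if time_limit is not None:
        options["time_limit"] = float(time_limit)
    res = milp(
        c,
        constraints=[constraint],
        integrality=integrality,
        bounds=Bounds(blo, bhi),
        options=options,
    )
    if res.status == 1:
        raise BudgetExceeded("MILP time/iteration budget exceeded")
    if res.status != 0 or res.x is None:
        return None
    z = res.x[dual.off_zp : dual.off_zp + dual.n] + res.x[dual.off_zn :]
    support = frozenset(
        dual.net.reaction_ids[i] for i in np.flatnonzero(z > 0.5)
    )
    return support


def solve_cmcs(dual: DualSystem, exclusions=(), tie_break: str = "solver",
               time_limit=None):
    """One minimum-cardinality cut set for the instance, or ``None`` when no
    cut set within the cardinality cap exists.

    ``exclusions`` are previously found sets, encoded as no-good cuts
    ``sum_{i in S} (zp_i + zn_i) <= |S| - 1`` (also bars supersets).
    ``tie_break='lex'`` refines the answer deterministically to the
    lexicographically smallest optimal support (extra solves).
    """
    support = _solve_instance(dual, exclusions, (), (), time_limit=time_limit)
    if support is None:
        return None
    if tie_break == "solver" or len(support) == 0:
        return CutSet(support)
    if tie_break != "lex":
        raise ValueError("tie_break must be 'solver' or 'lex'")

    k = len(support)
    forced_in: list = []
    forced_out: list = []
    candidates = sorted(
        rid
        for rid, ok in zip(dual.net.reaction_ids, dual.net.knockout_allowed)
        if ok
    )
    for rid in candidates:
        if len(forced_in) == k:
            break
        trial = _solve_instance(dual, exclusions, forced_in + [rid], forced_out,
                                time_limit=time_limit)
        if trial is not None and len(trial) == k:
            forced_in.append(rid)
        else:
            forced_out.append(rid)
    if len(forced_in) != k:  # numerically flaky refinement; keep first answer
        return CutSet(support)
    return CutSet(frozenset(forced_in))


def validate_cutset(net, problem: InterventionProblem, cs: CutSet) -> CutSet:
    """Set ``valid``: the knockout must make the target region infeasible
    while the desired region stays feasible; stores a desired witness."""
    knockouts = set(cs.reactions)
    target_gone = not region_feasible(net, problem.target, knockouts=knockouts)
    cs.valid = False
    cs.witness_flux = None
    if target_gone:
        res = fba_optimize(net, {}, sense="min", knockouts=knockouts,
                           region=problem.desired)
        if res.status != "infeasible":
            cs.valid = True
            cs.witness_flux = res.fluxes
    return cs


def check_minimality(net, problem: InterventionProblem, cs: CutSet) -> CutSet:
    """Set ``minimal``: no single-element-removed subset may itself be
    valid.  Sufficient because the cutting property is superset-monotone
    and desired-region survival is subset-monotone."""
    if not cs.valid:
        raise DualError("minimality is only defined for valid cut sets")
    cs.minimal = True
    for rid in cs.sorted():
        sub = CutSet(cs.reactions - {rid})
        validate_cutset(net, problem, sub)
        if sub.valid:
            cs.minimal = False
            break
    return cs


def enumerate_minimum_cmcs(net, problem: InterventionProblem, max_cardinality: int,
                           big_m: float = BIG_M, limit: int = 1000,
                           tie_break: str = "solver"):
    """Exhaust the minimum-cardinality stratum by iterating no-good cuts."""
    dual = build_dual(net, problem, max_cardinality, big_m=big_m)
    found: list[CutSet] = []
    k = None
    while len(found) < limit:
        cs = solve_cmcs(dual, exclusions=found, tie_break=tie_break)
        if cs is None:
            break
        if k is None:
            k = cs.cardinality
        elif cs.cardinality > k:
            break
        if k == 0:
            validate_cutset(net, problem, cs)
            return [cs]
        validate_cutset(net, problem, cs)
        found.append(cs)
    return found
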