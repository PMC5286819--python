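"""Fixtures and ground truth: the toy demonstration network, a random
small-network generator, and exhaustive brute-force oracles for cut sets
and optimal designs."""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .design import DesignSpec, Objective, build_intervention
from .dual import CutSet, validate_cutset
from .lp import fba_optimize, region_feasible, yield_bounds
from .network import MetabolicNetwork, loads_tabular
from .pso import fitness as fitness_fn

#: guard on the number of LP solves an oracle call may trigger
ORACLE_LP_GUARD = 200_000

# Toy demonstration network: three substrate inputs (R1-R3), three
# secretions (R4, R7, R8), an internal hub metabolite B fed by R2 and R9
# whose drains R5/R6 lead to the two non-product secretions.  Cutting
# {R2, R9} starves B, blocks R5 and R6 and funnels everything into the
# product secretion R4 at yield 1.
_TOY_TABULAR = """\
# id  rev  stoichiometry
R1  irr  A:1
R2  irr  B:1
R3  irr  A:1
R4  irr  A:-1
R5  irr  B:-1,C:1
R6  irr  B:-1,D:1
R7  irr  C:-1
R8  irr  D:-1
R9  irr  A:-1,B:1
"""

TOY_INPUTS = ("R1", "R2", "R3")
TOY_PRODUCT = "R4"


def toy_network() -> MetabolicNetwork:
    """The 9-reaction, 4-metabolite demonstration network."""
    return loads_tabular(_TOY_TABULAR)


def toy_design() -> DesignSpec:
    """Single objective: maximize the guaranteed yield of R4 per unit total
    substrate uptake (R1 + R2 + R3)."""
    return DesignSpec(
        objectives=[Objective(name="product", numerator=TOY_PRODUCT,
                              role="product_min_yield")],
        reference=list(TOY_INPUTS),
    )


@dataclass
class RandomNetworkSpec:
    m: int = 6
    n: int = 10
    branching: float = 0.3
    fraction_reversible: float = 0.2
    n_exchange: int = 3
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need at least 2 metabolites")
        if self.n < self.m + 1:
            raise ValueError("need n >= m + 1 reactions for a viable backbone")
        if self.n_exchange < 2:
            raise ValueError("need at least one uptake and one secretion")


def generate_random_network(spec: RandomNetworkSpec) -> MetabolicNetwork:
    """Sparse integer-coefficient network, consistency-checked by FBA.

    Structure: one uptake into the first metabolite, one secretion from the
    last, a backbone chain of conversions, then random extra conversions
    and exchanges.  Deterministic per seed; retries with derived seeds when
    a draw is inconsistent.
    """
    for attempt in range(spec.max_retries):
        rng = np.random.default_rng((spec.seed, attempt))
        net = _draw_network(spec, rng)
        if net is None:
            continue
        res = fba_optimize(net, {net.reaction_ids[-1]: 1.0}, sense="max",
                           fixed={net.reaction_ids[0]: 1.0})
        if res.status == "optimal" and res.objective > 1e-6:
            return net
    raise RuntimeError(f"no consistent network after {spec.max_retries} draws")


def _draw_network(spec: RandomNetworkSpec, rng) -> MetabolicNetwork:
    m, n = spec.m, spec.n
    cols = []
    rev = []

    def col(entries):
        c = np.zeros(m)
        for met, coef in entries:
            c[met] += coef
        return c

    # uptake -> M0, secretion from M_{m-1}
    cols.append(col([(0, 1.0)]))
    rev.append(False)
    cols.append(col([(m - 1, -1.0)]))
    rev.append(False)

    # backbone chain M_i -> M_{i+1}
    n_chain = min(m - 1, n - 2)
    for i in range(n_chain):
        cols.append(col([(i, -1.0), (i + 1, 1.0)]))
        rev.append(bool(rng.random() < spec.fraction_reversible))

    # extra exchanges: secretions from random metabolites (plus rare uptakes)
    n_extra_exch = max(0, min(spec.n_exchange - 2, n - len(cols)))
    for _ in range(n_extra_exch):
        met = int(rng.integers(m))
        sign = -1.0 if rng.random() < 0.8 else 1.0
        cols.append(col([(met, sign)]))
        rev.append(False)

    # remaining: random internal conversions
    while len(cols) < n:
        n_sub = 1 + int(rng.random() < spec.branching)
        n_prod = 1 + int(rng.random() < spec.branching)
        mets = rng.choice(m, size=n_sub + n_prod, replace=False)
        entries = [(int(mm), -float(rng.integers(1, 3))) for mm in mets[:n_sub]]
        entries += [(int(mm), float(rng.integers(1, 3))) for mm in mets[n_sub:]]
        c = col(entries)
        if np.count_nonzero(c) < 2:
            continue
        cols.append(c)
        rev.append(bool(rng.random() < spec.fraction_reversible))

    stoich = np.column_stack(cols)
    if np.any(np.all(stoich == 0, axis=0)):
        return None
    rev = np.array(rev)
    from .network import DEFAULT_BOUND

    return MetabolicNetwork(
        stoich=stoich,
        reaction_ids=[f"R{i+1}" for i in range(n)],
        metabolite_ids=[f"M{i}" for i in range(m)],
        reversible=rev,
        lower_bound=np.where(rev, -DEFAULT_BOUND, 0.0),
        upper_bound=np.full(n, DEFAULT_BOUND),
    )


def random_design(net: MetabolicNetwork) -> DesignSpec:
    """A product-yield design over the generator's conventions: total
    substrate uptake (all importing exchanges) is the reference, the
    backbone secretion R2 the product."""
    uptakes = []
    for j in np.flatnonzero(net.is_exchange):
        coef = net.stoich[np.flatnonzero(net.stoich[:, j])[0], j]
        if coef > 0 and net.upper_bound[j] > 0:
            uptakes.append(net.reaction_ids[j])
    return DesignSpec(
        objectives=[Objective(name="product", numerator=net.reaction_ids[1],
                              role="product_min_yield")],
        reference=uptakes,
    )


def brute_force_cmcs(net, problem, max_k: int, lp_guard: int = ORACLE_LP_GUARD):
    """All minimal valid cut sets of cardinality <= ``max_k`` by exhaustive
    subset enumeration with two LP feasibility checks per subset."""
    candidates = [rid for rid, ok in zip(net.reaction_ids, net.knockout_allowed) if ok]
    total = sum(
        _n_choose_k(len(candidates), k) for k in range(0, max_k + 1)
    )
    if 2 * total > lp_guard:
        raise RuntimeError(f"oracle guard exceeded: {2 * total} LP solves required")

    catalogue: list[CutSet] = []
    for k in range(0, max_k + 1):
        for combo in itertools.combinations(candidates, k):
            s = frozenset(combo)
            if any(found.reactions <= s for found in catalogue):
                continue  # superset of a known valid set: not minimal
            cs = CutSet(s)
            validate_cutset(net, problem, cs)
            if cs.valid:
                cs.minimal = True
                catalogue.append(cs)
    return catalogue


def _n_choose_k(n: int, k: int) -> int:
    import math

    return math.comb(n, k)


def brute_force_optimal_design(net, spec: DesignSpec, grid_points: int = 21,
                               max_k: int = 5, bounds=None,
                               lp_guard: int = ORACLE_LP_GUARD):
    """Grid-search oracle for the best achievable design.

    Evaluates the fitness at every grid point via ``brute_force_cmcs`` and
    returns ``(x, catalogue_best_cutset, fitness)`` for the grid optimum.
    Guarded to ``j <= 2`` dimensions.
    """
    if spec.j > 2:
        raise RuntimeError("oracle grid search is guarded to j <= 2")
    if bounds is None:
        ranges = yield_bounds(net, spec.ratios())
        bounds = [(fr.min, fr.max) for fr in ranges]
    x_max = np.array([hi for _, hi in bounds])
    axes = [np.linspace(lo, hi, grid_points) for lo, hi in bounds]

    best = (None, None, -np.inf)
    for point in itertools.product(*axes):
        x = np.array(point)
        problem = build_intervention(spec, x, net)
        if not region_feasible(net, problem.desired):
            continue
        catalogue = brute_force_cmcs(net, problem, max_k, lp_guard=lp_guard)
        if not catalogue:
            continue
        cs = min(catalogue, key=lambda c: (c.cardinality, c.sorted()))
        f = fitness_fn(x, cs, x_max, net.n_reactions)
        if f > best[2]:
            best = (x, cs, f)
    return best
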