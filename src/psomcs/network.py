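"""Metabolic network container plus loading, reduction, compression and
knockout-exclusion bookkeeping.

A network is a stoichiometric matrix ``N`` (m metabolites x n reactions)
at steady state (``N r = 0``) with a reversibility partition: irreversible
reactions satisfy ``r_i >= 0``.  Exchange reactions are detected
structurally as columns with a single nonzero entry.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import numpy as np

#: default magnitude used for unspecified flux bounds
DEFAULT_BOUND = 1000.0

#: |flux| below this is treated as zero when detecting blocked reactions
BLOCKED_TOL = 1e-9

#: relative tolerance for proportionality of null-space rows
SUBSET_RTOL = 1e-8

#: a knockout is "essential for" a protected reaction when the protected
#: reaction's maximal flux drops below this
ESSENTIAL_TOL = 1e-6


class NetworkError(ValueError):
    """Malformed model input or violated structural invariant."""


@dataclass
class MetabolicNetwork:
    """Stoichiometric model with reversibility, bounds and annotations.

    Attributes
    ----------
    stoich : (m, n) ndarray
        Stoichiometric coefficients, one column per reaction.
    reaction_ids, metabolite_ids : list of str
        Unique identifiers for columns and rows.
    reversible : (n,) bool ndarray
        ``True`` for reversible reactions; irreversible ones carry
        ``lower_bound >= 0``.
    lower_bound, upper_bound : (n,) float ndarray
        Flux bounds in model units.
    is_exchange, is_spontaneous, knockout_allowed : (n,) bool ndarray
        Structural/annotation flags.  ``knockout_allowed`` is the single
        source of truth for which reactions may enter a cut set.
    """

    stoich: np.ndarray
    reaction_ids: list[str]
    metabolite_ids: list[str]
    reversible: np.ndarray
    lower_bound: np.ndarray
    upper_bound: np.ndarray
    is_exchange: np.ndarray = None
    is_spontaneous: np.ndarray = None
    knockout_allowed: np.ndarray = None

    def __post_init__(self):
        self.stoich = np.asarray(self.stoich, dtype=float)
        self.reversible = np.asarray(self.reversible, dtype=bool)
        self.lower_bound = np.asarray(self.lower_bound, dtype=float)
        self.upper_bound = np.asarray(self.upper_bound, dtype=float)
        if self.is_exchange is None:
            self.is_exchange = detect_exchanges(self.stoich)
        else:
            self.is_exchange = np.asarray(self.is_exchange, dtype=bool)
        if self.is_spontaneous is None:
            self.is_spontaneous = np.zeros(self.n_reactions, dtype=bool)
        else:
            self.is_spontaneous = np.asarray(self.is_spontaneous, dtype=bool)
        if self.knockout_allowed is None:
            self.knockout_allowed = np.ones(self.n_reactions, dtype=bool)
        else:
            self.knockout_allowed = np.asarray(self.knockout_allowed, dtype=bool)
        self.validate()

    # -- bookkeeping ---------------------------------------------------

    @property
    def n_metabolites(self) -> int:
        return self.stoich.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoich.shape[1]

    def index(self, reaction_id: str) -> int:
        try:
            return self.reaction_ids.index(reaction_id)
        except ValueError:
            raise NetworkError(f"unknown reaction id: {reaction_id!r}") from None

    def indices(self, reaction_ids) -> list[int]:
        return [self.index(r) for r in reaction_ids]

    def copy(self) -> "MetabolicNetwork":
        return MetabolicNetwork(
            stoich=self.stoich.copy(),
            reaction_ids=list(self.reaction_ids),
            metabolite_ids=list(self.metabolite_ids),
            reversible=self.reversible.copy(),
            lower_bound=self.lower_bound.copy(),
            upper_bound=self.upper_bound.copy(),
            is_exchange=self.is_exchange.copy(),
            is_spontaneous=self.is_spontaneous.copy(),
            knockout_allowed=self.knockout_allowed.copy(),
        )

    def validate(self) -> None:
        m, n = self.stoich.shape
        if len(self.reaction_ids) != n:
            raise NetworkError("reaction_ids length does not match column count")
        if len(self.metabolite_ids) != m:
            raise NetworkError("metabolite_ids length does not match row count")
        if len(set(self.reaction_ids)) != n:
            raise NetworkError("duplicate reaction identifiers")
        if len(set(self.metabolite_ids)) != m:
            raise NetworkError("duplicate metabolite identifiers")
        for arr, name in [
            (self.reversible, "reversible"),
            (self.lower_bound, "lower_bound"),
            (self.upper_bound, "upper_bound"),
            (self.is_exchange, "is_exchange"),
            (self.is_spontaneous, "is_spontaneous"),
            (self.knockout_allowed, "knockout_allowed"),
        ]:
            if arr.shape != (n,):
                raise NetworkError(f"{name} has wrong shape {arr.shape}")
        if np.any(self.lower_bound > self.upper_bound):
            raise NetworkError("lower_bound exceeds upper_bound")
        bad = ~self.reversible & (self.lower_bound < 0)
        if np.any(bad):
            ids = [self.reaction_ids[i] for i in np.flatnonzero(bad)]
            raise NetworkError(f"irreversible reactions with negative lower bound: {ids}")

    def subnetwork(self, keep_reactions: np.ndarray, keep_metabolites=None) -> "MetabolicNetwork":
        """Restrict to a boolean reaction mask, dropping orphaned metabolites."""
        keep_reactions = np.asarray(keep_reactions, dtype=bool)
        sub = self.stoich[:, keep_reactions]
        if keep_metabolites is None:
            keep_metabolites = np.any(sub != 0, axis=1)
        return MetabolicNetwork(
            stoich=sub[keep_metabolites, :],
            reaction_ids=[r for r, k in zip(self.reaction_ids, keep_reactions) if k],
            metabolite_ids=[m for m, k in zip(self.metabolite_ids, keep_metabolites) if k],
            reversible=self.reversible[keep_reactions],
            lower_bound=self.lower_bound[keep_reactions],
            upper_bound=self.upper_bound[keep_reactions],
            is_exchange=self.is_exchange[keep_reactions],
            is_spontaneous=self.is_spontaneous[keep_reactions],
            knockout_allowed=self.knockout_allowed[keep_reactions],
        )


def detect_exchanges(stoich: np.ndarray) -> np.ndarray:
    """Columns with a single nonzero stoichiometric entry are exchanges."""
    return np.count_nonzero(np.asarray(stoich), axis=0) == 1


@dataclass
class CompressionMap:
    """Record of a subset-compression step.

    ``subset_members`` maps each compressed reaction id to the list of
    ``(original_id, coefficient)`` pairs such that member fluxes relate to
    the compressed flux ``s`` by ``r_member = coefficient * s``.
    Identity-mapped reactions appear with a single member of coefficient 1.
    """

    subset_members: dict = field(default_factory=dict)
    removed_blocked: list = field(default_factory=list)

    def members(self, compressed_id: str) -> list:
        return self.subset_members[compressed_id]

    def decompress(self, cut_reactions, allowed=None) -> set:
        """Map compressed cut-set ids to one knockable original reaction each.

        Knocking out any member of a subset removes the whole subset flux;
        when ``allowed`` (a set of knockable original ids) is given, the
        first knockable member is preferred.
        """
        out = set()
        for cid in cut_reactions:
            members = [rid for rid, _ in self.subset_members[cid]]
            pick = members[0]
            if allowed is not None:
                for rid in members:
                    if rid in allowed:
                        pick = rid
                        break
            out.add(pick)
        return out

    def expand(self, cut_reactions) -> set:
        """All original members of the given compressed reactions."""
        out = set()
        for cid in cut_reactions:
            out.update(rid for rid, _ in self.subset_members[cid])
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "subset_members": {
                    k: [[rid, float(c)] for rid, c in v]
                    for k, v in self.subset_members.items()
                },
                "removed_blocked": list(self.removed_blocked),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "CompressionMap":
        raw = json.loads(text)
        return cls(
            subset_members={
                k: [(rid, float(c)) for rid, c in v]
                for k, v in raw["subset_members"].items()
            },
            removed_blocked=list(raw["removed_blocked"]),
        )


# ---------------------------------------------------------------------------
# loading


def load_network(source, dialect: str = "tabular", spontaneous=()) -> MetabolicNetwork:
    """Load a model file in the named dialect (``tabular`` or ``sbml``).

    ``spontaneous`` is an optional iterable of reaction ids flagged as
    spontaneous (no standard SBML flag exists for this annotation).
    """
    if dialect == "tabular":
        with open(source) as fh:
            return loads_tabular(fh.read(), spontaneous=spontaneous)
    if dialect == "sbml":
        return _load_sbml(source, spontaneous=spontaneous)
    raise NetworkError(f"unknown dialect: {dialect!r}")


def loads_tabular(text: str, spontaneous=()) -> MetabolicNetwork:
    """Parse the tabular fixture dialect.

    One whitespace-separated row per reaction::

        <id> <rev|irr> <met:coef[,met:coef...]> [<lb> <ub>]

    Lines starting with ``#`` are comments.  Coefficients are signed;
    positive means the reaction produces the metabolite.
    """
    reaction_ids, reversible, lbs, ubs = [], [], [], []
    columns = []  # list of dict met -> coef
    met_order: dict[str, None] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) not in (3, 5):
            raise NetworkError(f"line {lineno}: expected 3 or 5 fields, got {len(parts)}")
        rid, rev, stoich_field = parts[:3]
        if rid in reaction_ids:
            raise NetworkError(f"line {lineno}: duplicate reaction id {rid!r}")
        if rev not in ("rev", "irr"):
            raise NetworkError(f"line {lineno}: reversibility must be 'rev' or 'irr'")
        col = {}
        for pair in stoich_field.split(","):
            met, _, coef = pair.partition(":")
            if not met or not coef:
                raise NetworkError(f"line {lineno}: malformed stoichiometry {pair!r}")
            col[met] = col.get(met, 0.0) + float(coef)
            met_order.setdefault(met, None)
        is_rev = rev == "rev"
        if len(parts) == 5:
            lb, ub = float(parts[3]), float(parts[4])
        else:
            lb = -DEFAULT_BOUND if is_rev else 0.0
            ub = DEFAULT_BOUND
        reaction_ids.append(rid)
        reversible.append(is_rev)
        lbs.append(lb)
        ubs.append(ub)
        columns.append(col)

    metabolite_ids = list(met_order)
    stoich = np.zeros((len(metabolite_ids), len(reaction_ids)))
    met_index = {m: i for i, m in enumerate(metabolite_ids)}
    for j, col in enumerate(columns):
        for met, coef in col.items():
            stoich[met_index[met], j] = coef

    net = MetabolicNetwork(
        stoich=stoich,
        reaction_ids=reaction_ids,
        metabolite_ids=metabolite_ids,
        reversible=np.array(reversible),
        lower_bound=np.array(lbs),
        upper_bound=np.array(ubs),
    )
    _apply_spontaneous(net, spontaneous)
    return net


def dumps_tabular(net: MetabolicNetwork) -> str:
    """Serialize a network to the tabular fixture dialect."""
    lines = ["# id  rev  stoichiometry  lb  ub"]
    for j, rid in enumerate(net.reaction_ids):
        entries = ",".join(
            f"{net.metabolite_ids[i]}:{net.stoich[i, j]:g}"
            for i in np.flatnonzero(net.stoich[:, j])
        )
        rev = "rev" if net.reversible[j] else "irr"
        lines.append(
            f"{rid}  {rev}  {entries}  {net.lower_bound[j]:g}  {net.upper_bound[j]:g}"
        )
    return "\n".join(lines) + "\n"


def _apply_spontaneous(net: MetabolicNetwork, spontaneous) -> None:
    for rid in spontaneous:
        net.is_spontaneous[net.index(rid)] = True


def _load_sbml(source, spontaneous=()) -> MetabolicNetwork:
    import cobra.io

    model = cobra.io.read_sbml_model(str(source))
    return from_cobra(model, spontaneous=spontaneous)


def from_cobra(model, spontaneous=()) -> MetabolicNetwork:
    """Convert a cobrapy model (metabolite rows are internal metabolites)."""
    mets = [m.id for m in model.metabolites]
    if len(set(mets)) != len(mets):
        raise NetworkError("duplicate metabolite identifiers in SBML model")
    rxns = [r.id for r in model.reactions]
    if len(set(rxns)) != len(rxns):
        raise NetworkError("duplicate reaction identifiers in SBML model")
    met_index = {m: i for i, m in enumerate(mets)}
    stoich = np.zeros((len(mets), len(rxns)))
    lbs = np.zeros(len(rxns))
    ubs = np.zeros(len(rxns))
    rev = np.zeros(len(rxns), dtype=bool)
    for j, rxn in enumerate(model.reactions):
        for met, coef in rxn.metabolites.items():
            stoich[met_index[met.id], j] = coef
        lbs[j], ubs[j] = rxn.lower_bound, rxn.upper_bound
        rev[j] = rxn.lower_bound < 0
    net = MetabolicNetwork(
        stoich=stoich,
        reaction_ids=rxns,
        metabolite_ids=mets,
        reversible=rev,
        lower_bound=np.clip(lbs, -DEFAULT_BOUND, DEFAULT_BOUND),
        upper_bound=np.clip(ubs, -DEFAULT_BOUND, DEFAULT_BOUND),
    )
    _apply_spontaneous(net, spontaneous)
    return net


# ---------------------------------------------------------------------------
# reduction


def reduce_to_condition(net: MetabolicNetwork, medium) -> MetabolicNetwork:
    """Close all uptake exchanges outside ``medium``, then drop blocked
    reactions and orphaned metabolites.

    The import direction of an exchange column is the direction that feeds
    its metabolite into the network (positive flux for a ``-> A`` column,
    negative flux for an ``A ->`` column).
    """
    from . import lp  # deferred: lp is independent of this module

    medium = set(medium)
    exchange_ids = {net.reaction_ids[i] for i in np.flatnonzero(net.is_exchange)}
    unknown = medium - set(net.reaction_ids)
    if unknown:
        raise NetworkError(f"medium names unknown reactions: {sorted(unknown)}")
    not_exchange = medium - exchange_ids
    if not_exchange:
        raise NetworkError(f"medium entries are not exchange reactions: {sorted(not_exchange)}")

    out = net.copy()
    for j in np.flatnonzero(out.is_exchange):
        if out.reaction_ids[j] in medium:
            continue
        coef = out.stoich[np.flatnonzero(out.stoich[:, j])[0], j]
        if coef > 0:  # import is positive flux
            out.upper_bound[j] = min(out.upper_bound[j], 0.0)
        else:  # import is negative flux
            out.lower_bound[j] = max(out.lower_bound[j], 0.0)
        if out.lower_bound[j] > out.upper_bound[j]:
            out.lower_bound[j] = out.upper_bound[j] = 0.0
        out.reversible[j] = out.lower_bound[j] < 0

    ranges = lp.flux_variability(out)
    keep = np.array(
        [
            abs(ranges[r][0]) > BLOCKED_TOL or abs(ranges[r][1]) > BLOCKED_TOL
            for r in out.reaction_ids
        ]
    )
    return out.subnetwork(keep)


# ---------------------------------------------------------------------------
# compression


def compress_subsets(net: MetabolicNetwork):
    """Merge reactions operating at fixed flux ratios into reaction subsets.

    Proportionality is detected from the null space of the stoichiometric
    matrix: two reactions belong to one subset iff their null-space rows are
    proportional.  Returns ``(compressed_network, CompressionMap)``.
    """
    from scipy.linalg import null_space

    kernel = null_space(net.stoich)
    if kernel.shape[1] == 0:
        raise NetworkError("network carries no steady-state flux; reduce it first")
    norms = np.linalg.norm(kernel, axis=1)
    if np.any(norms <= BLOCKED_TOL * max(1.0, norms.max())):
        blocked = [net.reaction_ids[i] for i in np.flatnonzero(norms <= BLOCKED_TOL * max(1.0, norms.max()))]
        raise NetworkError(f"blocked reactions present (reduce first): {blocked}")

    n = net.n_reactions
    group_of = -np.ones(n, dtype=int)
    groups: list[list[int]] = []
    for i in range(n):
        if group_of[i] >= 0:
            continue
        group = [i]
        group_of[i] = len(groups)
        for k in range(i + 1, n):
            if group_of[k] >= 0:
                continue
            # k proportional to i: kernel[k] == lam * kernel[i]
            lam = kernel[k] @ kernel[i] / (kernel[i] @ kernel[i])
            if np.allclose(kernel[k], lam * kernel[i], rtol=0, atol=SUBSET_RTOL * norms[k] + 1e-14):
                if abs(lam) > SUBSET_RTOL:
                    group.append(k)
                    group_of[k] = group_of[i]
        groups.append(group)

    cols, rids, rev, lbs, ubs, exch, spont, allowed = [], [], [], [], [], [], [], []
    cmap = CompressionMap()
    for group in groups:
        rep = group[0]
        lams = {}
        for j in group:
            lams[j] = float(kernel[j] @ kernel[rep] / (kernel[rep] @ kernel[rep]))
        lams[rep] = 1.0
        lb, ub = -np.inf, np.inf
        for j in group:
            lo, hi = net.lower_bound[j] / lams[j], net.upper_bound[j] / lams[j]
            if lams[j] < 0:
                lo, hi = hi, lo
            lb, ub = max(lb, lo), min(ub, hi)
        col = sum(lams[j] * net.stoich[:, j] for j in group)
        if ub < 0 or (ub <= 0 and lb < 0):  # orient subset to run forward
            for j in group:
                lams[j] = -lams[j]
            col = -col
            lb, ub = -ub, -lb
        cid = "*".join(net.reaction_ids[j] for j in group)
        cmap.subset_members[cid] = [(net.reaction_ids[j], lams[j]) for j in group]
        cols.append(col)
        rids.append(cid)
        lbs.append(lb)
        ubs.append(ub)
        rev.append(lb < 0)
        # a subset is an exchange/spontaneous only if every member is: any
        # non-exchange member provides a biological knockout handle
        exch.append(bool(all(net.is_exchange[j] for j in group)))
        spont.append(bool(all(net.is_spontaneous[j] for j in group)))
        allowed.append(bool(any(net.knockout_allowed[j] for j in group)))

    stoich = np.column_stack(cols)
    keep_mets = np.any(np.abs(stoich) > 1e-12, axis=1)
    compressed = MetabolicNetwork(
        stoich=np.where(np.abs(stoich) > 1e-12, stoich, 0.0)[keep_mets, :],
        reaction_ids=rids,
        metabolite_ids=[m for m, k in zip(net.metabolite_ids, keep_mets) if k],
        reversible=np.array(rev),
        lower_bound=np.array(lbs),
        upper_bound=np.array(ubs),
        is_exchange=np.array(exch),
        is_spontaneous=np.array(spont),
        knockout_allowed=np.array(allowed),
    )
    return compressed, cmap


# ---------------------------------------------------------------------------
# knockout exclusions


def apply_knockout_exclusions(
    net: MetabolicNetwork,
    extra_excluded=(),
    protect_essential_for=(),
) -> MetabolicNetwork:
    """Return a copy with ``knockout_allowed`` cleared for exchanges,
    spontaneous reactions, ``extra_excluded``, and every reaction whose
    single knockout forces (near-)zero maximal flux through any reaction in
    ``protect_essential_for``.
    """
    from . import lp

    out = net.copy()
    extra_idx = out.indices(extra_excluded)
    protect_idx = out.indices(protect_essential_for)

    out.knockout_allowed &= ~out.is_exchange
    out.knockout_allowed &= ~out.is_spontaneous
    out.knockout_allowed[extra_idx] = False

    if protect_idx:
        protect_ids = [out.reaction_ids[p] for p in protect_idx]
        for i in np.flatnonzero(out.knockout_allowed):
            rid = out.reaction_ids[i]
            for pid in protect_ids:
                res = lp.fba_optimize(out, {pid: 1.0}, sense="max", knockouts={rid})
                if res.status == "infeasible" or (
                    res.status == "optimal" and res.objective < ESSENTIAL_TOL
                ):
                    out.knockout_allowed[i] = False
                    break
    return out
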