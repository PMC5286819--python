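"""Translate a vector of yield thresholds into the pair of linear flux
regions consumed by the cut-set MILP.

For a threshold vector ``x`` the *target* (undesired) region collects the
flux distributions with reference uptake 1 whose product yield falls below
``x_product`` (by a small strictness margin), and the *desired* region the
distributions meeting every threshold.  A valid cut set makes the target
region infeasible while the desired region survives.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .lp import LinearRegion, _denominator_row, _objective_vector

#: strictness margin separating "yield below threshold" (eliminated) from
#: "yield at threshold" (kept); the regions would otherwise share their
#: boundary and no cut set could separate them at the achievable optimum.
#: Certificate magnitudes scale like strict_c / eps, so eps must satisfy
#: big_m * eps >> strict_c or valid cut sets are silently lost.
STRICT_EPS = 1e-3

ROLES = ("product_min_yield", "growth_min_yield", "custom")


class DesignError(ValueError):
    pass


@dataclass
class Objective:
    """One thresholded yield objective: ``numerator / sum(denominator)``.

    ``role`` decides where the threshold row goes: ``product_min_yield``
    contributes the target (elimination) row and, by default, a desired
    row; the other roles contribute desired-existence rows only.
    """

    name: str
    numerator: str
    role: str = "product_min_yield"
    denominator: list = None  # None -> the spec-level reference

    def __post_init__(self):
        if self.role not in ROLES:
            raise DesignError(f"unknown objective role: {self.role!r}")


@dataclass
class DesignSpec:
    """A design: reference (denominator) reactions plus thresholded
    objectives, one swarm dimension per objective."""

    objectives: list
    reference: list  # reaction ids whose summed flux is normalized to 1
    include_product_in_desired: bool = True

    def __post_init__(self):
        if not self.objectives:
            raise DesignError("at least one objective is required")
        n_product = sum(o.role == "product_min_yield" for o in self.objectives)
        if n_product != 1:
            raise DesignError(
                "exactly one objective must have role 'product_min_yield' "
                f"(got {n_product}); the target region is a single polyhedron"
            )
        if not self.reference:
            raise DesignError("reference (denominator) reactions are required")

    @property
    def j(self) -> int:
        """Dimensionality of the threshold search space."""
        return len(self.objectives)

    def ratios(self):
        """``(numerator, denominator)`` pairs for yield_bounds."""
        return [
            (o.numerator, o.denominator if o.denominator else self.reference)
            for o in self.objectives
        ]

    def validate_against(self, net) -> None:
        for o in self.objectives:
            net.index(o.numerator)
            for rid in o.denominator or ():
                net.index(rid)
        for rid in self.reference:
            net.index(rid)

    # -- (de)serialization --------------------------------------------

    def to_dict(self) -> dict:
        return {
            "reference": list(self.reference),
            "include_product_in_desired": self.include_product_in_desired,
            "objectives": [
                {
                    "name": o.name,
                    "numerator": o.numerator,
                    "role": o.role,
                    **({"denominator": o.denominator} if o.denominator else {}),
                }
                for o in self.objectives
            ],
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "DesignSpec":
        return cls(
            objectives=[
                Objective(
                    name=o.get("name", o["numerator"]),
                    numerator=o["numerator"],
                    role=o.get("role", "product_min_yield"),
                    denominator=o.get("denominator"),
                )
                for o in raw["objectives"]
            ],
            reference=list(raw["reference"]),
            include_product_in_desired=bool(raw.get("include_product_in_desired", True)),
        )

    @classmethod
    def from_json(cls, text: str) -> "DesignSpec":
        return cls.from_dict(json.loads(text))


@dataclass
class InterventionProblem:
    """The two linear regions induced by one threshold vector."""

    target: LinearRegion
    desired: LinearRegion
    x: np.ndarray

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        if self.target.n_cols != self.desired.n_cols:
            raise DesignError("target and desired regions disagree on n")


def build_intervention(spec: DesignSpec, x, net, eps: float = STRICT_EPS) -> InterventionProblem:
    """Build the target/desired region pair for threshold vector ``x``.

    Target region rows: reference flux pinned to 1 (two inequalities) and
    ``numerator - x_p * denominator <= -eps`` for the product objective,
    i.e. flux states whose product yield is strictly below the threshold.
    Desired region rows: reference flux pinned to 1 and
    ``numerator >= x_k * denominator`` for every objective (the product row
    is included unless ``spec.include_product_in_desired`` is off).
    """
    x = np.atleast_1d(np.asarray(x, dtype=float))
    if x.shape != (spec.j,):
        raise DesignError(f"threshold vector has length {x.shape[0]}, expected {spec.j}")
    n = net.n_reactions
    ref = _denominator_row(net, spec.reference)

    # normalization rows: ref . r == 1, expressed as two inequalities; they
    # exclude the trivial flux r = 0 from both regions
    norm_A = np.vstack([ref, -ref])
    norm_b = np.array([1.0, -1.0])

    target_rows, target_b = [norm_A], [norm_b]
    desired_rows, desired_b = [norm_A], [norm_b]
    for k, obj in enumerate(spec.objectives):
        num = _objective_vector(net, obj.numerator)
        den = _denominator_row(net, obj.denominator if obj.denominator else spec.reference)
        if obj.role == "product_min_yield":
            # undesired: yield below x_k (strictly, by the eps margin)
            target_rows.append((num - x[k] * den).reshape(1, -1))
            target_b.append(np.array([-eps]))
            if spec.include_product_in_desired:
                desired_rows.append((x[k] * den - num).reshape(1, -1))
                desired_b.append(np.array([0.0]))
        else:
            # existence objective: desired flux with yield >= x_k
            desired_rows.append((x[k] * den - num).reshape(1, -1))
            desired_b.append(np.array([0.0]))

    target = LinearRegion(np.vstack(target_rows), np.concatenate(target_b))
    desired = LinearRegion(np.vstack(desired_rows), np.concatenate(desired_b))
    return InterventionProblem(target=target, desired=desired, x=x)
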