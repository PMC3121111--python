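"""Bipartite metabolic-network model.

A metabolic network is represented bipartitely: ``m`` metabolites
``C_1..C_m`` and ``n`` irreversible reactions ``R_1..R_n``.  Reaction ``j``
consumes its reactants with the coefficients stored in column ``j`` of the
reactant matrix ``S`` (m x n) and produces its products with the
coefficients stored in row ``j`` of the product matrix ``T`` (n x m).  The
combined (net) stoichiometric matrix is ``Snet = -S + T.T``, the matrix that
appears in the steady-state condition ``Snet @ v = 0`` of ordinary flux
balance analysis.

Reversible reactions are handled by splitting them into a forward and a
backward irreversible copy before the matrices are built, so every flux
variable downstream is nonnegative.

Each metabolite is classified by its topological role:

* ``intermediate``  -- consumed by some reaction and produced by some other;
  subject to the strict mass-balance constraint in both LP stages.
* ``consumed_only`` -- a source: enters the system from outside.
* ``produced_only`` -- a sink: leaves the system (e.g. biomass precursors).
* ``isolated``      -- touches no reaction (kept, with a warning).
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "ReactionParseError",
    "NetworkValidationError",
    "parse_reaction_equation",
    "format_reaction_equation",
    "split_reversible",
    "build_network",
    "classify_metabolites",
    "ROLE_INTERMEDIATE",
    "ROLE_CONSUMED_ONLY",
    "ROLE_PRODUCED_ONLY",
    "ROLE_ISOLATED",
]

ROLE_INTERMEDIATE = "intermediate"
ROLE_CONSUMED_ONLY = "consumed_only"
ROLE_PRODUCED_ONLY = "produced_only"
ROLE_ISOLATED = "isolated"


class ReactionParseError(ValueError):
    """Raised when a reaction-equation string cannot be parsed."""


class NetworkValidationError(ValueError):
    """Raised when network components are mutually inconsistent."""


@dataclass(frozen=True)
class Metabolite:
    """A metabolite node.  The topological role is derived by the network,
    never supplied by the user."""

    id: str
    name: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("metabolite id must be non-empty")


def _validate_coeffs(side: str, coeffs: Mapping[str, float], rid: str) -> dict:
    out = {}
    for met, c in coeffs.items():
        c = float(c)
        if not math.isfinite(c) or c <= 0:
            raise NetworkValidationError(
                f"reaction {rid!r}: {side} coefficient for {met!r} must be "
                f"strictly positive and finite, got {c}"
            )
        out[str(met)] = c
    return out


@dataclass(frozen=True)
class Reaction:
    """An (irreversible, once finalized) reaction.

    ``reactants`` and ``products`` map metabolite id to a strictly positive
    stoichiometric coefficient.  An empty side is allowed only for explicit
    exchange/boundary reactions; both sides empty is rejected.
    """

    id: str
    reactants: Mapping[str, float]
    products: Mapping[str, float]
    enzymes: tuple[str, ...] = ()
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise NetworkValidationError("reaction id must be non-empty")
        object.__setattr__(self, "reactants", _validate_coeffs("reactant", self.reactants, self.id))
        object.__setattr__(self, "products", _validate_coeffs("product", self.products, self.id))
        object.__setattr__(self, "enzymes", tuple(self.enzymes))
        if not self.reactants and not self.products:
            raise NetworkValidationError(
                f"reaction {self.id!r} has neither reactants nor products"
            )

    @property
    def metabolite_ids(self) -> set[str]:
        return set(self.reactants) | set(self.products)


_ARROW_RE = re.compile(r"<->|↔|->|→")
# optional coefficient glued to or separated from the metabolite id
_TERM_RE = re.compile(
    r"^(?:(?P<coef>\d+(?:\.\d+)?(?:[eE][+-]?\d+)?)\s*)?(?P<met>[A-Za-z_][\w'\-()\[\],:]*)$"
)


def _parse_side(text: str, rid: str) -> dict[str, float]:
    text = text.strip()
    coeffs: dict[str, float] = {}
    if not text:
        return coeffs
    for raw in text.split("+"):
        term = raw.strip()
        if not term:
            raise ReactionParseError(f"reaction {rid!r}: empty term near '+' in {text!r}")
        m = _TERM_RE.match(term)
        if m is None:
            raise ReactionParseError(f"reaction {rid!r}: cannot parse term {term!r}")
        coef = float(m.group("coef")) if m.group("coef") else 1.0
        if coef <= 0:
            raise NetworkValidationError(
                f"reaction {rid!r}: coefficient for {m.group('met')!r} must be positive"
            )
        met = m.group("met")
        coeffs[met] = coeffs.get(met, 0.0) + coef  # duplicates on one side sum
    return coeffs


def parse_reaction_equation(
    equation: str,
    id: str,
    enzymes: Iterable[str] = (),
) -> Reaction:
    """Parse ``"2 C1 + 3 C2 -> C5 + 2 C6"`` into a :class:`Reaction`.

    The arrow ``->`` (or ``→``) marks an irreversible reaction; ``<->``
    (or ``↔``) marks a reversible one, recorded via the ``reversible`` flag
    (use :func:`split_reversible` before building a network).  Coefficients
    default to 1 and may be glued to the id (``2C1``) or space-separated.
    """
    arrows = _ARROW_RE.findall(equation)
    if len(arrows) != 1:
        raise ReactionParseError(
            f"reaction {id!r}: expected exactly one arrow in {equation!r}, "
            f"found {len(arrows)}"
        )
    reversible = arrows[0] in ("<->", "↔")
    lhs, rhs = _ARROW_RE.split(equation)
    return Reaction(
        id=id,
        reactants=_parse_side(lhs, id),
        products=_parse_side(rhs, id),
        enzymes=tuple(enzymes),
        reversible=reversible,
    )


def _format_coeff(c: float) -> str:
    if c == int(c):
        return str(int(c))
    return format(c, "g")


def format_reaction_equation(reaction: Reaction) -> str:
    """Inverse of :func:`parse_reaction_equation` (round-trips exactly)."""

    def side(coeffs: Mapping[str, float]) -> str:
        return " + ".join(
            (f"{_format_coeff(c)} {m}" if c != 1 else m) for m, c in coeffs.items()
        )

    arrow = "<->" if reaction.reversible else "->"
    return f"{side(reaction.reactants)} {arrow} {side(reaction.products)}".strip()


def split_reversible(reactions: Sequence[Reaction]) -> list[Reaction]:
    """Replace every reversible reaction X by irreversible X_fwd / X_bwd.

    The backward copy swaps reactants and products; both copies carry X's
    enzymes.  Irreversible reactions pass through unchanged and input order
    is preserved (``_bwd`` immediately follows ``_fwd``).  Idempotent.
    """
    out: list[Reaction] = []
    for r in reactions:
        if not r.reversible:
            out.append(r)
            continue
        out.append(
            Reaction(f"{r.id}_fwd", r.reactants, r.products, r.enzymes, reversible=False)
        )
        out.append(
            Reaction(f"{r.id}_bwd", r.products, r.reactants, r.enzymes, reversible=False)
        )
    return out


@dataclass
class MetabolicNetwork:
    """A finalized (all-irreversible) bipartite metabolic network.

    Ordering of metabolites and reactions is the input order, so matrix
    columns/rows and every downstream report are reproducible.

    Attributes
    ----------
    S : ndarray, shape (m, n)
        Reactant coefficients, ``S[i, j] = s_{i,j}``.
    T : ndarray, shape (n, m)
        Product coefficients, ``T[j, i] = t_{j,i}``.
    flux_upper_hints : dict
        Optional per-reaction flux upper bounds carried by a network file;
        consulted by the scenario resolution (scenario overrides win).
    """

    metabolites: list[Metabolite]
    reactions: list[Reaction]
    flux_upper_hints: dict[str, float] = field(default_factory=dict)
    S: np.ndarray = field(init=False, repr=False)
    T: np.ndarray = field(init=False, repr=False)
    roles: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.metabolites]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise NetworkValidationError(f"duplicate metabolite ids: {dupes}")
        rids = [r.id for r in self.reactions]
        if len(set(rids)) != len(rids):
            dupes = sorted({i for i in rids if rids.count(i) > 1})
            raise NetworkValidationError(f"duplicate reaction ids: {dupes}")
        for r in self.reactions:
            if r.reversible:
                raise NetworkValidationError(
                    f"reaction {r.id!r} is still reversible; apply split_reversible first"
                )
            unknown = sorted(r.metabolite_ids - set(ids))
            if unknown:
                raise NetworkValidationError(
                    f"reaction {r.id!r} references unknown metabolites: {unknown}"
                )
        self._met_index = {m: i for i, m in enumerate(ids)}
        self._rxn_index = {r: j for j, r in enumerate(rids)}
        m, n = len(ids), len(rids)
        S = np.zeros((m, n))
        T = np.zeros((n, m))
        for j, r in enumerate(self.reactions):
            for met, c in r.reactants.items():
                S[self._met_index[met], j] = c
            for met, c in r.products.items():
                T[j, self._met_index[met]] = c
        self.S = S
        self.T = T
        self.roles = classify_metabolites(self)
        isolated = [m for m, role in self.roles.items() if role == ROLE_ISOLATED]
        if isolated:
            warnings.warn(
                f"network contains isolated metabolites (no reaction): {isolated}",
                stacklevel=2,
            )

    # -- basic accessors ---------------------------------------------------
    @property
    def m(self) -> int:
        return len(self.metabolites)

    @property
    def n(self) -> int:
        return len(self.reactions)

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def Snet(self) -> np.ndarray:
        """Combined stoichiometric matrix ``-S + T.T`` (m x n)."""
        return -self.S + self.T.T

    def metabolite_index(self, met_id: str) -> int:
        return self._met_index[met_id]

    def reaction_index(self, rxn_id: str) -> int:
        return self._rxn_index[rxn_id]

    def reaction(self, rxn_id: str) -> Reaction:
        return self.reactions[self._rxn_index[rxn_id]]

    def metabolites_with_role(self, *roles: str) -> list[str]:
        return [m for m in self.metabolite_ids if self.roles[m] in roles]

    # -- derived networks --------------------------------------------------
    def without_reactions(self, reaction_ids: Iterable[str]) -> "MetabolicNetwork":
        """Copy of the network with the given reactions removed (metabolite
        list kept; roles and matrices rebuilt)."""
        drop = set(reaction_ids)
        unknown = drop - set(self.reaction_ids)
        if unknown:
            raise NetworkValidationError(f"unknown reaction ids: {sorted(unknown)}")
        kept = [r for r in self.reactions if r.id not in drop]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return MetabolicNetwork(
                list(self.metabolites), kept, dict(self.flux_upper_hints)
            )

    def restricted_to(self, reaction_ids: Iterable[str]) -> "MetabolicNetwork":
        """Subnetwork of exactly the given reactions plus the union of their
        reactants and products, in network order."""
        keep = list(reaction_ids)
        unknown = set(keep) - set(self.reaction_ids)
        if unknown:
            raise NetworkValidationError(f"unknown reaction ids: {sorted(unknown)}")
        keep_set = set(keep)
        rxns = [r for r in self.reactions if r.id in keep_set]
        touched = set()
        for r in rxns:
            touched |= r.metabolite_ids
        mets = [m for m in self.metabolites if m.id in touched]
        return MetabolicNetwork(mets, rxns, dict(self.flux_upper_hints))


def build_network(
    metabolite_ids: Sequence[str | Metabolite],
    reactions: Sequence[Reaction],
    flux_upper_hints: Mapping[str, float] | None = None,
) -> MetabolicNetwork:
    """Assemble a :class:`MetabolicNetwork` from ids and finalized reactions.

    All metabolite ids referenced by the reactions must appear in
    ``metabolite_ids``; reactions must already be irreversible (split).
    """
    mets = [m if isinstance(m, Metabolite) else Metabolite(str(m)) for m in metabolite_ids]
    return MetabolicNetwork(mets, list(reactions), dict(flux_upper_hints or {}))


def classify_metabolites(network: MetabolicNetwork) -> dict[str, str]:
    """Topological role of every metabolite (see module docstring)."""
    roles: dict[str, str] = {}
    consumed = network.S.sum(axis=1) > 0  # reactant of >= 1 reaction
    produced = network.T.sum(axis=0) > 0  # product of >= 1 reaction
    for i, met in enumerate(network.metabolite_ids):
        if consumed[i] and produced[i]:
            roles[met] = ROLE_INTERMEDIATE
        elif consumed[i]:
            roles[met] = ROLE_CONSUMED_ONLY
        elif produced[i]:
            roles[met] = ROLE_PRODUCED_ONLY
        else:
            roles[met] = ROLE_ISOLATED
    return roles
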