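"""Domain model for strand-displacement reaction networks.

A network is a list of :class:`Species` (each a named complex of one or two
DNA strands) and a list of mass-action :class:`Reaction` objects referencing
named rate constants in a :class:`RateSet`.  Because every reaction is a
strand-displacement or hybridization event, the multiset of strands is
conserved reaction by reaction; the per-strand conservation vectors are
derived automatically and double as integrator sanity checks.

Five experimental network topologies are provided by :func:`build_network`:

``template_binding``
    Template T invades the blocked monomer ML by toehold-mediated strand
    displacement (TMSD): ``ML + T <=> MT + L``.
``template_recovery``
    Proofreader P strips the monomer off the template, and the waste duplex
    MP is read out by an external reporter:
    ``MT + P <=> MP + T``; ``MP + RQ -> MPR + Q``.
``full_discard``
    Union of the two above — the complete catalytic discard pathway.
``dimerization``
    Adds handhold-mediated dimerization with the second monomer N and the
    product reporter: ``MT + N -> MN + T``; ``MN + RQ -> MNR + Q``; an
    optional leak lets the reporter react directly with blocked monomer.
``snp_detection``
    A blocked probe discriminates a candidate strand X (target or single
    nucleotide mutant): ``PL + X <=> XP + L``; ``XP + RQ -> XPR + Q``;
    ``XP + Psnp -> W + X``; ``W + S -> WS``.

Monomer-variant discrimination (matched vs mismatched toeholds) enters only
through the numerical rate values, never through the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import Counter
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "Species",
    "Reaction",
    "RateSet",
    "NetworkModel",
    "NetworkConfigError",
    "build_network",
    "validate_network",
    "NETWORK_KINDS",
]

NETWORK_KINDS = (
    "template_binding",
    "template_recovery",
    "full_discard",
    "dimerization",
    "snp_detection",
)

ROLE_TAGS = {
    "monomer",
    "blocker",
    "template",
    "proofreader",
    "second_monomer",
    "reporter",
    "quencher_product",
    "waste",
    "product",
    "sink",
    "probe",
    "target",
}


class NetworkConfigError(ValueError):
    """Raised for unknown network kinds or inconsistent build options."""


@dataclass(frozen=True)
class Species:
    """A molecular species: a strand or complex of strands.

    Parameters
    ----------
    name : str
        Unique name within a network (e.g. ``"MT"``).
    strands : tuple of str
        Constituent strand identifiers (e.g. ``("M", "T")``).
    roles : frozenset of str
        Functional role tags drawn from :data:`ROLE_TAGS`.
    """

    name: str
    strands: tuple[str, ...]
    roles: frozenset = frozenset()

    def __post_init__(self):
        if not self.strands:
            raise ValueError(f"species {self.name!r} has no constituent strands")
        bad = set(self.roles) - ROLE_TAGS
        if bad:
            raise ValueError(f"unknown role tags {sorted(bad)} on species {self.name!r}")


@dataclass(frozen=True)
class Reaction:
    """A uni- or bimolecular mass-action reaction between named species.

    ``rate_name`` refers into the accompanying :class:`RateSet`;
    ``reversible_partner`` holds the rate name of the reverse reaction when
    the pair forms a reversible group.
    """

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_name: str
    reversible_partner: str | None = None

    def __post_init__(self):
        if not 1 <= len(self.reactants) <= 2 or not 1 <= len(self.products) <= 2:
            raise ValueError(
                f"reaction {self.rate_name!r}: only uni/bimolecular reactions supported"
            )

    @property
    def order(self) -> int:
        return len(self.reactants)

    def __str__(self) -> str:
        arrow = "->"
        return (
            " + ".join(self.reactants)
            + f" {arrow} "
            + " + ".join(self.products)
            + f"  [{self.rate_name}]"
        )


@dataclass
class RateSet:
    """Named rate constants partitioned into known and unknown sets.

    Values use the interface units of the field: per-molar per-second
    (M^-1 s^-1) for bimolecular reactions and per-second (s^-1) for
    unimolecular ones.  The kinetics engine converts bimolecular constants to
    nM^-1 s^-1 internally.

    ``known`` holds names whose values are fixed during fitting (determined
    by earlier fits to different experiments); ``unknown`` holds the names to
    be estimated, with finite positive search ``bounds``.
    """

    values: dict[str, float]
    known: frozenset = frozenset()
    unknown: frozenset = frozenset()
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.known = frozenset(self.known)
        self.unknown = frozenset(self.unknown)
        overlap = self.known & self.unknown
        if overlap:
            raise ValueError(f"rates both known and unknown: {sorted(overlap)}")
        for name, v in self.values.items():
            if v < 0:
                raise ValueError(f"rate {name!r} is negative ({v})")
            lo_hi = self.bounds.get(name)
            if lo_hi is not None:
                lo, hi = lo_hi
                if not (0 <= lo <= v <= hi):
                    raise ValueError(
                        f"rate {name!r}={v} outside its bounds ({lo}, {hi})"
                    )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def with_values(self, updates: Mapping[str, float]) -> "RateSet":
        """Return a copy with some values replaced (partition unchanged)."""
        vals = dict(self.values)
        vals.update(updates)
        return RateSet(vals, self.known, self.unknown, dict(self.bounds))

    def partition(self, unknown: Iterable[str]) -> "RateSet":
        """Return a copy with the given names unknown and the rest known."""
        unknown = frozenset(unknown)
        missing = unknown - set(self.values)
        if missing:
            raise KeyError(f"unknown rate names not in rate set: {sorted(missing)}")
        known = frozenset(self.values) - unknown
        return RateSet(dict(self.values), known, unknown, dict(self.bounds))


@dataclass
class NetworkModel:
    """A validated strand-displacement reaction network."""

    kind: str
    species: list[Species]
    reactions: list[Reaction]

    def __post_init__(self):
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            dupes = [n for n, c in Counter(names).items() if c > 1]
            raise ValueError(f"duplicate species names: {dupes}")
        self._index = {n: i for i, n in enumerate(names)}

    # -- basic accessors -------------------------------------------------
    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unknown species {name!r} in {self.kind} network") from None

    @property
    def strands(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.species:
            for st in s.strands:
                seen.setdefault(st, None)
        return list(seen)

    @property
    def rate_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            seen.setdefault(r.rate_name, None)
        return list(seen)

    # -- linear-algebra views --------------------------------------------
    def stoichiometry_matrix(self) -> np.ndarray:
        """Integer net-stoichiometry matrix, shape (n_species, n_reactions)."""
        N = np.zeros((len(self.species), len(self.reactions)), dtype=int)
        for j, r in enumerate(self.reactions):
            for name in r.reactants:
                N[self.species_index(name), j] -= 1
            for name in r.products:
                N[self.species_index(name), j] += 1
        return N

    def conservation_vectors(self) -> dict[str, np.ndarray]:
        """Per-strand copy-number vectors over species.

        The vector for strand ``s`` counts how many copies of ``s`` each
        species carries; every such vector is invariant under every reaction
        (checked by :func:`validate_network`).
        """
        out = {}
        for strand in self.strands:
            v = np.zeros(len(self.species), dtype=int)
            for i, sp in enumerate(self.species):
                v[i] = sp.strands.count(strand)
            out[strand] = v
        return out

    def __str__(self) -> str:
        lines = [f"NetworkModel(kind={self.kind!r})"]
        lines += [f"  species: {', '.join(self.species_names)}"]
        lines += [f"  {r}" for r in self.reactions]
        return "\n".join(lines)


def validate_network(network: NetworkModel, rates: RateSet | None = None) -> list[str]:
    """Diagnose structural problems; returns a list of violation strings.

    Checks, in order: per-reaction strand conservation, invariance of every
    conservation vector against the stoichiometry matrix (exact integer
    arithmetic), orphan species, and — when a rate set is supplied —
    unresolved rate names.  An empty list means the network is well formed.
    """
    violations: list[str] = []
    idx = {s.name: s for s in network.species}

    for r in network.reactions:
        unknown = [n for n in r.reactants + r.products if n not in idx]
        if unknown:
            violations.append(f"reaction {r.rate_name!r}: unknown species {unknown}")
            continue
        lhs = Counter(st for n in r.reactants for st in idx[n].strands)
        rhs = Counter(st for n in r.products for st in idx[n].strands)
        if lhs != rhs:
            violations.append(
                f"reaction {r.rate_name!r} breaks strand conservation: "
                f"{dict(lhs)} -> {dict(rhs)}"
            )

    N = network.stoichiometry_matrix()
    for strand, v in network.conservation_vectors().items():
        residual = v @ N
        if np.any(residual != 0):
            bad = [network.reactions[j].rate_name for j in np.nonzero(residual)[0]]
            violations.append(
                f"conservation vector for strand {strand!r} not invariant "
                f"under reactions {bad}"
            )

    in_reaction = {n for r in network.reactions for n in r.reactants + r.products}
    for s in network.species:
        if s.name not in in_reaction:
            violations.append(f"orphan species {s.name!r}")

    if rates is not None:
        for r in network.reactions:
            if r.rate_name not in rates.values:
                violations.append(f"unresolved rate {r.rate_name!r}")

    return violations


# ---------------------------------------------------------------------------
# network builders
# ---------------------------------------------------------------------------

def _sp(name: str, strands: str | tuple[str, ...], *roles: str) -> Species:
    if isinstance(strands, str):
        strands = (strands,)
    return Species(name, tuple(strands), frozenset(roles))


def _binding_block(two_step: bool, reversible: bool):
    """Species/reactions for template invasion of the blocked monomer."""
    species = [
        _sp("ML", ("M", "L"), "monomer", "blocker"),
        _sp("T", "T", "template"),
        _sp("MT", ("M", "T"), "monomer", "template"),
        _sp("L", "L", "blocker"),
    ]
    reactions: list[Reaction] = []
    if two_step:
        species.append(_sp("MLT", ("M", "L", "T"), "monomer", "blocker", "template"))
        reactions.append(Reaction(("ML", "T"), ("MLT",), "k_on", "k_off"))
        reactions.append(Reaction(("MLT",), ("ML", "T"), "k_off", "k_on"))
        if reversible:
            reactions.append(Reaction(("MLT",), ("MT", "L"), "k_disp", "k_disp_rev"))
            reactions.append(Reaction(("MT", "L"), ("MLT",), "k_disp_rev", "k_disp"))
        else:
            reactions.append(Reaction(("MLT",), ("MT", "L"), "k_disp"))
    else:
        if reversible:
            reactions.append(Reaction(("ML", "T"), ("MT", "L"), "k_bind", "k_unbind"))
            reactions.append(Reaction(("MT", "L"), ("ML", "T"), "k_unbind", "k_bind"))
        else:
            reactions.append(Reaction(("ML", "T"), ("MT", "L"), "k_bind"))
    return species, reactions


def _recovery_block(reversible: bool):
    """Proofreading (template recovery) plus the waste reporter."""
    species = [
        _sp("MT", ("M", "T"), "monomer", "template"),
        _sp("P", "P", "proofreader"),
        _sp("MP", ("M", "P"), "waste"),
        _sp("T", "T", "template"),
        _sp("RQ", ("R", "Q"), "reporter"),
        _sp("MPR", ("M", "P", "R"), "waste", "reporter"),
        _sp("Q", "Q", "quencher_product"),
    ]
    reactions = [Reaction(("MT", "P"), ("MP", "T"), "k_proof",
                          "k_unproof" if reversible else None)]
    if reversible:
        reactions.append(Reaction(("MP", "T"), ("MT", "P"), "k_unproof", "k_proof"))
    reactions.append(Reaction(("MP", "RQ"), ("MPR", "Q"), "k_rep"))
    return species, reactions


def _merge(*blocks):
    species: dict[str, Species] = {}
    reactions: list[Reaction] = []
    seen_rates: set[str] = set()
    for sp_list, rx_list in blocks:
        for s in sp_list:
            if s.name in species:
                if species[s.name].strands != s.strands:
                    raise NetworkConfigError(
                        f"conflicting strand content for species {s.name!r}"
                    )
            else:
                species[s.name] = s
        for r in rx_list:
            if r.rate_name not in seen_rates:
                seen_rates.add(r.rate_name)
                reactions.append(r)
    return list(species.values()), reactions


def build_network(
    kind: str,
    *,
    reversible_binding: bool = True,
    reversible_proofreading: bool = True,
    leak: bool = False,
    two_step_binding: bool = False,
) -> NetworkModel:
    """Build one of the five study network topologies.

    Parameters
    ----------
    kind : str
        One of :data:`NETWORK_KINDS`.
    reversible_binding : bool
        Model blocker/template exchange as a reversible pair (default).
    reversible_proofreading : bool
        Include rebinding of proofread monomers to the template (default).
    leak : bool
        Add the direct reporter–monomer leak reaction; only meaningful for
        kinds that contain a reporter (``dimerization``, ``snp_detection``).
    two_step_binding : bool
        Resolve template invasion into association and displacement steps
        via a transient MLT intermediate (sensitivity-analysis variant).

    Returns
    -------
    NetworkModel
        Validated network (raises if any structural invariant fails).
    """
    if kind not in NETWORK_KINDS:
        raise NetworkConfigError(
            f"unknown network kind {kind!r}; choose from {NETWORK_KINDS}"
        )
    if leak and kind in ("template_binding", "template_recovery", "full_discard"):
        # The waste reporter of the discard networks is triggered by MP only;
        # the monomer leak was observed for the dimer/SNP product reporters.
        raise NetworkConfigError(
            "option 'leak' requires a product reporter "
            f"(network kind {kind!r} has none)"
        )
    if two_step_binding and kind in ("template_recovery", "snp_detection"):
        raise NetworkConfigError(
            f"option 'two_step_binding' does not apply to kind {kind!r}"
        )

    if kind == "template_binding":
        species, reactions = _binding_block(two_step_binding, reversible_binding)

    elif kind == "template_recovery":
        species, reactions = _recovery_block(reversible_proofreading)

    elif kind == "full_discard":
        species, reactions = _merge(
            _binding_block(two_step_binding, reversible_binding),
            _recovery_block(reversible_proofreading),
        )

    elif kind == "dimerization":
        bind = _binding_block(two_step_binding, reversible_binding)
        proof = (
            [
                _sp("MT", ("M", "T"), "monomer", "template"),
                _sp("P", "P", "proofreader"),
                _sp("MP", ("M", "P"), "waste"),
                _sp("T", "T", "template"),
            ],
            [Reaction(("MT", "P"), ("MP", "T"), "k_proof",
                      "k_unproof" if reversible_proofreading else None)]
            + (
                [Reaction(("MP", "T"), ("MT", "P"), "k_unproof", "k_proof")]
                if reversible_proofreading
                else []
            ),
        )
        dimer = (
            [
                _sp("N", "N", "second_monomer"),
                _sp("MN", ("M", "N"), "product"),
                _sp("RQ", ("R", "Q"), "reporter"),
                _sp("MNR", ("M", "N", "R"), "product", "reporter"),
                _sp("Q", "Q", "quencher_product"),
            ],
            [
                Reaction(("MT", "N"), ("MN", "T"), "k_dim"),
                Reaction(("MN", "RQ"), ("MNR", "Q"), "k_rep"),
            ],
        )
        blocks = [bind, proof, dimer]
        if leak:
            blocks.append(
                (
                    [_sp("MLR", ("M", "L", "R"), "monomer", "reporter")],
                    [Reaction(("ML", "RQ"), ("MLR", "Q"), "k_leak")],
                )
            )
        species, reactions = _merge(*blocks)

    else:  # snp_detection
        species = [
            _sp("PL", ("Pr", "Lk"), "probe", "blocker"),
            _sp("X", "X", "target"),
            _sp("XP", ("X", "Pr"), "target", "probe"),
            _sp("Lk", "Lk", "blocker"),
            _sp("RQ", ("R", "Q"), "reporter"),
            _sp("XPR", ("X", "Pr", "R"), "product", "reporter"),
            _sp("Q", "Q", "quencher_product"),
            _sp("Psnp", "Ps", "proofreader"),
            _sp("W", ("Pr", "Ps"), "waste"),
            _sp("S", "S", "sink"),
            _sp("WS", ("Pr", "Ps", "S"), "waste", "sink"),
        ]
        reactions = [
            Reaction(("PL", "X"), ("XP", "Lk"), "k_probe", "k_unprobe"),
            Reaction(("XP", "Lk"), ("PL", "X"), "k_unprobe", "k_probe"),
            Reaction(("XP", "RQ"), ("XPR", "Q"), "k_rep"),
            Reaction(("XP", "Psnp"), ("W", "X"), "k_proof"),
            Reaction(("W", "S"), ("WS",), "k_sink"),
        ]
        if not reversible_binding:
            reactions = [r for r in reactions if r.rate_name != "k_unprobe"]
            reactions[0] = Reaction(("PL", "X"), ("XP", "Lk"), "k_probe")
        if leak:
            species.append(_sp("PLR", ("Pr", "Lk", "R"), "probe", "reporter"))
            reactions.append(Reaction(("PL", "RQ"), ("PLR", "Q"), "k_leak"))

    net = NetworkModel(kind, species, reactions)
    problems = validate_network(net)
    if problems:  # pragma: no cover - builders are checked in tests
        raise NetworkConfigError(
            f"builder produced invalid {kind} network: {problems}"
        )
    return net
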