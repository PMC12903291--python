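"""Stoichiometric flux inference over a small central-metabolism network.

The model treats plasma as a lumped compartment exchanging with a
10-reaction central-metabolic-pathway (CMP) network spanning glycolysis,
the pentose phosphate branch, lactate fermentation, pyruvate oxidation and
ketogenesis.  Six intermediates (G6P, F6P, GAP, PEP, pyruvate, acetyl-CoA)
are assumed to be in pseudo-steady state, so each contributes a homogeneous
mass-balance row ``S_row . r = 0``.  Measured plasma concentrations of the
boundary species (glucose, lactate, beta-hydroxybutyrate, NADH) anchor
non-homogeneous rows through a concentration-to-rate proxy: the net
production rate of a measured metabolite is taken proportional to its
concentration relative to glucose, scaled so the glucose-uptake reaction
carries flux 100.  Solving the resulting linear system yields relative
fluxes; :meth:`FluxResults.normalize` rescales any solution so the
reference reaction is exactly 100.

The default network ships as a JSON data file (``data/cmp_network.json``)
and can be replaced by any user file in the same layout without touching
code.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import networkx as nx
from scipy import optimize

__all__ = [
    "MetaboliteNode",
    "Reaction",
    "NetworkModel",
    "BalanceSystem",
    "FluxModel",
    "FluxResults",
    "FluxSolution",
    "NetworkError",
    "parse_network",
    "load_default_network",
    "build_stoich_matrix",
    "boundary_sign",
    "assemble_balance_system",
    "solve_fluxes",
    "normalize_fluxes",
    "compare_conditions",
    "export_flux_graph",
]

ROLES = ("boundary_measured", "internal_pss", "sink_unmeasured")
PATHWAYS = ("glycolysis", "pentose_phosphate", "TCA", "ketogenesis", "fermentation", "other")


class NetworkError(ValueError):
    """Raised for malformed network definitions or infeasible systems."""


@dataclass(frozen=True)
class MetaboliteNode:
    """A metabolite in the network with its solver role.

    ``boundary_measured`` nodes carry a plasma concentration into the
    solve; ``internal_pss`` nodes contribute homogeneous balance rows;
    ``sink_unmeasured`` nodes are unconstrained outflows (their balance
    rows are dropped).
    """

    id: str
    name: str = ""
    role: str = "internal_pss"
    orientation: int | None = None  # +1 net-produced / -1 net-consumed; None = infer

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise NetworkError(f"metabolite {self.id!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: tuple[tuple[str, float], ...]
    products: tuple[tuple[str, float], ...]
    pathway: str = "other"
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise NetworkError(f"reaction {self.id!r} needs >=1 substrate and >=1 product")
        for met, coeff in (*self.substrates, *self.products):
            if coeff <= 0:
                raise NetworkError(f"reaction {self.id!r}: coefficient for {met!r} must be > 0")
        if self.pathway not in PATHWAYS:
            raise NetworkError(f"reaction {self.id!r}: unknown pathway {self.pathway!r}")

    @property
    def metabolites(self) -> set[str]:
        return {m for m, _ in self.substrates} | {m for m, _ in self.products}


@dataclass(frozen=True)
class NetworkModel:
    """Validated metabolic network: nodes, reactions and the reference reaction."""

    nodes: tuple[MetaboliteNode, ...]
    reactions: tuple[Reaction, ...]
    reference_reaction_id: str = "r1"

    def __post_init__(self) -> None:
        node_ids = [n.id for n in self.nodes]
        if len(set(node_ids)) != len(node_ids):
            raise NetworkError("duplicate metabolite ids in network")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise NetworkError(f"duplicate reaction id(s): {dupes}")
        declared = set(node_ids)
        for rxn in self.reactions:
            missing = rxn.metabolites - declared
            if missing:
                raise NetworkError(
                    f"reaction {rxn.id!r} references undeclared metabolite(s): {sorted(missing)}"
                )
        if self.reference_reaction_id not in set(rxn_ids):
            raise NetworkError(f"reference reaction {self.reference_reaction_id!r} not in network")
        if not self.boundary_ids:
            raise NetworkError("network declares no boundary_measured metabolite")

    @property
    def node_ids(self) -> list[str]:
        return [n.id for n in self.nodes]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def boundary_ids(self) -> list[str]:
        return [n.id for n in self.nodes if n.role == "boundary_measured"]

    @property
    def internal_ids(self) -> list[str]:
        return [n.id for n in self.nodes if n.role == "internal_pss"]

    def node(self, met_id: str) -> MetaboliteNode:
        for n in self.nodes:
            if n.id == met_id:
                return n
        raise KeyError(met_id)


def _parse_stoich_expr(expr: str) -> tuple[tuple[str, float], ...]:
    """Parse ``"2*A+B"`` into ``(("A", 2.0), ("B", 1.0))``."""
    out = []
    for term in expr.split("+"):
        term = term.strip()
        m = re.fullmatch(r"(?:([\d.]+)\s*\*\s*)?(\S+)", term)
        if m is None:
            raise NetworkError(f"cannot parse stoichiometry term {term!r}")
        coeff = float(m.group(1)) if m.group(1) else 1.0
        out.append((m.group(2), coeff))
    return tuple(out)


def parse_network(source: str | Path) -> NetworkModel:
    """Read a network definition file (JSON, or TSV with one reaction per line).

    The JSON layout declares ``metabolites: [{id, name, role}]`` and
    ``reactions: [{id, substrates: [[id, coeff]], products, pathway,
    reversible}]``.  The TSV alternative has columns
    ``id substrates products pathway reversible`` with stoichiometry
    written as ``2*A+B``; metabolite roles then default to internal_pss and
    must be annotated via ``#role <id> <role>`` comment lines.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        return _network_from_dict(json.loads(path.read_text()))
    return _network_from_tsv(path.read_text())


def _network_from_dict(doc: Mapping) -> NetworkModel:
    nodes = tuple(
        MetaboliteNode(
            id=m["id"],
            name=m.get("name", m["id"]),
            role=m.get("role", "internal_pss"),
            orientation=m.get("orientation"),
        )
        for m in doc["metabolites"]
    )
    reactions = tuple(
        Reaction(
            id=r["id"],
            substrates=tuple((str(m), float(c)) for m, c in r["substrates"]),
            products=tuple((str(m), float(c)) for m, c in r["products"]),
            pathway=r.get("pathway", "other"),
            reversible=bool(r.get("reversible", False)),
        )
        for r in doc["reactions"]
    )
    return NetworkModel(nodes, reactions, doc.get("reference_reaction", "r1"))


def _network_from_tsv(text: str) -> NetworkModel:
    roles: dict[str, str] = {}
    reactions = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#role"):
            _, met, role = line.split()
            roles[met] = role
            continue
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 5:
            raise NetworkError(f"TSV reaction line needs 5 fields, got {len(fields)}: {line!r}")
        rid, subs, prods, pathway, reversible = fields
        reactions.append(
            Reaction(
                id=rid,
                substrates=_parse_stoich_expr(subs),
                products=_parse_stoich_expr(prods),
                pathway=pathway,
                reversible=reversible.lower() in ("true", "1", "yes"),
            )
        )
    met_ids: list[str] = []
    for rxn in reactions:
        for m in [x for x, _ in rxn.substrates] + [x for x, _ in rxn.products]:
            if m not in met_ids:
                met_ids.append(m)
    nodes = tuple(
        MetaboliteNode(id=m, name=m, role=roles.get(m, "internal_pss")) for m in met_ids
    )
    ref = reactions[0].id if reactions else "r1"
    return NetworkModel(nodes, tuple(reactions), ref)


def load_default_network() -> NetworkModel:
    """The packaged 10-reaction CMP network."""
    doc = json.loads(
        resources.files("plasmaflux").joinpath("data/cmp_network.json").read_text()
    )
    return _network_from_dict(doc)


def build_stoich_matrix(network: NetworkModel) -> pd.DataFrame:
    """Signed stoichiometric matrix S (metabolites x reactions).

    Entry (m, r) = total product coefficient minus total substrate
    coefficient of m in r; rows/columns follow declaration order.
    """
    S = pd.DataFrame(
        0.0, index=network.node_ids, columns=network.reaction_ids
    )
    for rxn in network.reactions:
        for met, coeff in rxn.substrates:
            S.loc[met, rxn.id] -= coeff
        for met, coeff in rxn.products:
            S.loc[met, rxn.id] += coeff
    return S


def boundary_sign(network: NetworkModel, met_id: str) -> int:
    """Sign of the boundary net-rate for a measured metabolite.

    -1 (net consumed) iff the metabolite appears exclusively as a
    substrate across all reactions; +1 otherwise.  An explicit node
    ``orientation`` overrides the inference.
    """
    node = network.node(met_id)
    if node.orientation is not None:
        return 1 if node.orientation >= 0 else -1
    is_product = any(met_id in {m for m, _ in r.products} for r in network.reactions)
    return 1 if is_product else -1


@dataclass(frozen=True)
class BalanceSystem:
    """Assembled linear system A r = b with labelled equations."""

    A: np.ndarray
    b: np.ndarray
    reaction_ids: tuple[str, ...]
    equation_labels: tuple[str, ...]
    network: NetworkModel
    scale: float = 100.0

    @property
    def n_equations(self) -> int:
        return self.A.shape[0]

    @property
    def n_unknowns(self) -> int:
        return self.A.shape[1]


def assemble_balance_system(
    S: pd.DataFrame,
    network: NetworkModel,
    measurements: Mapping[str, float] | None = None,
    scale: float = 100.0,
    boundary_rates: Mapping[str, float] | None = None,
) -> BalanceSystem:
    """Build the equality system: PSS balances + anchor + boundary pins.

    Rows are (i) one homogeneous balance per internal_pss metabolite,
    (ii) the anchor flux(reference) = scale, and (iii) one pin per
    measured non-reference boundary metabolite:
    ``S_row . r = sign * scale * C_m / C_ref`` (the concentration-to-rate
    proxy).  ``boundary_rates`` bypasses the proxy with caller-supplied
    net rates.
    """
    rxn_ids = tuple(S.columns)
    ref_rxn = network.reference_reaction_id
    ref_mets = [m for m, _ in network.reactions[rxn_ids.index(ref_rxn)].substrates]

    rows, rhs, labels = [], [], []
    for met in network.internal_ids:
        rows.append(S.loc[met].to_numpy(dtype=float))
        rhs.append(0.0)
        labels.append(f"pss:{met}")

    anchor = np.zeros(len(rxn_ids))
    anchor[rxn_ids.index(ref_rxn)] = 1.0
    rows.append(anchor)
    rhs.append(float(scale))
    labels.append(f"anchor:{ref_rxn}")

    if boundary_rates is not None:
        for met, rate in boundary_rates.items():
            if met in ref_mets:
                continue
            rows.append(S.loc[met].to_numpy(dtype=float))
            rhs.append(float(rate))
            labels.append(f"boundary:{met}")
    else:
        if measurements is None:
            raise NetworkError("either measurements or boundary_rates must be supplied")
        missing = [m for m in network.boundary_ids if m not in measurements]
        if missing:
            raise NetworkError(f"missing measurement for boundary node(s): {missing}")
        # reference concentration: the measured substrate of the reference reaction
        ref_measured = [m for m in ref_mets if m in network.boundary_ids]
        if not ref_measured:
            raise NetworkError(
                f"reference reaction {ref_rxn!r} consumes no boundary_measured metabolite"
            )
        c_ref = float(measurements[ref_measured[0]])
        if c_ref <= 0:
            raise NetworkError("zero or negative reference concentration")
        for met in network.boundary_ids:
            if met in ref_mets:
                continue
            c_m = float(measurements[met])
            if c_m <= 0:
                raise NetworkError(f"nonpositive concentration for {met!r}")
            rows.append(S.loc[met].to_numpy(dtype=float))
            rhs.append(boundary_sign(network, met) * scale * c_m / c_ref)
            labels.append(f"boundary:{met}")

    return BalanceSystem(
        A=np.vstack(rows),
        b=np.asarray(rhs, dtype=float),
        reaction_ids=rxn_ids,
        equation_labels=tuple(labels),
        network=network,
        scale=float(scale),
    )


@dataclass
class FluxResults:
    """Solved flux distribution with diagnostics.

    Attributes
    ----------
    fluxes : pandas.Series
        Per-reaction flux, indexed by reaction id (relative units;
        dimensionless with reference = 100 once normalized).
    residual_norm : float
        2-norm of the internal pseudo-steady-state balance residuals.
    """

    fluxes: pd.Series
    residual_norm: float
    rank: int
    n_equations: int
    n_unknowns: int
    determinacy: str
    normalized: bool
    network: NetworkModel
    scale: float = 100.0
    nonnegative: bool = False

    def normalize(self, reference_reaction_id: str | None = None, scale: float = 100.0) -> "FluxResults":
        return normalize_fluxes(self, reference_reaction_id, scale)

    def internal_residuals(self) -> pd.Series:
        S = build_stoich_matrix(self.network)
        r = self.fluxes.reindex(S.columns).to_numpy()
        res = S.loc[self.network.internal_ids].to_numpy() @ r
        return pd.Series(res, index=self.network.internal_ids, name="residual")

    @property
    def diagnostics(self) -> dict:
        return {
            "rank": int(self.rank),
            "n_equations": int(self.n_equations),
            "n_unknowns": int(self.n_unknowns),
            "determinacy": self.determinacy,
            "residual_norm": float(self.residual_norm),
            "normalized": bool(self.normalized),
            "nonnegative": bool(self.nonnegative),
        }

    def to_frame(self) -> pd.DataFrame:
        pathways = {r.id: r.pathway for r in self.network.reactions}
        return pd.DataFrame(
            {
                "reaction": self.fluxes.index,
                "pathway": [pathways[r] for r in self.fluxes.index],
                "flux": self.fluxes.to_numpy(),
            }
        )

    def summary(self) -> str:
        lines = [
            "Stoichiometric flux solution",
            "=" * 46,
            f"equations: {self.n_equations}   unknowns: {self.n_unknowns}   "
            f"rank: {self.rank}   class: {self.determinacy}",
            f"internal-balance residual norm: {self.residual_norm:.3e}",
            f"normalized: {self.normalized} (reference = {self.network.reference_reaction_id})",
            "-" * 46,
            f"{'reaction':<10}{'pathway':<20}{'flux':>12}",
        ]
        pathways = {r.id: r.pathway for r in self.network.reactions}
        for rid, val in self.fluxes.items():
            lines.append(f"{rid:<10}{pathways[rid]:<20}{val:>12.3f}")
        return "\n".join(lines)


# alias: a solved flux distribution is also the "solution" object
FluxSolution = FluxResults


def _classify(rank: int, n_eq: int, n_unknown: int) -> str:
    if rank < n_unknown:
        return "underdetermined"
    if n_eq > n_unknown:
        return "overdetermined"
    return "determined"


def solve_fluxes(
    system: BalanceSystem,
    nonnegative: bool = False,
    tolerance: float = 1e-8,
) -> FluxResults:
    """Solve the assembled balance system for the flux vector.

    Consistent determined systems are solved exactly; otherwise the
    minimum-norm least-squares solution is returned.  With
    ``nonnegative=True``, fluxes of irreversible reactions are constrained
    >= 0 (bounded least squares); an active constraint that degrades the
    fit beyond tolerance raises :class:`NetworkError` listing the
    offending reactions.
    """
    A, b = system.A, system.b
    rank = int(np.linalg.matrix_rank(A, tol=tolerance))
    if rank == 0:
        raise NetworkError("balance system has rank 0")
    if nonnegative:
        reversible = {r.id: r.reversible for r in system.network.reactions}
        lower = np.array(
            [-np.inf if reversible.get(rid, False) else 0.0 for rid in system.reaction_ids]
        )
        res = optimize.lsq_linear(A, b, bounds=(lower, np.inf), tol=tolerance * 1e-2)
        x = res.x
        full_res = np.linalg.norm(A @ x - b)
        free = np.linalg.lstsq(A, b, rcond=None)[0]
        if full_res > max(tolerance * system.scale, np.linalg.norm(A @ free - b) + tolerance * system.scale):
            violated = [
                rid for rid, v in zip(system.reaction_ids, free) if v < -tolerance
            ]
            raise NetworkError(
                f"nonnegativity constraints infeasible; unconstrained solution "
                f"violates: {violated or 'none identifiable'}"
            )
    else:
        x = np.linalg.lstsq(A, b, rcond=None)[0]

    fluxes = pd.Series(x, index=list(system.reaction_ids), name="flux")
    pss_rows = [i for i, lab in enumerate(system.equation_labels) if lab.startswith("pss:")]
    residual = (A @ x - b)[pss_rows] if pss_rows else np.zeros(0)
    return FluxResults(
        fluxes=fluxes,
        residual_norm=float(np.linalg.norm(residual)),
        rank=rank,
        n_equations=system.n_equations,
        n_unknowns=system.n_unknowns,
        determinacy=_classify(rank, system.n_equations, system.n_unknowns),
        normalized=False,
        network=system.network,
        scale=system.scale,
        nonnegative=nonnegative,
    )


def normalize_fluxes(
    solution: FluxResults,
    reference_reaction_id: str | None = None,
    scale: float = 100.0,
) -> FluxResults:
    """Rescale so the reference reaction carries exactly ``scale`` flux."""
    ref = reference_reaction_id or solution.network.reference_reaction_id
    ref_flux = float(solution.fluxes[ref])
    if ref_flux == 0:
        raise NetworkError(f"reference reaction {ref!r} has zero flux; cannot normalize")
    factor = scale / ref_flux
    fluxes = solution.fluxes * factor
    fluxes[ref] = scale  # exact by construction
    out = replace(
        solution,
        fluxes=fluxes,
        normalized=True,
        residual_norm=float(abs(factor)) * solution.residual_norm,
    )
    return out


class FluxModel:
    """Relative-flux estimator for a metabolic network (model -> results).

    Parameters
    ----------
    network : NetworkModel
        Network topology with node roles; defaults to the packaged
        10-reaction CMP network when None.
    measurements : mapping, optional
        Plasma concentration (umol/mL) per boundary_measured metabolite.
    boundary_rates : mapping, optional
        Direct net production rates, bypassing the concentration proxy.
    scale : float
        Flux assigned to the reference (glucose-uptake) reaction.

    Examples
    --------
    >>> model = FluxModel.from_concentrations(
    ...     {"glc": 5.0, "lac": 2.0, "bhb": 0.3, "nadh": 0.05})
    >>> results = model.fit().normalize()
    >>> float(results.fluxes["r1"])
    100.0
    """

    def __init__(
        self,
        network: NetworkModel | None = None,
        measurements: Mapping[str, float] | None = None,
        boundary_rates: Mapping[str, float] | None = None,
        scale: float = 100.0,
    ) -> None:
        self.network = network if network is not None else load_default_network()
        self.measurements = dict(measurements) if measurements else None
        self.boundary_rates = dict(boundary_rates) if boundary_rates else None
        self.scale = float(scale)
        self.stoich = build_stoich_matrix(self.network)

    @classmethod
    def from_concentrations(
        cls, measurements: Mapping[str, float], network: NetworkModel | None = None, **kw
    ) -> "FluxModel":
        return cls(network=network, measurements=measurements, **kw)

    def system(self) -> BalanceSystem:
        return assemble_balance_system(
            self.stoich,
            self.network,
            measurements=self.measurements,
            scale=self.scale,
            boundary_rates=self.boundary_rates,
        )

    def fit(self, nonnegative: bool = False, tolerance: float = 1e-8) -> FluxResults:
        return solve_fluxes(self.system(), nonnegative=nonnegative, tolerance=tolerance)


def compare_conditions(
    network: NetworkModel,
    measurements_by_condition: Mapping[str, Mapping[str, float]],
    scale: float = 100.0,
    nonnegative: bool = False,
) -> pd.DataFrame:
    """Solve one flux distribution per condition and tabulate differences.

    Returns a frame with one row per reaction, a normalized-flux column
    per condition, and pairwise difference columns (later minus earlier
    in the mapping's order).
    """
    if len(measurements_by_condition) < 2:
        raise ValueError("need at least two conditions to compare")
    fluxes = {}
    for name, meas in measurements_by_condition.items():
        sol = FluxModel(network, measurements=meas, scale=scale).fit(
            nonnegative=nonnegative
        ).normalize()
        fluxes[f"flux_{name}"] = sol.fluxes
    out = pd.DataFrame(fluxes)
    pathways = {r.id: r.pathway for r in network.reactions}
    out.insert(0, "pathway", [pathways[r] for r in out.index])
    names = list(measurements_by_condition)
    for i in range(1, len(names)):
        out[f"diff_{names[i]}_minus_{names[0]}"] = (
            out[f"flux_{names[i]}"] - out[f"flux_{names[0]}"]
        )
    out.index.name = "reaction"
    return out


def export_flux_graph(
    network: NetworkModel,
    solution: FluxResults,
    destination: str | Path,
    min_penwidth: float = 0.5,
    max_penwidth: float = 5.0,
) -> dict[str, Path]:
    """Write the weighted directed flux network as GraphML and DOT.

    One directed edge per (substrate, product) pair of each reaction, all
    sharing the reaction's flux as the ``flux`` edge attribute; DOT pen
    width is an affine monotone map of flux (``min_penwidth`` at flux 0).
    Requires a normalized solution.
    """
    if not solution.normalized:
        raise NetworkError("export requires a normalized solution (call .normalize())")
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)

    G = nx.MultiDiGraph()
    for node in network.nodes:
        G.add_node(node.id, name=node.name or node.id, role=node.role)
    for rxn in network.reactions:
        flux = float(solution.fluxes[rxn.id])
        for sub, _ in rxn.substrates:
            for prod, _ in rxn.products:
                G.add_edge(sub, prod, reaction=rxn.id, pathway=rxn.pathway, flux=flux)

    graphml = dest / "flux_network.graphml"
    nx.write_graphml(G, graphml)

    fmax = max(float(solution.fluxes.abs().max()), 1e-12)
    slope = (max_penwidth - min_penwidth) / fmax
    lines = ["digraph cmp_flux {", "  rankdir=LR;"]
    for node in network.nodes:
        lines.append(f'  "{node.id}" [label="{node.name or node.id}", role="{node.role}"];')
    for u, v, data in G.edges(data=True):
        width = min_penwidth + slope * abs(data["flux"])
        lines.append(
            f'  "{u}" -> "{v}" [label="{data["reaction"]}: {data["flux"]:.1f}", '
            f"penwidth={width:.3f}];"
        )
    lines.append("}")
    dot = dest / "flux_network.dot"
    dot.write_text("\n".join(lines) + "\n")
    return {"graphml": graphml, "dot": dot}
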