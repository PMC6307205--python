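"""Generic mass-action reaction networks and ODE right-hand-side assembly.

A :class:`ReactionNetwork` is a list of species, a list of (possibly
reversible) mass-action reactions, and a table of named rate constants.
Several reactions may reference the same rate constant by name, which is how
shared kinetics (e.g. one trafficking rate set applied to every bound
receptor form) are expressed.

Units convention: cell-associated species are amounts in molecules/cell;
extracellular ligands are concentrations in nM and are clamped (their
time derivative is forced to zero). Rate-constant units follow from the
reaction order under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

COMPARTMENTS = ("extracellular", "surface", "internal", "degraded_pool")


class NetworkConfigError(ValueError):
    """Raised when a network references unknown species/parameters or
    violates a structural invariant."""


@dataclass
class Species:
    name: str
    compartment: str = "internal"
    initial_amount: float = 0.0
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise NetworkConfigError(
                f"unknown compartment {self.compartment!r} for species {self.name}"
            )
        if self.initial_amount < 0:
            raise NetworkConfigError(f"negative initial amount for {self.name}")


@dataclass
class Reaction:
    """A mass-action reaction, reversible when ``kr`` is given.

    ``kf``/``kr`` may be numeric rate constants or names into the owning
    network's parameter table. ``kr=None`` (or 0) marks an irreversible
    reaction. Stoichiometric coefficients must be positive integers.
    """

    label: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    kf: float | str = 0.0
    kr: float | str | None = None

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for _, coeff in side:
                if not (isinstance(coeff, (int, np.integer)) and coeff > 0):
                    raise NetworkConfigError(
                        f"reaction {self.label}: coefficients must be positive integers"
                    )

    @property
    def reversible(self) -> bool:
        return self.kr is not None

    def rate_constant_names(self) -> list[str]:
        names = []
        for k in (self.kf, self.kr):
            if isinstance(k, str):
                names.append(k)
        return names


def _resolve(k, parameters, label):
    if k is None:
        return 0.0
    if isinstance(k, str):
        try:
            return float(parameters[k])
        except KeyError:
            raise NetworkConfigError(f"reaction {label}: unknown parameter {k!r}")
    return float(k)


@dataclass
class ReactionNetwork:
    species: list[Species] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)
    name: str = "network"

    # -- structure ---------------------------------------------------------
    def species_index(self) -> dict[str, int]:
        return {s.name: i for i, s in enumerate(self.species)}

    def validate(self) -> None:
        idx = self.species_index()
        if len(idx) != len(self.species):
            raise NetworkConfigError("duplicate species names")
        labels = {r.label for r in self.reactions}
        if len(labels) != len(self.reactions):
            raise NetworkConfigError("duplicate reaction labels")
        for r in self.reactions:
            for sname, _ in r.reactants + r.products:
                if sname not in idx:
                    raise NetworkConfigError(
                        f"reaction {r.label} references unknown species {sname!r}"
                    )
            for pname in r.rate_constant_names():
                if pname not in self.parameters:
                    raise NetworkConfigError(
                        f"reaction {r.label} references unknown parameter {pname!r}"
                    )

    def initial_state(self, overrides: dict[str, float] | None = None) -> np.ndarray:
        y0 = np.array([s.initial_amount for s in self.species], dtype=float)
        if overrides:
            idx = self.species_index()
            for name, value in overrides.items():
                if name not in idx:
                    raise NetworkConfigError(f"unknown species {name!r} in overrides")
                y0[idx[name]] = value
        return y0

    def stoichiometry_matrix(self) -> np.ndarray:
        """Net stoichiometry S (species x reactions), products minus reactants."""
        idx = self.species_index()
        S = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for sname, c in r.reactants:
                S[idx[sname], j] -= c
            for sname, c in r.products:
                S[idx[sname], j] += c
        return S

    def clamped_mask(self) -> np.ndarray:
        return np.array([s.clamped for s in self.species], dtype=bool)


def mass_action_rate(
    reaction: Reaction,
    state: np.ndarray,
    species_index: dict[str, int],
    parameters: dict[str, float] | None = None,
) -> float:
    """Net flux kf*prod(reactants^coeff) - kr*prod(products^coeff)."""
    parameters = parameters or {}
    kf = _resolve(reaction.kf, parameters, reaction.label)
    kr = _resolve(reaction.kr, parameters, reaction.label)
    fwd = kf
    for sname, c in reaction.reactants:
        if sname not in species_index:
            raise NetworkConfigError(
                f"reaction {reaction.label}: unknown species {sname!r}"
            )
        fwd *= state[species_index[sname]] ** c
    rev = kr
    for sname, c in reaction.products:
        if sname not in species_index:
            raise NetworkConfigError(
                f"reaction {reaction.label}: unknown species {sname!r}"
            )
        rev *= state[species_index[sname]] ** c
    return fwd - rev


class AssembledRHS:
    """Compiled derivative function d(state)/dt = S @ v(state).

    Splits every reversible reaction into forward and reverse mass-action
    terms and evaluates all fluxes with vectorised gather/product. Clamped
    species get derivative identically zero. Also provides the analytic
    Jacobian, which the stiff integrators use.
    """

    def __init__(self, network: ReactionNetwork,
                 parameter_overrides: dict[str, float] | None = None):
        network.validate()
        params = dict(network.parameters)
        if parameter_overrides:
            unknown = set(parameter_overrides) - set(params)
            if unknown:
                raise NetworkConfigError(f"unknown parameters in overrides: {sorted(unknown)}")
            params.update(parameter_overrides)
        idx = network.species_index()
        self.n_species = len(network.species)
        self.clamped = network.clamped_mask()
        self.free = ~self.clamped

        # one row per directed (forward or reverse) flux term
        terms: list[tuple[float, list[tuple[int, int]], dict[int, int]]] = []
        S_cols: list[np.ndarray] = []
        Snet = network.stoichiometry_matrix()
        for j, r in enumerate(network.reactions):
            kf = _resolve(r.kf, params, r.label)
            kr = _resolve(r.kr, params, r.label)
            reac = [(idx[s], c) for s, c in r.reactants]
            prod = [(idx[s], c) for s, c in r.products]
            terms.append((kf, reac, j))
            S_cols.append(Snet[:, j])
            if r.reversible:
                terms.append((kr, prod, j))
                S_cols.append(-Snet[:, j])

        nt = len(terms)
        max_order = max((sum(c for _, c in t[1]) for t in terms), default=1)
        max_order = max(max_order, 1)
        # padded index matrix into state vector extended with a trailing 1.0
        self._gather = np.full((nt, max_order), self.n_species, dtype=np.intp)
        self._k = np.empty(nt)
        self._term_species: list[list[tuple[int, int]]] = []
        for t, (k, sp_coeffs, _) in enumerate(terms):
            self._k[t] = k
            col = 0
            for sidx, c in sp_coeffs:
                for _ in range(c):
                    self._gather[t, col] = sidx
                    col += 1
            self._term_species.append(sp_coeffs)
        self._S = np.column_stack(S_cols) if S_cols else np.zeros((self.n_species, 0))
        self._S[self.clamped, :] = 0.0
        self.parameters = params

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        yext = np.append(y, 1.0)
        v = self._k * yext[self._gather].prod(axis=1)
        return self._S @ v

    def fluxes(self, y: np.ndarray) -> np.ndarray:
        yext = np.append(y, 1.0)
        return self._k * yext[self._gather].prod(axis=1)

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        # d(flux_t)/dy_s via leave-one-out products over the padded gather
        # rows; each occurrence of a species contributes the product of the
        # remaining factors, which sums to the correct power-rule term
        yext = np.append(y, 1.0)
        prods = yext[self._gather]  # (nt, m)
        nt, m = prods.shape
        left = np.ones_like(prods)
        right = np.ones_like(prods)
        np.cumprod(prods[:, :-1], axis=1, out=left[:, 1:])
        np.cumprod(prods[:, :0:-1], axis=1, out=right[:, -2::-1])
        other = left * right * self._k[:, None]  # (nt, m)
        dv = np.zeros((nt, self.n_species + 1))
        rows = np.repeat(np.arange(nt), m)
        np.add.at(dv, (rows, self._gather.ravel()), other.ravel())
        return self._S @ dv[:, :-1]


def assemble_rhs(network: ReactionNetwork,
                 parameter_overrides: dict[str, float] | None = None) -> AssembledRHS:
    return AssembledRHS(network, parameter_overrides)


def conserved_moieties(network: ReactionNetwork) -> list[dict[str, float]]:
    """Basis of weight vectors w with w.T @ S = 0 over non-clamped species.

    Each returned mapping gives integer (where possible) weights per species;
    clamped species are excluded since holding them constant breaks the
    balance that conservation relies on.
    """
    import sympy

    network.validate()
    S = network.stoichiometry_matrix()
    free = ~network.clamped_mask()
    Sf = S[free, :]
    names = [s.name for s, keep in zip(network.species, free) if keep]
    null = sympy.Matrix(Sf.T).nullspace()
    out = []
    for vec in null:
        denom = sympy.lcm([sympy.fraction(x)[1] for x in vec]) if vec else 1
        vec = vec * denom
        weights = {n: float(vec[i]) for i, n in enumerate(names) if vec[i] != 0}
        out.append(weights)
    return out


# -- serialization ---------------------------------------------------------

def network_to_dict(network: ReactionNetwork) -> dict:
    return {
        "name": network.name,
        "species": [
            {
                "name": s.name,
                "compartment": s.compartment,
                "initial_amount": s.initial_amount,
                "clamped": s.clamped,
            }
            for s in network.species
        ],
        "reactions": [
            {
                "label": r.label,
                "reactants": [[s, c] for s, c in r.reactants],
                "products": [[s, c] for s, c in r.products],
                "kf": r.kf,
                "kr": r.kr,
            }
            for r in network.reactions
        ],
        "parameters": {k: float(v) for k, v in network.parameters.items()},
    }


def network_from_dict(data: dict) -> ReactionNetwork:
    net = ReactionNetwork(
        species=[Species(**s) for s in data["species"]],
        reactions=[
            Reaction(
                label=r["label"],
                reactants=[(s, int(c)) for s, c in r["reactants"]],
                products=[(s, int(c)) for s, c in r["products"]],
                kf=r["kf"],
                kr=r.get("kr"),
            )
            for r in data["reactions"]
        ],
        parameters=dict(data.get("parameters", {})),
        name=data.get("name", "network"),
    )
    net.validate()
    return net


def save_yaml(network: ReactionNetwork, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(network_to_dict(network), fh, sort_keys=False)


def load_yaml(path) -> ReactionNetwork:
    with open(path) as fh:
        return network_from_dict(yaml.safe_load(fh))


def to_sbml(network: ReactionNetwork) -> str:
    """Serialize as SBML Level 3 Version 2 with mass-action kinetic laws."""
    from lxml import etree

    SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"
    MATHML_NS = "http://www.w3.org/1998/Math/MathML"
    sbml = etree.Element("{%s}sbml" % SBML_NS, nsmap={None: SBML_NS})
    sbml.set("level", "3")
    sbml.set("version", "2")
    model = etree.SubElement(sbml, "model", id=network.name)
    lc = etree.SubElement(model, "listOfCompartments")
    for comp in COMPARTMENTS:
        etree.SubElement(lc, "compartment", id=comp, constant="true")
    ls = etree.SubElement(model, "listOfSpecies")
    for s in network.species:
        etree.SubElement(
            ls,
            "species",
            id=s.name,
            compartment=s.compartment,
            initialAmount=repr(float(s.initial_amount)),
            hasOnlySubstanceUnits="true",
            boundaryCondition="true" if s.clamped else "false",
            constant="false",
        )
    lp = etree.SubElement(model, "listOfParameters")
    for pname, pval in network.parameters.items():
        etree.SubElement(lp, "parameter", id=pname, value=repr(float(pval)),
                         constant="true")
    lr = etree.SubElement(model, "listOfReactions")

    def mathml_product(k, side):
        math = etree.Element("{%s}math" % MATHML_NS, nsmap={None: MATHML_NS})
        apply_ = etree.SubElement(math, "apply")
        etree.SubElement(apply_, "times")
        if isinstance(k, str):
            ci = etree.SubElement(apply_, "ci")
            ci.text = k
        else:
            cn = etree.SubElement(apply_, "cn")
            cn.text = repr(float(k))
        for sname, c in side:
            for _ in range(c):
                ci = etree.SubElement(apply_, "ci")
                ci.text = sname
        return math

    for r in network.reactions:
        rx = etree.SubElement(lr, "reaction", id=r.label,
                              reversible="true" if r.reversible else "false")
        lre = etree.SubElement(rx, "listOfReactants")
        for sname, c in r.reactants:
            etree.SubElement(lre, "speciesReference", species=sname,
                             stoichiometry=str(c), constant="true")
        lpr = etree.SubElement(rx, "listOfProducts")
        for sname, c in r.products:
            etree.SubElement(lpr, "speciesReference", species=sname,
                             stoichiometry=str(c), constant="true")
        kl = etree.SubElement(rx, "kineticLaw")
        # net rate: kf*prod(reactants) - kr*prod(products)
        math = etree.Element("{%s}math" % MATHML_NS, nsmap={None: MATHML_NS})
        if r.reversible:
            apply_ = etree.SubElement(math, "apply")
            etree.SubElement(apply_, "minus")
            apply_.append(mathml_product(r.kf, r.reactants)[0])
            apply_.append(mathml_product(r.kr, r.products)[0])
        else:
            math.append(mathml_product(r.kf, r.reactants)[0])
        kl.append(math)
    return etree.tostring(sbml, pretty_print=True, xml_declaration=True,
                          encoding="UTF-8").decode()
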