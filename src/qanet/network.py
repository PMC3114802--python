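"""Mass-action genetic-network models of the qa gene cluster.

The core network covers the seven clustered genes (the activator *qa-1F*,
the repressor *qa-1S*, and *qa-2/3/4/x/y*): each gene exists in a
transcriptionally inactive (g0) and active (g1) state toggled by activation
and deactivation reactions, transcribes its mRNA when active, and the mRNA
is translated into protein; QA is transported into the cell by QA-Y and
catabolized QA -> DHQ -> DHS (-> PCA, -> SA) by QA-3/QA-2/QA-4/QA-X; the
repressor sequesters QA-1F (reaction I1), sucrose facilitates that
sequestration (catabolite repression, I3), and internal QA sequesters the
repressor (I2). The extended network adds 36 non-cluster QA-responsive
gene blocks and a second transcription factor protein (NCU03643); the seven
regulatory variants differ in whether QA-1F or the NCU03643 protein (or
both) activates the non-cluster genes.

Every reaction follows mass-action kinetics: its rate is the rate constant
times the product of reactant and catalyst concentrations; catalysts are
consumed and re-produced, so their net stoichiometry is zero. The full
parameter vector theta is the concatenation of one rate constant per
reaction and one initial concentration per species.

The network inventory lives in a JSON registry shipped with the package
(``qanet/data/registry.json``); the builder expands the per-gene blocks and
enforces the expected species/reaction counts as validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from qanet._errors import (
    ParameterError,
    SolverDivergenceError,
    StructuralError,
    ValidationError,
)
from qanet._kernels import heun_integrate

ROLES = ("gene_inactive", "gene_active", "mRNA", "protein", "metabolite", "complex")

VARIANTS = ("all1F-2E", "all3643-2E", "all3643self-2E", "2genes-2E",
            "1F-3643-2E A", "1F-3643-2E B", "1F-3643-2E C")

DEFAULT_STEP_H = 0.01  # hr


@dataclass(frozen=True)
class Species:
    name: str
    role: str

    def __post_init__(self):
        if self.role not in ROLES:
            raise ParameterError(f"unknown species role {self.role!r}")


@dataclass(frozen=True)
class Reaction:
    """reactants/products are ((species name, count), ...); catalysts enter
    the rate and are conserved."""

    label: str
    reactants: tuple = ()
    products: tuple = ()
    catalysts: tuple = ()


@dataclass
class NetworkModel:
    species: tuple
    reactions: tuple
    variant: str = "custom"
    _compiled: dict | None = field(default=None, repr=False, compare=False)

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def n_parameters(self) -> int:
        return self.n_reactions + self.n_species

    def species_index(self, name: str) -> int:
        return self._index()[name]

    def _index(self) -> dict:
        c = self.compiled()
        return c["index"]

    def split_theta(self, theta: np.ndarray):
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (self.n_parameters,):
            raise StructuralError(
                f"theta must have length {self.n_parameters}, got {theta.shape}")
        return theta[: self.n_reactions], theta[self.n_reactions:]

    def compiled(self) -> dict:
        """Flattened factor/stoichiometry arrays for the solver kernel."""
        if self._compiled is None:
            index = {s.name: i for i, s in enumerate(self.species)}
            if len(index) != len(self.species):
                raise ValidationError("species names must be unique")
            f_idx, f_off = [], [0]
            s_idx, s_coef, s_off = [], [], [0]
            for rx in self.reactions:
                net: dict = {}
                for name, count in rx.reactants:
                    if name not in index:
                        raise StructuralError(f"unknown species {name!r}")
                    f_idx.extend([index[name]] * count)
                    net[name] = net.get(name, 0) - count
                for name in rx.catalysts:
                    if name not in index:
                        raise StructuralError(f"unknown species {name!r}")
                    f_idx.append(index[name])
                for name, count in rx.products:
                    if name not in index:
                        raise StructuralError(f"unknown species {name!r}")
                    net[name] = net.get(name, 0) + count
                f_off.append(len(f_idx))
                for name, coef in net.items():
                    if coef != 0:
                        s_idx.append(index[name])
                        s_coef.append(float(coef))
                s_off.append(len(s_idx))
            self._compiled = {
                "index": index,
                "f_idx": np.asarray(f_idx, dtype=np.int64),
                "f_off": np.asarray(f_off, dtype=np.int64),
                "s_idx": np.asarray(s_idx, dtype=np.int64),
                "s_coef": np.asarray(s_coef, dtype=np.float64),
                "s_off": np.asarray(s_off, dtype=np.int64),
            }
        return self._compiled


@dataclass(frozen=True)
class Trajectory:
    time_hr: np.ndarray
    states: np.ndarray  # (n_times, n_species)
    n_clamped: int
    step_h: float


def load_registry(path=None) -> dict:
    """Load the packaged model registry (or one from ``path``)."""
    if path is None:
        text = (resources.files("qanet") / "data" / "registry.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    return json.loads(text)


def _gene_block_species(gene: str) -> list:
    return [Species(f"{gene}:g0", "gene_inactive"),
            Species(f"{gene}:g1", "gene_active"),
            Species(f"{gene}:mRNA", "mRNA")]


def _core(registry: dict):
    core = registry["core"]
    activator = core["activator"]
    species, reactions = [], []
    for g in core["genes"]:
        species.extend(_gene_block_species(g))
        species.append(Species(core["proteins"][g], "protein"))
    for sp in core["extra_species"]:
        species.append(Species(sp["name"], sp["role"]))
    for g in core["genes"]:
        prot = core["proteins"][g]
        reactions += [
            Reaction(f"A_{g}", ((f"{g}:g0", 1),), ((f"{g}:g1", 1),), (activator,)),
            Reaction(f"Ad_{g}", ((f"{g}:g1", 1),), ((f"{g}:g0", 1),)),
            Reaction(f"S_{g}", (), ((f"{g}:mRNA", 1),), (f"{g}:g1",)),
            Reaction(f"Dr_{g}", ((f"{g}:mRNA", 1),), ()),
            Reaction(f"L_{g}", (), ((prot, 1),), (f"{g}:mRNA",)),
            Reaction(f"Dp_{g}", ((prot, 1),), ()),
        ]
    for rx in core["extra_reactions"]:
        reactions.append(Reaction(
            rx["label"],
            tuple((r, 1) for r in rx["reactants"]),
            tuple((p, 1) for p in rx["products"]),
            tuple(rx["catalysts"]),
        ))
    return species, reactions


def build_model(variant: str = "all1F-2E", registry: dict | None = None,
                core_only: bool = False) -> NetworkModel:
    """Expand the registry into a NetworkModel for one regulatory variant.

    Raises ``ValidationError`` if the expanded species/reaction counts
    deviate from the registry's enforced totals.
    """
    registry = registry or load_registry()
    species, reactions = _core(registry)
    expected = registry["expected_counts"]

    if core_only:
        model = NetworkModel(tuple(species), tuple(reactions), "core")
        _validate_counts(model, expected.get("core"))
        return model

    if variant not in registry["variants"]:
        raise ParameterError(f"unknown variant {variant!r}; "
                             f"known: {sorted(registry['variants'])}")
    rules = registry["variants"][variant]
    activator = registry["core"]["activator"]
    reg = registry["regulator_block"]
    reg_gene, reg_protein = reg["gene"], reg["protein"]
    qag = registry["qag_genes"]
    if reg_gene not in qag:
        raise ValidationError("regulator gene must be one of the qag genes")

    def activation_catalysts(gene: str):
        if gene == reg_gene:
            rule = rules["ncu3643_activator"]
            if rule == "dual":
                return (activator, reg_protein)
            return (rule,)
        override = rules.get("overrides", {}).get(gene)
        if override:
            return (override,)
        rule = rules["qag_activator"]
        if rule == "add_both":
            return (activator,)
        return (rule,)

    for g in qag:
        species.extend(_gene_block_species(g))
        reactions += [
            Reaction(f"A_{g}", ((f"{g}:g0", 1),), ((f"{g}:g1", 1),),
                     activation_catalysts(g)),
            Reaction(f"Ad_{g}", ((f"{g}:g1", 1),), ((f"{g}:g0", 1),)),
            Reaction(f"S_{g}", (), ((f"{g}:mRNA", 1),), (f"{g}:g1",)),
            Reaction(f"Dr_{g}", ((f"{g}:mRNA", 1),), ()),
        ]

    species.append(Species(reg_protein, "protein"))
    reactions += [
        Reaction(f"L_{reg_gene}", (), ((reg_protein, 1),), (f"{reg_gene}:mRNA",)),
        Reaction(f"Dp_{reg_gene}", ((reg_protein, 1),), ()),
    ]
    for i, target in enumerate(reg["toggle_targets"], start=1):
        reactions += [
            Reaction(f"X{i}", ((f"{target}:g0", 1),), ((f"{target}:g1", 1),),
                     (reg_protein,)),
            Reaction(f"X{i}r", ((f"{target}:g1", 1),), ((f"{target}:g0", 1),),
                     (reg_protein,)),
        ]

    if rules["qag_activator"] == "add_both":
        for g in qag:
            if g != reg_gene:
                reactions.append(Reaction(
                    f"A2_{g}", ((f"{g}:g0", 1),), ((f"{g}:g1", 1),),
                    (reg_protein,)))

    model = NetworkModel(tuple(species), tuple(reactions), variant)
    _validate_counts(model, expected.get(variant))
    return model


def _validate_counts(model: NetworkModel, expected: dict | None):
    model.compiled()  # also checks name uniqueness and references
    if expected is None:
        return
    if (model.n_species != expected["species"]
            or model.n_reactions != expected["reactions"]):
        raise ValidationError(
            f"variant {model.variant!r} built {model.n_species} species / "
            f"{model.n_reactions} reactions; registry requires "
            f"{expected['species']} / {expected['reactions']}")


def mass_action_rhs(model: NetworkModel, theta: np.ndarray,
                    state: np.ndarray) -> np.ndarray:
    """Time derivative of the concentration vector under mass action."""
    k, _ = model.split_theta(theta)
    state = np.asarray(state, dtype=float)
    if state.shape != (model.n_species,):
        raise StructuralError("state length does not match species count")
    c = model.compiled()
    dx = np.zeros(model.n_species)
    for j in range(model.n_reactions):
        rate = k[j]
        for t in range(c["f_off"][j], c["f_off"][j + 1]):
            rate *= state[c["f_idx"][t]]
        for t in range(c["s_off"][j], c["s_off"][j + 1]):
            dx[c["s_idx"][t]] += c["s_coef"][t] * rate
    return dx


def solve_modified_euler(model: NetworkModel, theta: np.ndarray, t_grid,
                         step_h: float = DEFAULT_STEP_H) -> Trajectory:
    """Heun (modified Euler) trajectory sampled at ``t_grid``.

    Internal steps have fixed size ``step_h`` starting at t = 0; grid values
    are linear interpolations of the internal steps. Negative components
    are clamped to zero and counted.
    """
    if step_h <= 0:
        raise ParameterError("step_h must be positive")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size == 0 or np.any(t_grid < 0):
        raise ParameterError("t_grid must be nonempty and nonnegative")
    k, x0 = model.split_theta(theta)
    c = model.compiled()
    t_max = float(t_grid.max())
    n_steps = max(1, int(np.ceil(t_max / step_h - 1e-12))) if t_max > 0 else 0
    traj, n_clamped, finite = heun_integrate(
        np.ascontiguousarray(x0), np.ascontiguousarray(k),
        c["f_idx"], c["f_off"], c["s_idx"], c["s_coef"], c["s_off"],
        float(step_h), n_steps)
    if not finite:
        raise SolverDivergenceError(
            "trajectory became non-finite; try a smaller step_h")
    step_times = np.arange(n_steps + 1) * step_h
    states = np.empty((t_grid.size, model.n_species))
    for i in range(model.n_species):
        states[:, i] = np.interp(t_grid, step_times, traj[:, i])
    return Trajectory(t_grid.copy(), states, int(n_clamped), step_h)


def reference_theta(model: NetworkModel) -> np.ndarray:
    """A plausible demonstration parameterization (synthetic, not fitted).

    Rates are assigned by reaction kind (per hr, or per unit*hr for
    second-order reactions) and initial concentrations by species role, in
    a regime emulating a shift onto QA: external QA high, sucrose absent,
    some free activator protein so the cluster switches on within hours.
    """
    k = np.empty(model.n_reactions)
    for j, rx in enumerate(model.reactions):
        lbl = rx.label
        if lbl.startswith(("A_", "A2_")):
            k[j] = 0.5
        elif lbl.startswith("Ad_"):
            k[j] = 0.2
        elif lbl.startswith("S_"):
            k[j] = 2.0
        elif lbl.startswith("Dr_"):
            k[j] = 0.5
        elif lbl.startswith("L_"):
            k[j] = 1.0
        elif lbl.startswith("Dp_"):
            k[j] = 0.3
        elif lbl.startswith("T_"):
            k[j] = 1.0
        elif lbl.startswith("P_"):
            k[j] = 0.5
        elif lbl.startswith("X"):
            k[j] = 0.1
        elif lbl.endswith("r"):
            k[j] = 0.1
        elif lbl.startswith("I"):
            k[j] = 0.5
        else:
            k[j] = 0.5
    x0 = np.empty(model.n_species)
    for i, sp in enumerate(model.species):
        if sp.role == "gene_inactive":
            x0[i] = 1.0
        elif sp.role == "gene_active":
            x0[i] = 1e-3
        elif sp.role == "mRNA":
            x0[i] = 0.01
        elif sp.role == "protein":
            x0[i] = 1.0 if sp.name == "QA-1F" else 0.01
        elif sp.role == "metabolite":
            x0[i] = 5.0 if sp.name == "QA_ext" else 1e-3
        else:
            x0[i] = 1e-3
    return np.concatenate([k, x0])


def cascade_model(n_genes: int = 2) -> NetworkModel:
    """Minimal demonstration network: gene 1 is constitutively active, its
    protein activates gene 2, whose protein activates gene 3, and so on.
    Useful for solver checks and small fitting exercises."""
    if n_genes < 1:
        raise ParameterError("need at least one gene")
    species, reactions = [], []
    for g in range(1, n_genes + 1):
        name = f"gene{g}"
        species.extend(_gene_block_species(name))
        species.append(Species(f"P{g}", "protein"))
        if g > 1:
            reactions += [
                Reaction(f"A_{name}", ((f"{name}:g0", 1),),
                         ((f"{name}:g1", 1),), (f"P{g-1}",)),
                Reaction(f"Ad_{name}", ((f"{name}:g1", 1),),
                         ((f"{name}:g0", 1),)),
            ]
        reactions += [
            Reaction(f"S_{name}", (), ((f"{name}:mRNA", 1),), (f"{name}:g1",)),
            Reaction(f"Dr_{name}", ((f"{name}:mRNA", 1),), ()),
            Reaction(f"L_{name}", (), ((f"P{g}", 1),), (f"{name}:mRNA",)),
            Reaction(f"Dp_{name}", ((f"P{g}", 1),), ()),
        ]
    return NetworkModel(tuple(species), tuple(reactions), "cascade")


def cascade_theta(model: NetworkModel) -> np.ndarray:
    """Reference parameters for :func:`cascade_model`: gene 1 starts fully
    active, later genes start off."""
    theta = reference_theta(model)
    _, x0 = model.split_theta(theta)
    idx = model._index()
    x0 = x0.copy()
    x0[idx["gene1:g0"]] = 1e-3
    x0[idx["gene1:g1"]] = 1.0
    for i, sp in enumerate(model.species):
        if sp.role == "protein":
            x0[i] = 0.01
    return np.concatenate([theta[: model.n_reactions], x0])
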