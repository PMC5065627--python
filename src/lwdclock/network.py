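"""Simplified circadian clock gene networks and their ODE simulation.

The two models describe the morning-loop hypothesis for the Arabidopsis
clock at the coarsest useful resolution: one state variable per gene
(mRNA-level abstraction), Hill-type transcriptional regulation and
first-order decay.  The shared core interlocks three motifs:

* the CCA1/TOC1 double-negative loop (CCA1 -| TOC1, TOC1 -| CCA1),
* a repressilator closed through the pseudo-response regulators
  (CCA1 -| TOC1 -| PRR9 -| CCA1) with the morning-loop activation
  CCA1 -> PRR9,
* the LWD1/PRR9 positive feedback loop (PRR9 -> LWD1, LWD1 -> PRR9).

Model I stops there; Model II adds a single activating edge
LWD1 -> CCA1, which contributes exactly two extra parameters (an
activation strength and a half-saturation constant).

Gene ``i`` evolves as

    dx_i/dt = dose_i * v_i * prod_repressors K^h/(K^h + x_s^h)
                       * (1 + sum_activators a_e x_s^h/(K_e^h + x_s^h))
              + ox_i  -  d_i * x_i

with a globally fixed Hill exponent ``h`` (default 2).  Time is
dimensionless during screening; periods are normalised downstream so
that the wild-type period reads 24 h.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

MODEL_I = "MODEL_I"
MODEL_II = "MODEL_II"

ACTIVATION = "activation"
REPRESSION = "repression"

SPECIES = ("CCA1", "PRR9", "TOC1", "LWD1")


class UnknownVariantError(ValueError):
    """Raised for a model variant tag other than MODEL_I / MODEL_II."""


class UnknownGeneError(ValueError):
    """Raised when a genotype perturbs a gene absent from the model."""


class NonIntegrableError(RuntimeError):
    """Raised when the ODE solver fails; screens treat this as a reject."""


@dataclass(frozen=True)
class Edge:
    source: str
    target: str
    sign: str  # ACTIVATION or REPRESSION

    def __post_init__(self):
        if self.sign not in (ACTIVATION, REPRESSION):
            raise ValueError(f"bad edge sign: {self.sign!r}")


# Regulatory wiring shared by both variants: the CCA1/TOC1 double-negative
# loop, the repressilator closed through TOC1 -| PRR9, the morning-loop
# activation CCA1 -> PRR9 and the LWD1/PRR9 positive feedback loop.
_EDGES_I = (
    Edge("CCA1", "TOC1", REPRESSION),
    Edge("TOC1", "CCA1", REPRESSION),
    Edge("PRR9", "CCA1", REPRESSION),
    Edge("TOC1", "PRR9", REPRESSION),
    Edge("CCA1", "PRR9", ACTIVATION),
    Edge("PRR9", "LWD1", ACTIVATION),
    Edge("LWD1", "PRR9", ACTIVATION),
)
_EDGE_LWD_CCA1 = Edge("LWD1", "CCA1", ACTIVATION)


def _edge_param_names(edge: Edge) -> tuple[str, ...]:
    tag = f"{edge.source}_{edge.target}"
    if edge.sign == REPRESSION:
        return (f"K_{tag}",)
    return (f"a_{tag}", f"K_{tag}")


@dataclass(frozen=True)
class GeneNetworkModel:
    """A clock gene network with named kinetic parameters.

    ``dose`` (per-gene production multiplier) and ``extra_production``
    (constitutive term, for overexpression) encode genotype
    perturbations; a wild-type model has dose 1 and no extra production.
    """

    variant_tag: str
    species: tuple[str, ...] = SPECIES
    edges: tuple[Edge, ...] = _EDGES_I
    parameters: dict[str, float] = field(default_factory=dict)
    hill_exponent: float = 2.0
    dose: dict[str, float] = field(default_factory=dict)
    extra_production: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.hill_exponent < 1:
            raise ValueError("hill exponent must be >= 1")
        for name, value in self.parameters.items():
            if name.startswith(("v_", "d_", "K_")) and value <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {value}")

    # -- structure ---------------------------------------------------
    def parameter_names(self) -> tuple[str, ...]:
        names = []
        for g in self.species:
            names.append(f"v_{g}")
        for g in self.species:
            names.append(f"d_{g}")
        for e in self.edges:
            names.extend(_edge_param_names(e))
        return tuple(names)

    def parameter_count(self) -> int:
        return len(self.parameter_names())

    def with_parameters(self, parameters: dict[str, float]) -> "GeneNetworkModel":
        missing = set(self.parameter_names()) - set(parameters)
        if missing:
            raise ValueError(f"missing parameters: {sorted(missing)}")
        return replace(self, parameters=dict(parameters))

    # -- ODE right-hand side ------------------------------------------
    def _production(self, x: np.ndarray) -> np.ndarray:
        """Production term per species at (clipped) state x."""
        x = np.maximum(x, 0.0)  # guard against solver excursions
        h = self.hill_exponent
        p = self.parameters
        idx = {g: i for i, g in enumerate(self.species)}
        prod = np.empty(len(self.species))
        for g in self.species:
            i = idx[g]
            rep = 1.0
            act = 0.0
            has_act = False
            for e in self.edges:
                if e.target != g:
                    continue
                xs = x[idx[e.source]] ** h
                if e.sign == REPRESSION:
                    K = p[f"K_{e.source}_{e.target}"] ** h
                    rep *= K / (K + xs)
                else:
                    has_act = True
                    a = p[f"a_{e.source}_{e.target}"]
                    K = p[f"K_{e.source}_{e.target}"] ** h
                    act += a * xs / (K + xs)
            factor = (1.0 + act) if has_act else 1.0
            prod[i] = (
                self.dose.get(g, 1.0) * p[f"v_{g}"] * rep * factor
                + self.extra_production.get(g, 0.0)
            )
        return prod

    def rhs(self, t: float, x: np.ndarray) -> np.ndarray:
        d = np.array([self.parameters[f"d_{g}"] for g in self.species])
        return self._production(x) - d * np.maximum(x, 0.0)

    # -- serialisation -------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "variant_tag": self.variant_tag,
            "species": list(self.species),
            "edges": [[e.source, e.target, e.sign] for e in self.edges],
            "parameters": self.parameters,
            "hill_exponent": self.hill_exponent,
            "dose": self.dose,
            "extra_production": self.extra_production,
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "GeneNetworkModel":
        doc = json.loads(text)
        return cls(
            variant_tag=doc["variant_tag"],
            species=tuple(doc["species"]),
            edges=tuple(Edge(*e) for e in doc["edges"]),
            parameters={k: float(v) for k, v in doc["parameters"].items()},
            hill_exponent=float(doc["hill_exponent"]),
            dose={k: float(v) for k, v in doc.get("dose", {}).items()},
            extra_production={
                k: float(v) for k, v in doc.get("extra_production", {}).items()
            },
        )


def build_model(variant: str) -> GeneNetworkModel:
    """Construct Model I or Model II (parameters unset until provided)."""
    if variant == MODEL_I:
        return GeneNetworkModel(variant_tag=MODEL_I, edges=_EDGES_I)
    if variant == MODEL_II:
        return GeneNetworkModel(
            variant_tag=MODEL_II, edges=_EDGES_I + (_EDGE_LWD_CCA1,)
        )
    raise UnknownVariantError(f"unknown model variant: {variant!r}")


# ---------------------------------------------------------------------------
# Genotypes

NULL = "null"
KNOCKDOWN = "knockdown"
OVEREXPRESS = "overexpress"


@dataclass(frozen=True)
class Perturbation:
    gene: str
    kind: str  # NULL, KNOCKDOWN or OVEREXPRESS
    strength: float = 1.0  # dose fraction (knockdown) or fold (overexpress)


@dataclass(frozen=True)
class Genotype:
    name: str
    perturbations: tuple[Perturbation, ...] = ()


WT = Genotype("WT")
#: lwd1 lwd2 double mutant: the single LWD1 node models the redundant pair,
#: so the double mutant is a full null of that node.
LWD1LWD2 = Genotype("lwd1lwd2", (Perturbation("LWD1", NULL),))

#: Representative hypomorphic perturbations for the in-silico mutant period
#: analysis.  Single mutants of partially redundant genes (cca1 with LHY
#: intact, prr9 with PRR7/PRR5 intact) retain rhythmicity in planta, so they
#: are modelled as a halved production dose rather than a full null.
MUTANT_DOSE = 0.5
CCA1_MUT = Genotype("cca1", (Perturbation("CCA1", KNOCKDOWN, MUTANT_DOSE),))
PRR9_MUT = Genotype("prr9", (Perturbation("PRR9", KNOCKDOWN, MUTANT_DOSE),))
TOC1_MUT = Genotype("toc1", (Perturbation("TOC1", KNOCKDOWN, MUTANT_DOSE),))

STANDARD_GENOTYPES = {
    g.name: g for g in (WT, LWD1LWD2, CCA1_MUT, PRR9_MUT, TOC1_MUT)
}


def apply_genotype(model: GeneNetworkModel, genotype: Genotype) -> GeneNetworkModel:
    """Return a new model with the genotype's perturbations applied."""
    dose = dict(model.dose)
    extra = dict(model.extra_production)
    for pert in genotype.perturbations:
        if pert.gene not in model.species:
            raise UnknownGeneError(f"unknown gene: {pert.gene!r}")
        if pert.kind == NULL:
            dose[pert.gene] = 0.0
        elif pert.kind == KNOCKDOWN:
            if not 0 < pert.strength < 1:
                raise ValueError("knockdown dose must be in (0, 1)")
            dose[pert.gene] = dose.get(pert.gene, 1.0) * pert.strength
        elif pert.kind == OVEREXPRESS:
            if pert.strength <= 0:
                raise ValueError("overexpression strength must be > 0")
            v = model.parameters.get(f"v_{pert.gene}")
            if v is None:
                raise ValueError("model parameters must be set before OX")
            extra[pert.gene] = extra.get(pert.gene, 0.0) + pert.strength * v
        else:
            raise ValueError(f"unknown perturbation kind: {pert.kind!r}")
    return replace(model, dose=dose, extra_production=extra)


# ---------------------------------------------------------------------------
# Traces and simulation


@dataclass
class Trace:
    """A multi-channel time series on a strictly increasing grid."""

    time: np.ndarray  # hours (or dimensionless screen time)
    values: np.ndarray  # (len(time), n_species)
    species: tuple[str, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.time.size, len(self.species)):
            raise ValueError("values shape does not match time/species")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")

    def channel(self, name: str) -> np.ndarray:
        return self.values[:, self.species.index(name)]

    def window(self, t0: float, t1: float) -> "Trace":
        m = (self.time >= t0) & (self.time <= t1)
        return Trace(self.time[m], self.values[m], self.species, dict(self.metadata))

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=list(self.species))
        df.insert(0, "time_h", self.time)
        return df

    def to_csv(self, path, sidecar: bool = True) -> None:
        self.to_frame().to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".json", "w") as fh:
                json.dump(self.metadata, fh, indent=2, default=str)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        import pandas as pd

        df = pd.read_csv(path)
        species = tuple(c for c in df.columns if c != "time_h")
        return cls(df["time_h"].to_numpy(), df[list(species)].to_numpy(), species)


def simulate(
    model: GeneNetworkModel,
    t_end: float,
    initial_state=None,
    dt_out: float = 0.1,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Trace:
    """Integrate the network ODEs with a stiff-capable adaptive solver.

    Output is resampled onto a uniform grid of spacing ``dt_out``.
    Solver failure raises :class:`NonIntegrableError`; screens catch it
    and count the parameter set as not meeting the criteria.
    """
    n = len(model.species)
    x0 = np.full(n, 0.1) if initial_state is None else np.asarray(
        initial_state, dtype=float
    )
    if x0.shape != (n,) or np.any(x0 < 0):
        raise ValueError("initial state must be nonnegative, one value per species")
    t_eval = np.arange(0.0, t_end + dt_out / 2, dt_out)
    sol = solve_ivp(
        model.rhs,
        (0.0, t_end),
        x0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        raise NonIntegrableError(sol.message)
    values = np.clip(sol.y.T, 0.0, None)
    return Trace(
        sol.t,
        values,
        model.species,
        metadata={
            "variant": model.variant_tag,
            "dose": dict(model.dose),
            "extra_production": dict(model.extra_production),
            "solver": {"method": "LSODA", "rtol": rtol, "atol": atol, "dt_out": dt_out},
        },
    )
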