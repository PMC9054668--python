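"""Reaction network and ODE integration for ligand-evoked ER Ca2+ release.

The network describes the cascade

    ligand + receptor <-> complex
    complex + G <-> complex.G        (the variant-sensitive coupling step)
    complex.G -> complex + Ga
    Ga -> G
    Ga + PLC <-> Ga.PLC
    Ga.PLC + PIP2 -> Ga.PLC + IP3
    IP3 -> 0
    Ca_ER -> Ca_cyt                  (IP3-gated, Hill on IP3)
    Ca_cyt -> Ca_ER                  (saturable pump, Hill n=2)
    Ca_ER -> Ca_cyt                  (first-order leak)

Units are nM and seconds throughout.  ER species concentrations are
expressed in ER volume; fluxes are written in cytosol-equivalent nM/s and
divided by ``er_cyt_volume_ratio`` when applied to ER species, so the
conserved total is ``Ca_cyt + ratio * Ca_ER``.

The ligand is a concentration clamp: its derivative is zero and its value
is stepped to the stimulus concentration on ``[t_on, t_off)`` and zero
elsewhere, mimicking fast perfusion exchange.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import (
    ConfigurationError,
    SimulationError,
    SpeciesLookupError,
    ValidationError,
)

COMPARTMENTS = ("extracellular", "plasma_membrane", "cytosol", "ER")
VARIANTS = ("WT", "A218T")

#: Name of the cytosolic free-Ca2+ species in the default network.
CA_CYT = "Ca_cyt"
CA_ER = "Ca_er"
LIGAND = "OXT"

DEFAULT_ER_CYT_VOLUME_RATIO = 0.18


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str
    initial_amount: float  # nM

    def __post_init__(self):
        if self.compartment not in COMPARTMENTS:
            raise ValidationError(
                f"unknown compartment {self.compartment!r} for species {self.name!r}"
            )
        if self.initial_amount < 0:
            raise ValidationError(
                f"species {self.name!r} has negative initial amount "
                f"{self.initial_amount}"
            )


@dataclass(frozen=True)
class RateParameter:
    name: str
    value: float
    variant_scope: str = "shared"  # shared | wt | mut

    def __post_init__(self):
        if self.variant_scope not in ("shared", "wt", "mut"):
            raise ValidationError(
                f"parameter {self.name!r}: bad variant_scope {self.variant_scope!r}"
            )
        if self.value < 0:
            raise ValidationError(
                f"parameter {self.name!r} has negative value {self.value}"
            )


@dataclass(frozen=True)
class Reaction:
    """One reaction with a rate law.

    law:
      * ``mass_action`` — forward k * prod [reactant]^stoich, optional
        reverse k * prod [product]^stoich.
      * ``michaelis_menten`` — Vmax * S^n / (Km^n + S^n) on the sole
        reactant S (n from law_constants, default 1; n=2 gives the
        saturable pump).
      * ``hill`` — k * [reg]^n / (Km^n + [reg]^n) * prod [reactant]^stoich
        with regulator species named in law_constants (gated transfer).
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    law: str
    forward_param: str
    reverse_param: str | None = None
    law_constants: Mapping[str, float | str] | None = None

    def __post_init__(self):
        if self.law not in ("mass_action", "michaelis_menten", "hill"):
            raise ValidationError(f"reaction {self.id!r}: unknown law {self.law!r}")
        for smap in (self.reactants, self.products):
            for name, sto in smap.items():
                if not (isinstance(sto, int) and sto > 0):
                    raise ValidationError(
                        f"reaction {self.id!r}: stoichiometry of {name!r} "
                        f"must be a positive integer, got {sto!r}"
                    )
        if self.law != "mass_action" and self.reverse_param is not None:
            raise ValidationError(
                f"reaction {self.id!r}: only mass_action may be reversible"
            )

    @property
    def reversible(self) -> bool:
        return self.reverse_param is not None


@dataclass(frozen=True)
class StimulusProtocol:
    ligand: str = LIGAND
    concentration: float = 100.0  # nM
    t_on: float = 50.0
    t_off: float = 250.0
    extracellular_ca: bool = False

    def __post_init__(self):
        if not (0 <= self.t_on < self.t_off):
            raise ValidationError("require 0 <= t_on < t_off")
        if self.concentration < 0:
            raise ValidationError("stimulus concentration must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    t_end: float = 300.0
    n_output_points: int = 2000
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10  # nM
    pre_equilibrate: bool = True

    def __post_init__(self):
        if self.t_end <= 0:
            raise ValidationError("t_end must be > 0")
        if self.n_output_points < 2:
            raise ValidationError("n_output_points must be >= 2")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ValidationError("tolerances must be > 0")


@dataclass
class ReactionNetwork:
    species: list[Species]
    reactions: list[Reaction]
    parameters: list[RateParameter]
    variant: str
    er_cyt_volume_ratio: float = DEFAULT_ER_CYT_VOLUME_RATIO
    ligand: str = LIGAND
    ca_cyt_species: str = CA_CYT

    # caches built by validate()
    _index: dict[str, int] = field(default_factory=dict, repr=False)
    _pvalues: dict[str, float] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        if self.er_cyt_volume_ratio <= 0:
            raise ValidationError("er_cyt_volume_ratio must be > 0")
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate species names")
        self._index = {n: i for i, n in enumerate(names)}
        keys = [(p.name, p.variant_scope) for p in self.parameters]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (parameter, scope) pairs")
        variant_names = {p.name for p in self.parameters if p.variant_scope != "shared"}
        if len(variant_names) > 1:
            raise ValidationError(
                "at most one parameter may carry wt/mut variant scopes, "
                f"found {sorted(variant_names)}"
            )
        want = "wt" if self.variant == "WT" else "mut"
        self._pvalues = {
            p.name: p.value
            for p in self.parameters
            if p.variant_scope in ("shared", want)
        }
        for rxn in self.reactions:
            for smap in (rxn.reactants, rxn.products):
                for name in smap:
                    if name not in self._index:
                        raise ValidationError(
                            f"reaction {rxn.id!r} references unknown species {name!r}"
                        )
            for pname in filter(None, (rxn.forward_param, rxn.reverse_param)):
                if pname not in self._pvalues:
                    raise ValidationError(
                        f"reaction {rxn.id!r} references parameter {pname!r} "
                        f"with no value for variant {self.variant}"
                    )
            if rxn.law == "hill":
                lc = rxn.law_constants or {}
                if lc.get("regulator") not in self._index:
                    raise ValidationError(
                        f"hill reaction {rxn.id!r} needs a known regulator species"
                    )
                if "regulator2" in lc and lc["regulator2"] not in self._index:
                    raise ValidationError(
                        f"hill reaction {rxn.id!r}: unknown regulator2"
                    )
            if rxn.law == "michaelis_menten" and len(rxn.reactants) != 1:
                raise ValidationError(
                    f"michaelis_menten reaction {rxn.id!r} needs exactly one reactant"
                )

    # -- convenience -------------------------------------------------------

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    def species_index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise SpeciesLookupError(f"species {name!r} not in network") from None

    def parameter_value(self, name: str) -> float:
        return self._pvalues[name]

    def with_parameter(self, name: str, value: float) -> "ReactionNetwork":
        """Return a copy with one parameter's value replaced.

        Only the value active for this network's variant is touched: a
        ``shared`` entry, or the wt/mut-scoped entry matching ``variant``.
        """
        if name not in {p.name for p in self.parameters}:
            raise ConfigurationError(f"unknown parameter {name!r}")
        active = ("shared", "wt" if self.variant == "WT" else "mut")
        params = [
            replace(p, value=value)
            if p.name == name and p.variant_scope in active
            else p
            for p in self.parameters
        ]
        return ReactionNetwork(
            species=list(self.species),
            reactions=list(self.reactions),
            parameters=params,
            variant=self.variant,
            er_cyt_volume_ratio=self.er_cyt_volume_ratio,
            ligand=self.ligand,
            ca_cyt_species=self.ca_cyt_species,
        )

    def initial_state(self) -> np.ndarray:
        return np.array([s.initial_amount for s in self.species], dtype=float)

    def volume_factors(self) -> np.ndarray:
        return np.array(
            [
                self.er_cyt_volume_ratio if s.compartment == "ER" else 1.0
                for s in self.species
            ]
        )

    def rhs(self, clamped: Sequence[str] = ()) -> "callable":
        """Build dy/dt(t, y) with the named species' derivatives zeroed."""
        n = len(self.species)
        vol = self.volume_factors()
        clamped_idx = [self._index[c] for c in clamped]

        terms = []  # (rate_fn, stoich_vector)
        for rxn in self.reactions:
            net = np.zeros(n)
            for name, sto in rxn.reactants.items():
                net[self._index[name]] -= sto
            for name, sto in rxn.products.items():
                net[self._index[name]] += sto
            net /= vol
            kf = self._pvalues[rxn.forward_param]
            lc = dict(rxn.law_constants or {})
            r_idx = [(self._index[m], s) for m, s in rxn.reactants.items()]
            if rxn.law == "mass_action":
                p_idx = [(self._index[m], s) for m, s in rxn.products.items()]
                kr = self._pvalues[rxn.reverse_param] if rxn.reversible else 0.0

                def rate(y, kf=kf, kr=kr, r_idx=r_idx, p_idx=p_idx):
                    fwd = kf
                    for i, s in r_idx:
                        fwd *= y[i] ** s
                    if kr:
                        rev = kr
                        for i, s in p_idx:
                            rev *= y[i] ** s
                        return fwd - rev
                    return fwd

            elif rxn.law == "michaelis_menten":
                km = float(lc["km"])
                hn = float(lc.get("hill_n", 1.0))
                (si, _), = r_idx

                def rate(y, kf=kf, km=km, hn=hn, si=si):
                    s = max(y[si], 0.0)
                    sn = s**hn
                    return kf * sn / (km**hn + sn)

            else:  # hill
                km = float(lc["km"])
                hn = float(lc.get("hill_n", 1.0))
                ri = self._index[str(lc["regulator"])]
                # optional second gate (e.g. Ca2+ co-agonism at the IP3R)
                ri2 = km2 = hn2 = None
                if "regulator2" in lc:
                    ri2 = self._index[str(lc["regulator2"])]
                    km2 = float(lc["km2"])
                    hn2 = float(lc.get("hill_n2", 1.0))

                def rate(y, kf=kf, km=km, hn=hn, ri=ri, r_idx=r_idx,
                         ri2=ri2, km2=km2, hn2=hn2):
                    g = max(y[ri], 0.0)
                    gn = g**hn
                    out = kf * gn / (km**hn + gn)
                    if ri2 is not None:
                        g2 = max(y[ri2], 0.0)
                        g2n = g2**hn2
                        out *= g2n / (km2**hn2 + g2n)
                    for i, s in r_idx:
                        out *= y[i] ** s
                    return out

            terms.append((rate, net))

        def f(t, y):
            dy = np.zeros(n)
            for rate, net in terms:
                dy += rate(y) * net
            for i in clamped_idx:
                dy[i] = 0.0
            return dy

        return f


@dataclass
class Trajectory:
    time: np.ndarray  # (T,)
    concentrations: np.ndarray  # (n_species, T)
    species_names: list[str]
    stimulus: StimulusProtocol | None = None
    ca_cyt_species: str = CA_CYT

    def __post_init__(self):
        if np.any(np.diff(self.time) <= 0):
            raise ValidationError("trajectory time must be strictly increasing")

    def species(self, name: str) -> np.ndarray:
        try:
            i = self.species_names.index(name)
        except ValueError:
            raise SpeciesLookupError(f"species {name!r} not in trajectory") from None
        return self.concentrations[i]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.concentrations.T, columns=self.species_names)
        df.insert(0, "time_s", self.time)
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Default parameter table and network topology
# ---------------------------------------------------------------------------

#: (name, compartment) of every species in the default cascade; initial
#: amounts come from the parameter table (``init_*`` rows).
_DEFAULT_SPECIES = [
    (LIGAND, "extracellular"),
    ("R", "plasma_membrane"),
    ("RL", "plasma_membrane"),
    ("G", "plasma_membrane"),
    ("RLG", "plasma_membrane"),
    ("Ga", "plasma_membrane"),
    ("PLC", "plasma_membrane"),
    ("GaPLC", "plasma_membrane"),
    ("PIP2", "plasma_membrane"),
    ("IP3", "cytosol"),
    (CA_CYT, "cytosol"),
    (CA_ER, "ER"),
]

_DEFAULT_REACTIONS = [
    Reaction("ligand_binding", {LIGAND: 1, "R": 1}, {"RL": 1}, "mass_action",
             "kf_bind", "kr_bind"),
    Reaction("coupling", {"RL": 1, "G": 1}, {"RLG": 1}, "mass_action",
             "kf_coupling", "kr_coupling"),
    Reaction("g_activation", {"RLG": 1}, {"RL": 1, "Ga": 1}, "mass_action",
             "k_gact"),
    Reaction("g_deactivation", {"Ga": 1}, {"G": 1}, "mass_action", "k_gdeact"),
    Reaction("plc_activation", {"Ga": 1, "PLC": 1}, {"GaPLC": 1}, "mass_action",
             "kf_plc", "kr_plc"),
    Reaction("ip3_production", {"GaPLC": 1, "PIP2": 1}, {"GaPLC": 1, "IP3": 1},
             "mass_action", "k_ip3prod"),
    Reaction("ip3_degradation", {"IP3": 1}, {}, "mass_action", "k_ip3deg"),
    # IP3R gating: IP3 binding plus Ca2+ co-agonism (CICR); constants are
    # structural and live with the topology, not in the rate table
    Reaction("er_release", {CA_ER: 1}, {CA_CYT: 1}, "hill", "k_rel",
             law_constants={"km": 350.0, "hill_n": 5.0, "regulator": "IP3",
                            "km2": 75.0, "hill_n2": 5.0,
                            "regulator2": CA_CYT}),
    Reaction("er_pump", {CA_CYT: 1}, {CA_ER: 1}, "michaelis_menten", "v_pump",
             law_constants={"km": 160.0, "hill_n": 2.0}),
    Reaction("er_leak", {CA_ER: 1}, {CA_CYT: 1}, "mass_action", "k_leak"),
]

#: Parameter names the coupling overlay requires.
COUPLING_WT = "kf_coupling_wt"
COUPLING_MUT = "kf_coupling_mut"

_REQUIRED_PARAMS = [
    "kf_bind", "kr_bind", COUPLING_WT, COUPLING_MUT, "kr_coupling",
    "k_gact", "k_gdeact", "kf_plc", "kr_plc", "k_ip3prod", "k_ip3deg",
    "k_rel", "v_pump", "k_leak",
] + [f"init_{name}" for name, _ in _DEFAULT_SPECIES]


def default_parameter_table() -> pd.DataFrame:
    """Load the packaged default parameter table.

    The table is a documented stand-in calibrated to produce a single
    physiological transient; any externally supplied table with the same
    column layout (name,value,scope,units,description) substitutes for it.
    """
    with resources.files("oxtrsim.data").joinpath("params_default.csv").open() as fh:
        return pd.read_csv(fh)


def read_parameter_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    missing = {"name", "value"} - set(df.columns)
    if missing:
        raise ConfigurationError(f"parameter table lacks columns {sorted(missing)}")
    return df


def build_network(
    variant: str,
    parameter_table: pd.DataFrame | None = None,
    er_cyt_volume_ratio: float = DEFAULT_ER_CYT_VOLUME_RATIO,
) -> ReactionNetwork:
    """Assemble the validated cascade network for one variant.

    The two variants share every parameter except the receptor/G-protein
    coupling constant: the WT build binds ``kf_coupling`` to the table's
    ``kf_coupling_wt`` value and the A218T build to ``kf_coupling_mut``.
    """
    if variant not in VARIANTS:
        raise ValidationError(f"variant must be one of {VARIANTS}, got {variant!r}")
    table = default_parameter_table() if parameter_table is None else parameter_table
    values: dict[str, float] = {}
    scopes: dict[str, str] = {}
    for _, row in table.iterrows():
        name = str(row["name"]).strip()
        values[name] = float(row["value"])
        scopes[name] = str(row.get("scope", "shared")).strip() or "shared"

    missing = [p for p in _REQUIRED_PARAMS if p not in values]
    if missing:
        raise ValidationError(
            f"parameter table is missing required entries: {missing}"
        )
    unknown = [n for n in values if n not in _REQUIRED_PARAMS]
    if unknown:
        raise ConfigurationError(f"unknown parameter name(s): {unknown}")
    for name, v in values.items():
        if v < 0:
            raise ValidationError(f"parameter {name!r} has negative value {v}")

    species = [
        Species(name, comp, values[f"init_{name}"])
        for name, comp in _DEFAULT_SPECIES
    ]
    params = [
        RateParameter(n, values[n])
        for n in _REQUIRED_PARAMS
        if not n.startswith("init_") and n not in (COUPLING_WT, COUPLING_MUT)
    ]
    params.append(RateParameter("kf_coupling", values[COUPLING_WT], "wt"))
    params.append(RateParameter("kf_coupling", values[COUPLING_MUT], "mut"))
    return ReactionNetwork(
        species=species,
        reactions=list(_DEFAULT_REACTIONS),
        parameters=params,
        variant=variant,
        er_cyt_volume_ratio=er_cyt_volume_ratio,
        ligand=LIGAND,
        ca_cyt_species=CA_CYT,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

PRE_EQUILIBRATION_TIME = 1.0e4  # s

#: concentrations beyond this are unphysical; the integrator is aborted
#: rather than left to grind toward a finite-time blowup
STATE_BOUND = 1.0e12  # nM


def _guarded(f):
    def g(t, y):
        if not np.all(np.isfinite(y)) or np.max(np.abs(y)) > STATE_BOUND:
            raise SimulationError(
                f"non-finite or unbounded state at t = {t:.6g} s",
                failure_time=float(t),
            )
        return f(t, y)

    return g


def _polish_steady_state(f, y, tol, max_iter=12, max_move=1.0):
    """Damped Newton refinement of a near-steady state.

    Uses minimum-norm least-squares steps (the Jacobian is singular along
    conserved totals; the minimum-norm step does not wander along them).
    Steps are capped so the polish can never leave the integrated state's
    neighborhood; if it tries, the unpolished state is returned.
    """
    y = y.copy()
    start = y.copy()
    n = y.size
    for _ in range(max_iter):
        r = f(0.0, y)
        if np.max(np.abs(r)) < 0.1 * tol:
            break
        jac = np.empty((n, n))
        for j in range(n):
            h = 1e-7 * max(abs(y[j]), 1e-3)
            yp = y.copy()
            yp[j] += h
            jac[:, j] = (f(0.0, yp) - r) / h
        step, *_ = np.linalg.lstsq(jac, -r, rcond=None)
        norm = np.max(np.abs(step))
        if norm > 0.1 * max_move:
            step *= 0.1 * max_move / norm
        y += step
        if np.max(np.abs(y - start)) > max_move:
            return start
    np.clip(y, 0.0, None, out=y)
    return y


def pre_equilibrate(network: ReactionNetwork, config: SimulationConfig) -> np.ndarray:
    """Relax the ligand-free system to steady state.

    Integrates for 1e4 s with the ligand clamped at zero, polishes with a
    bounded Newton refinement, and asserts max |dX/dt| < abs_tol/s.
    """
    f = network.rhs(clamped=(network.ligand,))
    y0 = network.initial_state()
    li = network.species_index(network.ligand)
    y0[li] = 0.0
    sol = solve_ivp(
        _guarded(f), (0.0, PRE_EQUILIBRATION_TIME), y0, method="LSODA",
        rtol=config.rel_tol, atol=config.abs_tol,
    )
    if not sol.success:
        raise SimulationError(f"pre-equilibration failed: {sol.message}")
    y = _polish_steady_state(f, sol.y[:, -1], config.abs_tol)
    y[li] = 0.0
    drift = np.max(np.abs(f(0.0, y)))
    if drift >= config.abs_tol:
        raise SimulationError(
            f"pre-equilibration did not reach steady state: "
            f"max |dX/dt| = {drift:.3e} nM/s >= abs_tol"
        )
    return y


def simulate(
    network: ReactionNetwork,
    stimulus: StimulusProtocol,
    config: SimulationConfig = SimulationConfig(),
) -> Trajectory:
    """Integrate the network under a clamped-ligand stimulus protocol.

    The ligand is held at ``stimulus.concentration`` on [t_on, t_off) and
    at 0 elsewhere.  With ``extracellular_ca=False`` (the only mode the
    default network models) there is no plasma-membrane Ca2+ flux, so
    ``Ca_cyt + ratio * Ca_er`` is conserved up to integration error.
    """
    if stimulus.extracellular_ca:
        raise ConfigurationError(
            "extracellular Ca2+ influx is not enabled in the default network; "
            "simulate with extracellular_ca=False"
        )
    if stimulus.ligand != network.ligand:
        raise SpeciesLookupError(
            f"stimulus ligand {stimulus.ligand!r} != network ligand "
            f"{network.ligand!r}"
        )
    li = network.species_index(network.ligand)
    f = network.rhs(clamped=(network.ligand,))

    if config.pre_equilibrate:
        y0 = pre_equilibrate(network, config)
    else:
        y0 = network.initial_state()
    y0 = y0.copy()
    y0[li] = 0.0

    t_grid = np.linspace(0.0, config.t_end, config.n_output_points)
    breaks = [b for b in (stimulus.t_on, stimulus.t_off) if 0.0 < b < config.t_end]
    edges = [0.0] + breaks + [config.t_end]

    out = np.empty((len(network.species), t_grid.size))
    out[:, 0] = y0
    filled = np.zeros(t_grid.size, dtype=bool)
    filled[0] = True

    y = y0
    for a, b in zip(edges[:-1], edges[1:]):
        clamp = stimulus.concentration if stimulus.t_on <= a < stimulus.t_off else 0.0
        y = y.copy()
        y[li] = clamp
        mask = (~filled) & (t_grid > a) & (t_grid <= b)
        t_eval = np.unique(np.concatenate([t_grid[mask], [b]]))
        sol = solve_ivp(
            _guarded(f), (a, b), y, method="LSODA", t_eval=t_eval,
            rtol=config.rel_tol, atol=config.abs_tol,
        )
        if not sol.success:
            raise SimulationError(
                f"integration failed on [{a}, {b}]: {sol.message}",
                failure_time=sol.t[-1] if sol.t.size else a,
            )
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError("non-finite state encountered", failure_time=b)
        interp = {t: sol.y[:, j] for j, t in enumerate(sol.t)}
        for j in np.nonzero(mask)[0]:
            out[:, j] = interp[t_grid[j]]
        filled |= mask
        y = sol.y[:, -1]

    # clamp column: report the held ligand concentration at each grid point
    lig = np.where(
        (t_grid >= stimulus.t_on) & (t_grid < stimulus.t_off),
        stimulus.concentration, 0.0,
    )
    out[li, :] = lig
    return Trajectory(
        time=t_grid,
        concentrations=out,
        species_names=network.species_names,
        stimulus=stimulus,
        ca_cyt_species=network.ca_cyt_species,
    )


def extract_ca_trace(trajectory: Trajectory):
    """Pull the cytosolic free-Ca2+ time series out of a trajectory."""
    from .metrics import CaTrace  # local import to avoid a cycle

    signal = trajectory.species(trajectory.ca_cyt_species)
    t_stim = trajectory.stimulus.t_on if trajectory.stimulus else trajectory.time[0]
    return CaTrace(
        time=trajectory.time.copy(),
        signal=signal.copy(),
        signal_kind="concentration_nM",
        cell_id="simulation",
        t_stim=float(t_stim),
    )


def conserved_totals(network: ReactionNetwork, trajectory: Trajectory) -> dict:
    """Totals that must stay constant with a clamped ligand and no PM flux.

    Returns arrays over time for total receptor, total G-protein and
    volume-weighted total Ca2+.  The clamped ligand is excluded.
    """
    g = trajectory
    r = network.er_cyt_volume_ratio
    return {
        "receptor": g.species("R") + g.species("RL") + g.species("RLG"),
        "g_protein": g.species("G") + g.species("RLG") + g.species("Ga")
        + g.species("GaPLC"),
        "calcium": g.species(CA_CYT) + r * g.species(CA_ER),
    }
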