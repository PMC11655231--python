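"""Mass-balance digital twin of the dynamic infant gastric simulator.

The stomach compartment starts as 100 g of reconstituted formula plus 10 g of
basal SGF. Two secretion streams add nutrient-free mass continuously
(0.5 g/min total at density 1 g/mL); every 20 min an emptying event withdraws
22 g of the emptiable (sub-sieve, well-mixed) phase through a 1 mm mesh.
Coagulated protein ("curd") and any lipid entrapped in it are sieve-retained:
they are excluded from the emptiable phase and never appear in emptied
aliquots. The curd fraction per nutrient follows the phenomenological
saturating time course in :class:`~igastro.protocol.CurdParams`.

Ordering at an event time is empty -> record -> secrete: the aliquot is
withdrawn before that instant's secretion increment, so retention at t = 0 is
exactly 100% and the first event at t = 20 min sees 120 g of chyme.

Mass is conserved to machine precision at every recorded state:
meal + basal SGF + cumulative secretion = chyme + sum of emptied aliquots.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kinetics import RetentionCurve
from .protocol import BufferingParams, DigestionProtocol, FormulaSpec, Nutrient

logger = logging.getLogger(__name__)

__all__ = [
    "GastricState",
    "Aliquot",
    "GastricTimeSeries",
    "init_state",
    "advance",
    "empty_event",
    "run_digestion",
    "nutrient_retention",
    "ph_trajectory",
]


@dataclass(frozen=True)
class GastricState:
    """Snapshot of the stomach compartment at one instant.

    ``water_g`` lumps water and non-protein, non-lipid solids;
    ``resident_secretion_g`` is the part of ``water_g`` contributed by
    secretions and still resident (used for dilution bookkeeping).
    Curd masses are the sieve-retained sub-pools of protein and lipid.
    """

    time: float
    water_g: float
    protein_g: float
    lipid_g: float
    protein_curd_g: float = 0.0
    lipid_curd_g: float = 0.0
    resident_secretion_g: float = 0.0
    secreted_acid_mmol: float = 0.0

    @property
    def chyme_mass_g(self) -> float:
        return self.water_g + self.protein_g + self.lipid_g

    @property
    def protein_emptiable_g(self) -> float:
        return self.protein_g - self.protein_curd_g

    @property
    def lipid_emptiable_g(self) -> float:
        return self.lipid_g - self.lipid_curd_g

    @property
    def emptiable_mass_g(self) -> float:
        return self.chyme_mass_g - self.protein_curd_g - self.lipid_curd_g


@dataclass(frozen=True)
class Aliquot:
    """One emptied digesta sample (the fraction delivered to the intestine)."""

    time: float
    mass_g: float
    protein_g: float
    lipid_g: float


@dataclass
class GastricTimeSeries:
    """Simulator output: chyme states on a time grid plus emptied aliquots."""

    states: list[GastricState]
    aliquots: list[Aliquot]
    formula: FormulaSpec
    protocol: DigestionProtocol
    meal_mass_g: float = 0.0
    basal_mass_g: float = 0.0

    def __post_init__(self) -> None:
        times = [s.time for s in self.states]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("state times must be strictly increasing")

    @property
    def times(self) -> np.ndarray:
        return np.array([s.time for s in self.states])

    def state_at(self, t: float) -> GastricState:
        for s in self.states:
            if math.isclose(s.time, t, abs_tol=1e-9):
                return s
        raise KeyError(f"no recorded state at t = {t} min")

    def secreted_to(self, t: float) -> float:
        """Cumulative secretion mass (g) delivered up to time t."""
        return self.protocol.secretion_rate_g_min * min(t, self.protocol.total_time_min)

    def emptied_to(self, t: float) -> float:
        return sum(a.mass_g for a in self.aliquots if a.time <= t + 1e-9)

    def conservation_error(self, t: float) -> float:
        """inputs(t) - chyme(t) - emptied(t); zero up to float rounding."""
        inputs = self.meal_mass_g + self.basal_mass_g + self.secreted_to(t)
        return inputs - self.state_at(t).chyme_mass_g - self.emptied_to(t)

    def to_frame(self):
        """Tidy table: sample, time_min, compartment, mass_g, protein_g, lipid_g."""
        import pandas as pd

        rows = [
            {
                "sample": self.formula.name,
                "time_min": s.time,
                "compartment": "chyme",
                "mass_g": s.chyme_mass_g,
                "protein_g": s.protein_g,
                "lipid_g": s.lipid_g,
            }
            for s in self.states
        ]
        rows += [
            {
                "sample": self.formula.name,
                "time_min": a.time,
                "compartment": "emptied",
                "mass_g": a.mass_g,
                "protein_g": a.protein_g,
                "lipid_g": a.lipid_g,
            }
            for a in self.aliquots
        ]
        return pd.DataFrame(rows)


def init_state(formula: FormulaSpec, protocol: DigestionProtocol) -> GastricState:
    """Mix the meal with basal SGF at t = 0.

    chyme = meal + basal SGF; protein = meal x protein fraction;
    lipid = meal x fat fraction; no curd yet.
    """
    if protocol.meal_mass_g <= 0:
        raise ValueError("meal mass must be positive")
    protein = protocol.meal_mass_g * formula.protein_frac
    lipid = protocol.meal_mass_g * formula.fat_frac
    water = protocol.meal_mass_g - protein - lipid + protocol.basal_sgf_mass_g
    return GastricState(time=0.0, water_g=water, protein_g=protein, lipid_g=lipid)


def advance(
    state: GastricState,
    dt: float,
    protocol: DigestionProtocol,
    buffering: BufferingParams | None = None,
) -> GastricState:
    """Add dt minutes of continuous, nutrient-free secretion.

    The caller's grid must not straddle an emptying event.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    added = protocol.secretion_rate_g_min * dt
    acid_delivery = buffering.acid_delivery if buffering is not None else 0.0
    acid = protocol.sgf_flow_ml_min * dt * acid_delivery
    return replace(
        state,
        time=state.time + dt,
        water_g=state.water_g + added,
        resident_secretion_g=state.resident_secretion_g + added,
        secreted_acid_mmol=state.secreted_acid_mmol + acid,
    )


def _with_curd(state: GastricState, formula: FormulaSpec) -> GastricState:
    """Refresh the sieve-retained sub-pools from the curd time course."""
    f_p = formula.curd_protein.fraction(state.time)
    f_l = formula.curd_lipid.fraction(state.time)
    return replace(
        state,
        protein_curd_g=f_p * state.protein_g,
        lipid_curd_g=f_l * state.lipid_g,
    )


def empty_event(
    state: GastricState, protocol: DigestionProtocol, formula: FormulaSpec | None = None
) -> tuple[GastricState, Aliquot]:
    """Withdraw one sieved aliquot from the emptiable phase.

    The aliquot has the emptiable phase's composition (well-mixed contract);
    curd pools stay behind. If less than the scheduled 22 g is emptiable the
    stomach is drained of its emptiable phase and a warning is logged.
    """
    if formula is not None:
        state = _with_curd(state, formula)
    emptiable = state.emptiable_mass_g
    if emptiable <= 0:
        logger.warning("no emptiable mass at t = %.1f min; empty aliquot", state.time)
        return state, Aliquot(state.time, 0.0, 0.0, 0.0)
    mass = min(protocol.emptying_mass_g, emptiable)
    if mass < protocol.emptying_mass_g:
        logger.warning(
            "stomach drained at t = %.1f min: %.2f g available of %.2f g scheduled",
            state.time,
            emptiable,
            protocol.emptying_mass_g,
        )
    q = mass / emptiable
    aliquot = Aliquot(
        time=state.time,
        mass_g=mass,
        protein_g=q * state.protein_emptiable_g,
        lipid_g=q * state.lipid_emptiable_g,
    )
    new = replace(
        state,
        water_g=state.water_g * (1 - q),
        protein_g=state.protein_g - aliquot.protein_g,
        lipid_g=state.lipid_g - aliquot.lipid_g,
        resident_secretion_g=state.resident_secretion_g * (1 - q),
    )
    return _with_curd(new, formula) if formula is not None else new, aliquot


def _time_grid(protocol: DigestionProtocol) -> np.ndarray:
    """Union of a 1-min base grid, emptying times and sampling times.

    Points closer than 1e-6 min are merged so float-accumulated event times
    (k x interval) cannot duplicate base-grid points.
    """
    pts = set(np.arange(0.0, protocol.total_time_min + 0.5, 1.0))
    pts.update(protocol.emptying_times())
    pts.update(protocol.sampling_times_min)
    pts.add(protocol.total_time_min)
    ordered = sorted(t for t in pts if 0.0 <= t <= protocol.total_time_min)
    grid = [ordered[0]]
    for t in ordered[1:]:
        if t - grid[-1] > 1e-6:
            grid.append(t)
    if grid[0] != 0.0:
        raise ValueError("time grid must start at 0")
    return np.asarray(grid)


def run_digestion(
    formula: FormulaSpec,
    protocol: DigestionProtocol,
    buffering: BufferingParams | None = None,
) -> GastricTimeSeries:
    """Integrate the digestion protocol over its full time course.

    At each event time the ordering is empty -> record -> secrete. States are
    recorded at every grid point (1-min base grid plus event and sampling
    times), so any sampling time can be read back exactly.
    """
    grid = _time_grid(protocol)
    event_idx = {
        int(np.argmin(np.abs(grid - te)))
        for te in protocol.emptying_times()
        if np.min(np.abs(grid - te)) <= 1e-6
    }
    state = _with_curd(init_state(formula, protocol), formula)
    states = [state]
    aliquots: list[Aliquot] = []
    for i, (prev, t) in enumerate(zip(grid[:-1], grid[1:]), start=1):
        state = advance(state, t - prev, protocol, buffering)
        if i in event_idx:
            state, aliquot = empty_event(state, protocol, formula)
            aliquots.append(aliquot)
        else:
            state = _with_curd(state, formula)
        states.append(state)
    return GastricTimeSeries(
        states=states,
        aliquots=aliquots,
        formula=formula,
        protocol=protocol,
        meal_mass_g=protocol.meal_mass_g,
        basal_mass_g=protocol.basal_sgf_mass_g,
    )


def nutrient_retention(
    ts: GastricTimeSeries,
    nutrient: Nutrient | str,
    at_times: list[float] | None = None,
) -> RetentionCurve:
    """Percent of the initial nutrient mass still in the stomach over time.

    100% at t = 0 by construction (the aliquot precedes secretion at each
    event). ``at_times`` restricts the curve to selected recorded times.
    """
    nutrient = Nutrient(nutrient)
    if nutrient not in (Nutrient.protein, Nutrient.lipid):
        raise ValueError("retention is defined for protein or lipid")
    attr = "protein_g" if nutrient is Nutrient.protein else "lipid_g"
    initial = getattr(ts.states[0], attr)
    if initial <= 0:
        raise ValueError(f"initial {nutrient.value} mass is zero; retention undefined")
    states = ts.states
    if at_times is not None:
        states = [ts.state_at(t) for t in at_times]
    times = [s.time for s in states]
    retained = [100.0 * getattr(s, attr) / initial for s in states]
    return RetentionCurve(
        times=times, retained_pct=retained, nutrient=nutrient.value, sample_id=ts.formula.name
    )


def ph_trajectory(
    ts: GastricTimeSeries, buffering: BufferingParams
) -> list[tuple[float, float]]:
    """Simplified chyme pH over time from the linear titration model.

    pH(t) = max(min_ph, pH0 - acid(t) / (capacity * protein(t))); clamps to
    the floor when chyme protein vanishes. Qualitative use only.
    """
    out = []
    for s in ts.states:
        if buffering.buffer_capacity == 0.0 or s.protein_g <= 0:
            ph = buffering.initial_ph if s.secreted_acid_mmol == 0 else buffering.min_ph
        else:
            drop = s.secreted_acid_mmol / (buffering.buffer_capacity * s.protein_g)
            ph = max(buffering.min_ph, buffering.initial_ph - drop)
        out.append((s.time, ph))
    return out
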