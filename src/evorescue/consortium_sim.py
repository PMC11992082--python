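"""Stochastic serial growth-dilution simulator of an obligate cross-feeding
two-strain consortium.

The model is a minimal mechanistic stand-in for the wet serial-transfer
experiment: two Escherichia coli auxotrophs, ΔI (isoleucine auxotroph,
releases methionine) and ΔM (methionine auxotroph, releases isoleucine),
grow in batch on a shared carbon resource with Monod kinetics on both the
partner-supplied amino acid and the resource.  Amino-acid release is
proportional to the producer's growth, plus a small growth-independent
basal leakage that lets a fresh coculture bootstrap from empty pools.
Rare mutations during auxotroph divisions create autonomous revertants
that grow independently of the amino-acid pools at the prototroph rate
minus a small autonomy cost; arrivals are Poisson with mean
mutation_rate × divisions, seeded at one-cell density.  Stress multiplies
growth rates and adds a death rate, hitting the auxotrophs much harder
than prototroph-like cells (the consortium's heightened stress
sensitivity is what makes reversion to autonomy a rescue route).  Every
48 h cycle ends with a binomial 1:20 bottleneck on absolute cell counts
(demographic stochasticity) and fresh medium.

Deterministic fixed-step integration (dt ≤ 0.05 h) between stochastic
events; mutation arrivals and dilution draws are the only randomness
besides the recorded measurement noise.  Identical config + seed gives
bit-identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .plate_io import (
    CultureType,
    DataError,
    KineticCurve,
    PlateLayout,
    TransferTrajectory,
    Treatment,
)

__all__ = [
    "SimConfig",
    "StressPreset",
    "ConsortiumState",
    "ReplicateTruth",
    "SimulationResult",
    "STRESS_PRESETS",
    "simulate_cycle",
    "apply_dilution",
    "simulate_experiment",
    "ground_truth_table",
]


@dataclass(frozen=True)
class StressPreset:
    """Stress effects, split by physiology.

    Auxotrophs engaged in the mutualism are far more stress-sensitive than
    prototroph-like cells (wild type or autonomy revertants), so growth
    factors and death rates are specified separately.  Yield factors scale
    biomass produced per unit resource under stress and set the stressed
    plateau relative to the benign carrying capacity.
    """

    name: str
    aux_growth_factor: float = 1.0
    aux_death_rate: float = 0.0  # per hour
    proto_growth_factor: float = 1.0
    proto_death_rate: float = 0.0  # per hour
    proto_yield_factor: float = 1.0
    revertant_yield_factor: float = 1.0


# Presets tuned to the qualitative orderings of the two stressors:
# salinity-like = harsher collapse, later recovery onset, but fast
# recovery to a relatively high plateau; PNP-like = milder collapse,
# earlier onset, slower recovery to a lower plateau.
STRESS_PRESETS: dict[str, StressPreset] = {
    "none": StressPreset("none"),
    "salinity-like": StressPreset(
        "salinity-like",
        aux_growth_factor=0.25,
        aux_death_rate=0.030,
        proto_growth_factor=1.00,
        proto_death_rate=0.004,
        proto_yield_factor=0.90,
        revertant_yield_factor=0.38,
    ),
    "pnp-like": StressPreset(
        "pnp-like",
        aux_growth_factor=0.05,
        aux_death_rate=0.080,
        proto_growth_factor=0.95,
        proto_death_rate=0.004,
        proto_yield_factor=0.85,
        revertant_yield_factor=0.17,
    ),
}

_PRESET_TREATMENT = {
    "none": Treatment.NONE,
    "salinity-like": Treatment.SALINITY,
    "pnp-like": Treatment.PNP,
}


@dataclass(frozen=True)
class SimConfig:
    """Simulator parameters.

    Culture-protocol constants default to the serial-transfer protocol:
    20 cycles of 48 h, 40 µl into 760 µl (dilution fraction 0.05), stress
    from the fourth transfer, seeding OD600 of 0.05 per strain.  Biological
    rates are model choices documented in the methods note.
    """

    n_cycles: int = 20
    cycle_hours: float = 48.0
    dt_hours: float = 0.05
    dilution_fraction: float = 0.05
    stress_start: int = 4
    r_max_prototroph: float = 0.14  # per hour
    r_max_auxotroph: float = 0.12  # per hour
    monod_K_aa: float = 0.001  # amino-acid pool, OD-equivalent units
    monod_K_resource: float = 0.25  # OD-equivalent
    release_met: float = 0.50  # met released by ΔI per unit ΔI growth
    release_ile: float = 3.0  # ile released by ΔM per unit ΔM growth
    basal_release: float = 0.01  # aa per OD biomass per hour
    mutation_rate: float = 1e-8  # autonomy reversions per division
    autonomy_cost: float = 0.05  # fractional growth-rate reduction
    resource_capacity: float = 0.9  # OD-equivalent carrying capacity
    od_noise_sd: float = 0.003  # measurement noise, OD600
    cells_per_od: float = 6.4e8  # 8e8 cells/ml/OD × 0.8 ml working volume
    extinction_cells: float = 1.0
    initial_od_per_strain: float = 0.05
    seed: int = 0
    revertant_strains: tuple[str, ...] = ("dI",)  # which auxotroph can revert
    pre_stress_mutation: bool = True  # standing variation before stress onset

    def __post_init__(self) -> None:
        if not (0.0 < self.dilution_fraction <= 1.0):
            raise DataError("dilution_fraction must be in (0, 1]")
        if not (0.0 <= self.mutation_rate < 1.0):
            raise DataError("mutation_rate must be in [0, 1)")
        if not (0.0 <= self.autonomy_cost <= 1.0):
            raise DataError("autonomy_cost must be in [0, 1]")
        for name in ("r_max_prototroph", "r_max_auxotroph", "release_met",
                     "release_ile", "basal_release", "od_noise_sd"):
            if getattr(self, name) < 0:
                raise DataError(f"{name} must be >= 0")
        bad = set(self.revertant_strains) - {"dI", "dM"}
        if bad:
            raise DataError(f"unknown revertant strains {sorted(bad)}")


@dataclass
class ConsortiumState:
    """Densities (OD-equivalent) of each strain plus the shared pools."""

    n_dI: float
    n_dM: float
    n_rev_dI: float = 0.0
    n_rev_dM: float = 0.0
    n_prototroph: float = 0.0
    aa_met: float = 0.0
    aa_ile: float = 0.0
    resource: float = 0.9

    @property
    def n_revertant(self) -> float:
        return self.n_rev_dI + self.n_rev_dM

    @property
    def total_biomass(self) -> float:
        return self.n_dI + self.n_dM + self.n_rev_dI + self.n_rev_dM + self.n_prototroph

    def check(self) -> None:
        vals = (self.n_dI, self.n_dM, self.n_rev_dI, self.n_rev_dM,
                self.n_prototroph, self.aa_met, self.aa_ile, self.resource)
        if any(v < -1e-9 for v in vals):
            raise RuntimeError(f"negative simulator state: {self}")


def fresh_state(config: SimConfig, culture: str = "mutualism") -> ConsortiumState:
    if culture == "mutualism":
        return ConsortiumState(
            n_dI=config.initial_od_per_strain,
            n_dM=config.initial_od_per_strain,
            resource=config.resource_capacity,
        )
    if culture == "prototroph":
        return ConsortiumState(
            n_dI=0.0, n_dM=0.0,
            n_prototroph=config.initial_od_per_strain,
            resource=config.resource_capacity,
        )
    raise DataError(f"unknown culture {culture!r}")


def simulate_cycle(
    state: ConsortiumState,
    config: SimConfig,
    stress: StressPreset,
    rng: np.random.Generator,
    mutation_enabled: bool = True,
    record_every_minutes: float | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray] | None, ConsortiumState]:
    """Integrate one batch growth cycle.

    Returns ``(trajectory, end_state)`` where trajectory is
    ``(times_minutes, total_od)`` sampled every ``record_every_minutes``
    (None disables recording).  Growth of each auxotroph is capped per
    step by its amino-acid pool (1:1 consumption) and all growth by the
    remaining resource; release of the partner amino acid is proportional
    to the producer's realized growth.  Mutant lineages arrive as Poisson
    events with mean mutation_rate × divisions and are seeded at one-cell
    density.
    """
    cfg = config
    dt = cfg.dt_hours
    n_steps = max(1, int(round(cfg.cycle_hours / dt)))
    K_aa, K_R = cfg.monod_K_aa, cfg.monod_K_resource
    r_aux = cfg.r_max_auxotroph * stress.aux_growth_factor
    r_rev = cfg.r_max_prototroph * (1.0 - cfg.autonomy_cost) * stress.proto_growth_factor
    r_pro = cfg.r_max_prototroph * stress.proto_growth_factor
    d_aux, d_pro = stress.aux_death_rate, stress.proto_death_rate
    y_rev, y_pro = stress.revertant_yield_factor, stress.proto_yield_factor
    rel_met, rel_ile, basal = cfg.release_met, cfg.release_ile, cfg.basal_release
    cells = cfg.cells_per_od
    one_cell = 1.0 / cells
    mu = cfg.mutation_rate if mutation_enabled else 0.0
    mutate_dI = mu > 0 and "dI" in cfg.revertant_strains
    mutate_dM = mu > 0 and "dM" in cfg.revertant_strains

    nI, nM = state.n_dI, state.n_dM
    rI, rM = state.n_rev_dI, state.n_rev_dM
    nP = state.n_prototroph
    met, ile, R = state.aa_met, state.aa_ile, state.resource

    record = record_every_minutes is not None
    if record:
        every = max(1, int(round(record_every_minutes / (dt * 60.0))))
        times = [0.0]
        ods = [nI + nM + rI + rM + nP]

    for step in range(n_steps):
        fR = R / (K_R + R) if R > 0 else 0.0
        # potential biomass gains this step, capped by amino-acid pools
        gI = r_aux * (ile / (K_aa + ile)) * fR * nI * dt if ile > 0 else 0.0
        if gI > ile:
            gI = ile
        gM = r_aux * (met / (K_aa + met)) * fR * nM * dt if met > 0 else 0.0
        if gM > met:
            gM = met
        gRI = r_rev * fR * rI * dt
        gRM = r_rev * fR * rM * dt
        gP = r_pro * fR * nP * dt
        # shared resource: auxotrophs at unit yield, revertants/prototroph
        # at their stressed yield factors
        demand = gI + gM + (gRI + gRM) / y_rev + gP / y_pro
        if demand > R and demand > 0:
            scale = R / demand
            gI *= scale
            gM *= scale
            gRI *= scale
            gRM *= scale
            gP *= scale
            demand = R
        R -= demand
        met += rel_met * gI + basal * nI * dt - gM
        ile += rel_ile * gM + basal * nM * dt - gI
        if met < 0.0:
            met = 0.0
        if ile < 0.0:
            ile = 0.0
        nI += gI - d_aux * nI * dt
        nM += gM - d_aux * nM * dt
        rI += gRI - d_pro * rI * dt
        rM += gRM - d_pro * rM * dt
        nP += gP - d_pro * nP * dt
        if mutate_dI and gI > 0:
            k = rng.poisson(mu * gI * cells)
            if k:
                rI += k * one_cell
                nI = max(nI - k * one_cell, 0.0)
        if mutate_dM and gM > 0:
            k = rng.poisson(mu * gM * cells)
            if k:
                rM += k * one_cell
                nM = max(nM - k * one_cell, 0.0)
        if record and (step + 1) % every == 0:
            times.append((step + 1) * dt * 60.0)
            ods.append(nI + nM + rI + rM + nP)

    end = ConsortiumState(nI, nM, rI, rM, nP, met, ile, R)
    end.check()
    traj = (np.asarray(times), np.asarray(ods)) if record else None
    return traj, end


def apply_dilution(
    state: ConsortiumState,
    config: SimConfig,
    rng: np.random.Generator,
) -> ConsortiumState:
    """Binomial 1:20 bottleneck into fresh medium.

    Each strain's transferred cell count is binomial with
    p = dilution_fraction over its absolute cell count; strains landing
    below ``extinction_cells`` are set to zero.  The transferred aliquot
    is spent medium, so the free amino-acid pools carry over at the
    dilution fraction (deterministically — molecule numbers are huge);
    the resource resets to the fresh-medium capacity.
    """
    cells = config.cells_per_od
    p = config.dilution_fraction

    def draw(od: float) -> float:
        n = int(round(od * cells))
        if n <= 0:
            return 0.0
        k = rng.binomial(n, p)
        if k < config.extinction_cells:
            return 0.0
        return k / cells

    out = ConsortiumState(
        n_dI=draw(state.n_dI),
        n_dM=draw(state.n_dM),
        n_rev_dI=draw(state.n_rev_dI),
        n_rev_dM=draw(state.n_rev_dM),
        n_prototroph=draw(state.n_prototroph),
        aa_met=state.aa_met * p,
        aa_ile=state.aa_ile * p,
        resource=config.resource_capacity,
    )
    out.check()
    return out


@dataclass
class ReplicateTruth:
    """Ground truth extracted from the simulator, for pipeline validation."""

    population: str
    rescued: bool
    establishment_cycle: int | None  # first cycle after which a revertant lineage persists
    surviving_strain: str  # dI-revertant | dM-revertant | both | none
    final_od: float  # noiseless end-of-run biomass


@dataclass
class SimulationResult:
    trajectories: list[TransferTrajectory]
    truths: list[ReplicateTruth]
    kinetic_curves: list[KineticCurve] = field(default_factory=list)
    treatment: str = "none"
    culture: str = "mutualism"


def _establishment_cycle(rev_cells_by_cycle: Sequence[float]) -> int | None:
    """First 1-based cycle from which the revertant pool stays >= 1 cell."""
    est = None
    for c, cells in enumerate(rev_cells_by_cycle, start=1):
        if cells >= 1.0:
            if est is None:
                est = c
        else:
            est = None
    return est


def simulate_experiment(
    config: SimConfig,
    n_replicates: int = 48,
    treatment: str | StressPreset = "salinity-like",
    culture: str = "mutualism",
    kinetics_cycles: Sequence[int] = (),
    survival_od: float = 0.02,
) -> SimulationResult:
    """Run the full serial-transfer experiment for one treatment arm.

    The first ``stress_start - 1`` cycles are unstressed; the treatment
    preset applies from cycle ``stress_start`` through ``n_cycles``.
    End-of-cycle OD600 readings are total biomass plus Gaussian
    measurement noise (sd ``od_noise_sd``, truncated at 0).  Fully
    reproducible from ``config.seed``; each replicate consumes its own
    spawned stream.
    """
    if n_replicates < 1:
        raise DataError("n_replicates must be >= 1")
    preset = (
        treatment if isinstance(treatment, StressPreset)
        else STRESS_PRESETS.get(treatment)
    )
    if preset is None:
        raise DataError(
            f"unknown treatment {treatment!r}; presets: {sorted(STRESS_PRESETS)}"
        )
    no_stress = STRESS_PRESETS["none"]
    mapped = _PRESET_TREATMENT.get(preset.name, Treatment.NONE)
    culture_type = (
        CultureType.MUTUALISM if culture == "mutualism" else CultureType.PROTOTROPH
    )
    culture_code = 0 if culture == "mutualism" else 1
    tag = {"mutualism": "mut", "prototroph": "pro"}[culture]
    prefix = preset.name.replace("-like", "").replace("-", "")

    trajs: list[TransferTrajectory] = []
    truths: list[ReplicateTruth] = []
    kcurves: list[KineticCurve] = []
    transfers = np.arange(1, config.n_cycles + 1)
    record_cycles = set(int(c) for c in kinetics_cycles)

    for rep in range(n_replicates):
        rng = np.random.default_rng([config.seed, culture_code, rep])
        state = fresh_state(config, culture)
        pop_id = f"{prefix}_{tag}_{rep + 1:02d}"
        meta = PlateLayout(pop_id, culture_type, mapped, replicate=rep + 1)
        readings = np.empty(config.n_cycles)
        rev_cells = []
        for cycle in range(1, config.n_cycles + 1):
            stressed = preset.name != "none" and cycle >= config.stress_start
            mutation_enabled = config.pre_stress_mutation or stressed
            rec = 5.0 if cycle in record_cycles else None
            ktraj, state = simulate_cycle(
                state,
                config,
                preset if stressed else no_stress,
                rng,
                mutation_enabled=mutation_enabled,
                record_every_minutes=rec,
            )
            if ktraj is not None:
                times, ods = ktraj
                noise = rng.normal(0.0, config.od_noise_sd, size=len(ods))
                kcurves.append(
                    KineticCurve(
                        times,
                        np.clip(ods + noise, 0.0, None),
                        PlateLayout(
                            f"{pop_id}_c{cycle:02d}", culture_type, mapped,
                            replicate=rep + 1,
                        ),
                    )
                )
            readings[cycle - 1] = max(
                state.total_biomass + rng.normal(0.0, config.od_noise_sd), 0.0
            )
            rev_cells.append(state.n_revertant * config.cells_per_od)
            if cycle < config.n_cycles:
                state = apply_dilution(state, config, rng)
        trajs.append(
            TransferTrajectory(transfers, readings, config.stress_start, meta)
        )
        final_od = state.total_biomass
        est = _establishment_cycle(rev_cells)
        has_rev_dI = state.n_rev_dI * config.cells_per_od >= 1.0
        has_rev_dM = state.n_rev_dM * config.cells_per_od >= 1.0
        if has_rev_dI and has_rev_dM:
            surv = "both"
        elif has_rev_dI:
            surv = "dI-revertant"
        elif has_rev_dM:
            surv = "dM-revertant"
        else:
            surv = "none"
        truths.append(
            ReplicateTruth(
                population=pop_id,
                rescued=bool(est is not None and final_od > survival_od),
                establishment_cycle=est,
                surviving_strain=surv,
                final_od=final_od,
            )
        )
    return SimulationResult(trajs, truths, kcurves, preset.name, culture)


def ground_truth_table(result: SimulationResult | Iterable[ReplicateTruth]) -> pd.DataFrame:
    truths = result.truths if isinstance(result, SimulationResult) else list(result)
    return pd.DataFrame(
        {
            "population": t.population,
            "rescued": t.rescued,
            "establishment_cycle": t.establishment_cycle,
            "surviving_strain": t.surviving_strain,
            "final_od": t.final_od,
        }
        for t in truths
    )
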