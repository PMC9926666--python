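"""Synthetic plate experiments: mechanistic batch cultures under secondary
substrate limitation, their 2D fluorescence spectra, offline tables and
headspace pO2 traces.

The kinetic scheme is this package's own minimal mechanism reproducing the
qualitative phases of glycerol batch cultures of a GFP-expressing yeast whose
medium is starved of one secondary substrate (Mg2+, K+ or PO4 3-):

* phase 1 (secondary substrate M and glycerol S both present): Monod growth
  on glycerol, M and S consumed stoichiometrically with biomass X;
* phase 2 (M depleted, S left): growth decouples from the secondary
  substrate -- biomass accumulates at a slow, roughly linear rate while
  glycerol keeps being consumed for growth and maintenance;
* phase 3 (S depleted): metabolic activity ceases; the culture pH relaxes
  back toward its starting value.

GFP expression is driven by derepression of a glycerol-repressed promoter:
production scales with biomass times a saturating derepression term that
switches on as glycerol runs low.  Under limitation the behaviour is
substrate-specific (``gfp_limitation_mode``): magnesium/potassium starvation
stalls GFP production, phosphate starvation amplifies the final burst.  After
glycerol depletion GFP production decays exponentially, giving the
asymptotic flattening seen in such cultures.

Culture pH falls linearly with accumulated biomass (lumped MES-buffer
acidification) and relaxes first-order after depletion.  The oxygen transfer
rate is coupled to glycerol uptake through a fixed respiratory yield.

Fluorescence spectra are sums of Gaussian fluorophore peaks (GFP, NADH,
flavins) whose amplitudes follow the culture state, a biomass-driven
scattered-light ridge along the diagonal, a flat baseline, and
intensity-dependent Gaussian noise.  Peak positions place signal under the
conventional readout channels (GFP ex 420 / em 530 nm, scattered light
600/600 nm); their shapes are configuration, not measured truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .data_model import (
    CultureCondition,
    EEMGrid,
    EEMeasurement,
    OfflineSample,
    OfflineTable,
    PlateExperiment,
    SpectrumSeries,
    default_grid,
)
from .otr_monitor import O2_PARTIAL_PRESSURE_AIR_BAR, R_BAR_L, PO2Trace

__all__ = [
    "KineticParams",
    "FluorophoreComponent",
    "SimConfig",
    "BioprocessTrajectory",
    "media_design",
    "simulate_batch",
    "synthesize_eem",
    "generate_experiment",
    "cdw_from_od600",
    "default_fluorophores",
    "PRESETS",
]

GLYCEROL_MOLAR_MASS = 92.09  # g/mol


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------


@dataclass
class KineticParams:
    """Parameters of the three-phase batch mechanism.

    Units: concentrations g/L (X, S) and mg/L (M); rates 1/h; yields gX/gS
    and gX/mg(M); ``yos`` mol O2 per mol glycerol consumed.
    """

    mu_max: float = 0.22  # 1/h
    ks_glycerol: float = 0.1  # g/L
    yield_xs: float = 0.34  # gX per g glycerol
    yield_xm: float = 0.45  # gX per mg secondary substrate
    s0: float = 12.0  # g/L glycerol
    m0: float = 295.8  # mg/L secondary substrate
    x0: float = 0.03  # g/L initial CDW
    limited_growth_rate: float = 0.06  # g/L/h biomass rate after M depletion
    maintenance_qs: float = 0.02  # g glycerol per gX per h, phase 2 only
    gfp_derepression_k: float = 0.5  # g/L; half-saturation of derepression
    gfp_rate: float = 50.0  # a.u. per (gX/L) per h
    gfp_limitation_mode: str = "stall"  # stall | continue | burst
    gfp_burst_amp: float = 3.0  # amplification of the burst mode near S -> 0
    gfp_post_decay: float = 0.15  # 1/h; GFP production decay after S depletion
    ph0: float = 6.0
    ph_drop_per_gX: float = 0.128  # pH units per g/L biomass formed
    ph_recovery_rate: float = 0.15  # 1/h toward ph0 after S depletion
    yos: float = 1.40  # mol O2 per mol glycerol

    def __post_init__(self) -> None:
        for name in ("mu_max", "ks_glycerol", "yield_xs", "yield_xm", "s0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.x0 < 0 or self.m0 < 0:
            raise ValueError("x0 and m0 must be non-negative")
        if self.gfp_limitation_mode not in ("stall", "continue", "burst"):
            raise ValueError(f"unknown gfp_limitation_mode {self.gfp_limitation_mode!r}")


@dataclass
class BioprocessTrajectory:
    """Simulated state time-courses of one culture."""

    times: np.ndarray  # h
    X: np.ndarray  # biomass CDW, g/L
    S: np.ndarray  # glycerol, g/L
    M: np.ndarray  # secondary substrate, mg/L
    G: np.ndarray  # GFP, a.u.
    ph: np.ndarray
    otr: np.ndarray  # mmol O2 / L / h
    po2: np.ndarray  # % air saturation (end of a nominal measuring phase)

    def at(self, times: np.ndarray) -> dict[str, np.ndarray]:
        """Linear interpolation of all state variables at arbitrary times."""
        q = np.asarray(times, dtype=float)
        return {
            name: np.interp(q, self.times, getattr(self, name))
            for name in ("X", "S", "M", "G", "ph", "otr", "po2")
        }


def _po2_percent_from_otr(
    otr_mmol: np.ndarray,
    vg: float = 2.6e-3,
    vl: float = 0.8e-3,
    temperature: float = 303.15,
    t_measure: float = 0.125,
) -> np.ndarray:
    """Headspace pO2 at the end of a stop-flow measuring phase (%, air = 100)."""
    slope_bar = otr_mmol / 1000.0 * vl * R_BAR_L * temperature / vg  # bar/h
    drop_pct = slope_bar * t_measure / O2_PARTIAL_PRESSURE_AIR_BAR * 100.0
    return np.clip(100.0 - drop_pct, 0.0, None)


def simulate_batch(
    params: KineticParams, duration: float, dt: float = 0.01
) -> BioprocessTrajectory:
    """Deterministic forward integration of the three-phase batch mechanism.

    Explicit Euler with stoichiometric clamping: within a step, biomass
    growth is limited by the remaining glycerol and secondary substrate, so
    the mass link X - x0 <= Yxs (s0 - S) holds exactly (to float rounding)
    and states never go negative.  If a step still drives a state negative
    (pathological parameters) the step size is halved adaptively.
    """
    if duration <= 0 or dt <= 0:
        raise ValueError("duration and dt must be positive")
    p = params
    n = int(round(duration / dt)) + 1
    times = np.linspace(0.0, duration, n)
    X = np.empty(n)
    S = np.empty(n)
    M = np.empty(n)
    G = np.empty(n)
    ph = np.empty(n)
    otr = np.empty(n)

    x, s, m, g = p.x0, p.s0, p.m0, 0.0
    cur_ph = p.ph0
    t_dep: float | None = None  # time glycerol ran out
    eps = 1e-12

    for i, t in enumerate(times):
        # --- record rates at the current state -------------------------
        if s > eps and m > eps:
            mu = p.mu_max * s / (p.ks_glycerol + s)
            ds_dt = mu * x / p.yield_xs
        elif s > eps:
            dx_dt = p.limited_growth_rate * s / (p.ks_glycerol + s)
            ds_dt = dx_dt / p.yield_xs + p.maintenance_qs * x
        else:
            ds_dt = 0.0
        otr[i] = p.yos * ds_dt * 1000.0 / GLYCEROL_MOLAR_MASS
        X[i], S[i], M[i], G[i], ph[i] = x, s, m, g, cur_ph
        if i == n - 1:
            break

        # --- advance one step (with adaptive halving safeguard) --------
        h = dt
        sub_left = 1.0
        guard = 0
        while sub_left > 1e-9:
            xn, sn, mn, gn, phn, hit_dep = _euler_step(p, x, s, m, g, cur_ph, h, t_dep, t)
            if min(xn, sn, mn) < -1e-9:
                h /= 2.0
                guard += 1
                if guard > 40:
                    raise FloatingPointError("step size underflow during integration")
                continue
            x, s, m, g, cur_ph = xn, sn, mn, gn, phn
            if hit_dep and t_dep is None:
                t_dep = t + h
            t += h
            sub_left -= h / dt
            h = min(h, dt * sub_left) if sub_left > 1e-9 else h

    po2 = _po2_percent_from_otr(otr)
    return BioprocessTrajectory(times=times, X=X, S=S, M=M, G=G, ph=ph, otr=otr, po2=po2)


def _euler_step(
    p: KineticParams,
    x: float,
    s: float,
    m: float,
    g: float,
    cur_ph: float,
    h: float,
    t_dep: float | None,
    t: float,
):
    """One clamped Euler step; returns new state and whether S hit zero."""
    eps = 1e-12
    hit_dep = False
    if s > eps and m > eps:
        mu = p.mu_max * s / (p.ks_glycerol + s)
        dx = mu * x * h
        dx = min(dx, s * p.yield_xs, m * p.yield_xm)  # stoichiometric clamp
        ds = dx / p.yield_xs
        dm = dx / p.yield_xm
        x += dx
        s = 0.0 if s - ds < eps else s - ds
        m = 0.0 if m - dm < eps else m - dm
        gfp_factor = 1.0
        if s == 0.0:
            hit_dep = True
    elif s > eps:
        dx = p.limited_growth_rate * s / (p.ks_glycerol + s) * h
        ds = dx / p.yield_xs + p.maintenance_qs * x * h
        if ds > s:  # scale the step so S lands exactly on zero
            frac = s / ds
            dx *= frac
            ds = s
            hit_dep = True
        x += dx
        s -= ds
        if s < eps:
            s = 0.0
            hit_dep = True
        if p.gfp_limitation_mode == "stall":
            gfp_factor = 0.0
        elif p.gfp_limitation_mode == "continue":
            gfp_factor = 1.0
        else:  # burst: amplified as glycerol runs out
            k = p.gfp_derepression_k
            gfp_factor = 1.0 + (p.gfp_burst_amp - 1.0) * k / (k + s)
    else:
        dx = 0.0
        gfp_factor = math.exp(-p.gfp_post_decay * (t - (t_dep if t_dep is not None else t)))

    derep = p.gfp_derepression_k / (p.gfp_derepression_k + s)
    g += p.gfp_rate * x * derep * gfp_factor * h

    if s > eps:
        cur_ph = p.ph0 - p.ph_drop_per_gX * (x - p.x0)
    else:
        cur_ph += p.ph_recovery_rate * (p.ph0 - cur_ph) * h
    return x, s, m, g, cur_ph, hit_dep


# ---------------------------------------------------------------------------
# Spectra
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FluorophoreComponent:
    """One Gaussian fluorophore peak whose amplitude follows the culture state."""

    name: str
    ex_center: float  # nm
    em_center: float  # nm
    ex_sigma: float  # nm
    em_sigma: float  # nm
    amplitude_source: str  # gfp | biomass | active_biomass | constant
    gain: float  # intensity per source unit

    def __post_init__(self) -> None:
        if self.ex_sigma <= 0 or self.em_sigma <= 0:
            raise ValueError("sigmas must be positive")
        if self.amplitude_source != "constant" and self.em_center < self.ex_center:
            raise ValueError("fluorophore emission centre must be >= excitation centre")
        if self.amplitude_source not in ("gfp", "biomass", "active_biomass", "constant"):
            raise ValueError(f"unknown amplitude source {self.amplitude_source!r}")


def default_fluorophores() -> list[FluorophoreComponent]:
    """Conventional literature peak centres placing signal under the readout pixels."""
    return [
        FluorophoreComponent("GFP", 420.0, 530.0, 40.0, 30.0, "gfp", 3.0),
        FluorophoreComponent("NADH", 340.0, 450.0, 30.0, 35.0, "active_biomass", 150.0),
        FluorophoreComponent("flavins", 450.0, 530.0, 30.0, 30.0, "biomass", 100.0),
    ]


@dataclass(frozen=True)
class ScatterModel:
    """Biomass-driven elastic scatter ridge along the em = ex diagonal."""

    amplitude_sat: float = 4000.0  # intensity at saturating biomass
    k_x: float = 2.0  # g/L; half-saturation in biomass
    sigma_nm: float = 5.0  # ridge width


def _source_value(source: str, state: dict[str, float], ks_glycerol: float) -> float:
    if source == "gfp":
        return state["G"]
    if source == "biomass":
        return state["X"]
    if source == "active_biomass":
        return state["X"] * state["S"] / (ks_glycerol + state["S"])
    return 1.0  # constant


def synthesize_eem(
    state: dict[str, float],
    components: list[FluorophoreComponent],
    grid: EEMGrid,
    rng: np.random.Generator | None,
    scatter: ScatterModel | None = None,
    baseline: float = 30.0,
    noise_floor: float = 2.0,
    noise_rel: float = 0.01,
    ks_glycerol: float = 0.1,
    well_id: str = "",
    time: float = 0.0,
) -> EEMeasurement:
    """One synthetic EEM for a culture state (dict with keys X, S, G, ...).

    intensity(ex, em) = sum_k gain_k * source_k * G(ex; exc_k, sx_k) * G(em; emc_k, sm_k)
                        + A_sat * X/(Kx + X) * G(em - ex; 0, s_sc) + baseline + noise,
    with unit-height Gaussians G and noise ~ N(0, floor + rel * signal),
    clipped at zero (a CCD reports non-negative counts).
    """
    ex = grid.excitation[:, None]
    em = grid.emission[None, :]
    clean = np.full(grid.shape, float(baseline))
    for c in components:
        amp = c.gain * _source_value(c.amplitude_source, state, ks_glycerol)
        if amp == 0.0:
            continue
        gx = np.exp(-((grid.excitation - c.ex_center) ** 2) / (2 * c.ex_sigma**2))
        gm = np.exp(-((grid.emission - c.em_center) ** 2) / (2 * c.em_sigma**2))
        clean += amp * np.outer(gx, gm)
    if scatter is not None:
        x = state["X"]
        amp = scatter.amplitude_sat * x / (scatter.k_x + x)
        if amp > 0:
            clean += amp * np.exp(-((em - ex) ** 2) / (2 * scatter.sigma_nm**2))
    if rng is not None and (noise_floor > 0 or noise_rel > 0):
        sd = noise_floor + noise_rel * clean
        clean = clean + rng.normal(0.0, 1.0, size=clean.shape) * sd
    np.clip(clean, 0.0, None, out=clean)
    return EEMeasurement(well_id=well_id, time=time, intensities=clean, grid=grid)


# ---------------------------------------------------------------------------
# Plate presets and experiment generation
# ---------------------------------------------------------------------------


def media_design(fraction: float, full_conc_mg_L: float) -> float:
    """Supplementation concentration for a dilution fraction, at printed precision.

    Rounds half-up to 2 decimals below 10 mg/L and to 1 decimal otherwise,
    matching how such media recipes are conventionally printed.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be in [0, 1]")
    if full_conc_mg_L <= 0:
        raise ValueError("full concentration must be positive")
    value = fraction * full_conc_mg_L
    quantum = Decimal("0.01") if value < 10.0 else Decimal("0.1")
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def cdw_from_od600(od600: float, slope: float, intercept: float = 0.0) -> float:
    """CDW (g/L) from optical density via the experiment's linear correlation."""
    if od600 < 0:
        raise ValueError("od600 must be non-negative")
    cdw = slope * od600 + intercept
    if cdw < 0:
        raise ValueError(f"correlation yields negative CDW ({cdw})")
    return cdw


@dataclass(frozen=True)
class _ConditionSpec:
    label: str
    fraction: float
    x0: float
    role: str  # calibration | prediction


@dataclass(frozen=True)
class _Preset:
    substrate: str
    full_conc: float  # mg/L
    conditions: tuple[_ConditionSpec, ...]
    duration: float  # h
    t_max_model: float | None
    offline_interval: float  # h
    sparse_min_gap: float  # h
    gfp_mode: str
    yield_xm: float  # gX per mg of the limited substrate
    limited_rate_coeff: float  # 1/h; phase-2 rate per g/L biomass at transition

    @property
    def calibration_ids(self) -> list[str]:
        return [c.label for c in self.conditions if c.role == "calibration"]

    @property
    def full_supplementation_ids(self) -> list[str]:
        """Fully supplemented conditions outside calibration (the '-100%' exclusion)."""
        cal = set(self.calibration_ids)
        return [
            c.label
            for c in self.conditions
            if c.fraction == 1.0 and c.label not in cal
        ]


PRESETS: dict[str, _Preset] = {
    "Mg": _Preset(
        substrate="Mg",
        full_conc=295.8,
        conditions=(
            _ConditionSpec("Mg100-x0.03", 1.0, 0.03, "prediction"),
            _ConditionSpec("Mg100-x0.06", 1.0, 0.06, "calibration"),
            _ConditionSpec("Mg100-x0.11", 1.0, 0.11, "prediction"),
            _ConditionSpec("Mg1.8", 0.018, 0.03, "prediction"),
            _ConditionSpec("Mg1.4", 0.014, 0.03, "prediction"),
            _ConditionSpec("Mg0.8", 0.008, 0.03, "prediction"),
            _ConditionSpec("Mg0.4", 0.004, 0.03, "calibration"),
            _ConditionSpec("Mg0", 0.0, 0.03, "prediction"),
        ),
        duration=30.0,
        t_max_model=None,
        offline_interval=1.5,
        sparse_min_gap=6.0,
        gfp_mode="stall",
        yield_xm=0.45,
        limited_rate_coeff=0.06,
    ),
    "K": _Preset(
        substrate="K",
        full_conc=2017.3,
        conditions=(
            _ConditionSpec("K100", 1.0, 0.03, "prediction"),
            _ConditionSpec("K5", 0.05, 0.03, "calibration"),
            _ConditionSpec("K4", 0.04, 0.03, "prediction"),
            _ConditionSpec("K3", 0.03, 0.03, "prediction"),
            _ConditionSpec("K2.5", 0.025, 0.03, "prediction"),
            _ConditionSpec("K1.75", 0.0175, 0.03, "prediction"),
            _ConditionSpec("K1.25", 0.0125, 0.03, "prediction"),
            _ConditionSpec("K1", 0.01, 0.03, "calibration"),
        ),
        duration=48.0,
        t_max_model=43.0,
        offline_interval=1.5,
        sparse_min_gap=5.0,
        gfp_mode="stall",
        yield_xm=0.04,
        limited_rate_coeff=0.06,
    ),
    "PO4": _Preset(
        substrate="PO4",
        full_conc=697.9,
        conditions=(
            _ConditionSpec("PO4-100", 1.0, 0.03, "prediction"),
            _ConditionSpec("PO4-35", 0.35, 0.03, "calibration"),
            _ConditionSpec("PO4-20", 0.20, 0.03, "prediction"),
            _ConditionSpec("PO4-15", 0.15, 0.03, "prediction"),
            _ConditionSpec("PO4-12.5", 0.125, 0.03, "prediction"),
            _ConditionSpec("PO4-10", 0.10, 0.03, "prediction"),
            _ConditionSpec("PO4-7.5", 0.075, 0.03, "calibration"),
            _ConditionSpec("PO4-0", 0.0, 0.03, "prediction"),
        ),
        duration=40.0,
        t_max_model=34.5,
        offline_interval=1.5,
        sparse_min_gap=5.0,
        gfp_mode="burst",
        yield_xm=0.03,
        limited_rate_coeff=0.12,
    ),
}


@dataclass
class SimConfig:
    """Configuration of one synthetic plate experiment.

    The defaults are the study conditions: spectra every 0.5 h, duplicate
    wells per condition, dense offline sampling every 1.5 h, noise levels
    matching stated offline measurement precisions (glycerol CV 0.2 %, CDW CV
    3 %, pH sd 0.02) and a mild spectral noise floor.
    """

    preset: str = "Mg"
    seed: int = 0
    replicates: int = 2
    n_blank_wells: int = 2
    cadence: float = 0.5  # h between spectra
    duration: float | None = None  # h; preset default if None
    offline_interval: float | None = None  # h; preset default if None
    dt: float = 0.01  # h; integration step
    emission_preset: str = "caption"
    noise_floor: float = 2.0  # a.u.
    noise_rel: float = 0.01
    offline_glycerol_cv: float = 0.002
    offline_cdw_cv: float = 0.03
    offline_ph_sigma: float = 0.02
    od600_slope: float = 0.28  # g CDW per OD unit
    baseline: float = 30.0
    include_po2: bool = True
    kinetics_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.preset not in PRESETS:
            raise ValueError(f"unknown preset {self.preset!r}; choose from {list(PRESETS)}")
        if self.seed is None:
            raise ValueError("a seed is mandatory for stochastic output")
        if self.replicates < 1:
            raise ValueError("at least one replicate well per condition")


def _condition_params(preset: _Preset, spec: _ConditionSpec, overrides: dict) -> KineticParams:
    m0 = media_design(spec.fraction, preset.full_conc)
    base = KineticParams(
        m0=m0,
        x0=spec.x0,
        yield_xm=preset.yield_xm,
        gfp_limitation_mode=preset.gfp_mode,
    )
    # phase-2 linear rate scales with the biomass present at the transition,
    # so a culture with no secondary substrate at all barely grows
    x_transition = min(spec.x0 + preset.yield_xm * m0, base.yield_xs * base.s0 + spec.x0)
    base = replace(base, limited_growth_rate=preset.limited_rate_coeff * x_transition)
    if overrides:
        base = replace(base, **overrides)
    return base


def _well_names(n: int) -> list[str]:
    rows = "ABCDEF"
    return [f"{rows[i // 8]}{i % 8 + 1}" for i in range(n)]


def generate_experiment(cfg: SimConfig) -> PlateExperiment:
    """Generate a complete synthetic plate experiment for one preset.

    Per condition one deterministic trajectory is integrated; each replicate
    well gets independent spectral noise.  Offline samples follow the dense
    schedule with measurement noise; blanks (non-inoculated medium) and pO2
    traces consistent with the simulated OTR are included.  Fully seeded:
    the same config yields byte-identical output.
    """
    preset = PRESETS[cfg.preset]
    duration = cfg.duration if cfg.duration is not None else preset.duration
    offline_dt = (
        cfg.offline_interval if cfg.offline_interval is not None else preset.offline_interval
    )
    rng = np.random.default_rng(cfg.seed)
    grid = default_grid(cfg.emission_preset)
    components = default_fluorophores()
    scatter = ScatterModel()

    n_wells = len(preset.conditions) * cfg.replicates + cfg.n_blank_wells
    names = _well_names(n_wells)
    name_iter = iter(names)

    spectra_times = np.arange(0.0, duration + 1e-9, cfg.cadence)
    offline_times = np.arange(0.0, duration + 1e-9, offline_dt)

    conditions: list[CultureCondition] = []
    series_list: list[SpectrumSeries] = []
    offline_samples: list[OfflineSample] = []
    po2_traces: list[PO2Trace] = []

    for spec in preset.conditions:
        params = _condition_params(preset, spec, cfg.kinetics_overrides)
        traj = simulate_batch(params, duration, cfg.dt)
        wells = [next(name_iter) for _ in range(cfg.replicates)]
        conditions.append(
            CultureCondition(
                condition_id=spec.label,
                substrate_fraction=spec.fraction,
                substrate_conc=params.m0,
                cdw_t0=spec.x0,
                replicate_wells=wells,
                role=spec.role,
            )
        )
        state_at = traj.at(spectra_times)
        for well in wells:
            measurements = [
                synthesize_eem(
                    {k: state_at[k][i] for k in ("X", "S", "G")},
                    components,
                    grid,
                    rng,
                    scatter=scatter,
                    baseline=cfg.baseline,
                    noise_floor=cfg.noise_floor,
                    noise_rel=cfg.noise_rel,
                    ks_glycerol=params.ks_glycerol,
                    well_id=well,
                    time=float(t),
                )
                for i, t in enumerate(spectra_times)
            ]
            series_list.append(
                SpectrumSeries(
                    well_id=well,
                    measurements=measurements,
                    condition_id=spec.label,
                    cadence=cfg.cadence,
                )
            )
            if cfg.include_po2:
                po2_traces.append(
                    _po2_trace_for_well(well, traj, duration, rng, cfg.noise_rel)
                )
        off = traj.at(offline_times)
        for i, t in enumerate(offline_times):
            gly = off["S"][i] * (1.0 + rng.normal(0.0, cfg.offline_glycerol_cv))
            cdw = off["X"][i] * (1.0 + rng.normal(0.0, cfg.offline_cdw_cv))
            phv = off["ph"][i] + rng.normal(0.0, cfg.offline_ph_sigma)
            cdw = max(cdw, 0.0)
            offline_samples.append(
                OfflineSample(
                    condition_id=spec.label,
                    time=float(t),
                    glycerol=max(gly, 0.0),
                    cdw=cdw,
                    ph=phv,
                    od600=cdw / cfg.od600_slope,
                )
            )

    # blank wells: non-inoculated medium, baseline-only spectra
    blank_wells = [next(name_iter) for _ in range(cfg.n_blank_wells)]
    if blank_wells:
        conditions.append(
            CultureCondition(
                condition_id="blank",
                substrate_fraction=1.0,
                substrate_conc=preset.full_conc,
                cdw_t0=0.0,
                replicate_wells=blank_wells,
                role="blank",
            )
        )
        blank_state = {"X": 0.0, "S": 12.0, "G": 0.0}
        for well in blank_wells:
            measurements = [
                synthesize_eem(
                    blank_state,
                    components,
                    grid,
                    rng,
                    scatter=scatter,
                    baseline=cfg.baseline,
                    noise_floor=cfg.noise_floor,
                    noise_rel=cfg.noise_rel,
                    well_id=well,
                    time=float(t),
                )
                for t in spectra_times
            ]
            series_list.append(
                SpectrumSeries(
                    well_id=well,
                    measurements=measurements,
                    condition_id="blank",
                    cadence=cfg.cadence,
                )
            )

    t_max = preset.t_max_model
    return PlateExperiment(
        experiment_id=f"synthetic-{cfg.preset}-seed{cfg.seed}",
        limited_substrate=preset.substrate,
        conditions=conditions,
        spectra=series_list,
        offline=OfflineTable(samples=offline_samples, schedule_label="full"),
        po2_traces=po2_traces if cfg.include_po2 else None,
        t_max_model=t_max,
    )


def _po2_trace_for_well(
    well: str,
    traj: BioprocessTrajectory,
    duration: float,
    rng: np.random.Generator,
    noise_rel: float,
    cycle_h: float = 0.5,
    t_measure: float = 0.125,
    n_measure_points: int = 6,
    vg: float = 2.6e-3,
    vl: float = 0.8e-3,
    temperature: float = 303.15,
) -> PO2Trace:
    """Stop-flow headspace pO2 trace consistent with the simulated OTR.

    Each cycle holds one measuring phase (pO2 declining at the rate implied
    by the OTR through the inverted headspace balance) followed by a flush
    point resetting to air saturation.
    """
    times: list[float] = []
    po2: list[float] = []
    phase: list[str] = []
    n_cycles = int(np.floor(duration / cycle_h))
    sub = np.linspace(0.0, t_measure, n_measure_points)
    for c in range(n_cycles):
        t0 = c * cycle_h
        otr_mid = float(np.interp(t0 + t_measure / 2, traj.times, traj.otr))
        slope_bar = otr_mid / 1000.0 * vl * R_BAR_L * temperature / vg
        slope_pct = slope_bar / O2_PARTIAL_PRESSURE_AIR_BAR * 100.0
        for ts in sub:
            val = 100.0 - slope_pct * ts
            if noise_rel > 0:
                val += rng.normal(0.0, 0.05)
            times.append(t0 + ts)
            po2.append(max(val, 0.0))
            phase.append("measure")
        times.append(t0 + cycle_h * 0.75)
        po2.append(100.0)
        phase.append("flush")
    return PO2Trace(
        well_id=well,
        times=np.array(times),
        po2=np.array(po2),
        phase=np.array(phase),
        unit="percent_air",
    )
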