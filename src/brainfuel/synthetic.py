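"""Synthetic inputs for the dual-tracer PET pipeline.

Every downstream stage (Patlak, partial-volume correction, regional
statistics, associations) is exercised on data produced here:

* analytic plasma input functions (tri-exponential with a linear upslope,
  the standard Feng-type family used to model bolus-injection curves);
* tissue time–activity curves from an irreversible two-tissue-compartment
  system, whose true Patlak slope Ki = K1*k3/(k2+k3) is known in closed
  form;
* deterministic digital head phantoms (GM/WM/CSF maps plus a 43-region
  label volume);
* a three-visit longitudinal cohort (25/25/16 participants at baseline,
  year 2 and year 4) whose per-region rate constants follow a linear
  mixed model in age, with default region means and annual slopes taken
  from the bundled regional reference tables.

All randomness flows through explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.spatial import cKDTree

from .kinetics import PlasmaInputFunction, TimeActivityCurve, GLUCOSE_TRACER, ACAC_TRACER
from .schedules import FrameSchedule

__all__ = [
    "InputFunctionParameters",
    "make_input_function",
    "default_input_parameters",
    "CompartmentParameters",
    "simulate_tissue_tac",
    "DigitalPhantom",
    "make_phantom",
    "CohortSpec",
    "simulate_cohort",
    "COGNITIVE_TESTS",
]


# ---------------------------------------------------------------------------
# plasma input function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InputFunctionParameters:
    """Parameters of the analytic bolus input curve

        Cp(t) = (A1*t - A2 - A3) e^(-l1 t) + A2 e^(-l2 t) + A3 e^(-l3 t)

    The form is zero at t=0, rises linearly, peaks once and decays as a
    mixture of exponentials.  ``A1`` is not free: it is solved from the
    stationarity condition Cp'(peak_time) = 0 and the whole curve is then
    scaled so that Cp(peak_time) = peak_amplitude.

    Parameters
    ----------
    peak_time : float
        Location of the curve maximum (min).
    peak_amplitude : float
        Plasma activity at the peak (kBq/mL).
    decay_rates : (l1, l2, l3)
        Positive exponential rates (min^-1); l1 governs the fast bolus
        passage, l2 and l3 the slower clearance phases.
    mixing_coefficients : (A2, A3)
        Non-negative amplitudes (kBq/mL) of the two slow phases, before
        the global rescaling.
    """

    peak_time: float = 0.6
    peak_amplitude: float = 35.0
    decay_rates: tuple[float, float, float] = (4.0, 0.12, 0.01)
    mixing_coefficients: tuple[float, float] = (21.0, 20.0)

    def __post_init__(self) -> None:
        if self.peak_time <= 0 or self.peak_amplitude <= 0:
            raise ValueError("peak time and amplitude must be positive")
        if any(l <= 0 for l in self.decay_rates):
            raise ValueError("decay rates must be positive")
        if any(a < 0 for a in self.mixing_coefficients):
            raise ValueError("mixing coefficients must be non-negative")

    def amplitudes(self) -> tuple[float, float, float]:
        """(A1, A2, A3) after solving the peak conditions."""
        l1, l2, l3 = self.decay_rates
        a2, a3 = self.mixing_coefficients
        tp = self.peak_time
        if a2 == 0.0 and a3 == 0.0:
            # pure t*exp(-l1 t): the peak sits at 1/l1 by construction
            a1 = 1.0
        else:
            coef = (1.0 - l1 * tp) * np.exp(-l1 * tp)
            rhs = (
                l2 * a2 * np.exp(-l2 * tp)
                + l3 * a3 * np.exp(-l3 * tp)
                - l1 * (a2 + a3) * np.exp(-l1 * tp)
            )
            if abs(coef) < 1e-12:
                raise ValueError("peak_time = 1/l1 is degenerate for this form")
            a1 = rhs / coef
            if a1 <= 0:
                raise ValueError("parameters admit no rising bolus peak at peak_time")
        scale = self.peak_amplitude / self._unscaled(np.array([tp if (a2 or a3) else 1.0 / l1]), a1, a2, a3)[0]
        return a1 * scale, a2 * scale, a3 * scale

    def _unscaled(self, t: np.ndarray, a1: float, a2: float, a3: float) -> np.ndarray:
        l1, l2, l3 = self.decay_rates
        return (a1 * t - a2 - a3) * np.exp(-l1 * t) + a2 * np.exp(-l2 * t) + a3 * np.exp(-l3 * t)

    def __call__(self, t) -> np.ndarray:
        a1, a2, a3 = self.amplitudes()
        return self._unscaled(np.asarray(t, dtype=float), a1, a2, a3)


_DEFAULTS = {
    # 18F-FDG: slow clearance, 60-min support
    "glucose": InputFunctionParameters(
        peak_time=0.6, peak_amplitude=35.0, decay_rates=(4.0, 0.12, 0.01),
        mixing_coefficients=(21.0, 20.0),
    ),
    # 11C-acetoacetate: faster bolus and clearance, 10-min scan
    "acac": InputFunctionParameters(
        peak_time=0.5, peak_amplitude=40.0, decay_rates=(5.0, 0.6, 0.05),
        mixing_coefficients=(15.0, 10.0),
    ),
}


def default_input_parameters(tracer: str = "glucose") -> InputFunctionParameters:
    """Default bolus parameters per tracer ('glucose' or 'acac')."""
    try:
        return _DEFAULTS[tracer]
    except KeyError:
        raise ValueError(f"unknown tracer {tracer!r}") from None


def make_input_function(
    params: InputFunctionParameters,
    duration: float = 70.0,
    dt: float = 0.01,
    cp_met: float | None = None,
) -> PlasmaInputFunction:
    """Densely sampled plasma input function from analytic parameters.

    The curve is validated numerically on its sample grid: non-negative
    everywhere, zero at the origin, and a single maximum located at
    ``peak_time`` to within one sample step.
    """
    t = np.arange(0.0, duration + 0.5 * dt, dt)
    cp = params(t)
    if np.any(cp < -1e-9 * params.peak_amplitude):
        raise ValueError("parameters yield a negative plasma curve")
    cp = np.clip(cp, 0.0, None)
    cp[0] = 0.0  # the form is exactly zero at the origin; clear float residue
    imax = int(np.argmax(cp))
    a2, a3 = params.mixing_coefficients
    expected_peak = params.peak_time if (a2 or a3) else 1.0 / params.decay_rates[0]
    if abs(t[imax] - expected_peak) > dt + 1e-9:
        raise ValueError("curve maximum not at the requested peak time")
    return PlasmaInputFunction(t, cp, cp_met=cp_met)


# ---------------------------------------------------------------------------
# irreversible two-tissue-compartment tissue curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompartmentParameters:
    """Irreversible two-tissue-compartment kinetics.

    dC1/dt = K1*Cp - (k2+k3)*C1 ; dC2/dt = k3*C1 ; no return from C2.
    The asymptotic Patlak slope is Ki = K1*k3/(k2+k3).

    K1 is in mL plasma/mL tissue/min, k2 and k3 in min^-1, vb is the
    fractional blood volume in [0, 1].
    """

    K1: float
    k2: float
    k3: float
    vb: float = 0.0

    def __post_init__(self) -> None:
        if min(self.K1, self.k2, self.k3) < 0:
            raise ValueError("rate constants must be non-negative")
        if not 0.0 <= self.vb <= 1.0:
            raise ValueError("blood volume fraction must be in [0, 1]")

    @property
    def Ki(self) -> float:
        """Closed-form net influx constant K1*k3/(k2+k3) (min^-1)."""
        if self.k2 + self.k3 == 0:
            raise ValueError("Ki undefined when k2 + k3 = 0")
        return self.K1 * self.k3 / (self.k2 + self.k3)


def _solve_2tc(cp_vals: np.ndarray, t: np.ndarray, params: CompartmentParameters) -> np.ndarray:
    """Tissue concentration C1+C2 on grid ``t`` for piecewise-linear Cp.

    C1 is propagated with the integrating factor in chunks short enough
    that exp(alpha * chunk) stays well-conditioned; C2 is the running
    integral of k3*C1.
    """
    alpha = params.k2 + params.k3
    n = len(t)
    c1 = np.zeros(n)
    if params.K1 > 0:
        if alpha == 0:
            c1 = params.K1 * cumulative_trapezoid(cp_vals, t, initial=0.0)
        else:
            chunk_span = max(min(5.0, 40.0 / alpha), t[1] - t[0])
            start = 0
            while start < n - 1:
                stop = int(np.searchsorted(t, t[start] + chunk_span, side="right"))
                stop = min(max(stop, start + 2), n)
                ts = t[start:stop] - t[start]
                grow = np.exp(alpha * ts)
                integ = cumulative_trapezoid(grow * cp_vals[start:stop], ts, initial=0.0)
                c1[start:stop] = (c1[start] + params.K1 * integ) / grow
                start = stop - 1
    c2 = params.k3 * cumulative_trapezoid(c1, t, initial=0.0)
    return c1 + c2


def simulate_tissue_tac(
    cp: PlasmaInputFunction,
    params: CompartmentParameters,
    schedule: FrameSchedule,
    noise_sd_scale: float = 0.0,
    seed: int = 0,
    tracer_label: str = GLUCOSE_TRACER,
    dt: float = 0.0025,
) -> TimeActivityCurve:
    """Frame-averaged tissue curve of the irreversible 2TC system.

    Each frame value is the time-average over the frame of
    vb*Cp + (1-vb)*(C1+C2).  Gaussian noise with standard deviation
    ``noise_sd_scale * |value| / sqrt(frame duration)`` is added per
    frame — the usual count-statistics heuristic in which long frames
    are less noisy.
    """
    if noise_sd_scale < 0:
        raise ValueError("noise_sd_scale must be non-negative")
    if schedule.total_duration > cp.end_time + 1e-9:
        raise ValueError("input function does not cover the scan duration")

    # fine grid with frame boundaries as exact knots
    segs = []
    slices = []
    pos = 0
    for (s, e) in schedule.frames:
        nstep = max(int(np.ceil((e - s) / dt)), 2)
        seg = np.linspace(s, e, nstep + 1)
        segs.append(seg if not segs else seg[1:])
        slices.append((pos if pos == 0 else pos - 1, pos + len(segs[-1])))
        pos += len(segs[-1])
    t = np.concatenate(segs)

    cp_vals = cp(t)
    tissue = _solve_2tc(cp_vals, t, params)
    total = params.vb * cp_vals + (1.0 - params.vb) * tissue

    values = np.empty(schedule.n_frames)
    for i, ((s, e), (a, b)) in enumerate(zip(schedule.frames, slices)):
        values[i] = np.trapezoid(total[a:b], t[a:b]) / (e - s)

    if noise_sd_scale > 0:
        rng = np.random.default_rng(seed)
        sd = noise_sd_scale * np.abs(values) / np.sqrt(schedule.durations)
        values = values + rng.normal(0.0, 1.0, size=values.shape) * sd
    return TimeActivityCurve(schedule, values, tracer_label=tracer_label)


# ---------------------------------------------------------------------------
# digital head phantom
# ---------------------------------------------------------------------------

@dataclass
class DigitalPhantom:
    """Deterministic head phantom: tissue probability maps, a region
    label volume, the voxel size (mm) and the intracranial volume (mL)."""

    gm_map: np.ndarray
    wm_map: np.ndarray
    csf_map: np.ndarray
    label_volume: np.ndarray
    voxel_size: float
    icv: float

    def __post_init__(self) -> None:
        total = self.gm_map + self.wm_map + self.csf_map
        if np.any(total > 1.0 + 1e-9):
            raise ValueError("tissue probabilities must sum to <= 1 everywhere")
        if self.icv <= 0:
            raise ValueError("intracranial volume must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.gm_map.shape

    def region_ids(self) -> np.ndarray:
        ids = np.unique(self.label_volume)
        return ids[ids != 0]


def make_phantom(shape: tuple[int, int, int], atlas, seed: int = 0, voxel_size: float = 2.0) -> DigitalPhantom:
    """Ellipsoidal head phantom with a GM shell parcellated into the
    atlas regions by seeded nearest-neighbour (Voronoi) assignment.

    The white-matter core fills the inner ellipsoid, grey matter the
    shell around it, and a thin CSF layer surrounds the brain.  Every
    atlas region must receive at least 8 grey-matter voxels; otherwise
    the grid is too small and a ValueError is raised.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3-D")
    n_regions = len(atlas.regions)
    idx = np.indices(shape, dtype=float)
    center = (np.array(shape, dtype=float) - 1.0) / 2.0
    semi = 0.42 * np.array(shape, dtype=float)
    r2 = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    brain = r2 <= 1.0
    wm = r2 <= 0.55**2
    gm = brain & ~wm
    csf = (r2 > 1.0) & (r2 <= 1.18**2)

    gm_count = int(gm.sum())
    if gm_count < 8 * n_regions:
        raise ValueError(
            f"grid {shape} provides {gm_count} GM voxels; "
            f"{8 * n_regions} needed for {n_regions} regions"
        )

    coords = np.argwhere(gm)
    rng = np.random.default_rng(seed)
    labels = np.zeros(shape, dtype=np.int32)
    region_ids = np.array([r.id for r in atlas.regions], dtype=np.int32)
    for attempt in range(64):
        seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
        assignment = cKDTree(seeds).query(coords, k=1)[1]
        counts = np.bincount(assignment, minlength=n_regions)
        if counts.min() >= 8:
            labels[tuple(coords.T)] = region_ids[assignment]
            break
    else:
        raise ValueError("could not place all regions with >= 8 voxels; enlarge the grid")

    icv = float(brain.sum() + csf.sum()) * voxel_size**3 / 1000.0
    return DigitalPhantom(
        gm_map=gm.astype(float),
        wm_map=wm.astype(float),
        csf_map=csf.astype(float),
        label_volume=labels,
        voxel_size=float(voxel_size),
        icv=icv,
    )


# ---------------------------------------------------------------------------
# longitudinal cohort
# ---------------------------------------------------------------------------

COGNITIVE_TESTS: dict[str, str] = {
    # test column stem -> cognitive domain
    "stroop_inhibition_switching": "executive",
    "verbal_fluency_switching": "executive",
    "trail_number_letter_sequencing": "executive",
    "letter_number_sequencing": "working_memory",
    "spatial_span_backward": "working_memory",
    "digit_span_backward": "working_memory",
    "digit_span_sequencing": "working_memory",
    "rcft_immediate_recall": "episodic_memory",
    "rcft_delayed_recall": "episodic_memory",
    "verbal_paired_associates_1": "episodic_memory",
    "verbal_paired_associates_2": "episodic_memory",
    "logical_memory_1": "episodic_memory",
    "logical_memory_2": "episodic_memory",
    "boston_naming": "language",
    "symbol_search": "attention_speed",
    "coding": "attention_speed",
    "trail_visual_scanning": "attention_speed",
    "trail_number_sequencing": "attention_speed",
    "trail_letter_sequencing": "attention_speed",
}


@dataclass
class CohortSpec:
    """Design of the simulated three-visit aging cohort.

    Per-region rate constants follow the linear mixed model

        K[s, r, v] = mean_r + slope_r * (age[s, v] - age_mean)
                     + intercept_s + eps,   intercept_s ~ N(0, between_subject_sd),
                                            eps ~ N(0, residual_sd)

    with a shared per-subject random intercept across regions.  A single
    latent factor per subject couples the random intercept negatively to
    insulin (hence to HOMA-IR) and positively to cognitive scaled
    scores, emulating the observed insulin-resistance and cognition
    associations without fixing their magnitudes.

    Defaults reproduce the study design: 25 participants at baseline and
    year 2, 16 at year 4; baseline age 70.9 ± 5 y truncated to [60, 85];
    plasma glucose 5.1 mM; region means and annual slopes from the
    bundled glucose reference table.
    """

    n_baseline: int = 25
    visit_years: tuple[float, ...] = (0.0, 2.0, 4.0)
    n_per_visit: tuple[int, ...] = (25, 25, 16)
    region_baseline_means: dict[str, float] = field(default_factory=dict)
    region_slopes: dict[str, float] = field(default_factory=dict)
    between_subject_sd: float = 0.006
    residual_sd: float = 0.004
    age_mean: float = 70.9
    age_sd: float = 5.0
    age_range: tuple[float, float] = (60.0, 85.0)
    glucose_mean_mM: float = 5.1
    glucose_sd_mM: float = 0.5
    insulin_mean_uUI: float = 5.1
    insulin_sd_uUI: float = 2.0
    insulin_k_coupling: float = -0.5
    cognition_k_coupling: float = 0.4
    bhb_mean_uM: float = 270.0
    acac_mean_uM: float = 140.0
    tracer: str = "glucose"
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.n_per_visit) != len(self.visit_years):
            raise ValueError("n_per_visit must match visit_years")
        if any(b < a for a, b in zip(self.n_per_visit[1:], self.n_per_visit[:-1])):
            raise ValueError("n_per_visit must be non-increasing")
        if self.n_per_visit[0] > self.n_baseline:
            raise ValueError("visit counts cannot exceed n_baseline")
        if not self.region_baseline_means:
            from .regional import load_reference_table

            table = load_reference_table(self.tracer)
            self.region_baseline_means = dict(zip(table["region"], table["T0"]))
            self.region_slopes = dict(zip(table["region"], table["fixed_effect"]))
        if set(self.region_slopes) != set(self.region_baseline_means):
            raise ValueError("region_slopes must cover the same regions as the means")

    def with_seed(self, seed: int) -> "CohortSpec":
        return replace(self, seed=seed)


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate the longitudinal cohort as one row per (subject, visit).

    Columns: subject_id, visit (T0/T2/...), age_yr, glucose_mM,
    insulin_uUI_per_mL, bhb_uM, acac_uM, scaled_<test> for each
    cognitive test, and K_<region> for each atlas region.  Deterministic
    for a fixed spec (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_baseline
    regions = list(spec.region_baseline_means)

    # baseline ages, truncated normal by resampling
    ages0 = np.empty(n)
    for i in range(n):
        a = rng.normal(spec.age_mean, spec.age_sd)
        while not (spec.age_range[0] <= a <= spec.age_range[1]):
            a = rng.normal(spec.age_mean, spec.age_sd)
        ages0[i] = a

    z = rng.normal(size=n)  # latent subject factor
    intercepts = spec.between_subject_sd * z
    c_ins = spec.insulin_k_coupling
    insulin_subject = spec.insulin_mean_uUI + spec.insulin_sd_uUI * (
        c_ins * z + np.sqrt(max(0.0, 1.0 - c_ins**2)) * rng.normal(size=n)
    )
    c_cog = spec.cognition_k_coupling
    cog_subject = c_cog * z + np.sqrt(max(0.0, 1.0 - c_cog**2)) * rng.normal(size=n)

    # nested retention: participants present at visit v+1 were present at v
    retained: list[np.ndarray] = []
    current = np.arange(n)
    for count in spec.n_per_visit:
        if len(current) > count:
            current = np.sort(rng.choice(current, size=count, replace=False))
        retained.append(current.copy())

    rows = []
    for v, (offset, keep) in enumerate(zip(spec.visit_years, retained)):
        visit = f"T{int(offset)}"
        for s in keep:
            age = ages0[s] + offset
            row = {
                "subject_id": f"S{s + 1:03d}",
                "visit": visit,
                "age_yr": age,
                "glucose_mM": max(3.5, rng.normal(spec.glucose_mean_mM, spec.glucose_sd_mM)),
                "insulin_uUI_per_mL": max(0.5, insulin_subject[s] + rng.normal(0.0, 0.8)),
                "bhb_uM": max(
                    40.0,
                    spec.bhb_mean_uM * (1.0 - 0.15 * np.tanh(insulin_subject[s] - spec.insulin_mean_uUI))
                    + rng.normal(0.0, 60.0),
                ),
            }
            row["acac_uM"] = max(20.0, row["bhb_uM"] * rng.normal(0.5, 0.08))
            for test in COGNITIVE_TESTS:
                raw = 10.0 + 3.0 * (cog_subject[s] + 0.5 * rng.normal())
                row[f"scaled_{test}"] = int(np.clip(np.rint(raw), 1, 19))
            for r in regions:
                mean_r = spec.region_baseline_means[r]
                slope_r = spec.region_slopes[r]
                row[f"K_{r}"] = (
                    mean_r
                    + slope_r * (age - spec.age_mean)
                    + intercepts[s]
                    + rng.normal(0.0, spec.residual_sd)
                )
            rows.append(row)
    return pd.DataFrame(rows)
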