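"""Synthetic 700-MHz-like CSF spectra and longitudinal cohorts.

Spectra are sums of Lorentzian lines (default FWHM 0.0021 ppm, about 1.5 Hz
at 700 MHz) for the discriminating CSF metabolites — lactate, citrate,
glucose and ethanol — plus a TSP reference singlet at 0 ppm, an optional
broad residual-water hump confined to 4.30-5.00 ppm, an optional methanol
contaminant singlet at 3.36 ppm, additive Gaussian noise and small
chemical-shift jitter.  Group structure is injected on the concentration
scale: each sample draws a per-metabolite scale factor from a truncated
normal whose mean/SD are the group's ratio-vs-control moments, so the whole
bucketing -> scaling -> PLS-DA -> quantification pipeline can be exercised
end-to-end with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import Patient, Visit
from .spectra import Spectrum1D

__all__ = [
    "PeakGroup",
    "GenerativeGroupModel",
    "SyntheticTruth",
    "TruthRecord",
    "CohortData",
    "DEFAULT_PEAK_LIBRARY",
    "DEFAULT_BASE_AMPLITUDES",
    "CONTROL_RATIO_SDS",
    "EFFECT_COLUMNS",
    "LORENTZ_FWHM",
    "DEFAULT_AXIS",
    "render_spectrum",
    "generate_case_control",
    "generate_cohort",
    "default_group_model",
]

#: Lorentzian full width at half maximum, ppm (~1.5 Hz at 700 MHz).
LORENTZ_FWHM = 0.0021

#: (low ppm, high ppm, number of points) of the synthetic acquisition grid.
DEFAULT_AXIS: tuple[float, float, int] = (-0.2, 10.0, 32768)


@dataclass(frozen=True)
class PeakGroup:
    """One metabolite's multiplet pattern: centres (ppm) and relative heights."""

    metabolite: str
    centers: tuple[float, ...]
    relative_heights: tuple[float, ...]
    linewidth: float = LORENTZ_FWHM

    def __post_init__(self) -> None:
        if len(self.centers) != len(self.relative_heights):
            raise ValueError(f"{self.metabolite}: centers/heights length mismatch")
        if any(h <= 0 for h in self.relative_heights):
            raise ValueError(f"{self.metabolite}: heights must be positive")
        if any(not 0.2 <= c <= 9.6 for c in self.centers):
            raise ValueError(f"{self.metabolite}: centres must lie in [0.2, 9.6]")


def _glucose_comb() -> tuple[tuple[float, ...], tuple[float, ...]]:
    # One line per 0.02-ppm tile of each glucose region; ring-proton envelope
    # approximated by mildly varying heights rather than exact J-couplings.
    regions = [
        (3.24, 3.28),
        (3.38, 3.44),
        (3.46, 3.52),
        (3.54, 3.56),
        (3.70, 3.80),
        (3.82, 3.86),
        (3.88, 3.92),
    ]
    centers: list[float] = []
    heights: list[float] = []
    pattern = (0.8, 1.0, 0.9, 1.1, 0.7, 1.0)
    k = 0
    for lo, hi in regions:
        n = round((hi - lo) / 0.02)
        for i in range(n):
            centers.append(lo + 0.01 + 0.02 * i)
            heights.append(pattern[k % len(pattern)])
            k += 1
    return tuple(centers), tuple(heights)


_GLC_CENTERS, _GLC_HEIGHTS = _glucose_comb()

DEFAULT_PEAK_LIBRARY: tuple[PeakGroup, ...] = (
    # methyl doublet at 1.33 plus the CH quartet at 4.11-4.13
    PeakGroup(
        "Lactic acid",
        (1.326, 1.334, 4.105, 4.113, 4.121, 4.129),
        (3.0, 3.0, 0.25, 0.75, 0.75, 0.25),
    ),
    # AB system of the two CH2 groups
    PeakGroup("Citric acid", (2.645, 2.655), (1.0, 1.0)),
    PeakGroup("Glucose", _GLC_CENTERS, _GLC_HEIGHTS),
    # CH3 triplet at 1.19 and CH2 quartet at 3.66-3.68
    PeakGroup(
        "Ethanol",
        (1.184, 1.190, 1.196, 3.663, 3.668, 3.673, 3.678),
        (1.0, 2.0, 1.0, 0.33, 1.0, 1.0, 0.33),
    ),
)

#: Typical CSF concentrations (mM) and the proton count of the modelled
#: resonances; a metabolite's total integral at ratio 1 is their product
#: (integral per proton is constant in 1H NMR), so the per-line base
#: amplitude is that product divided by the multiplet's summed heights.
CSF_CONCENTRATIONS_MM: dict[str, float] = {
    "Lactic acid": 1.6,
    "Citric acid": 0.3,
    "Glucose": 3.3,
    "Ethanol": 0.1,
}
MODELLED_PROTONS: dict[str, int] = {
    "Lactic acid": 4,  # CH3 (3H) + CH (1H)
    "Citric acid": 4,  # two CH2 groups
    "Glucose": 6,  # ring CH protons inside the bucketed regions
    "Ethanol": 5,  # CH3 (3H) + CH2 (2H)
}


def _base_amplitudes(library: Sequence["PeakGroup"]) -> dict[str, float]:
    heights = {pg.metabolite: sum(pg.relative_heights) for pg in library}
    return {
        m: CSF_CONCENTRATIONS_MM[m] * MODELLED_PROTONS[m] / heights[m]
        for m in CSF_CONCENTRATIONS_MM
    }

DEFAULT_BASE_AMPLITUDES: dict[str, float] = _base_amplitudes(DEFAULT_PEAK_LIBRARY)

#: Within-group coefficient of variation of the control ratios.
CONTROL_RATIO_SDS: dict[str, float] = {
    "Lactic acid": 0.14,
    "Citric acid": 0.17,
    "Glucose": 0.08,
    "Ethanol": 0.09,
}

#: Group effect sizes: metabolite -> (mean ratio vs control, SD).
EFFECT_COLUMNS: dict[str, dict[str, tuple[float, float]]] = {
    "control": {m: (1.0, sd) for m, sd in CONTROL_RATIO_SDS.items()},
    "als_ge06": {
        "Lactic acid": (1.22, 0.16),
        "Citric acid": (1.39, 0.23),
        "Glucose": (1.17, 0.18),
        "Ethanol": (1.31, 0.38),
    },
    "als_ge12": {
        "Lactic acid": (1.22, 0.16),
        "Citric acid": (1.39, 0.26),
        "Glucose": (1.19, 0.19),
        "Ethanol": (1.30, 0.36),
    },
    "als_ge18": {
        "Lactic acid": (1.21, 0.18),
        "Citric acid": (1.36, 0.29),
        "Glucose": (1.20, 0.21),
        "Ethanol": (1.18, 0.10),
    },
    "gt5yr": {
        "Lactic acid": (1.23, 0.19),
        "Citric acid": (1.31, 0.26),
        "Glucose": (1.18, 0.15),
        "Ethanol": (1.17, 0.14),
    },
    "null": {m: (1.0, sd) for m, sd in CONTROL_RATIO_SDS.items()},
}


@dataclass
class GenerativeGroupModel:
    """Everything the cohort generator needs to emulate the study.

    ``effect`` names the case group's ratio column; ``als_strata`` maps each
    ALS patient's maximum follow-up (months) to a patient count, fixed so
    the nested cohort sizes are reproduced deterministically.
    """

    effect: str = "als_ge12"
    ratio_columns: Mapping[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: EFFECT_COLUMNS
    )
    base_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_AMPLITUDES)
    )
    noise_sd: float = 0.002
    jitter_sd: float = 0.002
    n_controls: int = 14
    n_pls: int = 5
    als_strata: Mapping[int, int] = field(
        default_factory=lambda: {0: 20, 6: 6, 12: 3, 18: 5, 24: 6}
    )
    axis: tuple[float, float, int] = DEFAULT_AXIS

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.jitter_sd < 0:
            raise ValueError("noise and jitter SDs must be >= 0")
        for col in self.ratio_columns.values():
            for m, (mean, sd) in col.items():
                if mean <= 0 or sd < 0:
                    raise ValueError(f"{m}: ratio mean must be > 0 and SD >= 0")
        if self.n_controls < 2 or self.n_pls < 0 or not self.als_strata:
            raise ValueError("infeasible cohort sizes")


def default_group_model(effect: str = "als_ge12") -> GenerativeGroupModel:
    if effect not in EFFECT_COLUMNS:
        raise KeyError(f"unknown effect column {effect!r}; have {sorted(EFFECT_COLUMNS)}")
    return GenerativeGroupModel(effect=effect)


@dataclass(frozen=True)
class TruthRecord:
    sample_id: str
    group_label: str
    effect_column: str
    ratios: dict[str, float]
    global_shift_ppm: float


@dataclass
class SyntheticTruth:
    """Ground-truth scale factors and shifts, reproducible from the seed."""

    seed: int
    records: list[TruthRecord] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            row = {
                "sample_id": r.sample_id,
                "group_label": r.group_label,
                "effect_column": r.effect_column,
                "global_shift_ppm": r.global_shift_ppm,
            }
            row.update({f"ratio:{m}": v for m, v in r.ratios.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def ratios_for(self, sample_id: str) -> dict[str, float]:
        for r in self.records:
            if r.sample_id == sample_id:
                return r.ratios
        raise KeyError(sample_id)


# ---------------------------------------------------------------------------
# Spectrum rendering


def _lorentz(x: np.ndarray, center: float, fwhm: float) -> np.ndarray:
    hwhm = fwhm / 2.0
    return 1.0 / (1.0 + ((x - center) / hwhm) ** 2)


def render_spectrum(
    concentrations: Mapping[str, float],
    peak_library: Sequence[PeakGroup] = DEFAULT_PEAK_LIBRARY,
    axis: tuple[float, float, int] = DEFAULT_AXIS,
    noise_sd: float = 0.002,
    jitter_sd: float = 0.0,
    tsp_amplitude: float = 2.0,
    methanol_amplitude: float = 0.0,
    water_amplitude: float = 0.0,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "synthetic",
    group_label: str | None = None,
) -> Spectrum1D:
    """Render one synthetic spectrum (deterministic for a fixed seed).

    ``concentrations`` maps metabolite name to a non-negative peak-height
    scale.  Jitter is a whole-spectrum shift ~N(0, jitter_sd) plus an
    independent per-metabolite shift ~N(0, jitter_sd/2); the TSP reference
    singlet stays exactly at 0 ppm.  The residual-water hump is a Gaussian
    at 4.65 ppm truncated to the 4.30-5.00 ppm exclusion window.
    """
    for name, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
    lo, hi, n = axis
    if lo > 0.2 or hi < 9.6 or n < 16384:
        raise ValueError("axis must cover [0.2, 9.6] ppm with at least 16384 points")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x = np.linspace(lo, hi, n)
    y = np.zeros(n)

    global_shift = rng.normal(0.0, jitter_sd) if jitter_sd > 0 else 0.0
    for pg in peak_library:
        conc = concentrations.get(pg.metabolite, 0.0)
        local = rng.normal(0.0, jitter_sd / 2.0) if jitter_sd > 0 else 0.0
        if conc == 0.0:
            continue
        for center, height in zip(pg.centers, pg.relative_heights):
            y += conc * height * _lorentz(x, center + global_shift + local, pg.linewidth)
    if methanol_amplitude > 0:
        y += methanol_amplitude * _lorentz(x, 3.36 + global_shift, LORENTZ_FWHM)
    if tsp_amplitude > 0:
        y += tsp_amplitude * _lorentz(x, 0.0, LORENTZ_FWHM)
    if water_amplitude > 0:
        hump = water_amplitude * np.exp(-((x - 4.65) ** 2) / (2 * 0.12**2))
        hump[(x < 4.30) | (x > 5.00)] = 0.0
        y += hump
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, n)
    return Spectrum1D(sample_id, x, y, group_label)


def _draw_ratios(
    rng: np.random.Generator, column: Mapping[str, tuple[float, float]]
) -> dict[str, float]:
    """Truncated-normal (>0) per-metabolite ratio draws."""
    out = {}
    for m, (mean, sd) in column.items():
        v = rng.normal(mean, sd)
        while v <= 0:
            v = rng.normal(mean, sd)
        out[m] = float(v)
    return out


def _render_sample(
    rng: np.random.Generator,
    model: GenerativeGroupModel,
    ratios: Mapping[str, float],
    sample_id: str,
    group_label: str,
) -> Spectrum1D:
    conc = {m: model.base_amplitudes[m] * r for m, r in ratios.items()}
    return render_spectrum(
        conc,
        axis=model.axis,
        noise_sd=model.noise_sd,
        jitter_sd=model.jitter_sd,
        tsp_amplitude=2.0,
        methanol_amplitude=abs(rng.normal(0.4, 0.15)),
        water_amplitude=abs(rng.normal(5.0, 1.5)),
        seed=rng,
        sample_id=sample_id,
        group_label=group_label,
    )


def generate_case_control(
    n_case: int = 14,
    n_control: int = 14,
    effect: str = "als_ge12",
    seed: int = 0,
    model: GenerativeGroupModel | None = None,
) -> tuple[list[Spectrum1D], SyntheticTruth]:
    """A simple two-group cohort (one spectrum per subject) for model tests."""
    model = model if model is not None else default_group_model(effect)
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed)
    spectra: list[Spectrum1D] = []
    groups = [("control", "control", model.ratio_columns["control"], n_control)]
    groups.append(("case", effect, model.ratio_columns[effect], n_case))
    for label, column_name, column, count in groups:
        for i in range(count):
            sid = f"{label.upper()}{i + 1:02d}"
            ratios = _draw_ratios(rng, column)
            sp = _render_sample(rng, model, ratios, sid, label)
            spectra.append(sp)
            truth.records.append(TruthRecord(sid, label, column_name, ratios, np.nan))
    return spectra, truth


# ---------------------------------------------------------------------------
# Longitudinal cohort


@dataclass
class CohortData:
    patients: list[Patient]
    spectra: list[Spectrum1D]
    truth: SyntheticTruth


def _effect_for_months(months: float) -> str:
    if months >= 18:
        return "als_ge18"
    if months >= 12:
        return "als_ge12"
    if months >= 6:
        return "als_ge06"
    return "baseline"


def _baseline_column(columns: Mapping[str, dict]) -> dict[str, tuple[float, float]]:
    # Half the >= 6-months effect: the baseline-only model is weak.
    ge06 = columns["als_ge06"]
    return {m: (1.0 + 0.5 * (mean - 1.0), sd) for m, (mean, sd) in ge06.items()}


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float) -> float:
    v = rng.normal(mean, sd)
    while not lo <= v <= hi:
        v = rng.normal(mean, sd)
    return float(v)


def generate_cohort(
    model: GenerativeGroupModel | None = None, seed: int = 0
) -> CohortData:
    """Generate the full longitudinal study: roster, spectra and truth.

    Attrition is deterministic: each ALS patient is pre-assigned a maximum
    follow-up stratum so the nested cohort sizes (40/20/14/11/6 at
    thresholds 0/6/12/18/24 months) are exact; PLS patients are followed to
    24 months and controls are sampled once.  Clinical covariates (disease
    duration at enrolment, progression rate, hence ALSFRS-R per visit) are
    drawn from truncated normals consistent with the cohort summary moments.
    """
    model = model if model is not None else default_group_model()
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(seed)
    patients: list[Patient] = []
    spectra: list[Spectrum1D] = []
    columns = dict(model.ratio_columns)
    baseline_col = _baseline_column(columns)

    def add_visit_sample(pid: str, group: str, months: float, column_name: str) -> None:
        column = baseline_col if column_name == "baseline" else columns[column_name]
        sid = f"{pid}-M{int(months):02d}"
        ratios = _draw_ratios(rng, column)
        spectra.append(_render_sample(rng, model, ratios, sid, group))
        truth.records.append(TruthRecord(sid, group, column_name, ratios, np.nan))

    pid_counter = 0
    for max_months, count in sorted(model.als_strata.items()):
        for _ in range(count):
            pid_counter += 1
            pid = f"ALS{pid_counter:03d}"
            duration0 = _trunc_normal(rng, 30.0, 25.0, 6.0, 150.0)
            rate = _trunc_normal(rng, 0.7, 0.6, 0.05, 3.5)
            visits = []
            for m in range(0, int(max_months) + 1, 6):
                duration = duration0 + m
                score = int(np.clip(round(48 - rate * duration), 1, 48))
                visits.append(Visit(pid, f"{pid}-M{m:02d}", float(m), duration, score))
                add_visit_sample(pid, "ALS", float(m), _effect_for_months(m))
            patients.append(Patient(pid, "ALS", visits))
    for i in range(model.n_pls):
        pid = f"PLS{i + 1:03d}"
        duration0 = _trunc_normal(rng, 140.0, 70.0, 36.0, 400.0)
        rate = _trunc_normal(rng, 0.2, 0.07, 0.02, 0.6)
        visits = []
        for m in range(0, 25, 6):
            duration = duration0 + m
            score = int(np.clip(round(48 - rate * duration), 1, 48))
            visits.append(Visit(pid, f"{pid}-M{m:02d}", float(m), duration, score))
            add_visit_sample(pid, "PLS", float(m), "gt5yr")
        patients.append(Patient(pid, "PLS", visits))
    for i in range(model.n_controls):
        pid = f"CTRL{i + 1:03d}"
        visits = [Visit(pid, f"{pid}-M00", 0.0, None, None)]
        add_visit_sample(pid, "control", 0.0, "control")
        patients.append(Patient(pid, "control", visits))
    return CohortData(patients, spectra, truth)
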