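"""Seeded synthetic cohorts and DIMS spectra for pipeline testing.

No raw data accompany the study design this package targets (an obese-pregnancy
cohort screened for gestational diabetes at ~28 weeks, with fasting-plasma
direct-infusion lipidomics and neonatal outcomes), so every downstream stage is
exercised against a generator that embodies the assumed statistical structure:

* a cohort of obese pregnant women (BMI >= 30) with a correlated OGTT glucose
  triplet, IADPSG-classified gestational diabetes (GDM), Table-1-style
  covariate marginals, and neonatal outcomes (birthweight percentile, LGA,
  abdominal circumference) receiving additive contributions from fasting
  glucose and from the de-novo-lipogenesis (DNL) lipid panel;
* a latent lipid abundance table in which DNL-panel species rise linearly (on
  the standardized scale) with fasting glucose;
* rendered centroided spectra with ppm mass error, multiplicative intensity
  noise, decoy peaks, a per-spectrum noise level, and a pooled-plasma QC
  dilution series (0.25x / 0.5x / 1.0x) — including optional saturating or
  dropout species to exercise the linearity and presence filters.

All randomness flows from a single seed through named child streams, so stage
outputs are bit-reproducible and stage-local parameter changes do not perturb
other stages' draws.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .masslist import (
    KNOWN_ADDUCTS,
    LipidSpecies,
    MassList,
    MassListEntry,
    ion_mz,
    parse_shorthand,
)
from .processing import PeakList

# IADPSG one-step OGTT thresholds, mmol/L (fasting, 1 h, 2 h).
IADPSG_THRESHOLDS = (5.1, 10.0, 8.5)

#: The nine DNL-related di/triglyceride species (acyls 16:0/16:1/18:0/18:1).
DNL_PANEL: tuple[str, ...] = (
    "DG(32:0)",
    "DG(32:1)",
    "DG(34:1)",
    "TG(46:0)",
    "TG(46:1)",
    "TG(48:0)",
    "TG(48:1)",
    "TG(50:1)",
    "TG(50:2)",
)

# Default glucose->lipid effects: slope of the standardized species per mmol/L
# fasting glucose (the generator's ground truth for parameter-recovery tests).
DEFAULT_LIPID_EFFECTS: dict[str, float] = {
    "DG(32:0)": 0.40,
    "DG(32:1)": 0.14,
    "DG(34:1)": 0.16,
    "TG(46:0)": 0.30,
    "TG(46:1)": 0.21,
    "TG(48:0)": 0.43,
    "TG(48:1)": 0.28,
    "TG(50:1)": 0.35,
    "TG(50:2)": 0.23,
}

# Default lipid->outcome effects per 1 SD lipid: (birthweight percentile
# points, abdominal circumference cm).
DEFAULT_OUTCOME_EFFECTS: dict[str, tuple[float, float]] = {
    "DG(32:0)": (2.84, 0.28),
    "DG(32:1)": (0.46, 0.11),
    "DG(34:1)": (1.65, 0.20),
    "TG(46:0)": (2.71, 0.23),
    "TG(46:1)": (1.98, 0.24),
    "TG(48:0)": (2.93, 0.19),
    "TG(48:1)": (1.68, 0.19),
    "TG(50:1)": (1.76, 0.23),
    "TG(50:2)": (0.73, 0.26),
}

# Background (non-panel) plasma species rendered alongside the panel so the
# per-mille denominator is not dominated by the glucose-responsive species.
DEFAULT_BACKGROUND_SPECIES: tuple[str, ...] = (
    "TG(50:3)", "TG(52:2)", "TG(52:3)", "TG(52:4)", "TG(54:2)", "TG(54:3)",
    "TG(54:4)", "TG(56:5)", "DG(34:2)", "DG(36:2)", "DG(36:3)",
    "PC(32:0)", "PC(32:1)", "PC(34:1)", "PC(34:2)", "PC(36:2)", "PC(36:4)",
    "PC(38:4)", "SM(34:1)", "SM(36:1)", "SM(42:2)", "CE(16:0)", "CE(18:1)",
    "CE(18:2)", "CE(20:4)",
    "PE(34:2)", "PE(36:2)", "PE(38:4)", "FA(16:0)", "FA(18:1)", "FA(18:2)",
)

# Which adduct/polarity each class is rendered under in simulated spectra
# (one variable per species keeps the truth <-> matrix mapping unambiguous).
RENDER_ADDUCTS: dict[str, tuple[str, str]] = {
    "TG": ("positive", "[M+NH4]+"),
    "DG": ("positive", "[M+NH4]+"),
    "PC": ("positive", "[M+H]+"),
    "SM": ("positive", "[M+H]+"),
    "CE": ("positive", "[M+Na]+"),
    "PE": ("negative", "[M-H]-"),
    "FA": ("negative", "[M-H]-"),
}


class GenerationError(RuntimeError):
    """Raised when generator targets are infeasible."""


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass
class GeneratorParams:
    """All knobs of the synthetic study, with cohort-report-style defaults.

    Defaults reproduce the study conditions: 867 subjects with a 241/867 GDM
    fraction, euglycemic-median OGTT glucose triplet with pairwise log-scale
    correlation 0.5, panel effect sizes from the glucose-association table,
    outcome effects from the unadjusted neonatal-outcome table, abdominal
    circumference missing in 450/867 and 1-h glucose in 40/867.
    """

    n_subjects: int = 867
    gdm_target_fraction: float = 241 / 867
    seed: int = 0

    # Covariates (marginal summaries by GDM group where reported)
    age_mean_eu: float = 30.3
    age_sd_eu: float = 5.7
    age_mean_gdm: float = 31.9
    age_sd_gdm: float = 4.7
    bmi_log_median: float = math.log(35.1)
    bmi_log_sd: float = 0.10
    bmi_floor: float = 30.0  # obesity inclusion criterion
    ethnicity_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "White": 582 / 867,
            "Black": 181 / 867,
            "Asian": 62 / 867,
            "Other": 42 / 867,
        }
    )
    nulliparous_p: float = 391 / 867
    control_arm_p: float = 450 / 867
    female_p: float = 409 / 867

    # OGTT glucose (log-normal, euglycemic-median location before the GDM shift)
    glucose_log_medians: tuple[float, float, float] = (
        math.log(4.5),
        math.log(7.1),
        math.log(5.6),
    )
    glucose_log_sds: tuple[float, float, float] = (0.082, 0.23, 0.19)
    glucose_corr: float = 0.5

    insulin_log_median: float = math.log(19.0)
    insulin_log_sd: float = 0.45
    insulin_glucose_loading: float = 0.6

    ga_ogtt_mean: float = 27.8
    ga_ogtt_sd: float = 0.8
    ga_birth_mean: float = 39.9
    ga_birth_sd: float = 1.3

    # Effect channels
    lipid_effect_map: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LIPID_EFFECTS)
    )
    outcome_effect_map: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_EFFECTS)
    )
    glucose_percentile_effect: float = 6.0  # percentile points per mmol/L fasting
    glucose_ac_effect: float = 0.25  # cm per mmol/L fasting
    percentile_noise_sd: float = 27.0
    ac_mean: float = 32.4
    ac_noise_sd: float = 2.0

    # Missingness (completely at random)
    ac_missing_fraction: float = 450 / 867
    glucose1h_missing_fraction: float = 40 / 867

    # Lipid abundance layer. DNL-panel species are minor plasma components:
    # their baselines sit well below the bulk PC/TG background, so the total
    # (per-mille denominator) is dominated by glucose-independent species.
    background_species: tuple[str, ...] = DEFAULT_BACKGROUND_SPECIES
    species_log_sd: float = 0.30  # log-scale amplitude of 1 SD latent score
    baseline_log10_range: tuple[float, float] = (4.5, 5.5)
    panel_baseline_log10_range: tuple[float, float] = (3.8, 4.3)
    baseline_scale: float = 1.0

    # Instrument layer
    ppm_error_sd: float = 3.0
    intensity_noise_log_sd: float = 0.10
    n_decoy_peaks: int = 120
    decoy_intensity_scale: float = 300.0
    noise_level: float = 300.0
    qc_dilutions: tuple[float, ...] = (0.25, 0.5, 1.0)
    qc_replicates_per_level: int = 1
    saturating_species: tuple[str, ...] = ()
    dropout_species: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not (0.0 <= self.gdm_target_fraction <= 1.0):
            raise GenerationError("gdm_target_fraction must lie in [0, 1]")
        if any(d <= 0 for d in self.qc_dilutions):
            raise ValueError("qc_dilutions must be strictly positive")
        if self.ppm_error_sd >= 3.0 and self.ppm_error_sd >= 9.0 / 3.0 + 1e-12:
            warnings.warn(
                "ppm_error_sd >= 3 ppm: annotation recall within the 9 ppm "
                "window is no longer guaranteed",
                stacklevel=2,
            )

    @property
    def species(self) -> tuple[str, ...]:
        panel = tuple(sorted(self.lipid_effect_map))
        return panel + tuple(s for s in self.background_species if s not in panel)

    def stream(self, key: int) -> np.random.Generator:
        """Named child RNG stream: one master seed, independent per stage."""
        return np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(self.seed, spawn_key=(key,)))
        )


# stream keys
_S_COHORT, _S_LIPID, _S_BACKGROUND, _S_OUTCOME, _S_MISSING, _S_SPECTRA, _S_BASELINE = (
    range(7)
)


# ---------------------------------------------------------------------------
# GDM classification
# ---------------------------------------------------------------------------


def classify_gdm(g0: float, g1: float, g2: float) -> bool:
    """IADPSG diagnosis from the OGTT triplet (mmol/L), thresholds inclusive.

    True iff fasting >= 5.1, or 1-hour >= 10.0, or 2-hour >= 8.5 mmol/L.
    """
    values = (g0, g1, g2)
    for v in values:
        if not (v > 0):
            raise ValueError(f"glucose values must be positive, got {values}")
    return any(v >= t for v, t in zip(values, IADPSG_THRESHOLDS))


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


@dataclass
class CohortRecord:
    """One pregnancy's covariates and neonatal outcomes."""

    subject_id: str
    age: float
    bmi: float
    ethnicity: str
    nulliparous: bool
    trial_arm: str
    glucose_0h: float
    glucose_1h: float  # NaN when missing
    glucose_2h: float
    insulin: float
    insulin_resistance_index: float
    gdm: bool
    neonatal_sex: str
    gestational_age_ogtt: float
    gestational_age_birth: float
    birthweight_percentile: float
    lga: bool
    abdominal_circumference: float  # NaN when missing


def _glucose_draws(params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    """Correlated standard-normal triplet underlying the glucose log-scales."""
    rho = params.glucose_corr
    corr = np.full((3, 3), rho)
    np.fill_diagonal(corr, 1.0)
    chol = np.linalg.cholesky(corr)
    return rng.standard_normal((params.n_subjects, 3)) @ chol.T


def _solve_gdm_shift(
    u: np.ndarray, params: GeneratorParams
) -> tuple[float, np.ndarray]:
    """Common log-scale location shift hitting the GDM target count exactly.

    A subject becomes GDM once the shift delta exceeds their critical value
    d_i = min_k (log thr_k - mu_k - sd_k * u_ik); placing delta between order
    statistics of d is the exact root of count(delta) = target on the
    empirical classifier.
    """
    n = u.shape[0]
    mus = np.array(params.glucose_log_medians)
    sds = np.array(params.glucose_log_sds)
    thr = np.log(np.array(IADPSG_THRESHOLDS))
    crit = (thr[None, :] - mus[None, :] - sds[None, :] * u).min(axis=1)
    m = int(round(params.gdm_target_fraction * n))
    if not (0 <= m <= n):
        raise GenerationError(
            f"gdm_target_fraction {params.gdm_target_fraction} infeasible for n={n}"
        )
    order = np.sort(crit)
    if m == 0:
        delta = order[0] - 1.0
    elif m == n:
        delta = order[-1] + 1.0
    else:
        # subjects with crit <= delta are GDM; take midpoint of the gap
        delta = 0.5 * (order[m - 1] + order[m])
        if order[m - 1] == order[m]:  # pragma: no cover - measure zero
            raise GenerationError("tied critical shifts; cannot hit GDM target exactly")
    glucose = np.exp(mus[None, :] + delta + sds[None, :] * u)
    return delta, glucose


def _panel_scores(
    g0: np.ndarray, params: GeneratorParams
) -> tuple[list[str], np.ndarray]:
    """Latent standardized DNL-panel scores shared by outcomes and abundances.

    z_s = beta_s * (g0 - mean(g0)) + e with Var(e) chosen so Var(z_s) ~ 1;
    the population slope of z_s on fasting glucose equals beta_s exactly.
    Drawn from the lipid stream so cohort outcomes and lipid profiles agree.
    """
    rng = np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(params.seed, spawn_key=(_S_LIPID,)))
    )
    names = sorted(params.lipid_effect_map)
    n = g0.shape[0]
    gc = g0 - g0.mean()
    var_g = gc.var()
    z = np.empty((n, len(names)))
    for j, name in enumerate(names):
        beta = params.lipid_effect_map[name]
        resid_sd = math.sqrt(max(0.05, 1.0 - beta * beta * var_g))
        z[:, j] = beta * gc + resid_sd * rng.standard_normal(n)
    return names, z


def generate_cohort(params: GeneratorParams) -> list[CohortRecord]:
    """Generate the cohort with IADPSG-consistent GDM labels and outcomes.

    Birthweight percentile and abdominal circumference receive additive
    contributions from fasting glucose and from the DNL-panel latent SD-scores
    (per ``outcome_effect_map``); LGA is derived as percentile >= 90. A
    configurable fraction of abdominal circumference and 1-h glucose is set
    missing completely at random.
    """
    for name in params.outcome_effect_map:
        if name not in params.lipid_effect_map:
            raise GenerationError(
                f"outcome_effect_map species {name!r} absent from lipid_effect_map"
            )
    n = params.n_subjects
    rng = params.stream(_S_COHORT)

    u = _glucose_draws(params, rng)
    _, glucose = _solve_gdm_shift(u, params)
    g0, g1, g2 = glucose.T
    gdm = np.array([classify_gdm(*row) for row in glucose])

    age = np.where(
        gdm,
        params.age_mean_gdm + params.age_sd_gdm * rng.standard_normal(n),
        params.age_mean_eu + params.age_sd_eu * rng.standard_normal(n),
    ).clip(16.5, 52.0)
    # BMI: log-normal left-truncated at the obesity inclusion threshold
    bmi = np.exp(params.bmi_log_median + params.bmi_log_sd * rng.standard_normal(n))
    low = bmi < params.bmi_floor
    while low.any():
        bmi[low] = np.exp(
            params.bmi_log_median + params.bmi_log_sd * rng.standard_normal(low.sum())
        )
        low = bmi < params.bmi_floor
    eth_names = list(params.ethnicity_probs)
    eth_p = np.array([params.ethnicity_probs[e] for e in eth_names], dtype=float)
    ethnicity = rng.choice(eth_names, size=n, p=eth_p / eth_p.sum())
    nulliparous = rng.random(n) < params.nulliparous_p
    trial_arm = np.where(rng.random(n) < params.control_arm_p, "control", "intervention")
    neonatal_sex = np.where(rng.random(n) < params.female_p, "female", "male")
    ga_ogtt = (params.ga_ogtt_mean + params.ga_ogtt_sd * rng.standard_normal(n)).clip(
        24.3, 30.0
    )
    ga_birth = (params.ga_birth_mean + params.ga_birth_sd * rng.standard_normal(n)).clip(
        34.0, 42.5
    )
    zg0 = (np.log(g0) - np.log(g0).mean()) / np.log(g0).std()
    insulin = np.exp(
        params.insulin_log_median
        + params.insulin_log_sd
        * (
            params.insulin_glucose_loading * zg0
            + math.sqrt(1 - params.insulin_glucose_loading**2)
            * rng.standard_normal(n)
        )
    )
    ir_index = insulin * g0 / 22.5

    panel_names, z = _panel_scores(g0, params)
    pct_eff = np.array(
        [params.outcome_effect_map.get(s, (0.0, 0.0))[0] for s in panel_names]
    )
    ac_eff = np.array(
        [params.outcome_effect_map.get(s, (0.0, 0.0))[1] for s in panel_names]
    )

    out_rng = params.stream(_S_OUTCOME)
    gc = g0 - g0.mean()
    percentile = (
        50.0
        + params.glucose_percentile_effect * gc
        + z @ pct_eff
        + params.percentile_noise_sd * out_rng.standard_normal(n)
    ).clip(0.1, 99.9)
    lga = percentile >= 90.0
    ac = (
        params.ac_mean
        + params.glucose_ac_effect * gc
        + z @ ac_eff
        + params.ac_noise_sd * out_rng.standard_normal(n)
    ).clip(24.0, 42.0)

    miss_rng = params.stream(_S_MISSING)
    ac_missing = miss_rng.random(n) < params.ac_missing_fraction
    g1_missing = miss_rng.random(n) < params.glucose1h_missing_fraction
    ac = np.where(ac_missing, np.nan, ac)
    g1_obs = np.where(g1_missing, np.nan, g1)

    width = len(str(n))
    return [
        CohortRecord(
            subject_id=f"S{i + 1:0{width}d}",
            age=float(age[i]),
            bmi=float(bmi[i]),
            ethnicity=str(ethnicity[i]),
            nulliparous=bool(nulliparous[i]),
            trial_arm=str(trial_arm[i]),
            glucose_0h=float(g0[i]),
            glucose_1h=float(g1_obs[i]),
            glucose_2h=float(g2[i]),
            insulin=float(insulin[i]),
            insulin_resistance_index=float(ir_index[i]),
            gdm=bool(gdm[i]),
            neonatal_sex=str(neonatal_sex[i]),
            gestational_age_ogtt=float(ga_ogtt[i]),
            gestational_age_birth=float(ga_birth[i]),
            birthweight_percentile=float(percentile[i]),
            lga=bool(lga[i]),
            abdominal_circumference=float(ac[i]),
        )
        for i in range(n)
    ]


def cohort_to_frame(cohort: Sequence[CohortRecord]) -> pd.DataFrame:
    df = pd.DataFrame([vars(r) for r in cohort]).set_index("subject_id")
    return df


# ---------------------------------------------------------------------------
# Lipid abundance layer
# ---------------------------------------------------------------------------


def generate_lipid_profiles(
    cohort: Sequence[CohortRecord], params: GeneratorParams
) -> pd.DataFrame:
    """Latent (pre-instrument) abundance table, samples x species, positive.

    Per species, log-abundance = baseline + species_log_sd * z, where z is the
    standardized latent score: for DNL-panel species z carries the
    linear-in-fasting-glucose shift from ``lipid_effect_map``; background
    species are independent of glucose. Baselines are deterministic under the
    seed; ``baseline_scale`` multiplies all abundances (a change that per-mille
    normalization must cancel downstream).
    """
    if not cohort:
        raise ValueError("cohort is empty")
    for name in params.lipid_effect_map:
        parse_shorthand(name)  # raises on unknown species keys
    g0 = np.array([r.glucose_0h for r in cohort])
    panel_names, z_panel = _panel_scores(g0, params)
    bg_names = [s for s in params.background_species if s not in set(panel_names)]
    bg_rng = params.stream(_S_BACKGROUND)
    z_bg = bg_rng.standard_normal((len(cohort), len(bg_names)))

    names = panel_names + bg_names
    z = np.hstack([z_panel, z_bg]) if bg_names else z_panel
    base_rng = params.stream(_S_BASELINE)
    p_lo, p_hi = params.panel_baseline_log10_range
    b_lo, b_hi = params.baseline_log10_range
    panel_base = base_rng.uniform(p_lo, p_hi, size=len(panel_names))
    bg_base = base_rng.uniform(b_lo, b_hi, size=len(bg_names))
    baselines = 10.0 ** np.concatenate([panel_base, bg_base])
    values = (
        params.baseline_scale
        * baselines[None, :]
        * np.exp(params.species_log_sd * z)
    )
    return pd.DataFrame(
        values, index=[r.subject_id for r in cohort], columns=names
    )


# ---------------------------------------------------------------------------
# Spectrum rendering
# ---------------------------------------------------------------------------


def simulation_mass_list(species_names: Iterable[str]) -> dict[str, MassList]:
    """Compact annotation lists: one rendered adduct per species per polarity."""
    entries: dict[str, list[MassListEntry]] = {"positive": [], "negative": []}
    for name in species_names:
        sp = parse_shorthand(name)
        pol, adduct_label = RENDER_ADDUCTS[sp.lipid_class]
        adduct = KNOWN_ADDUCTS[adduct_label]
        entries[pol].append(MassListEntry(ion_mz(sp, adduct), sp, adduct))
    return {
        pol: MassList(ents, pol)
        for pol, ents in entries.items()
        if ents
    }


def _render_polarity(
    values: np.ndarray,
    sample_ids: Sequence[str],
    theo_mz: np.ndarray,
    params: GeneratorParams,
    rng: np.random.Generator,
    polarity: str,
    is_qc: bool = False,
    dilutions: Sequence[float] | None = None,
    drop_mask: np.ndarray | None = None,
) -> list[PeakList]:
    n, k = values.shape
    eps = rng.normal(0.0, params.ppm_error_sd, size=(n, k)) if params.ppm_error_sd else np.zeros((n, k))
    mz_obs = theo_mz[None, :] * (1.0 + eps * 1e-6)
    if params.intensity_noise_log_sd:
        inten = values * np.exp(
            rng.normal(0.0, params.intensity_noise_log_sd, size=(n, k))
        )
    else:
        inten = values.copy()
    keep = inten > 0
    if drop_mask is not None:
        keep &= ~drop_mask
    lists = []
    lo, hi = 150.0, 1200.0
    for i in range(n):
        mzs = mz_obs[i, keep[i]]
        ints = inten[i, keep[i]]
        if params.n_decoy_peaks:
            d_mz = rng.uniform(lo, hi, params.n_decoy_peaks)
            d_int = rng.exponential(params.decoy_intensity_scale, params.n_decoy_peaks)
            mzs = np.concatenate([mzs, d_mz])
            ints = np.concatenate([ints, d_int])
        order = np.argsort(mzs)
        lists.append(
            PeakList(
                sample_id=sample_ids[i],
                polarity=polarity,
                mz=mzs[order],
                intensity=ints[order],
                noise_level=params.noise_level,
                is_qc=is_qc,
                qc_dilution=None if dilutions is None else float(dilutions[i]),
            )
        )
    return lists


def render_spectra(
    truth: pd.DataFrame,
    masslists: Mapping[str, MassList] | MassList,
    params: GeneratorParams,
) -> tuple[list[PeakList], list[PeakList]]:
    """Render centroided sample and QC spectra from the latent abundances.

    Each species contributes one centroid at its rendered-adduct theoretical
    m/z, perturbed by N(0, ppm_error_sd) multiplicative ppm error, with
    intensity proportional to truth under multiplicative log-normal noise;
    uniform-m/z decoy peaks with exponential intensities are added and a
    per-spectrum noise level emitted. QC spectra are rendered from the pooled
    truth scaled by each dilution factor; species listed in
    ``saturating_species`` respond flat across dilutions (to exercise the
    linearity filter) and ``dropout_species`` maps species to per-sample
    dropout probabilities (to exercise the presence filter).

    Returns ``(sample_peaklists, qc_peaklists)``; a subject contributes one
    peak list per rendered polarity, sharing its sample id.
    """
    if isinstance(masslists, MassList):
        masslists = {masslists.polarity: masslists}
    rng = params.stream(_S_SPECTRA)
    # map each truth species to its rendered entry, grouped by polarity
    by_pol: dict[str, list[tuple[int, float, str]]] = {}
    for j, name in enumerate(truth.columns):
        sp = parse_shorthand(name)
        pol, adduct_label = RENDER_ADDUCTS[sp.lipid_class]
        ml = masslists.get(pol)
        entry = None
        if ml is not None:
            for e in ml:
                if e.species == sp and e.adduct.label == adduct_label:
                    entry = e
                    break
            if entry is None:  # fall back to any adduct of the species
                for e in ml:
                    if e.species == sp:
                        entry = e
                        break
        if entry is None:
            raise ValueError(
                f"species {name} has no mass-list entry in rendered polarity {pol}"
            )
        by_pol.setdefault(pol, []).append((j, entry.mz, name))

    sample_ids = list(truth.index)
    n = len(sample_ids)
    pooled = truth.to_numpy().mean(axis=0)
    qc_levels = [
        d for d in params.qc_dilutions for _ in range(params.qc_replicates_per_level)
    ]
    sample_lists: list[PeakList] = []
    qc_lists: list[PeakList] = []
    for pol in sorted(by_pol):
        cols = by_pol[pol]
        idx = np.array([c[0] for c in cols])
        theo = np.array([c[1] for c in cols])
        names = [c[2] for c in cols]
        vals = truth.to_numpy()[:, idx]
        drop = None
        if params.dropout_species:
            drop = np.zeros((n, len(cols)), dtype=bool)
            for jj, nm in enumerate(names):
                p_drop = params.dropout_species.get(nm, 0.0)
                if p_drop > 0:
                    drop[:, jj] = rng.random(n) < p_drop
        sample_lists.extend(
            _render_polarity(vals, sample_ids, theo, params, rng, pol, drop_mask=drop)
        )
        # QC dilution series from pooled truth
        qc_vals = pooled[None, idx] * np.array(qc_levels)[:, None]
        for jj, nm in enumerate(names):
            if nm in params.saturating_species:
                qc_vals[:, jj] = pooled[idx[jj]]  # flat response
        qc_ids = [f"QC{q + 1:02d}" for q in range(len(qc_levels))]
        qc_lists.extend(
            _render_polarity(
                qc_vals, qc_ids, theo, params, rng, pol, is_qc=True,
                dilutions=qc_levels,
            )
        )
    return sample_lists, qc_lists
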