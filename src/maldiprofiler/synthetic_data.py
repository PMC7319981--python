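"""Synthetic MALDI profiling cohorts and clinical / IHC tables.

The generator emulates the study design of a two-class (fibroadenoma vs.
low-grade phyllodes tumor), two-compartment (epithelial / stromal) profiling
cohort: ~30 cases per class, 20 annotated spots per compartment per case, one
spectrum per spot, near-identical class peak profiles with heavy case-level
heterogeneity. Every nuisance the preprocessing chain is built to remove is
planted explicitly: an exponential chemical-noise baseline, a log-normal
per-case intensity gain (exercises TIC normalization), and a uniform
per-spectrum mass shift (exercises re-alignment).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .spectra_io import Spectrum, ProfileDataset


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic cohort.

    Defaults mirror the emulated study design: 30 cases per class, 20 spots
    per compartment, tryptic-peptide mass range 800-3500 Da on a 1 Da grid,
    and a null class difference (no discriminating peaks) — the regime in
    which the cohort's two classes are proteomically indistinguishable.
    ``effect_log2fc`` is applied to the discriminating peaks in the LGP
    stromal spectra (the compartment where class differences would live).
    """

    n_cases_per_class: int = 30
    spots_per_compartment: int = 20
    mz_min: float = 800.0
    mz_max: float = 3500.0
    mz_step: float = 1.0
    n_peaks: int = 60
    n_discriminating_peaks: int = 0
    effect_log2fc: float = 0.0
    effect_compartments: tuple = ("stromal",)
    peak_width_sigma: float = 2.0
    peak_height_median: float = 100.0
    peak_height_log_sd: float = 0.5
    baseline_amplitude: float = 30.0
    baseline_decay: float = 0.002
    noise_sd: float = 1.0
    case_gain_sd: float = 0.5
    case_peak_sd: float = 0.3
    mass_shift_max: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_discriminating_peaks <= self.n_peaks):
            raise ValueError("need 0 <= n_discriminating_peaks <= n_peaks")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        for name in (
            "peak_width_sigma", "baseline_amplitude", "baseline_decay",
            "noise_sd", "case_gain_sd", "case_peak_sd", "mass_shift_max",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_cases_per_class < 1 or self.spots_per_compartment < 1:
            raise ValueError("need >= 1 case per class and >= 1 spot per compartment")

    @property
    def mz_axis(self) -> np.ndarray:
        return np.arange(self.mz_min, self.mz_max + self.mz_step / 2, self.mz_step)


@dataclass
class GroundTruth:
    """What was planted: discriminating peaks, true class per case, the
    planted per-peak table, and the per-case / per-spectrum nuisances."""

    discriminating_peak_mzs: list
    true_class_by_case: dict
    planted_peak_table: pd.DataFrame  # columns: mz, sigma, height_base, height_lgp_effect
    case_gain: dict = field(default_factory=dict)
    mass_shift_by_spot: dict = field(default_factory=dict)
    case_peak_factors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        planted = set(np.round(self.planted_peak_table["mz"].to_numpy(), 6))
        for mz in self.discriminating_peak_mzs:
            if round(float(mz), 6) not in planted:
                raise ValueError(f"discriminating m/z {mz} not in planted peak table")

    def to_json(self, path) -> None:
        payload = {
            "discriminating_peak_mzs": [float(m) for m in self.discriminating_peak_mzs],
            "true_class_by_case": self.true_class_by_case,
            "planted_peak_table": self.planted_peak_table.to_dict(orient="list"),
            "case_gain": self.case_gain,
            "mass_shift_by_spot": self.mass_shift_by_spot,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def spectrum_model(
    mz_axis: np.ndarray,
    planted_peaks: pd.DataFrame,
    baseline_amplitude: float,
    baseline_decay: float,
    case_gain: float,
    mass_shift: float,
    noise_sd: float,
    rng: np.random.Generator,
    **provenance,
) -> Spectrum:
    """Render one spectrum from the generative model.

    intensity = case_gain * [ sum of Gaussians(center + mass_shift, sigma,
    height) + baseline_amplitude * exp(-baseline_decay * (mz - mz_min)) ]
    + additive Gaussian noise, truncated at zero.

    ``planted_peaks`` needs columns mz, sigma, height.
    """
    mz = np.asarray(mz_axis, dtype=float)
    d = np.diff(mz)
    if len(mz) < 2 or np.any(d <= 0) or not np.allclose(d, d[0]):
        raise ValueError("mz_axis must be strictly increasing with uniform spacing")
    signal = np.zeros_like(mz)
    for row in planted_peaks.itertuples():
        c = row.mz + mass_shift
        signal += row.height * np.exp(-0.5 * ((mz - c) / row.sigma) ** 2)
    baseline = baseline_amplitude * np.exp(-baseline_decay * (mz - mz[0]))
    intensity = case_gain * (signal + baseline)
    if noise_sd > 0:
        intensity = intensity + rng.normal(0.0, noise_sd, size=len(mz))
    intensity = np.maximum(intensity, 0.0)
    return Spectrum(mz=mz, intensity=intensity, **provenance)


def _plant_peaks(config: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw peak centers (minimum separation 8 sigma) and log-normal heights."""
    margin = 6 * config.peak_width_sigma
    min_sep = 8 * config.peak_width_sigma
    lo, hi = config.mz_min + margin, config.mz_max - margin
    centers: list[float] = []
    attempts = 0
    while len(centers) < config.n_peaks:
        c = float(rng.uniform(lo, hi))
        if all(abs(c - x) >= min_sep for x in centers):
            centers.append(c)
        attempts += 1
        if attempts > 1000 * config.n_peaks:
            raise ValueError("cannot place peaks at the requested density; widen the mass range")
    centers = np.sort(np.array(centers))
    heights = config.peak_height_median * np.exp(
        rng.normal(0.0, config.peak_height_log_sd, size=config.n_peaks)
    )
    disc = np.zeros(config.n_peaks, dtype=bool)
    if config.n_discriminating_peaks:
        disc[rng.choice(config.n_peaks, size=config.n_discriminating_peaks, replace=False)] = True
    return pd.DataFrame(
        {
            "mz": centers,
            "sigma": config.peak_width_sigma,
            "height_base": heights,
            "discriminating": disc,
        }
    )


def generate_dataset(config: SyntheticConfig):
    """Generate a full two-class cohort; returns (ProfileDataset, GroundTruth).

    Case ids are ``FA01..`` / ``LGP01..``; every case gets
    ``spots_per_compartment`` spectra in each of the epithelial and stromal
    compartments. Discriminating peaks are multiplied by ``2**effect_log2fc``
    in LGP spectra of the compartments named in ``effect_compartments``.
    The partition map is all-``unassigned`` until ``classify.split_dataset``.
    """
    rng = np.random.default_rng(config.seed)
    table = _plant_peaks(config, rng)
    mz_axis = config.mz_axis
    fc = 2.0 ** config.effect_log2fc
    disc_mask = table["discriminating"].to_numpy()

    spectra = []
    truth_class: dict[str, str] = {}
    case_gain: dict[str, float] = {}
    shifts: dict[str, float] = {}
    case_factors: dict[str, list] = {}

    for label in ("FA", "LGP"):
        for k in range(config.n_cases_per_class):
            case_id = f"{label}{k + 1:02d}"
            truth_class[case_id] = label
            gain = float(np.exp(rng.normal(0.0, config.case_gain_sd)))
            case_gain[case_id] = gain
            # per-case multiplicative peak-height perturbation (tumor heterogeneity)
            factors = np.exp(rng.normal(0.0, config.case_peak_sd, size=config.n_peaks))
            case_factors[case_id] = factors.tolist()
            for compartment in ("epithelial", "stromal"):
                heights = table["height_base"].to_numpy() * factors
                if label == "LGP" and compartment in config.effect_compartments:
                    heights = np.where(disc_mask, heights * fc, heights)
                peaks = pd.DataFrame(
                    {"mz": table["mz"], "sigma": table["sigma"], "height": heights}
                )
                for spot in range(config.spots_per_compartment):
                    spot_id = f"{case_id}_{compartment[0]}{spot + 1:02d}"
                    shift = float(rng.uniform(-config.mass_shift_max, config.mass_shift_max))
                    shifts[spot_id] = shift
                    spectra.append(
                        spectrum_model(
                            mz_axis,
                            peaks,
                            config.baseline_amplitude,
                            config.baseline_decay,
                            gain,
                            shift,
                            config.noise_sd,
                            rng,
                            case_id=case_id,
                            spot_id=spot_id,
                            compartment=compartment,
                            class_label=label,
                        )
                    )

    truth = GroundTruth(
        discriminating_peak_mzs=table.loc[disc_mask, "mz"].tolist(),
        true_class_by_case=truth_class,
        planted_peak_table=table,
        case_gain=case_gain,
        mass_shift_by_spot=shifts,
        case_peak_factors=case_factors,
    )
    dataset = ProfileDataset(
        spectra=spectra, partition={c: "unassigned" for c in truth_class}
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# clinical / IHC tables

#: per-group clinical distribution defaults: mean, sd, and clipping range,
#: matching the emulated cohort summaries.
CLINICAL_DEFAULTS = {
    "LGP": {
        "age": (35.5, 11.0, 14.0, 63.0),
        "size": (3.0, 1.3, 0.8, 7.0),
        "followup": (44.6, 30.0, 0.0, 131.0),
        "recurrence_p": 2.0 / 31.0,
        "death_p": 0.0,
    },
    "FA": {
        "age": (27.0, 8.5, 15.0, 49.0),
        "size": (2.7, 0.9, 1.2, 5.1),
        "followup": (59.2, 28.0, 0.0, 109.0),
        "recurrence_p": 0.0,
        "death_p": 0.0,
    },
}

#: per-marker (FA, LGP, HGP) mean percent positive stromal cells with
#: per-group sd and clip range.
IHC_DEFAULTS = {
    "Ki67": {"FA": (2.5, 2.0, 1, 10), "LGP": (7.7, 6.5, 2, 30), "HGP": (45.0, 17.0, 20, 70)},
    "p53": {"FA": (2.7, 4.0, 1, 20), "LGP": (10.0, 14.0, 1, 60), "HGP": (30.5, 30.0, 2, 100)},
    "beta_catenin": {"FA": (38.2, 22.0, 0, 80), "LGP": (48.8, 25.0, 2, 90), "HGP": (9.5, 12.0, 0, 40)},
    "E_cadherin": {"FA": (0.0, 0.0, 0, 0), "LGP": (0.0, 0.0, 0, 0), "HGP": (0.0, 0.0, 0, 0)},
}


def _clipped_normal(rng, mean, sd, lo, hi, n):
    """Clipped normal draws whose expectation equals ``mean``.

    Clipping a normal to [lo, hi] shifts its mean, so the pre-clip location
    is solved (bisection on the closed-form clipped-normal mean) to make the
    realized mean match the requested one.
    """
    from scipy import optimize, stats as _stats

    if sd == 0:
        return np.full(n, float(np.clip(mean, lo, hi)))

    def clipped_mean(mu):
        a, b = (lo - mu) / sd, (hi - mu) / sd
        phi_a, phi_b = _stats.norm.pdf(a), _stats.norm.pdf(b)
        cdf_a, cdf_b = _stats.norm.cdf(a), _stats.norm.cdf(b)
        return (
            lo * cdf_a
            + hi * (1 - cdf_b)
            + mu * (cdf_b - cdf_a)
            + sd * (phi_a - phi_b)
        )

    lo_mu, hi_mu = lo - 6 * sd, hi + 6 * sd
    mu = optimize.brentq(lambda m: clipped_mean(m) - mean, lo_mu, hi_mu)
    return np.clip(rng.normal(mu, sd, size=n), lo, hi)


def generate_clinical_table(n_lgp: int, n_fa: int, seed: int = 0) -> list:
    """Synthetic per-patient outcome records with group-specific age, tumor
    size, follow-up, and recurrence distributions.

    Recurrent cases get an event time uniform within their follow-up window;
    everyone else is censored at last follow-up.
    """
    from .clinstats import ClinicalRecord

    if n_lgp < 1 or n_fa < 1:
        raise ValueError("need >= 1 patient per group")
    rng = np.random.default_rng(seed)
    records = []
    for group, n in (("LGP", n_lgp), ("FA", n_fa)):
        d = CLINICAL_DEFAULTS[group]
        ages = _clipped_normal(rng, *d["age"], n)
        sizes = _clipped_normal(rng, *d["size"], n)
        fus = _clipped_normal(rng, *d["followup"], n)
        rec = rng.random(n) < d["recurrence_p"]
        death = rng.random(n) < d["death_p"]
        for i in range(n):
            fu = float(round(fus[i], 1))
            event = bool(rec[i] or death[i])
            tte = float(round(rng.uniform(0.2, 1.0) * fu, 1)) if event and fu > 0 else fu
            records.append(
                ClinicalRecord(
                    case_id=f"{group}{i + 1:02d}",
                    group=group,
                    age=float(round(ages[i], 1)),
                    tumor_size=float(round(sizes[i], 1)),
                    followup_months=fu,
                    recurrence=bool(rec[i]),
                    death_from_disease=bool(death[i]),
                    time_to_event=tte,
                )
            )
    return records


def generate_ihc_table(n_fa: int, n_lgp: int, n_hgp: int, seed: int = 0) -> list:
    """Synthetic two-reader IHC percent-positivity records for Ki-67, p53,
    beta-catenin, and E-cadherin across the three diagnostic groups.

    Each case's true positivity is drawn from the group distribution; the two
    readers see it with independent estimation noise (sd 15% of the true
    value, minimum 0.5 points), clipped to [0, 100].
    """
    from .clinstats import IHCRecord

    rng = np.random.default_rng(seed)
    records = []
    for group, n in (("FA", n_fa), ("LGP", n_lgp), ("HGP", n_hgp)):
        trues = {
            marker: _clipped_normal(rng, *groups[group], n)
            for marker, groups in IHC_DEFAULTS.items()
        }
        for i in range(n):
            case_id = f"{group}{i + 1:02d}"
            for marker in IHC_DEFAULTS:
                true = float(trues[marker][i])
                reader_sd = max(0.15 * true, 0.5) if true > 0 else 0.0
                r1 = float(np.clip(rng.normal(true, reader_sd), 0, 100))
                r2 = float(np.clip(rng.normal(true, reader_sd), 0, 100))
                records.append(
                    IHCRecord(
                        case_id=case_id,
                        group=group,
                        marker=marker,
                        reader1_pct=round(r1, 1),
                        reader2_pct=round(r2, 1),
                    )
                )
    return records


def config_to_yaml(config: SyntheticConfig, path) -> None:
    import yaml

    d = asdict(config)
    d["effect_compartments"] = list(d["effect_compartments"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh)


def config_from_yaml(path) -> SyntheticConfig:
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["effect_compartments"] = tuple(d.get("effect_compartments", ("stromal",)))
    return SyntheticConfig(**d)
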