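"""Synthetic fly NIR spectra with the full study's cohort structure.

No raw spectra were ever deposited for the original fly studies, so this
module generates stand-in populations with the same design: two Drosophila
species with two lines each (Alst/Dah for D. melanogaster, Hw/Ky for
D. simulans), both sexes, seven calibration age cohorts (1, 5, 9, 13, 17,
21, 25 days after eclosion) of 45 flies per cell, independent cohorts at
5/13/21 days, and a separate Wolbachia population (lines Hw2/Hw152,
infected/uninfected pairs scanned at 15 days).

Spectral model
--------------
Each fly's absorbance spectrum is an additive composition

    a(lambda) = baseline(lambda) + offset
                + sum_bands amp_fly,band * Gaussian(lambda; center, width)
                + noise(lambda)

with Gaussian absorption bands at 1225, 1390, 1450, 1540, 1570 and 1620 nm
(lipid CH and water OH overtone regions), a smooth polynomial baseline, a
per-fly additive scatter offset, and instrument noise whose standard
deviation rises outside 500–2200 nm.

Class information enters through per-fly latent traits.  A fly's species,
sex and infection status set the mean of a latent trait (+-0.5) around which
individual flies scatter (biological variation); chronological age enters
through a "physiological age" latent t_eff = age + noise that drives a
mildly saturating band response g(t) = t + gamma*(1 - exp(-rate*t)).  Band
amplitudes are linear in these latents, so classes are exactly separable
when all variances are zero, and realistically overlapping at the defaults.
Independent-set lines carry small line-specific shifts and amplitude
multipliers to emulate between-line differences that degrade cross-line
prediction.  Everything is deterministic given the seed.

The defaults are calibrated once to the qualitative behaviour of the fly
studies (binary accuracies in the low-to-mid 90s, age regressions with
slope ~0.9 and r^2 ~0.87, age bias positive before 9 d and negative after
13 d); they are modelling conveniences, not measured biology.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, ValidationError
from .spectra_io import META_COLUMNS, SpectrumSet, write_metadata, write_spectra


@dataclass(frozen=True)
class BandSpec:
    """One Gaussian absorption band and its class/age effect loadings.

    ``base_amp`` is the amplitude (absorbance units) for a reference fly;
    the ``*_coef`` loadings convert a latent trait (species/sex/infection,
    scaled +-0.5 between classes) or the saturating age response g(t) (days)
    into an amplitude change.
    """

    center_nm: float
    width_nm: float
    base_amp: float
    species_coef: float = 0.0
    sex_coef: float = 0.0
    infection_coef: float = 0.0
    age_coef: float = 0.0

    def __post_init__(self) -> None:
        if self.width_nm <= 0:
            raise ConfigError("band width must be positive")


def default_bands() -> tuple[BandSpec, ...]:
    """The six bands of the default generator.

    Species differences sit on the lipid CH-overtone bands (1225, 1390,
    1620 nm, weakly 1570), sex and infection differences on the water/lipid
    bands (1450, 1540, plus 1620 for infection), and age drives all bands
    equally — an echo of cuticular-hydrocarbon and water-content chemistry,
    chosen for plausibility rather than measured from flies.
    """
    return (
        BandSpec(1225.0, 25.0, 0.06, species_coef=0.025, age_coef=0.0016),
        BandSpec(1390.0, 20.0, 0.05, species_coef=0.019, age_coef=0.0016),
        BandSpec(1450.0, 30.0, 0.10, sex_coef=0.025, infection_coef=0.029,
                 age_coef=0.0016),
        BandSpec(1540.0, 35.0, 0.08, sex_coef=0.020, infection_coef=0.024,
                 age_coef=0.0016),
        BandSpec(1570.0, 20.0, 0.05, species_coef=0.010, age_coef=0.0016),
        BandSpec(1620.0, 25.0, 0.06, species_coef=0.022, infection_coef=0.016,
                 age_coef=0.0016),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Design and noise parameters of the synthetic populations."""

    # wavelength grid (nm)
    grid_lo: float = 350.0
    grid_hi: float = 2500.0
    grid_step: float = 1.0
    # spectral composition
    bands: tuple[BandSpec, ...] = field(default_factory=default_bands)
    baseline_coeffs: tuple[float, float, float] = (0.35, 2.5e-4, -6.0e-8)
    scatter_sd: float = 0.03            # per-fly additive offset (absorbance)
    noise_in: float = 0.0015            # instrument noise inside 500-2200 nm
    noise_out: float = 0.010            # elevated noise outside that region
    noise_lo: float = 500.0
    noise_hi: float = 2200.0
    # biological variation (latent trait scatter around the class means)
    species_latent_sd: float = 0.21
    sex_latent_sd: float = 0.25
    infection_latent_sd: float = 0.22
    age_latent_sd: float = 2.8          # physiological vs chronological age, days
    band_noise_sd: float = 0.002        # per-fly, per-band amplitude noise
    # saturating age response g(t) = t + gamma * (1 - exp(-rate * t))
    age_sat_gamma: float = 2.5
    age_sat_rate: float = 0.2
    # species/gender/age population design
    n_per_cell: int = 45
    cal_cohorts: tuple[int, ...] = (1, 5, 9, 13, 17, 21, 25)
    indep_cohorts: tuple[int, ...] = (5, 13, 21)
    cal_lines: tuple[str, ...] = ("Alst", "Dah", "Hw", "Ky")
    indep_lines: tuple[str, ...] = ("Dah", "Ky")
    line_species: tuple[tuple[str, str], ...] = (
        ("Alst", "melanogaster"), ("Dah", "melanogaster"),
        ("Hw", "simulans"), ("Ky", "simulans"),
        ("Hw2", "simulans"), ("Hw152", "simulans"),
    )
    # line idiosyncrasies (shift of the species/infection latent toward the
    # decision boundary; multiplier on all band amplitudes)
    line_latent_shift: tuple[tuple[str, float], ...] = (
        ("Dah", 0.05), ("Ky", -0.05), ("Hw2", 0.04), ("Hw152", -0.04),
    )
    line_amp_mult: tuple[tuple[str, float], ...] = (
        ("Dah", 1.03), ("Ky", 0.97),
    )
    # Wolbachia population design (cohort sizes mirror the study: 300
    # calibration flies and ~120 independent flies)
    wol_lines: tuple[str, ...] = ("Hw2", "Hw152")
    wol_age: int = 15
    wol_n_cal: int = 75                 # per line x infection cell
    wol_n_indep: int = 30

    def __post_init__(self) -> None:
        if self.n_per_cell < 1 or self.wol_n_cal < 1 or self.wol_n_indep < 0:
            raise ConfigError("cell sizes must be positive")
        for sd in (self.scatter_sd, self.noise_in, self.noise_out,
                   self.species_latent_sd, self.sex_latent_sd,
                   self.infection_latent_sd, self.age_latent_sd,
                   self.band_noise_sd):
            if sd < 0:
                raise ConfigError("noise standard deviations must be >= 0")
        for b in self.bands:
            if not self.grid_lo <= b.center_nm <= self.grid_hi:
                raise ConfigError(
                    f"band center {b.center_nm} nm outside grid "
                    f"[{self.grid_lo}, {self.grid_hi}]"
                )

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_hi - self.grid_lo) / self.grid_step)) + 1
        return self.grid_lo + self.grid_step * np.arange(n)

    def species_of(self, line: str) -> str:
        table = dict(self.line_species)
        if line not in table:
            raise ConfigError(f"unknown line {line!r}")
        return table[line]

    def latent_shift_of(self, line: str) -> float:
        return dict(self.line_latent_shift).get(line, 0.0)

    def amp_mult_of(self, line: str) -> float:
        return dict(self.line_amp_mult).get(line, 1.0)


def noiseless(cfg: SyntheticConfig) -> SyntheticConfig:
    """Copy of the config with every random variance set to zero."""
    return replace(cfg, scatter_sd=0.0, noise_in=0.0, noise_out=0.0,
                   species_latent_sd=0.0, sex_latent_sd=0.0,
                   infection_latent_sd=0.0, age_latent_sd=0.0,
                   band_noise_sd=0.0)


# ---------------------------------------------------------------------------
# core spectrum synthesis


def _band_profiles(cfg: SyntheticConfig) -> np.ndarray:
    """(n_bands, p) matrix of unit-amplitude Gaussian band shapes."""
    wl = cfg.grid
    profiles = np.empty((len(cfg.bands), wl.size))
    for i, b in enumerate(cfg.bands):
        profiles[i] = np.exp(-0.5 * ((wl - b.center_nm) / b.width_nm) ** 2)
    return profiles


def _age_response(cfg: SyntheticConfig, t: np.ndarray) -> np.ndarray:
    """Saturating band response g(t) = t + gamma (1 - exp(-rate t))."""
    return t + cfg.age_sat_gamma * (1.0 - np.exp(-cfg.age_sat_rate * t))


def _synthesize(cfg: SyntheticConfig, design: pd.DataFrame,
                rng: np.random.Generator) -> SpectrumSet:
    """Draw one absorbance spectrum per design row."""
    wl = cfg.grid
    n, p = len(design), wl.size
    x = wl - cfg.grid_lo
    a0, a1, a2 = cfg.baseline_coeffs
    baseline = a0 + a1 * x + a2 * x * x

    # per-fly latent traits
    half = {"melanogaster": -0.5, "simulans": 0.5}
    z_species = (design["species"].map(half).to_numpy(dtype=float)
                 + design["line"].map(cfg.latent_shift_of).to_numpy(dtype=float)
                 + rng.normal(0.0, cfg.species_latent_sd, n))
    z_sex = (design["sex"].map({"male": -0.5, "female": 0.5}).to_numpy(dtype=float)
             + rng.normal(0.0, cfg.sex_latent_sd, n))
    inf_mean = design["infection"].map(
        {"infected": 0.5, "uninfected": -0.5, "unknown": 0.0}
    ).to_numpy(dtype=float)
    infection_shift = np.where(
        design["infection"].to_numpy() == "unknown", 0.0,
        design["line"].map(cfg.latent_shift_of).to_numpy(dtype=float))
    z_inf = np.where(
        inf_mean == 0.0, 0.0,
        inf_mean + infection_shift + rng.normal(0.0, cfg.infection_latent_sd, n))
    t_eff = (design["age_days"].to_numpy(dtype=float)
             + rng.normal(0.0, cfg.age_latent_sd, n))
    g = _age_response(cfg, t_eff)

    # per-fly band amplitudes: (n, n_bands)
    bands = cfg.bands
    base = np.array([b.base_amp for b in bands])
    amp = (base[None, :]
           + np.outer(z_species, [b.species_coef for b in bands])
           + np.outer(z_sex, [b.sex_coef for b in bands])
           + np.outer(z_inf, [b.infection_coef for b in bands])
           + np.outer(g, [b.age_coef for b in bands])
           + rng.normal(0.0, cfg.band_noise_sd, (n, len(bands))))
    amp *= design["line"].map(cfg.amp_mult_of).to_numpy(dtype=float)[:, None]

    values = baseline[None, :] + amp @ _band_profiles(cfg)
    values += rng.normal(0.0, cfg.scatter_sd, n)[:, None]
    noise_sd = np.where((wl >= cfg.noise_lo) & (wl <= cfg.noise_hi),
                        cfg.noise_in, cfg.noise_out)
    if np.any(noise_sd > 0):
        values += rng.normal(0.0, 1.0, (n, p)) * noise_sd[None, :]

    meta = design[META_COLUMNS].copy()
    return SpectrumSet(wl, values, meta, units="absorbance")


# ---------------------------------------------------------------------------
# study populations


def _design_rows(cfg: SyntheticConfig) -> pd.DataFrame:
    rows = []
    for split, lines, cohorts in (
        ("calibration", cfg.cal_lines, cfg.cal_cohorts),
        ("independent", cfg.indep_lines, cfg.indep_cohorts),
    ):
        for line in lines:
            for sex in ("male", "female"):
                for age in cohorts:
                    for i in range(cfg.n_per_cell):
                        rows.append({
                            "sample_id": f"{line}_{sex[0]}_a{age:02d}_{split[:3]}_{i:03d}",
                            "line": line,
                            "species": cfg.species_of(line),
                            "sex": sex,
                            "age_days": int(age),
                            "infection": "unknown",
                            "split": split,
                        })
    return pd.DataFrame(rows)


def generate_population(cfg: SyntheticConfig | None = None,
                        seed: int = 0) -> SpectrumSet:
    """The species/gender/age population: calibration + independent splits.

    At the defaults: 4 lines x 2 sexes x 7 cohorts x 45 flies = 2520
    calibration spectra, plus 2 independent lines x 2 sexes x 3 cohorts x 45
    = 540 independent spectra, all on the 350–2500 nm grid.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)
    sset = _synthesize(cfg, _design_rows(cfg), rng)
    sset.meta.attrs["seed"] = int(seed)
    return sset


def generate_wolbachia_population(cfg: SyntheticConfig | None = None,
                                  seed: int = 0) -> SpectrumSet:
    """The Wolbachia population: infected/uninfected pairs scanned at 15 d.

    Two D. simulans lines, each with an infected and a tetracycline-cured
    counterpart; sexes alternate within each cell.  Defaults give 300
    calibration and 120 independent flies.
    """
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(seed)
    rows = []
    for split, n_cell in (("calibration", cfg.wol_n_cal),
                          ("independent", cfg.wol_n_indep)):
        for line in cfg.wol_lines:
            for infection in ("infected", "uninfected"):
                for i in range(n_cell):
                    sex = "male" if i % 2 == 0 else "female"
                    rows.append({
                        "sample_id": f"{line}_{infection[:3]}_{split[:3]}_{i:03d}",
                        "line": line,
                        "species": cfg.species_of(line),
                        "sex": sex,
                        "age_days": int(cfg.wol_age),
                        "infection": infection,
                        "split": split,
                    })
    sset = _synthesize(cfg, pd.DataFrame(rows), rng)
    sset.meta.attrs["seed"] = int(seed)
    return sset


# ---------------------------------------------------------------------------
# named fixtures for the test suite and demos

_FIXTURE_SEEDS = {"tiny": 101, "species_demo": 202, "age_demo": 303,
                  "wolbachia_demo": 404}


def make_fixture(name: str, outdir) -> tuple[str, str]:
    """Write a small named CSV fixture (spectra + metadata); deterministic.

    ``tiny`` — 12 spectra on a truncated 101-point grid, both splits.
    ``species_demo`` — well-separated two-species set (independent lines
    carry no idiosyncratic shift, tighter latent scatter) sized for fast
    end-to-end tests.  ``age_demo`` and ``wolbachia_demo`` are the
    corresponding small single-task sets at default noise.
    Returns (spectra_path, metadata_path).
    """
    if name not in _FIXTURE_SEEDS:
        raise ConfigError(f"unknown fixture {name!r}; "
                          f"choose from {sorted(_FIXTURE_SEEDS)}")
    seed = _FIXTURE_SEEDS[name]
    if name == "tiny":
        cfg = SyntheticConfig(
            grid_lo=350.0, grid_hi=450.0,
            bands=(BandSpec(400.0, 15.0, 0.08, species_coef=0.02,
                            sex_coef=0.01, age_coef=0.001),),
            noise_lo=350.0, noise_hi=450.0,
            n_per_cell=1, cal_cohorts=(5, 13), indep_cohorts=(13,),
            cal_lines=("Alst", "Hw"), indep_lines=("Alst", "Hw"),
        )
        sset = generate_population(cfg, seed)
    elif name == "species_demo":
        cfg = SyntheticConfig(
            n_per_cell=2, cal_cohorts=(5, 13, 21), indep_cohorts=(5, 13, 21),
            species_latent_sd=0.10, line_latent_shift=(), line_amp_mult=(),
        )
        sset = generate_population(cfg, seed)
    elif name == "age_demo":
        cfg = SyntheticConfig(
            n_per_cell=4,
            cal_lines=("Alst",), indep_lines=("Dah",),
        )
        sset = generate_population(cfg, seed).where(sex="female")
    else:  # wolbachia_demo
        cfg = SyntheticConfig(wol_n_cal=8, wol_n_indep=4)
        sset = generate_wolbachia_population(cfg, seed)

    os.makedirs(outdir, exist_ok=True)
    spectra_path = os.path.join(outdir, f"{name}_spectra.csv")
    meta_path = os.path.join(outdir, f"{name}_metadata.csv")
    write_spectra(sset, spectra_path)
    write_metadata(sset.meta, meta_path)
    return spectra_path, meta_path
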