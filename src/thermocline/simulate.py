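"""Synthetic field-study generator with known ground truth.

Every downstream stage — theta estimation, variance components, P_ST grids,
climate summaries, plasticity metrics — can be exercised against data whose
generating parameters are known exactly:

* genotypes from a Balding–Nichols island model around a target F_ST,
* phenotypes from a one-way random-effects model (sigma_b2 between
  populations, sigma_w2 within),
* pond logger series as seasonal + diel sinusoids plus Gaussian noise,
* acclimation experiments with a per-population true ARR slope.

A single global seed is expanded into per-generator child seeds with
``numpy.random.SeedSequence.spawn`` at fixed positions (genotypes 0,
traits 1, logger 2, acclimation 3), so adding a generator never perturbs
the streams of the others.

Defaults mirror the study conditions the package targets: 11 populations,
6 usable microsatellite loci, a global F_ST of 0.066, CTmax-like trait
variances, pond loggers sampling every 30 min, and acclimation treatments
at 6/13/20/27 degC.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .microclimate import LoggerSeries
from .popgen import GenotypeDataset, write_genepop

__all__ = [
    "LoggerParams",
    "SimulationConfig",
    "simulate_genotypes",
    "simulate_traits",
    "simulate_logger_series",
    "simulate_acclimation_experiment",
    "write_bundle",
]

_CHILD = {"genotypes": 0, "traits": 1, "logger": 2, "acclimation": 3}


@dataclass(frozen=True)
class LoggerParams:
    """Shape of the simulated pond temperature series.

    ``T(t) = mean + A_s sin(2 pi (doy - phase_s)/365)
            + A_d sin(2 pi (hour - phase_d)/24) + eps``.
    """

    mean_c: float = 12.0
    seasonal_amplitude_c: float = 6.0
    diel_amplitude_c: float = 3.0
    noise_sd_c: float = 0.5
    interval_minutes: int = 30
    start: str = "2013-03-01"
    n_days: int = 120
    seasonal_phase_day: float = 80.0
    diel_phase_hour: float = 9.0

    def validate(self) -> None:
        if not (1 <= self.interval_minutes <= 120):
            raise ValueError("sampling interval must be in [1, 120] minutes")
        if self.n_days < 2:
            raise ValueError("logger span must cover at least 2 days")
        if self.noise_sd_c < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters for one synthetic study.

    sigma_b2 / sigma_w2 are the between- and within-population trait
    variances (degC^2); target_fst parameterizes the Balding–Nichols
    island model; arr_true is the plasticity slope (degC tolerance per
    degC acclimation) per population, a scalar meaning "same everywhere".
    """

    n_populations: int = 11
    n_per_pop: int = 16
    n_loci: int = 6
    alleles_per_locus: int = 8
    target_fst: float = 0.066
    ancestral_freqs: tuple[tuple[float, ...], ...] | None = None
    sigma_b2: float = 0.06
    sigma_w2: float = 0.16
    grand_mean: float = 36.8
    trait: str = "CTmax"
    mass_meanlog: float = 5.7  # ~300 mg median tadpole mass
    mass_sdlog: float = 0.3
    mass_slope: float = 0.0  # degC per log-mg; 0 = mass independent of trait
    logger_params: LoggerParams = field(default_factory=LoggerParams)
    arr_true: float | tuple[float, ...] = 0.1
    acclimation_temps: tuple[float, ...] = (6.0, 13.0, 20.0, 27.0)
    reference_temp: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_fst < 1.0):
            raise ValueError("target_fst must be in [0, 1)")
        if self.sigma_b2 < 0 or self.sigma_w2 < 0:
            raise ValueError("variances must be >= 0")
        if self.alleles_per_locus < 2:
            raise ValueError("need >= 2 alleles per locus")
        if self.n_per_pop < 2:
            raise ValueError("need >= 2 individuals per population")
        if len(self.acclimation_temps) < 2:
            raise ValueError("need >= 2 acclimation temperatures")
        if self.ancestral_freqs is not None:
            if len(self.ancestral_freqs) != self.n_loci:
                raise ValueError("ancestral_freqs must give one vector per locus")
            for vec in self.ancestral_freqs:
                arr = np.asarray(vec, dtype=float)
                if arr.min() <= 0 or abs(arr.sum() - 1.0) > 1e-9:
                    raise ValueError("each ancestral frequency vector must be positive and sum to 1")
        self.logger_params.validate()

    def rng(self, component: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_CHILD))
        return np.random.default_rng(children[_CHILD[component]])

    def population_labels(self) -> list[str]:
        return [f"pop{i + 1:02d}" for i in range(self.n_populations)]

    def arr_per_pop(self) -> np.ndarray:
        if np.isscalar(self.arr_true):
            return np.full(self.n_populations, float(self.arr_true))
        arr = np.asarray(self.arr_true, dtype=float)
        if arr.shape != (self.n_populations,):
            raise ValueError("arr_true must be scalar or one value per population")
        return arr


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Draw an island-model genotype panel with expected F_ST = target_fst.

    Population allele-frequency vectors are Dirichlet with parameters
    ``p_a (1 - F) / F`` around the ancestral vector (Balding–Nichols);
    at F = 0 the ancestral frequencies are copied to every population.
    Genotypes are Hardy–Weinberg draws within populations.
    """
    rng = config.rng("genotypes")
    k = config.alleles_per_locus
    if config.ancestral_freqs is not None:
        ancestral = [np.asarray(v, dtype=float) for v in config.ancestral_freqs]
    else:
        # mildly uneven ancestral spectra, drawn once per locus
        ancestral = [rng.dirichlet(np.full(k, 5.0)) for _ in range(config.n_loci)]

    F = config.target_fst
    labels = config.population_labels()
    n = config.n_per_pop
    calls = np.zeros((config.n_populations * n, config.n_loci, 2), dtype=np.int64)
    for li, p_anc in enumerate(ancestral):
        for pi in range(config.n_populations):
            if F == 0.0:
                freqs = p_anc
            else:
                freqs = rng.dirichlet(p_anc * (1.0 - F) / F)
            block = rng.choice(len(freqs), size=(n, 2), p=freqs) + 1
            calls[pi * n : (pi + 1) * n, li, :] = block
    ids = [f"{lab}-{i + 1:03d}" for lab in labels for i in range(n)]
    return GenotypeDataset(
        populations=labels,
        loci=[f"locus{li + 1:02d}" for li in range(config.n_loci)],
        individual_ids=ids,
        pop_index=np.repeat(np.arange(config.n_populations), n),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------

def simulate_traits(config: SimulationConfig) -> pd.DataFrame:
    """One-way random-effects phenotypes as a TraitTable.

    Columns: individual_id, population, trait, value_c, mass_mg. Body mass
    is lognormal and independent of the trait unless ``mass_slope`` is set,
    in which case ``mass_slope * (log(mass) - meanlog)`` is added.
    """
    rng = config.rng("traits")
    labels = config.population_labels()
    pop_eff = rng.normal(0.0, np.sqrt(config.sigma_b2), size=config.n_populations)
    rows = []
    for pi, lab in enumerate(labels):
        resid = rng.normal(0.0, np.sqrt(config.sigma_w2), size=config.n_per_pop)
        logmass = rng.normal(config.mass_meanlog, config.mass_sdlog, size=config.n_per_pop)
        values = (
            config.grand_mean
            + pop_eff[pi]
            + resid
            + config.mass_slope * (logmass - config.mass_meanlog)
        )
        for i in range(config.n_per_pop):
            rows.append(
                {
                    "individual_id": f"{lab}-t{i + 1:03d}",
                    "population": lab,
                    "trait": config.trait,
                    "value_c": values[i],
                    "mass_mg": float(np.exp(logmass[i])),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logger series
# ---------------------------------------------------------------------------

def simulate_logger_series(config: SimulationConfig, population: str = "pop01") -> LoggerSeries:
    """Seasonal + diel sinusoid pond series at a fixed sampling interval."""
    p = config.logger_params
    p.validate()
    rng = config.rng("logger")
    start = pd.Timestamp(p.start)
    n = int(p.n_days * 24 * 60 / p.interval_minutes)
    times = start + pd.to_timedelta(np.arange(n) * p.interval_minutes, unit="m")
    doy = times.dayofyear.to_numpy(dtype=float)
    hour = times.hour.to_numpy(dtype=float) + times.minute.to_numpy(dtype=float) / 60.0
    temp = (
        p.mean_c
        + p.seasonal_amplitude_c * np.sin(2 * np.pi * (doy - p.seasonal_phase_day) / 365.0)
        + p.diel_amplitude_c * np.sin(2 * np.pi * (hour - p.diel_phase_hour) / 24.0)
    )
    if p.noise_sd_c > 0:
        temp = temp + rng.normal(0.0, p.noise_sd_c, size=n)
    frame = pd.DataFrame({"timestamp": times, "temp_c": temp})
    return LoggerSeries(population=population, frame=frame)


# ---------------------------------------------------------------------------
# acclimation experiment
# ---------------------------------------------------------------------------

def simulate_acclimation_experiment(
    config: SimulationConfig,
    group_sizes: Mapping[tuple[str, float], int] | None = None,
) -> pd.DataFrame:
    """Acclimation-treatment phenotypes with known per-population ARR.

    tolerance = pop intercept + arr_true[pop] * (T_acc - reference_temp)
    + N(0, sigma_w2). Returns a TraitTable with an ``acclimation_c``
    column; ``group_sizes`` maps (population, temperature) to n for
    unbalanced designs (default n_per_pop everywhere).
    """
    rng = config.rng("acclimation")
    labels = config.population_labels()
    arr = config.arr_per_pop()
    intercepts = config.grand_mean + rng.normal(
        0.0, np.sqrt(config.sigma_b2), size=config.n_populations
    )
    rows = []
    for pi, lab in enumerate(labels):
        for t_acc in config.acclimation_temps:
            n = config.n_per_pop if group_sizes is None else group_sizes.get((lab, t_acc), 0)
            noise = rng.normal(0.0, np.sqrt(config.sigma_w2), size=n)
            mu = intercepts[pi] + arr[pi] * (t_acc - config.reference_temp)
            logmass = rng.normal(config.mass_meanlog, config.mass_sdlog, size=n)
            for i in range(n):
                rows.append(
                    {
                        "individual_id": f"{lab}-a{t_acc:g}-{i + 1:03d}",
                        "population": lab,
                        "trait": config.trait,
                        "value_c": mu + noise[i],
                        "mass_mg": float(np.exp(logmass[i])),
                        "acclimation_c": float(t_acc),
                        "censored": False,
                    }
                )
    return pd.DataFrame(rows)


def write_bundle(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Materialize one synthetic study on disk (GENEPOP + CSVs).

    Returns a map of artifact name to path: genotypes, traits, acclimation,
    one logger CSV per population, phenology windows and a macro table
    consistent with the logger climate.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ds = simulate_genotypes(config)
    paths["genotypes"] = out / "genotypes.gen"
    write_genepop(ds, paths["genotypes"])

    # both limits, so the vulnerability stage has CTmax and CTmin means
    ctmax = simulate_traits(replace(config, trait="CTmax"))
    ctmin = simulate_traits(
        replace(config, trait="CTmin", grand_mean=-1.8, seed=config.seed + 7)
    )
    traits = pd.concat([ctmax, ctmin], ignore_index=True)
    paths["traits"] = out / "traits.csv"
    traits.to_csv(paths["traits"], index=False)

    acc = simulate_acclimation_experiment(config)
    paths["acclimation"] = out / "acclimation.csv"
    acc.to_csv(paths["acclimation"], index=False)

    loggers = out / "loggers"
    loggers.mkdir(exist_ok=True)
    windows = []
    macro_rows = []
    p = config.logger_params
    start = pd.Timestamp(p.start)
    end = start + pd.Timedelta(days=p.n_days - 1)
    for pi, lab in enumerate(config.population_labels()):
        # distinct noise stream per pond, still a pure function of the seed
        series = simulate_logger_series(
            replace(config, seed=config.seed + 101 * (pi + 1)), population=lab
        )
        lp = loggers / f"{lab}.csv"
        series.frame.to_csv(lp, index=False)
        paths[f"logger:{lab}"] = lp
        windows.append(
            {
                "population": lab,
                "start": f"{start.month:02d}-{start.day:02d}",
                "end": f"{end.month:02d}-{end.day:02d}",
            }
        )
        for month in range(1, 13):
            seasonal = p.seasonal_amplitude_c * np.sin(
                2 * np.pi * ((month - 0.5) * 30.4 - p.seasonal_phase_day) / 365.0
            )
            macro_rows.append(
                {
                    "population": lab,
                    "month": month,
                    "tmax_c": p.mean_c + seasonal + p.diel_amplitude_c,
                    "tmin_c": p.mean_c + seasonal - p.diel_amplitude_c,
                }
            )
    paths["phenology"] = out / "phenology.csv"
    pd.DataFrame(windows).to_csv(paths["phenology"], index=False)
    paths["macro"] = out / "macro.csv"
    pd.DataFrame(macro_rows).to_csv(paths["macro"], index=False)
    return paths
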