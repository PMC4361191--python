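"""Synthetic stream-mesocosm experiments and gradient-survey site tables.

The generator emulates the data structures the diagnosis pipeline assumes:

* a balanced 2x2 nutrient x sediment factorial of flow-through stream
  channels (16 replicates per combination over 2 years = 64 records at
  defaults), with shade-cloth over half the channels in each year, and 11
  nonnegative biological responses (benthic chlorophyll *a*, familial
  richness, total abundance, and 8 taxon abundances) under multiplicative
  lognormal noise;
* a 27-site river survey spanning a catchment-grazing gradient (0–80 % of
  upstream area) in which a latent fine-sediment stress level increases with
  grazing while the latent nutrient level, by default, does not.

Treatment responses are multiplicative: the expected value of variable *v*
in a channel is ``control_mean[v] * nutrient_effect[v]**(N-1) *
sediment_effect[v]**(S-1) * light_effect[v]**(L-1)`` with levels N, S, L in
{1, 2} (1 = low/ambient). Survey sites evaluate the same response surface at
fractional latent levels in [1, 2], so the field data stay inside the domain
the mesocosm contrast spans. Default effect sizes are chosen so that only
chlorophyll *a* (nutrients) and Orthocladiinae midges (fine sediments) carry
clearly significant two-way-ANOVA effects at 16 replicates; the remaining
responses carry weak signal typical of noisy community data.

The lognormal noise is parameterised by its coefficient of variation and has
unit mean, so control-cell sample means converge to the configured control
means. All randomness flows from the config seed; fixed seed means
bit-identical tables.
"""

from __future__ import annotations

import functools
import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError

__all__ = [
    "RESPONSE_NAMES",
    "MesocosmConfig",
    "SurveyConfig",
    "generate_mesocosm",
    "generate_survey",
    "write_mesocosm_csv",
    "write_survey_csv",
    "write_truth_csv",
    "load_defaults",
]

#: Canonical order of the 11 biological response variables. This order is
#: also the tie-break order everywhere a deterministic variable order is
#: needed (input screening, priority ranking).
RESPONSE_NAMES: tuple[str, ...] = (
    "chlorophyll_a",
    "familial_richness",
    "total_abundance",
    "Oligochaeta",
    "Leptoperla_varia",
    "Nousia",
    "Austrophlebioides",
    "Orthocladiinae",
    "Tanypodinae",
    "Tipulidae",
    "Scirtidae_larvae",
)


@functools.cache
def load_defaults() -> dict:
    """Load the checked-in default study conditions (defaults.yaml)."""
    text = importlib.resources.files("streamdiag").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


def _full_effect_map(partial: dict[str, float] | None, names: tuple[str, ...]) -> dict[str, float]:
    out = {v: 1.0 for v in names}
    if partial:
        unknown = set(partial) - set(names)
        if unknown:
            raise ConfigError(f"effect map references unknown variables: {sorted(unknown)}")
        out.update({k: float(v) for k, v in partial.items()})
    return out


@dataclass(frozen=True)
class MesocosmConfig:
    """Conditions of one synthetic mesocosm experiment."""

    control_means: dict[str, float]
    nutrient_effect: dict[str, float]
    sediment_effect: dict[str, float]
    light_effect: dict[str, float]
    year_effect: dict[str, float] = field(default_factory=dict)
    n_per_combination: int = 16
    years: int = 2
    response_names: tuple[str, ...] = RESPONSE_NAMES
    noise_cv: float = 0.35
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "MesocosmConfig":
        d = load_defaults()["mesocosm"]
        cfg = cls(
            control_means=dict(d["control_means"]),
            nutrient_effect=_full_effect_map(d.get("nutrient_effect"), RESPONSE_NAMES),
            sediment_effect=_full_effect_map(d.get("sediment_effect"), RESPONSE_NAMES),
            light_effect=_full_effect_map(d.get("light_effect"), RESPONSE_NAMES),
            year_effect=_full_effect_map(d.get("year_effect"), RESPONSE_NAMES),
            n_per_combination=int(d["n_per_combination"]),
            years=int(d["years"]),
            noise_cv=float(d["noise_cv"]),
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    def validate(self) -> None:
        names = tuple(self.response_names)
        if len(names) == 0:
            raise ConfigError("response_names must be non-empty")
        if set(self.control_means) != set(names):
            raise ConfigError("control_means must cover exactly the response names")
        for v, m in self.control_means.items():
            if not m > 0:
                raise ConfigError(f"control mean for {v!r} must be positive, got {m}")
        for label, eff in (
            ("nutrient_effect", self.nutrient_effect),
            ("sediment_effect", self.sediment_effect),
        ):
            for v, e in eff.items():
                if e < 0:
                    raise ConfigError(f"{label}[{v!r}] must be >= 0, got {e}")
        if self.n_per_combination < 1 or self.years < 1:
            raise ConfigError("counts must be positive")
        if self.n_per_combination % (self.years * 2) != 0:
            raise ConfigError(
                "n_per_combination must be divisible by years x 2 light levels "
                f"({self.years * 2}), got {self.n_per_combination}"
            )
        if self.noise_cv < 0:
            raise ConfigError("noise_cv must be nonnegative")


def _lognormal_noise(rng: np.random.Generator, cv: float, shape: tuple[int, ...]) -> np.ndarray:
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = np.log1p(cv * cv)
    sigma = np.sqrt(sigma2)
    return np.exp(rng.normal(0.0, 1.0, shape) * sigma - sigma2 / 2.0)


def _expected_response(
    config: MesocosmConfig,
    nutrient: np.ndarray,
    sediment: np.ndarray,
    light: np.ndarray,
    year: np.ndarray | None = None,
) -> np.ndarray:
    """Noise-free response surface, rows = records, columns = variables.

    Levels may be fractional (latent survey stress); exponents are level - 1.
    """
    cols = []
    for v in config.response_names:
        mean = (
            config.control_means[v]
            * config.nutrient_effect.get(v, 1.0) ** (nutrient - 1.0)
            * config.sediment_effect.get(v, 1.0) ** (sediment - 1.0)
            * config.light_effect.get(v, 1.0) ** (light - 1.0)
        )
        if year is not None:
            mean = mean * config.year_effect.get(v, 1.0) ** (year - 1.0)
        cols.append(mean)
    return np.column_stack(cols)


def generate_mesocosm(config: MesocosmConfig) -> pd.DataFrame:
    """Simulate one balanced mesocosm experiment.

    Returns a table with one row per channel: ``record_id``, ``year``,
    ``nutrient_level``, ``sediment_level``, ``light_level`` and the 11
    response columns. All responses are nonnegative; fixed seed gives
    bit-identical output.
    """
    config.validate()
    per_year = config.n_per_combination // config.years
    per_light = per_year // 2
    rows = []
    for nutrient in (1, 2):
        for sediment in (1, 2):
            for year in range(1, config.years + 1):
                for light in (1, 2):
                    rows.extend([(year, nutrient, sediment, light)] * per_light)
    design = pd.DataFrame(rows, columns=["year", "nutrient_level", "sediment_level", "light_level"])
    design.insert(0, "record_id", np.arange(1, len(design) + 1))

    rng = np.random.default_rng(config.seed)
    mean = _expected_response(
        config,
        design["nutrient_level"].to_numpy(float),
        design["sediment_level"].to_numpy(float),
        design["light_level"].to_numpy(float),
        design["year"].to_numpy(float),
    )
    values = mean * _lognormal_noise(rng, config.noise_cv, mean.shape)
    for j, v in enumerate(config.response_names):
        design[v] = values[:, j]
    return design


@dataclass(frozen=True)
class SurveyConfig:
    """Conditions of the synthetic gradient survey.

    ``sediment_coupling`` (and analogously ``nutrient_coupling``) sets how
    steeply the latent stress level rises with the grazing proportion:
    ``latent = 1 + coupling * grazing + N(0, latent_noise_sd)`` clipped to
    [1, 2]. Coupling 0 is the null model (no land-use pathway).
    """

    n_sites: int = 27
    grazing_range: tuple[float, float] = (0.0, 0.8)
    sediment_coupling: float = 0.9
    nutrient_coupling: float = 0.0
    latent_noise_sd: float = 0.05
    site_noise_cv: float = 0.35
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, **overrides) -> "SurveyConfig":
        d = load_defaults()["survey"]
        cfg = cls(
            n_sites=int(d["n_sites"]),
            grazing_range=tuple(float(x) for x in d["grazing_range"]),
            sediment_coupling=float(d["sediment_coupling"]),
            nutrient_coupling=float(d["nutrient_coupling"]),
            latent_noise_sd=float(d["latent_noise_sd"]),
            site_noise_cv=float(d["site_noise_cv"]),
            seed=seed,
        )
        return replace(cfg, **overrides) if overrides else cfg

    def validate(self) -> None:
        if self.n_sites < 3:
            raise ConfigError("need at least 3 survey sites for a regression")
        lo, hi = self.grazing_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ConfigError(f"grazing_range must be within [0, 1], got {self.grazing_range}")
        if lo >= 0.0095:
            raise ConfigError(
                "grazing_range must start below 1% so that at least two "
                "field control sites (<1% grazing) exist"
            )
        if self.latent_noise_sd < 0 or self.site_noise_cv < 0:
            raise ConfigError("noise parameters must be nonnegative")


def _grazing_gradient(config: SurveyConfig) -> np.ndarray:
    """Deterministic site gradient: two <1%-grazing control sites plus an
    even spread over the full range (endpoints included)."""
    lo, hi = config.grazing_range
    controls = np.array([lo, min(lo + 0.005, 0.0094)])
    spread = np.linspace(lo, hi, config.n_sites - 2)
    return np.concatenate([controls, spread])


def generate_survey(
    config: SurveyConfig, mesocosm_config: MesocosmConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the gradient survey.

    Returns ``(survey, truth)``. ``survey`` has one row per site: site_id,
    grazing_proportion, the 11 responses generated from the mesocosm
    response surface evaluated at the site's latent stress levels, and
    order-level counts (``ept_count``, ``non_ept_count``) for %EPT. The
    community degrades with latent sediment stress: the EPT fraction falls
    from about one half at unstressed sites toward about one fifth at full
    stress. ``truth`` is the hidden-state side table (latent levels) kept
    for parameter-recovery tests, never consumed by the pipeline.
    """
    config.validate()
    mesocosm_config.validate()
    n = config.n_sites
    rng = np.random.default_rng(config.seed)

    grazing = _grazing_gradient(config)
    latent_sed = np.clip(
        1.0 + config.sediment_coupling * grazing + rng.normal(0.0, config.latent_noise_sd, n),
        1.0,
        2.0,
    )
    latent_nut = np.clip(
        1.0 + config.nutrient_coupling * grazing + rng.normal(0.0, config.latent_noise_sd, n),
        1.0,
        2.0,
    )

    mean = _expected_response(
        mesocosm_config, latent_nut, latent_sed, np.ones(n)
    )
    values = mean * _lognormal_noise(rng, config.site_noise_cv, mean.shape)

    ept_frac = np.clip(
        0.5 - 0.38 * (latent_sed - 1.0) + rng.normal(0.0, 0.04, n), 0.05, 0.95
    )
    totals = rng.poisson(600, n) + 1
    ept = rng.binomial(totals, ept_frac)

    site_ids = [f"S{i + 1:02d}" for i in range(n)]
    survey = pd.DataFrame({"site_id": site_ids, "grazing_proportion": grazing})
    for j, v in enumerate(mesocosm_config.response_names):
        survey[v] = values[:, j]
    survey["ept_count"] = ept
    survey["non_ept_count"] = totals - ept

    truth = pd.DataFrame(
        {"site_id": site_ids, "latent_sediment": latent_sed, "latent_nutrient": latent_nut}
    )
    return survey, truth


def write_mesocosm_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_survey_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def write_truth_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)
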