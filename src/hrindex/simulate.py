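"""Seeded synthetic study-level cohorts.

The source studies publish only group means, so the per-point heart-rate
and VO2 values behind the pooled comparisons are unavailable. This module
generates aggregate cohorts with the statistical structure the analysis
assumes, making every pipeline stage testable end to end:

* true fitness ``METs_i ~ Normal(mets_mean, mets_sd)``, truncated at >= 1.5;
* resting HR ``~ Normal(hr_rest_mean, hr_rest_sd)``, truncated at >= 40;
* the heart-rate index consistent with the surrogate model plus relative
  noise, ``HRI_i = ((METs_i + 5)/6) * (1 + eps_i)``; maximal HR is derived
  as ``hr_rest_i * HRI_i`` so the cohort is consistent-by-construction
  with the surrogate — misspecification enters only through the noise and
  bias terms;
* the treadmill arm value: measured cohorts report ``METs_i * (1 + delta_i)``;
  predicted cohorts additionally carry a systematic over-prediction factor
  ``(1 + b_i)``, uniform or graded by fitness tertile (handrail support
  inflates predictions most in the least fit).

Noise is multiplicative (relative): reported aggregate SDs scale with
means across fitness tertiles, which additive noise would not reproduce.
A single root seed feeds one independent substream per variable, so adding
a variable never shifts existing draws and identical configs yield
identical cohorts.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .records import Arm, RailSupport, StudyRecord, Vo2Source, write_records
from .stats import assign_tertiles

__all__ = [
    "SyntheticConfig", "measured_arm_config", "predicted_arm_config",
    "generate_cohort", "make_fixture_suite", "FIXTURE_SEEDS",
]

#: Fitness-tertile over-prediction gradient (fractions, tertile 1 = least
#: fit) mirroring the pattern reported for equation-predicted cohorts.
DEFAULT_GRADIENT: tuple[float, float, float] = (0.312, 0.296, 0.091)

_MAX_REDRAWS = 1000


@dataclass(frozen=True)
class SyntheticConfig:
    """All parameters needed to reproduce one synthetic cohort.

    Defaults describe a predicted-arm cohort: 57 data points, true fitness
    6.71 ± 1.92 METs, resting HR 75.6 ± 5.3 beats·min⁻¹, a 21.1%
    over-prediction bias, and 5% relative noise on both the heart-rate
    index and the treadmill value. Study sizes are drawn log-uniformly
    over the observed range of large treadmill studies.
    """

    n_points: int = 57
    arm: Arm = Arm.PREDICTED
    mets_mean: float = 6.71
    mets_sd: float = 1.92
    hr_rest_mean: float = 75.6
    hr_rest_sd: float = 5.3
    hri_noise_sd: float = 0.05
    vo2_noise_sd: float = 0.05
    overprediction_bias: float = 0.211
    tertile_bias_gradient: tuple[float, float, float] | None = None
    n_range: tuple[int, int] = (110, 22275)
    seed: int = 0
    mets_floor: float = 1.5
    hr_rest_floor: float = 40.0

    def __post_init__(self) -> None:
        def bad(f: str, msg: str) -> ConfigError:
            return ConfigError(f"invalid SyntheticConfig.{f}: {msg}", field=f)

        if self.n_points < 1:
            raise bad("n_points", f"must be >= 1, got {self.n_points}")
        for f in ("mets_sd", "hr_rest_sd", "hri_noise_sd", "vo2_noise_sd"):
            if getattr(self, f) < 0:
                raise bad(f, f"must be >= 0, got {getattr(self, f)}")
        if not self.mets_mean > 1:
            raise bad("mets_mean", f"must exceed 1 MET, got {self.mets_mean}")
        if self.overprediction_bias < 0:
            raise bad("overprediction_bias",
                      f"must be >= 0, got {self.overprediction_bias}")
        g = self.tertile_bias_gradient
        if g is not None and (len(g) != 3 or any(b < 0 for b in g)):
            raise bad("tertile_bias_gradient",
                      f"must be 3 nonnegative fractions, got {g!r}")
        lo, hi = self.n_range
        if not 1 <= lo <= hi:
            raise bad("n_range", f"must satisfy 1 <= lo <= hi, got {self.n_range}")


def measured_arm_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Config emulating a measured-VO2 cohort: 45 data points, true
    fitness 6.54 ± 2.28 METs, resting HR 77.6 ± 7.7, no systematic bias."""
    base = SyntheticConfig(
        n_points=45, arm=Arm.MEASURED, mets_mean=6.54, mets_sd=2.28,
        hr_rest_mean=77.6, hr_rest_sd=7.7, overprediction_bias=0.0, seed=seed,
    )
    return replace(base, **overrides)


def predicted_arm_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """Config emulating an equation-predicted cohort: 57 data points with
    a 21.1% over-prediction bias (the package default)."""
    return replace(SyntheticConfig(seed=seed), **overrides)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      low: float, size: int) -> np.ndarray:
    """Draw Normal(mean, sd) truncated below at ``low`` by redrawing."""
    if sd == 0.0:
        if mean < low:
            raise ConfigError(f"degenerate draw: constant {mean} below floor {low}")
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    for _ in range(_MAX_REDRAWS):
        mask = out < low
        if not mask.any():
            return out
        out[mask] = rng.normal(mean, sd, int(mask.sum()))
    raise ConfigError(f"truncation at {low} rejected too many draws "
                      f"(mean={mean}, sd={sd})")


def generate_cohort(config: SyntheticConfig) -> list[StudyRecord]:
    """Generate one cohort of aggregate study records.

    Deterministic: identical configs (including seed) yield identical
    records. Every emitted record satisfies the StudyRecord invariants;
    draws producing physiologically impossible values (heart-rate index
    at or below 1, maximal HR at or above 250, nonpositive VO2) are
    redrawn from their own substreams.
    """
    ss = np.random.SeedSequence(config.seed)
    streams = {name: np.random.default_rng(child) for name, child in
               zip(("mets", "hr_rest", "hri_noise", "vo2_noise", "n_subjects"),
                   ss.spawn(5))}
    m = config.n_points

    mets = _truncated_normal(streams["mets"], config.mets_mean,
                             config.mets_sd, config.mets_floor, m)
    hr_rest = _truncated_normal(streams["hr_rest"], config.hr_rest_mean,
                                config.hr_rest_sd, config.hr_rest_floor, m)

    hri_base = (mets + 5.0) / 6.0
    eps = (streams["hri_noise"].normal(0.0, config.hri_noise_sd, m)
           if config.hri_noise_sd > 0 else np.zeros(m))
    hri = hri_base * (1.0 + eps)
    # keep activity strictly above rest: redraw noise where HRI <= 1
    if config.hri_noise_sd > 0:
        for _ in range(_MAX_REDRAWS):
            mask = hri <= 1.0
            if not mask.any():
                break
            eps[mask] = streams["hri_noise"].normal(
                0.0, config.hri_noise_sd, int(mask.sum()))
            hri = hri_base * (1.0 + eps)
        else:
            raise ConfigError("hri_noise_sd too large: cannot keep HRI above 1")

    hr_max = hr_rest * hri
    # physiological ceiling: redraw resting HR where derived max reaches 250
    for _ in range(_MAX_REDRAWS):
        mask = hr_max >= 250.0
        if not mask.any():
            break
        hr_rest[mask] = _truncated_normal(
            streams["hr_rest"], config.hr_rest_mean, config.hr_rest_sd,
            config.hr_rest_floor, int(mask.sum()))
        hr_max = hr_rest * hri
    else:
        raise ConfigError("cannot satisfy hr_max < 250 under this config")

    delta = (streams["vo2_noise"].normal(0.0, config.vo2_noise_sd, m)
             if config.vo2_noise_sd > 0 else np.zeros(m))
    for _ in range(_MAX_REDRAWS):
        mask = delta <= -1.0
        if not mask.any():
            break
        delta[mask] = streams["vo2_noise"].normal(
            0.0, config.vo2_noise_sd, int(mask.sum()))
    else:  # pragma: no cover - requires extreme noise SDs
        raise ConfigError("vo2_noise_sd too large: cannot keep VO2 positive")

    if config.arm is Arm.MEASURED:
        bias = np.zeros(m)
        source = Vo2Source.MEASURED
    else:
        source = Vo2Source.EQUATION
        if config.tertile_bias_gradient is not None and m >= 3:
            grad = np.asarray(config.tertile_bias_gradient, dtype=float)
            bias = grad[assign_tertiles(mets) - 1]
        else:
            bias = np.full(m, config.overprediction_bias)
    vo2 = mets * (1.0 + bias) * (1.0 + delta)

    lo, hi = config.n_range
    n_subj = np.exp(streams["n_subjects"].uniform(np.log(lo), np.log(hi), m))
    n_subj = np.clip(np.rint(n_subj).astype(int), lo, hi)

    width = max(3, len(str(m)))
    return [
        StudyRecord(
            study_id=f"syn{i:0{width}d}",
            first_author="Synthetic",
            year=2016,
            arm=config.arm,
            n=int(n_subj[i]),
            age_mean=55.0,
            male_pct=70.0,
            category="SYN",
            protocol="ramp",
            rail_support=RailSupport.NOT_STATED,
            hr_rest=float(hr_rest[i]),
            hr_max=float(hr_max[i]),
            vo2peak=float(vo2[i]),
            vo2_source=source,
        )
        for i in range(m)
    ]


#: Fixed seeds of the fixture suite, keyed by fixture name.
FIXTURE_SEEDS: dict[str, int] = {
    "null": 101,
    "biased_uniform": 202,
    "biased_gradient": 303,
    "degenerate_small": 404,
}


def fixture_configs() -> dict[str, SyntheticConfig]:
    """The four seeded configurations making up the fixture suite."""
    return {
        "null": measured_arm_config(seed=FIXTURE_SEEDS["null"]),
        "biased_uniform": predicted_arm_config(seed=FIXTURE_SEEDS["biased_uniform"]),
        "biased_gradient": predicted_arm_config(
            seed=FIXTURE_SEEDS["biased_gradient"],
            tertile_bias_gradient=DEFAULT_GRADIENT),
        "degenerate_small": measured_arm_config(
            seed=FIXTURE_SEEDS["degenerate_small"], n_points=2,
            mets_sd=0.0, hr_rest_sd=0.0, hri_noise_sd=0.0, vo2_noise_sd=0.0),
    }


def make_fixture_suite(out_dir: str | Path) -> dict[str, Path]:
    """Write the fixed seeded fixture cohorts plus the packaged study table.

    Produces ``null.csv`` (measured arm, no bias), ``biased_uniform.csv``
    (predicted arm, uniform 21.1% bias), ``biased_gradient.csv``
    (tertile-graded bias), ``degenerate_small.csv`` (two identical
    noise-free records) and a copy of ``table1.csv``. Regenerating into
    the same directory yields byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, config in fixture_configs().items():
        path = out / f"{name}.csv"
        write_records(generate_cohort(config), path)
        written[name] = path
    table1 = out / "table1.csv"
    with resources.as_file(resources.files("hrindex.data") / "table1.csv") as src:
        shutil.copyfile(src, table1)
    written["table1"] = table1
    return written
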