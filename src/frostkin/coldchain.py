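"""Cold-chain scenarios: stage durations plus temperature distributions.

A distribution scenario is an ordered sequence of stages (e.g. 60 days
in a distribution warehouse, 40 days on retail display, 30 days in a
domestic freezer), each with a temperature distribution describing the
variability recorded in cold-chain field surveys.  The packaged default
stage distributions are synthetic truncated-normal emulations of such
survey data — broad and occasionally abusive at the domestic stage,
which field studies identify as the weakest link of the chain.

Temperatures here are in °C at every interface; Kelvin conversion
happens when a realized :class:`~frostkin.kinetics.TemperatureProfile`
is built.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import yaml
from scipy import stats

from .errors import InvalidInputError
from .kinetics import TemperatureProfile

__all__ = [
    "TemperatureDistribution",
    "TruncatedNormal",
    "HistogramDistribution",
    "ColdChainStage",
    "ColdChainScenario",
    "sample_temperature",
    "realize_profile",
    "mean_profile",
    "case_study_scenario",
    "load_scenario",
    "save_scenario",
]


class TemperatureDistribution:
    """Base class for per-stage temperature laws (all values in °C)."""

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        raise NotImplementedError

    def mean(self) -> float:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    @staticmethod
    def from_dict(d: dict) -> "TemperatureDistribution":
        form = d["form"]
        if form == "truncated-normal":
            return TruncatedNormal(d["mean_C"], d["sd_C"], d["lower_C"], d["upper_C"])
        if form == "histogram":
            return HistogramDistribution(d["bin_edges_C"], d["probabilities"])
        raise InvalidInputError(f"unknown distribution form {form!r}")


@dataclass(frozen=True)
class TruncatedNormal(TemperatureDistribution):
    """Normal(mean, sd) truncated to [lower, upper], sampled by inverse CDF."""

    mean_C: float
    sd_C: float
    lower_C: float
    upper_C: float

    def __post_init__(self):
        if not (self.sd_C > 0):
            raise InvalidInputError(f"sd must be > 0, got {self.sd_C}")
        if not (self.lower_C < self.upper_C):
            raise InvalidInputError("lower bound must be below upper bound")

    def _frozen(self):
        a = (self.lower_C - self.mean_C) / self.sd_C
        b = (self.upper_C - self.mean_C) / self.sd_C
        return stats.truncnorm(a, b, loc=self.mean_C, scale=self.sd_C)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        u = rng.random(size)
        draw = self._frozen().ppf(u)
        return float(draw) if size is None else draw

    def mean(self) -> float:
        return float(self._frozen().mean())

    def narrowed(self, sd_scale: float, mean_shift: float = 0.0) -> "TruncatedNormal":
        """Convenience for what-if analyses: rescale sd and shift the mean."""
        return TruncatedNormal(
            self.mean_C + mean_shift, self.sd_C * sd_scale, self.lower_C, self.upper_C
        )

    def to_dict(self) -> dict:
        return {
            "form": "truncated-normal",
            "mean_C": self.mean_C,
            "sd_C": self.sd_C,
            "lower_C": self.lower_C,
            "upper_C": self.upper_C,
        }


@dataclass(frozen=True)
class HistogramDistribution(TemperatureDistribution):
    """Binned empirical law: bin chosen by probability, uniform within bin."""

    bin_edges_C: tuple[float, ...]
    probabilities: tuple[float, ...]

    def __post_init__(self):
        edges = tuple(float(e) for e in self.bin_edges_C)
        probs = tuple(float(p) for p in self.probabilities)
        if len(edges) != len(probs) + 1:
            raise InvalidInputError("need len(bin_edges) = len(probabilities) + 1")
        if np.any(np.diff(edges) <= 0):
            raise InvalidInputError("bin edges must be strictly increasing")
        if np.any(np.asarray(probs) < 0) or abs(sum(probs) - 1.0) > 1e-12:
            raise InvalidInputError("probabilities must be nonnegative and sum to 1")
        object.__setattr__(self, "bin_edges_C", edges)
        object.__setattr__(self, "probabilities", probs)

    def sample(self, rng: np.random.Generator, size: Optional[int] = None):
        n = 1 if size is None else size
        edges = np.asarray(self.bin_edges_C)
        cum = np.cumsum(self.probabilities)
        idx = np.searchsorted(cum, rng.random(n), side="right")
        idx = np.minimum(idx, len(self.probabilities) - 1)
        lo, hi = edges[idx], edges[idx + 1]
        draw = lo + rng.random(n) * (hi - lo)
        return float(draw[0]) if size is None else draw

    def mean(self) -> float:
        centers = 0.5 * (np.asarray(self.bin_edges_C[:-1]) + np.asarray(self.bin_edges_C[1:]))
        return float(np.dot(centers, self.probabilities))

    def to_dict(self) -> dict:
        return {
            "form": "histogram",
            "bin_edges_C": list(self.bin_edges_C),
            "probabilities": list(self.probabilities),
        }


def sample_temperature(dist: TemperatureDistribution, rng: np.random.Generator) -> float:
    """One temperature draw (°C) from a stage distribution."""
    return dist.sample(rng)


@dataclass(frozen=True)
class ColdChainStage:
    """One stage of the chain: a label, a duration and a temperature law.

    ``resample_interval`` controls how often the temperature is redrawn
    within the stage; the default (None) means a single draw held for the
    whole stage duration.
    """

    name: str
    duration_days: float
    distribution: TemperatureDistribution
    resample_interval: Optional[float] = None

    def __post_init__(self):
        if not (self.duration_days > 0):
            raise InvalidInputError(f"stage duration must be > 0 d, got {self.duration_days}")
        if self.resample_interval is not None:
            if not (0 < self.resample_interval <= self.duration_days):
                raise InvalidInputError("resample_interval must lie in (0, duration]")

    def chunk_durations(self) -> np.ndarray:
        """Durations of the within-stage constant-temperature chunks."""
        if self.resample_interval is None:
            return np.array([self.duration_days])
        n_full = int(np.floor(self.duration_days / self.resample_interval - 1e-12))
        rem = self.duration_days - n_full * self.resample_interval
        chunks = [self.resample_interval] * n_full
        if rem > 1e-12:
            chunks.append(rem)
        return np.array(chunks)


@dataclass(frozen=True)
class ColdChainScenario:
    """Ordered stages of a distribution scenario."""

    stages: tuple[ColdChainStage, ...]

    def __post_init__(self):
        if len(self.stages) == 0:
            raise InvalidInputError("scenario must contain at least one stage")

    @property
    def total_duration(self) -> float:
        return float(sum(s.duration_days for s in self.stages))

    def replace_stage(self, name: str, distribution: TemperatureDistribution) -> "ColdChainScenario":
        if name not in {s.name for s in self.stages}:
            raise InvalidInputError(f"no stage named {name!r}")
        return ColdChainScenario(
            tuple(
                ColdChainStage(s.name, s.duration_days, distribution, s.resample_interval)
                if s.name == name
                else s
                for s in self.stages
            )
        )

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "name": s.name,
                    "duration_days": s.duration_days,
                    "distribution": s.distribution.to_dict(),
                    **(
                        {"resample_interval_days": s.resample_interval}
                        if s.resample_interval is not None
                        else {}
                    ),
                }
                for s in self.stages
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ColdChainScenario":
        stages = tuple(
            ColdChainStage(
                name=s["name"],
                duration_days=float(s["duration_days"]),
                distribution=TemperatureDistribution.from_dict(s["distribution"]),
                resample_interval=s.get("resample_interval_days"),
            )
            for s in d["stages"]
        )
        return cls(stages)


def realize_profile(scenario: ColdChainScenario, rng: np.random.Generator) -> TemperatureProfile:
    """Draw one stochastic temperature history for the scenario.

    One temperature draw per within-stage chunk (one per stage by
    default); the total duration is preserved exactly.
    """
    steps = []
    for stage in scenario.stages:
        for dur in stage.chunk_durations():
            steps.append((float(dur), stage.distribution.sample(rng)))
    return TemperatureProfile.from_celsius_steps(steps)


def mean_profile(scenario: ColdChainScenario) -> TemperatureProfile:
    """Deterministic profile holding each stage at its distribution mean."""
    return TemperatureProfile.from_celsius_steps(
        [(s.duration_days, s.distribution.mean()) for s in scenario.stages]
    )


def case_study_scenario() -> ColdChainScenario:
    """The packaged 130-day frozen-peas scenario: 60 d warehouse, 40 d
    retail, 30 d domestic freezer.

    Stage temperature laws are synthetic truncated-normal emulations of
    cold-chain survey histograms (the underlying survey data are not
    public as numbers); the domestic stage is the broadest and warmest.
    """
    return ColdChainScenario(
        (
            ColdChainStage("warehouse", 60.0, TruncatedNormal(-22.0, 2.0, -30.0, -12.0)),
            ColdChainStage("retail", 40.0, TruncatedNormal(-18.0, 3.5, -30.0, -5.0)),
            ColdChainStage("domestic", 30.0, TruncatedNormal(-15.0, 4.5, -30.0, -2.0)),
        )
    )


def load_scenario(path: Union[str, Path]) -> ColdChainScenario:
    """Read a scenario from a YAML or JSON config file."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    return ColdChainScenario.from_dict(data)


def save_scenario(scenario: ColdChainScenario, path: Union[str, Path]) -> None:
    """Write a scenario config as YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    d = scenario.to_dict()
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
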