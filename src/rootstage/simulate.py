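"""Synthetic stage-progression data emulating the two lateral-root assays.

The generator treats LRP development as a linear continuous-time Markov chain
over the stage ontology I → II → … → VII → E, with independent stage dwell
times.  Dwell time in stage *s* is Exponential with per-hour exit rate
``stage_rates[s] × multiplier(genotype)`` (or Erlang-k with the same mean for
less dispersed timing); ``E`` (emerged) is absorbing.  A single per-genotype
rate multiplier encodes overall faster (> 1) or slower (< 1) initiation and
progression — the qualitative signature distinguishing loss-of-function
mutants from overexpressors in stage-distribution assays.

Two experimental designs are emulated:

* the gravistimulated induction assay (:func:`simulate_induced`): each
  seedling initiates a single LRP after an exponential lag and its stage is
  scored at fixed observation times (18 h and 42 h by default);
* the whole-root survey (:func:`simulate_whole_root`): each root carries a
  Poisson number of LRPs of uniformly distributed ages, yielding per-root
  stage counts, emerged-LR counts and positions for density metrics.

Everything is reproducible bit-for-bit from ``(scenario, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import yaml

from .data_model import (
    NONE_STAGE,
    STAGES,
    InducedLRPRecord,
    RootObservation,
    StageCountVector,
    ValidationError,
)

__all__ = [
    "ProgressionScenario",
    "SimulatedDataset",
    "DEFAULT_SCENARIO",
    "simulate_induced",
    "simulate_whole_root",
    "simulate_dataset",
]

_N_TRANSIENT = 7  # stages I..VII; the 7 exit rates lead to absorption at E


@dataclass(frozen=True)
class ProgressionScenario:
    """Parameterization of the stage-progression simulator.

    Parameters
    ----------
    stage_rates
        Seven per-hour exit rates for transitions I→II … VII→E, before
        genotype scaling.
    genotype_multipliers
        Per-genotype scaling of all stage exit rates; 1.0 is the wild-type
        baseline, > 1 faster progression, < 1 slower.
    initiation_intensity
        Expected LRP initiations per cm of primary root (whole-root survey).
    pr_length_mean_cm, pr_length_sd_cm
        Primary-root length distribution (Normal truncated at 0).
    initiation_lag_h_mean
        Mean exponential delay from gravistimulus to the first pericycle
        division in the induced assay; 0 means immediate initiation.
    observation_times_h
        Times after gravistimulation at which induced LRPs are scored.
    root_age_h
        Age horizon of the whole-root LRP population: each primordium's age
        is Uniform(0, root_age_h), approximating steady ongoing initiation
        along a growing root.
    n_roots
        Seedlings per genotype (both assay designs).
    erlang_k
        Dwell-time shape: 1 = exponential; k > 1 = Erlang-k with the same
        mean, giving less dispersed stage timing.
    """

    stage_rates: tuple[float, ...] = (0.13,) * _N_TRANSIENT
    genotype_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"Col0": 1.0, "myb93": 1.5, "MYB93oe": 0.67}
    )
    initiation_intensity: float = 3.0
    pr_length_mean_cm: float = 6.0
    pr_length_sd_cm: float = 1.0
    initiation_lag_h_mean: float = 2.0
    observation_times_h: tuple[float, ...] = (18.0, 42.0)
    root_age_h: float = 96.0
    n_roots: int = 30
    erlang_k: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "stage_rates", tuple(float(r) for r in self.stage_rates))
        object.__setattr__(
            self, "observation_times_h", tuple(float(t) for t in self.observation_times_h)
        )
        object.__setattr__(self, "genotype_multipliers", dict(self.genotype_multipliers))
        if len(self.stage_rates) != _N_TRANSIENT:
            raise ValidationError(f"need {_N_TRANSIENT} stage exit rates")
        if any(r <= 0 for r in self.stage_rates):
            raise ValidationError("stage exit rates must be positive")
        if not self.genotype_multipliers or any(
            m <= 0 for m in self.genotype_multipliers.values()
        ):
            raise ValidationError("genotype multipliers must be positive")
        if self.pr_length_mean_cm <= 0 or self.pr_length_sd_cm < 0:
            raise ValidationError("PR length mean must be > 0 and sd >= 0")
        if self.initiation_intensity < 0:
            raise ValidationError("initiation intensity must be >= 0")
        if self.initiation_lag_h_mean < 0:
            raise ValidationError("initiation lag mean must be >= 0")
        if any(t <= 0 for t in self.observation_times_h) or not self.observation_times_h:
            raise ValidationError("observation times must be positive")
        if self.root_age_h <= 0:
            raise ValidationError("root age horizon must be positive")
        if self.n_roots < 1:
            raise ValidationError("n_roots must be >= 1")
        if self.erlang_k < 1:
            raise ValidationError("erlang_k must be >= 1")

    def with_(self, **changes) -> "ProgressionScenario":
        """Copy with fields replaced."""
        return replace(self, **changes)

    @classmethod
    def from_yaml(cls, path) -> "ProgressionScenario":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = {
            "stage_rates": list(self.stage_rates),
            "genotype_multipliers": dict(self.genotype_multipliers),
            "initiation_intensity": self.initiation_intensity,
            "pr_length_mean_cm": self.pr_length_mean_cm,
            "pr_length_sd_cm": self.pr_length_sd_cm,
            "initiation_lag_h_mean": self.initiation_lag_h_mean,
            "observation_times_h": list(self.observation_times_h),
            "root_age_h": self.root_age_h,
            "n_roots": self.n_roots,
            "erlang_k": self.erlang_k,
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)


#: Baseline study conditions: wild-type plus a faster loss-of-function mutant
#: and a slower overexpressor, with rates placing the wild-type median induced
#: LRP near stage III at 18 h and near stage VI at 42 h.
DEFAULT_SCENARIO = ProgressionScenario()


@dataclass(frozen=True)
class SimulatedDataset:
    """Both assay tables generated from one scenario and seed."""

    roots: tuple[RootObservation, ...]
    induced: tuple[InducedLRPRecord, ...]
    scenario: ProgressionScenario
    seed_used: int


def _dwell_times(
    rng: np.random.Generator, rates: np.ndarray, size: int, erlang_k: int
) -> np.ndarray:
    """(size, 7) matrix of stage dwell times; Erlang-k keeps the exponential mean."""
    if erlang_k == 1:
        return rng.exponential(1.0 / rates, size=(size, rates.size))
    return rng.gamma(shape=erlang_k, scale=1.0 / (erlang_k * rates), size=(size, rates.size))


def _stage_at(entry_time: np.ndarray, dwell: np.ndarray, t: float) -> np.ndarray:
    """Stage index at time t: -1 = not initiated, 0..6 = stages I..VII, 7 = E."""
    boundaries = entry_time[:, None] + np.cumsum(dwell, axis=1)
    idx = (boundaries <= t).sum(axis=1)  # completed transitions by time t
    idx[entry_time > t] = -1
    return idx


def simulate_induced(scenario: ProgressionScenario, seed: int | None = None) -> list[InducedLRPRecord]:
    """Simulate the gravistimulated single-LRP induction time course.

    Each seedling draws an initiation lag (Exponential with the scenario's
    mean; 0 if the mean is 0) and then progresses through stages with
    independent dwell times at the genotype-scaled rates.  Its occupied stage
    is recorded at every observation time: ``NONE`` before initiation, ``E``
    once emerged (absorbing).
    """
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rates = np.asarray(scenario.stage_rates)
    records: list[InducedLRPRecord] = []
    for genotype in scenario.genotype_multipliers:
        m = scenario.genotype_multipliers[genotype]
        n = scenario.n_roots
        if scenario.initiation_lag_h_mean > 0:
            lag = rng.exponential(scenario.initiation_lag_h_mean, size=n)
        else:
            lag = np.zeros(n)
        dwell = _dwell_times(rng, rates * m, n, scenario.erlang_k)
        for t in scenario.observation_times_h:
            idx = _stage_at(lag, dwell, t)
            for i in range(n):
                stage = NONE_STAGE if idx[i] < 0 else STAGES[min(idx[i], 7)]
                records.append(
                    InducedLRPRecord(
                        seedling_id=f"{genotype}_s{i + 1}",
                        genotype=genotype,
                        observation_time_h=t,
                        stage=stage,
                    )
                )
    return records


def simulate_whole_root(scenario: ProgressionScenario, seed: int | None = None) -> list[RootObservation]:
    """Simulate a whole-root LRP staging and density survey.

    Per root: PR length ~ Normal(mean, sd) truncated > 0; LRP count ~
    Poisson(intensity × length); each LRP's age ~ Uniform(0, root_age_h) and
    its stage follows the dwell-time chain at that age (no initiation lag —
    age is measured from the first division).  Emerged LRs get uniform
    positions along the PR.
    """
    seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    rates = np.asarray(scenario.stage_rates)
    observations: list[RootObservation] = []
    for genotype in scenario.genotype_multipliers:
        m = scenario.genotype_multipliers[genotype]
        for i in range(scenario.n_roots):
            length = 0.0
            while length <= 0.0:
                length = rng.normal(scenario.pr_length_mean_cm, scenario.pr_length_sd_cm)
            n_lrp = rng.poisson(scenario.initiation_intensity * length)
            counts = np.zeros(len(STAGES), dtype=np.int64)
            if n_lrp > 0:
                ages = rng.uniform(0.0, scenario.root_age_h, size=n_lrp)
                dwell = _dwell_times(rng, rates * m, n_lrp, scenario.erlang_k)
                # stage of each LRP at its own age: completed transitions by age
                boundaries = np.cumsum(dwell, axis=1)
                idx = (boundaries <= ages[:, None]).sum(axis=1)
                counts = np.bincount(np.minimum(idx, 7), minlength=len(STAGES))
            emerged = int(counts[7])
            positions = tuple(sorted(rng.uniform(0.0, length, size=emerged))) if emerged else ()
            observations.append(
                RootObservation(
                    root_id=f"{genotype}_r{i + 1}",
                    genotype=genotype,
                    pr_length_cm=float(length),
                    emerged_count=emerged,
                    stage_counts=StageCountVector(tuple(int(c) for c in counts)),
                    lr_positions_cm=positions if emerged else None,
                )
            )
    return observations


def simulate_dataset(scenario: ProgressionScenario, seed: int | None = None) -> SimulatedDataset:
    """Generate both assay tables from one scenario with split RNG streams."""
    seed = scenario.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    s_roots, s_induced = (int(c.generate_state(1)[0] & 0x7FFFFFFF) for c in ss.spawn(2))
    return SimulatedDataset(
        roots=tuple(simulate_whole_root(scenario, seed=s_roots)),
        induced=tuple(simulate_induced(scenario, seed=s_induced)),
        scenario=scenario,
        seed_used=seed,
    )
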