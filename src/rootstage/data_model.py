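"""Domain types and tidy CSV I/O for lateral-root phenotyping tables.

The central object is the lateral-root primordium (LRP) stage ontology:
eight ordered morphological levels, stages I–VII of primordium development
plus ``E`` for an emerged lateral root.  Every assay table in the package is
expressed over this fixed ontology so that count vectors from different
genotypes, roots and experiments are always conformable.

Two tidy CSV schemas are supported:

``roots.csv``
    one row per seedling: ``root_id, genotype, pr_length_cm, emerged_count,
    stage_I .. stage_VII, stage_E`` and optionally ``lr_positions_cm``
    (semicolon-joined positions of emerged LRs, in cm from the root–shoot
    junction).

``induced.csv``
    one row per scored seedling per observation time in the gravistimulated
    single-LRP induction assay: ``seedling_id, genotype, observation_time_h,
    stage`` where ``stage`` is an ontology level or ``NONE`` (no primordium
    initiated yet).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "NONE_STAGE",
    "StageOntology",
    "ONTOLOGY",
    "StageCountVector",
    "RootObservation",
    "InducedLRPRecord",
    "GenotypeStageTable",
    "SchemaError",
    "ValidationError",
    "read_root_table",
    "write_root_table",
    "read_induced_table",
    "write_induced_table",
    "pool_by_genotype",
    "write_result_table",
]

#: Ordered developmental stage labels; ``E`` = emerged lateral root
#: (the morphological stage sometimes labelled "VIII").
STAGES: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI", "VII", "E")

#: Sentinel stage for an induced-assay seedling with no initiated primordium.
NONE_STAGE = "NONE"

_STAGE_INDEX = {s: i for i, s in enumerate(STAGES)}


class SchemaError(ValueError):
    """A table is missing required columns or has an unknown column layout."""


class ValidationError(ValueError):
    """A row or value violates a domain invariant."""


@dataclass(frozen=True)
class StageOntology:
    """The closed, ordered set of LRP developmental stages.

    ``early_set`` (stages I–IV) and ``late_set`` (stage VII and emerged)
    are the groupings conventionally used to summarise whether a genotype's
    primordium population is shifted early or late.
    """

    levels: tuple[str, ...] = STAGES
    early_set: frozenset[str] = frozenset({"I", "II", "III", "IV"})
    late_set: frozenset[str] = frozenset({"VII", "E"})

    def __post_init__(self) -> None:
        if len(self.levels) != 8 or len(set(self.levels)) != 8:
            raise ValidationError("stage ontology must have 8 distinct levels")
        if not (self.early_set <= set(self.levels) and self.late_set <= set(self.levels)):
            raise ValidationError("early/late sets must be subsets of the levels")
        if self.early_set & self.late_set:
            raise ValidationError("early and late stage sets must be disjoint")

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise ValidationError(f"unknown stage label {level!r}") from None


#: The canonical ontology instance used throughout the package.
ONTOLOGY = StageOntology()


@dataclass(frozen=True)
class StageCountVector:
    """Non-negative LRP counts, one per ontology level, in ontology order."""

    counts: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.counts) != len(STAGES):
            raise ValidationError(
                f"expected {len(STAGES)} stage counts, got {len(self.counts)}"
            )
        if any(c < 0 or c != int(c) for c in self.counts):
            raise ValidationError(f"stage counts must be nonnegative integers: {self.counts}")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @property
    def n(self) -> int:
        """Total number of scored LRPs."""
        return int(sum(self.counts))

    def __getitem__(self, key: int | str) -> int:
        if isinstance(key, str):
            key = _STAGE_INDEX[key] if key in _STAGE_INDEX else ONTOLOGY.index(key)
        return self.counts[key]

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def __add__(self, other: "StageCountVector") -> "StageCountVector":
        return StageCountVector(tuple(a + b for a, b in zip(self.counts, other.counts)))

    @classmethod
    def zeros(cls) -> "StageCountVector":
        return cls((0,) * len(STAGES))


@dataclass(frozen=True)
class RootObservation:
    """One seedling's root-architecture phenotypes.

    ``pr_length_cm`` is the primary-root length; ``emerged_count`` must agree
    with the ``E`` entry of ``stage_counts``.  ``lr_positions_cm`` optionally
    records where each emerged LR sits along the PR (cm from the root–shoot
    junction, increasing rootward); it is needed only for the branching-zone
    density metric.
    """

    root_id: str
    genotype: str
    pr_length_cm: float
    emerged_count: int
    stage_counts: StageCountVector
    lr_positions_cm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.pr_length_cm > 0:
            raise ValidationError(
                f"root {self.root_id!r}: pr_length_cm must be positive, got {self.pr_length_cm}"
            )
        if self.emerged_count < 0:
            raise ValidationError(f"root {self.root_id!r}: negative emerged_count")
        if self.emerged_count != self.stage_counts["E"]:
            raise ValidationError(
                f"root {self.root_id!r}: emerged_count ({self.emerged_count}) does not "
                f"match stage_E count ({self.stage_counts['E']})"
            )
        if self.lr_positions_cm is not None:
            object.__setattr__(self, "lr_positions_cm", tuple(float(x) for x in self.lr_positions_cm))
            for x in self.lr_positions_cm:
                if not (0.0 <= x <= self.pr_length_cm):
                    raise ValidationError(
                        f"root {self.root_id!r}: LR position {x} outside [0, {self.pr_length_cm}]"
                    )


@dataclass(frozen=True)
class InducedLRPRecord:
    """One scored seedling from the gravistimulated single-LRP induction assay."""

    seedling_id: str
    genotype: str
    observation_time_h: float
    stage: str

    def __post_init__(self) -> None:
        if not self.observation_time_h > 0:
            raise ValidationError(
                f"seedling {self.seedling_id!r}: observation_time_h must be positive"
            )
        if self.stage not in STAGES and self.stage != NONE_STAGE:
            raise ValidationError(
                f"seedling {self.seedling_id!r}: unknown stage {self.stage!r}"
            )


@dataclass(frozen=True)
class GenotypeStageTable:
    """Pooled stage counts for one genotype, with the number of roots pooled."""

    genotype: str
    pooled: StageCountVector
    n_roots: int

    def __post_init__(self) -> None:
        if self.n_roots < 1:
            raise ValidationError(f"genotype {self.genotype!r}: n_roots must be >= 1")


# ---------------------------------------------------------------------------
# CSV ingestion / emission

_ROOT_REQUIRED = ["root_id", "genotype", "pr_length_cm", "emerged_count"] + [
    f"stage_{s}" for s in STAGES
]
_INDUCED_REQUIRED = ["seedling_id", "genotype", "observation_time_h", "stage"]


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def read_root_table(path) -> list[RootObservation]:
    """Read a ``roots.csv`` table into validated :class:`RootObservation` records.

    Malformed rows are reported collectively with their 1-based data-row
    numbers; any malformed row aborts the read.
    """
    df = pd.read_csv(path, dtype={"root_id": str, "genotype": str})
    _require_columns(df, _ROOT_REQUIRED, path)
    obs: list[RootObservation] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            counts = StageCountVector(tuple(int(getattr(row, f"stage_{s}")) for s in STAGES))
            positions = None
            if "lr_positions_cm" in df.columns:
                raw = getattr(row, "lr_positions_cm")
                if isinstance(raw, str) and raw.strip():
                    positions = tuple(float(x) for x in raw.split(";"))
            obs.append(
                RootObservation(
                    root_id=str(row.root_id),
                    genotype=str(row.genotype),
                    pr_length_cm=float(row.pr_length_cm),
                    emerged_count=int(row.emerged_count),
                    stage_counts=counts,
                    lr_positions_cm=positions,
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return obs


def write_root_table(observations: Iterable[RootObservation], path) -> None:
    """Write :class:`RootObservation` records as a ``roots.csv`` table."""
    rows = []
    for o in observations:
        row = {
            "root_id": o.root_id,
            "genotype": o.genotype,
            "pr_length_cm": o.pr_length_cm,
            "emerged_count": o.emerged_count,
        }
        for s, c in zip(STAGES, o.stage_counts.counts):
            row[f"stage_{s}"] = c
        row["lr_positions_cm"] = (
            ";".join(format(x, ".6g") for x in o.lr_positions_cm)
            if o.lr_positions_cm is not None
            else ""
        )
        rows.append(row)
    cols = _ROOT_REQUIRED + ["lr_positions_cm"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.6g")


def read_induced_table(path) -> list[InducedLRPRecord]:
    """Read an ``induced.csv`` table into validated :class:`InducedLRPRecord` records."""
    df = pd.read_csv(path, dtype={"seedling_id": str, "genotype": str, "stage": str})
    _require_columns(df, _INDUCED_REQUIRED, path)
    records: list[InducedLRPRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                InducedLRPRecord(
                    seedling_id=str(row.seedling_id),
                    genotype=str(row.genotype),
                    observation_time_h=float(row.observation_time_h),
                    stage=str(row.stage),
                )
            )
        except (ValidationError, ValueError) as exc:
            errors.append(f"row {i}: {exc}")
    if errors:
        raise ValidationError(f"{path}: " + "; ".join(errors))
    return records


def write_induced_table(records: Iterable[InducedLRPRecord], path) -> None:
    rows = [
        {
            "seedling_id": r.seedling_id,
            "genotype": r.genotype,
            "observation_time_h": r.observation_time_h,
            "stage": r.stage,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_INDUCED_REQUIRED).to_csv(path, index=False, float_format="%.6g")


def pool_by_genotype(observations: Sequence[RootObservation]) -> list[GenotypeStageTable]:
    """Pool per-root stage counts into one count vector per genotype.

    Zero-LRP roots are legal and contribute zero counts (but are counted in
    ``n_roots``).  Pooling conserves totals: the pooled counts summed over
    genotypes equal the per-root counts summed over roots.
    """
    if not observations:
        raise ValidationError("cannot pool an empty collection of observations")
    pooled: dict[str, StageCountVector] = {}
    n_roots: dict[str, int] = {}
    for o in observations:
        pooled[o.genotype] = pooled.get(o.genotype, StageCountVector.zeros()) + o.stage_counts
        n_roots[o.genotype] = n_roots.get(o.genotype, 0) + 1
    return [
        GenotypeStageTable(genotype=g, pooled=pooled[g], n_roots=n_roots[g])
        for g in sorted(pooled)
    ]


def write_result_table(results, path) -> None:
    """Write any tabular result to CSV with deterministic columns and fixed precision.

    ``results`` may be a DataFrame, a sequence of dataclasses, or a sequence of
    dicts.  Floats are printed at 6 significant digits, so tables round-trip
    through :func:`pandas.read_csv` at that precision.
    """
    if isinstance(results, pd.DataFrame):
        df = results
    else:
        rows = []
        for r in results:
            if dataclasses.is_dataclass(r):
                rows.append(dataclasses.asdict(r))
            elif isinstance(r, dict):
                rows.append(dict(r))
            else:
                raise TypeError(f"cannot tabulate object of type {type(r).__name__}")
        df = pd.DataFrame(rows)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
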