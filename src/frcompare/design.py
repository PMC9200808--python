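"""Experimental design and the feeding-trial data model.

A functional-response feeding experiment is a flat table of trials: each row
records the treatment factors (predator sex, water temperature, salinity), the
initial prey density ``N0``, the number of prey killed ``Ne`` over the trial,
the trial duration, and whether the unit was a predator-free control used to
measure background prey mortality.

Durations are stored in experimental-period units (1.0 = one full feeding
period; the study design this package ships with used a 72 h period, recorded
as metadata on :class:`DesignSpec`). Attack rates and handling times are then
per-period quantities, which keeps maximum feeding rates on the scale of prey
per period.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "Trial",
    "DesignSpec",
    "InvalidDesignError",
    "TrialValidationError",
    "default_design",
    "enumerate_units",
    "read_trials",
    "write_trials",
    "trials_to_frame",
    "frame_to_trials",
]


class InvalidDesignError(ValueError):
    """Raised when a :class:`DesignSpec` is structurally invalid."""


class TrialValidationError(ValueError):
    """Raised when a trial row violates the data model (names the row)."""


#: canonical CSV column order
TRIAL_COLUMNS = (
    "sex",
    "temperature",
    "salinity",
    "n_initial",
    "n_killed",
    "duration",
    "is_control",
)

_TRUE = {"true", "1", "yes", "t", "y"}
_FALSE = {"false", "0", "no", "f", "n", ""}


@dataclass(frozen=True)
class Trial:
    """One experimental unit.

    ``sex`` is ``None`` for predator-free controls. ``n_killed`` may be ``None``
    for units that have been enumerated but not yet run.
    """

    sex: str | None
    temperature: float
    salinity: float
    n_initial: int
    n_killed: int | None = None
    duration: float = 1.0
    is_control: bool = False

    def __post_init__(self) -> None:
        if self.n_initial < 1:
            raise TrialValidationError(f"n_initial must be >= 1, got {self.n_initial}")
        if self.n_killed is not None and not 0 <= self.n_killed <= self.n_initial:
            raise TrialValidationError(
                f"n_killed={self.n_killed} outside [0, n_initial={self.n_initial}]"
            )
        if self.duration <= 0:
            raise TrialValidationError(f"duration must be > 0, got {self.duration}")
        if self.is_control and self.sex is not None:
            raise TrialValidationError("control trials must have sex=None")

    @property
    def proportion_killed(self) -> float:
        if self.n_killed is None:
            raise ValueError("n_killed is unset")
        return self.n_killed / self.n_initial


@dataclass(frozen=True)
class DesignSpec:
    """Fully crossed feeding-experiment design.

    Predator units: every sex x temperature x salinity x density cell replicated
    ``replicates_predator`` times. Control units: every temperature x salinity x
    density cell (no predator, hence no sex) replicated ``replicates_control``
    times. ``period_hours`` records the wall-clock length of one experimental
    period and is metadata only; all analysis runs in period units.
    """

    densities: tuple[int, ...] = (1, 2, 4, 6, 8, 16, 32, 64)
    replicates_predator: int = 5
    replicates_control: int = 3
    sexes: tuple[str, ...] = ("M", "F")
    temperatures: tuple[float, ...] = (16.0, 22.0)
    salinities: tuple[float, ...] = (15.0, 10.0)
    duration: float = 1.0
    period_hours: float = 72.0

    def __post_init__(self) -> None:
        dens = tuple(int(d) for d in self.densities)
        object.__setattr__(self, "densities", dens)
        if not dens:
            raise InvalidDesignError("densities must be non-empty")
        if any(d < 1 for d in dens):
            raise InvalidDesignError("all densities must be >= 1")
        if any(b <= a for a, b in zip(dens, dens[1:])):
            raise InvalidDesignError("densities must be strictly increasing")
        if self.replicates_predator < 1:
            raise InvalidDesignError("replicates_predator must be >= 1")
        if self.replicates_control < 0:
            raise InvalidDesignError("replicates_control must be >= 0")
        for name in ("sexes", "temperatures", "salinities"):
            if len(getattr(self, name)) == 0:
                raise InvalidDesignError(f"factor level list '{name}' is empty")
        if self.duration <= 0:
            raise InvalidDesignError("duration must be > 0")

    @property
    def n_predator_units(self) -> int:
        return (
            self.replicates_predator
            * len(self.sexes)
            * len(self.temperatures)
            * len(self.salinities)
            * len(self.densities)
        )

    @property
    def n_control_units(self) -> int:
        return (
            self.replicates_control
            * len(self.temperatures)
            * len(self.salinities)
            * len(self.densities)
        )

    @property
    def n_units(self) -> int:
        return self.n_predator_units + self.n_control_units


def default_design() -> DesignSpec:
    """The bundled study design: densities 1-64, 5 predator replicates per cell,
    3 predator-free controls per abiotic cell, 2 sexes x 2 temperatures x
    2 salinities, 72 h period (416 units total)."""
    return DesignSpec()


def enumerate_units(spec: DesignSpec) -> list[Trial]:
    """Expand a design into its experimental units (``n_killed`` unset).

    Predator cells come first (sex, temperature, salinity, density, replicate in
    row-major order), then control cells.
    """
    if not isinstance(spec, DesignSpec):
        raise InvalidDesignError("spec must be a DesignSpec")
    units: list[Trial] = []
    for sex in spec.sexes:
        for temp in spec.temperatures:
            for sal in spec.salinities:
                for dens in spec.densities:
                    for _ in range(spec.replicates_predator):
                        units.append(
                            Trial(sex=sex, temperature=temp, salinity=sal,
                                  n_initial=dens, duration=spec.duration)
                        )
    for temp in spec.temperatures:
        for sal in spec.salinities:
            for dens in spec.densities:
                for _ in range(spec.replicates_control):
                    units.append(
                        Trial(sex=None, temperature=temp, salinity=sal,
                              n_initial=dens, duration=spec.duration,
                              is_control=True)
                    )
    return units


# ---------------------------------------------------------------------------
# I/O


def _parse_sex(raw: str) -> str | None:
    s = raw.strip()
    if s == "" or s.lower() in {"none", "na", "nan"}:
        return None
    up = s.upper()
    if up in {"M", "MALE"}:
        return "M"
    if up in {"F", "FEMALE"}:
        return "F"
    raise TrialValidationError(f"unknown sex level {raw!r} (expected M, F or none)")


def _parse_bool(raw: str, row: int, col: str) -> bool:
    s = raw.strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise TrialValidationError(f"row {row}: cannot parse {col}={raw!r} as boolean")


def read_trials(path, column_map: Mapping[str, str] | None = None) -> list[Trial]:
    """Read a trial table from CSV.

    ``column_map`` maps canonical field names (``sex``, ``temperature``,
    ``salinity``, ``n_initial``, ``n_killed``, ``duration``, ``is_control``) to
    the file's header names, so tables with arbitrary headers can be ingested.
    Headers are matched case-insensitively. ``duration`` and ``is_control`` are
    optional (defaults 1.0 and False). Validation errors name the offending row
    (1-based, excluding the header).
    """
    colmap = {k: (column_map or {}).get(k, k).lower() for k in TRIAL_COLUMNS}
    trials: list[Trial] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise TrialValidationError("empty file: header row required")
        header = {name.lower().strip(): name for name in reader.fieldnames}
        for canon in ("temperature", "salinity", "n_initial", "n_killed"):
            if colmap[canon] not in header:
                raise TrialValidationError(f"missing required column '{colmap[canon]}'")
        for i, row in enumerate(reader, start=1):
            def get(canon: str, default: str | None = None) -> str | None:
                name = header.get(colmap[canon])
                if name is None:
                    return default
                val = row.get(name)
                return default if val is None or val.strip() == "" else val

            try:
                trials.append(
                    Trial(
                        sex=_parse_sex(get("sex", "") or ""),
                        temperature=float(get("temperature")),  # type: ignore[arg-type]
                        salinity=float(get("salinity")),  # type: ignore[arg-type]
                        n_initial=int(float(get("n_initial"))),  # type: ignore[arg-type]
                        n_killed=int(float(get("n_killed"))),  # type: ignore[arg-type]
                        duration=float(get("duration", "1.0")),  # type: ignore[arg-type]
                        is_control=_parse_bool(get("is_control", "false") or "false", i, "is_control"),
                    )
                )
            except TrialValidationError as exc:
                raise TrialValidationError(f"row {i}: {exc}") from None
            except (TypeError, ValueError) as exc:
                raise TrialValidationError(f"row {i}: {exc}") from None
    return trials


def write_trials(trials: Iterable[Trial], path) -> None:
    """Write trials as canonical CSV (UTF-8, comma-separated, header row)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(TRIAL_COLUMNS)
        for t in trials:
            writer.writerow(
                [
                    "" if t.sex is None else t.sex,
                    repr(t.temperature),
                    repr(t.salinity),
                    t.n_initial,
                    "" if t.n_killed is None else t.n_killed,
                    repr(t.duration),
                    t.is_control,
                ]
            )


def trials_to_frame(trials: Iterable[Trial]) -> pd.DataFrame:
    """Trial list -> DataFrame with the canonical columns."""
    recs = [
        {
            "sex": t.sex,
            "temperature": t.temperature,
            "salinity": t.salinity,
            "n_initial": t.n_initial,
            "n_killed": t.n_killed,
            "duration": t.duration,
            "is_control": t.is_control,
        }
        for t in trials
    ]
    return pd.DataFrame(recs, columns=list(TRIAL_COLUMNS))


def frame_to_trials(df: pd.DataFrame) -> list[Trial]:
    """DataFrame -> validated Trial list (inverse of :func:`trials_to_frame`)."""
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            nk = row.n_killed
            out.append(
                Trial(
                    sex=None if (row.sex is None or (isinstance(row.sex, float) and pd.isna(row.sex))) else str(row.sex),
                    temperature=float(row.temperature),
                    salinity=float(row.salinity),
                    n_initial=int(row.n_initial),
                    n_killed=None if nk is None or pd.isna(nk) else int(nk),
                    duration=float(row.duration),
                    is_control=bool(row.is_control),
                )
            )
        except TrialValidationError as exc:
            raise TrialValidationError(f"row {i}: {exc}") from None
    return out


def as_frame(trials) -> pd.DataFrame:
    """Normalize a trial collection (list of Trial or DataFrame) to a DataFrame."""
    if isinstance(trials, pd.DataFrame):
        missing = [c for c in ("n_initial", "n_killed") if c not in trials.columns]
        if missing:
            raise TrialValidationError(f"trial frame missing columns {missing}")
        df = trials.copy()
        for col, default in (("duration", 1.0), ("is_control", False), ("sex", None)):
            if col not in df.columns:
                df[col] = default
        return df
    return trials_to_frame(trials)
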