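"""Validated data model and CSV I/O for predation trials and damage time series.

The central records are :class:`PredationTrial` (one replicate of a
predator–prey consumption trial: one predator larva offered ``n0`` prey for
``exposure_h`` hours, ``na`` of them completely or partially consumed) and
:class:`DamageSeries` (a day-indexed trajectory of surviving prey and
cumulative leaf defoliation for one experimental arena).  Both are plain
frozen dataclasses whose invariants are enforced at construction time, so no
invalid record can reach the fitting modules.

CSV interchange is UTF-8, comma-separated, header required, ``.`` decimal
separator.  Counts are integers; a fractional consumption count in an input
file is an error, never a rounding.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("funcresp")

__all__ = [
    "SchemaError",
    "ValidationError",
    "DesignError",
    "PredationTrial",
    "ExperimentDesign",
    "DamageSeries",
    "read_trials",
    "write_trials",
    "read_damage_series",
    "write_damage_series",
    "write_results",
    "TRIAL_COLUMNS",
    "DAMAGE_COLUMNS",
]


class SchemaError(ValueError):
    """An input table is missing a required column or has a wrong dtype."""


class ValidationError(ValueError):
    """A record violates a domain invariant (row number reported when known)."""


class DesignError(ValueError):
    """An experimental design is unusable for the requested analysis."""


TRIAL_COLUMNS = ["predator_instar", "treatment", "n0", "na", "exposure_h", "replicate_id"]
DAMAGE_COLUMNS = ["treatment", "replicate", "day", "survivors", "defoliation_pct", "predator_release_day"]


@dataclass(frozen=True)
class PredationTrial:
    """One replicate: a single predator larva offered ``n0`` prey for ``exposure_h`` h.

    ``na`` counts prey completely *or partially* consumed — partial consumption
    is consumption, so the field is a plain integer with no fractional kills.
    Treatment labels are normalised to lowercase on construction.
    """

    predator_instar: int
    treatment: str
    n0: int
    na: int
    exposure_h: float = 24.0
    replicate_id: int = 0
    excluded: bool = False  # no exclusion rule is applied by default; carried for provenance

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", str(self.treatment).strip().lower())
        if self.predator_instar not in (1, 2, 3):
            raise ValidationError(f"predator_instar must be 1, 2 or 3, got {self.predator_instar!r}")
        for name in ("n0", "na", "replicate_id", "predator_instar"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or isinstance(v, bool):
                raise ValidationError(f"{name} must be an integer count, got {v!r}")
        if self.n0 < 1:
            raise ValidationError(f"n0 must be >= 1, got {self.n0}")
        if not 0 <= self.na <= self.n0:
            raise ValidationError(f"na must satisfy 0 <= na <= n0, got na={self.na}, n0={self.n0}")
        if not self.exposure_h > 0:
            raise ValidationError(f"exposure_h must be > 0, got {self.exposure_h}")

    @property
    def proportion_consumed(self) -> float:
        return self.na / self.n0


@dataclass(frozen=True)
class ExperimentDesign:
    """A density ladder with replication: the skeleton of one functional-response assay.

    Defaults follow the common bench design: 15 replicates (one predator larva
    per replicate) per density and a 24-h exposure window.
    """

    densities: tuple[int, ...]
    replicates: int = 15
    exposure_h: float = 24.0
    treatments: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"control": {}, "cry3aa": {"cry3aa_conc_ug_ml": 4.22}}
    )

    def __post_init__(self) -> None:
        d = tuple(int(x) for x in self.densities)
        object.__setattr__(self, "densities", d)
        if len(d) < 1 or any(x < 1 for x in d):
            raise ValidationError(f"densities must all be >= 1, got {d}")
        if any(b <= a for a, b in zip(d, d[1:])):
            raise ValidationError(f"densities must be strictly increasing, got {d}")
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")
        if not self.exposure_h > 0:
            raise ValidationError(f"exposure_h must be > 0, got {self.exposure_h}")

    @property
    def n_trials(self) -> int:
        return len(self.densities) * self.replicates


@dataclass(frozen=True)
class DamageSeries:
    """Day-indexed survivor counts and cumulative defoliation for one arena.

    Survivors must be non-increasing and defoliation non-decreasing in day;
    day coverage must be gap-free.  ``predator_release_day`` is ``None`` when
    no predator was released in this arena.
    """

    treatment: str
    replicate: int
    days: tuple[int, ...]
    survivors: tuple[int, ...]
    defoliation_pct: tuple[float, ...]
    predator_release_day: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "treatment", str(self.treatment).strip().lower())
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))
        object.__setattr__(self, "survivors", tuple(int(s) for s in self.survivors))
        object.__setattr__(self, "defoliation_pct", tuple(float(x) for x in self.defoliation_pct))
        if not (len(self.days) == len(self.survivors) == len(self.defoliation_pct)):
            raise ValidationError("days, survivors and defoliation_pct must have equal length")
        if len(self.days) == 0:
            raise ValidationError("empty series")
        if any(b != a + 1 for a, b in zip(self.days, self.days[1:])):
            raise ValidationError(
                f"day gaps in series (treatment={self.treatment!r}, replicate={self.replicate}): {self.days}"
            )
        if any(s < 0 for s in self.survivors):
            raise ValidationError("survivors must be >= 0")
        if any(b > a for a, b in zip(self.survivors, self.survivors[1:])):
            raise ValidationError(
                f"survivors increase within series (treatment={self.treatment!r}, replicate={self.replicate})"
            )
        if any(not 0.0 <= x <= 100.0 for x in self.defoliation_pct):
            raise ValidationError("defoliation_pct must lie in [0, 100]")

    @property
    def final_day(self) -> int:
        return self.days[-1]


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; found {list(df.columns)}")


def _int_cell(value, column: str, row: int):
    """Parse an integer count; fractional values are errors, not roundings."""
    f = float(value)
    if math.isnan(f):
        raise ValidationError(f"row {row}: {column} is missing")
    if f != int(f):
        raise ValidationError(f"row {row}: {column} must be an integer count, got {value!r}")
    return int(f)


def read_trials(path) -> list[PredationTrial]:
    """Read a trials CSV into validated :class:`PredationTrial` records.

    Required columns: ``predator_instar, treatment, n0, na``; optional
    ``exposure_h`` (default 24), ``replicate_id`` (default row order) and
    ``excluded``.  Row numbers in error messages are 1-based data rows
    (header excluded).
    """
    df = pd.read_csv(path)
    _require_columns(df, ["predator_instar", "treatment", "n0", "na"], path)
    trials: list[PredationTrial] = []
    for i, rec in enumerate(df.to_dict("records"), start=1):
        try:
            trials.append(
                PredationTrial(
                    predator_instar=_int_cell(rec["predator_instar"], "predator_instar", i),
                    treatment=rec["treatment"],
                    n0=_int_cell(rec["n0"], "n0", i),
                    na=_int_cell(rec["na"], "na", i),
                    exposure_h=float(rec.get("exposure_h", 24.0)) if not pd.isna(rec.get("exposure_h", 24.0)) else 24.0,
                    replicate_id=_int_cell(rec.get("replicate_id", i), "replicate_id", i),
                    excluded=bool(rec.get("excluded", False)) if not pd.isna(rec.get("excluded", False)) else False,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path}, row {i}: {e}") from e
    if not trials:
        logger.warning("%s: no trial rows found (header-only file)", path)
    return trials


def write_trials(trials: Iterable[PredationTrial], path) -> None:
    df = pd.DataFrame(
        [
            {
                "predator_instar": t.predator_instar,
                "treatment": t.treatment,
                "n0": t.n0,
                "na": t.na,
                "exposure_h": t.exposure_h,
                "replicate_id": t.replicate_id,
            }
            for t in trials
        ],
        columns=TRIAL_COLUMNS,
    )
    df.to_csv(path, index=False)


def read_damage_series(path, strict_defoliation: bool = False) -> list[DamageSeries]:
    """Read a damage CSV and group rows into per-replicate :class:`DamageSeries`.

    Required columns: ``treatment, replicate, day, survivors, defoliation_pct``;
    optional ``predator_release_day``.  A defoliation decrease within a
    replicate is a warning (set ``strict_defoliation=True`` to make it an
    error); a survivor increase or a day gap is always an error.
    """
    df = pd.read_csv(path)
    _require_columns(df, ["treatment", "replicate", "day", "survivors", "defoliation_pct"], path)
    if df.empty:
        logger.warning("%s: no damage rows found (header-only file)", path)
        return []
    series: list[DamageSeries] = []
    for (treatment, replicate), g in df.groupby(["treatment", "replicate"], sort=True):
        g = g.sort_values("day")
        defol = [float(x) for x in g["defoliation_pct"]]
        for a, b in zip(defol, defol[1:]):
            if b < a:
                msg = f"{path}: defoliation decreases within treatment={treatment!r} replicate={replicate}"
                if strict_defoliation:
                    raise ValidationError(msg)
                logger.warning(msg)
                break
        release = None
        if "predator_release_day" in g.columns:
            v = g["predator_release_day"].iloc[0]
            release = None if pd.isna(v) else int(v)
        series.append(
            DamageSeries(
                treatment=str(treatment),
                replicate=int(replicate),
                days=tuple(_int_cell(d, "day", -1) for d in g["day"]),
                survivors=tuple(_int_cell(s, "survivors", -1) for s in g["survivors"]),
                defoliation_pct=tuple(min(max(x, 0.0), 100.0) if strict_defoliation is False else x for x in defol),
                predator_release_day=release,
            )
        )
    return series


def write_damage_series(series: Iterable[DamageSeries], path) -> None:
    rows = []
    for s in series:
        for d, surv, defol in zip(s.days, s.survivors, s.defoliation_pct):
            rows.append(
                {
                    "treatment": s.treatment,
                    "replicate": s.replicate,
                    "day": d,
                    "survivors": surv,
                    "defoliation_pct": defol,
                    "predator_release_day": s.predator_release_day,
                }
            )
    pd.DataFrame(rows, columns=DAMAGE_COLUMNS).to_csv(path, index=False)


def write_results(logistic_fits, rogers_fits, outdir) -> dict[str, Path]:
    """Write fitted results as ``table1.csv`` (logistic terms) and ``table2.csv``.

    ``table2.csv`` carries one row per (instar, treatment) with point estimate
    and 95% confidence limits for the attack rate ``a``, handling time ``th``
    and derived maximum attack ``tth = T/Th``, plus CL-overlap group letters
    (per instar, per parameter; ``group_letter`` is the handling-time grouping).
    Empty fit lists produce header-only files.
    """
    from .rogers import assign_group_letters  # local import to avoid a cycle

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    rows1 = []
    for f in logistic_fits:
        for term in f.term_order:
            stats = f.terms.get(term)
            rows1.append(
                {
                    "instar": f.instar,
                    "treatment": f.treatment,
                    "term": term,
                    "estimate": stats.estimate if stats else np.nan,
                    "df": 1 if stats else np.nan,
                    "chi2": stats.chi2 if stats else np.nan,
                    "p": stats.p if stats else np.nan,
                    "retained": term in f.retained_terms,
                    "response_type": f.response_type,
                }
            )
    t1 = outdir / "table1.csv"
    pd.DataFrame(
        rows1, columns=["instar", "treatment", "term", "estimate", "df", "chi2", "p", "retained", "response_type"]
    ).to_csv(t1, index=False)
    paths["table1"] = t1

    fits = list(rogers_fits)
    # group letters are assigned within instar, comparing treatments
    letters: dict[int, dict[str, dict[str, str]]] = {}
    for instar in sorted({f.instar for f in fits}):
        sub = [f for f in fits if f.instar == instar]
        letters[instar] = {}
        for param in ("a", "th", "tth"):
            ivals = [getattr(f, f"{param}_cl") for f in sub]
            ests = [getattr(f, f"{param}_hat") for f in sub]
            ls = assign_group_letters(ests, ivals)
            letters[instar][param] = {f.treatment: l for f, l in zip(sub, ls)}
    rows2 = []
    for f in fits:
        rows2.append(
            {
                "instar": f.instar,
                "treatment": f.treatment,
                "a_hat": f.a_hat,
                "a_lo": f.a_cl[0],
                "a_hi": f.a_cl[1],
                "th_hat": f.th_hat,
                "th_lo": f.th_cl[0],
                "th_hi": f.th_cl[1],
                "tth_hat": f.tth_hat,
                "tth_lo": f.tth_cl[0],
                "tth_hi": f.tth_cl[1],
                "group_letter": letters[f.instar]["th"][f.treatment],
                "a_letter": letters[f.instar]["a"][f.treatment],
                "tth_letter": letters[f.instar]["tth"][f.treatment],
            }
        )
    t2 = outdir / "table2.csv"
    pd.DataFrame(
        rows2,
        columns=[
            "instar", "treatment", "a_hat", "a_lo", "a_hi", "th_hat", "th_lo", "th_hi",
            "tth_hat", "tth_lo", "tth_hi", "group_letter", "a_letter", "tth_letter",
        ],
    ).to_csv(t2, index=False)
    paths["table2"] = t2
    return paths
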