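"""Epigenetic-clock DNAm age computation.

An epigenetic clock is a linear predictor of age from methylation beta values
at a fixed probe set:

    DNAmAge = m0 + m1*beta1 + m2*beta2 + ... + mn*betan

where ``m0`` is the model intercept and ``mi`` the coefficient for probe ``i``.
The Horvath clock additionally applies a piecewise age transformation during
training, so its raw linear score must be mapped back to years with
:func:`horvath_inverse`.  The Zhang ("improved precision") clock standardises
beta values within each sample before applying its coefficients, which
``ClockDefinition.standardize_per_sample`` reproduces.

Beta matrices are pandas DataFrames with probe IDs as the index and sample IDs
as columns, values in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ClockDefinition",
    "ClockFormatError",
    "ProbeAvailability",
    "load_clock_table",
    "intersect_probes",
    "linear_predictor",
    "horvath_inverse",
    "compute_dnam_age",
]

INTERCEPT_SENTINEL = "(Intercept)"

#: Allowed output transforms for a clock's raw linear score.
TRANSFORMS = ("identity", "horvath_inverse")

#: Allowed missing-probe policies for :func:`compute_dnam_age`.
PROBE_POLICIES = ("intersect_tissues", "drop_missing", "strict")


class ClockFormatError(ValueError):
    """Raised when a clock coefficient table violates the expected format."""


class MissingProbeError(KeyError):
    """Raised under the strict probe policy when a clock probe is absent."""


@dataclass(frozen=True)
class ClockDefinition:
    """A named epigenetic clock: intercept, probe coefficients, output transform.

    Parameters
    ----------
    name:
        Identifier, e.g. ``"horvath"``.
    intercept:
        The model intercept ``m0``, in the clock's internal units (transformed
        age for Horvath, years for the others).
    coefficients:
        Mapping ``probe_id -> coefficient``.
    transform:
        ``"identity"`` or ``"horvath_inverse"``.
    standardize_per_sample:
        If True, beta values are z-scored within each sample over the probe
        set before the dot product (the Zhang clock convention).
    adult_age:
        Constant of the Horvath transformation; ignored for identity clocks.
    """

    name: str
    intercept: float
    coefficients: Mapping[str, float]
    transform: str = "identity"
    standardize_per_sample: bool = False
    adult_age: float = 20.0

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(
                f"unknown transform {self.transform!r}; expected one of {TRANSFORMS}"
            )
        if len(self.coefficients) == 0:
            raise ClockFormatError(f"clock {self.name!r} has no probe coefficients")

    @property
    def probes(self) -> list[str]:
        return list(self.coefficients)

    @property
    def n_probes(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class ProbeAvailability:
    """Result of intersecting a clock's probes with one or more beta matrices."""

    clock: str
    retained: tuple[str, ...]
    missing: tuple[str, ...]

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_missing(self) -> int:
        return len(self.missing)

    def report(self) -> pd.DataFrame:
        """One-row availability summary (clock, probes in clock/retained/missing)."""
        return pd.DataFrame(
            {
                "clock": [self.clock],
                "n_clock_probes": [self.n_retained + self.n_missing],
                "n_retained": [self.n_retained],
                "n_missing": [self.n_missing],
            }
        )


def load_clock_table(
    path: str | Path,
    name: str,
    transform: str = "identity",
    standardize_per_sample: bool = False,
    adult_age: float = 20.0,
) -> ClockDefinition:
    """Load a clock coefficient CSV into a :class:`ClockDefinition`.

    The CSV must have columns ``probe_id`` and ``coefficient`` and exactly one
    row whose ``probe_id`` is the literal ``"(Intercept)"``, which supplies the
    model intercept; all other rows are probe coefficients.

    Raises
    ------
    ClockFormatError
        On a duplicated probe ID, a missing or duplicated intercept row, or a
        table with no probe rows.
    """
    table = pd.read_csv(path)
    required = {"probe_id", "coefficient"}
    if not required.issubset(table.columns):
        raise ClockFormatError(
            f"{path}: expected columns {sorted(required)}, found {list(table.columns)}"
        )
    is_intercept = table["probe_id"] == INTERCEPT_SENTINEL
    n_intercept = int(is_intercept.sum())
    if n_intercept == 0:
        raise ClockFormatError(f"{path}: no {INTERCEPT_SENTINEL!r} row")
    if n_intercept > 1:
        raise ClockFormatError(f"{path}: {n_intercept} intercept rows; expected one")
    probes = table.loc[~is_intercept]
    if probes.empty:
        raise ClockFormatError(f"{path}: no probe coefficient rows")
    dupes = probes["probe_id"][probes["probe_id"].duplicated()].unique()
    if len(dupes):
        raise ClockFormatError(f"{path}: duplicated probe IDs: {list(dupes)[:5]}")
    intercept = float(table.loc[is_intercept, "coefficient"].iloc[0])
    coefficients = dict(
        zip(probes["probe_id"].astype(str), probes["coefficient"].astype(float))
    )
    return ClockDefinition(
        name=name,
        intercept=intercept,
        coefficients=coefficients,
        transform=transform,
        standardize_per_sample=standardize_per_sample,
        adult_age=adult_age,
    )


def intersect_probes(
    clock: ClockDefinition, matrices: Mapping[str, pd.DataFrame]
) -> ProbeAvailability:
    """Probes present in the clock AND in every supplied tissue matrix.

    Mirrors the cross-tissue comparability rule: only clock probes available in
    all tissues (e.g. both CSF and blood) are retained, and the count of
    missing probes per clock is reported.
    """
    if not matrices:
        raise ValueError("at least one tissue matrix is required")
    available: set[str] | None = None
    for betas in matrices.values():
        probe_set = set(map(str, betas.index))
        available = probe_set if available is None else (available & probe_set)
    assert available is not None
    retained = tuple(p for p in clock.probes if p in available)
    missing = tuple(p for p in clock.probes if p not in available)
    return ProbeAvailability(clock=clock.name, retained=retained, missing=missing)


def _validate_betas(values: np.ndarray) -> None:
    if not np.isfinite(values).all():
        raise ValueError("beta matrix contains non-finite values")
    if (values < 0).any() or (values > 1).any():
        raise ValueError("beta values must lie in [0, 1]")


def linear_predictor(
    clock: ClockDefinition,
    betas: pd.DataFrame,
    probe_set: Iterable[str] | None = None,
) -> pd.Series:
    """Raw clock score per sample: ``m0 + sum_i mi * beta_i`` over ``probe_set``.

    With ``clock.standardize_per_sample``, each sample's betas over the probe
    set are centered and scaled (population SD) before the dot product.

    Returns a float Series indexed by sample ID, in the clock's internal units
    (apply the clock transform to obtain years).
    """
    probes = list(probe_set) if probe_set is not None else clock.probes
    if len(probes) == 0:
        raise ValueError("empty probe set")
    missing = [p for p in probes if p not in betas.index]
    if missing:
        raise MissingProbeError(
            f"probes absent from beta matrix: {missing[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    sub = betas.loc[probes].to_numpy(dtype=float)  # probes x samples
    _validate_betas(sub)
    coef = np.array([clock.coefficients[p] for p in probes], dtype=float)
    if clock.standardize_per_sample:
        mu = sub.mean(axis=0, keepdims=True)
        sd = sub.std(axis=0, keepdims=True)
        sd = np.where(sd == 0, 1.0, sd)
        sub = (sub - mu) / sd
    score = clock.intercept + coef @ sub
    return pd.Series(score, index=betas.columns, name=clock.name)


def horvath_inverse(x: float | np.ndarray, adult_age: float = 20.0) -> float | np.ndarray:
    """Map a Horvath-transformed score back to age in years.

    The Horvath clock regresses a transformed age F(age) on methylation, with
    F(a) = log(a+1) - log(A+1) for a <= A and F(a) = (a-A)/(A+1) above, A the
    "adult age" constant (20).  The inverse is::

        x <= 0:  (A+1) * exp(x) - 1
        x  > 0:  (A+1) * x + A

    which is continuous and strictly increasing in ``x``.
    """
    arr = np.asarray(x, dtype=float)
    if not np.isfinite(arr).all():
        raise ValueError("horvath_inverse requires finite input")
    out = np.where(arr <= 0, (adult_age + 1.0) * np.exp(arr) - 1.0, (adult_age + 1.0) * arr + adult_age)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    return out


def horvath_forward(age: float | np.ndarray, adult_age: float = 20.0) -> float | np.ndarray:
    """The Horvath age transformation F(age); inverse of :func:`horvath_inverse`."""
    arr = np.asarray(age, dtype=float)
    out = np.where(
        arr <= adult_age,
        np.log(arr + 1.0) - math.log(adult_age + 1.0),
        (arr - adult_age) / (adult_age + 1.0),
    )
    if np.isscalar(age) or arr.ndim == 0:
        return float(out)
    return out


def compute_dnam_age(
    clock: ClockDefinition,
    betas: pd.DataFrame,
    probe_policy: str = "drop_missing",
    tissue_matrices: Mapping[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Predicted DNAm age per sample, with probe-availability accounting.

    Parameters
    ----------
    probe_policy:
        * ``"drop_missing"`` — score over the clock probes present in ``betas``,
          logging the number dropped (the default; matches proceeding with a
          handful of missing probes rather than imputing).
        * ``"intersect_tissues"`` — restrict to probes present in every matrix
          of ``tissue_matrices`` (cross-tissue comparability).
        * ``"strict"`` — raise if any clock probe is absent.

    Returns
    -------
    DataFrame indexed by sample ID with columns ``clock``, ``dnam_age`` (years),
    ``n_probes_used`` and ``n_probes_missing``; the two counts always sum to
    the clock's probe count.
    """
    if probe_policy not in PROBE_POLICIES:
        raise ValueError(f"probe_policy must be one of {PROBE_POLICIES}")
    if probe_policy == "intersect_tissues":
        if not tissue_matrices:
            raise ValueError("intersect_tissues policy requires tissue_matrices")
        avail = intersect_probes(clock, tissue_matrices)
    else:
        avail = intersect_probes(clock, {"self": betas})
        if probe_policy == "strict" and avail.n_missing:
            raise MissingProbeError(
                f"clock {clock.name!r}: {avail.n_missing} probes missing under strict policy"
            )
    if avail.n_retained == 0:
        raise ValueError(f"clock {clock.name!r}: no probes available in the beta matrix")
    score = linear_predictor(clock, betas, avail.retained)
    if clock.transform == "horvath_inverse":
        years = horvath_inverse(score.to_numpy(), adult_age=clock.adult_age)
    else:
        years = score.to_numpy()
    return pd.DataFrame(
        {
            "clock": clock.name,
            "dnam_age": years,
            "n_probes_used": avail.n_retained,
            "n_probes_missing": avail.n_missing,
        },
        index=score.index.rename("sample_id"),
    )
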