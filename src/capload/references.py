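"""External growth/BP references and LMS z-scoring.

A reference distribution for one measurement and sex is represented by the
LMS model: at each age the distribution of the raw measurement ``x`` is
described by a skewness power L, median M and coefficient of variation S,
under which the standard deviation score (SDS) is

    z = ((x / M)**L - 1) / (L * S)      for L != 0
    z = ln(x / M) / S                   for L == 0

L, M and S are interpolated linearly in age between grid points.  With
L = 1 the model reduces to a Gaussian with mean M and SD M*S, which is how
the blood-pressure centile references are represented here.

References are stored in a plain CSV dialect with header
``measurement,sex,age,L,M,S`` (one row per grid point, UTF-8); the age unit
(weeks of gestation for birth measurements, postnatal months otherwise) is
carried in the container, declared by the writer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import TABLE1_MOMENTS, SEXES
from .exceptions import AgeRangeError, DomainError, SchemaError

__all__ = [
    "LMSReference",
    "ReferenceSet",
    "lms_zscore",
    "zscore_to_value",
    "bp_centile_cutoff",
    "read_reference_csv",
    "write_reference_csv",
    "synthetic_reference_set",
]


@dataclass(frozen=True)
class LMSReference:
    """One (measurement, sex) reference: L/M/S triples on an age grid."""

    measurement: str
    sex: str
    ages: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray
    age_unit: str = "months"

    def __post_init__(self) -> None:
        for name in ("ages", "L", "M", "S"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.sex not in SEXES:
            raise SchemaError(f"sex must be one of {SEXES}, got {self.sex!r}")
        n = self.ages.size
        if n < 2 or any(getattr(self, k).size != n for k in ("L", "M", "S")):
            raise SchemaError("ages, L, M, S must share length >= 2")
        if not np.all(np.diff(self.ages) > 0):
            raise SchemaError(f"{self.measurement}/{self.sex}: ages must be strictly increasing")
        if not (np.all(self.M > 0) and np.all(self.S > 0) and np.all(np.isfinite(self.L))):
            raise SchemaError(f"{self.measurement}/{self.sex}: require M > 0, S > 0, finite L")

    # -- interpolation ----------------------------------------------------
    def lms_at(self, age) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Linearly interpolated (L, M, S) at `age`; errors outside the grid."""
        a = np.asarray(age, dtype=float)
        lo, hi = self.ages[0], self.ages[-1]
        bad = (a < lo) | (a > hi) | ~np.isfinite(a)
        if np.any(bad):
            offending = np.atleast_1d(a)[np.atleast_1d(bad)][:5]
            raise AgeRangeError(
                f"{self.measurement}/{self.sex}: age(s) {offending.tolist()} outside "
                f"reference grid [{lo}, {hi}] {self.age_unit}; extrapolation is not performed"
            )
        return (
            np.interp(a, self.ages, self.L),
            np.interp(a, self.ages, self.M),
            np.interp(a, self.ages, self.S),
        )

    # -- transforms -------------------------------------------------------
    def zscore(self, x, age) -> np.ndarray:
        """SDS of raw measurement(s) ``x`` at ``age``; NaN passes through."""
        x = np.asarray(x, dtype=float)
        L, M, S = self.lms_at(age)
        missing = np.isnan(x)
        if np.any(x[~missing] <= 0):
            raise DomainError(
                f"{self.measurement}/{self.sex}: non-positive measurement in z-score input"
            )
        xs = np.where(missing, M, x)  # placeholder, masked back to NaN below
        # |L| below the threshold uses the L -> 0 (log) limit for stability
        safe_L = np.where(np.abs(L) < _L_EPS, 1.0, L)
        with np.errstate(divide="ignore", invalid="ignore"):
            z_gen = ((xs / M) ** safe_L - 1.0) / (safe_L * S)
            z_log = np.log(xs / M) / S
        z = np.where(np.abs(L) < _L_EPS, z_log, z_gen)
        z = np.where(missing, np.nan, z)
        return z if z.ndim else float(z)

    def value(self, z, age) -> np.ndarray:
        """Inverse transform: raw measurement whose SDS at ``age`` equals ``z``."""
        z = np.asarray(z, dtype=float)
        L, M, S = self.lms_at(age)
        missing = np.isnan(z)
        log_branch = np.abs(L) < _L_EPS
        base = 1.0 + L * S * np.where(missing, 0.0, z)
        invalid = (base <= 0) & ~log_branch & ~missing
        if np.any(invalid):
            zb = np.atleast_1d(z)[np.atleast_1d(invalid)][:5]
            raise DomainError(
                f"{self.measurement}/{self.sex}: inverse undefined for z = {zb.tolist()} "
                f"(1 + L*S*z <= 0)"
            )
        safe_L = np.where(log_branch, 1.0, L)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_gen = M * np.where(invalid, np.nan, base) ** (1.0 / safe_L)
            x_log = M * np.exp(S * np.where(missing, 0.0, z))
        x = np.where(log_branch, x_log, x_gen)
        x = np.where(missing, np.nan, x)
        return x if x.ndim else float(x)


def lms_zscore(x, age, sex: str, ref: LMSReference):
    """Convert raw measurement(s) to SDS against ``ref`` (must match ``sex``)."""
    if ref.sex != sex:
        raise SchemaError(f"reference is for sex={ref.sex!r}, asked for {sex!r}")
    return ref.zscore(x, age)


def zscore_to_value(z, age, sex: str, ref: LMSReference):
    """Invert an SDS back to the raw measurement scale."""
    if ref.sex != sex:
        raise SchemaError(f"reference is for sex={ref.sex!r}, asked for {sex!r}")
    return ref.value(z, age)


def bp_centile_cutoff(ref: LMSReference, centile: float, age, sex: str):
    """Raw threshold at a reference centile (e.g. the 95th BP centile).

    The cutoff is the raw value whose SDS equals the standard-normal
    quantile of ``centile``.
    """
    if not 0.0 < centile < 1.0:
        raise DomainError(f"centile must lie in (0, 1), got {centile}")
    return zscore_to_value(stats.norm.ppf(centile), age, sex, ref)


# ---------------------------------------------------------------------------
# container + CSV dialect
# ---------------------------------------------------------------------------

_L_EPS = 1e-7  # |L| below this uses the log-limit branch

REFERENCE_COLUMNS = ["measurement", "sex", "age", "L", "M", "S"]


@dataclass
class ReferenceSet:
    """All references of a study, keyed by (measurement, sex)."""

    tables: dict[tuple[str, str], LMSReference] = field(default_factory=dict)

    def add(self, ref: LMSReference) -> None:
        self.tables[(ref.measurement, ref.sex)] = ref

    def get(self, measurement: str, sex: str) -> LMSReference:
        try:
            return self.tables[(measurement, sex)]
        except KeyError:
            raise SchemaError(f"no reference for measurement={measurement!r}, sex={sex!r}")

    def __contains__(self, key) -> bool:
        return key in self.tables


def write_reference_csv(refs: ReferenceSet, path) -> None:
    rows = []
    for (meas, sex), ref in sorted(refs.tables.items()):
        for a, l, m, s in zip(ref.ages, ref.L, ref.M, ref.S):
            rows.append({"measurement": meas, "sex": sex, "age": a, "L": l, "M": m, "S": s})
    pd.DataFrame(rows, columns=REFERENCE_COLUMNS).to_csv(path, index=False)


def read_reference_csv(path, age_units: dict[str, str] | None = None) -> ReferenceSet:
    """Read the reference CSV dialect; ``age_units`` maps measurement -> unit."""
    df = pd.read_csv(path)
    missing = set(REFERENCE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"reference CSV missing columns: {sorted(missing)}")
    age_units = age_units or DEFAULT_AGE_UNITS
    refs = ReferenceSet()
    for (meas, sex), grp in df.groupby(["measurement", "sex"], sort=True):
        grp = grp.sort_values("age")
        refs.add(
            LMSReference(
                measurement=str(meas),
                sex=str(sex),
                ages=grp["age"].to_numpy(),
                L=grp["L"].to_numpy(),
                M=grp["M"].to_numpy(),
                S=grp["S"].to_numpy(),
                age_unit=age_units.get(str(meas), "months"),
            )
        )
    return refs


# ---------------------------------------------------------------------------
# synthetic reference fixture
# ---------------------------------------------------------------------------

#: which age axis each reference uses
DEFAULT_AGE_UNITS = {
    "weight_birth": "weeks_gestation",
    "length_birth": "weeks_gestation",
    "weight": "months",
    "height": "months",
    "sbp": "months",
    "dbp": "months",
    "pp": "months",
}

# per-week raw growth slopes near term for the birth references
_BIRTH_SLOPES = {"weight_birth": 0.16, "length_birth": 0.85}


def _linear_grid_ref(measurement, sex, ages, anchors, age_unit, L=1.0):
    """Reference whose M (and S) interpolate linearly through anchor points.

    anchors: list of (age, mean, sd); M(age) continues the line of the first
    /last anchor pair beyond the anchor range so the grid stays monotone.
    """
    ages = np.asarray(ages, dtype=float)
    an_age = np.array([a for a, _, _ in anchors])
    an_m = np.array([m for _, m, _ in anchors])
    an_cv = np.array([s / m for _, m, s in anchors])
    if an_age.size == 1:
        M = np.full_like(ages, an_m[0])
        S = np.full_like(ages, an_cv[0])
    else:
        slope_m = (an_m[-1] - an_m[0]) / (an_age[-1] - an_age[0])
        slope_cv = (an_cv[-1] - an_cv[0]) / (an_age[-1] - an_age[0])
        M = an_m[0] + slope_m * (ages - an_age[0])
        S = an_cv[0] + slope_cv * (ages - an_age[0])
    return LMSReference(measurement, sex, ages, np.full_like(ages, L), M, S, age_unit)


def synthetic_reference_set(moments: dict | None = None) -> ReferenceSet:
    """Smooth synthetic references anchored at the calibration moments.

    The references are Gaussian at each age (L = 1), with the median running
    linearly through the cohort's visit-age anchors, so that a child at the
    cohort mean for their sex scores SDS 0.  They stand in for the external
    published growth and BP references, which are not redistributable; real
    tables can be supplied in the same CSV dialect.
    """
    moments = moments or TABLE1_MOMENTS
    refs = ReferenceSet()
    ga_grid = np.arange(28.0, 45.0, 1.0)
    mo_grid = np.arange(48.0, 151.0, 6.0)
    for sex in SEXES:
        m = moments[sex]
        for meas, col in (("weight_birth", "bw_kg"), ("length_birth", "blen_cm")):
            mean, sd = m[col]
            slope = _BIRTH_SLOPES[meas]
            anchor_age = m["gest_age_wk"][0]
            # two synthetic anchors bracketing term, same CV
            anchors = [
                (anchor_age - 2, mean - 2 * slope, sd * (mean - 2 * slope) / mean),
                (anchor_age + 2, mean + 2 * slope, sd * (mean + 2 * slope) / mean),
            ]
            refs.add(_linear_grid_ref(meas, sex, ga_grid, anchors, "weeks_gestation"))
        a7, a9 = m["age7_mo"][0], m["age9_mo"][0]
        refs.add(_linear_grid_ref(
            "weight", sex, mo_grid,
            [(a7, *m["wt7_kg"]), (a9, *m["wt9_kg"])], "months"))
        refs.add(_linear_grid_ref(
            "height", sex, mo_grid,
            [(a7, *m["ht7_cm"]), (a9, *m["ht9_cm"])], "months"))
        for meas in ("sbp", "dbp", "pp"):
            refs.add(_linear_grid_ref(meas, sex, mo_grid, [(a9, *m[meas])], "months"))
    return refs


def demo_reference(measurement="weight", sex="male") -> LMSReference:
    """A small non-Gaussian reference (L varying, gentle S trend) for demos
    and for exercising the L != 1 branches."""
    ages = np.linspace(48.0, 150.0, 18)
    L = np.linspace(-0.4, -1.2, ages.size)
    M = 20.0 + 0.12 * (ages - 48.0)
    S = np.linspace(0.14, 0.21, ages.size)
    return LMSReference(measurement, sex, ages, L, M, S, "months")
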