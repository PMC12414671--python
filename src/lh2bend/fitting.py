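"""Three-regime fitting of decay-rate-versus-size data.

Measured (or synthetic) lifetime tables are fitted in rate space
(1/tau), the quantity the scaling laws predict, with weights propagated
from the lifetime uncertainties by the delta method.  The size axis is
partitioned into three regions:

* region 1 (large d): cocurvature law  1/tau = b + A / d^2,
* region 2 (intermediate): a plateau — the bending-stiffness regime,
* region 3 (small d): plate-deflection law
  1/tau = b + A rho^2 / (1 + 4 r0^2 / d^2)^3 with rho = c / d.

The public surface follows the model/results idiom: build a
:class:`LifetimeSizeModel` from a table (or DataFrame / CSV), call
``fit()``, and read estimates, uncertainties and diagnostics off the
returned :class:`LifetimeSizeResults`, whose ``summary()`` renders a
report table.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .lifetime import region3_geometry_factor

REQUIRED_COLUMNS = (
    "diameter_nm",
    "diameter_sd_nm",
    "tau_ns",
    "tau_sd_ns",
    "label",
)

DEFAULT_D_HIGH = 160.0
DEFAULT_D_LOW = 80.0
DEFAULT_RING_RADIUS = 3.8

#: documented boundary-scan grids (nm)
DEFAULT_D_HIGH_GRID = (120.0, 140.0, 160.0, 180.0, 200.0)
DEFAULT_D_LOW_GRID = (60.0, 70.0, 80.0, 90.0, 100.0)


class InsufficientDataError(ValueError):
    """Raised when a region holds too few points for its fit."""


@dataclass(frozen=True)
class LifetimeTable:
    """Records of (diameter, lifetime) with uncertainties and labels."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        frame = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"lifetime table missing columns: {missing}")
        if len(frame) and (frame["diameter_nm"] <= 0).any():
            raise ValueError("diameters must be positive")
        if len(frame) and (frame["tau_ns"] <= 0).any():
            raise ValueError("lifetimes must be positive")
        object.__setattr__(
            self, "data", frame.reset_index(drop=True).copy()
        )

    @classmethod
    def from_records(
        cls, records: Sequence[tuple], label: str = "LH2@SiO2"
    ) -> "LifetimeTable":
        """Build from (diameter, diameter_sd, tau, tau_sd[, label]) rows."""
        rows = []
        for rec in records:
            rec = list(rec)
            if len(rec) == 4:
                rec.append(label)
            rows.append(rec)
        return cls(pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS)))

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame) -> "LifetimeTable":
        return cls(frame)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def diameters(self) -> np.ndarray:
        return self.data["diameter_nm"].to_numpy(float)

    @property
    def rates(self) -> np.ndarray:
        """Decay rates 1/tau (ns^-1)."""
        return 1.0 / self.data["tau_ns"].to_numpy(float)

    @property
    def rate_variances(self) -> np.ndarray:
        """Delta-method variance of 1/tau from the tau uncertainties."""
        tau = self.data["tau_ns"].to_numpy(float)
        sd = self.data["tau_sd_ns"].to_numpy(float)
        return (sd / tau**2) ** 2

    def exclude_labels(self, labels: Sequence[str]) -> "LifetimeTable":
        mask = ~self.data["label"].isin(list(labels))
        return LifetimeTable(self.data[mask])


def segment_regions(
    table: LifetimeTable,
    d_high: float = DEFAULT_D_HIGH,
    d_low: float = DEFAULT_D_LOW,
) -> np.ndarray:
    """Region index (1, 2 or 3) per record by diameter.

    Region 1: d >= d_high; region 2: d_low <= d < d_high; region 3:
    d < d_low — boundary ties go to the larger-d region.  Empty regions
    raise a warning, not an error.
    """
    if not d_high > d_low > 0:
        raise ValueError("require d_high > d_low > 0")
    d = table.diameters
    region = np.where(d >= d_high, 1, np.where(d >= d_low, 2, 3))
    for r in (1, 2, 3):
        if not np.any(region == r):
            warnings.warn(f"region {r} holds no records", stacklevel=2)
    return region


def _weights(table: LifetimeTable, mask: np.ndarray) -> np.ndarray:
    var = table.rate_variances[mask]
    if np.all(var > 0):
        return 1.0 / var
    # no stated uncertainties -> unweighted
    return np.ones(mask.sum())


@dataclass
class Region1Fit:
    amplitude: float
    baseline: float
    amplitude_se: float
    baseline_se: float
    rss: float
    n: int


@dataclass
class PlateauFit:
    rate: float
    rate_se: float
    slope: float
    slope_se: float
    slope_p: float
    rss: float
    n: int


@dataclass
class Region3Fit:
    amplitude: float
    baseline: float
    charge_coefficient: float
    identifiable_product: float
    rss: float
    n: int
    n_starts: int
    converged: bool


def fit_region1(
    diameters: np.ndarray, rates: np.ndarray, weights: np.ndarray
) -> Region1Fit:
    """Weighted, non-negativity-bounded fit of 1/tau = b + A / d^2."""
    d = np.asarray(diameters, float)
    y = np.asarray(rates, float)
    w = np.asarray(weights, float)
    if d.size < 3:
        raise InsufficientDataError(
            f"region-1 fit needs >= 3 points, got {d.size}"
        )
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(d), d**-2])
    # scale columns to O(1) so the bounded solver converges tightly
    scale = design.max(axis=0)
    scaled = design / scale
    coef, *_ = np.linalg.lstsq(scaled * sw[:, None], y * sw, rcond=None)
    round_off = 1e-9 * max(1.0, float(np.abs(coef).max()))
    if np.all(coef >= -round_off):
        x = np.clip(coef, 0.0, None) / scale
    else:
        res = optimize.lsq_linear(
            scaled * sw[:, None], y * sw, bounds=(0.0, np.inf), tol=1e-14
        )
        x = res.x / scale
    baseline, amplitude = x
    resid = (y - design @ x) * sw
    rss = float(resid @ resid)
    dof = max(d.size - 2, 1)
    try:
        cov = np.linalg.inv(design.T @ (design * w[:, None])) * (rss / dof)
        baseline_se, amplitude_se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate design
        baseline_se = amplitude_se = math.nan
    return Region1Fit(
        amplitude=float(amplitude),
        baseline=float(baseline),
        amplitude_se=float(amplitude_se),
        baseline_se=float(baseline_se),
        rss=rss,
        n=int(d.size),
    )


def fit_region2_plateau(
    diameters: np.ndarray, rates: np.ndarray, weights: np.ndarray
) -> PlateauFit:
    """Weighted mean rate with a slope-versus-size test.

    The standard error of the plateau uses the stated weights directly
    (1/sqrt(sum w)); the slope of a weighted straight-line fit in d, with
    its p-value, makes the "plateau" claim checkable.
    """
    d = np.asarray(diameters, float)
    y = np.asarray(rates, float)
    w = np.asarray(weights, float)
    if d.size < 2:
        raise InsufficientDataError(
            f"plateau fit needs >= 2 points, got {d.size}"
        )
    plateau = float(np.sum(w * y) / np.sum(w))
    rate_se = float(1.0 / math.sqrt(np.sum(w)))
    resid = y - plateau
    rss = float(np.sum(w * resid**2))
    slope = slope_se = slope_p = math.nan
    if d.size >= 3 and np.ptp(d) > 0:
        import statsmodels.api as sm

        wls = sm.WLS(y, sm.add_constant(d), weights=w).fit()
        slope = float(wls.params[1])
        slope_se = float(wls.bse[1])
        slope_p = float(wls.pvalues[1])
    return PlateauFit(
        rate=plateau,
        rate_se=rate_se,
        slope=slope,
        slope_se=slope_se,
        slope_p=slope_p,
        rss=rss,
        n=int(d.size),
    )


def _region3_model(
    d: np.ndarray, amplitude: float, charge_coefficient: float, baseline: float,
    r0: float,
) -> np.ndarray:
    rho = charge_coefficient / d
    return baseline + amplitude * rho**2 * region3_geometry_factor(d, r0)


def fit_region3(
    diameters: np.ndarray,
    rates: np.ndarray,
    weights: np.ndarray,
    r0: float = DEFAULT_RING_RADIUS,
) -> Region3Fit:
    """Bounded nonlinear fit of the plate-deflection law with rho = c/d.

    A deterministic multistart grid (amplitude scale x {0.3, 1, 3},
    charge coefficient {0.5, 1, 2}, baseline {0, 0.9 min rate}) seeds
    trust-region least squares; the lowest-cost convergent start wins.
    ``amplitude`` and ``charge_coefficient`` are only jointly identifiable
    through ``amplitude * charge_coefficient^2``, which is reported as
    ``identifiable_product``.
    """
    d = np.asarray(diameters, float)
    y = np.asarray(rates, float)
    w = np.asarray(weights, float)
    if d.size < 4:
        raise InsufficientDataError(
            f"region-3 fit needs >= 4 points, got {d.size}"
        )
    sw = np.sqrt(w)

    def residuals(x: np.ndarray) -> np.ndarray:
        return (_region3_model(d, x[0], x[1], x[2], r0) - y) * sw

    shape = d**-2 * region3_geometry_factor(d, r0)
    spread = max(y.max() - y.min(), 1e-12)
    amp_scale = spread / shape.max()
    starts = [
        (amp_scale * m, c, b)
        for m in (0.3, 1.0, 3.0)
        for c in (0.5, 1.0, 2.0)
        for b in (0.0, 0.9 * y.min())
    ]
    best = None
    diagnostics = []
    for x0 in starts:
        try:
            sol = optimize.least_squares(
                residuals,
                x0=np.asarray(x0, float),
                bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            )
        except Exception as exc:  # pragma: no cover - solver failure path
            diagnostics.append(f"start {x0}: {exc}")
            continue
        if not sol.success:
            diagnostics.append(f"start {x0}: {sol.message}")
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            "region-3 fit failed to converge from any start; "
            + "; ".join(diagnostics)
        )
    amplitude, charge, baseline = best.x
    return Region3Fit(
        amplitude=float(amplitude),
        baseline=float(baseline),
        charge_coefficient=float(charge),
        identifiable_product=float(amplitude * charge**2),
        rss=float(2.0 * best.cost),
        n=int(d.size),
        n_starts=len(starts),
        converged=True,
    )


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------


@dataclass
class LifetimeSizeResults:
    """Fit results of the three-regime decay-rate model."""

    d_high: float
    d_low: float
    r0: float
    region1: Region1Fit | None
    plateau: PlateauFit | None
    region3: Region3Fit | None
    missing_regions: tuple[int, ...]
    total_rss: float
    n_obs: int
    scan_table: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        def _clean(obj):
            if obj is None:
                return None
            return {
                k: (None if isinstance(v, float) and math.isnan(v) else v)
                for k, v in vars(obj).items()
            }

        return {
            "boundaries_nm": {"d_high": self.d_high, "d_low": self.d_low},
            "r0_nm": self.r0,
            "region1": _clean(self.region1),
            "region2_plateau": _clean(self.plateau),
            "region3": _clean(self.region3),
            "missing_regions": list(self.missing_regions),
            "total_rss": self.total_rss,
            "n_obs": self.n_obs,
        }

    def summary(self) -> str:
        lines = [
            "Three-regime decay-rate fit (1/tau vs particle size)",
            "=" * 56,
            f"observations: {self.n_obs}   boundaries: "
            f"d_high = {self.d_high:g} nm, d_low = {self.d_low:g} nm",
        ]
        if self.region1:
            r = self.region1
            lines += [
                "-" * 56,
                f"region 1 (d >= {self.d_high:g} nm): "
                "1/tau = b + A/d^2",
                f"  A = {r.amplitude:.6g} +/- {r.amplitude_se:.2g} ns^-1 nm^2",
                f"  b = {r.baseline:.6g} +/- {r.baseline_se:.2g} ns^-1"
                f"   (n = {r.n}, RSS = {r.rss:.3g})",
            ]
        if self.plateau:
            p = self.plateau
            lines += [
                "-" * 56,
                f"region 2 ({self.d_low:g}-{self.d_high:g} nm): plateau",
                f"  rate = {p.rate:.6g} +/- {p.rate_se:.2g} ns^-1"
                f"   (n = {p.n}, RSS = {p.rss:.3g})",
                f"  slope test: {p.slope:.3g} +/- {p.slope_se:.2g} "
                f"ns^-1/nm, p = {p.slope_p:.3g}",
            ]
        if self.region3:
            r = self.region3
            lines += [
                "-" * 56,
                f"region 3 (d < {self.d_low:g} nm): "
                "1/tau = b + A rho^2/(1+4 r0^2/d^2)^3, rho = c/d",
                f"  A c^2 = {r.identifiable_product:.6g} ns^-1 nm^2 "
                "(identifiable product)",
                f"  b = {r.baseline:.6g} ns^-1   (n = {r.n}, "
                f"RSS = {r.rss:.3g}, starts = {r.n_starts})",
            ]
        if self.missing_regions:
            lines += [
                "-" * 56,
                "missing regions: "
                + ", ".join(str(r) for r in self.missing_regions),
            ]
        lines.append("=" * 56)
        return "\n".join(lines)


class LifetimeSizeModel:
    """Three-regime model of B850 decay rate versus particle size.

    Parameters
    ----------
    table
        A :class:`LifetimeTable` (or DataFrame with the standard columns).
    d_high, d_low
        Region boundaries (nm); defaults 160 and 80.
    r0
        Ring radius (nm) entering the region-3 geometry factor.
    exclude_labels
        Record labels excluded from the fits (liposome overlays by
        default); they are carried in the table but not fitted.
    """

    def __init__(
        self,
        table: LifetimeTable | pd.DataFrame,
        d_high: float = DEFAULT_D_HIGH,
        d_low: float = DEFAULT_D_LOW,
        r0: float = DEFAULT_RING_RADIUS,
        exclude_labels: Sequence[str] = ("LH2-L",),
    ) -> None:
        if isinstance(table, pd.DataFrame):
            table = LifetimeTable(table)
        self.full_table = table
        self.table = table.exclude_labels(exclude_labels)
        if not d_high > d_low > 0:
            raise ValueError("require d_high > d_low > 0")
        self.d_high = float(d_high)
        self.d_low = float(d_low)
        self.r0 = float(r0)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "LifetimeSizeModel":
        from .io import read_lifetime_table

        return cls(read_lifetime_table(path), **kwargs)

    # -- fitting -----------------------------------------------------------

    def _fit_at(
        self, d_high: float, d_low: float, warn_empty: bool
    ) -> LifetimeSizeResults:
        table = self.table
        d = table.diameters
        rates = table.rates
        if warn_empty:
            region = segment_regions(table, d_high, d_low)
        else:
            region = np.where(d >= d_high, 1, np.where(d >= d_low, 2, 3))

        fits: dict[int, object] = {}
        missing = []
        total_rss = 0.0
        for idx, fitter, min_n in (
            (1, fit_region1, 3),
            (2, fit_region2_plateau, 2),
            (3, lambda dd, yy, ww: fit_region3(dd, yy, ww, self.r0), 4),
        ):
            mask = region == idx
            if mask.sum() < min_n:
                missing.append(idx)
                fits[idx] = None
                continue
            fits[idx] = fitter(d[mask], rates[mask], _weights(table, mask))
            total_rss += fits[idx].rss
        return LifetimeSizeResults(
            d_high=d_high,
            d_low=d_low,
            r0=self.r0,
            region1=fits[1],
            plateau=fits[2],
            region3=fits[3],
            missing_regions=tuple(missing),
            total_rss=total_rss,
            n_obs=len(table),
        )

    def fit(
        self,
        scan_boundaries: bool = False,
        d_high_grid: Sequence[float] = DEFAULT_D_HIGH_GRID,
        d_low_grid: Sequence[float] = DEFAULT_D_LOW_GRID,
        rss_tolerance: float = 0.5,
    ) -> LifetimeSizeResults:
        """Fit the three regions; optionally re-estimate the boundaries.

        With ``scan_boundaries`` the (d_high, d_low) pair is chosen from
        the documented deterministic grids by total weighted RSS over
        partitions where all three regions are fittable.  Because the
        region-1 and region-3 laws both nest a constant, shrinking the
        plateau can only lower the RSS by letting their extra parameters
        absorb noise; the scan therefore treats partitions whose total
        RSS lies within ``rss_tolerance`` times the minimum's per-point
        variance scale (rss_min / dof) of the minimum as ties and
        resolves them parsimoniously — the widest plateau wins (largest
        d_high, then smallest d_low).  Noise-free data has a zero scale,
        so the exact minimizer is returned.
        """
        if not scan_boundaries:
            return self._fit_at(self.d_high, self.d_low, warn_empty=True)

        rows = []
        fits: dict[tuple[float, float], LifetimeSizeResults] = {}
        for dh in d_high_grid:
            for dl in d_low_grid:
                if not dh > dl:
                    continue
                try:
                    res = self._fit_at(float(dh), float(dl), warn_empty=False)
                except (InsufficientDataError, RuntimeError):
                    continue
                if res.missing_regions:
                    continue
                rows.append(
                    {"d_high": dh, "d_low": dl, "total_rss": res.total_rss}
                )
                fits[(float(dh), float(dl))] = res
        if not fits:
            raise RuntimeError(
                "boundary scan found no partition with all regions fittable"
            )
        rss_min = min(r.total_rss for r in fits.values())
        dof = max(len(self.table) - 6, 1)
        tol = rss_tolerance * rss_min / dof
        tied = [
            key
            for key, r in fits.items()
            if r.total_rss <= rss_min + tol
        ]
        dh_best, dl_best = max(tied, key=lambda k: (k[0], -k[1]))
        best = fits[(dh_best, dl_best)]
        best.scan_table = pd.DataFrame(rows)
        return best
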