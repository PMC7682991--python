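"""Isotropic vs linear growth-model analysis of per-oligomer CCS series.

An unstructured (globular) aggregate grows isotropically:
Omega(n) = Omega_ref * (n / n_ref)^(2/3), volume-to-area scaling anchored at
a reference oligomer (the dimer by default).  Fibrillar stacking adds a
constant cross-section increment per monomer: Omega(n) = a + b*n.  The
analysis locates the order n* at which a CCS series departs from the
isotropic curve, and compares two series (compact vs large-CCS families):
equal slopes with different intercepts is the signature of the same
stacking unit on a different base — monomer-based (MB) vs dimer-based (DB).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel returned when a series never leaves the isotropic curve.
NO_CROSSOVER = -1


@dataclass
class CCSSeries:
    """Per-oligomer mean CCS with uncertainties, tagged MB/DB/untagged."""

    n: np.ndarray
    ccs_a2: np.ndarray
    sigma: np.ndarray | None = None
    tag: str = "untagged"
    charge_states: list[tuple[int, ...]] | None = None

    def __post_init__(self) -> None:
        self.n = np.asarray(self.n, dtype=int)
        self.ccs_a2 = np.asarray(self.ccs_a2, dtype=float)
        if np.any(np.diff(self.n) <= 0):
            raise ValueError("oligomer orders must be strictly increasing")
        if np.any(self.ccs_a2 <= 0):
            raise ValueError("CCS values must be positive")
        if self.sigma is None:
            self.sigma = np.zeros_like(self.ccs_a2)
        else:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.sigma) != len(self.n) or len(self.ccs_a2) != len(self.n):
            raise ValueError("series arrays must have equal length")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"n": self.n, "ccs_a2": self.ccs_a2, "sigma": self.sigma, "tag": self.tag}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CCSSeries":
        df = pd.read_csv(path)
        tag = str(df["tag"].iloc[0]) if "tag" in df else "untagged"
        return cls(
            n=df["n"].to_numpy(),
            ccs_a2=df["ccs_a2"].to_numpy(),
            sigma=df["sigma"].to_numpy() if "sigma" in df else None,
            tag=tag,
        )


@dataclass
class LinearFit:
    slope: float  # Angstrom^2 per added monomer
    intercept: float  # Angstrom^2
    cov: np.ndarray  # 2x2 covariance of (slope, intercept)
    flags: list[str] = field(default_factory=list)


@dataclass
class GrowthFitResult:
    n_ref: int
    ccs_ref: float
    linear: LinearFit
    isotropic_residuals: np.ndarray
    linear_residuals: np.ndarray
    crossover: int  # n*, or NO_CROSSOVER


def isotropic_model(n, n_ref: int, ccs_ref: float):
    """Isotropic growth: Omega = Omega_ref * (n/n_ref)^(2/3)."""
    if n_ref < 1 or ccs_ref <= 0:
        raise ValueError("reference order and CCS must be positive")
    return ccs_ref * (np.asarray(n, dtype=float) / n_ref) ** (2.0 / 3.0)


def fit_linear(series: CCSSeries, n_min: int = 1) -> LinearFit:
    """Weighted least squares (weights 1/sigma^2) of CCS on n over n >= n_min."""
    mask = series.n >= n_min
    n = series.n[mask].astype(float)
    y = series.ccs_a2[mask]
    sig = series.sigma[mask]
    if len(n) < 2:
        raise ValueError(f"need >= 2 points with n >= {n_min}")
    flags = []
    if np.all(sig > 0):
        w = 1.0 / sig**2
    else:
        w = np.ones_like(y)
    X = np.column_stack([n, np.ones_like(n)])
    W = np.diag(w)
    xtwx = X.T @ W @ X
    beta = np.linalg.solve(xtwx, X.T @ W @ y)
    if len(n) == 2:
        flags.append("interpolating-two-points")
        warnings.warn("linear fit on two points: interpolating line, variance unbounded")
        cov = np.full((2, 2), np.inf)
    elif np.all(sig > 0):
        cov = np.linalg.inv(xtwx)  # sigma treated as known absolute errors
    else:
        resid = y - X @ beta
        s2 = float(resid @ resid) / (len(n) - 2)
        cov = np.linalg.inv(X.T @ X) * s2
    return LinearFit(slope=float(beta[0]), intercept=float(beta[1]), cov=cov, flags=flags)


def two_regime_ccs_law(
    n, ccs_dimer: float = 700.0, slope: float = 400.0
) -> np.ndarray:
    """Canonical two-regime growth law: isotropic from the dimer up to the
    tetramer, then linear with ``slope`` per monomer, continuous at n = 4 —
    the constructed analog of a series that departs cleanly from isotropic
    growth above the tetramer."""
    n = np.asarray(n, dtype=float)
    iso = isotropic_model(n, 2, ccs_dimer)
    ccs4 = isotropic_model(4, 2, ccs_dimer)
    return np.where(n <= 4, iso, ccs4 + slope * (n - 4))


def detect_crossover(
    series: CCSSeries,
    n_ref: int = 2,
    tolerance_sigma: float = 2.5,
    sigma_floor_rel: float = 1e-9,
) -> GrowthFitResult:
    """Locate the order n* where growth departs from the isotropic model.

    n* is the largest order such that every order up to it stays within
    ``tolerance_sigma`` effective standard deviations of the isotropic
    curve anchored at (n_ref, Omega(n_ref)) — "effective" because the
    anchor's own uncertainty propagates into the prediction at each order;
    all orders above n* must fit the linear model better (smaller absolute
    residual) or :data:`NO_CROSSOVER` is returned.
    """
    if len(series.n) < 4:
        raise ValueError("need at least 4 oligomer orders")
    if n_ref not in series.n:
        raise ValueError(f"reference order {n_ref} not in series")
    ccs_ref = float(series.ccs_a2[series.n == n_ref][0])
    iso = isotropic_model(series.n, n_ref, ccs_ref)
    iso_resid = series.ccs_a2 - iso
    sig = np.maximum(series.sigma, sigma_floor_rel * series.ccs_a2)
    sigma_ref = float(sig[series.n == n_ref][0])
    scaling = (series.n / n_ref) ** (2.0 / 3.0)
    sig_eff = np.sqrt(sig**2 + (scaling * sigma_ref) ** 2)
    sig_eff[series.n == n_ref] = sig[series.n == n_ref]

    within = np.abs(iso_resid) <= tolerance_sigma * sig_eff
    # longest all-within prefix over orders >= n_ref
    considered = series.n >= n_ref
    n_star = n_ref
    for n_i, ok in zip(series.n[considered], within[considered]):
        if not ok:
            break
        n_star = int(n_i)

    if n_star >= series.n.max():
        lin = fit_linear(series, n_min=n_ref)
        lin_resid = series.ccs_a2 - (lin.slope * series.n + lin.intercept)
        return GrowthFitResult(
            n_ref, ccs_ref, lin, iso_resid, lin_resid, NO_CROSSOVER
        )

    lin = fit_linear(series, n_min=n_star)
    lin_resid = series.ccs_a2 - (lin.slope * series.n + lin.intercept)
    above = series.n > n_star
    if not np.all(np.abs(lin_resid[above]) <= np.abs(iso_resid[above]) + 1e-12):
        return GrowthFitResult(n_ref, ccs_ref, lin, iso_resid, lin_resid, NO_CROSSOVER)
    return GrowthFitResult(n_ref, ccs_ref, lin, iso_resid, lin_resid, int(n_star))


@dataclass
class SeriesComparison:
    delta_slope: float
    delta_slope_ci: tuple[float, float]
    delta_intercept: float
    delta_intercept_ci: tuple[float, float]
    common_range: tuple[int, int]
    mb_db_signature: bool  # equal slopes, distinct intercepts


def compare_series(
    mb: CCSSeries,
    db: CCSSeries,
    n_min: int | None = None,
    z_crit: float = 1.96,
) -> SeriesComparison:
    """Slope/intercept comparison of two CCS series over their common range.

    Reports Delta-slope and Delta-intercept with normal-approximation CIs
    and whether the slope CI contains zero while the intercept CI excludes
    it — the signature of the same stacking unit growing on different bases.
    """
    lo = max(mb.n.min(), db.n.min())
    hi = min(mb.n.max(), db.n.max())
    if lo > hi:
        raise ValueError("series have no overlapping oligomer range")
    if n_min is not None:
        lo = max(lo, n_min)

    def restrict(s: CCSSeries) -> CCSSeries:
        mask = (s.n >= lo) & (s.n <= hi)
        return CCSSeries(s.n[mask], s.ccs_a2[mask], s.sigma[mask], s.tag)

    fit_a = fit_linear(restrict(mb))
    fit_b = fit_linear(restrict(db))
    d_slope = fit_b.slope - fit_a.slope
    d_int = fit_b.intercept - fit_a.intercept
    var_slope = fit_a.cov[0, 0] + fit_b.cov[0, 0]
    var_int = fit_a.cov[1, 1] + fit_b.cov[1, 1]
    hw_slope = z_crit * math.sqrt(var_slope) if np.isfinite(var_slope) else math.inf
    hw_int = z_crit * math.sqrt(var_int) if np.isfinite(var_int) else math.inf
    ci_slope = (d_slope - hw_slope, d_slope + hw_slope)
    ci_int = (d_int - hw_int, d_int + hw_int)
    signature = (ci_slope[0] <= 0.0 <= ci_slope[1]) and not (
        ci_int[0] <= 0.0 <= ci_int[1]
    )
    return SeriesComparison(
        delta_slope=d_slope,
        delta_slope_ci=ci_slope,
        delta_intercept=d_int,
        delta_intercept_ci=ci_int,
        common_range=(int(lo), int(hi)),
        mb_db_signature=signature,
    )


def series_from_features(
    groups: dict,
    ccs_by_feature: dict,
    family: str = "MB",
) -> CCSSeries:
    """Collapse per-feature CCS values into one series per conformer family:
    mean over charge states, standard deviation as sigma."""
    per_n: dict[int, list[float]] = {}
    zs: dict[int, list[int]] = {}
    for (n, z), group in groups.items():
        for feat in group["features"]:
            if feat.conformer == family and id(feat) in ccs_by_feature:
                per_n.setdefault(n, []).append(ccs_by_feature[id(feat)])
                zs.setdefault(n, []).append(z)
    if not per_n:
        raise ValueError(f"no features labeled {family}")
    orders = sorted(per_n)
    means = [float(np.mean(per_n[n])) for n in orders]
    sigmas = [
        float(np.std(per_n[n], ddof=1)) if len(per_n[n]) > 1 else 0.0 for n in orders
    ]
    return CCSSeries(
        n=np.array(orders),
        ccs_a2=np.array(means),
        sigma=np.array(sigmas),
        tag=family,
        charge_states=[tuple(sorted(zs[n])) for n in orders],
    )
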