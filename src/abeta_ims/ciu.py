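"""Collision-induced unfolding (CIU) and dissociation (CID) analysis.

Collisional activation is ramped as trap voltage; the relevant scale is the
lab-frame energy E = z * V, which puts oligomers of different charge on a
common axis.  A CIU transition is a logistic rise of the extended
(unfolded) fraction with its own amplitude cap — a ligand-stabilized ion
may dissociate before ever reaching 50% absolute unfolding, so "50% CIU" is
read against the transition's own amplitude, with the absolute convention
reported alongside.  A CID transition is a logistic fall of total survival.
The energy-gap analysis looks for a change in the per-oligomer stability
increment: a two-segment constant-gap fit over first differences of E50.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit


def lab_frame_energy(trap_voltage: float, z: int) -> float:
    """Lab-frame collision energy E = z * V (eV)."""
    if trap_voltage <= 0 or z <= 0:
        raise ValueError("voltage and charge must be positive")
    return z * trap_voltage


@dataclass
class StabilityCurve:
    """Per-energy compact/extended/dissociated fractions for one ion."""

    energy_ev: np.ndarray
    compact: np.ndarray
    extended: np.ndarray
    species: tuple[int, int] = (0, 0)  # (n, z)
    ligand: str = "free"

    def __post_init__(self) -> None:
        self.energy_ev = np.asarray(self.energy_ev, dtype=float)
        self.compact = np.asarray(self.compact, dtype=float)
        self.extended = np.asarray(self.extended, dtype=float)
        if np.any(np.diff(self.energy_ev) <= 0):
            raise ValueError("energies must be increasing")
        for frac in (self.compact, self.extended):
            if np.any(frac < 0):
                raise ValueError("fractions must be >= 0")
        if np.any(self.compact + self.extended > 1.0 + 1e-6):
            raise ValueError("fractions must sum to <= 1")

    @property
    def surviving(self) -> np.ndarray:
        return self.compact + self.extended

    @property
    def dissociated(self) -> np.ndarray:
        return 1.0 - self.surviving

    @classmethod
    def from_series(
        cls, series: pd.DataFrame, species=(0, 0), ligand: str = "free"
    ) -> "StabilityCurve":
        """Adapt the generator's (energy_ev, folded, unfolded, surviving)
        table."""
        return cls(
            energy_ev=series["energy_ev"].to_numpy(),
            compact=series["folded"].to_numpy(),
            extended=series["unfolded"].to_numpy(),
            species=species,
            ligand=ligand,
        )


@dataclass
class TransitionFit:
    """Fitted midpoint/width/cap of one CIU or CID transition."""

    kind: str  # "CIU" | "CID"
    e50_ev: float  # energy of half the transition's own amplitude
    width_ev: float
    cap: float
    e50_se: float = 0.0
    e50_absolute_ev: float | None = None  # energy of absolute 50%; None if never reached
    cov: np.ndarray | None = None
    species: tuple[int, int] = (0, 0)
    ligand: str = "free"
    flags: list[str] = field(default_factory=list)

    @property
    def cap_limited(self) -> bool:
        return "cap-limited" in self.flags


def _rise(e, e50, width, cap):
    return cap / (1.0 + np.exp(-(e - e50) / width))


def _fall(e, e50, width):
    return 1.0 / (1.0 + np.exp((e - e50) / width))


def fit_transition(
    curve: StabilityCurve,
    kind: str = "CIU",
    n_bootstrap: int = 200,
    seed: int = 0,
    min_amplitude: float = 0.02,
    min_survival: float = 0.05,
) -> TransitionFit:
    """Fit a logistic transition to a stability curve.

    CIU fits the unfolded share of the *surviving* population (extended /
    surviving, the per-energy fingerprint normalization — dissociation must
    not masquerade as refolding) as a capped logistic rise; energies where
    survival has dropped below ``min_survival`` carry no conformational
    information and are excluded.  CID fits total survival as a logistic
    fall.  E50 is the midpoint parameter (half of the transition's own
    amplitude); the energy where the absolute 50% level is crossed is
    reported alongside and is ``None`` for cap-limited transitions
    (cap < 0.5).  Uncertainty on E50 comes from a seeded nonparametric
    bootstrap over energy points.
    """
    if kind not in ("CIU", "CID"):
        raise ValueError("kind must be 'CIU' or 'CID'")
    e = curve.energy_ev
    if len(e) < 5:
        raise ValueError("need at least 5 energy points")
    if kind == "CIU":
        alive = curve.surviving >= min_survival
        with np.errstate(invalid="ignore", divide="ignore"):
            share = np.where(
                curve.surviving > 0, curve.extended / np.maximum(curve.surviving, 1e-12), 0.0
            )
        if alive.sum() < 5:
            # the ion dissociates across most of the ramp; if it never
            # unfolded while alive, that is the "no CIU" phenotype
            if share[alive].max(initial=0.0) < min_amplitude:
                return TransitionFit(
                    kind=kind,
                    e50_ev=math.nan,
                    width_ev=math.nan,
                    cap=float(share[alive].max(initial=0.0)),
                    species=curve.species,
                    ligand=curve.ligand,
                    flags=["absent"],
                )
            raise ValueError("fewer than 5 energy points with measurable survival")
        e = e[alive]
        y = share[alive]
    else:
        y = curve.surviving
        if np.all(y == 0):
            raise ValueError("all-zero survival signal")
    flags: list[str] = []

    signal_span = float(y.max() - y.min())
    if kind == "CIU" and y.max() < min_amplitude:
        return TransitionFit(
            kind=kind,
            e50_ev=math.nan,
            width_ev=math.nan,
            cap=float(y.max()),
            species=curve.species,
            ligand=curve.ligand,
            flags=["absent"],
        )
    diffs = np.diff(y)
    expected_sign = 1.0 if kind == "CIU" else -1.0
    backwards = float(np.clip(expected_sign * diffs, None, 0.0).sum())
    if abs(backwards) > 0.15 * max(signal_span, 1e-9):
        flags.append("non-monotone")
        warnings.warn(f"{kind} signal is non-monotone beyond noise tolerance")

    span = e[-1] - e[0]

    def do_fit(ee, yy):
        if kind == "CIU":
            cap0 = min(1.0, float(yy.max()))
            e50_0 = float(ee[np.argmin(np.abs(yy - cap0 / 2))])
            popt, pcov = curve_fit(
                _rise,
                ee,
                yy,
                p0=[e50_0, span / 10.0, max(cap0, 0.05)],
                bounds=([ee[0] - span, 1e-3, 1e-3], [ee[-1] + span, span, 1.2]),
                maxfev=20000,
            )
            return popt, pcov
        e50_0 = float(ee[np.argmin(np.abs(yy - 0.5))])
        popt, pcov = curve_fit(
            _fall,
            ee,
            yy,
            p0=[e50_0, span / 10.0],
            bounds=([ee[0] - span, 1e-3], [ee[-1] + span, span]),
            maxfev=20000,
        )
        return popt, pcov

    popt, pcov = do_fit(e, y)
    if kind == "CIU":
        e50, width, cap = popt
    else:
        (e50, width), cap = popt, 1.0

    if cap < 0.5:
        flags.append("cap-limited")
        e50_abs = None
    else:
        # energy where the absolute 50% level is crossed
        if kind == "CIU":
            e50_abs = float(e50 + width * math.log(2.0 * cap - 1.0)) if cap > 0.5 else float(e50)
        else:
            e50_abs = float(e50)

    e50_se = 0.0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        estimates = []
        idx_all = np.arange(len(e))
        for _ in range(n_bootstrap):
            idx = np.sort(rng.choice(idx_all, size=len(e), replace=True))
            try:
                p, _ = do_fit(e[idx], y[idx])
                estimates.append(p[0])
            except RuntimeError:
                continue
        if len(estimates) > 1:
            e50_se = float(np.std(estimates, ddof=1))

    return TransitionFit(
        kind=kind,
        e50_ev=float(e50),
        width_ev=float(width),
        cap=float(cap),
        e50_se=e50_se,
        e50_absolute_ev=e50_abs,
        cov=pcov,
        species=curve.species,
        ligand=curve.ligand,
        flags=flags,
    )


@dataclass
class GapAnalysis:
    """Two-segment constant-gap summary of E50 vs oligomer order."""

    breakpoint_order: int | None  # last order of the first regime
    gap_low_ev: float  # mean gap up to the breakpoint
    gap_high_ev: float  # mean gap above it
    sse: float
    degenerate: bool  # no breakpoint improves on a single constant gap


def gap_analysis(e50_by_order: dict[int, float]) -> GapAnalysis:
    """Fit two constant energy gaps with one breakpoint to E50 first
    differences, by exhaustive search over interior split positions."""
    orders = sorted(e50_by_order)
    if len(orders) < 4:
        raise ValueError("need at least 4 oligomer orders")
    if orders != list(range(orders[0], orders[-1] + 1)):
        raise ValueError("orders must be consecutive")
    e50 = np.array([e50_by_order[n] for n in orders])
    gaps = np.diff(e50)  # gap[i] is the step from orders[i] to orders[i+1]

    def sse_of(values: np.ndarray) -> float:
        return float(((values - values.mean()) ** 2).sum()) if len(values) else 0.0

    single_sse = sse_of(gaps)
    best = None
    for split in range(1, len(gaps)):  # split gaps into [:split], [split:]
        sse = sse_of(gaps[:split]) + sse_of(gaps[split:])
        if best is None or sse < best[0]:
            best = (sse, split)
    sse, split = best
    if single_sse - sse <= 1e-12 * max(single_sse, 1.0):
        return GapAnalysis(
            breakpoint_order=None,
            gap_low_ev=float(gaps.mean()),
            gap_high_ev=float(gaps.mean()),
            sse=single_sse,
            degenerate=True,
        )
    return GapAnalysis(
        breakpoint_order=int(orders[split]),
        gap_low_ev=float(gaps[:split].mean()),
        gap_high_ev=float(gaps[split:].mean()),
        sse=sse,
        degenerate=False,
    )


@dataclass
class BoundFreeComparison:
    delta_e50_ev: float
    delta_e50_se: float
    classes: list[str]


def compare_bound_free(
    free: TransitionFit, bound: TransitionFit, threshold_ev: float = 5.0
) -> BoundFreeComparison:
    """Ligand-bound vs free transition shift, with qualitative classes:
    "CID-stabilized" (bound needs more energy to dissociate),
    "CIU-suppressed (cap-limited)" (ligand blocks unfolding before CID),
    "unchanged" otherwise."""
    if free.kind != bound.kind:
        raise ValueError("cannot compare transitions of different kinds")
    if free.species != bound.species:
        raise ValueError(
            f"species mismatch: {free.species} vs {bound.species}"
        )
    classes: list[str] = []
    if bound.cap_limited and not free.cap_limited:
        classes.append("CIU-suppressed (cap-limited)")
        delta = math.nan
        se = math.nan
    else:
        delta = bound.e50_ev - free.e50_ev
        se = math.hypot(free.e50_se, bound.e50_se)
        if free.kind == "CID" and delta > threshold_ev:
            classes.append("CID-stabilized")
        elif abs(delta) <= threshold_ev:
            classes.append("unchanged")
        elif delta > 0:
            classes.append("stabilized")
        else:
            classes.append("destabilized")
    return BoundFreeComparison(delta_e50_ev=delta, delta_e50_se=se, classes=classes)


def build_fingerprint(
    frames: list[tuple[float, np.ndarray]],
    drift_grid: np.ndarray,
) -> pd.DataFrame:
    """CIU fingerprint heat map: rows = trap voltages (energies), columns =
    the shared drift grid, each row normalized to its total intensity."""
    drift_grid = np.asarray(drift_grid, dtype=float)
    rows = []
    voltages = []
    for voltage, profile in frames:
        profile = np.asarray(profile, dtype=float)
        if profile.shape != drift_grid.shape:
            raise ValueError(
                f"arrival-time profile at {voltage} V does not match the "
                "shared drift grid"
            )
        total = profile.sum()
        if total <= 0:
            raise ValueError(f"empty arrival-time profile at {voltage} V")
        rows.append(profile / total)
        voltages.append(voltage)
    return pd.DataFrame(rows, index=pd.Index(voltages, name="trap_v"), columns=drift_grid)
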