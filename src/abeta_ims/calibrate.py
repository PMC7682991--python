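"""Traveling-wave IMS collision-cross-section calibration.

TWIMS drift times have no first-principles CCS relation, so the instrument
is calibrated against denatured proteins of known CCS (the experiment used
cytochrome c, apo-myoglobin and ubiquitin).  The protocol:

1. correct each drift time for the mass-dependent transfer delay,
   t' = t_D - c * sqrt(m/z) / 1000 (c = EDC delay coefficient);
2. reduce literature CCS for charge and reduced mass,
   Omega' = Omega_lit / (z * sqrt(1/m_ion + 1/m_gas));
3. fit the power law Omega' = A * t'^B by least squares in log-log space;
4. apply: Omega = A * t'^B * z * sqrt(1/m_ion + 1/m_gas).

Literature calibrant CCS values are user-supplied, never bundled as truth.
Drift gas defaults to N2 (28.0134 Da); CCS units are Angstrom^2.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import Feature

#: N2 drift-gas mass (Da).
NITROGEN_MASS = 28.0134

#: Default EDC (enhanced-duty-cycle) delay coefficient.
DEFAULT_EDC = 1.41

A2_PER_NM2 = 100.0


def a2_to_nm2(ccs_a2: float) -> float:
    return ccs_a2 / A2_PER_NM2


def nm2_to_a2(ccs_nm2: float) -> float:
    return ccs_nm2 * A2_PER_NM2


@dataclass(frozen=True)
class CalibrantEntry:
    """One calibrant ion: literature CCS plus its measured drift time."""

    name: str
    z: int
    mass_da: float
    ccs_a2: float
    td_ms: float
    gas: str = "N2"

    def __post_init__(self) -> None:
        if min(self.z, self.mass_da, self.ccs_a2, self.td_ms) <= 0:
            raise ValueError(f"calibrant {self.name}: all quantities must be positive")


@dataclass
class CalibrationFit:
    """Power-law fit Omega' = A * t'^B with its log-log diagnostics."""

    A: float
    B: float
    edc_coefficient: float
    gas_mass_da: float
    r_squared: float
    residuals: dict[str, float] = field(default_factory=dict)
    cov_loglog: np.ndarray | None = None  # covariance of (B, ln A)

    def __post_init__(self) -> None:
        if self.B <= 0:
            raise ValueError("power-law exponent B must be > 0")
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 must lie in [0, 1]")

    def to_json(self, path) -> None:
        payload = {
            "A": self.A,
            "B": self.B,
            "edc_coefficient": self.edc_coefficient,
            "gas_mass_da": self.gas_mass_da,
            "r_squared": self.r_squared,
            "residuals": self.residuals,
            "cov_loglog": None
            if self.cov_loglog is None
            else np.asarray(self.cov_loglog).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "CalibrationFit":
        with open(path) as fh:
            payload = json.load(fh)
        cov = payload.pop("cov_loglog", None)
        return cls(cov_loglog=None if cov is None else np.asarray(cov), **payload)


def corrected_drift(td_ms: float, mz: float, edc_coefficient: float = DEFAULT_EDC) -> float:
    """EDC-corrected drift time t' = t_D - c * sqrt(m/z) / 1000 (ms)."""
    if td_ms <= 0:
        raise ValueError("drift time must be positive")
    t_prime = td_ms - edc_coefficient * math.sqrt(mz) / 1000.0
    if t_prime <= 0:
        raise ValueError(
            f"EDC correction exceeds drift time (t_D={td_ms} ms, m/z={mz}, "
            f"c={edc_coefficient})"
        )
    return t_prime


def reduced_ccs(ccs_a2: float, z: int, ion_mass_da: float, gas_mass_da: float = NITROGEN_MASS) -> float:
    """Charge- and reduced-mass-normalized CCS,
    Omega' = Omega / (z * sqrt(1/m_ion + 1/m_gas))."""
    return ccs_a2 / (z * math.sqrt(1.0 / ion_mass_da + 1.0 / gas_mass_da))


def _mass_charge_factor(z: int, ion_mass_da: float, gas_mass_da: float) -> float:
    return z * math.sqrt(1.0 / ion_mass_da + 1.0 / gas_mass_da)


def fit_calibration(
    entries: list[CalibrantEntry],
    edc_coefficient: float = DEFAULT_EDC,
    gas_mass_da: float = NITROGEN_MASS,
) -> CalibrationFit:
    """Ordinary least squares of ln(Omega') on ln(t') over the calibrants."""
    if len(entries) < 3:
        raise ValueError("need at least 3 calibrant entries")
    ln_t, ln_o = [], []
    for e in entries:
        mz = (e.mass_da + e.z * 1.00728) / e.z
        ln_t.append(math.log(corrected_drift(e.td_ms, mz, edc_coefficient)))
        ln_o.append(math.log(reduced_ccs(e.ccs_a2, e.z, e.mass_da, gas_mass_da)))
    ln_t = np.asarray(ln_t)
    ln_o = np.asarray(ln_o)
    if not (np.all(np.isfinite(ln_t)) and np.all(np.isfinite(ln_o))):
        raise ValueError("non-finite calibrant data")
    if len(np.unique(ln_t)) < 2:
        raise ValueError("calibrants must span distinct corrected drift times")
    X = np.column_stack([ln_t, np.ones_like(ln_t)])
    coef, _, _, _ = np.linalg.lstsq(X, ln_o, rcond=None)
    slope, intercept = coef
    pred = X @ coef
    ss_res = float(((ln_o - pred) ** 2).sum())
    ss_tot = float(((ln_o - ln_o.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    dof = max(1, len(entries) - 2)
    cov = np.linalg.inv(X.T @ X) * (ss_res / dof)
    residuals = {e.name: float(r) for e, r in zip(entries, ln_o - pred)}
    return CalibrationFit(
        A=float(math.exp(intercept)),
        B=float(slope),
        edc_coefficient=edc_coefficient,
        gas_mass_da=gas_mass_da,
        r_squared=min(r2, 1.0),
        residuals=residuals,
        cov_loglog=cov,
    )


def apply_calibration(
    fit: CalibrationFit,
    feature: Feature,
    drift_sigma_ms: float | None = None,
    min_r_squared: float = 0.98,
    enforce_quality: bool = True,
    convention: str = "average",
) -> tuple[float, float]:
    """CCS (Angstrom^2) and first-order propagated uncertainty for an
    assigned feature.

    Refuses (configurably) to apply calibrations with R^2 below
    ``min_r_squared``.  Uncertainty combines the drift-centroid uncertainty
    with the log-log fit covariance.
    """
    if not feature.assigned:
        raise ValueError("feature must carry an assigned IonSpecies")
    if enforce_quality and fit.r_squared < min_r_squared:
        raise ValueError(
            f"calibration R^2={fit.r_squared:.4f} below quality gate {min_r_squared}"
        )
    s = feature.species
    m_ion = s.n * (s.m_avg if convention == "average" else s.m_mono)
    t_prime = corrected_drift(feature.drift_ms, feature.mz, fit.edc_coefficient)
    factor = _mass_charge_factor(s.z, m_ion, fit.gas_mass_da)
    ccs = fit.A * t_prime**fit.B * factor

    sigma_t = feature.drift_sigma_ms if drift_sigma_ms is None else drift_sigma_ms
    ln_t = math.log(t_prime)
    var_log = 0.0
    if fit.cov_loglog is not None:
        v = np.array([ln_t, 1.0])
        var_log += float(v @ fit.cov_loglog @ v)
    if sigma_t:
        var_log += (fit.B * sigma_t / t_prime) ** 2
    return ccs, ccs * math.sqrt(var_log)


def read_calibrant_table(path) -> list[CalibrantEntry]:
    """Read a calibrant CSV with columns name, z, mass_da, ccs_a2, td_ms."""
    df = pd.read_csv(path)
    return [
        CalibrantEntry(
            name=str(r["name"]),
            z=int(r["z"]),
            mass_da=float(r["mass_da"]),
            ccs_a2=float(r["ccs_a2"]),
            td_ms=float(r["td_ms"]),
        )
        for _, r in df.iterrows()
    ]


def synthetic_calibrants(
    A: float = 400.0,
    B: float = 0.55,
    n: int = 10,
    noise_sigma: float = 0.0,
    seed: int = 0,
    edc_coefficient: float = DEFAULT_EDC,
    gas_mass_da: float = NITROGEN_MASS,
) -> list[CalibrantEntry]:
    """Calibrant entries generated exactly from a known power law — a
    synthetic stand-in for a literature calibrant table, used for round-trip
    validation (drift-time noise optional)."""
    rng = np.random.default_rng(seed)
    entries = []
    for i in range(n):
        z = 5 + i % 8
        mass = 8000.0 + 1200.0 * i
        t_prime = 2.0 + 10.0 * i / max(1, n - 1)
        omega_prime = A * t_prime**B
        ccs = omega_prime * _mass_charge_factor(z, mass, gas_mass_da)
        mz = (mass + z * 1.00728) / z
        td = t_prime + edc_coefficient * math.sqrt(mz) / 1000.0
        if noise_sigma:
            td *= 1.0 + noise_sigma * rng.standard_normal()
        entries.append(
            CalibrantEntry(
                name=f"cal{i}", z=z, mass_da=mass, ccs_a2=ccs, td_ms=td
            )
        )
    return entries
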