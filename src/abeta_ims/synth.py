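"""Seeded synthetic-data generators emulating the instrument outputs the
pipeline consumes: driftscope frames with isotopically resolved oligomer
ions, collision-energy-ramped unfolding/dissociation series, time-resolved
oligomer distributions, and toy fibril structures.

The generators encode the statistical structure the analysis assumes —
separable 2D peaks with exact isotopologue envelopes, two conformer families
(compact monomer-based MB at shorter drift, dimer-based DB at longer drift,
plus unfolded "extended" states), m/z-degenerate n/z overlaps, two-state
logistic CIU/CID transitions, and a mass-conserving assembly chain — not
instrument physics.  Every generator is bit-deterministic under its seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import chem
from .chem import ElementalComposition, IonSpecies
from .frames import DriftscopeFrame

GAUSS_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Default TWIMS resolving power (m / FWHM at the peak's own m/z).
DEFAULT_RESOLVING_POWER = 20_000.0

#: Default drift centroids (ms) for the 5+ dimer conformer families,
#: mirroring the observed compact MB (~8 ms) / DB (~11 ms) signals.
MB_DRIFT_MS = 8.0
DB_DRIFT_MS = 11.0


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian noise plus an additive baseline, seeded."""

    sigma: float = 0.0
    baseline: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0 or self.baseline < 0:
            raise ValueError("noise levels must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def apply(self, clean: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        noisy = clean * (1.0 + self.sigma * rng.standard_normal(clean.shape))
        if self.baseline > 0:
            noisy = noisy + self.baseline * np.abs(
                rng.standard_normal(clean.shape)
            )
        return np.clip(noisy, 0.0, None)


@dataclass(frozen=True)
class Conformer:
    """One drift-dimension component of an ion: a Gaussian arrival peak."""

    drift_ms: float
    width_ms: float
    abundance: float
    label: str = "MB"  # MB | DB | extended-MB | extended-DB

    def __post_init__(self) -> None:
        if self.abundance < 0 or self.width_ms <= 0 or self.drift_ms <= 0:
            raise ValueError("conformer parameters must be positive")


@dataclass(frozen=True)
class SpeciesSpec:
    """An ion plus its conformer family, with the n-mer composition needed to
    draw the exact isotopologue envelope."""

    species: IonSpecies
    composition: ElementalComposition  # of the neutral n-mer
    conformers: tuple[Conformer, ...]

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        n: int,
        z: int,
        conformers: list[Conformer] | tuple[Conformer, ...],
        peptide: str | None = None,
    ) -> "SpeciesSpec":
        comp = chem.composition_from_sequence(sequence) * n
        return cls(
            species=IonSpecies.from_sequence(sequence, n, z, peptide),
            composition=comp,
            conformers=tuple(conformers),
        )


def isotope_envelope(
    spec: SpeciesSpec,
    mz_grid: np.ndarray,
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    n_peaks: int = 30,
) -> np.ndarray:
    """Grid-sampled isotopologue envelope of a species, normalized so the
    grid sum equals one (each isotope peak carries its relative abundance)."""
    pattern = chem.isotope_pattern(spec.composition, spec.species.z, n_peaks)
    envelope = np.zeros_like(mz_grid, dtype=float)
    for mz_k, ab_k in zip(pattern.mz, pattern.abundances):
        sigma = (mz_k / resolving_power) / GAUSS_FWHM
        g = np.exp(-0.5 * ((mz_grid - mz_k) / sigma) ** 2)
        total = g.sum()
        if total <= 0:
            raise ValueError(
                f"isotope envelope of {spec.species.label} falls outside the "
                f"m/z grid [{mz_grid[0]:.2f}, {mz_grid[-1]:.2f}]"
            )
        envelope += ab_k * g / total
    return envelope


def simulate_driftscope(
    specs: list[SpeciesSpec] | tuple[SpeciesSpec, ...],
    mz_grid: np.ndarray,
    drift_grid: np.ndarray,
    noise: NoiseModel = NoiseModel(),
    resolving_power: float = DEFAULT_RESOLVING_POWER,
    n_peaks: int = 30,
) -> DriftscopeFrame:
    """Build a driftscope frame as a sum of separable 2D peaks.

    Each conformer contributes (drift Gaussian, grid-sum 1) x (isotope
    envelope, grid-sum 1) x abundance; noise is applied last.  The returned
    frame records the generator ground truth in its metadata.
    """
    if not specs:
        raise ValueError("need at least one species")
    mz_grid = np.asarray(mz_grid, dtype=float)
    drift_grid = np.asarray(drift_grid, dtype=float)
    clean = np.zeros((len(drift_grid), len(mz_grid)))
    truth = []
    for spec in specs:
        envelope = isotope_envelope(spec, mz_grid, resolving_power, n_peaks)
        for conf in spec.conformers:
            g = np.exp(-0.5 * ((drift_grid - conf.drift_ms) / conf.width_ms) ** 2)
            total = g.sum()
            if total <= 0:
                raise ValueError(
                    f"drift peak of {spec.species.label} at {conf.drift_ms} ms "
                    "falls outside the drift grid"
                )
            clean += conf.abundance * np.outer(g / total, envelope)
            truth.append(
                {
                    "n": spec.species.n,
                    "z": spec.species.z,
                    "drift_ms": conf.drift_ms,
                    "abundance": conf.abundance,
                    "label": conf.label,
                }
            )
    intensity = noise.apply(clean, noise.rng())
    return DriftscopeFrame(
        mz=mz_grid,
        drift_ms=drift_grid,
        intensity=intensity,
        metadata={
            "seed": noise.seed,
            "noise_sigma": noise.sigma,
            "noise_baseline": noise.baseline,
            "resolving_power": resolving_power,
            "ground_truth": truth,
        },
    )


# ---------------------------------------------------------------------------
# CIU / CID collision-energy series


@dataclass(frozen=True)
class CIUGroundTruth:
    """Two-state unfolding + dissociation ground truth for one (n, z) ion.

    Midpoints are lab-frame energies (eV); ``cap`` limits the maximum
    unfolded fraction (a ligand-stabilized ion may dissociate before it can
    fully unfold).
    """

    e50_ciu: float
    e50_cid: float
    width_ciu: float = 10.0
    width_cid: float = 10.0
    cap: float = 1.0

    def __post_init__(self) -> None:
        if self.width_ciu <= 0 or self.width_cid <= 0:
            raise ValueError("transition widths must be > 0")
        if self.e50_ciu <= 0 or self.e50_cid <= 0:
            raise ValueError("midpoints must be > 0")
        if not 0.0 <= self.cap <= 1.0:
            raise ValueError("cap must be in [0, 1]")


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_ciu_series(
    truth: CIUGroundTruth,
    trap_voltages: np.ndarray,
    z: int,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """CE-ramped folded/unfolded/surviving fractions vs lab-frame energy.

    Lab-frame energy is E = z * V_trap.  The unfolded fraction follows a
    logistic rise to ``cap`` with midpoint ``e50_ciu``; total survival
    follows a logistic fall with midpoint ``e50_cid``.  Columns:
    energy_ev, folded, unfolded, surviving.
    """
    volts = np.asarray(trap_voltages, dtype=float)
    if np.any(volts <= 0) or np.any(np.diff(volts) <= 0):
        raise ValueError("trap voltages must be positive and increasing")
    energy = z * volts
    with np.errstate(over="ignore"):
        unfolded_share = truth.cap * _logistic((energy - truth.e50_ciu) / truth.width_ciu)
        surviving = _logistic(-(energy - truth.e50_cid) / truth.width_cid)
    unfolded = surviving * unfolded_share
    folded = surviving * (1.0 - unfolded_share)
    dissociated = 1.0 - surviving
    # noise acts on the three channel intensities; fractions are then
    # re-derived from the noisy total, so they stay on the simplex
    rng = noise.rng()
    noisy = np.stack(
        [noise.apply(ch, rng) for ch in (folded, unfolded, dissociated)]
    )
    total = np.maximum(noisy.sum(axis=0), 1e-12)
    noisy /= total
    out = pd.DataFrame(
        {
            "energy_ev": energy,
            "folded": noisy[0],
            "unfolded": noisy[1],
            "surviving": noisy[0] + noisy[1],
        }
    )
    out.attrs["seed"] = noise.seed
    out.attrs["charge"] = z
    return out


def methods_voltage_ramp() -> np.ndarray:
    """The instrument CE ramp used throughout: 5 to 50 V in 5 V steps."""
    return np.arange(5.0, 50.0 + 1e-9, 5.0)


# ---------------------------------------------------------------------------
# Time-resolved oligomer distributions (LILBID-style)


@dataclass(frozen=True)
class KineticsGroundTruth:
    """Deterministic mass-action assembly chain with an optional dimer-base
    channel — synthetic scaffolding for testing the kinetics statistics, not
    a mechanistic claim about the peptide.

    Monomer addition O_n + O_1 -> O_{n+1} proceeds at ``rate``; the
    nucleating dimerization step is slower by ``nucleation_factor`` and is
    split between an MB channel and a DB channel with weight ``db_weight``;
    an inhibitor suppresses the DB channel by ``db_suppression`` (0 = fully
    blocked) and caps the reachable order.
    """

    monomer_pool: float = 50.0  # initial monomer amount (concentration units)
    rate: float = 2.0e-3  # elongation rate constant (1/(conc*min))
    nucleation_factor: float = 0.05  # dimerization slowdown vs elongation
    n_max: int = 12
    db_weight: float = 0.5
    inhibitor: bool = False
    db_suppression: float = 0.0
    order_cap: int | None = None

    def __post_init__(self) -> None:
        if self.rate < 0 or self.monomer_pool < 0:
            raise ValueError("rates and pools must be >= 0")
        if not 0.0 <= self.db_weight <= 1.0:
            raise ValueError("db_weight must be in [0, 1]")

    @property
    def effective_cap(self) -> int:
        cap = self.order_cap if (self.inhibitor and self.order_cap) else self.n_max
        return min(cap, self.n_max)

    @property
    def dimerization_rate(self) -> float:
        k_nuc = self.rate * self.nucleation_factor
        mb = k_nuc * (1.0 - self.db_weight)
        db = k_nuc * self.db_weight
        if self.inhibitor:
            db *= self.db_suppression
        return mb + db


@dataclass
class LilbidRun:
    """Raw generator output: per-replicate, per-timepoint intensity vectors."""

    times_min: np.ndarray  # (T,)
    intensities: np.ndarray  # (replicates, T, n_max)
    truth: KineticsGroundTruth
    seed: int

    @property
    def noiseless(self) -> np.ndarray:
        return self.intensities.mean(axis=0)


def _assembly_rhs(truth: KineticsGroundTruth) -> callable:
    cap = truth.effective_cap
    k_dim = truth.dimerization_rate
    k = truth.rate

    def rhs(_t: float, y: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        y1 = y[0]
        if cap >= 2:
            flux1 = k_dim * y1 * y1
            dy[0] -= 2.0 * flux1
            dy[1] += flux1
        for n in range(2, cap):  # O_n + O_1 -> O_{n+1}
            flux = k * y1 * y[n - 1]
            dy[0] -= flux
            dy[n - 1] -= flux
            dy[n] += flux
        return dy

    return rhs


def simulate_lilbid_timeseries(
    truth: KineticsGroundTruth,
    timepoints: np.ndarray,
    replicates: int = 4,
    noise: NoiseModel = NoiseModel(),
) -> LilbidRun:
    """Integrate the assembly ODE and emit replicate intensity vectors.

    The noiseless solution conserves total peptide mass (sum of n * I_n).
    Default of four replicates mirrors the four spectra averaged per
    timepoint in the experimental protocol.
    """
    times = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    y0 = np.zeros(truth.n_max)
    y0[0] = truth.monomer_pool
    t_span = (min(0.0, times[0]), times[-1])
    sol = solve_ivp(
        _assembly_rhs(truth),
        t_span,
        y0,
        t_eval=times,
        method="LSODA",
        rtol=1e-9,
        atol=1e-12,
    )
    if not sol.success:
        raise RuntimeError(f"kinetics integration failed: {sol.message}")
    clean = np.clip(sol.y.T, 0.0, None)  # (T, n_max)
    rng = noise.rng()
    reps = np.stack([noise.apply(clean, rng) for _ in range(replicates)])
    return LilbidRun(
        times_min=times, intensities=reps, truth=truth, seed=noise.seed
    )


def lilbid_to_dataframe(run: LilbidRun, condition: str = "free") -> pd.DataFrame:
    """Flatten a run to the tabular exchange format
    (time_min, replicate, condition, I_1..I_n)."""
    records = []
    n_max = run.truth.n_max
    for r in range(run.intensities.shape[0]):
        for i, t in enumerate(run.times_min):
            row = {"time_min": t, "replicate": r, "condition": condition}
            row.update(
                {f"I_{n + 1}": run.intensities[r, i, n] for n in range(n_max)}
            )
            records.append(row)
    return pd.DataFrame(records)


# ---------------------------------------------------------------------------
# Toy fibril structures


def _s_shaped_monomer() -> np.ndarray:
    """Fixed C-alpha trace of a rigid S-shaped dummy monomer (24 atoms, Å),
    lying in the xy-plane."""
    points = []
    for i in range(12):  # upper arc of the S
        theta = math.pi * (0.5 - i / 11.0)
        points.append((4.75 * math.cos(theta), 4.75 + 4.75 * math.sin(theta)))
    for i in range(1, 13):  # lower arc, opposite handedness
        theta = math.pi * (0.5 + i / 11.0)
        points.append((4.75 * math.cos(theta), -4.75 - 4.75 * math.sin(theta)))
    xy = np.array(points)
    return np.column_stack([xy, np.zeros(len(xy))])


TOY_LAYER_SPACING = 4.8  # Å, axial stacking distance between layers
TOY_DB_OFFSET = 24.0  # Å, in-plane separation of the C2 partner


def toy_layer_map(n_layers: int, base: str) -> dict:
    """Chain -> {layer, protofilament} map for a toy fibril."""
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    layer_map = {}
    for i in range(n_layers):
        layer_map[letters[i]] = {"layer": i + 1, "protofilament": 0}
        if base == "DB":
            layer_map[letters[n_layers + i]] = {
                "layer": i + 1,
                "protofilament": 1,
            }
    return layer_map


def make_toy_fibril_pdb(n_layers: int, base: str = "DB") -> str:
    """PDB text of a toy fibril: rigid S-shaped dummy monomers stacked in
    ``n_layers`` axial layers; ``base='DB'`` duplicates each layer with a
    C2-symmetric partner protofilament (two monomers per layer)."""
    import gemmi

    if n_layers < 1:
        raise ValueError("need at least one layer")
    if base not in ("MB", "DB"):
        raise ValueError("base must be 'MB' or 'DB'")
    template = _s_shaped_monomer()
    layer_map = toy_layer_map(n_layers, base)
    chains: dict[str, np.ndarray] = {}
    for chain_id, info in layer_map.items():
        coords = template.copy()
        if info["protofilament"] == 1:
            # C2 rotation about the axis midway between the protofilaments
            coords[:, 0] = TOY_DB_OFFSET - coords[:, 0]
            coords[:, 1] = -coords[:, 1]
        coords[:, 2] += (info["layer"] - 1) * TOY_LAYER_SPACING
        chains[chain_id] = coords

    st = gemmi.Structure()
    st.name = f"toy {base} fibril, {n_layers} layers"
    model = gemmi.Model("1")
    for chain_id, coords in sorted(chains.items()):
        chain = gemmi.Chain(chain_id)
        for i, (x, y, z) in enumerate(coords, start=1):
            res = gemmi.Residue()
            res.name = "ALA"
            res.seqid = gemmi.SeqId(i, " ")
            atom = gemmi.Atom()
            atom.name = "CA"
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(x, y, z)
            atom.occ = 1.0
            atom.b_iso = 20.0
            res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    return st.make_pdb_string()


# ---------------------------------------------------------------------------
# Canonical fixtures


def dimer_conformer_fixture(
    sequence: str = chem.ABETA42_SEQUENCE,
    extended: bool = True,
) -> SpeciesSpec:
    """The 5+ dimer at nominal m/z 1806 with its MB (8 ms) and DB (11 ms)
    compact conformers and, optionally, an extended unfolding product."""
    conformers = [
        Conformer(MB_DRIFT_MS, 0.35, 1.0, "MB"),
        Conformer(DB_DRIFT_MS, 0.35, 0.8, "DB"),
    ]
    if extended:
        conformers.append(Conformer(13.0, 0.45, 0.35, "extended-MB"))
    return SpeciesSpec.from_sequence(sequence, 2, 5, conformers)


def degenerate_overlap_fixture(
    sequence: str = chem.ABETA42_SEQUENCE,
) -> list[SpeciesSpec]:
    """Monomer 2+, dimer 4+ and trimer 6+ — m/z-degenerate at nominal 2258,
    distinguishable only by isotopologue spacing and drift time."""
    return [
        SpeciesSpec.from_sequence(
            sequence, 1, 2, [Conformer(5.5, 0.30, 1.0, "MB")]
        ),
        SpeciesSpec.from_sequence(
            sequence, 2, 4, [Conformer(8.5, 0.30, 0.8, "MB")]
        ),
        SpeciesSpec.from_sequence(
            sequence, 3, 6, [Conformer(11.5, 0.30, 0.6, "MB")]
        ),
    ]
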