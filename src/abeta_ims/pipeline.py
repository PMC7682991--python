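"""End-to-end replica workflow on synthetic fixtures.

``run_replica`` chains every stage of the analysis the way the experiment
does: driftscope assignment (including the m/z-degenerate overlap), TWIMS
calibration, CCS growth-model fitting with crossover detection, CIU/CID
transition fitting with the energy-gap analysis and the free-vs-bound
comparison, time-resolved kinetics with the M/O statistic, and theoretical
CCS from a toy fibril.  Everything is generated from the run seed; the
report is a plain dict (serialized to JSON) plus CSV tables, and two runs
with the same config are identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import assign, calibrate, chem, ciu, growth, kinetics, structure, synth

log = logging.getLogger("abeta_ims.pipeline")


@dataclass
class RunConfig:
    """Effective configuration of a replica run; JSON round-trippable.

    Every stage tolerance and seed lands in the run log.  Convention
    switches: ``mass_convention`` (average | monoisotopic),
    ``mo_include_monomer`` (Eq.-style M/O denominator over n>=1 vs n>=2).
    """

    seed: int = 1
    outdir: str = "replica_out"
    mass_convention: str = "average"
    mo_include_monomer: bool = True
    db_present: bool = True  # False emulates an inhibited / mutant sample
    inhibitor_kinetics: bool = True
    noise_sigma: float = 0.02
    edc_coefficient: float = calibrate.DEFAULT_EDC
    resolving_power: float = synth.DEFAULT_RESOLVING_POWER
    mz_tolerance: float = 0.1
    crossover_tolerance_sigma: float = 2.0
    n_max: int = 9
    # CIU ground truth: per-order MB unfolding midpoints (eV, lab frame)
    e50_ciu_by_order: dict = field(
        default_factory=lambda: {2: 85.0, 3: 185.0, 4: 285.0, 5: 340.0, 6: 395.0, 7: 450.0}
    )
    e50_cid_dimer: float = 125.0
    bound_cap: float = 0.15
    bound_cid_shift: float = 10.0
    # kinetics
    kinetics_horizon_min: float = 200.0
    kinetics_bin_min: float = 10.0
    replicates: int = 4
    # structure stage sampling (kept modest; the MC error enters the report)
    pa_orientations: int = 120
    pa_rays: int = 2000

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        payload["e50_ciu_by_order"] = {
            int(k): v for k, v in payload.get("e50_ciu_by_order", {}).items()
        }
        return cls(**payload)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


def _stage(name):
    def wrap(fn):
        def inner(*args, **kw):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kw)
            except Exception as exc:  # abort with stage-tagged error
                raise StageError(name, exc) from exc
            log.info("stage=%s wall_s=%.2f", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


@_stage("assignment")
def _run_assignment(cfg: RunConfig) -> dict:
    comp = chem.composition_from_sequence(chem.ABETA42_SEQUENCE)
    noise = synth.NoiseModel(sigma=cfg.noise_sigma, seed=cfg.seed)
    drift = np.arange(4.0, 16.0, 0.05)

    dimer_spec = synth.dimer_conformer_fixture(extended=cfg.db_present)
    if not cfg.db_present:
        dimer_spec = synth.SpeciesSpec(
            species=dimer_spec.species,
            composition=dimer_spec.composition,
            conformers=(
                synth.Conformer(synth.MB_DRIFT_MS, 0.35, 1.0, "MB"),
                synth.Conformer(13.0, 0.45, 0.35, "extended-MB"),
            ),
        )
    frame_1806 = synth.simulate_driftscope(
        [dimer_spec], np.arange(1804.0, 1810.5, 0.01), drift, noise,
        resolving_power=cfg.resolving_power,
    )
    frame_2258 = synth.simulate_driftscope(
        synth.degenerate_overlap_fixture(),
        np.arange(2254.0, 2264.0, 0.008),
        drift,
        synth.NoiseModel(sigma=cfg.noise_sigma, seed=cfg.seed + 1),
        resolving_power=cfg.resolving_power,
    )
    out = {}
    all_feats = []
    for tag, frame in (("dimer_1806", frame_1806), ("overlap_2258", frame_2258)):
        feats = assign.detect_features(frame)
        assign.assign_species(feats, comp, n_max=12, z_max=8, mz_tolerance=cfg.mz_tolerance)
        groups = assign.group_conformers(feats)
        all_feats.extend(feats)
        out[tag] = {
            "features": [
                {
                    "mz": round(f.mz, 3),
                    "drift_ms": round(f.drift_ms, 3),
                    "spacing": None if f.spacing is None else round(f.spacing, 4),
                    "n": f.n,
                    "z": f.z,
                    "conformer": f.conformer,
                    "flags": f.flags,
                }
                for f in feats
            ],
            "group_flags": {f"{k[0]}:{k[1]}": v["flags"] for k, v in groups.items()},
        }
    dimer_flags = out["dimer_1806"]["group_flags"].get("2:5", [])
    out["db_absent"] = "db-missing" in dimer_flags
    out["_features"] = all_feats
    return out


@_stage("calibration")
def _run_calibration(cfg: RunConfig) -> tuple[calibrate.CalibrationFit, dict]:
    entries = calibrate.synthetic_calibrants(
        noise_sigma=0.002, seed=cfg.seed + 2, edc_coefficient=cfg.edc_coefficient
    )
    fit = calibrate.fit_calibration(entries, edc_coefficient=cfg.edc_coefficient)
    return fit, {"A": fit.A, "B": fit.B, "r_squared": fit.r_squared}


@_stage("growth")
def _run_growth(cfg: RunConfig, fit: calibrate.CalibrationFit) -> dict:
    rng = np.random.default_rng(cfg.seed + 3)
    comp = chem.composition_from_sequence(chem.ABETA42_SEQUENCE)
    m_avg = chem.average_mass(comp)
    orders = np.arange(2, cfg.n_max + 1)
    laws = {"MB": growth.two_regime_ccs_law(orders, ccs_dimer=700.0)}
    if cfg.db_present:
        laws["DB"] = growth.two_regime_ccs_law(orders, ccs_dimer=1000.0)

    series = {}
    for family, truth_ccs in laws.items():
        per_n_ccs, per_n_sigma = [], []
        for n_i, ccs_true in zip(orders, truth_ccs):
            recovered = []
            for z in (n_i + 2, n_i + 3):  # two charge states per oligomer
                m_ion = n_i * m_avg
                mz = (m_ion + z * chem.PROTON_MASS) / z
                omega_prime = ccs_true / (
                    z * np.sqrt(1.0 / m_ion + 1.0 / fit.gas_mass_da)
                )
                t_prime = (omega_prime / fit.A) ** (1.0 / fit.B)
                td = t_prime + fit.edc_coefficient * np.sqrt(mz) / 1000.0
                td *= 1.0 + cfg.noise_sigma * 0.5 * rng.standard_normal()
                feat = assign.Feature(mz=mz, drift_ms=td, intensity=1.0)
                feat.z, feat.n = int(z), int(n_i)
                feat.species = chem.IonSpecies(
                    n=int(n_i), z=int(z), m_avg=m_avg, m_mono=m_avg
                )
                ccs, _ = calibrate.apply_calibration(fit, feat, drift_sigma_ms=0.0)
                recovered.append(ccs)
            per_n_ccs.append(float(np.mean(recovered)))
            per_n_sigma.append(
                max(float(np.std(recovered, ddof=1)), 0.01 * float(np.mean(recovered)))
            )
        series[family] = growth.CCSSeries(
            n=orders.copy(), ccs_a2=np.array(per_n_ccs), sigma=np.array(per_n_sigma),
            tag=family,
        )

    out = {"series": {k: {"n": s.n.tolist(), "ccs_a2": np.round(s.ccs_a2, 1).tolist()}
                      for k, s in series.items()}}
    cross = growth.detect_crossover(
        series["MB"], n_ref=2, tolerance_sigma=cfg.crossover_tolerance_sigma
    )
    out["crossover_order"] = cross.crossover
    out["linear_slope_a2_per_monomer"] = round(cross.linear.slope, 2)
    if cfg.db_present:
        comparison = growth.compare_series(series["MB"], series["DB"], n_min=4)
        out["mb_db"] = {
            "delta_slope": round(comparison.delta_slope, 2),
            "delta_intercept": round(comparison.delta_intercept, 1),
            "signature": comparison.mb_db_signature,
        }
    out["_series"] = series
    return out


@_stage("ciu_cid")
def _run_ciu(cfg: RunConfig) -> dict:
    ramp = synth.methods_voltage_ramp()
    e50_fits = {}
    for i, (n, e50) in enumerate(sorted(cfg.e50_ciu_by_order.items())):
        z = 2 * n + 1  # charge scales with size; keeps E50 inside the ramp
        truth = synth.CIUGroundTruth(
            e50_ciu=e50, e50_cid=e50 * 10, width_ciu=10.0 + 2.0 * n
        )
        df = synth.simulate_ciu_series(
            truth, ramp, z, synth.NoiseModel(sigma=cfg.noise_sigma, seed=cfg.seed + 10 + i)
        )
        curve = ciu.StabilityCurve.from_series(df, species=(n, z))
        fitres = ciu.fit_transition(curve, "CIU", n_bootstrap=50, seed=cfg.seed + i)
        e50_fits[n] = fitres
    gap = ciu.gap_analysis({n: f.e50_ev for n, f in e50_fits.items()})

    # free vs ligand-bound 5+ dimer
    z = 5
    free_truth = synth.CIUGroundTruth(e50_ciu=85.0, e50_cid=cfg.e50_cid_dimer)
    bound_truth = synth.CIUGroundTruth(
        e50_ciu=85.0,
        e50_cid=cfg.e50_cid_dimer + cfg.bound_cid_shift,
        cap=cfg.bound_cap,
    )
    noise = synth.NoiseModel(sigma=cfg.noise_sigma, seed=cfg.seed + 20)
    free_df = synth.simulate_ciu_series(free_truth, ramp, z, noise)
    bound_df = synth.simulate_ciu_series(
        bound_truth, ramp, z, synth.NoiseModel(sigma=cfg.noise_sigma, seed=cfg.seed + 21)
    )
    free_cid = ciu.fit_transition(
        ciu.StabilityCurve.from_series(free_df, (2, 5), "free"), "CID",
        n_bootstrap=50, seed=cfg.seed,
    )
    bound_cid = ciu.fit_transition(
        ciu.StabilityCurve.from_series(bound_df, (2, 5), "CLR01"), "CID",
        n_bootstrap=50, seed=cfg.seed,
    )
    free_ciu = ciu.fit_transition(
        ciu.StabilityCurve.from_series(free_df, (2, 5), "free"), "CIU",
        n_bootstrap=0,
    )
    bound_ciu = ciu.fit_transition(
        ciu.StabilityCurve.from_series(bound_df, (2, 5), "CLR01"), "CIU",
        n_bootstrap=0,
    )
    cid_cmp = ciu.compare_bound_free(free_cid, bound_cid)
    ciu_cmp = ciu.compare_bound_free(free_ciu, bound_ciu)

    # fingerprint of the free dimer: compact at 8 ms hands off to 13 ms
    drift = np.arange(4.0, 16.0, 0.05)
    frames = []
    for _, row in free_df.iterrows():
        profile = row["folded"] * np.exp(-0.5 * ((drift - 8.0) / 0.35) ** 2)
        profile += row["unfolded"] * np.exp(-0.5 * ((drift - 13.0) / 0.45) ** 2)
        frames.append((row["energy_ev"] / z, profile + 1e-12))
    fingerprint = ciu.build_fingerprint(frames, drift)

    return {
        "e50_by_order": {n: round(f.e50_ev, 1) for n, f in e50_fits.items()},
        "gap_breakpoint_order": gap.breakpoint_order,
        "gap_low_ev": round(gap.gap_low_ev, 1),
        "gap_high_ev": round(gap.gap_high_ev, 1),
        "dimer_cid_e50_ev": round(free_cid.e50_ev, 1),
        "bound_cid_e50_ev": round(bound_cid.e50_ev, 1),
        "bound_ciu_cap": round(bound_ciu.cap, 3),
        "cid_classes": cid_cmp.classes,
        "ciu_classes": ciu_cmp.classes,
        "_fingerprint": fingerprint,
    }


@_stage("kinetics")
def _run_kinetics(cfg: RunConfig) -> dict:
    times = np.arange(2.5, cfg.kinetics_horizon_min + 1e-9, 2.5)
    free_truth = synth.KineticsGroundTruth()
    free_run = synth.simulate_lilbid_timeseries(
        free_truth, times, cfg.replicates,
        synth.NoiseModel(sigma=cfg.noise_sigma, seed=cfg.seed + 30),
    )
    free_tbl = kinetics.bin_and_average(
        synth.lilbid_to_dataframe(free_run, "free"), cfg.kinetics_bin_min
    )
    out = {
        "free_m_over_o": kinetics.m_over_o_curve(
            free_tbl, cfg.mo_include_monomer
        )["m_over_o"].round(4).tolist(),
        "free_final_max_order": kinetics.max_order_present(free_tbl.intensities[-1]),
        "n_bins": len(free_tbl.times_min),
    }
    if cfg.inhibitor_kinetics:
        inh_truth = synth.KineticsGroundTruth(
            inhibitor=True, db_suppression=0.0, order_cap=6
        )
        inh_run = synth.simulate_lilbid_timeseries(
            inh_truth, times, cfg.replicates,
            synth.NoiseModel(sigma=cfg.noise_sigma, seed=cfg.seed + 31),
        )
        inh_tbl = kinetics.bin_and_average(
            synth.lilbid_to_dataframe(inh_run, "+CLR01"), cfg.kinetics_bin_min
        )
        cmp_res = kinetics.compare_conditions(
            free_tbl, inh_tbl, seed=cfg.seed + 32,
            include_monomer=cfg.mo_include_monomer,
        )
        out["inhibited_final_max_order"] = kinetics.max_order_present(
            inh_tbl.intensities[-1]
        )
        out["delta_m_over_o_final"] = round(float(cmp_res.delta_m_over_o[-1]), 4)
        out["inhibited_m_over_o_ge_free"] = bool(
            np.all(cmp_res.delta_m_over_o >= -1e-9)
        )
    return out


@_stage("structure_ccs")
def _run_structure(cfg: RunConfig) -> dict:
    fibril = structure.read_structure(synth.make_toy_fibril_pdb(9, "DB"))
    layer_map = synth.toy_layer_map(9, "DB")
    mb = structure.ccs_series_from_fibril(
        fibril, "MB", range(1, 6), layer_map,
        n_orientations=cfg.pa_orientations, n_rays_per_orientation=cfg.pa_rays,
        seed=cfg.seed + 40,
    )
    db = structure.ccs_series_from_fibril(
        fibril, "DB", range(2, 10, 2), layer_map,
        n_orientations=cfg.pa_orientations, n_rays_per_orientation=cfg.pa_rays,
        seed=cfg.seed + 41,
    )
    fit_mb = growth.fit_linear(mb, n_min=2)
    fit_db = growth.fit_linear(db, n_min=2)
    return {
        "mb_ccs_a2": np.round(mb.ccs_a2, 1).tolist(),
        "db_ccs_a2": np.round(db.ccs_a2, 1).tolist(),
        "mb_slope": round(fit_mb.slope, 1),
        "db_slope": round(fit_db.slope, 1),
        "db_intercept_minus_mb": round(fit_db.intercept - fit_mb.intercept, 1),
    }


def run_replica(config: RunConfig) -> dict:
    """Run the full synthetic replica workflow and write the report.

    Returns the report dict; writes ``report.json`` plus CSV tables
    (CCS-vs-n series, E50 table, M/O curves, fingerprint matrix) under
    ``config.outdir``.  Any stage failure aborts with a stage-tagged error.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.json")
    log.info("replica run: seed=%d outdir=%s", config.seed, outdir)

    report: dict = {"seed": config.seed}
    assignment = _run_assignment(config)
    features = assignment.pop("_features")
    report["assignment"] = assignment
    assign.features_to_dataframe(features).to_csv(outdir / "features.csv", index=False)

    fit, cal_summary = _run_calibration(config)
    report["calibration"] = cal_summary
    fit.to_json(outdir / "calibration.json")

    growth_out = _run_growth(config, fit)
    series = growth_out.pop("_series")
    for family, s in series.items():
        s.to_csv(outdir / f"ccs_series_{family}.csv")
    report["growth"] = growth_out

    ciu_out = _run_ciu(config)
    fingerprint = ciu_out.pop("_fingerprint")
    fingerprint.to_csv(outdir / "fingerprint_free_dimer.csv")
    pd.DataFrame(
        {"n": list(ciu_out["e50_by_order"]), "e50_ev": list(ciu_out["e50_by_order"].values())}
    ).to_csv(outdir / "e50_table.csv", index=False)
    report["ciu_cid"] = ciu_out

    report["kinetics"] = _run_kinetics(config)
    report["structure_ccs"] = _run_structure(config)

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    return report
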