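"""Time-resolved oligomer-distribution statistics (LILBID-style data).

Raw per-droplet spectra arrive as replicate intensity vectors I_1..I_n with
timestamps.  The analysis averages replicates in fixed time bins (10 min in
the experimental protocol), normalizes each spectrum to its total
intensity, and tracks two summaries over time: the monomer-over-oligomer
ratio

    M/O = I_1 / sum_n (n * I_n)

and the highest oligomer order present above a relative threshold.  With
the sum taken over all n >= 1 (the default), M/O is the monomer's share of
total peptide mass and is bounded by 1; the alternative n >= 2 denominator
is also provided.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class KineticsTable:
    """Binned time course: per-timepoint mean intensity vectors plus the
    per-replicate means kept for bootstrap resampling."""

    times_min: np.ndarray  # (T,) bin centers
    intensities: np.ndarray  # (T, n_max) replicate-averaged
    replicate_intensities: np.ndarray | None = None  # (R, T, n_max)
    condition: str = "free"
    bin_width_min: float = 10.0

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("timepoints must be increasing")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_max(self) -> int:
        return self.intensities.shape[1]

    @property
    def n_replicates(self) -> int:
        return 1 if self.replicate_intensities is None else self.replicate_intensities.shape[0]


def bin_and_average(
    table: pd.DataFrame,
    bin_width_min: float = 10.0,
    condition: str | None = None,
) -> KineticsTable:
    """Average replicate spectra within fixed time bins.

    ``table`` uses the exchange format (time_min, replicate, condition,
    I_1..I_n).  Bins with no data are dropped with a warning.  Binning is
    idempotent: re-binning an already binned table at the same width leaves
    it unchanged.
    """
    if bin_width_min <= 0:
        raise ValueError("bin width must be positive")
    df = table if condition is None else table[table["condition"] == condition]
    if condition is None and "condition" in table:
        conds = table["condition"].unique()
        if len(conds) > 1:
            raise ValueError(f"multiple conditions present: {list(conds)}; pick one")
        condition = str(conds[0]) if len(conds) else "free"
    intensity_cols = sorted(
        (c for c in df.columns if c.startswith("I_")), key=lambda c: int(c[2:])
    )
    if not intensity_cols:
        raise ValueError("no intensity columns I_1..I_n found")
    if not df["time_min"].is_monotonic_increasing:
        df = df.sort_values("time_min")
    bins = np.floor(df["time_min"].to_numpy() / bin_width_min).astype(int)
    df = df.assign(_bin=bins)

    bin_ids = np.unique(bins)
    expected = np.arange(bin_ids.min(), bin_ids.max() + 1)
    missing = set(expected) - set(bin_ids)
    if missing:
        import warnings

        warnings.warn(f"dropping {len(missing)} empty time bins")

    centers, means, rep_means = [], [], []
    replicates = sorted(df["replicate"].unique()) if "replicate" in df else [0]
    for b in bin_ids:
        sub = df[df["_bin"] == b]
        centers.append((b + 0.5) * bin_width_min)
        means.append(sub[intensity_cols].mean().to_numpy())
        rep_means.append(
            [
                sub[sub["replicate"] == r][intensity_cols].mean().to_numpy()
                if "replicate" in sub
                else sub[intensity_cols].mean().to_numpy()
                for r in replicates
            ]
        )
    rep_arr = np.array(rep_means)  # (T, R, n)
    return KineticsTable(
        times_min=np.array(centers),
        intensities=np.array(means),
        replicate_intensities=np.transpose(rep_arr, (1, 0, 2)),
        condition=condition or "free",
        bin_width_min=bin_width_min,
    )


def normalize_spectrum(intensities: np.ndarray) -> np.ndarray:
    """Fractions of the spectrum's total intensity."""
    i = np.asarray(intensities, dtype=float)
    total = i.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero spectrum")
    return i / total


def m_over_o(intensities: np.ndarray, include_monomer: bool = True) -> float:
    """Monomer-over-oligomer ratio M/O = I_1 / sum(n * I_n).

    With ``include_monomer`` (default) the denominator sum runs over all
    n >= 1, bounding M/O by 1 (equal to 1 iff only monomer is present);
    ``include_monomer=False`` restricts the sum to n >= 2.
    """
    i = np.asarray(intensities, dtype=float)
    n = np.arange(1, len(i) + 1)
    denom = float((n * i).sum()) if include_monomer else float((n[1:] * i[1:]).sum())
    if denom <= 0:
        raise ValueError("zero denominator in M/O")
    return float(i[0] / denom)


def max_order_present(intensities: np.ndarray, threshold_fraction: float = 0.01) -> int:
    """Largest oligomer order whose normalized intensity exceeds the
    threshold; 0 when nothing does."""
    if not 0.0 <= threshold_fraction < 1.0:
        raise ValueError("threshold must be in [0, 1)")
    i = np.asarray(intensities, dtype=float)
    if i.sum() <= 0:
        return 0
    frac = i / i.sum()
    above = np.flatnonzero(frac > threshold_fraction)
    return int(above.max() + 1) if len(above) else 0


@dataclass
class ConditionComparison:
    times_min: np.ndarray
    delta_m_over_o: np.ndarray  # b - a per bin
    delta_m_over_o_ci: np.ndarray | None  # (T, 2) bootstrap CI, None if unavailable
    delta_max_order: np.ndarray
    flags: list[str] = field(default_factory=list)


def compare_conditions(
    a: KineticsTable,
    b: KineticsTable,
    threshold_fraction: float = 0.01,
    n_bootstrap: int = 200,
    seed: int = 0,
    include_monomer: bool = True,
) -> ConditionComparison:
    """Per-timepoint difference curves (b - a) of M/O and max order, with
    bootstrap CIs over replicates when both tables carry more than one."""
    if len(a.times_min) != len(b.times_min) or np.any(a.times_min != b.times_min):
        raise ValueError("time bins are not aligned; bin both tables first")
    d_mo = np.array(
        [
            m_over_o(b.intensities[t], include_monomer)
            - m_over_o(a.intensities[t], include_monomer)
            for t in range(len(a.times_min))
        ]
    )
    d_max = np.array(
        [
            max_order_present(b.intensities[t], threshold_fraction)
            - max_order_present(a.intensities[t], threshold_fraction)
            for t in range(len(a.times_min))
        ]
    )
    flags: list[str] = []
    ci = None
    if a.n_replicates > 1 and b.n_replicates > 1 and n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        draws = np.empty((n_bootstrap, len(a.times_min)))
        for k in range(n_bootstrap):
            ia = rng.integers(0, a.n_replicates, a.n_replicates)
            ib = rng.integers(0, b.n_replicates, b.n_replicates)
            mean_a = a.replicate_intensities[ia].mean(axis=0)
            mean_b = b.replicate_intensities[ib].mean(axis=0)
            draws[k] = [
                m_over_o(mean_b[t], include_monomer)
                - m_over_o(mean_a[t], include_monomer)
                for t in range(len(a.times_min))
            ]
        ci = np.percentile(draws, [2.5, 97.5], axis=0).T
    else:
        flags.append("ci-unavailable-single-replicate")
    return ConditionComparison(
        times_min=a.times_min.copy(),
        delta_m_over_o=d_mo,
        delta_m_over_o_ci=ci,
        delta_max_order=d_max,
        flags=flags,
    )


def m_over_o_curve(table: KineticsTable, include_monomer: bool = True) -> pd.DataFrame:
    """M/O and max order per time bin, as a tidy frame."""
    return pd.DataFrame(
        {
            "time_min": table.times_min,
            "m_over_o": [
                m_over_o(v, include_monomer) for v in table.intensities
            ],
            "max_order": [max_order_present(v) for v in table.intensities],
            "condition": table.condition,
        }
    )
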