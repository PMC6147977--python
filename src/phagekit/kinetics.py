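"""Phage kinetics estimators: burst size, latent period, adsorption, host range.

Burst size is the ratio of the post-burst to pre-burst titer plateaus of a
one-step growth experiment; the latent period is read off the curve as the
first sampling time whose mean titer exceeds a rise factor over the initial
plateau. The adsorption rate constant comes from the log-linear decay of the
free-phage fraction. Host-range tables of spot-assay outcomes are summarized
per strain class (clearing vs productive lysis percentages).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OneStepGrowthData",
    "AdsorptionData",
    "SpotAssayTable",
    "burst_size",
    "latent_period",
    "adsorption_profile",
    "AdsorptionProfile",
    "host_range_summary",
]


@dataclass
class OneStepGrowthData:
    """Timed plaque-titer table of a one-step growth experiment.

    ``titers`` has shape (n_times, n_replicates) in pfu/ml.
    """

    times: np.ndarray           # min
    titers: np.ndarray          # pfu/ml
    dilution_factor: float = 1e-4
    moi_nominal: float = 0.01

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.titers = np.atleast_2d(np.asarray(self.titers, dtype=float))
        if self.titers.shape[0] != len(self.times):
            raise ValueError("titers must have one row per sampling time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.titers < 0):
            raise ValueError("titers must be >= 0")


@dataclass
class AdsorptionData:
    """Free-phage titers over time after mixing phage with host cells."""

    times: np.ndarray           # min
    free_titers: np.ndarray     # pfu/ml, shape (n_times, n_replicates)
    cell_density: float         # cfu/ml
    p0: float                   # initial pfu/ml

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.free_titers = np.atleast_2d(
            np.asarray(self.free_titers, dtype=float)
        )
        if self.free_titers.shape[0] != len(self.times):
            raise ValueError("free_titers must have one row per time")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.free_titers < 0):
            raise ValueError("free titers must be >= 0")
        if self.p0 <= 0:
            raise ValueError("p0 must be > 0")


def burst_size(data: OneStepGrowthData, k: int = 3) -> tuple[float, float]:
    """Burst size as the final/initial plateau titer ratio, mean +- sd.

    The initial (final) plateau is the mean of the first (last) ``k``
    samples; the ratio is computed per replicate and summarized across
    replicates.
    """
    if len(data.times) < 2 * k:
        raise ValueError(
            f"need >= {2 * k} sampling times for plateaus of k={k}"
        )
    initial = data.titers[:k].mean(axis=0)
    final = data.titers[-k:].mean(axis=0)
    if np.any(initial == 0):
        raise ValueError("initial plateau titer is zero; burst undefined")
    ratios = final / initial
    sd = float(np.std(ratios, ddof=1)) if len(ratios) > 1 else 0.0
    return float(np.mean(ratios)), sd


def latent_period(
    data: OneStepGrowthData, rise_factor: float = 2.0, k: int = 3
) -> tuple[float, bool]:
    """First sampled time whose mean titer exceeds rise_factor x the
    initial plateau; reported at sampling resolution.

    Returns ``(time_min, burst_detected)``; when the titer never rises the
    horizon (last sampling time) is reported with ``burst_detected=False``.
    """
    initial = float(data.titers[:k].mean())
    means = data.titers.mean(axis=1)
    above = np.nonzero(means > rise_factor * initial)[0]
    if len(above) == 0:
        return float(data.times[-1]), False
    return float(data.times[above[0]]), True


@dataclass
class AdsorptionProfile:
    """Adsorption summary: free fraction per time, t99, fitted rate."""

    times: np.ndarray
    fraction_free: np.ndarray
    t99: float | None           # min; first sampled time with <=1% free
    k_hat: float | None         # effective first-order rate (1/min)


def adsorption_profile(data: AdsorptionData) -> AdsorptionProfile:
    """Free-phage fraction over time, t99 and the fitted decay rate.

    fraction_free(t) = mean free titer / p0. t99 is the first sampled time
    at which no more than 1% of phage remains free (none if never reached).
    k_hat is minus the slope of ln(fraction_free) vs t, fitted by weighted
    least squares over times with positive mean counts, weights proportional
    to the counts (variance-stabilizing for Poisson plaque counts).
    """
    means = data.free_titers.mean(axis=1)
    frac = means / data.p0
    below = np.nonzero(frac <= 0.01 + 1e-12)[0]
    t99 = float(data.times[below[0]]) if len(below) else None
    pos = means > 0
    if pos.sum() < 2:
        return AdsorptionProfile(
            times=data.times, fraction_free=frac, t99=t99, k_hat=None
        )
    x = data.times[pos]
    y = np.log(frac[pos])
    w = means[pos]
    xm = np.average(x, weights=w)
    ym = np.average(y, weights=w)
    slope = np.sum(w * (x - xm) * (y - ym)) / np.sum(w * (x - xm) ** 2)
    return AdsorptionProfile(
        times=data.times, fraction_free=frac, t99=t99, k_hat=float(-slope)
    )


@dataclass
class SpotAssayTable:
    """Spot-assay host-range outcomes, one row per strain.

    Columns: strain_id, strain_class ("clinical" | "reference"),
    clearing_undiluted (bool), plaques_at_dilution (bool). Visible plaques
    at dilution imply clearing when spotted undiluted.
    """

    rows: pd.DataFrame

    REQUIRED = ("strain_id", "strain_class", "clearing_undiluted",
                "plaques_at_dilution")

    def __post_init__(self) -> None:
        if isinstance(self.rows, list):
            self.rows = pd.DataFrame(self.rows, columns=list(self.REQUIRED))
        missing = [c for c in self.REQUIRED if c not in self.rows.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        bad = self.rows["plaques_at_dilution"] & ~self.rows["clearing_undiluted"]
        if bad.any():
            raise ValueError(
                "plaques_at_dilution implies clearing_undiluted; violated by "
                f"strains {list(self.rows.loc[bad, 'strain_id'])}"
            )
        unknown = set(self.rows["strain_class"]) - {"clinical", "reference"}
        if unknown:
            raise ValueError(f"unknown strain classes: {sorted(unknown)}")


def host_range_summary(table: SpotAssayTable) -> pd.DataFrame:
    """Per-class host-range counts and percentages.

    Clearing = lysis zone with the undiluted spot; productive = individual
    plaques visible on titration (true phage replication rather than lysis
    from without). Percentages are rounded half-up to the nearest integer.
    """
    df = table.rows
    if len(df) == 0:
        raise ValueError("empty spot-assay table")
    out = []
    for cls, grp in df.groupby("strain_class", sort=True):
        n = len(grp)
        n_clear = int(grp["clearing_undiluted"].sum())
        n_prod = int(grp["plaques_at_dilution"].sum())
        out.append(
            {
                "strain_class": cls,
                "n": n,
                "n_clearing": n_clear,
                "n_productive": n_prod,
                "pct_clearing": int(np.floor(100.0 * n_clear / n + 0.5)),
                "pct_productive": int(np.floor(100.0 * n_prod / n + 0.5)),
            }
        )
    return pd.DataFrame(out).set_index("strain_class")
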