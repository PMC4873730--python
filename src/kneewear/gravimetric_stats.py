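"""Gravimetric wear analysis and group statistics for simulator studies.

Insert wear in a physical knee simulator is measured by weighing: the mass
loss of each loaded insert, corrected for fluid uptake using unloaded soak
controls, is converted to a wear volume with the polyethylene density
(0.93 mg/mm^3).  Per-insert volumetric wear rates come from a
least-squares slope of cumulative volume against million cycles (through
the origin by default), station groups are summarised as mean with
t-based 95% confidence limits, and conditions are compared with a
homogeneity-of-variance check, one-way ANOVA, and Tukey's post-hoc test at
p < 0.05.

Input records are long-format tables (one row per weighing) with columns
``station``, ``insert``, ``cycles_mc``, ``mass_mg``, ``role`` where role is
``test`` or ``soak_control``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POLYETHYLENE_DENSITY_MG_PER_MM3",
    "GravimetricRecord",
    "WearRateEstimate",
    "mass_to_volume",
    "volumes_from_records",
    "fit_wear_rate",
    "compare_conditions",
    "simulate_gravimetric_study",
]

POLYETHYLENE_DENSITY_MG_PER_MM3 = 0.93
RECORD_COLUMNS = ["station", "insert", "cycles_mc", "mass_mg", "role"]


@dataclass(frozen=True)
class GravimetricRecord:
    """One weighing of one insert."""

    station: str
    insert: str
    cycles_mc: float
    mass_mg: float
    role: str = "test"  # "test" | "soak_control"


@dataclass
class WearRateEstimate:
    """Group wear rate: mean, symmetric 95% confidence limit, per-insert rates."""

    mean_rate_mm3_per_MC: float
    ci95_mm3_per_MC: float  # half-width; NaN when not estimable
    per_insert_rates: pd.Series

    @property
    def limits(self) -> tuple[float, float]:
        return (
            self.mean_rate_mm3_per_MC - self.ci95_mm3_per_MC,
            self.mean_rate_mm3_per_MC + self.ci95_mm3_per_MC,
        )


def mass_to_volume(
    mass_loss_mg,
    soak_gain_mg=0.0,
    density_mg_per_mm3: float = POLYETHYLENE_DENSITY_MG_PER_MM3,
):
    """Convert a soak-corrected mass loss to a wear volume (mm^3).

    The apparent mass loss of a loaded insert understates true wear by the
    fluid the insert absorbed; the mean mass *gain* of the unloaded soak
    controls is added back before dividing by density.  A negative
    corrected loss (fluid uptake exceeding wear) is returned as a negative
    volume with a warning rather than clipped.
    """
    if density_mg_per_mm3 <= 0:
        raise ValueError("density must be positive")
    loss = np.asarray(mass_loss_mg, dtype=float)
    vol = (loss + np.asarray(soak_gain_mg, dtype=float)) / density_mg_per_mm3
    if np.any(np.atleast_1d(vol) < 0):
        warnings.warn(
            "corrected mass loss is negative (fluid uptake exceeded wear); "
            "returning negative volume",
            stacklevel=2,
        )
    return vol if np.ndim(mass_loss_mg) else float(vol)


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        df = records.copy()
    else:
        df = pd.DataFrame([r.__dict__ for r in records])
    missing = set(RECORD_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    return df


def volumes_from_records(
    records,
    density_mg_per_mm3: float = POLYETHYLENE_DENSITY_MG_PER_MM3,
) -> pd.DataFrame:
    """Cumulative soak-corrected wear volume per test insert and time point.

    The soak correction at each time point is the mean cumulative mass gain
    of the soak-control inserts at that time point.  Cycle counts must be
    non-decreasing within each insert.
    """
    df = _as_frame(records)
    for insert, grp in df.groupby("insert"):
        if np.any(np.diff(grp.sort_index()["cycles_mc"].to_numpy()) < 0):
            raise ValueError(f"cycle counts decrease for insert {insert!r}")

    def cumulative_change(grp: pd.DataFrame) -> pd.Series:
        grp = grp.sort_values("cycles_mc")
        m0 = grp.loc[grp["cycles_mc"].idxmin(), "mass_mg"]
        return grp.assign(delta_mg=grp["mass_mg"] - m0)

    test = df[df["role"] == "test"]
    ctrl = df[df["role"] == "soak_control"]
    test = pd.concat(
        [cumulative_change(g) for _, g in test.groupby("insert")], ignore_index=True
    )
    if len(ctrl):
        ctrl = pd.concat(
            [cumulative_change(g) for _, g in ctrl.groupby("insert")],
            ignore_index=True,
        )
        soak = ctrl.groupby("cycles_mc")["delta_mg"].mean()
    else:
        soak = pd.Series(dtype=float)

    gain = test["cycles_mc"].map(soak).fillna(0.0)
    loss = -test["delta_mg"]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        volume = mass_to_volume(loss.to_numpy(), gain.to_numpy(), density_mg_per_mm3)
    out = test[["station", "insert", "cycles_mc"]].copy()
    out["volume_mm3"] = volume
    return out[out["cycles_mc"] > 0].reset_index(drop=True)


def _slope_through_origin(x: np.ndarray, y: np.ndarray) -> float:
    return float(x @ y / (x @ x))


def fit_wear_rate(
    volumes: pd.DataFrame,
    mode: str = "regression",
    confidence: float = 0.95,
) -> WearRateEstimate:
    """Per-insert wear rates and the group mean with t-based confidence limits.

    ``volumes`` is the output of :func:`volumes_from_records` (columns
    ``insert``, ``cycles_mc``, ``volume_mm3``).  ``mode='regression'`` fits
    a least-squares slope through the origin per insert; ``'endpoint'``
    divides the final volume by the final cycle count.  An insert with a
    single time point falls back to the endpoint rate.  The confidence
    limit uses the t distribution across inserts (NaN for one insert).
    """
    if mode not in ("regression", "endpoint"):
        raise ValueError("mode must be 'regression' or 'endpoint'")
    rates = {}
    for insert, grp in volumes.groupby("insert"):
        x = grp["cycles_mc"].to_numpy(dtype=float)
        y = grp["volume_mm3"].to_numpy(dtype=float)
        if len(x) == 0:
            continue
        if mode == "endpoint" or len(x) == 1:
            idx = np.argmax(x)
            rates[insert] = y[idx] / x[idx]
        else:
            rates[insert] = _slope_through_origin(x, y)
    per = pd.Series(rates, name="rate_mm3_per_MC").sort_index()
    n = len(per)
    if n == 0:
        raise ValueError("no test-insert volumes to fit")
    mean = float(per.mean())
    if n < 2:
        ci = float("nan")
    else:
        tcrit = stats.t.ppf(0.5 + confidence / 2.0, n - 1)
        ci = float(tcrit * per.std(ddof=1) / np.sqrt(n))
    return WearRateEstimate(mean, ci, per)


def compare_conditions(groups: dict, alpha: float = 0.05) -> dict:
    """Homogeneity check, one-way ANOVA, and Tukey pairwise comparisons.

    ``groups`` maps condition name to an array of per-insert wear rates
    (each of size >= 2).  Returns a dict with the Levene statistic, the
    ANOVA F and p, and a Tukey table (DataFrame with adjusted p-values and
    significance flags at ``alpha``).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")

    lev_stat, lev_p = stats.levene(*arrays.values())
    f_stat, p_value = stats.f_oneway(*arrays.values())

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    values = np.concatenate(list(arrays.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arrays.items()])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    table = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    table["significant"] = table["reject"].astype(bool)
    return {
        "levene_stat": float(lev_stat),
        "levene_p": float(lev_p),
        "anova_F": float(f_stat),
        "anova_p": float(p_value),
        "alpha": alpha,
        "tukey": table,
    }


def simulate_gravimetric_study(
    rng: np.random.Generator,
    true_rates_mm3_per_MC: dict,
    n_inserts: int = 6,
    timepoints_mc=(1.0, 2.0, 3.0),
    insert_rate_sd: float = 1.5,
    balance_sd_mg: float = 0.02,
    soak_rate_mg_per_mc: float = 0.2,
    n_controls: int = 2,
    density_mg_per_mm3: float = POLYETHYLENE_DENSITY_MG_PER_MM3,
) -> pd.DataFrame:
    """Synthetic gravimetric records for one or more test conditions.

    Emulates the measurement chain of a six-station simulator study:
    insert-to-insert wear-rate variation (normal, ``insert_rate_sd``),
    linear fluid uptake shared with unloaded soak controls
    (``soak_rate_mg_per_mc``), and balance read noise (``balance_sd_mg``;
    a research microbalance resolves 0.01 mg).  Mass readings start from a
    nominal 30 g insert.  Returns a long-format record table suitable for
    :func:`volumes_from_records`.
    """
    rows = []
    m0 = 30_000.0  # mg, nominal insert mass
    for cond, rate in true_rates_mm3_per_MC.items():
        insert_rates = rng.normal(rate, insert_rate_sd, size=n_inserts)
        for i, r in enumerate(insert_rates):
            name = f"{cond}/insert{i + 1}"
            rows.append((cond, name, 0.0, m0 + rng.normal(0, balance_sd_mg), "test"))
            for tp in timepoints_mc:
                mass = (
                    m0
                    - r * tp * density_mg_per_mm3
                    + soak_rate_mg_per_mc * tp
                    + rng.normal(0, balance_sd_mg)
                )
                rows.append((cond, name, tp, mass, "test"))
        for i in range(n_controls):
            name = f"{cond}/soak{i + 1}"
            rows.append((cond, name, 0.0, m0 + rng.normal(0, balance_sd_mg), "soak_control"))
            for tp in timepoints_mc:
                mass = m0 + soak_rate_mg_per_mc * tp + rng.normal(0, balance_sd_mg)
                rows.append((cond, name, tp, mass, "soak_control"))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)
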