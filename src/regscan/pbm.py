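"""Protein-binding microarray (PBM) profile construction and comparison.

Replicate arrays are combined by quantile normalization, the eight replicate
probes of each unique sequence are summarized by their median fluorescence,
and log median fluorescence is standardized against the random-background
probe set:

    z = (ln F - mu) / sigma

where mu and sigma are the mean and (population) standard deviation of
ln F over background sequences only.  Two profiles are compared by ordinary
least squares on shared sequences after excluding pairs whose z-scores fall
below 2 (the exclusion rule is configurable to either / both / first axis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from . import io

log = logging.getLogger(__name__)

EXCLUSION_RULES = ("either", "both", "first")


@dataclass
class BindingProfile:
    """Per-unique-sequence z-scores with background membership flags."""

    z: pd.Series                # index: sequence
    is_background: pd.Series    # index: sequence, bool
    background_mu: float        # mean of ln F over background sequences
    background_sigma: float     # population sd of ln F over background sequences
    n_background: int

    def __post_init__(self):
        if self.background_sigma <= 0:
            raise ValueError("background_sigma must be positive")
        if not self.z.index.equals(self.is_background.index):
            raise ValueError("z and is_background must be indexed by the same sequences")

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame({
            "sequence": self.z.index,
            "z": self.z.values,
            "is_background": self.is_background.values,
        }).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "BindingProfile":
        df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
        z = pd.Series(df["z"].values, index=df["sequence"])
        bg = pd.Series(df["is_background"].astype(bool).values, index=df["sequence"])
        bgz = z[bg]
        # mu/sigma are recoverable only up to the z transform; store the
        # standardized background moments (0, 1) on round-trip.
        return cls(z, bg, background_mu=float(bgz.mean()), background_sigma=1.0,
                   n_background=int(bg.sum()))


@dataclass
class ProfileComparison:
    r_squared: float
    slope: float
    intercept: float
    n_used: int
    n_total: int

    def __post_init__(self):
        if self.n_used > self.n_total:
            raise ValueError("n_used cannot exceed n_total")


def quantile_normalize(tables: pd.DataFrame | Iterable[pd.Series]) -> pd.DataFrame:
    """Quantile-normalize per-array fluorescence vectors over identical probes.

    Columns are arrays, rows probes.  The value at rank r in each array is
    replaced by the mean across arrays of the rank-r values; tied values
    within an array receive the mean of their tied ranks' row means.  After
    normalization all arrays share one sorted value multiset.
    """
    if not isinstance(tables, pd.DataFrame):
        tables = list(tables)
        if len(tables) >= 2:
            idx = tables[0].index
            for t in tables[1:]:
                if not t.index.sort_values().equals(idx.sort_values()):
                    raise ValueError("arrays must cover identical probe sets")
        tables = pd.concat([t.reindex(tables[0].index) for t in tables], axis=1)
        tables.columns = range(tables.shape[1])
    if tables.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 arrays")
    if tables.isna().any().any():
        raise ValueError("arrays must cover identical probe sets (missing values found)")
    values = tables.to_numpy(dtype=float)
    row_means = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for c in range(values.shape[1]):
        col = values[:, c]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(row_means)
        assigned[order] = row_means
        # ties: average the row means assigned within each tied group
        out[:, c] = pd.Series(assigned).groupby(col, sort=False).transform("mean").to_numpy()
    return pd.DataFrame(out, index=tables.index, columns=tables.columns)


def aggregate_probes(measurements: pd.DataFrame) -> pd.DataFrame:
    """Median fluorescence per unique sequence across replicates and arrays.

    Expects probe-table columns (sequence, fluorescence, is_background); the
    background flag must be consistent within each sequence and is carried
    through to the output.
    """
    flags = measurements.groupby("sequence")["is_background"].nunique()
    conflicted = flags[flags > 1]
    if len(conflicted):
        raise ValueError(
            f"inconsistent is_background flag for sequences: {list(conflicted.index[:5])}"
        )
    agg = measurements.groupby("sequence").agg(
        fluorescence=("fluorescence", "median"),
        is_background=("is_background", "first"),
    )
    return agg.reset_index()


def zscore_profile(
    medians: Mapping[str, float] | pd.Series | pd.DataFrame,
    background: Iterable[str] | None = None,
) -> BindingProfile:
    """Standardize log median fluorescence against the background probe set.

    ``medians`` may be a mapping sequence -> median F (with ``background``
    the set of background sequences) or the aggregate_probes output frame.
    Natural log throughout; sigma is the population standard deviation.
    """
    if isinstance(medians, pd.DataFrame):
        series = pd.Series(medians["fluorescence"].values, index=medians["sequence"])
        background = set(medians.loc[medians["is_background"], "sequence"])
    else:
        series = pd.Series(medians, dtype=float)
        background = set(background or [])
    if not background:
        raise ValueError("background sequence set must be non-empty")
    if (series <= 0).any():
        raise ValueError("all fluorescence values must be positive for the log transform")
    logf = np.log(series.astype(float))
    bg_logf = logf.loc[logf.index.isin(background)]
    if bg_logf.empty:
        raise ValueError("no background sequences present in the median table")
    mu = float(bg_logf.mean())
    sigma = float(bg_logf.std(ddof=0))
    if sigma == 0:
        raise ValueError("background fluorescence is constant (sigma = 0)")
    z = (logf - mu) / sigma
    is_bg = pd.Series(z.index.isin(background), index=z.index)
    return BindingProfile(z, is_bg, mu, sigma, int(is_bg.sum()))


def compare_profiles(
    p1: BindingProfile,
    p2: BindingProfile,
    rule: str = "either",
    z_min: float = 2.0,
) -> ProfileComparison:
    """Best-fit line and R^2 between two profiles on shared sequences.

    Pairs with z below ``z_min`` are excluded: rule "either" retains a pair
    when at least one profile reaches z_min, "both" requires both, "first"
    filters on p1 only.
    """
    if rule not in EXCLUSION_RULES:
        raise ValueError(f"rule must be one of {EXCLUSION_RULES}")
    shared = p1.z.index.intersection(p2.z.index)
    if shared.empty:
        raise ValueError("profiles share no sequences")
    z1 = p1.z.loc[shared].to_numpy(dtype=float)
    z2 = p2.z.loc[shared].to_numpy(dtype=float)
    if rule == "either":
        keep = (z1 >= z_min) | (z2 >= z_min)
    elif rule == "both":
        keep = (z1 >= z_min) & (z2 >= z_min)
    else:
        keep = z1 >= z_min
    n_used = int(keep.sum())
    if n_used < 3:
        raise ValueError(f"fewer than 3 sequence pairs retained after exclusion ({n_used})")
    fit = stats.linregress(z1[keep], z2[keep])
    return ProfileComparison(
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n_used=n_used,
        n_total=int(len(shared)),
    )


def plot_comparison(p1: BindingProfile, p2: BindingProfile, path: str | Path,
                    rule: str = "either", z_min: float = 2.0) -> None:
    """Scatter of shared z-scores with the best-fit line, colored by background flag."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cmp = compare_profiles(p1, p2, rule=rule, z_min=z_min)
    shared = p1.z.index.intersection(p2.z.index)
    z1, z2 = p1.z.loc[shared], p2.z.loc[shared]
    bg = p1.is_background.loc[shared]
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(z1[bg], z2[bg], s=6, c="red", label="background")
    ax.scatter(z1[~bg], z2[~bg], s=6, c="blue", label="binding sites")
    xs = np.linspace(z1.min(), z1.max(), 10)
    ax.plot(xs, cmp.slope * xs + cmp.intercept, "k-", lw=1)
    ax.set_xlabel("z (profile 1)")
    ax.set_ylabel("z (profile 2)")
    ax.set_title(f"R$^2$ = {cmp.r_squared:.2f} (n = {cmp.n_used})")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def profile_from_probe_tables(paths: Iterable[str | Path]) -> BindingProfile:
    """Full PBM chain from probe TSVs: quantile-normalize arrays, take medians
    per unique sequence, z-score against background."""
    frames = [io.read_probe_table(p) for p in paths]
    df = pd.concat(frames, ignore_index=True)
    return profile_from_measurements(df)


def profile_from_measurements(df: pd.DataFrame) -> BindingProfile:
    arrays = sorted(df["array"].unique())
    if len(arrays) >= 2:
        wide = df.pivot_table(index="probe_id", columns="array",
                              values="fluorescence", aggfunc="first")
        norm = quantile_normalize(wide)
        long = norm.stack().rename("fluorescence").reset_index()
        df = df.drop(columns="fluorescence").merge(long, on=["probe_id", "array"])
    else:
        log.info("single array: skipping quantile normalization")
    medians = aggregate_probes(df)
    return zscore_profile(medians)
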