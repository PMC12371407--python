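"""Wave-level epidemic trend statistics.

Within-host diversity is summarized per (year, season, wave) stratum by its
median; a wave missing from one season can be imputed as the mean of the same
wave's medians from the other seasons; and the wave-over-wave decline in
heterozygosity is tested with a one-sided permutation test of

    median(pi | W1) - median(pi | W2 u W3),

permuting wave labels within season strata so that the season blocking of the
sampling design is respected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import IsolateMeta, Wave

__all__ = ["WaveTrend", "median_pi_by_wave", "impute_missing_wave", "test_wave_decline"]


@dataclass
class WaveTrend:
    """Per-stratum medians; rows (year, season, wave, median_pi, n, imputed)."""

    table: pd.DataFrame
    decline_statistic: float | None = None
    decline_p_value: float | None = None
    decline_method: str | None = None


def _strata_frame(
    pi_within: dict[str, float], metas: list[IsolateMeta]
) -> pd.DataFrame:
    meta_by_id = {m.sample_id: m for m in metas}
    rows = []
    for sid, pi in pi_within.items():
        m = meta_by_id.get(sid)
        if m is None:
            raise ValueError(f"sample {sid} has diversity but no metadata")
        if m.wave is None or m.season is None or m.year is None:
            raise ValueError(f"sample {sid} lacks (year, season, wave) labels")
        rows.append(
            {
                "sample_id": sid,
                "year": m.year,
                "season": m.season.value,
                "wave": m.wave.value,
                "pi": float(pi),
            }
        )
    return pd.DataFrame(rows)


def median_pi_by_wave(
    pi_within: dict[str, float], metas: list[IsolateMeta]
) -> WaveTrend:
    """Median within-host diversity per (year, season, wave).

    Strata present in the metadata but without any diversity values appear as
    missing rows (NaN median, zero count).
    """
    df = _strata_frame(pi_within, metas)
    agg = (
        df.groupby(["year", "season", "wave"])["pi"]
        .agg(median_pi="median", n="count")
        .reset_index()
    )
    seasons = agg[["year", "season"]].drop_duplicates()
    waves = pd.DataFrame({"wave": [w.value for w in Wave]})
    full = seasons.merge(waves, how="cross").merge(
        agg, on=["year", "season", "wave"], how="left"
    )
    full["n"] = full["n"].fillna(0).astype(int)
    full["imputed"] = False
    return WaveTrend(table=full.sort_values(["year", "season", "wave"]).reset_index(drop=True))


def impute_missing_wave(trend: WaveTrend) -> WaveTrend:
    """Fill a (season, wave) stratum missing its median with the mean of the
    same wave's medians from the other seasons; the imputed flag is set and
    the isolate count stays zero. A wave missing from every season is an
    error (nothing to average). Non-missing strata are never altered.
    """
    table = trend.table.copy()
    for wave in table["wave"].unique():
        rows = table["wave"] == wave
        missing = rows & table["median_pi"].isna()
        if not missing.any():
            continue
        donors = table.loc[rows & ~table["median_pi"].isna(), "median_pi"]
        if donors.empty:
            raise ValueError(f"wave {wave} missing in all seasons; cannot impute")
        table.loc[missing, "median_pi"] = float(donors.mean())
        table.loc[missing, "imputed"] = True
    return WaveTrend(
        table=table,
        decline_statistic=trend.decline_statistic,
        decline_p_value=trend.decline_p_value,
        decline_method=trend.decline_method,
    )


def test_wave_decline(
    pi_within: dict[str, float],
    metas: list[IsolateMeta],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[float, float]:
    """One-sided permutation test of the W1-vs-later decline in diversity.

    Statistic: median(pi | W1) - median(pi | W2 u W3). Wave labels are
    permuted within (year, season) strata; p = (1 + #permuted >= observed) /
    (1 + n_permutations). Requires >= 2 waves with >= 3 isolates each.
    """
    df = _strata_frame(pi_within, metas)
    counts = df.groupby("wave")["pi"].count()
    if (counts >= 3).sum() < 2:
        raise ValueError("need >= 2 waves with >= 3 isolates each")
    pi = df["pi"].to_numpy()
    is_w1 = (df["wave"] == "W1").to_numpy()
    if is_w1.sum() == 0 or (~is_w1).sum() == 0:
        raise ValueError("both W1 and later waves must be present")
    observed = float(np.median(pi[is_w1]) - np.median(pi[~is_w1]))
    season_codes = (
        df["year"].astype(str) + ":" + df["season"].astype(str)
    ).to_numpy()
    rng = np.random.default_rng(seed)
    n = len(pi)
    R = n_permutations
    # permute W1 membership within each season stratum; the W1 count per
    # stratum is fixed, so every permutation selects the same total k sites
    masks = np.zeros((R, n), dtype=bool)
    for code in np.unique(season_codes):
        idx = np.flatnonzero(season_codes == code)
        k = int(is_w1[idx].sum())
        if k == 0 or k == len(idx):
            masks[:, idx] = is_w1[idx]
            continue
        for r in range(R):
            chosen = rng.choice(idx, size=k, replace=False)
            masks[r, chosen] = True
    k_total = int(is_w1.sum())
    order = np.argsort(~masks, axis=1, kind="stable")
    w1_vals = pi[order[:, :k_total]]
    rest_vals = pi[order[:, k_total:]]
    perm_stats = np.median(w1_vals, axis=1) - np.median(rest_vals, axis=1)
    p = (1 + int(np.sum(perm_stats >= observed - 1e-15))) / (1 + R)
    return observed, float(p)


test_wave_decline.__test__ = False  # not a pytest test despite the name
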