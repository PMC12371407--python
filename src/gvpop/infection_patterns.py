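"""Within-host allele-frequency pattern classification.

An isolate's alternative-allele frequencies at the cohort's segregating sites
fall into three shapes: Pattern A (frequencies pinned at 0 or 1 — a single
detectable strain), Pattern B (bimodal — exactly two strains), and Pattern C
(high diversity without bimodality — more than two strains). The field
observation behind this taxonomy is qualitative, so the classifier
operationalizes it: frequencies inside an intermediate band are counted, and
if their fraction exceeds the Pattern-A threshold, 1-D Gaussian mixtures with
1..max_components components are fitted to the intermediate frequencies and
the component count chosen by BIC (2 -> B, >= 3 -> C; a single component is
resolved to Pattern B with a "merged modes" note, since one strain cannot put
a peak at intermediate frequency).

To make the classification exactly invariant under relabelling alleles
(p -> 1-p), each mixture size is fitted to both orientations of the data and
the better-likelihood fit is kept.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .diversity import AlleleProfile, pi_within_host
from .io_formats import IsolateMeta, Wave
from .variant_filtering import SegregatingSiteSet

__all__ = [
    "Pattern",
    "PatternCall",
    "classify_pattern",
    "classify_cohort",
    "mixed_to_single_ratio",
]


class Pattern(str, enum.Enum):
    A = "A"  # single strain
    B = "B"  # two strains
    C = "C"  # more than two strains
    UNDETERMINED = "undetermined"


@dataclass
class PatternCall:
    sample_id: str
    pattern: Pattern
    n_intermediate_sites: int
    intermediate_fraction: float
    n_modes: int
    pi_within: float
    note: str | None = None


def _best_mixture_bic(x: np.ndarray, max_components: int, seed: int) -> tuple[int, float]:
    """BIC-selected component count and the winning fit's mean variance.

    Each size is fitted to both orientations of the data (x and 1-x) and the
    better likelihood kept, which makes the selection exactly invariant under
    allele relabelling.
    """
    X = x.reshape(-1, 1)
    Xf = (1.0 - x).reshape(-1, 1)
    best_k, best_bic, best_var = 1, np.inf, float("nan")
    for k in range(1, min(max_components, len(x)) + 1):
        for data in (X, Xf):
            gm = GaussianMixture(
                n_components=k,
                covariance_type="spherical",
                random_state=seed,
                n_init=3,
                reg_covar=1e-5,
            ).fit(data)
            bic = gm.bic(data)
            if bic < best_bic - 1e-9:
                best_bic, best_k = bic, k
                best_var = float(np.mean(gm.covariances_))
    return best_k, best_var


def classify_pattern(
    profile: AlleleProfile,
    sites: SegregatingSiteSet,
    intermediate_band: tuple[float, float] = (0.10, 0.90),
    max_intermediate_fraction_for_A: float = 0.05,
    max_components: int = 4,
    min_sites: int = 10,
    min_depth: int = 10,
    overdispersion_factor: float = 4.0,
    seed: int = 0,
) -> PatternCall:
    """Classify one isolate's within-host allele-frequency distribution.

    Frequencies are taken at the segregating sites with depth >= min_depth
    (absent sites count as p = 0). Fewer than ``min_sites`` usable sites
    yields an UNDETERMINED call, never a silent Pattern A.

    A fit with <= 2 components whose component variance exceeds
    ``overdispersion_factor`` times the binomial sequencing-noise expectation
    p(1-p)/D is called Pattern C: the frequencies are too dispersed for two
    clean strains, which is the "high diversity but no bimodality" signature.
    """
    lo, hi = intermediate_band
    pos_set = {int(p) for p in sites.positions}
    keep = np.array(
        [int(p) in pos_set and d >= min_depth for p, d in zip(profile.positions, profile.depth)],
        dtype=bool,
    ) if len(profile.positions) else np.zeros(0, bool)
    p_obs = profile.p[keep] if keep.size else np.empty(0)
    # segregating sites absent from the profile are fixed reference
    n_absent = len(pos_set) - len({int(q) for q in profile.positions[keep]} & pos_set) if keep.size else len(pos_set)
    p_all = np.concatenate([p_obs, np.zeros(n_absent)])
    pi = pi_within_host(profile, sites) if len(sites) else float("nan")
    # only sites actually observed at adequate depth count toward the minimum
    if len(p_obs) < min_sites:
        return PatternCall(
            sample_id=profile.sample_id,
            pattern=Pattern.UNDETERMINED,
            n_intermediate_sites=0,
            intermediate_fraction=float("nan"),
            n_modes=0,
            pi_within=pi,
            note="fewer usable sites than the minimum",
        )
    inter_mask = (p_obs >= lo) & (p_obs <= hi)
    inter = p_obs[inter_mask]
    inter_depth = profile.depth[keep][inter_mask] if keep.size else np.empty(0)
    frac = len(inter) / len(p_all)
    if frac <= max_intermediate_fraction_for_A:
        return PatternCall(
            sample_id=profile.sample_id,
            pattern=Pattern.A,
            n_intermediate_sites=len(inter),
            intermediate_fraction=frac,
            n_modes=1,
            pi_within=pi,
        )
    k, fit_var = _best_mixture_bic(inter, max_components, seed)
    noise_var = float(np.mean(inter * (1 - inter) / np.maximum(inter_depth, 1)))
    if k >= 3:
        pattern, note = Pattern.C, None
    elif fit_var > overdispersion_factor * max(noise_var, 1e-12):
        pattern, note = Pattern.C, "overdispersed modes (no clean bimodality)"
    elif k == 2:
        pattern, note = Pattern.B, None
    else:
        pattern, note = Pattern.B, "merged modes (two strains near 50:50)"
    return PatternCall(
        sample_id=profile.sample_id,
        pattern=pattern,
        n_intermediate_sites=len(inter),
        intermediate_fraction=frac,
        n_modes=k,
        pi_within=pi,
        note=note,
    )


def classify_cohort(
    profiles: dict[str, AlleleProfile],
    sites: SegregatingSiteSet,
    seed: int = 0,
    **kwargs,
) -> list[PatternCall]:
    return [
        classify_pattern(profiles[sid], sites, seed=seed, **kwargs)
        for sid in sorted(profiles)
    ]


def mixed_to_single_ratio(
    calls: list[PatternCall],
    metas: list[IsolateMeta],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Mixed:single infection ratio per (year, season, wave) stratum.

    ratio = (#B + #C) / #A; strata without Pattern-A calls are flagged
    infinite and excluded from the correlation. Returns (table, Spearman rho
    of ratio vs wave ordinal, one-sided permutation p-value for negative
    correlation).
    """
    meta_by_id = {m.sample_id: m for m in metas}
    rows = []
    for c in calls:
        m = meta_by_id.get(c.sample_id)
        if m is None:
            raise ValueError(f"no metadata for sample {c.sample_id}")
        if c.pattern is Pattern.UNDETERMINED or m.wave is None:
            continue
        rows.append(
            {
                "year": m.year,
                "season": m.season.value,
                "wave": m.wave.value,
                "wave_ordinal": m.wave.ordinal,
                "pattern": c.pattern.value,
            }
        )
    if not rows:
        raise ValueError("no classified strata")
    df = pd.DataFrame(rows)
    strata = (
        df.groupby(["year", "season", "wave", "wave_ordinal"])["pattern"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["A", "B", "C"], fill_value=0)
        .reset_index()
    )
    strata["mixed"] = strata["B"] + strata["C"]
    strata["ratio"] = np.where(
        strata["A"] > 0, strata["mixed"] / strata["A"], np.inf
    )
    strata["infinite"] = ~np.isfinite(strata["ratio"])
    finite = strata[~strata["infinite"]]
    if len(finite) < 3 or finite["ratio"].nunique() < 2 or finite["wave_ordinal"].nunique() < 2:
        return strata, float("nan"), float("nan")
    rho = float(stats.spearmanr(finite["wave_ordinal"], finite["ratio"]).statistic)
    rng = np.random.default_rng(seed)
    ratios = finite["ratio"].to_numpy()
    ordinals = finite["wave_ordinal"].to_numpy()
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(ordinals)
        r = stats.spearmanr(perm, ratios).statistic
        if r <= rho:
            count += 1
    p = (1 + count) / (1 + n_permutations)
    return strata, rho, p
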