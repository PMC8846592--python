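"""Columnar color selectivity and selectivity-conditioned transmission.

Per recording site, the color selectivity index (CSI) contrasts gamma-band
(30-150 Hz) power evoked by red vs green distractors in the receptive field:

    CSI = (r_red - r_green) / (r_red + r_green),

bounded in [-1, 1], positive for red preference.  The column color
selectivity index (CCSI) is the mean CSI across the column's 15 sites.

Column-level significance compares the column's Wilcoxon signed-rank
statistic with the distribution of the same statistic over bootstrap
pseudo-columns: each pseudo-column draws 15 site values with replacement
from the pooled site CSIs of all columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SelectivityProfile:
    site_csi: np.ndarray
    ccsi: float
    p: float
    selective: bool
    preferred_color: str       # 'red', 'green' or 'none'
    degenerate: bool = False


def csi(r_red, r_green):
    """Color selectivity index from red/green gamma powers.

    Antisymmetric under swapping its inputs and bounded in [-1, 1].  Accepts
    scalars or arrays; rejects non-positive denominators.
    """
    r_red = np.asarray(r_red, dtype=float)
    r_green = np.asarray(r_green, dtype=float)
    denom = r_red + r_green
    if np.any(denom <= 0):
        raise ValueError("r_red + r_green must be positive")
    out = (r_red - r_green) / denom
    return float(out) if out.ndim == 0 else out


def ccsi(site_csis) -> float:
    """Column color selectivity index: arithmetic mean of the site CSIs."""
    arr = np.asarray(site_csis, dtype=float)
    if arr.size == 0:
        raise ValueError("no site CSIs supplied")
    return float(arr.mean())


def bootstrap_null(
    all_site_ratios: np.ndarray,
    n_sites: int = 15,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Bootstrap pseudo-columns from the pooled per-site CSI values.

    Each of ``n_boot`` rows holds ``n_sites`` values resampled with
    replacement from the pool (the paper's pool holds 450 site values from
    30 columns).  Returns an (n_boot, n_sites) array.
    """
    pool = np.asarray(all_site_ratios, dtype=float).ravel()
    if pool.size == 0:
        raise ValueError("empty site-ratio pool")
    if pool.size < n_sites:
        raise ValueError("pool smaller than a column")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.choice(pool, size=(n_boot, n_sites), replace=True)


def _signed_rank_statistic(values: np.ndarray) -> float:
    """Signed rank sum W = sum(sign(v) * rank(|v|)), zeros dropped."""
    v = np.asarray(values, dtype=float)
    v = v[v != 0]
    if v.size == 0:
        return 0.0
    ranks = stats.rankdata(np.abs(v))
    return float(np.sum(np.sign(v) * ranks))


def test_selectivity(
    column_csis: np.ndarray,
    null_distributions: np.ndarray,
    alpha: float = 0.05,
) -> SelectivityProfile:
    """Column selectivity via signed-rank statistic vs its bootstrap null.

    The column's signed-rank statistic (CSIs against zero) is compared
    two-sidedly with the distribution of the same statistic over the
    bootstrap pseudo-columns; selective iff p < alpha.  The preferred color
    follows the CCSI sign.  A column of all-tied (zero) CSIs is flagged
    degenerate with p = 1.
    """
    col = np.asarray(column_csis, dtype=float)
    null = np.asarray(null_distributions, dtype=float)
    if null.ndim != 2 or null.shape[1] != col.size:
        raise ValueError("null column width must match the column's site count")
    if np.all(col == 0):
        return SelectivityProfile(
            site_csi=col, ccsi=0.0, p=1.0, selective=False,
            preferred_color="none", degenerate=True,
        )
    w_obs = _signed_rank_statistic(col)
    w_null = np.array([_signed_rank_statistic(row) for row in null])
    n_boot = w_null.size
    p = (1.0 + np.sum(np.abs(w_null) >= abs(w_obs))) / (1.0 + n_boot)
    c = ccsi(col)
    selective = p < alpha
    preferred = "none"
    if selective and c != 0:
        preferred = "red" if c > 0 else "green"
    return SelectivityProfile(
        site_csi=col, ccsi=c, p=float(p), selective=bool(selective),
        preferred_color=preferred,
    )


def profile_to_frame(profile: SelectivityProfile) -> pd.DataFrame:
    """Per-site rows plus a column-summary row, for CSV export."""
    rows = [
        {"site_index": i, "csi": v, "ccsi": np.nan, "p": np.nan,
         "selective": np.nan, "preferred": ""}
        for i, v in enumerate(profile.site_csi)
    ]
    rows.append(
        {"site_index": -1, "csi": np.nan, "ccsi": profile.ccsi, "p": profile.p,
         "selective": profile.selective, "preferred": profile.preferred_color}
    )
    return pd.DataFrame(rows)


@dataclass
class ConditionedTransmission:
    """Preferred-minus-non-preferred transmission difference per compartment."""

    times_ms: np.ndarray
    difference: dict[str, np.ndarray]       # preferred minus non-preferred, bits
    subset_average: dict[str, np.ndarray]   # mean over the two color subsets
    preferred_color: str
    n_trials_preferred: int
    n_trials_nonpreferred: int


def conditioned_transmission(
    x: np.ndarray,
    compartments: dict[str, np.ndarray],
    extracortical: np.ndarray,
    rf_colors: np.ndarray,
    preferred_color: str,
    times_ms: np.ndarray,
    t_indices: np.ndarray,
    *,
    lag_samples: int = 10,
    n_bins: int = 5,
    min_trials: int = 20,
) -> ConditionedTransmission:
    """Information transmission computed separately per RF-color subset.

    For each laminar compartment, I_T(target; CSD -> extracortical) is
    evaluated on trials with the preferred color in the receptive field and
    on trials with the non-preferred color, and the difference (preferred
    minus non-preferred) plus the subset average is returned per timepoint.
    Requires a classified preferred color and at least ``min_trials`` trials
    per subset.
    """
    from .infotheory import TransmissionSpec, information_transmission

    if preferred_color not in ("red", "green"):
        raise ValueError("column is not color selective; conditioned transmission skipped")
    rf_colors = np.asarray(rf_colors)
    pref_mask = rf_colors == preferred_color
    nonpref_mask = ~pref_mask
    if pref_mask.sum() < min_trials or nonpref_mask.sum() < min_trials:
        raise ValueError(
            f"need >= {min_trials} trials per color subset "
            f"(got {int(pref_mask.sum())} / {int(nonpref_mask.sum())})"
        )
    t_indices = np.asarray(t_indices)
    diff: dict[str, np.ndarray] = {}
    avg: dict[str, np.ndarray] = {}
    for name, series in compartments.items():
        per_color = {}
        for label, mask in (("pref", pref_mask), ("nonpref", nonpref_mask)):
            spec = TransmissionSpec(
                x=np.asarray(x)[mask],
                y=np.asarray(series)[mask],
                z=np.asarray(extracortical)[mask],
                lag_samples=lag_samples,
                n_bins=n_bins,
            )
            per_color[label] = np.array(
                [information_transmission(spec, int(t)) for t in t_indices]
            )
        diff[name] = per_color["pref"] - per_color["nonpref"]
        avg[name] = 0.5 * (per_color["pref"] + per_color["nonpref"])
    return ConditionedTransmission(
        times_ms=np.asarray(times_ms)[t_indices],
        difference=diff,
        subset_average=avg,
        preferred_color=preferred_color,
        n_trials_preferred=int(pref_mask.sum()),
        n_trials_nonpreferred=int(nonpref_mask.sum()),
    )


def ccsi_transmission_correlation(
    ccsi_values: np.ndarray,
    transmission_differences: dict[str, np.ndarray],
) -> dict[str, tuple[float, float]]:
    """Spearman correlation of |CCSI| vs transmission difference per compartment.

    ``transmission_differences[name]`` holds one session-level difference
    value per session (e.g. averaged over 160-180 ms).  Returns
    {compartment: (rho, p)}.  Requires >= 5 sessions; constant inputs yield
    (NaN, NaN).
    """
    cc = np.abs(np.asarray(ccsi_values, dtype=float))
    out: dict[str, tuple[float, float]] = {}
    for name, vals in transmission_differences.items():
        v = np.asarray(vals, dtype=float)
        if v.shape != cc.shape:
            raise ValueError("one difference value per session required")
        ok = np.isfinite(v) & np.isfinite(cc)
        if ok.sum() < 5:
            raise ValueError("need at least 5 sessions with valid values")
        if np.std(v[ok]) == 0 or np.std(cc[ok]) == 0:
            out[name] = (float("nan"), float("nan"))
            continue
        rho, p = stats.spearmanr(cc[ok], v[ok])
        out[name] = (float(rho), float(p))
    return out
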