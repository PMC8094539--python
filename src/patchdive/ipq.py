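"""Index of Patch Quality (IPQ) from optimal-diving theory.

The model: during the bottom phase of a dive, energy gain follows a
diminishing-returns curve g(t) = a * t^x, where the exponent x measures
patch quality.  The post-dive surface pause needed to recover from a dive
of duration u is s(u) = b * exp(c*u).  A diver maximizing its long-run
gain rate

    R(u) = g(u - tau) / (u + s(u)),    tau = transit (descent + ascent)

chooses a dive duration u* that satisfies the first-order condition; by
the principle of inverse optimality the observed u therefore reveals x:

    x = (1 + b*c*e^{cu}) * (u - tau) / (b*e^{cu} + u)        ("consistent")

The widely printed variant with denominator b*c*e^{cu} + u is retained as
``form="as_printed"``; it does NOT follow from the rate-maximization above
and fails the forward-model inversion check, so the consistent form is the
default (see docs/methods.md).

Constants b and c are estimated from observed (u, s) pairs of foraging
dives by a median-based (Theil-Sen) fit of log s = log b + c*u.  Dives
whose pause exceeds the bout threshold (default 325 s) are excluded from
both estimation and IPQ computation, as long pauses no longer measure
recovery.  Computed IPQ values above 5 are discarded as unphysical.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "IPQConstants",
    "PAUSE_THRESHOLD_S",
    "IPQ_CAP",
    "compute_ipq",
    "fit_constants",
    "estimate_pause_threshold",
    "detect_bouts",
    "summarize_bouts",
    "add_ipq",
]

PAUSE_THRESHOLD_S = 325.0
IPQ_CAP = 5.0


@dataclass(frozen=True)
class IPQConstants:
    """Shared surface-pause model parameters: s(u) = b * exp(c*u)."""

    b: float  # s; pause extrapolated to a zero-length dive
    c: float  # 1/s; exponential growth rate of pause with dive duration
    n_dives_used: int = 0
    method: str = "theil-sen"

    def __post_init__(self):
        if not (self.b > 0 and self.c > 0):
            raise ValueError(f"pause model requires b, c > 0 (got b={self.b}, c={self.c})")

    def pause(self, u):
        return self.b * np.exp(self.c * np.asarray(u, dtype=float))


def compute_ipq(u, tau, b: float, c: float, form: str = "consistent"):
    """Per-dive patch quality x from duration u and transit time tau.

    Vectorized over u/tau.  Dives with u <= tau return NaN.  Evaluated via
    exp(-c*u) so it never overflows.  Values above ``IPQ_CAP`` are NOT
    masked here (see :func:`add_ipq` for the exclusion bookkeeping).
    """
    if b <= 0 or c <= 0:
        raise ValueError("b and c must be positive")
    u = np.asarray(u, dtype=float)
    tau = np.asarray(tau, dtype=float)
    e = np.exp(-c * u)  # in (0, 1]; no overflow for any u >= 0
    if form == "consistent":
        x = (u - tau) * (e + b * c) / (u * e + b)
    elif form == "as_printed":
        x = (u - tau) * (e + b * c) / (u * e + b * c)
    else:
        raise ValueError(f"unknown form {form!r}")
    x = np.where(u > tau, x, np.where(u == tau, 0.0, np.nan))
    if x.ndim == 0:
        return float(x)
    return x


def add_ipq(
    dives: pd.DataFrame,
    constants: IPQConstants,
    pause_threshold_s: float = PAUSE_THRESHOLD_S,
    ipq_cap: float = IPQ_CAP,
    form: str = "consistent",
) -> pd.DataFrame:
    """Attach an ``ipq`` column (and ``ipq_excluded`` reason) to foraging dives.

    IPQ is computed only for foraging dives with a defined post-dive pause
    not exceeding ``pause_threshold_s``; values above ``ipq_cap`` are set
    to NaN and counted.
    """
    out = dives.copy()
    out["ipq"] = np.nan
    out["ipq_excluded"] = ""
    forage = out["dive_type"] == "forage"
    no_pause = forage & out["s_post"].isna()
    long_pause = forage & (out["s_post"] > pause_threshold_s)
    ok = forage & ~no_pause & ~long_pause
    x = compute_ipq(out.loc[ok, "u"], out.loc[ok, "tau"], constants.b, constants.c, form=form)
    x = np.asarray(x, dtype=float)
    out.loc[ok, "ipq"] = x
    out.loc[no_pause, "ipq_excluded"] = "no_pause"
    out.loc[long_pause, "ipq_excluded"] = "long_pause"
    capped = ok & (out["ipq"] > ipq_cap)
    out.loc[capped, "ipq"] = np.nan
    out.loc[capped, "ipq_excluded"] = "ipq_gt_cap"
    negative = ok & out["ipq"].isna() & (out["ipq_excluded"] == "")
    out.loc[negative, "ipq_excluded"] = "u_le_tau"
    n_cap = int(capped.sum())
    if n_cap:
        logger.info("excluded %d dive(s) with IPQ > %.1f", n_cap, ipq_cap)
    return out


def fit_constants(
    u,
    s_post,
    method: str = "theil-sen",
    max_pairs_n: int = 3000,
) -> IPQConstants:
    """Estimate the pause-model constants from foraging dives.

    Fits log s = log b + c*u.  The default estimator is Theil-Sen: c is
    the median of pairwise slopes and log b the median of the implied
    intercepts (log s_i - c*u_i) — the natural median-based estimate of
    the two constants.  Ordinary least squares is available as an
    alternative.
    """
    u = np.asarray(u, dtype=float)
    s = np.asarray(s_post, dtype=float)
    keep = np.isfinite(u) & np.isfinite(s) & (s > 0)
    u, s = u[keep], s[keep]
    if len(u) < 10:
        raise ValueError(f"need >= 10 usable foraging dives to fit constants (got {len(u)})")
    if np.ptp(u) == 0:
        raise ValueError("all dive durations identical; pause model unidentifiable")
    if method == "theil-sen" and len(u) > max_pairs_n:
        # Theil-Sen is O(n^2) in memory; thin deterministically (u-ordered,
        # evenly spaced) to keep the pairwise-slope matrix bounded
        order = np.argsort(u, kind="stable")
        pick = order[np.linspace(0, len(u) - 1, max_pairs_n).round().astype(int)]
        u, s = u[pick], s[pick]
    y = np.log(s)
    if method == "theil-sen":
        c = float(stats.theilslopes(y, u).slope)
        logb = float(np.median(y - c * u))
    elif method == "ols":
        c, logb = np.polyfit(u, y, 1)
        c, logb = float(c), float(logb)
    else:
        raise ValueError(f"unknown method {method!r}")
    if c <= 0:
        raise ValueError(
            f"fitted c = {c:.4g} <= 0: pauses do not grow with dive duration; pause model violated"
        )
    return IPQConstants(b=float(np.exp(logb)), c=c, n_dives_used=len(u), method=method)


def estimate_pause_threshold(
    pauses,
    max_considered_s: float = 1500.0,
    bin_width_s: float = 15.0,
) -> float:
    """Bout threshold from the inflection of the pause-frequency curve.

    A histogram of pause durations is built up to ``max_considered_s``;
    log-frequency vs pause duration is fitted with a continuous two-segment
    broken-stick regression, and the breakpoint is returned.  Analyses can
    bypass this and supply a fixed threshold (e.g. the conventional 325 s)
    directly to :func:`detect_bouts`.
    """
    p = np.asarray(pauses, dtype=float)
    p = p[np.isfinite(p) & (p >= 0) & (p <= max_considered_s)]
    if len(p) < 100:
        raise ValueError("need >= 100 pauses to locate an inflection")
    if np.ptp(p) == 0:
        raise ValueError("degenerate pause distribution (all equal); supply a fixed threshold")
    edges = np.arange(0.0, max_considered_s + bin_width_s, bin_width_s)
    counts, _ = np.histogram(p, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    m = counts > 0
    x, y = centers[m], np.log(counts[m].astype(float))
    w = np.sqrt(counts[m].astype(float))  # Poisson: var(log count) ~ 1/count
    if len(x) < 6:
        raise ValueError("too few occupied histogram bins; widen bins or supply a fixed threshold")
    best = None
    for psi in x[2:-2]:
        A = np.column_stack([np.ones_like(x), x, np.maximum(x - psi, 0.0)])
        coef, _, *_ = np.linalg.lstsq(A * w[:, None], y * w, rcond=None)
        sse = float((w * (A @ coef - y) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, psi, coef)
    _, psi, coef = best
    if coef[1] >= 0:
        raise ValueError("pause frequencies do not decay; no inflection — supply a fixed threshold")
    return float(psi)


# ---------------------------------------------------------------------------
# bouts


def _bout_runs(gaps: np.ndarray, threshold_s: float) -> np.ndarray:
    """Run id per dive given inter-dive surface gaps (len n-1)."""
    ids = np.zeros(len(gaps) + 1, dtype=int)
    for i, g in enumerate(gaps):
        ids[i + 1] = ids[i] if (np.isfinite(g) and g < threshold_s) else ids[i] + 1
    return ids


def detect_bouts(
    dives: pd.DataFrame,
    threshold_s: float = PAUSE_THRESHOLD_S,
    group_cols: tuple[str, ...] = ("bird_id", "trip_id"),
) -> pd.DataFrame:
    """Partition foraging dives into diving bouts and single dives.

    Consecutive foraging dives within a trip merge into a bout when the
    surface interval between them (next start minus this dive's end,
    regardless of intervening non-foraging dives) is below ``threshold_s``.
    Runs of length 1 are non-bout ("single") dives.  Adds ``bout_id``
    (NaN for non-foraging dives) and a boolean ``in_bout`` column.
    """
    out = dives.copy()
    out["bout_id"] = pd.NA
    out["in_bout"] = False
    forage = out[out["dive_type"] == "forage"]
    cols = [c for c in group_cols if c in out.columns]
    groups = forage.groupby(list(cols), sort=False) if cols else [((), forage)]
    for key, sub in groups:
        sub = sub.sort_values("start_time")
        if len(sub) == 0:
            continue
        t0 = sub["start_time"].astype("int64").to_numpy() / 1e9
        ends = t0 + sub["u"].to_numpy()
        gaps = t0[1:] - ends[:-1]
        runs = _bout_runs(gaps, threshold_s)
        key_tag = "_".join(str(k) for k in (key if isinstance(key, tuple) else (key,)))
        labels = [f"{key_tag}_B{r:03d}" for r in runs]
        out.loc[sub.index, "bout_id"] = labels
        sizes = pd.Series(runs).groupby(runs).transform("size").to_numpy()
        out.loc[sub.index, "in_bout"] = sizes >= 2
    # singles keep bout_id only for bookkeeping; mask it to NA
    single = (~out["in_bout"]) & (out["dive_type"] == "forage")
    out.loc[single, "bout_id"] = pd.NA
    return out


def summarize_bouts(dives: pd.DataFrame) -> pd.DataFrame:
    """Per-bout summary: dive count, mean distance to colony, mean IPQ.

    ``mean_ipq`` averages only dives with a defined IPQ; bouts with none
    carry NaN.  Carries bird/trip/colony/stage metadata when present.
    """
    in_bouts = dives[dives["in_bout"].fillna(False)]
    if len(in_bouts) == 0:
        return pd.DataFrame(
            columns=["bout_id", "bird_id", "n_dives", "mean_dist", "mean_ipq", "t_start", "t_end", "duration_s"]
        )
    rows = []
    meta_cols = [c for c in ("bird_id", "trip_id", "colony", "stage") if c in dives.columns]
    for bout_id, sub in in_bouts.groupby("bout_id", sort=False):
        end_last = sub["start_time"].max() + pd.to_timedelta(float(sub.loc[sub["start_time"].idxmax(), "u"]), unit="s")
        row = {
            "bout_id": bout_id,
            "n_dives": int(len(sub)),
            "mean_dist": float(sub["dist_to_colony"].mean()) if "dist_to_colony" in sub.columns else np.nan,
            "mean_ipq": float(sub["ipq"].mean()) if sub["ipq"].notna().any() else np.nan,
            "t_start": sub["start_time"].min(),
            "t_end": end_last,
        }
        row["duration_s"] = (row["t_end"] - row["t_start"]).total_seconds()
        for c in meta_cols:
            row[c] = sub[c].iloc[0]
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["bout_id"]).reset_index(drop=True)
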