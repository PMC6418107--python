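"""Percentile cut-points, operating-band classification, and cohort summary
statistics.

The post-mission permissible outcome limit (POL) for hip load capacity is
the 75th percentile of the fractured elderly reference cohort's FE capacity
distribution; the adopted values are 9537 N for single-limb stance (NLS) and
3664 N for the posterolateral fall (NLF).  Classification combines these FE
cut-points with the DXA T-score bands: certification at T >= -1.0, an FE
screening band for -1.5 < T < -1.0, and a post-flight T-score POL of -2.0.
Change in capacity between paired scans is judged against the least
significant change (LSC) of the FE measurement: 3.6% for NLS, 11.3% for NLF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .synth_cohort import DXAMeasure, SubjectParams

__all__ = [
    "RiskBandConfig",
    "SubjectRecord",
    "Classification",
    "derive_pol",
    "classify_preflight",
    "classify_postflight",
    "significant_change",
    "regress_r2",
    "summarize_cohort",
]


@dataclass(frozen=True)
class RiskBandConfig:
    """Cut-points and test settings for the operating bands.

    One POL applies to both sexes.  Boundary convention: values at or above
    a cut-point pass ("T-score >= -1.0" certifies); LSC exceedance is a
    strict inequality.
    """

    pol_nls: float = 9537.0         # N
    pol_nlf: float = 3664.0         # N
    t_preflight: float = -1.0
    t_screen_floor: float = -1.5
    t_postflight_pol: float = -2.0
    lsc_nls: float = 3.6            # %
    lsc_nlf: float = 11.3           # %
    percentile_q: float = 75.0
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.t_screen_floor >= self.t_preflight:
            raise ValueError("t_screen_floor must be < t_preflight")
        if not 0 < self.percentile_q < 100:
            raise ValueError("percentile_q must be in (0, 100)")
        if self.lsc_nls <= 0 or self.lsc_nlf <= 0:
            raise ValueError("LSC values must be > 0")


@dataclass
class SubjectRecord:
    """Per-subject analysis record: demographics reference, paired DXA and
    FE capacities, cohort label."""

    params: Optional[SubjectParams] = None
    dxa_pre: Optional[DXAMeasure] = None
    dxa_post: Optional[DXAMeasure] = None
    f_nls_pre: Optional[float] = None
    f_nls_post: Optional[float] = None
    f_nlf_pre: Optional[float] = None
    f_nlf_post: Optional[float] = None
    cohort_label: str = ""

    def __post_init__(self) -> None:
        for name in ("f_nls_pre", "f_nls_post", "f_nlf_pre", "f_nlf_post"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be > 0 when present")


@dataclass(frozen=True)
class Classification:
    """Pure-function decision for one subject against the operating bands."""

    quadrant: str                    # pass_both | dxa_only | fe_only | fail_both
    preflight_decision: str = ""     # certified | screen_with_fe | not_certified
    postflight_flags: frozenset[str] = frozenset()
    changes: dict = field(default_factory=dict)


def derive_pol(values: Sequence[float], q: float = 75.0) -> float:
    """q-th percentile with linear interpolation between closest ranks; the
    population POL when invoked on a fractured-cohort capacity sample."""
    vals = np.asarray(values, dtype=float)
    if vals.size < 4:
        raise ValueError("need >= 4 values to derive a percentile cut-point")
    if not 0 < q < 100:
        raise ValueError("q must be in (0, 100)")
    return float(np.percentile(vals, q, method="linear"))


def classify_preflight(t_score: float, f_nls: Optional[float],
                       cfg: RiskBandConfig | None = None) -> Classification:
    """Pre-flight certification: T >= -1.0 certifies outright; in the
    screening band (-1.5, -1.0) the FE stance capacity decides against the
    NLS POL; at or below the floor the subject is not certified."""
    cfg = cfg or RiskBandConfig()
    if not np.isfinite(t_score):
        raise ValueError("t_score must be finite")
    if t_score >= cfg.t_preflight:
        decision = "certified"
    elif t_score > cfg.t_screen_floor:
        if f_nls is None:
            decision = "screen_with_fe"
        else:
            decision = ("certified" if f_nls >= cfg.pol_nls
                        else "not_certified")
    else:
        decision = "not_certified"
    quadrant = _quadrant(t_score, f_nls, cfg.t_preflight, cfg.pol_nls)
    return Classification(quadrant=quadrant, preflight_decision=decision)


def classify_postflight(t_score: float, f_nls: Optional[float],
                        f_nlf: Optional[float],
                        pre: SubjectRecord | None = None,
                        cfg: RiskBandConfig | None = None) -> Classification:
    """Post-flight flags against the POLs plus LSC-based change flags when a
    pre-flight record is available."""
    cfg = cfg or RiskBandConfig()
    flags: set[str] = set()
    changes: dict = {}
    if t_score < cfg.t_postflight_pol:
        flags.add("below_t_pol")
    if f_nls is not None and f_nls < cfg.pol_nls:
        flags.add("below_fe_pol_nls")
    if f_nlf is not None and f_nlf < cfg.pol_nlf:
        flags.add("below_fe_pol_nlf")
    if pre is not None:
        if pre.f_nls_pre is not None and f_nls is not None:
            sig, rel = significant_change(pre.f_nls_pre, f_nls, cfg.lsc_nls)
            changes["nls_change_pct"] = rel
            if sig and rel < 0:
                flags.add("significant_loss_nls")
        if pre.f_nlf_pre is not None and f_nlf is not None:
            sig, rel = significant_change(pre.f_nlf_pre, f_nlf, cfg.lsc_nlf)
            changes["nlf_change_pct"] = rel
            if sig and rel < 0:
                flags.add("significant_loss_nlf")
    quadrant = _quadrant(t_score, f_nls, cfg.t_preflight, cfg.pol_nls)
    return Classification(quadrant=quadrant, postflight_flags=frozenset(flags),
                          changes=changes)


def _quadrant(t_score: float, f: Optional[float],
              t_cut: float, f_cut: float) -> str:
    """Operating-chart quadrant against the DXA and FE cut-point lines."""
    dxa_ok = t_score >= t_cut
    fe_ok = f is None or f >= f_cut
    if dxa_ok and fe_ok:
        return "pass_both"
    if dxa_ok:
        return "dxa_only"
    if fe_ok:
        return "fe_only"
    return "fail_both"


def significant_change(pre: float, post: float,
                       lsc_percent: float) -> tuple[bool, float]:
    """Relative change in % and whether it strictly exceeds the least
    significant change of the measurement."""
    if pre <= 0:
        raise ValueError("pre-flight value must be > 0")
    rel = 100.0 * (post - pre) / pre
    return bool(abs(rel) > lsc_percent), float(rel)


def regress_r2(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Simple linear regression R^2 and the two-sided p-value of the
    correlation t-test (n - 2 degrees of freedom)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue ** 2), float(res.pvalue)


def _fmt(mean: float, sd: float, lo: float, hi: float, nd: int = 1) -> str:
    return (f"{mean:.{nd}f} ± {sd:.{nd}f} "
            f"({lo:.{nd}f}–{hi:.{nd}f})")


def summarize_cohort(records, digits: int = 1) -> pd.DataFrame:
    """Per-variable 'mean ± SD (range)' summary table.

    Accepts a DataFrame or a sequence of :class:`SubjectRecord`; SDs use the
    sample (n-1) convention, collapsing to 0 for a single record.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            row = {"cohort": r.cohort_label}
            if r.params is not None:
                row.update(age=r.params.age, height=r.params.height,
                           weight=r.params.weight)
                if r.params.flight_duration is not None:
                    row["flight_duration"] = r.params.flight_duration
            for name in ("f_nls_pre", "f_nls_post", "f_nlf_pre", "f_nlf_post"):
                v = getattr(r, name)
                if v is not None:
                    row[name] = v
            if r.dxa_pre is not None:
                row["abmd_pre"] = r.dxa_pre.aBMD
                row["t_score_pre"] = r.dxa_pre.t_score
            if r.dxa_post is not None:
                row["abmd_post"] = r.dxa_post.aBMD
                row["t_score_post"] = r.dxa_post.t_score
            rows.append(row)
        df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError("no records to summarise")
    num = df.select_dtypes(include=[np.number])
    out = {}
    for col in num.columns:
        v = num[col].dropna().to_numpy()
        if v.size == 0:
            continue
        sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
        out[col] = {
            "n": int(v.size),
            "mean": float(v.mean()),
            "sd": sd,
            "min": float(v.min()),
            "max": float(v.max()),
            "summary": _fmt(v.mean(), sd, v.min(), v.max(), digits),
        }
    return pd.DataFrame(out).T
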