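"""Contingency-table association statistics between multiscale drought and
yield anomalies.

For each (country, cropping system, duration, timing) the paired yearly
SPEI and SYI values are cross-tabulated into a 7 × 7 table of magnitude
classes. Frequency association is measured by an Asymmetry index on the
four anomalous macro-class counts (LY_D, HY_W, LY_W, HY_D) and a one-sided
Fisher exact test; magnitude association by two-sided Wilcoxon rank-sum
tests of SYI under drought vs. non-drought and of SPEI under low- vs.
non-low-yield years. The three p-values are merged by the most conservative
of the Vovk–Wang scaled arithmetic, geometric and harmonic means. Within
the LY_D block, two Dominance indices quantify how often the yield-anomaly
class is at least as severe (or strictly severer) than the drought class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .indices import classify_array
from .spatial import SeasonWindow

__all__ = [
    "ContingencyTable",
    "build_table",
    "AsymmetryResult",
    "asymmetry",
    "fisher_macro",
    "rank_sum_test",
    "wilcoxon_split",
    "merge_pvalues",
    "classify_p",
    "dominance",
    "dominance_summary",
    "syi_by_spei_class",
    "AssocResult",
    "associate_pairs",
    "pair_series",
]

#: Fig.-1-style significance bands on the merged p-value: bin upper edges
#: and confidence labels ((0, .005] → at least 99.5 %, … , (0.1, 1] → ns).
P_BINS = (0.005, 0.01, 0.05, 0.1)
P_LABELS = (">=99.5%", "99-99.5%", "95-99%", "90-95%", "ns")

_E = math.e
_LN3 = math.log(3.0)


@dataclass(frozen=True)
class ContingencyTable:
    """7 × 7 class-co-occurrence counts.

    ``counts[r, c]`` is the number of years with SYI class ``r`` (rows,
    ELY..EHY ordered lowest to highest yield) and SPEI class ``c``
    (columns, ED..EW ordered driest to wettest). Macro counts sum the
    3 × 3 corner blocks; the nine LY_D cells are lettered row-major

        a b c      (ELY, ED) (ELY, SD) (ELY, MD)
        d e f   =  (SLY, ED) (SLY, SD) (SLY, MD)
        g h i      (MLY, ED) (MLY, SD) (MLY, MD)

    so the diagonal a, e, i holds equal-severity co-occurrences and b, c,
    f the cells where the yield class is severer than the drought class.
    """

    counts: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (7, 7):
            raise ValueError("contingency table must be 7x7")
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def ly_d(self) -> int:
        return int(self.counts[:3, :3].sum())

    @property
    def ly_w(self) -> int:
        return int(self.counts[:3, 4:].sum())

    @property
    def hy_d(self) -> int:
        return int(self.counts[4:, :3].sum())

    @property
    def hy_w(self) -> int:
        return int(self.counts[4:, 4:].sum())

    @property
    def letters(self) -> dict[str, int]:
        keys = "abcdefghi"
        block = self.counts[:3, :3].ravel()
        return {k: int(v) for k, v in zip(keys, block)}

    def macro(self) -> np.ndarray:
        """3 × 3 macro-class table (rows LY, NY, HY; cols D, N, W)."""
        edges = (slice(0, 3), slice(3, 4), slice(4, 7))
        return np.array(
            [[self.counts[r, c].sum() for c in edges] for r in edges], dtype=int
        )


def build_table(spei: np.ndarray, syi: np.ndarray) -> ContingencyTable:
    """Cross-tabulate paired yearly SPEI and SYI values.

    Years where either value is undefined are dropped pairwise.
    """
    s = np.asarray(spei, dtype=float)
    y = np.asarray(syi, dtype=float)
    if s.shape != y.shape:
        raise ValueError("paired series must have equal length")
    keep = np.isfinite(s) & np.isfinite(y)
    sc = classify_array(s[keep])
    yc = classify_array(y[keep])
    counts = np.zeros((7, 7), dtype=int)
    np.add.at(counts, (yc, sc), 1)
    return ContingencyTable(counts)


@dataclass(frozen=True)
class AsymmetryResult:
    """Asymmetry components (percent) of one macro-class against the other
    three anomalous macro-classes, and their mean when all exceed 50 %."""

    computed: bool
    components: dict[str, float] = field(default_factory=dict)
    mean: float | None = None
    reason: str = ""


def asymmetry(
    table: ContingencyTable, target: str = "LY_D", min_n: int = 36
) -> AsymmetryResult:
    """Share of the target macro-class against each other anomalous one.

    Each component is 100 · T / (T + X) for the target count T and one of
    the other three anomalous macro-class counts X; the mean is returned
    only when every component exceeds 50 % (occurrences fully skewed
    toward the target). Tables with fewer than ``min_n`` years are not
    analysed. A component with T > 0 and X = 0 is 100 %; with T = X = 0 it
    is undefined and the mean cannot be returned.
    """
    macros = {
        "LY_D": table.ly_d,
        "HY_W": table.hy_w,
        "LY_W": table.ly_w,
        "HY_D": table.hy_d,
    }
    if target not in macros:
        raise ValueError(f"unknown asymmetry target {target!r}")
    if table.n < min_n:
        return AsymmetryResult(computed=False, reason=f"n={table.n} < {min_n}")
    t = macros.pop(target)
    comps: dict[str, float] = {}
    for name, x in macros.items():
        if t + x == 0:
            comps[name] = np.nan
        else:
            comps[name] = 100.0 * t / (t + x)
    vals = np.array(list(comps.values()))
    if np.all(np.isfinite(vals)) and np.all(vals > 50.0):
        mean = float(vals.mean())
    else:
        mean = None
    return AsymmetryResult(computed=True, components=comps, mean=mean)


def fisher_macro(table: ContingencyTable) -> float:
    """One-sided Fisher exact p for excess low-yield/dry co-occurrence.

    The 2 × 2 table is [[LY_D, LY_W], [HY_D, HY_W]] (normal classes
    excluded) with the alternative of positive association between dry
    conditions and lower yields (odds ratio > 1); computed as the
    hypergeometric upper-tail probability of the LY_D count under fixed
    margins. A zero margin gives p = 1.
    """
    a, b, c, d = table.ly_d, table.ly_w, table.hy_d, table.hy_w
    n = a + b + c + d
    if n == 0:
        return 1.0
    return float(stats.hypergeom.sf(a - 1, n, a + b, a + c))


def _exact_rank_sum_p(ranks: np.ndarray, n1: int) -> float:
    """Two-sided exact rank-sum p by enumeration of all group-1 index
    subsets (midranks, doubling rule capped at 1)."""
    n = ranks.size
    w_obs = ranks[:n1].sum()
    sums = np.fromiter(
        (sum(ranks[list(ix)]) for ix in itertools.combinations(range(n), n1)),
        dtype=float,
    )
    eps = 1e-9
    lo = np.mean(sums <= w_obs + eps)
    hi = np.mean(sums >= w_obs - eps)
    return float(min(1.0, 2.0 * min(lo, hi)))


def rank_sum_test(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """Two-sided Wilcoxon rank-sum test for independent samples.

    Exact permutation distribution when both groups have ≤ 10 values (ties
    handled by midranks); otherwise the tie-corrected normal approximation
    with continuity correction. Returns (p, x_lower) where ``x_lower``
    flags a lower median in ``x`` than in ``y`` (ties count as not lower).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    x_lower = bool(np.median(x) < np.median(y))
    if np.array_equal(np.sort(x), np.sort(y)):
        return 1.0, x_lower
    if max(x.size, y.size) <= 10:
        ranks = stats.rankdata(np.concatenate([x, y]))
        return _exact_rank_sum_p(ranks, x.size), x_lower
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.pvalue), x_lower


def wilcoxon_split(
    values: np.ndarray,
    split_by: np.ndarray,
    threshold: float = -1.0,
    min_group: int = 5,
) -> tuple[float, bool, bool]:
    """Rank-sum comparison of ``values`` split by ``split_by ≤ threshold``.

    Years with either quantity undefined are dropped pairwise. Returns
    (p, low_group_lower, computed); when either group is smaller than
    ``min_group`` the test is not computed (p = NaN).
    """
    v = np.asarray(values, dtype=float)
    s = np.asarray(split_by, dtype=float)
    keep = np.isfinite(v) & np.isfinite(s)
    v, s = v[keep], s[keep]
    low = v[s <= threshold]
    high = v[s > threshold]
    if low.size < min_group or high.size < min_group:
        return np.nan, False, False
    p, lower = rank_sum_test(low, high)
    return p, lower, True


def merge_pvalues(p_fisher: float, p_w1: float, p_w2: float) -> float:
    """Conservative Vovk–Wang merger of three p-values.

    The scaled arithmetic (×2), geometric (×e) and harmonic (×e·ln 3)
    means are each valid merged p-values for K = 3 tests under arbitrary
    dependence; the worst (largest, most conservative) of the three,
    capped at 1, is returned. Undefined inputs give NaN.
    """
    p = np.array([p_fisher, p_w1, p_w2], dtype=float)
    if not np.all(np.isfinite(p)):
        return np.nan
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    arith = min(1.0, 2.0 * p.mean())
    geom = min(1.0, _E * float(np.exp(np.mean(np.log(p)))))
    harm = min(1.0, _E * _LN3 * p.size / float(np.sum(1.0 / p)))
    return max(arith, geom, harm)


def classify_p(p: float) -> str:
    """Significance band of a merged p-value (confidence-level labels)."""
    if not np.isfinite(p):
        raise ValueError("p must be defined")
    for edge, label in zip(P_BINS, P_LABELS):
        if p <= edge:
            return label
    return P_LABELS[-1]


def dominance(table: ContingencyTable) -> tuple[float, float]:
    """Dominance shares (percent) within the LY_D block.

    ``dominance_ge`` = 100·(a+b+c+e+f+i)/(a+…+i): co-occurrences where the
    yield class is at least as severe as the drought class, over all LY_D
    co-occurrences. ``dominance_gt`` = 100·(b+c+f)/(b+c+d+f+g+h): strictly
    severer yield classes over all non-analogous co-occurrences. A zero
    denominator yields NaN.
    """
    L = table.letters
    num_ge = L["a"] + L["b"] + L["c"] + L["e"] + L["f"] + L["i"]
    den_ge = sum(L.values())
    num_gt = L["b"] + L["c"] + L["f"]
    den_gt = L["b"] + L["c"] + L["d"] + L["f"] + L["g"] + L["h"]
    ge = 100.0 * num_ge / den_ge if den_ge else np.nan
    gt = 100.0 * num_gt / den_gt if den_gt else np.nan
    return ge, gt


def dominance_summary(
    dominances: dict[str, list[tuple[float, float]]],
    thr_ge: float = 66.7,
    thr_gt: float = 50.0,
) -> pd.DataFrame:
    """Per-cropping-system dominance aggregation plus weighted average.

    ``dominances`` maps cropping system → list of (ge, gt) pairs, one per
    analysed duration-timing contingency table. For each system the
    arithmetic mean of each dominance is reported together with the share
    of analysed tables strictly above the threshold (66.7 % for ge, 50 %
    for gt). The final "average" row weights systems by their number of
    analysed tables.
    """
    rows = []
    for system, pairs in dominances.items():
        if not pairs:
            continue
        ge = np.array([p[0] for p in pairs], dtype=float)
        gt = np.array([p[1] for p in pairs], dtype=float)
        n = len(pairs)
        rows.append(
            {
                "cropping_system": system,
                "n_tables": n,
                "mean_dominance_ge": float(np.nanmean(ge)),
                "share_ge_above": 100.0 * float(np.sum(ge > thr_ge)) / n,
                "mean_dominance_gt": (
                    float(np.nanmean(gt)) if np.any(np.isfinite(gt)) else np.nan
                ),
                "share_gt_above": 100.0 * float(np.sum(gt > thr_gt)) / n,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        w = df["n_tables"].to_numpy(dtype=float)
        avg = {"cropping_system": "average", "n_tables": int(w.sum())}
        for col in df.columns[2:]:
            v = df[col].to_numpy(dtype=float)
            ok = np.isfinite(v)
            avg[col] = float(np.sum(v[ok] * w[ok]) / np.sum(w[ok])) if ok.any() else np.nan
        df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return df


def syi_by_spei_class(
    spei: np.ndarray,
    syi: np.ndarray,
    syi_threshold: float = -1.0,
) -> dict:
    """Class-conditional low-yield SYI samples and pairwise comparisons.

    Pools paired (SPEI, SYI) values (across years, countries, durations
    and timings) and, keeping only years with SYI ≤ ``syi_threshold``,
    splits the SYI values by the drought class of the co-occurring SPEI:
    moderate (−1.5 < SPEI ≤ −1), severe (−2 < SPEI ≤ −1.5) and extreme
    (SPEI ≤ −2). Pairwise two-sided rank-sum tests are run between
    non-empty classes.

    Returns {"samples": {class: array}, "pvalues": {(c1, c2): p}}.
    """
    s = np.asarray(spei, dtype=float).ravel()
    y = np.asarray(syi, dtype=float).ravel()
    keep = np.isfinite(s) & np.isfinite(y) & (y <= syi_threshold)
    s, y = s[keep], y[keep]
    samples = {
        "MD": y[(s > -1.5) & (s <= -1.0)],
        "SD": y[(s > -2.0) & (s <= -1.5)],
        "ED": y[s <= -2.0],
    }
    pvalues: dict[tuple[str, str], float] = {}
    for c1, c2 in itertools.combinations(samples, 2):
        a, b = samples[c1], samples[c2]
        if a.size and b.size:
            pvalues[(c1, c2)] = rank_sum_test(a, b)[0]
    return {"samples": samples, "pvalues": pvalues}


@dataclass(frozen=True)
class AssocResult:
    """All association statistics for one duration-timing cell."""

    country: int | str
    cropping_system: str
    duration: int
    month: int
    year_offset: int
    mbh: int
    n: int
    asym_components: dict[str, float]
    asym_mean: float | None
    fisher_p: float
    wilcoxon_syi_p: float
    wilcoxon_syi_lower: bool
    wilcoxon_spei_p: float
    wilcoxon_spei_lower: bool
    merged_p: float
    sig_class: str
    dominance_ge: float
    dominance_gt: float


def pair_series(series: np.ndarray, year_offset: int) -> np.ndarray:
    """Align an index series dated by calendar year to harvest years.

    For a window pair whose ending month falls ``-year_offset`` calendar
    years before the harvest year, the value paired with harvest year y is
    the series value at year y + year_offset; harvest years whose shifted
    index precedes the record are undefined.
    """
    s = np.asarray(series, dtype=float)
    if year_offset == 0:
        return s.copy()
    if year_offset > 0:
        raise ValueError("year_offset must be <= 0")
    out = np.full(s.shape, np.nan)
    out[-year_offset:] = s[:year_offset]
    return out


def associate_pairs(
    spei_cube: "np.ndarray | object",
    syi_series: np.ndarray,
    window: SeasonWindow,
    country: int | str = 0,
    cropping_system: str = "crop",
    min_table_n: int = 36,
    min_group: int = 5,
    asym_target: str = "LY_D",
) -> list[AssocResult]:
    """Run the full per-cell statistics for every window pair.

    ``spei_cube`` is a country-level DataArray (duration, month, year) —
    or anything exposing ``.sel(duration=d, month=m).values``; the merged
    p-value is defined only when the asymmetry gate holds (all components
    > 50 %) and all three tests are computable. The significance class is
    "not_computed" for gated-out cells, "reversed" when a nominally
    significant merged p has the wrong direction in either magnitude test
    (higher SYI under drought or higher SPEI under low yield), otherwise
    the confidence band of the merged p.
    """
    results = []
    syi = np.asarray(syi_series, dtype=float)
    for pair in window.pairs:
        raw = np.asarray(
            spei_cube.sel(duration=pair.duration, month=pair.month).values,
            dtype=float,
        )
        spei = pair_series(raw, pair.year_offset)
        table = build_table(spei, syi)
        asym = asymmetry(table, target=asym_target, min_n=min_table_n)
        fisher = fisher_macro(table) if asym.computed else np.nan
        w1, w1_lower, w1_ok = wilcoxon_split(syi, spei, min_group=min_group)
        w2, w2_lower, w2_ok = wilcoxon_split(spei, syi, min_group=min_group)
        gate = asym.computed and asym.mean is not None
        if gate and w1_ok and w2_ok and np.isfinite(fisher):
            merged = merge_pvalues(fisher, w1, w2)
            if classify_p(merged) != "ns" and not (w1_lower and w2_lower):
                sig = "reversed"
            else:
                sig = classify_p(merged)
        else:
            merged = np.nan
            sig = "not_computed"
        dom_ge, dom_gt = dominance(table)
        results.append(
            AssocResult(
                country=country,
                cropping_system=cropping_system,
                duration=pair.duration,
                month=pair.month,
                year_offset=pair.year_offset,
                mbh=pair.mbh,
                n=table.n,
                asym_components=asym.components,
                asym_mean=asym.mean,
                fisher_p=fisher,
                wilcoxon_syi_p=w1,
                wilcoxon_syi_lower=w1_lower,
                wilcoxon_spei_p=w2,
                wilcoxon_spei_lower=w2_lower,
                merged_p=merged,
                sig_class=sig,
                dominance_ge=dom_ge,
                dominance_gt=dom_gt,
            )
        )
    return results
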