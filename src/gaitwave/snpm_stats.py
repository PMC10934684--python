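"""Statistical non-parametric mapping over the gait-cycle axis.

At each of the 100 gait-phase points a classical two-way mixed ANOVA is
computed: group (overground O vs treadmill T) is the between-subject
factor, condition (self-selected sSC vs cued SC) the within-subject
factor.  Group is tested against the subject-within-group mean square;
condition and the group x condition interaction against the
condition x subject-within-group mean square.

Family-wise control over the 100-point continuum uses max-statistic
permutation: the critical threshold F* is the (1 - alpha) quantile of
the permutation distribution of the maximum F over the curve, and
suprathreshold clusters get p-values from the permutation distribution
of maximal cluster extent.  Permutation schemes respect the design's
exchangeability: group labels are permuted across whole subjects;
condition labels are swapped within subjects; the interaction composes
both (approximate exchangeability under the no-interaction null).
Exhaustive enumeration replaces Monte-Carlo sampling automatically
whenever the number of distinct relabelings is no larger than the
requested permutation count.

Monte-Carlo p-values carry the add-one correction
``p = (1 + #{perm >= obs}) / (n_perm + 1)``; exhaustive enumerations
include the identity relabeling, so ``p = #{perm >= obs} / n_total``.
F* is the matching order statistic, so ``observed max >= F*`` holds
exactly when the omnibus p is at most alpha.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as ss

from .epoching import N_PHASE_POINTS

logger = logging.getLogger(__name__)

__all__ = [
    "DesignMatrix",
    "AnovaCurves",
    "PermutationDistribution",
    "Cluster",
    "PosthocResult",
    "SnpmResult",
    "NormalityReport",
    "EFFECTS",
    "normality_check",
    "anova_curves",
    "permutation_distribution",
    "permutation_threshold",
    "cluster_inference",
    "posthoc",
    "run_snpm",
    "run_snpm_all_electrodes",
]

EFFECTS = ("group", "condition", "interaction")
CONDITIONS = ("sSC", "SC")


@dataclass
class DesignMatrix:
    """One electrode's data in the 2 (group) x 2 (condition) mixed design.

    ``data[i, c, t]`` is subject ``i``'s value under condition ``c``
    (0 = sSC, 1 = SC) at gait-phase point ``t``.  Subjects are stored
    with group 'O' first.
    """

    data: np.ndarray                 # subjects x 2 x T
    group: np.ndarray                # per-subject 'O' / 'T'
    subject_ids: list[str] = field(default_factory=list)
    electrode: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.group = np.asarray(self.group, dtype=object)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("data must be subjects x 2 conditions x T")
        if self.group.shape[0] != self.data.shape[0]:
            raise ValueError("one group label per subject required")
        bad = set(self.group) - {"O", "T"}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        if not self.subject_ids:
            self.subject_ids = [f"S{i:02d}" for i in range(self.data.shape[0])]
        # canonical subject order: all O subjects first
        order = np.argsort([g != "O" for g in self.group], kind="stable")
        self.data = self.data[order]
        self.group = self.group[order]
        self.subject_ids = [self.subject_ids[i] for i in order]
        self.n_o = int(np.sum(self.group == "O"))
        if self.n_o == 0 or self.n_o == len(self.group):
            raise ValueError("both groups must be non-empty")

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[2]

    def cell(self, name: str) -> np.ndarray:
        """Subjects x T data for one design cell, e.g. ``'TsSC'``."""
        g, c = name[0], name[1:]
        if g not in ("O", "T") or c not in CONDITIONS:
            raise ValueError(f"unknown design cell {name!r}")
        mask = self.group == g
        if not mask.any():
            raise ValueError(f"design has no subjects in group {g!r}")
        return self.data[mask, CONDITIONS.index(c), :]


@dataclass
class AnovaCurves:
    """Per-timepoint F curves with degeneracy flags.

    ``degenerate`` marks timepoints whose denominator mean square is
    zero: F is +inf there if the numerator is positive, NaN if the
    statistic is 0/0.
    """

    F_group: np.ndarray
    F_condition: np.ndarray
    F_interaction: np.ndarray
    degenerate: dict[str, np.ndarray] = field(default_factory=dict)
    df: dict[str, tuple[int, int]] = field(default_factory=dict)

    def curve(self, effect: str) -> np.ndarray:
        return {"group": self.F_group, "condition": self.F_condition,
                "interaction": self.F_interaction}[effect]


def _mixed_f(y: np.ndarray, n_o: int, effect: str | None = None) -> dict:
    """Split-plot F statistics, vectorized over leading batch dims.

    ``y`` has shape (..., N, 2, T).  Returns the requested effect's F
    (or all three) along with the sums of squares.  Division by a zero
    mean square yields inf/nan, handled by the caller.
    """
    n = y.shape[-3]
    n_t = n - n_o
    s = y.mean(axis=-2)                      # (..., N, T) subject means
    d = y[..., 0, :] - y[..., 1, :]          # within-subject differences
    out: dict[str, np.ndarray] = {}

    with np.errstate(divide="ignore", invalid="ignore"):
        if effect in (None, "group"):
            m = s.mean(axis=-2)
            m_o = s[..., :n_o, :].mean(axis=-2)
            m_t = s[..., n_o:, :].mean(axis=-2)
            ss_group = 2.0 * (n_o * (m_o - m) ** 2 + n_t * (m_t - m) ** 2)
            ss_subj = 2.0 * ((s - m[..., None, :]) ** 2).sum(axis=-2) - ss_group
            ss_subj = np.maximum(ss_subj, 0.0)
            out["group"] = ss_group / (ss_subj / (n - 2))
        if effect in (None, "condition", "interaction"):
            db = d.mean(axis=-2)
            db_o = d[..., :n_o, :].mean(axis=-2)
            db_t = d[..., n_o:, :].mean(axis=-2)
            ss_err = (((d[..., :n_o, :] - db_o[..., None, :]) ** 2).sum(axis=-2)
                      + ((d[..., n_o:, :] - db_t[..., None, :]) ** 2).sum(axis=-2)
                      ) / 2.0
            ms_err = ss_err / (n - 2)
            if effect in (None, "condition"):
                out["condition"] = (n * db ** 2 / 2.0) / ms_err
            if effect in (None, "interaction"):
                ss_int = (n_o * (db_o - db) ** 2 + n_t * (db_t - db) ** 2) / 2.0
                out["interaction"] = ss_int / ms_err
    return out


def anova_curves(design: DesignMatrix) -> AnovaCurves:
    """Classical 2 x 2 mixed-model ANOVA F ratios at every timepoint."""
    n = design.n_subjects
    if design.n_o < 2 or n - design.n_o < 2:
        raise ValueError("need at least 2 subjects per group")
    f = _mixed_f(design.data, design.n_o)
    degenerate = {k: ~np.isfinite(v) for k, v in f.items()}
    for k, mask in degenerate.items():
        if mask.any():
            logger.warning("%s: %d degenerate timepoint(s) for %s effect",
                           design.electrode or "design", int(mask.sum()), k)
    return AnovaCurves(
        F_group=f["group"], F_condition=f["condition"],
        F_interaction=f["interaction"], degenerate=degenerate,
        df={"group": (1, n - 2), "condition": (1, n - 2),
            "interaction": (1, n - 2)},
    )


# --------------------------------------------------------------------------
# Permutation machinery
# --------------------------------------------------------------------------

@dataclass
class PermutationDistribution:
    """Permutation F curves and their maxima for one effect."""

    effect: str
    curves: np.ndarray          # n_perm x T
    maxima: np.ndarray          # n_perm
    exhaustive: bool
    n_distinct: int
    valid_mask: np.ndarray      # timepoints entering the max-statistic

    @property
    def n_perm(self) -> int:
        return self.curves.shape[0]


def n_distinct_permutations(design: DesignMatrix, effect: str) -> int:
    n, n_o = design.n_subjects, design.n_o
    n_group = math.comb(n, n_o)
    n_cond = 2 ** n
    return {"group": n_group, "condition": n_cond,
            "interaction": n_group * n_cond}[effect]


def _valid_timepoints(design: DesignMatrix) -> np.ndarray:
    """Timepoints with any variance across observations."""
    flat = design.data.reshape(-1, design.n_timepoints)
    valid = flat.std(axis=0) > 0
    if not valid.all():
        logger.warning("excluding %d zero-variance timepoint(s) from the "
                       "max-statistic", int((~valid).sum()))
    return valid


def _perm_curves(design: DesignMatrix, effect: str, perm_idx, flips,
                 batch: int = 512) -> np.ndarray:
    """F curves for a stack of relabelings.

    ``perm_idx`` (P, N) permutes subjects (group relabeling); ``flips``
    (P, N) swaps the two condition values within flagged subjects.
    Either may be None (identity).
    """
    y = design.data
    n_o = design.n_o
    p = perm_idx.shape[0] if perm_idx is not None else flips.shape[0]
    out = np.empty((p, design.n_timepoints))
    for lo in range(0, p, batch):
        hi = min(lo + batch, p)
        yb = y[perm_idx[lo:hi]] if perm_idx is not None \
            else np.broadcast_to(y, (hi - lo,) + y.shape)
        if flips is not None:
            fb = flips[lo:hi][:, :, None, None]
            yb = np.where(fb, yb[:, :, ::-1, :], yb)
        out[lo:hi] = _mixed_f(yb, n_o, effect)[effect]
    return out


def _enumerate_relabelings(design: DesignMatrix, effect: str):
    """All distinct (perm_idx, flips) pairs for small designs."""
    n, n_o = design.n_subjects, design.n_o
    subjects = np.arange(n)
    if effect in ("group", "interaction"):
        group_orders = []
        for comb in itertools.combinations(range(n), n_o):
            rest = [i for i in range(n) if i not in comb]
            group_orders.append(np.array(list(comb) + rest))
        group_orders = np.array(group_orders)
    else:
        group_orders = subjects[None, :]
    if effect in ("condition", "interaction"):
        flips = np.array(list(itertools.product([False, True], repeat=n)))
    else:
        flips = np.zeros((1, n), dtype=bool)
    perm_idx = np.repeat(group_orders, flips.shape[0], axis=0)
    flips = np.tile(flips, (group_orders.shape[0], 1))
    return perm_idx, flips


def _sample_relabelings(design: DesignMatrix, effect: str, n_perm: int,
                        rng: np.random.Generator):
    n = design.n_subjects
    perm_idx = None
    flips = None
    if effect in ("group", "interaction"):
        perm_idx = np.array([rng.permutation(n) for _ in range(n_perm)])
    if effect in ("condition", "interaction"):
        flips = rng.random((n_perm, n)) < 0.5
    return perm_idx, flips


def permutation_distribution(design: DesignMatrix, effect: str,
                             n_perm: int = 10000,
                             seed: int | np.random.SeedSequence = 0,
                             ) -> PermutationDistribution:
    """Permutation F curves under the effect's exchangeability scheme."""
    if effect not in EFFECTS:
        raise ValueError(f"unknown effect {effect!r}")
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    n_distinct = n_distinct_permutations(design, effect)
    valid = _valid_timepoints(design)
    if n_distinct <= n_perm:
        perm_idx, flips = _enumerate_relabelings(design, effect)
        curves = _perm_curves(design, effect, perm_idx, flips)
        exhaustive = True
    else:
        rng = np.random.default_rng(seed)
        perm_idx, flips = _sample_relabelings(design, effect, n_perm, rng)
        curves = _perm_curves(design, effect, perm_idx, flips)
        exhaustive = False
    curves = np.where(np.isfinite(curves), curves, 0.0)
    masked = curves[:, valid] if valid.any() else np.zeros((curves.shape[0], 1))
    maxima = masked.max(axis=1)
    return PermutationDistribution(effect=effect, curves=curves,
                                   maxima=maxima, exhaustive=exhaustive,
                                   n_distinct=n_distinct, valid_mask=valid)


def _critical_rank(dist: PermutationDistribution, alpha: float) -> int:
    """Order-statistic rank m such that F* = m-th largest maximum."""
    if dist.exhaustive:
        m = math.floor(alpha * dist.n_perm)
    else:
        m = math.floor(alpha * (dist.n_perm + 1))
    if m < 1:
        raise ValueError(
            f"alpha unattainable: only {dist.n_perm} permutations "
            f"available for alpha={alpha}")
    return min(m, dist.n_perm)


def threshold_from_distribution(dist: PermutationDistribution,
                                alpha: float) -> float:
    m = _critical_rank(dist, alpha)
    return float(np.sort(dist.maxima)[::-1][m - 1])


def permutation_threshold(design: DesignMatrix, effect: str,
                          n_perm: int = 10000, alpha: float = 0.05,
                          seed: int | np.random.SeedSequence = 0,
                          return_distribution: bool = False):
    """Critical F* controlling the family-wise rate over the curve."""
    dist = permutation_distribution(design, effect, n_perm=n_perm, seed=seed)
    f_star = threshold_from_distribution(dist, alpha)
    if return_distribution:
        return f_star, dist
    return f_star


def omnibus_p(dist: PermutationDistribution, observed_max: float) -> float:
    count = int(np.sum(dist.maxima >= observed_max))
    if dist.exhaustive:
        return count / dist.n_perm
    return (1 + count) / (dist.n_perm + 1)


# --------------------------------------------------------------------------
# Cluster inference
# --------------------------------------------------------------------------

@dataclass
class Cluster:
    """One suprathreshold run, with interpolated percent extents."""

    effect: str
    start_pct: float
    end_pct: float
    f_max: float
    p_cluster: float

    @property
    def extent(self) -> float:
        return self.end_pct - self.start_pct

    def overlaps(self, start_pct: float, end_pct: float) -> bool:
        return self.start_pct <= end_pct and start_pct <= self.end_pct


def _cluster_extents(curve: np.ndarray, f_star: float) -> list[tuple[float, float, float]]:
    """(start_pct, end_pct, F_max) for each maximal suprathreshold run.

    Point k maps to k% of the cycle; edges are linearly interpolated at
    the threshold crossing where a neighbouring point exists.
    """
    above = np.asarray(curve) >= f_star
    if not above.any():
        return []
    runs = []
    k = 0
    t = len(curve)
    while k < t:
        if not above[k]:
            k += 1
            continue
        k0 = k
        while k + 1 < t and above[k + 1]:
            k += 1
        k1 = k
        if k0 == 0:
            start = 0.0
        else:
            denom = curve[k0] - curve[k0 - 1]
            frac = (f_star - curve[k0 - 1]) / denom if denom > 0 else 1.0
            start = (k0 - 1) + frac
        if k1 == t - 1:
            end = float(t - 1)
        else:
            denom = curve[k1] - curve[k1 + 1]
            frac = (curve[k1] - f_star) / denom if denom > 0 else 1.0
            end = k1 + frac
        runs.append((float(start), float(end), float(np.max(curve[k0:k1 + 1]))))
        k = k1 + 1
    return runs


def cluster_inference(f_curve: np.ndarray, f_star: float,
                      dist: PermutationDistribution,
                      effect: str | None = None) -> list[Cluster]:
    """Suprathreshold clusters with extent-based permutation p-values.

    A cluster's p is the proportion of permutations whose largest
    suprathreshold cluster extent reaches the observed extent (add-one
    corrected for Monte-Carlo streams).
    """
    f_curve = np.where(np.isfinite(f_curve), f_curve, 0.0)
    masked = np.where(dist.valid_mask, f_curve, 0.0)
    observed = _cluster_extents(masked, f_star)
    if not observed:
        return []
    perm_max_extent = np.zeros(dist.n_perm)
    for i in range(dist.n_perm):
        pc = np.where(dist.valid_mask, dist.curves[i], 0.0)
        runs = _cluster_extents(pc, f_star)
        if runs:
            perm_max_extent[i] = max(r[1] - r[0] for r in runs)
    clusters = []
    for start, end, f_max in observed:
        extent = end - start
        count = int(np.sum(perm_max_extent >= extent))
        if dist.exhaustive:
            p = max(count, 1) / dist.n_perm
        else:
            p = (1 + count) / (dist.n_perm + 1)
        clusters.append(Cluster(effect=effect or dist.effect,
                                start_pct=start, end_pct=end,
                                f_max=f_max, p_cluster=p))
    return clusters


# --------------------------------------------------------------------------
# Post hoc comparisons
# --------------------------------------------------------------------------

DEFAULT_COMPARISONS = (
    ("OSC", "OsSC"),   # auditory cue effect, overground (paired)
    ("TSC", "TsSC"),   # auditory cue effect, treadmill (paired)
    ("OSC", "TSC"),    # surface effect under the cue (unpaired)
    ("OsSC", "TsSC"),  # surface effect at self-selected speed (unpaired)
)


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    paired: bool
    t_max: float
    p_raw: float
    p_adjusted: float
    windows: list[tuple[float, float]] = field(default_factory=list)


def _max_abs_t_paired(diff: np.ndarray) -> np.ndarray:
    """|t| curve for a one-sample test on paired differences (n x T)."""
    n = diff.shape[0]
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.abs(np.where(np.isfinite(t), t, 0.0))


def _max_abs_t_unpaired(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample |t| curve (n_a x T vs n_b x T)."""
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / np.sqrt(sp2 * (1 / na + 1 / nb))
    return np.abs(np.where(np.isfinite(t), t, 0.0))


def posthoc(design: DesignMatrix, clusters: list[Cluster] | None = None,
            comparisons=DEFAULT_COMPARISONS, n_perm: int = 10000,
            alpha: float = 0.05,
            seed: int | np.random.SeedSequence = 0) -> list[PosthocResult]:
    """Bonferroni-adjusted SnPM t comparisons between design cells.

    Each pair is tested with a max-|t| permutation test over the full
    100-point cycle (sign flips for paired contrasts, group-label
    shuffles for unpaired ones); raw p-values are multiplied by the
    number of executed comparisons and capped at 1.  Intended to run
    only after the omnibus interaction shows a significant cluster.
    """
    rng = np.random.default_rng(seed)
    k = len(comparisons)
    results = []
    for cell_a, cell_b in comparisons:
        a = design.cell(cell_a)
        b = design.cell(cell_b)
        paired = cell_a[0] == cell_b[0]
        if paired:
            diff = a - b
            obs_curve = _max_abs_t_paired(diff)
            obs = obs_curve.max()
            perm_max = np.empty(n_perm)
            t_star_stack = np.empty((n_perm, diff.shape[1]))
            for i in range(n_perm):
                signs = np.where(rng.random(diff.shape[0]) < 0.5, -1.0, 1.0)
                c = _max_abs_t_paired(diff * signs[:, None])
                t_star_stack[i] = c
                perm_max[i] = c.max()
        else:
            pooled = np.vstack([a, b])
            na = a.shape[0]
            obs_curve = _max_abs_t_unpaired(a, b)
            obs = obs_curve.max()
            perm_max = np.empty(n_perm)
            t_star_stack = np.empty((n_perm, pooled.shape[1]))
            for i in range(n_perm):
                order = rng.permutation(pooled.shape[0])
                c = _max_abs_t_unpaired(pooled[order[:na]], pooled[order[na:]])
                t_star_stack[i] = c
                perm_max[i] = c.max()
        p_raw = (1 + int(np.sum(perm_max >= obs))) / (n_perm + 1)
        p_adj = min(1.0, k * p_raw)
        windows: list[tuple[float, float]] = []
        try:
            m = math.floor(alpha * (n_perm + 1))
            if m >= 1:
                t_star = float(np.sort(perm_max)[::-1][m - 1])
                windows = [(s, e) for s, e, _ in
                           _cluster_extents(obs_curve, t_star)]
        except ValueError:
            pass
        results.append(PosthocResult(pair=(cell_a, cell_b), paired=paired,
                                     t_max=float(obs), p_raw=p_raw,
                                     p_adjusted=p_adj, windows=windows))
    return results


# --------------------------------------------------------------------------
# Normality gate (advisory)
# --------------------------------------------------------------------------

@dataclass
class NormalityReport:
    """Shapiro-Wilk on cell-mean-centered residuals, per timepoint.

    Advisory only: the pipeline always proceeds to permutation
    inference regardless of the outcome.
    """

    statistic: np.ndarray
    pvalue: np.ndarray
    nonnormal_fraction: float
    nonnormal: bool


def normality_check(design: DesignMatrix, alpha: float = 0.05) -> NormalityReport:
    """Shapiro-Wilk test of the pooled cell-centered residuals.

    At each timepoint the 2N observations are centered on their
    group x condition cell means and tested jointly.
    """
    n = design.n_subjects
    if 2 * n < 3 or design.n_o < 2 or n - design.n_o < 2:
        raise ValueError("too few residuals for a normality check")
    resid = design.data.copy()
    for g in ("O", "T"):
        mask = design.group == g
        for c in range(2):
            resid[mask, c, :] -= design.data[mask, c, :].mean(axis=0)
    t_pts = design.n_timepoints
    stat = np.full(t_pts, np.nan)
    pval = np.full(t_pts, np.nan)
    for t in range(t_pts):
        sample = resid[:, :, t].ravel()
        if np.std(sample) == 0:
            continue
        res = ss.shapiro(sample)
        stat[t], pval[t] = res.statistic, res.pvalue
    tested = np.isfinite(pval)
    frac = float(np.mean(pval[tested] < alpha)) if tested.any() else 0.0
    return NormalityReport(statistic=stat, pvalue=pval,
                           nonnormal_fraction=frac, nonnormal=frac > alpha)


# --------------------------------------------------------------------------
# Omnibus driver
# --------------------------------------------------------------------------

@dataclass
class SnpmResult:
    """Complete SnPM output for one electrode."""

    electrode: str
    F_group: np.ndarray
    F_condition: np.ndarray
    F_interaction: np.ndarray
    F_star: dict[str, float]
    p_omnibus: dict[str, float]
    clusters: list[Cluster]
    posthoc: list[PosthocResult]
    n_permutations: int
    alpha: float
    seed: int | None

    def clusters_for(self, effect: str) -> list[Cluster]:
        return [c for c in self.clusters if c.effect == effect]

    def significant(self, effect: str) -> bool:
        return self.p_omnibus[effect] <= self.alpha

    def to_dict(self) -> dict:
        return {
            "electrode": self.electrode,
            "F_star": self.F_star,
            "p_omnibus": self.p_omnibus,
            "clusters": [
                {"effect": c.effect, "start_pct": c.start_pct,
                 "end_pct": c.end_pct, "F_max": c.f_max, "p": c.p_cluster}
                for c in self.clusters],
            "posthoc": [
                {"pair": list(r.pair), "paired": r.paired, "t_max": r.t_max,
                 "p_raw": r.p_raw, "p_adj": r.p_adjusted,
                 "windows": [list(w) for w in r.windows]}
                for r in self.posthoc],
            "n_permutations": self.n_permutations,
            "alpha": self.alpha,
        }


def run_snpm(design: DesignMatrix, n_perm: int = 10000, alpha: float = 0.05,
             seed: int | np.random.SeedSequence = 0,
             effects=EFFECTS, run_posthoc: bool = True) -> SnpmResult:
    """Full SnPM for one electrode: curves, thresholds, clusters, post hoc."""
    curves = anova_curves(design)
    if isinstance(seed, np.random.SeedSequence):
        seq = seed
        seed_int = None
    else:
        seq = np.random.SeedSequence(seed)
        seed_int = int(seed)
    children = seq.spawn(len(effects) + 1)
    f_star: dict[str, float] = {}
    p_omni: dict[str, float] = {}
    clusters: list[Cluster] = []
    for effect, child in zip(effects, children):
        dist = permutation_distribution(design, effect, n_perm=n_perm,
                                        seed=child)
        star = threshold_from_distribution(dist, alpha)
        obs_curve = np.where(np.isfinite(curves.curve(effect)),
                             curves.curve(effect), 0.0)
        obs_max = float(np.where(dist.valid_mask, obs_curve, 0.0).max())
        f_star[effect] = star
        p_omni[effect] = omnibus_p(dist, obs_max)
        clusters.extend(cluster_inference(obs_curve, star, dist, effect))
    ph: list[PosthocResult] = []
    interaction_hit = ("interaction" in effects
                       and p_omni.get("interaction", 1.0) <= alpha)
    if run_posthoc and interaction_hit:
        ph = posthoc(design, clusters=[c for c in clusters
                                       if c.effect == "interaction"],
                     n_perm=n_perm, alpha=alpha, seed=children[-1])
    return SnpmResult(
        electrode=design.electrode,
        F_group=curves.F_group, F_condition=curves.F_condition,
        F_interaction=curves.F_interaction, F_star=f_star,
        p_omnibus=p_omni, clusters=clusters, posthoc=ph,
        n_permutations=n_perm, alpha=alpha, seed=seed_int)


def build_designs(matrices, electrodes) -> dict[str, DesignMatrix]:
    """Per-electrode design matrices from subject cycle matrices.

    ``matrices`` is a flat list of :class:`~gaitwave.epoching.CycleMatrix`
    covering every subject under both conditions.
    """
    by_subject: dict[str, dict[str, object]] = {}
    groups: dict[str, str] = {}
    for m in matrices:
        by_subject.setdefault(m.subject_id, {})[m.condition] = m
        groups[m.subject_id] = m.group
    subject_ids = sorted(by_subject)
    for sid in subject_ids:
        missing = set(CONDITIONS) - set(by_subject[sid])
        if missing:
            raise ValueError(f"subject {sid} is missing condition(s) {missing}")
    designs = {}
    for e, label in enumerate(electrodes):
        data = np.stack([
            np.stack([by_subject[sid][c].values[e] for c in CONDITIONS])
            for sid in subject_ids])
        designs[label] = DesignMatrix(
            data=data, group=np.array([groups[s] for s in subject_ids],
                                      dtype=object),
            subject_ids=list(subject_ids), electrode=label)
    return designs


def run_snpm_all_electrodes(matrices, electrodes, n_perm: int = 10000,
                            alpha: float = 0.05, seed: int = 0,
                            run_posthoc: bool = True,
                            ) -> dict[str, SnpmResult]:
    """Independent SnPM per electrode from a cohort of cycle matrices.

    A common seed sequence spawns one child stream per electrode, so the
    whole report is deterministic given ``seed``.  No correction is
    applied across electrodes (results are electrode-wise).
    """
    designs = build_designs(matrices, electrodes)
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(designs))
    results = {}
    for (label, design), child in zip(designs.items(), children):
        results[label] = run_snpm(design, n_perm=n_perm, alpha=alpha,
                                  seed=child, run_posthoc=run_posthoc)
    return results
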