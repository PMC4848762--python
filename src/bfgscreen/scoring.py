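"""Interaction scoring for pooled two-hybrid screens.

The readout of the screen is, per condition × fusion type × replicate, a
matrix of fused-barcode read counts over bait strains × prey strains.
Scoring proceeds as:

1. ``normalize`` — counts to frequencies *f* summing to one.
2. ``infer_nonselective`` — the expected non-selective abundance of each
   diploid is the outer product of the bait and prey marginal frequencies of
   the non-selective (+His) pool.  This absorbs uneven strain abundance and
   barcode-dependent amplification differences, which act (approximately)
   multiplicatively per strain.
3. ``compute_s`` — enrichment *s* = selective frequency / inferred
   non-selective frequency.
4. ``correct_autoactivation`` — baits that activate the reporter without any
   interacting prey inflate their whole row of *s*; dividing each row by a
   per-bait background level (an upper quantile of the row) yields the
   interaction signal *s′*.  A symmetric per-prey step can be applied after.
5. ``combine_scores`` — *s′* values are averaged over the barcode replicates
   (and by default fusion types) of each ORF pair, then combined across
   replicates and conditions into one interaction score per ORF pair.
6. ``optimize_threshold`` — the score cutoff is calibrated by scanning every
   rank cutoff and maximizing the Matthews correlation coefficient against a
   reference set of known interacting pairs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import CountMatrix, ReferenceSet, ScreenDesign, canonical_pair

__all__ = [
    "FrequencyMatrix",
    "ScoringConfig",
    "ScreenScores",
    "ThresholdResult",
    "normalize",
    "infer_nonselective",
    "compute_s",
    "correct_autoactivation",
    "combine_scores",
    "filter_covered_strains",
    "mcc",
    "optimize_threshold",
    "select_scoring_model",
    "score_screen",
    "collapse_orientations",
]


@dataclass
class FrequencyMatrix:
    """Normalized fused-barcode frequencies for one count matrix."""

    axis_baits: list[str]
    axis_preys: list[str]
    f: np.ndarray
    condition: str = ""
    fusion_type: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.shape != (len(self.axis_baits), len(self.axis_preys)):
            raise ValueError("frequency matrix shape does not match axes")
        if (self.f < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(self.f.sum() - 1.0) > 1e-9:
            raise ValueError("frequencies must sum to 1")

    @property
    def bait_marginals(self) -> np.ndarray:
        return self.f.sum(axis=1)

    @property
    def prey_marginals(self) -> np.ndarray:
        return self.f.sum(axis=0)


def normalize(counts: CountMatrix, pseudocount: float = 0.0) -> FrequencyMatrix:
    """Counts → frequencies: f = (n + pseudocount) / Σ(n + pseudocount)."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = counts.counts.astype(float) + pseudocount
    total = x.sum()
    if total <= 0:
        raise ValueError("normalize: all-zero matrix with pseudocount 0 is degenerate")
    return FrequencyMatrix(
        axis_baits=list(counts.axis_baits),
        axis_preys=list(counts.axis_preys),
        f=x / total,
        condition=counts.condition,
        fusion_type=counts.fusion_type,
        replicate=counts.replicate,
    )


def infer_nonselective(f_his: FrequencyMatrix) -> FrequencyMatrix:
    """Expected non-selective pair abundance as the outer product of marginals.

    Row and column marginals are conserved exactly; any rank-1 frequency
    matrix is a fixed point.
    """
    f_inf = np.outer(f_his.bait_marginals, f_his.prey_marginals)
    return FrequencyMatrix(
        axis_baits=list(f_his.axis_baits),
        axis_preys=list(f_his.axis_preys),
        f=f_inf,
        condition=f"{f_his.condition} inferred",
        fusion_type=f_his.fusion_type,
        replicate=f_his.replicate,
    )


def compute_s(
    f_sel: FrequencyMatrix, f_inf: FrequencyMatrix, floor: float = 1e-9
) -> np.ndarray:
    """Selective enrichment s = f_sel / max(f_inf, floor), elementwise."""
    if floor <= 0:
        raise ValueError("floor must be > 0")
    if (
        f_sel.axis_baits != f_inf.axis_baits
        or f_sel.axis_preys != f_inf.axis_preys
    ):
        raise ValueError("compute_s: axis mismatch between selective and inferred")
    s = f_sel.f / np.maximum(f_inf.f, floor)
    assert np.isfinite(s).all()
    return s


def correct_autoactivation(
    s: np.ndarray,
    background_quantile: float = 0.75,
    floor: float = 1e-3,
    axis: str = "bait",
) -> np.ndarray:
    """Divide out per-bait (or per-prey) reporter background.

    The background level of bait *b* is the ``background_quantile`` of its
    row of *s* (most preys do not interact with any one bait, so an upper
    quantile tracks the bait's autonomous reporter activity plus its
    abundance miscalibration).  s′ = s / max(B_b, floor).  A bait with a
    constant positive row maps to s′ ≡ 1.  NaN cells (masked strains) are
    ignored in the quantile and propagate.
    """
    if not 0.0 <= background_quantile <= 1.0:
        raise ValueError("background_quantile must lie in [0, 1]")
    if floor <= 0:
        raise ValueError("floor must be > 0")
    s = np.asarray(s, dtype=float)
    along = 1 if axis == "bait" else 0
    with np.errstate(all="ignore"):
        bg = np.nanquantile(s, background_quantile, axis=along, keepdims=True)
    bg = np.where(np.isnan(bg), floor, bg)
    return s / np.maximum(bg, floor)


def _iterative_ratio(
    s: np.ndarray, w: np.ndarray, exclude_factor: float, max_iter: int
) -> np.ndarray:
    """Per-row abundance-weighted background ratio with outlier exclusion.

    Rows of ``s`` are enrichment ratios, ``w`` the corresponding expected
    (inferred non-selective) frequencies, so s·w is the observed selective
    frequency and the weighted mean of a row is its pooled reads-over-
    expectation ratio.  Cells more than ``exclude_factor`` times the current
    estimate are treated as genuine interactions and excluded, and the
    ratio is re-estimated until stable.
    """
    valid = ~np.isnan(s)
    sw = np.where(valid, s * w, 0.0)
    ww = np.where(valid, w, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        bg = sw.sum(axis=1) / np.maximum(ww.sum(axis=1), 1e-300)
    for _ in range(max_iter):
        keep = valid & (s <= exclude_factor * bg[:, None] + 1e-300)
        num = np.where(keep, sw, 0.0).sum(axis=1)
        den = np.where(keep, ww, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            new = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
        if np.allclose(new, bg, rtol=1e-12, atol=0.0):
            bg = new
            break
        bg = new
    return bg


def background_level(
    s: np.ndarray,
    f_inf: np.ndarray,
    exclude_factor: float = 5.0,
    axis: str = "bait",
    max_iter: int = 10,
) -> np.ndarray:
    """Robust per-bait (or per-prey) background enrichment ratio.

    Under the screen model a bait's reporter background is shared by every
    non-interacting prey in its row, so it is estimated by pooling reads
    across the row — (selective reads) / (expected reads) — rather than by
    a per-cell quantile, which collapses to zero as soon as single cells of
    background fall below one read of depth.  Genuine interactions sit
    orders of magnitude above background and are excluded by iterating:
    drop cells with s > exclude_factor × current estimate, re-estimate,
    repeat until stable.

    Per-row estimates are floored at the median of the detected per-row
    backgrounds, which puts rows whose own background sits below detection
    on the typical scale of the screen instead of an arbitrary constant;
    being a median, it is insensitive to individual extreme rows (a strong
    auto-activator neither escapes its own correction nor perturbs anyone
    else's).  The estimate is a function of frequency ratios only, hence
    invariant to overall sequencing depth; a constant row returns that
    constant.
    """
    if exclude_factor <= 1.0:
        raise ValueError("exclude_factor must be > 1")
    s = np.asarray(s, dtype=float)
    w = np.asarray(f_inf, dtype=float)
    if axis == "prey":
        s, w = s.T, w.T
    bg = _iterative_ratio(s, w, exclude_factor, max_iter)
    detected = bg > 0
    if detected.any():
        bg = np.maximum(bg, np.median(bg[detected]))
    return bg


def filter_covered_strains(
    f_his: FrequencyMatrix, min_marginal: float = 1e-7
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean keep-masks for baits and preys with sufficient non-selective coverage.

    Strains whose +His marginal frequency falls below ``min_marginal`` cannot
    be quantified (their inferred non-selective abundance is unreliable) and
    are excluded from scoring.
    """
    bait_keep = f_his.bait_marginals >= min_marginal
    prey_keep = f_his.prey_marginals >= min_marginal
    if not bait_keep.any() or not prey_keep.any():
        raise ValueError("filter_covered_strains: every strain masked")
    return bait_keep, prey_keep


def combine_scores(measurements: np.ndarray, method: str = "mean") -> tuple[float, int]:
    """Combine the per-replicate measurements of one ORF pair into one score.

    NaN measurements (masked or absent) are excluded.  Returns
    ``(score, n_contributing)``; with zero contributing measurements the
    score is NaN (unscored), never 0.
    """
    m = np.asarray(measurements, dtype=float).ravel()
    m = m[~np.isnan(m)]
    if m.size == 0:
        return float("nan"), 0
    if method == "mean":
        return float(m.mean()), m.size
    if method == "median":
        return float(np.median(m)), m.size
    if method == "min":
        return float(m.min()), m.size
    if method == "max":
        return float(m.max()), m.size
    raise ValueError(f"unknown combine method {method!r}")


# ---------------------------------------------------------------------------
# MCC calibration
# ---------------------------------------------------------------------------

def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient of a confusion table.

    Any zero factor in the denominator yields 0 by the standard convention.
    """
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("confusion counts must be non-negative")
    if tp + fp + fn + tn == 0:
        raise ValueError("mcc: empty confusion table")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


@dataclass
class ThresholdResult:
    rank_cutoff: int
    score_cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int
    precision: float
    recall: float
    mcc: float


def optimize_threshold(
    scores: dict[tuple[str, str], float] | pd.Series,
    reference: ReferenceSet,
    tested_space: set[tuple[str, str]],
    homodimer_policy: str = "keep",
) -> tuple[ThresholdResult, pd.DataFrame]:
    """Scan every rank cutoff of the score ranking and maximize MCC.

    ``scores`` maps canonical ORF pairs to interaction scores (NaN = pair
    tested but unscorable; such pairs are never called positive).  Positives
    at rank cutoff *k* are the top-*k* scored pairs; tied scores are kept
    together, so cutoffs fall only between distinct score values.  Returns
    the MCC-optimal cutoff and the full rank-vs-MCC profile.
    """
    if homodimer_policy not in ("keep", "exclude"):
        raise ValueError("homodimer_policy must be 'keep' or 'exclude'")
    universe = {canonical_pair(*p) for p in tested_space}
    if homodimer_policy == "exclude":
        universe = {p for p in universe if p[0] != p[1]}
    ref = reference.restricted_to(universe)
    if not ref:
        raise ValueError("optimize_threshold: reference has no overlap with tested space")

    items = [
        (p, float(v))
        for p, v in (scores.items() if hasattr(scores, "items") else scores)
        if canonical_pair(*p) in universe and not np.isnan(v)
    ]
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    n_universe = len(universe)
    n_ref = len(ref)

    vals = np.array([v for _, v in items])
    is_ref = np.array([p in ref for p, _ in items], dtype=int)
    cum_tp = np.cumsum(is_ref)
    # candidate cutoffs: after the last element of each distinct-score block
    if len(vals):
        boundary = np.flatnonzero(np.diff(vals) != 0)
        ks = np.append(boundary + 1, len(vals))
    else:
        ks = np.array([], dtype=int)

    rows = [(0, float("inf"), 0, 0, n_ref, n_universe - n_ref)]
    for k in ks:
        tp = int(cum_tp[k - 1])
        fp = int(k - tp)
        fn = n_ref - tp
        tn = n_universe - n_ref - fp
        rows.append((int(k), vals[k - 1], tp, fp, fn, tn))

    profile = pd.DataFrame(
        rows, columns=["rank_cutoff", "score_cutoff", "tp", "fp", "fn", "tn"]
    )
    profile["precision"] = profile.tp / (profile.tp + profile.fp).replace(0, np.nan)
    profile["recall"] = profile.tp / n_ref
    profile["mcc"] = [
        mcc(r.tp, r.fp, r.fn, r.tn) for r in profile.itertuples(index=False)
    ]
    best = profile.iloc[int(profile["mcc"].to_numpy().argmax())]
    result = ThresholdResult(
        rank_cutoff=int(best.rank_cutoff),
        score_cutoff=float(best.score_cutoff),
        tp=int(best.tp),
        fp=int(best.fp),
        fn=int(best.fn),
        tn=int(best.tn),
        precision=float(best.precision) if not np.isnan(best.precision) else 0.0,
        recall=float(best.recall),
        mcc=float(best.mcc),
    )
    return result, profile


# ---------------------------------------------------------------------------
# Screen-level pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScoringConfig:
    """Tunables of the scoring pipeline.

    ``conditions`` is the subset of selective conditions combined into the
    final score; the non-selective pool named ``nonselective_condition``
    supplies marginals.  Defaults reflect the configuration that performed
    best in calibration of this class of screen: the plain −His selection,
    mean combination, background quantile 0.75.
    """

    conditions: tuple[str, ...] = ("-His",)
    combine: str = "mean"
    background_quantile: float = 0.75  # used by the "quantile" estimator
    background_estimator: str = "pooled"  # "pooled" | "quantile"
    background_exclude_factor: float = 5.0  # signal exclusion for "pooled"
    prey_correction: bool = True
    pseudocount: float = 0.0
    freq_floor: float = 1e-9
    background_floor: float = 1e-3
    min_marginal: float = 1e-7
    average_fusion_types: bool = True
    nonselective_condition: str = "+His"


@dataclass
class ScreenScores:
    """Full scoring output: per-matrix signals and per-ORF-pair scores."""

    config: ScoringConfig
    s_prime: dict[tuple[str, str, str], np.ndarray]  # (cond, fusion, rep) -> matrix
    pair_scores: pd.DataFrame  # bait_orf, prey_orf, score, n_measurements, f_average
    masked_baits: list[str]
    masked_preys: list[str]

    def canonical_scores(self) -> dict[tuple[str, str], float]:
        return collapse_orientations(self.pair_scores)


def collapse_orientations(pair_scores: pd.DataFrame) -> dict[tuple[str, str], float]:
    """Directed (bait, prey) ORF scores → canonical unordered pair scores.

    A pair screened in both orientations keeps the larger score: either
    orientation scoring positive recovers the unordered reference pair.
    Unscored orientations (NaN) are ignored unless every orientation is
    unscored.
    """
    out: dict[tuple[str, str], float] = {}
    for a, b, v in zip(
        pair_scores["bait_orf"], pair_scores["prey_orf"], pair_scores["score"]
    ):
        key = canonical_pair(a, b)
        prev = out.get(key)
        if prev is None or np.isnan(prev) or (not np.isnan(v) and v > prev):
            out[key] = float(v)
    return out


def score_screen(
    design: ScreenDesign,
    counts: dict[tuple[str, str, str], CountMatrix],
    config: ScoringConfig = ScoringConfig(),
) -> ScreenScores:
    """Run the full scoring pipeline on one screen's count matrices.

    ``counts`` is keyed by (condition, fusion_type, replicate) and must
    contain a non-selective matrix for every (fusion_type, replicate) that
    carries a selective matrix.
    """
    bait_orfs = np.array([s.orf_id for s in design.baits])
    prey_orfs = np.array([s.orf_id for s in design.preys])

    s_prime: dict[tuple[str, str, str], np.ndarray] = {}
    f_sel_store: dict[tuple[str, str, str], np.ndarray] = {}
    masked_b: set[str] = set()
    masked_p: set[str] = set()

    for (cond, ftype, rep), cm in sorted(counts.items()):
        if cond not in config.conditions:
            continue
        his_key = (config.nonselective_condition, ftype, rep)
        if his_key not in counts:
            raise ValueError(f"missing non-selective matrix for {his_key}")
        f_his = normalize(counts[his_key], config.pseudocount)
        bait_keep, prey_keep = filter_covered_strains(f_his, config.min_marginal)
        f_sel = normalize(cm, config.pseudocount)
        f_inf = infer_nonselective(f_his)
        s = compute_s(f_sel, f_inf, config.freq_floor)
        s[~bait_keep, :] = np.nan
        s[:, ~prey_keep] = np.nan
        if config.background_estimator == "pooled":
            bg_b = background_level(
                s, f_inf.f, config.background_exclude_factor, axis="bait"
            )
            sp = s / np.maximum(bg_b, config.background_floor)[:, None]
            if config.prey_correction:
                bg_p = background_level(
                    sp, f_inf.f, config.background_exclude_factor, axis="prey"
                )
                sp = sp / np.maximum(bg_p, config.background_floor)[None, :]
        elif config.background_estimator == "quantile":
            sp = correct_autoactivation(
                s, config.background_quantile, config.background_floor, axis="bait"
            )
            if config.prey_correction:
                sp = correct_autoactivation(
                    sp, config.background_quantile, config.background_floor, axis="prey"
                )
        else:
            raise ValueError(
                f"unknown background_estimator {config.background_estimator!r}"
            )
        s_prime[(cond, ftype, rep)] = sp
        fs = f_sel.f.copy()
        fs[~bait_keep, :] = np.nan
        fs[:, ~prey_keep] = np.nan
        f_sel_store[(cond, ftype, rep)] = fs
        masked_b.update(np.array(design.bait_ids)[~bait_keep])
        masked_p.update(np.array(design.prey_ids)[~prey_keep])

    if not s_prime:
        raise ValueError("no selective count matrices match the configured conditions")

    # group strain-level cells by ORF pair
    ub, bait_grp = np.unique(bait_orfs, return_inverse=True)
    up, prey_grp = np.unique(prey_orfs, return_inverse=True)

    def orf_average(mat: np.ndarray) -> np.ndarray:
        """Mean over barcode-replicate strains per (bait ORF, prey ORF)."""
        acc = np.zeros((len(ub), len(up)))
        cnt = np.zeros((len(ub), len(up)))
        valid = ~np.isnan(mat)
        np.add.at(acc, (bait_grp[:, None], prey_grp[None, :]), np.where(valid, mat, 0.0))
        np.add.at(cnt, (bait_grp[:, None], prey_grp[None, :]), valid.astype(float))
        with np.errstate(invalid="ignore"):
            return np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)

    # one measurement per (condition, replicate) [and per fusion type unless averaged]
    ftypes = sorted({k[1] for k in s_prime})
    meas_keys: list[tuple] = []
    if config.average_fusion_types:
        for cond in config.conditions:
            for rep in sorted({k[2] for k in s_prime if k[0] == cond}):
                meas_keys.append((cond, rep))
    else:
        for cond in config.conditions:
            for ftype in ftypes:
                for rep in sorted({k[2] for k in s_prime if k[:2] == (cond, ftype)}):
                    meas_keys.append((cond, ftype, rep))

    measurements = []
    for key in meas_keys:
        if config.average_fusion_types:
            cond, rep = key
            mats = [s_prime[k] for k in s_prime if k[0] == cond and k[2] == rep]
            stacked = np.stack([orf_average(m) for m in mats])
            with np.errstate(invalid="ignore"):
                measurements.append(np.nanmean(stacked, axis=0))
        else:
            measurements.append(orf_average(s_prime[key]))
    meas = np.stack(measurements)  # (n_meas, n_bait_orfs, n_prey_orfs)

    f_stack = np.stack([orf_average(m) for m in f_sel_store.values()])
    with np.errstate(invalid="ignore"):
        f_average = np.nanmean(f_stack, axis=0)

    n_meas = (~np.isnan(meas)).sum(axis=0)
    with np.errstate(invalid="ignore"):
        if config.combine == "mean":
            score = np.nanmean(meas, axis=0)
        elif config.combine == "median":
            score = np.nanmedian(meas, axis=0)
        elif config.combine == "min":
            score = np.nanmin(np.where(np.isnan(meas), np.inf, meas), axis=0)
            score[n_meas == 0] = np.nan
        elif config.combine == "max":
            score = np.nanmax(np.where(np.isnan(meas), -np.inf, meas), axis=0)
            score[n_meas == 0] = np.nan
        else:
            raise ValueError(f"unknown combine method {config.combine!r}")
    score = np.where(n_meas == 0, np.nan, score)

    bi, pi = np.meshgrid(np.arange(len(ub)), np.arange(len(up)), indexing="ij")
    pair_scores = pd.DataFrame(
        {
            "bait_orf": ub[bi.ravel()],
            "prey_orf": up[pi.ravel()],
            "score": score.ravel(),
            "n_measurements": n_meas.ravel(),
            "f_average": f_average.ravel(),
        }
    )
    return ScreenScores(
        config=config,
        s_prime=s_prime,
        pair_scores=pair_scores,
        masked_baits=sorted(masked_b),
        masked_preys=sorted(masked_p),
    )


def select_scoring_model(
    design: ScreenDesign,
    counts: dict[tuple[str, str, str], CountMatrix],
    reference: ReferenceSet,
    candidate_configs: list[ScoringConfig] | None = None,
    tested_space: set[tuple[str, str]] | None = None,
) -> tuple[ScoringConfig, pd.DataFrame]:
    """Pick the scoring configuration that maximizes calibration MCC.

    The default grid mirrors the comparison of plain −His selection against
    the more stringent 3-AT selection and of mean against median replicate
    combination.  Ties break toward the simpler configuration (fewer
    conditions, mean before median, grid order).
    """
    if candidate_configs is None:
        grids = itertools.product(
            [("-His",), ("3-AT",), ("-His", "3-AT")], ["mean", "median"]
        )
        base = ScoringConfig()
        candidate_configs = [
            replace(base, conditions=conds, combine=comb) for conds, comb in grids
        ]
    if not candidate_configs:
        raise ValueError("select_scoring_model: empty candidate grid")
    if tested_space is None:
        tested_space = design.tested_orf_pairs()

    combine_order = {"mean": 0, "median": 1, "min": 2, "max": 3}
    rows = []
    results = []
    errors = []
    for i, cfg in enumerate(candidate_configs):
        try:
            scores = score_screen(design, counts, cfg)
            thr, _ = optimize_threshold(
                scores.canonical_scores(), reference, tested_space
            )
        except ValueError as exc:
            errors.append((cfg, exc))
            continue
        rows.append(
            {
                "conditions": "+".join(cfg.conditions),
                "combine": cfg.combine,
                "background_quantile": cfg.background_quantile,
                "rank_cutoff": thr.rank_cutoff,
                "mcc": thr.mcc,
                "precision": thr.precision,
                "recall": thr.recall,
            }
        )
        results.append((thr.mcc, len(cfg.conditions), combine_order.get(cfg.combine, 9), i, cfg))
    if not results:
        raise ValueError(f"select_scoring_model: every configuration failed: {errors}")
    results.sort(key=lambda t: (-t[0], t[1], t[2], t[3]))
    return results[0][-1], pd.DataFrame(rows)
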