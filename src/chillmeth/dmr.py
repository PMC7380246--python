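"""Windowed DMR calling from per-cytosine methylation calls.

The genome is tiled into fixed-width windows (default 100 bp, non-overlapping)
and each window in each sample is quantified as a log2 enrichment

    E = log2( ((m_w + c) / L_w) / ((M + c) / L) )

where ``m_w`` is the methylated-call count in the window, ``L_w`` the window
width, ``M`` the genome-wide methylated-call total of the sample, ``L`` the
genome length, and ``c`` a pseudocount (default 0.5) that keeps E finite for
empty windows.  E compares the window's methylated-call density to the
sample-wide density, so it is robust to differences in sequencing depth.

Windows with fewer than 20 methylated cytosine positions (union over samples)
are discarded.  A window is a differentially methylated region (DMR) when a
one-way ANOVA across the chilling conditions survives Benjamini-Hochberg
control (q < 0.01) and the largest pairwise difference of condition-mean E
exceeds 3 log2 units.  Direction (hyper/hypo) is reported per
condition-vs-baseline contrast from the sign of the mean-E difference.

:class:`DMRModel` / :class:`DMRResults` wrap this procedure in a fit/results
pair; the module-level functions expose each step individually.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans

from .io import CONTEXTS

__all__ = [
    "tile_windows",
    "WindowQuant",
    "quantify_windows",
    "quantify_window",
    "filter_windows",
    "anova_window",
    "anova_windows",
    "bh_adjust",
    "DMRModel",
    "DMRResults",
    "call_dmrs",
    "split_by_context",
    "top_variance",
    "cluster_profiles",
]

logger = logging.getLogger(__name__)

#: Smallest p-value reported for degenerate perfect separation.
MIN_P = np.finfo(float).tiny


# ---------------------------------------------------------------------------
# windows

def tile_windows(
    chrom_sizes: Mapping[str, int], width: int = 100, step: int | None = None
) -> pd.DataFrame:
    """Tile chromosomes into windows starting at position 1.

    With ``step == width`` (default) windows are disjoint and exhaustive; the
    final window of a chromosome may be shorter than *width*.
    """
    if width < 1:
        raise ValueError("width must be >= 1")
    step = width if step is None else step
    if not 1 <= step <= width:
        raise ValueError("step must satisfy 1 <= step <= width")
    rows = []
    for chrom, length in chrom_sizes.items():
        if length < 1:
            raise ValueError(f"invalid length {length} for {chrom}")
        start = 1
        while start <= length:
            rows.append((chrom, start, min(start + width - 1, length)))
            start += step
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["window_id"] = (
        df["chrom"].astype(str) + ":" + df["start"].astype(str)
        + "-" + df["end"].astype(str)
    )
    return df


@dataclass
class WindowQuant:
    """Per-sample quantification of a set of genomic windows.

    Attributes
    ----------
    windows : DataFrame with chrom/start/end/window_id, one row per window.
    samples : ordered sample ids.
    E : (n_windows, n_samples) log2 enrichment.
    m : (n_windows, n_samples) methylated-call counts.
    c : (n_windows, n_samples) covered-cytosine counts.
    n_meth_positions : (n_windows,) distinct positions with >= 1 methylated
        call in the union across samples (the default unit of the >= 20
        filter).
    n_meth_positions_per_sample : (n_windows, n_samples) positions with >= 1
        methylated call, counted within each sample separately.
    sample_totals : per-sample genome-wide methylated-call totals M.
    genome_length : total genome length L.
    """

    windows: pd.DataFrame
    samples: list[str]
    E: np.ndarray
    m: np.ndarray
    c: np.ndarray
    n_meth_positions: np.ndarray
    sample_totals: pd.Series
    genome_length: int
    n_meth_positions_per_sample: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.windows)

    def subset(self, mask: np.ndarray) -> "WindowQuant":
        return WindowQuant(
            windows=self.windows.loc[mask].reset_index(drop=True),
            samples=list(self.samples),
            E=self.E[mask],
            m=self.m[mask],
            c=self.c[mask],
            n_meth_positions=self.n_meth_positions[mask],
            sample_totals=self.sample_totals,
            genome_length=self.genome_length,
            n_meth_positions_per_sample=(
                None if self.n_meth_positions_per_sample is None
                else self.n_meth_positions_per_sample[mask]
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        """Windows with per-sample E columns (``E:<sample>``)."""
        out = self.windows.copy()
        for j, s in enumerate(self.samples):
            out[f"E:{s}"] = self.E[:, j]
        out["n_meth_positions"] = self.n_meth_positions
        return out


def _window_index(calls: pd.DataFrame, windows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Map each window to a slice of per-chromosome position-sorted calls.

    Returns (lo, hi) searchsorted bounds per window into the sorted call
    table; the caller uses cumulative sums for range aggregation.  Assumes
    *calls* is sorted by (chrom, pos).
    """
    lo = np.zeros(len(windows), dtype=np.int64)
    hi = np.zeros(len(windows), dtype=np.int64)
    for chrom, widx in windows.groupby("chrom", sort=False).groups.items():
        sel = calls["chrom"].to_numpy() == chrom
        offset = int(np.argmax(sel)) if sel.any() else 0
        pos = calls.loc[sel, "pos"].to_numpy()
        w = windows.loc[widx]
        lo[widx] = offset + np.searchsorted(pos, w["start"].to_numpy(), "left")
        hi[widx] = offset + np.searchsorted(pos, w["end"].to_numpy(), "right")
    return lo, hi


def quantify_windows(
    calls_by_sample: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    genome_length: int,
    pseudocount: float = 0.5,
    sample_totals: Mapping[str, int] | None = None,
) -> WindowQuant:
    """Quantify windows as log2 enrichment for every sample.

    ``calls_by_sample`` must already carry the coverage filter (the reader's
    ``min_coverage``); ``sample_totals`` (genome-wide methylated-call totals)
    default to sums over the supplied calls.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    widths = (windows["end"] - windows["start"] + 1).to_numpy()
    if (widths <= 0).any():
        raise ValueError("window of non-positive width")
    samples = list(calls_by_sample)
    n_w, n_s = len(windows), len(samples)
    E = np.zeros((n_w, n_s))
    m = np.zeros((n_w, n_s), dtype=np.int64)
    c = np.zeros((n_w, n_s), dtype=np.int64)
    mp = np.zeros((n_w, n_s), dtype=np.int64)
    totals = {}

    for j, s in enumerate(samples):
        calls = calls_by_sample[s]
        calls = calls.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)
        M = int(calls["n_meth"].sum()) if sample_totals is None else int(sample_totals[s])
        totals[s] = M
        lo, hi = _window_index(calls, windows)
        nm = calls["n_meth"].to_numpy()
        cm = np.concatenate([[0], np.cumsum(nm)])
        cmp_ = np.concatenate([[0], np.cumsum(nm >= 1)])
        m[:, j] = cm[hi] - cm[lo]
        c[:, j] = hi - lo
        mp[:, j] = cmp_[hi] - cmp_[lo]
        E[:, j] = np.log2(
            ((m[:, j] + pseudocount) / widths) / ((M + pseudocount) / genome_length)
        )

    # union of positions with >= 1 methylated call, per window
    meth_calls = pd.concat(
        [df.loc[df["n_meth"] >= 1, ["chrom", "pos"]] for df in calls_by_sample.values()],
        ignore_index=True,
    )
    meth_pos = meth_calls.drop_duplicates().sort_values(
        ["chrom", "pos"], kind="stable"
    ).reset_index(drop=True)
    meth_pos["n_meth"] = 1  # sentinel so _window_index's contract holds
    lo, hi = _window_index(meth_pos, windows)
    n_meth_positions = hi - lo

    return WindowQuant(
        windows=windows.reset_index(drop=True),
        samples=samples,
        E=E,
        m=m,
        c=c,
        n_meth_positions=n_meth_positions,
        sample_totals=pd.Series(totals),
        genome_length=int(genome_length),
        n_meth_positions_per_sample=mp,
    )


def quantify_window(
    m_w: int, window_width: int, M: int, genome_length: int, pseudocount: float = 0.5
) -> float:
    """Log2 enrichment of a single window (scalar form of the E formula)."""
    if window_width <= 0 or genome_length <= 0:
        raise ValueError("window width and genome length must be positive")
    return float(np.log2(
        ((m_w + pseudocount) / window_width)
        / ((M + pseudocount) / genome_length)
    ))


def filter_windows(
    wq: WindowQuant, min_meth_cytosines: int = 20, count_mode: str = "union"
) -> WindowQuant:
    """Keep windows with >= *min_meth_cytosines* methylated cytosines.

    ``count_mode="union"`` (default) counts distinct positions with at least
    one methylated call in the union across samples.  ``"per-sample-sum"``
    sums the per-sample methylated-position counts instead; this is the unit
    used for per-context calling, where the union count is capped by the
    context's site density (a 100-bp window holds only ~7 CpG positions in a
    38%-GC genome, so a union threshold of 20 would empty the CpG set).
    """
    if count_mode == "union":
        counts = wq.n_meth_positions
    elif count_mode == "per-sample-sum":
        if wq.n_meth_positions_per_sample is None:
            raise ValueError("per-sample methylated-position counts unavailable")
        counts = wq.n_meth_positions_per_sample.sum(axis=1)
    else:
        raise ValueError(f"unknown count_mode {count_mode!r}")
    return wq.subset(counts >= min_meth_cytosines)


# ---------------------------------------------------------------------------
# statistics

def anova_windows(E: np.ndarray, group_index: Sequence[np.ndarray]) -> np.ndarray:
    """Vectorised one-way fixed-effects ANOVA over the rows of E.

    ``group_index`` holds the sample-column indices of each condition.  Rows
    with zero total variance get p = 1; rows with zero within-group variance
    but non-zero between-group variance get the smallest positive float.
    """
    k = len(group_index)
    if k < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for g in group_index:
        if len(g) < 2:
            raise ValueError("each group needs >= 2 replicates")
    cols = np.concatenate(group_index)
    n = len(cols)
    X = E[:, cols]
    grand = X.mean(axis=1, keepdims=True)
    ss_total = ((X - grand) ** 2).sum(axis=1)
    ss_within = np.zeros(E.shape[0])
    ss_between = np.zeros(E.shape[0])
    for g in group_index:
        Xg = E[:, g]
        mg = Xg.mean(axis=1, keepdims=True)
        ss_within += ((Xg - mg) ** 2).sum(axis=1)
        ss_between += len(g) * (mg[:, 0] - grand[:, 0]) ** 2
    df_b, df_w = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
        p = sps.f.sf(F, df_b, df_w)
    tol = 1e-12 * np.maximum(ss_total, 1.0)
    p = np.where(ss_within <= tol, np.where(ss_between <= tol, 1.0, MIN_P), p)
    p = np.where(ss_total <= 1e-300, 1.0, p)
    return p


def anova_window(groups: Sequence[Sequence[float]]) -> float:
    """One-way ANOVA p-value for one window (see :func:`anova_windows`).

    Returns NaN (and logs a warning) when any group has < 2 replicates,
    matching the model-level behaviour of skipping such windows.
    """
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    if any(len(g) < 2 for g in groups):
        logger.warning("ANOVA undefined: a group has < 2 replicates")
        return float("nan")
    E = np.concatenate([np.asarray(g, dtype=float) for g in groups])[None, :]
    idx, off = [], 0
    for g in groups:
        idx.append(np.arange(off, off + len(g)))
        off += len(g)
    return float(anova_windows(E, idx)[0])


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j over the ascending order statistics,
    capped at 1, returned in the original order.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# model / results

def _design_groups(
    design: Mapping[str, str], samples: Sequence[str], baseline: str
) -> tuple[list[str], dict[str, np.ndarray]]:
    """Condition order (baseline first) and per-condition column indices."""
    conditions: list[str] = []
    for s in samples:
        cond = design[s]
        if cond not in conditions:
            conditions.append(cond)
    if baseline not in conditions:
        raise ValueError(f"baseline {baseline!r} absent from design")
    conditions = [baseline] + [cnd for cnd in conditions if cnd != baseline]
    idx = {
        cond: np.array([j for j, s in enumerate(samples) if design[s] == cond])
        for cond in conditions
    }
    return conditions, idx


class DMRModel:
    """Windowed DMR model over a multi-condition design.

    Parameters
    ----------
    windows
        A :class:`WindowQuant` that already passed :func:`filter_windows`.
    design
        Mapping sample id -> condition label (e.g. chilling-hour label).
    baseline
        Condition against which hyper/hypo direction is reported (the 0 CH
        condition in a chilling time course).
    """

    def __init__(
        self,
        windows: WindowQuant,
        design: Mapping[str, str],
        baseline: str,
    ) -> None:
        missing = [s for s in windows.samples if s not in design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.wq = windows
        self.design = dict(design)
        self.baseline = baseline
        self.conditions, self._group_idx = _design_groups(
            design, windows.samples, baseline
        )

    def condition_means(self) -> pd.DataFrame:
        """Per-condition mean E, one row per window."""
        means = {
            cond: self.wq.E[:, idx].mean(axis=1)
            for cond, idx in self._group_idx.items()
        }
        out = pd.DataFrame(means, index=self.wq.windows["window_id"])
        return out[self.conditions]

    def fit(self, q_max: float = 0.01, min_delta: float = 3.0) -> "DMRResults":
        """Run ANOVA + BH + fold-change gates and return :class:`DMRResults`."""
        groups = [self._group_idx[cnd] for cnd in self.conditions]
        usable = all(len(g) >= 2 for g in groups)
        if not usable:
            raise ValueError("every condition needs >= 2 replicates")
        p = anova_windows(self.wq.E, groups)
        q = bh_adjust(p)
        cm = self.condition_means()
        arr = cm.to_numpy()
        delta_max = arr.max(axis=1) - arr.min(axis=1)  # max pairwise |diff|
        is_dmr = (q < q_max) & (delta_max > min_delta)

        table = self.wq.windows.copy()
        table["p_anova"] = p
        table["q"] = q
        table["delta_max"] = delta_max
        table["is_dmr"] = is_dmr
        for cond in self.conditions[1:]:
            diff = cm[cond].to_numpy() - cm[self.baseline].to_numpy()
            direction = np.where(diff > 0, "hyper", "hypo")
            table[f"direction_{cond}"] = np.where(is_dmr, direction, "")
        return DMRResults(
            table=table,
            condition_means=cm,
            conditions=self.conditions,
            baseline=self.baseline,
            q_max=q_max,
            min_delta=min_delta,
            model=self,
        )


@dataclass
class DMRResults:
    """Result of :meth:`DMRModel.fit`.

    ``table`` has one row per tested window with p/q/delta_max/is_dmr and one
    ``direction_<condition>`` column per non-baseline contrast.
    """

    table: pd.DataFrame
    condition_means: pd.DataFrame
    conditions: list[str]
    baseline: str
    q_max: float
    min_delta: float
    model: DMRModel = field(repr=False)

    @property
    def dmrs(self) -> pd.DataFrame:
        return self.table[self.table["is_dmr"]].reset_index(drop=True)

    @property
    def n_dmrs(self) -> int:
        return int(self.table["is_dmr"].sum())

    def direction_counts(self, condition: str) -> pd.Series:
        """Hyper/hypo tallies for a vs-baseline contrast."""
        col = f"direction_{condition}"
        if col not in self.table:
            raise KeyError(f"no contrast {condition!r}")
        d = self.dmrs[col]
        return pd.Series(
            {"hyper": int((d == "hyper").sum()), "hypo": int((d == "hypo").sum())}
        )

    def dmr_profiles(self) -> pd.DataFrame:
        """Per-condition mean-E profiles of the called DMRs."""
        return self.condition_means.loc[self.dmrs["window_id"]]

    def top_variance(self, n: int = 1000) -> pd.DataFrame:
        return top_variance(self.dmr_profiles(), n)

    def cluster(self, k: int = 16, seed: int = 0, n_top: int | None = None) -> pd.DataFrame:
        profiles = self.dmr_profiles() if n_top is None else self.top_variance(n_top)
        return cluster_profiles(profiles, k, seed)

    def summary(self) -> str:
        lines = [
            "DMR model (windowed log2 enrichment, one-way ANOVA + BH)",
            f"  windows tested:  {len(self.table)}",
            f"  conditions:      {', '.join(self.conditions)} (baseline {self.baseline})",
            f"  thresholds:      q < {self.q_max}, delta_max > {self.min_delta}",
            f"  DMRs called:     {self.n_dmrs}",
        ]
        for cond in self.conditions[1:]:
            cnt = self.direction_counts(cond)
            lines.append(
                f"    {cond} vs {self.baseline}: hyper={cnt['hyper']}, hypo={cnt['hypo']}"
            )
        return "\n".join(lines)

    def to_bed(self, path) -> None:
        """BED-like TSV: 0-based half-open coordinates plus call metadata."""
        d = self.dmrs
        contexts = d["contexts"] if "contexts" in d else "all"
        bed = pd.DataFrame(
            {
                "chrom": d["chrom"],
                "start": d["start"] - 1,
                "end": d["end"],
                "id": d["window_id"],
                "q": d["q"],
                "delta_max": d["delta_max"],
                "direction": d[f"direction_{self.conditions[-1]}"],
                "contexts": contexts,
            }
        )
        bed.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def plot_profiles(self, ax=None, n: int = 50):
        """Line plot of the top-variance DMR profiles (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        prof = self.top_variance(n)
        for _, row in prof.iterrows():
            ax.plot(self.conditions, row[self.conditions], alpha=0.4, lw=0.8)
        ax.set_xlabel("condition")
        ax.set_ylabel("mean log2 enrichment")
        return ax


def call_dmrs(
    windows: WindowQuant,
    design: Mapping[str, str],
    baseline: str,
    q_max: float = 0.01,
    min_delta: float = 3.0,
) -> DMRResults:
    """Functional wrapper: ``DMRModel(windows, design, baseline).fit(...)``."""
    return DMRModel(windows, design, baseline).fit(q_max=q_max, min_delta=min_delta)


def split_by_context(
    calls_by_sample: Mapping[str, pd.DataFrame],
    windows: pd.DataFrame,
    design: Mapping[str, str],
    baseline: str,
    genome_length: int,
    min_meth_cytosines: int = 20,
    q_max: float = 0.01,
    min_delta: float = 3.0,
    pseudocount: float = 0.5,
) -> dict[str, DMRResults]:
    """Call DMRs independently within each cytosine context.

    Quantification is restricted to calls of one context and the per-sample
    totals M are recomputed over that context, so each context's enrichment is
    measured against its own genome-wide density.  The methylated-cytosine
    filter uses per-sample-summed counts here (see :func:`filter_windows`).
    """
    out: dict[str, DMRResults] = {}
    for ctx in CONTEXTS:
        sub = {
            s: df[df["context"] == ctx].reset_index(drop=True)
            for s, df in calls_by_sample.items()
        }
        wq = quantify_windows(sub, windows, genome_length, pseudocount=pseudocount)
        wq = filter_windows(wq, min_meth_cytosines, count_mode="per-sample-sum")
        if len(wq) == 0:
            empty = wq.windows.assign(
                p_anova=pd.Series(dtype=float), q=pd.Series(dtype=float),
                delta_max=pd.Series(dtype=float), is_dmr=pd.Series(dtype=bool),
            )
            model = DMRModel.__new__(DMRModel)
            out[ctx] = DMRResults(
                table=empty,
                condition_means=pd.DataFrame(),
                conditions=[],
                baseline=baseline,
                q_max=q_max,
                min_delta=min_delta,
                model=model,
            )
            continue
        res = call_dmrs(wq, design, baseline, q_max=q_max, min_delta=min_delta)
        res.table["contexts"] = ctx
        out[ctx] = res
    return out


# ---------------------------------------------------------------------------
# profile ranking and clustering

def top_variance(profiles: pd.DataFrame, n: int = 1000) -> pd.DataFrame:
    """The *n* profiles with highest variance across conditions.

    Sorted by descending variance; ties broken lexicographically by item id
    so the ranking is deterministic.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    var = profiles.var(axis=1, ddof=0)
    order = pd.DataFrame({"var": var, "id": profiles.index.astype(str)})
    order = order.sort_values(["var", "id"], ascending=[False, True], kind="stable")
    return profiles.loc[order.index[:n]]


def cluster_profiles(profiles: pd.DataFrame, k: int, seed: int = 0) -> pd.DataFrame:
    """K-means clustering of per-condition profiles (z-scored per item).

    Returns a DataFrame indexed like *profiles* with a ``cluster_id`` column;
    cluster centroids (on the z-scored scale) are attached as ``.attrs['centroids']``.
    Deterministic for a given seed.
    """
    n_items = len(profiles)
    if not 1 <= k <= n_items:
        raise ValueError(f"k must be in [1, {n_items}]")
    X = profiles.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    Z = np.where(sd > 0, (X - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(Z)
    out = pd.DataFrame({"cluster_id": labels}, index=profiles.index)
    out.attrs["centroids"] = pd.DataFrame(
        km.cluster_centers_, columns=profiles.columns
    )
    out.attrs["inertia"] = float(km.inertia_)
    return out
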