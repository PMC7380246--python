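"""Count-matrix normalisation, differential expression and summaries.

Libraries are scaled with trimmed-mean-of-M-values (TMM) factors; per-gene
differential expression between a condition and the 0 CH baseline is tested
with a negative-binomial likelihood-ratio test (common method-of-moments
dispersion, TMM-adjusted library sizes as offsets), and calls use FDR < 0.01
(Benjamini-Hochberg) together with a two-fold change (|log2FC| >= 1).  The
NB-LRT engine is this package's own documented implementation; its contract
is calibration (null type-I error, planted-effect recovery), not numeric
identity with any external tool.

Also provided: FPKM, co-expression k-means subclusters, a PCA summary of
sample structure, the qPCR delta-Ct relative-expression transform, and
chilling-hour / chilling-requirement utilities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

from .dmr import bh_adjust, cluster_profiles

__all__ = [
    "NormalizationResult",
    "tmm_factors",
    "DEGModel",
    "DEGResults",
    "deg_test",
    "fpkm",
    "coexpression_clusters",
    "pca_summary",
    "PCASummary",
    "relative_expression_dct",
    "chilling_hours",
    "chilling_requirement",
]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# TMM

@dataclass
class NormalizationResult:
    """TMM scaling factors and effective library sizes.

    Factors have geometric mean 1; the effective library size of sample j is
    ``lib_size[j] * factor[j]``.
    """

    factors: pd.Series
    lib_sizes: pd.Series
    ref_sample: str

    @property
    def effective_lib_sizes(self) -> pd.Series:
        return self.lib_sizes * self.factors


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, n_obs: float, n_ref: float,
    trim_M: float, trim_A: float,
) -> float:
    """TMM factor of one sample against the reference (log2 scale -> 2**)."""
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    if obs.size == 0:
        return 1.0
    p_obs, p_ref = obs / n_obs, ref / n_ref
    M = np.log2(p_obs / p_ref)
    A = 0.5 * np.log2(p_obs * p_ref)
    # delta-method variance of M: binomial sampling on both sides
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    if np.max(np.abs(M)) < 1e-6:  # identical relative abundances
        return 1.0
    n = M.size
    loM = np.floor(n * trim_M) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_A) + 1
    hiA = n + 1 - loA
    rM = sps.rankdata(M, method="average")
    rA = sps.rankdata(A, method="average")
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep2.any():
        return 1.0
    f = np.sum(M[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    return float(2.0 ** f)


def tmm_factors(
    counts: pd.DataFrame,
    ref_sample: str | None = None,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values scaling factors (Robinson-Oshlack).

    Per sample j against a reference r, gene-wise log ratios
    M_g = log2((y_gj/N_j)/(y_gr/N_r)) and abundances
    A_g = 0.5*log2((y_gj/N_j)*(y_gr/N_r)) are computed over genes expressed in
    both samples, doubly trimmed (30% per tail on M, 5% per tail on A), and
    combined as a precision-weighted mean; the factor is 2**(that mean).
    Factors are rescaled to geometric mean 1.  The reference defaults to the
    sample whose upper-quartile CPM is closest to the mean upper quartile.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs >= 2 samples")
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"sample {bad!r} has all-zero counts")
    if ref_sample is None:
        uq = counts.div(lib, axis=1).quantile(0.75)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy()
    n_ref = float(lib[ref_sample])
    f = {}
    for s in counts.columns:
        if s == ref_sample:
            f[s] = 1.0
        else:
            f[s] = _tmm_pair(
                counts[s].to_numpy(), ref, float(lib[s]), n_ref, trim_M, trim_A
            )
    factors = pd.Series(f)[counts.columns]
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationResult(factors=factors, lib_sizes=lib, ref_sample=str(ref_sample))


# ---------------------------------------------------------------------------
# NB likelihood machinery

def _nb_loglik(y: np.ndarray, mu: np.ndarray, alpha: float) -> np.ndarray:
    """Row-wise NB log-likelihood (mean mu, Var = mu + alpha*mu^2)."""
    mu = np.maximum(mu, 1e-300)
    if alpha < 1e-10:  # Poisson limit
        return (y * np.log(mu) - mu - gammaln(y + 1)).sum(axis=-1)
    inv = 1.0 / alpha
    ll = (
        gammaln(y + inv) - gammaln(inv) - gammaln(y + 1)
        + y * np.log(alpha * mu / (1 + alpha * mu))
        - inv * np.log1p(alpha * mu)
    )
    return ll.sum(axis=-1)


def _nb_fit_mean(y: np.ndarray, s: np.ndarray, alpha: float) -> np.ndarray:
    """MLE of the common (offset-scaled) mean per row: mu_ij = m_i * s_j.

    Solves sum_j (y_ij - m*s_j) / (1 + alpha*m*s_j) = 0 by damped Newton on
    log m, vectorised over rows.  Rows with all-zero counts get m = 0.
    """
    tot = y.sum(axis=1)
    m = tot / s.sum()
    zero = tot == 0
    m = np.where(zero, 1.0, m)  # placeholder; zeroed at the end
    logm = np.log(m)
    for _ in range(60):
        mu = np.exp(logm)[:, None] * s[None, :]
        denom = 1.0 + alpha * mu
        g = ((y - mu) / denom).sum(axis=1)
        gp = -(mu * (1.0 + alpha * y) / denom**2).sum(axis=1)
        step = np.where(gp != 0, g / gp, 0.0)
        step = np.clip(step, -2.0, 2.0)
        logm = logm - step
        if np.max(np.abs(step)) < 1e-12:
            break
    m = np.exp(logm)
    m[zero] = 0.0
    return m


def _common_dispersion(y: np.ndarray, mu: np.ndarray, n_params: int) -> float:
    """Pooled method-of-moments dispersion: Var = mu + alpha*mu^2.

    Residual sums of squares are inflated by n/(n-p) to correct for the
    fitted group means.
    """
    n = y.shape[1]
    c = n / max(n - n_params, 1)
    num = ((y - mu) ** 2).sum() * c - mu.sum()
    den = (mu**2).sum()
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, 0.0, 100.0))


# ---------------------------------------------------------------------------
# DEG model

class DEGModel:
    """Negative-binomial differential-expression model for a count matrix.

    Parameters
    ----------
    counts
        genes x samples integer DataFrame.
    design
        Mapping sample id -> condition label.
    lengths
        Optional per-gene lengths in bp (for FPKM).
    norm
        Optional precomputed :class:`NormalizationResult`; computed with
        :func:`tmm_factors` otherwise.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        design: Mapping[str, str],
        lengths: pd.Series | None = None,
        norm: NormalizationResult | None = None,
    ) -> None:
        if (counts < 0).any().any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in design]
        if missing:
            raise ValueError(f"samples missing from design: {missing}")
        self.counts = counts
        self.design = dict(design)
        self.lengths = lengths
        self.norm = tmm_factors(counts) if norm is None else norm

    @classmethod
    def from_dataframe(
        cls, counts: pd.DataFrame, sample_sheet: pd.DataFrame, **kw
    ) -> "DEGModel":
        """Build from a counts table and a sample sheet with ``sample_id`` and
        ``condition`` columns."""
        design = dict(
            zip(sample_sheet["sample_id"].astype(str), sample_sheet["condition"].astype(str))
        )
        return cls(counts, design, **kw)

    def _group_samples(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.design[s] == condition]

    def fit(
        self,
        contrast: tuple[str, str],
        q_max: float = 0.01,
        min_abs_log2fc: float = 1.0,
        dispersion_mode: str = "common",
        pseudocount: float = 0.5,
    ) -> "DEGResults":
        """Test *contrast* = (condition, baseline) and return :class:`DEGResults`.

        Per gene, the NB likelihood-ratio statistic compares a one-mean null
        with a mean-per-group alternative, with effective library sizes as
        offsets and a shared method-of-moments dispersion (``common``) or
        per-gene floored moments (``tagwise-moments``).  log2FC is computed
        from group means of normalised counts with *pseudocount* added, and
        calls are ``up``/``down``/``ns`` per the q and fold-change gates.
        """
        cond, base = contrast
        g1 = self._group_samples(cond)
        g0 = self._group_samples(base)
        if not g1 or not g0:
            raise ValueError(f"contrast group absent from design: {contrast}")
        if len(g1) < 2 or len(g0) < 2:
            raise ValueError("each contrast group needs >= 2 replicates")
        cols = g0 + g1
        y = self.counts[cols].to_numpy(dtype=float)
        eff = self.norm.effective_lib_sizes[cols].to_numpy(dtype=float)
        s = eff / np.exp(np.mean(np.log(eff)))  # geometric-mean-1 offsets
        labels = np.array([0] * len(g0) + [1] * len(g1))

        # provisional group means (Poisson start) for the dispersion moment
        mu_hat = np.zeros_like(y)
        for grp in (0, 1):
            sel = labels == grp
            m = y[:, sel].sum(axis=1) / s[sel].sum()
            mu_hat[:, sel] = m[:, None] * s[None, sel]
        if dispersion_mode == "common":
            alpha = _common_dispersion(y, mu_hat, n_params=2)
            alphas = np.full(y.shape[0], alpha)
        elif dispersion_mode == "tagwise-moments":
            n = y.shape[1]
            c = n / max(n - 2, 1)
            num = ((y - mu_hat) ** 2).sum(axis=1) * c - mu_hat.sum(axis=1)
            den = (mu_hat**2).sum(axis=1)
            common = _common_dispersion(y, mu_hat, n_params=2)
            with np.errstate(divide="ignore", invalid="ignore"):
                tag = np.where(den > 0, num / den, common)
            alphas = np.clip(tag, 0.0, 100.0)
        else:
            raise ValueError(f"unknown dispersion_mode {dispersion_mode!r}")

        # LRT per gene; vectorise over genes that share the common alpha,
        # loop over distinct alphas otherwise
        lrt = np.zeros(y.shape[0])
        for alpha in np.unique(alphas) if dispersion_mode != "common" else [alphas[0]]:
            sel = alphas == alpha
            ys = y[sel]
            m_null = _nb_fit_mean(ys, s, alpha)
            ll_null = _nb_loglik(ys, m_null[:, None] * s[None, :], alpha)
            ll_alt = np.zeros(sel.sum())
            mu_alt = np.zeros_like(ys)
            for grp in (0, 1):
                gsel = labels == grp
                mg = _nb_fit_mean(ys[:, gsel], s[gsel], alpha)
                mu_alt[:, gsel] = mg[:, None] * s[None, gsel]
            ll_alt = _nb_loglik(ys, mu_alt, alpha)
            lrt[sel] = np.maximum(2.0 * (ll_alt - ll_null), 0.0)

        p = sps.chi2.sf(lrt, df=1)
        q = bh_adjust(p)

        norm_counts = y / s[None, :]
        mean1 = norm_counts[:, labels == 1].mean(axis=1)
        mean0 = norm_counts[:, labels == 0].mean(axis=1)
        log2fc = np.log2((mean1 + pseudocount) / (mean0 + pseudocount))

        call = np.where(
            (q < q_max) & (log2fc >= min_abs_log2fc), "up",
            np.where((q < q_max) & (log2fc <= -min_abs_log2fc), "down", "ns"),
        )
        table = pd.DataFrame(
            {
                "gene_id": self.counts.index,
                "log2FC": log2fc,
                "p": p,
                "q": q,
                "call": call,
            }
        ).set_index("gene_id")
        return DEGResults(
            table=table,
            contrast=(cond, base),
            dispersion=alphas if dispersion_mode != "common" else float(alphas[0]),
            dispersion_mode=dispersion_mode,
            q_max=q_max,
            min_abs_log2fc=min_abs_log2fc,
            model=self,
        )

    def fit_all(self, baseline: str, **kw) -> dict[str, "DEGResults"]:
        """Fit every condition-vs-baseline contrast in the design."""
        conds = []
        for s in self.counts.columns:
            cnd = self.design[s]
            if cnd != baseline and cnd not in conds:
                conds.append(cnd)
        return {cnd: self.fit((cnd, baseline), **kw) for cnd in conds}

    def fpkm(self) -> pd.DataFrame:
        if self.lengths is None:
            raise ValueError("gene lengths required for FPKM")
        return fpkm(self.counts, self.lengths, self.norm)

    def cpm(self) -> pd.DataFrame:
        """TMM-scaled counts per million."""
        eff = self.norm.effective_lib_sizes
        return self.counts.div(eff, axis=1) * 1e6

    def pca(self) -> "PCASummary":
        return pca_summary(self.cpm())


@dataclass
class DEGResults:
    """Per-gene differential-expression table for one contrast."""

    table: pd.DataFrame
    contrast: tuple[str, str]
    dispersion: float | np.ndarray
    dispersion_mode: str
    q_max: float
    min_abs_log2fc: float
    model: DEGModel = field(repr=False)

    @property
    def n_up(self) -> int:
        return int((self.table["call"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.table["call"] == "down").sum())

    @property
    def degs(self) -> pd.DataFrame:
        return self.table[self.table["call"] != "ns"]

    def summary(self) -> str:
        cond, base = self.contrast
        disp = (
            f"{self.dispersion:.4g}" if np.isscalar(self.dispersion)
            else f"tagwise (median {np.median(self.dispersion):.4g})"
        )
        return "\n".join(
            [
                f"DEG model (NB-LRT, TMM offsets), contrast {cond} vs {base}",
                f"  genes tested:   {len(self.table)}",
                f"  dispersion:     {disp} ({self.dispersion_mode})",
                f"  thresholds:     q < {self.q_max}, |log2FC| >= {self.min_abs_log2fc}",
                f"  up / down / ns: {self.n_up} / {self.n_down} / "
                f"{len(self.table) - self.n_up - self.n_down}",
            ]
        )

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", float_format="%.6g")

    def plot_ma(self, ax=None):
        """MA-style plot of mean expression vs log2FC (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        cpm = self.model.cpm().mean(axis=1)
        colors = self.table["call"].map({"up": "red", "down": "blue", "ns": "grey"})
        ax.scatter(np.log10(cpm + 1), self.table["log2FC"], s=4, c=colors)
        ax.set_xlabel("log10 mean CPM")
        ax.set_ylabel("log2FC")
        return ax


def deg_test(
    counts: pd.DataFrame,
    design: Mapping[str, str],
    contrast: tuple[str, str],
    dispersion_mode: str = "common",
    **kw,
) -> DEGResults:
    """Functional wrapper over :class:`DEGModel` for a single contrast."""
    return DEGModel(counts, design).fit(contrast, dispersion_mode=dispersion_mode, **kw)


# ---------------------------------------------------------------------------
# FPKM / clustering / PCA

def fpkm(
    counts: pd.DataFrame, lengths: pd.Series, norm: NormalizationResult
) -> pd.DataFrame:
    """FPKM_gj = counts_gj * 1e9 / (effective_lib_size_j * length_g).

    Genes without a (positive) length are skipped with a warning.
    """
    lengths = lengths.reindex(counts.index)
    bad = lengths.isna() | (lengths <= 0)
    if bad.any():
        logger.warning("fpkm: skipping %d genes without a valid length", int(bad.sum()))
    keep = counts.loc[~bad]
    eff = norm.effective_lib_sizes[counts.columns]
    return keep.mul(1e9).div(eff, axis=1).div(lengths[~bad], axis=0)


def coexpression_clusters(
    expr: pd.DataFrame, k: int = 10, seed: int = 0
) -> pd.DataFrame:
    """K-means subclusters of per-condition expression profiles.

    Shares the implementation (z-scoring, determinism) of
    :func:`chillmeth.dmr.cluster_profiles`.
    """
    return cluster_profiles(expr, k, seed)


@dataclass
class PCASummary:
    """Per-sample principal-component coordinates and variance explained (%)."""

    coordinates: pd.DataFrame
    variance_explained: pd.Series

    def summary(self) -> str:
        parts = ", ".join(
            f"{pc}: {v:.1f}%" for pc, v in self.variance_explained.head(3).items()
        )
        return f"PCA of {len(self.coordinates)} samples ({parts})"


def pca_summary(expr: pd.DataFrame) -> PCASummary:
    """PCA of samples from a genes x samples expression matrix.

    The matrix is transformed as log2(x+1), genes are centred, and the
    sample x gene matrix is decomposed by singular values.  Variance explained
    is reported in percent and sums to <= 100.
    """
    if expr.shape[1] < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = np.log2(expr.to_numpy(dtype=float).T + 1.0)  # samples x genes
    X = X - X.mean(axis=0, keepdims=True)
    U, svals, _ = np.linalg.svd(X, full_matrices=False)
    coords = U * svals
    total = float((svals**2).sum())
    var_exp = 100.0 * svals**2 / total if total > 0 else np.zeros_like(svals)
    k = min(X.shape)
    pcs = [f"PC{i+1}" for i in range(k)]
    return PCASummary(
        coordinates=pd.DataFrame(coords[:, :k], index=expr.columns, columns=pcs),
        variance_explained=pd.Series(var_exp[:k], index=pcs),
    )


# ---------------------------------------------------------------------------
# qPCR and chilling utilities

def relative_expression_dct(ct_target: float, ct_reference: float) -> float:
    """Delta-Ct relative expression: 2**-(Ct_target - Ct_reference)."""
    return float(2.0 ** -(ct_target - ct_reference))


def chilling_hours(temps: Sequence[float], threshold: float = 7.2) -> int:
    """Number of hourly temperatures strictly below *threshold* degC.

    7.2 degC is the classic chilling-hour cutoff; an hour at exactly the
    threshold does not count.
    """
    t = np.asarray(list(temps), dtype=float)
    if t.size == 0:
        return 0
    if not np.isfinite(t).all():
        raise ValueError("temperatures must be finite")
    return int((t < threshold).sum())


def chilling_requirement(
    bud_break: Mapping[str, float] | pd.Series, min_fraction: float = 0.5
) -> str | None:
    """First condition at which the bud-break fraction reaches *min_fraction*.

    The chilling requirement is considered complete when at least 50% of buds
    resume growth under forcing conditions; returns the first qualifying
    condition label (insertion order), or None if never reached.
    """
    series = pd.Series(bud_break)
    hit = series[series >= min_fraction]
    return None if hit.empty else str(hit.index[0])
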