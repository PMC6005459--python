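"""Expression-subtype analysis: filtering, clustering, moderated differential
expression, cross-cohort signature overlap, and developmental-stage metagenes.

The matrix is assumed to be normalised log2-scale array data (probes ×
samples).  Differential expression uses an empirical-Bayes moderated t:
gene-wise sample variances are shrunk toward a pooled prior whose scale and
degrees of freedom are estimated by marginal moment matching on log
variances, and p values use the augmented degrees of freedom; multiplicity is
controlled with Benjamini–Hochberg step-up.  Metagenes summarise a marker
gene set as the first singular component of the z-scaled marker submatrix.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist
from scipy.special import digamma, polygamma
from skbio import TreeNode
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class ExpressionMatrix:
    """Probes × samples log-scale expression with per-sample group labels."""

    values: pd.DataFrame
    sample_groups: pd.Series

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        self.sample_groups = self.sample_groups.reindex(self.values.columns)
        if self.sample_groups.isna().any():
            raise ValueError("every sample needs a group label")

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_probes(self, probes: list[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(values=self.values.loc[probes],
                                sample_groups=self.sample_groups)


@dataclass(frozen=True)
class MarkerGeneSet:
    """A named developmental-stage marker gene list (defines one metagene)."""

    stage_name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise ValueError("marker gene set must be non-empty")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("marker gene ids must be unique")


def variance_filter(matrix: ExpressionMatrix, keep_fraction: float = 0.5) -> ExpressionMatrix:
    """Retain the most variable probes across samples.

    Probes are ranked by inter-sample variance (sample variance, ddof 1) and
    the top ``ceil(keep_fraction * n_probes)`` kept; ties resolved by probe
    id order.  Original probe order is preserved in the output.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must lie in (0, 1]")
    if matrix.values.shape[1] < 2:
        raise ValueError("variance filtering needs >= 2 samples")
    n = matrix.values.shape[0]
    k = math.ceil(keep_fraction * n)
    var = matrix.values.var(axis=1, ddof=1).to_numpy()
    order = np.lexsort((np.arange(n), -var))  # descending variance, stable
    keep_idx = np.sort(order[:k])
    return matrix.subset_probes([matrix.probe_ids[i] for i in keep_idx])


def exclude_probes(matrix: ExpressionMatrix, blacklist: list[str]) -> ExpressionMatrix:
    """Remove blacklisted probes (e.g. known cross-hybridising probe sets)."""
    bl = set(blacklist)
    keep = [p for p in matrix.probe_ids if p not in bl]
    n_removed = len(matrix.probe_ids) - len(keep)
    logger.info("exclude_probes: removed %d probe(s)", n_removed)
    if not keep:
        raise ValueError("blacklist removes every probe")
    return matrix.subset_probes(keep)


@dataclass
class ClusterResult:
    """UPGMA clustering of samples: linkage matrix, leaf order, Newick tree."""

    linkage_matrix: np.ndarray
    sample_ids: list[str]
    leaf_order: list[str]
    newick: str


def hierarchical_cluster(matrix: ExpressionMatrix) -> ClusterResult:
    """Cluster samples with Euclidean distance and average (UPGMA) linkage."""
    if matrix.values.shape[1] < 2:
        raise ValueError("clustering needs >= 2 samples")
    X = matrix.values.to_numpy().T
    Z = linkage(pdist(X, metric="euclidean"), method="average")
    tree = TreeNode.from_linkage_matrix(Z, matrix.sample_ids)
    order = [matrix.sample_ids[i] for i in leaves_list(Z)]
    return ClusterResult(
        linkage_matrix=Z,
        sample_ids=matrix.sample_ids,
        leaf_order=order,
        newick=str(tree).strip(),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone decreasing)."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = float(polygamma(1, x))
        dif = tri * (1.0 - tri / y) / float(polygamma(2, x))
        x = x + dif
        if abs(dif / x) < 1e-10:
            break
    return x


def fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Estimate the scaled-inverse-chi-square variance prior (s0^2, d0).

    Moment matching on e = log(s2) corrected for the chi-square bias: the
    excess variance of e over trigamma(df/2) identifies the prior degrees of
    freedom d0; no excess means effectively infinite d0 (all variances equal).
    Zero sample variances are excluded from the fit.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    if pos.sum() < 2:
        raise ValueError("need >= 2 positive gene-wise variances to fit the prior")
    e = np.log(s2[pos]) - digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(emean + float(digamma(d0 / 2.0)) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s02 = math.exp(emean)
    return s02, d0


def moderated_de(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group empirical-Bayes moderated-t differential expression.

    Log fold change is the mean difference (``group_a`` minus ``group_b``) on
    the log scale.  Gene-wise pooled variances are shrunk toward the fitted
    prior; the moderated t uses ``residual_df + prior_df`` degrees of freedom
    and two-sided p values, adjusted with Benjamini–Hochberg step-up.

    ``prior_df`` overrides the estimated prior degrees of freedom (``0``
    recovers the ordinary two-sample t).  Returns a per-probe table with
    attrs ``prior_df`` and ``prior_var``.
    """
    g = matrix.sample_groups
    cols_a = g.index[g == group_a]
    cols_b = g.index[g == group_b]
    na, nb = len(cols_a), len(cols_b)
    if na < 2 or nb < 2:
        raise ValueError("moderated DE requires >= 2 samples per group "
                         f"(got {na} vs {nb}); insufficient residual df")
    A = matrix.values[cols_a].to_numpy()
    B = matrix.values[cols_b].to_numpy()
    lfc = A.mean(axis=1) - B.mean(axis=1)
    df_resid = na + nb - 2
    s2 = (A.var(axis=1, ddof=1) * (na - 1) + B.var(axis=1, ddof=1) * (nb - 1)) / df_resid

    if prior_df is None:
        s02, d0 = fit_variance_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        s02 = float(fit_variance_prior(s2, df_resid)[0]) if d0 > 0 else 0.0

    if math.isinf(d0):
        s2_post = np.full_like(s2, s02)
        df_total = math.inf
    else:
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
        df_total = df_resid + d0

    se = np.sqrt(s2_post * (1.0 / na + 1.0 / nb))
    t = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    degenerate = (se == 0) & (lfc != 0)
    if degenerate.any():
        t[degenerate] = np.sign(lfc[degenerate]) * np.inf
    if math.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    adj = multipletests(p, method="fdr_bh")[1]

    out = pd.DataFrame({
        "log_fc": lfc,
        "t": t,
        "p_value": p,
        "adj_p_value": adj,
        "direction": np.where(lfc > 0, "up", np.where(lfc < 0, "down", "none")),
    }, index=matrix.probe_ids)
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s02
    out.attrs["residual_df"] = df_resid
    return out


def select_by_fold_and_fdr(
    de: pd.DataFrame, fold_min: float = 2.0, adj_p_max: float = 0.01
) -> tuple[list[str], list[str]]:
    """Select up/down probe lists by fold change and adjusted p.

    'Two-fold' on log2 data means |log_fc| >= log2(fold_min).  Returns
    (up, down) probe id lists.
    """
    if fold_min < 1:
        raise ValueError("fold_min must be >= 1")
    lmin = math.log2(fold_min)
    sig = de["adj_p_value"] < adj_p_max
    up = de.index[sig & (de["log_fc"] >= lmin) & (de["log_fc"] > 0)].tolist()
    down = de.index[sig & (de["log_fc"] <= -lmin) & (de["log_fc"] < 0)].tolist()
    return up, down


def _round_half_up_percent(x: float) -> int:
    return int(math.floor(100.0 * x + 0.5))


def signature_overlap(
    query_up: list[str],
    query_down: list[str],
    reference_up: list[str],
    reference_down: list[str],
) -> dict:
    """Directional overlap of a query signature with a reference signature.

    For each direction reports |query ∩ reference| and the percentage of the
    query covered, rounded to the nearest integer (half up).  An empty query
    direction yields a missing percentage.
    """
    out = {}
    for direction, q, r in (("up", query_up, reference_up),
                            ("down", query_down, reference_down)):
        qs, rs = set(q), set(r)
        inter = len(qs & rs)
        out[direction] = {
            "n_query": len(qs),
            "n_overlap": inter,
            "percent": _round_half_up_percent(inter / len(qs)) if qs else None,
        }
    return out


@dataclass
class MetageneScore:
    """First-singular-component summary of a marker gene set per sample."""

    stage_name: str
    scores: pd.Series
    variance_explained: float
    sign_anchor: str
    n_genes_used: int
    n_genes_dropped: int


def metagene_scores(matrix: ExpressionMatrix, marker_set: MarkerGeneSet) -> MetageneScore:
    """Score samples on a developmental-stage metagene.

    Marker genes present in the matrix are z-scaled per gene across samples
    (zero-variance genes dropped with a warning); the per-sample score is the
    first right-singular vector scaled by the first singular value, with its
    sign fixed to correlate positively with the mean marker z-score.
    """
    present = [g for g in marker_set.gene_ids if g in matrix.values.index]
    sub = matrix.values.loc[present]
    sd = sub.std(axis=1, ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        logger.warning("metagene %s: dropped %d zero-variance gene(s)",
                       marker_set.stage_name, len(dropped))
    used = sd.index[sd > 0].tolist()
    if len(used) < 2:
        raise ValueError(f"metagene {marker_set.stage_name!r}: fewer than 2 usable "
                         "marker genes in the matrix")
    Z = sub.loc[used].sub(sub.loc[used].mean(axis=1), axis=0).div(sd[used], axis=0)
    Zv = Z.to_numpy()
    _, s, vt = np.linalg.svd(Zv, full_matrices=False)
    scores = s[0] * vt[0]
    anchor = Zv.mean(axis=0)
    if np.dot(scores - scores.mean(), anchor - anchor.mean()) < 0:
        scores = -scores
    total = float((s ** 2).sum())
    return MetageneScore(
        stage_name=marker_set.stage_name,
        scores=pd.Series(scores, index=matrix.sample_ids),
        variance_explained=float(s[0] ** 2 / total) if total > 0 else 0.0,
        sign_anchor="positive correlation with mean marker z-score",
        n_genes_used=len(used),
        n_genes_dropped=len(dropped),
    )


def compare_metagene(score: MetageneScore, groups: pd.Series,
                     group_a: str, group_b: str) -> dict:
    """Welch two-sample comparison of metagene scores between two groups.

    The returned p value is two-sided and deliberately uncorrected for
    multiple comparisons across stages.
    """
    g = groups.reindex(score.scores.index)
    a = score.scores[g == group_a].to_numpy()
    b = score.scores[g == group_b].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 samples per group to compare metagene scores")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variability; equal means are a null result
        p = 1.0 if a.mean() == b.mean() else 0.0
        t = 0.0 if a.mean() == b.mean() else math.inf * np.sign(a.mean() - b.mean())
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return {
        "stage": score.stage_name,
        "t": float(t),
        "p_value": float(p),
        "corrected": False,
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
    }
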