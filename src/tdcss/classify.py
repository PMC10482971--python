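"""Transition-mode gene classification from state-labelled count matrices.

Cells recovered at known points of the activation process carry a state
label — ``pre`` (before stimulation), ``transition`` (recovered within a
short delay of their own secretion onset), ``activated`` (secretion
positive at the late observation time) and, for the four-state design,
``silent`` (secretion negative at the late time).  Genes whose expression
varies across these states are selected by one-way ANOVA on log2(CPM+1),
summarised as per-state mean profiles (z-scored per gene), clustered by
K-means, and the cluster centroids are matched by Pearson correlation to
named transition-mode templates:

=====  ====================================  ===============================
class  meaning                               pattern over states
=====  ====================================  ===============================
EIG    early induced                         up at transition, stays up
ERG    early reduced                         down at transition, stays down
LIG    late induced                          up only in activated
LRG    late reduced                          down only in activated
SIG    silent induced                        up only in silent
TIG    transiently induced                   up only at transition
TRG    transiently reduced (3-state design)  down only at transition
LEG    late reduced (3-state design)         down only in activated
=====  ====================================  ===============================

Transiently induced genes (TIGs) are the class that snapshot sampling
cannot see: their expression is indistinguishable between pre-stimulation
and the late states, so they only surface when cells are recovered at
their individual transition timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError, SchemaError

__all__ = [
    "StateCountMatrix",
    "StateProfileMatrix",
    "GeneClassAssignment",
    "MOUSE6_TEMPLATES",
    "HUMAN5_TEMPLATES",
    "cpm_normalize",
    "log2_cpm",
    "size_factors",
    "expression_matrix",
    "anova_select_genes",
    "build_state_profiles",
    "kmeans_transition_clusters",
    "merge_clusters_to_classes",
    "classify_transition_modes",
    "snapshot_deg",
    "tig_overlap",
    "alternative_tig_rule",
]

#: Expression-pattern templates over the ordered four-state set
#: (pre, transition, activated, silent).  Values are relative levels; the
#: matching is correlation-based so only the pattern matters.
MOUSE6_TEMPLATES: dict[str, np.ndarray] = {
    "EIG": np.array([-1.0, +1.0, +1.0, -1.0]),
    "ERG": np.array([+1.0, -1.0, -1.0, +1.0]),
    "LIG": np.array([-1.0, -1.0, +1.0, -1.0]),
    "LRG": np.array([+1.0, +1.0, -1.0, +1.0]),
    "SIG": np.array([-1.0, -1.0, -1.0, +1.0]),
    "TIG": np.array([-1.0, +1.0, -1.0, -1.0]),
}

#: Templates over the ordered three-state set (pre, transition, activated).
HUMAN5_TEMPLATES: dict[str, np.ndarray] = {
    "EIG": np.array([-1.0, +1.0, +1.0]),
    "LIG": np.array([-1.0, -1.0, +1.0]),
    "LEG": np.array([+1.0, +1.0, -1.0]),
    "TRG": np.array([+1.0, -1.0, +1.0]),
    "TIG": np.array([-1.0, +1.0, -1.0]),
}


@dataclass
class StateCountMatrix:
    """Gene x cell raw counts with per-cell state (and donor) labels."""

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    state: np.ndarray
    donor: np.ndarray | None = None
    spikein_mask: np.ndarray | None = None
    states: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise SchemaError("counts must be a 2-D gene x cell matrix")
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise SchemaError(
                f"{n_genes} count rows but {len(self.gene_ids)} gene ids"
            )
        if len(self.cell_ids) != n_cells:
            raise SchemaError(
                f"{n_cells} count columns but {len(self.cell_ids)} cell ids"
            )
        if len(set(self.gene_ids)) != n_genes:
            raise SchemaError("duplicate gene ids")
        if len(set(self.cell_ids)) != n_cells:
            raise SchemaError("duplicate cell ids")
        if np.any(self.counts < 0):
            raise SchemaError("negative counts")
        self.state = np.asarray(self.state)
        if self.state.size != n_cells:
            raise SchemaError("state labels must cover every cell")
        if self.donor is not None:
            self.donor = np.asarray(self.donor)
            if self.donor.size != n_cells:
                raise SchemaError("donor labels must cover every cell")
        if self.spikein_mask is None:
            self.spikein_mask = np.zeros(n_genes, dtype=bool)
        else:
            self.spikein_mask = np.asarray(self.spikein_mask, dtype=bool)
            if self.spikein_mask.size != n_genes:
                raise SchemaError("spikein_mask must cover every gene")
        observed = list(dict.fromkeys(self.state.tolist()))
        if self.states is None:
            self.states = tuple(observed)
        else:
            unknown = set(observed) - set(self.states)
            if unknown:
                raise SchemaError(f"cells carry unknown state labels {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def cells_in_state(self, state: str) -> np.ndarray:
        return np.flatnonzero(self.state == state)


@dataclass
class StateProfileMatrix:
    """Per-gene mean expression profile over the ordered states."""

    values: pd.DataFrame  # genes x states
    per_donor: bool = False
    zscored: bool = True

    @property
    def states(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class GeneClassAssignment:
    """Per-gene transition-mode labels plus clustering provenance."""

    table: pd.DataFrame  # gene_id, cluster, class, template_correlation
    class_counts: dict[str, int] = field(default_factory=dict)
    cluster_to_class: dict[int, tuple[str, float]] = field(default_factory=dict)

    def genes_in_class(self, cls: str) -> set[str]:
        return set(self.table.loc[self.table["class"] == cls, "gene_id"])


# ---------------------------------------------------------------------------
# normalisation and gene selection
# ---------------------------------------------------------------------------

def cpm_normalize(
    matrix: StateCountMatrix,
    include_spikeins_in_total: bool = True,
) -> np.ndarray:
    """Counts-per-million: scale each cell (column) to a total of 1e6.

    Spike-in rows contribute to the per-cell totals by default; set
    ``include_spikeins_in_total=False`` to normalise on endogenous counts
    only.  Spike-in rows themselves are still returned (scaled by the same
    per-cell factor).
    """
    counts = matrix.counts.astype(float)
    if include_spikeins_in_total:
        totals = counts.sum(axis=0)
    else:
        totals = counts[~matrix.spikein_mask].sum(axis=0)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        names = [matrix.cell_ids[i] for i in zero[:5]]
        raise SchemaError(f"cells with zero total count: {names}")
    return counts / totals[None, :] * 1e6


def log2_cpm(matrix: StateCountMatrix, **kwargs) -> np.ndarray:
    """log2(CPM + 1)."""
    return np.log2(cpm_normalize(matrix, **kwargs) + 1.0)


def size_factors(
    matrix: StateCountMatrix,
    exclude_genes: Iterable[str] | None = None,
) -> np.ndarray:
    """Median-of-ratios (DESeq-style) per-cell size factors.

    For each cell the factor is the median over reference genes of
    count / geometric-mean-count, where reference genes are endogenous
    genes with a positive count in every cell.  Unlike total-count
    scaling, the median is robust when a large gene set moves in one
    direction (composition bias).  ``exclude_genes`` removes known or
    suspected differential genes from the reference (used by the
    two-pass normalisation in :func:`classify_transition_modes`).
    Spike-in rows are excluded from the estimate because they do not
    scale with cellular RNA content.  Falls back to total-count factors
    when no reference gene exists (tiny or very sparse matrices).
    """
    counts = matrix.counts.astype(float)
    drop = set(exclude_genes) if exclude_genes is not None else set()
    keep = np.array(
        [not sp and g not in drop for g, sp in zip(matrix.gene_ids, matrix.spikein_mask)]
    )
    endo = counts[keep]
    ref = endo[np.all(endo > 0, axis=1)]
    if ref.shape[0] == 0:
        totals = counts.sum(axis=0)
        if np.any(totals == 0):
            raise SchemaError("cells with zero total count")
        return totals / totals.mean()
    logref = np.log(ref)
    loggm = logref.mean(axis=1, keepdims=True)
    sf = np.exp(np.median(logref - loggm, axis=0))
    return sf


def expression_matrix(
    matrix: StateCountMatrix,
    scale: str = "median_ratios",
    exclude_genes: Iterable[str] | None = None,
) -> np.ndarray:
    """Per-cell normalised log2 expression.

    ``scale="median_ratios"`` (default): log2(count / size_factor + 1)
    with composition-robust median-of-ratios size factors.
    ``scale="cpm"``: log2(CPM + 1) on raw per-cell totals.
    """
    if scale == "median_ratios":
        sf = size_factors(matrix, exclude_genes=exclude_genes)
        return np.log2(matrix.counts / sf[None, :] + 1.0)
    if scale == "cpm":
        return log2_cpm(matrix)
    raise ConfigError(f"unknown expression scale {scale!r}")


def _donor_state_means(
    expr: np.ndarray, matrix: StateCountMatrix, states: Sequence[str]
) -> dict[str, np.ndarray]:
    """Per-state observation matrix where each observation is one donor's
    mean over its cells in that state (genes x donors)."""
    if matrix.donor is None:
        raise SchemaError("per-donor averaging requested but no donor labels present")
    out = {}
    for st in states:
        cols = []
        in_state = matrix.state == st
        for d in dict.fromkeys(matrix.donor[in_state].tolist()):
            sel = in_state & (matrix.donor == d)
            cols.append(expr[:, sel].mean(axis=1))
        out[st] = np.column_stack(cols)
    return out


def anova_select_genes(
    matrix: StateCountMatrix,
    states_to_compare: Sequence[str] | None = None,
    alpha: float = 0.05,
    per_donor: bool = False,
    expression: np.ndarray | None = None,
    scale: str = "median_ratios",
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA across activation states per gene.

    Expression is normalised log2 counts (see :func:`expression_matrix`;
    median-of-ratios by default, log2(CPM+1) with ``scale="cpm"``, or an
    explicit ``expression`` array).  Observations are cells, or per-donor
    state means when ``per_donor`` (the three-donor human design, which
    removes the bias from unequal cell numbers per state).  Spike-in rows
    are not tested.  Returns a DataFrame (``gene_id``, ``F``, ``p``,
    ``selected``) over tested genes; ``selected`` marks p < alpha.

    Genes that are constant in every group get F = 0 / p = 1; genes with
    zero within-group variance but differing group means get p = 0 with
    the ``degenerate`` flag set.
    """
    states = list(states_to_compare) if states_to_compare else list(matrix.states)
    if len(states) < 2:
        raise SchemaError("need at least 2 states for ANOVA")
    expr = expression_matrix(matrix, scale) if expression is None else expression

    keep = ~matrix.spikein_mask
    if per_donor:
        groups = [g[keep] for g in _donor_state_means(expr, matrix, states).values()]
    else:
        groups = []
        for st in states:
            idx = matrix.cells_in_state(st)
            if idx.size < 2:
                raise SchemaError(f"state {st!r} has {idx.size} observations; need >= 2")
            groups.append(expr[np.ix_(keep, idx)])
    for st, g in zip(states, groups):
        if g.shape[1] < 2:
            raise SchemaError(f"state {st!r} has {g.shape[1]} observations; need >= 2")

    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.f_oneway(*groups, axis=1)
    F = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)

    # Degenerate rows: zero within-group variance.  With equal means scipy
    # returns nan (treated as F=0, p=1); with differing means it returns
    # F=inf, p=0, which we surface with the degeneracy flag.
    all_vals = np.hstack(groups)
    overall_const = np.ptp(all_vals, axis=1) == 0
    degenerate = (np.isnan(F) & ~overall_const) | np.isinf(F)
    F = np.where(overall_const, 0.0, F)
    p = np.where(overall_const, 1.0, p)
    F = np.where(degenerate, np.inf, F)
    p = np.where(degenerate, 0.0, p)

    gene_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "F": F,
            "p": p,
            "selected": p < alpha,
            "degenerate": degenerate,
        }
    )


def build_state_profiles(
    matrix: StateCountMatrix,
    deg_list: Iterable[str],
    per_donor: bool = False,
    zscore: bool = True,
    states: Sequence[str] | None = None,
    scale: str = "median_ratios",
    expression: np.ndarray | None = None,
) -> StateProfileMatrix:
    """Mean normalised log2 expression per gene per state for the
    selected genes.

    With ``per_donor``, cell means are taken within donor x state first and
    then averaged across donors.  With ``zscore``, each gene row is
    standardised across states (constant rows become all zeros).
    """
    deg_list = list(deg_list)
    if not deg_list:
        raise SchemaError("deg_list is empty")
    states = list(states) if states else list(matrix.states)
    missing = set(states) - set(np.unique(matrix.state))
    if missing:
        raise SchemaError(f"states absent from data: {sorted(missing)}")
    expr = expression_matrix(matrix, scale) if expression is None else expression
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    try:
        rows = [gene_index[g] for g in deg_list]
    except KeyError as exc:
        raise SchemaError(f"unknown gene id {exc.args[0]!r}") from None
    expr = expr[rows]

    if per_donor:
        per_state = _donor_state_means(expr, matrix, states)
        values = np.column_stack([per_state[st].mean(axis=1) for st in states])
    else:
        values = np.column_stack(
            [expr[:, matrix.cells_in_state(st)].mean(axis=1) for st in states]
        )

    if zscore:
        mu = values.mean(axis=1, keepdims=True)
        sd = values.std(axis=1, keepdims=True)
        values = np.where(sd > 0, (values - mu) / np.where(sd == 0, 1, sd), 0.0)

    df = pd.DataFrame(values, index=deg_list, columns=states)
    return StateProfileMatrix(values=df, per_donor=per_donor, zscored=zscore)


# ---------------------------------------------------------------------------
# clustering and template matching
# ---------------------------------------------------------------------------

def kmeans_transition_clusters(
    profiles: StateProfileMatrix,
    k: int,
    seed: int = 0,
    n_init: int = 50,
) -> tuple[np.ndarray, np.ndarray]:
    """K-means over per-gene state profiles; returns (labels, centroids)."""
    X = profiles.values.to_numpy()
    if k < 2:
        raise ConfigError(f"k must be >= 2, got {k}")
    if X.shape[0] < k:
        raise ConfigError(f"k={k} exceeds the {X.shape[0]} genes available")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(X)
    return labels, km.cluster_centers_


def _pearson(u: np.ndarray, v: np.ndarray) -> float:
    du, dv = u - u.mean(), v - v.mean()
    denom = np.linalg.norm(du) * np.linalg.norm(dv)
    if denom == 0:
        return np.nan
    return float(du @ dv / denom)


def merge_clusters_to_classes(
    centroids: np.ndarray,
    templates: Mapping[str, np.ndarray],
    min_correlation: float = 0.6,
) -> dict[int, tuple[str, float]]:
    """Assign each centroid to the template class with maximal Pearson
    correlation; below ``min_correlation`` the cluster is ``unclassified``.
    Returns cluster index -> (class, correlation)."""
    n_states = centroids.shape[1]
    for cls, tpl in templates.items():
        if np.asarray(tpl).size != n_states:
            raise ConfigError(
                f"template {cls} has {np.asarray(tpl).size} states, centroids have {n_states}"
            )
    out: dict[int, tuple[str, float]] = {}
    for i, c in enumerate(centroids):
        best_cls, best_r = "unclassified", -np.inf
        for cls, tpl in templates.items():
            r = _pearson(c, np.asarray(tpl, dtype=float))
            if np.isfinite(r) and r > best_r:
                best_cls, best_r = cls, r
        if not np.isfinite(best_r) or best_r < min_correlation:
            out[i] = ("unclassified", best_r if np.isfinite(best_r) else np.nan)
        else:
            out[i] = (best_cls, best_r)
    return out


def classify_transition_modes(
    matrix: StateCountMatrix,
    mode: str = "mouse6",
    alpha: float | None = None,
    k: int | None = None,
    seed: int = 0,
    min_correlation: float = 0.6,
    min_amplitude: float = 1.0,
    per_donor: bool | None = None,
    templates: Mapping[str, np.ndarray] | None = None,
    scale: str = "median_ratios",
    refine_normalization: bool = True,
) -> GeneClassAssignment:
    """Full pipeline: normalisation -> ANOVA gene selection -> state
    profiles -> K-means -> template merge.

    ``mode="mouse6"`` uses the four-state design (requires a silent state;
    ANOVA alpha 0.05, k=14 clusters merged to six classes).
    ``mode="human5"`` uses the three-state design with per-donor averaging
    when donor labels exist (alpha 0.01, k=8, five classes).

    With ``refine_normalization`` (default, median-of-ratios scale only)
    the gene selection runs twice: genes flagged by a first ANOVA pass are
    removed from the size-factor reference before the definitive pass, so
    a large one-sided block of regulated genes cannot drag the size
    factors and leak composition shifts into unregulated genes.

    A gene keeps its cluster's class only if its own profile correlates at
    least ``min_correlation`` with that class template and swings by at
    least ``min_amplitude`` log2 units between its extreme states (default
    1.0, i.e. a 2-fold change); otherwise it is labelled unclassified.
    Statistically significant but hair-thin fluctuations thereby never
    become induced/reduced calls.
    """
    if mode == "mouse6":
        states = ["pre", "transition", "activated", "silent"]
        alpha = 0.05 if alpha is None else alpha
        k = 14 if k is None else k
        templates = MOUSE6_TEMPLATES if templates is None else templates
        if per_donor is None:
            per_donor = False
    elif mode == "human5":
        states = ["pre", "transition", "activated"]
        alpha = 0.01 if alpha is None else alpha
        k = 8 if k is None else k
        templates = HUMAN5_TEMPLATES if templates is None else templates
        if per_donor is None:
            per_donor = matrix.donor is not None
    else:
        raise ConfigError(f"unknown mode {mode!r}")
    missing = set(states) - set(np.unique(matrix.state))
    if missing:
        raise SchemaError(f"mode {mode} requires states {sorted(missing)}")

    anova = anova_select_genes(matrix, states, alpha=alpha, per_donor=per_donor, scale=scale)
    expr = None
    if refine_normalization and scale == "median_ratios":
        flagged = anova.loc[anova["selected"], "gene_id"]
        expr = expression_matrix(matrix, scale, exclude_genes=flagged)
        anova = anova_select_genes(
            matrix, states, alpha=alpha, per_donor=per_donor, expression=expr
        )
    degs = anova.loc[anova["selected"], "gene_id"].tolist()
    if not degs:
        empty = pd.DataFrame(
            columns=["gene_id", "cluster", "class", "template_correlation"]
        )
        return GeneClassAssignment(table=empty, class_counts={}, cluster_to_class={})

    profiles = build_state_profiles(
        matrix, degs, per_donor=per_donor, zscore=True, states=states,
        scale=scale, expression=expr,
    )
    k_eff = min(k, len(degs))
    if k_eff >= 2:
        labels, centroids = kmeans_transition_clusters(profiles, k_eff, seed=seed)
    else:
        labels = np.zeros(len(degs), dtype=int)
        centroids = profiles.values.to_numpy().mean(axis=0, keepdims=True)
    cluster_map = merge_clusters_to_classes(centroids, templates, min_correlation)

    # Gene-level label: the cluster proposes the class; a gene keeps it
    # only if its own profile both matches the class template
    # (correlation floor) and swings by a meaningful amount (amplitude
    # floor, on the un-z-scored per-state means).
    raw_profiles = build_state_profiles(
        matrix, degs, per_donor=per_donor, zscore=False, states=states,
        scale=scale, expression=expr,
    )
    amplitude = np.ptp(raw_profiles.values.to_numpy(), axis=1)
    P = profiles.values.to_numpy()
    gene_class, gene_corr = [], []
    for g, c in enumerate(labels):
        cls = cluster_map[c][0]
        if cls == "unclassified":
            gene_class.append(cls)
            gene_corr.append(cluster_map[c][1])
            continue
        r = _pearson(P[g], np.asarray(templates[cls], dtype=float))
        if not np.isfinite(r) or r < min_correlation or amplitude[g] < min_amplitude:
            gene_class.append("unclassified")
        else:
            gene_class.append(cls)
        gene_corr.append(r)

    table = pd.DataFrame(
        {
            "gene_id": degs,
            "cluster": labels,
            "class": gene_class,
            "template_correlation": gene_corr,
        }
    )
    counts = table["class"].value_counts().to_dict()
    return GeneClassAssignment(
        table=table, class_counts=counts, cluster_to_class=cluster_map
    )


# ---------------------------------------------------------------------------
# snapshot differential expression and transient-induction rules
# ---------------------------------------------------------------------------

def snapshot_deg(
    matrix: StateCountMatrix,
    group_a: str,
    group_b: str,
    min_cells: int = 4,
    min_fold: float = 4.0,
    fdr: float = 0.1,
    alpha_adj: float = 0.05,
) -> pd.DataFrame:
    """Snapshot-style DEG selection between two states (a over b).

    Sequential filters: the gene must be expressed (count > 0) in more than
    ``min_cells`` cells of the two groups; its mean-CPM fold-change
    (pseudocount 1) must be >= ``min_fold`` in the a > b direction; a
    two-sided Mann-Whitney rank test is then applied and p-values are
    Benjamini-Hochberg adjusted over the tested genes; genes with adjusted
    p < ``alpha_adj`` are selected.  ``fdr`` is retained as the documented
    alternative BH threshold and is not applied by default.

    Returns a DataFrame (``gene_id``, ``fold``, ``p``, ``p_adj``,
    ``selected``) over the genes that reached the rank test.
    """
    for g in (group_a, group_b):
        if (matrix.state == g).sum() < 2:
            raise SchemaError(f"group {g!r} has fewer than 2 cells")
    ia, ib = matrix.cells_in_state(group_a), matrix.cells_in_state(group_b)
    both = np.concatenate([ia, ib])
    cpm = cpm_normalize(matrix)
    keep = ~matrix.spikein_mask

    expressed = (matrix.counts[:, both] > 0).sum(axis=1) > min_cells
    fold = (cpm[:, ia].mean(axis=1) + 1.0) / (cpm[:, ib].mean(axis=1) + 1.0)
    tested = keep & expressed & (fold >= min_fold)

    idx = np.flatnonzero(tested)
    if idx.size == 0:
        return pd.DataFrame(columns=["gene_id", "fold", "p", "p_adj", "selected"])
    with np.errstate(invalid="ignore"):
        res = stats.mannwhitneyu(
            cpm[np.ix_(idx, ia)], cpm[np.ix_(idx, ib)],
            alternative="two-sided", axis=1,
        )
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # identical constant groups
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "gene_id": [matrix.gene_ids[i] for i in idx],
            "fold": fold[idx],
            "p": p,
            "p_adj": p_adj,
            "selected": p_adj < alpha_adj,
        }
    )


def tig_overlap(
    tig_set: Iterable[str],
    deg_sets: Mapping[str, Iterable[str]],
) -> dict:
    """Overlap bookkeeping between the transient-induction set and named
    snapshot DEG sets: pairwise intersection sizes, the total overlap and
    the TIGs absent from every snapshot set."""
    tigs = set(tig_set)
    named = {name: set(s) for name, s in deg_sets.items()}
    pairwise = {name: len(tigs & s) for name, s in named.items()}
    union = set().union(*named.values()) if named else set()
    return {
        "n_tigs": len(tigs),
        "pairwise": pairwise,
        "in_any": len(tigs & union),
        "tig_only": sorted(tigs - union),
    }


def alternative_tig_rule(
    matrix: StateCountMatrix,
    alpha: float = 0.05,
    min_fold: float = 2.0,
) -> tuple[set[str], pd.DataFrame]:
    """Direct transient-induction rule, independent of clustering.

    A gene qualifies iff its transition-state expression exceeds both the
    pre-stimulation and the activated state, each supported by a one-sided
    Mann-Whitney test at ``alpha`` and a mean-CPM fold-change (pseudocount
    1) >= ``min_fold``.  Returns the qualifying gene set and a per-gene
    evidence table.
    """
    required = {"pre", "transition", "activated"}
    missing = required - set(np.unique(matrix.state))
    if missing:
        raise SchemaError(f"states absent from data: {sorted(missing)}")
    cpm = cpm_normalize(matrix)
    keep = ~matrix.spikein_mask
    it = matrix.cells_in_state("transition")
    ip = matrix.cells_in_state("pre")
    ia = matrix.cells_in_state("activated")

    idx = np.flatnonzero(keep)
    mt = cpm[np.ix_(idx, it)].mean(axis=1) + 1.0
    mp = cpm[np.ix_(idx, ip)].mean(axis=1) + 1.0
    ma = cpm[np.ix_(idx, ia)].mean(axis=1) + 1.0
    fold_pre = mt / mp
    fold_act = mt / ma

    with np.errstate(invalid="ignore"):
        p_pre = np.asarray(
            stats.mannwhitneyu(
                cpm[np.ix_(idx, it)], cpm[np.ix_(idx, ip)],
                alternative="greater", axis=1,
            ).pvalue,
            dtype=float,
        )
        p_act = np.asarray(
            stats.mannwhitneyu(
                cpm[np.ix_(idx, it)], cpm[np.ix_(idx, ia)],
                alternative="greater", axis=1,
            ).pvalue,
            dtype=float,
        )
    p_pre = np.where(np.isnan(p_pre), 1.0, p_pre)
    p_act = np.where(np.isnan(p_act), 1.0, p_act)

    qualifies = (
        (fold_pre >= min_fold) & (fold_act >= min_fold)
        & (p_pre < alpha) & (p_act < alpha)
    )
    evidence = pd.DataFrame(
        {
            "gene_id": [matrix.gene_ids[i] for i in idx],
            "fold_vs_pre": fold_pre,
            "fold_vs_activated": fold_act,
            "p_vs_pre": p_pre,
            "p_vs_activated": p_act,
            "selected": qualifies,
        }
    )
    return set(evidence.loc[evidence["selected"], "gene_id"]), evidence
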