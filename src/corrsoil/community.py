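"""Community-response statistics for treatment-structured 16S zOTU tables.

This module covers the analyses run on amplicon feature tables from
corrinoid-amended enrichment cultures and soil microcosms:

* taxonomy-level aggregation (zOTU -> genus -> ... -> phylum),
* Bray-Curtis / Jaccard dissimilarity and principal coordinates analysis,
* ANOSIM and PERMANOVA group-separation tests with seeded permutations,
* a per-taxon Kruskal-Wallis screen for corrinoid responsiveness at every
  taxonomic rank and timepoint,
* the two distinct "fraction responsive" summaries — the count-based union
  across timepoints used for enrichments and the abundance-weighted
  per-timepoint sum used for microcosms — kept as separately named
  operations so they are never conflated,
* pairwise Mann-Whitney comparisons between corrinoid treatments.

Following the study design, significance is reported at raw P <= .05 with no
multiple-testing correction, but a Benjamini-Hochberg adjusted column is
always emitted alongside so the choice is visible.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu, rankdata
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "DistanceMatrix",
    "OrdinationResult",
    "TestResult",
    "RANKS",
    "CORRINOIDS",
    "aggregate",
    "relative_abundance",
    "bray_curtis",
    "jaccard",
    "pcoa",
    "anosim",
    "permanova",
    "kw_screen",
    "responsive_fraction_count",
    "responsive_fraction_abundance",
    "pairwise_mw",
]

#: taxonomy schema, coarse to fine; "zotu" is the terminal rank
RANKS = ("phylum", "class", "order", "family", "genus", "zotu")

#: the seven amendment conditions (water control plus six corrinoids)
CORRINOIDS = (
    "none",
    "Cbl",
    "Cbi",
    "[Ade]Cba",
    "[2-MeAde]Cba",
    "[Cre]Cba",
    "[5-OHBza]Cba",
)

ALPHA = 0.05
DEFAULT_PERMUTATIONS = 999

REQUIRED_META = ("medium", "corrinoid", "timepoint", "replicate", "inoculated")


@dataclass
class FeatureTable:
    """zOTU x sample counts with sample metadata and per-zOTU taxonomy.

    ``counts``: DataFrame indexed by zotu_id, columns sample ids,
    non-negative integers. ``sample_meta``: DataFrame indexed by sample id
    with at least `medium`, `corrinoid`, `timepoint`, `replicate`,
    `inoculated`. ``taxonomy``: DataFrame indexed by zotu_id with one column
    per rank in :data:`RANKS` (missing ranks filled ``unassigned_<rank>``).
    """

    counts: pd.DataFrame
    sample_meta: pd.DataFrame
    taxonomy: pd.DataFrame
    rank: str = "zotu"

    def __post_init__(self) -> None:
        problems = []
        if (self.counts.values < 0).any():
            problems.append("negative counts present")
        zero_cols = self.counts.columns[self.counts.sum(axis=0) == 0]
        if len(zero_cols):
            problems.append(f"all-zero samples: {list(zero_cols)}")
        missing_meta = set(self.counts.columns) - set(self.sample_meta.index)
        if missing_meta:
            problems.append(f"samples missing from metadata: {sorted(missing_meta)}")
        missing_cols = set(REQUIRED_META) - set(self.sample_meta.columns)
        if missing_cols:
            problems.append(f"metadata lacks required columns: {sorted(missing_cols)}")
        if self.rank == "zotu":
            missing_tax = set(self.counts.index) - set(self.taxonomy.index)
            if missing_tax:
                problems.append(
                    f"features missing from taxonomy: {sorted(missing_tax)[:5]}..."
                    if len(missing_tax) > 5
                    else f"features missing from taxonomy: {sorted(missing_tax)}"
                )
        if problems:
            raise ValueError("invalid feature table: " + "; ".join(problems))
        self.sample_meta = self.sample_meta.loc[self.counts.columns]

    @property
    def n_features(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def select_samples(self, mask: pd.Series) -> "FeatureTable":
        cols = self.counts.columns[mask.loc[self.counts.columns].astype(bool)]
        return FeatureTable(
            self.counts[cols].copy(),
            self.sample_meta.loc[cols].copy(),
            self.taxonomy,
            self.rank,
        )


def aggregate(table: FeatureTable, rank: str) -> FeatureTable:
    """Sum zOTU counts sharing a label at ``rank``.

    Aggregation at the terminal rank is the identity; per-sample totals are
    invariant across ranks.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if table.rank != "zotu":
        raise ValueError("aggregate expects a zOTU-level table")
    if rank == "zotu":
        return table
    labels = table.taxonomy.loc[table.counts.index, rank]
    agg = table.counts.groupby(labels).sum()
    agg.index.name = rank
    # lineage of each aggregated taxon truncated at the rank
    keep = RANKS[: RANKS.index(rank) + 1]
    tax = table.taxonomy.groupby(labels).first()[list(keep[:-1])]
    tax[rank] = tax.index
    return FeatureTable(agg, table.sample_meta.copy(), tax, rank)


def relative_abundance(table: FeatureTable) -> pd.DataFrame:
    """Per-sample relative abundances (columns sum to 1)."""
    totals = table.counts.sum(axis=0)
    return table.counts / totals


# ---------------------------------------------------------------------------
# dissimilarity and ordination
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[Hashable, ...]
    data: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        d = self.data
        if d.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("distance matrix diagonal not zero")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("distances outside [0, 1]")


def _sample_matrix(rel: pd.DataFrame) -> tuple[np.ndarray, tuple]:
    zero = rel.columns[rel.sum(axis=0) == 0]
    if len(zero):
        raise ValueError(f"all-zero samples: {list(zero)}")
    return rel.values.T, tuple(rel.columns)


def bray_curtis(rel_table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between sample columns:
    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i)."""
    X, labels = _sample_matrix(rel_table)
    if len(labels) < 2:
        raise ValueError("need >= 2 samples")
    return DistanceMatrix(labels, squareform(pdist(X, metric="braycurtis")), "bray_curtis")


def jaccard(presence_table: pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance on presence/absence: 1 - |A & B| / |A | B|."""
    X, labels = _sample_matrix(presence_table)
    if len(labels) < 2:
        raise ValueError("need >= 2 samples")
    return DistanceMatrix(labels, squareform(pdist(X > 0, metric="jaccard")), "jaccard")


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA axes ordered by eigenvalue.

    Negative eigenvalues (possible for semi-metric dissimilarities like
    Bray-Curtis) are reported as-is and excluded from the variance
    proportions, which are computed over positive eigenvalues only.
    """

    coordinates: pd.DataFrame  # samples x axes, columns PC1..PCk (positive axes)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per positive axis, over positive sum


def pcoa(dist: DistanceMatrix) -> OrdinationResult:
    """Principal coordinates analysis (classical metric MDS).

    Eigendecomposition of the Gower-centred matrix -0.5 * J D^2 J where J is
    the centring projector. For a Euclidean input the pairwise distances of
    the returned coordinates reproduce the input exactly.
    """
    d2 = dist.data.astype(float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > max(1e-12, 1e-10 * abs(evals).max())
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    prop = evals[pos] / evals[pos].sum() if pos.any() else np.array([])
    frame = pd.DataFrame(
        coords,
        index=list(dist.labels),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, evals, prop)


# ---------------------------------------------------------------------------
# group-separation tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    test: str  # "kruskal_wallis" | "mann_whitney" | "anosim" | "permanova"
    unit: str  # taxon name or "community"
    grouping: str
    n_permutations: int | None = None
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p_value <= ALPHA


def _check_groups(groups: Sequence, min_size: int = 2) -> np.ndarray:
    groups = np.asarray(groups)
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    small = labels[counts < min_size]
    if len(small):
        raise ValueError(f"groups with fewer than {min_size} samples: {list(small)}")
    return groups


def _anosim_r(dists_condensed: np.ndarray, within_mask: np.ndarray, n: int) -> float:
    ranks = rankdata(dists_condensed)
    r_w = ranks[within_mask].mean()
    r_b = ranks[~within_mask].mean()
    return (r_b - r_w) / (n * (n - 1) / 4.0)


def anosim(
    dist: DistanceMatrix,
    groups: Sequence,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    grouping: str = "group",
) -> TestResult:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (N(N-1)/4) on
    the ranked pairwise dissimilarities; R in [-1, 1], 0 under the null. The
    p-value is the permutation tail (1 + #{perm >= obs}) / (1 + n_perm)
    under random relabelling of samples.
    """
    groups = _check_groups(groups)
    if n_perm < 99:
        logger.warning("anosim with n_perm=%d (<99) has coarse p resolution", n_perm)
    n = len(dist.labels)
    cond = squareform(dist.data, checks=False)
    i_idx, j_idx = np.triu_indices(n, k=1)

    def within(g: np.ndarray) -> np.ndarray:
        return g[i_idx] == g[j_idx]

    obs = _anosim_r(cond, within(groups), n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _anosim_r(cond, within(perm), n) >= obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(obs, p, "anosim", "community", grouping, n_perm, seed)


def _permanova_f(d2_condensed: np.ndarray, groups: np.ndarray, n: int) -> float:
    i_idx, j_idx = np.triu_indices(n, k=1)
    ss_total = d2_condensed.sum() / n
    ss_within = 0.0
    labels, counts = np.unique(groups, return_counts=True)
    for lab, cnt in zip(labels, counts):
        mask = (groups[i_idx] == lab) & (groups[j_idx] == lab)
        ss_within += d2_condensed[mask].sum() / cnt
    a = len(labels)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(
    dist: DistanceMatrix,
    groups: Sequence,
    n_perm: int = DEFAULT_PERMUTATIONS,
    seed: int = 0,
    grouping: str = "group",
) -> TestResult:
    """Permutational multivariate analysis of variance.

    pseudo-F = (SS_among / (a-1)) / (SS_within / (N-a)) computed from
    pairwise squared dissimilarities; p-value by sample relabelling as in
    :func:`anosim`.
    """
    groups = _check_groups(groups)
    if n_perm < 99:
        logger.warning("permanova with n_perm=%d (<99) has coarse p resolution", n_perm)
    n = len(dist.labels)
    d2 = squareform(dist.data, checks=False) ** 2
    obs = _permanova_f(d2, groups, n)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if _permanova_f(d2, rng.permutation(groups), n) >= obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return TestResult(obs, p, "permanova", "community", grouping, n_perm, seed)


# ---------------------------------------------------------------------------
# responsiveness screens
# ---------------------------------------------------------------------------


def kw_screen(
    table: FeatureTable,
    rank: str,
    grouping: str = "corrinoid",
    timepoints: Iterable | None = None,
    exclude_uninoculated: bool = True,
) -> pd.DataFrame:
    """Kruskal-Wallis responsiveness screen per taxon, per timepoint.

    For each taxon at ``rank`` and each timepoint, tests whether relative
    abundance differs across the levels of ``grouping`` (by default the
    corrinoid treatment) over replicates. Taxa observed in fewer than two
    groups at a timepoint are skipped and logged. Returns a tidy frame with
    columns taxon, timepoint, statistic, p_value, p_bh, significant,
    mean_rel_abundance.
    """
    agg = aggregate(table, rank)
    meta = agg.sample_meta
    if exclude_uninoculated and "inoculated" in meta:
        agg = agg.select_samples(meta["inoculated"].astype(bool))
        meta = agg.sample_meta
    rel = relative_abundance(agg)
    tps = sorted(meta["timepoint"].unique()) if timepoints is None else list(timepoints)

    rows = []
    for tp in tps:
        cols = meta.index[meta["timepoint"] == tp]
        sub_meta = meta.loc[cols]
        levels = sub_meta[grouping].unique()
        if len(levels) < 2:
            raise ValueError(f"timepoint {tp!r}: need >= 2 {grouping} groups")
        for taxon in rel.index:
            vals_by_group = [
                rel.loc[taxon, sub_meta.index[sub_meta[grouping] == lev]].values
                for lev in levels
            ]
            n_groups_present = sum(v.sum() > 0 for v in vals_by_group)
            if n_groups_present < 2:
                logger.info("kw_screen: %r at %r observed in <2 groups; skipped", taxon, tp)
                continue
            flat = np.concatenate(vals_by_group)
            if np.ptp(flat) == 0:
                h, p = 0.0, 1.0  # all values tied; no evidence of effect
            else:
                h, p = kruskal(*vals_by_group)
            rows.append(
                {
                    "taxon": taxon,
                    "rank": rank,
                    "timepoint": tp,
                    "statistic": float(h),
                    "p_value": float(p),
                    "mean_rel_abundance": float(rel.loc[taxon, cols].mean()),
                }
            )
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    out["p_bh"] = np.nan
    for tp in out["timepoint"].unique():
        m = out["timepoint"] == tp
        out.loc[m, "p_bh"] = multipletests(out.loc[m, "p_value"], method="fdr_bh")[1]
    out["significant"] = out["p_value"] <= ALPHA
    return out


def responsive_fraction_count(screen: pd.DataFrame, all_taxa: Iterable[str]) -> float:
    """Count-based responsive fraction (enrichment-style summary).

    |union over timepoints of taxa significant at any timepoint| divided by
    |all taxa observed at the rank|.
    """
    all_taxa = set(all_taxa)
    if not all_taxa:
        raise ValueError("empty taxon set")
    if screen.empty:
        return 0.0
    hits = set(screen.loc[screen["significant"], "taxon"])
    return len(hits & all_taxa) / len(all_taxa)


def responsive_fraction_abundance(screen: pd.DataFrame, timepoint) -> float:
    """Abundance-weighted responsive fraction at one timepoint
    (microcosm-style summary): the summed mean relative abundance of the
    significant taxa at that timepoint."""
    if screen.empty:
        return 0.0
    sub = screen[screen["timepoint"] == timepoint]
    return float(sub.loc[sub["significant"], "mean_rel_abundance"].sum())


def pairwise_mw(
    table: FeatureTable,
    taxon: str,
    rank: str,
    timepoint,
    treatments: Sequence[str] | None = None,
    exclude_uninoculated: bool = True,
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U for one taxon between every treatment pair.

    Uses the exact null distribution when sample sizes permit (scipy's
    default policy with tie fallback). Returns a tidy frame with one row per
    unordered pair.
    """
    agg = aggregate(table, rank)
    meta = agg.sample_meta
    if exclude_uninoculated and "inoculated" in meta:
        agg = agg.select_samples(meta["inoculated"].astype(bool))
        meta = agg.sample_meta
    rel = relative_abundance(agg)
    if taxon not in rel.index:
        raise ValueError(f"taxon {taxon!r} not present at rank {rank!r}")
    meta_tp = meta[meta["timepoint"] == timepoint]
    treatments = (
        list(treatments)
        if treatments is not None
        else sorted(meta_tp["corrinoid"].unique())
    )
    series = rel.loc[taxon]
    rows = []
    for a, b in itertools.combinations(treatments, 2):
        xa = series[meta_tp.index[meta_tp["corrinoid"] == a]].values
        xb = series[meta_tp.index[meta_tp["corrinoid"] == b]].values
        if len(xa) < 2 or len(xb) < 2:
            raise ValueError(f"treatment pair ({a}, {b}): need >= 2 replicates each")
        u, p = mannwhitneyu(xa, xb, alternative="two-sided")
        rows.append(
            {
                "treatment_a": a,
                "treatment_b": b,
                "U": float(u),
                "p_value": float(p),
                "significant": p <= ALPHA,
            }
        )
    return pd.DataFrame(rows)
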