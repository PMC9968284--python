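"""Alpha/beta-diversity statistics, ordination and PERMANOVA.

Alpha diversity is the Shannon index (natural log), Pielou's evenness J and
rarefied richness (expected taxon count at a fixed subsampling depth).  Beta
diversity uses Canberra distance by default (sensitive to rare taxa, which
dominate virome catalogues) with Bray-Curtis as the abundance-weighted
alternative.  Ordination is classical metric scaling (PCoA); group effects on
a distance matrix are tested with PERMANOVA using whole-label permutations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.special import gammaln
from scipy.stats import spearmanr

from viromeflow.io_formats import AbundanceMatrix, ValidationError

SUPPORTED_METRICS = ("canberra", "bray_curtis")

#: default ordinal encoding of condition for rank correlations; configurable.
DEFAULT_CONDITION_ENCODING = {"Control": 0, "UC": 1, "CD": 2}


# ---------------------------------------------------------------------------
# alpha diversity


def relative_abundance(counts: pd.DataFrame | AbundanceMatrix) -> pd.DataFrame:
    """Convert per-sample counts to proportions; all-zero samples are excluded."""
    if isinstance(counts, pd.DataFrame):
        counts = AbundanceMatrix(counts)
    return counts.relative_abundance()


def shannon(p: np.ndarray | Sequence[float]) -> float:
    """Shannon index in nats, -sum p ln p with 0 ln 0 taken as 0."""
    arr = np.asarray(p, dtype=float)
    nz = arr[arr > 0]
    return float(-(nz * np.log(nz)).sum())


def pielou(p: np.ndarray | Sequence[float]) -> float:
    """Pielou's evenness J = H / ln(S); NaN when observed richness is 1."""
    arr = np.asarray(p, dtype=float)
    s = int(np.count_nonzero(arr > 0))
    if s <= 1:
        return float("nan")
    return shannon(arr) / np.log(s)


def rarefied_richness(
    counts: Sequence[int] | np.ndarray,
    depth: int,
    reps: int = 100,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Mean observed richness over ``reps`` draws of ``depth`` reads without
    replacement (multivariate hypergeometric subsampling)."""
    arr = np.asarray(counts, dtype=np.int64)
    total = int(arr.sum())
    if depth > total:
        raise ValueError(f"rarefaction depth {depth} exceeds sample total {total}")
    if depth == total:
        return float(np.count_nonzero(arr))
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    nz = arr[arr > 0]
    richness = np.empty(reps)
    for i in range(reps):
        sub = rng.multivariate_hypergeometric(nz, depth)
        richness[i] = np.count_nonzero(sub)
    return float(richness.mean())


def expected_rarefied_richness(counts: Sequence[int], depth: int) -> float:
    """Closed-form hypergeometric expectation sum_i 1 - C(N-n_i, d)/C(N, d)."""
    arr = np.asarray(counts, dtype=np.int64)
    arr = arr[arr > 0]
    n_total = int(arr.sum())

    def log_choose(n: np.ndarray | int, k: int) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    out = np.where(
        n_total - arr < depth,
        1.0,
        1.0 - np.exp(log_choose(n_total - arr, depth) - log_choose(n_total, depth)),
    )
    return float(out.sum())


def alpha_table(
    counts: AbundanceMatrix,
    depth: int | None = None,
    reps: int = 100,
    seed: int | np.random.Generator | None = 0,
) -> pd.DataFrame:
    """Per-sample Shannon, Pielou and rarefied richness.

    Rarefaction depth defaults to the minimum per-sample total among samples
    with any counts.  All-zero samples are excluded (see
    :meth:`AbundanceMatrix.relative_abundance`).
    """
    rel = counts.relative_abundance()
    raw = counts.counts[rel.columns]
    totals = raw.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rows = {}
    for sample in rel.columns:
        p = rel[sample].to_numpy()
        rows[sample] = {
            "shannon": shannon(p),
            "pielou": pielou(p),
            "rarefied_richness": rarefied_richness(
                raw[sample].to_numpy(), depth, reps, rng
            ),
            "observed_richness": int(np.count_nonzero(p)),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# beta diversity


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample distances with zero diagonal."""

    ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal is not zero")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def distance_matrix(
    table: pd.DataFrame, metric: str = "canberra"
) -> DistanceMatrix:
    """Pairwise distances between samples (columns of ``table``).

    ``canberra``: sum over coordinates with x+y>0 of \\|x-y\\|/(x+y).
    ``bray_curtis``: 1 - 2*sum(min(x,y)) / (sum x + sum y).
    """
    if metric not in SUPPORTED_METRICS:
        raise ValueError(
            f"unknown metric {metric!r}; supported: {', '.join(SUPPORTED_METRICS)}"
        )
    x = table.to_numpy(dtype=float).T  # samples in rows for pdist
    if x.shape[0] < 2:
        raise ValidationError("need >= 2 samples for a distance matrix")
    scipy_name = {"canberra": "canberra", "bray_curtis": "braycurtis"}[metric]
    # for non-negative data scipy's canberra (|x-y|/(|x|+|y|), 0/0 skipped)
    # and braycurtis (sum|x-y|/sum(x+y)) coincide with the definitions above
    vals = squareform(pdist(x, metric=scipy_name))
    return DistanceMatrix(list(table.columns), vals, metric)


# ---------------------------------------------------------------------------
# ordination


@dataclass
class OrdinationResult:
    """PCoA coordinates with eigenvalues (axes ordered by descending eigenvalue).

    ``eigenvalues`` includes any negative eigenvalues of the double-centred
    matrix (reported, not corrected); ``coordinates`` carries only the axes
    with positive eigenvalues.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.proportion_explained is None:
            pos = self.eigenvalues[self.eigenvalues > 0]
            prop = np.zeros_like(self.eigenvalues)
            if pos.sum() > 0:
                prop[: len(pos)] = pos / pos.sum()
            self.proportion_explained = prop


def pcoa(d: DistanceMatrix) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Double-centres -d^2/2, eigendecomposes, and scales eigenvectors by the
    square root of their (positive) eigenvalues.
    """
    n = len(d.ids)
    if n < 3:
        raise ValidationError("need >= 3 samples for ordination")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # tiny negative round-off on conceptually-zero eigenvalues is clipped
    eigvals[np.abs(eigvals) < 1e-10 * max(1.0, abs(eigvals[0]))] = 0.0
    pos = eigvals > 0
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    frame = pd.DataFrame(
        coords,
        index=d.ids,
        columns=[f"PCo{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, eigvals)


# ---------------------------------------------------------------------------
# PERMANOVA


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    r_squared: float
    p_value: float
    n_permutations: int


def _ss_partition(
    d2: np.ndarray, codes: np.ndarray, n_groups: int
) -> tuple[float, float]:
    """(SS_total, SS_within) from squared distances and group codes."""
    n = d2.shape[0]
    iu = np.triu_indices(n, k=1)
    ss_total = d2[iu].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        if idx.size == 0:
            raise ValidationError("PERMANOVA group of size 0")
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub.sum() / 2.0 / idx.size
    return float(ss_total), float(ss_within)


def _pseudo_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total, ss_within = _ss_partition(d2, codes, n_groups)
    ss_between = ss_total - ss_within
    return (ss_between / (n_groups - 1)) / (ss_within / (n - n_groups))


def permanova(
    d: DistanceMatrix,
    groups: Sequence[str] | Mapping[str, str],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = 0,
    exact: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix with whole-label permutations.

    SS are partitioned on squared distances (SS_total = sum_{i<j} d_ij^2 / n;
    within-group analogues divided by group size).  With ``exact=True`` every
    distinct assignment of the observed label multiset is enumerated and the
    p-value is the exact fraction of assignments with F >= observed (the
    identity assignment included); otherwise p = (1 + #{F_perm >= F_obs}) /
    (1 + n_perm), which cannot be zero.
    """
    if isinstance(groups, Mapping):
        labels = [groups[s] for s in d.ids]
    else:
        labels = list(groups)
    if len(labels) != len(d.ids):
        raise ValidationError("group labels do not match distance matrix ids")
    uniq = sorted(set(labels))
    if len(uniq) < 2:
        raise ValidationError("PERMANOVA needs >= 2 groups")
    code_of = {g: i for i, g in enumerate(uniq)}
    codes = np.array([code_of[g] for g in labels])
    n_groups = len(uniq)
    n = len(labels)
    d2 = d.values**2

    f_obs = _pseudo_f(d2, codes, n_groups)
    ss_total, ss_within = _ss_partition(d2, codes, n_groups)
    r2 = (ss_total - ss_within) / ss_total if ss_total > 0 else 0.0

    if exact:
        seen: set[tuple[int, ...]] = set()
        count_ge = 0
        for perm in itertools.permutations(codes.tolist()):
            if perm in seen:
                continue
            seen.add(perm)
            f_perm = _pseudo_f(d2, np.array(perm), n_groups)
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = count_ge / len(seen)
        n_done = len(seen)
    else:
        rng = (
            seed
            if isinstance(seed, np.random.Generator)
            else np.random.default_rng(seed)
        )
        count_ge = 0
        for _ in range(n_perm):
            f_perm = _pseudo_f(d2, rng.permutation(codes), n_groups)
            if f_perm >= f_obs - 1e-12:
                count_ge += 1
        p = (1 + count_ge) / (1 + n_perm)
        n_done = n_perm

    return PermanovaResult(float(f_obs), float(r2), float(p), n_done)


# ---------------------------------------------------------------------------
# centroids and condition correlation


def centroids_and_extremes(
    ordination: OrdinationResult,
    alpha: pd.Series | Mapping[str, float],
    groups: Mapping[str, str],
    n_extreme: int = 10,
) -> pd.DataFrame:
    """Per-group centroids plus the centroids of the ``n_extreme`` highest-
    and lowest-Shannon samples, on the first two ordination axes.

    Centroids are the mean location of data points.  Ties at the boundary of
    the extreme sets are broken deterministically by sample id.
    """
    coords = ordination.coordinates.iloc[:, :2]
    if n_extreme > len(coords):
        raise ValidationError(
            f"n_extreme={n_extreme} exceeds sample count {len(coords)}"
        )
    alpha = pd.Series(alpha).reindex(coords.index)
    rows = {}
    for g in sorted(set(groups.values())):
        members = [s for s in coords.index if groups[s] == g]
        rows[f"group:{g}"] = coords.loc[members].mean(axis=0)
    ranked = sorted(coords.index, key=lambda s: (-alpha[s], s))
    rows["high_alpha"] = coords.loc[ranked[:n_extreme]].mean(axis=0)
    ranked_low = sorted(coords.index, key=lambda s: (alpha[s], s))
    rows["low_alpha"] = coords.loc[ranked_low[:n_extreme]].mean(axis=0)
    return pd.DataFrame.from_dict(rows, orient="index")


def alpha_condition_correlation(
    alpha: pd.Series | Sequence[float],
    conditions: Sequence[str],
    encoding: Mapping[str, int] | None = None,
) -> tuple[float, float]:
    """Spearman correlation between per-sample alpha diversity and condition.

    Conditions are mapped to ordinal ranks through ``encoding`` (default
    Control=0, UC=1, CD=2).  Returns (rho, p) with the t-approximation p-value;
    (nan, nan) when either input is constant.
    """
    if encoding is None:
        encoding = DEFAULT_CONDITION_ENCODING
    a = np.asarray(pd.Series(alpha).to_numpy(), dtype=float)
    c = np.array([encoding[x] for x in conditions], dtype=float)
    if np.all(a == a[0]) or np.all(c == c[0]):
        return float("nan"), float("nan")
    rho, p = spearmanr(a, c)
    return float(rho), float(p)
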