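"""Hashtag classification: CLR, k-medoids, NB background thresholds, calls.

The classification procedure, applied to every barcode with at least
``min_rna_umi`` transcriptome UMIs:

1. CLR-normalize the raw tag counts (natural log, pseudocount 1).
2. k-medoids (PAM) clustering of the normalized profiles with
   k = n_tags + 1, expecting one cluster per hashtag plus one background
   cluster.
3. Per tag: drop the cluster with the highest mean normalized value for
   that tag, drop the top 0.5% of the remaining raw counts as outliers, fit
   a negative binomial to the rest, and take the q = 0.99 quantile as the
   positivity threshold.
4. A barcode is positive for a tag iff its raw count exceeds the threshold;
   0 positives → negative, 1 → singlet, ≥2 → multiplet named by its two
   most highly expressed (CLR) positive hashtags.

Barcodes with 50–200 RNA UMIs, normally discarded as ambient RNA, can be
rescued afterwards by re-applying the frozen thresholds
(:func:`rescue_low_umi`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from scipy.spatial.distance import cdist

from .matrix import TagCountMatrix

__all__ = [
    "clr_normalize",
    "kmedoids",
    "nb_fit_mle",
    "nb_quantile",
    "fit_background",
    "classify",
    "demultiplex",
    "rescue_low_umi",
    "TagBackground",
    "BackgroundModel",
    "NEGATIVE",
    "SINGLET",
    "MULTIPLET",
]

NEGATIVE = "negative"
SINGLET = "singlet"
MULTIPLET = "multiplet"


# ---------------------------------------------------------------------------
# CLR normalization
# ---------------------------------------------------------------------------

def clr_normalize(counts, pseudocount: int = 1) -> pd.DataFrame:
    """Centered log-ratio transform of tag counts, per tag across cells.

    x'_i = ln(x_i + pc) − mean_i ln(x_i + pc), i.e. each pseudocounted
    count divided by the per-tag geometric mean and log-transformed
    (natural log). The per-tag mean of the result is 0.

    Parameters
    ----------
    counts : TagCountMatrix or DataFrame
    pseudocount : int
        Added to every count before the log; must be positive if any
        count is zero (the transform is otherwise undefined).
    """
    if isinstance(counts, TagCountMatrix):
        df = counts.to_dataframe()
    else:
        df = pd.DataFrame(counts)
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    X = df.to_numpy(dtype=float) + pseudocount
    if (X <= 0).any():
        raise ValueError(
            "zero counts with pseudocount 0: CLR is undefined (log of zero)"
        )
    L = np.log(X)
    return pd.DataFrame(L - L.mean(axis=0), index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# k-medoids (PAM) clustering
# ---------------------------------------------------------------------------

def _pam(D: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """PAM build + swap on a full distance matrix. Returns medoid indices."""
    n = D.shape[0]
    # BUILD: greedy — first medoid minimizes total distance, each next
    # medoid maximizes the decrease in cost.
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[medoids[0]].copy()
    while len(medoids) < k:
        gain = np.maximum(d_near[None, :] - D, 0.0).sum(axis=1)
        gain[medoids] = -np.inf
        h = int(np.argmax(gain))
        medoids.append(h)
        d_near = np.minimum(d_near, D[h])

    medoids = np.array(medoids)
    for _ in range(max_iter):
        Dm = D[medoids]                      # (k, n)
        order = np.argsort(Dm, axis=0)
        d1 = Dm[order[0], np.arange(n)]      # nearest medoid distance
        d2 = Dm[order[1], np.arange(n)]      # second nearest
        nearest = order[0]                   # index into medoid list
        base = d1.sum()
        best_delta, best_swap = -1e-9, None
        for mi in range(len(medoids)):
            excl = np.where(nearest == mi, d2, d1)   # cost if medoid mi removed
            tot = np.minimum(D, excl[None, :]).sum(axis=1)  # cost per candidate
            tot[medoids] = np.inf
            h = int(np.argmin(tot))
            delta = tot[h] - base
            if delta < best_delta:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]
    return medoids


def kmedoids(
    normalized,
    k: int,
    seed: int = 0,
    subsample: int = 2000,
    return_medoids: bool = False,
):
    """Seeded PAM k-medoids on Euclidean distances of normalized profiles.

    For inputs larger than ``subsample`` points, PAM runs on a seeded
    random subsample and every point is then assigned to its nearest
    medoid (CLARA-style scaling); below that size the partition is exact
    PAM (build + swap). Deterministic for identical (data, seed).

    Parameters
    ----------
    normalized : DataFrame or ndarray, shape (n, d)
    k : int
        Number of clusters; requires at least k distinct rows.

    Returns
    -------
    labels : ndarray of int, shape (n,), values in 0..k-1
        (0-based cluster indices; every point is labeled).
    """
    X = np.asarray(normalized, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n = X.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    distinct = np.unique(X, axis=0)
    if distinct.shape[0] < k:
        raise ValueError(
            f"need at least k={k} distinct rows, found {distinct.shape[0]}"
        )
    rng = np.random.default_rng(seed)
    if n > subsample:
        idx = rng.choice(n, size=subsample, replace=False)
        sub = X[idx]
        if np.unique(sub, axis=0).shape[0] < k:
            # ensure the sample carries enough distinct points
            extra = []
            have = {tuple(r) for r in sub}
            for r in distinct:
                t = tuple(r)
                if t not in have:
                    extra.append(r)
                    have.add(t)
                if len(have) >= k:
                    break
            sub = np.vstack([sub, np.array(extra)])
    else:
        sub = X
    D = cdist(sub, sub)
    med_idx = _pam(D, k)
    medoid_points = sub[med_idx]
    labels = np.argmin(cdist(X, medoid_points), axis=1)
    if return_medoids:
        return labels, medoid_points
    return labels


# ---------------------------------------------------------------------------
# Negative-binomial background fitting
# ---------------------------------------------------------------------------

def _nb_loglik(x: np.ndarray, mean: float, size: float) -> float:
    r, mu = size, mean
    return float(
        np.sum(
            special.gammaln(x + r)
            - special.gammaln(r)
            - special.gammaln(x + 1)
            + r * math.log(r / (r + mu))
            + x * np.log(mu / (r + mu))
        )
    )


def nb_fit_mle(x) -> tuple[float, float]:
    """Fit NB(mean, size) by maximum likelihood.

    For fixed size the NB mean MLE is the sample mean, so the mean is
    profiled out and the size maximized by a bounded 1-D search on log
    size, initialized by method of moments. Returns (mean, size); size is
    ``inf`` (Poisson limit) for under- or equi-dispersed data.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot fit NB to empty data")
    mu = float(x.mean())
    var = float(x.var())
    if mu == 0:
        return 0.0, np.inf
    if var <= mu:
        return mu, np.inf
    r0 = mu * mu / (var - mu)  # method of moments
    lo, hi = math.log(max(r0, 1e-3)) - 7.0, math.log(max(r0, 1e-3)) + 7.0
    res = optimize.minimize_scalar(
        lambda lr: -_nb_loglik(x, mu, math.exp(lr)),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return mu, float(math.exp(res.x))


def nb_quantile(q: float, mean: float, size: float) -> int:
    """Smallest integer c with CDF(c) >= q for NB(mean, size) / Poisson."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if mean == 0:
        return 0
    if np.isinf(size):
        dist = stats.poisson(mean)
    else:
        dist = stats.nbinom(size, size / (size + mean))
    c = int(dist.ppf(q))
    while c > 0 and dist.cdf(c - 1) >= q:
        c -= 1
    while dist.cdf(c) < q:
        c += 1
    return c


@dataclass
class TagBackground:
    """Fitted background distribution and positivity threshold for one tag."""

    tag: str
    nb_mean: float
    nb_size: float          # inf ⇒ Poisson (or point mass if degenerate)
    threshold: int          # positive iff raw count > threshold
    q: float
    n_background: int
    degenerate: bool = False


def fit_background(
    raw_counts_for_tag,
    cluster_labels,
    normalized_for_tag,
    outlier_fraction: float = 0.005,
    q: float = 0.99,
    tag: str = "",
    min_background: int = 20,
) -> TagBackground:
    """Fit one tag's negative-binomial background and threshold.

    Cells in the cluster with the highest mean normalized value for this
    tag (its positive population) are excluded; of the remainder, the top
    ``outlier_fraction`` by raw count are excluded; a negative binomial is
    fitted to the remaining raw counts by ML and the threshold is the
    smallest integer count whose NB CDF reaches ``q``.

    Degenerate inputs: exactly constant background counts are a point mass
    (threshold = that constant, with a warning); under-dispersed counts
    fall back to a Poisson fit (size → ∞, with a warning).
    """
    if not 0 <= outlier_fraction <= 0.05:
        raise ValueError("outlier_fraction must be in [0, 0.05]")
    if not 0.5 < q < 1:
        raise ValueError("q must be in (0.5, 1)")
    x = np.asarray(raw_counts_for_tag)
    labels = np.asarray(cluster_labels)
    norm = np.asarray(normalized_for_tag, dtype=float)
    if not (len(x) == len(labels) == len(norm)):
        raise ValueError("counts, labels and normalized values must align")

    # positive cluster: highest mean normalized value; ties → lowest index
    uniq = np.unique(labels)
    means = np.array([norm[labels == c].mean() for c in uniq])
    top = uniq[int(np.argmax(means))]
    bg = x[labels != top]

    n_out = int(math.floor(len(bg) * outlier_fraction))
    if n_out > 0:
        bg = np.sort(bg)[: len(bg) - n_out]
    if len(bg) < min_background:
        raise ValueError(
            f"only {len(bg)} background cells for tag {tag!r} after "
            f"exclusions (need >= {min_background}); fit would be unstable"
        )

    if bg.var() == 0:
        warnings.warn(
            f"tag {tag!r}: constant background ({bg[0]}); treating as a "
            "point mass",
            UserWarning,
            stacklevel=2,
        )
        c = int(bg[0])
        return TagBackground(tag, float(c), np.inf, c, q, len(bg), degenerate=True)

    mean, size = nb_fit_mle(bg)
    if np.isinf(size):
        warnings.warn(
            f"tag {tag!r}: background not overdispersed; Poisson fallback",
            UserWarning,
            stacklevel=2,
        )
    return TagBackground(tag, mean, size, nb_quantile(q, mean, size), q, len(bg))


@dataclass
class BackgroundModel:
    """Per-tag fitted backgrounds plus the frozen CLR transform.

    ``clr_log_means`` holds the per-tag mean of ln(count + pseudocount)
    over the cells used for fitting, so the identical normalization can be
    re-applied to held-out (low-UMI) barcodes during rescue.
    """

    tags: list
    entries: list            # list[TagBackground], aligned with tags
    pseudocount: int
    clr_log_means: list      # per-tag, natural-log scale
    q: float

    @property
    def thresholds(self) -> np.ndarray:
        return np.array([e.threshold for e in self.entries])

    def normalize(self, counts) -> pd.DataFrame:
        """Apply the frozen CLR transform to a (new) count matrix."""
        if isinstance(counts, TagCountMatrix):
            df = counts.to_dataframe()
        else:
            df = pd.DataFrame(counts)
        if list(df.columns) != list(self.tags):
            raise ValueError("count matrix tags do not match fitted model")
        L = np.log(df.to_numpy(dtype=float) + self.pseudocount)
        return pd.DataFrame(
            L - np.asarray(self.clr_log_means)[None, :],
            index=df.index,
            columns=df.columns,
        )

    def to_dict(self) -> dict:
        return {
            "q": self.q,
            "pseudocount": self.pseudocount,
            "clr_log_means": [float(v) for v in self.clr_log_means],
            "tags": {
                e.tag: {
                    "nb_mean": e.nb_mean,
                    "nb_size": None if np.isinf(e.nb_size) else e.nb_size,
                    "threshold": int(e.threshold),
                    "q": e.q,
                    "n_background": int(e.n_background),
                    "degenerate": bool(e.degenerate),
                }
                for e in self.entries
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundModel":
        entries = [
            TagBackground(
                tag=t,
                nb_mean=v["nb_mean"],
                nb_size=np.inf if v["nb_size"] is None else v["nb_size"],
                threshold=v["threshold"],
                q=v["q"],
                n_background=v["n_background"],
                degenerate=v.get("degenerate", False),
            )
            for t, v in d["tags"].items()
        ]
        return cls(
            tags=list(d["tags"].keys()),
            entries=entries,
            pseudocount=d["pseudocount"],
            clr_log_means=list(d["clr_log_means"]),
            q=d["q"],
        )


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------

def classify(
    counts,
    model: BackgroundModel,
    normalized: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Call each barcode singlet / multiplet / negative.

    A tag is positive iff its raw count strictly exceeds the tag's
    threshold. Singlets take the positive tag's name as ``hash_id``;
    multiplets are named by their two most highly expressed positive tags
    (by normalized value, descending), joined "A+B"; negatives get
    "negative".
    """
    if isinstance(counts, TagCountMatrix):
        df = counts.to_dataframe()
    else:
        df = pd.DataFrame(counts)
    if list(df.columns) != list(model.tags):
        raise ValueError("count matrix tags do not match fitted model")
    if normalized is None:
        normalized = model.normalize(df)
    X = df.to_numpy()
    N = normalized.to_numpy()
    pos = X > model.thresholds[None, :]
    n_pos = pos.sum(axis=1)
    tags = np.asarray(model.tags, dtype=object)

    global_class = np.full(len(df), NEGATIVE, dtype=object)
    global_class[n_pos == 1] = SINGLET
    global_class[n_pos >= 2] = MULTIPLET

    hash_id = np.full(len(df), NEGATIVE, dtype=object)
    single_rows = np.where(n_pos == 1)[0]
    if len(single_rows):
        hash_id[single_rows] = tags[np.argmax(pos[single_rows], axis=1)]
    for i in np.where(n_pos >= 2)[0]:
        idx = np.where(pos[i])[0]
        # stable sort on -normalized → ties broken by tag order
        order = idx[np.argsort(-N[i, idx], kind="stable")][:2]
        hash_id[i] = f"{tags[order[0]]}+{tags[order[1]]}"

    return pd.DataFrame(
        {
            "global_class": global_class,
            "hash_id": hash_id,
            "n_positive_tags": n_pos,
        },
        index=df.index,
    )


def demultiplex(
    counts,
    rna_umi: pd.Series | None = None,
    k: int | None = None,
    q: float = 0.99,
    outlier_fraction: float = 0.005,
    min_rna_umi: int = 200,
    pseudocount: int = 1,
    seed: int = 0,
    kmedoids_subsample: int = 2000,
) -> tuple[pd.DataFrame, BackgroundModel, dict]:
    """Full hashtag demultiplexing pipeline.

    CLR-normalize → k-medoids (k = n_tags + 1 by default) → per-tag NB
    background fit → threshold and classify. If ``rna_umi`` totals are
    supplied, barcodes below ``min_rna_umi`` are excluded from both
    fitting and classification (held out for :func:`rescue_low_umi`).

    Returns
    -------
    classification : DataFrame indexed by barcode
        Columns ``global_class``, ``hash_id``, ``n_positive_tags``.
    model : BackgroundModel
    diagnostics : dict
        Per-class counts, per-tag thresholds, cluster sizes, parameters.
    """
    if isinstance(counts, TagCountMatrix):
        df = counts.to_dataframe()
    else:
        df = pd.DataFrame(counts)

    if rna_umi is not None:
        rna_umi = pd.Series(rna_umi)
        missing = df.index.difference(rna_umi.index)
        if len(missing):
            raise ValueError(
                f"rna_umi missing {len(missing)} barcodes, e.g. {missing[0]!r}"
            )
        eligible = df.index[rna_umi.reindex(df.index) >= min_rna_umi]
        df = df.loc[eligible]
    if k is None:
        k = df.shape[1] + 1

    normalized = clr_normalize(df, pseudocount)
    labels = kmedoids(normalized, k=k, seed=seed, subsample=kmedoids_subsample)

    X = df.to_numpy()
    entries = []
    for j, tag in enumerate(df.columns):
        entries.append(
            fit_background(
                X[:, j],
                labels,
                normalized.iloc[:, j].to_numpy(),
                outlier_fraction=outlier_fraction,
                q=q,
                tag=str(tag),
            )
        )
    log_means = np.log(X.astype(float) + pseudocount).mean(axis=0)
    model = BackgroundModel(
        tags=list(df.columns),
        entries=entries,
        pseudocount=pseudocount,
        clr_log_means=list(log_means),
        q=q,
    )
    classification = classify(df, model, normalized)
    counts_by_class = classification["global_class"].value_counts().to_dict()
    diagnostics = {
        "n_barcodes_classified": int(len(df)),
        "counts_by_class": {c: int(counts_by_class.get(c, 0)) for c in (SINGLET, MULTIPLET, NEGATIVE)},
        "thresholds": {str(t): int(e.threshold) for t, e in zip(df.columns, entries)},
        "cluster_sizes": np.bincount(labels, minlength=k).tolist(),
        "params": {
            "k": k,
            "q": q,
            "outlier_fraction": outlier_fraction,
            "min_rna_umi": min_rna_umi if rna_umi is not None else None,
            "pseudocount": pseudocount,
            "seed": seed,
        },
    }
    return classification, model, diagnostics


def rescue_low_umi(
    counts,
    model: BackgroundModel,
    rna_umi: pd.Series | None = None,
    low: int = 50,
    high: int = 200,
) -> pd.DataFrame:
    """Re-classify low-RNA-content barcodes with frozen thresholds.

    Ambient-RNA droplets and true low-content cells are indistinguishable
    on RNA UMIs alone; applying the previously fitted hashtag thresholds
    to barcodes with RNA UMIs in [low, high) recovers additional singlets
    whose hashtag signal is unambiguous. If ``rna_umi`` is None the given
    matrix is classified as-is (no window filtering). An empty window
    yields an empty classification.
    """
    if isinstance(counts, TagCountMatrix):
        df = counts.to_dataframe()
    else:
        df = pd.DataFrame(counts)
    if rna_umi is not None:
        rna_umi = pd.Series(rna_umi).reindex(df.index)
        sel = (rna_umi >= low) & (rna_umi < high)
        df = df.loc[sel.fillna(False)]
    if len(df) == 0:
        return pd.DataFrame(
            columns=["global_class", "hash_id", "n_positive_tags"]
        )
    return classify(df, model)
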