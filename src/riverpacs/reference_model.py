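"""RIVPACS-style predictive reference model.

The model follows the classic predictive-bioassessment recipe: reference
sites are clustered into biological groups on their presence/absence
community composition (Sorensen dissimilarity, average linkage), linear
discriminant models predict group membership from environmental predictors,
and per-group taxon frequencies supply the weights from which capture
probabilities are later derived.  A site whose environment lies outside the
experience of the model is detected by a chi-square test on the nearest-group
Mahalanobis distance, voted over the best few discriminant models.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2
from sklearn.metrics import silhouette_score

__all__ = [
    "BiologicalGroups",
    "DiscriminantModel",
    "PredictiveModel",
    "cluster_reference_sites",
    "choose_k_by_silhouette",
    "compute_group_frequencies",
    "fit_discriminant_model",
    "select_best_models",
    "test_outlier",
    "site_in_model_range",
]


class FitError(RuntimeError):
    """A discriminant model could not be fitted."""


@dataclass(frozen=True)
class BiologicalGroups:
    """Partition of reference sites into k biological groups (1..k)."""

    k: int
    assignment: pd.Series  # site_id -> group index in 1..k

    def __post_init__(self) -> None:
        counts = self.assignment.value_counts()
        if len(counts) != self.k or counts.min() < 1:
            raise ValueError("every group must be nonempty")

    def sites_in(self, g: int) -> pd.Index:
        return self.assignment.index[self.assignment == g]


def cluster_reference_sites(
    occurrence: pd.DataFrame, k: int, min_group_size: int = 1
) -> BiologicalGroups:
    """Cluster sites on community composition into ``k`` biological groups.

    Uses Sorensen dissimilarity (Bray-Curtis on presence/absence) with
    average-linkage (UPGMA) hierarchical clustering, the classic RIVPACS
    classification step.  Deterministic; invariant to site order up to group
    relabelling.

    Average linkage readily splits off tiny clusters of atypical sites,
    which cannot support a discriminant model.  With ``min_group_size`` > 1
    every cluster smaller than that is absorbed into the large group with
    the smallest mean dissimilarity to its sites, so the returned partition
    may have fewer than ``k`` groups.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(occurrence):
        raise ValueError("k cannot exceed the number of sites")
    if occurrence.index.duplicated().any():
        raise ValueError("duplicate site ids")
    mat = occurrence.to_numpy(dtype=float)
    if (mat.sum(axis=1) == 0).any():
        empty = occurrence.index[mat.sum(axis=1) == 0].tolist()
        raise ValueError(f"sites with empty taxa sets (dissimilarity undefined): {empty}")
    d = pdist(mat, metric="braycurtis")
    tree = linkage(d, method="average")
    labels = fcluster(tree, t=k, criterion="maxclust")

    if min_group_size > 1:
        dm = squareform(d)
        while True:
            sizes = pd.Series(labels).value_counts()
            small = sizes[sizes < min_group_size]
            big = sizes[sizes >= min_group_size]
            if small.empty or big.empty:
                break
            # absorb the smallest offending cluster into its closest big group
            g_small = small.index[np.lexsort((small.index, small.to_numpy()))][0]
            members = np.flatnonzero(labels == g_small)
            mean_d = {
                g_big: dm[np.ix_(members, np.flatnonzero(labels == g_big))].mean()
                for g_big in big.index
            }
            target = min(sorted(mean_d), key=lambda g: (mean_d[g], g))
            labels[members] = target
        # relabel 1..k' preserving order of first appearance of sorted labels
        remap = {old: new for new, old in enumerate(sorted(set(labels)), start=1)}
        labels = np.array([remap[v] for v in labels])

    return BiologicalGroups(k=int(labels.max()), assignment=pd.Series(labels, index=occurrence.index))


def choose_k_by_silhouette(occurrence: pd.DataFrame, k_range=range(2, 13)) -> int:
    """Pick the number of biological groups by maximal silhouette width."""
    mat = occurrence.to_numpy(dtype=float)
    d = squareform(pdist(mat, metric="braycurtis"))
    best_k, best_s = None, -np.inf
    for k in k_range:
        if k >= len(occurrence):
            break
        labels = cluster_reference_sites(occurrence, k).assignment.to_numpy()
        if len(np.unique(labels)) < 2:
            continue
        s = silhouette_score(d, labels, metric="precomputed")
        if s > best_s:
            best_k, best_s = k, s
    if best_k is None:
        raise ValueError("no valid k in range")
    return best_k


def compute_group_frequencies(occurrence: pd.DataFrame, groups: BiologicalGroups) -> pd.DataFrame:
    """Fraction of group-g reference sites containing each taxon.

    Returns a groups x taxa DataFrame with values in [0, 1], invariant to
    site ordering.
    """
    missing = occurrence.index.difference(groups.assignment.index)
    if len(missing):
        raise ValueError(f"sites without group assignment: {list(missing)}")
    freq = occurrence.groupby(groups.assignment.loc[occurrence.index]).mean()
    freq.index.name = "group"
    return freq.sort_index()


@dataclass
class DiscriminantModel:
    """Linear discriminant model of group membership on environment.

    Predictors are standardized internally (z-scores over the training
    sites); ``group_means`` and ``pooled_covariance`` live on that
    standardized scale.  Priors are proportional to group sizes and
    ``cv_accuracy`` is leave-one-out classification accuracy.
    """

    predictor_subset: list[str]
    group_means: np.ndarray  # (k, d), standardized scale
    pooled_covariance: np.ndarray  # (d, d)
    priors: np.ndarray  # (k,)
    cv_accuracy: float
    scale_mean: np.ndarray = field(repr=False, default=None)
    scale_sd: np.ndarray = field(repr=False, default=None)
    _cov_inv: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if abs(self.priors.sum() - 1.0) > 1e-9:
            raise ValueError("priors must sum to 1")
        if not 0.0 <= self.cv_accuracy <= 1.0:
            raise ValueError("cv_accuracy must lie in [0, 1]")
        if self._cov_inv is None:
            self._cov_inv = np.linalg.inv(self.pooled_covariance)

    # -- geometry ----------------------------------------------------------
    def _standardize(self, env: pd.DataFrame) -> np.ndarray:
        missing = [p for p in self.predictor_subset if p not in env.columns]
        if missing:
            raise KeyError(f"missing predictors: {missing}")
        x = env[self.predictor_subset].to_numpy(dtype=float)
        return (x - self.scale_mean) / self.scale_sd

    def mahalanobis_sq(self, env: pd.DataFrame) -> np.ndarray:
        """Squared Mahalanobis distance of each row to each group mean (n, k)."""
        z = self._standardize(env)
        diff = z[:, None, :] - self.group_means[None, :, :]  # (n, k, d)
        return np.einsum("nkd,de,nke->nk", diff, self._cov_inv, diff)

    def posterior(self, env: pd.DataFrame) -> np.ndarray:
        """LDA posterior membership probabilities, rows summing to 1."""
        d2 = self.mahalanobis_sq(env)
        logp = np.log(self.priors)[None, :] - 0.5 * d2
        logp -= logp.max(axis=1, keepdims=True)
        w = np.exp(logp)
        return w / w.sum(axis=1, keepdims=True)

    def is_outlier(self, env: pd.DataFrame, alpha: float) -> np.ndarray:
        """Nearest-group distance test: outside the model's environmental range?

        True where the minimum squared Mahalanobis distance strictly exceeds
        the chi-square quantile at 1 - alpha with df = number of predictors.
        """
        d2min = self.mahalanobis_sq(env).min(axis=1)
        return d2min > chi2.ppf(1.0 - alpha, df=len(self.predictor_subset))


def _pooled_lda(x: np.ndarray, g: np.ndarray, k: int, ridge: float = 1e-8):
    """Group means, pooled within-group covariance (ridge-floored), priors."""
    n, d = x.shape
    means = np.vstack([x[g == j].mean(axis=0) for j in range(k)])
    scatter = np.zeros((d, d))
    for j in range(k):
        r = x[g == j] - means[j]
        scatter += r.T @ r
    cov = scatter / max(n - k, 1)
    cov = cov + np.eye(d) * (ridge * np.trace(cov) / d + 1e-12)
    priors = np.array([(g == j).sum() for j in range(k)], dtype=float) / n
    return means, cov, priors


def _classify(x, means, cov, priors):
    inv = np.linalg.inv(cov)
    diff = x[:, None, :] - means[None, :, :]
    d2 = np.einsum("nkd,de,nke->nk", diff, inv, diff)
    return np.argmax(np.log(priors)[None, :] - 0.5 * d2, axis=1)


def fit_discriminant_model(
    env_table: pd.DataFrame,
    groups: BiologicalGroups,
    predictor_subset: list[str],
    ridge: float = 1e-8,
) -> DiscriminantModel:
    """Fit a linear discriminant model on a subset of predictors.

    Predictors are z-scored; the pooled within-group covariance receives a
    small ridge floor (``ridge * trace/d`` on the diagonal) to keep it
    positive definite.  Leave-one-out accuracy refits the model without each
    site in turn.  Constant predictors raise :class:`FitError` by name.
    """
    missing = [p for p in predictor_subset if p not in env_table.columns]
    if missing:
        raise KeyError(f"predictors not in table: {missing}")
    x_raw = env_table[predictor_subset].to_numpy(dtype=float)
    sd = x_raw.std(axis=0, ddof=0)
    constant = [p for p, s in zip(predictor_subset, sd) if s == 0]
    if constant:
        raise FitError(f"constant predictors make the fit singular: {constant}")
    mean = x_raw.mean(axis=0)
    x = (x_raw - mean) / sd

    g = groups.assignment.loc[env_table.index].to_numpy() - 1
    k = groups.k
    n = len(env_table)
    counts = np.bincount(g, minlength=k)
    if (counts <= len(predictor_subset)).any():
        raise FitError("each group needs more sites than predictors")

    means, cov, priors = _pooled_lda(x, g, k, ridge)

    # Leave-one-out accuracy (refit without the held-out site).
    hits = 0
    idx = np.arange(n)
    for i in range(n):
        keep = idx != i
        gi = g[keep]
        if len(np.unique(gi)) < k or (np.bincount(gi, minlength=k) == 0).any():
            continue  # degenerate fold: removing i empties a group
        m_i, c_i, p_i = _pooled_lda(x[keep], gi, k, ridge)
        if _classify(x[i : i + 1], m_i, c_i, p_i)[0] == g[i]:
            hits += 1
    cv_accuracy = hits / n

    return DiscriminantModel(
        predictor_subset=list(predictor_subset),
        group_means=means,
        pooled_covariance=cov,
        priors=priors,
        cv_accuracy=cv_accuracy,
        scale_mean=mean,
        scale_sd=sd,
    )


def select_best_models(
    env_table: pd.DataFrame,
    groups: BiologicalGroups,
    n_models: int = 5,
    candidate_subsets: list[list[str]] | None = None,
    predictors: list[str] | None = None,
    max_subset_size: int = 6,
) -> list[DiscriminantModel]:
    """Fit candidate predictor subsets and keep the ``n_models`` best.

    Candidates default to all non-empty subsets of ``predictors`` up to
    ``max_subset_size``.  Ranking is by leave-one-out accuracy (descending),
    ties broken by fewer predictors, then by the candidate's position in the
    candidate list (a deterministic, input-order rule).
    """
    if candidate_subsets is None:
        if predictors is None:
            raise ValueError("give either candidate_subsets or predictors")
        candidate_subsets = [
            list(c)
            for r in range(1, min(max_subset_size, len(predictors)) + 1)
            for c in itertools.combinations(predictors, r)
        ]
    if not candidate_subsets:
        raise ValueError("candidate_subsets must be nonempty")
    if n_models > len(candidate_subsets):
        raise ValueError("n_models exceeds the number of candidates")

    fitted: list[tuple[float, int, int, DiscriminantModel]] = []
    for pos, subset in enumerate(candidate_subsets):
        try:
            m = fit_discriminant_model(env_table, groups, subset)
        except FitError:
            continue
        fitted.append((-m.cv_accuracy, len(subset), pos, m))
    if not fitted:
        raise FitError("no candidate predictor subset could be fitted")
    fitted.sort(key=lambda t: t[:3])
    return [m for *_, m in fitted[:n_models]]


def test_outlier(env: pd.DataFrame, model: DiscriminantModel, alpha: float = 0.01) -> np.ndarray:
    """Environmental-range test for one discriminant model (see is_outlier)."""
    return model.is_outlier(env, alpha)


@dataclass
class PredictiveModel:
    """Complete predictive model: groups, ranked DF models, frequencies, rules."""

    groups: BiologicalGroups
    models: list[DiscriminantModel]
    frequencies: pd.DataFrame  # groups x taxa
    outlier_alpha: float = 0.01
    outlier_vote_threshold: int = 3

    def __post_init__(self) -> None:
        accs = [m.cv_accuracy for m in self.models]
        if any(a < b for a, b in zip(accs, accs[1:])):
            raise ValueError("models must be sorted by cv_accuracy descending")
        if not 1 <= self.outlier_vote_threshold <= len(self.models):
            raise ValueError("outlier_vote_threshold must lie in [1, #models]")
        if ((self.frequencies < 0) | (self.frequencies > 1)).any().any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def taxa(self) -> list[str]:
        return list(self.frequencies.columns)

    def out_of_range(self, env: pd.DataFrame) -> np.ndarray:
        """Vote the per-model outlier flags: out of range iff >= threshold."""
        votes = np.zeros(len(env), dtype=int)
        for m in self.models:
            votes += m.is_outlier(env, self.outlier_alpha).astype(int)
        return votes >= self.outlier_vote_threshold

    # -- JSON round trip ---------------------------------------------------
    def to_json(self) -> str:
        doc = {
            "groups": {
                "k": self.groups.k,
                "assignment": {s: int(g) for s, g in self.groups.assignment.items()},
            },
            "models": [
                {
                    "predictor_subset": m.predictor_subset,
                    "group_means": m.group_means.tolist(),
                    "pooled_covariance": m.pooled_covariance.tolist(),
                    "priors": m.priors.tolist(),
                    "cv_accuracy": m.cv_accuracy,
                    "scale_mean": m.scale_mean.tolist(),
                    "scale_sd": m.scale_sd.tolist(),
                }
                for m in self.models
            ],
            "frequencies": {
                "taxa": list(self.frequencies.columns),
                "groups": [int(g) for g in self.frequencies.index],
                "values": self.frequencies.to_numpy().tolist(),
            },
            "outlier_alpha": self.outlier_alpha,
            "outlier_vote_threshold": self.outlier_vote_threshold,
        }
        return json.dumps(doc, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PredictiveModel":
        doc = json.loads(text)
        groups = BiologicalGroups(
            k=doc["groups"]["k"],
            assignment=pd.Series(doc["groups"]["assignment"], name="group"),
        )
        models = [
            DiscriminantModel(
                predictor_subset=m["predictor_subset"],
                group_means=np.array(m["group_means"]),
                pooled_covariance=np.array(m["pooled_covariance"]),
                priors=np.array(m["priors"]),
                cv_accuracy=m["cv_accuracy"],
                scale_mean=np.array(m["scale_mean"]),
                scale_sd=np.array(m["scale_sd"]),
            )
            for m in doc["models"]
        ]
        freq = pd.DataFrame(
            doc["frequencies"]["values"],
            index=pd.Index(doc["frequencies"]["groups"], name="group"),
            columns=doc["frequencies"]["taxa"],
        )
        return cls(
            groups=groups,
            models=models,
            frequencies=freq,
            outlier_alpha=doc["outlier_alpha"],
            outlier_vote_threshold=doc["outlier_vote_threshold"],
        )


def site_in_model_range(env: pd.DataFrame, pm: PredictiveModel) -> np.ndarray:
    """Convenience inverse of the vote: True where the site is usable."""
    return ~pm.out_of_range(env)
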