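"""PCA + Gaussian-mixture clustering of quintile profiles, with role labels.

The 5-quintile proportion vectors of all genes, pooled across the synonymous,
missense and combined-pLoF classes, are reduced by PCA (4 components retained
— the 5-simplex has 4 degrees of freedom) and clustered with a 7-component
full-covariance Gaussian mixture.  Seven components leave room for several
distinct non-uniform patterns plus a component that captures the all-zero
"no variants" vector.

Each mixture component is given a biological role from its back-projected
centroid (inverse PCA transform of the component mean, clipped to [0, 1]):

* ``empty``       — centroid mass sums below 0.5: the no-variants component;
* ``non_uniform`` — some quintile holds < 0.05 of the centroid mass: at least
  one fifth of the CDS is (almost) devoid of variants;
* ``uniform``     — otherwise.

Auxiliary profile sets (pLoF SNVs, possible pLoFs, simulations, clinical
variants, MANE Plus Clinical transcripts) are projected through the fitted
model unchanged; the model is never refitted on them.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture
from sklearn.mixture._gaussian_mixture import _compute_precision_cholesky
from sklearn.utils.validation import check_is_fitted

from ._exceptions import ConfigurationError, ValidationError

ROLES = ("uniform", "non_uniform", "empty")


def label_roles(
    centroids: np.ndarray,
    empty_mass_threshold: float = 0.5,
    depleted_quintile_threshold: float = 0.05,
) -> list[str]:
    """Assign a role to each back-projected cluster centroid.

    ``centroids`` is a (k, 5) array of proportions already clipped to [0, 1].
    """
    centroids = np.asarray(centroids, dtype=float)
    roles = []
    for row in centroids:
        if row.sum() < empty_mass_threshold:
            roles.append("empty")
        elif row.min() < depleted_quintile_threshold:
            roles.append("non_uniform")
        else:
            roles.append("uniform")
    return roles


class PositionClusterer(ClusterMixin, BaseEstimator):
    """Cluster 5-quintile variant-proportion profiles into positional roles.

    Parameters
    ----------
    n_clusters : int, default 7
        Gaussian-mixture components.  The default allows three roughly
        uniform clusters, three distinct non-uniform patterns and one
        no-variants cluster, mirroring what emerges on population exome data.
    n_pca_components : int, default 4
        PCA components retained before mixture fitting.
    n_init : int, default 10
        Mixture restarts; the best by log-likelihood is kept.
    reg_covar : float, default 1e-6
        Diagonal regularisation of the full covariance matrices.
    empty_mass_threshold, depleted_quintile_threshold : float
        Role-labelling cut-offs (see :func:`label_roles`).
    random_state : int or None
        Seed; a fixed seed makes fitting fully deterministic.

    Attributes
    ----------
    pca_ : fitted :class:`~sklearn.decomposition.PCA`
    gmm_ : fitted :class:`~sklearn.mixture.GaussianMixture`
    centroids_ : (k, 5) back-projected component means, clipped to [0, 1]
    roles_ : list of str, role per component
    labels_ : component index per training profile
    """

    def __init__(
        self,
        n_clusters: int = 7,
        n_pca_components: int = 4,
        n_init: int = 10,
        reg_covar: float = 1e-6,
        covariance_type: str = "full",
        empty_mass_threshold: float = 0.5,
        depleted_quintile_threshold: float = 0.05,
        random_state: int | None = None,
    ) -> None:
        self.n_clusters = n_clusters
        self.n_pca_components = n_pca_components
        self.n_init = n_init
        self.reg_covar = reg_covar
        self.covariance_type = covariance_type
        self.empty_mass_threshold = empty_mass_threshold
        self.depleted_quintile_threshold = depleted_quintile_threshold
        self.random_state = random_state

    @staticmethod
    def _validate_profiles(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 5:
            raise ValidationError("profiles must form an (n, 5) array")
        if np.any(X < 0):
            raise ValidationError("profile proportions must be non-negative")
        sums = X.sum(axis=1)
        ok = np.isclose(sums, 1.0, atol=1e-6) | np.isclose(sums, 0.0, atol=1e-9)
        if not np.all(ok):
            raise ValidationError(
                "profile rows must sum to 1 (observed) or 0 (no variants)"
            )
        return X

    def fit(self, X, y=None) -> "PositionClusterer":
        X = self._validate_profiles(X)
        n_distinct = len(np.unique(X, axis=0))
        if n_distinct < self.n_clusters:
            raise ConfigurationError(
                f"only {n_distinct} distinct profiles for {self.n_clusters} mixture "
                f"components; reduce n_clusters to at most {n_distinct}"
            )
        zero_mask = X.sum(axis=1) == 0
        # Observed proportion vectors live on the 4-dof simplex, but the
        # all-zero no-variants encoding adds a fifth direction (total mass);
        # keep it so the zero vector back-projects to itself and the empty
        # cluster is labellable from its centroid.
        n_comp = 5 if zero_mask.any() else self.n_pca_components
        self.pca_ = PCA(n_components=n_comp).fit(X)
        Z = self.pca_.transform(X)
        if (
            self.covariance_type == "full"
            and zero_mask.any()
            and (~zero_mask).sum() >= self.n_clusters - 1
        ):
            # The no-variants profiles are one exactly repeated point; start
            # one component degenerate on it (tight covariance) so EM locks
            # there — its likelihood contribution dominates and the first
            # E-step gives other points essentially zero responsibility.
            # The remaining components start from k-means on observed
            # profiles with their per-cluster empirical covariances.
            from sklearn.cluster import KMeans

            Zn = Z[~zero_mask]
            km = KMeans(
                n_clusters=self.n_clusters - 1,
                n_init=self.n_init,
                random_state=self.random_state,
            ).fit(Zn)
            d = Z.shape[1]
            means_init = np.vstack([Z[zero_mask][0], km.cluster_centers_])
            precisions = [np.eye(d) / max(self.reg_covar, 1e-9)]
            weights = [zero_mask.mean()]
            for c in range(self.n_clusters - 1):
                pts = Zn[km.labels_ == c]
                cov = np.cov(pts.T) if len(pts) > d else np.eye(d)
                cov = np.atleast_2d(cov) + self.reg_covar * np.eye(d)
                precisions.append(np.linalg.inv(cov))
                weights.append((1 - zero_mask.mean()) * len(pts) / len(Zn))
            self.gmm_ = GaussianMixture(
                n_components=self.n_clusters,
                covariance_type="full",
                reg_covar=self.reg_covar,
                weights_init=np.asarray(weights),
                means_init=means_init,
                precisions_init=np.stack(precisions),
                n_init=1,
                random_state=self.random_state,
            ).fit(Z)
        else:
            self.gmm_ = GaussianMixture(
                n_components=self.n_clusters,
                covariance_type=self.covariance_type,
                reg_covar=self.reg_covar,
                n_init=self.n_init,
                random_state=self.random_state,
            ).fit(Z)
        self.centroids_ = np.clip(self.pca_.inverse_transform(self.gmm_.means_), 0, 1)
        self.roles_ = label_roles(
            self.centroids_,
            self.empty_mass_threshold,
            self.depleted_quintile_threshold,
        )
        self.labels_ = self.gmm_.predict(Z)
        return self

    def predict(self, X) -> np.ndarray:
        """Most likely mixture component per profile."""
        check_is_fitted(self, "gmm_")
        X = self._validate_profiles(X)
        return self.gmm_.predict(self.pca_.transform(X))

    def predict_proba(self, X) -> np.ndarray:
        """Posterior responsibilities, one row per profile (rows sum to 1)."""
        check_is_fitted(self, "gmm_")
        X = self._validate_profiles(X)
        return self.gmm_.predict_proba(self.pca_.transform(X))

    def predict_roles(self, X) -> np.ndarray:
        """Role of the most likely component per profile."""
        roles = np.asarray(self.roles_, dtype=object)
        return roles[self.predict(X)]

    # --- serialisation -------------------------------------------------

    def to_json(self) -> dict:
        """Serialise the fitted model to a JSON-compatible document."""
        check_is_fitted(self, "gmm_")
        return {
            "params": self.get_params(),
            "pca": {
                "mean": self.pca_.mean_.tolist(),
                "components": self.pca_.components_.tolist(),
                "explained_variance": self.pca_.explained_variance_.tolist(),
                "shape": list(self.pca_.components_.shape),
            },
            "gmm": {
                "weights": self.gmm_.weights_.tolist(),
                "means": self.gmm_.means_.tolist(),
                "covariances": self.gmm_.covariances_.tolist(),
                "covariance_type": self.gmm_.covariance_type,
                "shape": list(np.asarray(self.gmm_.covariances_).shape),
            },
            "centroids": self.centroids_.tolist(),
            "roles": list(self.roles_),
        }

    @classmethod
    def from_json(cls, doc: Mapping) -> "PositionClusterer":
        """Reconstruct a fitted model from :meth:`to_json` output."""
        est = cls(**doc["params"])
        components = np.asarray(doc["pca"]["components"], dtype=float)
        pca = PCA(n_components=components.shape[0])
        pca.mean_ = np.asarray(doc["pca"]["mean"], dtype=float)
        pca.components_ = components
        pca.n_components_ = components.shape[0]
        pca.explained_variance_ = np.asarray(
            doc["pca"]["explained_variance"], dtype=float
        )
        est.pca_ = pca
        gmm = GaussianMixture(
            n_components=est.n_clusters,
            covariance_type=doc["gmm"]["covariance_type"],
            reg_covar=est.reg_covar,
        )
        gmm.weights_ = np.asarray(doc["gmm"]["weights"], dtype=float)
        gmm.means_ = np.asarray(doc["gmm"]["means"], dtype=float)
        gmm.covariances_ = np.asarray(doc["gmm"]["covariances"], dtype=float)
        gmm.precisions_cholesky_ = _compute_precision_cholesky(
            gmm.covariances_, gmm.covariance_type
        )
        est.gmm_ = gmm
        est.centroids_ = np.asarray(doc["centroids"], dtype=float)
        est.roles_ = list(doc["roles"])
        return est

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "PositionClusterer":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_clusterer(
    profiles: pd.DataFrame,
    n_clusters: int = 7,
    random_state: int | None = None,
    **kwargs,
) -> PositionClusterer:
    """Fit a :class:`PositionClusterer` on a pooled profile table."""
    from .profiles import profile_matrix

    est = PositionClusterer(
        n_clusters=n_clusters, random_state=random_state, **kwargs
    )
    return est.fit(profile_matrix(profiles))


def assign(profiles: pd.DataFrame, model: PositionClusterer) -> pd.DataFrame:
    """Assign each profile to its most likely cluster with posteriors.

    Used both for the training profiles and, unchanged, for projecting
    auxiliary profile sets.  Output columns: gene_id, class, dataset, n,
    cluster_id, role, posterior_1..posterior_k.
    """
    from .profiles import profile_matrix

    X = profile_matrix(profiles)
    proba = model.predict_proba(X)
    cluster_id = np.argmax(proba, axis=1)
    roles = np.asarray(model.roles_, dtype=object)[cluster_id]
    out = profiles[["gene_id", "class", "dataset", "n"]].copy().reset_index(drop=True)
    out["cluster_id"] = cluster_id
    out["role"] = roles
    for j in range(proba.shape[1]):
        out[f"posterior_{j + 1}"] = proba[:, j]
    return out


def role_composition(
    assignments: pd.DataFrame,
    gene_set: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Fraction of genes per role for each class, among non-empty profiles.

    The no-variants (``empty``) profiles are excluded from the denominator.
    Classes whose denominator is zero are reported with NaN fractions and
    ``defined = False`` rather than zero.
    """
    df = assignments
    if gene_set is not None:
        df = df[df["gene_id"].isin(set(gene_set))]
    rows = []
    for (cls, ds), grp in df.groupby(["class", "dataset"], observed=True):
        nonempty = grp[grp["role"] != "empty"]
        denom = len(nonempty)
        for role in ("uniform", "non_uniform"):
            k = int((nonempty["role"] == role).sum())
            rows.append(
                {
                    "class": cls,
                    "dataset": ds,
                    "role": role,
                    "n_genes": k,
                    "n_nonempty": denom,
                    "fraction": (k / denom) if denom else float("nan"),
                    "defined": denom > 0,
                }
            )
    return pd.DataFrame(rows)
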