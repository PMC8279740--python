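"""Cell-class identification from waveform features.

Units are clustered in the 2-D space of trough-to-peak duration and
repolarization time with a Gaussian mixture whose component covariances are
constrained to be diagonal.  The EM fit is restarted from 500 k-means++
initializations (keeping the best log-likelihood), the number of components
is chosen by minimizing the BIC over K = 1..10, and units are hard-assigned
to their maximum-posterior component.  Classes are numbered by ascending
mean trough-to-peak duration, so class 1 is the narrowest-spiking class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .errors import ParameterError

N_REPLICATES = 500
MAX_ITER = 100
K_MAX = 10
VARIANCE_FLOOR = 1e-6  # ms^2; EM regularization against singular components


@dataclass
class CellClassModel:
    """Fitted diagonal-covariance Gaussian mixture over waveform features."""

    K: int
    means: np.ndarray            # (K, 2) ms, sorted by trough-to-peak
    variances: np.ndarray        # (K, 2) ms^2, diagonal
    weights: np.ndarray          # (K,)
    log_likelihood: float
    bic_by_k: dict = field(default_factory=dict)
    assignments: np.ndarray = None   # (n,) 1-based class labels
    posteriors: np.ndarray = None    # (n, K)
    floored_components: np.ndarray = None  # bool (K,): variance at the floor

    def log_component_densities(self, x):
        """Log of weight_k * N(x | mean_k, diag var_k) for each component."""
        x = np.atleast_2d(x)
        diff = x[:, None, :] - self.means[None, :, :]
        log_det = np.log(self.variances).sum(axis=1)
        quad = (diff**2 / self.variances[None, :, :]).sum(axis=2)
        return (np.log(self.weights)[None, :]
                - 0.5 * (2 * np.log(2 * np.pi) + log_det)[None, :]
                - 0.5 * quad)

    def posterior(self, x):
        lg = self.log_component_densities(x)
        lg -= lg.max(axis=1, keepdims=True)
        p = np.exp(lg)
        return p / p.sum(axis=1, keepdims=True)

    def assign(self, x):
        """1-based hard assignment by maximum posterior."""
        return np.argmax(self.posterior(x), axis=1) + 1


def _order_by_trough_to_peak(gm):
    return np.argsort(gm.means_[:, 0], kind="stable")


def fit_gmm(features, K, n_replicates=N_REPLICATES, seed=0):
    """Best-of-`n_replicates` EM fit of a K-component diagonal mixture."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ParameterError("features must be an (n, 2) array")
    n_distinct = np.unique(X, axis=0).shape[0]
    if K > n_distinct:
        raise ParameterError(
            f"K={K} exceeds the {n_distinct} distinct feature points")
    gm = GaussianMixture(
        n_components=K, covariance_type="diag", n_init=int(n_replicates),
        init_params="k-means++", max_iter=MAX_ITER, reg_covar=VARIANCE_FLOOR,
        random_state=np.random.RandomState(seed))
    gm.fit(X)
    return gm


def _wrap_model(gm, X, bic_by_k=None):
    order = _order_by_trough_to_peak(gm)
    model = CellClassModel(
        K=gm.n_components,
        means=gm.means_[order].copy(),
        variances=gm.covariances_[order].copy(),
        weights=gm.weights_[order].copy(),
        log_likelihood=float(gm.score(X) * X.shape[0]),
        bic_by_k=dict(bic_by_k or {}),
        floored_components=(gm.covariances_[order] <= 1.5 * VARIANCE_FLOOR
                            ).any(axis=1),
    )
    model.posteriors = model.posterior(X)
    model.assignments = np.argmax(model.posteriors, axis=1) + 1
    return model


def bic(gm, X):
    """BIC with 5K-1 free parameters (2 means + 2 variances + weights - 1)."""
    return float(gm.bic(X))


def select_K_by_bic(features, k_max=K_MAX, n_replicates=N_REPLICATES, seed=0):
    """Fit K = 1..k_max and return the model minimizing the BIC.

    Ties and K values exceeding the number of distinct points resolve to the
    smallest feasible K.
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] < 2:
        raise ParameterError("need at least 2 feature points")
    n_distinct = np.unique(X, axis=0).shape[0]
    fits, bics = {}, {}
    for K in range(1, int(k_max) + 1):
        if K > n_distinct:
            break
        fits[K] = fit_gmm(X, K, n_replicates=n_replicates, seed=seed)
        bics[K] = bic(fits[K], X)
    best = min(bics, key=lambda k: (bics[k], k))
    return _wrap_model(fits[best], X, bic_by_k=bics)


def bic_selection_study(n_points=355, n_seeds=25, k_max=K_MAX,
                        n_replicates=N_REPLICATES, seed=0,
                        sample_points=None):
    """Selected K over repeated draws from the default 3-class feature mixture.

    Each repetition draws `n_points` feature points (via
    `simulate.sample_feature_points` unless `sample_points` is given) and
    runs the full BIC selection; returns the list of selected K values.
    """
    from .simulate import sample_feature_points
    sample_points = sample_points or sample_feature_points
    ks = []
    for child in np.random.SeedSequence(seed).spawn(n_seeds):
        rng = np.random.default_rng(child)
        X, _ = sample_points(n=n_points, seed=int(rng.integers(2**31)))
        model = select_K_by_bic(X, k_max=k_max, n_replicates=n_replicates,
                                seed=int(rng.integers(2**31)))
        ks.append(model.K)
    return ks


def separation_accuracy(model, n_draws=10_000, seed=0):
    """Monte-Carlo class separability of a fitted mixture.

    Draws `n_draws` labelled points from the mixture, reassigns each by
    maximum posterior, and returns the row-normalized confusion matrix and
    the accuracy (mean of the diagonal).
    """
    if n_draws < model.K:
        raise ParameterError(f"n_draws must be >= K={model.K}")
    rng = np.random.default_rng(seed)
    comp = rng.choice(model.K, size=n_draws, p=model.weights)
    x = model.means[comp] + rng.standard_normal((n_draws, 2)) \
        * np.sqrt(model.variances[comp])
    pred = np.argmax(model.posterior(x), axis=1)
    confusion = np.zeros((model.K, model.K))
    np.add.at(confusion, (comp, pred), 1.0)
    row_sums = confusion.sum(axis=1, keepdims=True)
    confusion = np.divide(confusion, row_sums, where=row_sums > 0,
                          out=np.zeros_like(confusion))
    accuracy = float(np.mean(np.diag(confusion)))
    return confusion, accuracy


def confidence_ellipses(model, coverage=0.68):
    """Axis-aligned coverage ellipses of each component (diagonal covariance).

    The semi-axes are the per-dimension SDs scaled by
    ``sqrt(chi2.ppf(coverage, df=2))``, the bivariate analog of a standard
    error at 68% coverage.
    """
    r = np.sqrt(stats.chi2.ppf(coverage, df=2))
    ellipses = []
    for k in range(model.K):
        ellipses.append({
            "center": tuple(model.means[k]),
            "semi_axes": tuple(r * np.sqrt(model.variances[k])),
            "orientation_deg": 0.0,
            "degenerate": bool(model.floored_components[k]),
        })
    return ellipses


def compare_class_composition(unit_table):
    """Class-composition homogeneity across areas.

    Parameters
    ----------
    unit_table : DataFrame with columns ``area`` and ``cell_class``.

    Returns
    -------
    dict with per-area class counts/proportions, a goodness-of-fit chi-square
    of each area against the pooled class distribution, and pairwise
    area-by-area contingency chi-squares (no continuity correction).
    """
    df = unit_table[["area", "cell_class"]].copy()
    counts = pd.crosstab(df["area"], df["cell_class"])
    empty = [a for a in counts.index if counts.loc[a].sum() == 0]
    if empty:
        import warnings
        warnings.warn(f"areas with no units excluded: {empty}")
        counts = counts.drop(index=empty)
    pooled = counts.sum(axis=0)
    pooled_prop = pooled / pooled.sum()
    per_area = {}
    for area in counts.index:
        obs = counts.loc[area].to_numpy(dtype=float)
        expected = pooled_prop.to_numpy() * obs.sum()
        chi2 = float(((obs - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=len(obs) - 1))
        per_area[area] = {"counts": counts.loc[area].to_dict(),
                          "proportions": (counts.loc[area] / obs.sum()).to_dict(),
                          "chi2": chi2, "p": p}
    pairwise = {}
    areas = list(counts.index)
    for i, a in enumerate(areas):
        for b in areas[i + 1:]:
            table = counts.loc[[a, b]].to_numpy()
            table = table[:, table.sum(axis=0) > 0]
            chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
            pairwise[(a, b)] = {"chi2": float(chi2), "p": float(p), "dof": int(dof)}
    return {"counts": counts, "per_area": per_area, "pairwise": pairwise}
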