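"""Pooled PCA turning 7 habitat proportions into niche dimensions.

The ordination is fitted once on the habitat-composition rows of *all*
sites, years and origins (bird and random points pooled), so that every
site-year niche lives in the same space.  By default it is a covariance
PCA on the raw proportions (the variables are already commensurate); a
correlation mode is available.  Three axes are retained; each axis is
sign-oriented so that a designated anchor habitat loads positively
(cereal on PC1, ploughed on PC2, natural vegetation on PC3), which makes
axis signs reproducible across refits.

No log-ratio transform is applied to the compositional data; this is a
documented limitation, not an oversight.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .synth import HABITAT_CLASSES, N_HABITATS

DEFAULT_ANCHORS = ("cereal", "ploughed", "natural_vegetation")


class CompositionValidationError(ValueError):
    """A composition row does not sum to 1."""


@dataclass(frozen=True)
class NicheSpace:
    """Fitted habitat ordination.

    loadings : (7, K) orthonormal columns, PC1..PCK
    explained_variance_pct : (K,) non-increasing, sums to <= 100
    center : (7,) variable means removed before projection
    scale : (7,) divisors (all 1 in covariance mode)
    anchors : habitat used to orient the sign of each axis
    """

    loadings: np.ndarray
    explained_variance_pct: np.ndarray
    center: np.ndarray
    scale: np.ndarray
    anchors: tuple[str, ...]
    habitats: tuple[str, ...] = HABITAT_CLASSES

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def axis_labels(self) -> list[str]:
        return [f"PC{i + 1}" for i in range(self.k)]

    def to_table(self) -> pd.DataFrame:
        """Loadings + explained-variance row, mirroring the usual
        ordination summary layout."""
        df = pd.DataFrame(
            self.loadings, index=list(self.habitats), columns=self.axis_labels()
        )
        df.loc["explained_variance_pct"] = self.explained_variance_pct
        return df


def _validate_rows(rows: np.ndarray) -> np.ndarray:
    x = np.asarray(rows, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    if x.shape[1] != N_HABITATS:
        raise CompositionValidationError(
            f"composition rows must have {N_HABITATS} habitat proportions"
        )
    sums = x.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = int(np.argmax(np.abs(sums - 1.0)))
        raise CompositionValidationError(
            f"composition row {bad} sums to {sums[bad]:.6f}, expected 1"
        )
    return x


def fit_habitat_pca(
    rows,
    k: int = 3,
    mode: str = "covariance",
    anchors: tuple[str, ...] = DEFAULT_ANCHORS,
) -> NicheSpace:
    """Fit the pooled PCA on all composition rows.

    Parameters
    ----------
    rows
        (n, 7) array or DataFrame of habitat proportions (each row sums
        to 1); n >= 8.
    k
        Number of axes retained (explicit, not variance-thresholded).
    mode
        'covariance' (default) or 'correlation'.
    anchors
        One habitat name per retained axis; the axis sign is flipped if
        needed so the anchor's loading is positive.
    """
    if isinstance(rows, pd.DataFrame):
        cols = [c for c in rows.columns if c.startswith("p_")]
        rows = rows[cols].to_numpy() if cols else rows.to_numpy()
    x = _validate_rows(rows)
    n = x.shape[0]
    if n < 8:
        raise CompositionValidationError(f"need >= 8 rows to fit the PCA, got {n}")
    if mode not in ("covariance", "correlation"):
        raise ValueError("mode must be 'covariance' or 'correlation'")

    center = x.mean(axis=0)
    if mode == "correlation":
        scale = x.std(axis=0, ddof=1)
        zero = scale <= 0
        if zero.any():
            warnings.warn(
                "zero-variance habitat columns in correlation PCA: "
                + ", ".join(np.array(HABITAT_CLASSES)[zero]),
                stacklevel=2,
            )
            scale = np.where(zero, 1.0, scale)
    else:
        scale = np.ones(N_HABITATS)
    z = (x - center) / scale

    rank = np.linalg.matrix_rank(z, tol=1e-10)
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(
            f"input covariance is rank deficient (rank {rank}); "
            f"retaining {k_eff} axes instead of {k}",
            stacklevel=2,
        )
    pca = PCA(n_components=k_eff, svd_solver="full")
    pca.fit(z)
    loadings = pca.components_.T.copy()  # (7, k_eff)
    explained = 100.0 * pca.explained_variance_ratio_.copy()

    for j in range(k_eff):
        # axes beyond the anchor list (or with a zero anchor loading) are
        # oriented by their largest-|loading| variable instead
        a = HABITAT_CLASSES.index(anchors[j]) if j < len(anchors) else None
        if a is not None and loadings[a, j] != 0:
            if loadings[a, j] < 0:
                loadings[:, j] *= -1.0
        else:
            m = int(np.argmax(np.abs(loadings[:, j])))
            if loadings[m, j] < 0:
                loadings[:, j] *= -1.0
    return NicheSpace(
        loadings=loadings,
        explained_variance_pct=explained,
        center=center,
        scale=scale,
        anchors=tuple(anchors)[: min(len(anchors), k_eff)],
    )


def project(space: NicheSpace, rows) -> np.ndarray:
    """Scores of composition rows in the fitted niche space: (n, K)."""
    if isinstance(rows, pd.DataFrame):
        cols = [c for c in rows.columns if c.startswith("p_")]
        rows = rows[cols].to_numpy() if cols else rows.to_numpy()
    x = _validate_rows(rows)
    return ((x - space.center) / space.scale) @ space.loadings
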