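"""PCA reduction and two-group MANOVA via Wilks' lambda.

Each ROI x emotion feature block (subjects x 48 temperature changes) is
reduced to k = 9 principal components fitted across subjects, then the two
severity groups are compared with a one-way MANOVA.  For g = 2 groups the
Wilks likelihood-ratio statistic

    Lambda = det(E) / det(E + H)

(E, H = within- and between-group SSCP matrices) transforms exactly to

    F = ((1 - Lambda) / Lambda) * (N - k - 1) / k   on (k, N - k - 1) df,

which coincides with the F form of Hotelling's T².  For N = 35 subjects and
k = 9 the degrees of freedom are (9, 25).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .core import FeatureMatrix, ThermofaceError
from .schedule import ALL_BLOCKS, EmotionType


class StatsError(ThermofaceError):
    pass


@dataclass
class PcaModel:
    """Centered (unscaled) PCA of one feature block."""

    mean: np.ndarray  # (p,)
    components: np.ndarray  # (k, p), orthonormal rows
    explained_variance_ratio: np.ndarray  # (k,), non-increasing

    def transform(self, values: np.ndarray) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) @ self.components.T

    def to_dict(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }


def pca_reduce(block: FeatureMatrix, k: int = 9) -> tuple[PcaModel, FeatureMatrix]:
    """Reduce a subjects x p block to its top-k principal-component scores.

    Columns are centered but not scaled (all features share °C units).
    Component signs follow the convention that the largest-magnitude loading
    of each component is positive, so results do not depend on row order or
    SVD implementation details.
    """
    X = block.values
    n, p = X.shape
    if n < 2:
        raise StatsError("PCA needs at least two subjects")
    if k > min(n - 1, p):
        raise StatsError(f"k={k} exceeds min(n-1, p) = {min(n - 1, p)}")
    mean = X.mean(axis=0)
    if np.allclose(X, mean, atol=1e-12):
        model = PcaModel(
            mean=mean,
            components=np.eye(p)[:k],
            explained_variance_ratio=np.zeros(k),
        )
        scores = np.zeros((n, k))
    else:
        pca = PCA(n_components=k, svd_solver="full")
        scores = pca.fit_transform(X)
        comps = pca.components_.copy()
        for j in range(k):
            lead = np.argmax(np.abs(comps[j]))
            if comps[j, lead] < 0:
                comps[j] = -comps[j]
                scores[:, j] = -scores[:, j]
        model = PcaModel(
            mean=pca.mean_,
            components=comps,
            explained_variance_ratio=pca.explained_variance_ratio_,
        )
    reduced = FeatureMatrix(
        values=scores, labels=block.labels, roi=block.roi, emotion=block.emotion
    )
    return model, reduced


@dataclass
class ManovaResult:
    """Wilks' lambda MANOVA for one ROI x emotion cell, two groups."""

    wilks_lambda: float
    f_value: float
    df1: int
    df2: int
    p_value: float
    roi: str = ""
    emotion: str = ""

    @property
    def stars(self) -> str:
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return ""

    def summary(self) -> str:
        cell = f"{self.roi} / {self.emotion}".strip(" /")
        lines = [
            "MANOVA (Wilks' lambda, two groups)" + (f" — {cell}" if cell else ""),
            f"  Wilks' lambda : {self.wilks_lambda:.6f}",
            f"  F({self.df1}, {self.df2})      : {self.f_value:.4f}",
            f"  p-value       : {self.p_value:.4g} {self.stars}",
        ]
        return "\n".join(lines)


def _sscp(reduced: FeatureMatrix) -> tuple[np.ndarray, np.ndarray, int]:
    X, y = reduced.values, reduced.labels
    groups = sorted(set(y.tolist()))
    if len(groups) != 2:
        raise StatsError(f"exactly two groups required, got {groups}")
    grand = X.mean(axis=0)
    E = np.zeros((X.shape[1],) * 2)
    H = np.zeros_like(E)
    for g in groups:
        Xg = X[y == g]
        if len(Xg) < 2:
            raise StatsError(f"group {g!r} needs at least two subjects")
        d = Xg - Xg.mean(axis=0)
        E += d.T @ d
        m = Xg.mean(axis=0) - grand
        H += len(Xg) * np.outer(m, m)
    return E, H, X.shape[0]


def manova_wilks(reduced: FeatureMatrix) -> ManovaResult:
    """Two-group MANOVA on a reduced block; exact F via Wilks' lambda.

    Raises :class:`StatsError` when the within-group SSCP matrix is singular
    (too many components for the sample size — reduce k).
    """
    E, H, n = _sscp(reduced)
    k = E.shape[0]
    df2 = n - k - 1
    if df2 < 1:
        raise StatsError(f"N - k - 1 = {df2} < 1: reduce k")
    sign_e, logdet_e = np.linalg.slogdet(E)
    sign_t, logdet_t = np.linalg.slogdet(E + H)
    if sign_e <= 0 or not np.isfinite(logdet_e):
        raise StatsError("within-group SSCP matrix is singular: reduce k")
    lam = float(np.exp(logdet_e - logdet_t)) if sign_t > 0 else 0.0
    lam = min(lam, 1.0)
    f_value = (1.0 - lam) / lam * df2 / k if lam > 0 else np.inf
    p = float(sps.f.sf(f_value, k, df2)) if np.isfinite(f_value) else 0.0
    return ManovaResult(
        wilks_lambda=lam,
        f_value=float(f_value),
        df1=k,
        df2=df2,
        p_value=p,
        roi=reduced.roi,
        emotion=reduced.emotion,
    )


def table2_analysis(
    reduced_blocks: dict[tuple[str, EmotionType], FeatureMatrix],
) -> pd.DataFrame:
    """MANOVA across all 5 ROIs x 4 blocks (3 emotions + no-stimulus rest).

    Returns a long-form table (roi, emotion, wilks_lambda, F, df1, df2, p,
    stars).  Raises :class:`StatsError` naming the first missing cell.
    """
    from .roi import ROI_NAMES

    rows = []
    for roi in ROI_NAMES:
        for emo in ALL_BLOCKS:
            key = (roi, emo)
            if key not in reduced_blocks:
                raise StatsError(f"missing block for cell ({roi}, {emo.value})")
            res = manova_wilks(reduced_blocks[key])
            rows.append(
                {
                    "roi": roi,
                    "emotion": emo.value,
                    "wilks_lambda": res.wilks_lambda,
                    "F": res.f_value,
                    "df1": res.df1,
                    "df2": res.df2,
                    "p": res.p_value,
                    "stars": res.stars,
                }
            )
    return pd.DataFrame(rows)


def analyze_cohort(
    raw_blocks: dict[tuple[str, EmotionType], FeatureMatrix],
    k: int = 9,
    on_error: str = "record",
) -> pd.DataFrame:
    """PCA-reduce every raw block to k components and run the MANOVA table.

    ``on_error="record"`` reports unanalysable cells (e.g. singular
    within-group covariance at tiny n) as NaN rows with the error message
    instead of raising; ``"raise"`` propagates.
    """
    rows = []
    from .roi import ROI_NAMES

    for roi in ROI_NAMES:
        for emo in ALL_BLOCKS:
            key = (roi, emo)
            if key not in raw_blocks:
                raise StatsError(f"missing block for cell ({roi}, {emo.value})")
            try:
                _, reduced = pca_reduce(raw_blocks[key], k=k)
                res = manova_wilks(reduced)
                rows.append(
                    {
                        "roi": roi,
                        "emotion": emo.value,
                        "wilks_lambda": res.wilks_lambda,
                        "F": res.f_value,
                        "df1": res.df1,
                        "df2": res.df2,
                        "p": res.p_value,
                        "stars": res.stars,
                        "error": "",
                    }
                )
            except StatsError as exc:
                if on_error == "raise":
                    raise
                rows.append(
                    {
                        "roi": roi,
                        "emotion": emo.value,
                        "wilks_lambda": np.nan,
                        "F": np.nan,
                        "df1": 0,
                        "df2": 0,
                        "p": np.nan,
                        "stars": "",
                        "error": str(exc),
                    }
                )
    return pd.DataFrame(rows)
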