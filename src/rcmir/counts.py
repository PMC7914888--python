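"""Count-matrix container, size-factor normalization, and PCA sample scores.

Small-RNA-seq produces a miRNA x sample table of non-negative integer read
counts.  Library depth varies between samples, so raw counts are made
comparable with the median-of-ratios size-factor estimator: each sample's
factor is the median, over miRNAs detected in every sample, of that sample's
count divided by the miRNA's geometric mean across samples.  Dividing a
sample's column by its factor yields normalized counts on a common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA


class CountMatrixError(ValueError):
    """Raised for malformed count matrices or group maps."""


@dataclass
class CountMatrix:
    """Integer miRNA x sample count matrix with per-sample condition labels.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows indexed by miRNA id (miRBase-style, e.g. ``mmu-mir-30d-5p``),
        columns by sample id; non-negative integers.
    groups : dict
        Sample id -> condition label (e.g. ``control``, ``LTyr``, ``BrdU``).
    """

    counts: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dup = df.index[df.index.duplicated()].tolist()
            raise CountMatrixError(f"duplicate miRNA ids: {dup}")
        if df.columns.has_duplicates:
            raise CountMatrixError("duplicate sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise CountMatrixError("counts must be numeric")
        if np.any(arr < 0):
            raise CountMatrixError("counts must be non-negative")
        if np.any(arr != np.floor(arr)) or np.any(~np.isfinite(arr.astype(float))):
            raise CountMatrixError("counts must be integers")
        self.counts = df.astype(np.int64)
        missing = [s for s in df.columns if s not in self.groups]
        if missing:
            raise CountMatrixError(f"samples without a group label: {missing}")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.groups[s] == group]

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="mirna_id")


@dataclass
class NormalizedMatrix:
    """Size-factor-normalized expression values with the factors that made them."""

    values: pd.DataFrame
    size_factors: pd.Series

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="mirna_id")


def read_count_matrix(path, group_map: dict[str, str], sep: str = "\t") -> CountMatrix:
    """Read a counts table (first column miRNA id, header row sample ids)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.has_duplicates:
        raise CountMatrixError(f"duplicate miRNA id in {path}")
    try:
        as_int = df.astype(np.int64)
    except (ValueError, TypeError) as exc:
        raise CountMatrixError(f"non-integer cell in {path}: {exc}") from exc
    if not (df.to_numpy() == as_int.to_numpy()).all():
        raise CountMatrixError(f"non-integer cell in {path}")
    return CountMatrix(as_int, dict(group_map))


def size_factors(m: CountMatrix) -> pd.Series:
    """Median-of-ratios size factor per sample.

    factor_s = median over miRNAs g of count_gs / geomean_g(count), where the
    median runs only over miRNAs with a positive count in every sample.
    """
    arr = m.counts.to_numpy(dtype=float)
    all_positive = (arr > 0).all(axis=1)
    if not all_positive.any():
        raise CountMatrixError(
            "no miRNA has positive counts in all samples; size factors undefined"
        )
    pos = arr[all_positive]
    log_geomean = np.mean(np.log(pos), axis=1)
    ratios = np.log(pos) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=m.counts.columns, name="size_factor")


def normalize(m: CountMatrix) -> NormalizedMatrix:
    """Divide each sample's counts by its median-of-ratios size factor."""
    f = size_factors(m)
    values = m.counts / f
    return NormalizedMatrix(values=values, size_factors=f)


def pca_scores(nm: NormalizedMatrix, k: int) -> pd.DataFrame:
    """Scores of samples on the first ``k`` principal components.

    The input is log2(value + 1) transformed and centered per miRNA; samples
    are the observations.  Component signs are fixed by making the
    largest-magnitude loading of each component positive, so scores are
    reproducible across runs and BLAS implementations.
    """
    n_samples = len(nm.sample_ids)
    n_mirnas = len(nm.mirna_ids)
    if not 1 <= k <= min(n_samples, n_mirnas):
        raise ValueError(f"k={k} out of range [1, {min(n_samples, n_mirnas)}]")
    x = np.log2(nm.values.to_numpy(dtype=float) + 1.0).T  # samples x miRNAs
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    # sign convention: largest |loading| positive per component
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] *= -1.0
    return pd.DataFrame(
        scores, index=nm.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )
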