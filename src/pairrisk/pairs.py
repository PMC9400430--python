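"""Binary lncRNA-pair indicator matrices.

For an ordered gene list g1..gk, every unordered pair (a, b) with a listed
before b gets one row named "a|b"; a sample scores 1 when a is expressed
strictly above b, else 0 (ties fall to 0). Because each indicator depends
only on the within-sample ordering of two genes, the matrix is invariant
under any strictly increasing per-sample transform of the expression values
— the property that makes pair signatures portable across platforms without
batch correction.

The minority-frequency filter then drops pairs whose indicator is (nearly)
constant: the rarer value must occur in strictly more than a floor fraction
of samples (default 20%), i.e. the mean indicator must lie strictly inside
(0.2, 0.8). Constant pairs carry no ordering information and can never
separate outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

PAIR_SEP = "|"


@dataclass
class PairIndicatorMatrix:
    """Pairs x samples binary matrix; rows named 'lncRNA1|lncRNA2'."""

    indicators: pd.DataFrame  # int8 0/1, index pair ids, columns sample ids

    def __post_init__(self):
        arr = self.indicators.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pair indicators must be 0 or 1")
        if self.indicators.index.duplicated().any():
            dup = self.indicators.index[self.indicators.index.duplicated()][0]
            raise ValueError(f"duplicated pair id: {dup!r}")

    @property
    def pair_ids(self):
        return list(self.indicators.index)

    @property
    def sample_ids(self):
        return list(self.indicators.columns)

    @property
    def n_pairs(self):
        return self.indicators.shape[0]

    def minority_frac(self) -> pd.Series:
        """Per-pair frequency of the rarer indicator value, in [0, 0.5]."""
        mean = self.indicators.mean(axis=1)
        return np.minimum(mean, 1.0 - mean)

    def subset_pairs(self, pair_ids) -> "PairIndicatorMatrix":
        missing = [p for p in pair_ids if p not in self.indicators.index]
        if missing:
            raise KeyError(f"pairs not in matrix: {missing[:5]}")
        return PairIndicatorMatrix(self.indicators.loc[list(pair_ids)])

    def subset_samples(self, sample_ids) -> "PairIndicatorMatrix":
        return PairIndicatorMatrix(self.indicators[list(sample_ids)])


def pair_id(a: str, b: str) -> str:
    return f"{a}{PAIR_SEP}{b}"


def split_pair_id(pid: str) -> tuple:
    a, b = pid.split(PAIR_SEP)
    return a, b


def build_pairs(expr: ExpressionMatrix, samples=None) -> PairIndicatorMatrix:
    """Construct the full k(k-1)/2 pair indicator matrix.

    ``samples`` restricts the columns (typically the tumor samples, since
    the survival model never sees normals); pair orientation follows the
    input gene order, making results deterministic.
    """
    genes = expr.gene_ids
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to build pairs")
    if samples is None:
        samples = expr.sample_ids
    samples = list(samples)
    if not samples:
        raise ValueError("need at least 1 sample to build pairs")
    G = expr.values.loc[genes, samples].to_numpy(float)
    ii, jj = np.triu_indices(len(genes), k=1)
    ind = (G[ii] > G[jj]).astype(np.int8)  # ties -> 0: rule is strictly "lower than"
    ids = [pair_id(genes[i], genes[j]) for i, j in zip(ii, jj)]
    return PairIndicatorMatrix(pd.DataFrame(ind, index=pd.Index(ids, name="pair_id"),
                                            columns=samples))


def filter_pairs(m: PairIndicatorMatrix, pair_minority_min: float = 0.20
                 ) -> PairIndicatorMatrix:
    """Keep pairs whose mean indicator lies strictly inside
    (pair_minority_min, 1 - pair_minority_min).

    Constant pairs (all 0 or all 1) are always dropped. Boundary values are
    excluded: a pair at exactly the floor is removed.
    """
    if m.n_pairs == 0:
        raise ValueError("empty pair matrix")
    frac = m.minority_frac()
    keep = frac > pair_minority_min
    return PairIndicatorMatrix(m.indicators.loc[keep])
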