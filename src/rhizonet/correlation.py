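"""All-pairs Spearman correlation with FDR adjustment.

Correlations are computed on per-sample relative abundances: each taxon's
values are converted to mid-ranks (average ranks for ties) across samples and
the Pearson correlation of the rank vectors is taken. Two-sided p-values use
the t approximation t = rho * sqrt((n-2)/(1-rho^2)) on n-2 degrees of
freedom, which matches common statistical software at moderate n; exact
permutation tests can differ below ~10 samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from rhizonet.datasets import AbundanceTable
from rhizonet.errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationSet:
    """Upper-triangle (i < j) Spearman correlations among taxa.

    ``pairs`` has columns taxon_i, taxon_j, rho, p_raw, p_adj, n. ``taxa`` is
    the ordered list of non-constant taxa entering the pair list.
    """

    pairs: pd.DataFrame
    taxa: list

    def __post_init__(self):
        required = {"taxon_i", "taxon_j", "rho", "p_raw", "n"}
        missing = required - set(self.pairs.columns)
        if missing:
            raise ValidationError(f"pairs frame missing columns: {sorted(missing)}")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    def rho_matrix(self) -> pd.DataFrame:
        """Symmetric taxon x taxon matrix of rho with unit diagonal."""
        k = len(self.taxa)
        mat = np.eye(k)
        idx = {t: i for i, t in enumerate(self.taxa)}
        ii = self.pairs["taxon_i"].map(idx).to_numpy()
        jj = self.pairs["taxon_j"].map(idx).to_numpy()
        mat[ii, jj] = self.pairs["rho"].to_numpy()
        mat[jj, ii] = self.pairs["rho"].to_numpy()
        return pd.DataFrame(mat, index=self.taxa, columns=self.taxa)

    def to_frame(self) -> pd.DataFrame:
        return self.pairs.copy()

    def write_tsv(self, path) -> None:
        self.pairs.to_csv(path, sep="\t", index=False)


def spearman_all_pairs(data: AbundanceTable | pd.DataFrame) -> CorrelationSet:
    """Spearman rho and raw p-value for every unordered taxon pair.

    Accepts an :class:`AbundanceTable` (converted to relative abundances) or a
    pre-computed samples x taxa DataFrame of relative abundances. Constant
    taxa have undefined rho and are dropped from the pair list (logged).
    """
    if isinstance(data, AbundanceTable):
        rel = data.to_relative()
    else:
        rel = data
    n, k = rel.shape
    if n < 4:
        raise InsufficientDataError(f"need >= 4 samples for correlations, got {n}")
    if k < 2:
        raise InsufficientDataError(f"need >= 2 taxa for correlations, got {k}")

    values = rel.to_numpy(dtype=float)
    constant = values.std(axis=0) == 0
    if constant.any():
        logger.info(
            "spearman_all_pairs: dropping %d constant taxa", int(constant.sum())
        )
    taxa = [t for t, c in zip(rel.columns, constant) if not c]
    values = values[:, ~constant]
    k = values.shape[1]
    if k < 2:
        raise InsufficientDataError("fewer than 2 non-constant taxa")

    ranks = np.apply_along_axis(stats.rankdata, 0, values)  # mid-ranks per taxon
    rho = np.corrcoef(ranks, rowvar=False)
    rho = np.clip(rho, -1.0, 1.0)

    iu, ju = np.triu_indices(k, k=1)
    r = rho[iu, ju]
    # two-sided p from the t approximation; |rho| == 1 -> p = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * stats.t.sf(np.abs(t), df=n - 2))
    p = np.clip(p, 0.0, 1.0)

    taxa_arr = np.asarray(taxa, dtype=object)
    pairs = pd.DataFrame(
        {
            "taxon_i": taxa_arr[iu],
            "taxon_j": taxa_arr[ju],
            "rho": r,
            "p_raw": p,
            "p_adj": np.nan,
            "n": n,
        }
    )
    return CorrelationSet(pairs=pairs, taxa=taxa)


def bh_adjust(p_raw: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped to 1.

    q_(k) = min_{j >= k} p_(j) * m / j over the ascending order statistics;
    values are returned in the original order.
    """
    p = np.asarray(p_raw, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def adjust_fdr(cset: CorrelationSet) -> CorrelationSet:
    """Return a copy with p_adj filled by Benjamini-Hochberg; order preserved."""
    pairs = cset.pairs.copy()
    pairs["p_adj"] = bh_adjust(pairs["p_raw"].to_numpy())
    return replace(cset, pairs=pairs)
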