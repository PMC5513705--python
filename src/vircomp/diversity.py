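"""Alpha diversity, rarefaction, OTU overlap and family-level rollups.

Input is an OTU table: integer read counts per OTU per sample, as produced by
97%-identity clustering of 16S rRNA amplicons. The estimators follow the
conventions of classical amplicon community analysis:

* Shannon index ``H = -sum p_i ln p_i`` in **nats**, with an approximate 95%
  confidence interval from the large-sample variance
  ``var(H) = [sum p_i (ln p_i)^2 - (sum p_i ln p_i)^2] / N + (S-1)/(2 N^2)``;
* Simpson index in the finite-sample **dominance** form
  ``D = sum n_i (n_i - 1) / (N (N - 1))`` — the probability two reads drawn
  without replacement belong to the same OTU — with a normal-approximation CI;
* Good's coverage ``C = (1 - F1/N) * 100`` with ``F1`` the singleton count;
* analytic rarefaction: the exact hypergeometric expectation of richness in a
  random subsample, computed in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from .errors import (
    DepthError,
    EmptySampleError,
    InsufficientReadsError,
    LookupError_,
    ParameterError,
)

__all__ = [
    "OtuTable",
    "TaxonomyMap",
    "DiversityResult",
    "shannon_index",
    "simpson_index",
    "goods_coverage",
    "rarefaction_curve",
    "otu_intersections",
    "family_rollup",
    "diversity_table",
]

_Z95 = norm.ppf(0.975)


@dataclass
class OtuTable:
    """Integer read counts per OTU (rows) per sample (columns)."""

    frame: pd.DataFrame  # index = otu ids, columns = sample ids, int counts

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            raise ParameterError("OtuTable: duplicate OTU ids")
        if df.columns.has_duplicates:
            raise ParameterError("OtuTable: duplicate sample ids")
        if (df.values < 0).any():
            raise ParameterError("OtuTable: negative counts")
        if not np.issubdtype(df.values.dtype, np.integer):
            raise ParameterError("OtuTable: counts must be integers")
        if (df.sum(axis=0) == 0).any():
            empty = df.columns[df.sum(axis=0) == 0][0]
            raise EmptySampleError(f"OtuTable: sample {empty!r} has no reads")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.frame.index)

    def counts(self, sample_id: str) -> np.ndarray:
        return self.frame[sample_id].to_numpy()

    def present(self, sample_id: str) -> frozenset[str]:
        col = self.frame[sample_id]
        return frozenset(col.index[col > 0])


#: otu_id -> (phylum, family, genus)
TaxonomyMap = dict


@dataclass(frozen=True)
class DiversityResult:
    sample_id: str
    n_reads: int
    n_otus: int
    shannon: float
    shannon_ci: tuple[float, float]
    simpson: float
    simpson_ci: tuple[float, float]
    coverage: float


def _positive(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or arr.sum() <= 0:
        raise EmptySampleError("need at least one positive count")
    if (arr < 0).any():
        raise ParameterError("counts must be non-negative")
    return arr[arr > 0]


def shannon_index(counts) -> tuple[float, tuple[float, float]]:
    """Shannon diversity in nats with an approximate 95% CI.

    The CI is ``H ± 1.96 sqrt(var(H))`` with the large-sample variance given
    in the module docstring; it collapses to a point for a single-OTU sample.
    """
    n = _positive(counts)
    N = n.sum()
    S = n.size
    p = n / N
    logp = np.log(p)
    H = float(-(p * logp).sum())
    var = float(((p * logp**2).sum() - (p * logp).sum() ** 2) / N
                + (S - 1) / (2 * N**2))
    half = _Z95 * np.sqrt(max(var, 0.0))
    return H, (max(H - half, 0.0), H + half)


def simpson_index(counts) -> tuple[float, tuple[float, float]]:
    """Simpson dominance ``D = sum n_i(n_i-1) / (N(N-1))`` with a 95% CI.

    The CI uses the asymptotic variance of the unbiased estimator,
    ``var(D) ≈ 4/N (λ3 − λ2²)`` with ``λk = sum p_i^k``.
    """
    n = _positive(counts)
    N = n.sum()
    if N < 2:
        raise InsufficientReadsError("simpson_index needs N >= 2 reads")
    D = float((n * (n - 1)).sum() / (N * (N - 1)))
    p = n / N
    lam2 = float((p**2).sum())
    lam3 = float((p**3).sum())
    var = max(4.0 / N * (lam3 - lam2**2), 0.0)
    half = _Z95 * np.sqrt(var)
    return D, (max(D - half, 0.0), min(D + half, 1.0))


def goods_coverage(counts) -> float:
    """Good's coverage ``(1 - singletons/N) * 100`` as a percentage."""
    n = _positive(counts)
    N = n.sum()
    f1 = int((n == 1).sum())
    return float((1.0 - f1 / N) * 100.0)


def rarefaction_curve(counts, depths) -> np.ndarray:
    """Expected OTU richness at each subsampling depth (without replacement).

    ``E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)]`` evaluated via log-gamma
    to stay finite at amplicon-scale N. Non-decreasing in n; equals S at n=N.
    """
    n_i = _positive(counts)
    N = int(n_i.sum())
    depths = np.atleast_1d(np.asarray(depths, dtype=int))
    if (depths < 1).any():
        raise DepthError("rarefaction depths must be >= 1")
    if (depths > N).any():
        raise DepthError(
            f"rarefaction depth {int(depths.max())} exceeds sample size {N}"
        )

    def log_choose(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    out = np.empty(depths.size, dtype=float)
    for j, d in enumerate(depths):
        keep = (N - n_i) >= d
        term = np.zeros(n_i.size)
        if keep.any():
            term[keep] = np.exp(log_choose(N - n_i[keep], d) - log_choose(N, d))
        out[j] = float((1.0 - term).sum())
    return out


def otu_intersections(table: OtuTable) -> tuple[dict[frozenset[str], int], float]:
    """Venn-region OTU counts plus the read share of the full intersection.

    Each OTU present anywhere is assigned to exactly one region keyed by the
    frozenset of samples where its count is nonzero. The second return value
    is the percentage of all reads carried by OTUs present in every sample.
    """
    if len(table.sample_ids) < 2:
        raise ParameterError("otu_intersections needs at least 2 samples")
    regions: dict[frozenset[str], int] = {}
    df = table.frame
    membership = df.gt(0)
    total_reads = df.values.sum()
    core_reads = 0
    all_samples = frozenset(table.sample_ids)
    for otu in df.index:
        present = frozenset(membership.columns[membership.loc[otu]])
        if not present:
            continue
        regions[present] = regions.get(present, 0) + 1
        if present == all_samples:
            core_reads += df.loc[otu].sum()
    share = 100.0 * core_reads / total_reads if total_reads else 0.0
    return regions, float(share)


def family_rollup(
    table: OtuTable, tax: TaxonomyMap, threshold: float = 1.0
) -> pd.DataFrame:
    """Per-sample family relative abundances (%) with small families pooled.

    Families holding less than ``threshold`` percent of a sample's reads are
    summed into an ``Others`` bucket (the bucket appears only when something
    was pooled). Shares per sample sum to 100 up to float rounding.
    """
    missing = [o for o in table.otu_ids if o not in tax]
    if missing:
        raise LookupError_(f"taxonomy entry missing for OTU {missing[0]!r}")
    fam = pd.Series({o: tax[o][1] for o in table.otu_ids}, name="family")
    rows = []
    for sample in table.sample_ids:
        col = table.frame[sample]
        total = col.sum()
        by_family = col.groupby(fam).sum() / total * 100.0
        small = by_family[by_family < threshold]
        kept = by_family[by_family >= threshold]
        for family, share in kept.items():
            rows.append({"sample_id": sample, "family": family,
                         "share_pct": float(share)})
        if small.sum() > 0:
            rows.append({"sample_id": sample, "family": "Others",
                         "share_pct": float(small.sum())})
    return pd.DataFrame(rows, columns=["sample_id", "family", "share_pct"])


def diversity_table(table: OtuTable) -> list[DiversityResult]:
    """Per-sample summary: reads, OTUs, coverage, Shannon and Simpson with CIs."""
    results = []
    for sample in table.sample_ids:
        counts = table.counts(sample)
        H, hci = shannon_index(counts)
        D, dci = simpson_index(counts)
        results.append(
            DiversityResult(
                sample_id=sample,
                n_reads=int(counts.sum()),
                n_otus=int((counts > 0).sum()),
                shannon=H,
                shannon_ci=hci,
                simpson=D,
                simpson_ci=dci,
                coverage=goods_coverage(counts),
            )
        )
    return results
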