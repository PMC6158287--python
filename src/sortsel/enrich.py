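"""Replicate QC, read-count thresholds with flooring, frequencies and ER.

Variants with a single substitution and variants with two substitutions are
analyzed as separate classes: each class has its own read-count threshold
(defaults 100 and 10) and its own frequency denominator. The threshold rule
is asymmetric on purpose — a variant below threshold in both the naive and
sorted libraries is discarded, while a variant below threshold in only one
library has that count floored *to* the threshold value, bounding its
enrichment ratio away from sampling noise. Frequencies are computed after
flooring, so the denominator sees the adjusted counts:

    F_v = Reads_v / sum(Reads_v)        ER_v = F_v,sorted / F_v,naive
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .variantcall import PARENT_KEY

__all__ = [
    "ThresholdPolicy",
    "ReplicateQC",
    "replicate_concordance",
    "pool_replicates",
    "apply_threshold",
    "frequencies",
    "enrichment_ratio",
    "build_enrichment_table",
]


@dataclass(frozen=True)
class ThresholdPolicy:
    """Minimum read counts per mutation class."""

    single_threshold: int = 100
    double_threshold: int = 10

    def __post_init__(self) -> None:
        if self.single_threshold < 1 or self.double_threshold < 1:
            raise ValueError("thresholds must be >= 1")

    def threshold_for(self, n_mut: int) -> int:
        if n_mut == 1:
            return self.single_threshold
        if n_mut == 2:
            return self.double_threshold
        raise ValueError(f"no threshold for n_mut={n_mut}; landscape uses 1-2 only")


@dataclass
class ReplicateQC:
    """Pairwise Spearman rank correlations between replicate count vectors."""

    rhos: dict  # (rep_i, rep_j) -> rho
    min_rho_required: float

    @property
    def min_rho(self) -> float:
        return min(self.rhos.values())

    @property
    def passed(self) -> bool:
        return self.min_rho >= self.min_rho_required


def replicate_concordance(
    replicates: Mapping[str, Mapping[str, int]] | Sequence[Mapping[str, int]],
    min_rho: float = 0.95,
) -> ReplicateQC:
    """Spearman rho for every replicate pair on the union of variant keys.

    A variant absent from one replicate counts as zero there. Average ranks
    are used for ties (scipy default).
    """
    if not isinstance(replicates, Mapping):
        replicates = {f"rep{i + 1}": r for i, r in enumerate(replicates)}
    if len(replicates) < 2:
        raise ValueError("replicate QC needs at least two replicates")
    keys = sorted(set(itertools.chain.from_iterable(r.keys() for r in replicates.values())))
    vectors = {
        name: np.array([rep.get(k, 0) for k in keys], dtype=float)
        for name, rep in replicates.items()
    }
    rhos = {}
    for (na, va), (nb, vb) in itertools.combinations(vectors.items(), 2):
        rho = spearmanr(va, vb).statistic
        rhos[(na, nb)] = float(rho)
    return ReplicateQC(rhos=rhos, min_rho_required=min_rho)


def pool_replicates(
    replicates: Sequence[Mapping[str, int]] | Mapping[str, Mapping[str, int]],
) -> dict[str, int]:
    """Sum counts variant-wise across replicates."""
    if isinstance(replicates, Mapping):
        replicates = list(replicates.values())
    pooled: dict[str, int] = {}
    for rep in replicates:
        for k, n in rep.items():
            pooled[k] = pooled.get(k, 0) + int(n)
    return pooled


def apply_threshold(
    reads_naive: int,
    reads_sorted: int,
    n_mut: int,
    policy: ThresholdPolicy = ThresholdPolicy(),
) -> tuple[int, int] | None:
    """Floor-or-discard rule; None means the variant is dropped."""
    t = policy.threshold_for(n_mut)
    below_n, below_s = reads_naive < t, reads_sorted < t
    if below_n and below_s:
        return None
    return (t if below_n else reads_naive, t if below_s else reads_sorted)


def frequencies(adjusted_counts: Mapping[str, int]) -> dict[str, float]:
    """F_v = Reads_v / sum Reads_v over the retained variants of one class."""
    total = sum(adjusted_counts.values())
    if total <= 0:
        raise ValueError("cannot normalize an empty variant class")
    return {k: n / total for k, n in adjusted_counts.items()}


def enrichment_ratio(f_sorted: float, f_naive: float) -> float:
    assert f_naive > 0, "naive frequency must be positive after thresholding"
    return f_sorted / f_naive


def build_enrichment_table(
    naive_counts: Mapping[str, int],
    sorted_counts: Mapping[str, int],
    n_mut: Mapping[str, int],
    policy: ThresholdPolicy = ThresholdPolicy(),
    sort_id: str = "sort",
    classes: Sequence[int] = (1, 2),
    shared_denominator: bool = False,
) -> pd.DataFrame:
    """Threshold, normalize and ratio two count tables into one ER table.

    Parameters
    ----------
    naive_counts, sorted_counts
        Variant-key -> read count for the naive and sorted libraries.
    n_mut
        Variant-key -> number of substitutions. Parent (0) and >2-mutation
        variants are outside the landscape classes and are ignored here.
    shared_denominator
        When True, frequencies are normalized over all retained variants of
        all requested classes together instead of per class.
    """
    keys = sorted(set(naive_counts) | set(sorted_counts))
    retained: list[dict] = []
    for key in keys:
        if key == PARENT_KEY:
            continue
        nm = n_mut.get(key)
        if nm not in classes:
            continue
        adj = apply_threshold(
            int(naive_counts.get(key, 0)), int(sorted_counts.get(key, 0)), nm, policy
        )
        if adj is None:
            continue
        retained.append(
            {"variant_key": key, "n_mut": nm, "reads_naive": adj[0], "reads_sorted": adj[1]}
        )
    df = pd.DataFrame(
        retained, columns=["variant_key", "n_mut", "reads_naive", "reads_sorted"]
    )
    if df.empty:
        df["F_naive"] = df["F_sorted"] = df["ER"] = df["log2_ER"] = []
        df.insert(2, "sort_id", [])
        return df

    group = [True] * len(df) if shared_denominator else df["n_mut"]
    df["F_naive"] = df["reads_naive"] / df.groupby(group)["reads_naive"].transform("sum")
    df["F_sorted"] = df["reads_sorted"] / df.groupby(group)["reads_sorted"].transform("sum")
    df["ER"] = df["F_sorted"] / df["F_naive"]
    df["log2_ER"] = np.log2(df["ER"])
    df.insert(2, "sort_id", sort_id)
    return df
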