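"""Selectivity landscapes built from enrichment tables.

A pairwise FACS selectivity screen yields, for each pair of target
proteases, two reciprocal sorted gates and hence two enrichment tables.
This module turns those tables into the landscape views used to read out a
screen: position x amino-acid log2(ER) heatmaps; hot-spot / cold-spot
classification of positions (a hot spot has most observed substitutions
depleted, ER < 1; a cold spot most enriched, ER > 1); selectivity-switch
mutations (enriched in one gate of a screen and depleted in the reciprocal
gate); a fold-change-based pairwise selectivity score between two mutations;
and residue-pair maps for double mutants, where the ER of all doubles
sharing the same mutated position pair is summed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .variantcall import AMINO_ACIDS, PARENT_KEY, ReferenceProtein, VariantKey

__all__ = [
    "single_mut_heatmap",
    "classify_positions",
    "find_selectivity_switches",
    "pairwise_selectivity",
    "double_residue_map",
    "residue_pair_combination_map",
    "total_selectivity",
    "er_lookup",
]

HOT_SPOT = "hot_spot"
COLD_SPOT = "cold_spot"
NEUTRAL = "neutral"
INSUFFICIENT = "insufficient_data"


def er_lookup(enrichment: pd.DataFrame) -> dict[str, float]:
    """variant_key -> ER mapping; the parent maps to the neutral value 1.0."""
    lut = dict(zip(enrichment["variant_key"], enrichment["ER"].astype(float)))
    lut.setdefault(PARENT_KEY, 1.0)
    return lut


def _singles(enrichment: pd.DataFrame) -> pd.DataFrame:
    return enrichment[enrichment["n_mut"] == 1]


def single_mut_heatmap(
    enrichment: pd.DataFrame, ref: ReferenceProtein | None = None
) -> pd.DataFrame:
    """Amino acid (rows) x position (columns) matrix of log2(ER).

    Cells are NaN for substitutions removed by thresholding, and the
    reference-identity cell of each column is inherently absent. Positions
    default to those seen in the table; with a reference, all loop positions
    appear even if empty.
    """
    singles = _singles(enrichment)
    entries = {}
    for key, er in zip(singles["variant_key"], singles["ER"]):
        sub = VariantKey.from_string(key).substitutions[0]
        cell = (sub.mut_aa, sub.position)
        if cell in entries:
            raise ValueError(f"duplicate single-mutant entry for {key}")
        entries[cell] = math.log2(er)
    positions = sorted({pos for _, pos in entries})
    if ref is not None:
        positions = sorted(set(positions) | set(ref.loop_positions))
    mat = pd.DataFrame(np.nan, index=list(AMINO_ACIDS), columns=positions)
    for (aa, pos), val in entries.items():
        mat.loc[aa, pos] = val
    return mat


def classify_positions(heatmap: pd.DataFrame, min_observed: int = 8) -> pd.DataFrame:
    """Majority-rule position classes from a log2(ER) heatmap.

    hot_spot: strictly more than half of observed substitutions depleted
    (log2 ER < 0); cold_spot: strictly more than half enriched; positions
    with fewer than ``min_observed`` observed substitutions are
    insufficient_data; ER exactly 1 counts toward neither majority.
    """
    rows = []
    for pos in heatmap.columns:
        col = heatmap[pos].dropna()
        n_obs = len(col)
        n_below = int((col < 0).sum())
        n_above = int((col > 0).sum())
        if n_obs < min_observed:
            label = INSUFFICIENT
        elif n_below * 2 > n_obs:
            label = HOT_SPOT
        elif n_above * 2 > n_obs:
            label = COLD_SPOT
        else:
            label = NEUTRAL
        rows.append(
            {"position": pos, "n_observed": n_obs, "n_ER_below_1": n_below,
             "n_ER_above_1": n_above, "label": label}
        )
    return pd.DataFrame(rows)


def find_selectivity_switches(
    er_table_a: pd.DataFrame,
    er_table_b: pd.DataFrame,
    high_cut: float = 2.0,
    low_cut: float = 0.5,
    target_a: str = "A",
    target_b: str = "B",
) -> pd.DataFrame:
    """Single mutations enriched in one gate and depleted in the reciprocal.

    Both tables must come from the two gates of one pairwise screen.
    Mutations observed in only one gate cannot be assessed and are listed in
    the returned frame's ``attrs['unpaired']``.
    """
    er_a = er_lookup(_singles(er_table_a))
    er_b = er_lookup(_singles(er_table_b))
    records = []
    shared = (set(er_a) & set(er_b)) - {PARENT_KEY}
    for key in sorted(shared):
        a, b = er_a[key], er_b[key]
        if a >= high_cut and b <= low_cut:
            direction = f"{target_b}->{target_a}"
        elif b >= high_cut and a <= low_cut:
            direction = f"{target_a}->{target_b}"
        else:
            continue
        records.append(
            {"mutation": key, "target_A": target_a, "target_B": target_b,
             "ER_A": a, "ER_B": b, "direction": direction}
        )
    out = pd.DataFrame(
        records, columns=["mutation", "target_A", "target_B", "ER_A", "ER_B", "direction"]
    )
    out.attrs["unpaired"] = sorted((set(er_a) ^ set(er_b)) - {PARENT_KEY})
    return out


def pairwise_selectivity(
    m1: str,
    m2: str,
    er_table_a: pd.DataFrame | Mapping[str, float],
    er_table_b: pd.DataFrame | Mapping[str, float],
) -> float:
    """Fold change of ER toward target A divided by the fold toward B.

    S = (ER_A(m2) / ER_A(m1)) / (ER_B(m2) / ER_B(m1)); S > 1 means moving
    from m1 to m2 shifts selectivity toward target A. The parent acts as the
    neutral reference (ER = 1). Returns NaN when any ER is missing.
    """
    lut_a = er_table_a if isinstance(er_table_a, Mapping) else er_lookup(er_table_a)
    lut_b = er_table_b if isinstance(er_table_b, Mapping) else er_lookup(er_table_b)
    try:
        return (lut_a[m2] / lut_a[m1]) / (lut_b[m2] / lut_b[m1])
    except KeyError:
        return float("nan")


def _double_positions(key: str) -> tuple[int, int]:
    subs = VariantKey.from_string(key).substitutions
    if len(subs) != 2:
        raise ValueError(f"{key!r} is not a double mutant")
    return subs[0].position, subs[1].position


def double_residue_map(enrichment: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sum ER over all double mutants sharing a mutated position pair.

    Returns the symmetric position x position matrix of summed ER and the
    matching matrix of contributing-variant counts N. The per-pair mean
    (sum / N) is a division away; the summed value is what the landscape
    heatmaps show.
    """
    doubles = enrichment[enrichment["n_mut"] == 2]
    sums: dict[tuple[int, int], float] = {}
    counts: dict[tuple[int, int], int] = {}
    for key, er in zip(doubles["variant_key"], doubles["ER"]):
        x, y = _double_positions(key)
        sums[(x, y)] = sums.get((x, y), 0.0) + float(er)
        counts[(x, y)] = counts.get((x, y), 0) + 1
    positions = sorted({p for pair in sums for p in pair})
    er_mat = pd.DataFrame(np.nan, index=positions, columns=positions)
    n_mat = pd.DataFrame(0, index=positions, columns=positions)
    for (x, y), total in sums.items():
        er_mat.loc[x, y] = er_mat.loc[y, x] = total
        n_mat.loc[x, y] = n_mat.loc[y, x] = counts[(x, y)]
    return er_mat, n_mat


def residue_pair_combination_map(
    enrichment: pd.DataFrame, x: int, y: int
) -> pd.DataFrame:
    """ER of each amino-acid combination of doubles at positions x and y.

    Rows are the substituting amino acid at x, columns at y. Cells are NaN
    where the combination was discarded or never observed.
    """
    if x == y:
        raise ValueError("positions must differ")
    doubles = enrichment[enrichment["n_mut"] == 2]
    cells: dict[tuple[str, str], float] = {}
    for key, er in zip(doubles["variant_key"], doubles["ER"]):
        subs = {s.position: s.mut_aa for s in VariantKey.from_string(key).substitutions}
        if set(subs) != {x, y}:
            continue
        cell = (subs[x], subs[y])
        if cell in cells:
            raise ValueError(f"duplicate double mutant at ({x},{y}): {key}")
        cells[cell] = float(er)
    mat = pd.DataFrame(np.nan, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS))
    for (aa_x, aa_y), er in cells.items():
        mat.loc[aa_x, aa_y] = er
    mat.index.name = f"aa_at_{x}"
    mat.columns.name = f"aa_at_{y}"
    return mat


def plot_heatmap(matrix: pd.DataFrame, path: str, title: str = "",
                 cmap: str = "RdYlGn_r", symmetric: bool = True) -> None:
    """Render a landscape matrix (log2 ER or summed ER) to an image file.

    With ``symmetric`` the color scale is centered on zero so enrichment and
    depletion get equal visual weight.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.to_numpy(dtype=float)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.5 * matrix.shape[1] + 2), 0.35 * matrix.shape[0] + 2)
    )
    vmax = np.nanmax(np.abs(data)) if np.isfinite(data).any() else 1.0
    kwargs = {"vmin": -vmax, "vmax": vmax} if symmetric else {}
    im = ax.imshow(data, aspect="auto", cmap=cmap, **kwargs)
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns])
    ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index])
    ax.set_xlabel(matrix.columns.name or "position")
    ax.set_ylabel(matrix.index.name or "substituting amino acid")
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def total_selectivity(relative_selectivities: Sequence[float]) -> float:
    """Product of per-competitor relative selectivities."""
    values = list(relative_selectivities)
    if not values:
        raise ValueError("need at least one relative selectivity")
    if any(v <= 0 for v in values):
        raise ValueError("relative selectivities must be positive")
    return float(np.prod(values))
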