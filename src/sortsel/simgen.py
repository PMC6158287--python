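"""Synthetic data with known ground truth: sort-seq libraries and kinetics.

The library simulator emulates the data-generating process the pipeline
assumes: a displayed variant roster (0-2 substitutions, loop-biased) with
lognormal naive abundances; FACS gating modeled as deterministic top-fraction
selection on per-cell log selection weight perturbed by lognormal display
noise; multinomial sequencing of the naive and gated pools into overlapping
paired-end reads with uniform per-base substitution errors and a two-segment
quality profile (high plateau, sagging tail). Every variant's ground-truth
enrichment proxy (its selection weight normalized by the abundance-weighted
mean weight) is recorded, so end-to-end runs can be scored against truth.

The kinetics simulator draws slow tight-binding progress curves over an
inhibitor titration from the same model the fitting code assumes
(Morrison steady-state velocities, exponential approach at kobs), plus
Gaussian noise scaled to the signal range.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import ProgressCurve, morrison_vs
from .variantcall import (
    AMINO_ACIDS,
    PARENT_KEY,
    ReferenceProtein,
    Substitution,
    VariantKey,
)

__all__ = [
    "LibrarySimSpec",
    "KineticsSimSpec",
    "SortSimulation",
    "build_roster",
    "pairwise_weight_column",
    "simulate_sort",
    "simulate_competitor_pool",
    "simulate_kinetics",
]

# deterministic codon per amino acid for building mutant ORFs
_PREFERRED_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT", "E": "GAA",
    "Q": "CAA", "G": "GGT", "H": "CAT", "I": "ATT", "L": "CTG", "K": "AAA",
    "M": "ATG", "F": "TTT", "P": "CCG", "S": "TCT", "T": "ACT", "W": "TGG",
    "Y": "TAT", "V": "GTT",
}

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT_LUT = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMPLEMENT_LUT[_a] = _b


@dataclass
class LibrarySimSpec:
    """Study conditions for one simulated sort-seq library."""

    reference: ReferenceProtein
    roster: pd.DataFrame  # variant_key, n_mut, abundance, weight_<target>...
    gate_fraction: float = 0.05
    depth: int = 100_000
    n_cells: int = 200_000
    error_rate: float = 1e-3
    read_len: int = 120
    display_noise_sd: float = 1.15
    low_quality_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gate_fraction <= 1.0:
            raise ValueError("gate_fraction must be in (0, 1]")
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if (self.roster["abundance"] <= 0).any():
            raise ValueError("abundances must be positive")


def build_roster(
    ref: ReferenceProtein,
    targets: Sequence[str],
    seed: int,
    n_doubles: int = 150,
    effect_sd: float = 0.6,
    hotspot: dict | None = None,
    abundance_sd: float = 0.5,
) -> pd.DataFrame:
    """Loop-saturating roster: all singles at loop positions plus doubles.

    Per-target selection weights are multiplicative over per-substitution
    effects drawn lognormally around neutrality (sd ``effect_sd`` in log
    space). ``hotspot`` maps a target to a position whose every substitution
    is forced to effect 0.5 (a constructed hot spot). Weights must be > 0.
    """
    rng = np.random.default_rng(seed)
    positions = sorted(ref.loop_positions)
    singles: list[VariantKey] = []
    for pos in positions:
        wt = ref.protein[ref.index_of(pos)]
        for aa in AMINO_ACIDS:
            if aa != wt:
                singles.append(VariantKey((Substitution(pos, wt, aa),)))

    doubles: set[VariantKey] = set()
    while len(doubles) < n_doubles:
        p1, p2 = sorted(rng.choice(positions, size=2, replace=False))
        wt1 = ref.protein[ref.index_of(int(p1))]
        wt2 = ref.protein[ref.index_of(int(p2))]
        a1 = AMINO_ACIDS[rng.integers(20)]
        a2 = AMINO_ACIDS[rng.integers(20)]
        if a1 == wt1 or a2 == wt2:
            continue
        doubles.add(VariantKey((Substitution(int(p1), wt1, a1),
                                Substitution(int(p2), wt2, a2))))
    variants = [VariantKey()] + singles + sorted(doubles, key=str)

    hotspot = hotspot or {}
    effects: dict[str, dict[str, float]] = {t: {} for t in targets}
    for t in targets:
        for v in singles:
            sub = v.substitutions[0]
            if hotspot.get(t) == sub.position:
                effects[t][str(sub)] = 0.5
            else:
                effects[t][str(sub)] = float(np.exp(rng.normal(0.0, effect_sd)))

    rows = []
    for v in variants:
        abundance = float(np.exp(rng.normal(0.0, abundance_sd)))
        if v.n_mut == 0:
            abundance *= 20.0  # parent dominates a naive library
        row = {"variant_key": str(v), "n_mut": v.n_mut, "abundance": abundance}
        for t in targets:
            w = 1.0
            for sub in v.substitutions:
                w *= effects[t][str(sub)]
            row[f"weight_{t}"] = w
        rows.append(row)
    return pd.DataFrame(rows)


def pairwise_weight_column(
    roster: pd.DataFrame, target: str, versus: str, name: str | None = None
) -> pd.DataFrame:
    """Add the gate weight of a pairwise screen: bright in ``target``, dim in
    ``versus`` — the ratio of the two binding weights."""
    name = name or f"weight_{target}_vs_{versus}"
    out = roster.copy()
    out[name] = roster[f"weight_{target}"] / roster[f"weight_{versus}"]
    return out


@dataclass
class SortSimulation:
    """Outputs of one simulated sort: counts, truth, optional FASTQ paths."""

    target: str
    naive_counts: dict
    sorted_counts: dict
    truth: pd.DataFrame
    files: dict = field(default_factory=dict)


def _variant_dna(key: str, ref: ReferenceProtein) -> str:
    dna = list(ref.dna)
    for sub in VariantKey.from_string(key).substitutions:
        idx = ref.index_of(sub.position)
        dna[3 * idx : 3 * idx + 3] = _PREFERRED_CODON[sub.mut_aa]
    return "".join(dna)


def _quality_profile(read_len: int) -> np.ndarray:
    """High plateau (Q38) over the first 70%, sagging linearly to Q30."""
    q = np.full(read_len, 38, dtype=int)
    tail = read_len - int(0.7 * read_len)
    if tail > 0:
        q[-tail:] = np.linspace(38, 30, tail).round().astype(int)
    return q


def _reads_for_variant(
    dna: str, n: int, read_len: int, error_rate: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """n error-bearing fragments -> (R1 array, R2 array) of uint8 bases."""
    frag = np.frombuffer(dna.encode(), dtype=np.uint8)
    reads = np.tile(frag, (n, 1))
    if error_rate > 0:
        err = rng.random(reads.shape) < error_rate
        n_err = int(err.sum())
        if n_err:
            # substitute with a uniformly random different base
            shift = rng.integers(1, 4, size=n_err)
            base_idx = np.searchsorted(_BASES, reads[err])
            reads[err] = _BASES[(base_idx + shift) % 4]
    r1 = reads[:, :read_len]
    r2 = _COMPLEMENT_LUT[reads[:, -read_len:]][:, ::-1]
    return r1, r2


def _write_fastq_pair(
    spec: LibrarySimSpec,
    counts: dict,
    prefix: Path,
    rng: np.random.Generator,
) -> tuple[Path, Path]:
    qual = _quality_profile(spec.read_len)
    qual_str = "".join(chr(q + 33) for q in qual)
    low_qual_str = chr(10 + 33) * spec.read_len
    r1_path = prefix.with_name(prefix.name + "_R1.fastq")
    r2_path = prefix.with_name(prefix.name + "_R2.fastq")
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        serial = 0
        for key in sorted(counts):
            n = counts[key]
            if n == 0:
                continue
            dna = _variant_dna(key, spec.reference)
            r1, r2 = _reads_for_variant(dna, n, spec.read_len, spec.error_rate, rng)
            degrade = (
                rng.random(n) < spec.low_quality_fraction
                if spec.low_quality_fraction > 0
                else np.zeros(n, dtype=bool)
            )
            for j in range(n):
                serial += 1
                q = low_qual_str if degrade[j] else qual_str
                f1.write(f"@sim_{prefix.name}_{serial}\n"
                         f"{r1[j].tobytes().decode()}\n+\n{q}\n")
                f2.write(f"@sim_{prefix.name}_{serial}\n"
                         f"{r2[j].tobytes().decode()}\n+\n{q}\n")
    return r1_path, r2_path


def _gate(
    spec: LibrarySimSpec, weights: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Cell-level top-fraction gate; returns per-variant selected-cell counts."""
    p = spec.roster["abundance"].to_numpy(float)
    p = p / p.sum()
    cells = rng.multinomial(spec.n_cells, p)
    variant_idx = np.repeat(np.arange(len(p)), cells)
    signal = np.log(weights)[variant_idx] + rng.normal(
        0.0, spec.display_noise_sd, size=len(variant_idx)
    )
    n_keep = max(1, int(round(spec.gate_fraction * len(variant_idx))))
    keep = np.argpartition(signal, -n_keep)[-n_keep:]
    return np.bincount(variant_idx[keep], minlength=len(p))


def simulate_sort(
    spec: LibrarySimSpec,
    target: str,
    outdir: str | Path | None = None,
    weight_column: str | None = None,
) -> SortSimulation:
    """Simulate one naive library and one sorted gate against ``target``.

    Naive reads are multinomial over abundances; sorted reads are multinomial
    over the composition of the top ``gate_fraction`` of cells ranked by
    noisy log selection weight. The truth table records each variant's
    weight-normalized abundance ratio as its expected-enrichment proxy.
    Fixed seed implies byte-identical FASTQ output.
    """
    rng = np.random.default_rng(spec.seed)
    roster = spec.roster
    col = weight_column or f"weight_{target}"
    weights = roster[col].to_numpy(float)
    if (weights <= 0).any():
        raise ValueError("selection weights must be positive")

    p_naive = roster["abundance"].to_numpy(float)
    p_naive = p_naive / p_naive.sum()
    naive_reads = rng.multinomial(spec.depth, p_naive)

    gated = _gate(spec, weights, rng)
    p_sorted = gated / gated.sum()
    sorted_reads = rng.multinomial(spec.depth, p_sorted)

    mean_w = float(np.sum(p_naive * weights))
    truth = roster[["variant_key", "n_mut", "abundance"]].copy()
    truth["weight"] = weights
    truth["true_er_proxy"] = weights / mean_w
    truth["naive_reads"] = naive_reads
    truth["sorted_reads"] = sorted_reads

    keys = roster["variant_key"].tolist()
    naive_counts = dict(zip(keys, naive_reads.tolist()))
    sorted_counts = dict(zip(keys, sorted_reads.tolist()))

    files: dict = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        files["naive"] = _write_fastq_pair(spec, naive_counts, outdir / "naive", rng)
        files[target] = _write_fastq_pair(
            spec, sorted_counts, outdir / f"sorted_{target}", rng
        )
    return SortSimulation(
        target=target, naive_counts=naive_counts, sorted_counts=sorted_counts,
        truth=truth, files=files,
    )


def simulate_competitor_pool(
    spec: LibrarySimSpec,
    target: str,
    competitors: Sequence[str],
    mode: str = "max",
    outdir: str | Path | None = None,
) -> SortSimulation:
    """One-target-versus-pooled-competitors sort.

    The gate weight is the target binding weight divided by the aggregated
    competitor weight (``max`` by default — the gate must beat the best
    competitor — or ``sum``). With a single competitor this reduces exactly
    to the pairwise mode.
    """
    if not competitors:
        raise ValueError("need at least one competitor")
    if mode not in ("max", "sum"):
        raise ValueError("mode must be 'max' or 'sum'")
    comp = np.stack(
        [spec.roster[f"weight_{c}"].to_numpy(float) for c in competitors]
    )
    agg = comp.max(axis=0) if mode == "max" else comp.sum(axis=0)
    col = f"weight_{target}_vs_pool"
    roster = spec.roster.copy()
    roster[col] = roster[f"weight_{target}"].to_numpy(float) / agg
    pooled_spec = replace(spec, roster=roster)
    sim = simulate_sort(pooled_spec, target, outdir=outdir, weight_column=col)
    sim.target = f"{target}_vs_pool"
    return sim


@dataclass
class KineticsSimSpec:
    """Study conditions for one simulated tight-binding titration.

    Concentrations in pM for enzyme/inhibitor; substrate and Km share any
    common unit. Enzyme defaults to the true Ki — the tight-binding regime
    where the Morrison quadratic is obligatory.
    """

    ki: float
    enzyme: float | None = None
    substrate: float = 100.0
    km: float = 100.0
    inhibitor_grid: np.ndarray | None = None
    t_end: float = 3600.0
    n_time_points: int = 61
    k_off: float = 2e-3
    kcat: float = 1.0
    noise_sd: float = 0.01  # fraction of each curve's signal range
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ki <= 0 or self.substrate <= 0 or self.km <= 0:
            raise ValueError("concentrations must be positive")
        if self.enzyme is None:
            self.enzyme = self.ki
        if self.inhibitor_grid is None:
            scale = self.enzyme + self.ki_app
            self.inhibitor_grid = np.array(
                [0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0]
            ) * scale

    @property
    def ki_app(self) -> float:
        return self.ki * (1.0 + self.substrate / self.km)


def simulate_kinetics(spec: KineticsSimSpec) -> tuple[list[ProgressCurve], dict]:
    """Progress curves over the titration, plus the generating truth."""
    rng = np.random.default_rng(spec.seed)
    t = np.linspace(0.0, spec.t_end, spec.n_time_points)
    v0 = spec.kcat * spec.enzyme * spec.substrate / (spec.substrate + spec.km)
    curves: list[ProgressCurve] = []
    truth_rows = []
    for rep in range(spec.n_replicates):
        for i_conc in np.asarray(spec.inhibitor_grid, dtype=float):
            vs = float(morrison_vs(np.array([i_conc]), v0, spec.ki_app, spec.enzyme)[0])
            kobs = spec.k_off * (1.0 + i_conc / spec.ki_app)
            clean = vs * t + (v0 - vs) * (1.0 - np.exp(-kobs * t)) / kobs
            span = clean.max() - clean.min()
            noisy = clean + rng.normal(0.0, spec.noise_sd * max(span, 1e-12), len(t))
            curves.append(
                ProgressCurve(
                    t=t, signal=noisy, enzyme=spec.enzyme, inhibitor=float(i_conc),
                    substrate=spec.substrate, km=spec.km,
                    curve_id=f"rep{rep}_I{i_conc:g}",
                )
            )
            truth_rows.append({"rep": rep, "inhibitor": float(i_conc),
                               "vs_true": vs, "kobs_true": kobs})
    truth = {
        "ki": spec.ki, "ki_app": spec.ki_app, "v0": v0,
        "enzyme": spec.enzyme, "curves": pd.DataFrame(truth_rows),
    }
    return curves, truth
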