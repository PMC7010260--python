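"""Synthetic sequence generation and recovery experiments.

Two generators cover the study conditions the estimator is validated under:

* :func:`simulate_jc_pair` — an i.i.d. uniform-ACGT ancestor copied with
  independent per-site Jukes-Cantor substitutions at total divergence d
  (child-from-parent at divergence d is marginally identical to two
  lineages of d/2 each under JC). No indels: the pair is globally
  homologous, which is the regime the indel-free expectation describes.
* :func:`embed_local_homology` — a homologous core pair embedded in
  unrelated i.i.d. random flanks, emulating genomes that share only a
  local region of homology. Flank totals are equal in the two output
  sequences and are split half left / half right (odd remainder right).

Experiment runners aggregate distance estimates over replicate pairs into
tidy tables: :func:`recovery_experiment` (estimated vs true distance) and
:func:`homology_ratio_experiment` (sensitivity to the homologous fraction).
All generators are bit-reproducible given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import estimate_distance
from .patterns import PatternSet
from .seq_io import NucleotideSequence
from .slope_model import ModelParams

__all__ = [
    "JCPairSpec",
    "LocalHomologySpec",
    "simulate_jc_pair",
    "embed_local_homology",
    "recovery_experiment",
    "homology_ratio_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class JCPairSpec:
    """A simulated pair: length L, Jukes-Cantor distance d, seed."""

    length: int
    distance: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"length must be >= 1, got {self.length}")
        if self.distance < 0:
            raise ValueError(f"distance must be >= 0, got {self.distance}")


@dataclass(frozen=True)
class LocalHomologySpec:
    """A homologous core pair to embed at homology fraction rho."""

    core_pair: tuple[NucleotideSequence, NucleotideSequence]
    homology_fraction: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.homology_fraction <= 1.0:
            raise ValueError(
                f"homology fraction must be in (0, 1], got {self.homology_fraction}"
            )


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def _random_codes(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n, dtype=np.uint8)


def substitution_probability(d: float) -> float:
    """Per-site substitution probability at JC distance d: (3/4)(1-e^(-4d/3))."""
    return 0.75 * (1.0 - np.exp(-4.0 * d / 3.0))


def simulate_jc_pair(spec: JCPairSpec) -> tuple[NucleotideSequence, NucleotideSequence]:
    """Generate a globally homologous pair at JC distance ``spec.distance``.

    Sequence 1 is i.i.d. uniform over ACGT; sequence 2 copies it with each
    site independently substituted (to one of the three other bases,
    uniformly) with probability (3/4)(1 - exp(-4d/3)).
    """
    rng = np.random.default_rng(spec.seed)
    s1 = _random_codes(rng, spec.length)
    m = substitution_probability(spec.distance)
    mutate = rng.random(spec.length) < m
    shift = rng.integers(1, 4, size=spec.length, dtype=np.uint8)
    s2 = np.where(mutate, (s1 + shift) % 4, s1).astype(np.uint8)
    tag = f"jc_L{spec.length}_d{spec.distance:g}_s{spec.seed}"
    return (
        NucleotideSequence(name=f"{tag}_a", records=[_decode(s1)]),
        NucleotideSequence(name=f"{tag}_b", records=[_decode(s2)]),
    )


def embed_local_homology(
    spec: LocalHomologySpec,
) -> tuple[NucleotideSequence, NucleotideSequence]:
    """Embed a homologous core pair in unrelated random flanks.

    Each output is left flank + core + right flank (cores with several
    records are concatenated first). Per sequence, the total flank length is
    core_length * (1 - rho) / rho, so the core makes up exactly the fraction
    rho of the output; the flanks of the two outputs are generated
    independently and share no designed homology. rho = 1 returns the core
    pair unchanged.
    """
    core_a, core_b = spec.core_pair
    rho = spec.homology_fraction
    if rho == 1.0:
        return core_a, core_b
    rng = np.random.default_rng(spec.seed)
    out = []
    for core, suffix in ((core_a, "a"), (core_b, "b")):
        core_str = "".join(core.records)
        flank_total = round(len(core_str) * (1.0 - rho) / rho)
        left = flank_total // 2
        right = flank_total - left
        seq = (
            _decode(_random_codes(rng, left))
            + core_str
            + _decode(_random_codes(rng, right))
        )
        out.append(
            NucleotideSequence(
                name=f"{core.name}_rho{rho:g}_{suffix}", records=[seq]
            )
        )
    return out[0], out[1]


def _replicate_seed(base_seed: int, *key: int) -> int:
    return int(
        np.random.SeedSequence(base_seed, spawn_key=tuple(key)).generate_state(1)[0]
        % (2**31)
    )


def recovery_experiment(
    d_grid: list[float],
    L: int,
    replicates: int,
    mode: str = "spaced",
    seed: int = 0,
    params: ModelParams | None = None,
    return_estimates: bool = False,
) -> pd.DataFrame:
    """Estimate known distances from simulated pairs and aggregate.

    For each true distance d in ``d_grid``, generates ``replicates``
    independent JC pairs of length L, runs the estimator and reports the
    mean and standard deviation of the successful estimates plus the number
    of failures (status other than ok). Replicate pairs depend only on
    (seed, grid index, replicate), never on the mode, so runs in k-mer and
    spaced mode with the same seed see identical sequence pairs.
    """
    if replicates < 2:
        raise ValueError(f"need >= 2 replicates, got {replicates}")
    patterns = PatternSet(mode, seed)
    rows = []
    detail = []
    for i, d in enumerate(d_grid):
        estimates = []
        failed = 0
        for r in range(replicates):
            a, b = simulate_jc_pair(JCPairSpec(L, d, _replicate_seed(seed, i, r)))
            est = estimate_distance(a, b, params=params, pattern_set=patterns)
            if est.ok:
                estimates.append(est.jc_distance)
            else:
                failed += 1
            if return_estimates:
                detail.append(
                    {
                        "d_true": d,
                        "replicate": r,
                        "estimate": est.jc_distance,
                        "status": est.status,
                    }
                )
        arr = np.asarray(estimates)
        rows.append(
            {
                "d_true": d,
                "mean_estimate": arr.mean() if arr.size else np.nan,
                "std_estimate": arr.std(ddof=1) if arr.size > 1 else np.nan,
                "n_ok": arr.size,
                "n_failed": failed,
            }
        )
    if return_estimates:
        return pd.DataFrame(rows), pd.DataFrame(detail)
    return pd.DataFrame(rows)


def homology_ratio_experiment(
    core_spec: JCPairSpec,
    rho_grid: list[float],
    replicates: int,
    seed: int = 0,
    mode: str = "spaced",
    params: ModelParams | None = None,
) -> pd.DataFrame:
    """Sensitivity of the estimator to the homologous fraction rho.

    Per replicate, a fresh JC core pair (length and distance from
    ``core_spec``) is estimated as-is (the rho = 1 baseline) and after
    embedding in random flanks at each rho in ``rho_grid``; the per-replicate
    ratio d(rho)/d(1) is aggregated into a mean and standard deviation per
    rho. Ratios are only formed when both estimates succeed.
    """
    if replicates < 2:
        raise ValueError(f"need >= 2 replicates, got {replicates}")
    patterns = PatternSet(mode, seed)
    ratios: dict[float, list[float]] = {rho: [] for rho in rho_grid}
    failed: dict[float, int] = {rho: 0 for rho in rho_grid}
    for r in range(replicates):
        core = simulate_jc_pair(
            JCPairSpec(core_spec.length, core_spec.distance, _replicate_seed(seed, 0, r))
        )
        base = estimate_distance(core[0], core[1], params=params, pattern_set=patterns)
        for j, rho in enumerate(rho_grid):
            emb = embed_local_homology(
                LocalHomologySpec(core, rho, seed=_replicate_seed(seed, 1, r, j))
            )
            est = estimate_distance(emb[0], emb[1], params=params, pattern_set=patterns)
            if base.ok and est.ok and base.jc_distance > 0:
                ratios[rho].append(est.jc_distance / base.jc_distance)
            else:
                failed[rho] += 1
    rows = []
    for rho in rho_grid:
        arr = np.asarray(ratios[rho])
        rows.append(
            {
                "rho": rho,
                "mean_ratio": arr.mean() if arr.size else np.nan,
                "std_ratio": arr.std(ddof=1) if arr.size > 1 else np.nan,
                "n_ok": arr.size,
                "n_failed": failed[rho],
            }
        )
    return pd.DataFrame(rows)


def write_table(table: pd.DataFrame, path) -> None:
    """Write an experiment table as tab-separated text with a header line."""
    table.to_csv(path, sep="\t", index=False)
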