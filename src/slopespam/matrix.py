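"""All-vs-all distance matrices and PHYLIP / TSV output."""

from __future__ import annotations

import logging
import math
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import SlopeSpaM
from .patterns import PatternSet
from .seq_io import NucleotideSequence
from .slope_model import KRangeError, ModelParams, SlopeEstimate

__all__ = ["DistanceMatrix", "all_pairs", "write_phylip", "read_phylip", "write_tsv"]

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric matrix of Jukes-Cantor distances with zero diagonal.

    Failed pairs (undefined F, p̂ out of range) hold NaN. ``estimates``
    keeps the per-pair fit details keyed by the unordered name pair;
    ``n_pairs_evaluated`` is the number of distinct pairs actually run.
    """

    labels: list[str]
    values: np.ndarray
    estimates: dict[frozenset, SlopeEstimate] = field(default_factory=dict)
    n_pairs_evaluated: int = 0

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match number of labels")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


def all_pairs(
    genomes: list[NucleotideSequence],
    mode: str = "spaced",
    params: ModelParams | None = None,
    seed: int = 0,
    strand_mode: str = "both",
    threads: int = 1,
) -> DistanceMatrix:
    """Estimate all n(n-1)/2 pairwise distances among ``genomes``.

    Patterns are generated once per weight and shared across pairs, so the
    result does not depend on input order or thread count. Raises on
    duplicate genome names before any computation.
    """
    if len(genomes) < 2:
        raise ValueError("need at least 2 genomes")
    names = [g.name for g in genomes]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate genome names: {dupes}")
    patterns = PatternSet(mode, seed)
    n = len(genomes)
    values = np.zeros((n, n))
    estimates: dict[frozenset, SlopeEstimate] = {}
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]

    def run(idx: tuple[int, int]) -> tuple[int, int, SlopeEstimate | None]:
        i, j = idx
        try:
            est = SlopeSpaM(
                genomes[i],
                genomes[j],
                params=params,
                strand_mode=strand_mode,
                pattern_set=patterns,
            ).fit().estimate
        except KRangeError as exc:
            logger.warning("%s vs %s: %s", names[i], names[j], exc)
            return i, j, None
        return i, j, est

    # warm the pattern cache serially so threads never race on it
    from .slope_model import compute_k_range

    for i, j in pairs:
        L = 0.5 * (genomes[i].total_length + genomes[j].total_length)
        try:
            kr = compute_k_range(L, params)
        except KRangeError:
            continue
        patterns.get(kr.k_min)
        patterns.get(kr.k_max)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            results = list(pool.map(run, pairs))
    else:
        results = [run(p) for p in pairs]

    for i, j, est in results:
        if est is None:
            d = math.nan
        else:
            estimates[frozenset((names[i], names[j]))] = est
            d = est.jc_distance
            if not est.ok:
                logger.warning(
                    "%s vs %s: status=%s, distance recorded as NaN",
                    names[i],
                    names[j],
                    est.status,
                )
            else:
                logger.info(
                    "%s vs %s: k=[%d,%d] F=(%.4f, %.4f) slope=%.5f p̂=%.5f d=%.5f",
                    names[i],
                    names[j],
                    est.k_range.k_min if est.k_range else -1,
                    est.k_range.k_max if est.k_range else -1,
                    est.F_kmin,
                    est.F_kmax,
                    est.slope,
                    est.p_hat,
                    est.jc_distance,
                )
        values[i, j] = values[j, i] = d
    return DistanceMatrix(
        labels=names, values=values, estimates=estimates, n_pairs_evaluated=len(pairs)
    )


def write_phylip(
    matrix: DistanceMatrix, path: str | Path, strict: bool = False
) -> Path:
    """Write a (relaxed) PHYLIP square distance matrix.

    Relaxed format: taxon count on the first line, then one whitespace-
    delimited row per taxon with the full name. NaN cells are written as -1
    and the affected pairs listed in '#' comment lines above the count line;
    ``strict=True`` refuses NaN and enforces 10-character padded names.
    """
    path = Path(path)
    n = len(matrix.labels)
    nan_pairs = [
        (matrix.labels[i], matrix.labels[j])
        for i in range(n)
        for j in range(i + 1, n)
        if math.isnan(matrix.values[i, j])
    ]
    if strict and nan_pairs:
        raise ValueError(
            "strict PHYLIP output refused, undefined distances for pairs: "
            + ", ".join(f"{a}/{b}" for a, b in nan_pairs)
        )
    lines = []
    if nan_pairs:
        lines.append(
            "# undefined distances written as -1 for pairs: "
            + ", ".join(f"{a}/{b}" for a, b in nan_pairs)
        )
    lines.append(str(n))
    for i, label in enumerate(matrix.labels):
        name = f"{label[:10]:<10}" if strict else label
        vals = " ".join(
            "-1" if math.isnan(v) else f"{v:.6f}" for v in matrix.values[i]
        )
        lines.append(f"{name} {vals}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Parse a square (relaxed) PHYLIP matrix written by :func:`write_phylip`."""
    lines = [
        ln for ln in Path(path).read_text().splitlines() if ln and not ln.startswith("#")
    ]
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for ln in lines[1 : n + 1]:
        parts = ln.split()
        labels.append(parts[0])
        rows.append([math.nan if v == "-1" else float(v) for v in parts[1:]])
    return DistanceMatrix(labels=labels, values=np.asarray(rows))


def write_tsv(matrix: DistanceMatrix, path: str | Path) -> Path:
    """Long-format TSV: one row per unordered pair with fit diagnostics."""
    path = Path(path)
    rows = []
    n = len(matrix.labels)
    for i in range(n):
        for j in range(i + 1, n):
            key = frozenset((matrix.labels[i], matrix.labels[j]))
            est = matrix.estimates.get(key)
            rows.append(
                {
                    "name1": matrix.labels[i],
                    "name2": matrix.labels[j],
                    "d": matrix.values[i, j],
                    "p_hat": est.p_hat if est else math.nan,
                    "k_min": est.k_range.k_min if est and est.k_range else -1,
                    "k_max": est.k_range.k_max if est and est.k_range else -1,
                    "status": est.status if est else "k_range_error",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path
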