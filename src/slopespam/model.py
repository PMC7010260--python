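"""Pairwise distance model: fit the slope of F(k) for two genomes.

:class:`SlopeSpaM` bundles a genome pair with the counting and design
choices (k-mer vs spaced-word mode, strand handling, range parameters);
``fit()`` chooses the pair-specific weight range from the average sequence
length, counts matches at k_min and k_max only, and returns a
:class:`SlopeSpaMResults` carrying the match-probability and distance
estimates plus diagnostics. Counting at just the two endpoint weights is
what makes the method fast; the full F(k) curve is computed only on demand
for diagnostic plots.
"""

from __future__ import annotations

import math

import pandas as pd

from .matching import MatchCount, count_matches
from .patterns import PatternSet
from .seq_io import NucleotideSequence
from .slope_model import (
    KRange,
    KRangeError,
    ModelParams,
    SlopeEstimate,
    compute_k_range,
    estimate_match_probability,
    log_corrected_count,
    min_match_probability,
)

__all__ = ["SlopeSpaM", "SlopeSpaMResults", "estimate_distance"]


class SlopeSpaM:
    """Match-count decay model for one pair of genomes.

    Parameters
    ----------
    seq1, seq2
        The genomes to compare.
    mode
        "spaced" (default) uses one random pattern per required weight with
        match-position probability ``match_prob``; "kmer" uses contiguous
        words. Spaced words give statistically more stable estimates.
    params
        Affine-linear-range design parameters (see :class:`ModelParams`).
    pattern_seed
        Seed for spaced-pattern generation; ignored in k-mer mode.
    strand_mode
        "both" (default) also counts matches against the reverse complement
        of the second sequence; "single" is intended for validation against
        the indel-free, forward-strand theory.
    pattern_set
        Optional pre-built shared :class:`PatternSet` (used by all-vs-all
        runs so every pair shares the same P_k); overrides mode/seed.
    """

    def __init__(
        self,
        seq1: NucleotideSequence,
        seq2: NucleotideSequence,
        mode: str = "spaced",
        params: ModelParams | None = None,
        pattern_seed: int = 0,
        strand_mode: str = "both",
        match_prob: float = 0.5,
        pattern_set: PatternSet | None = None,
    ):
        # canonical internal order => distance is exactly symmetric in its
        # arguments even for non-palindromic spaced patterns
        if (seq2.name, seq2.total_length) < (seq1.name, seq1.total_length):
            seq1, seq2 = seq2, seq1
        self.seq1 = seq1
        self.seq2 = seq2
        self.params = params or ModelParams()
        self.strand_mode = strand_mode
        self.patterns = pattern_set or PatternSet(mode, pattern_seed, match_prob)
        self.mode = self.patterns.mode

    @property
    def average_length(self) -> float:
        return 0.5 * (self.seq1.total_length + self.seq2.total_length)

    def k_range(self) -> KRange:
        return compute_k_range(self.average_length, self.params)

    def _F(self, n_matches: float, k: int) -> float:
        return log_corrected_count(
            n_matches,
            self.seq1.total_length,
            self.seq2.total_length,
            k,
            q=self.params.q,
            model="general_two_strand",
        )

    def fit(self) -> "SlopeSpaMResults":
        """Estimate the match probability and Jukes-Cantor distance.

        Identical sequence content short-circuits to distance 0. A
        :class:`KRangeError` (sequences too short) propagates to the caller;
        an undefined F at either endpoint is reported through the result's
        status, not as an exception.
        """
        if self.seq1.records == self.seq2.records:
            est = SlopeEstimate(
                F_kmin=math.nan,
                F_kmax=math.nan,
                slope=0.0,
                p_hat=1.0,
                jc_distance=0.0,
                status="ok",
            )
            return SlopeSpaMResults(self, est, counts={})
        k_range = self.k_range()
        counts: dict[int, MatchCount] = {}
        F = {}
        for k in (k_range.k_min, k_range.k_max):
            counts[k] = count_matches(
                self.seq1, self.seq2, self.patterns.get(k), self.strand_mode
            )
            F[k] = self._F(counts[k].n_matches, k)
        est = estimate_match_probability(
            F[k_range.k_min], F[k_range.k_max], k_range
        )
        return SlopeSpaMResults(self, est, counts)

    def diagnostic_curve(self, pad: int = 2) -> pd.DataFrame:
        """F(k) over [k_min - pad, k_max + pad] for curve plots.

        Returns a DataFrame with columns k, pattern, n_matches, F; F is NaN
        where the background-corrected count is non-positive.
        """
        k_range = self.k_range()
        rows = []
        for k in range(max(1, k_range.k_min - pad), k_range.k_max + pad + 1):
            mc = count_matches(
                self.seq1, self.seq2, self.patterns.get(k), self.strand_mode
            )
            rows.append(
                {
                    "k": k,
                    "pattern": str(mc.pattern),
                    "n_matches": mc.n_matches,
                    "F": self._F(mc.n_matches, k),
                }
            )
        return pd.DataFrame(rows)


class SlopeSpaMResults:
    """Fitted estimates and diagnostics for one genome pair."""

    def __init__(
        self,
        model: SlopeSpaM,
        estimate: SlopeEstimate,
        counts: dict[int, MatchCount],
    ):
        self.model = model
        self.estimate = estimate
        self.counts = counts

    # conveniences mirroring the underlying estimate
    @property
    def distance(self) -> float:
        """Jukes-Cantor distance in substitutions per site (NaN if not ok)."""
        return self.estimate.jc_distance

    @property
    def p_hat(self) -> float:
        return self.estimate.p_hat

    @property
    def slope(self) -> float:
        return self.estimate.slope

    @property
    def status(self) -> str:
        return self.estimate.status

    @property
    def ok(self) -> bool:
        return self.estimate.ok

    def summary(self) -> str:
        """Human-readable fit report."""
        m, e = self.model, self.estimate
        lines = [
            "Slope-SpaM distance estimate",
            "=" * 40,
            f"pair:            {m.seq1.name}  vs  {m.seq2.name}",
            f"lengths:         {m.seq1.total_length:,}  /  {m.seq2.total_length:,}",
            f"mode:            {m.mode} ({m.strand_mode} strand)",
        ]
        if e.k_range is not None:
            kr = e.k_range
            lines.append(f"k range:         [{kr.k_min}, {kr.k_max}] (L̄ = {kr.L_effective:,.0f})")
            for k in sorted(self.counts):
                mc = self.counts[k]
                Fv = e.F_kmin if k == kr.k_min else e.F_kmax
                lines.append(
                    f"  k={k:<3d} P={str(mc.pattern)}  N_k={mc.n_matches:<12,d} F(k)={Fv:.4f}"
                )
            lines.append(
                f"min usable p:    {min_match_probability(kr.L_effective, m.params):.4f}"
            )
        lines += [
            f"slope:           {e.slope:.6f}",
            f"match prob p̂:    {e.p_hat:.6f}" + ("  (clamped)" if e.clamped else ""),
            f"JC distance d:   {e.jc_distance:.6f}",
            f"status:          {e.status}",
        ]
        return "\n".join(lines)

    def diagnostic_curve(self, pad: int = 2) -> pd.DataFrame:
        return self.model.diagnostic_curve(pad=pad)

    def plot_curve(self, ax=None, pad: int = 2):
        """Plot F(k) against k with the fitted range marked."""
        import matplotlib.pyplot as plt

        curve = self.diagnostic_curve(pad=pad)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(curve["k"], curve["F"], "o-", label="F(k)")
        if self.estimate.k_range is not None:
            kr = self.estimate.k_range
            ax.axvspan(kr.k_min, kr.k_max, alpha=0.15, label="fitted range")
        ax.set_xlabel("word weight k")
        ax.set_ylabel("F(k)")
        ax.set_title(f"{self.model.seq1.name} vs {self.model.seq2.name}")
        ax.legend()
        return ax


def estimate_distance(
    a: NucleotideSequence,
    b: NucleotideSequence,
    mode: str = "spaced",
    params: ModelParams | None = None,
    seed: int = 0,
    strand_mode: str = "both",
    pattern_set: PatternSet | None = None,
) -> SlopeEstimate:
    """One-call distance estimate for a genome pair (see :class:`SlopeSpaM`)."""
    return SlopeSpaM(
        a,
        b,
        mode=mode,
        params=params,
        pattern_seed=seed,
        strand_mode=strand_mode,
        pattern_set=pattern_set,
    ).fit().estimate
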