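"""Closed-form machinery of the slope estimator.

Model: two DNA sequences that diverged under the Jukes-Cantor substitution
model. Homologous positions match with probability p, background positions
with probability q (≈ 1/4 for DNA). The expected number of weight-k word
matches decomposes into a homologous term decaying like p^k and a background
term decaying like q^k:

    indel-free, global homology:  E[X_k] = (L-k+1) p^k + (L-k+1)(L-k) q^k
    general (indels, local homology, both strands):
                                  E[X_k] ≈ L_H p^k + 2 L1 L2 q^k

Subtracting the background from the observed count N_k and taking logs gives

    F(k) = ln(N_k - B(k)),   B(k) = 2 L1 L2 q^k   (general)
                             B(k) = (L-k+1)(L-k) q^k   (indel-free)

which is approximately affine-linear in k with slope ln p wherever
homologous matches both dominate the background and remain numerous. The
bounds of that range yield pair-specific weights k_min and k_max; p is then
estimated as exp of the finite-difference slope of F between them, and the
Jukes-Cantor correction turns p̂ into a distance in substitutions per site:

    d = -(3/4) ln(1 - (4/3)(1 - p̂))
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "ModelParams",
    "KRange",
    "SlopeEstimate",
    "KRangeError",
    "expected_match_count",
    "log_corrected_count",
    "compute_k_range",
    "min_match_probability",
    "estimate_match_probability",
    "jukes_cantor_distance",
    "jukes_cantor_match_probability",
]


class KRangeError(ValueError):
    """Sequences too short for a non-empty affine-linear range."""


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the affine-linear-range design.

    q is the background match probability (1/4 for uniform DNA); alpha
    requires homologous matches to outnumber background matches by that
    factor at k_min; beta is the minimum expected number of homologous
    matches at k_max; p_prime_kmin / p_prime_kmax are the design match
    probabilities the bounds are evaluated at — the estimator is reliable
    for any true p above them. Defaults are the values that reduce the
    bounds to ceil((ln L + 0.69)/0.875) and floor(ln L / 0.634).
    """

    q: float = 0.25
    alpha: float = 1.0
    beta: float = 1.0
    p_prime_kmin: float = 0.6
    p_prime_kmax: float = 0.53

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError(f"q must be in (0, 1), got {self.q}")
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.beta < 1:
            raise ValueError(f"beta must be >= 1, got {self.beta}")
        if not self.q < self.p_prime_kmax <= self.p_prime_kmin < 1.0:
            raise ValueError(
                "need q < p_prime_kmax <= p_prime_kmin < 1, got "
                f"q={self.q}, p'_kmax={self.p_prime_kmax}, p'_kmin={self.p_prime_kmin}"
            )


@dataclass(frozen=True)
class KRange:
    """Pair-specific word-weight range with the parameters that produced it."""

    k_min: int
    k_max: int
    L_effective: float
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if not 1 <= self.k_min < self.k_max:
            raise KRangeError(
                f"need 1 <= k_min < k_max, got k_min={self.k_min}, k_max={self.k_max}"
            )

    @property
    def span(self) -> int:
        return self.k_max - self.k_min


@dataclass(frozen=True)
class SlopeEstimate:
    """Result of the slope fit for one sequence pair.

    status is "ok" when both F values exist and p̂ > 1/4; "F_undefined" when
    the background-corrected count is non-positive at either end of the
    range (sequences too diverged or too short); "p_out_of_range" when p̂
    falls below the Jukes-Cantor domain boundary 1/4. jc_distance is NaN
    unless status is "ok". clamped records a positive raw slope (sampling
    noise on near-identical sequences) truncated to p̂ = 1.
    """

    F_kmin: float
    F_kmax: float
    slope: float
    p_hat: float
    jc_distance: float
    status: str
    k_range: KRange | None = None
    clamped: bool = False

    @property
    def ok(self) -> bool:
        return self.status == "ok"


def expected_match_count(
    L1: float,
    L2: float,
    k: int,
    p: float,
    q: float,
    model: str = "general_two_strand",
    L_H: float | None = None,
) -> float:
    """Expected number of weight-k word matches under the evolution model.

    ``indel_free_global`` requires L1 == L2 and uses L - k + 1 homologous
    window pairs plus (L-k+1)(L-k) single-strand background pairs.
    ``general_two_strand`` uses L_H homologous windows plus the two-strand
    background 2 L1 L2 q^k.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not (0 <= p <= 1 and 0 <= q <= 1):
        raise ValueError(f"p and q must be probabilities, got p={p}, q={q}")
    if model == "indel_free_global":
        if L1 != L2:
            raise ValueError("indel_free_global model requires equal lengths")
        L = L1
        return (L - k + 1) * p**k + (L - k + 1) * (L - k) * q**k
    if model == "general_two_strand":
        if L_H is None:
            raise ValueError("general_two_strand model requires L_H")
        return L_H * p**k + 2.0 * L1 * L2 * q**k
    raise ValueError(f"unknown model {model!r}")


def log_corrected_count(
    n_matches: float,
    L1: float,
    L2: float,
    k: int,
    q: float = 0.25,
    model: str = "general_two_strand",
) -> float:
    """F(k): log of the observed count minus the expected background.

    Returns NaN when N_k does not exceed the background term, in which case
    the transform is undefined and no slope can be taken at this weight.
    """
    if n_matches < 0:
        raise ValueError(f"n_matches must be >= 0, got {n_matches}")
    if model == "general_two_strand":
        background = 2.0 * L1 * L2 * q**k
    elif model == "indel_free_global":
        if L1 != L2:
            raise ValueError("indel_free_global model requires equal lengths")
        background = (L1 - k + 1) * (L1 - k) * q**k
    else:
        raise ValueError(f"unknown model {model!r}")
    excess = n_matches - background
    if excess <= 0:
        return math.nan
    return math.log(excess)


def compute_k_range(L: float, params: ModelParams | None = None) -> KRange:
    """Word-weight range [k_min, k_max] for average sequence length L.

        k_min = ceil( (ln L + ln 2 + ln alpha) / (ln p'_kmin - ln q) )
        k_max = floor( (ln beta - ln L) / ln p'_kmax )

    With default parameters these reduce to ceil((ln L + 0.69)/0.875) and
    floor(ln L / 0.634). Raises :class:`KRangeError` when k_min >= k_max
    (sequences too short for the default design probabilities).
    """
    params = params or ModelParams()
    if L < 2:
        raise ValueError(f"average length must be >= 2, got {L}")
    lnL = math.log(L)
    k_min = math.ceil(
        (lnL + math.log(2.0) + math.log(params.alpha))
        / (math.log(params.p_prime_kmin) - math.log(params.q))
    )
    k_max = math.floor((math.log(params.beta) - lnL) / math.log(params.p_prime_kmax))
    if k_min >= k_max:
        raise KRangeError(
            f"empty affine-linear range for L={L:g}: k_min={k_min}, k_max={k_max}; "
            "sequences are too short for the chosen design probabilities"
        )
    return KRange(k_min=k_min, k_max=k_max, L_effective=float(L), params=params)


def min_match_probability(L: float, params: ModelParams | None = None) -> float:
    """Smallest match probability p for which the range can be non-empty.

    Diagnostic bound exp[ln q (ln L - ln beta) / (2 ln L + ln 2 + ln alpha
    - ln beta)]; distances whose p falls below it are outside the method's
    reach at this sequence length.
    """
    params = params or ModelParams()
    if L < 2:
        raise ValueError(f"length must be >= 2, got {L}")
    lnL, lnb = math.log(L), math.log(params.beta)
    num = math.log(params.q) * (lnL - lnb)
    den = 2.0 * lnL + math.log(2.0) + math.log(params.alpha) - lnb
    return math.exp(num / den)


def estimate_match_probability(
    F_kmin: float, F_kmax: float, k_range: KRange
) -> SlopeEstimate:
    """Slope of F over the range and the resulting match probability p̂.

    slope = (F(k_max) - F(k_min)) / (k_max - k_min); p̂ = exp(slope),
    clamped to 1 when sampling noise makes the slope positive. The
    Jukes-Cantor correction is applied when p̂ is inside its domain.
    """
    if math.isnan(F_kmin) or math.isnan(F_kmax):
        return SlopeEstimate(
            F_kmin=F_kmin,
            F_kmax=F_kmax,
            slope=math.nan,
            p_hat=math.nan,
            jc_distance=math.nan,
            status="F_undefined",
            k_range=k_range,
        )
    slope = (F_kmax - F_kmin) / k_range.span
    clamped = slope > 0
    p_hat = min(math.exp(slope), 1.0)
    if p_hat <= 0.25:
        return SlopeEstimate(
            F_kmin=F_kmin,
            F_kmax=F_kmax,
            slope=slope,
            p_hat=p_hat,
            jc_distance=math.nan,
            status="p_out_of_range",
            k_range=k_range,
            clamped=clamped,
        )
    return SlopeEstimate(
        F_kmin=F_kmin,
        F_kmax=F_kmax,
        slope=slope,
        p_hat=p_hat,
        jc_distance=jukes_cantor_distance(p_hat),
        status="ok",
        k_range=k_range,
        clamped=clamped,
    )


def jukes_cantor_distance(p_hat: float) -> float:
    """Jukes-Cantor distance d = -(3/4) ln(1 - (4/3)(1 - p̂)).

    Valid for match probabilities p̂ in (1/4, 1]; inverse of
    p = 1/4 + (3/4) exp(-4d/3) to machine precision.
    """
    if not 0.25 < p_hat <= 1.0:
        raise ValueError(
            f"Jukes-Cantor correction needs 1/4 < p <= 1, got {p_hat}"
        )
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * (1.0 - p_hat))


def jukes_cantor_match_probability(d: float) -> float:
    """Match probability at Jukes-Cantor distance d: 1/4 + (3/4) e^(-4d/3)."""
    if d < 0:
        raise ValueError(f"distance must be >= 0, got {d}")
    return 0.25 + 0.75 * math.exp(-4.0 * d / 3.0)
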