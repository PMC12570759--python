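"""Chained-binomial tests of whether eDNA donates spacer sequences.

If free phage DNA (eDNA) were the template for new CRISPR spacers, BIMs
obtained after supplementing a specific DNA fragment should preferentially
carry spacers mapping back to that fragment.  The test chains a ledger of
probability factors — the fraction of BIMs attributable to the eDNA
effect, the share of eDNA that is the supplemented fragment, the fraction
of protospacers the detection assay covers, sampling losses — into a
per-trial success probability p, then asks how surprising observing
*zero* successes in n independent trials would be: P0 = (1 - p)^n.  A
small P0 rejects the sequence-donation hypothesis.

Each factor carries a free-form provenance note so the whole assumption
trail is auditable, and a retention-sensitivity bound quantifies how much
combined DNA loss (extraction + PCR inefficiency) the rejection survives.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

from scipy import stats

__all__ = [
    "AssumptionFactor",
    "AssumptionLedger",
    "ProvenanceResult",
    "RetentionBound",
    "InconsistentLedgerError",
    "attributable_fraction",
    "supplementation_share",
    "combine_ledger",
    "zero_detection_probability",
    "binomial_pmf",
    "binomial_cdf",
    "expected_bims",
    "retention_sensitivity",
    "fragment_mapping_ledger",
    "multiplex_detection_ledger",
    "run_provenance_test",
]


class InconsistentLedgerError(ValueError):
    """The combined per-trial probability exceeds 1."""


@dataclass(frozen=True)
class AssumptionFactor:
    """One probability factor with its provenance note."""

    label: str
    value: float
    provenance: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValueError(
                f"factor {self.label!r} must lie in [0, 1], got {self.value}"
            )


@dataclass(frozen=True)
class AssumptionLedger:
    """Sum-of-products expression for the per-trial success probability.

    ``terms`` is a list of terms; each term is a list of factors whose
    values are multiplied, and the terms are summed.  This covers both a
    pure product of assumptions and a product-plus-background form such
    as "(chance via eDNA) + (background chance)".
    """

    terms: tuple[tuple[AssumptionFactor, ...], ...]
    n_trials: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.n_trials < 0:
            raise ValueError("n_trials must be >= 0")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")

    @classmethod
    def from_terms(
        cls,
        terms: Sequence[Sequence["AssumptionFactor | float | tuple"]],
        n_trials: int,
        alpha: float = 0.05,
    ) -> "AssumptionLedger":
        def coerce(f) -> AssumptionFactor:
            if isinstance(f, AssumptionFactor):
                return f
            if isinstance(f, (int, float)):
                return AssumptionFactor("unnamed", float(f))
            label, value, *rest = f
            return AssumptionFactor(label, float(value), *(rest or [""]))

        return cls(
            terms=tuple(tuple(coerce(f) for f in term) for term in terms),
            n_trials=int(n_trials),
            alpha=alpha,
        )

    @classmethod
    def from_json(cls, source) -> "AssumptionLedger":
        """Load a ledger from a JSON file path, file object, or string."""
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        terms = tuple(
            tuple(
                AssumptionFactor(
                    f["label"], float(f["value"]), f.get("provenance", "")
                )
                for f in term
            )
            for term in payload["terms"]
        )
        return cls(
            terms=terms,
            n_trials=int(payload["n_trials"]),
            alpha=float(payload.get("alpha", 0.05)),
        )

    def to_json(self) -> str:
        return json.dumps(
            {
                "terms": [[asdict(f) for f in term] for term in self.terms],
                "n_trials": self.n_trials,
                "alpha": self.alpha,
            },
            indent=2,
        )


def attributable_fraction(fold_change: float) -> float:
    """Fraction of BIMs attributable to the eDNA effect, from a fold change.

    For an *increase* f >= 0 (e.g. f = 0.7 for 70% more BIMs), the excess
    BIMs are f/(1+f) of the total.  For a *reduction* expressed as a
    negative fold change (e.g. -0.4 for 40% fewer BIMs after removing
    eDNA), the lost fraction is attributable directly: returns -f.
    """
    if fold_change <= -1.0:
        raise ValueError(
            f"fold change must exceed -1 (total loss), got {fold_change}"
        )
    if fold_change >= 0.0:
        return fold_change / (1.0 + fold_change)
    return -fold_change


def supplementation_share(supplemented: float, background: float) -> float:
    """Share of eDNA that is the supplemented DNA (mass fraction)."""
    if supplemented < 0 or background < 0:
        raise ValueError("concentrations must be non-negative")
    total = supplemented + background
    if total == 0:
        raise ValueError("supplemented and background cannot both be zero")
    return supplemented / total


def combine_ledger(ledger: AssumptionLedger) -> float:
    """Evaluate the sum-of-products ledger into a per-trial probability."""
    p = sum(math.prod(f.value for f in term) for term in ledger.terms)
    if p > 1.0:
        raise InconsistentLedgerError(
            f"combined per-trial probability {p} exceeds 1; "
            "the ledger terms are inconsistent"
        )
    return p


def zero_detection_probability(p: float, n: int) -> float:
    """P(zero successes in n independent trials) = (1 - p)^n.

    Computed in log space (``exp(n * log1p(-p))``) so that small
    probabilities at large n (thousands of trials) keep full precision.
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"p must lie in [0, 1], got {p}")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if n == 0 or p == 0.0:
        return 1.0
    if p == 1.0:
        return 0.0
    return math.exp(n * math.log1p(-p))


def binomial_pmf(k: int, n: int, p: float) -> float:
    """Binomial point mass P(X = k)."""
    return float(stats.binom.pmf(k, n, p))


def binomial_cdf(k: int, n: int, p: float) -> float:
    """Binomial lower tail P(X <= k)."""
    return float(stats.binom.cdf(k, n, p))


def expected_bims(
    cultures: int, volume_ml: float, cfu_per_ml: float, acquisition_rate: float
) -> float:
    """Expected number of independent BIMs across liquid cultures.

    The product cultures x volume x cell density x per-cell spacer
    acquisition rate; each expected BIM is one trial of the provenance
    test.
    """
    for name, v in (
        ("cultures", cultures),
        ("volume_ml", volume_ml),
        ("cfu_per_ml", cfu_per_ml),
        ("acquisition_rate", acquisition_rate),
    ):
        if v < 0:
            raise ValueError(f"{name} must be >= 0, got {v}")
    return cultures * volume_ml * cfu_per_ml * acquisition_rate


@dataclass(frozen=True)
class RetentionBound:
    """Sensitivity of the rejection to combined DNA-retention losses.

    ``r_star`` is the smallest retention multiplier r for which
    ``(1 - r * p_full)^n <= alpha`` still holds; ``rejectable`` is False
    when even full retention (r = 1) cannot reach alpha.
    """

    r_star: float
    rejectable: bool
    p_full: float
    n: int
    alpha: float

    def predicate(self, retention: float) -> bool:
        """Does the test still reject at this retention multiplier?"""
        if not (0.0 <= retention <= 1.0):
            raise ValueError("retention must lie in [0, 1]")
        return (
            zero_detection_probability(retention * self.p_full, self.n)
            <= self.alpha
        )


def retention_sensitivity(p_full: float, n: int, alpha: float) -> RetentionBound:
    """Solve for the minimal DNA-retention rate preserving the rejection.

    From ``(1 - r p)^n <= alpha``: ``r* = (1 - alpha^(1/n)) / p``.
    """
    if not (0.0 < p_full <= 1.0):
        raise ValueError(f"p_full must lie in (0, 1], got {p_full}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    r_star = -math.expm1(math.log(alpha) / n) / p_full
    return RetentionBound(
        r_star=r_star,
        rejectable=r_star <= 1.0,
        p_full=p_full,
        n=n,
        alpha=alpha,
    )


@dataclass(frozen=True)
class ProvenanceResult:
    """Outcome of a zero-detection provenance test with its audit trail."""

    p_per_trial: float
    n_trials: int
    p_zero: float
    reject: bool
    alpha: float
    ledger: AssumptionLedger
    observed_zero: bool = True

    def to_json(self) -> str:
        return json.dumps(
            {
                "p_per_trial": self.p_per_trial,
                "n_trials": self.n_trials,
                "p_zero": self.p_zero,
                "reject": self.reject,
                "alpha": self.alpha,
                "observed_zero": self.observed_zero,
                "ledger": json.loads(self.ledger.to_json()),
            },
            indent=2,
        )


def fragment_mapping_ledger(
    attributable: float = 0.427,
    cr1_fraction: float = 0.9,
    background: float = 0.03,
    n_trials: int = 16,
    alpha: float = 0.05,
    coherent: bool = False,
) -> AssumptionLedger:
    """Ledger for the spacer-back-mapping test of a supplemented fragment.

    Per sequenced BIM, the chance its spacer maps to the fragment is the
    chance it is an eDNA-driven CR1 acquisition (cr1_fraction x
    attributable) plus a background chance (the fragment's share of all
    protospacers) for the rest.  ``coherent=False`` (default) adds the
    background as a plain extra term; ``coherent=True`` weights the
    background by the non-eDNA fraction so the two terms partition the
    BIMs.
    """
    edna_term = (
        AssumptionFactor("cr1_fraction", cr1_fraction, "share of acquisitions in CR1"),
        AssumptionFactor(
            "attributable", attributable, "fraction of BIMs due to the eDNA effect"
        ),
    )
    if coherent:
        bg_term = (
            AssumptionFactor(
                "non_edna_fraction",
                1.0 - cr1_fraction * attributable,
                "complement of the eDNA term",
            ),
            AssumptionFactor(
                "background", background, "fragment's share of all protospacers"
            ),
        )
    else:
        bg_term = (
            AssumptionFactor(
                "background", background, "fragment's share of all protospacers"
            ),
        )
    return AssumptionLedger(
        terms=(edna_term, bg_term), n_trials=n_trials, alpha=alpha
    )


def multiplex_detection_ledger(
    attributable: float = 0.40,
    supplement_share: float = 10.0 / 10.5,
    target_fraction: float = 10.0 / 234.0,
    template_fraction: float = 0.25,
    n_trials: int = 3500,
    alpha: float = 0.05,
) -> AssumptionLedger:
    """Ledger for the multiplex-PCR detection of non-protective spacers.

    A single product term: fraction of BIMs due to eDNA, share of eDNA
    that is the supplemented related-phage DNA, fraction of that phage's
    protospacers the multiplex primer mix targets, and the fraction of
    extracted DNA used as PCR template.
    """
    return AssumptionLedger(
        terms=(
            (
                AssumptionFactor(
                    "attributable", attributable, "fraction of BIMs due to eDNA"
                ),
                AssumptionFactor(
                    "supplement_share",
                    supplement_share,
                    "supplemented DNA over total phage eDNA",
                ),
                AssumptionFactor(
                    "target_fraction",
                    target_fraction,
                    "protospacers covered by the multiplex primer mix",
                ),
                AssumptionFactor(
                    "template_fraction",
                    template_fraction,
                    "share of extracted DNA used in the PCR",
                ),
            ),
        ),
        n_trials=n_trials,
        alpha=alpha,
    )


def run_provenance_test(
    ledger: AssumptionLedger, observed_zero: bool = True
) -> ProvenanceResult:
    """Combine the ledger, compute the zero-detection probability, and
    decide rejection at the ledger's alpha.

    The rejection is only meaningful when zero successes were actually
    observed (``observed_zero=True``); with successes observed the
    zero-detection probability is reported but ``reject`` is False by
    construction (the hypothesis predicted successes and got them).
    """
    p = combine_ledger(ledger)
    p_zero = zero_detection_probability(p, ledger.n_trials)
    reject = observed_zero and p_zero < ledger.alpha
    return ProvenanceResult(
        p_per_trial=p,
        n_trials=ledger.n_trials,
        p_zero=p_zero,
        reject=reject,
        alpha=ledger.alpha,
        ledger=ledger,
        observed_zero=observed_zero,
    )
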