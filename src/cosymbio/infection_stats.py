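"""Infection calling, prevalence/coinfection statistics, and titer estimation.

The study design this module serves: single host individuals are assayed by
PCR for each of two endosymbionts (here *Cardinium* and *Wolbachia*), with a
universal host 18S rRNA PCR as an extraction control.  A negative symbiont
assay is only believed when the host control amplified; otherwise the
individual is *invalid* for that symbiont and excluded from denominators.

Prevalence is the fraction of valid individuals testing positive, with a
Wilson score (default) or Clopper–Pearson interval.  Coinfection is
summarised as the 2x2 table of jointly-valid individuals, a nestedness flag
(no individual carries symbiont B without symbiont A), and a two-sided
Fisher exact test.

Titer ("intensity") converts relative sequencing depth into cells per
infected host: with symbiont depth ``d_s``, the depth ``d_h`` of a
single-copy host gene, population prevalence ``p``, and an assumed ``N``
host cells per individual,

    cells = (d_s * p) / (d_h / N)          (``as_printed``)
    cells = (d_s / p) / (d_h / N)          (``per_infected_alternative``)

The first form is the arithmetic used in the source analyses and is the
default; the second treats prevalence as a dilution factor of the pooled
sample and is exposed explicitly, never silently substituted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

from scipy.stats import fisher_exact
from statsmodels.stats.proportion import proportion_confint

from .display import floor_percent
from .errors import CosymbioError, EmptyInputError, UsageError, ValidationError
from .types import PanelRow, PcrPanel

logger = logging.getLogger("cosymbio.infection")

SYMBIONTS = ("cardinium", "wolbachia")
CI_METHODS = ("wilson", "clopper_pearson", "none")


@dataclass(frozen=True)
class InfectionCall:
    """Validated infection state of one individual for both symbionts."""

    individual_id: str
    cardinium: str  # infected | uninfected | invalid
    wolbachia: str

    def get(self, symbiont: str) -> str:
        if symbiont not in SYMBIONTS:
            raise UsageError(f"unknown symbiont {symbiont!r}")
        return getattr(self, symbiont)


@dataclass
class PrevalenceEstimate:
    symbiont: str
    n_positive: int
    n_valid: int
    point: float
    ci_low: Optional[float]
    ci_high: Optional[float]
    ci_method: str
    percent_display: int

    def validate(self) -> "PrevalenceEstimate":
        if self.n_positive > self.n_valid:
            raise ValidationError("n_positive > n_valid")
        if self.ci_low is not None and not (
            self.ci_low - 1e-12 <= self.point <= self.ci_high + 1e-12
        ):
            raise ValidationError("point outside its own confidence interval")
        return self


@dataclass
class CoinfectionTable:
    """2x2 joint counts over individuals valid for both symbionts."""

    n_both: int          # C+W+
    n_first_only: int    # C+W-
    n_second_only: int   # C-W+
    n_neither: int       # C-W-
    nested: bool
    fisher_p: float

    @property
    def n_total(self) -> int:
        return self.n_both + self.n_first_only + self.n_second_only + self.n_neither


@dataclass
class CoverageProfile:
    """Sequencing-depth summary used by the titer estimator."""

    symbiont_coverage: Dict[str, float]
    host_single_copy_coverage: float
    prevalence: Dict[str, float]
    cells_per_host: int = 1000

    def validate(self) -> "CoverageProfile":
        for name, cov in self.symbiont_coverage.items():
            if cov < 0:
                raise ValidationError(f"{name}: negative coverage")
        if self.host_single_copy_coverage < 0:
            raise ValidationError("negative host coverage")
        for name, p in self.prevalence.items():
            if not (0 <= p <= 1):
                raise ValidationError(f"{name}: prevalence {p} outside [0, 1]")
        if self.cells_per_host < 1:
            raise ValidationError("cells_per_host must be >= 1")
        return self


@dataclass
class IntensityEstimate:
    symbiont: str
    cells_per_infected_host: float
    rounded_display: int
    formula_variant: str


def _call_one(symbiont_pcr: str, host_pcr: str) -> str:
    if symbiont_pcr == "pos":
        return "infected"
    if host_pcr == "pos":
        return "uninfected"
    return "invalid"


def call_individual(row: PanelRow) -> InfectionCall:
    """Turn one panel row into an :class:`InfectionCall`.

    A positive symbiont PCR is infected regardless of the host control; a
    negative (or missing) symbiont PCR is only scored uninfected when the
    host 18S control is positive, else the individual is invalid.
    """
    row.validate()
    return InfectionCall(
        individual_id=row.individual_id,
        cardinium=_call_one(row.cardinium_pcr, row.host_18s_pcr),
        wolbachia=_call_one(row.wolbachia_pcr, row.host_18s_pcr),
    )


def call_panel(panel: PcrPanel) -> List[InfectionCall]:
    panel.validate()
    return [call_individual(r) for r in panel.rows]


def estimate_prevalence(
    calls: Sequence[InfectionCall],
    symbiont: str,
    ci_method: str = "wilson",
    alpha: float = 0.05,
) -> PrevalenceEstimate:
    """Prevalence of one symbiont over non-invalid calls.

    ``percent_display`` is the whole percent truncated toward zero (123/127
    displays as 96%).  Invalid individuals are excluded from the
    denominator; the exclusion count is logged.
    """
    if ci_method not in CI_METHODS:
        raise UsageError(f"unknown ci_method {ci_method!r}")
    states = [c.get(symbiont) for c in calls]
    n_invalid = sum(s == "invalid" for s in states)
    if n_invalid:
        logger.info("%s: excluded %d invalid individuals", symbiont, n_invalid)
    n_valid = sum(s != "invalid" for s in states)
    if n_valid == 0:
        raise EmptyInputError(f"no valid calls for {symbiont}")
    n_positive = sum(s == "infected" for s in states)
    point = n_positive / n_valid
    if ci_method == "none":
        ci_low = ci_high = None
    else:
        method = {"wilson": "wilson", "clopper_pearson": "beta"}[ci_method]
        ci_low, ci_high = proportion_confint(n_positive, n_valid, alpha=alpha, method=method)
    return PrevalenceEstimate(
        symbiont=symbiont,
        n_positive=n_positive,
        n_valid=n_valid,
        point=point,
        ci_low=ci_low,
        ci_high=ci_high,
        ci_method=ci_method,
        percent_display=floor_percent(n_positive, n_valid),
    ).validate()


def coinfection_summary(calls: Sequence[InfectionCall]) -> CoinfectionTable:
    """2x2 coinfection counts, nestedness flag and two-sided Fisher exact p.

    Only individuals with valid calls for both symbionts contribute.
    Nestedness is true iff no individual carries the second symbiont
    (wolbachia) without the first (cardinium).
    """
    joint = [
        c for c in calls if c.cardinium != "invalid" and c.wolbachia != "invalid"
    ]
    if not joint:
        raise EmptyInputError("no individuals jointly valid for both symbionts")
    a = sum(c.cardinium == "infected" and c.wolbachia == "infected" for c in joint)
    b = sum(c.cardinium == "infected" and c.wolbachia == "uninfected" for c in joint)
    c_ = sum(c.cardinium == "uninfected" and c.wolbachia == "infected" for c in joint)
    d = sum(c.cardinium == "uninfected" and c.wolbachia == "uninfected" for c in joint)
    _, p = fisher_exact([[a, b], [c_, d]], alternative="two-sided")
    return CoinfectionTable(
        n_both=a,
        n_first_only=b,
        n_second_only=c_,
        n_neither=d,
        nested=(c_ == 0),
        fisher_p=float(p),
    )


def estimate_intensity(
    profile: CoverageProfile,
    symbiont: str,
    formula_variant: str = "as_printed",
) -> IntensityEstimate:
    """Cells of one symbiont per infected host, from relative read depth."""
    profile.validate()
    if formula_variant not in ("as_printed", "per_infected_alternative"):
        raise UsageError(f"unknown formula variant {formula_variant!r}")
    if symbiont not in profile.symbiont_coverage:
        raise UsageError(f"symbiont {symbiont!r} not in coverage profile")
    if profile.host_single_copy_coverage <= 0:
        raise CosymbioError("host single-copy coverage must be positive")
    cov = profile.symbiont_coverage[symbiont]
    prev = profile.prevalence[symbiont]
    per_cell_depth = profile.host_single_copy_coverage / profile.cells_per_host
    if cov == 0:
        cells = 0.0
    elif formula_variant == "as_printed":
        cells = (cov * prev) / per_cell_depth
    else:
        if prev <= 0:
            raise UsageError(
                "per_infected_alternative requires a positive prevalence"
            )
        cells = (cov / prev) / per_cell_depth
    return IntensityEstimate(
        symbiont=symbiont,
        cells_per_infected_host=cells,
        rounded_display=int(math.floor(cells + 0.5)),
        formula_variant=formula_variant,
    )
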