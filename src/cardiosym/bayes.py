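"""Default (JZS) Bayes-factor t tests with multiplicity-corrected odds.

The Bayes factor BF10 for the paired/one-sample t setting uses the
Jeffreys–Zellner–Siow default prior: effect size δ ~ Cauchy(0, r) with
r = 1/√2 by default.  Following Rouder et al.'s formulation, with the
Cauchy written as a scale mixture of normals (g ~ InverseGamma(1/2,
r²/2) on the variance of δ),

    BF10 = ∫₀^∞ (1 + N g)^(-1/2) (1 + t²/((1 + N g) ν))^(-(ν+1)/2)
           π(g) dg  /  (1 + t²/ν)^(-(ν+1)/2),

where N is the effective sample size and ν the degrees of freedom.
The integral is evaluated by adaptive quadrature after the bounding
transform u = g/(1+g).

For a family of pairwise comparisons among k conditions, the prior
odds per comparison are corrected for multiplicity by fixing at 0.5
the prior probability that *all* nulls hold (Westfall, Johnson & Utts
convention): the per-comparison null prior is p₀ = 0.5^(2/k), giving
prior odds (1−p₀)/p₀ ≈ 0.587 for k = 3.  Posterior odds are prior
odds × BF10, and the replication probability reported alongside is
100·BF10/(BF10 + 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

__all__ = [
    "BayesConfig",
    "BayesComparison",
    "BayesTTest",
    "BayesTTestResults",
    "PairwiseBayes",
    "PairwiseBayesResults",
    "jzs_bf10",
    "jzs_bf10_paired",
    "westfall_prior_odds",
    "posterior_odds",
    "posterior_probability_pct",
    "evidence_label",
    "EVIDENCE_LETTERS",
]

DEFAULT_R = 1.0 / math.sqrt(2.0)

# Lee–Wagenmakers evidence bands (upper edges on BF10 for H1).
_BANDS = [(3.0, "anecdotal"), (10.0, "moderate"), (30.0, "strong"),
          (100.0, "very strong"), (math.inf, "extreme")]
EVIDENCE_LETTERS = {"anecdotal": "A", "moderate": "M", "strong": "S",
                    "very strong": "VS", "extreme": "E"}


@dataclass(frozen=True)
class BayesConfig:
    """Prior settings for a family of pairwise default-Bayes t tests."""

    cauchy_scale: float = DEFAULT_R
    correction: str = "westfall_fixed_half"  # or 'none'
    prior_odds: float | None = None  # overrides the correction when set

    def __post_init__(self) -> None:
        if self.cauchy_scale <= 0:
            raise ValueError("cauchy_scale must be positive")
        if self.correction not in ("westfall_fixed_half", "none"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.prior_odds is not None and self.prior_odds <= 0:
            raise ValueError("prior_odds must be positive")

    def resolve_prior_odds(self, k_groups: int) -> float:
        if self.prior_odds is not None:
            return self.prior_odds
        if self.correction == "none":
            return 1.0
        return westfall_prior_odds(k_groups)


def jzs_bf10(t: float, n: float, r: float = DEFAULT_R, *, df: float | None = None,
             rel_tol: float = 1e-9) -> float:
    """JZS Bayes factor BF10 from a t statistic.

    Parameters
    ----------
    t
        Observed t statistic.
    n
        Effective sample size: the number of pairs for a paired test, or
        ``n1*n2/(n1+n2)`` for two independent samples (pass ``df`` too).
    r
        Cauchy prior scale on the standardised effect size.
    df
        Degrees of freedom; defaults to ``n - 1`` (one-sample/paired).
    """
    if not math.isfinite(t):
        raise ValueError("t must be finite")
    if n < 2:
        raise ValueError("need n >= 2")
    nu = float(n - 1 if df is None else df)
    if nu < 1:
        raise ValueError("degrees of freedom must be >= 1")
    t2 = t * t
    r2 = r * r

    def log_h1_integrand(g: float) -> float:
        # g is the mixing variance of delta, scaled by r^2
        c = 1.0 + n * g * r2
        return (
            -0.5 * math.log(c)
            - (nu + 1.0) / 2.0 * math.log1p(t2 / (c * nu))
            - 0.5 * math.log(2.0 * math.pi)
            - 1.5 * math.log(g)
            - 1.0 / (2.0 * g)
        )

    def integrand(u: float) -> float:
        # u = g/(1+g) maps (0, inf) to (0, 1); dg = du/(1-u)^2
        if u <= 0.0 or u >= 1.0:
            return 0.0
        g = u / (1.0 - u)
        return math.exp(log_h1_integrand(g)) / (1.0 - u) ** 2

    h1, _ = integrate.quad(integrand, 0.0, 1.0, epsabs=0.0, epsrel=rel_tol,
                           limit=200)
    log_h0 = -(nu + 1.0) / 2.0 * math.log1p(t2 / nu)
    return h1 / math.exp(log_h0)


def jzs_bf10_paired(differences=None, *, t: float | None = None,
                    n: int | None = None, r: float = DEFAULT_R) -> float:
    """Paired-sample BF10 from raw differences or from (t, n).

    Either supply the per-subject differences (the t statistic is then
    computed internally) or the t statistic together with the number of
    pairs.
    """
    if differences is not None:
        d = np.asarray(differences, dtype=float)
        if d.size < 2:
            raise ValueError("need at least 2 differences")
        sd = d.std(ddof=1)
        if sd == 0:
            if d.mean() != 0:
                raise ValueError(
                    "zero variance with nonzero mean: t is infinite, "
                    "the default Bayes factor is undefined"
                )
            t_stat, n_eff = 0.0, d.size
        else:
            t_stat = d.mean() / (sd / math.sqrt(d.size))
            n_eff = d.size
    else:
        if t is None or n is None:
            raise ValueError("supply either differences or both t and n")
        t_stat, n_eff = float(t), int(n)
    return jzs_bf10(t_stat, n_eff, r)


def westfall_prior_odds(k_groups: int) -> float:
    """Multiplicity-corrected prior odds for all pairwise comparisons.

    Fixes at 0.5 the prior probability that every null among the
    ``k·(k−1)/2`` pairwise comparisons holds; with independent
    per-comparison priors this gives a per-comparison null probability
    ``p₀ = 0.5^(2/k)`` and prior odds ``(1−p₀)/p₀`` (0.587 for k = 3).
    """
    if k_groups < 2:
        raise ValueError("need at least 2 groups")
    p0 = 0.5 ** (2.0 / k_groups)
    return (1.0 - p0) / p0


def posterior_odds(prior_odds: float, bf10: float) -> float:
    """Corrected posterior odds: prior odds × BF10."""
    if prior_odds <= 0 or bf10 < 0:
        raise ValueError("prior_odds must be positive and bf10 non-negative")
    return prior_odds * bf10


def posterior_probability_pct(bf10: float) -> float:
    """Replication probability, percent: 100·BF10/(BF10 + 1)."""
    if bf10 < 0:
        raise ValueError("bf10 must be non-negative")
    return 100.0 * bf10 / (bf10 + 1.0)


def evidence_label(bf10: float) -> tuple[str, str]:
    """Lee–Wagenmakers evidence band and favoured hypothesis.

    Returns ``(band, direction)`` with band in {anecdotal, moderate,
    strong, very strong, extreme} and direction 'H1' or 'H0'.  BF10
    exactly 1 is labelled anecdotal-H1 by convention; band edges belong
    to the stronger band (BF10 = 3 is moderate).
    """
    if bf10 <= 0:
        raise ValueError("bf10 must be positive")
    direction = "H1" if bf10 >= 1.0 else "H0"
    magnitude = bf10 if bf10 >= 1.0 else 1.0 / bf10
    for upper, band in _BANDS:
        if magnitude < upper:
            return band, direction
    return "extreme", direction  # pragma: no cover


def _letter(band: str, direction: str) -> str:
    letter = EVIDENCE_LETTERS[band]
    return letter if direction == "H1" else letter.lower()


@dataclass(frozen=True)
class BayesComparison:
    """One pairwise contrast row of a Bayes table."""

    contrast: tuple[str, str]
    prior_odds: float
    bf10_uncorrected: float
    n: int

    @property
    def posterior_odds(self) -> float:
        return posterior_odds(self.prior_odds, self.bf10_uncorrected)

    @property
    def posterior_probability_pct(self) -> float:
        return posterior_probability_pct(self.bf10_uncorrected)

    @property
    def evidence(self) -> tuple[str, str]:
        return evidence_label(self.bf10_uncorrected)

    def as_row(self) -> dict:
        band, direction = self.evidence
        return {
            "contrast": f"{self.contrast[0]}-{self.contrast[1]}",
            "prior_odds": self.prior_odds,
            "posterior_odds": self.posterior_odds,
            "bf10_u": self.bf10_uncorrected,
            "probability_pct": self.posterior_probability_pct,
            "label": _letter(band, direction),
            "n": self.n,
        }


class BayesTTest:
    """Default Bayesian paired t test on one set of differences.

    Statsmodels-style model object: construct from the per-subject
    differences (or two paired condition vectors), then :meth:`fit`.
    """

    def __init__(self, differences, r: float = DEFAULT_R):
        d = np.asarray(differences, dtype=float)
        if d.ndim != 1 or d.size < 2:
            raise ValueError("need a 1-D array of at least 2 differences")
        self.differences = d
        self.r = r

    @classmethod
    def from_paired(cls, x, y, r: float = DEFAULT_R) -> "BayesTTest":
        x, y = np.asarray(x, float), np.asarray(y, float)
        if x.shape != y.shape:
            raise ValueError("paired samples must have equal length")
        return cls(x - y, r=r)

    def fit(self) -> "BayesTTestResults":
        d = self.differences
        n = d.size
        sd = d.std(ddof=1)
        if sd == 0 and d.mean() != 0:
            raise ValueError("zero variance with nonzero mean difference")
        t = 0.0 if sd == 0 else float(d.mean() / (sd / math.sqrt(n)))
        bf = jzs_bf10(t, n, self.r)
        return BayesTTestResults(t=t, n=n, r=self.r, bf10=bf,
                                 mean_diff=float(d.mean()))


@dataclass(frozen=True)
class BayesTTestResults:
    t: float
    n: int
    r: float
    bf10: float
    mean_diff: float

    @property
    def posterior_probability_pct(self) -> float:
        return posterior_probability_pct(self.bf10)

    @property
    def evidence(self) -> tuple[str, str]:
        return evidence_label(self.bf10)

    def summary(self) -> str:
        band, direction = self.evidence
        return (
            f"Default Bayesian paired t test (Cauchy scale r = {self.r:.4f})\n"
            f"  n = {self.n}, mean difference = {self.mean_diff:.4g}, "
            f"t = {self.t:.3f}\n"
            f"  BF10 = {self.bf10:.3f}  ({band}, favouring {direction})\n"
            f"  P(replication) = {self.posterior_probability_pct:.1f}%"
        )


class PairwiseBayes:
    """All pairwise default-Bayes comparisons of a within-subject variable.

    Construct from a long-format DataFrame with one observation per
    subject × condition; :meth:`fit` runs a paired JZS t test for every
    ordered condition pair and applies the multiplicity-corrected prior
    odds for the family.
    """

    def __init__(self, data: pd.DataFrame, dv: str, *, within: str = "condition",
                 subject: str = "subject", config: BayesConfig = BayesConfig(),
                 order: tuple[str, ...] | None = None):
        for col in (dv, within, subject):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data
        self.dv = dv
        self.within = within
        self.subject = subject
        self.config = config
        levels = list(pd.unique(data[within]))
        if order is not None:
            missing = set(order) - set(levels)
            if missing:
                raise ValueError(f"unknown condition labels: {sorted(missing)}")
            levels = [l for l in order if l in levels]
        self.levels = levels

    def fit(self) -> "PairwiseBayesResults":
        wide = self.data.pivot_table(
            index=self.subject, columns=self.within, values=self.dv
        )
        if wide.isna().any().any():
            raise ValueError("incomplete crossover: every subject needs every level")
        k = len(self.levels)
        prior = self.config.resolve_prior_odds(k)
        comps = []
        for i in range(k):
            for j in range(i + 1, k):
                a, b = self.levels[i], self.levels[j]
                d = (wide[a] - wide[b]).to_numpy()
                bf = jzs_bf10_paired(d, r=self.config.cauchy_scale)
                comps.append(BayesComparison((a, b), prior, bf, n=d.size))
        return PairwiseBayesResults(comparisons=tuple(comps), dv=self.dv,
                                    prior_odds=prior)


@dataclass(frozen=True)
class PairwiseBayesResults:
    comparisons: tuple[BayesComparison, ...]
    dv: str
    prior_odds: float

    def summary(self, *, rounded: bool = True) -> pd.DataFrame:
        """Bayes table shaped like the study's report tables.

        Columns: contrast, prior odds, corrected posterior odds,
        uncorrected BF10, replication probability (%), evidence letter.
        Rounding follows the report convention (odds 2 dp, BF 3 dp,
        probability 1 dp) unless ``rounded=False``.
        """
        rows = [c.as_row() for c in self.comparisons]
        df = pd.DataFrame(rows)
        if rounded and len(df):
            df["prior_odds"] = df["prior_odds"].round(3)
            df["posterior_odds"] = df["posterior_odds"].round(2)
            df["bf10_u"] = df["bf10_u"].round(3)
            df["probability_pct"] = df["probability_pct"].round(1)
        return df
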