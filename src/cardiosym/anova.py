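"""Frequentist layer: repeated-measures ANOVA and companions.

The study design is a randomised crossover: every subject is measured
under every supplementation condition and (for time-trial variables) at
every moment, so both factors are within-subject.  The ANOVA is the
classical two-way fully-repeated decomposition: each effect is tested
against its own effect-by-subject interaction,

    F_effect = MS_effect / MS_(effect × subject),

with Mauchly's sphericity test on the orthonormal-contrast covariance
and the Greenhouse–Geisser degrees-of-freedom correction applied when
sphericity is rejected at α = 0.05.  Effect sizes are partial eta
squared, SS_effect / (SS_effect + SS_error).  Variables that fail a
Shapiro–Wilk normality gate are routed to Kruskal–Wallis instead.

Also here: condition deltas (caffeine minus placebo means) and the
a-priori sample-size computation for a one-group repeated-measures
design based on the noncentral F distribution, matching the G*Power
"ANOVA: repeated measures, within factors" conventions.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RepeatedMeasuresAnova",
    "RMAnovaResults",
    "EffectTest",
    "SphericityDiagnostics",
    "PowerQuery",
    "shapiro_gate",
    "kruskal_fallback",
    "deltas",
    "rm_anova_power",
    "rm_sample_size",
    "tukey_posthoc",
]

ALPHA = 0.05


# ---------------------------------------------------------------------------
# normality gate / fallback


def shapiro_gate(cells, alpha: float = ALPHA) -> str:
    """Route a variable to ANOVA or a rank test by Shapiro–Wilk normality.

    ``cells`` is an iterable of per-cell samples (each n ≥ 3).  Returns
    ``'normal'`` when no cell rejects normality at ``alpha``, else
    ``'non_normal'``.  A zero-variance cell is degenerate and raises.
    """
    cells = [np.asarray(c, dtype=float) for c in cells]
    if not cells:
        raise ValueError("no cells supplied")
    for c in cells:
        if c.size < 3:
            raise ValueError("Shapiro-Wilk needs at least 3 observations per cell")
        if np.ptp(c) == 0:
            raise ValueError("degenerate cell: all values identical")
    for c in cells:
        if stats.shapiro(c).pvalue < alpha:
            return "non_normal"
    return "normal"


def kruskal_fallback(groups) -> tuple[float, float]:
    """Kruskal–Wallis H (tie-corrected) and p for ≥ 2 independent groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(g.size for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        raise ValueError("degenerate data: all values identical")
    res = stats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def deltas(
    table: pd.DataFrame,
    variable: str,
    *,
    condition: str = "condition",
    reference: str = "PP",
) -> dict[str, float]:
    """Condition-mean deltas against the placebo reference.

    Δ(X vs reference) = mean(X) − mean(reference); by construction the
    reference maps to 0.  Negative time deltas mean faster completion
    under the supplemented condition.
    """
    if reference not in set(table[condition]):
        raise ValueError(f"unknown reference condition {reference!r}")
    means = table.groupby(condition)[variable].mean()
    ref = means[reference]
    return {cond: float(m - ref) for cond, m in means.items()}


# ---------------------------------------------------------------------------
# sphericity machinery


def _orthonormal_contrasts(m: int) -> np.ndarray:
    """(m−1)×m orthonormal contrast matrix (rows orthonormal, sum 0)."""
    helmert = np.zeros((m - 1, m))
    for i in range(m - 1):
        helmert[i, : i + 1] = 1.0
        helmert[i, i + 1] = -(i + 1.0)
        helmert[i] /= np.linalg.norm(helmert[i])
    return helmert


@dataclass(frozen=True)
class SphericityDiagnostics:
    """Mauchly's W with its chi-square p, and Greenhouse–Geisser ε̂."""

    mauchly_w: float
    mauchly_p: float
    gg_epsilon: float
    contrast_dim: int

    @property
    def violated(self) -> bool:
        return self.mauchly_p < ALPHA


def _sphericity(contrast_scores: np.ndarray) -> SphericityDiagnostics:
    """Diagnostics from per-subject orthonormal-contrast scores (n × p)."""
    n, p = contrast_scores.shape
    if p == 1:
        # two levels: a single contrast is trivially spherical
        return SphericityDiagnostics(1.0, 1.0, 1.0, p)
    S = np.cov(contrast_scores, rowvar=False, ddof=1)
    tr = float(np.trace(S))
    eps = tr * tr / (p * float(np.sum(S * S)))
    eps = float(min(1.0, max(eps, 1.0 / p)))
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0 or n - 1 <= p:
        # singular covariance: W degenerates to 0, sphericity rejected
        return SphericityDiagnostics(0.0, 0.0, eps, p)
    w = float(math.exp(logdet - p * math.log(tr / p)))
    d = 1.0 - (2.0 * p * p + p + 2.0) / (6.0 * p * (n - 1.0))
    chi2 = -(n - 1.0) * d * (logdet - p * math.log(tr / p))
    dof = p * (p + 1) // 2 - 1
    pval = float(stats.chi2.sf(chi2, dof))
    return SphericityDiagnostics(w, pval, eps, p)


# ---------------------------------------------------------------------------
# the model


@dataclass(frozen=True)
class EffectTest:
    """One within-subject effect of the repeated-measures decomposition."""

    name: str
    ss: float
    ss_error: float
    df: float
    df_error: float
    f_value: float
    p_uncorrected: float
    partial_eta_sq: float
    sphericity: SphericityDiagnostics
    p_gg: float
    gg_applied: bool

    @property
    def p_value(self) -> float:
        """The p to report: GG-corrected when sphericity was rejected."""
        return self.p_gg if self.gg_applied else self.p_uncorrected


class RepeatedMeasuresAnova:
    """Fully within-subject one- or two-way repeated-measures ANOVA.

    Parameters
    ----------
    data
        Long-format DataFrame, one row per subject × cell.
    dv
        Response column name.
    within
        One or two within-subject factor names (treatment, measure).
    subject
        Subject identifier column.

    The design must be a balanced complete crossover: every subject
    contributes exactly one observation to every factor-level cell.
    """

    def __init__(self, data: pd.DataFrame, dv: str, within, subject: str = "subject"):
        if isinstance(within, str):
            within = (within,)
        within = tuple(within)
        if not 1 <= len(within) <= 2:
            raise ValueError("within must name one or two factors")
        for col in (dv, subject, *within):
            if col not in data.columns:
                raise ValueError(f"column {col!r} not in data")
        self.data = data
        self.dv = dv
        self.within = within
        self.subject = subject

    @classmethod
    def from_dataframe(cls, data, dv, within, subject="subject"):
        return cls(data, dv, within, subject)

    def _cube(self) -> tuple[np.ndarray, list, list, list]:
        """Response as a subjects × A-levels × B-levels array."""
        d = self.data
        a_col = self.within[0]
        b_col = self.within[1] if len(self.within) == 2 else None
        subjects = list(pd.unique(d[self.subject]))
        a_levels = list(pd.unique(d[a_col]))
        b_levels = list(pd.unique(d[b_col])) if b_col else [None]
        pivot = d.pivot_table(
            index=self.subject,
            columns=list(self.within),
            values=self.dv,
            aggfunc="count",
        )
        if pivot.isna().any().any() or (pivot != 1).any().any():
            raise ValueError(
                "unbalanced design: every subject needs exactly one "
                "observation per cell"
            )
        y = np.empty((len(subjects), len(a_levels), len(b_levels)))
        val = d.set_index([self.subject, *self.within])[self.dv]
        for si, s in enumerate(subjects):
            for ai, a in enumerate(a_levels):
                for bi, b in enumerate(b_levels):
                    key = (s, a) if b_col is None else (s, a, b)
                    y[si, ai, bi] = val.loc[key]
        return y, subjects, a_levels, b_levels

    def fit(self, *, gg: str = "auto") -> "RMAnovaResults":
        """Fit the decomposition.

        ``gg`` controls the Greenhouse–Geisser correction: ``'auto'``
        applies it when Mauchly's test rejects at α = 0.05, ``'always'``
        applies it unconditionally, ``'never'`` reports raw-df p values.
        """
        if gg not in ("auto", "always", "never"):
            raise ValueError("gg must be 'auto', 'always' or 'never'")
        y, subjects, a_levels, b_levels = self._cube()
        n, a, b = y.shape
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if a < 2:
            raise ValueError("the first within factor needs at least 2 levels")
        g = y.mean()
        mean_s = y.mean(axis=(1, 2))
        mean_a = y.mean(axis=(0, 2))
        mean_b = y.mean(axis=(0, 1))
        mean_as = y.mean(axis=2)
        mean_bs = y.mean(axis=1)
        mean_ab = y.mean(axis=0)

        ss_s = a * b * np.sum((mean_s - g) ** 2)
        ss_a = n * b * np.sum((mean_a - g) ** 2)
        ss_as = b * np.sum((mean_as - mean_a[None, :] - mean_s[:, None] + g) ** 2)

        effects: list[EffectTest] = []

        def make_effect(name, ss, df, ss_err, df_err, scores):
            ms, ms_err = ss / df, ss_err / df_err
            f_val = ms / ms_err if ms_err > 0 else np.inf
            p_unc = float(stats.f.sf(f_val, df, df_err))
            sph = _sphericity(scores)
            eps = sph.gg_epsilon
            p_gg = float(stats.f.sf(f_val, df * eps, df_err * eps))
            applied = (gg == "always") or (gg == "auto" and sph.violated)
            eta = ss / (ss + ss_err) if (ss + ss_err) > 0 else 0.0
            return EffectTest(name, ss, ss_err, df, df_err, f_val, p_unc,
                              float(eta), sph, p_gg, applied)

        c_a = _orthonormal_contrasts(a)
        scores_a = mean_as @ c_a.T  # n × (a−1)
        effects.append(
            make_effect(self.within[0], ss_a, a - 1, ss_as, (a - 1) * (n - 1),
                        scores_a)
        )

        ss_total = np.sum((y - g) ** 2)
        if b > 1:
            ss_b = n * a * np.sum((mean_b - g) ** 2)
            ss_bs = a * np.sum((mean_bs - mean_b[None, :] - mean_s[:, None] + g) ** 2)
            ss_ab = n * np.sum(
                (mean_ab - mean_a[:, None] - mean_b[None, :] + g) ** 2
            )
            ss_abs = ss_total - (ss_s + ss_a + ss_as + ss_b + ss_bs + ss_ab)
            ss_abs = max(ss_abs, 0.0)
            c_b = _orthonormal_contrasts(b)
            scores_b = mean_bs @ c_b.T
            effects.append(
                make_effect(self.within[1], ss_b, b - 1, ss_bs,
                            (b - 1) * (n - 1), scores_b)
            )
            c_ab = np.kron(c_a, c_b)  # (a−1)(b−1) × ab
            scores_ab = y.reshape(n, a * b) @ c_ab.T
            effects.append(
                make_effect(f"{self.within[0]}:{self.within[1]}", ss_ab,
                            (a - 1) * (b - 1), ss_abs,
                            (a - 1) * (b - 1) * (n - 1), scores_ab)
            )

        ms_as = ss_as / ((a - 1) * (n - 1))
        return RMAnovaResults(
            effects=tuple(effects),
            model=self,
            subjects=tuple(subjects),
            a_levels=tuple(a_levels),
            b_levels=tuple(b_levels) if b > 1 else (),
            marginal_means_a={lv: float(m) for lv, m in zip(a_levels, mean_a)},
            ms_error_a=float(ms_as),
            df_error_a=float((a - 1) * (n - 1)),
            n_subjects=n,
            n_b=b,
            ss_total=float(ss_total),
            ss_subject=float(ss_s),
        )


@dataclass(frozen=True)
class RMAnovaResults:
    """Fitted repeated-measures decomposition with diagnostics."""

    effects: tuple[EffectTest, ...]
    model: RepeatedMeasuresAnova
    subjects: tuple
    a_levels: tuple
    b_levels: tuple
    marginal_means_a: dict
    ms_error_a: float
    df_error_a: float
    n_subjects: int
    n_b: int
    ss_total: float
    ss_subject: float

    def effect(self, name: str) -> EffectTest:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)

    def anova_table(self) -> pd.DataFrame:
        rows = []
        for e in self.effects:
            rows.append({
                "effect": e.name,
                "SS": e.ss,
                "df": e.df,
                "SS_error": e.ss_error,
                "df_error": e.df_error,
                "F": e.f_value,
                "p": e.p_value,
                "p_uncorrected": e.p_uncorrected,
                "partial_eta_sq": e.partial_eta_sq,
                "mauchly_W": e.sphericity.mauchly_w,
                "mauchly_p": e.sphericity.mauchly_p,
                "gg_epsilon": e.sphericity.gg_epsilon,
                "gg_applied": e.gg_applied,
            })
        return pd.DataFrame(rows)

    def posthoc_tukey(self, *, only_if_significant: bool = True) -> pd.DataFrame:
        """Tukey HSD on the first factor's marginal means.

        Uses the within-subject error term (MS of treatment × subject)
        and the studentized-range distribution.  By default runs only
        when the omnibus treatment effect is significant at α = 0.05
        (returning an empty table otherwise).
        """
        omnibus = self.effects[0]
        if only_if_significant and omnibus.p_value >= ALPHA:
            return pd.DataFrame(
                columns=["A", "B", "mean_diff", "q", "p_tukey"]
            )
        return tukey_posthoc(
            self.marginal_means_a,
            ms_error=self.ms_error_a,
            df_error=self.df_error_a,
            n_per_mean=self.n_subjects * self.n_b,
        )

    def summary(self) -> str:
        lines = [
            f"Repeated-measures ANOVA: {self.model.dv} ~ "
            + " * ".join(self.model.within)
            + f"  (n = {self.n_subjects} subjects)",
            "-" * 72,
        ]
        for e in self.effects:
            corr = " (GG-corrected)" if e.gg_applied else ""
            lines.append(
                f"{e.name:<24s} F({e.df:g}, {e.df_error:g}) = {e.f_value:7.3f}"
                f"  p = {e.p_value:.4f}{corr}  eta_p^2 = {e.partial_eta_sq:.3f}"
            )
            lines.append(
                f"{'':<24s} Mauchly W = {e.sphericity.mauchly_w:.3f}"
                f" (p = {e.sphericity.mauchly_p:.3f}),"
                f" GG epsilon = {e.sphericity.gg_epsilon:.3f}"
            )
        return "\n".join(lines)


def tukey_posthoc(
    means: dict, *, ms_error: float, df_error: float, n_per_mean: int
) -> pd.DataFrame:
    """Tukey HSD over a set of marginal means with a supplied error term."""
    labels = list(means)
    k = len(labels)
    se = math.sqrt(ms_error / n_per_mean)
    rows = []
    for x, y in itertools.combinations(labels, 2):
        diff = means[x] - means[y]
        q = abs(diff) / se if se > 0 else np.inf
        p = float(stats.studentized_range.sf(q, k, df_error))
        rows.append({"A": x, "B": y, "mean_diff": diff, "q": q, "p_tukey": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# a-priori power / sample size


@dataclass(frozen=True)
class PowerQuery:
    """A-priori power query for a one-group repeated-measures design.

    ``effect_size_f`` is Cohen's f; ``n_measurements`` the number of
    repeated measurements m; ``corr_among_measures`` the assumed
    correlation ρ among them (0.5 by default); ``nonsphericity`` the ε
    multiplier (1 = spherical).  Matches the conventions of the
    standard a-priori calculator for this design: noncentrality
    λ = f²·N·m·ε/(1−ρ), df₁ = (m−1)·ε, df₂ = (N−1)·(m−1)·ε.
    """

    effect_size_f: float
    alpha: float = 0.05
    target_power: float = 0.80
    n_measurements: int = 3
    corr_among_measures: float = 0.5
    nonsphericity: float = 1.0

    def __post_init__(self) -> None:
        if self.effect_size_f < 0:
            raise ValueError("effect_size_f must be non-negative")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must be in (0, 1)")
        if self.n_measurements < 2:
            raise ValueError("need at least 2 repeated measurements")
        if not 0 <= self.corr_among_measures < 1:
            raise ValueError("corr_among_measures must be in [0, 1)")
        if not 0 < self.nonsphericity <= 1:
            raise ValueError("nonsphericity must be in (0, 1]")


def rm_anova_power(n_subjects: int, query: PowerQuery) -> float:
    """Achieved power of the within-factor F test at a given N."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    f2 = query.effect_size_f**2
    m = query.n_measurements
    eps = query.nonsphericity
    lam = f2 * n_subjects * m * eps / (1.0 - query.corr_among_measures)
    df1 = (m - 1) * eps
    df2 = (n_subjects - 1) * (m - 1) * eps
    fcrit = stats.f.isf(query.alpha, df1, df2)
    return float(stats.ncf.sf(fcrit, df1, df2, lam))


def rm_sample_size(query: PowerQuery, *, n_max: int = 10_000) -> int:
    """Smallest N whose repeated-measures F test reaches the target power."""
    if query.effect_size_f == 0:
        raise ValueError("power never reaches the target at effect size 0")
    for n in range(2, n_max + 1):
        if rm_anova_power(n, query) >= query.target_power:
            return n
    raise ValueError(f"target power not reached by N = {n_max}")
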