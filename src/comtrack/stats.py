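"""Method-agreement statistics: classical and Bayes-factor repeated-measures ANOVA.

The question is whether the displacement range measured by the pelvis
tracker differs systematically from the range measured by the optical COM,
per horizontal direction, across the five standing tasks. The design is
fully within-subject: subject x task x method, with missing cells allowed.

Tasks are averaged into a per-subject paired contrast (complete-case within
each subject-task cell), and the method effect is tested two ways:

* classically, via the one-within-factor repeated-measures ANOVA computed
  from sums of squares — F on (1, n-1) degrees of freedom, equal to the
  squared paired t;
* as a Bayes factor BF10 for the model with the method effect against the
  null, under a Jeffreys-Zellner-Siow (Cauchy) prior on the standardised
  effect, evaluated by adaptive one-dimensional quadrature of the
  noncentral-t marginal likelihood over the prior. BF10 < 1 favours the
  null (method equivalence). Verbal labels follow the Lee-Wagenmakers
  classification.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate, stats as sps

from .errors import ConfigurationError, InsufficientDataError, ValidationError

#: default Cauchy prior scale on the standardised method effect
DEFAULT_PRIOR_SCALE = 0.5


@dataclass
class PairedDesign:
    """Long-format within-subject responses: subject x task x method."""

    data: pd.DataFrame  # columns: subject, task, method, response

    def __post_init__(self) -> None:
        required = {"subject", "task", "method", "response"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"design missing columns: {sorted(missing)}")
        if self.data.duplicated(["subject", "task", "method"]).any():
            raise ValidationError("at most one response per subject-task-method cell")
        methods = set(self.data["method"].unique())
        if not methods <= {"com", "tracker"}:
            raise ValidationError(f"unknown method labels: {methods - {'com', 'tracker'}}")

    @classmethod
    def from_displacement_rows(cls, rows, direction: str) -> "PairedDesign":
        """Build a design from agreement-module displacement rows.

        ``direction`` selects the X (anteroposterior) or Y (mediolateral)
        range as the response.
        """
        if direction.upper() not in ("X", "Y"):
            raise ConfigurationError("direction must be 'X' or 'Y'")
        attr = "range_x" if direction.upper() == "X" else "range_y"
        recs = [
            {
                "subject": r.participant_id,
                "task": r.task_id,
                "method": r.method,
                "response": getattr(r, attr),
            }
            for r in rows
        ]
        return cls(pd.DataFrame(recs, columns=["subject", "task", "method", "response"]))

    def subject_method_means(self) -> pd.DataFrame:
        """Complete-case collapse: per subject, per method mean over tasks
        where *both* methods are present; subjects with no complete pair
        are dropped. Returns a wide frame with columns com, tracker."""
        wide = self.data.pivot_table(
            index=["subject", "task"], columns="method", values="response", aggfunc="first"
        )
        for col in ("com", "tracker"):
            if col not in wide.columns:
                wide[col] = np.nan
        complete = wide.dropna(subset=["com", "tracker"])
        if complete.empty:
            return pd.DataFrame(columns=["com", "tracker"])
        return complete.groupby(level="subject")[["com", "tracker"]].mean()


@dataclass(frozen=True)
class BayesResult:
    direction: str
    bf10: float
    classical_f: float
    classical_p: float
    n_subjects_used: int
    evidence_label: str

    def __post_init__(self) -> None:
        if not self.bf10 > 0:
            raise ValidationError("bf10 must be positive")


# ---------------------------------------------------------------------------
# classical RM-ANOVA
# ---------------------------------------------------------------------------
def _anova_from_wide(y: np.ndarray) -> tuple[float, float]:
    """Method-effect F and p from an (n_subjects, 2) response table.

    Two-way layout with subject as blocking factor, one observation per
    cell: F = MS_method / MS_(subject x method) on (1, n-1) df. A zero
    error variance with a nonzero effect reports F = +inf, p = 0.
    """
    n = y.shape[0]
    grand = y.mean()
    method_means = y.mean(axis=0)
    subject_means = y.mean(axis=1)
    ss_method = n * np.sum((method_means - grand) ** 2)
    ss_subject = 2 * np.sum((subject_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_error = max(ss_total - ss_method - ss_subject, 0.0)
    df_error = n - 1
    ms_error = ss_error / df_error
    # treat error variance as zero when it is numerically negligible
    # relative to the total variation (degenerate perfect-effect case)
    tol = 1e-12 * ss_total / (2 * n - 1)
    if ms_error <= tol or ms_error <= 1e-300:
        if ss_method <= tol or ss_method <= 1e-300:
            return 0.0, 1.0
        return math.inf, 0.0
    f = float(ss_method / ms_error)
    p = float(sps.f.sf(f, 1, df_error))
    return f, p


def classical_rm_anova(design: PairedDesign) -> tuple[float, float, int]:
    """Repeated-measures ANOVA for the method main effect.

    Returns (F, p, n_subjects_used). Requires >= 2 subjects with at least
    one complete method pair.
    """
    means = design.subject_method_means()
    n = len(means)
    if n < 2:
        raise InsufficientDataError(
            f"classical RM-ANOVA needs >= 2 complete subjects, got {n}"
        )
    f, p = _anova_from_wide(means[["com", "tracker"]].to_numpy())
    return f, p, n


# ---------------------------------------------------------------------------
# JZS Bayes factor
# ---------------------------------------------------------------------------
def jzs_paired_bf10(t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE) -> float:
    """JZS Bayes factor for a paired/one-sample t statistic.

    Marginal likelihood of the data under a Cauchy(0, r) prior on the
    standardised effect delta, relative to the point null:

        BF10 = int nct_pdf(t; nu, delta*sqrt(n)) Cauchy(delta; 0, r) d_delta
               / t_pdf(t; nu)

    evaluated by adaptive quadrature (relative tolerance 1e-8).
    """
    if prior_scale <= 0:
        raise ConfigurationError("prior_scale must be positive")
    if n < 2:
        raise InsufficientDataError("Bayes factor needs n >= 2")
    if not math.isfinite(t):
        return math.inf
    nu = n - 1
    m0 = sps.t.pdf(t, nu)

    def integrand(delta: float) -> float:
        return sps.nct.pdf(t, nu, delta * math.sqrt(n)) * sps.cauchy.pdf(
            delta, loc=0.0, scale=prior_scale
        )

    # split at 0 and at the MLE of delta so quad sees the mass
    centre = t / math.sqrt(n)
    pts = sorted({0.0, centre})
    m1 = 0.0
    bounds = [-math.inf] + pts + [math.inf]
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        val, _ = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=1e-8, limit=200)
        m1 += val
    return float(m1 / m0)


def bayes_rm_anova(
    design: PairedDesign,
    direction: str = "X",
    prior_scale: float = DEFAULT_PRIOR_SCALE,
) -> BayesResult:
    """Bayes-factor repeated-measures ANOVA for the method effect.

    The two-method within-subject design collapses to a per-subject paired
    contrast (tasks averaged, complete-case); BF10 is the JZS paired Bayes
    factor of that contrast. Also reports the classical F and p.
    """
    f, p, n = classical_rm_anova(design)
    means = design.subject_method_means()
    d = (means["com"] - means["tracker"]).to_numpy()
    sd = d.std(ddof=1)
    if sd == 0:
        t = 0.0 if np.allclose(d.mean(), 0.0) else math.inf
    else:
        t = float(d.mean() / (sd / math.sqrt(len(d))))
    bf10 = jzs_paired_bf10(t, len(d), prior_scale)
    return BayesResult(
        direction=direction.upper(),
        bf10=bf10,
        classical_f=f,
        classical_p=p,
        n_subjects_used=n,
        evidence_label=label_evidence(bf10),
    )


# ---------------------------------------------------------------------------
# evidence labels
# ---------------------------------------------------------------------------
_BANDS = [
    (100.0, "extreme evidence for H1"),
    (30.0, "very strong evidence for H1"),
    (10.0, "strong evidence for H1"),
    (3.0, "moderate evidence for H1"),
    (1.0, "anecdotal evidence for H1"),
]


def label_evidence(bf10: float) -> str:
    """Lee-Wagenmakers verbal category for a Bayes factor.

    Cut points 1, 3, 10, 30, 100 for the alternative and their reciprocals
    for the null; BF10 = 1 carries no evidence either way.
    """
    if not bf10 > 0:
        raise ValidationError("bf10 must be positive")
    if bf10 == 1.0:
        return "no evidence"
    if bf10 > 1.0:
        for cut, lab in _BANDS:
            if bf10 > cut:
                return lab
        return "anecdotal evidence for H1"
    inv = 1.0 / bf10
    for cut, lab in _BANDS:
        if inv > cut:
            return lab.replace("H1", "the null")
    return "anecdotal evidence for the null"


def analyze_directions(
    displacement_rows, prior_scale: float = DEFAULT_PRIOR_SCALE
) -> list[BayesResult]:
    """Run the classical + Bayesian method comparison for X and Y."""
    out = []
    for direction in ("X", "Y"):
        design = PairedDesign.from_displacement_rows(displacement_rows, direction)
        out.append(bayes_rm_anova(design, direction, prior_scale))
    return out
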