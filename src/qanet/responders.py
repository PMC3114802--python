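"""Detection of responding genes from normalized time courses.

For each feature k of one experiment the 8-point Z profile is summarized as
(Z0, Zavg): the value at t = 0 and the mean of the seven later time points.
Across all features these pairs are strongly linear; a gene that switches on
falls far above the line. Two lines are fitted -- ordinary least squares,
which outliers can distort, and least median of squares (LMS), which resists
up to ~50% contamination -- and their coefficient-wise average is the
predictor line. Residuals from the averaged line are standardized by a
robust scale s = p75(|residual|) / 1.15 (1.15 being the 75th percentile of
|N(0,1)|), upper-tail normal p-values p = 1 - Phi(r) are corrected by the
Benjamini-Yekutieli step-up at alpha = 0.10, and a feature is called up-
(or, symmetrically, down-) significant.

A QA-responsive gene is then one that is up-significant in the QA-shift
experiment but not significant in the qa-1F-mutant or control experiments;
overlap with the starvation experiment is flagged rather than dropped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy import stats

from qanet._errors import ParameterError, StructuralError
from qanet.synth import ChipLayout

#: p75 of |N(0,1)|: calibration of the robust residual scale.
RESIDUAL_SCALE_DIVISOR = 1.15

#: Two-sided 0.05 critical value of Student's t with 7 df (paired screen).
PAIRED_T_CRITICAL = 2.365

#: Above this many points the LMS search switches from exhaustive pair
#: enumeration to seeded pair resampling.
LMS_EXACT_MAX_N = 300

#: Pair subsamples drawn in the resampling branch. 25 already gives a
#: >0.999 chance of at least one outlier-free pair at 50% contamination
#: (0.25 clean-pair probability); 60 leaves a wide margin.
LMS_DEFAULT_SUBSETS = 60


@dataclass(frozen=True)
class LineFit:
    beta0: float
    beta1: float
    method: str  # "OLS", "LMS" or "averaged"
    objective: float | None = None  # median squared residual (LMS only)

    def predict(self, x):
        return self.beta0 + self.beta1 * np.asarray(x, dtype=float)


@dataclass(frozen=True)
class ResidualStats:
    raw: np.ndarray
    scale_s: float
    standardized: np.ndarray
    p_upper: np.ndarray
    p_lower: np.ndarray
    degenerate_scale: bool = False


@dataclass(frozen=True)
class ExperimentCalls:
    """Per-feature outcome of identify_experiment for one experiment."""

    up: np.ndarray
    down: np.ndarray
    p_upper: np.ndarray
    p_lower: np.ndarray
    standardized: np.ndarray
    line_ols: LineFit
    line_lms: LineFit
    alpha: float

    @property
    def line_averaged(self) -> LineFit:
        return averaged_line(self.line_ols, self.line_lms)


FINAL_CLASSES = ("qa_responsive", "qa_and_starvation", "rejected_by_control",
                 "rejected_by_qa1F", "not_responsive")


@dataclass(frozen=True)
class CallSet:
    """Cross-experiment classification of every feature."""

    feature_ids: tuple
    final_class: np.ndarray  # of FINAL_CLASSES strings
    calls: dict  # experiment name -> ExperimentCalls
    alpha: float

    def responsive_mask(self) -> np.ndarray:
        return np.isin(self.final_class, ("qa_responsive", "qa_and_starvation"))

    def responsive_features(self) -> list:
        return [f for f, m in zip(self.feature_ids, self.responsive_mask()) if m]

    def responsive_genes(self, layout: ChipLayout) -> list:
        """Distinct genes with >=1 responsive feature (duplicates collapse)."""
        genes = dict.fromkeys(
            layout.gene_of_feature[f] for f in self.responsive_features()
            if f in layout.gene_of_feature
        )
        return list(genes)


def gene_summary(z_profile) -> tuple:
    """(Z at t=0, mean of the seven later time points)."""
    z = np.asarray(z_profile, dtype=float)
    if z.shape != (8,) or not np.all(np.isfinite(z)):
        raise ParameterError("profile must be 8 finite values")
    return float(z[0]), float(z[1:].mean())


def gene_summaries(z_matrix: np.ndarray) -> tuple:
    """Vectorized gene_summary over a (8, n_features) matrix."""
    z = np.asarray(z_matrix, dtype=float)
    if z.shape[0] != 8:
        raise ParameterError("expected 8 time points on axis 0")
    return z[0].copy(), z[1:].mean(axis=0)


def fit_ols(x, y) -> LineFit:
    """Least-squares line through the (x, y) cloud."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise ParameterError("need at least 2 points")
    if np.ptp(x) == 0:
        raise ParameterError("x values all equal: singular fit")
    xm, ym = x.mean(), y.mean()
    beta1 = np.sum((x - xm) * (y - ym)) / np.sum((x - xm) ** 2)
    return LineFit(float(ym - beta1 * xm), float(beta1), "OLS")


def _lms_intercept_and_objective(t_sorted: np.ndarray):
    """Best intercept for fixed slope: midpoint of the narrowest band that
    covers floor(n/2)+1 of the slope-detrended values."""
    n = t_sorted.size
    h = n // 2 + 1
    widths = t_sorted[h - 1:] - t_sorted[: n - h + 1]
    i = int(np.argmin(widths))
    return 0.5 * (t_sorted[i] + t_sorted[i + h - 1])


def _lms_objective(x, y, beta0, beta1) -> float:
    return float(np.median((y - beta0 - beta1 * x) ** 2))


def fit_lms(x, y, seed: int = 0, n_exact: int = LMS_EXACT_MAX_N,
            n_subsets: int = LMS_DEFAULT_SUBSETS) -> LineFit:
    """Least-median-of-squares line.

    Candidate slopes come from point pairs -- all pairs when n <= n_exact,
    a seeded random sample of pairs otherwise -- each combined with the
    narrowest-band intercept for that slope; the OLS line is included as one
    further candidate, which guarantees the returned objective never exceeds
    the OLS line's median squared residual. The candidate minimizing the
    median squared residual wins (first on ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 points")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ParameterError("all points identical: degenerate")

    if n <= n_exact:
        pairs = itertools.combinations(range(n), 2)
    else:
        rng = np.random.default_rng(seed)
        pairs = (tuple(rng.choice(n, size=2, replace=False))
                 for _ in range(n_subsets))

    best = None
    for i, j in pairs:
        if x[i] == x[j]:
            continue
        slope = (y[j] - y[i]) / (x[j] - x[i])
        t = np.sort(y - slope * x)
        b0 = _lms_intercept_and_objective(t)
        obj = _lms_objective(x, y, b0, slope)
        if best is None or obj < best[0]:
            best = (obj, b0, slope)

    if np.ptp(x) > 0:
        ols = fit_ols(x, y)
        # the OLS slope with its own band-optimal intercept, and the OLS
        # line itself, as safeguard candidates
        t = np.sort(y - ols.beta1 * x)
        for b0, b1 in ((_lms_intercept_and_objective(t), ols.beta1),
                       (ols.beta0, ols.beta1)):
            obj = _lms_objective(x, y, b0, b1)
            if best is None or obj < best[0]:
                best = (obj, b0, b1)
    if best is None:
        raise ParameterError("no valid candidate line (x values all equal)")
    obj, b0, b1 = best
    return LineFit(float(b0), float(b1), "LMS", objective=obj)


def averaged_line(line_ols: LineFit, line_lms: LineFit) -> LineFit:
    """Coefficient-wise average of the OLS and LMS lines (equivalent to
    averaging their predictions, both being straight lines)."""
    return LineFit(0.5 * (line_ols.beta0 + line_lms.beta0),
                   0.5 * (line_ols.beta1 + line_lms.beta1), "averaged")


def standardized_residuals(x, y, line_ols: LineFit, line_lms: LineFit) -> ResidualStats:
    """Residuals from the averaged line, standardized robustly.

    s = p75(|residual|) / 1.15. When s collapses to 0 (at least 75% of the
    points exactly on the line) the nonzero residuals standardize to +/-inf
    -- their p-values are exactly 0 or 1 -- and a degenerate flag is set
    instead of failing, so a noise-free dataset still classifies.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 4:
        raise ParameterError("need at least 4 points")
    line = averaged_line(line_ols, line_lms)
    raw = y - line.predict(x)
    # residuals at rounding-noise level (e.g. every point exactly on the
    # line) are zero, not signal: otherwise the robust scale would
    # standardize float noise into O(1) values
    tol = 1e-9 * (1.0 + np.max(np.abs(x)) + np.max(np.abs(y)))
    raw = np.where(np.abs(raw) <= tol, 0.0, raw)
    s = float(np.percentile(np.abs(raw), 75)) / RESIDUAL_SCALE_DIVISOR
    if s > 0:
        r = raw / s
        degenerate = False
    else:
        r = np.where(raw > 0, np.inf, np.where(raw < 0, -np.inf, 0.0))
        degenerate = True
    p_upper = stats.norm.sf(r)
    p_lower = stats.norm.cdf(r)
    return ResidualStats(raw, s, r, p_upper, p_lower, degenerate)


def harmonic_number(m: int) -> float:
    return float(np.sum(1.0 / np.arange(1, m + 1)))


def by_correct(p_values, alpha: float = 0.10) -> np.ndarray:
    """Benjamini-Yekutieli step-up rejection flags.

    Rejects the ordered p-values up to the largest k with
    p_(k) <= k * alpha / (m * c(m)), c(m) the m-th harmonic number; valid
    under arbitrary dependence of the tests. alpha <= 0 rejects nothing.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ParameterError("p-values must lie in [0, 1]")
    if alpha <= 0:
        return np.zeros(p.shape, dtype=bool)
    m = p.size
    order = np.argsort(p, kind="stable")
    thresholds = np.arange(1, m + 1) * alpha / (m * harmonic_number(m))
    passing = np.nonzero(p[order] <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    return reject


def identify_experiment(z_matrix: np.ndarray, alpha: float = 0.10,
                        seed: int = 0) -> ExperimentCalls:
    """Run the full detection chain on one experiment's (8, n) Z matrix."""
    z0, z_avg = gene_summaries(z_matrix)
    line_ols = fit_ols(z0, z_avg)
    line_lms = fit_lms(z0, z_avg, seed=seed)
    res = standardized_residuals(z0, z_avg, line_ols, line_lms)
    up = by_correct(res.p_upper, alpha) & (res.standardized > 0)
    down = by_correct(res.p_lower, alpha) & (res.standardized < 0)
    return ExperimentCalls(up, down, res.p_upper, res.p_lower,
                           res.standardized, line_ols, line_lms, alpha)


def classify_responders(calls_qa: ExperimentCalls,
                        calls_starvation: ExperimentCalls,
                        calls_qa1f: ExperimentCalls,
                        calls_control: ExperimentCalls,
                        feature_ids) -> CallSet:
    """Combine the four experiments into the QA-responsive definition.

    A feature is QA-responsive iff up-significant under the QA shift and not
    significant (either tail) in the qa-1F-mutant and control experiments;
    requiring the upper-tail call in the QA experiment enforces both the
    response and its direction. Features also up-significant under
    starvation are kept but flagged as the overlap class.
    """
    n = len(feature_ids)
    for c in (calls_qa, calls_starvation, calls_qa1f, calls_control):
        if c.up.shape != (n,):
            raise StructuralError("call vectors must cover the same features")
    sig = lambda c: c.up | c.down
    final = np.full(n, "not_responsive", dtype=object)
    final[calls_qa.up & sig(calls_qa1f)] = "rejected_by_qa1F"
    final[calls_qa.up & ~sig(calls_qa1f) & sig(calls_control)] = "rejected_by_control"
    ok = calls_qa.up & ~sig(calls_qa1f) & ~sig(calls_control)
    final[ok & ~calls_starvation.up] = "qa_responsive"
    final[ok & calls_starvation.up] = "qa_and_starvation"
    return CallSet(tuple(feature_ids), final,
                   {"qa": calls_qa, "starvation": calls_starvation,
                    "qa1f_mutant": calls_qa1f, "control": calls_control},
                   calls_qa.alpha)


def paired_t_screen(exp_profiles: np.ndarray, control_profiles: np.ndarray,
                    t_critical: float = PAIRED_T_CRITICAL):
    """Classical paired t screen between an experiment and the control.

    Both inputs are (8, n_features). Returns ``(t, significant, zero_var)``:
    the paired t statistic on the 8 time-point differences (7 df), a call
    when t > t_critical, and a flag for features whose differences have zero
    variance (t infinite by convention when the mean difference is nonzero).
    """
    a = np.asarray(exp_profiles, dtype=float)
    b = np.asarray(control_profiles, dtype=float)
    if a.shape != b.shape or a.shape[0] != 8:
        raise StructuralError("need matched (8, n) profile matrices")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    n = d.shape[0]
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where(zero_var, np.where(mean > 0, np.inf,
                                    np.where(mean < 0, -np.inf, 0.0)), t)
    return t, t > t_critical, zero_var


def summary_counts(z_by_experiment: dict, alpha: float = 0.10,
                   seed: int = 0) -> dict:
    """Naive vs corrected and OLS vs LMS vs averaged call counts per
    experiment (the shape of the paper-style summary tables)."""
    out: dict = {}
    for name, z in z_by_experiment.items():
        z0, z_avg = gene_summaries(z)
        line_ols = fit_ols(z0, z_avg)
        line_lms = fit_lms(z0, z_avg, seed=seed)
        entry = {}
        for label, (lo, ll) in {
            "OLS": (line_ols, line_ols),
            "LMS": (line_lms, line_lms),
            "averaged": (line_ols, line_lms),
        }.items():
            res = standardized_residuals(z0, z_avg, lo, ll)
            naive = int(np.sum((res.p_upper < alpha) & (res.standardized > 0)))
            corrected = int(np.sum(by_correct(res.p_upper, alpha)
                                   & (res.standardized > 0)))
            entry[label] = {"naive": naive, "corrected": corrected}
        out[name] = entry
    return out
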