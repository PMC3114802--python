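"""Operating characteristics of the detection chain.

Negative-control features (unrelated-genome sequences that should never
respond) estimate the false-positive rate; known positive-control genes
estimate the false-negative rate and hence the power (1 - FNR). GEL50 --
the fold change at which a gene has a 50% chance of being called -- is a
power proxy estimated by logistic regression of the call indicator on the
log2 fold change. Leakiness flags disqualify reporter candidates whose
baseline expression on sucrose already exceeds 1,000 counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from qanet._errors import ParameterError, StructuralError

LEAKY_SUCROSE_THRESHOLD = 1000.0
GOOD_MARKER_QA_THRESHOLD = 10000.0


@dataclass(frozen=True)
class OperatingCharacteristics:
    false_positive_rate: float
    false_negative_rate: float
    power: float


@dataclass(frozen=True)
class Gel50Result:
    gel50: float
    beta0: float
    beta1: float
    separation_flag: bool
    degenerate_slope: bool


def control_rates(called_ids, positive_ids, negative_ids) -> OperatingCharacteristics:
    """FPR/FNR/power from disjoint positive- and negative-control id sets."""
    called = set(called_ids)
    pos = set(positive_ids)
    neg = set(negative_ids)
    if pos & neg:
        raise ParameterError("positive and negative control sets overlap")
    if not pos or not neg:
        raise ParameterError("control sets must be nonempty")
    fpr = len(called & neg) / len(neg)
    fnr = len(pos - called) / len(pos)
    return OperatingCharacteristics(fpr, fnr, 1.0 - fnr)


def gel50(called: np.ndarray, log2_fold_changes: np.ndarray,
          method: str = "logistic") -> Gel50Result:
    """Fold change at 50% detection probability.

    ``method='logistic'`` (default) fits call ~ log2FC by logistic
    regression and returns 2**(-beta0/beta1); ``method='median'`` returns
    the median fold change among called genes (the verbal reading of the
    definition), with the regression fields set to nan.
    """
    called = np.asarray(called, dtype=bool)
    lfc = np.asarray(log2_fold_changes, dtype=float)
    if called.shape != lfc.shape:
        raise StructuralError("calls and fold changes must align")
    if called.sum() < 2 or (~called).sum() < 2:
        raise ParameterError("need >=2 called and >=2 uncalled genes")
    if method == "median":
        return Gel50Result(float(2.0 ** np.median(lfc[called])),
                           np.nan, np.nan, False, False)
    if method != "logistic":
        raise ParameterError(f"unknown method {method!r}")
    X = sm.add_constant(lfc)
    separation = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(called.astype(float), X).fit(disp=0, maxiter=200)
        b0, b1 = fit.params
        if not np.all(np.isfinite(fit.bse)):
            separation = True
    except Exception:
        # perfect separation: fall back to the midpoint between the groups
        separation = True
        lo = lfc[called].min()
        hi = lfc[~called].max()
        mid = 0.5 * (lo + hi)
        b1 = np.inf
        b0 = -np.inf if mid > 0 else np.inf
        return Gel50Result(float(2.0 ** mid), b0, b1, True, False)
    if b1 == 0 or not np.isfinite(b1):
        return Gel50Result(np.nan, float(b0), float(b1), separation, True)
    return Gel50Result(float(2.0 ** (-b0 / b1)), float(b0), float(b1),
                       separation, False)


def leakiness_flag(abundance_sucrose_t0: float, max_abundance_qa: float):
    """(leaky, good_marker) on the raw 0-64,000 scale.

    Leaky means strictly above 1,000 counts on sucrose at t = 0; a good
    induction reporter is a non-leaky gene reaching strictly above 10,000
    counts on QA at some later time.
    """
    leaky = abundance_sucrose_t0 > LEAKY_SUCROSE_THRESHOLD
    good = (not leaky) and (max_abundance_qa > GOOD_MARKER_QA_THRESHOLD)
    return leaky, good


def max_fold_change(intensities: np.ndarray, aggregator: str = "max") -> np.ndarray:
    """Per-feature |log2 FC| of later time points vs t = 0.

    ``intensities`` is (n_times, n_features) of background-subtracted
    counts; a +1 offset keeps zeros finite. ``aggregator`` is 'max'
    (default) or 'mean' over the later time points.
    """
    x = np.asarray(intensities, dtype=float) + 1.0
    lfc = np.abs(np.log2(x[1:] / x[0]))
    if aggregator == "max":
        return lfc.max(axis=0)
    if aggregator == "mean":
        return lfc.mean(axis=0)
    raise ParameterError(f"unknown aggregator {aggregator!r}")


def overlap_counts(called_qa, called_starvation, called_qa1f, called_control,
                   universe) -> dict:
    """Three-set Venn region counts after removing control responders.

    Returns the seven region counts keyed by membership pattern (e.g.
    ``'qa&starvation'``) plus ``'none'``, the non-responding remainder.
    """
    universe = set(universe)
    ctrl = set(called_control) & universe
    a = (set(called_qa) & universe) - ctrl
    b = (set(called_starvation) & universe) - ctrl
    c = (set(called_qa1f) & universe) - ctrl
    regions = {
        "qa_only": len(a - b - c),
        "starvation_only": len(b - a - c),
        "qa1f_only": len(c - a - b),
        "qa&starvation": len((a & b) - c),
        "qa&qa1f": len((a & c) - b),
        "starvation&qa1f": len((b & c) - a),
        "qa&starvation&qa1f": len(a & b & c),
    }
    regions["none"] = len(universe) - len(ctrl) - len(a | b | c)
    return regions


def global_null_fdp(n_features: int = 11911, n_seeds: int = 50,
                    noise_sd_log2: float = 0.4, alpha: float = 0.10,
                    seed: int = 0, baseline: float = 1000.0) -> np.ndarray:
    """Realized false-discovery proportion of the full chain under a
    global null.

    Each replicate simulates ``n_features`` features over 8 time points as
    a constant baseline with i.i.d. multiplicative log-normal noise (no
    signal anywhere), runs background subtraction, robust Z normalization,
    the averaged OLS/LMS detection statistic and the Benjamini-Yekutieli
    step-up at ``alpha``, and records V / max(R, 1) -- which is 1 whenever
    anything is rejected, since every rejection is false. Returns the
    per-replicate FDP vector; its mean estimates the realized FDR.
    """
    from qanet.preprocess import normalize_chip
    from qanet.responders import identify_experiment
    from qanet.synth import make_chip_layout

    layout = make_chip_layout(n_features, 0, 0.0, seed=seed)
    root = np.random.SeedSequence(seed)
    fdps = np.empty(n_seeds)
    for i, child in enumerate(root.spawn(n_seeds)):
        rng = np.random.default_rng(child)
        raw = baseline * 2.0 ** rng.normal(0.0, noise_sd_log2,
                                           size=(8, n_features))
        z = np.stack([normalize_chip(raw[j], layout)[0] for j in range(8)])
        calls = identify_experiment(z, alpha=alpha, seed=int(
            child.generate_state(1)[0] % (2**31)))
        fdps[i] = 1.0 if calls.up.any() else 0.0
    return fdps


def diagnostics_table(rows: list) -> pd.DataFrame:
    """Assemble the per-experiment operating-characteristics report
    (columns: experiment, alpha, FPR, FNR, power, GEL50)."""
    return pd.DataFrame(rows, columns=["experiment", "alpha",
                                       "false_positive_rate",
                                       "false_negative_rate",
                                       "power", "gel50"])
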