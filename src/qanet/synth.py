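"""Synthetic microarray data with known truth labels.

The generator emulates the study design: 12K oligonucleotide chips with
11,911 gene-of-interest features (some genes duplicated) plus 633 negative
controls, four shift experiments (QA, starvation, QA in a *qa-1F* mutant,
and a sucrose-to-sucrose control), eight time points at 0, 0.5, 1, 1.5, 2,
4, 6 and 8 hr, raw scanner counts on a 0-64,000 scale, and the response
shapes observed among QA-responsive genes (immediate, gradual, delayed and
concave-down rises, plus transporters down-regulated in the control).

Observed intensity for feature k at time j of experiment i is

    clamp(baseline_k * 2**(shape_i(t_j) + eps), 0, 64000) + offset_i

with eps ~ N(0, noise_sd_log2) drawn independently per feature and time
point (duplicate features of one gene get independent noise) and offset_i a
small per-experiment additive scanner effect on the raw scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from qanet._errors import ParameterError, StructuralError

TIME_GRID_HR = np.array([0.0, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0])
EXPERIMENTS = ("qa", "starvation", "qa1f_mutant", "control")
INTENSITY_MAX = 64000.0

#: Gene classes. qa_* classes respond only in experiment 1 (leaky responders
#: differ only in baseline); starvation responds only in experiment 2; the
#: overlap class responds in both 1 and 2; down_regulated_in_control falls in
#: experiment 4; qa1f_mutant_responsive realizes the handful of spurious
#: experiment-3 calls seen on real chips; null is flat everywhere.
CLASSES = (
    "qa_responsive_immediate",
    "qa_responsive_gradual",
    "qa_responsive_delayed",
    "qa_responsive_concave",
    "leaky_qa_responsive",
    "starvation_responsive",
    "both_qa_and_starvation",
    "down_regulated_in_control",
    "qa1f_mutant_responsive",
    "null",
)

QA_CLASSES = frozenset(
    c for c in CLASSES if c.startswith("qa_responsive") or c in
    ("leaky_qa_responsive", "both_qa_and_starvation")
)


@dataclass(frozen=True)
class ChipLayout:
    """Feature layout of one chip design (identical across all 32 chips)."""

    feature_ids: tuple
    gene_of_feature: dict  # feature id -> gene id; negative controls absent
    negative_control_flags: np.ndarray
    spike_flags: np.ndarray

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def gene_mask(self) -> np.ndarray:
        return ~self.negative_control_flags

    @property
    def genes(self) -> tuple:
        seen = dict.fromkeys(
            self.gene_of_feature[f] for f in self.feature_ids
            if f in self.gene_of_feature
        )
        return tuple(seen)

    def features_of_gene(self) -> dict:
        out: dict = {}
        for f in self.feature_ids:
            g = self.gene_of_feature.get(f)
            if g is not None:
                out.setdefault(g, []).append(f)
        return out

    def __post_init__(self):
        n = len(self.feature_ids)
        if len(self.negative_control_flags) != n or len(self.spike_flags) != n:
            raise StructuralError("flag arrays must match feature count")
        for i, f in enumerate(self.feature_ids):
            if (f in self.gene_of_feature) == bool(self.negative_control_flags[i]):
                raise StructuralError(
                    f"feature {f}: negative controls map to no gene and "
                    "gene features must map to one"
                )


@dataclass(frozen=True)
class TruthLabels:
    """Per-gene class and shape parameters of the planted signal."""

    table: pd.DataFrame  # index gene id; cls, baseline, log2_fold, delay_hr, peak_hr

    @property
    def class_of_gene(self) -> dict:
        return self.table["cls"].to_dict()

    def genes_of_class(self, cls: str) -> list:
        return list(self.table.index[self.table["cls"] == cls])


@dataclass(frozen=True)
class ChipSet:
    """Raw intensities for all experiments, time points and features."""

    intensities: np.ndarray  # (n_experiments, n_times, n_features)
    time_grid_hr: np.ndarray = field(default_factory=lambda: TIME_GRID_HR.copy())
    scanner_offsets: np.ndarray = field(default_factory=lambda: np.zeros(4))
    experiments: tuple = EXPERIMENTS
    n_clamped: int = 0

    def __post_init__(self):
        if self.intensities.ndim != 3:
            raise StructuralError("intensities must be 3-d (experiment, time, feature)")
        if self.intensities.shape[1] != len(self.time_grid_hr):
            raise StructuralError("time grid does not match intensity array")
        if np.any(np.diff(self.time_grid_hr) <= 0):
            raise StructuralError("time grid must be strictly increasing")


@dataclass(frozen=True)
class TruthConfig:
    """Class composition and shape-parameter ranges of the planted truth.

    Defaults mirror the magnitudes of the study's own results so pipeline
    outputs are comparable: ~50 QA-responsive features' worth of genes, 49
    starvation responders, 5 genes responding to both, 2 spurious responders
    in the qa-1F mutant experiment.
    """

    n_qa_immediate: int = 20
    n_qa_gradual: int = 10
    n_qa_delayed: int = 10
    n_qa_concave: int = 5
    n_leaky: int = 5
    n_starvation: int = 49
    n_both: int = 5
    n_down_in_control: int = 10
    n_qa1f_spurious: int = 2
    baseline_range: tuple = (100.0, 5000.0)
    leaky_baseline_range: tuple = (1500.0, 5000.0)
    negctl_baseline_range: tuple = (200.0, 2500.0)
    log2_fold_range: tuple = (2.0, 4.0)
    delay_range_hr: tuple = (2.0, 4.0)
    peak_range_hr: tuple = (1.5, 3.0)

    def planted_counts(self) -> dict:
        return {
            "qa_responsive_immediate": self.n_qa_immediate,
            "qa_responsive_gradual": self.n_qa_gradual,
            "qa_responsive_delayed": self.n_qa_delayed,
            "qa_responsive_concave": self.n_qa_concave,
            "leaky_qa_responsive": self.n_leaky,
            "starvation_responsive": self.n_starvation,
            "both_qa_and_starvation": self.n_both,
            "down_regulated_in_control": self.n_down_in_control,
            "qa1f_mutant_responsive": self.n_qa1f_spurious,
        }


def make_chip_layout(n_genes: int, n_negative: int, duplicate_fraction: float,
                     seed: int, n_spike_groups: int = 4,
                     spike_replicates: int = 22) -> ChipLayout:
    """Build a chip layout with ``n_genes`` gene-of-interest features.

    ``duplicate_fraction`` of the gene features are duplicate copies of
    already-present genes (chosen uniformly at random), so the number of
    distinct genes is ``n_genes - round(duplicate_fraction * n_genes)``.
    Spike quality-control features (``n_spike_groups`` distinct spikes x
    ``spike_replicates``) are flagged among the negative controls.
    Deterministic given ``seed``.
    """
    if n_genes < 0 or n_negative < 0:
        raise ParameterError("feature counts must be nonnegative")
    if not (0 <= duplicate_fraction < 1):
        raise ParameterError("duplicate_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed)

    n_dup = int(round(duplicate_fraction * n_genes))
    n_distinct = n_genes - n_dup
    if n_genes > 0 and n_distinct == 0:
        raise ParameterError("duplicate_fraction leaves no distinct genes")

    genes = [f"G{i:05d}" for i in range(n_distinct)]
    gene_assignment = list(genes)
    if n_dup:
        extra = rng.choice(n_distinct, size=n_dup, replace=n_dup > n_distinct)
        gene_assignment += [genes[i] for i in np.sort(extra)]

    feature_ids = [f"F{i:05d}" for i in range(n_genes)] + \
                  [f"NC{i:04d}" for i in range(n_negative)]
    gene_of_feature = {f"F{i:05d}": gene_assignment[i] for i in range(n_genes)}
    neg = np.zeros(n_genes + n_negative, dtype=bool)
    neg[n_genes:] = True
    spikes = np.zeros_like(neg)
    n_spikes = min(n_negative, n_spike_groups * spike_replicates)
    if n_spikes:
        spikes[n_genes:n_genes + n_spikes] = True
    return ChipLayout(tuple(feature_ids), gene_of_feature, neg, spikes)


def _shape_matrix(cls: str, params: pd.Series, t: np.ndarray) -> np.ndarray:
    """Planted log2 deviation from baseline, per experiment (4, n_times)."""
    if cls == "null":
        return np.zeros((4, len(t)))
    A = params["log2_fold"]
    d = params["delay_hr"]
    p = params["peak_hr"]
    t_end = t[-1]
    immediate = A * np.minimum(t / 0.5, 1.0)
    gradual = A * t / t_end
    delayed = A * np.clip((t - d) / (t_end - d), 0.0, 1.0)
    rise = np.minimum(t / p, 1.0)
    fall = np.clip((t - p) / (t_end - p), 0.0, 1.0)
    concave = A * (rise - 0.75 * fall)
    down = -A * t / t_end

    shapes = np.zeros((4, len(t)))
    if cls in ("qa_responsive_immediate", "leaky_qa_responsive"):
        shapes[0] = immediate
    elif cls == "qa_responsive_gradual":
        shapes[0] = gradual
    elif cls == "qa_responsive_delayed":
        shapes[0] = delayed
    elif cls == "qa_responsive_concave":
        shapes[0] = concave
    elif cls == "starvation_responsive":
        shapes[1] = immediate
    elif cls == "both_qa_and_starvation":
        shapes[0] = immediate
        shapes[1] = immediate
    elif cls == "down_regulated_in_control":
        shapes[3] = down
    elif cls == "qa1f_mutant_responsive":
        shapes[2] = immediate
    elif cls != "null":
        raise ParameterError(f"unknown gene class {cls!r}")
    return shapes


def make_truth(layout: ChipLayout, config: TruthConfig, seed: int) -> TruthLabels:
    """Assign classes and shape parameters to the genes of a layout."""
    rng = np.random.default_rng(seed)
    genes = list(layout.genes)
    counts = config.planted_counts()
    total_planted = sum(counts.values())
    if total_planted > len(genes):
        raise StructuralError(
            f"cannot plant {total_planted} responders among {len(genes)} genes"
        )
    order = rng.permutation(len(genes))
    rows = []
    cursor = 0
    lo_b, hi_b = config.baseline_range
    for cls, n in counts.items():
        for _ in range(n):
            g = genes[order[cursor]]
            cursor += 1
            if cls == "leaky_qa_responsive":
                lo, hi = config.leaky_baseline_range
            else:
                lo, hi = lo_b, hi_b
            rows.append({
                "gene": g,
                "cls": cls,
                "baseline": np.exp(rng.uniform(np.log(lo), np.log(hi))),
                "log2_fold": rng.uniform(*config.log2_fold_range),
                "delay_hr": rng.uniform(*config.delay_range_hr),
                "peak_hr": rng.uniform(*config.peak_range_hr),
            })
    for i in order[cursor:]:
        rows.append({
            "gene": genes[i],
            "cls": "null",
            "baseline": np.exp(rng.uniform(np.log(lo_b), np.log(hi_b))),
            "log2_fold": 0.0,
            "delay_hr": 0.0,
            "peak_hr": 0.0,
        })
    table = pd.DataFrame(rows).set_index("gene").loc[genes]
    return TruthLabels(table)


def simulate_experiment_set(layout: ChipLayout,
                            truth_config: TruthConfig | None = None,
                            noise_sd_log2: float = 0.4,
                            seed: int = 0,
                            truth: TruthLabels | None = None):
    """Simulate raw intensities for all four experiments.

    Returns ``(ChipSet, TruthLabels)``. A pre-built ``truth`` may be passed
    (it must cover exactly the layout's genes); otherwise labels are drawn
    from ``truth_config``.
    """
    if noise_sd_log2 < 0:
        raise ParameterError("noise_sd_log2 must be nonnegative")
    rng = np.random.default_rng(seed)
    if truth is None:
        truth = make_truth(layout, truth_config or TruthConfig(), seed=rng.integers(2**31))
    if set(truth.table.index) != set(layout.genes):
        raise StructuralError("truth labels do not cover the layout's genes")

    t = TIME_GRID_HR
    n_feat = layout.n_features
    log2_mean = np.zeros((4, len(t), n_feat))
    baseline = np.zeros(n_feat)

    neg_lo, neg_hi = (truth_config or TruthConfig()).negctl_baseline_range
    gene_rows = {g: truth.table.loc[g] for g in truth.table.index}
    shape_cache = {g: _shape_matrix(row["cls"], row, t)
                   for g, row in gene_rows.items()}
    # 4 distinct spike oligos at fixed concentrations; replicates of one
    # spike share a baseline so the spike CV reflects noise alone
    spike_levels = (250.0, 500.0, 1000.0, 2000.0)
    n_spike_seen = 0
    for idx, f in enumerate(layout.feature_ids):
        g = layout.gene_of_feature.get(f)
        if g is None:
            if layout.spike_flags[idx]:
                baseline[idx] = spike_levels[n_spike_seen % len(spike_levels)]
                n_spike_seen += 1
            else:
                baseline[idx] = np.exp(rng.uniform(np.log(neg_lo), np.log(neg_hi)))
            continue
        baseline[idx] = gene_rows[g]["baseline"]
        log2_mean[:, :, idx] = shape_cache[g]

    noise = rng.normal(0.0, noise_sd_log2, size=log2_mean.shape) \
        if noise_sd_log2 > 0 else 0.0
    raw = baseline[None, None, :] * 2.0 ** (log2_mean + noise)
    offsets = rng.uniform(0.0, 200.0, size=4)
    raw = raw + offsets[:, None, None]
    clamped = int(np.sum((raw < 0) | (raw > INTENSITY_MAX)))
    raw = np.clip(raw, 0.0, INTENSITY_MAX)
    return ChipSet(raw, t.copy(), offsets, EXPERIMENTS, clamped), truth


def simulate_from_network(model, theta, mapping: dict, layout: ChipLayout | None = None,
                          noise_sd_log2: float = 0.0, seed: int = 0,
                          scale: dict | None = None, step_h: float = 0.01) -> ChipSet:
    """Simulate a one-experiment ChipSet from an ODE network trajectory.

    ``mapping`` maps gene id -> mRNA species name; sampled trajectories are
    scaled per gene (default 1.0) and noised multiplicatively on the log2
    scale. Experiments 2-4 are filled with the time-0 value held flat, so
    the result slots into the four-experiment pipeline as a pure QA signal.
    """
    from qanet._errors import MappingError
    from qanet.network import solve_modified_euler

    name_to_idx = {s.name: i for i, s in enumerate(model.species)}
    for g, sp in mapping.items():
        if sp not in name_to_idx:
            raise MappingError(f"unknown mRNA species {sp!r}")
    rng = np.random.default_rng(seed)
    traj = solve_modified_euler(model, theta, TIME_GRID_HR, step_h=step_h)
    genes = list(mapping)
    n = len(genes)
    prof = np.stack([traj.states[:, name_to_idx[mapping[g]]] for g in genes], axis=1)
    sc = np.array([1.0 if scale is None else scale.get(g, 1.0) for g in genes])
    prof = prof * sc[None, :]
    raw = np.zeros((4, len(TIME_GRID_HR), n))
    raw[0] = prof
    raw[1:] = prof[0][None, None, :]
    if noise_sd_log2 > 0:
        raw = raw * 2.0 ** rng.normal(0.0, noise_sd_log2, size=raw.shape)
    clamped = int(np.sum((raw < 0) | (raw > INTENSITY_MAX)))
    raw = np.clip(raw, 0.0, INTENSITY_MAX)
    return ChipSet(raw, TIME_GRID_HR.copy(), np.zeros(4), EXPERIMENTS, clamped)


def plant_upstream_sequences(genes: list, patterns: list, plant_fraction: float,
                             length: int = 1000, seed: int = 0,
                             planted_mismatches: int = 0):
    """Generate i.i.d. uniform upstream sequences with planted motif sites.

    For ``round(plant_fraction * len(genes))`` genes (chosen at random) one
    pattern instance is embedded at a random offset, with
    ``planted_mismatches`` random mismatches at specified positions. Returns
    ``(dict gene -> sequence, DataFrame truth table)`` with columns gene,
    pattern, offset, mismatch_count.
    """
    if not (0 <= plant_fraction <= 1):
        raise ParameterError("plant_fraction must be in [0, 1]")
    for p in patterns:
        if p.length > length:
            raise ParameterError(f"pattern {p.source} longer than sequence")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACGT"))
    seqs = {}
    n_plant = int(round(plant_fraction * len(genes)))
    planted = set(rng.choice(len(genes), size=n_plant, replace=False)) if n_plant else set()
    rows = []
    for i, g in enumerate(genes):
        s = rng.integers(0, 4, size=length)
        if i in planted:
            pat = patterns[rng.integers(len(patterns))]
            offset = int(rng.integers(0, length - pat.length + 1))
            site = pat.realize(rng)
            mism_pos = rng.choice(len(pat.positions),
                                  size=min(planted_mismatches, len(pat.positions)),
                                  replace=False)
            n_mism = 0
            for j in mism_pos:
                rel, allowed = pat.positions[j]
                cur = site[rel]
                choices = [b for b in "ACGT" if b not in allowed]
                if choices:
                    site[rel] = choices[rng.integers(len(choices))]
                    n_mism += 1
            for rel, base in enumerate(site):
                s[offset + rel] = "ACGT".index(base)
            rows.append({"gene": g, "pattern": pat.source, "offset": offset,
                         "mismatch_count": n_mism})
        seqs[g] = "".join(alphabet[s])
    truth = pd.DataFrame(rows, columns=["gene", "pattern", "offset", "mismatch_count"])
    return seqs, truth
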